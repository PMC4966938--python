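"""Genomic complexity: fraction of the genome with aberrant copy number.

Complexity is the percent of analyzed base pairs whose copy-number estimate
exceeds the aberration cutoff (default +/-0.1), a fraction-of-genome-altered
measure of chromosomal instability. The denominator is the retained
(post-filter) autosomal territory the segments cover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AlleleSpecificProfile, AtomicSegmentMatrix, CohortTable, SegmentedProfile
from .segmentation import call_aberrations

logger = logging.getLogger("methet")


@dataclass(frozen=True)
class ComplexityResult:
    sample_id: str
    percent_bp_aberrant: float
    cutoff: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_bp_aberrant <= 100.0):
            raise ValueError("percent aberrant outside [0, 100]")


def genomic_complexity(
    profile: SegmentedProfile, cutoff: float = 0.1
) -> ComplexityResult:
    """Percent of covered base pairs in segments called gain or loss."""
    if not profile.segments:
        raise ValueError(f"{profile.sample_id}: empty profile")
    lengths = np.array([s.end_bp - s.start_bp + 1 for s in profile.segments], float)
    estimates = np.array([s.estimate for s in profile.segments])
    calls = call_aberrations(estimates, cutoff)
    percent = 100.0 * lengths[calls != 0].sum() / lengths.sum()
    return ComplexityResult(profile.sample_id, float(percent), cutoff)


def patient_complexity(
    profiles: Sequence[SegmentedProfile], cutoff: float = 0.1
) -> float:
    """Arithmetic mean complexity over a patient's first-resection deposits."""
    if not profiles:
        raise ValueError("no profiles for patient")
    return float(
        np.mean([genomic_complexity(p, cutoff).percent_bp_aberrant for p in profiles])
    )


def cohort_complexity(
    profiles: Sequence[SegmentedProfile],
    cohort: CohortTable,
    cutoff: float = 0.1,
) -> pd.DataFrame:
    """Sample- and patient-level complexity for first-resection deposits.

    Returns a patient-level frame (patient_id, complexity, n_samples); the
    per-sample values are averaged within patient.
    """
    by_id = {p.sample_id: p for p in profiles}
    rows = []
    for pid in cohort.patient_ids:
        samples = [s for s in cohort.samples_of(pid, resection=1) if s in by_id]
        if not samples:
            rows.append((pid, np.nan, 0))
            continue
        rows.append((pid, patient_complexity([by_id[s] for s in samples], cutoff),
                     len(samples)))
    return pd.DataFrame(rows, columns=["patient_id", "complexity", "n_samples"])


def patientwise_aberration_frequency(
    atoms: AtomicSegmentMatrix,
    cohort: CohortTable,
    cutoff: float = 0.1,
) -> pd.DataFrame:
    """Per-atom fraction of patients with >=1 gained (resp. lost) deposit.

    A patient counts as having an aberration if any of their deposits shows
    it, so a patient with one gained and one lost deposit contributes to both
    frequencies at that atom.
    """
    calls = call_aberrations(atoms.estimates, cutoff)
    patient_ids = []
    gain_rows = []
    loss_rows = []
    in_matrix = set(atoms.samples)
    for pid in cohort.patient_ids:
        samples = [s for s in cohort.samples_of(pid) if s in in_matrix]
        if not samples:
            continue
        idx = [atoms.sample_index(s) for s in samples]
        patient_ids.append(pid)
        gain_rows.append((calls[idx] == 1).any(axis=0))
        loss_rows.append((calls[idx] == -1).any(axis=0))
    if not patient_ids:
        raise ValueError("no patients with samples in the matrix")
    out = atoms.atoms[["chrom", "start_bp", "end_bp", "length_bp"]].copy()
    out["gain_freq"] = np.stack(gain_rows).mean(axis=0)
    out["loss_freq"] = np.stack(loss_rows).mean(axis=0)
    return out


def cnloh_fraction(profile: AlleleSpecificProfile) -> float:
    """Percent of base pairs with allele copies {0, 2} (copy-neutral LOH)."""
    seg = profile.segments
    lengths = (seg["end_bp"] - seg["start_bp"] + 1).to_numpy(dtype=float)
    lo = np.minimum(seg["nA"], seg["nB"]).to_numpy()
    hi = np.maximum(seg["nA"], seg["nB"]).to_numpy()
    is_cnloh = (lo == 0) & (hi == 2)
    total = lengths.sum()
    if total == 0:
        return 0.0
    return float(100.0 * lengths[is_cnloh].sum() / total)
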