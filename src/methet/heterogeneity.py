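"""Intra-patient inter-metastatic heterogeneity scores.

A patient's heterogeneity is the mean pairwise Euclidean distance between
the atomic-segment copy-number estimate vectors of their metastatic
deposits. Atoms enter the distance as unweighted dimensions; a cross-sample
variance filter (default > 0.03, sample variance) keeps only informative
atoms. The proportion-of-genome-different variant instead sums base pairs
where two deposits differ by more than a cutoff, with no variance filter.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import AlleleSpecificProfile, AtomicSegmentMatrix, CohortTable
from .segmentation import atomic_segments

logger = logging.getLogger("methet")


@dataclass(frozen=True)
class HeterogeneityResult:
    patient_id: str
    score: Optional[float]
    method: str  # euclidean | proportion_genome | euclidean_ploidy_adjusted
    n_samples: int
    n_pairs: int
    variance_filter: Optional[float]
    n_atoms_used: int
    reason: Optional[str] = None  # set when the score is absent

    @property
    def available(self) -> bool:
        return self.score is not None


def variance_filter(
    matrix: AtomicSegmentMatrix, cutoff: Optional[float] = 0.03
) -> AtomicSegmentMatrix:
    """Keep atoms whose across-sample variance (ddof=1) strictly exceeds cutoff.

    The variance is taken across all samples in the supplied analysis set.
    ``cutoff=None`` is the identity.
    """
    if cutoff is None:
        return matrix
    if matrix.estimates.shape[0] < 2:
        raise ValueError("variance filter needs at least two samples")
    var = matrix.estimates.var(axis=0, ddof=1)
    keep = var > cutoff
    if not keep.any():
        raise ValueError(
            "no atoms exceed the variance cutoff; rerun with cutoff=None"
        )
    logger.info(
        "variance filter %.3g: retained %d/%d atoms (%.1f%%)",
        cutoff, int(keep.sum()), len(keep), 100 * keep.mean(),
    )
    return matrix.subset_atoms(keep)


def pairwise_euclidean(a: np.ndarray, b: np.ndarray) -> float:
    """sqrt(sum of squared per-atom differences); atoms are unweighted."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def patient_heterogeneity(
    matrix: AtomicSegmentMatrix,
    patient_samples: Sequence[str],
    patient_id: str = "",
    variance_cutoff: Optional[float] = 0.03,
) -> HeterogeneityResult:
    """Mean pairwise Euclidean distance among a patient's deposits.

    The variance filter is computed across *all* samples in ``matrix`` (the
    full analysis set), then distances are averaged over the patient's
    unordered sample pairs. Patients with fewer than two deposits get an
    absent score with a reason.
    """
    pid = patient_id or (patient_samples[0] if patient_samples else "?")
    if len(patient_samples) < 2:
        return HeterogeneityResult(
            pid, None, "euclidean", len(patient_samples), 0, variance_cutoff, 0,
            reason="fewer than two deposits",
        )
    filtered = variance_filter(matrix, variance_cutoff)
    vecs = [filtered.sample_values(s) for s in patient_samples]
    dists = [
        pairwise_euclidean(x, y) for x, y in itertools.combinations(vecs, 2)
    ]
    return HeterogeneityResult(
        pid, float(np.mean(dists)), "euclidean", len(patient_samples),
        len(dists), variance_cutoff, filtered.n_atoms,
    )


def proportion_genome_different(
    matrix: AtomicSegmentMatrix,
    patient_samples: Sequence[str],
    patient_id: str = "",
    diff_cutoff: float = 0.1,
) -> HeterogeneityResult:
    """Mean pairwise percent of base pairs with copy-number differences.

    Per pair: sum of atom lengths where |a - b| > diff_cutoff (strict),
    divided by the total covered length, times 100. No variance pre-filter.
    """
    pid = patient_id or (patient_samples[0] if patient_samples else "?")
    if len(patient_samples) < 2:
        return HeterogeneityResult(
            pid, None, "proportion_genome", len(patient_samples), 0, None,
            matrix.n_atoms, reason="fewer than two deposits",
        )
    lengths = matrix.lengths_bp.astype(float)
    total = lengths.sum()
    vecs = [matrix.sample_values(s) for s in patient_samples]
    props = [
        100.0 * lengths[np.abs(x - y) > diff_cutoff].sum() / total
        for x, y in itertools.combinations(vecs, 2)
    ]
    return HeterogeneityResult(
        pid, float(np.mean(props)), "proportion_genome", len(patient_samples),
        len(props), None, matrix.n_atoms,
    )


def longitudinal_heterogeneity(
    matrix: AtomicSegmentMatrix,
    first_samples: Sequence[str],
    second_samples: Sequence[str],
    patient_id: str = "",
    variance_cutoff: Optional[float] = 0.03,
    cross_pairs_only: bool = True,
) -> HeterogeneityResult:
    """Mean Euclidean distance between first- and second-resection deposits.

    Pairs are cross-resection (first x second) by default; the all-pairs
    alternative over the union is available via ``cross_pairs_only=False``.
    """
    pid = patient_id or "?"
    if not first_samples or not second_samples:
        return HeterogeneityResult(
            pid, None, "euclidean", len(first_samples) + len(second_samples), 0,
            variance_cutoff, 0, reason="a resection has no samples",
        )
    filtered = variance_filter(matrix, variance_cutoff)
    if cross_pairs_only:
        pairs = list(itertools.product(first_samples, second_samples))
    else:
        pairs = list(itertools.combinations(list(first_samples) + list(second_samples), 2))
    logger.info("%s: longitudinal pairs %s", pid, pairs)
    dists = [
        pairwise_euclidean(filtered.sample_values(a), filtered.sample_values(b))
        for a, b in pairs
    ]
    return HeterogeneityResult(
        pid, float(np.mean(dists)), "euclidean",
        len(set(first_samples) | set(second_samples)), len(dists),
        variance_cutoff, filtered.n_atoms,
    )


def ploidy_adjusted_heterogeneity(
    profiles: Sequence[AlleleSpecificProfile],
    patient_samples: Sequence[str],
    patient_id: str = "",
) -> HeterogeneityResult:
    """Euclidean score over total copies divided by sample ploidy; no filter.

    Works on the atomic partition of the allele-specific profiles'
    breakpoints; deposits with a missing profile are skipped (logged).
    """
    pid = patient_id or "?"
    by_id = {p.sample_id: p for p in profiles}
    usable = [s for s in patient_samples if s in by_id]
    skipped = [s for s in patient_samples if s not in by_id]
    if skipped:
        logger.info("%s: no allele-specific profile for %s; skipped", pid, skipped)
    if len(usable) < 2:
        return HeterogeneityResult(
            pid, None, "euclidean_ploidy_adjusted", len(usable), 0, None, 0,
            reason="fewer than two deposits with allele-specific profiles",
        )
    # express each profile as a segmented profile of ploidy-adjusted copies
    from .core import Segment, SegmentedProfile

    seg_profiles = []
    for s in usable:
        prof = by_id[s]
        segs = [
            Segment(str(r.chrom), int(r.start_bp), int(r.end_bp), 0,
                    (r.nA + r.nB) / prof.ploidy)
            for r in prof.segments.itertuples()
        ]
        seg_profiles.append(SegmentedProfile(sample_id=s, segments=segs))
    atoms = atomic_segments(seg_profiles)
    vecs = [atoms.sample_values(s) for s in usable]
    dists = [pairwise_euclidean(x, y) for x, y in itertools.combinations(vecs, 2)]
    return HeterogeneityResult(
        pid, float(np.mean(dists)), "euclidean_ploidy_adjusted", len(usable),
        len(dists), None, atoms.n_atoms,
    )


def ccf_diversity(cohort: CohortTable, patient_id: str) -> Optional[float]:
    """Mean absolute pairwise difference in cancer-cell fraction.

    Deposits with a missing fraction are excluded; absent if fewer than two
    usable deposits remain.
    """
    samples = cohort.samples_of(patient_id, resection=1)
    ccfs = [cohort.ccf_of(s) for s in samples]
    ccfs = [c for c in ccfs if not np.isnan(c)]
    if len(ccfs) < 2:
        return None
    diffs = [abs(a - b) for a, b in itertools.combinations(ccfs, 2)]
    return float(np.mean(diffs))


def cohort_heterogeneity(
    matrix: AtomicSegmentMatrix,
    cohort: CohortTable,
    method: str = "euclidean",
    variance_cutoff: Optional[float] = 0.03,
    diff_cutoff: float = 0.1,
) -> list[HeterogeneityResult]:
    """Per-patient scores over first-resection deposits for a whole cohort."""
    results = []
    in_matrix = set(matrix.samples)
    for pid in cohort.patient_ids:
        samples = [s for s in cohort.samples_of(pid, resection=1) if s in in_matrix]
        if method == "euclidean":
            results.append(
                patient_heterogeneity(matrix, samples, pid, variance_cutoff)
            )
        elif method == "proportion_genome":
            results.append(
                proportion_genome_different(matrix, samples, pid, diff_cutoff)
            )
        else:
            raise ValueError(f"unknown method {method!r}")
    return results
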