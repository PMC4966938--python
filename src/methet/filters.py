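"""Probe exclusion: class-based filters and the non-cancer region blacklist.

Regions recurrently aberrant in non-cancer tissue reflect germline copy
number variation or platform artefacts; markers inside them are removed
before any tumor analysis. A region qualifies if its aberration frequency
is strictly above the threshold in *every* supplied non-cancer cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AtomicSegmentMatrix, LRRMatrix, SegmentedProfile
from .genome import is_autosome

logger = logging.getLogger("methet")


@dataclass(frozen=True)
class RegionBlacklist:
    """Merged, non-overlapping excluded regions with per-cohort provenance."""

    regions: pd.DataFrame  # columns: chrom, start_bp, end_bp [, freq_<cohort>...]

    def __post_init__(self) -> None:
        for chrom, g in self.regions.groupby("chrom"):
            g = g.sort_values("start_bp")
            if (g["start_bp"].to_numpy()[1:] <= g["end_bp"].to_numpy()[:-1]).any():
                raise ValueError(f"blacklist regions overlap on {chrom}")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def total_bp(self) -> int:
        if self.regions.empty:
            return 0
        return int((self.regions["end_bp"] - self.regions["start_bp"] + 1).sum())

    def contains(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: position inside a closed blacklist interval."""
        chroms = np.asarray(chroms)
        positions = np.asarray(positions)
        mask = np.zeros(len(positions), dtype=bool)
        for chrom, g in self.regions.groupby("chrom"):
            sel = chroms == chrom
            if not sel.any():
                continue
            pos = positions[sel]
            starts = g["start_bp"].to_numpy()
            ends = g["end_bp"].to_numpy()
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            idx = np.searchsorted(starts, pos, side="right") - 1
            inside = (idx >= 0) & (pos <= ends[np.clip(idx, 0, len(ends) - 1)])
            mask[np.flatnonzero(sel)[inside]] = True
        return mask

    @classmethod
    def empty(cls) -> "RegionBlacklist":
        return cls(pd.DataFrame(columns=["chrom", "start_bp", "end_bp"]))


def region_aberration_frequency(
    atoms: AtomicSegmentMatrix, cutoff: float = 0.1
) -> np.ndarray:
    """Per-atom fraction of samples whose |estimate| exceeds the cutoff.

    Gains and losses both count as aberrant; the comparison is strict.
    """
    if atoms.estimates.shape[0] == 0:
        raise ValueError("empty cohort: no samples to compute frequencies from")
    aberrant = np.abs(atoms.estimates) > cutoff
    return aberrant.mean(axis=0)


def build_blacklist(
    cohorts: Sequence[AtomicSegmentMatrix],
    freq_threshold: float = 0.10,
    aberration_cutoff: float = 0.1,
) -> RegionBlacklist:
    """Regions aberrant in > ``freq_threshold`` of samples in EVERY cohort.

    All cohorts must be segmented on the same atomic partition; flagged
    atoms are merged into maximal contiguous intervals.
    """
    if not cohorts:
        raise ValueError("at least one non-cancer cohort is required")
    ref = cohorts[0].atoms[["chrom", "start_bp", "end_bp"]].reset_index(drop=True)
    for other in cohorts[1:]:
        got = other.atoms[["chrom", "start_bp", "end_bp"]].reset_index(drop=True)
        if not ref.equals(got):
            raise ValueError("cohorts are segmented on mismatched atomic partitions")

    freqs = np.stack(
        [region_aberration_frequency(c, aberration_cutoff) for c in cohorts]
    )
    flagged = (freqs > freq_threshold).all(axis=0)

    rows = []
    current: Optional[list] = None
    for i, atom in enumerate(ref.itertuples()):
        if not flagged[i]:
            current = None
            continue
        f = freqs[:, i]
        if (
            current is not None
            and atom.chrom == current[0]
            and atom.start_bp == current[2] + 1
        ):
            current[2] = atom.end_bp
            current[3].append(f)
        else:
            current = [atom.chrom, atom.start_bp, atom.end_bp, [f]]
            rows.append(current)

    records = []
    n_cohorts = len(cohorts)
    for chrom, start, end, fs in rows:
        mean_f = np.mean(np.stack(fs), axis=0)
        records.append((chrom, start, end, *mean_f))
    cols = ["chrom", "start_bp", "end_bp"] + [f"freq_cohort{i}" for i in range(n_cohorts)]
    regions = pd.DataFrame(records, columns=cols)
    logger.info(
        "blacklist: %d regions, %s bp (threshold %.3g, %d cohorts)",
        len(regions),
        int((regions["end_bp"] - regions["start_bp"] + 1).sum()) if len(regions) else 0,
        freq_threshold,
        n_cohorts,
    )
    return RegionBlacklist(regions)


def apply_filters(
    matrix: LRRMatrix,
    blacklist: Optional[RegionBlacklist] = None,
    drop_control: bool = True,
    drop_duplicates: bool = True,
) -> LRRMatrix:
    """Remove allosomal, control, duplicate, and blacklisted probes.

    Duplicate probes (identical chrom+pos) keep the first in genomic order.
    Idempotent; an empty result is allowed with a warning.
    """
    table = matrix.panel.table
    keep = np.ones(len(table), dtype=bool)

    auto = table["chrom"].map(is_autosome).to_numpy()
    n_allo = int((~auto).sum())
    keep &= auto

    n_control = 0
    if drop_control:
        is_control = (table["probe_class"] == "control").to_numpy()
        n_control = int((keep & is_control).sum())
        keep &= ~is_control

    n_dup = 0
    if drop_duplicates:
        dup = table.duplicated(subset=["chrom", "pos"], keep="first").to_numpy()
        n_dup = int((keep & dup).sum())
        keep &= ~dup

    n_black = 0
    if blacklist is not None and blacklist.n_regions:
        inside = blacklist.contains(table["chrom"].to_numpy(), table["pos"].to_numpy())
        n_black = int((keep & inside).sum())
        keep &= ~inside

    logger.info(
        "probe filters: dropped %d allosomal, %d control, %d duplicate, "
        "%d blacklisted; %d probes retained",
        n_allo, n_control, n_dup, n_black, int(keep.sum()),
    )
    if not keep.any():
        logger.warning("probe filters removed every probe")
    return matrix.subset_probes(keep)
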