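"""Piecewise-constant copy-number segmentation.

The segmentation model minimizes, per chromosome,

    sum_over_segments SSE(segment) + gamma * (number_of_segments - 1)

subject to every segment containing at least ``k_min`` probes, where SSE is
the within-segment sum of squared deviations from the segment mean. The
minimizer is computed *exactly* by an O(n^2) dynamic program over breakpoint
positions (not the pruned heuristic of common implementations). The segment
mean log-ratio is the segment's copy-number estimate.

With ``normalize=True`` (default) the penalty is applied on the scale of the
per-sample noise variance (gamma * sigma_hat^2, sigma_hat from MAD of lagged
differences), so the conventional gamma=100 behaves consistently across
noise levels. ``normalize=False`` penalizes raw SSE exactly as written above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AtomicSegmentMatrix, LRRMatrix, Segment, SegmentedProfile
from .genome import chrom_sort_key

logger = logging.getLogger("methet")

_MIN_SIGMA = 1e-4  # noise floor so noiseless data still prefers fewer segments


@dataclass(frozen=True)
class SegmentationParams:
    """Tuning constants for winsorization and PCF.

    gamma: per-breakpoint penalty (conventional value 100).
    k_min: minimum probes per segment (conventional value 5).
    winsor_window: centered running window, in probes (odd).
    winsor_tau: clamp width in MAD-based standard deviations.
    normalize: scale the penalty by the estimated noise variance.
    """

    gamma: float = 100.0
    k_min: int = 5
    winsor_window: int = 25
    winsor_tau: float = 2.5
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")
        if self.winsor_window % 2 != 1:
            raise ValueError("winsor_window must be odd")


# ---------------------------------------------------------------------------
# Winsorization


def winsorize(values: np.ndarray, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Clamp outliers against a running median +/- tau * running MAD.

    The window of ``winsor_window`` probes is centered and truncated at the
    chromosome ends. MAD is scaled by 1.4826 to estimate a Gaussian SD; a
    zero MAD clamps the value to the window median.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n == 0:
        return y.copy()
    k = min(params.winsor_window, n if n % 2 == 1 else n - 1)
    k = max(k, 1)
    half = k // 2

    med = np.empty(n)
    mad = np.empty(n)
    if n >= k:
        from numpy.lib.stride_tricks import sliding_window_view

        windows = sliding_window_view(y, k)
        m = np.median(windows, axis=1)
        s = np.median(np.abs(windows - m[:, None]), axis=1)
        med[half : n - half] = m
        mad[half : n - half] = s
    for i in list(range(half)) + list(range(n - half, n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        w = y[lo:hi]
        med[i] = np.median(w)
        mad[i] = np.median(np.abs(w - med[i]))

    sd = 1.4826 * mad
    lo_b = med - params.winsor_tau * sd
    hi_b = med + params.winsor_tau * sd
    return np.clip(y, lo_b, hi_b)


def impute_missing(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Fill NaNs with the nearest observed neighbor (ties to the left).

    Returns the dense vector and the number of imputed probes.
    """
    y = np.asarray(values, dtype=float).copy()
    nan = np.isnan(y)
    n_missing = int(nan.sum())
    if n_missing == 0:
        return y, 0
    if n_missing == len(y):
        raise ValueError("cannot impute a fully missing chromosome")
    idx = np.flatnonzero(~nan)
    targets = np.flatnonzero(nan)
    right = np.searchsorted(idx, targets)
    left = np.clip(right - 1, 0, len(idx) - 1)
    right = np.clip(right, 0, len(idx) - 1)
    d_left = np.abs(targets - idx[left])
    d_right = np.abs(idx[right] - targets)
    nearest = np.where(d_left <= d_right, idx[left], idx[right])
    y[targets] = y[nearest]
    return y, n_missing


def estimate_noise_sd(values: np.ndarray) -> float:
    """Robust noise SD from lagged differences (MAD * 1.4826 / sqrt(2))."""
    y = np.asarray(values, dtype=float)
    d = np.diff(y[~np.isnan(y)])
    if len(d) == 0:
        return _MIN_SIGMA
    sd = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
    return max(float(sd), _MIN_SIGMA)


# ---------------------------------------------------------------------------
# Exact PCF dynamic program


def pcf_breakpoints(values: np.ndarray, gamma: float, k_min: int) -> list[tuple[int, int]]:
    """Exact minimizer of total SSE + gamma*(segments-1) over one chromosome.

    ``values``: (n_samples, n_probes); the SSE is summed over samples (the
    one-sample case is ordinary single-sample PCF). Returns half-open probe
    index intervals [(i, j), ...] covering 0..n.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    n = v.shape[1]
    if n == 0:
        return []
    if n < k_min:
        return [(0, n)]

    c1 = np.zeros((v.shape[0], n + 1))
    c2 = np.zeros((v.shape[0], n + 1))
    np.cumsum(v, axis=1, out=c1[:, 1:])
    np.cumsum(v * v, axis=1, out=c2[:, 1:])

    best = np.full(n + 1, np.inf)
    best[0] = -gamma
    prev = np.zeros(n + 1, dtype=np.int64)
    for j in range(k_min, n + 1):
        m = j - k_min + 1  # candidate starts 0..m-1
        seg_len = j - np.arange(m)
        sse = (
            (c2[:, j, None] - c2[:, :m])
            - (c1[:, j, None] - c1[:, :m]) ** 2 / seg_len
        ).sum(axis=0)
        cand = best[:m] + sse + gamma
        k = int(np.argmin(cand))
        best[j] = cand[k]
        prev[j] = k

    bounds: list[tuple[int, int]] = []
    j = n
    while j > 0:
        i = int(prev[j])
        bounds.append((i, j))
        j = i
    bounds.reverse()
    return bounds


def _segments_from_bounds(
    bounds: Sequence[tuple[int, int]],
    values: np.ndarray,
    positions: np.ndarray,
    chrom: str,
) -> list[Segment]:
    """Convert probe-index intervals into bp segments for one sample.

    A segment over probes [i, j) spans from the first probe's position to
    one bp before the next segment's first probe (the last segment ends at
    the last probe), so that the covered territory is identical for every
    sample on the panel regardless of breakpoint placement.
    """
    n = len(positions)
    segs = []
    for i, j in bounds:
        start = int(positions[i])
        end = int(positions[j] - 1) if j < n else int(positions[n - 1])
        segs.append(Segment(chrom, start, end, j - i, float(np.mean(values[i:j]))))
    return segs


def pcf_single(
    values: np.ndarray,
    positions: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    chrom: str = "1",
    sample_id: str = "sample",
) -> SegmentedProfile:
    """Single-sample PCF on one chromosome (values already winsorized)."""
    y = np.asarray(values, dtype=float)
    if len(y) != len(positions):
        raise ValueError("values and positions differ in length")
    if len(y) < params.k_min:
        logger.warning(
            "%s %s: %d probes < k_min=%d, returning a single segment",
            sample_id, chrom, len(y), params.k_min,
        )
        bounds = [(0, len(y))]
    else:
        gamma = params.gamma
        if params.normalize:
            gamma = params.gamma * estimate_noise_sd(y) ** 2
        bounds = pcf_breakpoints(y[None, :], gamma, params.k_min)
    segs = _segments_from_bounds(bounds, y, np.asarray(positions), chrom)
    return SegmentedProfile(sample_id=sample_id, segments=segs)


def segment_samples(
    matrix: LRRMatrix,
    params: SegmentationParams = SegmentationParams(),
    apply_winsor: bool = True,
) -> list[SegmentedProfile]:
    """Winsorize and segment every sample of an LRR matrix independently."""
    chrom_groups = _chrom_blocks(matrix)
    profiles = []
    for si, sample in enumerate(matrix.samples):
        segs: list[Segment] = []
        prepared: dict[str, np.ndarray] = {}
        for chrom, idx in chrom_groups:
            y, n_imputed = impute_missing(matrix.values[si, idx])
            if n_imputed:
                logger.info("%s %s: imputed %d missing probes", sample, chrom, n_imputed)
            prepared[chrom] = winsorize(y, params) if apply_winsor else y
        gamma = params.gamma
        if params.normalize:
            pooled = np.concatenate([np.diff(v) for v in prepared.values() if len(v) > 1])
            sd = (
                max(1.4826 * np.median(np.abs(pooled - np.median(pooled))) / np.sqrt(2), _MIN_SIGMA)
                if len(pooled)
                else _MIN_SIGMA
            )
            gamma = params.gamma * sd**2
        for chrom, idx in chrom_groups:
            y = prepared[chrom]
            pos = matrix.panel.positions[idx]
            if len(y) < params.k_min:
                logger.warning(
                    "%s %s: %d probes < k_min=%d, single segment",
                    sample, chrom, len(y), params.k_min,
                )
                bounds = [(0, len(y))]
            else:
                bounds = pcf_breakpoints(y[None, :], gamma, params.k_min)
            segs.extend(_segments_from_bounds(bounds, y, pos, chrom))
        profiles.append(SegmentedProfile(sample_id=sample, segments=segs))
    return profiles


def multipcf(
    matrix: LRRMatrix,
    params: SegmentationParams = SegmentationParams(),
    apply_winsor: bool = True,
) -> list[SegmentedProfile]:
    """Joint segmentation: all samples share breakpoints, means are per-sample.

    Minimizes the across-sample total SSE plus gamma per shared breakpoint.
    With one sample this reduces exactly to ``pcf_single``.
    """
    if matrix.n_samples == 0:
        raise ValueError("multipcf requires at least one sample")
    chrom_groups = _chrom_blocks(matrix)

    prepared: dict[str, np.ndarray] = {}
    for chrom, idx in chrom_groups:
        block = np.empty((matrix.n_samples, len(idx)))
        for si in range(matrix.n_samples):
            y, _ = impute_missing(matrix.values[si, idx])
            block[si] = winsorize(y, params) if apply_winsor else y
        prepared[chrom] = block

    gamma = params.gamma
    if params.normalize:
        var_sum = 0.0
        for si in range(matrix.n_samples):
            pooled = np.concatenate(
                [np.diff(prepared[c][si]) for c, _ in chrom_groups if prepared[c].shape[1] > 1]
            )
            sd = (
                max(1.4826 * np.median(np.abs(pooled - np.median(pooled))) / np.sqrt(2), _MIN_SIGMA)
                if len(pooled)
                else _MIN_SIGMA
            )
            var_sum += sd**2
        gamma = params.gamma * var_sum / matrix.n_samples

    all_segs: list[list[Segment]] = [[] for _ in matrix.samples]
    for chrom, idx in chrom_groups:
        block = prepared[chrom]
        pos = matrix.panel.positions[idx]
        if block.shape[1] < params.k_min:
            logger.warning(
                "%s: %d probes < k_min=%d, single shared segment",
                chrom, block.shape[1], params.k_min,
            )
            bounds = [(0, block.shape[1])]
        else:
            bounds = pcf_breakpoints(block, gamma, params.k_min)
        for si in range(matrix.n_samples):
            all_segs[si].extend(_segments_from_bounds(bounds, block[si], pos, chrom))
    return [
        SegmentedProfile(sample_id=s, segments=all_segs[i])
        for i, s in enumerate(matrix.samples)
    ]


def _chrom_blocks(matrix: LRRMatrix) -> list[tuple[str, np.ndarray]]:
    chroms = matrix.panel.chroms
    order = sorted(set(chroms), key=chrom_sort_key)
    return [(c, np.flatnonzero(chroms == c)) for c in order]


# ---------------------------------------------------------------------------
# Atomic segments and aberration calls


def atomic_segments(
    profiles: Sequence[SegmentedProfile],
    positions: Optional[dict[str, np.ndarray]] = None,
) -> AtomicSegmentMatrix:
    """Partition the covered genome by the union of all samples' breakpoints.

    Every sample's atom estimate is the estimate of the unique parent
    segment containing the atom; atom probe counts are filled in when probe
    positions are supplied.
    """
    if not profiles:
        raise ValueError("no profiles given")
    by_sample = [p.by_chrom() for p in profiles]
    chrom_sets = [set(b) for b in by_sample]
    if any(cs != chrom_sets[0] for cs in chrom_sets[1:]):
        raise ValueError("profiles cover different chromosome sets")
    chroms = sorted(chrom_sets[0], key=chrom_sort_key)

    atom_rows = []
    columns: list[np.ndarray] = []
    for chrom in chroms:
        territory = {
            (segs[0].start_bp, segs[-1].end_bp)
            for segs in (b[chrom] for b in by_sample)
        }
        if len(territory) != 1:
            raise ValueError(f"profiles cover inconsistent territory on {chrom}")
        terr_start, terr_end = next(iter(territory))

        starts = sorted({seg.start_bp for b in by_sample for seg in b[chrom]})
        bounds = starts + [terr_end + 1]
        chrom_pos = positions.get(chrom) if positions is not None else None
        n_atoms_before = len(atom_rows)
        for a_start, nxt in zip(bounds[:-1], bounds[1:]):
            a_end = nxt - 1
            n_probes = (
                int(np.searchsorted(chrom_pos, a_end, side="right")
                    - np.searchsorted(chrom_pos, a_start, side="left"))
                if chrom_pos is not None
                else 0
            )
            atom_rows.append((chrom, a_start, a_end, a_end - a_start + 1, n_probes))

        est_block = np.empty((len(profiles), len(atom_rows) - n_atoms_before))
        a_starts = np.array([r[1] for r in atom_rows[n_atoms_before:]])
        a_ends = np.array([r[2] for r in atom_rows[n_atoms_before:]])
        for si, b in enumerate(by_sample):
            segs = b[chrom]
            seg_starts = np.array([s.start_bp for s in segs])
            seg_ends = np.array([s.end_bp for s in segs])
            parent = np.searchsorted(seg_starts, a_starts, side="right") - 1
            if (parent < 0).any() or (a_ends > seg_ends[parent]).any():
                raise ValueError(
                    f"{profiles[si].sample_id}: atoms not nested in segments on {chrom}"
                )
            est_block[si] = [segs[k].estimate for k in parent]
        columns.append(est_block)

    atoms = pd.DataFrame(
        atom_rows, columns=["chrom", "start_bp", "end_bp", "length_bp", "n_probes"]
    )
    estimates = np.concatenate(columns, axis=1)
    return AtomicSegmentMatrix(
        atoms=atoms, samples=[p.sample_id for p in profiles], estimates=estimates
    )


def call_aberrations(estimates: np.ndarray, cutoff: float = 0.1) -> np.ndarray:
    """Ternary calls: +1 gain (> cutoff), -1 loss (< -cutoff), 0 neutral.

    Comparisons are strict, so an estimate exactly at +/-cutoff is neutral.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    x = np.asarray(estimates, dtype=float)
    return np.where(x > cutoff, 1, np.where(x < -cutoff, -1, 0))
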