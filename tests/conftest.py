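import itertools

import numpy as np
import pandas as pd
import pytest

from methet import (
    AtomicSegmentMatrix,
    CohortTable,
    LRRMatrix,
    ProbePanel,
    Segment,
    SegmentedProfile,
    SimulationConfig,
    simulate_cohort,
)


def make_atoms(lengths_bp, estimates, samples=None, chrom="1"):
    """AtomicSegmentMatrix from per-atom lengths and a (samples x atoms) array."""
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    lengths = np.asarray(lengths_bp, dtype=np.int64)
    starts = np.concatenate([[1], 1 + np.cumsum(lengths)[:-1]])
    ends = starts + lengths - 1
    atoms = pd.DataFrame(
        {
            "chrom": chrom,
            "start_bp": starts,
            "end_bp": ends,
            "length_bp": lengths,
            "n_probes": 0,
        }
    )
    if samples is None:
        samples = [f"s{i}" for i in range(estimates.shape[0])]
    return AtomicSegmentMatrix(atoms=atoms, samples=list(samples), estimates=estimates)


def make_profile(sample_id, lengths_bp, estimates, chrom="1", n_probes=5):
    lengths = np.asarray(lengths_bp, dtype=np.int64)
    starts = np.concatenate([[1], 1 + np.cumsum(lengths)[:-1]])
    segs = [
        Segment(chrom, int(s), int(s + l - 1), n_probes, float(e))
        for s, l, e in zip(starts, lengths, estimates)
    ]
    return SegmentedProfile(sample_id=sample_id, segments=segs)


def make_cohort(mapping, resections=None, ccf=None, **patient_fields):
    """CohortTable from {patient: [samples]}; extra per-patient columns allowed."""
    sample_rows, patient_rows = [], []
    for pid, samples in mapping.items():
        for s in samples:
            sample_rows.append(
                dict(
                    sample_id=s,
                    patient_id=pid,
                    resection=(resections or {}).get(s, 1),
                    ccf=(ccf or {}).get(s, np.nan),
                )
            )
        row = dict(patient_id=pid)
        for key, values in patient_fields.items():
            row[key] = values[pid]
        patient_rows.append(row)
    return CohortTable(
        samples=pd.DataFrame(sample_rows), patients=pd.DataFrame(patient_rows)
    )


# ---------------------------------------------------------------------------
# Independent segmentation oracles


def compositions(n, k_min):
    """All ordered segment-length compositions of n with parts >= k_min."""
    if n == 0:
        yield []
        return
    for first in range(k_min, n + 1):
        rest = n - first
        if rest == 0:
            yield [first]
        elif rest >= k_min:
            for tail in compositions(rest, k_min):
                yield [first] + tail


def brute_force_objective(y, gamma, k_min):
    """Exhaustive enumeration of all admissible segmentations (small n)."""
    y = np.asarray(y, dtype=float)
    best = np.inf
    for comp in compositions(len(y), k_min):
        idx, sse = 0, 0.0
        for length in comp:
            seg = y[idx : idx + length]
            sse += float(((seg - seg.mean()) ** 2).sum())
            idx += length
        best = min(best, sse + gamma * (len(comp) - 1))
    return best


def exact_search_objective(y, gamma, k_min):
    """Exact recursive search over all admissible first-segment lengths.

    Memoized on the suffix start, hence exact for n up to a few dozen while
    remaining independent of the production dynamic program.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best_from(i):
        if i == n:
            return -gamma
        out = np.inf
        for j in range(i + k_min, n + 1):
            seg = y[i:j]
            out = min(out, float(((seg - seg.mean()) ** 2).sum()) + gamma + best_from(j))
        return out

    return best_from(0)


def segmentation_objective(profile_bounds, y, gamma):
    """Objective value of a concrete segmentation given as index bounds."""
    y = np.asarray(y, dtype=float)
    sse = sum(
        float(((y[i:j] - y[i:j].mean()) ** 2).sum()) for i, j in profile_bounds
    )
    return sse + gamma * (len(profile_bounds) - 1)


@pytest.fixture(scope="session")
def small_cohort():
    """A small noiseless-free simulated cohort shared across tests."""
    return simulate_cohort(SimulationConfig.small(seed=11, n_patients=8))
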