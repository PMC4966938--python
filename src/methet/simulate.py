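"""Synthetic multi-deposit metastatic cohorts with known truth.

Each patient's deposits share a clonal ancestor copy-number profile
(diploid plus Poisson-many arm-level or focal events, with an arm prior
favoring the gains and losses recurrent in colorectal cancer: gains on
7p, 7q, 8q, 13q, 20q and losses on 1p, 4p, 4q, 8p, 17p, 18q) and each
deposit adds Poisson-many private events — the branched-evolution structure
the heterogeneity analysis assumes. Probe-level log ratios are rendered
from the integer allele copies through a purity mixture,
LRR = log2(((1-rho)*2 + rho*(nA+nB)) / 2) + Gaussian noise, and survival
times follow an exponential hazard raised for patients whose true
inter-deposit divergence is above the cohort median.

One random stream is derived per patient from the master seed, so a
patient's genomic truth is invariant to the cohort size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import AlleleSpecificProfile, CohortTable, LRRMatrix, ProbePanel
from .genome import GenomeBuild
from . import io as mio

logger = logging.getLogger("methet")

GAIN_FAVORED_ARMS = {("7", "p"), ("7", "q"), ("8", "q"), ("13", "q"), ("20", "q")}
LOSS_FAVORED_ARMS = {("1", "p"), ("4", "p"), ("4", "q"), ("8", "p"), ("17", "p"),
                     ("18", "q")}


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort generator settings; defaults emulate the study conditions.

    45 patients with 1-7 deposits at first resection (mean ~2.7, median 2),
    tumor purity uniform on 26-95%, SNP-array-like markers. The genome may
    be scaled down (with proportionally wider marker spacing) for fast runs;
    every downstream statistic is a proportion or per-segment value and is
    invariant to that scaling.
    """

    seed: int
    n_patients: int = 45
    genome_scale: float = 1.0
    probe_spacing: int = 700
    deposits_extra_mean: float = 1.7  # deposits = 1 + min(Poisson(.), max-1)
    max_deposits: int = 7
    lambda_ancestor: float = 25.0
    lambda_divergence: float = 2.0
    # per-patient private-event rate ~ Gamma(shape, mean=lambda_divergence):
    # patients differ widely in how heterogeneous their deposits are
    divergence_shape: float = 1.0
    lambda_cnloh: float = 1.2
    arm_event_fraction: float = 0.5
    focal_length_median_bp: float = 10e6  # before genome scaling
    focal_length_sigma: float = 0.8
    purity_range: tuple[float, float] = (0.26, 0.95)
    purity_within_sd: float = 0.05  # deposits of one patient share a mean purity
    noise_sd: float = 0.1
    ccf_missing_prob: float = 0.045
    second_resection_fraction: float = 8 / 45
    # survival: monthly exponential baseline hazards for the low-divergence
    # group; the high group multiplies the hazard by exp(log_hr).
    hazard_pfs: float = np.log(2) / 17.0
    hazard_os: float = np.log(2) / 52.0
    log_hr_pfs: float = float(np.log(2.5))
    log_hr_os: float = float(np.log(10.0 / 3.0))
    censor_frac: float = 0.3
    min_lrr: float = -8.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("lambda_ancestor", "lambda_divergence", "lambda_cnloh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity range must lie in (0, 1]")
        if self.probe_spacing < 1:
            raise ValueError("probe_spacing must be >= 1 (zero probes otherwise)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def small(cls, seed: int, **overrides) -> "SimulationConfig":
        """1/10-length genome with 100 kb marker spacing (fast runs)."""
        base = dict(genome_scale=0.1, probe_spacing=100_000)
        base.update(overrides)
        return cls(seed=seed, **base)

    def genome(self) -> GenomeBuild:
        return GenomeBuild.hg19_autosomes(self.genome_scale)

    def panel(self) -> ProbePanel:
        genome = self.genome()
        chroms, positions = [], []
        for chrom, length in genome.lengths.items():
            pos = np.arange(1, length + 1, self.probe_spacing, dtype=np.int64)
            chroms.extend([chrom] * len(pos))
            positions.append(pos)
        if not positions or sum(len(p) for p in positions) == 0:
            raise ValueError("configuration yields zero probes")
        return ProbePanel.from_positions(chroms, np.concatenate(positions))


# ---------------------------------------------------------------------------
# Event machinery


def _arm_table(genome: GenomeBuild) -> list[tuple[str, str, int, int, float, float]]:
    """(chrom, arm, start, end, selection weight, P(gain)) per arm."""
    out = []
    for chrom, arm, start, end in genome.arms():
        key = (chrom, arm)
        weight = 3.0 if key in GAIN_FAVORED_ARMS | LOSS_FAVORED_ARMS else 1.0
        p_gain = 0.8 if key in GAIN_FAVORED_ARMS else (
            0.2 if key in LOSS_FAVORED_ARMS else 0.5
        )
        out.append((chrom, arm, start, end, weight, p_gain))
    return out


def _draw_events(
    n: int,
    arms: list[tuple[str, str, int, int, float, float]],
    config: SimulationConfig,
    rng: np.random.Generator,
    cnloh: bool = False,
) -> list[tuple[str, int, int, int, int]]:
    """Draw ``n`` events as (chrom, start, end, dA, dB) deltas."""
    if n == 0:
        return []
    weights = np.array([a[4] for a in arms])
    weights = weights / weights.sum()
    events = []
    min_len = 5 * config.probe_spacing
    for _ in range(n):
        chrom, arm, a_start, a_end, _, p_gain = arms[rng.choice(len(arms), p=weights)]
        arm_len = a_end - a_start + 1
        if rng.random() < config.arm_event_fraction:
            start, end = a_start, a_end
        else:
            median = config.focal_length_median_bp * config.genome_scale
            length = int(rng.lognormal(np.log(median), config.focal_length_sigma))
            length = int(np.clip(length, min(min_len, arm_len), arm_len))
            start = int(a_start + rng.integers(0, max(1, arm_len - length + 1)))
            end = min(start + length - 1, a_end)
        if cnloh:
            # lose one parental allele, gain the other: copy-neutral
            if rng.random() < 0.5:
                dA, dB = -1, 1
            else:
                dA, dB = 1, -1
        else:
            delta = 1 if rng.random() < p_gain else -1
            if rng.random() < 0.5:
                dA, dB = delta, 0
            else:
                dA, dB = 0, delta
        events.append((chrom, start, end, dA, dB))
    return events


def _profile_from_events(
    genome: GenomeBuild, events: list[tuple[str, int, int, int, int]]
) -> pd.DataFrame:
    """Overlay event deltas on a diploid (1,1) genome; copies clip at 0.

    Deltas are summed per interval before clipping, so overlapping gain and
    loss events cancel.
    """
    rows = []
    by_chrom: dict[str, list] = {}
    for chrom, start, end, dA, dB in events:
        by_chrom.setdefault(chrom, []).append((start, end, dA, dB))
    for chrom, length in genome.lengths.items():
        evs = by_chrom.get(chrom, [])
        bounds = {1, length + 1}
        for start, end, _, _ in evs:
            bounds.add(start)
            bounds.add(end + 1)
        cuts = sorted(bounds)
        prev = None
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            dA = sum(e[2] for e in evs if e[0] <= lo and hi - 1 <= e[1])
            dB = sum(e[3] for e in evs if e[0] <= lo and hi - 1 <= e[1])
            nA, nB = max(0, 1 + dA), max(0, 1 + dB)
            if prev is not None and prev[3] == nA and prev[4] == nB:
                prev[2] = hi - 1  # merge equal-copy neighbors
            else:
                prev = [chrom, lo, hi - 1, nA, nB]
                rows.append(prev)
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "nA", "nB"])


def _pairwise_diff_fraction(a: pd.DataFrame, b: pd.DataFrame, total_bp: int) -> float:
    """Fraction of the genome where total copies differ between two profiles."""
    diff = 0
    for chrom in a["chrom"].unique():
        ga = a[a["chrom"] == chrom]
        gb = b[b["chrom"] == chrom]
        bounds = sorted(
            set(ga["start_bp"]) | set(gb["start_bp"])
            | {int(ga["end_bp"].max()) + 1}
        )
        sa = ga["start_bp"].to_numpy()
        sb = gb["start_bp"].to_numpy()
        ta = (ga["nA"] + ga["nB"]).to_numpy()
        tb = (gb["nA"] + gb["nB"]).to_numpy()
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            ia = np.searchsorted(sa, lo, side="right") - 1
            ib = np.searchsorted(sb, lo, side="right") - 1
            if ta[ia] != tb[ib]:
                diff += hi - lo
    return diff / total_bp


def _aberrant_fraction(profile: pd.DataFrame, total_bp: int) -> float:
    lengths = (profile["end_bp"] - profile["start_bp"] + 1).to_numpy()
    aberrant = (profile["nA"] + profile["nB"]) != 2
    return float(lengths[aberrant].sum() / total_bp)


def _cnloh_bp(profile: pd.DataFrame) -> int:
    lengths = (profile["end_bp"] - profile["start_bp"] + 1).to_numpy()
    lo = np.minimum(profile["nA"], profile["nB"]).to_numpy()
    hi = np.maximum(profile["nA"], profile["nB"]).to_numpy()
    return int(lengths[(lo == 0) & (hi == 2)].sum())


# ---------------------------------------------------------------------------
# Patient and cohort simulation


@dataclass
class PatientTruth:
    patient_id: str
    sample_ids: list[str]
    resections: list[int]
    profiles: dict[str, pd.DataFrame]
    purities: dict[str, float]
    true_divergence: float  # mean pairwise differing-bp fraction, resection 1
    aberrant_fraction: dict[str, float]
    cnloh_bp: dict[str, int]


def _patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, patient_index]))


def simulate_patient(
    config: SimulationConfig, patient_index: int
) -> PatientTruth:
    """Draw one patient: ancestor clone, per-deposit private events, purity."""
    rng = _patient_rng(config.seed, patient_index)
    genome = config.genome()
    arms = _arm_table(genome)
    total_bp = genome.total_bp
    pid = f"P{patient_index:02d}"

    n_deposits = 1 + int(min(rng.poisson(config.deposits_extra_mean),
                             config.max_deposits - 1))
    has_second = rng.random() < config.second_resection_fraction
    n_second = int(1 + rng.integers(0, 2)) if has_second else 0

    ancestor_events = _draw_events(
        int(rng.poisson(config.lambda_ancestor)), arms, config, rng
    ) + _draw_events(int(rng.poisson(config.lambda_cnloh)), arms, config, rng,
                     cnloh=True)

    patient_rate = (
        float(rng.gamma(config.divergence_shape,
                        config.lambda_divergence / config.divergence_shape))
        if config.lambda_divergence > 0
        else 0.0
    )

    sample_ids, resections = [], []
    profiles: dict[str, pd.DataFrame] = {}
    purities: dict[str, float] = {}
    lo, hi = config.purity_range
    # hierarchical purity: deposits of one patient have correlated purity
    patient_purity = float(rng.uniform(lo, hi))
    for k in range(n_deposits + n_second):
        resection = 1 if k < n_deposits else 2
        sid = f"{pid}M{k + 1}" if resection == 1 else f"{pid}R2M{k - n_deposits + 1}"
        private = _draw_events(
            int(rng.poisson(patient_rate)), arms, config, rng
        ) + _draw_events(int(rng.poisson(config.lambda_cnloh)), arms, config, rng,
                         cnloh=True)
        profiles[sid] = _profile_from_events(genome, ancestor_events + private)
        purities[sid] = float(
            np.clip(patient_purity + rng.normal(0.0, config.purity_within_sd), lo, hi)
        )
        sample_ids.append(sid)
        resections.append(resection)

    first = [s for s, r in zip(sample_ids, resections) if r == 1]
    if len(first) >= 2:
        fracs = [
            _pairwise_diff_fraction(profiles[a], profiles[b], total_bp)
            for i, a in enumerate(first)
            for b in first[i + 1:]
        ]
        divergence = float(np.mean(fracs))
    else:
        divergence = 0.0

    return PatientTruth(
        patient_id=pid,
        sample_ids=sample_ids,
        resections=resections,
        profiles=profiles,
        purities=purities,
        true_divergence=divergence,
        aberrant_fraction={s: _aberrant_fraction(profiles[s], total_bp)
                           for s in sample_ids},
        cnloh_bp={s: _cnloh_bp(profiles[s]) for s in sample_ids},
    )


def render_lrr(
    profile: pd.DataFrame,
    purity: float,
    noise_sd: float,
    panel: ProbePanel,
    rng: np.random.Generator,
    min_lrr: float = -8.0,
) -> np.ndarray:
    """Per-probe log ratio from integer copies through the purity mixture.

    LRR = log2(((1-rho)*2 + rho*(nA+nB)) / 2) + N(0, sd); a homozygous
    deletion at purity 1 is floored at ``min_lrr``.
    """
    if not (0 < purity <= 1):
        raise ValueError("purity must be in (0, 1]")
    chroms = panel.chroms
    positions = panel.positions
    total = np.full(len(positions), 2.0)  # uncovered probes read diploid
    for chrom, g in profile.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = g["start_bp"].to_numpy()
        copies = (g["nA"] + g["nB"]).to_numpy()
        idx = np.searchsorted(starts, positions[sel], side="right") - 1
        total[sel] = copies[np.clip(idx, 0, len(copies) - 1)]
    signal = (1 - purity) * 2 + purity * total
    with np.errstate(divide="ignore"):
        lrr = np.log2(signal / 2.0)
    lrr = np.maximum(lrr, min_lrr)
    if noise_sd > 0:
        lrr = lrr + rng.normal(0.0, noise_sd, size=len(lrr))
    return lrr


def simulate_survival(
    divergence: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Exponential event times with hazard raised for high-divergence patients.

    The high group is true divergence above the cohort median. Censoring is
    independent Uniform(0, u) with u solved so the expected censoring
    fraction matches the configuration; the 36-month horizon is applied by
    the downstream analyses, not here.
    """
    div = np.asarray(divergence, dtype=float)
    high = div > np.median(div)
    out = {}
    for name, h0, log_hr in (
        ("pfs", config.hazard_pfs, config.log_hr_pfs),
        ("os", config.hazard_os, config.log_hr_os),
    ):
        rates = h0 * np.exp(log_hr * high)
        times = rng.exponential(1.0 / rates)
        if config.censor_frac >= 1.0:
            out[f"{name}_months"] = np.full(len(div), DEFAULT_FOLLOWUP)
            out[f"{name}_event"] = np.zeros(len(div), dtype=bool)
            continue
        if config.censor_frac <= 0.0:
            out[f"{name}_months"] = times
            out[f"{name}_event"] = np.ones(len(div), dtype=bool)
            continue

        def censored_frac(u: float) -> float:
            # P(C < T) = (1 - e^(-rate*u)) / (rate*u) for C ~ U(0,u), T ~ Exp(rate)
            lam = rates * u
            return float(np.mean((1.0 - np.exp(-lam)) / lam))

        u = brentq(lambda x: censored_frac(x) - config.censor_frac, 1e-6, 1e6)
        censor_times = rng.uniform(0.0, u, size=len(div))
        event = times <= censor_times
        out[f"{name}_months"] = np.where(event, times, censor_times)
        out[f"{name}_event"] = event
    out["high_divergence"] = high
    return pd.DataFrame(out)


DEFAULT_FOLLOWUP = 60.0  # months; censoring time when censor_frac >= 1


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    lrr: LRRMatrix
    allele_profiles: list[AlleleSpecificProfile]
    cohort: CohortTable
    patient_truth: pd.DataFrame  # patient_id, true_divergence, high_divergence
    sample_truth: pd.DataFrame  # sample_id, purity, aberrant_fraction, cnloh_bp


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Full cohort: truth, rendered probe data, clinical table, survival."""
    panel = config.panel()
    genome = config.genome()
    patients = [simulate_patient(config, i) for i in range(config.n_patients)]

    survival_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 10**6])
    )
    divergence = np.array([p.true_divergence for p in patients])
    surv = simulate_survival(divergence, config, survival_rng)

    sample_rows, patient_rows = [], []
    allele_profiles = []
    lrr_columns, sample_order = [], []
    truth_sample_rows = []
    for i, pt in enumerate(patients):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i, 7]))
        age = int(np.clip(round(rng.normal(63, 9)), 41, 83))
        sex = "M" if rng.random() < 25 / 45 else "F"
        synchronous = bool(rng.random() < 20 / 45)
        chemo = bool(rng.random() < 25 / 41)
        tp53 = ["mutated", "wild-type", "heterogeneous"][
            int(rng.choice(3, p=[0.51, 0.38, 0.11]))
        ]
        patient_rows.append(
            dict(
                patient_id=pt.patient_id, synchronous=synchronous,
                chemo_exposed=chemo, tp53_status=tp53, age=age, sex=sex,
                pfs_months=float(surv.loc[i, "pfs_months"]),
                pfs_event=bool(surv.loc[i, "pfs_event"]),
                os_months=float(surv.loc[i, "os_months"]),
                os_event=bool(surv.loc[i, "os_event"]),
            )
        )
        for sid, resection in zip(pt.sample_ids, pt.resections):
            purity = pt.purities[sid]
            ccf = np.nan if rng.random() < config.ccf_missing_prob else purity
            sample_rows.append(
                dict(sample_id=sid, patient_id=pt.patient_id,
                     resection=resection, ccf=ccf)
            )
            profile = pt.profiles[sid]
            lengths = (profile["end_bp"] - profile["start_bp"] + 1).to_numpy()
            ploidy = float(
                ((profile["nA"] + profile["nB"]).to_numpy() * lengths).sum()
                / lengths.sum()
            )
            allele_profiles.append(
                AlleleSpecificProfile(
                    sample_id=sid, purity=purity, ploidy=ploidy,
                    segments=profile.copy(),
                )
            )
            lrr_columns.append(
                render_lrr(profile, purity, config.noise_sd, panel, rng,
                           config.min_lrr)
            )
            sample_order.append(sid)
            truth_sample_rows.append(
                dict(sample_id=sid, patient_id=pt.patient_id, purity=purity,
                     ploidy=ploidy,
                     aberrant_fraction=pt.aberrant_fraction[sid],
                     cnloh_bp=pt.cnloh_bp[sid])
            )

    lrr = LRRMatrix(panel=panel, samples=sample_order,
                    values=np.stack(lrr_columns))
    cohort = CohortTable(
        samples=pd.DataFrame(sample_rows),
        patients=pd.DataFrame(patient_rows),
    )
    patient_truth = pd.DataFrame(
        dict(
            patient_id=[p.patient_id for p in patients],
            true_divergence=divergence,
            high_divergence=surv["high_divergence"].to_numpy(),
        )
    )
    return SimulatedCohort(
        config=config,
        lrr=lrr,
        allele_profiles=allele_profiles,
        cohort=cohort,
        patient_truth=patient_truth,
        sample_truth=pd.DataFrame(truth_sample_rows),
    )


def emit_cohort(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Write the cohort to disk in the pipeline's input formats.

    Outputs are byte-identical across runs with the same configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_cohort(config)
    paths = {
        "lrr": out / "lrr.tsv",
        "allele": out / "allele_truth.tsv",
        "clinical": out / "clinical.csv",
        "truth_patients": out / "truth_patients.tsv",
        "truth_samples": out / "truth_samples.tsv",
    }
    mio.write_lrr_table(sim.lrr, paths["lrr"])
    mio.write_allele_profiles(sim.allele_profiles, paths["allele"])
    mio.write_clinical(sim.cohort, paths["clinical"])
    sim.patient_truth.to_csv(paths["truth_patients"], sep="\t", index=False,
                             float_format="%.17g")
    sim.sample_truth.to_csv(paths["truth_samples"], sep="\t", index=False,
                            float_format="%.17g")
    logger.info("simulated cohort written to %s (%d patients, %d samples)",
                out, config.n_patients, len(sim.lrr.samples))
    return paths
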