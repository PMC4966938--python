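"""End-to-end analysis: filter -> segment -> atoms -> scores -> survival.

``analyze_cohort`` is the in-memory engine; ``run_pipeline`` wraps it with
file IO, a YAML-configurable parameter set, per-stage logging and a text
report. Every stage is deterministic given the configured seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .clustering import ClusterTree, cluster_samples, multiscale_bootstrap, patient_cluster_purity
from .complexity import cohort_complexity, cnloh_fraction
from .core import AtomicSegmentMatrix, CohortTable, LRRMatrix, SegmentedProfile
from .filters import RegionBlacklist, apply_filters
from .heterogeneity import ccf_diversity, cohort_heterogeneity
from .segmentation import SegmentationParams, atomic_segments, multipcf, segment_samples
from .survival import (
    combined_strata,
    cox_fit,
    logrank_trend,
    median_split,
    multivariable_fit,
    three_year_rate,
)

logger = logging.getLogger("methet")


class PipelineError(RuntimeError):
    """Raised with the failing stage's name and context."""


@dataclass
class PipelineConfig:
    lrr_path: str
    clinical_path: str
    out_dir: str
    allele_path: Optional[str] = None
    blacklist_path: Optional[str] = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    joint_by_patient: bool = False
    variance_cutoff: Optional[float] = 0.03
    aberration_cutoff: float = 0.1
    diff_cutoff: float = 0.1
    complexity_threshold: float = 25.0
    blacklist_freq: float = 0.10
    horizon: float = 36.0
    cluster_nboot: int = 0  # 0 skips bootstrap supports
    cluster_seed: int = 7

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        return cls(segmentation=seg, **raw)

    def validate(self) -> None:
        if not Path(self.lrr_path).exists():
            raise PipelineError(f"validation: LRR file not found: {self.lrr_path}")
        if not Path(self.clinical_path).exists():
            raise PipelineError(
                f"validation: clinical file not found: {self.clinical_path}"
            )


@dataclass
class AnalysisResult:
    profiles: list[SegmentedProfile]
    atoms_first: AtomicSegmentMatrix
    heterogeneity: pd.DataFrame  # patient_id, euclidean, proportion_pct, ...
    complexity: pd.DataFrame  # patient_id, complexity, n_samples
    groups: pd.DataFrame  # patient_id, het_group, cx_group, stratum
    km_rates: pd.DataFrame  # endpoint, group, rate
    cox_univariable: pd.DataFrame
    cox_multivariable: pd.DataFrame
    trend_tests: pd.DataFrame  # endpoint, chi2, p (combined strata)
    tree: Optional[ClusterTree]
    cluster_purity: dict[str, str]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name}: {err}") from err
            return out

        return wrapper

    return deco


def analyze_cohort(
    lrr: LRRMatrix,
    cohort: CohortTable,
    config: Optional[PipelineConfig] = None,
    blacklist: Optional[RegionBlacklist] = None,
) -> AnalysisResult:
    """Run the analysis stages on in-memory inputs."""
    cfg = config or PipelineConfig(lrr_path="", clinical_path="", out_dir="")
    params = cfg.segmentation

    filtered = _stage("probe_filter")(apply_filters)(lrr, blacklist)
    logger.info("stage probe_filter: %d probes retained", filtered.n_probes)

    @_stage("segmentation")
    def _segment() -> list[SegmentedProfile]:
        if cfg.joint_by_patient:
            profiles = []
            for pid in cohort.patient_ids:
                samples = [s for s in cohort.samples_of(pid) if s in filtered.samples]
                if not samples:
                    continue
                profiles.extend(multipcf(filtered.subset_samples(samples), params))
            return profiles
        known = [s for s in filtered.samples if s in set(cohort.samples["sample_id"])]
        unknown = set(filtered.samples) - set(known)
        if unknown:
            logger.warning("samples absent from clinical table: %s", sorted(unknown))
        return segment_samples(filtered.subset_samples(known), params)

    profiles = _segment()
    logger.info(
        "stage segmentation: %d samples, median %d segments",
        len(profiles), int(np.median([len(p.segments) for p in profiles])),
    )

    @_stage("atomic_segments")
    def _atoms() -> AtomicSegmentMatrix:
        first = [
            p for p in profiles
            if cohort.samples.set_index("sample_id")["resection"].get(p.sample_id, 1) == 1
        ]
        return atomic_segments(first, positions=filtered.panel.positions_by_chrom())

    atoms_first = _atoms()
    logger.info("stage atomic_segments: %d atoms over %d samples",
                atoms_first.n_atoms, len(atoms_first.samples))

    @_stage("heterogeneity")
    def _het() -> pd.DataFrame:
        euc = cohort_heterogeneity(
            atoms_first, cohort, "euclidean", cfg.variance_cutoff, cfg.diff_cutoff
        )
        prop = cohort_heterogeneity(
            atoms_first, cohort, "proportion_genome", None, cfg.diff_cutoff
        )
        rows = []
        for e, p in zip(euc, prop):
            rows.append(
                dict(
                    patient_id=e.patient_id,
                    euclidean=e.score,
                    proportion_pct=p.score,
                    n_samples=e.n_samples,
                    n_pairs=e.n_pairs,
                    ccf_diversity=ccf_diversity(cohort, e.patient_id),
                )
            )
        return pd.DataFrame(rows)

    het = _het()
    n_scored = int(het["euclidean"].notna().sum())
    logger.info("stage heterogeneity: %d/%d patients scored", n_scored, len(het))

    @_stage("complexity")
    def _cx() -> pd.DataFrame:
        return cohort_complexity(profiles, cohort, cfg.aberration_cutoff)

    cx = _cx()

    @_stage("clustering")
    def _cluster() -> tuple[Optional[ClusterTree], dict[str, str]]:
        if len(atoms_first.samples) < 2:
            return None, {}
        if cfg.cluster_nboot > 0:
            tree = multiscale_bootstrap(
                atoms_first, n_boot=cfg.cluster_nboot, seed=cfg.cluster_seed,
                variance_cutoff=cfg.variance_cutoff,
            )
        else:
            tree = cluster_samples(atoms_first, cfg.variance_cutoff)
        return tree, patient_cluster_purity(tree, cohort)

    tree, purity = _cluster()

    @_stage("survival")
    def _survival():
        het_scores = {
            r.patient_id: r.euclidean for r in het.itertuples() if r.euclidean is not None
            and not (isinstance(r.euclidean, float) and np.isnan(r.euclidean))
        }
        cx_scores = dict(zip(cx["patient_id"], cx["complexity"]))
        split = median_split(het_scores)
        strata = combined_strata(het_scores, cx_scores, cfg.complexity_threshold)

        pf = cohort.patients.set_index("patient_id")
        scored = sorted(het_scores)
        df = pd.DataFrame(
            {
                "patient_id": scored,
                "het_low": [int(split[p] == "low") for p in scored],
                "cx_low": [int(cx_scores.get(p, np.nan) < cfg.complexity_threshold)
                           if not np.isnan(cx_scores.get(p, np.nan)) else np.nan
                           for p in scored],
                "age": [pf.loc[p, "age"] if "age" in pf else np.nan for p in scored],
                "female": [int(pf.loc[p, "sex"] == "F") if "sex" in pf else np.nan
                           for p in scored],
                "synchronous": [int(pf.loc[p, "synchronous"]) for p in scored],
                "chemo": [int(pf.loc[p, "chemo_exposed"]) for p in scored],
                "tp53_mutated": [
                    {"mutated": 1, "wild-type": 0}.get(pf.loc[p, "tp53_status"], np.nan)
                    if "tp53_status" in pf else np.nan
                    for p in scored
                ],
                "pfs_months": [pf.loc[p, "pfs_months"] for p in scored],
                "pfs_event": [int(pf.loc[p, "pfs_event"]) for p in scored],
                "os_months": [pf.loc[p, "os_months"] for p in scored],
                "os_event": [int(pf.loc[p, "os_event"]) for p in scored],
            }
        )
        groups = pd.DataFrame(
            {
                "patient_id": scored,
                "het_group": [split[p] for p in scored],
                "cx_group": [
                    "low" if (p in cx_scores and cx_scores[p] < cfg.complexity_threshold)
                    else "high"
                    for p in scored
                ],
            }
        ).merge(strata, on="patient_id", how="left")

        km_rows, trend_rows = [], []
        uni_frames, multi_frames = [], []
        covariates = ["het_low", "cx_low", "age", "female", "synchronous",
                      "chemo", "tp53_mutated"]
        for endpoint in ("pfs", "os"):
            t = df[f"{endpoint}_months"].to_numpy()
            e = df[f"{endpoint}_event"].to_numpy().astype(bool)
            rates = three_year_rate(t, e, groups["het_group"], cfg.horizon)
            for grp, rate in rates.items():
                km_rows.append((endpoint, f"het_{grp}", rate))
            merged = df.merge(strata, on="patient_id", how="inner")
            if merged["stratum"].nunique() >= 2:
                chi2, p = logrank_trend(
                    merged[f"{endpoint}_months"], merged[f"{endpoint}_event"],
                    merged["stratum"], horizon=cfg.horizon,
                )
                trend_rows.append((endpoint, chi2, p))
                strat_rates = three_year_rate(
                    merged[f"{endpoint}_months"],
                    merged[f"{endpoint}_event"].astype(bool),
                    merged["stratum"], cfg.horizon,
                )
                for grp, rate in strat_rates.items():
                    km_rows.append((endpoint, f"stratum_{grp}", rate))
            uni, multi = multivariable_fit(
                df, f"{endpoint}_months", f"{endpoint}_event", covariates,
                horizon=cfg.horizon,
            )
            uni.insert(0, "endpoint", endpoint)
            multi.insert(0, "endpoint", endpoint) if len(multi) else None
            uni_frames.append(uni)
            multi_frames.append(multi)

        km = pd.DataFrame(km_rows, columns=["endpoint", "group", "rate"])
        trend = pd.DataFrame(trend_rows, columns=["endpoint", "chi2", "p"])
        return groups, km, pd.concat(uni_frames, ignore_index=True), pd.concat(
            [m for m in multi_frames if len(m)], ignore_index=True
        ) if any(len(m) for m in multi_frames) else pd.DataFrame(), trend

    groups, km, uni, multi, trend = _survival()

    return AnalysisResult(
        profiles=profiles,
        atoms_first=atoms_first,
        heterogeneity=het,
        complexity=cx,
        groups=groups,
        km_rates=km,
        cox_univariable=uni,
        cox_multivariable=multi,
        trend_tests=trend,
        tree=tree,
        cluster_purity=purity,
    )


def run_pipeline(config: PipelineConfig) -> AnalysisResult:
    """File-based pipeline entry point; writes the result bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = _stage("read_clinical")(mio.read_clinical)(config.clinical_path)
    lrr = _stage("read_lrr")(mio.read_lrr_table)(config.lrr_path)
    blacklist = None
    if config.blacklist_path:
        regions = _stage("read_blacklist")(mio.read_blacklist)(config.blacklist_path)
        blacklist = RegionBlacklist(regions)

    result = analyze_cohort(lrr, cohort, config, blacklist)

    mio.write_segments(result.profiles, out / "segments.tsv")
    result.heterogeneity.to_csv(out / "heterogeneity.tsv", sep="\t", index=False,
                                float_format="%.17g")
    result.complexity.to_csv(out / "complexity.tsv", sep="\t", index=False,
                             float_format="%.17g")
    result.groups.to_csv(out / "groups.tsv", sep="\t", index=False)
    result.km_rates.to_csv(out / "km_rates.tsv", sep="\t", index=False,
                           float_format="%.17g")
    result.cox_univariable.to_csv(out / "cox_univariable.tsv", sep="\t",
                                  index=False, float_format="%.17g")
    result.cox_multivariable.to_csv(out / "cox_multivariable.tsv", sep="\t",
                                    index=False, float_format="%.17g")
    result.trend_tests.to_csv(out / "trend_tests.tsv", sep="\t", index=False,
                              float_format="%.17g")
    if result.tree is not None:
        (out / "clusters.newick").write_text(result.tree.to_newick() + "\n")
    (out / "report.txt").write_text(render_report(result))

    if config.allele_path:
        profiles = _stage("read_allele")(mio.read_allele_profiles)(config.allele_path)
        rows = [
            (p.sample_id, p.purity, p.ploidy, cnloh_fraction(p)) for p in profiles
        ]
        pd.DataFrame(rows, columns=["sample_id", "purity", "ploidy",
                                    "cnloh_pct"]).to_csv(
            out / "cnloh.tsv", sep="\t", index=False, float_format="%.17g"
        )
    return result


def render_report(result: AnalysisResult) -> str:
    """Human-readable summary of the analysis bundle."""
    lines = ["Inter-metastatic heterogeneity analysis", "=" * 40, ""]
    het = result.heterogeneity["euclidean"].dropna()
    if len(het):
        lines.append(
            f"Heterogeneity (Euclidean): median {het.median():.2f}, "
            f"range {het.min():.2f}-{het.max():.2f} over {len(het)} patients"
        )
    cx = result.complexity["complexity"].dropna()
    if len(cx):
        lines.append(
            f"Patient-wise genomic complexity: median {cx.median():.1f}%, "
            f"range {cx.min():.1f}-{cx.max():.1f}%"
        )
    if result.cluster_purity:
        mono = sum(v == "monophyletic" for v in result.cluster_purity.values())
        split = sum(v == "split" for v in result.cluster_purity.values())
        lines.append(f"Clustering: {mono} patient-wise (monophyletic), {split} split")
    lines.append("")
    lines.append("Three-year survival rates (Kaplan-Meier):")
    for r in result.km_rates.itertuples():
        rate = "inestimable" if r.rate is None or pd.isna(r.rate) else f"{100 * r.rate:.0f}%"
        lines.append(f"  {r.endpoint.upper():3s} {r.group:>12s}: {rate}")
    lines.append("")
    if len(result.cox_univariable):
        lines.append("Cox regression (univariable):")
        for r in result.cox_univariable.itertuples():
            if pd.isna(r.hr):
                continue
            lines.append(
                f"  {r.endpoint.upper():3s} {r.covariate:>14s}: "
                f"HR {r.hr:.2f} [{r.ci_low:.2f}-{r.ci_high:.2f}], P = {r.p:.3g}"
            )
    if len(result.cox_multivariable):
        lines.append("Cox regression (multivariable):")
        for r in result.cox_multivariable.itertuples():
            lines.append(
                f"  {r.endpoint.upper():3s} {r.covariate:>14s}: "
                f"HR {r.hr:.2f} [{r.ci_low:.2f}-{r.ci_high:.2f}], P = {r.p:.3g}"
            )
    if len(result.trend_tests):
        lines.append("")
        for r in result.trend_tests.itertuples():
            lines.append(
                f"Log-rank trend across combined strata ({r.endpoint.upper()}): "
                f"chi2 = {r.chi2:.2f}, P = {r.p:.3g}"
            )
    return "\n".join(lines) + "\n"
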