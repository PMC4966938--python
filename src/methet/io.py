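"""Readers and writers for the tab-delimited pipeline formats.

All files use tab separators, '.' decimal points, and 1-based inclusive
coordinates. Writers print estimates at full precision so that
write -> read round-trips bit-for-bit.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    AlleleSpecificProfile,
    CohortTable,
    LRRMatrix,
    ProbePanel,
    Segment,
    SegmentedProfile,
)
from .genome import GenomeBuild, chrom_sort_key, is_autosome

logger = logging.getLogger("methet")

PathLike = Union[str, Path]

_LRR_META = ("marker", "chrom", "pos")


def read_lrr_table(path: PathLike, genome: Optional[GenomeBuild] = None) -> LRRMatrix:
    """Read a probe x sample log-ratio table.

    Expected header: marker, chrom, pos, [probe_class,] then one column per
    sample. Non-autosomal rows are dropped (with a logged count); probes are
    sorted genomically; sample column order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str},
                     float_precision="round_trip")
    missing = set(_LRR_META) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_class = "probe_class" in df.columns
    sample_cols = [c for c in df.columns if c not in _LRR_META + ("probe_class",)]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")

    if df["marker"].duplicated().any():
        dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
        raise ValueError(f"{path}: duplicate marker id {dup!r}")

    auto = df["chrom"].map(is_autosome)
    n_dropped = int((~auto).sum())
    if n_dropped:
        logger.warning("%s: excluded %d non-autosomal probe rows", path, n_dropped)
    df = df.loc[auto].copy()
    if genome is not None:
        known = df["chrom"].isin(genome.chromosomes)
        n_unknown = int((~known).sum())
        if n_unknown:
            logger.warning(
                "%s: excluded %d probes on chromosomes absent from the genome build",
                path,
                n_unknown,
            )
            df = df.loc[known].copy()

    for col in sample_cols:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = df.loc[bad, "marker"].iloc[0]
            raise ValueError(f"{path}: non-numeric value in column {col!r}, marker {row!r}")
        df[col] = values

    df = df.sort_values(
        ["chrom", "pos"],
        key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
        kind="stable",
    ).reset_index(drop=True)

    panel = ProbePanel(
        pd.DataFrame(
            {
                "marker": df["marker"].to_numpy(),
                "chrom": df["chrom"].to_numpy(),
                "pos": df["pos"].to_numpy(dtype=np.int64),
                "probe_class": df["probe_class"].to_numpy() if has_class else "SNP",
            }
        )
    )
    values = df[sample_cols].to_numpy(dtype=float).T
    return LRRMatrix(panel=panel, samples=list(sample_cols), values=values)


def write_lrr_table(matrix: LRRMatrix, path: PathLike) -> None:
    df = matrix.panel.table.copy()
    for i, sample in enumerate(matrix.samples):
        df[sample] = matrix.values[i]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


_SEG_COLUMNS = ["sample", "chrom", "start_bp", "end_bp", "n_probes", "estimate"]


def write_segments(profiles: Iterable[SegmentedProfile], path: PathLike) -> None:
    """BED-like TSV: sample, chrom, start, end, n_probes, estimate."""
    rows = []
    for prof in profiles:
        prof.validate()
        for seg in prof.segments:
            rows.append((prof.sample_id, *seg))
    pd.DataFrame(rows, columns=_SEG_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_segments(path: PathLike) -> list[SegmentedProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str},
                     float_precision="round_trip")
    missing = set(_SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    profiles = []
    for sample, g in df.groupby("sample", sort=False):
        segments = [
            Segment(str(r.chrom), int(r.start_bp), int(r.end_bp), int(r.n_probes),
                    float(r.estimate))
            for r in g.itertuples()
        ]
        profiles.append(SegmentedProfile(sample_id=str(sample), segments=segments))
    return profiles


_CLINICAL_SAMPLE_COLS = ["sample_id", "patient_id", "resection", "ccf"]
_CLINICAL_PATIENT_COLS = [
    "patient_id", "synchronous", "chemo_exposed", "tp53_status", "age", "sex",
    "pfs_months", "pfs_event", "os_months", "os_event",
]


def read_clinical(path: PathLike) -> CohortTable:
    """Read the clinical CSV (one row per sample, patient fields repeated).

    A missing event flag is parsed as censored (0) with a warning.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str},
                     float_precision="round_trip")
    required = {"sample_id", "patient_id"}
    if required - set(df.columns):
        raise ValueError(f"{path}: clinical file needs sample_id and patient_id")
    if "resection" not in df.columns:
        df["resection"] = 1
    if "ccf" not in df.columns:
        df["ccf"] = np.nan

    for col in ("pfs_event", "os_event"):
        if col in df.columns and df[col].isna().any():
            logger.warning(
                "%s: %d missing %s flags parsed as censored",
                path, int(df[col].isna().sum()), col,
            )
            df[col] = df[col].fillna(0)

    samples = df[_CLINICAL_SAMPLE_COLS].copy()
    samples["resection"] = samples["resection"].astype(int)

    patient_cols = [c for c in _CLINICAL_PATIENT_COLS if c in df.columns]
    patients = df[patient_cols].drop_duplicates()
    if patients["patient_id"].duplicated().any():
        bad = patients.loc[patients["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(
            f"{path}: inconsistent patient-level fields for patient {bad!r}"
        )
    for col in ("pfs_event", "os_event", "synchronous", "chemo_exposed"):
        if col in patients.columns:
            patients[col] = patients[col].astype(bool)
    return CohortTable(samples=samples.reset_index(drop=True),
                       patients=patients.reset_index(drop=True))


def write_clinical(cohort: CohortTable, path: PathLike) -> None:
    df = cohort.samples.merge(cohort.patients, on="patient_id", how="left")
    # int event flags keep the CSV round-trippable through bool coercion
    for col in ("pfs_event", "os_event", "synchronous", "chemo_exposed"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    df.to_csv(path, index=False, float_format="%.17g")


_ALLELE_COLUMNS = ["sample", "chrom", "start_bp", "end_bp", "nA", "nB", "rho", "psi"]


def write_allele_profiles(
    profiles: Iterable[AlleleSpecificProfile], path: PathLike
) -> None:
    rows = []
    for prof in profiles:
        for r in prof.segments.itertuples():
            rows.append(
                (prof.sample_id, r.chrom, r.start_bp, r.end_bp, r.nA, r.nB,
                 prof.purity, prof.ploidy)
            )
    pd.DataFrame(rows, columns=_ALLELE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_allele_profiles(path: PathLike) -> list[AlleleSpecificProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str},
                     float_precision="round_trip")
    missing = set(_ALLELE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for sample, g in df.groupby("sample", sort=False):
        rho = g["rho"].iloc[0]
        psi = g["psi"].iloc[0]
        if g["rho"].nunique() > 1 or g["psi"].nunique() > 1:
            raise ValueError(f"{path}: inconsistent rho/psi for sample {sample!r}")
        seg = g[["chrom", "start_bp", "end_bp", "nA", "nB"]].reset_index(drop=True)
        seg[["start_bp", "end_bp", "nA", "nB"]] = seg[
            ["start_bp", "end_bp", "nA", "nB"]
        ].astype(int)
        out.append(
            AlleleSpecificProfile(
                sample_id=str(sample), purity=float(rho), ploidy=float(psi),
                segments=seg,
            )
        )
    return out


def write_blacklist(regions: pd.DataFrame, path: PathLike) -> None:
    regions.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_blacklist(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "start_bp", "end_bp"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
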