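"""Core in-memory containers for the copy-number heterogeneity pipeline.

Coordinates are 1-based inclusive base pairs throughout; reported segment
and atom lengths are ``end - start + 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeBuild, chrom_sort_key, is_autosome

logger = logging.getLogger("methet")

PROBE_CLASSES = ("SNP", "CN", "control")


class Segment(NamedTuple):
    """A constant copy-number stretch; ``estimate`` is the mean log-ratio."""

    chrom: str
    start_bp: int
    end_bp: int
    n_probes: int
    estimate: float


@dataclass(frozen=True)
class ProbePanel:
    """Marker panel: positions sorted genomically, unique marker ids."""

    table: pd.DataFrame  # columns: marker, chrom, pos, probe_class

    def __post_init__(self) -> None:
        required = {"marker", "chrom", "pos", "probe_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ProbePanel table missing columns {sorted(missing)}")
        if self.table["marker"].duplicated().any():
            dup = self.table.loc[self.table["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r} in panel")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    def positions_by_chrom(self) -> dict[str, np.ndarray]:
        return {
            str(c): g["pos"].to_numpy()
            for c, g in self.table.groupby("chrom", sort=False)
        }

    @classmethod
    def from_positions(
        cls,
        chroms: Sequence[str],
        positions: Sequence[int],
        markers: Optional[Sequence[str]] = None,
        probe_class: Optional[Sequence[str]] = None,
    ) -> "ProbePanel":
        n = len(positions)
        if markers is None:
            markers = [f"m{i}" for i in range(n)]
        if probe_class is None:
            probe_class = ["SNP"] * n
        df = pd.DataFrame(
            {
                "marker": list(markers),
                "chrom": [str(c) for c in chroms],
                "pos": np.asarray(positions, dtype=np.int64),
                "probe_class": list(probe_class),
            }
        )
        df = df.sort_values(
            ["chrom", "pos"],
            key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
            kind="stable",
        ).reset_index(drop=True)
        return cls(df)


@dataclass
class LRRMatrix:
    """Per-probe log2 ratios for a set of samples on a shared panel.

    ``values`` has shape (n_samples, n_probes), NaN = missing.
    """

    panel: ProbePanel
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.panel)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.samples)}, {len(self.panel)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_probes(self) -> int:
        return len(self.panel)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "LRRMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return LRRMatrix(self.panel, list(sample_ids), self.values[idx].copy())

    def subset_probes(self, mask: np.ndarray) -> "LRRMatrix":
        mask = np.asarray(mask, dtype=bool)
        panel = ProbePanel(self.panel.table.loc[mask].reset_index(drop=True))
        return LRRMatrix(panel, list(self.samples), self.values[:, mask].copy())


@dataclass
class SegmentedProfile:
    """One sample's piecewise-constant profile, contiguous per chromosome."""

    sample_id: str
    segments: list[Segment]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_chrom: dict[str, list[Segment]] = {}
        for seg in self.segments:
            if seg.start_bp > seg.end_bp:
                raise ValueError(
                    f"{self.sample_id}: segment {seg} has start > end"
                )
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start_bp)
            for a, b in zip(segs, segs[1:]):
                if b.start_bp <= a.end_bp:
                    raise ValueError(
                        f"{self.sample_id}: overlapping segments on {chrom}: "
                        f"{a} / {b}"
                    )

    @property
    def total_bp(self) -> int:
        return sum(s.end_bp - s.start_bp + 1 for s in self.segments)

    def by_chrom(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, []).append(seg)
        for segs in out.values():
            segs.sort(key=lambda s: s.start_bp)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.segments, columns=["chrom", "start_bp", "end_bp", "n_probes", "estimate"]
        )


@dataclass
class AtomicSegmentMatrix:
    """Shared partition of the covered genome x samples.

    Atoms are the intervals delimited by the union of all samples' segment
    boundaries; within an atom every sample has one constant estimate.
    """

    atoms: pd.DataFrame  # columns: chrom, start_bp, end_bp, length_bp, n_probes
    samples: list[str]
    estimates: np.ndarray  # shape (n_samples, n_atoms)

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=float)
        if self.estimates.shape != (len(self.samples), len(self.atoms)):
            raise ValueError("estimates shape does not match samples x atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def lengths_bp(self) -> np.ndarray:
        return self.atoms["length_bp"].to_numpy()

    @property
    def total_bp(self) -> int:
        return int(self.atoms["length_bp"].sum())

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def sample_values(self, sample_id: str) -> np.ndarray:
        return self.estimates[self.sample_index(sample_id)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "AtomicSegmentMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return AtomicSegmentMatrix(
            self.atoms.copy(), list(sample_ids), self.estimates[idx].copy()
        )

    def subset_atoms(self, mask: np.ndarray) -> "AtomicSegmentMatrix":
        mask = np.asarray(mask, dtype=bool)
        return AtomicSegmentMatrix(
            self.atoms.loc[mask].reset_index(drop=True),
            list(self.samples),
            self.estimates[:, mask].copy(),
        )


@dataclass
class AlleleSpecificProfile:
    """Integer allele copies per segment with tumor purity and ploidy."""

    sample_id: str
    purity: float
    ploidy: float
    segments: pd.DataFrame  # columns: chrom, start_bp, end_bp, nA, nB

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise ValueError(f"{self.sample_id}: purity must be in (0, 1]")
        if self.ploidy <= 0:
            raise ValueError(f"{self.sample_id}: ploidy must be positive")
        seg = self.segments
        required = {"chrom", "start_bp", "end_bp", "nA", "nB"}
        if required - set(seg.columns):
            raise ValueError("allele-specific segments missing columns")
        if (seg[["nA", "nB"]].to_numpy() < 0).any():
            raise ValueError(f"{self.sample_id}: negative allele copy number")
        for chrom, g in seg.groupby("chrom"):
            g = g.sort_values("start_bp")
            if (g["start_bp"].to_numpy()[1:] <= g["end_bp"].to_numpy()[:-1]).any():
                raise ValueError(f"{self.sample_id}: overlapping segments on {chrom}")

    @property
    def total_bp(self) -> int:
        return int((self.segments["end_bp"] - self.segments["start_bp"] + 1).sum())

    def total_copies(self) -> pd.DataFrame:
        df = self.segments.copy()
        df["total"] = df["nA"] + df["nB"]
        return df


@dataclass
class CohortTable:
    """Sample-to-patient mapping with clinical covariates and endpoints.

    ``samples``: sample_id, patient_id, resection (1/2), ccf (NaN allowed).
    ``patients``: patient_id, synchronous (bool), chemo_exposed (bool),
    tp53_status (wild-type/mutated/heterogeneous), age, sex,
    pfs_months, pfs_event, os_months, os_event.
    """

    samples: pd.DataFrame
    patients: pd.DataFrame

    def __post_init__(self) -> None:
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples.loc[
                self.samples["sample_id"].duplicated(), "sample_id"
            ].iloc[0]
            raise ValueError(f"sample {dup!r} mapped to more than one patient")
        if self.patients["patient_id"].duplicated().any():
            raise ValueError("duplicate patient rows")
        unknown = set(self.samples["patient_id"]) - set(self.patients["patient_id"])
        if unknown:
            raise ValueError(f"samples reference unknown patients {sorted(unknown)}")
        for col in ("pfs_months", "os_months"):
            if col in self.patients and (self.patients[col].dropna() < 0).any():
                raise ValueError(f"negative survival time in {col}")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patients["patient_id"])

    def samples_of(self, patient_id: str, resection: Optional[int] = None) -> list[str]:
        sel = self.samples["patient_id"] == patient_id
        if resection is not None:
            sel &= self.samples["resection"] == resection
        return list(self.samples.loc[sel, "sample_id"])

    def patient_of(self, sample_id: str) -> str:
        row = self.samples.loc[self.samples["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"unknown sample {sample_id!r}")
        return str(row["patient_id"].iloc[0])

    def ccf_of(self, sample_id: str) -> float:
        row = self.samples.loc[self.samples["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"unknown sample {sample_id!r}")
        return float(row["ccf"].iloc[0]) if "ccf" in row else float("nan")

    def multi_deposit_patients(self, resection: int = 1) -> list[str]:
        counts = (
            self.samples[self.samples["resection"] == resection]
            .groupby("patient_id")["sample_id"]
            .count()
        )
        return [p for p in self.patient_ids if counts.get(p, 0) >= 2]
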