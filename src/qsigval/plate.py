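"""Plate-level data model and tab-separated readers/writers.

All tabular exchange uses TSV with a header row.  Undetected wells are
represented as empty cells on disk and as ``None``/NaN in memory, never as a
sentinel Ct: a sentinel (e.g. 40) silently corrupts replicate means.

Plate table columns: ``sample_id  plate_id  gene  replicate  ct``
(optional ``batch_id``; defaults to the plate id).
Dilution table columns: ``concentration  gene  replicate  ct`` with
concentration in ng/uL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import ClinicalParams, GenePanel

__all__ = [
    "PlateFormatError",
    "WellRecord",
    "SampleRun",
    "DilutionSeries",
    "read_plate_table",
    "write_plate_table",
    "read_clinical_table",
    "read_dilution_table",
    "write_dilution_table",
    "write_scores",
    "read_scores",
]

MAX_REPLICATES = 3
CT_MAX = 45.0


class PlateFormatError(ValueError):
    """Raised on malformed plate/dilution tables."""


@dataclass(frozen=True)
class WellRecord:
    sample_id: str
    gene: str
    replicate_index: int
    ct: float | None
    plate_id: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.replicate_index <= MAX_REPLICATES:
            raise PlateFormatError(
                f"replicate index {self.replicate_index} outside 1..{MAX_REPLICATES} "
                f"({self.sample_id}/{self.gene})"
            )
        if self.ct is not None:
            if not math.isfinite(self.ct) or not 0.0 < self.ct <= CT_MAX:
                raise PlateFormatError(
                    f"Ct {self.ct} outside (0, {CT_MAX}] for {self.sample_id}/{self.gene}"
                )


@dataclass
class SampleRun:
    """One sample's wells (up to 12 genes x 3 replicates) on one plate."""

    sample_id: str
    plate_id: str
    wells: list[WellRecord]
    batch_id: str = ""
    clinical: ClinicalParams | None = None

    def __post_init__(self) -> None:
        if not self.batch_id:
            self.batch_id = self.plate_id
        seen: set[tuple[str, int]] = set()
        for w in self.wells:
            key = (w.gene, w.replicate_index)
            if key in seen:
                raise PlateFormatError(
                    f"duplicate well (sample={self.sample_id}, gene={w.gene}, "
                    f"replicate={w.replicate_index})"
                )
            seen.add(key)

    def cts(self, gene: str) -> list[float | None]:
        """Replicate Cts for ``gene`` in replicate-index order (missing = None)."""
        wells = sorted(
            (w for w in self.wells if w.gene == gene), key=lambda w: w.replicate_index
        )
        return [w.ct for w in wells]

    def valid_cts(self, gene: str) -> list[float]:
        return [ct for ct in self.cts(gene) if ct is not None]


@dataclass
class DilutionSeries:
    """A concentration ladder with replicate Ct values per gene.

    ``data`` columns: concentration (ng/uL), gene, replicate, ct.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"concentration", "gene", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise PlateFormatError(f"dilution table missing columns: {sorted(missing)}")
        if (self.data["concentration"] <= 0).any():
            raise PlateFormatError("concentrations must be positive")

    @property
    def concentrations(self) -> np.ndarray:
        """Distinct tested concentrations, descending."""
        return np.sort(self.data["concentration"].unique())[::-1]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.data["gene"].unique())

    def mean_ct(self, gene: str, concentrations: Sequence[float] | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
        """(log2 concentration, replicate-mean Ct) arrays for one gene."""
        sub = self.data[self.data["gene"] == gene].dropna(subset=["ct"])
        if concentrations is not None:
            sub = sub[sub["concentration"].isin(concentrations)]
        grouped = sub.groupby("concentration")["ct"].mean().sort_index(ascending=False)
        return np.log2(grouped.index.to_numpy(float)), grouped.to_numpy(float)


def _float_or_none(value: object) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)  # type: ignore[arg-type]


def read_plate_table(path: str | Path, panel: GenePanel) -> list[SampleRun]:
    """Parse a TSV plate export into one :class:`SampleRun` per sample.

    Empty ct cells mean undetected.  Genes outside the panel, duplicate wells
    and >3 replicates are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "plate_id": str, "gene": str})
    required = {"sample_id", "plate_id", "gene", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise PlateFormatError(f"plate table missing columns: {sorted(missing)}")
    known = set(panel.all_genes)
    unknown = sorted(set(df["gene"]) - known)
    if unknown:
        raise PlateFormatError(f"gene not in panel: {', '.join(unknown)}")
    has_batch = "batch_id" in df.columns

    runs: list[SampleRun] = []
    for sample_id, sub in df.groupby("sample_id", sort=True):
        counts = sub.groupby("gene")["replicate"].count()
        over = counts[counts > MAX_REPLICATES]
        if not over.empty:
            raise PlateFormatError(
                f"more than {MAX_REPLICATES} replicates for sample {sample_id}, "
                f"gene(s) {', '.join(over.index)}"
            )
        plate_id = str(sub["plate_id"].iloc[0])
        wells = [
            WellRecord(
                sample_id=str(sample_id),
                gene=str(r.gene),
                replicate_index=int(r.replicate),
                ct=_float_or_none(r.ct),
                plate_id=plate_id,
            )
            for r in sub.itertuples()
        ]
        batch = str(sub["batch_id"].iloc[0]) if has_batch else plate_id
        runs.append(SampleRun(str(sample_id), plate_id, wells, batch_id=batch))
    return runs


def write_plate_table(runs: Iterable[SampleRun], path: str | Path) -> None:
    rows = [
        {
            "sample_id": run.sample_id,
            "plate_id": run.plate_id,
            "batch_id": run.batch_id,
            "gene": w.gene,
            "replicate": w.replicate_index,
            "ct": "" if w.ct is None else f"{w.ct:.4f}",
        }
        for run in runs
        for w in run.wells
    ]
    cols = ["sample_id", "plate_id", "batch_id", "gene", "replicate", "ct"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_clinical_table(path: str | Path) -> dict[str, ClinicalParams]:
    """TSV columns: sample_id, tumor_size_category, positive_nodes."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "tumor_size_category", "positive_nodes"}
    missing = required - set(df.columns)
    if missing:
        raise PlateFormatError(f"clinical table missing columns: {sorted(missing)}")
    out: dict[str, ClinicalParams] = {}
    for r in df.itertuples():
        out[str(r.sample_id)] = ClinicalParams(
            tumor_size_category=r.tumor_size_category,
            positive_nodes=int(r.positive_nodes),
        )
    return out


def read_dilution_table(path: str | Path) -> DilutionSeries:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return DilutionSeries(df)


def write_dilution_table(series: DilutionSeries, path: str | Path) -> None:
    df = series.data.copy()
    df["ct"] = df["ct"].map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
    df.to_csv(path, sep="\t", index=False)


SCORE_COLUMNS = [
    "sample_id",
    "plate_id",
    "qc_pass",
    "qc_reasons",
    "hkm",
    "molecular_score",
    "clinical_score",
    "clinical_score_1dp",
    "risk",
]


def write_scores(results: Iterable["ScoreResult"], path: str | Path) -> None:  # noqa: F821
    """Write score results as TSV: scores at 2 decimals, the clinical score
    additionally at the 1-decimal reporting granularity used for risk calls."""
    rows = []
    for r in results:
        rows.append(
            {
                "sample_id": r.sample_id,
                "plate_id": r.plate_id,
                "qc_pass": str(r.qc.passed).lower(),
                "qc_reasons": ";".join(r.qc.reasons),
                "hkm": "" if r.qc.hkm is None else f"{r.qc.hkm:.2f}",
                "molecular_score": ""
                if r.molecular_score is None
                else f"{r.molecular_score:.2f}",
                "clinical_score": ""
                if r.clinical_score is None
                else f"{r.clinical_score:.2f}",
                "clinical_score_1dp": ""
                if r.clinical_score_1dp is None
                else f"{r.clinical_score_1dp:.1f}",
                "risk": r.risk or "",
            }
        )
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "risk": str})
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise PlateFormatError(f"score table missing columns: {sorted(missing)}")
    return df
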