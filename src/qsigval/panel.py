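"""Static assay definition: gene roles, score coefficients and QC thresholds.

The assay measures eight target genes whose housekeeper-normalized expression
enters a linear molecular score, three housekeeper genes whose mean Ct (the
housekeeper mean, HKM) both normalizes expression and gates RNA input, and one
contamination-control gene that amplifies only from genomic DNA.  A
:class:`GenePanel` bundles that structure with the numeric constants of the
deployed test (score coefficients, HKM validity window, contamination cutoff,
risk cutoffs) so that everything downstream is configuration-driven.

Panels are loaded from a TOML file via :func:`read_panel_config`; the package
ships a synthetic example panel (the published coefficient values are not
public) accessible through :func:`example_panel`.
"""

from __future__ import annotations

import importlib.resources
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "PanelConfigError",
    "ClinicalModel",
    "ClinicalParams",
    "GenePanel",
    "read_panel_config",
    "example_panel",
]

N_TARGETS = 8
N_HOUSEKEEPERS = 3


class PanelConfigError(ValueError):
    """Raised when a panel configuration violates the assay structure."""


@dataclass(frozen=True)
class ClinicalModel:
    """Linear combination of molecular score, tumor size code and node count.

    clinical = intercept + w_molecular*mol + w_size*size_code + w_nodes*node_code

    ``size_codes`` optionally maps size-category labels to numeric codes;
    numeric categories pass through unchanged.  ``node_cap`` caps the node
    count before weighting (None = uncapped).
    """

    w_molecular: float
    w_size: float
    w_nodes: float
    intercept: float = 0.0
    size_codes: Mapping[str, float] | None = None
    node_cap: int | None = None

    def size_code(self, category: object) -> float:
        if self.size_codes is not None:
            key = str(category)
            if key not in self.size_codes:
                raise PanelConfigError(
                    f"tumor size category {category!r} not in configured coding table"
                )
            return float(self.size_codes[key])
        return float(category)  # type: ignore[arg-type]

    def node_code(self, positive_nodes: int) -> float:
        n = int(positive_nodes)
        if n < 0:
            raise PanelConfigError("positive node count must be non-negative")
        if self.node_cap is not None:
            n = min(n, self.node_cap)
        return float(n)


@dataclass(frozen=True)
class ClinicalParams:
    """Per-sample clinical covariates entering the clinical score."""

    tumor_size_category: object
    positive_nodes: int


@dataclass(frozen=True)
class GenePanel:
    targets: tuple[str, ...]
    housekeepers: tuple[str, ...]
    contamination_gene: str
    score_intercept: float
    score_coefficients: Mapping[str, float]
    clip_bounds: tuple[float, float] | None = None
    hkm_valid_range: tuple[float, float] = (19.0, 27.0)
    contamination_ct_cutoff: float = 38.0
    contamination_min_replicates: int = 2
    risk_cutoff_low: float = 3.3
    risk_cutoff_high: float = 3.4
    clinical: ClinicalModel | None = None
    name: str = "unnamed-panel"

    def __post_init__(self) -> None:
        if len(self.targets) != N_TARGETS:
            raise PanelConfigError(
                f"panel must define exactly {N_TARGETS} target genes, got {len(self.targets)}"
            )
        if len(self.housekeepers) != N_HOUSEKEEPERS:
            raise PanelConfigError(
                f"panel must define exactly {N_HOUSEKEEPERS} housekeeper genes, "
                f"got {len(self.housekeepers)}"
            )
        all_genes = (*self.targets, *self.housekeepers, self.contamination_gene)
        if len(set(all_genes)) != len(all_genes):
            raise PanelConfigError("gene identifiers must be distinct across roles")
        missing = set(self.targets) - set(self.score_coefficients)
        if missing:
            raise PanelConfigError(
                f"missing score coefficient for target(s): {', '.join(sorted(missing))}"
            )
        extra = set(self.score_coefficients) - set(self.targets)
        if extra:
            raise PanelConfigError(
                f"score coefficient for non-target gene(s): {', '.join(sorted(extra))}"
            )
        lo, hi = self.hkm_valid_range
        if not lo < hi:
            raise PanelConfigError("hkm_valid_range low must be < high")
        if self.clip_bounds is not None and not self.clip_bounds[0] < self.clip_bounds[1]:
            raise PanelConfigError("clip_bounds min must be < max")
        if not self.risk_cutoff_low < self.risk_cutoff_high:
            raise PanelConfigError("risk_cutoff_low must be < risk_cutoff_high")
        if self.contamination_min_replicates < 1:
            raise PanelConfigError("contamination_min_replicates must be >= 1")

    @property
    def expression_genes(self) -> tuple[str, ...]:
        """The 11 genes whose Ct measures expression (targets + housekeepers)."""
        return self.targets + self.housekeepers

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.expression_genes + (self.contamination_gene,)


def _pair(value: object, what: str) -> tuple[float, float]:
    try:
        a, b = value  # type: ignore[misc]
        return float(a), float(b)
    except (TypeError, ValueError) as exc:
        raise PanelConfigError(f"malformed {what}: {value!r}") from exc


def _build_panel(cfg: Mapping, name: str) -> GenePanel:
    try:
        genes = cfg["genes"]
        score = cfg["score"]
    except KeyError as exc:
        raise PanelConfigError(f"panel config missing section {exc}") from exc
    qc = cfg.get("qc", {})
    risk = cfg.get("risk", {})

    clinical = None
    if "clinical" in cfg:
        c = cfg["clinical"]
        clinical = ClinicalModel(
            w_molecular=float(c["w_molecular"]),
            w_size=float(c["w_size"]),
            w_nodes=float(c["w_nodes"]),
            intercept=float(c.get("intercept", 0.0)),
            size_codes={str(k): float(v) for k, v in c["size_codes"].items()}
            if "size_codes" in c
            else None,
            node_cap=int(c["node_cap"]) if "node_cap" in c else None,
        )

    clip = _pair(score["clip"], "clip bounds") if "clip" in score else None
    return GenePanel(
        targets=tuple(genes["targets"]),
        housekeepers=tuple(genes["housekeepers"]),
        contamination_gene=str(genes["contamination"]),
        score_intercept=float(score.get("intercept", 0.0)),
        score_coefficients={str(k): float(v) for k, v in score["coefficients"].items()},
        clip_bounds=clip,
        hkm_valid_range=_pair(qc.get("hkm_range", (19.0, 27.0)), "hkm_range"),
        contamination_ct_cutoff=float(qc.get("contamination_ct_cutoff", 38.0)),
        contamination_min_replicates=int(qc.get("contamination_min_replicates", 2)),
        risk_cutoff_low=float(risk.get("low_max", 3.3)),
        risk_cutoff_high=float(risk.get("high_min", 3.4)),
        clinical=clinical,
        name=name,
    )


def read_panel_config(path: str | Path) -> GenePanel:
    """Load and validate a :class:`GenePanel` from a TOML config file.

    Unspecified QC/risk thresholds take the deployed test's defaults:
    HKM range (19, 27), contamination Ct cutoff 38 at >=2 replicates,
    risk cutoffs (3.3, 3.4).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    return _build_panel(cfg, name=path.stem)


def example_panel() -> GenePanel:
    """The bundled SYNTHETIC example panel.

    Gene identities, roles and QC thresholds are the published assay's; the
    score coefficients, intercept and clinical weights are synthetic
    placeholders (the deployed values are proprietary and unpublished).
    """
    ref = importlib.resources.files("qsigval.data").joinpath("example_panel.toml")
    cfg = tomllib.loads(ref.read_text())
    return _build_panel(cfg, name="example_panel")
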