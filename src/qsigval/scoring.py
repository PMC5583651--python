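"""Per-sample scoring: replicate averaging, HKM normalization, QC gates,
molecular and clinical scores, risk dichotomization.

Pipeline for one sample run::

    triplicate Ct -> per-gene mean -> HKM (mean of 3 housekeepers)
                  -> normalized expression (HKM - Ct, higher = more expressed)
                  -> molecular score (intercept + sum coef_g * expr_g, clipped)
                  -> clinical score (+ tumor size, positive nodes)
                  -> risk class (rounded to 1 decimal; <=3.3 low, >=3.4 high)

QC gates (any failure withholds the scores):

* HKM inside the validated window (inclusive; default 19-27) — proxy for
  adequate RNA input.
* No genomic-DNA contamination: fewer than 2 replicates of the control gene
  (HBB) with Ct strictly below 38.
* Every expression gene measured with at least 2 valid replicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

from .panel import ClinicalParams, GenePanel
from .plate import SampleRun

__all__ = [
    "QCResult",
    "ScoreResult",
    "average_replicates",
    "compute_hkm",
    "check_dna_contamination",
    "normalize_targets",
    "molecular_score",
    "clinical_score",
    "classify_risk",
    "score_sample",
]

logger = logging.getLogger(__name__)

# QC reason codes
HKM_OUT_OF_RANGE = "HKM_OUT_OF_RANGE"
DNA_CONTAMINATION = "DNA_CONTAMINATION"
INSUFFICIENT_REPLICATES = "INSUFFICIENT_REPLICATES"
MISSING_GENE = "MISSING_GENE"
REPLICATE_SPREAD = "REPLICATE_SPREAD"  # warning only, never a failure

MIN_VALID_REPLICATES = 2
REPLICATE_SPREAD_WARN_CT = 1.0


@dataclass(frozen=True)
class QCResult:
    hkm: float | None
    hkm_in_range: bool
    dna_contaminated: bool
    n_hbb_below_cutoff: int
    replicate_ok: bool
    reasons: tuple[str, ...]
    warnings: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return self.hkm_in_range and not self.dna_contaminated and self.replicate_ok


@dataclass(frozen=True)
class ScoreResult:
    sample_id: str
    plate_id: str
    qc: QCResult
    gene_means: Mapping[str, float]
    normalized_expression: Mapping[str, float]
    molecular_score: float | None
    clinical_score: float | None
    risk: str | None

    @property
    def clinical_score_1dp(self) -> float | None:
        if self.clinical_score is None:
            return None
        return _round_half_up(self.clinical_score, 1)


def average_replicates(run: SampleRun, panel: GenePanel) -> tuple[dict[str, float], list[str]]:
    """Arithmetic mean of non-missing replicate Cts per expression gene.

    The contamination gene is excluded (it is gated, not averaged).  Returns
    ``(means, flagged)`` where ``flagged`` lists genes with fewer than 2 valid
    replicates; such genes still get a mean if they have one value, but the
    sample fails replicate QC downstream.
    """
    means: dict[str, float] = {}
    flagged: list[str] = []
    for gene in panel.expression_genes:
        values = run.valid_cts(gene)
        if len(values) < MIN_VALID_REPLICATES:
            flagged.append(gene)
        if values:
            means[gene] = sum(values) / len(values)
    return means, flagged


def compute_hkm(gene_means: Mapping[str, float], panel: GenePanel) -> float | None:
    """Housekeeper mean: arithmetic mean of the 3 housekeeper mean-Cts.

    Returns None if any housekeeper mean is missing (the sample then fails).
    """
    try:
        return sum(gene_means[g] for g in panel.housekeepers) / len(panel.housekeepers)
    except KeyError:
        return None


def check_dna_contamination(run: SampleRun, panel: GenePanel) -> tuple[bool, int]:
    """Genomic-DNA gate on the contamination-control gene.

    A replicate counts if its Ct is strictly below the cutoff (missing wells
    never count); the sample is contaminated when at least
    ``contamination_min_replicates`` replicates count.
    """
    count = sum(
        1
        for ct in run.valid_cts(panel.contamination_gene)
        if ct < panel.contamination_ct_cutoff
    )
    return count >= panel.contamination_min_replicates, count


def normalize_targets(
    gene_means: Mapping[str, float], hkm: float, panel: GenePanel
) -> dict[str, float]:
    """Housekeeper-normalized expression, HKM - Ct (higher = more expressed)."""
    missing = [g for g in panel.targets if g not in gene_means]
    if missing:
        raise KeyError(f"missing target mean(s): {', '.join(missing)}")
    return {g: hkm - gene_means[g] for g in panel.targets}


def molecular_score(normalized: Mapping[str, float], panel: GenePanel) -> float:
    """Linear combination of the 8 normalized target expressions, clipped to
    the panel's reporting bounds if configured."""
    score = panel.score_intercept + sum(
        panel.score_coefficients[g] * normalized[g] for g in panel.targets
    )
    if panel.clip_bounds is not None:
        lo, hi = panel.clip_bounds
        score = min(max(score, lo), hi)
    return score


def clinical_score(
    mol: float, clinical: ClinicalParams | None, panel: GenePanel
) -> float | None:
    """Configured linear combination of molecular score, tumor-size code and
    positive-node code; None when covariates or the model are absent."""
    model = panel.clinical
    if model is None or clinical is None:
        return None
    return (
        model.intercept
        + model.w_molecular * mol
        + model.w_size * model.size_code(clinical.tumor_size_category)
        + model.w_nodes * model.node_code(clinical.positive_nodes)
    )


def _round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals, immune to binary
    float artifacts (e.g. 3.35 -> 3.4)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def classify_risk(score: float, panel: GenePanel) -> str:
    """Dichotomize a clinical score at the published cutoffs.

    The score is first rounded to 1 decimal (the cutoffs' granularity), which
    closes the (3.3, 3.4) gap: <=3.3 -> low, >=3.4 -> high.
    """
    rounded = _round_half_up(score, 1)
    return "low" if rounded <= panel.risk_cutoff_low else "high"


def score_sample(run: SampleRun, panel: GenePanel) -> ScoreResult:
    """Full per-sample pipeline; QC failures withhold scores, never raise."""
    gene_means, flagged = average_replicates(run, panel)
    reasons: list[str] = []
    warnings: list[str] = []

    if any(g not in gene_means for g in flagged):
        reasons.append(MISSING_GENE)
    if any(g in gene_means for g in flagged):
        reasons.append(INSUFFICIENT_REPLICATES)
    replicate_ok = not flagged

    for gene in panel.expression_genes:
        values = run.valid_cts(gene)
        if len(values) >= 2 and max(values) - min(values) > REPLICATE_SPREAD_WARN_CT:
            warnings.append(f"{REPLICATE_SPREAD}:{gene}")

    hkm = compute_hkm(gene_means, panel)
    lo, hi = panel.hkm_valid_range
    hkm_in_range = hkm is not None and lo <= hkm <= hi
    if not hkm_in_range:
        reasons.append(HKM_OUT_OF_RANGE)

    contaminated, n_below = check_dna_contamination(run, panel)
    if contaminated:
        reasons.append(DNA_CONTAMINATION)

    qc = QCResult(
        hkm=hkm,
        hkm_in_range=hkm_in_range,
        dna_contaminated=contaminated,
        n_hbb_below_cutoff=n_below,
        replicate_ok=replicate_ok,
        reasons=tuple(dict.fromkeys(reasons)),
        warnings=tuple(warnings),
    )

    normalized: dict[str, float] = {}
    mol: float | None = None
    clin: float | None = None
    risk: str | None = None
    if qc.passed:
        normalized = normalize_targets(gene_means, hkm, panel)  # type: ignore[arg-type]
        mol = molecular_score(normalized, panel)
        clin = clinical_score(mol, run.clinical, panel)
        if clin is not None:
            risk = classify_risk(clin, panel)
    else:
        logger.info("sample %s failed QC: %s", run.sample_id, ",".join(qc.reasons))

    return ScoreResult(
        sample_id=run.sample_id,
        plate_id=run.plate_id,
        qc=qc,
        gene_means=gene_means,
        normalized_expression=normalized,
        molecular_score=mol,
        clinical_score=clin,
        risk=risk,
    )
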