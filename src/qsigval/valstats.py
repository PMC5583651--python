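"""Analytical-validation statistics for the qPCR signature.

Accuracy
    Agreement between two laboratories' scores on the same samples:
    Lin's concordance correlation coefficient (CCC) with a Fisher-z
    confidence interval, plus a paired t-test on the score differences.

Precision
    Pooled SD = sqrt(mean within-group sample variance) over replicate
    groups, with a two-sided chi-square confidence interval.  The default
    degrees-of-freedom convention is the number of groups, which reproduces
    a pooled SD of 0.21 over 12 samples giving a 95% interval (0.15, 0.35);
    the Satterthwaite-free pooled convention (sum of per-group n_i - 1) is
    available as an option.

Linearity / efficiency
    Per-gene ordinary least squares of replicate-mean Ct on log2(RNA
    concentration); amplification efficiency from the slope via the base-2
    dilution-curve formula eff% = (2**(-1/slope) - 1) * 100; the assay's
    linear range as the widest contiguous concentration window over which
    every expression gene fits with R^2 above threshold.

Stability
    Per-sample SD of the molecular score across storage timepoints.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .panel import GenePanel
from .plate import DilutionSeries
from .scoring import molecular_score, normalize_targets

__all__ = [
    "ConcordanceResult",
    "PrecisionResult",
    "GeneFit",
    "LinearityResult",
    "StabilityResult",
    "HkmConcentrationMap",
    "lin_ccc",
    "pooled_sd",
    "sd_confidence_interval",
    "fit_gene_dilution",
    "amplification_efficiency",
    "determine_linear_range",
    "score_sd_over_dilution",
    "hkm_concentration_map",
    "stability_analysis",
    "input_mass",
]

logger = logging.getLogger(__name__)

DEFAULT_INOCULATION_VOLUME_UL = 45.0


# --------------------------------------------------------------------------
# accuracy


@dataclass(frozen=True)
class ConcordanceResult:
    ccc: float
    ccc_ci: tuple[float, float]
    mean_diff: float
    mean_diff_ci: tuple[float, float]
    t_pvalue: float
    n_pairs: int


def lin_ccc(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> ConcordanceResult:
    """Lin's concordance correlation between paired measurements.

    CCC = 2*cov(x,y) / (var(x) + var(y) + (mean(x)-mean(y))**2) with
    population (1/n) moments.  The CI uses Lin's asymptotic standard error on
    the Fisher z scale.  ``mean_diff`` is mean(x - y) with a paired-t CI and
    two-sided p-value.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("need >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")

    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError("CCC undefined: zero variance and equal means")
    ccc = 2.0 * sxy / denom

    # Lin (1989) variance of the z-transformed estimate
    zcrit = stats.norm.ppf(1 - alpha / 2)
    r = sxy / math.sqrt(sx2 * sy2) if sx2 > 0 and sy2 > 0 else 0.0
    if r != 0.0 and abs(ccc) < 1:
        u2 = (mx - my) ** 2 / math.sqrt(sx2 * sy2)
        se_z2 = (
            (1 - r**2) * ccc**2 / ((1 - ccc**2) * r**2)
            + 2 * ccc**3 * (1 - ccc) * u2 / (r * (1 - ccc**2) ** 2)
            - ccc**4 * u2**2 / (2 * r**2 * (1 - ccc**2) ** 2)
        ) / (n - 2)
        z = math.atanh(ccc)
        half = zcrit * math.sqrt(max(se_z2, 0.0))
        ci = (math.tanh(z - half), math.tanh(z + half))
    else:
        ci = (ccc, ccc)

    d = x - y
    mean_diff = float(d.mean())
    sd_d = float(d.std(ddof=1))
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    half_d = tcrit * sd_d / math.sqrt(n)
    if sd_d == 0:
        pval = 1.0 if mean_diff == 0 else 0.0
    else:
        tstat = mean_diff / (sd_d / math.sqrt(n))
        pval = float(2 * stats.t.sf(abs(tstat), n - 1))
    return ConcordanceResult(
        ccc=float(ccc),
        ccc_ci=ci,
        mean_diff=mean_diff,
        mean_diff_ci=(mean_diff - half_d, mean_diff + half_d),
        t_pvalue=pval,
        n_pairs=int(n),
    )


# --------------------------------------------------------------------------
# precision


@dataclass(frozen=True)
class PrecisionResult:
    pooled_sd: float
    sd_ci: tuple[float, float]
    df_convention: str
    n_groups: int
    reps_per_group: tuple[int, ...]


def sd_confidence_interval(sd: float, df: int, alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided chi-square interval for an SD: sd * sqrt(df / chi2_{q, df})."""
    if df < 1:
        raise ValueError("df must be >= 1")
    lower = sd * math.sqrt(df / stats.chi2.ppf(1 - alpha / 2, df))
    upper = sd * math.sqrt(df / stats.chi2.ppf(alpha / 2, df))
    return float(lower), float(upper)


def pooled_sd(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    df_convention: str = "groups",
    alpha: float = 0.05,
) -> PrecisionResult:
    """Square root of the mean within-group sample variance.

    ``df_convention``: 'groups' uses df = number of groups for the chi-square
    interval; 'pooled' uses df = sum(n_i - 1).
    """
    if isinstance(groups, Mapping):
        items = list(groups.items())
    else:
        items = [(str(i), g) for i, g in enumerate(groups)]
    if not items:
        raise ValueError("no groups supplied")
    variances = []
    sizes = []
    for name, values in items:
        arr = np.asarray(values, float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        variances.append(float(arr.var(ddof=1)))
        sizes.append(int(arr.size))
    sd = math.sqrt(sum(variances) / len(variances))
    if df_convention == "groups":
        df = len(items)
    elif df_convention == "pooled":
        df = sum(n - 1 for n in sizes)
    else:
        raise ValueError(f"unknown df convention {df_convention!r}")
    return PrecisionResult(
        pooled_sd=sd,
        sd_ci=sd_confidence_interval(sd, df, alpha),
        df_convention=df_convention,
        n_groups=len(items),
        reps_per_group=tuple(sizes),
    )


# --------------------------------------------------------------------------
# linearity / efficiency


@dataclass(frozen=True)
class GeneFit:
    slope: float  # Ct per log2 concentration unit
    intercept: float
    r2: float
    max_abs_residual: float
    efficiency_pct: float | None


@dataclass(frozen=True)
class LinearityResult:
    per_gene: Mapping[str, GeneFit]
    linear_range: tuple[float, float]  # (conc_low, conc_high) ng/uL
    score_mean: float | None = None
    score_sd: float | None = None
    score_sd_ci: tuple[float, float] | None = None


def fit_gene_dilution(
    series: DilutionSeries,
    gene: str,
    concentrations: Sequence[float] | None = None,
) -> GeneFit:
    """OLS of replicate-mean Ct on log2(concentration) for one gene."""
    log2c, ct = series.mean_ct(gene, concentrations)
    if log2c.size < 3:
        raise ValueError(f"gene {gene!r}: need >= 3 distinct concentrations, got {log2c.size}")
    fit = stats.linregress(log2c, ct)
    residuals = ct - (fit.intercept + fit.slope * log2c)
    r2 = float(fit.rvalue**2)
    eff = amplification_efficiency(fit.slope) if fit.slope < 0 else None
    return GeneFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        max_abs_residual=float(np.max(np.abs(residuals))),
        efficiency_pct=eff,
    )


def amplification_efficiency(slope: float) -> float:
    """Per-cycle amplification rate (%) from the log2 dilution-curve slope.

    eff% = (2**(-1/slope) - 1) * 100; a slope of -1 Ct per concentration
    doubling means perfect doubling per cycle, 100%.
    """
    if slope >= 0:
        raise ValueError("non-amplifying fit: slope must be negative")
    return (2.0 ** (-1.0 / slope) - 1.0) * 100.0


def determine_linear_range(
    series: DilutionSeries,
    panel: GenePanel,
    r2_threshold: float = 0.95,
    min_points: int = 3,
) -> tuple[float, float]:
    """Widest contiguous concentration window with per-gene R^2 >= threshold
    for every expression gene; ties broken toward the window including lower
    concentrations.  Returns (conc_low, conc_high)."""
    concs = series.concentrations  # descending
    if concs.size < 4:
        raise ValueError("need >= 4 dilution points")
    genes = [g for g in panel.expression_genes if g in series.genes]
    if not genes:
        raise ValueError("series contains no panel expression genes")

    best: tuple[float, float] | None = None
    best_width = -1
    # iterate windows widest-first; among equal widths prefer the one
    # extending furthest down the ladder (largest start index)
    for width in range(concs.size, min_points - 1, -1):
        for start in range(concs.size - width, -1, -1):
            window = concs[start : start + width]
            ok = True
            for gene in genes:
                fit = fit_gene_dilution(series, gene, concentrations=window)
                if fit.r2 < r2_threshold:
                    ok = False
                    break
            if ok and width > best_width:
                best = (float(window[-1]), float(window[0]))
                best_width = width
                break
        if best is not None:
            break
    if best is None:
        raise ValueError(f"no contiguous sub-range of >= {min_points} points is linear")
    return best


def score_sd_over_dilution(
    series: DilutionSeries,
    panel: GenePanel,
    alpha: float = 0.05,
) -> tuple[float, float, tuple[float, float]]:
    """Molecular-score consistency across the dilution ladder.

    Scores each dilution point from the replicate-mean Cts (QC gates relaxed:
    the ladder deliberately exceeds the clinical HKM window) and returns
    (mean score, SD across points, chi-square CI with df = number of points).
    """
    scores = []
    for conc in series.concentrations:
        sub = series.data[series.data["concentration"] == conc].dropna(subset=["ct"])
        means = sub.groupby("gene")["ct"].mean().to_dict()
        if any(g not in means for g in panel.expression_genes):
            logger.warning("dilution point %g ng/uL not scoreable; excluded", conc)
            continue
        hkm = sum(means[g] for g in panel.housekeepers) / len(panel.housekeepers)
        normalized = normalize_targets(means, hkm, panel)
        scores.append(molecular_score(normalized, panel))
    if len(scores) < 2:
        raise ValueError("need >= 2 scoreable dilution points for an SD")
    arr = np.asarray(scores)
    sd = float(arr.std(ddof=1))
    return float(arr.mean()), sd, sd_confidence_interval(sd, len(scores), alpha)


@dataclass(frozen=True)
class HkmConcentrationMap:
    """Invertible linear map between HKM and log2 RNA concentration, from the
    pooled housekeeper dilution regression HKM = intercept + slope*log2(conc)."""

    slope: float
    intercept: float
    volume_ul: float = DEFAULT_INOCULATION_VOLUME_UL

    def hkm_at(self, concentration: float) -> float:
        return self.intercept + self.slope * math.log2(concentration)

    def concentration_at(self, hkm: float) -> float:
        return 2.0 ** ((hkm - self.intercept) / self.slope)

    def input_mass_at(self, hkm: float) -> float:
        """RNA input mass (ng) at the configured inoculation volume."""
        return input_mass(self.concentration_at(hkm), self.volume_ul)


def input_mass(concentration_ng_ul: float, volume_ul: float = DEFAULT_INOCULATION_VOLUME_UL) -> float:
    """RNA mass (ng) loaded at a given concentration and inoculation volume."""
    return concentration_ng_ul * volume_ul


def hkm_concentration_map(
    series: DilutionSeries,
    panel: GenePanel,
    volume_ul: float = DEFAULT_INOCULATION_VOLUME_UL,
) -> HkmConcentrationMap:
    """Fit the HKM <-> concentration map from the housekeeper dilution data."""
    hkms = []
    log2cs = []
    for conc in series.concentrations:
        sub = series.data[series.data["concentration"] == conc].dropna(subset=["ct"])
        means = sub.groupby("gene")["ct"].mean().to_dict()
        if any(g not in means for g in panel.housekeepers):
            continue
        hkms.append(sum(means[g] for g in panel.housekeepers) / len(panel.housekeepers))
        log2cs.append(math.log2(conc))
    if len(hkms) < 3:
        raise ValueError("housekeeper fit failure: fewer than 3 usable dilution points")
    fit = stats.linregress(log2cs, hkms)
    if fit.slope == 0:
        raise ValueError("housekeeper fit failure: zero slope")
    return HkmConcentrationMap(float(fit.slope), float(fit.intercept), volume_ul)


# --------------------------------------------------------------------------
# stability


@dataclass(frozen=True)
class StabilityResult:
    per_sample_sd: Mapping[str, float]
    delta_scores: Mapping[tuple[str, object], float]
    max_sd: float


def stability_analysis(
    timecourse: Mapping[tuple[str, object], float],
) -> StabilityResult:
    """Per-sample SD of scores across storage timepoints.

    ``timecourse`` maps (sample, timepoint) to a molecular score.  Samples
    with a single timepoint are excluded with a warning.  Delta scores are
    deviations from each sample's own timecourse mean (so they sum to ~0).
    """
    by_sample: dict[str, dict[object, float]] = {}
    for (sample, tp), score in timecourse.items():
        by_sample.setdefault(sample, {})[tp] = score
    per_sample_sd: dict[str, float] = {}
    deltas: dict[tuple[str, object], float] = {}
    for sample, points in by_sample.items():
        values = np.asarray(list(points.values()), float)
        if values.size < 2:
            logger.warning("sample %s has a single timepoint; excluded", sample)
            continue
        per_sample_sd[sample] = float(values.std(ddof=1))
        mean = values.mean()
        for tp, score in points.items():
            deltas[(sample, tp)] = float(score - mean)
    if not per_sample_sd:
        raise ValueError("no sample has >= 2 timepoints")
    return StabilityResult(
        per_sample_sd=per_sample_sd,
        delta_scores=deltas,
        max_sd=max(per_sample_sd.values()),
    )
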