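"""Seeded simulation of plate-level Ct data with the statistical structure
the validation framework assumes.

The generator emulates the assay's measurement model on Ct scale:

* each gene amplifies with a per-gene efficiency ``eff`` (percent), so its
  dilution-curve slope is ``-1 / log2(1 + eff/100)`` Ct per concentration
  doubling (exactly -1 at 100%);
* replicate wells carry additive Gaussian noise (default SD 0.3 Ct, the
  scale of the assay's observed per-gene replicate SDs);
* plates contribute per-gene batch shifts shared by all wells of a gene on
  that plate (inter-batch runs redraw them; intra-batch runs share them);
* the contamination-control gene is silent (high/undetected Ct) unless
  genomic-DNA contamination is injected.

Default per-gene efficiencies and intercepts are calibrated so the stock
two-fold ladder (12 points, 100 down to 100/2**11 ~ 0.049 ng/uL) spans a
housekeeper mean of roughly 17 to 28, and so sample molecular scores under
the bundled example panel span roughly 2 to 7.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import GenePanel
from .plate import CT_MAX, DilutionSeries, SampleRun, WellRecord

__all__ = [
    "SimulationConfig",
    "default_ladder",
    "slope_for_efficiency",
    "well_sd_for_score_sd",
    "simulate_dilution_series",
    "simulate_sample_batch",
    "simulate_timecourse",
    "inject_contamination",
]

#: per-gene amplification efficiencies (%) used as simulation truth
DEFAULT_EFFICIENCY: Mapping[str, float] = {
    "AZGP1": 97.6,
    "BIRC5": 98.8,
    "DHCR7": 99.3,
    "IL6ST": 98.1,
    "MGP": 97.0,
    "RBBP8": 98.9,
    "STC2": 101.1,
    "UBE2C": 95.9,
    "CALM2": 101.0,
    "OAZ1": 101.1,
    "RPL37A": 97.8,
}

#: per-gene Ct at 1 ng/uL for the dilution-series positive control; the
#: housekeeper values center on 23.6 so the stock ladder maps to HKM ~17-28
DEFAULT_INTERCEPT: Mapping[str, float] = {
    "AZGP1": 24.5,
    "BIRC5": 26.0,
    "DHCR7": 25.0,
    "IL6ST": 23.5,
    "MGP": 21.5,
    "RBBP8": 26.5,
    "STC2": 24.0,
    "UBE2C": 26.0,
    "CALM2": 23.2,
    "OAZ1": 23.6,
    "RPL37A": 24.0,
}


def default_ladder(top: float = 100.0, n_points: int = 12, fold: float = 2.0) -> tuple[float, ...]:
    """Serial dilution ladder: ``n_points`` steps of ``fold``-fold dilution
    from ``top`` ng/uL (default 100 down to ~0.049)."""
    return tuple(top / fold**k for k in range(n_points))


@dataclass(frozen=True)
class SimulationConfig:
    panel: GenePanel
    per_gene_efficiency: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFICIENCY)
    )
    per_gene_intercept: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTERCEPT)
    )
    replicate_noise_sd: float = 0.3  # Ct, per well
    batch_effect_sd: float = 0.15  # Ct, per gene per plate
    n_samples: int = 12
    reps: int = 3
    dilution_ladder: tuple[float, ...] = field(default_factory=default_ladder)
    contamination_rate: float = 0.0
    contamination_ct: float = 36.0
    clean_hbb_ct: float = 41.0
    #: uniform half-width of true normalized target expression around its center
    expression_spread: float = 2.1
    #: per-sample true HKM drawn uniformly in this window
    hkm_window: tuple[float, float] = (21.0, 25.0)
    timepoints: tuple[float, ...] = (0, 1, 2, 3, 4, 5, 6)  # weeks
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_noise_sd < 0 or self.batch_effect_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if any(e <= 0 for e in self.per_gene_efficiency.values()):
            raise ValueError("efficiencies must be > 0")
        ladder = np.asarray(self.dilution_ladder)
        if (ladder <= 0).any():
            raise ValueError("concentrations must be positive")
        if (np.diff(ladder) >= 0).any():
            raise ValueError("dilution ladder must be strictly decreasing")
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ValueError("contamination_rate must be in [0, 1]")


def slope_for_efficiency(efficiency_pct: float) -> float:
    """Dilution-curve slope (Ct per log2 concentration) implied by a per-gene
    amplification efficiency; the inverse of the estimator's formula."""
    return -1.0 / np.log2(1.0 + efficiency_pct / 100.0)


def simulate_dilution_series(cfg: SimulationConfig) -> DilutionSeries:
    """Simulate the positive-control serial dilution experiment.

    Ct(gene, conc, rep) = intercept_g + slope(eff_g) * log2(conc) + N(0, sd).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.panel.expression_genes
    rows = []
    for gene in genes:
        slope = slope_for_efficiency(cfg.per_gene_efficiency[gene])
        intercept = cfg.per_gene_intercept[gene]
        for conc in cfg.dilution_ladder:
            mean_ct = intercept + slope * np.log2(conc)
            noise = rng.normal(0.0, cfg.replicate_noise_sd, size=cfg.reps)
            for rep in range(cfg.reps):
                rows.append(
                    {
                        "concentration": conc,
                        "gene": gene,
                        "replicate": rep + 1,
                        "ct": mean_ct + noise[rep],
                    }
                )
    return DilutionSeries(pd.DataFrame(rows))


def well_sd_for_score_sd(
    panel: GenePanel, score_sd: float, wells_per_gene: int = 3
) -> float:
    """Per-well Ct noise SD that yields a given molecular-score SD.

    The score is linear in the per-gene mean Cts with weight -c_g on target g
    and sum(c)/len(housekeepers) on each housekeeper, so iid per-gene
    perturbations of SD s give score variance
    s**2 * (sum c_g**2 + (sum c_g)**2 / n_hk); per-well noise averages over
    ``wells_per_gene`` replicate wells.
    """
    coefs = np.array([panel.score_coefficients[g] for g in panel.targets])
    gain = float(np.sum(coefs**2) + np.sum(coefs) ** 2 / len(panel.housekeepers))
    return score_sd / np.sqrt(gain) * np.sqrt(wells_per_gene)


def _true_sample_cts(cfg: SimulationConfig, rng: np.random.Generator) -> list[dict[str, float]]:
    """Per-sample true Ct per expression gene, built from a true HKM and true
    normalized target expressions (uniform around centers chosen so example
    scores span roughly 2-7)."""
    panel = cfg.panel
    samples = []
    for _ in range(cfg.n_samples):
        hkm = rng.uniform(*cfg.hkm_window)
        hk_offsets = rng.normal(0.0, 0.7, size=len(panel.housekeepers))
        hk_offsets -= hk_offsets.mean()  # keep the true HKM exact
        cts = {g: hkm + off for g, off in zip(panel.housekeepers, hk_offsets)}
        for g in panel.targets:
            expr = rng.uniform(2.5 - cfg.expression_spread, 2.5 + cfg.expression_spread)
            cts[g] = hkm - expr
        samples.append(cts)
    return samples


def simulate_sample_batch(
    cfg: SimulationConfig, mode: str = "inter"
) -> list[SampleRun]:
    """Simulate a precision experiment: ``n_samples`` samples, each run
    ``reps`` times.

    ``mode='inter'`` re-draws per-gene batch effects for every run replicate
    (new day, new plate); ``mode='intra'`` shares one set of batch effects
    across the replicates of a sample (same plate).  Each run is a full
    triplicate-well measurement of all 12 genes.
    """
    if mode not in ("inter", "intra"):
        raise ValueError("mode must be 'inter' or 'intra'")
    rng = np.random.default_rng(cfg.seed)
    panel = cfg.panel
    truths = _true_sample_cts(cfg, rng)
    genes = panel.expression_genes
    runs: list[SampleRun] = []
    for s, true_ct in enumerate(truths):
        sample_id = f"S{s + 1:03d}"
        shared_batch = rng.normal(0.0, cfg.batch_effect_sd, size=len(genes))
        for r in range(cfg.reps):
            plate_id = f"P{r + 1:02d}" if mode == "inter" else "P01"
            if mode == "inter":
                batch = rng.normal(0.0, cfg.batch_effect_sd, size=len(genes))
            else:
                batch = shared_batch
            wells = []
            for gi, gene in enumerate(genes):
                noise = rng.normal(0.0, cfg.replicate_noise_sd, size=3)
                for w in range(3):
                    ct = true_ct[gene] + batch[gi] + noise[w]
                    wells.append(
                        WellRecord(
                            sample_id=f"{sample_id}_r{r + 1}",
                            gene=gene,
                            replicate_index=w + 1,
                            ct=float(np.clip(ct, 1.0, CT_MAX)),
                            plate_id=plate_id,
                        )
                    )
            # clean contamination-control wells: silent, above cutoff
            for w in range(3):
                hbb = cfg.clean_hbb_ct + rng.normal(0.0, cfg.replicate_noise_sd)
                wells.append(
                    WellRecord(
                        sample_id=f"{sample_id}_r{r + 1}",
                        gene=panel.contamination_gene,
                        replicate_index=w + 1,
                        ct=float(np.clip(hbb, 1.0, CT_MAX)),
                        plate_id=plate_id,
                    )
                )
            runs.append(
                SampleRun(f"{sample_id}_r{r + 1}", plate_id, wells, batch_id=plate_id)
            )
    return runs


def inject_contamination(runs: Sequence[SampleRun], cfg: SimulationConfig) -> list[SampleRun]:
    """Replace the contamination-control wells of a random subset of runs
    with genomic-DNA-positive signal (>= 2 replicates below the cutoff)."""
    rng = np.random.default_rng(cfg.seed + 1)
    gene = cfg.panel.contamination_gene
    out: list[SampleRun] = []
    for run in runs:
        contaminated = rng.random() < cfg.contamination_rate
        wells = [w for w in run.wells if w.gene != gene]
        for w in range(3):
            if contaminated:
                ct = cfg.contamination_ct + rng.normal(0.0, cfg.replicate_noise_sd)
                ct = min(ct, cfg.panel.contamination_ct_cutoff - 0.05)
            else:
                ct = max(
                    cfg.clean_hbb_ct + rng.normal(0.0, cfg.replicate_noise_sd),
                    cfg.panel.contamination_ct_cutoff + 0.05,
                )
            wells.append(
                WellRecord(
                    sample_id=run.sample_id,
                    gene=gene,
                    replicate_index=w + 1,
                    ct=float(np.clip(ct, 1.0, CT_MAX)),
                    plate_id=run.plate_id,
                )
            )
        out.append(
            SampleRun(run.sample_id, run.plate_id, wells, batch_id=run.batch_id,
                      clinical=run.clinical)
        )
    return out


def simulate_timecourse(
    cfg: SimulationConfig, score_noise_sd: float = 0.2, n_samples: int = 6
) -> dict[tuple[str, float], float]:
    """Simulate an RNA-stability time course at score level: ``n_samples``
    samples with true scores spread over ~2-7, re-measured at each timepoint
    with Gaussian score noise."""
    rng = np.random.default_rng(cfg.seed)
    true_scores = np.linspace(2.0, 7.0, n_samples) + rng.uniform(-0.3, 0.3, n_samples)
    out: dict[tuple[str, float], float] = {}
    for s in range(n_samples):
        for tp in cfg.timepoints:
            out[(f"S{s + 1:03d}", float(tp))] = float(
                true_scores[s] + rng.normal(0.0, score_noise_sd)
            )
    return out
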