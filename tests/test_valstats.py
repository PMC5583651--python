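"""Analytical-validation statistics: concordance, precision, linearity,
efficiency, linear range, HKM-concentration map, stability."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsigval import valstats as vs
from qsigval.plate import DilutionSeries
from qsigval.simulate import SimulationConfig, simulate_dilution_series


def ccc_bruteforce(x, y):
    """Independent direct evaluation of the concordance formula."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    vx = sum((v - mx) ** 2 for v in x) / n
    vy = sum((v - my) ** 2 for v in y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * cov / (vx + vy + (mx - my) ** 2)


class TestLinCCC:
    def test_perfect_concordance(self):
        x = [1.0, 2.0, 5.0, 9.0]
        r = vs.lin_ccc(x, x)
        assert r.ccc == pytest.approx(1.0)

    def test_hand_value(self):
        r = vs.lin_ccc([1, 2, 3], [2, 3, 4])
        assert r.ccc == pytest.approx(4 / 7)
        assert r.mean_diff == pytest.approx(-1.0)
        assert r.n_pairs == 3

    def test_negative_for_anticorrelated(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert vs.lin_ccc(x, -x).ccc < 0

    def test_undefined_when_degenerate(self):
        with pytest.raises(ValueError, match="undefined"):
            vs.lin_ccc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])

    def test_ci_brackets_estimate_and_paired_t_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(7)
        x = rng.normal(4, 1, 30)
        y = x + rng.normal(0.15, 0.2, 30)
        r = vs.lin_ccc(x, y)
        assert r.ccc_ci[0] <= r.ccc <= r.ccc_ci[1]
        t = stats.ttest_rel(x, y)
        assert r.t_pvalue == pytest.approx(t.pvalue)
        assert r.mean_diff_ci[0] <= r.mean_diff <= r.mean_diff_ci[1]

    @given(
        st.integers(3, 10).flatmap(
            lambda n: st.tuples(
                st.lists(st.floats(-50, 50), min_size=n, max_size=n),
                st.lists(st.floats(-50, 50), min_size=n, max_size=n),
            )
        )
    )
    @settings(max_examples=1000, deadline=None, derandomize=True)
    def test_oracle_equivalence_and_bounded_by_pearson(self, pair):
        x, y = pair
        denom_ok = (
            np.var(x) + np.var(y) + (np.mean(x) - np.mean(y)) ** 2 > 1e-9
        )
        if not denom_ok:
            return
        r = vs.lin_ccc(x, y)
        assert r.ccc == pytest.approx(ccc_bruteforce(x, y), abs=1e-9)
        if np.std(x) > 1e-6 and np.std(y) > 1e-6:
            pearson = np.corrcoef(x, y)[0, 1]
            assert abs(r.ccc) <= abs(pearson) + 1e-9


class TestPooledSD:
    def test_constant_groups_give_zero(self):
        r = vs.pooled_sd([[3.0, 3.0, 3.0], [5.0, 5.0]])
        assert r.pooled_sd == 0.0

    def test_hand_pooling(self):
        # variances 1 and 4 -> sqrt(2.5)
        r = vs.pooled_sd([[1, 2, 3], [4, 6, 8]])
        assert r.pooled_sd == pytest.approx(math.sqrt(2.5))

    def test_single_group_reduces_to_sample_sd(self):
        values = [2.0, 2.5, 3.1, 1.8]
        r = vs.pooled_sd([values])
        assert r.pooled_sd == pytest.approx(np.std(values, ddof=1))

    def test_interbatch_ci_reconstruction(self):
        """SD 0.21 over 12 groups gives the published-style (0.15, 0.35) band."""
        lo, hi = vs.sd_confidence_interval(0.21, df=12)
        assert round(lo, 2) == 0.15
        assert round(hi, 2) == 0.35

    def test_small_group_rejected_by_name(self):
        with pytest.raises(ValueError, match="lonely"):
            vs.pooled_sd({"ok": [1.0, 2.0], "lonely": [1.0]})

    def test_df_conventions_differ(self):
        groups = [[1.0, 2.0, 3.0]] * 12
        by_groups = vs.pooled_sd(groups, df_convention="groups")
        by_pooled = vs.pooled_sd(groups, df_convention="pooled")
        assert by_groups.pooled_sd == by_pooled.pooled_sd
        assert by_pooled.sd_ci[1] < by_groups.sd_ci[1]  # more df, tighter band


def make_series(gene_lines, reps=1, noise=None, rng=None):
    """Build a DilutionSeries from {gene: (intercept, slope)} over a 12-point
    two-fold ladder; optional Gaussian replicate noise."""
    ladder = [100.0 / 2**k for k in range(12)]
    rows = []
    for gene, (intercept, slope) in gene_lines.items():
        for conc in ladder:
            for rep in range(reps):
                ct = intercept + slope * math.log2(conc)
                if noise:
                    ct += rng.normal(0, noise)
                rows.append(
                    {"concentration": conc, "gene": gene, "replicate": rep + 1, "ct": ct}
                )
    return DilutionSeries(pd.DataFrame(rows))


class TestDilutionFit:
    def test_exact_line_recovered(self):
        series = make_series({"AZGP1": (30.0, -1.0)})
        fit = vs.fit_gene_dilution(series, "AZGP1")
        assert fit.slope == pytest.approx(-1.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.max_abs_residual == pytest.approx(0.0, abs=1e-10)
        assert fit.efficiency_pct == pytest.approx(100.0)

    def test_saturated_top_point_dominates_residuals(self):
        series = make_series({"AZGP1": (30.0, -1.0)})
        data = series.data.copy()
        top = data["concentration"].max()
        data.loc[data["concentration"] == top, "ct"] += 2.0
        series = DilutionSeries(data)
        fit = vs.fit_gene_dilution(series, "AZGP1")
        log2c, ct = series.mean_ct("AZGP1")
        resid = ct - (fit.intercept + fit.slope * log2c)
        assert fit.max_abs_residual == pytest.approx(abs(resid[0]))
        assert np.argmax(np.abs(resid)) == 0  # the doctored top point

    def test_too_few_concentrations_rejected(self):
        rows = [
            {"concentration": c, "gene": "AZGP1", "replicate": 1, "ct": 25.0 - math.log2(c)}
            for c in (100.0, 50.0)
        ]
        with pytest.raises(ValueError, match="3 distinct"):
            vs.fit_gene_dilution(DilutionSeries(pd.DataFrame(rows)), "AZGP1")

    def test_noisy_series_stays_linear(self, panel):
        """At the assay's replicate noise scale (0.3 Ct) the 12-point ladder
        still fits with R^2 > 0.98 for every gene."""
        cfg = SimulationConfig(panel=panel, seed=11)
        series = simulate_dilution_series(cfg)
        for gene in panel.expression_genes:
            assert vs.fit_gene_dilution(series, gene).r2 > 0.98


class TestEfficiency:
    @pytest.mark.parametrize(
        "slope, expected",
        [(-1.0, 100.0), (-1.02, 97.3), (-0.95, 107.4)],
    )
    def test_formula_values(self, slope, expected):
        assert vs.amplification_efficiency(slope) == pytest.approx(expected, abs=0.05)

    def test_non_amplifying_rejected(self):
        with pytest.raises(ValueError, match="non-amplifying"):
            vs.amplification_efficiency(0.5)

    @given(st.floats(-3.0, -0.3))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_strictly_decreasing_in_slope_magnitude(self, slope):
        eff = vs.amplification_efficiency(slope)
        steeper = vs.amplification_efficiency(slope - 0.01)
        assert steeper < eff
        if slope == -1.0:
            assert eff == pytest.approx(100.0)


class TestLinearRange:
    def _lines(self, panel):
        return {g: (25.0 + i * 0.3, -1.0) for i, g in enumerate(panel.expression_genes)}

    def test_full_ladder_when_perfectly_linear(self, panel):
        series = make_series(self._lines(panel))
        lo, hi = vs.determine_linear_range(series, panel)
        assert hi == pytest.approx(100.0)
        assert lo == pytest.approx(100.0 / 2**11)

    def test_curved_top_points_excluded(self, panel):
        series = make_series(self._lines(panel))
        data = series.data.copy()
        concs = np.sort(data["concentration"].unique())[::-1]
        # bend one gene upward at the two highest concentrations
        for c, bump in zip(concs[:2], (6.0, 3.0)):
            mask = (data["gene"] == "MGP") & (data["concentration"] == c)
            data.loc[mask, "ct"] += bump
        lo, hi = vs.determine_linear_range(DilutionSeries(data), panel)
        assert hi == pytest.approx(concs[2])
        assert lo == pytest.approx(concs[-1])

    def test_no_linear_subrange_is_an_error(self, panel):
        rng = np.random.default_rng(0)
        series = make_series(
            {g: (25.0, 0.0) for g in panel.expression_genes},
            noise=3.0,
            rng=rng,
        )
        with pytest.raises(ValueError, match="no contiguous"):
            vs.determine_linear_range(series, panel)


class TestScoreOverDilution:
    def test_matched_efficiencies_cancel_exactly(self, panel):
        """With every gene at 100% efficiency the score is identical at every
        dilution point, so its SD is exactly zero."""
        eff = {g: 100.0 for g in panel.expression_genes}
        cfg = SimulationConfig(panel=panel, seed=0, replicate_noise_sd=0.0,
                               per_gene_efficiency=eff)
        series = simulate_dilution_series(cfg)
        mean, sd, _ = vs.score_sd_over_dilution(series, panel)
        assert sd == pytest.approx(0.0, abs=1e-10)

    def test_assay_like_noise_gives_sub_half_unit_sd(self, panel):
        cfg = SimulationConfig(panel=panel, seed=19)
        series = simulate_dilution_series(cfg)
        mean, sd, ci = vs.score_sd_over_dilution(series, panel)
        assert 0.0 < sd < 0.6  # same order as the published 0.34
        assert ci[0] <= sd <= ci[1]

    def test_single_point_is_degenerate(self, panel):
        rows = [
            {"concentration": 10.0, "gene": g, "replicate": 1, "ct": 25.0}
            for g in panel.expression_genes
        ]
        with pytest.raises(ValueError, match=">= 2"):
            vs.score_sd_over_dilution(DilutionSeries(pd.DataFrame(rows)), panel)


class TestHkmConcentrationMap:
    def test_input_mass_arithmetic(self):
        assert vs.input_mass(18.5, 45.0) == pytest.approx(832.5)
        assert vs.input_mass(0.049, 45.0) == pytest.approx(2.2, abs=0.01)

    def test_map_inverts_its_own_fit(self, panel):
        cfg = SimulationConfig(panel=panel, seed=2, replicate_noise_sd=0.0)
        series = simulate_dilution_series(cfg)
        m = vs.hkm_concentration_map(series, panel)
        for conc in (100.0, 1.5625, 0.048828125):
            assert m.concentration_at(m.hkm_at(conc)) == pytest.approx(conc, rel=1e-9)

    def test_default_calibration_spans_validated_window(self, panel):
        """The stock ladder maps to HKM ~17-28, and the validated HKM window
        (19-27) maps back inside the tested concentrations."""
        cfg = SimulationConfig(panel=panel, seed=2, replicate_noise_sd=0.0)
        m = vs.hkm_concentration_map(simulate_dilution_series(cfg), panel)
        assert m.hkm_at(100.0) == pytest.approx(17.0, abs=0.5)
        assert m.hkm_at(100.0 / 2**11) == pytest.approx(28.0, abs=0.5)
        assert 0.049 < m.concentration_at(27.0) < m.concentration_at(19.0) < 100.0


class TestStability:
    def test_constant_scores(self):
        tc = {("S1", t): 4.0 for t in range(6)}
        r = vs.stability_analysis(tc)
        assert r.per_sample_sd["S1"] == 0.0
        assert all(d == 0.0 for d in r.delta_scores.values())

    def test_pair_sd_hand_value(self):
        tc = {("S1", 0): 2.0, ("S1", 1): 2.2}
        r = vs.stability_analysis(tc)
        assert r.per_sample_sd["S1"] == pytest.approx(0.2 / math.sqrt(2))

    def test_deltas_sum_to_zero_per_sample(self):
        rng = np.random.default_rng(5)
        tc = {
            (f"S{s}", t): float(4 + rng.normal(0, 0.2))
            for s in range(6)
            for t in range(7)
        }
        r = vs.stability_analysis(tc)
        for s in range(6):
            total = sum(d for (sample, _), d in r.delta_scores.items() if sample == f"S{s}")
            assert total == pytest.approx(0.0, abs=1e-9)
        assert r.max_sd == max(r.per_sample_sd.values())

    def test_single_timepoint_sample_excluded(self):
        tc = {("S1", 0): 2.0, ("S1", 1): 2.1, ("S2", 0): 5.0}
        r = vs.stability_analysis(tc)
        assert "S2" not in r.per_sample_sd
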