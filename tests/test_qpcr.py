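"""Standard curves, geNORM normalization, contamination QC, stage stats."""

import numpy as np
import pandas as pd
import pytest

from follistage.qpcr import (
    QpcrError,
    QpcrPanel,
    StandardCurve,
    contamination_qc,
    fit_standard_curve,
    genorm_normalize,
    linear_trend_test,
    log_transform,
    newman_keuls,
    quantify,
    stage_stats,
)
from follistage.synthetic import simulate_qpcr


def dilution_frame(slope, intercept, quantities=(1e-4, 1e-5, 1e-6, 1e-7, 1e-8), noise=None, seed=0):
    q = np.asarray(quantities)
    cq = intercept + slope * np.log10(q)
    if noise:
        cq = cq + np.random.default_rng(seed).normal(0, noise, len(q))
    return pd.DataFrame({"gene": "X", "Cq": cq, "input_ng": q})


def make_panel(values, stages, refs=(1.0, 1.0)):
    """Panel with one target gene 'T' and constant-quantity references."""
    samples = list(values)
    q = pd.DataFrame(
        {
            s: [values[s], refs[0], refs[1]]
            for s in samples
        },
        index=["T", "EIF2B2", "SF3A1"],
    )
    return QpcrPanel(quantities=q, stages=stages)


class TestStandardCurve:
    def test_perfect_doubling_efficiency(self):
        curve = fit_standard_curve(dilution_frame(-3.3219, 20.0))
        assert curve.efficiency == pytest.approx(1.0, abs=1e-4)
        assert curve.n_points == 5
        assert curve.r2 == pytest.approx(1.0)

    def test_slope_recovery_under_noise(self):
        curve = fit_standard_curve(dilution_frame(-3.5, 18.0, noise=0.1, seed=3))
        assert curve.slope == pytest.approx(-3.5, abs=0.1)

    def test_positive_slope_rejected(self):
        with pytest.raises(QpcrError, match="miswired"):
            fit_standard_curve(dilution_frame(+3.3, 20.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(QpcrError, match=">= 3"):
            fit_standard_curve(dilution_frame(-3.3, 20.0, quantities=(1e-4, 1e-5)))


class TestQuantify:
    def test_closed_forms(self):
        curve = StandardCurve(gene="X", slope=-3.3219, intercept=20.0, r2=1.0, n_points=5)
        assert quantify(20.0, curve) == pytest.approx(1.0)
        assert quantify(20.0 + (-3.3219) * (-4), curve) == pytest.approx(1e-4, rel=1e-9)

    def test_absent_cq_propagates(self):
        curve = StandardCurve(gene="X", slope=-3.3219, intercept=20.0, r2=1.0, n_points=5)
        out = quantify([20.0, np.nan], curve)
        assert np.isnan(out[1]) and out[0] == pytest.approx(1.0)

    def test_roundtrip_through_generator(self):
        stages = {"G1": "growing", "P1": "plateau", "A1": "atretic"}
        cq = simulate_qpcr(stages, genes=["VNN1"], noise_sd=0.0, bio_cv=0.0, seed=0)
        panel = QpcrPanel.from_cq_table(cq)
        # stage-independent gene at its configured base quantity
        assert panel.quantities.loc["VNN1"].to_numpy() == pytest.approx(2e-6, rel=1e-6)


class TestGenorm:
    def test_geometric_mean_factor(self):
        panel = make_panel({"s1": 10.0}, {"s1": "growing"}, refs=(4.0, 9.0))
        out = genorm_normalize(panel)
        assert out.norm_factors["s1"] == pytest.approx(6.0)
        assert out.normalized.loc["T", "s1"] == pytest.approx(10.0 / 6.0)

    def test_constant_references_preserve_ratios(self):
        panel = make_panel({"s1": 10.0, "s2": 20.0}, {"s1": "growing", "s2": "plateau"}, refs=(2.0, 8.0))
        out = genorm_normalize(panel)
        t = out.normalized.loc["T"]
        assert t["s2"] / t["s1"] == pytest.approx(2.0)

    def test_global_efficiency_artifact_removed(self):
        q = pd.DataFrame(
            {"s1": [10.0, 2.0, 8.0], "s2": [10.0, 2.0, 8.0]},
            index=["T", "EIF2B2", "SF3A1"],
        )
        q["s2"] *= 10.0  # whole-sample multiplicative artifact
        panel = QpcrPanel(quantities=q, stages={"s1": "growing", "s2": "plateau"})
        out = genorm_normalize(panel)
        assert out.normalized.loc["T", "s1"] == pytest.approx(out.normalized.loc["T", "s2"])

    def test_missing_reference_names_sample(self):
        q = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [1.0, np.nan, 3.0]}, index=["T", "EIF2B2", "SF3A1"])
        panel = QpcrPanel(quantities=q, stages={})
        with pytest.raises(QpcrError, match="s2"):
            genorm_normalize(panel)


class TestContaminationQC:
    def stages(self, n=6):
        out = {}
        for g in ("growing", "plateau", "atretic"):
            for i in range(n):
                out[f"{g[0].upper()}{i + 1}"] = g
        return out

    def test_homogeneous_panel_not_flagged(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            stages = self.stages()
            q = pd.DataFrame(
                {s: [float(rng.lognormal(0, 0.3))] for s in stages}, index=["CYP17A1"]
            )
            panel = QpcrPanel(quantities=q, stages=stages)
            flagged, report = contamination_qc(panel, "CYP17A1")
            assert flagged == []

    def test_extreme_outlier_flagged(self):
        rng = np.random.default_rng(1)
        stages = self.stages()
        q = pd.DataFrame({s: [float(rng.lognormal(0, 0.2))] for s in stages}, index=["CYP17A1"])
        q["A2"] *= 100.0
        panel = QpcrPanel(quantities=q, stages=stages)
        flagged, report = contamination_qc(panel, "CYP17A1")
        assert flagged == ["A2"]
        assert report["bartlett_p"] < 0.05
        assert report["leave_one_out"]["A2"] >= 0.05

    def test_constant_groups_handled(self):
        stages = self.stages(3)
        q = pd.DataFrame({s: [1.0] for s in stages}, index=["CYP17A1"])
        panel = QpcrPanel(quantities=q, stages=stages)
        flagged, report = contamination_qc(panel, "CYP17A1")
        assert flagged == [] and report["bartlett_p"] == 1.0

    def test_small_group_rejected(self):
        q = pd.DataFrame({"a1": [1.0], "b1": [2.0], "b2": [3.0]}, index=["CYP17A1"])
        panel = QpcrPanel(quantities=q, stages={"a1": "g", "b1": "p", "b2": "p"})
        with pytest.raises(QpcrError, match="size < 2"):
            contamination_qc(panel, "CYP17A1")


class TestPosthocMachinery:
    def test_transform_closed_form(self):
        assert log_transform(1e-12) == pytest.approx(0.0)
        assert log_transform(1e-11) == pytest.approx(1.0)

    def test_newman_keuls_separated_means(self):
        rng = np.random.default_rng(2)
        groups = {
            "growing": rng.normal(1, 0.05, 7),
            "plateau": rng.normal(2, 0.05, 7),
            "atretic": rng.normal(3, 0.05, 7),
        }
        sig, letters = newman_keuls(groups)
        assert len({letters[g] for g in groups}) == 3
        # agrees with all-pairs Welch separation on this construction
        from scipy import stats as sps

        for a, b in (("growing", "plateau"), ("plateau", "atretic"), ("growing", "atretic")):
            assert sps.ttest_ind(groups[a], groups[b], equal_var=False).pvalue < 0.05
            assert frozenset((a, b)) in sig

    def test_newman_keuls_respects_global_nonsignificance(self):
        # no pair may be declared different when ANOVA and every pairwise
        # t test are non-significant on the same data
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(100):
            groups = {c: rng.normal(0, 1, 7) for c in "abc"}
            anova_p = sps.f_oneway(*groups.values()).pvalue
            pairs_ns = all(
                sps.ttest_ind(groups[x], groups[y]).pvalue >= 0.05
                for x, y in (("a", "b"), ("b", "c"), ("a", "c"))
            )
            if anova_p >= 0.05 and pairs_ns:
                checked += 1
                sig, _ = newman_keuls(groups)
                assert sig == set()
        assert checked > 30  # the null regime was actually exercised

    def test_null_trend_rarely_significant(self):
        rng = np.random.default_rng(4)
        hits = sum(
            linear_trend_test([rng.normal(1, 0.3, 7) for _ in range(3)])[1] < 0.05
            for _ in range(50)
        )
        assert hits / 50 <= 0.10

    def test_monotone_trend_detected(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(m, 0.1, 7) for m in (1.0, 2.0, 3.0)]
        slope, p = linear_trend_test(groups)
        assert slope > 0 and p < 1e-6


class TestStageStats:
    def panel_from_values(self, gene_values, n=7, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        stages, cols = {}, {}
        for g in ("growing", "plateau", "atretic"):
            for i in range(n):
                s = f"{g[0].upper()}{i + 1}"
                stages[s] = g
                cols[s] = [
                    gene_values[gene][g] * float(rng.lognormal(0, noise)) for gene in gene_values
                ]
        q = pd.DataFrame(cols, index=list(gene_values))
        panel = QpcrPanel(quantities=q, stages=stages)
        panel.normalized = q  # already on a normalized scale for the test
        return panel

    def test_monotone_gene_full_battery(self):
        panel = self.panel_from_values({"VNN1": {"growing": 1.0, "plateau": 2.0, "atretic": 4.0}})
        report = stage_stats(panel)
        st = report.genes["VNN1"]
        assert st.anova_p < 0.001
        assert st.trend_p < 0.001
        assert len(set(st.letters.values())) == 3
        assert all(p < 0.05 for p in st.t_one_tailed.values())

    def test_one_tailed_p_is_half_two_tailed_in_matching_direction(self):
        from scipy import stats as sps

        panel = self.panel_from_values({"G": {"growing": 1.0, "plateau": 1.5, "atretic": 1.5}})
        direction = {"G": {"G_vs_P": +1}}
        report = stage_stats(panel, expected_direction=direction)
        p_one = report.genes["G"].t_one_tailed[("growing", "plateau")]
        g = panel.normalized.loc["G"]
        gs = [s for s, lab in panel.stages.items() if lab == "growing"]
        ps = [s for s, lab in panel.stages.items() if lab == "plateau"]
        p_two = sps.ttest_ind(g[gs], g[ps]).pvalue
        assert p_one == pytest.approx(p_two / 2)

    def test_transform_applied_iff_bartlett_rejects(self):
        rng = np.random.default_rng(6)
        # heteroscedastic gene: spread grows with the mean
        cols, stages = {}, {}
        for g, (m, sd) in (("growing", (1.0, 0.02)), ("plateau", (10.0, 3.0)), ("atretic", (100.0, 40.0))):
            for i in range(7):
                s = f"{g[0].upper()}{i + 1}"
                stages[s] = g
                cols[s] = [float(rng.normal(m, sd))]
        panel = QpcrPanel(quantities=pd.DataFrame(cols, index=["H"]), stages=stages)
        panel.normalized = panel.quantities
        report = stage_stats(panel)
        st = report.genes["H"]
        assert st.bartlett_p < 0.05 and st.transform_applied
        assert st.bartlett_p_after is not None
        homo = self.panel_from_values({"K": {"growing": 1.0, "plateau": 1.0, "atretic": 1.0}}, noise=0.1)
        st2 = stage_stats(homo).genes["K"]
        assert (st2.bartlett_p < 0.05) == st2.transform_applied

    def test_undetected_values_reported_not_imputed(self):
        panel = self.panel_from_values({"RELN": {"growing": 1.0, "plateau": 1.0, "atretic": 1.0}})
        panel.normalized.loc["RELN", ["G1", "G2", "G3", "G4"]] = np.nan
        report = stage_stats(panel)
        st = report.genes["RELN"]
        assert st.detected_per_stage["growing"] == 3
        assert st.n_per_stage["growing"] == 7
        assert st.testable

    def test_zero_variance_gene_untestable_not_exception(self):
        panel = self.panel_from_values({"Z": {"growing": 1.0, "plateau": 1.0, "atretic": 1.0}}, noise=0.0)
        st = stage_stats(panel).genes["Z"]
        assert not st.testable and "variance" in st.note
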