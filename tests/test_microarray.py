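"""Two-color normalization chain, loop model and DEG logic."""

import numpy as np
import pandas as pd
import pytest

from follistage.microarray import (
    ContrastResult,
    DEGCriteria,
    DesignError,
    TwoColorArraySet,
    background_correct,
    bga_input_from_arrays,
    channel_stage_table,
    fit_loop_model,
    moderated_t,
    normalize_arrays,
    normalize_between_quantile,
    normalize_within_loess,
    partition_contrasts,
    select_degs,
)
from follistage.synthetic import simulate_loop_arrays


def tiny_set(fg_values, bg=20.0):
    rows = []
    for aid, vals in fg_values.items():
        for dye in ("red", "green"):
            for i, v in enumerate(vals[dye]):
                rows.append((aid, "G_vs_P", dye, f"s_{aid}_{dye}", f"P{i:05d}", v, bg))
    return TwoColorArraySet.from_long(
        pd.DataFrame(rows, columns=["array_id", "contrast", "dye", "sample_id", "probe_id", "fg", "bg"])
    )


class TestBackgroundCorrect:
    def test_simple_subtraction_and_floor(self):
        arr = tiny_set({"a1": {"red": [100.0, 10.0], "green": [60.0, 70.0]}}, bg=20.0)
        out = background_correct(arr, floor=0.5)
        sig = out.data.set_index(["dye", "probe_id"])["signal"]
        assert sig[("red", "P00000")] == 80.0
        assert sig[("red", "P00001")] == 0.5  # floored: 10 - 20 < 0.5
        assert sig[("green", "P00000")] == 40.0

    def test_zero_background_is_identity(self):
        arr = tiny_set({"a1": {"red": [100.0, 10.0], "green": [60.0, 70.0]}}, bg=0.0)
        out = background_correct(arr)
        assert (out.data["signal"] == out.data["fg"]).all()

    def test_negative_intensity_rejected(self):
        arr = tiny_set({"a1": {"red": [-5.0, 10.0], "green": [60.0, 70.0]}})
        with pytest.raises(ValueError, match="negative"):
            background_correct(arr)


class TestLoess:
    def test_removes_intensity_dependent_dye_curve(self):
        rng = np.random.default_rng(0)
        a_true = rng.normal(9, 1.5, 2000)
        curve = 0.4 * np.sin((a_true - 6) / 2.5) + 0.3
        g = a_true - curve / 2
        r = a_true + curve / 2 + rng.normal(0, 0.15, 2000)
        m_norm, a = normalize_within_loess(r, g)
        deciles = pd.qcut(a, 10)
        decile_means = pd.Series(m_norm).groupby(deciles, observed=True).mean()
        assert decile_means.abs().max() < 0.02

    def test_nearly_identity_on_centered_null(self):
        rng = np.random.default_rng(1)
        m0 = rng.normal(0, 0.2, 2000)
        a0 = rng.normal(9, 1.5, 2000)
        m1, _ = normalize_within_loess(a0 + m0 / 2, a0 - m0 / 2)
        assert np.abs(m1 - m0).max() < 0.05

    def test_absorbs_constant_offset(self):
        rng = np.random.default_rng(2)
        m0 = rng.normal(0, 0.2, 1000) + 0.5
        a0 = rng.normal(9, 1.5, 1000)
        m1, _ = normalize_within_loess(a0 + m0 / 2, a0 - m0 / 2)
        assert abs(np.mean(m1)) < 0.02

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError, match="50"):
            normalize_within_loess(np.ones(20), np.ones(20))


class TestQuantile:
    def test_location_shift_removed(self):
        rng = np.random.default_rng(3)
        x = rng.normal(9, 1, 500)
        mat = pd.DataFrame({"a": x, "b": x + 1.0})
        out = normalize_between_quantile(mat)
        assert np.allclose(np.sort(out["a"]), np.sort(out["b"]))

    def test_single_array_rejected(self):
        with pytest.raises(ValueError):
            normalize_between_quantile(pd.DataFrame({"a": [1.0, 2.0]}))

    def test_sorted_vectors_identical_and_idempotent(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.normal(9, 2, (300, 5)), columns=list("abcde"))
        out = normalize_between_quantile(mat)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        assert np.abs(sorted_cols - sorted_cols[:, [0]]).max() < 1e-12
        again = normalize_between_quantile(out)
        assert np.abs(again.to_numpy() - out.to_numpy()).max() < 1e-9

    def test_ranks_preserved_within_array(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.normal(9, 2, (200, 3)), columns=list("abc"))
        out = normalize_between_quantile(mat)
        for c in mat.columns:
            assert (np.argsort(mat[c].to_numpy()) == np.argsort(out[c].to_numpy())).all()


class TestLoopModel:
    def test_effect_recovery(self, stage_assignment):
        # keep the DE fraction realistic (~5%) so loess normalization does
        # not absorb the shared signal
        de = {"P_vs_A": {f"P{i + 1:05d}": 1.0 for i in range(25)}}
        arr = simulate_loop_arrays(stage_assignment, n_probes=500, de_config=de, dye_bias=0.5, seed=8)
        M, A, _ = normalize_arrays(arr)
        res = fit_loop_model(M, A, channel_stage_table(arr, stage_assignment))
        tab = res["P_vs_A"].table.set_index("probe_id")
        est = tab.loc[[f"P{i + 1:05d}" for i in range(25)], "log2fc"]
        assert est.mean() == pytest.approx(1.0, abs=0.1)

    def test_dye_coefficient_recovers_injected_bias(self, null_loop_arrays, stage_assignment):
        # fit on raw (pre-loess) M so the dye term carries the bias itself
        corr = background_correct(null_loop_arrays)
        log2 = np.log2(
            corr.data.pivot_table(index="probe_id", columns=["array_id", "dye"], values="signal")
        )
        aids = null_loop_arrays.array_ids
        M = pd.DataFrame({a: log2[(a, "red")] - log2[(a, "green")] for a in aids})
        A = pd.DataFrame({a: (log2[(a, "red")] + log2[(a, "green")]) / 2 for a in aids})
        res = fit_loop_model(M, A, channel_stage_table(null_loop_arrays, stage_assignment))
        assert res["dye_coefficient"] == pytest.approx(0.5, abs=0.05)
        for c in ("G_vs_P", "P_vs_A", "G_vs_A"):
            assert abs(res[c].table["log2fc"].mean()) < 0.05

    def test_dye_swap_inversion_flips_every_sign(self, null_loop_arrays, stage_assignment):
        M, A, _ = normalize_arrays(null_loop_arrays)
        stages = channel_stage_table(null_loop_arrays, stage_assignment)
        res = fit_loop_model(M, A, stages)
        res_sw = fit_loop_model(-M, A, stages)
        for c in ("G_vs_P", "P_vs_A", "G_vs_A"):
            assert np.allclose(res_sw[c].table["log2fc"], -res[c].table["log2fc"].to_numpy())

    def test_rank_deficient_design_names_missing_cell(self, stage_assignment):
        arr = simulate_loop_arrays(stage_assignment, n_probes=60, seed=1)
        keep = arr.data["contrast"] == "G_vs_P"
        partial = TwoColorArraySet.from_long(arr.data[keep])
        M, A, _ = normalize_arrays(partial)
        with pytest.raises(DesignError, match="atretic"):
            fit_loop_model(M, A, channel_stage_table(partial, stage_assignment))

    def test_moderated_t_limits(self):
        rng = np.random.default_rng(6)
        eff = rng.normal(0, 1, 50)
        s2 = rng.chisquare(6, 50) / 6
        t0, df0 = moderated_t(eff, s2, 0.25, 6, d0=1e-9, s0_sq=1.0)
        plain_t = eff / np.sqrt(s2 * 0.25)
        assert np.allclose(t0, plain_t, rtol=1e-6)
        tz, dfz = moderated_t(eff, s2, 0.25, 6, d0=np.inf, s0_sq=1.0)
        assert np.allclose(tz, eff / np.sqrt(0.25))
        assert dfz == np.inf

    def test_power_monotone_in_effect(self, stage_assignment):
        hits = []
        for effect in (0.5, 1.0, 1.5):
            de = {"G_vs_A": {f"P{i + 1:05d}": effect for i in range(50)}}
            arr = simulate_loop_arrays(stage_assignment, n_probes=300, de_config=de, seed=13)
            M, A, _ = normalize_arrays(arr)
            res = fit_loop_model(M, A, channel_stage_table(arr, stage_assignment))
            tab = res["G_vs_A"].table.set_index("probe_id")
            hits.append((tab.loc[[f"P{i + 1:05d}" for i in range(50)], "p_value"] < 0.05).mean())
        assert hits[0] <= hits[1] <= hits[2]


def contrast_result(rows):
    tab = pd.DataFrame(rows, columns=["probe_id", "log2fc", "A", "t", "p_value"])
    tab["fdr"] = tab["p_value"]
    return ContrastResult(contrast="G_vs_P", table=tab, d0=4.0, s0_sq=0.05)


class TestDegSelection:
    def test_cutoffs_are_strict_for_fc_and_p_inclusive_for_intensity(self):
        res = contrast_result(
            [
                ("kept_up", np.log2(1.6), 8.0, 3.0, 0.01),
                ("fc_exactly_1.5", np.log2(1.5), 8.0, 3.0, 0.01),
                ("kept_down", np.log2(1 / 1.7), 9.0, -3.0, 0.001),
                ("p_exactly_0.05", np.log2(2.0), 8.0, 3.0, 0.05),
                ("a_exactly_7", np.log2(2.0), 7.0, 3.0, 0.01),
                ("dim", np.log2(2.0), 6.9, 3.0, 0.01),
            ]
        )
        out = select_degs(res, DEGCriteria())
        assert set(out["probe_id"]) == {"kept_up", "kept_down", "a_exactly_7"}
        directions = dict(zip(out["probe_id"], out["direction"]))
        assert directions["kept_up"] == "up"
        assert directions["kept_down"] == "down"


class TestPartition:
    def deg(self, entries):
        return pd.DataFrame(
            {"probe_id": [g for g, _ in entries], "direction": [d for _, d in entries]}
        )

    def test_set_arithmetic_example(self):
        gp = self.deg([("a", "up"), ("b", "up"), ("c", "up")])
        pa = self.deg([("b", "up"), ("c", "up"), ("d", "down")])
        part = partition_contrasts(gp, pa)
        assert part.continuous == {"b", "c"}
        assert part.specific_g_vs_p == {"a"}
        assert part.specific_p_vs_a == {"d"}
        assert part.reversal == set()
        s = part.summary()
        assert s["specific_G_vs_P"] + s["shared"] == s["total_G_vs_P"]
        assert s["specific_P_vs_A"] + s["shared"] == s["total_P_vs_A"]

    def test_disjoint_tables_share_nothing(self):
        part = partition_contrasts(self.deg([("a", "up")]), self.deg([("b", "down")]))
        assert part.shared == set()

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(30)]
        for _ in range(20):
            gp_genes = rng.choice(genes, rng.integers(1, 15), replace=False)
            pa_genes = rng.choice(genes, rng.integers(1, 15), replace=False)
            gp = self.deg([(g, rng.choice(["up", "down"])) for g in gp_genes])
            pa = self.deg([(g, rng.choice(["up", "down"])) for g in pa_genes])
            part = partition_contrasts(gp, pa)
            dgp = dict(zip(gp["probe_id"], gp["direction"]))
            dpa = dict(zip(pa["probe_id"], pa["direction"]))
            for g in genes:  # exhaustive oracle over every gene
                in_gp, in_pa = g in dgp, g in dpa
                if in_gp and in_pa and dgp[g] == dpa[g]:
                    assert g in part.continuous
                elif in_gp and in_pa:
                    assert g in part.reversal
                elif in_gp:
                    assert g in part.specific_g_vs_p
                elif in_pa:
                    assert g in part.specific_p_vs_a
                else:
                    assert g not in (part.shared | part.specific_g_vs_p | part.specific_p_vs_a)

    def test_duplicate_ids_rejected(self):
        dup = self.deg([("a", "up"), ("a", "down")])
        with pytest.raises(ValueError, match="duplicate"):
            partition_contrasts(dup, self.deg([("b", "up")]))


class TestBgaInput:
    def test_eight_data_sets_per_stage(self, null_loop_arrays, stage_assignment):
        mat, labels = bga_input_from_arrays(null_loop_arrays, stage_assignment)
        assert mat.shape[1] == len(labels) == 24
        for stage in ("growing", "plateau", "atretic"):
            assert labels.count(stage) == 8


class TestLimmaCrossCheck:
    def test_loop_model_matches_independent_limma_fit(self, tmp_path, stage_assignment):
        """The per-probe loop fit and moderated statistics agree with an
        independent fit of the same design in R limma."""
        import subprocess

        de = {"P_vs_A": {f"P{i + 1:05d}": 1.0 for i in range(20)}}
        arr = simulate_loop_arrays(stage_assignment, n_probes=300, de_config=de, dye_bias=0.4, seed=21)
        M, A, _ = normalize_arrays(arr)
        cs = channel_stage_table(arr, stage_assignment)
        res = fit_loop_model(M, A, cs)

        m_path, st_path, out_path = (tmp_path / n for n in ("M.tsv", "st.tsv", "out.tsv"))
        M.to_csv(m_path, sep="\t")
        cs.to_csv(st_path, sep="\t", index=False)
        script = f"""
        suppressMessages(library(limma))
        M <- as.matrix(read.delim("{m_path}", row.names=1, check.names=FALSE))
        st <- read.delim("{st_path}")
        design <- t(sapply(colnames(M), function(a) {{
          red <- st$stage[st$array_id==a & st$dye=="red"]
          green <- st$stage[st$array_id==a & st$dye=="green"]
          cf <- c(plateau=0, atretic=0, dye=1)
          if (red!="growing") cf[red] <- cf[red]+1
          if (green!="growing") cf[green] <- cf[green]-1
          cf
        }}))
        fit <- lmFit(M, design)
        cm <- makeContrasts(PvsA = atretic - plateau, levels=colnames(design))
        fit2 <- eBayes(contrasts.fit(fit, cm))
        out <- data.frame(probe_id=rownames(M), log2fc=fit2$coefficients[,1], t=fit2$t[,1])
        write.table(out, "{out_path}", sep="\\t", row.names=FALSE, quote=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        r = pd.read_csv(out_path, sep="\t").set_index("probe_id")
        py = res["P_vs_A"].table.set_index("probe_id")
        assert np.abs(py["log2fc"] - r["log2fc"]).max() < 1e-10
        assert np.abs(py["t"] - r["t"]).max() < 0.05
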