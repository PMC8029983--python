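import numpy as np
import pandas as pd
import pytest

from panomix import (
    CohortConfig,
    ConfigError,
    simulate_clinical_survival,
    simulate_expression_pair,
    simulate_genomic_alterations,
    simulate_methylation,
    simulate_mirna_targets,
)


class TestDeterminism:
    def test_expression_identical_for_same_seed(self):
        a = simulate_expression_pair(CohortConfig(seed=7, n_genes=50))
        b = simulate_expression_pair(CohortConfig(seed=7, n_genes=50))
        pd.testing.assert_frame_equal(a.array.values, b.array.values)
        pd.testing.assert_frame_equal(a.counts.values, b.counts.values)

    def test_different_seed_differs(self):
        a = simulate_expression_pair(CohortConfig(seed=7, n_genes=50))
        b = simulate_expression_pair(CohortConfig(seed=8, n_genes=50))
        assert not a.counts.values.equals(b.counts.values)

    def test_mirna_lists_identical_for_same_seed(self):
        cfg = CohortConfig(seed=5, n_genes=40, n_tumor=8, n_normal=8)
        a = simulate_mirna_targets(cfg)
        b = simulate_mirna_targets(cfg)
        assert a.lists == b.lists


class TestExpressionTruth:
    def test_discordant_fraction_recorded(self):
        cfg = CohortConfig(seed=3, n_genes=200, de_fraction=0.2, discordant_fraction=0.25)
        pair = simulate_expression_pair(cfg)
        t = pair.truth
        planted = t[t["planted"]]
        assert len(planted) == 40
        assert t["discordant"].sum() == 10
        disc = t[t["discordant"]]
        assert (disc["direction_array"] == -disc["direction_seq"]).all()

    def test_counts_are_nonnegative_integers(self):
        pair = simulate_expression_pair(CohortConfig(seed=1, n_genes=30))
        arr = pair.counts.values.to_numpy()
        assert (arr >= 0).all() and np.allclose(arr, np.round(arr))


class TestMethylation:
    def test_all_shifted_gene_truth_is_hyper_or_hypo(self):
        sim = simulate_methylation(CohortConfig(seed=2, n_genes=100, meth_de_fraction=0.2))
        calls = set(sim.truth.loc[sim.truth["call"].isin(["hyper", "hypo"]), "call"])
        assert calls  # planted genes exist and are labelled by direction

    def test_na_rate_zero_means_complete(self):
        sim = simulate_methylation(CohortConfig(seed=2, n_genes=30, meth_na_rate=0.0))
        assert not sim.beta.values.isna().any().any()

    def test_beta_in_unit_interval(self):
        sim = simulate_methylation(CohortConfig(seed=2, n_genes=30))
        vals = sim.beta.values.to_numpy()
        finite = vals[~np.isnan(vals)]
        assert ((finite >= 0) & (finite <= 1)).all()


class TestClinicalSurvival:
    def test_all_censored_warns(self):
        cfg = CohortConfig(seed=4, n_genes=20, censoring_rate=1.0)
        pair = simulate_expression_pair(cfg)
        with pytest.warns(UserWarning, match="censor"):
            sheet, _ = simulate_clinical_survival(cfg, pair.counts, pair.seq_groups)
        tumors = sheet[sheet["group"] == "tumor"]
        assert (tumors["os_event"] == 0).all()

    def test_null_cox_coverage_near_nominal(self):
        # beta = 0 everywhere: 95% CIs of univariate Cox cover HR=1 ~95% of genes
        import pandas as pd

        from panomix import cox_fit, log_cpm, tmm_factors

        cfg = CohortConfig(seed=9, n_genes=200, n_tumor=150, n_normal=5, de_fraction=0.0)
        pair = simulate_expression_pair(cfg)
        sheet, _ = simulate_clinical_survival(cfg, pair.counts, pair.seq_groups)
        tumors = sheet.index[sheet["group"] == "tumor"]
        logcpm = log_cpm(pair.counts, tmm_factors(pair.counts))
        covered = 0
        for g in logcpm.genes:
            expr = logcpm.values.loc[g, tumors]
            z = (expr - expr.mean()) / expr.std()
            df = pd.DataFrame(
                {
                    "t": pd.to_numeric(sheet.loc[tumors, "os_time"]),
                    "e": pd.to_numeric(sheet.loc[tumors, "os_event"]),
                    "x": z,
                }
            )
            s = cox_fit(df, "t", "e", ["x"]).summary.loc["x"]
            covered += s["hr_lower"] <= 1.0 <= s["hr_upper"]
        assert 0.90 <= covered / len(logcpm.genes) <= 0.99

    def test_stage_trend_is_monotone_in_expectation(self):
        cfg = CohortConfig(
            seed=4, n_genes=20, n_tumor=200, n_normal=5, stage_trend_genes={"G0001": -1.0}
        )
        pair = simulate_expression_pair(cfg)
        sheet, adj = simulate_clinical_survival(cfg, pair.counts, pair.seq_groups)
        tumors = sheet[sheet["group"] == "tumor"]
        logx = np.log2(adj.values.loc["G0001", tumors.index] + 1.0)
        means = logx.groupby(tumors["stage"]).mean()
        assert means["I"] > means["IV"]


class TestAlterations:
    def test_mutation_frequency_matches_rate(self):
        cfg = CohortConfig(seed=9, n_genes=5, n_tumor=1000, n_normal=2, mutation_rate=0.05)
        mut, _, _ = simulate_genomic_alterations(cfg)
        nonsyn = mut[mut["classification"] != "Silent"]
        freq = nonsyn.groupby("gene")["sample"].nunique() / 1000
        assert ((freq - 0.05).abs() < 0.015).all()

    def test_rate_zero_gives_empty_table(self):
        cfg = CohortConfig(seed=9, n_genes=5, mutation_rate=0.0, silent_fraction=0.0)
        mut, _, _ = simulate_genomic_alterations(cfg)
        assert mut.empty

    def test_deletion_probability_recovered(self):
        cfg = CohortConfig(
            seed=9, n_genes=3, n_tumor=1000, n_normal=2, cnv_probs={"G0001": (0.4, 0.05)}
        )
        _, cnv, _ = simulate_genomic_alterations(cfg)
        del_freq = (cnv.loc["G0001"] < 0).mean()
        assert abs(del_freq - 0.4) < 0.05


class TestMirna:
    def test_single_list_mirna_not_consensus(self):
        sim = simulate_mirna_targets(CohortConfig(seed=6, n_genes=30, n_tumor=10, n_normal=10))
        t = sim.truth
        assert (t.loc[t["n_lists"] == 1, "consensus"] == False).all()  # noqa: E712
        assert (t.loc[t["regulator"], "n_lists"] >= 2).all()

    def test_regulator_anticorrelated_with_target(self):
        cfg = CohortConfig(seed=6, n_genes=30, n_tumor=40, n_normal=40, mirna_anticorr=0.8)
        pair = simulate_expression_pair(cfg)
        sim = simulate_mirna_targets(cfg, pair.counts, pair.seq_groups)
        target = sim.truth["target"].iloc[0]
        tvals = np.log2(pair.counts.values.loc[target].to_numpy() + 0.5)
        for m in sim.truth.index[sim.truth["regulator"]]:
            r = np.corrcoef(sim.mirna.values.loc[m], tvals)[0, 1]
            assert r < -0.4


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"de_fraction": 1.5},
            {"censoring_rate": -0.1},
            {"n_genes": 0},
            {"stage_probs": (0.5, 0.5, 0.5, 0.5)},
            {"cnv_del_prob": 0.7, "cnv_amp_prob": 0.6},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigError):
            CohortConfig(**kw)
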