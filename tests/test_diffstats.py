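"""Statistical engine: moderated t, rank tests, FDR and the pair analyses."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import isopair as ip
from isopair.diffstats import fit_f_dist


def _random_matrix(seed, n_features=80, n1=6, n0=6, scale_spread=True):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_features, n1 + n0))
    if scale_spread:
        x *= rng.uniform(0.4, 2.5, size=(n_features, 1))
    groups = np.array([True] * n1 + [False] * n0)
    return x, groups


class TestModeratedT:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_zero_prior_df_recovers_classical_t(self, seed):
        x, groups = _random_matrix(seed)
        res = ip.moderated_t_test(x, groups, prior_df=0.0)
        t_ref, p_ref = sps.ttest_ind(x[:, groups], x[:, ~groups], axis=1, equal_var=True)
        np.testing.assert_allclose(res.t, t_ref, atol=1e-10)
        np.testing.assert_allclose(res.p_value, p_ref, atol=1e-10)

    def test_effect_is_exact_mean_difference(self):
        x = np.array([[3.0, 3.0, 3.0, 1.0, 1.0, 1.0]]) + np.array(
            [[0.1, -0.1, 0.0, 0.1, -0.1, 0.0]])
        res = ip.moderated_t_test(x, [True, True, True, False, False, False])
        assert res.log_fc[0] == pytest.approx(2.0)

    def test_infinite_prior_df_gives_common_variance_z(self):
        x, groups = _random_matrix(3)
        res = ip.moderated_t_test(x, groups, prior_df=np.inf)
        assert np.all(res.s2_posterior == res.s2_posterior[0])
        np.testing.assert_allclose(res.p_value, 2 * sps.norm.sf(np.abs(res.t)))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ip.moderated_t_test(np.zeros((3, 4)), [True, False, False, False])

    def test_zero_variance_feature_handled_by_prior(self):
        x, groups = _random_matrix(4)
        x[0] = np.repeat([5.0, 3.0], 6)  # no within-group variance at all
        res = ip.moderated_t_test(x, groups)
        assert np.isfinite(res.t[0]) and 0 <= res.p_value[0] <= 1
        assert res.s2_posterior[0] > 0

    def test_nan_entries_reduce_residual_df(self):
        x, groups = _random_matrix(5)
        x[2, 0] = np.nan
        res = ip.moderated_t_test(x, groups)
        assert res.df_residual[2] == res.df_residual[0] - 1

    def test_moderation_shrinks_toward_prior(self):
        x, groups = _random_matrix(6)
        res = ip.moderated_t_test(x, groups)
        s2 = ((x[:, groups] - x[:, groups].mean(1, keepdims=True)) ** 2).sum(1)
        s2 += ((x[:, ~groups] - x[:, ~groups].mean(1, keepdims=True)) ** 2).sum(1)
        s2 /= res.df_residual
        lo = np.minimum(s2, res.params.prior_var) - 1e-12
        hi = np.maximum(s2, res.params.prior_var) + 1e-12
        assert np.all((res.s2_posterior >= lo) & (res.s2_posterior <= hi))

    def test_matches_limma_ebayes(self, tmp_path):
        """The empirical-Bayes fit agrees with the reference R implementation."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; limma cross-check cannot run")
        x, groups = _random_matrix(123, n_features=60, n1=5, n0=5)
        mat = tmp_path / "m.csv"
        out = tmp_path / "r.csv"
        np.savetxt(mat, x, delimiter=",")
        script = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.csv("{mat}", header=FALSE))
        design <- cbind(1, c(rep(1, 5), rep(0, 5)))
        fit <- eBayes(lmFit(x, design))
        write.csv(data.frame(t=fit$t[,2], p=fit$p.value[,2],
                             d0=fit$df.prior, s0=fit$s2.prior), "{out}", row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out)
        res = ip.moderated_t_test(x, groups)
        assert res.params.prior_df == pytest.approx(ref.d0[0], rel=1e-8)
        assert res.params.prior_var == pytest.approx(ref.s0[0], rel=1e-8)
        np.testing.assert_allclose(res.t, ref.t.values, atol=1e-10)
        np.testing.assert_allclose(res.p_value, ref.p.values, atol=1e-10)

    def test_type_i_error_near_nominal_under_global_null(self):
        """Identically distributed groups: about 5% of features reach p < 0.05."""
        fractions = []
        for seed in range(10):
            x, groups = _random_matrix(100 + seed, n_features=200, scale_spread=False)
            res = ip.moderated_t_test(x, groups)
            fractions.append(np.mean(res.p_value < 0.05))
        assert 0.03 <= np.mean(fractions) <= 0.07


class TestFitFDist:
    def test_recovers_known_prior(self):
        rng = np.random.default_rng(0)
        d0_true, s0_true, df = 8.0, 1.5, 10
        n = 20000
        s2 = s0_true * sps.f.rvs(df, d0_true, size=n, random_state=rng)
        params = fit_f_dist(s2, np.full(n, df))
        assert params.prior_df == pytest.approx(d0_true, rel=0.1)
        assert params.prior_var == pytest.approx(s0_true, rel=0.05)


def _mw_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumerating group assignments."""
    combined = np.concatenate([a, b])
    n = len(a)
    def u_stat(idx):
        aa = combined[list(idx)]
        bb = np.delete(combined, list(idx))
        return sum(1 for x in aa for y in bb if x > y)
    u_obs = u_stat(range(n))
    us = [u_stat(idx) for idx in itertools.combinations(range(len(combined)), n)]
    us = np.asarray(us)
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return min(p, 1.0)


class TestMannWhitney:
    def test_extreme_separation_exact_p(self):
        u, p = ip.mann_whitney_psi([0.1, 0.2], [0.8, 0.9])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_singletons(self):
        _, p = ip.mann_whitney_psi([0.5], [0.5])
        assert p == pytest.approx(1.0)

    def test_large_identical_samples_near_one(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(size=200)
        _, p = ip.mann_whitney_psi(a, a.copy())
        assert p > 0.9

    @pytest.mark.parametrize("n_a,n_b,seed", [(2, 3, 0), (3, 3, 1), (4, 5, 2), (6, 6, 3)])
    def test_exact_p_matches_enumeration(self, n_a, n_b, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(size=n_a)
        b = rng.uniform(size=n_b)
        _, p = ip.mann_whitney_psi(a, b)
        assert p == pytest.approx(_mw_exact_oracle(a, b), abs=1e-12)

    def test_missing_removed(self):
        u1, p1 = ip.mann_whitney_psi([0.1, 0.2, np.nan], [0.8, np.nan, 0.9])
        u2, p2 = ip.mann_whitney_psi([0.1, 0.2], [0.8, 0.9])
        assert (u1, p1) == (u2, p2)

    def test_all_missing_group_rejected(self):
        with pytest.raises(ValueError):
            ip.mann_whitney_psi([np.nan], [0.5])


def _spearman_rank_oracle(x, y):
    """Pearson correlation of average ranks (brute-force definition)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearman:
    def test_monotone_extremes(self):
        grades = [6, 7, 8, 9, 10]
        rho_up, _ = ip.spearman_assoc([1, 2, 3, 4, 5], grades)
        rho_dn, _ = ip.spearman_assoc([5, 4, 3, 2, 1], grades)
        assert rho_up == pytest.approx(1.0)
        assert rho_dn == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_pearson_on_ranks(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = rng.permutation(30).astype(float)  # tie-free
        rho, _ = ip.spearman_assoc(x, y)
        assert rho == pytest.approx(_spearman_rank_oracle(x, y), abs=1e-12)

    def test_tied_ordinal_uses_average_ranks(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1, 1, 2, 2]
        rho, _ = ip.spearman_assoc(x, y)
        assert rho == pytest.approx(_spearman_rank_oracle(x, y), abs=1e-12)

    def test_constant_ordinal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ip.spearman_assoc([1.0, 2.0, 3.0], [7, 7, 7])

    def test_constant_values_degenerate(self):
        assert ip.spearman_assoc([2.0, 2.0, 2.0], [6, 7, 8]) == (0.0, 1.0)


def _bh_oracle(p):
    """Hand step-up adjustment."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert ip.bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(ip.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(ip.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(2, 40))
        np.testing.assert_allclose(ip.bh_fdr(p), _bh_oracle(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_order_preserving(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=25)
        adj = ip.bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ip.bh_fdr([0.5, 1.2])


def _switch_scenario(delta, n_events=8, seed=0, **kw):
    eff_up = ip.AndrogenEffect.parse("Switch to isoform 1")
    events = [ip.EventScenario("FOCAL", eff_up, baseline_psi=0.4, delta_psi_true=delta, **kw)]
    events += [ip.EventScenario(f"NULL{i}", eff_up, baseline_psi=0.5)
               for i in range(n_events - 1)]
    return ip.SimulationScenario(n_tumour=100, n_normal=20, events=events, seed=seed)


class TestPairAnalyses:
    def test_null_simulation_has_small_median_delta_psi(self):
        scenario = _switch_scenario(0.0, n_events=40, seed=21)
        cohort = ip.simulate_cohort(scenario)
        de = ip.differential_pair_analysis(cohort.dataset, cohort.pairs)
        med = np.median([abs(s.delta_psi) for s in de.values()])
        assert med < 0.02

    def test_shifted_event_recovered(self):
        cohort = ip.simulate_cohort(_switch_scenario(+0.2, seed=5))
        de = ip.differential_pair_analysis(cohort.dataset, cohort.pairs)
        focal = de["FOCAL"]
        assert focal.psi_fdr < 0.05
        assert focal.delta_psi == pytest.approx(0.2, abs=0.05)

    def test_swapping_isoforms_negates_ratio_effects(self):
        cohort = ip.simulate_cohort(_switch_scenario(+0.2, seed=6))
        swapped = [ip.IsoformPair(p.gene, p.iso2_id, p.iso1_id, p.effect)
                   for p in cohort.pairs]
        de = ip.differential_pair_analysis(cohort.dataset, cohort.pairs)
        de_sw = ip.differential_pair_analysis(cohort.dataset, swapped)
        for g in de:
            assert de_sw[g].delta_psi == pytest.approx(-de[g].delta_psi, abs=1e-12)
            assert de_sw[g].iso1_log2fc == pytest.approx(de[g].iso2_log2fc)
            assert de_sw[g].iso2_log2fc == pytest.approx(de[g].iso1_log2fc)

    def test_missing_isoform_skipped(self):
        cohort = ip.simulate_cohort(_switch_scenario(0.0, n_events=3, seed=7))
        pairs = cohort.pairs + [ip.IsoformPair("GHOST", "nope1", "nope2", None)]
        de = ip.differential_pair_analysis(cohort.dataset, pairs)
        assert "GHOST" not in de and len(de) == 3

    def test_mannwhitney_variant_runs(self):
        cohort = ip.simulate_cohort(_switch_scenario(+0.3, n_events=4, seed=8))
        de = ip.differential_pair_analysis(cohort.dataset, cohort.pairs,
                                           psi_test="mannwhitney")
        assert de["FOCAL"].psi_fdr < 0.05

    def test_grade_trend_recovered_in_correlation_mode(self):
        eff = ip.AndrogenEffect.parse("Switch to isoform 1")
        events = [ip.EventScenario("TREND", eff, baseline_psi=0.5)]
        events += [ip.EventScenario(f"NULL{i}", eff, baseline_psi=0.5) for i in range(5)]
        scenario = ip.SimulationScenario(n_tumour=300, n_normal=10, events=events,
                                         grade_slope=0.0, seed=9)
        # rebuild with a grade trend confined to the focal event
        cohort = ip.simulate_cohort(scenario)
        grades = cohort.dataset.metadata["gleason"]
        rng = np.random.default_rng(10)
        tumour = cohort.dataset.group_mask("tumour")
        psi = 1 / (1 + np.exp(-(0.4 * (grades[tumour] - 6))))
        counts1 = rng.poisson(200 * psi)
        counts2 = rng.poisson(200 * (1 - psi))
        expr = cohort.dataset.expression.copy()
        expr.loc[tumour, "TREND_iso1"] = counts1.astype(float)
        expr.loc[tumour, "TREND_iso2"] = counts2.astype(float)
        dataset = ip.ExpressionDataset(expr, cohort.dataset.metadata, unit="tpm")
        corr = ip.correlation_pair_analysis(dataset, cohort.pairs, "gleason")
        assert corr["TREND"].psi_rho > 0
        assert corr["TREND"].psi_fdr < 0.05

    def test_permuted_covariate_yields_no_calls(self):
        scenario = _switch_scenario(0.0, n_events=30, seed=12)
        cohort = ip.simulate_cohort(scenario)
        meta = cohort.dataset.metadata.copy()
        rng = np.random.default_rng(13)
        meta["gleason"] = rng.permutation(meta["gleason"].to_numpy())
        dataset = ip.ExpressionDataset(cohort.dataset.expression, meta, unit="tpm")
        corr = ip.correlation_pair_analysis(dataset, cohort.pairs, "gleason")
        sig = [g for g, s in corr.items() if s.psi_fdr is not None and s.psi_fdr < 0.05]
        assert len(sig) / len(corr) <= 0.05
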