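"""Residualized Spearman, permutation inference and the follow-up statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import isrsa
from isrsa import (
    ControlDesign,
    RunResult,
    devectorize,
    familywise_count_test,
    holm_bonferroni,
    isc_fit_correlation,
    isrsa_node,
    model_comparison,
    network_enrichment,
    residualize,
    rho_vector,
    run_all_nodes,
    spearman,
    split_half,
    vectorize_lower,
)
from isrsa.similarity import annak_matrix, behavior_matrix, control_design


class TestResidualize:
    def test_orthogonal_vector_unchanged(self, rng):
        design = ControlDesign.intercept_only(10)
        v = rng.standard_normal(10)
        v -= v.mean()
        assert np.allclose(residualize(v, design), v, atol=1e-10)

    def test_design_column_maps_to_zero(self, rng):
        x = np.column_stack([np.ones(12), rng.standard_normal(12)])
        design = ControlDesign(["intercept", "c"], x)
        assert np.allclose(residualize(x[:, 1].copy(), design), 0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        x = np.column_stack([np.ones(45), rng.standard_normal((45, 2))])
        design = ControlDesign(["intercept", "a", "b"], x)
        v = rng.standard_normal(45)
        beta = np.linalg.solve(x.T @ x, x.T @ v)  # independent solve
        assert np.allclose(residualize(v, design), v - x @ beta, atol=1e-8)
        # residuals orthogonal to every column
        assert np.max(np.abs(x.T @ residualize(v, design))) < 1e-8

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            residualize(np.ones(5), ControlDesign.intercept_only(6))


class TestSpearman:
    def test_monotone_and_antitone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman(x, -(x**3)) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 4.0])
        y = np.array([3.0, 1.0, 4.0, 4.0])
        rx, ry = stats.rankdata(x), stats.rankdata(y)  # average ties
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(oracle, abs=1e-12)
        assert spearman(x, y) == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(5), np.arange(5.0))


def _annak_cohort(n, seed, noise=0.0):
    """Brain matrix = monotone function of the AnnaK behavior matrix."""
    rng = np.random.default_rng(seed)
    scores = rng.uniform(0, 1, size=n)
    b = annak_matrix(scores)
    brain = np.tanh(b) + noise * rng.standard_normal(b.shape)
    brain = (brain + brain.T) / 2
    np.fill_diagonal(brain, 1.0)
    return scores, brain


class TestIsrsaNode:
    def test_perfect_planted_agreement(self, rng):
        scores, brain = _annak_cohort(10, seed=1)
        design = ControlDesign.intercept_only(45)
        res = isrsa_node(brain, scores, "annak", design, n_perm=200, rng=rng)
        assert res.rho == pytest.approx(1.0)
        assert res.p_perm == pytest.approx(1 / 201)
        assert res.sig_uncorrected and res.sig_corrected

    def test_sampled_p_matches_exhaustive_enumeration(self, rng):
        """All 5! relabelings, statistic recomputed independently with scipy."""
        scores, brain = _annak_cohort(5, seed=4, noise=0.3)
        design = ControlDesign.intercept_only(10)
        res = isrsa_node(brain, scores, "annak", design, n_perm=4000, rng=rng)

        bv = vectorize_lower(brain)
        bv = bv - bv.mean()  # intercept-only residualization

        def rho_of(perm_scores):
            v = vectorize_lower(annak_matrix(perm_scores))
            return stats.spearmanr(bv, v - v.mean()).statistic

        obs = rho_of(scores)
        null = [rho_of(scores[list(p)]) for p in itertools.permutations(range(5))]
        exact = np.mean([abs(r) >= abs(obs) - 1e-12 for r in null])
        assert res.rho == pytest.approx(obs, abs=1e-12)
        assert res.p_perm == pytest.approx(exact, abs=0.02)

    def test_degenerate_scores_rejected(self, rng):
        _, brain = _annak_cohort(6, seed=2)
        with pytest.raises(ValueError, match="degenerate scores"):
            isrsa_node(brain, np.ones(6), "annak",
                       ControlDesign.intercept_only(15), 10, rng)


class TestRunAllNodes:
    def test_identical_nodes_get_identical_results(self, rng):
        scores, brain = _annak_cohort(12, seed=3, noise=0.2)
        design = ControlDesign.intercept_only(66)
        res = run_all_nodes(np.stack([brain, brain]), ["a", "b"], scores,
                            ["annak", "nn"], design, 300, rng)
        for model in ("annak", "nn"):
            sub = res.table[res.table["model"] == model]
            a, b = sub.iloc[0], sub.iloc[1]
            assert a["rho"] == b["rho"] and a["p_perm"] == b["p_perm"]

    def test_single_node_reduces_to_isrsa_node(self):
        scores, brain = _annak_cohort(12, seed=5, noise=0.2)
        design = ControlDesign.intercept_only(66)
        res = run_all_nodes(brain[None], ["n1"], scores, ["annak"], design,
                            250, np.random.default_rng(77))
        node = isrsa_node(brain, scores, "annak", design, 250,
                          np.random.default_rng(77), node_id="n1")
        row = res.table.iloc[0]
        assert row["rho"] == node.rho and row["p_perm"] == node.p_perm

    def test_relabeling_invariance(self):
        """Permuting subjects in both brain and behavior leaves rho unchanged."""
        scores, brain = _annak_cohort(14, seed=6, noise=0.4)
        design = ControlDesign.intercept_only(91)
        perm = np.random.default_rng(1).permutation(14)
        r1 = run_all_nodes(brain[None], ["n"], scores, ["annak", "nn"], design,
                           50, np.random.default_rng(0))
        r2 = run_all_nodes(brain[np.ix_(perm, perm)][None], ["n"], scores[perm],
                           ["annak", "nn"], design, 50, np.random.default_rng(0))
        assert np.allclose(r1.table["rho"], r2.table["rho"], atol=1e-10)

    def test_p_holm_dominates_p_perm(self, rng):
        scores, _ = _annak_cohort(10, seed=8)
        mats = np.stack([_annak_cohort(10, seed=s, noise=1.0)[1] for s in range(4)])
        res = run_all_nodes(mats, list("abcd"), scores, ["annak"],
                            ControlDesign.intercept_only(45), 99, rng)
        assert (res.table["p_holm"] >= res.table["p_perm"]).all()
        assert (~res.table["sig_corrected"] | res.table["sig_uncorrected"]).all()


class TestHolm:
    def test_hand_cases(self):
        assert holm_bonferroni([0.04]) == pytest.approx([0.04])
        assert holm_bonferroni([0.01, 0.02, 0.05]) == pytest.approx([0.03, 0.04, 0.05])

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=rng.integers(2, 50))
            ref = multipletests(p, method="holm")[1]
            assert np.allclose(holm_bonferroni(p), ref, atol=1e-12)

    def test_reorder_invariance(self, rng):
        p = rng.uniform(0.001, 1, size=15)
        perm = rng.permutation(15)
        assert np.allclose(holm_bonferroni(p)[perm], holm_bonferroni(p[perm]))

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            holm_bonferroni([0.1, 0.0])
        with pytest.raises(ValueError, match="p-values"):
            holm_bonferroni([0.1, 1.2])


class TestFamilywise:
    def test_zero_observed_count_is_one(self, rng):
        assert familywise_count_test(0, 268, 0.05, 50, rng).p_familywise == 1.0

    def test_invalid_parameters_rejected(self, rng):
        with pytest.raises(ValueError, match="alpha"):
            familywise_count_test(3, 10, 1.5, 10, rng)
        with pytest.raises(ValueError, match="observed_count"):
            familywise_count_test(11, 10, 0.05, 10, rng)


class TestModelComparison:
    @staticmethod
    def _result(rho_a, rho_b, null_a, null_b):
        rows = [{"node_id": f"n{i}", "model": m, "rho": r, "p_perm": 0.5,
                 "p_holm": 0.5, "sig_uncorrected": False, "sig_corrected": False}
                for m, rhos in (("annak", rho_a), ("nn", rho_b))
                for i, r in enumerate(rhos)]
        return RunResult(pd.DataFrame(rows),
                         {"annak": np.asarray(null_a), "nn": np.asarray(null_b)},
                         alpha=0.05, n_perm=len(null_a))

    def test_identical_fits_give_zero(self):
        rho = [0.3, -0.2, 0.1]
        null = np.zeros((10, 3))
        mc = model_comparison(self._result(rho, rho, null, null))
        assert mc.mean_z_diff == 0.0 and mc.rho_scale_diff == 0.0

    def test_single_node_round_trip(self):
        mc = model_comparison(self._result([0.5], [0.0], np.zeros((10, 1)),
                                           np.zeros((10, 1))))
        assert mc.rho_scale_diff == pytest.approx(0.5)
        assert mc.rho_scale_diff == pytest.approx(math.tanh(mc.mean_z_diff), abs=1e-12)

    def test_perfect_correlation_is_clipped_not_infinite(self):
        mc = model_comparison(self._result([1.0], [0.0], np.zeros((5, 1)),
                                           np.zeros((5, 1))))
        assert np.isfinite(mc.mean_z_diff)

    def test_missing_model_rejected(self):
        res = self._result([0.1], [0.2], np.zeros((5, 1)), np.zeros((5, 1)))
        with pytest.raises(ValueError, match="combined"):
            model_comparison(res, "annak", "combined")


class TestIscFitCorrelation:
    def test_affine_and_sign(self, rng):
        m = rng.uniform(0, 0.5, size=8)
        assert isc_fit_correlation(m, 2 * m + 1) == pytest.approx(1.0)
        assert isc_fit_correlation(m, -m) == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            isc_fit_correlation(np.ones(5), np.arange(5.0))


class TestNetworkEnrichment:
    def _nodes(self):
        nets = {f"n{i}": ("motor" if i < 5 else "visual" if i < 12 else "default")
                for i in range(20)}
        return pd.Series(nets)

    def test_degenerate_draws(self):
        nets = self._nodes()
        none = network_enrichment(pd.Series(False, index=nets.index), nets)
        assert (none["p"] == 1.0).all()
        full = network_enrichment(pd.Series(True, index=nets.index), nets)
        assert (full["p"] == 1.0).all()
        assert (full["n_significant"] == full["n_nodes"]).all()

    def test_concentrated_significance_matches_hypergeometric_sum(self):
        nets = self._nodes()
        sig = pd.Series(False, index=nets.index)
        sig[[f"n{i}" for i in range(4)]] = True  # 4 of 4 hits in the 5-node motor net
        tab = network_enrichment(sig, nets).set_index("network")
        # exact upper tail via explicit combinatorial sum, independent of scipy
        n_total, n_sig, m, k = 20, 4, 5, 4
        p_exact = sum(
            math.comb(n_sig, x) * math.comb(n_total - n_sig, m - x)
            for x in range(k, min(m, n_sig) + 1)
        ) / math.comb(n_total, m)
        assert tab.loc["motor", "p"] == pytest.approx(p_exact, abs=1e-12)
        assert tab.loc["motor", "expected"] == pytest.approx(5 * 4 / 20)

    def test_unmapped_node_rejected(self):
        nets = self._nodes().drop("n3")
        with pytest.raises(ValueError, match="mapping"):
            network_enrichment(pd.Series(True, index=self._nodes().index), nets)


class TestSplitHalf:
    def test_identical_cohorts_hook_gives_unit_consistency(self, toy_cohort):
        """Running the per-cohort analysis twice on the same sample must agree."""
        behavior, tc = toy_cohort
        r1 = rho_vector(tc, behavior, "annak")
        r2 = rho_vector(tc, behavior, "annak")
        assert isc_fit_correlation(r1, r2) == pytest.approx(1.0)

    def test_disjoint_halves_partition_sample(self, toy_cohort, rng):
        behavior, tc = toy_cohort
        sh = split_half(tc, behavior, "annak", rng)
        counts = sh.cohort_assignment.value_counts()
        assert counts.sum() == tc.n_subjects and abs(counts[1] - counts[2]) <= 1
        assert len(sh.rho_cohort1) == len(tc.node_ids)
        assert -1 <= sh.consistency_r <= 1

    def test_planted_signal_replicates_across_halves(self, rng):
        """With heterogeneous planted coupling the spatial profile of fit
        is strongly consistent across random halves."""
        spec = isrsa.SimSpec(n_subjects=48, n_nodes=20, n_timepoints=300,
                             node_models=("annak",) * 10 + ("null",) * 10,
                             coupling=(0.9,) * 10 + (0.0,) * 10, seed=61)
        beh = isrsa.generate_behavior(spec)
        tc = isrsa.generate_timecourses(beh, spec)
        sh = split_half(tc, beh, "annak", rng)
        assert sh.consistency_r > 0.5

    def test_null_consistency_centered_on_zero(self):
        """All-null cohorts: split-half consistency averages to ~0.

        Intercept-only design: tiny 8-subject cohorts can be exactly
        collinear in the full nuisance design, and the property under
        test concerns the splitting machinery, not the controls.
        """
        builder = lambda b: ControlDesign.intercept_only(len(b) * (len(b) - 1) // 2)
        rs = []
        for i in range(100):
            spec = isrsa.SimSpec(n_subjects=16, n_nodes=8, n_timepoints=60,
                                 seed=900 + i)
            beh = isrsa.generate_behavior(spec)
            tc = isrsa.generate_timecourses(beh, spec)
            sh = split_half(tc, beh, "annak", np.random.default_rng(i),
                            design_builder=builder)
            rs.append(sh.consistency_r)
        assert abs(np.mean(rs)) < 0.1

    def test_too_few_subjects_rejected(self, rng):
        spec = isrsa.SimSpec(n_subjects=6, n_nodes=1, n_timepoints=50, seed=0)
        beh = isrsa.generate_behavior(spec)
        tc = isrsa.generate_timecourses(beh, spec)
        with pytest.raises(ValueError, match="8 subjects"):
            split_half(tc, beh, "annak", rng)
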