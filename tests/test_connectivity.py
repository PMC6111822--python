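"""The signed-rank connection score, its null distribution, the 1/N
significance rule, perturbation stability and the drug ranking."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from revmap import (
    ConnectivityRun, GeneSignature, RefSimConfig, connection_pvalue,
    connection_strength, expected_false_discovery, null_moments,
    perturbation_stability, rank_drugs, score_drug, screen_library,
    significance_plot, significance_threshold, simulate_reference_library,
)
from revmap.connectivity import ConnectionResult
from revmap.errors import ConfigurationError, EstimationError, InputError


def exact_pvalue(ranks, m, c, tail="negative"):
    """Enumeration oracle: P(sum of m drawn ranks <= c) over all subsets."""
    sums = [sum(s) for s in itertools.combinations(ranks, m)]
    if tail == "negative":
        k = sum(1 for s in sums if s <= c)
    else:
        k = sum(1 for s in sums if s >= c)
    return k / len(sums)


class TestConnectionStrength:
    def test_top_rank_gene_maximal(self, toy_profile):
        c, cn = connection_strength(toy_profile, GeneSignature.from_genes(["g1"]))
        assert (c, cn) == (3.0, 1.0)

    def test_negative_rank_gene(self, toy_profile):
        c, cn = connection_strength(toy_profile, GeneSignature.from_genes(["g2"]))
        assert c == -2.0
        assert cn == pytest.approx(-2 / 3)

    def test_signed_two_gene_signature_maximal(self, toy_profile):
        sig = GeneSignature.from_pairs([("g1", 1), ("g2", -1)])
        c, cn = connection_strength(toy_profile, sig)
        assert (c, cn) == (5.0, 1.0)  # max attainable = 3 + 2

    def test_negating_signs_negates_c(self, toy_profile):
        sig = GeneSignature.from_pairs([("g1", 1), ("g2", -1), ("g3", 1)])
        c, _ = connection_strength(toy_profile, sig)
        c_neg, _ = connection_strength(toy_profile, sig.negated())
        assert c_neg == -c

    def test_missing_gene_listed(self, toy_profile):
        with pytest.raises(InputError, match="g9"):
            connection_strength(toy_profile, GeneSignature.from_genes(["g9"]))


class TestNullMoments:
    def test_hand_moments_three_point(self, toy_profile):
        mu, var = null_moments(toy_profile, 1)
        assert mu == pytest.approx(2 / 3)
        assert var == pytest.approx(38 / 9)

    def test_whole_universe_has_zero_variance(self, toy_profile):
        mu, var = null_moments(toy_profile, 3)
        assert var == 0.0
        assert mu == pytest.approx(2.0)  # 3 * mean

    def test_balanced_profile_zero_mean(self):
        # signed ranks summing to zero give a centred null
        profile = {"a": 1, "b": 2, "c": -3}
        mu, _ = null_moments(profile, 2)
        assert mu == pytest.approx(0.0)

    def test_moments_match_enumeration(self):
        rng = np.random.default_rng(0)
        for G, m in [(5, 2), (7, 3), (8, 4)]:
            signs = rng.choice([-1, 1], G)
            ranks = (np.arange(1, G + 1) * signs).astype(int)
            sums = np.array(
                [sum(s) for s in itertools.combinations(ranks.tolist(), m)],
                dtype=float,
            )
            mu, var = null_moments({f"g{i}": r for i, r in enumerate(ranks)}, m)
            assert mu == pytest.approx(sums.mean())
            assert var == pytest.approx(sums.var())

    def test_m_out_of_range_rejected(self, toy_profile):
        with pytest.raises(InputError):
            null_moments(toy_profile, 4)


class TestConnectionPvalue:
    def test_hand_standardized_score(self, toy_profile):
        run = ConnectivityRun(N=3)
        z, _ = connection_pvalue(-2, toy_profile, 1, run)
        assert z == pytest.approx(-8 / math.sqrt(38))

    def test_exact_enumeration_one_third(self, toy_profile):
        run = ConnectivityRun(N=3, null_method="exact")
        _, p = connection_pvalue(-2, toy_profile, 1, run)
        assert p == pytest.approx(1 / 3)

    def test_score_at_null_mean_gives_half(self):
        profile = {f"g{i}": r for i, r in enumerate([1, -2, 3, -4])}
        mu, _ = null_moments(profile, 2)
        run = ConnectivityRun(N=10)
        z, p = connection_pvalue(mu, profile, 2, run)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_monte_carlo_matches_exact_small_instances(self):
        # all instances with G <= 8, m <= 3 within 3 MC standard errors
        rng = np.random.default_rng(5)
        n_draws = 4000
        for G in range(4, 9):
            signs = rng.choice([-1, 1], G)
            ranks = (np.arange(1, G + 1) * signs).astype(int)
            profile = {f"g{i}": int(r) for i, r in enumerate(ranks)}
            for m in range(1, 4):
                c = float(np.sort(ranks)[:m].sum())  # an extreme observed score
                p_exact = exact_pvalue(ranks.tolist(), m, c)
                run = ConnectivityRun(
                    N=10, null_method="monte_carlo", n_draws=n_draws, seed=G * 10 + m
                )
                _, p_mc = connection_pvalue(c, profile, m, run)
                se = math.sqrt(max(p_exact * (1 - p_exact), 1e-12) / n_draws)
                assert abs(p_mc - p_exact) <= 3 * se + 2 / n_draws

    def test_analytic_z_matches_empirical_in_clt_regime(self):
        rng = np.random.default_rng(8)
        G, m = 200, 16
        signs = rng.choice([-1, 1], G)
        ranks = (rng.permutation(np.arange(1, G + 1)) * signs).astype(np.int64)
        mu, var = null_moments({f"g{i}": int(r) for i, r in enumerate(ranks)}, m)
        draws = np.array([
            rng.choice(ranks, m, replace=False).sum() for _ in range(20000)
        ])
        assert mu == pytest.approx(draws.mean(), abs=3 * draws.std() / 140)
        z_emp = (draws - mu) / math.sqrt(var)
        assert z_emp.std() == pytest.approx(1.0, abs=0.05)

    def test_monte_carlo_p_never_zero(self, toy_profile):
        run = ConnectivityRun(N=3, null_method="monte_carlo", n_draws=100, seed=1)
        _, p = connection_pvalue(-1e9, toy_profile, 1, run)
        assert p == pytest.approx(1 / 101)

    def test_degenerate_variance_rejected(self, toy_profile):
        run = ConnectivityRun(N=3)
        with pytest.raises(EstimationError):
            connection_pvalue(2.0, toy_profile, 3, run)


class TestScoreDrug:
    def _replicated(self, profile, n):
        return [dict(profile) for _ in range(n)]

    def test_single_replicate_matches_connection_pvalue(self, toy_profile):
        sig = GeneSignature.from_genes(["g2"])
        run = ConnectivityRun(N=3)
        res = score_drug([toy_profile], sig, run)
        z, p = connection_pvalue(-2, toy_profile, 1, run)
        assert res.z == pytest.approx(z)
        assert res.p == pytest.approx(p)
        assert res.replicate_count == 1

    def test_identical_replicates_gain_sqrt_n(self, toy_profile):
        sig = GeneSignature.from_genes(["g2"])
        run = ConnectivityRun(N=3)
        z1 = score_drug([toy_profile], sig, run).z
        for n in (2, 4, 9):
            zn = score_drug(self._replicated(toy_profile, n), sig, run).z
            assert zn == pytest.approx(math.sqrt(n) * z1)

    def test_planted_reverser_marked_significant_at_1432(self):
        sig = GeneSignature.from_genes([f"X{i:03d}" for i in range(16)])
        universe = [f"X{i:03d}" for i in range(1000)]
        cfg = RefSimConfig(
            n_drugs=3, gene_universe=universe, planted_reversers=["drug0002"],
            reversal_strength=3.0, n_replicates_range=(5, 5), seed=13,
        )
        refset, _ = simulate_reference_library(cfg, sig)
        run = ConnectivityRun(N=1432)
        res = score_drug(
            refset.profiles["drug0002"], sig, run,
            gene_universe=refset.gene_universe, drug_id="drug0002",
        )
        assert res.significance_mark == 1
        assert res.p < 1 / 1432


class TestPerturbationStability:
    def test_strong_reverser_fully_stable(self, planted_library):
        refset, truth, signature = planted_library
        run = ConnectivityRun(N=refset.N)
        for drug in refset.drug_ids:
            if truth[drug]:
                stab = perturbation_stability(
                    refset.profiles[drug], signature, run,
                    gene_universe=refset.gene_universe,
                )
                assert stab == 1.0

    def test_null_drug_fully_unstable(self, planted_library):
        refset, truth, signature = planted_library
        run = ConnectivityRun(N=refset.N)
        null_drug = next(d for d in refset.drug_ids if not truth[d])
        stab = perturbation_stability(
            refset.profiles[null_drug], signature, run,
            gene_universe=refset.gene_universe,
        )
        assert stab == pytest.approx(0.0)

    def test_fraction_takes_multiples_of_one_over_m(self, planted_library):
        refset, _, signature = planted_library
        run = ConnectivityRun(N=refset.N)
        m = signature.m
        for drug in refset.drug_ids[:10]:
            stab = perturbation_stability(
                refset.profiles[drug], signature, run,
                gene_universe=refset.gene_universe,
            )
            assert stab * m == pytest.approx(round(stab * m))

    def test_single_gene_signature_rejected(self, toy_profile):
        run = ConnectivityRun(N=3)
        with pytest.raises(InputError):
            perturbation_stability(
                [toy_profile], GeneSignature.from_genes(["g1"]), run
            )

    def test_stability_monotone_in_reversal_strength(self):
        sig = GeneSignature.from_genes([f"X{i:03d}" for i in range(16)])
        universe = [f"X{i:03d}" for i in range(300)]
        run = ConnectivityRun(N=100)
        prev = -1.0
        for strength in (0.5, 1.5, 3.0):
            cfg = RefSimConfig(
                n_drugs=1, gene_universe=universe,
                planted_reversers=["drug0001"], reversal_strength=strength,
                n_replicates_range=(3, 3), seed=77,
            )
            refset, _ = simulate_reference_library(cfg, sig)
            stab = perturbation_stability(
                refset.profiles["drug0001"], sig, run,
                gene_universe=refset.gene_universe,
            )
            assert stab >= prev
            prev = stab


class TestThresholdAndFdr:
    def test_threshold_is_exactly_one_over_n(self):
        assert significance_threshold(1432) == 1 / 1432
        assert f"{significance_threshold(1432):.1g}" == "0.0007"
        assert significance_threshold(1) == 1.0
        assert significance_threshold(1000) == 0.001

    def test_threshold_rejects_bad_n(self):
        with pytest.raises(InputError):
            significance_threshold(0)

    def test_expected_fdr_values(self):
        assert expected_false_discovery(95) == pytest.approx(1 / 95)
        assert round(expected_false_discovery(95), 2) == 0.01
        assert expected_false_discovery(1) == 1.0
        assert expected_false_discovery(200) == 0.005

    def test_expected_fdr_zero_flagged(self):
        assert math.isnan(expected_false_discovery(0))

    def test_type_i_expected_false_positives_near_one(self):
        # a random signature against null libraries: E[# significant] = 1
        sig = GeneSignature.from_genes([f"X{i:03d}" for i in range(16)])
        universe = [f"X{i:03d}" for i in range(500)]
        n_libs, counts = 100, []
        for seed in range(n_libs):
            cfg = RefSimConfig(
                n_drugs=50, gene_universe=universe, planted_reversers=[],
                n_replicates_range=(1, 2), seed=seed,
            )
            refset, _ = simulate_reference_library(cfg, sig)
            results = screen_library(refset, sig, with_stability=False)
            counts.append(sum(r.significance_mark for r in results))
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / math.sqrt(n_libs)
        assert abs(mean - 1.0) <= 3 * se


class TestRanking:
    def _res(self, drug, p, z, stab=1.0):
        return ConnectionResult(
            drug_id=drug, replicate_count=1, c_total=0.0, z=z, p=p,
            significance_mark=int(p < 0.0007), perturb_stability=stab,
        )

    def test_smaller_p_first(self):
        ranked = rank_drugs([
            self._res("calcitriol", 3.15e-10, -6.18),
            self._res("bendroflumethiazide", 1.51e-11, -6.65),
        ])
        assert [r.drug_id for r in ranked] == [
            "bendroflumethiazide", "calcitriol"
        ]

    def test_stability_breaks_p_ties(self):
        ranked = rank_drugs([
            self._res("a", 1e-5, -4.0, stab=0.5),
            self._res("b", 1e-5, -4.0, stab=1.0),
        ])
        assert [r.drug_id for r in ranked] == ["b", "a"]

    def test_z_then_id_break_remaining_ties(self):
        ranked = rank_drugs([
            self._res("b", 1e-5, -4.0), self._res("a", 1e-5, -4.0),
            self._res("c", 1e-5, -5.0),
        ])
        assert [r.drug_id for r in ranked] == ["c", "a", "b"]


class TestSignificancePlot:
    def _results(self):
        return [
            ConnectionResult("a", 1, -10.0, -5.0, 1e-6, 1, 1.0),
            ConnectionResult("b", 1, -1.0, -0.5, 0.3, 0, 0.0),
        ]

    def test_threshold_line_value_for_1432(self, tmp_path):
        line = significance_plot(
            self._results(), significance_threshold(1432), tmp_path / "f.png"
        )
        assert round(line, 2) == 3.16
        assert (tmp_path / "f.png").exists()

    def test_threshold_line_simple_case(self, tmp_path):
        assert significance_plot(
            self._results(), 1 / 10, tmp_path / "g.png"
        ) == pytest.approx(1.0)


class TestRunValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"N": 0},
            {"N": 5, "tail": "both"},
            {"N": 5, "null_method": "bootstrap"},
            {"N": 5, "n_draws": 0},
        ],
    )
    def test_bad_run_configs(self, kwargs):
        with pytest.raises(ConfigurationError):
            ConnectivityRun(**kwargs)

    def test_threshold_property(self):
        assert ConnectivityRun(N=1432).threshold == 1 / 1432


class TestScreenLibrary:
    def test_screen_matches_score_drug(self, planted_library):
        refset, _, signature = planted_library
        run = ConnectivityRun(N=refset.N)
        results = {r.drug_id: r for r in
                   screen_library(refset, signature, run, with_stability=False)}
        for drug in refset.drug_ids[:8]:
            solo = score_drug(
                refset.profiles[drug], signature, run,
                gene_universe=refset.gene_universe, drug_id=drug,
            )
            assert results[drug].z == pytest.approx(solo.z)
            assert results[drug].p == pytest.approx(solo.p)

    def test_fast_stability_matches_leave_one_out(self, planted_library):
        refset, _, signature = planted_library
        run = ConnectivityRun(N=refset.N)
        results = {r.drug_id: r for r in screen_library(refset, signature, run)}
        for drug in refset.drug_ids[:6]:
            slow = perturbation_stability(
                refset.profiles[drug], signature, run,
                gene_universe=refset.gene_universe,
            )
            assert results[drug].perturb_stability == pytest.approx(slow)

    def test_reversers_on_top(self, planted_library):
        refset, truth, signature = planted_library
        results = screen_library(refset, signature)
        top3 = [r.drug_id for r in results[:3]]
        assert all(truth[d] for d in top3)
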