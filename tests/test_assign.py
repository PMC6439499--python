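import math

import numpy as np
import pytest
from scipy.special import roots_jacobi

from gsikit.assign import (
    assign_individuals,
    assignment_scores,
    loo_self_assignment,
    lr_summary,
    rm_log_likelihood,
)
from gsikit.popgen import MISSING, AlleleCountTable, BaselineSet, allele_counts

from conftest import make_gm


def counts(n_alts, n_inds, lids=None):
    n_alts = np.asarray(n_alts)
    n_inds = np.asarray(n_inds)
    lids = lids or [f"L{i}" for i in range(len(n_alts))]
    # het counts are irrelevant to the likelihood; set to 0
    return AlleleCountTable(lids, n_alts, 2 * n_inds, np.zeros_like(n_alts), n_inds)


def beta_integral_oracle(dosage, n_a, n):
    """Posterior-predictive genotype probability by numerical integration
    of the binomial genotype probability against the Beta(1/2, 1/2)
    posterior for the allele frequency -- independent of the closed form.

    The posterior density p^(n_a-1/2) (1-p)^(n-n_a-1/2) is exactly the
    Gauss-Jacobi weight after mapping [0,1] -> [-1,1], and the genotype
    probability is a degree-2 polynomial, so a 5-node Jacobi rule is
    numerically exact."""
    gfun = {0: lambda p: (1 - p) ** 2, 1: lambda p: 2 * p * (1 - p), 2: lambda p: p**2}[
        dosage
    ]
    alpha = n - n_a - 0.5  # exponent of (1 - x) on [-1, 1]
    beta = n_a - 0.5
    x, w = roots_jacobi(5, alpha, beta)
    p = (x + 1.0) / 2.0
    return float(np.sum(w * gfun(p)) / np.sum(w))


class TestRmLogLikelihood:
    def test_hom_alt_closed_form(self):
        # baseline 9 alt of 10 copies, hom-alt genotype
        ll = rm_log_likelihood(np.array([2]), counts([9], [5]))
        assert ll == pytest.approx(math.log((9.5 / 11) * (10.5 / 12)), abs=1e-12)
        assert math.exp(ll) == pytest.approx(0.755681, abs=1e-6)

    def test_absent_allele_has_prior_floor(self):
        n = 10
        ll = rm_log_likelihood(np.array([2]), counts([0], [n // 2]))
        assert math.exp(ll) == pytest.approx((0.5 * 1.5) / ((n + 1) * (n + 2)), rel=1e-12)
        assert math.exp(ll) > 0

    def test_het_at_fixed_locus(self):
        n = 12
        ll = rm_log_likelihood(
            np.array([MISSING, 1]), counts([0, n], [3, n // 2])
        )
        expected = 2 * (n + 0.5) * 0.5 / ((n + 1) * (n + 2))
        assert math.exp(ll) == pytest.approx(expected, rel=1e-12)

    def test_matches_beta_integral_oracle(self, rng):
        for _ in range(100):
            n_ind = int(rng.integers(1, 40))
            n = 2 * n_ind
            n_a = int(rng.integers(0, n + 1))
            d = int(rng.integers(0, 3))
            ll = rm_log_likelihood(np.array([d]), counts([n_a], [n_ind]))
            oracle = beta_integral_oracle(d, n_a, n)
            assert math.exp(ll) == pytest.approx(oracle, abs=1e-8)

    def test_sums_over_loci(self):
        c = counts([9, 3], [5, 5])
        both = rm_log_likelihood(np.array([2, 0]), c)
        first = rm_log_likelihood(np.array([2, MISSING]), c)
        second = rm_log_likelihood(np.array([MISSING, 0]), c)
        assert both == pytest.approx(first + second, abs=1e-12)

    def test_zero_usable_loci_error(self):
        with pytest.raises(ValueError, match="usable"):
            rm_log_likelihood(np.array([MISSING]), counts([1], [5]))

    def test_misaligned_error(self):
        with pytest.raises(ValueError, match="align"):
            rm_log_likelihood(np.array([0, 1]), counts([1], [5]))


class TestAssignmentScores:
    def test_equal_logliks(self):
        s = assignment_scores({"e": -3.0, "w": -3.0})
        assert s["e"] == pytest.approx(50.0) and s["w"] == pytest.approx(50.0)

    def test_ratio_nine_to_one(self):
        s = assignment_scores({"e": math.log(9), "w": 0.0})
        assert s["e"] == pytest.approx(90.0, abs=1e-9)
        assert s["w"] == pytest.approx(10.0, abs=1e-9)

    def test_saturation_without_overflow(self):
        s = assignment_scores({"e": 0.0, "w": -50.0})
        assert s["e"] == pytest.approx(100.0, abs=1e-9)
        s = assignment_scores({"e": 0.0, "w": -1e4})
        assert s["e"] == 100.0 and s["w"] == 0.0

    def test_sum_is_100_and_shift_invariant(self, rng):
        for _ in range(20):
            ll = {k: float(v) for k, v in zip("abc", rng.normal(0, 10, 3))}
            s = assignment_scores(ll)
            assert sum(s.values()) == pytest.approx(100.0, abs=1e-9)
            shifted = assignment_scores({k: v + 123.4 for k, v in ll.items()})
            for k in ll:
                assert shifted[k] == pytest.approx(s[k], abs=1e-9)

    def test_all_neginf_error(self):
        with pytest.raises(ValueError):
            assignment_scores({"e": -math.inf, "w": -math.inf})

    def test_single_baseline_error(self):
        with pytest.raises(ValueError):
            assignment_scores({"e": 0.0})


def _baseline_set(freq_e, freq_w, n=150, lids=None):
    freq_e, freq_w = np.asarray(freq_e), np.asarray(freq_w)
    return BaselineSet(
        ["east", "west"],
        {
            "east": counts((freq_e * 2 * n).astype(int), np.full(freq_e.size, n), lids),
            "west": counts((freq_w * 2 * n).astype(int), np.full(freq_w.size, n), lids),
        },
    )


class TestAssignIndividuals:
    def test_divergent_simulated_east_assigns_east(self, rng):
        pe = np.full(39, 0.9)
        pw = np.full(39, 0.1)
        base = _baseline_set(pe, pw)
        d = rng.binomial(2, pe, size=(50, 39)).astype(np.int8)
        gm = make_gm(d)
        res = assign_individuals(gm, base)
        assert all(r.assigned == "east" for r in res)
        assert np.median([r.score["east"] for r in res]) > 99

    def test_symmetric_individual_ambiguous(self):
        # all-het genotype at loci with mirrored frequencies has exactly
        # equal likelihood under both baselines
        base = _baseline_set(np.array([0.8, 0.2]), np.array([0.2, 0.8]), n=10)
        gm = make_gm([[1, 1]])
        res = assign_individuals(gm, base)
        assert res[0].assigned == "ambiguous"

    def test_zero_usable_loci_flagged(self):
        base = _baseline_set(np.array([0.8]), np.array([0.2]))
        gm = make_gm([[MISSING], [2]])
        res = assign_individuals(gm, base)
        assert res[0].assigned == "unusable" and res[0].n_loci_used == 0
        assert res[1].assigned == "east"

    def test_n_loci_used_counts_missing(self):
        base = _baseline_set(np.array([0.9, 0.9]), np.array([0.1, 0.1]))
        gm = make_gm([[2, MISSING]])
        res = assign_individuals(gm, base)
        assert res[0].n_loci_used == 1


class TestLooSelfAssignment:
    def test_fixed_opposite_alleles_no_misassignment(self):
        east = make_gm(np.full((10, 5), 2, dtype=np.int8), ids=[f"e{i}" for i in range(10)])
        west = make_gm(np.zeros((10, 5), dtype=np.int8), ids=[f"w{i}" for i in range(10)])
        rep = loo_self_assignment({"east": east, "west": west})
        assert rep.per_population.loc["east", "n_misassigned"] == 0
        assert rep.per_population.loc["west", "n_misassigned"] == 0
        assert all(np.isfinite(r.lr_log10) for r in rep.records)

    def test_planted_migrant_misassigns(self):
        # a "west" individual carrying an eastern genotype at strongly
        # divergent loci misassigns; west rate = 1/2
        east = make_gm(np.full((4, 10), 2, dtype=np.int8), ids=[f"e{i}" for i in range(4)])
        west_d = np.zeros((2, 10), dtype=np.int8)
        west_d[1, :] = 2  # genotype copy drawn from east
        west = make_gm(west_d, ids=["w0", "w_migrant"])
        rep = loo_self_assignment({"east": east, "west": west})
        assert rep.per_population.loc["west", "misassignment_rate"] == pytest.approx(0.5)
        assert rep.per_population.loc["east", "n_misassigned"] == 0

    def test_loo_counts_exclude_own_alleles(self):
        # leave-one-out own likelihood must equal the likelihood against
        # counts recomputed from the other individuals only
        d = np.array([[2, 1], [0, 1], [1, 2]], dtype=np.int8)
        east = make_gm(d, ids=["a", "b", "c"])
        west = make_gm(np.zeros((3, 2), dtype=np.int8), ids=["x", "y", "z"])
        rep = loo_self_assignment({"east": east, "west": west})
        rec = next(r for r in rep.records if r.individual_id == "a")
        others = allele_counts(east, subset=["b", "c"])
        from gsikit.assign import rm_log_likelihood

        assert rec.loglik["east"] == pytest.approx(
            rm_log_likelihood(d[0], others), abs=1e-12
        )

    def test_population_of_one_permitted(self):
        east = make_gm(np.full((1, 3), 2, dtype=np.int8), ids=["e0"])
        west = make_gm(np.zeros((4, 3), dtype=np.int8), ids=[f"w{i}" for i in range(4)])
        rep = loo_self_assignment({"east": east, "west": west})
        # the single eastern fish is judged against prior-only own counts
        assert rep.per_population.loc["east", "n"] == 1

    def test_mismatched_loci_error(self):
        a = make_gm([[0]], ids=["a"])
        b = make_gm([[0, 1]], ids=["b"])
        with pytest.raises(ValueError, match="locus"):
            loo_self_assignment({"east": a, "west": b})


class TestLrSummary:
    def _report_with(self, lrs_by_pop):
        from gsikit.assign import PowerRecord, PowerReport
        import pandas as pd

        recs = [
            PowerRecord(f"{pop}{i}", pop, {}, pop, lr)
            for pop, lrs in lrs_by_pop.items()
            for i, lr in enumerate(lrs)
        ]
        return PowerReport(recs, pd.DataFrame(), list(lrs_by_pop))

    def test_constant_ratio(self):
        s, _ = lr_summary(self._report_with({"east": [3.0, 3.0, 3.0]}))
        assert s.loc[0, "geometric_mean_ratio"] == pytest.approx(1000.0)

    def test_log_mean(self):
        s, _ = lr_summary(self._report_with({"east": [1.0, 3.0]}))
        assert s.loc[0, "geometric_mean_ratio"] == pytest.approx(100.0)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            lr_summary(self._report_with({}))
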