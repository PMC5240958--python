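"""Partial Credit Model core: probabilities, gamma functions, conditional
likelihood and estimation, checked against closed forms and brute-force
pattern enumeration."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

import raschpcm as rp
from raschpcm.pcm import _log_gamma_recursion


def brute_force_log_gamma(betas):
    """Enumerate all response patterns; betas: per item cumulative vector."""
    R = sum(len(b) - 1 for b in betas)
    acc = np.zeros(R + 1)
    for pat in itertools.product(*[range(len(b)) for b in betas]):
        r = sum(pat)
        acc[r] += np.exp(-sum(b[x] for b, x in zip(betas, pat)))
    return np.log(acc)


def brute_force_pattern_loglik(scores, betas):
    """Sum over persons of log P(pattern | raw score) by enumeration."""
    total = 0.0
    lg_by_set = brute_force_log_gamma(betas)
    for row in scores:
        r = int(sum(row))
        num = -sum(b[x] for b, x in zip(betas, row))
        total += num - lg_by_set[r]
    return total


def random_item_params(rng, n_items=3, max_m=3):
    ms = rng.integers(1, max_m + 1, size=n_items)
    return rp.ItemParameters(
        thresholds=[rng.normal(0, 1, size=m) for m in ms],
        item_labels=[f"it{j}" for j in range(n_items)],
    )


class TestCategoryProbs:
    def test_symmetric_dichotomous_case(self):
        assert np.allclose(rp.pcm_category_probs(0.0, [0.0]), [0.5, 0.5])

    def test_closed_form_three_categories(self):
        # numerators 1, e^{1.5}, e^{1.0} at theta=0.5, delta=(-1, 1)
        p = rp.pcm_category_probs(0.5, [-1.0, 1.0])
        assert np.allclose(p, [0.1220, 0.5466, 0.3315], atol=5e-5)

    def test_extreme_ability_saturates_top_category(self):
        p = rp.pcm_category_probs(20.0, [0.0, 0.0, 0.0, 0.0])
        assert p[-1] > 0.999

    def test_nonfinite_theta_rejected(self):
        with pytest.raises(rp.InputError):
            rp.pcm_category_probs(np.inf, [0.0])

    def test_normalization_over_random_draws(self, rng):
        for _ in range(1000):
            m = rng.integers(1, 5)
            p = rp.pcm_category_probs(
                rng.normal(0, 3), rng.normal(0, 2, size=m)
            )
            assert abs(p.sum() - 1.0) < 1e-12
            assert np.all(p >= 0)


class TestGammaFunctions:
    def test_single_dichotomous_item(self):
        ip = rp.ItemParameters(thresholds=[[0.0]], item_labels=["a"])
        assert np.allclose(rp.gamma_functions(ip).gamma, [1.0, 1.0])

    def test_two_dichotomous_items_binomial_counts(self):
        ip = rp.ItemParameters(thresholds=[[0.0], [0.0]], item_labels=["a", "b"])
        assert np.allclose(rp.gamma_functions(ip).gamma, [1.0, 2.0, 1.0])

    def test_log_gamma_zero_at_score_zero(self, rng):
        ip = random_item_params(rng)
        assert rp.gamma_functions(ip).log_gamma[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_for_mixed_item_set(self, rng):
        ip = rp.ItemParameters(
            thresholds=[rng.normal(size=2), rng.normal(size=2), rng.normal(size=1)],
            item_labels=["a", "b", "c"],
        )
        lg = rp.gamma_functions(ip).log_gamma
        assert np.max(np.abs(lg - brute_force_log_gamma(ip.cumulative))) < 1e-10

    def test_item_subset_selection_by_label(self, rng):
        ip = random_item_params(rng, n_items=4)
        sub = rp.gamma_functions(ip, item_subset=["it1", "it3"])
        expect = brute_force_log_gamma(
            [ip.cumulative[1], ip.cumulative[3]]
        )
        assert np.allclose(sub.log_gamma, expect, atol=1e-10)


class TestConditionalLoglik:
    def make_responses(self, scores, max_cat):
        scores = np.asarray(scores)
        return rp.ResponseMatrix(
            scores=scores,
            max_cat=np.asarray(max_cat),
            missing_mask=np.zeros_like(scores, dtype=bool),
            person_ids=[str(i) for i in range(len(scores))],
            item_labels=[f"it{j}" for j in range(scores.shape[1])],
        )

    def test_extreme_scores_contribute_zero(self):
        ip = rp.ItemParameters(thresholds=[[0.3]], item_labels=["it0"])
        ip2 = rp.ItemParameters(thresholds=[[0.3], [-0.4]], item_labels=["it0", "it1"])
        # single dichotomous item: every score is extreme
        for s in (0, 1):
            rm = self.make_responses([[s], [1 - s]], [1])
            assert rp.conditional_loglik(rm, ip) == pytest.approx(
                rp.conditional_loglik(
                    self.make_responses([[0], [1]], [1]), ip
                )
            )
        rm = self.make_responses([[0, 0], [1, 1]], [1, 1])
        assert rp.conditional_loglik(rm, ip2) == pytest.approx(0.0, abs=1e-12)

    def test_two_equiprobable_patterns_give_log_half(self):
        ip = rp.ItemParameters(thresholds=[[0.0], [0.0]], item_labels=["it0", "it1"])
        rm = self.make_responses([[1, 0]], [1, 1])
        assert rp.conditional_loglik(rm, ip) == pytest.approx(np.log(0.5))

    def test_matches_enumeration_on_seeded_cohort(self, rng):
        ip = rp.ItemParameters(
            thresholds=[rng.normal(size=m) for m in (2, 3, 1, 2)],
            item_labels=[f"it{j}" for j in range(4)],
        )
        theta = rng.normal(0, 1, size=20)
        scores = np.column_stack(
            [
                [
                    np.searchsorted(
                        rp.pcm_category_probs(t, d).cumsum(), rng.random()
                    )
                    for t in theta
                ]
                for d in ip.thresholds
            ]
        )
        rm = self.make_responses(scores, [2, 3, 1, 2])
        ll = rp.conditional_loglik(rm, ip)
        llb = brute_force_pattern_loglik(scores, ip.cumulative)
        assert ll == pytest.approx(llb, abs=1e-10)

    def test_missing_data_conditions_on_answered_items(self, rng):
        ip = rp.ItemParameters(
            thresholds=[rng.normal(size=2) for _ in range(3)],
            item_labels=["it0", "it1", "it2"],
        )
        scores = np.array([[1, 2, 0], [2, 1, 1]])
        missing = np.array([[False, False, True], [False, False, False]])
        rm = rp.ResponseMatrix(
            scores=scores, max_cat=np.array([2, 2, 2]), missing_mask=missing,
            person_ids=["a", "b"], item_labels=["it0", "it1", "it2"],
        )
        # person a: enumeration over items 0, 1 only
        ll = rp.conditional_loglik(rm, ip)
        part_a = brute_force_pattern_loglik(
            np.array([[1, 2]]), ip.cumulative[:2]
        )
        part_b = brute_force_pattern_loglik(
            np.array([[2, 1, 1]]), ip.cumulative
        )
        assert ll == pytest.approx(part_a + part_b, abs=1e-10)


class TestGammaLogSpaceRecursion:
    def test_structural_zero_categories_are_skipped(self):
        # item with categories {0, 2} only: patterns can't reach odd scores
        lg = _log_gamma_recursion([np.array([0.0, -np.inf, -0.5])])
        assert lg[0] == pytest.approx(0.0)
        assert np.isneginf(lg[1])
        assert lg[2] == pytest.approx(-0.5)


class TestFitCML:
    def test_parameter_recovery_on_fixture(self, null_cohort_1000):
        est = null_cohort_1000.params
        truth = null_cohort_1000.items
        err = np.abs(est.locations - truth.locations)
        assert err.max() < 0.25
        all_delta = np.concatenate(est.thresholds)
        assert abs(all_delta.mean()) < 1e-9  # normalization holds exactly

    def test_convergence_metadata(self, null_cohort_1000):
        meta = null_cohort_1000.meta
        assert meta["converged"]
        assert meta["grad_norm"] <= 1e-8

    def test_symmetric_two_item_locations_mirror(self, rng):
        # symmetric score distribution: swap categories of item 2
        n = 400
        theta = rng.normal(0, 1, n)
        d1, d2 = np.array([-0.7, 0.7]), np.array([-0.7, 0.7])
        x1 = np.array(
            [np.searchsorted(rp.pcm_category_probs(t, d1).cumsum(), rng.random()) for t in theta]
        )
        x2 = 2 - x1  # mirrored responses: exact symmetry
        rm = rp.ResponseMatrix(
            scores=np.column_stack([x1, x2]),
            max_cat=np.array([2, 2]),
            missing_mask=np.zeros((n, 2), dtype=bool),
            person_ids=[str(i) for i in range(n)],
            item_labels=["a", "b"],
        )
        est, _ = rp.fit_cml(rm)
        L = est.locations
        assert L[0] == pytest.approx(-L[1], abs=1e-6)

    def test_item_order_permutation_invariance(self, mixture_cohort):
        resp = mixture_cohort.responses
        rev = resp.subset_items(list(range(resp.n_items))[::-1])
        est_rev, _ = rp.fit_cml(rev)
        orig = mixture_cohort.params
        assert np.allclose(
            est_rev.locations[::-1], orig.locations, atol=1e-6
        )

    def test_rmse_decreases_with_sample_size(self, fixture_items):
        rmses = []
        for n, seed in ((100, 1), (400, 2), (1600, 3)):
            errs = []
            for rep in range(3):
                cfg = rp.SimulationConfig(
                    n_persons=n, ability=("normal", 0, 1), seed=seed * 100 + rep
                )
                resp, _ = rp.simulate_responses(cfg, fixture_items)
                est, _ = rp.fit_cml(resp)
                errs.append(
                    np.concatenate(est.thresholds)
                    - np.concatenate(fixture_items.thresholds)
                )
            rmses.append(float(np.sqrt(np.mean(np.concatenate(errs) ** 2))))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_estimates_invariant_to_ability_location(self, fixture_items):
        # the conditional likelihood never sees theta: cohorts drawn at
        # shifted ability locations recover the same centered thresholds
        ests = []
        for mean in (0.0, 1.2):
            cfg = rp.SimulationConfig(
                n_persons=2000, ability=("normal", mean, 1.0), seed=77
            )
            resp, _ = rp.simulate_responses(cfg, fixture_items)
            est, _ = rp.fit_cml(resp)
            ests.append(est.locations)
        assert np.abs(ests[0] - ests[1]).max() < 0.2

    def test_degenerate_item_refused(self):
        rm = rp.ResponseMatrix(
            scores=np.array([[1, 0], [1, 1], [1, 2]]),
            max_cat=np.array([1, 2]),
            missing_mask=np.zeros((3, 2), dtype=bool),
            person_ids=["a", "b", "c"],
            item_labels=["flat", "ok"],
        )
        with pytest.raises(rp.DegenerateItemError):
            rp.fit_cml(rm)


class TestEstimatePersons:
    def test_symmetric_midpoint_gives_zero_ability(self):
        rm = rp.ResponseMatrix(
            scores=np.array([[1, 1], [0, 1], [2, 1], [1, 0], [1, 2]]),
            max_cat=np.array([2, 2]),
            missing_mask=np.zeros((5, 2), dtype=bool),
            person_ids=list("abcde"),
            item_labels=["x", "y"],
        )
        ip = rp.ItemParameters(
            thresholds=[[-0.5, 0.5], [-0.5, 0.5]], item_labels=["x", "y"]
        )
        pers = rp.estimate_persons(rm, ip)
        assert pers.theta[0] == pytest.approx(0.0, abs=1e-8)
        assert np.all(pers.se[np.isfinite(pers.se)] > 0)

    def test_theta_strictly_increasing_in_raw_score(self, fixture_items):
        n_items = fixture_items.n_items
        scores = []
        for r in range(0, 4 * n_items + 1):
            row = np.zeros(n_items, dtype=int)
            left = r
            for j in range(n_items):
                take = min(4, left)
                row[j] = take
                left -= take
            scores.append(row)
        rm = rp.ResponseMatrix(
            scores=np.array(scores),
            max_cat=fixture_items.max_cat,
            missing_mask=np.zeros((len(scores), n_items), dtype=bool),
            person_ids=[str(i) for i in range(len(scores))],
            item_labels=fixture_items.item_labels,
        )
        pers = rp.estimate_persons(rm, fixture_items)
        assert np.all(np.diff(pers.theta) > 0)
        assert pers.extreme_flag[0] and pers.extreme_flag[-1]
        assert not pers.extreme_flag[1:-1].any()

    def test_ability_recovery_bias_small(self, fixture_items):
        cfg = rp.SimulationConfig(
            n_persons=500, ability=("normal", 0, 1), seed=101
        )
        resp, truth = rp.simulate_responses(cfg, fixture_items)
        est, _ = rp.fit_cml(resp)
        pers = rp.estimate_persons(resp, est)
        ok = ~pers.extreme_flag
        bias = np.mean(pers.theta[ok] - truth["theta"][ok])
        assert abs(bias) < 0.1

    def test_person_answering_nothing_excluded_with_warning(self, fixture_items):
        scores = np.array([[1] * 9, [2] * 9, [0] * 9])
        missing = np.zeros_like(scores, dtype=bool)
        missing[2] = True
        rm = rp.ResponseMatrix(
            scores=scores,
            max_cat=fixture_items.max_cat,
            missing_mask=missing,
            person_ids=["a", "b", "void"],
            item_labels=fixture_items.item_labels,
        )
        with pytest.warns(UserWarning, match="zero items"):
            pers = rp.estimate_persons(rm, fixture_items)
        assert np.isnan(pers.theta[2])
        assert np.isfinite(pers.theta[:2]).all()
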