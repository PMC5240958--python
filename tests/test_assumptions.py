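"""Local independence, unidimensionality (PCA split, subset t-tests,
Martin-Löf) and DIF by residual ANOVA."""

import warnings

import numpy as np
import pandas as pd
import pytest

import raschpcm as rp
from raschpcm.assumptions import (
    dif_anova,
    martin_lof_test,
    pca_residual_split,
    residual_correlations,
    subset_person_ttests,
)
from raschpcm.residuals import standardized_residuals


class TestResidualCorrelations:
    def test_duplicated_item_pair_is_flagged(self, fixture_items):
        cfg = rp.SimulationConfig(n_persons=400, ability=("normal", 0, 1), seed=3)
        resp, _ = rp.simulate_responses(cfg, fixture_items)
        resp.scores[:, 1] = resp.scores[:, 0]  # clone item 0 into item 1
        est, _ = rp.fit_cml(resp)
        pers = rp.estimate_persons(resp, est)
        resid = standardized_residuals(resp, est, pers)
        rep = residual_correlations(resid)
        pair_corr = rep.corr.iloc[0, 1]
        assert pair_corr > 0.9
        flagged = {frozenset(p[:2]) for p in rep.flagged_pairs}
        assert frozenset(resp.item_labels[:2]) in flagged

    def test_diagonal_is_exactly_one(self, null_cohort_1000):
        rep = residual_correlations(null_cohort_1000.resid)
        assert np.allclose(np.diag(rep.corr.to_numpy()), 1.0)

    def test_matrix_symmetric_positive_semidefinite(self, null_cohort_1000):
        rep = residual_correlations(null_cohort_1000.resid)
        c = rep.corr.to_numpy()
        assert np.allclose(c, c.T, atol=1e-12)
        evals = np.linalg.eigvalsh(0.5 * (c + c.T))
        assert evals.min() > -1e-8

    def test_null_cohorts_rarely_flag_any_pair(self, fixture_items):
        flagged = 0
        for seed in range(20):
            cfg = rp.SimulationConfig(
                n_persons=1000, ability=("normal", 0, 1), seed=4000 + seed
            )
            resp, _ = rp.simulate_responses(cfg, fixture_items)
            est, _ = rp.fit_cml(resp)
            pers = rp.estimate_persons(resp, est)
            resid = standardized_residuals(resp, est, pers)
            flagged += bool(residual_correlations(resid).flagged_pairs)
        assert flagged <= 1  # no pair flagged in >= 95% of replicates

    def test_sparse_pair_reported_undefined(self):
        z = np.full((4, 2), np.nan)
        z[:, 0] = [0.1, -0.2, 0.3, 0.0]
        z[0, 1] = 0.5  # only one common person
        res = rp.ResidualMatrix(
            z=z, expected=z, variance=np.abs(z) + 1, kurtosis=np.abs(z) + 1,
            observed=z, person_ids=list("abcd"), item_labels=["x", "y"],
        )
        rep = residual_correlations(res)
        assert ("x", "y") in rep.undefined_pairs


class TestPCASplit:
    def test_two_factor_structure_recovers_blocks(self, fixture_items):
        cfg = rp.SimulationConfig(
            n_persons=1000,
            ability=("normal", 0, 1),
            second_dimension=([5, 6, 7, 8], 0.3),
            seed=21,
        )
        resp, _ = rp.simulate_responses(cfg, fixture_items)
        est, _ = rp.fit_cml(resp)
        pers = rp.estimate_persons(resp, est)
        resid = standardized_residuals(resp, est, pers)
        split = pca_residual_split(resid)
        blocks = (
            set(fixture_items.item_labels[:5]),
            set(fixture_items.item_labels[5:]),
        )
        got = (set(split.subset_A), set(split.subset_B))
        assert got == blocks or got == blocks[::-1]

    def test_constant_loadings_fall_back_to_median_split(self):
        n = 60
        rng = np.random.default_rng(0)
        base = rng.normal(size=n)
        z = np.column_stack([base + 1e-3 * rng.normal(size=n) for _ in range(4)])
        res = rp.ResidualMatrix(
            z=z, expected=z, variance=np.ones_like(z), kurtosis=np.ones_like(z),
            observed=z, person_ids=[str(i) for i in range(n)],
            item_labels=["a", "b", "c", "d"],
        )
        split = pca_residual_split(res)
        assert split.fallback_median_split
        assert split.subset_A and split.subset_B

    def test_split_stable_under_item_permutation(self, null_cohort_1000):
        resid = null_cohort_1000.resid
        split = pca_residual_split(resid)
        perm = np.arange(len(resid.item_labels))[::-1]
        res_p = rp.ResidualMatrix(
            z=resid.z[:, perm],
            expected=resid.expected[:, perm],
            variance=resid.variance[:, perm],
            kurtosis=resid.kurtosis[:, perm],
            observed=resid.observed[:, perm],
            person_ids=resid.person_ids,
            item_labels=[resid.item_labels[i] for i in perm],
        )
        split_p = pca_residual_split(res_p)
        got = {frozenset(split_p.subset_A), frozenset(split_p.subset_B)}
        want = {frozenset(split.subset_A), frozenset(split.subset_B)}
        assert got == want


class TestSubsetTTests:
    def test_identical_subsets_give_zero_statistics(self, mixture_cohort):
        labels = mixture_cohort.responses.item_labels
        out = subset_person_ttests(
            mixture_cohort.responses,
            mixture_cohort.params,
            (labels, labels),
        )
        assert np.allclose(out["t_values"], 0.0)
        assert out["pct_significant"] == 0.0

    def test_null_cohort_supports_unidimensionality(self, null_cohort_1000):
        split = pca_residual_split(null_cohort_1000.resid)
        out = subset_person_ttests(
            null_cohort_1000.responses,
            null_cohort_1000.params,
            (split.subset_A, split.subset_B),
        )
        assert out["pct_significant"] < 9.0
        assert out["supported"]

    def test_second_dimension_breaks_support(self, fixture_items):
        detected = 0
        for seed in range(5):
            cfg = rp.SimulationConfig(
                n_persons=1000,
                ability=("normal", 0, 1),
                second_dimension=([5, 6, 7, 8], 0.3),
                seed=600 + seed,
            )
            resp, _ = rp.simulate_responses(cfg, fixture_items)
            est, _ = rp.fit_cml(resp)
            pers = rp.estimate_persons(resp, est)
            resid = standardized_residuals(resp, est, pers)
            split = pca_residual_split(resid)
            out = subset_person_ttests(resp, est, (split.subset_A, split.subset_B))
            detected += not out["supported"]
        assert detected >= 4


class TestMartinLof:
    def split(self, items):
        return (items.item_labels[:5], items.item_labels[5:])

    def test_statistic_nonnegative_and_label_symmetric(self, mixture_cohort):
        a, b = self.split(mixture_cohort.items)
        r1 = martin_lof_test(mixture_cohort.responses, (a, b), bootstrap=None)
        r2 = martin_lof_test(mixture_cohort.responses, (b, a), bootstrap=None)
        assert r1["statistic"] >= -1e-8
        assert r1["statistic"] == pytest.approx(r2["statistic"], abs=1e-8)
        assert r1["df"] == r2["df"] == 20 * 16 - 1

    def test_duplicated_block_violates_unidimensionality(self, fixture_items):
        cfg = rp.SimulationConfig(n_persons=600, ability=("normal", 0, 1), seed=13)
        resp, _ = rp.simulate_responses(cfg, fixture_items)
        # subset B echoes subset A's responses: strong cross-subset dependence
        resp.scores[:, 5:9] = resp.scores[:, 0:4]
        out = martin_lof_test(
            resp, self.split(fixture_items), bootstrap=99, seed=5
        )
        assert out["p_value"] <= 0.05

    def test_subsets_must_partition_items(self, mixture_cohort):
        labels = mixture_cohort.responses.item_labels
        with pytest.raises(rp.InputError, match="partition"):
            martin_lof_test(
                mixture_cohort.responses, (labels[:3], labels[2:]), bootstrap=None
            )

    def test_incomplete_persons_dropped_listwise(self, mixture_cohort):
        resp = mixture_cohort.responses.subset_persons(
            np.arange(mixture_cohort.responses.n_persons)
        )
        resp.missing_mask[0, 0] = True
        out = martin_lof_test(resp, self.split(mixture_cohort.items), bootstrap=None)
        assert out["n_dropped_incomplete"] == 1
        assert out["n_persons"] == resp.n_persons - 1


class TestDIFAnova:
    def test_random_groups_rarely_flagged(self, fixture_items):
        flagged_reps = 0
        for seed in range(10):
            cfg = rp.SimulationConfig(
                n_persons=500, ability=("normal", 0, 1), seed=7000 + seed
            )
            resp, _ = rp.simulate_responses(cfg, fixture_items)
            est, _ = rp.fit_cml(resp)
            pers = rp.estimate_persons(resp, est)
            resid = standardized_residuals(resp, est, pers)
            table = dif_anova(resid, pers, resp.covariates["sex"].to_numpy())
            flagged_reps += bool(table.flagged_items())
        assert flagged_reps <= 1

    def test_injected_threshold_shift_is_flagged(self, fixture_items):
        cfg = rp.SimulationConfig(
            n_persons=1000, ability=("normal", 0, 1), dif=(2, 0.8), seed=31
        )
        resp, _ = rp.simulate_responses(cfg, fixture_items)
        est, _ = rp.fit_cml(resp)
        pers = rp.estimate_persons(resp, est)
        resid = standardized_residuals(resp, est, pers)
        table = dif_anova(resid, pers, resp.covariates["group"].to_numpy())
        assert fixture_items.item_labels[2] in table.flagged_items()

    def test_flags_invariant_to_group_relabeling(self, fixture_items):
        cfg = rp.SimulationConfig(
            n_persons=600, ability=("normal", 0, 1), dif=(4, 0.8), seed=37
        )
        resp, _ = rp.simulate_responses(cfg, fixture_items)
        est, _ = rp.fit_cml(resp)
        pers = rp.estimate_persons(resp, est)
        resid = standardized_residuals(resp, est, pers)
        g = resp.covariates["group"].to_numpy()
        t1 = dif_anova(resid, pers, g)
        relabeled = np.where(g == 0, "beta", "alpha")
        t2 = dif_anova(resid, pers, relabeled)
        assert t1.flagged_items() == t2.flagged_items()
        assert np.allclose(
            t1.table["F_main"].to_numpy(), t2.table["F_main"].to_numpy()
        )

    def test_single_stratum_reduces_to_one_way(self, null_cohort_1000):
        table = dif_anova(
            null_cohort_1000.resid,
            null_cohort_1000.persons,
            null_cohort_1000.responses.covariates["sex"].to_numpy(),
            n_strata=1,
        )
        assert table.table["F_interaction"].isna().all()
        assert table.table["F_main"].notna().all()

    def test_two_level_requirement(self, null_cohort_1000):
        with pytest.raises(rp.InputError, match="2 levels"):
            dif_anova(
                null_cohort_1000.resid,
                null_cohort_1000.persons,
                np.zeros(null_cohort_1000.responses.n_persons),
            )
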