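"""Differential-expression stage: filter arithmetic, TMM contracts, the
log-CPM transform, moderation limits, threshold strictness, and the BH
step-up property against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cerna_moml import diffexpr
from cerna_moml.formats_io import CountsMatrix
from cerna_moml.synthetic_data import SimulationConfig, simulate_cohort


def _counts(values, groups=None, classes=None):
    values = np.asarray(values)
    n_feat, n_samp = values.shape
    fids = [f"G{i}" for i in range(n_feat)]
    sids = [f"S{j}" for j in range(n_samp)]
    if groups is None:
        half = n_samp // 2
        groups = ["tumour"] * half + ["normal"] * (n_samp - half)
    return CountsMatrix(
        pd.DataFrame(values, index=fids, columns=sids),
        pd.Series(groups, index=sids),
        pd.Series(classes or ["mRNA"] * n_feat, index=fids),
    )


class TestLowExpressedFilter:
    def test_all_zero_feature_dropped(self):
        cm = _counts([[0, 0, 0, 0], [10_000, 10_000, 10_000, 10_000],
                      [990_000, 990_000, 990_000, 990_000]])
        kept = diffexpr.filter_low_expressed(cm)
        assert "G0" not in kept.feature_ids

    def test_boundary_half_low_is_kept(self):
        # lib ~1e6 per sample: G0 has CPM ~200 in S0/S1 (log2 ~7.6) and
        # CPM ~0.5 in S2/S3 (log2 ~ -1): low in exactly 2 of 4 = 50%,
        # which is not *more than* half, so it stays.  G1 is low in 3/4.
        filler = [999_800, 999_800, 1_000_000, 1_000_000]
        cm = _counts([[200, 200, 0, 0], [200, 0, 0, 0], filler])
        kept = diffexpr.filter_low_expressed(cm)
        assert "G0" in kept.feature_ids
        assert "G1" not in kept.feature_ids

    def test_high_count_matrix_unchanged(self):
        cm = _counts(np.full((5, 4), 1000))
        kept = diffexpr.filter_low_expressed(cm)
        assert kept.feature_ids == cm.feature_ids

    def test_empty_after_filtering_errors(self):
        # each feature is expressed in exactly one of 4 samples, hence
        # below threshold in 75% of them
        cm = _counts((np.eye(4, dtype=int) * 1_000_000))
        with pytest.raises(ValueError, match="empty after filtering"):
            diffexpr.filter_low_expressed(cm)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = np.random.default_rng(0).integers(10, 1000, size=50)
        cm = _counts(np.column_stack([col] * 4))
        f = diffexpr.tmm_factors(cm)
        np.testing.assert_allclose(f.to_numpy(), 1.0, atol=1e-12)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        # sample B = 2 x sample A elementwise: all M-values are 0 after
        # library-size scaling, so both factors are exactly 1
        col = np.random.default_rng(1).integers(10, 1000, size=50)
        cm = _counts(np.column_stack([col, 2 * col]),
                     groups=["tumour", "normal"])
        f = diffexpr.tmm_factors(cm)
        np.testing.assert_allclose(f.to_numpy(), 1.0, atol=1e-12)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(2)
        cm = _counts(rng.integers(0, 500, size=(200, 4)))
        f = diffexpr.tmm_factors(cm).to_numpy()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_zero_library_errors(self):
        cm = _counts([[0, 5], [0, 7]], groups=["tumour", "normal"])
        with pytest.raises(ValueError, match="zero library"):
            diffexpr.tmm_factors(cm)


class TestVoom:
    def test_logcpm_formula(self):
        # one sample with library exactly 1e6 and a zero count:
        # log2(0.5 / (1e6 + 1) * 1e6)
        vals = np.full((12, 2), 100)
        vals[0, 0] = 0
        vals[1, 0] = 1_000_000 - 100 * 10  # library of sample 0 sums to 1e6
        cm = _counts(vals, groups=["tumour", "normal"])
        ones = pd.Series(1.0, index=cm.sample_ids)
        norm = diffexpr.voom_transform(cm, ones, weight_mode="none")
        expected = np.log2(0.5 / (1e6 + 1.0) * 1e6)
        assert norm.matrix.iloc[0, 0] == pytest.approx(expected, abs=1e-12)
        assert (norm.weights.to_numpy() == 1.0).all()

    def test_scale_invariance_of_logcpm(self):
        # counts large enough that the 0.5 prior is negligible
        rng = np.random.default_rng(3)
        vals = rng.integers(100_000, 1_000_000, size=(50, 4))
        cm1, cm2 = _counts(vals), _counts(2 * vals)
        ones = pd.Series(1.0, index=cm1.sample_ids)
        n1 = diffexpr.voom_transform(cm1, ones, weight_mode="none")
        n2 = diffexpr.voom_transform(cm2, ones, weight_mode="none")
        np.testing.assert_allclose(n1.matrix, n2.matrix, atol=1e-5)

    def test_few_features_fall_back_with_warning(self):
        cm = _counts(np.full((4, 4), 500))
        with pytest.warns(UserWarning, match="fewer than 10"):
            norm = diffexpr.voom_transform(cm, pd.Series(1.0, index=cm.sample_ids))
        assert (norm.weights.to_numpy() == 1.0).all()


class TestModeratedT:
    @staticmethod
    def _norm(vals, groups):
        cm = _counts(np.asarray(vals, dtype=int), groups=groups)
        return diffexpr.NormalizedExpression(
            cm.values.astype(float),
            cm.values.astype(float) * 0 + 1.0,
            pd.Series(1.0, index=cm.sample_ids)), cm.group

    def test_no_moderation_equals_ordinary_t(self):
        rng = np.random.default_rng(4)
        vals = rng.integers(1, 200, size=(30, 12))
        norm, groups = self._norm(vals, ["tumour"] * 6 + ["normal"] * 6)
        res = diffexpr.moderated_t(norm, groups, d0=0)
        y = norm.matrix.to_numpy().astype(float)
        t_ref = stats.ttest_ind(y[:, :6], y[:, 6:], axis=1, equal_var=True)
        np.testing.assert_allclose([r.t_mod for r in res], t_ref.statistic,
                                   atol=1e-10)
        np.testing.assert_allclose([r.p for r in res], t_ref.pvalue, atol=1e-10)

    def test_infinite_prior_pools_completely(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(1, 200, size=(30, 10))
        norm, groups = self._norm(vals, ["tumour"] * 5 + ["normal"] * 5)
        res0 = diffexpr.moderated_t(norm, groups, d0=np.inf)
        # with complete pooling every feature uses the same variance, so
        # t is proportional to logFC
        t = np.array([r.t_mod for r in res0])
        lfc = np.array([r.log_fc for r in res0])
        ratio = t[lfc != 0] / lfc[lfc != 0]
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-10)

    def test_identical_group_means_zero_logfc(self):
        vals = np.tile([[10, 20, 10, 20]], (12, 1))
        norm, groups = self._norm(vals, ["tumour", "tumour", "normal", "normal"])
        res = diffexpr.moderated_t(norm, groups, d0=0)
        assert all(r.log_fc == 0 for r in res)

    def test_single_sample_groups_error(self):
        norm, groups = self._norm([[1, 2]], ["tumour", "normal"])
        with pytest.raises(ValueError, match="residual degrees"):
            diffexpr.moderated_t(norm, groups)


class TestSelectDe:
    def _results(self, rows):
        return [diffexpr.DEResult(f"G{i}", lfc, 0.0, p, p, False)
                for i, (lfc, p) in enumerate(rows)]

    def test_strictness_and_absolute_value(self):
        classes = pd.Series(["mRNA", "miRNA", "lncRNA"],
                            index=["G0", "G1", "G2"])
        res = self._results([(1.0, 0.005), (-1.2, 0.005), (2.0, 0.01)])
        de = diffexpr.select_de(res, classes)
        assert de["mRNA"] == set()          # logFC exactly 1: not > 1
        assert de["miRNA"] == {"G1"}        # |-1.2| passes
        assert de["lncRNA"] == set()        # fdr exactly 0.01: not < 0.01

    def test_all_null_gives_empty_sets(self):
        classes = pd.Series(["mRNA", "mRNA"], index=["G0", "G1"])
        de = diffexpr.select_de(self._results([(3.0, 1.0), (2.0, 1.0)]), classes)
        assert all(not v for v in de.values())


def _bh_oracle(p):
    """Brute-force BH step-up: find the largest k with p_(k) <= k/m * q by
    direct cumulative minima from the back."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
def test_bh_matches_step_up_oracle(pvals):
    adj = diffexpr.bh_adjust(np.array(pvals))
    np.testing.assert_allclose(adj, _bh_oracle(pvals), atol=1e-12)
    assert ((adj >= 0) & (adj <= 1)).all()
    order = np.argsort(pvals, kind="mergesort")
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_planted_fold_change_recovered_at_paper_thresholds():
    """NB counts with planted log2FC=2 at 30+30: nearly all planted
    features pass |logFC|>1 & FDR<0.01 and nulls rarely do."""
    n_pl = n_pl_pass = n_null = n_null_pass = 0
    for seed in (11, 12, 13):
        c = simulate_cohort(SimulationConfig(seed=seed, n_tumour=30,
                                             n_normal=30, nb_mean_log2fc=2.0))
        f = diffexpr.filter_low_expressed(c.counts)
        norm = diffexpr.voom_transform(f)
        res = diffexpr.moderated_t(norm, f.group)
        called = {r.feature_id for r in res if r.passed}
        planted = c.truth.de_features & set(f.feature_ids)
        nulls = set(f.feature_ids) - c.truth.de_features
        n_pl += len(planted)
        n_pl_pass += len(called & planted)
        n_null += len(nulls)
        n_null_pass += len(called & nulls)
    assert n_pl_pass / n_pl >= 0.9
    assert n_null_pass / max(1, n_null) <= 0.05
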