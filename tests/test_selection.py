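"""Correlation screen and feature-group assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import epichannel as ec
from epichannel.features import FEATURE_NAMES

SIGNIFICANT = ("theta", "alpha", "beta", "mean", "min", "skew", "kurt")
CORE = ("mean", "min", "skew", "kurt")


def screening_fixture(n=400, seed=0):
    """A 15-feature table engineered to the clinical screening structure:
    seven label-significant features, a {theta, alpha, beta} block with
    pairwise |r| >= 0.8, and a mutually near-uncorrelated core of
    {mean, min, skew, kurt}.  The eight remaining features are noise
    centred within each class, so their label association is exactly 0.
    """
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    z = rng.standard_normal(n) + 1.0 * y  # shared band-power factor
    cols = {}
    for name in ("theta", "alpha", "beta"):
        cols[name] = z + 0.3 * rng.standard_normal(n)
    for name in CORE:
        cols[name] = rng.standard_normal(n) + 0.5 * y
    for name in FEATURE_NAMES:
        if name not in cols:
            noise = rng.standard_normal(n)
            for cls in (0, 1):  # exact zero point-biserial correlation
                noise[y == cls] -= noise[y == cls].mean()
            cols[name] = noise
    table = pd.DataFrame({name: cols[name] for name in FEATURE_NAMES})
    return table, y


class TestCorrelationScreen:
    def test_duplicated_feature_perfectly_correlated(self, rng):
        x = rng.normal(size=100)
        table = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        rep = ec.correlation_screen(table, rng.integers(0, 2, size=100))
        i, j = rep.feature_names.index("a"), rep.feature_names.index("b")
        assert rep.r[i, j] == pytest.approx(1.0)
        assert rep.p[i, j] == pytest.approx(0.0, abs=1e-12)

    def test_matrix_invariants(self):
        table, y = screening_fixture()
        rep = ec.correlation_screen(table, y)
        np.testing.assert_allclose(np.diag(rep.r), 1.0)
        np.testing.assert_allclose(rep.r, rep.r.T, atol=1e-12)
        assert np.all((rep.p >= 0) & (rep.p <= 1))
        assert np.all((rep.class_p >= 0) & (rep.class_p <= 1))

    def test_null_features_rarely_significant(self):
        """Two independent Gaussian columns: |r| < 0.1 and p > 0.01 in
        at least 95% of 100 seeds at n = 1000."""
        hits = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            table = pd.DataFrame(
                {"a": g.normal(size=1000), "b": g.normal(size=1000)}
            )
            rep = ec.correlation_screen(table, g.integers(0, 2, size=1000))
            i, j = 0, 1
            hits += abs(rep.r[i, j]) < 0.1 and rep.p[i, j] > 0.01
        assert hits >= 95

    def test_separable_feature_has_tiny_class_p(self, rng):
        x = rng.normal(size=200)
        y = (x > 0).astype(int)
        table = pd.DataFrame({"sep": x, "noise": rng.normal(size=200)})
        rep = ec.correlation_screen(table, y)
        assert rep.class_p[0] < 1e-6

    def test_agrees_with_scipy_oracle(self, rng):
        """r and p match per-pair pearsonr on a small table."""
        table = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        rep = ec.correlation_screen(table, rng.integers(0, 2, size=30))
        for i in range(4):
            for j in range(i + 1, 4):
                r_ref, p_ref = stats.pearsonr(
                    table.iloc[:, i], table.iloc[:, j]
                )
                assert rep.r[i, j] == pytest.approx(r_ref, rel=1e-9)
                assert rep.p[i, j] == pytest.approx(p_ref, rel=1e-6)

    def test_constant_column_rejected_by_name(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=50), "flat": np.ones(50)})
        with pytest.raises(ValueError, match="flat"):
            ec.correlation_screen(table, rng.integers(0, 2, size=50))

    def test_too_few_rows_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError, match="3 rows"):
            ec.correlation_screen(table, [0, 1])


class TestBuildFeatureGroups:
    def test_clinical_structure_yields_three_groups(self):
        """The engineered screen reproduces the published outcome: three
        5-feature groups, {mean,min,skew,kurt} plus one band power."""
        table, y = screening_fixture()
        rep = ec.correlation_screen(table, y)
        kept = {
            n for n, p in zip(rep.feature_names, rep.class_p) if p < 0.05
        }
        assert kept == set(SIGNIFICANT)
        groups = ec.build_feature_groups(rep)
        assert len(groups) == 3
        members = [set(g.members) for g in groups]
        for band in ("theta", "alpha", "beta"):
            assert set(CORE) | {band} in members

    def test_no_cluster_gives_single_group_of_five(self, rng):
        n = 500
        y = np.repeat([0, 1], n // 2)
        table = pd.DataFrame(
            {
                f"f{i}": rng.standard_normal(n) + 0.6 * y
                for i in range(5)
            }
        )
        rep = ec.correlation_screen(table, y)
        groups = ec.build_feature_groups(rep)
        assert len(groups) == 1
        assert set(groups[0].members) == {f"f{i}" for i in range(5)}

    def test_two_member_cluster_gives_two_groups(self, rng):
        n = 600
        y = np.repeat([0, 1], n // 2)
        z = rng.standard_normal(n) + 1.0 * y
        cols = {
            "c1": z + 0.2 * rng.standard_normal(n),
            "c2": z + 0.2 * rng.standard_normal(n),
        }
        for i in range(4):
            cols[f"u{i}"] = rng.standard_normal(n) + 0.5 * y
        rep = ec.correlation_screen(pd.DataFrame(cols), y)
        groups = ec.build_feature_groups(rep)
        assert len(groups) == 2
        assert all(len(g.members) == 5 for g in groups)
        core = set.intersection(*(set(g.members) for g in groups))
        assert core == {f"u{i}" for i in range(4)}

    def test_threshold_monotonicity(self):
        """Raising low_thr never shrinks the core; raising high_thr never
        grows the cluster."""
        table, y = screening_fixture()
        rep = ec.correlation_screen(table, y)

        def core_and_cluster(low, high):
            groups = ec.build_feature_groups(rep, low_thr=low, high_thr=high)
            member_sets = [set(g.members) for g in groups]
            core = set.intersection(*member_sets)
            cluster = set.union(*member_sets) - core
            return core, cluster

        core_a, cluster_a = core_and_cluster(0.20, 0.80)
        core_b, cluster_b = core_and_cluster(0.30, 0.80)
        assert core_a <= core_b

        # cluster monotonicity checked on the clique finder directly:
        # a stricter high threshold can only shrink the mutual cluster
        from epichannel.selection import _largest_mutual_cluster

        names = list(rep.feature_names)
        base = _largest_mutual_cluster(names, rep.r, 0.80)
        for stricter in (0.90, 0.95, 0.99):
            assert len(_largest_mutual_cluster(names, rep.r, stricter)) <= len(base)

    def test_too_few_significant_features_rejected(self, rng):
        n = 200
        y = np.repeat([0, 1], n // 2)
        table = pd.DataFrame(
            {f"f{i}": rng.standard_normal(n) for i in range(3)}
        )
        # center within class so nothing is significant
        for c in table.columns:
            for cls in (0, 1):
                table.loc[y == cls, c] -= table.loc[y == cls, c].mean()
        rep = ec.correlation_screen(table, y)
        with pytest.raises(ValueError, match="label-significant"):
            ec.build_feature_groups(rep)
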