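import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigmap import (
    PreprocessConfig,
    SimulationConfig,
    apply_noise_floor,
    collapse_probes_to_genes,
    merge_on_common_features,
    merge_orthologs,
    quantile_normalize,
    remove_principal_components,
    simulate_compendium,
)
from sigmap.io import Compendium, OrthologTable

from conftest import make_compendium


def _with_genes(comp, genes):
    values = comp.values.copy()
    values.index = genes
    return Compendium(values=values, samples=comp.samples, scale=comp.scale)


class TestMerge:
    def test_feature_intersection(self):
        rng = np.random.default_rng(0)
        a = make_compendium(rng.normal(6, 1, (3, 2)), cell_types=["T", "T"])
        a = _with_genes(a, ["A", "B", "C"])
        b = make_compendium(rng.normal(6, 1, (3, 2)), cell_types=["T", "T"], datasets=["ds2"] * 2)
        b.values.columns = ["t00", "t01"]
        b.samples.index = ["t00", "t01"]
        b = Compendium(values=b.values, samples=b.samples, scale="log2")
        b = _with_genes(b, ["B", "C", "D"])
        merged = merge_on_common_features([a, b])
        assert list(merged.values.index) == ["B", "C"]
        assert merged.n_samples == 4
        assert set(merged.samples["dataset_id"]) == {"ds1", "ds2"}

    def test_disjoint_features_error(self):
        rng = np.random.default_rng(1)
        a = _with_genes(make_compendium(rng.normal(6, 1, (2, 2))), ["A", "B"])
        b = make_compendium(rng.normal(6, 1, (2, 2)), datasets=["ds2"] * 2)
        b.values.columns = ["t00", "t01"]
        b.samples.index = ["t00", "t01"]
        b = _with_genes(Compendium(values=b.values, samples=b.samples, scale="log2"), ["C", "D"])
        with pytest.raises(ValueError, match="intersection"):
            merge_on_common_features([a, b])

    def test_no_anchor_warns(self):
        rng = np.random.default_rng(2)
        a = make_compendium(rng.normal(6, 1, (3, 2)), cell_types=["X", "X"])
        b = make_compendium(rng.normal(6, 1, (3, 2)), cell_types=["Y", "Y"], datasets=["ds2"] * 2)
        b.values.columns = ["t00", "t01"]
        b.samples.index = ["t00", "t01"]
        b = Compendium(values=b.values, samples=b.samples, scale="log2")
        with pytest.warns(UserWarning, match="anchor"):
            merge_on_common_features([a, b])


class TestNoiseFloor:
    def test_floor_then_log2(self):
        comp = make_compendium([[2.0], [5.0], [8.0]], scale="linear")
        out = apply_noise_floor(comp, threshold=5.0)
        np.testing.assert_allclose(
            out.values.to_numpy().ravel(), [np.log2(5), np.log2(5), 3.0], atol=1e-4
        )
        assert out.scale == "log2"
        assert out.values.to_numpy().min() == pytest.approx(np.log2(5))

    def test_above_threshold_is_pure_log2(self):
        vals = np.array([[6.0, 32.0], [1024.0, 7.5]])
        comp = make_compendium(vals, scale="linear")
        out = apply_noise_floor(comp, threshold=5.0)
        np.testing.assert_allclose(out.values.to_numpy(), np.log2(vals))

    def test_double_transform_guard(self):
        comp = make_compendium([[6.0, 7.0]], scale="log2")
        with pytest.raises(ValueError, match="linear"):
            apply_noise_floor(comp, 5.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1e6), min_size=2, max_size=8), st.floats(0.1, 100))
    def test_monotone(self, values, threshold):
        comp = make_compendium(np.array(values)[:, None].repeat(2, axis=1), scale="linear")
        out = apply_noise_floor(comp, threshold)
        order_in = np.argsort(np.asarray(values), kind="stable")
        col = out.values.to_numpy()[:, 0]
        assert np.all(np.diff(col[order_in]) >= -1e-12)


class TestQuantileNormalize:
    def test_per_rank_means(self):
        comp = make_compendium(np.array([[1, 4], [2, 5], [3, 6]], dtype=float))
        out = quantile_normalize(comp)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_identical_distributions_fixed_point(self):
        col = np.array([1.0, 5.0, 3.0])
        comp = make_compendium(np.column_stack([col, col[::-1]]))
        out = quantile_normalize(comp)
        np.testing.assert_allclose(out.values.to_numpy(), comp.values.to_numpy())

    def test_tie_rules_on_three_row_case(self):
        # hand enumeration: sorted cols [1,1,2] and [3,4,5]; reference
        # per-rank means [2, 2.5, 3.5]
        comp = make_compendium(np.array([[1, 3], [1, 4], [2, 5]], dtype=float))
        ordinal = quantile_normalize(comp, ties="ordinal")
        np.testing.assert_allclose(
            ordinal.values.to_numpy(), [[2.0, 2.0], [2.5, 2.5], [3.5, 3.5]]
        )
        averaged = quantile_normalize(comp, ties="average")
        np.testing.assert_allclose(
            averaged.values.to_numpy(), [[2.25, 2.0], [2.25, 2.5], [3.5, 3.5]]
        )

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(3)
        X = rng.normal(6, 2, (40, 5))
        out = quantile_normalize(make_compendium(X)).values.to_numpy()
        for j in range(5):
            assert np.array_equal(
                np.argsort(X[:, j], kind="stable"), np.argsort(out[:, j], kind="stable")
            )

    def test_single_sample_error(self):
        with pytest.raises(ValueError):
            quantile_normalize(make_compendium([[1.0], [2.0]]))


class TestRemovePrincipalComponents:
    def _planted(self, rng, n_genes=30, per_ds=4):
        """gene means + exact rank-1 dataset shift."""
        means = rng.normal(6, 1, (n_genes, 1))
        shift = rng.normal(0, 2, (n_genes, 1))
        membership = np.array([0.0] * per_ds + [1.0] * per_ds)[None, :]
        X = means + shift * membership
        return make_compendium(
            X, datasets=["d1"] * per_ds + ["d2"] * per_ds,
            cell_types=["T"] * (2 * per_ds),
        )

    def test_empty_pcs_is_identity(self):
        comp = make_compendium(np.random.default_rng(0).normal(6, 1, (5, 4)))
        out = remove_principal_components(comp, set())
        assert out.values.equals(comp.values)

    def test_planted_rank1_batch_removed(self):
        rng = np.random.default_rng(4)
        comp = self._planted(rng)
        out = remove_principal_components(comp, {1})
        by_ds = out.values.T.groupby(out.samples["dataset_id"].to_numpy()).mean()
        np.testing.assert_allclose(
            by_ds.iloc[0].to_numpy(), by_ds.iloc[1].to_numpy(), atol=1e-9
        )

    def test_variance_removed_equals_leading_share(self):
        rng = np.random.default_rng(5)
        X = rng.normal(6, 1, (20, 8))
        comp = make_compendium(X)
        Xc = X - X.mean(axis=1, keepdims=True)
        s = np.linalg.svd(Xc, compute_uv=False)
        out = remove_principal_components(comp, {1})
        Yc = out.values.to_numpy() - out.values.to_numpy().mean(axis=1, keepdims=True)
        removed = (Xc**2).sum() - (Yc**2).sum()
        assert removed == pytest.approx(s[0] ** 2, rel=1e-9)
        assert out.meta["variance_removed_fraction"][1] == pytest.approx(
            s[0] ** 2 / (s**2).sum()
        )

    def test_idempotent_on_planted_structure(self):
        rng = np.random.default_rng(6)
        comp = self._planted(rng)
        once = remove_principal_components(comp, {1})
        twice = remove_principal_components(once, {1})
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-9
        )

    def test_index_beyond_components_errors(self):
        comp = make_compendium(np.random.default_rng(0).normal(6, 1, (5, 3)))
        with pytest.raises(ValueError, match="exceeds"):
            remove_principal_components(comp, {3})  # only 2 components exist

    def test_silhouette_batch_down_celltype_kept(self):
        """Planted batch (SD >= 5x noise) stops dominating sample structure."""
        from sklearn.metrics import silhouette_score

        from sigmap.explore import pca

        cfg = SimulationConfig(seed=9)
        comps, _, _ = simulate_compendium(cfg)
        comp = comps["mouse"]

        def silhouettes(c):
            scores = pca(c).scores.to_numpy()[:, :5]
            return (
                silhouette_score(scores, c.samples["dataset_id"]),
                silhouette_score(scores, c.samples["cell_type"]),
            )

        ds_before, ct_before = silhouettes(comp)
        corrected = remove_principal_components(quantile_normalize(comp), {1})
        ds_after, ct_after = silhouettes(corrected)
        assert ds_after < ds_before
        assert ct_after >= ct_before - 0.05


class TestCollapseAndOrthologs:
    def test_collapse_rules(self):
        comp = make_compendium(np.array([[1.0, 2.0], [9.0, 4.0], [2.0, 3.0]]))
        probe_map = {"g000": "GENE", "g001": "GENE", "g002": "GENE"}
        kept = collapse_probes_to_genes(comp, probe_map, rule="max_mean")
        # probe g001 has the largest mean (6.5)
        np.testing.assert_allclose(kept.values.loc["GENE"].to_numpy(), [9.0, 4.0])
        med = collapse_probes_to_genes(comp, probe_map, rule="median")
        np.testing.assert_allclose(med.values.loc["GENE"].to_numpy(), [2.0, 3.0])

    def test_collapse_single_probe_relabels(self):
        comp = make_compendium(np.array([[1.0, 2.0]]))
        out = collapse_probes_to_genes(comp, {"g000": "X"}, rule="max_mean")
        assert list(out.values.index) == ["X"]
        np.testing.assert_allclose(out.values.to_numpy(), comp.values.to_numpy())

    def test_merge_orthologs(self):
        rng = np.random.default_rng(7)
        a = make_compendium(rng.normal(6, 1, (3, 2)), species="human")
        a = Compendium(
            values=a.values.set_axis(["hA", "hB", "hC"], axis=0),
            samples=a.samples, scale="log2",
        )
        b = make_compendium(rng.normal(6, 1, (2, 2)), species="mouse", datasets=["m1"] * 2)
        b.values.columns = ["t00", "t01"]
        b.samples.index = ["t00", "t01"]
        b = Compendium(
            values=b.values.set_axis(["mA", "mB"], axis=0), samples=b.samples, scale="log2"
        )
        table = OrthologTable(pairs=[("hA", "mA"), ("hB", "mB"), ("hC", "mZ")])
        merged = merge_orthologs(a, b, table)
        assert list(merged.values.index) == ["hA|mA", "hB|mB"]
        assert merged.n_samples == 4
        assert merged.meta["n_ortholog_pairs_dropped"] == 1
        assert set(merged.samples["species"]) == {"human", "mouse"}

    def test_merge_orthologs_none_survive(self):
        rng = np.random.default_rng(8)
        a = make_compendium(rng.normal(6, 1, (1, 2)))
        b = make_compendium(rng.normal(6, 1, (1, 2)))
        table = OrthologTable(pairs=[("x", "y")])
        with pytest.raises(ValueError):
            merge_orthologs(a, b, table)
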