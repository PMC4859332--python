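"""Compendium preprocessing: merging, noise flooring, quantile cross-normalization,
principal-component dataset-effect removal, probe collapse and ortholog merging.

The intended order for multi-dataset intensity data is: per-dataset load ->
(linear data) noise floor + log2 -> merge on common features -> quantile
normalize -> principal-component removal. Already-log2 datasets skip the
flooring step. :func:`run_preprocessing` wires the steps together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Compendium, OrthologTable


@dataclass
class PreprocessConfig:
    """Preprocessing knobs.

    noise_threshold
        Linear-scale intensity floor; values below it are raised to it before
        the log2 transform. Default 5, the floor estimated from the density of
        expression signals on the arrays this pipeline was built around.
    pcs_to_remove
        1-based principal-component indices whose reconstruction is subtracted
        from the merged matrix (dataset-effect removal). Chosen by inspection,
        not auto-detected; typically {1}, sometimes {1, 2}.
    collapse_rule
        Probe-to-gene collapse: ``max_mean`` keeps the probe with the largest
        mean, ``median`` takes per-sample medians over a gene's probes.
    """

    noise_threshold: float = 5.0
    pcs_to_remove: frozenset = frozenset({1})
    collapse_rule: str = "max_mean"

    def __post_init__(self) -> None:
        if self.noise_threshold <= 0:
            raise ValueError("noise_threshold must be > 0")
        if self.collapse_rule not in ("max_mean", "median"):
            raise ValueError("collapse_rule must be 'max_mean' or 'median'")
        if any(int(p) < 1 for p in self.pcs_to_remove):
            raise ValueError("pcs_to_remove indices are 1-based and must be >= 1")


def merge_on_common_features(compendia: Sequence[Compendium]) -> Compendium:
    """Merge compendia on the exact intersection of their feature ids.

    Requires at least two compendia of the same species and scale. Emits a
    warning (not an error) if no cell type is shared by every compendium —
    without an anchor population, downstream dataset-effect correction is
    uninterpretable.
    """
    if len(compendia) < 2:
        raise ValueError("need at least two compendia to merge")
    scales = {c.scale for c in compendia}
    if len(scales) != 1:
        raise ValueError(f"cannot merge compendia with mixed scales {scales}")
    species = set().union(*(c.species_set() for c in compendia))
    if len(species) != 1:
        raise ValueError(f"cannot merge compendia from different species {species}")
    common_set = set(compendia[0].genes)
    for c in compendia[1:]:
        common_set &= set(c.genes)
    common = [g for g in compendia[0].genes if g in common_set]
    if not common:
        raise ValueError("empty feature intersection: compendia share no features")
    anchor = set(compendia[0].cell_types())
    for c in compendia[1:]:
        anchor &= set(c.cell_types())
    if not anchor:
        warnings.warn(
            "no cell type is shared by all merged compendia (no anchor population)",
            stacklevel=2,
        )
    values = pd.concat([c.values.loc[common] for c in compendia], axis=1)
    samples = pd.concat([c.samples for c in compendia], axis=0)
    merged = Compendium(values=values, samples=samples, scale=compendia[0].scale)
    merged.meta["anchor_cell_types"] = sorted(anchor)
    merged.meta["n_features_dropped"] = sum(c.n_genes for c in compendia) - len(common) * len(
        compendia
    )
    return merged


def apply_noise_floor(compendium: Compendium, threshold: float = 5.0) -> Compendium:
    """Floor linear intensities at ``threshold`` and log2-transform.

    Every value v becomes log2(max(v, threshold)); the output minimum is
    therefore log2(threshold). Refuses log2-scale input (double-transform
    guard).
    """
    if compendium.scale != "linear":
        raise ValueError("apply_noise_floor expects a linear-scale compendium")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    floored = np.maximum(compendium.values.to_numpy(float), threshold)
    values = pd.DataFrame(
        np.log2(floored), index=compendium.values.index, columns=compendium.values.columns
    )
    return compendium.with_values(values, scale="log2")


def quantile_normalize(compendium: Compendium, ties: str = "ordinal") -> Compendium:
    """Force every sample column onto the per-rank cross-sample mean distribution.

    The reference distribution is the mean, at each rank, of the sorted
    columns. Tie handling:

    ``ordinal`` (default)
        Tied values are assigned consecutive reference values in stable input
        order, so every output column's multiset equals the reference exactly
        — the defining contract of quantile normalization.
    ``average``
        Tied values all receive the mean of the reference values spanned by
        their tied ranks (the classic microarray convention); under ties the
        output multisets can then differ slightly between columns.
    """
    if compendium.n_samples < 2:
        raise ValueError("quantile normalization needs at least two samples")
    if ties not in ("ordinal", "average"):
        raise ValueError("ties must be 'ordinal' or 'average'")
    X = compendium.values.to_numpy(float)
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.take_along_axis(X, order, axis=0).mean(axis=1)
    out = np.empty_like(X)
    np.put_along_axis(out, order, ref[:, None], axis=0)
    if ties == "average":
        for j in range(X.shape[1]):
            col = X[:, j]
            # average assigned reference values within each group of equal inputs
            s = pd.Series(out[:, j]).groupby(col).transform("mean")
            out[:, j] = s.to_numpy()
    values = pd.DataFrame(out, index=compendium.values.index, columns=compendium.values.columns)
    return compendium.with_values(values)


def remove_principal_components(compendium: Compendium, pcs: Iterable[int]) -> Compendium:
    """Subtract the reconstruction of selected sample-space principal components.

    PCA is taken on gene-centered data, genes as variables, no unit-variance
    scaling; ``pcs`` are 1-based component indices. Gene means are restored
    after subtraction, and negative values that may result are retained.
    The gene-centered variance decreases by exactly the removed components'
    share. With ``pcs`` empty the input is returned unchanged.
    """
    pcs = sorted(int(p) for p in pcs)
    if not pcs:
        return compendium
    n_components = min(compendium.n_genes, compendium.n_samples - 1)
    if pcs[0] < 1:
        raise ValueError("component indices are 1-based")
    if pcs[-1] > n_components:
        raise ValueError(
            f"component index {pcs[-1]} exceeds the available {n_components} components"
        )
    X = compendium.values.to_numpy(float)
    mu = X.mean(axis=1, keepdims=True)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    idx = [p - 1 for p in pcs]
    recon = (U[:, idx] * s[idx]) @ Vt[idx, :]
    out = Xc - recon + mu
    values = pd.DataFrame(out, index=compendium.values.index, columns=compendium.values.columns)
    result = compendium.with_values(values)
    total = float((s**2).sum())
    result.meta["variance_removed_fraction"] = (
        {p: float(s[p - 1] ** 2 / total) for p in pcs} if total > 0 else {p: 0.0 for p in pcs}
    )
    return result


def collapse_probes_to_genes(
    compendium: Compendium, probe_map: Mapping[str, str], rule: str = "max_mean"
) -> Compendium:
    """Collapse probe-level rows to one row per gene.

    Probes absent from ``probe_map`` are dropped (counted in ``meta``).
    ``max_mean`` keeps, per gene, the probe with the largest mean across
    samples (ties broken by lexicographically smallest probe id); ``median``
    takes per-sample medians across the gene's probes.
    """
    if not probe_map:
        raise ValueError("empty probe-to-gene mapping")
    if rule not in ("max_mean", "median"):
        raise ValueError("rule must be 'max_mean' or 'median'")
    present = [p for p in compendium.genes if p in probe_map]
    if not present:
        raise ValueError("no probe in the compendium is covered by the mapping")
    n_unmapped = compendium.n_genes - len(present)
    vals = compendium.values.loc[present]
    gene_of = pd.Series([probe_map[p] for p in present], index=present)
    if rule == "max_mean":
        means = vals.mean(axis=1)
        stats = pd.DataFrame({"gene": gene_of, "mean": means, "probe": present})
        stats = stats.sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
        chosen = stats.groupby("gene", sort=True).head(1)
        out = vals.loc[chosen["probe"]]
        out.index = chosen["gene"].to_numpy()
        out = out.sort_index()
    else:
        out = vals.groupby(gene_of).median()
    result = Compendium(values=out, samples=compendium.samples, scale=compendium.scale)
    result.meta["n_probes_unmapped"] = n_unmapped
    return result


def merge_orthologs(
    comp_a: Compendium, comp_b: Compendium, table: OrthologTable
) -> Compendium:
    """Join two gene-level species compendia on one-to-one ortholog pairs.

    Rows are the pairs present in both compendia, indexed ``geneA|geneB``;
    columns are the union of samples (species recorded per sample by the
    annotations). Pairs absent from either compendium are dropped and counted.
    """
    if comp_a.scale != comp_b.scale:
        raise ValueError("compendia must share a scale flag")
    genes_a = set(comp_a.genes)
    genes_b = set(comp_b.genes)
    kept = [(a, b) for a, b in table.pairs if a in genes_a and b in genes_b]
    n_dropped = len(table.pairs) - len(kept)
    if not kept:
        raise ValueError("no ortholog pair is present in both compendia")
    rows_a = comp_a.values.loc[[a for a, _ in kept]].to_numpy()
    rows_b = comp_b.values.loc[[b for _, b in kept]].to_numpy()
    index = [f"{a}|{b}" for a, b in kept]
    values = pd.DataFrame(
        np.concatenate([rows_a, rows_b], axis=1),
        index=index,
        columns=list(comp_a.values.columns) + list(comp_b.values.columns),
    )
    samples = pd.concat([comp_a.samples, comp_b.samples], axis=0)
    merged = Compendium(values=values, samples=samples, scale=comp_a.scale)
    merged.meta["n_ortholog_pairs_dropped"] = n_dropped
    return merged


def run_preprocessing(
    compendia: Sequence[Compendium], config: PreprocessConfig | None = None
) -> Compendium:
    """Floor (if linear) -> merge -> quantile normalize -> remove components."""
    config = config or PreprocessConfig()
    prepared = [
        apply_noise_floor(c, config.noise_threshold) if c.scale == "linear" else c
        for c in compendia
    ]
    merged = prepared[0] if len(prepared) == 1 else merge_on_common_features(prepared)
    normalized = quantile_normalize(merged)
    return remove_principal_components(normalized, config.pcs_to_remove)
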