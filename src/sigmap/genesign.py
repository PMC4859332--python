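"""Cell-type marker-signature derivation by the minimal-pairwise-mean method.

A signature names the genes more highly expressed in a set of *test* classes
than in every *reference* class. Per gene, the governing statistic is the
minimum, over all (test, reference) class pairs, of the ratio of linear-scale
class means — the worst pair governs. Genes must clear a minimal linear fold
change (default 1.5, inclusive) and a maximal FDR (default 0.01, inclusive).

The significance machinery is a one-sided Welch t-test on log2 values per
class pair, aggregated by the maximum p over pairs (congruent with the
worst-pair fold-change logic), with Benjamini-Hochberg adjustment across
genes. Signatures are derived within one species' compendium only;
cross-species questions go through ortholog mapping and enrichment testing,
never direct gene-name matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ClassSelector, Compendium, GeneSetCollection, class_label


@dataclass
class SignatureSpec:
    """Definition of one signature: name, test/reference classes, thresholds."""

    name: str
    test_classes: tuple
    reference_classes: tuple
    min_fold_change: float = 1.5
    max_fdr: float = 0.01

    def __post_init__(self) -> None:
        self.test_classes = tuple(self.test_classes)
        self.reference_classes = tuple(self.reference_classes)
        if not self.test_classes or not self.reference_classes:
            raise ValueError("test and reference classes must both be non-empty")
        if set(self.test_classes) & set(self.reference_classes):
            raise ValueError("test and reference classes overlap")
        if self.min_fold_change <= 1:
            raise ValueError("min_fold_change must be > 1 (linear ratio)")
        if not 0 < self.max_fdr < 1:
            raise ValueError("max_fdr must be in (0, 1)")


@dataclass
class GeneSignature:
    """A derived signature: genes, per-gene statistics and provenance.

    ``stats`` holds ``min_pairwise_fc`` (linear) and ``fdr_q`` for the selected
    genes, sorted by descending fold change.
    """

    name: str
    genes: list
    stats: pd.DataFrame
    spec: SignatureSpec
    fold_change_only: bool = False

    def __len__(self) -> int:
        return len(self.genes)

    def summary(self, n: int = 10) -> str:
        head = self.stats.head(n).to_string(float_format=lambda v: f"{v:.4g}")
        mode = " (fold-change-only: FDR not assessed)" if self.fold_change_only else ""
        return (
            f"Signature {self.name!r}: {len(self.genes)} genes "
            f"(FC >= {self.spec.min_fold_change}, q <= {self.spec.max_fdr}){mode}\n{head}"
        )

    def to_collection(self) -> GeneSetCollection:
        test = ",".join(class_label(c) for c in self.spec.test_classes)
        ref = ",".join(class_label(c) for c in self.spec.reference_classes)
        desc = f"{self.name} test=[{test}] ref=[{ref}] fc>={self.spec.min_fold_change} fdr<={self.spec.max_fdr}"
        return GeneSetCollection(sets={self.name: (desc, list(self.genes))})


def _class_samples(compendium: Compendium, selector: ClassSelector) -> list:
    ids = compendium.class_sample_ids(selector)
    if not ids:
        raise ValueError(f"class {class_label(selector)!r} has no samples")
    return ids


def class_means_linear(
    compendium: Compendium, classes: Sequence[ClassSelector]
) -> pd.DataFrame:
    """Arithmetic per-class means on the linear scale (back-transformed from log2).

    Fold changes are specified in linear scale, which forces the arithmetic
    mean of 2**x, not 2**(mean of x): log2 replicates [2, 4] average to
    (4 + 16) / 2 = 10, not 8.
    """
    out = {}
    for sel in classes:
        ids = _class_samples(compendium, sel)
        block = compendium.values[ids].to_numpy(float)
        if compendium.scale == "log2":
            block = 2.0**block
        out[class_label(sel)] = block.mean(axis=1)
    return pd.DataFrame(out, index=compendium.values.index)


def min_pairwise_fold_change(
    test_means: pd.DataFrame, ref_means: pd.DataFrame
) -> pd.Series:
    """Per gene: min over all (test, reference) pairs of mean_test / mean_ref.

    Reference means of exactly zero indicate the noise floor was skipped and
    are an error.
    """
    if test_means.shape[1] < 1 or ref_means.shape[1] < 1:
        raise ValueError("need at least one test and one reference class")
    ref = ref_means.to_numpy(float)
    if np.any(ref == 0):
        raise ValueError("zero reference class mean (was the noise floor applied?)")
    ratios = test_means.to_numpy(float)[:, :, None] / ref[:, None, :]
    return pd.Series(ratios.min(axis=(1, 2)), index=test_means.index, name="min_pairwise_fc")


def signature_fdr(
    compendium: Compendium, spec: SignatureSpec, fold_change_only: bool = False
) -> pd.Series:
    """Per-gene q-values for the test-above-reference contrast.

    One-sided Welch t-test (test > reference) on log2 values for each
    (test, reference) class pair; per-gene p is the max over pairs;
    Benjamini-Hochberg across genes. Classes with fewer than two replicates
    are an error unless ``fold_change_only`` is set, in which case q is 0 for
    every gene and a loud warning is raised.
    """
    blocks = {}
    for sel in (*spec.test_classes, *spec.reference_classes):
        ids = _class_samples(compendium, sel)
        blocks[class_label(sel)] = compendium.values[ids].to_numpy(float)
    small = [lab for lab, b in blocks.items() if b.shape[1] < 2]
    if small:
        if not fold_change_only:
            raise ValueError(
                f"classes with < 2 replicates: {small}; "
                "rerun with fold_change_only=True to skip the FDR filter"
            )
        warnings.warn(
            f"classes {small} have < 2 replicates: FDR not assessed, q set to 0 "
            "for every gene (fold-change-only mode)",
            stacklevel=2,
        )
        return pd.Series(0.0, index=compendium.values.index, name="fdr_q")
    p_max = np.zeros(compendium.n_genes)
    for t_sel in spec.test_classes:
        t_block = blocks[class_label(t_sel)]
        for r_sel in spec.reference_classes:
            r_block = blocks[class_label(r_sel)]
            res = stats.ttest_ind(
                t_block, r_block, axis=1, equal_var=False, alternative="greater"
            )
            p = np.nan_to_num(res.pvalue, nan=1.0)
            p_max = np.maximum(p_max, p)
    q = multipletests(p_max, method="fdr_bh")[1]
    return pd.Series(q, index=compendium.values.index, name="fdr_q")


def make_signature(
    compendium: Compendium, spec: SignatureSpec, fold_change_only: bool = False
) -> GeneSignature:
    """Derive the signature: inclusive FC and FDR filters, sorted by FC.

    An empty result is a warning plus an empty signature object, not an error
    (downstream enrichment refuses empty sets on its own).
    """
    test_means = class_means_linear(compendium, spec.test_classes)
    ref_means = class_means_linear(compendium, spec.reference_classes)
    fc = min_pairwise_fold_change(test_means, ref_means)
    q = signature_fdr(compendium, spec, fold_change_only=fold_change_only)
    stats_df = pd.DataFrame({"min_pairwise_fc": fc, "fdr_q": q})
    keep = (fc >= spec.min_fold_change) & (q <= spec.max_fdr)
    selected = stats_df[keep.to_numpy()].sort_values(
        ["min_pairwise_fc", "fdr_q"], ascending=[False, True]
    )
    if selected.empty:
        warnings.warn(f"signature {spec.name!r} is empty at the given thresholds",
                      stacklevel=2)
    return GeneSignature(
        name=spec.name,
        genes=list(selected.index),
        stats=selected,
        spec=spec,
        fold_change_only=fold_change_only,
    )
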