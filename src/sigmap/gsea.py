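"""Gene set enrichment: class-contrast ranking, weighted running-sum enrichment
score, geneset-permutation null, and NES / nominal-p computation.

Genes are ranked by "difference of classes" — the difference of class means on
the log2 scale. The enrichment score is the signed extremum of the classic
weighted Kolmogorov-Smirnov running sum: set members ("hits") increment the
walk by |score|^p normalized by the total hit weight, non-members decrement by
1/(N - N_hit), so the walk starts and ends at zero and the score lies in
[-1, 1]. The null is built from random same-size gene sets drawn from the
ranked universe ("geneset-based permutation"); sample-label permutation is
deliberately not implemented — the small replicate counts this pipeline is
designed for (2-3 per class) cannot support it. NES divides the score by the
mean magnitude of same-sign null scores, so NES ~ 1 reads as "no enrichment";
the nominal p carries a +1 pseudocount and is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClassSelector, Compendium, class_label


@dataclass
class RankedList:
    """Genes in descending class-contrast order with their scores."""

    genes: np.ndarray
    scores: np.ndarray
    class_a: str
    class_b: str

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GseaResult:
    """One signature x one class pair: ES, NES, nominal p, adjusted q,
    leading edge and enrichment direction."""

    es: float
    nes: float
    p_nominal: float
    leading_edge: list
    direction: str
    size_used: int
    n_permutations: int
    seed: int
    q: float = np.nan


def rank_genes(
    compendium: Compendium, class_a: ClassSelector, class_b: ClassSelector
) -> RankedList:
    """Rank genes by mean log2 in class_a minus mean log2 in class_b.

    Descending order; ties broken lexicographically by gene id. Positive
    scores mean higher in class_a.
    """
    if compendium.scale != "log2":
        raise ValueError("ranking expects a log2-scale compendium")
    ids_a = compendium.class_sample_ids(class_a)
    ids_b = compendium.class_sample_ids(class_b)
    if not ids_a or not ids_b:
        empty = class_label(class_a) if not ids_a else class_label(class_b)
        raise ValueError(f"class {empty!r} has no samples")
    if set(ids_a) & set(ids_b):
        raise ValueError("classes overlap")
    diff = (
        compendium.values[ids_a].mean(axis=1) - compendium.values[ids_b].mean(axis=1)
    )
    order = sorted(range(len(diff)), key=lambda i: (-diff.iloc[i], str(diff.index[i])))
    return RankedList(
        genes=diff.index.to_numpy(object)[order],
        scores=diff.to_numpy()[order],
        class_a=class_label(class_a),
        class_b=class_label(class_b),
    )


def enrichment_score(
    ranked: RankedList, gene_set, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray, list]:
    """Weighted running-sum enrichment score.

    Returns ``(es, running_sum, leading_edge)``. ``es`` is the extremum of the
    walk with the larger magnitude (positive preferred on exact ties); the
    leading edge contains the set members at or before the positive extremum
    (at or after the negative extremum for es < 0). If every hit weight is
    zero (all in-set scores exactly zero under weighting), hits fall back to
    equal steps.
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be >= 0")
    members = set(gene_set)
    in_set = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=len(ranked))
    k = int(in_set.sum())
    if k == 0:
        raise ValueError("gene set has empty intersection with the ranked universe")
    n = len(ranked)
    w = np.abs(ranked.scores) ** weight_exponent
    wh = np.where(in_set, w, 0.0)
    total = wh.sum()
    if total == 0:
        wh = in_set.astype(float)
        total = float(k)
    steps = wh / total
    if k < n:
        steps = steps - (~in_set) / float(n - k)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    pos, neg = running[i_max], running[i_min]
    # extremum ties within summation round-off resolve to the positive side
    if pos + 1e-12 >= -neg:
        es = float(pos)
        leading = list(ranked.genes[: i_max + 1][in_set[: i_max + 1]])
    else:
        es = float(neg)
        leading = list(ranked.genes[i_min:][in_set[i_min:]])
    return es, running, leading


def geneset_permutation_null(
    ranked: RankedList,
    set_size: int,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> np.ndarray:
    """Null ES sample from random same-size gene sets.

    Draws ``n_perm`` gene sets of ``set_size`` uniformly without replacement
    from the ranked universe and scores each; reproducible under ``seed``.
    """
    n = len(ranked)
    if set_size > n:
        raise ValueError(f"set_size {set_size} exceeds the ranked universe ({n})")
    if set_size < 1 or n_perm < 1:
        raise ValueError("set_size and n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if set_size == n:
        es, _, _ = enrichment_score(ranked, list(ranked.genes), weight_exponent)
        return np.full(n_perm, es)
    # vectorized: uniform keys -> first k columns of the argsort are a uniform
    # without-replacement draw of positions
    keys = rng.random((n_perm, n))
    positions = np.sort(np.argpartition(keys, set_size, axis=1)[:, :set_size], axis=1)
    return _es_at_positions(ranked.scores, positions, weight_exponent)


def _es_at_positions(
    scores: np.ndarray, positions: np.ndarray, weight_exponent: float
) -> np.ndarray:
    """ES for many gene sets given their sorted rank positions (2D, per row).

    Evaluates the running sum only at the compressed walk's corner points:
    its local maxima sit immediately after hits, its local minima immediately
    before hits (and the walk pins to 0 at both ends).
    """
    n = len(scores)
    n_perm, k = positions.shape
    m = 1.0 / (n - k)
    w = np.abs(scores) ** weight_exponent
    wvals = w[positions]
    totals = wvals.sum(axis=1)
    degenerate = totals == 0
    if np.any(degenerate):
        wvals[degenerate] = 1.0
        totals[degenerate] = float(k)
    cumw = np.cumsum(wvals, axis=1) / totals[:, None]
    miss_count = positions - np.arange(k)[None, :]
    after = cumw - miss_count * m
    before = after - wvals / totals[:, None]
    pos_ext = np.maximum(after.max(axis=1), 0.0)
    neg_ext = np.minimum(before.min(axis=1), 0.0)
    return np.where(pos_ext + 1e-12 >= -neg_ext, pos_ext, neg_ext)


def normalize_and_test(es: float, null: np.ndarray) -> tuple[float, float]:
    """NES and nominal p from a null ES sample.

    NES = es / mean(|same-sign null|); p = (1 + #{same-sign null at least as
    extreme}) / (1 + #same-sign null). es == 0 returns (0, 1).
    """
    null = np.asarray(null, dtype=float)
    if es == 0:
        return 0.0, 1.0
    same = null[null > 0] if es > 0 else null[null < 0]
    if same.size == 0:
        raise ValueError(
            f"no permutation null values share the sign of es={es:.4g}; "
            "increase n_perm or inspect the ranking"
        )
    nes = es / float(np.abs(same).mean())
    p = (1 + int(np.sum(np.abs(same) >= abs(es)))) / (1 + same.size)
    return float(nes), float(p)


def gsea(
    compendium: Compendium,
    gene_set,
    class_a: ClassSelector,
    class_b: ClassSelector,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> GseaResult:
    """One complete enrichment test for a gene set between two classes."""
    ranked = rank_genes(compendium, class_a, class_b)
    universe = set(ranked.genes)
    used = [g for g in gene_set if g in universe]
    if not used:
        raise ValueError("gene set has empty intersection with the ranked universe")
    es, _, leading = enrichment_score(ranked, used, weight_exponent)
    null = geneset_permutation_null(
        ranked, len(used), n_perm=n_perm, seed=seed, weight_exponent=weight_exponent
    )
    nes, p = normalize_and_test(es, null)
    direction = ranked.class_a if es >= 0 else ranked.class_b
    return GseaResult(
        es=es,
        nes=nes,
        p_nominal=p,
        leading_edge=leading,
        direction=direction,
        size_used=len(used),
        n_permutations=n_perm,
        seed=seed,
    )
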