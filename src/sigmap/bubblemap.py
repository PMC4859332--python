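"""All-pairwise enrichment grids with map-wide multiple-testing correction and
bubble rendering.

:class:`BubbleMap` is the model object: a compendium plus a gene-set
collection. ``fit(seed)`` runs one enrichment test per (gene set, class pair)
cell — ranking, running-sum score, geneset-permutation null, NES and nominal p
— then adjusts p across the whole grid with the Benjamini-Yekutieli procedure
(valid under arbitrary dependence between the heavily overlapping cells) and
returns :class:`BubbleMapResults`. Per-cell RNG seeds are derived from the
global seed and the cell's (set, pair) identity, so grid values do not depend
on the order in which cells are computed.

A cell is drawn / counted significant iff |NES| > 1 and q < 0.25.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .gsea import (
    RankedList,
    enrichment_score,
    geneset_permutation_null,
    normalize_and_test,
    rank_genes,
)
from .io import Compendium, GeneSetCollection


@dataclass
class BubbleStyle:
    """Rendering rule-book: area ~ |NES| (clipped), two direction hues,
    opacity rising with -log10(q), and the significance rule."""

    max_abs_nes: float = 5.0
    color_first: str = "#2166ac"   # enrichment toward the lexicographically first class
    color_second: str = "#b2182b"
    min_alpha: float = 0.15
    max_alpha: float = 1.0
    q_alpha_cap: float = 4.0       # -log10(q) at which opacity saturates
    nes_rule: float = 1.0
    q_rule: float = 0.25

    def significant(self, nes: float, q: float) -> bool:
        return abs(nes) > self.nes_rule and q < self.q_rule

    def alpha(self, q: float, significant: bool) -> float:
        if not significant:
            return self.min_alpha
        strength = min(-np.log10(max(q, 1e-300)), self.q_alpha_cap) / self.q_alpha_cap
        return self.min_alpha + (self.max_alpha - self.min_alpha) * strength


def enumerate_class_pairs(
    compendium: Compendium, selectors: Sequence[str] | None = None
) -> list:
    """All unordered class pairs, lexicographic; the smaller class is first."""
    classes = sorted(selectors) if selectors is not None else compendium.cell_types()
    missing = [c for c in classes if not compendium.class_sample_ids(c)]
    if missing:
        raise ValueError(f"selected classes with no samples: {missing}")
    if len(classes) < 2:
        raise ValueError("need at least two classes to form pairs")
    return list(combinations(classes, 2))


def derive_cell_seed(global_seed: int, set_name: str, class_a: str, class_b: str) -> int:
    """Deterministic, cell-addressed RNG seed (stable across process runs)."""
    key = f"{global_seed}|{set_name}|{class_a}|{class_b}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def adjust_by(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli adjusted q-values across one grid."""
    return multipletests(np.asarray(p_values, float), method="fdr_by")[1]


@dataclass
class BubbleMapResults:
    """Fitted grid: one row per (gene set, class pair) with ES, NES, p, q."""

    cells: pd.DataFrame
    n_permutations: int
    seed: int
    weight_exponent: float
    correction: str
    skipped: list = field(default_factory=list)
    style: BubbleStyle = field(default_factory=BubbleStyle)

    def to_frame(self) -> pd.DataFrame:
        return self.cells.copy()

    def significant(self) -> pd.DataFrame:
        mask = [
            self.style.significant(r.nes, r.q) for r in self.cells.itertuples()
        ]
        return self.cells[mask]

    def summary(self) -> str:
        n_sig = len(self.significant())
        lines = [
            f"BubbleMap: {self.cells['set'].nunique()} gene sets x "
            f"{self.cells[['class_a', 'class_b']].drop_duplicates().shape[0]} class pairs "
            f"({len(self.cells)} cells, {len(self.skipped)} skipped)",
            f"permutations per cell: {self.n_permutations}; seed: {self.seed}; "
            f"correction: Benjamini-Yekutieli ({self.correction})",
            f"significant cells (|NES| > {self.style.nes_rule}, q < {self.style.q_rule}): {n_sig}",
        ]
        cols = ["set", "class_a", "class_b", "size_used", "es", "nes", "p_nominal", "q", "direction"]
        lines.append(self.cells[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.cells.copy()
        out["leading_edge"] = out["leading_edge"].map(lambda le: ",".join(le))
        out.to_csv(path, sep="\t", index=False)

    def plot(self, ax=None, style: BubbleStyle | None = None, max_area: float = 600.0):
        """Bubble-grid rendering; returns the matplotlib Figure.

        Area is proportional to |NES| clipped at the style cap; hue encodes
        the direction of enrichment; opacity deepens with significance;
        non-significant cells sit at minimum opacity; NES = 0 draws nothing.
        """
        if self.cells["q"].isna().any():
            raise ValueError("grid has unadjusted q values; run the BY adjustment first")
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from matplotlib.lines import Line2D

        style = style or self.style
        sets = list(dict.fromkeys(self.cells["set"]))
        pairs = list(dict.fromkeys(zip(self.cells["class_a"], self.cells["class_b"])))
        if ax is None:
            fig, ax = plt.subplots(
                figsize=(1.0 + 0.6 * len(pairs), 1.5 + 0.45 * len(sets))
            )
        else:
            fig = ax.figure
        for row in self.cells.itertuples():
            x = pairs.index((row.class_a, row.class_b))
            y = sets.index(row.set)
            if row.nes == 0:
                continue
            area = max_area * min(abs(row.nes), style.max_abs_nes) / style.max_abs_nes
            sig = style.significant(row.nes, row.q)
            color = style.color_first if row.direction == row.class_a else style.color_second
            ax.scatter(
                [x], [y], s=[area], c=[color], alpha=style.alpha(row.q, sig),
                edgecolors="black" if sig else "none", linewidths=0.5, zorder=3,
            )
        ax.set_xticks(range(len(pairs)))
        ax.set_xticklabels([f"{a}\nvs\n{b}" for a, b in pairs], fontsize=7)
        ax.set_yticks(range(len(sets)))
        ax.set_yticklabels(sets, fontsize=8)
        ax.set_xlim(-0.5, len(pairs) - 0.5)
        ax.set_ylim(len(sets) - 0.5, -0.5)
        ax.set_title(
            f"enrichment grid (area ~ |NES| <= {style.max_abs_nes}; "
            f"significant: |NES| > {style.nes_rule}, q < {style.q_rule})",
            fontsize=8,
        )
        handles = [
            Line2D([], [], marker="o", ls="", color=style.color_first,
                   label="enriched in first (blue) class"),
            Line2D([], [], marker="o", ls="", color=style.color_second,
                   label="enriched in second (red) class"),
        ]
        ax.legend(handles=handles, fontsize=6, loc="upper left", bbox_to_anchor=(1.01, 1))
        fig.tight_layout()
        return fig


class BubbleMap:
    """Model object: enrichment of every gene set between every class pair.

    Parameters
    ----------
    compendium
        Log2-scale compendium whose ``cell_type`` labels define the classes.
    sets
        Gene sets (exported signatures and/or external collections).
    selectors
        Optional subset of classes; defaults to every cell type present.
    n_perm, weight_exponent
        Permutations per cell and the running-sum weight exponent.
    correction
        ``"grid"`` adjusts p across all cells jointly (default, the stricter
        reading); ``"row"`` adjusts within each gene-set row.
    """

    def __init__(
        self,
        compendium: Compendium,
        sets: GeneSetCollection,
        selectors: Sequence[str] | None = None,
        n_perm: int = 1000,
        weight_exponent: float = 1.0,
        correction: str = "grid",
    ) -> None:
        if correction not in ("grid", "row"):
            raise ValueError("correction must be 'grid' or 'row'")
        self.compendium = compendium
        self.sets = sets
        self.pairs = enumerate_class_pairs(compendium, selectors)
        self.n_perm = int(n_perm)
        self.weight_exponent = float(weight_exponent)
        self.correction = correction

    def fit(self, seed: int = 0) -> BubbleMapResults:
        rows = []
        skipped = []
        ranked_cache: dict = {}
        for class_a, class_b in self.pairs:
            ranked = ranked_cache.get((class_a, class_b))
            if ranked is None:
                ranked = rank_genes(self.compendium, class_a, class_b)
                ranked_cache[(class_a, class_b)] = ranked
            universe = set(ranked.genes)
            for set_name in self.sets.names():
                used = [g for g in self.sets.genes(set_name) if g in universe]
                if not used:
                    skipped.append((set_name, class_a, class_b))
                    continue
                cell_seed = derive_cell_seed(seed, set_name, class_a, class_b)
                es, _, leading = enrichment_score(ranked, used, self.weight_exponent)
                null = geneset_permutation_null(
                    ranked, len(used), n_perm=self.n_perm, seed=cell_seed,
                    weight_exponent=self.weight_exponent,
                )
                nes, p = normalize_and_test(es, null)
                rows.append(
                    {
                        "set": set_name,
                        "class_a": class_a,
                        "class_b": class_b,
                        "size_used": len(used),
                        "es": es,
                        "nes": nes,
                        "p_nominal": p,
                        "q": np.nan,
                        "direction": class_a if es >= 0 else class_b,
                        "leading_edge": leading,
                    }
                )
        if not rows:
            raise ValueError("every grid cell was skipped (no set intersects any ranking)")
        cells = pd.DataFrame(rows)
        cells = cells.sort_values(["set", "class_a", "class_b"], kind="stable").reset_index(
            drop=True
        )
        if self.correction == "grid":
            cells["q"] = adjust_by(cells["p_nominal"].to_numpy())
        else:
            cells["q"] = (
                cells.groupby("set")["p_nominal"].transform(lambda p: adjust_by(p.to_numpy()))
            )
        return BubbleMapResults(
            cells=cells,
            n_permutations=self.n_perm,
            seed=seed,
            weight_exponent=self.weight_exponent,
            correction=self.correction,
            skipped=skipped,
        )


def render_bubblemap(results: BubbleMapResults, style: BubbleStyle | None = None,
                     path=None):
    """Render a fitted grid as a bubble graphic; optionally save (SVG etc.)."""
    fig = results.plot(style=style)
    if path is not None:
        fig.savefig(path)
    return fig


def run_bubblemap(
    compendium: Compendium,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    selectors: Sequence[str] | None = None,
    weight_exponent: float = 1.0,
    correction: str = "grid",
) -> BubbleMapResults:
    """Functional convenience wrapper over :class:`BubbleMap`."""
    model = BubbleMap(
        compendium,
        sets,
        selectors=selectors,
        n_perm=n_perm,
        weight_exponent=weight_exponent,
        correction=correction,
    )
    return model.fit(seed=seed)
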