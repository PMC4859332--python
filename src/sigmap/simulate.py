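"""Synthetic multi-dataset, multi-species compendium generator with ground truth.

The generator emulates the structure of merged microarray compendia of
mononuclear-phagocyte subsets: several datasets per species sharing anchor
cell types, cell-type-specific marker programs, additive dataset (batch)
shifts that dominate the leading principal component, replicate-level
Gaussian noise on the log2 scale, and cross-species homologous programs
linked through a one-to-one ortholog map (homologous cell types carry the
same marker program on orthologous genes).

The log2 value for gene g in sample s is

    baseline(g) + effect * 1[g is a marker of s's cell type]
                + batch_shift(dataset(s), g) + noise

Batch shifts are dataset-constant gene-wise vectors — exactly the additive
rank-deficient structure that principal-component subtraction can remove. A
``nonlinear_batch`` switch instead rescales gene deviations per dataset, a
structure PC subtraction cannot fully remove; it exists to demonstrate the
limits of the correction, not as a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Compendium, GeneSetCollection, OrthologTable


@dataclass
class SimulationConfig:
    """Study-condition knobs for the generator (log2 units throughout).

    Defaults describe a realistic compendium of six mononuclear-phagocyte
    subsets — three datasets for the first species and two for the second
    (the typical asymmetry of public MP compendia) — with 3 replicates per
    type, 50 markers per type at +2 log2, entry noise SD 0.5 and batch-shift
    SD 2.5 (five times the noise SD, so the dataset effect dominates the
    leading principal components).
    """

    n_genes: int = 2000
    species: tuple = ("human", "mouse")
    datasets_per_species: tuple = (3, 2)
    cell_types: tuple = ("cDC1", "cDC2", "pDC", "LC", "Mono", "Mac")
    shared_anchor_types: tuple | None = None  # None -> all cell types in every dataset
    marker_count: int = 50
    marker_effect: float = 2.0
    batch_shift_sd: float = 2.5
    noise_sd: float = 0.5
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    replicates_per_type: int = 3
    ortholog_fraction: float = 0.7
    nonlinear_batch: bool = False
    nonlinear_batch_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species) != 2:
            raise ValueError("exactly two species are simulated")
        if not 0 < self.ortholog_fraction <= 1:
            raise ValueError("ortholog_fraction must be in (0, 1]")
        n_orth = int(round(self.n_genes * self.ortholog_fraction))
        if self.marker_count * len(self.cell_types) > n_orth:
            raise ValueError(
                "marker programs exceed the orthologous gene pool: "
                f"{self.marker_count} x {len(self.cell_types)} > {n_orth}"
            )
        if self.shared_anchor_types is not None:
            if not set(self.shared_anchor_types) <= set(self.cell_types):
                raise ValueError("shared_anchor_types must be a subset of cell_types")
        self.datasets_per_species = tuple(self.datasets_per_species)
        if len(self.datasets_per_species) != len(self.species):
            raise ValueError("datasets_per_species must give one count per species")
        if self.replicates_per_type < 1 or min(self.datasets_per_species) < 1:
            raise ValueError("replicates_per_type and dataset counts must be >= 1")


@dataclass
class GroundTruth:
    """What was planted: markers, batch vectors, ortholog pairing, homologies."""

    markers: dict            # species -> cell_type -> [gene ids]
    batch_shifts: dict       # species -> dataset -> np.ndarray over genes
    ortholog_pairs: list     # [(gene_a, gene_b)]
    homologous_types: list   # [(cell_type_a, cell_type_b)], here identical labels

    def marker_set(self, species: str, cell_type: str) -> set:
        return set(self.markers[species][cell_type])


def _gene_ids(prefix: str, n: int) -> list:
    return [f"{prefix}{i:05d}" for i in range(n)]


def simulate_compendium(
    config: SimulationConfig,
) -> tuple[dict, OrthologTable, GroundTruth]:
    """Generate per-species log2 compendia, the ortholog table and ground truth.

    Reproducible: identical config (including seed) gives bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    sp_a, sp_b = config.species
    n_orth = int(round(config.n_genes * config.ortholog_fraction))
    prefixes = {sp_a: sp_a[:1].upper() + "G", sp_b: sp_b[:1].upper() + "G"}
    genes = {sp: _gene_ids(prefixes[sp], config.n_genes) for sp in config.species}
    ortholog_pairs = [(genes[sp_a][i], genes[sp_b][i]) for i in range(n_orth)]

    # marker programs drawn from the orthologous pool, disjoint across types,
    # identical indices in both species (homology through the ortholog map)
    marker_pool = rng.permutation(n_orth)
    markers_idx = {}
    for t, cell_type in enumerate(config.cell_types):
        lo = t * config.marker_count
        markers_idx[cell_type] = np.sort(marker_pool[lo : lo + config.marker_count])
    markers = {
        sp: {ct: [genes[sp][i] for i in idx] for ct, idx in markers_idx.items()}
        for sp in config.species
    }

    anchor = (
        tuple(config.cell_types)
        if config.shared_anchor_types is None
        else tuple(config.shared_anchor_types)
    )
    compendia = {}
    batch_shifts: dict = {}
    for sp, n_datasets in zip(config.species, config.datasets_per_species):
        baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
        batch_shifts[sp] = {}
        columns = []
        col_values = []
        ann_rows = []
        for d in range(n_datasets):
            dataset_id = f"{sp}_ds{d + 1}"
            shift = rng.normal(0.0, config.batch_shift_sd, config.n_genes)
            scale = (
                rng.normal(1.0, config.nonlinear_batch_sd, config.n_genes)
                if config.nonlinear_batch
                else np.ones(config.n_genes)
            )
            batch_shifts[sp][dataset_id] = shift
            # every dataset carries all cell types unless anchors were
            # restricted, in which case later datasets carry only the anchors
            if config.shared_anchor_types is None or d == 0:
                types_here = config.cell_types
            else:
                types_here = anchor
            for cell_type in types_here:
                effect = np.zeros(config.n_genes)
                effect[markers_idx[cell_type]] = config.marker_effect
                for r in range(1, config.replicates_per_type + 1):
                    noise = rng.normal(0.0, config.noise_sd, config.n_genes)
                    signal = baseline + effect
                    value = baseline + scale * (signal - baseline + shift) + noise
                    columns.append(f"{dataset_id}_{cell_type}_r{r}")
                    col_values.append(value)
                    ann_rows.append(
                        {
                            "sample_id": f"{dataset_id}_{cell_type}_r{r}",
                            "dataset_id": dataset_id,
                            "cell_type": cell_type,
                            "species": sp,
                            "replicate_index": r,
                        }
                    )
        values = pd.DataFrame(
            np.column_stack(col_values), index=genes[sp], columns=columns
        )
        samples = pd.DataFrame(ann_rows).set_index("sample_id")
        compendia[sp] = Compendium(values=values, samples=samples, scale="log2")

    table = OrthologTable(pairs=ortholog_pairs, species_a=sp_a, species_b=sp_b)
    truth = GroundTruth(
        markers=markers,
        batch_shifts=batch_shifts,
        ortholog_pairs=ortholog_pairs,
        homologous_types=[(ct, ct) for ct in config.cell_types],
    )
    return compendia, table, truth


def to_linear(compendium: Compendium) -> Compendium:
    """Linear-scale export (2**x) for exercising the noise-floor path."""
    if compendium.scale != "log2":
        raise ValueError("expected a log2 compendium")
    return compendium.with_values(2.0**compendium.values, scale="linear")


# ---------------------------------------------------------------------------
# recovery scoring against ground truth
# ---------------------------------------------------------------------------

def score_recovery(truth: GroundTruth, result, **kwargs) -> dict:
    """Recovery metrics for a signature or a fitted grid against ground truth.

    Dispatches to :func:`signature_recovery` (pass ``species`` and
    ``cell_type``) or :func:`grid_recovery` (pass ``signature_targets``)
    depending on what ``result`` is.
    """
    if hasattr(result, "genes"):
        return signature_recovery(truth, kwargs["species"], kwargs["cell_type"], result)
    if hasattr(result, "cells"):
        return grid_recovery(truth, result, kwargs["signature_targets"])
    raise ValueError("result must be a GeneSignature or BubbleMapResults")


def signature_recovery(truth: GroundTruth, species: str, cell_type: str, signature) -> dict:
    """Sensitivity / precision of a derived signature vs the planted markers."""
    planted = truth.marker_set(species, cell_type)
    if not planted:
        raise ValueError(f"no planted markers for {species}/{cell_type}")
    found = set(signature.genes)
    tp = len(found & planted)
    return {
        "sensitivity": tp / len(planted),
        "precision": tp / len(found) if found else 0.0,
        "n_selected": len(found),
        "n_false": len(found - planted),
    }


def grid_recovery(truth: GroundTruth, results, signature_targets: dict) -> dict:
    """Classify every grid cell against the planted homology map.

    ``signature_targets`` maps gene-set name -> the cell type whose program it
    represents (in the grid's species). A cell is *homologous* when its pair
    involves that target class; it is counted correct when significant with
    the enrichment pointing at the target. Non-homologous cells are correct
    when non-significant.
    """
    style = results.style
    hom_total = hom_correct = non_total = non_correct = 0
    for row in results.cells.itertuples():
        target = signature_targets.get(row.set)
        if target is None:
            continue
        sig = style.significant(row.nes, row.q)
        if target in (row.class_a, row.class_b):
            hom_total += 1
            if sig and row.direction == target:
                hom_correct += 1
        else:
            non_total += 1
            if not sig:
                non_correct += 1
    if hom_total == 0 or non_total == 0:
        raise ValueError("grid and signature targets do not overlap usefully")
    return {
        "homologous_significant_fraction": hom_correct / hom_total,
        "nonhomologous_nonsignificant_fraction": non_correct / non_total,
        "n_homologous_cells": hom_total,
        "n_nonhomologous_cells": non_total,
    }
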