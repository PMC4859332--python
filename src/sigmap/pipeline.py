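"""End-to-end cross-species homology mapping.

Wires the stages together: simulate (or load) per-species compendia ->
preprocess each species (quantile cross-normalization, dataset-effect
removal) -> derive cell-type signatures in the source species -> translate
signature genes through the one-to-one ortholog table -> fit a BubbleMap on
the target species -> score the grid against the planted homology map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .bubblemap import BubbleMap, BubbleMapResults
from .genesign import GeneSignature, SignatureSpec, make_signature
from .io import Compendium, GeneSetCollection, OrthologTable
from .preprocess import PreprocessConfig, quantile_normalize, remove_principal_components
from .simulate import GroundTruth, SimulationConfig, grid_recovery, simulate_compendium


@dataclass
class HomologyRun:
    """Everything one cross-species run produced."""

    compendia: dict
    signatures: dict
    mapped_sets: GeneSetCollection
    results: BubbleMapResults
    recovery: dict
    truth: GroundTruth
    n_unmapped: dict = field(default_factory=dict)


def preprocess_species(compendium: Compendium, config: PreprocessConfig | None = None) -> Compendium:
    """Quantile normalize and remove the dataset-effect components.

    With an explicit config the configured components are removed; otherwise
    the first D-1 components for D datasets — an additive dataset-constant
    shift across D datasets spans a (D-1)-dimensional gene-centered subspace
    (one PC removed for two datasets, two for three, matching how many
    leading components the dataset effect occupies).
    """
    if config is None:
        n_datasets = compendium.samples["dataset_id"].nunique()
        pcs = frozenset(range(1, n_datasets)) if n_datasets > 1 else frozenset()
        config = PreprocessConfig(pcs_to_remove=pcs) if pcs else None
    out = quantile_normalize(compendium)
    if config is None:
        return out
    return remove_principal_components(out, config.pcs_to_remove)


def derive_signatures(
    compendium: Compendium,
    min_fold_change: float = 1.5,
    max_fdr: float = 0.01,
) -> dict:
    """One signature per cell type: that type vs all other types as references."""
    signatures = {}
    for cell_type in compendium.cell_types():
        refs = tuple(ct for ct in compendium.cell_types() if ct != cell_type)
        spec = SignatureSpec(
            name=f"{cell_type}_sig",
            test_classes=(cell_type,),
            reference_classes=refs,
            min_fold_change=min_fold_change,
            max_fdr=max_fdr,
        )
        signatures[spec.name] = make_signature(compendium, spec)
    return signatures


def translate_signatures(
    signatures: dict, table: OrthologTable, side: str = "a"
) -> tuple[GeneSetCollection, dict]:
    """Map signature genes into the other species' namespace; drop empties."""
    sets = {}
    n_unmapped = {}
    for name, sig in signatures.items():
        mapped, dropped = table.translate(sig.genes, side=side)
        n_unmapped[name] = dropped
        if mapped:
            sets[name] = (f"{name} mapped via one-to-one orthologs", mapped)
    if not sets:
        raise ValueError("no signature survived ortholog mapping")
    return GeneSetCollection(sets=sets), n_unmapped


def run_cross_species_homology(
    sim_config: SimulationConfig | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    preprocess_config: PreprocessConfig | None = None,
) -> HomologyRun:
    """Simulated end-to-end run: signatures from species A, grid on species B."""
    sim_config = sim_config or SimulationConfig(seed=seed)
    compendia, table, truth = simulate_compendium(sim_config)
    sp_a, sp_b = sim_config.species
    prepped = {sp: preprocess_species(compendia[sp], preprocess_config) for sp in compendia}
    signatures = derive_signatures(prepped[sp_a])
    mapped_sets, n_unmapped = translate_signatures(signatures, table, side="a")
    model = BubbleMap(prepped[sp_b], mapped_sets, n_perm=n_perm)
    results = model.fit(seed=seed)
    targets = {name: name.removesuffix("_sig") for name in mapped_sets.names()}
    recovery = grid_recovery(truth, results, targets)
    return HomologyRun(
        compendia=prepped,
        signatures=signatures,
        mapped_sets=mapped_sets,
        results=results,
        recovery=recovery,
        truth=truth,
        n_unmapped=n_unmapped,
    )
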