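"""Readers, writers and validated containers for the formats the pipeline touches.

Expression matrices travel as TSV (header row required) or GCT v1.2, always
genes-in-rows / samples-in-columns; gene sets as GMT; sample annotations and
ortholog tables as TSV. Validation is strict: dimension mismatches, duplicate
identifiers, missing annotations and non-numeric cells are errors that name the
offending row or column, never silently repaired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ("sample_id", "dataset_id", "cell_type", "species", "replicate_index")

SCALES = ("linear", "log2")

#: A class selector is either a cell-type name (pooling datasets) or an explicit
#: (dataset_id, cell_type) pair.
ClassSelector = Union[str, tuple]


def class_label(selector: ClassSelector) -> str:
    if isinstance(selector, str):
        return selector
    return f"{selector[0]}:{selector[1]}"


@dataclass
class Compendium:
    """A gene x sample expression matrix with per-sample annotations.

    Parameters
    ----------
    values
        DataFrame, rows = feature ids (probes or gene symbols), columns =
        sample ids. Log2 scale unless ``scale`` says otherwise.
    samples
        DataFrame indexed by sample id with columns ``dataset_id``,
        ``cell_type``, ``species``, ``replicate_index``.
    scale
        ``"log2"`` or ``"linear"``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "log2"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        missing_ann = [s for s in self.values.columns if s not in self.samples.index]
        if missing_ann:
            raise ValueError(f"samples without annotation: {missing_ann[:5]}")
        extra_ann = [s for s in self.samples.index if s not in self.values.columns]
        if extra_ann:
            raise ValueError(f"annotations without matrix column: {extra_ann[:5]}")
        # align annotation order to the matrix
        self.samples = self.samples.loc[list(self.values.columns)]
        for col in ("dataset_id", "cell_type", "species", "replicate_index"):
            if col not in self.samples.columns:
                raise ValueError(f"annotation table lacks required column {col!r}")
        if (self.samples["replicate_index"].astype(int) < 1).any():
            raise ValueError("replicate_index must be >= 1")
        triple = self.samples[["dataset_id", "cell_type", "replicate_index"]]
        if triple.duplicated().any():
            bad = triple[triple.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (dataset, cell_type, replicate) triple: {bad}")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            # locate first offending cell for the error message
            for col in self.values.columns:
                coerced = pd.to_numeric(self.values[col], errors="coerce")
                if coerced.isna().any():
                    gene = self.values.index[coerced.isna().to_numpy()][0]
                    raise ValueError(f"non-numeric value at gene {gene!r}, sample {col!r}")
            self.values = self.values.astype(float)
            vals = self.values.to_numpy()
        if np.isnan(vals).any():
            g, s = np.argwhere(np.isnan(vals))[0]
            raise ValueError(
                f"missing value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )

    # ---- convenience -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def genes(self) -> list:
        return list(self.values.index)

    def species_set(self) -> set:
        return set(self.samples["species"])

    def cell_types(self) -> list:
        return sorted(set(self.samples["cell_type"]))

    def class_sample_ids(self, selector: ClassSelector) -> list:
        """Sample ids belonging to one class selector."""
        if isinstance(selector, str):
            mask = self.samples["cell_type"] == selector
        else:
            dataset_id, cell_type = selector
            mask = (self.samples["dataset_id"] == dataset_id) & (
                self.samples["cell_type"] == cell_type
            )
        return list(self.samples.index[mask])

    def subset_samples(self, sample_ids: Sequence[str]) -> "Compendium":
        return Compendium(
            values=self.values[list(sample_ids)],
            samples=self.samples.loc[list(sample_ids)],
            scale=self.scale,
        )

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "Compendium":
        return Compendium(
            values=values,
            samples=self.samples.loc[list(values.columns)],
            scale=self.scale if scale is None else scale,
        )


@dataclass
class OrthologTable:
    """One-to-one ortholog pairs between two species' gene namespaces."""

    pairs: list
    species_a: str = "a"
    species_b: str = "b"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        a_genes = [a for a, _ in self.pairs]
        b_genes = [b for _, b in self.pairs]
        if len(set(a_genes)) != len(a_genes) or len(set(b_genes)) != len(b_genes):
            raise ValueError("ortholog table is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def a_to_b(self) -> dict:
        return dict(self.pairs)

    def b_to_a(self) -> dict:
        return {b: a for a, b in self.pairs}

    def translate(self, genes: Iterable[str], side: str = "a") -> tuple[list, int]:
        """Map gene ids through the table; returns (mapped, n_unmapped).

        ``side`` names the namespace the input genes live in ("a" or "b").
        """
        mapping = self.a_to_b() if side == "a" else self.b_to_a()
        mapped = [mapping[g] for g in genes if g in mapping]
        return mapped, sum(1 for g in genes if g not in mapping)


@dataclass
class GeneSetCollection:
    """Named gene sets: mapping name -> (description, gene list)."""

    sets: dict

    def __post_init__(self) -> None:
        for name, (desc, genes) in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, name: str) -> list:
        return self.sets[name][1]

    def names(self) -> list:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_matrix_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: matrix has no sample columns")
    return df


def _read_matrix_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ValueError(f"{path}: malformed GCT dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if "Description" in df.columns:
        df = df.drop(columns=["Description"])
    if df.shape != (n_rows, n_cols):
        raise ValueError(
            f"{path}: GCT header declares {n_rows} x {n_cols} "
            f"but file contains {df.shape[0]} x {df.shape[1]}"
        )
    return df


def read_compendium(matrix_path, annotation_path, scale: str = "log2") -> Compendium:
    """Load a matrix (TSV or GCT v1.2) plus its sample-annotation TSV."""
    matrix_path = Path(matrix_path)
    if matrix_path.suffix.lower() == ".gct":
        values = _read_matrix_gct(matrix_path)
    else:
        values = _read_matrix_tsv(matrix_path)
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"{annotation_path}: annotation table lacks columns {missing}")
    ann = ann.set_index("sample_id")
    return Compendium(values=values, samples=ann, scale=scale)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene [<tab> gene ...]."""
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: set with no genes at line {lineno}")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ValueError(f"{path}: set with no genes at line {lineno}")
            sets[name] = (desc, genes)
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return GeneSetCollection(sets=sets)


def read_ortholog_table(path, species_a: str = "a", species_b: str = "b",
                        col_a: str | None = None, col_b: str | None = None) -> OrthologTable:
    """Read a two-column ortholog TSV, dropping rows that violate one-to-one.

    Extra columns are ignored; ``col_a``/``col_b`` select columns by header
    name (defaults: the first two columns). A gene appearing more than once on
    its side removes *all* rows involving it (one-to-many is not resolvable).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty ortholog table")
    if col_a is None:
        col_a = df.columns[0]
    if col_b is None:
        col_b = df.columns[1]
    df = df[[col_a, col_b]].dropna()
    a_counts = df[col_a].value_counts()
    b_counts = df[col_b].value_counts()
    keep = df[col_a].map(a_counts).eq(1) & df[col_b].map(b_counts).eq(1)
    n_dropped = int((~keep).sum())
    kept = df[keep]
    if kept.shape[0] == 0:
        raise ValueError(f"{path}: no one-to-one pairs remain after filtering")
    pairs = list(zip(kept[col_a], kept[col_b]))
    return OrthologTable(pairs=pairs, species_a=species_a, species_b=species_b,
                         n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_compendium(compendium: Compendium, matrix_path, annotation_path) -> None:
    """Write matrix TSV + annotation TSV (full float repr; round-trips exactly)."""
    out = compendium.values.copy()
    out.index.name = "gene"
    out.to_csv(matrix_path, sep="\t")
    ann = compendium.samples.reset_index()
    ann = ann.rename(columns={ann.columns[0]: "sample_id"})
    ann[list(ANNOTATION_COLUMNS)].to_csv(annotation_path, sep="\t", index=False)


def write_gct(compendium: Compendium, path) -> None:
    """Write the expression matrix as GCT v1.2."""
    n_rows, n_cols = compendium.values.shape
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{n_rows}\t{n_cols}\n")
        header = "NAME\tDescription\t" + "\t".join(map(str, compendium.values.columns))
        fh.write(header + "\n")
        for gene, row in compendium.values.iterrows():
            fh.write(str(gene) + "\tna\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")
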