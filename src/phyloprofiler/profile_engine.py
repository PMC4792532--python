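"""Phylogenetic profile construction over five homology relationships.

For a query ("reference") gene and one target species, an InParanoid-style
cluster supports exactly one of five relationships:

* ``NONE`` — no detectable ortholog in the target species;
* ``ONE_TO_ONE`` — a single query gene, a single target ortholog;
* ``ONE_TO_MANY`` — a single query gene, two or more target orthologs
  (lineage-specific duplication in the target);
* ``MANY_TO_ONE`` — the query gene plus at least one reference in-paralog
  map to a single target gene;
* ``MANY_TO_MANY`` — at least two genes on both sides of the cluster.

Collating these calls across all target species yields the phylogenetic
profile of the gene; stacking profiles for a gene list yields the
:class:`ProfileMatrix` that the clustered heatmap views render.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import OrthologRecord

__all__ = [
    "RelationshipCategory",
    "ProfileMatrix",
    "classify_relationship",
    "build_profile_matrix",
    "encode_matrix",
    "CATEGORICAL_CODES",
]


class RelationshipCategory(enum.Enum):
    NONE = "none"
    ONE_TO_ONE = "1:1"
    ONE_TO_MANY = "1:M"
    MANY_TO_ONE = "M:1"
    MANY_TO_MANY = "M:M"


#: Integer codes for the categorical heatmap encoding.
CATEGORICAL_CODES: dict[RelationshipCategory, int] = {
    RelationshipCategory.NONE: 0,
    RelationshipCategory.ONE_TO_ONE: 1,
    RelationshipCategory.ONE_TO_MANY: 2,
    RelationshipCategory.MANY_TO_ONE: 3,
    RelationshipCategory.MANY_TO_MANY: 4,
}


def classify_relationship(record: OrthologRecord | None) -> RelationshipCategory:
    """Classify one (reference gene, target species) pair.

    Absence of a cluster means no detectable ortholog.  Otherwise the
    cardinalities of the reference in-paralog set and the target ortholog
    set decide the quadrant.
    """
    if record is None:
        return RelationshipCategory.NONE
    n_ref = len(record.reference_paralogs)
    n_tgt = len(record.target_genes)
    if n_tgt == 0:
        raise ValueError(
            f"group {record.group_id}: cluster without target genes cannot be classified"
        )
    if n_ref == 1:
        return (
            RelationshipCategory.ONE_TO_ONE
            if n_tgt == 1
            else RelationshipCategory.ONE_TO_MANY
        )
    return (
        RelationshipCategory.MANY_TO_ONE
        if n_tgt == 1
        else RelationshipCategory.MANY_TO_MANY
    )


@dataclasses.dataclass
class ProfileMatrix:
    """Genes x species grid of relationship categories.

    ``detail`` keeps, for every non-``NONE`` cell, the target ortholog set
    and the reference in-paralog set, so per-tile drill-down (orthologs and
    predicted in-paralogs) is answerable after the fact.
    """

    genes: list[str]
    species: list[str]
    cells: dict[tuple[str, str], RelationshipCategory]
    detail: dict[tuple[str, str], tuple[frozenset[str], frozenset[str]]]

    def category(self, gene: str, species: str) -> RelationshipCategory:
        return self.cells[(gene, species)]

    def cell_detail(self, gene: str, species: str):
        """(reference paralogs, target genes) for a non-NONE cell."""
        return self.detail[(gene, species)]

    def to_frame(self) -> pd.DataFrame:
        data = {
            sp: [self.cells[(g, sp)].value for g in self.genes] for sp in self.species
        }
        return pd.DataFrame(data, index=pd.Index(self.genes, name="gene"))


def build_profile_matrix(
    genes: Sequence[str],
    species: Sequence[str],
    records: Iterable[OrthologRecord],
    max_genes: int = 1000,
) -> ProfileMatrix:
    """Assemble the profile matrix for a gene list.

    Row and column order follow the input lists (clustering reorders rows
    later; species stay in the supplied phylogenetic order).  Genes absent
    from every cluster get all-``NONE`` rows.  Gene lists are capped at
    ``max_genes`` (default 1000) per run.
    """
    genes = list(genes)
    species = list(species)
    if not genes or not species:
        raise ValueError("gene and species lists must be non-empty")
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"duplicate genes in gene list: {', '.join(dupes)}")
    if len(genes) > max_genes:
        raise ValueError(f"{len(genes)} genes exceeds the per-run cap of {max_genes}")

    by_pair: dict[tuple[str, str], OrthologRecord] = {}
    for rec in records:
        key = (rec.reference_gene, rec.target_species)
        if key in by_pair and by_pair[key] != rec:
            raise ValueError(
                f"conflicting ortholog records for gene {key[0]!r} in species {key[1]!r}"
            )
        by_pair[key] = rec

    cells: dict[tuple[str, str], RelationshipCategory] = {}
    detail: dict[tuple[str, str], tuple[frozenset[str], frozenset[str]]] = {}
    for g in genes:
        for sp in species:
            rec = by_pair.get((g, sp))
            cat = classify_relationship(rec)
            cells[(g, sp)] = cat
            if rec is not None and cat is not RelationshipCategory.NONE:
                detail[(g, sp)] = (rec.reference_paralogs, rec.target_genes)
    return ProfileMatrix(genes=genes, species=species, cells=cells, detail=detail)


def encode_matrix(matrix: ProfileMatrix, scheme: str = "binary") -> pd.DataFrame:
    """Numeric grid for clustering/rendering.

    ``binary``: presence/absence (NONE -> 0, anything else -> 1) — the
    color-vs-black tile semantics.  ``categorical``: NONE -> 0, 1:1 -> 1,
    1:M -> 2, M:1 -> 3, M:M -> 4.
    """
    if scheme not in {"binary", "categorical"}:
        raise ValueError(f"unknown encoding scheme: {scheme!r}")
    grid = np.empty((len(matrix.genes), len(matrix.species)), dtype=int)
    for i, g in enumerate(matrix.genes):
        for j, sp in enumerate(matrix.species):
            code = CATEGORICAL_CODES[matrix.cells[(g, sp)]]
            grid[i, j] = code if scheme == "categorical" else int(code > 0)
    return pd.DataFrame(
        grid, index=pd.Index(matrix.genes, name="gene"), columns=matrix.species
    )
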