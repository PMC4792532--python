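"""Readers, writers and record-level filters for every external format.

Coordinate convention: all amino-acid coordinates are 1-based and inclusive
at both ends (the pfam_scan convention).  Pfam accession version suffixes
(``PF00047.12`` -> ``PF00047``) are stripped on input so that architectures
compare by accession family across Pfam releases.

Formats handled here:

* pfam_scan tabular output (whitespace separated, ``#`` comments);
* InParanoid "SQLtable" ortholog clusters and a simpler headered TSV
  (``reference_gene  target_species  target_gene  group_id``) for users who
  have not run InParanoid;
* FASTA proteomes (via Biopython);
* TSV matrices, GraphML / JSON graph exports (round-trippable).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO

__all__ = [
    "DomainHit",
    "Protein",
    "OrthologRecord",
    "ParseError",
    "ENTRY_TYPES",
    "read_pfamscan",
    "write_pfamscan",
    "read_ortholog_table",
    "write_simple_ortholog_tsv",
    "read_fasta",
    "write_fasta",
    "longest_peptide",
    "read_go_annotations",
    "select_genes_by_term",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_graph",
    "read_graph_json",
]

#: Pfam-A entry types.  Only ``Domain`` and ``Family`` entries contribute to
#: domain architectures; the rest are parsed but filtered out downstream.
ENTRY_TYPES = frozenset(
    {"Family", "Domain", "Repeat", "Motif", "Coiled-coil", "Disordered"}
)


class ParseError(ValueError):
    """A malformed line or record in an input file."""


@dataclasses.dataclass(frozen=True)
class DomainHit:
    """One Pfam match on one protein (1-based inclusive coordinates)."""

    protein_id: str
    ali_start: int
    ali_end: int
    env_start: int
    env_end: int
    hmm_acc: str
    hmm_name: str
    entry_type: str
    bit_score: float
    e_value: float
    clan: str = ""

    def __post_init__(self) -> None:
        if self.ali_start > self.ali_end:
            raise ValueError(
                f"{self.protein_id}: ali_start {self.ali_start} > ali_end {self.ali_end}"
            )
        if self.env_start > self.env_end:
            raise ValueError(
                f"{self.protein_id}: env_start {self.env_start} > env_end {self.env_end}"
            )
        if self.e_value < 0:
            raise ValueError(f"{self.protein_id}: negative E-value {self.e_value}")


@dataclasses.dataclass(frozen=True)
class Protein:
    """A protein sequence record; ``sequence`` is optional but, when present,
    must agree with ``length``."""

    protein_id: str
    species: str = ""
    gene_id: str = ""
    length: int = 0
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.protein_id}: non-positive length {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.protein_id}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclasses.dataclass(frozen=True)
class OrthologRecord:
    """One (cluster, reference gene, target species) orthology assignment.

    ``reference_paralogs`` holds every reference-species gene in the cluster
    (the in-paralogs), and always contains ``reference_gene`` itself.
    """

    group_id: str
    reference_gene: str
    target_species: str
    target_genes: frozenset[str]
    reference_paralogs: frozenset[str]

    def __post_init__(self) -> None:
        if self.reference_gene not in self.reference_paralogs:
            raise ValueError(
                f"reference gene {self.reference_gene} missing from its own paralog set"
            )
        if self.target_genes & self.reference_paralogs:
            raise ValueError(
                f"group {self.group_id}: target genes overlap reference paralogs"
            )


# ---------------------------------------------------------------------------
# pfam_scan tabular output
# ---------------------------------------------------------------------------

# pfam_scan column order (whitespace separated):
# seq_id ali_start ali_end env_start env_end hmm_acc hmm_name type
# hmm_start hmm_end hmm_length bit_score e_value significance clan
_PFAMSCAN_MIN_FIELDS = 15


def _strip_version(acc: str) -> str:
    return acc.split(".", 1)[0]


def read_pfamscan(path: str | Path) -> list[DomainHit]:
    """Parse pfam_scan tabular output into :class:`DomainHit` records.

    Comment lines (``#``) and blank lines are skipped; data-line order is
    preserved.  Accession version suffixes are stripped.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _PFAMSCAN_MIN_FIELDS:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {_PFAMSCAN_MIN_FIELDS} fields, "
                    f"got {len(fields)}"
                )
            try:
                hit = DomainHit(
                    protein_id=fields[0],
                    ali_start=int(fields[1]),
                    ali_end=int(fields[2]),
                    env_start=int(fields[3]),
                    env_end=int(fields[4]),
                    hmm_acc=_strip_version(fields[5]),
                    hmm_name=fields[6],
                    entry_type=fields[7],
                    bit_score=float(fields[11]),
                    e_value=float(fields[12]),
                    clan=fields[14],
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_pfamscan(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits back out in pfam_scan column order (hmm coords synthesized
    from the alignment span; significance fixed at 1)."""
    with open(path, "w") as fh:
        fh.write("# pfam_scan-style domain hits\n")
        for h in hits:
            span = h.ali_end - h.ali_start + 1
            fh.write(
                f"{h.protein_id} {h.ali_start} {h.ali_end} {h.env_start} "
                f"{h.env_end} {h.hmm_acc} {h.hmm_name} {h.entry_type} "
                f"1 {span} {span} {h.bit_score:g} {h.e_value:g} 1 "
                f"{h.clan or 'No_clan'}\n"
            )


# ---------------------------------------------------------------------------
# Orthology tables
# ---------------------------------------------------------------------------

SIMPLE_TSV_COLUMNS = ("reference_gene", "target_species", "target_gene", "group_id")


def read_ortholog_table(
    path: str | Path,
    dialect: str = "simple_tsv",
    reference_species: str | None = None,
) -> list[OrthologRecord]:
    """Read an orthology table into per-(cluster, reference gene, species)
    records.

    ``inparanoid_sqltable`` is the headerless InParanoid dump with columns
    (cluster id, bit score, species, inparalog score, gene); the reference
    species must be named explicitly because the format does not mark it.
    ``simple_tsv`` is a headered TSV with columns
    ``reference_gene, target_species, target_gene, group_id``.
    """
    if dialect == "inparanoid_sqltable":
        if reference_species is None:
            raise ValueError("inparanoid_sqltable requires reference_species")
        return _read_inparanoid_sqltable(path, reference_species)
    if dialect == "simple_tsv":
        return _read_simple_tsv(path)
    raise ValueError(f"unknown ortholog table dialect: {dialect!r}")


def _read_inparanoid_sqltable(path: str | Path, reference_species: str) -> list[OrthologRecord]:
    clusters: dict[str, list[tuple[str, str]]] = {}  # cluster -> [(species, gene)]
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected >= 5 columns")
            cluster, species, gene = fields[0], fields[2], fields[4]
            if cluster not in clusters:
                clusters[cluster] = []
                order.append(cluster)
            clusters[cluster].append((species, gene))
    records: list[OrthologRecord] = []
    for cluster in order:
        members = clusters[cluster]
        species_here = {sp for sp, _ in members}
        if len(species_here) > 2:
            raise ParseError(
                f"{path}: cluster {cluster} spans {len(species_here)} species; "
                "InParanoid SQLtables are pairwise"
            )
        if reference_species not in species_here:
            raise ParseError(
                f"{path}: cluster {cluster} contains no gene from reference "
                f"species {reference_species!r}"
            )
        ref_genes = frozenset(g for sp, g in members if sp == reference_species)
        others = species_here - {reference_species}
        if not others:
            continue  # self-comparison cluster with no target genes
        (target_species,) = others
        tgt_genes = frozenset(g for sp, g in members if sp == target_species)
        for ref_gene in sorted(ref_genes):
            records.append(
                OrthologRecord(
                    group_id=cluster,
                    reference_gene=ref_gene,
                    target_species=target_species,
                    target_genes=tgt_genes,
                    reference_paralogs=ref_genes,
                )
            )
    return records


def _read_simple_tsv(path: str | Path) -> list[OrthologRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SIMPLE_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records: list[OrthologRecord] = []
    for (group_id, species), sub in df.groupby(["group_id", "target_species"], sort=False):
        ref_genes = frozenset(sub["reference_gene"])
        tgt_genes = frozenset(sub["target_gene"].dropna())
        for ref_gene in sorted(ref_genes):
            records.append(
                OrthologRecord(
                    group_id=str(group_id),
                    reference_gene=ref_gene,
                    target_species=str(species),
                    target_genes=tgt_genes,
                    reference_paralogs=ref_genes,
                )
            )
    return records


def write_simple_ortholog_tsv(records: Iterable[OrthologRecord], path: str | Path) -> None:
    """Serialize records in the ``simple_tsv`` dialect (one row per
    reference-gene x target-gene pair within a group)."""
    rows = []
    seen_groups: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.group_id, rec.target_species)
        if key in seen_groups:
            continue  # groups are expanded per reference gene on read
        seen_groups.add(key)
        for ref in sorted(rec.reference_paralogs):
            for tgt in sorted(rec.target_genes):
                rows.append((ref, rec.target_species, tgt, rec.group_id))
    with open(path, "w") as fh:
        fh.write("\t".join(SIMPLE_TSV_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, species: str = "") -> list[Protein]:
    """Read a proteome FASTA; duplicate ids or empty records are errors."""
    proteins: list[Protein] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ParseError(f"{path}: empty sequence for record {rec.id!r}")
        seen[rec.id] = seen.get(rec.id, 0) + 1
        proteins.append(
            Protein(
                protein_id=rec.id,
                species=species,
                gene_id=_gene_from_description(rec.description),
                length=len(seq),
                sequence=seq,
            )
        )
    dups = sorted(pid for pid, n in seen.items() if n > 1)
    if dups:
        raise ParseError(f"{path}: duplicate protein ids: {', '.join(dups)}")
    return proteins


def _gene_from_description(description: str) -> str:
    # Convention: optional "gene=<id>" token in the FASTA header.
    for token in description.split():
        if token.startswith("gene="):
            return token[len("gene="):]
    return ""


def write_fasta(proteins: Iterable[Protein], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            if p.sequence is None:
                raise ValueError(f"{p.protein_id}: no sequence to write")
            header = f">{p.protein_id}"
            if p.gene_id:
                header += f" gene={p.gene_id}"
            fh.write(header + "\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


def longest_peptide(gene_id: str, proteins: Sequence[Protein]) -> Protein:
    """The longest isoform mapping to ``gene_id``; ties broken by
    lexicographically smallest protein id.  This isoform represents the gene
    in all domain comparisons."""
    candidates = [p for p in proteins if p.gene_id == gene_id or p.protein_id == gene_id]
    if not candidates:
        raise KeyError(f"no protein maps to gene {gene_id!r}")
    return min(candidates, key=lambda p: (-p.length, p.protein_id))


# ---------------------------------------------------------------------------
# GO-term gene selection
# ---------------------------------------------------------------------------


def read_go_annotations(path: str | Path) -> pd.DataFrame:
    """Read a two-column headered TSV (``gene``, ``term``) of functional
    annotations used to populate query gene lists."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene", "term"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def select_genes_by_term(
    annotations: pd.DataFrame, term: str, max_genes: int = 1000
) -> list[str]:
    """Genes annotated to ``term``, deduplicated in first-seen order.

    Terms whose gene frequency exceeds ``max_genes`` (default 1000, the bulk
    query cap) are rejected rather than truncated.
    """
    genes = list(dict.fromkeys(annotations.loc[annotations["term"] == term, "gene"]))
    if len(genes) > max_genes:
        raise ValueError(
            f"term {term!r} annotates {len(genes)} genes, above the cap of {max_genes}"
        )
    return genes


# ---------------------------------------------------------------------------
# Matrix / graph serialization
# ---------------------------------------------------------------------------


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x species matrix as TSV with row index and header."""
    matrix.to_csv(path, sep="\t", index=True, index_label="gene")


def read_matrix_tsv(path: str | Path, numeric: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene", dtype=str)
    df.index = df.index.astype(str)
    if numeric:
        df = df.astype(int)
    return df


def write_graph(graph, path: str | Path, format: str = "json") -> None:
    """Serialize a :class:`~phyloprofiler.domain_network.DomainGraph`.

    ``json`` preserves full provenance and node status (round-trippable via
    :func:`read_graph_json`); ``graphml`` flattens set-valued attributes to
    sorted comma-joined strings for interoperability.
    """
    if format == "json":
        with open(path, "w") as fh:
            json.dump(graph.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "graphml":
        g = nx.DiGraph()
        for node, attrs in sorted(graph.nodes.items()):
            g.add_node(node, count=attrs.count, status=attrs.status)
        for (src, dst), edge in sorted(graph.edges.items()):
            g.add_edge(
                src, dst, weight=edge.weight, provenance=",".join(sorted(edge.provenance))
            )
        nx.write_graphml(g, str(path))
    else:
        raise ValueError(f"unknown graph format: {format!r}")


def read_graph_json(path: str | Path):
    """Read a JSON graph export back into a DomainGraph (field-checked)."""
    from .domain_network import DomainGraph  # local import avoids a cycle

    with open(path) as fh:
        payload = json.load(fh)
    for key in ("nodes", "edges", "seed_proteins"):
        if key not in payload:
            raise ParseError(f"{path}: graph JSON missing key {key!r}")
    return DomainGraph.from_dict(payload)
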