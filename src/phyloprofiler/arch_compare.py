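"""Domain architectures and parsimonious conservation classification.

A domain architecture is the linear, N-terminal-to-C-terminal ordered
sequence of Pfam-A accessions on a protein, restricted to entries of type
``Domain`` or ``Family`` (the entry types that behave as independent folding
units; Repeat/Motif/Coiled-coil/Disordered entries are excluded).

Comparing a target ortholog's architecture against the reference yields one
of a small set of single-event explanations:

* ``CONSERVED``   — sequences identical;
* ``GAIN``        — the reference is a proper subsequence of the target
                    (a pure-insertion script exists);
* ``LOSS``        — the target is a proper subsequence of the reference;
* ``REARRANGEMENT`` — same domain multiset, different order;
* ``COMPLEX``     — none of the above: no single event class explains the
                    difference, i.e. several mixed gain/loss/reorder
                    histories are equally parsimonious;
* ``NO_DOMAINS``  — both architectures empty;
* ``NO_ORTHOLOG`` — no target ortholog to compare.

"Parsimonious" is made concrete as the minimum insert/delete script over
domain sequences (no substitution op), whose cost is
``|ref| + |tgt| - 2*LCS(ref, tgt)``.  Domain order always matters, and a
repeat-aware granular refinement (run-length encoding of adjacent identical
accessions) separates repeat copy-number changes from single-domain events.
"""

from __future__ import annotations

import dataclasses
import enum
from collections import Counter
from typing import Iterable, Mapping, Sequence

from .formats_io import DomainHit, Protein

__all__ = [
    "Architecture",
    "ArchClass",
    "GranularClass",
    "EditOp",
    "EditScript",
    "build_architecture",
    "edit_script",
    "collapse_repeats",
    "expand_repeats",
    "is_subsequence",
    "classify_pair",
    "DomainConservationMatrix",
    "build_domain_conservation_matrix",
    "ARCHCLASS_CODES",
]


@dataclasses.dataclass(frozen=True)
class Architecture:
    """Ordered N->C domain accession list for one protein (may be empty)."""

    protein_id: str
    domains: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.domains)


class ArchClass(enum.Enum):
    NO_ORTHOLOG = "no_ortholog"
    CONSERVED = "conserved"
    GAIN = "gain"
    LOSS = "loss"
    REARRANGEMENT = "rearrangement"
    COMPLEX = "complex"
    NO_DOMAINS = "no_domains"


class GranularClass(enum.Enum):
    IDENTICAL = "identical"
    SINGLE_GAIN = "single_gain"
    SINGLE_LOSS = "single_loss"
    REPEAT_EXPANSION = "repeat_expansion"
    REPEAT_CONTRACTION = "repeat_contraction"
    MIXED_GAIN = "mixed_gain"
    MIXED_LOSS = "mixed_loss"
    REORDERED = "reordered"
    COMPLEX = "complex"
    EMPTY_TARGET = "empty_target"
    EMPTY_REFERENCE = "empty_reference"
    EMPTY_BOTH = "empty_both"


#: Integer coding used when clustering domain-conservation heatmaps.
ARCHCLASS_CODES: dict[ArchClass, int] = {
    ArchClass.NO_ORTHOLOG: 0,
    ArchClass.NO_DOMAINS: 1,
    ArchClass.COMPLEX: 2,
    ArchClass.REARRANGEMENT: 3,
    ArchClass.LOSS: 4,
    ArchClass.GAIN: 5,
    ArchClass.CONSERVED: 6,
}

_ARCHITECTURE_ENTRY_TYPES = frozenset({"Domain", "Family"})


# ---------------------------------------------------------------------------
# Architecture extraction
# ---------------------------------------------------------------------------


def build_architecture(hits: Sequence[DomainHit], protein: Protein) -> Architecture:
    """Extract the ordered architecture of one protein from its Pfam hits.

    Hits are filtered to entry types Domain/Family, sorted N->C by alignment
    start (ties: end, then accession), and overlapping survivors are resolved
    by keeping the higher bit score (ties: lower E-value, then accession).
    """
    for h in hits:
        if h.protein_id != protein.protein_id:
            raise ValueError(
                f"hit on {h.protein_id!r} passed with protein {protein.protein_id!r}"
            )
    survivors = [h for h in hits if h.entry_type in _ARCHITECTURE_ENTRY_TYPES]
    # Greedy by score so the retained set never contains overlapping spans.
    ranked = sorted(survivors, key=lambda h: (-h.bit_score, h.e_value, h.hmm_acc))
    accepted: list[DomainHit] = []
    for h in ranked:
        if all(h.ali_end < a.ali_start or h.ali_start > a.ali_end for a in accepted):
            accepted.append(h)
    accepted.sort(key=lambda h: (h.ali_start, h.ali_end, h.hmm_acc))
    return Architecture(
        protein_id=protein.protein_id, domains=tuple(h.hmm_acc for h in accepted)
    )


# ---------------------------------------------------------------------------
# Edit scripts (insert/delete only)
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class EditOp:
    kind: str  # "delete" | "insert"
    position: int  # delete: index in the reference; insert: index in the target
    accession: str


@dataclasses.dataclass(frozen=True)
class EditScript:
    """A minimal insert/delete script transforming reference into target."""

    ops: tuple[EditOp, ...]

    @property
    def cost(self) -> int:
        return len(self.ops)

    def apply(self, ref: Sequence[str]) -> tuple[str, ...]:
        """Replay the script: deletions by reference index, then insertions
        by target index."""
        kept = list(ref)
        for op in sorted(
            (o for o in self.ops if o.kind == "delete"),
            key=lambda o: -o.position,
        ):
            if kept[op.position] != op.accession:
                raise ValueError(f"delete op mismatch at reference index {op.position}")
            del kept[op.position]
        for op in sorted(
            (o for o in self.ops if o.kind == "insert"), key=lambda o: o.position
        ):
            kept.insert(op.position, op.accession)
        return tuple(kept)


def _lcs_table(a: Sequence[str], b: Sequence[str]):
    n, m = len(a), len(b)
    lcs = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row, below = lcs[i], lcs[i + 1]
        for j in range(m - 1, -1, -1):
            row[j] = below[j + 1] + 1 if a[i] == b[j] else max(below[j], row[j + 1])
    return lcs


def edit_script(ref: Architecture | Sequence[str], tgt: Architecture | Sequence[str]) -> EditScript:
    """Minimum-cost insert/delete script from ``ref`` to ``tgt``.

    Cost equals ``|ref| + |tgt| - 2*LCS``.  Among equal-cost scripts the
    backtrace prefers deletions before insertions, scanning left to right,
    which makes the op sequence deterministic.
    """
    a = tuple(ref.domains if isinstance(ref, Architecture) else ref)
    b = tuple(tgt.domains if isinstance(tgt, Architecture) else tgt)
    lcs = _lcs_table(a, b)
    ops: list[EditOp] = []
    i = j = 0
    while i < len(a) and j < len(b):
        if a[i] == b[j] and lcs[i][j] == lcs[i + 1][j + 1] + 1:
            i += 1
            j += 1
        elif lcs[i + 1][j] == lcs[i][j]:  # deleting a[i] loses no common symbol
            ops.append(EditOp("delete", i, a[i]))
            i += 1
        else:
            ops.append(EditOp("insert", j, b[j]))
            j += 1
    for k in range(i, len(a)):
        ops.append(EditOp("delete", k, a[k]))
    for k in range(j, len(b)):
        ops.append(EditOp("insert", k, b[k]))
    return EditScript(ops=tuple(ops))


# ---------------------------------------------------------------------------
# Repeats
# ---------------------------------------------------------------------------


def collapse_repeats(arch: Architecture | Sequence[str]) -> list[tuple[str, int]]:
    """Run-length encode maximal runs of identical adjacent accessions."""
    seq = tuple(arch.domains if isinstance(arch, Architecture) else arch)
    runs: list[tuple[str, int]] = []
    for acc in seq:
        if runs and runs[-1][0] == acc:
            runs[-1] = (acc, runs[-1][1] + 1)
        else:
            runs.append((acc, 1))
    return runs


def expand_repeats(runs: Sequence[tuple[str, int]]) -> tuple[str, ...]:
    return tuple(acc for acc, n in runs for _ in range(n))


# ---------------------------------------------------------------------------
# Pairwise classification
# ---------------------------------------------------------------------------


def is_subsequence(needle: Sequence[str], haystack: Sequence[str]) -> bool:
    """Ordered, not necessarily contiguous containment (greedy two-pointer)."""
    it = iter(haystack)
    return all(any(x == y for y in it) for x in needle)


def classify_pair(
    ref: Architecture | Sequence[str] | None,
    tgt: Architecture | Sequence[str] | None,
) -> tuple[ArchClass, GranularClass | None, EditScript | None]:
    """Classify a target architecture against the reference.

    ``tgt=None`` encodes absence of an ortholog (``ref=None`` likewise for
    the symmetric direction).  The decision cascade tries each single-event
    explanation in turn and falls through to ``COMPLEX`` when none applies.
    """
    if ref is None or tgt is None:
        return ArchClass.NO_ORTHOLOG, None, None
    a = tuple(ref.domains if isinstance(ref, Architecture) else ref)
    b = tuple(tgt.domains if isinstance(tgt, Architecture) else tgt)
    script = edit_script(a, b)

    if not a and not b:
        return ArchClass.NO_DOMAINS, GranularClass.EMPTY_BOTH, script
    if a == b:
        return ArchClass.CONSERVED, GranularClass.IDENTICAL, script
    if is_subsequence(a, b):  # proper: a != b already established
        return ArchClass.GAIN, _granular_gain_loss(a, b, script, gain=True), script
    if is_subsequence(b, a):
        return ArchClass.LOSS, _granular_gain_loss(a, b, script, gain=False), script
    if Counter(a) == Counter(b):
        return ArchClass.REARRANGEMENT, GranularClass.REORDERED, script
    return ArchClass.COMPLEX, GranularClass.COMPLEX, script


def _granular_gain_loss(
    a: tuple[str, ...], b: tuple[str, ...], script: EditScript, gain: bool
) -> GranularClass:
    if gain and not a:
        return GranularClass.EMPTY_REFERENCE
    if not gain and not b:
        return GranularClass.EMPTY_TARGET
    runs_a, runs_b = collapse_repeats(a), collapse_repeats(b)
    if [acc for acc, _ in runs_a] == [acc for acc, _ in runs_b]:
        return GranularClass.REPEAT_EXPANSION if gain else GranularClass.REPEAT_CONTRACTION
    if script.cost == 1:
        return GranularClass.SINGLE_GAIN if gain else GranularClass.SINGLE_LOSS
    return GranularClass.MIXED_GAIN if gain else GranularClass.MIXED_LOSS


# ---------------------------------------------------------------------------
# Matrix over genes x species
# ---------------------------------------------------------------------------

# Tie-break priority when several target orthologs share the minimum edit
# cost: prefer the most conservative explanation.
_CLASS_PRIORITY: dict[ArchClass, int] = {
    ArchClass.CONSERVED: 0,
    ArchClass.NO_DOMAINS: 0,
    ArchClass.GAIN: 1,
    ArchClass.LOSS: 1,
    ArchClass.REARRANGEMENT: 2,
    ArchClass.COMPLEX: 3,
}


@dataclasses.dataclass
class DomainConservationMatrix:
    """Per-cell architecture conservation calls plus full per-ortholog detail.

    ``cells`` holds the call for the best (minimum-edit-cost) target ortholog
    of each (gene, species) pair; ``detail`` is one row per compared target
    ortholog, suitable for the downloadable summary TSV.
    """

    genes: list[str]
    species: list[str]
    cells: dict[tuple[str, str], tuple[ArchClass, GranularClass | None]]
    best_target: dict[tuple[str, str], str | None]
    detail: "list[dict]"

    def arch_class(self, gene: str, species: str) -> ArchClass:
        return self.cells[(gene, species)][0]

    def to_frame(self):
        import pandas as pd

        data = {
            sp: [self.cells[(g, sp)][0].value for g in self.genes]
            for sp in self.species
        }
        return pd.DataFrame(data, index=pd.Index(self.genes, name="gene"))

    def to_codes(self):
        import pandas as pd

        data = {
            sp: [ARCHCLASS_CODES[self.cells[(g, sp)][0]] for g in self.genes]
            for sp in self.species
        }
        return pd.DataFrame(data, index=pd.Index(self.genes, name="gene"))

    def detail_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.detail,
            columns=[
                "gene",
                "species",
                "target_gene",
                "arch_class",
                "granular_class",
                "edit_cost",
                "ref_arch",
                "tgt_arch",
            ],
        )


def build_domain_conservation_matrix(
    genes: Sequence[str],
    species: Sequence[str],
    records,
    reference_architectures: Mapping[str, Architecture],
    target_architectures: Mapping[str, Mapping[str, Architecture]],
) -> DomainConservationMatrix:
    """Classify every (gene, species) cell of the domain-conservation view.

    ``reference_architectures`` maps reference gene -> longest-peptide
    architecture; ``target_architectures`` maps species -> target gene ->
    architecture.  For 1:M / M:M cells every target ortholog is classified
    and the cell reports the minimum-edit-cost target (ties resolved toward
    the more conservative class, then lexicographic gene id); all
    per-ortholog calls are retained in ``detail``.
    """
    genes = list(genes)
    species = list(species)
    by_pair: dict[tuple[str, str], "object"] = {}
    for rec in records:
        by_pair[(rec.reference_gene, rec.target_species)] = rec

    cells: dict[tuple[str, str], tuple[ArchClass, GranularClass | None]] = {}
    best_target: dict[tuple[str, str], str | None] = {}
    detail: list[dict] = []
    for g in genes:
        if g not in reference_architectures:
            raise KeyError(f"no architecture for reference protein {g!r}")
        ref_arch = reference_architectures[g]
        for sp in species:
            rec = by_pair.get((g, sp))
            if rec is None:
                cells[(g, sp)] = (ArchClass.NO_ORTHOLOG, None)
                best_target[(g, sp)] = None
                continue
            calls: list[tuple[int, int, str, ArchClass, GranularClass]] = []
            for tgt_gene in sorted(rec.target_genes):
                sp_archs = target_architectures.get(sp, {})
                if tgt_gene not in sp_archs:
                    raise KeyError(f"no architecture for target protein {tgt_gene!r}")
                tgt_arch = sp_archs[tgt_gene]
                cls, gran, script = classify_pair(ref_arch, tgt_arch)
                cost = script.cost if script is not None else 0
                calls.append((cost, _CLASS_PRIORITY[cls], tgt_gene, cls, gran))
                detail.append(
                    {
                        "gene": g,
                        "species": sp,
                        "target_gene": tgt_gene,
                        "arch_class": cls.value,
                        "granular_class": gran.value,
                        "edit_cost": cost,
                        "ref_arch": ";".join(ref_arch.domains),
                        "tgt_arch": ";".join(tgt_arch.domains),
                    }
                )
            cost, _prio, tgt_gene, cls, gran = min(calls)
            cells[(g, sp)] = (cls, gran)
            best_target[(g, sp)] = tgt_gene
    return DomainConservationMatrix(
        genes=genes,
        species=species,
        cells=cells,
        best_target=best_target,
        detail=detail,
    )
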