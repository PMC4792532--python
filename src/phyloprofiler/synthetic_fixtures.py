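"""Seeded synthetic data with planted orthology and architecture events.

The generator emulates everything the pipeline consumes — an orthology
table, per-species pfam_scan-style domain hits, proteome FASTA files — for a
configurable number of reference genes and target species, together with
truth tables recording the planted relationship category and the planted
architecture event for every (gene, species) cell.  Events are realized
constructively (a gain really inserts a domain absent from the reference, a
rearrangement really swaps two distinct adjacent domains, ...), and each
transformed architecture is re-checked with the classifier at generation
time, so ground truth is exact rather than statistical.

Reference architectures are built so that every event class is realizable:
each has at least one tandem run (for repeat contraction), at least one
singleton domain (for a clean single loss), at least one pair of distinct
adjacent domains (for rearrangement) and uses fewer accessions than the
alphabet (so a novel domain exists to gain).

Species names come from a fixed fictional list; no real taxa are implied.
Everything is driven by one integer seed: fixed seed, byte-identical files.
"""

from __future__ import annotations

import dataclasses
import random
from pathlib import Path
from typing import Mapping

from . import arch_compare, formats_io, profile_engine
from .arch_compare import ArchClass, Architecture, GranularClass, classify_pair
from .formats_io import DomainHit, OrthologRecord, Protein
from .profile_engine import RelationshipCategory

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "RecoveryReport",
    "FICTIONAL_SPECIES",
    "EVENT_CLASSES",
    "generate_scenario",
    "write_scenario",
    "load_scenario_dir",
    "verify_recovery",
    "draw_relationship",
    "draw_event",
    "event_label",
]

REFERENCE_SPECIES = "Archetypus_primus"

FICTIONAL_SPECIES = (
    "Velutina_mirans",
    "Caelistella_aurora",
    "Pseudomorpha_lenta",
    "Quercivora_saltans",
    "Umbraculum_tacitum",
    "Nivalia_serpens",
    "Ferrodora_pallida",
    "Lucifuga_tremula",
    "Ostenta_vagans",
    "Petricola_fingens",
    "Aurantia_dormiens",
    "Brevicauda_errans",
    "Crystallina_mordax",
    "Dulcamara_rigida",
    "Echinopha_levis",
    "Fulgurita_modesta",
    "Glaucoma_stellata",
    "Hiemalis_curvata",
    "Ignota_plumosa",
    "Juncella_obliqua",
    "Kalotheca_rapax",
    "Limulita_verna",
    "Mirabilis_torta",
    "Noctiluca_pigra",
)

EVENT_CLASSES = (
    "conserved",
    "gain",
    "loss",
    "rearrangement",
    "complex",
    "repeat_expansion",
    "repeat_contraction",
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclasses.dataclass
class ScenarioConfig:
    """Knobs of one synthetic study.

    Relationship probabilities apply per (gene, species) cell and must sum
    to 1 with ``p_one_to_one``; ``event_mix`` is a distribution over the
    architecture event planted in each non-absent cell.
    """

    seed: int = 0
    n_species: int = 20
    n_genes: int = 200
    domain_alphabet_size: int = 30
    p_no_ortholog: float = 0.2
    p_one_to_one: float = 0.4
    p_one_to_many: float = 0.15
    p_many_to_one: float = 0.15
    p_many_to_many: float = 0.10
    event_mix: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "conserved": 0.30,
            "gain": 0.14,
            "loss": 0.14,
            "rearrangement": 0.10,
            "complex": 0.12,
            "repeat_expansion": 0.10,
            "repeat_contraction": 0.10,
        }
    )
    max_arch_len: int = 8

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_genes < 1:
            raise ValueError("n_species and n_genes must be >= 1")
        if self.domain_alphabet_size < 4:
            raise ValueError("domain alphabet must have at least 4 accessions")
        if self.max_arch_len < 4:
            raise ValueError("max_arch_len must be >= 4")
        probs = self.relationship_probs()
        if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1) > 1e-9:
            raise ValueError("relationship probabilities must be >= 0 and sum to 1")
        if set(self.event_mix) - set(EVENT_CLASSES):
            raise ValueError(f"unknown event classes: {set(self.event_mix) - set(EVENT_CLASSES)}")
        if any(p < 0 for p in self.event_mix.values()) or abs(
            sum(self.event_mix.values()) - 1
        ) > 1e-9:
            raise ValueError("event_mix must be >= 0 and sum to 1")

    def relationship_probs(self) -> dict[RelationshipCategory, float]:
        return {
            RelationshipCategory.NONE: self.p_no_ortholog,
            RelationshipCategory.ONE_TO_ONE: self.p_one_to_one,
            RelationshipCategory.ONE_TO_MANY: self.p_one_to_many,
            RelationshipCategory.MANY_TO_ONE: self.p_many_to_one,
            RelationshipCategory.MANY_TO_MANY: self.p_many_to_many,
        }


@dataclasses.dataclass
class Scenario:
    """In-memory view of one generated study."""

    config: ScenarioConfig
    genes: list[str]
    species: list[str]
    records: list[OrthologRecord]
    reference_architectures: dict[str, Architecture]
    target_architectures: dict[str, dict[str, Architecture]]
    hits: dict[str, list[DomainHit]]  # species -> hits (reference under its name)
    proteins: dict[str, list[Protein]]  # species -> proteins
    truth_profile: dict[tuple[str, str], str]
    truth_events: dict[tuple[str, str], str]


# ---------------------------------------------------------------------------
# Random draws
# ---------------------------------------------------------------------------


def draw_relationship(rng: random.Random, config: ScenarioConfig) -> RelationshipCategory:
    probs = config.relationship_probs()
    cats = list(probs)
    return rng.choices(cats, weights=[probs[c] for c in cats], k=1)[0]


def draw_event(rng: random.Random, config: ScenarioConfig) -> str:
    events = [e for e in EVENT_CLASSES if config.event_mix.get(e, 0.0) > 0]
    return rng.choices(events, weights=[config.event_mix[e] for e in events], k=1)[0]


# ---------------------------------------------------------------------------
# Architecture construction and event transforms
# ---------------------------------------------------------------------------


def _alphabet(config: ScenarioConfig) -> list[str]:
    return [f"PF{10000 + i:05d}" for i in range(config.domain_alphabet_size)]


def _make_reference_architecture(
    rng: random.Random, config: ScenarioConfig, max_tries: int = 200
) -> tuple[str, ...]:
    """A reference architecture on which every event class is realizable."""
    alphabet = _alphabet(config)
    for _ in range(max_tries):
        core_len = rng.randint(2, config.max_arch_len - 1)
        core = [rng.choice(alphabet) for _ in range(core_len)]
        dup_at = rng.randrange(core_len)
        arch = tuple(core[:dup_at] + [core[dup_at]] + core[dup_at:])
        if _all_events_realizable(arch, config):
            return arch
    raise RuntimeError(
        "could not draw a reference architecture realizing all event classes; "
        "increase domain_alphabet_size or max_arch_len"
    )


def _singleton_positions(arch: tuple[str, ...]) -> list[int]:
    """Indices that are runs of length one (deleting them is a clean single loss)."""
    positions, i = [], 0
    while i < len(arch):
        j = i
        while j < len(arch) and arch[j] == arch[i]:
            j += 1
        if j - i == 1:
            positions.append(i)
        i = j
    return positions


def _run_positions(arch: tuple[str, ...]) -> list[int]:
    """One index inside each maximal run of length >= 2."""
    positions, i = [], 0
    while i < len(arch):
        j = i
        while j < len(arch) and arch[j] == arch[i]:
            j += 1
        if j - i >= 2:
            positions.append(i)
        i = j
    return positions


def _distinct_adjacent_positions(arch: tuple[str, ...]) -> list[int]:
    return [i for i in range(len(arch) - 1) if arch[i] != arch[i + 1]]


def _all_events_realizable(arch: tuple[str, ...], config: ScenarioConfig) -> bool:
    return (
        len(arch) >= 2
        and len(set(arch)) >= 2
        and len(set(arch)) < config.domain_alphabet_size  # a novel accession exists
        and bool(_run_positions(arch))
        and bool(_singleton_positions(arch))
        and bool(_distinct_adjacent_positions(arch))
    )


def _apply_event(
    rng: random.Random, ref: tuple[str, ...], event: str, config: ScenarioConfig
) -> tuple[str, ...]:
    alphabet = _alphabet(config)
    novel = [a for a in alphabet if a not in ref]
    if event == "conserved":
        return ref
    if event == "gain":
        pos = rng.randint(0, len(ref))
        return ref[:pos] + (rng.choice(novel),) + ref[pos:]
    if event == "loss":
        pos = rng.choice(_singleton_positions(ref))
        return ref[:pos] + ref[pos + 1 :]
    if event == "rearrangement":
        pos = rng.choice(_distinct_adjacent_positions(ref))
        return ref[:pos] + (ref[pos + 1], ref[pos]) + ref[pos + 2 :]
    if event == "complex":
        pos = rng.choice(_singleton_positions(ref))
        trimmed = ref[:pos] + ref[pos + 1 :]
        ins = rng.randint(0, len(trimmed))
        return trimmed[:ins] + (rng.choice(novel),) + trimmed[ins:]
    if event == "repeat_expansion":
        pos = rng.randrange(len(ref))
        return ref[:pos] + (ref[pos],) + ref[pos:]
    if event == "repeat_contraction":
        pos = rng.choice(_run_positions(ref))
        return ref[:pos] + ref[pos + 1 :]
    raise ValueError(f"unknown event class: {event!r}")


_EXPECTED = {
    "conserved": (ArchClass.CONSERVED, GranularClass.IDENTICAL),
    "gain": (ArchClass.GAIN, GranularClass.SINGLE_GAIN),
    "loss": (ArchClass.LOSS, GranularClass.SINGLE_LOSS),
    "rearrangement": (ArchClass.REARRANGEMENT, GranularClass.REORDERED),
    "complex": (ArchClass.COMPLEX, GranularClass.COMPLEX),
    "repeat_expansion": (ArchClass.GAIN, GranularClass.REPEAT_EXPANSION),
    "repeat_contraction": (ArchClass.LOSS, GranularClass.REPEAT_CONTRACTION),
}


def _realize_event(
    rng: random.Random,
    ref: tuple[str, ...],
    event: str,
    config: ScenarioConfig,
    max_tries: int = 50,
) -> tuple[str, ...]:
    """Apply the transform and verify it realizes exactly the planted class;
    retry with fresh random choices rather than ever mislabeling."""
    for _ in range(max_tries):
        tgt = _apply_event(rng, ref, event, config)
        cls, gran, _ = classify_pair(ref, tgt)
        if (cls, gran) == _EXPECTED[event]:
            return tgt
    raise RuntimeError(f"event {event!r} unrealizable on architecture {ref}")


def event_label(cls: ArchClass, gran: GranularClass | None) -> str:
    """Map a classifier call back onto the generator's event vocabulary."""
    if cls is ArchClass.GAIN:
        return "repeat_expansion" if gran is GranularClass.REPEAT_EXPANSION else "gain"
    if cls is ArchClass.LOSS:
        return "repeat_contraction" if gran is GranularClass.REPEAT_CONTRACTION else "loss"
    return cls.value


# ---------------------------------------------------------------------------
# Scenario generation
# ---------------------------------------------------------------------------


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate a full in-memory scenario with exact planted truth."""
    rng = random.Random(config.seed)
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    species = list(FICTIONAL_SPECIES[: config.n_species])
    for i in range(len(species), config.n_species):
        species.append(f"Synthetica_fictae{i + 1:03d}")

    ref_archs: dict[str, Architecture] = {}
    tgt_archs: dict[str, dict[str, Architecture]] = {sp: {} for sp in species}
    records: list[OrthologRecord] = []
    truth_profile: dict[tuple[str, str], str] = {}
    truth_events: dict[tuple[str, str], str] = {}

    for g in genes:
        ref_seq = _make_reference_architecture(rng, config)
        ref_archs[g] = Architecture(protein_id=g, domains=ref_seq)
        for k, sp in enumerate(species):
            cat = draw_relationship(rng, config)
            truth_profile[(g, sp)] = cat.value
            if cat is RelationshipCategory.NONE:
                truth_events[(g, sp)] = ArchClass.NO_ORTHOLOG.value
                continue
            event = draw_event(rng, config)
            truth_events[(g, sp)] = event
            tgt_seq = _realize_event(rng, ref_seq, event, config)

            n_ref = 1 if cat in (RelationshipCategory.ONE_TO_ONE, RelationshipCategory.ONE_TO_MANY) else rng.randint(2, 3)
            n_tgt = 1 if cat in (RelationshipCategory.ONE_TO_ONE, RelationshipCategory.MANY_TO_ONE) else rng.randint(2, 3)
            ref_paralogs = frozenset(
                [g] + [f"{g}~p{j}" for j in range(1, n_ref)]
            )
            tgt_genes = frozenset(
                f"{sp[:4].upper()}{k:02d}_{g}_t{j}" for j in range(1, n_tgt + 1)
            )
            records.append(
                OrthologRecord(
                    group_id=f"grp_{g}_{k:02d}",
                    reference_gene=g,
                    target_species=sp,
                    target_genes=tgt_genes,
                    reference_paralogs=ref_paralogs,
                )
            )
            for tg in sorted(tgt_genes):
                tgt_archs[sp][tg] = Architecture(protein_id=tg, domains=tgt_seq)

    hits: dict[str, list[DomainHit]] = {}
    proteins: dict[str, list[Protein]] = {}
    hits[REFERENCE_SPECIES], proteins[REFERENCE_SPECIES] = _materialize(
        ref_archs.values(), REFERENCE_SPECIES
    )
    for sp in species:
        hits[sp], proteins[sp] = _materialize(tgt_archs[sp].values(), sp)

    return Scenario(
        config=config,
        genes=genes,
        species=species,
        records=records,
        reference_architectures=ref_archs,
        target_architectures=tgt_archs,
        hits=hits,
        proteins=proteins,
        truth_profile=truth_profile,
        truth_events=truth_events,
    )


def _materialize(architectures, species: str) -> tuple[list[DomainHit], list[Protein]]:
    """Turn architectures into pfam_scan-style hits plus FASTA proteins.

    Domains occupy 50-aa spans at a 60-aa pitch.  One decoy ``Motif`` hit is
    appended per protein past the last domain; it must be filtered out on
    the way back in and therefore exercises the entry-type filter end to
    end.
    """
    all_hits: list[DomainHit] = []
    prots: list[Protein] = []
    for arch in sorted(architectures, key=lambda a: a.protein_id):
        n = len(arch.domains)
        length = 60 * n + 80
        for i, acc in enumerate(arch.domains):
            start = 1 + 60 * i
            num = int(acc[2:])
            all_hits.append(
                DomainHit(
                    protein_id=arch.protein_id,
                    ali_start=start,
                    ali_end=start + 49,
                    env_start=max(1, start - 2),
                    env_end=start + 51,
                    hmm_acc=acc,
                    hmm_name=f"dom{num}",
                    entry_type="Domain" if num % 2 else "Family",
                    bit_score=50.0 + (num % 7),
                    e_value=1e-12,
                    clan=f"CL{num % 5:04d}",
                )
            )
        decoy_start = 60 * n + 5
        all_hits.append(
            DomainHit(
                protein_id=arch.protein_id,
                ali_start=decoy_start,
                ali_end=decoy_start + 19,
                env_start=decoy_start,
                env_end=decoy_start + 20,
                hmm_acc="PF99999",
                hmm_name="decoy_motif",
                entry_type="Motif",
                bit_score=20.0,
                e_value=1e-3,
                clan="CL9999",
            )
        )
        seq = ("M" + _AA * (length // len(_AA) + 1))[:length]
        prots.append(
            Protein(
                protein_id=arch.protein_id,
                species=species,
                gene_id=arch.protein_id,
                length=length,
                sequence=seq,
            )
        )
    return all_hits, prots


# ---------------------------------------------------------------------------
# On-disk emission / loading
# ---------------------------------------------------------------------------


def write_scenario(scenario: Scenario, out_dir: str | Path) -> dict[str, Path]:
    """Emit orth.tsv, arch/<species>.tsv, proteome/<species>.fasta and the
    two truth tables.  Deterministic: fixed seed means byte-identical files."""
    out = Path(out_dir)
    (out / "arch").mkdir(parents=True, exist_ok=True)
    (out / "proteome").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["orthologs"] = out / "orth.tsv"
    formats_io.write_simple_ortholog_tsv(scenario.records, paths["orthologs"])

    for sp in [REFERENCE_SPECIES] + scenario.species:
        arch_path = out / "arch" / f"{sp}.tsv"
        formats_io.write_pfamscan(scenario.hits[sp], arch_path)
        paths[f"arch/{sp}"] = arch_path
        fasta_path = out / "proteome" / f"{sp}.fasta"
        formats_io.write_fasta(scenario.proteins[sp], fasta_path)
        paths[f"proteome/{sp}"] = fasta_path

    import pandas as pd

    profile_df = pd.DataFrame(
        {
            sp: [scenario.truth_profile[(g, sp)] for g in scenario.genes]
            for sp in scenario.species
        },
        index=pd.Index(scenario.genes, name="gene"),
    )
    events_df = pd.DataFrame(
        {
            sp: [scenario.truth_events[(g, sp)] for g in scenario.genes]
            for sp in scenario.species
        },
        index=pd.Index(scenario.genes, name="gene"),
    )
    paths["truth_profile"] = out / "truth_profile.tsv"
    paths["truth_domcons"] = out / "truth_domcons.tsv"
    formats_io.write_matrix_tsv(profile_df, paths["truth_profile"])
    formats_io.write_matrix_tsv(events_df, paths["truth_domcons"])

    with open(out / "species_order.txt", "w") as fh:
        fh.write("\n".join(scenario.species) + "\n")
    with open(out / "genes.txt", "w") as fh:
        fh.write("\n".join(scenario.genes) + "\n")
    paths["species_order"] = out / "species_order.txt"
    paths["genes"] = out / "genes.txt"
    return paths


def load_scenario_dir(out_dir: str | Path):
    """Re-read an emitted scenario through the public readers.

    Returns (genes, species, records, reference architectures, per-species
    target architectures, truth profile frame, truth event frame).
    """
    out = Path(out_dir)
    genes = (out / "genes.txt").read_text().split()
    species = (out / "species_order.txt").read_text().split()
    records = formats_io.read_ortholog_table(out / "orth.tsv", dialect="simple_tsv")

    def _arch_map(sp: str) -> dict[str, Architecture]:
        hits = formats_io.read_pfamscan(out / "arch" / f"{sp}.tsv")
        prots = formats_io.read_fasta(out / "proteome" / f"{sp}.fasta", species=sp)
        by_protein: dict[str, list[DomainHit]] = {}
        for h in hits:
            by_protein.setdefault(h.protein_id, []).append(h)
        archs: dict[str, Architecture] = {}
        for p in prots:
            rep = formats_io.longest_peptide(p.gene_id or p.protein_id, prots)
            archs[p.gene_id or p.protein_id] = arch_compare.build_architecture(
                by_protein.get(rep.protein_id, []), rep
            )
        return archs

    ref_archs = _arch_map(REFERENCE_SPECIES)
    tgt_archs = {sp: _arch_map(sp) for sp in species}
    truth_profile = formats_io.read_matrix_tsv(out / "truth_profile.tsv")
    truth_events = formats_io.read_matrix_tsv(out / "truth_domcons.tsv")
    return genes, species, records, ref_archs, tgt_archs, truth_profile, truth_events


# ---------------------------------------------------------------------------
# Recovery verification
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RecoveryReport:
    n_cells: int
    relationship_correct: int
    event_correct: int
    relationship_confusion: dict[tuple[str, str], int]
    event_confusion: dict[tuple[str, str], int]

    @property
    def relationship_accuracy(self) -> float:
        return self.relationship_correct / self.n_cells

    @property
    def event_accuracy(self) -> float:
        return self.event_correct / self.n_cells


def verify_recovery(out_dir: str | Path) -> RecoveryReport:
    """Run the profile and architecture classifiers over an emitted scenario
    and tally agreement with the planted truth, cell by cell."""
    genes, species, records, ref_archs, tgt_archs, truth_profile, truth_events = (
        load_scenario_dir(out_dir)
    )
    profile = profile_engine.build_profile_matrix(genes, species, records)
    domcons = arch_compare.build_domain_conservation_matrix(
        genes, species, records, ref_archs, tgt_archs
    )
    rel_conf: dict[tuple[str, str], int] = {}
    ev_conf: dict[tuple[str, str], int] = {}
    rel_ok = ev_ok = n = 0
    for g in genes:
        for sp in species:
            n += 1
            truth_cat = truth_profile.loc[g, sp]
            called_cat = profile.cells[(g, sp)].value
            rel_conf[(truth_cat, called_cat)] = rel_conf.get((truth_cat, called_cat), 0) + 1
            rel_ok += truth_cat == called_cat
            truth_ev = truth_events.loc[g, sp]
            cls, gran = domcons.cells[(g, sp)]
            called_ev = event_label(cls, gran)
            ev_conf[(truth_ev, called_ev)] = ev_conf.get((truth_ev, called_ev), 0) + 1
            ev_ok += truth_ev == called_ev
    return RecoveryReport(
        n_cells=n,
        relationship_correct=rel_ok,
        event_correct=ev_ok,
        relationship_confusion=rel_conf,
        event_confusion=ev_conf,
    )
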