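"""Architecture extraction, edit scripts and conservation classification."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_classify, brute_edit_cost

from phyloprofiler.arch_compare import (
    ArchClass,
    Architecture,
    GranularClass,
    build_architecture,
    build_domain_conservation_matrix,
    classify_pair,
    collapse_repeats,
    edit_script,
    expand_repeats,
)
from phyloprofiler.formats_io import DomainHit, OrthologRecord, Protein

accessions = st.sampled_from(["A", "B", "C"])
short_archs = st.lists(accessions, min_size=0, max_size=6).map(tuple)


def _hit(pid="P1", start=1, end=None, acc="PF00001", etype="Domain", bits=50.0, ev=1e-10):
    end = end if end is not None else start + 49
    return DomainHit(
        protein_id=pid,
        ali_start=start,
        ali_end=end,
        env_start=start,
        env_end=end + 2,
        hmm_acc=acc,
        hmm_name=acc.lower(),
        entry_type=etype,
        bit_score=bits,
        e_value=ev,
    )


PROT = Protein(protein_id="P1", length=1000)


class TestBuildArchitecture:
    def test_sorted_n_to_c(self):
        hits = [_hit(start=s, acc=f"PF{s:05d}") for s in (200, 10, 90)]
        arch = build_architecture(hits, PROT)
        assert arch.domains == ("PF00010", "PF00090", "PF00200")

    def test_non_domain_family_types_filtered(self):
        hits = [
            _hit(start=1 + 60 * i, acc=f"PF{i:05d}", etype=t)
            for i, t in enumerate(["Repeat", "Motif", "Coiled-coil", "Disordered"])
        ]
        assert build_architecture(hits, PROT).domains == ()

    def test_family_entries_contribute(self):
        hits = [_hit(start=1, acc="PF00001", etype="Family")]
        assert build_architecture(hits, PROT).domains == ("PF00001",)

    def test_overlap_resolved_by_bit_score(self):
        hits = [
            _hit(start=50, end=80, acc="PF11111", bits=40.0),
            _hit(start=60, end=95, acc="PF22222", bits=55.0),
        ]
        assert build_architecture(hits, PROT).domains == ("PF22222",)

    def test_overlap_tie_broken_by_evalue_then_accession(self):
        hits = [
            _hit(start=50, end=80, acc="PF11111", bits=50.0, ev=1e-5),
            _hit(start=60, end=95, acc="PF22222", bits=50.0, ev=1e-9),
        ]
        assert build_architecture(hits, PROT).domains == ("PF22222",)

    @given(st.integers(min_value=0, max_value=5000))
    @settings(max_examples=50, deadline=None)
    def test_disjoint_hits_survive_in_start_order(self, seed):
        r = random.Random(seed)
        n = r.randint(0, 8)
        starts = sorted(r.sample(range(1, 900, 60), n))
        hits = [
            _hit(start=s, acc=f"PF{r.randint(1, 30):05d}", bits=r.uniform(20, 90))
            for s in starts
        ]
        r.shuffle(hits)
        arch = build_architecture(hits, PROT)
        assert arch.domains == tuple(
            h.hmm_acc for h in sorted(hits, key=lambda h: h.ali_start)
        )

    def test_foreign_hit_rejected(self):
        with pytest.raises(ValueError, match="P2"):
            build_architecture([_hit(pid="P2")], PROT)


class TestEditScript:
    def test_single_deletion(self):
        s = edit_script(("A", "B", "C"), ("A", "C"))
        assert s.cost == 1
        assert s.ops[0].kind == "delete" and s.ops[0].accession == "B"

    def test_disjoint_symbols(self):
        assert edit_script(("A",), ("B",)).cost == 2

    @given(short_archs, short_archs)
    @settings(max_examples=200, deadline=None)
    def test_script_applies_to_reach_target(self, a, b):
        assert edit_script(a, b).apply(a) == b

    @given(short_archs, short_archs, short_archs)
    @settings(max_examples=150, deadline=None)
    def test_cost_triangle_inequality(self, a, b, c):
        assert edit_script(a, c).cost <= edit_script(a, b).cost + edit_script(b, c).cost

    def test_cost_matches_brute_force_on_all_short_pairs(self):
        """Exhaustive check over all pairs of length <= 3 here (the full
        length-4 sweep runs in the acceptance tests)."""
        universe = [
            tuple(p)
            for n in range(4)
            for p in itertools.product("ABC", repeat=n)
        ]
        for a, b in itertools.product(universe, repeat=2):
            assert edit_script(a, b).cost == brute_edit_cost(a, b)


class TestCollapseRepeats:
    def test_run_length_encoding(self):
        assert collapse_repeats(("L", "E", "E", "E")) == [("L", 1), ("E", 3)]

    def test_empty(self):
        assert collapse_repeats(()) == []

    @given(short_archs)
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, arch):
        runs = collapse_repeats(arch)
        assert expand_repeats(runs) == arch
        assert all(n >= 1 for _, n in runs)
        assert all(x != y for (x, _), (y, _) in zip(runs, runs[1:]))


class TestClassifyPair:
    @pytest.mark.parametrize(
        "ref,tgt,cls,gran",
        [
            (("A", "B"), ("A", "B"), ArchClass.CONSERVED, GranularClass.IDENTICAL),
            (("A", "B"), ("B", "A"), ArchClass.REARRANGEMENT, GranularClass.REORDERED),
            (("A", "B"), ("A", "C"), ArchClass.COMPLEX, GranularClass.COMPLEX),
            ((), (), ArchClass.NO_DOMAINS, GranularClass.EMPTY_BOTH),
            (("A",), (), ArchClass.LOSS, GranularClass.EMPTY_TARGET),
            ((), ("A",), ArchClass.GAIN, GranularClass.EMPTY_REFERENCE),
            (("A", "B"), ("A", "C", "B"), ArchClass.GAIN, GranularClass.SINGLE_GAIN),
            (
                ("A", "B", "C", "D"),
                ("A", "D"),
                ArchClass.LOSS,
                GranularClass.MIXED_LOSS,
            ),
        ],
    )
    def test_cascade_examples(self, ref, tgt, cls, gran):
        got_cls, got_gran, _ = classify_pair(ref, tgt)
        assert (got_cls, got_gran) == (cls, gran)

    def test_absent_ortholog(self):
        assert classify_pair(("A",), None)[0] is ArchClass.NO_ORTHOLOG

    def test_repeat_contraction_and_expansion(self):
        """One fewer copy within a tandem repeat: a loss whose granular call
        is repeat contraction; the reverse comparison is a repeat
        expansion."""
        ref = ("L", "L", "E", "E", "E", "G")
        tgt = ("L", "L", "E", "E", "G")
        assert classify_pair(ref, tgt)[:2] == (
            ArchClass.LOSS,
            GranularClass.REPEAT_CONTRACTION,
        )
        assert classify_pair(tgt, ref)[:2] == (
            ArchClass.GAIN,
            GranularClass.REPEAT_EXPANSION,
        )

    @given(short_archs, short_archs)
    @settings(max_examples=300, deadline=None)
    def test_antisymmetry_and_symmetry(self, a, b):
        cls_ab = classify_pair(a, b)[0]
        cls_ba = classify_pair(b, a)[0]
        if cls_ab is ArchClass.GAIN:
            assert cls_ba is ArchClass.LOSS
        elif cls_ab is ArchClass.LOSS:
            assert cls_ba is ArchClass.GAIN
        else:
            assert cls_ba is cls_ab

    @given(short_archs, short_archs)
    @settings(max_examples=300, deadline=None)
    def test_rearrangement_implies_equal_multiset(self, a, b):
        from collections import Counter

        cls = classify_pair(a, b)[0]
        if cls is ArchClass.REARRANGEMENT:
            assert Counter(a) == Counter(b) and a != b

    def test_agrees_with_brute_force_on_short_pairs(self):
        universe = [
            tuple(p)
            for n in range(4)
            for p in itertools.product("ABC", repeat=n)
        ]
        for a, b in itertools.product(universe, repeat=2):
            assert classify_pair(a, b)[0] is brute_classify(a, b)


class TestDomainConservationMatrix:
    def _setup(self, target_archs_by_gene):
        ref = {"gA": Architecture("gA", ("A", "B"))}
        rec = OrthologRecord(
            group_id="c1",
            reference_gene="gA",
            target_species="sp1",
            target_genes=frozenset(target_archs_by_gene),
            reference_paralogs=frozenset({"gA"}),
        )
        tgt = {
            "sp1": {
                g: Architecture(g, arch) for g, arch in target_archs_by_gene.items()
            }
        }
        return build_domain_conservation_matrix(["gA"], ["sp1"], [rec], ref, tgt)

    def test_no_ortholog_cell(self):
        ref = {"gA": Architecture("gA", ("A",))}
        m = build_domain_conservation_matrix(["gA"], ["sp1"], [], ref, {"sp1": {}})
        assert m.arch_class("gA", "sp1") is ArchClass.NO_ORTHOLOG
        assert m.best_target[("gA", "sp1")] is None

    def test_single_ortholog_equals_classify_pair(self):
        m = self._setup({"t1": ("A", "C", "B")})
        assert m.cells[("gA", "sp1")] == (ArchClass.GAIN, GranularClass.SINGLE_GAIN)

    def test_one_to_two_best_is_min_cost_with_detail(self):
        m = self._setup({"t1": ("A", "B"), "t2": ("A", "Z", "Q")})
        assert m.arch_class("gA", "sp1") is ArchClass.CONSERVED
        assert m.best_target[("gA", "sp1")] == "t1"
        detail = m.detail_frame()
        assert set(detail["target_gene"]) == {"t1", "t2"}
        assert set(detail["arch_class"]) == {"conserved", "complex"}

    def test_missing_architecture_names_protein(self):
        ref = {"gA": Architecture("gA", ("A",))}
        rec = OrthologRecord(
            group_id="c1",
            reference_gene="gA",
            target_species="sp1",
            target_genes=frozenset({"tMissing"}),
            reference_paralogs=frozenset({"gA"}),
        )
        with pytest.raises(KeyError, match="tMissing"):
            build_domain_conservation_matrix(["gA"], ["sp1"], [rec], ref, {"sp1": {}})

    def test_planted_events_recovered(self, small_scenario):
        from phyloprofiler.synthetic_fixtures import event_label

        scenario, _ = small_scenario
        m = build_domain_conservation_matrix(
            scenario.genes,
            scenario.species,
            scenario.records,
            scenario.reference_architectures,
            scenario.target_architectures,
        )
        for (g, sp), want in scenario.truth_events.items():
            cls, gran = m.cells[(g, sp)]
            assert event_label(cls, gran) == want
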