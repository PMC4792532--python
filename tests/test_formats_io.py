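"""I/O: pfam_scan parsing, ortholog tables, FASTA, serializer round trips."""

import random

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyloprofiler import formats_io
from phyloprofiler.domain_network import Architecture, build_adjacency_graph
from phyloprofiler.formats_io import (
    DomainHit,
    ParseError,
    Protein,
    longest_peptide,
    read_fasta,
    read_ortholog_table,
    read_pfamscan,
)

PFAM_LINE = (
    "P1 5 100 3 102 PF00001.21 7tm_1 Domain 1 250 268 55.2 1.2e-14 1 CL0192"
)


class TestReadPfamscan:
    def test_field_mapping_and_version_stripping(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("# comment\n" + PFAM_LINE + "\n")
        (hit,) = read_pfamscan(path)
        assert hit.protein_id == "P1"
        assert (hit.ali_start, hit.ali_end) == (5, 100)
        assert hit.hmm_acc == "PF00001"  # version suffix removed
        assert hit.entry_type == "Domain"
        assert hit.bit_score == pytest.approx(55.2)
        assert hit.e_value == pytest.approx(1.2e-14)
        assert hit.clan == "CL0192"

    def test_comment_only_file_is_empty(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("# a\n# b\n\n")
        assert read_pfamscan(path) == []

    def test_order_preserved_with_interleaved_comments(self, tmp_path):
        lines = []
        for i, pid in enumerate(["Pa", "Pb", "Pc"]):
            lines.append(f"# block {i}")
            lines.append(PFAM_LINE.replace("P1", pid, 1))
        path = tmp_path / "hits.tsv"
        path.write_text("\n".join(lines) + "\n")
        assert [h.protein_id for h in read_pfamscan(path)] == ["Pa", "Pb", "Pc"]

    @pytest.mark.parametrize(
        "bad",
        ["P1 5 100", PFAM_LINE.replace(" 5 ", " five ", 1)],
        ids=["too-few-fields", "non-numeric-coordinate"],
    )
    def test_malformed_line_names_line_number(self, tmp_path, bad):
        path = tmp_path / "hits.tsv"
        path.write_text("# ok\n" + bad + "\n")
        with pytest.raises(ParseError, match=":2"):
            read_pfamscan(path)

    def test_writer_reader_round_trip_is_byte_stable(self, tmp_path, rng):
        hits = [
            DomainHit(
                protein_id=f"P{i}",
                ali_start=1 + 60 * i,
                ali_end=50 + 60 * i,
                env_start=60 * i + 1,
                env_end=52 + 60 * i,
                hmm_acc=f"PF{rng.randint(1, 99999):05d}",
                hmm_name=f"n{i}",
                entry_type=rng.choice(["Domain", "Family", "Motif"]),
                bit_score=round(rng.uniform(10, 300), 1),
                e_value=10 ** -rng.randint(3, 40),
                clan=f"CL{rng.randint(0, 999):04d}",
            )
            for i in range(25)
        ]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        formats_io.write_pfamscan(hits, p1)
        back = read_pfamscan(p1)
        assert back == hits
        formats_io.write_pfamscan(back, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestOrthologTables:
    def _sqltable(self, tmp_path, rows):
        path = tmp_path / "sqltable.tsv"
        path.write_text("\n".join("\t".join(map(str, r)) for r in rows) + "\n")
        return path

    def test_minimal_cluster(self, tmp_path):
        path = self._sqltable(
            tmp_path,
            [(1, 900, "refsp", "1.0", "gA"), (1, 900, "tgtsp", "1.0", "gX")],
        )
        (rec,) = read_ortholog_table(path, "inparanoid_sqltable", "refsp")
        assert rec.reference_gene == "gA"
        assert rec.reference_paralogs == {"gA"}
        assert rec.target_genes == {"gX"}
        assert rec.target_species == "tgtsp"

    def test_one_to_many_cluster(self, tmp_path):
        path = self._sqltable(
            tmp_path,
            [
                (1, 900, "refsp", "1.0", "gA"),
                (1, 900, "tgtsp", "1.0", "gX"),
                (1, 880, "tgtsp", "0.7", "gY"),
            ],
        )
        (rec,) = read_ortholog_table(path, "inparanoid_sqltable", "refsp")
        assert rec.target_genes == {"gX", "gY"}

    def test_many_to_one_yields_record_per_reference_gene(self, tmp_path):
        path = self._sqltable(
            tmp_path,
            [
                (7, 900, "refsp", "1.0", "gA"),
                (7, 850, "refsp", "0.6", "gB"),
                (7, 900, "tgtsp", "1.0", "gX"),
            ],
        )
        recs = read_ortholog_table(path, "inparanoid_sqltable", "refsp")
        assert [r.reference_gene for r in recs] == ["gA", "gB"]
        assert all(r.reference_paralogs == {"gA", "gB"} for r in recs)

    def test_three_species_cluster_rejected(self, tmp_path):
        path = self._sqltable(
            tmp_path,
            [
                (1, 900, "refsp", "1.0", "gA"),
                (1, 900, "tgtsp", "1.0", "gX"),
                (1, 900, "thirdsp", "1.0", "gZ"),
            ],
        )
        with pytest.raises(ParseError, match="pairwise"):
            read_ortholog_table(path, "inparanoid_sqltable", "refsp")

    def test_unknown_dialect(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("")
        with pytest.raises(ValueError, match="dialect"):
            read_ortholog_table(path, "mystery")

    def test_simple_tsv_round_trip(self, tmp_path):
        path = tmp_path / "orth.tsv"
        path.write_text(
            "reference_gene\ttarget_species\ttarget_gene\tgroup_id\n"
            "gA\tsp1\tgX\tc1\n"
            "gA\tsp1\tgY\tc1\n"
            "gA\tsp2\tgZ\tc2\n"
        )
        recs = read_ortholog_table(path, "simple_tsv")
        out = tmp_path / "back.tsv"
        formats_io.write_simple_ortholog_tsv(recs, out)
        assert read_ortholog_table(out, "simple_tsv") == recs


class TestFasta:
    def test_basic_record(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">P1\nMKV\n")
        (prot,) = read_fasta(path)
        assert (prot.protein_id, prot.length) == ("P1", 3)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">P1\nMKV\n>P1\nMM\n")
        with pytest.raises(ParseError, match="P1"):
            read_fasta(path)

    def test_crlf_equals_lf(self, tmp_path):
        lf, crlf = tmp_path / "lf.fasta", tmp_path / "crlf.fasta"
        text = ">P1 gene=g1\nMKVLT\n>P2\nAC\n"
        lf.write_text(text)
        crlf.write_bytes(text.replace("\n", "\r\n").encode())
        assert read_fasta(lf) == read_fasta(crlf)

    def test_write_read_round_trip(self, tmp_path):
        prots = [
            Protein(protein_id="P1", gene_id="g1", length=5, sequence="MKVLT"),
            Protein(protein_id="P2", length=2, sequence="AC"),
        ]
        path = tmp_path / "p.fasta"
        formats_io.write_fasta(prots, path)
        back = read_fasta(path)
        assert [(p.protein_id, p.gene_id, p.sequence) for p in back] == [
            ("P1", "g1", "MKVLT"),
            ("P2", "", "AC"),
        ]


class TestLongestPeptide:
    PROTS = [
        Protein(protein_id="P2", gene_id="g", length=250, sequence=None),
        Protein(protein_id="P1", gene_id="g", length=100),
    ]

    def test_picks_longest(self):
        assert longest_peptide("g", self.PROTS).protein_id == "P2"

    def test_single_isoform_identity(self):
        assert longest_peptide("g", self.PROTS[:1]).protein_id == "P2"

    def test_missing_gene_raises(self):
        with pytest.raises(KeyError):
            longest_peptide("absent", self.PROTS)

    def test_tie_break_invariant_to_input_order(self):
        import itertools

        prots = [
            Protein(protein_id=pid, gene_id="g", length=100)
            for pid in ("Pb", "Pa", "Pc")
        ]
        for perm in itertools.permutations(prots):
            assert longest_peptide("g", list(perm)).protein_id == "Pa"


class TestMatrixAndGraphSerialization:
    def test_empty_matrix_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["sp1", "sp2"], index=pd.Index([], name="gene"))
        path = tmp_path / "m.tsv"
        formats_io.write_matrix_tsv(df, path)
        assert path.read_text() == "gene\tsp1\tsp2\n"

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None)
    def test_random_matrix_round_trip(self, seed):
        r = random.Random(seed)
        df = pd.DataFrame(
            [[r.randint(0, 4) for _ in range(5)] for _ in range(5)],
            index=pd.Index([f"g{i}" for i in range(5)], name="gene"),
            columns=[f"sp{j}" for j in range(5)],
        )
        import tempfile, os

        fd, path = tempfile.mkstemp(suffix=".tsv")
        os.close(fd)
        try:
            formats_io.write_matrix_tsv(df, path)
            back = formats_io.read_matrix_tsv(path, numeric=True)
            pd.testing.assert_frame_equal(back, df)
        finally:
            os.unlink(path)

    def test_graph_json_round_trip(self, tmp_path):
        graph = build_adjacency_graph(
            [
                Architecture("P1", ("A", "B", "B")),
                Architecture("P2", ("B", "C")),
            ]
        )
        path = tmp_path / "g.json"
        formats_io.write_graph(graph, path, format="json")
        back = formats_io.read_graph_json(path)
        assert back.to_dict() == graph.to_dict()

    def test_graphml_single_edge(self, tmp_path):
        import networkx as nx

        graph = build_adjacency_graph([Architecture("P1", ("A", "B"))])
        path = tmp_path / "g.graphml"
        formats_io.write_graph(graph, path, format="graphml")
        g = nx.read_graphml(path)
        assert sorted(g.nodes) == ["A", "B"]
        assert list(g.edges) == [("A", "B")]
        assert g.is_directed()
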