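"""Format readers/writers and the taxonomy index."""
import gzip
import textwrap

import pytest

from phylosample import (
    build_index,
    make_tree,
    parse_gtdb_taxonomy_string,
    parse_newick,
    read_gtdb_metadata,
    read_ncbi_taxonomy,
    read_newick,
    write_newick,
    write_selection,
)
from phylosample.errors import (
    FormatError,
    NewickParseError,
    SchemaError,
    TaxonomyError,
)
from hypothesis import given, settings
from hypothesis import strategies as st

from phylosample.tax_sampler import Selection, SelectionEntry
from phylosample.taxonomy_io import (
    CANONICAL_RANKS,
    GTDB_PREFIXES,
    GenomeRecord,
    detect_source,
    normalize_accession,
)

from conftest import record


class TestGtdbTaxonomyString:
    def test_full_string_parses_all_seven_ranks(self):
        lin = parse_gtdb_taxonomy_string(
            "d__Bacteria;p__Planctomycetota;c__Planctomycetia;o__X;f__Y;g__Z;s__Z sp1"
        )
        assert lin.get("phylum") == "Planctomycetota"
        assert lin.get("class") == "Planctomycetia"
        assert [r for r, _ in lin.ranks] == list(CANONICAL_RANKS)

    def test_empty_fields_become_placeholders(self):
        lin = parse_gtdb_taxonomy_string("d__Archaea;p__;c__;o__;f__;g__;s__")
        assert lin.get("domain") == "Archaea"
        assert [lin.get(r) for r in CANONICAL_RANKS[1:]] == [
            "p__", "c__", "o__", "f__", "g__", "s__",
        ]

    @pytest.mark.parametrize(
        "bad",
        ["d__Bacteria;p__A;c__B", "x__Bacteria;p__;c__;o__;f__;g__;s__"],
        ids=["wrong-field-count", "bad-prefix"],
    )
    def test_malformed_strings_raise_format_error(self, bad):
        with pytest.raises(FormatError):
            parse_gtdb_taxonomy_string(bad)


class TestAccessions:
    @pytest.mark.parametrize(
        "acc,normalized,source",
        [
            ("GCF_000001.1", "GCF_000001.1", "refseq"),
            ("GCA_000001.1", "GCA_000001.1", "genbank"),
            ("RS_GCF_000001.1", "GCF_000001.1", "refseq"),
            ("GB_GCA_000001.1", "GCA_000001.1", "genbank"),
            ("XYZ_1", "XYZ_1", "unknown"),
        ],
    )
    def test_gtdb_prefix_stripping_and_source_detection(self, acc, normalized, source):
        assert normalize_accession(acc) == normalized
        assert detect_source(acc) == source


class TestGtdbMetadata:
    def test_three_row_fixture(self, metadata_tsv):
        records = read_gtdb_metadata(metadata_tsv)
        assert len(records) == 3
        assert records[0].lineage.get("phylum") == "Planctomycetota"
        assert records[0].completeness == 97.3
        assert records[0].contamination == 1.2
        assert records[2].accession == "GCF_000000003.1"  # RS_ stripped
        assert records[2].source == "refseq"

    def test_gzip_input_is_transparent(self, metadata_tsv, tmp_path):
        gz = tmp_path / "meta.tsv.gz"
        gz.write_bytes(gzip.compress(metadata_tsv.read_bytes()))
        assert len(read_gtdb_metadata(gz)) == 3

    def test_missing_taxonomy_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("accession\tfoo\nGCA_1.1\tx\n")
        with pytest.raises(SchemaError, match="gtdb_taxonomy"):
            read_gtdb_metadata(path)

    def test_unparseable_row_reports_row_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "accession\tgtdb_taxonomy\nGCA_1.1\td__B;p__A;c__C\n"
        )
        with pytest.raises(FormatError, match="row 2"):
            read_gtdb_metadata(path)


_taxon_name = st.text(
    alphabet="abcdefghijklmnopqrstuvwxyzABCDE0123456789-", min_size=1, max_size=12
)


class TestLineageProperties:
    @given(names=st.lists(_taxon_name, min_size=7, max_size=7))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_gtdb_string_roundtrip(self, names):
        s = ";".join(p + n for p, n in zip(GTDB_PREFIXES, names))
        lin = parse_gtdb_taxonomy_string(s)
        assert lin.to_gtdb_string() == s

    @given(present=st.lists(st.booleans(), min_size=7, max_size=7))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_missing_ranks_become_placeholders_never_dropped(self, present):
        s = ";".join(p + ("Tax" if keep else "") for p, keep in zip(GTDB_PREFIXES, present))
        lin = parse_gtdb_taxonomy_string(s)
        assert len(lin.ranks) == 7
        for (rank, name), prefix, keep in zip(lin.ranks, GTDB_PREFIXES, present):
            assert name == ("Tax" if keep else prefix)


class TestIndexProperties:
    @given(
        assignments=st.lists(
            st.tuples(st.sampled_from("AB"), st.sampled_from("XYZ"), st.sampled_from("mn")),
            min_size=1,
            max_size=30,
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_count_sum_rule_holds_for_arbitrary_taxonomies(self, assignments):
        records = [
            record(f"GCA_{i:06d}.1", p=f"p{p}", c=f"c{p}{c}", g=f"g{p}{c}{g}", s=f"sp{i}")
            for i, (p, c, g) in enumerate(assignments)
        ]
        idx = build_index(records)
        stack = [idx.root]
        while stack:
            node = stack.pop()
            if node.children:
                assert node.genome_count() == sum(
                    c.genome_count() for c in node.children.values()
                )
                stack.extend(node.children.values())
        assert idx.root.genome_count() == len(records)


NODES_DMP = textwrap.dedent(
    """\
    1\t|\t1\t|\tno rank\t|
    2\t|\t1\t|\tsuperkingdom\t|
    3\t|\t2\t|\tphylum\t|
    4\t|\t3\t|\tclass\t|
    5\t|\t4\t|\torder\t|
    6\t|\t5\t|\tsuborder\t|
    7\t|\t6\t|\tfamily\t|
    8\t|\t7\t|\tgenus\t|
    9\t|\t8\t|\tspecies\t|
    10\t|\t8\t|\tspecies\t|
    """
)
NAMES_DMP = textwrap.dedent(
    """\
    1\t|\troot\t|\t\t|\tscientific name\t|
    2\t|\tBacteria\t|\t\t|\tscientific name\t|
    2\t|\teubacteria\t|\t\t|\tsynonym\t|
    3\t|\tPlanctomycetota\t|\t\t|\tscientific name\t|
    4\t|\tPlanctomycetia\t|\t\t|\tscientific name\t|
    5\t|\tPirellulales\t|\t\t|\tscientific name\t|
    6\t|\tPirellulineae\t|\t\t|\tscientific name\t|
    7\t|\tPirellulaceae\t|\t\t|\tscientific name\t|
    8\t|\tPirellula\t|\t\t|\tscientific name\t|
    9\t|\tPirellula staleyi\t|\t\t|\tscientific name\t|
    10\t|\tPirellula marina\t|\t\t|\tscientific name\t|
    """
)


class TestNcbiTaxonomy:
    def _write(self, tmp_path, table):
        (tmp_path / "nodes.dmp").write_text(NODES_DMP)
        (tmp_path / "names.dmp").write_text(NAMES_DMP)
        (tmp_path / "assem.tsv").write_text(table)
        return tmp_path / "nodes.dmp", tmp_path / "names.dmp", tmp_path / "assem.tsv"

    def test_lineages_from_hand_walked_parent_links(self, tmp_path):
        # hand walk: 9 -> 8(genus) -> 7(family) -> 6(skip suborder) -> 5(order)
        # -> 4(class) -> 3(phylum) -> 2(domain)
        paths = self._write(
            tmp_path, "accession\ttaxid\nGCA_1.1\t9\nGCF_2.1\t10\n"
        )
        records = read_ncbi_taxonomy(*paths)
        assert len(records) == 2
        lin = records[0].lineage
        assert lin.names() == (
            "Bacteria", "Planctomycetota", "Planctomycetia", "Pirellulales",
            "Pirellulaceae", "Pirellula", "Pirellula staleyi",
        )
        assert records[1].lineage.get("species") == "Pirellula marina"
        assert records[1].source == "refseq"

    def test_genus_level_taxid_gets_species_placeholder(self, tmp_path):
        paths = self._write(tmp_path, "accession\ttaxid\nGCA_1.1\t8\n")
        (rec,) = read_ncbi_taxonomy(*paths)
        assert rec.lineage.get("genus") == "Pirellula"
        assert rec.lineage.get("species") == "s__"

    def test_ncbi_and_gtdb_encodings_agree(self, tmp_path):
        """The same genome encoded via taxdump and via a GTDB string yields
        an identical Lineage."""
        paths = self._write(tmp_path, "accession\ttaxid\nGCA_1.1\t9\n")
        (ncbi_rec,) = read_ncbi_taxonomy(*paths)
        gtdb_lin = parse_gtdb_taxonomy_string(
            "d__Bacteria;p__Planctomycetota;c__Planctomycetia;o__Pirellulales;"
            "f__Pirellulaceae;g__Pirellula;s__Pirellula staleyi"
        )
        assert ncbi_rec.lineage == gtdb_lin

    def test_orphan_taxid_lists_accessions(self, tmp_path):
        paths = self._write(tmp_path, "accession\ttaxid\nGCA_9.1\t999\n")
        with pytest.raises(TaxonomyError, match="GCA_9.1"):
            read_ncbi_taxonomy(*paths)

    def test_cyclic_parent_link_detected(self, tmp_path):
        nodes = NODES_DMP.replace("5\t|\t4\t|\torder", "5\t|\t7\t|\torder")
        (tmp_path / "nodes.dmp").write_text(nodes)
        (tmp_path / "names.dmp").write_text(NAMES_DMP)
        (tmp_path / "assem.tsv").write_text("accession\ttaxid\nGCA_1.1\t9\n")
        with pytest.raises(TaxonomyError, match="cycle"):
            read_ncbi_taxonomy(
                tmp_path / "nodes.dmp", tmp_path / "names.dmp", tmp_path / "assem.tsv"
            )


class TestBuildIndex:
    def test_per_node_counts_on_two_phylum_fixture(self):
        records = [
            record("GCA_1.1", p="pA", c="cA1", s="s1"),
            record("GCA_2.1", p="pA", c="cA1", s="s2"),
            record("GCA_3.1", p="pA", c="cA2", s="s3"),
            record("GCA_4.1", p="pB", c="cB1", s="s4"),
        ]
        idx = build_index(records)
        assert idx.find("pA").genome_count() == 3
        assert idx.find("pB").genome_count() == 1
        assert idx.find("cA1").genome_count() == 2
        assert idx.root.genome_count() == 4

    def test_count_sum_rule_holds_everywhere(self, pvc_like_index):
        for node in [pvc_like_index.root] + pvc_like_index.root.descendants_at_rank("class"):
            if node.children:
                assert node.genome_count() == sum(
                    c.genome_count() for c in node.children.values()
                )

    def test_single_record_makes_a_seven_node_path(self):
        idx = build_index([record("GCA_1.1")])
        node, depth = idx.root, 0
        while node.children:
            assert len(node.children) == 1
            node = next(iter(node.children.values()))
            depth += 1
        assert depth == 7
        assert node.rank == "species"

    def test_duplicate_accession_rejected(self):
        with pytest.raises(TaxonomyError, match="duplicate"):
            build_index([record("GCA_1.1"), record("GCA_1.1", s="other")])

    def test_empty_input_rejected(self):
        with pytest.raises(TaxonomyError):
            build_index([])


class TestNewick:
    def test_parse_simple_tree(self):
        tree = parse_newick("((A:1,B:2):1,C:3);")
        assert tree.leaf_labels() == {"A", "B", "C"}
        assert [c[:2] for c in tree.cherries()] == [("A", "B")]

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("n", [5, 50, 200])
    def test_roundtrip_is_identity_on_random_trees(self, n, seed):
        tree = make_tree(n, seed=seed)
        text = tree.newick()
        assert parse_newick(text).newick() == text

    def test_file_roundtrip(self, tmp_path):
        tree = make_tree(50, seed=7)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        assert read_newick(path).newick() == tree.newick()

    def test_quoted_labels_preserved(self):
        text = "('taxon one':1.0,'taxon(2)':2.0);"
        tree = parse_newick(text)
        assert tree.leaf_labels() == {"taxon one", "taxon(2)"}
        assert tree.newick() == "('taxon one':1.0,'taxon(2)':2.0);"

    def test_internal_labels_preserved(self):
        text = "((A:1.0,B:2.0)clade1:1.0,C:3.0)root_label;"
        assert parse_newick(text).newick() == text

    def test_unbalanced_parentheses_raise_parse_error(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A:1,B:2:1,C:3);")

    def test_missing_branch_length_warns_and_becomes_zero(self):
        with pytest.warns(UserWarning, match="branch length"):
            tree = parse_newick("((A,B:1):1,C:2);")
        assert tree.leaf("A").length == 0.0


class TestSelectionTable:
    def _selection(self, entries):
        return Selection(entries=entries, seed=0)

    def test_three_genome_selection_makes_three_rows(self, tmp_path):
        sel = self._selection(
            [
                SelectionEntry(record("GCA_2.1", s="s2"), 1),
                SelectionEntry(record("GCA_1.1", s="s1"), 2),
                SelectionEntry(record("GCA_3.1", s="s3"), 1, required=True),
            ]
        )
        path = tmp_path / "sel.tsv"
        write_selection(sel, path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == [
            "accession", *CANONICAL_RANKS, "criterion_id", "required",
        ]
        # criterion order first, then accession lexicographic
        assert [l.split("\t")[0] for l in lines[1:]] == [
            "GCA_2.1", "GCA_3.1", "GCA_1.1",
        ]
        assert lines[2].split("\t")[-1] == "true"

    def test_empty_selection_writes_header_only(self, tmp_path):
        path = tmp_path / "sel.tsv"
        write_selection(self._selection([]), path)
        assert path.read_text().splitlines() == [
            "\t".join(["accession", *CANONICAL_RANKS, "criterion_id", "required"])
        ]

    def test_rewrite_is_byte_identical(self, tmp_path):
        sel = self._selection([SelectionEntry(record("GCA_1.1"), 1)])
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_selection(sel, a)
        write_selection(sel, b)
        assert a.read_bytes() == b.read_bytes()
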