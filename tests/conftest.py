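import textwrap

import pytest

from phylosample import build_index, read_gtdb_metadata
from phylosample.taxonomy_io import GenomeRecord, Lineage, parse_gtdb_taxonomy_string


def lineage(d="Bacteria", p="P", c="C", o="O", f="F", g="G", s="S"):
    return parse_gtdb_taxonomy_string(
        f"d__{d};p__{p};c__{c};o__{o};f__{f};g__{g};s__{s}"
    )


def record(accession, **ranks):
    return GenomeRecord.make(accession, lineage(**ranks))


@pytest.fixture
def metadata_tsv(tmp_path):
    """Three-genome GTDB-style metadata file."""
    text = textwrap.dedent(
        """\
        accession\tgtdb_taxonomy\tcheckm_completeness\tcheckm_contamination
        GCA_000000001.1\td__Bacteria;p__Planctomycetota;c__Planctomycetia;o__Pirellulales;f__Pirellulaceae;g__Pirellula;s__Pirellula staleyi\t97.3\t1.2
        GCF_000000002.1\td__Bacteria;p__Planctomycetota;c__Phycisphaerae;o__Phycisphaerales;f__Phycisphaeraceae;g__Phycisphaera;s__Phycisphaera mikurensis\t88.0\t4.5
        RS_GCF_000000003.1\td__Archaea;p__Thermoproteota;c__Nitrososphaeria;o__Nitrososphaerales;f__Nitrososphaeraceae;g__Nitrososphaera;s__Nitrososphaera viennensis\t99.1\t0.3
        """
    )
    path = tmp_path / "meta.tsv"
    path.write_text(text)
    return path


@pytest.fixture
def small_index(metadata_tsv):
    return build_index(read_gtdb_metadata(metadata_tsv))


@pytest.fixture
def pvc_like_index():
    """Two phyla under one domain: pA dense (2 classes x 2 orders x 3 genomes),
    pB sparse (2 classes x 1 order x 2 genomes).  Used for hierarchical
    exclusion and precedence tests."""
    records = []
    n = 0
    for ci in ("cA1", "cA2"):
        for oi in ("o1", "o2"):
            for k in range(3):
                n += 1
                records.append(
                    record(
                        f"GCA_{n:09d}.1",
                        p="pA", c=ci, o=f"{ci}{oi}", f=f"{ci}{oi}f",
                        g=f"{ci}{oi}g", s=f"{ci}{oi}g sp{k}",
                    )
                )
    for ci in ("cB1", "cB2"):
        for k in range(2):
            n += 1
            records.append(
                record(
                    f"GCA_{n:09d}.1",
                    p="pB", c=ci, o=f"{ci}o", f=f"{ci}f", g=f"{ci}g",
                    s=f"{ci}g sp{k}",
                )
            )
    return build_index(records)
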