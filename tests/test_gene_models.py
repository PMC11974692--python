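import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proxisplice.gene_models import (
    DepthExperiment,
    GeneModel,
    SchemaError,
    compute_rpkm,
    read_depth_table,
    read_gene_models,
    read_junction_table,
    write_depth_table,
    write_junction_table,
)


class TestGeneModel:
    def test_single_exon_gene_has_no_introns(self):
        g = GeneModel("G", "Chr1", "+", ((0, 100),))
        assert g.introns == ()

    def test_intron_derivation_plus_strand(self, three_exon_plus):
        introns = three_exon_plus.introns
        assert [(i.start, i.end, i.ordinal) for i in introns] == [
            (100, 200, 1),
            (300, 400, 2),
        ]

    def test_intron_ordinals_reverse_on_minus_strand(self, three_exon_minus):
        introns = three_exon_minus.introns
        # genomic gap (300, 400) is the 5'-most intron in transcription order
        assert [(i.start, i.end, i.ordinal) for i in introns] == [
            (100, 200, 2),
            (300, 400, 1),
        ]

    def test_position_classes(self, three_exon_plus):
        assert three_exon_plus.intron_position_class(1) == "first"
        assert three_exon_plus.intron_position_class(2) == "last"
        two_exon = GeneModel("G", "Chr1", "+", ((0, 10), (20, 30)))
        assert two_exon.intron_position_class(1) == "only"

    def test_flanking_exons_are_strand_oriented(self, three_exon_minus):
        up, down = three_exon_minus.flanking_exons(1)  # 5'-most intron
        assert up == (400, 500)  # genomically last exon is 5' on '-'
        assert down == (200, 300)

    def test_rejects_unstranded_and_overlapping(self):
        with pytest.raises(ValueError, match="strand"):
            GeneModel("G", "Chr1", ".", ((0, 10),))
        with pytest.raises(ValueError, match="overlap"):
            GeneModel("G", "Chr1", "+", ((0, 100), (50, 150)))

    @given(
        st.lists(
            st.tuples(st.integers(1, 200), st.integers(1, 300)),
            min_size=1,
            max_size=8,
        )
    )
    @settings(deadline=None)
    def test_span_partition_invariant(self, pieces):
        """Exon + intron lengths always tile the gene span exactly."""
        exons, pos = [], 0
        for length, gap in pieces:
            exons.append((pos, pos + length))
            pos += length + gap
        exons[-1] = (exons[-1][0], pos - pieces[-1][1])  # drop trailing gap
        g = GeneModel("G", "Chr1", "+", tuple(exons))
        total = sum(e - s for s, e in g.exons) + sum(i.length for i in g.introns)
        assert total == g.end - g.start
        assert g.introns == g.introns  # derivation is pure/stable


class TestRpkm:
    @pytest.mark.parametrize(
        "reads,length,lib,expected",
        [(1000, 2000, 1e7, 50.0), (0, 500, 1e6, 0.0), (250, 500, 5e6, 100.0)],
    )
    def test_worked_values(self, reads, length, lib, expected):
        assert compute_rpkm(reads, length, lib) == pytest.approx(expected)

    def test_zero_length_or_library_rejected(self):
        with pytest.raises(ValueError):
            compute_rpkm(10, 0, 1e6)
        with pytest.raises(ValueError):
            compute_rpkm(10, 1000, 0)

    @given(
        st.integers(1, 10**6),
        st.integers(1, 10**5),
        st.integers(1, 10**9),
        st.integers(2, 10),
    )
    def test_scaling_laws(self, reads, length, lib, c):
        base = compute_rpkm(reads, length, lib)
        assert compute_rpkm(reads * c, length, lib) == pytest.approx(c * base)
        assert compute_rpkm(reads, length * c, lib) == pytest.approx(base / c)
        assert compute_rpkm(reads, length, lib * c) == pytest.approx(base / c)


class TestAnnotationIO:
    def test_reads_models_and_picks_longest_transcript(self, gff3_file):
        models = {m.gene_id: m for m in read_gene_models(gff3_file, "GFF3")}
        ga = models["GA"]
        assert len(ga.exons) == 3  # GA.2 (300 nt exonic) beats GA.1 (200 nt)
        assert ga.exons[0] == (0, 100)  # 1-based inclusive -> 0-based half-open
        gb = models["GB"]
        assert gb.strand == "-"
        assert gb.introns[0].ordinal == 1
        assert (gb.introns[0].start, gb.introns[0].end) == (1100, 1300)

    def test_tie_breaks_to_lexicographically_smallest(self, tmp_path):
        text = (
            "##gff-version 3\n"
            "Chr1\tt\tgene\t1\t100\t.\t+\t.\tID=G\n"
            "Chr1\tt\tmRNA\t1\t100\t.\t+\t.\tID=G.b;Parent=G\n"
            "Chr1\tt\texon\t1\t100\t.\t+\t.\tParent=G.b\n"
            "Chr1\tt\tmRNA\t1\t100\t.\t+\t.\tID=G.a;Parent=G\n"
            "Chr1\tt\texon\t1\t100\t.\t+\t.\tParent=G.a\n"
        )
        p = tmp_path / "tie.gff3"
        p.write_text(text)
        models = read_gene_models(str(p), "GFF3")
        assert len(models) == 1  # equal lengths: G.a chosen, model unchanged

    def test_gtf_dialect(self, tmp_path):
        text = (
            'Chr1\tt\texon\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "G.1";\n'
            'Chr1\tt\texon\t201\t300\t.\t+\t.\tgene_id "G"; transcript_id "G.1";\n'
        )
        p = tmp_path / "anno.gtf"
        p.write_text(text)
        (model,) = read_gene_models(str(p), "GTF")
        assert model.gene_id == "G"
        assert [(i.start, i.end) for i in model.introns] == [(100, 200)]


class TestDepthTableIO:
    def test_round_trip_exact(self, tiny_depth_experiment, tmp_path):
        path = str(tmp_path / "depths.tsv")
        write_depth_table(tiny_depth_experiment, path, extra_meta={"seed": 42})
        back = read_depth_table(path)
        pd.testing.assert_frame_equal(back.table, tiny_depth_experiment.table)
        assert back.groups == tiny_depth_experiment.groups
        assert back.library_size == tiny_depth_experiment.library_size
        assert back.meta["seed"] == "42"  # parameters echoed in the header

    def test_missing_sample_column_is_schema_error(self, tiny_depth_experiment, tmp_path):
        path = str(tmp_path / "depths.tsv")
        write_depth_table(tiny_depth_experiment, path)
        lines = open(path).read().splitlines()
        # drop required metadata column
        header = lines[2].split("\t")
        idx = header.index("feature_type")
        trimmed = [
            "\t".join(v for i, v in enumerate(l.split("\t")) if i != idx)
            for l in lines[2:]
        ]
        (tmp_path / "bad.tsv").write_text("\n".join(lines[:2] + trimmed))
        with pytest.raises(SchemaError, match="feature_type"):
            read_depth_table(str(tmp_path / "bad.tsv"))

    def test_negative_depth_rejected(self, tiny_depth_experiment):
        bad = tiny_depth_experiment.table.copy()
        bad.loc[1, "wt_1"] = -3
        with pytest.raises(SchemaError, match="negative"):
            DepthExperiment(bad, tiny_depth_experiment.groups,
                            tiny_depth_experiment.library_size)

    def test_gene_rpkm_uses_gene_rows(self, tiny_depth_experiment):
        rpkm = tiny_depth_experiment.gene_rpkm()
        # G1: mean(900,1000,950,1050)=975 reads, 300 nt, 1e6 lib
        assert rpkm["G1"] == pytest.approx(975 / (0.3 * 1.0))


class TestJunctionTableIO:
    def test_round_trip(self, tmp_path):
        from proxisplice.gene_models import JunctionTable

        tbl = pd.DataFrame(
            {
                "chrom": ["Chr1"], "donor": [100], "acceptor": [200],
                "strand": ["+"], "gene_id": ["G1"], "annotated": [True],
                "wt_1": [5], "mut_1": [7],
            }
        )
        jt = JunctionTable(tbl, ("wt", "mut"))
        path = str(tmp_path / "j.tsv")
        write_junction_table(jt, path)
        back = read_junction_table(path)
        pd.testing.assert_frame_equal(back.table, jt.table)

    def test_donor_after_acceptor_rejected(self):
        from proxisplice.gene_models import JunctionTable

        tbl = pd.DataFrame(
            {
                "chrom": ["Chr1"], "donor": [300], "acceptor": [200],
                "strand": ["+"], "gene_id": ["G1"], "annotated": [False],
                "wt_1": [5], "mut_1": [7],
            }
        )
        with pytest.raises(SchemaError, match="donor"):
            JunctionTable(tbl, ("wt", "mut"))
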