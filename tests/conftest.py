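import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from proxisplice.gene_models import DepthExperiment, GeneModel

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def three_exon_plus():
    """3-exon plus-strand gene: exons 0-100, 200-300, 400-500 (half-open)."""
    return GeneModel("G1", "Chr1", "+", ((0, 100), (200, 300), (400, 500)))


@pytest.fixture
def three_exon_minus():
    return GeneModel("G2", "Chr1", "-", ((0, 100), (200, 300), (400, 500)))


@pytest.fixture
def tiny_depth_experiment():
    """Two genes (2 introns + 1 intron), two groups x 2 replicates."""
    samples = ["wt_1", "wt_2", "mut_1", "mut_2"]

    def row(fid, gid, ftype, ordinal, length, vals):
        return {
            "feature_id": fid, "gene_id": gid, "feature_type": ftype,
            "ordinal": ordinal, "length": length,
            **dict(zip(samples, vals)),
        }

    rows = [
        row("G1:gene", "G1", "gene", 0, 300, [900, 1000, 950, 1050]),
        row("G1:exon:1", "G1", "exon", 1, 100, [100, 110, 100, 105]),
        row("G1:exon:2", "G1", "exon", 2, 100, [100, 90, 100, 95]),
        row("G1:exon:3", "G1", "exon", 3, 100, [95, 100, 105, 100]),
        row("G1:intron:1", "G1", "intron", 1, 100, [20, 22, 60, 62]),
        row("G1:intron:2", "G1", "intron", 2, 100, [30, 28, 30, 32]),
        row("G2:gene", "G2", "gene", 0, 200, [600, 650, 640, 620]),
        row("G2:exon:1", "G2", "exon", 1, 100, [80, 85, 82, 84]),
        row("G2:exon:2", "G2", "exon", 2, 100, [78, 80, 86, 82]),
        row("G2:intron:1", "G2", "intron", 1, 100, [40, 42, 41, 39]),
    ]
    return DepthExperiment(
        table=pd.DataFrame(rows),
        groups=("wt", "mut"),
        library_size={s: 1e6 for s in samples},
    )


@pytest.fixture
def gff3_file(tmp_path):
    """Small annotation: two genes, one with two transcripts (tie-breaking)."""
    text = """##gff-version 3
Chr1\ttest\tgene\t1\t500\t.\t+\t.\tID=GA
Chr1\ttest\tmRNA\t1\t500\t.\t+\t.\tID=GA.2;Parent=GA
Chr1\ttest\texon\t1\t100\t.\t+\t.\tParent=GA.2
Chr1\ttest\texon\t201\t300\t.\t+\t.\tParent=GA.2
Chr1\ttest\texon\t401\t500\t.\t+\t.\tParent=GA.2
Chr1\ttest\tmRNA\t1\t300\t.\t+\t.\tID=GA.1;Parent=GA
Chr1\ttest\texon\t1\t100\t.\t+\t.\tParent=GA.1
Chr1\ttest\texon\t201\t300\t.\t+\t.\tParent=GA.1
Chr1\ttest\tgene\t1001\t1400\t.\t-\t.\tID=GB
Chr1\ttest\tmRNA\t1001\t1400\t.\t-\t.\tID=GB.1;Parent=GB
Chr1\ttest\texon\t1001\t1100\t.\t-\t.\tParent=GB.1
Chr1\ttest\texon\t1301\t1400\t.\t-\t.\tParent=GB.1
"""
    path = tmp_path / "anno.gff3"
    path.write_text(text)
    return str(path)
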