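"""Shared fixtures: tiny annotations, genomes, and simulated datasets.

All fixtures are generated programmatically; nothing is read from disk
outside pytest temp directories.
"""

from __future__ import annotations

import textwrap

import pandas as pd
import pytest

from apaquant import TerminalFragment
from apaquant.simulation import SimConfig, emit_fixture

TOY_GFF3 = textwrap.dedent(
    """\
    ##gff-version 3
    chr1\ttest\tgene\t1\t5000\t.\t+\t.\tID=geneA
    chr1\ttest\ttranscript\t1\t2000\t.\t+\t.\tID=geneA.t1;Parent=geneA;transcript_type=protein_coding
    chr1\ttest\texon\t1\t500\t.\t+\t.\tID=geneA.t1.e1;Parent=geneA.t1
    chr1\ttest\texon\t1000\t2000\t.\t+\t.\tID=geneA.t1.e2;Parent=geneA.t1
    chr1\ttest\ttranscript\t1\t4000\t.\t+\t.\tID=geneA.t2;Parent=geneA;transcript_type=lncRNA;tag=mRNA_end_NF
    chr1\ttest\texon\t1\t500\t.\t+\t.\tID=geneA.t2.e1;Parent=geneA.t2
    chr1\ttest\texon\t1000\t4000\t.\t+\t.\tID=geneA.t2.e2;Parent=geneA.t2
    """
)


@pytest.fixture
def toy_gff3(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF3)
    return path


@pytest.fixture
def toy_genome(tmp_path):
    """A 120-nt single-chromosome genome with a recognisable sequence."""
    seq = ("ACGT" * 30)[:120]
    path = tmp_path / "genome.fa"
    path.write_text(f">chr1\n{seq}\n")
    return path, seq


def make_fragment(
    end: int,
    strand: str = "+",
    gene_id: str = "g1",
    transcript_id: str | None = None,
    exon_len: int = 50,
    chrom: str = "chr1",
) -> TerminalFragment:
    """A single-exon terminal fragment whose 3' end is at ``end``."""
    if strand == "+":
        exons = ((end - exon_len + 1, end),)
    else:
        exons = ((end, end + exon_len - 1),)
    return TerminalFragment(
        transcript_id=transcript_id or f"tx_{strand}{end}",
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        fragment_exons=exons,
        three_prime_end=end,
        fragment_length=exon_len,
    )


@pytest.fixture(scope="session")
def smoke_fixture(tmp_path_factory):
    """A 60-gene simulated dataset shared by pipeline-level tests."""
    outdir = tmp_path_factory.mktemp("smoke_fixture")
    config = SimConfig(
        n_genes=60, n_positive=15, n_negative=15, n_control=30, seed=11
    )
    truth = emit_fixture(config, outdir)
    return config, truth, outdir


@pytest.fixture
def samplesheet_3v3():
    samples = [f"sample{c}_rep{r}" for c in "AB" for r in (1, 2, 3)]
    return pd.DataFrame(
        {
            "condition": ["A"] * 3 + ["B"] * 3,
            "replicate": ["1", "2", "3"] * 2,
        },
        index=pd.Index(samples, name="sample_id"),
    )
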