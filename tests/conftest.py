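"""Shared fixtures: a hand-built micro genome and the default synthetic study."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from leafscreen.genome import GeneRecord, GenomeModel, Transcript
from leafscreen.simulate import simulate_study

STUDY_SEED = 7

# CDS used in the micro genome: ATG GGC TGG AGC CTG CAT TAA
# (Met Gly Trp Ser Leu His stop) -- gives known codons at known offsets.
MICRO_CDS = "ATGGGCTGGAGCCTGCATTAA"


@pytest.fixture(scope="session")
def micro_genome() -> GenomeModel:
    """Tiny hand-built genome with known codons, strands, and overlaps.

    chr1 (2000 bp):
      gp  (+): UTR5 [100,130) CDS [130,151)=MICRO_CDS UTR3 [151,181)
      gm  (-): UTR3 [500,530) CDS [530,551)=revcomp(MICRO_CDS) UTR5 [551,581)
      geneA (+): CDS [1000,1012) nested inside geneB's intron
      geneB (+): CDS [950,962)+[1100,1112), intron [962,1100)
    Promoter window is 200 bp here.
    """
    seq = list("ACGT" * 500)
    seq[130:151] = list(MICRO_CDS)
    seq[530:551] = list(str(Seq(MICRO_CDS).reverse_complement()))
    genes = [
        GeneRecord(
            gene_id="gp",
            chrom="chr1",
            strand="+",
            biotype="characterized",
            transcripts=[
                Transcript("gp.t1", cds=[(130, 151)], utr5=[(100, 130)],
                           utr3=[(151, 181)])
            ],
        ),
        GeneRecord(
            gene_id="gm",
            chrom="chr1",
            strand="-",
            biotype="unknown",
            transcripts=[
                Transcript("gm.t1", cds=[(530, 551)], utr5=[(551, 581)],
                           utr3=[(500, 530)])
            ],
        ),
        GeneRecord(
            gene_id="geneA",
            chrom="chr1",
            strand="+",
            biotype="characterized",
            transcripts=[
                Transcript("geneA.t1", cds=[(1000, 1012)], utr5=[(990, 1000)],
                           utr3=[(1012, 1022)])
            ],
        ),
        GeneRecord(
            gene_id="geneB",
            chrom="chr1",
            strand="+",
            biotype="transposable_element",
            transcripts=[
                Transcript(
                    "geneB.t1",
                    cds=[(950, 962), (1100, 1112)],
                    utr5=[(940, 950)],
                    utr3=[(1112, 1122)],
                )
            ],
        ),
    ]
    return GenomeModel({"chr1": "".join(seq)}, genes, promoter_len=200)


@pytest.fixture(scope="session")
def study():
    """The default synthetic study (10 accessions, 60 genes, 500 kb)."""
    return simulate_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
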