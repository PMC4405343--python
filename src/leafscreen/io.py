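"""Readers and writers for the standard formats the pipeline touches.

Coordinates are 0-based half-open everywhere inside the package; GFF3 and
VCF are converted to/from their 1-based conventions at this boundary.  BED
and BEDGraph stay 0-based half-open.  All writers produce plain text so a
written dataset round-trips losslessly through the matching reader.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from leafscreen.enrichment import ExpressionMatrix
from leafscreen.genome import GeneRecord, GenomeModel, Transcript
from leafscreen.qc import ReadRecord
from leafscreen.structural import DepthProfile
from leafscreen.variants import VariantCall


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(seqs: dict[str, str] | list[tuple[str, str]], path: str) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def read_fastq(path: str) -> list[ReadRecord]:
    out = []
    for rec in SeqIO.parse(path, "fastq"):
        out.append(
            ReadRecord(
                id=rec.id,
                bases=str(rec.seq),
                quals=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return out


def write_fastq(reads: list[ReadRecord], path: str) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = r.quals
        records.append(rec)
    SeqIO.write(records, path, "fastq")


# ---------------------------------------------------------------------------
# GFF3 gene models


def write_gff3(genome: GenomeModel, path: str) -> None:
    """Write gene models as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, seq in genome.chromosomes.items():
            fh.write(f"##sequence-region {chrom} 1 {len(seq)}\n")
        for g in genome.genes:
            gs, ge = g.span
            fh.write(
                _gff_line(g.chrom, "gene", gs, ge, g.strand,
                          f"ID={g.gene_id};biotype={g.biotype}")
            )
            for t in g.transcripts:
                ts, te = t.span
                fh.write(
                    _gff_line(g.chrom, "mRNA", ts, te, g.strand,
                              f"ID={t.transcript_id};Parent={g.gene_id}")
                )
                for kind, blocks in (
                    ("five_prime_UTR", t.utr5),
                    ("CDS", t.cds),
                    ("three_prime_UTR", t.utr3),
                ):
                    for s, e in blocks:
                        fh.write(
                            _gff_line(g.chrom, kind, s, e, g.strand,
                                      f"Parent={t.transcript_id}")
                        )


def _gff_line(chrom, kind, start0, end0, strand, attrs) -> str:
    return f"{chrom}\tleafscreen\t{kind}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}\n"


def read_gff3(path: str, chromosomes: dict[str, str],
              promoter_len: int = 2000) -> GenomeModel:
    """Parse a GFF3 of gene/mRNA/CDS/UTR features into a GenomeModel.

    The ``biotype`` attribute on gene features is honoured (default
    'unknown').  Requires the chromosome sequences separately (FASTA).
    """
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gf in db.features_of_type("gene"):
        transcripts = []
        for mf in db.children(gf, featuretype="mRNA"):
            cds, utr5, utr3 = [], [], []
            for child in db.children(mf):
                iv = (child.start - 1, child.end)
                if child.featuretype == "CDS":
                    cds.append(iv)
                elif child.featuretype == "five_prime_UTR":
                    utr5.append(iv)
                elif child.featuretype == "three_prime_UTR":
                    utr3.append(iv)
            transcripts.append(
                Transcript(
                    transcript_id=mf.id,
                    cds=sorted(cds),
                    utr5=sorted(utr5),
                    utr3=sorted(utr3),
                )
            )
        genes.append(
            GeneRecord(
                gene_id=gf.id,
                chrom=gf.seqid,
                strand=gf.strand,
                biotype=gf.attributes.get("biotype", ["unknown"])[0],
                transcripts=transcripts,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.span))
    return GenomeModel(chromosomes, genes, promoter_len=promoter_len)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    variants: list[VariantCall],
    path: str,
    chrom_lengths: dict[str, int],
    accession: str,
) -> None:
    """Write one accession's calls as a minimal VCF 4.2 (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=leafscreen\n##accession={accession}\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=ACC,Number=1,Type=String,Description="Accession">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"ACC={accession}\n"
            )


def read_vcf(path: str, accession: str | None = None) -> list[VariantCall]:
    """Read a VCF into VariantCall records (positions converted to 0-based)."""
    import pysam

    out = []
    with pysam.VariantFile(path) as vf:
        acc = accession
        if acc is None:
            for line in str(vf.header).splitlines():
                if line.startswith("##accession="):
                    acc = line.split("=", 1)[1]
        for rec in vf:
            for alt in rec.alts or ():
                indel_len = len(alt) - len(rec.ref)
                out.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.start,  # pysam exposes the 0-based start
                        ref=rec.ref,
                        alt=alt,
                        accession=acc or "",
                        is_indel=indel_len != 0,
                        indel_len=indel_len,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# depth (BEDGraph) and intervals (BED)


def write_bedgraph(profiles: dict[str, DepthProfile], path: str) -> None:
    """Run-length encoded per-base depth, 0-based half-open."""
    with open(path, "w") as fh:
        for chrom in sorted(profiles):
            d = profiles[chrom].depth
            change = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(d)]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{d[s]}\n")


def read_bedgraph(path: str, chrom_lengths: dict[str, int]) -> dict[str, DepthProfile]:
    out = {c: np.zeros(n, dtype=int) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            try:
                chrom, s, e, v = line.split()
                out[chrom][int(s) : int(e)] = int(float(v))
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}:{ln}: malformed BEDGraph line") from exc
    return {c: DepthProfile(chrom=c, depth=d) for c, d in out.items()}


def write_bed(intervals: list[tuple[str, int, int]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT) and expression (TSV)


def write_gmt(gene_sets: dict[str, set[str]], path: str,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc] + sorted(gene_sets[name])) + "\n")


def read_gmt(path: str) -> dict[str, set[str]]:
    out = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: GMT line needs name, desc, genes")
            out[parts[0]] = set(parts[2:])
    return out


def write_fpkm_tsv(m: ExpressionMatrix, path: str) -> None:
    """Genes x accession:stage FPKM table; the reference accession is recorded
    in a header comment."""
    flat = m.fpkm.copy()
    flat.columns = [f"{a}:{s}" for a, s in m.fpkm.columns]
    with open(path, "w") as fh:
        fh.write(f"#reference={m.reference}\n")
        flat.to_csv(fh, sep="\t", index_label="gene_id")


def read_fpkm_tsv(path: str, reference: str | None = None) -> ExpressionMatrix:
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#reference="):
            ref = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            ref = None
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    cols = [tuple(c.split(":", 1)) for c in df.columns]
    if any(len(c) != 2 for c in cols):
        raise ParseError(f"{path}: FPKM columns must be 'accession:stage'")
    df.columns = pd.MultiIndex.from_tuples(cols, names=["accession", "stage"])
    reference = reference or ref
    if reference is None:
        raise ParseError(f"{path}: no reference accession given or recorded")
    return ExpressionMatrix(fpkm=df, reference=reference)


# ---------------------------------------------------------------------------
# trees


def write_newick(tree, path: str) -> None:
    tree.write(path, format="newick")


def read_newick(path: str):
    from skbio import TreeNode

    return TreeNode.read(path, format="newick")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
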