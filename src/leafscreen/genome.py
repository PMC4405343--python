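"""Genome model: coordinate arithmetic, gene-model queries, and codon logic.

All coordinates are 0-based, half-open ``[start, end)`` internally.  GFF3 and
VCF readers/writers convert to/from 1-based coordinates at the I/O boundary.

Region labels
-------------
A genomic position receives exactly one label from::

    CDS > five_prime_UTR > three_prime_UTR > intron > promoter > intergenic

The precedence matters when transcripts overlap (e.g. a position inside the
CDS of one transcript and the intron of another is labelled ``CDS``), so that
region summaries over a SNP set are disjoint and sum to the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from intervaltree import IntervalTree

Interval = tuple[int, int]

# region labels, in precedence order (lower rank wins)
CDS = "CDS"
FIVE_UTR = "five_prime_UTR"
THREE_UTR = "three_prime_UTR"
INTRON = "intron"
PROMOTER = "promoter"
INTERGENIC = "intergenic"

REGION_PRECEDENCE = (CDS, FIVE_UTR, THREE_UTR, INTRON, PROMOTER, INTERGENIC)
_RANK = {label: i for i, label in enumerate(REGION_PRECEDENCE)}

BIOTYPES = ("characterized", "unknown", "transposable_element")

#: amino-acid physicochemical classes used for consequence interpretation
AA_PROPERTY = {
    **{aa: "hydrophobic" for aa in "AVLIMFWP"},
    **{aa: "polar-uncharged" for aa in "STNQCY"},
    **{aa: "basic" for aa in "KRH"},
    **{aa: "acidic" for aa in "DE"},
    "G": "special",
    "*": "stop",
}

_DNA = set("ACGT")


class GenomeError(ValueError):
    """Raised for malformed genome models or invalid genomic queries."""


@dataclass
class Transcript:
    """One transcript of a gene.

    ``cds``, ``utr5`` and ``utr3`` are lists of half-open genomic intervals
    sorted by start coordinate (regardless of strand).  Introns are the gaps
    between consecutive exonic blocks.
    """

    transcript_id: str
    cds: list[Interval]
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def exon_blocks(self) -> list[Interval]:
        blocks = sorted(self.cds + self.utr5 + self.utr3)
        merged: list[Interval] = []
        for s, e in blocks:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    @property
    def introns(self) -> list[Interval]:
        blocks = self.exon_blocks
        return [(blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1)]

    @property
    def span(self) -> Interval:
        blocks = self.exon_blocks
        return (blocks[0][0], blocks[-1][1])

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    biotype: str  # one of BIOTYPES
    transcripts: list[Transcript]
    promoter: Interval | None = None

    @property
    def span(self) -> Interval:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return (min(starts), max(ends))

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        s, e = self.span
        return s if self.strand == "+" else e

    def cds_positions(self) -> set[int]:
        """Union of CDS base positions over all transcripts."""
        pos: set[int] = set()
        for t in self.transcripts:
            for s, e in t.cds:
                pos.update(range(s, e))
        return pos


@dataclass
class CodonChange:
    """A single-base codon substitution and its protein-level consequence."""

    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect: str  # synonymous | nonsynonymous | stop_gain | stop_loss
    property_change: tuple[str, str]

    @classmethod
    def from_codons(cls, ref_codon: str, alt_codon: str) -> "CodonChange":
        ref_aa = translate_codon(ref_codon)
        alt_aa = translate_codon(alt_codon)
        if ref_aa == alt_aa:
            effect = "synonymous"
        elif alt_aa == "*":
            effect = "stop_gain"
        elif ref_aa == "*":
            effect = "stop_loss"
        else:
            effect = "nonsynonymous"
        return cls(
            ref_codon=ref_codon,
            alt_codon=alt_codon,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            effect=effect,
            property_change=classify_aa_property(ref_aa, alt_aa),
        )


class GenomeModel:
    """Reference sequences plus hierarchical gene annotation.

    Parameters
    ----------
    chromosomes
        Mapping of chromosome name to DNA sequence (uppercase IUPAC).
    genes
        Gene records; intervals must lie within their chromosome and each
        transcript's total CDS length must be a positive multiple of 3.
    promoter_len
        Width in bp of the strand-aware promoter window upstream of the TSS,
        truncated at chromosome edges.  Applied to genes whose ``promoter``
        field is unset.
    """

    def __init__(
        self,
        chromosomes: dict[str, str],
        genes: list[GeneRecord],
        promoter_len: int = 2000,
    ):
        self.chromosomes = chromosomes
        self.genes = genes
        self.promoter_len = promoter_len
        for g in genes:
            if g.promoter is None:
                g.promoter = self._promoter_window(g)
        self._validate()
        self._trees = self._build_index()
        self._genes_by_id = {g.gene_id: g for g in genes}
        self._transcripts_by_id = {
            t.transcript_id: (g, t) for g in genes for t in g.transcripts
        }

    # -- construction helpers ------------------------------------------------

    def _promoter_window(self, g: GeneRecord) -> Interval:
        clen = len(self.chromosomes[g.chrom])
        if g.strand == "+":
            return (max(0, g.tss - self.promoter_len), g.tss)
        return (g.tss, min(clen, g.tss + self.promoter_len))

    def _validate(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise GenomeError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if g.biotype not in BIOTYPES:
                raise GenomeError(f"gene {g.gene_id}: bad biotype {g.biotype!r}")
            if g.strand not in "+-":
                raise GenomeError(f"gene {g.gene_id}: bad strand {g.strand!r}")
            clen = len(self.chromosomes[g.chrom])
            s, e = g.span
            if not (0 <= s < e <= clen):
                raise GenomeError(f"gene {g.gene_id}: span {s, e} outside chromosome")
            for t in g.transcripts:
                if t.cds_len <= 0 or t.cds_len % 3:
                    raise GenomeError(
                        f"transcript {t.transcript_id}: CDS length {t.cds_len} "
                        "is not a positive multiple of 3"
                    )
                for iv in t.cds + t.utr5 + t.utr3:
                    if not (s <= iv[0] < iv[1] <= e):
                        raise GenomeError(
                            f"transcript {t.transcript_id}: block {iv} escapes gene span"
                        )

    def _build_index(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {c: IntervalTree() for c in self.chromosomes}
        for g in self.genes:
            tree = trees[g.chrom]
            if g.promoter and g.promoter[0] < g.promoter[1]:
                tree.addi(*g.promoter, (_RANK[PROMOTER], PROMOTER))
            for t in g.transcripts:
                for s, e in t.cds:
                    tree.addi(s, e, (_RANK[CDS], CDS))
                for s, e in t.utr5:
                    tree.addi(s, e, (_RANK[FIVE_UTR], FIVE_UTR))
                for s, e in t.utr3:
                    tree.addi(s, e, (_RANK[THREE_UTR], THREE_UTR))
                for s, e in t.introns:
                    tree.addi(s, e, (_RANK[INTRON], INTRON))
        return trees

    # -- queries ---------------------------------------------------------------

    def gene(self, gene_id: str) -> GeneRecord:
        return self._genes_by_id[gene_id]

    def transcript(self, transcript_id: str) -> tuple[GeneRecord, Transcript]:
        return self._transcripts_by_id[transcript_id]

    def locate(self, chrom: str, pos: int) -> str:
        """Region label of a position (precedence CDS > UTR > intron > promoter)."""
        if chrom not in self.chromosomes:
            raise GenomeError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < len(self.chromosomes[chrom]):
            raise GenomeError(f"position {pos} outside chromosome {chrom}")
        hits = self._trees[chrom][pos]
        if not hits:
            return INTERGENIC
        return min(h.data for h in hits)[1]

    def transcripts_with_cds_at(self, chrom: str, pos: int) -> list[tuple[GeneRecord, Transcript]]:
        out = []
        for g in self.genes:
            if g.chrom != chrom:
                continue
            for t in g.transcripts:
                if any(s <= pos < e for s, e in t.cds):
                    out.append((g, t))
        return out

    def spliced_cds(self, gene: GeneRecord, transcript: Transcript) -> str:
        """CDS sequence in translation order (reverse-complemented on '-')."""
        seq = self.chromosomes[gene.chrom]
        cat = "".join(seq[s:e] for s, e in transcript.cds)
        if gene.strand == "-":
            cat = str(Seq(cat).reverse_complement())
        return cat

    def cds_offset(self, gene: GeneRecord, transcript: Transcript, pos: int) -> int:
        """Offset of genomic ``pos`` within the translation-order CDS."""
        off = 0
        for s, e in transcript.cds:
            if s <= pos < e:
                plus_off = off + (pos - s)
                if gene.strand == "+":
                    return plus_off
                return transcript.cds_len - 1 - plus_off
            off += e - s
        raise GenomeError(
            f"position {pos} not in CDS of transcript {transcript.transcript_id}"
        )

    def codon_at(
        self, gene: GeneRecord, transcript: Transcript, pos: int
    ) -> tuple[str, int]:
        """Reference codon covering genomic ``pos`` and the within-codon offset.

        Both are in translation order: offset 0 is the first base of the codon
        as read by the ribosome.
        """
        off = self.cds_offset(gene, transcript, pos)
        cds = self.spliced_cds(gene, transcript)
        codon_start = (off // 3) * 3
        return cds[codon_start : codon_start + 3], off % 3


def translate_codon(codon: str) -> str:
    """Translate a DNA codon with the standard genetic code; stop is ``*``.

    Raises ``GenomeError`` on anything other than an ACGT 3-mer.
    """
    codon = codon.upper()
    if len(codon) != 3 or not set(codon) <= _DNA:
        raise GenomeError(f"invalid codon {codon!r}: expected [ACGT]{{3}}")
    return str(Seq(codon).translate())


def classify_aa_property(ref_aa: str, alt_aa: str) -> tuple[str, str]:
    """Physicochemical class pair for an amino-acid substitution.

    Classes: hydrophobic {A,V,L,I,M,F,W,P}, polar-uncharged {S,T,N,Q,C,Y},
    basic {K,R,H}, acidic {D,E}, special {G}, stop {*}.  A change such as
    glycine→serine is (special, polar-uncharged); a stop gain ends in 'stop'.
    """
    out = []
    for aa in (ref_aa, alt_aa):
        aa = aa.upper()
        if aa not in AA_PROPERTY:
            raise GenomeError(f"unknown amino acid code {aa!r}")
        out.append(AA_PROPERTY[aa])
    return (out[0], out[1])


def locate(genome: GenomeModel, chrom: str, pos: int) -> str:
    """Module-level alias for :meth:`GenomeModel.locate`."""
    return genome.locate(chrom, pos)
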