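"""Synthetic study generator with a known implanted truth set.

Emulates the statistical structure of a 10-accession rice resequencing +
RNA-seq design at desk scale: a toy reference genome with annotated gene
models, per-accession SNP/indel calls with clade structure and one strongly
divergent outlier (~10x the SNP load), per-base depth profiles around 40x
with depth forced below the loss-calling threshold across implanted
deletions, novel-sequence gain contigs, and a 3-stage FPKM expression matrix
with implanted up/down gene sets.  Every implanted event is recorded in a
:class:`TruthSet` so downstream stages can be scored for recovery without
any external download.

The default accession panel mirrors the study design this package targets:
a green reference cultivar (Dongjin), a dark-red cultivar (Jado), a strongly
divergent yellow cultivar (Hwangdo), and seven Dongjin-derived mutant lines
(D052..D131) falling into two relatedness clades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from leafscreen.enrichment import STAGES, ExpressionMatrix
from leafscreen.genome import GeneRecord, GenomeModel, Transcript, translate_codon
from leafscreen.structural import DepthProfile
from leafscreen.variants import VariantCall

import pandas as pd

DEFAULT_ACCESSIONS = (
    "Dongjin",
    "Jado",
    "Hwangdo",
    "D052",
    "D056",
    "D101",
    "D120",
    "D122",
    "D128",
    "D131",
)
DEFAULT_CLADES = {
    "cladeA": ("D052", "D056", "D120"),
    "cladeB": ("D122", "D131", "D128"),
}
DEFAULT_OUTLIER = "Hwangdo"
GLY_SER_ACCESSIONS = ("D052", "D056", "D120", "D122", "D128", "D131")

_BASES = np.array(list("ACGT"))


class GenerationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# truth records


@dataclass
class SnpTruth:
    chrom: str
    pos: int
    ref: str
    alt: str
    accession: str
    region: str | None = None
    effect: str | None = None  # synonymous / nonsynonymous / stop_gain / ...
    aa_change: tuple[str, str] | None = None


@dataclass
class LossTruth:
    accession: str
    gene_id: str
    interval: tuple[int, int]
    chrom: str
    mode: str  # "full" | "partial"


@dataclass
class GainTruth:
    accession: str
    contig_id: str
    length: int
    gene_class: str = "unknown"  # characterized | unknown


@dataclass
class DESpec:
    gene_id: str
    accession: str
    stage: str
    direction: str  # "up" | "down"
    fold: float


@dataclass
class DisruptionTruth:
    accession: str
    transcript_id: str
    mechanism: str  # "gap" | "frameshift"


@dataclass
class TruthSet:
    implanted_snps: list[SnpTruth] = field(default_factory=list)
    implanted_losses: list[LossTruth] = field(default_factory=list)
    implanted_gains: list[GainTruth] = field(default_factory=list)
    de_genes: list[DESpec] = field(default_factory=list)
    disrupted_transcripts: list[DisruptionTruth] = field(default_factory=list)


# ---------------------------------------------------------------------------
# reference generation


def generate_reference(
    n_chrom: int = 1,
    chrom_len: int = 500_000,
    n_genes: int = 60,
    seed: int | None = None,
    biotype_props: tuple[float, float, float] = (0.45, 0.45, 0.10),
    promoter_len: int = 2000,
) -> GenomeModel:
    """Toy reference genome with non-overlapping annotated genes.

    Genes carry 1-3 transcripts sharing one CDS structure (2-4 coding exons,
    total CDS length a multiple of 3) and differing in UTR extent.  Biotypes
    (characterized / unknown / transposable_element) are drawn with
    ``biotype_props``.  Deterministic given ``seed``; raises
    :class:`GenerationError` when the genes cannot be packed into the genome.
    """
    rng = np.random.default_rng(seed)
    chroms = {
        f"chr{c + 1}": "".join(rng.choice(_BASES, size=chrom_len))
        for c in range(n_chrom)
    }
    margin = 1500  # room for depth flanks at chromosome ends
    genes: list[GeneRecord] = []
    per_chrom = [n_genes // n_chrom + (c < n_genes % n_chrom) for c in range(n_chrom)]
    gi = 0
    for cname, n_here in zip(chroms, per_chrom):
        cursor = margin + int(rng.integers(0, 500))
        for _ in range(n_here):
            cursor += promoter_len + int(rng.integers(500, 1500))
            gene = _make_gene(f"gene{gi:03d}", cname, cursor, rng, biotype_props)
            end = gene.span[1]
            if end > chrom_len - margin:
                raise GenerationError(
                    f"cannot pack {n_genes} genes into {n_chrom} x {chrom_len} bp "
                    f"(ran out of room at gene {gi})"
                )
            genes.append(gene)
            cursor = end
            gi += 1
    return GenomeModel(chroms, genes, promoter_len=promoter_len)


def _make_gene(gene_id, chrom, start, rng, biotype_props) -> GeneRecord:
    strand = "+" if rng.random() < 0.5 else "-"
    utr_a = int(rng.integers(100, 300))  # lowest-coordinate UTR
    utr_b = int(rng.integers(100, 300))
    n_exons = int(rng.integers(2, 5))
    exon_lens = [int(rng.integers(120, 400)) for _ in range(n_exons)]
    rem = sum(exon_lens) % 3
    if rem:
        exon_lens[-1] += 3 - rem
    intron_lens = [int(rng.integers(100, 400)) for _ in range(n_exons - 1)]

    pos = start
    utr_low = (pos, pos + utr_a)
    pos += utr_a
    cds = []
    for k, el in enumerate(exon_lens):
        cds.append((pos, pos + el))
        pos += el
        if k < n_exons - 1:
            pos += intron_lens[k]
    utr_high = (pos, pos + utr_b)
    pos += utr_b

    if strand == "+":
        utr5_full, utr3_full = [utr_low], [utr_high]
    else:
        utr5_full, utr3_full = [utr_high], [utr_low]

    n_tx = int(rng.integers(1, 4))
    transcripts = []
    for t in range(n_tx):
        if t == 0:
            u5, u3 = utr5_full, utr3_full
        else:
            # alternative transcripts trim the UTRs toward the CDS
            (s5, e5), (s3, e3) = utr5_full[0], utr3_full[0]
            if strand == "+":
                u5 = [(s5 + int(rng.integers(0, e5 - s5 - 20)), e5)]
                u3 = [(s3, e3 - int(rng.integers(0, e3 - s3 - 20)))]
            else:
                u5 = [(s5, e5 - int(rng.integers(0, e5 - s5 - 20)))]
                u3 = [(s3 + int(rng.integers(0, e3 - s3 - 20)), e3)]
        transcripts.append(
            Transcript(
                transcript_id=f"{gene_id}.t{t + 1}",
                cds=list(cds),
                utr5=u5,
                utr3=u3,
            )
        )
    biotype = ("characterized", "unknown", "transposable_element")[
        int(rng.choice(3, p=biotype_props))
    ]
    return GeneRecord(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        biotype=biotype,
        transcripts=transcripts,
    )


# ---------------------------------------------------------------------------
# accession simulation


def simulate_accessions(
    ref: GenomeModel,
    accessions: tuple[str, ...] = DEFAULT_ACCESSIONS,
    snp_rate: float = 0.002,
    n_losses: int = 12,
    n_gains: int = 8,
    n_disruptions: int = 6,
    seed: int | None = None,
    clades: dict[str, tuple[str, ...]] | None = None,
    outlier: str | None = DEFAULT_OUTLIER,
    outlier_rate_mult: float = 10.0,
    n_forced_cds: int = 5,
    implant_gly_ser: bool = True,
    gain_len_range: tuple[int, int] = (2000, 5000),
    decoy_contigs: bool = True,
    disruption_families: dict[str, list[str]] | None = None,
) -> tuple[dict[str, list[VariantCall]], dict[str, list[tuple[str, str]]], TruthSet]:
    """Simulate per-accession variant calls, gain contigs, and the truth set.

    SNPs are placed uniformly: clade members share a common SNP block (so the
    clade is recoverable from SNP distances) plus private SNPs; the outlier
    accession carries ``outlier_rate_mult`` times the private rate.  Per
    accession, ``n_forced_cds`` SNPs are forced into CDS with known
    synonymous/nonsynonymous truth labels, and optionally the canonical
    glycine(GGC)->serine(AGC) substitution (G->A at codon position 1) is
    implanted into the six mutant-line accessions.  Losses are full or
    partial gene deletions; gains are novel sequence contigs; frameshift
    disruptions are CDS indels of length not divisible by 3, drawn from
    ``disruption_families`` transcripts when given.
    """
    if not 0 <= snp_rate < 1:
        raise GenerationError("snp_rate must be in [0, 1)")
    if n_losses > len(ref.genes):
        raise GenerationError(
            f"requested {n_losses} losses but the reference has {len(ref.genes)} genes"
        )
    rng = np.random.default_rng(seed)
    clades = DEFAULT_CLADES if clades is None else clades
    clades = {k: tuple(a for a in v if a in accessions) for k, v in clades.items()}
    truth = TruthSet()
    variants: dict[str, list[VariantCall]] = {a: [] for a in accessions}
    used: dict[str, set[int]] = {a: set() for a in accessions}

    # forced CDS SNPs with known consequence labels
    if implant_gly_ser:
        _implant_gly_ser(ref, accessions, variants, used, truth, rng)
    for acc in accessions:
        for k in range(n_forced_cds):
            want = "synonymous" if k % 2 else "nonsynonymous"
            _force_cds_snp(ref, acc, want, variants, used, truth, rng)

    # clade-shared then private SNPs
    for members in clades.values():
        shared = _sample_snps(ref, snp_rate, rng)
        for acc in members:
            _add_snps(ref, acc, shared, variants, used, truth)
    for acc in accessions:
        rate = snp_rate * (outlier_rate_mult if acc == outlier else 1.0)
        _add_snps(ref, acc, _sample_snps(ref, rate, rng), variants, used, truth)

    # gene losses (full or partial deletions)
    loss_genes = rng.choice(len(ref.genes), size=n_losses, replace=False)
    for gidx in loss_genes:
        gene = ref.genes[int(gidx)]
        acc = accessions[int(rng.integers(0, len(accessions)))]
        cds_pos = sorted(gene.cds_positions())
        if rng.random() < 0.5:
            pad = int(rng.integers(0, 300))
            iv = (max(0, gene.span[0] - pad), gene.span[1] + pad)
            mode = "full"
        else:
            cut = cds_pos[max(0, int(0.9 * len(cds_pos)) - 1)]
            iv = (cds_pos[0], cut + 1)
            mode = "partial"
        truth.implanted_losses.append(
            LossTruth(accession=acc, gene_id=gene.gene_id, interval=iv,
                      chrom=gene.chrom, mode=mode)
        )
        for tx in gene.transcripts:
            truth.disrupted_transcripts.append(
                DisruptionTruth(accession=acc, transcript_id=tx.transcript_id,
                                mechanism="gap")
            )

    # frameshift disruptions in CDS, avoiding lost genes
    lost_pairs = {(l.accession, l.gene_id) for l in truth.implanted_losses}
    candidates = []
    if disruption_families:
        for fam in disruption_families.values():
            candidates.extend(fam)
    else:
        candidates = [t.transcript_id for g in ref.genes for t in g.transcripts[:1]]
    picked = 0
    order = rng.permutation(len(candidates))
    for idx in order:
        if picked >= n_disruptions:
            break
        tid = candidates[int(idx)]
        gene, tx = ref.transcript(tid)
        acc = accessions[int(rng.integers(0, len(accessions)))]
        if (acc, gene.gene_id) in lost_pairs:
            continue
        s, e = tx.cds[len(tx.cds) // 2]
        pos = int(rng.integers(s + 3, e - 6))
        del_len = int(rng.choice([1, 2]))
        seq = ref.chromosomes[gene.chrom]
        variants[acc].append(
            VariantCall(
                chrom=gene.chrom,
                pos=pos,
                ref=seq[pos : pos + 1 + del_len],
                alt=seq[pos],
                accession=acc,
                is_indel=True,
                indel_len=-del_len,
            )
        )
        # all transcripts of the gene share the CDS, so the frameshift breaks
        # every one of them
        for tx_all in gene.transcripts:
            truth.disrupted_transcripts.append(
                DisruptionTruth(
                    accession=acc,
                    transcript_id=tx_all.transcript_id,
                    mechanism="frameshift",
                )
            )
        picked += 1

    # gains: novel contigs absent from the reference
    contigs: dict[str, list[tuple[str, str]]] = {a: [] for a in accessions}
    for k in range(n_gains):
        acc = accessions[int(rng.integers(0, len(accessions)))]
        length = int(rng.integers(*gain_len_range))
        cid = f"{acc}_gain{k}"
        contigs[acc].append((cid, "".join(rng.choice(_BASES, size=length))))
        gclass = "characterized" if rng.random() < 0.3 else "unknown"
        truth.implanted_gains.append(
            GainTruth(accession=acc, contig_id=cid, length=length,
                      gene_class=gclass)
        )
    if decoy_contigs:
        for acc in accessions:
            short = "".join(rng.choice(_BASES, size=int(rng.integers(300, 1900))))
            contigs[acc].append((f"{acc}_short_decoy", short))
            true_gains = [c for c in contigs[acc] if "_gain" in c[0]]
            if true_gains:  # exact copy, exercising the redundancy filter
                cid, seq = true_gains[0]
                contigs[acc].append((f"zz_{acc}_dup_decoy", seq))
    return variants, contigs, truth


def _sample_snps(ref: GenomeModel, rate: float, rng) -> list[tuple[str, int]]:
    out = []
    for chrom, seq in ref.chromosomes.items():
        n = rng.binomial(len(seq), rate)
        if n:
            pos = rng.choice(len(seq), size=n, replace=False)
            out.extend((chrom, int(p)) for p in np.sort(pos))
    return out


def _add_snps(ref, acc, sites, variants, used, truth) -> None:
    for chrom, pos in sites:
        if pos in used[acc]:
            continue
        used[acc].add(pos)
        ref_base = ref.chromosomes[chrom][pos]
        alts = [b for b in "ACGT" if b != ref_base]
        alt = alts[pos % 3]
        variants[acc].append(
            VariantCall(chrom=chrom, pos=pos, ref=ref_base, alt=alt, accession=acc)
        )
        truth.implanted_snps.append(
            SnpTruth(chrom=chrom, pos=pos, ref=ref_base, alt=alt, accession=acc)
        )


def _cds_codons(ref: GenomeModel, rng):
    """Yield (gene, tx, genomic positions of one codon, ref codon) in random order."""
    gene_order = rng.permutation(len(ref.genes))
    for gi in gene_order:
        gene = ref.genes[int(gi)]
        tx = gene.transcripts[0]
        cds = ref.spliced_cds(gene, tx)
        n_codons = len(cds) // 3
        for ci in rng.permutation(n_codons):
            yield gene, tx, int(ci), cds[3 * ci : 3 * ci + 3]


def _genomic_pos_of_cds_offset(ref, gene, tx, off):
    """Genomic position of translation-order CDS offset ``off``."""
    if gene.strand == "-":
        off = tx.cds_len - 1 - off
    for s, e in tx.cds:
        if off < e - s:
            return s + off
        off -= e - s
    raise GenerationError("CDS offset out of range")


def _force_cds_snp(ref, acc, want_effect, variants, used, truth, rng) -> None:
    from Bio.Seq import Seq

    for gene, tx, ci, codon in _cds_codons(ref, rng):
        ref_aa = translate_codon(codon)
        for within in range(3):
            for alt_b in "ACGT":
                if alt_b == codon[within]:
                    continue
                alt_codon = codon[:within] + alt_b + codon[within + 1 :]
                alt_aa = translate_codon(alt_codon)
                effect = (
                    "synonymous"
                    if alt_aa == ref_aa
                    else "stop_gain"
                    if alt_aa == "*"
                    else "stop_loss"
                    if ref_aa == "*"
                    else "nonsynonymous"
                )
                if effect != want_effect:
                    continue
                pos = _genomic_pos_of_cds_offset(ref, gene, tx, 3 * ci + within)
                if pos in used[acc]:
                    continue
                ref_base = ref.chromosomes[gene.chrom][pos]
                alt_base = (
                    alt_b if gene.strand == "+" else str(Seq(alt_b).complement())
                )
                used[acc].add(pos)
                variants[acc].append(
                    VariantCall(chrom=gene.chrom, pos=pos, ref=ref_base,
                                alt=alt_base, accession=acc)
                )
                truth.implanted_snps.append(
                    SnpTruth(
                        chrom=gene.chrom,
                        pos=pos,
                        ref=ref_base,
                        alt=alt_base,
                        accession=acc,
                        region="CDS",
                        effect=effect,
                        aa_change=(ref_aa, alt_aa),
                    )
                )
                return
    raise GenerationError(f"could not force a {want_effect} CDS SNP")


def _implant_gly_ser(ref, accessions, variants, used, truth, rng) -> None:
    """Implant the canonical GGC(Gly)->AGC(Ser) first-position G->A SNP."""
    targets = [a for a in GLY_SER_ACCESSIONS if a in accessions]
    if not targets:
        return
    for gene, tx, ci, codon in _cds_codons(ref, rng):
        if codon != "GGC" or gene.strand != "+":
            continue
        pos = _genomic_pos_of_cds_offset(ref, gene, tx, 3 * ci)
        for acc in targets:
            if pos in used[acc]:
                continue
            used[acc].add(pos)
            variants[acc].append(
                VariantCall(chrom=gene.chrom, pos=pos, ref="G", alt="A",
                            accession=acc)
            )
            truth.implanted_snps.append(
                SnpTruth(
                    chrom=gene.chrom,
                    pos=pos,
                    ref="G",
                    alt="A",
                    accession=acc,
                    region="CDS",
                    effect="nonsynonymous",
                    aa_change=("G", "S"),
                )
            )
        return
    raise GenerationError("no forward-strand GGC codon available for the Gly->Ser implant")


# ---------------------------------------------------------------------------
# depth simulation


def simulate_depth(
    ref: GenomeModel,
    truth: TruthSet,
    accession: str,
    mean_depth: float = 40.0,
    seed: int | None = None,
    dispersion: float | None = None,
) -> dict[str, DepthProfile]:
    """Per-base depth profiles for one accession.

    Depth is Poisson with the given mean (negative binomial with
    ``dispersion`` > 0 for overdispersion: variance = mean + mean^2/dispersion).
    Depth is forced below 4 (residual 0-3x) across this accession's implanted
    deleted intervals.  Deterministic given ``seed``.
    """
    if mean_depth <= 0:
        raise GenerationError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    out = {}
    for chrom, seq in ref.chromosomes.items():
        n = len(seq)
        if dispersion:
            p = dispersion / (dispersion + mean_depth)
            depth = rng.negative_binomial(dispersion, p, size=n)
        else:
            depth = rng.poisson(mean_depth, size=n)
        for loss in truth.implanted_losses:
            if loss.accession == accession and loss.chrom == chrom:
                s, e = loss.interval
                e = min(e, n)
                depth[s:e] = np.minimum(rng.poisson(0.3, size=e - s), 3)
        out[chrom] = DepthProfile(chrom=chrom, depth=depth)
    return out


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(
    ref: GenomeModel,
    de_spec: list[DESpec],
    n_stages: int = 3,
    reference_accession: str = "Dongjin",
    accessions: tuple[str, ...] = DEFAULT_ACCESSIONS,
    sigma: float = 0.2,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, list[DESpec]]:
    """FPKM matrix with implanted differential expression.

    Baseline FPKM per gene is log-normal (median ~20); every accession x
    stage measurement multiplies the baseline by log-normal noise exp(N(0,
    sigma)).  Each ``DESpec`` multiplies (up) or divides (down) the target
    accession/stage by its fold.  The reference accession never carries
    implanted shifts.  Raises on fold < 1.
    """
    if n_stages < 1:
        raise GenerationError("n_stages must be >= 1")
    for d in de_spec:
        if d.fold < 1:
            raise GenerationError(f"DE fold must be >= 1, got {d.fold} for {d.gene_id}")
        if d.accession == reference_accession:
            raise GenerationError("cannot implant DE into the reference accession")
    rng = np.random.default_rng(seed)
    stages = list(STAGES[:n_stages]) if n_stages <= len(STAGES) else [
        f"stage{i + 1}" for i in range(n_stages)
    ]
    genes = [g.gene_id for g in ref.genes]
    baseline = rng.lognormal(mean=3.0, sigma=1.0, size=len(genes))
    cols = pd.MultiIndex.from_product([accessions, stages],
                                      names=["accession", "stage"])
    m = np.empty((len(genes), len(cols)))
    for j, (acc, stage) in enumerate(cols):
        noise = rng.lognormal(0.0, sigma, size=len(genes)) if sigma > 0 else 1.0
        m[:, j] = baseline * noise
    fpkm = pd.DataFrame(m, index=genes, columns=cols)
    gene_idx = {g: i for i, g in enumerate(genes)}
    for d in de_spec:
        if d.gene_id not in gene_idx or d.stage not in stages:
            raise GenerationError(f"DE spec refers to unknown gene/stage: {d}")
        f = d.fold if d.direction == "up" else 1.0 / d.fold
        fpkm.loc[d.gene_id, (d.accession, d.stage)] *= f
    return ExpressionMatrix(fpkm=fpkm, reference=reference_accession), list(de_spec)


# ---------------------------------------------------------------------------
# full study bundle


@dataclass
class SyntheticStudy:
    genome: GenomeModel
    variants: dict[str, list[VariantCall]]
    contigs: dict[str, list[tuple[str, str]]]
    depths: dict[str, dict[str, DepthProfile]]
    expression: ExpressionMatrix
    gene_sets: dict[str, set[str]]
    families: dict[str, list[str]]  # transcript families for disruption screens
    pathway_groups: dict[str, str]
    truth: TruthSet
    accessions: tuple[str, ...]
    reference_accession: str


def simulate_study(
    seed: int | None = None,
    n_chrom: int = 1,
    chrom_len: int = 500_000,
    n_genes: int = 60,
    accessions: tuple[str, ...] = DEFAULT_ACCESSIONS,
    reference_accession: str = "Dongjin",
    mean_depth: float = 40.0,
    snp_rate: float = 0.002,
    n_losses: int = 12,
    n_gains: int = 8,
    n_disruptions: int = 6,
    de_fold: float = 4.0,
    sigma: float = 0.2,
) -> SyntheticStudy:
    """Generate the full default synthetic study.

    Beyond the raw layers, the bundle defines the functional structure the
    screen operates on: a photosynthesis category implanted down-regulated in
    every non-reference accession, a cellular-homeostasis category implanted
    up-regulated, a flavonoid pathway up-shifted in Jado and down-shifted in
    Hwangdo, and magnesium/sulfur transporter families whose implanted
    frameshifts also depress the damaged gene's expression in the affected
    accession (so the transporter pathways surface in the Fisher screen).
    Implanted expression shifts are sustained across all stages.
    """
    ss = np.random.SeedSequence(seed)
    s_ref, s_acc, s_depth, s_expr = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    genome = generate_reference(
        n_chrom=n_chrom, chrom_len=chrom_len, n_genes=n_genes, seed=s_ref
    )
    gene_ids = [g.gene_id for g in genome.genes]
    rng = np.random.default_rng(s_ref + 1)
    order = [gene_ids[i] for i in rng.permutation(len(gene_ids))]
    n = len(order)
    sizes = [max(3, n // 6), max(3, n // 6), max(2, n // 7), max(2, n // 12),
             max(2, n // 8)]
    if sum(sizes) > n:
        raise GenerationError("too few genes to lay out the functional gene sets")
    bounds = np.cumsum([0] + sizes)
    photo, homeo, flav, mg_genes, s_genes = (
        order[bounds[i] : bounds[i + 1]] for i in range(5)
    )
    families = {
        "magnesium_transport": [
            t.transcript_id for g in mg_genes for t in genome.gene(g).transcripts
        ],
        "sulfur_transport": [
            t.transcript_id for g in s_genes for t in genome.gene(g).transcripts
        ],
    }
    gene_sets = {
        "photosynthesis": set(photo),
        "cellular_homeostasis": set(homeo),
        "flavonoid_pathway": set(flav),
        "magnesium_transport": set(mg_genes),
        "sulfur_transport": set(s_genes),
    }
    pathway_groups = {
        "magnesium_transport": "macronutrient_transport",
        "sulfur_transport": "macronutrient_transport",
        "flavonoid_pathway": "flavonoid",
    }
    variants, contigs, truth = simulate_accessions(
        genome,
        accessions=accessions,
        snp_rate=snp_rate,
        n_losses=n_losses,
        n_gains=n_gains,
        n_disruptions=n_disruptions,
        seed=s_acc,
        disruption_families=families,
    )
    depth_ss = np.random.SeedSequence(s_depth)
    depths = {
        acc: simulate_depth(
            genome, truth, acc, mean_depth=mean_depth,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        for acc, child in zip(accessions, depth_ss.spawn(len(accessions)))
    }
    stages = list(STAGES)
    de_spec: list[DESpec] = []
    non_ref = [a for a in accessions if a != reference_accession]
    for acc in non_ref:
        for g in photo:
            de_spec.extend(DESpec(g, acc, st, "down", de_fold) for st in stages)
        for g in homeo:
            de_spec.extend(DESpec(g, acc, st, "up", de_fold) for st in stages)
    if "Jado" in non_ref:
        for g in flav:
            de_spec.extend(DESpec(g, "Jado", st, "up", de_fold) for st in stages)
    if "Hwangdo" in non_ref:
        for g in flav:
            de_spec.extend(DESpec(g, "Hwangdo", st, "down", de_fold) for st in stages)
    tid_to_gene = {
        t.transcript_id: g.gene_id for g in genome.genes for t in g.transcripts
    }
    seen_pairs: set[tuple[str, str]] = set()
    for d in truth.disrupted_transcripts:
        gid = tid_to_gene[d.transcript_id]
        if d.mechanism == "frameshift" and gid in (set(mg_genes) | set(s_genes)):
            if d.accession != reference_accession and (gid, d.accession) not in seen_pairs:
                seen_pairs.add((gid, d.accession))
                de_spec.extend(
                    DESpec(gid, d.accession, st, "down", de_fold) for st in stages
                )
    expression, _ = simulate_expression(
        genome,
        de_spec,
        n_stages=len(stages),
        reference_accession=reference_accession,
        accessions=accessions,
        sigma=sigma,
        seed=s_expr,
    )
    truth.de_genes = de_spec
    return SyntheticStudy(
        genome=genome,
        variants=variants,
        contigs=contigs,
        depths=depths,
        expression=expression,
        gene_sets=gene_sets,
        families=families,
        pathway_groups=pathway_groups,
        truth=truth,
        accessions=tuple(accessions),
        reference_accession=reference_accession,
    )
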