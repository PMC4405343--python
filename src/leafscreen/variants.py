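"""Threshold-based variant calling and consequence annotation.

Calling follows a simple per-site threshold rule (minimum depth 10, minimum
mismatch count 5, mismatch fraction >= 35%) applied to allele counts; there is
no genotype-likelihood model by design.  Annotation assigns each variant a
single region label (see :mod:`leafscreen.genome`) and, for coding SNPs,
reconstructs the affected codon strand-aware and attaches the amino-acid
consequence.  Summaries mirror the layout of per-accession "distribution of
SNPs within genetic regions" tables: counts and one-decimal percentages per
region class, plus an across-accession average row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from leafscreen.genome import (
    CDS,
    FIVE_UTR,
    INTERGENIC,
    INTRON,
    PROMOTER,
    THREE_UTR,
    CodonChange,
    GenomeModel,
)

logger = logging.getLogger(__name__)

_EFFECT_SEVERITY = {"stop_gain": 0, "stop_loss": 1, "nonsynonymous": 2, "synonymous": 3}


class VariantError(ValueError):
    pass


@dataclass
class SiteCounts:
    """Allele counts at one site for one accession."""

    chrom: str
    pos: int  # 0-based
    ref_allele: str
    depth: int
    alt_allele: str
    alt_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.depth:
            raise VariantError(
                f"{self.chrom}:{self.pos}: alt_count {self.alt_count} "
                f"outside [0, depth={self.depth}]"
            )


@dataclass
class VariantCall:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    accession: str
    region: str | None = None
    effect: CodonChange | None = None
    is_indel: bool = False
    indel_len: int = 0  # signed: + insertion, - deletion
    transcript_effects: dict[str, CodonChange] = field(default_factory=dict)

    @property
    def is_snp(self) -> bool:
        return not self.is_indel


def call_variant(
    site: SiteCounts,
    min_depth: int = 10,
    min_mismatch: int = 5,
    min_fraction: float = 0.35,
) -> bool:
    """Apply the threshold calling rule to one site.

    Called iff depth >= ``min_depth`` AND alt count >= ``min_mismatch`` AND
    alt fraction >= ``min_fraction``.  Monotone: raising any threshold never
    turns a not-called site into a called one.
    """
    return (
        site.depth >= min_depth
        and site.alt_count >= min_mismatch
        and site.alt_count / site.depth >= min_fraction
    )


def filter_mapping_regions(
    region_stats: pd.DataFrame,
    min_identity: float = 0.95,
    min_hsp_cov: float = 1.0,
) -> pd.Series:
    """Mask of mapping regions passing identity and coverage thresholds.

    ``region_stats`` needs columns ``chrom, start, end, identity, coverage``
    (fractions in [0,1]).  A region is kept iff identity >= ``min_identity``
    and coverage >= ``min_hsp_cov``.
    """
    for col in ("chrom", "start", "end", "identity", "coverage"):
        if col not in region_stats.columns:
            raise VariantError(f"region_stats missing column {col!r}")
    return (region_stats["identity"] >= min_identity) & (
        region_stats["coverage"] >= min_hsp_cov
    )


def apply_region_filter(
    variants: list[VariantCall],
    region_stats: pd.DataFrame,
    min_identity: float = 0.95,
    min_hsp_cov: float = 1.0,
) -> list[VariantCall]:
    """Retain only variants inside a kept mapping region.

    A variant not covered by any region record is dropped (conservative) and
    counted in a log message.
    """
    keep_mask = filter_mapping_regions(region_stats, min_identity, min_hsp_cov)
    kept = region_stats[keep_mask]
    out, uncovered = [], 0
    covered_any = 0
    for v in variants:
        rows = region_stats[
            (region_stats["chrom"] == v.chrom)
            & (region_stats["start"] <= v.pos)
            & (v.pos < region_stats["end"])
        ]
        if rows.empty:
            uncovered += 1
            continue
        covered_any += 1
        hit = kept[
            (kept["chrom"] == v.chrom) & (kept["start"] <= v.pos) & (v.pos < kept["end"])
        ]
        if not hit.empty:
            out.append(v)
    if uncovered:
        logger.warning("%d variants had no mapping-region stats; dropped", uncovered)
    return out


def annotate_variant(v: VariantCall, genome: GenomeModel) -> VariantCall:
    """Attach region label and, for coding SNPs, the codon consequence.

    The reference allele must match the genome sequence at the site (on the
    forward strand, as in VCF).  For a CDS SNP every transcript whose CDS
    contains the site gets a per-transcript :class:`CodonChange`; ``v.effect``
    is the worst consequence (stop_gain > stop_loss > nonsynonymous >
    synonymous).
    """
    seq = genome.chromosomes[v.chrom]
    if v.is_snp and seq[v.pos] != v.ref:
        raise VariantError(
            f"{v.accession} {v.chrom}:{v.pos}: ref allele {v.ref!r} does not "
            f"match genome base {seq[v.pos]!r}"
        )
    v.region = genome.locate(v.chrom, v.pos)
    v.transcript_effects = {}
    v.effect = None
    if v.region == CDS and v.is_snp:
        from Bio.Seq import Seq

        for gene, tx in genome.transcripts_with_cds_at(v.chrom, v.pos):
            codon, within = genome.codon_at(gene, tx, v.pos)
            alt_base = v.alt if gene.strand == "+" else str(Seq(v.alt).complement())
            alt_codon = codon[:within] + alt_base + codon[within + 1 :]
            v.transcript_effects[tx.transcript_id] = CodonChange.from_codons(
                codon, alt_codon
            )
        if v.transcript_effects:
            v.effect = min(
                v.transcript_effects.values(),
                key=lambda c: _EFFECT_SEVERITY[c.effect],
            )
    return v


def snp_density(
    variants: list[VariantCall], chrom_lengths: dict[str, int], window: int = 10_000
) -> dict[str, np.ndarray]:
    """Variant counts in non-overlapping fixed windows starting at position 0.

    Windows are half-open, so a variant at position ``window`` falls in window
    1.  Counts sum to the number of input variants on known chromosomes.
    """
    tracks = {
        c: np.zeros(max(1, -(-length // window)), dtype=int)
        for c, length in chrom_lengths.items()
    }
    for v in variants:
        tracks[v.chrom][v.pos // window] += 1
    return tracks


_SUMMARY_COLS = [
    "total",
    "cds_sy",
    "cds_ns",
    "cds_total",
    "cds_pct",
    "intron",
    "intron_pct",
    "utr5",
    "utr5_pct",
    "utr3",
    "utr3_pct",
    "promoter",
    "promoter_pct",
    "intergenic",
    "intergenic_pct",
]


def summarize_regions(
    variants_by_accession: dict[str, list[VariantCall]],
    snps_only: bool = True,
) -> pd.DataFrame:
    """Per-accession region distribution with an across-accession average row.

    Counts per region class, percentages against the accession total rounded
    to one decimal, and an ``Average`` row of arithmetic means (counts rounded
    to the nearest integer, percentages recomputed from the averaged counts).
    """
    rows = {}
    for acc, variants in variants_by_accession.items():
        vs = [v for v in variants if v.is_snp] if snps_only else variants
        counts = {
            CDS: 0,
            INTRON: 0,
            FIVE_UTR: 0,
            THREE_UTR: 0,
            PROMOTER: 0,
            INTERGENIC: 0,
        }
        sy = ns = 0
        for v in vs:
            if v.region is None:
                raise VariantError(f"variant at {v.chrom}:{v.pos} is not annotated")
            counts[v.region] += 1
            if v.region == CDS and v.effect is not None:
                if v.effect.effect == "synonymous":
                    sy += 1
                else:
                    ns += 1
        total = len(vs)
        rows[acc] = _summary_row(
            total,
            sy,
            ns,
            counts[CDS],
            counts[INTRON],
            counts[FIVE_UTR],
            counts[THREE_UTR],
            counts[PROMOTER],
            counts[INTERGENIC],
        )
    df = pd.DataFrame.from_dict(rows, orient="index", columns=_SUMMARY_COLS)
    return append_average_row(df)


def _summary_row(total, sy, ns, cds, intron, utr5, utr3, promoter, intergenic):
    def pct(x):
        return round(100.0 * x / total, 1) if total else 0.0

    return [
        total,
        sy,
        ns,
        cds,
        pct(cds),
        intron,
        pct(intron),
        utr5,
        pct(utr5),
        utr3,
        pct(utr3),
        promoter,
        pct(promoter),
        intergenic,
        pct(intergenic),
    ]


def append_average_row(df: pd.DataFrame) -> pd.DataFrame:
    """Append an ``Average`` row: mean counts (rounded), recomputed percentages."""
    counts = [c for c in df.columns if not c.endswith("_pct")]
    avg = {}
    for c in counts:
        avg[c] = int(round(df[c].mean()))
    for c in df.columns:
        if c.endswith("_pct"):
            base = c[: -len("_pct")]
            key = "cds_total" if base == "cds" else base
            avg[c] = round(100.0 * avg[key] / avg["total"], 1) if avg["total"] else 0.0
    out = df.copy()
    out.loc["Average"] = pd.Series(avg)
    return out.astype({c: int for c in counts})
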