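"""Depth-based structural events: coverage gaps, gene losses, and gene gains.

A *gap* is a maximal run of bases mapped at low depth (< 4x) whose two 1-kb
flanks are themselves well covered (> 20x on average), ruling out regions
where the whole neighbourhood maps poorly.  A gene is called *lost* in an
accession when too small a fraction of its CDS bases is adequately covered
(< 20% of CDS bases at >= 4x by default).  *Gains* are novel contigs
assembled from unmapped reads; here they arrive as FASTA records and are
length-filtered and deduplicated (strand-aware self-alignment), assembly
itself being upstream of this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from leafscreen.genome import GenomeModel

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass
class DepthProfile:
    """Per-base read depth along one chromosome for one accession."""

    chrom: str
    depth: np.ndarray  # int per base

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError(f"{self.chrom}: negative depth")


@dataclass
class GeneEvent:
    accession: str
    gene_id: str  # contig id for gains
    kind: str  # "loss" | "gain"
    gene_class: str  # characterized | unknown | transposable_element
    gaps: list[Interval] = field(default_factory=list)
    cds_coverage: float | None = None
    contig_len: int | None = None


def detect_gaps(
    profile: DepthProfile,
    low: int = 4,
    flank_len: int = 1000,
    flank_min: float = 20.0,
    flank_stat: str = "mean",
) -> list[Interval]:
    """Maximal low-depth runs with well-covered 1-kb flanks.

    A run of consecutive bases with depth < ``low`` is reported iff a full
    ``flank_len`` window exists on both sides (runs touching a chromosome end
    are rejected) and the flank depth statistic (mean by default, min with
    ``flank_stat='min'``) strictly exceeds ``flank_min`` on each side.
    Intervals are half-open, disjoint, and sorted.
    """
    d = profile.depth
    is_low = d < low
    if not is_low.any():
        return []
    # run boundaries of the low mask
    padded = np.diff(np.concatenate(([0], is_low.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    stat = np.mean if flank_stat == "mean" else np.min
    gaps = []
    for s, e in zip(starts, ends):
        if s < flank_len or e + flank_len > len(d):
            continue  # no full flank on one side
        if stat(d[s - flank_len : s]) > flank_min and stat(d[e : e + flank_len]) > flank_min:
            gaps.append((int(s), int(e)))
    return gaps


def call_gene_losses(
    profiles: dict[str, DepthProfile],
    genome: GenomeModel,
    accession: str,
    cov_threshold: float = 0.20,
    cov_min_depth: int = 4,
    gap_kwargs: dict | None = None,
) -> list[GeneEvent]:
    """Call genes lost in one accession from its depth profiles.

    A gene is lost iff the fraction of its CDS bases (union over transcripts)
    covered at >= ``cov_min_depth`` is < ``cov_threshold``.  Detected gaps
    overlapping the gene span are attached as evidence.  Genes without CDS
    are skipped with a warning.
    """
    gaps_by_chrom = {
        c: detect_gaps(p, **(gap_kwargs or {})) for c, p in profiles.items()
    }
    events = []
    for gene in genome.genes:
        if gene.chrom not in profiles:
            continue
        cds_pos = sorted(gene.cds_positions())
        if not cds_pos:
            logger.warning("gene %s has no CDS; skipped", gene.gene_id)
            continue
        depth = profiles[gene.chrom].depth
        frac = float(np.mean(depth[np.array(cds_pos)] >= cov_min_depth))
        if frac < cov_threshold:
            s, e = gene.span
            evid = [g for g in gaps_by_chrom[gene.chrom] if g[0] < e and s < g[1]]
            events.append(
                GeneEvent(
                    accession=accession,
                    gene_id=gene.gene_id,
                    kind="loss",
                    gene_class=gene.biotype,
                    gaps=evid,
                    cds_coverage=frac,
                )
            )
    return events


def filter_gain_contigs(
    contigs: list[tuple[str, str]],
    min_len: int = 2000,
    max_redundant_divergence: float = 0.05,
    min_overlap_frac: float = 0.95,
) -> list[tuple[str, str]]:
    """Length-filter and deduplicate gain contigs, longest first.

    Contigs shorter than ``min_len`` are dropped.  A contig is redundant, and
    dropped, when it aligns to an already-retained contig (either strand) with
    <= ``max_redundant_divergence`` edit divergence over at least
    ``min_overlap_frac`` of its own length.
    """
    kept: list[tuple[str, str]] = []
    for cid, seq in sorted(contigs, key=lambda c: (-len(c[1]), c[0])):
        if len(seq) < min_len:
            continue
        if any(_is_redundant(seq, kseq, max_redundant_divergence, min_overlap_frac)
               for _, kseq in kept):
            continue
        kept.append((cid, seq))
    return kept


def _is_redundant(query: str, target: str, max_div: float, min_frac: float) -> bool:
    # infix alignment of the (shorter) query within the retained target
    budget = int(max_div * len(query) + (1 - min_frac) * len(query))
    for q in (query, str(Seq(query).reverse_complement())):
        res = edlib.align(q, target, mode="HW", task="distance", k=budget)
        if res["editDistance"] != -1:
            return True
    return False


def classify_gains(
    contigs: list[tuple[str, str]],
    annotation_map: dict[str, str],
    accession: str,
) -> list[GeneEvent]:
    """Gain events classed by the supplied contig -> gene-class map.

    Contigs with no map entry default to 'unknown' (novel sequence with no
    annotated homolog).
    """
    return [
        GeneEvent(
            accession=accession,
            gene_id=cid,
            kind="gain",
            gene_class=annotation_map.get(cid, "unknown"),
            contig_len=len(seq),
        )
        for cid, seq in contigs
    ]


LOSS_ROWS = [
    ("loss", "total"),
    ("loss", "characterized"),
    ("loss", "unknown"),
    ("loss", "transposable_element"),
    ("gain", "total"),
    ("gain", "characterized"),
    ("gain", "unknown"),
]


def summarize_events(
    events_by_accession: dict[str, list[GeneEvent]]
) -> pd.DataFrame:
    """Loss/gain tallies per class per accession, plus an Average column.

    Rows: loss (total, characterized, unknown, transposable_element) and gain
    (total, characterized, unknown); columns: accessions then ``Average``
    (mean rounded to the nearest integer).
    """
    idx = pd.MultiIndex.from_tuples(LOSS_ROWS, names=["kind", "class"])
    df = pd.DataFrame(0, index=idx, columns=list(events_by_accession))
    for acc, events in events_by_accession.items():
        for ev in events:
            df.loc[(ev.kind, "total"), acc] += 1
            df.loc[(ev.kind, ev.gene_class), acc] += 1
    df["Average"] = df.mean(axis=1).round().astype(int)
    return df
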