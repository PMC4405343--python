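"""Gene-disruption status, clustering, and the Fisher-test candidate screen.

A transcript is *broken* in an accession when a coverage gap overlaps its CDS
or a CDS indel shifts the reading frame (length not a multiple of 3); gap
takes precedence when both apply.  Disruption profiles over a gene family are
clustered hierarchically (Euclidean distance on the 0/1 matrix, average
linkage by default) to group accessions with similar transporter damage.
The candidate screen crosses three evidence layers: membership in a pathway
enriched for differentially expressed genes (two-sided Fisher's exact test,
p <= 0.05), disruption in at least one accession, and a >= 2-fold expression
change at at least one developmental stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import fisher_exact

from leafscreen.genome import GenomeModel, Transcript

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


class ScreenError(ValueError):
    pass


def transcript_status(
    transcript: Transcript,
    gaps: list[Interval],
    indels: list,
) -> tuple[str, str]:
    """(status, mechanism) of one transcript in one accession.

    ``indels`` are variant calls with ``pos`` and signed ``indel_len``.
    Broken iff a gap interval overlaps any CDS block, or a CDS indel has
    length not a multiple of 3; gap wins when both apply.  Returns one of
    ("broken", "gap"), ("broken", "frameshift"), ("normal", "none").
    """
    if not transcript.cds:
        raise ScreenError(f"transcript {transcript.transcript_id} has no CDS")
    for gs, ge in gaps:
        if any(gs < e and s < ge for s, e in transcript.cds):
            return ("broken", "gap")
    for v in indels:
        if getattr(v, "indel_len", 0) % 3 == 0:
            continue
        if any(s <= v.pos < e for s, e in transcript.cds):
            return ("broken", "frameshift")
    return ("normal", "none")


@dataclass
class DisruptionMatrix:
    """Transcripts x accessions broken/normal status with mechanisms."""

    status: pd.DataFrame  # 1 = broken, 0 = normal
    mechanism: pd.DataFrame  # "gap" | "frameshift" | "none"

    @property
    def transcripts(self) -> list[str]:
        return list(self.status.index)

    @property
    def accessions(self) -> list[str]:
        return list(self.status.columns)


def build_disruption_matrix(
    transcript_ids: list[str],
    accessions: list[str],
    genome: GenomeModel,
    gaps_by_accession: dict[str, dict[str, list[Interval]]],
    indels_by_accession: dict[str, list],
) -> DisruptionMatrix:
    """Complete disruption matrix for a transcript family.

    ``gaps_by_accession`` maps accession -> chrom -> gap intervals;
    ``indels_by_accession`` maps accession -> indel variant calls.  Absent
    events mean 'normal' (missing data is disallowed by construction).
    """
    if not transcript_ids:
        raise ScreenError("empty transcript family")
    status = pd.DataFrame(0, index=transcript_ids, columns=accessions, dtype=int)
    mech = pd.DataFrame("none", index=transcript_ids, columns=accessions, dtype=object)
    for tid in transcript_ids:
        try:
            gene, tx = genome.transcript(tid)
        except KeyError as exc:
            raise ScreenError(f"unknown transcript id {tid!r}") from exc
        for acc in accessions:
            gaps = gaps_by_accession.get(acc, {}).get(gene.chrom, [])
            indels = [
                v
                for v in indels_by_accession.get(acc, [])
                if v.is_indel and v.chrom == gene.chrom
            ]
            st, how = transcript_status(tx, gaps, indels)
            status.loc[tid, acc] = int(st == "broken")
            mech.loc[tid, acc] = how
    return DisruptionMatrix(status=status, mechanism=mech)


def cluster_disruptions(
    m: DisruptionMatrix, metric: str = "euclidean", method: str = "average"
) -> dict:
    """Hierarchical clustering of accessions and transcripts.

    Binary encoding broken=1 / normal=0, Euclidean distance (two accessions
    differing in k entries are sqrt(k) apart), average linkage by default.
    Returns linkage matrices and leaf orders for both axes.  Deterministic:
    scipy's agglomeration breaks distance ties by lowest cluster index.
    """
    x = m.status.to_numpy(dtype=float)
    if x.shape[1] < 2:
        logger.warning("single accession: trivial ordering")
        return {
            "accession_linkage": None,
            "accession_order": list(m.accessions),
            "transcript_linkage": None,
            "transcript_order": list(m.transcripts),
        }
    acc_z = linkage(pdist(x.T, metric=metric), method=method)
    tx_z = (
        linkage(pdist(x, metric=metric), method=method) if x.shape[0] > 1 else None
    )
    return {
        "accession_linkage": acc_z,
        "accession_order": [m.accessions[i] for i in leaves_list(acc_z)],
        "transcript_linkage": tx_z,
        "transcript_order": (
            [m.transcripts[i] for i in leaves_list(tx_z)]
            if tx_z is not None
            else list(m.transcripts)
        ),
    }


def fisher_enrichment(
    de_genes: set[str],
    pathway: set[str],
    universe: set[str],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Fisher's exact test for pathway enrichment in a DE gene set.

    2x2 table: (DE & pathway, DE \\ pathway, pathway \\ DE, neither).
    Returns (odds ratio, p-value); two-sided by default, 'greater' for a
    one-sided enrichment test.
    """
    if not universe:
        raise ScreenError("empty gene universe")
    if not pathway <= universe or not de_genes <= universe:
        raise ScreenError("pathway and DE genes must be subsets of the universe")
    a = len(de_genes & pathway)
    b = len(de_genes - pathway)
    c = len(pathway - de_genes)
    d = len(universe) - a - b - c
    odds, p = fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(odds), float(p)


@dataclass
class CandidateGene:
    gene_id: str
    disrupted: bool
    de: bool
    pathways: list[str] = field(default_factory=list)
    group: str | None = None
    fold_changes: dict[str, float] = field(default_factory=dict)


def screen_pathways(
    de: set[str],
    pathways: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> dict[str, tuple[float, float]]:
    """Fisher test over all pathways; returns {pathway: (odds, p)} for p <= alpha."""
    out = {}
    for pid, genes in pathways.items():
        odds, p = fisher_enrichment(de, genes & universe, universe, alternative)
        if p <= alpha:
            out[pid] = (odds, p)
    return out


def integrate_candidates(
    enriched_pathways: dict[str, set[str]],
    disrupted_genes: set[str],
    de: set[str],
    pathway_groups: dict[str, str] | None = None,
    fold_changes: pd.DataFrame | None = None,
) -> list[CandidateGene]:
    """Cross the evidence layers into the final candidate list.

    Candidates are the genes belonging to at least one enriched pathway that
    are additionally disrupted in >= 1 accession or differentially expressed
    at >= 1 stage.  Each candidate carries its evidence flags, supporting
    pathways, group label (from ``pathway_groups``), and per-stage fold
    changes when supplied.
    """
    membership: dict[str, list[str]] = {}
    for pid, genes in enriched_pathways.items():
        for g in genes:
            membership.setdefault(g, []).append(pid)
    candidates = []
    for gene_id in sorted(membership):
        is_disrupted = gene_id in disrupted_genes
        is_de = gene_id in de
        if not (is_disrupted or is_de):
            continue
        pids = sorted(membership[gene_id])
        group = None
        if pathway_groups:
            groups = {pathway_groups[p] for p in pids if p in pathway_groups}
            group = ";".join(sorted(groups)) if groups else None
        fc = {}
        if fold_changes is not None and gene_id in fold_changes.index:
            fc = {str(k): float(v) for k, v in fold_changes.loc[gene_id].items()}
        candidates.append(
            CandidateGene(
                gene_id=gene_id,
                disrupted=is_disrupted,
                de=is_de,
                pathways=pids,
                group=group,
                fold_changes=fc,
            )
        )
    return candidates
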