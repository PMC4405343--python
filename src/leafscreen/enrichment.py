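"""FPKM fold changes and running-sum gene-set enrichment (GSEA).

Expression arrives as an FPKM matrix over genes x (accession, stage) with a
designated reference accession.  Genes are ranked by log2 fold change against
the reference; a gene set's enrichment score (ES) is the signed maximum
deviation of the running sum that increments on set members (weighted by the
ranking metric) and decrements on non-members.  Because the design has a
single library per accession and stage, significance uses gene-label
permutation: random same-size gene sets drawn from the ranked universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES = ("30d", "45d", "60d")


class EnrichmentError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """FPKM values over genes x (accession, stage) with a reference accession."""

    fpkm: pd.DataFrame  # index: gene ids; columns: MultiIndex (accession, stage)
    reference: str

    def __post_init__(self) -> None:
        if (self.fpkm.to_numpy() < 0).any():
            raise EnrichmentError("FPKM values must be non-negative")
        if self.reference not in self.accessions:
            raise EnrichmentError(f"reference accession {self.reference!r} absent")

    @property
    def accessions(self) -> list[str]:
        return list(self.fpkm.columns.get_level_values(0).unique())

    @property
    def stages(self) -> list[str]:
        return list(self.fpkm.columns.get_level_values(1).unique())


def fold_change(
    m: ExpressionMatrix, accession: str, stage: str, pseudocount: float = 1.0
) -> pd.Series:
    """Per-gene log2((FPKM_acc + eps) / (FPKM_ref + eps)) at one stage."""
    if accession == m.reference:
        raise EnrichmentError("fold change of the reference against itself")
    try:
        acc = m.fpkm[(accession, stage)]
        ref = m.fpkm[(m.reference, stage)]
    except KeyError as exc:
        raise EnrichmentError(f"unknown accession/stage {exc}") from exc
    return np.log2((acc + pseudocount) / (ref + pseudocount))


def de_genes(
    m: ExpressionMatrix,
    accession: str,
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
    rule: str = "any",
) -> set[str]:
    """Genes differentially expressed vs. the reference accession.

    A gene is DE when its absolute fold change is >= ``min_fold`` (i.e.
    |log2 ratio| >= log2(min_fold)) at any stage (``rule='any'``, default) or
    at every stage (``rule='all'``).
    """
    cut = np.log2(min_fold)
    flags = pd.DataFrame(
        {s: fold_change(m, accession, s, pseudocount).abs() >= cut for s in m.stages}
    )
    hit = flags.any(axis=1) if rule == "any" else flags.all(axis=1)
    return set(hit.index[hit])


@dataclass
class EnrichmentResult:
    gene_set_id: str
    es: float
    p_value: float
    direction: str  # "up" | "down"
    leading_edge: list[str] = field(default_factory=list)
    n_perm: int = 0


def _ranked(ranking: pd.Series) -> pd.Series:
    if ranking.index.has_duplicates:
        raise EnrichmentError("ranking contains duplicate gene ids")
    # deterministic order: descending metric, gene id as tie-break
    order = sorted(ranking.index, key=lambda g: (-ranking[g], g))
    return ranking.loc[order]


def _es_curve(metric: np.ndarray, hit: np.ndarray, p: float) -> np.ndarray:
    n = len(metric)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise EnrichmentError("gene set has empty intersection with the ranking")
    if n_hit == n:
        return np.zeros(n)  # set == universe: no misses, ES defined as 0
    w = np.abs(metric) ** p if p > 0 else np.ones(n)
    wsum = (w * hit).sum()
    if wsum == 0:  # all hit weights zero (flat metric): fall back to p=0
        w = np.ones(n)
        wsum = float(n_hit)
    p_hit = np.cumsum(w * hit) / wsum
    p_miss = np.cumsum(~hit) / (n - n_hit)
    return p_hit - p_miss


def _es_from_curve(curve: np.ndarray) -> float:
    if not len(curve) or not curve.any():
        return 0.0
    i = int(np.argmax(np.abs(curve)))
    return float(curve[i])


def gsea_score(
    ranking: pd.Series, gene_set: set[str], p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Enrichment score and running-sum curve for one gene set.

    ``ranking`` maps gene id -> ranking metric; genes are walked in
    descending metric order.  Set members add ``|metric|^p`` normalised by the
    total member weight; non-members subtract ``1/(N - N_hit)``.  The ES is
    the curve value of largest magnitude (positive: concentration at the top
    of the ranking).  Genes in the set but absent from the ranking are
    ignored; a set covering the whole ranking has ES 0.
    """
    r = _ranked(ranking)
    hit = np.fromiter((g in gene_set for g in r.index), dtype=bool, count=len(r))
    curve = _es_curve(r.to_numpy(dtype=float), hit, p)
    return _es_from_curve(curve), curve


def gsea_significance(
    ranking: pd.Series,
    gene_set: set[str],
    n_perm: int = 1000,
    seed: int | None = None,
    p: float = 1.0,
    gene_set_id: str = "",
) -> EnrichmentResult:
    """Permutation p-value for a gene set's enrichment score.

    The null resamples gene labels: ``n_perm`` random sets of the same size
    drawn from the ranked universe.  p = (1 + #{|ES_perm| >= |ES_obs|}) /
    (n_perm + 1), so p is always in (0, 1].
    """
    if n_perm < 1:
        raise EnrichmentError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    r = _ranked(ranking)
    genes = list(r.index)
    metric = r.to_numpy(dtype=float)
    hit = np.fromiter((g in gene_set for g in genes), dtype=bool, count=len(genes))
    curve = _es_curve(metric, hit, p)
    es = _es_from_curve(curve)
    n_hit = int(hit.sum())
    exceed = 0
    for _ in range(n_perm):
        perm_hit = np.zeros(len(genes), dtype=bool)
        perm_hit[rng.choice(len(genes), size=n_hit, replace=False)] = True
        if n_hit == len(genes):
            es_p = 0.0
        else:
            es_p = _es_from_curve(_es_curve(metric, perm_hit, p))
        if abs(es_p) >= abs(es):
            exceed += 1
    p_value = (1 + exceed) / (n_perm + 1)
    if es >= 0:
        peak = int(np.argmax(np.abs(curve)))
        leading = [g for k, g in enumerate(genes[: peak + 1]) if hit[k]]
    else:
        peak = int(np.argmax(np.abs(curve)))
        leading = [g for k, g in enumerate(genes) if k >= peak and hit[k]]
    return EnrichmentResult(
        gene_set_id=gene_set_id,
        es=es,
        p_value=p_value,
        direction="up" if es >= 0 else "down",
        leading_edge=leading,
        n_perm=n_perm,
    )


def category_regulation(
    m: ExpressionMatrix,
    categories: dict[str, set[str]],
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    p: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-accession up/down/neutral call for each gene-set category.

    Each non-reference accession is ranked by its mean log2 fold change over
    stages; a category is called 'up' when its ES is significantly positive
    at level ``alpha``, 'down' when significantly negative, else 'neutral'.
    The reference accession (fold change identically zero against itself) is
    reported neutral throughout.
    """
    ss = np.random.SeedSequence(seed)
    out = pd.DataFrame(
        "neutral", index=m.accessions, columns=list(categories), dtype=object
    )
    for acc in m.accessions:
        if acc == m.reference:
            continue
        metric = pd.DataFrame(
            {s: fold_change(m, acc, s, pseudocount) for s in m.stages}
        ).mean(axis=1)
        for cat, genes in categories.items():
            child = ss.spawn(1)[0]
            res = gsea_significance(
                metric,
                genes,
                n_perm=n_perm,
                seed=int(child.generate_state(1)[0] % (2**31)),
                p=p,
                gene_set_id=cat,
            )
            if res.p_value <= alpha:
                out.loc[acc, cat] = res.direction
    return out
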