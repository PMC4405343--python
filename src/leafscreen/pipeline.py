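"""End-to-end orchestration: dataset layout, stage runners, report bundle.

A *dataset directory* is the on-disk interchange format between the
synthetic generator (or a user's own data prepared in the same layout) and
the pipeline::

    reference.fasta      genes.gff3        meta.json
    vcf/<acc>.vcf        depth/<acc>.bedgraph      contigs/<acc>.fasta
    contig_annotation.tsv fpkm.tsv         gene_sets.gmt
    families.tsv         pathway_groups.tsv
    truth/*.tsv          (present only for synthetic data; never read by run)

``run_pipeline`` executes variants -> structural -> population ->
expression -> screen, writing per-stage TSV/BED/newick outputs plus a
machine-readable ``summary.json``.  Any stage failure raises
:class:`StageError` naming the stage.  Reruns with the same seed produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np
import pandas as pd

from leafscreen import enrichment, io, phylo, screen, structural, variants as var
from leafscreen.config import PipelineConfig
from leafscreen.simulate import SyntheticStudy


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# dataset writing / loading


def write_study(study: SyntheticStudy, out_dir: str) -> None:
    """Serialise a synthetic study into a dataset directory (all plain text)."""
    io.ensure_dir(out_dir)
    chrom_lengths = {c: len(s) for c, s in study.genome.chromosomes.items()}
    io.write_fasta(study.genome.chromosomes, os.path.join(out_dir, "reference.fasta"))
    io.write_gff3(study.genome, os.path.join(out_dir, "genes.gff3"))
    io.ensure_dir(os.path.join(out_dir, "vcf"))
    io.ensure_dir(os.path.join(out_dir, "depth"))
    io.ensure_dir(os.path.join(out_dir, "contigs"))
    for acc in study.accessions:
        io.write_vcf(
            study.variants[acc],
            os.path.join(out_dir, "vcf", f"{acc}.vcf"),
            chrom_lengths,
            acc,
        )
        io.write_bedgraph(
            study.depths[acc], os.path.join(out_dir, "depth", f"{acc}.bedgraph")
        )
        io.write_fasta(
            study.contigs[acc], os.path.join(out_dir, "contigs", f"{acc}.fasta")
        )
    pd.DataFrame(
        [(g.contig_id, g.gene_class) for g in study.truth.implanted_gains],
        columns=["contig_id", "gene_class"],
    ).to_csv(os.path.join(out_dir, "contig_annotation.tsv"), sep="\t", index=False)
    io.write_fpkm_tsv(study.expression, os.path.join(out_dir, "fpkm.tsv"))
    io.write_gmt(study.gene_sets, os.path.join(out_dir, "gene_sets.gmt"))
    pd.DataFrame(
        [(fam, tid) for fam, tids in study.families.items() for tid in tids],
        columns=["family", "transcript_id"],
    ).to_csv(os.path.join(out_dir, "families.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(study.pathway_groups.items()), columns=["pathway", "group"]
    ).to_csv(os.path.join(out_dir, "pathway_groups.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "meta.json"), "w") as fh:
        json.dump(
            {
                "accessions": list(study.accessions),
                "reference_accession": study.reference_accession,
                "chrom_lengths": chrom_lengths,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    tdir = io.ensure_dir(os.path.join(out_dir, "truth"))
    for name in (
        "implanted_snps",
        "implanted_losses",
        "implanted_gains",
        "de_genes",
        "disrupted_transcripts",
    ):
        rows = [dataclasses.asdict(r) for r in getattr(study.truth, name)]
        pd.DataFrame(rows).to_csv(
            os.path.join(tdir, f"{name}.tsv"), sep="\t", index=False
        )


def load_meta(input_dir: str) -> dict:
    with open(os.path.join(input_dir, "meta.json")) as fh:
        return json.load(fh)


def load_genome(input_dir: str):
    chroms = io.read_fasta(os.path.join(input_dir, "reference.fasta"))
    return io.read_gff3(os.path.join(input_dir, "genes.gff3"), chroms)


def load_variants(input_dir: str, accessions: list[str]):
    return {
        acc: io.read_vcf(os.path.join(input_dir, "vcf", f"{acc}.vcf"), acc)
        for acc in accessions
    }


# ---------------------------------------------------------------------------
# stage runners


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc

        wrapped.__name__ = fn.__name__
        wrapped.__doc__ = fn.__doc__
        return wrapped

    return deco


@_stage("variants")
def run_variants(cfg: PipelineConfig, ctx: dict) -> None:
    genome, meta = ctx["genome"], ctx["meta"]
    calls = load_variants(cfg.input_dir, meta["accessions"])
    for acc, vs in calls.items():
        for v in vs:
            var.annotate_variant(v, genome)
    ctx["variants"] = calls
    summary = var.summarize_regions(calls)
    summary.to_csv(
        os.path.join(cfg.out_dir, "region_summary.tsv"), sep="\t",
        index_label="accession",
    )
    rows = []
    for acc, vs in calls.items():
        tracks = var.snp_density(
            [v for v in vs if v.is_snp], meta["chrom_lengths"], cfg.snp_window
        )
        for chrom, counts in tracks.items():
            for w, n in enumerate(counts):
                rows.append((acc, chrom, w * cfg.snp_window, n))
    pd.DataFrame(rows, columns=["accession", "chrom", "window_start", "n_snps"]).to_csv(
        os.path.join(cfg.out_dir, "snp_density.tsv"), sep="\t", index=False
    )
    ctx["summary"]["n_variants"] = {a: len(v) for a, v in calls.items()}


@_stage("structural")
def run_structural(cfg: PipelineConfig, ctx: dict) -> None:
    genome, meta = ctx["genome"], ctx["meta"]
    gap_kwargs = dict(
        low=cfg.gap_low,
        flank_len=cfg.flank_len,
        flank_min=cfg.flank_min,
        flank_stat=cfg.flank_stat,
    )
    gaps_by_acc: dict[str, dict[str, list]] = {}
    events: dict[str, list] = {}
    ann = pd.read_csv(
        os.path.join(cfg.input_dir, "contig_annotation.tsv"), sep="\t"
    )
    annotation_map = dict(zip(ann["contig_id"], ann["gene_class"]))
    gap_bed_dir = io.ensure_dir(os.path.join(cfg.out_dir, "gaps"))
    for acc in meta["accessions"]:
        profiles = io.read_bedgraph(
            os.path.join(cfg.input_dir, "depth", f"{acc}.bedgraph"),
            meta["chrom_lengths"],
        )
        gaps_by_acc[acc] = {
            c: structural.detect_gaps(p, **gap_kwargs) for c, p in profiles.items()
        }
        io.write_bed(
            [(c, s, e) for c, gs in gaps_by_acc[acc].items() for s, e in gs],
            os.path.join(gap_bed_dir, f"{acc}.bed"),
        )
        losses = structural.call_gene_losses(
            profiles,
            genome,
            acc,
            cov_threshold=cfg.cov_threshold,
            cov_min_depth=cfg.cov_min_depth,
            gap_kwargs=gap_kwargs,
        )
        contigs = list(
            io.read_fasta(os.path.join(cfg.input_dir, "contigs", f"{acc}.fasta")).items()
        )
        retained = structural.filter_gain_contigs(contigs, min_len=cfg.contig_min_len)
        gains = structural.classify_gains(retained, annotation_map, acc)
        events[acc] = losses + gains
    ctx["gaps"] = gaps_by_acc
    ctx["events"] = events
    structural.summarize_events(events).to_csv(
        os.path.join(cfg.out_dir, "events_summary.tsv"), sep="\t"
    )
    rows = [
        (
            ev.accession,
            ev.kind,
            ev.gene_id,
            ev.gene_class,
            ev.cds_coverage if ev.cds_coverage is not None else "",
            ev.contig_len if ev.contig_len is not None else "",
        )
        for acc in sorted(events)
        for ev in events[acc]
    ]
    pd.DataFrame(
        rows,
        columns=["accession", "kind", "gene_or_contig", "class", "cds_coverage",
                 "contig_len"],
    ).to_csv(os.path.join(cfg.out_dir, "gene_events.tsv"), sep="\t", index=False)
    ctx["summary"]["n_losses"] = sum(
        1 for evs in events.values() for e in evs if e.kind == "loss"
    )
    ctx["summary"]["n_gains"] = sum(
        1 for evs in events.values() for e in evs if e.kind == "gain"
    )


@_stage("population")
def run_population(cfg: PipelineConfig, ctx: dict) -> None:
    calls = ctx["variants"]
    g = phylo.genotype_matrix(calls)
    d = phylo.snp_distance_matrix(g)
    phylo.write_phylip_distances(d, os.path.join(cfg.out_dir, "distances.phylip"))
    tree = phylo.bootstrap_support(g, n_reps=cfg.n_boot, seed=cfg.seed)
    io.write_newick(tree, os.path.join(cfg.out_dir, "tree.nwk"))
    ctx["tree"] = tree
    ctx["summary"]["n_sites"] = int(g.shape[1])


@_stage("expression")
def run_expression(cfg: PipelineConfig, ctx: dict) -> None:
    fpkm_path = os.path.join(cfg.input_dir, "fpkm.tsv")
    if not os.path.exists(fpkm_path):
        raise StageError("expression", f"missing FPKM file {fpkm_path}")
    m = io.read_fpkm_tsv(fpkm_path, reference=cfg.reference_accession)
    gene_sets = io.read_gmt(os.path.join(cfg.input_dir, "gene_sets.gmt"))
    regulation = enrichment.category_regulation(
        m,
        gene_sets,
        alpha=cfg.alpha,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
        p=cfg.gsea_weight,
        pseudocount=cfg.pseudocount,
    )
    regulation.to_csv(
        os.path.join(cfg.out_dir, "category_regulation.tsv"), sep="\t",
        index_label="accession",
    )
    de_by_acc = {
        acc: enrichment.de_genes(
            m, acc, min_fold=cfg.fold_threshold, pseudocount=cfg.pseudocount,
            rule=cfg.de_rule,
        )
        for acc in m.accessions
        if acc != m.reference
    }
    ctx["expression"] = m
    ctx["gene_sets"] = gene_sets
    ctx["de_by_acc"] = de_by_acc
    ctx["summary"]["n_de_genes"] = len(set().union(*de_by_acc.values()))


@_stage("screen")
def run_screen(cfg: PipelineConfig, ctx: dict) -> None:
    genome, meta = ctx["genome"], ctx["meta"]
    fam_df = pd.read_csv(os.path.join(cfg.input_dir, "families.tsv"), sep="\t")
    families = {
        fam: list(sub["transcript_id"]) for fam, sub in fam_df.groupby("family")
    }
    groups_path = os.path.join(cfg.input_dir, "pathway_groups.tsv")
    pathway_groups = {}
    if os.path.exists(groups_path):
        gdf = pd.read_csv(groups_path, sep="\t")
        pathway_groups = dict(zip(gdf["pathway"], gdf["group"]))
    indels_by_acc = {
        acc: [v for v in vs if v.is_indel] for acc, vs in ctx["variants"].items()
    }
    # full-genome disruption status feeds the candidate screen
    all_tx = [t.transcript_id for g in genome.genes for t in g.transcripts]
    full = screen.build_disruption_matrix(
        all_tx, meta["accessions"], genome, ctx["gaps"], indels_by_acc
    )
    tid_to_gene = {t.transcript_id: g.gene_id for g in genome.genes
                   for t in g.transcripts}
    broken_any = full.status.any(axis=1)
    disrupted_genes = {tid_to_gene[t] for t in full.status.index[broken_any]}
    # family-level matrices and clusterings
    for fam, tids in families.items():
        m = screen.build_disruption_matrix(
            tids, meta["accessions"], genome, ctx["gaps"], indels_by_acc
        )
        out = m.status.copy()
        out.to_csv(
            os.path.join(cfg.out_dir, f"disruption_{fam}.tsv"), sep="\t",
            index_label="transcript_id",
        )
        m.mechanism.to_csv(
            os.path.join(cfg.out_dir, f"disruption_{fam}_mechanism.tsv"), sep="\t",
            index_label="transcript_id",
        )
        cl = screen.cluster_disruptions(m, method=cfg.linkage_method)
        with open(os.path.join(cfg.out_dir, f"cluster_{fam}.json"), "w") as fh:
            json.dump(
                {
                    "accession_order": cl["accession_order"],
                    "transcript_order": cl["transcript_order"],
                },
                fh,
                indent=1,
            )
    de_union: set[str] = set().union(*ctx["de_by_acc"].values())
    universe = {g.gene_id for g in genome.genes}
    gene_sets = ctx["gene_sets"]
    enriched_stats = screen.screen_pathways(
        de_union & universe,
        gene_sets,
        universe,
        alpha=cfg.alpha,
        alternative=cfg.fisher_alternative,
    )
    pd.DataFrame(
        [(pid, odds, p) for pid, (odds, p) in sorted(enriched_stats.items())],
        columns=["pathway", "odds_ratio", "p_value"],
    ).to_csv(os.path.join(cfg.out_dir, "enrichment.tsv"), sep="\t", index=False)
    enriched_sets = {pid: gene_sets[pid] & universe for pid in enriched_stats}
    fold_table = pd.DataFrame(
        {
            f"{acc}:{stage}": enrichment.fold_change(
                ctx["expression"], acc, stage, cfg.pseudocount
            )
            for acc in ctx["expression"].accessions
            if acc != ctx["expression"].reference
            for stage in ctx["expression"].stages
        }
    )
    candidates = screen.integrate_candidates(
        enriched_sets,
        disrupted_genes,
        de_union,
        pathway_groups=pathway_groups,
        fold_changes=fold_table,
    )
    pd.DataFrame(
        [
            (
                c.gene_id,
                int(c.disrupted),
                int(c.de),
                ";".join(c.pathways),
                c.group or "",
            )
            for c in candidates
        ],
        columns=["gene_id", "disrupted", "de", "pathways", "group"],
    ).to_csv(os.path.join(cfg.out_dir, "candidates.tsv"), sep="\t", index=False)
    ctx["candidates"] = candidates
    ctx["summary"]["n_enriched_pathways"] = len(enriched_stats)
    ctx["summary"]["n_candidates"] = len(candidates)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages over a dataset directory; returns the summary dict."""
    io.ensure_dir(cfg.out_dir)
    ctx: dict = {"summary": {"seed": cfg.seed}}
    try:
        ctx["meta"] = load_meta(cfg.input_dir)
        ctx["genome"] = load_genome(cfg.input_dir)
    except Exception as exc:
        raise StageError("load", str(exc)) from exc
    run_variants(cfg, ctx)
    run_structural(cfg, ctx)
    run_population(cfg, ctx)
    run_expression(cfg, ctx)
    run_screen(cfg, ctx)
    with open(os.path.join(cfg.out_dir, "summary.json"), "w") as fh:
        json.dump(ctx["summary"], fh, indent=1, sort_keys=True)
    return ctx["summary"]
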