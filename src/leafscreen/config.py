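"""Pipeline configuration: every threshold of every stage, validated once."""

from __future__ import annotations

from pydantic import BaseModel, Field


class PipelineConfig(BaseModel):
    """All inputs, outputs, and thresholds of the integrated screen.

    The seed is mandatory: bootstrap and permutation stages are stochastic
    and the pipeline promises byte-identical reruns for a fixed seed.
    """

    input_dir: str
    out_dir: str
    seed: int
    reference_accession: str = "Dongjin"

    # read QC
    q_min: int = Field(20, ge=0)
    min_len: int = Field(90, ge=0)
    max_n_frac: float = Field(0.10, ge=0.0, le=1.0)

    # variant calling
    min_depth: int = Field(10, ge=1)
    min_mismatch: int = Field(5, ge=1)
    min_fraction: float = Field(0.35, ge=0.0, le=1.0)
    snp_window: int = Field(10_000, ge=1)

    # structural events
    gap_low: int = Field(4, ge=1)
    flank_len: int = Field(1000, ge=1)
    flank_min: float = Field(20.0, ge=0.0)
    flank_stat: str = "mean"
    cov_threshold: float = Field(0.20, gt=0.0, le=1.0)
    cov_min_depth: int = Field(4, ge=1)
    contig_min_len: int = Field(2000, ge=1)

    # population structure
    n_boot: int = Field(1000, ge=1)

    # expression / enrichment
    fold_threshold: float = Field(2.0, ge=1.0)
    de_rule: str = "any"  # "any" or "all" developmental stages
    pseudocount: float = Field(1.0, ge=0.0)
    alpha: float = Field(0.05, gt=0.0, le=1.0)
    n_perm: int = Field(1000, ge=1)
    gsea_weight: float = Field(1.0, ge=0.0)

    # candidate screen
    fisher_alternative: str = "two-sided"
    linkage_method: str = "average"
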