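"""Reference per-accession summary statistics for the ten-accession panel.

Per-accession summary rows for the ten rice leaf-color accessions the
default synthetic panel emulates (the Dongjin, Jado and Hwangdo cultivars
plus seven Dongjin-derived mutant lines): mapping depth and coverage, gene
loss/gain tallies by class, and the distribution of SNPs across genetic
regions.  They serve as the worked arithmetic dataset for the
across-accession summary operations — the average row of each table is
*recomputed* from the per-accession rows, with the same rounding
conventions as :func:`leafscreen.variants.append_average_row`.
"""

from __future__ import annotations

import pandas as pd

ACCESSIONS = (
    "D052",
    "D056",
    "D101",
    "D120",
    "D122",
    "D128",
    "D131",
    "Hwangdo",
    "Jado",
    "Dongjin",
)

# mapping depth and reference coverage per accession
_MAPPING = {
    #            depth  all-mapped cov %  >=3-read cov %
    "D052": (39.04, 97.6, 96.4),
    "D056": (41.02, 97.6, 96.2),
    "D101": (40.86, 97.7, 96.4),
    "D120": (37.85, 97.6, 96.4),
    "D122": (42.94, 97.4, 95.5),
    "D128": (41.38, 97.6, 96.3),
    "D131": (38.36, 97.4, 95.9),
    "Hwangdo": (34.55, 91.5, 88.2),
    "Jado": (36.48, 97.2, 94.9),
    "Dongjin": (36.03, 97.6, 95.9),
}

# gene loss / gain events per accession, by gene class
_EVENTS = {
    #            loss: total char unk TE   gain: total char unk
    "D052": (167, 29, 105, 33, 79, 26, 53),
    "D056": (147, 31, 95, 21, 70, 20, 50),
    "D101": (98, 19, 62, 17, 85, 25, 60),
    "D120": (155, 27, 96, 32, 78, 25, 53),
    "D122": (244, 52, 148, 44, 74, 21, 53),
    "D128": (104, 23, 65, 16, 81, 20, 61),
    "D131": (148, 33, 88, 27, 82, 23, 59),
    "Hwangdo": (270, 61, 169, 40, 317, 79, 238),
    "Jado": (395, 102, 233, 60, 2, 0, 2),
    "Dongjin": (224, 43, 137, 44, 54, 16, 38),
}

# SNP counts per genetic region per accession
_SNP_REGIONS = {
    #            total    CDS-SY  CDS-NS  CDS     intron  5'UTR  3'UTR  promoter intergenic
    "D052": (336_101, 36_538, 20_701, 57_239, 55_479, 3_126, 5_561, 70_529, 144_167),
    "D056": (334_957, 36_227, 20_033, 56_260, 54_989, 3_031, 5_669, 71_375, 143_633),
    "D101": (563_811, 53_244, 30_630, 83_874, 92_100, 5_567, 10_933, 129_283, 242_054),
    "D120": (334_278, 36_596, 20_208, 56_804, 55_119, 3_071, 5_590, 70_520, 143_174),
    "D122": (382_402, 37_808, 22_855, 60_663, 62_022, 2_900, 5_891, 83_085, 167_841),
    "D128": (415_239, 44_937, 26_523, 71_460, 66_203, 3_468, 6_426, 86_776, 180_906),
    "D131": (421_219, 45_124, 26_040, 71_164, 68_145, 3_246, 6_558, 90_200, 181_906),
    "Hwangdo": (3_724_388, 266_772, 212_176, 478_948, 612_986, 29_788, 70_171, 894_150, 1_638_345),
    "Jado": (294_871, 30_632, 16_895, 47_527, 48_323, 2_548, 4_926, 63_758, 127_789),
    "Dongjin": (323_873, 31_295, 18_594, 49_889, 52_207, 2_966, 6_364, 72_963, 139_484),
}


def mapping_table() -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        _MAPPING,
        orient="index",
        columns=["depth", "mapped_coverage_pct", "mapped3x_coverage_pct"],
    ).loc[list(ACCESSIONS)]


def events_table() -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        _EVENTS,
        orient="index",
        columns=[
            "loss_total",
            "loss_characterized",
            "loss_unknown",
            "loss_te",
            "gain_total",
            "gain_characterized",
            "gain_unknown",
        ],
    ).loc[list(ACCESSIONS)]


def snp_region_table() -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        _SNP_REGIONS,
        orient="index",
        columns=[
            "total",
            "cds_sy",
            "cds_ns",
            "cds_total",
            "intron",
            "utr5",
            "utr3",
            "promoter",
            "intergenic",
        ],
    ).loc[list(ACCESSIONS)]


def summary_statistics() -> dict[str, float]:
    """Across-accession averages recomputed from the per-accession rows.

    Counts are averaged and rounded to the nearest integer; depths and
    coverages to one decimal; region percentages are recomputed against the
    averaged total and rounded to one decimal.
    """
    mapping = mapping_table()
    events = events_table()
    snps = snp_region_table()
    avg_total = int(round(snps["total"].mean()))
    avg_cds = int(round(snps["cds_total"].mean()))
    avg_intron = int(round(snps["intron"].mean()))
    return {
        "mean_depth": round(float(mapping["depth"].mean()), 1),
        "mapped_coverage_pct": round(float(mapping["mapped_coverage_pct"].mean()), 1),
        "mapped3x_coverage_pct": round(float(mapping["mapped3x_coverage_pct"].mean()), 1),
        "avg_gene_losses": int(round(events["loss_total"].mean())),
        "avg_gene_gains": int(round(events["gain_total"].mean())),
        "avg_te_losses": int(round(events["loss_te"].mean())),
        "avg_snps_per_accession": avg_total,
        "cds_snp_pct": round(100.0 * avg_cds / avg_total, 1),
        "intron_snp_pct": round(100.0 * avg_intron / avg_total, 1),
    }
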