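"""Variant calling thresholds, consequence annotation, and region summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from leafscreen.variants import (
    SiteCounts,
    VariantCall,
    VariantError,
    annotate_variant,
    apply_region_filter,
    call_variant,
    filter_mapping_regions,
    snp_density,
    summarize_regions,
)


def site(depth, alt):
    return SiteCounts(chrom="chr1", pos=100, ref_allele="A", depth=depth,
                      alt_allele="G", alt_count=alt)


class TestCallVariant:
    @pytest.mark.parametrize(
        "depth,alt,called",
        [
            (12, 6, True),   # all thresholds met (0.5 >= 0.35)
            (9, 9, False),   # below minimum depth
            (20, 6, False),  # 0.30 < 0.35 although counts pass
            (10, 5, True),   # exact boundary on all three rules
            (10, 4, False),  # below mismatch count
        ],
    )
    def test_threshold_rule(self, depth, alt, called):
        assert call_variant(site(depth, alt)) is called

    @settings(derandomize=True, max_examples=100)
    @given(
        depth=st.integers(1, 100),
        frac=st.floats(0, 1),
        d_depth=st.integers(0, 10),
        d_mm=st.integers(0, 10),
        d_frac=st.floats(0, 0.5),
    )
    def test_monotone_in_thresholds(self, depth, frac, d_depth, d_mm, d_frac):
        """Raising any threshold never converts not-called into called."""
        s = site(depth, int(frac * depth))
        base = call_variant(s, 10, 5, 0.35)
        stricter = call_variant(s, 10 + d_depth, 5 + d_mm, min(1.0, 0.35 + d_frac))
        assert not (stricter and not base)


class TestMappingRegionFilter:
    @pytest.mark.parametrize(
        "identity,coverage,kept",
        [(0.96, 1.0, True), (0.94, 1.0, False), (1.0, 0.99, False)],
    )
    def test_identity_and_coverage_thresholds(self, identity, coverage, kept):
        stats = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000],
             "identity": [identity], "coverage": [coverage]}
        )
        assert bool(filter_mapping_regions(stats).iloc[0]) is kept

    def test_uncovered_variants_dropped_conservatively(self):
        stats = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [100],
             "identity": [1.0], "coverage": [1.0]}
        )
        inside = VariantCall("chr1", 50, "A", "G", "acc")
        outside = VariantCall("chr1", 500, "A", "G", "acc")
        kept = apply_region_filter([inside, outside], stats)
        assert kept == [inside]


class TestAnnotation:
    def test_gly_to_ser_on_plus_strand(self, micro_genome):
        # G->A at position 1 of the GGC codon: glycine -> serine
        v = annotate_variant(
            VariantCall("chr1", 133, "G", "A", "acc"), micro_genome
        )
        assert v.region == "CDS"
        assert v.effect.effect == "nonsynonymous"
        assert (v.effect.ref_aa, v.effect.alt_aa) == ("G", "S")
        assert v.effect.property_change == ("special", "polar-uncharged")

    def test_gly_to_ser_on_minus_strand(self, micro_genome):
        # same codon change seen from the reverse strand: genomic C->T
        v = annotate_variant(
            VariantCall("chr1", 547, "C", "T", "acc"), micro_genome
        )
        assert v.effect.effect == "nonsynonymous"
        assert (v.effect.ref_aa, v.effect.alt_aa) == ("G", "S")

    def test_third_position_wobble_is_synonymous(self, micro_genome):
        v = annotate_variant(
            VariantCall("chr1", 135, "C", "T", "acc"), micro_genome
        )
        assert v.effect.effect == "synonymous"
        assert v.effect.alt_codon == "GGT"

    def test_stop_gain_enumeration_of_tgg(self, micro_genome):
        """All 9 single-base changes of TGG; stop_gain iff TGA or TAG."""
        # TGG codon occupies genomic 136..138 on gp
        for offset, ref_base in enumerate("TGG"):
            pos = 136 + offset
            for alt in "ACGT":
                if alt == ref_base:
                    continue
                v = annotate_variant(
                    VariantCall("chr1", pos, ref_base, alt, "acc"), micro_genome
                )
                alt_codon = "TGG"[:offset] + alt + "TGG"[offset + 1:]
                expected = "stop_gain" if alt_codon in ("TGA", "TAG") else (
                    "synonymous" if alt_codon == "TGG" else "nonsynonymous"
                )
                assert v.effect.effect == expected, alt_codon

    def test_ref_mismatch_raises(self, micro_genome):
        with pytest.raises(VariantError, match="chr1:133"):
            annotate_variant(VariantCall("chr1", 133, "T", "A", "acc"),
                             micro_genome)

    def test_intergenic_variant_has_no_effect(self, micro_genome):
        base = micro_genome.chromosomes["chr1"][1900]
        alt = "A" if base != "A" else "C"
        v = annotate_variant(VariantCall("chr1", 1900, base, alt, "acc"),
                             micro_genome)
        assert v.region == "intergenic" and v.effect is None


class TestDensity:
    def test_all_in_first_window(self):
        vs = [VariantCall("chr1", p, "A", "G", "a") for p in (0, 5, 9999)]
        tracks = snp_density(vs, {"chr1": 30_000})
        assert tracks["chr1"].tolist() == [3, 0, 0]

    def test_window_boundary_is_half_open(self):
        vs = [VariantCall("chr1", 10_000, "A", "G", "a")]
        tracks = snp_density(vs, {"chr1": 30_000})
        assert tracks["chr1"].tolist() == [0, 1, 0]

    def test_empty_input_gives_zero_track(self):
        tracks = snp_density([], {"chr1": 25_000})
        assert tracks["chr1"].sum() == 0 and len(tracks["chr1"]) == 3


class TestSummaries:
    def test_counts_conserved_and_percentages_close(self, micro_genome):
        vs = []
        for pos in (140, 145, 110, 980, 1900, 1901):  # 2 CDS, UTR, intron, 2 inter
            base = micro_genome.chromosomes["chr1"][pos]
            alt = "A" if base != "A" else "C"
            vs.append(
                annotate_variant(VariantCall("chr1", pos, base, alt, "acc"),
                                 micro_genome)
            )
        df = summarize_regions({"acc": vs})
        row = df.loc["acc"]
        assert row["total"] == 6
        region_cols = ["cds_total", "intron", "utr5", "utr3", "promoter",
                       "intergenic"]
        assert sum(row[c] for c in region_cols) == row["total"]
        pct_cols = [c for c in df.columns if c.endswith("_pct")]
        assert sum(row[c] for c in pct_cols) == pytest.approx(100, abs=0.3)

    def test_simple_percentage_arithmetic(self, micro_genome):
        vs = []
        for pos in (140, 141, 143, 146):  # 4 CDS
            base = micro_genome.chromosomes["chr1"][pos]
            alt = "A" if base != "A" else "C"
            vs.append(annotate_variant(VariantCall("chr1", pos, base, alt, "a"),
                                       micro_genome))
        for pos in range(1890, 1896):  # 6 intergenic
            base = micro_genome.chromosomes["chr1"][pos]
            alt = "A" if base != "A" else "C"
            vs.append(annotate_variant(VariantCall("chr1", pos, base, alt, "a"),
                                       micro_genome))
        df = summarize_regions({"a": vs})
        assert df.loc["a", "cds_pct"] == 40.0

    def test_forced_cds_labels_recovered_exactly(self, study):
        """Annotation recovers every implanted CDS consequence label."""
        truth = [t for t in study.truth.implanted_snps if t.effect is not None]
        assert truth
        for t in truth:
            v = annotate_variant(
                VariantCall(t.chrom, t.pos, t.ref, t.alt, t.accession),
                study.genome,
            )
            assert v.region == "CDS"
            assert v.effect.effect == t.effect, (t.pos, t.accession)
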