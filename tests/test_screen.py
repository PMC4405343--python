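"""Disruption status, clustering, Fisher enrichment, and candidate integration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, fcluster
from scipy.spatial.distance import squareform

from leafscreen.genome import Transcript
from leafscreen.screen import (
    DisruptionMatrix,
    ScreenError,
    build_disruption_matrix,
    cluster_disruptions,
    fisher_enrichment,
    integrate_candidates,
    screen_pathways,
    transcript_status,
)
from leafscreen.variants import VariantCall


def hypergeom_two_sided(a, b, c, d):
    """Exhaustive two-sided Fisher p: sum of table probabilities <= P(obs).

    Enumerates every table with the observed margins; probabilities from
    log-factorials, summed for all tables at most as probable as observed.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lf = [0.0] * (n + 1)
    for i in range(1, n + 1):
        lf[i] = lf[i - 1] + math.log(i)

    def logp(x):
        y, z, w = r1 - x, c1 - x, r2 - (c1 - x)
        if min(y, z, w) < 0:
            return None
        return (lf[r1] + lf[r2] + lf[c1] + lf[n - c1] - lf[n]
                - lf[x] - lf[y] - lf[z] - lf[w])

    p_obs = logp(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        lp = logp(x)
        if lp is not None and lp <= p_obs + 1e-9:
            total += math.exp(lp)
    return min(1.0, total)


def make_tx(tid="t1", cds=((100, 160), (300, 360))):
    return Transcript(transcript_id=tid, cds=[tuple(c) for c in cds])


def indel(pos, length):
    return VariantCall("chr1", pos, "NN", "N", "acc", is_indel=True,
                       indel_len=length)


class TestTranscriptStatus:
    def test_one_bp_cds_deletion_is_frameshift(self):
        assert transcript_status(make_tx(), [], [indel(120, -1)]) == (
            "broken", "frameshift")

    def test_in_frame_deletion_is_normal(self):
        assert transcript_status(make_tx(), [], [indel(120, -3)]) == (
            "normal", "none")

    def test_gap_over_exon_breaks(self):
        assert transcript_status(make_tx(), [(290, 400)], []) == ("broken", "gap")

    def test_gap_wins_over_frameshift(self):
        status = transcript_status(make_tx(), [(90, 200)], [indel(320, -2)])
        assert status == ("broken", "gap")

    def test_non_cds_indel_ignored(self):
        assert transcript_status(make_tx(), [], [indel(200, -1)]) == (
            "normal", "none")


class TestDisruptionMatrix:
    def test_13_by_10_family_has_130_all_normal_entries(self, study):
        # the magnesium-transporter analysis shape: 13 transcripts x 10 accessions
        all_tx = [t.transcript_id for g in study.genome.genes
                  for t in g.transcripts]
        tids = all_tx[:13]
        accs = list(study.accessions)
        m = build_disruption_matrix(tids, accs, study.genome, {}, {})
        assert m.status.shape == (13, 10) and m.status.size == 130
        assert m.status.to_numpy().sum() == 0
        assert (m.mechanism.to_numpy() == "none").all()

    def test_unknown_transcript_raises(self, study):
        with pytest.raises(ScreenError):
            build_disruption_matrix(["nope.t1"], list(study.accessions),
                                    study.genome, {}, {})

    def test_recovers_implanted_disruptions(self, study):
        """Every implanted gap/frameshift entry is broken; nothing else is."""
        from leafscreen.structural import detect_gaps

        gaps = {
            acc: {c: detect_gaps(p) for c, p in study.depths[acc].items()}
            for acc in study.accessions
        }
        indels = {
            acc: [v for v in vs if v.is_indel]
            for acc, vs in study.variants.items()
        }
        all_tx = [t.transcript_id for g in study.genome.genes
                  for t in g.transcripts]
        m = build_disruption_matrix(all_tx, list(study.accessions),
                                    study.genome, gaps, indels)
        called = {(t, a) for t in m.status.index for a in m.status.columns
                  if m.status.loc[t, a]}
        truth = {(d.transcript_id, d.accession)
                 for d in study.truth.disrupted_transcripts}
        assert called == truth


class TestClustering:
    @staticmethod
    def dm(status: np.ndarray, accs=None):
        accs = accs or [f"a{i}" for i in range(status.shape[1])]
        tids = [f"t{i}" for i in range(status.shape[0])]
        s = pd.DataFrame(status, index=tids, columns=accs)
        mech = s.replace({1: "frameshift", 0: "none"})
        return DisruptionMatrix(status=s, mechanism=mech)

    def test_identical_profiles_join_at_distance_zero(self):
        status = np.array([[1, 1, 0], [0, 0, 1]])
        cl = cluster_disruptions(self.dm(status))
        assert cl["accession_linkage"][0, 2] == 0.0  # a0 and a1 merge first

    def test_euclidean_distance_is_sqrt_k(self):
        status = np.zeros((5, 2), dtype=int)
        status[:3, 0] = 1  # differ in 3 entries
        cl = cluster_disruptions(self.dm(status))
        assert cl["accession_linkage"][0, 2] == pytest.approx(np.sqrt(3))

    def test_heavily_broken_pair_forms_a_cluster(self):
        """Two accessions with many broken transcripts group together,
        mirroring the magnesium-transporter pattern."""
        rng = np.random.default_rng(1)
        status = np.zeros((13, 10), dtype=int)
        status[:10, 3] = 1  # heavy damage in accessions 3 and 4
        status[:11, 4] = 1
        status[0, 7] = 1  # a stray single break elsewhere
        cl = cluster_disruptions(self.dm(status))
        z = cl["accession_linkage"]
        groups = fcluster(z, t=2, criterion="maxclust")
        accs = [f"a{i}" for i in range(10)]
        by_group = {}
        for acc, grp in zip(accs, groups):
            by_group.setdefault(grp, set()).add(acc)
        assert {"a3", "a4"} in by_group.values()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        status = rng.integers(0, 2, size=(8, 6))
        accs = [f"a{i}" for i in range(6)]
        m1 = self.dm(status, accs)
        perm = [3, 1, 5, 0, 2, 4]
        m2 = self.dm(status[:, perm], [accs[i] for i in perm])
        c1 = squareform(cophenet(cluster_disruptions(m1)["accession_linkage"]))
        c2 = squareform(cophenet(cluster_disruptions(m2)["accession_linkage"]))
        d1 = pd.DataFrame(c1, index=accs, columns=accs)
        d2_names = [accs[i] for i in perm]
        d2 = pd.DataFrame(c2, index=d2_names, columns=d2_names)
        d2 = d2.loc[accs, accs]
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-12)


class TestFisher:
    def test_named_table_matches_oracle(self):
        universe = {f"g{i}" for i in range(100)}
        genes = sorted(universe)
        de = set(genes[:10])
        pathway = set(genes[:8]) | set(genes[50:52])  # a=8, b=2, c=2, d=88
        _, p = fisher_enrichment(de, pathway, universe)
        assert p == pytest.approx(hypergeom_two_sided(8, 2, 2, 88), abs=1e-12)

    def test_exhaustive_small_tables_match_oracle(self):
        """All 2x2 tables with total <= 14 match the enumeration oracle."""
        for n in range(1, 15):
            for a, b, c in itertools.product(range(n + 1), repeat=3):
                d = n - a - b - c
                if d < 0:
                    continue
                from scipy.stats import fisher_exact

                _, p = fisher_exact([[a, b], [c, d]])
                assert p == pytest.approx(hypergeom_two_sided(a, b, c, d),
                                          abs=1e-12), (a, b, c, d)

    def test_degenerate_margins(self):
        universe = {f"g{i}" for i in range(20)}
        _, p = fisher_enrichment(set(list(universe)[:5]), universe, universe)
        assert p == 1.0
        _, p = fisher_enrichment(set(), set(list(universe)[:5]), universe)
        assert p == 1.0

    def test_empty_universe_raises(self):
        with pytest.raises(ScreenError):
            fisher_enrichment(set(), set(), set())

    def test_subset_validation(self):
        with pytest.raises(ScreenError):
            fisher_enrichment({"x"}, {"y"}, {"y"})


class TestCandidateIntegration:
    def make_layers(self):
        universe = {f"g{i}" for i in range(100)}
        transporter = {f"g{i}" for i in range(5)}  # 5 disrupted genes
        flavonoid = {f"g{i}" for i in range(10, 13)}  # 3 DE genes
        return universe, transporter, flavonoid

    def test_two_group_scenario_yields_eight_candidates(self):
        universe, transporter, flavonoid = self.make_layers()
        enriched = {"transporter": transporter, "flavonoid": flavonoid}
        cands = integrate_candidates(
            enriched,
            disrupted_genes=transporter,
            de=flavonoid,
            pathway_groups={"transporter": "macronutrient_transport",
                            "flavonoid": "flavonoid"},
        )
        assert len(cands) == 8
        by_id = {c.gene_id: c for c in cands}
        for g in transporter:
            assert by_id[g].disrupted and not by_id[g].de
            assert by_id[g].group == "macronutrient_transport"
        for g in flavonoid:
            assert by_id[g].de and not by_id[g].disrupted

    def test_disrupted_gene_outside_enriched_pathways_excluded(self):
        universe, transporter, flavonoid = self.make_layers()
        cands = integrate_candidates(
            {"flavonoid": flavonoid},
            disrupted_genes=transporter | {"g50"},
            de=flavonoid,
        )
        assert {c.gene_id for c in cands} == flavonoid

    def test_no_enrichment_gives_empty_list(self):
        assert integrate_candidates({}, {"g1"}, {"g2"}) == []

    def test_monotone_in_disruption_evidence(self):
        """Adding a disruption never removes a candidate."""
        universe, transporter, flavonoid = self.make_layers()
        enriched = {"transporter": transporter, "flavonoid": flavonoid}
        base = {c.gene_id for c in integrate_candidates(
            enriched, transporter, flavonoid)}
        more = {c.gene_id for c in integrate_candidates(
            enriched, transporter | {"g11"}, flavonoid)}
        assert base <= more

    def test_screen_pathways_filters_by_alpha(self):
        universe = {f"g{i}" for i in range(100)}
        genes = sorted(universe)
        de = set(genes[:10])
        enriched_pw = set(genes[:8])  # strongly enriched
        random_pw = set(genes[40:48])  # no overlap with DE
        hits = screen_pathways(de, {"hot": enriched_pw, "cold": random_pw},
                               universe)
        assert "hot" in hits and "cold" not in hits
        assert hits["hot"][1] <= 0.05
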