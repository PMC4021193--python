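"""Tandem detection, NG86 Ka/Ks, 4DTv, and segmental-event dating."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import famevol as fv
from famevol.duplication import jukes_cantor

from conftest import ORACLE_CODE, ORACLE_STOPS


def locus_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "rank"])


class TestTandemClusters:
    def test_consecutive_ranks_form_one_cluster(self):
        tbl = locus_table(
            [("g1", "c1", 1), ("g2", "c1", 2), ("g3", "c1", 3), ("x", "c1", 9)]
        )
        (c,) = fv.detect_tandem_clusters(tbl, ["g1", "g2", "g3"])
        assert c.members == ["g1", "g2", "g3"] and c.size == 3

    def test_single_intervening_gene_allowed(self):
        # the rank-1,2,3,5 layout: one non-family gene at rank 4 intervenes
        tbl = locus_table(
            [("g1", "c1", 1), ("g2", "c1", 2), ("g3", "c1", 3),
             ("bg", "c1", 4), ("g4", "c1", 5)]
        )
        (c,) = fv.detect_tandem_clusters(tbl, ["g1", "g2", "g3", "g4"])
        assert c.members == ["g1", "g2", "g3", "g4"]

    def test_two_intervening_genes_break_the_chain(self):
        tbl = locus_table(
            [("g1", "c1", 1), ("b1", "c1", 2), ("b2", "c1", 3), ("g2", "c1", 4)]
        )
        assert fv.detect_tandem_clusters(tbl, ["g1", "g2"]) == []

    def test_clusters_never_span_chromosomes(self):
        tbl = locus_table([("g1", "c1", 5), ("g2", "c2", 6)])
        assert fv.detect_tandem_clusters(tbl, ["g1", "g2"]) == []

    def test_unknown_family_id_raises(self):
        tbl = locus_table([("g1", "c1", 1)])
        with pytest.raises(KeyError, match="ghost"):
            fv.detect_tandem_clusters(tbl, ["g1", "ghost"])

    @pytest.mark.parametrize("seed", range(100))
    def test_recovers_planted_clusters_on_seeded_fixtures(self, seed):
        fx = fv.generate_genome_fixture(
            3, 120, tandem_spec=[2, 3, 4][: 1 + seed % 3], seed=seed
        )
        found = fv.detect_tandem_clusters(fx.locus_table, fx.family_ids)
        found_sets = sorted(tuple(c.members) for c in found)
        planted = sorted(tuple(c) for c in fx.planted_tandem_clusters)
        assert found_sets == planted


# ---------------------------------------------------------------------------
# an independent NG86 oracle: site counts from degeneracy, differences by
# exhaustive pathway enumeration, both on Biopython's code table
# ---------------------------------------------------------------------------

def oracle_sites(codon):
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for nt in "TCAG":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in ORACLE_STOPS:
                continue
            valid += 1
            syn += ORACLE_CODE[alt] == ORACLE_CODE[codon]
        s += syn / valid if valid else 0.0
    return s


def oracle_pair(c1, c2):
    diffs = [k for k in range(3) if c1[k] != c2[k]]
    paths = []
    for order in itertools.permutations(diffs):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in ORACLE_STOPS:
                ok = False
                break
            if ORACLE_CODE[cur] == ORACLE_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        return None
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def oracle_ng86(seq1, seq2):
    S = N = Sd = Nd = 0.0
    for j in range(0, len(seq1), 3):
        c1, c2 = seq1[j : j + 3], seq2[j : j + 3]
        d = oracle_pair(c1, c2)
        if d is None:
            continue
        S += (oracle_sites(c1) + oracle_sites(c2)) / 2
        N += 3 - (oracle_sites(c1) + oracle_sites(c2)) / 2
        Sd += d[0]
        Nd += d[1]
    ks = -0.75 * math.log(1 - 4 * (Sd / S) / 3)
    ka = -0.75 * math.log(1 - 4 * (Nd / N) / 3)
    return ka, ks, N, S, Nd, Sd


class TestNG86:
    def test_identical_sequences_zero(self):
        aln = fv.CodonAlignment(["a", "b"], ["ATGGGT", "ATGGGT"])
        r = fv.compute_ng86(aln)
        assert r.ka == 0.0 and r.ks == 0.0 and math.isnan(r.omega)

    def test_single_nonsynonymous_difference(self):
        # Phe -> Leu at one codon: Sd = 0, Nd = 1
        aln = fv.CodonAlignment(["a", "b"], ["TTT", "TTA"])
        r = fv.compute_ng86(aln)
        assert r.s_diffs == 0.0 and r.n_diffs == 1.0
        assert r.ks == 0.0 and r.ka > 0.0

    def test_sites_sum_to_three_per_codon(self):
        seq1, seq2 = self._diverged_pair(2, n_codons=30, t=0.6)
        r = fv.compute_ng86(fv.CodonAlignment(["a", "b"], [seq1, seq2]))
        assert r.n_sites + r.s_sites == pytest.approx(3 * r.n_codons, abs=1e-9)
        assert r.n_diffs <= r.n_sites and r.s_diffs <= r.s_sites

    def test_multi_hit_codon_matches_pathway_enumeration_oracle(self):
        """A pair with a double-hit codon averaged over minimal pathways."""
        seq1 = "ATGGGTACCCTTAAAGAAGGTTGTCCAATC"  # 10 codons
        seq2 = "ATGGGAAGTCTTAGAGACGGTTGGCCAATC"  # ACC->AGT double hit, etc.
        r = fv.compute_ng86(fv.CodonAlignment(["a", "b"], [seq1, seq2]))
        ka, ks, N, S, Nd, Sd = oracle_ng86(seq1, seq2)
        assert r.ka == pytest.approx(ka, abs=1e-12)
        assert r.ks == pytest.approx(ks, abs=1e-12)
        assert r.s_diffs == pytest.approx(Sd, abs=1e-12)
        assert r.n_diffs == pytest.approx(Nd, abs=1e-12)

    @staticmethod
    def _diverged_pair(seed, n_codons=40, t=0.4):
        tree = fv.Tree.from_newick(f"(a:{t / 2},b:{t / 2});")
        spec = fv.SimModelSpec(
            "M0", kappa=2.0, omega_classes=[(1.0, 0.5)], seed=seed
        )
        aln, _ = fv.simulate_codon_alignment(tree, spec, n_codons)
        return aln["a"], aln["b"]

    @pytest.mark.parametrize("seed", range(10))
    def test_diverged_pairs_match_oracle(self, seed):
        seq1, seq2 = self._diverged_pair(seed)
        r = fv.compute_ng86(fv.CodonAlignment(["a", "b"], [seq1, seq2]))
        ka, ks, *_ = oracle_ng86(seq1, seq2)
        assert r.ka == pytest.approx(ka, abs=1e-12)
        assert r.ks == pytest.approx(ks, abs=1e-12)

    def test_swap_invariance(self):
        s1, s2 = self._diverged_pair(10, t=0.8)
        r1 = fv.compute_ng86(fv.CodonAlignment(["a", "b"], [s1, s2]))
        r2 = fv.compute_ng86(fv.CodonAlignment(["a", "b"], [s2, s1]))
        assert r1.ka == pytest.approx(r2.ka, abs=1e-12)
        assert r1.ks == pytest.approx(r2.ks, abs=1e-12)

    def test_saturation_raises(self):
        with pytest.raises(ValueError, match="3/4"):
            jukes_cantor(0.8)

    def test_ks_tracks_simulated_synonymous_divergence(self):
        """On M0-simulated pairs with moderate divergence, the Monte-Carlo
        mean of NG86 Ks matches the model's expected synonymous divergence
        per synonymous site."""
        from famevol._codon import GENETIC_CODE, SENSE_CODONS
        from famevol.gy94 import rate_matrix, uniform_codon_freqs

        t = 0.3  # expected substitutions/codon along the whole path
        est = []
        s_per_codon = []
        for rep in range(20):
            tree = fv.Tree.from_newick(f"(A:{t / 2},B:{t / 2});")
            spec = fv.SimModelSpec(
                "M0", kappa=2.0, omega_classes=[(1.0, 0.3)], seed=300 + rep
            )
            aln, _ = fv.simulate_codon_alignment(tree, spec, 500)
            r = fv.compute_ng86(aln)
            est.append(r.ks)
            s_per_codon.append(r.s_sites / r.n_codons)
        # expected synonymous flux per codon per unit branch length
        pi = uniform_codon_freqs()
        Q = rate_matrix(2.0, 0.3, pi)
        syn_flux = sum(
            pi[i] * Q[i, j]
            for i, ci in enumerate(SENSE_CODONS)
            for j, cj in enumerate(SENSE_CODONS)
            if i != j and GENETIC_CODE[ci] == GENETIC_CODE[cj]
        )
        expected_ks = t * syn_flux / (np.mean(s_per_codon) / 3) / 3
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - expected_ks) < 3 * se + 0.02


class TestFourDTv:
    def test_identical_sequences_zero(self):
        aln = fv.CodonAlignment(["a", "b"], ["GGAGGA", "GGAGGA"])
        r = fv.compute_4dtv(aln)
        assert r.value == 0.0 and r.n_4d_sites == 2

    def test_transversion_counts_one(self):
        r = fv.compute_4dtv(fv.CodonAlignment(["a", "b"], ["GGA", "GGT"]))
        assert r.value == 1.0

    def test_transition_counts_zero(self):
        r = fv.compute_4dtv(fv.CodonAlignment(["a", "b"], ["GGA", "GGG"]))
        assert r.value == 0.0

    def test_non_fourfold_sites_ignored(self):
        # TTT (Phe) is twofold at position 3: not a 4D site
        with pytest.raises(ValueError, match="qualifying"):
            fv.compute_4dtv(fv.CodonAlignment(["a", "b"], ["TTT", "TTC"]))

    def test_value_never_exceeds_one(self):
        rng = np.random.default_rng(4)
        from famevol._codon import SENSE_CODONS

        for _ in range(20):
            s1 = "".join(rng.choice(SENSE_CODONS, size=50))
            s2 = "".join(rng.choice(SENSE_CODONS, size=50))
            try:
                r = fv.compute_4dtv(fv.CodonAlignment(["a", "b"], [s1, s2]))
            except ValueError:
                continue
            assert 0.0 <= r.value <= 1.0


class TestSegmentalDating:
    def test_six_anchors_mean_point_one_gives_eight_my(self):
        ev = fv.date_segmental_event(("GmEXPA22", "GmEXPA49"), [0.1] * 6)
        assert ev.accepted and ev.t_my == 8

    def test_three_anchors_mean_0817_gives_67_my(self):
        ev = fv.date_segmental_event(("GmEXPA43", "GmEXPA45"), [0.817] * 3)
        assert ev.t_my == 67

    def test_fewer_than_three_anchors_rejected(self):
        ev = fv.date_segmental_event(("a", "b"), [0.2, 0.3])
        assert not ev.accepted and "3" in ev.reject_reason

    def test_window_is_open(self):
        # exactly 0 and exactly 1 are excluded by "between 0 and 1"
        ev = fv.date_segmental_event(("a", "b"), [0.0, 1.0, 0.5, 0.4, 0.3])
        assert ev.filtered_ks == [0.5, 0.4, 0.3]

    def test_sample_standard_deviation(self):
        ev = fv.date_segmental_event(("a", "b"), [0.1, 0.2, 0.3])
        assert ev.sd_ks == pytest.approx(np.std([0.1, 0.2, 0.3], ddof=1))

    def test_dating_linear_in_mean_ks(self):
        ks = [0.11, 0.14, 0.17, 0.21]
        e1 = fv.date_segmental_event(("a", "b"), ks)
        e2 = fv.date_segmental_event(("a", "b"), [2 * k for k in ks])
        assert e2.t_years == pytest.approx(2 * e1.t_years)

    def test_empty_anchor_list_raises(self):
        with pytest.raises(ValueError, match="empty"):
            fv.date_segmental_event(("a", "b"), [])


class TestDuplicationReport:
    def test_printed_family_percentages(self):
        members = [f"g{i}" for i in range(75)]
        clusters = [
            fv.TandemCluster("c1", [f"g{i}" for i in range(11)], list(range(11)), 1)
        ]
        events = [
            fv.date_segmental_event((f"g{2 * i}", f"g{2 * i + 1}"), [0.2] * 3)
            for i in range(26)
        ]  # genes g0..g51 -> 51 within the family after intersection
        events[-1] = fv.date_segmental_event(("g50", "x_outside"), [0.2] * 3)
        rep = fv.duplication_report(members, clusters, events)
        assert rep.n_tandem == 11 and rep.tandem_pct == 14.7
        assert rep.n_segmental == 51 and rep.segmental_pct == 68.0

    def test_empty_family(self):
        rep = fv.duplication_report([], [], [])
        assert rep.tandem_pct == 0.0 and rep.segmental_pct == 0.0
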