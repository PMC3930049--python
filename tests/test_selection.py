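"""Codon-level diversity and selection statistics."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from mhcpop import selection, simulate
from mhcpop._codon import CODON_TABLE, SENSE_CODONS
from mhcpop.amplicon import CodonAlignment
from mhcpop.selection import (
    DEFAULT_MASKS,
    PbrMask,
    nei_gojobori_pair,
    percent_polymorphic,
    site_diversity,
    welch_t_test,
    z_test_selection,
)

from _oracles import oracle_ng_pair

AA_BY_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}


def test_codon_table_matches_biopython():
    for codon, aa in CODON_TABLE.items():
        assert str(Seq(codon).translate()) == aa


class TestSiteDiversity:
    def test_analytic_cases(self, toy_alignment):
        # conserved column, 50/50 two-residue column, uniform-20 column
        n = 20
        col_conserved = ["GCT"] * n
        col_half = ["GCT"] * 10 + ["TCT"] * 10
        col_uniform = [AA_BY_CODON[aa] for aa in AA_BY_CODON]
        rows = [
            col_conserved[i] + col_half[i] + col_uniform[i] for i in range(n)
        ]
        aln = toy_alignment(rows)
        div = site_diversity(aln, PbrMask("L", (1,), 3))
        assert div.loc[0, "D"] == pytest.approx(0.05)
        assert div.loc[0, "D_rescaled"] == pytest.approx(0.0)
        assert div.loc[1, "D"] == pytest.approx(0.1)
        assert div.loc[2, "D"] == pytest.approx(1.0)
        assert div.loc[2, "D_rescaled"] == pytest.approx(1.0)

    def test_bounds_and_monotonicity(self, toy_alignment):
        """D grows as the residue distribution approaches uniform."""
        last = 0.0
        for k in (1, 2, 4, 5, 10, 20):
            aas = list(AA_BY_CODON.values())[:k] * (20 // k)
            aln = toy_alignment(aas)
            d = site_diversity(aln, PbrMask("L", (1,), 1)).loc[0, "D"]
            assert 0.05 <= d <= 1.0
            assert d > last or k == 1
            last = d

    def test_gap_codons_excluded(self, toy_alignment):
        aln = toy_alignment(["GCT", "---", "TCT"])
        d = site_diversity(aln, PbrMask("L", (1,), 1)).loc[0, "D"]
        assert d == pytest.approx(0.1)  # two observed residues, 50/50


class TestPercentPolymorphic:
    def test_toy_alignment_by_hand(self, toy_alignment):
        """4 sequences x 12 codons with exactly 3 polymorphic columns: 25%
        overall, verified by exhaustive column scan."""
        base = [AA_BY_CODON[a] for a in "ARNDCQEGHILK"]
        rows = []
        for i in range(4):
            cods = list(base)
            if i == 0:
                cods[0] = AA_BY_CODON["V"]
                cods[5] = AA_BY_CODON["W"]
            if i == 2:
                cods[9] = AA_BY_CODON["Y"]
            rows.append("".join(cods))
        aln = toy_alignment(rows, 12)
        mask = PbrMask("L", (1, 2, 3, 4), 12)
        s = percent_polymorphic(aln, mask)
        assert s.pct_polymorphic_all == pytest.approx(25.0)
        assert s.pct_polymorphic_pbr == pytest.approx(25.0)  # codon 1 of 4
        assert s.pct_polymorphic_nonpbr == pytest.approx(25.0)  # codons 6,10 of 8

    def test_identical_sequences_zero_everywhere(self, toy_alignment):
        aln = toy_alignment(["GCTTCT"] * 5)
        s = percent_polymorphic(aln, PbrMask("L", (1,), 2))
        assert (s.pct_polymorphic_pbr, s.pct_polymorphic_all) == (0.0, 0.0)

    def test_single_sequence_subset_warns(self, toy_alignment):
        aln = toy_alignment(["GCTTCT", "GCTTCA"])
        with pytest.warns(UserWarning):
            s = percent_polymorphic(aln, PbrMask("L", (1,), 2), subset_ids=["V0"])
        assert s.pct_polymorphic_all == 0.0


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        """Textbook Welch statistic and Satterthwaite df computed by direct
        arithmetic."""
        x, y = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        mx, my = 2.0, 3.5
        vx = sum((v - mx) ** 2 for v in x) / 2  # 1.0
        vy = sum((v - my) ** 2 for v in y) / 5  # 3.5
        se2 = vx / 3 + vy / 6
        t_exp = (mx - my) / math.sqrt(se2)
        df_exp = se2**2 / ((vx / 3) ** 2 / 2 + (vy / 6) ** 2 / 5)
        t, df, _ = welch_t_test(x, y)
        assert t == pytest.approx(t_exp, abs=1e-12)
        assert df == pytest.approx(df_exp, abs=1e-12)

    def test_fractional_df_on_unequal_variances(self):
        _, df, _ = welch_t_test([1, 2, 3, 4], [10, 30, 50, 90, 120])
        assert df != int(df)


class TestNeiGojobori:
    def test_identical_sequences(self):
        r = nei_gojobori_pair("TTTACG", "TTTACG")
        assert r.Nd == r.Sd == 0.0
        assert r.dN == 0.0 and r.dS == 0.0

    def test_ttt_vs_tta_by_hand(self):
        """One nonsynonymous difference (F->L); synonymous site counts 1/3
        (TTT) and 2/3 (TTA, whose first position also reaches L codons),
        averaged to 1/2."""
        r = nei_gojobori_pair("TTT", "TTA")
        assert r.s_sites == pytest.approx(0.5)
        assert r.n_sites == pytest.approx(2.5)
        assert (r.Nd, r.Sd) == (1.0, 0.0)
        assert r.dS == 0.0
        assert r.dN == pytest.approx(-0.75 * math.log(1 - 4 * (1 / 2.5) / 3))

    def test_two_difference_pathway_conservation(self):
        r = nei_gojobori_pair("TTT", "GTA")
        assert r.Nd + r.Sd == pytest.approx(2.0)

    def test_difference_count_conserved_on_random_pairs(self, rng):
        codons = list(SENSE_CODONS)
        for _ in range(300):
            a = "".join(rng.choice(codons, size=5))
            b = "".join(rng.choice(codons, size=5))
            diffs = sum(x != y for x, y in zip(a, b))
            r = nei_gojobori_pair(a, b)
            assert r.Nd + r.Sd == pytest.approx(diffs, abs=1e-9)

    def test_matches_bruteforce_oracle(self, rng):
        codons = list(SENSE_CODONS)
        for _ in range(100):
            a = "".join(rng.choice(codons, size=4))
            b = "".join(rng.choice(codons, size=4))
            r = nei_gojobori_pair(a, b)
            nd, sd, n, s = oracle_ng_pair(a, b)
            assert r.Nd == pytest.approx(nd, abs=1e-12)
            assert r.Sd == pytest.approx(sd, abs=1e-12)
            assert r.n_sites == pytest.approx(n, abs=1e-12)
            assert r.s_sites == pytest.approx(s, abs=1e-12)

    def test_gap_codons_skipped_pairwise(self):
        full = nei_gojobori_pair("TTTACG", "TTAACG")
        gapped = nei_gojobori_pair("TTT---ACG", "TTA---ACG")
        assert gapped.Nd == full.Nd and gapped.s_sites == full.s_sites

    def test_stop_codons_rejected(self):
        with pytest.raises(ValueError):
            nei_gojobori_pair("TAA", "TTT")


class TestZTest:
    def test_identical_alignment_is_null(self, toy_alignment):
        aln = toy_alignment(["GCTTCTACTGGT"] * 4)
        r = z_test_selection(aln, PbrMask("L", (1, 2, 3), 4), "PBR", n_boot=50, seed=0)
        assert r.Z == 0.0 and r.P == 1.0

    def test_small_partition_refused(self, toy_alignment):
        aln = toy_alignment(["GCTTCT", "GCATCA"])
        with pytest.raises(ValueError):
            z_test_selection(aln, PbrMask("L", (1,), 2), "PBR")

    def test_recovers_diversifying_selection_at_pbr(self):
        """PBR-elevated nonsynonymous acceptance in the generator is detected
        at PBR codons and not at non-PBR codons."""
        cfg = simulate.SimConfig(seed=0)
        alleles = simulate.simulate_allele_pool(cfg)
        aln = CodonAlignment(list(alleles), list(alleles.values()), cfg.n_codons)
        mask = PbrMask("L", cfg.pbr_mask, cfg.n_codons)
        pbr = z_test_selection(aln, mask, "PBR", n_boot=500, seed=0)
        non = z_test_selection(aln, mask, "non-PBR", n_boot=500, seed=0)
        assert pbr.P < 0.05
        assert non.P > 0.05
        assert pbr.ratio > 1
        assert pbr.ratio > non.ratio

    def test_neutral_generator_is_calibrated(self):
        """Under the neutral regime the selection test stays non-significant
        in at least 90% of seeds."""
        ok = 0
        for seed in range(30):
            cfg = simulate.SimConfig(seed=seed, regime="neutral", n_alleles_global=12)
            alleles = simulate.simulate_allele_pool(cfg)
            aln = CodonAlignment(list(alleles), list(alleles.values()), cfg.n_codons)
            mask = PbrMask("L", cfg.pbr_mask, cfg.n_codons)
            ok += z_test_selection(aln, mask, "PBR", n_boot=200, seed=seed).P > 0.05
        assert ok >= 27


class TestMasks:
    @pytest.mark.parametrize(
        "locus,n_pbr,n_total", [("DAB1", 10, 55), ("DAB3", 11, 58)]
    )
    def test_partition_exhaustive(self, locus, n_pbr, n_total):
        mask = DEFAULT_MASKS[locus]
        assert len(mask.pbr_codons) == n_pbr
        assert len(mask.non_pbr_codons) == n_total - n_pbr
        assert set(mask.pbr_codons) | set(mask.non_pbr_codons) == set(
            range(1, n_total + 1)
        )

    def test_out_of_range_mask_rejected(self):
        with pytest.raises(ValueError):
            PbrMask("X", (0, 5), 10)
        with pytest.raises(ValueError):
            PbrMask("X", (5, 11), 10)
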