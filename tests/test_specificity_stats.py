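"""Residue/position matrices, probability-logo heights, charge statistics."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phosphoscreen as ps
from phosphoscreen.specificity_stats import log10_binom_cdf, log10_binom_sf


def exact_tail_log10(k: int, n: int, p: float, upper: bool) -> float:
    """Oracle: exact rational binomial tail, summed with Fractions."""
    pf = Fraction(p)
    rng = range(k, n + 1) if upper else range(0, k + 1)
    total = sum(
        Fraction(math.comb(n, i)) * pf**i * (1 - pf) ** (n - i) for i in rng
    )
    return math.log10(float(total))


def _ct(counts: dict) -> ps.CountTable:
    s = pd.Series(counts)
    return ps.CountTable("s", s, int(s.sum()))


class TestFrequencyMatrix:
    def test_single_peptide_is_one_hot(self, tiny_library):
        pid = tiny_library.entries[0].peptide_id
        counts = {p: (10 if p == pid else 0) for p in tiny_library.peptide_ids}
        mat = ps.residue_position_frequency(_ct(counts), tiny_library)
        seq = tiny_library[pid].aa_seq
        for pos in ps.POSITIONS:
            col = mat.df[pos]
            assert col[seq[pos + 7]] == 1.0 and col.sum() == 1.0

    def test_equal_counts_split_a_position(self):
        a = "A" * 7 + "Y" + "DAAAAAA"
        b = "A" * 7 + "Y" + "EAAAAAA"
        lib = ps.PeptideLibrary(
            [ps.PeptideEntry("a_8", a, "wildtype"), ps.PeptideEntry("b_8", b, "wildtype")]
        )
        mat = ps.residue_position_frequency(_ct({"a_8": 50, "b_8": 50}), lib)
        assert mat.df.at["D", 1] == 0.5 and mat.df.at["E", 1] == 0.5

    def test_columns_sum_to_one_and_center_is_tyrosine(self, sim_library):
        rng = np.random.default_rng(3)
        counts = dict(zip(sim_library.peptide_ids, rng.integers(1, 100, len(sim_library))))
        mat = ps.residue_position_frequency(_ct(counts), sim_library)
        assert np.allclose(mat.df.sum(axis=0), 1.0, atol=1e-9)
        assert mat.df.at["Y", 0] == 1.0


class TestResidueEnrichment:
    def test_identity_and_arithmetic(self):
        f1 = pd.DataFrame(0.1, index=list(ps.AA_ALPHABET), columns=list(ps.POSITIONS))
        f1.loc["D", -1] = 0.2
        m1 = ps.PositionMatrix(f1, "frequency")
        m2 = ps.PositionMatrix(f1 / 2, "frequency")
        identity = ps.residue_enrichment(m1, m1)
        assert np.allclose(identity.df, 1.0)
        assert ps.residue_enrichment(m1, m2).df.at["D", -1] == pytest.approx(2.0)

    def test_replicate_averaging_after_division(self):
        base = pd.DataFrame(1.0, index=list(ps.AA_ALPHABET), columns=list(ps.POSITIONS))
        e1 = ps.PositionMatrix(base * 1.0, "enrichment")
        e2 = ps.PositionMatrix(base * 3.0, "enrichment")
        assert ps.average_matrices([e1, e2]).df.at["A", 2] == 2.0

    def test_log_ratio_values_and_antisymmetry(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0.1, 5.0, (20, 15))
        e_a = ps.PositionMatrix(
            pd.DataFrame(vals, index=list(ps.AA_ALPHABET), columns=list(ps.POSITIONS)),
            "enrichment",
        )
        e_b = ps.PositionMatrix(
            pd.DataFrame(vals[::-1], index=list(ps.AA_ALPHABET), columns=list(ps.POSITIONS)),
            "enrichment",
        )
        ab = ps.enrichment_ratio(e_a, e_b).df
        ba = ps.enrichment_ratio(e_b, e_a).df
        assert np.allclose(ab + ba, 0.0, atol=1e-12)
        assert np.allclose(ps.enrichment_ratio(e_a, e_a).df, 0.0)
        two = ps.PositionMatrix(e_a.df * 2, "enrichment")
        assert ps.enrichment_ratio(two, e_a).df.at["C", 4] == pytest.approx(np.log10(2))


class TestPlogo:
    @pytest.mark.parametrize(
        "k, n, p",
        [(3, 10, 0.25), (60, 200, 0.05), (0, 50, 0.1), (199, 200, 0.9), (25, 100, 0.25)],
    )
    def test_tails_match_exact_fraction_oracle(self, k, n, p):
        assert log10_binom_sf(k, n, p) == pytest.approx(
            exact_tail_log10(k, n, p, upper=True), abs=1e-9
        )
        assert log10_binom_cdf(k, n, p) == pytest.approx(
            exact_tail_log10(k, n, p, upper=False), abs=1e-9
        )

    def test_heights_match_oracle_on_planted_foreground(self, sim_library):
        """Planted Ile at -1 in the foreground yields the exact oracle heights."""
        background = sim_library.sequences()
        foreground = [s[:6] + "I" + s[7:] for s in background[:100]]
        mat = ps.plogo_matrix(foreground, background)
        fg_counts = {}
        for aa in ps.AA_ALPHABET:
            for pos in ps.POSITIONS:
                fg_counts[(aa, pos)] = sum(s[pos + 7] == aa for s in foreground)
        n = len(foreground)
        for (aa, pos), k in fg_counts.items():
            p = sum(s[pos + 7] == aa for s in background) / len(background)
            h = mat.df.at[aa, pos]
            if p == 0:
                continue
            expected = (
                -exact_tail_log10(k, n, p, upper=True)
                if k / n >= p
                else exact_tail_log10(k, n, p, upper=False)
            )
            assert h == pytest.approx(expected, abs=1e-9), (aa, pos)
        assert mat.df.at["I", -1] > 30  # strong over-representation

    def test_foreground_equal_to_background_is_near_zero(self, sim_library):
        seqs = sim_library.sequences()
        mat = ps.plogo_matrix(seqs, seqs)
        finite = mat.df.to_numpy()[np.isfinite(mat.df.to_numpy())]
        assert np.all(np.abs(finite) <= np.log10(2) + 1e-12)

    def test_absent_residue_with_positive_background_is_negative(self, sim_library):
        background = sim_library.sequences()
        foreground = [s for s in background if s[6] != "E"][:50]
        mat = ps.plogo_matrix(foreground, background)
        assert mat.df.at["E", -1] < 0


class TestNormalizedAbundance:
    def test_worked_ratio(self):
        lib = ["A" * 7 + "Y" + "A" * 4 + "K" + "AA"] * 8 + ["A" * 7 + "Y" + "A" * 7] * 92
        sub = lib[:8] + lib[8:50]  # 8/50 = 16% vs 8% in the library
        assert ps.normalized_abundance(sub, lib, "K", 5) == pytest.approx(2.0)

    def test_subset_equal_to_library_is_one(self, sim_library):
        seqs = sim_library.sequences()
        for aa, pos in [("D", -3), ("K", 5), ("L", -1)]:
            assert ps.normalized_abundance(seqs, seqs, aa, pos) == pytest.approx(1.0)

    def test_devoid_subset_is_zero(self, sim_library):
        seqs = sim_library.sequences()
        sub = [s for s in seqs if s[12] != "K"][:30]
        assert ps.normalized_abundance(sub, seqs, "K", 5) == 0.0


class TestNetCharge:
    @pytest.mark.parametrize(
        "seq, charge",
        [
            ("GGGGGGGYGGGGGGG", 0),
            ("GPLDGSLYAKVKKKD", 2),
            ("ERFLFPEYILDPEPQ", -3),
            ("HHHHHHHYHHHHHHH", 0),  # histidine ignored
        ],
    )
    def test_examples(self, seq, charge):
        assert ps.net_charge(seq) == charge

    def test_distribution_sums_to_set_size(self, sim_library):
        dist = ps.net_charge_distribution(sim_library.sequences())
        assert dist.sum() == len(sim_library)


class TestSelectiveSubstrates:
    def test_identical_scores_have_no_selective_sets(self):
        s = pd.Series({"a": 2.0, "b": 1.0})
        sets, fractions = ps.selective_substrates(s, s)
        assert len(sets["a_only"]) == len(sets["b_only"]) == 0
        assert fractions["both_high"] + fractions["both_low"] == 1.0

    def test_four_way_toy_partition(self):
        a = pd.Series({"p1": 2.0, "p2": 2.0, "p3": 1.0, "p4": 1.0})
        b = pd.Series({"p1": 2.0, "p2": 1.0, "p3": 2.0, "p4": 1.0})
        sets, fractions = ps.selective_substrates(a, b, name_a="src", name_b="lck")
        assert sets["both_high"].peptide_ids == frozenset({"p1"})
        assert sets["src_only"].peptide_ids == frozenset({"p2"})
        assert sets["lck_only"].peptide_ids == frozenset({"p3"})
        assert sets["both_low"].peptide_ids == frozenset({"p4"})
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_undefined_scores_are_excluded(self):
        a = pd.Series({"p1": 2.0, "p2": np.nan})
        b = pd.Series({"p1": 2.0, "p2": 2.0})
        sets, _ = ps.selective_substrates(a, b)
        assert all("p2" not in s.peptide_ids for s in sets.values())


def test_charge_preferring_kinase_shifts_high_scorers_positive(planted_screen, sim_library):
    """A kinase rewarding positive net charge yields high-scoring substrates
    whose net-charge distribution is shifted positive relative to the library
    (one-sided rank test)."""
    _, _, table, _ = planted_screen
    high = table.high_efficiency_ids()
    high_charges = [ps.net_charge(sim_library[p].aa_seq) for p in high]
    all_charges = [ps.net_charge(s) for s in sim_library.sequences()]
    assert np.mean(high_charges) > np.mean(all_charges)
    p = stats.mannwhitneyu(high_charges, all_charges, alternative="greater").pvalue
    assert p < 0.01
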