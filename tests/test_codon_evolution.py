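"""NG86 estimator: exhaustive-enumeration oracles, filters, classification."""

import math
from itertools import permutations, product

import pytest
from Bio.Seq import Seq

from ploidtrace.codon_evolution import (
    SENSE_CODONS,
    STOP_CODONS,
    CodonAlignment,
    back_translate,
    classify_selection,
    codon_alignment_for_pair,
    fisher_gate,
    jukes_cantor,
    kaks_pair,
    ng86_differences,
    ng86_site_fraction,
)
from ploidtrace.synthetic_data import mutate_to_target

from conftest import random_cds

BASES = "ACGT"


def oracle_aa(codon):
    return str(Seq(codon).translate())


def oracle_site_fraction(codon):
    """Independent enumeration of the nine single-base mutants."""
    total = 0.0
    for pos in range(3):
        syn = nonstop = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if oracle_aa(mut) == "*":
                continue
            nonstop += 1
            if oracle_aa(mut) == oracle_aa(codon):
                syn += 1
        if nonstop:
            total += syn / nonstop
    return total


def oracle_differences(a, b):
    """Independent pathway enumeration using the translation table."""
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return (0.0, 0.0)
    paths = []
    blocked_free = []
    for order in permutations(diffs):
        cur, sd, nd, blocked = a, 0.0, 0.0, False
        for k, pos in enumerate(order):
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if oracle_aa(nxt) == "*" and k < len(order) - 1:
                blocked = True
            if oracle_aa(nxt) == oracle_aa(cur) and oracle_aa(nxt) != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd))
        if not blocked:
            blocked_free.append((sd, nd))
    use = blocked_free or paths
    return (sum(p[0] for p in use) / len(use), sum(p[1] for p in use) / len(use))


class TestSiteFractions:
    @pytest.mark.parametrize(
        "codon,expected",
        [("TTT", 1 / 3), ("GGG", 1.0), ("ATG", 0.0), ("TGG", 0.0)],
    )
    def test_known_codons(self, codon, expected):
        assert ng86_site_fraction(codon) == pytest.approx(expected, abs=1e-12)

    def test_all_sense_codons_match_enumeration(self):
        for codon in SENSE_CODONS:
            assert ng86_site_fraction(codon) == pytest.approx(
                oracle_site_fraction(codon), abs=1e-12
            ), codon

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_site_fraction("TAA")


class TestPathwayDifferences:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("TTT", "TTC", (1.0, 0.0)),
            ("TTT", "GTT", (0.0, 1.0)),
            ("TTT", "GTA", (0.5, 1.5)),
            ("AAA", "AAA", (0.0, 0.0)),
        ],
    )
    def test_known_pairs(self, a, b, expected):
        assert ng86_differences(a, b) == pytest.approx(expected, abs=1e-12)

    def test_step_count_conserved_on_sample(self):
        # Sd + Nd equals the number of differing positions, any pair
        for a, b in [("TTT", "GGA"), ("ATG", "TGA"[::-1]), ("CGT", "AGA")]:
            sd, nd = ng86_differences(a, b)
            assert sd + nd == sum(x != y for x, y in zip(a, b))


class TestJukesCantor:
    def test_closed_form(self):
        assert jukes_cantor(0) == 0
        assert jukes_cantor(0.1) == pytest.approx(0.10733, abs=1e-5)

    def test_saturation_flag_not_exception(self):
        assert math.isnan(jukes_cantor(0.75))
        assert math.isnan(jukes_cantor(0.8))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            jukes_cantor(-0.01)


class TestKaksPair:
    def test_identical_sequences(self):
        cds = random_cds(100, seed=1)
        codons = tuple(cds[i : i + 3] for i in range(0, len(cds), 3))
        st = kaks_pair(CodonAlignment(codons, codons))
        assert st.ka == 0 and st.ks == 0
        assert math.isnan(st.kaks)
        assert st.fisher_p == 1.0

    def test_site_conservation_and_symmetry(self):
        a = random_cds(300, seed=2)
        b = mutate_to_target(a, 0.05, 0.3, seed=3)
        ca = tuple(a[i : i + 3] for i in range(0, len(a), 3))
        cb = tuple(b[i : i + 3] for i in range(0, len(b), 3))
        st = kaks_pair(CodonAlignment(ca, cb))
        st_rev = kaks_pair(CodonAlignment(cb, ca))
        assert st.S + st.N == pytest.approx(3 * st.n_codons, abs=1e-9)
        for attr in ("S", "N", "Sd", "Nd", "ka", "ks"):
            assert getattr(st, attr) == pytest.approx(getattr(st_rev, attr), abs=1e-12)

    def test_round_trip_fixture_pair(self):
        root = random_cds(3000, seed=5)
        mut = mutate_to_target(root, 0.03, 0.30, seed=7)
        st = kaks_pair(codon_alignment_for_pair(root, mut))
        assert st.ka == pytest.approx(0.03, rel=0.15)
        assert st.ks == pytest.approx(0.30, rel=0.15)

    def test_saturated_ks_not_applicable(self):
        # every synonymous site differing -> ps at the JC boundary
        a = ("GGA",) * 200
        b = ("GGC",) * 200
        st = kaks_pair(CodonAlignment(a, b))
        assert math.isnan(st.ks)
        assert st.selection_class == "excluded"

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            kaks_pair(CodonAlignment(("---",), ("---",)))


class TestFisherGate:
    @staticmethod
    def oracle_fisher(sd, s_rest, nd, n_rest):
        """Brute-force two-sided Fisher from the hypergeometric law."""
        from fractions import Fraction
        from math import comb

        row1, row2 = sd + s_rest, nd + n_rest
        col1 = sd + nd
        total = row1 + row2
        denom = comb(total, col1)
        def prob(k):
            if k < 0 or k > row1 or col1 - k > row2:
                return Fraction(0)
            return Fraction(comb(row1, k) * comb(row2, col1 - k), denom)
        p_obs = prob(sd)
        return float(sum(p for k in range(col1 + 1) if (p := prob(k)) <= p_obs))

    def test_no_differences(self):
        assert fisher_gate(10, 30, 0, 0) == 1.0

    @pytest.mark.parametrize("table", [(10, 30, 5, 1), (20, 60, 1, 3), (15, 45, 7, 2)])
    def test_matches_enumeration(self, table):
        S, N, Sd, Nd = table
        expected = self.oracle_fisher(Sd, S - Sd, Nd, N - Nd)
        assert fisher_gate(S, N, Sd, Nd) == pytest.approx(expected, rel=1e-9)

    def test_proportional_table_p1(self):
        assert fisher_gate(20, 60, 1, 3) == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fisher_gate(10, 30, -1, 0)


class TestClassification:
    @staticmethod
    def make(ka, ks):
        from ploidtrace.codon_evolution import OrthologPairStats

        ratio = math.nan if (math.isnan(ka) or math.isnan(ks) or ks == 0) else ka / ks
        return OrthologPairStats(
            gene_a="a", gene_b="b", n_codons=100, S=75, N=225,
            Sd=0, Nd=0, ka=ka, ks=ks, kaks=ratio, fisher_p=1.0,
        )

    @pytest.mark.parametrize(
        "ka,ks,expected",
        [
            (0.6, 0.4, "strong_positive"),
            (0.4, 0.4, "weak_positive"),  # ratio 1.0 -> weak bin (closed)
            (0.28, 0.4, "weak_positive"),
            (0.2, 0.4, "neutral"),  # ratio 0.5 boundary -> neutral
            (0.08, 0.4, "neutral"),
            (0.05, 0.5, "neutral"),  # ratio 0.1 boundary -> neutral
            (0.02, 0.4, "purifying"),
            (0.0, 0.4, "purifying"),  # ka = 0 kept, ratio 0
            (0.07, 0.05, "excluded"),  # Ks <= 0.1 filter precedence
            (math.nan, 0.4, "excluded"),
        ],
    )
    def test_bins(self, ka, ks, expected):
        assert classify_selection(self.make(ka, ks)) == expected

    def test_partition_on_fixture_pairs(self):
        # every non-excluded pair receives exactly one class
        classes = set()
        for ks in (0.05, 0.2, 0.4):
            for ka in (0.01, 0.1, 0.3, 0.5):
                classes.add(classify_selection(self.make(ka, ks)))
        valid = {"strong_positive", "weak_positive", "neutral", "purifying", "excluded"}
        assert classes <= valid


class TestBackTranslate:
    def test_gapless_concatenation(self):
        cds = random_cds(50, seed=9) + "TAA"
        from ploidtrace.coding_regions import translate

        prot = translate(cds)
        out = back_translate({"g": prot}, {"g": cds})
        assert out["g"] == cds[: 3 * len(prot)]

    def test_gap_becomes_gap_codon(self):
        cds = "ATGTTTAAA"
        out = back_translate({"g": "M-FK"}, {"g": cds})
        assert out["g"] == "ATG---TTTAAA"

    def test_mismatch_reports_position(self):
        cds = "ATGTTTAAA"
        with pytest.raises(ValueError, match="residue 1"):
            back_translate({"g": "MYK"}, {"g": cds})
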