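"""CRE scanning and occurrence statistics: IUPAC matching on both strands,
binomial per-sequence significance, set-level Z scores, complexity
classification, Venn partition, ABA summary and the LTR chi-square test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from ferrex.cre import (
    AbaSummary,
    Motif,
    OccurrenceMatrix,
    aba_cre_summary,
    background_from,
    classify_complexity,
    effective_count,
    effective_trials,
    enrich_catalog,
    group_cre_sets,
    load_catalog,
    ltr_distribution_chi2,
    match_probability,
    per_sequence_significance,
    scan_catalog,
    scan_motif,
    set_enrichment_z,
    shuffle_null,
    venn_partition,
)
from ferrex.sequences import IUPAC, revcomp

UNIFORM = {b: 0.25 for b in "ACGT"}

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)
iupac_motif = st.text(alphabet=sorted(IUPAC), min_size=1, max_size=8)


def brute_count(consensus, seq):
    """Window-enumeration oracle: check every window on both strands."""
    def matches(window, pattern):
        return all(b in IUPAC[s] for b, s in zip(window, pattern))

    w = len(consensus)
    total = 0
    for pattern in (consensus, revcomp(consensus)):
        for i in range(len(seq) - w + 1):
            window = seq[i : i + w]
            if "N" in window:
                if all(s == "N" or (b != "N" and b in IUPAC[s])
                       for b, s in zip(window, pattern)):
                    total += 1
            elif matches(window, pattern):
                total += 1
    return total


class TestScanMotif:
    @pytest.mark.parametrize(
        "consensus,seq,count",
        [
            ("RY", "AC", 2),       # forward AC matches R,Y; reverse scan too
            ("TATA", "ATATAA", 2),  # one occurrence per strand
            ("ACGT", "", 0),
            ("ACGT", "ACG", 0),
            ("A", "AAAA", 4),
            ("N", "ANA", 6),       # motif N matches any base including N, on both strands
            ("A", "NNN", 0),       # sequence N never matches a concrete symbol
        ],
    )
    def test_hand_enumerated_counts(self, consensus, seq, count):
        assert scan_motif(consensus, seq)[0] == count

    def test_positions_are_one_based_forward(self):
        _, hits = scan_motif("TATA", "ATATAA")
        assert hits == [(2, "+"), (2, "-")]

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError):
            Motif("m", "ACGQ")
        with pytest.raises(ValueError):
            scan_motif("ACGT", "ACXT")

    @given(iupac_motif, dna)
    def test_two_strand_symmetry(self, consensus, seq):
        assert scan_motif(consensus, seq)[0] == scan_motif(consensus, revcomp(seq))[0]

    def test_equals_window_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        symbols = sorted(IUPAC)
        for _ in range(300):
            consensus = "".join(rng.choice(symbols, size=rng.integers(1, 9)))
            seq = "".join(rng.choice(list("ACGT"), size=rng.integers(0, 120)))
            assert scan_motif(consensus, seq)[0] == brute_count(consensus, seq)


class TestPerSequenceSignificance:
    def test_zero_count_gives_p_one(self):
        assert per_sequence_significance(0, 100, Motif("m", "A"), UNIFORM) == 1.0

    def test_trial_counting_rules(self):
        # self-reverse-complement patterns collapse to one physical scan
        assert Motif("m", "RY").is_self_revcomp()
        assert Motif("m", "TATA").is_self_revcomp()
        assert not Motif("m", "A").is_self_revcomp()
        assert effective_trials(Motif("m", "TATA"), 100) == 97
        assert effective_trials(Motif("m", "ACG"), 100) == 2 * 98
        assert effective_count(Motif("m", "TATA"), 10) == 5
        assert effective_count(Motif("m", "ACG"), 10) == 10

    def test_exact_binomial_against_hand_summation(self):
        """Upper-tail probability equals a direct sum of binomial terms."""
        motif = Motif("m", "TATA")  # self-RC: n = L - w + 1
        length, count = 20, 4  # raw both-strand count -> 2 physical hits
        n = length - 4 + 1
        q = match_probability(motif, UNIFORM)
        expected = sum(
            math.comb(n, k) * q**k * (1 - q) ** (n - k) for k in range(2, n + 1)
        )
        assert per_sequence_significance(count, length, motif, UNIFORM) == pytest.approx(
            expected, rel=1e-12
        )

    def test_non_palindromic_motif_uses_both_strand_trials(self):
        motif = Motif("m", "A")
        p = per_sequence_significance(34, 100, motif, UNIFORM)
        assert p == pytest.approx(float(sps.binom.sf(33, 200, 0.25)), rel=1e-12)

    def test_match_everything_motif_gives_p_one(self):
        # q = 1: any count up to n is certain
        assert per_sequence_significance(50, 100, Motif("m", "N"), UNIFORM) == 1.0
        assert per_sequence_significance(2 * 100, 100, Motif("m", "N"), UNIFORM) == 1.0

    def test_impossible_observation_rejected(self):
        bg = {"A": 0.0, "C": 0.5, "G": 0.25, "T": 0.25}
        with pytest.raises(ValueError):
            per_sequence_significance(3, 100, Motif("m", "A"), bg)


class TestSetEnrichment:
    def test_observed_equal_expected_gives_z_zero(self):
        motif = Motif("m", "A")
        seqs = {"s1": "C" * 100}  # trials 200, q 0.25, E 50
        rec = set_enrichment_z(motif, seqs, UNIFORM, counts={"s1": 50})
        assert rec.z == pytest.approx(0.0)
        assert rec.p == pytest.approx(0.5)

    def test_frozen_z_example(self):
        motif = Motif("m", "A")
        seqs = {"s1": "C" * 50}  # trials 100, E 25, sd 4.3301
        rec = set_enrichment_z(motif, seqs, UNIFORM, counts={"s1": 34})
        assert rec.expected == pytest.approx(25.0)
        assert rec.sd == pytest.approx(4.3301270189, rel=1e-9)
        assert rec.z == pytest.approx(2.0785, abs=1e-4)
        assert rec.p == pytest.approx(0.018833, abs=1e-5)

    def test_zero_variance_null_is_flagged(self):
        rec = set_enrichment_z(Motif("m", "N"), {"s": "ACGT"}, UNIFORM)
        assert rec.flagged and math.isnan(rec.z)

    def test_agrees_with_frequency_preserving_shuffle_null(self):
        """Analytic mean/sd of the pooled count match the empirical shuffle
        null (letters permuted within each sequence), and the normal-tail
        p-value agrees with the empirical tail probability."""
        rng = np.random.default_rng(9)
        motif = Motif("m", "ACGTGG")
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGT"), size=500, p=[0.3, 0.2, 0.2, 0.3]))
            for i in range(40)
        }
        bg = background_from(seqs.values())
        rec = set_enrichment_z(motif, seqs, bg)
        null = shuffle_null(motif, seqs, n_shuffles=300, rng=rng)
        se_mean = null.std(ddof=1) / np.sqrt(len(null))
        assert abs(null.mean() - rec.expected) < 4 * se_mean + 0.5
        assert rec.sd == pytest.approx(null.std(ddof=1), rel=0.35)
        empirical_p = (null >= rec.observed).mean()
        assert abs(rec.p - empirical_p) < 0.06

    def test_enrich_catalog_shapes(self):
        motifs = [Motif("a", "ACGTG"), Motif("b", "GATA")]
        seqs = {"s1": "ACGTGACGTG" * 10, "s2": "TTTT" * 25}
        occ = scan_catalog(motifs, seqs, background="uniform")
        table = enrich_catalog(motifs, occ, seqs)
        assert list(table["motif_id"]) == ["a", "b"]
        assert (table["observed"] >= 0).all()


class TestComplexity:
    def test_identical_counts_all_normal_with_warning(self):
        with pytest.warns(UserWarning):
            groups = classify_complexity({f"g{i}": 7 for i in range(5)})
        assert set(groups.labels) == {"normal"}
        assert groups.sigma == 0.0

    def test_hand_computed_thresholds(self):
        counts = {f"g{i}": c for i, c in enumerate([0, 10, 10, 10, 10, 10, 10, 10, 10, 40])}
        groups = classify_complexity(counts)
        assert groups.mu == pytest.approx(12.0)
        assert groups.sigma == pytest.approx(np.sqrt(96.0))
        assert groups.labels["g9"] == "complex"  # 40 >= 12 + 2*9.798
        assert groups.labels["g0"] == "normal"  # 0 > 12 - 2*9.798
        assert set(groups.labels[[f"g{i}" for i in range(1, 9)]]) == {"normal"}

    def test_constructed_simple_gene(self):
        counts = {f"g{i}": 10 for i in range(30)}
        counts["low"] = 0
        groups = classify_complexity(counts)
        assert groups.labels["low"] == "simple"

    def test_partition_and_order_invariance(self):
        rng = np.random.default_rng(4)
        counts = pd.Series(rng.poisson(8, size=60), index=[f"g{i}" for i in range(60)])
        a = classify_complexity(counts)
        b = classify_complexity(counts.sample(frac=1, random_state=1))
        assert a.labels.sort_index().equals(b.labels.sort_index())
        assert sum(a.sizes().values()) == 60

    def test_needs_two_genes(self):
        with pytest.raises(ValueError):
            classify_complexity({"g": 3})


class TestVenn:
    def test_disjoint_and_identical_sets(self):
        v = venn_partition({"a"}, {"b"}, {"c"})
        assert (v["simple_only"], v["normal_only"], v["complex_only"]) == (1, 1, 1)
        assert v["all_three"] == 0 and v["union"] == 3
        v2 = venn_partition({"a", "b"}, {"a", "b"}, {"a", "b"})
        assert v2["all_three"] == 2 and v2["union"] == 2

    def test_matches_membership_enumeration(self):
        rng = np.random.default_rng(6)
        universe = [f"m{i}" for i in range(40)]
        sets = [set(rng.choice(universe, size=rng.integers(0, 30), replace=False))
                for _ in range(3)]
        v = venn_partition(*sets)
        brute = {k: 0 for k in v}
        for m in universe:
            member = tuple(m in s for s in sets)
            key = {
                (True, False, False): "simple_only",
                (False, True, False): "normal_only",
                (False, False, True): "complex_only",
                (True, True, False): "simple_normal",
                (True, False, True): "simple_complex",
                (False, True, True): "normal_complex",
                (True, True, True): "all_three",
            }.get(member)
            if key:
                brute[key] += 1
                brute["union"] += 1
        assert v == brute


def _occurrence_from_pvalues(pvalues: pd.DataFrame) -> OccurrenceMatrix:
    return OccurrenceMatrix(
        counts=(pvalues <= 0.05).astype(int), pvalues=pvalues, background=UNIFORM
    )


class TestAbaSummary:
    def _catalog(self):
        return [Motif("ABRE1", "ACGTG", "ABA-responsive element"),
                Motif("ABRE2", "MACGYGB", "ABA-responsive element"),
                Motif("GATA", "GATA", "light response")]

    def test_half_planted_promoters_give_fifty_percent(self):
        motifs = self._catalog()
        pv = pd.DataFrame(
            {"ABRE1": [0.01] * 10 + [0.9] * 10, "ABRE2": [0.9] * 20, "GATA": [0.01] * 20},
            index=[f"g{i}" for i in range(20)],
        )
        summary = aba_cre_summary(_occurrence_from_pvalues(pv), motifs)
        assert isinstance(summary, AbaSummary)
        assert summary.n_aba_cres_present == 1
        assert summary.n_genes_with_any == 10
        assert summary.percent == 50

    def test_no_significant_aba_cre_gives_zeroes(self):
        motifs = self._catalog()
        pv = pd.DataFrame({"ABRE1": [1.0] * 4, "ABRE2": [0.5] * 4, "GATA": [0.01] * 4},
                          index=list("abcd"))
        summary = aba_cre_summary(_occurrence_from_pvalues(pv), motifs)
        assert (summary.n_aba_cres_present, summary.n_genes_with_any, summary.percent) == (0, 0, 0)

    def test_catalog_without_aba_flags_rejected(self):
        pv = pd.DataFrame({"GATA": [0.01]}, index=["g"])
        with pytest.raises(ValueError):
            aba_cre_summary(_occurrence_from_pvalues(pv), [Motif("GATA", "GATA", "light")])

    def test_reported_share_arithmetic(self):
        # the percentage rule applied to the modeled study's printed counts
        assert int(round(100.0 * 665 / 2457)) == 27


class TestLtrChi2:
    def test_balanced_table_gives_zero(self):
        up = [f"u{i}" for i in range(20)]
        rest = [f"r{i}" for i in range(20)]
        sig = up[:10] + rest[:10]
        chi2, p, table, method = ltr_distribution_chi2(sig, up, up + rest)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert method == "chi2"
        assert table.tolist() == [[10, 10], [10, 10]]

    def test_hand_computed_chi2(self):
        up = [f"u{i}" for i in range(40)]
        rest = [f"r{i}" for i in range(40)]
        sig = up[:30] + rest[:10]
        chi2, p, _, _ = ltr_distribution_chi2(sig, up, up + rest)
        # n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 80*800^2/40^4 = 20
        assert chi2 == pytest.approx(20.0)
        assert p == pytest.approx(float(sps.chi2.sf(20.0, 1)))

    def test_sparse_table_falls_back_to_fisher(self):
        chi2, p, _, method = ltr_distribution_chi2(["u1"], ["u1", "u2"], ["u1", "u2", "r1"])
        assert method == "fisher"
        assert 0 < p <= 1 and math.isnan(chi2)

    def test_up_set_must_be_subset(self):
        with pytest.raises(ValueError):
            ltr_distribution_chi2([], ["x"], ["y"])


def test_bundled_catalog_loads_with_aba_flags():
    motifs = load_catalog()
    assert len(motifs) >= 40
    assert len({m.id for m in motifs}) == len(motifs)
    aba = [m for m in motifs if m.aba]
    assert len(aba) >= 8
    for m in motifs:
        assert set(m.consensus) <= set(IUPAC)


def test_group_cre_sets_uses_group_membership():
    pv = pd.DataFrame({"m1": [0.01, 0.9], "m2": [0.9, 0.01]}, index=["lo", "hi"])
    occ = _occurrence_from_pvalues(pv)
    groups = classify_complexity({"lo": 0, "hi": 10, "mid1": 5, "mid2": 5})
    sets = group_cre_sets(occ, groups)
    assert set(sets) == {"simple", "normal", "complex"}
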