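"""Multiplicity accounting, Fisher/BH enrichment and dN/dS normalization."""

import math

import numpy as np
import pandas as pd
import pytest

from evotraj import parallelism as par
from evotraj import refdata


def hypergeom_tail_oracle(k, G, M, L):
    """Brute-force upper-tail P(X >= k): direct summation of hypergeometric
    terms via log-gamma, independent of the implementation under test."""
    def log_comb(n, r):
        return math.lgamma(n + 1) - math.lgamma(r + 1) - math.lgamma(n - r + 1)

    total = 0.0
    for x in range(k, min(L, M) + 1):
        total += math.exp(
            log_comb(M, x) + log_comb(G - M, L - x) - log_comb(G, L)
        )
    return min(total, 1.0)


class TestMultiplicityTable:
    def annotations(self, loci):
        return pd.DataFrame(
            {"locus": loci, "length_bp": 1000, "functional_class": ""}
        )

    def test_no_repeated_locus_gives_empty_table(self):
        cases = pd.DataFrame(
            {"locus": ["a", "b", "c"], "effect": ["nonsynonymous"] * 3,
             "population": ["P1"] * 3, "max_frequency": [1.0] * 3}
        )
        out = par.multiplicity_table(cases, self.annotations(["a", "b", "c"]))
        assert out.empty

    def test_counts_by_effect_and_population(self):
        cases = pd.DataFrame(
            {
                "locus": ["geneA"] * 3 + ["geneB"],
                "effect": ["nonsynonymous", "nonsynonymous", "synonymous", "indel"],
                "population": ["P1", "P2", "P1", "P1"],
                "max_frequency": [10.0, 40.0, 5.0, 1.0],
            }
        )
        out = par.multiplicity_table(cases, self.annotations(["geneA", "geneB"]))
        assert len(out) == 1
        row = out.iloc[0]
        assert row["locus"] == "geneA"
        assert (row["total_cases"], row["ns_count"], row["s_count"]) == (3, 2, 1)
        assert (row["n_P1"], row["n_P2"]) == (2, 1)
        assert row["max_frequency"] == 40.0

    def test_missing_annotation_raises(self):
        cases = pd.DataFrame(
            {"locus": ["x", "x"], "effect": ["nonsynonymous"] * 2,
             "population": ["P1"] * 2, "max_frequency": [1.0, 2.0]}
        )
        with pytest.raises(KeyError):
            par.multiplicity_table(cases, self.annotations(["y"]))

    def test_reference_summary_reproduces_published_accounting(self):
        out = par.multiplicity_table(
            refdata.expand_cases(), refdata.reference_annotations()
        )
        ge3 = out[out["total_cases"] >= 3]
        assert len(ge3) == 40
        assert int(ge3["total_cases"].sum()) == 179


class TestFisherTest:
    def test_zero_cases_gives_p_one(self):
        assert par.fisher_locus_test(0, 1000, 624, 6_537_648) == pytest.approx(1.0)

    def test_saturated_locus_boundary(self):
        p = par.fisher_locus_test(100, 99_999, 100, 100_000)
        assert 0 < p <= 1

    def test_matches_bruteforce_tail_on_grid(self):
        G, M = 100_000, 100
        for L in (100, 1000, 10_000):
            for k in range(0, 21):
                p = par.fisher_locus_test(k, L, M, G)
                oracle = hypergeom_tail_oracle(k, G, M, L)
                assert p == pytest.approx(oracle, rel=1e-9)

    def test_realistic_locus_matches_oracle(self):
        # full genome scale: log-gamma summation and scipy agree closely,
        # though less tightly than on the reduced grid above
        p = par.fisher_locus_test(3, 1000, 624, 6_537_648)
        oracle = hypergeom_tail_oracle(3, 6_537_648, 624, 1000)
        assert p == pytest.approx(oracle, rel=1e-6)

    def test_equals_scipy_fisher_exact(self):
        # cross-check the 2x2 construction against the generic Fisher test
        from scipy.stats import fisher_exact

        k, L, M, G = 4, 2000, 500, 100_000
        table = [[k, L - k], [M - k, (G - L) - (M - k)]]
        _, p_ref = fisher_exact(table, alternative="greater")
        assert par.fisher_locus_test(k, L, M, G) == pytest.approx(p_ref, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            par.fisher_locus_test(5, 3, 100, 1000)  # more cases than bases
        with pytest.raises(ValueError):
            par.fisher_locus_test(-1, 10, 100, 1000)


class TestBenjaminiHochberg:
    def test_all_ones_none_significant(self):
        assert not par.bh_correct([1.0, 1.0, 1.0]).any()

    def test_stepup_flags_all_when_every_rank_passes(self):
        flags = par.bh_correct([0.001, 0.01, 0.02, 0.04], Q=0.05)
        assert flags.tolist() == [True, True, True, True]

    def test_stepup_rejects_when_first_rank_fails(self):
        flags = par.bh_correct([0.04, 0.9, 0.9, 0.9], Q=0.05)
        assert not flags.any()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(3, 40))
            ours = par.bh_correct(p, Q=0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert (ours == ref).all()

    def test_monotone_in_p_values(self, rng):
        p = rng.uniform(0, 1, size=25)
        base = par.bh_correct(p, Q=0.05)
        p2 = p.copy()
        p2[rng.integers(25)] *= 0.1
        lowered = par.bh_correct(p2, Q=0.05)
        assert (lowered | ~base)[np.isclose(p, p2)].all()

    def test_type_i_error_controlled_under_null(self):
        # mutations placed uniformly on a toy genome; flagged-locus fraction
        # across simulated datasets stays near/below the FDR
        rng = np.random.default_rng(99)
        G, M, L, n_loci = 100_000, 100, 100, 1000
        n_datasets = 200
        flagged = 0
        for _ in range(n_datasets):
            hits = np.bincount(rng.integers(n_loci, size=M), minlength=n_loci)
            screened = hits[hits >= 2]
            if screened.size == 0:
                continue
            p = np.array([par.fisher_locus_test(int(k), L, M, G) for k in screened])
            flagged += par.bh_correct(p, 0.05).sum()
        total = n_datasets * n_loci
        rate = flagged / total
        se = math.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 3 * se


class TestDnds:
    def test_neutral_identity(self):
        for x in (1, 5, 37):
            assert par.normalized_dnds(2.96 * x, x) == pytest.approx(1.0)

    def test_arithmetic_example(self):
        assert par.normalized_dnds(10, 2) == pytest.approx(5 / 2.96)

    def test_zero_synonymous_is_undefined(self):
        assert math.isnan(par.normalized_dnds(10, 0))

    def test_single_codon_lysine(self):
        # AAA (Lys): only AAA->AAG is synonymous among the 9 single-base changes
        freqs = {c: 0.0 for c in _all_codons()}
        freqs["AAA"] = 1.0
        assert par.neutral_dnds_from_codon_usage(freqs) == pytest.approx(8.0)

    def test_uniform_usage_matches_independent_enumeration(self):
        from Bio.Seq import Seq

        ns = s = 0
        for codon in _all_codons():
            aa = str(Seq(codon).translate())
            for i in range(3):
                for b in "ACGT":
                    if b == codon[i]:
                        continue
                    alt = codon[:i] + b + codon[i + 1 :]
                    aa2 = str(Seq(alt).translate())
                    if aa2 == aa and aa != "*":
                        s += 1
                    else:
                        ns += 1
        freqs = {c: 1 / 64 for c in _all_codons()}
        assert par.neutral_dnds_from_codon_usage(freqs) == pytest.approx(ns / s)

    def test_two_codon_mix_is_weighted_sum_not_mean_of_ratios(self):
        # TGG (Trp): all 9 changes NS -> ratio contribution 9 NS / 0 S
        freqs = {c: 0.0 for c in _all_codons()}
        freqs["AAA"] = freqs["TGG"] = 0.5
        # AAA: 8 NS + 1 S; TGG: 9 NS + 0 S, equally weighted
        assert par.neutral_dnds_from_codon_usage(freqs) == pytest.approx((8 + 9) / 1)

    def test_bad_table_rejected(self):
        with pytest.raises(ValueError):
            par.neutral_dnds_from_codon_usage({"AAA": 0.5})


class TestLifestyleSpecificity:
    def test_toy_labels(self):
        table = pd.DataFrame(
            {
                "locus": ["x", "y", "z"],
                "n_B1": [2, 0, 1],
                "n_P1": [0, 3, 1],
            }
        )
        labels = par.lifestyle_specificity(table, {"B1": "biofilm", "P1": "planktonic"})
        assert labels.tolist() == ["biofilm-only", "planktonic-only", "shared"]

    def test_reference_biofilm_only_loci(self):
        mt = par.multiplicity_table(refdata.expand_cases(), refdata.reference_annotations())
        labels = par.lifestyle_specificity(mt, refdata.TREATMENT_OF)
        biofilm_only = set(mt.loc[labels == "biofilm-only", "locus"])
        assert {"rpoB", "gacS", "PA14_71750", "PA14_13150"} <= biofilm_only
        planktonic_only = set(mt.loc[labels == "planktonic-only", "locus"])
        assert {"PA14_51840", "PA14_47900"} <= planktonic_only


def _all_codons():
    return ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"]
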