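"""Gene-level parallelism accounting and enrichment statistics.

Independent mutations repeatedly hitting the same locus across replicate
populations are the classic signature of selection in evolve-and-resequence
experiments.  Given the final filtered mutation set and a locus annotation
table, this module builds the multiplicity table (one row per locus mutated
at least twice, with counts by effect class and by population), tests each
locus for enrichment against a uniform-mutation null with a one-sided
Fisher exact test that conditions on locus length, applies the
Benjamini–Hochberg step-up at a chosen false-discovery rate, and computes
codon-usage-normalized dN/dS ratios.

The Fisher 2×2 table is (bases mutated / unmutated) × (inside / outside the
locus): ``[[k, L−k], [M−k, (G−L)−(M−k)]]`` for ``k`` hits in a locus of
``L`` bp given ``M`` total mutations on a ``G`` bp genome.  Its one-sided
"greater" p-value is exactly the hypergeometric upper tail
P(X ≥ k | G, M, L).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from evotraj.simdata import PA14_GENOME_LENGTH

__all__ = [
    "ParallelismConfig",
    "multiplicity_table",
    "fisher_locus_test",
    "bh_correct",
    "annotate_significance",
    "normalized_dnds",
    "neutral_dnds_from_codon_usage",
    "lifestyle_specificity",
]


@dataclass
class ParallelismConfig:
    """Null-model inputs for the locus enrichment test."""

    genome_length: int = PA14_GENOME_LENGTH
    total_mutations: int = 624
    fdr: float = 0.05
    min_cases_screen: int = 2  # loci entering the multiplicity table
    min_cases_report: int = 3  # loci counted as "parallel" in summaries

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if self.total_mutations > self.genome_length:
            raise ValueError("more mutations than genome positions")


def multiplicity_table(
    cases: pd.DataFrame,
    annotations: pd.DataFrame,
    min_cases: int = 2,
) -> pd.DataFrame:
    """Per-locus parallelism accounting from independent mutation cases.

    ``cases`` has one row per independent mutation with columns ``locus``,
    ``effect`` (nonsynonymous / synonymous / indel / intergenic / nonsense),
    ``population`` and ``max_frequency`` (the mutation's peak observed
    frequency, on whatever scale the caller used).  ``annotations`` maps
    each locus to its length in bp.  Returns one row per locus with at
    least ``min_cases`` mutations: total cases, counts by effect class,
    per-population counts, the highest member frequency and the locus
    length.  Raises if a locus lacks an annotation.
    """
    required = {"locus", "effect", "population"}
    if not required <= set(cases.columns):
        raise ValueError(f"cases must have columns {sorted(required)}")
    lengths = annotations.set_index("locus")["length_bp"]
    functions = (
        annotations.set_index("locus")["functional_class"]
        if "functional_class" in annotations.columns
        else pd.Series(dtype=object)
    )
    missing = set(cases["locus"]) - set(lengths.index)
    if missing:
        raise KeyError(f"loci missing from annotations: {sorted(missing)[:5]} ...")

    rows = []
    populations = sorted(cases["population"].unique())
    for locus, grp in cases.groupby("locus", sort=True):
        total = len(grp)
        if total < min_cases:
            continue
        eff = grp["effect"].astype(str)
        ns = int(eff.isin(["nonsynonymous", "nonsense"]).sum())
        s = int((eff == "synonymous").sum())
        indel = int((eff == "indel").sum())
        row = {
            "locus": locus,
            "total_cases": total,
            "ns_count": ns,
            "s_count": s,
            "indel_count": indel,
            "max_frequency": float(grp["max_frequency"].max())
            if "max_frequency" in grp.columns
            else float("nan"),
            "locus_length": int(lengths[locus]),
            "functional_class": functions.get(locus, ""),
        }
        for p in populations:
            row[f"n_{p}"] = int((grp["population"] == p).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def fisher_locus_test(k: int, L: int, M: int, G: int) -> float:
    """One-sided (greater) Fisher exact p for ``k`` mutations in an
    ``L``-bp locus given ``M`` mutations on a ``G``-bp genome.

    Identical to the hypergeometric upper tail P(X ≥ k) with population
    ``G``, ``M`` marked elements and ``L`` draws.
    """
    if not 0 <= k <= M:
        raise ValueError("need 0 <= k <= M")
    if not 1 <= L < G:
        raise ValueError("need 1 <= L < G")
    if k > L:
        raise ValueError("more cases than bases in the locus")
    return float(stats.hypergeom.sf(k - 1, G, M, L))


def bh_correct(p_values, Q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up significance flags at FDR ``Q``.

    Sort the m p-values ascending, find the largest rank i with
    p_(i) ≤ (i/m)·Q, and flag everything at or below that rank; tied
    p-values share the better outcome.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = (np.arange(1, m + 1) / m) * Q
    passed = p[order] <= thresholds
    flags = np.zeros(m, dtype=bool)
    if passed.any():
        cut = int(np.flatnonzero(passed).max())
        p_cut = p[order][cut]
        flags = p <= p_cut  # ties with the cut p-value share significance
    return flags


def annotate_significance(
    table: pd.DataFrame, config: ParallelismConfig | None = None
) -> pd.DataFrame:
    """Attach Fisher p-values, BH ranks/thresholds and significance flags
    to a multiplicity table.  ``m`` for the step-up is the number of loci
    actually tested (the rows of ``table``)."""
    cfg = config or ParallelismConfig()
    out = table.copy()
    out["p_value"] = [
        fisher_locus_test(int(k), int(L), cfg.total_mutations, cfg.genome_length)
        for k, L in zip(out["total_cases"], out["locus_length"])
    ]
    m = len(out)
    rank = out["p_value"].rank(method="first").astype(int)
    out["bh_rank"] = rank
    out["bh_threshold"] = rank / m * cfg.fdr
    out["significant"] = bh_correct(out["p_value"].to_numpy(), cfg.fdr)
    return out


def normalized_dnds(ns_count: int, s_count: int, neutral_ratio: float = 2.96) -> float:
    """Observed NS/S ratio standardized by its neutral expectation.

    Returns NaN (an explicit undefined marker) when no synonymous
    mutations were observed.
    """
    if ns_count < 0 or s_count < 0:
        raise ValueError("counts must be >= 0")
    if neutral_ratio <= 0:
        raise ValueError("neutral_ratio must be positive")
    if s_count == 0:
        return float("nan")
    return (ns_count / s_count) / neutral_ratio


def neutral_dnds_from_codon_usage(codon_frequencies: dict[str, float]) -> float:
    """Expected NS/S count ratio under uniform single-base substitution.

    ``codon_frequencies`` maps the 64 codons (DNA alphabet) to usage
    frequencies summing to 1 (stop codons may carry zero weight).  Every
    codon contributes its 9 single-base changes, classified against the
    standard genetic code (changes to or from stop count as
    nonsynonymous), weighted by the codon's frequency; the ratio is
    Σ NS weights / Σ S weights.
    """
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"

    freqs = {k.upper().replace("U", "T"): float(v) for k, v in codon_frequencies.items()}
    unknown = set(freqs) - set(table)
    if unknown:
        raise ValueError(f"invalid codons: {sorted(unknown)}")
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"codon frequencies sum to {total}, expected 1")

    ns_w = s_w = 0.0
    for codon, w in freqs.items():
        if w == 0:
            continue
        aa = table[codon]
        for i in range(3):
            for b in "ACGT":
                if b == codon[i]:
                    continue
                alt = codon[:i] + b + codon[i + 1:]
                if table[alt] == aa and aa != "*":
                    s_w += w
                else:
                    ns_w += w  # includes stop gains/losses
    if s_w == 0:
        return float("inf")
    return ns_w / s_w


def lifestyle_specificity(
    table: pd.DataFrame, treatment_of: dict[str, str]
) -> pd.Series:
    """Label each locus biofilm-only / planktonic-only / shared from its
    per-population case counts (``n_<population>`` columns)."""
    pop_cols = {c: c[2:] for c in table.columns if c.startswith("n_")}
    if not pop_cols:
        raise ValueError("table lacks per-population count columns (n_*)")
    labels = []
    for _, row in table.iterrows():
        seen = {
            treatment_of[pop]
            for col, pop in pop_cols.items()
            if row[col] > 0 and pop in treatment_of
        }
        if seen == {"biofilm"}:
            labels.append("biofilm-only")
        elif seen == {"planktonic"}:
            labels.append("planktonic-only")
        else:
            labels.append("shared")
    return pd.Series(labels, index=table.index, name="lifestyle")
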