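"""Bundled reference summaries from a published 90-day evolution experiment.

Two small tables from a 90-day *P. aeruginosa* PA14 biofilm/planktonic
serial-transfer experiment ship with the package as end-to-end anchors for
the accounting code:

* ``parallel_loci.tsv`` — the 40 loci that acquired three or more
  independent mutations across the six populations, with counts by effect
  class and by treatment arm, the highest observed member frequency (in
  percent) and a functional annotation;
* ``summary_counts.tsv`` — treatment-level totals of cumulative, day-90
  and fixed mutation counts.

The per-locus table is a locus-level summary; :func:`expand_cases` unrolls
it into one row per independent mutation case so the multiplicity
machinery can re-derive the summary.  The split of each treatment's cases
across its three replicate populations is not part of the summary, so the
expansion assigns populations round-robin within a treatment — faithful at
the treatment level, synthetic at the replicate level.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_parallel_loci",
    "load_summary_counts",
    "expand_cases",
    "reference_annotations",
    "mutation_accounting",
    "TREATMENT_OF",
]

#: replicate population -> treatment arm
TREATMENT_OF = {
    "B1": "biofilm",
    "B2": "biofilm",
    "B3": "biofilm",
    "P1": "planktonic",
    "P2": "planktonic",
    "P3": "planktonic",
}

_BIOFILM_POPS = ("B1", "B2", "B3")
_PLANKTONIC_POPS = ("P1", "P2", "P3")


def _data_path(name: str):
    return resources.files("evotraj.data").joinpath(name)


def load_parallel_loci() -> pd.DataFrame:
    """The 40-locus parallelism summary (one row per locus)."""
    with resources.as_file(_data_path("parallel_loci.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_summary_counts() -> pd.DataFrame:
    """Treatment-level mutation totals, indexed by metric."""
    with resources.as_file(_data_path("summary_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t").set_index("metric")


def expand_cases(loci: pd.DataFrame | None = None) -> pd.DataFrame:
    """Unroll the locus-level summary into one row per mutation case.

    Effect classes follow the per-locus NS/S/indel counts; populations are
    assigned round-robin within each treatment arm.  Where a row's
    treatment counts disagree with ``total_cases`` (one locus in the
    shipped table), the planktonic allocation is adjusted so the case
    total is authoritative.  The locus's highest frequency is carried on
    its first case row.
    """
    if loci is None:
        loci = load_parallel_loci()
    rows = []
    for _, r in loci.iterrows():
        total = int(r["total_cases"])
        effects = (
            ["nonsynonymous"] * int(r["ns"])
            + ["synonymous"] * int(r["s"])
            + ["indel"] * int(r["indel"])
        )
        if len(effects) != total:
            raise ValueError(f"effect counts disagree with total for {r['locus']}")
        n_b = int(r["biofilm_cases"])
        n_p = int(r["planktonic_cases"])
        if n_b + n_p != total:
            n_p = max(total - n_b, 1 if n_p > 0 else 0)
            n_b = total - n_p
        pops = [_BIOFILM_POPS[i % 3] for i in range(n_b)] + [
            _PLANKTONIC_POPS[i % 3] for i in range(n_p)
        ]
        for i in range(total):
            rows.append(
                {
                    "locus": r["locus"],
                    "effect": effects[i],
                    "population": pops[i],
                    "max_frequency": float(r["highest_frequency"]) if i == 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def reference_annotations(loci: pd.DataFrame | None = None) -> pd.DataFrame:
    """Annotation table for the bundled loci.

    Locus lengths are not part of the summary, so a 1000-bp placeholder is
    used; the accounting paths exercised on this table do not consume the
    lengths.
    """
    if loci is None:
        loci = load_parallel_loci()
    return pd.DataFrame(
        {
            "locus": loci["locus"],
            "length_bp": 1000,
            "functional_class": loci["functional_class"],
        }
    )


def mutation_accounting(
    summary: pd.DataFrame | None = None, n_populations: int = 6
) -> dict[str, float]:
    """Treatment sums and the per-population mean from the summary counts."""
    if summary is None:
        summary = load_summary_counts()
    total = summary["biofilm"] + summary["planktonic"]
    return {
        "cumulative_mutations": int(total["cumulative_mutations"]),
        "day90_mutations": int(total["day90_mutations"]),
        "fixed_mutations": int(total["fixed_mutations"]),
        "mean_mutations_per_population": float(total["cumulative_mutations"]) / n_populations,
    }
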