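"""Read, filter and consolidate mutation calls into frequency trajectories.

The input is the per-population, per-timepoint output of a polymorphism
caller run on pooled-population sequencing: one row per called mutation
with its frequency and strand-resolved read support.  This module applies
the standard post-calling filters for such data — removal of variants
already present in the ancestor, a minimum per-strand read support (default
three reads on each strand), exclusion of calls in locally polymorphic
windows (a proxy for misalignment artifacts), and a repeat-region mask —
then consolidates the surviving calls across timepoints into a
mutation × day frequency matrix (:class:`TrajectoryTable`).

Coordinates are 1-based inclusive throughout; mutation identity is the
``(position, ref, alt)`` triple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "MutationCall",
    "AncestorVariantSet",
    "RepeatMask",
    "TrajectoryTable",
    "read_calls",
    "read_locus_annotations",
    "subtract_ancestor",
    "filter_strand_support",
    "filter_dense_windows",
    "filter_repeat_mask",
    "strand_qualified_keys",
    "build_trajectories",
    "classify_substitution",
    "spectrum_summary",
]

_REQUIRED_COLUMNS = (
    "population",
    "day",
    "position",
    "ref",
    "alt",
    "kind",
    "effect",
    "locus",
    "frequency",
    "fwd_reads",
    "rev_reads",
    "depth",
)

_KINDS = {"SNP", "insertion", "deletion"}


@dataclass(frozen=True)
class MutationCall:
    """One polymorphism observation at one timepoint in one population."""

    population: str
    day: int
    position: int
    ref: str
    alt: str
    kind: str
    effect: str
    locus: str
    frequency: float
    fwd_reads: int
    rev_reads: int
    depth: int

    def __post_init__(self) -> None:
        if not 0 <= self.frequency <= 1:
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based coordinates)")
        if self.day < 0:
            raise ValueError("day must be >= 0")
        if self.fwd_reads < 0 or self.rev_reads < 0:
            raise ValueError("read counts must be >= 0")
        if self.fwd_reads + self.rev_reads > self.depth:
            raise ValueError("fwd_reads + rev_reads exceeds depth")

    @property
    def key(self) -> tuple[int, str, str]:
        """Mutation identity: (position, ref, alt)."""
        return (self.position, self.ref, self.alt)


@dataclass(frozen=True)
class AncestorVariantSet:
    """Variants separating the ancestral clone from the reference genome;
    these pre-date the experiment and are removed from every sample."""

    entries: frozenset[tuple[int, str]] = frozenset()

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, str]]) -> "AncestorVariantSet":
        return cls(frozenset((int(p), str(a)) for p, a in pairs))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AncestorVariantSet":
        df = pd.read_csv(path, sep="\t")
        if not {"position", "alt"} <= set(df.columns):
            raise ValueError("ancestor TSV needs 'position' and 'alt' columns")
        return cls.from_pairs(zip(df["position"], df["alt"]))

    def __contains__(self, item: tuple[int, str]) -> bool:
        return item in self.entries


@dataclass
class RepeatMask:
    """Normalized set of 1-based inclusive genomic intervals to exclude."""

    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted((int(s), int(e)) for s, e in self.intervals)
        for s, e in ivs:
            if s > e:
                raise ValueError(f"interval start {s} > end {e}")
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        self.intervals = merged
        # +1: IntervalTree is half-open, ours are inclusive
        self._tree = IntervalTree.from_tuples((s, e + 1) for s, e in merged) if merged else IntervalTree()

    @classmethod
    def from_bed(cls, path: str | Path) -> "RepeatMask":
        """BED (0-based half-open) -> internal 1-based inclusive intervals."""
        ivs = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            ivs.append((int(fields[1]) + 1, int(fields[2])))
        return cls(ivs)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RepeatMask":
        df = pd.read_csv(path, sep="\t")
        if not {"start", "end"} <= set(df.columns):
            raise ValueError("mask TSV needs 'start' and 'end' columns")
        return cls(list(zip(df["start"], df["end"])))

    def __contains__(self, position: int) -> bool:
        return bool(self._tree[position])


def _calls_from_frame(df: pd.DataFrame, source: str) -> list[MutationCall]:
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            calls.append(
                MutationCall(
                    population=str(row.population),
                    day=int(row.day),
                    position=int(row.position),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    kind=str(row.kind),
                    effect=str(row.effect),
                    locus=str(row.locus),
                    frequency=float(row.frequency),
                    fwd_reads=int(row.fwd_reads),
                    rev_reads=int(row.rev_reads),
                    depth=int(row.depth),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{source}, row {i}: {exc}") from exc
    return calls


def read_calls(path: str | Path, dialect: str = "tsv") -> list[MutationCall]:
    """Read mutation calls from a TSV table or a single-sample VCF.

    The TSV dialect requires the columns
    ``population day position ref alt kind effect locus frequency
    fwd_reads rev_reads depth``.  The VCF dialect takes the frequency from
    INFO/AF and strand support from a DP4-style INFO tag (ref-fwd, ref-rev,
    alt-fwd, alt-rev) and needs ``population`` and ``day`` supplied via
    INFO tags POP and DAY.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        if df.empty and df.columns.size <= 1:
            return []
        missing = set(_REQUIRED_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        return _calls_from_frame(df, str(path))
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vcf(path: Path) -> list[MutationCall]:
    from cyvcf2 import VCF  # optional dependency

    calls = []
    for rec in VCF(str(path)):
        alt = rec.ALT[0] if rec.ALT else "."
        if len(rec.REF) == len(alt) == 1:
            kind = "SNP"
        elif len(alt) > len(rec.REF):
            kind = "insertion"
        else:
            kind = "deletion"
        dp4 = rec.INFO.get("DP4")
        fwd, rev = (int(dp4[2]), int(dp4[3])) if dp4 is not None else (0, 0)
        af = rec.INFO.get("AF")
        if isinstance(af, tuple):
            af = af[0]
        depth = int(rec.INFO.get("DP", fwd + rev))
        calls.append(
            MutationCall(
                population=str(rec.INFO.get("POP", "NA")),
                day=int(rec.INFO.get("DAY", 0)),
                position=int(rec.POS),
                ref=str(rec.REF),
                alt=str(alt),
                kind=kind,
                effect=str(rec.INFO.get("EFFECT", "unknown")),
                locus=str(rec.INFO.get("LOCUS", "unknown")),
                frequency=float(af) if af is not None else 0.0,
                fwd_reads=fwd,
                rev_reads=rev,
                depth=depth,
            )
        )
    return calls


def read_locus_annotations(path: str | Path) -> pd.DataFrame:
    """Locus annotation TSV: columns locus, length_bp, functional_class."""
    df = pd.read_csv(path, sep="\t")
    missing = {"locus", "length_bp"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["length_bp"] < 1).any():
        raise ValueError("locus lengths must be >= 1 bp")
    if "functional_class" not in df.columns:
        df["functional_class"] = ""
    return df


def subtract_ancestor(
    calls: Sequence[MutationCall], ancestor: AncestorVariantSet
) -> list[MutationCall]:
    """Drop calls whose (position, alt) is already present in the ancestor."""
    return [c for c in calls if (c.position, c.alt) not in ancestor]


def filter_strand_support(
    calls: Sequence[MutationCall], min_per_strand: int = 3
) -> list[MutationCall]:
    """Keep calls supported by at least ``min_per_strand`` reads on *each*
    strand (forward and reverse)."""
    return [
        c for c in calls if c.fwd_reads >= min_per_strand and c.rev_reads >= min_per_strand
    ]


def strand_qualified_keys(
    calls: Sequence[MutationCall], min_per_strand: int = 3
) -> set[tuple[int, str, str]]:
    """Mutation identities meeting the per-strand support rule at >= 1
    timepoint; used to admit whole trajectories rather than single calls."""
    return {c.key for c in filter_strand_support(calls, min_per_strand)}


def filter_dense_windows(
    calls: Sequence[MutationCall], window: int = 15, max_neighbors: int = 2
) -> list[MutationCall]:
    """Drop calls in locally polymorphic regions.

    A call is removed when more than ``max_neighbors`` *other* calls from
    the same population and day lie within ±``window`` bp of it — a
    deterministic surrogate for manual inspection of alignments around
    suspiciously variant-dense windows.  Symmetric and order-independent.
    """
    by_group: dict[tuple[str, int], list[int]] = {}
    for i, c in enumerate(calls):
        by_group.setdefault((c.population, c.day), []).append(i)
    keep = [True] * len(calls)
    for idx in by_group.values():
        pos = np.array(sorted(calls[i].position for i in idx))
        for i in idx:
            p = calls[i].position
            n_within = int(np.searchsorted(pos, p + window, "right") - np.searchsorted(pos, p - window, "left"))
            if n_within - 1 > max_neighbors:  # exclude the call itself
                keep[i] = False
    return [c for i, c in enumerate(calls) if keep[i]]


def filter_repeat_mask(calls: Sequence[MutationCall], mask: RepeatMask) -> list[MutationCall]:
    """Drop calls whose position falls in a masked interval (inclusive ends)."""
    return [c for c in calls if c.position not in mask]


@dataclass
class TrajectoryTable:
    """Mutation × timepoint frequency matrix for one population.

    ``freq`` rows are indexed by mutation key ``(position, ref, alt)``;
    undetected cells are 0, with ``detected`` carrying the boolean mask so
    "sampled but below detection" stays distinguishable from absent data.
    """

    population: str
    days: list[int]
    mutations: pd.DataFrame  # index: mutation key; columns: position/ref/alt/locus/effect/kind
    freq: pd.DataFrame  # index: mutation key; columns: days
    detected: pd.DataFrame  # same shape as freq, boolean

    def __post_init__(self) -> None:
        if list(self.freq.columns) != list(self.days):
            raise ValueError("freq columns must equal days")
        vals = self.freq.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_mutations(self) -> int:
        return len(self.freq)

    def max_frequency(self) -> pd.Series:
        """Highest frequency each mutation ever reaches."""
        return self.freq.max(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        out = self.mutations.join(self.freq.rename(columns=lambda d: f"day_{d}"))
        out.insert(0, "population", self.population)
        out.to_csv(path, sep="\t", index=False)


def build_trajectories(
    calls: Sequence[MutationCall],
    days: Sequence[int],
    restrict_to: set[tuple[int, str, str]] | None = None,
) -> TrajectoryTable:
    """Consolidate one population's calls across timepoints.

    Mutation identity is keyed on ``(position, ref, alt)``; the table rows
    are the union of mutations over all days (optionally restricted to
    ``restrict_to``, e.g. the strand-qualified set), with zeros where a
    mutation was not detected.  Raises on duplicate (mutation, day) pairs.
    """
    days = [int(d) for d in days]
    if sorted(set(days)) != days:
        raise ValueError("days must be strictly increasing and unique")
    pops = {c.population for c in calls}
    if len(pops) > 1:
        raise ValueError(f"calls span multiple populations: {sorted(pops)}")
    population = pops.pop() if pops else "NA"

    kept = [c for c in calls if restrict_to is None or c.key in restrict_to]
    for c in kept:
        if c.day not in days:
            raise ValueError(f"call at day {c.day} not among table days {days}")
    keys = sorted({c.key for c in kept})
    index = pd.Index(keys, tupleize_cols=False, name="mutation")
    freq = pd.DataFrame(0.0, index=index, columns=days)
    detected = pd.DataFrame(False, index=index, columns=days)
    meta: dict[tuple, MutationCall] = {}
    seen: set[tuple] = set()
    for c in kept:
        cell = (c.key, c.day)
        if cell in seen:
            raise ValueError(f"duplicate call for mutation {c.key} at day {c.day}")
        seen.add(cell)
        freq.loc[[c.key], c.day] = c.frequency
        detected.loc[[c.key], c.day] = True
        meta.setdefault(c.key, c)
    mutations = pd.DataFrame(
        [
            {
                "position": meta[k].position,
                "ref": meta[k].ref,
                "alt": meta[k].alt,
                "locus": meta[k].locus,
                "effect": meta[k].effect,
                "kind": meta[k].kind,
            }
            for k in keys
        ],
        index=index,
    )
    return TrajectoryTable(
        population=population, days=days, mutations=mutations, freq=freq, detected=detected
    )


_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a ref→alt change as transition, transversion or indel.

    A↔G and C↔T are transitions; any other single-base swap is a
    transversion; a length change (or ``.`` allele) is an indel.
    """
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty")
    if ref == "." or alt == "." or len(ref) != len(alt):
        return "indel"
    if len(ref) != 1:
        return "indel"  # multi-base substitution blocks are treated as indels
    for b in (ref, alt):
        if b not in "ACGT":
            raise ValueError(f"ambiguous or invalid base {b!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if {ref, alt} <= _PURINES or {ref, alt} <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def spectrum_summary(calls: Sequence[MutationCall]) -> pd.DataFrame:
    """Counts and fractions of transitions/transversions/indels.

    Fractions are over all classified calls and sum to 1 when any call is
    present.  Each *call* counts once; deduplicate to unique mutations
    first if a per-mutation spectrum is wanted.
    """
    counts = {"transition": 0, "transversion": 0, "indel": 0}
    for c in calls:
        if c.kind != "SNP":
            counts["indel"] += 1
        else:
            counts[classify_substitution(c.ref, c.alt)] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "count": pd.Series(counts),
            "fraction": pd.Series(
                {k: (v / total if total else 0.0) for k, v in counts.items()}
            ),
        }
    )
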