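"""Cluster mutation trajectories into genotypes and infer nested genealogies.

In an asexual population, mutations that reside on the same genetic
background rise and fall together, so their frequency trajectories are
(nearly) shared; and a genotype derived from another can never exceed its
parent background's frequency.  This module exploits both principles:

* :func:`cluster_genotypes` groups mutations whose trajectories differ by
  at most ``cutoff`` in mean absolute frequency (single-linkage), yielding
  genotype cohorts;
* :func:`infer_genealogy` attaches each cohort to the tightest earlier
  cohort under which its trajectory nests, producing a genealogy forest;
* :func:`detect_fixations` finds sweeps (a cohort reaching and holding
  ~100% frequency) and accounts for every mutation carried to fixation;
* :func:`muller_table` converts the forest into the exclusive per-day
  frequencies a Muller (stacked-area genealogy) plot needs.

Sampling noise at typical pooled-sequencing depth (~600×) gives binomial
standard errors up to ~0.02, which motivates the default nesting slack
``nest_tolerance = 0.05`` and a fixation threshold of 0.97 rather than a
literal 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from evotraj.variants import TrajectoryTable

__all__ = [
    "GenotypeCluster",
    "GenealogyForest",
    "FixationEvent",
    "GenealogyError",
    "cluster_genotypes",
    "infer_genealogy",
    "detect_fixations",
    "muller_table",
    "genotype_richness",
]

ROOT = "ROOT"


class GenealogyError(ValueError):
    """Raised when no genealogy consistent with the nesting constraints exists."""


@dataclass
class GenotypeCluster:
    """A cohort of mutations with a shared frequency trajectory."""

    id: str
    members: list[Hashable]
    trajectory: pd.Series  # index: days; unweighted mean over members
    first_detected_day: int | None

    @property
    def n_members(self) -> int:
        return len(self.members)

    def max_frequency(self) -> float:
        return float(self.trajectory.max())


@dataclass
class GenealogyForest:
    """Genotype clusters plus child → parent links (``ROOT`` for founders)."""

    nodes: dict[str, GenotypeCluster]
    parent: dict[str, str]
    nest_tolerance: float = 0.05

    def children(self, gid: str) -> list[str]:
        return [c for c, p in self.parent.items() if p == gid]

    def roots(self) -> list[str]:
        return [c for c, p in self.parent.items() if p == ROOT]

    def ancestors(self, gid: str) -> list[str]:
        out = []
        p = self.parent[gid]
        while p != ROOT:
            out.append(p)
            p = self.parent[p]
        return out

    def validate(self) -> None:
        """Check acyclicity, per-edge nesting and children-sum constraints."""
        tol = self.nest_tolerance
        for gid in self.nodes:
            seen = {gid}
            p = self.parent[gid]
            while p != ROOT:
                if p in seen:
                    raise GenealogyError(f"cycle through {gid}")
                seen.add(p)
                p = self.parent[p]
        for gid, cluster in self.nodes.items():
            p = self.parent[gid]
            if p != ROOT:
                gap = self.nodes[p].trajectory - cluster.trajectory
                if (gap < -tol).any():
                    raise GenealogyError(f"{gid} exceeds parent {p} beyond tolerance")
            kids = self.children(gid)
            if kids:
                ksum = sum(self.nodes[k].trajectory for k in kids)
                if ((ksum - cluster.trajectory) > tol).any():
                    raise GenealogyError(f"children of {gid} exceed it beyond tolerance")
        rsum = sum((self.nodes[r].trajectory for r in self.roots()), start=0)
        if np.any(np.asarray(rsum) > 1 + tol):
            raise GenealogyError("root genotypes exceed total frequency 1")


@dataclass
class FixationEvent:
    """A genotype sweep: the day a cohort reaches fixation and the number of
    mutations (its own plus uncounted ancestral ones) carried along."""

    genotype_id: str
    fixation_day: int
    n_mutations_swept: int


def _pairwise_distances(freq: np.ndarray, detection_floor: float) -> np.ndarray:
    """Mean |Δfrequency| per pair, over days where either member is detected."""
    above = freq > detection_floor
    either = above[:, None, :] | above[None, :, :]
    diff = np.abs(freq[:, None, :] - freq[None, :, :])
    with np.errstate(invalid="ignore"):
        d = np.where(either, diff, 0.0).sum(-1) / either.sum(-1)
    # pairs never co-detected on any day: maximally distant
    d[~np.isfinite(d)] = np.inf
    np.fill_diagonal(d, 0.0)
    return d


def cluster_genotypes(
    table: TrajectoryTable,
    cutoff: float = 0.1,
    detection_floor: float = 0.02,
) -> list[GenotypeCluster]:
    """Group mutations whose trajectories travel together.

    Distance between two mutations is the mean absolute frequency
    difference over days where at least one of the pair exceeds
    ``detection_floor``; single-linkage agglomeration joins everything at
    distance ≤ ``cutoff``.  Clusters are labelled ``G01, G02, …`` in order
    of first detection then descending peak frequency; ties break on the
    lowest member mutation key, so the result is deterministic and
    invariant to input row order.
    """
    if len(table.days) < 2:
        raise ValueError("need >= 2 timepoints to compare trajectories")
    if table.n_mutations == 0:
        return []
    # canonical row order for determinism under input permutation
    order = np.argsort(table.freq.index.to_numpy(), kind="stable")
    freq = table.freq.to_numpy()[order]
    keys = [table.freq.index[i] for i in order]

    n = len(keys)
    if n == 1:
        labels = np.array([1])
    else:
        d = _pairwise_distances(freq, detection_floor)
        finite_cap = np.nanmax(d[np.isfinite(d)]) if np.isfinite(d).any() else 1.0
        d = np.where(np.isfinite(d), d, finite_cap + 2 * cutoff + 1.0)
        condensed = d[np.triu_indices(n, k=1)]
        labels = fcluster(linkage(condensed, method="single"), t=cutoff, criterion="distance")

    days = np.asarray(table.days)
    clusters = []
    for lab in np.unique(labels):
        member_idx = np.flatnonzero(labels == lab)
        members = [keys[i] for i in member_idx]
        traj = pd.Series(freq[member_idx].mean(axis=0), index=table.days)
        detected_days = days[traj.to_numpy() > detection_floor]
        first = int(detected_days[0]) if detected_days.size else None
        clusters.append((first, -traj.max(), min(members), members, traj))
    clusters.sort(key=lambda t: (t[0] if t[0] is not None else np.inf, t[1], t[2]))
    return [
        GenotypeCluster(
            id=f"G{i:02d}",
            members=members,
            trajectory=traj,
            first_detected_day=first,
        )
        for i, (first, _negmax, _mk, members, traj) in enumerate(clusters, start=1)
    ]


def _nests_under(
    child: pd.Series, parent: pd.Series, sibling_sum: pd.Series | float, tol: float
) -> bool:
    if ((child - parent) > tol).any():
        return False
    return not ((sibling_sum + child - parent) > tol).any()


def infer_genealogy(
    clusters: Sequence[GenotypeCluster], nest_tolerance: float = 0.05
) -> GenealogyForest:
    """Attach each cluster to the tightest valid parent.

    Clusters are placed in order of first detection then descending peak
    frequency.  A parent is valid when the child's trajectory never exceeds
    the parent's by more than ``nest_tolerance`` on any day, and the
    parent's direct children (including the candidate) never sum above the
    parent likewise.  Among valid parents the one minimizing
    Σ_t (parent − child) is chosen (ties: lowest id); with no valid parent
    the cluster becomes a root, provided roots still sum to ≤ 1 within
    tolerance — otherwise the trajectories admit no consistent genealogy
    and :class:`GenealogyError` is raised.
    """
    tol = nest_tolerance
    ordered = sorted(
        clusters,
        key=lambda c: (
            c.first_detected_day if c.first_detected_day is not None else np.inf,
            -c.max_frequency(),
            c.id,
        ),
    )
    nodes: dict[str, GenotypeCluster] = {}
    parent: dict[str, str] = {}
    child_sum: dict[str, pd.Series] = {}
    root_sum: pd.Series | float = 0.0

    for c in ordered:
        best, best_area = None, np.inf
        for pid in sorted(nodes):
            p = nodes[pid]
            if _nests_under(c.trajectory, p.trajectory, child_sum[pid], tol):
                area = float((p.trajectory - c.trajectory).sum())
                if area < best_area - 1e-12 or (
                    abs(area - best_area) <= 1e-12 and (best is None or pid < best)
                ):
                    best, best_area = pid, area
        if best is None:
            new_root_sum = root_sum + c.trajectory
            if np.any(np.asarray(new_root_sum) > 1 + tol):
                raise GenealogyError(
                    f"no valid parent for {c.id} and root frequencies would exceed 1"
                )
            root_sum = new_root_sum
            parent[c.id] = ROOT
        else:
            parent[c.id] = best
            child_sum[best] = child_sum[best] + c.trajectory
        nodes[c.id] = c
        child_sum[c.id] = c.trajectory * 0.0

    forest = GenealogyForest(nodes=nodes, parent=parent, nest_tolerance=tol)
    forest.validate()
    return forest


def detect_fixations(
    forest: GenealogyForest, fixed_threshold: float = 0.97
) -> list[FixationEvent]:
    """Find genotype sweeps and count the mutations each carries to fixation.

    A genotype fixes at the first sampled day its trajectory reaches
    ``fixed_threshold`` and never falls below ``fixed_threshold −
    nest_tolerance`` afterwards.  The swept-mutation count covers the
    genotype's own members plus those of all its ancestors that were not
    already swept by an earlier event.
    """
    tol = forest.nest_tolerance
    candidates = []
    for gid, cluster in forest.nodes.items():
        traj = cluster.trajectory
        days = list(traj.index)
        # only the first crossing counts: a genotype that reaches the
        # threshold but later collapses never fixed, even if it recovers
        crossing = next(
            (i for i in range(len(days)) if traj.iloc[i] >= fixed_threshold), None
        )
        if crossing is not None and (traj.iloc[crossing:] >= fixed_threshold - tol).all():
            candidates.append((int(days[crossing]), gid))
    candidates.sort(key=lambda t: (t[0], t[1]))

    counted: set[str] = set()
    events = []
    for day, gid in candidates:
        sweep_set = [g for g in [gid, *forest.ancestors(gid)] if g not in counted]
        n_swept = sum(forest.nodes[g].n_members for g in sweep_set)
        counted.update(sweep_set)
        if n_swept >= 1:
            events.append(FixationEvent(genotype_id=gid, fixation_day=day, n_mutations_swept=n_swept))
    return events


BACKGROUND = "background"


def muller_table(forest: GenealogyForest) -> pd.DataFrame:
    """Exclusive per-day genotype frequencies for a Muller plot.

    Each genotype's exclusive frequency is its trajectory minus its direct
    children's (clamped at 0); an extra ``background`` row absorbs the
    frequency not explained by any root genotype.  Rows come out in
    genealogical preorder and the per-day total is 1 by construction; if
    clamping has to remove more than ``nest_tolerance`` of mass on some
    day, the forest is reported as inconsistent instead.
    """
    tol = forest.nest_tolerance
    if forest.nodes:
        days = list(next(iter(forest.nodes.values())).trajectory.index)
    else:
        days = []
    rows = []
    clamp_loss = pd.Series(0.0, index=days)

    root_sum = sum(
        (forest.nodes[r].trajectory for r in forest.roots()),
        start=pd.Series(0.0, index=days),
    )
    background = (1.0 - root_sum).clip(lower=0.0)
    clamp_loss += (root_sum - 1.0).clip(lower=0.0)
    rows.append((BACKGROUND, ROOT, background))

    def visit(gid: str) -> None:
        kids = sorted(forest.children(gid))
        ksum = sum(
            (forest.nodes[k].trajectory for k in kids),
            start=pd.Series(0.0, index=days),
        )
        own = forest.nodes[gid].trajectory
        exclusive = (own - ksum).clip(lower=0.0)
        clamp_loss.update(clamp_loss + (ksum - own).clip(lower=0.0))
        rows.append((gid, forest.parent[gid], exclusive))
        for k in kids:
            visit(k)

    for r in sorted(forest.roots()):
        visit(r)

    if (clamp_loss > tol).any():
        worst = float(clamp_loss.max())
        raise GenealogyError(
            f"clamping removed {worst:.3f} total frequency on some day (> {tol})"
        )

    records = [
        {"genotype": gid, "day": int(day), "frequency": float(traj.loc[day]), "parent": pid}
        for gid, pid, traj in rows
        for day in days
    ]
    out = pd.DataFrame(records, columns=["genotype", "day", "frequency", "parent"])
    # renormalize the residual clamping slack into the background row so the
    # per-day stack sums to exactly 1
    for day in days:
        total = out.loc[out["day"] == day, "frequency"].sum()
        bg = (out["genotype"] == BACKGROUND) & (out["day"] == day)
        out.loc[bg, "frequency"] += 1.0 - total
        out.loc[bg, "frequency"] = out.loc[bg, "frequency"].clip(lower=0.0)
        total = out.loc[out["day"] == day, "frequency"].sum()
        out.loc[out["day"] == day, "frequency"] /= total
    return out


def genotype_richness(
    clusters: Sequence[GenotypeCluster], day: int, detection_floor: float = 0.02
) -> int:
    """Number of genotypes present above ``detection_floor`` at ``day``."""
    return sum(1 for c in clusters if float(c.trajectory.get(day, 0.0)) > detection_floor)
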