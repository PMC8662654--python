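"""Forward-time serial-passage simulator with sequencing-noise emulation.

Models a daily batch-transfer evolution experiment: each day the population
grows ``dilution_factor``-fold (``log2(dilution_factor)`` ≈ 6.6 doublings at
the default 1:100 dilution), new mutations arrive as a Poisson process over
cell divisions, and a multinomial bottleneck resamples ``n_bottleneck``
founders for the next day.  Biofilm-style propagation adds a binomial
"bead" propagule bottleneck before the dilution, mimicking transfer of the
attached subpopulation only.  Selection acts deterministically within a day
(genotype *i* grows by ``(1+s_i)**g`` relative to the mean); all
stochasticity lives in the bottlenecks and in mutation arrivals.

Each mutation founds a new genotype (infinite sites), so the genotype
genealogy is a tree rooted at the ancestor and a mutation's population
frequency equals the inclusive (clade) frequency of the genotype it
founded.  Mutator lineages arise at a small per-division rate and multiply
the genome-wide mutation rate of their whole clade (e.g. 116-fold for a
mismatch-repair knockout), with a transition-biased spectrum typical of
MMR defects.

Sequencing is emulated per sampled day: depth from a truncated normal
(defaults ≈ 617 ± 142 reads), alt reads binomial in the true frequency and
split binomially between strands; calls below ``detection_floor`` are
dropped from the observed tables, as a polymorphism caller would drop them.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_population",
    "sequence_sample",
    "write_dataset",
    "planted_genotype_table",
    "locus_annotations",
    "generations_per_day",
    "PA14_GENOME_LENGTH",
]

#: reference genome length (P. aeruginosa PA14 chromosome, bp)
PA14_GENOME_LENGTH = 6_537_648

# synthetic locus grid: genes of _GENE_BP separated by _IGR_BP intergenic gaps
_GENE_BP = 950
_IGR_BP = 100
_BLOCK = _GENE_BP + _IGR_BP

CALL_COLUMNS = [
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
]


def generations_per_day(dilution_factor: float = 100.0) -> float:
    """Doublings per transfer implied by a 1:``dilution_factor`` daily dilution."""
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must exceed 1")
    return math.log2(dilution_factor)


@dataclass
class SimConfig:
    """Parameters of one simulated serial-transfer population.

    Bottleneck and mutation-supply defaults are desk-scale choices tuned to
    produce tens of contending genotypes over a 90-day run; they are not
    calibrated census estimates for any particular experiment.
    """

    n_bottleneck: int = 100_000
    dilution_factor: float = 100.0
    generations_per_day: float | None = None  # default: log2(dilution_factor)
    n_days: int = 90
    sample_days: tuple[int, ...] = (17, 25, 44, 66, 75, 90)
    genome_length: int = PA14_GENOME_LENGTH
    mu: float = 1e-3  # genome-wide mutations per cell division
    frac_beneficial: float = 0.05
    dfe_mean_s: float = 0.08  # mean of the exponential DFE of beneficial s
    mutator_target: float = 3e-7  # per-division mutator-allele probability
    mutator_multiplier: float = 116.0
    mode: str = "planktonic"  # "planktonic" | "biofilm"
    bead_fraction: float = 0.1
    depth_mean: float = 617.1
    depth_sd: float = 142.3
    detection_floor: float = 0.05
    seed: int = 42
    population: str = "P1"
    # spectrum of simulated mutations
    indel_frac: float = 0.08
    transition_frac: float = 1 / 3
    mutator_transition_frac: float = 0.85
    # optional neutral marked lineage present from day 0 (for drift checks)
    initial_marked_fraction: float = 0.0
    initial_marked_is_mutator: bool = False
    # clades enter the truth tables once they reach this frequency on a
    # sampled day; everything below is treated as never-observed background
    record_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.n_bottleneck < 1:
            raise ValueError("n_bottleneck must be >= 1")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0 <= self.frac_beneficial <= 1:
            raise ValueError("frac_beneficial must lie in [0, 1]")
        for name in ("mu", "mutator_target", "dfe_mean_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.mode not in ("planktonic", "biofilm"):
            raise ValueError("mode must be 'planktonic' or 'biofilm'")
        if not 0 < self.bead_fraction <= 1:
            raise ValueError("bead_fraction must lie in (0, 1]")
        if not 0 <= self.initial_marked_fraction < 1:
            raise ValueError("initial_marked_fraction must lie in [0, 1)")
        days = tuple(int(d) for d in self.sample_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sample_days must be strictly increasing")
        if days and (days[0] < 1 or days[-1] > self.n_days):
            raise ValueError("sample_days must lie within [1, n_days]")
        self.sample_days = days
        if self.generations_per_day is None:
            self.generations_per_day = math.log2(self.dilution_factor)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sample_days"] = list(self.sample_days)
        return d


@dataclass
class SimResult:
    """Ground truth plus noisy observations from one simulated population.

    ``true_trajectories`` holds the inclusive (clade) frequency of every
    recorded genotype at each sample day.  Every genotype is founded by
    exactly one mutation (sharing its id), so a mutation's true frequency
    trajectory is the row of its founding genotype.
    """

    config: SimConfig
    lineage_tree: dict[int, int]  # genotype id -> parent genotype id (root 0 -> -1)
    mutation_assignments: dict[int, int]  # mutation id -> founding genotype id
    mutation_info: pd.DataFrame  # indexed by mutation id
    true_trajectories: pd.DataFrame  # index genotype id, columns sample days
    observed_calls: pd.DataFrame  # detected calls, CALL_COLUMNS + mutation_id
    census: dict[int, int]  # sample day -> census size sequenced
    arrivals: dict[str, float]  # realized mutation counts / divisions by background

    def true_mutation_frequency(self, mutation_id: int, day: int) -> float:
        gid = self.mutation_assignments[mutation_id]
        return float(self.true_trajectories.loc[gid, day])


def _draw_depths(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    d = np.rint(rng.normal(mean, sd, size=n)).astype(np.int64)
    return np.maximum(d, 1)


def sequence_sample(
    true_freqs,
    depth_mean: float = 617.1,
    depth_sd: float = 142.3,
    seed: int | np.random.Generator = 42,
    detection_floor: float = 0.05,
) -> pd.DataFrame:
    """Emulate pooled-population sequencing of known allele frequencies.

    Per mutation: depth ``D`` ~ round(Normal(depth_mean, depth_sd))
    truncated at 1; alt reads ~ Binomial(D, f), split Binomial(alt, 1/2)
    into forward/reverse strands.  Returns columns ``frequency`` (alt/D),
    ``fwd_reads``, ``rev_reads``, ``depth`` and ``detected`` (reported
    frequency ≥ ``detection_floor``).
    """
    f = np.atleast_1d(np.asarray(true_freqs, dtype=float))
    if f.ndim != 1:
        raise ValueError("true_freqs must be one-dimensional")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    depth = _draw_depths(rng, f.size, depth_mean, depth_sd)
    alt = rng.binomial(depth, f)
    fwd = rng.binomial(alt, 0.5)
    rev = alt - fwd
    freq = alt / depth
    return pd.DataFrame(
        {
            "frequency": freq,
            "fwd_reads": fwd,
            "rev_reads": rev,
            "depth": depth,
            "detected": freq >= detection_floor,
        }
    )


def _locus_of(position: int) -> str:
    block, offset = divmod(position - 1, _BLOCK)
    return f"gene_{block:05d}" if offset < _GENE_BP else f"igr_{block:05d}"


def locus_annotations(genome_length: int = PA14_GENOME_LENGTH) -> pd.DataFrame:
    """Locus annotation table for the simulator's synthetic gene grid."""
    n_blocks = (genome_length + _BLOCK - 1) // _BLOCK
    rows = []
    for b in range(n_blocks):
        rows.append((f"gene_{b:05d}", _GENE_BP, "simulated gene"))
        rows.append((f"igr_{b:05d}", _IGR_BP, "simulated intergenic region"))
    return pd.DataFrame(rows, columns=["locus", "length_bp", "functional_class"])


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _mutation_identity(
    rng: np.random.Generator, cfg: SimConfig, on_mutator: bool, used: set[int]
):
    """Draw position/ref/alt/kind/effect for one mutation (unique position)."""
    position = int(rng.integers(1, cfg.genome_length + 1))
    while position in used:
        position = int(rng.integers(1, cfg.genome_length + 1))
    used.add(position)
    ref = "ACGT"[rng.integers(4)]
    locus = _locus_of(position)
    if rng.random() < cfg.indel_frac:
        return position, ref, ".", "deletion", "indel", locus
    p_ts = cfg.mutator_transition_frac if on_mutator else cfg.transition_frac
    if rng.random() < p_ts:
        alt = _TRANSITION[ref]
    else:
        alt = str(rng.choice([b for b in "ACGT" if b not in (ref, _TRANSITION[ref])]))
    if locus.startswith("igr_"):
        effect = "intergenic"
    else:
        effect = "nonsynonymous" if rng.random() < 0.75 else "synonymous"
    return position, ref, alt, "SNP", effect, locus


def simulate_population(config: SimConfig) -> SimResult:
    """Run the serial-transfer Wright–Fisher loop for one population.

    Daily cycle: deterministic-expectation growth to census
    ``n_bottleneck × dilution_factor`` with per-genotype weights
    ``(1+s)**generations_per_day``; Poisson mutation arrivals proportional
    to each genotype's share of cell divisions (rate ``mu`` per division,
    times ``mutator_multiplier`` on mutator clades), each founding a child
    genotype at one cell; optional binomial bead propagule (biofilm mode);
    multinomial bottleneck back to ``n_bottleneck`` founders.  With
    ``mu = 0`` the ancestral genotype persists alone at frequency 1.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    g = float(cfg.generations_per_day)
    census_size = int(round(cfg.n_bottleneck * cfg.dilution_factor))

    # genotype state; positions are compacted, ids are stable and parents
    # always precede children in array order
    ids = np.array([0], dtype=np.int64)
    par = np.array([-1], dtype=np.int64)  # position of parent in arrays
    fitness = np.array([1.0])
    s_of = np.array([0.0])
    mutator = np.array([False])
    mutator_allele = np.array([False])  # founding mutation is a mutator allele
    counts = np.array([cfg.n_bottleneck], dtype=np.int64)
    next_id = 1

    if cfg.initial_marked_fraction > 0:
        marked = int(round(cfg.n_bottleneck * cfg.initial_marked_fraction))
        counts = np.array([cfg.n_bottleneck - marked, marked], dtype=np.int64)
        ids = np.array([0, 1], dtype=np.int64)
        par = np.array([-1, 0], dtype=np.int64)
        fitness = np.array([1.0, 1.0])
        s_of = np.array([0.0, 0.0])
        mutator = np.array([False, cfg.initial_marked_is_mutator])
        mutator_allele = np.array([False, cfg.initial_marked_is_mutator])
        next_id = 2

    sample_days = set(cfg.sample_days)
    snapshots: dict[int, dict[int, float]] = {}
    census: dict[int, int] = {}
    ever_recorded: set[int] = set(ids[1:].tolist())
    arrivals = {
        "mutator_mutations": 0.0,
        "nonmutator_mutations": 0.0,
        "mutator_divisions": 0.0,
        "nonmutator_divisions": 0.0,
    }

    for day in range(1, cfg.n_days + 1):
        grown = counts * fitness**g
        total = grown.sum()
        if total <= 0:
            raise RuntimeError(f"population census underflow at day {day}")
        census_counts = grown / total * census_size

        # Poisson mutation supply over each genotype's cell divisions;
        # divisions per day ≈ cells at census (each end-of-day cell is the
        # product of one terminal division)
        mult = np.where(mutator, cfg.mutator_multiplier, 1.0)
        n_new = rng.poisson(cfg.mu * mult * census_counts)
        n_new_mut = rng.poisson(cfg.mutator_target * mult * census_counts)
        arrivals["mutator_mutations"] += float(n_new[mutator].sum())
        arrivals["nonmutator_mutations"] += float(n_new[~mutator].sum())
        arrivals["mutator_divisions"] += float(census_counts[mutator].sum())
        arrivals["nonmutator_divisions"] += float(census_counts[~mutator].sum())

        k_total = int(n_new.sum() + n_new_mut.sum())
        if k_total:
            hosts = np.concatenate(
                [np.repeat(np.arange(ids.size), n_new), np.repeat(np.arange(ids.size), n_new_mut)]
            )
            founds_mutator = np.zeros(k_total, dtype=bool)
            founds_mutator[int(n_new.sum()):] = True
            beneficial = (~founds_mutator) & (rng.random(k_total) < cfg.frac_beneficial)
            s_new = np.where(beneficial, rng.exponential(cfg.dfe_mean_s, size=k_total), 0.0)
            new_ids = np.arange(next_id, next_id + k_total, dtype=np.int64)
            next_id += k_total
            par = np.concatenate([par, hosts])
            ids = np.concatenate([ids, new_ids])
            fitness = np.concatenate([fitness, fitness[hosts] * (1.0 + s_new)])
            s_of = np.concatenate([s_of, s_new])
            mutator = np.concatenate([mutator, mutator[hosts] | founds_mutator])
            mutator_allele = np.concatenate([mutator_allele, founds_mutator])
            census_counts = np.concatenate([census_counts, np.ones(k_total)])

        if day in sample_days:
            clade = _clade_frequencies(census_counts, par)
            census[day] = census_size
            rec = clade >= cfg.record_floor
            rec[0] = False  # the root ancestor is background, not a mutation
            snapshots[day] = dict(zip(ids[rec].tolist(), clade[rec].tolist()))
            ever_recorded.update(ids[rec].tolist())

        pool = census_counts
        if cfg.mode == "biofilm":
            pool = rng.binomial(np.rint(pool).astype(np.int64), cfg.bead_fraction).astype(float)
            if pool.sum() <= 0:  # degenerate bead draw; resample from census
                pool = census_counts
        counts = rng.multinomial(cfg.n_bottleneck, pool / pool.sum())

        # prune dead clades that never entered a snapshot
        keep = counts > 0
        if ever_recorded:
            keep |= np.isin(ids, np.fromiter(ever_recorded, dtype=np.int64))
        # ancestors of kept nodes stay; walk each kept node's parent chain
        # upward, stopping at already-marked ancestors
        for i in np.flatnonzero(keep)[::-1]:
            j = par[i]
            while j >= 0 and not keep[j]:
                keep[j] = True
                j = par[j]
        if not keep.all():
            new_pos = np.cumsum(keep) - 1
            idx = np.flatnonzero(keep)
            par = np.where(par[idx] >= 0, new_pos[np.maximum(par[idx], 0)], -1)
            ids, fitness, s_of = ids[idx], fitness[idx], s_of[idx]
            mutator, mutator_allele, counts = mutator[idx], mutator_allele[idx], counts[idx]

    return _assemble_result(
        cfg, rng, ids, par, s_of, mutator, mutator_allele,
        snapshots, census, arrivals,
    )


def _clade_frequencies(census_counts: np.ndarray, par: np.ndarray) -> np.ndarray:
    """Inclusive clade frequency per genotype (parents precede children)."""
    clade = census_counts.astype(float).copy()
    for i in range(clade.size - 1, 0, -1):
        if par[i] >= 0:
            clade[par[i]] += clade[i]
    return np.clip(clade / census_counts.sum(), 0.0, 1.0)


def _assemble_result(
    cfg, rng, ids, par, s_of, mutator, mutator_allele,
    snapshots, census, arrivals,
) -> SimResult:
    days = list(cfg.sample_days)
    recorded = sorted(set().union(*snapshots.values())) if snapshots else []
    # parent ids from the live arrays: recorded clades and their ancestors
    # are never pruned, so every recorded id is still present
    parent_id = {
        int(gid): (int(ids[par[i]]) if par[i] >= 0 else -1)
        for i, gid in enumerate(ids)
    }
    # ancestors of recorded clades always satisfy freq >= child's, so the
    # recorded set is ancestor-closed (minus the root) by construction
    traj = pd.DataFrame(0.0, index=pd.Index(recorded, name="genotype_id"), columns=days)
    for day, snap in snapshots.items():
        for gid, f in snap.items():
            traj.loc[gid, day] = f

    pos_of = {int(gid): i for i, gid in enumerate(ids)}
    lineage_tree = {int(gid): int(parent_id[int(gid)]) for gid in recorded}
    mutation_assignments = {int(gid): int(gid) for gid in recorded}

    used_positions: set[int] = set()
    info_rows = []
    for gid in recorded:
        i = pos_of[int(gid)]
        host_mut = bool(mutator[i]) and not bool(mutator_allele[i])
        position, ref, alt, kind, effect, locus = _mutation_identity(
            rng, cfg, host_mut or bool(mutator_allele[i]), used_positions
        )
        info_rows.append(
            (int(gid), position, ref, alt, kind, effect, locus,
             float(s_of[i]), bool(mutator_allele[i]), bool(mutator[i]))
        )
    mutation_info = pd.DataFrame(
        info_rows,
        columns=["mutation_id", "position", "ref", "alt", "kind", "effect",
                 "locus", "s", "is_mutator_allele", "on_mutator_background"],
    ).set_index("mutation_id")

    call_frames = []
    for day in days:
        if not recorded:
            break
        f_true = traj[day].to_numpy()
        seq = sequence_sample(
            f_true, cfg.depth_mean, cfg.depth_sd, rng, cfg.detection_floor
        )
        det = seq["detected"].to_numpy()
        if det.any():
            sub = mutation_info.iloc[det].reset_index()
            call_frames.append(
                pd.DataFrame(
                    {
                        "population": cfg.population,
                        "day": day,
                        "position": sub["position"].to_numpy(),
                        "ref": sub["ref"].to_numpy(),
                        "alt": sub["alt"].to_numpy(),
                        "kind": sub["kind"].to_numpy(),
                        "effect": sub["effect"].to_numpy(),
                        "locus": sub["locus"].to_numpy(),
                        "frequency": seq.loc[det, "frequency"].to_numpy(),
                        "fwd_reads": seq.loc[det, "fwd_reads"].to_numpy(),
                        "rev_reads": seq.loc[det, "rev_reads"].to_numpy(),
                        "depth": seq.loc[det, "depth"].to_numpy(),
                        "mutation_id": sub["mutation_id"].to_numpy(),
                    }
                )
            )
    observed = (
        pd.concat(call_frames, ignore_index=True)
        if call_frames
        else pd.DataFrame(columns=CALL_COLUMNS + ["mutation_id"])
    )

    div_m, div_n = arrivals["mutator_divisions"], arrivals["nonmutator_divisions"]
    rates = {
        "mutator_rate": arrivals["mutator_mutations"] / div_m if div_m else float("nan"),
        "nonmutator_rate": arrivals["nonmutator_mutations"] / div_n if div_n else float("nan"),
    }
    return SimResult(
        config=cfg,
        lineage_tree=lineage_tree,
        mutation_assignments=mutation_assignments,
        mutation_info=mutation_info,
        true_trajectories=traj,
        observed_calls=observed,
        census=census,
        arrivals={**arrivals, **rates},
    )


#: planted five-genotype genealogy used by recovery tests and examples:
#: trajectory per sample day, truth parent, number of member mutations
PLANTED_GENOTYPES = {
    "A": ([0.10, 0.30, 0.55, 0.75, 0.85, 0.95], "ROOT", 4),
    "B": ([0.00, 0.10, 0.28, 0.50, 0.65, 0.75], "A", 3),
    "C": ([0.00, 0.00, 0.10, 0.30, 0.45, 0.55], "B", 3),
    "D": ([0.35, 0.12, 0.06, 0.03, 0.00, 0.00], "ROOT", 3),
    "E": ([0.00, 0.18, 0.25, 0.20, 0.15, 0.10], "A", 3),
}
PLANTED_DAYS = (17, 25, 44, 66, 75, 90)


def planted_genotype_table(
    noise_sd: float = 0.02,
    seed: int = 42,
    days: tuple[int, ...] = PLANTED_DAYS,
    population: str = "SIM",
):
    """Build a trajectory table around five known nested genotype cohorts.

    Each cohort's member mutations follow the cohort trajectory plus
    i.i.d. Gaussian noise of ``noise_sd`` (clipped to [0, 1]); pairwise
    cohort separation is ≥ 0.145 mean absolute frequency so the default
    clustering cutoff of 0.1 cleanly splits them.  Returns
    ``(TrajectoryTable, truth_labels, truth_parent)`` where
    ``truth_labels`` maps mutation key -> cohort name and ``truth_parent``
    maps cohort name -> parent cohort (or ``"ROOT"``).
    """
    from evotraj.variants import TrajectoryTable

    rng = np.random.default_rng(seed)
    days = list(days)
    keys, rows, labels = [], [], {}
    used: set[int] = set()
    for name, (traj, _parent, n_members) in PLANTED_GENOTYPES.items():
        base = np.asarray(traj)
        for _ in range(n_members):
            position = int(rng.integers(1, PA14_GENOME_LENGTH + 1))
            while position in used:
                position = int(rng.integers(1, PA14_GENOME_LENGTH + 1))
            used.add(position)
            ref = "ACGT"[rng.integers(4)]
            alt = _TRANSITION[ref]
            key = (position, ref, alt)
            noisy = np.clip(base + rng.normal(0.0, noise_sd, size=base.size), 0.0, 1.0)
            # keep the mutation formally detected where the cohort exists
            noisy[base == 0.0] = 0.0
            keys.append(key)
            rows.append(noisy)
            labels[key] = name
    index = pd.Index(keys, tupleize_cols=False, name="mutation")
    freq = pd.DataFrame(np.vstack(rows), index=index, columns=days)
    detected = freq > 0
    mutations = pd.DataFrame(
        [
            {"position": k[0], "ref": k[1], "alt": k[2],
             "locus": _locus_of(k[0]), "effect": "nonsynonymous", "kind": "SNP"}
            for k in keys
        ],
        index=index,
    )
    table = TrajectoryTable(
        population=population, days=days, mutations=mutations, freq=freq, detected=detected
    )
    truth_parent = {name: spec[1] for name, spec in PLANTED_GENOTYPES.items()}
    return table, labels, truth_parent


def write_dataset(result: SimResult, outdir: str | Path) -> list[Path]:
    """Write one mutation-call TSV per sample day, a truth TSV and a JSON
    manifest; returns the paths written.

    The call tables use the trajectory pipeline's TSV dialect and contain
    only detected calls, as a polymorphism caller's output would.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    written = []
    for day in cfg.sample_days:
        sub = result.observed_calls[result.observed_calls["day"] == day]
        path = outdir / f"{cfg.population}_day{day:03d}.calls.tsv"
        sub[CALL_COLUMNS].to_csv(path, sep="\t", index=False)
        written.append(path)

    truth = result.mutation_info.copy()
    truth.insert(0, "genotype_id", [result.mutation_assignments[m] for m in truth.index])
    truth.insert(1, "parent_genotype", [result.lineage_tree[g] for g in truth["genotype_id"]])
    for day in cfg.sample_days:
        truth[f"freq_day{day}"] = result.true_trajectories.loc[truth["genotype_id"], day].to_numpy()
    truth_path = outdir / f"{cfg.population}.truth.tsv"
    truth.to_csv(truth_path, sep="\t")
    written.append(truth_path)

    manifest = {
        "population": cfg.population,
        "config": cfg.to_dict(),
        "census": {str(k): v for k, v in result.census.items()},
        "n_mutations_recorded": int(len(result.mutation_info)),
        "n_calls_observed": int(len(result.observed_calls)),
    }
    manifest_path = outdir / f"{cfg.population}.manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written.append(manifest_path)
    return written
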