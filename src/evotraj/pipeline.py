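"""End-to-end orchestration: filters → trajectories → genotypes → statistics.

:func:`run_pipeline` wires the module stages together for a directory of
per-population, per-day mutation-call tables and writes every output table
plus a JSON manifest recording the configuration, package version and
input checksums, so a run is reproducible from its output directory alone.
:func:`make_fixtures` emits a small two-population simulated dataset (one
planktonic arm, one biofilm arm carrying a 116× mutator lineage) for
examples and tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from evotraj import genotypes as gt
from evotraj import parallelism as par
from evotraj import popstats
from evotraj import simdata
from evotraj import variants as var

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures", "muller_to_ggmuller"]


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, echoed verbatim into the run manifest."""

    input_dir: str = "."
    output_dir: str = "results"
    ancestor_tsv: str | None = None
    repeat_mask_bed: str | None = None
    annotations_tsv: str | None = None
    # variant filters
    min_per_strand: int = 3
    window: int = 15
    max_neighbors: int = 2
    # genotype inference
    cutoff: float = 0.1
    cutoff_per_population: dict = field(default_factory=dict)
    nest_tolerance: float = 0.05
    detection_floor: float = 0.02
    fixed_threshold: float = 0.97
    # parallelism
    genome_length: int = simdata.PA14_GENOME_LENGTH
    total_mutations: int | None = None  # default: count from the data
    fdr: float = 0.05
    min_cases_screen: int = 2
    # enrichment
    enrichment_factor: float = 4.0
    seed: int = 42

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def muller_to_ggmuller(muller: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a Muller table into the two frames ggmuller expects:
    (Generation, Identity, Frequency) populations and (Parent, Identity)
    edges."""
    pop = muller.rename(
        columns={"day": "Generation", "genotype": "Identity", "frequency": "Frequency"}
    )[["Generation", "Identity", "Frequency"]]
    edges = (
        muller[muller["parent"] != gt.ROOT][["parent", "genotype"]]
        .drop_duplicates()
        .rename(columns={"parent": "Parent", "genotype": "Identity"})
    )
    return pop, edges


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage on the call tables under ``config.input_dir``.

    Expects files matching ``*.calls.tsv`` (one population+day each, the
    simulator's layout) or any TSVs in the calls dialect.  Writes, per
    population: trajectory, genotype-membership, genotype-trajectory,
    Muller (ggmuller layout), fixation and diversity tables; across
    populations: the multiplicity/enrichment table.  Returns the output
    directory.
    """
    cfg = config
    indir = Path(cfg.input_dir)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    call_files = sorted(indir.glob("*.calls.tsv")) or sorted(indir.glob("*.tsv"))
    if not call_files:
        raise FileNotFoundError(f"no call tables found under {indir}")
    calls: list[var.MutationCall] = []
    for f in call_files:
        calls.extend(var.read_calls(f))

    if cfg.ancestor_tsv:
        calls = var.subtract_ancestor(calls, var.AncestorVariantSet.from_tsv(cfg.ancestor_tsv))
    if cfg.repeat_mask_bed:
        calls = var.filter_repeat_mask(calls, var.RepeatMask.from_bed(cfg.repeat_mask_bed))
    calls = var.filter_dense_windows(calls, cfg.window, cfg.max_neighbors)

    populations = sorted({c.population for c in calls})
    tables: dict[str, var.TrajectoryTable] = {}
    all_cases = []
    for pop in populations:
        pop_calls = [c for c in calls if c.population == pop]
        days = sorted({c.day for c in pop_calls})
        qualified = var.strand_qualified_keys(pop_calls, cfg.min_per_strand)
        table = var.build_trajectories(pop_calls, days, restrict_to=qualified)
        tables[pop] = table
        table.to_tsv(outdir / f"{pop}.trajectories.tsv")

        cutoff = cfg.cutoff_per_population.get(pop, cfg.cutoff)
        clusters = gt.cluster_genotypes(table, cutoff, cfg.detection_floor)
        forest = gt.infer_genealogy(clusters, cfg.nest_tolerance)
        membership = pd.DataFrame(
            [
                {"mutation": str(m), "genotype": c.id, "parent": forest.parent[c.id]}
                for c in clusters
                for m in c.members
            ]
        )
        membership.to_csv(outdir / f"{pop}.genotypes.tsv", sep="\t", index=False)
        gtraj = pd.DataFrame({c.id: c.trajectory for c in clusters}).T
        gtraj.index.name = "genotype"
        gtraj.to_csv(outdir / f"{pop}.genotype_trajectories.tsv", sep="\t")

        muller = gt.muller_table(forest)
        pop_frame, edges = muller_to_ggmuller(muller)
        pop_frame.to_csv(outdir / f"{pop}.muller_populations.csv", index=False)
        edges.to_csv(outdir / f"{pop}.muller_edges.csv", index=False)

        events = gt.detect_fixations(forest, cfg.fixed_threshold)
        pd.DataFrame(
            [dataclasses.asdict(e) for e in events],
            columns=["genotype_id", "fixation_day", "n_mutations_swept"],
        ).to_csv(outdir / f"{pop}.fixations.tsv", sep="\t", index=False)

        popstats.diversity_trajectory(table).to_csv(
            outdir / f"{pop}.diversity.tsv", sep="\t", index=False
        )

        maxf = table.max_frequency()
        for key in table.freq.index:
            all_cases.append(
                {
                    "locus": table.mutations.loc[[key], "locus"].iloc[0],
                    "effect": table.mutations.loc[[key], "effect"].iloc[0],
                    "population": pop,
                    "max_frequency": float(maxf.loc[[key]].iloc[0]) * 100,
                }
            )

    cases = pd.DataFrame(all_cases)
    if cfg.annotations_tsv:
        annotations = var.read_locus_annotations(cfg.annotations_tsv)
    else:
        annotations = simdata.locus_annotations(cfg.genome_length)
    mt = par.multiplicity_table(cases, annotations, cfg.min_cases_screen)
    if len(mt):
        pcfg = par.ParallelismConfig(
            genome_length=cfg.genome_length,
            total_mutations=cfg.total_mutations or len(cases),
            fdr=cfg.fdr,
            min_cases_screen=cfg.min_cases_screen,
        )
        mt = par.annotate_significance(mt, pcfg)
    mt.to_csv(outdir / "multiplicity.tsv", sep="\t", index=False)

    manifest = {
        "package": "evotraj",
        "version": _version(),
        "config": cfg.to_dict(),
        "inputs": {f.name: _sha256(f) for f in call_files},
        "populations": populations,
        "n_calls": len(calls),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def _version() -> str:
    from evotraj import __version__

    return __version__


def make_fixtures(seed: int = 42, outdir: str | Path = "fixtures") -> Path:
    """Emit a small two-population simulated dataset.

    One planktonic-like population and one biofilm-like population whose
    marked founder lineage carries a 116× mutator allele; both are scaled
    down (bottleneck 2×10⁴) so the pair simulates in seconds.  Also writes
    the matching locus-annotation table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    common = dict(
        n_bottleneck=20_000,
        n_days=90,
        mu=2e-4,
        frac_beneficial=0.02,
        dfe_mean_s=0.05,
    )
    plank = simdata.SimConfig(
        population="P1",
        mode="planktonic",
        sample_days=(17, 44, 66, 90),
        seed=seed,
        **common,
    )
    bio = simdata.SimConfig(
        population="B1",
        mode="biofilm",
        sample_days=(17, 25, 44, 66, 75, 90),
        seed=seed + 1,
        initial_marked_fraction=0.02,
        initial_marked_is_mutator=True,
        mutator_multiplier=116.0,
        **common,
    )
    for cfg in (plank, bio):
        simdata.write_dataset(simdata.simulate_population(cfg), outdir)
    ann = simdata.locus_annotations()
    ann.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    return outdir
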