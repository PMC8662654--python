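"""Call parsing, filtering rules and trajectory consolidation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from evotraj import simdata, variants
from evotraj.variants import (
    AncestorVariantSet,
    MutationCall,
    RepeatMask,
    build_trajectories,
    classify_substitution,
    filter_dense_windows,
    filter_repeat_mask,
    filter_strand_support,
    read_calls,
    spectrum_summary,
    strand_qualified_keys,
    subtract_ancestor,
)


def call(position=100, day=17, frequency=0.2, fwd=5, rev=5, depth=600, ref="A",
         alt="G", population="P1", locus="geneX", effect="nonsynonymous", kind="SNP"):
    return MutationCall(
        population=population, day=day, position=position, ref=ref, alt=alt,
        kind=kind, effect=effect, locus=locus, frequency=frequency,
        fwd_reads=fwd, rev_reads=rev, depth=depth,
    )


class TestMutationCall:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            call(frequency=1.2)
        with pytest.raises(ValueError):
            call(position=0)
        with pytest.raises(ValueError):
            call(fwd=400, rev=300, depth=600)

    def test_key_is_position_ref_alt(self):
        assert call().key == (100, "A", "G")


class TestReadCalls:
    HEADER = "population\tday\tposition\tref\talt\tkind\teffect\tlocus\tfrequency\tfwd_reads\trev_reads\tdepth\n"

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text(self.HEADER)
        assert read_calls(p) == []

    def test_toy_tsv_parses_all_rows(self, tmp_path):
        rows = [
            "P1\t17\t100\tA\tG\tSNP\tnonsynonymous\tgeneA\t0.25\t10\t12\t90",
            "P1\t17\t250\tC\tT\tSNP\tsynonymous\tgeneB\t0.5\t30\t31\t122",
            "P1\t44\t100\tA\tG\tSNP\tnonsynonymous\tgeneA\t0.75\t45\t44\t120",
        ]
        p = tmp_path / "toy.tsv"
        p.write_text(self.HEADER + "\n".join(rows) + "\n")
        calls = read_calls(p)
        assert len(calls) == 3
        assert calls[0].position == 100 and calls[0].frequency == 0.25
        assert calls[2].day == 44 and calls[2].fwd_reads == 45

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("population\tday\tposition\nP1\t17\t100\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_calls(p)

    def test_malformed_row_reports_row_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            self.HEADER
            + "P1\t17\t100\tA\tG\tSNP\tnonsynonymous\tgeneA\t1.7\t10\t12\t90\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_calls(p)

    def test_vcf_record_maps_af_and_dp4(self, tmp_path):
        vcf = tmp_path / "one.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AF,Number=1,Type=Float,Description="allele frequency">\n'
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">\n'
            '##INFO=<ID=DP4,Number=4,Type=Integer,Description="strand depths">\n'
            '##INFO=<ID=POP,Number=1,Type=String,Description="population">\n'
            '##INFO=<ID=DAY,Number=1,Type=Integer,Description="day">\n'
            '##INFO=<ID=LOCUS,Number=1,Type=String,Description="locus">\n'
            '##INFO=<ID=EFFECT,Number=1,Type=String,Description="effect">\n'
            "##contig=<ID=chr1,length=1000000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t1234\t.\tA\tG\t50\tPASS\t"
            "AF=0.25;DP=100;DP4=40,35,13,12;POP=P1;DAY=17;LOCUS=geneA;EFFECT=synonymous\n"
        )
        (rec,) = read_calls(vcf, dialect="vcf")
        assert rec.position == 1234
        assert rec.frequency == pytest.approx(0.25)
        assert (rec.fwd_reads, rec.rev_reads) == (13, 12)
        assert rec.population == "P1" and rec.day == 17


class TestAncestorSubtraction:
    def test_empty_set_is_identity(self):
        calls = [call(position=p) for p in (1, 2, 3)]
        assert subtract_ancestor(calls, AncestorVariantSet()) == calls

    def test_full_overlap_empties_output(self):
        calls = [call(position=p) for p in (1, 2, 3)]
        anc = AncestorVariantSet.from_pairs((c.position, c.alt) for c in calls)
        assert subtract_ancestor(calls, anc) == []

    def test_partial_overlap_counts(self):
        calls = [call(position=p) for p in range(1, 11)]
        anc = AncestorVariantSet.from_pairs([(2, "G"), (5, "G"), (9, "G")])
        assert len(subtract_ancestor(calls, anc)) == 7


class TestStrandSupport:
    def test_boundary_and_mixed_supports(self):
        supports = [(3, 3), (2, 3), (3, 2), (0, 0), (5, 5), (4, 1)]
        calls = [call(position=i + 1, fwd=f, rev=r) for i, (f, r) in enumerate(supports)]
        kept = filter_strand_support(calls, min_per_strand=3)
        assert [(c.fwd_reads, c.rev_reads) for c in kept] == [(3, 3), (5, 5)]

    def test_qualification_at_any_timepoint_admits_trajectory(self):
        weak = call(position=7, day=17, fwd=2, rev=2)
        strong = call(position=7, day=44, fwd=8, rev=9)
        keys = strand_qualified_keys([weak, strong])
        assert keys == {(7, "A", "G")}


class TestDenseWindows:
    def test_isolated_call_retained(self):
        assert len(filter_dense_windows([call(position=500)])) == 1

    def test_cluster_of_four_all_dropped(self):
        calls = [call(position=p) for p in (100, 105, 110, 112)]
        assert filter_dense_windows(calls, window=15, max_neighbors=2) == []

    def test_distant_pair_retained(self):
        calls = [call(position=100), call(position=140)]
        assert len(filter_dense_windows(calls)) == 2

    def test_different_days_do_not_interact(self):
        calls = [call(position=p, day=17) for p in (100, 105, 110)] + [
            call(position=112, day=44)
        ]
        kept = filter_dense_windows(calls, max_neighbors=2)
        assert len(kept) == 4  # three neighbors within a day never exceed 2


class TestRepeatMask:
    def test_empty_mask_is_identity(self):
        calls = [call(position=p) for p in (10, 20)]
        assert filter_repeat_mask(calls, RepeatMask()) == calls

    def test_interval_ends_are_inclusive(self):
        mask = RepeatMask([(100, 200)])
        calls = [call(position=p) for p in (99, 100, 200, 201)]
        kept = filter_repeat_mask(calls, mask)
        assert [c.position for c in kept] == [99, 201]

    def test_partial_masking(self):
        mask = RepeatMask([(100, 110), (300, 310)])
        calls = [call(position=p) for p in (105, 150, 305, 400, 500)]
        assert len(filter_repeat_mask(calls, mask)) == 3

    def test_bed_conversion_to_one_based_inclusive(self, tmp_path):
        bed = tmp_path / "mask.bed"
        bed.write_text("chr1\t99\t110\n")
        mask = RepeatMask.from_bed(bed)
        assert mask.intervals == [(100, 110)]


class TestFilterCommutativity:
    def test_order_independent_retained_set(self):
        rng = np.random.default_rng(0)
        calls = [
            call(
                position=int(rng.integers(1, 10_000)),
                fwd=int(rng.integers(0, 10)),
                rev=int(rng.integers(0, 10)),
                depth=40,
                frequency=float(rng.uniform(0, 1)),
            )
            for _ in range(80)
        ]
        anc = AncestorVariantSet.from_pairs([(c.position, c.alt) for c in calls[:10]])
        mask = RepeatMask([(2000, 4000)])
        filters = {
            "anc": lambda cs: subtract_ancestor(cs, anc),
            "strand": lambda cs: filter_strand_support(cs),
            "mask": lambda cs: filter_repeat_mask(cs, mask),
        }
        results = set()
        for order in itertools.permutations(filters.values()):
            out = calls
            for f in order:
                out = f(out)
            results.add(frozenset((c.position, c.day) for c in out))
        assert len(results) == 1


class TestBuildTrajectories:
    def test_partial_detection_fills_zeros(self):
        days = [17, 44, 66, 90]
        calls = [call(position=5, day=17, frequency=0.2), call(position=5, day=44, frequency=0.6)]
        table = build_trajectories(calls, days)
        row = table.freq.loc[[(5, "A", "G")]].iloc[0]
        assert list(row) == [0.2, 0.6, 0.0, 0.0]
        det = table.detected.loc[[(5, "A", "G")]].iloc[0]
        assert list(det) == [True, True, False, False]

    def test_union_of_disjoint_day_sets(self):
        calls = [call(position=p, day=17) for p in (1, 2)] + [
            call(position=p, day=44) for p in (3, 4, 5)
        ]
        table = build_trajectories(calls, [17, 44])
        assert table.n_mutations == 5

    def test_duplicate_mutation_day_raises(self):
        calls = [call(position=5, day=17), call(position=5, day=17, frequency=0.9, fwd=100, rev=100)]
        with pytest.raises(ValueError, match="duplicate"):
            build_trajectories(calls, [17, 44])

    def test_mixed_populations_rejected(self):
        calls = [call(population="P1"), call(population="P2", position=200)]
        with pytest.raises(ValueError, match="multiple populations"):
            build_trajectories(calls, [17])

    def test_simulator_roundtrip_matches_observed_table(self, sim_result, tmp_path):
        simdata.write_dataset(sim_result, tmp_path)
        calls = []
        for day in sim_result.config.sample_days:
            calls.extend(read_calls(tmp_path / f"P1_day{day:03d}.calls.tsv"))
        table = build_trajectories(calls, list(sim_result.config.sample_days))
        obs = sim_result.observed_calls
        assert table.n_mutations == obs["position"].nunique()
        for _, row in obs.iterrows():
            key = (row["position"], row["ref"], row["alt"])
            assert float(table.freq.loc[[key], row["day"]].iloc[0]) == pytest.approx(
                row["frequency"]
            )


class TestSubstitutionSpectrum:
    def test_all_twelve_single_base_changes(self):
        transitions = transversions = 0
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                cls = classify_substitution(ref, alt)
                transitions += cls == "transition"
                transversions += cls == "transversion"
        assert (transitions, transversions) == (4, 8)

    def test_indels_and_ambiguity(self):
        assert classify_substitution("A", "AG") == "indel"
        assert classify_substitution("A", ".") == "indel"
        with pytest.raises(ValueError):
            classify_substitution("N", "A")

    def test_spectrum_fractions(self):
        calls = (
            [call(position=i, ref="A", alt="G") for i in range(1, 7)]
            + [call(position=i, ref="A", alt="T") for i in range(7, 9)]
            + [call(position=i, ref="A", alt=".", kind="deletion") for i in range(9, 11)]
        )
        out = spectrum_summary(calls)
        assert out.loc["transition", "fraction"] == pytest.approx(0.6)
        assert out.loc["transversion", "fraction"] == pytest.approx(0.2)
        assert out.loc["indel", "fraction"] == pytest.approx(0.2)

    def test_empty_input_all_zero(self):
        out = spectrum_summary([])
        assert (out["count"] == 0).all()

    def test_mutator_simulation_has_elevated_transition_fraction(self):
        cfg = dict(
            n_bottleneck=10_000, n_days=20, sample_days=(20,), mu=2e-4, seed=5,
            record_floor=1e-6,  # record every lineage alive at the sample day
        )
        plain = simdata.simulate_population(simdata.SimConfig(population="X", **cfg))
        mut = simdata.simulate_population(
            simdata.SimConfig(
                population="Y",
                initial_marked_fraction=0.5,
                initial_marked_is_mutator=True,
                **cfg,
            )
        )
        def ts_frac(info):
            snp = info[info["kind"] == "SNP"]
            ts = sum(
                classify_substitution(r, a) == "transition"
                for r, a in zip(snp["ref"], snp["alt"])
            )
            return ts / len(snp)
        assert ts_frac(mut.mutation_info) > ts_frac(plain.mutation_info)
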