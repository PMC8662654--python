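"""Post-calling filters and trajectory consolidation on a toy call set.

Shows the three standard filters (ancestral subtraction, per-strand read
support, dense-window exclusion) and the mutation x day frequency matrix
they produce.
"""

from evotraj import variants
from evotraj.variants import AncestorVariantSet, MutationCall

calls = [
    # a real mutation, well supported on both strands at two days
    MutationCall("P1", 17, 1_204_331, "A", "G", "SNP", "nonsynonymous", "geneA", 0.12, 35, 38, 610),
    MutationCall("P1", 44, 1_204_331, "A", "G", "SNP", "nonsynonymous", "geneA", 0.55, 160, 170, 600),
    # ancestral variant, present before the experiment
    MutationCall("P1", 17, 2_500_000, "C", "T", "SNP", "synonymous", "geneB", 0.99, 300, 290, 600),
    # weakly supported on one strand: rejected
    MutationCall("P1", 17, 3_100_000, "G", "T", "SNP", "nonsynonymous", "geneC", 0.05, 28, 2, 612),
    # three co-called neighbours within 15 bp: a misalignment signature
    *[
        MutationCall("P1", 44, 4_000_000 + d, "T", "C", "SNP", "synonymous", "geneD", 0.08, 25, 24, 605)
        for d in (0, 6, 11, 14)
    ],
]

ancestor = AncestorVariantSet.from_pairs([(2_500_000, "T")])
kept = variants.subtract_ancestor(calls, ancestor)
kept = variants.filter_strand_support(kept, min_per_strand=3)
kept = variants.filter_dense_windows(kept, window=15, max_neighbors=2)
print(f"{len(calls)} raw calls -> {len(kept)} after filtering")

table = variants.build_trajectories(kept, days=[17, 44, 66, 90])
print(table.freq)
# Each row is one mutation's frequency trajectory; zeros mean "sampled but
# below detection", and the geneA mutation is rising toward fixation.
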