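"""Relative telomere length and weak-evidence variant sharing.

The telomere ratio is the log2 of coverage-normalised motif-read counts
(tumour over matched normal); negative values mean telomere shortening.
The overlap fraction measures, over the union of two call sets from one
donor, how many variants have pileup evidence in both samples.
"""

from somacat.overlap import overlap_fraction
from somacat.synthetic import simulate_pair, simulate_telomere_reads
from somacat.telomere import TelomereInput, count_motif_reads, telomere_ratio

# count telomeric reads (>= 3 tandem TTAGGG copies, either strand)
reads = simulate_telomere_reads(n_motif_reads=30, n_background_reads=200, rng=2)
print(f"motif-bearing reads counted: {count_motif_reads(reads)} of {len(reads)}")

tumour = TelomereInput("tumour", motif_read_count=300, mean_coverage=60.0)
normal = TelomereInput("normal", motif_read_count=250, mean_coverage=40.0)
ratio = telomere_ratio(tumour, normal)
print(f"log2 telomere ratio: {ratio:.4f}  (negative = shorter tumour telomeres)")

# paired samples simulated with 80% of the variant union truly shared
calls_a, calls_b, ev_a, ev_b, truth = simulate_pair(sharing_fraction=0.8, rng=3)
res = overlap_fraction(calls_a, calls_b, ev_a, ev_b)
print(f"overlap: union={res.union_fraction:.3f} "
      f"a-in-b={res.fraction_a_in_b:.3f} b-in-a={res.fraction_b_in_a:.3f} "
      f"(n_union={res.n_union})")
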