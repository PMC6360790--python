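"""Detect an injected hypermutation cluster on a synthetic chromosome.

Background mutations arrive every ~100 kb; a 12-mutation cluster with
~100 bp spacing is injected.  The caller segments the log10 inter-mutation
distances by exact piecewise constant fitting and emits regions with at
least 6 mutations and mean spacing <= 1000 bp.
"""

from somacat.kataegis import call_kataegis
from somacat.synthetic import KataegisInjection, simulate_positions

records, truth = simulate_positions(
    {"chr1": 50_000_000},
    injections=[KataegisInjection(chrom="chr1", n_mutations=12, target_imd=100.0)],
    rng=7,
)
print(f"{len(records)} mutations simulated; injected cluster at "
      f"{truth.iloc[0].chrom}:{truth.iloc[0].start}-{truth.iloc[0].end}")

for region in call_kataegis(records):
    # n_mutations and mean_imd re-state the thresholds every region satisfies
    print(f"kataegis {region.chrom}:{region.start}-{region.end}  "
          f"n={region.n_mutations}  mean_imd={region.mean_imd:.1f} bp")
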