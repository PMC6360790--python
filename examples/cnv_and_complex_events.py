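"""Ploidy-gated copy-number calls and complex-event flagging.

Engineers one chromothripsis-like, one BFB-like and one quiet chromosome,
then shows per-segment amplification/loss calls, the genome fraction
altered, and the per-chromosome complex-event flags with their rule traces.
"""

from somacat.cnv import call_amplification, call_loss, genome_fraction_altered
from somacat.complex_events import detect_complex_events
from somacat.rearrangements import cluster_breakpoints
from somacat.synthetic import DEFAULT_CHROM_SIZES, simulate_cn

tags = {"chr1": "chromothripsis", "chr2": "bfb", "chr3": "quiet"}
profile, events, truth = simulate_cn(tags, ploidy=2.0, rng=4)
events = cluster_breakpoints(events)

# segment-level event calls are gated by the sample's average ploidy:
# near-diploid genomes amplify at CN >= 6 and lose at CN = 0
print(f"ploidy {profile.ploidy}: CN 6 amplified? {call_amplification(6, profile.ploidy)}; "
      f"CN 8 at ploidy 3.0 amplified? {call_amplification(8, 3.0)}")
genome = sum(DEFAULT_CHROM_SIZES.values())
frac = genome_fraction_altered(profile, genome, deletion_rule="results")
print(f"genome fraction altered (CN<=1 or CN>=6): {frac:.4f}")

for report in detect_complex_events(events, profile, chrom_sizes=DEFAULT_CHROM_SIZES):
    f = report.features
    print(f"{f.chrom}: oscillations={f.n_cn_oscillations} "
          f"inv_frac={f.inversion_breakend_fraction:.2f} "
          f"telomeric_loss={f.telomeric_loss} flags={report.flags or '-'}")
    for line in report.rule_trace:
        print(f"    {line}")
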