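# Methods

This note documents the models and procedures somacat implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Substitution catalogues

Single-base substitutions are expressed on the pyrimidine strand: calls
with a purine reference are reverse-complemented (context included)
before labelling, so each substitution maps to one of 96 classes
(6 pyrimidine substitution types × 16 flanking-base contexts). The label
ordering is fixed — substitution-type major, contexts lexicographic —
which is the convention shared by the common signature toolkits; the
class alphabet is never inferred from data. Contexts may be supplied with
the calls or looked up from a FASTA (1-based position ± 1 bp); records
whose context contains N, indels, and multi-nucleotide events are
excluded from the catalogue and reported in a skip log. Indels still
count toward mutation-burden summaries; signature analysis is
substitution-only, the standard choice for this class system.

## Signature model

A catalogue matrix V (m classes × n samples) is modelled as V ≈ S·E with
S ≥ 0 column-stochastic and E ≥ 0.

**Extraction.** NMF with multiplicative updates under the Frobenius
objective (scikit-learn's `mu` solver), random initialisation,
`n_restarts` independent seeded restarts (default 200), convergence
tolerance 1e−6 or 10,000 iterations; the restart with the lowest
reconstruction error is kept. All restart seeds derive from one user
seed, so results are bit-reproducible. S columns are normalised to sum
to 1 with the scale absorbed into E.

**Exposures.** Raw NMF loadings do not conserve per-sample totals, so
exposures are always produced by the quadratic programme
min ‖v/T − S·w‖² on the probability simplex (SLSQP with analytic
gradient, ftol 1e−14), reported as counts w·T. This guarantees
Σ exposures = T exactly per sample.

**Pruning.** Signatures attributed < 10% of a sample's mutations are
removed and the survivors refit; this is iterated to a fixed point
because a single pass can leave a refit signature below threshold. A
single-signature solution is always a fixed point, so termination is
guaranteed; each pass is logged.

**Rank choice.** k is a user parameter. `rank_survey` reports
reconstruction error and a restart-stability silhouette over a k-range;
the package deliberately does not auto-select k.

**Matching.** Extracted signatures are matched to a user-supplied
reference matrix by maximal cosine similarity, ties broken to the lowest
reference index (logged). A small bundled synthetic reference
(`synthetic_signature_matrix`) ships so tests and examples need no
download; it is synthetic, not a community catalogue.

## Kataegis

Per sample and chromosome, positions are deduplicated (logged), IMDs
computed, and log10 IMDs segmented by exact penalised least squares: the
dynamic programme minimises Σ within-segment SSE + γ·(number of
segments) over all partitions with segments ≥ kmin, in O(n²) via prefix
sums. A segment spanning IMDs i…j covers mutations i…j+1 and is emitted
iff it has ≥ 6 mutations and mean raw-scale IMD ≤ 1000 bp. Fitting on
the log scale stabilises the segmentation; the emission threshold is
deliberately on the bp scale, where the 1000 bp definition lives.

**Penalty default γ = 12, kmin = 2.** The penalty has to sit between two
scales. The smallest emittable cluster — 6 mutations at ~100 bp spacing
against a ~100 kb background — contributes 5 IMDs roughly 3 log10-decades
below the background mean, an SSE gain of ≈ 5·3² = 45 for the two
changepoints needed to excise an interior cluster; a per-changepoint
penalty must therefore stay below ≈ 22.5 or minimal clusters become
structurally undetectable. The background log10-IMD variance is ≈ 0.3 per
point, so spurious changepoints pay for themselves only at penalties of
order 1. γ = 12 sits comfortably between; emission thresholds (n ≥ 6,
mean ≤ 1000 bp) provide the specificity, and background-only simulations
produce zero emitted regions. Adjacent qualifying segments are emitted
separately and flagged rather than merged.

## Rearrangement classes and clustering

Event types are taken from input (del, dup, inv, translocation; aliases
accepted), never re-derived from breakend geometry. Sizes |pos2 − pos1|
fall into half-open bins [1–10 kb), [10–100 kb), [100 kb–1 Mb),
[1–10 Mb), [10 Mb, ∞); events under 1 kb go into the smallest bin and are
logged. Translocations carry no size bin. With the clustered/non-clustered
axis this yields exactly 32 classes.

Clustering reconciles an interval-clustering operation with a
density rule: per chromosome, breakends are single-linkage grouped
(linked when ≤ 1 Mb apart); a group is clustered when it holds ≥ 10
breakends and some sliding 1 Mb span within it contains ≥ 10. An event is
clustered iff either breakend is; translocation breakends count on both
chromosomes. The procedure is order-independent by construction.
Samples with fewer than `min_sv` (default 10) events are excluded from
rearrangement-signature extraction — too few events to constrain a
mixture — and logged.

## Copy-number events

Only high-level events are called, gated by average genome ploidy with
the 2.7 cutoff: amplification CN ≥ 6 (ploidy ≤ 2.7) or ≥ 9 (ploidy
> 2.7); loss CN = 0 (ploidy ≤ 2.7) or CN < ploidy − 2.7 (ploidy > 2.7).
The thresholds make amplification and loss mutually exclusive at every
grid point, which the tests assert exhaustively.

Two deletion conventions coexist in practice: the event-call rule above
(homozygous deletion only, when near-diploid) and a ploidy-independent
summary convention (deletion CN ≤ 1, amplification CN ≥ 6) used for
genome-fraction-altered reporting. Both are implemented behind a
`deletion_rule` switch — `"methods"` for event lists, `"results"`
(default) for fraction-altered — because they answer different
questions; the discrepancy is deliberate and surfaced here. Gene
annotation is any-overlap (≥ 1 bp) against the segment calls; amplified
and lost may co-occur for a gene spanning both and are reported
separately, with uncovered genes flagged.

## Telomere content

Reads containing ≥ `min_copies` (default 3) tandem copies of the motif
or its reverse complement are counted; counts are divided by mean
genomic coverage and the tumour/normal ratio reported on log2 scale.
Zero counts yield an undefined ratio (None), flagged rather than raised.
The default motif is the canonical human telomeric repeat TTAGGG; the
variant spelling TTAAGG that appears in some tool documentation is
selectable, and whether tandemness (vs any occurrence) is required is a
parameter because counting tools differ — 3 tandem copies is a
conservative middle ground. The ratio is exactly antisymmetric under
swapping samples and invariant to rescaling a sample's count and
coverage together.

## Complex-event flags

The underlying criteria were designed for expert review of per-chromosome
plots; somacat operationalises them as explicit thresholds so the flags
are reproducible and auditable. Feature definitions: copy numbers are
rounded to integers; the oscillation count is the length − 1 of the
longest run strictly alternating between exactly two CN states;
heterozygosity retention is the fraction of oscillating-run segments with
minor CN ≥ 1; telomeric loss is a deleted/lost segment within 1 Mb of
either chromosome end (chromosome sizes supplied, or the covered extent
as fallback); "random joins" is proxied by the Shannon entropy of the
chromosome's SV-type composition normalised by log 4 — a stated proxy,
not a reconstruction of join randomness.

Flags (all conjunctive, defaults in `ComplexEventThresholds`):

* chromothripsis-like — oscillations ≥ 8 AND clustered SVs present AND
  heterozygosity retention ≥ 0.5 AND type entropy ≥ 0.5;
* BFB-like — telomeric loss AND inversion-breakend fraction ≥ 0.5 AND a
  ploidy-gated amplification on the chromosome;
* local complexity — clustered SVs AND (≥ 3 CN changepoints OR CN > 9).

Every fired condition is recorded in a rule trace; there is never a flag
without a trace. The thresholds are package decisions, not community
standards, and should be sensitivity-swept on real cohorts.

## Variant overlap

A read is good when non-duplicate, mapping quality ≥ 10, ≥ 34 aligned
(match/mismatch) bases and ≤ 3 mismatches; "≥ 34 aligned bases" is this
package's interpretation of a CIGAR-based length score whose original
definition is tool-internal. A variant is present when the matched
normal has zero alt reads, coverage ≥ 10 and ≥ 1 good alt read. The
overlap between two samples is reported three ways: over the union of
call sets (symmetric; the headline number) and per direction. Missing
evidence rows count as absent and are logged. Presence is monotone in
coverage and alt support and anti-monotone in normal alt support.

## Synthetic cohort generator

The generator produces inputs with exactly the structure each stage
assumes, plus truth manifests for recovery scoring. Defaults define the
study conditions used throughout the tests: 30 samples, 5 signatures,
Dirichlet(1) exposure proportions, 2000 mutations per sample; a
3 × 50 Mb synthetic genome; exponential background inter-mutation
spacing with mean 100 kb and geometric injected-cluster spacing with
mean 100 bp; uniform-by-default 32-class SV mixtures with clustered
classes placed in constructive sub-1 Mb foci (so the density rule holds
by construction, not by chance); engineered chromosomes — chromothripsis:
13–18 segments alternating two CN states with minor CN 1 and ≥ 12
clustered mixed-type SVs in a sub-1 Mb focus; BFB: a deleted telomeric
segment, a CN ≥ 10 amplicon, and inversion-dominated breakends inside
it; quiet: flat CN at ploidy with a handful of scattered SVs — Poisson
telomere counts (tumour mean 300 at 60×, normal 250 at 40×), and paired
call sets whose shared fraction is specified on the union scale, the
scale on which overlap is measured. All randomness flows from one seed
through spawned child generators; fixed seed ⇒ byte-identical output
files.

What it does not emulate: subclonality and purity, sequencing artefacts
and caller-specific error modes, replication-timing and chromatin
covariates of mutation density, realistic chromosome counts and sizes,
SV breakend orientation, and correlated tumour/normal coverage. Passing
tests therefore demonstrate algorithmic correctness and recovery under
the stated statistical model — not robustness to real-data artefacts.

## Problem sizes and numerics

The test suite and the acceptance script use deliberately small problem
sizes — 30-sample cohorts, 50 Mb chromosomes (~500 mutations each), 50–100
simulated chromosomes per check, 200-event SV sets — chosen so the full
suite runs in well under a minute while keeping every statistical check
comfortably powered. The PCF dynamic programme is exact, so scale only
affects runtime (O(n²) per chromosome), not results. QP solutions are
validated against a derivative-free nested grid-search oracle on the
simplex (coarse 0.05 sweep, 5× local refinement to 0.001). Multinomial
convergence checks compare the L1 deviation to its closed-form
expectation Σ√(2pᵢ(1−pᵢ)/(πT)) rather than a fixed constant, which is
the correct yardstick at 96 classes.

## Known limitations

* NMF rank selection is left to the user; the stability survey is a
  guide, not a criterion.
* Complex-event thresholds encode one reasonable operationalisation of
  qualitative review criteria; different cohorts may need different
  values, which is why every threshold is configuration.
* The clustered-breakend rule flags whole linkage groups; very long
  sparse groups attached to one dense focus are all marked clustered.
* Rearrangement signatures on samples with few SVs are unstable; the
  `min_sv` exclusion is a blunt but honest guard.
* Telomere counting from unaligned reads cannot distinguish interstitial
  telomeric repeats from true telomeres.
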