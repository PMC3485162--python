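# Methods

## Melting-temperature model

`tm_basic` uses the salt-adjusted GC%/length form

    Tm = base + gc_coef · (%GC) − length_const / N        [°C]

with defaults `base = 62.30`, `gc_coef = 0.41`, `length_const = 500`. This is
the Marmur–Schildkraut–Doty equation
`81.5 + 16.6·log10[Na+] + 0.41·%GC − 500/N` with the salt term folded into a
single constant (−19.20, i.e. ≈ 70 mM monovalent salt). The constants were
calibrated against the melting temperatures published with the bundled maize
panel: they reproduce 34 of the 37 published values exactly at two decimals.
The three exceptions are internal inconsistencies of the published table
itself, not model error: the phi120-F/phi120-R values are transposed
relative to their sequences (each matches the *other* primer's formula
value), and the C-umc1268-F value (71.93) corresponds to no integer GC count
at 43 nt (the formula gives 72.60). These rows are flagged
`formula_concordant = 0` in `umpcr/data/reference_oligos.tsv` and the tests
assert both the 34 exact matches and the transposition.

Numerical choice: the formula is evaluated in exact decimal arithmetic and
rounded half-up to `report_decimals` (default 2). Two published values
(71.33, twice) sit exactly on a `.xx5` tie that binary floating point would
round down; decimal evaluation is required to reproduce them. Oligos shorter
than 8 nt are rejected — the −500/N term degenerates. `TmParams` exposes the
constants so nearest-neighbour models can be slotted in without changing the
interface; no thermodynamic cross-check against an external predictor is
bundled.

## Complementarity model

Dimer and hairpin screening counts only perfect antiparallel Watson–Crick
pairs (A:T, G:C) — no wobbles, bulges, or free energies. This matches the
design rule being enforced, which is a run-length rule ("no more than six
consecutive complementary base pairs"), not a thermodynamic one.
`longest_complementary_run(a, b)` is the longest common substring of `a` and
`revcomp(b)` (suffix-extension dynamic programming, O(|a|·|b|); ties broken
by smallest position in `a`, then in `b`); it is property-tested against an
exhaustive substring-pair oracle. Hairpins are maximal perfect stems with a
loop of at least `min_loop` (default 3) nt; a stem whose full run would
pinch the loop shorter is trimmed inward (each trimmed pair lengthens the
loop by 2) and reported only if it still reaches `min_stem`.

A reproducible observation from running the validator on the bundled panel:
the published five-locus U-panel does **not** satisfy the six-base rule as
literally stated — U-umc1478-F contains a 10-bp self-complementary
palindrome (AGAAGCTTCT) spanning the adapter/primer junction, and several
adapter-primers carry perfect 5-bp hairpin stems. The two bare adapters do
satisfy it (worst run 4 bp, adapter-F's internal GTAC). The validator
reports all of this as found; the junction chimeras evidently worked in
practice, so the rule is best read as a screening guideline for candidate
adapters rather than a property the published oligos all have.

## Panel validation defaults

* `tm_window = (69.5, 74.5)` °C — brackets the published U-adapter-primer
  range (69.92–73.96) with margin, centred on the stated ≈ 70 °C target; the
  C-adapter variants (up to 76.12) fall outside and are flagged, consistent
  with the common adapter's poorer performance.
* `max_run = 6`, `max_hairpin_stem = 5` (loop ≥ 3) — the published rules.
* The SSR-portion Tm spread is informational (flag above 10 °C): a wide
  spread is exactly the situation the adapters rescue.
* Adapter genome rarity is informational and only computed when a genome
  FASTA is supplied; matches are exact, both strands, overlapping, flagged
  at ≥ 1 hit/Mb. No published numeric threshold exists; the value is a
  screening default, configurable.
* Dimer rules cover every unordered pair of tube oligos including self-pairs
  and the bare adapters.

`balance_concentrations` generalizes the published single-locus adjustment
(double the weakest locus's primers) to `factor = median(yield)/yield`:
median-robust, scale-invariant, and reducing to exactly "2× for a locus at
half the median intensity".

## Thermal program

Defaults: 94 °C/300 s init; first round 3 cycles of [94 °C/40 s, one
20 s annealing step per locus, 72 °C/30 s]; second round 30 cycles of
[94 °C/40 s, 70 °C/50 s]; 72 °C/600 s final. The published procedure never
states the per-locus first-round annealing temperatures; this package uses
the mean of the locus's forward/reverse SSR-portion Tm under the calibrated
formula, with an `anneal_offset` knob (set 5 for the common Tm−5 practice;
default 0 since the published Tm column is the only temperature data
available). Within a cycle the annealing steps run in descending temperature
(configurable `desc`/`asc`/`panel`): the conservative order, since a cool
step first would let low-Tm primers misprime before the high-Tm primers have
annealed. Descending order also canonicalizes the program against panel
ordering. A second-round count outside 28–32 warns but runs.

## Mechanism simulator

`mechsim` tracks expected copy numbers of six strand classes per locus
(genomic ±, half products `half_f`/`half_r` with one defined end, full
products `full_±` with both ends defined). First-round recursion (per cycle,
efficiency `e`, increments computed from cycle-start counts):

    half_f  += e · genomic_minus
    half_r  += e · genomic_plus
    full_+  += e · (half_r + full_−)
    full_−  += e · (half_f + full_+)

Second round: only `full_± += e · full_∓`; genomic and half classes are
fixed points (full-length annealing has no template on them — the mechanism's
specificity argument). Assumptions: primers in excess (each template strand
makes at most one copy per cycle), deterministic expected counts rather than
stochastic molecules, no mispriming, no polymerase errors. Efficiency can be
per-locus; with `couple_concentration` the effective efficiency is
`min(1, e · concentration_factor)` — the simplest expression of "double the
primer for the weak locus", and enough to show primer-amount compensation
closing the yield gap that unequal efficiencies open.

Consequences the simulator reproduces (and the tests pin): with 1 starting
dsDNA and e = 1 the first full products appear at the end of **cycle 2**
(before that the adapters have no template), full-length annealing first has
templates at the start of **cycle 3**, the end-of-round-1 state is
(half 3/3, full 4/4), and the second round doubles full strands exactly:
`2^(n+3)` total full strands after n second-round cycles (8.6 × 10⁹ at
n = 30). One modelling simplification: a first-round 3'-portion priming
event on a full product yields a full product directly (no separate
"run-off onto full template" subclass); this is validated against the
oracle, which carries no such shortcut.

`enumerate_lineages` is the independent oracle: every single strand is an
explicit sequence string; per cycle each strand is primed at most once
(3'-core match in round 1, full-length match in round 2) and extended to the
template's 5' end; products are classified by inspecting their ends. It is
exact at efficiency 1, refuses more than 10 total cycles (2^n molecules),
and must agree with the recursion cycle-for-cycle — the suite checks this on
toy loci built from all five bundled primer pairs. A byproduct check: every
full-product string has exactly the tailed amplicon length.

## In-silico PCR

Coordinates are 0-based half-open on the plus strand. A primer binds where
its locus-specific 3' core matches with at most `max_mismatches` (default 0)
and its 3'-terminal `min_3p_exact` bases (default 3) match exactly —
extension needs a paired 3' terminus. An adapter tail never hybridizes
genomic DNA and is carried as `tail_length`, not as mismatches. Amplicons
pair a plus-strand site of one primer with a downstream minus-strand site of
its mate in either orientation, so predictions are invariant under
reverse-complementing the template; site pairs whose product would be
shorter than the two primers are rejected, as are products above `max_len`
(default 1500 bp). Product length counts both primers at full length
including tails: a panel with 18+18 nt adapters therefore shifts every band
up by exactly 36 bp relative to the plain SSR primers — the gel-observable
signature of adapter-tailed amplification. Multiple FASTA records are
treated as haplotypes of one sample, so a heterozygote is two records whose
band patterns union.

## Purity typing

Classification is codominant and rule-ordered: (1) **hybrid** if the
observed band set equals the parental union at every locus; (2)
**female_parent** if observed bands stay within the female set everywhere
and equal it at every informative locus (where the parents differ); (3)
**male_parent** symmetrically; (4) **off_type** otherwise (any foreign
allele, or a mixed-but-incomplete pattern). Where the parents share every
allele the hybrid and parental patterns coincide; rule order then calls the
seed a hybrid — the convention implicit in counting only clearly parental
seeds as contaminants. A locus with no bands is off-type evidence under
`missing_policy="strict"` (default) or dropped under `"ignore_locus"`; both
readings are exposed because published practice does not specify one.
Band-size comparison is exact integer equality by default; `size_tolerance`
(bp) accommodates gel-sizing noise. Purity = 100 · n_hybrid / n_total,
reported to one decimal; parental and off-type seeds both count against
purity but are reported separately.

## Synthetic data

`synth` plants exact primer binding sites on random uniform-base templates
and re-draws until each planted motif is unique on both strands and no
adapter sequence occurs, so site finding has a known ground truth.
`default_reference_profiles` models two homozygous inbred parents (one
allele per locus each, 8 bp apart, loci staggered 20 bp starting at 120 bp —
typical maize SSR allele sizes). `make_seed_lot` apportions class counts
from the requested proportions by largest remainder (so 96 % of 200 is
exactly 192), shuffles seed order with the seeded generator, gives hybrids
the union pattern, parents their own pattern, and off-types 1–2 loci with an
allele shifted in 4 bp steps until foreign to both parents; band dropout
blanks one band per affected locus, with the per-locus uniform draws made
regardless of rate so that a higher rate strictly nests a lower one under
the same seed (making monotone degradation exactly testable). Defaults for
the demonstration lot are n = 200 seeds with 96/2/0/2 %
hybrid/female/male/off-type — the composition of a realistic
commercial maize lot of the kind the method was demonstrated on.

What the synthetic data does *not* emulate: near-match mispriming sites and
nonspecific products, SSR stutter, partial digestion/extraction artifacts,
and gel-calling uncertainty. Passing the round-trip tests therefore shows
the classification logic and size bookkeeping are correct, not that the
method is robust to real-gel noise; the `size_tolerance` and
`missing_policy` knobs are the intended accommodation for that noise.

## Problem sizes

The test suite and acceptance script run at desk scale by design: lineage
enumeration to 8–10 total cycles (the oracle is exponential by nature),
dimer-scan property tests on sequences ≤ 40 nt, binding-site oracle trials
on ~2 kb templates, seed lots of 200. All randomness flows through explicit
integer seeds; repeated runs are byte-identical.

## Known limitations

* The Tm formula is a single-salt calibration; it is not a nearest-neighbour
  model and should not be used for oligos with extreme composition.
* Perfect-pair complementarity scanning cannot rank near-complementary
  (mismatch-containing) dimers.
* The simulator's efficiency is a phenomenological per-locus scalar; it does
  not model primer depletion, polymerase kinetics, or stochastic drop-out at
  low template counts.
* In-silico PCR with the default zero-mismatch setting will miss sites under
  real sequence variation; raising `max_mismatches` trades specificity.
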