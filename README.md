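# umpcr — Universal Multiplex PCR design and verification toolkit

Conventional multiplex PCR is fragile: primers with different melting
temperatures compete in one tube, amplification efficiencies diverge between
the linear and exponential phases, and every new panel needs re-optimization.
Universal Multiplex PCR (UM-PCR) sidesteps this by linking two fixed 18-nt
**universal adapters** to the 5' ends of every locus-specific SSR primer —
adapter-F onto the forward primers, adapter-R onto the reverse primers — and
amplifying with a **Two Rounds Mode** thermal program:

* **Round 1 ("One by One Annealing", 3 cycles)** — each locus gets its own
  20 s annealing step at its SSR primers' temperature. In cycle 1 only the
  locus-specific 3' portions prime, producing run-off strands that carry an
  adapter at their 5' end; from cycle 2 those strands are copied, creating
  the first products bounded by one adapter and the complement of the other.
* **Round 2 (28–32 cycles, usually 30)** — a single combined 70 °C/50 s
  annealing/extension step. Only full-length adapter-primer annealing is
  stable this hot, and only the adapter-flanked products can serve as
  templates, so all loci amplify exponentially with near-identical primers
  and genomic mispriming is suppressed.

This package implements that method as a design-and-verification toolkit for
people building SSR multiplexes (e.g. for hybrid-seed genetic purity
testing in maize):

* `umpcr.seqcore` — melting temperatures by the calibrated salt-adjusted
  GC%/length formula `Tm = 62.30 + 0.41·(%GC) − 500/N` (°C), and perfect-pair
  complementarity scans (cross/self dimers, hairpins);
* `umpcr.panel` — adapter-primer construction, the design rules (Tm window
  around 70 °C, ≤ 6 consecutive complementary base pairs, hairpin stems,
  adapter rarity in a genome), primer-amount balancing, panel TSV I/O, and
  the bundled published maize panel (5+1 SSR loci, U- and C-adapter variants);
* `umpcr.cycler` — Two-Rounds-Mode thermal program generation and JSON/text
  serialization;
* `umpcr.mechsim` — a deterministic cycle-by-cycle strand-class simulator of
  the mechanism, with an exact molecule-by-molecule lineage oracle;
* `umpcr.vpcr` — in-silico multiplex PCR (binding sites with a 3'-anchor
  rule, amplicon and band-pattern prediction);
* `umpcr.puritytyping` — codominant seed classification
  (hybrid / female parent / male parent / off-type) and the genetic-purity
  statistic;
* `umpcr.synth` — seeded synthetic templates and seed lots with known truth.

## Worked example

Melting temperatures of the bundled published oligos (`umpcr tm --bundled`):

```
name	length	tm
universal adapter-F	18	57.30
universal adapter-R	18	55.02
common adapter	18	61.86
phi085-F	21	61.92
phi085-R	18	57.30
U-phi085-F	39	72.61
```

The 18-nt adapter-F melts at 57.30 °C; the 39-nt chimera U-phi085-F
(adapter-F + phi085-F) reaches 72.61 °C — the tails lift every adapter-primer
to ≈ 70 °C, which is what makes the hot second round work.

A synthetic 200-seed lot with a realistic composition (96 % hybrids, 2 %
selfed female parent, 2 % off-types), typed back blind:

```sh
umpcr synth --n 200 --seed 7 > lot.tsv
umpcr purity lot.tsv
```

```
seeds: 200
  hybrid:        192
  female parent: 4
  male parent:   0
  off-type:      4
genetic purity: 96.0%
```

Each seed's per-locus band sizes are compared with the parental references:
a hybrid shows the union of both parents' bands at every locus (SSR markers
are codominant), a selfed female shows only the female bands, and any allele
foreign to both parents marks an off-type. Purity is the percentage of seeds
typing as the hybrid — here 192/200 = 96.0 %.

The thermal program for the bundled five-locus panel
(`umpcr program --format text`):

```
# Two Rounds Mode program — panel maize-ssr-U
initial denaturation:
  94 °C	5 min	init_denature
first round — One by One Annealing (3 cycles):
 cycle 1:
  94 °C	40s	denature
  64.66 °C	20s	anneal  (umc1478)
  62.95 °C	20s	anneal  (phi041)
  61.95 °C	20s	anneal  (phi123)
  60.3 °C	20s	anneal  (umc1268)
  59.61 °C	20s	anneal  (phi085)
  72 °C	30s	extend
```

Each first-round cycle anneals the five loci one by one, hottest first, at
the mean Tm of each locus's forward/reverse SSR primers; the second round is
30 cycles of 94 °C/40 s + 70 °C/50 s, and the program ends with 72 °C/10 min.

Other subcommands: `design` (attach adapters to an SSR panel TSV),
`validate` (design rules), `simulate` (mechanism simulator), `ispcr`
(in-silico PCR on FASTA templates). See `umpcr --help`.

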