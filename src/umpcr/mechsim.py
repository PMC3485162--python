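"""Mechanistic strand-class simulation of UM-PCR amplification.

The simulator tracks, per locus and per cycle, the expected copy number of
four product strand classes plus the two genomic template strands:

* ``genomic_plus`` / ``genomic_minus`` — the original template; constant.
* ``half_f`` — run-off strands starting 5'-[adapter-F + forward primer] with
  an indefinite 3' end (extension ran to the template end). Plus-sense.
* ``half_r`` — symmetric, 5'-[adapter-R + reverse primer]. Minus-sense.
* ``full_plus`` / ``full_minus`` — strands bounded by one adapter at the 5'
  end and the complement of the other adapter at the 3' end: the defined
  amplicon, the only species that doubles exponentially.

First-round cycles anneal by the primer's locus-specific 3' portion, so any
minus-sense strand templates a new plus-sense strand (and vice versa); each
template strand makes at most one copy per cycle (primer excess). In the
second round only full-length adapter-primer annealing is stable at 70 °C,
so strands lacking an adapter complement (genomic, half products) are inert —
this is why the second round amplifies only the intended products.

With one starting dsDNA copy and efficiency 1 the recursion yields half
products (1,1) after cycle 1, the first full products (1,1) after cycle 2 —
the adapters have no template before that — and from cycle 3 on the full
products feed exponential amplification. ``enumerate_lineages`` is an exact
oracle: it replays the same process molecule by molecule as explicit
sequence strings on a toy locus and classifies every product by its ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .seqcore import Oligo, revcomp

__all__ = [
    "ClassCounts",
    "StrandClassState",
    "SimConfig",
    "SimResult",
    "step",
    "run",
    "enumerate_lineages",
    "PRODUCT_CLASSES",
]

PRODUCT_CLASSES = ("half_f", "half_r", "full_plus", "full_minus")
ALL_CLASSES = ("genomic_plus", "genomic_minus") + PRODUCT_CLASSES


@dataclass(frozen=True)
class ClassCounts:
    """Expected strand copy numbers for one locus."""

    genomic_plus: float = 1.0
    genomic_minus: float = 1.0
    half_f: float = 0.0
    half_r: float = 0.0
    full_plus: float = 0.0
    full_minus: float = 0.0

    def __post_init__(self):
        for name in ALL_CLASSES:
            if getattr(self, name) < 0:
                raise ValueError(f"negative count for {name}")

    @property
    def full_total(self) -> float:
        return self.full_plus + self.full_minus

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in ALL_CLASSES}


@dataclass(frozen=True)
class StrandClassState:
    """Per-locus strand-class counts after ``cycle`` cycles (0 = initial)."""

    cycle: int
    counts: dict[str, ClassCounts]
    round_mode: str = "first"

    def locus(self, name: str) -> ClassCounts:
        return self.counts[name]


@dataclass
class SimConfig:
    """Simulation conditions.

    ``efficiency`` is the per-cycle priming/extension success fraction, a
    scalar or a per-locus mapping in [0, 1]. ``concentration_factors`` model
    the primer-amount adjustment: when ``couple_concentration`` is set the
    effective efficiency is ``min(1, efficiency * factor)``, the simplest
    expression of "double the primer for the weak locus".
    """

    first_cycles: int = 3
    second_cycles: int = 30
    efficiency: float | Mapping[str, float] = 1.0
    loci: tuple[str, ...] = ("locus",)
    initial_copies: float = 1.0
    couple_concentration: bool = False
    concentration_factors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.first_cycles < 0 or self.second_cycles < 0:
            raise ValueError("cycle counts must be >= 0")
        if self.initial_copies < 0:
            raise ValueError("initial_copies must be >= 0")
        for locus in self.loci:
            e = self.locus_efficiency(locus)
            if not 0 <= e <= 1:
                raise ValueError(f"efficiency for {locus} outside [0, 1]: {e}")

    def locus_efficiency(self, locus: str) -> float:
        e = (
            self.efficiency.get(locus, 1.0)
            if isinstance(self.efficiency, Mapping)
            else self.efficiency
        )
        if self.couple_concentration:
            e = min(1.0, e * float(self.concentration_factors.get(locus, 1.0)))
        return e


def _step_counts(c: ClassCounts, mode: str, e: float) -> ClassCounts:
    if mode == "first":
        # 3'-portion annealing: every opposite-sense strand is a template.
        return ClassCounts(
            genomic_plus=c.genomic_plus,
            genomic_minus=c.genomic_minus,
            half_f=c.half_f + e * c.genomic_minus,
            half_r=c.half_r + e * c.genomic_plus,
            full_plus=c.full_plus + e * (c.half_r + c.full_minus),
            full_minus=c.full_minus + e * (c.half_f + c.full_plus),
        )
    if mode == "second":
        # full-length annealing only: adapter-less strands are inert
        return ClassCounts(
            genomic_plus=c.genomic_plus,
            genomic_minus=c.genomic_minus,
            half_f=c.half_f,
            half_r=c.half_r,
            full_plus=c.full_plus + e * c.full_minus,
            full_minus=c.full_minus + e * c.full_plus,
        )
    raise ValueError(f"mode must be 'first' or 'second', got {mode!r}")


def step(
    state: StrandClassState,
    mode: str,
    efficiency: float | Mapping[str, float] = 1.0,
) -> StrandClassState:
    """Advance one thermal cycle. Increments from cycle-start counts only."""
    new = {}
    for locus, c in state.counts.items():
        e = (
            efficiency.get(locus, 1.0)
            if isinstance(efficiency, Mapping)
            else efficiency
        )
        if not 0 <= e <= 1:
            raise ValueError(f"efficiency for {locus} outside [0, 1]: {e}")
        new[locus] = _step_counts(c, mode, e)
    return StrandClassState(cycle=state.cycle + 1, counts=new, round_mode=mode)


@dataclass
class SimResult:
    states: list[StrandClassState]
    adapter_template_onset: dict[str, int | None]
    full_amplification_onset: dict[str, int | None]
    config: SimConfig

    @property
    def final(self) -> StrandClassState:
        return self.states[-1]


def run(config: SimConfig) -> SimResult:
    """Run the Two-Rounds-Mode recursion and report onset cycles.

    ``adapter_template_onset``: first cycle at whose *end* full (adapter-
    flanked) strands exist — the cycle in which templates for the adapters
    are first synthesized. ``full_amplification_onset``: first cycle at
    whose *start* full templates are available for full-length annealing,
    i.e. onset + 1. With any efficiency > 0 and at least one starting dsDNA
    these are cycles 2 and 3.
    """
    init = ClassCounts(
        genomic_plus=config.initial_copies, genomic_minus=config.initial_copies
    )
    state = StrandClassState(cycle=0, counts={l: init for l in config.loci})
    states = [state]
    eff = {l: config.locus_efficiency(l) for l in config.loci}
    for _ in range(config.first_cycles):
        state = step(state, "first", eff)
        states.append(state)
    for _ in range(config.second_cycles):
        state = step(state, "second", eff)
        states.append(state)
    adapter_onset: dict[str, int | None] = {}
    full_onset: dict[str, int | None] = {}
    for locus in config.loci:
        onset = next(
            (s.cycle for s in states if s.counts[locus].full_total > 0), None
        )
        adapter_onset[locus] = onset
        full_onset[locus] = None if onset is None else onset + 1
    return SimResult(states, adapter_onset, full_onset, config)


# ---------------------------------------------------------------------------
# exact per-molecule oracle


def _classify(strand: str, plus: str, minus: str, fwd: Oligo, rev: Oligo) -> str:
    if strand == plus:
        return "genomic_plus"
    if strand == minus:
        return "genomic_minus"
    if strand.startswith(fwd.sequence):
        return "full_plus" if strand.endswith(revcomp(rev.sequence)) else "half_f"
    if strand.startswith(rev.sequence):
        return "full_minus" if strand.endswith(revcomp(fwd.sequence)) else "half_r"
    raise ValueError(f"unclassifiable strand {strand[:30]}...")


def _prime_once(strand: str, primers: list[Oligo], full_length: bool) -> str | None:
    products = []
    for p in primers:
        probe = revcomp(p.sequence if full_length else p.core)
        n = strand.count(probe)
        if n > 1:
            raise ValueError(
                f"primer {p.name} binds {n} sites on one strand; toy locus is "
                f"not clean enough for lineage enumeration"
            )
        if n == 1:
            idx = strand.index(probe)
            products.append(p.sequence + revcomp(strand[:idx]))
    if len(products) > 1:
        raise ValueError("both primers bind one strand; ambiguous toy locus")
    return products[0] if products else None


def enumerate_lineages(
    template: str,
    forward: Oligo,
    reverse: Oligo,
    first_cycles: int,
    second_cycles: int = 0,
    max_cycles: int = 10,
) -> list[ClassCounts]:
    """Explicit molecule-by-molecule replay of the mechanism (efficiency 1).

    Every single strand is a sequence string. Each cycle, each strand
    templates at most one new strand: in first-round cycles a primer anneals
    wherever the reverse complement of its locus-specific 3' portion occurs;
    in second-round cycles the full adapter-primer must anneal full-length.
    Extension always runs to the template's 5' end. Products are classified
    into strand classes by inspecting their ends; the returned per-cycle
    counts must match the :func:`run` recursion exactly.

    Both primers must carry adapter tails, and the template must contain
    exactly one binding site per primer and no adapter-like sequence.
    Refuses more than ``max_cycles`` total cycles (2^n molecules).
    """
    total = first_cycles + second_cycles
    if total > max_cycles:
        raise ValueError(
            f"{total} cycles would enumerate ~2^{total} molecules; limit is "
            f"{max_cycles}"
        )
    if forward.tail_length == 0 or reverse.tail_length == 0:
        raise ValueError("lineage enumeration requires adapter-tailed primers")
    plus = template.upper()
    minus = revcomp(plus)
    if plus.count(forward.core) != 1 or plus.count(revcomp(reverse.core)) != 1:
        raise ValueError("template must contain exactly one site per primer")
    for tail in (forward.tail, reverse.tail):
        if tail in plus or revcomp(tail) in plus:
            raise ValueError("adapter tail sequence occurs in the template")
    molecules = [plus, minus]
    primers = [forward, reverse]

    def counts() -> ClassCounts:
        tally = dict.fromkeys(ALL_CLASSES, 0.0)
        for m in molecules:
            tally[_classify(m, plus, minus, forward, reverse)] += 1
        return ClassCounts(**tally)

    out = [counts()]
    for cyc in range(total):
        full_length = cyc >= first_cycles
        new = []
        for m in molecules:
            product = _prime_once(m, primers, full_length)
            if product is not None:
                new.append(product)
        molecules.extend(new)
        out.append(counts())
    return out
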