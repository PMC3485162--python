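"""Adapter-primer panels: construction, design-rule validation, and I/O.

A UM-PCR panel attaches two fixed 18-nt universal adapters to the 5' ends of
every locus's forward (adapter-F) and reverse (adapter-R) SSR primer. The
tailed chimeras ("adapter-primers") all melt near 70 °C regardless of the
spread of the underlying SSR primers, which is what makes the multiplex
universal. Validation enforces the published design rules:

* every adapter-primer Tm inside a window around 70 °C (default 69.5-74.5);
* no more than six consecutive complementary base pairs between any two
  oligos in the tube (including self-pairs and the bare adapters);
* no hairpin stem of 5+ bp;
* (informational) the SSR-portion Tm spread, flagged above 10 °C;
* (optional) rarity of the adapter sequences in a target genome — an adapter
  that occurs frequently in the genome behaves like a nonspecific primer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from statistics import median
from typing import Iterable, Mapping, TextIO

from Bio import SeqIO

from .seqcore import (
    ComplementarityHit,
    Oligo,
    TmParams,
    DEFAULT_TM_PARAMS,
    find_hairpins,
    longest_complementary_run,
    revcomp,
    tm_basic,
)

__all__ = [
    "LocusPrimerPair",
    "PrimerPanel",
    "RuleResult",
    "ValidationReport",
    "PanelError",
    "make_adapter_primer",
    "validate_panel",
    "adapter_genome_count",
    "GenomeCount",
    "balance_concentrations",
    "read_panel",
    "write_panel",
    "load_reference_oligos",
    "load_maize_panel",
    "UNIVERSAL_ADAPTER_F",
    "UNIVERSAL_ADAPTER_R",
    "COMMON_ADAPTER",
]

UNIVERSAL_ADAPTER_F = Oligo("universal adapter-F", "CTCGTAGACTGCGTACCA", role="adapter")
UNIVERSAL_ADAPTER_R = Oligo("universal adapter-R", "TACTCAGGACTCATCGTC", role="adapter")
COMMON_ADAPTER = Oligo("common adapter", "CCTTCCTTCCTTCCCCCC", role="adapter")


class PanelError(ValueError):
    """Structural problem with a primer panel (missing tails, empty, ...)."""


@dataclass
class LocusPrimerPair:
    """One SSR locus: forward/reverse primers and their optional adapter tails."""

    locus: str
    forward: Oligo
    reverse: Oligo
    forward_tail: Oligo | None = None
    reverse_tail: Oligo | None = None
    concentration_factor: float = 1.0

    def __post_init__(self):
        if self.concentration_factor < 0:
            raise ValueError("concentration_factor must be >= 0")
        for tail in (self.forward_tail, self.reverse_tail):
            if tail is not None and tail.role != "adapter":
                raise ValueError(f"tail {tail.name!r} must have role 'adapter'")

    @property
    def tailed(self) -> bool:
        return self.forward_tail is not None and self.reverse_tail is not None

    @property
    def tailed_forward(self) -> Oligo:
        if self.forward_tail is None:
            raise PanelError(f"locus {self.locus}: forward primer has no adapter tail")
        return make_adapter_primer(self.forward_tail, self.forward)

    @property
    def tailed_reverse(self) -> Oligo:
        if self.reverse_tail is None:
            raise PanelError(f"locus {self.locus}: reverse primer has no adapter tail")
        return make_adapter_primer(self.reverse_tail, self.reverse)


@dataclass
class PrimerPanel:
    """An ordered multiplex panel sharing a pair of adapters."""

    loci: list[LocusPrimerPair]
    adapter_f: Oligo = UNIVERSAL_ADAPTER_F
    adapter_r: Oligo = UNIVERSAL_ADAPTER_R
    name: str = "panel"

    def __post_init__(self):
        if not self.loci:
            raise PanelError("panel must contain at least one locus")
        labels = [lp.locus for lp in self.loci]
        if len(set(labels)) != len(labels):
            raise PanelError(f"duplicate locus labels in panel: {labels}")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [lp.locus for lp in self.loci]

    def attach_adapters(self) -> "PrimerPanel":
        """Return a copy with the panel adapters attached to every locus."""
        return PrimerPanel(
            loci=[
                LocusPrimerPair(
                    lp.locus, lp.forward, lp.reverse,
                    forward_tail=self.adapter_f, reverse_tail=self.adapter_r,
                    concentration_factor=lp.concentration_factor,
                )
                for lp in self.loci
            ],
            adapter_f=self.adapter_f,
            adapter_r=self.adapter_r,
            name=self.name,
        )

    def with_factors(self, factors: Mapping[str, float]) -> "PrimerPanel":
        """Return a copy with per-locus concentration factors replaced."""
        return PrimerPanel(
            loci=[
                LocusPrimerPair(
                    lp.locus, lp.forward, lp.reverse,
                    forward_tail=lp.forward_tail, reverse_tail=lp.reverse_tail,
                    concentration_factor=float(factors.get(lp.locus, lp.concentration_factor)),
                )
                for lp in self.loci
            ],
            adapter_f=self.adapter_f,
            adapter_r=self.adapter_r,
            name=self.name,
        )


def make_adapter_primer(tail: Oligo, primer: Oligo) -> Oligo:
    """Link an adapter to the 5' end of an SSR primer.

    The product is the 5'-tail+primer-3' concatenation with role
    ``adapter_primer``; its name is ``"<tail prefix>-<primer name>"`` where
    the prefix is ``U`` for the universal adapters, ``C`` for the common one.
    """
    if tail.role != "adapter":
        raise ValueError(f"tail {tail.name!r} must have role 'adapter'")
    prefix = "C" if tail.sequence == COMMON_ADAPTER.sequence else "U"
    return Oligo(
        name=f"{prefix}-{primer.name}",
        sequence=tail.sequence + primer.sequence,
        role="adapter_primer",
        tail_length=len(tail),
    )


# ---------------------------------------------------------------------------
# validation


@dataclass
class RuleResult:
    rule: str
    passed: bool
    informational: bool = False
    measured: object = None
    offenders: list = field(default_factory=list)
    detail: str = ""


@dataclass
class ValidationReport:
    panel_name: str
    rules: list[RuleResult]

    @property
    def passed(self) -> bool:
        """True when every non-informational rule passed."""
        return all(r.passed for r in self.rules if not r.informational)

    def rule(self, rule_id: str) -> RuleResult:
        for r in self.rules:
            if r.rule == rule_id:
                return r
        raise KeyError(rule_id)

    def to_json(self) -> str:
        return json.dumps(
            {
                "panel": self.panel_name,
                "passed": self.passed,
                "rules": [
                    {
                        "rule": r.rule,
                        "passed": r.passed,
                        "informational": r.informational,
                        "measured": r.measured,
                        "offenders": r.offenders,
                        "detail": r.detail,
                    }
                    for r in self.rules
                ],
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [f"Panel {self.panel_name}: {'PASS' if self.passed else 'FAIL'}"]
        for r in self.rules:
            status = "info" if r.informational else ("pass" if r.passed else "FAIL")
            lines.append(f"  [{status}] {r.rule}: {r.detail}")
            for off in r.offenders:
                lines.append(f"        - {off}")
        return "\n".join(lines)


def validate_panel(
    panel: PrimerPanel,
    tm_window: tuple[float, float] = (69.5, 74.5),
    max_run: int = 6,
    max_hairpin_stem: int = 5,
    min_hairpin_loop: int = 3,
    max_ssr_tm_spread: float = 10.0,
    tm_params: TmParams = DEFAULT_TM_PARAMS,
    genome: str | Path | None = None,
    rarity_per_mb: float = 1.0,
) -> ValidationReport:
    """Check a tailed panel against the UM-PCR design rules.

    Rules ``tm_window``, ``max_complementary_run`` and ``hairpin_stem`` are
    pass/fail; ``ssr_tm_spread`` is informational (a wide spread of the bare
    SSR primers is precisely the situation the adapters are meant to rescue);
    ``adapter_rarity`` is evaluated only when a ``genome`` FASTA is supplied
    and is informational (no published numeric threshold exists).

    Raises :class:`PanelError` if any locus lacks adapter tails.
    """
    untailed = [lp.locus for lp in panel if not lp.tailed]
    if untailed:
        raise PanelError(
            f"panel {panel.name!r}: loci without adapter tails: {untailed}; "
            f"attach adapters before validation (PrimerPanel.attach_adapters)"
        )

    tailed: list[Oligo] = []
    for lp in panel:
        tailed.extend([lp.tailed_forward, lp.tailed_reverse])
    oligos = sorted(tailed + [panel.adapter_f, panel.adapter_r], key=lambda o: o.name)

    rules: list[RuleResult] = []

    # (a) adapter-primer Tm window
    lo, hi = tm_window
    tms = {o.name: tm_basic(o, tm_params) for o in tailed}
    out = [(n, t) for n, t in sorted(tms.items()) if not lo <= t <= hi]
    rules.append(
        RuleResult(
            rule="tm_window",
            passed=not out,
            measured={"min": min(tms.values()), "max": max(tms.values())},
            offenders=[f"{n} Tm={t:.2f} outside [{lo}, {hi}]" for n, t in out],
            detail=f"adapter-primer Tm range [{min(tms.values()):.2f}, "
                   f"{max(tms.values()):.2f}] vs window [{lo}, {hi}]",
        )
    )

    # (b) longest complementary run over every unordered pair incl. self-pairs
    worst = 0
    run_offenders = []
    for i, a in enumerate(oligos):
        for b in oligos[i:]:
            hit = longest_complementary_run(a, b)
            worst = max(worst, hit.length)
            if hit.length > max_run:
                run_offenders.append(f"{a.name} x {b.name}: run {hit.length}")
    rules.append(
        RuleResult(
            rule="max_complementary_run",
            passed=not run_offenders,
            measured=worst,
            offenders=run_offenders,
            detail=f"maximal complementary run {worst} (limit {max_run})",
        )
    )

    # (c) hairpins
    hp_offenders = []
    for o in oligos:
        for h in find_hairpins(o, min_stem=max_hairpin_stem, min_loop=min_hairpin_loop):
            hp_offenders.append(
                f"{o.name}: stem {h.length} at {h.pos_a}/{h.pos_b} loop {h.loop_length}"
            )
    rules.append(
        RuleResult(
            rule="hairpin_stem",
            passed=not hp_offenders,
            measured=len(hp_offenders),
            offenders=hp_offenders,
            detail=f"{len(hp_offenders)} hairpin stems >= {max_hairpin_stem} bp "
                   f"(loop >= {min_hairpin_loop})",
        )
    )

    # (d) informational: SSR-portion Tm spread
    ssr_tms = []
    for lp in panel:
        ssr_tms.extend([tm_basic(lp.forward, tm_params), tm_basic(lp.reverse, tm_params)])
    spread = max(ssr_tms) - min(ssr_tms)
    rules.append(
        RuleResult(
            rule="ssr_tm_spread",
            passed=spread <= max_ssr_tm_spread,
            informational=True,
            measured=spread,
            detail=f"SSR-portion Tm spread {spread:.2f} °C "
                   f"(flagged above {max_ssr_tm_spread})",
        )
    )

    # (e) optional: adapter rarity in a genome
    if genome is not None:
        rarity = []
        total_bp = 0
        counts = {}
        for ad in (panel.adapter_f, panel.adapter_r):
            gc = adapter_genome_count(ad, genome)
            counts[ad.name] = gc.total
            total_bp = gc.genome_length
        per_mb = {
            n: (c / total_bp * 1e6 if total_bp else 0.0) for n, c in counts.items()
        }
        frequent = [f"{n}: {c} hits ({per_mb[n]:.2f}/Mb)"
                    for n, c in counts.items() if per_mb[n] >= rarity_per_mb]
        rules.append(
            RuleResult(
                rule="adapter_rarity",
                passed=not frequent,
                informational=True,
                measured=counts,
                offenders=frequent,
                detail=f"adapter occurrences in genome ({total_bp} bp): {counts}",
            )
        )

    return ValidationReport(panel_name=panel.name, rules=rules)


# ---------------------------------------------------------------------------
# genome occurrence


@dataclass
class GenomeCount:
    total: int
    plus: int
    minus: int
    per_record: dict[str, int]
    genome_length: int


def _count_overlapping(text: str, pattern: str) -> int:
    count = start = 0
    while True:
        idx = text.find(pattern, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def adapter_genome_count(adapter: Oligo | str, genome: str | Path | TextIO) -> GenomeCount:
    """Count exact, overlapping occurrences of an adapter on both genome strands.

    ``genome`` is a (multi-)FASTA path or handle. Matches of the adapter and
    of its reverse complement are both counted on the plus-strand text, which
    equals the two-strand occurrence count. An empty genome yields zero.
    """
    seq = adapter.sequence if isinstance(adapter, Oligo) else adapter.upper()
    if len(seq) < 8:
        raise ValueError("adapter must be at least 8 nt for occurrence counting")
    rc = revcomp(seq)
    per_record: dict[str, int] = {}
    plus = minus = glen = 0
    for rec in SeqIO.parse(str(genome) if isinstance(genome, (str, Path)) else genome, "fasta"):
        text = str(rec.seq).upper()
        glen += len(text)
        p = _count_overlapping(text, seq)
        m = _count_overlapping(text, rc)
        per_record[rec.id] = p + m
        plus += p
        minus += m
    return GenomeCount(
        total=plus + minus, plus=plus, minus=minus,
        per_record=per_record, genome_length=glen,
    )


def balance_concentrations(yields: Mapping[str, float]) -> dict[str, float]:
    """Primer concentration factors that equalize per-locus band intensity.

    ``factor(locus) = median(yields) / yield(locus)``: the median locus keeps
    factor 1.0 and weak loci get proportionally more primer. A locus that
    amplifies at half the median intensity gets its primer amount doubled —
    the adjustment that equalized the weakest locus in the published panel.
    """
    if not yields:
        raise ValueError("yields must be non-empty")
    bad = {k: v for k, v in yields.items() if not v > 0}
    if bad:
        raise ValueError(f"yields must be strictly positive, got {bad}")
    med = median(yields.values())
    return {locus: med / y for locus, y in yields.items()}


# ---------------------------------------------------------------------------
# I/O and bundled reference panel


def read_panel(source: str | Path | TextIO, name: str | None = None,
               attach: bool = True) -> PrimerPanel:
    """Read a panel TSV.

    Dialect: UTF-8; ``#`` starts a comment; ``#@ key = value`` lines declare
    the panel adapters (``adapter_f``, ``adapter_r``); the header row is
    ``locus<TAB>forward<TAB>reverse[<TAB>conc_factor]``. When adapters are
    declared and ``attach`` is true, tails are attached to every locus.
    """
    close = False
    if isinstance(source, (str, Path)):
        fh = open(source, encoding="utf-8")
        close = True
        if name is None:
            name = Path(source).stem
    else:
        fh = source
    config: dict[str, str] = {}
    rows: list[list[str]] = []
    header: list[str] | None = None
    try:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if line.startswith("#@"):
                key, _, value = line[2:].partition("=")
                config[key.strip()] = value.strip()
                continue
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                if header[:3] != ["locus", "forward", "reverse"]:
                    raise PanelError(
                        f"line {lineno}: expected header 'locus forward reverse "
                        f"[conc_factor]', got {line!r}"
                    )
                continue
            rows.append(fields)
    finally:
        if close:
            fh.close()
    if header is None or not rows:
        raise PanelError("panel file contains no loci")
    adapter_f = Oligo("universal adapter-F", config["adapter_f"], role="adapter") \
        if "adapter_f" in config else UNIVERSAL_ADAPTER_F
    adapter_r = Oligo("universal adapter-R", config["adapter_r"], role="adapter") \
        if "adapter_r" in config else UNIVERSAL_ADAPTER_R
    loci = []
    for fields in rows:
        locus, fwd, rev = fields[0].strip(), fields[1].strip(), fields[2].strip()
        factor = float(fields[3]) if len(fields) > 3 and fields[3].strip() else 1.0
        loci.append(
            LocusPrimerPair(
                locus,
                Oligo(f"{locus}-F", fwd, role="ssr_primer"),
                Oligo(f"{locus}-R", rev, role="ssr_primer"),
                concentration_factor=factor,
            )
        )
    pan = PrimerPanel(loci, adapter_f=adapter_f, adapter_r=adapter_r,
                      name=name or "panel")
    return pan.attach_adapters() if attach else pan


def write_panel(panel: PrimerPanel, dest: str | Path | TextIO) -> None:
    """Write a panel in the TSV dialect of :func:`read_panel`."""
    close = False
    if isinstance(dest, (str, Path)):
        fh = open(dest, "w", encoding="utf-8")
        close = True
    else:
        fh = dest
    try:
        fh.write(f"#@ adapter_f = {panel.adapter_f.sequence}\n")
        fh.write(f"#@ adapter_r = {panel.adapter_r.sequence}\n")
        fh.write("locus\tforward\treverse\tconc_factor\n")
        for lp in panel:
            fh.write(
                f"{lp.locus}\t{lp.forward.sequence}\t{lp.reverse.sequence}\t"
                f"{lp.concentration_factor:g}\n"
            )
    finally:
        if close:
            fh.close()


def _data_path(filename: str) -> Path:
    return Path(resources.files("umpcr").joinpath("data", filename))


def load_reference_oligos() -> "pandas.DataFrame":
    """The bundled published panel as a DataFrame.

    Columns: ``name``, ``role``, ``tail_length``, ``sequence``,
    ``tm_reported`` (°C, as published) and ``formula_concordant`` (1 where the
    published value equals the calibrated formula; three published values are
    internally inconsistent with their sequences and are flagged 0).
    """
    import pandas as pd

    return pd.read_csv(_data_path("reference_oligos.tsv"), sep="\t", comment="#")


def load_maize_panel(loci: Iterable[str] | None = None,
                     adapters: str = "universal") -> PrimerPanel:
    """The bundled maize SSR panel with adapters attached.

    By default returns the five-locus quintuple panel (phi085, phi041,
    phi123, umc1478, umc1268) with the universal adapters and the published
    concentration factors (phi085 doubled). ``loci`` selects/orders loci
    (``"all"``-style selection by passing the six names); ``adapters`` may be
    ``"universal"`` or ``"common"``.
    """
    pan = read_panel(_data_path("maize_ssr_panel.tsv"), name="maize-ssr", attach=False)
    if loci is None:
        loci = ["phi085", "phi041", "phi123", "umc1478", "umc1268"]
    index = {lp.locus: lp for lp in pan}
    missing = [l for l in loci if l not in index]
    if missing:
        raise PanelError(f"unknown loci {missing}; available: {sorted(index)}")
    if adapters == "universal":
        af, ar = UNIVERSAL_ADAPTER_F, UNIVERSAL_ADAPTER_R
    elif adapters == "common":
        af = ar = COMMON_ADAPTER
    else:
        raise ValueError("adapters must be 'universal' or 'common'")
    sub = PrimerPanel([index[l] for l in loci], adapter_f=af, adapter_r=ar,
                      name=f"maize-ssr-{adapters[0].upper()}")
    return sub.attach_adapters()
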