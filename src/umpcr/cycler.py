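"""Two-Rounds-Mode thermal program generation and serialization.

The UM-PCR thermal program has two rounds. The first round ("One by One
Annealing Round", 3 cycles) gives each locus its own 20 s annealing step at
the mean Tm of its forward/reverse SSR portions, so every specific primer
gets a chance to prime its genomic target; steps within a cycle run in
descending temperature by default so that low-temperature steps cannot
enable mispriming before high-Tm primers have annealed (this is what
distinguishes the mode from touchdown PCR, which ramps across cycles).
The second round (28-32 cycles, usually 30) combines annealing and extension
in a single 70 °C/50 s step: by then every target is flanked by the adapter
sequences, and only full-length adapter-primer annealing is stable at 70 °C.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

from .panel import PrimerPanel
from .seqcore import TmParams, DEFAULT_TM_PARAMS, tm_basic

__all__ = [
    "ThermalStep",
    "ThermalProgram",
    "build_program",
    "serialize_program",
    "parse_program",
    "locus_annealing_temperature",
]

_LABELS = ("denature", "anneal", "extend", "anneal_extend", "init_denature",
           "final_extend")


@dataclass(frozen=True)
class ThermalStep:
    temperature: float  # °C
    duration: float     # seconds
    label: str
    locus: str | None = None

    def __post_init__(self):
        if not 0 <= self.temperature <= 100:
            raise ValueError(f"temperature {self.temperature} outside [0, 100] °C")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS}")


@dataclass
class ThermalProgram:
    init: ThermalStep
    round1: list[list[ThermalStep]]
    round2: list[list[ThermalStep]]
    final: ThermalStep
    metadata: dict = field(default_factory=dict)

    def steps(self) -> list[ThermalStep]:
        """All steps in execution order."""
        out = [self.init]
        for cyc in self.round1:
            out.extend(cyc)
        for cyc in self.round2:
            out.extend(cyc)
        out.append(self.final)
        return out

    @property
    def total_duration(self) -> float:
        """Program duration in seconds (sum of step durations; no ramps)."""
        return sum(s.duration for s in self.steps())


def locus_annealing_temperature(
    lp, anneal_offset: float = 0.0, tm_params: TmParams = DEFAULT_TM_PARAMS
) -> float:
    """First-round annealing temperature for one locus.

    Mean of the forward and reverse SSR-portion Tm minus ``anneal_offset``.
    Only the locus-specific 3' portion anneals to genomic DNA in the first
    round, so the tail is excluded from the Tm.
    """
    return round(
        (tm_basic(lp.forward, tm_params) + tm_basic(lp.reverse, tm_params)) / 2
        - anneal_offset,
        2,
    )


def build_program(
    panel: PrimerPanel,
    first_cycles: int = 3,
    second_cycles: int = 30,
    second_anneal_temp: float = 70.0,
    second_anneal_time: float = 50.0,
    anneal_offset: float = 0.0,
    order: str = "desc",
    init_temp: float = 94.0,
    init_time: float = 300.0,
    denature_temp: float = 94.0,
    denature_time: float = 40.0,
    anneal_time: float = 20.0,
    extend_temp: float = 72.0,
    extend_time: float = 30.0,
    final_temp: float = 72.0,
    final_time: float = 600.0,
    tm_params: TmParams = DEFAULT_TM_PARAMS,
) -> ThermalProgram:
    """Generate the Two-Rounds-Mode program for a panel.

    Defaults reproduce the published procedure: 94 °C/5 min initial
    denaturation; 3 first-round cycles of [94 °C/40 s, one 20 s annealing
    step per locus, 72 °C/30 s]; 30 second-round cycles of
    [94 °C/40 s, 70 °C/50 s]; 72 °C/10 min final extension.

    ``order`` controls the within-cycle arrangement of the per-locus
    annealing steps: ``desc`` (default) and ``asc`` sort by temperature,
    ``panel`` preserves panel order. A ``second_cycles`` outside [28, 32]
    triggers a warning (the established working range), not an error.
    """
    if first_cycles < 1 or second_cycles < 0:
        raise ValueError("first_cycles must be >= 1 and second_cycles >= 0")
    if order not in ("desc", "asc", "panel"):
        raise ValueError("order must be one of 'desc', 'asc', 'panel'")
    if second_cycles and not 28 <= second_cycles <= 32:
        warnings.warn(
            f"second_cycles={second_cycles} outside the usual 28-32 range",
            stacklevel=2,
        )

    anneal_steps = [
        ThermalStep(
            locus_annealing_temperature(lp, anneal_offset, tm_params),
            anneal_time, "anneal", locus=lp.locus,
        )
        for lp in panel
    ]
    if order == "desc":
        anneal_steps.sort(key=lambda s: (-s.temperature, s.locus))
    elif order == "asc":
        anneal_steps.sort(key=lambda s: (s.temperature, s.locus))

    cycle1 = (
        [ThermalStep(denature_temp, denature_time, "denature")]
        + anneal_steps
        + [ThermalStep(extend_temp, extend_time, "extend")]
    )
    cycle2 = [
        ThermalStep(denature_temp, denature_time, "denature"),
        ThermalStep(second_anneal_temp, second_anneal_time, "anneal_extend"),
    ]
    return ThermalProgram(
        init=ThermalStep(init_temp, init_time, "init_denature"),
        round1=[list(cycle1) for _ in range(first_cycles)],
        round2=[list(cycle2) for _ in range(second_cycles)],
        final=ThermalStep(final_temp, final_time, "final_extend"),
        metadata={
            "panel": panel.name,
            "loci": panel.locus_names,
            "first_cycles": first_cycles,
            "second_cycles": second_cycles,
            "anneal_offset": anneal_offset,
            "order": order,
        },
    )


def _step_dict(s: ThermalStep) -> dict:
    d = {"temperature": s.temperature, "duration": s.duration, "label": s.label}
    if s.locus is not None:
        d["locus"] = s.locus
    return d


def serialize_program(program: ThermalProgram, format: str = "json") -> str:
    """Serialize a program as lossless JSON or a human-readable block table."""
    if format == "json":
        return json.dumps(
            {
                "init": _step_dict(program.init),
                "round1": [[_step_dict(s) for s in c] for c in program.round1],
                "round2": [[_step_dict(s) for s in c] for c in program.round2],
                "final": _step_dict(program.final),
                "metadata": program.metadata,
            },
            indent=2,
        )
    if format == "text":
        def fmt_time(sec: float) -> str:
            return f"{sec / 60:g} min" if sec >= 60 else f"{sec:g}s"

        def fmt_step(s: ThermalStep) -> str:
            who = f"  ({s.locus})" if s.locus else ""
            return f"  {s.temperature:g} °C\t{fmt_time(s.duration)}\t{s.label}{who}"

        lines = [f"# Two Rounds Mode program — panel {program.metadata.get('panel', '?')}"]
        lines.append("initial denaturation:")
        lines.append(fmt_step(program.init))
        lines.append(f"first round — One by One Annealing ({len(program.round1)} cycles):")
        for n, cyc in enumerate(program.round1, 1):
            lines.append(f" cycle {n}:")
            lines.extend(fmt_step(s) for s in cyc)
        lines.append(f"second round ({len(program.round2)} cycles):")
        for n, cyc in enumerate(program.round2, 1):
            lines.append(f" cycle {n}:")
            lines.extend(fmt_step(s) for s in cyc)
        lines.append("final extension:")
        lines.append(fmt_step(program.final))
        return "\n".join(lines)
    raise ValueError(f"unknown format {format!r}; use 'json' or 'text'")


def _parse_step(d: dict) -> ThermalStep:
    return ThermalStep(d["temperature"], d["duration"], d["label"], d.get("locus"))


def parse_program(document: str) -> ThermalProgram:
    """Inverse of :func:`serialize_program` for the JSON format."""
    obj = json.loads(document)
    return ThermalProgram(
        init=_parse_step(obj["init"]),
        round1=[[_parse_step(s) for s in c] for c in obj["round1"]],
        round2=[[_parse_step(s) for s in c] for c in obj["round2"]],
        final=_parse_step(obj["final"]),
        metadata=obj.get("metadata", {}),
    )
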