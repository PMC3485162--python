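"""Codominant SSR seed classification and genetic-purity statistics.

A hybrid seed lot contains, besides true F1 hybrids, selfed female-parent
seeds and off-type contaminants. Because SSR markers are codominant, an F1
shows the union of both parents' bands at every locus, a selfed parental
seed shows only that parent's bands, and an off-type shows at least one
allele foreign to both parents. Genetic purity is the percentage of seeds
typing as the declared hybrid: 192 hybrids among 200 seeds is 96.0 %.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from .vpcr import BandPattern

__all__ = [
    "ReferenceProfiles",
    "SeedCall",
    "PurityReport",
    "classify_seed",
    "purity",
    "make_seed_lot",
    "read_band_patterns",
    "write_band_patterns",
    "read_reference_profiles",
    "SEED_CLASSES",
]

SEED_CLASSES = ("hybrid", "female_parent", "male_parent", "off_type")


@dataclass(frozen=True)
class ReferenceProfiles:
    """Per-locus allele sizes (bp) of the two parents of the declared hybrid."""

    female: dict[str, frozenset[int]]
    male: dict[str, frozenset[int]]

    def __post_init__(self):
        if set(self.female) != set(self.male):
            raise ValueError(
                "female and male profiles must cover the same loci; "
                f"difference: {set(self.female) ^ set(self.male)}"
            )
        object.__setattr__(
            self, "female", {k: frozenset(v) for k, v in self.female.items()}
        )
        object.__setattr__(
            self, "male", {k: frozenset(v) for k, v in self.male.items()}
        )
        for parent in (self.female, self.male):
            for locus, alleles in parent.items():
                if not alleles or any(a <= 0 for a in alleles):
                    raise ValueError(f"locus {locus}: allele sizes must be positive")

    @property
    def loci(self) -> list[str]:
        return sorted(self.female)

    def hybrid_expected(self, locus: str) -> frozenset[int]:
        """Expected F1 pattern: union of the parental allele sets."""
        return self.female[locus] | self.male[locus]


@dataclass
class SeedCall:
    seed: str
    seed_class: str
    evidence: dict[str, dict] = field(default_factory=dict)


@dataclass
class PurityReport:
    n_total: int
    n_hybrid: int
    n_female: int
    n_male: int
    n_off_type: int

    def __post_init__(self):
        if self.n_hybrid + self.n_female + self.n_male + self.n_off_type != self.n_total:
            raise ValueError("class counts must sum to n_total")

    @property
    def purity_percent(self) -> float:
        """Percent of seeds typing as the declared hybrid, to 1 decimal."""
        return round(100.0 * self.n_hybrid / self.n_total, 1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_total": self.n_total,
                "n_hybrid": self.n_hybrid,
                "n_female_parent": self.n_female,
                "n_male_parent": self.n_male,
                "n_off_type": self.n_off_type,
                "purity_percent": self.purity_percent,
            },
            indent=2,
        )

    def to_text(self) -> str:
        return (
            f"seeds: {self.n_total}\n"
            f"  hybrid:        {self.n_hybrid}\n"
            f"  female parent: {self.n_female}\n"
            f"  male parent:   {self.n_male}\n"
            f"  off-type:      {self.n_off_type}\n"
            f"genetic purity: {self.purity_percent}%"
        )


def _match(observed: frozenset[int], expected: frozenset[int], tol: int) -> bool:
    if tol == 0:
        return observed == expected
    # sizing tolerance: every observed band within tol of an expected one and
    # every expected band hit by an observed one
    return all(any(abs(o - e) <= tol for e in expected) for o in observed) and all(
        any(abs(o - e) <= tol for o in observed) for e in expected
    )


def _subset(observed: frozenset[int], expected: frozenset[int], tol: int) -> bool:
    if tol == 0:
        return observed <= expected
    return all(any(abs(o - e) <= tol for e in expected) for o in observed)


def classify_seed(
    profile: BandPattern,
    refs: ReferenceProfiles,
    missing_policy: str = "strict",
    size_tolerance: int = 0,
) -> SeedCall:
    """Classify one seed's band pattern against the parental references.

    Rule order (codominant logic):

    1. **hybrid** — observed equals the parental union at every locus;
    2. **female_parent** — observed within the female allele set everywhere
       and equal to it at every informative locus (where the parents differ);
    3. **male_parent** — symmetric;
    4. **off_type** — anything else (an allele foreign to both parents, or a
       mixed-but-incomplete pattern).

    A locus with no bands is off-type evidence under ``missing_policy
    "strict"``; ``"ignore_locus"`` drops it from consideration.
    ``size_tolerance`` (bp) loosens band-size comparison for gel sizing noise.
    """
    if missing_policy not in ("strict", "ignore_locus"):
        raise ValueError("missing_policy must be 'strict' or 'ignore_locus'")
    unknown = [l for l in profile.bands if l not in refs.female]
    if unknown:
        raise KeyError(f"profile contains loci absent from references: {unknown}")

    evidence: dict[str, dict] = {}
    considered: list[str] = []
    blank_strict = False
    for locus in refs.loci:
        observed = frozenset(profile.sizes(locus))
        expected = refs.hybrid_expected(locus)
        evidence[locus] = {
            "observed": sorted(observed),
            "expected_hybrid": sorted(expected),
            "female": sorted(refs.female[locus]),
            "male": sorted(refs.male[locus]),
        }
        if not observed:
            if missing_policy == "strict":
                blank_strict = True
            continue  # ignore_locus: drop from consideration
        considered.append(locus)

    def verdict() -> str:
        if blank_strict or not considered:
            return "off_type"
        tol = size_tolerance
        if all(
            _match(frozenset(profile.sizes(l)), refs.hybrid_expected(l), tol)
            for l in considered
        ):
            return "hybrid"
        for parent_name, parent, other in (
            ("female_parent", refs.female, refs.male),
            ("male_parent", refs.male, refs.female),
        ):
            ok = True
            for l in considered:
                obs = frozenset(profile.sizes(l))
                informative = parent[l] != refs.hybrid_expected(l)
                if informative:
                    if not _match(obs, parent[l], tol):
                        ok = False
                        break
                elif not _subset(obs, parent[l], tol):
                    ok = False
                    break
            if ok:
                return parent_name
        return "off_type"

    cls = verdict()
    for locus in refs.loci:
        evidence[locus]["verdict"] = cls
    return SeedCall(seed=profile.sample, seed_class=cls, evidence=evidence)


def purity(calls: Sequence[SeedCall]) -> PurityReport:
    """Aggregate seed calls into a purity report (percent hybrids)."""
    if not calls:
        raise ValueError("purity requires at least one seed call")
    tally = dict.fromkeys(SEED_CLASSES, 0)
    for c in calls:
        if c.seed_class not in tally:
            raise ValueError(f"unknown seed class {c.seed_class!r}")
        tally[c.seed_class] += 1
    return PurityReport(
        n_total=len(calls),
        n_hybrid=tally["hybrid"],
        n_female=tally["female_parent"],
        n_male=tally["male_parent"],
        n_off_type=tally["off_type"],
    )


def default_reference_profiles(loci: Sequence[str],
                               base: int = 120, locus_step: int = 20,
                               allele_gap: int = 8) -> ReferenceProfiles:
    """Deterministic synthetic parental profiles for a list of loci.

    Models two homozygous inbred parents: one allele per parent per locus,
    the male allele ``allele_gap`` bp above the female one, loci staggered by
    ``locus_step`` bp. Depends only on locus order, so repeated runs agree.
    """
    female = {}
    male = {}
    for i, locus in enumerate(loci):
        a = base + locus_step * i
        female[locus] = frozenset({a})
        male[locus] = frozenset({a + allele_gap})
    return ReferenceProfiles(female=female, male=male)


# ---------------------------------------------------------------------------
# synthetic seed lots


def _apportion(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n seeds over classes."""
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {total}")
    raw = {k: n * p for k, p in proportions.items()}
    counts = {k: int(v) for k, v in raw.items()}
    leftovers = sorted(raw, key=lambda k: (counts[k] - raw[k], k))
    for k in leftovers[: n - sum(counts.values())]:
        counts[k] += 1
    return counts


def make_seed_lot(
    n: int,
    proportions: Mapping[str, float],
    refs: ReferenceProfiles,
    dropout_rate: float = 0.0,
    offtype_allele_shift: int = 4,
    seed: int = 0,
) -> tuple[list[BandPattern], list[str]]:
    """Generate a synthetic seed lot with known class composition.

    Class counts are apportioned deterministically from ``proportions``
    (largest remainder), so e.g. 96 % hybrids of n=200 yields exactly 192;
    seed order is then shuffled by the seeded RNG. Hybrid seeds carry the
    parental-union pattern, parental seeds their parent's pattern; each
    off-type seed gets 1-2 loci where one allele is shifted by
    ``offtype_allele_shift`` bp (re-shifted until foreign to both parents).
    ``dropout_rate`` blanks one band per affected locus at random; the
    per-locus uniform draws are made for every seed regardless of rate, so a
    larger rate strictly nests the dropouts of a smaller one under the same
    RNG seed. Returns band patterns and true labels, index-aligned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    unknown = set(proportions) - set(SEED_CLASSES)
    if unknown:
        raise ValueError(f"unknown seed classes {unknown}")
    rng = np.random.default_rng(seed)
    counts = _apportion(n, proportions)
    labels = [cls for cls in SEED_CLASSES for _ in range(counts.get(cls, 0))]
    rng.shuffle(labels)
    loci = refs.loci
    patterns: list[BandPattern] = []
    for i, label in enumerate(labels):
        bands: dict[str, list[int]] = {}
        for locus in loci:
            if label == "hybrid":
                alleles = set(refs.hybrid_expected(locus))
            elif label == "female_parent":
                alleles = set(refs.female[locus])
            elif label == "male_parent":
                alleles = set(refs.male[locus])
            else:
                alleles = set(refs.hybrid_expected(locus))
            bands[locus] = sorted(alleles)
        if label == "off_type":
            k = int(rng.integers(1, min(2, len(loci)) + 1))
            which = rng.choice(len(loci), size=k, replace=False)
            for idx in which:
                locus = loci[int(idx)]
                alleles = set(bands[locus])
                victim = sorted(alleles)[int(rng.integers(0, len(alleles)))]
                forbidden = refs.hybrid_expected(locus)
                shifted = victim + offtype_allele_shift
                while shifted in forbidden:
                    shifted += offtype_allele_shift
                alleles.discard(victim)
                alleles.add(shifted)
                bands[locus] = sorted(alleles)
        # dropout draws happen for every locus so rates nest deterministically
        for locus in loci:
            u = rng.random()
            drop = int(rng.integers(0, max(1, len(bands[locus]))))
            if u < dropout_rate and bands[locus]:
                bands[locus] = bands[locus][:drop] + bands[locus][drop + 1:]
        patterns.append(BandPattern(sample=f"seed{i + 1:04d}", bands=bands))
    return patterns, labels


# ---------------------------------------------------------------------------
# I/O


def write_band_patterns(patterns: Iterable[BandPattern],
                        dest: str | Path | TextIO) -> None:
    """Write patterns as TSV: ``sample<TAB>locus<TAB>comma-separated sizes``."""
    close = False
    if isinstance(dest, (str, Path)):
        fh = open(dest, "w", encoding="utf-8")
        close = True
    else:
        fh = dest
    try:
        fh.write("sample\tlocus\tsizes\n")
        for p in patterns:
            for locus, sizes in p.bands.items():
                fh.write(f"{p.sample}\t{locus}\t{','.join(map(str, sizes))}\n")
    finally:
        if close:
            fh.close()


def read_band_patterns(source: str | Path | TextIO) -> list[BandPattern]:
    """Inverse of :func:`write_band_patterns`; empty size field = no bands."""
    close = False
    if isinstance(source, (str, Path)):
        fh = open(source, encoding="utf-8")
        close = True
    else:
        fh = source
    out: dict[str, BandPattern] = {}
    try:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "sample":
                continue
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected 3 tab-separated fields")
            sample, locus, sizes = fields[0], fields[1], fields[2].strip()
            pat = out.setdefault(sample, BandPattern(sample=sample, bands={}))
            pat.bands[locus] = (
                sorted(int(s) for s in sizes.split(",")) if sizes else []
            )
    finally:
        if close:
            fh.close()
    return list(out.values())


def read_reference_profiles(source: str | Path | TextIO) -> ReferenceProfiles:
    """Read parental profiles from JSON or TSV.

    JSON: ``{"female": {locus: [sizes]}, "male": {locus: [sizes]}}``.
    TSV: header ``parent<TAB>locus<TAB>sizes`` with comma-separated sizes.
    """
    close = False
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        obj = json.loads(text)
        return ReferenceProfiles(
            female={k: frozenset(v) for k, v in obj["female"].items()},
            male={k: frozenset(v) for k, v in obj["male"].items()},
        )
    female: dict[str, frozenset[int]] = {}
    male: dict[str, frozenset[int]] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#") or line.startswith("parent\t"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: expected 3 tab-separated fields")
        parent, locus, sizes = fields[0].strip(), fields[1].strip(), fields[2]
        alleles = frozenset(int(s) for s in sizes.split(","))
        if parent == "female":
            female[locus] = alleles
        elif parent == "male":
            male[locus] = alleles
        else:
            raise ValueError(f"line {lineno}: parent must be 'female' or 'male'")
    return ReferenceProfiles(female=female, male=male)
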