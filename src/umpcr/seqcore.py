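"""DNA sequence primitives for UM-PCR design.

Melting temperatures are computed with a salt-adjusted GC%/length formula,

    Tm = base + gc_coef * (%GC) - length_const / N,

the Marmur-Schildkraut-Doty form ``81.5 + 16.6*log10[Na+] + 0.41*%GC - 500/N``
with the salt term folded into a single calibrated base constant (62.30 °C).
Complementarity screening (cross-dimers, self-dimers, hairpins) uses a
perfect-stem run scan: only contiguous antiparallel Watson-Crick pairs
(A:T, G:C) count, with no wobbles, bulges or free-energy model. This matches
the design rule used for universal adapter-primers — no more than six
consecutive complementary base pairs between any two oligos in the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "Oligo",
    "TmParams",
    "ComplementarityHit",
    "InvalidAlphabetError",
    "OligoTooShortError",
    "revcomp",
    "gc_percent",
    "tm_basic",
    "longest_complementary_run",
    "find_hairpins",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Minimum oligo length accepted by :func:`tm_basic`; the -length_const/N term
#: degenerates for very short oligos.
MIN_TM_LENGTH = 8


class InvalidAlphabetError(ValueError):
    """A sequence contained a character outside {A, C, G, T}."""

    def __init__(self, sequence: str, position: int):
        self.position = position
        self.character = sequence[position]
        super().__init__(
            f"invalid character {self.character!r} at position {position} "
            f"(only A/C/G/T are accepted)"
        )


class OligoTooShortError(ValueError):
    """An oligo shorter than the minimum for Tm computation."""


def _canonical(seq: str) -> str:
    """Uppercase and validate a DNA string, raising on the first bad char."""
    if not isinstance(seq, str):
        raise TypeError(f"sequence must be str, got {type(seq).__name__}")
    s = seq.upper()
    for i, c in enumerate(s):
        if c not in "ACGT":
            raise InvalidAlphabetError(s, i)
    return s


@dataclass(frozen=True)
class Oligo:
    """A single-stranded DNA oligo, stored 5'→3'.

    Parameters
    ----------
    name:
        Label, e.g. ``"phi085-F"`` or ``"universal adapter-F"``.
    sequence:
        DNA over {A, C, G, T}; canonicalized to uppercase. ``U`` is rejected.
    role:
        One of ``adapter``, ``ssr_primer``, ``adapter_primer``.
    tail_length:
        For an ``adapter_primer``, the number of 5' bases contributed by the
        adapter tail (they do not hybridize genomic template); 0 otherwise.
    """

    name: str
    sequence: str
    role: str = "ssr_primer"
    tail_length: int = 0

    _ROLES = ("adapter", "ssr_primer", "adapter_primer")

    def __post_init__(self):
        object.__setattr__(self, "sequence", _canonical(self.sequence))
        if not self.sequence:
            raise ValueError("oligo sequence must be non-empty")
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}, got {self.role!r}")
        if not 0 <= self.tail_length <= len(self.sequence):
            raise ValueError("tail_length must lie within the sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def core(self) -> str:
        """The 3' locus-specific portion (sequence minus any adapter tail)."""
        return self.sequence[self.tail_length:]

    @property
    def tail(self) -> str:
        """The 5' adapter tail portion (empty for untailed oligos)."""
        return self.sequence[: self.tail_length]


@dataclass(frozen=True)
class TmParams:
    """Constants of the calibrated GC%/length melting-temperature formula."""

    base_constant: float = 62.30
    gc_coefficient: float = 0.41
    length_constant: float = 500.0
    report_decimals: int = 2

    def __post_init__(self):
        for name in ("base_constant", "gc_coefficient", "length_constant"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"{name} must be finite")
        if self.report_decimals < 0:
            raise ValueError("report_decimals must be >= 0")


DEFAULT_TM_PARAMS = TmParams()


@dataclass(frozen=True)
class ComplementarityHit:
    """A contiguous antiparallel Watson-Crick duplex between two oligo regions.

    ``pos_a``/``pos_b`` are 0-based start offsets of the paired run on each
    oligo as written 5'→3'. For hairpins both offsets are on the same oligo
    (``pos_a`` the 5' arm, ``pos_b`` the 3' arm) and ``loop_length`` is the
    number of unpaired bases between the arms.
    """

    length: int
    pos_a: int
    pos_b: int
    kind: str = "cross_dimer"
    loop_length: int | None = None


def revcomp(seq: str) -> str:
    """Return the reverse complement of ``seq``, 5'→3'."""
    return _canonical(seq).translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """GC content of ``seq`` in percent."""
    s = _canonical(seq)
    return 100.0 * sum(c in "GC" for c in s) / len(s)


def tm_basic(seq: str | Oligo, params: TmParams = DEFAULT_TM_PARAMS) -> float:
    """Melting temperature by the calibrated GC%/length formula, in °C.

    Computed in exact decimal arithmetic and rounded half-up to
    ``params.report_decimals`` — several published panel values fall on exact
    .xx5 ties that binary floating point would round the wrong way.

    Raises
    ------
    OligoTooShortError
        If the sequence is shorter than 8 nt (the formula degenerates).
    """
    s = seq.sequence if isinstance(seq, Oligo) else _canonical(seq)
    if not s:
        raise ValueError("empty sequence")
    n = len(s)
    if n < MIN_TM_LENGTH:
        raise OligoTooShortError(
            f"oligo of length {n} nt is below the minimum of {MIN_TM_LENGTH} nt "
            f"for Tm computation"
        )
    gc_count = sum(c in "GC" for c in s)
    tm = (
        Decimal(str(params.base_constant))
        + Decimal(str(params.gc_coefficient)) * (Decimal(100 * gc_count) / Decimal(n))
        - Decimal(str(params.length_constant)) / Decimal(n)
    )
    quantum = Decimal(1).scaleb(-params.report_decimals)
    return float(tm.quantize(quantum, rounding=ROUND_HALF_UP))


def _seq_of(x: str | Oligo) -> str:
    return x.sequence if isinstance(x, Oligo) else _canonical(x)


def longest_complementary_run(a: str | Oligo, b: str | Oligo) -> ComplementarityHit:
    """Maximal contiguous antiparallel duplex between any regions of a and b.

    Equivalent to the longest common substring of ``a`` and ``revcomp(b)``,
    with positions mapped back onto ``b`` as written 5'→3'. Ties are broken by
    smallest ``pos_a``, then smallest ``pos_b``. When not a single base pair
    can form, a hit of length 0 is returned.
    """
    sa, sb = _seq_of(a), _seq_of(b)
    kind = "self_dimer" if sa == sb else "cross_dimer"
    rb = revcomp(sb)
    n, m = len(sa), len(rb)
    best: tuple[int, int, int] | None = None  # (-length, pos_a, pos_b)
    # suffix-extension DP over (a, revcomp(b)); row-rolling keeps it O(n*m)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = sa[i - 1]
        for k in range(1, m + 1):
            if ai == rb[k - 1]:
                length = prev[k - 1] + 1
                cur[k] = length
                i0 = i - length           # start in a
                j0 = len(sb) - k          # start in b (5'->3' on b)
                key = (-length, i0, j0)
                if best is None or key < best:
                    best = key
        prev = cur
    if best is None:
        return ComplementarityHit(0, 0, 0, kind=kind)
    return ComplementarityHit(-best[0], best[1], best[2], kind=kind)


def find_hairpins(
    seq: str | Oligo, min_stem: int = 4, min_loop: int = 3
) -> list[ComplementarityHit]:
    """All maximal intramolecular perfect stems of length >= ``min_stem``.

    A stem pairs ``seq[i:i+L]`` antiparallel against ``seq[j:j+L]`` (i.e.
    ``seq[i:i+L] == revcomp(seq[j:j+L])``) with an unpaired loop of
    ``j - (i + L) >= min_loop`` nt between the arms. Stems are maximal along
    their pairing diagonal; a stem whose untrimmed run would pinch the loop
    below ``min_loop`` is trimmed inward and reported only if the trimmed
    stem still reaches ``min_stem``.

    Returns an empty list (never an error) when no qualifying stem exists.
    """
    if min_stem < 1:
        raise ValueError("min_stem must be >= 1")
    if min_loop < 0:
        raise ValueError("min_loop must be >= 0")
    s = _seq_of(seq)
    n = len(s)
    r = revcomp(s)
    hits: list[ComplementarityHit] = []
    # Diagonals of the (s, revcomp(s)) matching matrix; a maximal run on a
    # diagonal is a maximal perfect stem candidate.
    seen: set[tuple[int, int, int]] = set()
    for d in range(-(n - 1), n):
        i = max(0, d)
        k = max(0, -d)
        while i < n and k < n:
            if s[i] == r[k]:
                run = 0
                while i + run < n and k + run < n and s[i + run] == r[k + run]:
                    run += 1
                length, i0, k0 = run, i, k
                # map back: arm2 occupies s[j:j+L] with j = n - k0 - L
                j0 = n - k0 - length
                a, b = (i0, j0) if i0 <= j0 else (j0, i0)
                loop = b - (a + length)
                if loop < min_loop:
                    # trimming one inner pair lengthens the loop by 2
                    deficit = min_loop - loop
                    trim = (deficit + 1) // 2
                    length -= trim
                    loop += 2 * trim
                if length >= min_stem and b != a:
                    key = (a, a + length + loop, length)
                    if key not in seen:
                        seen.add(key)
                        hits.append(
                            ComplementarityHit(
                                length, a, a + length + loop,
                                kind="hairpin", loop_length=loop,
                            )
                        )
                i += run
                k += run
            else:
                i += 1
                k += 1
    hits.sort(key=lambda h: (h.pos_a, h.pos_b, -h.length))
    return hits
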