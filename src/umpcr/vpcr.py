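"""In-silico multiplex PCR: binding sites, amplicons, band patterns.

Coordinates are 0-based half-open on the plus strand throughout. A binding
site covers only the hybridized (locus-specific 3') portion of a primer; a
5' adapter tail does not hybridize genomic template and is recorded as
``tail_length``. Product length counts both primers at full length including
tails — which is why a product amplified with 18+18 nt tailed primers runs
exactly 36 bp above the plain-primer product of the same locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO

from .panel import PrimerPanel
from .seqcore import Oligo, revcomp

__all__ = [
    "BindingSite",
    "Amplicon",
    "BandPattern",
    "find_binding_sites",
    "predict_amplicons",
    "band_pattern",
    "load_templates",
]


@dataclass(frozen=True)
class BindingSite:
    record: str
    strand: str  # '+' or '-'
    start: int   # plus-strand coords of the hybridized portion
    end: int
    primer: Oligo
    mismatches: int = 0
    tail_length: int = 0


@dataclass(frozen=True)
class Amplicon:
    record: str
    locus: str
    forward_site: BindingSite
    reverse_site: BindingSite
    product_length: int
    sequence: str


@dataclass
class BandPattern:
    """Per-locus sorted, deduplicated product lengths for one sample."""

    sample: str
    bands: dict[str, list[int]] = field(default_factory=dict)

    def sizes(self, locus: str) -> list[int]:
        return self.bands.get(locus, [])


def _records(source) -> list[tuple[str, str]]:
    if isinstance(source, (list, tuple)):
        return [(rid, str(seq).upper()) for rid, seq in source]
    return [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(source) if isinstance(source, (str, Path)) else source, "fasta")
    ]


def load_templates(source: str | Path | TextIO) -> list[tuple[str, str]]:
    """Read a multi-FASTA of template sequences as (id, sequence) pairs.

    Multiple records are treated as independent haplotypes of one sample,
    which is how a diploid (heterozygous) individual is represented.
    """
    return _records(source)


def _matches(core: str, window: str, max_mm: int, min_3p_exact: int,
             three_prime_first: bool) -> int | None:
    """Mismatch count of core against an equal-length window, honoring the 3'
    anchor; None when the site is rejected."""
    if len(window) != len(core):
        return None
    mm = 0
    anchor = core[-min_3p_exact:] if min_3p_exact else ""
    wanchor = window[-min_3p_exact:] if min_3p_exact else ""
    if three_prime_first and anchor != wanchor:
        return None
    for a, b in zip(core, window):
        if a != b:
            mm += 1
            if mm > max_mm:
                return None
    return mm


def find_binding_sites(
    template: tuple[str, str] | str,
    primer: Oligo,
    max_mismatches: int = 0,
    min_3p_exact: int = 3,
) -> list[BindingSite]:
    """Scan both strands of one template record for primer binding sites.

    The primer's 3' locus-specific portion (``primer.core``; the full
    sequence for an untailed primer) must hybridize with at most
    ``max_mismatches``, and its 3'-terminal ``min_3p_exact`` bases must match
    perfectly — polymerase extension needs a paired 3' end. The adapter tail
    is carried through as ``tail_length`` and never counted as mismatch.
    Sites are returned in plus-strand coordinate order.
    """
    rid, seq = template if isinstance(template, tuple) else ("template", template)
    seq = seq.upper()
    core = primer.core
    if len(core) < min_3p_exact:
        raise ValueError(
            f"primer {primer.name} core ({len(core)} nt) shorter than the 3' "
            f"anchor ({min_3p_exact} nt)"
        )
    L = len(core)
    sites: list[BindingSite] = []
    rc_core = revcomp(core)
    for start in range(0, len(seq) - L + 1):
        window = seq[start:start + L]
        # plus strand: primer extends rightwards; core aligns directly
        mm = _matches(core, window, max_mismatches, min_3p_exact, True)
        if mm is not None:
            sites.append(BindingSite(rid, "+", start, start + L, primer, mm,
                                     primer.tail_length))
        # minus strand: the plus-strand text shows revcomp(core); the 3'
        # anchor of the primer maps to the window's left edge
        mm = _matches(rc_core, window, max_mismatches,
                      min_3p_exact=0, three_prime_first=False)
        if mm is not None:
            if min_3p_exact and window[:min_3p_exact] != rc_core[:min_3p_exact]:
                mm = None
        if mm is not None:
            sites.append(BindingSite(rid, "-", start, start + L, primer, mm,
                                     primer.tail_length))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplicons(
    templates,
    panel: PrimerPanel,
    max_len: int = 1500,
    max_mismatches: int = 0,
    min_3p_exact: int = 3,
    use_tails: bool = True,
) -> list[Amplicon]:
    """Predict all multiplex products of a panel on (multi-)FASTA templates.

    Every plus-strand site of one primer is paired with every downstream
    minus-strand site of its mate (both orientations, so the prediction is
    invariant under reverse-complementing the template) whose product would
    be at most ``max_len`` bp; overlapping site pairs (product shorter than
    the two primers) are rejected. With ``use_tails`` (default) the tailed
    adapter-primers are simulated: the product sequence carries both adapter
    tails and the product length grows by their combined length.
    """
    recs = _records(templates)
    out: list[Amplicon] = []
    for rid, seq in recs:
        for lp in panel:
            if use_tails and lp.tailed:
                fwd, rev = lp.tailed_forward, lp.tailed_reverse
            else:
                fwd, rev = lp.forward, lp.reverse
            fsites = find_binding_sites((rid, seq), fwd, max_mismatches, min_3p_exact)
            rsites = find_binding_sites((rid, seq), rev, max_mismatches, min_3p_exact)
            # canonical orientation: forward on '+', reverse on '-' downstream;
            # flipped orientation (the same amplicon on the other strand):
            # reverse on '+', forward on '-' downstream
            for left, right, l_oligo, r_oligo in (
                (fsites, rsites, fwd, rev),
                (rsites, fsites, rev, fwd),
            ):
                for ls in (s for s in left if s.strand == "+"):
                    for rs in (s for s in right if s.strand == "-"):
                        if rs.start < ls.end:
                            continue  # overlapping or upstream
                        length = (rs.end - ls.start) + ls.tail_length + rs.tail_length
                        if length > max_len:
                            continue
                        product = (
                            l_oligo.tail
                            + l_oligo.core
                            + seq[ls.end:rs.start]
                            + revcomp(r_oligo.core)
                            + revcomp(r_oligo.tail)
                        )
                        fs, rvs = (ls, rs) if l_oligo is fwd else (rs, ls)
                        out.append(
                            Amplicon(rid, lp.locus, fs, rvs, length, product)
                        )
    out.sort(key=lambda a: (a.record, a.locus, a.forward_site.start, a.product_length))
    return out


def band_pattern(amplicons: Iterable[Amplicon], sample: str) -> BandPattern:
    """Collapse amplicons of one sample into a per-locus band-size pattern.

    Lengths are sorted ascending and deduplicated: two haplotypes with the
    same allele give one band, a heterozygous locus gives two.
    """
    bands: dict[str, set[int]] = {}
    for amp in amplicons:
        bands.setdefault(amp.locus, set()).add(amp.product_length)
    return BandPattern(sample, {loc: sorted(v) for loc, v in sorted(bands.items())})
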