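"""Synthetic template generation with planted primer binding sites.

These generators produce the ground-truth inputs the rest of the toolkit is
exercised against: single-locus toy templates for the mechanism oracle, and
multi-locus (optionally diploid) templates whose amplicon sizes are known by
construction. Sequences are drawn from a seeded ``numpy`` generator;
planted sites are verified to be unique (primer cores, their reverse
complements, and the adapter tails must each occur exactly where intended)
and the draw is retried otherwise, so downstream site finding is exact.

What this emulates: clean genomic templates with one perfect binding site
per primer and SSR length alleles encoded purely as inter-primer distance.
What it does not emulate: near-match mispriming sites, repeat stutter,
heterogeneous extraction quality — the features behind nonspecific bands on
real gels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import PrimerPanel
from .seqcore import Oligo, revcomp

__all__ = ["ToyLocus", "make_toy_locus", "make_multilocus_template", "random_dna"]

_BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _clean(template: str, motifs: dict[str, int]) -> bool:
    """True when each motif occurs in the template exactly its expected count
    (counting both strands)."""
    rc = revcomp(template)
    for motif, expected in motifs.items():
        if template.count(motif) + rc.count(motif) != expected:
            return False
    return True


@dataclass(frozen=True)
class ToyLocus:
    """A synthetic locus: template plus one tailed primer pair.

    ``fwd_start`` is the 0-based plus-strand offset of the forward core;
    ``rev_end`` the half-open end of the reverse-core site; the plain (SSR)
    amplicon spans [fwd_start, rev_end).
    """

    template: str
    forward: Oligo
    reverse: Oligo
    fwd_start: int
    rev_end: int

    @property
    def ssr_product_length(self) -> int:
        return self.rev_end - self.fwd_start

    @property
    def tailed_product_length(self) -> int:
        return self.ssr_product_length + self.forward.tail_length + self.reverse.tail_length


def make_toy_locus(
    forward: Oligo,
    reverse: Oligo,
    insert: int = 60,
    flank: int = 40,
    seed: int | np.random.Generator = 0,
    max_tries: int = 200,
) -> ToyLocus:
    """Plant one forward and one reverse binding site on a random template.

    Layout: ``flank + forward.core + insert + revcomp(reverse.core) + flank``.
    The random flanks and insert are redrawn until the primer cores (and, for
    tailed primers, the adapter tails) occur nowhere else on either strand.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fcore, rcore = forward.core, reverse.core
    site_r = revcomp(rcore)
    for _ in range(max_tries):
        template = (
            random_dna(rng, flank) + fcore + random_dna(rng, insert)
            + site_r + random_dna(rng, flank)
        )
        motifs = {fcore: 1, site_r: 1}
        for tail in (forward.tail, reverse.tail):
            if tail:
                motifs.setdefault(tail, 0)
        if _clean(template, motifs):
            return ToyLocus(
                template=template,
                forward=forward,
                reverse=reverse,
                fwd_start=flank,
                rev_end=flank + len(fcore) + insert + len(rcore),
            )
    raise RuntimeError("could not generate a clean toy template")


def make_multilocus_template(
    panel: PrimerPanel,
    inserts: dict[str, int] | None = None,
    spacer: int = 50,
    seed: int | np.random.Generator = 0,
    max_tries: int = 200,
) -> tuple[str, dict[str, int]]:
    """A single template carrying one amplicon per panel locus.

    ``inserts`` gives per-locus inter-primer insert lengths (default 60 +
    10·index, so every locus has a distinct band). Returns the template and
    the per-locus plain-primer product length (core-to-core span), which by
    construction is ``len(forward.core) + insert + len(reverse.core)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    inserts = inserts or {
        lp.locus: 60 + 10 * i for i, lp in enumerate(panel)
    }
    for _ in range(max_tries):
        parts = [random_dna(rng, spacer)]
        sizes: dict[str, int] = {}
        motifs: dict[str, int] = {}
        for lp in panel:
            fcore, rcore = lp.forward.sequence, lp.reverse.sequence
            ins = inserts[lp.locus]
            parts.append(fcore + random_dna(rng, ins) + revcomp(rcore))
            parts.append(random_dna(rng, spacer))
            sizes[lp.locus] = len(fcore) + ins + len(rcore)
            motifs[fcore] = motifs.get(fcore, 0) + 1
            motifs[revcomp(rcore)] = motifs.get(revcomp(rcore), 0) + 1
        template = "".join(parts)
        motifs.setdefault(panel.adapter_f.sequence, 0)
        motifs.setdefault(panel.adapter_r.sequence, 0)
        if _clean(template, motifs):
            return template, sizes
    raise RuntimeError("could not generate a clean multi-locus template")
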