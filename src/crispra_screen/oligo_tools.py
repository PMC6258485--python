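"""Synthesis-oligo formatting and in-silico BbsI Golden-Gate verification.

Pooled libraries are synthesized as 77-mer single-stranded oligos: a 39-nt
5' flank, the 19-nt spacer, and a 19-nt 3' flank. Both flanks carry one
BbsI site oriented inward, so digestion of the PCR-amplified duplex drops
out a 24-bp insert, `CACCG` + spacer on the top strand, with 4-nt 5'
overhangs (CACC left, AAAC right) compatible with the BbsI-cut expression
vector. Individually cloned guides are made as annealed 24-mer pairs with
the same overhangs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .guide_design import GuideLibrary, SPACER_LEN
from .sequence import BBSI_FWD, BBSI_REV, revcomp, validate_dna

FLANK5 = "GCAGATGGCTCTTTGTCCTAGACATCGAAGACAACACCG"
FLANK3 = "GTTTTAGTCTTCTCGTCGC"
OLIGO_LEN = 77

# BbsI: GAAGAC(2/6) — top-strand cut 2 nt 3' of the site, bottom 6 nt,
# leaving 4-nt 5' overhangs.
_CUT_TOP_OFFSET = 2
_CUT_BOTTOM_OFFSET = 6

assert len(FLANK5) == 39 and len(FLANK3) == 19
assert len(FLANK5) + SPACER_LEN + len(FLANK3) == OLIGO_LEN
assert FLANK5.count(BBSI_FWD) == 1 and FLANK5.count(BBSI_REV) == 0
assert FLANK3.count(BBSI_REV) == 1 and FLANK3.count(BBSI_FWD) == 0


@dataclass(frozen=True)
class SynthesisOligo:
    guide_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != OLIGO_LEN:
            raise ValueError(f"oligo must be {OLIGO_LEN} nt")
        if not self.sequence.startswith(FLANK5) or not self.sequence.endswith(FLANK3):
            raise ValueError("oligo flanks do not match the synthesis design")

    @property
    def spacer19(self) -> str:
        return self.sequence[len(FLANK5) : len(FLANK5) + SPACER_LEN]


@dataclass(frozen=True)
class DigestedInsert:
    """Guide-containing fragment after BbsI digestion, as the 24-nt top
    strand plus the two 4-nt 5' overhangs (top-left, bottom-right)."""

    top_strand: str
    left_overhang: str
    right_overhang: str

    def __post_init__(self) -> None:
        if len(self.top_strand) != 24:
            raise ValueError("digested insert top strand must be 24 nt")
        if len(self.left_overhang) != 4 or len(self.right_overhang) != 4:
            raise ValueError("overhangs must be 4 nt")


def format_synthesis_oligo(spacer19: str, guide_id: str = "") -> SynthesisOligo:
    """77-mer pool oligo FLANK5 + spacer + FLANK3.

    Rejects spacers of the wrong length, with non-ACGT characters, or
    containing a BbsI site (which would add a third cut site)."""
    if len(spacer19) != SPACER_LEN:
        raise ValueError(f"spacer must be {SPACER_LEN} nt, got {len(spacer19)}")
    validate_dna(spacer19, context="spacer19")
    if BBSI_FWD in spacer19 or BBSI_REV in spacer19:
        raise ValueError("spacer contains an internal BbsI site")
    seq = FLANK5 + spacer19 + FLANK3
    # a spacer starting with AAGAC or TCTTC completes an extra BbsI site
    # across the 5'-flank junction and would mis-digest
    if seq.count(BBSI_FWD) != 1 or seq.count(BBSI_REV) != 1:
        raise ValueError("spacer creates an extra BbsI site at a flank junction")
    return SynthesisOligo(guide_id or spacer19, seq)


def bbsi_digest(oligo: SynthesisOligo) -> DigestedInsert:
    """Apply BbsI cut geometry to the (double-stranded) oligo and return
    the guide-containing insert.

    Requires exactly one forward site (in the 5' flank) and one reverse
    site (in the 3' flank) on the top strand."""
    seq = oligo.sequence
    if seq.count(BBSI_FWD) != 1 or seq.count(BBSI_REV) != 1:
        raise ValueError("expected exactly one BbsI site per flank")
    fwd = seq.index(BBSI_FWD)
    rev = seq.index(BBSI_REV)
    # Left site (GAAGAC on top): top cut 2 nt past the site, bottom cut 6 nt.
    left_top_cut = fwd + len(BBSI_FWD) + _CUT_TOP_OFFSET
    left_bottom_cut = fwd + len(BBSI_FWD) + _CUT_BOTTOM_OFFSET
    # Right site (GAAGAC on the bottom strand, i.e. GTCTTC on top): offsets
    # run leftward in top-strand coordinates.
    right_bottom_cut = rev - _CUT_TOP_OFFSET
    right_top_cut = rev - _CUT_BOTTOM_OFFSET
    top = seq[left_top_cut:right_top_cut]
    left_overhang = seq[left_top_cut:left_bottom_cut]
    # 5' overhang on the bottom strand, read 5'->3' on the bottom.
    right_overhang = revcomp(seq[right_top_cut:right_bottom_cut])
    if len(top) != 24:
        raise ValueError("unexpected insert length; malformed oligo")
    return DigestedInsert(top, left_overhang, right_overhang)


def format_annealed_pair(spacer19: str) -> tuple[str, str]:
    """Top/bottom 24-mers for individual cloning; annealing reproduces the
    BbsI-digested insert (same duplex, same overhangs)."""
    if len(spacer19) != SPACER_LEN:
        raise ValueError(f"spacer must be {SPACER_LEN} nt")
    validate_dna(spacer19, context="spacer19")
    if BBSI_FWD in spacer19 or BBSI_REV in spacer19:
        raise ValueError("spacer contains an internal BbsI site")
    top = "CACCG" + spacer19
    bottom = "AAAC" + revcomp(spacer19) + "C"
    return top, bottom


def annealed_duplex(top: str, bottom: str) -> DigestedInsert:
    """Interpret an annealed 24-mer pair as a duplex with 4-nt 5' overhangs,
    in the same representation as :func:`bbsi_digest` output."""
    if len(top) != 24 or len(bottom) != 24:
        raise ValueError("annealed oligos must be 24 nt")
    if bottom[4:] != revcomp(top[4:]):
        raise ValueError("oligos do not base-pair in the 20-bp duplex core")
    return DigestedInsert(top, top[:4], bottom[:4])


def write_oligo_pool(oligos: Iterable[SynthesisOligo], path: str | Path,
                     fmt: str = "fasta") -> None:
    """Vendor-style output: FASTA or single-column TXT."""
    with open(path, "w") as fh:
        for o in oligos:
            if fmt == "fasta":
                fh.write(f">{o.guide_id}\n{o.sequence}\n")
            elif fmt == "txt":
                fh.write(o.sequence + "\n")
            else:
                raise ValueError(f"unknown format {fmt!r}")


def write_annealed_pairs(spacers: Iterable[tuple[str, str]], path: str | Path) -> None:
    """2-column TSV of (guide_id, spacer) -> top/bottom oligos."""
    with open(path, "w") as fh:
        fh.write("guide_id\ttop_oligo\tbottom_oligo\n")
        for guide_id, spacer in spacers:
            top, bottom = format_annealed_pair(spacer)
            fh.write(f"{guide_id}\t{top}\t{bottom}\n")


def pool_from_library(lib: GuideLibrary) -> list[SynthesisOligo]:
    """Synthesis oligos for every guide and control in a library."""
    out = [format_synthesis_oligo(g.spacer19, g.guide_id) for g in lib.guides]
    out += [format_synthesis_oligo(c.spacer19, c.control_id) for c in lib.controls]
    return out
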