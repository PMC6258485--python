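"""Small DNA-string helpers shared across the package.

Hot loops work on plain Python strings; file I/O goes through Biopython /
pyfaidx elsewhere.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: BbsI recognition site and its reverse complement. A hit on either strand
#: of a spacer breaks Golden-Gate cloning, so both are screened.
BBSI_FWD = "GAAGAC"
BBSI_REV = "GTCTTC"

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G or C bases; exact rational over the sequence length."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_base_run(seq: str, base: str) -> int:
    """Length of the longest run of `base` in `seq`."""
    best = cur = 0
    for ch in seq:
        cur = cur + 1 if ch == base else 0
        best = max(best, cur)
    return best


def has_bbsi_site(seq: str) -> bool:
    return BBSI_FWD in seq or BBSI_REV in seq


def validate_dna(seq: str, *, allow_n: bool = False, context: str = "sequence") -> None:
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"{context} contains non-DNA characters: {sorted(bad)}")


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random ACGT string."""
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))


def random_dna_no_pam(rng: np.random.Generator, length: int, prefix: str = "") -> str:
    """Random DNA containing no GG or CC dinucleotide (hence no NGG PAM on
    either strand), optionally continuing from `prefix` so the junction is
    also PAM-free. Returns only the newly generated part."""
    out = []
    prev = prefix[-1] if prefix else ""
    for _ in range(length):
        choices = [b for b in DNA_ALPHABET if not (prev == b and b in "GC")]
        base = choices[int(rng.integers(len(choices)))]
        out.append(base)
        prev = base
    return "".join(out)
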