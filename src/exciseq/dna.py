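"""Small DNA string helpers shared across the package.

Sequences are plain uppercase ACGT strings throughout; ambiguity codes are
rejected at load time rather than propagated.
"""

from __future__ import annotations

import re

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID = re.compile(r"^[ACGT]+$")

# SaCas9 PAM: NNGRRT, R = A or G, read on the protospacer strand.
PAM_PATTERN = re.compile(r"^[ACGT]{2}G[AG][AG]T$")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, name: str = "sequence") -> str:
    """Uppercase and validate a DNA string; N or other ambiguity codes are errors."""
    seq = seq.upper()
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"{name} contains non-ACGT characters: {bad}")
    return seq


def is_valid_pam(hexamer: str) -> bool:
    """True if a 6-mer satisfies the SaCas9 NNGRRT motif."""
    return bool(PAM_PATTERN.match(hexamer.upper()))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))
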