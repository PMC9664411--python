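"""Synthetic demonstration locus and barcode set.

All sequences here are synthetic, generated from a fixed RNG seed; they are
not the murine Dmd locus or any real AAV vector. The geometry, however,
mirrors the targeted exon-excision assay this package analyses: an 833 bp
amplicon, two guide cut sites 387 bp apart flanking a 213 bp exon (so the
exon-deletion product is 446 bp), valid NNGRRT PAMs at both sites, and two
AAV vector backbones long enough to donate integration fragments up to the
simulator's maximum.
"""

from __future__ import annotations

import functools

import numpy as np

from .dna import hamming, revcomp
from .locus import LocusModel, build_locus

AMPLICON_LEN = 833
CUT5 = 200
CUT3 = 587  # inter-cut distance 387 -> 446 bp deletion product
EXON = (280, 493)  # 213 bp exon, strictly between the cuts
PROTOSPACER_LEN = 21
BACKBONE_LEN = 2000

_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, n: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, size=n)])


@functools.lru_cache(maxsize=1)
def demo_locus() -> LocusModel:
    """Build the synthetic demo locus (deterministic, cached)."""
    rng = np.random.default_rng(833_387)
    seq = _random_dna(rng, AMPLICON_LEN)

    # guide5 on the + strand: protospacer at [182, 203), PAM at [203, 209),
    # blunt cut 3 nt 5' of the PAM = 200
    s5 = CUT5 - (PROTOSPACER_LEN - 3)
    pam5_at = s5 + PROTOSPACER_LEN
    seq[pam5_at + 2] = "G"
    seq[pam5_at + 3] = "A"
    seq[pam5_at + 4] = "G"
    seq[pam5_at + 5] = "T"

    # guide3 on the - strand: protospacer occupies [584, 605) on the
    # reference, PAM (on the guide strand) is the revcomp of [578, 584),
    # cut 3 nt 5' of the PAM = 587
    s3 = CUT3 - 3
    seq[s3 - 6] = "A"  # rc -> T at PAM pos 6
    seq[s3 - 5] = "C"  # rc -> G (R)
    seq[s3 - 4] = "T"  # rc -> A (R)
    seq[s3 - 3] = "C"  # rc -> G

    reference = "".join(seq)
    protospacer5 = reference[s5 : s5 + PROTOSPACER_LEN]
    protospacer3 = revcomp(reference[s3 : s3 + PROTOSPACER_LEN])

    backbones = [
        ("sacas9-vector", "".join(_random_dna(rng, BACKBONE_LEN))),
        ("sgrna-vector", "".join(_random_dna(rng, BACKBONE_LEN))),
    ]
    primers = (reference[:20], revcomp(reference[-20:]))
    return build_locus(
        reference=reference,
        protospacer5=protospacer5,
        protospacer3=protospacer3,
        exon_interval=EXON,
        aav_backbones=backbones,
        primers=primers,
    )


@functools.lru_cache(maxsize=1)
def demo_barcode_pairs(n_pairs: int = 3) -> tuple[tuple[str, str], ...]:
    """Deterministic 8-mer barcode pairs, mutually distant for demultiplexing.

    Every barcode in the set (and its reverse complement) is at Hamming
    distance >= 5 from every other, so single-substitution-tolerant
    demultiplexing is unambiguous.
    """
    rng = np.random.default_rng(8)
    chosen: list[str] = []
    while len(chosen) < 2 * n_pairs:
        cand = "".join(_BASES[rng.integers(0, 4, size=8)])
        pool = chosen + [revcomp(b) for b in chosen] + [revcomp(cand)]
        if all(hamming(cand, other) >= 5 for other in pool):
            chosen.append(cand)
    return tuple((chosen[2 * i], chosen[2 * i + 1]) for i in range(n_pairs))
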