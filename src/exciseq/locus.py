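"""Model of the dual-guide target locus and its expected edited products.

The locus is an amplicon (primer-to-primer) containing a target exon flanked
by two SaCas9 guide target sites. Simultaneous cleavage at both sites excises
the exon; repair by NHEJ yields either the intended deletion product (intron
fusion), an inversion of the excised fragment, indels at one or both cut
sites, or integration of AAV vector backbone sequence at the break.

This module locates guide sites (protospacer + NNGRRT PAM), predicts the
deletion and inversion products, and derives the diagnostic k-mer feature
sets used by the classifier: k-mers spanning each intact cut site, the
deletion fusion junction, the two inversion junctions, k-mers internal to the
exon, and every k-mer of each AAV backbone in both orientations.

Coordinates are 0-based, half-open, on the + strand of the reference. The
blunt double-strand break is placed 3 nt 5' of the PAM (standard Cas9
biochemistry; configurable via ``CUT_OFFSET_FROM_PAM``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import edlib
import yaml
from Bio import SeqIO

from .dna import is_valid_pam, revcomp, validate_dna

PAM_LEN = 6
CUT_OFFSET_FROM_PAM = 3  # blunt cut this many nt 5' of the PAM

JUNCTION_FEATURES = ("intact5", "intact3", "fusion", "inversion_left", "inversion_right")
#: features whose presence is diagnostic of editing and must therefore be
#: absent from the unedited amplicon
EDIT_DIAGNOSTIC = ("fusion", "inversion_left", "inversion_right")


class GuideNotFoundError(ValueError):
    pass


class AmbiguousGuideError(ValueError):
    pass


class InvalidPamError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class GuideSite:
    """A guide target site located on the amplicon reference.

    ``match_start`` is the 0-based offset of the protospacer-occupied interval
    on the reference + strand; ``cut_pos`` is the inter-base position of the
    blunt double-strand break, also in reference coordinates.
    """

    name: str
    protospacer: str
    pam: str
    strand: str  # '+' or '-'
    match_start: int
    cut_pos: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not is_valid_pam(self.pam):
            raise InvalidPamError(f"PAM {self.pam} does not match NNGRRT")


def find_guide_site(reference: str, protospacer: str, name: str = "guide") -> GuideSite:
    """Locate a protospacer (either strand) with a valid NNGRRT PAM.

    The protospacer must occur exactly once with a valid PAM immediately 3' of
    it on its own strand. The cut position is reported in reference
    coordinates regardless of strand.
    """
    reference = validate_dna(reference, "reference")
    protospacer = validate_dna(protospacer, "protospacer")
    L = len(protospacer)
    raw: list[tuple[int, str, str]] = []  # (match_start, strand, pam_or_empty)

    for s in _find_all(reference, protospacer):
        pam = reference[s + L : s + L + PAM_LEN]
        raw.append((s, "+", pam if len(pam) == PAM_LEN else ""))
    rc = revcomp(protospacer)
    for s in _find_all(reference, rc):
        pam_fwd = reference[max(0, s - PAM_LEN) : s]
        pam = revcomp(pam_fwd) if len(pam_fwd) == PAM_LEN else ""
        raw.append((s, "-", pam))

    valid = [(s, strand, pam) for s, strand, pam in raw if pam and is_valid_pam(pam)]
    if not valid:
        if raw:
            pams = [pam or "<edge>" for _, _, pam in raw]
            raise InvalidPamError(
                f"{name}: protospacer found but adjacent hexamer {pams} fails NNGRRT"
            )
        raise GuideNotFoundError(f"{name}: guide not found on either strand")
    if len(valid) > 1:
        raise AmbiguousGuideError(f"{name}: ambiguous guide ({len(valid)} matches)")

    s, strand, pam = valid[0]
    if strand == "+":
        cut = s + L - CUT_OFFSET_FROM_PAM
    else:
        cut = s + CUT_OFFSET_FROM_PAM
    return GuideSite(name, protospacer, pam, strand, s, cut)


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return
        yield i
        start = i + 1


@dataclasses.dataclass(frozen=True)
class LocusModel:
    """The amplicon reference with both guide sites and the target exon."""

    reference: str
    exon_interval: tuple[int, int]
    guide5: GuideSite
    guide3: GuideSite
    primers: tuple[str, str] | None = None
    aav_backbones: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        validate_dna(self.reference, "reference")
        c5, c3 = self.guide5.cut_pos, self.guide3.cut_pos
        if not 0 <= c5 <= len(self.reference) or not 0 <= c3 <= len(self.reference):
            raise ValueError("cut positions outside reference")
        if c5 >= c3:
            raise ValueError("guide order violation: guide5.cut_pos must precede guide3.cut_pos")
        es, ee = self.exon_interval
        if not (c5 < es < ee < c3):
            raise ValueError("exon_interval must lie strictly between the two cut sites")
        for vname, seq in self.aav_backbones:
            validate_dna(seq, f"AAV backbone {vname}")

    @property
    def cut5(self) -> int:
        return self.guide5.cut_pos

    @property
    def cut3(self) -> int:
        return self.guide3.cut_pos

    @property
    def intercut_distance(self) -> int:
        return self.cut3 - self.cut5


def build_locus(
    reference: str,
    protospacer5: str,
    protospacer3: str,
    exon_interval: tuple[int, int],
    aav_backbones: Iterable[tuple[str, str]] = (),
    primers: tuple[str, str] | None = None,
) -> LocusModel:
    """Locate both guides on ``reference`` and assemble a validated LocusModel.

    Guides are named by their position relative to the exon; the two
    protospacers may be given in either order.
    """
    g_a = find_guide_site(reference, protospacer5, "guide5")
    g_b = find_guide_site(reference, protospacer3, "guide3")
    if g_a.cut_pos > g_b.cut_pos:
        g_a, g_b = (
            dataclasses.replace(g_b, name="guide5"),
            dataclasses.replace(g_a, name="guide3"),
        )
    return LocusModel(
        reference=validate_dna(reference, "reference"),
        exon_interval=tuple(exon_interval),
        guide5=g_a,
        guide3=g_b,
        primers=primers,
        aav_backbones=tuple((n, validate_dna(s, n)) for n, s in aav_backbones),
    )


def expected_products(locus: LocusModel) -> dict[str, str]:
    """Predict the exon-deletion and exon-inversion repair products.

    deletion  = reference with the inter-cut segment excised (intron fusion);
    inversion = reference with the inter-cut segment reverse-complemented in
    place. Both assume seamless blunt-end joining.
    """
    ref, c5, c3 = locus.reference, locus.cut5, locus.cut3
    return {
        "deletion": ref[:c5] + ref[c3:],
        "inversion": ref[:c5] + revcomp(ref[c5:c3]) + ref[c3:],
    }


@dataclasses.dataclass
class FeatureSet:
    """Named diagnostic k-mer collections driving read classification.

    ``features`` maps a feature name (``intact5``, ``intact3``, ``fusion``,
    ``inversion_left``, ``inversion_right``, ``exon_internal`` or
    ``aav:<vector>:<fwd|rev>``) to its k-mer list. A feature is considered
    matched in a read when any of its k-mers occurs within ``max_dist``
    Levenshtein edits on either strand.
    """

    k: int
    max_dist: int
    features: dict[str, list[str]]

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for name, kmers in self.features.items():
            for kmer in kmers:
                if len(kmer) != self.k:
                    raise ValueError(f"{name}: k-mer {kmer} has length {len(kmer)} != k={self.k}")
                validate_dna(kmer, f"{name} k-mer")
                prev = seen.get(kmer)
                if prev is not None and prev != name:
                    raise ValueError(
                        f"k-mer collision: {kmer} assigned to both {prev} and {name}"
                    )
                seen[kmer] = name

    @property
    def aav_feature_names(self) -> list[str]:
        return [n for n in self.features if n.startswith("aav:")]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\n#max_dist={self.max_dist}\n")
            fh.write("feature_name\tkmer\n")
            for name in self.features:
                for kmer in self.features[name]:
                    fh.write(f"{name}\t{kmer}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureSet":
        k = max_dist = None
        features: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#k="):
                    k = int(line[3:])
                elif line.startswith("#max_dist="):
                    max_dist = int(line[10:])
                elif line and not line.startswith("#") and not line.startswith("feature_name"):
                    name, kmer = line.split("\t")
                    features.setdefault(name, []).append(kmer)
        if k is None or max_dist is None:
            raise ValueError("feature TSV missing #k= / #max_dist= header")
        fs = cls(k=k, max_dist=max_dist, features=features)
        fs.validate()
        return fs


def _stagger_offsets(n: int, step: int) -> list[int]:
    return [round(step * (i - (n - 1) / 2)) for i in range(n)]


def _junction_kmers(product: str, junction: int, k: int, offsets: list[int]) -> list[str]:
    out: list[str] = []
    for off in offsets:
        start = junction - k // 2 + off
        if start < 0 or start + k > len(product):
            raise ValueError("junction k-mer window falls outside product; k too large for flank")
        out.append(product[start : start + k])
    # staggered windows can coincide on tiny loci; keep order, drop repeats
    return list(dict.fromkeys(out))


def _occurs_within(kmer: str, seq: str, max_dist: int) -> bool:
    for target in (seq, revcomp(seq)):
        res = edlib.align(kmer, target, mode="HW", task="distance", k=max_dist)
        if res["editDistance"] != -1:
            return True
    return False


def derive_features(
    locus: LocusModel,
    k: int = 25,
    max_dist: int = 2,
    n_per_junction: int = 3,
    stagger: int | None = None,
    aav_stride: int = 1,
    exon_margin: int = 15,
) -> FeatureSet:
    """Derive the diagnostic FeatureSet for a locus.

    Junction features carry ``n_per_junction`` staggered copies (window shifts
    of ``stagger`` nt) so that a cluster of sequencing errors in one window
    does not blind the feature. Every k-mer keeps at least floor(k/3) bases on
    each side of its junction. AAV backbone features enumerate every k-mer
    (``aav_stride`` = 1) of each backbone in both orientations; these, and the
    fusion/inversion junction k-mers, are checked for absence from the
    unedited amplicon within ``max_dist`` so that their presence in a read is
    unambiguous evidence of editing.
    """
    if n_per_junction < 1:
        raise ValueError("n_per_junction must be >= 1")
    if stagger is None:
        # widest shift keeping >= floor(k/3) bases on both sides of a junction
        stagger = max(1, min(4, k // 2 - k // 3))
    max_off = max(abs(o) for o in _stagger_offsets(n_per_junction, stagger))
    if k // 2 - max_off < k // 3:
        raise ValueError(
            "stagger too wide: junction k-mers must span the junction with "
            ">= floor(k/3) bases on both sides"
        )

    ref = locus.reference
    products = expected_products(locus)
    offsets = _stagger_offsets(n_per_junction, stagger)
    c5, c3 = locus.cut5, locus.cut3

    features: dict[str, list[str]] = {
        "intact5": _junction_kmers(ref, c5, k, offsets),
        "intact3": _junction_kmers(ref, c3, k, offsets),
        "fusion": _junction_kmers(products["deletion"], c5, k, offsets),
        "inversion_left": _junction_kmers(products["inversion"], c5, k, offsets),
        "inversion_right": _junction_kmers(products["inversion"], c3, k, offsets),
    }

    es, ee = locus.exon_interval
    lo, hi = es + exon_margin, ee - exon_margin - k
    if hi < lo:
        lo, hi = es, ee - k
        if hi < lo:
            raise ValueError("exon shorter than k; cannot derive exon_internal k-mers")
    n_exon = n_per_junction
    if n_exon == 1:
        starts = [(lo + hi) // 2]
    else:
        starts = [lo + round(i * (hi - lo) / (n_exon - 1)) for i in range(n_exon)]
    features["exon_internal"] = list(dict.fromkeys(ref[s : s + k] for s in starts))

    for vname, seq in locus.aav_backbones:
        if len(seq) < k:
            raise ValueError(f"AAV backbone {vname} shorter than k")
        fwd = [seq[i : i + k] for i in range(0, len(seq) - k + 1, aav_stride)]
        rcs = revcomp(seq)
        rev = [rcs[i : i + k] for i in range(0, len(rcs) - k + 1, aav_stride)]
        features[f"aav:{vname}:fwd"] = list(dict.fromkeys(fwd))
        features[f"aav:{vname}:rev"] = list(dict.fromkeys(rev))

    # diagnostic features must not occur in the unedited amplicon
    for name, kmers in features.items():
        if name in EDIT_DIAGNOSTIC or name.startswith("aav:"):
            for kmer in kmers:
                if _occurs_within(kmer, ref, max_dist):
                    raise ValueError(
                        f"non-diagnostic feature set: {name} k-mer {kmer} occurs in "
                        f"the unedited reference within edit distance {max_dist}"
                    )

    fs = FeatureSet(k=k, max_dist=max_dist, features=features)
    fs.validate()
    return fs


# ---------------------------------------------------------------------------
# config / FASTA loading


def _read_single_fasta(path: Path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    return str(records[0].seq)


def load_locus(config_path: str | Path) -> LocusModel:
    """Load a LocusModel from a YAML config.

    Keys: ``reference`` (inline sequence or FASTA path), ``exon`` ([start,
    end], 0-based half-open), ``guides`` (``five_prime``/``three_prime``
    protospacers), optional ``primers`` ([fwd, rev]) and ``aav_backbones``
    (FASTA path, multi-record, or mapping name -> sequence). Relative paths
    resolve against the config file's directory.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent

    ref = cfg["reference"]
    if set(ref.upper()) - set("ACGT"):  # looks like a path, not a sequence
        ref = _read_single_fasta(base / ref)

    backbones: list[tuple[str, str]] = []
    bb = cfg.get("aav_backbones")
    if isinstance(bb, str):
        for rec in SeqIO.parse(str(base / bb), "fasta"):
            backbones.append((rec.id, str(rec.seq)))
    elif isinstance(bb, dict):
        backbones = list(bb.items())

    primers = tuple(cfg["primers"]) if "primers" in cfg else None
    return build_locus(
        reference=ref,
        protospacer5=cfg["guides"]["five_prime"],
        protospacer3=cfg["guides"]["three_prime"],
        exon_interval=tuple(cfg["exon"]),
        aav_backbones=backbones,
        primers=primers,
    )
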