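"""Seeded synthetic long-read amplicon library generator.

Produces multiplexed CCS-style FASTQ libraries with the editing-outcome
structure the classifier assumes: reads drawn i.i.d. from per-category
proportions, molecules built from the locus model (unedited amplicon,
exon-deletion product, exon inversion, cut-site indels, AAV backbone
fragments inserted at cut junctions), 8-mer internal barcodes on both primers,
random read orientation, and an i.i.d. substitution/insertion/deletion error
model with matching Phred quality strings. Fully deterministic for a given
seed, and every read is paired with a ground-truth record for recovery tests.

Default proportions follow the long-read survey of editing outcomes in
CRISPR-treated cardiac muscle (mid-points of the reported ranges: indels at
the 5' site 11.5%, at the 3' site 2%, both sites 0.5%, productive exon
deletion 0.55%, inversion 0.05%, AAV backbone integration 0.75%, remainder
unedited). Cut-site indel sizes are geometric, truncated by default to a
minimum of 3 nt — the smallest edit the default classifier tolerance (2
Levenshtein edits) can distinguish from sequencing error; see
docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .demo import demo_barcode_pairs
from .dna import revcomp
from .locus import LocusModel, expected_products
from .reads import ReadRecord, write_fastq

#: the fixed category vocabulary; 'unclassified' is a classifier outcome only
#: and never appears in truth
CATEGORIES = (
    "unedited",
    "indel5",
    "indel3",
    "indel_both",
    "delta_exon",
    "inversion",
    "aav_integration",
)

DEFAULT_PROPORTIONS = {
    "unedited": 0.8465,
    "indel5": 0.115,
    "indel3": 0.02,
    "indel_both": 0.005,
    "delta_exon": 0.0055,
    "inversion": 0.0005,
    "aav_integration": 0.0075,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclasses.dataclass(frozen=True)
class JunctionIndelPreset:
    """A fixed indel relative to the fusion seam of the deletion product.

    ``side`` is 'upstream' (5' of the seam) or 'downstream' (3' of it);
    negative size = deletion, positive = insertion. The default presets are
    the two cloned repair variants seen around the intron fusion site: a 4 bp
    deletion downstream and an 11 bp deletion upstream of the seam.
    """

    size: int
    side: str  # 'upstream' | 'downstream'


DEFAULT_PRESETS = (
    JunctionIndelPreset(-4, "downstream"),
    JunctionIndelPreset(-11, "upstream"),
)


@dataclasses.dataclass
class IndelModel:
    """Cut-site and fusion-junction indel size model.

    Sizes are geometric(geom_p) shifted to start at ``min_size`` and truncated
    at ``max_size``; deletions outnumber insertions ``p_deletion``:(1-p).
    ``junction_indel_prob`` is the probability that a deletion-product
    (delta_exon) molecule carries an indel at the fusion seam; when one is
    applied, a preset is used with probability ``preset_prob``, otherwise a
    random geometric indel.
    """

    min_size: int = 3
    max_size: int = 25
    geom_p: float = 0.3
    p_deletion: float = 0.75
    junction_indel_prob: float = 0.0
    preset_prob: float = 0.5
    presets: tuple[JunctionIndelPreset, ...] = DEFAULT_PRESETS
    #: cut-site indel draws are rejected until the edited site differs from
    #: the intact site by more than this many edits in every detect_k window
    #: around the cut (0 disables). Repetitive context can otherwise collapse
    #: an indel's edit distance (e.g. a 3 nt deletion inside a homopolymer),
    #: yielding a molecule whose target site is not genuinely disrupted.
    ensure_disruption: int = 2
    detect_k: int = 25

    def draw_size(self, rng: np.random.Generator) -> int:
        """Signed indel size: negative = deletion, positive = insertion."""
        for _ in range(1000):
            size = self.min_size - 1 + rng.geometric(self.geom_p)
            if size <= self.max_size:
                break
        else:
            size = self.max_size
        return -size if rng.random() < self.p_deletion else size


@dataclasses.dataclass
class AavFragmentModel:
    """AAV backbone fragment insertion model.

    Fragment lengths are uniform on [min_len, max_len], capped so the total
    molecule stays at or below ``max_total_len`` (long templates amplify
    poorly in the assay's PCR). Fragments insert in reverse orientation with
    probability ``p_reverse``.
    """

    min_len: int = 100
    max_len: int = 1600
    p_reverse: float = 0.5
    max_total_len: int = 1750


@dataclasses.dataclass
class ErrorModel:
    """Per-base i.i.d. sequencing error and quality model.

    Defaults approximate a high-accuracy CCS profile in the Q20-Q30 band:
    1% total error (0.5% substitution, 0.25% insertion, 0.25% deletion) with
    qualities uniform on mean_q +/- q_jitter, so the expected mean Phred
    equals ``mean_q``.
    """

    p_sub: float = 0.005
    p_ins: float = 0.0025
    p_del: float = 0.0025
    mean_q: int = 27
    q_jitter: int = 3

    def validate(self) -> None:
        for name in ("p_sub", "p_ins", "p_del"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def error_free(self) -> bool:
        return self.p_sub == self.p_ins == self.p_del == 0.0


ZERO_ERROR = ErrorModel(p_sub=0.0, p_ins=0.0, p_del=0.0, q_jitter=0)


@dataclasses.dataclass
class SimConfig:
    n_reads: int = 20_000
    seed: int = 0
    proportions: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    indel_model: IndelModel = dataclasses.field(default_factory=IndelModel)
    aav_fragment_model: AavFragmentModel = dataclasses.field(default_factory=AavFragmentModel)
    error_model: ErrorModel = dataclasses.field(default_factory=ErrorModel)
    barcode_pairs: tuple[tuple[str, str], ...] = dataclasses.field(
        default_factory=demo_barcode_pairs
    )
    p_reverse_read: float = 0.5

    def validate(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category proportions must sum to 1, got {total}")
        unknown = set(self.proportions) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in proportions: {sorted(unknown)}")
        self.error_model.validate()
        flat = [b for pair in self.barcode_pairs for b in pair]
        if len(set(flat)) != len(flat):
            raise ValueError("barcode collision between samples")


def apply_errors(
    seq: str, error_model: ErrorModel, rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    """Apply i.i.d. substitution/insertion/deletion errors; return bases + quals.

    Each template base independently substitutes with p_sub or drops with
    p_del; a random base inserts before each position (and at the end) with
    p_ins. Qualities are drawn uniformly on mean_q +/- q_jitter for every
    emitted base.
    """
    error_model.validate()
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.uint8)
    lut[_BASES] = np.arange(4)
    codes = lut[codes]  # 0..3
    n = len(codes)

    if not error_model.error_free:
        r = rng.random(n)
        sub_mask = r < error_model.p_sub
        del_mask = (r >= error_model.p_sub) & (r < error_model.p_sub + error_model.p_del)
        ins_mask = rng.random(n + 1) < error_model.p_ins
        if sub_mask.any():
            codes[sub_mask] = (codes[sub_mask] + rng.integers(1, 4, sub_mask.sum())) % 4
        if ins_mask.any() or del_mask.any():
            ins_bases = rng.integers(0, 4, int(ins_mask.sum()))
            pieces: list[np.ndarray] = []
            ins_at = np.flatnonzero(ins_mask)
            keep = ~del_mask
            prev = 0
            for j, pos in enumerate(ins_at):
                pieces.append(codes[prev:pos][keep[prev:pos]])
                pieces.append(ins_bases[j : j + 1].astype(np.uint8))
                prev = pos
            pieces.append(codes[prev:][keep[prev:]])
            codes = np.concatenate(pieces)
        else:
            pass  # substitutions only, length unchanged

    out_n = len(codes)
    if error_model.q_jitter:
        quals = rng.integers(
            error_model.mean_q - error_model.q_jitter,
            error_model.mean_q + error_model.q_jitter + 1,
            out_n,
        )
    else:
        quals = np.full(out_n, error_model.mean_q, dtype=np.int64)
    quals = np.clip(quals, 0, 93)
    bases = _BASES[codes].tobytes().decode()
    return bases, quals


# ---------------------------------------------------------------------------
# molecule construction


def _apply_indel(seq: str, pos: int, size: int, rng: np.random.Generator) -> str:
    """Apply a signed indel centred at inter-base position ``pos``."""
    if size < 0:
        s = -size
        start = max(0, pos - s // 2)
        return seq[:start] + seq[start + s :]
    ins = "".join(chr(b) for b in _BASES[rng.integers(0, 4, size)])
    return seq[:pos] + ins + seq[pos:]


def _junction_window_kmers(product: str, junction: int, k: int) -> list[str]:
    out = []
    for off in (-4, 0, 4):
        start = junction - k // 2 + off
        if 0 <= start and start + k <= len(product):
            out.append(product[start : start + k])
    return out


def _diagnostic_junction_kmers(locus: LocusModel, k: int) -> list[str]:
    """Fusion/inversion junction k-mers an indel must not accidentally create.

    These junctions share one flank with the unedited cut-site sequence, so a
    chance indel at a cut can land within matching tolerance of one of them;
    such a molecule is genuinely ambiguous and must not be labelled as a
    plain cut-site indel.
    """
    products = expected_products(locus)
    c5, c3 = locus.cut5, locus.cut3
    kmers = _junction_window_kmers(products["deletion"], c5, k)
    kmers += _junction_window_kmers(products["inversion"], c5, k)
    kmers += _junction_window_kmers(products["inversion"], c3, k)
    return kmers


def _site_cleanly_disrupted(
    mol: str, ref: str, cut: int, k: int, max_dist: int, avoid: list[str]
) -> bool:
    """No intact-site window survives, and no diagnostic junction is created."""
    import edlib  # local import keeps simulate importable without matching deps

    lo = max(0, cut - k - 40)
    region = mol[lo : cut + k + 40]
    region_rc = revcomp(region)
    for off in (-4, 0, 4):
        start = cut - k // 2 + off
        if start < 0 or start + k > len(ref):
            continue
        kmer = ref[start : start + k]
        if edlib.align(kmer, region, mode="HW", task="distance", k=max_dist)[
            "editDistance"
        ] != -1:
            return False
    for kmer in avoid:
        for target in (region, region_rc):
            if edlib.align(kmer, target, mode="HW", task="distance", k=max_dist)[
                "editDistance"
            ] != -1:
                return False
    return True


def _draw_site_indel(
    mol: str,
    ref: str,
    cut: int,
    im: IndelModel,
    rng: np.random.Generator,
    avoid: list[str],
) -> tuple[str, int]:
    """Draw a cut-site indel, rejecting draws that fail to disrupt the site
    (or that chance-create a fusion/inversion junction signature)."""
    for _ in range(200):
        size = im.draw_size(rng)
        edited = _apply_indel(mol, cut, size, rng)
        if not im.ensure_disruption or _site_cleanly_disrupted(
            edited, ref, cut, im.detect_k, im.ensure_disruption, avoid
        ):
            return edited, size
    raise RuntimeError(
        "could not draw a site-disrupting indel in 200 tries; "
        "locus context too repetitive for the configured sizes"
    )


def _build_molecule(
    category: str,
    locus: LocusModel,
    cfg: SimConfig,
    rng: np.random.Generator,
    avoid: list[str] | None = None,
) -> tuple[str, dict]:
    """Construct the (error-free) template molecule for one truth category."""
    ref = locus.reference
    c5, c3 = locus.cut5, locus.cut3
    products = expected_products(locus)
    info: dict = {"indel_site": "", "indel_size": 0, "aav_vector": "",
                  "aav_start": -1, "aav_len": 0, "aav_orientation": ""}
    im = cfg.indel_model

    if category == "unedited":
        return ref, info

    if category in ("indel5", "indel3", "indel_both"):
        if avoid is None:
            avoid = _diagnostic_junction_kmers(locus, im.detect_k)
        # apply the 3' indel first so 5' coordinates stay valid
        mol = ref
        if category in ("indel3", "indel_both"):
            mol, size3 = _draw_site_indel(mol, ref, c3, im, rng, avoid)
        if category in ("indel5", "indel_both"):
            mol, size5 = _draw_site_indel(mol, ref, c5, im, rng, avoid)
        if category == "indel5":
            info.update(indel_site="5", indel_size=size5)
        elif category == "indel3":
            info.update(indel_site="3", indel_size=size3)
        else:
            info.update(indel_site="both", indel_size=size5)  # 5' size recorded
        return mol, info

    if category == "delta_exon":
        mol = products["deletion"]  # fusion seam at c5
        if rng.random() < im.junction_indel_prob:
            if im.presets and rng.random() < im.preset_prob:
                preset = im.presets[rng.integers(0, len(im.presets))]
                if preset.size < 0 and preset.side == "downstream":
                    mol = mol[:c5] + mol[c5 - preset.size :]
                elif preset.size < 0:
                    mol = mol[: c5 + preset.size] + mol[c5:]
                else:
                    mol = _apply_indel(mol, c5, preset.size, rng)
                info.update(indel_site=f"fusion_{preset.side}", indel_size=preset.size)
            else:
                size = im.draw_size(rng)
                mol = _apply_indel(mol, c5, size, rng)
                info.update(indel_site="fusion", indel_size=size)
        return mol, info

    if category == "inversion":
        return products["inversion"], info

    if category == "aav_integration":
        am = cfg.aav_fragment_model
        # half the events sit in a completed deletion junction, half at a
        # single 5' cut with the exon retained
        if rng.random() < 0.5:
            left, right = ref[:c5], ref[c3:]
        else:
            left, right = ref[:c5], ref[c5:]
        vi = rng.integers(0, len(locus.aav_backbones))
        vname, vseq = locus.aav_backbones[vi]
        cap = min(am.max_len, am.max_total_len - (len(left) + len(right)), len(vseq))
        lo = min(am.min_len, cap)
        frag_len = int(rng.integers(lo, cap + 1))
        start = int(rng.integers(0, len(vseq) - frag_len + 1))
        frag = vseq[start : start + frag_len]
        orient = "rev" if rng.random() < am.p_reverse else "fwd"
        if orient == "rev":
            frag = revcomp(frag)
        info.update(aav_vector=vname, aav_start=start, aav_len=frag_len,
                    aav_orientation=orient)
        return left + frag + right, info

    raise ValueError(f"unknown category {category!r}")


def simulate_library(
    locus: LocusModel, cfg: SimConfig
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate a multiplexed library; returns reads and the truth table.

    Reads draw their category i.i.d. from ``cfg.proportions`` and their sample
    uniformly from ``cfg.barcode_pairs``; each molecule is barcoded
    (fwd barcode + molecule + revcomp(rev barcode)), sequencing errors are
    applied, and the whole read is reverse-complemented with probability
    ``cfg.p_reverse_read``. Deterministic for a given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cats = list(cfg.proportions)
    probs = np.array([cfg.proportions[c] for c in cats])
    cat_idx = rng.choice(len(cats), size=cfg.n_reads, p=probs)
    sample_idx = rng.integers(0, len(cfg.barcode_pairs), size=cfg.n_reads)
    flip = rng.random(cfg.n_reads) < cfg.p_reverse_read

    avoid = _diagnostic_junction_kmers(locus, cfg.indel_model.detect_k)
    reads: list[ReadRecord] = []
    truth_rows: list[dict] = []
    for i in range(cfg.n_reads):
        category = cats[cat_idx[i]]
        mol, info = _build_molecule(category, locus, cfg, rng, avoid)
        fwd_bc, rev_bc = cfg.barcode_pairs[sample_idx[i]]
        template = fwd_bc + mol + revcomp(rev_bc)
        bases, quals = apply_errors(template, cfg.error_model, rng)
        if flip[i]:
            bases = revcomp(bases)
            quals = quals[::-1]
        read_id = f"read{i:06d}"
        reads.append(ReadRecord(id=read_id, bases=bases, quals=quals))
        truth_rows.append(
            {
                "read_id": read_id,
                "sample": f"sample{sample_idx[i] + 1}",
                "true_category": category,
                "orientation": "reverse" if flip[i] else "forward",
                **info,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return reads, truth


def write_library(
    locus: LocusModel,
    cfg: SimConfig,
    fastq_path: str | Path,
    truth_path: str | Path,
) -> tuple[int, pd.DataFrame]:
    """Simulate and write FASTQ (Phred+33) plus a truth TSV."""
    reads, truth = simulate_library(locus, cfg)
    n = write_fastq(reads, fastq_path)
    truth.to_csv(truth_path, sep="\t", index=False)
    return n, truth


def sample_names(cfg: SimConfig) -> list[str]:
    return [f"sample{i + 1}" for i in range(len(cfg.barcode_pairs))]


def barcode_map(cfg: SimConfig) -> dict[str, tuple[str, str]]:
    return {f"sample{i + 1}": pair for i, pair in enumerate(cfg.barcode_pairs)}
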