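"""Barcode demultiplexing and read quality/length filtering.

Reads carry asymmetric internal 8-mer barcodes on both primers: a forward
read is ``fwd_barcode + insert + revcomp(rev_barcode)``; a reverse-oriented
read is the reverse complement of that. Demultiplexing matches both end
windows with up to ``max_mismatch`` substitutions (no indels), flags the
orientation, and trims the barcodes.

Quality filtering retains reads whose mean quality — computed on the
error-probability scale, Q_mean = -10*log10(mean per-base error probability)
— is at least ``min_mean_q`` (default Q20) and whose trimmed length is at
least ``min_len`` (default 400 bases). Both boundaries are inclusive. The
probability-scale mean is the defensible error-rate reading of a
minimum-average-quality ("maq") threshold; the arithmetic mean of Phred
scores is available as an alternative.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dna import hamming, revcomp
from .reads import ReadRecord

UNASSIGNED = "unassigned"


@dataclasses.dataclass
class FilterReport:
    """Read-accounting over demultiplexing and filtering.

    Invariants: input == failed_barcode + sum(demuxed); per sample,
    demuxed == passed + failed_maq + failed_length.
    """

    input: int = 0
    failed_barcode: int = 0
    demuxed: dict[str, int] = dataclasses.field(default_factory=dict)
    failed_maq: dict[str, int] = dataclasses.field(default_factory=dict)
    failed_length: dict[str, int] = dataclasses.field(default_factory=dict)
    passed: dict[str, int] = dataclasses.field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        samples = sorted(self.demuxed)
        rows = [
            {
                "sample": s,
                "demuxed": self.demuxed.get(s, 0),
                "failed_maq": self.failed_maq.get(s, 0),
                "failed_length": self.failed_length.get(s, 0),
                "passed": self.passed.get(s, 0),
            }
            for s in samples
        ]
        df = pd.DataFrame(rows, columns=["sample", "demuxed", "failed_maq",
                                         "failed_length", "passed"])
        df.attrs["input"] = self.input
        df.attrs["failed_barcode"] = self.failed_barcode
        return df

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _as_barcode_map(
    barcode_pairs: Mapping[str, tuple[str, str]] | Sequence[tuple[str, str]],
) -> dict[str, tuple[str, str]]:
    if isinstance(barcode_pairs, Mapping):
        return dict(barcode_pairs)
    return {f"sample{i + 1}": tuple(pair) for i, pair in enumerate(barcode_pairs)}


def validate_barcodes(
    barcodes: Mapping[str, tuple[str, str]], max_mismatch: int
) -> None:
    """All barcodes (and their revcomps) must be mutually separable."""
    flat: list[str] = []
    for fwd, rev in barcodes.values():
        if len(fwd) != len(rev):
            raise ValueError("forward and reverse barcodes must have equal length")
        flat += [fwd, rev]
    lens = {len(b) for b in flat}
    if len(lens) > 1:
        raise ValueError("all barcodes must have the same length")
    for i, a in enumerate(flat):
        for b in flat[i + 1 :]:
            if hamming(a, b) <= 2 * max_mismatch:
                raise ValueError(
                    f"barcode collision: {a} and {b} are within "
                    f"2*max_mismatch={2 * max_mismatch} substitutions"
                )


def demultiplex(
    reads: Iterable[ReadRecord],
    barcode_pairs: Mapping[str, tuple[str, str]] | Sequence[tuple[str, str]],
    max_mismatch: int = 1,
) -> tuple[dict[str, list[ReadRecord]], FilterReport]:
    """Assign reads to samples by their end barcodes; trim the barcodes.

    A read joins sample s when its 5' window matches s's forward barcode and
    its 3' window the reverse complement of s's reverse barcode, each within
    ``max_mismatch`` substitutions (forward orientation), or the mirrored
    pattern (reverse orientation). Unassigned or ambiguous reads are counted
    under ``failed_barcode`` and returned in the ``unassigned`` bucket,
    untrimmed.
    """
    barcodes = _as_barcode_map(barcode_pairs)
    validate_barcodes(barcodes, max_mismatch)
    blen = len(next(iter(barcodes.values()))[0])

    # precompute per-sample expected end windows for both orientations
    patterns: list[tuple[str, str, str, str]] = []  # (sample, orientation, head, tail)
    for s, (fwd, rev) in barcodes.items():
        patterns.append((s, "forward", fwd, revcomp(rev)))
        patterns.append((s, "reverse", rev, revcomp(fwd)))

    buckets: dict[str, list[ReadRecord]] = {s: [] for s in barcodes}
    buckets[UNASSIGNED] = []
    report = FilterReport(demuxed={s: 0 for s in barcodes})

    for read in reads:
        report.input += 1
        if len(read) < 2 * blen + 1:
            report.failed_barcode += 1
            buckets[UNASSIGNED].append(read)
            continue
        head, tail = read.bases[:blen], read.bases[-blen:]
        hits = []
        for s, orient, exp_head, exp_tail in patterns:
            mm_head = hamming(head, exp_head)
            if mm_head > max_mismatch:
                continue
            mm_tail = hamming(tail, exp_tail)
            if mm_tail > max_mismatch:
                continue
            hits.append((mm_head + mm_tail, s, orient))
        samples_hit = {s for _, s, _ in hits}
        if len(samples_hit) != 1:
            report.failed_barcode += 1
            buckets[UNASSIGNED].append(read)
            continue
        _, s, orient = min(hits)
        trimmed = ReadRecord(
            id=read.id,
            bases=read.bases[blen:-blen],
            quals=read.quals[blen:-blen],
            sample=s,
            orientation=orient,
        )
        buckets[s].append(trimmed)
        report.demuxed[s] += 1
    return buckets, report


def mean_quality(quals: np.ndarray, method: str = "probability") -> float:
    """Mean read quality in Phred units.

    ``probability`` (default): -10*log10 of the mean per-base error
    probability; ``arithmetic``: plain mean of the Phred scores.
    """
    quals = np.asarray(quals, dtype=np.float64)
    if quals.size == 0:
        return 0.0
    if method == "probability":
        return float(-10.0 * np.log10(np.mean(10.0 ** (-quals / 10.0))))
    if method == "arithmetic":
        return float(np.mean(quals))
    raise ValueError(f"unknown mean-quality method {method!r}")


def quality_length_filter(
    reads: Iterable[ReadRecord],
    min_mean_q: float = 20.0,
    min_len: int = 400,
    maq_method: str = "probability",
    report: FilterReport | None = None,
) -> tuple[list[ReadRecord], FilterReport]:
    """Retain reads with mean quality >= min_mean_q and length >= min_len.

    Length is measured on the (barcode-trimmed) bases as given. Reads failing
    both checks are counted once, under ``failed_maq``. Deterministic and
    idempotent.
    """
    if report is None:
        report = FilterReport()
    passed: list[ReadRecord] = []
    for read in reads:
        s = read.sample or "all"
        if mean_quality(read.quals, maq_method) < min_mean_q - 1e-9:
            report.failed_maq[s] = report.failed_maq.get(s, 0) + 1
        elif len(read) < min_len:
            report.failed_length[s] = report.failed_length.get(s, 0) + 1
        else:
            report.passed[s] = report.passed.get(s, 0) + 1
            passed.append(read)
    return passed, report
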