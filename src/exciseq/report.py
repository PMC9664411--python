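"""Per-category amplicon-size QC and summary report files.

The size distribution of each classification bin is a cheap sanity check on
the classifier: exon-deletion reads should sit at the deletion-product
length, unedited/indel/inversion reads at the full amplicon length, and AAV
integration reads should shift toward larger sizes than the unedited mode.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import CLASS_CATEGORIES, CategoryTable, ClassificationResult
from .locus import LocusModel, expected_products

BIN_WIDTH = 10  # bp; length modes are taken on binned lengths to absorb indel jitter


@dataclasses.dataclass
class SizeSummary:
    category: str
    n: int
    min_len: int | None
    max_len: int | None
    median_len: float | None
    mode_len: int | None
    expected_len: int | None
    mode_deviation: int | None  # mode - expected, where an expectation exists


def _binned_mode(lengths: np.ndarray) -> int:
    """Most frequent exact length within the most populated BIN_WIDTH bin."""
    bins = lengths // BIN_WIDTH
    modal_bin = Counter(bins.tolist()).most_common(1)[0][0]
    in_bin = lengths[bins == modal_bin]
    return int(Counter(in_bin.tolist()).most_common(1)[0][0])


def size_distributions(
    results: list[ClassificationResult], locus: LocusModel
) -> list[SizeSummary]:
    """Per-category length summaries with expected lengths from the locus."""
    ref_len = len(locus.reference)
    del_len = len(expected_products(locus)["deletion"])
    expected = {
        "unedited": ref_len,
        "indel5": ref_len,
        "indel3": ref_len,
        "indel_both": ref_len,
        "inversion": ref_len,
        "delta_exon": del_len,
        "aav_integration": None,  # expect mode > unedited mode
        "unclassified": None,
    }
    by_cat: dict[str, list[int]] = {c: [] for c in CLASS_CATEGORIES}
    for r in results:
        by_cat[r.category].append(r.read_length)

    out: list[SizeSummary] = []
    for cat in CLASS_CATEGORIES:
        lens = np.array(by_cat[cat], dtype=np.int64)
        if len(lens) == 0:
            out.append(SizeSummary(cat, 0, None, None, None, None, expected[cat], None))
            continue
        mode = _binned_mode(lens)
        exp = expected[cat]
        out.append(
            SizeSummary(
                category=cat,
                n=len(lens),
                min_len=int(lens.min()),
                max_len=int(lens.max()),
                median_len=float(np.median(lens)),
                mode_len=mode,
                expected_len=exp,
                mode_deviation=None if exp is None else mode - exp,
            )
        )
    return out


def format_percent(p: float) -> str:
    """Percentages to 2 decimals, 4 decimals for rates below 0.01%."""
    return f"{p:.4f}" if 0.0 < p < 0.01 else f"{p:.2f}"


def length_histogram(results: list[ClassificationResult]) -> pd.DataFrame:
    """Counts of read lengths per category in BIN_WIDTH-bp bins."""
    rows = []
    by_cat: dict[str, Counter] = {c: Counter() for c in CLASS_CATEGORIES}
    for r in results:
        by_cat[r.category][(r.read_length // BIN_WIDTH) * BIN_WIDTH] += 1
    for cat in CLASS_CATEGORIES:
        for bin_start in sorted(by_cat[cat]):
            rows.append({"category": cat, "bin_start": bin_start,
                         "count": by_cat[cat][bin_start]})
    return pd.DataFrame(rows, columns=["category", "bin_start", "count"])


def write_report(
    tables: CategoryTable | list[CategoryTable],
    sizes: list[SizeSummary],
    out_prefix: str | Path,
    results: list[ClassificationResult] | None = None,
) -> list[Path]:
    """Write category tables, size summaries and length histograms as TSV/JSON.

    Files: ``<prefix>.categories.tsv``, ``<prefix>.categories.json``,
    ``<prefix>.sizes.tsv``, ``<prefix>.length_hist.tsv``. Ordering is fixed by
    the category vocabulary, so reruns are byte-identical.
    """
    if isinstance(tables, CategoryTable):
        tables = [tables]
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    cat_df = pd.concat([t.to_frame() for t in tables], ignore_index=True)
    cat_df["percent"] = cat_df["percent"].map(format_percent)
    p = prefix.with_suffix(prefix.suffix + ".categories.tsv")
    cat_df.to_csv(p, sep="\t", index=False)
    written.append(p)

    p = prefix.with_suffix(prefix.suffix + ".categories.json")
    payload = [
        {"sample": t.sample, "total": t.total, "counts": t.counts,
         "percent": {c: round(v, 6) for c, v in t.percentages.items()}}
        for t in tables
    ]
    with open(p, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    written.append(p)

    size_df = pd.DataFrame([dataclasses.asdict(s) for s in sizes])
    p = prefix.with_suffix(prefix.suffix + ".sizes.tsv")
    size_df.to_csv(p, sep="\t", index=False)
    written.append(p)

    hist = length_histogram(results) if results is not None else length_histogram([])
    p = prefix.with_suffix(prefix.suffix + ".length_hist.tsv")
    hist.to_csv(p, sep="\t", index=False)
    written.append(p)
    return written
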