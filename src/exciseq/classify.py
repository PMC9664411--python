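"""Editing-outcome classification of amplicon reads.

Each read is matched against the locus FeatureSet: a feature is present when
any of its k-mers occurs in the read or its reverse complement within
``max_dist`` Levenshtein edits (substitutions and indels). A fixed-precedence
decision procedure then assigns exactly one category per read:

1. any AAV backbone k-mer        -> aav_integration
2. an inversion junction k-mer   -> inversion
3. fusion junction, no exon      -> delta_exon
4. exon present, both cut sites disrupted -> indel_both
5. only the 5' cut site disrupted -> indel5
6. only the 3' cut site disrupted -> indel3
7. both cut sites intact         -> unedited
otherwise                        -> unclassified

AAV evidence dominates because backbone k-mers cannot occur in the unedited
amplicon (enforced at feature build time); the inversion junctions outrank
the fusion junction because an inverted molecule retains exon sequence.
"Disrupted" means the intact-site feature was not matched within max_dist, so
junction indels no larger than max_dist are indistinguishable from sequencing
error and are called unedited — a documented detection limit.

Small feature sets are searched directly with edlib (infix alignment, both
strands). AAV backbone features enumerate thousands of stride-1 k-mers; these
are matched through an exact q-gram seed index: any k-mer occurring within
``d`` edits must, by the q-gram pigeonhole bound, share at least two exact
q-grams (q = (k-1)//(d+1)) with the read at mutually consistent offsets, so
only seed pairs satisfying that geometry are verified with edlib. The two
paths are equivalent; the seed index only prunes windows that provably cannot
match.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .dna import revcomp
from .locus import FeatureSet, LocusModel, derive_features
from .reads import ReadRecord

CLASS_CATEGORIES = (
    "unedited",
    "indel5",
    "indel3",
    "indel_both",
    "delta_exon",
    "inversion",
    "aav_integration",
    "unclassified",
)

@dataclasses.dataclass(frozen=True)
class MatchHit:
    feature: str
    kmer: str
    offset: int  # start of the best match, forward-strand read coordinates
    strand: str  # '+' = found in the read, '-' = in its reverse complement
    distance: int


@dataclasses.dataclass
class ClassificationResult:
    read_id: str
    category: str
    evidence: list[MatchHit]
    read_length: int


@dataclasses.dataclass
class CategoryTable:
    """Per-sample category counts and percentages over all classified reads."""

    sample: str
    counts: dict[str, int]
    total: int

    @property
    def percentages(self) -> dict[str, float]:
        if self.total == 0:
            return {c: 0.0 for c in CLASS_CATEGORIES}
        return {c: 100.0 * self.counts.get(c, 0) / self.total for c in CLASS_CATEGORIES}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "sample": self.sample,
                "category": list(CLASS_CATEGORIES),
                "count": [self.counts.get(c, 0) for c in CLASS_CATEGORIES],
                "percent": [pct[c] for c in CLASS_CATEGORIES],
            }
        )


# ---------------------------------------------------------------------------
# matching


def _best_location(res: dict) -> int:
    return min(loc[0] for loc in res["locations"])


def _direct_best_hit(
    kmers: Sequence[str], read: str, read_rc: str, max_dist: int
) -> tuple[int, int, str, str] | None:
    """Best (distance, offset, strand, kmer) over a small k-mer list, or None."""
    best: tuple[int, int, str, str] | None = None
    n = len(read)
    for kmer in kmers:
        for strand, target in (("+", read), ("-", read_rc)):
            res = edlib.align(kmer, target, mode="HW", task="locations", k=max_dist)
            if res["editDistance"] == -1:
                continue
            start = _best_location(res)
            if strand == "-":
                end = max(loc[1] for loc in res["locations"])
                start = n - 1 - end
            cand = (res["editDistance"], start, strand, kmer)
            if best is None or cand[:2] < best[:2]:
                best = cand
    return best


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _qgram_hashes(codes: np.ndarray, q: int) -> np.ndarray:
    if len(codes) < q:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, q).astype(np.int64)
    weights = 4 ** np.arange(q - 1, -1, -1, dtype=np.int64)
    return windows @ weights


def _chain_contigs(kmers: Sequence[str], k: int) -> list[str]:
    """Re-assemble stride-1 k-mer runs into contigs (falls back to singletons)."""
    contigs: list[str] = []
    cur = kmers[0]
    for km in kmers[1:]:
        if km[: k - 1] == cur[-(k - 1) :]:
            cur += km[-1]
        else:
            contigs.append(cur)
            cur = km
    contigs.append(cur)
    return contigs


def _seed_params(k: int, d: int) -> tuple[int, int]:
    """(q, required): q-gram length and guaranteed surviving-seed count.

    A k-mer aligned within d edits keeps >= k-d exactly matched characters in
    at most d+1 runs, hence at least (k-d) - (d+1)(q-1) exact q-gram
    occurrences at mutually consistent diagonals. q is chosen as the largest
    value guaranteeing >= 4 such seeds (falling back to smaller guarantees
    for small k or large d), so chance seed clusters are rare but no true
    match can be missed.
    """
    for target in (4, 2, 1):
        q = (k - d - target) // (d + 1) + 1
        if q >= 4 or target == 1:
            break
    q = max(1, min(q, 24))
    required = max(1, (k - d) - (d + 1) * (q - 1))
    return q, required


class _SeedIndex:
    """Exact q-gram seed index over large (stride-1) feature k-mer sets."""

    def __init__(self, features: dict[str, Sequence[str]], k: int, max_dist: int):
        self.k = k
        self.d = max_dist
        self.q, self.required = _seed_params(k, max_dist)
        gap = k + self.q + 8  # inter-contig spacer in global coordinates
        self.contig_feature: list[str] = []
        self.contig_seq: list[str] = []
        starts: list[int] = []
        hashes: list[np.ndarray] = []
        gpos: list[np.ndarray] = []
        offset = 0
        for name, kmers in features.items():
            for contig in _chain_contigs(kmers, k):
                starts.append(offset)
                self.contig_feature.append(name)
                self.contig_seq.append(contig)
                h = _qgram_hashes(_encode(contig), self.q)
                hashes.append(h)
                gpos.append(np.arange(len(h), dtype=np.int64) + offset)
                offset += len(contig) + gap
        self.contig_starts = np.array(starts, dtype=np.int64)
        allh = np.concatenate(hashes) if hashes else np.empty(0, dtype=np.int64)
        allp = np.concatenate(gpos) if gpos else np.empty(0, dtype=np.int64)
        order = np.argsort(allh, kind="stable")
        self.sorted_hashes = allh[order]
        self.sorted_gpos = allp[order]
        # O(1) hash lookup table when the q-gram space is small enough
        self.space = 4**self.q
        if self.space <= 1 << 24:
            counts = np.bincount(self.sorted_hashes, minlength=self.space)
            self.tab_lo = np.concatenate([[0], np.cumsum(counts)[:-1]])
            self.tab_count = counts
        else:
            self.tab_lo = self.tab_count = None

    def _collisions(self, read: str) -> tuple[np.ndarray, np.ndarray]:
        rh = _qgram_hashes(_encode(read), self.q)
        if not len(rh) or not len(self.sorted_hashes):
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        if self.tab_lo is not None:
            # windows containing non-ACGT bases hash past the table: no match
            ok = (rh >= 0) & (rh < self.space)
            lo = np.zeros(len(rh), dtype=np.int64)
            counts = np.zeros(len(rh), dtype=np.int64)
            lo[ok] = self.tab_lo[rh[ok]]
            counts[ok] = self.tab_count[rh[ok]]
        else:
            lo = np.searchsorted(self.sorted_hashes, rh, side="left")
            hi = np.searchsorted(self.sorted_hashes, rh, side="right")
            counts = hi - lo
        sel = counts > 0
        c = counts[sel]
        if not len(c):
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        # gather sorted_gpos[lo:hi) slices without a python loop
        offs = np.arange(int(c.sum())) - np.repeat(np.cumsum(c) - c, c)
        gi = self.sorted_gpos[np.repeat(lo[sel], c) + offs]
        gj = np.repeat(np.flatnonzero(sel), c)
        return gi, gj

    def search(self, read: str, read_rc: str) -> dict[str, tuple[int, int, str, str]]:
        """Best hit per feature: feature -> (distance, offset, strand, kmer)."""
        best: dict[str, tuple[int, int, str, str]] = {}
        for strand, target in (("+", read), ("-", read_rc)):
            self._search_strand(target, strand, len(read), best)
        return best

    def _search_strand(
        self, target: str, strand: str, read_len: int, best: dict
    ) -> None:
        k, d, q = self.k, self.d, self.q
        gi_a, gj_a = self._collisions(target)
        if not len(gi_a):
            return
        order = np.argsort(gi_a, kind="stable")
        gi_a, gj_a = gi_a[order], gj_a[order]
        ci_a = np.searchsorted(self.contig_starts, gi_a, side="right") - 1
        gi, gj, cis = gi_a.tolist(), gj_a.tolist(), ci_a.tolist()
        diag = [j - i for i, j in zip(gi, gj)]
        verified: dict[int, set[int]] = {}
        done: set[int] = set()  # contigs whose feature already has a 0-distance hit
        n = len(gi)
        win = k - q
        required = self.required
        for a in range(n):
            ci = cis[a]
            if ci in done:
                continue
            ia, da = gi[a], diag[a]
            # cluster: seeds within one k-mer span of ia, on diagonals within
            # +/-d of seed a's (any true match anchors such a cluster at its
            # smallest-position surviving seed)
            count = 1
            i_max = ia
            b = a + 1
            while b < n and gi[b] - ia <= win:
                if abs(diag[b] - da) <= d:
                    count += 1
                    i_max = gi[b]
                b += 1
            if count < required:
                continue
            feat = self.contig_feature[ci]
            cur = best.get(feat)
            if cur is not None and cur[0] == 0:
                done.add(ci)
                continue
            self._verify(ci, ia, i_max, gj[a], target, strand, read_len,
                         verified, best)
            cur = best.get(feat)
            if cur is not None and cur[0] == 0:
                done.add(ci)

    def _verify(
        self,
        ci: int,
        i1: int,
        i2: int,
        j1: int,
        target: str,
        strand: str,
        read_len: int,
        verified: dict[int, set[int]],
        best: dict,
    ) -> None:
        k, d, q = self.k, self.d, self.q
        feat = self.contig_feature[ci]
        contig = self.contig_seq[ci]
        c0 = int(self.contig_starts[ci])
        l1, l2 = i1 - c0, i2 - c0  # seed offsets within the contig
        t_lo = max(0, l2 + q - k)
        t_hi = min(l1, len(contig) - k)
        seen = verified.setdefault(ci, set())
        win_lo = max(0, j1 - (l1 - t_lo) - d - 2)
        win_hi = min(len(target), j1 + k + d + 2)
        window = target[win_lo:win_hi]
        for t in range(t_lo, t_hi + 1):
            if t in seen:
                continue
            seen.add(t)
            kmer = contig[t : t + k]
            res = edlib.align(kmer, window, mode="HW", task="locations", k=d)
            if res["editDistance"] == -1:
                continue
            start = win_lo + _best_location(res)
            if strand == "-":
                end = win_lo + max(loc[1] for loc in res["locations"])
                start = read_len - 1 - end
            cand = (res["editDistance"], start, strand, kmer)
            cur = best.get(feat)
            if cur is None or cand[:2] < cur[:2]:
                best[feat] = cand
            if cand[0] == 0:
                return


class FeatureMatcher:
    """Reusable matcher for one FeatureSet (build once, match many reads).

    By default every feature is matched through the exact q-gram seed index;
    ``use_index=False`` forces a direct per-k-mer edlib search instead. The
    two paths find the same feature hits at the same distances (the index
    only prunes windows that provably cannot match); the direct path exists
    as the simple reference implementation and for cross-checking.
    """

    def __init__(self, fs: FeatureSet, use_index: bool = True):
        fs.validate()
        self.fs = fs
        if use_index:
            self.direct: dict[str, list[str]] = {}
            self.index: _SeedIndex | None = _SeedIndex(fs.features, fs.k, fs.max_dist)
        else:
            self.direct = dict(fs.features)
            self.index = None

    def match(self, read: ReadRecord | str) -> list[MatchHit]:
        bases = read if isinstance(read, str) else read.bases
        rc = revcomp(bases)
        hits: list[MatchHit] = []
        for name, kmers in self.direct.items():
            found = _direct_best_hit(kmers, bases, rc, self.fs.max_dist)
            if found is not None:
                dist, off, strand, kmer = found
                hits.append(MatchHit(name, kmer, off, strand, dist))
        if self.index is not None:
            for name, (dist, off, strand, kmer) in self.index.search(bases, rc).items():
                hits.append(MatchHit(name, kmer, off, strand, dist))
        return hits


def match_features(read: ReadRecord | str, fs: FeatureSet) -> list[MatchHit]:
    """Best hit per feature for one read (builds a throwaway matcher).

    For whole libraries, build a :class:`FeatureMatcher` once instead.
    """
    return FeatureMatcher(fs).match(read)


# ---------------------------------------------------------------------------
# decision procedure


def classify_read(
    hits: list[MatchHit], read_id: str = "", read_length: int = 0
) -> ClassificationResult:
    """Assign exactly one category from the feature hits (fixed precedence)."""
    present = {h.feature for h in hits}
    has = present.__contains__
    if any(f.startswith("aav:") for f in present):
        cat = "aav_integration"
    elif has("inversion_left") or has("inversion_right"):
        cat = "inversion"
    elif has("fusion") and not has("exon_internal"):
        cat = "delta_exon"
    elif has("exon_internal") and not has("intact5") and not has("intact3"):
        cat = "indel_both"
    elif not has("intact5") and has("intact3"):
        cat = "indel5"
    elif not has("intact3") and has("intact5"):
        cat = "indel3"
    elif has("intact5") and has("intact3"):
        cat = "unedited"
    else:
        cat = "unclassified"
    return ClassificationResult(read_id, cat, hits, read_length)


def classify_library(
    reads: Iterable[ReadRecord],
    fs: FeatureSet,
    sample: str = "library",
) -> tuple[list[ClassificationResult], CategoryTable]:
    """Match and classify every read; returns per-read results and the table."""
    matcher = FeatureMatcher(fs)
    results: list[ClassificationResult] = []
    counts = {c: 0 for c in CLASS_CATEGORIES}
    for read in reads:
        res = classify_read(matcher.match(read), read.id, len(read))
        results.append(res)
        counts[res.category] += 1
    if not results:
        warnings.warn(f"{sample}: empty input, empty category table", stacklevel=2)
    table = CategoryTable(sample=sample, counts=counts, total=len(results))
    return results, table


def results_to_frame(results: list[ClassificationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        ev = ";".join(
            f"{h.feature}@{h.offset}{h.strand}d{h.distance}" for h in sorted(
                r.evidence, key=lambda h: (h.distance, h.offset, h.feature)
            )
        )
        rows.append(
            {"read_id": r.read_id, "category": r.category, "length": r.read_length,
             "evidence": ev}
        )
    return pd.DataFrame(rows, columns=["read_id", "category", "length", "evidence"])


# ---------------------------------------------------------------------------
# control-library parameter optimization


@dataclasses.dataclass
class OptimizeResult:
    k: int
    max_dist: int
    diagnostics: pd.DataFrame


def optimize_params(
    control: Sequence[ReadRecord],
    locus: LocusModel,
    k_values: Sequence[int],
    max_dist_values: Sequence[int],
    **feature_kwargs,
) -> OptimizeResult:
    """Pick (k, max_dist) minimizing false calls on an untreated control.

    The control library is unedited by construction, so the objective for
    each grid cell is the fraction of control reads assigned to any category
    other than unedited. Ties break toward larger max_dist (more error
    tolerance), then smaller k. Cells whose feature set is non-diagnostic for
    the locus (a junction or backbone k-mer occurs in the unedited amplicon
    within max_dist — typical for short k with high tolerance) are reported
    as infeasible and excluded from selection.
    """
    if not k_values or not max_dist_values:
        raise ValueError("parameter grid is empty")
    rows = []
    for k in k_values:
        for d in max_dist_values:
            try:
                fs = derive_features(locus, k=k, max_dist=d, **feature_kwargs)
            except ValueError as err:
                rows.append({"k": k, "max_dist": d, "objective": np.nan,
                             "n_reads": 0, "n_misclassified": 0,
                             "note": str(err).split(":")[0]})
                continue
            _, table = classify_library(control, fs, sample=f"control_k{k}_d{d}")
            bad = table.total - table.counts.get("unedited", 0)
            objective = bad / table.total if table.total else 0.0
            rows.append({"k": k, "max_dist": d, "objective": objective,
                         "n_reads": table.total, "n_misclassified": bad, "note": ""})
    diag = pd.DataFrame(rows)
    feasible = diag.dropna(subset=["objective"])
    if feasible.empty:
        raise ValueError("no feasible (k, max_dist) cell for this locus")
    best = feasible.sort_values(
        ["objective", "max_dist", "k"], ascending=[True, False, True], kind="stable"
    ).iloc[0]
    return OptimizeResult(k=int(best["k"]), max_dist=int(best["max_dist"]), diagnostics=diag)
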