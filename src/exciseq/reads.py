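"""Read records and FASTQ I/O (Phred+33, via Biopython)."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MAX_PHRED = 93


@dataclasses.dataclass
class ReadRecord:
    """One sequencing read with per-base Phred qualities.

    ``sample`` and ``orientation`` are filled in by demultiplexing;
    orientation is 'forward', 'reverse', or 'unknown'.
    """

    id: str
    bases: str
    quals: np.ndarray  # integer Phred scores, one per base
    sample: str | None = None
    orientation: str = "unknown"

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if len(self.bases) != len(self.quals):
            raise ValueError(f"{self.id}: {len(self.bases)} bases vs {len(self.quals)} quals")
        if len(self.quals) and (self.quals.min() < 0 or self.quals.max() > MAX_PHRED):
            raise ValueError(f"{self.id}: Phred scores must lie in [0, {MAX_PHRED}]")

    def __len__(self) -> int:
        return len(self.bases)


ReadSet = list  # a ReadSet is simply a list[ReadRecord]


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(
            id=rec.id,
            bases=str(rec.seq),
            quals=np.array(rec.letter_annotations["phred_quality"], dtype=np.int64),
        )


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.bases), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = [int(q) for q in r.quals]
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n
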