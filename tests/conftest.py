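"""Shared fixtures: demo locus, feature sets, and simulated libraries.

Library fixtures are session-scoped because simulation and classification of
thousands of reads dominate suite runtime; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from exciseq.classify import classify_library
from exciseq.demo import demo_locus
from exciseq.demux import demultiplex, quality_length_filter
from exciseq.dna import revcomp
from exciseq.locus import LocusModel, build_locus, derive_features
from exciseq.simulate import SimConfig, ZERO_ERROR, simulate_library

BASES = np.array(list("ACGT"))


def make_random_locus(
    rng: np.random.Generator,
    length: int = 600,
    cut5: int = 150,
    cut3: int = 430,
    exon: tuple[int, int] = (220, 360),
    n_backbones: int = 0,
) -> LocusModel:
    """Random amplicon with implanted guide sites (guide5 +, guide3 -)."""
    seq = list(BASES[rng.integers(0, 4, size=length)])
    s5 = cut5 - 18  # 21-nt protospacer on + strand, PAM just 3' of it
    pam5 = s5 + 21
    seq[pam5 + 2], seq[pam5 + 3], seq[pam5 + 4], seq[pam5 + 5] = "G", "A", "G", "T"
    s3 = cut3 - 3  # 21-nt protospacer on - strand
    seq[s3 - 6], seq[s3 - 5], seq[s3 - 4], seq[s3 - 3] = "A", "C", "T", "C"
    ref = "".join(seq)
    backbones = [
        (f"vec{i}", "".join(BASES[rng.integers(0, 4, size=500)]))
        for i in range(n_backbones)
    ]
    return build_locus(
        reference=ref,
        protospacer5=ref[s5 : s5 + 21],
        protospacer3=revcomp(ref[s3 : s3 + 21]),
        exon_interval=exon,
        aav_backbones=backbones,
    )


@pytest.fixture(scope="session")
def locus():
    return demo_locus()


@pytest.fixture(scope="session")
def features(locus):
    return derive_features(locus)


@pytest.fixture(scope="session")
def zero_error_library(locus):
    cfg = SimConfig(n_reads=5000, seed=7, error_model=ZERO_ERROR)
    reads, truth = simulate_library(locus, cfg)
    return cfg, reads, truth


@pytest.fixture(scope="session")
def noisy_library(locus):
    cfg = SimConfig(n_reads=3000, seed=11)
    reads, truth = simulate_library(locus, cfg)
    return cfg, reads, truth


@pytest.fixture(scope="session")
def zero_error_classified(zero_error_library, features, locus):
    """Full pipeline on the zero-error library: demux -> filter -> classify."""
    cfg, reads, truth = zero_error_library
    buckets, demux_report = demultiplex(reads, cfg.barcode_pairs)
    pooled = [r for s in sorted(buckets) if s != "unassigned" for r in buckets[s]]
    passed, filter_report = quality_length_filter(pooled)
    results, table = classify_library(passed, features)
    return {
        "cfg": cfg,
        "truth": truth,
        "demux_report": demux_report,
        "filter_report": filter_report,
        "passed_reads": passed,
        "results": results,
        "table": table,
    }
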