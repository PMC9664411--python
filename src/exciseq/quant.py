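"""qPCR quantification arithmetic.

Absolute quantification against standard curves (Cq = m*log10(copies) + b),
the exon-skipped transcript fraction, AAV vector genomes per host genome, and
efficiency-corrected (Pfaffl) relative expression ratios.

Conventions: the amplification factor is A = 10^(-1/m) (A = 2 for perfect
doubling) and the efficiency E = A - 1 is reported as a fraction. Technical
replicates are combined by mean Cq before conversion to copies. The Pfaffl
delta-Cq sign is control minus sample, so ratios above 1 mean the target is
up in the sample.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: mass of one diploid mouse genome equivalent, used to convert a gDNA
#: standard of known mass into genome copies
PG_PER_DIPLOID_GENOME = 6.6


@dataclasses.dataclass(frozen=True)
class StandardCurve:
    """Least-squares qPCR calibration line Cq = slope*log10(copies) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    @property
    def amplification_factor(self) -> float:
        return 10.0 ** (-1.0 / self.slope)

    @property
    def efficiency(self) -> float:
        """Fractional efficiency; 1.0 (100%) corresponds to perfect doubling."""
        return self.amplification_factor - 1.0

    def copies_from_cq(self, cq: float) -> float:
        return 10.0 ** ((cq - self.intercept) / self.slope)

    def cq_from_copies(self, copies: float) -> float:
        if copies <= 0:
            raise ValueError("copies must be positive")
        return self.slope * np.log10(copies) + self.intercept


def fit_standard_curve(dilutions: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit a standard curve to (copies, Cq) dilution points.

    Requires at least three points with positive copy numbers; the slope must
    come out negative (more template, earlier Cq) or the curve is rejected.
    """
    if len(dilutions) < 3:
        raise ValueError("standard curve requires >= 3 dilution points")
    copies = np.array([c for c, _ in dilutions], dtype=np.float64)
    cq = np.array([q for _, q in dilutions], dtype=np.float64)
    if (copies <= 0).any():
        raise ValueError("copy numbers must be positive")
    x = np.log10(copies)
    slope, intercept = np.polyfit(x, cq, 1)
    if slope >= 0:
        raise ValueError("invalid curve: non-negative slope")
    pred = slope * x + intercept
    ss_res = float(np.sum((cq - pred) ** 2))
    ss_tot = float(np.sum((cq - cq.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return StandardCurve(float(slope), float(intercept), r2, len(dilutions))


def percent_skipped(copies_dex: float, copies_fl: float) -> float:
    """Exon-skipped transcripts as % of total (skipped + full-length)."""
    if copies_dex < 0 or copies_fl < 0:
        raise ValueError("copy numbers must be non-negative")
    total = copies_dex + copies_fl
    if total == 0:
        raise ValueError("percent_skipped undefined when both copy numbers are zero")
    return 100.0 * copies_dex / total


def vg_per_genome(
    vg_copies: float,
    genome_copies: float,
    per_diploid_genome: bool = False,
    ploidy: int = 2,
) -> float:
    """AAV vector genome copies per host genome.

    ``genome_copies`` is typically measured with a single-copy-gene assay,
    which counts one copy per haploid genome per ploidy level. With
    ``per_diploid_genome`` the denominator is divided by ``ploidy`` to report
    vector genomes per diploid genome equivalent (off by default).
    """
    if genome_copies <= 0:
        raise ValueError("genome_copies must be positive")
    denom = genome_copies / ploidy if per_diploid_genome else genome_copies
    return vg_copies / denom


def mass_to_genome_copies(mass_pg: float, pg_per_genome: float = PG_PER_DIPLOID_GENOME) -> float:
    """Convert a gDNA mass in picograms to diploid genome copies."""
    if mass_pg < 0:
        raise ValueError("mass must be non-negative")
    return mass_pg / pg_per_genome


def pfaffl_ratio(e_target: float, dcq_target: float, e_ref: float, dcq_ref: float) -> float:
    """Efficiency-corrected expression ratio (E_t^dCq_t) / (E_r^dCq_r).

    Efficiencies are amplification factors in (1, 2.2]; delta-Cq is
    Cq(control) - Cq(sample).
    """
    for name, e in (("e_target", e_target), ("e_ref", e_ref)):
        if not 1.0 < e <= 2.2:
            raise ValueError(f"{name} must be an amplification factor in (1, 2.2], got {e}")
    return (e_target**dcq_target) / (e_ref**dcq_ref)


# ---------------------------------------------------------------------------
# Cq tables


def read_cq_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns sample, assay, cq (and optional replicate)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "assay", "cq"} - set(df.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    return df


def mean_cq(cq_table: pd.DataFrame) -> pd.DataFrame:
    """Mean Cq over technical replicates, per (sample, assay)."""
    return (
        cq_table.groupby(["sample", "assay"], as_index=False)["cq"]
        .mean()
        .rename(columns={"cq": "mean_cq"})
    )


def absolute_quantify(
    cq_table: pd.DataFrame, curves: dict[str, StandardCurve]
) -> pd.DataFrame:
    """Convert replicate-averaged Cq values to absolute copies per assay."""
    df = mean_cq(cq_table)
    df = df[df["assay"].isin(curves)].copy()
    df["copies"] = [
        curves[a].copies_from_cq(c) for a, c in zip(df["assay"], df["mean_cq"])
    ]
    return df


def percent_skipped_table(
    quant: pd.DataFrame, fl_assay: str, dex_assay: str
) -> pd.DataFrame:
    """Per-sample %skipped from an absolute_quantify result."""
    wide = quant.pivot(index="sample", columns="assay", values="copies")
    out = pd.DataFrame(
        {
            "sample": wide.index,
            "copies_fl": wide[fl_assay].to_numpy(),
            "copies_dex": wide[dex_assay].to_numpy(),
        }
    )
    out["percent_dex"] = [
        percent_skipped(d, f) for d, f in zip(out["copies_dex"], out["copies_fl"])
    ]
    return out.reset_index(drop=True)
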