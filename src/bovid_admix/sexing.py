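"""Molecular sexing from X-vs-autosome read densities and sex-bias tests.

Rx compares the read density on the X chromosome to each autosome's: a
female (XX) carries the X at the same copy number as autosomes (Rx ~ 1),
a male (XY) at half (Rx ~ 0.5).  The cattle karyotype has 29 autosomes, so
Rx is the mean of 29 per-autosome ratios with a CI from their spread.

Sex-biased admixture leaves a footprint on the X: with mostly male wild
migrants, X-chromosomal wild ancestry falls below autosomal.  The bias
test compares jackknife ancestry estimates from the disjoint chromosome
sets with an independent-errors Z statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

N_AUTOSOMES = 29


@dataclass
class CoverageSummary:
    """Mapped-read counts and lengths for 29 autosomes plus X."""

    chroms: list
    lengths: np.ndarray
    counts: np.ndarray
    x_label: str = "X"

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.chroms) != N_AUTOSOMES + 1:
            raise ValueError(
                f"expected {N_AUTOSOMES} autosomes plus X "
                f"({N_AUTOSOMES + 1} entries), got {len(self.chroms)}")
        if self.x_label not in self.chroms:
            raise ValueError(f"no {self.x_label!r} chromosome in summary")
        if (self.counts < 0).any():
            raise ValueError("negative read count")

    @property
    def total_reads(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_idxstats(cls, path: str, x_label: str = "X") -> "CoverageSummary":
        """Read a samtools-idxstats-style TSV (chrom, length, mapped)."""
        chroms, lengths, counts = [], [], []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts or parts[0] in ("*",):
                    continue
                chroms.append(parts[0])
                lengths.append(float(parts[1]))
                counts.append(float(parts[2]))
        return cls(chroms, lengths, counts, x_label=x_label)


@dataclass
class SexAssignment:
    rx: float
    ci: tuple
    sex: str  # "XX", "XY" or "unassigned"


@dataclass
class SexBiasResult:
    alpha_auto: float
    se_auto: float
    alpha_x: float
    se_x: float
    z: float
    p_value: float


def rx_statistic(cov: CoverageSummary) -> tuple:
    """Mean X/autosome density ratio over the 29 autosomes, with 95% CI."""
    if cov.total_reads == 0:
        raise ValueError("no mapped reads")
    ix = cov.chroms.index(cov.x_label)
    total_len = cov.lengths.sum()
    rates = (cov.counts / cov.total_reads) / (cov.lengths / total_len)
    auto_idx = [i for i in range(len(cov.chroms)) if i != ix]
    zero = [cov.chroms[i] for i in auto_idx if cov.counts[i] == 0]
    if zero:
        raise ValueError(f"zero mapped reads on autosome(s) {zero}")
    ratios = rates[ix] / rates[auto_idx]
    rx = float(ratios.mean())
    half = 1.96 * float(ratios.std(ddof=1)) / np.sqrt(len(ratios)) \
        if len(ratios) > 1 else 0.0
    return rx, (rx - half, rx + half)


def assign_sex(rx_ci: tuple, female_min: float = 0.8,
               male_max: float = 0.6) -> SexAssignment:
    """XX when the whole CI sits above female_min, XY when below male_max."""
    rx, (lo, hi) = rx_ci
    if lo > female_min:
        sex = "XX"
    elif hi < male_max:
        sex = "XY"
    else:
        sex = "unassigned"
    return SexAssignment(rx, (lo, hi), sex)


def sex_bias_test(alpha_auto, alpha_x) -> SexBiasResult:
    """Z test for autosomal vs X-chromosomal ancestry.

    Positive Z = less wild ancestry on the X, the signature of male-biased
    wild introgression.  X and autosomal blocks are disjoint chromosomes,
    so the two jackknife errors are treated as independent.
    """
    se_a, se_x = alpha_auto.se, alpha_x.se
    if se_a == 0 and se_x == 0:
        raise ValueError("both estimates have zero SE; Z undefined")
    z = (alpha_auto.estimate - alpha_x.estimate) / np.sqrt(se_a ** 2 + se_x ** 2)
    p = 2 * sps.norm.sf(abs(z))
    return SexBiasResult(alpha_auto.estimate, se_a, alpha_x.estimate, se_x,
                         float(z), float(p))
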