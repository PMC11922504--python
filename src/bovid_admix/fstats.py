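"""f-statistics with weighted block jackknife and the f4-ratio estimator.

f2, f3 and f4 are moments of allele-frequency differences:

    f2(A,B)   = E[(pA - pB)^2]
    f3(O;A,B) = E[(pO - pA)(pO - pB)]
    f4(A,B;C,D) = E[(pA - pB)(pC - pD)]

estimated as weighted means over sites, complete cases per statistic, with
standard errors from a weighted delete-one-block jackknife over contiguous
genomic blocks (default 5 Mbp) to absorb linkage.  The f4-ratio

    alpha = 1 - f4(O1, O2; X, Wild) / f4(O1, O2; Dom, Wild)

estimates the Wild ancestry proportion in a target X admixed between Wild
and Dom, given O1 shares drift with Wild relative to Dom.  No small-sample
heterozygosity correction is applied: with single pseudohaploid genomes per
population (the common ancient-DNA case) no unbiased correction exists, a
known bias shared with the field's standard tooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


class NoDataError(ValueError):
    """Raised when a statistic has zero usable sites."""


@dataclass(frozen=True)
class PopulationSpec:
    """A named set of individuals from a GenotypeMatrix."""

    name: str
    members: tuple

    def __init__(self, name: str, members: Sequence[str]):
        if not members:
            raise ValueError(f"population {name!r} has no members")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", tuple(members))


@dataclass
class FStatResult:
    """An f-statistic estimate with jackknife uncertainty."""

    kind: str
    pops: tuple
    estimate: float
    se: float
    n_blocks: int
    n_sites: int

    @property
    def ci(self) -> tuple:
        return (self.estimate - 1.96 * self.se, self.estimate + 1.96 * self.se)

    @property
    def z(self) -> float:
        return self.estimate / self.se if self.se > 0 else np.inf

    def __repr__(self):
        lo, hi = self.ci
        return (f"{self.kind}{self.pops} = {self.estimate:.6g} "
                f"+/- {self.se:.3g} [{lo:.4g}, {hi:.4g}] "
                f"({self.n_sites} sites, {self.n_blocks} blocks)")


class BlockPartition:
    """Contiguous genomic blocks (half-open) used for the jackknife."""

    def __init__(self, block_ids: np.ndarray, intervals: list | None = None):
        block_ids = np.asarray(block_ids, dtype=np.int64)
        self.block_ids = block_ids
        self.n_blocks = int(block_ids.max()) + 1 if block_ids.size else 0
        self.intervals = intervals or []

    @classmethod
    def from_panel(cls, panel, block_size: int = 5_000_000) -> "BlockPartition":
        """Assign every panel site to a (chrom, 5 Mbp window) block."""
        keys = [(c, (p - 1) // block_size) for c, p in zip(panel.chrom, panel.pos)]
        uniq = sorted(set(keys))
        lookup = {k: i for i, k in enumerate(uniq)}
        ids = np.array([lookup[k] for k in keys], dtype=np.int64)
        intervals = [(c, w * block_size, (w + 1) * block_size) for c, w in uniq]
        return cls(ids, intervals)

    @classmethod
    def equal_site_blocks(cls, n_sites: int, n_blocks: int) -> "BlockPartition":
        """SNP-count blocks, the convention of some f4-ratio tools."""
        ids = np.minimum(np.arange(n_sites) * n_blocks // max(n_sites, 1),
                         n_blocks - 1)
        return cls(ids)

    def site_counts(self, mask: np.ndarray) -> np.ndarray:
        return np.bincount(self.block_ids[mask], minlength=self.n_blocks)


def allele_freq(pop: PopulationSpec, matrix, site_subset=None) -> np.ma.MaskedArray:
    """Alt-allele frequency per site over non-missing calls; masked when all
    members are missing."""
    calls = matrix.rows(pop.members).astype(float)
    calls[calls < 0] = np.nan
    if site_subset is not None:
        calls = calls[:, site_subset]
    defined = np.sum(~np.isnan(calls), axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(defined > 0, np.nansum(calls, axis=0)
                        / np.maximum(defined, 1), np.nan)
    return np.ma.masked_invalid(freq)


def block_jackknife(values: np.ndarray, weights: np.ndarray) -> tuple:
    """Weighted delete-one block jackknife for a weighted mean.

    ``values`` are per-block means, ``weights`` the usable-site counts.
    Returns (estimate, SE) with the Busing et al. weighted jackknife
    variance; with equal weights this reduces to the classical delete-one
    jackknife, i.e. SE = SD(values, ddof=1)/sqrt(B) for the plain mean.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    used = weights > 0
    values, weights = values[used], weights[used]
    B = values.size
    if B < 2:
        raise NoDataError("jackknife SE undefined with fewer than 2 blocks")
    n = weights.sum()
    total = float(np.dot(values, weights))
    theta = total / n
    loo = (total - values * weights) / (n - weights)
    h = n / weights
    theta_j = B * theta - float(np.sum((1 - weights / n) * loo))
    tau = h * theta - (h - 1) * loo
    var = float(np.sum((tau - theta_j) ** 2 / (h - 1)) / B)
    return theta, np.sqrt(var)


def _per_block(terms: np.ndarray, defined: np.ndarray,
               blocks: BlockPartition) -> tuple:
    """Per-block sums of statistic terms and usable-site counts."""
    ids = blocks.block_ids
    sums = np.bincount(ids[defined], weights=terms[defined],
                       minlength=blocks.n_blocks)
    counts = np.bincount(ids[defined], minlength=blocks.n_blocks).astype(float)
    return sums, counts


def _freqs(matrix, pops):
    return [allele_freq(p, matrix) for p in pops]


def _fstat_from_terms(kind, names, terms, defined, blocks) -> FStatResult:
    n_sites = int(defined.sum())
    if n_sites == 0:
        raise NoDataError(f"{kind}{tuple(names)}: no sites with all "
                          "populations defined")
    sums, counts = _per_block(terms, defined, blocks)
    used = counts > 0
    if used.sum() < 2:
        est = float(sums.sum() / counts.sum())
        return FStatResult(kind, tuple(names), est, np.nan, int(used.sum()),
                           n_sites)
    est, se = block_jackknife(sums[used] / counts[used], counts[used])
    return FStatResult(kind, tuple(names), est, se, int(used.sum()), n_sites)


def f4_from_freqs(pa, pb, pc, pd, blocks: BlockPartition,
                  names=("A", "B", "C", "D")) -> FStatResult:
    pa, pb, pc, pd = (np.ma.masked_invalid(np.ma.filled(np.ma.asarray(p), np.nan))
                      for p in (pa, pb, pc, pd))
    defined = ~(pa.mask | pb.mask | pc.mask | pd.mask)
    terms = np.ma.filled((pa - pb) * (pc - pd), 0.0)
    return _fstat_from_terms("f4", names, terms, np.asarray(defined), blocks)


def f4(a, b, c, d, matrix, blocks) -> FStatResult:
    fa, fb, fc, fd = _freqs(matrix, (a, b, c, d))
    return f4_from_freqs(fa, fb, fc, fd, blocks,
                         names=(a.name, b.name, c.name, d.name))


def f3_from_freqs(po, pa, pb, blocks, names=("O", "A", "B")) -> FStatResult:
    po, pa, pb = (np.ma.masked_invalid(np.ma.filled(np.ma.asarray(p), np.nan))
                  for p in (po, pa, pb))
    defined = ~(po.mask | pa.mask | pb.mask)
    terms = np.ma.filled((po - pa) * (po - pb), 0.0)
    return _fstat_from_terms("f3", names, terms, np.asarray(defined), blocks)


def f3(o, a, b, matrix, blocks) -> FStatResult:
    fo, fa, fb = _freqs(matrix, (o, a, b))
    return f3_from_freqs(fo, fa, fb, blocks, names=(o.name, a.name, b.name))


def f2_from_freqs(pa, pb, blocks, names=("A", "B")) -> FStatResult:
    pa, pb = (np.ma.masked_invalid(np.ma.filled(np.ma.asarray(p), np.nan))
              for p in (pa, pb))
    defined = ~(pa.mask | pb.mask)
    terms = np.ma.filled((pa - pb) ** 2, 0.0)
    return _fstat_from_terms("f2", names, terms, np.asarray(defined), blocks)


def f2(a, b, matrix, blocks) -> FStatResult:
    fa, fb = _freqs(matrix, (a, b))
    return f2_from_freqs(fa, fb, blocks, names=(a.name, b.name))


def f4_ratio_from_freqs(px, p_wild, p_dom, p_o1, p_o2, blocks,
                        names=("X", "Wild", "Dom", "O1", "O2"),
                        denominator_tol: float = 1e-12) -> FStatResult:
    """alpha = 1 - f4(O1,O2;X,Wild)/f4(O1,O2;Dom,Wild) with jackknife SE.

    The SE recomputes the full ratio on each leave-one-block-out replicate
    (not the delta method).  alpha is not clamped to [0, 1]: sampling noise
    legitimately produces estimates outside the unit interval.
    """
    arrs = [np.ma.masked_invalid(np.ma.filled(np.ma.asarray(p), np.nan))
            for p in (px, p_wild, p_dom, p_o1, p_o2)]
    px, pw, pd_, po1, po2 = arrs

    def block_stats(left_diff, right_diff, defined):
        terms = np.ma.filled(left_diff * right_diff, 0.0)
        return _per_block(terms, np.asarray(defined), blocks)

    num_def = ~(po1.mask | po2.mask | px.mask | pw.mask)
    den_def = ~(po1.mask | po2.mask | pd_.mask | pw.mask)
    if not num_def.any() or not den_def.any():
        raise NoDataError("f4-ratio: no usable sites in numerator or denominator")
    num_sums, num_counts = block_stats(po1 - po2, px - pw, num_def)
    den_sums, den_counts = block_stats(po1 - po2, pd_ - pw, den_def)

    def ratio(ns, nc, ds, dc):
        num = ns.sum() / nc.sum()
        den = ds.sum() / dc.sum()
        if abs(den) < denominator_tol:
            raise ZeroDivisionError(
                f"f4-ratio denominator f4({names[3]},{names[4]};{names[2]},"
                f"{names[1]}) = {den:.3g} is numerically zero: the chosen "
                "outgroup shares no drift with the source contrast")
        return 1.0 - num / den

    alpha = ratio(num_sums, num_counts, den_sums, den_counts)
    used = (num_counts > 0) | (den_counts > 0)
    block_idx = np.flatnonzero(used)
    B = block_idx.size
    if B < 2:
        return FStatResult("f4_ratio", tuple(names), alpha, np.nan, B,
                           int(num_def.sum()))
    loo = np.empty(B)
    for k, j in enumerate(block_idx):
        keep = np.ones(blocks.n_blocks, dtype=bool)
        keep[j] = False
        loo[k] = ratio(num_sums[keep], num_counts[keep],
                       den_sums[keep], den_counts[keep])
    weights = (num_counts + den_counts)[block_idx]
    n = weights.sum()
    h = n / weights
    theta_j = B * alpha - float(np.sum((1 - weights / n) * loo))
    tau = h * alpha - (h - 1) * loo
    var = float(np.sum((tau - theta_j) ** 2 / (h - 1)) / B)
    res = FStatResult("f4_ratio", tuple(names), alpha, np.sqrt(var), B,
                      int(num_def.sum()))
    den_est, den_se = block_jackknife(
        den_sums[den_counts > 0] / den_counts[den_counts > 0],
        den_counts[den_counts > 0])
    res.denominator = den_est
    res.denominator_weak = abs(den_est) < 2 * den_se
    return res


def f4_ratio(x, european_aurochs, anatolian_domestic, o1, o2, matrix,
             blocks) -> FStatResult:
    fx, fw, fd, fo1, fo2 = _freqs(
        matrix, (x, european_aurochs, anatolian_domestic, o1, o2))
    return f4_ratio_from_freqs(
        fx, fw, fd, fo1, fo2, blocks,
        names=(x.name, european_aurochs.name, anatolian_domestic.name,
               o1.name, o2.name))


def outgroup_f3_matrix(pops: Sequence[PopulationSpec], outgroup, matrix,
                       blocks) -> tuple:
    """Symmetric matrix of outgroup-f3 shared-drift estimates.

    Diagonal entries are f3(O; a, a).  Returns (labels, matrix of floats).
    """
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    fo = allele_freq(outgroup, matrix)
    freqs = [allele_freq(p, matrix) for p in pops]
    n = len(pops)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            try:
                res = f3_from_freqs(fo, freqs[i], freqs[j], blocks,
                                    names=(outgroup.name, pops[i].name,
                                           pops[j].name))
            except NoDataError as err:
                raise NoDataError(
                    f"outgroup-f3 pair ({pops[i].name}, {pops[j].name}): {err}"
                ) from err
            out[i, j] = out[j, i] = res.estimate
    return [p.name for p in pops], out


def f4_profile(x, ref_wild, ref_domestic, outgroup, matrix,
               blocks) -> FStatResult:
    """f4(Outgroup, X; Domestic, Wild): positive = excess wild allele sharing."""
    return f4(outgroup, x, ref_domestic, ref_wild, matrix, blocks)


def spearman_compare(estimates_a, estimates_b) -> tuple:
    """Spearman rank correlation (mid-ranks, t-approximation p-value)."""
    a = np.asarray(estimates_a, dtype=float)
    b = np.asarray(estimates_b, dtype=float)
    if a.size < 3 or a.size != b.size:
        raise ValueError("need >= 3 paired estimates")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(a, b)
    return float(rho), float(p)
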