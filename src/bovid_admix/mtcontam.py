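"""Mitochondrial contamination from nearly-private consensus alleles.

The sample's mitogenome consensus is compared to a reference panel of
diverse mitogenomes.  Positions where the consensus allele is rare in the
panel (< 5% by default) are diagnostic: a read not matching the consensus
there most plausibly comes from a contaminating individual.  At each
diagnostic site with sufficient depth one read is drawn, and the fraction
of non-consensus draws estimates the contamination fraction with binomial
uncertainty (one draw per site avoids pseudo-replicating reads within a
site).  Transition mismatches at C/G-consensus sites are excluded because
post-mortem C->T / G->A damage mimics contamination there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import SitePile, is_transition

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class MitoPanel:
    """Aligned mitogenome collection with per-position allele frequencies."""

    def __init__(self, sequences: list, names: list | None = None):
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError("panel sequences must share one aligned length")
        self.sequences = [s.upper() for s in sequences]
        self.names = names or [f"mt{i}" for i in range(len(sequences))]
        self.length = lengths.pop()
        counts = np.zeros((self.length, 4))
        for seq in self.sequences:
            for i, b in enumerate(seq):
                if b in BASE_INDEX:
                    counts[i, BASE_INDEX[b]] += 1
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            self.frequencies = np.where(totals > 0, counts / totals, 0.0)
        self._counts = counts

    def __len__(self) -> int:
        return len(self.sequences)

    def allele_frequency(self, pos: int, base: str) -> float:
        """Frequency of ``base`` at 0-based ``pos`` over non-gap alleles."""
        if base not in BASE_INDEX:
            return 0.0
        return float(self.frequencies[pos, BASE_INDEX[base]])

    def major_allele(self, pos: int) -> str:
        if self._counts[pos].sum() == 0:
            return "N"
        return BASES[int(np.argmax(self._counts[pos]))]

    @classmethod
    def from_fasta(cls, path: str) -> "MitoPanel":
        names, seqs, current = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if current:
                        seqs.append("".join(current))
                        current = []
                    names.append(line[1:].split()[0])
                elif line:
                    current.append(line)
        if current:
            seqs.append("".join(current))
        return cls(seqs, names)


@dataclass
class ContaminationEstimate:
    """A binomial contamination fraction with its site counts."""

    estimate: float
    se: float
    ci: tuple
    n_informative_sites: int
    n_nonconsensus: int
    site_details: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_nonconsensus > self.n_informative_sites:
            raise ValueError("more mismatching draws than informative sites")
        if self.ci[0] > self.ci[1]:
            raise ValueError("CI bounds inverted")


def call_mito_consensus(piles: dict, length: int, min_bq: int = 30,
                        min_mq: int = 30) -> tuple:
    """Majority-base consensus per position; N where nothing passes.

    ``piles`` maps 0-based position -> SitePile.  Ties are broken by the
    fixed base order A < C < G < T.  Returns (sequence, depth array).
    """
    consensus = []
    depth = np.zeros(length, dtype=int)
    for pos in range(length):
        pile = piles.get(pos)
        counts = np.zeros(4, dtype=int)
        if pile is not None:
            for o in pile.observations:
                if (o.base in BASE_INDEX and o.base_quality >= min_bq
                        and o.mapping_quality >= min_mq):
                    counts[BASE_INDEX[o.base]] += 1
        depth[pos] = counts.sum()
        consensus.append(BASES[int(np.argmax(counts))] if depth[pos] else "N")
    return "".join(consensus), depth


def find_private_sites(consensus: str, panel: MitoPanel,
                       freq_max: float = 0.05) -> list:
    """0-based positions whose consensus allele is rare (< freq_max) in the
    panel; N positions are excluded."""
    if len(consensus) != panel.length:
        raise ValueError(
            f"consensus length {len(consensus)} != panel length {panel.length}")
    out = []
    for pos, base in enumerate(consensus):
        if base == "N":
            continue
        if panel.allele_frequency(pos, base) < freq_max:
            out.append(pos)
    return out


def binomial_estimate(n_nonconsensus: int, n_sites: int,
                      interval: str = "normal") -> ContaminationEstimate:
    """Point estimate, SE and 95% CI (truncated to [0, 1]) from counts."""
    if n_sites == 0:
        raise ValueError("zero informative sites: contamination inestimable "
                         "(distinct from an estimate of 0)")
    c = n_nonconsensus / n_sites
    se = float(np.sqrt(c * (1 - c) / n_sites))
    if interval == "normal":
        lo, hi = c - 1.96 * se, c + 1.96 * se
    elif interval == "wilson":
        z = 1.96
        denom = 1 + z ** 2 / n_sites
        center = (c + z ** 2 / (2 * n_sites)) / denom
        half = z * np.sqrt(c * (1 - c) / n_sites
                           + z ** 2 / (4 * n_sites ** 2)) / denom
        lo, hi = center - half, center + half
    else:
        raise ValueError(f"unknown interval type {interval!r}")
    return ContaminationEstimate(c, se, (max(lo, 0.0), min(hi, 1.0)),
                                 n_sites, n_nonconsensus)


def estimate_contamination(piles: dict, consensus: str, private_sites: list,
                           panel: MitoPanel | None = None,
                           min_depth: int = 10, min_bq: int = 30,
                           min_mq: int = 30, seed: int = 0,
                           transition_filter: str = "pairwise",
                           pooled_reads: bool = False,
                           interval: str = "normal") -> ContaminationEstimate:
    """Estimate the contamination fraction at diagnostic sites.

    Informative sites are private sites with quality-passing depth >=
    ``min_depth``, excluding damage-prone sites: with
    ``transition_filter="pairwise"`` a C/G-consensus site is dropped when
    the consensus vs panel-major allele pair is a transition, with
    ``"strict"`` every C/G-consensus site is dropped.  One read per
    informative site is drawn (seeded); pooled_reads=True instead counts
    every read, giving a smaller (pseudo-replicated) SE.
    """
    rng = np.random.default_rng(seed)
    n_sites = 0
    mismatches = 0
    pooled_n = 0
    pooled_mismatch = 0
    details = []
    for pos in private_sites:
        cons = consensus[pos]
        if cons == "N":
            continue
        if cons in "CG":
            if transition_filter == "strict":
                continue
            major = panel.major_allele(pos) if panel is not None else None
            if major and major != cons and major != "N" and \
                    is_transition(cons, major):
                continue
        pile = piles.get(pos)
        if pile is None:
            continue
        passing = [o for o in pile.observations
                   if o.base in BASE_INDEX and o.base_quality >= min_bq
                   and o.mapping_quality >= min_mq]
        if len(passing) < min_depth:
            continue
        n_sites += 1
        drawn = passing[int(rng.integers(len(passing)))]
        mm = drawn.base != cons
        mismatches += int(mm)
        pooled_n += len(passing)
        pooled_mismatch += sum(o.base != cons for o in passing)
        details.append({"pos": pos, "consensus": cons, "depth": len(passing),
                        "drawn": drawn.base, "mismatch": bool(mm)})
    if n_sites == 0:
        raise ValueError("zero informative sites after filters: "
                         "contamination inestimable (distinct from 0)")
    if pooled_reads:
        est = binomial_estimate(pooled_mismatch, pooled_n, interval)
    else:
        est = binomial_estimate(mismatches, n_sites, interval)
    est.site_details = details
    return est
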