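"""Synthetic data with the statistical structure of the ancient-cattle study.

A Balding-Nichols drift tree relates an outgroup (yak-like), bison-like,
indicine-like, Caucasus-aurochs-like, European-aurochs-like and
Anatolian-domestic-like populations; admixed targets mix European-aurochs
and Anatolian-domestic frequencies at a known autosomal proportion alpha
and X-chromosomal proportion alpha_X.  Read-level noise covers Poisson
depth, sequencing error and fragment-end C->T / G->A deamination, and a
mitochondrial simulator plants rare consensus alleles and contaminant
reads at a known fraction.

Balding-Nichols drift gives closed-form moments (E[f2] between sister
populations is (F1 + F2) * E[p(1-p)] over the ancestral distribution), so
f-statistic estimators can be checked against exact oracles.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .genotypes import (CALL_MISSING, GenotypeMatrix, Observation, SitePile,
                        SnpPanel, SnpRecord)
from .fstats import BlockPartition
from .mtcontam import MitoPanel

LEAVES = ("yak", "bison", "indicine", "caucasus_aurochs",
          "european_aurochs", "anatolian_domestic")

_TRANSVERSION_PAIRS = [("A", "C"), ("A", "T"), ("C", "A"), ("G", "C"),
                       ("G", "T"), ("T", "A"), ("C", "G"), ("T", "G")]
_TRANSITION_PAIRS = [("C", "T"), ("T", "C"), ("G", "A"), ("A", "G")]


@dataclass(frozen=True)
class AdmixtureEvent:
    """An admixed leaf: alpha from source_a, (1 - alpha) from source_b."""

    name: str
    source_a: str
    source_b: str
    alpha: float
    alpha_x: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha {self.alpha} outside [0, 1]")
        if self.alpha_x is not None and not 0.0 <= self.alpha_x <= 1.0:
            raise ValueError(f"alpha_x {self.alpha_x} outside [0, 1]")


@dataclass
class DemographyConfig:
    """Drift-tree topology (child -> (parent, F)) plus admixture events.

    F is the Balding-Nichols drift per branch: child frequencies are drawn
    from Beta(p(1-F)/F, (1-p)(1-F)/F) around the parent frequency p; F = 0
    copies the parent exactly.  The default tree places the Caucasus and
    European aurochs in a clade sister to the Anatolian domestic lineage,
    so an f4-ratio with the Caucasus aurochs and yak as outgroups resolves
    European-aurochs ancestry.  Drift values are chosen so that desk-scale
    site counts (tens of thousands) give ancestry resolution comparable to
    the genome-wide panels real studies use.
    """

    branches: dict = field(default_factory=lambda: {
        "yak": ("root", 0.20),
        "anc1": ("root", 0.03),
        "bison": ("anc1", 0.25),
        "anc2": ("anc1", 0.03),
        "indicine": ("anc2", 0.15),
        "anc3": ("anc2", 0.03),
        "aurochs_clade": ("anc3", 0.60),
        "anatolian_domestic": ("anc3", 0.12),
        "caucasus_aurochs": ("aurochs_clade", 0.08),
        "european_aurochs": ("aurochs_clade", 0.10),
    })
    admixture_events: list = field(default_factory=list)
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95

    def __post_init__(self):
        for child, (parent, F) in self.branches.items():
            if not 0.0 <= F < 1.0:
                raise ValueError(f"branch {parent}->{child}: F = {F} "
                                 "outside [0, 1)")
        order, seen = [], {"root"}
        pending = dict(self.branches)
        while pending:
            progressed = False
            for child, (parent, _) in list(pending.items()):
                if parent in seen:
                    order.append(child)
                    seen.add(child)
                    del pending[child]
                    progressed = True
            if not progressed:
                raise ValueError(f"tree is cyclic or disconnected: {pending}")
        self._topo_order = order


@dataclass
class ReadSimConfig:
    """Read-level noise parameters for the pseudohaploid pipeline."""

    mean_depth: float = 2.0
    error_rate: float = 0.001
    damage_p0: float = 0.0          # 5' C->T amplitude at offset 0
    damage_decay: float = 0.5       # per-base exponential decay of damage
    frag_len_min: int = 35
    frag_len_max: int = 80
    base_quality: int = 40
    mapping_quality: int = 60

    def __post_init__(self):
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        for r in (self.error_rate, self.damage_p0):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class MitoSimConfig:
    """Mitochondrial contamination scenario parameters."""

    contamination: float = 0.0
    n_private: int = 60
    depth: float = 20.0
    length: int = 1000
    panel_size: int = 278
    error_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError("contamination must be in [0, 1]")


def _balding_nichols(parent: np.ndarray, F: float,
                     rng: np.random.Generator) -> np.ndarray:
    if F == 0.0:
        return parent.copy()
    a = parent * (1.0 - F) / F
    b = (1.0 - parent) * (1.0 - F) / F
    # guard the Beta parameters at fixed sites
    a = np.clip(a, 1e-12, None)
    b = np.clip(b, 1e-12, None)
    return np.clip(rng.beta(a, b), 0.0, 1.0)


def simulate_frequencies(cfg: DemographyConfig, n_sites: int, seed=0,
                         chromosome: str = "autosome") -> dict:
    """Per-population allele frequencies under the drift tree.

    ``chromosome="X"`` applies each admixture event's alpha_x instead of
    alpha (falling back to alpha when alpha_x is unset).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    freqs = {"root": rng.uniform(cfg.ancestral_low, cfg.ancestral_high,
                                 n_sites)}
    for child in cfg._topo_order:
        parent, F = cfg.branches[child]
        freqs[child] = _balding_nichols(freqs[parent], F, rng)
    for event in cfg.admixture_events:
        alpha = event.alpha
        if chromosome == "X" and event.alpha_x is not None:
            alpha = event.alpha_x
        freqs[event.name] = (alpha * freqs[event.source_a]
                             + (1.0 - alpha) * freqs[event.source_b])
    return {name: freqs[name] for name in freqs if not name.startswith("anc")
            and name not in ("root", "aurochs_clade")}


def simulate_individuals(freqs: np.ndarray, ploidy: int, n: int,
                         seed=0) -> np.ndarray:
    """Hardy-Weinberg genotypes (allele counts) from population frequencies."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 (hemizygous) or 2")
    return rng.binomial(ploidy, freqs, size=(n, freqs.size)).astype(np.int8)


def random_panel(n_sites: int, seed=0, ts_fraction: float = 0.66,
                 n_chroms: int = 20, spacing: int = 50_000,
                 chrom_prefix: str = "chr") -> SnpPanel:
    """A synthetic SNP panel laid out over ``n_chroms`` chromosomes.

    ts_fraction controls the transition share of allele pairs (~2:1 in real
    SNP data).  Sites are evenly spaced so 5 Mbp jackknife blocks hold
    roughly equal numbers of sites.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    per_chrom = int(np.ceil(n_sites / n_chroms))
    records = []
    for s in range(n_sites):
        chrom = f"{chrom_prefix}{s // per_chrom + 1}"
        pos = (s % per_chrom) * spacing + 1
        if rng.random() < ts_fraction:
            ref, alt = _TRANSITION_PAIRS[int(rng.integers(4))]
        else:
            ref, alt = _TRANSVERSION_PAIRS[int(rng.integers(8))]
        records.append(SnpRecord(chrom, pos, ref, alt, maf=0.25))
    return SnpPanel(records, provenance="simulated")


# ---------------------------------------------------------------------------
# read-level simulation
# ---------------------------------------------------------------------------

_BASE_TO_INT = {b: i for i, b in enumerate("ACGT")}
_INT_C, _INT_G, _INT_T, _INT_A = 1, 2, 3, 0


@dataclass
class ReadTable:
    """Flat arrays describing every simulated read of one individual."""

    site_idx: np.ndarray
    base: np.ndarray       # 0..3 = A,C,G,T
    off5: np.ndarray
    off3: np.ndarray
    bq: np.ndarray
    mq: np.ndarray

    def to_site_piles(self, panel: SnpPanel) -> dict:
        piles = {}
        bases = "ACGT"
        for k in range(self.site_idx.size):
            j = int(self.site_idx[k])
            rec = panel[j]
            key = (rec.chrom, rec.pos)
            pile = piles.setdefault(key, SitePile(rec.chrom, rec.pos))
            pile.observations.append(Observation(
                bases[int(self.base[k])], int(self.bq[k]), int(self.mq[k]),
                int(self.off5[k]), int(self.off3[k])))
        return piles


def simulate_reads(genotype: np.ndarray, panel: SnpPanel, cfg: ReadSimConfig,
                   seed=0, ploidy: int = 2) -> ReadTable:
    """Simulate reads over panel sites for one individual.

    Depth is Poisson per site; each read samples one chromosome copy,
    applies fragment-end deamination (C->T near 5', G->A near 3', amplitude
    damage_p0 decaying exponentially) and then uniform sequencing error.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n_sites = len(panel)
    depth = rng.poisson(cfg.mean_depth, n_sites)
    site_idx = np.repeat(np.arange(n_sites), depth)
    R = site_idx.size
    ref_i = np.array([_BASE_TO_INT[b] for b in panel.ref], dtype=np.int8)
    alt_i = np.array([_BASE_TO_INT[b] for b in panel.alt], dtype=np.int8)
    g = np.asarray(genotype)
    p_alt = g[site_idx] / ploidy
    is_alt = rng.random(R) < p_alt
    base = np.where(is_alt, alt_i[site_idx], ref_i[site_idx]).astype(np.int8)

    frag_len = rng.integers(cfg.frag_len_min, cfg.frag_len_max + 1, R)
    off5 = rng.integers(0, frag_len)
    off3 = frag_len - 1 - off5

    if cfg.damage_p0 > 0:
        p5 = cfg.damage_p0 * np.exp(-cfg.damage_decay * off5)
        p3 = cfg.damage_p0 * np.exp(-cfg.damage_decay * off3)
        u = rng.random(R)
        base = np.where((base == _INT_C) & (u < p5), _INT_T, base)
        base = np.where((base == _INT_G) & (u < p3), _INT_A, base)
    if cfg.error_rate > 0:
        err = rng.random(R) < cfg.error_rate
        shift = rng.integers(1, 4, R)
        base = np.where(err, (base + shift) % 4, base).astype(np.int8)

    bq = np.full(R, cfg.base_quality, dtype=np.int16)
    mq = np.full(R, cfg.mapping_quality, dtype=np.int16)
    return ReadTable(site_idx, base, off5, off3, bq, mq)


def calls_from_read_table(reads: ReadTable, panel: SnpPanel, seed=0,
                          rescale_ends: int = 5, min_bq: int = 30,
                          floor_quality: int = 2) -> np.ndarray:
    """Pseudohaploid calls from a read table (vectorized calling rule).

    With ``rescale_ends`` > 0, terminal T (5') and A (3') reads receive
    ``floor_quality`` and therefore fail the quality filter, exactly as the
    fragment-level rescaling does; set rescale_ends=0 for untreated data.
    Returns int8 calls of length len(panel) coded 0/1/missing (third-allele
    draws are recorded as missing).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    ref_i = np.array([_BASE_TO_INT[b] for b in panel.ref], dtype=np.int8)
    alt_i = np.array([_BASE_TO_INT[b] for b in panel.alt], dtype=np.int8)
    bq = reads.bq.astype(np.int32).copy()
    if rescale_ends > 0:
        floored = (((reads.base == _INT_T) & (reads.off5 < rescale_ends))
                   | ((reads.base == _INT_A) & (reads.off3 < rescale_ends)))
        bq[floored] = floor_quality
    eligible = bq >= min_bq
    calls = np.full(len(panel), CALL_MISSING, dtype=np.int8)
    if reads.site_idx.size == 0:
        return calls
    # draw one eligible read per covered site: sort by (site, ineligible,
    # random key) and take the first read of each site
    key = rng.random(reads.site_idx.size)
    order = np.lexsort((key, ~eligible, reads.site_idx))
    sites_sorted = reads.site_idx[order]
    first = np.unique(sites_sorted, return_index=True)[1]
    chosen = order[first]
    chosen = chosen[eligible[chosen]]
    sites = reads.site_idx[chosen]
    drawn = reads.base[chosen]
    calls[sites[drawn == ref_i[sites]]] = 0
    calls[sites[drawn == alt_i[sites]]] = 1
    return calls


# ---------------------------------------------------------------------------
# mitochondrial scenario
# ---------------------------------------------------------------------------

def simulate_mito(cfg: MitoSimConfig, seed=0) -> tuple:
    """(piles, endogenous haplotype, panel, planted private positions).

    The panel shares a common haplotype with sparse rare variation; the
    endogenous mitogenome carries planted transversions to A or T (so the
    damage filter never removes them) at known positions, each absent from
    the panel.  Reads are contaminant (panel-major haplotype) with
    probability ``contamination``.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    L, P = cfg.length, cfg.panel_size
    major = rng.integers(0, 4, L)
    bases = "ACGT"
    panel_seqs = []
    for _ in range(P):
        seq = major.copy()
        n_var = rng.poisson(L * 0.002)
        if n_var:
            pos = rng.choice(L, size=min(n_var, L), replace=False)
            seq[pos] = (seq[pos] + rng.integers(1, 4, pos.size)) % 4
        panel_seqs.append("".join(bases[i] for i in seq))
    panel = MitoPanel(panel_seqs)

    private_pos = np.sort(rng.choice(L, size=cfg.n_private, replace=False))
    endo = major.copy()
    for pos in private_pos:
        # transversion to A or T never tripped by the C/G damage filter
        current = bases[endo[pos]]
        target = "T" if current in "AG" else "A"
        # ensure the planted allele is genuinely rare in the panel
        while panel.allele_frequency(pos, target) >= 0.05:
            target = {"T": "A", "A": "T"}[target]
        endo[pos] = _BASE_TO_INT[target]
    endo_seq = "".join(bases[i] for i in endo)

    contaminant = major
    piles = {}
    depth = rng.poisson(cfg.depth, L)
    for pos in range(L):
        if depth[pos] == 0:
            continue
        from_contam = rng.random(depth[pos]) < cfg.contamination
        obs = []
        for c in from_contam:
            b = contaminant[pos] if c else endo[pos]
            if cfg.error_rate > 0 and rng.random() < cfg.error_rate:
                b = (b + int(rng.integers(1, 4))) % 4
            obs.append(Observation(bases[int(b)], 40, 60))
        piles[pos] = SitePile("MT", pos + 1, obs)
    return piles, endo_seq, panel, [int(p) for p in private_pos]


# ---------------------------------------------------------------------------
# chromosome coverage for sexing
# ---------------------------------------------------------------------------

def simulate_coverage(sex: str, n_reads: int, seed=0,
                      autosome_length: int = 100_000_000,
                      x_length: int = 140_000_000):
    """Poisson per-chromosome read counts for an XX or XY individual."""
    from .sexing import CoverageSummary, N_AUTOSOMES

    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    lengths = np.array([autosome_length] * N_AUTOSOMES + [x_length], float)
    copy = np.array([2.0] * N_AUTOSOMES + [2.0 if sex == "XX" else 1.0])
    expected = lengths * copy
    expected = expected / expected.sum() * n_reads
    counts = rng.poisson(expected)
    chroms = [str(i) for i in range(1, N_AUTOSOMES + 1)] + ["X"]
    return CoverageSummary(chroms, lengths, counts)


# ---------------------------------------------------------------------------
# end-to-end dataset + on-disk fixtures
# ---------------------------------------------------------------------------

REFERENCE_POPS = LEAVES
DEFAULT_N_REF_HAPLOIDS = 25


def simulate_dataset(targets: list, n_sites: int = 20_000, seed: int = 0,
                     cfg: DemographyConfig | None = None,
                     read_cfg: ReadSimConfig | None = None,
                     n_ref_haploids: int = DEFAULT_N_REF_HAPLOIDS,
                     chromosome: str = "autosome",
                     n_chroms: int = 20) -> tuple:
    """Simulate a GenotypeMatrix: reference panels plus pseudohaploid targets.

    ``targets`` is a list of (name, alpha, alpha_x) tuples; reference
    populations are represented by ``n_ref_haploids`` sampled haploid
    genomes each (panel-like references), targets by one low-coverage
    pseudohaploid individual each.  Returns (matrix, blocks, truth dict,
    frequency table).
    """
    cfg = cfg or DemographyConfig()
    read_cfg = read_cfg or ReadSimConfig()
    cfg.admixture_events = [
        AdmixtureEvent(name, "european_aurochs", "anatolian_domestic",
                       alpha, alpha_x)
        for name, alpha, alpha_x in targets]
    rng = np.random.default_rng(seed)
    prefix = "X" if chromosome == "X" else "chr"
    panel = random_panel(n_sites, seed=rng, n_chroms=n_chroms,
                         chrom_prefix=prefix)
    freqs = simulate_frequencies(cfg, n_sites, seed=rng,
                                 chromosome=chromosome)
    individuals, groups, rows = [], [], []
    for pop in REFERENCE_POPS:
        hap = simulate_individuals(freqs[pop], 1, n_ref_haploids, seed=rng)
        for i in range(n_ref_haploids):
            individuals.append(f"{pop}_{i}")
            groups.append(pop)
            rows.append(hap[i])
    truth = {}
    for name, alpha, alpha_x in targets:
        diploid = simulate_individuals(freqs[name], 2, 1, seed=rng)[0]
        reads = simulate_reads(diploid, panel, read_cfg, seed=rng)
        calls = calls_from_read_table(reads, panel, seed=rng)
        individuals.append(name)
        groups.append(name)
        rows.append(calls)
        truth[name] = {"alpha": alpha, "alpha_x": alpha_x}
    matrix = GenotypeMatrix(individuals, groups, panel,
                            np.array(rows, dtype=np.int8))
    blocks = BlockPartition.from_panel(panel)
    return matrix, blocks, truth, freqs


SCENARIOS = {
    "iberia_timeline": "11 targets with alpha from 0 to 1 in steps of 0.1",
    "sex_biased": "alpha_auto = 0.25, alpha_X = 0.15 (male-biased wild flow)",
    "three_source": "target with 20% indicine ancestry on top of the "
                    "wild/domestic mix",
    "mito_contam": "mitochondrial reads contaminated at 10%",
}


def make_fixture(scenario_name: str, out_dir: str, seed: int = 0,
                 n_sites: int = 20_000) -> dict:
    """Write a named scenario to disk (EIGENSTRAT + truth JSON)."""
    from .genotypes import write_eigenstrat

    if scenario_name not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario_name!r}; available: "
                         f"{sorted(SCENARIOS)}")
    os.makedirs(out_dir, exist_ok=True)
    truth: dict = {"scenario": scenario_name, "seed": seed,
                   "n_sites": n_sites}
    if scenario_name == "iberia_timeline":
        targets = [(f"target_{i:02d}", round(i / 10, 1), None)
                   for i in range(11)]
        matrix, blocks, t, _ = simulate_dataset(targets, n_sites, seed)
        write_eigenstrat(matrix, os.path.join(out_dir, scenario_name))
        truth["targets"] = t
    elif scenario_name == "sex_biased":
        targets = [("admixed", 0.25, 0.15)]
        matrix, blocks, t, _ = simulate_dataset(targets, n_sites, seed)
        write_eigenstrat(matrix, os.path.join(out_dir, scenario_name))
        mx, bx, tx, _ = simulate_dataset(targets, max(n_sites // 10, 2000),
                                         seed + 1, chromosome="X",
                                         n_chroms=1)
        write_eigenstrat(mx, os.path.join(out_dir, scenario_name + "_X"))
        truth["targets"] = t
    elif scenario_name == "three_source":
        cfg = DemographyConfig()
        targets = [("admixed3", 0.4, None)]
        matrix, blocks, t, freqs = simulate_dataset(targets, n_sites, seed,
                                                    cfg=cfg)
        # overwrite the target with a three-way mixture including indicine
        rng = np.random.default_rng(seed + 17)
        mix = (0.4 * freqs["european_aurochs"]
               + 0.4 * freqs["anatolian_domestic"] + 0.2 * freqs["indicine"])
        diploid = simulate_individuals(mix, 2, 1, seed=rng)[0]
        reads = simulate_reads(diploid, matrix.panel, ReadSimConfig(),
                               seed=rng)
        matrix.calls[-1] = calls_from_read_table(reads, matrix.panel,
                                                 seed=rng)
        write_eigenstrat(matrix, os.path.join(out_dir, scenario_name))
        truth["targets"] = {"admixed3": {"alpha": 0.4, "alpha_indicine": 0.2}}
    elif scenario_name == "mito_contam":
        cfg = MitoSimConfig(contamination=0.1)
        piles, endo, panel, private = simulate_mito(cfg, seed)
        with open(os.path.join(out_dir, "mito_consensus.fasta"), "w") as fh:
            fh.write(">endogenous\n" + endo + "\n")
        with open(os.path.join(out_dir, "mito_panel.fasta"), "w") as fh:
            for name, seq in zip(panel.names, panel.sequences):
                fh.write(f">{name}\n{seq}\n")
        with open(os.path.join(out_dir, "mito.pileup"), "w") as fh:
            for pos in sorted(piles):
                pile = piles[pos]
                bs = "".join(o.base for o in pile.observations)
                qs = "".join(chr(o.base_quality + 33)
                             for o in pile.observations)
                fh.write(f"MT\t{pos + 1}\t{endo[pos]}\t{len(bs)}\t{bs}\t{qs}\n")
        truth["contamination"] = cfg.contamination
        truth["private_sites"] = private
    with open(os.path.join(out_dir, scenario_name + "_truth.json"),
              "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
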