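"""SNP panels, damage-aware quality rescaling and pseudohaploid genotyping.

Low-coverage ancient genomes are represented by a single randomly sampled
read allele per SNP ("pseudohaploid" calls).  Residual post-mortem
deamination in UDG-treated libraries survives mostly at fragment ends, so
before calling, terminal T (5') and A (3') bases are down-weighted to a
base quality below the calling threshold rather than discarding all
transition sites.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

NUCLEOTIDES = frozenset("ACGT")
TRANSITION_PAIRS = (frozenset("CT"), frozenset("AG"))

# call codes used throughout the package
CALL_REF = 0
CALL_ALT = 1
CALL_MISSING = -1
CALL_SITE_REMOVED = -2  # drawn read carried a third allele


class PanelError(ValueError):
    """Raised for malformed SNP panels (unsorted, duplicated, bad alleles)."""


def is_transition(ref: str, alt: str) -> bool:
    """True for C/T and G/A allele pairs.

    Observations are assumed pre-oriented to the reference strand, so no
    complement folding is applied.
    """
    return frozenset((ref, alt)) in TRANSITION_PAIRS


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP: 1-based position, reference/alternative allele, MAF."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float = float("nan")

    def __post_init__(self):
        if self.ref_allele not in NUCLEOTIDES or self.alt_allele not in NUCLEOTIDES:
            raise PanelError(
                f"{self.chrom}:{self.pos}: alleles must be A/C/G/T, got "
                f"{self.ref_allele}/{self.alt_allele}"
            )
        if self.ref_allele == self.alt_allele:
            raise PanelError(f"{self.chrom}:{self.pos}: ref and alt alleles identical")
        if np.isfinite(self.maf) and not 0.0 <= self.maf <= 0.5:
            raise PanelError(f"{self.chrom}:{self.pos}: MAF {self.maf} outside [0, 0.5]")

    @property
    def is_transition(self) -> bool:
        return is_transition(self.ref_allele, self.alt_allele)


class SnpPanel:
    """An ordered biallelic SNP panel, strictly sorted by (chrom, pos)."""

    def __init__(self, records: Sequence[SnpRecord], provenance: str = ""):
        records = list(records)
        last = None
        for rec in records:
            key = (rec.chrom, rec.pos)
            if last is not None and last[0] == rec.chrom and key <= last:
                raise PanelError(
                    f"panel not strictly sorted at {rec.chrom}:{rec.pos} "
                    f"(previous {last[0]}:{last[1]})"
                )
            last = key
        seen = {}
        for rec in records:
            key = (rec.chrom, rec.pos)
            if key in seen:
                raise PanelError(f"duplicate panel position {rec.chrom}:{rec.pos}")
            seen[key] = True
        self._records = records
        self.provenance = provenance
        self.chrom = np.array([r.chrom for r in records], dtype=object)
        self.pos = np.array([r.pos for r in records], dtype=np.int64)
        self.ref = np.array([r.ref_allele for r in records], dtype="U1")
        self.alt = np.array([r.alt_allele for r in records], dtype="U1")
        self.maf = np.array([r.maf for r in records], dtype=float)
        self._index = {(r.chrom, r.pos): i for i, r in enumerate(records)}

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, i: int) -> SnpRecord:
        return self._records[i]

    def __iter__(self):
        return iter(self._records)

    def index_of(self, chrom: str, pos: int) -> int:
        return self._index[(chrom, pos)]

    def __contains__(self, key) -> bool:
        return key in self._index

    @property
    def transition_mask(self) -> np.ndarray:
        return np.array([r.is_transition for r in self._records], dtype=bool)

    def subset(self, mask_or_indices) -> "SnpPanel":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SnpPanel([self._records[i] for i in idx], provenance=self.provenance)


def filter_panel(raw_sites: Iterable, maf_min: float = 0.10,
                 provenance: str = "") -> SnpPanel:
    """Reduce candidate sites to biallelic SNPs with MAF >= ``maf_min``.

    ``raw_sites`` yields tuples ``(chrom, pos, ref, alt, ref_count,
    alt_count)`` or ``SnpRecord`` objects that already carry a MAF.
    Monomorphic sites (MAF 0) never pass a positive threshold.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5], got {maf_min}")
    kept: list[SnpRecord] = []
    last = None
    for site in raw_sites:
        if isinstance(site, SnpRecord):
            rec = site
        else:
            chrom, pos, ref, alt, n_ref, n_alt = site
            if n_ref < 0 or n_alt < 0:
                raise ValueError(f"negative allele count at {chrom}:{pos}")
            total = n_ref + n_alt
            maf = min(n_ref, n_alt) / total if total else 0.0
            rec = SnpRecord(str(chrom), int(pos), ref, alt, maf)
        key = (rec.chrom, rec.pos)
        if last is not None and last[0] == rec.chrom and key <= last:
            raise PanelError(
                f"input sites unsorted or duplicated at {rec.chrom}:{rec.pos}"
            )
        last = key
        if rec.maf >= maf_min and rec.maf > 0.0:
            kept.append(rec)
        elif maf_min == 0.0 and rec.maf >= 0.0:
            kept.append(rec)
    return SnpPanel(kept, provenance=provenance)


def transversions_only(panel: SnpPanel) -> SnpPanel:
    """Drop C/T and G/A sites, the sites post-mortem damage can mimic."""
    return panel.subset(~panel.transition_mask)


# ---------------------------------------------------------------------------
# reads and piles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedFragment:
    """A sequenced fragment with per-base qualities and end offsets."""

    bases: str
    quals: tuple
    mapq: int = 60
    covered_positions: tuple = ()

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and qualities differ in length")
        if any(q < 0 for q in self.quals):
            raise ValueError("negative base quality")

    def __len__(self) -> int:
        return len(self.bases)

    def offset_5p(self, i: int) -> int:
        return i

    def offset_3p(self, i: int) -> int:
        return len(self.bases) - 1 - i


def rescale_damage(fragment: AlignedFragment, n_end: int = 5,
                   floor_quality: int = 2) -> AlignedFragment:
    """Floor the quality of terminal T (5') and A (3') bases.

    Residual C->T deamination appears as T in the first ``n_end`` bases and
    as A (G->A on the opposite strand) in the last ``n_end``; those bases are
    assigned ``floor_quality`` so a min-quality-30 caller ignores them.
    Idempotent; a T that sits in both windows is floored regardless.
    """
    if n_end < 0:
        raise ValueError("n_end must be >= 0")
    n = len(fragment)
    quals = list(fragment.quals)
    for i, base in enumerate(fragment.bases):
        if (base == "T" and i < n_end) or (base == "A" and (n - 1 - i) < n_end):
            quals[i] = floor_quality
    return replace(fragment, quals=tuple(quals))


@dataclass(frozen=True)
class Observation:
    """One read's evidence at a SNP site."""

    base: str
    base_quality: int
    mapping_quality: int
    offset_5p: int = 0
    offset_3p: int = 0

    def __post_init__(self):
        if self.base not in "ACGTN":
            raise ValueError(f"invalid base {self.base!r}")


@dataclass
class SitePile:
    """All observations overlapping one panel SNP."""

    chrom: str
    pos: int
    observations: list = field(default_factory=list)

    def __len__(self):
        return len(self.observations)


def pseudohaploid_call(pile: SitePile, snp: SnpRecord, min_bq: int = 30,
                       min_mq: int = 30, rng: np.random.Generator | None = None) -> int:
    """Draw one quality-passing read and code its allele against (ref, alt).

    Returns CALL_REF/CALL_ALT for a known allele, CALL_SITE_REMOVED when the
    drawn base matches neither (a third allele), CALL_MISSING when nothing
    passes the filters.  N bases are excluded before drawing.
    """
    eligible = [o for o in pile.observations
                if o.base != "N" and o.base_quality >= min_bq
                and o.mapping_quality >= min_mq]
    if not eligible:
        return CALL_MISSING
    if rng is None:
        rng = np.random.default_rng()
    obs = eligible[int(rng.integers(len(eligible)))]
    if obs.base == snp.ref_allele:
        return CALL_REF
    if obs.base == snp.alt_allele:
        return CALL_ALT
    return CALL_SITE_REMOVED


def _substream(seed: int, label: str) -> np.random.Generator:
    # per-individual stream derived from (seed, label): adding individuals
    # never perturbs existing calls
    digest = hashlib.sha256(label.encode()).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


class GenotypeMatrix:
    """Pseudohaploid calls: individuals x panel sites, {0, 1, missing}."""

    def __init__(self, individuals: Sequence[str], groups: Sequence[str],
                 panel: SnpPanel, calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(individuals), len(panel)):
            raise ValueError(
                f"call matrix shape {calls.shape} inconsistent with "
                f"{len(individuals)} individuals x {len(panel)} sites"
            )
        bad = ~np.isin(calls, (CALL_REF, CALL_ALT, CALL_MISSING))
        if bad.any():
            raise ValueError("calls must be 0, 1 or missing")
        if len(individuals) != len(set(individuals)):
            raise ValueError("duplicate individual labels")
        self.individuals = list(individuals)
        self.groups = list(groups)
        self.panel = panel
        self.calls = calls
        self._row = {name: i for i, name in enumerate(self.individuals)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.panel)

    def row(self, individual: str) -> np.ndarray:
        return self.calls[self._row[individual]]

    def rows(self, members: Sequence[str]) -> np.ndarray:
        return self.calls[[self._row[m] for m in members]]

    def members_of(self, group: str) -> list:
        return [ind for ind, g in zip(self.individuals, self.groups) if g == group]

    def subset_sites(self, mask_or_indices) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(self.individuals, self.groups,
                              self.panel.subset(idx), self.calls[:, idx])


def build_genotype_matrix(piles: dict, panel: SnpPanel, seed: int,
                          min_bq: int = 30, min_mq: int = 30,
                          drop_sites_globally: bool = False,
                          groups: dict | None = None) -> GenotypeMatrix:
    """Apply the pseudohaploid calling rule per individual over a panel.

    ``piles`` maps individual label -> {(chrom, pos): SitePile}.  Third-allele
    draws are by default treated as missing for the affected individual only;
    with ``drop_sites_globally`` the whole site is removed for everyone.
    Deterministic given ``seed``: each individual draws from its own
    label-derived substream.
    """
    individuals = list(piles)
    for ind, site_piles in piles.items():
        extra = [key for key in site_piles if key not in panel]
        if extra:
            raise PanelError(f"{ind}: pile positions not in panel: {extra[:5]}")
    calls = np.full((len(individuals), len(panel)), CALL_MISSING, dtype=np.int8)
    removed_sites: set[int] = set()
    stats = {}
    for i, ind in enumerate(individuals):
        rng = _substream(seed, ind)
        n_called = n_missing = n_removed = 0
        for key, pile in sorted(piles[ind].items()):
            j = panel.index_of(*key)
            call = pseudohaploid_call(pile, panel[j], min_bq, min_mq, rng)
            if call == CALL_SITE_REMOVED:
                n_removed += 1
                removed_sites.add(j)
                calls[i, j] = CALL_MISSING
            elif call == CALL_MISSING:
                n_missing += 1
            else:
                n_called += 1
                calls[i, j] = call
        stats[ind] = {"called": n_called, "missing": n_missing,
                      "removed": n_removed}
    if drop_sites_globally and removed_sites:
        keep = np.ones(len(panel), dtype=bool)
        keep[list(removed_sites)] = False
        panel = panel.subset(keep)
        calls = calls[:, keep]
    group_list = [groups.get(ind, ind) if groups else ind for ind in individuals]
    matrix = GenotypeMatrix(individuals, group_list, panel, calls)
    matrix.call_stats = stats
    return matrix


# ---------------------------------------------------------------------------
# EIGENSTRAT / VCF / pileup I/O
# ---------------------------------------------------------------------------

def write_eigenstrat(matrix: GenotypeMatrix, prefix: str,
                     dialect: str = "0/2", sexes: dict | None = None) -> None:
    """Write geno/snp/ind files.

    EIGENSTRAT geno counts *reference* alleles per individual; a
    pseudohaploid call is written as 0 (alt) / 2 (ref) / 9 (missing) in the
    default diploid-style dialect, or 0/1/9 with ``dialect="0/1"``.
    """
    alt_char = {"0/2": "0", "0/1": "0"}[dialect]
    ref_char = {"0/2": "2", "0/1": "1"}[dialect]
    with open(prefix + ".geno", "w") as geno:
        for j in range(matrix.n_sites):
            col = matrix.calls[:, j]
            chars = [ref_char if c == CALL_REF else
                     alt_char if c == CALL_ALT else "9" for c in col]
            geno.write("".join(chars) + "\n")
    with open(prefix + ".snp", "w") as snp:
        for rec in matrix.panel:
            snp.write(f"{rec.chrom}_{rec.pos}\t{rec.chrom}\t0.0\t{rec.pos}"
                      f"\t{rec.ref_allele}\t{rec.alt_allele}\n")
    with open(prefix + ".ind", "w") as ind:
        for name, group in zip(matrix.individuals, matrix.groups):
            sex = sexes.get(name, "U") if sexes else "U"
            ind.write(f"{name}\t{sex}\t{group}\n")


def read_eigenstrat(prefix: str, dialect: str = "0/2") -> GenotypeMatrix:
    """Read geno/snp/ind files written by :func:`write_eigenstrat`."""
    records = []
    with open(prefix + ".snp") as snp:
        for ln, line in enumerate(snp, 1):
            parts = line.split()
            if len(parts) < 6:
                raise PanelError(f"{prefix}.snp line {ln}: expected 6 columns")
            _, chrom, _gpos, pos, ref, alt = parts[:6]
            records.append(SnpRecord(chrom, int(pos), ref, alt))
    panel = SnpPanel(records, provenance=prefix)
    individuals, groups = [], []
    with open(prefix + ".ind") as ind:
        for ln, line in enumerate(ind, 1):
            parts = line.split()
            if len(parts) < 3:
                raise PanelError(f"{prefix}.ind line {ln}: expected 3 columns")
            individuals.append(parts[0])
            groups.append(parts[2])
    ref_char = {"0/2": "2", "0/1": "1"}[dialect]
    calls = np.full((len(individuals), len(panel)), CALL_MISSING, dtype=np.int8)
    with open(prefix + ".geno") as geno:
        for j, line in enumerate(geno):
            row = line.strip()
            if len(row) != len(individuals):
                raise PanelError(
                    f"{prefix}.geno line {j + 1}: {len(row)} genotypes for "
                    f"{len(individuals)} individuals"
                )
            for i, ch in enumerate(row):
                if ch == "9":
                    continue
                calls[i, j] = CALL_REF if ch == ref_char else CALL_ALT
    return GenotypeMatrix(individuals, groups, panel, calls)


def read_vcf(path: str, panel: SnpPanel | None = None,
             seed: int = 0) -> GenotypeMatrix:
    """Read genotypes from a VCF into a pseudohaploid matrix.

    Haploid GT fields are taken as-is; diploid heterozygotes are collapsed
    by drawing one allele (seeded).  Sites whose alleles mismatch the panel
    are flagged and skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    individuals = list(vcf.samples)
    records, rows, flagged = [], [], []
    rng = np.random.default_rng(seed)
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        rec = SnpRecord(var.CHROM, var.POS, var.REF, var.ALT[0])
        if panel is not None:
            key = (rec.chrom, rec.pos)
            if key not in panel:
                continue
            known = panel[panel.index_of(*key)]
            if {known.ref_allele, known.alt_allele} != {rec.ref_allele, rec.alt_allele}:
                flagged.append(key)
                continue
        row = np.full(len(individuals), CALL_MISSING, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if not alleles:
                continue
            allele = alleles[0] if len(set(alleles)) == 1 else \
                alleles[int(rng.integers(len(alleles)))]
            row[i] = CALL_ALT if allele > 0 else CALL_REF
        records.append(rec)
        rows.append(row)
    matrix = GenotypeMatrix(individuals, individuals,
                            SnpPanel(records, provenance=path),
                            np.array(rows, dtype=np.int8).reshape(len(rows), len(individuals)).T
                            if rows else np.empty((len(individuals), 0), dtype=np.int8))
    matrix.flagged_sites = flagged
    return matrix


def _decode_pileup_bases(bases: str, ref: str) -> list:
    """Expand a samtools pileup base string into upper-case bases."""
    out = []
    i = 0
    while i < len(bases):
        ch = bases[i]
        if ch == "^":            # read start: skip the mapq character
            i += 2
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":           # indel: skip the length digits and sequence
            i += 1
            num = ""
            while i < len(bases) and bases[i].isdigit():
                num += bases[i]
                i += 1
            i += int(num)
            continue
        if ch in ".,":
            out.append(ref.upper())
        elif ch in "*<>":
            out.append("N")
        else:
            out.append(ch.upper())
        i += 1
    return out


def read_pileup(path: str) -> dict:
    """Parse samtools pileup text into {(chrom, pos): SitePile}.

    Columns: chrom, pos, ref, depth, bases, base-quals and, when produced
    with ``-s``, a trailing mapping-quality string.  Qualities are Phred+33.
    """
    piles = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise PanelError(f"{path} line {ln}: expected >= 6 columns")
            chrom, pos, ref, depth, bases, quals = parts[:6]
            mapqs = parts[6] if len(parts) > 6 else None
            decoded = _decode_pileup_bases(bases, ref)
            if len(decoded) != len(quals):
                raise PanelError(
                    f"{path} line {ln}: {len(decoded)} bases vs "
                    f"{len(quals)} qualities"
                )
            obs = []
            for k, (b, q) in enumerate(zip(decoded, quals)):
                mq = (ord(mapqs[k]) - 33) if mapqs else 60
                obs.append(Observation(b, ord(q) - 33, mq))
            piles[(chrom, int(pos))] = SitePile(chrom, int(pos), obs)
    return piles
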