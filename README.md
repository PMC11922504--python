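# bovid-admix

Ancestry analysis for low-coverage ancient cattle genomes: how much of an
ancient (or modern) *Bos taurus* genome traces back to the extinct European
aurochs (*Bos primigenius*)?  The package implements the complete
statistical pipeline such a study needs — pseudohaploid genotyping of
damaged reads, f-statistics with block-jackknife uncertainty, f4-ratio and
qpAdm-style admixture estimation, NMDS ordination of outgroup-f3
distances, mitochondrial contamination estimation, and Rx molecular
sexing — together with a drift-tree simulator that generates synthetic
cohorts with known ancestry for validation.

It is written for population geneticists working with shotgun ancient-DNA
data who want a transparent, testable implementation of these standard
analyses end to end.

## The statistics

**Pseudohaploid calls.**  A low-coverage genome is represented at each
biallelic SNP by one randomly drawn read with base and mapping quality
≥ 30.  Residual post-mortem deamination is handled by flooring the quality
of T bases in the first 5 bp and A bases in the last 5 bp of each fragment
to 2, so damaged bases fail the filter without discarding all transition
sites.

**f-statistics.**  For population allele frequencies *p*,

    f2(A,B)     = E[(pA − pB)²]
    f3(O; A,B)  = E[(pO − pA)(pO − pB)]
    f4(A,B;C,D) = E[(pA − pB)(pC − pD)]

estimated as means over complete-case sites, with standard errors from a
weighted delete-one block jackknife over 5 Mbp genomic blocks.  Wild
(European aurochs) ancestry α of a target X is the f4 ratio

    α = 1 − f4(O1, O2; X, Wild) / f4(O1, O2; Dom, Wild)

where O1 is an outgroup sharing drift with Wild relative to Dom (a
Caucasus aurochs) and O2 a deep outgroup (yak).  The qpAdm-style estimator
instead fits weights w (Σw = 1) by generalized least squares on the system
f4(X, r₁; rⱼ, r₁) = Σᵢ wᵢ f4(Sᵢ, r₁; rⱼ, r₁) over "right" reference
populations rⱼ, with a χ² model-fit test that can reject the source
configuration.

**Ordination, contamination, sexing.**  Pairwise outgroup-f3 similarities
become distances as 1 − f3 and are embedded by NMDS (SMACOF with isotonic
regression, best of many starts including a metric start).  Mitochondrial
contamination is the fraction of non-consensus reads drawn at sites where
the sample's consensus allele is rare (< 5%) in a panel of diverse
mitogenomes, with binomial SE.  Genetic sex comes from the Rx statistic —
the mean ratio of X-chromosome to autosome read densities over the 29
cattle autosomes (≈ 1 for XX, ≈ 0.5 for XY) — and sex-biased admixture
from a Z test comparing autosomal and X-chromosomal α.

## Worked example

Simulate a cohort (reference panels plus one low-coverage pseudohaploid
target with 30% aurochs ancestry) and estimate α:

```python
from bovid_admix.fstats import PopulationSpec, f4_ratio
from bovid_admix.simulate import simulate_dataset

matrix, blocks, truth, _ = simulate_dataset(
    [("moo_like", 0.3, None)], n_sites=20_000, seed=42)
pop = lambda g: PopulationSpec(g, matrix.members_of(g))
res = f4_ratio(pop("moo_like"), pop("european_aurochs"),
               pop("anatolian_domestic"), pop("caucasus_aurochs"),
               pop("yak"), matrix, blocks)
print(f"alpha = {res.estimate:.3f} [{res.ci[0]:.3f}, {res.ci[1]:.3f}] "
      f"({res.n_sites} sites, {res.n_blocks} blocks)")
```

prints

```
alpha = 0.297 [0.270, 0.324] (16954 sites, 200 blocks)
```

— the estimate recovers the simulated 0.3 and the block-jackknife 95% CI
covers it; 16954 of 20000 panel sites were covered by at least one
quality-passing read of the target.

## Analysis scripts

The `analysis/` directory holds numbered drivers that run the whole study
shape on synthetic cohorts and write tables under `results/`:

| script | what it does |
| --- | --- |
| `01_simulate_cohort.py` | writes the fixture scenarios (EIGENSTRAT + truth JSON) |
| `02_ancestry_timeline.py` | f4-ratio and qpAdm α for 11 targets spanning α = 0..1, vs truth |
| `03_sex_bias.py` | autosome-vs-X α comparison on a male-biased admixture scenario |
| `04_mito_contamination.py` | contamination estimate from a simulated mitochondrial pileup |
| `05_filtering_comparison.py` | damage handling: rescaled qualities vs transversion-only panel |

A thin CLI (`bovid-admix simulate/fstat/f4ratio/qpadm/nmds/mtcontam/sex/run`)
exposes the same operations on files.

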