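"""End-to-end orchestration: genotypes -> f-statistics -> ancestry report.

Reproduces the analysis shape of an ancient-introgression study: per-target
f4 allele-sharing profiles, f4-ratio ancestry on autosomes and X,
qpAdm-style model fits with rotation fallback, an NMDS ordination of
1 - outgroup-f3 distances, and a consolidated per-individual report.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fstats
from .admixture import build_f4_system, qpadm_fit, rotate_models
from .fstats import BlockPartition, NoDataError, PopulationSpec
from .ordination import distance_from_f3, nmds, orient_axis


@dataclass
class RunConfig:
    """Populations, thresholds and paths for one workflow run.

    Role names refer to groups in the genotype matrix: ``outgroup`` is the
    deep outgroup (yak-like), ``o1`` the wild outgroup sharing drift with
    the wild source (Caucasus-aurochs-like), ``wild`` the European-aurochs
    source, ``domestic`` the Anatolian-domestic source.
    """

    geno_prefix: str
    out_dir: str
    targets: list
    outgroup: str = "yak"
    o1: str = "caucasus_aurochs"
    wild: str = "european_aurochs"
    domestic: str = "anatolian_domestic"
    rights: list = field(default_factory=lambda: [
        "caucasus_aurochs", "indicine", "yak", "bison"])
    rotatable: list = field(default_factory=list)
    x_geno_prefix: str | None = None
    block_size: int = 5_000_000
    maxmiss: float = 0.5
    p_threshold: float = 0.01
    nmds_starts: int = 20
    seed: int = 0

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _pop(matrix, group: str) -> PopulationSpec:
    members = matrix.members_of(group)
    if not members:
        raise NoDataError(f"population {group!r} resolves to no individuals")
    return PopulationSpec(group, members)


def run_workflow(cfg: RunConfig, matrix=None, x_matrix=None) -> pd.DataFrame:
    """Run the full analysis and write report + artifacts to cfg.out_dir.

    Deterministic given ``cfg.seed``.  Stage logs carry site/block counts;
    on failure, completed artifacts remain on disk with a MANIFEST of the
    stages that finished.
    """
    from .genotypes import read_eigenstrat

    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: list = []
    log_path = os.path.join(cfg.out_dir, "stages.log")
    log_fh = open(log_path, "w")

    def log(stage, **info):
        line = f"{stage}\t" + "\t".join(f"{k}={v}" for k, v in info.items())
        log_fh.write(line + "\n")
        log_fh.flush()

    def finish_stage(name):
        manifest.append(name)
        with open(os.path.join(cfg.out_dir, "MANIFEST"), "w") as fh:
            fh.write("\n".join(manifest) + "\n")

    try:
        stage = "load"
        t0 = time.time()
        if matrix is None:
            matrix = read_eigenstrat(cfg.geno_prefix)
        if x_matrix is None and cfg.x_geno_prefix:
            x_matrix = read_eigenstrat(cfg.x_geno_prefix)
        blocks = BlockPartition.from_panel(matrix.panel, cfg.block_size)
        log(stage, n_sites=matrix.n_sites, n_blocks=blocks.n_blocks,
            n_individuals=matrix.n_individuals,
            wall=f"{time.time() - t0:.2f}s")
        finish_stage(stage)

        outgroup = _pop(matrix, cfg.outgroup)
        o1 = _pop(matrix, cfg.o1)
        wild = _pop(matrix, cfg.wild)
        domestic = _pop(matrix, cfg.domestic)
        rights = [_pop(matrix, r) for r in cfg.rights]
        targets = [_pop(matrix, t) for t in cfg.targets]

        stage = "f4_profiles"
        t0 = time.time()
        profiles = {}
        for tgt in targets:
            res = fstats.f4_profile(tgt, wild, domestic, outgroup, matrix,
                                    blocks)
            profiles[tgt.name] = res
        log(stage, n_targets=len(profiles), wall=f"{time.time() - t0:.2f}s")
        finish_stage(stage)

        stage = "f4_ratio"
        t0 = time.time()
        ratios, ratios_x = {}, {}
        for tgt in targets:
            ratios[tgt.name] = fstats.f4_ratio(tgt, wild, domestic, o1,
                                               outgroup, matrix, blocks)
        if x_matrix is not None:
            x_blocks = BlockPartition.from_panel(x_matrix.panel,
                                                 cfg.block_size)
            for tgt in targets:
                if not x_matrix.members_of(tgt.name):
                    continue
                ratios_x[tgt.name] = fstats.f4_ratio(
                    _pop(x_matrix, tgt.name), _pop(x_matrix, cfg.wild),
                    _pop(x_matrix, cfg.domestic), _pop(x_matrix, cfg.o1),
                    _pop(x_matrix, cfg.outgroup), x_matrix, x_blocks)
        log(stage, n_targets=len(ratios), n_x=len(ratios_x),
            wall=f"{time.time() - t0:.2f}s")
        finish_stage(stage)

        stage = "qpadm"
        t0 = time.time()
        models = {}
        for tgt in targets:
            system = build_f4_system(tgt, [domestic, wild], rights, matrix,
                                     blocks, maxmiss=cfg.maxmiss)
            model = qpadm_fit(system, p_threshold=cfg.p_threshold)
            if model.rejected and cfg.rotatable:
                alts = rotate_models(tgt, [domestic, wild], rights,
                                     [_pop(matrix, r) for r in cfg.rotatable],
                                     matrix, blocks, maxmiss=cfg.maxmiss,
                                     p_threshold=cfg.p_threshold)
                model = alts[0]
            models[tgt.name] = model
        log(stage, n_models=len(models), wall=f"{time.time() - t0:.2f}s")
        finish_stage(stage)

        stage = "nmds"
        t0 = time.time()
        ord_pops = [wild, domestic, o1] + targets
        labels, f3_mat = fstats.outgroup_f3_matrix(ord_pops, outgroup,
                                                   matrix, blocks)
        dist = distance_from_f3(labels, f3_mat)
        ordination = orient_axis(
            nmds(dist, n_starts=cfg.nmds_starts, seed=cfg.seed),
            reference_label=wild.name)
        pd.DataFrame(f3_mat, index=labels, columns=labels).to_csv(
            os.path.join(cfg.out_dir, "f3_matrix.tsv"), sep="\t")
        pd.DataFrame(ordination.coordinates, index=labels,
                     columns=[f"axis{i + 1}" for i in
                              range(ordination.coordinates.shape[1])]
                     ).to_csv(os.path.join(cfg.out_dir, "nmds_coords.tsv"),
                              sep="\t")
        log(stage, stress=f"{ordination.stress:.4f}",
            wall=f"{time.time() - t0:.2f}s")
        finish_stage(stage)

        stage = "report"
        rows = []
        for tgt in targets:
            name = tgt.name
            ratio = ratios[name]
            model = models[name]
            wild_i = model.sources.index(wild.name)
            row = {
                "individual": name,
                "group": name,
                "f4_profile": profiles[name].estimate,
                "f4_profile_se": profiles[name].se,
                "f4_ratio_alpha": ratio.estimate,
                "f4_ratio_ci_low": ratio.ci[0],
                "f4_ratio_ci_high": ratio.ci[1],
                "qpadm_alpha": float(model.weights[wild_i]),
                "qpadm_se": float(model.weight_ses[wild_i]),
                "qpadm_p": model.p_value,
                "qpadm_feasible": model.feasible,
                "n_sites": ratio.n_sites,
            }
            if name in ratios_x:
                rx = ratios_x[name]
                row["x_alpha"] = rx.estimate
                row["x_ci_low"] = rx.ci[0]
                row["x_ci_high"] = rx.ci[1]
            rows.append(row)
        report = pd.DataFrame(rows)
        report.to_csv(os.path.join(cfg.out_dir, "report.tsv"), sep="\t",
                      index=False, float_format="%.6g")
        report.to_json(os.path.join(cfg.out_dir, "report.json"),
                       orient="records", indent=1)
        finish_stage(stage)
        return report
    except Exception as err:
        raise StageFailure(stage, err) from err
    finally:
        log_fh.close()


def compare_filtering_strategies(read_tables: dict, matrix, blocks,
                                 wild: str, domestic: str, outgroup: str,
                                 o1: str, seed: int = 0) -> pd.DataFrame:
    """Rescaled-quality vs transversion-only estimates per target.

    ``read_tables`` maps target name -> simulated/observed ReadTable over
    ``matrix.panel``; ``matrix`` holds the reference individuals.  For each
    target, pseudohaploid calls are produced twice — with fragment-end
    quality rescaling on the full panel, and untreated on the
    transversion-only panel — and the f4 profile and f4 ratio are computed
    under both treatments.  Transitions carry the damage signal, so the
    rescaled route keeps more sites while the transversion route keeps
    none of the damage-prone ones.
    """
    from .genotypes import transversions_only
    from .simulate import calls_from_read_table

    panel = matrix.panel
    tv_mask = ~panel.transition_mask
    if not tv_mask.any():
        raise NoDataError("transversion panel is empty")
    tv_idx = np.flatnonzero(tv_mask)
    tv_matrix = matrix.subset_sites(tv_idx)
    tv_blocks = BlockPartition.from_panel(tv_matrix.panel)
    rng = np.random.default_rng(seed)

    def freq(mat, group):
        return fstats.allele_freq(_pop(mat, group), mat)

    rows = []
    for name, reads in read_tables.items():
        calls_rescaled = calls_from_read_table(reads, panel, seed=rng,
                                               rescale_ends=5)
        calls_raw = calls_from_read_table(reads, panel, seed=rng,
                                          rescale_ends=0)
        fx_res = np.ma.masked_equal(calls_rescaled.astype(float), -1)
        fx_raw = np.ma.masked_equal(calls_raw.astype(float)[tv_idx], -1)
        if fx_raw.count() == 0 or fx_res.count() == 0:
            raise NoDataError(f"{name}: no overlapping usable sites between "
                              "treatments")
        f4_res = fstats.f4_from_freqs(
            freq(matrix, outgroup), fx_res, freq(matrix, domestic),
            freq(matrix, wild), blocks,
            names=(outgroup, name, domestic, wild))
        f4_tv = fstats.f4_from_freqs(
            freq(tv_matrix, outgroup), fx_raw, freq(tv_matrix, domestic),
            freq(tv_matrix, wild), tv_blocks,
            names=(outgroup, name, domestic, wild))
        ratio_res = fstats.f4_ratio_from_freqs(
            fx_res, freq(matrix, wild), freq(matrix, domestic),
            freq(matrix, o1), freq(matrix, outgroup), blocks)
        ratio_tv = fstats.f4_ratio_from_freqs(
            fx_raw, freq(tv_matrix, wild), freq(tv_matrix, domestic),
            freq(tv_matrix, o1), freq(tv_matrix, outgroup), tv_blocks)
        rows.append({
            "individual": name,
            "f4_rescaled": f4_res.estimate, "f4_rescaled_se": f4_res.se,
            "f4_transversion": f4_tv.estimate,
            "f4_transversion_se": f4_tv.se,
            "alpha_rescaled": ratio_res.estimate,
            "alpha_rescaled_se": ratio_res.se,
            "alpha_transversion": ratio_tv.estimate,
            "alpha_transversion_se": ratio_tv.se,
        })
    table = pd.DataFrame(rows)
    table["f4_se_ratio"] = (table["f4_transversion_se"]
                            / table["f4_rescaled_se"])
    table["alpha_se_ratio"] = (table["alpha_transversion_se"]
                               / table["alpha_rescaled_se"])
    from scipy.stats import linregress
    fit = linregress(table["f4_rescaled"], table["f4_transversion"])
    table.attrs["slope"] = float(fit.slope)
    table.attrs["slope_stderr"] = float(fit.stderr)
    table.attrs["r_squared"] = float(fit.rvalue ** 2)
    return table
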