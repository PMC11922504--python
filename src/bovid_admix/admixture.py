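"""qpAdm-style admixture modelling on systems of f4 statistics.

A target T is modelled as a mixture of source populations S_i with weights
summing to 1.  For "right" reference populations r_1..r_R (r_1 the base),
every f4(T, r_1; r_j, r_1) must equal the same mixture of the source rows
f4(S_i, r_1; r_j, r_1) if the model holds.  Weights are fitted by
generalized least squares under the sum-to-one constraint, with the
covariance of the f4 vector estimated by block jackknife; the minimized
quadratic form is a chi-square model-fit test with
dof = (n_rights - 1) - (n_sources - 1).  Weights are not sign-constrained:
infeasible fits (weights outside [0, 1]) are flagged, and model rotation
explores alternative source/right assignments instead of constraining.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .fstats import BlockPartition, NoDataError, PopulationSpec, allele_freq


@dataclass
class AdmixtureModel:
    """A fitted source decomposition of one target."""

    target: str
    sources: tuple
    rights: tuple
    weights: np.ndarray
    weight_ses: np.ndarray
    p_value: float
    n_sites: int
    dof: int
    chi2: float

    def __post_init__(self):
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-10:
            raise ValueError("weights must sum to 1")

    @property
    def feasible(self) -> bool:
        return bool(np.all((self.weights >= 0.0) & (self.weights <= 1.0)))

    @property
    def rejected(self) -> bool:
        return (not self.feasible) or (np.isfinite(self.p_value)
                                       and self.p_value < self.p_threshold)

    p_threshold: float = 0.01

    def summary(self) -> dict:
        return {
            "target": self.target,
            "sources": list(self.sources),
            "rights": list(self.rights),
            "weights": [float(w) for w in self.weights],
            "weight_ses": [float(s) for s in self.weight_ses],
            "p_value": float(self.p_value),
            "feasible": self.feasible,
            "n_sites": self.n_sites,
            "dof": self.dof,
        }


class F4System:
    """Per-block f4 building blocks for one target/sources/rights layout."""

    def __init__(self, target, sources, rights, y_sums, y_counts, A_sums,
                 A_counts, n_sites, n_blocks):
        self.target = target
        self.sources = tuple(sources)
        self.rights = tuple(rights)
        self.y_sums = y_sums          # (R-1, B)
        self.y_counts = y_counts
        self.A_sums = A_sums          # (S, R-1, B)
        self.A_counts = A_counts
        self.n_sites = n_sites
        self.n_blocks = n_blocks

    @property
    def n_equations(self) -> int:
        return self.y_sums.shape[0]

    @property
    def n_sources(self) -> int:
        return self.A_sums.shape[0]

    def block_weights(self) -> np.ndarray:
        return self.y_counts.sum(axis=0)

    def values(self, exclude: int | None = None) -> tuple:
        """(y, A) estimated from all blocks, optionally leaving one out."""
        keep = np.ones(self.n_blocks, dtype=bool)
        if exclude is not None:
            keep[exclude] = False
        y = self.y_sums[:, keep].sum(1) / self.y_counts[:, keep].sum(1)
        A = self.A_sums[:, :, keep].sum(2) / self.A_counts[:, :, keep].sum(2)
        return y, A


def _masked_freqs(pops, matrix):
    return {p.name: allele_freq(p, matrix) for p in pops}


def build_f4_system(target: PopulationSpec, sources, rights, matrix,
                    blocks: BlockPartition, maxmiss: float = 0.5) -> F4System:
    """Assemble the f4 response vector and design rows per genomic block.

    The first right population is the base.  Sites where more than
    ``maxmiss`` of the involved populations lack data are excluded; within
    the retained set each f4 entry uses its own complete cases (the
    allsnps-style convention that keeps low-coverage targets usable).
    """
    if len(rights) < 3:
        raise ValueError("need >= 2 right populations beyond the base")
    if len(sources) < 1:
        raise ValueError("need >= 1 source")
    dof = (len(rights) - 1) - (len(sources) - 1)
    if dof < 0:
        raise ValueError(
            f"{len(sources)} sources with {len(rights)} rights leaves "
            f"dof = {dof}; add right populations or drop sources")
    pops = [target] + list(sources) + list(rights)
    freqs = _masked_freqs(pops, matrix)
    masks = np.stack([np.ma.getmaskarray(freqs[p.name]) for p in pops])
    missing_frac = masks.mean(axis=0)
    usable = missing_frac <= maxmiss
    if not usable.any():
        raise NoDataError("no sites pass the maxmiss filter")

    base = rights[0]
    others = rights[1:]
    B = blocks.n_blocks
    ids = blocks.block_ids

    def per_block_f4(p_left, p_right):
        # f4(left, base; r_j, base) terms per block, complete cases within
        # the maxmiss-filtered set
        fb = freqs[base.name]
        terms = (p_left - fb) * (p_right - fb)
        defined = usable & ~np.ma.getmaskarray(terms)
        vals = np.ma.filled(terms, 0.0)
        sums = np.bincount(ids[defined], weights=vals[defined], minlength=B)
        counts = np.bincount(ids[defined], minlength=B).astype(float)
        return sums, counts

    y_sums = np.zeros((len(others), B))
    y_counts = np.zeros((len(others), B))
    A_sums = np.zeros((len(sources), len(others), B))
    A_counts = np.zeros((len(sources), len(others), B))
    for j, rj in enumerate(others):
        y_sums[j], y_counts[j] = per_block_f4(freqs[target.name],
                                              freqs[rj.name])
        for i, src in enumerate(sources):
            A_sums[i, j], A_counts[i, j] = per_block_f4(freqs[src.name],
                                                        freqs[rj.name])
    if (y_counts.sum(1) == 0).any() or (A_counts.sum(2) == 0).any():
        raise NoDataError("an f4 entry of the system has zero usable sites")
    return F4System(target.name, [s.name for s in sources],
                    [r.name for r in rights], y_sums, y_counts, A_sums,
                    A_counts, int(usable.sum()), B)


def _jackknife_cov(system: F4System, w: np.ndarray,
                   ridge_eps: float = 1e-6,
                   cond_max: float = 1e12) -> np.ndarray:
    """Block-jackknife covariance of the residual vector y - A'w."""
    y, A = system.values()
    e_full = y - A.T @ w
    bw = system.block_weights()
    used = np.flatnonzero(bw > 0)
    B = used.size
    n = bw[used].sum()
    h = n / bw[used]
    taus = np.empty((B, system.n_equations))
    for k, b in enumerate(used):
        yb, Ab = system.values(exclude=b)
        e_b = yb - Ab.T @ w
        taus[k] = h[k] * e_full - (h[k] - 1) * e_b
    center = taus.mean(axis=0)
    dev = taus - center
    Q = (dev.T * (1.0 / (h - 1))) @ dev / B
    dim = Q.shape[0]
    tr = np.trace(Q)
    if tr <= 0:
        Q = Q + np.eye(dim) * ridge_eps
    if np.linalg.cond(Q) > cond_max:
        Q = Q + np.eye(dim) * ridge_eps * np.trace(Q) / dim
    return Q


def _solve_constrained_gls(y, A, Qinv):
    """argmin_w (y - A'w)' Qinv (y - A'w) subject to sum(w) = 1."""
    S = A.shape[0]
    M = A @ Qinv @ A.T
    c = A @ Qinv @ y
    kkt = np.zeros((S + 1, S + 1))
    kkt[:S, :S] = M
    kkt[:S, S] = 1.0
    kkt[S, :S] = 1.0
    rhs = np.concatenate([c, [1.0]])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular f4 system after regularization; use larger blocks or "
            "fewer right populations") from err
    return sol[:S]


def qpadm_fit(system: F4System, n_iter: int = 3,
              p_threshold: float = 0.01) -> AdmixtureModel:
    """Fit mixture weights by constrained GLS and test model fit.

    The residual covariance depends on the weights, so the fit iterates:
    weights -> jackknife covariance of the residual vector -> refit.  The
    minimized quadratic form is chi-square with
    dof = (n_rights - 1) - (n_sources - 1) under the model; weight SEs come
    from refitting on each leave-one-block-out replicate.
    """
    S = system.n_sources
    w = np.full(S, 1.0 / S)
    y, A = system.values()
    Q = None
    for _ in range(max(n_iter, 1)):
        Q = _jackknife_cov(system, w)
        Qinv = np.linalg.pinv(Q)
        if S == 1:
            w = np.array([1.0])
        else:
            w = _solve_constrained_gls(y, A, Qinv)
    resid = y - A.T @ w
    chi2 = float(resid @ Qinv @ resid)
    dof = (len(system.rights) - 1) - (S - 1)
    p_value = float(sps.chi2.sf(chi2, dof)) if dof > 0 else float("nan")

    bw = system.block_weights()
    used = np.flatnonzero(bw > 0)
    B = used.size
    n = bw[used].sum()
    h = n / bw[used]
    loo_w = np.empty((B, S))
    for k, b in enumerate(used):
        yb, Ab = system.values(exclude=b)
        loo_w[k] = np.array([1.0]) if S == 1 else \
            _solve_constrained_gls(yb, Ab, Qinv)
    theta_j = B * w - ((1 - bw[used] / n)[:, None] * loo_w).sum(axis=0)
    tau = h[:, None] * w[None, :] - (h - 1)[:, None] * loo_w
    var = ((tau - theta_j) ** 2 / (h - 1)[:, None]).sum(axis=0) / B
    ses = np.sqrt(var)
    model = AdmixtureModel(system.target, system.sources, system.rights,
                           w, ses, p_value, system.n_sites, dof, chi2)
    model.p_threshold = p_threshold
    return model


def rotate_models(target, base_sources, fixed_rights, rotatable, matrix,
                  blocks, maxmiss: float = 0.5,
                  p_threshold: float = 0.01) -> list:
    """Enumerate source/right/unused assignments of rotatable populations.

    Every rotatable population is tried as an extra source (expanding e.g. a
    two-source to a three-source model), as an extra right population, or
    left out.  Models are ranked by (feasible, p-value); fits with p below
    ``p_threshold`` or weights outside [0, 1] are marked rejected.
    """
    fixed_names = {p.name for p in fixed_rights}
    for pop in rotatable:
        if pop.name in fixed_names:
            raise ValueError(f"rotatable population {pop.name} is already a "
                             "fixed right")
    if not base_sources:
        raise ValueError("empty model space: no base sources")
    models = []
    for assignment in itertools.product(("source", "right", "unused"),
                                        repeat=len(rotatable)):
        sources = list(base_sources)
        rights = list(fixed_rights)
        for pop, role in zip(rotatable, assignment):
            if role == "source":
                sources.append(pop)
            elif role == "right":
                rights.append(pop)
        if (len(rights) - 1) - (len(sources) - 1) < 0:
            continue
        try:
            system = build_f4_system(target, sources, rights, matrix, blocks,
                                     maxmiss=maxmiss)
            model = qpadm_fit(system, p_threshold=p_threshold)
        except (NoDataError, np.linalg.LinAlgError):
            continue
        models.append(model)
    if not models:
        raise ValueError("empty model space: no model could be evaluated")
    # saturated (dof 0) models carry no fit test; rank them after any
    # feasible tested model
    models.sort(key=lambda m: (not m.feasible, not np.isfinite(m.p_value),
                               -(m.p_value if np.isfinite(m.p_value)
                                 else 0.0)))
    return models
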