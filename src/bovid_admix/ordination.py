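"""Non-metric multidimensional scaling of 1 - outgroup-f3 distances.

Shared drift with an outgroup (outgroup-f3) behaves like a similarity, so
1 - f3 is used as a dissimilarity and embedded by NMDS: alternating
monotone (isotonic) regression of configuration distances on the
dissimilarity ranks with a Guttman-transform update of the configuration
(SMACOF), minimizing Kruskal stress-1.  Multiple random starts guard
against local minima; the best configuration is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress
from sklearn.isotonic import IsotonicRegression


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative dissimilarities with a zero diagonal."""

    labels: list
    values: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != d.shape[0]:
            raise ValueError("labels inconsistent with matrix size")
        if np.isnan(d).any():
            raise ValueError("missing distances are not imputed; fill the "
                             "f3 matrix first")
        if not np.allclose(d, d.T, atol=0.0):
            raise ValueError("distance matrix must be exactly symmetric")
        self.values = d

    @property
    def n(self) -> int:
        return self.values.shape[0]


def distance_from_f3(labels, f3_matrix) -> DistanceMatrix:
    """d_ij = 1 - f3_ij, diagonal forced to 0.

    Values may exceed 1 when f3 < 0; that is a legitimate dissimilarity.
    """
    f3 = np.asarray(f3_matrix, dtype=float)
    if not np.allclose(f3, f3.T, atol=0.0):
        raise ValueError("f3 matrix must be symmetric")
    if np.isnan(f3).any():
        raise ValueError("missing f3 pair; no imputation is performed")
    d = 1.0 - f3
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(labels), d)


@dataclass
class OrdinationResult:
    coordinates: np.ndarray      # (n, k), centered at the origin
    stress: float                # Kruskal stress-1
    n_starts: int
    best_start_seed: int
    converged: bool
    labels: list | None = None


def monotone_regression(y: np.ndarray, increasing: bool = True) -> np.ndarray:
    """Pool-adjacent-violators fit of y by a monotone sequence (equal weights)."""
    x = np.arange(len(y))
    iso = IsotonicRegression(increasing=increasing)
    return iso.fit_transform(x, np.asarray(y, dtype=float))


def _stress1(dist_flat, disp_flat) -> float:
    denom = float(np.sum(dist_flat ** 2))
    if denom == 0:
        return 1.0
    return float(np.sqrt(np.sum((disp_flat - dist_flat) ** 2) / denom))


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson PCoA configuration used as the metric start."""
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:k]
    return vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0, None))


def _single_start(d_flat, order, n, k, rng, max_iter, tol, init=None):
    """One SMACOF run from a random (or given) configuration; stress never
    increases."""
    X = rng.normal(size=(n, k)) if init is None else init.copy()
    stress_prev = np.inf
    converged = False
    history = []
    for _ in range(max_iter):
        dist = pdist(X)
        # untied ("primary") monotone regression on the dissimilarity order;
        # ties were broken by input index when `order` was built
        disp = np.empty_like(dist)
        disp[order] = monotone_regression(dist[order], increasing=True)
        stress = _stress1(dist, disp)
        history.append(stress)
        if stress > stress_prev + 1e-12:
            break
        if stress_prev - stress < tol:
            converged = True
            stress_prev = stress
            break
        stress_prev = stress
        # Guttman transform: X <- (1/n) B(X) X
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, disp / dist, 0.0)
        Bmat = -squareform(ratio)
        np.fill_diagonal(Bmat, -Bmat.sum(axis=1))
        X = Bmat @ X / n
    X = X - X.mean(axis=0)
    return X, stress_prev, converged, history


def nmds(d: DistanceMatrix, k: int = 2, n_starts: int = 100,
         max_iter: int = 500, tol: float = 1e-7,
         seed: int = 0) -> OrdinationResult:
    """Best-of-``n_starts`` NMDS embedding of a dissimilarity matrix."""
    n = d.n
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} points for {k} dimensions")
    d_flat = squareform(d.values, checks=False)
    if np.ptp(d_flat) == 0:
        raise ValueError("all dissimilarities equal: ordination degenerate")
    order = np.lexsort((np.arange(d_flat.size), d_flat))
    best = None
    root = np.random.SeedSequence(seed)
    # start 0 is the metric (PCoA) configuration, as metaMDS-style NMDS
    # does; remaining starts are random
    inits = [_classical_scaling(d.values, k)] + [None] * max(n_starts - 1, 0)
    for start, (child, init) in enumerate(zip(root.spawn(len(inits)), inits)):
        rng = np.random.default_rng(child)
        X, stress, converged, history = _single_start(d_flat, order, n, k,
                                                      rng, max_iter, tol,
                                                      init=init)
        if best is None or stress < best[1]:
            best = (X, stress, converged, start, history)
    X, stress, converged, start, history = best
    result = OrdinationResult(X, min(max(stress, 0.0), 1.0), n_starts, start,
                              converged, labels=d.labels)
    result.stress_history = history
    return result


def orient_axis(result: OrdinationResult, reference_label: str,
                axis: int = 0) -> OrdinationResult:
    """Fix the sign of an axis so a designated sample scores positive."""
    i = result.labels.index(reference_label)
    if result.coordinates[i, axis] < 0:
        result.coordinates[:, axis] = -result.coordinates[:, axis]
    return result


def procrustes_align(a: np.ndarray, b: np.ndarray) -> tuple:
    """Align b to a by rotation/reflection/scaling/translation; return
    (aligned b, RMSE)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("configurations must have the same shape")
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    norm_a = np.linalg.norm(a0)
    norm_b = np.linalg.norm(b0)
    if norm_a == 0 or norm_b == 0:
        raise ValueError("degenerate configuration: all points identical")
    R, scale = orthogonal_procrustes(b0 / norm_b, a0 / norm_a)
    aligned = (b0 / norm_b) @ R * scale * norm_a + a.mean(axis=0)
    rmse = float(np.sqrt(np.mean(np.sum((aligned - a) ** 2, axis=1))))
    return aligned, rmse


def correlate_axis_with_f4(result: OrdinationResult, axis_index: int,
                           f4_values) -> tuple:
    """OLS of f4 profile values on one ordination axis; returns (R^2, p)."""
    scores = result.coordinates[:, axis_index]
    y = np.asarray(f4_values, dtype=float)
    if y.size != scores.size or y.size < 3:
        raise ValueError("need >= 3 shared samples")
    if np.ptp(scores) == 0:
        raise ValueError("constant axis: correlation undefined")
    fit = linregress(scores, y)
    return float(fit.rvalue ** 2), float(fit.pvalue)
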