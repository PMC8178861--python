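"""Exploratory factor analysis: iterated principal-axis extraction, Horn's
parallel analysis for factor retention, direct-oblimin (quartimin) rotation,
and cutoff-based variable assignment.

Retention follows Horn's original comparison: the observed eigenvalues of
the *full* Pearson correlation matrix against the per-position 95th
percentile of eigenvalues from iid standard-normal data of the same shape
(100 iterations by default); k is the length of the initial run of observed
eigenvalues exceeding their threshold.

Extraction is iterated principal-axis factoring with squared-multiple-
correlation initial communalities (pseudoinverse-based when the correlation
matrix is singular, e.g. p > n; per-row max |off-diagonal| as a final
fallback), Heywood cases clamped at 0.995. Rotation is direct oblimin with
gamma = 0 via gradient projection with multiple seeded random starts,
keeping the lowest criterion value. Variables are assigned to their
largest-|pattern-loading| factor only where that loading clears the cutoff
(0.6 by default — conservative, appropriate for small samples); ties go to
the lower factor index.

Per-factor variance proportions are pattern-loading sums of squares over p.
With oblique factors these need not sum to the total common variance; they
are descriptive shares, not an orthogonal decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EFAResult",
    "parallel_analysis",
    "principal_axis_factor",
    "oblimin_rotate",
    "run_efa",
    "tucker_congruence",
]


@dataclass(frozen=True)
class EFAResult:
    k: int
    variables: tuple[str, ...]
    pattern: np.ndarray          # p x k
    structure: np.ndarray        # p x k
    phi: np.ndarray              # k x k factor correlations
    communalities: np.ndarray    # p
    var_prop: np.ndarray         # k, proportions of total variance
    assignments: dict[str, int | None] = field(default_factory=dict)
    eigen_observed: np.ndarray | None = None
    eigen_thresholds: np.ndarray | None = None
    converged: bool = True


# ---------------------------------------------------------------------------
# Parallel analysis
# ---------------------------------------------------------------------------

def parallel_analysis(
    data: np.ndarray | pd.DataFrame,
    n_iter: int = 100,
    percentile: float = 95.0,
    seed: int | np.random.Generator = 0,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Horn's parallel analysis on the columns of ``data``.

    Returns (k, observed eigenvalues, per-position percentile thresholds);
    k is the length of the initial run where observed > threshold.
    """
    x = np.asarray(data, dtype=float)
    n, p = x.shape
    if n < 3 or p < 2:
        raise ValueError(f"parallel analysis needs n >= 3 and p >= 2, got {n}x{p}")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        cols = np.nonzero(sd == 0)[0]
        names = (list(data.columns[cols]) if isinstance(data, pd.DataFrame) else list(cols))
        raise ValueError(f"constant column(s) in parallel analysis input: {names}")
    observed = np.linalg.eigvalsh(np.corrcoef(x, rowvar=False))[::-1]

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    random_eigs = np.empty((n_iter, p))
    for i in range(n_iter):
        z = rng.standard_normal((n, p))
        random_eigs[i] = np.linalg.eigvalsh(np.corrcoef(z, rowvar=False))[::-1]
    # ceiling order statistic: a Monte Carlo quantile estimated from a finite
    # draw should err upward for a retention threshold, never interpolate down
    thresholds = np.percentile(random_eigs, percentile, axis=0, method="higher")

    k = 0
    for obs, thr in zip(observed, thresholds):
        if obs > thr:
            k += 1
        else:
            break
    return k, observed, thresholds


# ---------------------------------------------------------------------------
# Principal-axis factoring
# ---------------------------------------------------------------------------

def _initial_communalities(r: np.ndarray) -> np.ndarray:
    """Squared multiple correlations, 1 - 1/diag(R^-1); pseudoinverse when
    singular, per-row max |off-diagonal| where that still misbehaves."""
    p = r.shape[0]
    with np.errstate(all="ignore"):
        try:
            inv = np.linalg.inv(r)
        except np.linalg.LinAlgError:
            inv = np.linalg.pinv(r)
        diag = np.diag(inv).copy()
    smc = 1.0 - 1.0 / diag
    fallback = np.max(np.abs(r - np.eye(p)), axis=1)
    bad = ~np.isfinite(smc) | (smc <= 0) | (smc >= 1)
    smc[bad] = fallback[bad]
    return np.clip(smc, 0.0, 0.995)


def principal_axis_factor(
    r: np.ndarray,
    k: int,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Iterated principal-axis factoring of a correlation matrix.

    Returns (loadings p x k, communalities, converged). Each sweep replaces
    the diagonal with the current communalities, eigendecomposes, forms
    Lambda = V_k sqrt(max(lambda, 0)), and updates h^2 as row sums of
    Lambda^2 (clamped at 0.995 against Heywood cases) until the largest
    communality change is below ``tol``.
    """
    r = np.asarray(r, dtype=float)
    p = r.shape[0]
    if r.shape != (p, p) or not np.allclose(r, r.T, atol=1e-8):
        raise ValueError("R must be a symmetric correlation matrix")
    if k < 1:
        raise ValueError("k must be >= 1")
    h2 = _initial_communalities(r)
    loadings = np.zeros((p, k))
    converged = False
    for _ in range(max_iter):
        reduced = r.copy()
        np.fill_diagonal(reduced, h2)
        eigvals, eigvecs = np.linalg.eigh(reduced)
        idx = np.argsort(eigvals)[::-1][:k]
        lam = np.maximum(eigvals[idx], 0.0)
        loadings = eigvecs[:, idx] * np.sqrt(lam)
        new_h2 = np.clip(np.sum(loadings**2, axis=1), 0.0, 0.995)
        delta = np.max(np.abs(new_h2 - h2))
        h2 = new_h2
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("principal-axis factoring did not converge", stacklevel=2)
    # deterministic sign: largest-|loading| entry of each factor positive
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return loadings, h2, converged


# ---------------------------------------------------------------------------
# Direct oblimin rotation (gradient projection)
# ---------------------------------------------------------------------------

def _quartimin_vgq(loadings: np.ndarray) -> tuple[float, np.ndarray]:
    """Quartimin (oblimin gamma=0) criterion value and gradient."""
    l2 = loadings**2
    k = loadings.shape[1]
    n = np.ones((k, k)) - np.eye(k)
    x = l2 @ n
    return float(np.sum(l2 * x) / 4.0), loadings * x


def _gpa_oblique(
    a: np.ndarray,
    t0: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Gradient-projection oblique rotation of unrotated loadings ``a``.

    Returns (pattern, T, criterion, converged) with pattern = A (T^-1)'.
    """
    t = t0.copy()
    ti = np.linalg.inv(t)
    loadings = a @ ti.T
    f, gq = _quartimin_vgq(loadings)
    g = -(loadings.T @ gq @ ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        gp = g - t @ np.diag(np.sum(t * g, axis=0))
        s = np.sqrt(np.sum(gp**2))
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(20):
            tt = t - al * gp
            norms = np.sqrt(np.sum(tt**2, axis=0))
            tt = tt / norms
            try:
                ti_new = np.linalg.inv(tt)
            except np.linalg.LinAlgError:
                al /= 2.0
                continue
            l_new = a @ ti_new.T
            f_new, gq_new = _quartimin_vgq(l_new)
            if f_new < f - 0.5 * s**2 * al:
                t, ti, loadings, f = tt, ti_new, l_new, f_new
                g = -(loadings.T @ gq_new @ ti).T
                break
            al /= 2.0
        else:
            break
    return loadings, t, f, converged


def oblimin_rotate(
    loadings: np.ndarray,
    n_starts: int = 30,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Direct-oblimin (gamma = 0) rotation with seeded random starts.

    Returns (pattern, structure, phi, converged). k = 1 is the identity
    rotation. Factors are sign-flipped so each factor's largest-|loading|
    is positive, and ordered by descending variance explained.
    """
    a = np.asarray(loadings, dtype=float)
    p, k = a.shape
    if k == 1:
        pattern = a.copy()
        i = np.argmax(np.abs(pattern[:, 0]))
        if pattern[i, 0] < 0:
            pattern = -pattern
        return pattern, pattern.copy(), np.array([[1.0]]), True

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, bool] | None = None
    for start in range(n_starts):
        if start == 0:
            t0 = np.eye(k)
        else:
            t0 = rng.standard_normal((k, k))
            t0 /= np.sqrt(np.sum(t0**2, axis=0))
        pattern, t, f, conv = _gpa_oblique(a, t0)
        if best is None or f < best[0] - 1e-12:
            best = (f, pattern, t, conv)
    assert best is not None
    _, pattern, t, conv = best
    if not conv:
        warnings.warn("oblimin rotation did not fully converge", stacklevel=2)
    phi = t.T @ t

    # sign convention
    for j in range(k):
        i = np.argmax(np.abs(pattern[:, j]))
        if pattern[i, j] < 0:
            pattern[:, j] = -pattern[:, j]
            phi[j, :] = -phi[j, :]
            phi[:, j] = -phi[:, j]
    # order by variance explained (pattern sum of squares), descending
    order = np.argsort(-np.sum(pattern**2, axis=0), kind="stable")
    pattern = pattern[:, order]
    phi = phi[np.ix_(order, order)]
    structure = pattern @ phi
    return pattern, structure, phi, conv


# ---------------------------------------------------------------------------
# Full EFA
# ---------------------------------------------------------------------------

def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def run_efa(
    features: pd.DataFrame,
    cutoff: float = 0.6,
    n_iter_pa: int = 100,
    percentile: float = 95.0,
    seed: int | np.random.Generator = 0,
) -> EFAResult:
    """End-to-end EFA of a samples x variables matrix (already restricted to
    the screened variables): standardize, retain k by parallel analysis,
    principal-axis extraction, oblimin rotation, and cutoff assignment.

    A variable is assigned to the factor with its largest |pattern loading|
    among factors where that loading clears ``cutoff``; otherwise it is
    unassigned (None). k = 0 yields a factorless result.
    """
    if features.shape[1] == 0:
        raise ValueError("run_efa: empty variable set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = features.to_numpy(dtype=float)
    variables = tuple(features.columns)
    p = len(variables)

    k, observed, thresholds = parallel_analysis(
        x, n_iter=n_iter_pa, percentile=percentile, seed=rng
    )
    if k == 0:
        return EFAResult(
            k=0, variables=variables,
            pattern=np.zeros((p, 0)), structure=np.zeros((p, 0)),
            phi=np.zeros((0, 0)), communalities=np.zeros(p),
            var_prop=np.zeros(0),
            assignments={v: None for v in variables},
            eigen_observed=observed, eigen_thresholds=thresholds,
        )

    r = np.corrcoef(x, rowvar=False)
    if p > x.shape[0]:
        warnings.warn(
            f"EFA with p={p} variables > n={x.shape[0]} samples: the correlation "
            "matrix is singular; SMC initial communalities use a pseudoinverse",
            stacklevel=2,
        )
    loadings, h2, paf_conv = principal_axis_factor(r, k)
    pattern, structure, phi, rot_conv = oblimin_rotate(loadings, seed=rng)

    assignments: dict[str, int | None] = {}
    for i, var in enumerate(variables):
        eligible = np.nonzero(np.abs(pattern[i]) >= cutoff)[0]
        if eligible.size == 0:
            assignments[var] = None
        else:
            best = eligible[np.argmax(np.abs(pattern[i, eligible]))]
            # exact ties between factors go to the lower index
            ties = eligible[np.abs(pattern[i, eligible]) == np.abs(pattern[i, best])]
            assignments[var] = int(ties.min())

    var_prop = np.sum(pattern**2, axis=0) / p
    return EFAResult(
        k=k, variables=variables,
        pattern=pattern, structure=structure, phi=phi,
        communalities=h2, var_prop=var_prop,
        assignments=assignments,
        eigen_observed=observed, eigen_thresholds=thresholds,
        converged=paf_conv and rot_conv,
    )
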