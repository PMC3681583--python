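"""Flury hierarchy of relationships among covariance matrices.

Two (or more) covariance matrices can be related anywhere between complete
equality and no shared structure at all.  The Flury hierarchy orders the
possibilities by increasing constraint:

    unrelated < PCPC(1) < ... < PCPC(p-2) < CPC < proportional < equal

where CPC (common principal components) means all eigenvectors are shared
and only eigenvalues differ, PCPC(q) means exactly ``q`` principal axes are
shared, and proportional means shared eigenvectors with eigenvalues scaled
by a per-group constant.  Each model is fitted by maximum likelihood under
the assumption of Wishart-distributed sample covariance matrices; the
likelihood-ratio statistic of model m against the unconstrained model is

    chi2_m = sum_i (n_i - 1) * ln( det(Sigma_hat_i) / det(S_i) )

Model choice is offered both by the classical step-up sequence of
likelihood-ratio tests and by AIC with Akaike weights, from which a 95%
confidence set of models is assembled.

The common eigenvector basis is found by the Flury-Gautschi (FG) approach:
Jacobi-style sweeps over column pairs, each pair rotated by the angle that
minimises the weighted log-determinant deviance.  Partial-CPC bases are
fitted with the same pairwise machinery, restricted to rotations that move
a common column, and initialised from the full-CPC solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering

import numpy as np
from scipy import stats

from .datamodel import CovarianceEstimate

__all__ = [
    "FluryLevel",
    "UNRELATED",
    "CPC",
    "PROPORTIONAL",
    "EQUAL",
    "pcpc",
    "hierarchy",
    "count_params",
    "fg_common_basis",
    "fit_level",
    "fit_hierarchy",
    "step_up_select",
    "aic_select",
    "ModelFit",
    "HierarchyResult",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge."""


@total_ordering
@dataclass(frozen=True)
class FluryLevel:
    """One rung of the hierarchy; ordered by increasing constraint."""

    kind: str  # "unrelated" | "pcpc" | "cpc" | "proportional" | "equal"
    q: int = 0  # number of common components, for kind == "pcpc"

    _ORDER = {"unrelated": 0, "pcpc": 1, "cpc": 2, "proportional": 3, "equal": 4}

    def __post_init__(self) -> None:
        if self.kind not in self._ORDER:
            raise ValueError(f"unknown hierarchy level kind {self.kind!r}")
        if self.kind == "pcpc" and self.q < 0:
            # q = 0 is permitted as a degenerate level for parameter-count
            # algebra; it never appears in a fitted hierarchy
            raise ValueError("PCPC order q must be >= 0")

    def _key(self) -> tuple[int, int]:
        return (self._ORDER[self.kind], self.q)

    def __lt__(self, other: "FluryLevel") -> bool:
        return self._key() < other._key()

    def __str__(self) -> str:
        if self.kind == "pcpc":
            return f"PCPC({self.q})"
        return {"unrelated": "Unrelated", "cpc": "CPC",
                "proportional": "Proportional", "equal": "Equal"}[self.kind]


UNRELATED = FluryLevel("unrelated")
CPC = FluryLevel("cpc")
PROPORTIONAL = FluryLevel("proportional")
EQUAL = FluryLevel("equal")


def pcpc(q: int) -> FluryLevel:
    """Partial common principal components with ``q`` shared axes."""
    return FluryLevel("pcpc", q)


def hierarchy(p: int) -> list[FluryLevel]:
    """The full model ladder for ``p`` traits: ``p + 2`` levels.

    PCPC orders run from 1 to ``p - 2`` (sharing ``p - 1`` orthonormal axes
    already determines the last one, so PCPC(p-1) coincides with CPC).
    """
    if p < 2:
        raise ValueError("need at least 2 traits")
    return [UNRELATED, *(pcpc(q) for q in range(1, p - 1)), CPC, PROPORTIONAL, EQUAL]


def count_params(level: FluryLevel, p: int, g: int) -> int:
    """Free-parameter count of a hierarchy level for p traits and g groups."""
    if p < 2 or g < 1:
        raise ValueError("need p >= 2 and g >= 1")
    if level.kind == "equal":
        return p * (p + 1) // 2
    if level.kind == "proportional":
        return p * (p + 1) // 2 + (g - 1)
    if level.kind == "cpc":
        return p * (p - 1) // 2 + g * p
    if level.kind == "pcpc":
        q = level.q
        return p * (p - 1) // 2 + g * p + (g - 1) * (p - q) * (p - q - 1) // 2
    return g * p * (p + 1) // 2  # unrelated


# ---------------------------------------------------------------------------
# FG pairwise-rotation machinery
# ---------------------------------------------------------------------------

_GRID = np.linspace(-np.pi / 4, np.pi / 4, 17)


def _cc_angle(T_list, w, j, k, iters=30, tol=1e-14):
    """Optimal rotation angle for a pair of common columns.

    The FG two-by-two subproblem: with per-group blocks T_i, iterate the
    fixed point in which the rotation diagonalises
    ``M = sum_i w_i (d_i1 - d_i2)/(d_i1 d_i2) T_i``,
    where d_i1, d_i2 are the rotated diagonal entries.  Converges in a
    handful of iterations; returns the angle in (-pi/4, pi/4]."""
    blocks = [np.array([[T[j, j], T[j, k]], [T[j, k], T[k, k]]]) for T in T_list]
    theta = 0.0
    for _ in range(iters):
        c, s = np.cos(theta), np.sin(theta)
        m00 = m01 = m11 = 0.0
        for T2, wi in zip(blocks, w):
            d1 = c * c * T2[0, 0] + 2 * c * s * T2[0, 1] + s * s * T2[1, 1]
            d2 = s * s * T2[0, 0] - 2 * c * s * T2[0, 1] + c * c * T2[1, 1]
            coef = wi * (d1 - d2) / (d1 * d2)
            m00 += coef * T2[0, 0]
            m01 += coef * T2[0, 1]
            m11 += coef * T2[1, 1]
        new_theta = 0.5 * np.arctan2(2.0 * m01, m00 - m11)
        if abs(new_theta - theta) < tol:
            theta = new_theta
            break
        theta = new_theta
    return theta


def _fix_signs_and_order(B: np.ndarray, pooled: np.ndarray, n_free: int | None = None
                         ) -> np.ndarray:
    """Order columns by descending pooled variance; make the largest-magnitude
    element of each column positive (ties broken by first index).

    With ``n_free`` set, only the first ``n_free`` columns are reordered among
    themselves (used for partial-CPC bases, whose trailing columns only span
    the group-specific subspace)."""
    B = B.copy()
    p = B.shape[1]
    k = p if n_free is None else n_free
    pooled_var = np.einsum("ij,jk,ik->i", B[:, :k].T, pooled, B[:, :k].T)
    order = np.argsort(-pooled_var, kind="stable")
    B[:, :k] = B[:, order]
    for j in range(p):
        col = B[:, j]
        idx = int(np.argmax(np.abs(col)))
        if col[idx] < 0:
            B[:, j] = -col
    return B


def _pair_value_cc(T_list, w, j, k, thetas):
    """Deviance terms for rotating columns (j, k) when both are common."""
    c, s = np.cos(thetas), np.sin(thetas)
    total = np.zeros_like(thetas)
    for T, wi in zip(T_list, w):
        tjj, tjk, tkk = T[j, j], T[j, k], T[k, k]
        d1 = c * c * tjj + 2 * c * s * tjk + s * s * tkk
        d2 = s * s * tjj - 2 * c * s * tjk + c * c * tkk
        total += wi * (np.log(d1) + np.log(d2))
    return total


def _pair_value_cn(T_list, w, j, k, nc_idx, thetas):
    """Deviance terms for rotating common column j against non-common k.

    The group-specific block contributes ln det of the rotated non-common
    principal submatrix, evaluated per angle."""
    thetas = np.atleast_1d(thetas)
    c, s = np.cos(thetas), np.sin(thetas)
    pos_k = nc_idx.index(k)
    other = [m for m in nc_idx if m != k]
    oi = [nc_idx.index(m) for m in other]
    total = np.zeros_like(thetas)
    for T, wi in zip(T_list, w):
        tjj, tjk, tkk = T[j, j], T[j, k], T[k, k]
        d1 = c * c * tjj + 2 * c * s * tjk + s * s * tkk
        base = T[np.ix_(nc_idx, nc_idx)]
        stack = np.broadcast_to(base, (len(thetas),) + base.shape).copy()
        if other:
            cross = -s[:, None] * T[j, other][None, :] + c[:, None] * T[k, other][None, :]
            stack[:, pos_k, oi] = cross
            stack[:, oi, pos_k] = cross
        stack[:, pos_k, pos_k] = s * s * tjj - 2 * c * s * tjk + c * c * tkk
        sign, logdet = np.linalg.slogdet(stack)
        total += wi * (np.log(d1) + logdet)
    return total


def _rotate(B, T_list, j, k, theta):
    c, s = np.cos(theta), np.sin(theta)
    bj, bk = B[:, j].copy(), B[:, k].copy()
    B[:, j], B[:, k] = c * bj + s * bk, -s * bj + c * bk
    for T in T_list:
        tj, tk = T[:, j].copy(), T[:, k].copy()
        T[:, j], T[:, k] = c * tj + s * tk, -s * tj + c * tk
        tj, tk = T[j, :].copy(), T[k, :].copy()
        T[j, :], T[k, :] = c * tj + s * tk, -s * tj + c * tk


def _partial_deviance(T_list, w, q):
    """Weighted deviance of a (partial) CPC basis given T_i = B' S_i B.

    For q common columns: sum_i w_i [ sum_{j<q} ln T_i[j,j]
    + ln det(T_i[q:, q:]) - ln det(T_i) ]; for q = p the last block is empty.
    """
    total = 0.0
    for T, wi in zip(T_list, w):
        val = np.sum(np.log(np.diag(T)[:q]))
        if q < T.shape[0]:
            val += np.linalg.slogdet(T[q:, q:])[1]
        val -= np.linalg.slogdet(T)[1]
        total += wi * val
    return total


def _optimize_basis(S_list, w, q, B0, tol=1e-10, max_sweeps=500):
    """Minimise the (partial-)CPC deviance by pairwise column rotations.

    ``q`` is the number of common columns (q = p gives the full FG common
    basis).  Returns (B, deviance, n_sweeps)."""
    p = S_list[0].shape[0]
    B = B0.copy()
    T_list = [B.T @ S @ B for S in S_list]
    pairs = [(j, k) for j in range(min(q, p)) for k in range(j + 1, p)]
    dev = _partial_deviance(T_list, w, q)
    nc_idx = list(range(q, p))
    for sweep in range(1, max_sweeps + 1):
        for j, k in pairs:
            if k < q:  # both columns common: analytic FG subproblem
                theta = _cc_angle(T_list, w, j, k)
                if theta != 0.0:
                    f0, f1 = _pair_value_cc(T_list, w, j, k,
                                            np.array([0.0, theta]))
                    if f1 < f0 - 1e-14:
                        _rotate(B, T_list, j, k, theta)
                continue
            fun = lambda th: _pair_value_cn(T_list, w, j, k, nc_idx, th)
            grid = _GRID
            vals = fun(grid)
            f0 = vals[len(grid) // 2]  # grid is symmetric: centre is theta = 0
            best = int(np.argmin(vals))
            theta, fbest = grid[best], vals[best]
            half = (grid[1] - grid[0])
            for _ in range(3):  # vectorised shrinking-grid refinement
                grid = np.linspace(theta - half, theta + half, 9)
                vals = fun(grid)
                best = int(np.argmin(vals))
                theta, fbest = grid[best], vals[best]
                half = grid[1] - grid[0]
            if fbest < f0 - 1e-14:
                _rotate(B, T_list, j, k, theta)
        new_dev = _partial_deviance(T_list, w, q)
        if not np.isfinite(new_dev):
            raise ConvergenceError(f"deviance diverged (last value {dev!r})")
        if abs(dev - new_dev) < tol * max(1.0, abs(new_dev)):
            return B, new_dev, sweep
        dev = new_dev
    raise ConvergenceError(
        f"pairwise sweeps did not converge in {max_sweeps} sweeps "
        f"(last deviance {dev!r})"
    )


def _extract(samples):
    S_list = [np.asarray(s.matrix, float) for s in samples]
    n_list = [s.n for s in samples]
    w = np.array([n - 1.0 for n in n_list])
    p = S_list[0].shape[0]
    names = samples[0].trait_names
    for s in S_list[1:]:
        if s.shape != (p, p):
            raise ValueError("all covariance matrices must share the trait set")
    for s in samples[1:]:
        if s.trait_names != names:
            raise ValueError("all covariance matrices must share the trait set")
    for i, S in enumerate(S_list):
        evals = np.linalg.eigvalsh(S)
        if evals.min() <= 1e-12 * max(evals.max(), 1.0):
            raise ValueError(f"group {i} covariance is singular; cannot fit")
    return S_list, n_list, w, p


def fg_common_basis(
    samples: list[CovarianceEstimate],
    weights: np.ndarray | None = None,
    tol: float = 1e-10,
    max_sweeps: int = 500,
) -> np.ndarray:
    """Maximum-likelihood common eigenvector basis for a set of covariances.

    Minimises the deviance ``sum_i w_i ln[det(diag(B'S_iB)) / det(B'S_iB)]``
    over orthogonal B via FG pairwise rotations, with group weights
    defaulting to ``n_i - 1``.  Columns are ordered by descending pooled
    variance and sign-fixed so each column's largest-magnitude element is
    positive.  A single group degenerates to ordinary PCA of that matrix.
    """
    S_list, n_list, w, p = _extract(samples)
    if weights is not None:
        w = np.asarray(weights, float)
    pooled = sum(wi * S for wi, S in zip(w, S_list)) / w.sum()
    if len(S_list) == 1:
        _, vecs = np.linalg.eigh(S_list[0])
        return _fix_signs_and_order(vecs, pooled)
    _, B0 = np.linalg.eigh(pooled)
    B, _, _ = _optimize_basis(S_list, w, p, B0, tol=tol, max_sweeps=max_sweeps)
    return _fix_signs_and_order(B, pooled)


# ---------------------------------------------------------------------------
# Per-level maximum-likelihood fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelFit:
    """Constrained ML fit of one hierarchy level."""

    level: FluryLevel
    constrained: tuple[np.ndarray, ...]  # per-group Sigma_hat
    basis: np.ndarray | None  # common basis (CPC/PCPC), else None
    chi2: float  # LR statistic vs the unrelated model
    params: int
    df_vs_unrelated: int
    aic: float


def _chi2_from_estimates(S_list, constrained, w):
    val = 0.0
    for S, C, wi in zip(S_list, constrained, w):
        val += wi * (np.linalg.slogdet(C)[1] - np.linalg.slogdet(S)[1])
    return max(val, 0.0)


def _fit_proportional(S_list, w, tol=1e-10, max_iter=1000):
    g = len(S_list)
    p = S_list[0].shape[0]
    rho = np.ones(g)
    for _ in range(max_iter):
        sigma = sum(wi * S / r for wi, S, r in zip(w, S_list, rho)) / w.sum()
        new_rho = np.array(
            [np.trace(np.linalg.solve(sigma, S)) / p for S in S_list]
        )
        new_rho = new_rho / new_rho[0]  # identifiability: rho_1 = 1
        if np.max(np.abs(new_rho - rho)) < tol * max(1.0, np.max(np.abs(new_rho))):
            rho = new_rho
            break
        rho = new_rho
    else:
        raise ConvergenceError("proportionality constants did not converge")
    sigma = sum(wi * S / r for wi, S, r in zip(w, S_list, rho)) / w.sum()
    return [r * sigma for r in rho], rho


def _cpc_estimates(S_list, B):
    return [B @ np.diag(np.diag(B.T @ S @ B)) @ B.T for S in S_list]


def _pcpc_estimates(S_list, B, q):
    Q, N = B[:, :q], B[:, q:]
    out = []
    for S in S_list:
        out.append(
            Q @ np.diag(np.diag(Q.T @ S @ Q)) @ Q.T + N @ (N.T @ S @ N) @ N.T
        )
    return out


def fit_level(
    samples: list[CovarianceEstimate],
    level: FluryLevel,
    basis_init: np.ndarray | None = None,
    tol: float = 1e-10,
    max_sweeps: int = 500,
) -> ModelFit:
    """Fit one hierarchy level by constrained maximum likelihood.

    ``basis_init`` seeds the pairwise-rotation optimiser for CPC/PCPC levels
    (defaults to the eigenbasis of the pooled covariance).
    """
    S_list, n_list, w, p = _extract(samples)
    g = len(S_list)
    if level.kind == "pcpc" and not 1 <= level.q <= p - 2:
        raise ValueError(f"PCPC({level.q}) infeasible for p={p} (1 <= q <= {p - 2})")

    basis = None
    if level.kind == "unrelated":
        constrained = list(S_list)
    elif level.kind == "equal":
        pooled = sum(wi * S for wi, S in zip(w, S_list)) / w.sum()
        constrained = [pooled] * g
    elif level.kind == "proportional":
        constrained, _ = _fit_proportional(S_list, w)
    else:
        pooled = sum(wi * S for wi, S in zip(w, S_list)) / w.sum()
        if basis_init is None:
            _, basis_init = np.linalg.eigh(pooled)
        q = p if level.kind == "cpc" else level.q
        B, _, _ = _optimize_basis(S_list, w, q, basis_init, tol=tol,
                                  max_sweeps=max_sweeps)
        basis = _fix_signs_and_order(B, pooled, n_free=q)
        if level.kind == "cpc":
            constrained = _cpc_estimates(S_list, basis)
        else:
            constrained = _pcpc_estimates(S_list, basis, q)

    for C in constrained:
        if np.linalg.eigvalsh(C).min() <= 0:
            raise ConvergenceError(f"constrained estimate at {level} is not PD")
    chi2 = _chi2_from_estimates(S_list, constrained, w)
    params = count_params(level, p, g)
    df = count_params(UNRELATED, p, g) - params
    return ModelFit(
        level=level,
        constrained=tuple(constrained),
        basis=basis,
        chi2=chi2,
        params=params,
        df_vs_unrelated=df,
        aic=chi2 + 2.0 * params,
    )


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HierarchyResult:
    """All per-level fits plus both model selections."""

    fits: tuple[ModelFit, ...]  # ordered by increasing constraint
    stepup_selected: FluryLevel
    stepup_pvalues: tuple[float, ...]  # one per adjacent pair
    aic_selected: FluryLevel
    weights: tuple[float, ...]  # Akaike weights, aligned with fits
    confidence_set: tuple[FluryLevel, ...]

    @property
    def levels(self) -> tuple[FluryLevel, ...]:
        return tuple(f.level for f in self.fits)

    def fit(self, level: FluryLevel) -> ModelFit:
        for f in self.fits:
            if f.level == level:
                return f
        raise KeyError(f"level {level} not in result")


def step_up_select(
    fits: list[ModelFit], alpha: float = 0.05
) -> tuple[FluryLevel, tuple[float, ...]]:
    """Classical step-up selection: climb the ladder until the first rejection.

    Each level is tested against the next-less-constrained one with
    Delta-chi2 on Delta-params degrees of freedom; the selected level is the
    most constrained model reached before the first p-value drops below
    ``alpha``.
    """
    pvalues = []
    selected = fits[0].level
    rejected = False
    for prev, cur in zip(fits, fits[1:]):
        dchi2 = cur.chi2 - prev.chi2
        if dchi2 < -1e-6 * max(1.0, abs(cur.chi2)):
            raise ConvergenceError(
                f"chi2 decreased from {prev.level} ({prev.chi2:.6g}) to "
                f"{cur.level} ({cur.chi2:.6g}); numerical failure"
            )
        ddf = prev.params - cur.params
        pval = float(stats.chi2.sf(max(dchi2, 0.0), ddf))
        pvalues.append(pval)
        if not rejected:
            if pval < alpha:
                rejected = True
            else:
                selected = cur.level
    return selected, tuple(pvalues)


def aic_select(
    fits: list[ModelFit], conf: float = 0.95
) -> tuple[FluryLevel, tuple[float, ...], tuple[FluryLevel, ...]]:
    """AIC selection with Akaike weights and a confidence set of models.

    Weights ``w_i = exp(-Delta_i / 2) / sum_j exp(-Delta_j / 2)`` are read as
    the probability that model i is the best of the set; the confidence set
    is the smallest weight-descending prefix with cumulative weight >= conf.
    Ties on minimal AIC resolve to the more constrained level.
    """
    aics = np.array([f.chi2 + 2.0 * f.params for f in fits])
    delta = aics - aics.min()
    raw = np.exp(-delta / 2.0)
    weights = raw / raw.sum()
    best = int(np.flatnonzero(aics == aics.min())[-1])
    order = np.argsort(-weights, kind="stable")
    cum = 0.0
    members: list[FluryLevel] = []
    for idx in order:
        members.append(fits[idx].level)
        cum += weights[idx]
        if cum >= conf - 1e-12:
            break
    return fits[best].level, tuple(float(x) for x in weights), tuple(members)


def fit_hierarchy(
    samples: list[CovarianceEstimate],
    alpha: float = 0.05,
    conf: float = 0.95,
    tol: float = 1e-10,
    max_sweeps: int = 500,
) -> HierarchyResult:
    """Fit every level of the Flury hierarchy and run both selectors.

    Partial-CPC fits are chained: PCPC(p-2) starts from the full-CPC basis
    and each PCPC(q) starts from the PCPC(q+1) solution, which guarantees
    the fitted chi2 sequence is monotone in the constraint ordering.
    """
    S_list, n_list, w, p = _extract(samples)
    by_level: dict[FluryLevel, ModelFit] = {}
    ladder = hierarchy(p)

    cpc_fit = fit_level(samples, CPC, tol=tol, max_sweeps=max_sweeps)
    by_level[CPC] = cpc_fit
    prev_basis = cpc_fit.basis
    for q in range(p - 2, 0, -1):
        fit = fit_level(samples, pcpc(q), basis_init=prev_basis, tol=tol,
                        max_sweeps=max_sweeps)
        by_level[pcpc(q)] = fit
        prev_basis = fit.basis
    for level in (UNRELATED, PROPORTIONAL, EQUAL):
        by_level[level] = fit_level(samples, level, tol=tol, max_sweeps=max_sweeps)

    fits = [by_level[lv] for lv in ladder]
    stepup_level, pvals = step_up_select(fits, alpha=alpha)
    aic_level, weights, conf_set = aic_select(fits, conf=conf)
    return HierarchyResult(
        fits=tuple(fits),
        stepup_selected=stepup_level,
        stepup_pvalues=pvals,
        aic_selected=aic_level,
        weights=weights,
        confidence_set=conf_set,
    )
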