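"""Robust estimation of read coordinates from overlap observations.

Each observation y = beta_j - beta_i is a row of a sparse oriented-incidence
system Y = X beta + eps, whose weakly connected components correspond to
contigs.  Within a component the incidence block has rank n_k - 1, so one
read per component is anchored (a pseudo read at its known coordinate, else
the member with the smallest prior at that prior) by appending a single-entry
anchor row, which restores full column rank without biasing the fit: residuals
of overlap rows are invariant to a constant shift, so every (weighted) least
squares optimum satisfies the anchor exactly.

Estimation is a two-step robust procedure:

Step 1 - a Huber M-estimate computed by iteratively reweighted least squares
(IRLS): starting from the OLS solution, each iteration solves the weighted
normal equations X' W X beta = X' W Y with W the product of the initial
observation weights and the Huber weights w_H(eps) = 1 for |eps| <= c, else
c/|eps|, until the max coordinate change drops below alpha.  The Huber loss is
convex, so the iteration converges to the global minimum; residuals are taken
in bp and not rescaled by a robust scale estimate (the tuning constant c is
expressed directly in bp).

Step 2 - observations whose Step-1 residuals exceed r_o are flagged as
potential outliers (false overlaps) and an ordinary least squares fit is
computed on the remaining rows.  If trimming disconnects a component, each
new component is re-anchored and refit separately.  Final coordinates are
rounded to the nearest integer (ties away from zero).

The statsmodels-style surface is `HuberLayoutModel` / `LayoutFitResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import lgmres, splu

from .overlap import OverlapObservation
from .util import round_half_away

#: relative tolerance of the inner LGMRES solves; the final solve is tightened
SOLVER_RTOL = 1e-6
SOLVER_RTOL_FINAL = 1e-10


@dataclass
class RobustConfig:
    """Tuning constants of the two-step robust fit (all in bp)."""

    c: float = 2.0  # Huber tuning constant
    r_o: float = 10.0  # outlier residual threshold
    alpha: float = 2.0  # IRLS convergence threshold (max coordinate change)
    max_iter: int = 100

    def __post_init__(self):
        if self.c <= 0 or self.r_o <= 0 or self.alpha <= 0 or self.max_iter < 1:
            raise ValueError("c, r_o, alpha must be positive and max_iter >= 1")


def huber_rho(eps: np.ndarray, c: float) -> np.ndarray:
    """Huber loss: eps^2/2 inside |eps| <= c, c|eps| - c^2/2 outside."""
    a = np.abs(eps)
    return np.where(a <= c, 0.5 * eps**2, c * a - 0.5 * c**2)


def huber_weight(eps: np.ndarray, c: float) -> np.ndarray:
    """IRLS weight induced by the Huber loss: 1 inside, c/|eps| outside."""
    a = np.abs(np.asarray(eps, dtype=float))
    with np.errstate(divide="ignore"):
        return np.where(a <= c, 1.0, c / np.where(a > 0, a, 1.0))


@dataclass
class RegressionProblem:
    """Sparse oriented-incidence system with components and anchors."""

    n: int
    m: int
    X: sp.csr_matrix  # m x n, each row -1 at i and +1 at j
    Y: np.ndarray
    W0: np.ndarray
    observations: list[OverlapObservation]
    priors: np.ndarray
    pseudo_anchors: dict[int, float]
    components: list[np.ndarray]
    anchors: list[tuple[int, float]]  # per component: (read index, coordinate)


def _split_components(n: int, edges: Sequence[tuple[int, int]]) -> list[np.ndarray]:
    if edges:
        ii = [e[0] for e in edges]
        jj = [e[1] for e in edges]
        A = sp.coo_matrix((np.ones(len(edges)), (ii, jj)), shape=(n, n))
    else:
        A = sp.coo_matrix((n, n))
    ncomp, labels = connected_components(A, directed=False)
    return [np.nonzero(labels == k)[0] for k in range(ncomp)]


def _anchor_for(
    members: np.ndarray, priors: np.ndarray, pseudo_anchors: dict[int, float]
) -> tuple[int, float]:
    for idx in members:
        if int(idx) in pseudo_anchors:
            return int(idx), float(pseudo_anchors[int(idx)])
    k = members[int(np.argmin(priors[members]))]
    return int(k), float(priors[k])


def build_problem(
    observations: Sequence[OverlapObservation],
    n: int,
    priors: Optional[Sequence[float]] = None,
    pseudo_anchors: Optional[dict[int, float]] = None,
) -> RegressionProblem:
    """Assemble the sparse incidence system and anchor each component.

    Duplicate (i, j) observations are kept as separate rows: they are
    independent measurements.  Reads with no observations form singleton
    components anchored at their prior.
    """
    observations = list(observations)
    m = len(observations)
    priors = np.zeros(n) if priors is None else np.asarray(priors, dtype=float)
    pseudo_anchors = dict(pseudo_anchors or {})
    for o in observations:
        if not (0 <= o.i < n and 0 <= o.j < n):
            raise ValueError("observation read index out of range")
    rows = np.repeat(np.arange(m), 2)
    cols = np.empty(2 * m, dtype=np.int64)
    vals = np.empty(2 * m)
    for k, o in enumerate(observations):
        cols[2 * k], cols[2 * k + 1] = o.i, o.j
        vals[2 * k], vals[2 * k + 1] = -1.0, 1.0
    X = sp.csr_matrix((vals, (rows, cols)), shape=(m, n))
    Y = np.array([o.y for o in observations], dtype=float)
    W0 = np.array([o.weight for o in observations], dtype=float)
    comps = _split_components(n, [(o.i, o.j) for o in observations])
    anchors = [_anchor_for(c, priors, pseudo_anchors) for c in comps]
    return RegressionProblem(
        n=n, m=m, X=X, Y=Y, W0=W0, observations=observations,
        priors=priors, pseudo_anchors=pseudo_anchors,
        components=comps, anchors=anchors,
    )


def _augmented(problem: RegressionProblem, anchors) -> tuple[sp.csr_matrix, np.ndarray]:
    """Append one single-entry anchor row per component."""
    rows = []
    vals = []
    for idx, coord in anchors:
        r = sp.csr_matrix(([1.0], ([0], [idx])), shape=(1, problem.n))
        rows.append(r)
        vals.append(coord)
    Xa = sp.vstack([problem.X] + rows, format="csr") if rows else problem.X
    Ya = np.concatenate([problem.Y, np.array(vals)])
    return Xa, Ya


def _solve_wls(
    Xa: sp.csr_matrix, Ya: np.ndarray, w: np.ndarray,
    x0: Optional[np.ndarray], rtol: float,
) -> np.ndarray:
    """Solve the weighted normal equations Xa' W Xa beta = Xa' W Ya."""
    W = sp.diags(w)
    A = (Xa.T @ W @ Xa).tocsc()
    b = Xa.T @ (w * Ya)
    x, info = lgmres(A, b, x0=x0, rtol=rtol, atol=0.0, maxiter=1000)
    if info != 0 or not np.all(np.isfinite(x)):
        x = splu(A.tocsc()).solve(b)  # direct fallback on non-convergence
    return x


def objective(problem: RegressionProblem, beta: np.ndarray, cfg: RobustConfig) -> float:
    """Weighted Huber objective sum_i w0_i rho_H(y_i - x_i' beta)."""
    resid = problem.Y - problem.X @ beta
    return float(np.sum(problem.W0 * huber_rho(resid, cfg.c)))


@dataclass
class IRLSResult:
    beta: np.ndarray
    residuals: np.ndarray
    iterations: int
    converged: bool
    objective_path: list[float]


def huber_irls(problem: RegressionProblem, cfg: Optional[RobustConfig] = None) -> IRLSResult:
    """Huber M-estimate of the read coordinates by IRLS.

    Initialized at the OLS solution; stops when the max coordinate change is
    below ``cfg.alpha`` or after ``cfg.max_iter`` iterations (then
    ``converged`` is False and the best iterate is returned).  Anchor rows
    always keep weight 1 and are never reweighted.
    """
    cfg = cfg or RobustConfig()
    Xa, Ya = _augmented(problem, problem.anchors)
    n_anchor = len(problem.anchors)
    w0 = np.concatenate([problem.W0, np.ones(n_anchor)])
    beta = _solve_wls(Xa, Ya, w0, None, SOLVER_RTOL)
    path = [objective(problem, beta, cfg)]
    converged = problem.m == 0
    it = 0
    for it in range(1, cfg.max_iter + 1):
        resid = problem.Y - problem.X @ beta
        w = np.concatenate([problem.W0 * huber_weight(resid, cfg.c), np.ones(n_anchor)])
        beta_new = _solve_wls(Xa, Ya, w, beta, SOLVER_RTOL)
        path.append(objective(problem, beta_new, cfg))
        delta = np.max(np.abs(beta_new - beta)) if problem.n else 0.0
        beta = beta_new
        if delta < cfg.alpha:
            converged = True
            break
    # tightened final solve at the converged weights
    resid = problem.Y - problem.X @ beta
    w = np.concatenate([problem.W0 * huber_weight(resid, cfg.c), np.ones(n_anchor)])
    beta = _solve_wls(Xa, Ya, w, beta, SOLVER_RTOL_FINAL)
    resid = problem.Y - problem.X @ beta
    path.append(objective(problem, beta, cfg))
    return IRLSResult(beta=beta, residuals=resid, iterations=it,
                      converged=converged, objective_path=path)


@dataclass
class RobustFit:
    """Result of the two-step robust fit."""

    beta: np.ndarray  # rounded integer coordinates
    beta_continuous: np.ndarray
    beta_step1: np.ndarray
    residuals: np.ndarray  # all observation rows at the final estimate
    outliers: np.ndarray  # boolean mask over observations
    iterations: int
    converged: bool
    components_final: list[np.ndarray]
    anchors_final: list[tuple[int, float]]

    @property
    def outlier_indices(self) -> np.ndarray:
        return np.nonzero(self.outliers)[0]


def ols_fit(problem: RegressionProblem) -> np.ndarray:
    """Plain OLS coordinates (no reweighting, no trimming); for comparison."""
    Xa, Ya = _augmented(problem, problem.anchors)
    w = np.concatenate([problem.W0, np.ones(len(problem.anchors))])
    return _solve_wls(Xa, Ya, w, None, SOLVER_RTOL_FINAL)


def two_step_fit(problem: RegressionProblem, cfg: Optional[RobustConfig] = None) -> RobustFit:
    """Huber M-estimate, outlier trimming at r_o, then OLS on the kept rows.

    If trimming disconnects a component, each new component is re-anchored (at
    its pseudo read's coordinate when present, else at its smallest-prior
    member's Step-1 estimate) and refit.  Coordinates are rounded to the
    nearest integer, ties away from zero.
    """
    cfg = cfg or RobustConfig()
    step1 = huber_irls(problem, cfg)
    out_mask = np.abs(step1.residuals) > cfg.r_o
    kept = [o for o, bad in zip(problem.observations, out_mask) if not bad]
    kept_idx = np.nonzero(~out_mask)[0]

    comps = _split_components(problem.n, [(o.i, o.j) for o in kept])
    anchors: list[tuple[int, float]] = []
    for members in comps:
        found = None
        for idx in members:
            if int(idx) in problem.pseudo_anchors:
                found = (int(idx), float(problem.pseudo_anchors[int(idx)]))
                break
        if found is None:
            k = members[int(np.argmin(problem.priors[members]))]
            found = (int(k), float(step1.beta[k]))
        anchors.append(found)

    sub = RegressionProblem(
        n=problem.n, m=len(kept),
        X=problem.X[kept_idx] if len(kept) else sp.csr_matrix((0, problem.n)),
        Y=problem.Y[kept_idx], W0=problem.W0[kept_idx],
        observations=kept, priors=problem.priors,
        pseudo_anchors=problem.pseudo_anchors,
        components=comps, anchors=anchors,
    )
    Xa, Ya = _augmented(sub, anchors)
    w = np.concatenate([sub.W0, np.ones(len(anchors))])
    beta = _solve_wls(Xa, Ya, w, step1.beta, SOLVER_RTOL_FINAL)
    resid = problem.Y - problem.X @ beta
    return RobustFit(
        beta=round_half_away(beta),
        beta_continuous=beta,
        beta_step1=step1.beta,
        residuals=resid,
        outliers=out_mask,
        iterations=step1.iterations,
        converged=step1.converged,
        components_final=comps,
        anchors_final=anchors,
    )


class HuberLayoutModel:
    """Read-layout model: overlap observations -> robust read coordinates.

    Parameters
    ----------
    observations : sequence of OverlapObservation
        Distance observations between reads' ending bases.
    n_reads : int
        Number of reads (model parameters).
    priors : sequence of float, optional
        Prior coordinates, used for anchoring unanchored components.
    pseudo_anchors : dict, optional
        Read index -> fixed coordinate for reads with known positions.

    Examples
    --------
    >>> obs = [OverlapObservation(0, 1, 5.0)]
    >>> res = HuberLayoutModel(obs, n_reads=2).fit()
    >>> list(res.params)
    [0, 5]
    """

    def __init__(self, observations, n_reads, priors=None, pseudo_anchors=None):
        self.problem = build_problem(observations, n_reads, priors, pseudo_anchors)

    @classmethod
    def from_arrays(cls, i, j, y, n_reads, weights=None, **kw) -> "HuberLayoutModel":
        weights = np.ones(len(y)) if weights is None else weights
        obs = [
            OverlapObservation(i=int(a), j=int(b), y=float(v), weight=float(w))
            for a, b, v, w in zip(i, j, y, weights)
        ]
        return cls(obs, n_reads, **kw)

    def fit(self, cfg: Optional[RobustConfig] = None, method: str = "two_step") -> "LayoutFitResults":
        cfg = cfg or RobustConfig()
        if method == "two_step":
            fit = two_step_fit(self.problem, cfg)
        elif method == "huber":
            r = huber_irls(self.problem, cfg)
            fit = RobustFit(
                beta=round_half_away(r.beta), beta_continuous=r.beta,
                beta_step1=r.beta, residuals=r.residuals,
                outliers=np.zeros(self.problem.m, dtype=bool),
                iterations=r.iterations, converged=r.converged,
                components_final=self.problem.components,
                anchors_final=self.problem.anchors,
            )
        elif method == "ols":
            b = ols_fit(self.problem)
            fit = RobustFit(
                beta=round_half_away(b), beta_continuous=b, beta_step1=b,
                residuals=self.problem.Y - self.problem.X @ b,
                outliers=np.zeros(self.problem.m, dtype=bool),
                iterations=0, converged=True,
                components_final=self.problem.components,
                anchors_final=self.problem.anchors,
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        return LayoutFitResults(self, fit, cfg, method)


class LayoutFitResults:
    """Estimates, residuals, outlier diagnostics, and a summary table."""

    def __init__(self, model: HuberLayoutModel, fit: RobustFit, cfg: RobustConfig, method: str):
        self.model = model
        self._fit = fit
        self.config = cfg
        self.method = method

    @property
    def params(self) -> np.ndarray:
        """Rounded integer read coordinates."""
        return self._fit.beta

    @property
    def params_continuous(self) -> np.ndarray:
        return self._fit.beta_continuous

    @property
    def resid(self) -> np.ndarray:
        return self._fit.residuals

    @property
    def outlier_mask(self) -> np.ndarray:
        return self._fit.outliers

    @property
    def n_outliers(self) -> int:
        return int(self._fit.outliers.sum())

    @property
    def n_iter(self) -> int:
        return self._fit.iterations

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def components(self) -> list[np.ndarray]:
        return self._fit.components_final

    @property
    def anchors(self) -> list[tuple[int, float]]:
        return self._fit.anchors_final

    def bse(self) -> Optional[np.ndarray]:
        """OLS standard errors of coordinates on the trimmed system.

        Computed densely; None for systems with more than 2000 reads.
        """
        p = self.model.problem
        if p.n > 2000:
            return None
        keep = ~self._fit.outliers
        Xk = p.X[np.nonzero(keep)[0]]
        rows = [sp.csr_matrix(([1.0], ([0], [i])), shape=(1, p.n))
                for i, _ in self._fit.anchors_final]
        Xa = sp.vstack([Xk] + rows, format="csr")
        resid = self._fit.residuals[keep]
        dof = max(Xa.shape[0] - p.n, 1)
        s2 = float(resid @ resid) / dof
        A = (Xa.T @ Xa).toarray()
        try:
            cov = s2 * np.linalg.inv(A)
        except np.linalg.LinAlgError:
            return None
        return np.sqrt(np.clip(np.diag(cov), 0, None))

    def summary(self) -> str:
        p = self.model.problem
        lines = [
            "Huber layout model fit",
            "=" * 46,
            f"method:          {self.method}",
            f"reads (n):       {p.n}",
            f"observations:    {p.m}",
            f"components:      {len(self._fit.components_final)}",
            f"outliers:        {self.n_outliers}"
            f" ({100.0 * self.n_outliers / max(p.m, 1):.1f}%)",
            f"IRLS iterations: {self.n_iter} (converged={self.converged})",
            f"huber c={self.config.c}  r_o={self.config.r_o}  alpha={self.config.alpha}",
        ]
        kept = self._fit.residuals[~self._fit.outliers]
        if kept.size:
            lines.append(
                f"kept-row residuals: median {np.median(np.abs(kept)):.2f} bp, "
                f"max {np.max(np.abs(kept)):.2f} bp"
            )
        return "\n".join(lines)
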