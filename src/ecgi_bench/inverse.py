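"""Zero-order Tikhonov inversion with L-curve regularization selection.

The epicardial potentials are recovered per time instant by minimizing
``||A x - y||^2 + lambda^2 ||x||^2``.  The SVD of ``A`` is computed once
and shared across instants and lambdas, so each solve reduces to
filter-factor multiplications.  The regularization parameter is chosen per
instant at the corner (maximum curvature) of the L-curve — the log-log
residual-norm vs solution-norm trade-off — using the exact closed-form
curvature in the SVD basis; the median lambda over the analysis window is
then used to solve every instant, matching the common single-lambda ECGI
practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bem import ForwardModel
from .recording import PotentialRecording


@dataclass
class SVDCache:
    U: np.ndarray
    s: np.ndarray
    Vt: np.ndarray

    @classmethod
    def of(cls, A: np.ndarray) -> "SVDCache":
        U, s, Vt = np.linalg.svd(np.asarray(A, dtype=float), full_matrices=False)
        return cls(U, s, Vt)


@dataclass
class InverseSolution:
    """Reconstructed epicardial potentials with the lambdas that made them."""

    X: np.ndarray  # (n_sources, n_samples), mV
    lambda_per_instant: np.ndarray  # over the analysis window(s)
    lambda_median: float
    beat_lambdas: list[float]  # median lambda used per beat
    residual_norms: np.ndarray
    solution_norms: np.ndarray
    forward: ForwardModel | None = None
    analysis_samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.lambda_per_instant):
            med = float(np.median(self.lambda_per_instant))
            if not np.isclose(med, self.lambda_median, rtol=1e-12, atol=0):
                raise ValueError("lambda_median must be the median of lambda_per_instant")


def default_lambda_grid(s: np.ndarray, n: int = 200, lo: float = 1e-8, hi: float = 1e2) -> np.ndarray:
    """Log-spaced lambdas spanning [lo, hi] x largest singular value."""
    smax = float(np.max(s))
    return np.logspace(np.log10(lo * smax), np.log10(hi * smax), n)


def tikhonov_solve(
    A: np.ndarray, y: np.ndarray, lam: float, svd: SVDCache | None = None, rank_tol: float = 1e-10
) -> np.ndarray:
    """Unique minimizer of the zero-order Tikhonov functional.

    ``y`` may be a vector or an (M, T) matrix of time instants.  With
    ``lam == 0`` the forward matrix must have full column rank.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if svd is None:
        svd = SVDCache.of(A)
    if lam == 0:
        rank = int(np.sum(svd.s > rank_tol * svd.s[0]))
        if rank < len(svd.s):
            raise np.linalg.LinAlgError(
                f"lambda = 0 with rank-deficient A (rank {rank} of {len(svd.s)})"
            )
    beta = svd.U.T @ y
    factors = svd.s / (svd.s**2 + lam**2)
    return svd.Vt.T @ (factors[:, None] * beta if beta.ndim == 2 else factors * beta)


def _lcurve_terms(svd: SVDCache, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta = svd.U.T @ y
    # component of y outside range(A): constant residual floor
    c0sq = max(float(y @ y - beta @ beta), 0.0)
    return beta, c0sq


def lcurve_curvature(
    s: np.ndarray, beta: np.ndarray, lams: np.ndarray, c0sq: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed curvature of (log rho, log eta) vs log lambda, closed form.

    With a = s_i^2, u = lambda^2:
      rho^2 = sum b_i^2 u^2/(a+u)^2 + c0^2,   eta^2 = sum b_i^2 a/(a+u)^2
    and all derivatives of log rho / log eta w.r.t. log lambda reduce to the
    sums S = sum b^2 a/(a+u)^3 and Q = sum b^2 a/(a+u)^4.  Returns
    (curvature, rho, eta) on the grid.
    """
    a = (s**2)[:, None]
    b2 = (beta**2)[:, None]
    u = (np.asarray(lams) ** 2)[None, :]
    den = a + u
    rho2 = np.sum(b2 * u**2 / den**2, axis=0) + c0sq
    eta2 = np.sum(b2 * a / den**2, axis=0)
    S = np.sum(b2 * a / den**3, axis=0)
    Q = np.sum(b2 * a / den**4, axis=0)
    u = u[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        xp = 2 * u**2 * S / rho2
        yp = -2 * u * S / eta2
        xpp = (8 * u**2 * S - 12 * u**3 * Q) / rho2 - 8 * u**4 * S**2 / rho2**2
        ypp = (-4 * u * S + 12 * u**2 * Q) / eta2 - 8 * u**2 * S**2 / eta2**2
        kappa = (xp * ypp - yp * xpp) / (xp**2 + yp**2) ** 1.5
    kappa = np.nan_to_num(kappa, nan=-np.inf)
    return kappa, np.sqrt(rho2), np.sqrt(eta2)


def lcurve_lambda(
    A: np.ndarray | SVDCache,
    y: np.ndarray,
    grid: np.ndarray | None = None,
) -> float:
    """Corner of the L-curve for a single time instant.

    Maximizes the signed curvature over the grid, breaking ties toward the
    larger lambda.  If the curvature never turns positive (no corner), the
    grid point of maximum curvature is returned with a warning.
    """
    svd = A if isinstance(A, SVDCache) else SVDCache.of(A)
    if grid is None:
        grid = default_lambda_grid(svd.s)
    if len(grid) < 2:
        raise ValueError("lambda grid needs at least 2 points")
    beta, c0sq = _lcurve_terms(svd, np.asarray(y, dtype=float))
    kappa, _, _ = lcurve_curvature(svd.s, beta, grid, c0sq)
    best = len(kappa) - 1 - int(np.argmax(kappa[::-1]))  # ties -> larger lambda
    if kappa[best] <= 0:
        warnings.warn("L-curve has no corner (curvature never positive); returning max-curvature point")
    return float(grid[best])


def _per_instant_lambdas(svd: SVDCache, Y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Vectorized L-curve corners for every column of Y."""
    beta = svd.U.T @ Y  # (r, T)
    c0sq = np.maximum(np.sum(Y * Y, axis=0) - np.sum(beta * beta, axis=0), 0.0)
    a = (svd.s**2)[:, None]
    u = (grid**2)[None, :]
    den = a + u  # (r, n_lam)
    b2 = beta**2  # (r, T)
    # all sums are matrix products: (n_lam, r) @ (r, T)
    rho2 = (u**2 / den**2).T @ b2 + c0sq[None, :]
    eta2 = (a / den**2).T @ b2
    S = (a / den**3).T @ b2
    Q = (a / den**4).T @ b2
    uu = grid[:, None] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        xp = 2 * uu**2 * S / rho2
        yp = -2 * uu * S / eta2
        xpp = (8 * uu**2 * S - 12 * uu**3 * Q) / rho2 - 8 * uu**4 * S**2 / rho2**2
        ypp = (-4 * uu * S + 12 * uu**2 * Q) / eta2 - 8 * uu**2 * S**2 / eta2**2
        kappa = (xp * ypp - yp * xpp) / (xp**2 + yp**2) ** 1.5
    kappa = np.nan_to_num(kappa, nan=-np.inf)
    rev = kappa[::-1]
    best = kappa.shape[0] - 1 - np.argmax(rev, axis=0)
    return grid[best]


def reconstruct(
    forward: ForwardModel,
    rec: PotentialRecording,
    window: slice | None = None,
    grid: np.ndarray | None = None,
    svd: SVDCache | None = None,
    pool: str = "global",
) -> InverseSolution:
    """Reconstruct epicardial potentials beat by beat.

    L-curve lambdas are selected at every instant of the analysis windows
    (the QRS windows from the segmentation, or ``window``); their median
    is the final lambda used to solve every instant.  ``pool="global"``
    (default) takes one median over all analyzed instants — instants whose
    L-curve has no corner are then outvoted by the rest of the recording —
    while ``pool="per-beat"`` uses each beat's own median.  Without
    segmentation the whole record is one beat.
    """
    if pool not in ("global", "per-beat"):
        raise ValueError("pool must be 'global' or 'per-beat'")
    A = forward.A
    if A.shape[0] != rec.n_leads:
        raise ValueError("forward rows do not match recording leads")
    if svd is None:
        svd = SVDCache.of(A)
    if grid is None:
        grid = default_lambda_grid(svd.s)

    seg = rec.segmentation
    if window is not None:
        analysis = [window]
        regions = [slice(0, rec.n_samples)]
    elif seg is not None and seg.n_beats > 0:
        analysis = [seg.qrs_window(b) for b in range(seg.n_beats)]
        regions = seg.beat_regions(rec.n_samples)
    else:
        analysis = [slice(0, rec.n_samples)]
        regions = [slice(0, rec.n_samples)]
    if any(a.stop <= a.start for a in analysis):
        raise ValueError("empty analysis window")
    if any(a.stop > rec.n_samples for a in analysis):
        raise ValueError("analysis window exceeds record length")

    per_window = [
        _per_instant_lambdas(svd, rec.values[:, awin], grid) for awin in analysis
    ]
    lam_all = np.concatenate(per_window)
    samples_all = np.concatenate([np.arange(a.start, a.stop) for a in analysis])
    lam_global = float(np.median(lam_all))
    X = np.zeros((A.shape[1], rec.n_samples))
    beat_lambdas = []
    for lams, region in zip(per_window, regions):
        lam_beat = lam_global if pool == "global" else float(np.median(lams))
        X[:, region] = tikhonov_solve(A, rec.values[:, region], lam_beat, svd=svd)
        beat_lambdas.append(lam_beat)
    resid = np.linalg.norm(A @ X[:, samples_all] - rec.values[:, samples_all], axis=0)
    sol = np.linalg.norm(X[:, samples_all], axis=0)
    return InverseSolution(
        X=X,
        lambda_per_instant=lam_all,
        lambda_median=float(np.median(lam_all)),
        beat_lambdas=beat_lambdas,
        residual_norms=resid,
        solution_norms=sol,
        forward=forward,
        analysis_samples=samples_all,
    )
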