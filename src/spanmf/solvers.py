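"""NMF solvers under a common stopping contract.

Four single-level solvers of ``min 0.5 ||X - WH||_F^2, W >= 0, H >= 0``:

- :func:`ahals_solve` — accelerated hierarchical alternating least squares:
  exact cyclic rank-one block-coordinate updates with extra inner passes.
- :func:`gd_solve` — gradient-descent NMF: the constraint is removed by the
  change of variables ``W = U*U``, ``H = V*V`` (element-wise squares) and the
  resulting nonlinear least-squares problem is solved by Gauss-Newton with a
  dogleg trust region, the linearized step computed by conjugate gradients
  from Jacobian-vector products.
- :func:`pg_solve` — alternating non-negative least squares, each subproblem
  solved by projected gradient with the Armijo rule along the projection arc.
- :func:`convexnmf_solve` — Convex NMF ``X ~ X A H`` (sources constrained to
  the column space of the data) by multiplicative updates of ``A`` and ``H``.

Every solver records ``||X - WH||_F`` per outer iteration (including the
initialization at index 0) and stops when the relative change of that
residual between successive iterations falls below ``cfg.tol`` or when
``cfg.max_iter`` is reached, so iteration counts are comparable across
solvers.  :func:`run_with_restarts` orchestrates the repetitive runs used
with the non-deterministic initializers and keeps the run with the lowest
final residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .initializers import fcm_init, random_init
from .matrix import Factorization, InitFactors, as_feature_matrix, residual
from .spa import convex_weights_init

__all__ = [
    "SolverConfig",
    "ahals_solve",
    "gd_solve",
    "pg_solve",
    "convexnmf_solve",
    "run_with_restarts",
    "solve",
    "SOLVERS",
]

logger = logging.getLogger(__name__)

_EPS = 1e-16  # denominator / non-negativity floor for block and multiplicative updates


@dataclass
class SolverConfig:
    """Stopping and per-solver tuning parameters.

    ``tol`` applies to the relative change of the Frobenius residual between
    successive outer iterations; ``max_iter`` caps outer iterations;
    ``n_restarts`` is the number of repetitions used for the
    non-deterministic initializers.
    """

    tol: float = 1e-5
    max_iter: int = 10000
    n_restarts: int = 30
    # aHALS: inner-pass acceleration factor
    ahals_alpha: float = 0.5
    # GD: trust-region controls
    gd_radius0: float = 1.0
    gd_eta_lo: float = 0.25
    gd_eta_hi: float = 0.75
    gd_shrink: float = 0.25
    gd_grow: float = 2.0
    gd_cg_maxiter: int = 100
    # PG: Armijo sufficient-decrease sigma, backtracking ratio beta,
    # initial subproblem tolerance as a fraction of the initial gradient norm
    pg_sigma: float = 0.01
    pg_beta: float = 0.1
    pg_subtol0: float = 1e-3
    pg_sub_maxiter: int = 1000

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.max_iter < 1 or self.n_restarts < 1:
            raise ValueError("tol > 0, max_iter >= 1 and n_restarts >= 1 required")


def _relchange(prev: float, cur: float) -> float:
    return abs(prev - cur) / max(prev, _EPS)


def _stop(prev: float, cur: float, tol: float, xnorm: float) -> bool:
    """Common stopping rule: relative residual change below tol, or the
    residual itself at machine-precision scale (exact factorization)."""
    return cur <= 1e-13 * xnorm or _relchange(prev, cur) < tol


# ---------------------------------------------------------------------------
# aHALS


def _hals_update_H(XtW: np.ndarray, WtW: np.ndarray, H: np.ndarray,
                   n_pass: int) -> np.ndarray:
    """Cyclic exact rank-one updates of the rows of H, repeated ``n_pass``
    times with an early stop once later sweeps change little."""
    r = H.shape[0]
    first_sweep_delta = None
    for sweep in range(n_pass):
        delta = 0.0
        for k in range(r):
            denom = WtW[k, k]
            if denom < _EPS:
                # degenerate basis column: its row of H carries no signal
                continue
            hk_new = np.maximum(_EPS, H[k] + (XtW[k] - WtW[k] @ H) / denom)
            delta += float(np.sum((hk_new - H[k]) ** 2))
            H[k] = hk_new
        if sweep == 0:
            first_sweep_delta = delta
        elif first_sweep_delta is not None and delta <= 1e-4 * first_sweep_delta:
            break
    return H


def ahals_solve(X, init: InitFactors, cfg: SolverConfig | None = None) -> Factorization:
    """Accelerated HALS NMF.

    Alternates exact block-coordinate updates of the rows of ``H`` (W fixed)
    and the columns of ``W`` (H fixed).  Each alternation performs
    ``1 + floor(alpha * rho)`` inner sweeps, where ``rho`` is the flop ratio
    between the one-off Gram/cross-product setup and one sweep, so the cheap
    inner updates are repeated while the expensive products are amortized.
    A basis column whose entries all collapse is reset to small uniform
    random values (standard HALS safeguard, logged).
    """
    cfg = cfg or SolverConfig()
    fm = as_feature_matrix(X)
    Xd = fm.data
    m, n = Xd.shape
    W = init.W0.copy()
    H = init.H0.copy()
    r = W.shape[1]
    rng = np.random.default_rng(init.seed if init.seed is not None else 0)
    # setup cost ~ mnr; sweep cost ~ r^2 * (n or m)
    n_pass_H = 1 + int(cfg.ahals_alpha * (m * n * r + m * r * r) / max(n * r * r + n * r, 1))
    n_pass_W = 1 + int(cfg.ahals_alpha * (m * n * r + n * r * r) / max(m * r * r + m * r, 1))
    xnorm = float(np.linalg.norm(Xd, "fro"))
    trace = [residual(Xd, W, H)]
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        # safeguard degenerate columns/rows before the updates
        dead_w = np.where(W.max(axis=0) < _EPS)[0]
        if dead_w.size:
            logger.warning("aHALS: resetting collapsed W columns %s", dead_w.tolist())
            W[:, dead_w] = rng.uniform(_EPS, 1e-6, size=(m, dead_w.size))
        H = _hals_update_H(W.T @ Xd, W.T @ W, H, n_pass_H)
        dead_h = np.where(H.max(axis=1) < _EPS)[0]
        if dead_h.size:
            logger.warning("aHALS: resetting collapsed H rows %s", dead_h.tolist())
            H[dead_h] = rng.uniform(_EPS, 1e-6, size=(dead_h.size, n))
        Wt = _hals_update_H(H @ Xd.T, H @ H.T, W.T.copy(), n_pass_W)
        W = Wt.T
        trace.append(residual(Xd, W, H))
        if _stop(trace[-2], trace[-1], cfg.tol, xnorm):
            converged = True
            break
    return Factorization(W=W, H=H, residual_trace=trace, n_iter=it,
                         converged=converged, init_method=init.method, seed=init.seed)


# ---------------------------------------------------------------------------
# GD (Gauss-Newton dogleg on squared variables)


def gd_solve(X, init: InitFactors, cfg: SolverConfig | None = None) -> Factorization:
    """Gradient-descent NMF via squared variables and Gauss-Newton dogleg.

    With ``W = U*U`` and ``H = V*V`` the problem becomes unconstrained
    nonlinear least squares in ``(U, V)``.  Each outer iteration computes the
    Gauss-Newton step by conjugate gradients on the normal equations (using
    only Jacobian-vector products), combines it with the steepest-descent
    Cauchy point by the dogleg rule inside a trust region, and adapts the
    radius from the agreement between predicted and actual decrease.  The
    radius is shrunk until a step is accepted, so the residual trace is
    non-increasing.  Entries initialized exactly at zero stay at zero, which
    is why the NNDSVD initializer applies its zero fix.
    """
    cfg = cfg or SolverConfig()
    fm = as_feature_matrix(X)
    Xd = fm.data
    U = np.sqrt(init.W0)
    V = np.sqrt(init.H0)

    def WH(U, V):
        return U * U, V * V

    W, H = WH(U, V)
    xnorm = float(np.linalg.norm(Xd, "fro"))
    R = Xd - W @ H  # residual matrix
    f = 0.5 * float(np.sum(R * R))
    trace = [float(np.sqrt(2.0 * f))]
    radius = cfg.gd_radius0
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        # gradient of 0.5||X - (U*U)(V*V)||^2 w.r.t. (U, V)
        gU = -2.0 * U * (R @ H.T)
        gV = -2.0 * V * (W.T @ R)
        gnorm2 = float(np.sum(gU * gU) + np.sum(gV * gV))
        if gnorm2 < 1e-30:
            converged = True
            trace.append(trace[-1])
            break

        def jvp(dU, dV):
            return (2.0 * U * dU) @ H + W @ (2.0 * V * dV)

        def jtvp(M):
            return 2.0 * U * (M @ H.T), 2.0 * V * (W.T @ M)

        # CG on the Gauss-Newton normal equations  J^T J p = -g
        bU, bV = -gU, -gV
        pU = np.zeros_like(U)
        pV = np.zeros_like(V)
        rU, rV = bU.copy(), bV.copy()
        dU, dV = rU.copy(), rV.copy()
        rs = float(np.sum(rU * rU) + np.sum(rV * rV))
        bnorm = np.sqrt(rs)
        cg_tol = min(0.1, np.sqrt(bnorm)) * bnorm
        for _ in range(cfg.gd_cg_maxiter):
            if np.sqrt(rs) <= cg_tol:
                break
            Jd = jvp(dU, dV)
            AdU, AdV = jtvp(Jd)
            dAd = float(np.sum(dU * AdU) + np.sum(dV * AdV))
            if dAd <= 1e-30:
                break
            alpha = rs / dAd
            pU += alpha * dU
            pV += alpha * dV
            rU -= alpha * AdU
            rV -= alpha * AdV
            rs_new = float(np.sum(rU * rU) + np.sum(rV * rV))
            beta = rs_new / rs
            rs = rs_new
            dU = rU + beta * dU
            dV = rV + beta * dV

        # Cauchy point along -g for the dogleg interpolation
        Jg = jvp(gU, gV)
        gBg = float(np.sum(Jg * Jg))
        accepted = False
        while radius > 1e-14 and not accepted:
            pn_gn = np.sqrt(float(np.sum(pU * pU) + np.sum(pV * pV)))
            if pn_gn <= radius:
                sU, sV = pU, pV
            else:
                tau_c = gnorm2 / max(gBg, 1e-30)
                cU, cV = -tau_c * gU, -tau_c * gV
                cn = np.sqrt(float(np.sum(cU * cU) + np.sum(cV * cV)))
                if cn >= radius:
                    scale = radius / max(np.sqrt(gnorm2), 1e-30)
                    sU, sV = -scale * gU, -scale * gV
                else:
                    # solve ||c + t (p - c)|| = radius for t in (0, 1)
                    eU, eV = pU - cU, pV - cV
                    a = float(np.sum(eU * eU) + np.sum(eV * eV))
                    b = 2.0 * float(np.sum(cU * eU) + np.sum(cV * eV))
                    c0 = cn * cn - radius * radius
                    t = (-b + np.sqrt(max(b * b - 4 * a * c0, 0.0))) / (2 * a)
                    sU, sV = cU + t * eU, cV + t * eV
            Js = jvp(sU, sV)
            pred = -(float(np.sum(gU * sU) + np.sum(gV * sV))
                     + 0.5 * float(np.sum(Js * Js)))
            U_new, V_new = U + sU, V + sV
            W_new, H_new = WH(U_new, V_new)
            R_new = Xd - W_new @ H_new
            f_new = 0.5 * float(np.sum(R_new * R_new))
            if not np.isfinite(f_new):
                raise FloatingPointError("GD NMF produced a non-finite residual")
            rho = (f - f_new) / max(pred, 1e-30)
            step_norm = np.sqrt(float(np.sum(sU * sU) + np.sum(sV * sV)))
            if rho < cfg.gd_eta_lo:
                radius *= cfg.gd_shrink
            elif rho > cfg.gd_eta_hi and step_norm > 0.99 * radius:
                radius *= cfg.gd_grow
            if rho > 0 and f_new <= f:
                U, V, R, f = U_new, V_new, R_new, f_new
                W, H = W_new, H_new
                accepted = True
        trace.append(float(np.sqrt(2.0 * f)))
        if radius <= 1e-14:
            # trust region collapsed: no further progress possible
            converged = True
            break
        if _stop(trace[-2], trace[-1], cfg.tol, xnorm):
            converged = True
            break
    return Factorization(W=W, H=H, residual_trace=trace, n_iter=it,
                         converged=converged, init_method=init.method, seed=init.seed)


# ---------------------------------------------------------------------------
# PG (projected gradient, Armijo along the projection arc)


def _pg_subproblem(V: np.ndarray, W: np.ndarray, Hinit: np.ndarray,
                   tol: float, max_iter: int, sigma: float, beta: float):
    """Solve ``min_{H>=0} 0.5 ||V - W H||_F^2`` by projected gradient.

    Steps along the negative gradient, projects negatives to zero and picks
    the step size by the Armijo rule along the projection arc; stops when the
    projected-gradient norm falls below ``tol``.  Returns ``(H, n_iter)``.
    """
    H = Hinit
    WtV = W.T @ V
    WtW = W.T @ W
    alpha = 1.0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        grad = WtW @ H - WtV
        pg = np.linalg.norm(grad[(grad < 0) | (H > 0)])
        if pg < tol:
            break
        # Armijo along the projection arc, with step-size memory: first probe
        # decides whether to grow or shrink alpha from its previous value
        decrease_alpha = False
        Hp = H
        for inner in range(1, 21):
            Hn = np.maximum(H - alpha * grad, 0.0)
            d = Hn - H
            gd = float(np.sum(grad * d))
            dQd = float(np.sum((WtW @ d) * d))
            suff_decr = (1.0 - sigma) * gd + 0.5 * dQd <= 0.0
            if inner == 1:
                decrease_alpha = not suff_decr
            if decrease_alpha:
                if suff_decr:
                    H = Hn
                    break
                alpha *= beta
            else:
                if not suff_decr or np.array_equal(Hp, Hn):
                    H = Hp
                    break
                alpha /= beta
                Hp = Hn
        else:
            H = Hp
    return H, n_iter


def pg_solve(X, init: InitFactors, cfg: SolverConfig | None = None) -> Factorization:
    """Projected-gradient NMF (alternating NNLS subproblems).

    ``H`` (W fixed) and ``W`` (H fixed) are updated alternately, each by the
    projected-gradient subproblem solver.  Subproblem tolerances start at
    ``pg_subtol0`` times the initial projected-gradient norm and are
    tightened by a factor 10 whenever a subproblem converges immediately.
    """
    cfg = cfg or SolverConfig()
    fm = as_feature_matrix(X)
    Xd = fm.data
    W = init.W0.copy()
    H = init.H0.copy()
    gW = (W @ H - Xd) @ H.T
    gH = W.T @ (W @ H - Xd)
    initgrad = float(np.sqrt(np.sum(gW * gW) + np.sum(gH * gH)))
    tolW = tolH = max(cfg.pg_subtol0 * initgrad, 1e-15)
    xnorm = float(np.linalg.norm(Xd, "fro"))
    trace = [residual(Xd, W, H)]
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        Wt, iterW = _pg_subproblem(Xd.T, H.T, W.T.copy(), tolW,
                                   cfg.pg_sub_maxiter, cfg.pg_sigma, cfg.pg_beta)
        W = Wt.T
        if iterW <= 1:
            tolW = max(0.1 * tolW, 1e-15)
        H, iterH = _pg_subproblem(Xd, W, H, tolH,
                                  cfg.pg_sub_maxiter, cfg.pg_sigma, cfg.pg_beta)
        if iterH <= 1:
            tolH = max(0.1 * tolH, 1e-15)
        res = residual(Xd, W, H)
        if not np.isfinite(res):
            raise FloatingPointError("PG NMF produced a non-finite residual")
        trace.append(res)
        if _stop(trace[-2], trace[-1], cfg.tol, xnorm):
            converged = True
            break
    return Factorization(W=W, H=H, residual_trace=trace, n_iter=it,
                         converged=converged, init_method=init.method, seed=init.seed)


# ---------------------------------------------------------------------------
# Convex NMF


def convexnmf_solve(X, A0, H0, cfg: SolverConfig | None = None,
                    *, init_method: str = "unknown",
                    seed: int | None = None) -> Factorization:
    """Convex NMF ``X ~ X A H`` by multiplicative updates.

    The sources are constrained to the column space of the data
    (``W = X A``), so each source is a weighted sum of voxels.  With
    ``K = X^T X`` split into positive and negative parts
    ``K+ = (|K| + K)/2`` and ``K- = (|K| - K)/2``, ``H`` and ``A`` are
    updated by the monotone multiplicative square-root rules with a small
    denominator floor.  The residual traced is ``||X - X A H||_F``.
    """
    cfg = cfg or SolverConfig()
    fm = as_feature_matrix(X)
    Xd = fm.data
    A = np.asarray(A0, dtype=float).copy()
    H = np.asarray(H0, dtype=float).copy()
    if A.ndim != 2 or H.ndim != 2 or A.shape != (Xd.shape[1], H.shape[0]):
        raise ValueError(
            f"A0 {A.shape} / H0 {H.shape} inconsistent with X {Xd.shape}"
        )
    K = Xd.T @ Xd
    Kp = 0.5 * (np.abs(K) + K)
    Kn = 0.5 * (np.abs(K) - K)
    xnorm = float(np.linalg.norm(Xd, "fro"))
    trace = [residual(Xd, Xd @ A, H)]
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        AtKp = A.T @ Kp
        AtKn = A.T @ Kn
        AtKpA = AtKp @ A
        AtKnA = AtKn @ A
        num = AtKp + AtKnA @ H
        den = AtKn + AtKpA @ H
        H *= np.sqrt(num / np.maximum(den, _EPS))
        HHt = H @ H.T
        num = Kp @ H.T + (Kn @ A) @ HHt
        den = Kn @ H.T + (Kp @ A) @ HHt
        A *= np.sqrt(num / np.maximum(den, _EPS))
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(H))):
            raise FloatingPointError("Convex NMF produced non-finite factors")
        trace.append(residual(Xd, Xd @ A, H))
        if _stop(trace[-2], trace[-1], cfg.tol, xnorm):
            converged = True
            break
    W = Xd @ A
    return Factorization(W=W, H=H, residual_trace=trace, n_iter=it,
                         converged=converged, init_method=init_method,
                         seed=seed, A=A)


# ---------------------------------------------------------------------------
# dispatch and restarts

SOLVERS = ("ahals", "gd", "pg", "convex")


def _make_init(X, r: int, init_method: str, seed: int | None,
               need_A0: bool) -> InitFactors:
    from .spa import init_from_spa
    from .initializers import nndsvd_init

    fm = as_feature_matrix(X)
    if init_method == "spa":
        init = init_from_spa(fm, r)
    elif init_method == "nndsvd":
        init = nndsvd_init(fm, r)
    elif init_method == "random":
        init = random_init(fm.m, fm.n, r, seed if seed is not None else 0)
    elif init_method == "fcm":
        init = fcm_init(fm, r, seed if seed is not None else 0)
    else:
        raise ValueError(f"unknown init method {init_method!r}")
    if need_A0:
        init.A0 = convex_weights_init(np.maximum(init.H0, 0.0), mode="zero_fallback")
    return init


def solve(X, r: int, solver: str, init: InitFactors | str,
          cfg: SolverConfig | None = None, seed: int | None = None) -> Factorization:
    """Run one NMF solve with a prepared or named initialization.

    ``init`` may be an :class:`InitFactors` or one of
    ``{"spa", "nndsvd", "random", "fcm"}`` (built on the fly with ``seed``).
    """
    cfg = cfg or SolverConfig()
    if isinstance(init, str):
        init = _make_init(X, r, init, seed, need_A0=(solver == "convex"))
    if solver == "ahals":
        return ahals_solve(X, init, cfg)
    if solver == "gd":
        return gd_solve(X, init, cfg)
    if solver == "pg":
        return pg_solve(X, init, cfg)
    if solver == "convex":
        A0 = init.A0
        if A0 is None:
            A0 = convex_weights_init(np.maximum(init.H0, 0.0), mode="zero_fallback")
        return convexnmf_solve(X, A0, init.H0, cfg,
                               init_method=init.method, seed=init.seed)
    raise ValueError(f"unknown solver {solver!r}")


def run_with_restarts(X, r: int, solver: str, init_method: str,
                      cfg: SolverConfig | None = None,
                      base_seed: int = 0) -> Factorization:
    """Best-of-``n_restarts`` orchestration for non-deterministic initializers.

    Runs the solver with seeds ``base_seed .. base_seed + n_restarts - 1``
    and returns the run with the lowest final Frobenius residual (ties by
    smallest seed).  All final residuals are recorded on the returned
    factorization as ``restart_residuals``.  Individual failed runs are
    logged and skipped; only if every run fails is an error raised.
    """
    cfg = cfg or SolverConfig()
    if init_method not in ("random", "fcm"):
        raise ValueError(
            f"run_with_restarts is for non-deterministic initializers, got {init_method!r}"
        )
    best: Factorization | None = None
    finals: list[float] = []
    for k in range(cfg.n_restarts):
        s = base_seed + k
        try:
            fac = solve(X, r, solver, init_method, cfg, seed=s)
        except Exception as exc:  # noqa: BLE001 - any single-run failure is skippable
            logger.warning("restart seed %d failed: %s", s, exc)
            continue
        finals.append(fac.final_residual)
        if best is None or fac.final_residual < best.final_residual:
            best = fac
    if best is None:
        raise RuntimeError("all restart runs failed")
    best.restart_residuals = finals  # type: ignore[attr-defined]
    return best
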