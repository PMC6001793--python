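"""PARAFAC trilinear decomposition and PowerSlicing.

The PARAFAC model ``X[i, j, k] = sum_f A[i, f] B[j, f] C[k, f]`` is fitted
by alternating least squares on the three mode unfoldings, optionally with
per-mode non-negativity.  When the physical data are only two-way but
decay exponentially along one axis, PowerSlicing builds an artificial
third mode from shifted windows of that axis; for pure exponentials the
resulting cube is exactly trilinear and PARAFAC recovers the decay rates,
matching DECRA's algebraic solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "TrilinearFactors",
    "parafac",
    "power_slice",
    "decay_rate_from_loading",
    "diagnostics",
]


@dataclass
class TrilinearFactors:
    """PARAFAC factor matrices, unit-norm in modes B and C (scale carried
    in A), components ordered by explained variation."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    fit_percent: float
    iterations: int
    converged: bool
    extra: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.A.shape[1]

    def reconstruct(self) -> np.ndarray:
        I, J, K = self.A.shape[0], self.B.shape[0], self.C.shape[0]
        return np.einsum("if,jf,kf->ijk", self.A, self.B, self.C)


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    F = a.shape[1]
    return (a[:, None, :] * b[None, :, :]).reshape(-1, F)


def _unfold(X: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)


def _solve_mode(Z: np.ndarray, Y: np.ndarray, nonneg: bool) -> np.ndarray:
    """min ||Z F' - Y'|| for factor F: rows of the mode unfolding."""
    if not nonneg:
        F, *_ = np.linalg.lstsq(Z, Y.T, rcond=None)
        return F.T
    out = np.empty((Y.shape[0], Z.shape[1]))
    for r in range(Y.shape[0]):
        out[r], _ = nnls(Z, Y[r])
    return out


def _init_factors(X: np.ndarray, F: int, how: str, rng: np.random.Generator):
    shapes = X.shape
    if how == "svd":
        facs = []
        for mode in range(3):
            U, _, _ = np.linalg.svd(_unfold(X, mode), full_matrices=False)
            k = U.shape[1]
            fac = U[:, :F] if k >= F else np.hstack(
                [U, rng.standard_normal((shapes[mode], F - k))]
            )
            facs.append(np.abs(fac) + 1e-12)
        return facs
    return [np.abs(rng.standard_normal((s, F))) + 1e-12 for s in shapes]


def parafac(
    X: np.ndarray,
    F: int,
    nonneg: tuple[bool, bool, bool] | bool = False,
    init: str = "svd",
    tol: float = 1e-12,
    max_iter: int = 2500,
    seed: int | None = 0,
    n_starts: int = 5,
) -> TrilinearFactors:
    """Alternating-least-squares PARAFAC of a 3-way array.

    ``nonneg`` may be a single flag or one per mode.  ``init`` is ``svd``
    (leading singular vectors of the unfoldings), ``random``, or
    ``best_of_n`` (``n_starts`` random starts plus one SVD start, short
    trial runs, the best continued).  Iteration stops when the relative
    fit change drops below ``tol``; a fit *decrease* beyond 1e-10 aborts
    with diagnostics (the ALS residual contract is monotone).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("PARAFAC input must be a 3-way array")
    if isinstance(nonneg, bool):
        nonneg = (nonneg, nonneg, nonneg)
    for mode in range(3):
        if F > min(X.shape[mode], X.size // X.shape[mode]):
            raise ValueError(f"F={F} exceeds the rank bound of mode {mode}")
    rng = np.random.default_rng(seed)
    norm_x2 = float(np.sum(X * X)) or 1.0

    def run(facs, iters):
        A, B, C = facs
        prev = np.inf
        for it in range(iters):
            A = _solve_mode(_khatri_rao(B, C), _unfold(X, 0), nonneg[0])
            B = _solve_mode(_khatri_rao(A, C), _unfold(X, 1), nonneg[1])
            C = _solve_mode(_khatri_rao(A, B), _unfold(X, 2), nonneg[2])
            resid2 = float(
                np.sum((X - np.einsum("if,jf,kf->ijk", A, B, C)) ** 2)
            )
            if resid2 > prev + 1e-10 * norm_x2:
                raise RuntimeError(
                    f"ALS diverged at iteration {it}: residual {resid2:.3e} "
                    f"> previous {prev:.3e}"
                )
            change = (prev - resid2) / norm_x2 if np.isfinite(prev) else np.inf
            prev = resid2
            if change < tol:
                return (A, B, C), resid2, it + 1, True
        return (A, B, C), prev, iters, False

    if init == "best_of_n":
        candidates = [_init_factors(X, F, "svd", rng)] + [
            _init_factors(X, F, "random", rng) for _ in range(n_starts)
        ]
        trials = []
        for facs in candidates:
            try:
                trials.append(run([f.copy() for f in facs], 30))
            except RuntimeError:
                continue
        if not trials:
            raise RuntimeError("all PARAFAC starts diverged")
        facs = list(min(trials, key=lambda t: t[1])[0])
        (A, B, C), resid2, iters, converged = run(facs, max_iter)
    else:
        facs = _init_factors(X, F, init, rng)
        (A, B, C), resid2, iters, converged = run(facs, max_iter)

    # normalise: B, C unit-norm, scale in A; order by explained variation
    nb = np.linalg.norm(B, axis=0)
    nc = np.linalg.norm(C, axis=0)
    nb[nb == 0] = 1.0
    nc[nc == 0] = 1.0
    B, C = B / nb, C / nc
    A = A * (nb * nc)
    strength = np.linalg.norm(A, axis=0)
    order = np.argsort(-strength)
    A, B, C = A[:, order], B[:, order], C[:, order]
    fit = 100.0 * (1.0 - resid2 / norm_x2)
    return TrilinearFactors(
        A=A, B=B, C=C, fit_percent=float(fit), iterations=iters,
        converged=converged, extra={"residual2": resid2},
    )


def power_slice(X2: np.ndarray, slabs: int = 3, slab_length: int | None = None,
                exponent_values: np.ndarray | None = None) -> np.ndarray:
    """Trilinearise a points × increments matrix of exponential decays.

    Slab ``s`` (0-based) holds columns ``[s : s + slab_length]``; the
    output is ``[points, slab_length, slabs]``.  For pure exponentials the
    cube is exactly trilinear with third-mode loading ``rho_k**s``.  When
    ``exponent_values`` (e.g. g^2-proportional X_i) are supplied they must
    be equally spaced — the same precondition as DECRA.
    """
    X2 = np.asarray(X2, dtype=float)
    S = int(slabs)
    n_inc = X2.shape[1]
    if slab_length is None:
        slab_length = n_inc - S + 1
    L = int(slab_length)
    if S < 2:
        raise ValueError("at least 2 slabs required")
    if L + S - 1 > n_inc:
        raise ValueError("slab_length + slabs - 1 must be <= n_increments")
    if exponent_values is not None:
        dv = np.diff(np.asarray(exponent_values, dtype=float))
        if not np.allclose(dv, dv[0], rtol=1e-6, atol=0.0):
            raise ValueError(
                "PowerSlicing requires increments equally spaced in the "
                "exponent variable"
            )
    cube = np.empty((X2.shape[0], L, S))
    for s in range(S):
        cube[:, :, s] = X2[:, s : s + L]
    return cube


def decay_rate_from_loading(loading: np.ndarray, step: float) -> float:
    """Decay constant from a PowerSlicing third-mode loading: log-linear
    fit of ``rho**s``, ``D = -ln(rho) / step``."""
    c = np.asarray(loading, dtype=float)
    if np.any(c <= 0):
        c = np.abs(c)
    s = np.arange(c.size)
    slope = np.polyfit(s, np.log(c), 1)[0]
    return float(-slope / step)


def diagnostics(factors: TrilinearFactors, X: np.ndarray) -> dict:
    """Per-mode leverages ``diag(F (F'F)^-1 F')`` and residual sums per
    mode slice (values only; plotting left to the caller)."""
    X = np.asarray(X, dtype=float)
    resid = X - factors.reconstruct()
    out: dict = {"leverages": [], "residual_ss": []}
    for mode, F in enumerate((factors.A, factors.B, factors.C)):
        G = F.T @ F
        lev = np.einsum("if,fg,ig->i", F, np.linalg.pinv(G), F)
        out["leverages"].append(lev)
        axes = tuple(a for a in range(3) if a != mode)
        out["residual_ss"].append(np.sum(resid**2, axis=axes))
    return out
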