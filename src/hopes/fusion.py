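"""Global similarity fusion.

Given per-layer local affinities ``S_1..S_C`` with support masks
``Omega_1..Omega_C``, the fused patient-similarity matrix ``W`` minimises
the high-order path energy

    E(W) = sum_i ( ||W - S_i||_F^2                    (path-0: fit each layer)
                 + alpha ||W - S_i W||_F^2            (path-1: one-hop filtration)
                 + beta sum_j ||W - S_i W S_j^T||_F^2 (path-2: cross-layer) )

plus a tiny ridge ``lambda ||W||_F^2`` that keeps the quadratic strictly
convex in every degenerate limit.  The path-0 term splits over each
layer's KNN support Omega_i as

    ||W - S_i||^2 = ||(W - S_i) . Omega_i||^2  +  ||W . (1 - Omega_i)||^2,

i.e. W is fitted to the observed neighbour weights on the support and
anchored to zero where the layer records no neighbour relation; an edge
backed by a single layer is thereby averaged against the other layers'
zeros, and the path-2 filtration weakens it further unless each pair of
layers supports it.  Path-1 requires W to be stable under one-hop
smoothing by each layer.  (Fitting S_i on its support only, with
off-support entries held solely by the ridge, makes the minimiser the
harmonic extension of the smoothing terms -- a provably near-constant
matrix with no cluster contrast -- so the zero anchor is part of the
model, not a regularisation nicety.)

The minimiser is found by consensus ADMM with one block per term family:

* path-0 (plus ridge): elementwise closed form,
* path-1, one block per layer: a prefactorised linear solve in
  ``2 alpha (I - S_i)^T (I - S_i) + rho I``,
* path-2, a single block pooling all (i, j) pairs: conjugate gradient on
  the pooled normal operator, which collapses to six matrix products per
  application regardless of C.

:func:`direct_solve_oracle` solves the same normal equations densely in
``vec(W)`` (Kronecker form) and is the independent correctness check for
the ADMM at small n.

The classical similarity-network-fusion (SNF) iteration is provided as a
baseline in :func:`snf_fuse`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "FusionConfig",
    "FusedSimilarity",
    "FusionDiagnostics",
    "hopes_energy",
    "hopes_energy_gradient",
    "hopes_fuse",
    "direct_solve_oracle",
    "snf_update_step",
    "snf_fuse",
    "postprocess_similarity",
]


@dataclass
class FusionConfig:
    """Solver settings for the fused-similarity optimisation.

    alpha, beta weight the path-1 / path-2 consistency terms and are meant
    to be set empirically (grid {0.1, 0.5, 1, 2} is a reasonable sweep);
    ridge is the strict-convexity regulariser; rho, tol, max_iter control
    the ADMM.
    """

    alpha: float = 1.0
    beta: float = 1.0
    ridge: float = 1e-8
    rho: float = 1.0
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.ridge < 0:
            raise ValueError("alpha, beta and ridge must be >= 0")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class FusedSimilarity:
    """A fused n x n similarity matrix with its optimisation trace.

    ``matrix`` is the post-processed similarity used downstream (symmetric,
    nonnegative, diagonal = per-row max); ``matrix_raw`` is the
    unconstrained minimiser before post-processing, kept for solver
    verification.
    """

    matrix: np.ndarray
    sample_ids: list[str] | None
    energy_trace: list[float]
    converged: bool
    matrix_raw: np.ndarray | None = None
    method: str = "hopes"


@dataclass
class FusionDiagnostics:
    primal_residuals: list[float] = field(default_factory=list)
    dual_residuals: list[float] = field(default_factory=list)
    iterations_used: int = 0
    final_energy: float = float("nan")
    rho_trace: list[float] = field(default_factory=list)


def _check_inputs(S_list, masks):
    S_list = [np.asarray(S, dtype=float) for S in S_list]
    masks = [np.asarray(M, dtype=float) for M in masks]
    if len(S_list) != len(masks) or not S_list:
        raise ValueError("need equally many (>=1) affinities and masks")
    n = S_list[0].shape[0]
    for A in [*S_list, *masks]:
        if A.shape != (n, n):
            raise ValueError(f"all matrices must be {n}x{n}; got {A.shape}")
    return S_list, masks, n


def hopes_energy(
    W: np.ndarray,
    S_list: list[np.ndarray],
    masks: list[np.ndarray],
    alpha: float,
    beta: float,
) -> float:
    """Evaluate the path-0/1/2 energy at W (ridge term *not* included).

    The path-0 contribution per layer is the full fit ``||W - S_i||^2``,
    i.e. the on-support deviation from S_i plus the off-support zero
    anchor (the two pieces the mask Omega_i separates).
    """
    S_list, masks, n = _check_inputs(S_list, masks)
    W = np.asarray(W, dtype=float)
    if W.shape != (n, n):
        raise ValueError(f"W must be {n}x{n}")
    e = 0.0
    for S, M in zip(S_list, masks):
        e += float(np.sum((W - S) ** 2))
        if alpha:
            e += alpha * float(np.sum((W - S @ W) ** 2))
        if beta:
            for Sj in S_list:
                e += beta * float(np.sum((W - S @ W @ Sj.T) ** 2))
    return e


def _path2_operator(X, G, H, C):
    """Pooled path-2 normal operator sum_ij A_ij^T A_ij applied to X,
    with A_ij(X) = X - S_i X S_j^T, G = sum_i S_i, H = sum_i S_i^T S_i."""
    return C * C * X - G.T @ X @ G - G @ X @ G.T + H @ X @ H


def hopes_energy_gradient(
    W: np.ndarray,
    S_list: list[np.ndarray],
    masks: list[np.ndarray],
    alpha: float,
    beta: float,
    ridge: float = 0.0,
) -> np.ndarray:
    """Gradient of the energy (including the ridge term if given)."""
    S_list, masks, n = _check_inputs(S_list, masks)
    W = np.asarray(W, dtype=float)
    C = len(S_list)
    grad = 2.0 * ridge * W
    G = sum(S_list)
    H = sum(S.T @ S for S in S_list)
    for S, M in zip(S_list, masks):
        grad += 2.0 * (W - S)
        if alpha:
            R = W - S @ W
            grad += 2.0 * alpha * (R - S.T @ R)
    if beta:
        grad += 2.0 * beta * _path2_operator(W, G, H, C)
    return grad


def _cg_matrix(apply_A, B, X0, rtol, max_iter=500):
    """Conjugate gradient for A(X) = B with SPD operator A on matrices."""
    X = X0.copy()
    R = B - apply_A(X)
    P = R.copy()
    rs = float(np.sum(R * R))
    b_norm = float(np.linalg.norm(B))
    stop = max(rtol * b_norm, 1e-300)
    for _ in range(max_iter):
        if np.sqrt(rs) <= stop:
            break
        AP = apply_A(P)
        alpha = rs / float(np.sum(P * AP))
        X += alpha * P
        R -= alpha * AP
        rs_new = float(np.sum(R * R))
        P = R + (rs_new / rs) * P
        rs = rs_new
    return X


def postprocess_similarity(W: np.ndarray) -> np.ndarray:
    """Symmetrise, clamp negatives to zero, and set the diagonal to each
    row's maximum off-diagonal value (self-similarity dominates)."""
    W = np.asarray(W, dtype=float)
    W = (W + W.T) / 2.0
    W = np.maximum(W, 0.0)
    off = W - np.diag(np.diag(W))
    np.fill_diagonal(W, off.max(axis=1))
    return W


def hopes_fuse(
    S_list: list[np.ndarray],
    masks: list[np.ndarray],
    cfg: FusionConfig | None = None,
    sample_ids: list[str] | None = None,
    W0: np.ndarray | None = None,
) -> tuple[FusedSimilarity, FusionDiagnostics]:
    """Minimise the path energy by consensus ADMM.

    Blocks (path-0 + ridge; one per layer for path-1; one pooled path-2
    block) are held to a common consensus variable Z; each block solve is
    exact (closed form, prefactorised Cholesky, or warm-started CG).  The
    penalty rho is rebalanced from the primal/dual residual ratio during
    the first iterations.  Returns the post-processed similarity plus raw
    minimiser and residual diagnostics; if the residual tolerance is not
    met within ``max_iter`` the best iterate is returned with
    ``converged=False`` and a warning.
    """
    cfg = cfg or FusionConfig()
    S_list, masks, n = _check_inputs(S_list, masks)
    C = len(S_list)
    alpha, beta, lam, rho = cfg.alpha, cfg.beta, cfg.ridge, cfg.rho

    G = sum(S_list)
    H = sum(S.T @ S for S in S_list)
    S_sum = sum(S_list)

    # ---- block definitions -------------------------------------------------
    use_p1 = alpha > 0
    use_p2 = beta > 0
    n_blocks = 1 + (C if use_p1 else 0) + (1 if use_p2 else 0)

    def factor_p1(rho_val):
        facs = []
        for S in S_list:
            A = np.eye(n) - S
            facs.append(scipy.linalg.cho_factor(2.0 * alpha * (A.T @ A) + rho_val * np.eye(n)))
        return facs

    p1_factors = factor_p1(rho) if use_p1 else []

    Z = W0.copy() if W0 is not None else S_sum / C
    Xs = [Z.copy() for _ in range(n_blocks)]
    Us = [np.zeros((n, n)) for _ in range(n_blocks)]

    diag = FusionDiagnostics()
    energy_trace = [hopes_energy(Z, S_list, masks, alpha, beta) + lam * float(np.sum(Z * Z))]
    converged = False
    last_rel = 1.0

    for it in range(cfg.max_iter):
        # block updates
        b = 0
        V = Z - Us[b]
        Xs[b] = (2.0 * S_sum + rho * V) / (2.0 * C + 2.0 * lam + rho)
        b += 1
        if use_p1:
            for fac in p1_factors:
                V = Z - Us[b]
                Xs[b] = scipy.linalg.cho_solve(fac, rho * V)
                b += 1
        if use_p2:
            V = Z - Us[b]
            cg_rtol = max(1e-12, min(1e-4, 0.05 * last_rel))
            Xs[b] = _cg_matrix(
                lambda X: 2.0 * beta * _path2_operator(X, G, H, C) + rho * X,
                rho * V,
                Xs[b],
                rtol=cg_rtol,
            )

        # consensus + dual updates
        Z_old = Z
        Z = (sum(Xs) + sum(Us)) / n_blocks
        r2 = 0.0
        for b in range(n_blocks):
            diff = Xs[b] - Z
            Us[b] = Us[b] + diff
            r2 += float(np.sum(diff * diff))
        r = np.sqrt(r2)
        s = rho * np.sqrt(n_blocks) * float(np.linalg.norm(Z - Z_old))

        scale = max(
            np.sqrt(sum(float(np.sum(X * X)) for X in Xs)),
            np.sqrt(n_blocks) * float(np.linalg.norm(Z)),
            1e-12,
        )
        last_rel = r / scale
        diag.primal_residuals.append(r)
        diag.dual_residuals.append(s)
        diag.rho_trace.append(rho)
        energy_trace.append(
            hopes_energy(Z, S_list, masks, alpha, beta) + lam * float(np.sum(Z * Z))
        )

        if r <= cfg.tol * scale and s <= cfg.tol * max(
            rho * np.sqrt(sum(float(np.sum(U * U)) for U in Us)), 1.0
        ):
            converged = True
            diag.iterations_used = it + 1
            break

        # residual balancing (Boyd-style), early iterations only
        if it < 200 and (it + 1) % 10 == 0:
            if r > 10.0 * s and s > 0:
                rho_new = rho * 2.0
            elif s > 10.0 * r and r > 0:
                rho_new = rho / 2.0
            else:
                rho_new = rho
            if rho_new != rho:
                Us = [U * (rho / rho_new) for U in Us]
                rho = rho_new
                if use_p1:
                    p1_factors = factor_p1(rho)
    else:
        diag.iterations_used = cfg.max_iter
        warnings.warn(
            f"consensus ADMM did not reach tol={cfg.tol:g} in {cfg.max_iter} "
            "iterations; returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )

    diag.final_energy = energy_trace[-1]
    fused = FusedSimilarity(
        matrix=postprocess_similarity(Z),
        sample_ids=list(sample_ids) if sample_ids is not None else None,
        energy_trace=energy_trace,
        converged=converged,
        matrix_raw=Z,
        method="hopes",
    )
    return fused, diag


def direct_solve_oracle(
    S_list: list[np.ndarray],
    masks: list[np.ndarray],
    cfg: FusionConfig | None = None,
) -> np.ndarray:
    """Dense normal-equation solve of the same objective in vec(W).

    Builds the full n^2 x n^2 system with Kronecker products and solves it
    directly; intended as an independent verification path for the ADMM at
    small n (<= 64).
    """
    cfg = cfg or FusionConfig()
    S_list, masks, n = _check_inputs(S_list, masks)
    if n > 64:
        raise ValueError(f"direct solve is dense in n^2; n={n} > 64 refused")
    eye = np.eye(n)
    eye2 = np.eye(n * n)
    M = cfg.ridge * eye2
    rhs = np.zeros(n * n)
    for S, Om in zip(S_list, masks):
        M += eye2
        rhs += S.ravel(order="F")
        if cfg.alpha:
            A = eye - S
            M += cfg.alpha * np.kron(eye, A.T @ A)
        if cfg.beta:
            for Sj in S_list:
                B = eye2 - np.kron(Sj, S)
                M += cfg.beta * (B.T @ B)
    w = scipy.linalg.solve(M, rhs, assume_a="pos")
    return w.reshape((n, n), order="F")


# ---------------------------------------------------------------------------
# SNF baseline
# ---------------------------------------------------------------------------


def snf_update_step(S: np.ndarray, P_rest_mean: np.ndarray) -> np.ndarray:
    """One raw SNF message-passing update: S x (mean of other status
    matrices) x S^T."""
    return S @ P_rest_mean @ S.T


def _snf_normalize(P: np.ndarray) -> np.ndarray:
    """Row-stochastic rescaling with half the mass on the diagonal."""
    P = np.asarray(P, dtype=float)
    off = P - np.diag(np.diag(P))
    rowsum = off.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    out = off / (2.0 * rowsum)
    np.fill_diagonal(out, 0.5)
    return out


def snf_fuse(
    P_list: list[np.ndarray],
    S_list: list[np.ndarray],
    iterations: int = 20,
    sample_ids: list[str] | None = None,
) -> FusedSimilarity:
    """Similarity network fusion baseline.

    Each layer's status matrix is iteratively replaced by its local
    affinity applied to the average of the *other* layers' status matrices
    (parallel update), re-normalised after every step; the fused result is
    the symmetrised average of the C status matrices.
    """
    if len(P_list) < 2:
        raise ValueError("SNF needs at least two layers")
    if len(P_list) != len(S_list):
        raise ValueError("need one local affinity per status matrix")
    C = len(P_list)
    Ps = [_snf_normalize(np.asarray(P, dtype=float)) for P in P_list]
    Ss = [np.asarray(S, dtype=float) for S in S_list]
    for _ in range(iterations):
        new = []
        for v in range(C):
            rest = sum(Ps[k] for k in range(C) if k != v) / (C - 1)
            new.append(snf_update_step(Ss[v], rest))
        Ps = [_snf_normalize(P) for P in new]
    W = sum(Ps) / C
    W = (W + W.T) / 2.0
    return FusedSimilarity(
        matrix=W,
        sample_ids=list(sample_ids) if sample_ids is not None else None,
        energy_trace=[],
        converged=True,
        matrix_raw=None,
        method="snf",
    )
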