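"""Alternating-Projections (AP) least-squares multi-dipole fitting.

The AP fitter places K dipoles on a candidate grid by greedy initialization
(one exact single-source scan at a time against the already-placed set)
followed by cyclic coordinate descent: each source's grid location is
re-optimized with the other K-1 held fixed until a full sweep changes
nothing.  Every accepted step is an exact one-source least-squares scan, so
the residual sum of squares never increases.

Two source models are supported.  In ``fixed`` mode each dipole contributes
a single topography l(p) = L(p)o whose orientation is optimized analytically
per candidate point (dominant generalized eigendirection of the projected
3-column block against the projected data).  In ``free`` mode scanning and
projection use the full 3-column block (subspace fit); after convergence a
fixed orientation per dipole is extracted as the dominant left singular
vector of its 3×N moment time course and amplitudes are refit.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Optional

import h5py
import numpy as np
from sklearn.base import BaseEstimator

from .geometry import LeadFieldSet

#: Candidates whose projected block norm falls below this fraction of the
#: unprojected norm are skipped as collinear with the placed set.
COLLINEARITY_RTOL = 1e-12

_NULLSPACE_RTOL = 1e-10  # eigenvalue cutoff inside a 3-column block (norm^2 scale)


@dataclass
class DipoleFit:
    """Result of a K-dipole least-squares fit."""

    K: int
    grid_indices: np.ndarray
    orientations: Optional[np.ndarray]  # (K, 3) unit vectors
    amplitudes: np.ndarray  # (K, N)
    predicted: np.ndarray  # (M, N)
    ssr: float
    mode: str
    iterations: int = 0
    converged: bool = True
    ssr_subspace: Optional[float] = None  # free mode: SSR of the 3K-column fit

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("indices", data=self.grid_indices)
            if self.orientations is not None:
                f.create_dataset("orientations", data=self.orientations)
            f.create_dataset("amplitudes", data=self.amplitudes)
            f.create_dataset("ssr", data=self.ssr)
            f.attrs["mode"] = self.mode
            f.attrs["converged"] = self.converged
            f.attrs["iterations"] = self.iterations


@dataclass
class ScanResult:
    """One-source scan over the whole grid (others held fixed)."""

    index: int
    orientation: Optional[np.ndarray]
    ssr: float
    residuals: np.ndarray  # per-candidate SSR (skipped candidates = +inf)
    orientations: Optional[np.ndarray] = None  # per-candidate best orientation (fixed mode)


# ---------------------------------------------------------------------------
# vectorized scan machinery
# ---------------------------------------------------------------------------


def _compact_factor(Y: np.ndarray) -> np.ndarray:
    """Factor F with F F^T = Y Y^T and at most M columns.

    The scan criterion depends on the data only through its Gram matrix, so
    long recordings can be compressed to an M×r factor.
    """
    M, N = Y.shape
    if N <= M:
        return Y
    w, U = np.linalg.eigh(Y @ Y.T)
    w = np.clip(w, 0.0, None)
    return U * np.sqrt(w)


def _orth_basis(A: Optional[np.ndarray]) -> Optional[np.ndarray]:
    if A is None or A.size == 0:
        return None
    Q, R = np.linalg.qr(A)
    keep = np.abs(np.diag(R)) > 1e-14 * max(np.abs(np.diag(R)).max(), 1e-300)
    return Q[:, keep]


def _explained_from_gh(G: np.ndarray, H: np.ndarray, subspace: bool):
    """Explained energy per candidate from Gram blocks and data products.

    G : (n, d, d) block Grams; H : (n, d, r) block–data products.  With
    ``subspace`` the full d-column space counts; otherwise the best single
    direction (generalized eigenproblem) counts, and the per-candidate
    optimal direction (in block coordinates) is returned.  Null directions
    inside a block (e.g. the magnetically silent radial axis) are cut at a
    relative eigenvalue tolerance.
    """
    w, U = np.linalg.eigh(G)
    wmax = np.maximum(w[..., -1:], 1e-300)
    winv = np.where(w > _NULLSPACE_RTOL * wmax, 1.0 / np.maximum(w, 1e-300), 0.0)
    T = U.swapaxes(-1, -2) @ H  # (n, d, r)
    if subspace:
        expl = np.sum(np.sum(T * T, axis=-1) * winv, axis=-1)
        return expl, None
    Hh = np.sqrt(winv)[..., None] * T
    Cm = Hh @ Hh.swapaxes(-1, -2)
    cw, cU = np.linalg.eigh(Cm)
    expl = cw[..., -1]
    # direction back in block coordinates: o ∝ U diag(sqrt(winv)) v_top
    o = (U @ (np.sqrt(winv) * cU[..., -1])[..., None])[..., 0]
    nrm = np.linalg.norm(o, axis=1, keepdims=True)
    o = o / np.where(nrm > 0, nrm, 1.0)
    return expl, o


def _batched_explained(Bt: np.ndarray, F: np.ndarray, subspace: bool):
    """Explained energy per candidate block Bt (n, M, d) against F (M, r)."""
    G = np.einsum("nmi,nmj->nij", Bt, Bt)
    H = np.einsum("nmi,mr->nir", Bt, F)
    return _explained_from_gh(G, H, subspace)


def _leadfield_2d(lf: LeadFieldSet) -> np.ndarray:
    """Cached (M, P*3) view of the lead-field tensor for GEMM-shaped scans."""
    m2 = getattr(lf, "_matrix2d", None)
    if m2 is None:
        m2 = np.ascontiguousarray(np.moveaxis(lf.matrix, 0, 1).reshape(lf.M, -1))
        lf._matrix2d = m2
    return m2


class ScanContext:
    """Per-(data, lead-field) products reused across conditional scans.

    A conditional scan with placed topographies spanned by an orthonormal
    basis Qa needs only rank-k corrections of the unconditional Gram blocks
    G0 = L(p)ᵀL(p) and data products H0 = L(p)ᵀF (F a compact factor of the
    data), since (I-P)² = I-P:

        G = G0 - (QaᵀL)ᵀ(QaᵀL),   H = H0 - (QaᵀL)ᵀ(QaᵀF).
    """

    def __init__(self, data: np.ndarray, lf: LeadFieldSet):
        self.Y = np.asarray(data, dtype=float)
        self.lf = lf
        self.M = self.Y.shape[0]
        self.P = lf.n_points
        self.B2 = _leadfield_2d(lf)  # (M, P*3)
        self.F = _compact_factor(self.Y)  # (M, r)
        self.total = float(np.sum(self.F**2))
        self.G0 = None
        self.H0 = None
        norms = getattr(lf, "_block_norms", None)
        if norms is None:
            norms = np.sum(self.B2.reshape(self.M, self.P, 3) ** 2, axis=(0, 2))
            lf._block_norms = norms
        self.block_norms = norms

    def _base_products(self):
        if self.G0 is None:
            M, P = self.M, self.P
            B3 = np.ascontiguousarray(np.moveaxis(self.B2.reshape(M, P, 3), 0, 1))
            self.G0 = B3.swapaxes(1, 2) @ B3  # (P, 3, 3)
            self.H0 = np.ascontiguousarray(
                np.moveaxis((self.F.T @ self.B2).reshape(-1, P, 3), 0, 2)
            )  # (P, 3, r)
        return self.G0, self.H0

    def projected(self, Qa: Optional[np.ndarray]):
        """(G, H, total_residual_energy) given the placed-set basis Qa."""
        G0, H0 = self._base_products()
        if Qa is None:
            return G0, H0, self.total
        P = self.P
        QB = (Qa.T @ self.B2).reshape(-1, P, 3)  # (k, P, 3)
        QF = Qa.T @ self.F  # (k, r)
        QBt = np.ascontiguousarray(np.moveaxis(QB, 0, 1))  # (P, k, 3)
        G = G0 - QBt.swapaxes(1, 2) @ QBt
        H = H0 - np.einsum("pki,kr->pir", QBt, QF)
        total = self.total - float(np.sum(QF**2))
        return G, H, total


def scan_one(
    data: np.ndarray,
    lf: LeadFieldSet,
    fixed_topos: Optional[np.ndarray] = None,
    mode: str = "fixed",
    ctx: Optional[ScanContext] = None,
) -> ScanResult:
    """Exact one-source scan: best grid point given already-placed topographies.

    ``fixed_topos`` is an M×k matrix of placed-dipole topographies (columns;
    3-column blocks concatenated in free mode).  Candidates whose projected
    block is numerically collinear with the placed set are skipped.
    Ties break toward the lowest grid index.  ``ctx`` carries cached
    products when many scans run against the same data.
    """
    if ctx is None:
        ctx = ScanContext(data, lf)
    Qa = _orth_basis(fixed_topos)
    G, H, total = ctx.projected(Qa)
    expl, ori = _explained_from_gh(G, H, subspace=(mode == "free"))
    norm_proj = np.trace(G, axis1=1, axis2=2)
    mask = norm_proj < (COLLINEARITY_RTOL**2) * np.maximum(ctx.block_norms, 1e-300)
    expl = np.where(mask, -np.inf, expl)
    if not np.any(np.isfinite(expl)):
        raise RuntimeError("every candidate is collinear with the placed set")
    # lowest grid index among numerically tied maxima
    mx = np.max(expl)
    best = int(np.flatnonzero(expl >= mx - 1e-12 * max(total, 1e-300))[0])
    residuals = np.where(mask, np.inf, total - expl)
    return ScanResult(
        index=best,
        orientation=None if mode == "free" else ori[best],
        ssr=float(max(total - expl[best], 0.0)),
        residuals=residuals,
        orientations=None if mode == "free" else ori,
    )


# ---------------------------------------------------------------------------
# AP fitting
# ---------------------------------------------------------------------------


def _topos_matrix(lf, indices, orientations, mode) -> np.ndarray:
    blocks = lf.matrix[np.asarray(indices, int)]
    if mode == "fixed":
        return np.einsum("qmi,qi->qm", blocks, np.asarray(orientations)).T  # (M, k)
    return np.concatenate(list(np.moveaxis(blocks, 0, 0)), axis=1)  # (M, 3k)


def _fit_zero(Y: np.ndarray, mode: str) -> DipoleFit:
    return DipoleFit(
        K=0,
        grid_indices=np.empty(0, dtype=int),
        orientations=np.empty((0, 3)) if mode == "fixed" else None,
        amplitudes=np.empty((0, Y.shape[1])),
        predicted=np.zeros_like(Y),
        ssr=float(np.sum(Y**2)),
        mode=mode,
    )


def _refresh_orientations(Y, lf, indices, oris, n_iter: int = 3, ctx=None):
    """Cyclic re-solve of every source's orientation, positions held fixed.

    Each step is the exact analytic single-dipole orientation optimum given
    the other sources' current topographies, so the joint SSR never
    increases.  Needed because a conditional position scan holds the other
    sources' orientations fixed; without this refresh the (position,
    orientation) coordinate descent can stall on a stale orientation.
    """
    K = len(indices)
    if K < 2:
        return oris
    F = ctx.F if ctx is not None else _compact_factor(Y)
    for _ in range(n_iter):
        for i in range(K):
            others_idx = indices[:i] + indices[i + 1 :]
            others_ori = oris[:i] + oris[i + 1 :]
            A = _topos_matrix(lf, others_idx, others_ori, "fixed")
            Qa = _orth_basis(A)
            Bi = lf.matrix[indices[i]]  # (M, 3)
            Bp = Bi - Qa @ (Qa.T @ Bi)
            G = (Bp.T @ Bp)[None]
            H = (Bp.T @ F)[None]
            _, o = _explained_from_gh(G, H, subspace=False)
            oris[i] = o[0]
    return oris


def _cyclic_descent(Y, lf, indices, oris, mode, max_sweeps, tol, ctx=None):
    """Cyclic coordinate descent over source positions; never increases SSR.

    Returns (indices, oris, ssr, sweeps, converged); ``ssr`` is the scan
    criterion (subspace SSR in free mode).
    """
    K = len(indices)
    last_ssr = np.inf
    cur_ssr = np.inf
    sweeps = 0
    converged = False
    for sweeps in range(1, max_sweeps + 1):
        changed = False
        for i in range(K):
            others_idx = indices[:i] + indices[i + 1 :]
            others_ori = (oris[:i] + oris[i + 1 :]) if mode == "fixed" else None
            A = _topos_matrix(lf, others_idx, others_ori, mode) if others_idx else None
            res = scan_one(Y, lf, A, mode, ctx=ctx)
            if res.index != indices[i]:
                changed = True
            indices[i] = res.index
            if mode == "fixed":
                oris[i] = res.orientation
            cur_ssr = res.ssr
        ori_delta = 0.0
        if mode == "fixed" and K > 1:
            old = [o.copy() for o in oris]
            oris = _refresh_orientations(Y, lf, indices, oris, ctx=ctx)
            ori_delta = max(
                min(np.linalg.norm(o - p), np.linalg.norm(o + p))  # sign-invariant
                for o, p in zip(oris, old)
            )
        if not changed and ori_delta < 1e-9:
            converged = True
            break
        if np.isfinite(last_ssr) and last_ssr > 0 and abs(last_ssr - cur_ssr) <= tol * last_ssr:
            converged = True
            break
        last_ssr = cur_ssr
    if not np.isfinite(cur_ssr):  # K == 1 converging on the first scan
        res = scan_one(Y, lf, None, mode, ctx=ctx)
        indices[0] = res.index
        if mode == "fixed":
            oris[0] = res.orientation
        cur_ssr = res.ssr
    return indices, oris, cur_ssr, sweeps, converged


def ap_fit(
    data: np.ndarray,
    lf: LeadFieldSet,
    K: int,
    mode: str = "fixed",
    warm_start: Optional[DipoleFit] = None,
    max_sweeps: int = 10,
    tol: float = 1e-9,
    n_candidates: int = 3,
    n_starts: int = 1,
) -> DipoleFit:
    """K-dipole AP fit: greedy initialization then cyclic refinement.

    With ``warm_start`` the first K-1 sources are taken from the supplied
    fit (making the K-sequence of fits nested, as the sequential F-test
    requires); only the added source is found greedily before refinement.

    After the cyclic descent converges, a deterministic polish stage guards
    against coordinate-descent local minima: each source in turn is restarted
    from the ``n_candidates`` best runner-up grid points of its conditional
    scan and the descent re-run; a restart is adopted only when it strictly
    lowers the SSR.  ``n_candidates = 0`` disables polishing.  With
    ``n_starts > 1`` (and no warm start) the greedy initialization is
    additionally multi-started from the best ``n_starts`` first-source
    candidates and the lowest-SSR descent result is kept — a thorough search
    setting for hard multi-modal landscapes.
    """
    Y = np.asarray(data, dtype=float)
    M = Y.shape[0]
    if K >= M:
        raise ValueError("K must be smaller than the channel count")
    if K > lf.n_points:
        raise ValueError("K exceeds the number of grid points")
    if K == 0:
        return _fit_zero(Y, mode)

    base_indices: list[int] = []
    base_oris: list[np.ndarray] = []
    if warm_start is not None and warm_start.K > 0:
        take = min(warm_start.K, K - 1)
        base_indices = [int(i) for i in warm_start.grid_indices[:take]]
        if mode == "fixed":
            base_oris = [np.asarray(o, float) for o in warm_start.orientations[:take]]

    ctx = ScanContext(Y, lf)

    def _grow_and_descend(indices, oris):
        while len(indices) < K:
            A = (
                _topos_matrix(lf, indices, oris if mode == "fixed" else None, mode)
                if indices
                else None
            )
            res = scan_one(Y, lf, A, mode, ctx=ctx)
            indices.append(res.index)
            if mode == "fixed":
                oris.append(res.orientation)
        return _cyclic_descent(Y, lf, indices, oris, mode, max_sweeps, tol, ctx=ctx)

    # phases 1-2: greedy initialization(s) + cyclic coordinate descent;
    # with multistart, the few best distinct solutions are kept for polishing
    indices, oris, best_ssr, sweeps, converged = _grow_and_descend(
        list(base_indices), list(base_oris)
    )
    finalists = [(best_ssr, indices, oris, converged)]
    if n_starts > 1 and not base_indices and K > 1:
        first = scan_one(Y, lf, None, mode, ctx=ctx)
        order = np.argsort(first.residuals, kind="stable")
        seen = {frozenset(indices)}
        for alt in order[:n_starts]:
            alt = int(alt)
            start_ori = [first.orientations[alt]] if mode == "fixed" else []
            t_idx, t_ori, t_ssr, t_sweeps, t_conv = _grow_and_descend([alt], start_ori)
            sweeps += t_sweeps
            key = frozenset(t_idx)
            if key not in seen:
                seen.add(key)
                finalists.append((t_ssr, t_idx, t_ori, t_conv))
        finalists.sort(key=lambda t: t[0])
        finalists = finalists[:5]
        best_ssr, indices, oris, converged = finalists[0]

    # phase 3: runner-up polish against local minima, applied to every finalist
    if n_candidates > 0 and K > 1:
        polished = []
        for f_ssr, f_idx, f_ori, f_conv in finalists:
            p_idx, p_ori, p_ssr, p_sweeps, p_conv = _runner_up_polish(
                Y, lf, list(f_idx), list(f_ori), f_ssr, f_conv, mode,
                max_sweeps, tol, n_candidates, ctx=ctx,
            )
            sweeps += p_sweeps
            polished.append((p_ssr, p_idx, p_ori, p_conv))
        polished.sort(key=lambda t: t[0])
        best_ssr, indices, oris, converged = polished[0]

    return _finalize_fit(Y, lf, indices, oris, mode, sweeps, converged)


def _runner_up_polish(Y, lf, indices, oris, best_ssr, converged, mode, max_sweeps, tol, n_candidates, ctx=None):
    K = len(indices)
    sweeps = 0
    improved = True
    guard = 0
    while improved and guard < 5:
        improved = False
        guard += 1
        for i in range(K):
            others_idx = indices[:i] + indices[i + 1 :]
            others_ori = (oris[:i] + oris[i + 1 :]) if mode == "fixed" else None
            A = _topos_matrix(lf, others_idx, others_ori, mode)
            res = scan_one(Y, lf, A, mode, ctx=ctx)
            order = np.argsort(res.residuals, kind="stable")
            for alt in order[: n_candidates + 1]:
                alt = int(alt)
                if alt == indices[i] or alt in others_idx:
                    continue
                trial_idx = list(indices)
                trial_idx[i] = alt
                trial_ori = list(oris)
                if mode == "fixed":
                    trial_ori[i] = res.orientations[alt]
                t_idx, t_ori, t_ssr, t_sweeps, t_conv = _cyclic_descent(
                    Y, lf, trial_idx, trial_ori, mode, max_sweeps, tol, ctx=ctx
                )
                if t_ssr < best_ssr * (1.0 - 1e-12):
                    indices, oris, best_ssr = t_idx, t_ori, t_ssr
                    sweeps += t_sweeps
                    converged = t_conv
                    improved = True
                    break
            if improved:
                break
    return indices, oris, best_ssr, sweeps, converged


def _finalize_fit(Y, lf, indices, oris, mode, sweeps, converged) -> DipoleFit:
    indices = [int(i) for i in indices]
    K = len(indices)
    ssr_subspace = None
    if mode == "free":
        A = _topos_matrix(lf, indices, None, "free")  # (M, 3K)
        X, *_ = np.linalg.lstsq(A, Y, rcond=None)
        ssr_subspace = float(np.sum((Y - A @ X) ** 2))
        oris = []
        for q in range(K):
            moment = X[3 * q : 3 * q + 3]  # (3, N)
            U, s, _ = np.linalg.svd(moment, full_matrices=False)
            o = U[:, 0]
            if o[np.argmax(np.abs(o))] < 0:
                o = -o
            oris.append(o)
    A = _topos_matrix(lf, indices, oris, "fixed")
    if np.linalg.matrix_rank(A) < K:
        raise np.linalg.LinAlgError(
            f"rank-deficient topography set for grid indices {indices}"
        )
    S, *_ = np.linalg.lstsq(A, Y, rcond=None)
    predicted = A @ S
    return DipoleFit(
        K=K,
        grid_indices=np.asarray(indices, int),
        orientations=np.asarray(oris),
        amplitudes=S,
        predicted=predicted,
        ssr=float(np.sum((Y - predicted) ** 2)),
        mode=mode,
        iterations=sweeps,
        converged=converged,
        ssr_subspace=ssr_subspace,
    )


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------


def exhaustive_fit(
    data: np.ndarray, lf: LeadFieldSet, K: int, mode: str = "free"
) -> DipoleFit:
    """Global least-squares minimizer by enumerating all index subsets (K<=2).

    In free mode the per-subset criterion is the exact 3K-column subspace
    fit.  In fixed mode orientations per subset are solved by a short
    alternating sequence of analytic one-dipole orientation optimizations.
    """
    Y = np.asarray(data, dtype=float)
    P = lf.n_points
    if K > 2:
        raise ValueError("exhaustive search is limited to K <= 2")
    if comb(P, max(K, 1)) > 10**6:
        raise ValueError("combinatorial budget exceeded (C(P, K) > 1e6)")
    if K == 0:
        return _fit_zero(Y, mode)
    if K == 1:
        res = scan_one(Y, lf, None, mode)
        return _finalize_fit(
            Y, lf, [res.index], [res.orientation] if mode == "fixed" else None, mode, 0, True
        )

    ii, jj = np.triu_indices(P, 1)
    F = _compact_factor(Y)
    B = lf.matrix
    if mode == "free":
        pairs = np.concatenate([B[ii], B[jj]], axis=2)  # (n, M, 6)
        expl, _ = _batched_explained(pairs, F, subspace=True)
        best = int(np.argmax(expl))
        return _finalize_fit(Y, lf, [int(ii[best]), int(jj[best])], None, mode, 0, True)

    # fixed mode: alternate the analytic orientation solve between the two dipoles
    _, o_single = _batched_explained(B, F, subspace=False)
    o_i, o_j = o_single[ii].copy(), o_single[jj].copy()
    for _ in range(8):
        for which in (0, 1):
            a_idx, a_ori = (jj, o_j) if which == 0 else (ii, o_i)
            b_idx = ii if which == 0 else jj
            t = np.einsum("nmi,ni->nm", B[a_idx], a_ori)  # fixed topo per pair
            t = t / np.maximum(np.linalg.norm(t, axis=1, keepdims=True), 1e-300)
            # Bp ⊥ t, so Bpᵀ(projected data) reduces to BpᵀF: no per-pair
            # projected data matrix is ever materialized
            Bp = B[b_idx] - t[:, :, None] * np.einsum("nm,nmi->ni", t, B[b_idx])[:, None, :]
            G = np.einsum("nmi,nmj->nij", Bp, Bp)
            H = np.einsum("nmi,mr->nir", Bp, F)
            _, o_new = _explained_from_gh(G, H, subspace=False)
            if which == 0:
                o_i = o_new
            else:
                o_j = o_new
    t_i = np.einsum("nmi,ni->nm", B[ii], o_i)
    t_j = np.einsum("nmi,ni->nm", B[jj], o_j)
    pairs = np.stack([t_i, t_j], axis=2)  # (n, M, 2)
    expl, _ = _batched_explained(pairs, F, subspace=True)
    best = int(np.argmax(expl))
    return _finalize_fit(
        Y, lf, [int(ii[best]), int(jj[best])], [o_i[best], o_j[best]], mode, 0, True
    )


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------


class APDipoleFitter(BaseEstimator):
    """scikit-learn style facade over :func:`ap_fit`.

    Parameters
    ----------
    leadfields : LeadFieldSet
        Candidate grid and forward model (whitened if the data are).
    n_dipoles : int
    mode : {"fixed", "free"}
    max_sweeps, tol : refinement controls.
    warm_start : bool
        When True, a repeated :meth:`fit` reuses the previous solution as the
        first ``n_dipoles - 1`` sources.
    """

    def __init__(
        self,
        leadfields: LeadFieldSet,
        n_dipoles: int = 1,
        mode: str = "fixed",
        max_sweeps: int = 10,
        tol: float = 1e-9,
        warm_start: bool = False,
        n_candidates: int = 3,
        n_starts: int = 1,
    ):
        self.leadfields = leadfields
        self.n_dipoles = n_dipoles
        self.mode = mode
        self.max_sweeps = max_sweeps
        self.tol = tol
        self.warm_start = warm_start
        self.n_candidates = n_candidates
        self.n_starts = n_starts

    def fit(self, X: np.ndarray, y=None) -> "APDipoleFitter":
        prev = getattr(self, "fit_", None) if self.warm_start else None
        self.fit_ = ap_fit(
            X,
            self.leadfields,
            self.n_dipoles,
            mode=self.mode,
            warm_start=prev,
            max_sweeps=self.max_sweeps,
            tol=self.tol,
            n_candidates=self.n_candidates,
            n_starts=self.n_starts,
        )
        self.indices_ = self.fit_.grid_indices
        self.orientations_ = self.fit_.orientations
        self.amplitudes_ = self.fit_.amplitudes
        self.ssr_ = self.fit_.ssr
        self.n_iter_ = self.fit_.iterations
        self.converged_ = self.fit_.converged
        return self

    def predict(self, X=None) -> np.ndarray:
        """Predicted sensor field of the fitted dipole model."""
        return self.fit_.predicted

    def score(self, X: np.ndarray, y=None) -> float:
        """Goodness of fit: 1 - SSR / ||X||_F^2."""
        return 1.0 - self.ssr_ / float(np.sum(np.asarray(X, float) ** 2))
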