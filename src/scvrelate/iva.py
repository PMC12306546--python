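"""Independent vector analysis with a Laplacian + second-order source model.

Given K datasets X[k] (R x V), IVA jointly estimates demixing matrices W[k]
so that the estimated sources S[k] = W[k] X[k] are maximally independent
*across* source indices while dependence *within* each source component
vector (SCV) — the K-vector collecting source r from every dataset — is
retained and modelled.

The SCV density model is a correlated multivariate Laplacian,
p(s_r) ∝ det(Σ_r)^{-1/2} exp(-sqrt(s_r' Σ_r^{-1} s_r)), capturing both heavy
tails (higher-order statistics) and cross-dataset correlation (second-order
statistics).  Profiling the dispersion Σ_r analytically — its shape at the
sample covariance C_r of the current sources and its scale at the inner
minimiser (m_r / K)^2 with m_r = E_v sqrt(s_r' C_r^{-1} s_r) — gives the
cost actually minimised over the W[k]:

    J(W) = Σ_r [ (1/2) log det C_r + K log m_r ] - Σ_k log |det W[k]| + const,
    C_r = (1/V) S_r S_r' + λI.

Minimisation interleaves L-BFGS steps on the exact gradient of J (the chain
rule through C_r is included) with two discrete realignment moves that target
the characteristic local minima of IVA — cross-dataset permutation
misalignment of SCVs:

* per-dataset reassignment of source rows to SCV slots (optimal assignment
  on cross-dataset correlation), and
* joint swaps of a slot pair for a whole group of datasets, the groups being
  connected components of the thresholded correlation graph (this escapes
  "chimera" solutions in which two SCVs sharing some blocks are exchanged
  for a subset of datasets).

Every discrete move is accepted only if it lowers J, so the objective
trajectory is non-increasing throughout.  Sources are recovered up to a
per-row sign and an SCV-order permutation; everything downstream is
invariant to both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.optimize import minimize as _sp_minimize
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ._streams import substream

__all__ = [
    "DemixingSet",
    "IvaResult",
    "RunEnsemble",
    "iva_l_sos",
    "objective",
    "run_ensemble",
    "joint_isi",
]

_COV_REG = 1e-8      # ridge added to each SCV covariance before inversion
_Q_FLOOR = 1e-12     # floor on the Mahalanobis form inside sqrt
_SWAP_TAU = 0.1      # correlation threshold for the alignment graph
_MAX_ROUNDS = 6      # optimisation/realignment cycles per fit


@dataclass
class DemixingSet:
    """Demixing matrices W[k] (including any whitening) for K datasets."""

    W: list[np.ndarray]
    whitening: list[np.ndarray] | None = None

    def apply(self, X: list[np.ndarray]) -> list[np.ndarray]:
        """Estimated source matrices S[k] = W[k] X[k]."""
        return [Wk @ Xk for Wk, Xk in zip(self.W, X)]


@dataclass
class IvaResult:
    """One IVA fit: demixing, SCV-ordered sources and diagnostics."""

    demixing: DemixingSet
    sources: list[np.ndarray]          # R arrays of shape (K, V): the SCVs
    objective_trajectory: np.ndarray
    n_iter: int
    converged: bool
    seed: int

    @property
    def R(self) -> int:
        return len(self.sources)

    @property
    def K(self) -> int:
        return self.sources[0].shape[0]

    def dataset_sources(self, k: int) -> np.ndarray:
        """S[k]: rows are sources of dataset k, ordered by SCV index."""
        return np.stack([scv[k] for scv in self.sources])


@dataclass
class RunEnsemble:
    """Multiple IVA restarts with a cross-run consistency selection."""

    runs: list[IvaResult]
    pairwise_distance: np.ndarray
    selected: int

    @property
    def best(self) -> IvaResult:
        return self.runs[self.selected]


# ---------------------------------------------------------------------------
# objective and gradient
# ---------------------------------------------------------------------------

def _cost(W: np.ndarray, Z: np.ndarray, reg: float,
          want_grad: bool = True):
    """Profile cost and (optionally) its exact gradient, batched over SCVs.

    W is (K, R, R) and Z is (K, R, V); returns J or (J, GW).
    """
    K, R, V = Z.shape
    sign, logdet = np.linalg.slogdet(W)
    if np.any(sign == 0):
        return (np.inf, None) if want_grad else np.inf
    J = -float(np.sum(logdet))
    S = W @ Z                                           # (K, R, V)
    Y = S.transpose(1, 0, 2)                            # (R, K, V)
    C = Y @ Y.transpose(0, 2, 1) / V + reg * np.eye(K)
    sC, ldC = np.linalg.slogdet(C)
    if np.any(sC <= 0):
        return (np.inf, None) if want_grad else np.inf
    CinvY = np.linalg.solve(C, Y)                       # (R, K, V)
    q = np.maximum(np.einsum("rkv,rkv->rv", Y, CinvY), _Q_FLOOR)
    sq = np.sqrt(q)
    m = sq.mean(axis=1)                                 # (R,)
    J += 0.5 * float(np.sum(ldC)) + float(K * np.sum(np.log(m)))
    if not want_grad:
        return J
    # dJ/dY: logdet-C term + K log m term, both with the chain rule through C
    wgt = (K / (m * V))[:, None, None]
    CY_rq = CinvY / sq[:, None, :]
    M = CY_rq @ CinvY.transpose(0, 2, 1) / V
    GY = CinvY / V + wgt * (CY_rq - M @ Y)
    GW = GY.transpose(1, 0, 2) @ Z.transpose(0, 2, 1)
    GW -= np.linalg.inv(W).transpose(0, 2, 1)
    return J, GW


def objective(W: list[np.ndarray] | DemixingSet, X: list[np.ndarray]) -> float:
    """Evaluate the IVA profile cost for given demixing matrices and data.

    Returns ``inf`` for a singular W (such points are rejected during
    optimisation).
    """
    if isinstance(W, DemixingSet):
        W = W.W
    Wst = np.stack([np.asarray(w, dtype=float) for w in W])
    Xst = np.stack([np.asarray(x, dtype=float) for x in X])
    return _cost(Wst, Xst, _COV_REG, want_grad=False)


# ---------------------------------------------------------------------------
# optimisation: L-BFGS cycles + discrete realignment moves
# ---------------------------------------------------------------------------

def _lbfgs_cycle(W: np.ndarray, Z: np.ndarray, reg: float,
                 maxiter: int, gtol: float) -> tuple[np.ndarray, float, list, bool]:
    shape = W.shape
    traj: list[float] = []

    def fun(w):
        J, G = _cost(w.reshape(shape), Z, reg)
        if not np.isfinite(J):
            return 1e10, np.zeros_like(w)
        return J, G.ravel()

    def record(wk):
        traj.append(_cost(wk.reshape(shape), Z, reg, want_grad=False))

    res = _sp_minimize(
        fun, W.ravel(), jac=True, method="L-BFGS-B", callback=record,
        options=dict(maxiter=maxiter, gtol=gtol, ftol=1e-12),
    )
    return res.x.reshape(shape), float(res.fun), traj, bool(res.status == 0)


def _norm_rows(Y: np.ndarray) -> np.ndarray:
    """Centre and L2-normalise along the last axis."""
    T = Y - Y.mean(axis=-1, keepdims=True)
    n = np.linalg.norm(T, axis=-1, keepdims=True)
    n[n == 0] = 1.0
    return T / n


def _assignment_polish(W: np.ndarray, Z: np.ndarray, reg: float) -> tuple[np.ndarray, float]:
    """Reassign each dataset's rows to SCV slots by optimal assignment on
    mean cross-dataset |correlation|; accept only cost decreases."""
    K, R, V = Z.shape
    J = _cost(W, Z, reg, want_grad=False)
    for _ in range(10):
        improved = False
        T = _norm_rows(W @ Z)                           # (K, R, V)
        for k in range(K):
            ben = np.zeros((R, R))
            for l in range(K):
                if l != k:
                    ben += np.abs(T[k] @ T[l].T)
            ri, ci = linear_sum_assignment(-ben)
            if np.all(ri == ci):
                continue
            Wtry = W.copy()
            for i, c in zip(ri, ci):
                Wtry[k, c] = W[k, i]
            Jt = _cost(Wtry, Z, reg, want_grad=False)
            if Jt < J - 1e-12:
                W, J, improved = Wtry, Jt, True
                T = _norm_rows(W @ Z)
        if not improved:
            break
    return W, J


def _group_swap_polish(W: np.ndarray, Z: np.ndarray, reg: float,
                       tau: float = _SWAP_TAU) -> tuple[np.ndarray, float]:
    """Swap a slot pair jointly for a group of datasets; accept only cost
    decreases.  Groups are connected components of the correlation graph of
    the two slots, which is exactly how the dataset camps of a chimera
    solution separate."""
    K, R, V = Z.shape
    J = _cost(W, Z, reg, want_grad=False)
    for _ in range(6):
        improved = False
        T = _norm_rows((W @ Z).transpose(1, 0, 2))      # (R, K, V)
        for r in range(R):
            for r2 in range(r + 1, R):
                cr = np.abs(T[r] @ T[r].T)
                cr2 = np.abs(T[r2] @ T[r2].T)
                cx = np.abs(T[r] @ T[r2].T)
                A = np.maximum(np.maximum(cr, cr2), np.maximum(cx, cx.T))
                np.fill_diagonal(A, 0.0)
                n_comp, labels = connected_components(
                    csr_matrix(A > tau), directed=False
                )
                if n_comp <= 1:
                    continue
                for c in range(n_comp):
                    g = np.flatnonzero(labels == c)
                    if len(g) == K:
                        continue
                    Wtry = W.copy()
                    for k in g:
                        Wtry[k][[r, r2]] = Wtry[k][[r2, r]]
                    Jt = _cost(Wtry, Z, reg, want_grad=False)
                    if Jt < J - 1e-12:
                        W, J, improved = Wtry, Jt, True
                        T = _norm_rows((W @ Z).transpose(1, 0, 2))
        if not improved:
            break
    return W, J


def _whiten(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-dataset whitening; raises on rank deficiency."""
    K, R, V = X.shape
    P = np.empty((K, R, R))
    Z = np.empty_like(X)
    for k in range(K):
        C = X[k] @ X[k].T / V
        d, E = np.linalg.eigh(C)
        if d[0] <= d[-1] * 1e-12 or d[-1] <= 0:
            raise ValueError(
                f"dataset {k} is rank-deficient; reduce its dimension with "
                "PCA before running IVA"
            )
        P[k] = (E / np.sqrt(d)) @ E.T
        Z[k] = P[k] @ X[k]
    return Z, P


def _random_orthogonal(R: int, rng: np.random.Generator) -> np.ndarray:
    Q, Rm = np.linalg.qr(rng.standard_normal((R, R)))
    return Q * np.sign(np.diag(Rm))


def iva_l_sos(
    X: list[np.ndarray],
    max_iter: int = 1024,
    tol: float = 1e-6,
    seed: int = 0,
    whiten: bool = True,
    init: str | list[np.ndarray] = "random",
    reg: float = _COV_REG,
) -> IvaResult:
    """Fit IVA with the multivariate-Laplacian + second-order source model.

    Parameters
    ----------
    X : list of K arrays, each R x V
        Observed datasets with centred rows.
    max_iter : int
        Cap on L-BFGS iterations per optimisation cycle.
    tol : float
        Gradient-norm convergence threshold of each cycle.
    seed : int
        Seeds the random orthogonal initialisation.
    whiten : bool
        Pre-whiten each dataset (recommended); the returned demixing
        matrices always act on the *raw* X.
    init : "random" | "identity" | list of arrays
        Initial demixing in the (whitened) working space.

    Returns
    -------
    IvaResult
        Sources are normalised to unit sample variance (the scale is
        absorbed into W), so SCV covariances are correlation matrices.
    """
    Xst = np.stack([np.asarray(x, dtype=float) for x in X])
    K, R, V = Xst.shape
    if V <= R:
        raise ValueError("need more samples than source dimensions (V > R)")

    if whiten:
        Z, P = _whiten(Xst)
    else:
        Z, P = Xst, np.stack([np.eye(R)] * K)

    rng = substream(seed, "iva", "init")
    if isinstance(init, str):
        if init == "random":
            W = np.stack([_random_orthogonal(R, rng) for _ in range(K)])
        elif init == "identity":
            W = np.stack([np.eye(R)] * K)
        else:
            raise ValueError(f"unknown init {init!r}")
    else:
        W = np.stack([np.asarray(w, dtype=float) for w in init])

    trajectory = [_cost(W, Z, reg, want_grad=False)]
    n_iter = 0
    converged = False
    J_prev = np.inf
    for _ in range(_MAX_ROUNDS):
        W, J, traj, ok = _lbfgs_cycle(W, Z, reg, maxiter=max_iter, gtol=tol)
        trajectory.extend(traj)
        n_iter += len(traj)
        if not np.isfinite(J):
            raise FloatingPointError(
                f"objective became non-finite after iteration {n_iter}"
            )
        W, J = _assignment_polish(W, Z, reg)
        W, J = _group_swap_polish(W, Z, reg)
        trajectory.append(J)
        if J >= J_prev - 1e-9:
            converged = ok
            break
        J_prev = J

    # compose with whitening, then absorb source scales into W
    W_full = W @ P
    S = W_full @ Xst
    stds = S.std(axis=2, keepdims=True)
    stds[stds == 0] = 1.0
    W_full = W_full / stds
    S = S / stds

    sources = [S[:, r, :].copy() for r in range(R)]
    return IvaResult(
        demixing=DemixingSet(W=[W_full[k] for k in range(K)],
                             whitening=[P[k] for k in range(K)]),
        sources=sources,
        objective_trajectory=np.asarray(trajectory),
        n_iter=n_iter,
        converged=converged,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# multi-run consistency selection
# ---------------------------------------------------------------------------

def _scv_match_distance(a: IvaResult, b: IvaResult) -> float:
    """Cross-run discrepancy after resolving SCV permutation and sign.

    Mean over datasets of |row correlation| between SCVs of the two runs is
    maximised by optimal assignment; the distance is 1 minus the mean
    matched absolute correlation.
    """
    Sa = _norm_rows(np.stack(a.sources))   # (R, K, V)
    Sb = _norm_rows(np.stack(b.sources))
    K = Sa.shape[1]
    corr = np.zeros((Sa.shape[0], Sb.shape[0]))
    for k in range(K):
        corr += np.abs(Sa[:, k, :] @ Sb[:, k, :].T)
    corr /= K
    row, col = linear_sum_assignment(1.0 - corr)
    return float(np.mean(1.0 - corr[row, col]))


def run_ensemble(
    X: list[np.ndarray],
    n_runs: int = 20,
    seed: int = 0,
    **iva_kwargs,
) -> RunEnsemble:
    """Run IVA from ``n_runs`` random initialisations and pick the most
    consistent run: the one minimising the mean permutation/sign-resolved
    distance to all other runs."""
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    runs = [
        iva_l_sos(X, seed=s, **iva_kwargs) for s in _run_seeds(seed, n_runs)
    ]
    n = len(runs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _scv_match_distance(runs[i], runs[j])
    selected = int(np.argmin(D.sum(axis=1))) if n > 1 else 0
    return RunEnsemble(runs=runs, pairwise_distance=D, selected=selected)


def _run_seeds(seed: int, n_runs: int) -> list[int]:
    # stable derived integer seeds (< 2**31) for each restart
    ss = np.random.SeedSequence((int(seed), 0x49564121))
    return [int(s) for s in ss.generate_state(n_runs) % (2**31)]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def joint_isi(
    W: list[np.ndarray] | DemixingSet, A: list[np.ndarray]
) -> float:
    """Joint inter-symbol-interference of the demixing-mixing products.

    With G[k] = W[k] A[k] and Ḡ the entrywise mean of |G[k]| over datasets,
    returns the normalised cross-talk of Ḡ in [0, 1]: 0 iff every G[k] is
    the same permutation of a diagonal matrix (perfect joint separation up
    to the inherent ambiguities), 1 for uniform cross-talk.
    """
    if isinstance(W, DemixingSet):
        W = W.W
    Gbar = np.mean([np.abs(Wk @ Ak) for Wk, Ak in zip(W, A)], axis=0)
    N = Gbar.shape[0]
    if N < 2:
        return 0.0
    row_term = np.sum(Gbar.sum(axis=1) / Gbar.max(axis=1) - 1.0)
    col_term = np.sum(Gbar.sum(axis=0) / Gbar.max(axis=0) - 1.0)
    return float((row_term + col_term) / (2.0 * N * (N - 1.0)))
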