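"""Counting eigenvalues greater than 1 in SCV covariance matrices.

A noiseless block-correlation SCV covariance with d blocks has exactly d
eigenvalues greater than 1, so d separates *common* SCVs (d = 1, every
dataset correlated) from *structured* ones (d > 1, several correlated
groups).  With finite samples the zero off-block correlations are estimated
imperfectly and naive counting (``ev_count``) overestimates d.  The bootstrap
test resamples the SCV columns with replacement to approximate the null
distribution of T = λ̂[k] − 1 and rejects λ[k] ≤ 1 only when T exceeds the
(1 − Pfa) bootstrap quantile of λ̂_b[k] − λ̂[k].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._streams import substream

__all__ = [
    "CovEstimate",
    "BootstrapConfig",
    "EigCountResult",
    "scv_covariance",
    "bootstrap_count",
    "ev_count",
    "classify_scvs",
]

_BOOT_CHUNK = 256  # bootstrap replicates processed per batch (memory bound)


@dataclass
class CovEstimate:
    """Absolute sample correlation matrix of one SCV with its EVD.

    ``C_hat = |S S' / V|`` for row-standardised S; the absolute value absorbs
    the per-row sign ambiguity of separated sources, making block entries
    nonnegative.  Eigenvalues are sorted descending with eigenvector columns
    aligned.
    """

    C_hat: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    V: int


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap test configuration.

    B resamples and false-alarm probability Pfa give the threshold order
    statistic η = floor((B+1)(1−Pfa)), which must land inside 1..B.
    """

    B: int = 1000
    Pfa: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be a positive number of bootstrap resamples")
        if not 0.0 < self.Pfa < 1.0:
            raise ValueError("Pfa must lie in (0, 1)")
        eta = self.eta
        if not 1 <= eta <= self.B:
            raise ValueError(
                f"eta = floor((B+1)(1-Pfa)) = {eta} is outside 1..B={self.B}; "
                "increase B or adjust Pfa"
            )

    @property
    def eta(self) -> int:
        return math.floor((self.B + 1) * (1.0 - self.Pfa))


@dataclass
class EigCountResult:
    """Outcome of the bootstrap test for one SCV."""

    d_hat: int
    epsilon: np.ndarray        # K 0/1 rejection flags, one per eigenvalue
    T_hat: np.ndarray          # per-eigenvalue statistic λ̂[k] − 1
    thresholds: np.ndarray     # per-eigenvalue bootstrap threshold T*_η
    cov: CovEstimate
    config: BootstrapConfig


def _standardise_rows(S: np.ndarray) -> np.ndarray:
    # scale by the root mean square so the S S'/V diagonal is exactly 1;
    # rows are zero-mean upstream, making this the sample standard deviation
    S = np.asarray(S, dtype=float)
    rms = np.sqrt((S**2).mean(axis=1))
    if np.any(rms == 0):
        bad = int(np.flatnonzero(rms == 0)[0])
        raise ValueError(f"source row {bad} has zero variance")
    return S / rms[:, None]


def scv_covariance(S: np.ndarray) -> CovEstimate:
    """Absolute sample covariance of an SCV and its eigendecomposition.

    Rows are defensively rescaled to unit sample variance (they should
    already be close after source normalisation), so the result is an
    absolute correlation matrix: unit diagonal, entries in [0, 1].  The
    absolute value is applied *before* the EVD.
    """
    S = _standardise_rows(S)
    K, V = S.shape
    C = np.abs(S @ S.T / V)
    lam, U = np.linalg.eigh(C)
    order = np.argsort(lam)[::-1]
    return CovEstimate(C_hat=C, eigenvalues=lam[order], eigenvectors=U[:, order], V=V)


def _bootstrap_eigenvalues(
    S: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Descending eigenvalue spectra of B column-resampled abs-covariances.

    One shared column-index draw per replicate resamples the whole SCV,
    preserving cross-row dependence.  Rows are not re-centred or re-scaled
    inside a replicate.
    """
    K, V = S.shape
    out = np.empty((B, K))
    for start in range(0, B, _BOOT_CHUNK):
        stop = min(start + _BOOT_CHUNK, B)
        idx = rng.integers(0, V, size=(stop - start, V))
        Sb = S[:, idx].transpose(1, 0, 2)            # (b, K, V)
        Cb = np.abs(Sb @ Sb.transpose(0, 2, 1) / V)
        lam = np.linalg.eigvalsh(Cb)                 # ascending
        out[start:stop] = lam[:, ::-1]
    return out


def bootstrap_count(
    S: np.ndarray,
    cfg: BootstrapConfig | None = None,
    scv_index: int = 0,
) -> EigCountResult:
    """Estimate d̂ for one SCV by the bootstrap eigenvalue test.

    For each eigenvalue rank k the statistic T̂ = λ̂[k] − 1 is compared with
    the η-th smallest bootstrap deviation T*_b = λ̂_b[k] − λ̂[k]; the null
    λ[k] ≤ 1 is rejected when T̂ ≥ T*_η (ties reject).  d̂ is the number of
    rejections.  The RNG is a substream of (cfg.seed, scv_index), so per-SCV
    results do not depend on processing order.
    """
    cfg = cfg or BootstrapConfig()
    S = _standardise_rows(S)
    K, V = S.shape
    if V < K:
        raise ValueError("need at least as many samples as datasets (V >= K)")
    cov = scv_covariance(S)
    rng = substream(cfg.seed, "bootstrap", scv_index)
    boot = _bootstrap_eigenvalues(S, cfg.B, rng)     # (B, K) descending

    T_hat = cov.eigenvalues - 1.0
    T_star = np.sort(boot - cov.eigenvalues[None, :], axis=0)
    thresholds = T_star[cfg.eta - 1, :]
    epsilon = (T_hat >= thresholds).astype(int)
    return EigCountResult(
        d_hat=int(epsilon.sum()),
        epsilon=epsilon,
        T_hat=T_hat,
        thresholds=thresholds,
        cov=cov,
        config=cfg,
    )


def ev_count(cov: CovEstimate | np.ndarray) -> int:
    """Baseline: directly count eigenvalues strictly greater than 1."""
    lam = cov.eigenvalues if isinstance(cov, CovEstimate) else np.linalg.eigvalsh(cov)
    return int(np.sum(lam > 1.0))


def classify_scvs(d_hats: list[int]) -> tuple[list[int], list[int]]:
    """Split SCV indices (0-based) into common (d̂=1) and structured (d̂>1).

    SCVs with d̂ = 0 look like identity-covariance (fully uncorrelated)
    components; they carry no relationship information and are excluded from
    both sets with a warning.
    """
    common = [r for r, d in enumerate(d_hats) if d == 1]
    structured = [r for r, d in enumerate(d_hats) if d > 1]
    zeros = [r for r, d in enumerate(d_hats) if d == 0]
    if zeros:
        warnings.warn(
            f"SCVs {zeros} have d_hat = 0 (identity-like covariance); "
            "excluded from both the common and structured sets",
            stacklevel=2,
        )
    return common, structured
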