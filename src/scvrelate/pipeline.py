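"""End-to-end orchestration of the three-step method.

Step 1 estimates latent sources with IVA (multi-restart, consistency
selected); Step 2 classifies each SCV as common or structured by
bootstrap-counting eigenvalues greater than 1 of its covariance; Step 3
clusters the datasets on the structured SCVs' leading eigenvectors.  An
optional per-dataset PCA reduces raw I x J inputs to R x J before Step 1.

All randomness flows from one master seed through named substreams
(simulation, each IVA restart, each per-SCV bootstrap), making full runs
bit-reproducible and stage results independent of execution order.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import eigcount, iva, relate, simgen
from ._streams import substream

__all__ = [
    "PipelineConfig",
    "RunReport",
    "pca_reduce",
    "run_pipeline",
    "complexity_estimate",
    "save_mixture",
    "load_mixture",
    "load_observations",
]

logger = logging.getLogger("scvrelate")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full pipeline run.

    Defaults follow the method's standard operating point: 20 IVA restarts,
    B = 1000 bootstrap resamples, Pfa = 0.05, Ward linkage.  ``R`` triggers
    PCA reduction when the input dimension exceeds it; leave it None for
    data already at the source dimension.
    """

    R: int | None = None
    n_runs: int = 20
    B: int = 1000
    Pfa: float = 0.05
    linkage_method: str = "ward"
    n_clusters: int | None = None
    seed: int = 0
    max_iter: int = 1024
    tol: float = 1e-6
    skip_iva: bool = False

    def __post_init__(self) -> None:
        # validates B / Pfa / eta up front so misconfiguration fails fast
        eigcount.BootstrapConfig(B=self.B, Pfa=self.Pfa, seed=self.seed)
        if self.n_runs < 1:
            raise ValueError("n_runs must be at least 1")

    def test_config(self) -> eigcount.BootstrapConfig:
        return eigcount.BootstrapConfig(
            B=self.B, Pfa=self.Pfa, seed=int(substream(self.seed, "bootstrap").integers(2**31))
        )


@dataclass
class RunReport:
    """Everything needed to interpret — and bit-identically re-run — a run."""

    config: PipelineConfig
    d_hat: list[int]
    common: list[int]
    structured: list[int]
    labels: list[int] | None
    ami: float | None
    linkage: np.ndarray | None
    newick: str | None
    timings: dict[str, float] = field(default_factory=dict)
    selected_run: int | None = None
    joint_isi: float | None = None

    def to_json(self) -> str:
        payload = {
            "seed": self.config.seed,
            "n_runs": self.config.n_runs,
            "B": self.config.B,
            "Pfa": self.config.Pfa,
            "linkage_method": self.config.linkage_method,
            "d_hat": self.d_hat,
            "common": self.common,
            "structured": self.structured,
            "labels": self.labels,
            "ami": self.ami,
            "newick": self.newick,
            "timings": {k: round(v, 3) for k, v in self.timings.items()},
            "selected_run": self.selected_run,
            "joint_isi": self.joint_isi,
        }
        return json.dumps(payload, indent=1)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def pca_reduce(X: list[np.ndarray], R: int) -> list[np.ndarray]:
    """Reduce each dataset independently to its top R principal components.

    Rows are centred, then projected onto the R leading left singular
    vectors; the output is R x J per dataset.  The retained variance
    fraction per dataset is logged.
    """
    out = []
    for k, Xk in enumerate(X):
        Xk = np.asarray(Xk, dtype=float)
        I = Xk.shape[0]
        if R > min(Xk.shape):
            raise ValueError(f"R={R} exceeds the rank bound of dataset {k} {Xk.shape}")
        Xc = Xk - Xk.mean(axis=1, keepdims=True)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        if s[R - 1] <= s[0] * 1e-12:
            raise ValueError(f"R={R} exceeds the numerical rank of dataset {k}")
        retained = float(np.sum(s[:R] ** 2) / np.sum(s**2))
        logger.info("pca: dataset %d %s -> %d dims, variance retained %.4f",
                    k, Xk.shape, R, retained)
        out.append(U[:, :R].T @ Xc)
    return out


# ---------------------------------------------------------------------------
# stages (runnable in isolation)
# ---------------------------------------------------------------------------

def estimate_sources(X: list[np.ndarray], cfg: PipelineConfig) -> iva.RunEnsemble:
    """Step 1: multi-restart IVA with consistency selection."""
    return iva.run_ensemble(
        X, n_runs=cfg.n_runs, seed=cfg.seed, max_iter=cfg.max_iter, tol=cfg.tol
    )


def count_blocks(
    sources: list[np.ndarray], cfg: PipelineConfig
) -> list[eigcount.EigCountResult]:
    """Step 2: bootstrap-count eigenvalues > 1 for every SCV."""
    tc = cfg.test_config()
    return [eigcount.bootstrap_count(S, tc, scv_index=r) for r, S in enumerate(sources)]


def infer_structure(
    counts: list[eigcount.EigCountResult],
    cfg: PipelineConfig,
    labels_true: np.ndarray | None = None,
) -> tuple[relate.RelationshipStructure, list[int], list[int]]:
    """Step 3: eigenvector features + Ward clustering of the datasets."""
    d_hats = [c.d_hat for c in counts]
    common, structured = eigcount.classify_scvs(d_hats)
    if not structured:
        raise RuntimeError(
            "no structured SCVs were found (all d_hat <= 1); the relationship "
            "structure is undefined — check the data or lower Pfa/B settings"
        )
    feats = relate.build_features(
        [counts[r].cov for r in structured],
        [counts[r].d_hat for r in structured],
        scv_indices=structured,
    )
    rs = relate.cluster(
        feats,
        linkage_method=cfg.linkage_method,
        n_clusters=cfg.n_clusters,
        labels_true=labels_true,
    )
    return rs, common, structured


def run_pipeline(
    cfg: PipelineConfig,
    X: list[np.ndarray] | None = None,
    design: simgen.ScvDesign | None = None,
    labels_true: np.ndarray | None = None,
    mixing: list[np.ndarray] | None = None,
) -> RunReport:
    """Run the three steps end to end on data or on a simulation design.

    Exactly one of ``X`` (observed datasets) or ``design`` (simulate first)
    must be given.  With a design, ground-truth labels default to the
    design's and the selected run's joint-ISI against the true mixing is
    reported.
    """
    if (X is None) == (design is None):
        raise ValueError("provide exactly one of X or design")

    timings: dict[str, float] = {}
    truth_mixing = None
    if design is not None:
        t0 = time.perf_counter()
        mixture = simgen.simulate(design, seed=cfg.seed, mixing=mixing)
        X = mixture.observations
        truth_mixing = mixture.mixing
        if labels_true is None:
            labels_true = np.asarray(design.true_labels)
        timings["simulate"] = time.perf_counter() - t0
        logger.info("simulate: R=%d K=%d V=%d (%.2fs)",
                    design.R, design.K, design.V, timings["simulate"])

    assert X is not None
    X = [np.asarray(x, dtype=float) for x in X]
    if cfg.R is not None and X[0].shape[0] > cfg.R:
        t0 = time.perf_counter()
        X = pca_reduce(X, cfg.R)
        timings["pca"] = time.perf_counter() - t0

    selected = None
    jisi = None
    if cfg.skip_iva:
        # test/diagnostic path: treat inputs as already-separated sources
        R, V = X[0].shape
        sources = [np.stack([Xk[r] for Xk in X]) for r in range(R)]
    else:
        t0 = time.perf_counter()
        ens = estimate_sources(X, cfg)
        timings["iva"] = time.perf_counter() - t0
        best = ens.best
        selected = ens.selected
        sources = best.sources
        if truth_mixing is not None:
            jisi = iva.joint_isi(best.demixing, truth_mixing)
        logger.info("iva: %d runs, selected %d, converged=%s (%.2fs)",
                    cfg.n_runs, ens.selected, best.converged, timings["iva"])

    t0 = time.perf_counter()
    counts = count_blocks(sources, cfg)
    timings["bootstrap"] = time.perf_counter() - t0
    d_hats = [c.d_hat for c in counts]
    logger.info("bootstrap: d_hat=%s (%.2fs)", d_hats, timings["bootstrap"])

    t0 = time.perf_counter()
    rs, common, structured = infer_structure(counts, cfg, labels_true=labels_true)
    timings["cluster"] = time.perf_counter() - t0
    logger.info("cluster: labels=%s ami=%s (%.2fs)",
                rs.labels.tolist(), rs.ami, timings["cluster"])

    return RunReport(
        config=cfg,
        d_hat=d_hats,
        common=common,
        structured=structured,
        labels=rs.labels.tolist(),
        ami=rs.ami,
        linkage=rs.linkage,
        newick=relate.to_newick(rs),
        timings=timings,
        selected_run=selected,
        joint_isi=jisi,
    )


def complexity_estimate(R: int, K: int, V: int, I: int, B: int) -> float:
    """Planning figure for the dominant operation count, R K^2 V (I K + B).

    I is the expected IVA iteration count and B the bootstrap resamples;
    logged before long runs to set expectations.
    """
    return float(R * K**2 * V * (I * K + B))


# ---------------------------------------------------------------------------
# I/O: HDF5 container and delimited text
# ---------------------------------------------------------------------------

def save_mixture(path: str | Path, mixture: simgen.GroundTruthMixture) -> None:
    """Write observations and ground truth to an HDF5 container.

    Layout: /obs/<k>, /mix/<k>, /scv/<r>, /truth/d, /truth/labels, plus the
    design JSON as a root attribute.
    """
    import h5py

    with h5py.File(path, "w") as f:
        for k, Xk in enumerate(mixture.observations):
            f.create_dataset(f"obs/{k}", data=Xk)
        for k, Ak in enumerate(mixture.mixing):
            f.create_dataset(f"mix/{k}", data=Ak)
        for r, Sr in enumerate(mixture.sources):
            f.create_dataset(f"scv/{r}", data=Sr)
        f.create_dataset("truth/d", data=np.asarray(mixture.design.true_d))
        f.create_dataset("truth/labels", data=np.asarray(mixture.design.true_labels))
        f.attrs["design"] = mixture.design.to_json()


def load_mixture(path: str | Path) -> simgen.GroundTruthMixture:
    """Read a mixture written by :func:`save_mixture`."""
    import h5py

    with h5py.File(path, "r") as f:
        obs = [f[f"obs/{k}"][()] for k in sorted(f["obs"], key=int)]
        mixing = [f[f"mix/{k}"][()] for k in sorted(f["mix"], key=int)]
        sources = [f[f"scv/{r}"][()] for r in sorted(f["scv"], key=int)]
        design = simgen.ScvDesign.from_json(f.attrs["design"])
    return simgen.GroundTruthMixture(
        sources=sources, mixing=mixing, observations=obs, design=design
    )


def load_observations(path: str | Path) -> list[np.ndarray]:
    """Load K datasets from an HDF5 container or a directory of delimited
    text files (one matrix per file, rows = dimensions, columns = samples;
    files are ordered by name)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".csv", ".tsv", ".txt"}
        )
        if not files:
            raise FileNotFoundError(f"no .csv/.tsv/.txt files in {path}")
        out = []
        for p in files:
            delim = "\t" if p.suffix.lower() == ".tsv" else ","
            out.append(np.loadtxt(p, delimiter=delim, ndmin=2))
        return out
    import h5py

    with h5py.File(path, "r") as f:
        return [f[f"obs/{k}"][()] for k in sorted(f["obs"], key=int)]
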