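"""Sequential path models with bias-corrected bootstrap inference.

A path model is a DAG over ordered variables (canonically CPV -> VR -> VV ->
ABETA -> TAU).  Each node with parents is regressed, standardized, on its
parents plus the covariates; an indirect effect is the product of the edge
coefficients along a directed path of length >= 2 from an exposure to the
terminal outcome.  Indirect effects are assessed with bias-corrected (BC)
percentile bootstrap confidence intervals: participants are resampled with
replacement, the whole path model is refit per resample, and the interval
endpoints are the bootstrap quantiles at Phi(2*z0 +/- z_{1-alpha/2}) where
z0 = Phi^{-1}(fraction of bootstrap estimates below the point estimate).
Significance is declared when the interval excludes zero.

The bootstrap resamples whole participant rows (preserving the joint
covariate distribution); BC (not BCa) is used, i.e. no acceleration term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PathModelSpec",
    "MediationResult",
    "IndirectEffect",
    "fit_path_model",
    "indirect_effects",
    "bootstrap_ci",
    "PRESETS",
]

#: Map model node names to default cohort-table columns.
DEFAULT_COLUMNS = {
    "CPV": "latent_cpv",
    "VR": "latent_vr_amyloid",
    "VV": "latent_vv",
    "ABETA": "latent_abeta",
    "TAU": "latent_tau",
}


@dataclass(frozen=True)
class PathModelSpec:
    """Declared DAG of standardized linear regressions.

    ``edges`` must respect ``ordered_nodes`` (acyclic by construction).  The
    terminal outcome is the last ordered node that appears in any edge.
    """

    ordered_nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    covariates: tuple[str, ...] = ("age", "sex", "apoe4", "icv")
    n_boot: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    columns: dict = field(default_factory=lambda: dict(DEFAULT_COLUMNS))

    def __post_init__(self) -> None:
        order = {n: i for i, n in enumerate(self.ordered_nodes)}
        for s, t in self.edges:
            if s not in order or t not in order:
                raise ValueError(f"edge endpoint not in ordered_nodes: {s}->{t}")
            if order[s] >= order[t]:
                raise ValueError(f"edge {s}->{t} violates node order (cycle risk)")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")

    @property
    def terminal(self) -> str:
        targets = {t for _, t in self.edges}
        return [n for n in self.ordered_nodes if n in targets][-1]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.ordered_nodes)
        g.add_edges_from(self.edges)
        return g


#: Two literature-standard sequential topologies: ventricular volume mediating the
#: choroid-plexus / ventricular-radioactivity effects on amyloid, and
#: amyloid mediating all ventricular parameters' effects on tau.
PRESETS = {
    "vv_mediates_amyloid": PathModelSpec(
        ordered_nodes=("CPV", "VR", "VV", "ABETA"),
        edges=(
            ("CPV", "VR"),
            ("CPV", "VV"),
            ("VR", "VV"),
            ("CPV", "ABETA"),
            ("VR", "ABETA"),
            ("VV", "ABETA"),
        ),
    ),
    "abeta_mediates_tau": PathModelSpec(
        ordered_nodes=("CPV", "VR", "VV", "ABETA", "TAU"),
        edges=(
            ("CPV", "VR"),
            ("CPV", "VV"),
            ("VR", "VV"),
            ("CPV", "ABETA"),
            ("VR", "ABETA"),
            ("VV", "ABETA"),
            ("CPV", "TAU"),
            ("VV", "TAU"),
            ("ABETA", "TAU"),
        ),
    ),
}


@dataclass(frozen=True)
class IndirectEffect:
    path: tuple[str, ...]
    estimate: float
    bc_ci95: tuple[float, float] | None = None
    significant: bool | None = None


@dataclass
class MediationResult:
    path_coefficients: dict
    indirect_effects: list[IndirectEffect]
    direct_effects: dict
    n_boot_used: int
    n_resamples_rejected: int = 0


def _design_block(data: np.ndarray) -> np.ndarray:
    """Standardize columns (centre-only for binary) and prepend an intercept."""
    out = np.empty((data.shape[0], data.shape[1] + 1))
    out[:, 0] = 1.0
    for j in range(data.shape[1]):
        x = data[:, j]
        sd = x.std(ddof=1)
        if sd == 0:
            raise np.linalg.LinAlgError("constant column in path-model design")
        if np.unique(x).size <= 2:
            out[:, j + 1] = x - x.mean()
        else:
            out[:, j + 1] = (x - x.mean()) / sd
    return out


def _fit_paths_array(M: np.ndarray, C: np.ndarray, node_ix: dict, parents: dict) -> dict:
    """Fit every node-on-parents regression; M holds node columns, C covariates."""
    coefs = {}
    for node, pars in parents.items():
        if not pars:
            continue
        y = M[:, node_ix[node]]
        sd = y.std(ddof=1)
        if sd == 0:
            raise np.linalg.LinAlgError(f"node {node} is constant")
        y = (y - y.mean()) / sd
        X = np.column_stack([M[:, node_ix[p]] for p in pars])
        X = _design_block(np.column_stack([X, C]) if C.size else X)
        beta, res, rank, sv = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise np.linalg.LinAlgError(f"rank-deficient design for node {node}")
        for k, p in enumerate(pars):
            coefs[(p, node)] = float(beta[k + 1])
    return coefs


def _extract_arrays(cohort: pd.DataFrame, spec: PathModelSpec):
    cols = [spec.columns.get(n, n) for n in spec.ordered_nodes]
    missing = [c for c in cols + list(spec.covariates) if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table lacks columns: {missing}")
    sub = cohort[cols + list(spec.covariates)].dropna()
    M = sub[cols].to_numpy(dtype=float)
    # standardize node columns once; per-resample restandardization happens in
    # _fit_paths_array via the y/X scaling
    C = sub[list(spec.covariates)].to_numpy(dtype=float) if spec.covariates else np.empty((len(sub), 0))
    node_ix = {n: i for i, n in enumerate(spec.ordered_nodes)}
    parents = {n: [s for s, t in spec.edges if t == n] for n in spec.ordered_nodes}
    return M, C, node_ix, parents


def fit_path_model(cohort: pd.DataFrame, spec: PathModelSpec) -> dict:
    """Standardized path coefficients for every declared edge.

    Each node with parents is regressed on all its parents plus the
    covariates; the returned dict maps (source, target) to the standardized
    partial coefficient.
    """
    M, C, node_ix, parents = _extract_arrays(cohort, spec)
    n_par = max((len(p) for p in parents.values()), default=0) + len(spec.covariates)
    if len(M) <= n_par + 5:
        raise ValueError(f"n={len(M)} too small for {n_par} parameters")
    return _fit_paths_array(M, C, node_ix, parents)


def indirect_effects(coefficients: dict, spec: PathModelSpec) -> list[IndirectEffect]:
    """All product-of-coefficients indirect effects.

    Enumerates every directed path of length >= 2 from each non-terminal
    node to the terminal outcome and multiplies the coefficients along it.
    """
    g = spec.graph()
    term = spec.terminal
    out = []
    for src in spec.ordered_nodes:
        if src == term:
            continue
        for path in nx.all_simple_paths(g, src, term):
            if len(path) < 3:
                continue
            est = 1.0
            for a, b in zip(path[:-1], path[1:]):
                est *= coefficients[(a, b)]
            out.append(IndirectEffect(path=tuple(path), estimate=float(est)))
    return out


def _bc_interval(boot: np.ndarray, point: float, alpha: float) -> tuple[float, float]:
    B = len(boot)
    frac = np.clip(np.mean(boot < point), 1.0 / (B + 1), B / (B + 1.0))
    z0 = norm.ppf(frac)
    za = norm.ppf(1.0 - alpha / 2.0)
    lo_q = norm.cdf(2.0 * z0 - za)
    hi_q = norm.cdf(2.0 * z0 + za)
    return float(np.quantile(boot, lo_q)), float(np.quantile(boot, hi_q))


def bootstrap_ci(cohort: pd.DataFrame, spec: PathModelSpec, n_boot: int | None = None) -> MediationResult:
    """Fit the path model and attach BC bootstrap CIs to every indirect and
    direct (edge) effect.

    Resamples yielding a rank-deficient design are rejected and redrawn;
    more than 5% rejections triggers a warning.  Reproducible via
    ``spec.seed``.
    """
    n_boot = spec.n_boot if n_boot is None else int(n_boot)
    M, C, node_ix, parents = _extract_arrays(cohort, spec)
    n = len(M)
    point_coefs = fit_path_model(cohort, spec)
    point_ind = indirect_effects(point_coefs, spec)
    edges = list(point_coefs)
    paths = [e.path for e in point_ind]

    rng = np.random.default_rng(spec.seed)
    boot_edges = np.empty((n_boot, len(edges)))
    rejected = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, n)
        try:
            co = _fit_paths_array(M[idx], C[idx] if C.size else C, node_ix, parents)
        except np.linalg.LinAlgError:
            rejected += 1
            if rejected > 50 * max(n_boot, 1):
                raise RuntimeError("bootstrap cannot find full-rank resamples")
            continue
        boot_edges[b] = [co[e] for e in edges]
        b += 1
    if rejected > 0.05 * n_boot:
        warnings.warn(
            f"{rejected} bootstrap resamples rejected for rank deficiency", stacklevel=2
        )

    edge_col = {e: j for j, e in enumerate(edges)}
    results = []
    for eff in point_ind:
        prod = np.ones(n_boot)
        for a_, b_ in zip(eff.path[:-1], eff.path[1:]):
            prod *= boot_edges[:, edge_col[(a_, b_)]]
        lo, hi = _bc_interval(prod, eff.estimate, spec.alpha)
        results.append(
            IndirectEffect(
                path=eff.path,
                estimate=eff.estimate,
                bc_ci95=(lo, hi),
                significant=bool(lo > 0 or hi < 0),
            )
        )
    direct = {}
    for e in edges:
        lo, hi = _bc_interval(boot_edges[:, edge_col[e]], point_coefs[e], spec.alpha)
        direct[e] = (point_coefs[e], (lo, hi))
    return MediationResult(
        path_coefficients=point_coefs,
        indirect_effects=results,
        direct_effects=direct,
        n_boot_used=n_boot,
        n_resamples_rejected=rejected,
    )
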