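"""Robust ICA decomposition of the ATS transcriptome into iModulons.

The expression matrix (genes x conditions, log scale) is centered on a
reference condition (the unevolved wild type), reduced by PCA to the
dimensionality holding 99% of variance, and decomposed with FastICA from
many seeded restarts.  Components are pooled across restarts, clustered by
absolute Pearson correlation of their gene-weight vectors, and only cluster
centroids reproduced in at least half of the restarts are kept — the usual
guard against FastICA's run-to-run instability.  Each robust component's
high-weight gene set (an iModulon) is extracted with a 3-sigma rule applied
twice (once after trimming the first round of outliers).

Correlation analyses use tie-corrected Spearman throughout: transcriptome
similarity among evolved replicate endpoints, similarity of evolved
endpoints to their unevolved ancestor, and association of iModulon
activities with the ordinal aero-type class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import spearmanr
from sklearn.decomposition import PCA, FastICA

logger = logging.getLogger("aerotype")

RETAINED_VARIANCE = 0.99
DEFAULT_RESTARTS = 50
#: components from different restarts belong together above this |Pearson r|
CLUSTER_CORRELATION = 0.7
#: a component is robust if reproduced in at least this fraction of restarts
MIN_RESTART_FRACTION = 0.5
MEMBERSHIP_SIGMA = 3.0


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame                  # genes x conditions
    reference_condition: str | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ICAResult:
    S: pd.DataFrame                       # genes x components
    A: pd.DataFrame                       # components x conditions
    k: int
    imodulons: dict[str, set[str]]
    restarts_used: int
    empty_components: list[str] = field(default_factory=list)


@dataclass
class CorrelationReport:
    endpoint_replicate_rho: dict[str, float | None]
    pre_post_rho: dict[str, float | None]
    activity_vs_aerotype_rho: dict[str, tuple[float | None, int]]


# ---------------------------------------------------------------------------
# centering
# ---------------------------------------------------------------------------

def center_to_reference(matrix: pd.DataFrame | ExpressionMatrix,
                        reference: str) -> ExpressionMatrix:
    """Subtract the reference condition's column from every column."""
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if reference not in df.columns:
        raise KeyError(f"reference condition {reference!r} not in matrix")
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    centered = df.sub(df[reference], axis=0)
    return ExpressionMatrix(values=centered, reference_condition=reference)


# ---------------------------------------------------------------------------
# robust ICA
# ---------------------------------------------------------------------------

def _fix_signs(S: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude weight is positive."""
    S = S.copy()
    for j in range(S.shape[1]):
        i = np.argmax(np.abs(S[:, j]))
        if S[i, j] < 0:
            S[:, j] = -S[:, j]
    return S


def run_robust_ica(
    matrix: pd.DataFrame | ExpressionMatrix,
    k_max: int = 8,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    retained_variance: float = RETAINED_VARIANCE,
) -> ICAResult:
    """Restart-clustered FastICA; deterministic for a fixed seed.

    Raises if no component survives the reproducibility filter.
    """
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    X = df.to_numpy(dtype=float)
    n_genes, n_cond = X.shape
    if n_cond < 3:
        raise ValueError("need at least 3 conditions for ICA")
    if k_max >= min(n_genes, n_cond):
        raise ValueError("k_max must be below min(genes, conditions)")

    pca = PCA(n_components=min(k_max, n_cond - 1), random_state=0)
    pca.fit(X.T)                       # conditions as samples
    cum = np.cumsum(pca.explained_variance_ratio_)
    k_dim = int(np.searchsorted(cum, retained_variance) + 1)
    k_dim = max(1, min(k_dim, k_max))

    rng = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(n_restarts)]
    pool: list[np.ndarray] = []
    pool_run: list[int] = []
    import warnings as _warnings
    for run, s in enumerate(child_seeds):
        ica = FastICA(n_components=k_dim, random_state=s,
                      whiten="unit-variance", max_iter=5000, tol=1e-5)
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")   # per-restart convergence noise
                S_run = ica.fit_transform(X)       # genes x k_dim
        except Exception:                          # bad restart
            continue
        for j in range(S_run.shape[1]):
            col = S_run[:, j]
            norm = np.linalg.norm(col)
            if norm > 0:
                pool.append(col / norm)
                pool_run.append(run)
    if not pool:
        raise RuntimeError("ICA failed to converge in every restart")

    P = np.array(pool)                     # n_components_total x genes
    # cluster pooled components by absolute correlation distance
    C = np.corrcoef(P)
    D = 1.0 - np.abs(C)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2, 0.0, 2.0)
    if len(P) == 1:
        labels = np.array([1])
    else:
        condensed = D[np.triu_indices(len(P), k=1)]
        labels = fcluster(linkage(condensed, method="average"),
                          t=1.0 - CLUSTER_CORRELATION, criterion="distance")

    centroids = []
    n_runs_effective = len(set(pool_run))
    for lab in sorted(set(labels)):
        idx = np.where(labels == lab)[0]
        runs = {pool_run[i] for i in idx}
        if len(runs) / n_runs_effective < MIN_RESTART_FRACTION:
            continue
        ref = P[idx[0]]
        members = [P[i] * np.sign(P[i] @ ref or 1.0) for i in idx]
        centroid = np.mean(members, axis=0)
        norm = np.linalg.norm(centroid)
        if norm > 0:
            centroids.append(centroid / norm)
    if not centroids:
        raise RuntimeError(
            "no component reproduced in >= 50% of restarts; lower k_max")

    S = _fix_signs(np.array(centroids).T)  # genes x k
    # activities by least squares against the per-condition-centered matrix
    # (the decomposition models deviations, not the condition means)
    Xc = X - X.mean(axis=0, keepdims=True)
    A, *_ = np.linalg.lstsq(S, Xc, rcond=None)
    comp_ids = [f"IM{j+1:02d}" for j in range(S.shape[1])]
    S_df = pd.DataFrame(S, index=df.index, columns=comp_ids)
    A_df = pd.DataFrame(A, index=comp_ids, columns=df.columns)

    imodulons = threshold_memberships(S_df)
    empty = [c for c, members in imodulons.items() if not members]
    if empty:
        logger.warning("components with empty membership: %s", empty)
    return ICAResult(S=S_df, A=A_df, k=S.shape[1], imodulons=imodulons,
                     restarts_used=n_runs_effective, empty_components=empty)


def threshold_memberships(S: pd.DataFrame,
                          sigma: float = MEMBERSHIP_SIGMA) -> dict[str, set[str]]:
    """Member genes per component: |weight| > mean + sigma*std, re-estimated
    once after removing the first round of outliers."""
    out: dict[str, set[str]] = {}
    for comp in S.columns:
        w = S[comp].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError(f"non-finite weights in component {comp}")
        if np.std(w) == 0:
            out[comp] = set()
            continue
        absw = np.abs(w)
        # one robust trim round: excise provisional outliers around the
        # median (a member block can hold >10% of genes, which would inflate
        # a plain standard deviation enough to hide the block from itself),
        # then apply the mean + 3*sigma rule to the remaining background
        med = np.median(w)
        mad = np.median(np.abs(w - med))
        first = np.abs(w - med) > sigma * 1.4826 * mad
        rest = w[~first]
        if rest.size and np.std(rest) > 0:
            thr = np.mean(rest) + sigma * np.std(rest)
        else:
            thr = float(np.max(np.abs(rest))) if rest.size else 0.0
        # relative floor guards the noise-free limit, where the background
        # is numerically zero and any junk weight would otherwise qualify
        members = absw > max(thr, 0.05 * absw.max())
        out[comp] = set(S.index[members])
    return out


# ---------------------------------------------------------------------------
# correlation analyses
# ---------------------------------------------------------------------------

def _spearman(x, y) -> float | None:
    if len(x) < 3:
        return None
    rho = spearmanr(x, y).statistic
    return None if np.isnan(rho) else float(rho)


def _mean_pairwise_rho(cols: list[np.ndarray]) -> float | None:
    rhos = [_spearman(a, b) for a, b in combinations(cols, 2)]
    rhos = [r for r in rhos if r is not None]
    return float(np.mean(rhos)) if rhos else None


def correlate(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    activities: pd.DataFrame | None = None,
    aerotype_classes: dict[str, int] | None = None,
) -> CorrelationReport:
    """Spearman correlation report over the study design.

    ``metadata`` columns: condition, variant, replicate, phase (one of
    unevolved / evolved / wt).  Endpoint-replicate rho is the mean pairwise
    correlation among a variant's evolved columns; pre/post rho the mean
    correlation of each evolved column with the variant's unevolved column.
    If ``activities`` (components x conditions) and per-condition aero-type
    classes are given, each component's activity is correlated against the
    ordinal class.
    """
    meta = metadata.set_index("condition") if "condition" in metadata.columns else metadata
    endpoint: dict[str, float | None] = {}
    prepost: dict[str, float | None] = {}
    for variant in sorted(meta.loc[meta["phase"] != "wt", "variant"].unique()):
        rows = meta[meta["variant"] == variant]
        evolved = [c for c in rows[rows["phase"] == "evolved"].index
                   if c in expression.columns]
        unevolved = [c for c in rows[rows["phase"] == "unevolved"].index
                     if c in expression.columns]
        cols = [expression[c].to_numpy() for c in evolved]
        endpoint[variant] = _mean_pairwise_rho(cols)
        if unevolved:
            ref = expression[unevolved[0]].to_numpy()
            rhos = [_spearman(ref, c) for c in cols]
            rhos = [r for r in rhos if r is not None]
            prepost[variant] = float(np.mean(rhos)) if rhos else None
        else:
            prepost[variant] = None

    activity_rho: dict[str, tuple[float | None, int]] = {}
    if activities is not None and aerotype_classes:
        conds = [c for c in activities.columns if c in aerotype_classes]
        classes = np.array([aerotype_classes[c] for c in conds])
        for comp in activities.index:
            act = activities.loc[comp, conds].to_numpy(dtype=float)
            rho = _spearman(act, classes)
            sign = 0 if rho is None else int(np.sign(rho))
            activity_rho[comp] = (rho, sign)
    return CorrelationReport(
        endpoint_replicate_rho=endpoint,
        pre_post_rho=prepost,
        activity_vs_aerotype_rho=activity_rho,
    )
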