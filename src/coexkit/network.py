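"""Signed weighted co-expression network construction and module detection.

The construction chain is: robust correlation (biweight midcorrelation) ->
signed soft-threshold adjacency -> topological overlap -> average-linkage
hierarchical clustering with a static height cut and minimum module size ->
module eigengenes / kME -> eigengene-similarity module merging.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .types import (
    ExpressionMatrix,
    InputError,
    NetworkConfig,
    NetworkModel,
)

__all__ = [
    "bicor",
    "bicor_matrix",
    "signed_adjacency",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "kme_table",
    "merge_modules",
    "build_network",
]


# ---------------------------------------------------------------------------
# Biweight midcorrelation
# ---------------------------------------------------------------------------

def _bicor_standardize(X: np.ndarray) -> np.ndarray:
    """Per-row biweight standardization of a variables x observations array.

    Returns rows scaled so that the dot product of two rows is their biweight
    midcorrelation.  Rows with zero MAD fall back to Pearson standardization
    (mean-centering).  Constant rows come back as all-NaN.
    """
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    dev = X - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    fallback = (mad == 0).ravel()

    with np.errstate(divide="ignore", invalid="ignore"):
        u = dev / (9.0 * mad)
    u[fallback] = 0.0
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    a = dev * w

    if fallback.any():
        # Pearson standardization for zero-MAD rows only.
        xb = X[fallback]
        a[fallback] = xb - xb.mean(axis=1, keepdims=True)

    norm = np.sqrt((a ** 2).sum(axis=1, keepdims=True))
    constant = (norm == 0).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        out = a / norm
    out[constant] = np.nan
    return out


def bicor(x, y) -> float:
    """Biweight midcorrelation of two equal-length vectors.

    Weights are the Tukey biweight around the median with the conventional
    9*MAD scale; a vector whose MAD is zero is correlated Pearson-style.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise InputError("bicor requires two 1-d vectors of equal length")
    if x.size < 3:
        raise InputError("bicor requires length >= 3")
    sx = _bicor_standardize(x[None, :])[0]
    sy = _bicor_standardize(y[None, :])[0]
    if np.isnan(sx).all() and np.isnan(sy).all():
        raise InputError("bicor undefined: both vectors are constant")
    if np.isnan(sx).all() or np.isnan(sy).all():
        raise InputError("bicor undefined: constant vector")
    r = float(sx @ sy)
    return float(np.clip(r, -1.0, 1.0))


def bicor_matrix(X: np.ndarray) -> np.ndarray:
    """All-pairs biweight midcorrelation of the rows of ``X``.

    Constant rows yield NaN rows/columns (diagonal forced to 1 elsewhere).
    """
    S = _bicor_standardize(np.asarray(X, dtype=float))
    C = S @ S.T
    np.clip(C, -1.0, 1.0, out=C)
    ok = ~np.isnan(S).any(axis=1)
    np.fill_diagonal(C, np.where(ok, 1.0, np.nan))
    return C


def pearson_matrix(X: np.ndarray) -> np.ndarray:
    """All-pairs Pearson correlation of the rows of ``X`` (NaN for constants)."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc ** 2).sum(axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        S = Xc / norm
    C = S @ S.T
    np.clip(C, -1.0, 1.0, out=C)
    ok = (norm > 0).ravel()
    np.fill_diagonal(C, np.where(ok, 1.0, np.nan))
    return C


# ---------------------------------------------------------------------------
# Adjacency and soft-threshold selection
# ---------------------------------------------------------------------------

def signed_adjacency(C: np.ndarray, beta: float) -> np.ndarray:
    """Signed adjacency a_ij = ((1 + c_ij) / 2) ** beta with unit diagonal."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise InputError("correlation matrix must be square")
    diff = C - C.T
    if np.nanmax(np.abs(diff)) > 1e-10:
        raise InputError("correlation matrix must be symmetric")
    if np.nanmax(C) > 1 + 1e-9 or np.nanmin(C) < -1 - 1e-9:
        raise InputError("correlation entries must lie in [-1, 1]")
    A = ((1.0 + C) / 2.0) ** float(beta)
    np.fill_diagonal(A, 1.0)
    return A


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Bins log10(k) into equal-width bins, regresses log10(frequency) on
    log10(mean k per bin), and returns (signed R^2, slope).  R^2 is the squared
    Pearson correlation of the regression, negated when the slope is positive.
    Returns (nan, nan) for degenerate (near-constant) connectivities.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.isclose(k.max(), k.min()):
        return float("nan"), float("nan")
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max(), n_bins + 1)
    idx = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        xs.append(np.log10(np.mean(k[sel])))
        ys.append(np.log10(sel.sum() / k.size))
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    if xs.size < 3 or np.isclose(xs.std(), 0) or np.isclose(ys.std(), 0):
        return float("nan"), float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    slope = r * ys.std() / xs.std()
    r2 = r ** 2
    if slope > 0:
        r2 = -r2
    return float(r2), float(slope)


def pick_soft_threshold(
    C: np.ndarray,
    candidate_betas=(1, 2, 3, 4, 5, 5.5, 6, 7, 8, 10, 12, 14, 16, 18, 20),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Scale-free fit table over candidate powers.

    Returns a DataFrame with columns (beta, scale_free_r2, mean_connectivity,
    slope, recommended); ``recommended`` marks the smallest beta whose signed
    R^2 reaches ``r2_target`` (no row marked if none does).  Advisory only —
    callers fix beta in NetworkConfig.
    """
    C = np.asarray(C, dtype=float)
    if C.shape[0] < 50:
        warnings.warn("fewer than 50 genes: scale-free fit is unreliable")
    rows = []
    for beta in candidate_betas:
        A = signed_adjacency(C, beta)
        k = A.sum(axis=1) - 1.0
        r2, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {"beta": float(beta), "scale_free_r2": r2,
             "mean_connectivity": float(k.mean()), "slope": slope}
        )
    table = pd.DataFrame(rows)
    table["recommended"] = False
    ok = table["scale_free_r2"] >= r2_target
    if ok.any():
        table.loc[table.index[ok][0], "recommended"] = True
    return table


# ---------------------------------------------------------------------------
# Topological overlap
# ---------------------------------------------------------------------------

def tom_similarity(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1].

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; diagonal 1.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InputError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise InputError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-9:
        raise InputError("adjacency entries must lie in [0, 1]")
    n = A.shape[0]
    diag = np.diag(A).copy()
    # l_ij over u != i, j: remove the diagonal contributions from A @ A.
    L = A @ A
    L -= diag[:, None] * A
    L -= A * diag[None, :]
    k = A.sum(axis=1) - diag
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (L + A) / denom
    T[~np.isfinite(T)] = 0.0
    np.clip(T, 0.0, 1.0, out=T)
    T = (T + T.T) / 2.0
    np.fill_diagonal(T, 1.0)
    return T


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def _relabel_by_size(labels: np.ndarray, min_module_size: int) -> np.ndarray:
    """Zero out undersized clusters and renumber survivors 1..M by size desc.

    Ties in size break by the smallest original label, which is itself
    deterministic, so relabeling is reproducible.
    """
    out = np.zeros_like(labels, dtype=int)
    uniq, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = [(c, u) for u, c in zip(uniq, counts) if c >= min_module_size]
    keep.sort(key=lambda t: (-t[0], t[1]))
    for new, (_c, old) in enumerate(keep, start=1):
        out[labels == old] = new
    return out


def detect_modules(TOM: np.ndarray, config: NetworkConfig) -> np.ndarray:
    """Static-cut average-linkage module detection on 1 - TOM.

    The tree is cut at ``cut_height_fraction`` of the maximum merge height;
    clusters smaller than ``min_module_size`` get label 0; surviving clusters
    are labeled 1..M by decreasing size.
    """
    TOM = np.asarray(TOM, dtype=float)
    n = TOM.shape[0]
    if n < config.min_module_size:
        warnings.warn("fewer genes than min_module_size: all genes unassigned")
        return np.zeros(n, dtype=int)
    D = 1.0 - TOM
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    cut = config.cut_height_fraction * Z[:, 2].max()
    labels = fcluster(Z, t=cut, criterion="distance")
    return _relabel_by_size(labels, config.min_module_size)


# ---------------------------------------------------------------------------
# Eigengenes and kME
# ---------------------------------------------------------------------------

def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row z-scores (ddof=1); returns (standardized, keep-mask of non-constant)."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    Xs = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return Xs, keep


def module_eigengene(X: ExpressionMatrix, genes) -> tuple[np.ndarray, float]:
    """First-principal-component summary of a module's standardized expression.

    Returns (ME, variance_explained): per-sample PC1 scores scaled to unit
    variance (ddof=1), sign-aligned so the ME correlates non-negatively with
    the module's average standardized expression.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise InputError("module_eigengene requires at least 2 genes")
    missing = [g for g in genes if g not in X.data.index]
    if missing:
        raise InputError(f"genes absent from expression matrix: {missing}")
    M = X.data.loc[genes].to_numpy(dtype=float)
    Ms, keep = _standardize_rows(M)
    if keep.sum() < len(genes):
        warnings.warn(f"dropped {len(genes) - int(keep.sum())} constant gene rows")
    if Ms.shape[0] < 1:
        raise InputError("all module genes are constant")
    U, S, Vt = np.linalg.svd(Ms, full_matrices=False)
    me = Vt[0]
    var_explained = float(S[0] ** 2 / (S ** 2).sum())
    mean_profile = Ms.mean(axis=0)
    if me @ mean_profile < 0:
        me = -me
    sd = me.std(ddof=1)
    if sd > 0:
        me = me / sd
    return me, var_explained


def kme_table(X: ExpressionMatrix, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every gene with every module eigengene.

    Constant genes get NaN (explicit missing).
    """
    shared = [s for s in X.samples if s in eigengenes.columns]
    if not shared:
        raise InputError("no shared samples between expression and eigengenes")
    G = X.data[shared].to_numpy(dtype=float)
    E = eigengenes[shared].to_numpy(dtype=float)
    Gs, gkeep = _standardize_rows(G)
    Es, _ = _standardize_rows(E)
    n = len(shared)
    out = np.full((X.n_genes, E.shape[0]), np.nan)
    out[gkeep] = (Gs @ Es.T) / (n - 1)
    out = np.clip(out, -1.0, 1.0)
    return pd.DataFrame(out, index=X.genes, columns=eigengenes.index)


def hub_mask(kme: pd.DataFrame, assignment: pd.Series, threshold: float = 0.7) -> pd.Series:
    """Hub predicate: kME to own module positive, >= threshold, and maximal."""
    out = pd.Series(False, index=kme.index)
    for g in kme.index:
        m = int(assignment.get(g, 0))
        if m == 0 or m not in kme.columns:
            continue
        row = kme.loc[g]
        own = row[m]
        if np.isnan(own) or own < threshold:
            continue
        others = row.drop(m).dropna()
        if len(others) == 0 or own > others.max():
            out[g] = True
    return out


# ---------------------------------------------------------------------------
# Module merging by eigengene similarity
# ---------------------------------------------------------------------------

def _eigengene_frame(X: ExpressionMatrix, assignment: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    labels = sorted({int(l) for l in assignment if l > 0})
    mes, varexp = {}, {}
    for lab in labels:
        genes = assignment.index[assignment == lab]
        me, ve = module_eigengene(X, genes)
        mes[lab] = me
        varexp[lab] = ve
    if not mes:
        return (pd.DataFrame(columns=X.samples),
                pd.Series(dtype=float))
    E = pd.DataFrame(mes, index=X.samples).T
    E.index.name = "module"
    return E, pd.Series(varexp, name="variance_explained")


def merge_modules(X: ExpressionMatrix, assignment: pd.Series,
                  merge_height: float = 0.25) -> pd.Series:
    """Merge modules whose eigengenes cluster below ``merge_height`` in 1 - cor.

    Average-linkage on eigengene correlation dissimilarity; merged labels are
    renumbered by size; iterates to a fixpoint.
    """
    assignment = assignment.copy()
    for _ in range(20):
        E, _ = _eigengene_frame(X, assignment)
        if E.shape[0] < 2:
            return assignment
        C = pearson_matrix(E.to_numpy())
        D = 1.0 - C
        np.fill_diagonal(D, 0.0)
        D = np.maximum(D, 0.0)
        Z = linkage(squareform(D, checks=False), method="average")
        groups = fcluster(Z, t=merge_height, criterion="distance")
        if len(set(groups)) == E.shape[0]:
            return assignment
        label_of = dict(zip(E.index, groups))
        merged = assignment.map(lambda l: label_of.get(int(l), 0) if l > 0 else 0)
        arr = _relabel_by_size(merged.to_numpy(), min_module_size=1)
        assignment = pd.Series(arr, index=assignment.index)
    return assignment


# ---------------------------------------------------------------------------
# End-to-end construction
# ---------------------------------------------------------------------------

def _detect_block(Xv: np.ndarray, config: NetworkConfig) -> np.ndarray:
    C = bicor_matrix(Xv)
    C = np.nan_to_num(C, nan=0.0)
    np.fill_diagonal(C, 1.0)
    A = signed_adjacency(C, config.beta)
    T = tom_similarity(A)
    return detect_modules(T, config)


def _split_blocks(Xv: np.ndarray, max_block_size: int, n_genes: int) -> list[np.ndarray]:
    """Pre-cluster genes into correlation-coherent blocks of <= max_block_size.

    Projective k-means on row-standardized expression (cosine ~ correlation);
    oversized blocks are split round-robin, which keeps correlated genes
    mostly together while guaranteeing the size bound.
    """
    from sklearn.cluster import KMeans

    n_blocks = int(np.ceil(n_genes / max_block_size))
    Xs, keep = _standardize_rows(Xv)
    norms = np.sqrt((Xs ** 2).sum(axis=1, keepdims=True))
    proj = Xs / norms
    km = KMeans(n_clusters=n_blocks * 2, n_init=3, random_state=0).fit(proj)
    blocks: list[list[int]] = [[] for _ in range(n_blocks)]
    kept_idx = np.where(keep)[0]
    order = np.argsort(km.labels_, kind="stable")
    for pos, i in enumerate(order):
        blocks[pos * n_blocks // len(order)].append(int(kept_idx[i]))
    # Constant genes go to the first block (they stay unassigned anyway).
    for i in np.where(~keep)[0]:
        blocks[0].append(int(i))
    return [np.asarray(sorted(b), dtype=int) for b in blocks if b]


def build_network(X: ExpressionMatrix, config: NetworkConfig | None = None) -> NetworkModel:
    """Full pipeline: bicor -> adjacency -> TOM -> detect -> reassign -> merge.

    Expression larger than ``max_block_size`` genes is decomposed into
    correlation-coherent blocks, detected per block, then merged globally by
    eigengene similarity.
    """
    if config is None:
        config = NetworkConfig()
    Xv = X.values
    n = X.n_genes
    if n <= config.max_block_size:
        labels = _detect_block(Xv, config)
    else:
        labels = np.zeros(n, dtype=int)
        offset = 0
        for block in _split_blocks(Xv, config.max_block_size, n):
            bl = _detect_block(Xv[block], config)
            bl[bl > 0] += offset
            offset = max(offset, bl.max() if bl.size else 0)
            labels[block] = bl
        labels = _relabel_by_size(labels, config.min_module_size)

    assignment = pd.Series(labels, index=X.genes, name="module")

    if assignment.max() >= 1:
        assignment = merge_modules(X, assignment, config.merge_height)

    E, varexp = _eigengene_frame(X, assignment)
    kme = kme_table(X, E) if E.shape[0] else pd.DataFrame(index=X.genes)

    if config.reassign_kme_threshold is not None and E.shape[0] >= 1:
        assignment = _reassign_unassigned(assignment, kme, config)
        E, varexp = _eigengene_frame(X, assignment)
        kme = kme_table(X, E)

    return NetworkModel(config=config, assignment=assignment, eigengenes=E,
                        kme=kme, variance_explained=varexp)


def _reassign_unassigned(assignment: pd.Series, kme: pd.DataFrame,
                         config: NetworkConfig) -> pd.Series:
    """Assign label-0 genes with kME >= threshold to a unique best module."""
    thr = config.reassign_kme_threshold
    out = assignment.copy()
    un = assignment.index[assignment == 0]
    if len(un) == 0 or kme.shape[1] == 0:
        return out
    sub = kme.loc[un].to_numpy(dtype=float)
    cols = np.asarray(list(kme.columns))
    filled = np.nan_to_num(sub, nan=-np.inf)
    order = np.argsort(filled, axis=1)
    best_idx = order[:, -1]
    rows = np.arange(len(un))
    best_val = filled[rows, best_idx]
    second = filled[rows, order[:, -2]] if sub.shape[1] > 1 else np.full(len(un), -np.inf)
    ok = np.isfinite(best_val) & (best_val >= thr) & (best_val > second)
    newlab = out.loc[un].to_numpy().copy()
    newlab[ok] = cols[best_idx[ok]].astype(int)
    out.loc[un] = newlab
    return out
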