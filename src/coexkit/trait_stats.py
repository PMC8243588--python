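"""Module eigengene / clinical trait inference: robust correlation with
Student p-values, eigengene relatedness dendrogram, sample clustering on ME
profiles, and per-unit variance partitioning across covariates."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .network import bicor, pearson_matrix
from .types import InputError, SampleTraits

__all__ = [
    "ModuleTraitResult",
    "VarianceDecomposition",
    "module_trait_correlation",
    "me_dendrogram",
    "linkage_to_newick",
    "cluster_samples_by_me",
    "variance_partition",
]

RELAPSE_ENRICHED_FRACTION = 0.8  # cluster flagged when relapse fraction exceeds this


@dataclass
class ModuleTraitResult:
    rho: pd.DataFrame     # module x trait
    p: pd.DataFrame       # module x trait
    n_used: pd.DataFrame  # module x trait


@dataclass
class VarianceDecomposition:
    unit_id: str
    fractions: dict[str, float]
    residual: float


def correlation_p(rho: float, n: int) -> float:
    """Two-sided Student p for a correlation: t = rho * sqrt((n-2)/(1-rho^2))."""
    if n < 3 or np.isnan(rho):
        return float("nan")
    r2 = min(rho * rho, 1.0)
    if r2 >= 1.0:
        return 0.0
    t = abs(rho) * np.sqrt((n - 2) / (1.0 - r2))
    return float(2.0 * stats.t.sf(t, df=n - 2))


def module_trait_correlation(
    ME: pd.DataFrame, traits: SampleTraits, method: str = "bicor"
) -> ModuleTraitResult:
    """Correlate each module eigengene with each trait, pairwise-complete.

    Binary traits (0/1) correlate point-biserially: bicor's zero-MAD fallback
    reduces to Pearson on such vectors.  Traits with fewer than 4 non-missing
    values are reported as missing with a warning.
    """
    if method not in ("bicor", "pearson"):
        raise InputError(f"unknown correlation method {method!r}")
    shared = [s for s in ME.columns if s in traits.data.index]
    if not shared:
        raise InputError("no shared samples between eigengenes and traits")
    T = traits.data.loc[shared]
    numeric_traits = [c for c in T.columns if pd.api.types.is_numeric_dtype(T[c])]
    modules = list(ME.index)
    rho = pd.DataFrame(np.nan, index=modules, columns=numeric_traits, dtype=float)
    p = pd.DataFrame(np.nan, index=modules, columns=numeric_traits, dtype=float)
    n_used = pd.DataFrame(0, index=modules, columns=numeric_traits, dtype=int)
    for trait in numeric_traits:
        tv = T[trait].to_numpy(dtype=float)
        ok = ~np.isnan(tv)
        n = int(ok.sum())
        if n < 4:
            warnings.warn(f"trait {trait!r} has fewer than 4 non-missing values")
            continue
        for m in modules:
            me = ME.loc[m, shared].to_numpy(dtype=float)
            x, y = me[ok], tv[ok]
            if np.std(y) == 0 or np.std(x) == 0:
                continue
            if method == "bicor":
                r = bicor(x, y)
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rho.loc[m, trait] = r
            p.loc[m, trait] = correlation_p(r, n)
            n_used.loc[m, trait] = n
    return ModuleTraitResult(rho=rho, p=p, n_used=n_used)


def me_dendrogram(ME: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Average-linkage tree on 1 - cor(ME_i, ME_j).

    Returns (scipy linkage matrix, leaf labels in input order).  Leaves are the
    module labels; ties are already deterministic because modules enter in
    sorted label order.
    """
    if ME.shape[0] < 2:
        raise InputError("ME dendrogram requires at least 2 modules")
    order = sorted(ME.index)
    E = ME.loc[order]
    C = pearson_matrix(E.to_numpy())
    D = 1.0 - np.nan_to_num(C, nan=0.0)
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    return Z, list(order)


def linkage_to_newick(Z: np.ndarray, labels: list) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node_repr(i: int) -> str:
        if i < n:
            return str(labels[i])
        a, b, h, _ = Z[i - n]
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        return f"({node_repr(a)}:{la:.6g},{node_repr(b)}:{lb:.6g})"

    for idx in range(Z.shape[0]):
        heights[n + idx] = Z[idx, 2]
    return node_repr(n + Z.shape[0] - 1) + ";"


def cluster_samples_by_me(
    ME: pd.DataFrame,
    k: int | None = None,
    relapse: pd.Series | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Hierarchically cluster samples on z-scored ME profiles.

    Euclidean distance, average linkage; the tree is cut to ``k`` clusters, or
    to the k in 2..10 maximizing the silhouette when ``k`` is None.  Returns
    (sample labels 1..k, per-cluster summary).  When a relapse indicator is
    supplied the summary reports each cluster's relapse fraction and flags
    clusters whose fraction exceeds 0.8 as relapse-enriched.
    """
    n = ME.shape[1]
    if k is not None and k > n:
        raise InputError("k exceeds the number of samples")
    # z-score each ME row so every module weighs equally
    V = ME.to_numpy(dtype=float)
    sd = V.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    Vz = (V - V.mean(axis=1, keepdims=True)) / sd
    P = Vz.T  # samples x modules

    if k == 1:
        labels = pd.Series(1, index=ME.columns)
    else:
        Z = linkage(pdist(P, metric="euclidean"), method="average")
        if k is None:
            from sklearn.metrics import silhouette_score

            best_k, best_s = 2, -np.inf
            for kk in range(2, min(10, n - 1) + 1):
                lab = fcluster(Z, t=kk, criterion="maxclust")
                if len(set(lab)) < 2:
                    continue
                s = silhouette_score(P, lab)
                if s > best_s:
                    best_k, best_s = kk, s
            k = best_k
        labels = pd.Series(fcluster(Z, t=k, criterion="maxclust"), index=ME.columns)

    rows = []
    for c in sorted(labels.unique()):
        members = labels.index[labels == c]
        row = {"cluster": int(c), "n_samples": len(members)}
        if relapse is not None:
            rf = float(relapse.loc[members].mean())
            row["relapse_fraction"] = rf
            row["relapse_enriched"] = rf > RELAPSE_ENRICHED_FRACTION
        rows.append(row)
    return labels, pd.DataFrame(rows).set_index("cluster")


def _sequential_ss(y: np.ndarray, cols: list[np.ndarray]) -> np.ndarray:
    """Sequential (type-I) sums of squares for covariate columns, in order."""
    n = y.shape[0]
    ss = np.zeros(len(cols))
    Q = np.ones((n, 1)) / np.sqrt(n)  # intercept
    resid = y - Q @ (Q.T @ y)
    for j, c in enumerate(cols):
        v = c - Q @ (Q.T @ c)
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            continue
        q = (v / norm)[:, None]
        proj = q @ (q.T @ resid)
        ss[j] = float((proj ** 2).sum())
        resid = resid - proj
        Q = np.hstack([Q, q])
    return ss


def variance_partition(
    units: pd.DataFrame, covariates: pd.DataFrame, max_exhaustive: int = 5
) -> list[VarianceDecomposition]:
    """Per-unit variance fractions attributable to each covariate.

    Fits each unit (row of ``units``) on all covariates simultaneously and
    decomposes the model sum of squares sequentially; when there are at most
    ``max_exhaustive`` covariates the sequential decomposition is averaged
    over all covariate orderings, otherwise the declared column order is used.
    Fractions are invariant to covariate scaling.  Raises when two covariates
    are (near-)collinear, naming the pair.
    """
    shared = [s for s in units.columns if s in covariates.index]
    if len(shared) < len(units.columns):
        raise InputError("covariates missing for some samples")
    C = covariates.loc[shared]
    names = list(C.columns)
    mats = []
    for c in names:
        v = C[c].to_numpy(dtype=float)
        if np.std(v) == 0:
            raise InputError(f"covariate {c!r} is constant")
        mats.append((v - v.mean()) / v.std())
    for (i, a), (j, b) in itertools.combinations(enumerate(mats), 2):
        if abs(np.corrcoef(a, b)[0, 1]) > 0.999:
            raise InputError(f"collinear covariates: {names[i]!r} and {names[j]!r}")

    if len(names) <= max_exhaustive:
        orderings = list(itertools.permutations(range(len(names))))
    else:
        orderings = [tuple(range(len(names)))]

    out = []
    for uid, row in units.loc[:, shared].iterrows():
        y = row.to_numpy(dtype=float)
        tot = float(((y - y.mean()) ** 2).sum())
        if tot == 0:
            out.append(VarianceDecomposition(str(uid), {n: 0.0 for n in names}, 1.0))
            continue
        acc = np.zeros(len(names))
        for perm in orderings:
            ss = _sequential_ss(y, [mats[i] for i in perm])
            for pos, i in enumerate(perm):
                acc[i] += ss[pos]
        acc /= len(orderings)
        fractions = {n: float(v / tot) for n, v in zip(names, acc)}
        residual = 1.0 - sum(fractions.values())
        out.append(VarianceDecomposition(str(uid), fractions, float(residual)))
    return out
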