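"""RPKM matrix cleaning: low-expression filter, log2 transform, iterative
connectivity-based outlier-sample removal, and a PCA quality check."""

from __future__ import annotations

import numpy as np

from .network import bicor_matrix, pearson_matrix
from .types import (
    LOG2,
    RPKM,
    CleaningReport,
    ExpressionMatrix,
    InputError,
    ProceduralError,
)

__all__ = [
    "filter_low_expression",
    "log_transform",
    "remove_outlier_samples",
    "pca_qc",
    "preprocess",
]

DEFAULT_OFFSET = 0.05


def filter_low_expression(
    X: ExpressionMatrix, max_zero_fraction: float = 0.5
) -> tuple[ExpressionMatrix, CleaningReport]:
    """Drop genes whose exact-zero fraction is >= ``max_zero_fraction``.

    The boundary is inclusive on the removal side: a gene with zeros in
    exactly half the samples is removed at the default 0.5.
    """
    if X.n_genes == 0 or X.n_samples == 0:
        raise InputError("empty expression matrix")
    V = X.values
    if V.min() < 0:
        raise InputError("RPKM matrix must be non-negative")
    zero_frac = (V == 0).mean(axis=1)
    keep = zero_frac < max_zero_fraction
    out = ExpressionMatrix(X.data.loc[keep], scale=X.scale)
    report = CleaningReport(genes_in=X.n_genes, genes_kept=int(keep.sum()))
    return out, report


def log_transform(X: ExpressionMatrix, offset: float = DEFAULT_OFFSET) -> ExpressionMatrix:
    """Return log2(x + offset) with the scale tag flipped to log2."""
    V = X.values
    if V.min() < 0:
        raise InputError("cannot log-transform negative expression values")
    return ExpressionMatrix(
        X.data.apply(lambda col: np.log2(col + offset)), scale=LOG2
    )


def sample_connectivity_z(X: ExpressionMatrix, method: str = "bicor") -> np.ndarray:
    """z-scored per-sample connectivity k_i = sum_{j != i} corr(sample_i, sample_j)."""
    V = X.values.T  # samples as rows, genes as observations
    C = bicor_matrix(V) if method == "bicor" else pearson_matrix(V)
    C = np.nan_to_num(C, nan=0.0)
    k = C.sum(axis=1) - np.diag(C)
    sd = k.std(ddof=1)
    if sd == 0:
        return np.zeros_like(k)
    return (k - k.mean()) / sd


def remove_outlier_samples(
    X: ExpressionMatrix, z_threshold: float = 3.0, method: str = "bicor"
) -> tuple[ExpressionMatrix, CleaningReport]:
    """Iteratively drop samples with |z.k| >= ``z_threshold``.

    All offenders in an iteration are removed together, then connectivity is
    recomputed; iteration stops when no sample exceeds the threshold.  The
    report logs every removal with its z.k and iteration index.
    """
    if X.n_samples < 4:
        raise InputError("outlier removal requires at least 4 samples")
    report = CleaningReport(genes_in=X.n_genes, genes_kept=X.n_genes)
    current = X
    iteration = 0
    while True:
        iteration += 1
        zk = sample_connectivity_z(current, method=method)
        offenders = np.abs(zk) >= z_threshold
        if not offenders.any():
            report.iterations = iteration
            return current, report
        for s, z in zip(
            np.asarray(current.samples)[offenders], zk[offenders]
        ):
            report.samples_removed.append((str(s), float(z), iteration))
        keep = [s for s, bad in zip(current.samples, offenders) if not bad]
        if len(keep) < 3:
            report.iterations = iteration
            raise ProceduralError(
                "outlier removal eliminated (nearly) all samples", report=report
            )
        current = current.subset_samples(keep)


def pca_qc(X: ExpressionMatrix) -> dict:
    """Sample scores on the first two PCs of the sample x gene matrix.

    Genes are centered; variance fractions are eigenvalue shares of total
    variance.  Raises on a constant matrix.
    """
    if X.n_samples < 3:
        raise InputError("PCA QC requires at least 3 samples")
    V = X.values.T  # samples x genes
    Vc = V - V.mean(axis=0, keepdims=True)
    total_var = (Vc ** 2).sum()
    if total_var == 0:
        raise InputError("degenerate input: constant expression matrix")
    U, S, _ = np.linalg.svd(Vc, full_matrices=False)
    scores = U[:, :2] * S[:2]
    fractions = (S[:2] ** 2) / (S ** 2).sum()
    return {
        "samples": list(X.samples),
        "pc1": scores[:, 0].tolist(),
        "pc2": scores[:, 1].tolist() if scores.shape[1] > 1 else [0.0] * X.n_samples,
        "variance_fractions": fractions.tolist(),
    }


def preprocess(
    X: ExpressionMatrix,
    max_zero_fraction: float = 0.5,
    offset: float = DEFAULT_OFFSET,
    z_threshold: float = 3.0,
    connectivity_method: str = "bicor",
) -> tuple[ExpressionMatrix, CleaningReport]:
    """Full cleaning chain: zero filter -> log2(x + offset) -> outlier removal -> PCA."""
    if X.scale != RPKM:
        raise InputError("preprocess expects an RPKM-scale matrix")
    filtered, report = filter_low_expression(X, max_zero_fraction)
    logged = log_transform(filtered, offset)
    cleaned, outlier_report = remove_outlier_samples(
        logged, z_threshold, method=connectivity_method
    )
    report.offset = offset
    report.samples_removed = outlier_report.samples_removed
    report.iterations = outlier_report.iterations
    report.pca = pca_qc(cleaned)
    return cleaned, report
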