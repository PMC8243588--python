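"""Over-representation analysis of gene lists against GMT collections via the
one-sided Fisher (hypergeometric tail) test with Benjamini-Hochberg control."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import InputError

__all__ = ["EnrichmentRecord", "fisher_enrichment", "bh_adjust"]


@dataclass
class EnrichmentRecord:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    background_size: int
    p: float
    p_adj: float
    z: float


def hypergeom_tail(overlap: int, background: int, set_size: int, query: int) -> float:
    """P[X >= overlap] for X ~ Hypergeom(background, set_size, query)."""
    return float(stats.hypergeom.sf(overlap - 1, background, set_size, query))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def fisher_enrichment(
    query: list[str], sets: dict[str, list[str]], background: list[str]
) -> list[EnrichmentRecord]:
    """One-sided over-representation test of ``query`` against each gene set.

    Sets are intersected with the background before testing; the query must be
    a subset of the background.  The analytic z-score is
    (overlap - E[X]) / SD[X] under the hypergeometric null.  Records come back
    sorted by p then set name; an empty query yields all p = 1.
    """
    bg = set(background)
    if not bg:
        raise InputError("empty background universe")
    q = set(query)
    stray = q - bg
    if stray:
        raise InputError(f"query genes outside the background: {sorted(stray)[:10]}")
    M, nq = len(bg), len(q)

    records = []
    for name in sorted(sets):
        members = set(sets[name]) & bg
        s = len(members)
        if s == 0:
            continue
        ov = len(members & q)
        if nq == 0:
            p, z = 1.0, float("nan")
        else:
            p = hypergeom_tail(ov, M, s, nq)
            mean = nq * s / M
            var = nq * s * (M - s) * (M - nq) / (M ** 2 * (M - 1)) if M > 1 else 0.0
            z = (ov - mean) / np.sqrt(var) if var > 0 else float("nan")
        records.append(
            EnrichmentRecord(
                set_name=name, overlap=ov, set_size=s, query_size=nq,
                background_size=M, p=float(min(max(p, 0.0), 1.0)),
                p_adj=float("nan"), z=float(z),
            )
        )
    padj = bh_adjust([r.p for r in records])
    for r, a in zip(records, padj):
        r.p_adj = float(a)
    records.sort(key=lambda r: (r.p, r.set_name))
    return records


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "query_size": r.query_size,
                "background_size": r.background_size,
                "p": r.p,
                "p_adj": r.p_adj,
                "z": r.z,
            }
            for r in records
        ]
    )
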