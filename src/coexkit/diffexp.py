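"""Differential expression: one-way ANOVA with Tukey HSD post-hoc, two-group
rank-sum tests, log2 fold changes, and the hub-biomarker selection gate."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import InputError

__all__ = [
    "DiffExprRecord",
    "anova_tukey",
    "wilcoxon_two_group",
    "select_biomarkers",
    "volcano_table",
]

#: Four-group comparison: Binet stage x relapse status; the focal pair for
#: fold change and the volcano table is stage A relapse vs stage A no-relapse.
GROUP_A_NORELAPSE = "A_norelapse"
GROUP_A_RELAPSE = "A_relapse"
GROUP_B_NORELAPSE = "B_norelapse"
GROUP_B_RELAPSE = "B_relapse"
FOCAL_PAIR = (GROUP_A_RELAPSE, GROUP_A_NORELAPSE)


@dataclass
class DiffExprRecord:
    gene_id: str
    F: float
    anova_p: float
    tukey_p: dict[tuple[str, str], float] = field(default_factory=dict)
    lfc: float = float("nan")
    module: int = 0

    def focal_p(self, pair: tuple[str, str] = FOCAL_PAIR) -> float:
        key = tuple(sorted(pair))
        return self.tukey_p.get(key, float("nan"))


def anova_tukey(
    values: np.ndarray,
    groups: np.ndarray,
    focal_pair: tuple[str, str] = FOCAL_PAIR,
    gene_id: str = "",
    module: int = 0,
    pairs: list[tuple[str, str]] | None = None,
) -> DiffExprRecord:
    """One-way (equal-variance) ANOVA with Tukey HSD adjusted pairwise p.

    Pairwise p-values use the studentized range distribution with (k, N - k)
    parameters and the Tukey-Kramer standard error for unbalanced groups.
    ``lfc`` is mean(focal group) - mean(reference group) on the input scale
    (log2 data gives a log2 fold change).  Groups with fewer than 2
    observations are excluded from Tukey with a warning.  ``pairs`` restricts
    which pairwise p-values are evaluated (the studentized-range tail is
    expensive); default is every pair.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups)]
    sizes = {g: int((groups == g).sum()) for g in labels}
    usable = [g for g in labels if sizes[g] >= 2]
    if len(usable) < len(labels):
        warnings.warn(f"groups with < 2 samples excluded: "
                      f"{sorted(set(labels) - set(usable))}")
    if len(usable) < 2:
        raise InputError("ANOVA requires >= 2 groups with >= 2 samples each")

    arrays = {g: values[groups == g] for g in usable}
    k = len(usable)
    N = sum(len(a) for a in arrays.values())
    grand = np.concatenate(list(arrays.values())).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b, df_w = k - 1, N - k
    mse = ss_within / df_w
    if mse == 0:
        F = 0.0 if ss_between == 0 else float("inf")
        anova_p = 1.0 if ss_between == 0 else 0.0
    else:
        F = float((ss_between / df_b) / mse)
        anova_p = float(stats.f.sf(F, df_b, df_w))

    wanted = None if pairs is None else {tuple(sorted(p)) for p in pairs}
    tukey: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = usable[i], usable[j]
            if wanted is not None and tuple(sorted((gi, gj))) not in wanted:
                continue
            ai, aj = arrays[gi], arrays[gj]
            if mse == 0:
                p = 1.0 if ai.mean() == aj.mean() else 0.0
            else:
                se = np.sqrt(mse / 2.0 * (1.0 / len(ai) + 1.0 / len(aj)))
                q = abs(ai.mean() - aj.mean()) / se
                p = float(stats.studentized_range.sf(q, k, df_w))
            tukey[tuple(sorted((gi, gj)))] = min(max(p, 0.0), 1.0)

    lfc = float("nan")
    fa, fb = focal_pair
    if fa in arrays and fb in arrays:
        lfc = float(arrays[fa].mean() - arrays[fb].mean())

    return DiffExprRecord(gene_id=gene_id, F=F, anova_p=anova_p,
                          tukey_p=tukey, lfc=lfc, module=module)


def wilcoxon_two_group(x, labels) -> tuple[float, float]:
    """Mann-Whitney rank-sum test between the two label groups.

    Exact enumeration when both groups have n <= 10 and there are no ties;
    otherwise the tie-corrected two-sided normal approximation (with
    continuity correction).  Returns (U statistic of group 1, p).
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise InputError("wilcoxon_two_group requires exactly 2 groups")
    a = x[labels == uniq[0]]
    b = x[labels == uniq[1]]
    if len(a) == 0 or len(b) == 0:
        raise InputError("both groups must be non-empty")
    has_ties = len(np.unique(x)) < len(x)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def select_biomarkers(
    records: list[DiffExprRecord],
    kme: pd.DataFrame,
    assignment: pd.Series,
    p_max: float = 0.05,
    kme_min: float = 0.7,
    lfc_min: float = 0.5,
    focal_pair: tuple[str, str] = FOCAL_PAIR,
) -> dict[int, list[str]]:
    """Differentially expressed hub genes per module.

    Gate: focal Tukey p strictly below ``p_max``; kME to the gene's own module
    at least ``kme_min`` (inclusive); |lfc| at least ``lfc_min`` (inclusive).
    Returns module label -> passing gene list.
    """
    out: dict[int, list[str]] = {}
    for rec in records:
        m = int(assignment.get(rec.gene_id, rec.module))
        if m == 0 or rec.gene_id not in kme.index or m not in kme.columns:
            continue
        p = rec.focal_p(focal_pair)
        kv = kme.loc[rec.gene_id, m]
        if np.isnan(p) or np.isnan(kv) or np.isnan(rec.lfc):
            continue
        if p < p_max and kv >= kme_min and abs(rec.lfc) >= lfc_min:
            out.setdefault(m, []).append(rec.gene_id)
    return {m: sorted(gs) for m, gs in sorted(out.items())}


def volcano_table(
    records: list[DiffExprRecord], focal_pair: tuple[str, str] = FOCAL_PAIR
) -> pd.DataFrame:
    """Deterministic (gene, lfc, -log10 focal p, direction) table.

    Sorted by focal p ascending then |lfc| descending then gene id.
    """
    rows = []
    for rec in records:
        p = rec.focal_p(focal_pair)
        rows.append(
            {
                "gene_id": rec.gene_id,
                "lfc": rec.lfc,
                "p": p,
                "neg_log10_p": float(-np.log10(p)) if p > 0 else float("inf"),
                "direction": "up" if rec.lfc > 0 else ("down" if rec.lfc < 0 else "flat"),
                "module": rec.module,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["_abs_lfc"] = df["lfc"].abs()
    df = df.sort_values(
        ["p", "_abs_lfc", "gene_id"], ascending=[True, False, True]
    ).drop(columns="_abs_lfc")
    return df.reset_index(drop=True)


def binet_relapse_groups(traits_df: pd.DataFrame) -> pd.Series:
    """Derive the four Binet-stage x relapse group labels from a trait table."""
    binet = traits_df["binet_stage"].astype(str)
    relapse = traits_df["relapse"].astype(int)
    lab = binet + np.where(relapse == 1, "_relapse", "_norelapse")
    return pd.Series(lab, index=traits_df.index, name="group")
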