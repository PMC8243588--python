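"""Relapse-risk and survival evaluation: nonparametric ROC/AUC, prognostic
ratio combination screening at fixed relapse horizons, Kaplan-Meier curves,
log-rank tests with Pike hazard ratios, and optimal expression cutpoints."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, InputError

__all__ = [
    "SurvivalRecord",
    "RocResult",
    "CombinationScore",
    "roc_auc",
    "prognostic_ratio",
    "enumerate_combinations",
    "dichotomize_rfs",
    "km_curve",
    "logrank_and_hr",
    "optimal_cutpoint",
    "screen_combinations",
    "HORIZONS_DAYS",
]

#: Relapse-interval horizons in days (30.44-day months, 365.25-day years).
HORIZONS_DAYS = {"15mo": 456, "18mo": 548, "3y": 1095, "5y": 1826}

OVERALL_SURVIVAL = "overall_survival"
RELAPSE_FREE_SURVIVAL = "relapse_free_survival"


@dataclass
class SurvivalRecord:
    sample_id: str
    time: float
    event: int  # 1 = event observed, 0 = censored
    endpoint: str = OVERALL_SURVIVAL

    def __post_init__(self):
        if self.time < 0:
            raise InputError(f"negative time for {self.sample_id}")
        if self.event not in (0, 1):
            raise InputError("event flag must be 0 or 1")


@dataclass
class RocResult:
    marker_name: str
    auc: float
    z: float
    p: float
    n_pos: int
    n_neg: int


@dataclass
class CombinationScore:
    numerator_genes: tuple[str, ...]
    denominator_genes: tuple[str, ...]
    score_per_sample: pd.Series
    auc_by_horizon: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels, marker_name: str = "") -> RocResult:
    """Nonparametric AUC (Mann-Whitney with ties counted 0.5) with z-test.

    The standard error follows Hanley & McNeil; z = (AUC - 0.5)/SE with a
    two-sided normal p.  Perfectly separating scores give SE = 0, z = inf,
    p = 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    n_pos, n_neg = len(pos), len(neg)
    if n_pos == 0 or n_neg == 0:
        raise InputError("ROC requires both classes present")
    # AUC via midranks (equivalent to pair counting with ties at 0.5)
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc ** 2)
        + (n_neg - 1) * (q2 - auc ** 2)
    ) / (n_pos * n_neg)
    if var <= 0:
        z = float("inf") if auc != 0.5 else 0.0
        p = 0.0 if auc != 0.5 else 1.0
    else:
        z = (auc - 0.5) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return RocResult(marker_name=marker_name, auc=float(auc), z=float(z), p=p,
                     n_pos=n_pos, n_neg=n_neg)


# ---------------------------------------------------------------------------
# Prognostic ratio combinations
# ---------------------------------------------------------------------------

def prognostic_ratio(
    Z: ExpressionMatrix | pd.DataFrame,
    numerator: list[str],
    denominator: list[str],
    mode: str = "difference",
    eps: float = 1e-6,
) -> pd.Series:
    """Per-sample composite score contrasting two disjoint gene sets.

    ``difference`` (default): mean(Z[numerator]) - mean(Z[denominator]) —
    robust, antisymmetric under set swap.  ``literal_ratio``:
    mean(Z[num]) / (mean(Z[den]) + eps*sign) with a stability warning whenever
    any per-sample denominator mean lies in (-0.1, 0.1).  Input is expected on
    a z-scored scale.
    """
    df = Z.data if isinstance(Z, ExpressionMatrix) else Z
    num = list(numerator)
    den = list(denominator)
    if set(num) & set(den):
        raise InputError("numerator and denominator gene sets overlap")
    for s in (num, den):
        if not 1 <= len(s) <= 3:
            raise InputError("gene sets must have 1-3 genes")
        missing = [g for g in s if g not in df.index]
        if missing:
            raise InputError(f"genes absent from matrix: {missing}")
    num_mean = df.loc[num].mean(axis=0)
    den_mean = df.loc[den].mean(axis=0)
    if mode == "difference":
        return num_mean - den_mean
    if mode == "literal_ratio":
        near_zero = den_mean.abs() < 0.1
        if near_zero.any():
            warnings.warn(
                f"literal_ratio unstable: {int(near_zero.sum())} sample(s) "
                "have denominator mean in (-0.1, 0.1)"
            )
        sign = np.where(den_mean >= 0, 1.0, -1.0)
        return num_mean / (den_mean + eps * sign)
    raise InputError(f"unknown mode {mode!r}")


def enumerate_combinations(
    numerator_pool: list[str], denominator_pool: list[str], max_size: int = 3
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All (numerator subset, denominator subset) pairs of sizes 1..max_size.

    Deterministic lexicographic order over the input pool order; pools must be
    disjoint.
    """
    if set(numerator_pool) & set(denominator_pool):
        raise InputError("numerator and denominator pools overlap")
    combos = []
    for k in range(1, max_size + 1):
        for num in itertools.combinations(numerator_pool, k):
            for j in range(1, max_size + 1):
                for den in itertools.combinations(denominator_pool, j):
                    combos.append((num, den))
    return combos


def dichotomize_rfs(
    records: list[SurvivalRecord], horizon: float
) -> tuple[pd.Series, list[str]]:
    """Binary relapse-by-horizon labels from relapse-free-survival records.

    Positive: event within the horizon.  Negative: event-free follow-up to at
    least the horizon.  Censored before the horizon: excluded (returned in the
    second element).
    """
    if horizon <= 0:
        raise InputError("horizon must be positive")
    labels = {}
    excluded = []
    for r in records:
        if r.endpoint != RELAPSE_FREE_SURVIVAL:
            raise InputError("dichotomize_rfs expects relapse_free_survival records")
        if r.event == 1 and r.time <= horizon:
            labels[r.sample_id] = 1
        elif r.time >= horizon:
            labels[r.sample_id] = 0
        else:
            excluded.append(r.sample_id)
    return pd.Series(labels, dtype=int), excluded


def screen_combinations(
    Z: ExpressionMatrix | pd.DataFrame,
    numerator_pool: list[str],
    denominator_pool: list[str],
    records: list[SurvivalRecord],
    horizons: dict[str, float] = HORIZONS_DAYS,
    max_size: int = 3,
    mode: str = "difference",
) -> list[CombinationScore]:
    """Score every numerator/denominator combination at every horizon."""
    df = Z.data if isinstance(Z, ExpressionMatrix) else Z
    combos = enumerate_combinations(numerator_pool, denominator_pool, max_size)
    horizon_labels = {
        name: dichotomize_rfs(records, h)[0] for name, h in horizons.items()
    }
    out = []
    for num, den in combos:
        score = prognostic_ratio(df, list(num), list(den), mode=mode)
        aucs = {}
        for name, lab in horizon_labels.items():
            usable = lab.index.intersection(score.index)
            y = lab.loc[usable]
            if y.nunique() < 2:
                aucs[name] = float("nan")
                continue
            aucs[name] = roc_auc(score.loc[usable].to_numpy(), y.to_numpy()).auc
        out.append(
            CombinationScore(
                numerator_genes=num, denominator_genes=den,
                score_per_sample=score, auc_by_horizon=aucs,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_curve(records: list[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step table (time, at_risk, events, censored, survival) including
    the S(0) = 1 row; the curve drops only at event times.
    """
    if not records:
        raise InputError("km_curve requires at least one record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    if (times < 0).any():
        raise InputError("negative survival times")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    rows = [{"time": 0.0, "at_risk": len(times), "events": 0, "censored": 0,
             "survival": 1.0}]
    s = 1.0
    n = len(times)
    i = 0
    while i < n:
        t = times[i]
        at_risk = n - i
        d = c = 0
        while i < n and times[i] == t:
            if events[i] == 1:
                d += 1
            else:
                c += 1
            i += 1
        if d > 0:
            s *= 1.0 - d / at_risk
        rows.append({"time": float(t), "at_risk": at_risk, "events": d,
                     "censored": c, "survival": s})
    return pd.DataFrame(rows)


def logrank_and_hr(
    group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]
) -> tuple[float, float, float]:
    """Two-group log-rank test and Pike hazard ratio (group a vs group b).

    chi2 = (O_a - E_a)^2 / Var over pooled distinct event times; p from the
    chi-square distribution with 1 df; HR = (O_a/E_a) / (O_b/E_b).  Raises
    when no events occur in either group.
    """
    if not group_a or not group_b:
        raise InputError("both groups must be non-empty")
    ta = np.array([r.time for r in group_a])
    ea = np.array([r.event for r in group_a])
    tb = np.array([r.time for r in group_b])
    eb = np.array([r.event for r in group_b])
    if ea.sum() + eb.sum() == 0:
        raise InputError("log-rank undefined: no events in either group")

    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    O_a = E_a = O_b = E_b = V = 0.0
    for t in event_times:
        n_a = float((ta >= t).sum())
        n_b = float((tb >= t).sum())
        d_a = float(((ta == t) & (ea == 1)).sum())
        d_b = float(((tb == t) & (eb == 1)).sum())
        n = n_a + n_b
        d = d_a + d_b
        if n == 0:
            continue
        e_a = d * n_a / n
        O_a += d_a
        E_a += e_a
        O_b += d_b
        E_b += d - e_a
        if n > 1:
            V += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)

    if V == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (O_a - E_a) ** 2 / V
        p = float(stats.chi2.sf(chi2, df=1))
    if E_a > 0 and E_b > 0 and O_b > 0:
        hr = (O_a / E_a) / (O_b / E_b)
    elif O_a == 0 and O_b > 0:
        hr = 0.0
    else:
        hr = float("inf")
    return float(chi2), float(p), float(hr)


def optimal_cutpoint(
    expression, records: list[SurvivalRecord], min_group_frac: float = 0.1
) -> dict:
    """Expression cutpoint maximizing the log-rank chi2 between high/low groups.

    Scans midpoints between consecutive sorted unique values whose split keeps
    each side at >= ``min_group_frac`` of samples; ties prefer the lower
    cutpoint.  The selected test is selection-biased by construction and is
    reported as such (no correction).  Returns a status dict; status
    "no_admissible_split" when no split qualifies.
    """
    expression = pd.Series(expression)
    if len(records) < 10:
        raise InputError("optimal_cutpoint requires >= 10 subjects")
    ids = [r.sample_id for r in records]
    missing = [s for s in ids if s not in expression.index]
    if missing:
        raise InputError(f"expression missing for samples: {missing[:5]}")
    x = expression.loc[ids].to_numpy(dtype=float)
    uniq = np.unique(x)
    n = len(x)
    min_count = max(1, int(np.ceil(min_group_frac * n)))

    best = None
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = (lo + hi) / 2.0
        high = x > cut
        if high.sum() < min_count or (~high).sum() < min_count:
            continue
        ga = [r for r, h in zip(records, high) if h]
        gb = [r for r, h in zip(records, high) if not h]
        try:
            chi2, p, hr = logrank_and_hr(ga, gb)
        except InputError:
            continue
        if best is None or chi2 > best["chi2"]:
            best = {"cutpoint": float(cut), "chi2": chi2, "p": p, "hr_high_vs_low": hr,
                    "n_high": int(high.sum()), "n_low": int((~high).sum())}
    if best is None:
        return {"status": "no_admissible_split"}
    high_labels = pd.Series(
        np.where(x > best["cutpoint"], "high", "low"), index=ids
    )
    best.update({"status": "ok", "labels": high_labels,
                 "selection_biased": True})
    return best


def survival_records_from_traits(
    traits_df: pd.DataFrame, endpoint: str
) -> list[SurvivalRecord]:
    """Build SurvivalRecords from the simulator's standard trait columns."""
    if endpoint == OVERALL_SURVIVAL:
        tcol, ecol = "survival_days", "vital_status"
    elif endpoint == RELAPSE_FREE_SURVIVAL:
        tcol, ecol = "relapse_interval", "relapse"
    else:
        raise InputError(f"unknown endpoint {endpoint!r}")
    return [
        SurvivalRecord(sample_id=str(s), time=float(traits_df.loc[s, tcol]),
                       event=int(traits_df.loc[s, ecol]), endpoint=endpoint)
        for s in traits_df.index
    ]
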