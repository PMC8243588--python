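"""Synthetic cohort generator with planted co-expression modules.

Expression is simulated on the log2 scale as ``baseline + loading * factor +
noise`` per module gene, then emitted on the RPKM scale via ``2**x - 0.05``
floored at zero, so the preprocessing offset/log transform round-trips.
Binary relapse follows a logistic link on linked module factors; survival is
exponential with a proportional log-hazard; censoring is independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ckio
from .types import (
    RPKM,
    ConfigurationError,
    ExpressionMatrix,
    SampleTraits,
    TRAIT_AGE,
    TRAIT_BINET,
    TRAIT_RELAPSE,
    TRAIT_RELAPSE_INTERVAL,
    TRAIT_SEX,
    TRAIT_SURVIVAL_DAYS,
    TRAIT_VITAL_STATUS,
)

LOG_OFFSET = 0.05

#: Binet A:B prevalence 179:15, typical of watch-and-wait CLL cohorts.
BINET_P_A = 179 / 194


@dataclass
class ModuleTruth:
    """Ground truth for one planted module."""

    module_id: int
    gene_ids: list[str]
    eigen_signal: np.ndarray          # per-sample latent factor, unit variance
    loading_range: tuple[float, float]
    trait_links: dict[str, float] = field(default_factory=dict)
    loadings: np.ndarray | None = None  # per-gene loading on the factor

    def __post_init__(self):
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise ConfigurationError("loading_range must lie within (0, 1]")

    def to_dict(self) -> dict:
        return {
            "module_id": self.module_id,
            "gene_ids": list(self.gene_ids),
            "loading_range": list(self.loading_range),
            "trait_links": dict(self.trait_links),
            "loadings": None if self.loadings is None else list(map(float, self.loadings)),
        }


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort."""

    n_genes: int = 5000
    n_samples: int = 150
    n_modules: int = 6
    module_sizes: tuple[int, ...] = (300, 250, 200, 150, 100, 50)
    noise_sd: float = 0.5
    zero_inflation: float = 0.3
    relapse_effect: float = 1.5
    survival_effect: float = 1.0
    censor_rate: float = 0.3
    confounder_frac: float = 0.05
    loading_range: tuple[float, float] = (0.6, 0.95)
    seed: int = 0

    def __post_init__(self):
        if self.n_modules != len(self.module_sizes):
            raise ConfigurationError("n_modules must equal len(module_sizes)")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError("sum(module_sizes) exceeds n_genes")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not 0 <= self.zero_inflation <= 1:
            raise ConfigurationError("zero_inflation must be in [0, 1]")
        if not 0 <= self.censor_rate <= 1:
            raise ConfigurationError("censor_rate must be in [0, 1]")
        if not 0 <= self.confounder_frac <= 0.1:
            raise ConfigurationError("confounder_frac must be in [0, 0.1]")
        if self.n_samples < 4:
            raise ConfigurationError("n_samples must be >= 4")


def _unit_variance(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std(ddof=1)
    return x / sd if sd > 0 else x


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def rpkm_from_log2(x: np.ndarray) -> np.ndarray:
    """Back-transform log2(value + offset) expression to the RPKM scale."""
    return np.maximum(2.0 ** x - LOG_OFFSET, 0.0)


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, SampleTraits, list[ModuleTruth]]:
    """Simulate (expression, traits, ground truth) for one cohort.

    Module 1's factor drives the relapse logistic link (``relapse_effect`` in
    log-odds per factor SD); module 2's factor (module 1 when only one module)
    drives the survival log-hazard.  Identical config + seed gives bitwise
    identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_g, n_s = config.n_genes, config.n_samples
    genes = _gene_ids(n_g)
    samples = _sample_ids(n_s)

    baseline = rng.normal(3.5, 1.5, size=n_g)
    log2x = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n_g, n_s))

    truths: list[ModuleTruth] = []
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        factor = _unit_variance(rng.standard_normal(n_s))
        loadings = rng.uniform(*config.loading_range, size=size)
        rows = slice(pos, pos + size)
        log2x[rows] += loadings[:, None] * factor[None, :]
        links: dict[str, float] = {}
        if m == 1 and config.relapse_effect != 0:
            links[TRAIT_RELAPSE] = config.relapse_effect
        surv_module = 2 if config.n_modules >= 2 else 1
        if m == surv_module and config.survival_effect != 0:
            links[TRAIT_SURVIVAL_DAYS] = config.survival_effect
        truths.append(
            ModuleTruth(
                module_id=m,
                gene_ids=genes[pos : pos + size],
                eigen_signal=factor,
                loading_range=tuple(config.loading_range),
                trait_links=links,
                loadings=loadings,
            )
        )
        pos += size
    n_module_genes = pos

    # Confounders: sex and age inject at most confounder_frac of each gene's
    # variance, partitioned randomly between the two.
    sex = rng.integers(0, 2, size=n_s).astype(float)
    age = rng.normal(62.0, 10.0, size=n_s)
    while (age < 25).any():
        age[age < 25] = rng.normal(62.0, 10.0, size=int((age < 25).sum()))
    if config.confounder_frac > 0:
        sex_z = _unit_variance(sex)
        age_z = _unit_variance(age)
        base_var = log2x.var(axis=1, ddof=1)
        u = rng.uniform(0.0, config.confounder_frac, size=n_g)
        conf_var = base_var * u / (1.0 - u)
        split = rng.uniform(0.0, 1.0, size=n_g)
        b_sex = np.sqrt(conf_var * split) * rng.choice([-1.0, 1.0], size=n_g)
        b_age = np.sqrt(conf_var * (1.0 - split)) * rng.choice([-1.0, 1.0], size=n_g)
        log2x += b_sex[:, None] * sex_z[None, :] + b_age[:, None] * age_z[None, :]

    rpkm = rpkm_from_log2(log2x)

    # Zero inflation: exact zeros among background gene-sample cells only.
    if config.zero_inflation > 0 and n_module_genes < n_g:
        bg = rpkm[n_module_genes:]
        mask = rng.random(size=bg.shape) < config.zero_inflation
        bg[mask] = 0.0
        rpkm[n_module_genes:] = bg

    # Relapse: logistic link on the linked factor, ~45% base prevalence.
    relapse_lp = np.zeros(n_s)
    for t in truths:
        if TRAIT_RELAPSE in t.trait_links:
            relapse_lp += t.trait_links[TRAIT_RELAPSE] * t.eigen_signal
    p_relapse = 1.0 / (1.0 + np.exp(-(relapse_lp - 0.2)))
    relapse = (rng.random(n_s) < p_relapse).astype(int)

    # Relapse interval: event time for relapsers (hazard up with the linked
    # factor), event-free follow-up for the rest.
    relapse_time = rng.exponential(600.0, size=n_s) * np.exp(-0.3 * relapse_lp)
    relapse_time = np.maximum(relapse_time, 30.0)
    followup = rng.uniform(800.0, 3000.0, size=n_s)
    interval = np.where(relapse == 1, relapse_time, followup)

    # Survival: exponential with proportional log-hazard on the linked factor.
    surv_lp = np.zeros(n_s)
    for t in truths:
        if TRAIT_SURVIVAL_DAYS in t.trait_links:
            surv_lp += t.trait_links[TRAIT_SURVIVAL_DAYS] * t.eigen_signal
    surv_time = rng.exponential(1500.0, size=n_s) * np.exp(-surv_lp)
    censored = rng.random(n_s) < config.censor_rate
    censor_at = rng.uniform(0.0, 1.0, size=n_s) * surv_time
    survival_days = np.where(censored, censor_at, surv_time)
    vital = np.where(censored, 0, 1)

    binet = np.where(rng.random(n_s) < BINET_P_A, "A", "B")

    expr = ExpressionMatrix(pd.DataFrame(rpkm, index=genes, columns=samples), scale=RPKM)
    traits = SampleTraits(
        pd.DataFrame(
            {
                TRAIT_SEX: sex.astype(int),
                TRAIT_AGE: age,
                TRAIT_RELAPSE: relapse,
                TRAIT_RELAPSE_INTERVAL: interval,
                TRAIT_SURVIVAL_DAYS: survival_days,
                TRAIT_VITAL_STATUS: vital,
                TRAIT_BINET: binet,
            },
            index=samples,
        )
    )
    return expr, traits, truths


def generate_validation_cohort(
    truths: list[ModuleTruth],
    config: CohortConfig,
    preserved_modules: set[int] | None = None,
    seed: int = 1,
    n_samples: int | None = None,
) -> ExpressionMatrix:
    """Second cohort over the same genes, regenerating a subset of modules.

    Modules in ``preserved_modules`` (default: all) are re-simulated with the
    same per-gene loadings on fresh sample factors, so their correlation
    structure recurs; the rest become independent noise.  Used to exercise
    cross-cohort preservation statistics.
    """
    rng = np.random.default_rng(seed)
    n_s = n_samples if n_samples is not None else config.n_samples
    n_g = config.n_genes
    genes = _gene_ids(n_g)
    samples = [f"V{i:03d}" for i in range(1, n_s + 1)]
    if preserved_modules is None:
        preserved_modules = {t.module_id for t in truths}

    baseline = rng.normal(3.5, 1.5, size=n_g)
    log2x = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n_g, n_s))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for t in truths:
        if t.module_id not in preserved_modules:
            continue
        factor = _unit_variance(rng.standard_normal(n_s))
        loadings = (
            t.loadings
            if t.loadings is not None
            else rng.uniform(*t.loading_range, size=len(t.gene_ids))
        )
        idx = [gene_pos[g] for g in t.gene_ids]
        log2x[idx] += np.asarray(loadings)[:, None] * factor[None, :]

    rpkm = rpkm_from_log2(log2x)
    return ExpressionMatrix(pd.DataFrame(rpkm, index=genes, columns=samples), scale=RPKM)


def write_cohort(outdir, expr: ExpressionMatrix, traits: SampleTraits,
                 truths: list[ModuleTruth]) -> dict[str, str]:
    """Write expression TSV, traits TSV, and truth JSON into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(outdir / "expression.tsv"),
        "traits": str(outdir / "traits.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    ckio.write_expression(expr, paths["expression"], float_format="%.10g")
    ckio.write_traits(traits, paths["traits"])
    with open(paths["truth"], "w") as fh:
        json.dump([t.to_dict() for t in truths], fh, indent=2)
        fh.write("\n")
    return paths


def truth_assignment(truths: list[ModuleTruth], genes: list[str]) -> pd.Series:
    """Planted module label per gene (0 for background), aligned to ``genes``."""
    s = pd.Series(0, index=pd.Index(genes), dtype=int)
    for t in truths:
        present = [g for g in t.gene_ids if g in s.index]
        s.loc[present] = t.module_id
    return s
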