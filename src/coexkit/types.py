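"""Shared data containers for the co-expression analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InputError(ValueError):
    """Malformed or inadmissible input."""


class ConfigurationError(ValueError):
    """Invalid configuration parameters."""


class ProceduralError(RuntimeError):
    """A procedure reached an unusable state (e.g. all samples removed)."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


RPKM = "rpkm"
LOG2 = "log2"

#: Standard trait column names emitted by the simulator and consumed downstream.
TRAIT_SEX = "sex"
TRAIT_AGE = "age"
TRAIT_RELAPSE = "relapse"
TRAIT_RELAPSE_INTERVAL = "relapse_interval"
TRAIT_SURVIVAL_DAYS = "survival_days"
TRAIT_VITAL_STATUS = "vital_status"
TRAIT_BINET = "binet_stage"


@dataclass
class ExpressionMatrix:
    """Gene x sample numeric expression matrix with an explicit scale tag.

    ``data`` is indexed by gene identifier (rows) with sample identifiers as
    columns.  ``scale`` is either ``"rpkm"`` (non-negative linear scale) or
    ``"log2"`` (log2 of offset RPKM).
    """

    data: pd.DataFrame
    scale: str = RPKM

    def __post_init__(self):
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.scale not in (RPKM, LOG2):
            raise ConfigurationError(f"unknown expression scale: {self.scale!r}")
        dup = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup:
            raise InputError(f"duplicate gene identifiers: {dup}")
        dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
        if dup:
            raise InputError(f"duplicate sample identifiers: {dup}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)], scale=self.scale)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)], scale=self.scale)


@dataclass
class SampleTraits:
    """Per-sample clinical covariates (samples as rows, traits as columns)."""

    data: pd.DataFrame

    def __post_init__(self):
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        dup = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup:
            raise InputError(f"duplicate sample identifiers in traits: {dup}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def align(self, samples) -> "SampleTraits":
        missing = [s for s in samples if s not in self.data.index]
        if missing:
            raise InputError(f"samples absent from trait table: {missing}")
        return SampleTraits(self.data.loc[list(samples)])


@dataclass
class CleaningReport:
    """Provenance of preprocessing steps (filtering, outliers, PCA QC)."""

    genes_in: int = 0
    genes_kept: int = 0
    offset: float | None = None
    samples_removed: list[tuple[str, float, int]] = field(default_factory=list)
    iterations: int = 0
    pca: dict | None = None

    def to_dict(self) -> dict:
        return {
            "genes_in": self.genes_in,
            "genes_kept": self.genes_kept,
            "offset": self.offset,
            "samples_removed": [
                {"sample": s, "zk": z, "iteration": it}
                for s, z, it in self.samples_removed
            ],
            "iterations": self.iterations,
            "pca": self.pca,
        }


@dataclass
class NetworkConfig:
    """Parameters of signed-network construction and module detection."""

    beta: float = 5.5
    network_type: str = "signed"
    min_module_size: int = 30
    merge_height: float = 0.25
    max_block_size: int = 25000
    cut_height_fraction: float = 0.95
    reassign_kme_threshold: float | None = 0.7

    def __post_init__(self):
        if self.beta <= 0:
            raise ConfigurationError("beta must be positive")
        if self.network_type != "signed":
            raise ConfigurationError("only signed networks are supported")
        if self.min_module_size < 3:
            raise ConfigurationError("min_module_size must be >= 3")
        if not 0 < self.cut_height_fraction <= 1:
            raise ConfigurationError("cut_height_fraction must be in (0, 1]")


@dataclass
class NetworkModel:
    """Fitted co-expression network: assignment, eigengenes, kME."""

    config: NetworkConfig
    assignment: pd.Series            # gene -> int module label, 0 = unassigned
    eigengenes: pd.DataFrame         # module label (index) x sample
    kme: pd.DataFrame                # gene x module label
    variance_explained: pd.Series    # per module label

    def module_genes(self, label: int) -> list[str]:
        return list(self.assignment.index[self.assignment == label])

    @property
    def module_labels(self) -> list[int]:
        return [int(m) for m in self.eigengenes.index]


#: Color aliases in module-size rank order (label 1 = largest module), matching
#: the conventional palette used by reference implementations.
MODULE_COLORS = [
    "grey", "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown",
]


def module_color(label: int) -> str:
    """Color alias for a module label (0 = grey = unassigned)."""
    if label < len(MODULE_COLORS):
        return MODULE_COLORS[label]
    return f"module{label}"
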