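"""Delimited-text I/O for expression matrices, trait tables, and GMT gene sets."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .types import RPKM, ExpressionMatrix, InputError, SampleTraits

_SEP = {"tsv": "\t", "csv": ","}


def _sep(dialect: str) -> str:
    try:
        return _SEP[dialect]
    except KeyError:
        raise InputError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")


def read_expression(path, dialect: str = "tsv", scale: str = RPKM) -> ExpressionMatrix:
    """Read a gene x sample matrix (first column gene id, header = sample ids)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"expression file not found: {path}")
    if path.stat().st_size == 0:
        raise InputError(f"expression file is empty: {path}")
    # round_trip parser: written %.17g values re-read bit-exactly
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0,
                     float_precision="round_trip")
    if df.empty:
        raise InputError(f"expression file has no data rows: {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise InputError(f"duplicate gene ids in {path}: {dup}")
    return ExpressionMatrix(df, scale=scale)


def write_expression(X: ExpressionMatrix, path, dialect: str = "tsv",
                     float_format: str | None = "%.6g") -> None:
    df = X.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep=_sep(dialect), float_format=float_format)


def read_traits(path, dialect: str = "tsv") -> SampleTraits:
    """Read a sample x trait table (first column sample id)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"trait file not found: {path}")
    if path.stat().st_size == 0:
        raise InputError(f"trait file is empty: {path}")
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0)
    df.index = df.index.astype(str)
    return SampleTraits(df)


def write_traits(traits: SampleTraits, path, dialect: str = "tsv") -> None:
    df = traits.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep(dialect))


def check_sample_consistency(X: ExpressionMatrix, traits: SampleTraits) -> None:
    """Raise with the symmetric difference when sample ids disagree."""
    xs, ts = set(X.samples), set(traits.samples)
    if xs != ts:
        only_x = sorted(xs - ts)
        only_t = sorted(ts - xs)
        raise InputError(
            "sample ids differ between expression and traits; "
            f"expression-only={only_x}, traits-only={only_t}"
        )


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"GMT file not found: {path}")
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"GMT line {ln} has fewer than 3 fields")
            name, _desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise InputError(f"duplicate gene-set name in GMT: {name}")
            sets[name] = genes
    if not sets:
        raise InputError(f"GMT file contains no gene sets: {path}")
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"gene list not found: {path}")
    with open(path) as fh:
        genes = [ln.strip() for ln in fh if ln.strip()]
    return genes


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
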