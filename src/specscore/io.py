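"""Readers and writers for the supported text dialects.

Matrix dialects: plain TSV (header row of sample ids, first column gene ids)
and GCT v1.2 ("#1.2" line, dimensions line, Name/Description columns; the
Description column is dropped on read). Matrices are genes-in-rows only;
transposed input is rejected, never auto-detected. Annotation: TSV with
columns ``sample_id`` and ``state``. Prevalences: TSV with ``state`` and
``weight``. Output files carry '#'-prefixed provenance header lines.
"""

from __future__ import annotations

import warnings
from io import StringIO

import numpy as np
import pandas as pd

from . import __version__
from .containers import CountMatrix, PrevalenceWeights, SampleGrouping, SpecsResult

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
    "read_prevalences",
    "write_scores",
    "read_scores",
    "write_labels",
]

SCORE_DECIMALS = 6


def _validated_matrix(df: pd.DataFrame, path) -> CountMatrix:
    df.index = df.index.astype(str)
    bad = df.columns[~df.dtypes.map(lambda t: np.issubdtype(t, np.number))]
    if len(bad):
        raise ValueError(f"{path}: non-numeric column(s) {list(bad)[:5]}")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        g, s = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative value at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    return CountMatrix(list(df.index), [str(c) for c in df.columns], values)


def read_matrix(path, dialect: str = "tsv") -> CountMatrix:
    """Read a genes x samples matrix in the ``tsv`` or ``gct`` dialect."""
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return _validated_matrix(df, path)
    if dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ValueError(f"{path}: line 1: expected '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise ValueError(f"{path}: line 2: expected '<n_genes>\\t<n_samples>'")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            body = fh.read()
        df = pd.read_csv(StringIO(body), sep="\t", index_col=0)
        if df.columns[0] != "Description":
            raise ValueError(f"{path}: line 3: second column must be 'Description'")
        df = df.drop(columns="Description")
        if df.shape != (n_genes, n_samples):
            raise ValueError(
                f"{path}: declared {n_genes}x{n_samples}, found {df.shape[0]}x{df.shape[1]}"
            )
        return _validated_matrix(df, path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_matrix(counts: CountMatrix, path, dialect: str = "tsv",
                 float_format: str | None = None) -> None:
    df = counts.to_dataframe()
    if dialect == "tsv":
        df.to_csv(path, sep="\t", index_label="gene_id", float_format=float_format)
    elif dialect == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{counts.n_genes}\t{counts.n_samples}\n")
            out = df.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name", float_format=float_format)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_annotation(path) -> SampleGrouping:
    """Read a sample annotation TSV with columns ``sample_id`` and ``state``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("sample_id", "state"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample rows: {dups[:10]}")
    grouping = SampleGrouping(df["sample_id"].tolist(), df["state"].tolist())
    singletons = [d for d, n in grouping.group_sizes.items() if n == 1]
    if singletons:
        warnings.warn(
            f"states with a single sample: {singletons}; pairwise probabilities "
            "against them rest on one observation", stacklevel=2)
    return grouping


def write_annotation(grouping: SampleGrouping, path) -> None:
    pd.DataFrame({"sample_id": grouping.samples, "state": grouping.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_prevalences(path) -> PrevalenceWeights:
    """Read a prevalence TSV with columns ``state`` and ``weight``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("state", "weight"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return PrevalenceWeights(dict(zip(df["state"].astype(str), df["weight"])))


def _provenance(seed=None, upper=None, lower=None) -> list:
    lines = [f"# specscore {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if upper is not None and lower is not None:
        lines.append(f"# thresholds: upper={upper} lower={lower}")
    return lines


def write_scores(result: SpecsResult, path, seed=None) -> None:
    """Write the genes x states score matrix with provenance header lines."""
    with open(path, "w") as fh:
        for line in _provenance(seed=seed, upper=result.upper, lower=result.lower):
            fh.write(line + "\n")
        result.scores.round(SCORE_DECIMALS).to_csv(
            fh, sep="\t", index_label="gene_id",
            float_format=f"%.{SCORE_DECIMALS}f",
        )


def read_scores(path) -> SpecsResult:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = [str(c) for c in df.columns]
    return SpecsResult(scores=df)


def write_labels(result: SpecsResult, path, seed=None) -> None:
    """Write one row per (gene, state, direction) classification."""
    if result.labels is None:
        raise ValueError("result has no labels; run classify_features first")
    with open(path, "w") as fh:
        for line in _provenance(seed=seed, upper=result.upper, lower=result.lower):
            fh.write(line + "\n")
        pd.DataFrame(result.labels, columns=["gene_id", "state", "direction"]).to_csv(
            fh, sep="\t", index=False
        )
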