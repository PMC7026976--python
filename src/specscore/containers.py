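"""Core data containers: count matrices, sample groupings, prevalence weights, results.

All numeric payloads are plain numpy arrays / pandas objects; the dataclasses here
only add identifier bookkeeping and invariant validation on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleGrouping",
    "PrevalenceWeights",
    "SpecsResult",
]


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:10]}")


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative abundances.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique feature identifiers, one per row.
    sample_ids : sequence of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (n_genes, n_samples)
        Non-negative, finite abundances (raw or normalized counts).
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.sample_ids, "sample_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if np.any(self.values < 0):
            g, s = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def gene_row(self, gene: str) -> np.ndarray:
        """Values for one gene, in sample order."""
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None
        return self.values[i]

    def subset_genes(self, genes) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"unknown genes: {missing[:10]}")
        idx = [pos[g] for g in genes]
        return CountMatrix(list(genes), self.sample_ids, self.values[idx])

    def subset_samples(self, samples) -> "CountMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in pos]
        if missing:
            raise KeyError(f"unknown samples: {missing[:10]}")
        idx = [pos[s] for s in samples]
        return CountMatrix(self.gene_ids, list(samples), self.values[:, idx])


@dataclass
class SampleGrouping:
    """Assignment of samples to states (tissues, conditions, ...).

    ``samples`` fixes an ordering used to align per-sample vectors; ``labels``
    gives the state of each sample in that order. State order defaults to the
    order of first appearance and is preserved in all outputs.
    """

    samples: list
    labels: list
    states: list = field(default=None)

    def __post_init__(self):
        self.samples = list(self.samples)
        self.labels = list(self.labels)
        if len(self.samples) != len(self.labels):
            raise ValueError("samples and labels differ in length")
        _check_unique(self.samples, "sample ids")
        seen = list(dict.fromkeys(self.labels))
        if self.states is None:
            self.states = seen
        else:
            self.states = list(self.states)
            if set(self.states) != set(seen):
                raise ValueError("states list does not match labels")
        if len(self.states) < 2:
            raise ValueError("need at least 2 states")
        self._index = {}
        for i, lab in enumerate(self.labels):
            self._index.setdefault(lab, []).append(i)

    @classmethod
    def from_mapping(cls, assignment: dict, states=None) -> "SampleGrouping":
        samples = list(assignment)
        return cls(samples, [assignment[s] for s in samples], states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def group_sizes(self) -> dict:
        return {d: len(self._index[d]) for d in self.states}

    def indices(self, state) -> np.ndarray:
        """Positions (into ``samples``) of the samples in ``state``."""
        if state not in self._index:
            raise KeyError(f"unknown state {state!r}")
        return np.asarray(self._index[state], dtype=int)

    def align_to(self, sample_ids) -> "SampleGrouping":
        """Reorder to a matrix's sample order; errors list the offending ids."""
        here = set(self.samples)
        there = set(sample_ids)
        extra = sorted(there - here)
        missing = sorted(here - there)
        if extra or missing:
            raise ValueError(
                f"sample sets differ: {len(extra)} in matrix without annotation "
                f"{extra[:5]}, {len(missing)} annotated but absent {missing[:5]}"
            )
        lab = dict(zip(self.samples, self.labels))
        return SampleGrouping(list(sample_ids), [lab[s] for s in sample_ids], self.states)


@dataclass
class PrevalenceWeights:
    """Per-state prevalence weights pi_d, summing to 1 over all states."""

    weights: dict

    def __post_init__(self):
        self.weights = {k: float(v) for k, v in self.weights.items()}
        vals = np.array(list(self.weights.values()))
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("weights must be non-negative and finite")
        total = vals.sum()
        if total <= 0:
            raise ValueError("weights must sum to a positive value")
        if not np.isclose(total, 1.0):
            self.weights = {k: v / total for k, v in self.weights.items()}

    @classmethod
    def equilibrated(cls, states) -> "PrevalenceWeights":
        m = len(states)
        return cls({d: 1.0 / m for d in states})

    @classmethod
    def from_group_sizes(cls, grouping: SampleGrouping) -> "PrevalenceWeights":
        sizes = grouping.group_sizes
        n = sum(sizes.values())
        return cls({d: sizes[d] / n for d in sizes})

    def offtarget(self, target, states) -> np.ndarray:
        """Weights for states != target, renormalized to sum to 1.

        Renormalizing over the off-target states makes a perfectly separated
        target group attain a score of exactly 1 regardless of pi_target.
        """
        missing = [d for d in states if d not in self.weights]
        if missing:
            raise KeyError(f"no prevalence for states {missing}")
        w = np.array([self.weights[d] for d in states if d != target], dtype=float)
        total = w.sum()
        if total <= 0:
            raise ValueError(f"off-target prevalences for {target!r} sum to zero")
        return w / total


@dataclass
class SpecsResult:
    """Scores (genes x states DataFrame of p-hat in [0,1]) plus optional labels.

    ``labels`` is a list of ``(gene_id, state, direction)`` tuples where
    direction is ``"present"`` or ``"absent"``; populated by
    :func:`specscore.core.classify_features`.
    """

    scores: pd.DataFrame
    labels: list = None
    upper: float = None
    lower: float = None

    def __post_init__(self):
        v = self.scores.to_numpy()
        if v.size and (np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12):
            raise ValueError("scores outside [0, 1]")

    def labels_for(self, gene) -> set:
        if self.labels is None:
            raise ValueError("result has no labels; run classify_features first")
        return {(d, direction) for g, d, direction in self.labels if g == gene}
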