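"""Classical tissue-specificity metrics operating on per-state summary profiles.

These metrics (z-score, Gini coefficient, Tau, TSI, JSD score) first collapse
biological replicates to one value per state — here the arithmetic mean — and
then score the resulting profile. SPECS, by contrast, uses all replicates; the
collapse step is what these comparators lose.

Conventions: profiles are pandas Series indexed by state. Metrics that are
undefined on an all-zero (or constant, for the z-score) profile return NaN
rather than raising, so downstream ranking can place them deterministically
last.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix, PrevalenceWeights, SampleGrouping
from .core import specs_score_matrix

__all__ = [
    "collapse_to_profile",
    "zscore",
    "gini",
    "tau",
    "tsi",
    "jsd_score",
    "score_all_metrics",
]


def collapse_to_profile(counts: CountMatrix, grouping: SampleGrouping, gene) -> pd.Series:
    """Per-state arithmetic mean of one gene's values."""
    grouping = grouping.align_to(counts.sample_ids)
    y = counts.gene_row(gene)
    return pd.Series(
        {d: float(y[grouping.indices(d)].mean()) for d in grouping.states},
        name=gene,
    )[grouping.states]


def _profile_values(profile) -> np.ndarray:
    x = np.asarray(profile, dtype=float).ravel()
    if x.size == 0 or not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError("profile must be non-empty, finite and non-negative")
    return x


def zscore(profile, ddof: int = 1) -> pd.Series:
    """Standardized per-state values (x_i - mean) / sd across the profile.

    ``ddof=1`` (sample standard deviation) by default. A constant profile has
    sd 0; all states then get NaN.
    """
    x = _profile_values(profile)
    if x.size < 2:
        raise ValueError("z-score needs at least 2 states")
    sd = x.std(ddof=ddof)
    index = profile.index if isinstance(profile, pd.Series) else None
    if sd == 0 or np.ptp(x) == 0:
        return pd.Series(np.full(x.size, np.nan), index=index)
    return pd.Series((x - x.mean()) / sd, index=index)


def gini(profile) -> float:
    """Gini coefficient of the profile: 0 for a uniform profile, (n-1)/n one-hot.

    Gini = (n+1)/n - 2 * sum_i (n+1-i) x_(i) / (n * sum x), values ascending.
    """
    x = _profile_values(profile)
    total = x.sum()
    if total == 0:
        return float("nan")
    n = x.size
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    return float((n + 1) / n - 2.0 * ((n + 1 - i) * xs).sum() / (n * total))


def tau(profile) -> float:
    """Tau specificity: sum(1 - x_i / max) / (n - 1); 0 uniform, 1 one-hot."""
    x = _profile_values(profile)
    if x.size < 2:
        raise ValueError("tau needs at least 2 states")
    m = x.max()
    if m == 0:
        return float("nan")
    return float((1.0 - x / m).sum() / (x.size - 1))


def tsi(profile) -> float:
    """Tissue specificity index: max(x_i) / sum(x_i); 1/n uniform, 1 one-hot."""
    x = _profile_values(profile)
    total = x.sum()
    if total == 0:
        return float("nan")
    return float(x.max() / total)


def _entropy2(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def jsd_score(profile, target_state=None):
    """Jensen-Shannon specificity score against a one-hot reference pattern.

    The profile is normalized to a probability vector p; for each state t the
    score is ``1 - sqrt(JS(p, e_t))`` where ``e_t`` is the distribution with
    all mass in t and JS is the Jensen-Shannon divergence with base-2
    entropy (so the score stays in [0, 1]). Returns the per-state Series,
    or a single float when ``target_state`` is given. The overall tissue
    specificity is the maximum over states (``jsd_score(profile).max()``).
    """
    x = _profile_values(profile)
    index = profile.index if isinstance(profile, pd.Series) else np.arange(x.size)
    total = x.sum()
    if total == 0:
        out = pd.Series(np.full(x.size, np.nan), index=index)
        return float("nan") if target_state is not None else out
    p = x / total
    hp = _entropy2(p)
    scores = np.empty(x.size)
    for t in range(x.size):
        e = np.zeros(x.size)
        e[t] = 1.0
        js = _entropy2((p + e) / 2.0) - hp / 2.0  # H(e_t) = 0
        scores[t] = 1.0 - np.sqrt(max(js, 0.0))
    out = pd.Series(scores, index=index)
    if target_state is not None:
        return float(out[target_state])
    return out


def score_all_metrics(
    counts: CountMatrix,
    grouping: SampleGrouping,
    prevalences: PrevalenceWeights | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-gene table of all six specificity metrics.

    Columns: ``SPECS_<state>`` (one per state, from raw replicates),
    ``zscore_<state>``, ``JSD_<state>``, ``JSD_max``, then single-valued
    ``Gini``, ``Tau``, ``TSI`` (from mean-collapsed profiles). Missing values
    (all-zero genes for ratio metrics, constant profiles for z) propagate as
    NaN, never silently zeroed.
    """
    grouping = grouping.align_to(counts.sample_ids)
    states = grouping.states
    specs = specs_score_matrix(counts, grouping, prevalences).scores
    idx = {d: grouping.indices(d) for d in states}
    means = np.column_stack([counts.values[:, idx[d]].mean(axis=1) for d in states])
    rows = []
    for gi, gene in enumerate(counts.gene_ids):
        prof = pd.Series(means[gi], index=states)
        z = zscore(prof, ddof=ddof)
        j = jsd_score(prof)
        row = {f"SPECS_{d}": specs.at[gene, d] for d in states}
        row.update({f"zscore_{d}": z[d] for d in states})
        row.update({f"JSD_{d}": j[d] for d in states})
        row["JSD_max"] = j.max() if not j.isna().all() else np.nan
        row["Gini"] = gini(prof)
        row["Tau"] = tau(prof)
        row["TSI"] = tsi(prof)
        rows.append(row)
    return pd.DataFrame(rows, index=counts.gene_ids)
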