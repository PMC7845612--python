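"""Paired significance tests and module-wise trait summaries.

Observed-vs-null comparisons are paired across rarefied versions (each
version contributes one observed and one null index value); group and
compartment comparisons are paired across replicate plots. Tests are
two-sided classical paired t tests; raw P values are reported, with an
optional Holm correction helper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateTestError, ValidationError
from .consensus import ConsensusReport

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedTestResult:
    """Classical paired t: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1."""

    t: float
    df: int
    p: float
    mean_diff: float
    n: int


@dataclass
class TraitSummary:
    """Per-module trait medians, min-max scaled per trait across modules."""

    medians: pd.DataFrame  # modules x traits, raw medians
    scaled: pd.DataFrame   # same shape, each trait scaled to [0, 1]


def paired_t(x, y) -> PairedTestResult:
    """Two-sided paired t test of x against y.

    Raises
    ------
    DegenerateTestError
        For fewer than two pairs or zero-variance differences (e.g. an
        index a null model preserves exactly).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 2:
        raise DegenerateTestError("paired t needs at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateTestError(
            "zero-variance differences: paired t degenerate"
        )
    res = sps.ttest_rel(x, y)
    return PairedTestResult(
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        mean_diff=float(d.mean()),
        n=n,
    )


def observed_vs_null(observed, nulls) -> PairedTestResult:
    """Paired test of per-version observed index values against the
    per-version null values (pairing unit = rarefied version)."""
    return paired_t(observed, nulls)


def compare_index_table(
    observed_df: pd.DataFrame,
    null_df: pd.DataFrame,
    comparison: str = "observed_vs_null",
) -> pd.DataFrame:
    """Paired tests for every shared index column; one row per index.

    Indices a null model preserves exactly (zero-variance differences)
    are reported as degenerate with p = NaN, mirroring diversity indices
    under the shuffle null.
    """
    rows = []
    for col in observed_df.columns:
        if col not in null_df.columns:
            continue
        obs = observed_df[col].to_numpy(dtype=float)
        nul = null_df[col].to_numpy(dtype=float)
        if np.isnan(obs).all() or np.isnan(nul).all():
            continue
        try:
            res = paired_t(obs, nul)
            rows.append(
                (comparison, col, res.t, res.df, res.p, res.mean_diff, False)
            )
        except DegenerateTestError:
            rows.append(
                (comparison, col, np.nan, len(obs) - 1, np.nan,
                 float(np.mean(obs - nul)), True)
            )
    return pd.DataFrame(
        rows,
        columns=["comparison", "index", "t", "df", "p", "mean_diff", "degenerate"],
    )


def holm_correction(pvalues) -> np.ndarray:
    """Holm step-down adjusted p values (optional; raw values are the default report)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    n = p.size
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def trait_summary(consensus: ConsensusReport, traits: pd.DataFrame) -> TraitSummary:
    """Module-wise trait medians over member trees, min-max scaled per
    trait across modules (zero-range traits scale to 0, logged)."""
    medians = {}
    for module, trees in sorted(consensus.module_trees.items()):
        missing = set(trees) - set(traits.index)
        if missing:
            raise ValidationError(f"trees missing from trait table: {sorted(missing)}")
        medians[module] = traits.loc[sorted(trees)].median(axis=0)
    med = pd.DataFrame(medians).T
    rng = med.max(axis=0) - med.min(axis=0)
    zero_range = rng[rng == 0].index.tolist()
    if zero_range:
        log.info("trait_summary: zero-range traits scaled to 0: %s", zero_range)
    safe = rng.replace(0, 1.0)
    scaled = (med - med.min(axis=0)) / safe
    scaled[zero_range] = 0.0
    return TraitSummary(med, scaled)
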