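"""Seed-controlled rarefaction ensembles and the ACE depth diagnostic.

Rarefaction draws, for every sample, a fixed number of reads without
replacement (multivariate hypergeometric), equalizing sampling effort
across samples. Because a single rarefied table is an arbitrary draw,
downstream analyses run independently on an ensemble of rarefied
versions; seeds are ``base_seed + version_index`` so any single version
can be regenerated in isolation.

ACE (abundance-based coverage estimator) estimates total community
richness from the frequency-of-frequency counts of rare species (classical
rare-abundance cutoff 10). The ratio of post-rarefaction observed richness
to the ACE estimate is reported as a depth diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedEstimatorError, ValidationError
from .otu_io import OtuTable

log = logging.getLogger(__name__)

ACE_RARE_CUTOFF = 10


@dataclass(frozen=True)
class RarefactionConfig:
    """Ensemble settings: per-sample depth, number of versions, base seed."""

    depth: int
    n_versions: int = 1000
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if self.n_versions < 1:
            raise ValidationError("n_versions must be >= 1")


@dataclass(frozen=True)
class AceResult:
    """ACE richness estimate with its intermediate quantities.

    s_ace = S_abund + S_rare / C_ace + (F1 / C_ace) * gamma_sq, where
    C_ace = 1 - F1 / N_rare is the sample coverage of the rare group and
    gamma_sq the (non-negative) squared coefficient of variation term.
    """

    s_ace: float
    s_abund: int
    s_rare: int
    n_rare: int
    f: tuple[int, ...]  # F1..F10
    c_ace: float
    gamma_sq: float


def ace_richness(abundances) -> AceResult:
    """Classical ACE richness estimate from per-OTU total abundances.

    Raises
    ------
    UndefinedEstimatorError
        If every rare species is a singleton (coverage 0) or the rare
        group holds <= 1 individual.
    """
    a = np.asarray(abundances)
    if a.size == 0 or np.any(a < 0) or not np.allclose(a, np.round(a)):
        raise ValidationError("abundances must be non-negative integers")
    a = np.round(a).astype(np.int64)
    a = a[a > 0]
    if a.size == 0:
        raise ValidationError("at least one positive abundance required")

    rare = a[a <= ACE_RARE_CUTOFF]
    s_abund = int(np.sum(a > ACE_RARE_CUTOFF))
    s_rare = int(rare.size)
    n_rare = int(rare.sum())
    f = tuple(int(np.sum(rare == i)) for i in range(1, ACE_RARE_CUTOFF + 1))

    if s_rare == 0:
        # fully abundant community: estimator reduces to observed richness
        return AceResult(float(s_abund), s_abund, 0, 0, f, 1.0, 0.0)
    if n_rare <= 1:
        raise UndefinedEstimatorError("ACE undefined: rare group holds <= 1 individual")
    c_ace = 1.0 - f[0] / n_rare
    if c_ace == 0.0:
        raise UndefinedEstimatorError("ACE undefined: all rare species are singletons")
    ssum = sum(i * (i - 1) * f[i - 1] for i in range(1, ACE_RARE_CUTOFF + 1))
    gamma_sq = max(s_rare * ssum / (c_ace * n_rare * (n_rare - 1)) - 1.0, 0.0)
    s_ace = s_abund + s_rare / c_ace + (f[0] / c_ace) * gamma_sq
    return AceResult(float(s_ace), s_abund, s_rare, n_rare, f, c_ace, gamma_sq)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Deterministic given ``seed``. OTU columns are kept (possibly all-zero
    after subsampling) so ensemble versions stay aligned.
    """
    totals = table.sample_totals()
    short = totals[totals < depth]
    if len(short):
        raise ValidationError(
            f"samples below depth {depth}: "
            + ", ".join(f"{s}({t})" for s, t in short.items())
        )
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy()
    out = np.empty_like(counts)
    for k in range(counts.shape[0]):
        out[k] = rng.multivariate_hypergeometric(counts[k], depth)
    rarefied = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return table.with_counts(rarefied)


def rarefaction_ensemble(table: OtuTable, config: RarefactionConfig):
    """Yield ``n_versions`` rarefied tables, version i seeded base_seed+i."""
    for i in range(config.n_versions):
        yield rarefy(table, config.depth, config.base_seed + i)


def coverage_ratio(table: OtuTable, depth: int, seed: int = 0) -> float:
    """Observed richness after one rarefaction at ``depth``, divided by the
    ACE estimate on the pooled unrarefied abundances.

    A depth diagnostic: the study design reports what share of the
    estimated community richness a chosen depth retains.
    """
    ace = ace_richness(table.otu_totals().to_numpy())
    rarefied = rarefy(table, depth, seed)
    observed = int((rarefied.otu_totals() > 0).sum())
    return observed / ace.s_ace
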