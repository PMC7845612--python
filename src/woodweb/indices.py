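"""Network-, group- and species-level topological indices.

All entropies use the natural logarithm. The two-dimensional
specialization index H2' rescales the Shannon entropy of the interaction
matrix between its marginal-constrained extremes: the independence
entropy H2max (outer product of availabilities, no specialization) and a
greedily packed minimum H2min (maximal specialization for the given
interaction totals), so H2' = (H2max - H) / (H2max - H2min) runs from 0
(no specialization) to 1 (perfect specialization). Species-level d' is
the Kullback-Leibler divergence of a species' realized partner
distribution from partner availability, normalized by its maximum
ln(m / A_i); generality is the abundance-weighted mean effective partner
number per side. The continuous (real-valued) formulation is used
throughout, since network weights are medians of proportions rather than
integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .network import InteractionMatrix

CLAMP_TOL = 1e-9


@dataclass
class NetworkIndices:
    """One record of network-level index values for a single network."""

    shannon: float
    interaction_evenness: float
    generality_rows: float
    generality_cols: float
    h2prime: float
    h2: float
    h2_min: float
    h2_max: float
    links: int
    connectance: float
    modularity: float | None = field(default=None)

    FIELDS = (
        "shannon",
        "interaction_evenness",
        "generality_rows",
        "generality_cols",
        "h2prime",
        "h2",
        "h2_min",
        "h2_max",
        "modularity",
        "links",
        "connectance",
    )

    def as_series(self) -> pd.Series:
        return pd.Series({f: getattr(self, f) for f in self.FIELDS}, dtype=float)


@dataclass
class SpeciesSpecialization:
    """Per-species d, d_max and normalized d' along one axis."""

    labels: list[str]
    d: np.ndarray
    d_max: np.ndarray
    dprime: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"d": self.d, "d_max": self.d_max, "dprime": self.dprime},
            index=self.labels,
        )


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats of a (not necessarily normalized) mass vector."""
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def shannon_entries(M: InteractionMatrix) -> float:
    """Shannon diversity of the network entries, H = -sum p_ij ln p_ij."""
    return _entropy(M.p.ravel())


def interaction_evenness(M: InteractionMatrix, mode: str = "prod") -> float:
    """Shannon evenness of network entries.

    ``prod`` divides H by ln(n_rows * n_cols) (all cells as potential
    interactions); ``sum`` divides by ln(L) (realized links only).
    """
    H = shannon_entries(M)
    if mode == "prod":
        denom = np.log(M.shape[0] * M.shape[1])
    elif mode == "sum":
        denom = np.log(M.links)
    else:
        raise ValidationError(f"unknown evenness mode {mode!r}")
    if denom <= 0:
        raise ValidationError("evenness undefined: single-cell denominator")
    return H / denom


def effective_partners(v) -> float:
    """Effective number of partners: exp of the Shannon entropy of v."""
    v = np.asarray(v, dtype=float)
    s = v.sum()
    if s <= 0:
        raise ValidationError("all-zero partner vector")
    return float(np.exp(_entropy(v / s)))


def generality(M: InteractionMatrix, axis: str = "rows", method: str = "mean_effective") -> float:
    """Weighted mean effective partner number for one side of the network.

    For ``rows`` (trees): sum_i (A_i/m) * exp(H of row i) — the mean
    effective number of associated OTUs per tree, abundance-weighted.
    ``method="exp_mean_entropy"`` instead exponentiates the weighted mean
    row entropy, exp(sum_i (A_i/m) H_i); the two agree on uniform rows.
    """
    if axis == "rows":
        vectors, weights = M.weights, M.r
    elif axis == "cols":
        vectors, weights = M.weights.T, M.c
    else:
        raise ValidationError(f"axis must be 'rows' or 'cols', got {axis!r}")
    ent = np.array([_entropy(v / v.sum()) if v.sum() > 0 else 0.0 for v in vectors])
    if method == "mean_effective":
        return float(np.sum(weights * np.exp(ent)))
    if method == "exp_mean_entropy":
        return float(np.exp(np.sum(weights * ent)))
    raise ValidationError(f"unknown generality method {method!r}")


def h2_bounds(M: InteractionMatrix) -> tuple[float, float]:
    """(h2_min, h2_max): marginal-constrained entropy extremes.

    h2_max is the entropy of the outer product of the marginal
    availabilities (independence). h2_min greedily packs the mass:
    repeatedly pair the largest remaining row total with the largest
    remaining column total and place min(row, col) there, giving a
    maximally concentrated matrix with the same marginals.
    """
    r, c = M.r.copy(), M.c.copy()
    h2_max = _entropy(np.outer(r, c).ravel())

    # greedy maximally-packed matrix
    cells = []
    r_rem, c_rem = r.copy(), c.copy()
    # tolerance guards against float dust driving extra microscopic cells
    tol = 1e-12
    while True:
        i = int(np.argmax(r_rem))
        j = int(np.argmax(c_rem))
        amount = min(r_rem[i], c_rem[j])
        if amount <= tol:
            break
        cells.append(amount)
        r_rem[i] -= amount
        c_rem[j] -= amount
    h2_min = _entropy(np.asarray(cells))
    # packing can only concentrate mass, never beyond independence
    h2_min = min(h2_min, h2_max)
    return h2_min, h2_max


def h2prime(M: InteractionMatrix) -> float:
    """Two-dimensional network specialization H2' in [0, 1]."""
    h2_min, h2_max = h2_bounds(M)
    H = shannon_entries(M)
    span = h2_max - h2_min
    if span < CLAMP_TOL:
        return 0.0
    return float(np.clip((h2_max - H) / span, 0.0, 1.0))


def dprime(M: InteractionMatrix, axis: str = "rows") -> SpeciesSpecialization:
    """Species-level specialization d' along one axis.

    d_i = sum_j (a_ij/A_i) ln[(a_ij/A_i) / c_j] (KL divergence of the
    realized partner distribution from partner availability), normalized
    by d_max_i = ln(m / A_i); d' is clamped to [0, 1], with d' = 0 when
    d_max is 0 (a species holding all interaction mass).
    """
    if axis == "rows":
        W, avail, labels = M.weights, M.c, M.row_labels
    elif axis == "cols":
        W, avail, labels = M.weights.T, M.r, M.col_labels
    else:
        raise ValidationError(f"axis must be 'rows' or 'cols', got {axis!r}")
    totals = W.sum(axis=1)
    if np.any(totals <= 0):
        raise ValidationError("species with zero total on the chosen axis")
    m = M.m
    d = np.empty(len(totals))
    d_max = np.log(m / totals)
    for k, row in enumerate(W):
        p = row / totals[k]
        nz = p > 0
        d[k] = float(np.sum(p[nz] * np.log(p[nz] / avail[nz])))
    with np.errstate(divide="ignore", invalid="ignore"):
        dp = np.where(d_max > CLAMP_TOL, d / np.where(d_max > 0, d_max, 1.0), 0.0)
    dp = np.clip(dp, 0.0, 1.0)
    return SpeciesSpecialization(list(labels), d, d_max, dp)


def network_level(M: InteractionMatrix, evenness_mode: str = "prod") -> NetworkIndices:
    """All network-level indices for one network (modularity left unset;
    it is filled by the modularity optimizer)."""
    H = shannon_entries(M)
    h2_min, h2_max = h2_bounds(M)
    span = h2_max - h2_min
    h2p = 0.0 if span < CLAMP_TOL else float(np.clip((h2_max - H) / span, 0.0, 1.0))
    return NetworkIndices(
        shannon=H,
        interaction_evenness=interaction_evenness(M, evenness_mode),
        generality_rows=generality(M, "rows"),
        generality_cols=generality(M, "cols"),
        h2prime=h2p,
        h2=H,
        h2_min=h2_min,
        h2_max=h2_max,
        links=M.links,
        connectance=M.connectance,
    )
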