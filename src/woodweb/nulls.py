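"""Null models: constraint-differing randomizations of a network.

Three complementary randomizations benchmark observed topology:

* **patefield** — fixed-marginal contingency-table null: keeps the exact
  row and column sums (the abundance distribution) but not the number of
  links. Built by sequential multivariate-hypergeometric row filling, the
  classical fixed-margin table sampler. Requires integer weights
  (discretize quantitative networks with
  :func:`woodweb.network.to_integer_matrix` first).
* **vazquez** — connectance-preserving abundance-weighted null: keeps the
  number of links and the grand total, placing links with probability
  proportional to the product of marginal availabilities, without
  reproducing exact marginals; no row or column is left empty.
* **shuffle** — keeps connectance and the multiset of nonzero weights but
  permutes them over a random cell subset, strongly changing the
  abundance distribution (diversity indices that depend only on the value
  multiset are left unchanged by construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .indices import NetworkIndices, network_level
from .network import InteractionMatrix

log = logging.getLogger(__name__)

METHODS = ("patefield", "vazquez", "shuffle")


def patefield_null(M: InteractionMatrix, seed: int) -> InteractionMatrix:
    """Random contingency table with exactly M's row and column sums."""
    if not M.is_integer():
        raise ValidationError(
            "patefield_null needs integer weights; apply to_integer_matrix first"
        )
    W = np.round(M.weights).astype(np.int64)
    rng = np.random.default_rng(seed)
    col_rem = W.sum(axis=0).copy()
    row_tot = W.sum(axis=1)
    out = np.zeros_like(W)
    for i in range(W.shape[0] - 1):
        draw = rng.multivariate_hypergeometric(col_rem, int(row_tot[i]))
        out[i] = draw
        col_rem -= draw
    out[-1] = col_rem
    return InteractionMatrix(out.astype(float), list(M.row_labels), list(M.col_labels))


def vazquez_null(M: InteractionMatrix, seed: int, n_quanta: int | None = None) -> InteractionMatrix:
    """Connectance-preserving abundance-weighted null.

    Chooses L distinct cells sequentially with probability proportional to
    r_i * c_j, guaranteeing no empty row or column, then distributes the
    grand total m over the chosen cells: one quantum each plus a
    multinomial placement of the remaining mass (probabilities again
    proportional to r_i * c_j). Output has exactly L nonzero cells and
    total m.
    """
    nr, nc = M.shape
    L = M.links
    if L < nr or L < nc:
        raise ValidationError(
            f"infeasible link count L={L} for shape {nr}x{nc}: every row and column needs a link"
        )
    rng = np.random.default_rng(seed)
    probs = np.outer(M.r, M.c).ravel()

    chosen = _choose_cells_connected(rng, probs, nr, nc, L)

    if n_quanta is None:
        n_quanta = int(round(M.m)) if M.is_integer() and M.m >= L else 10_000
    if n_quanta < L:
        raise ValidationError(f"n_quanta {n_quanta} < link count {L}")
    cell_probs = probs[chosen]
    cell_probs = cell_probs / cell_probs.sum()
    quanta = np.ones(L, dtype=np.int64)
    quanta += rng.multinomial(n_quanta - L, cell_probs)
    out = np.zeros(nr * nc)
    out[chosen] = quanta * (M.m / n_quanta)
    return InteractionMatrix(
        out.reshape(nr, nc), list(M.row_labels), list(M.col_labels)
    )


def _choose_cells_connected(rng, probs, nr, nc, L):
    """Sequentially pick L distinct cells with prob ~ probs, rejecting picks
    that would make it impossible to give every row and column a link."""
    chosen: list[int] = []
    taken = np.zeros(nr * nc, dtype=bool)
    row_deg = np.zeros(nr, dtype=np.int64)
    col_deg = np.zeros(nc, dtype=np.int64)
    for step in range(L):
        remaining = L - step
        need = int(np.sum(row_deg == 0)) + int(np.sum(col_deg == 0))
        p = probs.copy()
        p[taken] = 0.0
        if need >= remaining:
            # no slack: only cells covering an empty row or column qualify
            rows_ok = row_deg == 0
            cols_ok = col_deg == 0
            mask = rows_ok[:, None] | cols_ok[None, :]
            # when both counts must drop, require cells covering an empty
            # row AND column if their joint need exceeds the budget
            if need > remaining:
                mask = rows_ok[:, None] & cols_ok[None, :]
            p[~mask.ravel()] = 0.0
        s = p.sum()
        if s <= 0:
            raise ValidationError("vazquez placement infeasible (no admissible cell)")
        idx = rng.choice(nr * nc, p=p / s)
        chosen.append(int(idx))
        taken[idx] = True
        row_deg[idx // nc] += 1
        col_deg[idx % nc] += 1
    return np.array(chosen)


def shuffle_null(M: InteractionMatrix, seed: int) -> InteractionMatrix:
    """Permute the multiset of nonzero weights over a random cell subset.

    Connectance and the value multiset are preserved exactly; marginals
    generally are not (a row may end up with no links, which is logged).
    """
    rng = np.random.default_rng(seed)
    nr, nc = M.shape
    values = M.weights[M.weights > 0]
    cells = rng.choice(nr * nc, size=values.size, replace=False)
    values = rng.permutation(values)
    out = np.zeros(nr * nc)
    out[cells] = values
    out = out.reshape(nr, nc)
    empty_rows = int(np.sum(out.sum(axis=1) == 0))
    empty_cols = int(np.sum(out.sum(axis=0) == 0))
    if empty_rows or empty_cols:
        log.info(
            "shuffle_null: %d empty rows, %d empty cols after shuffling",
            empty_rows, empty_cols,
        )
    return InteractionMatrix(out, list(M.row_labels), list(M.col_labels))


def patefield_table_null(table, seed: int):
    """Fixed-marginal randomization of an integer OTU count table.

    Preserves every sample's depth and every OTU's total count exactly,
    destroying any sample-OTU association. Propagating the result through
    the same network construction as the observed data gives a paired
    null whose construction-induced index biases cancel, avoiding the
    arbitrary quantum scale a matrix-level discretization would impose.
    """
    M = InteractionMatrix(
        table.counts.to_numpy(dtype=float),
        list(table.counts.index),
        list(table.counts.columns),
    )
    null_M = patefield_null(M, seed)
    counts = pd.DataFrame(
        null_M.weights.astype(np.int64),
        index=table.counts.index,
        columns=table.counts.columns,
    )
    return table.with_counts(counts)


_NULL_FUNCS = {
    "patefield": patefield_null,
    "vazquez": vazquez_null,
    "shuffle": shuffle_null,
}


@dataclass
class NullEnsemble:
    """n null matrices plus the per-index value distributions."""

    method: str
    n: int
    seed: int
    matrices: list[InteractionMatrix]
    index_records: list[NetworkIndices] = field(default_factory=list)

    @property
    def index_distributions(self) -> pd.DataFrame:
        return pd.DataFrame([rec.as_series() for rec in self.index_records])


def null_ensemble(
    M: InteractionMatrix,
    method: str,
    n: int,
    seed: int,
    compute_indices: bool = True,
) -> NullEnsemble:
    """n null matrices seeded seed+0 .. seed+n-1 with their index records."""
    if method not in _NULL_FUNCS:
        raise ValidationError(f"unknown null method {method!r}; use one of {METHODS}")
    func = _NULL_FUNCS[method]
    target = M
    if method == "patefield" and not M.is_integer():
        raise ValidationError(
            "patefield ensembles need integer weights; apply to_integer_matrix first"
        )
    matrices = [func(target, seed + i) for i in range(n)]
    records = [network_level(Mi) for Mi in matrices] if compute_indices else []
    return NullEnsemble(method, n, seed, matrices, records)
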