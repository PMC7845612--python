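"""Construction of weighted tree x OTU interaction matrices.

A network cell (tree i, OTU j) is the median over that tree's replicate
logs of OTU j's relative abundance, making the network robust to
replicate-to-replicate variation. Rows are the resource side (trees),
columns the colonizer side (OTUs), fixed throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .otu_io import OtuTable

log = logging.getLogger(__name__)


@dataclass
class InteractionMatrix:
    """Non-negative weighted bipartite matrix, trees (rows) x OTUs (cols).

    Carries labels and exposes the marginal quantities every index and
    null model consumes: grand total ``m``, row/column totals, cell
    proportions ``p`` and row/column availabilities ``r``/``c``.
    """

    weights: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise ValidationError("weights must be a 2-D matrix")
        if np.any(w < 0) or not np.isfinite(w).all():
            raise ValidationError("weights must be finite and non-negative")
        if w.sum() <= 0:
            raise ValidationError("matrix total must be positive")
        if not self.row_labels:
            self.row_labels = [f"R{i}" for i in range(w.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"C{j}" for j in range(w.shape[1])]
        if len(self.row_labels) != w.shape[0] or len(self.col_labels) != w.shape[1]:
            raise ValidationError("label lengths do not match matrix shape")
        self.weights = w

    # -- marginal quantities ----------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    @property
    def m(self) -> float:
        """Grand total of interaction weight."""
        return float(self.weights.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.weights.sum(axis=0)

    @property
    def p(self) -> np.ndarray:
        """Cell proportions a_ij / m (sum to 1)."""
        return self.weights / self.m

    @property
    def r(self) -> np.ndarray:
        """Row availabilities A_i. / m."""
        return self.row_totals / self.m

    @property
    def c(self) -> np.ndarray:
        """Column availabilities A_.j / m."""
        return self.col_totals / self.m

    @property
    def links(self) -> int:
        """Number of nonzero cells L."""
        return int(np.count_nonzero(self.weights))

    @property
    def connectance(self) -> float:
        return self.links / (self.shape[0] * self.shape[1])

    def is_integer(self) -> bool:
        return bool(np.allclose(self.weights, np.round(self.weights)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.row_labels, columns=self.col_labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "InteractionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample proportions: each sample's counts divided by its total."""
    totals = table.sample_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"zero-total samples: {list(zero.index)}")
    return table.counts.div(totals, axis=0)


def build_network(table: OtuTable) -> InteractionMatrix:
    """Median-over-replicates network from a single-compartment table.

    Every (resource, replicate) pair must hold exactly one sample. OTUs
    whose column is all-zero are dropped; all-zero trees are dropped with
    a warning (they cannot carry interactions).
    """
    comps = table.sample_meta["compartment"].unique()
    if len(comps) > 1:
        raise ValidationError(
            f"table mixes compartments {sorted(comps)}; split it first"
        )
    pairs = table.sample_meta.groupby(["resource", "replicate"], sort=False).size()
    dup = pairs[pairs > 1]
    if len(dup):
        raise ValidationError(f"duplicate (resource, replicate) samples: {list(dup.index)}")

    rel = relative_abundance(table)
    resources = table.sample_meta["resource"]
    if resources.groupby(resources).size().min() < 1:
        raise ValidationError("a resource with zero replicates")
    med = rel.groupby(resources, sort=True).median()

    arr = med.to_numpy()
    keep_cols = arr.sum(axis=0) > 0
    keep_rows = arr.sum(axis=1) > 0
    if not keep_rows.all():
        lost = [t for t, k in zip(med.index, keep_rows) if not k]
        log.warning("build_network: dropping all-zero trees %s", lost)
    med = med.loc[med.index[keep_rows], med.columns[keep_cols]]
    return InteractionMatrix.from_dataframe(med)


def to_integer_matrix(M: InteractionMatrix, target_total: int = 10_000) -> InteractionMatrix:
    """Largest-remainder rounding of the weights to a fixed integer total.

    Needed so the fixed-marginal (Patefield) null applies to quantitative
    networks: cell quanta are a_ij * target_total / m rounded so the grand
    total equals ``target_total`` exactly; zero cells stay zero.
    """
    L = M.links
    if target_total < L:
        raise ValidationError(
            f"target_total {target_total} < number of nonzero cells {L}"
        )
    scaled = M.weights * (target_total / M.m)
    base = np.floor(scaled)
    remainder = int(round(target_total - base.sum()))
    out = base.copy()
    if remainder > 0:
        frac = (scaled - base).ravel()
        order = np.argsort(-frac, kind="stable")[:remainder]
        np.add.at(out.ravel(), order, 1)
    lost = int(np.sum((M.weights > 0) & (out == 0)))
    if lost:
        log.debug("to_integer_matrix: %d tiny cells rounded to 0 quanta", lost)
    return InteractionMatrix(out, list(M.row_labels), list(M.col_labels))


def write_edge_list(M: InteractionMatrix, path) -> None:
    """Persist the network as a weighted edge list TSV (tree, OTU, weight)."""
    rows = []
    nz = np.argwhere(M.weights > 0)
    for i, j in nz:
        rows.append((M.row_labels[i], M.col_labels[j], M.weights[i, j]))
    pd.DataFrame(rows, columns=["tree", "otu", "weight"]).to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> InteractionMatrix:
    df = pd.read_csv(path, sep="\t")
    wide = df.pivot_table(index="tree", columns="otu", values="weight", fill_value=0.0)
    return InteractionMatrix.from_dataframe(wide)


def write_dense(M: InteractionMatrix, path) -> None:
    M.to_dataframe().to_csv(path, sep="\t", index_label="tree")


def read_dense(path) -> InteractionMatrix:
    return InteractionMatrix.from_dataframe(pd.read_csv(path, sep="\t", index_col=0))
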