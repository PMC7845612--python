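"""Aggregation of indices and module partitions across a rarefaction ensemble.

Because every rarefied version yields its own network, indices are
reported as ensemble summaries (mean plus variability statistics) and
modules as a consensus: partitions are reduced to their tree-side
grouping (trees are few and stable, OTU membership churns under
rarefaction), the modal grouping across versions wins, and per-OTU
support statistics record how consistently each OTU sits in its
consensus module. Module identity across versions is matched by the set
of member trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .indices import NetworkIndices
from .modularity import ModulePartition
from .network import InteractionMatrix, relative_abundance
from .otu_io import OtuTable

log = logging.getLogger(__name__)

CONSENSUS_COLUMNS = (
    "Module",
    "present",
    "inBestModule",
    "percInBestModule",
    "meanAbundanceModuleSamples",
    "meanAbundanceOtherSamples",
    "relAbundanceModuleSamplesVsOthers",
)


@dataclass
class EnsembleIndexSummary:
    """Per-index mean, variance, sd, min, median, max over versions."""

    table: pd.DataFrame  # rows = indices, cols = the six statistics

    def as_frame(self) -> pd.DataFrame:
        return self.table


@dataclass
class ConsensusReport:
    """Per-OTU module support statistics plus module -> member-tree map."""

    otu_stats: pd.DataFrame  # indexed by OTU id, CONSENSUS_COLUMNS
    module_trees: dict[str, frozenset[str]]
    consensus: ModulePartition

    def write(self, path) -> None:
        self.otu_stats.to_csv(path, sep="\t", index_label="OTU")


def summarize_indices(records) -> EnsembleIndexSummary:
    """Mean and variability statistics of index values over versions.

    Variance is the sample variance (ddof=1); a single record yields
    sd = 0 by convention (logged).
    """
    records = list(records)
    if not records:
        raise ValidationError("summarize_indices needs at least one record")
    if isinstance(records[0], NetworkIndices):
        df = pd.DataFrame([r.as_series() for r in records])
    else:
        df = pd.DataFrame(records)
    if len(df) == 1:
        log.info("summarize_indices: single record, sd set to 0 by convention")
        var = pd.Series(0.0, index=df.columns)
    else:
        var = df.var(axis=0, ddof=1)
    table = pd.DataFrame(
        {
            "mean": df.mean(axis=0),
            "variance": var,
            "sd": np.sqrt(var),
            "min": df.min(axis=0),
            "median": df.median(axis=0),
            "max": df.max(axis=0),
        }
    )
    return EnsembleIndexSummary(table)


def best_supported_partition(partitions) -> ModulePartition:
    """The modal tree-side grouping across versions.

    Each version's partition is reduced to its grouping of trees; the
    most frequent grouping wins, ties broken by higher mean Q then by
    lexicographically smallest grouping. Among versions carrying the
    winning grouping, the highest-Q partition is returned as the
    representative (its OTU labels seed the consensus report).
    """
    partitions = list(partitions)
    if not partitions:
        raise ValidationError("no partitions to aggregate")
    by_grouping: dict[frozenset, list[ModulePartition]] = {}
    for p in partitions:
        by_grouping.setdefault(p.tree_grouping(), []).append(p)

    def sort_key(grouping):
        members = by_grouping[grouping]
        mean_q = float(np.mean([p.Q for p in members]))
        lex = sorted(tuple(sorted(g)) for g in grouping)
        return (-len(members), -mean_q, lex)

    winner = min(by_grouping, key=sort_key)
    ranked = sorted(by_grouping[winner], key=lambda p: -p.Q)
    if len(by_grouping) > 1:
        counts = sorted((len(v) for v in by_grouping.values()), reverse=True)
        if counts[0] == counts[1]:
            log.info("best_supported_partition: tie on support, broke by mean Q")
    return ranked[0]


def _module_key(partition: ModulePartition, module: int) -> frozenset[str]:
    """Identity of a module: its set of member trees."""
    return frozenset(t for t, g in partition.row_modules.items() if g == module)


def consensus_modules(
    partitions,
    matrices,
    consensus: ModulePartition,
    table: OtuTable | None = None,
) -> ConsensusReport:
    """Per-OTU support statistics over the ensemble.

    For each OTU: ``present`` is the share of versions whose network
    contains it; its consensus module is the module (identified by member
    trees) it most often belongs to among the consensus partition's
    modules; ``inBestModule`` is the share of versions where it sits in
    that module, and ``percInBestModule = inBestModule / present``. When
    the unrarefied ``table`` is given, mean relative abundances inside
    and outside the module's member-tree samples are added, with their
    ratio (infinite when the outside mean is 0, reported as ``inf`` and
    logged).
    """
    partitions = list(partitions)
    matrices = list(matrices)
    if len(partitions) != len(matrices):
        raise ValidationError(
            f"version misalignment: {len(partitions)} partitions vs {len(matrices)} matrices"
        )
    n_versions = len(partitions)
    cons_modules = {}  # member-tree frozenset -> canonical module id
    for mod in set(consensus.row_modules.values()):
        cons_modules[_module_key(consensus, mod)] = mod

    present: dict[str, int] = {}
    in_module: dict[str, dict[frozenset, int]] = {}
    for part, M in zip(partitions, matrices):
        col_set = set(M.col_labels)
        for otu in col_set:
            present[otu] = present.get(otu, 0) + 1
        for otu, mod in part.col_modules.items():
            if otu not in col_set:
                continue
            key = _module_key(part, mod)
            if key in cons_modules:
                d = in_module.setdefault(otu, {})
                d[key] = d.get(key, 0) + 1

    module_names = {
        key: f"m{mod}" for key, mod in sorted(cons_modules.items(), key=lambda kv: kv[1])
    }
    rows = []
    for otu in sorted(present):
        pres = present[otu] / n_versions
        support = in_module.get(otu, {})
        if support:
            best_key = max(support, key=lambda k: (support[k], sorted(k)))
            in_best = support[best_key] / n_versions
        else:
            best_key, in_best = None, 0.0
        rows.append(
            {
                "OTU": otu,
                "Module": module_names.get(best_key, "unassigned"),
                "present": pres,
                "inBestModule": in_best,
                "percInBestModule": in_best / pres if pres > 0 else 0.0,
                "_module_key": best_key,
            }
        )
    stats = pd.DataFrame(rows).set_index("OTU")

    if table is not None:
        rel = relative_abundance(table)
        resource = table.sample_meta["resource"]
        mod_mean = np.full(len(stats), np.nan)
        other_mean = np.full(len(stats), np.nan)
        for k, (otu, row) in enumerate(stats.iterrows()):
            key = row["_module_key"]
            if key is None or otu not in rel.columns:
                continue
            in_mask = resource.isin(key).to_numpy()
            vals = rel[otu].to_numpy()
            mod_mean[k] = vals[in_mask].mean() if in_mask.any() else np.nan
            other_mean[k] = vals[~in_mask].mean() if (~in_mask).any() else np.nan
        stats["meanAbundanceModuleSamples"] = mod_mean
        stats["meanAbundanceOtherSamples"] = other_mean
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = mod_mean / other_mean
        n_inf = int(np.sum(np.isinf(ratio)))
        if n_inf:
            log.info("consensus_modules: %d OTUs absent outside their module (ratio inf)", n_inf)
        stats["relAbundanceModuleSamplesVsOthers"] = ratio
    else:
        for col in CONSENSUS_COLUMNS[4:]:
            stats[col] = np.nan

    stats = stats.drop(columns=["_module_key"])
    stats = stats[list(CONSENSUS_COLUMNS)]
    module_trees = {module_names[k]: k for k in cons_modules}
    return ConsensusReport(stats, module_trees, consensus)
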