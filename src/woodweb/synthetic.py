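"""Synthetic OTU tables with planted tree-OTU module structure.

The generator emulates the study design the pipeline assumes: a fixed
panel of deadwood tree species (13 by default), sampled in replicate
(3 plots) and optionally in two wood compartments, colonized by OTUs
whose base abundances follow a lognormal distribution. Trees are split
into K planted modules and every OTU is assigned to one; a
specialization dial s in [0, 1] sets the share of an OTU's expected mass
that falls on its own module's trees (the remainder is spread uniformly
over the other trees). Replicates receive multiplicative lognormal noise
and reads are drawn multinomially at a fixed depth, so generated tables
carry realistic compositional sampling noise while the ground truth
(planted maps and expected composition) is known exactly.

``specialization="equalizing"`` sets, per OTU, s = |its module| / n_trees,
which makes the expected composition exactly uniform across trees — the
no-structure reference point of the dial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .consensus import (
    ConsensusReport,
    EnsembleIndexSummary,
    best_supported_partition,
    consensus_modules,
    summarize_indices,
)
from .errors import ValidationError
from .indices import network_level
from .modularity import optimize_modules
from .network import build_network, to_integer_matrix
from .nulls import patefield_null, patefield_table_null, shuffle_null, vazquez_null
from .otu_io import OtuTable, split_table
from .rarefaction import rarefy
from .stats import compare_index_table

# the study panel: nine broadleaved genera and four conifers
TREE_PANEL = (
    "Acer", "Betula", "Carpinus", "Fagus", "Fraxinus", "Populus", "Prunus",
    "Quercus", "Tilia", "Larix", "Picea", "Pinus", "Pseudotsuga",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults mirror the emulated study design."""

    n_trees: int = 13
    n_otus: int = 300
    n_modules: int = 4
    specialization: float | str = 0.9
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    replicate_noise_cv: float = 0.03
    n_replicates: int = 3
    depth: int = 20_000
    compartments: tuple[str, ...] = ("sapwood",)
    distinct_partitions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules > self.n_trees:
            raise ValidationError("n_modules K must not exceed n_trees")
        if isinstance(self.specialization, str):
            if self.specialization != "equalizing":
                raise ValidationError(
                    "specialization must be a float in [0,1] or 'equalizing'"
                )
        elif not 0.0 <= self.specialization <= 1.0:
            raise ValidationError("specialization must lie in [0, 1]")
        if self.n_trees < 1 or self.n_otus < 1 or self.depth < 1 or self.n_replicates < 1:
            raise ValidationError("all counts must be positive")

    def tree_names(self) -> list[str]:
        if self.n_trees <= len(TREE_PANEL):
            return list(TREE_PANEL[: self.n_trees])
        return [f"Tree{i:02d}" for i in range(1, self.n_trees + 1)]

    def otu_names(self) -> list[str]:
        return [f"OTU{j:04d}" for j in range(1, self.n_otus + 1)]


@dataclass
class GroundTruth:
    """Planted maps and the expected per-tree community composition."""

    tree_modules: dict[str, int]
    otu_modules: dict[str, int]
    expected: pd.DataFrame  # trees x OTUs, rows sum to 1
    module_sizes: list[int] = field(default_factory=list)


def generate_expected_matrix(
    config: SyntheticConfig, rng: np.random.Generator | None = None,
    shuffle_trees: bool = False,
) -> GroundTruth:
    """Plant modules and OTU base abundances; return the expected
    per-tree composition (rows normalized to 1)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    trees = config.tree_names()
    otus = config.otu_names()
    T, K = config.n_trees, config.n_modules

    order = list(rng.permutation(T)) if shuffle_trees else list(range(T))
    # near-equal split: the first (T mod K) modules get one extra tree
    sizes = [T // K + (1 if k < T % K else 0) for k in range(K)]
    tree_modules: dict[str, int] = {}
    pos = 0
    for k, sz in enumerate(sizes):
        for idx in order[pos : pos + sz]:
            tree_modules[trees[idx]] = k
        pos += sz

    otu_modules = {otu: j % K for j, otu in enumerate(otus)}
    base = rng.lognormal(config.abundance_mu, config.abundance_sigma, size=config.n_otus)

    W = np.zeros((T, config.n_otus))
    tree_mod = np.array([tree_modules[t] for t in trees])
    for j, otu in enumerate(otus):
        k = otu_modules[otu]
        in_mod = tree_mod == k
        n_in = int(in_mod.sum())
        s = (n_in / T) if config.specialization == "equalizing" else float(config.specialization)
        W[in_mod, j] = base[j] * s / n_in
        if n_in < T:
            W[~in_mod, j] = base[j] * (1.0 - s) / (T - n_in)
    row_sums = W.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        raise ValidationError("a tree with zero expected mass; raise s < 1 or K < n_trees")
    expected = pd.DataFrame(W / row_sums, index=trees, columns=otus)
    return GroundTruth(tree_modules, otu_modules, expected, sizes)


def sample_counts(
    truth: GroundTruth,
    config: SyntheticConfig,
    compartment: str = "sapwood",
    rng: np.random.Generator | None = None,
) -> OtuTable:
    """Draw tree x replicate samples: lognormal replicate noise on the
    expected composition, renormalized, then multinomial reads at depth."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    cv = config.replicate_noise_cv
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    mu = -0.5 * sigma * sigma  # unit-mean noise

    rows, ids, meta = [], [], []
    exp = truth.expected.to_numpy()
    for i, tree in enumerate(truth.expected.index):
        for r in range(1, config.n_replicates + 1):
            comp = exp[i].copy()
            if cv > 0:
                comp = comp * rng.lognormal(mu, sigma, size=comp.size)
            comp = comp / comp.sum()
            counts = rng.multinomial(config.depth, comp)
            rows.append(counts)
            ids.append(f"{tree}_{compartment}_r{r}")
            meta.append({"resource": tree, "compartment": compartment, "replicate": f"plot{r}"})
    counts = pd.DataFrame(np.array(rows), index=ids, columns=truth.expected.columns)
    sample_meta = pd.DataFrame(meta, index=ids)
    return OtuTable(counts, sample_meta)


def generate_dataset(config: SyntheticConfig) -> tuple[OtuTable, dict[str, GroundTruth]]:
    """One OtuTable covering all configured compartments plus per-
    compartment ground truth. With ``distinct_partitions`` every
    compartment gets its own planted tree grouping."""
    rng = np.random.default_rng(config.seed)
    tables, truths = [], {}
    for ci, comp in enumerate(config.compartments):
        truth = generate_expected_matrix(
            config, rng, shuffle_trees=config.distinct_partitions and ci > 0
        )
        truths[comp] = truth
        tables.append(sample_counts(truth, config, comp, rng))
    counts = pd.concat([t.counts for t in tables], axis=0)
    meta = pd.concat([t.sample_meta for t in tables], axis=0)
    return OtuTable(counts, meta), truths


@dataclass(frozen=True)
class PipelineSettings:
    """Settings for an end-to-end ensemble run on a synthetic table."""

    n_versions: int = 50
    depth: int | None = None  # rarefaction depth; default 1/20 of min sample total
    base_seed: int = 0
    null_method: str = "patefield"
    null_level: str = "table"  # patefield at table level (exact pairing) or "matrix"
    n_starts: int = 5
    target_total: int = 10_000
    compute_modularity: bool = True


@dataclass
class RecoveryReport:
    """Planted-vs-recovered scores and ensemble summaries."""

    summary: EnsembleIndexSummary
    null_summary: EnsembleIndexSummary
    tests: pd.DataFrame
    consensus: ConsensusReport | None
    tree_ari: float | None
    otu_ari: float | None
    observed: pd.DataFrame
    nulls: pd.DataFrame


_NULLS = {"patefield": patefield_null, "vazquez": vazquez_null, "shuffle": shuffle_null}


def run_ensemble(
    table: OtuTable,
    settings: PipelineSettings,
):
    """Rarefy -> build -> indices (+ null, + modules) per version.

    Returns (observed records, null records, partitions, matrices).
    """
    depth = settings.depth
    if depth is None:
        # shallow rarefaction relative to sequencing depth, mirroring the
        # deep-sequencing / shallow-rarefaction design the pipeline assumes;
        # it also keeps ensemble versions close to independent draws
        depth = max(1, int(table.sample_totals().min()) // 20)
    null_func = _NULLS[settings.null_method]
    obs_records, null_records, partitions, matrices = [], [], [], []
    for v in range(settings.n_versions):
        seed = settings.base_seed + v
        rarefied = rarefy(table, depth, seed)
        M = build_network(rarefied)
        rec = network_level(M)
        if settings.compute_modularity:
            part = optimize_modules(M, n_starts=settings.n_starts, seed=seed)
            rec.modularity = part.Q
            partitions.append(part)
        matrices.append(M)
        if settings.null_method == "patefield" and settings.null_level == "table":
            # randomize the integer count table, rebuild through the same
            # median construction: paired null with no quantum-scale artifact
            null_M = build_network(patefield_table_null(rarefied, seed + 1_000_000))
        else:
            null_target = M
            if settings.null_method == "patefield":
                null_target = to_integer_matrix(M, settings.target_total)
            null_M = null_func(null_target, seed + 1_000_000)
        null_rec = network_level(null_M)
        if settings.compute_modularity:
            null_part = optimize_modules(null_M, n_starts=settings.n_starts, seed=seed)
            null_rec.modularity = null_part.Q
        obs_records.append(rec)
        null_records.append(null_rec)
    return obs_records, null_records, partitions, matrices


def recovery_experiment(
    config: SyntheticConfig,
    settings: PipelineSettings = PipelineSettings(),
    compartment: str | None = None,
) -> RecoveryReport:
    """Full pipeline on one synthetic compartment with planted-truth scoring.

    Generates a dataset, runs the rarefaction ensemble (network, indices,
    one null per version, modules), aggregates the consensus and scores
    planted-vs-recovered agreement with the adjusted Rand index on tree
    and OTU module labels.
    """
    table, truths = generate_dataset(config)
    comp = compartment or config.compartments[0]
    truth = truths[comp]
    sub = split_table(table, "compartment")[comp]

    obs_records, null_records, partitions, matrices = run_ensemble(sub, settings)

    obs_df = pd.DataFrame([r.as_series() for r in obs_records])
    null_df = pd.DataFrame([r.as_series() for r in null_records])
    tests = compare_index_table(obs_df, null_df, f"observed_vs_{settings.null_method}")

    consensus_report = tree_ari = otu_ari = None
    if settings.compute_modularity:
        cons = best_supported_partition(partitions)
        consensus_report = consensus_modules(partitions, matrices, cons, table=sub)
        trees = sorted(cons.row_modules)
        tree_ari = float(adjusted_rand_score(
            [truth.tree_modules[t] for t in trees],
            [cons.row_modules[t] for t in trees],
        ))
        stats = consensus_report.otu_stats
        otus = list(stats.index)
        otu_ari = float(adjusted_rand_score(
            [truth.otu_modules[o] for o in otus],
            list(stats["Module"]),
        ))
    return RecoveryReport(
        summary=summarize_indices(obs_records),
        null_summary=summarize_indices(null_records),
        tests=tests,
        consensus=consensus_report,
        tree_ari=tree_ari,
        otu_ari=otu_ari,
        observed=obs_df,
        nulls=null_df,
    )


def specialization_sweep(
    config: SyntheticConfig,
    s_values,
    settings: PipelineSettings = PipelineSettings(),
) -> pd.DataFrame:
    """Mean H2', mean d' (trees) and modularity across a specialization
    sweep at fixed seeds; one row per s value."""
    from .indices import dprime  # local: avoids cycle at import time

    rows = []
    for s in s_values:
        cfg = replace(config, specialization=s)
        table, _ = generate_dataset(cfg)
        sub = split_table(table, "compartment")[cfg.compartments[0]]
        obs, _nulls, parts, mats = run_ensemble(sub, settings)
        h2 = float(np.mean([r.h2prime for r in obs]))
        q = float(np.mean([p.Q for p in parts])) if parts else np.nan
        mean_dp = float(np.mean([dprime(M, "rows").dprime.mean() for M in mats]))
        rows.append({"s": s, "h2prime": h2, "mean_dprime": mean_dp, "modularity": q})
    return pd.DataFrame(rows)


def fungus_like() -> SyntheticConfig:
    """Preset echoing a fungal community: fewer OTUs, high specialization."""
    return SyntheticConfig(n_otus=200, n_modules=8, specialization=0.95, seed=7)


def prokaryote_like() -> SyntheticConfig:
    """Preset echoing a prokaryotic community: more OTUs, low specialization."""
    return SyntheticConfig(n_otus=600, n_modules=4, specialization=0.5, seed=7)
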