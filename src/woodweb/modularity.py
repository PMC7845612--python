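"""Weighted bipartite (Barber/Newman) modularity and module search.

Q = (1/m) * sum_ij [a_ij - A_i. * A_.j / m] * delta(g_i, g_j), where the
sum runs over (row, column) pairs sharing a module label. Q is 0 for the
all-in-one partition of any matrix and approaches 1 - 1/k for k equal
diagonal blocks with matching modules.

The optimizer is multi-start greedy search: each start assigns random
labels, then alternates single-node relocation sweeps with pairwise
module merges until Q stops improving; the best partition over starts is
returned with canonicalized labels. Module count is emergent. For
matrices with at most 10 total nodes an exhaustive enumeration over all
set partitions of the combined node set serves as a ground-truth oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .network import InteractionMatrix

Q_TOL = 1e-12


@dataclass
class ModulePartition:
    """Joint module assignment of rows and columns plus its Q score.

    Labels are canonical: modules numbered by descending internal weight,
    ties by the lexicographically smallest member.
    """

    row_modules: dict[str, int]
    col_modules: dict[str, int]
    Q: float
    n_modules: int
    seed: int | None = None
    n_starts: int | None = None

    def labels_for(self, M: InteractionMatrix) -> tuple[np.ndarray, np.ndarray]:
        try:
            g_rows = np.array([self.row_modules[l] for l in M.row_labels])
            g_cols = np.array([self.col_modules[l] for l in M.col_labels])
        except KeyError as exc:
            raise ValidationError(f"partition lacks a label for node {exc}") from exc
        return g_rows, g_cols

    def tree_grouping(self) -> frozenset[frozenset[str]]:
        """The partition reduced to its row-side (tree) grouping."""
        groups: dict[int, set[str]] = {}
        for label, mod in self.row_modules.items():
            groups.setdefault(mod, set()).add(label)
        return frozenset(frozenset(g) for g in groups.values())


def _modularity_matrix(M: InteractionMatrix) -> np.ndarray:
    """B_ij = a_ij - A_i. A_.j / m."""
    return M.weights - np.outer(M.row_totals, M.col_totals) / M.m


def barber_Q(M: InteractionMatrix, g_rows, g_cols=None) -> float:
    """Barber modularity of a row/column labeling (arrays or a partition)."""
    if isinstance(g_rows, ModulePartition):
        g_rows, g_cols = g_rows.labels_for(M)
    elif g_cols is None:
        raise ValidationError("pass a ModulePartition or both label arrays")
    g_rows = np.asarray(g_rows)
    g_cols = np.asarray(g_cols)
    if g_rows.shape[0] != M.shape[0] or g_cols.shape[0] != M.shape[1]:
        raise ValidationError("label arrays do not match matrix shape")
    B = _modularity_matrix(M)
    same = g_rows[:, None] == g_cols[None, :]
    return float(np.sum(B[same]) / M.m)


def _canonicalize(M: InteractionMatrix, g_rows, g_cols, Q, seed=None, n_starts=None) -> ModulePartition:
    labels = np.concatenate([g_rows, g_cols])
    names = list(M.row_labels) + list(M.col_labels)
    sides = [0] * len(M.row_labels) + [1] * len(M.col_labels)
    weight_r = M.row_totals
    weight_c = M.col_totals
    node_w = np.concatenate([weight_r, weight_c])
    mods = {}
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        w = float(node_w[members].sum())
        first = min(names[k] for k in members)
        mods[lab] = (-w, first, members)
    order = sorted(mods, key=lambda lab: mods[lab][:2])
    remap = {lab: new for new, lab in enumerate(order)}
    row_modules = {}
    col_modules = {}
    for k, (name, side) in enumerate(zip(names, sides)):
        target = row_modules if side == 0 else col_modules
        target[name] = remap[labels[k]]
    return ModulePartition(
        row_modules, col_modules, float(Q), len(order), seed, n_starts
    )


def _refine(B: np.ndarray, m: float, g_rows: np.ndarray, g_cols: np.ndarray, rng) -> float:
    """Greedy single-node relocations + pairwise merges until Q is stable.

    Labels are modified in place; returns the final Q.
    """
    nr, nc = B.shape
    n = nr + nc

    def q_of() -> float:
        same = g_rows[:, None] == g_cols[None, :]
        return float(np.sum(B[same]) / m)

    def compact() -> int:
        """Relabel modules to 0..K-1 in place; return K."""
        uniq, inv = np.unique(np.concatenate([g_rows, g_cols]), return_inverse=True)
        g_rows[:] = inv[:nr]
        g_cols[:] = inv[nr:]
        return len(uniq)

    improved = True
    while improved:
        improved = False
        K = compact()
        # single-node relocation sweep (random order); gain of placing a
        # row i into module c is sum of B[i, j] over cols j in c, since Q
        # only couples row-col pairs sharing a label
        for node in rng.permutation(n):
            if node < nr:
                i = node
                gains = np.bincount(g_cols, weights=B[i], minlength=K)
                cur = g_rows[i]
            else:
                j = node - nr
                gains = np.bincount(g_rows, weights=B[:, j], minlength=K)
                cur = g_cols[j]
            best = int(np.argmax(gains))
            best_gain = gains[best]
            if best_gain < 0.0:
                best, best_gain = K, 0.0  # fresh singleton module
            if best_gain > gains[cur] + Q_TOL:
                if node < nr:
                    g_rows[i] = best
                else:
                    g_cols[j] = best
                if best == K:
                    K += 1
                improved = True
        # pairwise module merges
        labels_pool = list(np.unique(np.concatenate([g_rows, g_cols])))
        merged = True
        while merged and len(labels_pool) > 1:
            merged = False
            best_gain, best_pair = Q_TOL, None
            for a_idx in range(len(labels_pool)):
                for b_idx in range(a_idx + 1, len(labels_pool)):
                    a, b = labels_pool[a_idx], labels_pool[b_idx]
                    ra, ca = g_rows == a, g_cols == a
                    rb, cb = g_rows == b, g_cols == b
                    gain = B[np.ix_(ra, cb)].sum() + B[np.ix_(rb, ca)].sum()
                    if gain > best_gain:
                        best_gain, best_pair = gain, (a, b)
            if best_pair is not None:
                a, b = best_pair
                g_rows[g_rows == b] = a
                g_cols[g_cols == b] = a
                labels_pool.remove(b)
                merged = True
                improved = True
    return q_of()


def optimize_modules(
    M: InteractionMatrix, n_starts: int = 20, seed: int = 0
) -> ModulePartition:
    """Multi-start greedy search for the Q-maximal bipartite partition.

    Deterministic given ``seed``. The all-in-one partition (Q = 0) is
    always a candidate, so the returned Q is never negative.
    """
    B = _modularity_matrix(M)
    m = M.m
    nr, nc = M.shape
    rng = np.random.default_rng(seed)

    best_q = 0.0
    best = (np.zeros(nr, dtype=np.int64), np.zeros(nc, dtype=np.int64))

    starts = []
    # deterministic seeds: singletons, and each column joining its best row
    starts.append((np.arange(nr), nr + np.arange(nc)))
    starts.append((np.arange(nr), np.argmax(M.weights, axis=0)))
    for _ in range(max(0, n_starts - len(starts))):
        k = int(rng.integers(1, nr + nc + 1))
        starts.append(
            (rng.integers(0, k, size=nr), rng.integers(0, k, size=nc))
        )
    for g0_rows, g0_cols in starts[:max(n_starts, 2)]:
        g_rows = np.asarray(g0_rows, dtype=np.int64).copy()
        g_cols = np.asarray(g0_cols, dtype=np.int64).copy()
        q = _refine(B, m, g_rows, g_cols, rng)
        if q > best_q + Q_TOL:
            best_q = q
            best = (g_rows.copy(), g_cols.copy())

    # iterated local search: perturb the incumbent and re-refine, escaping
    # local optima the plain multi-start misses
    for _ in range(max(n_starts, 2)):
        g_rows, g_cols = best[0].copy(), best[1].copy()
        labels = np.concatenate([g_rows, g_cols])
        n_kick = max(1, int(rng.integers(1, max(2, (nr + nc) // 3 + 1))))
        victims = rng.choice(nr + nc, size=n_kick, replace=False)
        fresh = labels.max() + 1
        for v in victims:
            new = int(rng.integers(0, fresh + 1))
            if v < nr:
                g_rows[v] = new
            else:
                g_cols[v - nr] = new
        q = _refine(B, m, g_rows, g_cols, rng)
        if q > best_q + Q_TOL:
            best_q = q
            best = (g_rows.copy(), g_cols.copy())
    return _canonicalize(M, best[0], best[1], best_q, seed=seed, n_starts=n_starts)


def _partitions_rgs(n: int):
    """All set partitions of range(n) as restricted-growth label arrays."""
    a = np.zeros(n, dtype=np.int64)
    b = np.zeros(n, dtype=np.int64)  # b[i] = max(a[:i+1])
    yield a.copy()
    while True:
        # find rightmost position that can be incremented
        i = n - 1
        while i > 0 and a[i] == b[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        b[i] = max(b[i - 1], a[i])
        for j in range(i + 1, n):
            a[j] = 0
            b[j] = b[i]
        yield a.copy()


def exhaustive_modules(M: InteractionMatrix) -> ModulePartition:
    """Enumerate every set partition of the combined node set, return the
    Q-maximal one. Test oracle; limited to 10 total nodes."""
    nr, nc = M.shape
    n = nr + nc
    if n > 10:
        raise ValidationError(f"exhaustive search limited to 10 nodes, got {n}")
    B = _modularity_matrix(M)
    m = M.m
    all_parts = np.array(list(_partitions_rgs(n)))
    g_rows = all_parts[:, :nr]
    g_cols = all_parts[:, nr:]
    same = g_rows[:, :, None] == g_cols[:, None, :]
    qs = (same * B[None, :, :]).sum(axis=(1, 2)) / m
    k = int(np.argmax(qs))
    return _canonicalize(M, g_rows[k], g_cols[k], float(qs[k]))
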