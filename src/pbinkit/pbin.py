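"""Bipartite phage-bacteria interaction networks and their topology statistics.

The central object is a binary incidence matrix of bacterial genomes (or
species-level bacterial OTUs) by viral OTUs.  This module provides Barber's
bipartite modularity, an LP-BRIM module search (label propagation seeding
followed by BRIM alternation), majority-rule module assignment at the OTU
level, NODF nestedness, probabilistic-degree null models with an empirical
two-sided significance test, and a local-neighborhood module-purity statistic
for auxiliary (e.g., proteome-sharedness) networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "BipartiteNetwork",
    "ModulePartition",
    "NestednessResult",
    "NeighborhoodPurity",
    "barber_modularity",
    "lp_brim",
    "assign_modules_majority",
    "nodf",
    "null_model",
    "nestedness_test",
    "neighborhood_purity",
]


@dataclass
class BipartiteNetwork:
    """Binary bipartite incidence matrix with labeled rows and columns.

    Rows are bacterial genomes or bOTUs, columns are vOTUs.  Entries are 0/1;
    an entry of 1 records an inferred infection link.  Optional per-edge
    evidence labels ("crispr", "homology", "both") can be attached.
    """

    row_labels: list[str]
    col_labels: list[str]
    matrix: np.ndarray
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.row_labels)} rows x {len(self.col_labels)} columns"
            )
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("incidence matrix must be binary")
        self.matrix = self.matrix.astype(np.int8)

    # -- degree structure ---------------------------------------------------
    @property
    def row_degrees(self) -> np.ndarray:
        return self.matrix.sum(axis=1).astype(np.int64)

    @property
    def col_degrees(self) -> np.ndarray:
        return self.matrix.sum(axis=0).astype(np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    # -- construction / IO --------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        evidence: Mapping[tuple[str, str], str] | None = None,
        row_labels: Sequence[str] | None = None,
        col_labels: Sequence[str] | None = None,
    ) -> "BipartiteNetwork":
        edges = list(edges)
        rows = list(row_labels) if row_labels is not None else sorted({r for r, _ in edges})
        cols = list(col_labels) if col_labels is not None else sorted({c for _, c in edges})
        ri = {r: i for i, r in enumerate(rows)}
        ci = {c: j for j, c in enumerate(cols)}
        mat = np.zeros((len(rows), len(cols)), dtype=np.int8)
        for r, c in edges:
            mat[ri[r], ci[c]] = 1
        return cls(rows, cols, mat, dict(evidence or {}))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BipartiteNetwork":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.row_labels, columns=self.col_labels)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="bacteria")

    @classmethod
    def read_tsv(cls, path) -> "BipartiteNetwork":
        return cls.from_dataframe(pd.read_csv(path, sep="\t", index_col=0))

    def subnetwork(self, rows: Sequence[str], cols: Sequence[str]) -> "BipartiteNetwork":
        ri = [self.row_labels.index(r) for r in rows]
        ci = [self.col_labels.index(c) for c in cols]
        return BipartiteNetwork(list(rows), list(cols), self.matrix[np.ix_(ri, ci)])


@dataclass
class ModulePartition:
    """Assignment of every row and column node to an interaction module.

    Module ids are contiguous integers starting at 1.  ``q`` is the Barber
    modularity of the partition on the network it was fitted to.
    """

    row_modules: dict[str, int]
    col_modules: dict[str, int]
    q: float

    @property
    def n_modules(self) -> int:
        return len(set(self.row_modules.values()) | set(self.col_modules.values()))

    def module_members(self, module: int) -> tuple[list[str], list[str]]:
        rows = [r for r, m in self.row_modules.items() if m == module]
        cols = [c for c, m in self.col_modules.items() if m == module]
        return rows, cols

    def to_dataframe(self) -> pd.DataFrame:
        recs = [(n, "row", m) for n, m in self.row_modules.items()]
        recs += [(n, "column", m) for n, m in self.col_modules.items()]
        return pd.DataFrame(recs, columns=["node", "side", "module"])

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class NestednessResult:
    module: object
    observed_nodf: float
    null_mean: float
    null_ci: tuple[float, float]
    p_value: float
    p_adjusted: float
    n_null: int


@dataclass
class NeighborhoodPurity:
    node: str
    neighborhood_size: int
    purity: float  # NaN when the neighborhood is empty


# ---------------------------------------------------------------------------
# Barber modularity
# ---------------------------------------------------------------------------

def _partition_vectors(
    network: BipartiteNetwork, partition: ModulePartition
) -> tuple[np.ndarray, np.ndarray]:
    try:
        g = np.array([partition.row_modules[r] for r in network.row_labels])
        h = np.array([partition.col_modules[c] for c in network.col_labels])
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"partition does not cover node {exc}") from exc
    return g, h


def barber_modularity(network: BipartiteNetwork, partition: ModulePartition) -> float:
    """Barber's bipartite modularity Q of a given partition.

    Q = (1/m) * sum_ij (A_ij - k_i d_j / m) * [g_i == h_j],
    where m is the total number of edges and k, d are row/column degrees.
    Q is 0 for the trivial single-module partition and approaches 1 for a
    perfectly modular network with many modules.
    """
    m = network.n_edges
    if m == 0:
        raise ValueError("modularity is undefined for an empty network")
    g, h = _partition_vectors(network, partition)
    return _q_from_vectors(network.matrix, g, h, m)


def _q_from_vectors(A: np.ndarray, g: np.ndarray, h: np.ndarray, m: int) -> float:
    k = A.sum(axis=1, dtype=np.float64)
    d = A.sum(axis=0, dtype=np.float64)
    same = g[:, None] == h[None, :]
    B = A - np.outer(k, d) / m
    return float((B * same).sum() / m)


# ---------------------------------------------------------------------------
# LP-BRIM module search
# ---------------------------------------------------------------------------

def _label_propagation(A: np.ndarray, rng: np.random.Generator, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Synchronous bipartite label propagation; ties broken at random."""
    R, C = A.shape
    g = np.arange(R)
    h = np.arange(R, R + C)
    for _ in range(max_iter):
        new_g = g.copy()
        for i in range(R):
            nb = np.flatnonzero(A[i])
            if nb.size == 0:
                continue
            labels, counts = np.unique(h[nb], return_counts=True)
            best = labels[counts == counts.max()]
            new_g[i] = rng.choice(best)
        new_h = h.copy()
        for j in range(C):
            nb = np.flatnonzero(A[:, j])
            if nb.size == 0:
                continue
            labels, counts = np.unique(new_g[nb], return_counts=True)
            best = labels[counts == counts.max()]
            new_h[j] = rng.choice(best)
        if np.array_equal(new_g, g) and np.array_equal(new_h, h):
            break
        g, h = new_g, new_h
    return g, h


def _brim(A: np.ndarray, g: np.ndarray, h: np.ndarray, tol: float = 1e-12, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray, float]:
    """BRIM alternation: fix one side's modules, optimally reassign the other.

    Each row is moved to the module maximizing its contribution
    sum_{j in module} (A_ij - k_i d_j / m); roles then swap.  Iterates until
    the modularity gain drops below ``tol``.
    """
    m = A.sum()
    k = A.sum(axis=1, dtype=np.float64)
    d = A.sum(axis=0, dtype=np.float64)
    B = A - np.outer(k, d) / m
    q = _q_from_vectors(A, g, h, int(m))
    for _ in range(max_iter):
        # membership indicator of columns per module, then optimal rows
        labels = np.unique(np.concatenate([g, h]))
        # rows: contribution of row i to module c = sum of B[i, j] over h_j == c
        T = np.stack([B[:, h == c].sum(axis=1) for c in labels], axis=1)
        g = labels[np.argmax(T, axis=1)]
        labels = np.unique(np.concatenate([g, h]))
        S = np.stack([B[g == c, :].sum(axis=0) for c in labels], axis=1)
        h = labels[np.argmax(S, axis=1)]
        q_new = _q_from_vectors(A, g, h, int(m))
        if q_new - q <= tol:
            q = max(q, q_new)
            break
        q = q_new
    return g, h, q


def _relabel_contiguous(g: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.unique(np.concatenate([g, h]))
    remap = {lab: i + 1 for i, lab in enumerate(labels)}
    return (
        np.array([remap[x] for x in g]),
        np.array([remap[x] for x in h]),
    )


def lp_brim(
    network: BipartiteNetwork,
    n_restarts: int = 20,
    seed: int | None = None,
) -> ModulePartition:
    """Search for the modularity-maximizing partition with LP-BRIM.

    Label propagation provides candidate module seeds; BRIM alternation then
    greedily refines them until Barber's Q converges (tolerance 1e-12).  The
    best of ``n_restarts`` independent restarts is returned.  If no candidate
    improves on the single-module baseline (Q = 0), the trivial one-module
    partition is returned with Q = 0.
    """
    if network.n_edges == 0:
        raise ValueError("cannot partition an empty network")
    A = network.matrix.astype(np.float64)
    R, C = A.shape
    rng = np.random.default_rng(seed)
    best_q = 0.0
    best: tuple[np.ndarray, np.ndarray] | None = None
    for restart in range(n_restarts):
        if restart % 3 == 0:
            g0, h0 = _label_propagation(network.matrix, rng)
        elif restart % 3 == 1:
            # every node its own module; BRIM prunes from the top
            g0 = np.arange(R)
            h0 = np.arange(R, R + C)
        else:
            c = int(rng.integers(2, max(3, min(R, C) + 2)))
            g0 = rng.integers(0, c, size=R)
            h0 = rng.integers(0, c, size=C)
        g, h, q = _brim(A, g0, h0)
        if q > best_q + 1e-15:
            best_q, best = q, (g, h)
    if best is None:
        R, C = network.shape
        g = np.ones(R, dtype=int)
        h = np.ones(C, dtype=int)
        best_q = 0.0
    else:
        g, h = _relabel_contiguous(*best)
    return ModulePartition(
        row_modules=dict(zip(network.row_labels, (int(x) for x in g))),
        col_modules=dict(zip(network.col_labels, (int(x) for x in h))),
        q=float(best_q),
    )


# ---------------------------------------------------------------------------
# Majority module assignment at the OTU level
# ---------------------------------------------------------------------------

def assign_modules_majority(
    partition: ModulePartition,
    genome_to_otu: Mapping[str, str],
    network: BipartiteNetwork | None = None,
) -> dict[str, int]:
    """Collapse a genome-level partition to OTUs by majority vote.

    Each bacterial OTU inherits the modal module of its member genomes.  Ties
    are broken toward the module with which the OTU shares the most vOTU
    interactions (requires ``network``), then toward the lowest module id.
    """
    by_otu: dict[str, list[str]] = {}
    for genome, otu in genome_to_otu.items():
        by_otu.setdefault(otu, []).append(genome)
    out: dict[str, int] = {}
    for otu, genomes in sorted(by_otu.items()):
        if not genomes:
            raise ValueError(f"OTU {otu} has no member genomes")
        mods = [partition.row_modules[g] for g in genomes]
        labels, counts = np.unique(mods, return_counts=True)
        winners = sorted(int(x) for x in labels[counts == counts.max()])
        if len(winners) > 1 and network is not None:
            shared = {}
            for mod in winners:
                cols = [
                    j
                    for j, c in enumerate(network.col_labels)
                    if partition.col_modules.get(c) == mod
                ]
                rows = [network.row_labels.index(g) for g in genomes if g in network.row_labels]
                shared[mod] = int(network.matrix[np.ix_(rows, cols)].sum()) if rows and cols else 0
            top = max(shared.values())
            winners = sorted(m for m in winners if shared[m] == top)
        out[otu] = winners[0]
    return out


# ---------------------------------------------------------------------------
# NODF nestedness
# ---------------------------------------------------------------------------

def nodf(matrix: np.ndarray) -> float:
    """Nestedness metric based on Overlap and Decreasing Fill, in [0, 100].

    For every ordered pair of rows (i, j) with degree k_i > k_j > 0 the paired
    term is 100 * |overlap| / k_j; pairs with equal or zero fill contribute 0.
    The same is computed over columns, and the total is divided by
    R(R-1)/2 + C(C-1)/2.  A strictly nested (triangular) matrix scores 100;
    a matrix whose rows and columns all have equal fill scores 0.
    """
    A = np.asarray(matrix)
    if not np.isin(A, (0, 1)).all():
        raise ValueError("NODF requires a binary matrix")
    if A.sum() == 0:
        raise ValueError("NODF is undefined for an all-zero matrix")
    R, C = A.shape

    def _axis_sum(M: np.ndarray) -> float:
        k = M.sum(axis=1)
        overlap = (M @ M.T).astype(np.float64)
        total = 0.0
        # decreasing-fill condition: only pairs with k_i > k_j > 0 count
        ki = k[:, None]
        kj = k[None, :]
        valid = (ki > kj) & (kj > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(valid, 100.0 * overlap / np.where(kj > 0, kj, 1), 0.0)
        total = float(terms.sum())
        return total

    n_pairs = R * (R - 1) / 2 + C * (C - 1) / 2
    return (_axis_sum(A) + _axis_sum(A.T)) / n_pairs


# ---------------------------------------------------------------------------
# Probabilistic-degree null model
# ---------------------------------------------------------------------------

def null_model(
    matrix: np.ndarray, n: int, seed: int | None = None
) -> np.ndarray:
    """Probabilistic-degree null ensemble of ``n`` binary matrices.

    Cell (i, j) of each null is Bernoulli with probability
    P_ij = (k_i / C + d_j / R) / 2 — the mean of the focal row's and column's
    fill fractions.  The ensemble preserves the observed row and column sums
    in expectation (and the overall fill exactly in expectation).
    Returns an array of shape (n, R, C).
    """
    A = np.asarray(matrix)
    R, C = A.shape
    k = A.sum(axis=1, dtype=np.float64)
    d = A.sum(axis=0, dtype=np.float64)
    P = (k[:, None] / C + d[None, :] / R) / 2.0
    assert (P <= 1.0 + 1e-12).all(), "cell probability above 1 from a binary input"
    rng = np.random.default_rng(seed)
    return (rng.random((n, R, C)) < P).astype(np.int8)


def nestedness_test(
    matrix: np.ndarray,
    n_null: int = 1000,
    seed: int | None = None,
    n_modules_tested: int = 1,
    module: object = None,
) -> NestednessResult:
    """Two-sided empirical test of NODF against the probabilistic-degree null.

    p = 2 * min(Pr(null >= obs), Pr(null <= obs)) with the +1 permutation
    correction, capped at 1; Bonferroni adjustment multiplies by the number
    of modules tested.  The 95% CI is the 2.5/97.5 percentile band of the
    null NODF distribution.
    """
    A = np.asarray(matrix)
    if A.shape[0] < 2 or A.shape[1] < 2:
        raise ValueError("nestedness test needs at least a 2x2 matrix")
    obs = nodf(A)
    nulls = null_model(A, n_null, seed=seed)
    null_vals = np.array(
        [nodf(nm) if nm.sum() > 0 else 0.0 for nm in nulls]
    )
    n = len(null_vals)
    p_hi = (np.sum(null_vals >= obs) + 1) / (n + 1)
    p_lo = (np.sum(null_vals <= obs) + 1) / (n + 1)
    p = min(1.0, 2.0 * min(p_hi, p_lo))
    return NestednessResult(
        module=module,
        observed_nodf=float(obs),
        null_mean=float(null_vals.mean()),
        null_ci=(
            float(np.percentile(null_vals, 2.5)),
            float(np.percentile(null_vals, 97.5)),
        ),
        p_value=float(p),
        p_adjusted=float(min(1.0, p * n_modules_tested)),
        n_null=n,
    )


# ---------------------------------------------------------------------------
# Neighborhood purity on an auxiliary (proteome-sharedness) network
# ---------------------------------------------------------------------------

def neighborhood_purity(
    edges: Iterable[tuple[str, str]],
    modules: Mapping[str, int],
    percentile: float = 1.0,
) -> list[NeighborhoodPurity]:
    """Module purity of each labeled node's close neighborhood.

    The neighborhood of a node contains every other labeled node reachable
    within the given percentile of the global multiset of finite pairwise
    shortest-path lengths (unweighted).  Purity is the fraction of the
    neighborhood sharing the focal node's module; nodes with an empty
    neighborhood get purity NaN.
    """
    G = nx.Graph()
    G.add_edges_from((a, b) for a, b in edges)
    if G.number_of_edges() == 0:
        raise ValueError("purity is undefined on a graph with no edges")
    labeled = [n for n in G.nodes if n in modules]
    dist = {n: nx.single_source_shortest_path_length(G, n) for n in labeled}
    all_lengths = [
        dist[a][b]
        for i, a in enumerate(labeled)
        for b in labeled[i + 1 :]
        if b in dist[a]
    ]
    if not all_lengths:
        raise ValueError("no finite path lengths among labeled nodes")
    threshold = float(np.percentile(all_lengths, percentile))
    out = []
    for a in labeled:
        nbhd = [b for b in labeled if b != a and b in dist[a] and dist[a][b] <= threshold]
        if nbhd:
            pur = sum(modules[b] == modules[a] for b in nbhd) / len(nbhd)
        else:
            pur = float("nan")
        out.append(NeighborhoodPurity(node=a, neighborhood_size=len(nbhd), purity=pur))
    return out
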