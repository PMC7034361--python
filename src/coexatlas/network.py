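"""Correlation graphs and Markov clustering of the expression atlas.

Pairwise Pearson correlation is computed between all genes (or, transposed,
all samples) on untransformed TPM. Edges are the correlations at or above a
chosen threshold; nodes are the entities retaining at least one edge, so
raising the threshold shrinks both node and edge counts — the threshold is
chosen by scanning to retain the most nodes with the fewest edges.

Clusters of densely interconnected genes are extracted with the Markov
clustering algorithm (MCL): the weighted adjacency matrix (with self-loops)
is column-normalized into a random-walk matrix which is alternately
expanded (squared) and inflated (element-wise powered and renormalized)
until idempotent; the surviving attractor systems are the clusters. The
inflation exponent controls granularity — 2.2 suits a many-tissue atlas,
1.7 a single-tissue compendium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Preset:
    """Analysis preset: expression filter, correlation threshold, MCL inflation."""

    min_tpm: float
    r_threshold: float
    inflation: float


#: The atlas presets: the cross-tissue atlas and the liver / CNS sub-analyses.
PRESETS = {
    "main": Preset(min_tpm=10.0, r_threshold=0.70, inflation=2.2),
    "liver": Preset(min_tpm=5.0, r_threshold=0.75, inflation=1.7),
    "cns": Preset(min_tpm=5.0, r_threshold=0.85, inflation=1.7),
}


@dataclass
class CorrelationMatrix:
    ids: list[str]
    r: np.ndarray  # symmetric, diagonal 1
    axis: str  # "gene" or "sample"


@dataclass
class CorrelationGraph:
    threshold: float
    nodes: list[str]  # entities with degree >= 1
    edges: list[tuple[str, str, float]]  # i < j in entity order

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class ClusterSet:
    """Disjoint clusters ordered by descending size; numbering is 1-based."""

    clusters: list[list[str]]
    inflation: float
    converged: bool = True

    def labels(self) -> dict[str, int]:
        out = {}
        for num, members in enumerate(self.clusters, start=1):
            for m in members:
                out[m] = num
        return out


@dataclass
class ClusterProfile:
    cluster_number: int
    size: int
    mean_tpm_per_sample: pd.Series
    top_samples: list[str]


def correlate(
    matrix: ExpressionMatrix,
    axis: str = "gene",
    log_transform: bool = False,
    block_size: int = 2000,
) -> CorrelationMatrix:
    """All-vs-all Pearson correlation over genes or samples.

    Correlation is computed on raw TPM by default (``log_transform`` applies
    log2(x+1) first). Zero-variance entities are excluded with a warning.
    Requires at least 3 observations per entity. Large gene sets are
    processed in row blocks to bound memory.
    """
    if axis == "gene":
        data = matrix.values.to_numpy(dtype=float)
        ids = matrix.gene_ids
    elif axis == "sample":
        data = matrix.values.to_numpy(dtype=float).T
        ids = matrix.sample_ids
    else:
        raise ValueError("axis must be 'gene' or 'sample'")
    if data.shape[1] < 3:
        raise ValueError("need at least 3 observations per entity")
    if log_transform:
        data = np.log2(data + 1.0)
    sd = data.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [i for i, k in zip(ids, keep) if not k]
        logger.warning("excluding %d zero-variance entities (e.g. %s)",
                       len(dropped), dropped[:3])
        data = data[keep]
        ids = [i for i, k in zip(ids, keep) if k]
    n = data.shape[0]
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    centered /= norms[:, None]
    r = np.empty((n, n), dtype=float)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        r[start:stop] = centered[start:stop] @ centered.T
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return CorrelationMatrix(ids=ids, r=r, axis=axis)


def build_graph(corr: CorrelationMatrix, threshold: float) -> CorrelationGraph:
    """Threshold the correlation matrix into an undirected weighted graph.

    An edge joins every pair with r >= threshold (inclusive); entities left
    without any edge are not admitted as nodes.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    iu, ju = np.triu_indices(len(corr.ids), k=1)
    mask = corr.r[iu, ju] >= threshold
    ids = corr.ids
    edges = [(ids[i], ids[j], float(corr.r[i, j]))
             for i, j in zip(iu[mask], ju[mask])]
    touched = np.zeros(len(ids), dtype=bool)
    touched[iu[mask]] = True
    touched[ju[mask]] = True
    nodes = [ids[i] for i in np.flatnonzero(touched)]
    return CorrelationGraph(threshold=threshold, nodes=nodes, edges=edges)


def threshold_scan(
    corr: CorrelationMatrix, grid: Sequence[float]
) -> pd.DataFrame:
    """Node and edge counts at each threshold of an ascending grid.

    Used to pick the threshold retaining the most nodes for the fewest
    edges; both counts are non-increasing in r.
    """
    grid = list(grid)
    if grid != sorted(grid):
        raise ValueError("grid must be sorted ascending")
    n = len(corr.ids)
    iu, ju = np.triu_indices(n, k=1)
    vals = corr.r[iu, ju]
    rows = []
    for t in grid:
        mask = vals >= t
        touched = np.zeros(n, dtype=bool)
        touched[iu[mask]] = True
        touched[ju[mask]] = True
        rows.append((t, int(touched.sum()), int(mask.sum())))
    return pd.DataFrame(rows, columns=["r", "nodes", "edges"])


def mcl(
    graph: CorrelationGraph,
    inflation: float = 2.2,
    expansion: int = 2,
    prune: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 200,
    validate: bool = False,
) -> ClusterSet:
    """Markov clustering of a weighted correlation graph.

    Self-loops are added with weight equal to each node's maximum incident
    edge weight, columns are normalized to a stochastic matrix, and the
    process alternates expansion (matrix power ``expansion``) with inflation
    (element-wise power ``inflation`` and column renormalization), pruning
    entries below ``prune`` per column, until the matrix stops changing
    (max column change < ``tol``) or ``max_iter`` rounds. Clusters are read
    from attractor systems; a node claimed by several systems goes to the
    larger cluster. Non-convergence returns the current interpretation with
    ``converged=False``. With ``validate=True`` the column-stochasticity
    invariant is asserted after every inflation step.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = graph.nodes
    n = len(nodes)
    if n == 0:
        return ClusterSet(clusters=[], inflation=inflation)
    pos = {node: i for i, node in enumerate(nodes)}
    a = np.zeros((n, n), dtype=float)
    for u, v, w in graph.edges:
        i, j = pos[u], pos[v]
        a[i, j] = a[j, i] = w
    np.fill_diagonal(a, a.max(axis=1))  # self-loop = max incident weight
    m = a / a.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        np.power(m, inflation, out=m)
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        # a fully pruned column keeps its attractor: restore argmax of the expanded matrix
        dead = np.flatnonzero(colsum[0] == 0)
        if dead.size:
            restore = prev[:, dead].argmax(axis=0)
            m[restore, dead] = 1.0
            colsum = m.sum(axis=0, keepdims=True)
        m /= colsum
        if validate and not np.allclose(m.sum(axis=0), 1.0, atol=1e-9):
            raise AssertionError("column stochasticity lost after inflation")
        if np.max(np.abs(m - prev)) < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations", max_iter)

    clusters = _interpret(m, nodes)
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return ClusterSet(clusters=clusters, inflation=inflation, converged=converged)


def _interpret(m: np.ndarray, nodes: Sequence[str]) -> list[list[str]]:
    """Read clusters from the (near-)idempotent MCL matrix.

    Attractors are nodes with residual mass on the diagonal; each attractor
    row spans the nodes it attracts, attractors sharing nodes form one
    system, and any node attracted by several systems is assigned to the
    largest (ties to the lower-numbered system).
    """
    n = len(nodes)
    eps = 1e-9
    attractors = np.flatnonzero(np.diag(m) > eps)
    if attractors.size == 0:  # degenerate; every node follows its argmax row
        attractors = np.unique(m.argmax(axis=0))
    # union attractors that attract one another into systems
    parent = {int(i): int(i) for i in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    attractor_set = set(int(i) for i in attractors)
    for i in attractor_set:
        for j in np.flatnonzero(m[i] > eps):
            if int(j) in attractor_set:
                ri, rj = find(i), find(int(j))
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    systems: dict[int, set[int]] = {}
    for i in attractor_set:
        systems.setdefault(find(i), set()).update(
            int(j) for j in np.flatnonzero(m[i] > eps)
        )
        systems[find(i)].add(i)
    roots = sorted(systems)
    # resolve overlaps: larger cluster wins, then lower root
    claim: dict[int, int] = {}
    sized = sorted(roots, key=lambda r: (-len(systems[r]), r))
    for root in sized:
        for node in systems[root]:
            claim.setdefault(node, root)
    for node in range(n):  # orphans (no attractor mass) follow their argmax row
        if node not in claim:
            owner = int(m[:, node].argmax())
            claim[node] = find(owner) if owner in parent else owner
    out: dict[int, list[str]] = {}
    for node, root in claim.items():
        out.setdefault(root, []).append(nodes[node])
    return [sorted(members) for members in out.values()]


def profiles(
    clusters: ClusterSet,
    matrix: ExpressionMatrix,
    min_size: int = 10,
) -> list[ClusterProfile]:
    """Mean expression profile per cluster of at least *min_size* genes.

    ``top_samples`` ranks the sample labels by descending mean TPM over the
    cluster's members.
    """
    out = []
    for number, members in enumerate(clusters.clusters, start=1):
        if len(members) < min_size:
            continue
        present = [g for g in members if g in matrix.values.index]
        mean = matrix.values.loc[present].mean(axis=0)
        top = list(mean.sort_values(ascending=False).index)
        out.append(ClusterProfile(
            cluster_number=number, size=len(members),
            mean_tpm_per_sample=mean, top_samples=top,
        ))
    return out


def write_edge_list(graph: CorrelationGraph, path: str | Path) -> None:
    """Write the graph as whitespace-separated ``node node weight`` lines (.abc)."""
    with open(path, "w") as fh:
        for u, v, w in graph.edges:
            fh.write(f"{u} {v} {w:.6g}\n")


def write_graphml(graph: CorrelationGraph, path: str | Path) -> None:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_weighted_edges_from(graph.edges)
    nx.write_graphml(g, path)


def write_clusters(clusters: ClusterSet, path: str | Path) -> None:
    """One cluster per line, members tab-separated (MCL native dialect)."""
    with open(path, "w") as fh:
        for members in clusters.clusters:
            fh.write("\t".join(members) + "\n")


def write_profiles(profs: Iterable[ClusterProfile], path: str | Path) -> None:
    rows = []
    for p in profs:
        row = {"cluster": p.cluster_number, "size": p.size,
               "top_sample": p.top_samples[0] if p.top_samples else ""}
        row.update({s: v for s, v in p.mean_tpm_per_sample.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def reproduce_atlas_statistics(
    matrix: ExpressionMatrix,
    sample_thresholds: Sequence[float] = (0.38, 0.85),
    gene_threshold: float = 0.70,
    min_tpm: float = 10.0,
) -> dict[str, int]:
    """Recompute the headline network statistics from an averaged atlas matrix.

    Returns node and edge counts of the sample-to-sample graph at each of
    *sample_thresholds* and of the gene-to-gene graph at *gene_threshold*
    after the >= *min_tpm*-in-one-sample gene filter, plus the sample count.
    """
    from .qc import expression_filter

    out: dict[str, int] = {"n_samples": matrix.n_samples}
    sample_corr = correlate(matrix, axis="sample")
    for t in sample_thresholds:
        g = build_graph(sample_corr, t)
        key = f"{t:g}".replace(".", "")
        out[f"sample_nodes_r{key}"] = g.n_nodes
        out[f"sample_edges_r{key}"] = g.n_edges
    filtered = expression_filter(matrix, min_tpm=min_tpm)
    gene_corr = correlate(filtered, axis="gene")
    g = build_graph(gene_corr, gene_threshold)
    key = f"{gene_threshold:g}".replace(".", "")
    out[f"gene_nodes_r{key}"] = g.n_nodes
    out[f"gene_edges_r{key}"] = g.n_edges
    return out
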