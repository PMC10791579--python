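"""Pseudobulk V(D)J feature space, differential usage and trajectory tools.

V(D)J gene calls are categorical, which blocks most continuous-data
machinery.  The feature space converts them to fractions: cells are
grouped into pseudobulks (metadata combinations, or partially
overlapping k-NN neighborhoods sampled from an embedding), and for each
pseudobulk the fraction of cells using each gene of a locus/segment
(e.g. each of TRAJ1..TRAJ61 in the TRAJ segment) is computed.  Each
(pseudobulk, locus, segment) block is normalised to unit sum, so the
concatenated matrix is a proper composition per block and supports PCA,
differential testing and pseudotime inference.

``baseline_trajectory`` is a self-contained pseudotime engine operating
on the feature space: PCA, a symmetric k-NN graph, shortest-path
pseudotime from a root pseudobulk, and branch probabilities from an
absorbing random walk with the terminal pseudobulks absorbing.  External
engines can be substituted by importing/exporting the assignment matrix
and per-pseudobulk value tables; per-pseudobulk quantities are projected
back to cells by averaging over a cell's neighborhoods weighted by
inverse neighborhood size.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from scipy.sparse.csgraph import dijkstra, minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .airr_io import first_gene
from .contig_qc import order_cell_contigs
from .errors import IntegrityError, ParameterError
from .stats import bh_adjust, pearson, wilcoxon_rank_sum

SEGMENT_COLUMNS = {"V": "v_call", "D": "d_call", "J": "j_call", "C": "c_call"}


@dataclass
class PseudobulkAssignment:
    """Binary cells x pseudobulks matrix; overlapping columns allowed."""

    matrix: sparse.csr_matrix
    cell_ids: list[str]
    labels: list[str]

    def __post_init__(self):
        self.matrix = sparse.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.cell_ids), len(self.labels)):
            raise IntegrityError("assignment matrix shape does not match labels")
        if len(self.labels) and self.sizes.min() < 1:
            raise IntegrityError("every pseudobulk must contain at least one cell")

    @property
    def sizes(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class VDJFeatureMatrix:
    """Pseudobulks x gene-usage fractions with per-block structure."""

    X: pd.DataFrame                 # pseudobulks x features
    feature_meta: pd.DataFrame      # feature, locus, segment, gene, genomic_index
    cell_counts: np.ndarray         # cells per pseudobulk

    def block(self, locus: str, segment: str) -> pd.DataFrame:
        mask = (self.feature_meta["locus"] == locus) & (self.feature_meta["segment"] == segment)
        return self.X.loc[:, self.feature_meta.loc[mask, "feature"]]


@dataclass
class TrajectoryResult:
    pseudotime: pd.Series           # per pseudobulk, in [0, 1], 0 at root
    branch_probabilities: pd.DataFrame  # pseudobulks x terminals, rows sum to 1
    root: str
    terminals: list[str]


# ---------------------------------------------------------------------------
# pseudobulk assignment

def pseudobulks_from_metadata(cells: pd.DataFrame, columns, min_cells: int = 10
                              ) -> PseudobulkAssignment:
    """One pseudobulk per unique combination of metadata columns.

    Combinations with fewer than ``min_cells`` cells are dropped.  The
    result is a partition: each retained cell sits in exactly one
    pseudobulk.
    """
    columns = list(columns)
    if not columns:
        raise ParameterError("at least one metadata column is required")
    missing = [c for c in columns if c not in cells.columns]
    if missing:
        raise ParameterError(f"unknown metadata column(s): {', '.join(missing)}")
    cell_ids = list(cells["cell_id"])
    index = {c: i for i, c in enumerate(cell_ids)}
    labels, cols_i, cols_j = [], [], []
    for key, members in cells.groupby(columns, sort=True)["cell_id"]:
        if len(members) < min_cells:
            continue
        key_t = key if isinstance(key, tuple) else (key,)
        labels.append("_".join(str(k) for k in key_t))
        j = len(labels) - 1
        for c in members:
            cols_i.append(index[c])
            cols_j.append(j)
    matrix = sparse.csr_matrix(
        (np.ones(len(cols_i)), (cols_i, cols_j)), shape=(len(cell_ids), len(labels)))
    return PseudobulkAssignment(matrix=matrix, cell_ids=cell_ids, labels=labels)


def sample_neighborhoods(embedding: np.ndarray, k: int, proportion: float,
                         seed: int, cell_ids: list[str] | None = None
                         ) -> PseudobulkAssignment:
    """Overlapping neighborhoods: sampled index cells + their k nearest neighbors.

    Index cells are drawn without replacement (``proportion`` of all
    cells, seeded); each neighborhood contains the index cell and its
    ``k`` Euclidean nearest neighbors, so neighborhoods overlap and some
    cells may belong to none.  Deterministic given the seed.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if k < 1 or k >= n:
        raise ParameterError("k must satisfy 1 <= k < n_cells")
    if not 0 < proportion <= 1:
        raise ParameterError("proportion must lie in (0, 1]")
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(n)]
    rng = np.random.default_rng(seed)
    n_index = max(1, int(round(proportion * n)))
    index_cells = np.sort(rng.choice(n, size=n_index, replace=False))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, neighbor_idx = nn.kneighbors(embedding[index_cells])
    rows, cols = [], []
    for j, neighbors in enumerate(neighbor_idx):
        members = set(neighbors.tolist()) | {int(index_cells[j])}
        for i in members:
            rows.append(i)
            cols.append(j)
    matrix = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n_index))
    labels = [f"nh{j}" for j in range(n_index)]
    return PseudobulkAssignment(matrix=matrix, cell_ids=list(cell_ids), labels=labels)


def write_assignment(assignment: PseudobulkAssignment, prefix: str) -> None:
    """Write an assignment as MatrixMarket + row/column label files."""
    spio.mmwrite(f"{prefix}.mtx", sparse.coo_matrix(assignment.matrix))
    pd.Series(assignment.cell_ids).to_csv(f"{prefix}.rows.txt", index=False, header=False)
    pd.Series(assignment.labels).to_csv(f"{prefix}.cols.txt", index=False, header=False)


def read_assignment(prefix: str) -> PseudobulkAssignment:
    matrix = sparse.csr_matrix(spio.mmread(f"{prefix}.mtx"))
    cell_ids = pd.read_csv(f"{prefix}.rows.txt", header=None)[0].astype(str).tolist()
    labels = pd.read_csv(f"{prefix}.cols.txt", header=None)[0].astype(str).tolist()
    return PseudobulkAssignment(matrix=matrix, cell_ids=cell_ids, labels=labels)


# ---------------------------------------------------------------------------
# feature space

def _natural_gene_key(gene: str):
    parts = re.split(r"(\d+)", gene)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _primary_gene_per_cell(table: pd.DataFrame, locus: str, segment: str) -> pd.Series:
    """First gene (allele stripped) of each cell's primary contig at a locus."""
    col = SEGMENT_COLUMNS[segment]
    sub = table[table["locus"] == locus]
    genes = {}
    for cell_id, cell_df in sub.groupby("cell_id", sort=False):
        top = order_cell_contigs(cell_df).iloc[0]
        gene = first_gene(top[col])
        if gene:
            genes[cell_id] = gene
    return pd.Series(genes, dtype=object)


def build_vdj_feature_space(table: pd.DataFrame, assignment: PseudobulkAssignment,
                            loci=("TRA", "TRB"), segments=("V", "J")
                            ) -> VDJFeatureMatrix:
    """Pseudobulk x gene-usage-fraction matrix.

    Per (locus, segment) block: each cell contributes a single binary
    indicator for the gene of its primary contig (productive ranked
    first, then highest UMI; first gene of a multi-gene call, allele
    stripped); indicators are summed per pseudobulk and the block row is
    divided by its sum.  Blocks absent from a pseudobulk stay all-zero
    rather than dropping the pseudobulk, keeping the matrix rectangular.
    """
    unknown = sorted(set(table["cell_id"]) - set(assignment.cell_ids))
    if unknown:
        raise IntegrityError(
            f"{len(unknown)} contig cell barcode(s) absent from the assignment, "
            f"e.g. {unknown[:5]}")
    cell_index = {c: i for i, c in enumerate(assignment.cell_ids)}
    A = assignment.matrix.T.tocsr()     # pseudobulks x cells
    blocks, meta_rows = [], []
    for locus in loci:
        for segment in segments:
            if segment == "D" and locus not in ("TRB", "TRD", "IGH"):
                continue
            genes = _primary_gene_per_cell(table, locus, segment)
            universe = sorted(set(genes), key=_natural_gene_key)
            counts = np.zeros((len(assignment.labels), len(universe)))
            if universe:
                gene_index = {g: j for j, g in enumerate(universe)}
                rows = [cell_index[c] for c in genes.index]
                cols = [gene_index[g] for g in genes.to_numpy()]
                C = sparse.csr_matrix(
                    (np.ones(len(rows)), (rows, cols)),
                    shape=(assignment.n_cells, len(universe)))
                counts = np.asarray((A @ C).todense())
            sums = counts.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                fractions = np.where(sums > 0, counts / np.where(sums == 0, 1, sums), 0.0)
            names = [f"{locus}_{segment}|{g}" for g in universe]
            blocks.append(pd.DataFrame(fractions, index=assignment.labels, columns=names))
            for j, g in enumerate(universe):
                meta_rows.append({"feature": names[j], "locus": locus,
                                  "segment": segment, "gene": g, "genomic_index": j + 1})
    X = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=assignment.labels)
    meta = pd.DataFrame(meta_rows, columns=["feature", "locus", "segment",
                                            "gene", "genomic_index"])
    return VDJFeatureMatrix(X=X, feature_meta=meta, cell_counts=assignment.sizes)


# ---------------------------------------------------------------------------
# differential usage

def differential_usage(features: VDJFeatureMatrix, groups) -> pd.DataFrame:
    """Per-feature group-vs-rest rank-sum tests on usage fractions.

    ``groups`` maps pseudobulk label to group label (dict or Series).
    Every group and its complement must contain at least two pseudobulks.
    Returns per (group, feature): two-sided Wilcoxon rank-sum statistic
    and p, BH-adjusted p within group, and group/rest means; sorted by
    adjusted p then absolute effect within each group.
    """
    groups = pd.Series(groups)
    labels = features.X.index
    missing = [l for l in labels if l not in groups.index]
    if missing:
        raise ParameterError(f"no group label for pseudobulk(s): {missing[:5]}")
    groups = groups.loc[labels]
    results = []
    for group in sorted(groups.unique(), key=str):
        in_group = (groups == group).to_numpy()
        if in_group.sum() < 2 or (~in_group).sum() < 2:
            raise ParameterError(
                f"group '{group}' needs >= 2 pseudobulks on both sides")
        # exact permutation enumeration is feasible (and handles the heavy
        # ties of usage fractions) for small pseudobulk counts
        mode = "exact" if len(labels) <= 12 else "auto"
        sub = []
        for feature in features.X.columns:
            values = features.X[feature].to_numpy()
            a, b = values[in_group], values[~in_group]
            stat, p = wilcoxon_rank_sum(a, b, mode=mode)
            sub.append({"group": group, "feature": feature, "statistic": stat,
                        "pvalue": p, "mean_group": a.mean(), "mean_rest": b.mean()})
        sub = pd.DataFrame(sub)
        sub["padj"] = bh_adjust(sub["pvalue"].to_numpy())
        sub["effect"] = sub["mean_group"] - sub["mean_rest"]
        sub["abs_effect"] = sub["effect"].abs()
        sub = sub.sort_values(["padj", "abs_effect"], ascending=[True, False],
                              kind="stable").drop(columns="abs_effect")
        results.append(sub)
    return pd.concat(results, ignore_index=True)


# ---------------------------------------------------------------------------
# baseline trajectory engine

def knn_graph(X: np.ndarray, k: int) -> sparse.csr_matrix:
    """Symmetric k-NN graph with Euclidean edge weights."""
    n = X.shape[0]
    if k >= n:
        raise ParameterError("k must be smaller than the number of pseudobulks")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    vals = dist[:, 1:].ravel()
    W = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return W.maximum(W.T)


def absorbing_probabilities(adjacency, terminal_indices) -> np.ndarray:
    """Absorption probabilities of a uniform random walk on a graph.

    ``adjacency`` is any (sparse or dense) n x n matrix whose non-zero
    pattern defines edges; the walk moves to a uniformly random
    neighbor, and ``terminal_indices`` are absorbing.  Returns an n x t
    matrix of probabilities of being absorbed in each terminal (rows sum
    to 1; a terminal's own row is the corresponding unit vector).  This
    is the classical gambler's-ruin calculation on a path graph.
    """
    A = sparse.csr_matrix(adjacency)
    n = A.shape[0]
    terminals = list(terminal_indices)
    transient = [i for i in range(n) if i not in set(terminals)]
    connect = (A != 0).astype(float)
    deg = np.asarray(connect.sum(axis=1)).ravel()
    if np.any(deg[transient] == 0):
        raise ParameterError("graph has isolated non-terminal nodes")
    P = sparse.diags(1.0 / np.maximum(deg, 1)) @ connect
    Q = P[transient][:, transient]
    R = P[transient][:, terminals]
    B_t = np.linalg.solve(np.eye(len(transient)) - Q.todense(), R.todense())
    out = np.zeros((n, len(terminals)))
    out[transient] = np.asarray(B_t)
    for t_col, t_idx in enumerate(terminals):
        out[t_idx, t_col] = 1.0
    return out


def baseline_trajectory(features: VDJFeatureMatrix, root: str, terminals,
                        k: int = 10, n_pcs: int = 5, seed: int = 0
                        ) -> TrajectoryResult:
    """Self-contained pseudotime + branch probabilities on the feature space.

    PCA to ``n_pcs`` components, a symmetric k-NN graph augmented with
    the Euclidean minimum spanning tree (so sparse feature spaces cannot
    fragment into unreachable islands), pseudotime as min-max-normalised
    shortest-path distance from the root pseudobulk, and branch
    probabilities from the absorbing random walk with the terminal
    pseudobulks absorbing.
    """
    labels = list(features.X.index)
    terminals = list(terminals)
    for name in [root, *terminals]:
        if name not in labels:
            raise ParameterError(f"unknown pseudobulk '{name}'")
    pos = {l: i for i, l in enumerate(labels)}
    X = features.X.to_numpy()
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    W = knn_graph(pcs, k)
    mst = sparse.csr_matrix(minimum_spanning_tree(squareform(pdist(pcs))))
    W = W.maximum(mst.maximum(mst.T))
    dist = dijkstra(W, directed=False, indices=pos[root])
    unreachable = [labels[i] for i in np.where(~np.isfinite(dist))[0]]
    if unreachable:
        raise ParameterError(
            f"{len(unreachable)} pseudobulk(s) unreachable from root, "
            f"e.g. {unreachable[:5]}")
    span = dist.max() - dist.min()
    pseudotime = (dist - dist.min()) / (span if span > 0 else 1.0)
    B = absorbing_probabilities(W, [pos[t] for t in terminals])
    return TrajectoryResult(
        pseudotime=pd.Series(pseudotime, index=labels),
        branch_probabilities=pd.DataFrame(B, index=labels, columns=terminals),
        root=root,
        terminals=terminals,
    )


# ---------------------------------------------------------------------------
# projection and trajectory-fidelity metrics

def project_to_cells(values, assignment: PseudobulkAssignment
                     ) -> tuple[pd.Series, int]:
    """Project per-pseudobulk values back to cells.

    A cell's value is the average over its containing pseudobulks,
    weighted by inverse pseudobulk size; cells belonging to no
    pseudobulk are omitted and their count returned.
    """
    v = pd.Series(values)
    if list(v.index) != list(assignment.labels):
        v = v.reindex(assignment.labels)
        if v.isna().any():
            raise ParameterError("values must cover every pseudobulk label")
    inv_size = 1.0 / assignment.sizes
    M = assignment.matrix
    weight_sum = np.asarray(M @ inv_size).ravel()
    weighted = np.asarray(M @ (inv_size * v.to_numpy())).ravel()
    in_any = weight_sum > 0
    out = pd.Series(weighted[in_any] / weight_sum[in_any],
                    index=np.asarray(assignment.cell_ids, dtype=object)[in_any])
    return out, int((~in_any).sum())


def relative_location_encoding(genes) -> dict[str, int]:
    """Map genes, given in 5'->3' genomic order, to 1-based indices."""
    return {g: i + 1 for i, g in enumerate(genes)}


def mean_relative_location(cell_genes: pd.Series, assignment: PseudobulkAssignment,
                           encoding: dict[str, int]) -> tuple[pd.Series, int]:
    """Mean gene location per pseudobulk over member cells.

    ``cell_genes`` maps cell_id to the cell's primary gene; cells whose
    gene is absent from the encoding are dropped (count returned).
    """
    mapped = cell_genes.map(encoding)
    n_unmapped = int(mapped.isna().sum())
    if n_unmapped:
        warnings.warn(f"{n_unmapped} cell(s) with unmapped genes dropped", stacklevel=2)
    mapped = mapped.dropna()
    cell_index = {c: i for i, c in enumerate(assignment.cell_ids)}
    values = np.full(assignment.n_cells, np.nan)
    for cell, loc in mapped.items():
        if cell in cell_index:
            values[cell_index[cell]] = loc
    M = assignment.matrix.toarray().astype(bool)
    out = {}
    for j, label in enumerate(assignment.labels):
        member_vals = values[M[:, j]]
        member_vals = member_vals[~np.isnan(member_vals)]
        out[label] = member_vals.mean() if len(member_vals) else np.nan
    return pd.Series(out), n_unmapped


def sliding_window_correlation(pseudotime, values, w: int = 30
                               ) -> tuple[pd.DataFrame, float]:
    """Local Pearson correlations over sliding pseudotime windows.

    Pseudobulks are ordered by pseudotime; each window of ``w``
    consecutive pseudobulks (stride 1) yields the Pearson r between
    pseudotime and the value; zero-variance windows are recorded as
    missing.  Returns the per-window table and the mean r over defined
    windows.
    """
    pt = pd.Series(pseudotime)
    vals = pd.Series(values).loc[pt.index]
    if w < 2:
        raise ParameterError("window width must be at least 2")
    if w > len(pt):
        raise ParameterError("window width exceeds the number of pseudobulks")
    order = pt.sort_values(kind="stable").index
    pt_o = pt.loc[order].to_numpy()
    vals_o = vals.loc[order].to_numpy()
    rows = []
    for start in range(len(pt_o) - w + 1):
        x = pt_o[start:start + w]
        y = vals_o[start:start + w]
        if np.std(x) == 0 or np.std(y) == 0 or np.any(np.isnan(y)):
            rows.append((start, np.nan))
        else:
            rows.append((start, pearson(x, y)[0]))
    out = pd.DataFrame(rows, columns=["window_start", "r"])
    mean_r = float(np.nanmean(out["r"])) if out["r"].notna().any() else float("nan")
    return out, mean_r
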