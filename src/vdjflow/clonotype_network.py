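"""Clonotype definition and per-clone network diversity.

Cells are grouped into clonotypes by three sequential criteria applied to
both the heavy-type (VDJ) and light-type (VJ) chain of each cell's
primary contigs:

1. identical V and J gene usage;
2. identical junction (CDR3) amino-acid length;
3. junction sequence similarity — for TCRs, 100% nucleotide identity
   (exact match); for BCRs, >= 85% amino-acid similarity under Hamming
   distance, with similar pairs merged by single-linkage by default.

Within each clonotype a cell graph is built from pairwise Levenshtein
distances of the cells' full amino-acid contig alignments (VDJ chain
concatenated with VJ chain).  A minimum-spanning forest over the
positive-distance edges gives the clone skeleton, after which every pair
of cells at edit distance zero is reconnected (an adjacency built from
distances cannot represent a zero-weight edge, so identical cells would
otherwise be pruned).  Repertoire diversity is then summarised by Gini
coefficients of the clone-size and node-centrality distributions: an
expanded, oligoclonal repertoire has high inequality (G near 1), a
diverse naive one has G near 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np
import pandas as pd

from .airr_io import VDJ_LOCI, VJ_LOCI, first_gene
from .contig_qc import order_cell_contigs
from .errors import ParameterError
from .stats import gini


@dataclass
class ClonotypeConfig:
    """Clone-calling parameters.

    ``similarity_threshold`` is the minimum junction similarity within a
    clone: 1.0 on nucleotides for TCR (exact identity), 0.85 on amino
    acids for BCR.  ``require_both_chains`` controls whether single-chain
    (orphan) cells may form clones from the available chain alone.
    """

    receptor: str = "tcr"
    cdr3_metric: str = ""            # filled from receptor if empty
    similarity_threshold: float = -1.0
    require_both_chains: bool | None = None
    linkage: str = "single"

    def __post_init__(self):
        if self.receptor not in ("tcr", "bcr"):
            raise ParameterError(f"unknown receptor '{self.receptor}'")
        if not self.cdr3_metric:
            self.cdr3_metric = ("nucleotide_identity" if self.receptor == "tcr"
                                else "aa_hamming_similarity")
        if self.similarity_threshold < 0:
            self.similarity_threshold = 1.0 if self.receptor == "tcr" else 0.85
        if not 0 <= self.similarity_threshold <= 1:
            raise ParameterError("similarity_threshold must lie in [0, 1]")
        if self.require_both_chains is None:
            self.require_both_chains = self.receptor == "bcr"
        if self.linkage not in ("single", "complete"):
            raise ParameterError(f"unknown linkage '{self.linkage}'")


def _cell_chain_table(table: pd.DataFrame) -> pd.DataFrame:
    """One row per cell with primary VDJ/VJ chain features."""
    rows = []
    for cell_id, cell_df in table.groupby("cell_id", sort=True):
        ordered = order_cell_contigs(cell_df)
        rec: dict = {"cell_id": cell_id}
        for side, loci in (("vdj", VDJ_LOCI), ("vj", VJ_LOCI)):
            chains = ordered[ordered["locus"].isin(loci)]
            if len(chains):
                top = chains.iloc[0]
                rec[f"{side}_v"] = first_gene(top["v_call"])
                rec[f"{side}_j"] = first_gene(top["j_call"])
                rec[f"{side}_junction"] = top["junction"]
                rec[f"{side}_junction_aa"] = top["junction_aa"]
                rec[f"{side}_aa"] = top.get("sequence_alignment_aa", "")
            else:
                rec.update({f"{side}_v": None, f"{side}_j": None,
                            f"{side}_junction": None, f"{side}_junction_aa": None,
                            f"{side}_aa": ""})
        rows.append(rec)
    return pd.DataFrame(rows)


def hamming_similarity(a: str, b: str) -> float:
    """1 - mismatches/length for equal-length strings."""
    if len(a) != len(b):
        raise ParameterError("Hamming similarity requires equal lengths")
    if len(a) == 0:
        return 1.0
    mismatches = sum(c1 != c2 for c1, c2 in zip(a, b))
    return 1.0 - mismatches / len(a)


def _pair_similar(rec_a, rec_b, config: ClonotypeConfig) -> bool:
    for side in ("vdj", "vj"):
        if rec_a[f"{side}_v"] is None:      # chain absent in both (same group key)
            continue
        if config.cdr3_metric == "nucleotide_identity":
            if rec_a[f"{side}_junction"] != rec_b[f"{side}_junction"]:
                return False
        else:
            sim = hamming_similarity(rec_a[f"{side}_junction_aa"],
                                     rec_b[f"{side}_junction_aa"])
            if sim < config.similarity_threshold - 1e-12:
                return False
    return True


def _partition_group(records: list[dict], config: ClonotypeConfig) -> list[list[int]]:
    """Partition one (V, J, length)-group into clones by junction similarity."""
    n = len(records)
    if n == 1:
        return [[0]]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if _pair_similar(records[i], records[j], config):
                g.add_edge(i, j)
    if config.linkage == "single":
        comps = [sorted(c) for c in nx.connected_components(g)]
    else:
        # complete linkage: iteratively peel off maximal cliques, largest
        # first, deterministic by sorted membership
        comps = []
        remaining = set(range(n))
        while remaining:
            sub = g.subgraph(remaining)
            cliques = sorted((sorted(c) for c in nx.find_cliques(sub)),
                             key=lambda c: (-len(c), c))
            comps.append(cliques[0])
            remaining -= set(cliques[0])
    return sorted(comps)


def define_clonotypes(table: pd.DataFrame,
                      config: ClonotypeConfig | None = None) -> pd.DataFrame:
    """Assign a clone id per cell (``cell_id``, ``clone_id`` table).

    Cells lacking junction data on every required chain are left
    unassigned (``clone_id`` is missing).  Clone ids are deterministic:
    groups are keyed by sorted (V, J, junction length) tuples of both
    chains and numbered ``<group>_<component>``.
    """
    config = config or ClonotypeConfig()
    chains = _cell_chain_table(table)
    assignments = {}
    groups: dict[tuple, list[dict]] = {}
    for rec in chains.to_dict("records"):
        has_vdj = rec["vdj_v"] is not None and rec["vdj_junction_aa"]
        has_vj = rec["vj_v"] is not None and rec["vj_junction_aa"]
        if config.require_both_chains:
            usable = has_vdj and has_vj
        else:
            usable = has_vdj or has_vj
        if not usable:
            assignments[rec["cell_id"]] = None
            continue
        if not has_vdj:
            rec = {**rec, "vdj_v": None, "vdj_j": None, "vdj_junction": None,
                   "vdj_junction_aa": None}
        if not has_vj:
            rec = {**rec, "vj_v": None, "vj_j": None, "vj_junction": None,
                   "vj_junction_aa": None}
        key = tuple(
            (rec[f"{side}_v"], rec[f"{side}_j"],
             len(rec[f"{side}_junction_aa"]) if rec[f"{side}_junction_aa"] else -1)
            for side in ("vdj", "vj"))
        groups.setdefault(key, []).append(rec)
    for gi, key in enumerate(sorted(groups, key=str)):
        records = groups[key]
        for ci, comp in enumerate(_partition_group(records, config)):
            for idx in comp:
                assignments[records[idx]["cell_id"]] = f"{gi}_{ci}"
    out = chains[["cell_id"]].copy()
    out["clone_id"] = out["cell_id"].map(assignments)
    return out


# ---------------------------------------------------------------------------
# clone networks

def levenshtein(a: str, b: str) -> int:
    """Exact Levenshtein edit distance (edlib)."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b)["editDistance"]


def _cell_strings(table: pd.DataFrame) -> pd.Series:
    """Per-cell string for edit distances: VDJ alignment ‖ VJ alignment."""
    chains = _cell_chain_table(table)
    joined = chains["vdj_aa"].fillna("") + "|" + chains["vj_aa"].fillna("")
    return pd.Series(joined.to_numpy(), index=chains["cell_id"].to_numpy())


def _kruskal(nodes: list[str], edges: list[tuple[float, str, str]]) -> list[tuple[str, str, float]]:
    """Minimum spanning forest; ties broken by (weight, min id, max id)."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    chosen = []
    for w, u, v in sorted(edges):
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            chosen.append((u, v, w))
    return chosen


def build_network(table: pd.DataFrame, clones: pd.DataFrame) -> nx.Graph:
    """Build the per-clonotype cell graph.

    Within each clone, pairwise Levenshtein distances between cell
    strings feed a minimum spanning forest over the positive-distance
    edges; all zero-distance pairs are then added back (provenance
    ``zero_distance``).  Unassigned cells are excluded.  Node attribute:
    ``clone_id``; edge attributes: ``weight``, ``provenance``.
    """
    strings = _cell_strings(table)
    assigned = clones.dropna(subset=["clone_id"])
    graph = nx.Graph()
    for clone_id, members in assigned.groupby("clone_id", sort=True)["cell_id"]:
        cells = sorted(members)
        for c in cells:
            graph.add_node(c, clone_id=clone_id)
        if len(cells) == 1:
            continue
        positive, zero = [], []
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                d = levenshtein(strings.get(cells[i], ""), strings.get(cells[j], ""))
                if d == 0:
                    zero.append((cells[i], cells[j]))
                else:
                    positive.append((float(d), cells[i], cells[j]))
        for u, v, w in _kruskal(cells, positive):
            graph.add_edge(u, v, weight=w, provenance="mst")
        for u, v in zero:
            graph.add_edge(u, v, weight=0.0, provenance="zero_distance")
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [(u, v, d["weight"], d["provenance"]) for u, v, d in graph.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "weight", "provenance"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# diversity

def gini_diversity(graph: nx.Graph, metadata: pd.DataFrame | None = None,
                   group_by: str | None = None) -> pd.DataFrame:
    """Gini diversity of clone sizes and node centralities, per group.

    ``metadata`` maps ``cell_id`` to grouping columns; without it a
    single overall row is returned.  ``gini_clone_size`` uses the
    distribution of cells per clone within the group;
    ``gini_node_degree`` (default centrality) and ``gini_node_closeness``
    use the network's node centralities restricted to the group's cells.
    """
    if (metadata is None) != (group_by is None):
        raise ParameterError("metadata and group_by must be given together")
    degree = dict(graph.degree())
    closeness = nx.closeness_centrality(graph)
    clone_of = nx.get_node_attributes(graph, "clone_id")
    if metadata is None:
        groups = {"all": list(graph.nodes)}
    else:
        if group_by not in metadata.columns:
            raise ParameterError(f"unknown group key '{group_by}'")
        members = metadata[metadata["cell_id"].isin(graph.nodes)]
        groups = {k: list(v) for k, v in members.groupby(group_by)["cell_id"]}
    rows = []
    for key in sorted(groups, key=str):
        cells = [c for c in groups[key] if c in clone_of]
        if not cells:
            import warnings
            warnings.warn(f"group '{key}' has no assigned cells; skipped", stacklevel=2)
            continue
        sizes = pd.Series([clone_of[c] for c in cells]).value_counts().to_numpy(float)
        rows.append({
            "group": key,
            "gini_clone_size": gini(sizes),
            "gini_node_degree": gini(np.array([degree[c] for c in cells], float)),
            "gini_node_closeness": gini(np.array([closeness[c] for c in cells], float)),
            "n_cells": len(cells),
            "n_clones": len(sizes),
        })
    return pd.DataFrame(rows)
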