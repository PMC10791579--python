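import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from scipy.stats import spearmanr

from vdjflow import vdj_space as vs
from vdjflow.errors import IntegrityError, ParameterError
from vdjflow.synthetic import SimConfig, simulate_repertoire, simulate_trajectory_cells

from conftest import make_contigs


def meta_frame(n_per_group, groups):
    rows = []
    i = 0
    for g in groups:
        for _ in range(n_per_group):
            rows.append({"cell_id": f"cell{i:04d}", **g})
            i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pseudobulk assignment

def test_pseudobulks_from_metadata_partition():
    meta = meta_frame(12, [{"donor": "D1", "celltype": "T"},
                           {"donor": "D1", "celltype": "B"},
                           {"donor": "D2", "celltype": "T"},
                           {"donor": "D2", "celltype": "B"}])
    asn = vs.pseudobulks_from_metadata(meta, ["donor", "celltype"])
    assert len(asn.labels) == 4
    col_sums = np.asarray(asn.matrix.sum(axis=1)).ravel()
    assert (col_sums == 1).all()                # a true partition
    assert sorted(asn.sizes) == [12] * 4


def test_pseudobulks_min_cells_dropped():
    meta = pd.concat([
        meta_frame(12, [{"ct": "big"}]),
        meta_frame(9, [{"ct": "small"}]),
    ], ignore_index=True)
    asn = vs.pseudobulks_from_metadata(meta, ["ct"])
    assert asn.labels == ["big"]
    single = vs.pseudobulks_from_metadata(meta, ["ct"], min_cells=1)
    assert len(single.labels) == 2
    with pytest.raises(ParameterError):
        vs.pseudobulks_from_metadata(meta, [])


def test_sample_neighborhoods_determinism_and_degenerate():
    rng = np.random.default_rng(0)
    emb = rng.normal(size=(40, 3))
    a = vs.sample_neighborhoods(emb, k=5, proportion=0.5, seed=9)
    b = vs.sample_neighborhoods(emb, k=5, proportion=0.5, seed=9)
    assert (a.matrix != b.matrix).nnz == 0
    full = vs.sample_neighborhoods(emb, k=39, proportion=1.0, seed=1)
    assert (np.asarray(full.matrix.sum(axis=0)).ravel() == 40).all()
    with pytest.raises(ParameterError):
        vs.sample_neighborhoods(emb, k=40, proportion=0.5, seed=1)


def test_neighborhoods_respect_planted_clusters():
    rng = np.random.default_rng(1)
    cluster_a = rng.normal(0, 0.1, size=(30, 2))
    cluster_b = rng.normal(100, 0.1, size=(30, 2))
    emb = np.vstack([cluster_a, cluster_b])
    asn = vs.sample_neighborhoods(emb, k=10, proportion=0.5, seed=2)
    M = asn.matrix.toarray().astype(bool)
    for j in range(M.shape[1]):
        members = np.where(M[:, j])[0]
        assert (members < 30).all() or (members >= 30).all()


# ---------------------------------------------------------------------------
# feature space

def small_assignment(cells, labels, membership):
    matrix = sparse.csr_matrix(np.array(membership, dtype=float))
    return vs.PseudobulkAssignment(matrix=matrix, cell_ids=cells, labels=labels)


def test_feature_fractions_arithmetic():
    rows = []
    for i, (av, aj) in enumerate([("TRAV8", "TRAJ1"), ("TRAV8", "TRAJ1"),
                                  ("TRAV8", "TRAJ2")]):
        rows.append({"cell_id": f"c{i}", "locus": "TRA", "v_call": f"{av}*01",
                     "j_call": f"{aj}*01", "junction": "TGT", "junction_aa": "C"})
    table = make_contigs(rows)
    asn = small_assignment([f"c{i}" for i in range(3)], ["pb"], [[1], [1], [1]])
    fm = vs.build_vdj_feature_space(table, asn, loci=("TRA",), segments=("V", "J"))
    assert fm.X.loc["pb", "TRA_J|TRAJ1"] == pytest.approx(2 / 3)
    assert fm.X.loc["pb", "TRA_J|TRAJ2"] == pytest.approx(1 / 3)
    assert fm.X.loc["pb", "TRA_V|TRAV8"] == pytest.approx(1.0)


def test_block_row_sums_unit_or_zero(sim_repertoire):
    contigs, cell_meta, _ = sim_repertoire
    asn = vs.pseudobulks_from_metadata(cell_meta, ["sample_id", "cell_type"],
                                       min_cells=5)
    # request an absent locus (IGH) alongside present ones
    fm = vs.build_vdj_feature_space(contigs, asn, loci=("TRA", "TRB", "IGH"),
                                    segments=("V", "J"))
    for locus in ("TRA", "TRB"):
        for segment in ("V", "J"):
            sums = fm.block(locus, segment).sum(axis=1).to_numpy()
            assert np.all((np.abs(sums - 1) < 1e-12) | (np.abs(sums) < 1e-12))
    igh = fm.block("IGH", "V")
    assert igh.shape[1] == 0                    # no IGH genes observed


def test_feature_space_unknown_barcode_rejected():
    table = make_contigs([{"cell_id": "ghost", "locus": "TRA",
                           "junction": "TGT", "junction_aa": "C"}])
    asn = small_assignment(["c0"], ["pb"], [[1]])
    with pytest.raises(IntegrityError, match="ghost"):
        vs.build_vdj_feature_space(table, asn, loci=("TRA",), segments=("V",))


def test_primary_contig_selection_in_feature_space():
    """The higher-UMI productive contig defines the cell's gene."""
    rows = [
        {"cell_id": "c0", "locus": "TRA", "v_call": "TRAV1*01", "duplicate_count": 2,
         "junction": "TGT", "junction_aa": "C"},
        {"cell_id": "c0", "locus": "TRA", "v_call": "TRAV2*01", "duplicate_count": 9,
         "junction": "TGT", "junction_aa": "C", "productive": "F"},
    ]
    table = make_contigs(rows)
    asn = small_assignment(["c0"], ["pb"], [[1]])
    fm = vs.build_vdj_feature_space(table, asn, loci=("TRA",), segments=("V",))
    assert fm.X.loc["pb", "TRA_V|TRAV1"] == 1.0


# ---------------------------------------------------------------------------
# differential usage

def test_differential_usage_recovers_planted_invariant_gene():
    config = SimConfig(seed=31, n_cells=2400, n_samples=10,
                       cell_type_props={"MAIT": 0.5, "conv": 0.5},
                       invariant_usage={"MAIT": {"TRAV": 2, "TRAJ": 33}})
    contigs, cell_meta, _ = simulate_repertoire(config)
    asn = vs.pseudobulks_from_metadata(cell_meta, ["sample_id", "cell_type"])
    fm = vs.build_vdj_feature_space(contigs, asn, loci=("TRA",), segments=("V", "J"))
    groups = pd.Series([l.split("_")[-1] for l in fm.X.index], index=fm.X.index)
    assert (groups == "MAIT").sum() == 10 and (groups == "conv").sum() == 10
    result = vs.differential_usage(fm, groups)
    mait = result[result["group"] == "MAIT"]
    top = mait.iloc[0]
    assert top["feature"] in ("TRA_V|TRAV2", "TRA_J|TRAJ33")
    assert top["padj"] < 0.05 and top["effect"] > 0


def test_differential_usage_flat_feature_and_errors():
    X = pd.DataFrame({"f": [0.5] * 10, "g": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]},
                     index=[f"pb{i}" for i in range(10)], dtype=float)
    fm = vs.VDJFeatureMatrix(X=X, feature_meta=pd.DataFrame(), cell_counts=np.ones(10))
    groups = pd.Series(["A"] * 5 + ["B"] * 5, index=X.index)
    out = vs.differential_usage(fm, groups).set_index(["group", "feature"])
    assert out.loc[("A", "f"), "pvalue"] == 1.0
    assert out.loc[("A", "f"), "effect"] == 0.0
    # fully separated feature attains the minimal achievable exact p
    assert out.loc[("A", "g"), "pvalue"] == pytest.approx(2 / 252)
    with pytest.raises(ParameterError):
        vs.differential_usage(fm, pd.Series(["A"] + ["B"] * 9, index=X.index))


# ---------------------------------------------------------------------------
# trajectory engine

def path_adjacency(n):
    A = np.zeros((n, n))
    for i in range(n - 1):
        A[i, i + 1] = A[i + 1, i] = 1.0
    return A


def test_gamblers_ruin_closed_form():
    B3 = vs.absorbing_probabilities(path_adjacency(3), [0, 2])
    assert np.allclose(B3[1], [0.5, 0.5])
    B4 = vs.absorbing_probabilities(path_adjacency(4), [0, 3])
    assert B4[1, 1] == pytest.approx(1 / 3)
    assert B4[2, 1] == pytest.approx(2 / 3)
    for n in range(4, 21):
        B = vs.absorbing_probabilities(path_adjacency(n), [0, n - 1])
        start = np.arange(n)
        assert np.allclose(B[:, 1], start / (n - 1))   # gambler's ruin
        assert np.allclose(B.sum(axis=1), 1.0)


def test_baseline_trajectory_properties(sim_repertoire):
    contigs, cell_meta, truth = sim_repertoire
    asn = vs.pseudobulks_from_metadata(cell_meta, ["sample_id", "cell_type"],
                                       min_cells=5)
    fm = vs.build_vdj_feature_space(contigs, asn, loci=("TRA", "TRB"),
                                    segments=("V", "J"))
    labels = list(fm.X.index)
    result = vs.baseline_trajectory(fm, root=labels[0],
                                    terminals=[labels[-1]], k=3)
    assert result.pseudotime[labels[0]] == 0.0
    assert result.pseudotime.max() == pytest.approx(1.0)
    assert np.allclose(result.branch_probabilities.sum(axis=1), 1.0)
    with pytest.raises(ParameterError):
        vs.baseline_trajectory(fm, root="nope", terminals=[labels[-1]])


def test_trajectory_recovers_latent_time():
    """End-to-end parameter recovery: neighborhood V(D)J pseudotime tracks
    the planted maturation time."""
    config = SimConfig(seed=17, n_cells=1500)
    cell_meta, contigs, truth = simulate_trajectory_cells(config)
    emb = cell_meta[["e0", "e1"]].to_numpy()
    asn = vs.sample_neighborhoods(emb, k=30, proportion=0.1, seed=17,
                                  cell_ids=list(cell_meta["cell_id"]))
    fm = vs.build_vdj_feature_space(contigs, asn, loci=("TRA", "TRB"),
                                    segments=("V", "J"))
    t = truth["cells"].set_index("cell_id")["latent_time"]
    M = asn.matrix.toarray().astype(bool)
    ids = np.asarray(asn.cell_ids)
    mean_t = pd.Series([t.loc[ids[M[:, j]]].mean() for j in range(len(asn.labels))],
                       index=asn.labels)
    root = mean_t.idxmin()
    branch = truth["cells"].set_index("cell_id")["branch"]
    dom = pd.Series([branch.loc[ids[M[:, j]]].mode()[0] for j in range(len(asn.labels))],
                    index=asn.labels)
    terminals = [mean_t[dom == b].idxmax() for b in (1, 2)]
    result = vs.baseline_trajectory(fm, root, terminals, k=10, n_pcs=5)
    rho = spearmanr(result.pseudotime, mean_t.loc[result.pseudotime.index]).statistic
    assert abs(rho) >= 0.8


# ---------------------------------------------------------------------------
# projection and fidelity metrics

def test_project_weighted_average():
    asn = small_assignment(["c0", "c1"], ["small", "big"],
                           np.array([[1, 1], [0, 1]]))
    # sizes: small=1, big=2; planted values 0.2 (small) and 0.6 (big)
    values = pd.Series({"small": 0.2, "big": 0.6})
    projected, dropped = vs.project_to_cells(values, asn)
    # c0: (0.2/1 + 0.6/2) / (1/1 + 1/2) = 0.5/1.5
    assert projected["c0"] == pytest.approx(0.5 / 1.5)
    assert projected["c1"] == pytest.approx(0.6)
    assert dropped == 0


def test_project_partition_is_identity(sim_repertoire):
    _, cell_meta, _ = sim_repertoire
    asn = vs.pseudobulks_from_metadata(cell_meta, ["sample_id", "cell_type"],
                                       min_cells=5)
    values = pd.Series(np.arange(len(asn.labels), dtype=float), index=asn.labels)
    projected, dropped = vs.project_to_cells(values, asn)
    M = asn.matrix.toarray()
    for j, label in enumerate(asn.labels):
        members = np.asarray(asn.cell_ids)[M[:, j] > 0]
        assert np.allclose(projected.loc[members], values[label])
    assert dropped == asn.n_cells - len(projected)


def test_project_orphan_cells_dropped():
    asn = small_assignment(["c0", "c1"], ["pb"], [[1], [0]])
    projected, dropped = vs.project_to_cells(pd.Series({"pb": 1.0}), asn)
    assert "c1" not in projected.index and dropped == 1


def test_relative_location_encoding_and_means():
    genes = [f"TRAJ{i}" for i in range(61, 0, -1)]    # 5'->3' order
    enc = vs.relative_location_encoding(genes)
    assert enc["TRAJ61"] == 1 and enc["TRAJ1"] == 61
    asn = small_assignment(["c0", "c1"], ["pb"], [[1], [1]])
    cell_genes = pd.Series({"c0": "TRAJ59", "c1": "TRAJ57"})
    means, n_unmapped = vs.mean_relative_location(cell_genes, asn, enc)
    assert means["pb"] == pytest.approx(4.0)          # indices 3 and 5
    assert n_unmapped == 0
    with pytest.warns(UserWarning):
        means, n_unmapped = vs.mean_relative_location(
            pd.Series({"c0": "TRAJ59", "c1": "UNKNOWN"}), asn, enc)
    assert n_unmapped == 1 and means["pb"] == 3.0


def test_sliding_window_correlation():
    pt = pd.Series(np.linspace(0, 1, 40), index=[f"pb{i}" for i in range(40)])
    df, mean_r = vs.sliding_window_correlation(pt, pt, w=30)
    assert len(df) == 11                              # n - w + 1 windows
    assert np.allclose(df["r"], 1.0) and mean_r == pytest.approx(1.0)
    df_neg, mean_neg = vs.sliding_window_correlation(pt, -pt, w=30)
    assert mean_neg == pytest.approx(-1.0)
    flat = pd.Series(np.ones(40), index=pt.index)
    df_flat, mean_flat = vs.sliding_window_correlation(pt, flat, w=30)
    assert df_flat["r"].isna().all() and np.isnan(mean_flat)
    with pytest.raises(ParameterError):
        vs.sliding_window_correlation(pt, pt, w=41)


def test_assignment_round_trip(tmp_path, sim_repertoire):
    _, cell_meta, _ = sim_repertoire
    asn = vs.pseudobulks_from_metadata(cell_meta, ["sample_id"], min_cells=5)
    prefix = str(tmp_path / "asn")
    vs.write_assignment(asn, prefix)
    back = vs.read_assignment(prefix)
    assert back.labels == asn.labels
    assert back.cell_ids == asn.cell_ids
    assert (back.matrix != asn.matrix).nnz == 0
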