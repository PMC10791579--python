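"""Seeded generative model of single-cell V(D)J repertoires.

Emits AIRR contig tables, blastn-style J-hit tables, cell metadata,
embeddings and truth tables carrying the latent variables, so that every
analysis in the package can be exercised and validated without external
data.  The generator plants the statistical structure the analyses
assume:

* per-locus V/J gene choice, with *processive* TRA usage — the window of
  V and J indices in use drifts monotonically with a latent maturation
  time t in [0, 1], mimicking successive rearrangement attempts marching
  from the middle to the distal ends of the locus;
* productive/nonproductive outcomes with per-cause structure (absent V
  gene, frameshift, premature stop codon, missing junction);
* multi-J mapping driven by a logistic model in cell type, 5'-end J
  gene, V presence and a translation-inhibitor treatment indicator (the
  treatment enters only through its interaction with V presence),
  emulating depletion of translatable multi-J transcripts by
  nonsense-mediated decay;
* hit-table geometry: 2-4 neighboring J genes in non-overlapping blocks,
  decoy overlapping hits with weaker support, and noise hits above the
  e-value cutoff;
* cell types with distinct usage profiles (including an invariant
  MAIT-like type with a fixed TRAV/TRAJ pair), clonal expansion, and a
  branching trajectory variant with a smooth 2-D embedding.

Junctions are random in-frame codon strings with canonical anchor
residues (C...F/W) — realistic enough for Hamming/Levenshtein logic
without germline sequences.  All randomness flows from a single seed via
independent per-component streams, so outputs are byte-identical across
runs and adding one feature does not perturb the draws of another.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .airr_io import first_gene
from .errors import ParameterError

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES if a + b + c not in _STOPS]
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def translate(nt: str) -> str:
    return "".join(_CODON_TABLE[nt[i:i + 3]] for i in range(0, len(nt) - len(nt) % 3, 3))


@dataclass
class SimConfig:
    """Generator parameters; the seed is mandatory.

    Gene pools default to realistic human locus sizes (50 TRAV, 61 TRAJ,
    48 TRBV, 13 TRBJ, 2 TRBD).  ``multij_*`` are the coefficients of the
    planted logistic model on the log-odds scale.
    """

    seed: int
    n_cells: int = 1000
    n_samples: int = 1
    library_type: str = "tr-ab"
    gene_pools: dict = field(default_factory=lambda: {
        "TRAV": 50, "TRAJ": 61, "TRBV": 48, "TRBJ": 13, "TRBD": 2,
        "IGHV": 50, "IGHJ": 6, "IGHD": 27, "IGKV": 40, "IGKJ": 5,
    })
    cell_type_props: dict = field(default_factory=lambda: {
        "CD4_T": 0.45, "CD8_T": 0.45, "MAIT": 0.10})
    #: cell types with an invariant (fixed-index) gene per segment
    invariant_usage: dict = field(default_factory=lambda: {
        "MAIT": {"TRAV": 2, "TRAJ": 33}})
    p_nonproductive: float = 0.15
    cause_mix: dict = field(default_factory=lambda: {
        "missing_v": 0.50, "frameshift": 0.20,
        "premature_stop": 0.25, "missing_junction": 0.05})
    #: processive TRA usage: window centre drifts linearly with t
    processive: bool = True
    window_sd: float = 4.0
    #: planted multi-J logistic model (log-odds)
    multij_intercept: float = -2.0
    multij_beta_celltype: dict = field(default_factory=dict)
    multij_beta_j: dict = field(default_factory=dict)
    multij_beta_v: float = -1.2      # NMD depletes translatable multi-J contigs
    multij_beta_cyclo: float = 0.8   # treatment relaxes NMD for V-present contigs
    multij_span: tuple = (2, 4)
    jhit_length: int = 50
    jhit_gap: tuple = (20, 40)
    jhit_log10e: tuple = (-30.0, -8.0)
    decoy_prob: float = 0.5
    decoy_log10e: tuple = (-7.0, -5.0)
    noise_prob: float = 0.3
    noise_log10e: tuple = (-3.0, -0.5)
    treatment_frac: float = 0.0
    expansion_rate: float = 0.2
    umi_mean: float = 3.0
    #: trajectory variant
    branch_time: float = 0.5
    branch_shift: float = 12.0
    embedding_noise: float = 0.02

    def __post_init__(self):
        if self.seed is None:
            raise ParameterError("seed is mandatory")
        for name in ("p_nonproductive", "decoy_prob", "noise_prob",
                     "treatment_frac", "expansion_rate", "branch_time"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if any(n < 1 for n in self.gene_pools.values()):
            raise ParameterError("gene pool sizes must be >= 1")
        if abs(sum(self.cause_mix.values()) - 1) > 1e-9:
            raise ParameterError("cause_mix must sum to 1")
        props = np.array(list(self.cell_type_props.values()), float)
        if abs(props.sum() - 1) > 1e-9 or (props < 0).any():
            raise ParameterError("cell_type_props must be a probability vector")
        for ct, usage in self.invariant_usage.items():
            for seg, idx in usage.items():
                if seg in self.gene_pools and not 1 <= idx <= self.gene_pools[seg]:
                    raise ParameterError(
                        f"invariant gene index {seg}{idx} outside pool for '{ct}'")

    def stream(self, name: str) -> np.random.Generator:
        """Independent, deterministic RNG stream keyed by component name."""
        key = zlib.crc32(name.encode())
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))

    def streams(self, *names: str) -> dict[str, np.random.Generator]:
        return {n: self.stream(n) for n in names}


def _gene(segment: str, index: int) -> str:
    return f"{segment}{index}"


def _gene_index(gene: str) -> int:
    m = re.search(r"(\d+)$", gene)
    return int(m.group(1)) if m else 0


def _germline_aa(gene: str, length: int = 20) -> str:
    """Deterministic pseudo-germline amino-acid string for a gene."""
    rng = np.random.default_rng(zlib.crc32(gene.encode()))
    return "".join(rng.choice(list(_AA_ALPHABET), size=length))


def _draw_index(rng, pool: int, center: float | None, sd: float) -> int:
    if center is None:
        return int(rng.integers(1, pool + 1))
    return int(np.clip(round(rng.normal(center, sd)), 1, pool))


def _junction(rng, n_codons: int) -> tuple[str, str]:
    codons = ["TGT"] + [str(rng.choice(_CODONS)) for _ in range(n_codons - 2)]
    codons.append(str(rng.choice(["TTT", "TGG"])))  # F or W anchor
    nt = "".join(codons)
    return nt, translate(nt)


def _receptor(rng, config: SimConfig, locus_v: str, locus_j: str,
              locus_d: str | None, t: float, cell_type: str,
              centers: dict | None = None) -> dict:
    """Draw the gene choices and junction for one chain."""
    inv = config.invariant_usage.get(cell_type, {})
    pool_v = config.gene_pools[locus_v]
    pool_j = config.gene_pools[locus_j]
    centers = centers or {}
    if locus_v in inv:
        v_idx = inv[locus_v]
    else:
        center = centers.get(locus_v)
        if center is None and config.processive and locus_v == "TRAV":
            center = 1 + t * (pool_v - 1)
        v_idx = _draw_index(rng, pool_v, center, config.window_sd)
    if locus_j in inv:
        j_idx = inv[locus_j]
    else:
        center = centers.get(locus_j)
        if center is None and config.processive and locus_j == "TRAJ":
            center = 1 + t * (pool_j - 1)
        j_idx = _draw_index(rng, pool_j, center, config.window_sd)
    n_codons = int(rng.integers(5, 9))
    nt, aa = _junction(rng, n_codons)
    rec = {
        "v_gene": _gene(locus_v, v_idx),
        "j_gene": _gene(locus_j, j_idx),
        "d_gene": _gene(locus_d, int(rng.integers(1, config.gene_pools[locus_d] + 1)))
        if locus_d else "",
        "junction": nt,
        "junction_aa": aa,
    }
    return rec


_LOCUS_PLAN = {
    "tr-ab": [("TRB", "TRBV", "TRBJ", "TRBD", "TRBC1"),
              ("TRA", "TRAV", "TRAJ", None, "TRAC")],
    "ig": [("IGH", "IGHV", "IGHJ", "IGHD", "IGHM"),
           ("IGK", "IGKV", "IGKJ", None, "IGKC")],
}


def simulate_repertoire(config: SimConfig):
    """Simulate paired-chain contigs for ``config.n_cells`` cells.

    Returns ``(contigs, cell_meta, truth)``: an AIRR-style contig table,
    per-cell metadata (sample, cell type, treatment) and a truth table
    with the latent time, clone id and per-contig nonproductive cause.
    """
    rng = config.streams("cells", "receptor", "productive", "umi", "clone")
    plan = _LOCUS_PLAN[config.library_type if config.library_type in _LOCUS_PLAN
                       else "tr-ab"]
    type_names = list(config.cell_type_props)
    type_p = np.array(list(config.cell_type_props.values()))
    contigs, cells, contig_truth = [], [], []
    clone_pool: list[tuple[str, dict]] = []   # (clone_id, receptors per locus)
    n_clones = 0
    causes = list(config.cause_mix)
    cause_p = np.array(list(config.cause_mix.values()))
    for i in range(config.n_cells):
        sample = f"S{1 + i % config.n_samples}"
        cell_id = f"{sample}_CELL{i:06d}"
        t = float(rng["cells"].uniform())
        cell_type = str(rng["cells"].choice(type_names, p=type_p))
        treated = bool(rng["cells"].uniform() < config.treatment_frac)
        if clone_pool and rng["clone"].uniform() < config.expansion_rate:
            clone_id, receptors = clone_pool[int(rng["clone"].integers(len(clone_pool)))]
        else:
            receptors = {
                locus: _receptor(rng["receptor"], config, lv, lj, ld, t, cell_type)
                for locus, lv, lj, ld, _ in plan}
            clone_id = f"clone{n_clones:05d}"
            n_clones += 1
            clone_pool.append((clone_id, receptors))
        cells.append({"cell_id": cell_id, "sample_id": sample,
                      "cell_type": cell_type, "treatment": treated,
                      "latent_time": t, "clone_id": clone_id})
        for k, (locus, lv, lj, ld, c_gene) in enumerate(plan):
            rec = receptors[locus]
            nonproductive = rng["productive"].uniform() < config.p_nonproductive
            cause = str(rng["productive"].choice(causes, p=cause_p)) if nonproductive else ""
            v_call = "" if cause == "missing_v" else f"{rec['v_gene']}*01"
            junction, junction_aa = rec["junction"], rec["junction_aa"]
            vj_in_frame, stop_codon = "T", "F"
            if cause == "missing_junction":
                junction, junction_aa = "", ""
            elif cause == "frameshift":
                junction = junction + "A"       # out-of-frame by one base
                vj_in_frame = "F"
            elif cause == "premature_stop":
                junction = junction[:3] + "TAA" + junction[6:]
                junction_aa = translate(junction)
                stop_codon = "T"
            aa_align = (_germline_aa(rec["v_gene"]) if v_call else "") \
                + junction_aa + _germline_aa(rec["j_gene"], 10)
            contigs.append({
                "sequence_id": f"{cell_id}_contig_{k + 1}",
                "cell_id": cell_id,
                "sample_id": sample,
                "locus": locus,
                "v_call": v_call,
                "d_call": f"{rec['d_gene']}*01" if rec["d_gene"] else "",
                "j_call": f"{rec['j_gene']}*01",
                "c_call": c_gene,
                "junction": junction,
                "junction_aa": junction_aa,
                "productive": "F" if nonproductive else "T",
                "vj_in_frame": vj_in_frame,
                "stop_codon": stop_codon,
                "duplicate_count": int(1 + rng["umi"].poisson(config.umi_mean)),
                "sequence_alignment_aa": aa_align,
            })
            contig_truth.append({"sequence_id": contigs[-1]["sequence_id"],
                                 "nonproductive_cause": cause})
    truth = {"cells": pd.DataFrame(cells)[["cell_id", "latent_time",
                                           "cell_type", "clone_id", "treatment"]],
             "contigs": pd.DataFrame(contig_truth)}
    cell_meta = pd.DataFrame(cells)[["cell_id", "sample_id", "cell_type", "treatment"]]
    return pd.DataFrame(contigs), cell_meta, truth


def multij_probability(design: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Planted multi-J probability per contig under the logistic model."""
    eta = np.full(len(design), config.multij_intercept)
    eta += design["cell_type"].map(
        lambda c: config.multij_beta_celltype.get(c, 0.0)).to_numpy()
    eta += design["j_gene"].map(
        lambda j: config.multij_beta_j.get(j, 0.0)).to_numpy()
    xv = design["v_gene_present"].astype(bool).to_numpy()
    xt = design["treatment"].astype(bool).to_numpy()
    eta = eta + config.multij_beta_v * xv + config.multij_beta_cyclo * (xv & xt)
    return 1.0 / (1.0 + np.exp(-eta))


def multij_design(contigs: pd.DataFrame, cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Covariate table for the multi-J model (one row per contig)."""
    design = contigs[["sequence_id", "cell_id", "locus", "v_call", "j_call"]].copy()
    design["v_gene_present"] = design["v_call"] != ""
    design["j_gene"] = design["j_call"].map(first_gene)
    design = design.merge(cell_meta[["cell_id", "cell_type", "treatment"]],
                          on="cell_id", how="left")
    if design["treatment"].dtype == object:     # TSV round-trip gives strings
        design["treatment"] = design["treatment"].astype(str).isin(
            ["True", "TRUE", "true", "T", "1"])
    return design


def simulate_jhits(config: SimConfig, contigs: pd.DataFrame,
                   cell_meta: pd.DataFrame):
    """Simulate a blastn-style J hit table for every contig.

    Multi-J status is drawn per contig from the planted logistic model;
    multi-J contigs receive 2-4 non-overlapping blocks on neighboring J
    genes with the intended (5'-leftmost) gene first, plus optional
    decoy overlapping hits with weaker support and noise hits above the
    e-value cutoff.  Returns ``(jhits, truth)`` where truth carries the
    planted flag per contig.
    """
    streams = config.streams("multij", "geometry")
    rng_flag, rng_geo = streams["multij"], streams["geometry"]
    design = multij_design(contigs, cell_meta)
    p = multij_probability(design, config)
    is_multij = rng_flag.uniform(size=len(design)) < p
    lo, hi = config.multij_span
    hits = []
    for row, multi in zip(design.to_dict("records"), is_multij):
        j_gene = row["j_gene"]
        segment = j_gene.rstrip("0123456789")
        pool = config.gene_pools.get(segment, 61)
        j_idx = _gene_index(j_gene)
        n_genes = int(rng_geo.integers(lo, hi + 1)) if multi else 1
        neighbor_pool = [x for x in range(j_idx + 1, pool + 1)] + \
            [x for x in range(j_idx - 1, 0, -1)]
        gene_indices = [j_idx] + neighbor_pool[:n_genes - 1]
        start = int(rng_geo.integers(250, 351))
        blocks = []
        for idx in gene_indices:
            end = start + config.jhit_length - 1
            blocks.append((idx, start, end))
            start = end + 1 + int(rng_geo.integers(*config.jhit_gap))
        for idx, s, e in blocks:
            log_e = rng_geo.uniform(*config.jhit_log10e)
            hits.append({"sequence_id": row["sequence_id"],
                         "j_gene": _gene(segment, idx),
                         "j_support": 10.0 ** log_e,
                         "bit_score": round(-2.0 * log_e, 1),
                         "j_sequence_start": s, "j_sequence_end": e})
        first = blocks[0]
        if rng_geo.uniform() < config.decoy_prob:
            decoy_idx = gene_indices[-1] % pool + 1
            log_e = rng_geo.uniform(*config.decoy_log10e)
            hits.append({"sequence_id": row["sequence_id"],
                         "j_gene": _gene(segment, decoy_idx),
                         "j_support": 10.0 ** log_e,
                         "bit_score": round(-2.0 * log_e, 1),
                         "j_sequence_start": first[1] + 5,
                         "j_sequence_end": first[2] + 5})
        if rng_geo.uniform() < config.noise_prob:
            log_e = rng_geo.uniform(*config.noise_log10e)
            hits.append({"sequence_id": row["sequence_id"],
                         "j_gene": _gene(segment, int(rng_geo.integers(1, pool + 1))),
                         "j_support": 10.0 ** log_e,
                         "bit_score": round(-2.0 * log_e, 1),
                         "j_sequence_start": first[1],
                         "j_sequence_end": first[2]})
    truth = design[["sequence_id", "cell_type", "j_gene",
                    "v_gene_present", "treatment"]].copy()
    truth["is_multij_true"] = is_multij
    truth["n_j_true"] = 1
    return pd.DataFrame(hits), truth


def simulate_multij_response(design: pd.DataFrame, config: SimConfig,
                             rng: np.random.Generator) -> np.ndarray:
    """Redraw the multi-J indicator for fixed covariates (fast, vectorised).

    Used for repeated null/recovery simulations of the logistic model
    without regenerating contigs.
    """
    p = multij_probability(design, config)
    return rng.uniform(size=len(design)) < p


def simulate_trajectory_cells(config: SimConfig):
    """Branching-trajectory variant with a smooth 2-D embedding.

    Cells carry a latent time t in [0, 1] and, past ``branch_time``, a
    binary branch label.  The embedding is a smooth function of
    (t, branch) plus Gaussian noise so k-NN neighborhoods are contiguous
    in t; TRAV/TRAJ usage is processive in t and the TRBV usage window
    shifts by ``branch_shift`` genes between branches after the branch
    point.  All contigs are productive.  Returns
    ``(cell_meta, contigs, truth)`` with the embedding in columns
    ``e0``/``e1`` of ``cell_meta``.
    """
    rng = config.streams("traj_cells", "traj_receptor", "traj_umi")
    n = config.n_cells
    t = rng["traj_cells"].uniform(size=n)
    branch = np.where(t >= config.branch_time,
                      rng["traj_cells"].integers(1, 3, size=n), 0)
    noise = config.embedding_noise
    e0 = t + rng["traj_cells"].normal(0, noise, size=n)
    sign = np.where(branch == 1, 1.0, np.where(branch == 2, -1.0, 0.0))
    e1 = sign * (t - config.branch_time) + rng["traj_cells"].normal(0, noise, size=n)
    pool_bv = config.gene_pools["TRBV"]
    contigs, cells = [], []
    for i in range(n):
        cell_id = f"S1_CELL{i:06d}"
        cells.append({"cell_id": cell_id, "sample_id": "S1",
                      "cell_type": {0: "DP_T", 1: "CD4_T", 2: "CD8_T"}[int(branch[i])],
                      "treatment": False, "e0": float(e0[i]), "e1": float(e1[i])})
        centers = {}
        if branch[i]:
            base = (pool_bv + 1) / 2
            shift = config.branch_shift if branch[i] == 1 else -config.branch_shift
            centers["TRBV"] = base + shift * (t[i] - config.branch_time) / (
                1 - config.branch_time)
        for k, (locus, lv, lj, ld, c_gene) in enumerate(_LOCUS_PLAN["tr-ab"]):
            rec = _receptor(rng["traj_receptor"], config, lv, lj, ld,
                            float(t[i]), "conv", centers)
            aa_align = _germline_aa(rec["v_gene"]) + rec["junction_aa"] \
                + _germline_aa(rec["j_gene"], 10)
            contigs.append({
                "sequence_id": f"{cell_id}_contig_{k + 1}",
                "cell_id": cell_id, "sample_id": "S1", "locus": locus,
                "v_call": f"{rec['v_gene']}*01",
                "d_call": f"{rec['d_gene']}*01" if rec["d_gene"] else "",
                "j_call": f"{rec['j_gene']}*01", "c_call": c_gene,
                "junction": rec["junction"], "junction_aa": rec["junction_aa"],
                "productive": "T", "vj_in_frame": "T", "stop_codon": "F",
                "duplicate_count": int(1 + rng["traj_umi"].poisson(config.umi_mean)),
                "sequence_alignment_aa": aa_align,
            })
    cell_meta = pd.DataFrame(cells)
    truth = {"cells": pd.DataFrame({"cell_id": cell_meta["cell_id"],
                                    "latent_time": t, "branch": branch})}
    return cell_meta, pd.DataFrame(contigs), truth
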