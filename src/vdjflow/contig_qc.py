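"""Cell-level receptor quality control.

Single cells should express one heavy-type (VDJ) and one light-type (VJ)
receptor chain.  ``check_contigs`` annotates each cell with a status —
``single_pair``, ``orphan_VDJ``/``orphan_VJ`` (one side missing),
``extra_pair`` (surplus productive chains) or ``ambiguous`` (TCR and BCR
contigs in the same cell, biologically irreconcilable) — without
discarding nonproductive contigs, which carry information about a cell's
recombination history.  Two biological exceptions are honoured:

* a productive IgM and IgD heavy chain may coexist in one B cell when no
  other isotype is present (alternative splicing of a single
  rearrangement);
* productive TRB and TRD contigs may co-occur, since the two loci
  rearrange concurrently and TRD shows allelic inclusion.

``filter_contigs`` is the stringent variant: it considers productive
contigs only and keeps cells with exactly one VDJ + VJ pair, or a lone
VDJ chain; everything else is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .airr_io import LIBRARY_LOCI, VDJ_LOCI, VJ_LOCI, first_gene, parse_gene_call
from .errors import ParameterError

STATUSES = ("single_pair", "orphan_VDJ", "orphan_VJ", "extra_pair", "ambiguous", "none")


@dataclass
class CellReceptorStatus:
    cell_id: str
    vdj_primary: str | None
    vj_primary: str | None
    chain_status: str
    flags: frozenset = field(default_factory=frozenset)
    retained_contigs: frozenset = field(default_factory=frozenset)


def order_cell_contigs(contigs: pd.DataFrame) -> pd.DataFrame:
    """Deterministic per-cell contig ordering.

    Productive contigs rank above nonproductive ones; within each class,
    UMI (duplicate) count descends; remaining ties break lexicographically
    on ``sequence_id``.
    """
    key = pd.DataFrame({
        "nonprod": contigs["productive"] != "T",
        "neg_umi": -contigs["duplicate_count"].astype(int),
        "sid": contigs["sequence_id"],
    }, index=contigs.index)
    order = key.sort_values(["nonprod", "neg_umi", "sid"], kind="stable").index
    return contigs.loc[order]


def select_primary_contigs(contigs: pd.DataFrame) -> tuple[str | None, str | None]:
    """Top-ranked contig per chain class (VDJ, VJ) for one cell."""
    ordered = order_cell_contigs(contigs)
    vdj = ordered[ordered["locus"].isin(VDJ_LOCI)]
    vj = ordered[ordered["locus"].isin(VJ_LOCI)]
    return (
        vdj["sequence_id"].iloc[0] if len(vdj) else None,
        vj["sequence_id"].iloc[0] if len(vj) else None,
    )


def locus_consistent(record: dict) -> bool:
    """All non-empty V/D/J/C gene calls share the contig's locus prefix."""
    locus = record.get("locus", "")
    for col in ("v_call", "d_call", "j_call", "c_call"):
        for gene, _ in parse_gene_call(record.get(col, "")):
            if not gene.startswith(locus):
                return False
    return True


def _igh_isotypes(cell_df: pd.DataFrame) -> set[str]:
    iso = set()
    for call in cell_df.loc[cell_df["locus"] == "IGH", "c_call"]:
        gene = first_gene(call)
        if gene:
            iso.add(gene)
    return iso


def _side_is_extra(prod: pd.DataFrame, side_loci: frozenset, all_igh_isotypes: set[str]) -> bool:
    """Surplus productive chains on one side, after the two exceptions."""
    side = prod[prod["locus"].isin(side_loci)]
    if len(side) <= 1:
        return False
    counts = side["locus"].value_counts()
    if side_loci is VDJ_LOCI:
        # within-locus surplus is always extra
        for locus, n in counts.items():
            if n > 1 and locus != "IGH":
                return True
        n_igh = counts.get("IGH", 0)
        if n_igh > 1:
            # IgM + IgD from one rearrangement are not a surplus, provided
            # no other isotype is detected in the cell
            igh = side[side["locus"] == "IGH"]
            iso = {first_gene(c) for c in igh["c_call"]}
            if not (n_igh == 2 and iso == {"IGHM", "IGHD"}
                    and all_igh_isotypes <= {"IGHM", "IGHD"}):
                return True
        # cross-locus: TRB + TRD co-occurrence is permitted; IGH cannot
        # co-occur with TR loci here (that cell is ambiguous upstream)
        return False
    # VJ side: no exceptions — more than one productive light-type chain
    # (same or different locus) is extra
    return True


def _cell_status(cell_df: pd.DataFrame) -> CellReceptorStatus:
    cell_id = cell_df["cell_id"].iloc[0]
    consistent = cell_df[cell_df["qc_locus_consistent"]]
    flags = set()
    if not cell_df["qc_locus_consistent"].all():
        flags.add("inconsistent_calls")
    vdj_primary, vj_primary = select_primary_contigs(consistent) if len(consistent) \
        else (None, None)
    receptor_classes = {locus[:2] for locus in consistent["locus"]}
    prod = consistent[consistent["productive"] == "T"]
    n_vdj = int(prod["locus"].isin(VDJ_LOCI).sum())
    n_vj = int(prod["locus"].isin(VJ_LOCI).sum())
    if receptor_classes == {"TR", "IG"}:
        status = "ambiguous"
        flags.add("ambiguous")
    elif n_vdj == 0 and n_vj == 0:
        status = "none"
    else:
        iso = _igh_isotypes(consistent)
        extra = (_side_is_extra(prod, VDJ_LOCI, iso)
                 or _side_is_extra(prod, VJ_LOCI, iso))
        if extra:
            status = "extra_pair"
            flags.add("extra")
        elif n_vdj > 0 and n_vj > 0:
            status = "single_pair"
        elif n_vdj > 0:
            status = "orphan_VDJ"
            flags.add("orphan")
        else:
            status = "orphan_VJ"
            flags.add("orphan")
    return CellReceptorStatus(
        cell_id=cell_id,
        vdj_primary=vdj_primary,
        vj_primary=vj_primary,
        chain_status=status,
        flags=frozenset(flags),
        retained_contigs=frozenset(cell_df["sequence_id"]),
    )


def _restrict(table: pd.DataFrame, gex_barcodes, library_type,
              allowed_loci) -> tuple[pd.DataFrame, dict]:
    counts = {"input_contigs": len(table)}
    if allowed_loci is None:
        if library_type is None:
            allowed_loci = None
        elif library_type in LIBRARY_LOCI:
            allowed_loci = LIBRARY_LOCI[library_type]
        else:
            raise ParameterError(f"unknown library_type '{library_type}'")
    kept = table
    if allowed_loci is not None:
        kept = kept[kept["locus"].isin(allowed_loci)]
    counts["library_removed"] = counts["input_contigs"] - len(kept)
    if gex_barcodes is not None:
        barcode_set = set(gex_barcodes)
        before = len(kept)
        kept = kept[kept["cell_id"].isin(barcode_set)]
        counts["barcode_removed"] = before - len(kept)
    else:
        counts["barcode_removed"] = 0
    return kept.reset_index(drop=True), counts


def _status_frame(statuses: list[CellReceptorStatus]) -> pd.DataFrame:
    return pd.DataFrame({
        "cell_id": [s.cell_id for s in statuses],
        "chain_status": [s.chain_status for s in statuses],
        "vdj_primary": [s.vdj_primary for s in statuses],
        "vj_primary": [s.vj_primary for s in statuses],
        "flags": ["|".join(sorted(s.flags)) for s in statuses],
    })


def check_contigs(table: pd.DataFrame, gex_barcodes=None,
                  library_type: str | None = "tr-ab",
                  allowed_loci: frozenset | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate receptor status per cell without dropping nonproductive contigs.

    Contigs are removed only by the library-type locus restriction and
    (when ``gex_barcodes`` is given) by absence from the gene-expression
    barcode list.  Returns the annotated contig table and a per-cell
    status table.  ``library_type=None`` disables the locus restriction.
    """
    kept, _ = _restrict(table, gex_barcodes, library_type, allowed_loci)
    kept["qc_locus_consistent"] = [locus_consistent(r) for r in kept.to_dict("records")]
    statuses = [_cell_status(g) for _, g in kept.groupby("cell_id", sort=True)]
    status_df = _status_frame(statuses)
    kept = kept.merge(status_df[["cell_id", "chain_status"]], on="cell_id", how="left")
    kept = kept.rename(columns={"chain_status": "qc_chain_status"})
    return kept, status_df


def _retained_for_cell(status: CellReceptorStatus, prod: pd.DataFrame,
                       keep_top: bool) -> set[str]:
    if status.chain_status == "single_pair":
        return set(prod["sequence_id"])
    if status.chain_status == "orphan_VDJ":
        return set(prod[prod["locus"].isin(VDJ_LOCI)]["sequence_id"])
    if status.chain_status == "extra_pair" and keep_top:
        return {c for c in (status.vdj_primary, status.vj_primary) if c is not None}
    return set()


def filter_contigs(table: pd.DataFrame, gex_barcodes=None,
                   library_type: str | None = "tr-ab",
                   allowed_loci: frozenset | None = None,
                   keep_top: bool = False,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stringent QC: keep one productive VDJ+VJ pair or a lone VDJ per cell.

    Only productive contigs are considered.  Cells that are ambiguous,
    VJ-orphan-only or carry irreconcilable extra chains are dropped
    entirely; with ``keep_top=True`` extra-pair cells instead keep their
    top-UMI primaries.  The IgM/IgD and TRB/TRD exceptions apply, in
    which case every chain of the allowed group is retained.
    """
    kept, _ = _restrict(table, gex_barcodes, library_type, allowed_loci)
    kept = kept[kept["productive"] == "T"].reset_index(drop=True)
    kept["qc_locus_consistent"] = [locus_consistent(r) for r in kept.to_dict("records")]
    kept = kept[kept["qc_locus_consistent"]].reset_index(drop=True)
    retained_ids: set[str] = set()
    statuses = []
    for _, cell_df in kept.groupby("cell_id", sort=True):
        status = _cell_status(cell_df)
        statuses.append(status)
        retained_ids |= _retained_for_cell(status, cell_df, keep_top)
    out = kept[kept["sequence_id"].isin(retained_ids)].reset_index(drop=True)
    out = out.drop(columns=["qc_locus_consistent"])
    return out, _status_frame(statuses)


def qc_report(status_df: pd.DataFrame) -> dict:
    """Per-status cell counts for a machine-readable run report."""
    counts = status_df["chain_status"].value_counts().to_dict()
    return {"n_cells": int(len(status_df)),
            "status_counts": {s: int(counts.get(s, 0)) for s in STATUSES}}
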