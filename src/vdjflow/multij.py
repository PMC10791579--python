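"""Multi-J mapping resolution from per-contig J-segment hit tables.

A contig is "multi-J" when two or more J gene segments map to
non-overlapping stretches of the same assembled transcript — the
signature of a partially spliced product in which the chosen J exon is
still followed by downstream J exons and introns.  Given a blastn-style
hit table (gene, e-value support, 1-based inclusive start/end on the
contig) this module:

* filters hits by an e-value cutoff (default 1e-4 for J, 1e-3 for D);
* greedily selects the best-supported set of mutually non-overlapping
  hits, strongest support first;
* for contigs with no V gene annotation, overwrites ``j_call`` with the
  5'-leftmost selected gene (the exon that would survive splicing);
  contigs that carry a V gene keep their upstream annotation;
* summarises multi-J proportions per sample/locus/V-presence group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ParameterError, SchemaError

#: Default e-value cutoffs applied on top of the aligner's own threshold.
DEFAULT_J_EVALUE = 1e-4
DEFAULT_D_EVALUE = 1e-3

HIT_COLUMNS = ("sequence_id", "j_gene", "j_support", "j_sequence_start", "j_sequence_end")


@dataclass
class MultiJResolution:
    """Outcome of non-overlapping J selection for one contig."""

    sequence_id: str
    selected: list[dict] = field(default_factory=list)  # in selection order
    #: selected genes ordered by 5' position (ascending start)
    j_call_multimappers: list[str] = field(default_factory=list)
    is_multij: bool = False
    #: gene that should overwrite j_call for V-less contigs (5'-leftmost)
    resolved_j_call: str | None = None


def read_jhits(path) -> pd.DataFrame:
    """Read a J-hit TSV (sequence_id, j_gene, j_support, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str, "j_gene": str})
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"J-hit column(s) missing: {', '.join(missing)}")
    return _validate_hits(df)


def _validate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    if (hits["j_support"] < 0).any():
        raise SchemaError("j_support (e-value) must be non-negative")
    if (hits["j_sequence_start"] > hits["j_sequence_end"]).any():
        raise SchemaError("j_sequence_start must be <= j_sequence_end")
    if "bit_score" not in hits.columns:
        hits = hits.copy()
        hits["bit_score"] = 0.0
    return hits


def filter_j_hits(hits: pd.DataFrame, e_cutoff: float = DEFAULT_J_EVALUE) -> pd.DataFrame:
    """Retain hits with ``j_support <= e_cutoff``."""
    if e_cutoff < 0:
        raise ParameterError("e-value cutoff must be non-negative")
    hits = _validate_hits(hits)
    return hits[hits["j_support"] <= e_cutoff].reset_index(drop=True)


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    # closed intervals; sharing a single base counts as overlap
    return not (a_end < b_start or b_end < a_start)


def _rank_key(hit: dict, rank_by: str):
    span = hit["j_sequence_end"] - hit["j_sequence_start"]
    if rank_by == "j_support":
        primary = (hit["j_support"], -hit.get("bit_score", 0.0))
    elif rank_by == "bit_score":
        primary = (-hit.get("bit_score", 0.0), hit["j_support"])
    else:
        raise ParameterError(f"unknown rank_by '{rank_by}'")
    return (*primary, -span, hit["j_sequence_start"], hit["j_gene"])


def select_nonoverlapping_j(hits: pd.DataFrame, rank_by: str = "j_support") -> MultiJResolution:
    """Greedy selection of mutually non-overlapping J hits for one contig.

    The best-supported hit is taken first; remaining hits are scanned in
    support order and accepted only if their interval overlaps none of
    the already-selected intervals.  Ties are broken by bit score, span,
    start position and gene name, in that order, so the result is
    deterministic.
    """
    if len(hits) == 0:
        return MultiJResolution(sequence_id="")
    ids = hits["sequence_id"].unique()
    if len(ids) > 1:
        raise ParameterError(f"hits span multiple contigs: {sorted(ids)[:5]}")
    hits = _validate_hits(hits)
    candidates = sorted(hits.to_dict("records"), key=lambda h: _rank_key(h, rank_by))
    selected: list[dict] = []
    for hit in candidates:
        if any(_overlaps(hit["j_sequence_start"], hit["j_sequence_end"],
                         s["j_sequence_start"], s["j_sequence_end"]) for s in selected):
            continue
        selected.append(hit)
    by_start = sorted(selected, key=lambda h: (h["j_sequence_start"], h["j_gene"]))
    return MultiJResolution(
        sequence_id=str(ids[0]),
        selected=selected,
        j_call_multimappers=[h["j_gene"] for h in by_start],
        is_multij=len(selected) >= 2,
        resolved_j_call=by_start[0]["j_gene"] if by_start else None,
    )


def resolve_j_call(record: dict, resolution: MultiJResolution) -> dict:
    """Apply a multi-J resolution to one contig record.

    V-less contigs have their ``j_call`` overwritten with the 5'-leftmost
    selected gene; contigs with a V gene keep the aligner's annotation.
    ``j_call_multimappers`` is populated either way.
    """
    out = dict(record)
    out["j_call_multimappers"] = ",".join(resolution.j_call_multimappers)
    out["is_multij"] = resolution.is_multij
    if not resolution.selected:
        return out
    if out.get("v_call", "") == "":
        out["j_call"] = resolution.resolved_j_call
    return out


def apply_multij(contigs: pd.DataFrame, hits: pd.DataFrame,
                 e_cutoff: float = DEFAULT_J_EVALUE,
                 rank_by: str = "j_support") -> pd.DataFrame:
    """Resolve multi-J status for every contig in a table.

    Filters the hit table at ``e_cutoff``, runs the greedy selection per
    contig and returns the contig table with ``j_call_multimappers``,
    ``is_multij`` and (for V-less contigs) an updated ``j_call``.
    Contigs without any retained hit keep their annotation with
    ``is_multij = False``.
    """
    kept = filter_j_hits(hits, e_cutoff)
    groups = dict(tuple(kept.groupby("sequence_id", sort=False)))
    records = []
    for record in contigs.to_dict("records"):
        contig_hits = groups.get(record["sequence_id"])
        if contig_hits is None:
            resolution = MultiJResolution(sequence_id=record["sequence_id"])
        else:
            resolution = select_nonoverlapping_j(contig_hits, rank_by=rank_by)
        records.append(resolve_j_call(record, resolution))
    out = pd.DataFrame(records)
    out["is_multij"] = out["is_multij"].astype(bool)
    return out


def summarize_multij(table: pd.DataFrame, group_by: list[str] | tuple[str, ...],
                     min_contigs: int = 10) -> pd.DataFrame:
    """Per-group contig counts and multi-J proportions.

    Groups (e.g. sample x locus x V-presence) with fewer than
    ``min_contigs`` contigs are flagged ``below_min`` for exclusion from
    downstream comparisons rather than silently dropped.
    """
    group_by = list(group_by)
    missing = [c for c in group_by if c not in table.columns]
    if missing:
        raise ParameterError(f"unknown group key(s): {', '.join(missing)}")
    if "is_multij" not in table.columns:
        raise ParameterError("table lacks 'is_multij'; run apply_multij first")
    if len(table) == 0:
        return pd.DataFrame(columns=group_by + ["n_contigs", "n_multij",
                                                "multij_proportion", "below_min"])
    grouped = table.groupby(group_by, sort=True, observed=True)["is_multij"]
    out = grouped.agg(n_contigs="size", n_multij="sum").reset_index()
    out["multij_proportion"] = out["n_multij"] / out["n_contigs"]
    out["below_min"] = out["n_contigs"] < min_contigs
    return out


def to_zero_based_half_open(hits: pd.DataFrame) -> pd.DataFrame:
    """Convert internal 1-based inclusive coordinates to 0-based half-open."""
    out = hits.copy()
    out["j_sequence_start"] = out["j_sequence_start"] - 1
    return out


def from_zero_based_half_open(hits: pd.DataFrame) -> pd.DataFrame:
    """Convert 0-based half-open input coordinates to 1-based inclusive."""
    out = hits.copy()
    out["j_sequence_start"] = out["j_sequence_start"] + 1
    return out
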