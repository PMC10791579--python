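"""Reading, validating and writing AIRR rearrangement tables.

The universal currency of this package is the *contig table*: a pandas
DataFrame with one row per assembled receptor contig, using AIRR
Rearrangement field names (``sequence_id``, ``cell_id``, ``locus``,
``v_call`` ... ).  All string columns are stored as plain ``str`` with the
empty string for missing values; ternary flags (``productive``,
``vj_in_frame``, ``stop_codon``) are normalised to ``"T"``, ``"F"`` or
``""`` (unknown).

Beyond plain I/O this module derives per-contig bookkeeping: gene-call
parsing, V-gene presence, and the cause of nonproductivity (a single
mutually exclusive category per nonproductive contig, mirroring how
failed rearrangements are tallied per locus).
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import pandas as pd

from .errors import IntegrityError, SchemaError

#: The seven receptor loci handled by the package.
LOCI = frozenset({"TRA", "TRB", "TRG", "TRD", "IGH", "IGK", "IGL"})

#: Loci whose chains carry a D segment (heavy-type chains).
VDJ_LOCI = frozenset({"TRB", "TRD", "IGH"})

#: Light-type chains (no D segment).
VJ_LOCI = frozenset({"TRA", "TRG", "IGK", "IGL"})

#: Loci expected per sequencing library type.  TRD is admitted in αβ
#: libraries because TRB and TRD rearrange concurrently during development
#: and genuine TRD contigs survive in αβ data.
LIBRARY_LOCI = {
    "tr-ab": frozenset({"TRA", "TRB", "TRD"}),
    "tr-gd": frozenset({"TRG", "TRD"}),
    "ig": frozenset({"IGH", "IGK", "IGL"}),
}

MANDATORY_COLUMNS = ("sequence_id", "cell_id", "locus", "v_call", "j_call", "productive")

TERNARY_COLUMNS = ("productive", "vj_in_frame", "stop_codon", "complete_vdj")

#: Default priority order for assigning a single nonproductive cause.
CAUSE_PRIORITY = ("missing_v", "missing_junction", "frameshift", "premature_stop")

_TERNARY_MAP = {
    "T": "T", "TRUE": "T", "True": "T", "true": "T",
    "F": "F", "FALSE": "F", "False": "F", "false": "F",
    "": "", "NA": "", "NAN": "", "None": "", "NONE": "", "nan": "",
}


def _normalize_ternary(series: pd.Series) -> pd.Series:
    out = series.fillna("").astype(str).str.strip()
    bad = ~out.isin(_TERNARY_MAP)
    if bad.any():
        values = sorted(out[bad].unique())
        raise SchemaError(f"unparseable ternary flag values in '{series.name}': {values}")
    return out.map(_TERNARY_MAP)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"mandatory AIRR column(s) missing: {', '.join(missing)}")
    dup = df["sequence_id"][df["sequence_id"].duplicated()]
    if len(dup):
        raise IntegrityError(f"duplicated sequence_id values: {sorted(dup.unique())[:5]}")
    bad_locus = sorted(set(df["locus"]) - LOCI)
    if bad_locus:
        raise SchemaError(f"unknown locus value(s): {bad_locus}")
    for col in TERNARY_COLUMNS:
        if col in df.columns:
            df[col] = _normalize_ternary(df[col])
    if "duplicate_count" in df.columns:
        counts = pd.to_numeric(df["duplicate_count"].replace("", "0"), errors="coerce")
        if counts.isna().any() or (counts < 0).any():
            raise SchemaError("duplicate_count must be a non-negative integer")
        df["duplicate_count"] = counts.astype(int)
    else:
        df["duplicate_count"] = 0
    # contigs without a junction cannot be productive
    if "junction" in df.columns and "junction_aa" in df.columns:
        no_junction = (df["junction"] == "") & (df["junction_aa"] == "")
        df.loc[no_junction & (df["productive"] == "T"), "productive"] = "F"
    for col in ("junction", "junction_aa", "d_call", "c_call", "sequence_alignment_aa"):
        if col not in df.columns:
            df[col] = ""
    return df


def read_airr(path, library_type: str | None = None) -> pd.DataFrame:
    """Read an AIRR Rearrangement TSV into a validated contig table.

    Parameters
    ----------
    path
        Tab-separated file with a header row carrying at least the
        mandatory AIRR columns.
    library_type
        Optional library restriction tag (``tr-ab``, ``tr-gd`` or ``ig``)
        recorded in a ``library_type`` column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = _validate(df)
    if library_type is not None:
        if library_type not in LIBRARY_LOCI:
            raise SchemaError(f"unknown library_type '{library_type}'")
        df["library_type"] = library_type
    return df


def write_airr(table: pd.DataFrame, path) -> None:
    """Write a contig table as an AIRR TSV (empty string for unknowns)."""
    out = table.copy()
    for col in out.columns:
        if out[col].dtype == object:
            out[col] = out[col].fillna("")
    out.to_csv(path, sep="\t", index=False)


_10X_RENAME = {
    "barcode": "cell_id",
    "contig_id": "sequence_id",
    "chain": "locus",
    "umis": "duplicate_count",
    "v_gene": "v_call",
    "d_gene": "d_call",
    "j_gene": "j_call",
    "c_gene": "c_call",
    "cdr3_nt": "junction",
    "cdr3": "junction_aa",
}


def read_10x_contigs(path, library_type: str | None = None,
                     high_confidence_only: bool = False) -> pd.DataFrame:
    """Adapter for 10X ``all_contig_annotations.csv``.

    Maps 10X column names onto the AIRR schema, parses the
    ``"True"``/``"False"``/``"None"`` flag dialect and drops contigs whose
    chain is not a recognised locus (e.g. ``Multi``).  With
    ``high_confidence_only`` the table is subset to contigs the assembler
    deemed high confidence before validation.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("barcode", "contig_id", "chain") if c not in df.columns]
    if missing:
        raise SchemaError(f"10X annotation column(s) missing: {', '.join(missing)}")
    df = df.rename(columns={k: v for k, v in _10X_RENAME.items() if k in df.columns})
    if high_confidence_only and "high_confidence" in df.columns:
        df = df[df["high_confidence"].isin(["True", "TRUE", "true", "T"])]
    df = df[df["locus"].isin(LOCI)].reset_index(drop=True)
    if "productive" not in df.columns:
        df["productive"] = ""
    df = _validate(df)
    if library_type is not None:
        df["library_type"] = library_type
    return df


def parse_gene_call(call: str) -> list[tuple[str, str | None]]:
    """Split a comma-separated gene call into ``(gene, allele)`` pairs.

    ``"IGHV1-69*02,IGHV1-69D*01"`` yields two entries in input order; an
    empty call yields an empty list.  Lenient: tokens without an allele
    suffix get ``None``.
    """
    if call is None or call == "" or pd.isna(call):
        return []
    out = []
    for token in str(call).split(","):
        token = token.strip()
        if not token:
            continue
        gene, _, allele = token.partition("*")
        out.append((gene, allele or None))
    return out


def first_gene(call: str) -> str:
    """First gene of a call with any allele suffix stripped ('' if none)."""
    parsed = parse_gene_call(call)
    return parsed[0][0] if parsed else ""


def classify_nonproductive(record, priority: Sequence[str] = CAUSE_PRIORITY) -> str | None:
    """Single cause of nonproductivity for one contig record, or ``None``.

    Productive contigs return ``None``.  Nonproductive contigs get exactly
    one cause, the first that applies in ``priority`` order (default:
    ``missing_v`` > ``missing_junction`` > ``frameshift`` >
    ``premature_stop``), falling back to ``other``.
    """
    if record.get("productive", "") == "T":
        return None
    checks = {
        "missing_v": lambda r: r.get("v_call", "") == "",
        "missing_junction": lambda r: r.get("junction", "") == "" and r.get("junction_aa", "") == "",
        "frameshift": lambda r: r.get("vj_in_frame", "") == "F",
        "premature_stop": lambda r: r.get("stop_codon", "") == "T",
    }
    for cause in priority:
        if checks[cause](record):
            return cause
    return "other"


def annotate_nonproductive(table: pd.DataFrame,
                           priority: Sequence[str] = CAUSE_PRIORITY) -> pd.DataFrame:
    """Add ``v_gene_present`` and ``nonproductive_cause`` columns."""
    out = table.copy()
    out["v_gene_present"] = out["v_call"] != ""
    out["nonproductive_cause"] = [
        classify_nonproductive(row, priority) or ""
        for row in out.to_dict("records")
    ]
    return out


def adjust_barcodes(table: pd.DataFrame, prefix: str = "", suffix: str = "") -> pd.DataFrame:
    """Rewrite cell and contig identifiers as ``prefix + id + suffix``.

    Used when concatenating samples so barcodes never collide; raises if
    the rewrite itself creates duplicate contig identifiers.
    """
    out = table.copy()
    out["cell_id"] = prefix + out["cell_id"].astype(str) + suffix
    out["sequence_id"] = prefix + out["sequence_id"].astype(str) + suffix
    if out["sequence_id"].duplicated().any():
        raise IntegrityError("barcode adjustment produced duplicated sequence_id values")
    return out


def concat_samples(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-sample contig tables, enforcing unique contig ids."""
    merged = pd.concat(list(tables), ignore_index=True)
    dup = merged["sequence_id"][merged["sequence_id"].duplicated()]
    if len(dup):
        raise IntegrityError(
            f"overlapping sequence_id across samples: {sorted(dup.unique())[:5]}; "
            "use adjust_barcodes with distinct prefixes"
        )
    return merged
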