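"""Readers and writers for the external formats the pipeline touches.

Formats: 12-column tabular similarity hits (blast outfmt-6 dialect,
1-based inclusive coordinates), profile-hit TSV, gene-annotation TSV,
FASTA, Newick, and Java TreeView CDT/GTR/ATR cluster files.  Readers
validate strictly and never drop a row silently: every rejected or
suspicious row is reported with its line number (errors) or logged
(warnings).
"""

from __future__ import annotations

import logging
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "HIT_COLUMNS",
    "read_hits",
    "write_hits",
    "read_profile_hits",
    "write_profile_hits",
    "read_annotations",
    "write_annotations",
    "read_fasta",
    "read_newick",
    "write_newick",
    "write_cdt",
    "read_cdt",
]

#: Column order of the 12-column tabular hit format.
HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "pident",
    "aln_len",
    "mismatches",
    "gap_opens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

_HIT_INT_COLS = ["aln_len", "mismatches", "gap_opens", "qstart", "qend", "sstart", "send"]
_HIT_FLOAT_COLS = ["pident", "evalue", "bitscore"]

#: Standard single-letter COG functional categories.
COG_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

ANNOTATION_COLUMNS = ["gene_id", "genome_id", "genus_id", "product", "cog", "length_aa"]
PROFILE_HIT_COLUMNS = ["gene_id", "profile_id", "evalue", "cov_gene", "cov_profile"]


# ---------------------------------------------------------------------------
# similarity hits (12-column tabular)
# ---------------------------------------------------------------------------

def read_hits(path, annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a 12-column tab-separated hit table.

    When ``annotations`` (a gene-record table with ``gene_id`` and
    ``length_aa``) is supplied, query/subject coverage fractions are
    computed as aligned span (end - start + 1, coordinates 1-based
    inclusive) over the annotated sequence length and stored in
    ``q_cov`` / ``s_cov``.  Hits whose gene ids are absent from the
    annotation table are kept with NaN coverage and logged.

    Malformed rows (wrong column count, unparseable numerics) raise with
    the offending line number.
    """
    rows = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            rows.append(fields)
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    for col in _HIT_INT_COLS + _HIT_FLOAT_COLS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            first = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: line {first + 1}: cannot parse {col}={df[col].iloc[first]!r}"
            )
        df[col] = converted
    df[_HIT_INT_COLS] = df[_HIT_INT_COLS].astype(int)

    if annotations is not None:
        lengths = annotations.set_index("gene_id")["length_aa"]
        for side, id_col, start, end in (
            ("q_cov", "query_id", "qstart", "qend"),
            ("s_cov", "subject_id", "sstart", "send"),
        ):
            span = (df[end] - df[start]).abs() + 1
            seq_len = df[id_col].map(lengths)
            unknown = seq_len.isna()
            if unknown.any():
                for i in np.flatnonzero(unknown.to_numpy())[:10]:
                    logger.warning(
                        "%s: line %d: unknown gene id %r; coverage left undefined",
                        path, i + 1, df[id_col].iloc[int(i)],
                    )
            df[side] = span / seq_len
    return df


def write_hits(hits: pd.DataFrame, path) -> None:
    """Write the 12 canonical columns as a headerless TSV."""
    df = hits[HIT_COLUMNS].copy()
    with open(path, "w", newline="") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        row.query_id,
                        row.subject_id,
                        f"{row.pident:.1f}",
                        str(row.aln_len),
                        str(row.mismatches),
                        str(row.gap_opens),
                        str(row.qstart),
                        str(row.qend),
                        str(row.sstart),
                        str(row.send),
                        f"{row.evalue:.3g}",
                        f"{row.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# profile hits
# ---------------------------------------------------------------------------

def read_profile_hits(path) -> pd.DataFrame:
    """Read a profile-hit TSV (gene, profile, evalue, cov_gene, cov_profile)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "profile_id": str})
    missing = set(PROFILE_HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing profile-hit columns {sorted(missing)}")
    for col in ("cov_gene", "cov_profile"):
        bad = (df[col] < 0) | (df[col] > 1)
        if bad.any():
            raise ValueError(
                f"{path}: line {int(np.flatnonzero(bad.to_numpy())[0]) + 2}: "
                f"{col} outside [0, 1]"
            )
    if (df["evalue"] < 0).any():
        raise ValueError(f"{path}: negative E-value")
    return df[PROFILE_HIT_COLUMNS]


def write_profile_hits(hits: pd.DataFrame, path) -> None:
    df = hits[PROFILE_HIT_COLUMNS].copy()
    df["evalue"] = df["evalue"].map(lambda v: f"{v:.4g}")
    df["cov_gene"] = df["cov_gene"].map(lambda v: f"{v:.4f}")
    df["cov_profile"] = df["cov_profile"].map(lambda v: f"{v:.4f}")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

def read_annotations(path) -> pd.DataFrame:
    """Read a gene-annotation TSV.

    Expected columns: ``gene_id genome_id genus_id product cog length_aa``.
    A missing ``cog`` column yields records with an empty category string
    (permissive parse).  COG letters must come from the standard alphabet;
    ``length_aa`` must be a positive integer; ``gene_id`` must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "genome_id", "genus_id", "product", "length_aa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    if "cog" not in df.columns:
        df["cog"] = ""
    df["length_aa"] = pd.to_numeric(df["length_aa"], errors="raise").astype(int)
    if (df["length_aa"] < 1).any():
        raise ValueError(f"{path}: length_aa must be >= 1")
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate gene_id {df.loc[dup, 'gene_id'].iloc[0]!r}")
    bad = df["cog"].map(lambda s: any(c not in COG_ALPHABET for c in s))
    if bad.any():
        raise ValueError(
            f"{path}: non-COG letter in categories {df.loc[bad, 'cog'].iloc[0]!r}"
        )
    return df[ANNOTATION_COLUMNS]


def write_annotations(genes: pd.DataFrame, path) -> None:
    genes[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# FASTA / Newick
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """Read FASTA into an ordered {id: sequence} mapping (wrapped lines and
    CRLF endings tolerated)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_newick(path) -> dendropy.Tree:
    """Parse a Newick tree, preserving underscores, branch lengths and
    internal labels."""
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=False,
    )


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


# ---------------------------------------------------------------------------
# Java TreeView CDT / GTR / ATR
# ---------------------------------------------------------------------------

def _node_lines(dendrogram, prefix: str) -> list[str]:
    """Serialise a Dendrogram's merges as TreeView node lines.

    Leaves are ``{prefix}{i}X`` in the dendrogram's *original* label
    order; internal nodes are ``NODE{k}X`` in merge order.
    """
    n = len(dendrogram.labels)

    def ref(cluster_id: int) -> str:
        if cluster_id < n:
            return f"{prefix}{cluster_id}X"
        return f"NODE{cluster_id - n + 1}X"

    lines = []
    for k, (left, right, height, _size) in enumerate(dendrogram.merges, start=1):
        lines.append(f"NODE{k}X\t{ref(int(left))}\t{ref(int(right))}\t{height:.6g}")
    return lines


def write_cdt(matrix, row_dendrogram, col_dendrogram, path_stem) -> dict:
    """Write TreeView CDT plus GTR (rows) and ATR (columns) files.

    Rows and columns appear in dendrogram leaf order; GWEIGHT and EWEIGHT
    are 1; binary values are written as integers.  Returns the mapping of
    suffix to written path.
    """
    from .matrix import PresenceMatrix  # local import to avoid a cycle

    if set(row_dendrogram.labels) != set(matrix.tribe_ids):
        raise ValueError("row dendrogram leaves do not match matrix rows")
    if set(col_dendrogram.labels) != set(matrix.genome_ids):
        raise ValueError("column dendrogram leaves do not match matrix columns")

    stem = Path(path_stem)
    frame = matrix.to_frame()
    row_order = row_dendrogram.leaf_order()
    col_order = col_dendrogram.leaf_order()
    frame = frame.loc[row_order, col_order]

    gid = {label: f"GENE{i}X" for i, label in enumerate(row_dendrogram.labels)}
    aid = {label: f"ARRY{i}X" for i, label in enumerate(col_dendrogram.labels)}
    is_binary = frame.isin([0, 1]).all().all()

    def fmt(v):
        return str(int(v)) if is_binary else f"{float(v):.6g}"

    cdt_path = stem.with_suffix(".cdt")
    with open(cdt_path, "w", newline="") as fh:
        fh.write("GID\tNAME\tGWEIGHT\t" + "\t".join(col_order) + "\n")
        fh.write("AID\t\t\t" + "\t".join(aid[c] for c in col_order) + "\n")
        fh.write("EWEIGHT\t\t\t" + "\t".join(["1"] * len(col_order)) + "\n")
        for label, row in frame.iterrows():
            fh.write(
                f"{gid[label]}\t{label}\t1\t" + "\t".join(fmt(v) for v in row) + "\n"
            )

    gtr_path = stem.with_suffix(".gtr")
    gtr_path.write_text("\n".join(_node_lines(row_dendrogram, "GENE")) + "\n")
    atr_path = stem.with_suffix(".atr")
    atr_path.write_text("\n".join(_node_lines(col_dendrogram, "ARRY")) + "\n")
    return {"cdt": cdt_path, "gtr": gtr_path, "atr": atr_path}


def read_cdt(path_stem):
    """Read back a CDT written by :func:`write_cdt`.

    Returns ``(matrix, row_order, col_order)`` where ``matrix`` is a
    PresenceMatrix-shaped DataFrame in file (clustered) order.
    """
    stem = Path(path_stem)
    with open(stem.with_suffix(".cdt")) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["GID", "NAME", "GWEIGHT"]:
            raise ValueError(f"{stem}: not a CDT written by this package")
        col_order = header[3:]
        aid_line = fh.readline().rstrip("\n").split("\t")
        if aid_line[0] != "AID":
            raise ValueError(f"{stem}: missing AID row")
        eweight = fh.readline().rstrip("\n").split("\t")
        if eweight[0] != "EWEIGHT":
            raise ValueError(f"{stem}: missing EWEIGHT row")
        names, values = [], []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3 + len(col_order):
                raise ValueError(f"{stem}: ragged CDT data row {fields[0]!r}")
            names.append(fields[1])
            values.append([float(v) for v in fields[3:]])
    frame = pd.DataFrame(values, index=names, columns=col_order)
    return frame, names, col_order
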