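"""Readers and writers for the plain-text formats the pipeline consumes.

Formats: a GenomeStudio-like expression TSV (per sample an
``<sample>.AVG_Signal`` and ``<sample>.Detection_Pval`` column pair), a
sample->group mapping TSV, GMT gene sets, SIF-like typed edge lists with
a node-role TSV, and (optionally) a GEO series-matrix text export.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .expression import ExpressionMatrix

SIGNAL_SUFFIX = ".AVG_Signal"
DETECTION_SUFFIX = ".Detection_Pval"


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    """Write the expression TSV dialect: probe_id, then per sample a
    signal and a detection p-value column."""
    out = pd.DataFrame(index=matrix.probe_ids)
    for s in matrix.samples:
        out[f"{s}{SIGNAL_SUFFIX}"] = matrix.intensities[s]
        out[f"{s}{DETECTION_SUFFIX}"] = matrix.detection_p[s]
    out.to_csv(path, sep="\t", index_label="probe_id")


def write_sample_map(groups: pd.Series, path) -> None:
    rows = []
    counts: dict[str, int] = {}
    for sample, group in groups.items():
        counts[group] = counts.get(group, 0) + 1
        rows.append((sample, group, counts[group]))
    pd.DataFrame(rows, columns=["sample", "group", "replicate"]).to_csv(
        path, sep="\t", index=False
    )


def read_sample_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(df["group"].values, index=df["sample"].values, name="group")


def read_expression_tsv(path, groups: pd.Series) -> ExpressionMatrix:
    """Read the expression TSV dialect back into an :class:`ExpressionMatrix`."""
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    samples = [c[: -len(SIGNAL_SUFFIX)] for c in df.columns if c.endswith(SIGNAL_SUFFIX)]
    intens = pd.DataFrame({s: df[f"{s}{SIGNAL_SUFFIX}"] for s in samples})
    det = pd.DataFrame({s: df[f"{s}{DETECTION_SUFFIX}"] for s in samples})
    return ExpressionMatrix(intens, det, groups)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: ``term<TAB>description<TAB>member...`` per line."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for term, members in sets.items():
            fh.write("\t".join([term, description, *members]) + "\n")


def read_sif(path) -> list[tuple[str, str, str]]:
    """Read a SIF-like edge list ``node_a<TAB>type(ppi|reg)<TAB>node_b``."""
    edges = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        a, etype, b = line.split("\t")
        if etype not in ("ppi", "reg"):
            raise ValueError(f"unknown edge type {etype!r}")
        edges.append((a, etype, b))
    return edges


def write_sif(edges, path) -> None:
    with open(path, "w") as fh:
        for a, etype, b in edges:
            fh.write(f"{a}\t{etype}\t{b}\n")


def read_roles(path) -> dict[str, str]:
    """Read the node-role TSV ``node<TAB>role(source|sink)``."""
    roles: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("node\t"):
            continue
        node, role = line.split("\t")
        if role not in ("source", "sink"):
            raise ValueError(f"unknown role {role!r} for node {node!r}")
        roles[node] = role
    return roles


def write_roles(roles: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("node\trole\n")
        for node, role in roles.items():
            fh.write(f"{node}\t{role}\n")


def load_geo_series(path, groups: pd.Series) -> ExpressionMatrix:
    """Parse a GEO series-matrix text export with detection p-value columns.

    Expects the ``!series_matrix_table_begin`` / ``_end`` block.  Sample
    columns must alternate signal and detection values, or carry
    Detection headers; the caller supplies the sample->group mapping.
    Raises a ``ValueError`` when no detection columns can be found.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end"))
    except StopIteration as exc:
        raise ValueError("not a GEO series-matrix export (missing table markers)") from exc
    header = lines[start + 1].strip().split("\t")
    header = [h.strip('"') for h in header]
    rows = [l.split("\t") for l in lines[start + 2 : end] if l.strip()]
    df = pd.DataFrame(rows, columns=header)
    df = df.set_index(header[0])
    det_cols = [c for c in df.columns if re.search("detection", c, re.IGNORECASE)]
    if not det_cols:
        raise ValueError(
            "series matrix has no detection p-value columns; export the matrix "
            "with 'Detection Pval' columns included — present/absent filtering "
            "requires them"
        )
    sig_cols = [c for c in df.columns if c not in det_cols]
    if len(sig_cols) != len(det_cols):
        raise ValueError("unequal numbers of signal and detection columns")
    samples = [c.strip('"') for c in sig_cols]
    intens = pd.DataFrame(
        {s: pd.to_numeric(df[c].str.strip('"')) for s, c in zip(samples, sig_cols)}
    )
    det = pd.DataFrame(
        {s: pd.to_numeric(df[c].str.strip('"')) for s, c in zip(samples, det_cols)}
    )
    return ExpressionMatrix(intens, det, groups)
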