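"""Read and write KGX-TSV tar.gz archives.

The KGX TSV serialization packs one or more node tables and edge tables into
a gzipped tar archive. Node files must carry at least ``id`` and ``category``
columns; edge files at least ``subject``, ``predicate`` and ``object``. Cells
may be multi-valued: following the KGX convention the values are joined with
a pipe character (configurable). On write, values containing a tab, newline,
backslash or the delimiter are protected with backslash escapes, and the
escapes are reversed on read, so arbitrary strings round-trip losslessly.

Conventions applied here (the standard leaves some latitude):

* archive members whose names end in ``nodes.tsv`` / ``edges.tsv``
  (case-insensitive) are node / edge files; all matches are concatenated;
* an empty cell means the attribute is absent for that row, not an empty
  string;
* duplicate node ids and duplicate (subject, predicate, object) triples are
  collapsed to their first occurrence with a logged warning;
* edges referencing an id absent from the node files are dropped with a
  warning, preserving the no-dangling-endpoint invariant;
* scalar columns whose values all look like integers, floats or booleans are
  converted to those types on read; everything else stays a string.

Archives written by :func:`write_kgx` are byte-deterministic for a given
graph (fixed timestamps and member order), which makes seeded fixtures
reproducible down to the byte.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
import tarfile
from typing import Mapping, Optional, Sequence

import pandas as pd

from .kg_model import (
    EDGE_REQUIRED_COLUMNS,
    NODE_REQUIRED_COLUMNS,
    DEFAULT_PREFERENCES,
    KnowledgeGraph,
    empty_edges_frame,
    empty_nodes_frame,
    is_missing,
    resolve_pcategory,
)

logger = logging.getLogger(__name__)

DEFAULT_DELIMITER = "|"


class KgxFormatError(ValueError):
    """The archive does not conform to the KGX-TSV layout."""


# --- cell-level escaping ----------------------------------------------------

_CONTROL_ESCAPES = {"\\": "\\\\", "\t": "\\t", "\n": "\\n", "\r": "\\r"}
_CONTROL_UNESCAPES = {"\\": "\\", "t": "\t", "n": "\n", "r": "\r"}


def _escape(text: str, delimiter: str) -> str:
    out = []
    for ch in text:
        if ch in _CONTROL_ESCAPES:
            out.append(_CONTROL_ESCAPES[ch])
        elif ch == delimiter:
            out.append("\\" + ch)
        else:
            out.append(ch)
    return "".join(out)


def _split_raw(cell: str, delimiter: str) -> list[str]:
    """Split on unescaped delimiters, leaving escape sequences intact."""
    parts, buf, i = [], [], 0
    while i < len(cell):
        ch = cell[i]
        if ch == "\\" and i + 1 < len(cell):
            buf.append(cell[i : i + 2])
            i += 2
        elif ch == delimiter:
            parts.append("".join(buf))
            buf = []
            i += 1
        else:
            buf.append(ch)
            i += 1
    parts.append("".join(buf))
    return parts


def _unescape(text: str, delimiter: str) -> str:
    def sub(m: re.Match) -> str:
        ch = m.group(1)
        if ch in _CONTROL_UNESCAPES:
            return _CONTROL_UNESCAPES[ch]
        if ch == delimiter:
            return ch
        return m.group(0)  # unknown escape: keep literally

    return re.sub(r"\\(.)", sub, text)


def _format_scalar(v) -> str:
    if isinstance(v, bool):
        return "True" if v else "False"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _serialize_cell(v, delimiter: str) -> str:
    if is_missing(v):
        return ""
    if isinstance(v, (list, tuple)):
        return delimiter.join(_escape(_format_scalar(x), delimiter) for x in v)
    return _escape(_format_scalar(v), delimiter)


_INT_RE = re.compile(r"^[+-]?\d+$")
_FLOAT_RE = re.compile(r"^[+-]?(\d+\.\d*|\.\d+|\d+)([eE][+-]?\d+)?$")


def _infer_column(values: list) -> list:
    """Convert a scalar string column to int/float/bool when homogeneous."""
    present = [v for v in values if v is not None]
    if not present or any(isinstance(v, list) for v in present):
        return values
    if all(v in ("True", "False") for v in present):
        return [None if v is None else v == "True" for v in values]
    if all(_INT_RE.match(v) for v in present):
        return [None if v is None else int(v) for v in values]
    if all(_FLOAT_RE.match(v) for v in present) and any(
        not _INT_RE.match(v) for v in present
    ):
        return [None if v is None else float(v) for v in values]
    return values


# --- TSV (de)serialization ---------------------------------------------------


def _parse_tsv(
    raw: bytes, name: str, required: Sequence[str], delimiter: str
) -> pd.DataFrame:
    text = raw.decode("utf-8")
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise KgxFormatError(f"{name}: empty file (no header row)")
    header = lines[0].split("\t")
    for col in required:
        if col not in header:
            raise KgxFormatError(f"{name}: missing required column {col!r}")
    rows = []
    for line in lines[1:]:
        fields = line.split("\t")
        if len(fields) < len(header):
            fields += [""] * (len(header) - len(fields))
        row = {}
        for col, cell in zip(header, fields):
            if cell == "":
                row[col] = None
            else:
                parts = _split_raw(cell, delimiter)
                if len(parts) > 1 or col == "category":
                    row[col] = [_unescape(p, delimiter) for p in parts if p != ""]
                    if not row[col]:
                        row[col] = None
                else:
                    row[col] = _unescape(parts[0], delimiter)
        rows.append(row)
    df = pd.DataFrame(rows, columns=header, dtype=object)
    if not rows:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in header})
    return df


def _frame_to_tsv(df: pd.DataFrame, delimiter: str) -> bytes:
    cols = list(df.columns)
    lines = ["\t".join(cols)]
    for row in df.itertuples(index=False):
        lines.append("\t".join(_serialize_cell(v, delimiter) for v in row))
    return ("\n".join(lines) + "\n").encode("utf-8")


# --- archive I/O --------------------------------------------------------------


def read_kgx(
    path,
    prefs: Sequence[str] = DEFAULT_PREFERENCES,
    delimiter: str = DEFAULT_DELIMITER,
) -> KnowledgeGraph:
    """Load a KGX-TSV tar.gz archive into a :class:`KnowledgeGraph`.

    Multi-valued cells are split into ordered lists, ``pcategory`` is derived
    for every node with ``prefs``, multiple node/edge files are concatenated,
    and duplicates / dangling edges are resolved as described in the module
    docstring. Raises :class:`KgxFormatError` on structural problems and
    propagates I/O errors for unreadable archives.
    """
    node_frames: list[pd.DataFrame] = []
    edge_frames: list[pd.DataFrame] = []
    path = str(path)
    with tarfile.open(path, "r:*") as tar:
        members = sorted(
            (m for m in tar.getmembers() if m.isfile()), key=lambda m: m.name
        )
        for m in members:
            lname = m.name.lower()
            if lname.endswith("nodes.tsv"):
                raw = tar.extractfile(m).read()
                node_frames.append(
                    _parse_tsv(raw, m.name, NODE_REQUIRED_COLUMNS, delimiter)
                )
            elif lname.endswith("edges.tsv"):
                raw = tar.extractfile(m).read()
                edge_frames.append(
                    _parse_tsv(raw, m.name, EDGE_REQUIRED_COLUMNS, delimiter)
                )
    if not node_frames:
        raise KgxFormatError(f"{path}: archive contains no node file (*nodes.tsv)")
    if not edge_frames:
        raise KgxFormatError(f"{path}: archive contains no edge file (*edges.tsv)")

    nodes = _concat(node_frames)
    edges = _concat(edge_frames)

    # type inference on scalar attribute columns
    for df, skip in ((nodes, {"id", "category"}), (edges, set(EDGE_REQUIRED_COLUMNS))):
        for col in df.columns:
            if col not in skip and len(df):
                df[col] = pd.Series(_infer_column(list(df[col])), dtype=object)

    bad_cat = [
        nid
        for nid, cats in zip(nodes["id"], nodes["category"])
        if not isinstance(cats, list) or not cats
    ]
    if bad_cat:
        logger.warning("dropping %d node(s) with empty category: %s", len(bad_cat), bad_cat[:5])
        nodes = nodes[~nodes["id"].isin(set(bad_cat))].reset_index(drop=True)

    dup_nodes = nodes.duplicated(subset="id")
    if dup_nodes.any():
        logger.warning(
            "collapsing %d duplicate node id(s) to first occurrence", int(dup_nodes.sum())
        )
        nodes = nodes[~dup_nodes].reset_index(drop=True)

    dup_edges = edges.duplicated(subset=list(EDGE_REQUIRED_COLUMNS))
    if dup_edges.any():
        logger.warning(
            "collapsing %d duplicate edge triple(s) to first occurrence",
            int(dup_edges.sum()),
        )
        edges = edges[~dup_edges].reset_index(drop=True)

    id_set = set(nodes["id"])
    if len(edges):
        ok = [
            (s in id_set) and (o in id_set)
            for s, o in zip(edges["subject"], edges["object"])
        ]
        if not all(ok):
            logger.warning(
                "dropping %d edge(s) with endpoints missing from node files",
                len(ok) - sum(ok),
            )
            edges = edges[ok].reset_index(drop=True)

    pcats = [resolve_pcategory(cats, prefs) for cats in nodes["category"]]
    nodes.insert(nodes.columns.get_loc("category") + 1, "pcategory", pd.Series(pcats, dtype=object))
    return KnowledgeGraph(nodes, edges, None)


def _concat(frames: list[pd.DataFrame]) -> pd.DataFrame:
    frames = [f for f in frames]
    if len(frames) == 1:
        return frames[0]
    out = pd.concat(frames, ignore_index=True).astype(object)
    return out.where(pd.notna(out), None)


def write_kgx(
    g: KnowledgeGraph,
    path,
    delimiter: str = DEFAULT_DELIMITER,
    extra_members: Optional[Mapping[str, bytes]] = None,
) -> str:
    """Write a graph as a KGX-TSV tar.gz archive; returns the path.

    The derived ``pcategory`` column is not written. ``extra_members`` allows
    embedding sidecar files (e.g. a generator census) that :func:`read_kgx`
    ignores. Output bytes are deterministic for a given graph.
    """
    path = str(path)
    nodes = g.nodes.drop(columns=["pcategory"], errors="ignore")
    node_cols = [c for c in NODE_REQUIRED_COLUMNS] + [
        c for c in nodes.columns if c not in NODE_REQUIRED_COLUMNS
    ]
    edge_cols = [c for c in EDGE_REQUIRED_COLUMNS] + [
        c for c in g.edges.columns if c not in EDGE_REQUIRED_COLUMNS
    ]
    members: list[tuple[str, bytes]] = [
        ("nodes.tsv", _frame_to_tsv(nodes[node_cols], delimiter)),
        ("edges.tsv", _frame_to_tsv(g.edges[edge_cols], delimiter)),
    ]
    for name, data in (extra_members or {}).items():
        members.append((name, data))

    with open(path, "wb") as fh:
        with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0, filename="") as gz:
            with tarfile.open(fileobj=gz, mode="w") as tar:
                for name, data in members:
                    info = tarfile.TarInfo(name=name)
                    info.size = len(data)
                    info.mtime = 0
                    info.uid = info.gid = 0
                    info.uname = info.gname = ""
                    tar.addfile(info, io.BytesIO(data))
    return path
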