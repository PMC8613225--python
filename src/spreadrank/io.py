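"""File input/output: Pajek .net and edge-list readers, TSV score tables.

Only the plain-text formats the package actually trades in are supported.
The Pajek dialect understood here covers ``*Vertices``, ``*Edges``, ``*Arcs``
and the list forms ``*Edgeslist`` / ``*Arcslist``; any other section is
skipped with a warning. All input is coerced to an undirected simple graph:
arcs are symmetrized, duplicate edges collapse, trailing edge weights are
ignored (hop-count distances are used throughout).
"""

from __future__ import annotations

import logging
import os
import re
from collections.abc import Iterable

import pandas as pd

from .graph import Graph

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file does not follow the expected format."""


def _as_text(source) -> str:
    """Accept a path or raw text; paths are read as UTF-8 (latin-1 fallback)."""
    s = str(source)
    if "\n" not in s and os.path.exists(s):
        try:
            with open(s, encoding="utf-8") as fh:
                return fh.read()
        except UnicodeDecodeError:
            with open(s, encoding="latin-1") as fh:
                return fh.read()
    return s


_SECTION_RE = re.compile(r"^\*(\w+)", re.IGNORECASE)


def read_pajek(source) -> Graph:
    """Parse Pajek ``.net`` text (or a path to it) into an undirected Graph.

    Vertex labels come from the quoted name on each ``*Vertices`` line, with
    the 1-based vertex number (as a string) as fallback. ``*Arcs`` are
    symmetrized; edge weights after the two endpoint ids are ignored.
    """
    text = _as_text(source)
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")

    n_declared = None
    labels: dict[int, str] = {}
    edges: list[tuple[int, int]] = []
    section = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        m = _SECTION_RE.match(line)
        if m:
            section = m.group(1).lower()
            if section == "vertices":
                parts = line.split()
                if len(parts) < 2 or not parts[1].isdigit():
                    raise FormatError(f"line {lineno}: malformed *Vertices header")
                n_declared = int(parts[1])
            elif section not in ("edges", "arcs", "edgeslist", "arcslist"):
                logger.warning("skipping unsupported Pajek section *%s", section)
            continue
        if section is None:
            raise FormatError(f"line {lineno}: content before *Vertices header")
        if section == "vertices":
            parts = line.split(None, 1)
            vid = int(parts[0])
            if not 1 <= vid <= n_declared:
                raise FormatError(f"line {lineno}: vertex id {vid} out of range 1..{n_declared}")
            name = None
            if len(parts) > 1:
                rest = parts[1].strip()
                qm = re.match(r'"([^"]*)"', rest)
                if qm:
                    name = qm.group(1)
                else:
                    name = rest.split()[0]
            labels[vid] = name if name else str(vid)
        elif section in ("edges", "arcs"):
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"line {lineno}: edge line needs two vertex ids")
            u, v = int(parts[0]), int(parts[1])
            edges.append((u, v))
        elif section in ("edgeslist", "arcslist"):
            parts = [int(p) for p in line.split()]
            u = parts[0]
            edges.extend((u, v) for v in parts[1:])
        # unsupported sections: body lines silently skipped
    if n_declared is None:
        raise FormatError("missing *Vertices header")
    for vid in range(1, n_declared + 1):
        labels.setdefault(vid, str(vid))
    for u, v in edges:
        for vid in (u, v):
            if not 1 <= vid <= n_declared:
                raise FormatError(f"edge endpoint {vid} out of range 1..{n_declared}")
    label_list = [labels[vid] for vid in range(1, n_declared + 1)]
    if len(set(label_list)) != len(label_list):
        # Pajek names need not be unique; disambiguate by id suffix
        logger.warning("duplicate vertex names in Pajek file; falling back to ids")
        label_list = [str(vid) for vid in range(1, n_declared + 1)]
        labels = {vid: str(vid) for vid in range(1, n_declared + 1)}
    return Graph(label_list, [(labels[u], labels[v]) for u, v in edges])


def read_edge_list(source) -> Graph:
    """Parse a whitespace- or comma-separated edge list (or a path to one).

    Each line holds two labels (an edge) or one label (an isolated node).
    ``#`` comments and blank lines are skipped.
    """
    text = _as_text(source)
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = [t for t in re.split(r"[,\s]+", line) if t]
        if len(tokens) == 1:
            nodes.append(tokens[0])
        elif len(tokens) == 2:
            edges.append((tokens[0], tokens[1]))
        else:
            raise FormatError(f"line {lineno}: expected 1 or 2 tokens, got {len(tokens)}")
    return Graph.from_edges(edges, nodes=nodes)


def write_edge_list(graph: Graph, path) -> None:
    """Write a graph as an edge list; isolated nodes appear as single-label
    lines so that ``read_edge_list`` round-trips exactly."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        connected = set()
        for a, b in graph.edges():
            fh.write(f"{a} {b}\n")
            connected.update((a, b))
        for lab in graph.labels:
            if lab not in connected:
                fh.write(f"{lab}\n")


SCORE_COLUMNS = ("node", "method", "score", "rank")


def score_table(results: Iterable) -> pd.DataFrame:
    """Assemble CentralityResult-like objects into a long-format score table.

    One row per node per method; ``rank`` is dense and 1-based within each
    method (descending score, equal scores share a rank).
    """
    frames = []
    for res in results:
        nodes = sorted(res.scores)
        scores = [res.scores[n] for n in nodes]
        df = pd.DataFrame({"node": nodes, "method": res.method, "score": scores})
        df["rank"] = (
            df["score"].rank(method="dense", ascending=False).astype(int)
        )
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=list(SCORE_COLUMNS))
    return pd.concat(frames, ignore_index=True)[list(SCORE_COLUMNS)]


def write_scores(table: pd.DataFrame, path) -> None:
    """Write a score table as TSV.

    Layout is bit-stable: header ``node<TAB>method<TAB>score<TAB>rank``,
    scores at 10 significant digits, rows in descending score order with
    ties broken by ascending label (within method, methods in first-seen
    order).
    """
    if hasattr(path, "write"):
        _write_scores_stream(table, path)
    else:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            _write_scores_stream(table, fh)


def _write_scores_stream(table: pd.DataFrame, fh) -> None:
    fh.write("node\tmethod\tscore\trank\n")
    if len(table) == 0:
        return
    method_order = {m: i for i, m in enumerate(table["method"].drop_duplicates())}
    rows = sorted(
        table.itertuples(index=False),
        key=lambda r: (method_order[r.method], -r.score, r.node),
    )
    for r in rows:
        fh.write(f"{r.node}\t{r.method}\t{r.score:.10g}\t{r.rank}\n")


def read_scores(path) -> pd.DataFrame:
    """Read a TSV score table written by :func:`write_scores`."""
    df = pd.read_csv(path, sep="\t", dtype={"node": str, "method": str})
    if list(df.columns) != list(SCORE_COLUMNS):
        raise FormatError(f"unexpected score-table columns: {list(df.columns)}")
    return df
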