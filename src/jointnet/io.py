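"""Readers and writers for networks, tallies and models.

Networks come in as edge-list CSV/TSV (header ``source,target[,weight]``),
square adjacency CSV (node ids in the first row and column), or GraphML.
Weights, if present, are binarized (> 0 becomes an edge) with a warning —
only presence and direction carry meaning in this model.  Tallies and
models round-trip through JSON with full float precision.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import Sequence

import networkx as nx

from .linkage import (
    STATES,
    DirectedBinaryNetwork,
    LinkageTally,
    parse_state,
    state_label,
)

FORMATS = ("edgelist", "adjacency", "graphml")


def read_node_list(path: str | Path) -> tuple[str, ...]:
    """One node id per line; blank lines ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            out.append(line)
    return tuple(out)


def _binarize(weight: str | float | None, where: str) -> bool:
    if weight is None or weight == "":
        return True
    w = float(weight)
    if w not in (0.0, 1.0):
        warnings.warn(f"binarizing weight {w} at {where} (presence/direction only)")
    return w > 0


def read_edgelist(
    path: str | Path, nodes: Sequence[str] | None = None
) -> DirectedBinaryNetwork:
    path = Path(path)
    delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    edges: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty edge-list file")
        cols = [c.strip().lower() for c in header]
        if cols[:2] != ["source", "target"]:
            raise ValueError(
                f"{path}: expected header 'source,target[,weight]', got {header!r}"
            )
        has_weight = len(cols) > 2 and cols[2] == "weight"
        for k, row in enumerate(reader, start=2):
            if not row or not any(x.strip() for x in row):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{k}: malformed row {row!r}")
            src, tgt = row[0].strip(), row[1].strip()
            w = row[2].strip() if has_weight and len(row) > 2 else None
            if _binarize(w, f"{path}:{k}"):
                edges.append((src, tgt))
    return DirectedBinaryNetwork.from_edges(edges, nodes=nodes, drop_self_loops=True)


def read_adjacency(path: str | Path) -> DirectedBinaryNetwork:
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if any(x.strip() for x in r)]
    if not rows:
        raise ValueError(f"{path}: empty adjacency file")
    col_ids = [c.strip() for c in rows[0][1:]]
    n = len(col_ids)
    edges: list[tuple[str, str]] = []
    row_ids = []
    for r in rows[1:]:
        rid = r[0].strip()
        row_ids.append(rid)
        vals = r[1:]
        if len(vals) != n:
            raise ValueError(f"{path}: row {rid!r} has {len(vals)} cells, expected {n}")
        for cid, v in zip(col_ids, vals):
            if rid == cid:
                if v.strip() and float(v) != 0:
                    warnings.warn(f"{path}: dropping diagonal entry at {rid!r}")
                continue
            if v.strip() and _binarize(v, f"{path} [{rid},{cid}]"):
                edges.append((rid, cid))
    if row_ids != col_ids:
        raise ValueError(f"{path}: row and column node ids disagree")
    return DirectedBinaryNetwork.from_edges(edges, nodes=col_ids, drop_self_loops=True)


def read_graphml(path: str | Path) -> DirectedBinaryNetwork:
    g = nx.read_graphml(str(path))
    if not g.is_directed():
        raise ValueError(f"{path}: GraphML graph is undirected")
    if any("weight" in d for _, _, d in g.edges(data=True)):
        warnings.warn(f"{path}: edge weights present in GraphML are ignored")
    return DirectedBinaryNetwork.from_edges(
        ((str(u), str(v)) for u, v in g.edges()),
        nodes=[str(x) for x in g.nodes()],
        drop_self_loops=True,
    )


def read_network(
    path: str | Path, fmt: str = "edgelist", nodes: Sequence[str] | None = None
) -> DirectedBinaryNetwork:
    if fmt == "edgelist":
        return read_edgelist(path, nodes=nodes)
    if fmt == "adjacency":
        return read_adjacency(path)
    if fmt == "graphml":
        return read_graphml(path)
    raise ValueError(f"unknown format {fmt!r}; choose from {FORMATS}")


def write_edgelist(net: DirectedBinaryNetwork, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target"])
        for u, v in sorted(net.edges):
            w.writerow([u, v])


def write_tally(tally: LinkageTally, path: str | Path) -> None:
    payload = {
        "n": tally.n,
        "convention": tally.convention,
        "counts": {state_label(s): tally.counts[s] for s in STATES},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_tally(path: str | Path) -> LinkageTally:
    payload = json.loads(Path(path).read_text())
    counts = {parse_state(k): int(v) for k, v in payload["counts"].items()}
    return LinkageTally(
        n=int(payload["n"]),
        counts=counts,
        convention=payload.get("convention", "paper-n2"),
    )
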