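"""Reading and writing graph ensembles, fitted models, and provenance.

Supported graph formats: whitespace-delimited edge lists (one undirected
edge per line, optional weight column), dense CSV adjacency matrices, and
Matrix Market coordinate files.  All graphs of an ensemble must resolve to
the same vertex set; vertex IDs are mapped to dense 0-based indices through
a stable sorted dictionary, undirected edges stored once are symmetrised,
and self-loops are dropped with a warning.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .core import GraphSample
from .mase import MaseFit

__all__ = [
    "read_graphs",
    "write_graphs",
    "read_fit",
    "write_fit",
    "write_manifest",
    "read_manifest",
]

logger = logging.getLogger("cosie.io")

FORMATS = ("edgelist", "dense-csv", "matrix-market")
_SUFFIX_FORMAT = {
    ".edgelist": "edgelist",
    ".txt": "edgelist",
    ".csv": "dense-csv",
    ".mtx": "matrix-market",
}


def _parse_edgelist(path: Path, weighted: bool):
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "%")):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: malformed edge line {line!r}")
            u, v = parts[0], parts[1]
            if len(parts) == 3:
                w = float(parts[2])
                if not weighted and w not in (0.0, 1.0):
                    warnings.warn(
                        f"{path}:{lineno}: weight column ignored in binary mode"
                    )
                    w = 1.0
            else:
                w = 1.0
            edges.append((u, v, w))
    return edges


def _edges_to_matrix(edges, vertex_index, path):
    n = len(vertex_index)
    A = np.zeros((n, n))
    for u, v, w in edges:
        if u == v:
            warnings.warn(f"{path}: self-loop on vertex {u!r} dropped")
            continue
        i, j = vertex_index[u], vertex_index[v]
        A[i, j] = w
        A[j, i] = w
    return A


def read_graphs(source, fmt: str | None = None, weighted: bool = False) -> GraphSample:
    """Load a graph ensemble from a directory, manifest, or list of files.

    ``source`` may be a directory (all recognised graph files, sorted), a
    manifest JSON produced by :func:`write_manifest`, or an explicit list
    of paths.  The union of vertex IDs across edge-list files defines the
    vertex set; dense/Matrix Market files must agree on n.
    """
    paths, n_hint = _resolve_paths(source)
    if not paths:
        raise FileNotFoundError(f"no graph files found in {source!r}")
    fmts = [fmt or _SUFFIX_FORMAT.get(Path(p).suffix, "edgelist") for p in paths]
    for f in fmts:
        if f not in FORMATS:
            raise ValueError(f"unknown graph format {f!r}")

    # first pass for edge lists: collect the shared vertex dictionary
    edge_sets, dense = {}, {}
    vertices = set()
    for p, f in zip(paths, fmts):
        p = Path(p)
        if f == "edgelist":
            edges = _parse_edgelist(p, weighted)
            edge_sets[p] = edges
            vertices.update(u for u, v, _ in edges)
            vertices.update(v for u, v, _ in edges)
        elif f == "dense-csv":
            dense[p] = pd.read_csv(p, header=None).to_numpy(dtype=float)
        else:
            M = scipy.io.mmread(str(p))
            dense[p] = np.asarray(
                M.todense() if scipy.sparse.issparse(M) else M, dtype=float
            )

    if edge_sets:
        try:
            vertex_ids = sorted(vertices, key=int)
        except ValueError:
            vertex_ids = sorted(vertices)
        if n_hint is not None and n_hint > len(vertex_ids):
            extra = [str(i) for i in range(n_hint) if str(i) not in set(vertex_ids)]
            vertex_ids = vertex_ids + extra[: n_hint - len(vertex_ids)]
        vertex_index = {u: i for i, u in enumerate(vertex_ids)}
    else:
        n = next(iter(dense.values())).shape[0]
        vertex_ids = list(range(n))
        vertex_index = None

    adjacency = []
    for p, f in zip(paths, fmts):
        p = Path(p)
        if f == "edgelist":
            A = _edges_to_matrix(edge_sets[p], vertex_index, p)
        else:
            A = dense[p]
            if A.shape[0] != A.shape[1]:
                raise ValueError(f"{p}: adjacency matrix must be square")
            A = np.maximum(A, A.T)  # symmetrise edges stored once
            if np.any(np.diag(A) != 0):
                warnings.warn(f"{p}: nonzero diagonal dropped (graphs are hollow)")
                np.fill_diagonal(A, 0.0)
        if A.shape[0] != len(vertex_ids):
            raise ValueError(f"{p}: inconsistent vertex set across graphs")
        if not weighted:
            A = (A != 0).astype(float)
        adjacency.append(A)
    return GraphSample(
        adjacency=adjacency,
        vertex_ids=list(vertex_ids),
        graph_ids=[Path(p).stem for p in paths],
    )


def _resolve_paths(source):
    n_hint = None
    if isinstance(source, (list, tuple)):
        return [Path(p) for p in source], n_hint
    source = Path(source)
    if source.is_dir():
        paths = sorted(
            p for p in source.iterdir() if p.suffix in _SUFFIX_FORMAT
            and p.name != "manifest.json"
        )
        return paths, n_hint
    if source.suffix == ".json":
        manifest = json.loads(source.read_text())
        base = source.parent
        n_hint = manifest.get("n")
        return [base / p for p in manifest["graphs"]], n_hint
    return [source], n_hint


def write_graphs(sample: GraphSample, out_dir, fmt: str = "edgelist") -> list[Path]:
    """Write each graph of an ensemble to its own file plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = {"edgelist": ".edgelist", "dense-csv": ".csv", "matrix-market": ".mtx"}[fmt]
    paths = []
    for gid, A in zip(sample.graph_ids, sample.adjacency):
        path = out_dir / f"graph_{gid}{suffix}"
        if fmt == "edgelist":
            iu = np.triu_indices_from(A, k=1)
            rows = [
                f"{sample.vertex_ids[i]} {sample.vertex_ids[j]}"
                for i, j, w in zip(*iu, A[iu])
                if w != 0
            ]
            path.write_text("\n".join(rows) + ("\n" if rows else ""))
        elif fmt == "dense-csv":
            pd.DataFrame(A).to_csv(path, header=False, index=False)
        else:
            scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(A), symmetry="symmetric")
            path = path if path.exists() else path.with_suffix(".mtx")
        paths.append(path)
    write_manifest(out_dir, paths, fmt=fmt, n=sample.n)
    return paths


def write_manifest(out_dir, paths, fmt: str, n: int, extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    record = {
        "graphs": [Path(p).name for p in paths],
        "format": fmt,
        "n": int(n),
    }
    if extra:
        record.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(record, indent=2, default=_jsonable) + "\n")
    return path


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def write_fit(fit: MaseFit, out_dir, provenance: dict | None = None) -> Path:
    """Persist a fitted model: V-hat CSV, stacked R-hat CSV, JSON metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(fit.V_hat).to_csv(out_dir / "V_hat.csv", header=False, index=False)
    stacked = np.vstack(fit.R_hat_list)
    pd.DataFrame(stacked).to_csv(out_dir / "R_hat.csv", header=False, index=False)
    meta = {
        "n": fit.n,
        "d": fit.d,
        "m": fit.m,
        "d_i_list": fit.d_i_list,
        "variant": fit.variant,
        "joint_singular_values": fit.joint_singular_values.tolist(),
    }
    if provenance:
        meta["provenance"] = provenance
    (out_dir / "fit.json").write_text(json.dumps(meta, indent=2, default=_jsonable) + "\n")
    logger.info("wrote fit (n=%d, d=%d, m=%d) to %s", fit.n, fit.d, fit.m, out_dir)
    return out_dir


def read_fit(in_dir) -> MaseFit:
    """Load a fit written by :func:`write_fit`."""
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "fit.json").read_text())
    V_hat = pd.read_csv(in_dir / "V_hat.csv", header=None).to_numpy(dtype=float)
    stacked = pd.read_csv(in_dir / "R_hat.csv", header=None).to_numpy(dtype=float)
    d = meta["d"]
    R_list = [stacked[i * d : (i + 1) * d] for i in range(meta["m"])]
    return MaseFit(
        V_hat=V_hat,
        R_hat_list=R_list,
        d_i_list=list(meta["d_i_list"]),
        variant=meta["variant"],
        joint_singular_values=np.asarray(meta["joint_singular_values"]),
    )
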