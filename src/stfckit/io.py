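"""Readers and writers for the pipeline's on-disk formats.

Streamlines travel as VTK polydata — legacy ASCII ``.vtk`` or XML ascii
``.vtp`` — with polyline cells, optional per-point scalar arrays named
``"FA"`` and ``"MD"``, and an optional per-cell integer array
``"cluster_id"`` that splits one file into multiple fiber clusters.  Both
dialects are read and written here directly (text encodings only), so a
round trip preserves coordinates bit-exactly via repr-precision floats.

Tabular data is TSV (UTF-8, '.' decimal): feature tables are subjects x
clusters with a header of cluster ids and empty cells for missing entries;
covariate tables carry subject id, sex, age; neighborhood graphs are edge
lists (node_a, node_b, distance_mm) with a JSON metadata sidecar.  CSV is
accepted on input.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import (
    ClusterFeatureTable,
    FiberCluster,
    NeighborhoodGraph,
    Streamline,
    assign_laterality,
)

__all__ = [
    "load_streamlines",
    "save_streamlines",
    "read_feature_table",
    "write_feature_table",
    "read_covariates",
    "write_covariates",
    "read_graph",
    "write_graph",
]

SCALAR_NAMES = ("FA", "MD")
_FMT = "%.17g"  # round-trips float64 exactly


class FormatError(ValueError):
    """Malformed streamline / table file."""


# ---------------------------------------------------------------------------
# VTK polydata


def _clusters_from_polydata(
    points: np.ndarray,
    lines: list[np.ndarray],
    point_data: dict[str, np.ndarray],
    cell_data: dict[str, np.ndarray],
) -> list[FiberCluster]:
    if not lines:
        raise FormatError("polydata contains no line cells")
    for name, arr in point_data.items():
        if len(arr) != len(points):
            raise FormatError(f"point array {name!r} has {len(arr)} values for {len(points)} points")
    streams = []
    for conn in lines:
        if conn.max(initial=-1) >= len(points) or conn.min(initial=0) < 0:
            raise FormatError("line connectivity indexes outside the point array")
        scalars = {k: v[conn] for k, v in point_data.items() if k in SCALAR_NAMES}
        streams.append(Streamline(points=points[conn], scalars=scalars))
    ids = cell_data.get("cluster_id")
    if ids is None:
        sl_pts = np.vstack([s.points for s in streams])
        return [FiberCluster(cluster_id=0, laterality=assign_laterality(sl_pts), streamlines=streams)]
    if len(ids) != len(streams):
        raise FormatError("cluster_id cell array length does not match line count")
    clusters = []
    for cid in sorted(set(int(i) for i in ids)):
        members = [s for s, i in zip(streams, ids) if int(i) == cid]
        pts = np.vstack([s.points for s in members])
        clusters.append(FiberCluster(cluster_id=cid, laterality=assign_laterality(pts), streamlines=members))
    return clusters


def _read_legacy_vtk(path: Path) -> list[FiberCluster]:
    text = path.read_text().split("\n")
    # tokenize everything after the 4-line header
    header_done = 0
    body: list[str] = []
    for line in text:
        if header_done < 4:
            header_done += 1
            if header_done == 3 and line.strip().upper() not in ("ASCII",):
                raise FormatError("only ASCII legacy VTK files are supported")
            continue
        body.extend(line.replace(",", " ").split())
    tok = body
    pos = 0

    def take(n: int) -> list[str]:
        nonlocal pos
        if pos + n > len(tok):
            raise FormatError("truncated VTK file")
        out = tok[pos : pos + n]
        pos += n
        return out

    points = np.empty((0, 3))
    lines: list[np.ndarray] = []
    point_data: dict[str, np.ndarray] = {}
    cell_data: dict[str, np.ndarray] = {}
    target = None  # which dict SCALARS sections fill
    while pos < len(tok):
        word = tok[pos].upper()
        if word == "DATASET":
            if take(2)[1].upper() != "POLYDATA":
                raise FormatError("dataset is not POLYDATA")
        elif word == "POINTS":
            _, n, _dtype = take(3)
            vals = np.array(take(3 * int(n)), dtype=float)
            points = vals.reshape(int(n), 3)
        elif word == "LINES":
            _, n_cells, total = take(3)
            n_cells = int(n_cells)
            remaining = int(total)
            for _ in range(n_cells):
                m = int(take(1)[0])
                lines.append(np.array(take(m), dtype=int))
                remaining -= m + 1
            if remaining != 0:
                raise FormatError("LINES size field inconsistent with connectivity")
        elif word == "POINT_DATA":
            take(2)
            target = point_data
        elif word == "CELL_DATA":
            take(2)
            target = cell_data
        elif word == "SCALARS":
            _, name, _dtype = take(3)
            extra = take(1)  # numComp or LOOKUP_TABLE
            if extra[0].upper() == "LOOKUP_TABLE":
                take(1)
            else:
                if tok[pos].upper() == "LOOKUP_TABLE":
                    take(2)
            count = len(points) if target is point_data else len(lines)
            if target is None:
                raise FormatError("SCALARS outside POINT_DATA/CELL_DATA")
            target[name] = np.array(take(count), dtype=float)
        else:
            pos += 1  # skip unhandled attribute sections token-wise
    return _clusters_from_polydata(points, lines, point_data, cell_data)


def _read_vtp(path: Path) -> list[FiberCluster]:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"not a parseable .vtp file: {exc}") from exc
    piece = root.find(".//Piece")
    if piece is None:
        raise FormatError("no <Piece> element")

    def arrays(section: str) -> dict[str, np.ndarray]:
        node = piece.find(section)
        out = {}
        if node is not None:
            for da in node.findall("DataArray"):
                if da.get("format", "ascii") != "ascii":
                    raise FormatError("only ascii-format DataArrays are supported")
                out[da.get("Name", "")] = np.array((da.text or "").split(), dtype=float)
        return out

    pts_node = piece.find("Points/DataArray")
    if pts_node is None:
        raise FormatError("no Points array")
    points = np.array((pts_node.text or "").split(), dtype=float).reshape(-1, 3)
    line_arrays = arrays("Lines")
    if "connectivity" not in line_arrays or "offsets" not in line_arrays:
        raise FormatError("polydata contains no line cells")
    conn = line_arrays["connectivity"].astype(int)
    offsets = line_arrays["offsets"].astype(int)
    lines, start = [], 0
    for end in offsets:
        lines.append(conn[start:end])
        start = end
    return _clusters_from_polydata(points, lines, arrays("PointData"), arrays("CellData"))


def load_streamlines(path, format: str | None = None) -> list[FiberCluster]:
    """Read fiber clusters from VTK polydata (``.vtp`` XML or ``.vtk`` legacy).

    Polylines and their per-point FA/MD scalars are preserved exactly;
    streamlines are grouped by the ``cluster_id`` cell array when present,
    otherwise the file is one cluster.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "vtp":
        return _read_vtp(path)
    if fmt == "vtk":
        return _read_legacy_vtk(path)
    raise FormatError(f"unknown streamline format {fmt!r}")


def _gather(clusters: Sequence[FiberCluster]):
    points, lines, cell_ids = [], [], []
    scalars: dict[str, list[np.ndarray]] = {}
    offset = 0
    present = {name for c in clusters for s in c.streamlines for name in s.scalars}
    for c in clusters:
        for s in c.streamlines:
            n = len(s.points)
            points.append(s.points)
            lines.append(np.arange(offset, offset + n))
            offset += n
            cell_ids.append(c.cluster_id)
            for name in present:
                if name not in s.scalars:
                    raise FormatError(f"scalar {name!r} present on some streamlines but not all")
                scalars.setdefault(name, []).append(s.scalars[name])
    if not points:
        raise FormatError("nothing to write: no streamlines")
    pts = np.vstack(points)
    pdata = {k: np.concatenate(v) for k, v in scalars.items()}
    return pts, lines, pdata, np.array(cell_ids)


def save_streamlines(clusters: Sequence[FiberCluster], path, format: str | None = None) -> None:
    """Write fiber clusters as ASCII VTK polydata (dialect from extension)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    pts, lines, pdata, cell_ids = _gather(clusters)
    if fmt == "vtk":
        out = ["# vtk DataFile Version 3.0", "stfckit streamlines", "ASCII", "DATASET POLYDATA"]
        out.append(f"POINTS {len(pts)} double")
        out.extend(" ".join(_FMT % v for v in row) for row in pts)
        total = sum(len(l) + 1 for l in lines)
        out.append(f"LINES {len(lines)} {total}")
        out.extend(f"{len(l)} " + " ".join(map(str, l)) for l in lines)
        if pdata:
            out.append(f"POINT_DATA {len(pts)}")
            for name, arr in sorted(pdata.items()):
                out.append(f"SCALARS {name} double 1")
                out.append("LOOKUP_TABLE default")
                out.extend(_FMT % v for v in arr)
        out.append(f"CELL_DATA {len(lines)}")
        out.append("SCALARS cluster_id int 1")
        out.append("LOOKUP_TABLE default")
        out.extend(str(int(i)) for i in cell_ids)
        path.write_text("\n".join(out) + "\n")
        return
    if fmt == "vtp":
        root = ET.Element("VTKFile", type="PolyData", version="0.1", byte_order="LittleEndian")
        poly = ET.SubElement(root, "PolyData")
        piece = ET.SubElement(
            poly, "Piece", NumberOfPoints=str(len(pts)), NumberOfLines=str(len(lines)),
            NumberOfVerts="0", NumberOfStrips="0", NumberOfPolys="0",
        )

        def data_array(parent, name, values, dtype="Float64", ncomp=None):
            attrs = {"type": dtype, "Name": name, "format": "ascii"}
            if ncomp:
                attrs["NumberOfComponents"] = str(ncomp)
            da = ET.SubElement(parent, "DataArray", **attrs)
            da.text = " ".join(_FMT % v if dtype == "Float64" else str(int(v)) for v in np.ravel(values))

        points_el = ET.SubElement(piece, "Points")
        data_array(points_el, "Points", pts, ncomp=3)
        lines_el = ET.SubElement(piece, "Lines")
        data_array(lines_el, "connectivity", np.concatenate(lines), dtype="Int64")
        data_array(lines_el, "offsets", np.cumsum([len(l) for l in lines]), dtype="Int64")
        if pdata:
            pd_el = ET.SubElement(piece, "PointData")
            for name, arr in sorted(pdata.items()):
                data_array(pd_el, name, arr)
        cd_el = ET.SubElement(piece, "CellData")
        data_array(cd_el, "cluster_id", cell_ids, dtype="Int64")
        ET.indent(root)
        ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
        return
    raise FormatError(f"unknown streamline format {fmt!r}")


# ---------------------------------------------------------------------------
# tables and graphs


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def write_feature_table(table: ClusterFeatureTable, path) -> None:
    path = Path(path)
    table.values.to_csv(path, sep="\t", index_label="subject", float_format="%.17g")


def read_feature_table(path, covariates=None, measure: str = "FA") -> ClusterFeatureTable | pd.DataFrame:
    """Read a subjects x clusters table; with ``covariates`` (path or frame)
    returns a full :class:`ClusterFeatureTable`, else the bare DataFrame."""
    path = Path(path)
    values = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    values.index = values.index.astype(str)
    if covariates is None:
        return values
    meta = read_covariates(covariates) if not isinstance(covariates, pd.DataFrame) else covariates
    meta = meta.loc[values.index]
    return ClusterFeatureTable(values=values, subject_meta=meta, measure=measure)


def write_covariates(meta: pd.DataFrame, path) -> None:
    meta.to_csv(Path(path), sep="\t", index_label="subject")


def read_covariates(path) -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    meta.index = meta.index.astype(str)
    missing = {"sex", "age"} - set(meta.columns)
    if missing:
        raise FormatError(f"covariate table lacks columns: {sorted(missing)}")
    return meta


def write_graph(graph: NeighborhoodGraph, path) -> None:
    """Edge-list TSV plus a JSON sidecar with k, metric and the node list."""
    path = Path(path)
    graph.to_edge_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {"k": graph.k, "metric": graph.metric, "nodes": [str(n) for n in graph.nodes]}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_graph(path) -> NeighborhoodGraph:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), dtype={"node_a": str, "node_b": str},
                        float_precision="round_trip")
    meta_path = path.with_suffix(path.suffix + ".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        nodes, k, metric = meta["nodes"], meta["k"], meta.get("metric", "mean_closest_point")
    else:
        nodes = sorted(set(frame["node_a"]) | set(frame["node_b"]))
        k, metric = 0, "mean_closest_point"
    return NeighborhoodGraph.from_edge_frame(frame, nodes=nodes, k=k, metric=metric)
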