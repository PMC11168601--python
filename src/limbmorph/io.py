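"""Readers and writers for the formats the pipeline touches.

STL carries the segmented surfaces (facet soup, binary or ASCII, welded on
read); ASCII PLY carries per-vertex scalar fields for heat-map display in
standard mesh viewers; CSV carries landmark pairs and histograms; JSON
carries run reports with provenance.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import trimesh as _trimesh

from .exceptions import LandmarkError, STLFormatError
from .mesh import LandmarkPairs, TriangleMesh

__all__ = [
    "ScalarMesh",
    "WELD_TOLERANCE_MM",
    "read_stl",
    "write_stl",
    "write_scalar_mesh",
    "read_scalar_mesh",
    "read_landmarks",
    "write_landmarks",
    "write_histogram_csv",
    "write_report_json",
]

#: Coincident-vertex weld tolerance on STL read. Far below MRI voxel scale
#: (>= 0.6 mm), so anatomy is unaffected while facet soup becomes a proper
#: shared-vertex mesh.
WELD_TOLERANCE_MM = 1e-6

_LANDMARK_COLUMNS = ["src_x", "src_y", "src_z", "dst_x", "dst_y", "dst_z"]


@dataclass
class ScalarMesh:
    """A surface plus one scalar per vertex (e.g. nearest distance, signed offset)."""

    mesh: TriangleMesh
    scalars: np.ndarray
    scalar_name: str = "scalar"
    missing: np.ndarray | None = None  # bool mask of explicitly-missing values

    def __post_init__(self) -> None:
        self.scalars = np.asarray(self.scalars, dtype=np.float64).reshape(-1)
        if len(self.scalars) != self.mesh.n_vertices:
            raise ValueError(
                f"scalar count {len(self.scalars)} != vertex count {self.mesh.n_vertices}"
            )
        bad = ~np.isfinite(self.scalars)
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool).reshape(-1)
            bad &= ~self.missing
        if bad.any():
            raise ValueError(
                f"non-finite scalar at vertex {int(np.flatnonzero(bad)[0])} "
                "without a missing flag"
            )


def _weld(vertices: np.ndarray, faces: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge coincident vertices by snapping coordinates to a grid of pitch tol.

    Grid quantization is order-independent: permuting facets in the file
    yields the same welded coordinate multiset.
    """
    decimals = max(0, int(round(-np.log10(tol))))
    key = np.round(vertices, decimals=decimals)
    uniq, index, inverse = np.unique(
        key, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(index)  # keep first-appearance ordering
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return vertices[np.sort(index)], rank[inverse][faces]


def _sniff_stl(path: Path) -> None:
    """Reject files that are neither a size-consistent binary STL nor ASCII.

    Binary STL is 80-byte header + uint32 facet count + 50 bytes per
    facet; a declared count exceeding the file length means truncation.
    ASCII must carry the ``solid`` token (and ``facet``/``endsolid``).
    """
    size = path.stat().st_size
    if size >= 84:
        import struct

        with path.open("rb") as fh:
            fh.seek(80)
            (count,) = struct.unpack("<I", fh.read(4))
        if size == 84 + 50 * count:
            return  # consistent binary
    head = path.read_bytes()[:4096]
    try:
        text = head.decode("ascii")
    except UnicodeDecodeError:
        raise STLFormatError(
            f"{path}: binary STL size inconsistent with declared facet count "
            "(truncated?)"
        ) from None
    lowered = text.lower()
    if lowered.lstrip().startswith("solid") and (
        "facet" in lowered or "endsolid" in lowered
    ):
        return
    raise STLFormatError(
        f"{path}: not an STL file (no consistent binary layout, "
        "no 'solid'/'facet' tokens)"
    )


def read_stl(path: str | Path, name: str = "") -> TriangleMesh:
    """Read a binary or ASCII STL (auto-detected) into a welded TriangleMesh.

    STL stores an unconnected facet soup; coincident vertices are welded
    within :data:`WELD_TOLERANCE_MM` to recover shared topology. Facet
    normals stored in the file are ignored; orientation comes from the
    facet winding alone.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _sniff_stl(path)
    try:
        tm = _trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises assorted struct/value errors
        raise STLFormatError(f"{path}: not a parseable STL file ({exc})") from exc
    if not isinstance(tm, _trimesh.Trimesh):
        if isinstance(tm, _trimesh.Scene) and tm.is_empty:
            return TriangleMesh(np.empty((0, 3)), np.empty((0, 3), int), name or path.stem)
        raise STLFormatError(f"{path}: STL did not contain a triangle mesh")
    v = np.asarray(tm.vertices, dtype=np.float64)
    f = np.asarray(tm.faces, dtype=np.int64)
    if len(v):
        v, f = _weld(v, f, WELD_TOLERANCE_MM)
    return TriangleMesh(v, f, name or path.stem)


def write_stl(mesh: TriangleMesh, path: str | Path, dialect: str = "binary") -> Path:
    """Write STL; binary (default, compact) or ASCII.

    Binary STL stores coordinates in IEEE single precision, so a
    round-trip quantizes geometry to float32 (< 1e-4 relative error);
    ASCII preserves the printed decimal form.
    """
    path = Path(path)
    tm = mesh.to_trimesh()
    if dialect == "binary":
        data = _trimesh.exchange.stl.export_stl(tm)
        path.write_bytes(data)
    elif dialect == "ascii":
        path.write_text(_trimesh.exchange.stl.export_stl_ascii(tm))
    else:
        raise ValueError(f"dialect must be 'binary' or 'ascii', got {dialect!r}")
    return path


def write_scalar_mesh(sm: ScalarMesh, path: str | Path) -> Path:
    """Write an ASCII PLY with the scalar as a named per-vertex property.

    Loadable by standard viewers (MeshLab, ParaView, CloudCompare) for
    heat-map display of distance or signed-offset fields.
    """
    path = Path(path)
    tm = sm.mesh.to_trimesh()
    tm.vertex_attributes[sm.scalar_name] = sm.scalars.astype(np.float64)
    data = _trimesh.exchange.ply.export_ply(
        tm, encoding="ascii", include_attributes=True
    )
    path.write_bytes(data)
    return path


def read_scalar_mesh(path: str | Path, scalar_name: str) -> ScalarMesh:
    """Read back a PLY written by :func:`write_scalar_mesh`."""
    path = Path(path)
    tm = _trimesh.load(str(path), file_type="ply", process=False)
    raw = tm.metadata.get("_ply_raw", {}).get("vertex", {})
    data = raw.get("data")
    # ascii PLY parses into a dict of columns, binary into a structured array
    if isinstance(data, dict):
        present = scalar_name in data
    else:
        present = data is not None and scalar_name in (data.dtype.names or ())
    if not present:
        raise STLFormatError(f"{path}: no per-vertex property {scalar_name!r}")
    scalars = np.asarray(data[scalar_name], dtype=np.float64).reshape(-1)
    mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces), path.stem)
    return ScalarMesh(mesh=mesh, scalars=scalars, scalar_name=scalar_name)


def read_landmarks(path: str | Path) -> LandmarkPairs:
    """Read paired landmarks from CSV with columns src_x..src_z, dst_x..dst_z (mm).

    Row order is preserved (rows are index-paired picks on equivalent
    anatomy of the two models).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in _LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise LandmarkError(f"{path}: missing column(s) {missing}")
    if len(df) < 3:
        raise LandmarkError(f"{path}: need at least 3 landmark rows, found {len(df)}")
    for col in _LANDMARK_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise LandmarkError(
                f"{path}: non-numeric value in column {col!r} at data row {row}"
            )
        df[col] = coerced
    src = df[["src_x", "src_y", "src_z"]].to_numpy(dtype=np.float64)
    dst = df[["dst_x", "dst_y", "dst_z"]].to_numpy(dtype=np.float64)
    return LandmarkPairs(src, dst)


def write_landmarks(pairs: LandmarkPairs, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        np.hstack([pairs.source_points, pairs.target_points]),
        columns=_LANDMARK_COLUMNS,
    )
    df.to_csv(path, index=False)
    return path


def write_histogram_csv(
    histograms: Mapping[str, "DistanceHistogram"], path: str | Path  # noqa: F821
) -> Path:
    """Write one or more distance histograms to CSV.

    Conditions sharing identical bin edges go into one aligned table with
    columns ``bin_lower_mm, bin_upper_mm, percent_<condition>...`` (the
    overlay layout); otherwise conditions are stacked as per-condition
    blocks with a ``condition`` column.
    """
    path = Path(path)
    items = list(histograms.items())
    if not items:
        raise ValueError("no histograms to write")
    for cname, h in items:
        if len(h.percents) == 0:
            raise ValueError(f"histogram for {cname!r} is empty")
    edges0 = items[0][1].bin_edges
    aligned = all(
        len(h.bin_edges) == len(edges0) and np.allclose(h.bin_edges, edges0)
        for _, h in items
    )
    if aligned:
        df = pd.DataFrame(
            {"bin_lower_mm": edges0[:-1], "bin_upper_mm": edges0[1:]}
        )
        for cname, h in items:
            df[f"percent_{cname}"] = h.percents
    else:
        blocks = []
        for cname, h in items:
            blocks.append(
                pd.DataFrame(
                    {
                        "condition": cname,
                        "bin_lower_mm": h.bin_edges[:-1],
                        "bin_upper_mm": h.bin_edges[1:],
                        "percent": h.percents,
                    }
                )
            )
        df = pd.concat(blocks, ignore_index=True)
    df.to_csv(path, index=False)
    return path


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, Path):
            return str(obj)
        return super().default(obj)


def write_report_json(report: Mapping, path: str | Path) -> Path:
    """Write a run report (summaries, metrics, provenance) as indented JSON."""
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")
    return path
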