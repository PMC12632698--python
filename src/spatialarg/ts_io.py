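"""Reading and writing spatial ARGs.

Tree sequences are stored in the standard succinct tables format
(``.trees``); a gzip-compressed variant is written with the ``.tsz``
suffix. Per-node locations are embedded as JSON node metadata (keys
``x``, ``y``) and the CRS tag in the top-level table metadata, so files
remain consumable by ordinary tree-sequence tooling.

Node coordinates can also be exchanged as CSV with a
``node_id,x,y`` header.
"""

from __future__ import annotations

import gzip
import json
import tempfile
import os
from typing import List, Optional, Union

import numpy as np
import pandas as pd
import tskit

from .errors import FormatError, StructuralError, ValidationError
from .model import (
    CRS_CUSTOM,
    CRS_LONLAT,
    CRS_UNIT_GRID,
    LocalTree,
    LocationTable,
    SpatialARG,
    validate_tables,
)

_METADATA_KEY = "spatialarg"
_GZIP_MAGIC = b"\x1f\x8b"


def _decode_node_metadata(raw) -> Optional[dict]:
    if isinstance(raw, dict):
        return raw
    if isinstance(raw, bytes):
        if not raw:
            return None
        try:
            return json.loads(raw.decode())
        except (ValueError, UnicodeDecodeError):
            return None
    return None


def _locations_from_tables(tables: tskit.TableCollection) -> Optional[LocationTable]:
    coords = {}
    for u, node in enumerate(tables.nodes):
        md = _decode_node_metadata(node.metadata)
        if md and "x" in md and "y" in md:
            coords[u] = (float(md["x"]), float(md["y"]))
    if not coords:
        return None
    crs = CRS_CUSTOM
    top = tables.metadata if isinstance(tables.metadata, dict) else None
    if top is None and isinstance(tables.metadata_bytes, bytes) and tables.metadata_bytes:
        try:
            top = json.loads(tables.metadata_bytes.decode())
        except (ValueError, UnicodeDecodeError):
            top = None
    if top and _METADATA_KEY in top and "crs" in top[_METADATA_KEY]:
        tag = top[_METADATA_KEY]["crs"]
        if tag in (CRS_UNIT_GRID, CRS_LONLAT, CRS_CUSTOM):
            crs = tag
    table = LocationTable(coords, crs=CRS_CUSTOM)
    if crs != CRS_CUSTOM:
        table = LocationTable(coords, crs=crs)
    return table


def load_tree_sequence(path: Union[str, os.PathLike]) -> SpatialARG:
    """Load a ``.trees`` (or gzip-compressed ``.tsz``) file.

    Locations are populated when the file carries per-node coordinate
    metadata. Structural invariants are checked before the tree sequence
    is assembled, so a table with e.g. a parent no older than its child
    produces a :class:`ValidationError` naming the offending edge.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    with open(path, "rb") as f:
        head = f.read(2)
    try:
        if head == _GZIP_MAGIC:
            # tskit wants a real file descriptor, so decompress to a
            # temporary file first
            with gzip.open(path, "rb") as f:
                payload = f.read()
            with tempfile.NamedTemporaryFile(suffix=".trees") as tmp:
                tmp.write(payload)
                tmp.flush()
                tables = tskit.TableCollection.load(tmp.name)
        else:
            tables = tskit.TableCollection.load(path)
    except (tskit.FileFormatError, tskit.LibraryError, EOFError, OSError) as err:
        raise FormatError(f"cannot read tree-sequence tables from {path}: {err}") from err
    validate_tables(tables)
    locations = _locations_from_tables(tables)
    tables.sort()
    tables.build_index()
    try:
        ts = tables.tree_sequence()
    except tskit.LibraryError as err:
        raise FormatError(f"malformed tables in {path}: {err}") from err
    return SpatialARG(ts, locations)


def save_tree_sequence(
    arg: SpatialARG,
    path: Union[str, os.PathLike],
    compressed: Optional[bool] = None,
) -> None:
    """Write ``arg`` to ``path`` (``.trees``; gzip when ``compressed``).

    When ``compressed`` is None it is inferred from a ``.tsz`` suffix.
    Locations are serialized into node metadata so a reload reproduces
    them; node/edge tables round-trip exactly.
    """
    path = os.fspath(path)
    if compressed is None:
        compressed = path.endswith(".tsz")
    tables = arg.ts.dump_tables()
    if arg.locations is not None:
        payloads: List[bytes] = []
        for u, node in enumerate(tables.nodes):
            md = _decode_node_metadata(node.metadata) or {}
            xy = arg.locations.get(u)
            if xy is not None:
                md["x"], md["y"] = float(xy[0]), float(xy[1])
            payloads.append(json.dumps(md, sort_keys=True).encode() if md else b"")
        tables.nodes.metadata_schema = tskit.MetadataSchema.null()
        tables.nodes.packset_metadata(payloads)
        top = {}
        if isinstance(tables.metadata, dict):
            top = dict(tables.metadata)
        top[_METADATA_KEY] = {"crs": arg.locations.crs}
        tables.metadata_schema = tskit.MetadataSchema.permissive_json()
        tables.metadata = top
    try:
        if compressed:
            with tempfile.NamedTemporaryFile(suffix=".trees") as tmp:
                tables.dump(tmp.name)
                tmp.seek(0)
                payload = tmp.read()
            # mtime=0 keeps the gzip container byte-stable across runs
            with open(path, "wb") as raw, gzip.GzipFile(
                fileobj=raw, mode="wb", mtime=0
            ) as f:
                f.write(payload)
        else:
            tables.dump(path)
    except OSError as err:
        raise FormatError(f"cannot write {path}: {err}") from err


def load_locations_csv(path: Union[str, os.PathLike]) -> LocationTable:
    """Read node coordinates from a CSV with header ``node_id,x,y``.

    Columns may appear in any order; extra columns are ignored.
    Duplicate node ids and non-numeric coordinates are errors.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as err:
        raise FormatError(f"cannot parse CSV {path}: {err}") from err
    missing = [c for c in ("node_id", "x", "y") if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; header must "
            "contain node_id,x,y"
        )
    coords = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # row 1 = header
        rec = {c: getattr(row, c) for c in ("node_id", "x", "y")}
        try:
            node = int(rec["node_id"])
            x = float(rec["x"])
            y = float(rec["y"])
        except (TypeError, ValueError) as err:
            raise FormatError(f"{path} row {i}: non-numeric value ({err})") from err
        if node in coords:
            raise FormatError(f"{path} row {i}: duplicate node_id {node}")
        coords[node] = (x, y)
    return LocationTable(coords, crs=detect_crs_from_coords(coords))


def save_locations_csv(table: LocationTable, path: Union[str, os.PathLike]) -> None:
    """Inverse of :func:`load_locations_csv` (same schema)."""
    df = pd.DataFrame(
        [(u, x, y) for u, (x, y) in table.items()], columns=["node_id", "x", "y"]
    )
    df.to_csv(path, index=False)


def detect_crs_from_coords(coords: dict) -> str:
    xs = np.array([xy[0] for xy in coords.values()], dtype=float)
    ys = np.array([xy[1] for xy in coords.values()], dtype=float)
    in_range = (
        xs.min() >= -180.0 and xs.max() <= 180.0 and ys.min() >= -90.0 and ys.max() <= 90.0
    )
    spans_unit = (xs.max() - xs.min() > 1.0) or (ys.max() - ys.min() > 1.0)
    return CRS_LONLAT if (in_range and spans_unit) else CRS_UNIT_GRID


def detect_crs(table: LocationTable) -> str:
    """Classify coordinates as lon/lat or an abstract unit grid.

    Lon/lat requires every point inside the geographic range and a
    bounding box wider than one unit on some axis (sub-unit clouds are
    assumed to live on the unit grid). Pure function of the bounding box.
    """
    if len(table) == 0:
        raise ValidationError("cannot detect CRS of an empty location table")
    return detect_crs_from_coords(table.coords)


def attach_locations(arg: SpatialARG, table: LocationTable) -> SpatialARG:
    """Return a new SpatialARG with ``table``'s coordinates attached.

    Every sample node must be covered; internal nodes are optional. The
    CRS is re-inferred from the coordinates via :func:`detect_crs`.
    """
    bad = sorted(u for u in table.coords if u < 0 or u >= arg.num_nodes)
    if bad:
        raise ValidationError(
            f"location table refers to nonexistent node ids {bad} "
            f"(ARG has {arg.num_nodes} nodes)"
        )
    missing = sorted(int(s) for s in arg.samples if s not in table)
    if missing:
        raise ValidationError(f"location table missing sample nodes {missing}")
    located = LocationTable(dict(table.coords), crs=detect_crs(table))
    return arg.with_locations(located)


def extract_local_trees(arg: SpatialARG) -> List[LocalTree]:
    """Decompose the ARG into its marginal trees.

    Intervals partition ``[0, sequence_length)``; adjacent trees with
    identical parent arrays are merged. An interior interval covered by
    no edge at all (while the ARG does have edges) indicates a gap in
    edge coverage and raises :class:`StructuralError`.
    """
    samples = arg.samples.copy()
    out: List[LocalTree] = []
    has_edges = arg.num_edges > 0
    for tree in arg.ts.trees():
        left, right = tree.interval
        if has_edges and tree.num_edges == 0:
            raise StructuralError(
                f"no edges cover genomic interval [{left:g}, {right:g})"
            )
        parent = tree.parent_array[: arg.num_nodes].astype(np.int32).copy()
        if out and np.array_equal(out[-1].parent, parent):
            prev = out[-1]
            out[-1] = LocalTree((prev.interval[0], right), prev.parent, prev.samples)
        else:
            out.append(LocalTree((left, right), parent, samples))
    return out


def content_digest(path: Union[str, os.PathLike]) -> str:
    """Canonical SHA-256 digest of a tree-sequence file's contents.

    The on-disk tables format embeds a fresh UUID on every write, so raw
    byte hashes of two identical saves differ. This digest instead hashes
    the table columns (provenance excluded), making it stable across
    re-saves of the same data and suitable for reproducibility checks.
    """
    import hashlib

    arg = load_tree_sequence(path)
    tables = arg.ts.dump_tables()
    tables.provenances.clear()
    h = hashlib.sha256()

    def feed(obj):
        if isinstance(obj, dict):
            for key in sorted(obj):
                if key in ("provenances", "file_uuid", "uuid", "time_units"):
                    continue
                feed(key)
                feed(obj[key])
        elif isinstance(obj, np.ndarray):
            h.update(np.ascontiguousarray(obj).tobytes())
        elif isinstance(obj, bytes):
            h.update(obj)
        else:
            h.update(repr(obj).encode())

    feed(tables.asdict())
    return h.hexdigest()
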