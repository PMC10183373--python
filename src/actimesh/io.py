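"""File formats: TIFF stacks, PLY/OBJ meshes, label exports, track tables.

Volumes travel as multi-page TIFF with ImageJ-style spacing metadata
(axis order ``(t, c, z, y, x)`` after normalisation); meshes as PLY
(binary little-endian by default, ASCII on request) carrying
``instance_id`` and ``frame_index`` in comment lines, or as OBJ.  Label
images are unsigned 16-bit TIFF with one label value per mesh.  Tracks
export as CSV and as a simplified TrackMate-style XML (spots + edges
subset of the schema).
"""

from __future__ import annotations

import struct
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import tifffile
import trimesh as _trimesh

from .errors import FormatError
from .labels import LabelTriplet
from .mesh import TriMesh, binarize
from .tracking import Track
from .volume import Volume

__all__ = [
    "read_stack",
    "write_stack",
    "save_mesh",
    "load_mesh",
    "save_labels",
    "export_label_volume",
    "tracks_to_csv",
    "tracks_to_trackmate_xml",
]


# ---------------------------------------------------------------------------
# TIFF volumes


def write_stack(path, volumes, spacing=None) -> None:
    """Write volumes as a (t, c, z, y, x) ImageJ TIFF with spacing metadata.

    ``volumes`` may be a single :class:`Volume`, a list (interpreted as
    channels of one timepoint) or a list of lists (frames of channels).
    """
    if isinstance(volumes, Volume):
        volumes = [[volumes]]
    elif volumes and isinstance(volumes[0], Volume):
        volumes = [volumes]
    sp = spacing or volumes[0][0].spacing
    data = np.stack([np.stack([np.asarray(v.data) for v in frame]) for frame in volumes])
    # ImageJ axis order TZCYX; we hold TCZYX
    data = np.moveaxis(data, 2, 1)
    tifffile.imwrite(
        path, data, imagej=True,
        resolution=(1.0 / sp[2], 1.0 / sp[1]),
        metadata={"spacing": sp[0], "unit": "um", "axes": "TZCYX"},
    )


def read_stack(path, spacing=None) -> list[list[Volume]]:
    """Read a TIFF stack into per-frame, per-channel volumes.

    Axis order is normalised to ``(t, c, z, y, x)``.  Spacing comes from
    ImageJ metadata (z) and the resolution tags (y, x) unless overridden;
    missing spacing without an override is an error.
    """
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        axes = series.axes
        data = series.asarray()
        meta = tf.imagej_metadata or {}
        if spacing is None:
            try:
                page = tf.pages[0]
                xres = page.tags["XResolution"].value
                yres = page.tags["YResolution"].value
                sx = xres[1] / xres[0]
                sy = yres[1] / yres[0]
                sz = float(meta["spacing"])
                spacing = (sz, sy, sx)
            except (KeyError, ZeroDivisionError) as exc:
                raise FormatError(
                    f"no voxel spacing in {path!s} and no override given") from exc
    # generic page axes (Q/I) mean "a plain page stack": read as Z; S is samples
    if "Z" not in axes:
        axes = axes.replace("Q", "Z", 1).replace("I", "Z", 1)
    if "C" not in axes:
        axes = axes.replace("S", "C", 1)
    order = {"T": 0, "C": 1, "Z": 2, "Y": 3, "X": 4}
    unknown = [a for a in axes if a not in order]
    if unknown:
        raise FormatError(f"ambiguous TIFF axes {axes!r} in {path!s}")
    full = data.reshape(data.shape + (1,) * (5 - data.ndim)) if data.ndim < 5 else data
    # insert missing axes in canonical spots
    expanded = data
    for a in "TCZYX":
        if a not in axes:
            expanded = np.expand_dims(expanded, axis=0)
            axes = a + axes
    perm = [axes.index(a) for a in "TCZYX"]
    expanded = np.transpose(expanded, perm)
    del full
    out = []
    for t in range(expanded.shape[0]):
        out.append([Volume(expanded[t, c], spacing) for c in range(expanded.shape[1])])
    return out


# ---------------------------------------------------------------------------
# meshes


def save_mesh(path, mesh: TriMesh, fmt: str | None = None, binary: bool = True) -> None:
    """Write a mesh as PLY (default) or OBJ.

    PLY carries ``instance_id`` and ``frame_index`` as comment lines and
    stores vertices in (x, y, z) order for interoperability.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower() or "ply"
    verts_xyz = mesh.vertices[:, ::-1]  # (z,y,x) -> (x,y,z)
    if fmt == "obj":
        tm = _trimesh.Trimesh(vertices=verts_xyz, faces=mesh.faces, process=False)
        path.write_text(tm.export(file_type="obj"))
        return
    if fmt != "ply":
        raise FormatError(f"unsupported mesh format {fmt!r}")
    v = np.ascontiguousarray(verts_xyz, dtype="<f4")
    f = np.ascontiguousarray(mesh.faces, dtype="<i4")
    header = [
        "ply",
        "format binary_little_endian 1.0" if binary else "format ascii 1.0",
        f"comment instance_id {mesh.instance_id}",
        f"comment frame_index {mesh.frame_index}",
        f"element vertex {len(v)}",
        "property float x", "property float y", "property float z",
        f"element face {len(f)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(v.tobytes())
            counts = np.full((len(f), 1), 3, dtype="<u1")
            rows = b"".join(struct.pack("<B3i", 3, *row) for row in f)
            fh.write(rows)
        else:
            for row in v:
                fh.write(f"{row[0]:.9g} {row[1]:.9g} {row[2]:.9g}\n".encode())
            for row in f:
                fh.write(f"3 {row[0]} {row[1]} {row[2]}\n".encode())


def load_mesh(path) -> TriMesh:
    """Read a PLY or OBJ mesh written by :func:`save_mesh`."""
    path = Path(path)
    instance_id = 0
    frame_index = 0
    if path.suffix.lower() == ".ply":
        with open(path, "rb") as fh:
            header = []
            while True:
                line = fh.readline().decode("ascii").strip()
                header.append(line)
                if line == "end_header":
                    break
            n_vert = n_face = 0
            binary = any("binary_little_endian" in l for l in header)
            for line in header:
                parts = line.split()
                if line.startswith("comment instance_id"):
                    instance_id = int(parts[-1])
                elif line.startswith("comment frame_index"):
                    frame_index = int(parts[-1])
                elif line.startswith("element vertex"):
                    n_vert = int(parts[-1])
                elif line.startswith("element face"):
                    n_face = int(parts[-1])
            if binary:
                v = np.frombuffer(fh.read(12 * n_vert), dtype="<f4").reshape(n_vert, 3)
                faces = np.empty((n_face, 3), dtype=np.int64)
                raw = fh.read(13 * n_face)
                for i in range(n_face):
                    cnt, a, b, c = struct.unpack_from("<B3i", raw, 13 * i)
                    if cnt != 3:
                        raise FormatError("only triangle faces are supported")
                    faces[i] = (a, b, c)
            else:
                text = fh.read().decode("ascii").split()
                v = np.array(text[:3 * n_vert], dtype=float).reshape(n_vert, 3)
                rest = text[3 * n_vert:]
                faces = []
                pos = 0
                for _ in range(n_face):
                    cnt = int(rest[pos])
                    faces.append([int(x) for x in rest[pos + 1:pos + 1 + cnt]])
                    pos += 1 + cnt
                faces = np.asarray(faces, dtype=np.int64)
        verts = np.asarray(v, dtype=float)[:, ::-1]  # (x,y,z) -> (z,y,x)
        return TriMesh(verts, faces, frame_index=frame_index, instance_id=instance_id)
    tm = _trimesh.load(path, process=False)
    return TriMesh(np.asarray(tm.vertices)[:, ::-1], np.asarray(tm.faces, dtype=np.int64))


# ---------------------------------------------------------------------------
# labels


def export_label_volume(meshes: list[TriMesh], grid: Volume) -> Volume:
    """Integer label image: each mesh voxelized with its instance id.

    Later meshes overwrite earlier ones on (rare) overlapping voxels.
    """
    out = np.zeros(grid.shape, dtype=np.uint16)
    for mesh in meshes:
        m = binarize(mesh, grid).data.astype(bool)
        out[m] = mesh.instance_id
    return grid.like(out)


def save_labels(path, triplet: LabelTriplet) -> None:
    """Three-channel float TIFF in fixed order (mask, border, dt)."""
    stack = np.stack([
        np.asarray(triplet.mask.data, dtype=np.float32),
        np.asarray(triplet.border.data, dtype=np.float32),
        np.asarray(triplet.dt.data, dtype=np.float32),
    ])
    write_stack(path, [[Volume(c, triplet.mask.spacing) for c in stack]])


# ---------------------------------------------------------------------------
# tracks


def tracks_to_csv(path, tracks: list[Track]) -> None:
    import pandas as pd

    rows = []
    for tr in tracks:
        for f, iid, c in zip(tr.frames, tr.instance_ids, tr.centroids):
            rows.append(dict(track_id=tr.track_id, parent_track_id=tr.parent_track_id,
                             frame=f, instance_id=iid, z=c[0], y=c[1], x=c[2]))
    pd.DataFrame(rows).to_csv(path, index=False)


def tracks_to_trackmate_xml(path, tracks: list[Track]) -> None:
    """Simplified TrackMate-style export: spots in frames plus edges.

    A documented subset of the schema — enough for downstream track
    viewers expecting ``Model/AllSpots/SpotsInFrame/Spot`` and
    ``Model/AllTracks/Track/Edge`` elements.
    """
    root = ET.Element("TrackMate", version="7")
    model = ET.SubElement(root, "Model", spatialunits="um", timeunits="frame")
    allspots = ET.SubElement(model, "AllSpots")
    frames: dict[int, ET.Element] = {}
    spot_ids: dict[tuple[int, int], int] = {}
    sid = 0
    for tr in tracks:
        for k, (f, c) in enumerate(zip(tr.frames, tr.centroids)):
            if f not in frames:
                frames[f] = ET.SubElement(allspots, "SpotsInFrame", frame=str(f))
            ET.SubElement(frames[f], "Spot", ID=str(sid), name=f"track{tr.track_id}",
                          FRAME=str(f), POSITION_X=f"{c[2]:.6g}",
                          POSITION_Y=f"{c[1]:.6g}", POSITION_Z=f"{c[0]:.6g}")
            spot_ids[(tr.track_id, k)] = sid
            sid += 1
    alltracks = ET.SubElement(model, "AllTracks")
    for tr in tracks:
        tel = ET.SubElement(alltracks, "Track", TRACK_ID=str(tr.track_id),
                            name=f"track{tr.track_id}")
        for k in range(1, len(tr.frames)):
            ET.SubElement(tel, "Edge",
                          SPOT_SOURCE_ID=str(spot_ids[(tr.track_id, k - 1)]),
                          SPOT_TARGET_ID=str(spot_ids[(tr.track_id, k)]))
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")
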