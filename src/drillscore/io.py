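"""Volume and mesh I/O.

Volumes round-trip as NRRD (detached minimal NRRD0004 dialect, raw
little-endian encoding), NIfTI (via nibabel, ``.nii``/``.nii.gz``), or a raw
binary + JSON sidecar pair (``.raw`` with ``<stem>.json`` holding shape,
spacing, origin and byte order).  Masks are stored as uint8 (0/1); shape,
spacing (cm) and origin (cm, voxel-(0,0,0) center) survive bit-exactly.
Meshes are written as binary little-endian PLY or as OBJ through trimesh.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh

from .volume import VoxelGrid

__all__ = ["read_volume", "write_volume", "write_mesh"]


class VolumeIOError(IOError):
    """Unreadable, truncated or inconsistent volume file."""


# ---------------------------------------------------------------------------
# NRRD (minimal hand-rolled dialect: NRRD0004, raw encoding, little endian)


def _write_nrrd(grid: VoxelGrid, path: Path) -> None:
    dirs = " ".join(
        "(" + ",".join(repr(grid.spacing[a] if i == a else 0.0) for i in range(3)) + ")"
        for a in range(3)
    )
    header = (
        "NRRD0004\n"
        "type: uint8\n"
        "dimension: 3\n"
        "space: left-posterior-superior\n"
        f"sizes: {grid.shape[0]} {grid.shape[1]} {grid.shape[2]}\n"
        f"space directions: {dirs}\n"
        "kinds: domain domain domain\n"
        "endian: little\n"
        "encoding: raw\n"
        f"space origin: ({grid.origin[0]},{grid.origin[1]},{grid.origin[2]})\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(grid.mask.astype(np.uint8)).tobytes())


def _parse_vectors(text: str) -> list[list[float]]:
    vecs = []
    for part in text.replace("(", " ").split(")"):
        part = part.strip().strip(",")
        if part:
            vecs.append([float(v) for v in part.replace(",", " ").split()])
    return vecs


def _read_nrrd(path: Path) -> VoxelGrid:
    with open(path, "rb") as fh:
        data = fh.read()
    if not data.startswith(b"NRRD"):
        raise VolumeIOError(f"{path}: not an NRRD file")
    try:
        head, body = data.split(b"\n\n", 1)
    except ValueError:
        raise VolumeIOError(f"{path}: truncated NRRD header") from None
    fields = {}
    for line in head.decode("ascii", "replace").splitlines()[1:]:
        if ":" in line and not line.startswith("#"):
            k, v = line.split(":", 1)
            fields[k.strip()] = v.strip()
    if fields.get("encoding") != "raw" or fields.get("type") not in ("uint8", "uchar"):
        raise VolumeIOError(f"{path}: only raw uint8 NRRD is supported")
    shape = tuple(int(s) for s in fields["sizes"].split())
    spacing = tuple(v[a] for a, v in enumerate(_parse_vectors(fields["space directions"])))
    origin = tuple(_parse_vectors(fields.get("space origin", "(0,0,0)"))[0])
    n = int(np.prod(shape))
    if len(body) < n:
        raise VolumeIOError(f"{path}: truncated NRRD data ({len(body)} < {n} bytes)")
    mask = np.frombuffer(body[:n], dtype=np.uint8).reshape(shape).astype(bool)
    return VoxelGrid(mask, spacing, origin)


# ---------------------------------------------------------------------------
# NIfTI


def _write_nifti(grid: VoxelGrid, path: Path) -> None:
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(grid.mask.astype(np.uint8), affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def _read_nifti(path: Path) -> VoxelGrid:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3D NIfTI volume, got ndim={data.ndim}")
    affine = img.affine
    spacing = tuple(float(abs(affine[a, a])) for a in range(3))
    origin = tuple(float(affine[a, 3]) for a in range(3))
    return VoxelGrid(data.astype(bool), spacing, origin)


# ---------------------------------------------------------------------------
# raw + JSON sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_raw(grid: VoxelGrid, path: Path) -> None:
    with open(path, "wb") as fh:
        fh.write(np.ascontiguousarray(grid.mask.astype(np.uint8)).tobytes())
    meta = {
        "shape": list(grid.shape),
        "spacing_cm": list(grid.spacing),
        "origin_cm": list(grid.origin),
        "dtype": "uint8",
        "byte_order": "little",
        "order": "C",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_raw(path: Path) -> VoxelGrid:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise VolumeIOError(f"{path}: missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    shape = tuple(meta["shape"])
    data = path.read_bytes()
    n = int(np.prod(shape))
    if len(data) != n:
        raise VolumeIOError(f"{path}: raw size {len(data)} does not match shape {shape}")
    mask = np.frombuffer(data, dtype=np.uint8).reshape(shape).astype(bool)
    return VoxelGrid(mask, tuple(meta["spacing_cm"]), tuple(meta["origin_cm"]))


# ---------------------------------------------------------------------------
# dispatch


def _format_of(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nrrd"):
        return "nrrd"
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    if name.endswith(".raw"):
        return "raw"
    raise VolumeIOError(f"{path}: unsupported volume format (use .nrrd, .nii[.gz] or .raw)")


def write_volume(grid: VoxelGrid, path) -> None:
    """Write a VoxelGrid; the format is chosen from the file extension."""
    path = Path(path)
    {"nrrd": _write_nrrd, "nifti": _write_nifti, "raw": _write_raw}[_format_of(path)](grid, path)


def read_volume(path) -> VoxelGrid:
    """Read a VoxelGrid; write-then-read round-trips mask/shape/spacing/origin bit-exactly."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"{path}: no such file")
    try:
        return {"nrrd": _read_nrrd, "nifti": _read_nifti, "raw": _read_raw}[_format_of(path)](path)
    except (ValueError, KeyError, OSError, gzip.BadGzipFile) as exc:
        if isinstance(exc, VolumeIOError):
            raise
        raise VolumeIOError(f"{path}: failed to read volume ({exc})") from exc


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    """Write a triangle mesh as binary little-endian PLY or as OBJ."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".ply":
        path.write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="binary_little_endian"))
    elif ext == ".obj":
        path.write_text(trimesh.exchange.obj.export_obj(mesh))
    else:
        raise VolumeIOError(f"{path}: unsupported mesh format (use .ply or .obj)")
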