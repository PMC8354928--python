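"""Reading, writing and resampling of surface scans.

A scanned cut mark (or its silicone cast) is handled as a :class:`HeightMap`:
a regular grid of surface heights in µm. Rows run along the cut direction,
so each row is one cross-section signal through the striation pattern;
columns form the profile axis.

Supported formats:

* ``grid-text`` — plain delimited floats, one grid row per line, with
  ``#``-prefixed header lines carrying ``dx``, ``dy``, ``kind`` and
  ``label``. Human-inspectable; exact decimal round trip.
* ``stl`` — binary or ASCII triangulated surface, resampled onto a regular
  grid by linear interpolation within the containing triangle.
* ``raster16`` — single-channel 16-bit PNG with a height scale (µm per
  count) and offset stored in the PNG text chunk.

Grayscale microscope-style images for contrast analysis are 8-bit PNG/
array data handled by :func:`read_image` / :func:`write_image`.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image as PILImage
from PIL.PngImagePlugin import PngInfo

from .config import DEFAULT_DX_UM, DEFAULT_DY_UM
from .exceptions import FormatError, GeometryError, ValidationError

__all__ = [
    "HeightMap",
    "Image",
    "read_heightmap",
    "write_heightmap",
    "resample_mesh_to_grid",
    "invert_scan",
    "read_image",
    "write_image",
]


@dataclass
class HeightMap:
    """Regular grid of surface heights.

    Parameters
    ----------
    z : ndarray, shape (S, P)
        Heights in µm; rows along the cut direction, columns across it.
    dx, dy : float
        Column and row spacing in µm.
    kind : {"cast", "direct-scan"}
        Whether the grid represents a cast (mirrored negative of the
        surface) or a direct scan.
    label : str
        Free-text mark identifier.
    """

    z: np.ndarray
    dx: float = DEFAULT_DX_UM
    dy: float = DEFAULT_DY_UM
    kind: str = "cast"
    label: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2:
            raise ValidationError(f"height grid must be 2-D, got ndim={self.z.ndim}")
        s, p = self.z.shape
        if s < 2 or p < 2:
            raise ValidationError(f"height grid must be at least 2x2, got {s}x{p}")
        if not np.all(np.isfinite(self.z)):
            raise ValidationError("height grid contains non-finite values")
        if self.dx <= 0 or self.dy <= 0:
            raise ValidationError("grid spacings dx, dy must be positive")
        if self.kind not in ("cast", "direct-scan"):
            raise ValidationError(f"unknown heightmap kind {self.kind!r}")

    @property
    def n_rows(self) -> int:
        return self.z.shape[0]

    @property
    def n_cols(self) -> int:
        return self.z.shape[1]


@dataclass
class Image:
    """Grayscale image with integer brightness values in [0, 255]."""

    b: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.b)
        if b.ndim != 2:
            raise ValidationError("image must be 2-D")
        if b.size == 0:
            raise ValidationError("image is empty")
        if np.any((b < 0) | (b > 255)):
            raise ValidationError("brightness values must lie in [0, 255]")
        self.b = b.astype(np.uint8)

    @property
    def n_pixels(self) -> int:
        return self.b.size


# ---------------------------------------------------------------------------
# grid-text dialect

def _write_grid_text(hm: HeightMap, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# striamark heightmap\n")
        fh.write(f"# dx {hm.dx!r}\n")
        fh.write(f"# dy {hm.dy!r}\n")
        fh.write(f"# kind {hm.kind}\n")
        fh.write(f"# label {hm.label}\n")
        for row in hm.z:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_grid_text(path: Path) -> HeightMap:
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.lstrip("#").strip().split(None, 1)
                if len(parts) == 2:
                    meta[parts[0]] = parts[1]
                continue
            try:
                rows.append([float(tok) for tok in line.replace(",", " ").split()])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise FormatError(f"{path}: no data rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        bad = next(i for i, r in enumerate(rows, 1) if len(r) != len(rows[0]))
        raise FormatError(f"{path}: ragged grid (row {bad} differs in length)")
    z = np.array(rows, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValidationError(f"{path}: non-finite heights")
    return HeightMap(
        z,
        dx=float(meta.get("dx", DEFAULT_DX_UM)),
        dy=float(meta.get("dy", DEFAULT_DY_UM)),
        kind=meta.get("kind", "cast"),
        label=meta.get("label", ""),
    )


# ---------------------------------------------------------------------------
# raster16 dialect — 16-bit PNG plus metadata text chunk

def _write_raster16(hm: HeightMap, path: Path, scale: float) -> None:
    if scale <= 0:
        raise ValidationError("raster16 height scale must be positive")
    offset = float(hm.z.min())
    counts = np.round((hm.z - offset) / scale)
    if counts.max() > 65535:
        raise ValidationError(
            "height range exceeds 16-bit raster capacity at this scale"
        )
    info = PngInfo()
    for key, value in (
        ("dx", repr(hm.dx)),
        ("dy", repr(hm.dy)),
        ("kind", hm.kind),
        ("label", hm.label),
        ("scale", repr(scale)),
        ("offset", repr(offset)),
    ):
        info.add_text(f"striamark:{key}", value)
    PILImage.fromarray(counts.astype(np.uint16)).save(path, pnginfo=info)


def _read_raster16(path: Path, scale: float | None) -> HeightMap:
    img = PILImage.open(path)
    text = {k.removeprefix("striamark:"): v for k, v in getattr(img, "text", {}).items()}
    if scale is None:
        if "scale" not in text:
            raise FormatError(
                f"{path}: raster16 requires a height scale (none stored, none given)"
            )
        scale = float(text["scale"])
    offset = float(text.get("offset", 0.0))
    counts = np.asarray(img, dtype=float)
    if counts.ndim != 2:
        raise FormatError(f"{path}: raster16 must be single-channel")
    z = counts * scale + offset
    return HeightMap(
        z,
        dx=float(text.get("dx", DEFAULT_DX_UM)),
        dy=float(text.get("dy", DEFAULT_DY_UM)),
        kind=text.get("kind", "cast"),
        label=text.get("label", ""),
    )


# ---------------------------------------------------------------------------
# public API

def read_heightmap(
    path,
    format: str = "grid-text",
    *,
    dx: float = DEFAULT_DX_UM,
    dy: float = DEFAULT_DY_UM,
    scale: float | None = None,
) -> HeightMap:
    """Read a surface scan into a :class:`HeightMap`.

    Parameters
    ----------
    path : path-like
        Input file.
    format : {"grid-text", "stl", "raster16"}
        File dialect. ``stl`` meshes are resampled at spacing ``dx``/``dy``;
        ``raster16`` needs a height ``scale`` (µm per count) unless one is
        stored in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if format == "grid-text":
        return _read_grid_text(path)
    if format == "raster16":
        return _read_raster16(path, scale)
    if format == "stl":
        import trimesh

        mesh = trimesh.load(str(path), file_type="stl", process=False)
        mesh.merge_vertices()  # STL stores a triangle soup; re-share vertices
        return resample_mesh_to_grid(mesh, dx=dx, dy=dy)
    raise FormatError(f"unknown heightmap format {format!r}")


def write_heightmap(hm: HeightMap, path, format: str = "grid-text", *, scale: float = 0.01) -> None:
    """Write a :class:`HeightMap` so that :func:`read_heightmap` recovers it.

    ``grid-text`` round-trips exactly; ``raster16`` quantizes to
    ``scale`` µm per count (worst-case error ``scale / 2``).
    """
    if not isinstance(hm, HeightMap):
        raise ValidationError("write_heightmap expects a HeightMap")
    path = Path(path)
    try:
        if format == "grid-text":
            _write_grid_text(hm, path)
        elif format == "raster16":
            _write_raster16(hm, path, scale)
        else:
            raise FormatError(f"unknown heightmap format {format!r}")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def resample_mesh_to_grid(mesh, dx: float = DEFAULT_DX_UM, dy: float = DEFAULT_DY_UM) -> HeightMap:
    """Resample a triangulated surface onto a regular height grid.

    The mesh must project one-to-one onto the x–y plane. Heights are
    linearly interpolated within the containing triangle (exact for any
    affine surface). Grid nodes outside the mesh footprint are invalid and
    trimmed away, keeping the largest full rectangle (greedy border peel).
    """
    from matplotlib.tri import LinearTriInterpolator, Triangulation

    vertices = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=int)
    if vertices.shape[0] < 3 or faces.shape[0] < 1:
        raise GeometryError("mesh has too few vertices or faces")

    # A folded/multivalued surface projects some faces with flipped
    # orientation; a degenerate projection collapses faces to zero area.
    v0, v1, v2 = (vertices[faces[:, k], :2] for k in range(3))
    e1, e2 = v1 - v0, v2 - v0
    areas2 = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    span = max(np.ptp(vertices[:, 0]), np.ptp(vertices[:, 1]))
    tiny = 1e-12 * max(span, 1.0) ** 2
    if np.any(np.abs(areas2) < tiny):
        raise GeometryError("mesh contains faces degenerate in x-y projection")
    if np.any(areas2 > 0) and np.any(areas2 < 0):
        raise GeometryError("mesh is folded: projected faces overlap")

    tri = Triangulation(vertices[:, 0], vertices[:, 1], faces)
    interp = LinearTriInterpolator(tri, vertices[:, 2])

    x0, x1 = vertices[:, 0].min(), vertices[:, 0].max()
    y0, y1 = vertices[:, 1].min(), vertices[:, 1].max()
    xs = x0 + dx * np.arange(int(np.floor((x1 - x0) / dx)) + 1)
    ys = y0 + dy * np.arange(int(np.floor((y1 - y0) / dy)) + 1)
    gx, gy = np.meshgrid(xs, ys)
    z = interp(gx, gy)
    z = np.ma.filled(z, np.nan)

    # Greedy border peel: drop the border line with the most invalid nodes
    # until the remaining rectangle is fully covered.
    r0, r1 = 0, z.shape[0]
    c0, c1 = 0, z.shape[1]
    bad = ~np.isfinite(z)
    while r1 - r0 >= 2 and c1 - c0 >= 2 and bad[r0:r1, c0:c1].any():
        counts = {
            "top": bad[r0, c0:c1].sum(),
            "bottom": bad[r1 - 1, c0:c1].sum(),
            "left": bad[r0:r1, c0].sum(),
            "right": bad[r0:r1, c1 - 1].sum(),
        }
        side = max(counts, key=lambda k: (counts[k], k))
        if counts[side] == 0:
            raise GeometryError("mesh footprint leaves interior holes in the grid")
        if side == "top":
            r0 += 1
        elif side == "bottom":
            r1 -= 1
        elif side == "left":
            c0 += 1
        else:
            c1 -= 1
    z = z[r0:r1, c0:c1]
    if z.shape[0] < 2 or z.shape[1] < 2 or not np.all(np.isfinite(z)):
        raise GeometryError("mesh footprint too small for a 2x2 grid at this spacing")
    return HeightMap(z, dx=dx, dy=dy, kind="direct-scan", label="")


def invert_scan(hm: HeightMap) -> HeightMap:
    """Convert between a surface and its cast.

    A cast is the mirrored negative of the scanned surface: heights are
    negated and the profile (column) axis mirrored. Applying the operation
    twice returns the original grid.
    """
    other = "direct-scan" if hm.kind == "cast" else "cast"
    return replace(hm, z=-hm.z[:, ::-1], kind=other)


def read_image(path) -> Image:
    """Read an 8-bit grayscale raster as an :class:`Image`."""
    img = PILImage.open(path).convert("L")
    return Image(np.asarray(img))


def write_image(img: Image, path) -> None:
    """Write an :class:`Image` as 8-bit grayscale PNG."""
    PILImage.fromarray(img.b, mode="L").save(path)
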