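"""Triangle meshes, STL I/O, rigid transforms and WET ray tracing.

Modulators are tessellated into watertight "wedding cake" shells (one closed
shell per pin, plus the base slab and the wall ring; shells may share faces,
which keeps every shell individually closed and makes the signed volume of
the soup the exact sum of the component volumes).  Misalignment studies
transform either the tessellated STL (MeshLab-style) or the analytic solid
itself; both paths produce an axial heightfield (material path length along
+z per lateral sample) that the dose engine converts to WET.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriangleMesh",
    "RigidTransform",
    "StlFormatError",
    "WetSampleTable",
    "apply_transform",
    "read_stl",
    "write_stl",
    "tessellate",
    "heightfield_of",
    "analytic_heightfield",
    "transformed_heightfield",
    "wet_sample_table",
]


class StlFormatError(ValueError):
    """Malformed STL input; carries the byte offset of the defect."""

    def __init__(self, message: str, byte_offset: int | None = None):
        if byte_offset is not None:
            message = f"{message} (byte offset {byte_offset})"
        super().__init__(message)
        self.byte_offset = byte_offset


@dataclass
class TriangleMesh:
    """Indexed triangle soup in mm with outward-consistent winding."""

    vertices: np.ndarray  # (n, 3) float
    triangles: np.ndarray  # (m, 3) int
    provenance: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_corners(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.triangles]

    def volume(self) -> float:
        """Enclosed volume via the divergence theorem (signed tetrahedra)."""
        c = self.triangle_corners()
        return float(np.einsum("ij,ij->i", c[:, 0],
                               np.cross(c[:, 1], c[:, 2])).sum() / 6.0)

    def is_watertight(self) -> bool:
        """Every undirected edge shared by exactly two triangles, with
        opposite directions (consistent winding)."""
        t = self.triangles
        edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        directed = {}
        for a, b in edges:
            key = (int(a), int(b))
            directed[key] = directed.get(key, 0) + 1
        for (a, b), n in directed.items():
            if n != 1 or directed.get((b, a), 0) != 1:
                return False
        return True

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)


_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about a named axis around a pivot, then a translation.

    Maps v -> R (v - pivot) + pivot + translation.  Positive angles are
    right-handed about the +axis.
    """

    rotation_deg: float = 0.0
    axis: str = "y"
    pivot: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def rotation_matrix(self) -> np.ndarray:
        if self.axis not in _AXES:
            raise ValueError(f"unknown axis {self.axis!r}")
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        i = _AXES[self.axis]
        j, k = (i + 1) % 3, (i + 2) % 3
        r = np.eye(3)
        r[j, j] = c
        r[j, k] = -s
        r[k, j] = s
        r[k, k] = c
        return r

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        pivot = np.asarray(self.pivot)
        return ((p - pivot) @ self.rotation_matrix().T + pivot
                + np.asarray(self.translation))

    def apply_inverse(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        pivot = np.asarray(self.pivot)
        return (p - np.asarray(self.translation) - pivot) @ \
            self.rotation_matrix() + pivot

    @property
    def is_identity(self) -> bool:
        return (self.rotation_deg == 0.0
                and all(t == 0.0 for t in self.translation))


def apply_transform(mesh: TriangleMesh, t: RigidTransform) -> TriangleMesh:
    """Rigidly transform every vertex; triangle topology is untouched."""
    if t.is_identity:
        return TriangleMesh(mesh.vertices.copy(), mesh.triangles.copy(),
                            mesh.provenance)
    return TriangleMesh(t.apply(mesh.vertices), mesh.triangles.copy(),
                        provenance=mesh.provenance + " +transform")


# ---------------------------------------------------------------------------
# STL I/O (binary little-endian and ASCII dialects)

def write_stl(mesh: TriangleMesh, path, dialect: str = "binary") -> None:
    corners = mesh.triangle_corners().astype(np.float32)
    normals = np.cross(corners[:, 1] - corners[:, 0],
                       corners[:, 2] - corners[:, 0])
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.where(norm > 0, normals / np.maximum(norm, 1e-30), 0.0)
    normals = normals.astype(np.float32)

    if dialect == "binary":
        header = (mesh.provenance or "rm3d modulator").encode()[:80]
        header = header.ljust(80, b"\0")
        rec = np.zeros(len(corners),
                       dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)),
                              ("attr", "<u2")])
        rec["n"] = normals
        rec["v"] = corners
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(struct.pack("<I", len(corners)))
            fh.write(rec.tobytes())
    elif dialect == "ascii":
        name = (mesh.provenance or "rm3d").split("\n")[0]
        with open(path, "w") as fh:
            fh.write(f"solid {name}\n")
            for n, tri in zip(normals, corners):
                fh.write(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
                fh.write("    outer loop\n")
                for v in tri:
                    fh.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write(f"endsolid {name}\n")
    else:
        raise ValueError(f"unknown STL dialect {dialect!r}")


def _read_stl_binary(data: bytes, path) -> TriangleMesh:
    if len(data) < 84:
        raise StlFormatError(f"{path}: truncated binary STL header",
                             byte_offset=len(data))
    (count,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * count
    if len(data) != expected:
        raise StlFormatError(
            f"{path}: binary STL promises {count} triangles "
            f"({expected} bytes) but file has {len(data)} bytes",
            byte_offset=min(len(data), expected))
    rec = np.frombuffer(data, offset=84,
                        dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)),
                               ("attr", "<u2")])
    corners = rec["v"].astype(np.float64).reshape(-1, 3)
    tris = np.arange(len(corners)).reshape(-1, 3)
    header = data[:80].rstrip(b"\0").decode(errors="replace")
    return TriangleMesh(corners, tris, provenance=header)


def _read_stl_ascii(data: bytes, path) -> TriangleMesh:
    text = data.decode(errors="replace")
    corners: list[list[float]] = []
    offset = 0
    for line in text.splitlines(keepends=True):
        stripped = line.strip()
        if stripped.startswith("vertex"):
            parts = stripped.split()
            if len(parts) != 4:
                raise StlFormatError(f"{path}: malformed vertex line",
                                     byte_offset=offset)
            try:
                corners.append([float(p) for p in parts[1:]])
            except ValueError:
                raise StlFormatError(f"{path}: non-numeric vertex",
                                     byte_offset=offset) from None
        offset += len(line)
    if len(corners) == 0 or len(corners) % 3 != 0:
        raise StlFormatError(
            f"{path}: ASCII STL with {len(corners)} vertex lines "
            "(not a multiple of 3)", byte_offset=offset)
    v = np.asarray(corners)
    name = text.splitlines()[0].removeprefix("solid").strip() if text else ""
    return TriangleMesh(v, np.arange(len(v)).reshape(-1, 3), provenance=name)


def read_stl(path) -> TriangleMesh:
    """Read either STL dialect; vertices are exact at float32 precision."""
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) >= 84:
        (count,) = struct.unpack_from("<I", data, 80)
        if len(data) == 84 + 50 * count:
            return _read_stl_binary(data, path)
    if data[:5].lower() == b"solid":
        return _read_stl_ascii(data, path)
    return _read_stl_binary(data, path)


# ---------------------------------------------------------------------------
# Tessellation of modulators

def _box_shell(x0, x1, y0, y1, z0, z1) -> tuple[np.ndarray, np.ndarray]:
    """Closed axis-aligned box with outward winding."""
    v = np.array([[x0, y0, z0], [x1, y0, z0], [x1, y1, z0], [x0, y1, z0],
                  [x0, y0, z1], [x1, y0, z1], [x1, y1, z1], [x0, y1, z1]],
                 dtype=float)
    t = np.array([
        [0, 2, 1], [0, 3, 2],          # bottom (-z)
        [4, 5, 6], [4, 6, 7],          # top (+z)
        [0, 1, 5], [0, 5, 4],          # -y
        [2, 3, 7], [2, 7, 6],          # +y
        [1, 2, 6], [1, 6, 5],          # +x
        [3, 0, 4], [3, 4, 7],          # -x
    ])
    return v, t


def _ring_quad(vertices, tris, quad, flip=False):
    a, b, c, d = quad
    if flip:
        tris.extend([[a, c, b], [a, d, c]])
    else:
        tris.extend([[a, b, c], [a, c, d]])


def _cake_shell(cx, cy, z_base, half_widths, heights):
    """Closed stacked-prism pin shell.

    ``half_widths`` are the outer half-widths of the square tiers from the
    widest (bottom) inward, ``heights`` the corresponding tier top heights
    above ``z_base`` (ascending).  Returns (vertices, triangles).
    """
    verts: list[list[float]] = []
    tris: list[list[int]] = []

    def square(hw, z):
        i0 = len(verts)
        verts.extend([[cx - hw, cy - hw, z], [cx + hw, cy - hw, z],
                      [cx + hw, cy + hw, z], [cx - hw, cy + hw, z]])
        return [i0, i0 + 1, i0 + 2, i0 + 3]

    bottom = square(half_widths[0], z_base)
    # bottom face (facing -z)
    tris.extend([[bottom[0], bottom[2], bottom[1]],
                 [bottom[0], bottom[3], bottom[2]]])
    lower = bottom
    for k in range(len(half_widths)):
        hw = half_widths[k]
        top_outer = square(hw, z_base + heights[k])
        # side walls between lower ring and this tier top
        for e in range(4):
            a, b = lower[e], lower[(e + 1) % 4]
            c, d = top_outer[(e + 1) % 4], top_outer[e]
            tris.extend([[a, b, c], [a, c, d]])
        if k + 1 < len(half_widths):
            inner = square(half_widths[k + 1], z_base + heights[k])
            # annulus facing +z between outer and inner squares
            for e in range(4):
                a, b = top_outer[e], top_outer[(e + 1) % 4]
                c, d = inner[(e + 1) % 4], inner[e]
                tris.extend([[a, b, d], [b, c, d]])
            lower = inner
        else:
            # tip cap
            tris.extend([[top_outer[0], top_outer[1], top_outer[2]],
                         [top_outer[0], top_outer[2], top_outer[3]]])
    return np.asarray(verts, dtype=float), np.asarray(tris, dtype=np.int64)


def tessellate(modulator, tolerance_mm: float = 0.1) -> TriangleMesh:
    """Tessellate a modulator into a watertight multi-shell triangle mesh.

    Step pins are tessellated exactly; stepless profiles are quantized into
    tiers no taller than ``tolerance_mm``.  The enclosed volume matches the
    analytic volume to well within 0.5%.
    """
    all_v: list[np.ndarray] = []
    all_t: list[np.ndarray] = []
    offset = 0

    def add(v, t):
        nonlocal offset
        all_v.append(v)
        all_t.append(np.asarray(t) + offset)
        offset += len(v)

    (x0, y0), (x1, y1) = modulator.footprint_bounds()
    if modulator.base_layer_mm > 0:
        add(*_box_shell(x0, x1, y0, y1, 0.0, modulator.base_layer_mm))

    a = modulator.period_mm
    for (i, j), placed in modulator.pins.items():
        cx, cy = modulator.cell_center(i, j)
        hw, hh = _pin_tiers(placed, a, tolerance_mm)
        if len(hw) == 0:
            continue
        add(*_cake_shell(cx, cy, modulator.base_layer_mm, hw, hh))

    wt = modulator.wall_thickness_mm
    if wt > 0:
        wh = modulator.wall_height_mm
        z1 = modulator.base_layer_mm + wh
        # four closed wall boxes around the footprint, sitting on the base
        # extension (their own footprints extend the base outward)
        add(*_box_shell(x0 - wt, x1 + wt, y0 - wt, y0, 0.0, z1))
        add(*_box_shell(x0 - wt, x1 + wt, y1, y1 + wt, 0.0, z1))
        add(*_box_shell(x0 - wt, x0, y0, y1, 0.0, z1))
        add(*_box_shell(x1, x1 + wt, y0, y1, 0.0, z1))

    return TriangleMesh(np.concatenate(all_v), np.concatenate(all_t),
                        provenance="rm3d tessellated modulator")


def _pin_tiers(placed, period: float, tolerance_mm: float):
    """Tier half-widths (descending) and top heights (ascending) of a pin."""
    pin = placed.contour
    extra = placed.extra_height_mm
    if pin.kind == "step":
        # levels stored tip first (heights descending)
        h_desc = pin.levels_height_mm + extra
        area_geq_desc = np.cumsum(pin.levels_area_fraction)
    else:
        n = max(2, int(np.ceil(pin.max_height / max(tolerance_mm, 1e-3))))
        c = np.linspace(0.0, 1.0, n + 1)
        h_desc = pin.height_at_cum_area(0.5 * (c[:-1] + c[1:])) + extra
        area_geq_desc = c[1:]
    heights = h_desc[::-1]           # ascending, bottom tier first
    areas = area_geq_desc[::-1]      # area fraction with height >= tier
    keep = heights > 1e-9
    heights, areas = heights[keep], areas[keep]
    if len(heights) == 0:
        return np.empty(0), np.empty(0)
    # merge tiers with equal heights, keeping the outermost extent
    uh, inv = np.unique(np.round(heights, 9), return_inverse=True)
    ua = np.array([areas[inv == k].max() for k in range(len(uh))])
    half_widths = 0.5 * period * np.sqrt(ua)
    return half_widths, uh


def _analytic_volume(modulator) -> float:
    """Exact solid volume of a modulator (base + pins + walls)."""
    (x0, y0), (x1, y1) = modulator.footprint_bounds()
    vol = (x1 - x0) * (y1 - y0) * modulator.base_layer_mm
    cell = modulator.period_mm**2
    for placed in modulator.pins.values():
        pin = placed.contour
        if pin.kind == "step":
            mean_h = float(np.dot(pin.levels_height_mm,
                                  pin.levels_area_fraction))
        else:
            mean_h = float(np.trapezoid(pin.profile_height_mm,
                                        pin.profile_cum_area))
        mean_h += placed.extra_height_mm
        vol += cell * mean_h
    wt = modulator.wall_thickness_mm
    if wt > 0:
        z1 = modulator.base_layer_mm + modulator.wall_height_mm
        vol += 2 * wt * ((x1 - x0 + 2 * wt) + (y1 - y0)) * z1
    return vol


# ---------------------------------------------------------------------------
# Heightfields (material path length along +z per lateral sample)

def analytic_heightfield(modulator, lateral_resolution_mm: float = 0.25,
                         pad_mm: float = 0.0):
    """Exact axial heightfield of an untransformed modulator.

    Samples are offset half a step from cell boundaries (tie-break away from
    step edges).  Returns (x_centers, y_centers, heights).
    """
    (x0, y0), (x1, y1) = modulator.footprint_bounds()
    wt = modulator.wall_thickness_mm + pad_mm
    res = lateral_resolution_mm
    xs = np.arange(x0 - wt + res / 2, x1 + wt, res)
    ys = np.arange(y0 - wt + res / 2, y1 + wt, res)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    h = modulator.column_height(gx.ravel(), gy.ravel()).reshape(gx.shape)
    return xs, ys, h


def heightfield_of(obj, lateral_resolution_mm: float = 0.25,
                   transform: RigidTransform | None = None,
                   z_step_mm: float = 0.25):
    """Axial material path length per lateral sample.

    For a modulator this is analytic (or analytic-solid ray integration when
    a transform is given); for a :class:`TriangleMesh` it ray-casts axial
    rays against the triangles and accumulates signed crossings.
    """
    if isinstance(obj, TriangleMesh):
        return _mesh_heightfield(obj, lateral_resolution_mm)
    if transform is None or transform.is_identity:
        return analytic_heightfield(obj, lateral_resolution_mm)
    return transformed_heightfield(obj, transform, lateral_resolution_mm,
                                   z_step_mm)


def _mesh_heightfield(mesh: TriangleMesh, res: float):
    """Ray-cast heightfield of a (closed) mesh on a lateral grid.

    Accumulates z-crossing depths weighted by facet orientation: the path
    length along +z equals sum(z_exit) - sum(z_entry).  Grazing hits are
    stabilized by the half-sample grid offset plus an epsilon nudge.
    """
    if not mesh.is_watertight():
        raise ValueError("heightfield requires a watertight mesh")
    lo, hi = mesh.bounds()
    # different nudges per axis keep rays off shared triangle edges (the
    # square faces are split along their diagonals)
    xs = np.arange(lo[0] + res / 2, hi[0], res) + 1e-6
    ys = np.arange(lo[1] + res / 2, hi[1], res) + 2.618e-6
    acc = np.zeros((xs.size, ys.size))

    corners = mesh.triangle_corners()
    for tri in corners:
        txmin, tymin = tri[:, 0].min(), tri[:, 1].min()
        txmax, tymax = tri[:, 0].max(), tri[:, 1].max()
        i0 = np.searchsorted(xs, txmin)
        i1 = np.searchsorted(xs, txmax, side="right")
        j0 = np.searchsorted(ys, tymin)
        j1 = np.searchsorted(ys, tymax, side="right")
        if i0 >= i1 or j0 >= j1:
            continue
        px, py = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
        d1 = tri[1, :2] - tri[0, :2]
        d2 = tri[2, :2] - tri[0, :2]
        det = d1[0] * d2[1] - d1[1] * d2[0]
        if abs(det) < 1e-12:  # vertical facet: never crossed by axial rays
            continue
        rx = px - tri[0, 0]
        ry = py - tri[0, 1]
        u = (rx * d2[1] - ry * d2[0]) / det
        v = (ry * d1[0] - rx * d1[1]) / det
        inside = (u >= 0) & (v >= 0) & (u + v <= 1)
        if not inside.any():
            continue
        z_hit = tri[0, 2] + u * (tri[1, 2] - tri[0, 2]) \
            + v * (tri[2, 2] - tri[0, 2])
        # det > 0 means the facet normal points along +z (exit face)
        acc[i0:i1, j0:j1] += np.where(inside, np.sign(det) * z_hit, 0.0)
    return xs, ys, np.maximum(acc, 0.0)


def transformed_heightfield(modulator, transform: RigidTransform,
                            lateral_resolution_mm: float = 0.5,
                            z_step_mm: float = 0.25,
                            fine_resolution_mm: float = 0.25,
                            pad_mm: float = 6.0):
    """Heightfield of a rigidly transformed modulator by solid ray casting.

    Lab-frame axial rays are sampled along z and tested against the analytic
    solid in the modulator's own frame (inverse transform + heightfield
    occupancy), which is the exact rigid-body operation without tessellation
    error.  The returned heights are in the lab frame; the caller places the
    modulator's own z = 0 plane in the scene.
    """
    fxs, fys, fh = analytic_heightfield(modulator, fine_resolution_mm)
    top = fh  # full column top in own frame (column_height includes base)
    (x0, y0), (x1, y1) = modulator.footprint_bounds()
    wt = modulator.wall_thickness_mm

    res = lateral_resolution_mm
    xs = np.arange(x0 - wt - pad_mm + res / 2, x1 + wt + pad_mm, res)
    ys = np.arange(y0 - wt - pad_mm + res / 2, y1 + wt + pad_mm, res)

    # z range in the lab frame from the transformed bounding box
    zmax_own = float(top.max())
    corners = np.array([(xc, yc, zc)
                        for xc in (x0 - wt, x1 + wt)
                        for yc in (y0 - wt, y1 + wt)
                        for zc in (0.0, zmax_own)])
    zlab = transform.apply(corners)[:, 2]
    z_lo, z_hi = zlab.min() - z_step_mm, zlab.max() + z_step_mm
    zs = np.arange(z_lo + z_step_mm / 2, z_hi, z_step_mm)

    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts_xy = np.stack([gx.ravel(), gy.ravel()], axis=1)
    acc = np.zeros(pts_xy.shape[0])

    fx0 = fxs[0] - fine_resolution_mm / 2
    fy0 = fys[0] - fine_resolution_mm / 2
    chunk = max(1, int(4e6 / max(pts_xy.shape[0], 1)))
    for k0 in range(0, zs.size, chunk):
        zc = zs[k0:k0 + chunk]
        p = np.empty((pts_xy.shape[0], zc.size, 3))
        p[:, :, 0] = pts_xy[:, 0:1]
        p[:, :, 1] = pts_xy[:, 1:2]
        p[:, :, 2] = zc[None, :]
        own = transform.apply_inverse(p.reshape(-1, 3))
        ix = np.floor((own[:, 0] - fx0) / fine_resolution_mm).astype(int)
        iy = np.floor((own[:, 1] - fy0) / fine_resolution_mm).astype(int)
        ok = ((ix >= 0) & (ix < fxs.size) & (iy >= 0) & (iy < fys.size)
              & (own[:, 2] >= 0.0))
        col_top = np.zeros(own.shape[0])
        col_top[ok] = top[ix[ok], iy[ok]]
        inside = ok & (own[:, 2] <= col_top)
        acc += inside.reshape(pts_xy.shape[0], zc.size).sum(axis=1) * z_step_mm
    return xs, ys, acc.reshape(gx.shape)




# ---------------------------------------------------------------------------
# Area-faithful WET sampling (the dose engine's geometry input)

@dataclass
class WetSampleTable:
    """Axial rays with exact material path lengths and area weights.

    ``x``/``y`` are lab-frame lateral ray positions, ``column_mm`` the
    physical material path length through the (possibly transformed)
    modulator, ``area_mm2`` the lateral area weight of each sample.  Ray
    positions form per-cell lattices whose offsets vary per lattice line, so
    the thin concentric pin rings are sampled without lattice aliasing:
    aggregated over cells, the sampled WET distribution converges to the
    exact area fractions of the pin design.
    """

    x: np.ndarray
    y: np.ndarray
    column_mm: np.ndarray
    area_mm2: np.ndarray


_PHI1, _PHI2 = 0.7548776662466927, 0.5698402909980532  # R2 low-discrepancy


def _jittered_lattice(x_lo, x_hi, y_lo, y_hi, pitch):
    """Pitch lattice; x offsets vary per sample row, y offsets per column,
    so ring-edge counting errors decorrelate across lattice lines."""
    nx = max(1, int(np.ceil((x_hi - x_lo) / pitch)))
    ny = max(1, int(np.ceil((y_hi - y_lo) / pitch)))
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    jx = (_PHI1 * ((iy * 2654435761) % 65536)) % 1.0
    jy = (_PHI2 * ((ix * 2654435761) % 65536)) % 1.0
    xs = x_lo + (ix + jx) * pitch
    ys = y_lo + (iy + jy) * pitch
    return xs.ravel(), ys.ravel()


def _box_path(xr0, sx, yr0, sy, dz, box):
    """Path length through an axis-aligned box for rays
    (x, y)(z) = (xr0 + sx z, yr0 + sy z), parametrized by own-frame z."""
    bx0, bx1, by0, by1, bz0, bz1 = box

    def axis_interval(r0, s, lo, hi):
        if abs(s) < 1e-12:
            inside = (r0 >= lo) & (r0 <= hi)
            return (np.where(inside, -np.inf, np.inf),
                    np.where(inside, np.inf, -np.inf))
        t1 = (lo - r0) / s
        t2 = (hi - r0) / s
        return np.minimum(t1, t2), np.maximum(t1, t2)

    xlo, xhi = axis_interval(xr0, sx, bx0, bx1)
    ylo, yhi = axis_interval(yr0, sy, by0, by1)
    z0 = np.maximum(np.maximum(xlo, ylo), bz0)
    z1 = np.minimum(np.minimum(xhi, yhi), bz1)
    return np.clip(z1 - z0, 0.0, None) / dz


def in_pin_mixing_slope(modulator, pv_mev: float = 447.0) -> float:
    """Representative straight-ray slope emulating in-pin scattering.

    A proton crossing a pin column of length L leaves it displaced by
    sigma ~ theta0(L) * L / sqrt(3) (Highland); the equivalent straight
    chord has slope theta0 / sqrt(3).  Evaluated at the mean material
    column of the modulator.
    """
    mean_cols = []
    for p in modulator.pins.values():
        pin = p.contour
        if pin.kind == "step":
            mh = float(np.dot(pin.levels_height_mm, pin.levels_area_fraction))
        else:
            mh = float(np.trapezoid(pin.profile_height_mm,
                                    pin.profile_cum_area))
        mean_cols.append(mh + p.extra_height_mm)
    length = modulator.base_layer_mm + float(np.mean(mean_cols))
    ratio = max(length / modulator.material.radiation_length_mm, 1e-9)
    theta0 = (13.6 / pv_mev) * np.sqrt(ratio) \
        * max(1.0 + 0.038 * np.log(ratio), 0.25)
    return theta0 / np.sqrt(3.0)


def _slab_column(modulator, xr, yr, sx, sy, dz, stepless_tier_mm):
    """Material path of oblique rays through pins + base + walls.

    Rays are given by own-frame foot points (xr, yr at z = 0) and slopes;
    pins are intersected via their stacked-box decomposition, bucketed by
    the mid-column cell to keep the candidate set local.
    """
    a = modulator.period_mm
    (fx0, fy0), (fx1, fy1) = modulator.footprint_bounds()
    wt = modulator.wall_thickness_mm
    zb = modulator.base_layer_mm
    ztop = zb + max(modulator.wall_height_mm,
                    max(p.contour.max_height + p.extra_height_mm
                        for p in modulator.pins.values()))

    col = np.zeros(xr.shape)
    if zb > 0:
        col += _box_path(xr, sx, yr, sy, dz, (fx0, fx1, fy0, fy1, 0.0, zb))
    if wt > 0:
        z1 = zb + modulator.wall_height_mm
        for b in ((fx0 - wt, fx1 + wt, fy0 - wt, fy0, 0.0, z1),
                  (fx0 - wt, fx1 + wt, fy1, fy1 + wt, 0.0, z1),
                  (fx0 - wt, fx0, fy0, fy1, 0.0, z1),
                  (fx1, fx1 + wt, fy0, fy1, 0.0, z1)):
            col += _box_path(xr, sx, yr, sy, dz, b)

    z_mid = zb + 0.5 * (ztop - zb)
    iu = np.floor((xr + sx * z_mid - modulator.origin_xy[0]) / a).astype(int)
    iv = np.floor((yr + sy * z_mid - modulator.origin_xy[1]) / a).astype(int)
    mu = int(np.ceil((abs(sx) * (ztop - zb) + a) / a))
    mv = int(np.ceil((abs(sy) * (ztop - zb) + a) / a))
    stride = 2 * (max(abs(iu.max(initial=0)), abs(iv.max(initial=0)),
                      abs(iu.min(initial=0)), abs(iv.min(initial=0)))
                  + mu + mv + 2)
    key = iv * stride + iu
    order = np.argsort(key, kind="stable")
    sorted_key = key[order]

    iu_min, iu_max = int(iu.min()), int(iu.max())
    iv_min, iv_max = int(iv.min()), int(iv.max())
    tier_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for (i, j), placed in modulator.pins.items():
        if not (iu_min - mu <= i <= iu_max + mu
                and iv_min - mv <= j <= iv_max + mv):
            continue
        tiers = tier_cache.get(id(placed.contour))
        if tiers is None or placed.extra_height_mm != 0.0:
            tiers = _pin_tiers(placed, a, stepless_tier_mm)
            if placed.extra_height_mm == 0.0:
                tier_cache[id(placed.contour)] = tiers
        hw, hh = tiers
        if len(hw) == 0:
            continue
        cx, cy = modulator.cell_center(i, j)
        idx_list = []
        for jj in range(j - mv, j + mv + 1):
            lo = np.searchsorted(sorted_key, jj * stride + (i - mu))
            hi = np.searchsorted(sorted_key, jj * stride + (i + mu),
                                 side="right")
            if hi > lo:
                idx_list.append(order[lo:hi])
        if not idx_list:
            continue
        idx = np.concatenate(idx_list)
        col[idx] += _pin_path(xr[idx], yr[idx], sx, sy, dz, cx, cy, zb,
                              hw, hh)
    return col


def _pin_path(xr, yr, sx, sy, dz, cx, cy, zb, hw, hh):
    """Vectorized path of oblique rays through one pin's stacked boxes."""
    z_edges = np.concatenate([[zb], zb + hh])  # (T+1,)
    hw_b = hw[None, :]

    def interval(r0, s, c):
        if abs(s) < 1e-12:
            inside = np.abs(r0[:, None] - c) <= hw_b
            lo = np.where(inside, -np.inf, np.inf)
            hi = np.where(inside, np.inf, -np.inf)
            return lo, hi
        t1 = (c - hw_b - r0[:, None]) / s
        t2 = (c + hw_b - r0[:, None]) / s
        return np.minimum(t1, t2), np.maximum(t1, t2)

    xlo, xhi = interval(xr, sx, cx)
    ylo, yhi = interval(yr, sy, cy)
    z0 = np.maximum(np.maximum(xlo, ylo), z_edges[None, :-1])
    z1 = np.minimum(np.minimum(xhi, yhi), z_edges[None, 1:])
    return np.clip(z1 - z0, 0.0, None).sum(axis=1) / dz


def wet_sample_table(modulator, transform: RigidTransform | None = None, *,
                     samples_per_cell: int = 12,
                     region=None, pad_mm: float = 3.0,
                     stepless_tier_mm: float = 0.5,
                     in_pin_scatter: bool = False) -> WetSampleTable:
    """Exact axial WET samples of a (possibly transformed) modulator.

    Each lab-frame lattice ray is intersected analytically with the
    modulator solid (stacked-box pin decomposition, base slab, walls) in
    the modulator's own frame — no raster and no tessellation, for the
    identity, translations and rotations about a lateral or the beam axis.
    With ``in_pin_scatter`` the rays are replaced by a symmetric
    five-direction ensemble at the in-pin scattering slope, emulating the
    lateral wander of protons inside tall pin columns (each sub-direction
    is itself an exact geometric sampling, so material is conserved).
    ``region`` optionally clips the lateral extent (x_lo, x_hi, y_lo, y_hi)
    to the beam footprint.
    """
    t = transform or RigidTransform()
    a = modulator.period_mm
    pitch = a / samples_per_cell
    (fx0, fy0), (fx1, fy1) = modulator.footprint_bounds()
    wt = modulator.wall_thickness_mm
    ztop = modulator.base_layer_mm + max(
        modulator.wall_height_mm,
        max(p.contour.max_height + p.extra_height_mm
            for p in modulator.pins.values()))

    corners = np.array([(xc, yc, zc)
                        for xc in (fx0 - wt, fx1 + wt)
                        for yc in (fy0 - wt, fy1 + wt)
                        for zc in (0.0, ztop)])
    lab = t.apply(corners)
    x_lo, x_hi = lab[:, 0].min() - pad_mm, lab[:, 0].max() + pad_mm
    y_lo, y_hi = lab[:, 1].min() - pad_mm, lab[:, 1].max() + pad_mm
    if region is not None:
        x_lo, x_hi = max(x_lo, region[0]), min(x_hi, region[1])
        y_lo, y_hi = max(y_lo, region[2]), min(y_hi, region[3])
    if x_lo >= x_hi or y_lo >= y_hi:
        return WetSampleTable(np.empty(0), np.empty(0), np.empty(0),
                              np.empty(0))

    x, y = _jittered_lattice(x_lo, x_hi, y_lo, y_hi, pitch)
    area = np.full(x.shape, pitch**2)

    rot = t.rotation_matrix()
    d_own = rot.T @ np.array([0.0, 0.0, 1.0])
    dz = d_own[2]
    if dz <= 0.1:
        raise ValueError("transform turns the modulator sideways")
    sx0, sy0 = d_own[0] / dz, d_own[1] / dz
    p0 = t.apply_inverse(np.stack([x, y, np.zeros_like(x)], axis=1))
    xr = p0[:, 0] - p0[:, 2] * sx0
    yr = p0[:, 1] - p0[:, 2] * sy0

    if in_pin_scatter:
        phi = in_pin_mixing_slope(modulator) * np.sqrt(2.5)
        slopes = [(sx0, sy0), (sx0 + phi, sy0), (sx0 - phi, sy0),
                  (sx0, sy0 + phi), (sx0, sy0 - phi)]
    else:
        slopes = [(sx0, sy0)]

    cols = []
    for sx, sy in slopes:
        if abs(sx) < 1e-12 and abs(sy) < 1e-12:
            cols.append(modulator.column_height(xr, yr) / dz)
        else:
            cols.append(_slab_column(modulator, xr, yr, sx, sy, dz,
                                     stepless_tier_mm))
    n = len(slopes)
    return WetSampleTable(np.tile(x, n), np.tile(y, n),
                          np.concatenate(cols),
                          np.tile(area / n, n))
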