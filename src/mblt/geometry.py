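"""Voxel grids, phantom surfaces and the rotating multi-camera gantry.

Coordinate conventions (right-handed, millimetres):

* the gantry rotation axis is +z and passes through the origin;
* view angle 0 deg places a camera on the +x axis looking toward -x;
* voxel indices are 0-based with the voxel-center convention
  ``world = origin + (index + 0.5) * voxel_size``.

Rotation is modelled as camera motion around a fixed scene; by reciprocity
this is equivalent to rotating the phantom in front of a fixed camera.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import trimesh

__all__ = [
    "VoxelGrid",
    "SurfaceMesh",
    "CameraPose",
    "GantryConfig",
    "build_cylinder_phantom",
    "build_gantry",
    "surface_pixel_map",
]


# --------------------------------------------------------------------------- #
# voxel grid
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned isotropic voxel grid."""

    shape: tuple[int, int, int]
    voxel_size: float
    origin: tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if any(s < 1 for s in self.shape):
            raise ValueError("grid shape components must be >= 1")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Voxel index (possibly fractional) -> world position of voxel center."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + (idx + 0.5) * self.voxel_size

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """World position -> fractional voxel index (centers map to integers)."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / self.voxel_size - 0.5

    def centers(self) -> np.ndarray:
        """All voxel centers, shape (*shape, 3)."""
        axes = [
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.voxel_size
            for a in range(3)
        ]
        out = np.empty(self.shape + (3,), dtype=float)
        out[..., 0] = axes[0][:, None, None]
        out[..., 1] = axes[1][None, :, None]
        out[..., 2] = axes[2][None, None, :]
        return out

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.voxel_size

    def crop_z(self, z_min: float, z_max: float) -> "VoxelGrid":
        """Sub-grid keeping whole voxel layers whose centers lie in [z_min, z_max]."""
        z = self.axis_coords(2)
        keep = np.nonzero((z >= z_min) & (z <= z_max))[0]
        if keep.size == 0:
            raise ValueError("empty crop range")
        new_origin = (self.origin[0], self.origin[1], self.origin[2] + keep[0] * self.voxel_size)
        return VoxelGrid((self.shape[0], self.shape[1], int(keep.size)), self.voxel_size, new_origin)


# --------------------------------------------------------------------------- #
# surface mesh
# --------------------------------------------------------------------------- #

class SurfaceMesh:
    """Closed triangle mesh with outward normals, backed by :mod:`trimesh`."""

    def __init__(self, vertices: np.ndarray, triangles: np.ndarray, *, validate: bool = True):
        self._tm = trimesh.Trimesh(
            vertices=np.asarray(vertices, dtype=float),
            faces=np.asarray(triangles, dtype=np.int64),
            process=False,
        )
        if validate:
            if not self._tm.is_watertight:
                raise ValueError("surface mesh must be closed (watertight)")
            if self._tm.volume <= 0:
                raise ValueError("surface mesh must be consistently oriented outward")

    # -- basic accessors ----------------------------------------------------
    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self._tm.vertices)

    @property
    def triangles(self) -> np.ndarray:
        return np.asarray(self._tm.faces)

    @property
    def face_normals(self) -> np.ndarray:
        return np.asarray(self._tm.face_normals)

    @property
    def face_areas(self) -> np.ndarray:
        return np.asarray(self._tm.area_faces)

    @property
    def face_centroids(self) -> np.ndarray:
        return np.asarray(self._tm.triangles_center)

    @property
    def n_faces(self) -> int:
        return len(self._tm.faces)

    @property
    def signed_volume(self) -> float:
        return float(self._tm.volume)

    @property
    def is_closed(self) -> bool:
        return bool(self._tm.is_watertight)

    @property
    def is_convex(self) -> bool:
        return bool(self._tm.is_convex)

    def ray_intersections(self, origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
        """Distances of every ray/triangle intersection (Moller-Trumbore).

        Returns a list-like object: for ray ``i`` the sorted array of hit
        distances ``t > 0`` along the (unit) direction.
        """
        origins = np.atleast_2d(np.asarray(origins, dtype=float))
        directions = np.atleast_2d(np.asarray(directions, dtype=float))
        tri = self.vertices[self.triangles]  # (M, 3, 3)
        e1 = tri[:, 1] - tri[:, 0]
        e2 = tri[:, 2] - tri[:, 0]
        hits = []
        for o, d in zip(origins, directions):
            p = np.cross(d, e2)
            det = np.einsum("ij,ij->i", e1, p)
            ok = np.abs(det) > 1e-12
            inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
            s = o - tri[:, 0]
            u = np.einsum("ij,ij->i", s, p) * inv
            q = np.cross(s, e1)
            v = np.einsum("j,ij->i", d, q) * inv
            t = np.einsum("ij,ij->i", e2, q) * inv
            good = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & (t > 1e-9)
            hits.append(np.sort(t[good]))
        return hits

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Point-in-mesh test by ray-crossing parity (robust direction)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        # irrational direction avoids edge/vertex grazing degeneracies
        d = np.array([0.57735026, 0.51449576, 0.63245553])
        d /= np.linalg.norm(d)
        hits = self.ray_intersections(pts, np.tile(d, (len(pts), 1)))
        return np.array([len(h) % 2 == 1 for h in hits])

    def ray_visibility(self, face_idx: np.ndarray, camera_position: np.ndarray) -> np.ndarray:
        """Ray-cast occlusion test: True where the face centroid sees the camera."""
        cam = np.asarray(camera_position, dtype=float)
        cent = self.face_centroids[np.asarray(face_idx)]
        d = cam - cent
        dist = np.linalg.norm(d, axis=1)
        d = d / dist[:, None]
        origins = cent + 1e-6 * d
        hits = self.ray_intersections(origins, d)
        # visible when no other surface crossing lies between centroid and camera
        return np.array(
            [not np.any(h < dd - 1e-6) for h, dd in zip(hits, dist)]
        )

    def save(self, path) -> None:
        self._tm.export(path)

    @classmethod
    def load(cls, path) -> "SurfaceMesh":
        # STL stores free triangles: merge coincident vertices to restore topology
        tm = trimesh.load(path, force="mesh", process=True)
        tm.merge_vertices()
        return cls(tm.vertices, tm.faces)


def _cylinder_mesh(radius: float, height: float, n_theta: int, n_z: int, n_r: int = 6) -> SurfaceMesh:
    """Closed cylinder (side + concentric-ring caps), axis +z, centered on z=0."""
    theta = np.arange(n_theta) * (2.0 * math.pi / n_theta)
    ct, st = np.cos(theta), np.sin(theta)

    verts: list[np.ndarray] = []
    faces: list[tuple[int, int, int]] = []

    # side rings, bottom to top
    z_levels = np.linspace(-height / 2.0, height / 2.0, n_z + 1)
    ring_start = []
    for z in z_levels:
        ring_start.append(len(verts))
        for i in range(n_theta):
            verts.append(np.array([radius * ct[i], radius * st[i], z]))
    for j in range(n_z):
        a, b = ring_start[j], ring_start[j + 1]
        for i in range(n_theta):
            i2 = (i + 1) % n_theta
            # outward orientation: CCW when seen from outside
            faces.append((a + i, a + i2, b + i))
            faces.append((a + i2, b + i2, b + i))

    # caps built from concentric rings; rim ring shared with the side surface
    for sign, rim in ((-1, ring_start[0]), (+1, ring_start[-1])):
        z = sign * height / 2.0
        inner_rings = [rim]
        for k in range(n_r - 1, 0, -1):
            r_k = radius * k / n_r
            inner_rings.append(len(verts))
            for i in range(n_theta):
                verts.append(np.array([r_k * ct[i], r_k * st[i], z]))
        center = len(verts)
        verts.append(np.array([0.0, 0.0, z]))
        for outer, inner in zip(inner_rings[:-1], inner_rings[1:]):
            for i in range(n_theta):
                i2 = (i + 1) % n_theta
                if sign > 0:  # top cap: CCW seen from +z
                    faces.append((outer + i, outer + i2, inner + i))
                    faces.append((outer + i2, inner + i2, inner + i))
                else:
                    faces.append((outer + i2, outer + i, inner + i))
                    faces.append((inner + i2, outer + i2, inner + i))
        last = inner_rings[-1]
        for i in range(n_theta):
            i2 = (i + 1) % n_theta
            if sign > 0:
                faces.append((last + i, last + i2, center))
            else:
                faces.append((last + i2, last + i, center))

    return SurfaceMesh(np.array(verts), np.array(faces, dtype=np.int64))


def build_cylinder_phantom(
    diameter: float,
    height: float,
    voxel_size: float = 0.5,
    *,
    n_theta: int = 80,
    n_z: int | None = None,
    margin_voxels: int = 2,
) -> tuple[VoxelGrid, SurfaceMesh, np.ndarray]:
    """Cylindrical phantom: voxel grid, closed surface mesh and inside mask.

    The grid is laid out so the cylinder axis is a line of voxel centers in
    x/y and the cap planes coincide with voxel-layer boundaries in z (so the
    voxelized volume tiles the analytic height exactly when ``height`` is a
    multiple of ``voxel_size``).

    ``n_theta`` defaults to 80 azimuthal sections so the tessellation is
    congruent under the 18-degree gantry steps.
    """
    if diameter <= 0 or height <= 0 or voxel_size <= 0:
        raise ValueError("diameter, height and voxel_size must be positive")
    if voxel_size > diameter:
        raise ValueError("voxel_size larger than the phantom diameter")

    radius = diameter / 2.0
    # x/y: odd count, axis on a voxel center
    n_half = int(math.ceil(radius / voxel_size)) + margin_voxels
    nxy = 2 * n_half + 1
    oxy = -(nxy / 2.0) * voxel_size
    # z: cap planes on voxel boundaries
    n_layers = int(math.ceil(height / voxel_size))
    nz = n_layers + 2 * margin_voxels
    oz = -height / 2.0 - margin_voxels * voxel_size

    grid = VoxelGrid((nxy, nxy, nz), voxel_size, (oxy, oxy, oz))

    if n_z is None:
        n_z = max(4, int(round(height / 1.25)))
    mesh = _cylinder_mesh(radius, height, n_theta=max(8, n_theta), n_z=n_z)

    c = grid.centers()
    mask = (c[..., 0] ** 2 + c[..., 1] ** 2 < radius**2) & (np.abs(c[..., 2]) < height / 2.0)
    return grid, mesh, mask


# --------------------------------------------------------------------------- #
# cameras and gantry
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class CameraPose:
    """Thin-lens perspective camera on the gantry circle.

    The camera is focused on the gantry axis: the image distance follows
    from the thin-lens equation at ``focus_distance_mm`` (the standoff), and
    the magnification is ``image_distance / focus_distance``.
    """

    view_angle_deg: float = 0.0
    position: tuple[float, float, float] = (115.0, 0.0, 0.0)
    optical_axis: tuple[float, float, float] = (-1.0, 0.0, 0.0)
    up: tuple[float, float, float] = (0.0, 0.0, 1.0)
    focal_length_mm: float = 25.0
    f_number: float = 0.95
    pixel_pitch_mm: float = 0.024
    detector_pixels: tuple[int, int] = (512, 512)
    focus_distance_mm: float | None = None
    camera_id: int = 0

    def __post_init__(self):
        a = np.asarray(self.optical_axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("optical axis must be a nonzero vector")
        object.__setattr__(self, "optical_axis", tuple(a / n))
        ang = float(self.view_angle_deg) % 360.0
        object.__setattr__(self, "view_angle_deg", ang)
        if self.focus_distance_mm is None:
            object.__setattr__(
                self, "focus_distance_mm", float(np.linalg.norm(np.asarray(self.position)[:2]))
            )
        if self.focus_distance_mm <= self.focal_length_mm:
            raise ValueError("focus distance must exceed the focal length")

    # -- derived optics ------------------------------------------------------
    @property
    def image_distance_mm(self) -> float:
        d, f = self.focus_distance_mm, self.focal_length_mm
        return f * d / (d - f)

    @property
    def magnification(self) -> float:
        return self.image_distance_mm / self.focus_distance_mm

    @property
    def aperture_diameter_mm(self) -> float:
        return self.focal_length_mm / self.f_number

    @property
    def aperture_area_mm2(self) -> float:
        return math.pi * (self.aperture_diameter_mm / 2.0) ** 2

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(right, up, forward) orthonormal camera basis in world coordinates."""
        fwd = np.asarray(self.optical_axis)
        up_hint = np.asarray(self.up, dtype=float)
        right = np.cross(fwd, up_hint)
        nr = np.linalg.norm(right)
        if nr < 1e-12:
            raise ValueError("up vector parallel to the optical axis")
        right /= nr
        up = np.cross(right, fwd)
        return right, up, fwd

    def project(self, points: np.ndarray, binning: int = 1):
        """Project world points to (row, col) pixel coordinates.

        Returns ``(rows, cols, depth)`` where depth is the distance along the
        optical axis (mm); points behind the camera get depth <= 0.
        """
        right, up, fwd = self.basis()
        q = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.position)
        depth = q @ fwd
        with np.errstate(divide="ignore", invalid="ignore"):
            x_img = self.image_distance_mm * (q @ right) / depth
            y_img = self.image_distance_mm * (q @ up) / depth
        pitch = self.pixel_pitch_mm * binning
        n_rows = self.detector_pixels[0] // binning
        n_cols = self.detector_pixels[1] // binning
        cols = x_img / pitch + (n_cols - 1) / 2.0
        rows = -y_img / pitch + (n_rows - 1) / 2.0
        return rows, cols, depth


@dataclass(frozen=True)
class GantryConfig:
    """Rotating multi-camera gantry: n_views poses at fixed angular steps."""

    n_cameras: int = 4
    n_views: int = 20
    angular_step_deg: float = 18.0

    def __post_init__(self):
        if self.n_cameras < 1 or self.n_views < 1:
            raise ValueError("camera and view counts must be positive")
        if abs(self.n_views * self.angular_step_deg - 360.0) > 1e-9:
            raise ValueError("n_views * angular_step must equal 360 degrees")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_views) * self.angular_step_deg


def build_gantry(
    config: GantryConfig,
    camera_template: CameraPose | None = None,
    radius: float = 115.0,
    axis_point: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> list[CameraPose]:
    """All camera poses of a full gantry rotation, ordered by view angle.

    Each of the ``n_cameras`` physical cameras contributes
    ``n_views / n_cameras`` rotational stops; every pose looks at the
    rotation axis.
    """
    if config.n_views % config.n_cameras != 0:
        raise ValueError("n_views must be divisible by n_cameras")
    if camera_template is None:
        camera_template = CameraPose(position=(radius, 0.0, 0.0), focus_distance_mm=radius)
    stops = config.n_views // config.n_cameras
    poses = []
    ax = np.asarray(axis_point, dtype=float)
    for k in range(config.n_views):
        ang = k * config.angular_step_deg
        rad = math.radians(ang)
        pos = ax + radius * np.array([math.cos(rad), math.sin(rad), 0.0])
        fwd = np.array([-math.cos(rad), -math.sin(rad), 0.0])
        poses.append(
            replace(
                camera_template,
                view_angle_deg=ang,
                position=tuple(pos),
                optical_axis=tuple(fwd),
                focus_distance_mm=radius,
                camera_id=k // stops,
            )
        )
    return poses


# --------------------------------------------------------------------------- #
# surface -> detector mapping
# --------------------------------------------------------------------------- #

def surface_pixel_map(
    mesh: SurfaceMesh,
    camera: CameraPose,
    binning: int = 1,
    *,
    min_cos: float = 1e-6,
    occlusion: str = "auto",
):
    """Map visible surface triangles to detector pixels with geometric weights.

    Returns a dict of arrays over visible triangles:

    ``face``    triangle index;
    ``row/col`` (float) pixel coordinates of the projected centroid;
    ``weight``  area * cos(obliqueness) * aperture solid angle (mm^2 * sr),
                i.e. the etendue factor turning surface radiance
                (photons/s/mm^2/sr) into photons/s collected by the lens;
    ``cos``     view obliqueness cosine; ``depth`` distance to the camera (mm).

    Back-facing triangles are excluded; occluded triangles are removed by a
    ray cast unless the mesh is convex (``occlusion='auto'``), where
    back-face culling is exact.
    """
    cam_pos = np.asarray(camera.position, dtype=float)
    if mesh.contains(cam_pos[None, :])[0]:
        raise ValueError("camera position lies inside the mesh")

    cent = mesh.face_centroids
    nrm = mesh.face_normals
    to_cam = cam_pos - cent
    dist = np.linalg.norm(to_cam, axis=1)
    cosv = np.einsum("ij,ij->i", nrm, to_cam) / dist
    vis = cosv > min_cos

    if occlusion == "always" or (occlusion == "auto" and not mesh.is_convex):
        idx = np.nonzero(vis)[0]
        vis_ray = mesh.ray_visibility(idx, cam_pos)
        vis = np.zeros(mesh.n_faces, dtype=bool)
        vis[idx[vis_ray]] = True

    idx = np.nonzero(vis)[0]
    rows, cols, depth = camera.project(cent[idx], binning=binning)
    in_front = depth > 0
    n_rows = camera.detector_pixels[0] // binning
    n_cols = camera.detector_pixels[1] // binning
    on_chip = (
        in_front & (rows > -0.5) & (rows < n_rows - 0.5) & (cols > -0.5) & (cols < n_cols - 0.5)
    )
    idx = idx[on_chip]
    rows, cols = rows[on_chip], cols[on_chip]
    d = dist[idx]
    omega = camera.aperture_area_mm2 / d**2
    weight = mesh.face_areas[idx] * cosv[idx] * omega
    return {
        "face": idx,
        "row": rows,
        "col": cols,
        "weight": weight,
        "cos": cosv[idx],
        "depth": d,
    }
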