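"""Fixed-topology two-surface LV lattice meshes and the geometry kernels
used throughout the pipeline.

The left ventricle is represented by two open surfaces (endocardium and
epicardium) sharing one structured lattice: ``n_long`` circumferential
rings of ``n_circ`` nodes ordered apex -> base, plus a single apex node
per surface.  Node correspondence across patients is positional: lattice
site ``(ring i, column j)`` always maps to the same shape-vector index,
which is the precondition for cross-patient PCA.

Coordinates are millimetres in a right-handed frame with +z running from
apex toward base.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class LatticeTopology:
    """Structured LV surface lattice: ``n_circ`` columns x ``n_long`` rings
    plus one apex node, per surface."""

    n_circ: int = 48
    n_long: int = 32

    def __post_init__(self) -> None:
        if self.n_circ < 3:
            raise ValueError(f"n_circ must be >= 3, got {self.n_circ}")
        if self.n_long < 2:
            raise ValueError(f"n_long must be >= 2, got {self.n_long}")

    @property
    def nodes_per_surface(self) -> int:
        return self.n_circ * self.n_long + 1

    @property
    def vector_length(self) -> int:
        """Length of the flattened two-surface shape vector."""
        return 6 * self.nodes_per_surface

    def node_index(self, ring: int, col: int) -> int:
        """Index of a lattice node; apex is index 0, rings run apex->base."""
        return 1 + ring * self.n_circ + (col % self.n_circ)

    def triangles(self) -> np.ndarray:
        """(M, 3) outward-wound triangulation of one surface."""
        return _surface_triangles(self.n_circ, self.n_long)

    def basal_ring(self) -> np.ndarray:
        """Node indices of the most basal ring."""
        return np.array(
            [self.node_index(self.n_long - 1, j) for j in range(self.n_circ)]
        )

    def laplacian(self):
        """Sparse combinatorial graph Laplacian of one surface lattice."""
        return _surface_laplacian(self.n_circ, self.n_long)


@lru_cache(maxsize=8)
def _surface_triangles(n_circ: int, n_long: int) -> np.ndarray:
    topo = LatticeTopology(n_circ, n_long)
    tris = []
    # apex fan, wound so that normals point toward -z at the apex (outward)
    for j in range(n_circ):
        tris.append((0, topo.node_index(0, j + 1), topo.node_index(0, j)))
    for i in range(n_long - 1):
        for j in range(n_circ):
            a = topo.node_index(i, j)
            b = topo.node_index(i, j + 1)
            c = topo.node_index(i + 1, j)
            d = topo.node_index(i + 1, j + 1)
            tris.append((a, b, c))
            tris.append((b, d, c))
    return np.asarray(tris, dtype=np.int64)


@lru_cache(maxsize=8)
def _surface_laplacian(n_circ: int, n_long: int):
    from scipy import sparse

    topo = LatticeTopology(n_circ, n_long)
    n = topo.nodes_per_surface
    rows, cols = [], []
    for i in range(n_long):
        for j in range(n_circ):
            me = topo.node_index(i, j)
            nbrs = [topo.node_index(i, j - 1), topo.node_index(i, j + 1)]
            nbrs.append(0 if i == 0 else topo.node_index(i - 1, j))
            if i < n_long - 1:
                nbrs.append(topo.node_index(i + 1, j))
            for nb in nbrs:
                rows.append(me)
                cols.append(nb)
    for j in range(n_circ):  # apex connects to the first ring
        rows.append(0)
        cols.append(topo.node_index(0, j))
    A = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    ).tocsr()
    deg = sparse.diags(np.asarray(A.sum(axis=1)).ravel())
    return (deg - A).tocsr()


@dataclass
class LVMesh:
    """Two-surface LV geometry on a fixed lattice.

    ``endo`` and ``epi`` are ``(nodes_per_surface, 3)`` arrays ordered
    apex node first, then rings apex -> base, column angle increasing
    counter-clockwise from +x.
    """

    endo: np.ndarray
    epi: np.ndarray
    topology: LatticeTopology = field(default_factory=LatticeTopology)
    rv_point: np.ndarray | None = None
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.endo = np.asarray(self.endo, dtype=float)
        self.epi = np.asarray(self.epi, dtype=float)
        k = self.topology.nodes_per_surface
        if self.endo.shape != (k, 3) or self.epi.shape != (k, 3):
            raise ValueError(
                f"node arrays must have shape ({k}, 3) for topology "
                f"{self.topology}, got {self.endo.shape} / {self.epi.shape}"
            )
        if self.rv_point is not None:
            self.rv_point = np.asarray(self.rv_point, dtype=float).reshape(3)

    # -- shape vector correspondence ------------------------------------
    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.endo.ravel(), self.epi.ravel()])

    @classmethod
    def from_vector(
        cls,
        vec: np.ndarray,
        topology: LatticeTopology,
        rv_point: np.ndarray | None = None,
        patient_id: str | None = None,
    ) -> "LVMesh":
        vec = np.asarray(vec, dtype=float).ravel()
        if vec.size != topology.vector_length:
            raise ValueError(
                f"shape vector length {vec.size} does not match topology "
                f"(expected {topology.vector_length})"
            )
        k = topology.nodes_per_surface
        return cls(
            endo=vec[: 3 * k].reshape(k, 3),
            epi=vec[3 * k :].reshape(k, 3),
            topology=topology,
            rv_point=rv_point,
            patient_id=patient_id,
        )

    def copy(self) -> "LVMesh":
        return replace(
            self,
            endo=self.endo.copy(),
            epi=self.epi.copy(),
            rv_point=None if self.rv_point is None else self.rv_point.copy(),
        )

    def all_nodes(self) -> np.ndarray:
        return np.vstack([self.endo, self.epi])

    def center_of_mass(self) -> np.ndarray:
        return self.all_nodes().mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LVMesh":
        """Apply ``x -> R x + t`` to every node (and the RV point)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float).reshape(3)
        rv = None if self.rv_point is None else R @ self.rv_point + t
        return replace(self, endo=self.endo @ R.T + t, epi=self.epi @ R.T + t, rv_point=rv)


# ---------------------------------------------------------------------------
# surface geometry kernels
# ---------------------------------------------------------------------------

def surface_triangle_coords(nodes: np.ndarray, topo: LatticeTopology) -> np.ndarray:
    """(M, 3, 3) triangle vertex coordinates of one surface."""
    return nodes[topo.triangles()]


def closed_cavity_triangles(nodes: np.ndarray, topo: LatticeTopology) -> np.ndarray:
    """Triangles of the surface closed by a basal-plane cap (fan from the
    basal-ring centroid), outward wound."""
    tris = surface_triangle_coords(nodes, topo)
    ring = nodes[topo.basal_ring()]
    cent = ring.mean(axis=0)
    n = len(ring)
    cap = np.empty((n, 3, 3))
    for j in range(n):
        cap[j, 0] = cent
        cap[j, 1] = ring[j]
        cap[j, 2] = ring[(j + 1) % n]
    return np.vstack([tris, cap])


def enclosed_volume(tris: np.ndarray) -> float:
    """Signed volume of a closed triangulated surface (divergence theorem),
    positive for outward winding.  Units: mm^3 when coords are mm."""
    v0, v1, v2 = tris[:, 0], tris[:, 1], tris[:, 2]
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def vertex_normals(nodes: np.ndarray, topo: LatticeTopology) -> np.ndarray:
    """Area-weighted outward vertex normals of one surface."""
    tri_idx = topo.triangles()
    tris = nodes[tri_idx]
    face_n = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    normals = np.zeros_like(nodes)
    for k in range(3):
        np.add.at(normals, tri_idx[:, k], face_n)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return normals / norm


def slice_surface(nodes: np.ndarray, topo: LatticeTopology, z: float) -> np.ndarray | None:
    """Intersect one surface with the plane at height ``z``.

    Walks each longitudinal lattice column (apex, ring0, ..., basal ring)
    and linearly interpolates the first z-crossing, so every returned
    point lies exactly on a triangle edge of the surface.  Returns an
    ``(n_circ, 2)`` polygon of in-plane (x, y) points, or None when the
    plane misses the surface.
    """
    n_circ, n_long = topo.n_circ, topo.n_long
    poly = np.empty((n_circ, 2))
    for j in range(n_circ):
        col = np.empty((n_long + 1, 3))
        col[0] = nodes[0]
        for i in range(n_long):
            col[i + 1] = nodes[topo.node_index(i, j)]
        zs = col[:, 2]
        seg = np.nonzero((zs[:-1] - z) * (zs[1:] - z) <= 0)[0]
        seg = seg[np.abs(zs[seg + 1] - zs[seg]) > 1e-12]
        if seg.size == 0:
            return None
        i0 = int(seg[0])
        t = (z - zs[i0]) / (zs[i0 + 1] - zs[i0])
        p = col[i0] + t * (col[i0 + 1] - col[i0])
        poly[j] = p[:2]
    return poly


# -- closest point on a triangulated surface --------------------------------

def _closest_point_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Vectorised closest point on triangles (Ericson's region method).

    All inputs broadcast to a common leading shape ``(...,)`` with final
    axis 3.  Returns (closest point, barycentric weights (..., 3)).
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    shape = va.shape
    u = np.empty(shape)
    v = np.empty(shape)
    w = np.empty(shape)

    # interior (default)
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v[...] = vb / denom
    w[...] = vc / denom
    u[...] = 1.0 - v - w

    with np.errstate(divide="ignore", invalid="ignore"):
        # edge BC
        t_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        m = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
        u[m], v[m], w[m] = 0.0, 1.0 - t_bc[m], t_bc[m]
        # edge AC
        t_ac = d2 / (d2 - d6)
        m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        u[m], v[m], w[m] = 1.0 - t_ac[m], 0.0, t_ac[m]
        # edge AB
        t_ab = d1 / (d1 - d3)
        m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        u[m], v[m], w[m] = 1.0 - t_ab[m], t_ab[m], 0.0
    # vertices
    m = (d6 >= 0) & (d5 <= d6)
    u[m], v[m], w[m] = 0.0, 0.0, 1.0
    m = (d3 >= 0) & (d4 <= d3)
    u[m], v[m], w[m] = 0.0, 1.0, 0.0
    m = (d1 <= 0) & (d2 <= 0)
    u[m], v[m], w[m] = 1.0, 0.0, 0.0

    closest = u[..., None] * a + v[..., None] * b + w[..., None] * c
    bary = np.stack([u, v, w], axis=-1)
    return closest, bary


def nearest_on_surface(
    points: np.ndarray,
    nodes: np.ndarray,
    topo: LatticeTopology,
    k: int = 48,
):
    """Closest point on a lattice surface for each query point.

    Candidate triangles are pruned with a KD-tree on triangle centroids
    (``k`` nearest per query), then the exact point-triangle distance is
    evaluated.  Returns ``(distances, node_indices (P, 3), barycentric
    (P, 3), closest_points (P, 3))``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri_idx = topo.triangles()
    tris = nodes[tri_idx]
    centroids = tris.mean(axis=1)
    k = min(k, len(tris))
    _, cand = cKDTree(centroids).query(points, k=k)
    cand = np.atleast_2d(cand)
    cand_tris = tris[cand]  # (P, k, 3, 3)
    p = points[:, None, :]
    closest, bary = _closest_point_triangles(
        p, cand_tris[:, :, 0], cand_tris[:, :, 1], cand_tris[:, :, 2]
    )
    d = np.linalg.norm(closest - p, axis=-1)
    best = np.argmin(d, axis=1)
    rows = np.arange(len(points))
    tri_of = cand[rows, best]
    return (
        d[rows, best],
        tri_idx[tri_of],
        bary[rows, best],
        closest[rows, best],
    )


def ray_surface_distance(
    origins: np.ndarray,
    directions: np.ndarray,
    nodes: np.ndarray,
    topo: LatticeTopology,
) -> np.ndarray:
    """Smallest positive ray-surface intersection distance per origin
    (Moller-Trumbore); NaN where the ray misses the surface."""
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    tris = nodes[topo.triangles()]
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    e1 = b - a
    e2 = c - a
    out = np.full(len(origins), np.nan)
    eps = 1e-12
    for i in range(len(origins)):
        o, d = origins[i], directions[i]
        pvec = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, pvec)
        ok = np.abs(det) > eps
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = o - a
        u = np.einsum("ij,ij->i", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        v = np.einsum("ij,j->i", qvec, d) * inv
        t = np.einsum("ij,ij->i", e2, qvec) * inv
        hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > 1e-9)
        if np.any(hit):
            out[i] = t[hit].min()
    return out


# ---------------------------------------------------------------------------
# idealised truncated half-ellipsoid template
# ---------------------------------------------------------------------------

def build_ellipsoid_mesh(
    semi_axes: tuple[float, float, float],
    wall_thickness: float,
    truncation_height: float,
    topology: LatticeTopology | None = None,
    rotation_z: float = 0.0,
    center: np.ndarray | None = None,
) -> LVMesh:
    """Truncated half-ellipsoid endocardium with a normally-offset
    epicardium.

    The endocardial apex sits at z = 0 and the basal ring at
    z = ``truncation_height``; ``semi_axes`` are (a, b, c) with c the
    long (z) semi-axis.  The epicardial surface is offset outward by
    ``wall_thickness`` along the analytic ellipsoid normal, preserving
    lattice correspondence.
    """
    a, b, c = semi_axes
    for name, val in [("semi-axis a", a), ("semi-axis b", b), ("semi-axis c", c),
                      ("wall_thickness", wall_thickness)]:
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    if not 0 < truncation_height <= c:
        raise ValueError(
            f"truncation_height must be in (0, c={c}], got {truncation_height}"
        )
    topo = topology or LatticeTopology()
    theta_max = np.arccos(np.clip(1.0 - truncation_height / c, -1.0, 1.0))
    thetas = theta_max * np.arange(1, topo.n_long + 1) / topo.n_long
    phis = 2 * np.pi * np.arange(topo.n_circ) / topo.n_circ + rotation_z

    endo = np.zeros((topo.nodes_per_surface, 3))
    endo[0] = (0.0, 0.0, 0.0)  # apex
    th, ph = np.meshgrid(thetas, phis, indexing="ij")
    pts = np.stack(
        [
            a * np.sin(th) * np.cos(ph),
            b * np.sin(th) * np.sin(ph),
            c * (1.0 - np.cos(th)),
        ],
        axis=-1,
    ).reshape(-1, 3)
    endo[1:] = pts

    # analytic outward normal of the ellipsoid at each endo node
    nrm = np.column_stack(
        [endo[:, 0] / a**2, endo[:, 1] / b**2, (endo[:, 2] - c) / c**2]
    )
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    epi = endo + wall_thickness * nrm

    if center is not None:
        center = np.asarray(center, dtype=float).reshape(3)
        endo = endo + center
        epi = epi + center
    return LVMesh(endo=endo, epi=epi, topology=topo)
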