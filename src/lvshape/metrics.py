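"""Geometric measurements of a fitted LV mesh: cavity volume, length,
wall thickness, sphericity, and 16-segment bullseye thickness maps."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mesh import (
    LVMesh,
    closed_cavity_triangles,
    enclosed_volume,
    ray_surface_distance,
    vertex_normals,
)

MM3_PER_ML = 1000.0


@dataclass
class GeometryMetrics:
    bpvol_ml: float
    length_mm: float
    mean_wall_thickness_mm: float
    sphericity: float


def cavity_volume(mesh: LVMesh) -> float:
    """Blood-pool (endocardial) volume in mL: the endo surface closed by
    its basal-plane cap, integrated by the divergence theorem."""
    tris = closed_cavity_triangles(mesh.endo, mesh.topology)
    _check_watertight(mesh)
    vol = enclosed_volume(tris)
    return abs(vol) / MM3_PER_ML


def _check_watertight(mesh: LVMesh) -> None:
    # lattice construction guarantees closure; reject degenerate geometry
    if not np.all(np.isfinite(mesh.endo)):
        raise ValueError("endocardial surface contains non-finite coordinates")


def lv_length(mesh: LVMesh) -> float:
    """Apex-to-base z-extent over both surfaces, mm."""
    nodes = mesh.all_nodes()
    return float(nodes[:, 2].max() - nodes[:, 2].min())


def wall_thickness_per_site(mesh: LVMesh) -> np.ndarray:
    """Endo-to-epi distance along the local endocardial outward normal,
    one value per endocardial lattice site (NaN where the ray misses)."""
    normals = vertex_normals(mesh.endo, mesh.topology)
    return ray_surface_distance(mesh.endo, normals, mesh.epi, mesh.topology)


def mean_wall_thickness(mesh: LVMesh, max_excluded_frac: float = 0.10) -> float:
    t = wall_thickness_per_site(mesh)
    missed = np.isnan(t)
    frac = missed.mean()
    if frac > max_excluded_frac:
        raise ValueError(
            f"{frac:.0%} of endocardial sites have no epicardial normal-ray "
            f"intersection (limit {max_excluded_frac:.0%})"
        )
    if missed.any():
        warnings.warn(
            f"{int(missed.sum())} endocardial sites excluded from wall "
            "thickness (normal ray missed the epicardium)",
            stacklevel=2,
        )
    return float(np.nanmean(t))


def sphericity(bpvol_ml: float, length_mm: float) -> float:
    """Cavity volume over the volume of a sphere of diameter L."""
    if bpvol_ml <= 0 or length_mm <= 0:
        raise ValueError("bpvol and length must be positive")
    sphere_ml = (4.0 / 3.0) * np.pi * (length_mm / 2.0) ** 3 / MM3_PER_ML
    return float(bpvol_ml / sphere_ml)


def geometry_metrics(mesh: LVMesh) -> GeometryMetrics:
    vol = cavity_volume(mesh)
    length = lv_length(mesh)
    return GeometryMetrics(
        bpvol_ml=vol,
        length_mm=length,
        mean_wall_thickness_mm=mean_wall_thickness(mesh),
        sphericity=sphericity(vol, length),
    )


# ---------------------------------------------------------------------------
# 16-segment bullseye
# ---------------------------------------------------------------------------

#: ring labels, apex ring last; sextant 0 is centred on +x (septal, toward
#: the RV landmark), angles increase counter-clockwise
SEGMENT_LABELS = (
    "basal septal", "basal anteroseptal", "basal anterior",
    "basal lateral", "basal inferior", "basal inferoseptal",
    "mid septal", "mid anteroseptal", "mid anterior",
    "mid lateral", "mid inferior", "mid inferoseptal",
    "apical septal", "apical anterior", "apical lateral", "apical inferior",
)


@dataclass
class BullseyeMap:
    """16 AHA-style segment values (basal 1-6, mid 7-12, apical 13-16)."""

    values: np.ndarray
    convention: str = "z-thirds basal/mid/apical; angle from +x (RV) CCW"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (16,):
            raise ValueError("a bullseye map has exactly 16 segment values")


def _segment_of_sites(mesh: LVMesh) -> np.ndarray:
    """Deterministic 16-segment assignment of each endocardial lattice
    site (-1 for the apex cap node, which has no ring segment)."""
    endo = mesh.endo
    seg = np.full(len(endo), -1, dtype=int)
    z = endo[:, 2]
    zmin, zmax = z.min(), z.max()
    zr = (z - zmin) / (zmax - zmin)
    third = np.clip((zr * 3).astype(int), 0, 2)  # 0 apical .. 2 basal
    ang = np.arctan2(endo[:, 1], endo[:, 0])  # alignment frame: +x toward RV
    for i in range(1, len(endo)):  # skip apex node 0
        if third[i] == 2:  # basal: sextants
            sector = int(((ang[i] + np.pi / 6) % (2 * np.pi)) // (np.pi / 3))
            seg[i] = sector
        elif third[i] == 1:  # mid
            sector = int(((ang[i] + np.pi / 6) % (2 * np.pi)) // (np.pi / 3))
            seg[i] = 6 + sector
        else:  # apical: quadrants
            sector = int(((ang[i] + np.pi / 4) % (2 * np.pi)) // (np.pi / 2))
            seg[i] = 12 + sector
    return seg


def bullseye_thickness_delta(mesh_a: LVMesh, mesh_b: LVMesh) -> BullseyeMap:
    """Per-segment mean wall-thickness change (b - a), mm.

    Both meshes must share topology and alignment; site correspondence
    is positional on the lattice.
    """
    if mesh_a.topology != mesh_b.topology:
        raise ValueError("meshes have different lattice topologies")
    ta = wall_thickness_per_site(mesh_a)
    tb = wall_thickness_per_site(mesh_b)
    delta = tb - ta
    seg = _segment_of_sites(mesh_a)
    values = np.empty(16)
    for s in range(16):
        mask = (seg == s) & np.isfinite(delta)
        if not mask.any():
            raise ValueError(f"segment {s} ({SEGMENT_LABELS[s]}) has no valid sites")
        values[s] = delta[mask].mean()
    return BullseyeMap(values=values)
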