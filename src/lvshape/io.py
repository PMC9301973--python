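"""Readers and writers for every artifact the pipeline touches.

Formats are deliberately plain text: one JSON document per patient for
contour stacks (explicit mm units + schema version), CSV for cohort
tables, legacy-ASCII VTK / OBJ for mesh export, and JSON for shape and
score models.  Readers validate and reject; they never silently repair.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .mesh import LatticeTopology, LVMesh

CONTOUR_SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Raised when an on-disk artifact violates its schema or invariants."""


# ---------------------------------------------------------------------------
# contour stacks
# ---------------------------------------------------------------------------

@dataclass
class ContourSlice:
    z: float
    epi: np.ndarray   # (n, 2) closed simple polygon, mm
    endo: np.ndarray  # (m, 2) strictly inside epi

    def __post_init__(self) -> None:
        self.epi = np.asarray(self.epi, dtype=float)
        self.endo = np.asarray(self.endo, dtype=float)


@dataclass
class ContourStack:
    """One patient's ordered (apex -> base) short-axis contour stack."""

    patient_id: str
    slices: list[ContourSlice]
    slice_thickness: float
    in_plane_res: float
    rv_landmark: np.ndarray  # (3,) mm, on the most basal retained slice
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rv_landmark = np.asarray(self.rv_landmark, dtype=float).reshape(3)

    @property
    def z_positions(self) -> np.ndarray:
        return np.array([s.z for s in self.slices])

    def validate(self) -> None:
        validate_stack(self)


def validate_stack(stack: ContourStack) -> None:
    if len(stack.slices) < 3:
        raise SchemaError(
            f"contour stack '{stack.patient_id}' has {len(stack.slices)} "
            "slices; at least 3 are required"
        )
    z = stack.z_positions
    if not np.all(np.diff(z) > 0):
        raise SchemaError(
            f"slice z-positions of '{stack.patient_id}' are not strictly "
            f"increasing (apex->base): {z.tolist()}"
        )
    for i, sl in enumerate(stack.slices):
        for name, poly in [("epi", sl.epi), ("endo", sl.endo)]:
            if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
                raise SchemaError(
                    f"slice {i}: malformed {name} polygon of shape {poly.shape}"
                )
            if not Polygon(poly).is_valid:
                raise SchemaError(f"slice {i}: {name} polygon is self-intersecting")
        epi_poly = Polygon(sl.epi)
        endo_poly = Polygon(sl.endo)
        if not epi_poly.contains(endo_poly):
            raise SchemaError(
                f"slice {i}: endo polygon is not strictly inside the epi polygon"
            )
    # landmark on/outside the epi contour of its (nearest-z) slice
    lm = stack.rv_landmark
    idx = int(np.argmin(np.abs(z - lm[2])))
    epi_poly = Polygon(stack.slices[idx].epi)
    if epi_poly.contains(Point(lm[0], lm[1])) and epi_poly.exterior.distance(
        Point(lm[0], lm[1])
    ) > 1e-9:
        raise SchemaError(
            f"rv_landmark lies strictly inside the epi contour of slice {idx}"
        )


def _canonical_dump(obj) -> str:
    return json.dumps(obj, sort_keys=True, indent=1) + "\n"


def write_contours(stack: ContourStack, path) -> None:
    validate_stack(stack)
    doc = {
        "schema_version": CONTOUR_SCHEMA_VERSION,
        "units": "mm",
        "patient_id": stack.patient_id,
        "slice_thickness": stack.slice_thickness,
        "in_plane_res": stack.in_plane_res,
        "rv_landmark": stack.rv_landmark.tolist(),
        "slices": [
            {"z": s.z, "epi": s.epi.tolist(), "endo": s.endo.tolist()}
            for s in stack.slices
        ],
        "meta": stack.meta,
    }
    Path(path).write_text(_canonical_dump(doc))


def read_contours(path) -> ContourStack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = json.loads(path.read_text())
    version = doc.get("schema_version")
    if version != CONTOUR_SCHEMA_VERSION:
        raise SchemaError(f"unrecognised contour schema version: {version!r}")
    if doc.get("units") != "mm":
        raise SchemaError(f"unsupported units: {doc.get('units')!r}")
    if "rv_landmark" not in doc:
        raise SchemaError("contour document is missing the rv_landmark")
    slices = [
        ContourSlice(z=s["z"], epi=np.asarray(s["epi"]), endo=np.asarray(s["endo"]))
        for s in doc["slices"]
    ]
    order = np.argsort([s.z for s in slices])
    stack = ContourStack(
        patient_id=doc["patient_id"],
        slices=[slices[i] for i in order],
        slice_thickness=doc["slice_thickness"],
        in_plane_res=doc["in_plane_res"],
        rv_landmark=np.asarray(doc["rv_landmark"]),
        meta=doc.get("meta", {}),
    )
    validate_stack(stack)
    return stack


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Covariates plus follow-up/event columns, one row per patient.

    ``data`` keeps pandas' native missingness (NaN).  Device implant
    times (years from baseline) are optional columns ``icd_time_years``
    and ``crt_time_years``; NaN means never implanted.
    """

    data: pd.DataFrame

    REQUIRED = ("follow_up_years", "event")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        for col in self.REQUIRED:
            if col not in df.columns:
                raise SchemaError(f"cohort table is missing required column '{col}'")
        if (df["follow_up_years"] <= 0).any():
            bad = df.index[df["follow_up_years"] <= 0].tolist()
            raise SchemaError(f"non-positive follow_up_years for patients {bad}")
        if not df["event"].isin([0, 1]).all():
            raise SchemaError("event column must be 0/1")
        for col in ("icd_time_years", "crt_time_years"):
            if col in df.columns:
                t = df[col]
                bad = df.index[(t.notna()) & (t > df["follow_up_years"] + 1e-9)]
                if len(bad):
                    raise SchemaError(
                        f"{col} after follow_up_years for patients {bad.tolist()}"
                    )

    @property
    def n(self) -> int:
        return len(self.data)

    def covariate_columns(self) -> list[str]:
        skip = {"follow_up_years", "event", "icd_time_years", "crt_time_years"}
        return [c for c in self.data.columns if c not in skip]


def read_cohort(path) -> CohortTable:
    df = pd.read_csv(path)
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# mesh export
# ---------------------------------------------------------------------------

def _mesh_vertices_faces(mesh: LVMesh):
    topo = mesh.topology
    k = topo.nodes_per_surface
    verts = np.vstack([mesh.endo, mesh.epi])
    tris = topo.triangles()
    faces = np.vstack([tris, tris + k])
    surface_id = np.concatenate(
        [np.zeros(len(tris), dtype=int), np.ones(len(tris), dtype=int)]
    )
    return verts, faces, surface_id


def write_mesh(mesh: LVMesh, path, format: str | None = None) -> None:
    """Export both surfaces as a triangulated mesh (mm units).

    ``format`` is 'vtk' (legacy ASCII polydata, endo/epi tagged via a
    cell-data scalar) or 'obj' (two named objects); inferred from the
    file suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    thickness = np.linalg.norm(mesh.epi - mesh.endo, axis=1)
    if np.any(thickness < 1e-9):
        warnings.warn(
            f"mesh has {int((thickness < 1e-9).sum())} zero-thickness sites; "
            "exporting anyway",
            stacklevel=2,
        )
    if format == "vtk":
        _write_vtk(mesh, path)
    elif format == "obj":
        _write_obj(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format: {format!r} (use 'vtk' or 'obj')")


def _write_vtk(mesh: LVMesh, path: Path) -> None:
    verts, faces, surface_id = _mesh_vertices_faces(mesh)
    lines = [
        "# vtk DataFile Version 3.0",
        "LV two-surface mesh (units mm; surface 0=endo, 1=epi)",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(verts)} double",
    ]
    lines += [" ".join(repr(float(x)) for x in v) for v in verts]
    lines.append(f"POLYGONS {len(faces)} {4 * len(faces)}")
    lines += [f"3 {a} {b} {c}" for a, b, c in faces]
    lines += [
        f"CELL_DATA {len(faces)}",
        "SCALARS surface int 1",
        "LOOKUP_TABLE default",
    ]
    lines += [str(s) for s in surface_id]
    path.write_text("\n".join(lines) + "\n")


def _write_obj(mesh: LVMesh, path: Path) -> None:
    topo = mesh.topology
    k = topo.nodes_per_surface
    tris = topo.triangles()
    lines = []
    for name, nodes, offset in [("endo", mesh.endo, 0), ("epi", mesh.epi, k)]:
        lines.append(f"o {name}")
        lines += [
            f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}" for v in nodes
        ]
    # OBJ indices are 1-based and global across objects
    lines_f = [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in tris]
    lines_f += [f"f {a + 1 + k} {b + 1 + k} {c + 1 + k}" for a, b, c in tris]
    path.write_text("\n".join(lines + lines_f) + "\n")


def read_mesh_obj(path, topology: LatticeTopology | None = None) -> LVMesh:
    """Re-import an OBJ written by :func:`write_mesh` (round-trip use)."""
    topo = topology or LatticeTopology()
    verts = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("v "):
            verts.append([float(x) for x in line.split()[1:4]])
    verts = np.asarray(verts)
    k = topo.nodes_per_surface
    if len(verts) != 2 * k:
        raise SchemaError(
            f"OBJ vertex count {len(verts)} does not match topology ({2 * k})"
        )
    return LVMesh(endo=verts[:k], epi=verts[k:], topology=topo)


# ---------------------------------------------------------------------------
# model serialization (shape model, LVAS)
# ---------------------------------------------------------------------------

def serialize_shape_model(model, path) -> None:
    doc = {
        "kind": "shape_model",
        "mean": model.mean.tolist(),
        "modes": model.modes.tolist(),
        "variances": model.variances.tolist(),
        "n_retained": model.n_retained,
        "n_train": model.n_train,
        "topology": {
            "n_circ": model.topology.n_circ,
            "n_long": model.topology.n_long,
        }
        if model.topology is not None
        else None,
    }
    Path(path).write_text(_canonical_dump(doc))


def load_shape_model(path):
    from .pca import ShapeModel

    doc = json.loads(Path(path).read_text())
    if doc.get("kind") != "shape_model":
        raise SchemaError("not a shape-model document")
    topo = doc.get("topology")
    return ShapeModel(
        mean=np.asarray(doc["mean"]),
        modes=np.asarray(doc["modes"]),
        variances=np.asarray(doc["variances"]),
        n_retained=doc["n_retained"],
        n_train=doc["n_train"],
        topology=None if topo is None else LatticeTopology(**topo),
    )


def serialize_lvas(model, path) -> None:
    doc = {
        "kind": "lvas_model",
        "weights": model.weights.tolist(),
        "selected_mode_indices": [int(i) for i in model.selected_mode_indices],
        "lambda_selected": model.lambda_selected,
        "cv_lambdas": model.cv_lambdas.tolist(),
        "cv_values": model.cv_values.tolist(),
        "raw_score_min": model.raw_score_min,
        "raw_score_max": model.raw_score_max,
        "quartile_cutpoints": model.quartile_cutpoints.tolist(),
    }
    Path(path).write_text(_canonical_dump(doc))


def load_lvas(path):
    from .lvas import LVASModel

    doc = json.loads(Path(path).read_text())
    if doc.get("kind") != "lvas_model":
        raise SchemaError("not an LVAS-model document")
    return LVASModel(
        weights=np.asarray(doc["weights"]),
        selected_mode_indices=tuple(doc["selected_mode_indices"]),
        lambda_selected=doc["lambda_selected"],
        cv_lambdas=np.asarray(doc["cv_lambdas"]),
        cv_values=np.asarray(doc["cv_values"]),
        raw_score_min=doc["raw_score_min"],
        raw_score_max=doc["raw_score_max"],
        quartile_cutpoints=np.asarray(doc["quartile_cutpoints"]),
    )
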