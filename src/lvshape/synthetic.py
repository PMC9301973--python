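"""Synthetic LV cohorts with known ground truth.

Generates anatomy (template + planted orthonormal deformation modes),
short-axis contour renderings, proportional-hazards outcomes, and
baseline covariates with optional confounding and missingness, all from
one integer master seed.  Every downstream stage of the pipeline can be
tested against the returned truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ContourSlice, ContourStack, CohortTable
from .mesh import LatticeTopology, LVMesh, build_ellipsoid_mesh, slice_surface

# named substreams of the master seed; order must never change
_STREAMS = {"anatomy": 0, "outcomes": 1, "covariates": 2, "render": 3, "devices": 4}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG substream of one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],))
    )


@dataclass(frozen=True)
class TemplateParams:
    semi_axes: tuple[float, float, float] = (32.0, 32.0, 78.0)
    wall_thickness: float = 8.0
    truncation_height: float = 70.0


@dataclass
class SyntheticTruth:
    """Ground truth underlying one synthetic cohort."""

    template_params: TemplateParams = field(default_factory=TemplateParams)
    planted_modes: np.ndarray | None = None  # (K, D) orthonormal rows
    mode_sd: tuple[float, ...] = (6.0, 4.0, 3.0)
    planted_log_hr: tuple[float, ...] = (0.0, 0.0, 0.7 / 3.0)  # per unit (mm) coeff
    baseline_hazard_rate: float = 0.015  # events / year
    censor_rate: float = 0.10  # / year
    horizon_years: float = 16.0
    confounding_coeffs: dict = field(default_factory=dict)  # covariate -> (K,) per-sd
    covariate_log_hr: dict = field(default_factory=dict)  # direct hazard effects
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_hazard_rate <= 0:
            raise ValueError("baseline_hazard_rate must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")
        if any(sd < 0 for sd in self.mode_sd):
            raise ValueError("mode_sd must be non-negative")
        if self.planted_modes is not None:
            G = self.planted_modes @ self.planted_modes.T
            if not np.allclose(G, np.eye(len(G)), atol=1e-8):
                raise ValueError("planted modes are not orthonormal")


# ---------------------------------------------------------------------------
# template and planted deformation fields
# ---------------------------------------------------------------------------

def make_template(
    params: TemplateParams, topology: LatticeTopology | None = None
) -> LVMesh:
    """Idealised truncated half-ellipsoid LV sized to the given parameters."""
    return build_ellipsoid_mesh(
        params.semi_axes,
        params.wall_thickness,
        params.truncation_height,
        topology=topology,
    )


def deformation_field(template: LVMesh, kind: str) -> np.ndarray:
    """Smooth low-order deformation field on the template lattice,
    flattened to shape-vector layout and unit-normalised.

    Kinds: ``size`` (isotropic scaling), ``long_axis_stretch`` (elongate
    while narrowing: a sphericity direction), ``base_widening`` (radial
    dilation ramping toward the base), ``basal_lateral_thinning``
    (endocardium pushed outward in the basal lateral wall).
    """
    nodes = template.all_nodes()
    com = nodes.mean(axis=0)
    rel = nodes - com
    zmin, zmax = nodes[:, 2].min(), nodes[:, 2].max()
    zr = (nodes[:, 2] - zmin) / (zmax - zmin)  # 0 apex .. 1 base
    radial = np.column_stack([rel[:, 0], rel[:, 1], np.zeros(len(rel))])

    if kind == "size":
        f = rel.copy()
    elif kind == "long_axis_stretch":
        f = np.column_stack([-0.4 * rel[:, 0], -0.4 * rel[:, 1], rel[:, 2]])
    elif kind == "base_widening":
        w = np.clip(2.0 * zr - 1.0, 0.0, None)  # ramps over the basal half
        f = w[:, None] * radial
    elif kind == "basal_lateral_thinning":
        r = np.linalg.norm(rel[:, :2], axis=1)
        lateral = np.clip(-rel[:, 0] / np.where(r > 1e-9, r, 1.0), 0.0, None)
        w = np.clip(2.0 * zr - 1.0, 0.0, None) * lateral
        f = w[:, None] * radial
        k = template.topology.nodes_per_surface
        f[k:] = 0.0  # endo only: moves endo toward epi => wall thins
    else:
        raise ValueError(f"unknown deformation field kind: {kind!r}")
    v = f.ravel()
    return v / np.linalg.norm(v)


def make_planted_modes(
    template: LVMesh,
    kinds: tuple[str, ...] = ("size", "long_axis_stretch", "arrhythmic"),
) -> np.ndarray:
    """Mutually orthonormal planted modes (Gram-Schmidt over smooth
    fields).  The ``arrhythmic`` kind mixes base widening with basal
    lateral wall thinning, mirroring a wide-base/parabolic direction."""
    fields = []
    for kind in kinds:
        if kind == "arrhythmic":
            v = deformation_field(template, "base_widening") + 0.6 * deformation_field(
                template, "basal_lateral_thinning"
            )
            v = v / np.linalg.norm(v)
        else:
            v = deformation_field(template, kind)
        fields.append(v)
    modes = []
    for v in fields:
        for u in modes:
            v = v - (u @ v) * u
        n = np.linalg.norm(v)
        if n < 1e-10:
            raise ValueError("planted fields are linearly dependent")
        modes.append(v / n)
    return np.vstack(modes)


#: per-node RMS displacement (mm) of one coefficient sd for the default
#: planted modes: size dominates, then elongation, then the arrhythmic
#: direction (kept small enough that +/-3 sd never inverts the wall)
_DEFAULT_MODE_RMS = (2.5, 1.2, 0.5)


def default_truth(
    seed: int = 0, topology: LatticeTopology | None = None, **overrides
) -> SyntheticTruth:
    """Cohort-realistic truth: planted modes are unit-norm in shape-vector
    space, so coefficient sds are scaled by sqrt(vector length) to reach
    the per-node RMS displacement targets, and the planted hazard is
    0.7 log-HR per sd of the arrhythmic mode."""
    params = overrides.pop("template_params", TemplateParams())
    template = make_template(params, topology)
    scale = np.sqrt(template.topology.vector_length)
    if "mode_sd" not in overrides:
        overrides["mode_sd"] = tuple(r * scale for r in _DEFAULT_MODE_RMS)
    if "planted_log_hr" not in overrides:
        sd = overrides["mode_sd"]
        overrides["planted_log_hr"] = (
            0.0, 0.0, 0.7 / sd[2] if sd[2] > 0 else 0.0
        )
    truth = SyntheticTruth(
        template_params=params,
        planted_modes=make_planted_modes(template),
        seed=seed,
        **overrides,
    )
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_shapes(
    template: LVMesh,
    truth: SyntheticTruth,
    n: int,
    covariates: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[LVMesh], np.ndarray]:
    """Draw ``n`` meshes as template + sum_k c_k * mode_k with
    c_k ~ Normal(0, mode_sd_k^2); returns the true coefficients.

    When ``truth.confounding_coeffs`` is non-empty and covariates are
    supplied, standardized covariates are added into the coefficient
    generator so the resulting shape score is confounded.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    truth.validate()
    modes = truth.planted_modes
    if modes is None:
        raise ValueError("truth has no planted modes")
    if modes.shape[1] != template.topology.vector_length:
        raise ValueError(
            f"planted mode dimension {modes.shape[1]} does not match template "
            f"shape vector ({template.topology.vector_length})"
        )
    rng = rng or substream(truth.seed, "anatomy")
    k = modes.shape[0]
    sd = np.asarray(truth.mode_sd, dtype=float)
    coeffs = rng.normal(0.0, 1.0, size=(n, k)) * sd
    if truth.confounding_coeffs and covariates is not None:
        for cov, gamma in truth.confounding_coeffs.items():
            x = covariates[cov].to_numpy(dtype=float)
            xs = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
            coeffs += np.outer(xs, np.asarray(gamma, dtype=float) * sd)
    base = template.to_vector()
    meshes = [
        LVMesh.from_vector(
            base + coeffs[i] @ modes, template.topology, patient_id=f"synth{i:04d}"
        )
        for i in range(n)
    ]
    return meshes, coeffs


def _reorder_star(poly: np.ndarray) -> np.ndarray:
    """Sort polygon vertices by angle about the centroid.

    Heavy per-point jitter on a tightly sampled contour can swap adjacent
    vertices and self-intersect the polygon; near-circular contours are
    star-shaped, so an angular sort restores simplicity without moving
    any point.
    """
    c = poly.mean(axis=0)
    ang = np.arctan2(poly[:, 1] - c[1], poly[:, 0] - c[0])
    return poly[np.argsort(ang, kind="stable")]


def render_contours(
    mesh: LVMesh,
    slice_thickness: float,
    in_plane_res: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    supra_basal: int = 0,
    landmark_angle: float = 0.0,
    landmark_offset: float = 5.0,
    thickness_range: tuple[float, float] = (7.0, 10.5),
) -> ContourStack:
    """Slice a mesh into short-axis epi/endo contour polygons.

    Slice planes sit at ``z_endo_min + (k + 1/2) * slice_thickness`` so a
    mesh of endocardial extent L yields floor(L / thickness) slices.
    Isotropic in-plane Gaussian jitter of sd ``noise_sd`` is added per
    point, and the RV landmark is placed ``landmark_offset`` mm outside
    the epi contour of the most basal (non-supra-basal) slice at a fixed
    angle from +x.  ``supra_basal`` extra slices are appended above the
    base (copies of the basal contours) to exercise basal truncation.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lo, hi = thickness_range
    if not lo <= slice_thickness <= hi:
        raise ValueError(
            f"slice_thickness {slice_thickness} outside the configured "
            f"range [{lo}, {hi}] mm"
        )
    topo = mesh.topology
    z0, z1 = mesh.endo[:, 2].min(), mesh.endo[:, 2].max()
    n_slices = int(np.floor((z1 - z0) / slice_thickness + 1e-9))
    if n_slices < 3:
        raise ValueError(
            f"slice thickness {slice_thickness} mm yields {n_slices} slices for a "
            f"{z1 - z0:.1f} mm mesh; at least 3 are required"
        )
    rng = np.random.default_rng(seed)
    slices = []
    for k in range(n_slices):
        z = z0 + (k + 0.5) * slice_thickness
        endo = slice_surface(mesh.endo, topo, z)
        epi = slice_surface(mesh.epi, topo, z)
        if endo is None or epi is None:
            continue
        if noise_sd > 0:
            endo = _reorder_star(endo + rng.normal(0.0, noise_sd, size=endo.shape))
            epi = _reorder_star(epi + rng.normal(0.0, noise_sd, size=epi.shape))
        slices.append(ContourSlice(z=z, epi=epi, endo=endo))

    basal = slices[-1]
    cen = basal.epi.mean(axis=0)
    direction = np.array([np.cos(landmark_angle), np.sin(landmark_angle)])
    radii = (basal.epi - cen) @ direction
    lm_xy = cen + (radii.max() + landmark_offset) * direction
    landmark = np.array([lm_xy[0], lm_xy[1], basal.z])

    for s in range(supra_basal):
        z = basal.z + (s + 1) * slice_thickness
        slices.append(ContourSlice(z=z, epi=basal.epi.copy(), endo=basal.endo.copy()))

    return ContourStack(
        patient_id=mesh.patient_id or "synthetic",
        slices=slices,
        slice_thickness=slice_thickness,
        in_plane_res=in_plane_res,
        rv_landmark=landmark,
        meta={"supra_basal": supra_basal},
    )


def simulate_outcomes(
    coefficients: np.ndarray,
    truth: SyntheticTruth,
    seed: int | None = None,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Exponential event times under the planted proportional-hazards
    model, with independent exponential censoring and an administrative
    follow-up horizon.

    hazard_i = baseline * exp(sum_k log_hr_k * c_ik + direct covariate
    effects).  Returns follow_up_years, event, and the latent
    (uncensored) event_time_years for diagnostics.
    """
    truth.validate()
    coeffs = np.atleast_2d(np.asarray(coefficients, dtype=float))
    log_hr = np.asarray(truth.planted_log_hr, dtype=float)
    if coeffs.shape[1] != log_hr.size:
        raise ValueError(
            f"coefficients have {coeffs.shape[1]} modes but truth plants {log_hr.size}"
        )
    eta = coeffs @ log_hr
    if covariates is not None:
        for cov, b in truth.covariate_log_hr.items():
            x = covariates[cov].to_numpy(dtype=float)
            eta = eta + b * x
    rates = truth.baseline_hazard_rate * np.exp(eta)
    if np.any(~np.isfinite(rates)) or np.any(rates <= 0):
        raise ValueError("non-positive or non-finite hazard rates")
    rng = (
        substream(truth.seed, "outcomes")
        if seed is None
        else np.random.default_rng(seed)
    )
    t_event = rng.exponential(1.0 / rates)
    if truth.censor_rate > 0:
        t_cens = rng.exponential(1.0 / truth.censor_rate, size=len(rates))
    else:
        t_cens = np.full(len(rates), np.inf)
    t_cens = np.minimum(t_cens, truth.horizon_years)
    follow = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "follow_up_years": follow,
            "event": event,
            "event_time_years": t_event,
        }
    )


_MISSING_COLS = ("smoking_status", "af_history", "mitral_regurg")


def simulate_covariates(
    n: int,
    confounding_coeffs: dict | None = None,
    missing_frac: float = 0.0,
    seed: int = 0,
    missing_cols: tuple[str, ...] = _MISSING_COLS,
) -> pd.DataFrame:
    """Baseline covariate table: a mix of continuous and binary columns
    at roughly cohort-realistic marginals, with MCAR missingness applied
    to the designated columns.

    ``confounding_coeffs`` is carried by :class:`SyntheticTruth` and
    applied inside :func:`sample_shapes`; it is accepted here only so a
    caller can document intent in one place.
    """
    del confounding_coeffs  # injection happens in sample_shapes
    if not 0 <= missing_frac < 1:
        raise ValueError(f"missing_frac must be in [0, 1), got {missing_frac}")
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "age": rng.normal(58.0, 12.0, n).round(1),
            "sex": rng.binomial(1, 0.82, n),
            "bsa": rng.normal(2.0, 0.25, n).round(2),
            "lvef": np.clip(rng.normal(38.0, 12.0, n), 10, 70).round(1),
            "nyha_34": rng.binomial(1, 0.17, n),
            "alcohol_excess": rng.binomial(1, 0.16, n),
            "beta_blocker": rng.binomial(1, 0.82, n),
            "lv_mass_index": rng.normal(96.0, 25.0, n).round(1),
            "lge_volume": rng.lognormal(np.log(7.0), 0.6, n).round(2),
            "smoking_status": rng.integers(0, 3, n),
            "af_history": rng.binomial(1, 0.32, n),
            "mitral_regurg": rng.binomial(1, 0.57, n),
        }
    )
    if missing_frac > 0:
        for col in missing_cols:
            mask = rng.random(n) < missing_frac
            df.loc[mask, col] = np.nan
    return df


# ---------------------------------------------------------------------------
# whole-cohort orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    truth: SyntheticTruth
    template: LVMesh
    meshes: list[LVMesh]
    coefficients: np.ndarray
    stacks: list[ContourStack]
    covariates: pd.DataFrame
    cohort: CohortTable


def generate_cohort(
    n: int = 156,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
    topology: LatticeTopology | None = None,
    noise_sd: float = 0.5,
    missing_frac: float = 0.0,
    render: bool = True,
    icd_frac: float = 0.52,
    crt_frac_of_icd: float = 0.55,
) -> SyntheticCohort:
    """End-to-end synthetic cohort; bit-reproducible for a fixed seed."""
    if truth is None:
        truth = default_truth(seed=seed, topology=topology)
    else:
        truth = SyntheticTruth(**{**truth.__dict__, "seed": seed})
    template = make_template(truth.template_params, topology)
    if truth.planted_modes is None:
        truth.planted_modes = make_planted_modes(template)

    cov_rng = substream(seed, "covariates")
    covariates = simulate_covariates(
        n, missing_frac=missing_frac, seed=cov_rng.integers(2**31)
    )
    meshes, coeffs = sample_shapes(template, truth, n, covariates=covariates)
    outcomes = simulate_outcomes(coeffs, truth, covariates=covariates)

    dev_rng = substream(seed, "devices")
    follow = outcomes["follow_up_years"].to_numpy()
    has_icd = dev_rng.random(n) < icd_frac
    icd_time = np.where(has_icd, dev_rng.uniform(0, 1, n) * follow, np.nan)
    has_crt = has_icd & (dev_rng.random(n) < crt_frac_of_icd)
    crt_time = np.where(has_crt, icd_time, np.nan)

    table = covariates.copy()
    table["follow_up_years"] = outcomes["follow_up_years"]
    table["event"] = outcomes["event"]
    table["icd_time_years"] = icd_time
    table["crt_time_years"] = crt_time
    cohort = CohortTable(table)

    stacks = []
    if render:
        render_rng = substream(seed, "render")
        for i, mesh in enumerate(meshes):
            thickness = float(render_rng.uniform(7.0, 10.5))
            res = float(render_rng.uniform(1.3, 2.2))
            stacks.append(
                render_contours(
                    mesh,
                    slice_thickness=thickness,
                    in_plane_res=res,
                    noise_sd=noise_sd,
                    seed=int(render_rng.integers(2**31)),
                )
            )
    return SyntheticCohort(
        truth=truth,
        template=template,
        meshes=meshes,
        coefficients=coeffs,
        stacks=stacks,
        covariates=covariates,
        cohort=cohort,
    )
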