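"""Synthetic tooth meshes, simulated resorption and full two-group cohorts.

The study conditions this generator emulates: posterior maxillary teeth
(first/second premolars and first molars) scanned at two timepoints in
independent scanner coordinate frames, with external root resorption
between the timepoints localized to the root apices and the buccal /
bucco-medial root surface. Two treatment groups (tooth-borne vs
bone-borne expansion appliances) differ in effect size; lower teeth act
as an untreated control arch whose changes are measurement noise around
zero. Per-tooth volume loss (mm^3), per-root length loss (mm) and
per-patient arch-width changes are drawn from configurable normal
distributions whose defaults are the group means and SDs reported for
this design.

Teeth are stylized surfaces (rounded crown frustum plus tapered root
tubes), not anatomical atlases: the measurement pipeline only needs
plausible topology, scale and landmark geometry. Every generated tooth
carries an exact, mesh-measured ground truth so parameter recovery can
be asserted end to end.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .mesh_core import Plane, TriangleMesh, ValidationError, cut_mesh, mesh_volume
from .registration import RigidTransform
from .root_analysis import (
    LandmarkSet,
    REGISTRATION_POINTS,
    build_radicular_template,
    cusp_for_root,
    root_length,
    roots_for,
)

__all__ = [
    "ToothTemplateSpec",
    "ResorptionSpec",
    "GroundTruth",
    "CohortSpec",
    "generate_tooth",
    "apply_resorption",
    "default_lacuna_sites",
    "draw_tooth_effects",
    "perturb_frame",
    "generate_cohort",
    "DEFAULT_EFFECTS",
]


# ---------------------------------------------------------------------------
# default effect tables: (mean, SD) of T0-T1 changes per group
#
# Upper (test) arch volume loss in mm^3 and per-root length loss in mm;
# lower (control) arch values are noise around zero, including small
# negative "losses" (apparent gain from continuing root development /
# cementum apposition). Arch-width changes (PWE/DAE = palatal and
# dento-alveolar width, T0 minus T1, negative under expansion) in mm.

DEFAULT_EFFECTS: dict = {
    "TB": {
        "upper": {
            "delta_v": {"P1": (9.74, 3.77), "P2": (8.23, 3.11), "M1": (26.21, 10.03)},
            "delta_length": {
                "P1": (0.51, 0.18),
                "P2": (0.39, 0.14),
                "M1m": (0.37, 0.10),
                "M1d": (0.43, 0.14),
                "M1p": (0.56, 0.19),
            },
        },
        "lower": {
            "delta_v": {"P1": (-0.25, 0.94), "P2": (-0.06, 0.76), "M1": (0.37, 1.34)},
            "delta_length": {
                "P1": (0.02, 0.21),
                "P2": (-0.06, 0.13),
                "M1m": (0.09, 0.48),
                "M1d": (0.01, 0.52),
            },
        },
        "expansion": {
            "PWE": {"P1": (-1.83, 0.64), "P2": (-1.60, 0.51), "M1": (-1.54, 0.48)},
            "DAE": {"P1": (-5.04, 1.79), "P2": (-4.73, 1.81), "M1": (-5.59, 1.68)},
        },
    },
    "BB": {
        "upper": {
            "delta_v": {"P1": (1.45, 0.64), "P2": (1.68, 0.53), "M1": (4.62, 3.12)},
            "delta_length": {
                "P1": (0.08, 0.03),
                "P2": (0.11, 0.02),
                "M1m": (0.10, 0.04),
                "M1d": (0.09, 0.02),
                "M1p": (0.15, 0.04),
            },
        },
        "lower": {
            "delta_v": {"P1": (-0.12, 0.76), "P2": (0.05, 0.41), "M1": (0.26, 1.21)},
            "delta_length": {
                "P1": (-0.05, 0.30),
                "P2": (0.04, 0.11),
                "M1m": (0.03, 0.35),
                "M1d": (0.04, 0.55),
            },
        },
        "expansion": {
            "PWE": {"P1": (-2.62, 1.22), "P2": (-2.29, 1.15), "M1": (-2.22, 1.13)},
            "DAE": {"P1": (-4.14, 1.92), "P2": (-3.99, 1.50), "M1": (-4.38, 1.57)},
        },
    },
}

#: gender split per group at n=20 (males, females) and age (mean, SD) years
DEFAULT_DEMOGRAPHICS = {"TB": (9, 11, 13.1, 1.08), "BB": (8, 12, 14.5, 1.11)}

# target radicular (below-CEJ) volumes per root, mm^3 — chosen so that
# the simulated absolute losses translate into percentage losses of the
# observed magnitude (a first molar root complex of ~315 mm^3, premolar
# roots of 120-130 mm^3)
_ROOT_VOLUME_TARGETS = {
    "P1": {"P1": 120.0},
    "P2": {"P2": 130.0},
    "M1": {"M1m": 100.0, "M1d": 95.0, "M1p": 120.0},
}


@dataclass
class ToothTemplateSpec:
    """Parametric description of one stylized tooth."""

    tooth_class: str
    arch: str = "upper"
    crown_height: float = 7.0
    crown_radius: float = 3.8
    # per-root: cusp-to-apex distance (mm) and horizontal apex offset
    root_lengths: dict = field(default_factory=dict)
    root_apex_offsets: dict = field(default_factory=dict)
    root_volumes: dict = field(default_factory=dict)
    taper_exponent: float = 0.45
    mesh_resolution: float = 0.7  # target ring spacing, mm
    n_theta: int = 20
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.roots = roots_for(self.tooth_class, self.arch)
        if any(length <= 0 for length in self.root_lengths.values()):
            raise ValidationError("root lengths must be positive")

    @classmethod
    def for_class(
        cls, tooth_class: str, arch: str = "upper", scale: float = 1.0, **overrides
    ) -> "ToothTemplateSpec":
        if tooth_class in ("P1", "P2"):
            base = dict(
                crown_height=7.0,
                crown_radius=3.8,
                root_lengths={tooth_class: 20.5 if tooth_class == "P1" else 20.0},
                root_apex_offsets={tooth_class: (0.4, 0.0)},
                root_volumes=dict(_ROOT_VOLUME_TARGETS[tooth_class]),
            )
        elif tooth_class == "M1":
            roots = roots_for("M1", arch)
            offsets = {"M1m": (2.2, 2.2), "M1d": (2.2, -2.2), "M1p": (-2.8, 0.0)}
            lengths = {"M1m": 19.5, "M1d": 19.0, "M1p": 20.0}
            base = dict(
                crown_height=6.5,
                crown_radius=5.0,
                root_lengths={r: lengths[r] for r in roots},
                root_apex_offsets={r: offsets[r] for r in roots},
                root_volumes={r: _ROOT_VOLUME_TARGETS["M1"][r] for r in roots},
            )
        else:
            raise ValidationError(f"unknown tooth class {tooth_class!r}")
        base.update(overrides)
        return cls(tooth_class=tooth_class, arch=arch, scale=scale, **base)


@dataclass
class ResorptionSpec:
    """What to remove from (or add to) a T0 tooth to make its T1 state.

    ``apical_truncation`` maps root label to the cusp-apex length change
    (mm); positive shortens the root by a capped apical cut, negative
    models slight apical extension. ``lacuna_sites`` are
    ``(point, radius_mm, depth_mm)`` triples on the root surface; depth
    is the inward displacement at the lacuna centre (negative = outward
    apposition). ``target_volume_loss`` (mm^3), if given, rescales the
    lacuna depths so the total mesh-measured radicular volume change
    hits the target.
    """

    apical_truncation: dict = field(default_factory=dict)
    lacuna_sites: list = field(default_factory=list)
    target_volume_loss: float | None = None

    def __post_init__(self) -> None:
        for point, radius, depth in self.lacuna_sites:
            if radius <= 0:
                raise ValidationError("lacuna radius must be positive")


@dataclass
class GroundTruth:
    """Mesh-measured truth for one generated T0/T1 pair."""

    true_volume_loss: float
    v0: float
    true_length_change: dict
    true_rigid_perturbation: RigidTransform | None = None


@dataclass
class CohortSpec:
    """Study design of a simulated two-group cohort."""

    n_per_group: int = 20
    seed: int = 0
    tooth_classes: tuple = ("P1", "P2", "M1")
    sides: tuple = ("R", "L")
    include_control: bool = True
    effects: dict = field(default_factory=lambda: DEFAULT_EFFECTS)
    # latent correlation between a tooth's volume loss and its length loss;
    # an assumption (no per-tooth correlation is reported), not a fitted value
    volume_length_corr: float = 0.5
    landmark_jitter: float = 0.2  # mm, manual landmark picking noise at T1
    frame_rotation_deg: float = 15.0  # independent scanner frame per timepoint
    frame_translation_mm: float = 8.0
    crown_scale_sd: float = 0.03  # per-tooth anatomical size variation
    mesh_resolution: float = 0.7
    lacunae_per_root: int = 3

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("need at least 2 patients per group")
        for group in self.effects.values():
            for arch in ("upper", "lower"):
                for table in group.get(arch, {}).values():
                    for mean, sd in table.values():
                        if sd < 0:
                            raise ValidationError("effect SDs must be non-negative")


# ---------------------------------------------------------------------------
# tooth construction

def _ring(center: np.ndarray, radius: float, n_theta: int, phase: float = 0.0) -> np.ndarray:
    th = 2 * np.pi * np.arange(n_theta) / n_theta + phase
    return np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th), np.full(n_theta, center[2])]
    )


def _tube(rings: list[np.ndarray], bottom: np.ndarray, top: np.ndarray) -> TriangleMesh:
    """Closed tube through horizontal rings, capped by apex fans.

    ``rings`` are ordered bottom to top; ``bottom``/``top`` are the cap
    apex points. Faces wind outward.
    """
    n_theta = len(rings[0])
    verts = [bottom[None, :]] + [r for r in rings] + [top[None, :]]
    v = np.concatenate(verts, axis=0)
    faces = []
    # bottom fan (outward: normal points downward)
    first = 1
    for i in range(n_theta):
        faces.append([0, first + (i + 1) % n_theta, first + i])
    for k in range(len(rings) - 1):
        a = 1 + k * n_theta
        b = a + n_theta
        for i in range(n_theta):
            i2 = (i + 1) % n_theta
            faces.append([a + i, b + i2, b + i])
            faces.append([a + i, a + i2, b + i2])
    top_idx = len(v) - 1
    last = 1 + (len(rings) - 1) * n_theta
    for i in range(n_theta):
        faces.append([top_idx, last + i, last + (i + 1) % n_theta])
    mesh = TriangleMesh(v, np.asarray(faces))
    # ensure outward orientation overall
    if mesh_volume_unchecked(mesh) < 0:
        mesh.faces = mesh.faces[:, [0, 2, 1]]
    return mesh


def mesh_volume_unchecked(mesh: TriangleMesh) -> float:
    tri = mesh.vertices[mesh.faces]
    return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


def _build_root_tube(
    spec: ToothTemplateSpec,
    root: str,
    cusp: np.ndarray,
    r0: float,
) -> TriangleMesh:
    """One tapered root tube from the cervical collar down to the apex."""
    ox, oy = spec.root_apex_offsets[root]
    ox, oy = ox * spec.scale, oy * spec.scale
    length = spec.root_lengths[root] * spec.scale
    lat2 = (ox - cusp[0]) ** 2 + (oy - cusp[1]) ** 2
    if length**2 <= lat2:
        raise ValidationError(f"root {root}: length shorter than lateral apex offset")
    za = cusp[2] - np.sqrt(length**2 - lat2)
    z_top = 1.2 * spec.scale
    top_center = np.array([0.35 * ox, 0.35 * oy, z_top])
    apex = np.array([ox, oy, za])
    n_rings = max(6, int(np.ceil((z_top - za) / spec.mesh_resolution)))
    rings = []
    for k in range(n_rings):
        s = k / (n_rings - 1)  # 0 at apex, 1 at top
        center = apex + s * (top_center - apex)
        radius = max(r0 * s**spec.taper_exponent, 0.12)
        rings.append(_ring(center, radius, spec.n_theta))
    top_apex = top_center + np.array([0.0, 0.0, 0.25])
    return _tube(rings, apex, top_apex)


def _build_crown(spec: ToothTemplateSpec) -> TriangleMesh:
    """Rounded frustum with a domed occlusal cap."""
    s = spec.scale
    z_bot, z_top = 0.4 * s, spec.crown_height * s
    n_rings = max(6, int(np.ceil((z_top - z_bot) / spec.mesh_resolution)))
    rings = []
    for k in range(n_rings):
        u = k / (n_rings - 1)
        radius = spec.crown_radius * s * (0.72 + 0.38 * np.sin(np.pi * u**0.9))
        rings.append(_ring(np.array([0.0, 0.0, z_bot + u * (z_top - z_bot)]), radius, spec.n_theta))
    bottom = np.array([0.0, 0.0, z_bot - 0.25 * s])
    dome = np.array([0.0, 0.0, z_top + 1.0 * s])
    return _tube(rings, bottom, dome)


def _concat(meshes: list[TriangleMesh], provenance: str = "") -> TriangleMesh:
    verts, faces, off = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + off)
        off += len(m.vertices)
    return TriangleMesh(np.concatenate(verts), np.concatenate(faces), provenance)


def _cusp_positions(spec: ToothTemplateSpec) -> dict:
    s = spec.scale
    ch = spec.crown_height * s
    if spec.tooth_class in ("P1", "P2"):
        return {"cusp_buccal": np.array([2.2 * s, 0.0, ch + 0.7 * s])}
    cusps = {
        "cusp_MB": np.array([2.6 * s, 2.4 * s, ch + 0.7 * s]),
        "cusp_DB": np.array([2.6 * s, -2.4 * s, ch + 0.7 * s]),
    }
    # the mesiolingual cusp exists on upper and lower molars alike
    cusps["cusp_ML"] = np.array([-2.6 * s, 2.4 * s, ch + 0.7 * s])
    return cusps


def generate_tooth(
    spec: ToothTemplateSpec, seed: int = 0
) -> tuple[TriangleMesh, LandmarkSet]:
    """Build a watertight tooth mesh with auto-placed landmarks.

    The local frame is anatomical: +x buccal, +y mesial, +z occlusal,
    CEJ near z=0. Root radial profiles are calibrated in closed form so
    each root's below-CEJ volume matches the spec target. Deterministic
    for a given (spec, seed).
    """
    rng = np.random.default_rng(seed)
    cusps = _cusp_positions(spec)
    parts = [_build_crown(spec)]
    cej_plane = Plane(np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]))
    for root in spec.roots:
        cusp = cusps[cusp_for_root(root)]
        tube = _build_root_tube(spec, root, cusp, r0=2.0)
        below = cut_mesh(tube, cej_plane, keep="below", cap=True)
        v_now = mesh_volume(below)
        target = spec.root_volumes[root] * spec.scale**3
        k = np.sqrt(target / v_now)
        # radial scaling about the tube's own centerline: cross-section
        # areas (and hence the cut volume) scale exactly by k^2
        tube2 = _build_root_tube(spec, root, cusp, r0=2.0 * k)
        parts.append(tube2)
    mesh = _concat(parts, provenance=f"synthetic-{spec.tooth_class}-{spec.arch}")

    landmarks = dict(cusps)
    for root in spec.roots:
        comp = parts[1 + list(spec.roots).index(root)]
        landmarks[f"apex_{root}"] = comp.vertices[np.argmin(comp.vertices[:, 2])]
    # CEJ landmarks: extreme buccal/lingual surface points at the CEJ level
    near_cej = mesh.vertices[np.abs(mesh.vertices[:, 2]) < 0.45 * spec.scale]
    landmarks["CEJB"] = near_cej[np.argmax(near_cej[:, 0])]
    landmarks["CEJL"] = near_cej[np.argmin(near_cej[:, 0])]
    # five registration points on the crown aspects + occlusal dome
    s = spec.scale
    mid_z = 0.55 * spec.crown_height * s
    r_mid = spec.crown_radius * s * (0.72 + 0.38 * np.sin(np.pi * 0.5))
    landmarks.update(
        {
            "reg_buccal": np.array([r_mid, 0.0, mid_z]),
            "reg_lingual": np.array([-r_mid, 0.0, mid_z]),
            "reg_mesial": np.array([0.0, r_mid, mid_z]),
            "reg_distal": np.array([0.0, -r_mid, mid_z]),
            "reg_occlusal": np.array([0.0, 0.0, spec.crown_height * s + 1.0 * s]),
        }
    )
    lm = LandmarkSet(spec.tooth_class, landmarks, spec.arch)
    if not mesh.is_watertight():  # pragma: no cover - construction guarantee
        raise RuntimeError("generated tooth is not watertight")
    return mesh, lm


# ---------------------------------------------------------------------------
# resorption

def _components(mesh: TriangleMesh) -> list[np.ndarray]:
    """Vertex-index sets of connected components."""
    e = np.concatenate([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    n = mesh.n_vertices
    adj = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    return [np.where(labels == c)[0] for c in range(n_comp)]


def _submesh(mesh: TriangleMesh, vert_idx: np.ndarray) -> TriangleMesh:
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    mask[vert_idx] = True
    fmask = mask[mesh.faces].all(axis=1)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[vert_idx] = np.arange(len(vert_idx))
    return TriangleMesh(mesh.vertices[vert_idx], remap[mesh.faces[fmask]], mesh.provenance)


def _solve_truncation(cusp: np.ndarray, apex: np.ndarray, target: float) -> float:
    """Axial cut height that changes the cusp-apex distance by ``target``.

    Solves |cusp - apex - t z| = L0 - target for t (the root tilts, so
    t is slightly larger than the length change itself).
    """
    rel = cusp - apex
    l0 = np.linalg.norm(rel)
    if target >= l0:
        raise ValidationError("truncation exceeds root length")
    # t^2 - 2 t rel_z + L0^2 - (L0-target)^2 = 0
    rz = rel[2]
    disc = rz**2 - (l0**2 - (l0 - target) ** 2)
    if disc < 0:
        raise ValidationError("truncation target unreachable for this root tilt")
    return rz - np.sqrt(disc)


def _lacuna_displacement(
    vertices: np.ndarray,
    axis_lines: dict,
    sites: list,
    scale: float,
) -> np.ndarray:
    """Inward (or outward) vertex displacement field from all lacunae.

    Displacement direction is horizontal, toward the nearest root
    centerline; magnitude is a Gaussian falloff from each site, clamped
    to 85% of the local radius so tubes never invert.
    """
    disp = np.zeros(len(vertices))
    for point, radius, depth in sites:
        d = np.linalg.norm(vertices - np.asarray(point), axis=1)
        disp += scale * depth * np.exp(-((d / radius) ** 2))
    # direction toward own root centerline
    dirs = np.zeros_like(vertices)
    radial = np.zeros(len(vertices))
    best = np.full(len(vertices), np.inf)
    for apex in axis_lines.values():
        rel = vertices[:, :2] - np.asarray(apex)[:2]
        r = np.linalg.norm(rel, axis=1)
        closer = r < best
        radial[closer] = r[closer]
        dirs[closer, :2] = -rel[closer] / np.maximum(r[closer, None], 1e-9)
        best[closer] = r[closer]
    limit = 0.85 * radial
    disp = np.clip(disp, -3.0, limit)  # outward growth capped at 3 mm
    return vertices + dirs * disp[:, None]


def apply_resorption(
    mesh: TriangleMesh,
    landmarks: LandmarkSet,
    spec: ResorptionSpec,
    seed: int = 0,
) -> tuple[TriangleMesh, GroundTruth]:
    """Produce the T1 state of a tooth and its mesh-measured ground truth.

    Apical length change is realized as a capped cut (or smooth apical
    extension for negative values) per root; lacunae displace root
    vertices with Gaussian falloff. With ``target_volume_loss`` set, a
    bisection on the global lacuna depth scale makes the radicular
    volume change match the target. Ground truth (volume loss below the
    CEJ plane and cusp-apex length changes) is measured on the actual
    output meshes.
    """
    comps = _components(mesh)
    root_comp: dict[str, int] = {}
    for root in landmarks.roots:
        apex = landmarks[f"apex_{root}"]
        dmin = [np.linalg.norm(mesh.vertices[c] - apex, axis=1).min() for c in comps]
        root_comp[root] = int(np.argmin(dmin))
    axis = landmarks.axis()

    pieces: dict[int, TriangleMesh] = {i: _submesh(mesh, c) for i, c in enumerate(comps)}

    # 1) apical truncation / extension per root
    for root, trunc in spec.apical_truncation.items():
        if root not in landmarks.roots:
            raise ValidationError(f"unknown root {root!r} in resorption spec")
        ci = root_comp[root]
        sub = pieces[ci]
        cusp = landmarks[cusp_for_root(root)]
        apex = landmarks[f"apex_{root}"]
        if trunc > 0:
            t = _solve_truncation(cusp, apex, trunc)
            plane = Plane(apex + t * np.array([0.0, 0.0, 1.0]), axis)
            cutted = cut_mesh(sub, plane, keep="above", cap=True)
            if cutted.n_faces == 0:
                raise ValidationError(f"truncation removed the whole root {root}")
            pieces[ci] = cutted
        elif trunc < 0:
            t = abs(_solve_truncation(cusp, apex, trunc))
            v = sub.vertices.copy()
            w = np.exp(-(np.linalg.norm(v - apex, axis=1) ** 2) / (2 * 1.2**2))
            v[:, 2] -= t * w
            pieces[ci] = TriangleMesh(v, sub.faces, sub.provenance)

    # 2) lacunae on the root components, optionally rescaled to a volume target
    root_cis = sorted(set(root_comp.values()))
    apex_lines = {r: landmarks[f"apex_{r}"] for r in landmarks.roots}

    def displaced(scale: float) -> dict[int, TriangleMesh]:
        out = dict(pieces)
        for ci in root_cis:
            sub = pieces[ci]
            v = _lacuna_displacement(sub.vertices, apex_lines, spec.lacuna_sites, scale)
            out[ci] = TriangleMesh(v, sub.faces, sub.provenance)
        return out

    def tube_loss(state: dict[int, TriangleMesh]) -> float:
        # lacunae sit well below the CEJ, so closed-tube volume change
        # equals the radicular volume change and needs no cutting
        v0 = sum(mesh_volume_unchecked(pieces[ci]) for ci in root_cis)
        v1 = sum(mesh_volume_unchecked(state[ci]) for ci in root_cis)
        return v0 - v1

    scale = 1.0
    if spec.lacuna_sites and spec.target_volume_loss is not None:
        trunc_state = displaced(0.0)
        # volume already removed by truncation, measured below the CEJ
        template, plane = build_radicular_template(mesh, landmarks)
        v0_root = mesh_volume(template)
        t1_trunc = _concat(list(trunc_state.values()), mesh.provenance)
        v_after_trunc = mesh_volume(cut_mesh(t1_trunc, plane, keep="below", cap=True))
        residual = spec.target_volume_loss - (v0_root - v_after_trunc)
        sign = 1.0 if residual >= 0 else -1.0
        magnitude = abs(residual)
        if magnitude < 1e-9:
            scale = 0.0
        else:
            # bisect on the magnitude; the sign (inward loss vs outward
            # apposition) is applied once, through the scale itself
            lo, hi = 0.0, 1.0
            while tube_loss(displaced(sign * hi)) * sign < magnitude and hi < 64:
                hi *= 2.0
            for _ in range(40):
                mid = (lo + hi) / 2.0
                if tube_loss(displaced(sign * mid)) * sign < magnitude:
                    lo = mid
                else:
                    hi = mid
            scale = sign * (lo + hi) / 2.0

    final = displaced(scale) if spec.lacuna_sites else dict(pieces)
    t1 = _concat([final[i] for i in sorted(final)], mesh.provenance + "|T1")

    # 3) measured ground truth
    template, plane = build_radicular_template(mesh, landmarks)
    v0_root = mesh_volume(template)
    v1_root = mesh_volume(cut_mesh(t1, plane, keep="below", cap=True))
    lengths = {
        r: root_length(landmarks, mesh, r) - root_length(landmarks, t1, r)
        for r in landmarks.roots
    }
    gt = GroundTruth(
        true_volume_loss=v0_root - v1_root,
        v0=v0_root,
        true_length_change=lengths,
        true_rigid_perturbation=None,
    )
    return t1, gt


def default_lacuna_sites(
    mesh: TriangleMesh,
    landmarks: LandmarkSet,
    rng: np.random.Generator,
    n_per_root: int = 3,
    buccal_halfangle_deg: float = 40.0,
) -> list:
    """Candidate lacuna sites on the buccal, apical-to-mid root surface.

    Sites are drawn from root vertices in the apical two thirds whose
    azimuth (about the root centerline) lies within the buccal sector
    (+x direction), matching where expansion forces compress the
    periodontal ligament.
    """
    axis = landmarks.axis()
    cej_h = float(((landmarks["CEJB"] + landmarks["CEJL"]) / 2.0) @ axis)
    sites = []
    for root in landmarks.roots:
        apex = landmarks[f"apex_{root}"]
        h = mesh.vertices @ axis
        apex_h = float(apex @ axis)
        span = cej_h - apex_h
        lo, hi = apex_h + 0.06 * span, apex_h + 0.55 * span
        rel = mesh.vertices[:, :2] - apex[:2]
        r = np.linalg.norm(rel, axis=1)
        with np.errstate(invalid="ignore"):
            cosang = np.where(r > 1e-9, rel[:, 0] / np.maximum(r, 1e-9), 0.0)
        near = np.linalg.norm(mesh.vertices - apex, axis=1) < 1.5 * span
        cand = np.where(
            (h > lo) & (h < hi) & near & (cosang > np.cos(np.deg2rad(buccal_halfangle_deg)))
        )[0]
        if not len(cand):
            continue
        pick = rng.choice(cand, size=min(n_per_root, len(cand)), replace=False)
        for i in pick:
            sites.append(
                (
                    mesh.vertices[i].copy(),
                    float(rng.uniform(1.4, 2.4)),
                    float(rng.uniform(0.5, 1.0)),
                )
            )
    return sites


def perturb_frame(
    mesh: TriangleMesh,
    landmarks: LandmarkSet,
    max_rotation_deg: float,
    max_translation_mm: float,
    seed: int = 0,
) -> tuple[TriangleMesh, LandmarkSet, RigidTransform]:
    """Move a tooth into an independent (scanner) coordinate frame.

    The same random rigid transform is applied to mesh and landmarks and
    returned so registration can be checked against it.
    """
    if max_rotation_deg < 0 or max_translation_mm < 0:
        raise ValidationError("perturbation bounds must be non-negative")
    rng = np.random.default_rng(seed)
    angle = np.deg2rad(rng.uniform(0, max_rotation_deg))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = RigidTransform(rot, direction * rng.uniform(0, max_translation_mm))
    moved = TriangleMesh(t.apply(mesh.vertices), mesh.faces.copy(), mesh.provenance)
    return moved, landmarks.transformed(t), t


# ---------------------------------------------------------------------------
# cohort generation

_ARCH_Y = {"P1": 20.0, "P2": 12.0, "M1": 4.0}
_PW_BASE = {"P1": 26.0, "P2": 29.0, "M1": 32.5}
_DAW_BASE = {"P1": 38.0, "P2": 42.0, "M1": 46.0}


def _arch_landmarks(widths: dict) -> dict:
    """Left/right arch landmark points realizing the given widths."""
    out: dict = {"PW": {}, "DAW": {}}
    for kind, zlev in (("PW", 10.0), ("DAW", 0.0)):
        for level, w in widths[kind].items():
            y = _ARCH_Y[level]
            out[kind][level] = {
                "right": [w / 2.0, y, zlev],
                "left": [-w / 2.0, y, zlev],
            }
    return out


def _draw_correlated(rng, rho: float):
    z1 = rng.standard_normal()
    z2 = rho * z1 + np.sqrt(max(1 - rho**2, 0.0)) * rng.standard_normal()
    return z1, z2


def draw_tooth_effects(
    effects_arch: dict,
    tooth_class: str,
    roots: tuple,
    rng: np.random.Generator,
    corr: float = 0.5,
    truncate_at_zero: bool = True,
) -> tuple[float, dict]:
    """Draw one tooth's (volume loss, per-root length loss) targets.

    Volume and length share a latent normal with correlation ``corr``;
    roots of the same tooth share a further latent (rho=0.7). Upper
    (test) teeth are truncated at zero — resorption cannot add tissue —
    while control teeth keep signed draws (measurement noise and
    apposition).
    """
    zv, zl = _draw_correlated(rng, corr)
    mv, sv = effects_arch["delta_v"][tooth_class]
    dv = mv + sv * zv
    if truncate_at_zero:
        dv = max(dv, 0.0)
    trunc = {}
    for rt in roots:
        ml, sl = effects_arch["delta_length"][rt]
        zr = 0.7 * zl + np.sqrt(1 - 0.7**2) * rng.standard_normal()
        dl = ml + sl * zr
        if truncate_at_zero:
            dl = max(dl, 0.0)
        trunc[rt] = dl
    return dv, trunc


def generate_cohort(spec: CohortSpec, out_dir) -> pd.DataFrame:
    """Write a full synthetic two-group cohort and return its manifest.

    Layout: one directory per patient with per-tooth T0/T1 STL files and
    landmark JSONs, per-timepoint arch landmark JSONs, plus cohort-level
    ``manifest.csv`` (per-tooth ground truth), ``length_truth.csv``
    (per-root), ``expansion_truth.csv``, ``demographics.csv`` and the
    fully-resolved ``cohort_spec.json``. Deterministic for a given seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_seq = np.random.SeedSequence(spec.seed)
    manifest_rows, length_rows, exp_rows, demo_rows = [], [], [], []

    arches = ("upper", "lower") if spec.include_control else ("upper",)
    for gi, group in enumerate(("TB", "BB")):
        males, females, age_mean, age_sd = DEFAULT_DEMOGRAPHICS[group]
        n_male = int(round(spec.n_per_group * males / (males + females)))
        for pi in range(spec.n_per_group):
            patient = f"{group}{pi:02d}"
            pdir = out / patient
            pdir.mkdir(exist_ok=True)
            pseed = np.random.SeedSequence([spec.seed, gi, pi])
            prng = np.random.default_rng(pseed)
            age = float(prng.normal(age_mean, age_sd))
            demo_rows.append(
                {
                    "patient": patient,
                    "group": group,
                    "gender": "M" if pi < n_male else "F",
                    "age": round(age, 1),
                }
            )
            # arch widths and their T0-T1 changes
            widths_t0 = {
                "PW": {lev: float(prng.normal(_PW_BASE[lev], 1.2)) for lev in spec.tooth_classes},
                "DAW": {lev: float(prng.normal(_DAW_BASE[lev], 1.6)) for lev in spec.tooth_classes},
            }
            widths_t1 = {"PW": {}, "DAW": {}}
            for kind, key in (("PW", "PWE"), ("DAW", "DAE")):
                for lev in spec.tooth_classes:
                    mean, sd = spec.effects[group]["expansion"][key][lev]
                    change = float(prng.normal(mean, sd))
                    widths_t1[kind][lev] = widths_t0[kind][lev] - change
                    exp_rows.append(
                        {
                            "patient": patient,
                            "group": group,
                            "level": lev,
                            "kind": key,
                            "true_change": change,
                        }
                    )
            (pdir / "arch_landmarks_T0.json").write_text(
                json.dumps(_arch_landmarks(widths_t0), indent=1)
            )
            (pdir / "arch_landmarks_T1.json").write_text(
                json.dumps(_arch_landmarks(widths_t1), indent=1)
            )

            for arch in arches:
                for cls in spec.tooth_classes:
                    for side in spec.sides:
                        trng = np.random.default_rng(
                            np.random.SeedSequence(
                                [spec.seed, gi, pi, arches.index(arch), spec.tooth_classes.index(cls), spec.sides.index(side)]
                            )
                        )
                        scale = float(np.clip(trng.normal(1.0, spec.crown_scale_sd), 0.9, 1.1))
                        tspec = ToothTemplateSpec.for_class(
                            cls, arch=arch, scale=scale, mesh_resolution=spec.mesh_resolution
                        )
                        t0, lm = generate_tooth(tspec, seed=int(trng.integers(2**31)))
                        dv, trunc = draw_tooth_effects(
                            spec.effects[group][arch],
                            cls,
                            lm.roots,
                            trng,
                            corr=spec.volume_length_corr,
                            truncate_at_zero=(arch == "upper"),
                        )
                        sites = default_lacuna_sites(
                            t0, lm, trng, n_per_root=spec.lacunae_per_root
                        )
                        rspec = ResorptionSpec(
                            apical_truncation=trunc,
                            lacuna_sites=sites,
                            target_volume_loss=dv,
                        )
                        t1, gt = apply_resorption(t0, lm, rspec, seed=int(trng.integers(2**31)))
                        t1m, lm1, rigid = perturb_frame(
                            t1,
                            lm,
                            spec.frame_rotation_deg,
                            spec.frame_translation_mm,
                            seed=int(trng.integers(2**31)),
                        )
                        gt.true_rigid_perturbation = rigid
                        # manual landmark picking noise at T1
                        if spec.landmark_jitter > 0:
                            for name in REGISTRATION_POINTS:
                                lm1.points[name] = lm1.points[name] + trng.normal(
                                    0, spec.landmark_jitter, 3
                                )
                        stem = f"{cls}_{side}_{arch}"
                        t0_path = pdir / f"{stem}_T0.stl"
                        t1_path = pdir / f"{stem}_T1.stl"
                        t0.to_trimesh().export(t0_path)
                        t1m.to_trimesh().export(t1_path)
                        (pdir / f"{stem}_T0.landmarks.json").write_text(lm.to_json())
                        (pdir / f"{stem}_T1.landmarks.json").write_text(lm1.to_json())
                        (pdir / f"{stem}_T1.transform.json").write_text(rigid.to_json())
                        manifest_rows.append(
                            {
                                "patient": patient,
                                "group": group,
                                "arch": arch,
                                "tooth_class": cls,
                                "side": side,
                                "t0_file": f"{patient}/{t0_path.name}",
                                "t1_file": f"{patient}/{t1_path.name}",
                                "true_v0_mm3": round(gt.v0, 6),
                                "true_delta_v_mm3": round(gt.true_volume_loss, 6),
                                "true_delta_v_pct": round(
                                    100.0 * gt.true_volume_loss / gt.v0, 6
                                ),
                            }
                        )
                        for rt, dl in gt.true_length_change.items():
                            length_rows.append(
                                {
                                    "patient": patient,
                                    "group": group,
                                    "arch": arch,
                                    "tooth_class": cls,
                                    "side": side,
                                    "root": rt,
                                    "true_delta_length_mm": round(dl, 6),
                                }
                            )

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(length_rows).to_csv(out / "length_truth.csv", index=False)
    pd.DataFrame(exp_rows).to_csv(out / "expansion_truth.csv", index=False)
    pd.DataFrame(demo_rows).to_csv(out / "demographics.csv", index=False)
    cfg = dataclasses.asdict(spec)
    (out / "cohort_spec.json").write_text(json.dumps(cfg, indent=1, default=str))
    return manifest
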