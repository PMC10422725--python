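"""Root isolation and longitudinal change measurement.

Implements the per-tooth measurement chain on a registered T0/T1 pair:

* root length — Euclidean distance from the assigned cusp tip to the
  most apical point of that root's surface;
* radicular template — the T0 model cut at the cemento-enamel junction
  (CEJ) plane, which also defines the synchronized crown cut applied to
  both timepoints;
* volume change — absolute (mm^3) and as a percentage of the T0 root
  volume;
* deviation field — signed nearest distance from every T0 root vertex
  to the T1 root surface (negative where the T1 surface lies inside the
  T0 surface, i.e. material loss), with the matching percentage: the
  share of samples within a tolerance band (default ±0.3 mm, the scan
  voxel size).

The CEJ plane is constructed to contain the buccal and lingual CEJ
landmarks; because two points underdetermine a plane, its normal is the
component of the tooth long axis orthogonal to the CEJB–CEJL line,
giving a near-transverse cervical cut.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._proximity import SurfaceDistance, ray_parity_inside, winding_number
from .mesh_core import Plane, TriangleMesh, ValidationError, cut_mesh, mesh_volume

__all__ = [
    "LandmarkSet",
    "RootMeasurement",
    "VolumeMeasurement",
    "DeviationField",
    "roots_for",
    "cusp_for_root",
    "root_length",
    "build_radicular_template",
    "cut_roots_synchronized",
    "volume_change",
    "deviation_analysis",
    "deviation_colors",
    "deviation_colormap",
    "sign_convention_check",
]

#: registration landmark names, in canonical order
REGISTRATION_POINTS = ("reg_buccal", "reg_lingual", "reg_mesial", "reg_distal", "reg_occlusal")

_ROOTS = {
    ("P1", "upper"): ("P1",),
    ("P2", "upper"): ("P2",),
    ("M1", "upper"): ("M1m", "M1d", "M1p"),
    ("P1", "lower"): ("P1",),
    ("P2", "lower"): ("P2",),
    # lower first molars have mesial and distal roots only
    ("M1", "lower"): ("M1m", "M1d"),
}

_CUSP_FOR_ROOT = {
    "M1m": "cusp_MB",
    "M1d": "cusp_DB",
    "M1p": "cusp_ML",
    "P1": "cusp_buccal",
    "P2": "cusp_buccal",
}

#: vertices within this band (mm) of the extreme apical height count as
#: candidate apex points; the one nearest their centroid is the apex.
APEX_TIE_BAND = 0.1


def roots_for(tooth_class: str, arch: str = "upper") -> tuple[str, ...]:
    try:
        return _ROOTS[(tooth_class, arch)]
    except KeyError:
        raise ValidationError(f"unknown tooth class/arch: {tooth_class}/{arch}") from None


def cusp_for_root(root: str) -> str:
    try:
        return _CUSP_FOR_ROOT[root]
    except KeyError:
        raise ValidationError(f"unknown root label {root!r}") from None


@dataclass
class LandmarkSet:
    """Named anatomical points (mm) of one tooth at one timepoint."""

    tooth_class: str
    points: dict
    arch: str = "upper"

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=np.float64).reshape(3) for k, v in self.points.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise ValidationError(
                f"landmark {name!r} missing for {self.tooth_class} ({self.arch})"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise ValidationError(f"missing landmarks: {missing}")

    @property
    def roots(self) -> tuple[str, ...]:
        return roots_for(self.tooth_class, self.arch)

    def registration_points(self) -> np.ndarray:
        self.require(*REGISTRATION_POINTS)
        return np.stack([self.points[n] for n in REGISTRATION_POINTS])

    def cusp_centroid(self) -> np.ndarray:
        cusps = {cusp_for_root(r) for r in self.roots}
        self.require(*cusps)
        return np.mean([self.points[c] for c in cusps], axis=0)

    def apex_centroid(self) -> np.ndarray:
        names = [f"apex_{r}" for r in self.roots]
        self.require(*names)
        return np.mean([self.points[n] for n in names], axis=0)

    def axis(self) -> np.ndarray:
        """Unit tooth long axis pointing occlusally (cusps minus apices)."""
        v = self.cusp_centroid() - self.apex_centroid()
        n = np.linalg.norm(v)
        if n < 1e-9:
            raise ValidationError("degenerate tooth axis")
        return v / n

    def transformed(self, t) -> "LandmarkSet":
        return LandmarkSet(
            self.tooth_class,
            {k: t.apply(v[None, :])[0] for k, v in self.points.items()},
            self.arch,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "tooth_class": self.tooth_class,
                "arch": self.arch,
                "points": {k: v.tolist() for k, v in self.points.items()},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LandmarkSet":
        d = json.loads(text)
        return cls(d["tooth_class"], d["points"], d.get("arch", "upper"))


@dataclass
class RootMeasurement:
    tooth_id: str
    root: str
    length_t0: float
    length_t1: float

    @property
    def delta_length(self) -> float:
        return self.length_t0 - self.length_t1


@dataclass
class VolumeMeasurement:
    tooth_id: str
    v_t0: float
    v_t1: float

    def __post_init__(self) -> None:
        if self.v_t0 <= 0 or self.v_t1 <= 0:
            raise ValidationError("root volumes must be positive")

    @property
    def delta_v(self) -> float:
        return self.v_t0 - self.v_t1

    @property
    def delta_v_pct(self) -> float:
        return 100.0 * self.delta_v / self.v_t0


@dataclass
class DeviationField:
    """Signed T0->T1 surface deviations sampled at all T0 root vertices."""

    points: np.ndarray
    distances: np.ndarray
    tolerance: float = 0.3

    @property
    def matching_pct(self) -> float:
        return float(100.0 * np.mean(np.abs(self.distances) <= self.tolerance + 1e-12))


# ---------------------------------------------------------------------------

def _apex_point(vertices: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Most apical point: lowest along the axis, ties broken centrally.

    A truncated (flat-cut) apex yields a ring of equally-low vertices;
    the point nearest the centroid of the low band (the cap centre) is
    the reproducible choice.
    """
    h = vertices @ axis
    band = vertices[h <= h.min() + APEX_TIE_BAND]
    centroid = band.mean(axis=0)
    return band[np.argmin(np.linalg.norm(band - centroid, axis=1))]


def _root_region(
    mesh: TriangleMesh, landmarks: LandmarkSet, root: str
) -> np.ndarray:
    """Vertices of the radicular surface assigned to one root.

    Radicular = below the CEJ midpoint along the tooth axis; multi-rooted
    assignment is by lateral distance to the axis-parallel line through
    each root's apex landmark.
    """
    axis = landmarks.axis()
    cej_h = float(((landmarks["CEJB"] + landmarks["CEJL"]) / 2.0) @ axis)
    h = mesh.vertices @ axis
    below = mesh.vertices[h < cej_h]
    if not len(below):
        return below
    lat = []
    for r in landmarks.roots:
        rel = below - landmarks[f"apex_{r}"]
        lat.append(np.linalg.norm(rel - np.outer(rel @ axis, axis), axis=1))
    owner = np.argmin(np.stack(lat, axis=1), axis=1)
    return below[owner == list(landmarks.roots).index(root)]


def root_length(
    landmarks: LandmarkSet,
    mesh: TriangleMesh,
    root: str,
    mode: str = "vertex",
) -> float:
    """Cusp-tip to root-apex distance (mm) for one root.

    ``mode="vertex"`` (default) re-detects the apex as the most apical
    mesh vertex of that root's region; ``mode="landmark"`` trusts the
    apex landmark instead.
    """
    cusp = landmarks[cusp_for_root(root)]
    if root not in landmarks.roots:
        raise ValidationError(f"root {root!r} not present on {landmarks.tooth_class}")
    if mode == "landmark":
        return float(np.linalg.norm(cusp - landmarks[f"apex_{root}"]))
    region = _root_region(mesh, landmarks, root)
    if not len(region):
        # region assignment ambiguous (e.g. cropped mesh): fall back
        return float(np.linalg.norm(cusp - landmarks[f"apex_{root}"]))
    apex = _apex_point(region, landmarks.axis())
    return float(np.linalg.norm(cusp - apex))


def cej_plane(landmarks: LandmarkSet) -> Plane:
    """Cervical cutting plane through CEJB and CEJL.

    Normal = component of the tooth long axis orthogonal to the
    CEJB-CEJL chord, oriented occlusally (roots on the negative side).
    """
    cejb, cejl = landmarks["CEJB"], landmarks["CEJL"]
    chord = cejl - cejb
    n_chord = np.linalg.norm(chord)
    if n_chord < 1e-9:
        raise ValidationError("CEJB and CEJL coincide")
    u = chord / n_chord
    axis = landmarks.axis()
    normal = axis - (axis @ u) * u
    if np.linalg.norm(normal) < 1e-9:
        raise ValidationError("tooth axis parallel to the CEJ chord")
    plane = Plane((cejb + cejl) / 2.0, normal)
    return plane.oriented_toward(landmarks.cusp_centroid())


def build_radicular_template(
    t0_mesh: TriangleMesh, landmarks: LandmarkSet
) -> tuple[TriangleMesh, Plane]:
    """Duplicate the T0 model and cut it at the CEJ plane, keeping the roots."""
    plane = cej_plane(landmarks)
    template = cut_mesh(t0_mesh, plane, keep="below", cap=True)
    if template.n_faces == 0:
        raise ValidationError("CEJ plane misses the mesh; no radicular side")
    template.provenance = f"{t0_mesh.provenance}|radicular-template"
    return template, plane


def cut_roots_synchronized(
    t0_mesh: TriangleMesh,
    t1_registered_mesh: TriangleMesh,
    template_plane: Plane,
) -> tuple[TriangleMesh, TriangleMesh]:
    """Remove both crowns at the same level.

    Both models (already in the same frame) are cut by the identical
    template plane, apical sides kept and capped, so any T0-T1 volume
    difference reflects surface change, not the cut.
    """
    t0_root = cut_mesh(t0_mesh, template_plane, keep="below", cap=True)
    t1_root = cut_mesh(t1_registered_mesh, template_plane, keep="below", cap=True)
    if t0_root.n_faces == 0 or t1_root.n_faces == 0:
        raise ValidationError("cut plane misses one of the meshes")
    t0_root.provenance = f"{t0_mesh.provenance}|root"
    t1_root.provenance = f"{t1_registered_mesh.provenance}|root"
    return t0_root, t1_root


def volume_change(
    t0_root: TriangleMesh, t1_root: TriangleMesh, tooth_id: str = ""
) -> VolumeMeasurement:
    return VolumeMeasurement(tooth_id, mesh_volume(t0_root), mesh_volume(t1_root))


def deviation_analysis(
    t0_root: TriangleMesh,
    t1_root: TriangleMesh,
    tolerance: float = 0.3,
) -> DeviationField:
    """Signed nearest distance from every T0 root vertex to the T1 surface.

    Sign is negative where the T0 point lies outside the T1 volume (the
    T1 surface receded inward: material loss) and positive where it lies
    inside (apparent gain); inside/outside via the generalized winding
    number, distance to the nearest point on the T1 triangle surface.
    """
    if t0_root.n_faces == 0 or t1_root.n_faces == 0:
        raise ValidationError("deviation analysis requires non-empty meshes")
    pts = t0_root.vertices
    d, _ = SurfaceDistance(t1_root.vertices, t1_root.faces).closest(pts)
    w = winding_number(pts, t1_root.vertices, t1_root.faces)
    sign = np.where(w > 0.5, 1.0, -1.0)
    return DeviationField(points=pts, distances=sign * d, tolerance=tolerance)


# colour anchors for the deviation map (uchar RGB)
_GREEN = np.array([0, 200, 0], dtype=np.float64)
_BLUE = np.array([0, 0, 255], dtype=np.float64)
_RED = np.array([255, 0, 0], dtype=np.float64)


def deviation_colors(
    distances: np.ndarray, tolerance: float = 0.3, clip_range: float = 0.5
) -> np.ndarray:
    """Per-sample RGB: green within ±tolerance, blue/red ramps outside.

    Ramps saturate at ±``clip_range`` mm.
    """
    if clip_range <= tolerance:
        raise ValidationError("clip_range must exceed the tolerance")
    d = np.asarray(distances, dtype=np.float64).reshape(-1)
    frac = np.clip((np.abs(d) - tolerance) / (clip_range - tolerance), 0.0, 1.0)
    out = np.empty((len(d), 3))
    neg = d < 0
    out[neg] = (1 - frac[neg, None]) * _GREEN + frac[neg, None] * _BLUE
    out[~neg] = (1 - frac[~neg, None]) * _GREEN + frac[~neg, None] * _RED
    return np.round(out).astype(np.uint8)


def deviation_colormap(field: DeviationField, clip_range: float = 0.5) -> np.ndarray:
    return deviation_colors(field.distances, field.tolerance, clip_range)


def sign_convention_check(
    t0_root: TriangleMesh,
    t1_root: TriangleMesh,
    n_samples: int = 200,
    seed: int = 0,
) -> dict:
    """Verify the deviation sign against an independent ray-parity test.

    For a sample of T0 vertices, the winding-number-based sign used by
    :func:`deviation_analysis` is compared with a ray-crossing parity
    inside/outside classification of the same points w.r.t. T1.
    Points essentially on the T1 surface (|d| < 1e-6) are excluded, as
    their sign is not meaningful.
    """
    field = deviation_analysis(t0_root, t1_root)
    rng = np.random.default_rng(seed)
    idx = np.arange(len(field.points))
    if len(idx) > n_samples:
        idx = rng.choice(idx, n_samples, replace=False)
    pts, d = field.points[idx], field.distances[idx]
    off = np.abs(d) > 1e-6
    inside_oracle = ray_parity_inside(pts[off], t1_root.vertices, t1_root.faces)
    agree = (d[off] > 0) == inside_oracle
    return {
        "n": int(off.sum()),
        "agreement_pct": float(100.0 * agree.mean()) if off.any() else 100.0,
        "all_agree": bool(agree.all()) if off.any() else True,
    }
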