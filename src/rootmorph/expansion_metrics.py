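"""Maxillary arch-width measurements and their longitudinal changes.

Skeletal (palatal width, PW) and dento-alveolar (DAW) widths are
Euclidean distances between paired left/right landmarks at the first
premolar, second premolar and first molar levels. Changes are reported
as T0 minus T1, so expansion (a wider arch at T1) yields negative
values (PWE/DAE). The anatomical placement of the landmark pairs is the
caller's responsibility (config-declared names); only the paired-point
distance computation lives here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .mesh_core import ValidationError

__all__ = ["ArchLandmarks", "ExpansionRecord", "width", "expansion_change"]

LEVELS = ("P1", "P2", "M1")
KINDS = ("PW", "DAW")


@dataclass
class ArchLandmarks:
    """Per-level left/right landmark pairs for one patient/timepoint.

    ``points[kind][level][side]`` is a 3D point in mm, ``kind`` in
    {"PW", "DAW"}, ``side`` in {"left", "right"}.
    """

    points: dict

    def get_pair(self, kind: str, level: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            pair = self.points[kind][level]
            left = np.asarray(pair["left"], dtype=np.float64).reshape(3)
            right = np.asarray(pair["right"], dtype=np.float64).reshape(3)
        except KeyError:
            raise ValidationError(f"missing {kind} landmark pair at level {level}") from None
        return left, right

    @classmethod
    def from_json(cls, text: str) -> "ArchLandmarks":
        return cls(json.loads(text))

    def to_json(self) -> str:
        return json.dumps(self.points, indent=1)


@dataclass
class ExpansionRecord:
    """T0-T1 width changes at one level (negative under expansion)."""

    level: str
    pwe: float
    dae: float


def width(landmarks: ArchLandmarks, level: str, kind: str) -> float:
    """Left-right distance (mm) of one landmark pair."""
    if kind not in KINDS:
        raise ValidationError(f"kind must be one of {KINDS}")
    left, right = landmarks.get_pair(kind, level)
    return float(np.linalg.norm(left - right))


def expansion_change(
    t0: ArchLandmarks, t1: ArchLandmarks, levels=LEVELS
) -> list[ExpansionRecord]:
    """PWE and DAE (T0 minus T1 widths) per level."""
    return [
        ExpansionRecord(
            level=lev,
            pwe=width(t0, lev, "PW") - width(t1, lev, "PW"),
            dae=width(t0, lev, "DAW") - width(t1, lev, "DAW"),
        )
        for lev in levels
    ]
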