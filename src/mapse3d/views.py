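"""Standardized midesophageal view geometry.

Three imaging planes — the LV long-axis view (LAX) and the two- and
four-chamber views (2C, 4C) — are obtained by rotating the slicing plane in
60 degree steps about the LV long axis.  Each plane intersects the mitral
annulus at two opposite azimuths, giving six wall landmarks per volume.

The azimuth origin of the LAX plane is an acquisition convention, not an
anatomical constant; the wall labels attached to the six azimuths follow the
standard midesophageal layout: LAX transects the anteroseptal and
inferolateral walls, 4C the inferoseptal and anterolateral walls, and 2C the
anterior and inferior walls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Six LV wall labels in azimuth order starting at the LAX plane azimuth.
WALL_ORDER: tuple[str, ...] = (
    "anteroseptal",   # lax + 0
    "inferoseptal",   # lax + 60   (4C plane)
    "anterior",       # lax + 120  (2C plane)
    "inferolateral",  # lax + 180
    "anterolateral",  # lax + 240
    "inferior",       # lax + 300
)

WALL_LABELS: frozenset[str] = frozenset(WALL_ORDER)

DEFAULT_ARC_HALFWIDTH_DEG = 15.0


def circular_delta_deg(a, b):
    """Signed smallest angular difference a - b in degrees, in (-180, 180]."""
    return (np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class ViewSet:
    """The three slicing planes and the wall-label -> azimuth convention."""

    lax_angle_deg: float
    view_angles: tuple[float, float, float]
    wall_azimuths: dict[str, float]
    arc_halfwidth_deg: float = DEFAULT_ARC_HALFWIDTH_DEG

    def __post_init__(self) -> None:
        if self.arc_halfwidth_deg <= 0:
            raise ValueError("arc_halfwidth_deg must be positive")
        angles = np.asarray(self.view_angles)
        if not np.allclose(np.diff(np.sort(angles % 180.0)), 60.0):
            raise ValueError("view angles must be separated by exactly 60 degrees")
        if set(self.wall_azimuths) != WALL_LABELS:
            raise ValueError(f"wall_azimuths must map exactly the labels {sorted(WALL_LABELS)}")


def slice_views(lax_angle_deg: float, arc_halfwidth_deg: float = DEFAULT_ARC_HALFWIDTH_DEG) -> ViewSet:
    """Derive the 2C/4C planes and the six wall azimuths from the LAX azimuth.

    The three planes sit at ``lax + {0, 60, 120}`` (mod 180, a plane being
    invariant to a half turn) and the six wall azimuths at
    ``lax + {0, 60, ..., 300}`` (mod 360), labelled per :data:`WALL_ORDER`.
    """
    lax = float(lax_angle_deg)
    if not np.isfinite(lax):
        raise ValueError("lax_angle_deg must be finite")
    view_angles = tuple((lax + k) % 180.0 for k in (0.0, 60.0, 120.0))
    wall_azimuths = {
        wall: (lax + 60.0 * i) % 360.0 for i, wall in enumerate(WALL_ORDER)
    }
    return ViewSet(
        lax_angle_deg=lax % 360.0,
        view_angles=view_angles,  # type: ignore[arg-type]
        wall_azimuths=wall_azimuths,
        arc_halfwidth_deg=float(arc_halfwidth_deg),
    )
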