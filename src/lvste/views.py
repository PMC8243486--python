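"""Sector-scan acquisition geometries of the nine simulated views.

Image (scan) coordinates are 2D: the probe sits at the origin, depth ``y``
grows along the sector axis and ``x`` is lateral; a beam at angle ``beta``
(degrees, positive toward +x) passes through ``(r sin beta, r cos beta)``.

World placement of the phantom:

* A2C views image the plane containing the LAX.  The probe looks down the
  LAX from beyond the apex; image x = -(world x), image y = world z - z_probe
  with ``z_probe = -(a_ext(ED) + standoff)``.  The AHA segments 1/7/13 (world
  azimuth 0) therefore lie at negative beam angles, where the tilted partial
  sectors point.
* pSAXM views image the plane perpendicular to the LAX located 5.2 cm above
  the ED apex.  The LAX pierces the image at ``(0, PSAXM_CENTER_DEPTH)`` and
  the probe looks at the annulus from wall azimuth PSAXM_PROBE_AZIMUTH_DEG,
  placing the anterior segment 7 nearest the probe and the tabulated partial
  sector tilts on their target segments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

A2C_STANDOFF_MM = 12.0        # probe distance beyond the ED epicardial apex
PSAXM_CENTER_DEPTH_MM = 80.0  # image depth of the LAX in short-axis views
# Wall azimuth of the point nearest the short-axis probe.  The tabulated tilts
# of the three partial pSAXM sectors (views 2-4) centre their target segments
# simultaneously only when the probe looks at the wall from ~27 degrees
# (between the anterior and anteroseptal segments).
PSAXM_PROBE_AZIMUTH_DEG = 27.0


@dataclass(frozen=True)
class SectorConfig:
    """Acquisition parameters of one view."""

    view_no: int
    projection: str            # "pSAXM" | "A2C"
    imaged_segments: tuple[int, ...]
    d_min: float               # cm
    d_max: float               # cm
    tilt: float                # degrees
    width: float               # degrees
    n_lines: int
    focus_depth: float         # cm
    fps: float
    view_type: str             # "Full" | "Part"

    def __post_init__(self):
        if not self.d_min < self.d_max:
            raise ValueError("d_min must be below d_max")
        if self.n_lines < 2 or self.width <= 0:
            raise ValueError("invalid sector")

    @property
    def beam_angles(self):
        """Beam steering angles (degrees), evenly covering the sector."""
        import numpy as np
        return self.tilt + np.linspace(-self.width / 2, self.width / 2,
                                       self.n_lines)

    @property
    def line_spacing_deg(self) -> float:
        return self.width / (self.n_lines - 1)

    def scaled(self, factor: float) -> "SectorConfig":
        """Reduced-resolution copy (lines scaled by ``factor``)."""
        if not 0 < factor <= 1:
            raise ValueError("scale factor in (0, 1]")
        n = max(8, int(round(self.n_lines * factor)))
        return replace(self, n_lines=n)


# Raw table rows kept verbatim next to their parsed values; focus depth is
# mid-sector in every unambiguous row, which disambiguates the rest.
_VIEWS = {
    # "1pSAXM7–12411.150601067.57565Full"
    1: SectorConfig(1, "pSAXM", (7, 8, 9, 10, 11, 12), 4.0, 11.15, 0.0, 60.0,
                    106, 7.575, 65.0, "Full"),
    # "2747.7 − 12.5351535.8565Part"
    2: SectorConfig(2, "pSAXM", (7,), 4.0, 7.7, -12.5, 35.0, 153, 5.85, 65.0,
                    "Part"),
    # "312610.2 − 17.5251168.165Part"
    3: SectorConfig(3, "pSAXM", (12,), 6.0, 10.2, -17.5, 25.0, 116, 8.1, 65.0,
                    "Part"),
    # "411811.15 − 822.51069.57565Part"
    4: SectorConfig(4, "pSAXM", (11,), 8.0, 11.15, -8.0, 22.5, 106, 9.575,
                    65.0, "Part"),
    # "5A2C1, 4, 7, 10, 13, 15, 170.511.40901035.9565Full"
    5: SectorConfig(5, "A2C", (1, 4, 7, 10, 13, 15, 17), 0.5, 11.4, 0.0, 90.0,
                    103, 5.95, 65.0, "Full"),
    # "6170.53.20903701.8565Part"
    6: SectorConfig(6, "A2C", (17,), 0.5, 3.2, 0.0, 90.0, 370, 1.85, 65.0,
                    "Part"),
    # "7131.756.2 − 20501913.97565Part"
    7: SectorConfig(7, "A2C", (13,), 1.75, 6.2, -20.0, 50.0, 191, 3.975, 65.0,
                    "Part"),
    # "874.59.2 − 22.5301286.8565Part"
    8: SectorConfig(8, "A2C", (7,), 4.5, 9.2, -22.5, 30.0, 128, 6.85, 65.0,
                    "Part"),
    # "91711.4 − 16.75191039.265Part"  (view 9 = partial of segment 1)
    9: SectorConfig(9, "A2C", (1,), 7.0, 11.4, -16.75, 19.0, 103, 9.2, 65.0,
                    "Part"),
}


def make_view(view_no: int) -> SectorConfig:
    """The tabulated acquisition configuration of view 1..9."""
    try:
        return _VIEWS[int(view_no)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown view {view_no!r}") from exc


def all_views() -> tuple[int, ...]:
    return tuple(sorted(_VIEWS))
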