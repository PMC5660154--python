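"""Acquisition geometry of a wide-field 3-D stack.

A stack is an ``n_z``-plane sequence of ``n_y x n_x`` images with voxel
pitch ``(dx, dy, dz)`` in micrometres.  The two presets mirror a common
human-cortex FISH protocol: 1024 x 1024-pixel fields of ~111 x 111 um
(60x objective, 0.25 um z-steps) or ~333 x 333 um (20x objective,
0.75 um z-steps) acquired through a 14-um cryosection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import GeometryError

#: nominal field widths (um) of the two objective presets at 1024 px
FIELD_60X_UM = 111.0
FIELD_20X_UM = 333.0

DEFAULT_CHANNELS = ("nuclear", "grain", "somatic", "autofluorescence")


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Voxel grid and physical dimensions of one acquisition.

    Parameters
    ----------
    n_x, n_y : int
        In-plane pixels.
    n_z : int
        Number of z-planes.
    dx, dy : float
        In-plane pixel pitch, um.
    dz : float
        Plane spacing, um.
    section_thickness : float
        Physical tissue thickness used as the stereological reference
        depth, um.
    exposure_ms : dict
        Per-channel exposure times in milliseconds.
    """

    n_x: int = 1024
    n_y: int = 1024
    n_z: int = 57
    dx: float = FIELD_60X_UM / 1024
    dy: float = FIELD_60X_UM / 1024
    dz: float = 0.25
    section_thickness: float = 14.0
    exposure_ms: dict = field(
        default_factory=lambda: {c: 10.0 for c in DEFAULT_CHANNELS}
    )

    def __post_init__(self) -> None:
        for name in ("n_x", "n_y", "n_z", "dx", "dy", "dz", "section_thickness"):
            value = getattr(self, name)
            if not value > 0:
                raise GeometryError(f"geometry field {name!r} must be > 0, got {value!r}")
        for channel, ms in self.exposure_ms.items():
            if not ms > 0:
                raise GeometryError(
                    f"geometry field 'exposure_ms[{channel}]' must be > 0, got {ms!r}"
                )

    # -- derived quantities -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape in (z, y, x) order."""
        return (self.n_z, self.n_y, self.n_x)

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def field_x_um(self) -> float:
        return self.n_x * self.dx

    @property
    def field_y_um(self) -> float:
        return self.n_y * self.dy

    @property
    def depth_um(self) -> float:
        return self.n_z * self.dz

    def stack_volume_mm3(self) -> float:
        """Imaged tissue volume using the section thickness as depth, mm^3."""
        return self.field_x_um * self.field_y_um * self.section_thickness * 1e-9


def preset_60x(n_xy: int = 1024, n_z: int = 57) -> AcquisitionGeometry:
    """60x oil-immersion preset: ~111 um field at 1024 px, 0.25 um z-steps.

    ``n_xy``/``n_z`` may be reduced for desk-scale work; the voxel pitch is
    preserved so object scales (grains, somata) stay physically correct and
    only the field of view shrinks.
    """
    dxy = FIELD_60X_UM / 1024
    thickness = min(14.0, n_z * 0.25)
    return AcquisitionGeometry(
        n_x=n_xy, n_y=n_xy, n_z=n_z, dx=dxy, dy=dxy, dz=0.25,
        section_thickness=thickness,
    )


def preset_20x(n_xy: int = 1024, n_z: int = 20) -> AcquisitionGeometry:
    """20x preset: ~333 um field at 1024 px, 0.75 um z-steps."""
    dxy = FIELD_20X_UM / 1024
    thickness = min(14.0, n_z * 0.75)
    return AcquisitionGeometry(
        n_x=n_xy, n_y=n_xy, n_z=n_z, dx=dxy, dy=dxy, dz=0.75,
        section_thickness=thickness,
    )


def with_exposures(geometry: AcquisitionGeometry, **exposure_ms: float) -> AcquisitionGeometry:
    """Return a copy of ``geometry`` with some channel exposures replaced."""
    merged = dict(geometry.exposure_ms)
    merged.update(exposure_ms)
    return replace(geometry, exposure_ms=merged)
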