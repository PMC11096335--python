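"""Optical-instrument description and derived geometry.

The imaging model is a wide-field common-path interferometric (iSCAT-type)
microscope: a camera records the interference between light scattered by
surface-bound nanoparticles and the reference reflection from the
substrate/water interface.  Particles appear as diffraction-limited spots
whose *contrast* -- fractional deviation from the local background -- is the
measured signal.  Everything downstream (synthetic frames, localisation,
densities) only needs the geometry captured here.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class InstrumentConfig:
    """Geometry and signal level of the wide-field interferometric microscope.

    Parameters
    ----------
    wavelength_nm:
        Illumination wavelength (nm).  Default 455 (blue LED).
    numerical_aperture:
        Objective NA.  Default 1.46 (oil immersion).
    camera_pixel_um:
        Physical camera pixel size (um).  Default 6.5.
    magnification:
        Total magnification onto the camera.  Default 100.
    frame_shape:
        (rows, cols) of a recorded frame.  Default (1024, 1024).
    background_counts:
        Mean background level of a single raw frame, in camera counts.
        Shot noise on a frame is Poissonian around this level.
    """

    wavelength_nm: float = 455.0
    numerical_aperture: float = 1.46
    camera_pixel_um: float = 6.5
    magnification: float = 100.0
    frame_shape: tuple[int, int] = (1024, 1024)
    background_counts: float = 10_000.0

    def __post_init__(self) -> None:
        for name in ("wavelength_nm", "numerical_aperture", "camera_pixel_um",
                     "magnification", "background_counts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if len(self.frame_shape) != 2 or any(int(s) <= 0 for s in self.frame_shape):
            raise ValueError("frame_shape must be two positive integers")

    @property
    def pitch_um(self) -> float:
        """Sample-plane pixel pitch in um (camera pixel / magnification)."""
        return self.camera_pixel_um / self.magnification

    @property
    def fov_um(self) -> tuple[float, float]:
        """Field-of-view side lengths (rows, cols) in um."""
        return (self.frame_shape[0] * self.pitch_um,
                self.frame_shape[1] * self.pitch_um)

    @property
    def fov_area_um2(self) -> float:
        h, w = self.fov_um
        return h * w

    @property
    def psf_sigma_um(self) -> float:
        """Gaussian approximation of the in-focus PSF: sigma = 0.21 lambda/NA."""
        return 0.21 * self.wavelength_nm / self.numerical_aperture * 1e-3

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_um / self.pitch_um


DEFAULT_INSTRUMENT = InstrumentConfig()
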