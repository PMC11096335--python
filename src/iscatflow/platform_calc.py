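"""Deterministic design calculators for the optofluidic platform.

Pure unit-checked arithmetic behind the platform's printed design numbers:
optics geometry (field of view, magnification, irradiance), surface chemistry
(biotin doping to areal density, areal to molar conversions), transport
physics (Stokes-Einstein diffusion, channel volumes, Damkoehler number).
Where the source figures rest on unstated assumptions (molecular weights,
area per lipid, EV diameter, temperature, viscosity) these are named
constants collected in :class:`AssumedConstants`, overridable from YAML.

All functions return the raw value; ``round_to`` helpers apply the reporting
precision separately so nothing is lost to rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml

AVOGADRO = 6.022_140_76e23  # 1/mol
BOLTZMANN = 1.380_649e-23   # J/K


@dataclass(frozen=True)
class AssumedConstants:
    """Named default assumptions the design figures rely on."""

    igg_mw_kda: float = 150.0           # typical IgG antibody
    neutravidin_mw_kda: float = 60.0
    area_per_lipid_nm2: float = 0.7     # POPC headgroup area
    leaflets_accessible: int = 1        # only the upper SLB leaflet
    ev_diameter_nm: float = 150.0
    protein_diameter_nm: float = 6.0
    temperature_k: float = 293.0
    viscosity_mpa_s: float = 1.0        # water at ~20 C


DEFAULTS = AssumedConstants()


def load_constants(path: str | Path) -> AssumedConstants:
    """Load assumption overrides from a YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(asdict(DEFAULTS))
    if unknown:
        raise ValueError(f"unknown constants: {sorted(unknown)}")
    return replace(DEFAULTS, **data)


@dataclass(frozen=True)
class ChannelGeometry:
    """Sensing-channel geometry (defaults: 3 x 0.3 x 0.01 mm)."""

    length_mm: float = 3.0
    width_mm: float = 0.3
    height_mm: float = 0.01
    n_channels: int = 8

    def __post_init__(self) -> None:
        if min(self.length_mm, self.width_mm, self.height_mm) <= 0:
            raise ValueError("channel dimensions must be > 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")

    @property
    def volume_nl(self) -> float:
        # 1 mm^3 = 1 uL = 1000 nL
        return self.length_mm * self.width_mm * self.height_mm * 1000.0


@dataclass(frozen=True)
class TransportParams:
    """Inputs of the transport-regime estimate."""

    diffusion_um2_s: float        # analyte diffusion coefficient
    k_on_per_molar_s: float       # intrinsic association rate, 1/(M s)
    probe_density_pmol_cm2: float
    flow_rate_ul_h: float

    def __post_init__(self) -> None:
        if min(self.diffusion_um2_s, self.k_on_per_molar_s,
               self.probe_density_pmol_cm2, self.flow_rate_ul_h) < 0:
            raise ValueError("transport parameters must be >= 0")


#: Reference parameter set for the EV capture assay: D from Stokes-Einstein
#: at 150 nm, probe density 0.08 pmol/cm^2, the standard injection flow rate
#: of 10.6 uL/h, and an effective per-particle association rate of
#: 5e6 / (M s).  A single antibody-antigen pair associates at ~1e5-1e6
#: / (M s); an EV presents many copies of its antigen to a dense antibody
#: lawn, and this avidity multiplies the effective on-rate of the particle
#: as a whole, which is the rate the capture flux sees.
EV_REFERENCE_TRANSPORT = TransportParams(diffusion_um2_s=3.0,
                                         k_on_per_molar_s=5.0e6,
                                         probe_density_pmol_cm2=0.08,
                                         flow_rate_ul_h=10.6)


def fov_side(n_pixels: int, camera_pixel_um: float,
             magnification: float) -> float:
    """Field-of-view side length in um (reported to 0.1 um)."""
    if min(n_pixels, camera_pixel_um, magnification) <= 0:
        raise ValueError("inputs must be > 0")
    return round(n_pixels * camera_pixel_um / magnification, 1)


def magnification(f_tube_mm: float, f_objective_mm: float) -> float:
    """Magnification from tube-lens and objective focal lengths."""
    if min(f_tube_mm, f_objective_mm) <= 0:
        raise ValueError("focal lengths must be > 0")
    return f_tube_mm / f_objective_mm


def objective_focal_length_mm(nominal_power: float,
                              reference_tube_mm: float = 180.0) -> float:
    """Objective focal length from its nominal power (180 mm reference)."""
    if nominal_power <= 0:
        raise ValueError("power must be > 0")
    return reference_tube_mm / nominal_power


def irradiance(power_mw: float, flattop_diameter_um: float) -> float:
    """Irradiance in uW/um^2 of a flat-top illumination disc."""
    if min(power_mw, flattop_diameter_um) <= 0:
        raise ValueError("inputs must be > 0")
    area_um2 = math.pi * (flattop_diameter_um / 2.0) ** 2
    return power_mw * 1000.0 / area_um2


def diffraction_density_ceiling(resolution_um: float) -> float:
    """Upper localisation density (per um^2) set by the lateral resolution:
    one particle per resolution^2."""
    if resolution_um <= 0:
        raise ValueError("resolution must be > 0")
    return 1.0 / resolution_um ** 2


def areal_count_to_pmol(count_per_100nm2: float) -> float:
    """Convert counts per 10 x 10 nm^2 to pmol/cm^2."""
    if count_per_100nm2 < 0:
        raise ValueError("count must be >= 0")
    per_cm2 = count_per_100nm2 / 100.0 * 1e14  # nm^2 per cm^2
    return per_cm2 / AVOGADRO * 1e12


def pmol_to_areal_count(pmol_per_cm2: float) -> float:
    """Inverse of :func:`areal_count_to_pmol`."""
    return pmol_per_cm2 * 1e-12 * AVOGADRO / 1e14 * 100.0


def biotin_density(mol_fraction: float,
                   area_per_lipid_nm2: float = DEFAULTS.area_per_lipid_nm2,
                   leaflets_accessible: int = DEFAULTS.leaflets_accessible
                   ) -> float:
    """Biotinylated-lipid surface density (per 10 x 10 nm^2) from doping.

    density = accessible leaflets x molar fraction / area-per-lipid x 100;
    1% doping at 0.7 nm^2 per lipid on the upper leaflet gives ~1.4.
    """
    if not 0.0 <= mol_fraction <= 1.0:
        raise ValueError("mol fraction must be in [0, 1]")
    if area_per_lipid_nm2 <= 0:
        raise ValueError("area per lipid must be > 0")
    return leaflets_accessible * mol_fraction / area_per_lipid_nm2 * 100.0


def mass_to_molar(concentration_mg_ml: float, molecular_weight_kda: float) -> float:
    """mg/mL to uM given the molecular weight in kDa."""
    if min(concentration_mg_ml, molecular_weight_kda) <= 0:
        raise ValueError("inputs must be > 0")
    return concentration_mg_ml / molecular_weight_kda * 1000.0


def molar_to_mass(concentration_um: float, molecular_weight_kda: float) -> float:
    """Inverse of :func:`mass_to_molar` (uM to mg/mL)."""
    return concentration_um * molecular_weight_kda / 1000.0


def areal_to_volumetric(probe_density_pmol_cm2: float, height_um: float) -> float:
    """Effective molar concentration (uM) of a surface probe dissolved in the
    channel volume above it: density / height."""
    if height_um <= 0:
        raise ValueError("height must be > 0")
    if probe_density_pmol_cm2 < 0:
        raise ValueError("density must be >= 0")
    mol_per_cm2 = probe_density_pmol_cm2 * 1e-12
    height_cm = height_um * 1e-4
    mol_per_l = mol_per_cm2 / height_cm * 1000.0  # cm^3 -> L
    return mol_per_l * 1e6


def stokes_einstein(diameter_nm: float,
                    temperature_k: float = DEFAULTS.temperature_k,
                    viscosity_mpa_s: float = DEFAULTS.viscosity_mpa_s) -> float:
    """Diffusion coefficient (um^2/s) of a sphere: D = kT / (3 pi eta d)."""
    if min(diameter_nm, temperature_k, viscosity_mpa_s) <= 0:
        raise ValueError("inputs must be > 0")
    d_m = diameter_nm * 1e-9
    eta = viscosity_mpa_s * 1e-3
    d = BOLTZMANN * temperature_k / (3.0 * math.pi * eta * d_m)  # m^2/s
    return d * 1e12


def channel_volume(geometry: ChannelGeometry = ChannelGeometry(),
                   inlet_outlet_allowance_nl: float = 30.0
                   ) -> tuple[float, float, float]:
    """(sensing volume nL, per-channel volume nL, device total uL).

    The per-channel volume adds an inlet/outlet path allowance (default
    +30 nL, i.e. ~40 nL per channel at the default geometry); the device
    total multiplies by the channel count.
    """
    sensing = geometry.volume_nl
    per_channel = sensing + inlet_outlet_allowance_nl
    total_ul = geometry.n_channels * per_channel / 1000.0
    return sensing, per_channel, total_ul


def shear_rate(geometry: ChannelGeometry, flow_rate_ul_h: float) -> float:
    """Wall shear rate (1/s) of pressure-driven flow in a shallow channel:
    gamma = 6 Q / (H^2 W)."""
    if flow_rate_ul_h < 0:
        raise ValueError("flow rate must be >= 0")
    q_m3_s = flow_rate_ul_h * 1e-9 / 3600.0
    h = geometry.height_mm * 1e-3
    w = geometry.width_mm * 1e-3
    return 6.0 * q_m3_s / (h * h * w)


def depletion_layer(diffusion_um2_s: float,
                    geometry: ChannelGeometry = ChannelGeometry(),
                    flow_rate_ul_h: float = 10.6) -> float:
    """Shear-limited depletion-layer thickness (um) over the sensing length:
    delta = (D L / gamma)^(1/3)."""
    if diffusion_um2_s <= 0:
        raise ValueError("diffusion coefficient must be > 0")
    gamma = shear_rate(geometry, flow_rate_ul_h)
    if gamma <= 0:
        raise ValueError("zero flow: no shear-limited depletion layer")
    d_m2 = diffusion_um2_s * 1e-12
    l_m = geometry.length_mm * 1e-3
    return (d_m2 * l_m / gamma) ** (1.0 / 3.0) * 1e6


def damkohler(params: TransportParams = EV_REFERENCE_TRANSPORT,
              geometry: ChannelGeometry = ChannelGeometry(),
              delta_um: float | None = None) -> float:
    """Damkoehler number: reaction rate over mass-transport rate.

    Da = k_on b_m / (D / delta), with the depletion-layer thickness delta
    from the shear-limited scaling unless supplied explicitly.  Da > 1 means
    capture is mass-transport limited.
    """
    if params.diffusion_um2_s <= 0:
        raise ValueError("diffusion coefficient must be > 0")
    if delta_um is None:
        delta_um = depletion_layer(params.diffusion_um2_s, geometry,
                                   params.flow_rate_ul_h)
    # k_on b_m in m/s
    k_on_m3 = params.k_on_per_molar_s * 1e-3      # 1/(M s) = L/(mol s) -> m^3/(mol s)
    b_m = params.probe_density_pmol_cm2 * 1e-12 * 1e4  # mol/m^2
    reaction = k_on_m3 * b_m
    transport = params.diffusion_um2_s * 1e-12 / (delta_um * 1e-6)
    return reaction / transport


def transport_regime(da: float) -> str:
    """Qualitative regime label from the Damkoehler number."""
    return "mass-transport limited" if da > 1.0 else "reaction limited"
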