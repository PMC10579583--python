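"""Tibial material mapping and a beam-theory strain surrogate.

Hounsfield units map to an elastic modulus through a configurable
calibration (linear HU -> apparent density, power-law density -> modulus).
Elements are classified as intramedullary tissue (E < 6 MPa), trabecular
bone (6 MPa <= E < 8 GPa), or cortical bone (E >= 8 GPa), with Poisson's
ratio 0.167 for intramedullary tissue and 0.325 otherwise.

The full subject-specific finite-element stage is deliberately replaced by a
hollow-annulus midshaft beam: axial surface strain is (F/A + M*c/I)/E, and
the scalar reported per stride is the von Mises (equivalent) strain of the
uniaxial stress state, summarized as the 90th percentile over cortical
elements.  This surrogate is a declared stand-in for volumetric FE analysis;
the risk model also accepts strain supplied directly from the configured
strain distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Class boundaries on elastic modulus, MPa.
INTRAMEDULLARY_MAX_E = 6.0
CORTICAL_MIN_E = 8000.0

POISSON_INTRAMEDULLARY = 0.167
POISSON_BONE = 0.325

TISSUE_CLASSES = ("intramedullary", "trabecular", "cortical")


@dataclass(frozen=True)
class HUCalibration:
    """HU -> modulus calibration: density (g/cm^3) = intercept + slope * HU,
    then E (MPa) = coeff * density ** exponent, clamped at zero density.

    Defaults follow common quantitative-CT practice (water/air line for
    density; a power law for apparent-density to modulus).
    """

    density_intercept: float = 0.0226  # g/cm^3
    density_slope: float = 0.0008772  # g/cm^3 per HU
    modulus_coeff: float = 6850.0  # MPa at density 1 g/cm^3
    modulus_exponent: float = 1.49


def hu_to_modulus(hu, calibration: HUCalibration = HUCalibration()):
    """Elastic modulus (MPa) from Hounsfield units.

    Negative implied densities clamp to zero (with a warning) and give E = 0;
    monotone non-decreasing in HU for positive coefficients.
    """
    hu = np.asarray(hu, dtype=float)
    density = calibration.density_intercept + calibration.density_slope * hu
    if np.any(density < 0):
        warnings.warn("negative implied density clamped to 0", stacklevel=2)
        density = np.maximum(density, 0.0)
    E = calibration.modulus_coeff * density**calibration.modulus_exponent
    return E if E.ndim else float(E)


def modulus_to_hu(modulus: float, calibration: HUCalibration = HUCalibration()) -> float:
    """Inverse of the default calibration (used to express class boundaries
    as HU intervals)."""
    density = (modulus / calibration.modulus_coeff) ** (1.0 / calibration.modulus_exponent)
    return (density - calibration.density_intercept) / calibration.density_slope


def class_hu_bounds(calibration: HUCalibration = HUCalibration()):
    """Per-class HU intervals (lo, hi arrays ordered as TISSUE_CLASSES), with
    a small margin inside the modulus boundaries so clipped draws classify
    consistently."""
    hu6 = modulus_to_hu(INTRAMEDULLARY_MAX_E, calibration)
    hu8000 = modulus_to_hu(CORTICAL_MIN_E, calibration)
    hu_zero = -calibration.density_intercept / calibration.density_slope
    eps = 1e-6
    lo = np.array([hu_zero, hu6 + eps, hu8000 + eps])
    hi = np.array([hu6 - eps, hu8000 - eps, 3000.0])
    return lo, hi


def classify_tissue(modulus: float) -> tuple[str, float]:
    """Tissue class and Poisson ratio for one modulus value (MPa).

    Boundaries are half-open exactly as published: E < 6 MPa intramedullary;
    6 MPa <= E < 8 GPa trabecular; E >= 8 GPa cortical.
    """
    if modulus < 0:
        raise ValueError("modulus must be non-negative")
    if modulus < INTRAMEDULLARY_MAX_E:
        return "intramedullary", POISSON_INTRAMEDULLARY
    if modulus < CORTICAL_MIN_E:
        return "trabecular", POISSON_BONE
    return "cortical", POISSON_BONE


def classify_elements(
    elements: pd.DataFrame, calibration: HUCalibration = HUCalibration()
) -> pd.DataFrame:
    """Add modulus_mpa, tissue_class and poisson columns to an element table
    with an ``hu`` column."""
    out = elements.copy()
    E = hu_to_modulus(out["hu"].to_numpy(), calibration)
    out["modulus_mpa"] = E
    tissue = np.where(
        E < INTRAMEDULLARY_MAX_E,
        "intramedullary",
        np.where(E < CORTICAL_MIN_E, "trabecular", "cortical"),
    )
    out["tissue_class"] = tissue
    out["poisson"] = np.where(
        tissue == "intramedullary", POISSON_INTRAMEDULLARY, POISSON_BONE
    )
    return out


@dataclass(frozen=True)
class BeamCrossSection:
    """Hollow circular (annulus) midshaft cross-section."""

    outer_radius: float  # m
    inner_radius: float  # m

    def __post_init__(self) -> None:
        if not 0 <= self.inner_radius < self.outer_radius:
            raise ValueError("need 0 <= inner_radius < outer_radius")

    @property
    def area(self) -> float:
        """m^2"""
        return np.pi * (self.outer_radius**2 - self.inner_radius**2)

    @property
    def second_moment(self) -> float:
        """m^4"""
        return np.pi * (self.outer_radius**4 - self.inner_radius**4) / 4.0


def beam_strain(
    axial_force: float,
    bending_moment: float,
    section: BeamCrossSection,
    modulus_mpa: float,
) -> float:
    """Axial surface strain (microstrain) of the annulus under combined
    axial force (N) and bending moment (N*m): eps = (F/A + M*c/I)/E with
    c = outer radius.  Linear in F and in M; homogeneous of degree -1 in E.
    """
    if modulus_mpa <= 0:
        raise ValueError("modulus must be positive")
    A = section.area
    I = section.second_moment
    if A <= 0 or I <= 0:
        raise ValueError("degenerate cross-section")
    stress_pa = axial_force / A + bending_moment * section.outer_radius / I
    return stress_pa / modulus_mpa  # Pa / (MPa) == 1e-6 strain == microstrain


def von_mises_strain_uniaxial(axial_strain, poisson: float):
    """Equivalent (von Mises) strain of a uniaxial stress state:
    eps_vm = (2/3) * (1 + nu) * |eps_axial| (same units as the input)."""
    if not 0.0 <= poisson <= 0.5:
        raise ValueError("Poisson ratio must lie in [0, 0.5]")
    return (2.0 / 3.0) * (1.0 + poisson) * np.abs(axial_strain)


def peak_von_mises(
    strains,
    tissue_classes,
    volumes=None,
    percentile: float = 90.0,
    volume_weighted: bool = False,
) -> float:
    """Peak von Mises strain: the given percentile over cortical elements only.

    Uses the linear-interpolation percentile convention; with
    ``volume_weighted`` the percentile is taken on the volume-weighted ECDF.
    """
    strains = np.asarray(strains, dtype=float)
    tissue_classes = np.asarray(tissue_classes)
    cortical = tissue_classes == "cortical"
    if not cortical.any():
        raise ValueError("no cortical elements")
    values = strains[cortical]
    if not volume_weighted:
        return float(np.percentile(values, percentile))
    if volumes is None:
        raise ValueError("volume_weighted requires volumes")
    w = np.asarray(volumes, dtype=float)[cortical]
    order = np.argsort(values)
    values, w = values[order], w[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(percentile / 100.0, cum, values))
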