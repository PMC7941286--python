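"""Bending-magnet spectrum synthesis and material attenuation data.

This module provides the photon-side physics that every other stage consumes:

* the vertically integrated Schwinger spectrum of a storage-ring bending
  magnet, characterized by the critical energy ``eps_c = 0.665 E^2 B`` keV;
* packaged mass attenuation tables (total + photoelectric / incoherent /
  coherent partials, cm^2/g) for the five materials in the beam path
  (beryllium, aluminium, tungsten, water, air), interpolated log-log;
* filter transmission, spectrum filtering, flux-weighted mean energy, and
  reproducible inverse-CDF energy sampling.

The mean energy convention is *photon-number* (flux) weighted, matching the
use of the spectrum as a Monte Carlo source term; a power-weighted mean would
be higher (weighting each photon by its energy).
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import integrate, special

__all__ = [
    "RingParameters", "FilterElement", "PhotonSpectrum", "MaterialTable",
    "SUPPORTED_MATERIALS", "material_table", "critical_energy",
    "bending_magnet_spectrum", "attenuation_coefficient", "filter_transmission",
    "apply_filters", "mean_energy", "sample_energies",
    "read_spectrum", "write_spectrum", "default_energy_grid",
]

SUPPORTED_MATERIALS = ("beryllium", "aluminium", "tungsten", "water", "air")

#: photons s^-1 mrad^-1 (0.1% bandwidth)^-1 per GeV per A — Schwinger constant
_SCHWINGER_FLUX_CONST = 2.457e13


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RingParameters:
    """Storage-ring parameters of the bending-magnet source."""

    electron_energy_gev: float = 2.4
    magnetic_field_t: float = 1.45
    ring_current_ma: float = 160.0

    def __post_init__(self):
        for name in ("electron_energy_gev", "magnetic_field_t", "ring_current_ma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class FilterElement:
    """A slab of filter material in the beam path."""

    material: str
    thickness_mm: float

    def __post_init__(self):
        if self.material not in SUPPORTED_MATERIALS:
            raise ValueError(f"unknown material {self.material!r}; "
                             f"supported: {SUPPORTED_MATERIALS}")
        if self.thickness_mm < 0:
            raise ValueError("thickness_mm must be >= 0")


@dataclass
class PhotonSpectrum:
    """Differential photon flux on an ascending energy grid.

    ``flux_density`` is photons s^-1 keV^-1 for the stated ring current and
    horizontal angular acceptance.
    """

    energy_kev: np.ndarray
    flux_density: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.energy_kev = np.asarray(self.energy_kev, dtype=float)
        self.flux_density = np.asarray(self.flux_density, dtype=float)
        if self.energy_kev.ndim != 1 or self.energy_kev.size < 2:
            raise ValueError("energy grid must be 1-D with >= 2 points")
        if np.any(np.diff(self.energy_kev) <= 0):
            raise ValueError("energy grid must be strictly ascending")
        if self.flux_density.shape != self.energy_kev.shape:
            raise ValueError("flux_density shape mismatch")
        if np.any(self.flux_density < 0):
            raise ValueError("flux_density must be non-negative")


@dataclass
class MaterialTable:
    """Tabulated mass attenuation coefficients for one material (cm^2/g)."""

    material: str
    density_g_cm3: float
    energy_kev: np.ndarray
    mu_total: np.ndarray
    mu_photoelectric: np.ndarray
    mu_incoherent: np.ndarray
    mu_coherent: np.ndarray

    _KINDS = ("total", "photoelectric", "incoherent", "coherent")

    def mu_over_rho(self, energy_kev, kind: str = "total") -> np.ndarray:
        """Log-log interpolated mass attenuation coefficient, cm^2/g."""
        if kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        e = np.asarray(energy_kev, dtype=float)
        lo, hi = self.energy_kev[0], self.energy_kev[-1]
        if np.any(e < lo * (1 - 1e-9)) or np.any(e > hi * (1 + 1e-9)):
            raise ValueError(
                f"energy outside [{lo:g}, {hi:g}] keV table range for "
                f"{self.material}")
        col = getattr(self, "mu_" + kind)
        out = np.exp(np.interp(np.log(e), np.log(self.energy_kev), np.log(col)))
        return out if out.ndim else float(out)

    def linear_mu(self, energy_kev, kind: str = "total") -> np.ndarray:
        """Linear attenuation coefficient, cm^-1."""
        return self.mu_over_rho(energy_kev, kind) * self.density_g_cm3


def _data_path(name: str) -> Path:
    return Path(str(resources.files("mrtdose").joinpath("data", name)))


@functools.lru_cache(maxsize=None)
def material_table(material: str) -> MaterialTable:
    """Load the packaged attenuation table for one supported material."""
    if material not in SUPPORTED_MATERIALS:
        raise ValueError(f"unknown material {material!r}")
    arr = np.loadtxt(_data_path(f"attenuation_{material}.csv"),
                     delimiter=",", skiprows=1)
    dens = json.loads(_data_path("densities.json").read_text())
    return MaterialTable(
        material=material,
        density_g_cm3=dens["density_g_cm3"][material],
        energy_kev=arr[:, 0], mu_total=arr[:, 1],
        mu_photoelectric=arr[:, 2], mu_incoherent=arr[:, 3],
        mu_coherent=arr[:, 4],
    )


# --------------------------------------------------------------------------
# spectrum synthesis
# --------------------------------------------------------------------------

def critical_energy(ring: RingParameters) -> float:
    """Critical energy eps_c = 0.665 E[GeV]^2 B[T] of a bending magnet, keV.

    Half the radiated power is emitted above, half below this energy.
    The B -> 0 limit (0 keV) is honoured for non-strict field values.
    """
    if ring.electron_energy_gev <= 0:
        raise ValueError("electron energy must be positive")
    if ring.magnetic_field_t < 0:
        raise ValueError("magnetic field must be non-negative")
    return 0.665 * ring.electron_energy_gev**2 * ring.magnetic_field_t


@functools.lru_cache(maxsize=4096)
def _g1(y: float) -> float:
    """Universal spectral function G1(y) = y * int_y^inf K_{5/3}(x) dx."""
    if y <= 0:
        raise ValueError("y must be positive")
    val, _ = integrate.quad(lambda x: special.kv(5.0 / 3.0, x), y, np.inf,
                            limit=200)
    return y * val


def default_energy_grid() -> np.ndarray:
    """5-150 keV in 0.5 keV steps: resolves the filtered pink-beam peak."""
    return np.arange(5.0, 150.0 + 0.25, 0.5)


def bending_magnet_spectrum(ring: RingParameters,
                            energy_kev=None,
                            horizontal_acceptance_mrad: float = 7.0,
                            ) -> PhotonSpectrum:
    """Vertically integrated Schwinger spectrum of the bending magnet.

    Returns photons s^-1 keV^-1 into the stated horizontal acceptance at the
    stated ring current.  The flux is strictly proportional to the current.
    """
    if energy_kev is None:
        energy_kev = default_energy_grid()
    e = np.asarray(energy_kev, dtype=float)
    if e.size == 0:
        raise ValueError("empty energy grid")
    if np.any(e <= 0):
        raise ValueError("energies must be positive")
    eps_c = critical_energy(ring)
    g1 = np.array([_g1(x) for x in e / eps_c])
    # per 0.1% bandwidth -> per keV:  divide by 1e-3 * E
    flux = (_SCHWINGER_FLUX_CONST * ring.electron_energy_gev
            * ring.ring_current_ma * 1e-3 * horizontal_acceptance_mrad
            * g1 / (1e-3 * e))
    return PhotonSpectrum(e, flux, meta={
        "critical_energy_kev": eps_c,
        "ring_current_ma": ring.ring_current_ma,
        "horizontal_acceptance_mrad": horizontal_acceptance_mrad,
        "filters": [],
    })


def attenuation_coefficient(material: str, energy_kev,
                            kind: str = "total") -> np.ndarray:
    """Mass attenuation coefficient of a supported material, cm^2/g."""
    return material_table(material).mu_over_rho(energy_kev, kind)


def filter_transmission(filters, energy_kev) -> np.ndarray:
    """Product of exp(-(mu/rho) rho t) over a filter stack; in [0, 1]."""
    e = np.asarray(energy_kev, dtype=float)
    t = np.ones_like(e)
    for f in filters:
        tab = material_table(f.material)
        t = t * np.exp(-tab.linear_mu(e) * f.thickness_mm * 0.1)
    return t if t.ndim else float(t)


def apply_filters(spectrum: PhotonSpectrum, filters) -> PhotonSpectrum:
    """Pointwise filtered spectrum; the energy grid is unchanged."""
    trans = filter_transmission(filters, spectrum.energy_kev)
    meta = dict(spectrum.meta)
    meta["filters"] = meta.get("filters", []) + [
        (f.material, f.thickness_mm) for f in filters]
    return PhotonSpectrum(spectrum.energy_kev.copy(),
                          spectrum.flux_density * trans, meta)


def mean_energy(spectrum: PhotonSpectrum) -> float:
    """Flux-weighted mean energy int E Phi dE / int Phi dE, keV (trapezoid)."""
    norm = np.trapezoid(spectrum.flux_density, spectrum.energy_kev)
    if norm <= 0:
        raise ValueError("spectrum has zero integrated flux")
    return float(np.trapezoid(spectrum.energy_kev * spectrum.flux_density,
                              spectrum.energy_kev) / norm)


def sample_energies(spectrum: PhotonSpectrum, n: int, rng) -> np.ndarray:
    """Inverse-CDF sample of n photon energies from the spectrum, keV.

    ``rng`` is either an integer seed or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    e, phi = spectrum.energy_kev, spectrum.flux_density
    if not np.any(phi > 0):
        raise ValueError("degenerate spectrum: all-zero flux")
    # CDF of the trapezoid-integrated flux density
    seg = 0.5 * (phi[1:] + phi[:-1]) * np.diff(e)
    cdf = np.concatenate([[0.0], np.cumsum(seg)])
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, e)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def write_spectrum(path, spectrum: PhotonSpectrum) -> None:
    """Two-column delimited text (energy_keV, flux_density) with header."""
    header = "energy_keV,flux_density_photons_per_s_per_keV"
    np.savetxt(path, np.column_stack([spectrum.energy_kev,
                                      spectrum.flux_density]),
               delimiter=",", header=header, comments="")


def read_spectrum(path) -> PhotonSpectrum:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return PhotonSpectrum(arr[:, 0], arr[:, 1])
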