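"""Multi-slit collimator (MSC) geometry and ray tracing.

Coordinate convention: beamline frame with the origin at the source, z along
the nominal beam, x horizontal, y vertical; all lengths in mm unless a field
name says otherwise.  The MSC is an ideal periodic comb of tungsten lamellae
of given depth, with ``n_slits`` openings of ``slit_width_um`` at
``pitch_um`` centre-to-centre, centred on the beam axis.

Because the source is 15.5 m upstream and the lamellae are 8 mm deep, rays
aimed at off-axis slits walk laterally by ``depth * x / source_to_msc``
inside the collimator, which narrows the effective opening of edge slits —
the divergence effect that restricts the usable array to the central slits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .xray_physics import material_table

__all__ = ["CollimatorSpec", "BeamlineLayout", "Ray", "tungsten_path_length",
           "ray_transmission", "effective_slit_width", "array_extent",
           "slit_centres_mm", "open_measure", "tungsten_path_lengths"]


@dataclass(frozen=True)
class CollimatorSpec:
    slit_width_um: float = 50.0
    pitch_um: float = 400.0
    depth_mm: float = 8.0
    n_slits: int = 74  # even comb: slit centres at +-(pitch/2 + k*pitch)
    horizontal_acceptance_mm: float = 30.0
    vertical_acceptance_mm: float = 5.0
    lamella_material: str = "tungsten"

    def __post_init__(self):
        if not 0 < self.slit_width_um < self.pitch_um:
            raise ValueError("need 0 < slit_width < pitch")
        if self.depth_mm <= 0:
            raise ValueError("depth_mm must be positive")
        if self.n_slits * self.pitch_um * 1e-3 > \
                self.horizontal_acceptance_mm + self.pitch_um * 1e-3:
            raise ValueError("slit comb exceeds horizontal acceptance")


@dataclass(frozen=True)
class BeamlineLayout:
    source_to_msc_m: float = 15.5
    msc_to_sample_m: float = 0.30
    horizontal_divergence_mrad: float = 7.0
    vertical_divergence_mrad: float = 0.175
    vertical_fwhm_at_sample_mm: float = 1.5
    projected_vertical_slit_opening_mm: float = 3.265  # informational
    aperture_h_mm: float = 8.0   # horizontal slit aperture (20 central beams)
    aperture_v_mm: float = 3.2   # vertical slit aperture at the MSC plane
    source_sigma_x_mm: float = 0.10
    source_sigma_y_mm: float = 0.02

    def __post_init__(self):
        if self.source_to_msc_m <= 0 or self.msc_to_sample_m <= 0:
            raise ValueError("distances must be positive")
        if self.horizontal_divergence_mrad <= 0 or \
                self.vertical_divergence_mrad <= 0:
            raise ValueError("divergences must be positive")

    @property
    def source_to_sample_m(self) -> float:
        return self.source_to_msc_m + self.msc_to_sample_m

    @property
    def magnification(self) -> float:
        """Geometric magnification source->sample (~1.019)."""
        return self.source_to_sample_m / self.source_to_msc_m


@dataclass(frozen=True)
class Ray:
    """A forward-going ray in the beamline frame (origin mm, unit direction)."""

    origin: tuple
    direction: tuple

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
            raise ValueError("direction must be a unit vector")
        if d[2] <= 0:
            raise ValueError("ray must be forward-going (positive z)")


def slit_centres_mm(msc: CollimatorSpec) -> np.ndarray:
    """x positions of the slit centres at the MSC, mm, centred on the axis."""
    k = np.arange(msc.n_slits)
    return (k - (msc.n_slits - 1) / 2.0) * msc.pitch_um * 1e-3


def open_measure(x_mm, msc: CollimatorSpec) -> np.ndarray:
    """Cumulative open (slit) length below x: measure of slits in (-inf, x]."""
    x = np.asarray(x_mm, dtype=float)
    w = msc.slit_width_um * 1e-3
    p = msc.pitch_um * 1e-3
    a0 = slit_centres_mm(msc)[0] - w / 2.0  # left edge of first slit
    m = np.clip(np.floor((x - a0) / p), 0, msc.n_slits - 1)
    return w * m + np.clip(x - (a0 + m * p), 0.0, w)


def tungsten_path_lengths(x_entry_mm, tan_theta_x, msc: CollimatorSpec,
                          tan_theta_y=0.0) -> np.ndarray:
    """Vectorized tungsten path for rays crossing the full MSC depth.

    ``x_entry_mm`` is the horizontal position at the entrance plane and
    ``tan_theta_x`` the horizontal slope dx/dz.  The lamella set is the
    complement of the slit comb; since x(z) is linear in z the in-tungsten
    fraction equals the in-tungsten fraction of the x interval swept.
    """
    x0 = np.asarray(x_entry_mm, dtype=float)
    tx = np.broadcast_to(np.asarray(tan_theta_x, dtype=float), x0.shape)
    ty = np.broadcast_to(np.asarray(tan_theta_y, dtype=float), x0.shape)
    d = msc.depth_mm
    slant = d * np.sqrt(1.0 + tx**2 + ty**2)
    dx = tx * d
    x1 = x0 + dx
    lo, hi = np.minimum(x0, x1), np.maximum(x0, x1)
    open_len = open_measure(hi, msc) - open_measure(lo, msc)
    adx = np.abs(dx)
    # near-axial rays: the swept interval degenerates to a point-in-slit test
    centres = slit_centres_mm(msc)
    nearest = centres[np.clip(np.round((x0 - centres[0]) /
                                       (msc.pitch_um * 1e-3)), 0,
                              msc.n_slits - 1).astype(np.int64)]
    in_slit = np.abs(x0 - nearest) <= msc.slit_width_um * 5e-4
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_w = np.where(adx > 1e-9,
                          1.0 - open_len / np.maximum(adx, 1e-300),
                          np.where(in_slit, 0.0, 1.0))
    return np.clip(frac_w, 0.0, 1.0) * slant


def tungsten_path_length(ray: Ray, msc: CollimatorSpec,
                         layout: BeamlineLayout | None = None) -> float:
    """Tungsten path length of one ray across the MSC depth, mm.

    The entrance plane sits at ``layout.source_to_msc_m`` (default layout if
    none given).  Rays outside the horizontal acceptance raise ``ValueError``
    (flagged miss).
    """
    layout = layout or BeamlineLayout()
    o = np.asarray(ray.origin, dtype=float)
    dvec = np.asarray(ray.direction, dtype=float)
    z_in = layout.source_to_msc_m * 1e3
    t = (z_in - o[2]) / dvec[2]
    if t < 0:
        raise ValueError("ray starts downstream of the MSC")
    x_in = o[0] + t * dvec[0]
    if abs(x_in) > msc.horizontal_acceptance_mm / 2.0:
        raise ValueError(f"ray misses MSC acceptance at x={x_in:.3f} mm")
    return float(tungsten_path_lengths(np.array([x_in]),
                                       dvec[0] / dvec[2], msc,
                                       dvec[1] / dvec[2])[0])


def ray_transmission(ray: Ray, energy_kev: float, msc: CollimatorSpec,
                     layout: BeamlineLayout | None = None) -> float:
    """exp(-mu_W(E) * path) through the collimator; in [0, 1]."""
    path_mm = tungsten_path_length(ray, msc, layout)
    mu = material_table(msc.lamella_material).linear_mu(energy_kev)  # cm^-1
    return float(np.exp(-mu * path_mm * 0.1))


def effective_slit_width(slit_centre_x_mm: float, msc: CollimatorSpec,
                         layout: BeamlineLayout, energy_kev: float = 30.0,
                         frame: str = "nominal") -> float:
    """FWHM of one slit's ray-traced transmission profile, micrometres.

    A point source at the origin illuminates the slit; the transmission
    profile is evaluated on a fine grid of entrance positions and its FWHM
    returned.  ``frame='nominal'`` reports at the MSC (collimator) plane so
    the central slit reads the nominal opening; ``frame='projected'`` applies
    the geometric magnification to the sample plane.
    """
    if abs(slit_centre_x_mm) > msc.horizontal_acceptance_mm / 2.0:
        raise ValueError("slit outside horizontal acceptance")
    if frame not in ("nominal", "projected"):
        raise ValueError("frame must be 'nominal' or 'projected'")
    z_in = layout.source_to_msc_m * 1e3
    w = msc.slit_width_um * 1e-3
    x = slit_centre_x_mm + np.linspace(-w, w, 4001)
    tan_t = x / z_in  # rays from the point source
    path = tungsten_path_lengths(x, tan_t, msc)
    mu = material_table(msc.lamella_material).linear_mu(energy_kev)
    trans = np.exp(-mu * path * 0.1)
    half = trans.max() / 2.0
    above = trans >= half
    if not above.any():
        raise ValueError("no transmission through slit")
    i0, i1 = np.argmax(above), len(above) - 1 - np.argmax(above[::-1])
    # sub-grid-refine the two half-maximum crossings by linear interpolation
    def cross(i, j):
        if i == j or trans[j] == trans[i]:
            return x[i]
        return x[i] + (half - trans[i]) * (x[j] - x[i]) / (trans[j] - trans[i])
    left = cross(i0, i0 - 1) if i0 > 0 else x[0]
    right = cross(i1, i1 + 1) if i1 < len(x) - 1 else x[-1]
    fwhm_mm = right - left
    if frame == "projected":
        fwhm_mm *= layout.magnification
    return float(fwhm_mm * 1e3)


def array_extent(n_central: int, msc: CollimatorSpec) -> float:
    """Width covered by n_central microbeams, mm (n * pitch)."""
    if not 1 <= n_central <= msc.n_slits:
        raise ValueError("n_central must be in [1, n_slits]")
    return n_central * msc.pitch_um * 1e-3
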