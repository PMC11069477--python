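"""Stokes algebra: reconstruction from intensities and derived polarization parameters.

The Stokes vector ``S = [S0, S1, S2, S3]`` describes the polarization state
of a light beam: total intensity, 0°−90° linear preference, ±45° linear
preference and right−left circular preference.  This module reconstructs
Stokes vectors from analyzer-channel intensities (either the six ideal
projections or the four channels of a division-of-amplitude polarimeter),
and computes the derived polarization parameters

    DOP  = sqrt(S1² + S2² + S3²) / S0
    DOLP = sqrt(S1² + S2²) / S0
    DOCP = |S3| / S0          (signed ratio kept as a secondary field)
    r    = 2·S1 / (3·S0 − S1)

both for scalar vectors and per-pixel image fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "StokesVector",
    "StokesImage",
    "PolarizationParams",
    "stokes_from_six",
    "stokes_from_instrument",
    "derived_params",
    "parameter_maps",
    "read_stokes_tiff",
    "write_stokes_tiff",
    "write_parameter_tiff",
]

#: Relative tolerance for the physicality check S1²+S2²+S3² ≤ S0²(1+tol).
PHYSICALITY_TOL = 1e-6

#: Per-pixel masking threshold factor: pixels with s0 <= EPS_FACTOR * max(s0)
#: are masked instead of divided.
EPS_FACTOR = 1e-12


@dataclass(frozen=True)
class StokesVector:
    """A four-component polarization state.

    Parameters
    ----------
    s0 : total intensity (arbitrary linear units, must be >= 0)
    s1 : 0° − 90° linear intensity difference
    s2 : +45° − −45° linear intensity difference
    s3 : right-circular − left-circular intensity difference
    """

    s0: float
    s1: float
    s2: float
    s3: float

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError(f"s0 must be non-negative, got {self.s0}")

    @property
    def array(self) -> np.ndarray:
        return np.array([self.s0, self.s1, self.s2, self.s3], dtype=float)

    def is_physical(self, tol: float = PHYSICALITY_TOL) -> bool:
        """Whether the polarized part does not exceed the total intensity.

        Measured, noisy vectors may violate this; they are flagged by this
        predicate, never rejected.
        """
        pol2 = self.s1**2 + self.s2**2 + self.s3**2
        return bool(pol2 <= self.s0**2 * (1.0 + tol))

    @classmethod
    def from_array(cls, a) -> "StokesVector":
        a = np.asarray(a, dtype=float)
        if a.shape != (4,):
            raise ValueError(f"expected 4 components, got shape {a.shape}")
        return cls(*a)


@dataclass
class StokesImage:
    """Per-pixel Stokes field: four planes (S0, S1, S2, S3) of equal shape."""

    planes: np.ndarray  # (4, H, W)

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim != 3 or self.planes.shape[0] != 4:
            raise ValueError(
                f"planes must have shape (4, H, W), got {self.planes.shape}"
            )

    @property
    def height(self) -> int:
        return self.planes.shape[1]

    @property
    def width(self) -> int:
        return self.planes.shape[2]

    @property
    def s0(self) -> np.ndarray:
        return self.planes[0]


@dataclass(frozen=True)
class PolarizationParams:
    """Derived polarization parameters of a single Stokes vector.

    dop, dolp, docp are dimensionless in [0, 1]; anisotropy r lies in
    [−0.5, 1].  ``docp_signed`` preserves the handedness (sign of S3/S0).
    """

    dop: float
    dolp: float
    docp: float
    r: float
    docp_signed: float = field(default=0.0)


def stokes_from_six(i0, i90, i45, i135, ircp, ilcp) -> StokesVector:
    """Reconstruct a Stokes vector from the six ideal analyzer intensities.

    ``S = [I0+I90, I0−I90, I45−I135, IRCP−ILCP]``.
    """
    intensities = (i0, i90, i45, i135, ircp, ilcp)
    if any(i < 0 for i in intensities):
        raise ValueError(f"intensities must be non-negative, got {intensities}")
    return StokesVector(i0 + i90, i0 - i90, i45 - i135, ircp - ilcp)


def project_to_six(s: StokesVector) -> tuple:
    """Forward model of the six ideal analyzers: the unique linear model that
    makes the reconstruction above exact.

    I0 = (S0+S1)/2, I90 = (S0−S1)/2, I45 = (S0+S2)/2, I135 = (S0−S2)/2,
    IRCP = (S0+S3)/2, ILCP = (S0−S3)/2.
    """
    s0, s1, s2, s3 = s.s0, s.s1, s.s2, s.s3
    return (
        (s0 + s1) / 2,
        (s0 - s1) / 2,
        (s0 + s2) / 2,
        (s0 - s2) / 2,
        (s0 + s3) / 2,
        (s0 - s3) / 2,
    )


def stokes_from_instrument(channels, instrument) -> StokesVector:
    """Invert a four-channel measurement through the instrument's analyzer
    matrix A: returns ``S = A⁻¹ · channels``.

    Parameters
    ----------
    channels : 4 detector intensities
    instrument : InstrumentModel (from :mod:`polartissue.mueller`)
    """
    c = np.asarray(channels, dtype=float)
    if c.shape != (4,):
        raise ValueError(f"expected 4 channels, got shape {c.shape}")
    a = np.asarray(instrument.a, dtype=float)
    cond = np.linalg.cond(a, 2)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"instrument matrix is singular (condition number {cond:g})"
        )
    try:
        s = np.linalg.solve(a, c)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"instrument matrix is singular (condition number {cond:g})"
        ) from exc
    return StokesVector.from_array(s)


def derived_params(s: StokesVector) -> PolarizationParams:
    """Compute DOP, DOLP, DOCP and anisotropy r from a Stokes vector.

    Raises a domain error for s0 <= 0 (the map form masks such pixels
    instead).
    """
    if s.s0 <= 0:
        raise ValueError(f"derived parameters require s0 > 0, got s0={s.s0}")
    s0, s1, s2, s3 = s.s0, s.s1, s.s2, s.s3
    dop = float(np.sqrt(s1**2 + s2**2 + s3**2) / s0)
    dolp = float(np.sqrt(s1**2 + s2**2) / s0)
    docp_signed = float(s3 / s0)
    r = float(2.0 * s1 / (3.0 * s0 - s1))
    return PolarizationParams(
        dop=dop, dolp=dolp, docp=abs(docp_signed), r=r, docp_signed=docp_signed
    )


def parameter_maps(img: StokesImage, eps_factor: float = EPS_FACTOR) -> dict:
    """Per-pixel polarization-parameter planes from a Stokes image.

    Returns a dict of masked arrays keyed ``dop``, ``dolp``, ``docp``,
    ``anisotropy`` (display ranges 0–1, 0–1, 0–1 and −0.5–1).  Pixels whose
    s0 falls at or below ``eps_factor · max(s0)`` are masked.
    """
    s0, s1, s2, s3 = img.planes
    smax = float(np.max(s0)) if s0.size else 0.0
    mask = s0 <= eps_factor * smax
    safe_s0 = np.where(mask, 1.0, s0)
    dop = np.sqrt(s1**2 + s2**2 + s3**2) / safe_s0
    dolp = np.sqrt(s1**2 + s2**2) / safe_s0
    docp = np.abs(s3) / safe_s0
    r = 2.0 * s1 / (3.0 * safe_s0 - s1)
    return {
        "dop": np.ma.masked_array(dop, mask=mask),
        "dolp": np.ma.masked_array(dolp, mask=mask),
        "docp": np.ma.masked_array(docp, mask=mask),
        "anisotropy": np.ma.masked_array(r, mask=mask),
    }


# display ranges used for GLCM quantization and plotting
PARAMETER_RANGES = {
    "dop": (0.0, 1.0),
    "dolp": (0.0, 1.0),
    "docp": (0.0, 1.0),
    "anisotropy": (-0.5, 1.0),
}


def write_stokes_tiff(path, img: StokesImage) -> None:
    """Write a Stokes image as a 4-plane 32-bit float TIFF (S0,S1,S2,S3)."""
    tifffile.imwrite(path, img.planes.astype(np.float32), photometric="minisblack")


def read_stokes_tiff(path) -> StokesImage:
    data = tifffile.imread(path)
    return StokesImage(planes=np.asarray(data, dtype=float))


def write_parameter_tiff(path, plane) -> None:
    """Write a single parameter map as single-plane float TIFF (masked
    pixels stored as NaN)."""
    arr = np.ma.filled(np.ma.asarray(plane, dtype=np.float32), np.nan)
    tifffile.imwrite(path, arr.astype(np.float32), photometric="minisblack")
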