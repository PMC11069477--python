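"""Mueller matrix assembly and elementary optical-element matrices.

A Mueller matrix is the 4×4 real matrix relating input to output Stokes
vectors, ``S_out = M · S_in``.  Probing a sample with the four input states
H (0°), P (45°), V (90°) and R (right circular) spans Stokes space, so the
sample matrix follows in closed form from the four measured output vectors:

    column 1 = (S_H + S_V)/2
    column 2 = (S_H − S_V)/2
    column 3 = S_P − column 1
    column 4 = S_R − column 1

This module also provides the standard elementary matrices (rotated linear
retarder, linear diattenuator, diagonal depolarizer) used by the phantom
generator and by decomposition tests, the default division-of-amplitude
instrument model, and its condition number.

Conventions: polarization angles counter-clockwise from horizontal looking
toward the source; S3 > 0 means right circular.  Element names M(i,j) are
1-based.  Elementary elements have unit transmittance (M(1,1) = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

__all__ = [
    "MuellerMatrix",
    "InstrumentModel",
    "FourStateMeasurement",
    "input_states",
    "assemble_mueller",
    "assemble_mueller_image",
    "normalize_mueller",
    "linear_retarder",
    "linear_diattenuator",
    "depolarizer",
    "condition_number",
    "ideal_instrument",
    "write_mueller_tiff",
    "read_mueller_tiff",
]


@dataclass
class MuellerMatrix:
    """4×4 real Mueller matrix; ``normalized`` records division by M(1,1)."""

    m: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if self.m.shape != (4, 4):
            raise ValueError(f"Mueller matrix must be 4x4, got {self.m.shape}")

    def element(self, i: int, j: int) -> float:
        """M(i,j) with the 1-based indices used in reports and figures."""
        return float(self.m[i - 1, j - 1])

    def apply(self, s) -> np.ndarray:
        return self.m @ np.asarray(s, dtype=float)

    def __matmul__(self, other: "MuellerMatrix") -> "MuellerMatrix":
        return MuellerMatrix(self.m @ other.m)


@dataclass
class InstrumentModel:
    """Analyzer matrix A mapping a Stokes vector to 4 channel intensities."""

    a: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.a.shape != (4, 4):
            raise ValueError(f"analyzer matrix must be 4x4, got {self.a.shape}")

    @property
    def cond(self) -> float:
        return condition_number(self)

    def project(self, s) -> np.ndarray:
        """Channel intensities for a Stokes vector (or stacked field)."""
        return np.einsum("ij,...j->...i", self.a, np.asarray(s, dtype=float))


def ideal_instrument() -> InstrumentModel:
    """Ideal division-of-amplitude analyzer set (rows H, V, 45°, RCP).

    The real instrument matrix of a four-camera polarimeter must be
    calibrated; this ideal stand-in is invertible and consistent with the
    six-projection analyzer model.
    """
    a = 0.5 * np.array(
        [
            [1, 1, 0, 0],
            [1, -1, 0, 0],
            [1, 0, 1, 0],
            [1, 0, 0, 1],
        ],
        dtype=float,
    )
    return InstrumentModel(a=a)


@dataclass
class FourStateMeasurement:
    """Output Stokes measurements for input states H (0°), P (45°), V (90°),
    R (right circular).  Each entry is a length-4 vector or a (4, H, W)
    Stokes plane stack; all four must share shape."""

    s_h: np.ndarray
    s_p: np.ndarray
    s_v: np.ndarray
    s_r: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(x, dtype=float) for x in
                  (self.s_h, self.s_p, self.s_v, self.s_r)]
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValueError(f"four-state measurements differ in shape: {shapes}")
        if arrays[0].shape[0] != 4:
            raise ValueError("each measurement must have 4 Stokes components first")
        self.s_h, self.s_p, self.s_v, self.s_r = arrays


_INPUT_STATES = {
    "H": np.array([1.0, 1.0, 0.0, 0.0]),
    "P": np.array([1.0, 0.0, 1.0, 0.0]),
    "V": np.array([1.0, -1.0, 0.0, 0.0]),
    "R": np.array([1.0, 0.0, 0.0, 1.0]),
}


def input_states() -> dict:
    """The four probing input Stokes vectors keyed H, P, V, R."""
    return {k: v.copy() for k, v in _INPUT_STATES.items()}


def assemble_mueller(meas: FourStateMeasurement) -> MuellerMatrix:
    """Assemble the sample Mueller matrix from the four-state measurement.

    Algebraically exact for any 4×4 M because the four input states span
    Stokes space.
    """
    c1 = 0.5 * (meas.s_h + meas.s_v)
    c2 = 0.5 * (meas.s_h - meas.s_v)
    c3 = meas.s_p - c1
    c4 = meas.s_r - c1
    m = np.stack([c1, c2, c3, c4], axis=1)  # components are rows, states columns
    return MuellerMatrix(m=m)


def assemble_mueller_image(meas: FourStateMeasurement) -> np.ndarray:
    """Per-pixel assembly: four (4, H, W) stacks → (H, W, 4, 4) field."""
    c1 = 0.5 * (meas.s_h + meas.s_v)
    c2 = 0.5 * (meas.s_h - meas.s_v)
    c3 = meas.s_p - c1
    c4 = meas.s_r - c1
    # each c* is (4, H, W); stack to (H, W, 4 rows, 4 cols)
    return np.stack([c1, c2, c3, c4], axis=-1).transpose(1, 2, 0, 3)


def normalize_mueller(m: MuellerMatrix) -> MuellerMatrix:
    """Divide every element by M(1,1)."""
    m11 = m.m[0, 0]
    if m11 == 0:
        raise ValueError("cannot normalize: M(1,1) = 0")
    return MuellerMatrix(m=m.m / m11, normalized=True)


def linear_retarder(delta: float, theta: float) -> MuellerMatrix:
    """Rotated linear retarder: retardance ``delta`` (rad), fast axis at
    ``theta`` (rad from horizontal)."""
    c, s = np.cos(2 * theta), np.sin(2 * theta)
    cd, sd = np.cos(delta), np.sin(delta)
    m = np.array(
        [
            [1, 0, 0, 0],
            [0, c * c + s * s * cd, c * s * (1 - cd), -s * sd],
            [0, c * s * (1 - cd), s * s + c * c * cd, c * sd],
            [0, s * sd, -c * sd, cd],
        ],
        dtype=float,
    )
    return MuellerMatrix(m=m, normalized=True)


def linear_diattenuator(d: float, theta: float) -> MuellerMatrix:
    """Linear diattenuator with diattenuation ``d`` in [0,1] and axis
    ``theta`` (rad), unit-transmittance convention (M(1,1)=1)."""
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"diattenuation must lie in [0, 1], got {d}")
    dvec = d * np.array([np.cos(2 * theta), np.sin(2 * theta), 0.0])
    return MuellerMatrix(m=_diattenuator_from_vector(dvec), normalized=True)


def _diattenuator_from_vector(dvec: np.ndarray) -> np.ndarray:
    """M_D for an arbitrary diattenuation vector (unit transmittance)."""
    d = np.linalg.norm(dvec)
    m = np.eye(4)
    m[0, 1:] = dvec
    m[1:, 0] = dvec
    if d > 0:
        dhat = dvec / d
        root = np.sqrt(max(0.0, 1.0 - d * d))
        m[1:, 1:] = root * np.eye(3) + (1.0 - root) * np.outer(dhat, dhat)
    return m


def depolarizer(a: float, b: float, c: float) -> MuellerMatrix:
    """Diagonal depolarizer diag(1, a, b, c); net depolarization
    Δ = 1 − (|a|+|b|+|c|)/3."""
    for f in (a, b, c):
        if abs(f) > 1.0:
            raise ValueError(f"depolarization factors must lie in [-1, 1], got {f}")
    return MuellerMatrix(m=np.diag([1.0, a, b, c]), normalized=True)


def condition_number(inst: InstrumentModel) -> float:
    """2-norm condition number of the analyzer matrix; +inf when singular.

    A well-conditioned instrument matrix keeps noise amplification in the
    Stokes inversion low.
    """
    sv = np.linalg.svd(np.asarray(inst.a, dtype=float), compute_uv=False)
    if sv[-1] == 0:
        return float("inf")
    return float(sv[0] / sv[-1])


def write_mueller_tiff(path, field: np.ndarray) -> None:
    """Write an (H, W, 4, 4) Mueller field as a 16-plane float TIFF in
    row-major element order M(1,1)…M(4,4)."""
    f = np.asarray(field, dtype=np.float32)
    h, w = f.shape[:2]
    tifffile.imwrite(path, f.reshape(h, w, 16).transpose(2, 0, 1), photometric="minisblack")


def read_mueller_tiff(path) -> np.ndarray:
    planes = np.asarray(tifffile.imread(path), dtype=float)  # (16, H, W)
    return planes.transpose(1, 2, 0).reshape(planes.shape[1], planes.shape[2], 4, 4)
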