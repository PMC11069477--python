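"""Lu-Chipman polar decomposition M = M_Δ · M_R · M_D.

Factors a (normalized) Mueller matrix into a diattenuator applied first,
then a retarder, then a depolarizer, and extracts the three scalar tissue
descriptors used throughout this package:

    d          diattenuation, sqrt(M(1,2)² + M(1,3)² + M(1,4)²) / M(1,1)
    Δ (net)    depolarization, 1 − |tr(m_Δ)| / 3
    δ (linear) retardance, arccos( sqrt((M_R(2,2)+M_R(3,3))²
                                        + (M_R(3,2)−M_R(2,3))²) − 1 )

The construction: strip the diattenuator built from the first row,
M' = M·M_D⁻¹; recover the depolarizer 3×3 block from the matrix square
root of m'm'ᵀ (sign from det m'); the retarder is the orthogonal
remainder m_Δ⁻¹ m'.  Exact for matrices composed in the Δ·R·D order;
numerical fallbacks (eigenvalue clamping, pure-diattenuator short-circuit,
pseudo-inverse) are recorded as flags.

All retardances are in radians.  A vectorized per-pixel path
(:func:`decompose_image`) applies the same algorithm to (H, W, 4, 4)
fields using batched linear algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mueller import MuellerMatrix, _diattenuator_from_vector, depolarizer, \
    linear_diattenuator, linear_retarder

__all__ = [
    "DecompositionResult",
    "lu_chipman",
    "diattenuation_of",
    "depolarization_of",
    "linear_retardance_of",
    "compose",
    "decompose_image",
]

# a diattenuator with d this close to 1 is singular: use the polarizer
# short-circuit instead of inverting it
PURE_DIATTENUATOR_TOL = 1e-9
# eigenvalues of m'm'^T below -EIG_CLAMP_TOL raise the clamped flag
EIG_CLAMP_TOL = 1e-9


@dataclass
class DecompositionResult:
    """Factor matrices and scalar summaries of one Lu-Chipman decomposition."""

    m_delta: MuellerMatrix
    m_r: MuellerMatrix
    m_d: MuellerMatrix
    d: float
    delta_net: float
    delta_lin: float
    r_total: float
    psi: float
    flags: list = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        return self.m_delta.m @ self.m_r.m @ self.m_d.m


def diattenuation_of(m: MuellerMatrix) -> float:
    """Diattenuation from the first row: sqrt(M(1,2)²+M(1,3)²+M(1,4)²)/M(1,1)."""
    return float(np.linalg.norm(m.m[0, 1:]) / m.m[0, 0])


def depolarization_of(m_delta: MuellerMatrix) -> float:
    """Net depolarization Δ = 1 − |tr(lower-right 3×3)| / 3 of a depolarizer
    factor."""
    return float(1.0 - abs(np.trace(m_delta.m[1:, 1:])) / 3.0)


def linear_retardance_of(m_r: MuellerMatrix) -> tuple:
    """(delta_lin, r_total, psi) of a pure retarder factor, radians.

    r_total = arccos(tr(M_R)/2 − 1); psi is the optical-rotation angle.
    Arccos arguments are clamped to [−1, 1].
    """
    m = m_r.m
    r_arg = np.clip(np.trace(m) / 2.0 - 1.0, -1.0, 1.0)
    r_total = float(np.arccos(r_arg))
    a = m[1, 1] + m[2, 2]
    b = m[2, 1] - m[1, 2]
    lin_arg = np.clip(np.sqrt(a * a + b * b) - 1.0, -1.0, 1.0)
    delta_lin = float(np.arccos(lin_arg))
    psi = float(0.5 * np.arctan2(b, a))
    return delta_lin, r_total, psi


def compose(
    d: float,
    theta_d: float,
    delta_lin: float,
    theta_r: float,
    delta_net: float,
) -> MuellerMatrix:
    """Forward model: depolarizer(uniform 1−Δ) · retarder(δ, θ_r) ·
    diattenuator(d, θ_d), normalized.  Domain-checks every parameter."""
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"diattenuation must lie in [0, 1], got {d}")
    if not 0.0 <= delta_net <= 1.0:
        raise ValueError(f"net depolarization must lie in [0, 1], got {delta_net}")
    if not 0.0 <= delta_lin <= np.pi:
        raise ValueError(f"linear retardance must lie in [0, pi], got {delta_lin}")
    f = 1.0 - delta_net
    m = (
        depolarizer(f, f, f).m
        @ linear_retarder(delta_lin, theta_r).m
        @ linear_diattenuator(d, theta_d).m
    )
    return MuellerMatrix(m=m / m[0, 0], normalized=True)


def lu_chipman(m: MuellerMatrix) -> DecompositionResult:
    """Polar-decompose a normalized Mueller matrix.

    Returns the three factors (depolarizer last applied) and the scalar
    descriptors.  Degenerate inputs take flagged fallback paths rather
    than raising.
    """
    mm = m.m / m.m[0, 0]
    flags: list = []

    dvec = mm[0, 1:].copy()
    d = float(np.linalg.norm(dvec))
    m_d = _diattenuator_from_vector(dvec)

    if d >= 1.0 - PURE_DIATTENUATOR_TOL:
        # non-invertible diattenuator: all residual structure goes to the
        # depolarizer, retarder taken as identity
        flags.append("pure-diattenuator")
        m_prime = mm @ np.linalg.pinv(m_d)
        m_delta4 = m_prime
        m_r3 = np.eye(3)
    else:
        m_prime = mm @ np.linalg.inv(m_d)
        m_delta3, m_r3, more_flags = _depolarizer_retarder_split(m_prime[1:, 1:])
        flags.extend(more_flags)
        pvec = mm[1:, 0]
        p_delta = (pvec - mm[1:, 1:] @ dvec) / (1.0 - d * d)
        m_delta4 = np.eye(4)
        m_delta4[1:, 0] = p_delta
        m_delta4[1:, 1:] = m_delta3

    m_r4 = np.eye(4)
    m_r4[1:, 1:] = m_r3

    res = DecompositionResult(
        m_delta=MuellerMatrix(m_delta4, normalized=True),
        m_r=MuellerMatrix(m_r4, normalized=True),
        m_d=MuellerMatrix(m_d, normalized=True),
        d=d,
        delta_net=depolarization_of(MuellerMatrix(m_delta4)),
        delta_lin=0.0,
        r_total=0.0,
        psi=0.0,
        flags=flags,
    )
    res.delta_lin, res.r_total, res.psi = linear_retardance_of(res.m_r)
    return res


def _depolarizer_retarder_split(m_prime3: np.ndarray) -> tuple:
    """Split the 3×3 block of M' = M_Δ·M_R into (m_Δ, m_R).

    m_Δ = ±[m'm'ᵀ + c2·I]⁻¹ [c1·m'm'ᵀ + c3·I] with c1 = Σ√λ,
    c2 = Σ√(λiλj), c3 = √(λ1λ2λ3) over the eigenvalues λ of m'm'ᵀ and
    sign = sign(det m'); then m_R = m_Δ⁻¹ m'.
    """
    flags = []
    mmt = m_prime3 @ m_prime3.T
    lam = np.linalg.eigvalsh(mmt)
    if np.any(lam < -EIG_CLAMP_TOL):
        flags.append("clamped-eigenvalue")
    lam = np.clip(lam, 0.0, None)
    s = np.sqrt(lam)
    c1 = s.sum()
    c2 = s[0] * s[1] + s[1] * s[2] + s[2] * s[0]
    c3 = s[0] * s[1] * s[2]
    sign = 1.0 if np.linalg.det(m_prime3) >= 0 else -1.0
    lhs = mmt + c2 * np.eye(3)
    rhs = c1 * mmt + c3 * np.eye(3)
    try:
        m_delta3 = sign * np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError:
        flags.append("singular-depolarizer")
        m_delta3 = sign * (np.linalg.pinv(lhs) @ rhs)
    try:
        m_r3 = np.linalg.solve(m_delta3, m_prime3)
    except np.linalg.LinAlgError:
        flags.append("singular-depolarizer")
        m_r3 = np.linalg.pinv(m_delta3) @ m_prime3
    return m_delta3, m_r3, flags


# ---------------------------------------------------------------------------
# per-pixel (batched) decomposition


def decompose_image(m_img: np.ndarray, labels: np.ndarray | None = None) -> dict:
    """Decompose an (H, W, 4, 4) normalized Mueller field pixel by pixel.

    Runs the same construction as :func:`lu_chipman` with batched linear
    algebra.  Returns per-pixel planes ``d``, ``delta_net``, ``delta_lin``,
    ``r_total``, ``psi``, boolean flag planes, and a ``summary`` dict of
    arithmetic means over unflagged pixels (per label class when ``labels``
    is given).
    """
    m = np.asarray(m_img, dtype=float)
    if m.ndim != 4 or m.shape[2:] != (4, 4):
        raise ValueError(f"expected (H, W, 4, 4) field, got {m.shape}")
    h, w = m.shape[:2]
    flat = (m / m[..., 0:1, 0:1]).reshape(-1, 4, 4)
    n = flat.shape[0]

    dvec = flat[:, 0, 1:]
    d = np.linalg.norm(dvec, axis=1)
    pure = d >= 1.0 - PURE_DIATTENUATOR_TOL
    d_safe = np.where(pure, 0.0, d)

    # batched M_D and its inverse (analytic: invert by negating D and
    # rescaling) — build directly instead
    root = np.sqrt(np.clip(1.0 - d_safe**2, 0.0, None))
    denom = np.where(d_safe > 0, d_safe, 1.0)
    dhat = np.where(d_safe[:, None] > 0, dvec / denom[:, None], 0.0)
    outer = dhat[:, :, None] * dhat[:, None, :]
    md = np.zeros((n, 4, 4))
    md[:, 0, 0] = 1.0
    md[:, 0, 1:] = np.where(pure[:, None], 0.0, dvec)
    md[:, 1:, 0] = md[:, 0, 1:]
    md[:, 1:, 1:] = root[:, None, None] * np.eye(3) + (1.0 - root)[:, None, None] * outer

    m_prime = flat @ np.linalg.inv(md)
    mp3 = m_prime[:, 1:, 1:]
    mmt = mp3 @ np.transpose(mp3, (0, 2, 1))
    lam = np.linalg.eigvalsh(mmt)
    clamped = np.any(lam < -EIG_CLAMP_TOL, axis=1)
    lam = np.clip(lam, 0.0, None)
    s = np.sqrt(lam)
    c1 = s.sum(axis=1)
    c2 = s[:, 0] * s[:, 1] + s[:, 1] * s[:, 2] + s[:, 2] * s[:, 0]
    c3 = s[:, 0] * s[:, 1] * s[:, 2]
    sign = np.where(np.linalg.det(mp3) >= 0, 1.0, -1.0)
    eye3 = np.eye(3)
    lhs = mmt + c2[:, None, None] * eye3
    rhs = c1[:, None, None] * mmt + c3[:, None, None] * eye3
    singular = np.abs(np.linalg.det(lhs)) < 1e-300
    lhs_safe = np.where(singular[:, None, None], eye3, lhs)
    m_delta3 = sign[:, None, None] * np.linalg.solve(lhs_safe, rhs)
    det_md3 = np.linalg.det(m_delta3)
    sing_delta = np.abs(det_md3) < 1e-300
    md3_safe = np.where(sing_delta[:, None, None], eye3, m_delta3)
    m_r3 = np.linalg.solve(md3_safe, mp3)

    delta_net = 1.0 - np.abs(np.trace(m_delta3, axis1=1, axis2=2)) / 3.0
    a = m_r3[:, 0, 0] + m_r3[:, 1, 1]
    b = m_r3[:, 1, 0] - m_r3[:, 0, 1]
    delta_lin = np.arccos(np.clip(np.sqrt(a * a + b * b) - 1.0, -1.0, 1.0))
    r_total = np.arccos(np.clip((1.0 + np.trace(m_r3, axis1=1, axis2=2)) / 2.0 - 1.0, -1.0, 1.0))
    psi = 0.5 * np.arctan2(b, a)

    flagged = pure | clamped | singular | sing_delta
    out = {
        "d": d.reshape(h, w),
        "delta_net": delta_net.reshape(h, w),
        "delta_lin": delta_lin.reshape(h, w),
        "r_total": r_total.reshape(h, w),
        "psi": psi.reshape(h, w),
        "flag_pure_diattenuator": pure.reshape(h, w),
        "flag_clamped_eigenvalue": clamped.reshape(h, w),
        "flag_singular": (singular | sing_delta).reshape(h, w),
    }
    out["summary"] = _summaries(out, flagged.reshape(h, w), labels)
    return out


def _summaries(planes: dict, flagged: np.ndarray, labels) -> dict:
    def region_stats(mask):
        ok = mask & ~flagged
        npx = int(ok.sum())
        if npx == 0:
            return {"d": float("nan"), "delta_net": float("nan"),
                    "delta_lin": float("nan"), "n_pixels": 0,
                    "n_flagged": int((mask & flagged).sum())}
        return {
            "d": float(planes["d"][ok].mean()),
            "delta_net": float(planes["delta_net"][ok].mean()),
            "delta_lin": float(planes["delta_lin"][ok].mean()),
            "n_pixels": npx,
            "n_flagged": int((mask & flagged).sum()),
        }

    all_mask = np.ones_like(flagged, dtype=bool)
    summary = {"all": region_stats(all_mask)}
    if labels is not None:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            summary[str(lab)] = region_stats(labels == lab)
    return summary
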