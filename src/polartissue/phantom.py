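"""Synthetic tissue-phantom generator.

Renders four-state (H/P/V/R), four-channel detector intensity stacks for
two tissue classes — "normal" and "tumour" — whose per-pixel Mueller
matrices are composed from class preset values of diattenuation d, linear
retardance δ and net depolarization Δ.  The presets are the region-level
values a transmission Mueller polarimeter reports for healthy versus
invasive-ductal-carcinoma breast tissue:

    normal : d = 0.043, δ = 2.373 rad, Δ = 0.644
    tumour : d = 0.110, δ = 0.748 rad, Δ = 0.826

Class-distinct spatial structure enters through the optical parameters
themselves rather than through post-hoc image noise, mirroring the physical
picture that image contrast is mediated by collagen-fibre organisation:

* multiplicative Gaussian random fields on (d, δ, Δ) with class-specific
  correlation length — long/smooth for the ordered collagen of normal
  stroma, short/patchy for tumour;
* a fast-axis orientation field: normal tissue jitters mildly around one
  base direction (aligned fibres), tumour draws an independent uniform
  orientation per correlation cell (disordered fibres).

Per pixel, M = depolarizer·retarder·diattenuator is applied to each of the
four probe states and projected through the instrument's analyzer matrix;
Gaussian read noise (and optional Poisson shot noise) is added last.
Ground-truth fields are kept alongside the stacks so every downstream
stage can be checked against what was rendered.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .mueller import (
    depolarizer,
    ideal_instrument,
    input_states,
    linear_diattenuator,
    linear_retarder,
)

__all__ = [
    "ClassPreset",
    "PhantomConfig",
    "PhantomRegion",
    "PhantomDataset",
    "sample_parameter_fields",
    "forward_intensities",
    "render_region",
    "render_dataset",
    "compose_field",
    "write_dataset",
    "read_dataset",
]

STATE_ORDER = ("H", "P", "V", "R")


@dataclass(frozen=True)
class ClassPreset:
    """Region-level optical parameters of one tissue class."""

    d: float
    delta_lin: float
    delta_net: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.d <= 1.0:
            raise ValueError(f"diattenuation preset out of [0,1]: {self.d}")
        if not 0.0 <= self.delta_lin <= np.pi:
            raise ValueError(f"retardance preset out of [0,pi]: {self.delta_lin}")
        if not 0.0 <= self.delta_net <= 1.0:
            raise ValueError(f"depolarization preset out of [0,1]: {self.delta_net}")


NORMAL_PRESET = ClassPreset(d=0.043, delta_lin=2.373, delta_net=0.644)
TUMOUR_PRESET = ClassPreset(d=0.11, delta_lin=0.748, delta_net=0.826)


@dataclass
class PhantomConfig:
    """Generator settings.

    Defaults define the study conditions: 256×256 px regions, four regions
    per class, 10 % relative parameter texture with correlation length
    24 px (normal) / 6 px (tumour), 5° orientation jitter for normal tissue
    versus per-cell random orientation for tumour, and 0.5 % full-scale
    Gaussian read noise.
    """

    image_size: tuple = (256, 256)
    normal: ClassPreset = field(default_factory=lambda: NORMAL_PRESET)
    tumour: ClassPreset = field(default_factory=lambda: TUMOUR_PRESET)
    texture_amplitude: float = 0.10
    corr_length_normal: float = 24.0
    corr_length_tumour: float = 6.0
    orientation_jitter_deg: float = 5.0
    base_orientation_deg: float = 30.0
    noise_sigma: float = 0.005  # fraction of full scale
    shot_noise: bool = False
    shot_noise_photons: float = 1e4
    n_regions: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.corr_length_normal <= 0 or self.corr_length_tumour <= 0:
            raise ValueError("correlation lengths must be positive")
        if self.texture_amplitude < 0:
            raise ValueError("texture amplitude must be non-negative")

    def preset(self, class_label: str) -> ClassPreset:
        if class_label == "normal":
            return self.normal
        if class_label == "tumour":
            return self.tumour
        raise ValueError(f"unknown class label {class_label!r}")

    def corr_length(self, class_label: str) -> float:
        return self.corr_length_normal if class_label == "normal" else self.corr_length_tumour

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PhantomRegion:
    """One rendered region: intensity stacks, ground truth, provenance."""

    region_id: str
    class_label: str
    seed: int
    stacks: dict  # state -> (4, H, W) channel intensities
    fields: dict  # 'd', 'delta_lin', 'delta_net', 'theta' -> (H, W)


@dataclass
class PhantomDataset:
    regions: list
    config: PhantomConfig

    def by_class(self, class_label: str) -> list:
        return [r for r in self.regions if r.class_label == class_label]

    def manifest(self) -> dict:
        return {
            "config_hash": self.config.config_hash(),
            "config": self.config.to_dict(),
            "regions": [
                {"region_id": r.region_id, "class": r.class_label, "seed": r.seed}
                for r in self.regions
            ],
        }


def _gaussian_random_field(rng: np.random.Generator, shape, corr_length: float) -> np.ndarray:
    """Smooth zero-mean unit-variance field: white noise blurred with a
    Gaussian kernel of width corr_length/2 then re-standardised."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=corr_length / 2.0, mode="wrap")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def sample_parameter_fields(cfg: PhantomConfig, class_label: str, seed: int) -> dict:
    """Ground-truth per-pixel (d, δ, Δ, θ) fields for one region.

    Multiplicative texture: each optical parameter is its class preset times
    (1 + amplitude · G) with G a smooth unit-variance field, clipped to the
    parameter's physical range.  Orientation: normal = base direction plus
    Gaussian jitter; tumour = uniform random direction per correlation cell.
    """
    preset = cfg.preset(class_label)
    shape = tuple(cfg.image_size)
    rng = np.random.default_rng(seed)
    corr = cfg.corr_length(class_label)

    def textured(value, lo, hi):
        g = _gaussian_random_field(rng, shape, corr)
        return np.clip(value * (1.0 + cfg.texture_amplitude * g), lo, hi)

    d_field = textured(preset.d, 0.0, 1.0)
    delta_lin_field = textured(preset.delta_lin, 0.0, np.pi)
    delta_net_field = textured(preset.delta_net, 0.0, 1.0)

    if class_label == "normal":
        base = np.deg2rad(cfg.base_orientation_deg)
        jitter = np.deg2rad(cfg.orientation_jitter_deg)
        theta = base + jitter * _gaussian_random_field(rng, shape, corr)
    else:
        # one independent uniform orientation per correlation cell
        cell = max(1, int(round(corr)))
        nh = -(-shape[0] // cell)
        nw = -(-shape[1] // cell)
        coarse = rng.uniform(0.0, np.pi, size=(nh, nw))
        theta = np.kron(coarse, np.ones((cell, cell)))[: shape[0], : shape[1]]

    return {
        "d": d_field,
        "delta_lin": delta_lin_field,
        "delta_net": delta_net_field,
        "theta": theta,
    }


def compose_field(fields: dict) -> np.ndarray:
    """Per-pixel Mueller field (H, W, 4, 4) from ground-truth parameters:
    depolarizer · retarder(δ, θ) · diattenuator(d, θ)."""
    d = np.asarray(fields["d"], dtype=float)
    dl = np.asarray(fields["delta_lin"], dtype=float)
    dn = np.asarray(fields["delta_net"], dtype=float)
    th = np.asarray(fields["theta"], dtype=float)
    h, w = d.shape

    c2t, s2t = np.cos(2 * th), np.sin(2 * th)
    cd, sd = np.cos(dl), np.sin(dl)

    # retarder, fast axis th
    mr = np.zeros((h, w, 4, 4))
    mr[..., 0, 0] = 1.0
    mr[..., 1, 1] = c2t**2 + s2t**2 * cd
    mr[..., 1, 2] = c2t * s2t * (1 - cd)
    mr[..., 1, 3] = -s2t * sd
    mr[..., 2, 1] = mr[..., 1, 2]
    mr[..., 2, 2] = s2t**2 + c2t**2 * cd
    mr[..., 2, 3] = c2t * sd
    mr[..., 3, 1] = s2t * sd
    mr[..., 3, 2] = -c2t * sd
    mr[..., 3, 3] = cd

    # diattenuator, same axis
    dvec = np.stack([d * c2t, d * s2t, np.zeros_like(d)], axis=-1)
    root = np.sqrt(np.clip(1.0 - d**2, 0.0, None))
    dnorm = np.where(d > 0, d, 1.0)
    dhat = dvec / dnorm[..., None]
    md = np.zeros((h, w, 4, 4))
    md[..., 0, 0] = 1.0
    md[..., 0, 1:] = dvec
    md[..., 1:, 0] = dvec
    md[..., 1:, 1:] = root[..., None, None] * np.eye(3) + (
        1.0 - root[..., None, None]
    ) * (dhat[..., :, None] * dhat[..., None, :])

    # uniform depolarizer
    f = 1.0 - dn
    mdep = np.zeros((h, w, 4, 4))
    mdep[..., 0, 0] = 1.0
    for k in (1, 2, 3):
        mdep[..., k, k] = f

    return mdep @ mr @ md


def forward_intensities(fields: dict, cfg: PhantomConfig, seed: int | None = None) -> dict:
    """Detector stacks: per pixel S_out = M·S_in for each probe state, then
    channels = A·S_out through the ideal analyzer matrix, scaled to [0, 1]
    full range; noise added last.  Returns {state: (4, H, W)}."""
    m_field = compose_field(fields)
    inst = ideal_instrument()
    rng = np.random.default_rng(seed)
    states = input_states()
    stacks = {}
    for name in STATE_ORDER:
        s_in = states[name]
        s_out = np.einsum("hwij,j->hwi", m_field, s_in)
        channels = inst.project(s_out)  # (H, W, 4)
        channels = np.clip(channels, 0.0, None)
        if cfg.shot_noise and seed is not None:
            scale = cfg.shot_noise_photons
            channels = rng.poisson(np.clip(channels, 0, None) * scale) / scale
        if cfg.noise_sigma > 0 and seed is not None:
            channels = channels + rng.normal(0.0, cfg.noise_sigma, channels.shape)
        stacks[name] = np.clip(channels, 0.0, None).transpose(2, 0, 1)
    return stacks


def render_region(cfg: PhantomConfig, class_label: str, region_index: int) -> PhantomRegion:
    """Render one region with a sub-seed derived from (config seed, class,
    index); regeneration with the same inputs is bit-identical."""
    tag = f"{cfg.seed}-{class_label}-{region_index}"
    sub_seed = int.from_bytes(hashlib.sha256(tag.encode()).digest()[:4], "big") % (2**31)
    fields = sample_parameter_fields(cfg, class_label, sub_seed)
    noise_seed = None if cfg.noise_sigma == 0 and not cfg.shot_noise else sub_seed + 1
    stacks = forward_intensities(fields, cfg, seed=noise_seed)
    return PhantomRegion(
        region_id=f"{class_label}_{region_index:02d}",
        class_label=class_label,
        seed=sub_seed,
        stacks=stacks,
        fields=fields,
    )


def render_dataset(cfg: PhantomConfig) -> PhantomDataset:
    """Render n_regions per class (default 4 normal + 4 tumour)."""
    regions = [
        render_region(cfg, label, i)
        for label in ("normal", "tumour")
        for i in range(cfg.n_regions)
    ]
    return PhantomDataset(regions=regions, config=cfg)


def write_dataset(ds: PhantomDataset, out_dir) -> None:
    """One directory per region: four 4-plane float TIFF state stacks,
    ground-truth field TIFFs, and a JSON manifest at the root."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for r in ds.regions:
        rdir = out / r.region_id
        rdir.mkdir(exist_ok=True)
        for state in STATE_ORDER:
            tifffile.imwrite(rdir / f"stack_{state}.tif", r.stacks[state].astype(np.float32), photometric="minisblack")
        for name, fld in r.fields.items():
            tifffile.imwrite(rdir / f"truth_{name}.tif", fld.astype(np.float32), photometric="minisblack")
        (rdir / "region.json").write_text(
            json.dumps({"region_id": r.region_id, "class": r.class_label, "seed": r.seed})
        )
    (out / "manifest.json").write_text(json.dumps(ds.manifest(), indent=2))


def read_dataset(in_dir) -> PhantomDataset:
    """Load a dataset previously written by :func:`write_dataset`."""
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    cfg_d = dict(manifest["config"])
    cfg_d["normal"] = ClassPreset(**cfg_d["normal"])
    cfg_d["tumour"] = ClassPreset(**cfg_d["tumour"])
    cfg_d["image_size"] = tuple(cfg_d["image_size"])
    cfg = PhantomConfig(**cfg_d)
    regions = []
    for entry in manifest["regions"]:
        rdir = root / entry["region_id"]
        if not rdir.is_dir():
            raise FileNotFoundError(f"missing region directory {rdir}")
        stacks = {}
        for state in STATE_ORDER:
            p = rdir / f"stack_{state}.tif"
            if not p.exists():
                raise FileNotFoundError(f"missing state stack {state} at {p}")
            stacks[state] = np.asarray(tifffile.imread(p), dtype=float)
        fields = {
            name: np.asarray(tifffile.imread(rdir / f"truth_{name}.tif"), dtype=float)
            for name in ("d", "delta_lin", "delta_net", "theta")
        }
        regions.append(
            PhantomRegion(
                region_id=entry["region_id"],
                class_label=entry["class"],
                seed=entry["seed"],
                stacks=stacks,
                fields=fields,
            )
        )
    return PhantomDataset(regions=regions, config=cfg)
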