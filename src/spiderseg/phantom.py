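"""Synthetic brain-like MRI phantoms with ground-truth masks.

The phantoms are procedural, not anatomical: a dark background, a bright
elliptical skull annulus, two brain-tissue intensity regimes and, for
tumor-labeled samples, one ellipsoidal lesion blob. The five intensity
regimes make 5-region multilevel thresholding well posed, and the
background stays below the 12.75 binarization cut so foreground extraction
separates it cleanly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ValidationError
from .preprocess import BINARIZATION_CUT

REGION_ROLES = ("background", "skull", "outer_tissue", "inner_tissue", "tumor")

DEFAULT_MEANS = {
    "background": 5.0,
    "skull": 230.0,
    "outer_tissue": 90.0,
    "inner_tissue": 140.0,
    "tumor": 200.0,
}
DEFAULT_SDS = {
    "background": 1.5,
    "skull": 4.0,
    "outer_tissue": 5.0,
    "inner_tissue": 5.0,
    "tumor": 5.0,
}

NORMAL, TUMOR = "normal", "tumor"


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic dataset generator."""

    image_size: int = 250
    n_normal: int = 60
    n_tumor: int = 60
    intensity_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MEANS))
    intensity_sds: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SDS))
    tumor_radius_range: tuple[float, float] = (0.10, 0.25)
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        means, sds = self.intensity_means, self.intensity_sds
        for role in REGION_ROLES:
            if role not in means or role not in sds:
                raise ValidationError(f"intensity_means/intensity_sds must define {role!r}")
        if self.image_size < 16:
            raise ValidationError("image_size must be >= 16")
        if self.n_normal < 0 or self.n_tumor < 0:
            raise ValidationError("sample counts must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        lo, hi = self.tumor_radius_range
        if not 0 < lo <= hi < 1:
            raise ValidationError("tumor_radius_range must satisfy 0 < min <= max < 1")
        for role in REGION_ROLES:
            if not 0 <= means[role] <= 255:
                raise ValidationError(f"mean intensity of {role!r} outside [0, 255]")
            if sds[role] < 0:
                raise ValidationError(f"intensity sd of {role!r} must be >= 0")
        bg_cap = means["background"] + 3 * sds["background"]
        if bg_cap >= BINARIZATION_CUT:
            raise ValidationError(
                "background mean + 3*sd must stay below the binarization cut "
                f"{BINARIZATION_CUT} (got {bg_cap})"
            )
        roles = list(REGION_ROLES)
        for i, a in enumerate(roles):
            for b in roles[i + 1:]:
                gap = abs(means[a] - means[b])
                if gap < 4 * max(sds[a], sds[b]):
                    raise ValidationError(
                        f"region means of {a!r} and {b!r} separated by {gap}, "
                        f"need >= 4x the larger sd ({max(sds[a], sds[b])})"
                    )


@dataclass(frozen=True)
class PhantomSample:
    """One generated phantom: image, class label, and ground-truth masks."""

    image: np.ndarray
    label: str
    tumor_mask: np.ndarray
    brain_mask: np.ndarray
    head_mask: np.ndarray  # brain + skull, i.e. everything above background


def _ellipse(size: int, cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def _region_noise(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    # Truncated at +-3 sd so the background invariant guarantees pixels
    # below the binarization cut when noise_sd = 0.
    if sd == 0:
        return np.zeros(n)
    return np.clip(rng.normal(0.0, sd, n), -3 * sd, 3 * sd)


def _draw(spec: PhantomSpec, label: str, rng: np.random.Generator) -> PhantomSample:
    if label not in (NORMAL, TUMOR):
        raise ValidationError(f"label must be {NORMAL!r} or {TUMOR!r}, got {label!r}")
    size = spec.image_size
    c = (size - 1) / 2.0
    rx, ry = 0.42 * size, 0.46 * size
    head = _ellipse(size, c, c, rx, ry)
    brain = _ellipse(size, c, c, 0.85 * rx, 0.85 * ry)
    inner = _ellipse(size, c, c, 0.55 * rx, 0.55 * ry)
    skull = head & ~brain
    outer = brain & ~inner

    tumor = np.zeros((size, size), dtype=bool)
    if label == TUMOR:
        lo, hi = spec.tumor_radius_range
        brain_r = 0.85 * min(rx, ry)
        r = rng.uniform(lo, hi) * brain_r
        squash = rng.uniform(0.9, 1.1)
        trx, try_ = r * squash, r / squash
        # Place the lesion fully inside the inner-tissue ellipse.
        max_dx = max(0.55 * rx - trx - 2, 0.0)
        max_dy = max(0.55 * ry - try_ - 2, 0.0)
        theta = rng.uniform(0, 2 * np.pi)
        rho = np.sqrt(rng.uniform(0, 1))
        tumor = _ellipse(size, c + rho * max_dx * np.cos(theta),
                         c + rho * max_dy * np.sin(theta), trx, try_)

    means, sds = spec.intensity_means, spec.intensity_sds
    img = np.full((size, size), means["background"], dtype=np.float64)
    img[~head] += _region_noise(rng, sds["background"], int((~head).sum()))
    for role, mask in (("skull", skull), ("outer_tissue", outer),
                       ("inner_tissue", inner & ~tumor), ("tumor", tumor)):
        n = int(mask.sum())
        if n:
            img[mask] = means[role] + _region_noise(rng, sds[role], n)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return PhantomSample(
        image=img,
        label=label,
        tumor_mask=tumor.astype(np.uint8),
        brain_mask=brain.astype(np.uint8),
        head_mask=head.astype(np.uint8),
    )


def generate_phantom(spec: PhantomSpec, label: str) -> PhantomSample:
    """Generate a single phantom; bit-identical for identical spec + label."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0 if label == NORMAL else 1]))
    return _draw(spec, label, rng)


def generate_samples(spec: PhantomSpec) -> list[PhantomSample]:
    """Generate the full labeled sample set in memory (normals first)."""
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_normal + spec.n_tumor)
    samples = []
    for i, child in enumerate(children):
        label = NORMAL if i < spec.n_normal else TUMOR
        samples.append(_draw(spec, label, np.random.default_rng(child)))
    return samples


def generate_dataset(spec: PhantomSpec, out_dir) -> pd.DataFrame:
    """Write PNG images + mask PNGs + a ``filename,label`` CSV manifest.

    Returns the manifest as a DataFrame; it is also written to
    ``out_dir/manifest.csv``.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(exist_ok=True)
        rows = []
        for i, sample in enumerate(generate_samples(spec)):
            name = f"{sample.label}_{i:04d}.png"
            Image.fromarray(sample.image, mode="L").save(out / name)
            Image.fromarray(sample.tumor_mask * 255, mode="L").save(
                out / "masks" / name.replace(".png", "_tumor.png"))
            rows.append({"filename": name, "label": sample.label})
        manifest = pd.DataFrame(rows, columns=["filename", "label"])
        manifest.to_csv(out / "manifest.csv", index=False)
        return manifest
    except OSError as exc:
        raise OSError(f"failed writing phantom dataset under {out}: {exc}") from exc


def spec_from_dict(d: Mapping) -> PhantomSpec:
    """Build a PhantomSpec from a config mapping, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(PhantomSpec)}
    unknown = set(d) - known
    if unknown:
        raise ValidationError(f"unknown phantom config keys: {sorted(unknown)}")
    return PhantomSpec(**d)
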