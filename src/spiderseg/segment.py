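"""Multilevel thresholding segmentation driven by Tsallis entropy.

A C-region segmentation is parameterized by m = C - 1 strictly increasing
integer thresholds. Internally a threshold vector (t_1 .. t_m) uses the
lower-bound convention: region 1 = [0, t_1 - 1], region j = [t_{j-1},
t_j - 1], region C = [t_m, 255]. The user-facing "inclusive" convention
instead lists the inclusive upper bound of each region except the last
(an entry of 20 means region 1 = [0, 20]); conversion is explicit.

The objective is the pseudo-additive Tsallis combination of per-region
entropies computed on renormalized within-region distributions; it is
maximized either exhaustively (small instances) or with the social spider
optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from . import sso
from .errors import DataError, ValidationError

DEFAULT_Q = 0.8


@dataclass(frozen=True)
class Histogram:
    """Normalized 256-bin intensity histogram."""

    probs: np.ndarray
    n_pixels: int

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        if p.shape != (256,):
            raise ValidationError(f"histogram must have 256 bins, got {p.shape}")
        if (p < 0).any():
            raise ValidationError("histogram probabilities must be >= 0")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError("histogram probabilities must sum to 1")
        object.__setattr__(self, "probs", p)


@dataclass(frozen=True)
class ThresholdVector:
    """Strictly increasing integer thresholds in [1, 255], lower-bound convention."""

    thresholds: tuple[int, ...]

    def __post_init__(self):
        ts = tuple(int(t) for t in self.thresholds)
        if any(not 1 <= t <= 255 for t in ts):
            raise ValidationError(f"thresholds must lie in [1, 255], got {ts}")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValidationError(f"thresholds must be strictly increasing, got {ts}")
        object.__setattr__(self, "thresholds", ts)

    @property
    def region_count(self) -> int:
        return len(self.thresholds) + 1

    def to_inclusive(self) -> tuple[int, ...]:
        """Inclusive upper bounds of regions 1..m (region j = [.., t_j])."""
        return tuple(t - 1 for t in self.thresholds)

    @classmethod
    def from_inclusive(cls, uppers) -> "ThresholdVector":
        """Build from inclusive region upper bounds (the Fig.-style vector)."""
        return cls(tuple(int(u) + 1 for u in uppers))


@dataclass(frozen=True)
class SegmentedImage:
    """Per-pixel region labels in [1, C] plus the thresholds that made them."""

    labels: np.ndarray
    thresholds: ThresholdVector
    fitness: float


def image_histogram(image) -> Histogram:
    """Probability of each 8-bit level over ALL pixels (background included)."""
    arr = np.asarray(image)
    if arr.size == 0:
        raise DataError("cannot histogram an empty image")
    counts = np.bincount(arr.ravel().astype(np.int64), minlength=256)
    if len(counts) > 256:
        raise ValidationError("pixel values must lie in [0, 255]")
    return Histogram(probs=counts / arr.size, n_pixels=int(arr.size))


def tsallis_entropy(probs, q: float) -> float:
    """Generalized entropy ``(1 - sum p_i^q) / (q - 1)``; q > 0, q != 1."""
    p = np.asarray(probs, dtype=np.float64)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError("probs must be a probability vector")
    if q <= 0:
        raise ValidationError("entropic index q must be > 0")
    if q == 1:
        raise ValidationError("q = 1 is the Shannon limit; use shannon_entropy")
    return float((1.0 - (p[p > 0] ** q).sum()) / (q - 1.0))


def shannon_entropy(probs) -> float:
    """``-sum p_i ln p_i`` (natural log), the q -> 1 limit of tsallis_entropy."""
    p = np.asarray(probs, dtype=np.float64)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _region_entropies(hist: Histogram, thresholds: tuple[int, ...], q: float) -> np.ndarray:
    p = hist.probs
    bounds = (0, *thresholds, 256)
    out = np.zeros(len(bounds) - 1)
    for j in range(len(bounds) - 1):
        seg = p[bounds[j]:bounds[j + 1]]
        mass = seg.sum()
        if mass > 0:
            seg = seg[seg > 0] / mass
            out[j] = (1.0 - (seg**q).sum()) / (q - 1.0)
    return out


def segmentation_fitness(hist: Histogram, thr: ThresholdVector, q: float = DEFAULT_Q) -> float:
    """Pseudo-additive Tsallis objective: ``sum S_j + (1-q) * prod S_j``.

    Per-region entropies are computed on within-region renormalized
    distributions; regions with zero mass contribute 0.
    """
    if q <= 0 or q == 1:
        raise ValidationError("entropic index q must be > 0 and != 1")
    s = _region_entropies(hist, thr.thresholds, q)
    if len(s) == 1:  # single region: nothing to combine
        return float(s[0])
    return float(s.sum() + (1.0 - q) * s.prod())


def repair_thresholds(raw, m: int) -> ThresholdVector:
    """Round, sort, and de-duplicate a candidate vector into a valid one."""
    t = np.sort(np.round(np.asarray(raw, dtype=np.float64))).astype(int)
    if t.shape != (m,):
        raise ValidationError(f"expected {m} thresholds, got shape {t.shape}")
    t = np.clip(t, 1, 255)
    for i in range(1, m):
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + 1
    # Push back below 255 if the de-duplication overflowed the top.
    for i in range(m - 1, -1, -1):
        cap = 255 - (m - 1 - i)
        if t[i] > cap:
            t[i] = cap
    for i in range(1, m):
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + 1
    return ThresholdVector(tuple(int(x) for x in t))


def exhaustive_thresholds(hist: Histogram, m: int, q: float = DEFAULT_Q
                          ) -> tuple[ThresholdVector, float]:
    """Globally optimal thresholds by brute force; lexicographic tie-break.

    Only thresholds up to (max populated level + m) need enumerating: any
    vector beyond that range produces region contents identical to one
    inside it.
    """
    if m == 0:
        return ThresholdVector(()), tsallis_entropy(hist.probs, q)
    top = int(np.max(np.nonzero(hist.probs)[0]))
    hi = min(top + m, 255)
    n_levels = top + 1
    n_combos = 1.0
    for i in range(m):
        n_combos *= (hi - i) / (i + 1)
    if n_levels > 32 and m > 3:
        raise ValidationError(
            f"exhaustive search infeasible for {n_levels} levels and m={m}; use SSO")
    if n_combos > 5e6:
        raise ValidationError("exhaustive search space too large; use SSO")
    best_thr, best_fit = None, -np.inf
    for combo in combinations(range(1, hi + 1), m):
        thr = ThresholdVector(combo)
        f = segmentation_fitness(hist, thr, q)
        if f > best_fit:
            best_fit, best_thr = f, thr
    return best_thr, float(best_fit)


def apply_thresholds(image, thr: ThresholdVector) -> np.ndarray:
    """Label every pixel with its region index in [1, C]."""
    arr = np.asarray(image)
    ts = np.asarray(thr.thresholds)
    return (np.searchsorted(ts, arr.ravel(), side="right").reshape(arr.shape) + 1).astype(np.uint8)


def segment_image(image, C: int = 5, q: float = DEFAULT_Q,
                  sso_config: sso.SSOConfig | None = None, seed: int = 0) -> SegmentedImage:
    """Segment an image into C regions by SSO-maximized Tsallis fitness."""
    if C < 2:
        raise ValidationError("region count C must be >= 2")
    m = C - 1
    hist = image_histogram(image)
    if sso_config is None:
        sso_config = sso.SSOConfig(bounds=tuple((1.0, 254.0) for _ in range(m)), seed=seed)
    elif len(sso_config.bounds) != m:
        raise ValidationError(
            f"sso_config has {len(sso_config.bounds)} dimensions, need m={m}")

    def objective(x: np.ndarray) -> float:
        return segmentation_fitness(hist, repair_thresholds(x, m), q)

    result = sso.optimize(objective, sso_config)
    thr = repair_thresholds(result.best_position, m)
    return SegmentedImage(labels=apply_thresholds(image, thr), thresholds=thr,
                          fitness=segmentation_fitness(hist, thr, q))
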