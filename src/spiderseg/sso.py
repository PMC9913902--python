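"""Social spider optimization over bounded continuous/integer domains.

Candidate solutions ("spiders") sit on a web; each emits a vibration whose
intensity grows with its fitness and decays exponentially with distance.
Every spider follows the strongest vibration it has ever perceived through
a dimension-masked random walk. The optimizer maximizes the objective and
is fully deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class SSOConfig:
    bounds: Sequence[tuple[float, float]] = ((0.0, 1.0),)
    population_size: int = 25
    max_iterations: int = 100
    attenuation_rate: float = 1.0  # r_a
    mask_change_prob: float = 0.7  # p_c
    mask_one_prob: float = 0.1  # p_m
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValidationError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if self.attenuation_rate <= 0:
            raise ValidationError("attenuation_rate must be > 0")
        for p, name in ((self.mask_change_prob, "mask_change_prob"),
                        (self.mask_one_prob, "mask_one_prob")):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if len(self.bounds) < 1:
            raise ValidationError("bounds must have at least one dimension")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValidationError(f"each bound must satisfy low < high, got ({lo}, {hi})")


@dataclass
class Spider:
    position: np.ndarray
    fitness: float
    target_position: np.ndarray
    target_intensity: float
    dimension_mask: np.ndarray
    inactive_steps: int = 0


@dataclass(frozen=True)
class SSOResult:
    best_position: np.ndarray
    best_fitness: float
    fitness_trace: np.ndarray  # best-so-far per iteration, non-decreasing


def attenuate(intensity: float, distance: float, sigma_bar: float, r_a: float) -> float:
    """Distance-attenuated vibration intensity: ``I * exp(-d / (sigma_bar * r_a))``."""
    if intensity < 0 or distance < 0:
        raise ValidationError("intensity and distance must be >= 0")
    if sigma_bar <= 0 or r_a <= 0:
        raise ValidationError("sigma_bar and r_a must be > 0")
    return float(intensity * np.exp(-distance / (sigma_bar * r_a)))


def _source_intensity(fitness: np.ndarray, best_seen: float) -> np.ndarray:
    # Intensity increases with (maximized) fitness: anchor slightly above
    # the best fitness seen so far so arguments stay positive.
    anchor = best_seen + 1e-9 * (1.0 + abs(best_seen))
    return np.log1p(1.0 / (anchor - fitness))


def optimize(objective: Callable[[np.ndarray], float], config: SSOConfig) -> SSOResult:
    """Maximize ``objective`` over the box in ``config.bounds``.

    Raises :class:`ValidationError` when the objective returns a non-finite
    value, naming the offending position.
    """
    rng = np.random.default_rng(config.seed)
    lows = np.array([b[0] for b in config.bounds], dtype=np.float64)
    highs = np.array([b[1] for b in config.bounds], dtype=np.float64)
    n, d = config.population_size, len(config.bounds)

    pos = rng.uniform(lows, highs, size=(n, d))
    prev_pos = pos.copy()
    target_pos = pos.copy()
    target_int = np.zeros(n)  # initial vibration intensity is zero
    masks = np.zeros((n, d), dtype=bool)
    inactive = np.zeros(n, dtype=int)

    best_pos = pos[0].copy()
    best_fit = -np.inf
    trace = np.empty(config.max_iterations)

    def evaluate(x: np.ndarray) -> float:
        f = float(objective(x))
        if not np.isfinite(f):
            raise ValidationError(f"objective returned non-finite value at {x!r}")
        return f

    for it in range(config.max_iterations):
        fit = np.array([evaluate(p) for p in pos])
        k = int(np.argmax(fit))
        if fit[k] > best_fit:
            best_fit = float(fit[k])
            best_pos = pos[k].copy()
        trace[it] = best_fit

        # Vibration propagation with distance attenuation.
        intensity = _source_intensity(fit, best_fit)
        sigma_bar = max(float(pos.std(axis=0).mean()), 1e-12)
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        received = intensity[None, :] * np.exp(-dist / (sigma_bar * config.attenuation_rate))

        strongest = np.argmax(received, axis=1)
        strongest_int = received[np.arange(n), strongest]
        follow = strongest_int > target_int
        target_pos[follow] = pos[strongest[follow]]
        target_int[follow] = strongest_int[follow]
        inactive[follow] = 0
        inactive[~follow] += 1

        # Masked random walk toward the followed vibration source.
        resample = rng.random(n) < config.mask_change_prob
        if resample.any():
            masks[resample] = rng.random((int(resample.sum()), d)) < config.mask_one_prob
        partners = rng.integers(0, n, size=(n, d))
        following = np.where(masks, pos[partners, np.arange(d)[None, :]], target_pos)
        r_momentum = rng.random((n, 1))
        r_step = rng.random((n, d))
        new_pos = pos + (pos - prev_pos) * r_momentum + (following - pos) * r_step
        prev_pos = pos
        pos = np.clip(new_pos, lows, highs)

    return SSOResult(best_position=best_pos, best_fitness=best_fit, fitness_trace=trace)


def config_from_dict(d: dict, bounds=None) -> SSOConfig:
    """Build an SSOConfig from a config mapping, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(SSOConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValidationError(f"unknown sso config keys: {sorted(unknown)}")
    d = dict(d)
    if bounds is not None:
        d["bounds"] = bounds
    return SSOConfig(**d)
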