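"""SVD feature extraction with an energy-based rank rule.

The corpus of flattened segmented images forms a P x S matrix (samples as
rows). A thin SVD is fit on training samples only; the selected rank N is
the smallest k whose cumulative squared singular values reach the energy
fraction (default 99%) of the total. Features of any image are its
projection onto the retained right singular vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, ValidationError


@dataclass(frozen=True)
class FeatureModel:
    """Truncated right singular basis plus the full singular spectrum."""

    basis: np.ndarray  # S x N, orthonormal columns
    singular_values: np.ndarray  # full spectrum, non-increasing
    rank: int
    energy_fraction: float


def select_rank(singular_values, energy_fraction: float = 0.99) -> int:
    """Smallest k with ``sum_{i<=k} s_i^2 >= energy_fraction * sum s_i^2``."""
    s = np.asarray(singular_values, dtype=np.float64)
    if not 0 < energy_fraction <= 1:
        raise ValidationError("energy_fraction must be in (0, 1]")
    energies = s**2
    total = energies.sum()
    if total == 0:
        raise DataError("all singular values are zero")
    cum = np.cumsum(energies) / total
    return int(np.searchsorted(cum, energy_fraction - 1e-12) + 1)


def build_feature_model(data, energy_fraction: float = 0.99) -> FeatureModel:
    """Fit the SVD model on a P x S data matrix (samples as rows)."""
    X = np.asarray(data, dtype=np.float64)
    if X.ndim != 2:
        raise ValidationError(f"data must be 2-D (samples x pixels), got {X.shape}")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 samples to fit the feature model")
    if np.isnan(X).any():
        raise ValidationError("data contains missing values")
    if not X.any():
        raise DataError("data matrix is identically zero")
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    n = select_rank(s, energy_fraction)
    return FeatureModel(basis=vt[:n].T.copy(), singular_values=s,
                        rank=n, energy_fraction=energy_fraction)


def project(model: FeatureModel, flattened_image) -> np.ndarray:
    """Map a flattened image (or a stack of them) to its N-dim features."""
    x = np.asarray(flattened_image, dtype=np.float64)
    if x.shape[-1] != model.basis.shape[0]:
        raise DataError(
            f"vector length {x.shape[-1]} does not match model input size "
            f"{model.basis.shape[0]}")
    return x @ model.basis


def rank_features(model: FeatureModel) -> np.ndarray:
    """Feature indices in importance order (singular-value order, stable)."""
    return np.arange(model.rank)
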