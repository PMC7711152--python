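"""Alpha-diversity estimators for single-sample count vectors."""

from __future__ import annotations

import numpy as np

from .otu import ValidationError


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("expected a single sample's 1-D count vector")
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    if arr.sum() == 0:
        raise ValidationError("all-zero count vector has undefined diversity")
    return arr


def shannon_index(counts) -> float:
    """Shannon diversity H = −Σ pᵢ ln pᵢ, in natural-log units (nats)."""
    arr = _as_counts(counts)
    p = arr[arr > 0] / arr.sum()
    return float(-(p * np.log(p)).sum())


def chao1(counts) -> float:
    """Chao1 richness estimate from singleton and doubleton counts.

    Uses S_obs + F1²/(2·F2) when doubletons are present, and the
    bias-corrected form S_obs + F1(F1−1)/2 when F2 = 0.  Always at least the
    observed richness.
    """
    arr = _as_counts(counts)
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0
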