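"""Bead-colocalization statistic for two labeled particle populations.

A reference particle counts as interacting when any opposite-channel
centroid lies strictly closer than the threshold (default 7.5 um, roughly
twice the particle radius).  The per-channel percentage is interacting
particles over total particles; across fields of view both the pooled
percentage (from summed counts) and the mean of per-field percentages are
reported, since either convention appears in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError


@dataclass(frozen=True)
class ParticleSet:
    """Centroids (um) of the segmented particles of one channel."""

    label: str
    centroids: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValidationError("particle centroids must be finite")
        object.__setattr__(self, "centroids", pts)

    def __len__(self) -> int:
        return self.centroids.shape[0]


@dataclass(frozen=True)
class ColocResult:
    n_ref: int
    n_other: int
    n_interacting_ref: int
    percent_ref: float
    threshold: float

    def __post_init__(self):
        if not 0 <= self.percent_ref <= 100:
            raise ValidationError("percent_ref must lie in [0, 100]")
        if self.n_interacting_ref > self.n_ref:
            raise ValidationError("interacting count cannot exceed total")


def colocalization(
    ref: ParticleSet, other: ParticleSet, threshold: float = 7.5
) -> ColocResult:
    """Fraction of reference particles with an opposite-channel neighbour
    strictly closer than ``threshold`` um."""
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    n_ref = len(ref)
    if n_ref == 0 or len(other) == 0:
        return ColocResult(n_ref, len(other), 0, 0.0, threshold)
    dists, _ = cKDTree(other.centroids).query(ref.centroids)
    n_hit = int(np.sum(dists < threshold))
    percent = 100.0 * n_hit / n_ref
    return ColocResult(n_ref, len(other), n_hit, percent, threshold)


def batch_colocalization(
    fields: list[tuple[ParticleSet, ParticleSet]], threshold: float = 7.5
) -> dict:
    """Per-field results plus pooled and mean-of-fields percentages.

    The pooled percentage divides summed interacting counts by summed
    totals; the mean percentage averages per-field percentages.
    """
    if not fields:
        raise ValidationError("field list must be nonempty")
    per_field = [colocalization(r, o, threshold) for r, o in fields]
    total_ref = sum(r.n_ref for r in per_field)
    total_hit = sum(r.n_interacting_ref for r in per_field)
    pooled = 100.0 * total_hit / total_ref if total_ref else 0.0
    mean = float(np.mean([r.percent_ref for r in per_field]))
    return {
        "per_field": per_field,
        "pooled_percent": pooled,
        "mean_percent": mean,
        "n_fields": len(per_field),
        "total_ref": total_ref,
        "total_interacting_ref": total_hit,
    }
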