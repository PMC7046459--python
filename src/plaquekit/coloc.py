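"""Thresholded Mander's colocalization coefficients on confocal z-stacks.

M1 is the fraction of channel A's total intensity residing in voxels where
channel B exceeds its threshold (restricted to voxels where A itself exceeds
its own threshold); M2 is the converse.  Computed over every voxel of the
full stack — no projection — with fixed per-channel thresholds applied
consistently across samples.  "Above threshold" is strict (>), so an
all-zero channel cleanly yields a missing value rather than 0/0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .grids import ZStack

logger = logging.getLogger(__name__)

__all__ = ["ColocResult", "manders"]


@dataclass(frozen=True)
class ColocResult:
    """Mander's coefficients with the thresholds that produced them."""

    m1: float | None
    m2: float | None
    threshold_a: float
    threshold_b: float
    n_voxels: int


def manders(stack_a: ZStack, stack_b: ZStack, thr_a: float, thr_b: float) -> ColocResult:
    """Thresholded Mander's M1/M2 over two aligned z-stacks.

    M1 = Σ A over voxels with A > thr_a and B > thr_b, divided by
    Σ A over voxels with A > thr_a; M2 symmetric with the roles swapped.
    A denominator of zero (no voxel above threshold) gives a missing
    coefficient, logged.
    """
    if stack_a.data.shape != stack_b.data.shape:
        raise ValueError(
            f"stacks must be aligned: {stack_a.data.shape} vs {stack_b.data.shape}"
        )
    if thr_a < 0 or thr_b < 0:
        raise ValueError("thresholds must be >= 0")
    a = np.asarray(stack_a.data, dtype=np.float64)
    b = np.asarray(stack_b.data, dtype=np.float64)
    above_a = a > thr_a
    above_b = b > thr_b
    co = above_a & above_b

    def _coeff(ch: np.ndarray, own: np.ndarray, name: str) -> float | None:
        # fsum: correctly rounded totals, independent of voxel order
        denom = math.fsum(ch[own])
        if denom == 0:
            logger.warning("no voxel above threshold in channel %s; %s undefined", name, name)
            return None
        return math.fsum(ch[co]) / denom

    return ColocResult(
        m1=_coeff(a, above_a, "M1"),
        m2=_coeff(b, above_b, "M2"),
        threshold_a=float(thr_a),
        threshold_b=float(thr_b),
        n_voxels=int(a.size),
    )
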