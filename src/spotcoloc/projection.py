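"""Collapse z-stack channels to 2D planes.

Two projections matter downstream.  The *stacked* projection is the plain
pixelwise sum over focal planes, kept in a widened integer range so nothing
clips.  The *saturated* projection is the same sum limited to the 8-bit
maximum: summation amplifies weakly stained regions until they saturate,
which is what makes it the preferred substrate for segmentation.  Spot
detection instead uses the stacked projection rescaled by the number of
planes, so percentile semantics do not depend on stack depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import MAX_INTENSITY, ImageStack


@dataclass(frozen=True)
class Projection2D:
    """A single-channel 2D plane produced by a z-projection.

    ``dynamic_range`` is the maximum representable value for the method that
    produced the plane (``255 * n_z`` for stacked sums, 255 otherwise).
    """

    plane: np.ndarray
    method: str
    role: str
    dynamic_range: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.plane.shape

    def with_plane(self, plane: np.ndarray) -> "Projection2D":
        return Projection2D(plane=plane, method=self.method, role=self.role,
                            dynamic_range=self.dynamic_range)


def project_stacked(stack: ImageStack, role: str) -> Projection2D:
    """Additive projection: plane[r,c] = sum over z, without clipping."""
    sub = stack.channel(role).astype(np.int64)
    plane = sub.sum(axis=0)
    return Projection2D(plane=plane, method="stacked_sum", role=role,
                        dynamic_range=float(MAX_INTENSITY * stack.n_z))


def project_saturated(stack: ImageStack, role: str) -> Projection2D:
    """Saturating 8-bit projection: the stacked sum clipped at 255."""
    summed = project_stacked(stack, role).plane
    plane = np.clip(summed, 0, MAX_INTENSITY).astype(np.int64)
    return Projection2D(plane=plane, method="saturated", role=role,
                        dynamic_range=float(MAX_INTENSITY))


def project_max(stack: ImageStack, role: str) -> Projection2D:
    """Maximum-intensity projection (alternative segmentation substrate)."""
    plane = stack.channel(role).astype(np.int64).max(axis=0)
    return Projection2D(plane=plane, method="max", role=role,
                        dynamic_range=float(MAX_INTENSITY))


def project_normalized_stacked(stack: ImageStack, role: str) -> Projection2D:
    """Stacked sum divided by n_z: float plane in [0, 255].

    This is the detection substrate; dividing by the plane count keeps
    percentile thresholds comparable across stacks of different depth.
    """
    summed = project_stacked(stack, role).plane
    plane = summed.astype(np.float64) / stack.n_z
    return Projection2D(plane=plane, method="stacked_normalized", role=role,
                        dynamic_range=float(MAX_INTENSITY))
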