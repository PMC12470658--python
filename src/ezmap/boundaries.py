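"""Segmented retinal boundary surfaces over the en-face grid.

Four outer-boundary surfaces are carried per cube, each as a per-A-scan
depth in micrometres from the frame top: the internal limiting membrane
(ILM), the outer boundary of the outer plexiform layer (OPL), the outer
boundary of the EZ band, and the inner boundary of the RPE.  At every valid
A-scan the boundaries must be non-crossing: ILM <= OPL <= EZ <= RPE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import GeometryError, ValidationError

BOUNDARY_NAMES = ("ilm", "opl", "ez", "rpe")


@dataclass
class BoundarySet:
    """Per-A-scan depths (um from frame top) of the four boundaries.

    Attributes
    ----------
    ilm_um, opl_um, ez_um, rpe_um
        (n_slow, n_fast) float arrays of boundary depths.
    valid
        Same-shape boolean mask; invalid A-scans carry no measurement.
    extras
        Optional pass-through columns preserved from a boundary CSV.
    """

    ilm_um: np.ndarray
    opl_um: np.ndarray
    ez_um: np.ndarray
    rpe_um: np.ndarray
    valid: np.ndarray
    extras: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in
                  (self.ilm_um, self.opl_um, self.ez_um, self.rpe_um)]
        self.ilm_um, self.opl_um, self.ez_um, self.rpe_um = arrays
        self.valid = np.asarray(self.valid, dtype=bool)
        shape = self.ilm_um.shape
        if len(shape) != 2:
            raise GeometryError("boundary surfaces must be 2-D grids")
        for a in arrays[1:] + [self.valid]:
            if a.shape != shape:
                raise GeometryError("boundary surfaces must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ilm_um.shape

    def depth(self, name: str) -> np.ndarray:
        if name not in BOUNDARY_NAMES:
            raise ValidationError(f"unknown boundary {name!r}")
        return getattr(self, f"{name}_um")

    def validate(self) -> None:
        """Raise ValidationError if any valid A-scan violates the invariants."""
        v = self.valid
        if not v.any():
            return
        stack = np.stack([self.ilm_um, self.opl_um, self.ez_um, self.rpe_um])
        vals = stack[:, v]
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite boundary depth at a valid A-scan")
        if (vals < 0).any():
            raise ValidationError("negative boundary depth at a valid A-scan")
        if (np.diff(vals, axis=0) < 0).any():
            raise ValidationError(
                "boundary crossing at a valid A-scan (require ILM <= OPL <= EZ <= RPE)"
            )

    def sanitized(self, crossing_tolerance_um: float = 2.0) -> "BoundarySet":
        """Return a copy with small crossings clamped and large ones masked.

        Crossings of at most ``crossing_tolerance_um`` (boundaries touching
        after correction) are resolved by clamping the deeper boundary, so
        the EZ-RPE gap becomes 0 rather than negative; A-scans crossing by
        more than the tolerance, or carrying non-finite depths, are marked
        invalid.
        """
        ilm, opl, ez, rpe = (a.copy() for a in
                             (self.ilm_um, self.opl_um, self.ez_um, self.rpe_um))
        valid = self.valid.copy()
        finite = np.isfinite(ilm) & np.isfinite(opl) & np.isfinite(ez) & np.isfinite(rpe)
        valid &= finite & (ilm >= 0)
        with np.errstate(invalid="ignore"):
            worst = np.maximum.reduce([ilm - opl, opl - ez, ez - rpe])
            valid &= ~(worst > crossing_tolerance_um)
        # clamp the tolerated small crossings into monotone order
        opl = np.maximum(opl, ilm)
        ez = np.maximum(ez, opl)
        rpe = np.maximum(rpe, ez)
        return BoundarySet(ilm, opl, ez, rpe, valid, extras=self.extras)
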