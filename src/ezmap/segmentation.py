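"""Simplified automated boundary segmentation of synthetic intensity cubes.

Each A-scan of a B-scan frame is correlated with a Gaussian band template
(axial Gaussian smoothing), intensity peaks are detected, and up to four
peaks are assigned to the ILM / OPL / EZ / RPE boundaries by depth order.
When only three bands are resolvable the deepest peak is treated as a
merged EZ+RPE complex (thickness 0): in attenuated retina the two bands
collapse onto each other, and dropping such A-scans would bias the
attenuation denominator.  A running-median continuity constraint rejects
A-scans whose boundaries jump away from their neighbors; cube-level
segmentation adds median smoothing across frames.

A manual-correction hook (:func:`apply_corrections`) lets point edits be
applied on top of the automated result, emulating analyst review; edits
that would introduce a boundary crossing beyond tolerance invalidate the
A-scan with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter
from scipy.signal import find_peaks

from .boundaries import BOUNDARY_NAMES, BoundarySet
from .exceptions import GeometryError, ValidationError
from .geometry import CubeGeometry
from .simulate import BAND_SIGMA_UM

#: Minimum peak prominence (intensity units) for a band detection.
PEAK_PROMINENCE = 0.12
#: Template width relative to the rendered band sigma.  Narrower than the
#: band itself: full-width smoothing pulls the nearly-merged EZ and RPE
#: peaks together and biases thin EZ-RPE gaps low.
TEMPLATE_SIGMA_FACTOR = 0.7
#: Minimum axial peak separation in pixels.
MIN_PEAK_DISTANCE_PX = 4
#: Running-median window (A-scans) for the continuity constraint.
CONTINUITY_WINDOW = 7
#: Maximum tolerated deviation from the running median, axial pixels.
CONTINUITY_TOL_PX = 6.0


def _refine_peak(profile: np.ndarray, idx: int) -> float:
    """Sub-pixel peak position by parabolic interpolation."""
    if idx <= 0 or idx >= len(profile) - 1:
        return float(idx)
    y0, y1, y2 = profile[idx - 1], profile[idx], profile[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(idx)
    return float(idx + 0.5 * (y0 - y2) / denom)


def segment_bscan(
    frame: np.ndarray,
    geometry: CubeGeometry,
    prominence: float = PEAK_PROMINENCE,
) -> dict[str, np.ndarray]:
    """Segment one B-scan frame into per-A-scan boundary depths.

    Parameters
    ----------
    frame
        (n_axial, n_fast) intensity image, frame top at row 0.
    geometry
        Supplies n_fast and the axial scale.

    Returns
    -------
    dict with keys "ilm", "opl", "ez", "rpe" (depths in um, NaN where
    undetected) and "valid" (boolean per A-scan).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[1] != geometry.n_fast:
        raise GeometryError(
            f"frame shape {frame.shape} does not match n_fast={geometry.n_fast}"
        )
    sigma_px = TEMPLATE_SIGMA_FACTOR * BAND_SIGMA_UM / geometry.axial_um_per_px
    smoothed = gaussian_filter1d(frame, sigma=sigma_px, axis=0)

    n_fast = geometry.n_fast
    depths_px = np.full((4, n_fast), np.nan)
    for i in range(n_fast):
        col = smoothed[:, i]
        peaks, props = find_peaks(col, prominence=prominence,
                                  distance=MIN_PEAK_DISTANCE_PX)
        if len(peaks) < 3:
            continue
        if len(peaks) > 4:
            keep = np.sort(np.argsort(props["prominences"])[-4:])
            peaks = peaks[keep]
        refined = [_refine_peak(col, p) for p in peaks]
        if len(peaks) == 4:
            depths_px[:, i] = refined
        else:  # 3 bands: merged EZ + RPE complex at the deepest peak
            depths_px[0, i], depths_px[1, i] = refined[0], refined[1]
            depths_px[2, i] = depths_px[3, i] = refined[2]

    valid = ~np.isnan(depths_px).any(axis=0)
    # continuity: reject A-scans whose reference surfaces (ILM, OPL, RPE)
    # stray from the running median along the B-scan.  The EZ is exempt:
    # at an attenuation edge it legitimately jumps onto the RPE, and
    # rejecting those A-scans would bias the attenuation denominator.
    if valid.sum() >= 3:
        for b in (0, 1, 3):
            med = median_filter(
                np.where(valid, depths_px[b], np.nanmedian(depths_px[b])),
                size=CONTINUITY_WINDOW, mode="nearest")
            valid &= ~(np.abs(depths_px[b] - med) > CONTINUITY_TOL_PX)
    um = geometry.axial_um_per_px
    out = {name: (depths_px[k] + 0.5) * um for k, name in enumerate(BOUNDARY_NAMES)}
    out["valid"] = valid
    return out


def segment_cube(cube: np.ndarray, geometry: CubeGeometry) -> BoundarySet:
    """Segment a full intensity cube into a BoundarySet.

    Frame-wise segmentation followed by a 3-frame median filter along the
    slow axis (suppressing frame-to-frame jitter), then re-validation so
    the output satisfies the non-crossing invariant.
    """
    cube = np.asarray(cube)
    if cube.ndim != 3 or cube.shape[0] != geometry.n_slow \
            or cube.shape[2] != geometry.n_fast:
        raise GeometryError(
            f"cube shape {cube.shape} does not match geometry "
            f"(n_slow={geometry.n_slow}, n_axial, n_fast={geometry.n_fast})"
        )
    per_frame = [segment_bscan(cube[s], geometry) for s in range(geometry.n_slow)]
    grids = {name: np.stack([f[name] for f in per_frame])
             for name in BOUNDARY_NAMES}
    valid = np.stack([f["valid"] for f in per_frame])
    for name in BOUNDARY_NAMES:
        g = grids[name]
        filled = np.where(valid, g, np.nanmedian(g[valid]) if valid.any() else 0.0)
        grids[name] = median_filter(filled, size=(3, 1), mode="nearest")
    bs = BoundarySet(grids["ilm"], grids["opl"], grids["ez"], grids["rpe"], valid)
    return bs.sanitized()


@dataclass(frozen=True)
class CorrectionEdit:
    """One manual segmentation correction.

    Sets a boundary to ``new_depth_um`` over an inclusive fast-index range
    of one B-scan, or marks the A-scans invalid when ``new_depth_um`` is
    None.
    """

    slow_index: int
    fast_start: int
    fast_stop: int  # inclusive
    boundary: str = "ez"
    new_depth_um: float | None = None

    def __post_init__(self) -> None:
        if self.boundary not in BOUNDARY_NAMES:
            raise ValidationError(f"unknown boundary {self.boundary!r}")
        if self.fast_stop < self.fast_start:
            raise ValidationError("fast_stop must be >= fast_start")


def apply_corrections(
    boundaries: BoundarySet, edits: list[CorrectionEdit]
) -> BoundarySet:
    """Apply manual correction edits in order and re-validate.

    Edited A-scans whose boundaries end up crossing by more than the
    sanitation tolerance are marked invalid, with a warning.
    """
    out = BoundarySet(
        boundaries.ilm_um.copy(), boundaries.opl_um.copy(),
        boundaries.ez_um.copy(), boundaries.rpe_um.copy(),
        boundaries.valid.copy(), extras=boundaries.extras,
    )
    n_slow, n_fast = out.shape
    for e in edits:
        if not (0 <= e.slow_index < n_slow and 0 <= e.fast_start < n_fast
                and 0 <= e.fast_stop < n_fast):
            raise ValidationError(f"edit indices out of range: {e}")
        sl = (e.slow_index, slice(e.fast_start, e.fast_stop + 1))
        if e.new_depth_um is None:
            out.valid[sl] = False
        else:
            out.depth(e.boundary)[sl] = e.new_depth_um
            out.valid[sl] = True
    result = out.sanitized()
    newly_invalid = out.valid & ~result.valid
    if newly_invalid.any():
        warnings.warn(
            f"{int(newly_invalid.sum())} A-scan(s) invalidated by "
            "crossing-inducing corrections", stacklevel=2)
    return result
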