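"""En-face map rendering: color-mapped thickness with zone overlays."""

from __future__ import annotations

import matplotlib as mpl
import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure
from matplotlib.patches import Circle

from .geometry import ZoneSpec
from .mapping import EZRPEMap

DEFAULT_ZONES = (ZoneSpec.central_subfield(), ZoneSpec.parafoveal())


def enface_rgba(
    ezmap: EZRPEMap, vmax_um: float = 60.0, cmap: str = "turbo"
) -> np.ndarray:
    """Color-map a thickness grid to an (n_slow, n_fast, 4) RGBA array.

    Invalid points map to black; thickness is scaled over [0, vmax_um].
    """
    colormap = mpl.colormaps[cmap].copy()
    colormap.set_bad("black")
    norm = mpl.colors.Normalize(vmin=0.0, vmax=vmax_um)
    grid = np.ma.masked_array(ezmap.thickness_um, mask=~ezmap.valid)
    return colormap(norm(grid))


def render_enface(
    ezmap: EZRPEMap,
    path,
    zones: tuple[ZoneSpec, ...] = DEFAULT_ZONES,
    vmax_um: float = 60.0,
    bscan_slow_index: int | None = None,
    cmap: str = "turbo",
    colorbar: bool = True,
) -> None:
    """Render an en-face thickness color map to a PNG.

    Foveal zone circles are overlaid at their physical radii; an optional
    horizontal locator line marks the B-scan at ``bscan_slow_index``.
    """
    geom = ezmap.geometry
    rgba = enface_rgba(ezmap, vmax_um=vmax_um, cmap=cmap)
    fig = Figure(figsize=(5, 5), dpi=120)
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    hx = geom.extent_fast_mm / 2
    hy = geom.extent_slow_mm / 2
    ax.imshow(rgba, origin="lower", extent=(-hx, hx, -hy, hy), aspect="equal")
    fx, fy = geom.fovea_xy_mm
    for zone in zones:
        ax.add_patch(Circle((fx, fy), zone.radius_mm, fill=False,
                            color="white", linewidth=1.0))
    if bscan_slow_index is not None:
        y = geom.y_centers_mm()[bscan_slow_index]
        ax.axhline(y, color="red", linewidth=1.0)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    if colorbar:
        mappable = mpl.cm.ScalarMappable(
            norm=mpl.colors.Normalize(0.0, vmax_um), cmap=cmap)
        fig.colorbar(mappable, ax=ax, label="EZ-RPE thickness (um)", shrink=0.8)
    fig.savefig(str(path), bbox_inches="tight")
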