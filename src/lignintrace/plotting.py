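"""Display helpers: 1D overlays and 2D contour plots.

Contour levels follow the common presentation convention for these spectra:
a geometric sequence starting at a chosen fraction of the maximum intensity
with a small multiplication factor (default 1.07) between levels.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .pipeline import contour_levels
from .shifts import SpectralRegion
from .synth import Spectrum1D, Spectrum2D


def plot_overlay_1d(
    spectra: Sequence[Spectrum1D],
    labels: Optional[Sequence[str]] = None,
    region: Optional[SpectralRegion] = None,
    ax=None,
):
    """Overlay 1D spectra (ppm axis reversed, NMR display convention)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = labels or [s.meta.get("label", f"spectrum {i}") for i, s in enumerate(spectra)]
    for spec, label in zip(spectra, labels):
        ax.plot(spec.ppm, spec.intensity, label=label, lw=0.8)
    if region is not None:
        ax.set_xlim(region.hi_ppm, region.lo_ppm)
    else:
        ax.invert_xaxis()
    ax.set_xlabel("$^{13}$C chemical shift (ppm)")
    ax.set_ylabel("intensity (a.u.)")
    ax.legend(frameon=False)
    return ax


def plot_contour_2d(
    spec: Spectrum2D,
    start_frac: float = 0.02,
    factor: float = 1.07,
    n_levels: int = 24,
    ref_region: Optional[SpectralRegion] = None,
    ax=None,
):
    """Contour plot with geometric levels relative to the maximum intensity
    (optionally the maximum within ``ref_region`` on both axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    z = spec.intensity
    if ref_region is not None:
        m1 = (spec.f1_ppm >= ref_region.lo_ppm) & (spec.f1_ppm <= ref_region.hi_ppm)
        m2 = (spec.f2_ppm >= ref_region.lo_ppm) & (spec.f2_ppm <= ref_region.hi_ppm)
        ref = z[m1][:, m2].max()
    else:
        ref = z.max()
    levels = contour_levels(start_frac, factor, n_levels) * ref
    levels = levels[levels < z.max()]
    ax.contour(spec.f2_ppm, spec.f1_ppm, z, levels=levels, linewidths=0.5)
    ax.invert_xaxis()
    ax.invert_yaxis()
    ax.set_xlabel("$^{13}$C chemical shift f2 (ppm)")
    ax.set_ylabel("$^{13}$C chemical shift f1 (ppm)")
    return ax
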