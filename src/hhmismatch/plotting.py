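"""Quick-look figures for phantoms and their segmentations."""

from __future__ import annotations

import numpy as np

from .study import ImagingStudy, LesionMasks


def plot_study_slices(study: ImagingStudy, masks: LesionMasks | None = None,
                      axial_axis: int = -1, slice_index: int | None = None,
                      ax=None):
    """Show NCCT / CBV / CBF / Tmax for one axial slice, with mask contours.

    Returns the matplotlib figure.  Matplotlib is imported lazily so the
    analysis stack stays importable on headless systems without it.
    """
    import matplotlib.pyplot as plt

    axial = axial_axis % study.ncct.ndim
    if slice_index is None:
        ref = masks.core if masks is not None and masks.core.any() else study.brain_mask
        slice_index = int(np.argmax(ref.sum(axis=tuple(
            i for i in range(ref.ndim) if i != axial))))

    def take(grid):
        return np.take(grid, slice_index, axis=axial).T

    if ax is None:
        fig, axes = plt.subplots(1, 4, figsize=(14, 4))
    else:
        fig, axes = ax.figure, ax
    panels = [("NCCT (HU)", study.ncct, "gray"),
              ("CBV (mL/100 mL)", study.cbv, "viridis"),
              ("CBF (mL/100 mL/min)", study.cbf, "viridis"),
              ("Tmax (s)", study.tmax, "inferno")]
    for a, (title, grid, cmap) in zip(np.ravel(axes), panels):
        im = a.imshow(take(grid), cmap=cmap, origin="lower")
        a.set_title(title)
        a.axis("off")
        fig.colorbar(im, ax=a, fraction=0.046)
        if masks is not None:
            for mask, color in ((masks.ischemic_area, "cyan"),
                                (masks.core, "red")):
                sl = take(mask).astype(float)
                if sl.any():
                    a.contour(sl, levels=[0.5], colors=color, linewidths=1.0)
    fig.suptitle(f"axial slice {slice_index}")
    fig.tight_layout()
    return fig
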