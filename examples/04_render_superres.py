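"""Render super-resolved images before and after axial filtering.

Simulates a labelled structure at the focal plane perforated by an
unlabelled elliptical void (think vacuoles in a stained cell), plus an
out-of-focus haze, and measures how filtering raises the rendered
structure-to-void contrast.
"""

import numpy as np

from vlsmlm import (
    RenderSettings,
    VlsCalibration,
    apply_thresholds,
    localize_stack,
    render_superres,
    shell_layout,
    simulate_smlm_movie,
)

field = (6400.0, 6400.0)
void = (3200.0, 3200.0, 1200.0, 900.0)  # cx, cy, rx, ry in nm
emitters = shell_layout(field, n_structure=250, voids=[void],
                        n_background=150, seed=3)
movie = simulate_smlm_movie(emitters, 300, seed=7, shape=(64, 64))
locs = localize_stack(movie, min_snr=4.0)
locs = locs[locs.fit_ok]

cal = VlsCalibration("structural", 0.0, 300.0, 219.0, 1000.0, 0.93, 0.93)
kept, report = apply_thresholds(locs, cal)

settings = RenderSettings(output_pixel_size=50.0, mode="equal-amplitude",
                          bounds_nm=(0, field[0], 0, field[1]))

def void_contrast(table):
    img = render_superres(table, settings)
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    xc, yc = (xx + 0.5) * 50.0, (yy + 0.5) * 50.0
    inside = ((xc - void[0]) / void[2]) ** 2 + ((yc - void[1]) / void[3]) ** 2 <= 1
    return img[~inside].mean() / img[inside].mean()

print(f"{len(locs)} localizations; filter kept {report.n_kept}")
print(f"structure/void contrast before filtering: {void_contrast(locs):6.1f}")
print(f"structure/void contrast after filtering:  {void_contrast(kept):6.1f}")
print("\nOut-of-focus haze fills the void in the unfiltered rendering; "
      "rejecting wide/dim localizations empties it, sharpening the "
      "reconstructed structure.")
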