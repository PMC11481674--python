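"""Unwrap the membrane contour of a two-channel cell and quantify
colocalization of cortical punctae.

Channel 2 carries punctae at the same contour positions as channel 1 with
0.1 um jitter (two proteins in the same cortical structures). The profile
correlation and the matched-peak fraction both read out that overlap; an
independent-channel simulation shows what "no colocalization" looks like
against a circular-permutation null.
"""

import numpy as np

import cortiquant as cq
from cortiquant.segment import mask_to_rois

for mode in ("colocalized", "independent"):
    cfg = cq.SimulationConfig(seed=4, n_cells=3, channel2_mode=mode,
                              colocalization_jitter=0.1,
                              membrane_fraction=0.7, puncta_enrichment=0.8)
    micro, mask, truth = cq.simulate_field(cfg)
    roi = mask_to_rois(mask)[0]

    prof = cq.extract_membrane_profile(micro, roi, n_samples=150)
    prof = cq.normalize_profile(prof)
    r, null, p = cq.circular_permutation_null(prof, "GFP", "mRFP",
                                              n_permutations=1000, seed=0)
    peaks1 = cq.detect_cortical_puncta(prof, "GFP")
    peaks2 = cq.detect_cortical_puncta(prof, "mRFP")
    frac, pairs = cq.puncta_overlap(peaks1, peaks2, prof.perimeter)

    print(f"{mode}: cell {roi.label}, perimeter {prof.perimeter:.1f} um")
    print(f"  profile correlation r = {r:.3f} "
          f"(permutation p = {p:.3f}, null 95% |r| = "
          f"{np.quantile(null, 0.95):.3f})")
    print(f"  {len(peaks1)} GFP punctae, {len(peaks2)} mRFP punctae, "
          f"overlap fraction = {frac:.2f}")

print("\ncolocalized punctae give r near 1 and overlap near 1; independent "
      "punctae give r within the null band and low overlap")
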