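"""Subspace baseline reconstructions and quantitative T1 estimation.

Reconstructs a 4x-undersampled phantom scan with the Tikhonov (CG) and
zero-filled subspace baselines, fits T1 per voxel inside the vial ROIs,
and reports per-vial percent errors against the known phantom values.
"""

import numpy as np

from mpnrage import (ImageSeries, build_dictionary, compute_temporal_basis,
                     normalize_kspace)
from mpnrage.baselines import (method2_cg_quadratic,
                               method4_zero_filled_subspace)
from mpnrage.fitting import fit_map
from mpnrage.phantom import (roi_mask_union, roi_stats,
                             standard_desk_acquisition)

acq = standard_desk_acquisition(noise_rel=0.005, seed=0)
ksp = acq["ksp"].subsample_blocks(32)
maps, seq, ph = acq["maps"], acq["seq"], acq["phantom"]
kn, _ = normalize_kspace(ksp, maps=maps)

dictionary = build_dictionary(seq)
basis = compute_temporal_basis(dictionary, rank=16)
print(f"temporal basis: rank {basis.rank} from {dictionary.n_atoms} Bloch atoms")

recons = {}
recons["method 2 (CG, quadratic)"], _ = method2_cg_quadratic(kn, maps, basis)
recons["method 4 (zero-filled)"], _ = method4_zero_filled_subspace(kn, maps, basis)

mask = roi_mask_union(ph)
print(f"fitting T1/B1/efficiency in {int(mask.sum())} ROI voxels per method")
for name, series in recons.items():
    pm = fit_map(ImageSeries(volumes=series.volumes), seq, mask=mask,
                 dictionary=dictionary)
    stats = roi_stats(pm.t1_ms, ph)
    errs = np.asarray(stats["percent_error"])
    print(f"\n{name}")
    for t1, err, sd in zip(stats["truth_t1_ms"], errs, stats["std_t1_ms"]):
        print(f"  vial T1 {t1:7.1f} ms: error {err:+6.2f}%  (ROI std {sd:6.1f} ms)")
    print(f"  mean |error| {np.mean(np.abs(errs)):.2f}%")
# percent error is 100*(ROI-mean fitted T1 - true T1)/true T1; the
# zero-filled route relies on the downstream regularized fitting, while
# the CG route trades some bias for lower streaking before the fit.
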