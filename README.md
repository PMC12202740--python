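# mpnrage

Self-supervised multicontrast reconstruction and quantitative T1 mapping
for inversion-recovery radial MRI.

An MPnRAGE-style acquisition plays an inversion pulse followed by a long
spoiled gradient-echo train, so a single scan samples hundreds of
inversion-time contrasts — but each contrast only sees a few radial
spokes, and shortening the scan (keeping fewer inversion blocks) makes
every contrast severely undersampled. This package is for researchers
who want to study how different reconstruction priors behave in that
regime, on fully synthetic data, end to end: from Bloch-level signal
simulation through k-space operators and reconstruction to voxelwise T1
estimation.

The core is a **deep factor model (DFM)**: the image at normalized
inversion time *tau* is the output of a small conditional CNN,

    eta(tau) = U_phi(gamma, v(tau)),      v(tau) = V_theta(tau),

where *gamma* is a cheap eight-bin zero-filled reconstruction of the
same scan fed as 16 real channels, and the MLP output v(tau) modulates
the CNN features channelwise. Both parameter sets are learned
*single-shot* from the scan's own k-space by minimizing

    sum_tau || A_tau( N_theta,phi(gamma, tau) ) - y_tau ||^2,

with A_tau the multicoil non-uniform Fourier operator restricted to the
views acquired at that inversion time. No training database is needed,
and weights learned on one scan transfer to another (run only the final
training stage). This generalizes linear subspace models eta = U V —
which are also implemented, with quadratic, wavelet-l1, deep-image-prior
and no regularization, as baselines sharing the same Bloch-dictionary
temporal basis V.

Everything runs on plain NumPy/SciPy (the NUFFT, the network and its
backpropagation included); no GPU or deep-learning framework is
required at the bundled desk scale (2D, 64x64, 48 contrasts).

## Worked example

```python
import numpy as np
from mpnrage import (TrainSchedule, bin_by_ti, gridding_recon,
                     normalize_kspace, psnr, ssl_train)
from mpnrage.phantom import standard_desk_acquisition

acq = standard_desk_acquisition(noise_rel=0.005, seed=0)   # 6-vial phantom
ksp = acq["ksp"].subsample_blocks(32)                      # 4x shorter scan
kn, scale = normalize_kspace(ksp, maps=acq["maps"])
result = ssl_train(kn, acq["maps"], TrainSchedule.desk(), seed=1)

truth = acq["truth"].volumes * scale
T = acq["seq"].n_contrasts
bins = bin_by_ti(T, 8)
gamma = gridding_recon(kn, bins, maps=acq["maps"]).volumes[bins.bin_of]
print(np.mean([psnr(np.abs(gamma[t]), np.abs(truth[t])) for t in range(T)]))
print(np.mean([psnr(np.abs(result.series.volumes[t]), np.abs(truth[t]))
               for t in range(T)]))
```

prints

```
26.63
27.48
```

— the mean PSNR (dB, over 48 contrasts against the known phantom) of
the binned zero-filled input and of the deep factor model trained from
it for two minutes on one CPU core: the network recovers ~0.9 dB of
contrast fidelity purely from data consistency. Feeding
`result.series` to `mpnrage.fitting.fit_map` then yields T1, B1,
inversion-efficiency and complex-scale maps; `mpnrage.phantom.roi_stats`
reports per-vial percent errors against the phantom's known T1 values
(300–2000 ms). The `examples/` scripts walk through signal simulation
and the temporal basis, acquisition and gridding, DFM training, and the
subspace baselines with T1 fitting; a thin CLI
(`mpnrage sim | recon | fit | eval`) wraps the same calls for shell use.

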