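"""Simulate inversion-recovery gradient-echo signals and build the
temporal subspace.

Builds the reference sequence (385 views per inversion block, 4/8 degree
two-segment flip schedule), simulates steady-state signals for a few
tissues, then constructs a Bloch dictionary and its SVD temporal basis.
"""

import numpy as np

from mpnrage import (SequenceParams, TissueParams, build_dictionary,
                     compute_temporal_basis, scan_duration, simulate_ir_spgr)

seq = SequenceParams()  # reference timing: TR 4.88 ms, 385 views, TD 503.5 ms
print(f"contrasts per block: {seq.n_contrasts}")
print(f"scan duration, 224 blocks: {scan_duration(seq, 224):.1f} s "
      f"(~{scan_duration(seq, 224) / 60:.0f} min)")

for t1 in (300.0, 800.0, 2000.0):
    sig = simulate_ir_spgr(seq, TissueParams(t1_ms=t1, eff=0.96)).real
    null = int(np.argmax(sig > 0))
    print(f"T1 = {t1:6.0f} ms: signal range [{sig.min():+.3f}, {sig.max():+.3f}], "
          f"null crossing at view {null} (TI ~ {null * seq.tr_ms:.0f} ms)")
# longer T1 recovers more slowly, so its signal crosses zero later: the
# null-crossing view is the fingerprint the T1 fit exploits.

dictionary = build_dictionary(seq)
basis = compute_temporal_basis(dictionary, rank=16)
resid = dictionary.atoms - basis.project(dictionary.atoms)
rel = np.linalg.norm(resid, axis=0) / np.linalg.norm(dictionary.atoms, axis=0)
print(f"\ndictionary: {dictionary.n_atoms} atoms over "
      f"T1 100-5000 ms x B1 0.8-1.2 x efficiency 0.7-1.0")
print(f"rank-16 basis: worst atom projection residual {rel.max():.2e}")
# a tiny residual means 16 temporal modes capture every physically
# plausible recovery curve, which is what subspace reconstruction relies on.
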