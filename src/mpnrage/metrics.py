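"""Image-quality metrics and evaluation reports.

NRMSE follows the convention of normalizing the root-mean-square error
by the mean intensity of the reference volume; PSNR uses the maximum
reference magnitude as the peak; SSIM is the standard structural
similarity with its default stabilization constants.  Metrics operate
on magnitude images per contrast by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["nrmse", "psnr", "ssim", "EvalReport", "evaluate_series",
           "PSNR_IDENTICAL_DB"]

PSNR_IDENTICAL_DB = 300.0  # sentinel for an exact match (infinite PSNR)


def _check_shapes(x, y):
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def nrmse(x: np.ndarray, y: np.ndarray) -> float:
    """Root-mean-square error of x against reference y over Mean(y)."""
    x, y = _check_shapes(x, y)
    mean_ref = float(np.mean(y))
    if mean_ref == 0:
        raise ValueError("reference volume has zero mean")
    rmse = float(np.sqrt(np.mean(np.abs(x - y) ** 2)))
    return rmse / mean_ref


def psnr(x: np.ndarray, y_ref: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; peak = max |reference|."""
    x, y_ref = _check_shapes(x, y_ref)
    mse = float(np.mean(np.abs(x - y_ref) ** 2))
    if mse == 0:
        return PSNR_IDENTICAL_DB
    peak = float(np.abs(y_ref).max())
    return 10.0 * np.log10(peak ** 2 / mse)


def ssim(x: np.ndarray, y_ref: np.ndarray) -> float:
    """Structural similarity of real magnitude images."""
    x, y_ref = _check_shapes(x, y_ref)
    x = np.abs(np.asarray(x, dtype=float))
    y_ref = np.abs(np.asarray(y_ref, dtype=float))
    win = min(7, min(x.shape) - (1 - min(x.shape) % 2))
    rng_ = float(y_ref.max() - y_ref.min()) or 1.0
    return float(structural_similarity(x, y_ref, data_range=rng_, win_size=win))


@dataclass
class EvalReport:
    """Per-contrast and summary image metrics plus T1-map accuracy."""

    psnr_per_contrast: np.ndarray
    mean_psnr: float
    mean_ssim: float
    t1_nrmse: float | None = None
    per_vial_percent_error: list[float] | None = None
    provenance: dict = field(default_factory=dict)

    def asdict(self) -> dict:
        return {
            "psnr_per_contrast": np.asarray(self.psnr_per_contrast).tolist(),
            "mean_psnr": self.mean_psnr,
            "mean_ssim": self.mean_ssim,
            "t1_nrmse": self.t1_nrmse,
            "per_vial_percent_error": self.per_vial_percent_error,
            "provenance": self.provenance,
        }


def evaluate_series(recon, reference, t1_map: np.ndarray | None = None,
                    t1_ref: np.ndarray | None = None,
                    roi=None, provenance: dict | None = None) -> EvalReport:
    """Magnitude PSNR/SSIM per contrast plus optional T1-map metrics.

    ``recon`` and ``reference`` are image series (or bare arrays with the
    contrast axis leading).
    """
    xr = np.abs(getattr(recon, "volumes", recon))
    yr = np.abs(getattr(reference, "volumes", reference))
    if xr.shape != yr.shape:
        raise ValueError("series shapes differ")
    ps = np.array([psnr(xr[t], yr[t]) for t in range(xr.shape[0])])
    ss = np.array([ssim(xr[t], yr[t]) for t in range(xr.shape[0])])
    t1_err = None
    if t1_map is not None and t1_ref is not None:
        sel = t1_ref > 0
        t1_err = nrmse(t1_map[sel], t1_ref[sel])
    report = EvalReport(psnr_per_contrast=ps, mean_psnr=float(ps.mean()),
                        mean_ssim=float(ss.mean()), t1_nrmse=t1_err,
                        per_vial_percent_error=roi["percent_error"] if roi else None,
                        provenance=provenance or {})
    if not np.all(np.isfinite(ps)):
        raise ValueError("non-finite PSNR in report")
    return report
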