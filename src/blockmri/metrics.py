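"""Reconstruction quality metrics and paired significance testing.

All metrics operate on magnitude images. PSNR uses the reference peak and
a 300 dB sentinel for zero error; SSIM averages the local index over all
7³ windows fully inside the volume (uniform window, K1 = 0.01,
K2 = 0.03, dynamic range = reference peak). The "relative difference" of
a reconstruction is its metric minus the gridded baseline's metric, both
against the same reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.stats import t as t_dist

from .types import as_array

__all__ = [
    "PSNR_SENTINEL_DB",
    "ReconMetrics",
    "psnr",
    "ssim",
    "relative_difference",
    "TTestResult",
    "paired_t_test",
]

PSNR_SENTINEL_DB = 300.0
_SSIM_WIN = 7
_SSIM_K1 = 0.01
_SSIM_K2 = 0.03


@dataclass
class ReconMetrics:
    psnr: float
    ssim: float
    psnr_rel: float
    ssim_rel: float

    def to_dict(self) -> dict:
        return {"psnr": self.psnr, "ssim": self.ssim,
                "psnr_rel": self.psnr_rel, "ssim_rel": self.ssim_rel}


def _magnitude_pair(recon, reference):
    r = np.abs(as_array(recon))
    ref = np.abs(as_array(reference))
    if r.shape != ref.shape:
        raise ValueError(f"shape mismatch {r.shape} vs {ref.shape}")
    return r, ref


def psnr(recon, reference) -> float:
    """20·log10(peak / rms error) on magnitude images; peak is the
    reference's max magnitude. Zero error returns the 300 dB sentinel."""
    r, ref = _magnitude_pair(recon, reference)
    mse = float(np.mean((r - ref) ** 2))
    if mse == 0.0:
        return PSNR_SENTINEL_DB
    peak = float(ref.max())
    return float(20.0 * np.log10(peak / np.sqrt(mse)))


def ssim(recon, reference) -> float:
    """Mean local SSIM over 7³ windows fully inside the volume."""
    r, ref = _magnitude_pair(recon, reference)
    if any(n < _SSIM_WIN for n in r.shape):
        raise ValueError(f"volume smaller than the {_SSIM_WIN}^3 SSIM window")
    peak = float(ref.max())
    if peak == 0.0:
        return 1.0 if np.array_equal(r, ref) else 0.0
    c1 = (_SSIM_K1 * peak) ** 2
    c2 = (_SSIM_K2 * peak) ** 2
    win = _SSIM_WIN
    mu_r = uniform_filter(r, win)
    mu_f = uniform_filter(ref, win)
    var_r = uniform_filter(r * r, win) - mu_r**2
    var_f = uniform_filter(ref * ref, win) - mu_f**2
    cov = uniform_filter(r * ref, win) - mu_r * mu_f
    s = ((2 * mu_r * mu_f + c1) * (2 * cov + c2)) / (
        (mu_r**2 + mu_f**2 + c1) * (var_r + var_f + c2)
    )
    h = win // 2
    interior = tuple(slice(h, n - h) for n in r.shape)
    return float(np.mean(s[interior]))


def relative_difference(recon, gridded, reference) -> ReconMetrics:
    """Metrics of ``recon`` and their differences from the gridded
    baseline, all against the same reference."""
    p = psnr(recon, reference)
    s = ssim(recon, reference)
    return ReconMetrics(
        psnr=p,
        ssim=s,
        psnr_rel=p - psnr(gridded, reference),
        ssim_rel=s - ssim(gridded, reference),
    )


@dataclass
class TTestResult:
    t: float
    p: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.t, self.p))


def paired_t_test(values_a, values_b) -> TTestResult:
    """Classical paired t-test on the elementwise differences.

    Zero-variance differences set the ``degenerate`` flag, reporting p = 1
    when the mean difference is 0 and p = 0 otherwise.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1D sequences")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return TTestResult(t=np.inf if mean != 0 else 0.0,
                           p=0.0 if mean != 0 else 1.0, degenerate=True)
    t_stat = mean / (sd / np.sqrt(n))
    p = 2.0 * float(t_dist.sf(abs(t_stat), df=n - 1))
    return TTestResult(t=float(t_stat), p=p)
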