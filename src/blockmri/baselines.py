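"""Iterative baseline reconstructions: CG-SENSE and L1-wavelet FISTA.

CG-SENSE (30 iterations by default) is the proxy-ground-truth
reconstruction; the L1-wavelet baseline minimizes
``0.5 ||Ex - y||^2 + lambda ||Wx||_1`` with an orthonormal periodic
Daubechies transform, FISTA acceleration, and function-value adaptive
restart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_model import EncodingOperator, max_eig_power_iteration
from .types import KSpaceData, as_array
from .wavelets import dwt3, idwt3

__all__ = ["CSConfig", "cg_sense", "soft_threshold", "l1_wavelet_cs"]


@dataclass
class CSConfig:
    reg_weight: float = 1e-4
    n_iters: int = 100
    wavelet: str = "d4"
    levels: int = 3

    def __post_init__(self):
        if self.reg_weight < 0:
            raise ValueError("reg_weight must be >= 0")
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")
        if self.wavelet != "d4":
            raise ValueError("only the 4-tap Daubechies transform is available")


def cg_sense(y: KSpaceData, op: EncodingOperator, n_iters: int = 30,
             x0=None, return_residuals: bool = False):
    """Conjugate gradient on the normal equations E^H E x = E^H y.

    The least-squares objective is monotonically non-increasing across
    iterations. Aborts on a non-finite residual.
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    b = op.encode_adjoint(y)
    x = np.zeros_like(b) if x0 is None else as_array(x0).astype(np.complex128)
    r = b - op.normal(x)
    p = r.copy()
    rs = float(np.real(np.vdot(r, r)))
    residuals = [np.sqrt(rs)]
    if rs == 0.0:
        return (x, residuals) if return_residuals else x
    for _ in range(n_iters):
        Ap = op.normal(p)
        denom = float(np.real(np.vdot(p, Ap)))
        if denom <= 0 or not np.isfinite(denom):
            break
        alpha = rs / denom
        x = x + alpha * p
        r = r - alpha * Ap
        rs_new = float(np.real(np.vdot(r, r)))
        if not np.isfinite(rs_new):
            raise RuntimeError("CG residual became non-finite")
        residuals.append(np.sqrt(rs_new))
        if rs_new == 0.0:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return (x, residuals) if return_residuals else x


def soft_threshold(c: np.ndarray, thresh: float) -> np.ndarray:
    """Complex magnitude shrinkage preserving phase (real inputs reduce to
    the ordinary scalar soft threshold)."""
    mag = np.abs(c)
    scale = np.maximum(1.0 - thresh / np.maximum(mag, 1e-300), 0.0)
    return c * scale


def _objective(x, y_samples, op, lam, levels):
    resid = np.concatenate(
        [op.encode_channel(x, c) - y_samples[c] for c in range(op.n_channels)]
    )
    obj = 0.5 * float(np.real(np.vdot(resid, resid)))
    if lam > 0:
        w = dwt3(x.real, levels) + 1j * dwt3(x.imag, levels)
        obj += lam * float(np.sum(np.abs(w)))
    return obj


def l1_wavelet_cs(y: KSpaceData, op: EncodingOperator,
                  cfg: CSConfig | None = None, x0=None,
                  return_trace: bool = False):
    """FISTA for 0.5||Ex−y||² + λ||Wx||₁ with adaptive restart.

    Step size is 1/L with L from power iteration (1 for a normalized
    operator). With λ = 0 the prox is the identity and the iterates are
    plain accelerated gradient descent on the data-fidelity term.
    """
    cfg = cfg or CSConfig()
    lam = cfg.reg_weight
    levels = cfg.levels
    y_samples = y.samples if isinstance(y, KSpaceData) else np.atleast_2d(y)
    L = max_eig_power_iteration(op, n_iter=30, tol=1e-4)
    step = 1.0 / L

    def grad(v):
        out = np.zeros(op.shape, dtype=np.complex128)
        for c in range(op.n_channels):
            out += op.encode_adjoint_channel(
                op.encode_channel(v, c) - y_samples[c], c
            )
        return out

    def prox(v):
        if lam == 0:
            return v
        wr = dwt3(v.real, levels)
        wi = dwt3(v.imag, levels)
        w = soft_threshold(wr + 1j * wi, lam * step)
        return idwt3(w.real, levels) + 1j * idwt3(w.imag, levels)

    x = np.zeros(op.shape, dtype=np.complex128) if x0 is None else (
        as_array(x0).astype(np.complex128)
    )
    z = x.copy()
    tk = 1.0
    trace = [_objective(x, y_samples, op, lam, levels)]
    for _ in range(cfg.n_iters):
        x_new = prox(z - step * grad(z))
        obj = _objective(x_new, y_samples, op, lam, levels)
        if not np.isfinite(obj):
            raise RuntimeError("CS objective became non-finite")
        if obj > trace[-1] * (1 + 1e-6) + 1e-300:
            # adaptive restart: drop momentum, retake the step from x
            tk = 1.0
            z = x.copy()
            x_new = prox(z - step * grad(z))
            obj = _objective(x_new, y_samples, op, lam, levels)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk**2))
        z = x_new + ((tk - 1.0) / t_new) * (x_new - x)
        x, tk = x_new, t_new
        trace.append(obj)
    return (x, trace) if return_trace else x
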