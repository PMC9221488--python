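"""Bivariate spectral Granger causality (Geweke), the linear baseline.

A bivariate VAR is fitted by least squares with the lag order selected by
AIC; the spectral matrix S(f) = H(f) Sigma H(f)* follows from the transfer
function H(f) = [I - sum_k A_k e^{-2 pi i f k / fs}]^{-1} and the innovation
covariance Sigma.  The Geweke measure from x to y is

    G_{x->y}(f) = ln [ S_yy(f) / ( H~_yy(f) Sigma_yy H~_yy*(f) ) ],

where H~_yy = H_yy + (Sigma_xy / Sigma_yy) H_yx removes the instantaneous
noise correlation.  The frequency average of G over [0, fs/2] recovers the
time-domain measure ln(sigma^2_restricted / sigma^2_full).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.vector_ar.var_model import VAR

__all__ = ["GrangerResult", "spectral_gc", "gc_matrix"]


@dataclass
class GrangerResult:
    order: int
    freqs: np.ndarray
    gc_xy: np.ndarray
    gc_yx: np.ndarray
    gc_xy_scalar: float
    gc_yx_scalar: float
    Sxx: np.ndarray
    Syy: np.ndarray
    noise_cov: np.ndarray
    H: np.ndarray  # (nfreq, 2, 2) complex transfer function

    def time_domain(self) -> tuple:
        """Frequency-averaged Geweke measures over the full band (equal to
        the time-domain log-variance-ratio measures up to VAR truncation)."""
        return float(np.mean(self.gc_xy)), float(np.mean(self.gc_yx))


def _var_spectral(coefs, sigma, fs, nfreq):
    p = coefs.shape[0]
    freqs = np.linspace(0.0, fs / 2.0, nfreq)
    k = np.arange(1, p + 1)
    # A(f) = I - sum_k A_k exp(-2 pi i f k / fs)
    phase = np.exp(-2j * np.pi * np.outer(freqs, k) / fs)  # (nfreq, p)
    A = np.eye(2)[None, :, :] - np.einsum("fk,kij->fij", phase, coefs)
    H = np.linalg.inv(A)
    S = H @ sigma @ np.conj(np.swapaxes(H, 1, 2))
    return freqs, H, S


def spectral_gc(
    x,
    y,
    fs: float = 1000.0,
    max_order: int = 20,
    band=(8.0, 30.0),
    nfreq: int = 512,
) -> GrangerResult:
    """Spectral Granger causality between two series.

    The scalar measures are means of the spectral curves over ``band`` (Hz).
    Raises on an unstable fitted VAR.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if x.size < 200:
        raise ValueError("need at least 200 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")

    data = np.column_stack([x, y])
    model = VAR(data)
    sel = model.fit(maxlags=max_order, ic="aic", trend="c")
    order = int(sel.k_ar)
    if order == 0:
        sel = model.fit(1, trend="c")
        order = 1
    if not sel.is_stable():
        raise ValueError(f"fitted VAR({order}) is unstable")
    coefs = sel.coefs  # (p, 2, 2)
    sigma = np.asarray(sel.sigma_u)

    freqs, H, S = _var_spectral(coefs, sigma, fs, nfreq)
    Sxx = S[:, 0, 0].real
    Syy = S[:, 1, 1].real
    sxx, syy, sxy = sigma[0, 0], sigma[1, 1], sigma[0, 1]

    Hyy_t = H[:, 1, 1] + (sxy / syy) * H[:, 1, 0]
    Hxx_t = H[:, 0, 0] + (sxy / sxx) * H[:, 0, 1]
    intr_y = (Hyy_t * syy * np.conj(Hyy_t)).real
    intr_x = (Hxx_t * sxx * np.conj(Hxx_t)).real
    with np.errstate(divide="ignore", invalid="ignore"):
        gc_xy = np.log(Syy / intr_y)
        gc_yx = np.log(Sxx / intr_x)
    gc_xy = np.clip(np.nan_to_num(gc_xy, nan=0.0), 0.0, None)
    gc_yx = np.clip(np.nan_to_num(gc_yx, nan=0.0), 0.0, None)

    lo, hi = band
    m = (freqs >= lo) & (freqs <= hi)
    if not m.any():
        raise ValueError(f"band {band} contains no frequency-grid point")
    return GrangerResult(
        order=order,
        freqs=freqs,
        gc_xy=gc_xy,
        gc_yx=gc_yx,
        gc_xy_scalar=float(gc_xy[m].mean()),
        gc_yx_scalar=float(gc_yx[m].mean()),
        Sxx=Sxx,
        Syy=Syy,
        noise_cov=sigma,
        H=H,
    )


def gc_matrix(
    data,
    fs: float = 1000.0,
    band=(8.0, 30.0),
    max_order: int = 20,
) -> np.ndarray:
    """Directed band-mean GC between all ordered channel pairs.

    ``data`` is channels x samples (or a ChannelMatrix).  Entry (i, j) is the
    band-mean G_{i->j}; the diagonal is 0.  Symmetrize with
    ``np.maximum(D, D.T)`` before undirected network construction.
    """
    X = getattr(data, "data", data)
    X = np.asarray(X, dtype=float)
    p = X.shape[0]
    D = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            try:
                r = spectral_gc(X[i], X[j], fs=fs, max_order=max_order, band=band)
            except ValueError as err:
                raise ValueError(f"spectral GC failed for pair ({i}, {j}): {err}")
            D[i, j] = r.gc_xy_scalar
            D[j, i] = r.gc_yx_scalar
    return D
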