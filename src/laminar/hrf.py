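"""Haemodynamic response modelling shared by the simulator and the GLM.

The canonical double-gamma HRF (peak at ~5-6 s, undershoot at ~16 s,
peak:undershoot ratio 6, 32-s support) is used both to generate synthetic
BOLD responses and to build temporal-GLM regressors, which is exactly the
assumption the temporal GLM makes about the data.  Event regressors are
built from stick functions on an oversampled time grid, convolved, and
sampled at volume acquisition times.  Low-frequency drift is removed with a
discrete-cosine high-pass basis applied identically to data and design.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as gamma_dist

HRF_KERNEL_S = 32.0


def double_gamma_hrf(dt: float, peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                     peak_disp: float = 1.0, undershoot_disp: float = 1.0,
                     ratio: float = 6.0, duration: float = HRF_KERNEL_S) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt``, peak normalised to 1."""
    t = np.arange(0, duration, dt)
    h = (gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp)
         - gamma_dist.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp) / ratio)
    return h / h.max()


def event_regressor(onsets_s: np.ndarray, n_vols: int, tr_s: float,
                    oversample: int = 16) -> np.ndarray:
    """HRF-convolved stick regressor sampled at volume times ``i * TR``.

    Events beyond the run end raise; the unit-amplitude sticks make the
    fitted beta directly interpretable as the response amplitude per event.
    """
    onsets_s = np.asarray(onsets_s, dtype=float)
    run_end = n_vols * tr_s
    late = onsets_s[onsets_s >= run_end]
    if late.size:
        raise ValueError(f"events at {late.tolist()} s fall after the run end ({run_end:.1f} s)")
    dt = tr_s / oversample
    n_fine = n_vols * oversample + int(np.ceil(HRF_KERNEL_S / dt))
    sticks = np.zeros(n_fine)
    idx = np.round(onsets_s / dt).astype(int)
    np.add.at(sticks, idx, 1.0)
    conv = np.convolve(sticks, double_gamma_hrf(dt))[:n_fine]
    vol_idx = (np.arange(n_vols) * oversample).astype(int)
    return conv[vol_idx]


def block_regressor(onsets_s: np.ndarray, duration_s: float, n_vols: int, tr_s: float,
                    oversample: int = 16) -> np.ndarray:
    """HRF-convolved boxcar regressor, scaled so a sustained block plateaus at 1."""
    dt = tr_s / oversample
    t_fine = np.arange(n_vols * oversample) * dt
    box = np.zeros_like(t_fine)
    for onset in np.atleast_1d(onsets_s):
        box[(t_fine >= onset) & (t_fine < onset + duration_s)] = 1.0
    h = double_gamma_hrf(dt)
    return (np.convolve(box, h)[: len(box)] / h.sum())[::oversample]


def dct_highpass_basis(n_vols: int, tr_s: float, cutoff_s: float | None = 128.0) -> np.ndarray:
    """Orthonormal discrete-cosine drift basis with periods above ``cutoff_s``.

    Returns an (n_vols, K) matrix with K = floor(2 * duration / cutoff); the
    constant term is excluded (intercepts are modelled separately).  A
    ``None``/infinite cutoff disables filtering (K = 0).
    """
    if cutoff_s is None or not np.isfinite(cutoff_s):
        return np.zeros((n_vols, 0))
    if cutoff_s <= 0:
        raise ValueError("high-pass cutoff must be positive")
    order = int(np.floor(2.0 * n_vols * tr_s / cutoff_s))
    i = np.arange(n_vols)
    basis = np.column_stack([
        np.cos(np.pi * k * (2 * i + 1) / (2.0 * n_vols)) for k in range(1, order + 1)
    ]) if order >= 1 else np.zeros((n_vols, 0))
    if basis.shape[1]:
        basis = basis / np.linalg.norm(basis, axis=0)
    return basis


def residualize(data: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Project the drift basis out of ``data`` (first axis = time)."""
    if basis.shape[1] == 0:
        return np.asarray(data, dtype=float)
    data = np.asarray(data, dtype=float)
    return data - basis @ (basis.T @ data)
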