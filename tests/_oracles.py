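"""Independent oracles shared by the test suite.

Everything here is deliberately decoupled from the implementation paths it
checks: the QP oracle minimizes the dual objective with a generic SQP
solver, the spectral oracle is a plain FFT periodogram, and the sliding
mean is brute force.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from sleeptransfer.tsvm import LabeledDataset, SourceModel, TsvmConfig


def dual_qp_oracle(
    data: LabeledDataset, source: SourceModel, cfg: TsvmConfig
) -> tuple[np.ndarray, float]:
    """Solve the transfer-SVM dual with a generic convex-QP method (SLSQP).

    The objective is rebuilt here from its definition rather than imported,
    so the oracle shares no solver code with the implementation.
    """
    X, y = data.X, data.y
    denom = 2.0 * cfg.mu + 1.0
    K = X @ X.T
    Q = (y[:, None] * y[None, :]) * K / denom
    p = (2.0 * cfg.mu / denom) * y * (X @ source.w_s) - 1.0
    const = -(cfg.mu / denom) * float(source.w_s @ source.w_s)
    n = p.size
    res = minimize(
        lambda b: 0.5 * b @ Q @ b + p @ b + const,
        np.zeros(n),
        jac=lambda b: Q @ b + p,
        method="SLSQP",
        bounds=[(0.0, cfg.C_t)] * n,
        constraints=[{"type": "eq", "fun": lambda b: b @ y, "jac": lambda b: y}],
        options={"maxiter": 5000, "ftol": 1e-16},
    )
    return res.x, float(res.fun)


def band_power_fraction(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Fraction of FFT-periodogram power inside [lo, hi] Hz (DC excluded)."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    total = spec[1:].sum()
    if total == 0:
        return 0.0
    sel = (freqs >= lo) & (freqs <= hi)
    sel[0] = False
    return float(spec[sel].sum() / total)


def peak_frequency(x: np.ndarray, fs: float) -> float:
    """Frequency of the periodogram maximum (DC excluded)."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    return float(freqs[1:][np.argmax(spec[1:])])


def brute_force_sliding_mean(base: np.ndarray, w: int) -> np.ndarray:
    """Centered sliding mean with edge truncation, computed naively."""
    n = base.shape[0]
    out = np.empty_like(base)
    for i in range(n):
        lo = max(0, i - (w - 1) // 2)
        hi = min(n, i + w // 2 + 1)
        out[i] = base[lo:hi].mean(axis=0)
    return out


def well_conditioned_qp_instance(
    rng: np.random.Generator,
) -> tuple[LabeledDataset, SourceModel, TsvmConfig]:
    """Random dual-QP instance whose optimum is numerically identifiable.

    The multiplier vector is only well determined when the Gram matrix has
    little null space along the feasible set, so the feature dimension is
    drawn comparable to the sample count (d >= n - 3); with n >> d the dual
    optimum lies on a face so flat that no two solvers agree to 1e-6.
    """
    n = int(rng.integers(6, 13))
    d = int(rng.integers(max(2, n - 3), 11))
    X = rng.normal(size=(n, d))
    y = np.where(rng.uniform(size=n) < 0.5, 1.0, -1.0)
    if abs(y.sum()) == n:  # force both classes
        y[0] *= -1
    cfg = TsvmConfig(
        C_t=float(rng.choice([0.5, 1.0, 10.0])),
        mu=float(rng.choice([0.0, 0.001, 0.1, 0.3, 0.5, 0.9])),
    )
    return LabeledDataset(X=X, y=y), SourceModel(w_s=rng.normal(size=d)), cfg
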