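"""Stochastic respiration: constant-amplitude waveform with per-breath
frequency redraw.

Breathing is modelled as a correlated stochastic process: within one breath
the waveform is a pure sinusoid of unit (constant) amplitude; at each breath
onset the cycle frequency is redrawn as ``f_br + xi`` with ``xi`` zero-mean
Gaussian noise of variance ``sigma2_xi``.  This is the model's only source
of randomness.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RespirationProcess", "respiration_signal"]

# Breaths slower than this are rejected and the frequency redrawn; with the
# shipped noise level the redraw probability is negligible (~1e-7).
F_MIN_HZ = 0.05


class RespirationProcess:
    """Reproducible breath-by-breath respiration waveform.

    Parameters
    ----------
    f_br : float
        Mean breathing frequency, Hz (> 0).
    sigma2_xi : float
        Variance of the zero-mean Gaussian frequency noise, Hz^2 (>= 0).
    duration : float
        Time span to cover, s.
    seed : int
        Seed of the dedicated random generator.
    amplitude : float
        Constant waveform amplitude (the model uses 1).
    """

    def __init__(self, f_br: float, sigma2_xi: float, duration: float,
                 seed: int, amplitude: float = 1.0):
        if not np.isfinite(f_br) or f_br <= 0:
            raise ValueError(f"f_br must be positive, got {f_br}")
        if not np.isfinite(sigma2_xi) or sigma2_xi < 0:
            raise ValueError(f"sigma2_xi must be >= 0, got {sigma2_xi}")
        if duration <= 0:
            raise ValueError("duration must be positive")
        self.f_br = float(f_br)
        self.sigma2_xi = float(sigma2_xi)
        self.amplitude = float(amplitude)
        self.seed = int(seed)

        rng = np.random.default_rng(seed)
        sigma = float(np.sqrt(sigma2_xi))
        onsets = [0.0]
        freqs = []
        t = 0.0
        while t <= duration:
            f = self.f_br + rng.normal(0.0, sigma) if sigma > 0 else self.f_br
            while f <= F_MIN_HZ:
                f = self.f_br + rng.normal(0.0, sigma)
            freqs.append(f)
            t += 1.0 / f
            onsets.append(t)
        self.onsets = np.asarray(onsets)          # len = n_breaths + 1
        self.frequencies = np.asarray(freqs)      # len = n_breaths

    @property
    def n_breaths(self) -> int:
        return len(self.frequencies)

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Evaluate r(t) on an array of times within the covered span."""
        t = np.asarray(t, dtype=float)
        if t.size and (t.min() < 0 or t.max() > self.onsets[-1]):
            raise ValueError("time outside the generated respiration span")
        k = np.clip(np.searchsorted(self.onsets, t, side="right") - 1,
                    0, self.n_breaths - 1)
        return self.amplitude * np.sin(
            2.0 * np.pi * self.frequencies[k] * (t - self.onsets[k]))


def respiration_signal(t, f_br: float, sigma2_xi: float, amplitude: float,
                       seed: int) -> np.ndarray:
    """Convenience wrapper: evaluate the respiration waveform at times ``t``."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    proc = RespirationProcess(f_br, sigma2_xi, float(t.max()) + 1.0, seed,
                              amplitude=amplitude)
    return proc.waveform(t)
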