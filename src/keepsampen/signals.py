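"""Seeded generators of physiological-like test signals.

These stand in for recorded physiological signals (air flow, RR intervals,
EEG amplitude, glucose) so every method and experiment can be exercised
without external downloads:

* ``iid_gaussian`` — independent standard normal draws (white noise).
* ``ar1`` — first-order autoregression ``x_t = phi * x_{t-1} + eps_t`` with a
  stationary start, mimicking the short-range autocorrelation of slow
  physiological signals.
* ``periodic_noise`` — a sinusoid of a given period plus Gaussian noise,
  mimicking quasi-periodic signals such as respiration.
* ``logistic_map`` — the deterministic chaotic map ``x_{t+1} = a x_t (1-x_t)``
  with a 1000-step burn-in discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core import TimeSeries

__all__ = ["SignalSpec", "generate_signal", "LOGISTIC_BURN_IN"]

SignalKind = Literal["iid_gaussian", "ar1", "periodic_noise", "logistic_map"]

LOGISTIC_BURN_IN = 1000


@dataclass(frozen=True)
class SignalSpec:
    """Which signal to generate, at what length, with which parameters.

    ``params`` holds kind-specific values: ``phi`` for ar1 (|phi| < 1);
    ``period`` (samples), ``noise_sd`` and optional ``amplitude`` for
    periodic_noise; ``a`` for the logistic map (chaotic for a in
    (3.57, 4]).
    """

    kind: SignalKind
    n: int
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("iid_gaussian", "ar1", "periodic_noise", "logistic_map"):
            raise ValueError(f"unknown signal kind {self.kind!r}")
        if self.n < 10:
            raise ValueError(f"n must be >= 10, got {self.n}")
        if self.kind == "ar1":
            phi = self.params.get("phi", 0.9)
            if not abs(phi) < 1:
                raise ValueError(f"ar1 requires |phi| < 1, got phi={phi}")
        if self.kind == "periodic_noise":
            if self.params.get("period", 50) <= 1:
                raise ValueError("periodic_noise requires period > 1")
            if self.params.get("noise_sd", 0.1) < 0:
                raise ValueError("periodic_noise requires noise_sd >= 0")
        if self.kind == "logistic_map":
            a = self.params.get("a", 4.0)
            if not 3.57 < a <= 4.0:
                raise ValueError(
                    f"logistic_map control parameter a must be in (3.57, 4] "
                    f"for the chaotic regime, got a={a}"
                )


def generate_signal(spec: SignalSpec) -> TimeSeries:
    """Generate a fully observed series; bit-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    if spec.kind == "iid_gaussian":
        values = rng.standard_normal(n)
    elif spec.kind == "ar1":
        phi = float(spec.params.get("phi", 0.9))
        eps = rng.standard_normal(n)
        values = np.empty(n)
        # stationary initialization: x_0 ~ N(0, 1 / (1 - phi^2))
        values[0] = rng.standard_normal() / np.sqrt(1.0 - phi * phi)
        for t in range(1, n):
            values[t] = phi * values[t - 1] + eps[t]
    elif spec.kind == "periodic_noise":
        period = float(spec.params.get("period", 50))
        noise_sd = float(spec.params.get("noise_sd", 0.1))
        amplitude = float(spec.params.get("amplitude", 1.0))
        t = np.arange(n)
        values = amplitude * np.sin(2.0 * np.pi * t / period)
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=n)
    else:  # logistic_map
        a = float(spec.params.get("a", 4.0))
        x = float(rng.uniform(0.1, 0.9))
        for _ in range(LOGISTIC_BURN_IN):
            x = a * x * (1.0 - x)
        values = np.empty(n)
        for t in range(n):
            x = a * x * (1.0 - x)
            values[t] = x
    return TimeSeries(values=values, mask=np.ones(n, dtype=bool))
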