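"""Firing-rate model of ICcl input neurons.

ICcl neurons (lateral shell of the central nucleus of the inferior
colliculus) are narrowly tuned to frequency and have quasi-sinusoidal ITD
tuning whose width depends on best frequency.  Their normalized rate in
response to a broadband stimulus at interaural time difference ``ITD`` is

    r_i(ITD) = (exp(b_i cos(2 pi bf_i (ITD - ITD_i))) - exp(-b_i))
               / (exp(b_i) - exp(-b_i))

with best frequency ``bf_i`` (kHz), best ITD ``ITD_i`` and a concentration
parameter ``b_i`` > 0 that narrows the peak relative to a raised cosine.
``b_i`` is tied to best frequency through the smaller root of a quadratic
calibrated against measured ICcl half-widths; see :func:`concentration_param`.

Units: interfaces take ITD in microseconds and frequency in kHz; internally
ITD is converted to milliseconds so that ``bf * itd`` is in cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QuadraticCoefficients",
    "ICclNeuron",
    "ICclPopulation",
    "concentration_param",
    "itd_tuning",
    "build_population",
    "tone_response",
]

BF_MIN_KHZ = 0.5
BF_MAX_KHZ = 10.0
ITD_MIN_US = -250.0
ITD_MAX_US = 250.0

#: Floor applied to the concentration parameter where the quadratic root
#: is non-positive (bf close to 10 kHz); tuning then degenerates gracefully
#: to a near-raised-cosine shape.
B_EPSILON = 0.01


@dataclass(frozen=True)
class QuadraticCoefficients:
    """Coefficients of the best-frequency -> concentration quadratic.

    The concentration parameter solves ``q2 b^2 - q1 b + (q0 - q3 bf) = 0``;
    :func:`concentration_param` takes the smaller root.
    """

    q1: float = 17.0
    q2: float = 2.8
    q0: float = 24.12
    q3: float = 2.44


DEFAULT_COEFFS = QuadraticCoefficients()


def concentration_param(
    bf: float | np.ndarray,
    coeffs: QuadraticCoefficients = DEFAULT_COEFFS,
    eps: float = B_EPSILON,
) -> float | np.ndarray:
    """ITD-tuning concentration parameter ``b`` for a given best frequency.

    Returns the smaller root ``(q1 - sqrt(q1^2 - 4 q2 (q0 - q3 bf))) / (2 q2)``,
    clamped below at ``eps``.  ``b`` decreases with best frequency: high-BF
    ICcl neurons have ITD curves closer to a raised cosine.

    Parameters
    ----------
    bf : float or array
        Best frequency in kHz, within [0.5, 10].

    Raises
    ------
    ValueError
        If ``bf`` is outside [0.5, 10] or the discriminant is negative.
    """
    bf_arr = np.asarray(bf, dtype=float)
    if np.any(bf_arr < BF_MIN_KHZ) or np.any(bf_arr > BF_MAX_KHZ):
        raise ValueError(f"best frequency out of range [0.5, 10] kHz: {bf!r}")
    disc = coeffs.q1**2 - 4.0 * coeffs.q2 * (coeffs.q0 - coeffs.q3 * bf_arr)
    if np.any(disc < 0):
        bad = np.atleast_1d(bf_arr)[np.atleast_1d(disc) < 0]
        raise ValueError(
            f"negative discriminant in concentration quadratic at bf={bad.tolist()} kHz"
        )
    root = (coeffs.q1 - np.sqrt(disc)) / (2.0 * coeffs.q2)
    out = np.maximum(root, eps)
    if np.isscalar(bf) or bf_arr.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class ICclNeuron:
    """A single ICcl input neuron.

    Attributes
    ----------
    bf : float
        Best frequency in kHz, in [0.5, 10].
    best_itd : float
        Preferred ITD in microseconds, in [-250, 250].
    b : float
        Concentration parameter of the ITD tuning curve (> 0).
    """

    bf: float
    best_itd: float
    b: float

    def __post_init__(self) -> None:
        if not (BF_MIN_KHZ <= self.bf <= BF_MAX_KHZ):
            raise ValueError(f"bf out of range: {self.bf}")
        if not (ITD_MIN_US <= self.best_itd <= ITD_MAX_US):
            raise ValueError(f"best_itd out of range: {self.best_itd}")
        if not self.b > 0:
            raise ValueError(f"concentration parameter must be > 0: {self.b}")


def itd_tuning(
    neuron: ICclNeuron, itd: float | np.ndarray
) -> float | np.ndarray:
    """Normalized ICcl firing rate at the given ITD (microseconds).

    The output is in [0, 1], equals 1 at ``best_itd`` and is periodic in ITD
    with period ``1/bf`` (bf in kHz, ITD converted to ms internally).
    """
    itd_ms = (np.asarray(itd, dtype=float) - neuron.best_itd) * 1e-3
    b = neuron.b
    num = np.exp(b * np.cos(2.0 * np.pi * neuron.bf * itd_ms)) - np.exp(-b)
    den = np.exp(b) - np.exp(-b)
    out = num / den
    if np.isscalar(itd):
        return float(out)
    return out


def tone_response(
    neuron: ICclNeuron,
    tone_freq: float,
    itd: float | np.ndarray,
    level_scale: float = 1.0,
    freq_tuning_width: float = 0.5,
) -> float | np.ndarray:
    """ICcl rate for a tonal stimulus.

    A Gaussian frequency-tuning factor (width ``freq_tuning_width`` kHz)
    multiplies the broadband ITD tuning curve; ``level_scale`` in [0, 1]
    scales the response with stimulus level.  ICcl ITD tuning is similar for
    tones and noise, so the ITD factor is shared with :func:`itd_tuning`.
    """
    if freq_tuning_width <= 0:
        raise ValueError("freq_tuning_width must be > 0")
    if not 0.0 <= level_scale <= 1.0:
        raise ValueError("level_scale must be in [0, 1]")
    gauss = np.exp(-0.5 * ((tone_freq - neuron.bf) / freq_tuning_width) ** 2)
    return level_scale * gauss * itd_tuning(neuron, itd)


@dataclass(frozen=True)
class ICclPopulation:
    """Regular (bf x best ITD) grid of ICcl neurons, bf-major ordered."""

    neurons: tuple[ICclNeuron, ...]
    bf_step: float
    itd_step: float

    # cached arrays for vectorized rate evaluation
    _bf: np.ndarray = field(repr=False, compare=False, default=None)
    _best_itd: np.ndarray = field(repr=False, compare=False, default=None)
    _b: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        pairs = {(n.bf, n.best_itd) for n in self.neurons}
        if len(pairs) != len(self.neurons):
            raise ValueError("duplicate (bf, best_itd) pairs in population")
        object.__setattr__(self, "_bf", np.array([n.bf for n in self.neurons]))
        object.__setattr__(
            self, "_best_itd", np.array([n.best_itd for n in self.neurons])
        )
        object.__setattr__(self, "_b", np.array([n.b for n in self.neurons]))

    def __len__(self) -> int:
        return len(self.neurons)

    @property
    def bf(self) -> np.ndarray:
        return self._bf

    @property
    def best_itd(self) -> np.ndarray:
        return self._best_itd

    @property
    def b(self) -> np.ndarray:
        return self._b

    def rates(self, itd_us: np.ndarray) -> np.ndarray:
        """Broadband rates, shape (n_itd, n_neurons), vectorized."""
        itd_us = np.atleast_1d(np.asarray(itd_us, dtype=float))
        dt_ms = (itd_us[:, None] - self._best_itd[None, :]) * 1e-3
        b = self._b[None, :]
        num = np.exp(b * np.cos(2.0 * np.pi * self._bf[None, :] * dt_ms)) - np.exp(-b)
        return num / (np.exp(b) - np.exp(-b))

    def tone_rates(
        self,
        tone_freq: float,
        itd_us: np.ndarray,
        level_scale: float = 1.0,
        freq_tuning_width: float = 0.5,
    ) -> np.ndarray:
        """Tone-stimulus rates, shape (n_itd, n_neurons)."""
        gauss = np.exp(
            -0.5 * ((tone_freq - self._bf) / freq_tuning_width) ** 2
        )
        return level_scale * gauss[None, :] * self.rates(itd_us)

    def to_frame(self) -> pd.DataFrame:
        """Population table with columns index, bf_khz, best_itd_us, b."""
        return pd.DataFrame(
            {
                "index": np.arange(len(self.neurons)),
                "bf_khz": self._bf,
                "best_itd_us": self._best_itd,
                "b": self._b,
            }
        )


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    vals = lo + step * np.arange(n)
    return vals[vals <= hi + 1e-9]


def build_population(
    bf_range: Sequence[float] = (BF_MIN_KHZ, BF_MAX_KHZ),
    itd_range: Sequence[float] = (0.0, 0.0),
    bf_step: float = 0.1,
    itd_step: float = 10.0,
    coeffs: QuadraticCoefficients = DEFAULT_COEFFS,
) -> ICclPopulation:
    """Build an ICcl population on a regular (bf x best ITD) grid.

    Defaults give best frequencies 0.5-10 kHz in 0.1-kHz steps with a single
    best-ITD column at 0 us (the two-layer simulations use subunit inputs
    tuned to the same ITD).
    """
    if bf_step <= 0 or itd_step <= 0:
        raise ValueError("grid steps must be > 0")
    bf_lo, bf_hi = bf_range
    itd_lo, itd_hi = itd_range
    if bf_lo < BF_MIN_KHZ or bf_hi > BF_MAX_KHZ:
        raise ValueError(f"bf_range outside [0.5, 10] kHz: {bf_range}")
    if itd_lo < ITD_MIN_US or itd_hi > ITD_MAX_US:
        raise ValueError(f"itd_range outside [-250, 250] us: {itd_range}")
    bfs = _grid(bf_lo, bf_hi, bf_step)
    itds = _grid(itd_lo, itd_hi, itd_step)
    if bfs.size == 0 or itds.size == 0:
        raise ValueError("empty population grid")
    neurons = tuple(
        ICclNeuron(bf=float(bf), best_itd=float(itd), b=float(concentration_param(bf, coeffs)))
        for bf in bfs
        for itd in itds
    )
    return ICclPopulation(neurons=neurons, bf_step=bf_step, itd_step=itd_step)
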