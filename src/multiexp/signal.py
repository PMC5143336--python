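"""Sampled kinetic signals.

A decay curve is a pair of equal-length sequences: times (seconds, strictly
increasing) and amplitudes (arbitrary units).  Both are stored as read-only
float arrays so that a signal can be shared between the optimizer and the
reporting layer without defensive copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SampledSignal"]


def _as_readonly(a) -> np.ndarray:
    out = np.array(a, dtype=float).ravel()
    out.flags.writeable = False
    return out


@dataclass(frozen=True)
class SampledSignal:
    """A kinetic curve sampled on a strictly increasing time grid.

    Parameters
    ----------
    times : array-like
        Sampling times in seconds, strictly increasing.
    amplitudes : array-like
        Signal amplitude in arbitrary units, one value per time point.
    """

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        t = _as_readonly(self.times)
        x = _as_readonly(self.amplitudes)
        if t.size != x.size:
            raise ValueError(
                f"times and amplitudes differ in length ({t.size} vs {x.size})"
            )
        if t.size < 2:
            raise ValueError("a sampled signal needs at least two points")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
            raise ValueError("times and amplitudes must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", x)

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.times.size

    @property
    def span(self) -> float:
        """Duration covered by the grid, ``t[-1] - t[0]``, in seconds."""
        return float(self.times[-1] - self.times[0])

    def peak_normalized(self) -> "SampledSignal":
        """Return a copy scaled so the first-sample amplitude equals 1.

        For a monotonically decaying curve the first sample is the peak.
        Raises if the first amplitude is not strictly positive, since the
        normalized curve would be meaningless.
        """
        x0 = self.amplitudes[0]
        if x0 <= 0:
            raise ValueError("cannot peak-normalize: first amplitude is not positive")
        return SampledSignal(self.times, self.amplitudes / x0)
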