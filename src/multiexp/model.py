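"""Model/Results front end for multiexponential decay decomposition.

`ExponentialDecayModel` is built from data (arrays, a `SampledSignal`, or a
two-column text file); its :meth:`~ExponentialDecayModel.fit` returns an
`ExponentialDecayResults` carrying the components, diagnostics, a summary
table, prediction, plotting, and writers for the two report files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io as _io
from .basis import dispersion as _dispersion
from .optimize import FitResult, OptimizerConfig, fit as _fit
from .signal import SampledSignal

__all__ = ["ExponentialDecayModel", "ExponentialDecayResults"]


class ExponentialDecayModel:
    """Sum-of-positive-exponentials model ``A(t) = sum_i a_i exp(-k_i t)``.

    Parameters
    ----------
    times, amplitudes : array-like
        The sampled decay curve (seconds; arbitrary units).

    Examples
    --------
    >>> from multiexp import ExponentialDecayModel
    >>> from multiexp.synthetic import generate_signal, table1_fixture
    >>> sig = generate_signal(table1_fixture("Pdl"))
    >>> res = ExponentialDecayModel.from_signal(sig).fit(max_components=3)
    >>> res.n_components
    3
    """

    def __init__(self, times, amplitudes):
        self.signal = SampledSignal(times, amplitudes)

    @classmethod
    def from_signal(cls, signal: SampledSignal) -> "ExponentialDecayModel":
        obj = cls.__new__(cls)
        obj.signal = signal
        return obj

    @classmethod
    def from_file(cls, path, strict: bool = False) -> "ExponentialDecayModel":
        """Build the model from a two-column time/amplitude text file."""
        return cls.from_signal(_io.read_signal(path, strict=strict))

    @property
    def nobs(self) -> int:
        return self.signal.n

    def fit(
        self, config: OptimizerConfig | None = None, **config_overrides
    ) -> "ExponentialDecayResults":
        """Run the greedy coordinate-descent decomposition.

        Accepts an :class:`~multiexp.optimize.OptimizerConfig` or its fields
        as keywords (``max_components``, ``points_per_decade``,
        ``improvement_tol`` ...).
        """
        result = _fit(self.signal, config, **config_overrides)
        return ExponentialDecayResults(self, result)


class ExponentialDecayResults:
    """Fitted decomposition: estimates, diagnostics and reporting."""

    def __init__(self, model: ExponentialDecayModel, result: FitResult):
        self.model = model
        self.result = result

    # -- estimates ---------------------------------------------------------
    @property
    def n_components(self) -> int:
        return self.result.n_components

    @property
    def weights(self) -> np.ndarray:
        """Component amplitudes a_i in the original units, fastest first."""
        return self.result.model.weights

    @property
    def decrements(self) -> np.ndarray:
        """Rate constants k_i in 1/s, descending."""
        return self.result.model.decrements

    @property
    def params(self) -> pd.DataFrame:
        """Component table: weight, weight fraction of peak, share %, decrement, lifetime."""
        w = self.weights
        return pd.DataFrame(
            {
                "weight": w,
                "weight_normalized": self.result.weights_normalized,
                "weight_percent": 100.0 * w / w.sum(),
                "decrement_per_s": self.decrements,
                "lifetime_s": 1.0 / self.decrements,
            },
            index=pd.RangeIndex(1, self.n_components + 1, name="component"),
        )

    # -- diagnostics -------------------------------------------------------
    @property
    def dispersion(self) -> float:
        """Mean squared residual of the peak-normalized curve."""
        return self.result.dispersion

    @property
    def resid(self) -> np.ndarray:
        return self.result.residuals

    @property
    def stage_trace(self) -> list[tuple[int, float]]:
        """(n_components, dispersion) of every accepted stage."""
        return list(self.result.stage_trace)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def predict(self, times=None) -> np.ndarray:
        t = self.model.signal.times if times is None else times
        return self.result.model.predict(t)

    def recompute_dispersion(self) -> float:
        """Re-derive the dispersion from signal and model (consistency check)."""
        return _dispersion(self.model.signal, self.result.model)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of the decomposition."""
        lines = [
            "Multiexponential decay decomposition",
            "=" * 64,
            f"components: {self.n_components:<6d} observations: {self.nobs}",
            f"dispersion (normalized MSE): {self.dispersion:.6g}",
            f"peak amplitude (scale): {self.result.scale:.6g}",
            "-" * 64,
            f"{'comp':>4} {'weight':>14} {'weight %':>9} {'k [1/s]':>14} {'tau [s]':>12}",
        ]
        total = self.weights.sum()
        for i, (w, k) in enumerate(self.result.model.components, start=1):
            lines.append(
                f"{i:>4d} {w:>14.6g} {100 * w / total:>9.1f} {k:>14.6g} {1 / k:>12.4g}"
            )
        lines.append("-" * 64)
        lines.append("stage trace (n, dispersion): " + ", ".join(
            f"({n}, {d:.3g})" for n, d in self.result.stage_trace
        ))
        return "\n".join(lines)

    def save_approximation(self, path) -> None:
        """Write the fitted curve on the input grid (two-column dialect)."""
        _io.write_approximation(self.model.signal, self.result, path)

    def save_parameters(self, path) -> None:
        """Write the component parameter table."""
        _io.write_parameters(self.result, path)

    def plot(self, ax=None):
        """Overlay the measured and fitted curves (peak-normalized)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sig = self.model.signal
        scale = self.result.scale
        ax.plot(sig.times, sig.amplitudes / scale, label="signal", lw=1)
        ax.plot(sig.times, self.predict() / scale, label="approximation", lw=1)
        ax.set_xlabel("time [s]")
        ax.set_ylabel("normalized amplitude")
        ax.legend()
        return ax

    def __repr__(self) -> str:
        return (
            f"<ExponentialDecayResults n_components={self.n_components} "
            f"dispersion={self.dispersion:.3g}>"
        )
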