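"""Two-column plain-text signal files and fit-report tables.

Dialect: whitespace-separated columns, '.' as the decimal mark, time in
seconds in the first column, amplitude in arbitrary units in the second.
Lines starting with '#' and blank lines are ignored.
"""

from __future__ import annotations

import logging
import os
import warnings
from contextlib import contextmanager

import numpy as np

from .exceptions import SignalFormatError
from .optimize import FitResult
from .signal import SampledSignal

__all__ = [
    "read_signal",
    "write_signal",
    "write_approximation",
    "write_parameters",
    "read_parameters",
]

logger = logging.getLogger(__name__)


@contextmanager
def _open(source, mode):
    if isinstance(source, (str, os.PathLike)):
        fh = open(source, mode)
        try:
            yield fh
        finally:
            fh.close()
    else:
        yield source


def read_signal(source, strict: bool = False) -> SampledSignal:
    """Parse a two-column time/amplitude text file.

    Rows that fail numeric parsing are skipped with a logged warning naming
    the line number — never silently.  A comma decimal mark is a hard error
    (the dialect requires the point).  Amplitudes that do not continuously
    decrease raise when ``strict`` is on and warn otherwise.

    Parameters
    ----------
    source : path or text stream
    strict : bool
        Enforce monotonically non-increasing amplitudes.
    """
    times: list[float] = []
    amps: list[float] = []
    with _open(source, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if any("," in p for p in parts):
                raise SignalFormatError(
                    f"line {lineno}: comma found; the dialect requires the "
                    "point '.' as decimal mark"
                )
            if len(parts) != 2:
                logger.warning(
                    "line %d skipped: expected 2 columns, found %d", lineno, len(parts)
                )
                continue
            try:
                t_val, a_val = float(parts[0]), float(parts[1])
            except ValueError:
                logger.warning("line %d skipped: non-numeric value", lineno)
                continue
            times.append(t_val)
            amps.append(a_val)

    if len(times) < 2:
        raise SignalFormatError(f"only {len(times)} valid data rows; need at least 2")
    t = np.array(times)
    x = np.array(amps)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
        raise SignalFormatError("non-finite value in a data row")
    if np.any(np.diff(t) <= 0):
        raise SignalFormatError("times must be strictly increasing")
    if np.any(np.diff(x) > 0):
        msg = "signal amplitude does not continuously reduce with time"
        if strict:
            raise SignalFormatError(msg)
        warnings.warn(msg, stacklevel=2)
    return SampledSignal(t, x)


def write_signal(signal: SampledSignal, sink) -> None:
    """Write a signal in the two-column dialect (10 significant digits)."""
    with _open(sink, "w") as fh:
        for t, a in zip(signal.times, signal.amplitudes):
            fh.write(f"{t:.9e} {a:.9e}\n")


def write_approximation(signal: SampledSignal, result: FitResult, sink) -> None:
    """Write the fitted curve on the signal's own time grid, original scale.

    The output round-trips through :func:`read_signal` (the fitted curve is
    strictly decreasing, so strict mode also accepts it).
    """
    if signal.n == 0:  # unreachable through SampledSignal, kept as a guard
        raise ValueError("cannot write an approximation for an empty grid")
    prediction = result.model.predict(signal.times)
    write_signal(SampledSignal(signal.times, prediction), sink)


def write_parameters(result: FitResult, sink) -> None:
    """Write the component table: index, weight, weight %, decrement.

    One row per component sorted by decrement descending; weights are in the
    original amplitude units, the percentage column gives each weight's share
    of the summed weights rounded to integers (so the column may not sum to
    exactly 100).  A footer row records the component count and dispersion.
    """
    model = result.model
    total = float(np.sum(model.weights))
    with _open(sink, "w") as fh:
        fh.write("# index\tweight\tweight_percent\tdecrement_per_s\n")
        for i, (w, k) in enumerate(model.components, start=1):
            fh.write(f"{i:d}\t{w:.9e}\t{round(100.0 * w / total):d}\t{k:.9e}\n")
        fh.write(
            f"# n_components = {model.n}\tdispersion = {result.dispersion:.9e}\n"
        )


def read_parameters(source) -> dict:
    """Parse a table written by :func:`write_parameters`.

    Returns a dict with ``weights``, ``weight_percents``, ``decrements``,
    ``n_components`` and ``dispersion``.
    """
    weights, percents, decrements = [], [], []
    n_components, disp = None, None
    with _open(source, "r") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "n_components" in line:
                    fields = line.lstrip("#").split("\t")
                    for f in fields:
                        key, _, value = f.partition("=")
                        key = key.strip()
                        if key == "n_components":
                            n_components = int(value)
                        elif key == "dispersion":
                            disp = float(value)
                continue
            _, w, pct, k = line.split("\t")
            weights.append(float(w))
            percents.append(int(pct))
            decrements.append(float(k))
    return {
        "weights": np.array(weights),
        "weight_percents": np.array(percents),
        "decrements": np.array(decrements),
        "n_components": n_components,
        "dispersion": disp,
    }
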