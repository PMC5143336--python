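"""Synthetic multiexponential decay signals with known ground truth.

Provides forward evaluation of ``A(t) = scale * sum_i a_i exp(-k_i t)`` with
optional additive Gaussian noise, plus the published parameter sets for the
chlorophyll-fluorescence induction decays of four winter-wheat genotypes
(Pdl, Per, Ods, Dos), so that recovery of weights and rate constants can be
tested end to end without any measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal import SampledSignal

__all__ = ["GeneratorSpec", "generate_signal", "table1_fixture", "GENOTYPES"]

#: Published three-component decompositions for four wheat genotypes:
#: (weight as fraction of initial amplitude, decrement in 1/s) per component.
GENOTYPES: dict[str, tuple[tuple[float, float], ...]] = {
    "Pdl": ((0.59, 400.0), (0.29, 87.0), (0.07, 11.0)),
    "Per": ((0.67, 300.0), (0.23, 57.0), (0.03, 5.0)),
    "Ods": ((0.67, 300.0), (0.22, 66.0), (0.04, 12.0)),
    "Dos": ((0.77, 370.0), (0.22, 71.0), (0.04, 13.0)),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic decay signal.

    ``components`` holds ``(weight fraction of initial amplitude, decrement
    1/s)`` pairs.  Noise is additive i.i.d. Gaussian with standard deviation
    ``noise_sd * scale`` — the simplest model consistent with photometric
    detection noise.  The same seed and spec always reproduce the identical
    signal bit for bit.
    """

    components: tuple[tuple[float, float], ...]
    t_start: float = 0.0
    t_end: float = 0.5
    dt: float = 2.5e-4
    noise_sd: float = 0.0
    seed: int = 0
    scale: float = 1.0

    def __post_init__(self) -> None:
        comps = tuple((float(w), float(k)) for w, k in self.components)
        if not comps:
            raise ValueError("at least one component is required")
        for w, k in comps:
            if not (np.isfinite(w) and w > 0):
                raise ValueError(f"component weight must be positive, got {w}")
            if not (np.isfinite(k) and k > 0):
                raise ValueError(f"component decrement must be positive, got {k}")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "components", comps)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for w, _ in self.components])

    @property
    def decrements(self) -> np.ndarray:
        return np.array([k for _, k in self.components])


def generate_signal(spec: GeneratorSpec) -> SampledSignal:
    """Evaluate the spec's decay on its grid, adding seeded Gaussian noise.

    The grid runs from ``t_start`` in steps of ``dt`` up to (at most)
    ``t_end`` inclusive.  With ``noise_sd=0`` the output is exactly the
    analytic sum at every point and strictly decreasing.
    """
    n_steps = int(np.floor((spec.t_end - spec.t_start) / spec.dt + 1e-9))
    times = spec.t_start + spec.dt * np.arange(n_steps + 1)
    clean = spec.scale * (spec.weights @ np.exp(-np.outer(spec.decrements, times)))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        amplitudes = clean + rng.normal(0.0, spec.noise_sd * spec.scale, times.size)
    else:
        amplitudes = clean
    return SampledSignal(times, amplitudes)


def table1_fixture(genotype: str, **overrides) -> GeneratorSpec:
    """Generator spec for a published wheat-genotype decomposition.

    Weights are the printed percentages taken verbatim as fractions (they do
    not sum to exactly 1 because of rounding in the published table; they are
    deliberately not renormalized).  The default grid, t in [0, 0.5] s with
    dt = 0.25 ms, covers more than five lifetimes of the slowest published
    component (k = 5 1/s) and resolves the fastest (k = 400 1/s, lifetime
    2.5 ms).  Keyword overrides (``noise_sd``, ``seed``, ``t_end`` ...) are
    forwarded to :class:`GeneratorSpec`.
    """
    try:
        components = GENOTYPES[genotype]
    except KeyError:
        raise ValueError(
            f"unknown genotype {genotype!r}; expected one of {sorted(GENOTYPES)}"
        ) from None
    return GeneratorSpec(components=components, **overrides)
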