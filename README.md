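# multiexp

Decomposition of monotonically decaying kinetic curves into a sum of
positively weighted exponential components, with automatic selection of the
number of components.

The basic light reactions of photosynthetic macromolecules produce decays
that are multiexponential: the absorption recovery of purple-bacteria
reaction centers after the excitation light is switched off, or the decay of
chlorophyll fluorescence induction in leaves with blocked electron
transport. Each monoexponential component is read as one quasi-stationary
conformational state of the ensemble, so the model is

    A(t) = Σᵢ aᵢ·exp(-kᵢ·t),   aᵢ > 0,  kᵢ > 0,  n < 8,

and the scientific questions are *how many* components the curve contains
and what their weights `aᵢ` and rate constants (decrements) `kᵢ` are. This
package is for experimentalists with such curves sampled as two-column text
(time in seconds, amplitude in arbitrary units).

## Method in brief

For fixed decrements, the optimal weights are a linear solve: with the
discrete inner product `(x, y) = Σⱼ x(tⱼ)y(tⱼ)`, the Gram matrix
`G_ij = (φᵢ, φⱼ)` of the non-orthogonal basis `φᵢ(t) = exp(-kᵢt)` gives the
normal equations `G a = β`, `βᵢ = (x, φᵢ)`; equivalently, the weights are
projections onto the reciprocal basis `θⱼ = Σₖ (G⁻¹)ⱼₖ φₖ`. The weights are
therefore never searched. Decrements are optimized one at a time over a
discrete logarithmic candidate grid with all weights re-projected per
candidate; candidates giving any non-positive weight are rejected.
Components are added greedily, cyclically refined until the dispersion (mean
squared residual of the peak-normalized curve) stops changing, polished by
joint pair moves and multiscale local grids, and a new component is kept
only if it lowers the dispersion by more than 2% relative with all weights
positive. See `docs/methods.md` for the full account.

## Worked example

```python
from multiexp import ExponentialDecayModel
from multiexp.synthetic import generate_signal, table1_fixture

# a published three-component fluorescence decay (wheat genotype "Pdl"),
# 2001 samples on [0, 0.5] s, 0.5% additive Gaussian noise
signal = generate_signal(table1_fixture("Pdl", noise_sd=0.005, seed=7))
results = ExponentialDecayModel.from_signal(signal).fit(max_components=3)
print(results.summary())
```

prints

```
Multiexponential decay decomposition
================================================================
components: 3      observations: 2001
dispersion (normalized MSE): 2.67274e-05
peak amplitude (scale): 0.950006
----------------------------------------------------------------
comp         weight  weight %        k [1/s]      tau [s]
   1       0.595074      62.6         402.74     0.002483
   2       0.287474      30.2         85.588      0.01168
   3      0.0684249       7.2        10.9912      0.09098
----------------------------------------------------------------
stage trace (n, dispersion): (1, 0.00047), (2, 5.48e-05), (3, 2.67e-05)
```

The three generating rate constants (400, 87, 11 s⁻¹) are recovered within
0.7–1.6%, the dispersion ≈ 2.7e-5 matches the injected noise variance
(0.005² = 2.5e-5) plus estimation overhead, and the stage trace shows each
added component earning its keep. `results.save_parameters(path)` and
`results.save_approximation(path)` write the component table and the fitted
curve as plain text.

From the shell:

```sh
multiexp generate Pdl --noise-sd 0.005 --seed 7 -o pdl.txt
multiexp fit -i pdl.txt --max-components 3 --save-approx
```

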