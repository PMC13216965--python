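# mesomelt

Mesoscopic analysis of nucleic-acid duplex melting: estimate
hydrogen-bond and stacking interaction parameters from oligonucleotide
melting temperatures, and predict melting temperatures and base-pair
opening profiles, for DNA/DNA (DD), RNA/RNA (RR) and DNA/RNA hybrid
(DR) duplexes.

## Who this is for

Melting experiments measure one number per duplex, Tm, yet that number
is shaped by the sequence's hydrogen bonding and base stacking — and by
whatever perturbs them: salt, cosolutes, crowding, chemical
modification. `mesomelt` is for researchers who want to turn tables of
melting temperatures into *interaction parameters* with a physical
meaning: a Morse well depth `D` per base-pair class (how strong is this
hydrogen bond?) and a harmonic stacking constant `k` per
nearest-neighbour step (how stiff is this stack?). Comparing parameter
sets fitted under two buffer conditions then localizes the perturbation:
e.g. whether a crowding agent acts on the AU hydrogen bond or on
CG stacking.

## The model

Each base pair i carries a displacement `y_i` (nm) from its bonded
equilibrium. The configurational energy is

    H = Σ_i D_α (e^{-y_i/λ_α} - 1)²
      + Σ_i (k_β/2)(y_i² - 2 y_i y_{i-1} cos θ + y_{i-1}²)

with pair classes α (dAdT/dCdG for DD; rArU/rCrG for RR; dArU, dTrA,
dCrG, dGrC for hybrids) and canonical NN step classes β (10 for DD/RR
after the antiparallel dyad symmetry, 16 for hybrids). The classical
partition function is evaluated by the transfer-integral technique,
yielding per-site averages ⟨y_i⟩ (opening profiles, end fraying) and a
dimensionless melting index τ_s per sequence. Experimental temperatures
are mapped onto τ by a two-level linear regression,

    T'_s = a_0(N) + a_1(N) τ_s,    a_k(N) = b_{0,k} + b_{1,k} √N,

and parameters are fitted by minimizing χ² = Σ_s (T_s - T'_s)² with a
multi-start downhill simplex: hundreds of restarts sampled within ±20%
of a seed, averaged, re-seeded until the averages converge, with a final
temperature-perturbation round that converts the experimental
uncertainty (e.g. 0.7 °C) into parameter standard deviations, reported
in compact notation like 22(2) meV. See `docs/methods.md` for the full
account, including the identifiability conventions.

## Worked example

Fit parameters to a synthetic DD dataset whose ground truth is known
(16 duplexes of 8 and 12 bp, 0.5 °C noise):

```python
import numpy as np
from mesomelt import MeltingModel, OptimizationConfig, SyntheticSpec
from mesomelt.synthetic import (EXPERIMENT_GRID, DEFAULT_B_TRUE, example_parameters,
                                generate_duplexes, simulate_melting_table)

spec = SyntheticSpec(kind="DD", n_sequences=16, lengths=(8, 12), sigma=0.5, seed=1)
rng = np.random.default_rng(1)
duplexes = generate_duplexes(spec, rng)
records, _ = simulate_melting_table(duplexes, example_parameters("DD"),
                                    DEFAULT_B_TRUE, 0.5, rng, grid=EXPERIMENT_GRID)
config = OptimizationConfig(grid=EXPERIMENT_GRID, tau_tol=1e-3, n_starts=4,
                            n_rounds=2, simplex_maxfev=250, simplex_maxiter=250, seed=0)
res = MeltingModel(records, config=config).fit()
print(res.summary())
```

prints

```
Mesoscopic melting fit (DD)
===========================
records: 16   free parameters: 12   rounds: 2
chi^2 = 0.3502 °C²    <ΔT> = 0.126 °C    accepted starts (final round): 4/4
regression: T' = (b00 + b10·√N) + (b01 + b11·√N)·τ
  b00=-42.15  b10=-10.11  b01=112.6  b11=4.124

condition  type       label        value (compact SD)   unit
--------------------------------------------------------------
PEG        Morse D    dAdT         38(2)                meV
PEG        Morse D    dCdG         66(3)                meV
PEG        stack k    dAdT-dAdT    2.2(2)               eV/nm^2
...
```

⟨ΔT⟩ = 0.126 °C says the fitted map reproduces the 16 temperatures to
about a tenth of a degree; the Morse depths 38(2) and 66(3) meV recover
the generating values (32 and 70 meV) to within the scale convention
set by the generic seed, and the parenthesised digits are one standard
deviation over the accepted restarts. `res.fit_table()` lists per-
sequence τ, predicted Tm and residuals; `res.predict(duplex)` scores new
sequences; `res.opening_profile(duplex, T)` gives ⟨y_i⟩ at a model
temperature.

The same pipeline is available from the shell:

```
mesomelt simulate --kind DD --n 40 --sigma 0.5 --seed 1 --out melt.tsv --truth-out truth.par
mesomelt optimize --data melt.tsv --params seed.par --seed 1 --out run/
mesomelt profile --seq "d(CGCAAATTTGCG)" --T 210K --params run/fitted.par
mesomelt compare-params run/fitted.par truth.par
```

Every run directory contains a `manifest.json` with the resolved
configuration, input digests and RNG seed.

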