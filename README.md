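# sti1dyn

Single-molecule FRET and hydrodynamic analysis of chaperone–cochaperone
dynamics, built around the experiments used to dissect how the Hsp70/Hsp90
cochaperone Sti1 (Hop) moves between conformations as chaperones bind.

Sti1 is an elongated, flexible adaptor with two Hsp70-binding TPR domains;
chaperone binding switches it between low-, intermediate- and high-FRET
conformations on the 30 ms–second timescale. Quantifying that behaviour
needs four analyses that this library implements as reusable, tested
components, together with seeded generators for every input they consume:

- **Confocal burst analysis** — double-label (PIE) selection, burst-wise
  FRET efficiency histograms `E = I_A/(I_A + γI_D)`, and photon
  distribution analysis (PDA): the shot-noise-limited histogram expected
  from a Gaussian inter-dye distance population `N(R̄, σ_R)` is computed by
  averaging `Binomial(N, E(R))` acceptor fractions over the distance
  density and the burst-size distribution, with `E(R) = 1/(1+(R/R₀)⁶)`,
  and `(R̄, σ_R)` fit by least squares.
- **Efficiency–lifetime dynamics diagnostic** — bursts from static
  molecules fall on the static line `E = 1 − τ_D(A)/τ_D(0)`; molecules
  exchanging between two states within a burst follow
  `E = 1 − τ₁τ₂/(τ_D(0)(τ₁+τ₂−⟨τ⟩_f))` and shift right of the static
  line. A signed deviation score with its standard error quantifies this.
- **TIRF trace analysis** — change-point photobleach screening (traces
  with more than one downward step are discarded; analysis stops at the
  first bleach), then a global K-state Gaussian-emission hidden Markov
  model: Baum–Welch EM with emissions and the per-frame transition matrix
  `A` shared across all traces, multi-restart initialization, Viterbi
  decoding, transition-density plots, dynamic-fraction classification and
  rates `k_ij = A_ij/Δt`.
- **Hydrodynamics and binding** — time-derivative (dc/dt) transformation
  of sedimentation-velocity scans onto the apparent-s grid
  `s* = ln(r/r_m)/(ω²t)`, multi-Gaussian species decomposition (with
  known centers optionally fixed), Svedberg-equation utilities
  `s = M(1−v̄ρ)/(N_A f)` with `f = (f/f₀)·6πηr₀`, and Langmuir 1:1
  isotherm fits `R(c) = S_max c/(K_d + c)`.

No raw single-molecule or AUC data are publicly deposited for this system,
so every analysis is validated by parameter recovery on synthetic data
generated at the published parameter values (`sti1dyn.synthetic` +
`sti1dyn.studies`).

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/tirf_hmm_rates.py` simulates 40 camera traces from the
three-state Hsp70-bound kinetics (states 0.16/0.52/0.84, 30 ms frames)
and refits them globally:

```
state      mean E   width
low          0.160   0.076
intermediate 0.520   0.079
high         0.837   0.077

rates (1/s), Viterbi transition counts in parentheses:
  low  -> int :  1.29 (78)
  low  -> high:  3.77 (239)
  ...
  high -> low :  0.94 (156)
```

The state means match the generating efficiencies to ~0.01 and the
low→high/high→low rates recover the generating 4.5/1.0 s⁻¹ up to the
small first-order `k = A/Δt` discretization bias (see
`docs/methods.md`). Likewise `python examples/burst_pda.py` prints

```
3487 of 5000 bursts carry both dyes
PDA: mean distance 65.1 +/- 0.1 A, s.d. 5.0 +/- 0.1 A (reduced chi^2 0.96)
```

— the 5 Å conformational spread of the rigid TPR2A–TPR2B–DP2 module is
recovered after the binomial shot noise is deconvolved, and
`examples/dcdt_species.py` decomposes a simulated free-Hsp70 +
Hsp70–Sti1 mixture into its 4.2 S and 5.6 S species.

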