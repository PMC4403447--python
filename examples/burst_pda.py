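"""Confocal burst analysis: selection, FRET histogram, PDA and E-tau diagnostic.

Simulates double-labelled molecules from a Gaussian inter-dye distance
population (65 +/- 5 A, E ~ 0.2 at R0 = 52 A) plus a donor-only
contamination, selects bursts carrying both dyes, fits the shot-noise
histogram by photon distribution analysis and checks for intra-burst
dynamics in the efficiency-lifetime plane. The fitted distance s.d.
reports the true conformational spread after shot noise is removed; the
deviation score is ~0 for the static population and strongly positive for
the dynamic two-state control.
"""

import numpy as np

from sti1dyn import burst, synthetic

bursts = synthetic.simulate_bursts(
    (65.0, 5.0), r0=52.0, n_bursts=5000, seed=0, donor_only_fraction=0.3
)
selected = burst.select_double_labelled(bursts)
print(f"{len(selected)} of {len(bursts)} bursts carry both dyes")

edges = np.linspace(0.0, 1.0, 52)
masses, _ = np.histogram(selected.efficiencies(), bins=edges)
hist = burst.EfficiencyHistogram(edges, masses / masses.sum() / np.diff(edges))
fit = burst.pda_fit(hist, selected.sizes(), r0=52.0, n_bursts=len(selected))
print(
    f"PDA: mean distance {fit.mean_r:.1f} +/- {fit.mean_r_stderr:.1f} A, "
    f"s.d. {fit.sigma_r:.1f} +/- {fit.sigma_r_stderr:.1f} A "
    f"(reduced chi^2 {fit.red_chi2:.2f})"
)

d_static = burst.e_tau_diagnostic(selected)
print(
    f"static population: E-tau deviation {d_static.deviation:+.3f} ns "
    f"(s.e. {d_static.stderr:.3f}) -> on the static line"
)

two_state = synthetic.StateModel(
    efficiencies=np.array([0.2, 0.8]),
    widths=np.full(2, 0.02),
    rate_matrix=np.array([[0.0, 3000.0], [3000.0, 0.0]]),
)
dynamic = synthetic.simulate_bursts(two_state, r0=52.0, n_bursts=3000, seed=1)
d_dyn = burst.e_tau_diagnostic(dynamic)
print(
    f"two-state exchange:  E-tau deviation {d_dyn.deviation:+.3f} ns "
    f"(s.e. {d_dyn.stderr:.3f}) -> right of the static line, i.e. dynamic"
)
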