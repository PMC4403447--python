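"""dc/dt sedimentation-velocity analysis of a chaperone complex mixture.

Simulates fluorescence-detected scans at 42,000 r.p.m. for free labelled
Hsp70 (4.2 S) mixed with its binary Sti1 complex (5.6 S), converts them to
a dc/dt profile on the apparent-s grid and decomposes it into bi-Gaussian
species with the free-species center fixed — the standard trick when the
free and complexed peaks overlap strongly. Prints the recovered centers
and the signal fraction bound.
"""

import numpy as np

from sti1dyn import auc, synthetic

omega = 42000 * 2 * np.pi / 60
radii = np.linspace(6.02, 7.2, 600)
times = np.linspace(8000, 11600, 10)

species = [
    synthetic.SpeciesSpec(s_value=4.2, diffusion=5.3e-7, plateau_conc=0.6),
    synthetic.SpeciesSpec(s_value=5.6, diffusion=3.9e-7, plateau_conc=0.4),
]
scans = synthetic.simulate_sedimentation(
    species, omega, meniscus=6.0, radii=radii, times=times, noise_sd=0.002, seed=0
)

profile = auc.dcdt_transform(scans)
print(f"dc/dt profile from {profile.n_pairs} scan pairs, "
      f"s* range {profile.s_star[0]:.1f}-{profile.s_star[-1]:.1f} S")

components = auc.fit_gaussian_components(
    profile, n_components=2, init=[4.2, 5.6], fix_centers={0: 4.2}
)
fractions = auc.species_populations(components)
for c, w, f in zip(components.centers, components.widths, fractions):
    print(f"  species at {c:.2f} S (width {w:.2f} S): {100 * f:.0f}% of signal")
print("the second center is the Hsp70-Sti1 binary complex; its fraction tracks")
print("how far the titration has shifted the binding equilibrium")
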