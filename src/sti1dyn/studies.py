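"""Parameter-recovery studies validating the pipeline end to end.

Each study generates synthetic data at the experimental conditions the
pipeline was built for — the three-state kinetics of the Sti1 linker
construct (G193C–G309C) in the presence of Hsp70, the single
Gaussian-distance population of the rigid TPR2A–TPR2B–DP2 module, and the
free-Hsp70 / Hsp70–Sti1 sedimenting species — runs the corresponding
analysis from scratch, and reports the recovered quantities next to the
ground truth. The studies double as acceptance checks: the same functions
back ``tests/test_acceptance.py`` and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import auc, burst, hmm, synthetic

__all__ = [
    "sti1_hsp70_state_model",
    "hmm_recovery_study",
    "pda_recovery_study",
    "dcdt_recovery_study",
]

# Three-state conformational kinetics of Sti1 G193C-G309C in the presence of
# Hsp70: low/intermediate/high FRET efficiencies and the six directed
# transition rates (1/s) between them. State order: low, intermediate, high.
STATE_EFFICIENCIES = (0.16, 0.52, 0.84)
TRANSITION_RATES = {
    ("low", "high"): 4.5,
    ("high", "low"): 1.0,
    ("low", "intermediate"): 1.5,
    ("intermediate", "low"): 1.5,
    ("intermediate", "high"): 0.9,
    ("high", "intermediate"): 1.5,
}

# Sedimentation coefficients observed by fluorescence-detected AUC:
# free labelled Hsp70 and its binary complex with Sti1.
FREE_HSP70_S = 4.2
BINARY_COMPLEX_S = 5.6

# Gaussian inter-dye distance population of the rigid C-terminal module:
# ~65 A mean separation (E ~ 0.2) with a 5 A standard deviation.
MODULE_MEAN_R = 65.0
MODULE_SIGMA_R = 5.0
DEFAULT_R0 = 52.0


def sti1_hsp70_state_model(emission_sd: float = 0.08) -> synthetic.StateModel:
    """Three-state model for the linker construct with Hsp70 bound."""
    order = ["low", "intermediate", "high"]
    k = len(order)
    q = np.zeros((k, k))
    for (a, b), rate in TRANSITION_RATES.items():
        q[order.index(a), order.index(b)] = rate
    return synthetic.StateModel(
        efficiencies=np.array(STATE_EFFICIENCIES),
        widths=np.full(k, emission_sd),
        rate_matrix=q,
    )


def hmm_recovery_study(
    seed: int = 1,
    n_traces: int = 100,
    n_frames: int = 400,
    frame_time: float = 0.03,
    emission_sd: float = 0.08,
    brightness: float = 5000.0,
    n_restarts: int = 10,
) -> dict:
    """Simulate TIRF traces from the Hsp70-bound kinetics and refit them.

    100 traces of 400 frames at 30 ms (40,000 usable frames) are generated
    from the published three-state efficiencies and rates with a 0.08
    emission s.d., read out through the EMCCD camera model, converted to
    per-frame efficiency, and fit with a global 3-state Gaussian HMM.
    Rates are recovered from the fitted per-frame transition matrix via
    k = A / frame_time; state switches are frame-synchronous
    (:func:`sti1dyn.synthetic.simulate_framewise_path`) so the fitted
    matrix is directly comparable to the generating rates — the published
    rates are themselves the output of a discrete-frame HMM analysis.
    """
    model = sti1_hsp70_state_model(emission_sd)
    rng = np.random.default_rng(seed)
    cfg = synthetic.SimConfig(
        frame_time=frame_time,
        n_frames=n_frames,
        brightness=brightness,
        background_d=20.0,
        background_a=20.0,
        gamma=1.0,
    )
    sequences = []
    for _ in range(n_traces):
        path = synthetic.simulate_framewise_path(model, n_frames, frame_time, seed=rng)
        trace = synthetic.simulate_tirf_trace(path, model, cfg, seed=rng)
        sequences.append(hmm.prepare_trace(trace, gamma=cfg.gamma, steps=[]))

    fit = hmm.fit_hmm_global(
        sequences,
        n_states=3,
        n_restarts=n_restarts,
        seed=int(rng.integers(2**31 - 1)),
    )
    paths = [hmm.viterbi_path(fit, s) for s in sequences]
    rates = hmm.rates_from_fit(fit, paths, frame_time)
    return {
        "fit": fit,
        "paths": paths,
        "rates": rates,
        "means": fit.means,
        "rate_low_high": float(rates.rates[0, 2]),
        "rate_high_low": float(rates.rates[2, 0]),
        "n_usable_frames": int(sum(len(s) for s in sequences)),
        "truth": {
            "means": np.array(STATE_EFFICIENCIES),
            "rate_low_high": TRANSITION_RATES[("low", "high")],
            "rate_high_low": TRANSITION_RATES[("high", "low")],
        },
    }


def pda_recovery_study(
    seed: int = 1,
    n_bursts: int = 5000,
    mean_r: float = MODULE_MEAN_R,
    sigma_r: float = MODULE_SIGMA_R,
    r0: float = DEFAULT_R0,
    burst_size_dist=(30, 150),
    n_bins: int = 51,
) -> dict:
    """Simulate confocal bursts from a Gaussian distance population and refit.

    5,000 bursts of 30-150 donor-excitation photons from a 65 +/- 5 A
    population (E ~ 0.2 at R0 = 52 A) are histogrammed in efficiency and
    fit by photon distribution analysis.
    """
    bursts = synthetic.simulate_bursts(
        (mean_r, sigma_r), r0, n_bursts, burst_size_dist=burst_size_dist, seed=seed
    )
    selected = burst.select_double_labelled(bursts)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    e = selected.efficiencies()
    masses, _ = np.histogram(e, bins=edges)
    hist = burst.EfficiencyHistogram(
        bin_edges=edges, density=masses / masses.sum() / np.diff(edges)
    )
    fitted = burst.pda_fit(hist, selected.sizes(), r0, n_bursts=len(selected))
    return {
        "fit": fitted,
        "mean_r": fitted.mean_r,
        "sigma_r": fitted.sigma_r,
        "truth": {"mean_r": mean_r, "sigma_r": sigma_r},
    }


def _diffusion_for(s_value: float, mass: float) -> float:
    """Svedberg-relation diffusion coefficient (cm^2/s) for an ideal species."""
    rt = 8.314e7 * 293.15  # erg/mol
    return s_value * auc.SVEDBERG * rt / (mass * (1.0 - auc.VBAR_PROTEIN * auc.WATER_DENSITY_20C))


def dcdt_recovery_study(
    seed: int = 1,
    rpm: float = 42000.0,
    meniscus: float = 6.0,
    noise_sd: float = 0.002,
) -> dict:
    """dc/dt species recovery for one species and a two-species mixture.

    Scans at 42,000 r.p.m. are simulated for free labelled Hsp70 (4.2 S)
    alone and for an equal-signal mixture with the 5.6 S binary
    Hsp70-Sti1 complex; the dc/dt transform plus Gaussian decomposition
    (mixture: first center fixed to the free-species value, as in the
    titration analysis) recovers the sedimentation coefficients.
    """
    omega = rpm * 2.0 * np.pi / 60.0
    radii = np.linspace(6.02, 7.2, 600)
    free = synthetic.SpeciesSpec(
        s_value=FREE_HSP70_S, diffusion=_diffusion_for(FREE_HSP70_S, 70e3), plateau_conc=1.0
    )
    complex_ = synthetic.SpeciesSpec(
        s_value=BINARY_COMPLEX_S, diffusion=_diffusion_for(BINARY_COMPLEX_S, 135e3), plateau_conc=1.0
    )

    # scans are taken while the boundary of interest crosses the middle of
    # the cell: the diffusional skew of g(s*) shrinks as the boundary
    # advances, so the free-species run uses a later window than the
    # mixture (whose faster 5.6 S boundary would otherwise leave the cell)
    times_single = np.linspace(12000.0, 15600.0, 10)
    times_mix = np.linspace(8000.0, 11600.0, 10)

    scans1 = synthetic.simulate_sedimentation(
        [free], omega, meniscus, radii, times_single, noise_sd=noise_sd, seed=seed
    )
    prof1 = auc.dcdt_transform(scans1)
    comp1 = auc.fit_gaussian_components(prof1, n_components=1)

    scans2 = synthetic.simulate_sedimentation(
        [free, complex_], omega, meniscus, radii, times_mix, noise_sd=noise_sd, seed=seed + 1
    )
    prof2 = auc.dcdt_transform(scans2)
    comp2 = auc.fit_gaussian_components(
        prof2, n_components=2, init=[FREE_HSP70_S, BINARY_COMPLEX_S], fix_centers={0: FREE_HSP70_S}
    )
    return {
        "single_center": float(comp1.centers[0]),
        "mixture_centers": comp2.centers,
        "mixture_second_center": float(comp2.centers[1]),
        "truth": {"single": FREE_HSP70_S, "mixture": (FREE_HSP70_S, BINARY_COMPLEX_S)},
        "profiles": (prof1, prof2),
    }
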