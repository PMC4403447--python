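"""Closed-form FRET relations shared by all analysis stages.

Pure functions: the Förster distance/efficiency conversion, the
intensity-based efficiency with detection (gamma) correction, and the
static and two-state dynamic efficiency-vs-donor-lifetime lines used to
diagnose conformational dynamics in burst data.

All functions accept scalars or numpy arrays and never touch global state.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "forster_efficiency",
    "distance_from_efficiency",
    "efficiency_from_intensities",
    "static_line",
    "dynamic_line",
]


def forster_efficiency(r, r0):
    """FRET efficiency for a donor-acceptor pair at distance ``r``.

    E = 1 / (1 + (r/r0)**6), with ``r0`` the Förster radius (the distance
    of half-maximal transfer). Both distances in the same unit (Å).
    """
    r = np.asarray(r, dtype=float)
    r0 = np.asarray(r0, dtype=float)
    if np.any(r <= 0) or np.any(r0 <= 0):
        raise ValueError("distances must be positive")
    out = 1.0 / (1.0 + (r / r0) ** 6)
    return float(out) if out.ndim == 0 else out


def distance_from_efficiency(e, r0):
    """Invert the Förster relation: distance at which efficiency is ``e``.

    Exact round-trip with :func:`forster_efficiency`; efficiencies of 0 or 1
    correspond to infinite / zero separation and are rejected.
    """
    e = np.asarray(e, dtype=float)
    r0 = np.asarray(r0, dtype=float)
    if np.any(r0 <= 0):
        raise ValueError("r0 must be positive")
    if np.any(e <= 0.0) or np.any(e >= 1.0):
        raise ValueError("efficiency must lie strictly in (0, 1)")
    out = r0 * ((1.0 - e) / e) ** (1.0 / 6.0)
    return float(out) if out.ndim == 0 else out


def efficiency_from_intensities(i_d, i_a, gamma=1.0):
    """Apparent FRET efficiency from donor/acceptor channel intensities.

    E = I_A / (I_A + gamma * I_D) where gamma corrects for the difference in
    detection efficiency and quantum yield between the two channels.
    The raw value is returned unclamped (background subtraction can push
    apparent E slightly outside [0, 1]; histograms keep that information).
    """
    i_d = np.asarray(i_d, dtype=float)
    i_a = np.asarray(i_a, dtype=float)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    total = i_a + gamma * i_d
    if np.any(total <= 0):
        raise ValueError("zero total signal: efficiency undefined")
    out = i_a / total
    return float(out) if out.ndim == 0 else out


def static_line(tau_da, tau_d0):
    """Efficiency of a conformationally static molecule at donor lifetime ``tau_da``.

    E = 1 - tau_da / tau_d0, the locus on which static populations fall in
    the efficiency-vs-lifetime plane. ``tau_d0`` is the donor-only lifetime.
    """
    tau_da = np.asarray(tau_da, dtype=float)
    if tau_d0 <= 0:
        raise ValueError("tau_d0 must be positive")
    out = 1.0 - tau_da / tau_d0
    return float(out) if out.ndim == 0 else out


def dynamic_line(tau1, tau2, tau_d0, tau_mean):
    """Efficiency-vs-lifetime locus for a molecule exchanging between two states.

    For intra-burst switching between conformations with donor lifetimes
    ``tau1`` and ``tau2``, the intensity-based efficiency as a function of the
    fluorescence-weighted mean donor lifetime ``tau_mean`` is

        E = 1 - tau1 * tau2 / (tau_d0 * (tau1 + tau2 - tau_mean))

    At ``tau_mean`` equal to either endpoint the curve meets the static line;
    strictly between the endpoints it lies to the right of it (larger lifetime
    at equal efficiency), the signature of dynamics.
    """
    tau_mean = np.asarray(tau_mean, dtype=float)
    if tau_d0 <= 0:
        raise ValueError("tau_d0 must be positive")
    if not (0 < tau1 <= tau_d0 and 0 < tau2 <= tau_d0):
        raise ValueError("state lifetimes must lie in (0, tau_d0]")
    lo, hi = min(tau1, tau2), max(tau1, tau2)
    if np.any(tau_mean < lo - 1e-12) or np.any(tau_mean > hi + 1e-12):
        raise ValueError("tau_mean must lie between the two state lifetimes")
    out = 1.0 - (tau1 * tau2) / (tau_d0 * (tau1 + tau2 - tau_mean))
    return float(out) if out.ndim == 0 else out
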