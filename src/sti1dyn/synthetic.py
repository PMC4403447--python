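"""Seeded generators for every input the analysis stages consume.

The generators emulate the statistical structure of the experiments:
continuous-time Markov switching among K FRET states (exact Gillespie
dwell sampling), EMCCD camera traces with Poisson shot noise, optional
Gaussian read noise and single-step photobleaching, confocal photon
bursts with binomial partition between detection channels and a
lifetime estimate whose error shrinks with donor counts, Faxén-type
error-function sedimentation boundaries, and Langmuir titration tables.

Every generator takes an integer seed (or a ``numpy`` Generator) and is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.special import erf

from .auc import SVEDBERG, SedimentationScan
from .burst import BurstSet
from .fret import forster_efficiency

__all__ = [
    "StateModel",
    "StatePath",
    "SimConfig",
    "SpeciesSpec",
    "FRETTrace",
    "simulate_state_path",
    "simulate_framewise_path",
    "simulate_tirf_trace",
    "simulate_bursts",
    "simulate_sedimentation",
    "simulate_titration",
    "write_trace",
    "read_trace",
    "write_scans",
    "read_scans",
    "write_bursts",
    "read_bursts",
]


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class StateModel:
    """K FRET states (mean efficiency, emission width) plus a rate matrix.

    ``rate_matrix`` holds off-diagonal transition rates in 1/s; the
    diagonal is defined as the negative row sum and is filled in on
    construction.
    """

    efficiencies: np.ndarray
    widths: np.ndarray
    rate_matrix: np.ndarray

    def __post_init__(self):
        self.efficiencies = np.atleast_1d(np.asarray(self.efficiencies, dtype=float))
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        q = np.array(self.rate_matrix, dtype=float)
        k = len(self.efficiencies)
        if k < 1:
            raise ValueError("model needs at least one state")
        if q.shape != (k, k):
            raise ValueError("rate matrix shape must match the number of states")
        if np.any(self.efficiencies < 0) or np.any(self.efficiencies > 1):
            raise ValueError("efficiencies must lie in [0, 1]")
        if np.any(self.widths <= 0):
            raise ValueError("widths must be positive")
        off = q[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        self.rate_matrix = q

    @property
    def n_states(self) -> int:
        return len(self.efficiencies)

    def exit_rates(self) -> np.ndarray:
        return -np.diag(self.rate_matrix)

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the continuous-time chain (uniform if frozen)."""
        q = self.rate_matrix
        k = self.n_states
        if np.allclose(q, 0.0):
            return np.full(k, 1.0 / k)
        a = np.vstack([q.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()


@dataclass
class StatePath:
    """Latent continuous-time trajectory: dwell states and switch times."""

    switch_times: np.ndarray  # s, strictly increasing, one fewer than states
    states: np.ndarray  # state index per dwell
    duration: float  # s

    def __post_init__(self):
        self.switch_times = np.asarray(self.switch_times, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        if len(self.states) != len(self.switch_times) + 1:
            raise ValueError("need exactly one more dwell than switch")
        if len(self.switch_times) and (
            np.any(np.diff(self.switch_times) <= 0)
            or self.switch_times[0] <= 0
            or self.switch_times[-1] >= self.duration
        ):
            raise ValueError("switch times must be strictly increasing within (0, duration)")
        if np.any(self.states[1:] == self.states[:-1]):
            raise ValueError("consecutive dwell states must differ")

    @property
    def n_switches(self) -> int:
        return len(self.switch_times)

    def dwell_times(self) -> np.ndarray:
        bounds = np.concatenate([[0.0], self.switch_times, [self.duration]])
        return np.diff(bounds)

    def occupancy(self, frame_time: float, n_frames: int, n_states: int | None = None) -> np.ndarray:
        """(n_frames, K) fraction of each frame spent in each state."""
        k = int(self.states.max()) + 1 if n_states is None else int(n_states)
        occ = np.zeros((n_frames, k))
        bounds = np.concatenate([[0.0], self.switch_times, [self.duration]])
        for s, t0, t1 in zip(self.states, bounds[:-1], bounds[1:]):
            f0 = int(np.floor(t0 / frame_time))
            f1 = min(int(np.ceil(t1 / frame_time)), n_frames)
            if f0 >= n_frames:
                break
            frames = np.arange(f0, f1)
            lo = np.maximum(frames * frame_time, t0)
            hi = np.minimum((frames + 1) * frame_time, t1)
            occ[frames, s] += np.maximum(hi - lo, 0.0) / frame_time
        return occ


@dataclass
class SimConfig:
    """Camera and photophysics settings for TIRF trace simulation.

    Defaults reflect a typical prism-type TIRF/EMCCD experiment at 30 ms
    frames; all values are configurable.
    """

    seed: int = 0
    frame_time: float = 0.03  # s
    n_frames: int = 200
    brightness: float = 2000.0  # expected total photons per frame
    background_d: float = 20.0  # mean background counts/frame, donor channel
    background_a: float = 20.0
    gamma: float = 1.0  # detection correction factor
    bleach_rate_d: float = 0.0  # 1/s
    bleach_rate_a: float = 0.0
    read_noise: float = 0.0  # Gaussian read noise s.d., counts

    def __post_init__(self):
        if self.frame_time <= 0 or self.brightness <= 0 or self.gamma <= 0:
            raise ValueError("frame_time, brightness and gamma must be positive")
        if self.bleach_rate_d < 0 or self.bleach_rate_a < 0:
            raise ValueError("bleach rates must be non-negative")


@dataclass
class SpeciesSpec:
    """One ideal sedimenting species."""

    s_value: float  # Svedberg
    diffusion: float  # cm^2/s
    plateau_conc: float  # signal units

    def __post_init__(self):
        if self.s_value <= 0:
            raise ValueError("s_value must be positive")
        if self.diffusion < 0 or self.plateau_conc < 0:
            raise ValueError("diffusion and plateau_conc must be non-negative")


@dataclass
class FRETTrace:
    """Uniformly sampled donor/acceptor camera intensities."""

    time: np.ndarray  # s, frame start times
    donor: np.ndarray  # counts per frame
    acceptor: np.ndarray
    frame_time: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.time) == len(self.donor) == len(self.acceptor)):
            raise ValueError("time, donor and acceptor must have equal length")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")


# ---------------------------------------------------------------------------
# continuous-time Markov paths


def simulate_state_path(model: StateModel, duration: float, seed=0) -> StatePath:
    """Exact (Gillespie) trajectory of the continuous-time FRET state chain.

    Dwells are sampled from the exponential with the state's exit rate and
    the successor from the embedded jump chain; the initial state is drawn
    from the stationary distribution.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed)
    k = model.n_states
    exit_rates = model.exit_rates()
    state = int(rng.choice(k, p=model.stationary()))
    t = 0.0
    states = [state]
    switches = []
    while True:
        rate = exit_rates[state]
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        row = model.rate_matrix[state].copy()
        row[state] = 0.0
        state = int(rng.choice(k, p=row / row.sum()))
        switches.append(t)
        states.append(state)
    return StatePath(switch_times=np.array(switches), states=np.array(states), duration=duration)


def simulate_framewise_path(
    model: StateModel, n_frames: int, frame_time: float, seed=0
) -> StatePath:
    """Frame-synchronous trajectory from the exact discrete-time chain.

    States are sampled at frame resolution from the one-frame transition
    matrix expm(Q * frame_time), so every switch falls on a frame
    boundary. This is the generative model of the discrete-frame HMM
    itself; use it for parameter-recovery studies where the fitted
    per-frame transition matrix should be directly comparable to the
    generating rates (see the methods note on intra-frame averaging bias).
    """
    if n_frames < 1 or frame_time <= 0:
        raise ValueError("n_frames must be >= 1 and frame_time positive")
    rng = _rng(seed)
    k = model.n_states
    a = expm(model.rate_matrix * frame_time)
    states = np.empty(n_frames, dtype=int)
    states[0] = rng.choice(k, p=model.stationary())
    u = rng.random(n_frames)
    cum = np.cumsum(a, axis=1)
    for t in range(1, n_frames):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    # compress runs into dwells
    chg = np.nonzero(np.diff(states) != 0)[0]
    dwell_states = states[np.concatenate([[0], chg + 1])]
    switch_times = (chg + 1) * frame_time
    return StatePath(
        switch_times=switch_times, states=dwell_states, duration=n_frames * frame_time
    )


# ---------------------------------------------------------------------------
# TIRF camera traces


def simulate_tirf_trace(path: StatePath, model: StateModel, cfg: SimConfig, seed=None) -> FRETTrace:
    """EMCCD camera trace of one immobilized molecule.

    Per frame the occupancy-weighted mean efficiency is perturbed by the
    occupancy-weighted state emission width (conformational noise within a
    state), split between acceptor (brightness*E) and donor
    (brightness*(1-E)/gamma) channels, and read out with Poisson shot
    noise, channel background and optional Gaussian read noise.
    Single-step photobleaching times are drawn per fluorophore; donor
    bleach silences both channels, acceptor bleach reroutes the transfer
    back into the donor channel.
    """
    if path.duration < cfg.n_frames * cfg.frame_time - 1e-12:
        raise ValueError("state path shorter than the requested trace")
    rng = _rng(cfg.seed if seed is None else seed)
    n = cfg.n_frames
    occ = path.occupancy(cfg.frame_time, n, n_states=model.n_states)
    e_bar = occ @ model.efficiencies
    width = np.sqrt(occ @ model.widths**2)
    e_frame = np.clip(rng.normal(e_bar, width), 0.0, 1.0)

    t_bleach_d = rng.exponential(1.0 / cfg.bleach_rate_d) if cfg.bleach_rate_d > 0 else np.inf
    t_bleach_a = rng.exponential(1.0 / cfg.bleach_rate_a) if cfg.bleach_rate_a > 0 else np.inf
    starts = np.arange(n) * cfg.frame_time
    # fraction of each frame during which the fluorophore is still emitting
    alive_d = np.clip((t_bleach_d - starts) / cfg.frame_time, 0.0, 1.0)
    alive_a = np.clip((t_bleach_a - starts) / cfg.frame_time, 0.0, 1.0)

    # while both dyes are alive, FRET operates; after acceptor bleach the
    # donor recovers its full emission; after donor bleach both are dark
    both = np.minimum(alive_d, alive_a)
    donor_only = np.clip(alive_d - both, 0.0, 1.0)
    mean_a = cfg.brightness * e_frame * both + cfg.background_a
    mean_d = (
        cfg.brightness / cfg.gamma * ((1.0 - e_frame) * both + donor_only)
        + cfg.background_d
    )
    donor = rng.poisson(mean_d).astype(float)
    acceptor = rng.poisson(mean_a).astype(float)
    if cfg.read_noise > 0:
        donor += rng.normal(0.0, cfg.read_noise, size=n)
        acceptor += rng.normal(0.0, cfg.read_noise, size=n)

    first_bleach = min(t_bleach_d, t_bleach_a)
    meta = {
        "true_e": e_bar,
        "bleach_frame_d": int(t_bleach_d / cfg.frame_time) if np.isfinite(t_bleach_d) else None,
        "bleach_frame_a": int(t_bleach_a / cfg.frame_time) if np.isfinite(t_bleach_a) else None,
        "first_bleach_frame": int(first_bleach / cfg.frame_time)
        if np.isfinite(first_bleach)
        else None,
    }
    return FRETTrace(time=starts, donor=donor, acceptor=acceptor, frame_time=cfg.frame_time, meta=meta)


# ---------------------------------------------------------------------------
# confocal bursts


def _burst_sizes(burst_size_dist, n, rng):
    if callable(burst_size_dist):
        return np.asarray(burst_size_dist(rng, n), dtype=int)
    if isinstance(burst_size_dist, tuple) and len(burst_size_dist) == 2:
        lo, hi = burst_size_dist
        return rng.integers(lo, hi + 1, size=n)
    sizes = np.asarray(burst_size_dist, dtype=int)
    return rng.choice(sizes, size=n, replace=True)


def simulate_bursts(
    distance_model,
    r0: float,
    n_bursts: int,
    burst_size_dist=(30, 150),
    lifetime_d0: float = 4.0,
    seed=0,
    donor_only_fraction: float = 0.0,
    burst_duration: float = 1e-3,
    aa_brightness_ratio: float = 1.0,
    gamma: float = 1.0,
) -> BurstSet:
    """Simulate a confocal burst set from a distance or state model.

    ``distance_model`` is either a ``(mean_r, sigma_r)`` Gaussian distance
    population (Å) or a :class:`StateModel`, in which case each burst
    carries a continuous-time state trajectory of length
    ``burst_duration`` and the intensity-weighted efficiency / the
    fluorescence-weighted mean donor lifetime follow from its occupancies
    (the source of the rightward shift on the dynamic line).

    Per burst: total donor-excitation photons N from ``burst_size_dist``
    (a (lo, hi) uniform tuple, an array of sizes, or a callable),
    acceptor counts ~ Binomial(N, E), acceptor-excitation counts ~
    Poisson(aa_brightness_ratio * N) for double-labelled molecules, and a
    lifetime estimate with s.d. tau/sqrt(n_donor_photons). A
    ``donor_only_fraction`` of molecules lack the acceptor entirely.
    """
    if r0 <= 0 or n_bursts < 1:
        raise ValueError("r0 must be positive and n_bursts >= 1")
    rng = _rng(seed)
    n = int(n_bursts)
    sizes = _burst_sizes(burst_size_dist, n, rng)
    is_double = rng.random(n) >= donor_only_fraction

    if isinstance(distance_model, StateModel):
        model = distance_model
        e_int = np.empty(n)
        tau_true = np.empty(n)
        eff = model.efficiencies
        for i in range(n):
            p = simulate_state_path(model, burst_duration, rng)
            occ = p.occupancy(burst_duration, 1, n_states=model.n_states)[0]
            e_int[i] = occ @ eff
            donor_w = occ * (1.0 - eff)
            if donor_w.sum() > 0:
                tau_true[i] = lifetime_d0 * (donor_w @ (1.0 - eff)) / donor_w.sum()
            else:
                tau_true[i] = 0.0
        true_r = np.full(n, np.nan)
    else:
        mean_r, sigma_r = distance_model
        if sigma_r < 0:
            raise ValueError("sigma_r must be non-negative")
        true_r = rng.normal(mean_r, sigma_r, size=n) if sigma_r > 0 else np.full(n, float(mean_r))
        true_r = np.clip(true_r, 1e-6, None)
        e_int = forster_efficiency(true_r, r0)
        tau_true = lifetime_d0 * (1.0 - e_int)

    e_burst = np.where(is_double, e_int, 0.0)
    n_da = rng.binomial(sizes, e_burst)
    n_dd = sizes - n_da
    lam_aa = np.where(is_double, aa_brightness_ratio * sizes, 0.0)
    n_aa = rng.poisson(lam_aa)
    tau_noise_sd = np.where(is_double, tau_true, lifetime_d0) / np.sqrt(np.maximum(n_dd, 1))
    tau_est = np.maximum(
        np.where(is_double, tau_true, lifetime_d0) + rng.normal(0.0, 1.0, size=n) * tau_noise_sd,
        0.0,
    )

    return BurstSet(
        n_dd=n_dd,
        n_da=n_da,
        n_aa=n_aa,
        tau_da=tau_est,
        gamma=gamma,
        tau_d0=lifetime_d0,
        r0=r0,
        meta={"is_double": is_double, "true_e": e_int, "true_r": true_r, "true_tau": tau_true},
    )


# ---------------------------------------------------------------------------
# sedimentation-velocity scans


def simulate_sedimentation(
    species,
    omega: float,
    meniscus: float,
    radii,
    times,
    radial_dilution: bool = False,
    noise_sd: float = 0.0,
    seed=0,
) -> list[SedimentationScan]:
    """Faxén-type error-function boundaries for a list of ideal species.

    Each species contributes ``plateau/2 * (1 + erf((r - r_b)/sqrt(4 D t)))``
    with the boundary midpoint at r_b(t) = meniscus * exp(omega^2 s t);
    ``radial_dilution`` additionally applies the exp(-2 omega^2 s t) plateau
    decay. Species contributions sum; an empty list yields zero scans.
    """
    radii = np.asarray(radii, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    if np.any(radii <= meniscus):
        raise ValueError("all radii must lie beyond the meniscus")
    rng = _rng(seed)
    scans = []
    for t in times:
        conc = np.zeros_like(radii)
        for sp in species:
            s_sec = sp.s_value * SVEDBERG
            r_b = meniscus * np.exp(omega**2 * s_sec * t)
            if sp.diffusion > 0:
                shape = 0.5 * (1.0 + erf((radii - r_b) / np.sqrt(4.0 * sp.diffusion * t)))
            else:
                shape = (radii >= r_b).astype(float)
            scale = sp.plateau_conc
            if radial_dilution:
                scale = scale * np.exp(-2.0 * omega**2 * s_sec * t)
            conc += scale * shape
        if noise_sd > 0:
            conc = conc + rng.normal(0.0, noise_sd, size=len(radii))
        scans.append(
            SedimentationScan(radius=radii.copy(), conc=conc, time=float(t), omega=omega, meniscus=meniscus)
        )
    return scans


# ---------------------------------------------------------------------------
# titrations


def simulate_titration(kd: float, smax: float, concentrations, noise_sd: float = 0.0, seed=0) -> pd.DataFrame:
    """Langmuir 1:1 titration table: response = smax*c/(kd + c) + noise."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    rng = _rng(seed)
    resp = smax * c / (kd + c)
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, size=len(c))
    return pd.DataFrame({"concentration": c, "response": resp})


# ---------------------------------------------------------------------------
# text IO (delimited formats shared with the analysis stages)


def write_trace(trace: FRETTrace, path) -> None:
    df = pd.DataFrame(
        {
            "frame_index": np.arange(len(trace.donor)),
            "time_s": trace.time,
            "donor_counts": trace.donor,
            "acceptor_counts": trace.acceptor,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_trace(path, frame_time: float | None = None) -> FRETTrace:
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy()
    if frame_time is None:
        frame_time = float(np.median(np.diff(t))) if len(t) > 1 else 0.03
    return FRETTrace(
        time=t,
        donor=df["donor_counts"].to_numpy(float),
        acceptor=df["acceptor_counts"].to_numpy(float),
        frame_time=frame_time,
    )


def write_scans(scans, path) -> None:
    data = {"radius_cm": scans[0].radius}
    for sc in scans:
        data[f"{sc.time:.6g}"] = sc.conc
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_scans(path, omega: float, meniscus: float) -> list:
    df = pd.read_csv(path, sep="\t")
    radius = df["radius_cm"].to_numpy(float)
    scans = []
    for col in df.columns[1:]:
        scans.append(
            SedimentationScan(
                radius=radius, conc=df[col].to_numpy(float), time=float(col), omega=omega, meniscus=meniscus
            )
        )
    return scans


def write_bursts(bursts: BurstSet, path) -> None:
    pd.DataFrame(
        {
            "n_dd": bursts.n_dd,
            "n_da": bursts.n_da,
            "n_aa": bursts.n_aa,
            "tau_da_ns": bursts.tau_da,
        }
    ).to_csv(path, sep="\t", index=False)


def read_bursts(path, gamma: float = 1.0, tau_d0: float = 4.0, r0: float = 52.0) -> BurstSet:
    df = pd.read_csv(path, sep="\t")
    return BurstSet(
        n_dd=df["n_dd"].to_numpy(float),
        n_da=df["n_da"].to_numpy(float),
        n_aa=df["n_aa"].to_numpy(float),
        tau_da=df["tau_da_ns"].to_numpy(float),
        gamma=gamma,
        tau_d0=tau_d0,
        r0=r0,
    )
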