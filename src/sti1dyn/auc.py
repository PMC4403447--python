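"""Hydrodynamics and binding: dc/dt sedimentation analysis and isotherm fits.

Sedimentation-velocity scans are converted to time-derivative (dc/dt)
profiles on an apparent-sedimentation-coefficient grid and decomposed into
Gaussian species components, following the Stafford approach of averaging
scan-pair differences. Closed-form Svedberg-equation utilities relate
sedimentation coefficient, mass and frictional ratio, and a Langmuir 1:1
isotherm fit extracts dissociation constants from titration tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

__all__ = [
    "SedimentationScan",
    "DcDtProfile",
    "GaussianComponents",
    "HydroParams",
    "BindingFit",
    "dcdt_transform",
    "fit_gaussian_components",
    "species_populations",
    "svedberg",
    "langmuir_fit",
]

AVOGADRO = 6.02214076e23  # 1/mol
SVEDBERG = 1e-13  # s

# water at 20 degC; Methods-standard defaults, configurable per call
WATER_DENSITY_20C = 0.99823  # g/cm^3
WATER_VISCOSITY_20C = 0.010016  # poise (g cm^-1 s^-1)
VBAR_PROTEIN = 0.73  # cm^3/g


@dataclass
class SedimentationScan:
    """One radial absorbance/fluorescence scan at a given time since speed."""

    radius: np.ndarray  # cm, strictly increasing
    conc: np.ndarray  # signal units
    time: float  # s since reaching speed
    omega: float  # rad/s
    meniscus: float  # cm

    def __post_init__(self):
        self.radius = np.asarray(self.radius, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if np.any(np.diff(self.radius) <= 0):
            raise ValueError("radius grid must be strictly increasing")
        if self.time <= 0 or self.omega <= 0:
            raise ValueError("time and omega must be positive")


@dataclass
class DcDtProfile:
    s_star: np.ndarray  # apparent sedimentation coefficient, Svedberg
    dcdt: np.ndarray  # signal per second
    n_pairs: int


@dataclass
class GaussianComponents:
    centers: np.ndarray  # Svedberg
    amplitudes: np.ndarray  # signal/s
    widths: np.ndarray  # Svedberg
    stderr: np.ndarray | None = None  # per-parameter fit s.e., flattened
    residual_se: float = float("nan")

    @property
    def n_components(self) -> int:
        return len(self.centers)


@dataclass
class HydroParams:
    """Svedberg-equation parameter set; exactly one of s/mass/f_ratio may be solved for."""

    mass: float  # Da (g/mol)
    vbar: float = VBAR_PROTEIN
    density: float = WATER_DENSITY_20C
    viscosity: float = WATER_VISCOSITY_20C
    s_value: float = float("nan")  # Svedberg
    f_ratio: float = float("nan")


@dataclass
class BindingFit:
    kd: float  # M
    smax: float  # response units
    kd_stderr: float
    smax_stderr: float


# ---------------------------------------------------------------------------
# dc/dt


def dcdt_transform(scans, stride: int = 1, n_grid: int = 200) -> DcDtProfile:
    """Time-derivative transform of a series of sedimentation scans.

    For each scan pair separated by ``stride``, the per-radius finite
    difference is mapped to the apparent sedimentation coefficient
    s* = ln(r/meniscus)/(omega^2 * t_mean), then all pairs are
    interpolated onto a common s* grid and averaged. The sign convention
    is -(c2 - c1)/(t2 - t1): concentration at fixed radius falls as a
    boundary passes, so each species appears as a positive peak at its
    sedimentation coefficient. Peak areas on the s* grid scale as
    plateau * s / t_mean; :func:`species_populations` divides by the
    fitted center to turn areas into signal fractions.
    """
    scans = list(scans)
    if len(scans) < 2:
        raise ValueError("need at least two scans")
    r = scans[0].radius
    for sc in scans[1:]:
        if len(sc.radius) != len(r) or not np.allclose(sc.radius, r):
            raise ValueError("scans must share a common radius grid")
    times = np.array([sc.time for sc in scans])
    if np.any(np.diff(times) < 0):
        raise ValueError("scan times must be increasing")
    if np.any(np.diff(times) == 0):
        raise ZeroDivisionError("identical scan times")
    omega = scans[0].omega
    meniscus = scans[0].meniscus
    valid = r > meniscus
    rr = r[valid]

    pair_s, pair_d = [], []
    for i in range(len(scans) - stride):
        a, b = scans[i], scans[i + stride]
        dc = -(b.conc[valid] - a.conc[valid]) / (b.time - a.time)
        tbar = 0.5 * (a.time + b.time)
        s_star = np.log(rr / meniscus) / (omega**2 * tbar) / SVEDBERG
        pair_s.append(s_star)
        pair_d.append(dc)

    lo = max(s[0] for s in pair_s)
    hi = min(s[-1] for s in pair_s)
    grid = np.linspace(lo, hi, n_grid)
    stacked = np.vstack([np.interp(grid, s, d) for s, d in zip(pair_s, pair_d)])
    return DcDtProfile(s_star=grid, dcdt=stacked.mean(axis=0), n_pairs=len(pair_s))


def _gauss_sum(s, *params):
    out = np.zeros_like(s)
    for c, a, w in zip(params[0::3], params[1::3], params[2::3]):
        out = out + a * np.exp(-0.5 * ((s - c) / w) ** 2)
    return out


def fit_gaussian_components(
    profile: DcDtProfile,
    n_components: int = 2,
    init=None,
    fix_centers=None,
) -> GaussianComponents:
    """Least-squares decomposition of a dc/dt profile into Gaussian species.

    ``init`` may supply starting centers; otherwise peaks of the profile
    (supplemented by quantile spread) seed the fit. ``fix_centers`` is a
    dict {component index: s value} pinning known species (e.g. the free
    protein) while the remaining parameters float — the standard trick when
    free and complexed species overlap strongly.
    """
    s = np.asarray(profile.s_star, dtype=float)
    y = np.asarray(profile.dcdt, dtype=float)
    if len(s) < 20:
        raise ValueError("profile too coarse: need >= 20 grid points")
    fix_centers = dict(fix_centers or {})

    if init is not None:
        centers0 = np.asarray(init, dtype=float)
    else:
        peaks, _ = find_peaks(y, height=0.1 * y.max())
        centers0 = s[peaks][np.argsort(y[peaks])[::-1]][:n_components]
        if len(centers0) < n_components:
            extra = np.quantile(s, np.linspace(0.3, 0.7, n_components))
            centers0 = np.concatenate([centers0, extra])[:n_components]
        centers0 = np.sort(centers0)
    span = s[-1] - s[0]
    amp0 = np.full(n_components, y.max())
    wid0 = np.full(n_components, span / (4.0 * n_components))

    free_idx = [i for i in range(n_components) if i not in fix_centers]

    def model(ss, *theta):
        params = []
        j = 0
        for i in range(n_components):
            if i in fix_centers:
                c = fix_centers[i]
                a, w = theta[j], theta[j + 1]
                j += 2
            else:
                c, a, w = theta[j], theta[j + 1], theta[j + 2]
                j += 3
            params.extend([c, a, w])
        return _gauss_sum(ss, *params)

    p0, lower, upper = [], [], []
    for i in range(n_components):
        if i not in fix_centers:
            p0.append(centers0[i])
            lower.append(s[0])
            upper.append(s[-1])
        p0.extend([amp0[i], wid0[i]])
        lower.extend([0.0, 1e-6 * span])
        upper.extend([np.inf, span])

    try:
        popt, pcov = curve_fit(model, s, y, p0=p0, bounds=(lower, upper), maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(
            f"Gaussian decomposition failed to converge (init centers {centers0})"
        ) from err

    centers, amps, widths, perr = [], [], [], []
    errs = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    j = 0
    for i in range(n_components):
        if i in fix_centers:
            centers.append(fix_centers[i])
            amps.append(popt[j])
            widths.append(popt[j + 1])
            perr.extend([0.0, errs[j], errs[j + 1]])
            j += 2
        else:
            centers.append(popt[j])
            amps.append(popt[j + 1])
            widths.append(popt[j + 2])
            perr.extend(errs[j : j + 3])
            j += 3
    order = np.argsort(centers)
    resid = y - model(s, *popt)
    dof = max(len(s) - len(popt), 1)
    comp = GaussianComponents(
        centers=np.asarray(centers)[order],
        amplitudes=np.asarray(amps)[order],
        widths=np.asarray(widths)[order],
        stderr=np.asarray(perr),
        residual_se=float(np.sqrt(np.sum(resid**2) / dof)),
    )
    if len(free_idx) < n_components and not np.all(np.diff(order) > 0):
        warnings.warn("component ordering changed after sorting by center", RuntimeWarning)
    return comp


def species_populations(components: GaussianComponents, weight_by_center: bool = True) -> np.ndarray:
    """Relative signal fraction per species.

    Gaussian area = amp*width*sqrt(2*pi). On the raw dc/dt profile a
    boundary's area scales as plateau * s / t_mean, so by default each
    area is divided by its center s value before normalizing (the common
    t_mean cancels); without this weight faster species are over-counted.
    ``weight_by_center=False`` returns plain area ratios.
    """
    areas = components.amplitudes * components.widths * np.sqrt(2.0 * np.pi)
    if weight_by_center:
        areas = areas / components.centers
    total = areas.sum()
    if total <= 0:
        raise ValueError("total component area is zero: fractions undefined")
    return areas / total


# ---------------------------------------------------------------------------
# Svedberg relations


def _sphere_radius(mass, vbar):
    """Radius (cm) of the anhydrous smooth sphere of equal mass and density."""
    return (3.0 * mass * vbar / (4.0 * np.pi * AVOGADRO)) ** (1.0 / 3.0)


def svedberg(params: HydroParams, solve_for: str) -> HydroParams:
    """Complete a Svedberg-equation parameter set for one unknown.

    s = M (1 - vbar*rho) / (N_A * f) with f = f_ratio * 6*pi*eta*r0 and
    r0 the equal-mass smooth-sphere radius. ``solve_for`` is one of
    's_value', 'f_ratio' or 'mass' (the latter uses s ~ M^(2/3) closed form).
    """
    buoy = 1.0 - params.vbar * params.density
    if buoy <= 0:
        raise ValueError("(1 - vbar*rho) <= 0: particle floats, no sedimentation")
    eta = params.viscosity
    if solve_for == "s_value":
        r0 = _sphere_radius(params.mass, params.vbar)
        f = params.f_ratio * 6.0 * np.pi * eta * r0
        s = params.mass * buoy / (AVOGADRO * f)
        return HydroParams(
            mass=params.mass, vbar=params.vbar, density=params.density,
            viscosity=params.viscosity, s_value=s / SVEDBERG, f_ratio=params.f_ratio,
        )
    if solve_for == "f_ratio":
        r0 = _sphere_radius(params.mass, params.vbar)
        f = params.mass * buoy / (AVOGADRO * params.s_value * SVEDBERG)
        return HydroParams(
            mass=params.mass, vbar=params.vbar, density=params.density,
            viscosity=params.viscosity, s_value=params.s_value,
            f_ratio=f / (6.0 * np.pi * eta * r0),
        )
    if solve_for == "mass":
        # s = M^(2/3) * buoy / (N_A f_ratio 6 pi eta (3 vbar / (4 pi N_A))^(1/3))
        k = buoy / (
            AVOGADRO
            * params.f_ratio
            * 6.0
            * np.pi
            * eta
            * (3.0 * params.vbar / (4.0 * np.pi * AVOGADRO)) ** (1.0 / 3.0)
        )
        mass = (params.s_value * SVEDBERG / k) ** 1.5
        return HydroParams(
            mass=mass, vbar=params.vbar, density=params.density,
            viscosity=params.viscosity, s_value=params.s_value, f_ratio=params.f_ratio,
        )
    raise ValueError("solve_for must be 's_value', 'f_ratio' or 'mass'")


# ---------------------------------------------------------------------------
# Langmuir isotherm


def langmuir_fit(concentrations, responses) -> BindingFit:
    """Fit a 1:1 Langmuir isotherm R(c) = smax * c / (kd + c) to a titration.

    Standard errors come from the fit covariance. A warning is raised when
    the titration does not reach half-saturation (kd poorly constrained).
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(c) < 4:
        raise ValueError("need at least 4 titration points")
    smax0 = r.max() if r.max() > 0 else 1.0
    half = 0.5 * smax0
    kd0 = c[np.argmin(np.abs(r - half))]
    kd0 = kd0 if kd0 > 0 else max(c[c > 0].min(), 1e-12)

    def model(cc, kd, smax):
        return smax * cc / (kd + cc)

    popt, pcov = curve_fit(
        model, c, r, p0=[kd0, smax0], bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000
    )
    kd, smax = popt
    errs = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    if c.max() < 0.5 * kd:
        warnings.warn(
            "titration stops far below kd: binding parameters poorly constrained",
            RuntimeWarning,
            stacklevel=2,
        )
    return BindingFit(kd=float(kd), smax=float(smax), kd_stderr=float(errs[0]), smax_stderr=float(errs[1]))
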