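"""TIRF trace analysis: bleach filtering and global Gaussian-emission HMM.

Camera traces of immobilized molecules are screened for single-step
photobleaching, converted to per-frame apparent FRET efficiency, and fit
with a K-state hidden Markov model whose emission and transition
parameters are shared across all traces (a global fit). Viterbi decoding
then yields per-trace state paths, from which transition-density plots,
first-order transition rates and the fraction of dynamic molecules are
derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .fret import efficiency_from_intensities

__all__ = [
    "BleachStep",
    "HMMFit",
    "ViterbiResult",
    "TransitionDensity",
    "RateTable",
    "detect_bleach_steps",
    "prepare_trace",
    "fit_hmm_global",
    "loglik_sequence",
    "viterbi_path",
    "transition_density",
    "rates_from_fit",
    "classify_dynamic",
    "fraction_dynamic",
]

_SD_FLOOR = 1e-3


# ---------------------------------------------------------------------------
# photobleach screening


@dataclass(frozen=True)
class BleachStep:
    """A single downward intensity step: the frame index and the channel call.

    ``channel`` is "donor" (total intensity and both channels drop),
    "acceptor" (acceptor drops while donor rises: transfer is rerouted to
    the donor channel) or "unknown".
    """

    frame: int
    channel: str


def _split_tstats(y: np.ndarray, min_seg: int) -> np.ndarray:
    """Welch t statistic of mean(before) - mean(after) for every split point."""
    n = len(y)
    t = np.full(n, 0.0)
    csum = np.cumsum(y)
    csum2 = np.cumsum(y * y)
    for b in range(min_seg, n - min_seg + 1):
        n1, n2 = b, n - b
        m1 = csum[b - 1] / n1
        m2 = (csum[-1] - csum[b - 1]) / n2
        v1 = max(csum2[b - 1] / n1 - m1 * m1, 1e-12)
        v2 = max((csum2[-1] - csum2[b - 1]) / n2 - m2 * m2, 1e-12)
        t[b] = (m1 - m2) / np.sqrt(v1 / max(n1 - 1, 1) + v2 / max(n2 - 1, 1))
    return t


def _scan_segment(y, lo, hi, alpha, min_seg, steps):
    seg = y[lo:hi]
    n = len(seg)
    if n < 2 * min_seg:
        return
    t = _split_tstats(seg, min_seg)
    b = int(np.argmax(np.abs(t)))
    # Bonferroni over the candidate split points of this segment
    n_tests = max(n - 2 * min_seg + 1, 1)
    thresh = stats.norm.isf(alpha / (2.0 * n_tests))
    if abs(t[b]) < thresh:
        return
    steps.append((lo + b, t[b]))
    _scan_segment(y, lo, lo + b, alpha, min_seg, steps)
    _scan_segment(y, lo + b, hi, alpha, min_seg, steps)


def detect_bleach_steps(
    trace,
    gamma: float = 1.0,
    alpha: float = 0.01,
    min_seg: int = 5,
    min_step_frac: float = 0.1,
):
    """Detect single-fluorophore photobleaching steps in a camera trace.

    Binary-segmentation change-point scan (two-sample t statistic,
    Bonferroni-corrected threshold ``alpha`` per segment, minimum segment
    ``min_seg`` frames) applied to two signals: the corrected total
    intensity I_T = gamma*I_D + I_A, in which only a donor bleach appears
    as a downward step (acceptor loss reroutes transfer into the donor
    channel and leaves I_T flat), and the acceptor channel, in which an
    acceptor bleach appears as a drop accompanied by a donor rise.
    Acceptor-channel steps coinciding with a total-intensity step (within
    3 frames) are the same donor event and are not double counted. Steps
    whose drop is smaller than ``min_step_frac`` of the signal's dynamic
    range are ignored — a bleach removes a whole fluorophore, not a few
    counts of background drift.

    Returns a list of :class:`BleachStep`, sorted by frame; traces showing
    more than one step are discarded upstream.
    """
    donor = np.asarray(trace.donor, dtype=float)
    acceptor = np.asarray(trace.acceptor, dtype=float)
    if len(donor) < 20:
        raise ValueError("need at least 20 frames for bleach screening")
    total = gamma * donor + acceptor

    def big_enough(signal, frame):
        # local drop across the step, against the trace's dynamic range
        w = 30
        before = signal[max(frame - w, 0) : frame].mean()
        after = signal[frame : frame + w].mean()
        span = np.percentile(signal, 97.5) - np.percentile(signal, 2.5)
        return before - after >= min_step_frac * span

    raw_total: list[tuple[int, float]] = []
    _scan_segment(total, 0, len(total), alpha, min_seg, raw_total)
    donor_steps = sorted(f for f, t in raw_total if t > 0 and big_enough(total, f))

    raw_acc: list[tuple[int, float]] = []
    _scan_segment(acceptor, 0, len(acceptor), alpha, min_seg, raw_acc)
    steps = [BleachStep(frame=f, channel="donor") for f in donor_steps]
    for frame, tstat in sorted(raw_acc):
        if tstat <= 0 or not big_enough(acceptor, frame):
            continue
        if any(abs(frame - f) <= 3 for f in donor_steps):
            continue
        d_before, d_after = donor[:frame].mean(), donor[frame:].mean()
        channel = "acceptor" if d_after > d_before else "unknown"
        steps.append(BleachStep(frame=frame, channel=channel))
    return sorted(steps, key=lambda s: s.frame)


def prepare_trace(trace, gamma: float = 1.0, steps=None, min_frames: int = 10):
    """Per-frame apparent efficiency up to the first photobleach.

    E_t = I_A / (I_A + gamma*I_D) for the frames preceding the first
    detected downward step (the whole trace if none is found). Traces whose
    first bleach falls before ``min_frames`` frames carry too little signal
    and raise ``ValueError``.
    """
    if steps is None:
        steps = detect_bleach_steps(trace, gamma=gamma)
    end = min((s.frame for s in steps), default=len(trace.donor))
    if end < min_frames:
        raise ValueError(f"trace bleaches after {end} frames (< {min_frames}): too short")
    return efficiency_from_intensities(
        np.asarray(trace.donor[:end], float), np.asarray(trace.acceptor[:end], float), gamma
    )


# ---------------------------------------------------------------------------
# global Gaussian HMM


@dataclass
class HMMFit:
    """Result of a global Gaussian-emission HMM fit.

    States are sorted by ascending mean efficiency, which resolves label
    switching deterministically.
    """

    n_states: int
    means: np.ndarray
    sds: np.ndarray
    trans: np.ndarray  # per-frame transition probability matrix, rows sum to 1
    start: np.ndarray
    log_lik: float
    n_iter: int
    converged: bool = True

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the fitted per-frame transition matrix."""
        vals, vecs = np.linalg.eig(self.trans.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass
class ViterbiResult:
    path: np.ndarray  # state index per frame
    path_log_lik: float


@dataclass
class TransitionDensity:
    """2-D transition histogram: one point (E_before, E_after) per Viterbi change."""

    e_before: np.ndarray
    e_after: np.ndarray
    counts: np.ndarray  # K x K integer matrix, zero diagonal

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())


@dataclass
class RateTable:
    """First-order transition rates (s^-1) and Viterbi transition counts."""

    rates: np.ndarray  # K x K, diagonal zero
    counts: np.ndarray  # K x K integer matrix of observed Viterbi changes


def _pad_sequences(seqs):
    lengths = np.array([len(s) for s in seqs], dtype=int)
    tmax = int(lengths.max())
    x = np.zeros((len(seqs), tmax))
    for i, s in enumerate(seqs):
        x[i, : len(s)] = s
    return x, lengths


def _emission_probs(x, means, sds):
    # (n, T, K) Gaussian densities, floored to keep the scaled recursions finite
    z = (x[:, :, None] - means[None, None, :]) / sds[None, None, :]
    b = np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * sds[None, None, :])
    return np.maximum(b, 1e-300)


def _forward_backward(x, lengths, means, sds, trans, start):
    """Scaled forward-backward over a padded batch of sequences.

    Frames at or beyond a sequence's length are masked out (their scale
    factor is 1 and their emission likelihood does not contribute).
    Returns (log_lik, gamma, xi_sum, c) where gamma is the state posterior
    per frame and xi_sum the posterior transition-count matrix.
    """
    n, tmax = x.shape
    k = len(means)
    b = _emission_probs(x, means, sds)
    mask = np.arange(tmax)[None, :] < lengths[:, None]

    alpha = np.zeros((n, tmax, k))
    c = np.ones((n, tmax))
    a = start[None, :] * b[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0, :] = a / c[:, 0, None]
    for t in range(1, tmax):
        a = (alpha[:, t - 1, :] @ trans) * b[:, t, :]
        ct = a.sum(axis=1)
        live = mask[:, t]
        c[:, t] = np.where(live, ct, 1.0)
        alpha[:, t, :] = np.where(live[:, None], a / c[:, t, None], alpha[:, t - 1, :])

    beta = np.ones((n, tmax, k))
    for t in range(tmax - 2, -1, -1):
        nxt = mask[:, t + 1]
        bb = ((b[:, t + 1, :] * beta[:, t + 1, :]) @ trans.T) / c[:, t + 1, None]
        beta[:, t, :] = np.where(nxt[:, None], bb, 1.0)

    gamma = alpha * beta
    gamma *= mask[:, :, None]
    # normalize per live frame (alpha*beta already sums to 1 up to round-off)
    norm = gamma.sum(axis=2, keepdims=True)
    np.divide(gamma, norm, out=gamma, where=norm > 0)

    xi_sum = np.zeros((k, k))
    for t in range(tmax - 1):
        live = mask[:, t + 1]
        if not live.any():
            continue
        w = (b[:, t + 1, :] * beta[:, t + 1, :]) / c[:, t + 1, None]
        xi_t = np.einsum("ni,ij,nj->ij", alpha[:, t, :] * live[:, None], trans, w)
        xi_sum += xi_t

    log_lik = float(np.sum(np.log(c[mask])))
    return log_lik, gamma, xi_sum, mask


def _sorted_by_mean(means, sds, trans, start):
    order = np.argsort(means)
    return means[order], sds[order], trans[np.ix_(order, order)], start[order]


def fit_hmm_global(
    sequences,
    n_states: int = 3,
    n_restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
    sd_floor: float = _SD_FLOOR,
    init=None,
) -> HMMFit:
    """Fit one Gaussian-emission HMM jointly to many efficiency sequences.

    Baum-Welch EM with emission means/s.d.s and the per-frame transition
    matrix shared across all traces. Initial means are placed at evenly
    spaced quantiles of the pooled data (10th-90th percentile), the
    transition matrix starts self-biased (0.9 on the diagonal), and
    ``n_restarts`` seeded jitters of that initialization are run to
    completion; the best log-likelihood wins. The log-likelihood is checked
    to be non-decreasing at every EM step.

    ``init`` may supply ``(means, sds)`` explicitly, in which case only one
    EM run is performed from it (plus the jittered restarts if
    ``n_restarts`` > 1).
    """
    sequences = [np.asarray(s, dtype=float) for s in sequences]
    if not sequences:
        raise ValueError("need at least one trace")
    for s in sequences:
        if len(s) < 10:
            raise ValueError("each trace must contain at least 10 frames")
        if not np.all(np.isfinite(s)):
            raise ValueError("traces must not contain NaN or infinities")
    k = int(n_states)
    if k < 1:
        raise ValueError("n_states must be >= 1")

    x, lengths = _pad_sequences(sequences)
    pooled = np.concatenate(sequences)
    rng = np.random.default_rng(seed)

    if init is not None:
        means0 = np.asarray(init[0], dtype=float)
        sds0 = np.asarray(init[1], dtype=float)
    else:
        qs = np.linspace(10, 90, k)
        means0 = np.percentile(pooled, qs)
        sds0 = np.full(k, max(pooled.std() / max(k, 1), 5 * sd_floor))

    best = None
    for r in range(max(n_restarts, 1)):
        means = means0.copy()
        sds = sds0.copy()
        if r > 0:
            means = means + rng.normal(0.0, max(pooled.std(), 0.02) / 2, size=k)
        trans = np.full((k, k), 0.1 / max(k - 1, 1))
        np.fill_diagonal(trans, 0.9 if k > 1 else 1.0)
        start = np.full(k, 1.0 / k)

        prev_ll = -np.inf
        ll = prev_ll
        n_iter = 0
        converged = False
        for n_iter in range(1, max_iter + 1):
            ll, gamma, xi_sum, mask = _forward_backward(x, lengths, means, sds, trans, start)
            if ll + 1e-8 * max(abs(ll), 1.0) < prev_ll:
                raise AssertionError(
                    f"EM log-likelihood decreased ({prev_ll:.6f} -> {ll:.6f})"
                )
            if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * max(abs(prev_ll), 1.0):
                converged = True
                break
            prev_ll = ll
            # M step
            occ = gamma.sum(axis=(0, 1))  # expected frames per state
            means = (gamma * x[:, :, None]).sum(axis=(0, 1)) / np.maximum(occ, 1e-12)
            var = (gamma * (x[:, :, None] - means[None, None, :]) ** 2).sum(axis=(0, 1))
            sds = np.sqrt(var / np.maximum(occ, 1e-12))
            low = sds < sd_floor
            if low.any():
                warnings.warn(
                    "degenerate state(s): emission s.d. hit the floor "
                    f"({sd_floor}); K may exceed the number of distinct levels",
                    RuntimeWarning,
                    stacklevel=2,
                )
                sds = np.maximum(sds, sd_floor)
            if k > 1:
                denom = xi_sum.sum(axis=1, keepdims=True)
                trans = np.where(denom > 0, xi_sum / np.maximum(denom, 1e-300), trans)
                trans = trans / trans.sum(axis=1, keepdims=True)
            start = gamma[:, 0, :].mean(axis=0)
            start = start / start.sum()

        if best is None or ll > best[0]:
            best = (ll, means, sds, trans, start, n_iter, converged)

    ll, means, sds, trans, start, n_iter, converged = best
    means, sds, trans, start = _sorted_by_mean(means, sds, trans, start)
    return HMMFit(
        n_states=k,
        means=means,
        sds=sds,
        trans=trans,
        start=start,
        log_lik=ll,
        n_iter=n_iter,
        converged=converged,
    )


def loglik_sequence(fit: HMMFit, sequence) -> float:
    """Forward-algorithm log-likelihood of one sequence under a fit."""
    s = np.asarray(sequence, dtype=float)
    x, lengths = _pad_sequences([s])
    ll, *_ = _forward_backward(x, lengths, fit.means, fit.sds, fit.trans, fit.start)
    return ll


def viterbi_path(fit: HMMFit, sequence) -> ViterbiResult:
    """Most probable state path for one efficiency sequence (log-space DP)."""
    s = np.asarray(sequence, dtype=float)
    k = fit.n_states
    log_b = (
        -0.5 * ((s[:, None] - fit.means[None, :]) / fit.sds[None, :]) ** 2
        - np.log(np.sqrt(2 * np.pi) * fit.sds)[None, :]
    )
    with np.errstate(divide="ignore"):
        log_a = np.log(fit.trans)
        log_pi = np.log(fit.start)
    t_len = len(s)
    delta = np.zeros((t_len, k))
    psi = np.zeros((t_len, k), dtype=int)
    delta[0] = log_pi + log_b[0]
    for t in range(1, t_len):
        cand = delta[t - 1][:, None] + log_a
        psi[t] = np.argmax(cand, axis=0)
        delta[t] = cand[psi[t], np.arange(k)] + log_b[t]
    path = np.zeros(t_len, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(t_len - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return ViterbiResult(path=path, path_log_lik=float(delta[-1].max()))


def transition_density(paths, fit: HMMFit) -> TransitionDensity:
    """Transition-density plot data from a set of decoded paths.

    One count at (mean_i, mean_j) per Viterbi state change i -> j; the
    diagonal is empty by construction.
    """
    k = fit.n_states
    counts = np.zeros((k, k), dtype=int)
    eb, ea = [], []
    for vr in paths:
        p = vr.path
        chg = np.nonzero(np.diff(p) != 0)[0]
        for t in chg:
            i, j = p[t], p[t + 1]
            counts[i, j] += 1
            eb.append(fit.means[i])
            ea.append(fit.means[j])
    return TransitionDensity(
        e_before=np.array(eb), e_after=np.array(ea), counts=counts
    )


def rates_from_fit(fit: HMMFit, paths, frame_time: float, method: str = "linear") -> RateTable:
    """Transition rates from the fitted per-frame transition matrix.

    ``method='linear'`` (default) uses the first-order expansion
    k_ij = A_ij / frame_time, valid when per-frame probabilities are small;
    ``method='matrix_log'`` uses logm(A)/frame_time instead. Counts are the
    number of Viterbi changes per ordered state pair.
    """
    if frame_time <= 0:
        raise ValueError("frame_time must be positive")
    if method == "linear":
        rates = fit.trans / frame_time
    elif method == "matrix_log":
        q = np.real(sla.logm(fit.trans)) / frame_time
        rates = np.maximum(q, 0.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    rates = rates.copy()
    np.fill_diagonal(rates, 0.0)
    counts = transition_density(paths, fit).counts
    return RateTable(rates=rates, counts=counts)


def classify_dynamic(
    vr: ViterbiResult,
    fit: HMMFit | None = None,
    min_dwell_frames: int = 3,
    min_separation: float = 0.1,
) -> bool:
    """Whether a decoded trace shows genuine state switching.

    A trace is dynamic iff its Viterbi path contains at least one state
    change whose flanking dwells both last >= ``min_dwell_frames`` frames
    and (when a fit is supplied) whose two state means differ by at least
    ``min_separation`` in efficiency, so changes between near-degenerate
    fitted states do not count.
    """
    p = vr.path
    chg = np.nonzero(np.diff(p) != 0)[0]
    if len(chg) == 0:
        return False
    bounds = np.concatenate([[-1], chg, [len(p) - 1]])
    dwells = np.diff(bounds)  # frames per dwell
    for n, t in enumerate(chg):
        if dwells[n] < min_dwell_frames or dwells[n + 1] < min_dwell_frames:
            continue
        if fit is not None and abs(fit.means[p[t + 1]] - fit.means[p[t]]) < min_separation:
            continue
        return True
    return False


def fraction_dynamic(paths, fit: HMMFit | None = None, **kwargs) -> float:
    """Percentage of traces classified as dynamic."""
    paths = list(paths)
    if not paths:
        raise ValueError("fraction undefined for an empty trace set")
    flags = [classify_dynamic(p, fit=fit, **kwargs) for p in paths]
    return 100.0 * float(np.mean(flags))
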