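"""Whole-cell gating analysis and FRET crosstalk correction.

Covers the macroscopic electrophysiology toolchain: peak I/V extraction,
conductance-transform activation curves, Boltzmann fits of activation and
steady-state inactivation (SSI), biexponential fits of current decay, the
independent-channels mixture null curve, deviation statistics against that
null, and sensitized-emission FRET crosstalk correction.

Sign convention: the single Boltzmann form Y = 1/(1 + exp(-(V - V1/2)/k))
serves both curve kinds. Activation curves carry positive k (response rises
with depolarization); SSI/availability curves carry negative k (availability
falls with depolarization).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GatingCurve",
    "BoltzmannFit",
    "DecayFit",
    "FretRecord",
    "boltzmann",
    "peak_iv",
    "activation_from_iv",
    "fit_boltzmann",
    "fit_decay",
    "independent_mixture",
    "coupling_deviation",
    "fret_correct",
    "acceptor_photobleach_stat",
]


def boltzmann(v, v_half: float, slope_k: float):
    """Boltzmann function Y = 1/(1 + exp(-(V - V1/2)/k))."""
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(v - v_half) / slope_k))
    return float(out) if out.ndim == 0 else out


@dataclass
class GatingCurve:
    """Voltage-dependent normalized activation or availability data."""

    voltages: np.ndarray
    response: np.ndarray
    kind: str = "activation"

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.voltages.shape != self.response.shape:
            raise ValueError("voltages and response must have identical shapes")
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")
        if self.kind not in ("activation", "ssi"):
            raise ValueError("kind must be 'activation' or 'ssi'")


@dataclass
class BoltzmannFit:
    v_half: float
    slope_k: float
    rss: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.v_half) and np.isfinite(self.slope_k)):
            raise ValueError("parameters must be finite")
        if self.slope_k == 0:
            raise ValueError("slope_k must be nonzero")

    def predict(self, voltages):
        return boltzmann(voltages, self.v_half, self.slope_k)


@dataclass
class DecayFit:
    """Biexponential inactivation fit I(t) = Af e^-t/tf + As e^-t/ts + C."""

    tau_f: float
    tau_s: float | None
    amp_f: float
    amp_s: float
    offset: float
    single_exponential: bool = False

    def __post_init__(self) -> None:
        if self.tau_f <= 0:
            raise ValueError("tau_f must be > 0")
        if self.tau_s is not None and self.tau_s < self.tau_f:
            raise ValueError("require tau_f <= tau_s")

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        out = self.amp_f * np.exp(-t / self.tau_f) + self.offset
        if self.tau_s is not None:
            out = out + self.amp_s * np.exp(-t / self.tau_s)
        return out


@dataclass
class FretRecord:
    """Per-ROI three-cube FRET intensities with crosstalk coefficients."""

    fret_raw: float
    cfp: float
    yfp: float
    a: float = 0.29
    b: float = 0.04
    fretc: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.a < 1 and 0 <= self.b < 1):
            raise ValueError("crosstalk coefficients must lie in [0, 1)")


def peak_iv(sweepsets_by_voltage: Sequence[tuple[float, np.ndarray]]) -> list[tuple[float, float]]:
    """Peak current per test voltage from episodic sweeps.

    ``sweepsets_by_voltage`` pairs a test potential (mV) with a sweep matrix
    (or single trace). The peak is the signed extremum of the mean trace —
    the minimum for inward current, whichever deviation from zero is larger.
    """
    if len(sweepsets_by_voltage) < 2:
        raise ValueError("need sweeps at >= 2 voltages")
    out = []
    for v, sweeps in sweepsets_by_voltage:
        arr = np.atleast_2d(np.asarray(sweeps, dtype=float))
        if arr.size == 0:
            raise ValueError(f"empty sweeps at {v} mV")
        mean = arr.mean(axis=0)
        peak = mean.min() if abs(mean.min()) >= abs(mean.max()) else mean.max()
        out.append((float(v), float(peak)))
    return out


def activation_from_iv(
    iv: Sequence[tuple[float, float]], e_rev: float | str = "auto"
) -> GatingCurve:
    """Conductance-transform activation curve G(V) = I/(V - E_rev), normalized.

    With ``e_rev="auto"`` the reversal potential is linearly interpolated from
    the zero crossing on the positive (outward) limb of the I/V relation.
    Points at V = E_rev are excluded; the curve is normalized by max |G|.
    """
    iv = sorted(iv)
    v = np.array([p[0] for p in iv], dtype=float)
    i = np.array([p[1] for p in iv], dtype=float)
    if e_rev == "auto":
        # zero crossing on the limb past the peak inward current
        k0 = int(np.argmin(i))
        erev = None
        for j in range(k0, v.size - 1):
            if i[j] == 0:
                erev = v[j]
                break
            if i[j] * i[j + 1] < 0:
                erev = v[j] - i[j] * (v[j + 1] - v[j]) / (i[j + 1] - i[j])
                break
        else:
            if i[-1] == 0:
                erev = v[-1]
        if erev is None:
            raise ValueError("no zero crossing found for automatic E_rev")
    else:
        erev = float(e_rev)
    keep = v != erev
    g = i[keep] / (v[keep] - erev)
    gmax = np.abs(g).max()
    if gmax == 0:
        raise ValueError("all conductances zero")
    return GatingCurve(voltages=v[keep], response=g / gmax, kind="activation")


def fit_boltzmann(curve: GatingCurve) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit of a gating curve.

    Initialization: V1/2 at the voltage whose response is nearest half-range;
    |k| from the 20-80% voltage spread divided by 2.2, signed by the data's
    monotonic direction. Non-monotone data (Spearman |rho| < 0.5) triggers a
    warning but the fit is still attempted.
    """
    v, y = curve.voltages, curve.response
    rng_y = np.ptp(y)
    if rng_y == 0:
        raise ValueError("constant response: no dynamic range to fit")
    rho = stats.spearmanr(v, y).statistic
    if abs(rho) < 0.5:
        warnings.warn("response is not monotone in voltage; fit may be unreliable")
    direction = 1.0 if rho >= 0 else -1.0
    half = y.min() + 0.5 * rng_y
    v0 = v[np.argmin(np.abs(y - half))]
    lo = y.min() + 0.2 * rng_y
    hi = y.min() + 0.8 * rng_y
    v20 = v[np.argmin(np.abs(y - lo))]
    v80 = v[np.argmin(np.abs(y - hi))]
    k0 = direction * max(abs(v80 - v20) / 2.2, 1e-3)

    def resid(p):
        return boltzmann(v, p[0], p[1]) - y

    res = optimize.least_squares(resid, x0=[v0, k0], xtol=1e-12, ftol=1e-12, gtol=1e-12)
    rss = float(np.sum(res.fun**2))
    return BoltzmannFit(v_half=float(res.x[0]), slope_k=float(res.x[1]), rss=rss)


def _single_exp_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares A e^-t/tau + C; returns (A, tau, C, rss)."""
    c0 = float(np.mean(y[-max(3, y.size // 20):]))
    a0 = float(y[0] - c0) or 1e-6
    span = t[-1] - t[0] or 1.0
    tau0 = span / 5.0

    def resid(p):
        return p[0] * np.exp(-t / abs(p[1])) + p[2] - y

    res = optimize.least_squares(resid, x0=[a0, tau0, c0], xtol=1e-12, ftol=1e-12)
    a, tau, c = res.x
    return float(a), float(abs(tau)), float(c), float(np.sum(res.fun**2))


def fit_decay(time_ms: np.ndarray, current: np.ndarray, t_peak_idx: int | None = None) -> DecayFit:
    """Biexponential fit of macroscopic current decay from the peak onward.

    Fits ``Af exp(-t/tau_f) + As exp(-t/tau_s) + C`` starting at the peak
    sample (found automatically as the extremum when ``t_peak_idx`` is None),
    with the fast/slow ordering enforced by swapping. If the two amplitudes
    disagree in sign on an otherwise monotone decay the fit falls back to a
    single exponential and ``tau_s`` is reported absent.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    current = np.asarray(current, dtype=float)
    if t_peak_idx is None:
        t_peak_idx = int(np.argmax(np.abs(current)))
    t = time_ms[t_peak_idx:] - time_ms[t_peak_idx]
    y = current[t_peak_idx:]
    if y.size < 20:
        raise ValueError("need >= 20 samples after the peak")
    if np.ptp(y) == 0 or abs(y[0] - np.mean(y[-5:])) < 1e-12:
        raise ValueError("no decay")

    c0 = float(np.mean(y[-max(3, y.size // 20):]))
    z = y - c0
    # log-linear split initialization: slow tau from the tail, fast from the head
    sgn = math.copysign(1.0, z[0] if z[0] != 0 else 1.0)
    zl = sgn * z
    pos = zl > 0
    half = y.size // 2
    tau_s0 = tau_f0 = None
    tail = pos.copy()
    tail[:half] = False
    if tail.sum() >= 3:
        coef = np.polyfit(t[tail], np.log(zl[tail]), 1)
        if coef[0] < 0:
            tau_s0 = -1.0 / coef[0]
    head = pos.copy()
    head[half:] = False
    if head.sum() >= 3:
        coef = np.polyfit(t[head], np.log(zl[head]), 1)
        if coef[0] < 0:
            tau_f0 = -1.0 / coef[0]
    span = t[-1] or 1.0
    if tau_s0 is None:
        tau_s0 = span / 2
    if tau_f0 is None or tau_f0 >= tau_s0:
        tau_f0 = tau_s0 / 10
    a0 = z[0] / 2.0 or 1e-6

    def resid(p):
        af, tf, as_, ts, c = p
        return af * np.exp(-t / abs(tf)) + as_ * np.exp(-t / abs(ts)) + c - y

    res = optimize.least_squares(
        resid, x0=[a0, tau_f0, a0, tau_s0, c0], xtol=1e-12, ftol=1e-12, gtol=1e-12
    )
    af, tf, as_, ts, c = res.x
    tf, ts = abs(tf), abs(ts)
    if tf > ts:
        tf, ts = ts, tf
        af, as_ = as_, af
    monotone = np.all(np.diff(zl) <= 1e-9 * max(abs(zl[0]), 1.0))
    if monotone and af * as_ < 0:
        a1, tau1, c1, rss1 = _single_exp_fit(t, y)
        return DecayFit(
            tau_f=tau1, tau_s=None, amp_f=a1, amp_s=0.0, offset=c1, single_exponential=True
        )
    return DecayFit(tau_f=float(tf), tau_s=float(ts), amp_f=float(af), amp_s=float(as_), offset=float(c))


def independent_mixture(
    fit_a: BoltzmannFit,
    fit_b: BoltzmannFit,
    voltages: Sequence[float],
    weight: float = 0.5,
    kind: str = "ssi",
) -> GatingCurve:
    """Theoretical gating curve for two independent channel populations.

    ``Y_mix(V) = w Y_a(V) + (1 - w) Y_b(V)`` — the null expected when the two
    co-expressed channels gate without interacting, i.e. the average of the
    two fitted single-population curves at the default w = 0.5.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    v = np.asarray(voltages, dtype=float)
    y = weight * fit_a.predict(v) + (1.0 - weight) * fit_b.predict(v)
    return GatingCurve(voltages=v, response=y, kind=kind)


def coupling_deviation(
    observed: GatingCurve,
    theoretical: GatingCurve,
    components: dict[str, GatingCurve] | None = None,
) -> tuple[float, float, str | None]:
    """Deviation of an observed gating curve from the independent-channels null.

    Returns ``(rms_dev, max_dev, nearer_component)``. Curves on different
    grids are linearly interpolated onto the overlapping voltage range. When
    single-component curves are supplied, ``nearer_component`` names the one
    with the smaller RMS distance to the observed data ("tie" on exact ties).
    """
    lo = max(observed.voltages.min(), theoretical.voltages.min())
    hi = min(observed.voltages.max(), theoretical.voltages.max())
    if lo > hi:
        raise ValueError("disjoint voltage ranges")
    mask = (observed.voltages >= lo) & (observed.voltages <= hi)
    v = observed.voltages[mask]
    obs = observed.response[mask]
    theo = np.interp(v, theoretical.voltages, theoretical.response)
    dev = obs - theo
    rms = float(np.sqrt(np.mean(dev**2)))
    mx = float(np.max(np.abs(dev)))
    nearer = None
    if components:
        dists = {}
        for name, comp in components.items():
            ci = np.interp(v, comp.voltages, comp.response)
            dists[name] = float(np.sqrt(np.mean((obs - ci) ** 2)))
        best = min(dists.values())
        winners = [k for k, d in dists.items() if d == best]
        nearer = winners[0] if len(winners) == 1 else "tie"
    return rms, mx, nearer


def fret_correct(record: FretRecord) -> FretRecord:
    """Apply sensitized-emission crosstalk correction FRETc = FRET - a·CFP - b·YFP.

    ``a`` removes donor bleed-through into the FRET channel and ``b`` removes
    direct acceptor excitation. The corrected value may be negative; it is
    not clipped.
    """
    if record.fret_raw < 0 or record.cfp < 0 or record.yfp < 0:
        raise ValueError("intensities must be >= 0")
    fretc = record.fret_raw - record.a * record.cfp - record.b * record.yfp
    return FretRecord(
        fret_raw=record.fret_raw,
        cfp=record.cfp,
        yfp=record.yfp,
        a=record.a,
        b=record.b,
        fretc=float(fretc),
    )


@dataclass
class PairedStat:
    mean_percent_increase: float
    sem_percent_increase: float
    t_statistic: float
    p_value: float
    n: int


def acceptor_photobleach_stat(
    donor_pre: Sequence[float], donor_post: Sequence[float]
) -> tuple[float, PairedStat]:
    """Donor dequenching after acceptor photobleaching, per paired ROI.

    Returns the mean percent increase ``100 (post - pre)/pre`` and a paired
    two-sided t-test summary. ROIs with nonpositive pre-bleach signal are
    excluded with a warning. For true FRET efficiency E the expected percent
    increase is 100 E / (1 - E) (the unquenched donor recovers I/(1-E)).
    """
    pre = np.asarray(donor_pre, dtype=float)
    post = np.asarray(donor_post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("donor_pre and donor_post must be paired (equal length)")
    keep = pre > 0
    if not np.all(keep):
        warnings.warn(f"excluding {np.sum(~keep)} ROI(s) with nonpositive pre-bleach signal")
        pre, post = pre[keep], post[keep]
    if pre.size < 3:
        raise ValueError("need >= 3 valid paired ROIs")
    pct = 100.0 * (post - pre) / pre
    t_res = stats.ttest_rel(post, pre)
    summary = PairedStat(
        mean_percent_increase=float(np.mean(pct)),
        sem_percent_increase=float(stats.sem(pct)) if pct.size > 1 else 0.0,
        t_statistic=float(t_res.statistic),
        p_value=float(t_res.pvalue),
        n=int(pct.size),
    )
    return summary.mean_percent_increase, summary
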