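"""Synthetic data generators for dimeric sodium-channel analyses.

Every generator draws from a single :class:`numpy.random.Generator` seeded
explicitly, so identical ``(params, seed)`` pairs give bit-identical output.

The gating simulator models a channel *pair* under a patch. Each protomer is a
three-state continuous-time Markov chain C <-> O -> I (closed, open,
inactivated). With coupling fraction ``phi`` a sweep's dimer is drawn
*coupled*: the pair gates as one concerted chain whose open state conducts
``2 i``; otherwise the two protomers gate independently, each conducting ``i``
when open. This reproduces the observable dichotomy of coupled gating: a
concerted dimer produces direct closed <-> double-conductance transitions and
never dwells at the single-open level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .stoichiometry import DoseResponse
from .biophys import GatingCurve, boltzmann

__all__ = [
    "GatingModel",
    "StepProtocol",
    "SweepSet",
    "BleachPopulationParams",
    "BleachTrace",
    "simulate_sweeps",
    "simulate_bleach_population",
    "simulate_dose_response",
    "simulate_gating_curve",
]

# protomer states
_C, _O, _I = 0, 1, 2


@dataclass(frozen=True)
class GatingModel:
    """Kinetic and conductance parameters for a simulated channel pair.

    Rates are in ms^-1; ``unitary_current`` is the single-channel amplitude i
    in pA (negative for inward Na+ current); ``coupling_fraction`` is the
    probability that a sweep's dimer gates as one concerted unit.
    """

    rate_co: float = 0.5
    rate_oc: float = 0.1
    rate_oi: float = 2.0
    rate_ic: float = 0.0
    unitary_current: float = -1.5
    coupling_fraction: float = 1.0
    noise_sd: float = 0.15

    def __post_init__(self) -> None:
        rates = (self.rate_co, self.rate_oc, self.rate_oi, self.rate_ic)
        if not all(np.isfinite(rates)):
            raise ValueError("rates must be finite")
        if any(r < 0 for r in rates):
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.coupling_fraction <= 1.0:
            raise ValueError("coupling_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.unitary_current == 0 or not np.isfinite(self.unitary_current):
            raise ValueError("unitary_current must be finite and nonzero")


# "-40 mV-like" regime: sparser, later openings (see GatingModel defaults for
# the "-20 mV-like" regime used elsewhere).
MODEL_MINUS40 = dict(rate_co=0.05, rate_oc=0.1, rate_oi=0.5, rate_ic=0.0)


@dataclass(frozen=True)
class StepProtocol:
    """Voltage-step acquisition protocol (single depolarizing step)."""

    holding_mv: float = -100.0
    step_mv: float = -40.0
    step_ms: float = 50.0
    sample_rate_hz: float = 30_000.0
    n_sweeps: int = 100

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        if self.step_ms <= 0:
            raise ValueError("step_ms must be > 0")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")

    @property
    def n_samples(self) -> int:
        return round(self.step_ms * self.sample_rate_hz / 1000.0)

    @property
    def sample_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz


@dataclass
class SweepSet:
    """Episodic current sweeps plus optional noise-free ground truth.

    ``sweeps`` is an ``(n_sweeps, n_samples)`` current matrix in pA.
    ``ground_truth``, when present, holds the true conductance level
    (0, 1 or 2 open protomers) for every sample.
    """

    sweeps: np.ndarray
    protocol: StepProtocol
    ground_truth: np.ndarray | None = None
    model: GatingModel | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        if self.sweeps.ndim != 2:
            raise ValueError("sweeps must be a 2-D matrix")
        if self.sweeps.shape[1] != self.protocol.n_samples:
            raise ValueError(
                f"n_samples {self.sweeps.shape[1]} does not match protocol "
                f"({self.protocol.n_samples})"
            )
        if self.ground_truth is not None:
            self.ground_truth = np.asarray(self.ground_truth)
            if self.ground_truth.shape != self.sweeps.shape:
                raise ValueError("ground_truth shape must match sweeps")

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.sweeps.shape[1]) * self.protocol.sample_ms


@dataclass(frozen=True)
class BleachPopulationParams:
    """Population parameters for single-molecule photobleaching traces."""

    n_subunits: int = 2
    p_active: float = 0.7
    bleach_rate: float = 0.2       # s^-1 per fluorophore
    frame_interval_s: float = 0.1
    unit_intensity: float = 1.0    # a.u. per active fluorophore
    noise_sd: float = 0.1
    n_molecules: int = 1000
    n_frames: int = 300

    def __post_init__(self) -> None:
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")
        if not 0.0 <= self.p_active <= 1.0:
            raise ValueError("p_active must lie in [0, 1]")
        if self.bleach_rate <= 0:
            raise ValueError("bleach_rate must be > 0")
        if self.unit_intensity <= 0:
            raise ValueError("unit_intensity must be > 0")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")


@dataclass
class BleachTrace:
    """Per-frame fluorescence intensity of one immobilized molecule."""

    molecule_id: int
    intensity: np.ndarray
    frame_interval_s: float
    true_step_count: int | None = None
    true_step_times: list[float] | None = None
    detectable: bool = True

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.size < 2:
            raise ValueError("intensity must have >= 2 frames")
        if (
            self.true_step_count is not None
            and self.true_step_times is not None
            and self.true_step_count != len(self.true_step_times)
        ):
            raise ValueError("true_step_count must equal len(true_step_times)")


def _gillespie(rng: np.random.Generator, model: GatingModel, t_end: float) -> list[tuple[float, int]]:
    """One protomer trajectory as [(entry_time_ms, state), ...] starting in C."""
    t, state = 0.0, _C
    traj = [(0.0, _C)]
    while t < t_end:
        if state == _C:
            total = model.rate_co
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            state = _O
        elif state == _O:
            total = model.rate_oc + model.rate_oi
            t += rng.exponential(1.0 / total)
            state = _C if rng.random() < model.rate_oc / total else _I
        else:  # inactivated
            total = model.rate_ic
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            state = _C
        if t < t_end:
            traj.append((t, state))
    return traj


def _open_intervals(traj: list[tuple[float, int]], t_end: float) -> list[tuple[float, float]]:
    """Merge a trajectory into [start, end) intervals spent in the open state."""
    out = []
    for idx, (t0, s) in enumerate(traj):
        if s != _O:
            continue
        t1 = traj[idx + 1][0] if idx + 1 < len(traj) else t_end
        out.append((t0, min(t1, t_end)))
    return out


def _sample_majority(levels: list[tuple[float, float, int]], n_samples: int, dt: float) -> np.ndarray:
    """Per-sample majority level for a piecewise-constant level function.

    ``levels`` is a list of (start_ms, end_ms, level) covering [0, n*dt).
    """
    occ = np.zeros((n_samples, 3))
    for t0, t1, lev in levels:
        if t1 <= t0:
            continue
        s0 = int(t0 // dt)
        s1 = min(int(math.ceil(t1 / dt)), n_samples)
        for s in range(s0, s1):
            lo = max(t0, s * dt)
            hi = min(t1, (s + 1) * dt)
            if hi > lo:
                occ[s, lev] += hi - lo
    # argmax returns the lowest index on ties -> tie toward lower level
    return occ.argmax(axis=1)


def _piecewise_levels(
    open_lists: list[list[tuple[float, float]]], increments: list[int], t_end: float
) -> list[tuple[float, float, int]]:
    """Combine per-unit open intervals into a piecewise-constant level function."""
    breaks = {0.0, t_end}
    for ivals in open_lists:
        for a, b in ivals:
            breaks.add(a)
            breaks.add(b)
    pts = sorted(breaks)
    out = []
    for a, b in zip(pts[:-1], pts[1:]):
        mid = 0.5 * (a + b)
        lev = 0
        for ivals, inc in zip(open_lists, increments):
            if any(t0 <= mid < t1 for t0, t1 in ivals):
                lev += inc
        out.append((a, b, lev))
    return out


def simulate_sweeps(model: GatingModel, protocol: StepProtocol, seed: int) -> SweepSet:
    """Simulate episodic single-channel current sweeps for one dimer.

    Per sweep the dimer is drawn coupled with probability
    ``model.coupling_fraction``. A coupled dimer evolves as one C<->O->I chain
    conducting ``2 i`` when open; an independent pair evolves as two such
    chains each conducting ``i``. Trajectories are simulated event-by-event
    (exponential waiting times), discretized so each sample carries the level
    occupying the majority of its interval, scaled to current and overlaid
    with Gaussian noise. All protomers start closed at step onset.
    """
    n_samples = protocol.n_samples
    if n_samples < 2:
        raise ValueError("protocol must span at least 2 samples")
    dt = protocol.sample_ms
    t_end = n_samples * dt
    rng = np.random.default_rng(seed)

    gt = np.zeros((protocol.n_sweeps, n_samples), dtype=np.int8)
    for sw in range(protocol.n_sweeps):
        coupled = rng.random() < model.coupling_fraction
        if coupled:
            traj = _gillespie(rng, model, t_end)
            levels = _piecewise_levels([_open_intervals(traj, t_end)], [2], t_end)
        else:
            trajs = [_gillespie(rng, model, t_end) for _ in range(2)]
            levels = _piecewise_levels(
                [_open_intervals(t, t_end) for t in trajs], [1, 1], t_end
            )
        gt[sw] = _sample_majority(levels, n_samples, dt)

    current = gt * model.unitary_current
    if model.noise_sd > 0:
        current = current + rng.normal(0.0, model.noise_sd, size=current.shape)
    else:
        current = current.astype(float)
    return SweepSet(sweeps=current, protocol=protocol, ground_truth=gt, model=model, seed=seed)


def simulate_bleach_population(params: BleachPopulationParams, seed: int) -> list[BleachTrace]:
    """Simulate a population of single-molecule photobleaching traces.

    Each molecule carries ``k ~ Binomial(n_subunits, p_active)`` active
    fluorophores; each bleaches at an independent exponential time. Intensity
    per frame is ``unit_intensity x survivors`` plus Gaussian noise. Dark
    molecules (k = 0) are retained with ``detectable=False`` so both
    conditional and unconditional tallies are possible.
    """
    rng = np.random.default_rng(seed)
    t_frames = np.arange(params.n_frames) * params.frame_interval_s
    traces: list[BleachTrace] = []
    ks = rng.binomial(params.n_subunits, params.p_active, size=params.n_molecules)
    for mol, k in enumerate(ks):
        bleach_times = np.sort(rng.exponential(1.0 / params.bleach_rate, size=k))
        survivors = (t_frames[:, None] < bleach_times[None, :]).sum(axis=1) if k else np.zeros(
            params.n_frames
        )
        intensity = params.unit_intensity * survivors
        if params.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, params.noise_sd, size=params.n_frames)
        traces.append(
            BleachTrace(
                molecule_id=mol,
                intensity=intensity,
                frame_interval_s=params.frame_interval_s,
                true_step_count=int(k),
                true_step_times=[float(t) for t in bleach_times],
                detectable=bool(k > 0),
            )
        )
    return traces


def simulate_dose_response(
    n: int, ratios: Sequence[float], noise_sd: float, seed: int
) -> DoseResponse:
    """Dominant-negative dose-response data under y = (1 - x)^n plus noise.

    ``x`` is the mutant cDNA fraction; noise is Gaussian, clipped so y >= 0;
    the SEM column is populated with ``noise_sd``.
    """
    if n < 1 or int(n) != n:
        raise ValueError("n must be a positive integer")
    x = np.asarray(sorted(ratios), dtype=float)
    if x.size == 0:
        raise ValueError("ratios must be non-empty")
    if x.min() < 0 or x.max() > 1:
        raise ValueError("ratios must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    y = (1.0 - x) ** n
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=x.size)
    y = np.clip(y, 0.0, None)
    return DoseResponse(x=x, y=y, sem=np.full(x.size, float(noise_sd)))


def simulate_gating_curve(
    v_half: float,
    slope_k: float,
    voltages: Sequence[float],
    noise_sd: float,
    seed: int,
    kind: str = "ssi",
) -> GatingCurve:
    """Boltzmann-distributed gating data Y(V) = 1/(1+exp(-(V-v_half)/k)) + noise.

    By convention steady-state inactivation (availability) curves carry a
    negative ``slope_k`` so that availability decreases with depolarization;
    activation curves carry positive ``slope_k``.
    """
    if slope_k == 0:
        raise ValueError("slope_k must be nonzero")
    v = np.asarray(voltages, dtype=float)
    rng = np.random.default_rng(seed)
    y = boltzmann(v, v_half, slope_k)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=v.size)
    y = np.clip(y, 0.0, None)
    return GatingCurve(voltages=v, response=y, kind=kind)
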