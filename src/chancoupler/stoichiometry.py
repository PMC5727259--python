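"""Subunit stoichiometry inference.

Two independent routes:

1. **Photobleaching step counting** (single-molecule pull-down): detect
   discrete downward intensity steps per molecule, tally the step-count
   histogram, and fit the subunit count ``n`` by conditional-binomial maximum
   likelihood. The per-subunit fluorophore maturation probability ``p``
   censors the observable counts: a molecule with ``n`` subunits shows
   ``k ~ Binomial(n, p)`` steps, and dark molecules (k = 0) are never spotted,
   so the likelihood conditions on detection (k >= 1).

2. **Dominant-negative dose-response** (binomial analysis): with random
   assembly of an ``n``-mer in which a single mutant subunit kills the
   complex, the normalized current at mutant cDNA fraction ``x`` follows
   ``y = (1 - x)^n``. The integer exponent is selected by weighted least
   squares over n in {1, 2, 3} (monomer / dimer / trimer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "StepCountHistogram",
    "StoichFit",
    "DoseResponse",
    "BinomialFit",
    "detect_steps",
    "step_histogram",
    "fit_subunit_count",
    "bleach_time_stats",
    "binomial_theoretical",
    "normalize_dose_response",
    "fit_binomial_exponent",
]


@dataclass
class StepCountHistogram:
    """Tally of detected photobleaching step counts per molecule."""

    counts: dict[int, int]
    n_undetected: int = 0

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.counts):
            raise ValueError("step counts in `counts` must be >= 1")
        if any(c < 0 for c in self.counts.values()) or self.n_undetected < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n_detected(self) -> int:
        return sum(self.counts.values())

    def fractions(self, conditional: bool = True) -> dict[int, float]:
        """Step-count fractions, conditional on detection or over all molecules."""
        denom = self.n_detected if conditional else self.n_detected + self.n_undetected
        return {k: c / denom for k, c in sorted(self.counts.items())}


@dataclass
class StoichFit:
    """Conditional-binomial maximum-likelihood subunit count."""

    n_hat: int
    p_active: float
    loglik: float
    predicted: dict[int, float]
    loglik_by_n: dict[int, float] = field(default_factory=dict)


@dataclass
class DoseResponse:
    """Normalized dominant-negative dose-response table.

    ``x``: mutant cDNA fraction in [0, 1]; ``y``: peak current density
    normalized to the all-wild-type reference (y = 1 at x = 0); ``sem``:
    per-point uncertainty.
    """

    x: np.ndarray
    y: np.ndarray
    sem: np.ndarray
    n_cells: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (self.x.shape == self.y.shape == self.sem.shape):
            raise ValueError("x, y, sem must have identical shapes")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if self.x.min() < 0 or self.x.max() > 1:
            raise ValueError("x must lie in [0, 1]")
        if np.any(self.y < 0):
            raise ValueError("y must be >= 0")


@dataclass
class BinomialFit:
    """Integer-exponent fit of y = (1 - x)^n to a dose-response curve."""

    n_best: int
    rss: dict[int, float]
    aic: dict[int, float]
    n_continuous: float | None = None


# ---------------------------------------------------------------------------
# photobleaching step detection


def _seg_rss(csum: np.ndarray, csum2: np.ndarray, a: int, b: int) -> float:
    """RSS of the constant fit to y[a:b] from precomputed cumulative sums."""
    n = b - a
    s = csum[b] - csum[a]
    s2 = csum2[b] - csum2[a]
    return max(s2 - s * s / n, 0.0)


def _best_split(csum: np.ndarray, csum2: np.ndarray, a: int, b: int) -> tuple[float, int]:
    """Largest RSS reduction over single splits of y[a:b]; (-inf, -1) if none."""
    if b - a < 2:
        return -math.inf, -1
    base = _seg_rss(csum, csum2, a, b)
    best_gain, best_cp = -math.inf, -1
    for cp in range(a + 1, b):
        gain = base - _seg_rss(csum, csum2, a, cp) - _seg_rss(csum, csum2, cp, b)
        if gain > best_gain:
            best_gain, best_cp = gain, cp
    return best_gain, best_cp


def _bic(rss: float, n: int, n_changepoints: int) -> float:
    # one mean per added segment plus a shared variance
    rss = max(rss, 1e-12)
    return n * math.log(rss / n) + (n_changepoints + 1) * math.log(n)


def _greedy_changepoints(y: np.ndarray) -> list[int]:
    """Greedy binary segmentation with BIC stopping; returns sorted indices.

    A change point at index ``cp`` means the new segment starts at frame cp.
    """
    n = y.size
    csum = np.concatenate(([0.0], np.cumsum(y)))
    csum2 = np.concatenate(([0.0], np.cumsum(y * y)))
    cps: list[int] = []
    rss = _seg_rss(csum, csum2, 0, n)
    bic = _bic(rss, n, 0)
    while True:
        bounds = [0] + cps + [n]
        best_gain, best_cp = -math.inf, -1
        for a, b in zip(bounds[:-1], bounds[1:]):
            gain, cp = _best_split(csum, csum2, a, b)
            if gain > best_gain:
                best_gain, best_cp = gain, cp
        if best_cp < 0:
            break
        new_rss = rss - best_gain
        new_bic = _bic(new_rss, n, len(cps) + 1)
        if new_bic >= bic:
            break
        cps = sorted(cps + [best_cp])
        rss, bic = new_rss, new_bic
    return cps


def detect_steps(trace, min_step_fraction: float = 0.5) -> tuple[int, list[float]]:
    """Count downward photobleaching steps in a single-molecule trace.

    Greedy binary change-point segmentation of the intensity into a
    piecewise-constant fit, with Bayesian-information-criterion stopping.
    Only downward steps of magnitude at least ``min_step_fraction`` times the
    unit step estimate (the median downward step) are retained; upward steps
    (blinking recovery) are ignored.

    Parameters
    ----------
    trace : BleachTrace
        Intensity trace with at least 4 frames.
    min_step_fraction : float
        Minimum retained step size as a fraction of the unit step estimate.

    Returns
    -------
    (step_count, step_times_s)
    """
    y = np.asarray(trace.intensity, dtype=float)
    if y.size < 4:
        raise ValueError("trace must have >= 4 frames")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities")
    if np.ptp(y) == 0:
        return 0, []
    cps = _greedy_changepoints(y)
    if not cps:
        return 0, []
    bounds = [0] + cps + [y.size]
    means = [y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    drops = [
        (cp, means[i] - means[i + 1])
        for i, cp in enumerate(cps)
        if means[i] - means[i + 1] > 0
    ]
    if not drops:
        return 0, []
    # unit step = median downward step among retained drops; iterated to a
    # fixed point from the largest drop so spurious small drops cannot set it
    unit = max(d for _, d in drops)
    for _ in range(10):
        kept = [(cp, d) for cp, d in drops if d >= min_step_fraction * unit]
        new_unit = float(np.median([d for _, d in kept]))
        if new_unit == unit:
            break
        unit = new_unit
    times = [cp * trace.frame_interval_s for cp, _ in kept]
    return len(kept), times


def exhaustive_changepoints(y: np.ndarray, max_changepoints: int | None = None) -> list[int]:
    """Globally optimal change points under the same BIC, by dynamic programming.

    Intended as an independent reference for short traces (quadratic cost in
    trace length per allowed change point).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    csum = np.concatenate(([0.0], np.cumsum(y)))
    csum2 = np.concatenate(([0.0], np.cumsum(y * y)))
    m_max = max_changepoints if max_changepoints is not None else n - 1
    # cost[m][j] = min RSS of fitting y[:j] with m change points
    cost = np.full((m_max + 1, n + 1), np.inf)
    back = np.zeros((m_max + 1, n + 1), dtype=int)
    for j in range(1, n + 1):
        cost[0][j] = _seg_rss(csum, csum2, 0, j)
    for m in range(1, m_max + 1):
        for j in range(m + 1, n + 1):
            for cp in range(m, j):
                c = cost[m - 1][cp] + _seg_rss(csum, csum2, cp, j)
                if c < cost[m][j]:
                    cost[m][j] = c
                    back[m][j] = cp
    best_m, best_bic = 0, _bic(cost[0][n], n, 0)
    for m in range(1, m_max + 1):
        if not np.isfinite(cost[m][n]):
            break
        b = _bic(cost[m][n], n, m)
        if b < best_bic:
            best_m, best_bic = m, b
    cps = []
    j = n
    for m in range(best_m, 0, -1):
        cp = back[m][j]
        cps.append(int(cp))
        j = cp
    return sorted(cps)


def step_histogram(results: Iterable[int]) -> StepCountHistogram:
    """Tally step counts; zero-step results go to ``n_undetected``."""
    results = list(results)
    if not results:
        raise ValueError("empty input")
    counts: dict[int, int] = {}
    n_undetected = 0
    for k in results:
        if k == 0:
            n_undetected += 1
        else:
            counts[k] = counts.get(k, 0) + 1
    return StepCountHistogram(counts=counts, n_undetected=n_undetected)


def conditional_step_pmf(n: int, p: float) -> dict[int, float]:
    """P(k | n, p, k >= 1) for k = 1..n — the detectable step-count model."""
    norm = 1.0 - (1.0 - p) ** n
    return {k: float(stats.binom.pmf(k, n, p)) / norm for k in range(1, n + 1)}


def fit_subunit_count(
    hist: StepCountHistogram, p_active: float = 0.7, n_max: int = 6
) -> StoichFit:
    """Maximum-likelihood subunit count from a step-count histogram.

    For each candidate ``n``, the detected counts are modelled as multinomial
    draws from the binomial step-count distribution conditioned on detection,
    ``P(k | n, p) = C(n,k) p^k (1-p)^(n-k) / (1 - (1-p)^n)``. Ties break
    toward the smaller ``n``.
    """
    if not 0.0 < p_active <= 1.0:
        raise ValueError("p_active must lie in (0, 1]")
    if hist.n_detected < 1:
        raise ValueError("need at least one detected molecule")
    k_max = max(hist.counts)
    if k_max > n_max:
        raise ValueError(f"observed k = {k_max} exceeds n_max = {n_max}")
    loglik_by_n: dict[int, float] = {}
    for n in range(k_max, n_max + 1):
        pmf = conditional_step_pmf(n, p_active)
        ll = 0.0
        for k, c in hist.counts.items():
            pk = pmf.get(k, 0.0)
            ll += c * (math.log(pk) if pk > 0 else -math.inf)
        loglik_by_n[n] = ll
    n_hat = max(sorted(loglik_by_n), key=lambda n: (loglik_by_n[n], -n))
    return StoichFit(
        n_hat=n_hat,
        p_active=p_active,
        loglik=loglik_by_n[n_hat],
        predicted=conditional_step_pmf(n_hat, p_active),
        loglik_by_n=loglik_by_n,
    )


def bleach_time_stats(
    traces: Sequence[tuple[Sequence[float], int]]
) -> tuple[float, float, float]:
    """Mean bleaching times by molecule class.

    Returns ``(mean_first_step_s, mean_total_time_s, mean_one_step_time_s)``:
    over two-step molecules, the mean time of the first step and of complete
    bleaching; over one-step molecules, the mean single step time.
    """
    firsts, totals, singles = [], [], []
    for step_times, step_count in traces:
        if step_count == 2 and len(step_times) >= 2:
            st = sorted(step_times)
            firsts.append(st[0])
            totals.append(st[-1])
        elif step_count == 1 and len(step_times) >= 1:
            singles.append(step_times[0])
    if not firsts or not singles:
        raise ValueError("need at least one two-step and one one-step molecule")
    return float(np.mean(firsts)), float(np.mean(totals)), float(np.mean(singles))


# ---------------------------------------------------------------------------
# dominant-negative binomial analysis


def binomial_theoretical(x, n: int):
    """Theoretical dominant-negative curve y = (1 - x)^n.

    With random assembly of an n-mer where one mutant subunit suffices to
    silence the complex, only all-wild-type complexes conduct; at mutant
    fraction x their probability is (1 - x)^n. n = 1 gives the linear decay
    expected for independent monomers.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("x must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    out = (1.0 - x) ** n
    return float(out) if out.ndim == 0 else out


def normalize_dose_response(
    raw: Sequence[tuple[float, float, float]]
) -> DoseResponse:
    """Normalize raw peak current densities to the x = 0 reference.

    ``raw`` rows are (mutant_fraction, peak_current_density, sem). The
    reference is the mean of all x = 0 entries; every y and sem is divided by
    it and rows are sorted by x (x = 0 replicates collapse to their mean).
    """
    raw = list(raw)
    refs = [y for x, y, _ in raw if x == 0]
    if not refs or np.mean(refs) == 0:
        raise ValueError("missing or zero x = 0 reference")
    ref = float(np.mean(refs))
    rows: dict[float, list[tuple[float, float]]] = {}
    for x, y, sem in raw:
        rows.setdefault(float(x), []).append((y / ref, sem / ref))
    xs = np.array(sorted(rows))
    ys = np.array([np.mean([v for v, _ in rows[x]]) for x in xs])
    sems = np.array([np.mean([s for _, s in rows[x]]) for x in xs])
    return DoseResponse(x=xs, y=ys, sem=sems)


def fit_binomial_exponent(dr: DoseResponse, fit_continuous: bool = True) -> BinomialFit:
    """Select the subunit count n in {1, 2, 3} for y = (1 - x)^n.

    Weighted least squares (weights 1/sem^2 where sem > 0, else 1) against the
    monomer, dimer and trimer theoretical curves; the best n minimizes the
    residual sum of squares. AIC is reported alongside (all candidates have
    equally many parameters, so the rankings coincide). Optionally also fits a
    continuous exponent on [0.5, 5] by 1-D minimization.
    """
    if dr.x.size < 3 or not np.any((dr.x > 0) & (dr.x < 1)):
        raise ValueError("need >= 3 points spanning x in (0, 1)")
    if np.ptp(dr.y) == 0:
        raise ValueError("degenerate response: all y identical")
    w = np.where(dr.sem > 0, 1.0 / np.where(dr.sem > 0, dr.sem, 1.0) ** 2, 1.0)
    m = dr.x.size

    def rss_of(n: float) -> float:
        return float(np.sum(w * (dr.y - (1.0 - dr.x) ** n) ** 2))

    rss = {n: rss_of(n) for n in (1, 2, 3)}
    aic = {n: m * math.log(max(r, 1e-300) / m) + 2 for n, r in rss.items()}
    n_best = min(rss, key=lambda n: (rss[n], n))
    n_cont = None
    if fit_continuous:
        res = optimize.minimize_scalar(rss_of, bounds=(0.5, 5.0), method="bounded")
        n_cont = float(res.x)
    return BinomialFit(n_best=n_best, rss=rss, aic=aic, n_continuous=n_cont)
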