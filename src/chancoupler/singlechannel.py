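"""Single-channel idealization and coupled-gating classification.

A cell-attached patch holding a channel pair shows three conductance levels:
closed, one channel open (O1), both open (O2). Records are segmented into
fixed 0.2 ms segments, each segment labelled with the nearest level, and
openings are classified by how fast they reach the double level:

* **coupled** — the event reaches level 2 within the coupling window
  (0.4 ms = two segments from onset, inclusive), i.e. the dimer opened as one
  concerted unit;
* **uncoupled_stacked** — level 2 is reached later, i.e. two independent
  openings happen to overlap; tallied downstream as TWO level-1 openings
  (one at the event onset, one where the second channel joined);
* **single** — the event never leaves level 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthgen import SweepSet

__all__ = [
    "IdealizationParams",
    "LevelEstimate",
    "IdealizedSweep",
    "EventTable",
    "estimate_levels",
    "idealize",
    "extract_events",
    "openings_vs_time",
    "ensemble_average",
]

CLASSIFICATIONS = ("single", "coupled", "uncoupled_stacked")


@dataclass(frozen=True)
class IdealizationParams:
    """Segmentation and coupling-rule parameters.

    ``segment_ms`` is the fixed segment length (0.2 ms);
    ``coupling_window_segments`` is the largest 0-based offset from event
    onset to the first level-2 segment still called "coupled" (2 segments =
    0.4 ms, inclusive).
    """

    segment_ms: float = 0.2
    coupling_window_segments: int = 2

    def __post_init__(self) -> None:
        if self.segment_ms <= 0:
            raise ValueError("segment_ms must be > 0")
        if self.coupling_window_segments < 1:
            raise ValueError("coupling_window_segments must be >= 1")


@dataclass
class LevelEstimate:
    """Baseline and open-level amplitudes (pA) for a dimer patch."""

    baseline: float
    i1: float
    i2: float
    i2_extrapolated: bool = False

    def __post_init__(self) -> None:
        d1 = self.i1 - self.baseline
        d2 = self.i2 - self.baseline
        if abs(d2) <= abs(d1):
            raise ValueError("|i2 - baseline| must exceed |i1 - baseline|")
        if d1 * d2 <= 0:
            raise ValueError("i1 and i2 must lie on the same side of baseline")


@dataclass
class IdealizedSweep:
    """Per-segment conductance level labels (0 = closed, 1 = O1, 2 = O2)."""

    labels: np.ndarray
    segment_ms: float
    sweep_id: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not np.all(np.isin(self.labels, (0, 1, 2))):
            raise ValueError("labels must be in {0, 1, 2}")


@dataclass
class EventTable:
    """Classified channel openings.

    ``events`` columns: sweep_id, onset_segment, max_level,
    segments_to_level2 (NaN for level-1 events), classification,
    duration_segments, truncated.
    """

    events: pd.DataFrame
    segment_ms: float
    coupling_window_segments: int

    def counts(self) -> dict[str, int]:
        c = self.events["classification"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in CLASSIFICATIONS}

    @property
    def total_openings(self) -> int:
        """Openings under the tally rule: singles + coupled + 2x stacked."""
        c = self.counts()
        return c["single"] + c["coupled"] + 2 * c["uncoupled_stacked"]


def _robust_sd(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def estimate_levels(sweeps: SweepSet) -> LevelEstimate:
    """Estimate baseline and the two open-level amplitudes from pooled samples.

    The baseline is the mode of the all-points amplitude histogram (the patch
    is closed most of the time, so the median pins it); openings are samples
    beyond a noise exclusion band of 3x the robust (MAD-based) noise SD on
    the signal-polarity side. The two most populated local modes of the
    open-sample histogram give i1 and i2, each refined as the mean of its
    assigned samples. If only one open mode exists, i2 is extrapolated as
    2 x i1 under the dimer assumption and flagged.
    """
    pooled = np.asarray(sweeps.sweeps, dtype=float).ravel()
    if pooled.size == 0:
        raise ValueError("empty sweep set")
    baseline = float(np.median(pooled))
    sd = _robust_sd(pooled)
    band = 3.0 * sd
    dev = pooled - baseline
    beyond = np.abs(dev) > band
    if not np.any(beyond):
        raise ValueError("no openings detected")
    polarity = np.sign(dev[beyond][np.argmax(np.abs(dev[beyond]))])
    open_amps = dev[beyond & (np.sign(dev) == polarity)]
    if open_amps.size == 0:
        raise ValueError("no openings detected")
    baseline = float(np.mean(pooled[~beyond])) if np.any(~beyond) else baseline

    mags = np.abs(open_amps)
    width = max(sd, mags.max() / 128.0, 1e-12)
    edges = np.arange(0.0, mags.max() + 2 * width, width)
    hist, _ = np.histogram(mags, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # local maxima of the open-amplitude histogram
    peaks = [
        j
        for j in range(len(hist))
        if hist[j] > 0
        and (j == 0 or hist[j] >= hist[j - 1])
        and (j == len(hist) - 1 or hist[j] > hist[j + 1])
    ]
    peaks.sort(key=lambda j: -hist[j])
    modes = []
    for j in peaks:
        # suppress peaks within one unit-level spacing of an accepted mode
        if all(abs(centers[j] - m) > max(3 * width, 0.3 * centers[j]) for m in modes):
            modes.append(centers[j])
        if len(modes) == 2:
            break
    modes.sort()
    if len(modes) == 2:
        m1, m2 = modes
        mid = 0.5 * (m1 + m2)
        i1 = float(np.mean(mags[mags <= mid]))
        i2 = float(np.mean(mags[mags > mid]))
        extrap = False
    else:
        i1 = float(np.mean(mags))
        i2 = 2.0 * i1
        extrap = True
    return LevelEstimate(
        baseline=baseline,
        i1=baseline + polarity * i1,
        i2=baseline + polarity * i2,
        i2_extrapolated=extrap,
    )


def idealize(
    sweeps: SweepSet, levels: LevelEstimate, params: IdealizationParams
) -> list[IdealizedSweep]:
    """Assign each fixed-length segment to the nearest conductance level.

    Every sample is matched to the nearest of {baseline, i1, i2} (labels
    0/1/2; exact ties break toward the lower level) and each segment takes
    the majority label of its samples (again ties toward the lower level).
    On a segment occupied by a single level this reduces to assigning the
    segment's mean current to the nearest level. A trailing partial segment
    is dropped.
    """
    spp = round(params.segment_ms * sweeps.protocol.sample_rate_hz / 1000.0)
    if spp < 2:
        raise ValueError("segment_ms must span >= 2 sample periods")
    n_seg = sweeps.sweeps.shape[1] // spp
    if n_seg < 1:
        raise ValueError("sweeps shorter than one segment")
    targets = np.array([levels.baseline, levels.i1, levels.i2])
    dist = np.abs(sweeps.sweeps[..., None] - targets[None, None, :])
    # argmin picks the lowest index on ties -> tie toward the lower level
    sample_labels = dist.argmin(axis=2)
    seg = sample_labels[:, : n_seg * spp].reshape(sweeps.sweeps.shape[0], n_seg, spp)
    counts = (seg[..., None] == np.arange(3)).sum(axis=2)
    labels = counts.argmax(axis=2).astype(np.int8)
    return [
        IdealizedSweep(labels=labels[k], segment_ms=params.segment_ms, sweep_id=k)
        for k in range(labels.shape[0])
    ]


def extract_events(
    ideal: list[IdealizedSweep], params: IdealizationParams
) -> EventTable:
    """Find openings in idealized sweeps and classify their coupling.

    An event opens at the first nonzero label after a closed segment (or
    sweep start) and closes at the next closed segment. Events reaching level
    2 within ``coupling_window_segments`` of onset (0-based, inclusive) are
    "coupled"; later level-2 arrivals are "uncoupled_stacked" (two
    independent openings overlapping); pure level-1 events are "single".
    Events cut off by sweep end keep their classification and are flagged
    truncated.
    """
    rows = []
    for sw in ideal:
        labels = sw.labels
        n = labels.size
        k = 0
        while k < n:
            if labels[k] == 0:
                k += 1
                continue
            onset = k
            while k < n and labels[k] != 0:
                k += 1
            seg = labels[onset:k]
            max_level = int(seg.max())
            if max_level == 2:
                off = int(np.argmax(seg == 2))
                cls = (
                    "coupled"
                    if off <= params.coupling_window_segments
                    else "uncoupled_stacked"
                )
                s2l = off
            else:
                cls = "single"
                s2l = np.nan
            rows.append(
                (sw.sweep_id, onset, max_level, s2l, cls, k - onset, k == n)
            )
    events = pd.DataFrame(
        rows,
        columns=[
            "sweep_id",
            "onset_segment",
            "max_level",
            "segments_to_level2",
            "classification",
            "duration_segments",
            "truncated",
        ],
    )
    return EventTable(
        events=events,
        segment_ms=params.segment_ms,
        coupling_window_segments=params.coupling_window_segments,
    )


def openings_vs_time(
    events: EventTable, bin_ms: float, step_ms: float
) -> pd.DataFrame:
    """Histogram of level-1 and level-2 opening onsets over the step.

    Level-2 counts are coupled events binned by onset time. Level-1 counts
    are single events plus two entries per uncoupled_stacked event (its onset
    and the segment where the second channel joined). Bins tile
    ``[0, step_ms)``; columns: bin_start_ms, level1, level2.
    """
    if bin_ms < events.segment_ms:
        raise ValueError("bin_ms must be >= segment_ms")
    edges = np.arange(0.0, step_ms + bin_ms, bin_ms)
    edges = edges[edges <= step_ms + 1e-9]
    if edges[-1] < step_ms:
        edges = np.append(edges, step_ms)
    df = events.events
    onset_t = df["onset_segment"].to_numpy(float) * events.segment_ms
    if np.any(onset_t >= step_ms):
        raise ValueError("events reference segments beyond step_ms")
    lvl2_t = onset_t[df["classification"] == "coupled"]
    stacked = df["classification"] == "uncoupled_stacked"
    lvl1_t = np.concatenate(
        [
            onset_t[df["classification"] == "single"],
            onset_t[stacked],
            (
                df.loc[stacked, "onset_segment"].to_numpy(float)
                + df.loc[stacked, "segments_to_level2"].to_numpy(float)
            )
            * events.segment_ms,
        ]
    )
    h1, _ = np.histogram(lvl1_t, bins=edges)
    h2, _ = np.histogram(lvl2_t, bins=edges)
    return pd.DataFrame(
        {"bin_start_ms": edges[:-1], "level1": h1, "level2": h2}
    )


def ensemble_average(sweeps: SweepSet) -> np.ndarray:
    """Pointwise mean current across sweeps (pA) — the macroscopic ensemble."""
    arr = np.asarray(sweeps.sweeps, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need >= 1 sweep with consistent shape")
    return arr.mean(axis=0)
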