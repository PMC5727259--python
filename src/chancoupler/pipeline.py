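"""End-to-end pipeline runner: generation -> analysis -> report.

A :class:`RunConfig` selects stages and carries every generator and analysis
parameter plus one explicit seed; :func:`run_pipeline` executes the selected
stages in dependency order, writes every intermediate table under the output
directory and returns a :class:`RunReport` sufficient to re-run identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, biophys, io, singlechannel, stoichiometry, synthgen

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

log = logging.getLogger("chancoupler")

STAGES = ("sweeps", "bleach", "dn", "gating", "fret")

_KNOWN_KEYS = {
    "stages",
    "seed",
    "out_dir",
    "gating_model",
    "protocol",
    "bleach_params",
    "dn",
    "gating_curve",
    "idealization",
    "p_active",
    "n_max",
    "min_step_fraction",
    "fret_records",
    "fret_a",
    "fret_b",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (one explicit seed per run)."""

    stages: list[str]
    seed: int
    out_dir: str
    gating_model: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    bleach_params: dict = field(default_factory=dict)
    dn: dict = field(default_factory=lambda: {"n": 2, "ratios": [0, 1/11, 1/5, 1/2, 4/5, 10/11, 1], "noise_sd": 0.0})
    gating_curve: dict = field(
        default_factory=lambda: {"v_half": -85.0, "slope_k": -6.0, "noise_sd": 0.0,
                                 "voltages": list(range(-140, -25, 5))}
    )
    idealization: dict = field(default_factory=dict)
    p_active: float = 0.7
    n_max: int = 6
    min_step_fraction: float = 0.5
    fret_records: list = field(default_factory=list)
    fret_a: float = 0.29
    fret_b: float = 0.04

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "seed" not in d:
            raise ValueError("config must set an explicit seed")
        bad = [s for s in d.get("stages", []) if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage(s) {bad}; valid: {STAGES}")
        return cls(
            stages=list(d.get("stages", list(STAGES))),
            seed=int(d["seed"]),
            out_dir=str(d.get("out_dir", ".")),
            **{k: d[k] for k in d if k not in ("stages", "seed", "out_dir")},
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class RunReport:
    stages: dict[str, dict]
    seed: int
    version: str
    config_echo: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str), encoding="utf-8")


def _stage_sweeps(cfg: RunConfig, out: Path, results: dict) -> None:
    model = synthgen.GatingModel(**cfg.gating_model)
    protocol = synthgen.StepProtocol(**cfg.protocol)
    sweeps = synthgen.simulate_sweeps(model, protocol, seed=cfg.seed)
    io.write_sweepset(sweeps, out / "sweeps.csv")
    params = singlechannel.IdealizationParams(**cfg.idealization)
    levels = singlechannel.estimate_levels(sweeps)
    ideal = singlechannel.idealize(sweeps, levels, params)
    pd.DataFrame(
        [
            (sw.sweep_id, k, int(lv))
            for sw in ideal
            for k, lv in enumerate(sw.labels)
        ],
        columns=["sweep_id", "segment_index", "level"],
    ).to_csv(out / "idealized.csv", index=False)
    events = singlechannel.extract_events(ideal, params)
    events.events.to_csv(out / "events.csv", index=False)
    hist = singlechannel.openings_vs_time(events, bin_ms=1.0, step_ms=protocol.step_ms)
    hist.to_csv(out / "openings_hist.csv", index=False)
    avg = singlechannel.ensemble_average(sweeps)
    pd.DataFrame({"time_ms": sweeps.time_ms, "mean_pA": avg}).to_csv(
        out / "ensemble.csv", index=False, float_format="%.6g"
    )
    results["levels"] = asdict(levels)
    results["event_counts"] = events.counts()


def _stage_bleach(cfg: RunConfig, out: Path, results: dict) -> None:
    params = synthgen.BleachPopulationParams(**cfg.bleach_params)
    traces = synthgen.simulate_bleach_population(params, seed=cfg.seed)
    io.write_bleach_traces(traces, out / "bleach.csv")
    counts = [
        stoichiometry.detect_steps(tr, cfg.min_step_fraction)[0]
        for tr in traces
        if tr.detectable
    ]
    n_dark = sum(not tr.detectable for tr in traces)
    hist = stoichiometry.step_histogram(counts + [0] * n_dark)
    fit = stoichiometry.fit_subunit_count(hist, p_active=cfg.p_active, n_max=cfg.n_max)
    pd.DataFrame(
        sorted(hist.counts.items()), columns=["step_count", "n_molecules"]
    ).to_csv(out / "step_histogram.csv", index=False)
    results["step_histogram"] = {str(k): v for k, v in sorted(hist.counts.items())}
    results["n_undetected"] = hist.n_undetected
    results["n_hat"] = fit.n_hat


def _stage_dn(cfg: RunConfig, out: Path, results: dict) -> None:
    d = dict(cfg.dn)
    dr = synthgen.simulate_dose_response(
        n=d.get("n", 2), ratios=d.get("ratios"), noise_sd=d.get("noise_sd", 0.0), seed=cfg.seed
    )
    io.write_dose_response(dr, out / "dose_response.csv")
    fit = stoichiometry.fit_binomial_exponent(dr)
    results["n_best"] = fit.n_best
    results["rss"] = {str(k): v for k, v in fit.rss.items()}
    results["n_continuous"] = fit.n_continuous


def _stage_gating(cfg: RunConfig, out: Path, results: dict) -> None:
    g = dict(cfg.gating_curve)
    curve = synthgen.simulate_gating_curve(
        v_half=g["v_half"],
        slope_k=g["slope_k"],
        voltages=g["voltages"],
        noise_sd=g.get("noise_sd", 0.0),
        seed=cfg.seed,
        kind=g.get("kind", "ssi"),
    )
    io.write_gating_curve(curve, out / "gating_curve.csv")
    fit = biophys.fit_boltzmann(curve)
    results["v_half"] = fit.v_half
    results["slope_k"] = fit.slope_k
    results["rss"] = fit.rss


def _stage_fret(cfg: RunConfig, out: Path, results: dict) -> None:
    records = cfg.fret_records or [[100.0, 100.0, 100.0]]
    rows = []
    for rec in records:
        fr = biophys.fret_correct(
            biophys.FretRecord(
                fret_raw=rec[0], cfp=rec[1], yfp=rec[2], a=cfg.fret_a, b=cfg.fret_b
            )
        )
        rows.append((fr.fret_raw, fr.cfp, fr.yfp, fr.fretc))
    pd.DataFrame(rows, columns=["fret", "cfp", "yfp", "fretc"]).to_csv(
        out / "fretc.csv", index=False, float_format="%.6g"
    )
    results["fretc"] = [r[3] for r in rows]


_STAGE_FN = {
    "sweeps": _stage_sweeps,
    "bleach": _stage_bleach,
    "dn": _stage_dn,
    "gating": _stage_gating,
    "fret": _stage_fret,
}


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the selected stages in dependency order and write a report.

    Each stage writes its tables under ``config.out_dir``; any stage failure
    aborts with the stage name while earlier outputs are retained. Seeds and
    parameter echoes are logged at INFO.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline seed=%d stages=%s", config.seed, config.stages)
    stage_reports: dict[str, dict] = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        results: dict = {}
        try:
            _STAGE_FN[stage](config, out, results)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        results["wall_clock_s"] = round(time.perf_counter() - t0, 4)
        log.info("stage %s done in %.2fs", stage, results["wall_clock_s"])
        stage_reports[stage] = results
    report = RunReport(
        stages=stage_reports,
        seed=config.seed,
        version=__version__,
        config_echo=asdict(config),
    )
    report.to_json(out / "report.json")
    return report
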