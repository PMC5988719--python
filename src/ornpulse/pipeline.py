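"""Config-driven end-to-end experiment runs.

A run is described by a structured config (YAML/JSON): which experiment
to run, generator parameters (or input paths), analysis parameters, and
a stats plan. One top-level seed is expanded deterministically into
per-stage child seeds via ``numpy.random.SeedSequence``; identical
configs therefore produce identical outputs.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behavior, stats, synthetic, trace_analysis
from .imaging_io import load_trace_table, write_trace_table

log = logging.getLogger("ornpulse")

EXPERIMENTS = ("prior_activity", "pulse_response", "continuous_response", "choice_assay")


@dataclass
class RunConfig:
    experiment: str
    groups: dict[str, dict]  # group name -> generator overrides or {'traces': path}
    n_per_group: int = 20
    analysis: dict = field(default_factory=dict)
    stats_plan: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "ornpulse_out"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"config error at 'experiment': {self.experiment!r} not in {EXPERIMENTS}"
            )
        if not self.groups:
            raise ValueError("config error at 'groups': at least one group required")
        for name, spec in self.groups.items():
            if not isinstance(spec, dict):
                raise ValueError(f"config error at 'groups.{name}': expected a mapping")
            if "traces" in spec and len(spec) > 1:
                raise ValueError(
                    f"config error at 'groups.{name}': give either an input path "
                    "or generator parameters, not both"
                )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        known = {"experiment", "groups", "n_per_group", "analysis", "stats_plan", "seed", "out_dir"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"config error: unknown fields {sorted(unknown)}")
        return cls(**data)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n)]


def _simulate_group_traces(spec: dict, n: int, seeds: list[int]):
    traces, truths = [], []
    for s in seeds[:n]:
        params = synthetic.CalciumSimParams(**spec, seed=s)
        tr, gt = synthetic.simulate_calcium_trace(params)
        traces.append(tr)
        truths.append(gt)
    return traces, truths


def _prior_activity(cfg: RunConfig, out: Path) -> None:
    analysis = cfg.analysis
    multiplier = analysis.get("multiplier", 2.0)
    group_seeds = _child_seeds(cfg.seed, len(cfg.groups))
    freq_by_group: dict[str, list[float]] = {}
    rows = []
    for (name, spec), gseed in zip(cfg.groups.items(), group_seeds):
        if "traces" in spec:
            traces = load_trace_table(spec["traces"])
        else:
            traces, _ = _simulate_group_traces(spec, cfg.n_per_group, _child_seeds(gseed, cfg.n_per_group))
        freqs = []
        for tr in traces:
            dff = trace_analysis.compute_dff(tr, mode="prior")
            ev = trace_analysis.detect_events(dff, multiplier=multiplier)
            f = trace_analysis.event_frequency(ev, tr.duration)
            freqs.append(f)
            rows.append((name, tr.label, ev.n_events, f))
        freq_by_group[name] = freqs
        write_trace_table(traces, out / f"traces_{name}.tsv")
    pd.DataFrame(rows, columns=["group", "trace", "n_events", "frequency_hz"]).to_csv(
        out / "metrics.tsv", sep="\t", index=False
    )
    _pairwise_ranksum(cfg, freq_by_group, out, default_adjust="bonferroni")
    box_rows = []
    for name, freqs in freq_by_group.items():
        b = stats.box_summary(freqs)
        box_rows.append((name, b.median, b.q1, b.q3, b.whisker_low, b.whisker_high, len(b.outliers)))
    pd.DataFrame(
        box_rows,
        columns=["group", "median", "q1", "q3", "whisker_low", "whisker_high", "n_outliers"],
    ).to_csv(out / "box_summaries.tsv", sep="\t", index=False)


def _stim_response(cfg: RunConfig, out: Path, continuous: bool) -> None:
    analysis = cfg.analysis
    post_window = analysis.get("post_window", 10.0)
    protocol_spec = analysis.get(
        "protocol",
        {"mode": "continuous", "onsets": [5.0], "durations": [18.0]}
        if continuous
        else {"mode": "pulse", "onsets": [5.0, 15.0, 25.0, 35.0], "durations": [2.0]},
    )
    protocol = trace_analysis.StimulusProtocol(**protocol_spec)
    group_seeds = _child_seeds(cfg.seed, len(cfg.groups))
    metrics_by_group: dict[str, list[trace_analysis.ResponseMetrics]] = {}
    rows = []
    for (name, spec), gseed in zip(cfg.groups.items(), group_seeds):
        if "traces" in spec:
            traces = load_trace_table(spec["traces"])
        else:
            traces = []
            for s in _child_seeds(gseed, cfg.n_per_group):
                params = synthetic.StimSimParams(protocol=protocol, **spec, seed=s)
                traces.append(synthetic.simulate_stim_response_trace(params))
        group_metrics = []
        baseline_mode = analysis.get("baseline_mode", "prior")
        for tr in traces:
            dff = trace_analysis.compute_dff(tr, mode=baseline_mode, protocol=protocol)
            m = trace_analysis.response_metrics(dff, protocol, post_window=post_window)
            group_metrics.append(m)
            rows.append(
                (
                    name,
                    tr.label,
                    100.0 * m.dff_max,
                    100.0 * m.undershoot,
                    m.return_time if m.return_time is not None else "not_reached",
                )
            )
        metrics_by_group[name] = group_metrics
        write_trace_table(traces, out / f"traces_{name}.tsv")
    pd.DataFrame(
        rows, columns=["group", "trace", "dff_max_pct", "undershoot_pct", "return_time_s"]
    ).to_csv(out / "metrics.tsv", sep="\t", index=False)
    maxima = {g: [m.dff_max for m in ms] for g, ms in metrics_by_group.items()}
    _pairwise_ranksum(cfg, maxima, out, default_adjust="bonferroni")


def _choice_assay(cfg: RunConfig, out: Path) -> None:
    analysis = cfg.analysis
    band_width = analysis.get("band_width", 0.5)
    arena = behavior.ArenaConfig(**analysis.get("arena", {}))
    group_seeds = _child_seeds(cfg.seed, len(cfg.groups))
    probs_by_group: dict[str, behavior.BoundaryProbabilities] = {}
    pi_rows = []
    for (name, spec), gseed in zip(cfg.groups.items(), group_seeds):
        params = synthetic.BehaviorSimParams(arena=arena, band_width=band_width, **spec, seed=gseed)
        ts, _ = synthetic.simulate_trajectories(params)
        ts.write(out / f"trajectories_{name}.tsv")
        pi = behavior.performance_index(ts, arena, band_width=0.0)
        events = behavior.detect_boundary_events(ts, arena, band_width=band_width)
        behavior.events_to_table(events).to_csv(
            out / f"boundary_events_{name}.tsv", sep="\t", index=False
        )
        probs = behavior.boundary_probabilities(events)
        probs_by_group[name] = probs
        pi_rows.append((name, pi.pi, pi.n_light, pi.n_dark, pi.n_total, pi.n_larvae))
    pd.DataFrame(
        pi_rows, columns=["group", "pi", "n_light", "n_dark", "n_total", "n_larvae"]
    ).to_csv(out / "performance_index.tsv", sep="\t", index=False)

    names = list(probs_by_group)
    rows = []
    if len(names) >= 2:
        plan = cfg.stats_plan
        method = plan.get("adjust", "benjamini_hochberg")
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
        results = []
        for a, b in pairs:
            for side in ("lit", "dark"):
                table = behavior.approach_count_table(probs_by_group[a], probs_by_group[b], side)
                res = stats.fisher_exact_test(table)
                results.append((f"{a} vs {b} ({side} side)", res))
        m = plan.get("m", len(results))
        adjusted = stats.adjust_pvalues([r.p_raw for _, r in results], method, m=m)
        for (label, res), p_adj in zip(results, adjusted):
            rows.append((label, res.test_name, res.statistic, res.p_raw, p_adj, method, *res.n_per_group))
    table_rows = [
        (
            g,
            p.p_enter_lit if p.p_enter_lit is not None else "undefined",
            p.n_dark_approaches,
            p.p_turn_back if p.p_turn_back is not None else "undefined",
            p.n_lit_approaches,
        )
        for g, p in probs_by_group.items()
    ]
    pd.DataFrame(
        table_rows,
        columns=["group", "p_enter_lit", "n_dark_approaches", "p_turn_back", "n_lit_approaches"],
    ).to_csv(out / "boundary_probabilities.tsv", sep="\t", index=False)
    if rows:
        pd.DataFrame(
            rows,
            columns=["comparison", "test", "statistic", "p_raw", "p_adjusted", "method", "n1", "n2"],
        ).to_csv(out / "stats.tsv", sep="\t", index=False)


def _pairwise_ranksum(cfg: RunConfig, samples: dict[str, list[float]], out: Path, default_adjust: str) -> None:
    names = list(samples)
    if len(names) < 2:
        return
    plan = cfg.stats_plan
    method = plan.get("adjust", default_adjust)
    mode = plan.get("mode", "auto")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    results = [(f"{a} vs {b}", stats.rank_sum_test(samples[a], samples[b], mode=mode)) for a, b in pairs]
    m = plan.get("m", len(results))
    adjusted = stats.adjust_pvalues([r.p_raw for _, r in results], method, m=m)
    rows = [
        (label, res.test_name, res.statistic, res.p_raw, p_adj, method, *res.n_per_group)
        for (label, res), p_adj in zip(results, adjusted)
    ]
    pd.DataFrame(
        rows, columns=["comparison", "test", "statistic", "p_raw", "p_adjusted", "method", "n1", "n2"]
    ).to_csv(out / "stats.tsv", sep="\t", index=False)


def run_experiment(cfg: RunConfig) -> Path:
    """Run one configured experiment; returns the output directory.

    Outputs: metric tables, a stats table, group summaries, a run
    manifest (config + seed + version) and a log file. Partial outputs
    are removed if the run fails.
    """
    out = Path(cfg.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("experiment=%s seed=%d groups=%s", cfg.experiment, cfg.seed, list(cfg.groups))
        if cfg.experiment == "prior_activity":
            _prior_activity(cfg, out)
        elif cfg.experiment == "pulse_response":
            _stim_response(cfg, out, continuous=False)
        elif cfg.experiment == "continuous_response":
            _stim_response(cfg, out, continuous=True)
        else:
            _choice_assay(cfg, out)
        manifest = {
            "config": {
                "experiment": cfg.experiment,
                "groups": cfg.groups,
                "n_per_group": cfg.n_per_group,
                "analysis": cfg.analysis,
                "stats_plan": cfg.stats_plan,
                "seed": cfg.seed,
            },
            "version": __version__,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        log.info("run complete")
    except Exception:
        log.exception("run failed; removing partial outputs")
        log.removeHandler(handler)
        handler.close()
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for f in out.iterdir():
                if f.suffix in (".tsv", ".json", ".log"):
                    f.unlink()
        raise
    finally:
        if handler in log.handlers:
            log.removeHandler(handler)
            handler.close()
    return out
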