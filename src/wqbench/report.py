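"""End-to-end benchmarking experiment: populations -> sub-samples -> inference
-> second-order metrics -> status classification.

One :func:`run_experiment` call reproduces, on synthetic (or user-supplied)
populations, the full comparison: sampling-distribution summaries per
monitoring scheme, second-order uncertainty summaries (hit rate, HDI95,
RMBE) per Bayesian method, and status-classification frequencies per
method against the benchmark status of the full record.

Seeds are derived per (population, scheme, stage, replicate) from the
master seed with a counter-based scheme, so increasing ``reps`` never
reshuffles earlier replicates and stages are independently reproducible.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import bayes_infer, classify, metrics, subsampling, synthetic_data
from .bayes_infer import PriorSpec
from .classify import IRISH_TRP_BOUNDARIES, ClassBoundaries, StatusClass
from .subsampling import OM, SM, MonitoringScheme
from .synthetic_data import PopulationSeries

__all__ = ["ExperimentConfig", "run_experiment", "read_series_csv", "derive_seed"]

log = logging.getLogger("wqbench")

_SCHEMES = {"OM": OM, "SM": SM}
_METHODS = ("face_value", "t_test_right", "t_test_left", "lognormal", "bayesian_bootstrap")
_BAYES_METHODS = ("lognormal", "bayesian_bootstrap")


def derive_seed(master: int, *parts) -> int:
    """Deterministic sub-seed below 2^31 from a master seed and labels."""
    ints = [int(master) & 0x7FFFFFFF]
    for p in parts:
        if isinstance(p, str):
            ints.append(zlib.crc32(p.encode()))
        else:
            ints.append(int(p) & 0xFFFFFFFF)
    return int(np.random.SeedSequence(ints).generate_state(1)[0]) & 0x7FFFFFFF


@dataclass(frozen=True)
class ExperimentConfig:
    """Protocol constants of the benchmarking experiment.

    Defaults mirror the regulatory protocol: 10,000 sub-sample replicates,
    OM (5x3) and SM (12x3) schemes, 1000 posterior draws, alpha = 0.01.
    """

    presets: tuple[str, ...] = ("good_near_boundary", "moderate_far")
    csv_paths: tuple[str, ...] = ()
    schemes: tuple[str, ...] = ("OM", "SM")
    reps: int = 10_000
    n_draws: int = 1000
    methods: tuple[str, ...] = _METHODS
    quantile_rule: str = "linear"
    prior: PriorSpec = field(default_factory=PriorSpec)
    boundaries: ClassBoundaries = field(default_factory=lambda: IRISH_TRP_BOUNDARIES)
    alpha: float = 0.01
    seed: int = 0
    n_hours: int = synthetic_data.HOURS_3_YEARS

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")
        unknown = set(self.methods) - set(_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}; choose from {_METHODS}")
        unknown = set(self.schemes) - set(_SCHEMES)
        if unknown:
            raise ValueError(f"unknown schemes {sorted(unknown)}")
        for name in self.presets:
            synthetic_data.preset_scenario(name)  # raises on unknown preset
        for path in self.csv_paths:
            if not Path(path).exists():
                raise FileNotFoundError(f"input series not found: {path}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("presets", "csv_paths", "schemes", "methods"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("reps", "n_draws", "seed", "n_hours"):
            if key in raw:
                kwargs[key] = int(raw[key])
        for key in ("alpha",):
            if key in raw:
                kwargs[key] = float(raw[key])
        if "quantile_rule" in raw:
            kwargs["quantile_rule"] = str(raw["quantile_rule"])
        if "prior" in raw:
            kwargs["prior"] = PriorSpec(
                mu_bounds=tuple(raw["prior"]["mu_bounds"]),
                sigma_bounds=tuple(raw["prior"]["sigma_bounds"]),
            )
        if "boundaries" in raw:
            kwargs["boundaries"] = ClassBoundaries.from_dict(raw["boundaries"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "presets": list(self.presets),
            "csv_paths": list(self.csv_paths),
            "schemes": list(self.schemes),
            "reps": self.reps,
            "n_draws": self.n_draws,
            "methods": list(self.methods),
            "quantile_rule": self.quantile_rule,
            "prior": {
                "mu_bounds": list(self.prior.mu_bounds),
                "sigma_bounds": list(self.prior.sigma_bounds),
            },
            "boundaries": self.boundaries.to_dict(),
            "alpha": self.alpha,
            "seed": self.seed,
            "n_hours": self.n_hours,
        }


def read_series_csv(path) -> PopulationSeries:
    """Parse a ``timestamp,concentration_mgP_L`` CSV into a population series."""
    frame = pd.read_csv(path, float_precision="round_trip")
    expected = ["timestamp", "concentration_mgP_L"]
    if list(frame.columns) != expected:
        raise ValueError(f"{path}: expected header {','.join(expected)!r}, got {list(frame.columns)}")
    if len(frame) == 0:
        raise ValueError(f"{path}: empty data section")
    conc = pd.to_numeric(frame["concentration_mgP_L"], errors="coerce")
    bad = frame.index[conc.isna() | (conc <= 0)]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:20])  # +2: header plus 1-based
        raise ValueError(f"{path}: nonpositive or unparseable concentration on rows {rows}")
    timestamps = pd.DatetimeIndex(pd.to_datetime(frame["timestamp"]))
    return PopulationSeries(timestamps=timestamps, values=conc.to_numpy(dtype=float))


def _posterior(method: str, sample: np.ndarray, config: ExperimentConfig, seed: int):
    if method == "lognormal":
        return bayes_infer.lognormal_posterior(
            sample, n_draws=config.n_draws, prior=config.prior, seed=seed
        )
    return bayes_infer.bayesian_bootstrap(sample, n_draws=config.n_draws, seed=seed)


def _frequencies(statuses: Sequence[StatusClass]) -> dict:
    n = len(statuses)
    return {
        cls.name: 100.0 * sum(s == cls for s in statuses) / n
        for cls in (StatusClass.High, StatusClass.Good, StatusClass.Moderate)
    }


def _quantile_box(values: np.ndarray) -> dict:
    probs = {"q2.5": 0.025, "q25": 0.25, "median": 0.5, "q75": 0.75, "q97.5": 0.975}
    return {k: float(np.quantile(values, p)) for k, p in probs.items()}


def _run_scheme(
    series: PopulationSeries,
    pop_name: str,
    scheme: MonitoringScheme,
    config: ExperimentConfig,
    benchmark: dict,
) -> dict:
    t0 = time.perf_counter()
    section: dict = {}

    # --- sampling-distribution summaries
    sampling = {}
    for which in ("mean", "q95"):
        dist = subsampling.subsample_statistics(
            series, scheme, config.reps,
            derive_seed(config.seed, pop_name, scheme.name, "subsample"),
            which, config.quantile_rule,
        )
        s = subsampling.summarize_sampling(dist)
        sampling[which] = {
            "bias": s.bias, "skewness": s.skewness, "hdi95_width": s.hdi95_width,
        }
    section["sampling"] = sampling
    log.info("%s/%s sampling distributions done in %.1fs", pop_name, scheme.name,
             time.perf_counter() - t0)

    # --- one shared set of sub-samples for inference and classification
    subs = subsampling.draw_subsamples(
        series, scheme, config.reps,
        derive_seed(config.seed, pop_name, scheme.name, "subsample"),
    )
    benchmark_status = StatusClass[benchmark["status"]]

    second_order: dict = {}
    classification: dict = {}
    class_prob_box: dict = {}

    for method in config.methods:
        t1 = time.perf_counter()
        if method in _BAYES_METHODS:
            pairs_mean, pairs_q95, statuses = [], [], []
            probs_hgm = []
            for sub in subs:
                post = _posterior(
                    method, sub.values, config,
                    derive_seed(config.seed, pop_name, scheme.name, method, sub.replicate),
                )
                for which, draws, pairs in (
                    ("mean", post.draws_mean, pairs_mean),
                    ("q95", post.draws_q95, pairs_q95),
                ):
                    pairs.append(
                        (metrics.hdi(draws, 0.95), metrics.rmbe(draws, benchmark[which]))
                    )
                cp = classify.bayes_class_probabilities(post, config.boundaries)
                probs_hgm.append((cp.p_high, cp.p_good, cp.p_moderate))
                statuses.append(cp.argmax_status())
            second_order[method] = {
                "mean": metrics.summarize_second_order(pairs_mean, benchmark["mean"]).to_dict(),
                "q95": metrics.summarize_second_order(pairs_q95, benchmark["q95"]).to_dict(),
            }
            probs_arr = np.asarray(probs_hgm)
            class_prob_box[method] = {
                "High": _quantile_box(probs_arr[:, 0]),
                "Good": _quantile_box(probs_arr[:, 1]),
                "Moderate": _quantile_box(probs_arr[:, 2]),
            }
        elif method == "face_value":
            statuses = [
                classify.face_value_status(sub.values, config.boundaries, config.quantile_rule)
                for sub in subs
            ]
        else:  # t_test_right / t_test_left
            tail = method.split("_")[-1]
            statuses = [
                classify.t_test_status(sub.values, config.boundaries, config.alpha, tail)
                for sub in subs
            ]
        mg = classify.misgrade_frequency(statuses, benchmark_status)
        classification[method] = {
            "frequencies": _frequencies(statuses),
            "misgrade": {
                "percent_correct": mg.percent_correct,
                "percent_over": mg.percent_over,
                "percent_under": mg.percent_under,
            },
        }
        log.info("%s/%s method %s done in %.1fs", pop_name, scheme.name, method,
                 time.perf_counter() - t1)

    section["second_order"] = second_order
    section["classification"] = classification
    if class_prob_box:
        section["class_probabilities"] = class_prob_box
    return section


def _load_populations(config: ExperimentConfig) -> list[tuple[str, PopulationSeries]]:
    populations = []
    for name in config.presets:
        preset = synthetic_data.preset_scenario(name)
        series = synthetic_data.generate_population(
            preset.spec, config.n_hours, derive_seed(config.seed, name, "population")
        )
        populations.append((name, series))
    for path in config.csv_paths:
        populations.append((Path(path).stem, read_series_csv(path)))
    return populations


def run_experiment(config: ExperimentConfig, out_dir=None) -> dict:
    """Run the full benchmark and return (and optionally write) the report bundle."""
    t_start = time.perf_counter()
    report: dict = {"config": config.to_dict(), "populations": {}}
    for pop_name, series in _load_populations(config):
        mean, q95 = synthetic_data.benchmark_statistics(series, config.quantile_rule)
        status = classify.combine_status(
            classify.classify_statistic(mean, "mean", config.boundaries),
            classify.classify_statistic(q95, "q95", config.boundaries),
        )
        benchmark = {"mean": mean, "q95": q95, "status": status.name}
        pop_section: dict = {"benchmark": benchmark, "schemes": {}}
        for scheme_name in config.schemes:
            pop_section["schemes"][scheme_name] = _run_scheme(
                series, pop_name, _SCHEMES[scheme_name], config, benchmark
            )
        report["populations"][pop_name] = pop_section
    log.info("experiment finished in %.1fs", time.perf_counter() - t_start)

    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: dict, out_dir) -> None:
    """Write the JSON bundle plus flat CSV tables mirroring the report sections."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    sampling_rows, second_rows, class_rows = [], [], []
    for pop, psec in report["populations"].items():
        for scheme, ssec in psec["schemes"].items():
            for which, s in ssec["sampling"].items():
                sampling_rows.append({"population": pop, "scheme": scheme, "statistic": which, **s})
            for method, per_stat in ssec.get("second_order", {}).items():
                for which, summary in per_stat.items():
                    second_rows.append({
                        "population": pop, "scheme": scheme, "method": method,
                        "statistic": which,
                        "hit_rate_percent": summary["hit_rate_percent"],
                        **{f"hdi95_width_{k}": v for k, v in summary["hdi95_width_mgP_L"].items()},
                        **{f"rmbe_{k}": v for k, v in summary["rmbe_percent"].items()},
                    })
            for method, c in ssec["classification"].items():
                class_rows.append({
                    "population": pop, "scheme": scheme, "method": method,
                    **{f"percent_{k}": v for k, v in c["frequencies"].items()},
                    **c["misgrade"],
                })
    pd.DataFrame(sampling_rows).to_csv(out / "sampling_summary.csv", index=False)
    if second_rows:
        pd.DataFrame(second_rows).to_csv(out / "second_order_summary.csv", index=False)
    pd.DataFrame(class_rows).to_csv(out / "classification_summary.csv", index=False)
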