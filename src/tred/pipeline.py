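"""End-to-end assay orchestration.

Runs the stages simulate/track → msd → popfit → hmm → report, persisting
every intermediate artifact (CSV/JSON/TIFF) under one output directory so
each number in the final report is recomputable from disk.  Deterministic
given the config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__, io, msd, stats
from .hmm import select_state_count, windowed_transitions
from .simulate import SimulationConfig, StateSpec, simulate_population
from .tracking import LinkingParams, detect_stack, filter_tracks, link_tracks

__all__ = ["RunConfig", "AssayReport", "run_pipeline", "make_figures", "PipelineError"]

logger = logging.getLogger(__name__)

_STAGES = ["simulate", "track", "msd", "popfit", "hmm", "report"]
_KNOWN_KEYS = set(_STAGES) | {"stages", "seed", "output_dir"}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    stages: list[str]
    output_dir: Path
    seed: int = 0
    simulate: dict[str, dict] = field(default_factory=dict)  # condition -> sim params
    track: dict[str, Any] = field(default_factory=dict)
    msd: dict[str, Any] = field(default_factory=dict)
    popfit: dict[str, Any] = field(default_factory=dict)
    hmm: dict[str, Any] = field(default_factory=dict)
    report: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(
            stages=list(data["stages"]),
            output_dir=Path(data.get("output_dir", "tred_out")),
            seed=int(data.get("seed", 0)),
            simulate=dict(data.get("simulate", {})),
            track=dict(data.get("track", {})),
            msd=dict(data.get("msd", {})),
            popfit=dict(data.get("popfit", {})),
            hmm=dict(data.get("hmm", {})),
            report=dict(data.get("report", {})),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for s in self.stages:
            if s not in _STAGES:
                raise ValueError(f"unknown stage {s!r}; valid: {_STAGES}")
        order = [_STAGES.index(s) for s in self.stages]
        if order != sorted(order):
            raise ValueError("stages must respect the order " + " -> ".join(_STAGES))


@dataclass
class AssayReport:
    """Per-condition summaries, pairwise tests, mixtures and comparisons."""

    conditions: list[str]
    n_per_condition: dict[str, int]
    D_summary: dict[str, dict]
    L_summary: dict[str, dict]
    tests_D: list[dict]
    tests_L: list[dict]
    mixtures_D: dict[str, dict]
    mixtures_L: dict[str, dict]
    percent_differences: list[dict]
    correlation_r: float | None
    provenance: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _condition_config(name: str, params: dict, seed: int) -> SimulationConfig:
    params = dict(params)
    if "states" in params:
        params["states"] = [
            s if isinstance(s, StateSpec) else StateSpec(
                label=s["label"],
                D_micro=float(s["D_micro"]),
                corral_L=float(s.get("corral_L", np.inf)),
                hop_prob=float(s.get("hop_prob", 0.0)),
            )
            for s in params["states"]
        ]
    params.setdefault("seed", seed)
    return SimulationConfig(**params)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(f"stage {stage!r}: missing upstream artifact {path}")
    return path


def _mixture_dict(fit: stats.MixtureFit) -> dict:
    return {
        "K": fit.K,
        "weights": fit.weights.tolist(),
        "means_log10": fit.means_log10.tolist(),
        "sds_log10": fit.sds_log10.tolist(),
        "aic": fit.aic,
        "aic_by_k": {str(k): v for k, v in fit.aic_by_k.items()},
        "arithmetic_means": fit.arithmetic_means.tolist(),
        "arithmetic_sds": fit.arithmetic_sds.tolist(),
        "component_labels": fit.component_labels,
    }


def run_pipeline(config: RunConfig) -> AssayReport | None:
    """Execute the configured stages in order, persisting intermediates.

    Returns the AssayReport when the ``report`` stage runs, else None.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    if "simulate" in config.stages:
        if not config.simulate:
            raise PipelineError("stage 'simulate': no conditions configured")
        for name, params in config.simulate.items():
            sub_seed = int(rng.integers(0, 2**31 - 1))
            cfg = _condition_config(name, params, sub_seed)
            tracks = simulate_population(cfg)
            for tr in tracks:
                tr.condition = name
            io.write_tracks_csv(tracks, out / f"tracks_{name}.csv")
            logger.info("simulate[%s]: %d tracks (seed %d)", name, len(tracks), cfg.seed)

    if "track" in config.stages:
        stacks = config.track.get("stacks", {})
        if not stacks:
            raise PipelineError("stage 'track': no input stacks configured")
        pixel_size = float(config.track.get("pixel_size", 0.107))
        fps = float(config.track.get("fps", 20.0))
        psf_sd = float(config.track.get("psf_sd", 0.15))
        snr = float(config.track.get("snr_threshold", 4.0))
        params = LinkingParams(
            max_disp=float(config.track.get("max_disp", 0.5)),
            max_gap=int(config.track.get("max_gap", 0)),
            min_duration=float(config.track.get("min_duration", 15.0)),
        )
        for name, stack_path in stacks.items():
            stack = io.read_stack_tiff(_require(Path(stack_path), "track"))
            locs = detect_stack(stack, psf_sd, pixel_size, snr)
            tracks = filter_tracks(link_tracks(locs, params, 1.0 / fps), params)
            for tr in tracks:
                tr.condition = name
            io.write_tracks_csv(tracks, out / f"tracks_{name}.csv")
            logger.info("track[%s]: %d tracks kept", name, len(tracks))

    if "msd" in config.stages:
        track_files = sorted(out.glob("tracks_*.csv"))
        if not track_files:
            raise PipelineError(f"stage 'msd': missing upstream artifact {out / 'tracks_*.csv'}")
        min_dur = float(config.msd.get("min_duration", 15.0))
        frac = float(config.msd.get("max_lag_fraction", 0.25))
        all_est = []
        for f in track_files:
            tracks = filter_tracks(
                io.read_tracks_csv(f), LinkingParams(min_duration=min_dur)
            )
            all_est.extend(msd.estimate_all(tracks, max_lag_fraction=frac))
        io.write_estimates_csv(all_est, out / "estimates.csv")
        logger.info("msd: %d estimates", len(all_est))

    report: AssayReport | None = None
    if "popfit" in config.stages or "report" in config.stages:
        est_path = _require(out / "estimates.csv", "popfit/report")
        df = io.read_estimates_csv(est_path)
        good = df[df["converged"]].copy()
        conditions = [str(c) for c in good["condition"].dropna().unique()]
        if not conditions:
            raise PipelineError("stage 'popfit': no labeled conditions in estimates")

        k_d = int(config.popfit.get("k_d", 3))
        k_l = int(config.popfit.get("k_l", 2))
        alpha = float(config.popfit.get("alpha", 0.05))
        d_by, l_by, n_by = {}, {}, {}
        mix_d, mix_l = {}, {}
        for c in conditions:
            sub = good[good["condition"] == c]
            d_vals = sub["D_um2_s"].to_numpy()
            l_vals = sub["L_nm"].to_numpy()
            n_by[c] = len(sub)
            d_by[c] = dataclasses.asdict(stats.summarize_group(d_vals))
            l_by[c] = dataclasses.asdict(stats.summarize_group(l_vals))
            pos_d = d_vals[d_vals > 0]
            pos_l = l_vals[l_vals > 0]
            if len(pos_d) >= 10 * k_d:
                mix_d[c] = _mixture_dict(
                    stats.fit_log_mixture(pos_d, 1, k_d, seed=config.seed)
                )
            if len(pos_l) >= 10 * k_l:
                mix_l[c] = _mixture_dict(
                    stats.fit_log_mixture(pos_l, 1, k_l, seed=config.seed)
                )

        tests_d, tests_l = [], []
        for a, b in combinations(conditions, 2):
            for col, sink in (("D_um2_s", tests_d), ("L_nm", tests_l)):
                res = stats.compare_groups(
                    good.loc[good["condition"] == a, col].to_numpy(),
                    good.loc[good["condition"] == b, col].to_numpy(),
                    alpha=alpha,
                )
                sink.append(
                    {"a": a, "b": b, **dataclasses.asdict(res),
                     "stars": stats.significance_stars(res.p_value)}
                )

        reference = config.popfit.get("reference", conditions[0])
        pct = []
        for c in conditions:
            if c == reference:
                continue
            for quantity, by in (("D", d_by), ("L", l_by)):
                pct.append(
                    {
                        "quantity": quantity,
                        "condition": c,
                        "reference": reference,
                        "percent": stats.percent_difference(
                            by[c]["mean"], by[reference]["mean"], rounded=True
                        ),
                    }
                )

        corr = None
        scores = config.popfit.get("scores")
        if scores:
            shared = [c for c in conditions if c in scores]
            if len(shared) >= 3:
                corr = stats.correlate(
                    np.array([d_by[c]["mean"] for c in shared]),
                    np.array([float(scores[c]) for c in shared]),
                )

        cfg_dict = dataclasses.asdict(config)
        cfg_dict["output_dir"] = str(cfg_dict["output_dir"])
        cfg_hash = hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest()
        report = AssayReport(
            conditions=conditions,
            n_per_condition=n_by,
            D_summary=d_by,
            L_summary=l_by,
            tests_D=tests_d,
            tests_L=tests_l,
            mixtures_D=mix_d,
            mixtures_L=mix_l,
            percent_differences=pct,
            correlation_r=corr,
            provenance={"config_sha256": cfg_hash, "tred_version": __version__,
                        "seed": config.seed},
        )
        report.to_json(out / "report.json")

    if "hmm" in config.stages:
        track_files = sorted(out.glob("tracks_*.csv"))
        if not track_files:
            raise PipelineError(f"stage 'hmm': missing upstream artifact {out / 'tracks_*.csv'}")
        k_max = int(config.hmm.get("k_max", 3))
        window = config.hmm.get("window")
        total = config.hmm.get("total")
        for f in track_files:
            name = f.stem.removeprefix("tracks_")
            tracks = io.read_tracks_csv(f)
            dt = tracks[0].frame_interval
            model = select_state_count(tracks, k_max, dt, seed=config.seed)
            payload = {
                "K": model.K,
                "D_states": model.D_states.tolist(),
                "trans": model.trans.tolist(),
                "occupancy": model.occupancy.tolist(),
                "dwell_times": model.dwell_times.tolist(),
                "loglik": model.loglik,
                "criterion": model.criterion,
                "n_tracks": model.n_tracks,
                "labels": model.labels,
            }
            if window and total and model.K >= 2:
                wins = windowed_transitions(tracks, model, float(window), float(total))
                payload["windowed_p_mobile_to_less"] = [
                    {"start": w.window_start, "end": w.window_end, "p": w.p_mobile_to_less}
                    for w in wins
                ]
            (out / f"hmm_{name}.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
            logger.info("hmm[%s]: K=%d selected", name, model.K)

    return report


def make_figures(
    report: AssayReport,
    estimates: pd.DataFrame,
    msd_curves: Mapping[str, msd.MSDCurve],
    outdir: str | Path,
) -> list[Path]:
    """Write the assay's standard figures: ensemble-MSD ribbon plot, D and L
    bar charts annotated with per-bar n, and log histograms with fitted
    mixture-component overlays."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not report.conditions:
        import warnings

        warnings.warn("make_figures: empty condition set, nothing to plot")
        return []
    paths: list[Path] = []

    if msd_curves:
        fig, ax = plt.subplots(figsize=(5, 4))
        for name, curve in msd_curves.items():
            ax.plot(curve.lags, curve.msd, label=name)
            if curve.sem is not None:
                ax.fill_between(
                    curve.lags, curve.msd - curve.sem, curve.msd + curve.sem, alpha=0.3
                )
        ax.set_xlabel("lag time (s)")
        ax.set_ylabel("MSD (µm²)")
        ax.legend()
        p = outdir / "ensemble_msd.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)

    for quantity, summary, unit in (
        ("D", report.D_summary, "µm²/s"),
        ("L", report.L_summary, "nm"),
    ):
        fig, ax = plt.subplots(figsize=(4, 4))
        names = report.conditions
        means = [summary[c]["mean"] for c in names]
        sems = [summary[c]["sem"] for c in names]
        bars = ax.bar(names, means, yerr=sems, capsize=4)
        for c, bar in zip(names, bars):
            ax.annotate(
                str(report.n_per_condition[c]),
                (bar.get_x() + bar.get_width() / 2, bar.get_height()),
                ha="center", va="bottom", fontsize=8,
            )
        ax.set_ylabel(f"{quantity} ({unit})")
        p = outdir / f"bar_{quantity}.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)

    good = estimates[estimates["converged"]]
    for quantity, col, mixes in (
        ("D", "D_um2_s", report.mixtures_D),
        ("L", "L_nm", report.mixtures_L),
    ):
        for c in report.conditions:
            if c not in mixes:
                continue
            vals = good.loc[(good["condition"] == c) & (good[col] > 0), col].to_numpy()
            logs = np.log10(vals)
            fig, ax = plt.subplots(figsize=(4, 3))
            counts, bins, _ = ax.hist(logs, bins=40, alpha=0.5)
            bw = bins[1] - bins[0]
            grid = np.linspace(bins[0], bins[-1], 300)
            m = mixes[c]
            for w, mu, sd, lab in zip(
                m["weights"], m["means_log10"], m["sds_log10"], m["component_labels"]
            ):
                ax.plot(grid, w * len(vals) * bw * norm.pdf(grid, mu, sd), label=lab)
            ax.set_xlabel(f"log10 {quantity}")
            ax.legend(fontsize=7)
            p = outdir / f"hist_{quantity}_{c}.png"
            fig.savefig(p, dpi=150, bbox_inches="tight")
            plt.close(fig)
            paths.append(p)
    return paths
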