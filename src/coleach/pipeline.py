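"""End-to-end analysis pipeline over a declarative run configuration.

Stages run in order — dilution, exposure encoding, growth estimation, leach
yields, series metrics, community correlations — each consuming files named
in the configuration and writing CSV outputs plus a structured JSON log of
the exact parameter set used.  A stage whose inputs are absent from the
configuration is marked skipped; a stage that fails aborts the run with the
stage name and cause.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .community import encode_exposure, correlate_genera
from .dilution import read_schedule, run_schedule
from .growth import estimate_mu2_pointwise, fit_mu2_constant
from .io import read_abundance, read_counts, read_timeseries
from .metrics import fe2_depletion_time, lag_phase_duration, time_to_threshold
from .stoich import LeachYieldInput, leach_yield

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("coleach")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Validated run configuration (typically loaded from YAML).

    Each stage block is a plain dict; an absent block skips the stage.
    """

    out_dir: Path
    seed: int = 0
    dilution: dict[str, Any] | None = None     # x0, schedule_path
    growth: dict[str, Any] | None = None       # counts_path, D, method, n_boot
    yields: list[dict[str, Any]] = field(default_factory=list)
    metrics: dict[str, Any] | None = None      # series_paths, thresholds...
    community: dict[str, Any] | None = None    # abundance_path, mode

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        if "out_dir" not in raw:
            raise ValueError("configuration must set out_dir")
        known = {"out_dir", "seed", "dilution", "growth", "yields", "metrics", "community"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        seed = raw.get("seed", 0)
        if not isinstance(seed, int):
            raise ValueError(f"seed must be an integer, got {seed!r}")
        cfg = cls(
            out_dir=Path(raw["out_dir"]),
            seed=seed,
            dilution=raw.get("dilution"),
            growth=raw.get("growth"),
            yields=raw.get("yields", []),
            metrics=raw.get("metrics"),
            community=raw.get("community"),
        )
        for block in (cfg.dilution, cfg.growth, cfg.metrics, cfg.community):
            if block is not None:
                for key, value in block.items():
                    if key.endswith("_path") and not Path(value).exists():
                        raise ValueError(f"configured path does not exist: {value}")
        return cfg


def _stage(report: dict, name: str, fn) -> None:
    t0 = time.perf_counter()
    try:
        result = fn()
    except Exception as exc:  # noqa: BLE001 - stage name must reach the caller
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    report["stages"][name] = {
        "status": "ok",
        "seconds": round(time.perf_counter() - t0, 4),
        **(result or {}),
    }
    logger.info("stage %s done in %.3fs", name, report["stages"][name]["seconds"])


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all configured stages; returns (and writes) the report."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "dilution": config.dilution,
            "growth": config.growth,
            "yields": config.yields,
            "metrics": config.metrics,
            "community": config.community,
        },
        "stages": {},
    }
    dilution_series = None

    if config.dilution:
        def do_dilution():
            nonlocal dilution_series
            sched = read_schedule(config.dilution["schedule_path"])
            dilution_series = run_schedule(float(config.dilution.get("x0", 5.0)), sched)
            dilution_series.to_frame().to_csv(out / "dilution.csv", index=False)
            return {"n_steps": len(sched), "final_conc_gL": dilution_series.conc[-1]}

        _stage(report, "dilution", do_dilution)
    else:
        report["stages"]["dilution"] = {"status": "skipped"}

    if config.growth:
        def do_growth():
            series = read_counts(config.growth["counts_path"])
            if "control" not in series or "experimental" not in series:
                raise ValueError("counts file must contain control and experimental reactors")
            D = float(config.growth.get("D", 0.2))
            method = config.growth.get("method", "fit")
            result: dict[str, Any] = {"D": D, "method": method}
            if method == "pointwise":
                t, mu2 = estimate_mu2_pointwise(series["control"], series["experimental"], D)
                pd.DataFrame({"time_days": t, "mu2_per_day": mu2}).to_csv(
                    out / "growth.csv", index=False
                )
                result["mu2_final"] = float(mu2[-1])
            elif method == "fit":
                fit = fit_mu2_constant(
                    series["control"], series["experimental"], D,
                    n_boot=int(config.growth.get("n_boot", 200)),
                    seed=config.seed,
                )
                pd.DataFrame(
                    [{"mu2_per_day": fit.mu2, "half_width": fit.half_width,
                      "n_points": fit.n_points, "n_boot": fit.n_boot}]
                ).to_csv(out / "growth.csv", index=False)
                result["mu2"] = fit.mu2
                result["half_width"] = fit.half_width
            else:
                raise ValueError(f"unknown growth method {method!r}")
            return result

        _stage(report, "growth", do_growth)
    else:
        report["stages"]["growth"] = {"status": "skipped"}

    if config.yields:
        def do_yields():
            rows = []
            for spec in config.yields:
                res = leach_yield(
                    LeachYieldInput(
                        m_LE=float(spec["m_le"]),
                        m_LC=float(spec["m_lc"]),
                        Xi=float(spec["xi"]),
                        V_total=float(spec["v_total"]),
                        omega=float(spec["omega"]),
                    )
                )
                rows.append(
                    {"metal": spec.get("metal", "?"), "yield_percent": res.percent,
                     "in_range": res.in_range}
                )
            pd.DataFrame(rows).to_csv(out / "yields.csv", index=False)
            return {"n_yields": len(rows)}

        _stage(report, "yields", do_yields)
    else:
        report["stages"]["yields"] = {"status": "skipped"}

    if config.metrics:
        def do_metrics():
            rows = []
            for path in config.metrics["series_paths"]:
                series = read_timeseries(path, reactor_id=Path(path).stem)
                row: dict[str, Any] = {"series": Path(path).stem}
                if series.pH is not None:
                    row["t_pH"] = time_to_threshold(
                        series, "pH", float(config.metrics.get("ph_ref", 1.2)), "falling"
                    )
                if series.Eh is not None:
                    row["t_Eh"] = time_to_threshold(
                        series, "Eh", float(config.metrics.get("eh_ref", 800.0)), "rising"
                    )
                if series.fe2 is not None:
                    row["t_fe2_depleted"] = fe2_depletion_time(
                        series, lod=float(config.metrics.get("fe_lod", 0.05))
                    )
                if series.cells is not None:
                    row["lag_days"] = lag_phase_duration(
                        series, k_fold=float(config.metrics.get("k_fold", 2.0))
                    )
                rows.append(row)
            pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
            return {"n_series": len(rows)}

        _stage(report, "metrics", do_metrics)
    else:
        report["stages"]["metrics"] = {"status": "skipped"}

    if config.community:
        def do_community():
            table = read_abundance(config.community["abundance_path"])
            mode = config.community.get("mode", "concentration")
            exposure = encode_exposure(table, dilution_series, mode=mode)
            corr = correlate_genera(table, exposure)
            corr.to_csv(out / "correlations.csv")
            return {"mode": mode, "n_genera": len(corr)}

        _stage(report, "community", do_community)
    else:
        report["stages"]["community"] = {"status": "skipped"}

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
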