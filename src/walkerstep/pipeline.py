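"""Pipeline stages: simulate, fit, extract, predict, compare.

The stages mirror the analysis chain of the study: a synthetic smFRET
experiment produces burst sets per (step size, fuel concentration)
condition; mixture fits turn bursts into measured yields; the kinetic
competition inverts yields into stepping rates; the mechanics model
predicts yields from geometry; and the comparison stage juxtaposes fitted
and predicted curves on a shared grid.

Every stage reads the same validated config, derives its randomness from
the single config seed, writes CSV tables plus a machine-readable JSON
summary, and drops a run manifest (config hash, seed, package versions) so
outputs are reproducible byte-for-byte given config + seed.
"""

from __future__ import annotations

import json
import logging
import math
import time
import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .fret import estimate_fractions, synthesize_experiment
from .io import (
    read_bursts,
    read_yield_table,
    write_bursts,
    write_contact_table,
    write_yield_table,
)
from .kinetics import stepping_rate_from_yield
from .mechanics import max_reach, predict_yield_curve

__all__ = [
    "ComparisonReport",
    "GridMismatchError",
    "run_simulate_fret",
    "run_fit_yields",
    "run_extract_rates",
    "run_predict_mechanics",
    "run_compare",
    "write_manifest",
]

logger = logging.getLogger("walkerstep")

#: Yields outside this open interval are flagged unreliable instead of
#: being inverted into stepping rates.
RELIABLE_YIELD_RANGE = (0.01, 0.99)


class GridMismatchError(ValueError):
    """Raised when fitted and model curves do not share a (d, F1) grid."""


def _stage_seed(config: RunConfig, stage: str) -> int:
    """Stable per-stage substream below 2**31, derived from the config seed."""
    stage_tag = zlib.crc32(stage.encode()) % 2**31
    ss = np.random.SeedSequence([config.seed, stage_tag])
    return int(ss.generate_state(1)[0] % 2**31)


def write_manifest(config: RunConfig, outdir: Path, stage: str, elapsed_s: float, extra: dict | None = None) -> Path:
    manifest = {
        "stage": stage,
        "config_sha256": config.config_hash(),
        "seed": config.seed,
        "elapsed_s": round(elapsed_s, 3),
        "versions": {
            "walkerstep": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def run_simulate_fret(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Generate per-condition burst sets and the noiseless true yield table."""
    t0 = time.perf_counter()
    outdir = Path(outdir) if outdir else config.output_directory / "simulate-fret"
    seed = _stage_seed(config, "simulate-fret")
    logger.info("simulate-fret: seed=%d, n_bursts=%d", seed, config.n_bursts)
    burst_sets, true_curve = synthesize_experiment(
        true_ks=config.true_stepping_rates(),
        k_FB=config.calibration().k_FB,
        F1_list=config.fuel_concentrations(),
        model=config.population_model(),
        n_bursts=config.n_bursts,
        seed=seed,
    )
    bursts_path = write_bursts(burst_sets, outdir / "bursts.csv")
    true_path = write_yield_table(true_curve, outdir / "true_yields.csv")
    summary = {
        "n_conditions": len(burst_sets),
        "n_bursts_per_condition": config.n_bursts,
        "bursts_csv": str(bursts_path),
        "true_yields_csv": str(true_path),
    }
    _finish(config, outdir, "simulate-fret", t0, summary)
    return summary


def run_fit_yields(
    config: RunConfig,
    bursts_path: str | Path | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Fit the two-population mixture per condition and emit a yield table."""
    t0 = time.perf_counter()
    outdir = Path(outdir) if outdir else config.output_directory / "fit-yields"
    bursts_path = (
        Path(bursts_path)
        if bursts_path
        else config.output_directory / "simulate-fret" / "bursts.csv"
    )
    seed = _stage_seed(config, "fit-yields")
    burst_sets = read_bursts(bursts_path)
    init = config.population_model(f_LP=0.5)
    rows = []
    for i, bs in enumerate(burst_sets):
        fit = estimate_fractions(
            bs, init, fix_means=True, n_bootstrap=config.fret_bootstrap, seed=seed + i
        )
        se = (fit.ci_high - fit.ci_low) / (2.0 * 1.96)
        rows.append(
            dict(
                step_size_nm=bs.condition_d_nm,
                fuel_conc_M=bs.condition_F1_M,
                **{"yield": fit.f_LP_hat},
                yield_se=se,
                source="synthetic",
            )
        )
        logger.info(
            "fit-yields: d=%.1f nm F1=%.3g M -> f_LP=%.3f [%.3f, %.3f]",
            bs.condition_d_nm, bs.condition_F1_M, fit.f_LP_hat, fit.ci_low, fit.ci_high,
        )
    fitted = pd.DataFrame(rows)
    path = write_yield_table(fitted, outdir / "fitted_yields.csv")
    summary = {"n_conditions": len(rows), "fitted_yields_csv": str(path)}
    _finish(config, outdir, "fit-yields", t0, summary)
    return summary


def extract_rates_table(yields: pd.DataFrame, k_FB: float) -> pd.DataFrame:
    """Invert measured yields into stepping rates, flagging unreliable rows.

    Conditions with yields outside (0.01, 0.99) carry almost no rate
    information (the competition saturates) and are flagged rather than
    inverted; rates from F1 = 0 conditions are likewise not defined.
    """
    if yields.empty:
        raise ValueError("empty yield table: nothing to invert")
    lo, hi = RELIABLE_YIELD_RANGE
    rows = []
    for _, row in yields.iterrows():
        y = float(row["yield"])
        f1 = float(row["fuel_conc_M"])
        se = float(row["yield_se"]) if not math.isnan(row["yield_se"]) else 0.0
        reliable = (lo < y < hi) and f1 > 0
        if reliable:
            k_s = stepping_rate_from_yield(y, k_FB, f1)
            # Delta method on k_s = kFB*F1*Y/(1-Y): dk/dY = kFB*F1/(1-Y)^2.
            k_se = k_FB * f1 * se / (1.0 - y) ** 2
            ci_low, ci_high = max(k_s - 1.96 * k_se, 0.0), k_s + 1.96 * k_se
        else:
            k_s = k_se = ci_low = ci_high = float("nan")
        rows.append(
            dict(
                step_size_nm=row["step_size_nm"],
                fuel_conc_M=f1,
                **{"yield": y},
                k_s_hat=k_s,
                k_s_se=k_se,
                ci_low=ci_low,
                ci_high=ci_high,
                reliable=reliable,
            )
        )
    return pd.DataFrame(rows)


def run_extract_rates(
    config: RunConfig,
    yields_path: str | Path | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Extract stepping rates from a (fitted or manual) yield table."""
    t0 = time.perf_counter()
    outdir = Path(outdir) if outdir else config.output_directory / "extract-rates"
    yields_path = (
        Path(yields_path)
        if yields_path
        else config.output_directory / "fit-yields" / "fitted_yields.csv"
    )
    k_FB = config.calibration().k_FB
    table = extract_rates_table(read_yield_table(yields_path), k_FB)
    path = outdir / "stepping_rates.csv"
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    n_rel = int(table["reliable"].sum())
    logger.info("extract-rates: %d/%d conditions reliable", n_rel, len(table))
    summary = {
        "n_conditions": len(table),
        "n_reliable": n_rel,
        "stepping_rates_csv": str(path),
    }
    _finish(config, outdir, "extract-rates", t0, summary)
    return summary


def run_predict_mechanics(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Predict the yield curve from the coarse mechanical model."""
    t0 = time.perf_counter()
    outdir = Path(outdir) if outdir else config.output_directory / "predict-mechanics"
    seed = _stage_seed(config, "predict-mechanics")
    design = config.design()
    track = config.track()
    logger.info(
        "predict-mechanics: track=%s, n=%d, seed=%d", track.kind, config.n_conformations, seed
    )
    prediction = predict_yield_curve(
        design,
        track,
        d_grid=config.step_grid,
        F1_list=config.fuel_concentrations(),
        calibration=config.calibration(),
        n=config.n_conformations,
        seed=seed,
        hairpin=config.hairpin(),
        grid_spacing=config.grid_spacing,
        bandwidth=config.bandwidth,
        n_boot=config.sampling_bootstrap,
    )
    curve_path = write_yield_table(prediction.curve, outdir / "model_yields.csv")
    contact_path = write_contact_table(prediction.contacts, outdir / "contacts.csv")
    summary = {
        "max_reach_nm": prediction.max_reach,
        "model_yields_csv": str(curve_path),
        "contacts_csv": str(contact_path),
    }
    _finish(config, outdir, "predict-mechanics", t0, summary)
    return summary


@dataclass
class ComparisonReport:
    """Fitted-vs-model comparison on a shared (d, F1) grid."""

    table: pd.DataFrame
    rms_residual: float
    crossovers_nm: dict[float, float | None]
    max_reach_nm: float

    def to_summary(self) -> dict:
        return {
            "rms_residual": self.rms_residual,
            "crossovers_nm": {f"{f1:.3e}": c for f1, c in self.crossovers_nm.items()},
            "max_reach_nm": self.max_reach_nm,
            "n_rows": len(self.table),
        }


def crossover_step(d: np.ndarray, y: np.ndarray) -> float | None:
    """Linear-interpolated step size at which the yield crosses 0.5.

    Returns None unless the curve brackets 0.5. With several bracketing
    intervals the first (smallest d) crossing is reported.
    """
    order = np.argsort(d)
    d, y = np.asarray(d, float)[order], np.asarray(y, float)[order]
    if not ((y > 0.5).any() and (y < 0.5).any()):
        return None
    for i in range(len(d) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - 0.5) * (y1 - 0.5) <= 0 and y0 != y1:
            return float(d[i] + (0.5 - y0) * (d[i + 1] - d[i]) / (y1 - y0))
    return None


def compare_curves(fitted: pd.DataFrame, model: pd.DataFrame, max_reach_nm: float) -> ComparisonReport:
    """Join two yield tables on the exact (d, F1) grid and compare.

    The grid is the single source of truth: missing pairs on either side
    raise, no silent reindexing or interpolation across step sizes.
    """
    keys = ["step_size_nm", "fuel_conc_M"]
    f = fitted[keys + ["yield"]].rename(columns={"yield": "Y_fit"})
    m = model[keys + ["yield"]].rename(columns={"yield": "Y_model"})
    merged = f.merge(m, on=keys, how="outer", indicator=True)
    missing = merged[merged["_merge"] != "both"]
    if not missing.empty:
        pairs = [
            (row["step_size_nm"], row["fuel_conc_M"], row["_merge"])
            for _, row in missing.iterrows()
        ]
        raise GridMismatchError(
            f"fitted and model curves do not share a grid; unmatched (d, F1) pairs: {pairs}"
        )
    table = merged.drop(columns="_merge").sort_values(keys).reset_index(drop=True)
    table["residual"] = table["Y_fit"] - table["Y_model"]
    rms = float(np.sqrt(np.mean(table["residual"] ** 2)))
    crossovers = {}
    for f1, group in table.groupby("fuel_conc_M"):
        crossovers[float(f1)] = crossover_step(
            group["step_size_nm"].to_numpy(), group["Y_model"].to_numpy()
        )
    return ComparisonReport(
        table=table, rms_residual=rms, crossovers_nm=crossovers, max_reach_nm=max_reach_nm
    )


def run_compare(
    config: RunConfig,
    fitted_path: str | Path | None = None,
    model_path: str | Path | None = None,
    outdir: str | Path | None = None,
) -> ComparisonReport:
    """Compare fitted ("experimental") and model yield curves."""
    t0 = time.perf_counter()
    outdir = Path(outdir) if outdir else config.output_directory / "compare"
    fitted_path = (
        Path(fitted_path)
        if fitted_path
        else config.output_directory / "fit-yields" / "fitted_yields.csv"
    )
    model_path = (
        Path(model_path)
        if model_path
        else config.output_directory / "predict-mechanics" / "model_yields.csv"
    )
    report = compare_curves(
        read_yield_table(fitted_path),
        read_yield_table(model_path),
        max_reach_nm=max_reach(config.design(), config.track()),
    )
    outdir.mkdir(parents=True, exist_ok=True)
    report.table.to_csv(outdir / "comparison.csv", index=False)
    logger.info(
        "compare: RMS residual %.4f over %d grid points", report.rms_residual, len(report.table)
    )
    _finish(config, outdir, "compare", t0, report.to_summary())
    return report


def _finish(config: RunConfig, outdir: Path, stage: str, t0: float, summary: dict) -> None:
    elapsed = time.perf_counter() - t0
    logger.info("%s: finished in %.2f s", stage, elapsed)
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    write_manifest(config, outdir, stage, elapsed)
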