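"""End-to-end pipeline orchestration.

A run is described by a single YAML-able config dict: a mandatory seed, a
list of stages, and one section per stage.  Stages execute in dependency
order (``simulate`` first, then the analyses, then ``report``); each stage
writes its outputs under ``<outdir>/<stage>/`` and a manifest recording the
config hash, input checksums, package version and per-stage status is
written once at the end.  A fixed config and seed yield byte-identical
analysis outputs across runs (the manifest's timestamps excepted).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__, io
from .densitometry import (BandWindow, band_ratio, quantify_band,
                           subtract_background)
from .errors import ConfigError, SarcoquantError
from .geneset import compute_ecdf, compute_shift, run_shift_panel
from .morphometry import (IntensityProfile, PeriodSearchRange, compare_groups,
                          count_series, estimate_period_fft)
from .synthetic import (LaneSimConfig, LfcSimConfig, StriationSimConfig,
                        simulate_lane, simulate_lfc_table,
                        simulate_striation_profile)

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "shift", "morpho", "densitometry", "report")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    stages: tuple[str, ...]
    sections: dict[str, dict]

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        if not isinstance(raw, Mapping):
            raise ConfigError("run config must be a mapping")
        stages = raw.get("stages")
        if not isinstance(stages, (list, tuple)) or not stages:
            raise ConfigError("stages: must be a non-empty list")
        for s in stages:
            if s not in STAGE_ORDER:
                raise ConfigError(f"stages: unknown stage {s!r} "
                                  f"(choose from {list(STAGE_ORDER)})")
        seed = raw.get("seed")
        if "simulate" in stages and not isinstance(seed, int):
            raise ConfigError("seed: an integer seed is mandatory when the "
                              "simulate stage is enabled")
        sections = {}
        for s in stages:
            sec = raw.get(s, {})
            if not isinstance(sec, Mapping):
                raise ConfigError(f"{s}: stage section must be a mapping")
            sections[s] = dict(sec)
        ordered = tuple(s for s in STAGE_ORDER if s in stages)
        return cls(seed=int(seed or 0), stages=ordered, sections=sections)


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    input_checksums: dict[str, str]
    stage_status: dict[str, str]
    started: float
    finished: float | None = None

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "package_version": self.package_version,
            "input_checksums": self.input_checksums,
            "stage_status": self.stage_status,
            "started": self.started,
            "finished": self.finished,
        }


def _sha256_of(obj: Any) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def _checksum_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: dict, outdir: Path, seed: int) -> None:
    out = outdir / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    lfc_cfg = cfg.get("lfc")
    if lfc_cfg:
        sigma = float(lfc_cfg.get("sigma", 0.3))
        n_bg = int(lfc_cfg.get("n_background_genes", 12000))
        all_sets = {}
        for i, tbl in enumerate(lfc_cfg.get("tables", [])):
            sets_spec = tbl.get("sets", {})
            sim = LfcSimConfig(
                n_background_genes=n_bg,
                set_sizes={k: int(v["size"]) for k, v in sets_spec.items()},
                delta={k: float(v["delta"]) for k, v in sets_spec.items()},
                sigma=sigma,
                seed=seed + 101 + i,
                comparison_label=str(tbl.get("label", f"comparison{i + 1}")),
            )
            table, sets = simulate_lfc_table(sim)
            io.write_lfc_table(table, out / f"{sim.comparison_label}.lfc.tsv")
            all_sets.update(sets)
        if all_sets:
            io.write_gmt(all_sets, out / "gene_sets.gmt")
    for i, prof in enumerate(cfg.get("striation", {}).get("profiles", [])):
        pid = str(prof.get("id", f"profile{i + 1}"))
        sim = StriationSimConfig(
            period_um=float(prof["period_um"]),
            pixel_size_um=float(prof.get("pixel_size_um", 0.1)),
            n_samples=int(prof.get("n_samples", 512)),
            amplitude=float(prof.get("amplitude", 100.0)),
            noise_sd=float(prof.get("noise_sd", 0.0)),
            baseline=float(prof.get("baseline", 200.0)),
            seed=seed + 201 + i,
        )
        io.write_profile_csv(simulate_striation_profile(sim),
                             out / f"{pid}.profile.csv")
    for i, lane in enumerate(cfg.get("lanes", [])):
        lid = str(lane.get("id", f"lane{i + 1}"))
        sim = LaneSimConfig(
            band_centers=tuple(lane["band_centers"]),
            band_amounts=tuple(lane["band_amounts"]),
            band_width=float(lane.get("band_width", 4.0)),
            baseline_level=float(lane.get("baseline_level", 0.0)),
            noise_sd=float(lane.get("noise_sd", 0.0)),
            n_samples=int(lane.get("n_samples", 512)),
            seed=seed + 301 + i,
        )
        io.write_lane_csv(simulate_lane(sim, lid), out / f"{lid}.lane.csv")


def _stage_shift(cfg: dict, outdir: Path) -> None:
    out = outdir / "shift"
    out.mkdir(parents=True, exist_ok=True)
    table_paths = [Path(p) for p in cfg.get("tables", [])] or sorted(
        (outdir / "simulate").glob("*.lfc.tsv")
    )
    if not table_paths:
        raise ConfigError("shift.tables: no LFC tables configured or simulated")
    sets_path = cfg.get("sets")
    if sets_path is None:
        sets_path = outdir / "simulate" / "gene_sets.gmt"
    sets = io.read_gmt(sets_path)
    tables = [io.read_lfc_table(p, p.name.removesuffix(".lfc.tsv"))
              for p in table_paths]
    mode = cfg.get("background_mode", "all_genes")
    panel = run_shift_panel(tables, list(sets.values()), mode)
    panel.to_csv(out / "shift_panel.tsv", sep="\t", index=False,
                 float_format="%.10g")
    for table in tables:
        ecdf = compute_ecdf(table.data["lfc"])
        pd.DataFrame({"lfc": ecdf.values, "fraction": ecdf.fractions}).to_csv(
            out / f"{table.comparison_label}.ecdf.csv", index=False,
            float_format="%.10g",
        )


def _stage_morpho(cfg: dict, outdir: Path) -> None:
    out = outdir / "morpho"
    out.mkdir(parents=True, exist_ok=True)
    paths = [Path(p) for p in cfg.get("profiles", [])] or sorted(
        (outdir / "simulate").glob("*.profile.csv")
    )
    if not paths:
        raise ConfigError("morpho.profiles: no profiles configured or simulated")
    lo, hi = cfg.get("range", (1.6, 3.4))
    search = PeriodSearchRange(float(lo), float(hi))
    threshold = int(cfg.get("series_threshold", 15))
    rows = []
    for p in paths:
        prof = io.read_profile_csv(p)
        est = estimate_period_fft(prof, search)
        series = count_series(prof, threshold)
        rows.append(dict(
            profile_id=p.name.removesuffix(".profile.csv"),
            period_um=est.period_um if est.period_um is not None else np.nan,
            peak_power=est.peak_power, in_range=est.in_range,
            n_series=series.n_striations_in_series, qualifies=series.qualifies,
        ))
    df = pd.DataFrame(rows)
    df.to_csv(out / "periods.csv", index=False, float_format="%.10g")
    groups_cfg = cfg.get("groups")
    if groups_cfg:
        groups = {
            name: df.loc[df["profile_id"].isin(ids), "period_um"].dropna().tolist()
            for name, ids in groups_cfg.items()
        }
        comparison = compare_groups(groups)
        with open(out / "group_comparison.json", "w") as fh:
            json.dump(
                {
                    "f_statistic": comparison.f_statistic,
                    "anova_p": comparison.anova_p,
                    "pairwise": {f"{a}|{b}": p
                                 for (a, b), p in comparison.pairwise.items()},
                },
                fh, indent=2, sort_keys=True,
            )


def _stage_densitometry(cfg: dict, outdir: Path) -> None:
    out = outdir / "densitometry"
    out.mkdir(parents=True, exist_ok=True)
    paths = [Path(p) for p in cfg.get("lanes", [])] or sorted(
        (outdir / "simulate").glob("*.lane.csv")
    )
    if not paths:
        raise ConfigError("densitometry.lanes: no lanes configured or simulated")
    windows_cfg = cfg.get("windows")
    if not windows_cfg:
        raise ConfigError("densitometry.windows: band windows are required "
                          "(name: [start_idx, end_idx])")
    radius = int(cfg.get("radius", 40))
    ratio_of = cfg.get("ratio")  # optional [numerator, denominator]
    rows = []
    for p in paths:
        lane = io.read_lane_csv(p)
        sub = subtract_background(lane, radius)
        quants = {}
        for name, (a, b) in windows_cfg.items():
            quants[name] = quantify_band(sub, BandWindow(name, int(a), int(b)))
        row: dict[str, Any] = {"lane_id": lane.lane_id}
        for name, q in quants.items():
            row[f"{name}_total"] = q.band_total
            row[f"{name}_fraction"] = q.fraction_of_lane
        row["lane_total"] = next(iter(quants.values())).lane_total if quants else 0.0
        if ratio_of:
            num, den = ratio_of
            row[f"{num}_over_{den}"] = band_ratio(quants[num], quants[den])
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "band_quants.csv", index=False,
                              float_format="%.10g")


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> RunManifest:
    """Execute the configured stages in dependency order and write a manifest.

    Schema violations abort before any stage runs.  A stage failure is
    recorded in the manifest and later stages that depend on its outputs are
    skipped rather than run against partial data.
    """
    rc = RunConfig.from_dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    checksums: dict[str, str] = {}
    for stage in ("shift", "morpho", "densitometry"):
        sec = rc.sections.get(stage, {})
        for key in ("tables", "profiles", "lanes", "sets"):
            val = sec.get(key)
            paths = val if isinstance(val, list) else [val] if isinstance(val, str) else []
            for p in paths:
                if not isinstance(p, (str, Path)):
                    raise ConfigError(f"{stage}.{key}: expected file path, got {p!r}")
                p = Path(p)
                if not p.exists():
                    raise ConfigError(f"{stage}.{key}: input path does not exist: {p}")
                checksums[str(p)] = _checksum_file(p)

    manifest = RunManifest(
        config_hash=_sha256_of(dict(config)),
        package_version=__version__,
        input_checksums=checksums,
        stage_status={s: "pending" for s in rc.stages},
        started=time.time(),
    )
    failed = False
    for stage in rc.stages:
        if failed:
            manifest.stage_status[stage] = "skipped"
            continue
        try:
            logger.info("running stage %s", stage)
            if stage == "simulate":
                _stage_simulate(rc.sections[stage], outdir, rc.seed)
            elif stage == "shift":
                _stage_shift(rc.sections[stage], outdir)
            elif stage == "morpho":
                _stage_morpho(rc.sections[stage], outdir)
            elif stage == "densitometry":
                _stage_densitometry(rc.sections[stage], outdir)
            elif stage == "report":
                from .report import make_report

                make_report(outdir)
            manifest.stage_status[stage] = "ok"
        except SarcoquantError as exc:
            logger.error("stage %s failed: %s", stage, exc)
            manifest.stage_status[stage] = f"failed: {exc}"
            failed = True
    manifest.finished = time.time()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
    return manifest


def demo_config(seed: int = 0) -> dict:
    """A self-contained synthetic demo exercising every stage."""
    return {
        "seed": seed,
        "stages": ["simulate", "shift", "morpho", "densitometry", "report"],
        "simulate": {
            "lfc": {
                "n_background_genes": 12000,
                "sigma": 0.3,
                "tables": [
                    {
                        "label": "day7_patterned_vs_unpatterned",
                        "sets": {
                            "sarcomere": {"size": 198, "delta": 0.1},
                            "invivo_up": {"size": 87, "delta": 0.3},
                        },
                    },
                    {
                        "label": "day4_patterned_vs_unpatterned",
                        "sets": {
                            "sarcomere": {"size": 198, "delta": 0.05},
                            "invivo_up": {"size": 87, "delta": 0.15},
                        },
                    },
                ],
            },
            "striation": {
                "profiles": [
                    {"id": "patterned_d7", "period_um": 2.4, "noise_sd": 20.0},
                    {"id": "unpatterned_d7", "period_um": 2.2, "noise_sd": 40.0},
                ]
            },
            "lanes": [
                {"id": "patterned", "band_centers": [0.25, 0.75],
                 "band_amounts": [3.0, 1.0], "baseline_level": 5.0,
                 "noise_sd": 0.01},
                {"id": "unpatterned", "band_centers": [0.25, 0.75],
                 "band_amounts": [1.5, 1.0], "baseline_level": 5.0,
                 "noise_sd": 0.01},
            ],
        },
        "shift": {"background_mode": "all_genes"},
        "morpho": {"range": [1.6, 3.4], "series_threshold": 15},
        "densitometry": {
            "windows": {"myhc": [116, 140], "actin": [372, 396]},
            "radius": 40,
            "ratio": ["myhc", "actin"],
        },
        "report": {},
    }
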