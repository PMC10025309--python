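"""End-to-end run: load measurements, normalize, compute indices, fit trends.

The pipeline is a pure function of (input, config, seed): identical inputs
produce identical output tables. A structured log records row counts per
stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .indices import INDEX_NAMES, index_table
from .io import read_long_csv
from .profiles import (
    Basis,
    ConditionVariable,
    ExperimentSeries,
    SampleProfile,
    ValueKind,
    normalize,
)
from .trends import anova_tukey, trend_report

logger = logging.getLogger("ohfa.pipeline")

__all__ = ["RunConfig", "run_pipeline", "build_series"]


@dataclass
class RunConfig:
    input_path: str
    output_dir: str
    condition_variable: ConditionVariable = ConditionVariable.TEMPERATURE_C
    mode: str = "per_replicate_then_aggregate"
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not Path(self.input_path).exists():
            raise FileNotFoundError(self.input_path)


def build_series(profiles: list[SampleProfile]) -> list[ExperimentSeries]:
    """Group replicate profiles into per-strain series."""
    by_key: dict[tuple, list[SampleProfile]] = {}
    for p in profiles:
        by_key.setdefault((p.strain_id, p.condition_variable), []).append(p)
    return [
        ExperimentSeries(strain_id=k[0], condition_variable=k[1], profiles=v)
        for k, v in by_key.items()
    ]


def _normalize_if_areas(profiles: list[SampleProfile]) -> list[SampleProfile]:
    out = []
    for p in profiles:
        kinds = {m.value_kind for m in p.measurements.values()}
        if kinds == {ValueKind.PEAK_AREA}:
            out.append(
                normalize(
                    list(p.measurements.values()),
                    p.basis,
                    strain_id=p.strain_id,
                    condition_variable=p.condition_variable,
                    condition_value=p.condition_value,
                    replicate_id=p.replicate_id,
                    fixed_condition=p.fixed_condition,
                )
            )
        else:
            out.append(p)
    return out


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; returns paths of the written tables."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("ohfa %s seed=%s input=%s", __version__, config.seed, config.input_path)

    profiles = read_long_csv(config.input_path)
    if not profiles:
        raise ValueError(f"{config.input_path}: no profiles parsed")
    logger.info("loaded %d replicate profiles", len(profiles))
    profiles = _normalize_if_areas(profiles)
    all_series = [
        s
        for s in build_series(profiles)
        if s.condition_variable == config.condition_variable
    ]
    if not all_series:
        raise ValueError(
            f"no series found for condition {config.condition_variable.value}"
        )

    outputs: dict[str, Path] = {}

    # (i) normalized profiles
    from .io import series_to_frame

    norm_frames = [series_to_frame(s) for s in all_series]
    norm = pd.concat(norm_frames, ignore_index=True)
    outputs["profiles"] = outdir / "profiles_normalized.csv"
    norm.to_csv(outputs["profiles"], index=False)
    logger.info("profiles_normalized.csv: %d rows", len(norm))

    # (ii) index tables, replicate-aggregated and ratio-of-means
    idx_frames = []
    for s in all_series:
        for mode in ("per_replicate_then_aggregate", "ratio_of_means"):
            t = index_table(s, mode=mode)
            t.insert(0, "strain_id", s.strain_id)
            t.insert(1, "mode", mode)
            idx_frames.append(t)
    idx = pd.concat(idx_frames, ignore_index=True)
    outputs["indices"] = outdir / "indices.csv"
    idx.to_csv(outputs["indices"], index=False)
    logger.info("indices.csv: %d rows", len(idx))

    # (iii) trend report
    trend_frames = []
    for s in all_series:
        t = trend_report(s, alpha=config.alpha)
        t.insert(0, "strain_id", s.strain_id)
        trend_frames.append(t)
    trends = pd.concat(trend_frames, ignore_index=True)
    outputs["trends"] = outdir / "trends.csv"
    trends.to_csv(outputs["trends"], index=False)
    logger.info("trends.csv: %d rows", len(trends))

    # (iv) ANOVA/Tukey on every index across levels
    anova_rows = []
    tukey_frames = []
    for s in all_series:
        per_rep = index_table(s, mode="per_replicate_then_aggregate")
        for name in INDEX_NAMES + ("iso", "anteiso", "normal"):
            groups: dict[float, list[float]] = {}
            for p in s.profiles:
                from .indices import compute_indices

                iset = compute_indices(p)
                val = (
                    getattr(iset, name)
                    if name in ("iso", "anteiso", "normal")
                    else iset.as_dict().get(name)
                )
                if val is not None:
                    groups.setdefault(p.condition_value, []).append(val)
            groups = {k: v for k, v in groups.items() if len(v) >= 2}
            if len(groups) < 2:
                continue
            res = anova_tukey(groups, alpha=config.alpha)
            anova_rows.append(
                {
                    "strain_id": s.strain_id,
                    "response": name,
                    "F": res.f_statistic,
                    "p": res.p_value,
                    "degenerate": res.degenerate,
                }
            )
            comp = res.comparisons.copy()
            comp.insert(0, "strain_id", s.strain_id)
            comp.insert(1, "response", name)
            tukey_frames.append(comp)
        del per_rep
    outputs["anova"] = outdir / "anova.csv"
    pd.DataFrame(anova_rows).to_csv(outputs["anova"], index=False)
    outputs["tukey"] = outdir / "tukey.csv"
    (
        pd.concat(tukey_frames, ignore_index=True)
        if tukey_frames
        else pd.DataFrame()
    ).to_csv(outputs["tukey"], index=False)
    logger.info("anova.csv: %d rows", len(anova_rows))

    # plain-text summary
    summary = outdir / "summary.txt"
    with summary.open("w") as fh:
        fh.write(f"ohfa {__version__}\n")
        fh.write(f"input: {config.input_path}\n")
        fh.write(f"condition: {config.condition_variable.value}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"strains: {', '.join(s.strain_id for s in all_series)}\n")
        fh.write(f"profiles: {len(profiles)}\n")
        for key, path in outputs.items():
            fh.write(f"{key}: {path.name}\n")
    outputs["summary"] = summary
    return outputs
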