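"""End-to-end run orchestration: ingestion -> extraction -> differencing
-> statistics -> tables and figures, with reproducibility metadata.

A run directory contains ``features.csv``, ``diffs.csv``,
``stats.json``, ``report.txt``, a ``figures/`` folder and
``run_config.json`` (the full configuration, library versions and input
checksums), so a run is reproducible from its own artefacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .audio_io import CohortManifest, peak_normalise, read_wav
from .prosody_features import AnalysisConfig, extract_profile, profiles_to_frame
from .treatment_analysis import (
    DEFAULT_FAMILIES,
    FeatureFamily,
    anova_univariate,
    manova_oneway,
    pairwise_contrasts,
    summarize_differences,
    within_speaker_differences,
)

__all__ = ["RunConfig", "run_pipeline", "extract_features", "compute_stats",
           "plot_group_differences"]

logger = logging.getLogger("prosodiff")

#: Features plotted by default in a report run.
REPORT_FEATURES = (
    "f0_min_hz",
    "f0_range_st",
    "h1_a2_db",
    "h1_a3_db",
    "rms_level_db",
    "rms_sd_db",
)


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a pipeline run, serialisable losslessly."""

    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    alpha: float = 0.1
    correction: str = "holm"
    manova_statistic: str = "wilks"
    families: tuple = DEFAULT_FAMILIES
    seed: int = 0
    plot_features: tuple = REPORT_FEATURES

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = [
            {"name": f.name, "members": list(f.members)} for f in self.families
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "analysis" in d:
            d["analysis"] = AnalysisConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["analysis"].items()
            })
        if "families" in d:
            d["families"] = tuple(
                FeatureFamily(f["name"], tuple(f["members"])) for f in d["families"]
            )
        if "plot_features" in d:
            d["plot_features"] = tuple(d["plot_features"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def extract_features(
    manifest: CohortManifest, config: RunConfig | None = None
) -> pd.DataFrame:
    """Extract one profile per manifest row; failures become warnings.

    Returns the batch feature table with ``gender``/``treatment``
    metadata merged in.
    """
    config = config or RunConfig()
    profiles = []
    for row in manifest.records.itertuples():
        try:
            signal = read_wav(row.path)
            signal = peak_normalise(signal, config.analysis.normalise_target)
        except (OSError, ValueError) as exc:
            logger.warning(
                "WARN dropped reading speaker=%s condition=%s: %s",
                row.speaker_id, row.condition, exc,
            )
            continue
        profile = extract_profile(
            signal,
            config=config.analysis,
            speaker_id=row.speaker_id,
            condition=row.condition,
        )
        for w in profile.warnings:
            logger.warning(
                "WARN speaker=%s condition=%s: %s", row.speaker_id, row.condition, w
            )
        profiles.append(profile)
    features = profiles_to_frame(profiles)
    meta = manifest.records[["speaker_id", "gender", "treatment"]].drop_duplicates()
    return features.merge(meta, on="speaker_id", how="left")


def compute_stats(diffs: pd.DataFrame, config: RunConfig | None = None) -> dict:
    """MANOVA per family, univariate follow-ups, contrasts, summaries."""
    config = config or RunConfig()
    out = {"groups": sorted(diffs["treatment"].unique()), "alpha": config.alpha,
           "correction": config.correction, "manova": {}, "features": {}}
    for family in config.families:
        try:
            res = manova_oneway(diffs, family, statistic=config.manova_statistic)
            out["manova"][family.name] = dataclasses.asdict(res)
        except ValueError as exc:
            logger.warning("WARN MANOVA skipped for family %s: %s", family.name, exc)
            out["manova"][family.name] = {"error": str(exc)}
        for feat in family.members:
            if feat not in diffs.columns:
                continue
            entry = {}
            try:
                entry["anova"] = dataclasses.asdict(anova_univariate(diffs, feat))
            except ValueError as exc:
                entry["anova"] = {"error": str(exc)}
            entry["contrasts"] = [
                {**dataclasses.asdict(c), "group_pair": list(c.group_pair)}
                for c in pairwise_contrasts(
                    diffs, feat, alpha=config.alpha, correction=config.correction
                )
            ]
            entry["group_summary"] = [
                dataclasses.asdict(s) for s in summarize_differences(diffs, feat)
            ]
            out["features"][feat] = entry
    return out


def _write_report(stats: dict, path: Path) -> None:
    lines = ["Treatment-effect report", "=" * 24, ""]
    lines.append(f"groups: {', '.join(stats['groups'])}")
    lines.append(f"alpha = {stats['alpha']}, correction = {stats['correction']}")
    lines.append("")
    lines.append("MANOVA per feature family (within-speaker BEF-AFT diffs)")
    for name, res in stats["manova"].items():
        if "error" in res:
            lines.append(f"  {name}: skipped ({res['error']})")
            continue
        lines.append(
            f"  {name}: Wilks lambda = {res['wilks_lambda']:.3f}, "
            f"F({res['df1']:.0f}, {res['df2']:.1f}) = {res['F_stat']:.2f}, "
            f"p = {res['p']:.4f}, partial eta^2 = {res['partial_eta_sq']:.3f}"
        )
    lines.append("")
    lines.append("Per-feature group means (BEF-AFT; positive = lower after treatment)")
    for feat, entry in stats["features"].items():
        summary = ", ".join(
            f"{s['treatment']}: {s['mean']:+.2f}±{s['se']:.2f}"
            for s in entry["group_summary"]
        )
        lines.append(f"  {feat}: {summary}")
        sig = [
            f"{c['group_pair'][0]}-{c['group_pair'][1]} (p_adj={c['p_adjusted']:.3f})"
            for c in entry["contrasts"]
            if c["significant"]
        ]
        if sig:
            lines.append(f"    significant contrasts: {'; '.join(sig)}")
    path.write_text("\n".join(lines) + "\n")


def plot_group_differences(diffs: pd.DataFrame, feature: str, out_path) -> Path:
    """Bar-with-error figure of per-arm mean difference values.

    One bar per treatment arm, sample-se error bars and a zero line; the
    caption states the sign convention (positive = lower after
    treatment).
    """
    if feature not in diffs.columns:
        raise ValueError(f"unknown feature {feature!r}")
    summaries = summarize_differences(diffs, feature)
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    arms = [s.treatment for s in summaries]
    means = [s.mean for s in summaries]
    ses = [0.0 if math.isnan(s.se) else s.se for s in summaries]
    ax.bar(arms, means, yerr=ses, capsize=4, color="#4878a8")
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_ylabel(f"mean BEF-AFT difference ({feature})")
    ax.set_title(feature)
    fig.text(
        0.5, 0.005,
        "Positive values: lower in AFT than BEF.",
        ha="center", fontsize=7,
    )
    fig.tight_layout(rect=(0, 0.04, 1, 1))
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def run_pipeline(
    manifest: CohortManifest, config: RunConfig | None = None, out_dir="run"
) -> Path:
    """Full chain on a cohort manifest; returns the run directory."""
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "figures").mkdir(exist_ok=True)

    features = extract_features(manifest, config)
    features.to_csv(out_dir / "features.csv", index=False)

    diffs = within_speaker_differences(features)
    diffs.to_csv(out_dir / "diffs.csv", index=False)

    stats = compute_stats(diffs, config)
    (out_dir / "stats.json").write_text(json.dumps(stats, indent=2, default=float))
    _write_report(stats, out_dir / "report.txt")

    for feat in config.plot_features:
        if feat in diffs.columns and diffs[feat].notna().any():
            plot_group_differences(diffs, feat, out_dir / "figures" / f"{feat}.png")

    checksums = {}
    for row in manifest.records.itertuples():
        try:
            checksums[Path(row.path).name] = _sha256(row.path)
        except OSError:
            checksums[Path(row.path).name] = None
    meta = {
        "config": config.to_dict(),
        "prosodiff_version": __version__,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "input_checksums": checksums,
    }
    (out_dir / "run_config.json").write_text(json.dumps(meta, indent=2))
    return out_dir
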