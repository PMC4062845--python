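"""Experiment templates tying the stages into reproducible runs.

Three templates cover the standard study designs: a 2D shell-erosion
comparison across conditions (:func:`run_2d_pipeline`), a 3D centroid /
pairwise-distance analysis (:func:`run_3d_pipeline`) and an ordered dose or
time series with onset detection (:func:`run_series`).  Each run is driven
by a :class:`RunConfig` (YAML round-trippable), takes every random draw from
one seed, and — when an output directory is set — writes CSV tables, plots
backed exactly by those tables, and a summary JSON embedding the resolved
configuration and package version.

Input images may be simulated (the ``conditions`` block) or loaded from
TIFF files listed in the ``inputs`` block with a channel mapping.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import ShellScheme
from .positioning import (
    PositionCall,
    RadialProfile,
    aggregate,
    anova_by_shell,
    classify_nuclei,
    classify_position,
    compare_conditions,
    position_frequency,
)
from .segmentation import (
    ChannelImage,
    NucleusMask,
    qc_filter,
    segment_ct,
    segment_nucleus_2d,
    segment_nucleus_3d,
)
from .shells import ShellSignal, partition_mask, quantify_shells
from .spatial3d import (
    DistanceSet,
    distance_frequency,
    geometric_center,
    pairwise_ct_distances,
    region_volume,
)
from .exceptions import EmptySignalError
from .synthetic import CTSpec, simulate_population

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "ShellsConfig",
    "ConditionSpec",
    "RunConfig",
    "Report",
    "analyze_scenes_2d",
    "run_2d_pipeline",
    "run_3d_pipeline",
    "run_series",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SegmentationConfig:
    sigma: float = 2.0
    sigma_3d: float = 1.0
    min_area: int = 200
    min_volume: int = 500
    ct_sigma: float = 1.0
    ct_min_size: int | None = None
    ct_threshold_factor: float | None = None
    qc_min_um: float = 20.0
    qc_max_um: float = 1500.0
    exclude_border: bool = True


@dataclass
class ShellsConfig:
    k: int = 5
    mode: str = "equal_area"  # equal_area | equal_volume | custom
    preset: str = "analytic"  # analytic | paper_1 (equal_volume only)
    custom_fractions: list[float] | None = None
    background_mode: str = "subtract_mean"
    quantification: str = "intensity"
    partition_method: str = "edt"

    def scheme(self) -> ShellScheme:
        if self.mode == "custom":
            if self.custom_fractions is None:
                raise ValueError("custom mode requires custom_fractions")
            return ShellScheme.custom(self.custom_fractions)
        if self.mode == "equal_volume":
            return ShellScheme.equal_volume(self.k, preset=self.preset)
        return ShellScheme.equal_area(self.k)


@dataclass
class ConditionSpec:
    """One simulated condition: population size and territory placement."""

    label: str
    n: int = 100
    cts: list[dict] = field(default_factory=lambda: [{"name": "A", "rho": "interior"}])

    def ct_specs(self) -> list[CTSpec]:
        return [CTSpec(**c) for c in self.cts]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str | None = None
    dims: int = 2
    conditions: list[ConditionSpec] = field(default_factory=list)
    inputs: list[dict] | None = None  # [{condition, dapi, probes: {name: path}}]
    pixel_size: float = 0.3
    z_step: float | None = None
    scene_overrides: dict = field(default_factory=dict)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    shells: ShellsConfig = field(default_factory=ShellsConfig)
    thresholds: tuple[float, float] | None = None
    alpha: float = 0.05
    correction: str | None = None
    bin_width: float = 1.0
    pair_label: str = "A-B"

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = SegmentationConfig(**d["segmentation"])
        if "shells" in d and isinstance(d["shells"], dict):
            d["shells"] = ShellsConfig(**d["shells"])
        if "conditions" in d:
            d["conditions"] = [
                c if isinstance(c, ConditionSpec) else ConditionSpec(**c)
                for c in d["conditions"]
            ]
        if d.get("thresholds") is not None:
            d["thresholds"] = tuple(d["thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# scene acquisition (simulate or load)


def _condition_seed(config: RunConfig, index: int) -> int:
    return int(np.random.SeedSequence((config.seed, index)).generate_state(1)[0] % (2**31))


def _collect_scenes(config: RunConfig):
    """Yield (label, list of (dapi, probes)) per condition."""
    if config.inputs:
        import tifffile

        by_cond: dict[str, list] = {}
        for entry in config.inputs:
            dapi = ChannelImage(
                tifffile.imread(entry["dapi"]),
                role="dapi",
                pixel_size=config.pixel_size,
                z_step=config.z_step,
            )
            probes = {
                name: ChannelImage(
                    tifffile.imread(p),
                    role=f"probe_{name}",
                    pixel_size=config.pixel_size,
                    z_step=config.z_step,
                )
                for name, p in entry.get("probes", {}).items()
            }
            by_cond.setdefault(entry["condition"], []).append((dapi, probes))
        return list(by_cond.items())
    if not config.conditions:
        raise ValueError("config has neither inputs nor simulated conditions")
    out = []
    for i, cond in enumerate(config.conditions):
        ds = simulate_population(
            cond.n,
            condition=cond.label,
            cts=cond.ct_specs(),
            seed=_condition_seed(config, i),
            dims=config.dims,
            scene_overrides=config.scene_overrides or None,
        )
        out.append((cond.label, [(d, p) for (_, d, p) in ds.scenes]))
    return out


# ---------------------------------------------------------------------------
# 2D pipeline


def analyze_scenes_2d(
    scenes: list[tuple[ChannelImage, dict[str, ChannelImage]]],
    config: RunConfig,
    probe_name: str | None = None,
) -> tuple[list[ShellSignal], pd.DataFrame]:
    """Segment, partition and quantify every nucleus of one condition.

    Returns the per-nucleus shell signals and the long-format shell table
    (one row per nucleus × shell).
    """
    seg = config.segmentation
    scheme = config.shells.scheme()
    signals: list[ShellSignal] = []
    rows = []
    nucleus_counter = 0
    for img_idx, (dapi, probes) in enumerate(scenes):
        if probe_name is None:
            probe = next(iter(probes.values()))
        else:
            probe = probes[probe_name]
        masks = qc_filter(
            segment_nucleus_2d(dapi, sigma=seg.sigma, min_area=seg.min_area),
            min_size_um=seg.qc_min_um,
            max_size_um=seg.qc_max_um,
            exclude_border=seg.exclude_border,
        )
        for mask in masks:
            nucleus_counter += 1
            mask.label = nucleus_counter
            part = partition_mask(mask, scheme, method=config.shells.partition_method)
            try:
                sig = quantify_shells(
                    part,
                    probe,
                    dapi,
                    background_mode=config.shells.background_mode,
                    quantification=config.shells.quantification,
                )
            except EmptySignalError:
                logger.warning("nucleus %d excluded: empty signal", nucleus_counter)
                continue
            signals.append(sig)
            for shell in range(scheme.k):
                rows.append(
                    {
                        "image": img_idx,
                        "nucleus_id": sig.nucleus_id,
                        "shell": shell + 1,
                        "p_pct": sig.p[shell],
                        "d_pct": sig.d[shell],
                        "n_norm": sig.n[shell],
                        "background_mode": sig.background_mode,
                        "scheme": scheme.mode,
                        "preset": scheme.preset,
                    }
                )
    return signals, pd.DataFrame(rows)


@dataclass
class Report:
    """Bundle of every table a run produced, plus the resolved config."""

    config: RunConfig
    signals: dict[str, list[ShellSignal]] = field(default_factory=dict)
    shell_table: pd.DataFrame | None = None
    profiles: dict[str, RadialProfile] = field(default_factory=dict)
    calls: dict[str, PositionCall | None] = field(default_factory=dict)
    per_nucleus_calls: dict[str, list[PositionCall]] = field(default_factory=dict)
    comparisons: pd.DataFrame | None = None
    anova: pd.DataFrame | None = None
    frequency: pd.DataFrame | None = None
    frequency_tests: pd.DataFrame | None = None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    distance_sets: dict[str, DistanceSet] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def run_2d_pipeline(config: RunConfig) -> Report:
    """Full 2D shell-erosion analysis across one or more conditions."""
    report = Report(config=config)
    shell_tables = []
    for label, scenes in _collect_scenes(config):
        signals, table = analyze_scenes_2d(scenes, config)
        if not signals:
            raise RuntimeError(
                f"condition {label!r}: zero nuclei passed segmentation/QC; "
                "check channel mapping, size bounds and border exclusion"
            )
        table.insert(0, "condition", label)
        shell_tables.append(table)
        report.signals[label] = signals
        profile = aggregate(signals, label)
        report.profiles[label] = profile
        try:
            report.calls[label] = classify_position(profile, config.thresholds)
        except ValueError as exc:
            logger.error("condition %r: classification refused: %s", label, exc)
            report.calls[label] = None
            report.summary.setdefault("classification_error", str(exc))
        if config.shells.k >= 2:
            report.per_nucleus_calls[label] = classify_nuclei(signals, config.thresholds)
    report.shell_table = pd.concat(shell_tables, ignore_index=True)

    labels = list(report.signals)
    if len(labels) >= 2:
        comp_rows = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                df = compare_conditions(
                    report.signals[labels[i]],
                    report.signals[labels[j]],
                    alpha=config.alpha,
                    correction=config.correction,
                )
                df.insert(0, "condition_a", labels[i])
                df.insert(1, "condition_b", labels[j])
                comp_rows.append(df)
        report.comparisons = pd.concat(comp_rows, ignore_index=True)
        if len(labels) > 2:
            report.anova = anova_by_shell([report.signals[l] for l in labels])
        if report.per_nucleus_calls:
            report.frequency, report.frequency_tests = position_frequency(
                report.per_nucleus_calls
            )

    report.summary.update(
        {
            "template": "2d",
            "version": __version__,
            "conditions": {
                label: {
                    "n_nuclei": report.profiles[label].n_nuclei,
                    "m": report.calls[label].m if report.calls[label] else None,
                    "category": report.calls[label].category
                    if report.calls[label]
                    else None,
                }
                for label in labels
            },
        }
    )
    _write_outputs(report)
    return report


# ---------------------------------------------------------------------------
# 3D pipeline


def run_3d_pipeline(config: RunConfig) -> Report:
    """3D centroid, radial-distance, pairwise-distance and volume analysis."""
    config = dataclasses.replace(config, dims=3)
    seg = config.segmentation
    report = Report(config=config)
    centroid_rows, distance_rows, volume_rows, pairwise_summaries = [], [], [], []
    freq_tables = []
    for label, scenes in _collect_scenes(config):
        per_nucleus_pairs = []
        probe_names: list[str] = []
        n_kept = 0
        for img_idx, (dapi, probes) in enumerate(scenes):
            probe_names = list(probes)
            masks = qc_filter(
                segment_nucleus_3d(dapi, sigma=seg.sigma_3d, min_volume=seg.min_volume),
                min_size_um=seg.qc_min_um,
                max_size_um=seg.qc_max_um,
                exclude_border=seg.exclude_border,
            )
            for mask in masks:
                n_kept += 1
                mask.label = n_kept
                nuc_center = geometric_center(mask, "nucleus")
                centroid_rows.append(_centroid_row(label, img_idx, nuc_center))
                volume_rows.append(
                    {
                        "condition": label,
                        "nucleus_id": mask.label,
                        "object": "nucleus",
                        "volume_um3": region_volume(mask),
                    }
                )
                ct_centroids: dict[str, list] = {}
                for name, probe in probes.items():
                    regions = segment_ct(
                        probe,
                        mask,
                        sigma=seg.ct_sigma,
                        min_size=seg.ct_min_size,
                        threshold_factor=seg.ct_threshold_factor,
                        name=name,
                    )
                    ct_centroids[name] = []
                    for region in regions:
                        cen = geometric_center(region, name)
                        cen.nucleus_id = mask.label
                        ct_centroids[name].append(cen)
                        centroid_rows.append(_centroid_row(label, img_idx, cen))
                        distance_rows.append(
                            {
                                "condition": label,
                                "nucleus_id": mask.label,
                                "object": name,
                                "distance_um": float(
                                    np.linalg.norm(
                                        np.subtract(cen.center, nuc_center.center)
                                    )
                                ),
                            }
                        )
                        volume_rows.append(
                            {
                                "condition": label,
                                "nucleus_id": mask.label,
                                "object": name,
                                "volume_um3": region_volume(region),
                            }
                        )
                if len(probe_names) >= 2:
                    per_nucleus_pairs.append(
                        (
                            ct_centroids.get(probe_names[0], []),
                            ct_centroids.get(probe_names[1], []),
                        )
                    )
        if n_kept == 0:
            raise RuntimeError(f"condition {label!r}: zero nuclei passed QC")
        if per_nucleus_pairs:
            pair = f"{probe_names[0]}-{probe_names[1]}"
            ds = pairwise_ct_distances(per_nucleus_pairs, pair=pair)
            report.distance_sets[label] = ds
            pairwise_summaries.append(
                {"condition": label, "pair": pair, "n_nuclei": ds.n_nuclei, **ds.summary}
            )

    report.tables["centroids"] = pd.DataFrame(centroid_rows)
    distances = pd.DataFrame(distance_rows)
    report.tables["distances"] = distances
    report.tables["volumes"] = pd.DataFrame(volume_rows)
    for (label, obj), grp in distances.groupby(["condition", "object"]):
        ft = distance_frequency(grp["distance_um"], config.bin_width)
        ft.insert(0, "condition", label)
        ft.insert(1, "object", obj)
        freq_tables.append(ft)
    report.tables["distance_frequency"] = pd.concat(freq_tables, ignore_index=True)
    if pairwise_summaries:
        report.tables["pairwise_summary"] = pd.DataFrame(pairwise_summaries)
    report.summary.update(
        {
            "template": "3d",
            "version": __version__,
            "median_pairwise_um": {
                label: ds.summary["median"] for label, ds in report.distance_sets.items()
            },
        }
    )
    _write_outputs(report)
    return report


def _centroid_row(condition, image, record):
    row = {
        "condition": condition,
        "image": image,
        "nucleus_id": record.nucleus_id,
        "object": record.object_label,
        "x_um": record.center[0],
        "y_um": record.center[1],
    }
    if len(record.center) == 3:
        row["z_um"] = record.center[2]
    return row


# ---------------------------------------------------------------------------
# ordered series


def run_series(config: RunConfig) -> Report:
    """Ordered dose/time series: per-condition calls and onset detection.

    The first condition is the reference.  Each later condition is compared
    to it shell-by-shell (Holm-adjusted unless the config overrides); the
    onset is the first condition with any flagged shell.
    """
    labels = [c.label for c in config.conditions]
    if len(labels) < 2:
        raise ValueError("a series needs at least two ordered conditions")
    if len(set(labels)) != len(labels):
        raise ValueError("series condition labels must be unique")
    correction = config.correction if config.correction is not None else "holm"
    base = dataclasses.replace(config, correction=correction)
    report = run_2d_pipeline(base)

    onset = None
    rows = []
    ref = labels[0]
    for label in labels[1:]:
        comp = report.comparisons
        sub = comp[(comp.condition_a == ref) & (comp.condition_b == label)]
        flagged = bool(sub["flag"].any())
        rows.append(
            {
                "condition": label,
                "m": report.calls[label].m if report.calls[label] else None,
                "category": report.calls[label].category if report.calls[label] else None,
                "min_p": float(sub["p"].min()),
                "flagged": flagged,
            }
        )
        if flagged and onset is None:
            onset = label
    report.tables["series"] = pd.DataFrame(rows)
    report.summary.update({"template": "series", "reference": ref, "onset": onset})
    _write_outputs(report)
    return report


# ---------------------------------------------------------------------------
# output


def _write_outputs(report: Report) -> None:
    out = report.config.out_dir
    if not out:
        return
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger("ctradial").addHandler(handler)
    try:
        if report.shell_table is not None:
            report.shell_table.to_csv(out / "shell_signals.csv", index=False)
        if report.profiles:
            prof_rows = [
                {
                    "condition": label,
                    "shell": i + 1,
                    "mean_n": p.mean_n[i],
                    "sem_n": p.sem_n[i],
                    "n_nuclei": p.n_nuclei,
                }
                for label, p in report.profiles.items()
                for i in range(p.k)
            ]
            pd.DataFrame(prof_rows).to_csv(out / "profiles.csv", index=False)
            _plot_profiles(report, out / "profiles.png")
        if report.per_nucleus_calls:
            call_rows = [
                {"condition": label, "nucleus_id": i, "m": c.m, "category": c.category}
                for label, calls in report.per_nucleus_calls.items()
                for i, c in enumerate(calls)
            ]
            pd.DataFrame(call_rows).to_csv(out / "calls.csv", index=False)
        if report.comparisons is not None:
            report.comparisons.to_csv(out / "comparisons.csv", index=False)
        if report.anova is not None:
            report.anova.to_csv(out / "anova.csv", index=False)
        if report.frequency is not None:
            report.frequency.to_csv(out / "position_frequency.csv")
            report.frequency_tests.to_csv(out / "position_frequency_tests.csv", index=False)
        for name, table in report.tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump({**report.summary, "config": report.config.as_dict()}, fh, indent=2)
        report.config.to_yaml(out / "config_resolved.yaml")
    finally:
        logging.getLogger("ctradial").removeHandler(handler)
        handler.close()


def _plot_profiles(report: Report, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    labels = list(report.profiles)
    k = report.profiles[labels[0]].k
    width = 0.8 / len(labels)
    x = np.arange(1, k + 1)
    for i, label in enumerate(labels):
        p = report.profiles[label]
        ax.bar(
            x + (i - (len(labels) - 1) / 2) * width,
            p.mean_n,
            width,
            yerr=p.sem_n,
            capsize=2,
            label=f"{label} (n={p.n_nuclei})",
        )
    ax.set_xlabel("shell (1 = interior)")
    ax.set_ylabel("normalized probe/DAPI ratio")
    ax.set_xticks(x)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
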