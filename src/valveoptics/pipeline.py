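"""End-to-end analysis pipeline: from section inputs to a study report.

For every section the pipeline computes the per-region TPEF ratio summary,
QPLI retardation/orientation/variance summary, PSR fiber-thickness bins and
ARS percent area; study-level it derives echo volumes, grades IHC scores, runs
diet x week comparisons per metric and region, and computes the correlation
panel (TPEF ratios against collagen-remodeling metrics and calcification,
pooled across regions and per region).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .echo import aggregate_score_table, echo_derive_table
from .histology import ars_percent_area, psr_bin, StainImage
from .phantom import PhantomConfig, StudyData, generate_study
from .qpli import directional_variance, fit_retardation_orientation, qpli_region_summary, PolarizationStack
from .roi import RegionAnnotation, rasterize
from .stats import compare_groups, correlate
from .tpef import ChannelSet, tpef_region_summary

SECTION_METRICS = (
    "ratio_755_860",
    "col_cal_ratio",
    "avg_retardation_deg",
    "avg_directional_variance",
    "collagen_density",
    "ars_percent_area",
)


@dataclass
class PipelineConfig:
    """Analysis-stage defaults; every knob mirrors a module default."""

    intensity_floor: float | None = None  # None: background mean + 2 sd
    collagen_threshold_deg: float = 5.0
    variance_window: int = 11
    variance_min_count: int = 10
    ars_threshold: int = 100
    ars_min_particle: int = 4
    psr_sat_floor: float = 0.25
    psr_val_floor: float = 0.10
    literal_echo_volumes: bool = False
    correlation_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def analyze_section(
    channels: ChannelSet,
    stack: PolarizationStack,
    psr: StainImage,
    ars: StainImage,
    annotation: RegionAnnotation,
    config: PipelineConfig | None = None,
    masks=None,
) -> dict:
    """Compute all per-region metrics for one section.

    Returns {"metrics": long DataFrame rows, "maps": per-pixel result fields,
    "tables": the raw per-module summary tables}. ``masks`` may carry a
    pre-rasterized RegionMask for the annotation (it is recomputed otherwise).
    """
    config = config or PipelineConfig()
    if masks is None:
        masks = rasterize(annotation, channels.shape)

    tpef_tab = tpef_region_summary(channels, masks, floor=config.intensity_floor)
    fibers = fit_retardation_orientation(
        stack, collagen_threshold_deg=config.collagen_threshold_deg
    )
    variance = directional_variance(
        fibers, window=config.variance_window, min_count=config.variance_min_count
    )
    qpli_tab = qpli_region_summary(fibers, variance, masks)
    psr_res = psr_bin(psr, masks, sat_floor=config.psr_sat_floor, val_floor=config.psr_val_floor)
    ars_res = ars_percent_area(
        ars, masks, threshold=config.ars_threshold, min_particle=config.ars_min_particle
    )

    rows = []
    for _, r in tpef_tab.iterrows():
        rows.append({"region": r.region, "metric": "ratio_755_860", "value": r.ratio_755_860})
        rows.append({"region": r.region, "metric": "col_cal_ratio", "value": r.col_cal_ratio})
        for key in ("mean_a755_460", "mean_a860_525", "mean_a810_460", "mean_a810_525"):
            rows.append({"region": r.region, "metric": key, "value": r[key]})
    for _, r in qpli_tab.iterrows():
        rows.append({"region": r.region, "metric": "avg_retardation_deg", "value": r.avg_retardation_deg})
        rows.append(
            {"region": r.region, "metric": "avg_directional_variance", "value": r.avg_directional_variance}
        )
        rows.append({"region": r.region, "metric": "collagen_density", "value": r.collagen_density})
    for _, r in psr_res.table.iterrows():
        for cls in ("thick", "thick_intermediate", "thin_intermediate", "thin"):
            rows.append({"region": r.region, "metric": f"psr_pct_{cls}", "value": r[f"pct_{cls}"]})
    for _, r in ars_res.table.iterrows():
        rows.append({"region": r.region, "metric": "ars_percent_area", "value": r.percent_area})

    from .tpef import ratio_755_860, ratio_col_cal, background_floor

    floor = config.intensity_floor
    if floor is None:
        floor = background_floor(channels, masks)
    maps = {
        "ratio_755_860": ratio_755_860(channels, floor).values,
        "col_cal_ratio": ratio_col_cal(channels, floor).values,
        "retardation_deg": fibers.retardation_deg,
        "orientation_deg": fibers.orientation_deg,
        "directional_variance": variance.directional_variance,
    }
    return {
        "metrics": pd.DataFrame(rows),
        "maps": maps,
        "tables": {"tpef": tpef_tab, "qpli": qpli_tab, "psr": psr_res.table, "ars": ars_res.table},
    }


def build_study_table(study: StudyData, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Measured long-format metric table for every animal in a phantom study,
    concatenated with the generator's truth table."""
    frames = []
    for ds in study.datasets:
        res = analyze_section(
            ds.channel_set, ds.polarization_stack, ds.psr, ds.ars, ds.annotation, config,
            masks=ds.masks,
        )
        m = res["metrics"].copy()
        for key in ("animal", "diet", "week"):
            m[key] = ds.meta[key]
        frames.append(m)
    measured = pd.concat(frames, ignore_index=True)
    return pd.concat([measured, study.truth_table], ignore_index=True)


def _pivot(table: pd.DataFrame, metric: str, region: str | None = None) -> pd.DataFrame:
    sub = table[table.metric == metric]
    if region is not None:
        sub = sub[sub.region == region]
    return sub


def correlation_panel(
    table: pd.DataFrame,
    score_table: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """TPEF-ratio vs collagen/calcification correlation panel.

    Each pair is computed pooled across regions and per region, labelled in the
    ``scope`` column. Score correlations (ordinal) force Spearman.
    """
    pairs = [
        ("ratio_755_860", "avg_retardation_deg", False),
        ("ratio_755_860", "avg_directional_variance", False),
        ("avg_retardation_deg", "avg_directional_variance", False),
        ("col_cal_ratio", "avg_retardation_deg", False),
        ("ratio_755_860", "ars_percent_area", False),
        ("ratio_755_860", "truth_calcium_burden", False),
        ("mean_a810_460", "collagen_density", False),
        ("mean_a810_525", "collagen_density", False),
    ]
    regions = sorted(table.region.unique())
    rows = []
    for metric_x, metric_y, ordinal in pairs:
        for scope in ["pooled", *regions]:
            region = None if scope == "pooled" else scope
            x = _pivot(table, metric_x, region).set_index(["animal", "region"]).value
            y = _pivot(table, metric_y, region).set_index(["animal", "region"]).value
            joined = pd.concat([x.rename("x"), y.rename("y")], axis=1, join="inner").dropna()
            if len(joined) < 3:
                continue
            try:
                res = correlate(joined.x, joined.y, method="auto", ordinal=ordinal, alpha=alpha)
            except ValueError:
                continue
            rows.append(
                {
                    "x": metric_x, "y": metric_y, "scope": scope, "method": res.method,
                    "coefficient": res.coefficient, "p": res.p, "n": res.n,
                }
            )

    if score_table is not None and not score_table.empty:
        graded = aggregate_score_table(score_table)
        for marker in ("RUNX2", "Ki67", "osteopontin"):
            sc = graded[graded.marker == marker].set_index("animal").mean_score
            for metric_x in ("ratio_755_860", "mean_a810_460", "mean_a810_525"):
                x = _pivot(table, metric_x, "commissure").set_index("animal").value
                joined = pd.concat([x.rename("x"), sc.rename("y")], axis=1, join="inner").dropna()
                if len(joined) < 3:
                    continue
                try:
                    res = correlate(joined.x, joined.y, method="spearman", ordinal=True)
                except ValueError:
                    continue
                rows.append(
                    {
                        "x": metric_x, "y": f"score_{marker}", "scope": "commissure",
                        "method": res.method, "coefficient": res.coefficient,
                        "p": res.p, "n": res.n,
                    }
                )
    return pd.DataFrame(rows)


def comparison_panel(
    table: pd.DataFrame,
    alpha: float = 0.05,
    metrics: tuple[str, ...] | None = None,
    regions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Diet x week comparison for every section metric and region; metrics or
    regions without sufficient replication are reported with a reason."""
    rows = []
    for metric in metrics or SECTION_METRICS:
        for region in regions or sorted(table.region.unique()):
            try:
                res = compare_groups(table, metric, region, alpha=alpha)
            except ValueError as exc:
                rows.append(
                    {"metric": metric, "region": region, "test": "skipped", "detail": str(exc)}
                )
                continue
            for _, f in res.factors.iterrows():
                rows.append(
                    {
                        "metric": metric, "region": region, "test": res.test_used,
                        "detail": f"factor:{f.factor}", "statistic": f.statistic, "p": f.p,
                    }
                )
            for _, c in res.contrasts.iterrows():
                rows.append(
                    {
                        "metric": metric, "region": region, "test": res.test_used,
                        "detail": f"contrast:{c.group1} vs {c.group2}", "p": c.p_adj,
                        "reject": bool(c.reject),
                    }
                )
    return pd.DataFrame(rows)


def analyze_study(
    study: StudyData,
    config: PipelineConfig | None = None,
    comparison_metrics: tuple[str, ...] | None = None,
    comparison_regions: tuple[str, ...] | None = None,
) -> dict:
    """Full study report: metric table, comparisons, correlations, derived
    echo table and graded scores. ``comparison_metrics``/``comparison_regions``
    restrict the comparison panel (the default covers every section metric)."""
    config = config or PipelineConfig()
    table = build_study_table(study, config)
    report = {
        "metrics": table,
        "comparisons": comparison_panel(
            table,
            alpha=config.correlation_alpha,
            metrics=comparison_metrics,
            regions=comparison_regions,
        ),
        "correlations": correlation_panel(
            table, study.score_table, alpha=config.correlation_alpha
        ),
        "echo": echo_derive_table(study.echo_table, literal_volumes=config.literal_echo_volumes),
        "scores": aggregate_score_table(study.score_table),
    }
    return report


def headline_signs(report: dict, week_late: int = 16) -> dict:
    """Qualitative headline checks on a study report.

    * ``ratio_lower``: commissure 755-860 ratio mean is lower in pro-calcific
      week-``week_late`` animals than in same-week controls.
    * ``contrast_significant``: that diet contrast is flagged significant in
      the comparison panel.
    * ``negative_correlation``: the commissure 755-860 ratio correlates
      negatively with truth calcium burden.
    * ``ars_increases``: pro-calcific ARS percent area rises from the earliest
      to the latest week.
    """
    table = report["metrics"]
    sub = _pivot(table, "ratio_755_860", "commissure")
    mean_pro = sub[(sub.diet == "pro_calcific") & (sub.week == week_late)].value.mean()
    mean_ctl = sub[(sub.diet == "control") & (sub.week == week_late)].value.mean()
    ratio_lower = bool(mean_pro < mean_ctl)

    comp = report["comparisons"]
    contrast = comp[
        (comp.metric == "ratio_755_860")
        & (comp.region == "commissure")
        & (comp.detail.astype(str).str.contains(f"control-{week_late} vs pro_calcific-{week_late}"))
    ]
    contrast_significant = bool(contrast.reject.any()) if not contrast.empty else False

    corr = report["correlations"]
    hit = corr[
        (corr.x == "ratio_755_860")
        & (corr.y == "truth_calcium_burden")
        & (corr.scope == "commissure")
    ]
    negative_correlation = bool(not hit.empty and hit.coefficient.iloc[0] < 0)

    ars = _pivot(table, "ars_percent_area", "commissure")
    pro = ars[ars.diet == "pro_calcific"]
    weeks = sorted(pro.week.unique())
    ars_increases = bool(
        len(weeks) >= 2
        and pro[pro.week == weeks[-1]].value.mean() > pro[pro.week == weeks[0]].value.mean()
    )
    return {
        "ratio_lower": ratio_lower,
        "contrast_significant": contrast_significant,
        "negative_correlation": negative_correlation,
        "ars_increases": ars_increases,
    }


def sign_reproduction_rate(
    n_replicates: int = 200,
    n_per_group: int = 4,
    effect_size: float = 3.0,
    weeks: tuple[int, ...] = (4, 16),
    image_size: tuple[int, int] = (64, 64),
    seed: int = 0,
    base_config: PhantomConfig | None = None,
) -> dict:
    """Fraction of seeded phantom-study replicates reproducing each headline
    sign. Returns per-check rates plus the joint rate under ``"all"``."""
    counts = {"ratio_lower": 0, "contrast_significant": 0, "negative_correlation": 0, "ars_increases": 0}
    joint = 0
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_replicates)]
    for child in child_seeds:
        if base_config is None:
            cfg = PhantomConfig(image_size=image_size, effect_size=effect_size, seed=child)
        else:
            cfg = replace(base_config, effect_size=effect_size, seed=child)
        study = generate_study(cfg, n_per_group=n_per_group, weeks=weeks)
        report = analyze_study(
            study,
            comparison_metrics=("ratio_755_860", "ars_percent_area"),
            comparison_regions=("commissure",),
        )
        signs = headline_signs(report, week_late=max(w for w in weeks if w <= 16))
        for key in counts:
            counts[key] += signs[key]
        joint += all(signs.values())
    rates = {key: val / n_replicates for key, val in counts.items()}
    rates["all"] = joint / n_replicates
    rates["n_replicates"] = n_replicates
    return rates


def _hash_file(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()[:16]


def run_pipeline(input_dir: str | Path, out_dir: str | Path, config: PipelineConfig | None = None) -> dict:
    """Run the full analysis on a study directory and write the report.

    Outputs: region_metrics.csv, comparisons.csv, correlations.csv,
    echo_derived.csv, scores_graded.csv, per-animal result maps (32-bit TIFF)
    and log.json with input hashes and configuration.
    """
    from .io import read_study

    config = config or PipelineConfig()
    src, out = Path(input_dir), Path(out_dir)
    study_files = read_study(src)
    out.mkdir(parents=True, exist_ok=True)
    (out / "maps").mkdir(exist_ok=True)

    frames = []
    for row in study_files["animals"].itertuples():
        sec = study_files["sections"][row.animal]
        res = analyze_section(
            sec["channels"], sec["stack"], sec["psr"], sec["ars"], sec["annotation"], config
        )
        m = res["metrics"].copy()
        m["animal"], m["diet"], m["week"] = row.animal, row.diet, row.week
        frames.append(m)
        for name, arr in res["maps"].items():
            tifffile.imwrite(out / "maps" / f"{row.animal}_{name}.tif", arr.astype(np.float32))
    table = pd.concat(frames, ignore_index=True)
    if study_files.get("truth") is not None:
        table = pd.concat([table, study_files["truth"]], ignore_index=True)

    report = {"metrics": table}
    report["comparisons"] = comparison_panel(table, alpha=config.correlation_alpha)
    report["correlations"] = correlation_panel(table, study_files.get("scores"))
    table.to_csv(out / "region_metrics.csv", index=False)
    report["comparisons"].to_csv(out / "comparisons.csv", index=False)
    report["correlations"].to_csv(out / "correlations.csv", index=False)
    if study_files.get("echo") is not None:
        report["echo"] = echo_derive_table(study_files["echo"], config.literal_echo_volumes)
        report["echo"].to_csv(out / "echo_derived.csv", index=False)
    if study_files.get("scores") is not None:
        report["scores"] = aggregate_score_table(study_files["scores"])
        report["scores"].to_csv(out / "scores_graded.csv", index=False)

    log = {
        "version": __version__,
        "config": asdict(config),
        "inputs": {
            str(p.relative_to(src)): _hash_file(p) for p in sorted(src.rglob("*")) if p.is_file()
        },
    }
    with open(out / "log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    report["log"] = log
    return report
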