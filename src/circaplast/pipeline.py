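"""End-to-end synthetic study: simulate → analyze → compare → report.

The default configuration mirrors the study design the package emulates:
four lighting conditions (LD 12:12, DD, LD 16:8, LL) × 8 animals recorded
for 10 days, and for imaging 4 time points (ZT/CT 0, 6, 12, 18) × 8 fields
× 3 presynaptic/postsynaptic protein pairs.  Condition blocks plant the
regime-typical patterns: light-locked onsets under LD, a ~19 min/cycle
onset advance under DD, a ~46 min/cycle delay with low activity and 50%
arrhythmicity under LL, regime-specific activity-phase lengths and
mid-activity breaks, and a day-high synapse (colocalization) fraction
except under LL where the cycle is flattened.

Every stochastic stage draws its seed from the master seed by stable
hashing of (module, entity id), so a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

from .records import LightSchedule, Regime, make_light_schedule
from .rhythm import (
    AnalysisConfig,
    RhythmParams,
    analyze_record,
    bin_activity,
    build_actogram,
    chi_square_periodogram,
)
from .puncta import ImageField, classify_expression_change, quantify_field
from .stats import ComparisonResult, GroupSample, compare_groups
from .synthetic import (
    SimActivityParams,
    SimImageParams,
    simulate_activity,
    simulate_puncta_field,
)

logger = logging.getLogger("circaplast.pipeline")

__all__ = [
    "RunConfig",
    "ReportBundle",
    "run_activity_study",
    "run_imaging_study",
    "full_run",
    "DEFAULT_ACTIVITY_BLOCKS",
    "DEFAULT_COLOC_PATTERNS",
]

CONDITIONS = ("LD12_12", "DD", "LD16_8", "LL")
PROTEIN_PAIRS = ("Syp1-PSD95", "Piccolo-Homer1", "NRXN-PICK1")

#: Per-condition simulation blocks emulating the regime-typical locomotor
#: patterns (activity-phase length, onset drift, break length, intensity).
DEFAULT_ACTIVITY_BLOCKS: dict[str, dict] = {
    "LD12_12": dict(
        masking=True, alpha_true=11.8, break_spec=(5.0, 1.46),
        mean_rate_active=15.0, mean_rate_rest=0.3,
    ),
    "DD": dict(
        drift_per_cycle=-19.0, alpha_true=12.7, break_spec=(5.5, 2.34),
        mean_rate_active=14.0, mean_rate_rest=0.4,
    ),
    "LD16_8": dict(
        masking=True, alpha_true=8.2, break_spec=(4.0, 0.29),
        mean_rate_active=20.0, mean_rate_rest=0.3,
    ),
    "LL": dict(
        drift_per_cycle=46.3, alpha_true=9.1,
        mean_rate_active=6.0, mean_rate_rest=0.2,
    ),
}

#: Planted colocalized fraction per condition and time point: day-high
#: synapse density under LD 12:12, a CT12 minimum under DD, a ZT0 peak
#: under LD 16:8, and a flattened cycle under constant light.
DEFAULT_COLOC_PATTERNS: dict[str, dict[int, float]] = {
    "LD12_12": {0: 0.63, 6: 0.65, 12: 0.50, 18: 0.49},
    "DD": {0: 0.66, 6: 0.58, 12: 0.48, 18: 0.57},
    "LD16_8": {0: 0.62, 6: 0.55, 12: 0.54, 18: 0.57},
    "LL": {0: 0.58, 6: 0.58, 12: 0.58, 18: 0.58},
}

#: Baseline puncta per channel for each protein pair (pre, post).
DEFAULT_PAIR_PUNCTA: dict[str, tuple[int, int]] = {
    "Syp1-PSD95": (100, 100),
    "Piccolo-Homer1": (110, 105),
    "NRXN-PICK1": (90, 95),
}


@dataclass
class RunConfig:
    """Study design, simulation blocks and analysis settings for one run."""

    master_seed: int = 0
    conditions: tuple[str, ...] = CONDITIONS
    n_animals: int = 8
    n_days: int = 10
    sim_bin_minutes: float = 1.0
    arrhythmic_fraction: dict[str, float] = field(
        default_factory=lambda: {"LL": 0.5}
    )
    activity_blocks: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ACTIVITY_BLOCKS.items()}
    )
    time_points: tuple[int, ...] = (0, 6, 12, 18)
    protein_pairs: tuple[str, ...] = PROTEIN_PAIRS
    n_fields: int = 8
    coloc_patterns: dict[str, dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COLOC_PATTERNS.items()}
    )
    pair_puncta: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_PUNCTA)
    )
    image_params: dict = field(default_factory=dict)  # SimImageParams overrides
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    lights_on_clock: float = 8.0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "analysis" in d and isinstance(d["analysis"], dict):
            d["analysis"] = AnalysisConfig(**d["analysis"])
        for key in ("conditions", "time_points", "protein_pairs"):
            if key in d:
                d[key] = tuple(d[key])
        if "coloc_patterns" in d:
            d["coloc_patterns"] = {
                k: {int(t): float(v) for t, v in pat.items()}
                for k, pat in d["coloc_patterns"].items()
            }
        if "pair_puncta" in d:
            d["pair_puncta"] = {k: tuple(v) for k, v in d["pair_puncta"].items()}
        if "activity_blocks" in d:
            d["activity_blocks"] = {
                k: {
                    kk: (tuple(vv) if kk == "break_spec" and vv is not None else vv)
                    for kk, vv in blk.items()
                }
                for k, blk in d["activity_blocks"].items()
            }
        return cls(**d)


def derive_seed(master_seed: int, *keys) -> int:
    """Stable child seed below 2**31 from the master seed and entity keys."""
    ss = np.random.SeedSequence(
        [int(master_seed)] + [zlib.crc32(str(k).encode()) for k in keys]
    )
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class ReportBundle:
    """All tables produced by a run (figures are written separately)."""

    activity_params: pd.DataFrame | None = None
    activity_comparisons: pd.DataFrame | None = None
    imaging_fields: pd.DataFrame | None = None
    imaging_comparisons: pd.DataFrame | None = None
    expression_labels: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        for sub, df, name in [
            ("activity", self.activity_params, "rhythm_params.csv"),
            ("stats", self.activity_comparisons, "activity_comparisons.csv"),
            ("imaging", self.imaging_fields, "field_quantification.csv"),
            ("stats", self.imaging_comparisons, "imaging_comparisons.csv"),
            ("stats", self.expression_labels, "expression_labels.csv"),
        ]:
            if df is not None:
                (outdir / sub).mkdir(parents=True, exist_ok=True)
                df.to_csv(outdir / sub / name, index=False)
        if self.warnings:
            (outdir).mkdir(parents=True, exist_ok=True)
            (outdir / "warnings.txt").write_text("\n".join(self.warnings) + "\n")


def _schedule_for(config: RunConfig, condition: str) -> LightSchedule:
    return make_light_schedule(
        Regime(condition),
        lights_on_clock=config.lights_on_clock,
        acclimation_lights_on=config.lights_on_clock,
    )


def _comparison_rows(
    result: ComparisonResult, **meta
) -> list[dict]:
    rows = []
    for _, r in result.pairwise.iterrows():
        rows.append(
            {
                **meta,
                "test": result.test_used,
                "omnibus_stat": result.statistic,
                "omnibus_p": result.p_value,
                "group_a": r.group_a,
                "group_b": r.group_b,
                "p_adj": r.p_adj,
                "direction": r.direction,
            }
        )
    return rows


ACTIVITY_COMPARED_VARS = (
    "tau_h",
    "delta_h",
    "alpha_h",
    "rho_h",
    "overall_activity",
    "percent_qp",
    "day_activity",
    "night_activity",
    "percent_day",
)


def run_activity_study(config: RunConfig) -> ReportBundle:
    """Simulate and analyze every animal, then compare conditions.

    Analysis starts 24 h after the lighting switch (the first recorded day
    is dropped), so eight-plus complete cycles remain for every animal.
    """
    rows = []
    warnings_: list[str] = []
    for condition in config.conditions:
        schedule = _schedule_for(config, condition)
        block = config.activity_blocks.get(condition, {})
        arr_frac = config.arrhythmic_fraction.get(condition, 0.0)
        n_arr = int(round(arr_frac * config.n_animals))
        for i in range(config.n_animals):
            animal = f"{condition}_{i:02d}"
            params = SimActivityParams(
                **block,
                arrhythmic=i < n_arr,
                seed=derive_seed(config.master_seed, "activity", animal),
            )
            record, _truth = simulate_activity(
                params,
                schedule,
                n_days=config.n_days,
                bin_minutes=config.sim_bin_minutes,
                animal_id=animal,
            )
            analyzed = record.slice_hours(24.0)  # span starts 24 h after switch
            rp = analyze_record(analyzed, config.analysis)
            logger.info("activity %s analyzed: tau=%.2f rhythmic=%s",
                        animal, rp.tau_h, rp.rhythmic)
            if not rp.rhythmic:
                warnings_.append(f"{animal}: arrhythmic; alpha/delta withheld")
            row = dataclasses.asdict(rp)
            row["condition"] = condition
            rows.append(row)
    params_df = pd.DataFrame(rows)
    front = ["condition", "animal_id"]
    params_df = params_df[front + [c for c in params_df.columns if c not in front]]

    comp_rows = []
    for var in ACTIVITY_COMPARED_VARS:
        samples = []
        for condition in config.conditions:
            vals = params_df.loc[params_df.condition == condition, var].dropna()
            if len(vals) >= 3:
                samples.append(GroupSample(condition, vals.to_numpy()))
            else:
                warnings_.append(
                    f"{var}: condition {condition} has n={len(vals)} < 3; excluded"
                )
        if len(samples) < 2:
            continue
        comp_rows.extend(
            _comparison_rows(compare_groups(samples), variable=var)
        )
    return ReportBundle(
        activity_params=params_df,
        activity_comparisons=pd.DataFrame(comp_rows),
        warnings=warnings_,
    )


IMAGING_COMPARED_VARS = (
    "count_pre",
    "area_fraction_pre_pct",
    "count_post",
    "area_fraction_post_pct",
    "density_per_um3",
)


def run_imaging_study(config: RunConfig) -> ReportBundle:
    """Simulate and quantify every field, compare time points per condition,
    and attach expression-change labels to each channel and contrast."""
    rows = []
    warnings_: list[str] = []
    base = dict(config.image_params)
    for pair in config.protein_pairs:
        n_pre, n_post = config.pair_puncta.get(pair, (100, 100))
        for condition in config.conditions:
            pattern = config.coloc_patterns.get(condition, {})
            for tp in config.time_points:
                cf = pattern.get(tp, 0.6)
                for f in range(config.n_fields):
                    fid = f"{pair}_{condition}_T{tp:02d}_F{f:02d}"
                    params = SimImageParams(
                        **{
                            "n_puncta_a": n_pre,
                            "n_puncta_b": n_post,
                            "coloc_fraction": cf,
                            **base,
                            "seed": derive_seed(config.master_seed, "imaging", fid),
                        }
                    )
                    img, _truth = simulate_puncta_field(params)
                    fieldobj = ImageField(
                        channels=img,
                        pixel_size_um=params.pixel_size,
                        optical_thickness_um=params.optical_thickness,
                        field_id=fid,
                    )
                    q = quantify_field(fieldobj)
                    row = dataclasses.asdict(q)
                    row.update(pair=pair, condition=condition, time_point=tp)
                    rows.append(row)
                logger.info("imaging %s/%s/T%02d quantified", pair, condition, tp)
    fields_df = pd.DataFrame(rows)
    front = ["pair", "condition", "time_point", "field_id"]
    fields_df = fields_df[front + [c for c in fields_df.columns if c not in front]]

    comp_rows = []
    results: dict[tuple[str, str, str], ComparisonResult] = {}
    for pair in config.protein_pairs:
        for condition in config.conditions:
            sub = fields_df[
                (fields_df.pair == pair) & (fields_df.condition == condition)
            ]
            for var in IMAGING_COMPARED_VARS:
                samples = [
                    GroupSample(
                        f"T{tp:02d}",
                        sub.loc[sub.time_point == tp, var].to_numpy(),
                    )
                    for tp in config.time_points
                ]
                res = compare_groups(samples)
                results[(pair, condition, var)] = res
                comp_rows.extend(
                    _comparison_rows(
                        res, pair=pair, condition=condition, variable=var
                    )
                )

    label_rows = []
    for pair in config.protein_pairs:
        for condition in config.conditions:
            for channel, cvar, avar in (
                ("presynaptic", "count_pre", "area_fraction_pre_pct"),
                ("postsynaptic", "count_post", "area_fraction_post_pct"),
            ):
                cres = results[(pair, condition, cvar)]
                ares = results[(pair, condition, avar)]
                for _, r in cres.pairwise.iterrows():
                    label = classify_expression_change(
                        r.direction, ares.verdict(r.group_a, r.group_b)
                    )
                    label_rows.append(
                        {
                            "pair": pair,
                            "condition": condition,
                            "channel": channel,
                            "from": r.group_a,
                            "to": r.group_b,
                            "label": label.value,
                        }
                    )
    return ReportBundle(
        imaging_fields=fields_df,
        imaging_comparisons=pd.DataFrame(comp_rows),
        expression_labels=pd.DataFrame(label_rows),
        warnings=warnings_,
    )


def write_figures(config: RunConfig, outdir: str | Path) -> None:
    """Representative actogram and periodogram per condition (conveniences)."""
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for condition in config.conditions:
        schedule = _schedule_for(config, condition)
        params = SimActivityParams(
            **config.activity_blocks.get(condition, {}),
            seed=derive_seed(config.master_seed, "activity", f"{condition}_00"),
        )
        record, _ = simulate_activity(
            params, schedule, n_days=config.n_days,
            bin_minutes=config.sim_bin_minutes, animal_id=condition,
        )
        rec30 = bin_activity(record, 30.0)
        act = build_actogram(rec30, 24.0, double_plot=True)
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.2))
        ax1.imshow(act.matrix, aspect="auto", cmap="Greys", interpolation="nearest")
        ax1.set(title=f"{condition} actogram", xlabel="bin (double-plotted)",
                ylabel="cycle")
        pg = chi_square_periodogram(bin_activity(record, 6.0))
        ax2.plot(pg.periods_h, pg.statistic, lw=0.8, label="Qp")
        ax2.plot(pg.periods_h, pg.significance_line, "r--", lw=0.8, label="p=0.05")
        ax2.set(title=f"peak {pg.peak_period:.2f} h", xlabel="period (h)")
        ax2.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / f"{condition}.png", dpi=110)
        plt.close(fig)


def full_run(config: RunConfig, outdir: str | Path | None = None,
             figures: bool = False) -> ReportBundle:
    """Run the activity and imaging studies and optionally write the report."""
    act = run_activity_study(config)
    img = run_imaging_study(config)
    bundle = ReportBundle(
        activity_params=act.activity_params,
        activity_comparisons=act.activity_comparisons,
        imaging_fields=img.imaging_fields,
        imaging_comparisons=img.imaging_comparisons,
        expression_labels=img.expression_labels,
        warnings=act.warnings + img.warnings,
    )
    if outdir is not None:
        bundle.write(outdir)
        if figures:
            write_figures(config, Path(outdir) / "figures")
    return bundle
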