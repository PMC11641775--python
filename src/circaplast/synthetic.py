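"""Synthetic wheel-running records and two-channel puncta fields.

These generators plant fully known ground truth so the whole analysis chain
(periodograms, onset detection, phase parameters, puncta segmentation,
colocalization) can be validated without any recorded data.

Activity model
--------------
A nocturnal animal is active in a window of length ``alpha_true`` that
recurs every ``tau_true`` hours (or locks to lights-off under a driven
regime when ``masking`` is set).  Counts per bin are drawn around
``mean_rate_active`` inside the window and ``mean_rate_rest`` outside;
an optional mid-activity break (the "siesta") reverts a stretch of the
active window to the rest rate.  Setting ``arrhythmic`` flattens the rate
to the time-averaged value, which is what roughly half the animals kept
under constant light display.

Image model
-----------
Each punctum is an isotropic Gaussian spot; a planted fraction of the
postsynaptic-channel puncta share centers (within one pixel) with
presynaptic puncta and represent true synapses.  A smooth background
gradient and Poisson shot noise emulate tissue autofluorescence and
photon statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .records import HOURS_PER_DAY, ActivityRecord, LightSchedule, Regime

__all__ = [
    "SimActivityParams",
    "ActivityTruth",
    "SimImageParams",
    "ImageTruth",
    "PackingError",
    "simulate_activity",
    "simulate_puncta_field",
]


# ---------------------------------------------------------------------------
# locomotor activity
# ---------------------------------------------------------------------------

@dataclass
class SimActivityParams:
    """Ground-truth parameters for one simulated animal.

    ``tau_true`` and ``drift_per_cycle`` are redundant under the onset
    progression model (successive onsets are ``tau_true`` apart, so the
    daily onset shift against the 24-h clock is ``60*(tau_true-24)`` min).
    Supplying only ``drift_per_cycle`` derives ``tau_true``; supplying both
    requires them to agree.
    """

    tau_true: float | None = None
    alpha_true: float = 12.0
    onset_phase0: float = 12.0
    drift_per_cycle: float | None = None  # minutes; advance negative
    mean_rate_active: float = 15.0  # counts per simulated bin
    mean_rate_rest: float = 0.5
    break_spec: tuple[float, float] | None = None  # (offset into alpha, duration) h
    masking: bool = False
    arrhythmic: bool = False
    noise: str = "poisson"  # none | poisson | negbin
    negbin_dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_true is None:
            drift = 0.0 if self.drift_per_cycle is None else self.drift_per_cycle
            self.tau_true = HOURS_PER_DAY + drift / 60.0
        elif self.drift_per_cycle is not None:
            implied = HOURS_PER_DAY + self.drift_per_cycle / 60.0
            if abs(self.tau_true - implied) > 1e-9:
                raise ValueError(
                    "tau_true and drift_per_cycle disagree: "
                    f"{self.tau_true} vs implied {implied}"
                )
        if self.alpha_true >= self.tau_true:
            raise ValueError("alpha_true must be shorter than tau_true")
        if self.mean_rate_active < 0 or self.mean_rate_rest < 0:
            raise ValueError("rates must be non-negative")
        if not self.arrhythmic and self.mean_rate_active <= self.mean_rate_rest:
            raise ValueError("active rate must exceed rest rate")
        if self.noise not in ("none", "poisson", "negbin"):
            raise ValueError(f"unknown noise law: {self.noise!r}")
        if self.break_spec is not None:
            off, dur = self.break_spec
            if off < 0 or dur <= 0 or off + dur > self.alpha_true:
                raise ValueError("break must lie inside the activity phase")


@dataclass
class ActivityTruth:
    """Planted truth accompanying a simulated record."""

    onsets_h: list[float]
    offsets_h: list[float]
    tau_h: float
    alpha_h: float
    rho_h: float
    delta_8cycles_min: float
    break_durations_h: list[float]
    day_activity_share: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def _active_intervals(
    params: SimActivityParams, schedule: LightSchedule, total_h: float
) -> tuple[list[tuple[float, float]], list[float], list[float]]:
    """Active (onset, offset) windows minus breaks, over [0, total_h]."""
    if params.masking and schedule.is_light_driven:
        # activity locks to lights-off; record starts at lights-on
        step = schedule.cycle_length
        first = schedule.photoperiod
    else:
        step = params.tau_true
        first = params.onset_phase0
    onsets, offsets, intervals = [], [], []
    k = 0
    while True:
        on = first + k * step
        off = on + params.alpha_true
        if on >= total_h:
            break
        if off <= total_h:  # truth lists complete cycles only
            onsets.append(on)
            offsets.append(off)
        # rendering clips the trailing partial window instead of dropping it
        if params.break_spec is None:
            intervals.append((on, min(off, total_h)))
        else:
            boff, bdur = params.break_spec
            intervals.append((on, min(on + boff, total_h)))
            intervals.append((min(on + boff + bdur, total_h), min(off, total_h)))
        k += 1
    return intervals, onsets, offsets


def simulate_activity(
    params: SimActivityParams,
    schedule: LightSchedule,
    n_days: int = 10,
    bin_minutes: float = 1.0,
    animal_id: str = "sim",
    start_date: str = "2024-01-01",
) -> tuple[ActivityRecord, ActivityTruth]:
    """Simulate a binned wheel-running record with known truth.

    The record starts exactly at the schedule anchor (lights-on for driven
    regimes, the acclimation lights-on under constant conditions), the
    convention under which day/night splits and overall activity partition
    the same 24-h cycles.
    """
    if n_days < 9:
        raise ValueError("need at least 9 days (8 analyzable cycles after the first)")
    if abs(60.0 / bin_minutes - round(60.0 / bin_minutes)) > 1e-9:
        raise ValueError("bin_minutes must divide 60")
    rng = np.random.default_rng(params.seed)
    total_h = n_days * HOURS_PER_DAY
    n_bins = int(round(total_h * 60.0 / bin_minutes))
    bin_h = bin_minutes / 60.0
    t0 = np.arange(n_bins) * bin_h

    if params.arrhythmic:
        duty = params.alpha_true / params.tau_true
        lam = np.full(
            n_bins,
            params.mean_rate_rest
            + (params.mean_rate_active - params.mean_rate_rest) * duty,
        )
        intervals, onsets, offsets = [], [], []
    else:
        intervals, onsets, offsets = _active_intervals(params, schedule, total_h)
        frac = np.zeros(n_bins)
        for a, b in intervals:
            frac += np.clip(np.minimum(b, t0 + bin_h) - np.maximum(a, t0), 0.0, None)
        frac /= bin_h
        frac[frac < 1e-9] = 0.0  # drop float-boundary crumbs
        frac[frac > 1 - 1e-9] = 1.0
        lam = params.mean_rate_rest + (
            params.mean_rate_active - params.mean_rate_rest
        ) * np.clip(frac, 0.0, 1.0)

    if params.noise == "none":
        counts = lam.copy()
    elif params.noise == "poisson":
        counts = rng.poisson(lam).astype(float)
    else:  # negbin via gamma-poisson mixture
        shape = 1.0 / params.negbin_dispersion
        counts = rng.poisson(rng.gamma(shape, lam * params.negbin_dispersion)).astype(
            float
        )

    anchor = schedule.anchor_clock
    start = pd.Timestamp(start_date) + pd.Timedelta(hours=anchor)
    record = ActivityRecord(
        animal_id=animal_id,
        start_time=start,
        bin_minutes=bin_minutes,
        counts=counts,
        schedule=schedule,
    )

    if params.masking and schedule.is_light_driven:
        tau = schedule.cycle_length
    else:
        tau = params.tau_true
    step_shift_min = 0.0 if (params.masking and schedule.is_light_driven) else (
        (tau - HOURS_PER_DAY) * 60.0
    )
    day_mask = (t0 % HOURS_PER_DAY) < HOURS_PER_DAY / 2  # record starts at anchor
    lam_total = lam.sum()
    truth = ActivityTruth(
        onsets_h=[float(x) for x in onsets],
        offsets_h=[float(x) for x in offsets],
        tau_h=float(tau),
        alpha_h=float("nan") if params.arrhythmic else params.alpha_true,
        rho_h=float("nan") if params.arrhythmic else tau - params.alpha_true,
        delta_8cycles_min=float("nan") if params.arrhythmic else 8.0 * step_shift_min,
        break_durations_h=(
            [params.break_spec[1]] * len(onsets)
            if (params.break_spec is not None and not params.arrhythmic)
            else []
        ),
        day_activity_share=float(lam[day_mask].sum() / lam_total)
        if lam_total > 0
        else float("nan"),
    )
    return record, truth


# ---------------------------------------------------------------------------
# two-channel puncta fields
# ---------------------------------------------------------------------------

class PackingError(RuntimeError):
    """Raised when puncta cannot be packed at the requested separation."""


@dataclass
class SimImageParams:
    """Ground-truth parameters for one simulated two-channel field.

    Geometry defaults follow a confocal section of mouse cortex at high
    magnification: 0.1 µm pixels and a 0.46 µm optical-section step.
    """

    field_size: tuple[int, int] = (256, 256)  # (H, W) px
    pixel_size: float = 0.1  # µm / px
    optical_thickness: float = 0.46  # µm
    n_puncta_a: int = 100
    n_puncta_b: int = 100
    coloc_fraction: float = 0.6
    spot_sigma: float = 1.2  # px
    amplitude_range: tuple[float, float] = (80.0, 150.0)
    background: float = 10.0
    min_separation: float = 7.0  # px, between distinct planted centers
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if self.n_puncta_a < 0 or self.n_puncta_b < 0:
            raise ValueError("puncta counts must be non-negative")
        n_coloc = round(self.coloc_fraction * self.n_puncta_b)
        if n_coloc > self.n_puncta_a:
            raise ValueError("colocalized puncta cannot exceed channel-A count")


@dataclass
class ImageTruth:
    """Planted truth accompanying a simulated field."""

    centroids_a: list[tuple[float, float]]
    centroids_b: list[tuple[float, float]]
    coloc_pairs: list[tuple[int, int]]  # (index into A, index into B)
    area_fraction_a_pct: float
    area_fraction_b_pct: float
    synapse_count: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def _pack_centers(
    rng: np.random.Generator,
    n: int,
    existing: list[tuple[float, float]],
    shape: tuple[int, int],
    margin: float,
    min_sep: float,
    budget: int,
) -> list[tuple[float, float]]:
    """Rejection-sample n centers ≥ min_sep from each other and `existing`."""
    pts = list(existing)
    new: list[tuple[float, float]] = []
    tries = 0
    h, w = shape
    while len(new) < n:
        if tries >= budget:
            raise PackingError(
                f"could not place {n} puncta at separation {min_sep} px "
                f"in a {h}x{w} field after {budget} draws"
            )
        tries += 1
        r = rng.uniform(margin, h - 1 - margin)
        c = rng.uniform(margin, w - 1 - margin)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc in pts):
            pts.append((r, c))
            new.append((r, c))
    return new


def _render_spots(
    shape: tuple[int, int],
    centers: list[tuple[float, float]],
    amplitudes: np.ndarray,
    sigma: float,
) -> np.ndarray:
    img = np.zeros(shape)
    h, w = shape
    rad = int(np.ceil(4 * sigma))
    for (r, c), amp in zip(centers, amplitudes):
        r0, r1 = max(0, int(r) - rad), min(h, int(r) + rad + 1)
        c0, c1 = max(0, int(c) - rad), min(w, int(c) + rad + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += amp * np.exp(
            -((yy - r) ** 2 + (xx - c) ** 2) / (2.0 * sigma**2)
        )
    return img


def simulate_puncta_field(params: SimImageParams) -> tuple[np.ndarray, ImageTruth]:
    """Render a (2, H, W) two-channel field with planted colocalization.

    Channel 0 is the presynaptic marker (A), channel 1 the postsynaptic
    marker (B).  ``round(coloc_fraction * n_puncta_b)`` B puncta share
    centers (within 1 px) with A puncta; all other planted centers respect
    ``min_separation``, so at moderate thresholds only the planted pairs
    produce mask overlap.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.field_size
    n_coloc = round(params.coloc_fraction * params.n_puncta_b)
    margin = max(3.0 * params.spot_sigma, 2.0)
    budget = 100 * max(1, params.n_puncta_a + params.n_puncta_b)

    shared = _pack_centers(rng, n_coloc, [], (h, w), margin, params.min_separation, budget)
    a_only = _pack_centers(
        rng, params.n_puncta_a - n_coloc, shared, (h, w), margin,
        params.min_separation, budget,
    )
    b_only = _pack_centers(
        rng, params.n_puncta_b - n_coloc, shared + a_only, (h, w), margin,
        params.min_separation, budget,
    )

    centers_a = shared + a_only
    # B twin sits within 1 px of its A partner
    jitter_ang = rng.uniform(0, 2 * np.pi, n_coloc)
    jitter_rad = rng.uniform(0, 0.5, n_coloc)
    shared_b = [
        (r + jr * np.sin(ja), c + jr * np.cos(ja))
        for (r, c), jr, ja in zip(shared, jitter_rad, jitter_ang)
    ]
    centers_b = shared_b + b_only
    pairs = [(i, i) for i in range(n_coloc)]

    amp_a = rng.uniform(*params.amplitude_range, len(centers_a))
    amp_b = rng.uniform(*params.amplitude_range, len(centers_b))
    spots_a = _render_spots((h, w), centers_a, amp_a, params.spot_sigma)
    spots_b = _render_spots((h, w), centers_b, amp_b, params.spot_sigma)

    yy, xx = np.mgrid[0:h, 0:w]
    bg = params.background * (0.5 + 0.5 * (yy / max(h - 1, 1) + xx / max(w - 1, 1)) / 2)

    # truth area fraction at the rendering threshold: half the weakest amplitude
    thr = 0.5 * params.amplitude_range[0]
    af_a = 100.0 * np.mean(spots_a > thr)
    af_b = 100.0 * np.mean(spots_b > thr)

    img = np.stack([spots_a + bg, spots_b + bg])
    if params.shot_noise:
        img = rng.poisson(img).astype(float)

    truth = ImageTruth(
        centroids_a=[(float(r), float(c)) for r, c in centers_a],
        centroids_b=[(float(r), float(c)) for r, c in centers_b],
        coloc_pairs=pairs,
        area_fraction_a_pct=float(af_a),
        area_fraction_b_pct=float(af_b),
        synapse_count=n_coloc,
    )
    return img, truth
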