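"""Locomotor rhythm analysis: periodograms, tau, Qp, onsets and phase splits.

Implements the classical chi-square periodogram (Sokolove–Bushell form,
``Qp(P) = N * s_h^2 / s^2`` over the column means of the series folded at
each tested period ``P``), a mean-subtracted Fourier periodogram, a 0–100
rhythm-robustness index (%Qp), threshold-based activity onset/offset
detection, and the derived phase parameters:

=========  ==========================================================
tau        period of the daily/circadian rhythm (periodogram peak)
alpha      activity-phase duration, onset to offset
rho        rest-phase duration, ``tau - alpha``
delta      cumulative onset shift against the 24-h clock over 8 cycles
           (advances negative, delays positive)
=========  ==========================================================

plus overall / day-night / activity-rest activity totals and mid-activity
break ("siesta") detection.  All times are hours from record start;
windows are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .records import HOURS_PER_DAY, ActivityRecord

__all__ = [
    "Actogram",
    "Periodogram",
    "OnsetSeries",
    "PhaseParams",
    "ActivityRestSplit",
    "BreakResult",
    "RhythmParams",
    "AnalysisConfig",
    "bin_activity",
    "build_actogram",
    "chi_square_periodogram",
    "fourier_periodogram",
    "estimate_tau",
    "percent_qp",
    "classify_rhythmicity",
    "detect_onsets",
    "derive_phase_params",
    "overall_activity",
    "split_day_night",
    "activity_rest_split",
    "detect_breaks",
    "analyze_record",
]


# ---------------------------------------------------------------------------
# binning and actograms
# ---------------------------------------------------------------------------

def bin_activity(record: ActivityRecord, target_bin_minutes: float) -> ActivityRecord:
    """Re-bin counts to a coarser bin width; totals are conserved.

    The target width must be an integer multiple of the source width;
    trailing bins that do not fill a complete target bin are dropped.
    """
    ratio = target_bin_minutes / record.bin_minutes
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError("target bin must be an integer multiple of the source bin")
    k = int(round(ratio))
    if k == 1:
        return replace(record, counts=record.counts.copy())
    n = (record.n_bins // k) * k
    summed = record.counts[:n].reshape(-1, k).sum(axis=1)
    return replace(record, bin_minutes=float(target_bin_minutes), counts=summed)


@dataclass
class Actogram:
    """Raster of activity, one row per plotted cycle."""

    matrix: np.ndarray  # (n_rows, row_bins) or (n_rows, 2*row_bins) if double
    row_period_h: float
    bin_minutes: float
    double_plot: bool


def build_actogram(
    record: ActivityRecord, row_period_hours: float = 24.0, double_plot: bool = True
) -> Actogram:
    """Fold the record into actogram rows; a double plot concatenates each
    cycle with the following one so onset drift reads as a slope."""
    bin_h = record.bin_minutes / 60.0
    per_row = int(round(row_period_hours / bin_h))
    n_rows = record.n_bins // per_row
    if n_rows < 2:
        raise ValueError("record must span at least two row periods")
    m = record.counts[: n_rows * per_row].reshape(n_rows, per_row)
    if double_plot:
        m = np.hstack([m[:-1], m[1:]])
    return Actogram(
        matrix=m,
        row_period_h=row_period_hours,
        bin_minutes=record.bin_minutes,
        double_plot=double_plot,
    )


# ---------------------------------------------------------------------------
# periodograms
# ---------------------------------------------------------------------------

@dataclass
class Periodogram:
    """Periodogram over a grid of tested periods.

    For the chi-square method the statistic is Qp and ``significance_line``
    is the per-period 0.95 chi-square quantile at ``P - 1`` degrees of
    freedom (``P`` in bins).  For the Fourier method the statistic is the
    normalized in-window power and the line is the 0.95 quantile of a
    single normalized white-noise component (``-ln(0.05)/m`` for ``m``
    in-window components).
    """

    method: str  # "chi_square" | "fourier"
    periods_h: np.ndarray
    statistic: np.ndarray
    significance_line: np.ndarray
    n_bins_used: np.ndarray
    periods_bins: np.ndarray | None  # chi-square only: P in bins
    peak_period: float
    peak_statistic: float


def _peak_index(periods_h: np.ndarray, statistic: np.ndarray) -> int:
    """Index of the maximal statistic; exact ties resolved toward 24 h."""
    mx = statistic.max()
    tied = np.flatnonzero(statistic >= mx * (1 - 1e-12) - 1e-300)
    tied = tied[np.isclose(statistic[tied], mx, rtol=1e-12, atol=0.0)]
    if len(tied) == 0:
        tied = np.array([int(np.argmax(statistic))])
    return int(tied[np.argmin(np.abs(periods_h[tied] - HOURS_PER_DAY))])


def chi_square_periodogram(
    record: ActivityRecord,
    period_min_h: float = 20.0,
    period_max_h: float = 28.0,
) -> Periodogram:
    """Chi-square periodogram on a one-bin-resolution grid of periods.

    At each integer bin period ``P`` only the first ``floor(N_total/P)*P``
    bins (complete cycles) enter; ``Qp = N * s_h^2 / s^2`` where ``s_h^2``
    is the mean squared deviation of the ``P`` circular-phase column means
    from the grand mean and ``s^2`` that of all ``N`` used bins.  A
    constant series has zero variance in both; 0/0 is defined as 0.
    """
    x = record.counts
    bin_h = record.bin_minutes / 60.0
    if record.duration_h < 2 * period_max_h:
        raise ValueError("record must span at least two cycles at period_max")
    p_lo = int(np.ceil(period_min_h / bin_h - 1e-9))
    p_hi = int(np.floor(period_max_h / bin_h + 1e-9))
    if p_hi < p_lo:
        raise ValueError("empty period grid; widen the window or re-bin")
    pbins = np.arange(p_lo, p_hi + 1)
    qp = np.empty(len(pbins))
    nused = np.empty(len(pbins), dtype=int)
    for i, p in enumerate(pbins):
        k = x.size // p
        n = k * p
        block = x[:n].reshape(k, p)
        col = block.mean(axis=0)
        gm = block.mean()
        s2 = np.mean((block - gm) ** 2)
        sh2 = np.mean((col - gm) ** 2)
        qp[i] = 0.0 if s2 == 0.0 else n * sh2 / s2
        nused[i] = n
    periods_h = pbins * bin_h
    line = sps.chi2.ppf(0.95, pbins - 1)
    j = _peak_index(periods_h, qp)
    return Periodogram(
        method="chi_square",
        periods_h=periods_h,
        statistic=qp,
        significance_line=line,
        n_bins_used=nused,
        periods_bins=pbins,
        peak_period=float(periods_h[j]),
        peak_statistic=float(qp[j]),
    )


def fourier_periodogram(
    record: ActivityRecord,
    period_min_h: float = 20.0,
    period_max_h: float = 28.0,
) -> Periodogram:
    """Mean-subtracted power spectrum restricted to the period window,
    normalized so the in-window power sums to 1.

    Note the FFT grid is coarse near 24 h for short records (period spacing
    ~P^2/T), so this estimator is kept for cross-checks while the
    chi-square grid carries the fine tau estimate.
    """
    x = record.counts.astype(float)
    bin_h = record.bin_minutes / 60.0
    if record.duration_h < 2 * period_max_h:
        raise ValueError("record must span at least two cycles at period_max")
    power = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freq = np.fft.rfftfreq(x.size, d=bin_h)  # cycles / hour
    with np.errstate(divide="ignore"):
        periods = np.where(freq > 0, 1.0 / np.maximum(freq, 1e-300), np.inf)
    sel = (periods >= period_min_h) & (periods <= period_max_h)
    if not np.any(sel):
        raise ValueError("no Fourier component falls inside the period window")
    periods_h = periods[sel][::-1]  # ascending period
    pw = power[sel][::-1]
    tot = pw.sum()
    pw = pw / tot if tot > 0 else pw
    m = pw.size
    line = np.full(m, -np.log(0.05) / m)
    j = _peak_index(periods_h, pw)
    return Periodogram(
        method="fourier",
        periods_h=periods_h,
        statistic=pw,
        significance_line=line,
        n_bins_used=np.full(m, x.size),
        periods_bins=None,
        peak_period=float(periods_h[j]),
        peak_statistic=float(pw[j]),
    )


def estimate_tau(periodogram: Periodogram) -> float:
    """Period at the periodogram peak; ties go to the period nearest 24 h."""
    return periodogram.peak_period


def percent_qp(periodogram: Periodogram) -> float:
    """Rescale peak Qp to a 0-100 robustness index.

    %Qp = 100 * (Qp_peak - c) / (N - c), clipped to [0, 100], where ``c``
    is the 0.95 significance line at the peak period and ``N`` the number
    of bins used there (the maximum attainable Qp).
    """
    if periodogram.method != "chi_square":
        raise ValueError("%Qp is defined for the chi-square periodogram only")
    j = int(np.argmin(np.abs(periodogram.periods_h - periodogram.peak_period)))
    c = periodogram.significance_line[j]
    n = periodogram.n_bins_used[j]
    val = 100.0 * (periodogram.peak_statistic - c) / (n - c)
    return float(np.clip(val, 0.0, 100.0))


def classify_rhythmicity(
    periodogram: Periodogram, significance_level: float = 0.05
) -> bool:
    """Flag the record rhythmic if Qp clears its significance line.

    The line is Bonferroni-adjusted across the tested period grid so that
    the family-wise false-positive rate over the whole 20-28 h scan is the
    nominal level (a raw per-period 0.95 line would flag essentially every
    noise record somewhere on an 80-period grid).
    """
    if periodogram.method != "chi_square":
        raise ValueError("rhythmicity is classified on the chi-square periodogram")
    m = periodogram.periods_h.size
    df = periodogram.periods_bins - 1
    adj_line = sps.chi2.ppf(1.0 - significance_level / m, df)
    return bool(np.any(periodogram.statistic > adj_line))


# ---------------------------------------------------------------------------
# onsets, offsets, phase parameters
# ---------------------------------------------------------------------------

@dataclass
class OnsetSeries:
    """Per-cycle activity onset/offset times (hours from record start).

    Cycles where no qualifying run was found carry NaN.
    """

    onsets_h: np.ndarray
    offsets_h: np.ndarray
    tau_h: float
    cycles_used: int  # cycles with both onset and offset


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal True runs, stop exclusive."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def detect_onsets(
    record: ActivityRecord,
    tau: float,
    active_threshold_frac: float = 0.25,
    min_active_bins: int = 3,
    min_quiescent_bins: int = 6,
) -> OnsetSeries:
    """Detect per-cycle activity onsets and offsets.

    The threshold is ``active_threshold_frac`` times the record mean.
    Sustained activity is first located on a 1-h moving average (which a
    noisy rest baseline cannot cross for ``min_active_bins`` in a row), as
    runs preceded by at least ``min_quiescent_bins`` sub-threshold smoothed
    bins; each block edge is then refined on the raw bins — the onset is
    the start of the first raw run of ``min_active_bins`` above-threshold
    bins near the smoothed edge, the offset the symmetric end.  Cycles are
    windows of length ``tau`` tiled from the first onset; each takes the
    candidate onset nearest its predicted time (within tau/4) and the last
    candidate offset before the next onset.  More than 25% missing cycles
    is treated as failure.
    """
    x = record.counts
    bin_h = record.bin_minutes / 60.0
    thr = active_threshold_frac * x.mean()
    above = x > thr
    q = min_quiescent_bins
    w = max(1, int(round(1.0 / bin_h)))  # 1-h refinement window
    kernel = np.ones(w) / w
    sm = np.convolve(x, kernel, mode="same")
    sm_above = sm > thr

    def _refine_start(s: int) -> int | None:
        lo, hi = max(0, s - w), min(x.size, s + w)
        for i in range(lo, hi):
            j = min(i + min_active_bins, x.size)
            if j - i >= min_active_bins and above[i:j].all():
                return i
        return None

    def _refine_end(e: int) -> int | None:
        lo, hi = max(min_active_bins, e - w), min(x.size, e + w)
        for j in range(hi, lo - 1, -1):
            if above[j - min_active_bins : j].all():
                return j
        return None

    onset_cand: list[int] = []
    offset_cand: list[int] = []
    for a, b in _runs(sm_above):
        if b - a < min_active_bins:
            continue
        if a >= q and not sm_above[a - q : a].any():
            i = _refine_start(a)
            if i is not None:
                onset_cand.append(i)
        if b + q <= x.size and not sm_above[b : b + q].any():
            j = _refine_end(b)
            if j is not None:
                offset_cand.append(j)
    if not onset_cand:
        raise ValueError("no qualifying activity onset found")
    onset_t = np.array(sorted(set(onset_cand))) * bin_h
    offset_t = np.array(sorted(set(offset_cand))) * bin_h

    t_first = onset_t[0]
    # one window per predicted onset inside the record; the last cycle may
    # lack its offset but its onset still contributes to delta
    n_cycles = int((record.duration_h - t_first) / tau + 1e-9) + 1
    if t_first + (n_cycles - 1) * tau >= record.duration_h:
        n_cycles -= 1
    if n_cycles < 1:
        raise ValueError("record too short past the first onset")
    onsets = np.full(n_cycles, np.nan)
    offsets = np.full(n_cycles, np.nan)
    for k in range(n_cycles):
        pred = t_first + k * tau
        d = np.abs(onset_t - pred)
        j = int(np.argmin(d))
        if d[j] <= tau / 4:
            onsets[k] = onset_t[j]
    for k in range(n_cycles):
        if np.isnan(onsets[k]):
            continue
        hi = onsets[k] + 0.95 * tau
        if k + 1 < n_cycles and not np.isnan(onsets[k + 1]):
            hi = min(hi, onsets[k + 1])
        ok = offset_t[(offset_t > onsets[k]) & (offset_t <= hi)]
        if ok.size:
            offsets[k] = ok[-1]
    used = int(np.sum(~np.isnan(onsets) & ~np.isnan(offsets)))
    if used < 0.75 * n_cycles:
        raise ValueError(
            f"only {used}/{n_cycles} cycles had detectable onset and offset"
        )
    return OnsetSeries(onsets_h=onsets, offsets_h=offsets, tau_h=tau, cycles_used=used)


@dataclass
class PhaseParams:
    alpha_h: float
    delta_h: float  # signed; advance negative
    rho_h: float
    mean_shift_min: float


def derive_phase_params(
    onsets: OnsetSeries, tau: float, n_cycles: int = 8
) -> PhaseParams:
    """Alpha, delta, rho from a detected onset series.

    Delta is the sum of the ``n_cycles`` successive onset-to-onset shifts
    measured against the 24-h clock (telescoping to ``onset[n] - onset[0]
    - n*24``), matching the drift read off a double-plotted actogram.
    Alpha averages offset-minus-onset over the first ``n_cycles`` complete
    cycles; rho is ``tau - alpha``.
    """
    on, off = onsets.onsets_h, onsets.offsets_h
    if on.size < n_cycles + 1 or np.isnan(on[0]) or np.isnan(on[n_cycles]):
        raise ValueError(
            f"delta needs {n_cycles + 1} consecutive detected onsets"
        )
    delta = on[n_cycles] - on[0] - n_cycles * HOURS_PER_DAY
    durs = (off - on)[:n_cycles]
    durs = durs[~np.isnan(durs)]
    if durs.size < n_cycles * 0.75:
        raise ValueError("too few complete cycles for alpha")
    alpha = float(durs.mean())
    return PhaseParams(
        alpha_h=alpha,
        delta_h=float(delta),
        rho_h=tau - alpha,
        mean_shift_min=float(delta / n_cycles * 60.0),
    )


# ---------------------------------------------------------------------------
# activity totals
# ---------------------------------------------------------------------------

def overall_activity(record: ActivityRecord, tau: float) -> float:
    """Mean wheel revolutions per complete cycle of length tau."""
    bin_h = record.bin_minutes / 60.0
    n_cyc = int(record.duration_h / tau + 1e-9)
    if n_cyc < 1:
        raise ValueError("record shorter than one cycle")
    n_bins = int(round(n_cyc * tau / bin_h))
    return float(record.counts[:n_bins].sum() / n_cyc)


def split_day_night(record: ActivityRecord) -> tuple[float, float, float]:
    """Per-cycle (subjective) day and night activity and percent day.

    The day window is the 12 h starting at the schedule anchor — lights-on
    under a driven regime (ZT0-ZT12; also for LD 16:8), the acclimation
    lights-on under constant conditions (CT0-CT12).  Complete 24-h cycles
    from the first anchor occurrence are averaged.
    """
    if record.schedule is None:
        raise ValueError("a light schedule with an anchor is required")
    bin_h = record.bin_minutes / 60.0
    offset_h = (record.schedule.anchor_clock - record.start_clock_h) % HOURS_PER_DAY
    b0 = int(round(offset_h / bin_h))
    per_cycle = int(round(HOURS_PER_DAY / bin_h))
    n_cyc = (record.n_bins - b0) // per_cycle
    if n_cyc < 1:
        raise ValueError("record spans no complete anchored cycle")
    block = record.counts[b0 : b0 + n_cyc * per_cycle].reshape(n_cyc, per_cycle)
    half = per_cycle // 2
    day = float(block[:, :half].sum() / n_cyc)
    night = float(block[:, half:].sum() / n_cyc)
    total = day + night
    pct = 100.0 * day / total if total > 0 else float("nan")
    return day, night, pct


@dataclass
class ActivityRestSplit:
    activity_phase_total: float
    rest_phase_total: float
    window_start_h: float  # phase of the activity half-cycle, hours into tau
    warned_arrhythmic: bool = False


def activity_rest_split(
    record: ActivityRecord, tau: float, rhythmic: bool = True
) -> ActivityRestSplit:
    """Split each cycle into the tau/2 window of highest activity and the rest.

    The mean waveform folded at tau is scanned circularly; the half-cycle
    window with the maximal sum starts the activity phase (ties break at
    phase 0).  Totals are per-cycle means inside and outside that window.
    For arrhythmic records the anchor is arbitrary and flagged.
    """
    bin_h = record.bin_minutes / 60.0
    per = int(round(tau / bin_h))
    n_cyc = record.n_bins // per
    if n_cyc < 1:
        raise ValueError("record shorter than one cycle at tau")
    wave = record.counts[: n_cyc * per].reshape(n_cyc, per).mean(axis=0)
    half = per // 2
    csum = np.concatenate([[0.0], np.cumsum(np.concatenate([wave, wave]))])
    window = csum[half : half + per] - csum[:per]  # sum starting at each phase
    best = int(np.argmax(window))
    act = float(window[best])
    return ActivityRestSplit(
        activity_phase_total=act,
        rest_phase_total=float(wave.sum() - act),
        window_start_h=best * bin_h,
        warned_arrhythmic=not rhythmic,
    )


# ---------------------------------------------------------------------------
# breaks ("siestas") inside the activity phase
# ---------------------------------------------------------------------------

@dataclass
class BreakResult:
    durations_h: list[list[float]]  # per analyzed cycle
    mean_duration_h: float  # NaN when no breaks at all


def detect_breaks(
    record: ActivityRecord,
    onsets: OnsetSeries,
    gap_threshold_frac: float = 0.25,
    min_gap_minutes: float = 30.0,
) -> BreakResult:
    """Sub-threshold runs of at least ``min_gap_minutes`` between onset and
    offset of each cycle; the threshold is a fraction of that cycle's
    activity-phase mean."""
    bin_h = record.bin_minutes / 60.0
    per_cycle: list[list[float]] = []
    all_durs: list[float] = []
    for on, off in zip(onsets.onsets_h, onsets.offsets_h):
        if np.isnan(on) or np.isnan(off):
            per_cycle.append([])
            continue
        a, b = int(round(on / bin_h)), int(round(off / bin_h))
        span = record.counts[a:b]
        if span.size == 0:
            per_cycle.append([])
            continue
        thr = gap_threshold_frac * span.mean()
        durs = [
            (stop - start) * record.bin_minutes / 60.0
            for start, stop in _runs(span < thr)
            if (stop - start) * record.bin_minutes >= min_gap_minutes
        ]
        per_cycle.append(durs)
        all_durs.extend(durs)
    mean = float(np.mean(all_durs)) if all_durs else float("nan")
    return BreakResult(durations_h=per_cycle, mean_duration_h=mean)


# ---------------------------------------------------------------------------
# one-call analysis
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Tunable analysis settings (defaults follow common actogram practice)."""

    bin_minutes: float = 6.0
    period_min_h: float = 20.0
    period_max_h: float = 28.0
    significance_level: float = 0.05
    onset_threshold_frac: float = 0.25
    min_active_bins: int = 3
    min_quiescent_bins: int = 6
    gap_threshold_frac: float = 0.25
    min_gap_minutes: float = 30.0
    delta_cycles: int = 8


@dataclass
class RhythmParams:
    """All per-animal locomotor parameters (one CSV row)."""

    animal_id: str
    tau_h: float
    delta_h: float
    alpha_h: float
    rho_h: float
    mean_shift_min: float
    overall_activity: float
    qp: float
    percent_qp: float
    rhythmic: bool
    day_activity: float
    night_activity: float
    percent_day: float
    activity_phase_total: float
    rest_phase_total: float
    break_mean_h: float


def analyze_record(
    record: ActivityRecord, config: AnalysisConfig | None = None
) -> RhythmParams:
    """Compute the full locomotor parameter set for one animal.

    Arrhythmic records (periodogram peak below the grid-wise significance
    line) keep tau, Qp and the activity totals but report alpha, delta, rho
    and breaks as NaN, since onset-based parameters are undefined without a
    rhythm.
    """
    cfg = config or AnalysisConfig()
    rec = bin_activity(record, cfg.bin_minutes)
    pg = chi_square_periodogram(rec, cfg.period_min_h, cfg.period_max_h)
    tau = estimate_tau(pg)
    pqp = percent_qp(pg)
    rhythmic = classify_rhythmicity(pg, cfg.significance_level)
    overall = overall_activity(rec, tau)
    day, night, pct_day = split_day_night(rec)
    ars = activity_rest_split(rec, tau, rhythmic=rhythmic)

    alpha = delta = rho = shift = brk = float("nan")
    if rhythmic:
        try:
            onsets = detect_onsets(
                rec,
                tau,
                cfg.onset_threshold_frac,
                cfg.min_active_bins,
                cfg.min_quiescent_bins,
            )
            phase = derive_phase_params(onsets, tau, cfg.delta_cycles)
            alpha, delta, rho, shift = (
                phase.alpha_h,
                phase.delta_h,
                phase.rho_h,
                phase.mean_shift_min,
            )
            brk = detect_breaks(
                rec, onsets, cfg.gap_threshold_frac, cfg.min_gap_minutes
            ).mean_duration_h
        except ValueError:
            # weakly rhythmic record: onset-based parameters stay NaN
            pass
    return RhythmParams(
        animal_id=record.animal_id,
        tau_h=tau,
        delta_h=delta,
        alpha_h=alpha,
        rho_h=rho,
        mean_shift_min=shift,
        overall_activity=overall,
        qp=pg.peak_statistic,
        percent_qp=pqp,
        rhythmic=rhythmic,
        day_activity=day,
        night_activity=night,
        percent_day=pct_day,
        activity_phase_total=ars.activity_phase_total,
        rest_phase_total=ars.rest_phase_total,
        break_mean_h=brk,
    )
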