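"""Core data containers for locomotor-activity analysis.

A recording is a regular, gap-free series of wheel-revolution counts per
time bin, annotated with the lighting regime the animal lived under.  Time
inside the package is expressed in hours from the start of the record;
Zeitgeber/circadian time (ZT/CT) is derived from the schedule's lights-on
anchor (for constant regimes, the anchor inherited from the light-dark
acclimation phase).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

HOURS_PER_DAY = 24.0


class Regime(str, enum.Enum):
    """Lighting regime of the recording room."""

    LD12_12 = "LD12_12"
    LD16_8 = "LD16_8"
    DD = "DD"
    LL = "LL"


#: Hours of light per 24-h cycle for each regime.
PHOTOPERIOD_H = {
    Regime.LD12_12: 12.0,
    Regime.LD16_8: 16.0,
    Regime.DD: 0.0,
    Regime.LL: 24.0,
}


@dataclass(frozen=True)
class LightSchedule:
    """Lighting regime plus the clock anchors needed for ZT/CT conversion.

    Parameters
    ----------
    regime : Regime
        One of LD 12:12, LD 16:8, DD (constant darkness), LL (constant
        light).
    lights_on_clock : float or None
        Hours-of-day at which lights turn on under a driven regime; ``None``
        under constant conditions.
    acclimation_lights_on : float
        Lights-on clock hour of the preceding LD 12:12 habituation phase.
        Every animal is habituated under LD 12:12 first, so this anchor is
        always present; it defines CT0 under DD/LL.
    cycle_length : float
        Length of the imposed cycle in hours (24 for all regimes used here).
    photoperiod : float
        Hours of light per cycle (12, 16, 0, 24).
    """

    regime: Regime
    lights_on_clock: float | None
    acclimation_lights_on: float
    cycle_length: float = HOURS_PER_DAY
    photoperiod: float = field(default=12.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.photoperiod <= self.cycle_length:
            raise ValueError("photoperiod must lie in [0, cycle_length]")
        if self.regime is Regime.DD and self.photoperiod != 0.0:
            raise ValueError("DD requires photoperiod 0")
        if self.regime is Regime.LL and self.photoperiod != self.cycle_length:
            raise ValueError("LL requires photoperiod == cycle_length")
        if self.acclimation_lights_on is None:
            raise ValueError("acclimation anchor is required")

    @property
    def is_light_driven(self) -> bool:
        return self.regime in (Regime.LD12_12, Regime.LD16_8)

    @property
    def lights_off_clock(self) -> float | None:
        if not self.is_light_driven:
            return None
        return (self.lights_on_clock + self.photoperiod) % HOURS_PER_DAY

    @property
    def anchor_clock(self) -> float:
        """Clock hour defining ZT0 (driven) or CT0 (constant conditions)."""
        if self.is_light_driven:
            return self.lights_on_clock
        return self.acclimation_lights_on

    def to_dict(self) -> dict:
        return {
            "regime": self.regime.value,
            "lights_on_clock": self.lights_on_clock,
            "acclimation_lights_on": self.acclimation_lights_on,
            "cycle_length": self.cycle_length,
            "photoperiod": self.photoperiod,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LightSchedule":
        d = dict(d)
        d["regime"] = Regime(d["regime"])
        return cls(**d)


def make_light_schedule(
    regime: Regime | str,
    lights_on_clock: float | None = 8.0,
    acclimation_lights_on: float | None = None,
) -> LightSchedule:
    """Build a :class:`LightSchedule` with the photoperiod implied by the regime.

    Under constant conditions (DD/LL) ``lights_on_clock`` is ignored and the
    acclimation anchor (defaulting to ``lights_on_clock``) carries the CT0
    reference.
    """
    try:
        regime = Regime(regime)
    except ValueError as exc:
        raise ValueError(f"unknown lighting regime: {regime!r}") from exc
    photoperiod = PHOTOPERIOD_H[regime]
    anchor = acclimation_lights_on
    if anchor is None:
        if lights_on_clock is None:
            raise ValueError("an acclimation lights-on anchor is required")
        anchor = lights_on_clock
    on = lights_on_clock if regime in (Regime.LD12_12, Regime.LD16_8) else None
    if regime in (Regime.LD12_12, Regime.LD16_8) and on is None:
        raise ValueError("light-driven regimes need lights_on_clock")
    return LightSchedule(
        regime=regime,
        lights_on_clock=on,
        acclimation_lights_on=float(anchor),
        photoperiod=photoperiod,
    )


@dataclass
class ActivityRecord:
    """A gap-free binned wheel-running record for one animal."""

    animal_id: str
    start_time: pd.Timestamp
    bin_minutes: float
    counts: np.ndarray
    schedule: LightSchedule

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if np.any(self.counts < 0) or np.any(~np.isfinite(self.counts)):
            raise ValueError("counts must be finite and non-negative")
        if self.bin_minutes <= 0:
            raise ValueError("bin_minutes must be positive")
        self.start_time = pd.Timestamp(self.start_time)

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def duration_h(self) -> float:
        return self.n_bins * self.bin_minutes / 60.0

    @property
    def start_clock_h(self) -> float:
        t = self.start_time
        return t.hour + t.minute / 60.0 + t.second / 3600.0

    def times_h(self) -> np.ndarray:
        """Bin start times in hours from record start."""
        return np.arange(self.n_bins) * self.bin_minutes / 60.0

    def slice_hours(self, start_h: float, end_h: float | None = None) -> "ActivityRecord":
        """Sub-record covering [start_h, end_h) hours from record start."""
        b0 = int(round(start_h * 60.0 / self.bin_minutes))
        b1 = self.n_bins if end_h is None else int(round(end_h * 60.0 / self.bin_minutes))
        if not 0 <= b0 < b1 <= self.n_bins:
            raise ValueError("slice outside the record")
        return replace(
            self,
            start_time=self.start_time + pd.Timedelta(minutes=b0 * self.bin_minutes),
            counts=self.counts[b0:b1].copy(),
        )

    # -- file I/O ---------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write as two-column CSV (ISO timestamp of bin start, counts)."""
        idx = self.start_time + pd.to_timedelta(
            np.arange(self.n_bins) * self.bin_minutes, unit="m"
        )
        pd.DataFrame({"timestamp": idx, "counts": self.counts}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        schedule: LightSchedule,
        animal_id: str | None = None,
    ) -> "ActivityRecord":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        ts = df["timestamp"]
        steps = ts.diff().dropna().dt.total_seconds().to_numpy() / 60.0
        if len(steps) == 0:
            raise ValueError("record must contain more than one bin")
        bin_minutes = steps[0]
        if not np.allclose(steps, bin_minutes):
            raise ValueError("record has gaps or irregular bins; zero-fill first")
        return cls(
            animal_id=animal_id or Path(path).stem,
            start_time=ts.iloc[0],
            bin_minutes=float(bin_minutes),
            counts=df["counts"].to_numpy(float),
            schedule=schedule,
        )

    def to_awd(self, path: str | Path) -> None:
        """Write the single-column per-epoch text dialect.

        Header line: ``# start=<ISO timestamp> epoch_min=<minutes>``; one
        count per subsequent line.
        """
        with open(path, "w") as fh:
            fh.write(
                f"# start={self.start_time.isoformat()} epoch_min={self.bin_minutes:g}\n"
            )
            for c in self.counts:
                fh.write(f"{c:g}\n")

    @classmethod
    def from_awd(
        cls,
        path: str | Path,
        schedule: LightSchedule,
        animal_id: str | None = None,
    ) -> "ActivityRecord":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("# start="):
                raise ValueError("missing per-epoch header line")
            fields = dict(
                tok.split("=", 1) for tok in header.lstrip("# ").split() if "=" in tok
            )
            counts = np.array([float(line) for line in fh if line.strip()])
        return cls(
            animal_id=animal_id or Path(path).stem,
            start_time=pd.Timestamp(fields["start"]),
            bin_minutes=float(fields["epoch_min"]),
            counts=counts,
            schedule=schedule,
        )


def schedule_to_yaml(schedule: LightSchedule, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schedule.to_dict(), fh, sort_keys=False)


def schedule_from_yaml(path: str | Path) -> LightSchedule:
    with open(path) as fh:
        return LightSchedule.from_dict(yaml.safe_load(fh))
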