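"""Processivity classification and gliding velocimetry.

A single-molecule event counts as processive when it lasts strictly longer
than 0.625 s and covers strictly more than 500 nm of unidirectional
displacement. "Unidirectional" is operationalized as: the excursion against
the net direction of travel never exceeds a tolerance (two camera pixels,
0.32 um, by default) -- the scoring criterion a kymograph reader applies by
eye, made numeric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kinetics import sem

logger = logging.getLogger(__name__)


@dataclass
class Track:
    """Time-ordered positions of one molecule (or one microtubule edge).

    ``samples`` is an ordered list of (time_s, position_um) pairs; position
    is the 1D coordinate along the microtubule axis.
    """

    track_id: str
    mt_id: str
    samples: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise ValueError(f"track {self.track_id}: needs >= 2 samples")
        times = [t for t, _ in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"track {self.track_id}: times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.samples])

    @property
    def positions(self) -> np.ndarray:
        return np.array([x for _, x in self.samples])

    @property
    def duration_s(self) -> float:
        return self.samples[-1][0] - self.samples[0][0]

    @property
    def net_displacement_um(self) -> float:
        return self.samples[-1][1] - self.samples[0][1]


@dataclass(frozen=True)
class ProcessivityParams:
    """Thresholds for scoring a processive event (strict inequalities)."""

    min_duration_s: float = 0.625
    min_displacement_nm: float = 500.0
    reversal_tolerance_um: float = 0.32  # 2 pixels at 0.16 um/px

    def __post_init__(self) -> None:
        for name in ("min_duration_s", "min_displacement_nm", "reversal_tolerance_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


def max_reversal_um(positions: np.ndarray, direction: float) -> float:
    """Largest excursion against the net direction of travel.

    For forward travel this is the largest drop below the running maximum;
    for backward travel, the largest rise above the running minimum.
    """
    if direction >= 0:
        return float(np.max(np.maximum.accumulate(positions) - positions))
    return float(np.max(positions - np.minimum.accumulate(positions)))


def classify_processive(
    track: Track, params: ProcessivityParams | None = None
) -> tuple[str, dict]:
    """Label a track processive or non-processive.

    Processive iff duration > min_duration_s AND |net displacement| >
    min_displacement_nm AND the counter-directional excursion never exceeds
    reversal_tolerance_um. Returns (label, metrics dict).
    """
    p = params or ProcessivityParams()
    pos = track.positions
    net_um = track.net_displacement_um
    reversal = max_reversal_um(pos, np.sign(net_um) if net_um != 0 else 1.0)
    metrics = {
        "duration_s": track.duration_s,
        "net_displacement_nm": net_um * 1000.0,
        "max_reversal_um": reversal,
    }
    processive = (
        track.duration_s > p.min_duration_s
        and abs(net_um) * 1000.0 > p.min_displacement_nm
        and reversal <= p.reversal_tolerance_um
    )
    return ("processive" if processive else "non-processive"), metrics


@dataclass
class MicrotubuleTracks:
    """Tracks observed on one microtubule, with its normalization metadata."""

    mt_id: str
    length_um: float
    duration_s: float
    conc_pM: float
    tracks: list[Track] = field(default_factory=list)


def processive_event_rate(
    groups: list[MicrotubuleTracks],
    params: ProcessivityParams | None = None,
) -> dict:
    """Processive events normalized per um, per s, and per pM for each MT.

    Reports both normalization conventions: ``rate`` divides by length x
    time x concentration; ``rate_no_time`` omits the per-second term (some
    presentations normalize only by length and motor amount). Mean and SEM
    are over microtubules.
    """
    if not groups:
        raise ValueError("processive_event_rate requires at least one microtubule")
    rates, rates_no_time, counts = [], [], []
    for g in groups:
        if g.length_um <= 0 or g.duration_s <= 0 or g.conc_pM <= 0:
            raise ValueError(
                f"microtubule {g.mt_id}: length, duration and concentration must be > 0"
            )
        n_proc = sum(
            1 for tr in g.tracks if classify_processive(tr, params)[0] == "processive"
        )
        counts.append(n_proc)
        rates.append(n_proc / (g.length_um * g.duration_s * g.conc_pM))
        rates_no_time.append(n_proc / (g.length_um * g.conc_pM))
    rates = np.array(rates)
    rates_no_time = np.array(rates_no_time)
    return {
        "per_mt_counts": counts,
        "per_mt_rates": rates,
        "rate_mean": float(rates.mean()),
        "rate_sem": sem(rates),
        "rate_no_time_mean": float(rates_no_time.mean()),
        "rate_no_time_sem": sem(rates_no_time),
    }


def gliding_velocity(tracks: list[Track]) -> dict:
    """Mean gliding speed per microtubule track and for the population.

    Per-track speed is the mean of |dx|/dt over consecutive samples (the
    speed of the filament's leading edge); the population statistic is the
    mean +/- SEM over tracks. Tracks with a single point are skipped with a
    warning.
    """
    speeds = []
    skipped = 0
    for tr in tracks:
        if len(tr.samples) < 2:
            skipped += 1
            continue
        t, x = tr.times, tr.positions
        speeds.append(float(np.mean(np.abs(np.diff(x)) / np.diff(t))))
    if skipped:
        logger.warning("gliding_velocity skipped %d single-point tracks", skipped)
    if not speeds:
        raise ValueError("no track with >= 2 points")
    arr = np.array(speeds)
    return {
        "per_track_speed_um_s": arr,
        "mean_um_s": float(arr.mean()),
        "sem_um_s": sem(arr),
        "n_tracks": len(speeds),
    }
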