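"""Size-exclusion chromatography quantification.

Complex formation is measured as the fraction of total protein eluting in a
peak window: the A280 trace is normalized by subtracting the baseline
reading at a reference volume (5 mL by default, well before the void), the
area under the curve (AUC) in the window is integrated by the trapezoid
rule on the native volume grid, and divided by the AUC of the whole trace.
Replicate fractions for two constructs are compared with an unpaired
two-tailed t test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ChromatogramTrace:
    """A280 absorbance versus elution volume."""

    volume_mL: np.ndarray
    a280: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.volume_mL = np.asarray(self.volume_mL, dtype=float)
        self.a280 = np.asarray(self.a280, dtype=float)
        if self.volume_mL.shape != self.a280.shape:
            raise ValueError("volume and absorbance grids must have equal length")
        if self.volume_mL.size < 10:
            raise ValueError(f"trace needs >= 10 points, got {self.volume_mL.size}")
        if np.any(np.diff(self.volume_mL) <= 0):
            raise ValueError("volume grid must be strictly increasing")


@dataclass(frozen=True)
class PeakWindow:
    """Integration window on the elution axis."""

    v_start_mL: float
    v_end_mL: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.v_start_mL >= self.v_end_mL:
            raise ValueError(
                f"window start ({self.v_start_mL}) must precede end ({self.v_end_mL})"
            )


def normalize_baseline(
    trace: ChromatogramTrace, reference_volume_mL: float = 5.0
) -> ChromatogramTrace:
    """Shift the trace so the baseline A280 at the reference volume is zero.

    The reference reading is linearly interpolated on the native grid; a
    constant offset of the input therefore never changes the output.
    """
    v = trace.volume_mL
    if not (v[0] <= reference_volume_mL <= v[-1]):
        raise ValueError(
            f"reference volume {reference_volume_mL} mL outside trace support "
            f"[{v[0]}, {v[-1]}]"
        )
    ref = float(np.interp(reference_volume_mL, v, trace.a280))
    return replace(trace, a280=trace.a280 - ref)


def _window_auc(v: np.ndarray, y: np.ndarray, window: PeakWindow) -> float:
    """Trapezoidal AUC over a window, interpolating the window endpoints."""
    v0 = max(window.v_start_mL, v[0])
    v1 = min(window.v_end_mL, v[-1])
    if v1 <= v0:
        return 0.0
    inside = (v > v0) & (v < v1)
    vv = np.concatenate([[v0], v[inside], [v1]])
    yy = np.concatenate([[np.interp(v0, v, y)], y[inside], [np.interp(v1, v, y)]])
    return float(np.trapezoid(yy, vv))


def auc_fraction(
    trace: ChromatogramTrace, window: PeakWindow, clip_negative: bool = True
) -> float:
    """Fraction of the total AUC falling inside the window.

    Negative post-normalization values are clipped to zero before
    integration (a trace cannot represent negative protein); pass
    ``clip_negative=False`` to integrate the signed trace.
    """
    y = trace.a280
    if clip_negative and np.any(y < 0):
        logger.info(
            "auc_fraction: clipping %d negative points to 0 before integration",
            int((y < 0).sum()),
        )
        y = np.clip(y, 0.0, None)
    total = float(np.trapezoid(y, trace.volume_mL))
    if total <= 0:
        raise ValueError("total AUC is <= 0; cannot form a fraction")
    return _window_auc(trace.volume_mL, y, window) / total


def compare_fractions(
    group_a, group_b, equal_var: bool = True
) -> tuple[float, float]:
    """Unpaired two-tailed t test between two groups of AUC fractions.

    Equal-variance Student's t by default; set ``equal_var=False`` for
    Welch's. Degenerate identical zero-variance groups return p = 1 with a
    warning rather than NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        logger.warning("compare_fractions: identical zero-variance groups; p = 1")
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


@dataclass
class SecComparison:
    """Per-trace fractions and the group comparison for two constructs."""

    fractions_a: list[float] = field(default_factory=list)
    fractions_b: list[float] = field(default_factory=list)
    label_a: str = "A"
    label_b: str = "B"

    def test(self, equal_var: bool = True) -> dict:
        t, p = compare_fractions(self.fractions_a, self.fractions_b, equal_var)
        a = np.asarray(self.fractions_a)
        b = np.asarray(self.fractions_b)
        def _sem(x):
            return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
        return {
            self.label_a: {"mean": float(a.mean()), "sem": _sem(a), "n": int(a.size)},
            self.label_b: {"mean": float(b.mean()), "sem": _sem(b), "n": int(b.size)},
            "t": t,
            "p": p,
        }
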