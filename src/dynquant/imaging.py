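"""ROI-based fluorescence quantification for fixed- and live-cell imaging.

Fixed-cell workflow: a SUM projection of the 11 z-slices around each
centrosome or spindle pole, a 12x12 pixel ROI on the structure, and three
12x12 cytoplasmic background ROIs. Centrosome signal subtracts the MEAN of
the backgrounds; spindle-pole signal divides by their MEDIAN (the two
conventions are deliberately not unified).

Live-cell workflow: MAX z-projections per timepoint, 3x3 pixel ROIs placed
on foci at the final frame and tracked backwards in time; when a focus
disappears its ROI is frozen in place for the earlier timepoints. The
summary is the mean +/- SD across foci at each timepoint.

The statistical comparison across conditions mirrors the standard
nonparametric workflow: Shapiro-Wilk normality and Bartlett variance
checks, a Kruskal-Wallis omnibus test, pairwise paired Wilcoxon tests, and
max-p aggregation across independent experiments.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ImageStack:
    """16-bit-semantics intensity stack, indexed (t?, z, y, x)."""

    intensities: np.ndarray
    has_time: bool = False
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        expected_ndim = 4 if self.has_time else 3
        if self.intensities.ndim != expected_ndim:
            raise ValueError(
                f"expected {expected_ndim}D array for has_time={self.has_time}, "
                f"got {self.intensities.ndim}D"
            )
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass(frozen=True)
class RoiSpec:
    """Square ROI anchored so the named center sits at (size//2, size//2)."""

    center_y: int
    center_x: int
    size_px: int = 12
    statistic: str = "mean"

    def __post_init__(self) -> None:
        if self.size_px < 1:
            raise ValueError(f"size_px must be >= 1, got {self.size_px}")
        if self.statistic not in ("mean", "sum"):
            raise ValueError(f"statistic must be 'mean' or 'sum', got {self.statistic!r}")

    def bounds(self) -> tuple[int, int, int, int]:
        y0 = self.center_y - self.size_px // 2
        x0 = self.center_x - self.size_px // 2
        return y0, y0 + self.size_px, x0, x0 + self.size_px


@dataclass(frozen=True)
class RoiMeasurement:
    """Raw, background and corrected ROI values."""

    raw: float
    background: float
    corrected: float
    mode: str  # 'subtract' or 'ratio'

    def __post_init__(self) -> None:
        if self.mode == "subtract":
            if abs(self.corrected - (self.raw - self.background)) > 1e-9:
                raise ValueError("subtract mode requires corrected = raw - background")
        elif self.mode == "ratio":
            if self.background <= 0:
                raise ValueError("ratio mode requires background > 0")
            if abs(self.corrected - self.raw / self.background) > 1e-9:
                raise ValueError("ratio mode requires corrected = raw / background")
        else:
            raise ValueError(f"mode must be 'subtract' or 'ratio', got {self.mode!r}")


# ---------------------------------------------------------------------------
# projections and ROI statistics
# ---------------------------------------------------------------------------

def sum_projection(stack: ImageStack, center_z: int, n_slices: int = 11) -> np.ndarray:
    """Pixelwise sum of ``n_slices`` z-slices centred on ``center_z``.

    The window must lie fully inside the stack; out-of-bounds windows are an
    error rather than silently truncated.
    """
    if n_slices % 2 == 0:
        raise ValueError(f"n_slices must be odd, got {n_slices}")
    if stack.has_time:
        raise ValueError("sum_projection expects a z-stack, not a time-lapse")
    half = n_slices // 2
    z0, z1 = center_z - half, center_z + half + 1
    nz = stack.intensities.shape[0]
    if z0 < 0 or z1 > nz:
        raise ValueError(
            f"projection window [{z0}, {z1}) exceeds stack bounds [0, {nz})"
        )
    return stack.intensities[z0:z1].sum(axis=0, dtype=np.float64)


def max_projection(stack_tzyx: np.ndarray) -> np.ndarray:
    """Pixelwise maximum over z for each timepoint of a (t, z, y, x) array."""
    arr = np.asarray(stack_tzyx)
    if arr.ndim != 4:
        raise ValueError(f"expected a (t, z, y, x) array, got {arr.ndim}D")
    return arr.max(axis=1)


def measure_roi(image: np.ndarray, roi: RoiSpec) -> float:
    """Mean (default) or sum intensity over a square ROI of a 2D image."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"measure_roi expects a 2D image, got {img.ndim}D")
    y0, y1, x0, x1 = roi.bounds()
    if y0 < 0 or x0 < 0 or y1 > img.shape[0] or x1 > img.shape[1]:
        raise ValueError(
            f"ROI [{y0}:{y1}, {x0}:{x1}] outside image of shape {img.shape}"
        )
    window = img[y0:y1, x0:x1].astype(np.float64)
    return float(window.sum() if roi.statistic == "sum" else window.mean())


def centrosome_signal(
    image: np.ndarray,
    centrosome_roi: RoiSpec,
    background_rois: list[RoiSpec],
    strict: bool = True,
) -> RoiMeasurement:
    """Background-subtracted centrosome intensity.

    corrected = ROI value - MEAN of exactly three cytoplasmic ROI values.
    Negative corrected values are meaningful (signal below local background)
    and pass through.
    """
    if len(background_rois) != 3:
        msg = f"centrosome workflow expects exactly 3 background ROIs, got {len(background_rois)}"
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    raw = measure_roi(image, centrosome_roi)
    bg = float(np.mean([measure_roi(image, r) for r in background_rois]))
    return RoiMeasurement(raw=raw, background=bg, corrected=raw - bg, mode="subtract")


def pole_ratio(
    image: np.ndarray,
    pole_roi: RoiSpec,
    background_rois: list[RoiSpec],
    strict: bool = True,
) -> RoiMeasurement:
    """Spindle-pole intensity over cytoplasmic background.

    corrected = ROI value / MEDIAN of exactly three cytoplasmic ROI values.
    """
    if len(background_rois) != 3:
        msg = f"pole workflow expects exactly 3 background ROIs, got {len(background_rois)}"
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    raw = measure_roi(image, pole_roi)
    bg = float(np.median([measure_roi(image, r) for r in background_rois]))
    if bg <= 0:
        raise ValueError(f"background median must be > 0 for a ratio, got {bg}")
    return RoiMeasurement(raw=raw, background=bg, corrected=raw / bg, mode="ratio")


# ---------------------------------------------------------------------------
# live-cell foci time course
# ---------------------------------------------------------------------------

def _local_max_shift(image: np.ndarray, y: int, x: int, radius: int = 1) -> tuple[int, int]:
    """Center of the brightest pixel within +/-radius of (y, x), clipped to bounds."""
    ny, nx = image.shape
    best, by, bx = -np.inf, y, x
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            yy, xx = y + dy, x + dx
            if 0 <= yy < ny and 0 <= xx < nx and image[yy, xx] > best:
                best, by, bx = image[yy, xx], yy, xx
    return by, bx


def foci_timecourse(
    stack: ImageStack,
    final_foci_yx: list[tuple[int, int]],
    background_yx: tuple[int, int],
    roi_size: int = 3,
    search_radius: int = 1,
    disappear_threshold: float = 0.0,
) -> dict:
    """Background-subtracted focus intensities through a time-lapse.

    Foci are defined at the final timepoint and tracked backwards by moving
    each ROI to the nearest local maximum within ``search_radius`` pixels.
    When a focus's corrected intensity drops to ``disappear_threshold`` or
    below, the ROI is frozen at its last position for all earlier
    timepoints. ROIs that would leave the field are flagged and excluded at
    that timepoint. Returns the per-focus matrix and per-timepoint mean +/- SD.
    """
    if not final_foci_yx:
        raise ValueError("at least one focus position is required")
    if stack.has_time:
        frames = max_projection(stack.intensities)
    else:
        raise ValueError("foci_timecourse requires a time-resolved stack (has_time=True)")
    n_t = frames.shape[0]
    n_foci = len(final_foci_yx)
    values = np.full((n_t, n_foci), np.nan)
    positions = list(final_foci_yx)
    frozen = [False] * n_foci

    bg_roi = RoiSpec(background_yx[0], background_yx[1], size_px=roi_size)
    for t in range(n_t - 1, -1, -1):
        img = frames[t]
        bg = measure_roi(img, bg_roi)
        for i, (y, x) in enumerate(positions):
            if not frozen[i] and t < n_t - 1:
                y, x = _local_max_shift(img, y, x, radius=search_radius)
            roi = RoiSpec(y, x, size_px=roi_size)
            y0, y1, x0, x1 = roi.bounds()
            if y0 < 0 or x0 < 0 or y1 > img.shape[0] or x1 > img.shape[1]:
                logger.warning("focus %d leaves the field at t=%d; excluded", i, t)
                continue
            corrected = measure_roi(img, roi) - bg
            values[t, i] = corrected
            if corrected <= disappear_threshold:
                frozen[i] = True  # freeze ROI for earlier timepoints
            else:
                positions[i] = (y, x)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(values, axis=1)
        sd = np.nanstd(values, axis=1, ddof=1) if n_foci > 1 else np.zeros(n_t)
    return {"per_focus": values, "mean": mean, "sd": sd, "n_foci": n_foci}


# ---------------------------------------------------------------------------
# nonparametric group comparison
# ---------------------------------------------------------------------------

def group_compare(experiments: list[dict[str, np.ndarray]]) -> dict:
    """Nonparametric comparison of conditions across independent experiments.

    ``experiments`` is a list (one entry per independent experiment) of
    {condition name: values} mappings. Per experiment: Shapiro-Wilk per
    condition, Bartlett across conditions, Kruskal-Wallis omnibus, and
    paired Wilcoxon for every condition pair (pairing by within-experiment
    measurement order; unpairable groups of unequal length are skipped with
    a warning). The reported p value per pairwise comparison is the MAXIMUM
    across experiments — the most conservative of the replicates.
    """
    if not experiments:
        raise ValueError("at least one experiment required")
    conditions = list(experiments[0].keys())
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions to compare")
    per_experiment = []
    pairwise_p: dict[tuple[str, str], list[float]] = {
        pair: [] for pair in itertools.combinations(conditions, 2)
    }
    kruskal_ps = []
    for k, exp in enumerate(experiments):
        groups = {c: np.asarray(exp[c], dtype=float) for c in conditions}
        shapiro = {}
        for c, v in groups.items():
            if v.size >= 3 and np.ptp(v) > 0:
                shapiro[c] = float(stats.shapiro(v).pvalue)
            else:
                shapiro[c] = float("nan")
        try:
            bartlett_p = float(stats.bartlett(*groups.values()).pvalue)
        except ValueError:
            bartlett_p = float("nan")
        if all(np.array_equal(groups[conditions[0]], g) for g in groups.values()):
            kruskal_p = 1.0  # identical groups carry no evidence of a difference
        else:
            kruskal_p = float(stats.kruskal(*groups.values()).pvalue)
        kruskal_ps.append(kruskal_p)
        report = {"shapiro": shapiro, "bartlett_p": bartlett_p, "kruskal_p": kruskal_p,
                  "wilcoxon": {}}
        for c1, c2 in pairwise_p:
            a, b = groups[c1], groups[c2]
            if a.size != b.size:
                logger.warning(
                    "experiment %d: %s vs %s unpairable (n=%d vs %d); skipped",
                    k, c1, c2, a.size, b.size,
                )
                continue
            if np.array_equal(a, b):
                p = 1.0
            else:
                p = float(stats.wilcoxon(a, b).pvalue)
            report["wilcoxon"][f"{c1} vs {c2}"] = p
            pairwise_p[(c1, c2)].append(p)
        per_experiment.append(report)
    return {
        "per_experiment": per_experiment,
        "kruskal_max_p": max(kruskal_ps),
        "pairwise_max_p": {
            f"{c1} vs {c2}": (max(ps) if ps else float("nan"))
            for (c1, c2), ps in pairwise_p.items()
        },
    }
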