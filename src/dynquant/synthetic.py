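"""Synthetic data generators with the statistical structure of the assays.

Each generator emulates one raw-data modality of the study conditions —
Poisson binding arrivals with two-phase exponential dwells quantized to the
125 ms camera cycle, static/diffusive/processive single-molecule tracks,
per-micrograph Poisson particle counts with multinomial conformational
labels, uniform inter-motor distances per state, multi-Gaussian
chromatograms on a baseline, and Gaussian foci on a noisy background —
and returns a ground-truth sidecar sufficient for parameter-recovery tests.

All randomness flows through ``numpy.random.default_rng(seed)``: a fixed
seed yields byte-identical output tables. Defaults are zero noise wherever
an analytic oracle exists downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .acquisition import AcquisitionParams
from .empop import MotorPairGeometry, ParticleRecord
from .imaging import ImageStack
from .kinetics import BindingEvent, MicrotubuleObservation
from .motility import Track
from .sec import ChromatogramTrace

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Seed, acquisition and per-scenario parameter blocks for a simulation."""

    seed: int = 0
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    kinetics: dict = field(default_factory=dict)
    motion: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)
    chromatogram: dict = field(default_factory=dict)
    imaging: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# single-molecule binding assay
# ---------------------------------------------------------------------------

def simulate_binding_assay(
    kon_per_site: float = 2.5e-5,
    fast_fraction: float = 0.8,
    tau_fast_s: float = 0.3,
    tau_slow_s: float = 3.0,
    mt_lengths_um: list[float] | None = None,
    duration_s: float = 120.0,
    conc_nM: float = 0.29,
    sites_per_um: float = 802.0,
    acquisition: AcquisitionParams | None = None,
    seed: int = 0,
) -> tuple[list[MicrotubuleObservation], dict]:
    """Poisson binding arrivals with two-phase exponential dwells.

    Arrivals on each microtubule are Poisson with mean
    kon_per_site x sites_per_um x length x conc x duration. Each dwell
    draws its phase by Bernoulli(fast_fraction) then an exponential with
    that phase's time constant. Event starts snap to the first frame
    boundary at or after the true arrival; dwells round to the nearest
    whole frame; events shorter than one frame after quantization are
    discarded and logged. Events still bound at movie end are emitted with
    ``censored=True``.

    Returns (observations, ground-truth dict).
    """
    acq = acquisition or AcquisitionParams()
    if kon_per_site < 0:
        raise ValueError(f"kon_per_site must be >= 0, got {kon_per_site}")
    for name, val in (("tau_fast_s", tau_fast_s), ("tau_slow_s", tau_slow_s),
                      ("conc_nM", conc_nM), ("sites_per_um", sites_per_um)):
        if val <= 0:
            raise ValueError(f"{name} must be > 0, got {val}")
    if not (0 <= fast_fraction <= 1):
        raise ValueError(f"fast_fraction must be in [0, 1], got {fast_fraction}")
    if tau_fast_s > tau_slow_s:
        raise ValueError(
            f"tau_fast_s ({tau_fast_s}) must not exceed tau_slow_s ({tau_slow_s})"
        )
    if duration_s <= 0:
        raise ValueError(f"duration_s must be > 0, got {duration_s}")
    cycle = acq.frame_cycle_s
    if abs(duration_s / cycle - round(duration_s / cycle)) > 1e-9:
        raise ValueError(
            f"duration_s ({duration_s}) must be a multiple of the frame cycle ({cycle})"
        )
    if mt_lengths_um is None:
        mt_lengths_um = [10.0] * 10
    if any(L <= 0 for L in mt_lengths_um):
        raise ValueError("mt_lengths_um entries must all be > 0")

    rng = np.random.default_rng(seed)
    observations = []
    n_discarded = 0
    for i, length in enumerate(mt_lengths_um):
        mt_id = f"mt{i:03d}"
        mean_events = kon_per_site * sites_per_um * length * conc_nM * duration_s
        n = rng.poisson(mean_events)
        events = []
        for _ in range(n):
            arrival = rng.uniform(0.0, duration_s)
            fast = rng.random() < fast_fraction
            dwell = rng.exponential(tau_fast_s if fast else tau_slow_s)
            start = np.ceil(arrival / cycle - 1e-12) * cycle
            frames = round(dwell / cycle)
            if frames < 1:
                n_discarded += 1
                continue
            end = start + frames * cycle
            censored = False
            if end > duration_s:
                end = duration_s
                censored = True
            if end <= start:
                n_discarded += 1
                continue
            events.append(
                BindingEvent(mt_id=mt_id, t_start_s=float(start), t_end_s=float(end),
                             censored=censored)
            )
        events.sort(key=lambda e: e.t_start_s)
        observations.append(
            MicrotubuleObservation(
                mt_id=mt_id, length_um=float(length),
                observation_duration_s=duration_s, conc_nM=conc_nM, events=events,
            )
        )
    if n_discarded:
        logger.info("simulate_binding_assay: discarded %d sub-frame events", n_discarded)
    truth = {
        "kon_per_site": kon_per_site,
        "kon_per_um_per_nM_per_s": kon_per_site * sites_per_um,
        "fast_fraction": fast_fraction,
        "tau_fast_s": tau_fast_s,
        "tau_slow_s": tau_slow_s,
        "koff_per_s": 1.0 / tau_fast_s,
        "kd_uM": (
            float("inf") if kon_per_site == 0
            else (1.0 / tau_fast_s) / kon_per_site / 1000.0
        ),
        "sites_per_um": sites_per_um,
        "n_discarded_subframe": n_discarded,
    }
    return observations, truth


# ---------------------------------------------------------------------------
# single-molecule / gliding tracks
# ---------------------------------------------------------------------------

def simulate_tracks(
    model: str = "processive",
    n_tracks: int = 50,
    v_um_s: float = 0.5,
    mean_run_um: float | None = 1.0,
    d_um2_s: float = 0.02,
    noise_um: float = 0.0,
    frame_cycle_s: float | None = None,
    pixel_size_um: float = 0.16,
    quantize: bool = True,
    n_frames: int = 40,
    acquisition: AcquisitionParams | None = None,
    seed: int = 0,
) -> tuple[list[Track], pd.DataFrame]:
    """Static, diffusive or processive 1D tracks sampled on the frame cycle.

    Processive tracks run at constant speed for an exponentially
    distributed run length (mean ``mean_run_um``) then stop; with
    ``mean_run_um=None`` they never stop (constant velocity over
    ``n_frames`` samples — the motion of a gliding microtubule's leading
    edge). Diffusive tracks take Gaussian steps with variance 2 D dt;
    static tracks stay put. Positions get Gaussian localization noise
    (``noise_um``, default zero) and are then quantized to the pixel grid
    unless ``quantize`` is False. Returns (tracks, ground-truth table).
    """
    if model not in ("static", "diffusive", "processive"):
        raise ValueError(f"model must be static|diffusive|processive, got {model!r}")
    if n_tracks < 1:
        raise ValueError(f"n_tracks must be >= 1, got {n_tracks}")
    if v_um_s < 0 or d_um2_s < 0:
        raise ValueError("velocity and diffusion coefficient must be >= 0")
    acq = acquisition or AcquisitionParams()
    dt = frame_cycle_s if frame_cycle_s is not None else acq.frame_cycle_s
    rng = np.random.default_rng(seed)
    tracks, truth_rows = [], []
    for i in range(n_tracks):
        if model == "processive":
            if mean_run_um is None:
                t = np.arange(n_frames) * dt
                x = v_um_s * t
                run = float("inf")
            else:
                run = rng.exponential(mean_run_um)
                run_t = run / v_um_s if v_um_s > 0 else 0.0
                nf = max(int(np.ceil(run_t / dt)) + 1, 2)
                t = np.arange(nf) * dt
                x = np.minimum(v_um_s * t, run)
        elif model == "diffusive":
            t = np.arange(n_frames) * dt
            steps = rng.normal(0.0, np.sqrt(2 * d_um2_s * dt), n_frames - 1)
            x = np.concatenate([[0.0], np.cumsum(steps)])
            run = 0.0
        else:
            t = np.arange(n_frames) * dt
            x = np.zeros(n_frames)
            run = 0.0
        if noise_um > 0:
            x = x + rng.normal(0.0, noise_um, x.size)
        if quantize:
            x = np.round(x / pixel_size_um) * pixel_size_um
        tracks.append(
            Track(track_id=f"tr{i:04d}", mt_id="mt000",
                  samples=list(zip(t.tolist(), x.tolist())))
        )
        truth_rows.append(
            {"track_id": f"tr{i:04d}", "model": model, "true_run_um": run,
             "true_v_um_s": v_um_s if model == "processive" else 0.0}
        )
    return tracks, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# EM particle populations and geometry
# ---------------------------------------------------------------------------

def simulate_particle_population(
    n_micrographs: int = 300,
    mean_particles_per_micrograph: float = 40.0,
    class_probs: dict[str, float] | None = None,
    orientation_probs: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[ParticleRecord], dict]:
    """Per-micrograph Poisson particle counts with multinomial class labels.

    Default class probabilities follow the wild-type population: 75% phi,
    22% open, 3% ambiguous. Optional orientation labels (defaults 52%
    inverted / 15% parallel / 33% ambiguous, the open-dynein split) are
    drawn independently of conformational class.
    """
    if n_micrographs < 1:
        raise ValueError(f"n_micrographs must be >= 1, got {n_micrographs}")
    class_probs = class_probs or {"phi": 0.75, "open": 0.22, "ambiguous": 0.03}
    _check_probs(class_probs, ("phi", "open", "ambiguous"))
    if orientation_probs is not None:
        _check_probs(orientation_probs, ("inverted", "parallel", "ambiguous"))
    rng = np.random.default_rng(seed)
    labels = list(class_probs)
    p = np.array([class_probs[k] for k in labels])
    records = []
    for m in range(n_micrographs):
        mg = f"micrograph_{m:04d}"
        n = rng.poisson(mean_particles_per_micrograph)
        drawn = rng.choice(len(labels), size=n, p=p)
        if orientation_probs is not None:
            olabels = list(orientation_probs)
            op = np.array([orientation_probs[k] for k in olabels])
            odrawn = rng.choice(len(olabels), size=n, p=op)
        for j in range(n):
            records.append(
                ParticleRecord(
                    micrograph_id=mg,
                    class_label=labels[drawn[j]],
                    orientation_label=(
                        olabels[odrawn[j]] if orientation_probs is not None else None
                    ),
                )
            )
    truth = {"class_probs": dict(class_probs),
             "orientation_probs": dict(orientation_probs) if orientation_probs else None,
             "n_micrographs": n_micrographs}
    return records, truth


def _check_probs(probs: dict[str, float], expected_keys: tuple[str, ...]) -> None:
    if set(probs) != set(expected_keys):
        raise ValueError(f"probabilities must have keys {expected_keys}, got {set(probs)}")
    vals = np.array(list(probs.values()))
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError(f"probabilities must lie in [0, 1], got {probs}")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {vals.sum()}")


def simulate_pair_geometry(
    state: str = "open",
    n_classes: int = 100,
    particles_per_class: float = 100.0,
    distance_range_nm: tuple[float, float] | None = None,
    orientation_probs: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[MotorPairGeometry], dict]:
    """One motor-center pair per 2D class with a uniform inter-motor distance.

    Default distance ranges: 10-45 nm for open dynein, 15-25 nm for the
    DDB-bound state. Orientation defaults: open 52/15/33 inverted/parallel/
    ambiguous; DDB 4/47/49. Per-class particle counts are Poisson.
    """
    if state not in ("open", "ddb"):
        raise ValueError(f"state must be 'open' or 'ddb', got {state!r}")
    if distance_range_nm is None:
        distance_range_nm = (10.0, 45.0) if state == "open" else (15.0, 25.0)
    lo, hi = distance_range_nm
    if lo <= 0 or hi < lo:
        raise ValueError(f"distance range must be positive and ordered, got {distance_range_nm}")
    if orientation_probs is None:
        orientation_probs = (
            {"inverted": 0.52, "parallel": 0.15, "ambiguous": 0.33}
            if state == "open"
            else {"inverted": 0.04, "parallel": 0.47, "ambiguous": 0.49}
        )
    _check_probs(orientation_probs, ("inverted", "parallel", "ambiguous"))
    rng = np.random.default_rng(seed)
    olabels = list(orientation_probs)
    op = np.array([orientation_probs[k] for k in olabels])
    geoms = []
    for c in range(n_classes):
        d = float(rng.uniform(lo, hi))
        theta = float(rng.uniform(0, 2 * np.pi))
        a = (0.0, 0.0)
        b = (d * np.cos(theta), d * np.sin(theta))
        geoms.append(
            MotorPairGeometry(
                class_id=c,
                particle_count=int(rng.poisson(particles_per_class)),
                center_a_nm=a, center_b_nm=b,
                orientation_label=olabels[int(rng.choice(len(olabels), p=op))],
            )
        )
    truth = {"distance_range_nm": distance_range_nm,
             "orientation_probs": dict(orientation_probs), "state": state}
    return geoms, truth


# ---------------------------------------------------------------------------
# chromatograms
# ---------------------------------------------------------------------------

def simulate_sec_trace(
    peaks: list[tuple[float, float, float]],
    baseline_level: float = 0.0,
    noise_sd: float = 0.0,
    volume_grid: np.ndarray | None = None,
    seed: int = 0,
    label: str = "",
) -> tuple[ChromatogramTrace, dict]:
    """Sum of Gaussian elution peaks on a flat baseline with optional noise.

    ``peaks`` is a list of (center_mL, sigma_mL, area) triples; the trace is
    baseline + sum of area-normalized Gaussians + N(0, noise_sd). The
    ground-truth sidecar carries each peak's parameters and total area, and
    an ``analytic_window_fraction(v0, v1)`` callable giving the exact
    Gaussian mass fraction in any window (the quadrature oracle).
    """
    if volume_grid is None:
        volume_grid = np.linspace(0.0, 24.0, 2401)
    v = np.asarray(volume_grid, dtype=float)
    if np.any(np.diff(v) <= 0):
        raise ValueError("volume grid must be strictly increasing (no duplicate points)")
    for center, sigma, area in peaks:
        if sigma <= 0:
            raise ValueError(f"peak sigma must be > 0, got {sigma}")
    rng = np.random.default_rng(seed)
    y = np.full_like(v, float(baseline_level))
    for center, sigma, area in peaks:
        y = y + area * stats.norm.pdf(v, loc=center, scale=sigma)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, v.size)
    total_area = sum(a for _, _, a in peaks)

    def analytic_window_fraction(v0: float, v1: float) -> float:
        mass = sum(
            a * (stats.norm.cdf(v1, c, s) - stats.norm.cdf(v0, c, s))
            for c, s, a in peaks
        )
        return mass / total_area if total_area > 0 else 0.0

    truth = {
        "peaks": list(peaks),
        "total_area": total_area,
        "baseline_level": baseline_level,
        "analytic_window_fraction": analytic_window_fraction,
    }
    return ChromatogramTrace(volume_mL=v, a280=y, label=label), truth


# ---------------------------------------------------------------------------
# cell images
# ---------------------------------------------------------------------------

def simulate_cell_image(
    shape_zyx: tuple[int, int, int] = (21, 128, 128),
    foci: list[tuple[int, int, int, float, float]] | None = None,
    background_level: float = 100.0,
    noise_model: str = "none",
    noise_sd: float = 0.0,
    n_timepoints: int | None = None,
    foci_onset_t: int | None = 0,
    seed: int = 0,
) -> tuple[ImageStack, pd.DataFrame]:
    """Gaussian foci on a uniform background, clipped to the 16-bit range.

    ``foci`` is a list of (z, y, x, amplitude, sigma_px); each focus is a 2D
    Gaussian in its home z-slice. ``noise_model`` is 'none', 'poisson'
    (shot-like, intensity-dependent) or 'gaussian' (additive, ``noise_sd``).
    With ``n_timepoints`` set, a (t, z, y, x) time-lapse is produced in
    which focus amplitudes ramp linearly from zero starting at
    ``foci_onset_t`` — the recovery kinetics of microtubule-dependent foci —
    or stay at full amplitude throughout when ``foci_onset_t`` is None.
    The ground-truth table carries each focus's true integrated signal.
    """
    nz, ny, nx = shape_zyx
    foci = foci or []
    for (z, y, x, amp, sig) in foci:
        if not (0 <= z < nz and 0 <= y < ny and 0 <= x < nx):
            raise ValueError(f"focus at ({z},{y},{x}) outside image bounds {shape_zyx}")
        if sig <= 0:
            raise ValueError(f"focus sigma must be > 0, got {sig}")
    if noise_model not in ("none", "poisson", "gaussian"):
        raise ValueError(f"noise_model must be none|poisson|gaussian, got {noise_model!r}")
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:ny, 0:nx]

    def render(amp_scale: float = 1.0) -> np.ndarray:
        img = np.full((nz, ny, nx), float(background_level))
        for (z, y, x, amp, sig) in foci:
            img[z] += amp_scale * amp * np.exp(
                -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sig**2)
            )
        return img

    def add_noise(img: np.ndarray) -> np.ndarray:
        if noise_model == "poisson":
            img = rng.poisson(img).astype(float)
        elif noise_model == "gaussian":
            img = img + rng.normal(0.0, noise_sd, img.shape)
        over = img > 65535
        if np.any(over):
            logger.warning("simulate_cell_image: clipping %d pixels above 16-bit range",
                           int(over.sum()))
        return np.clip(img, 0.0, 65535.0)

    rows = [
        {"z": z, "y": y, "x": x, "amplitude": amp, "sigma_px": sig,
         "true_integrated_signal": 2 * np.pi * sig**2 * amp}
        for (z, y, x, amp, sig) in foci
    ]
    truth = pd.DataFrame(rows)

    if n_timepoints is None:
        return ImageStack(add_noise(render()), has_time=False), truth

    frames = []
    for t in range(n_timepoints):
        if foci_onset_t is None:
            scale = 1.0
        else:
            scale = max(0.0, (t - foci_onset_t)) / max(1, n_timepoints - 1 - foci_onset_t)
        frames.append(add_noise(render(amp_scale=min(scale, 1.0))))
    return ImageStack(np.stack(frames), has_time=True), truth
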