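"""Population statistics for EM 2D-class assignments.

Conformational-class proportions (phi / open / ambiguous) are estimated with
a micrograph-resampling scheme: each round draws a fixed number of
micrographs uniformly without replacement from the remaining pool, the
drawn micrographs are removed so no micrograph contributes to two rounds,
and the mean +/- SEM of the per-round proportions is reported. Ambiguous
particles stay in the denominator.

Also provides the 2.5 nm inter-motor distance histogram, orientation
(inverted / parallel / ambiguous) summaries, and a geometric surrogate for
stalk-orientation assignment from motor-domain vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import sem

CLASS_LABELS = ("phi", "open", "ambiguous")
ORIENTATION_LABELS = ("inverted", "parallel", "ambiguous")


@dataclass(frozen=True)
class ParticleRecord:
    """One particle picked from one micrograph with its class assignment."""

    micrograph_id: str
    class_label: str
    orientation_label: str | None = None
    class_id: int | None = None
    center_a_nm: tuple[float, float] | None = None
    center_b_nm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        if self.orientation_label is not None and self.orientation_label not in ORIENTATION_LABELS:
            raise ValueError(
                f"orientation_label must be one of {ORIENTATION_LABELS}, "
                f"got {self.orientation_label!r}"
            )
        for c in (self.center_a_nm, self.center_b_nm):
            if c is not None and not all(math.isfinite(v) for v in c):
                raise ValueError("motor centers must be finite coordinate pairs")


@dataclass(frozen=True)
class ResamplingPlan:
    """Rounds of micrograph draws, without replacement across rounds."""

    micrographs_per_round: int = 25
    n_rounds: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.micrographs_per_round < 1 or self.n_rounds < 1:
            raise ValueError("micrographs_per_round and n_rounds must be >= 1")

    @property
    def required_micrographs(self) -> int:
        return self.micrographs_per_round * self.n_rounds


@dataclass
class ResamplingSummary:
    """Mean +/- SEM class proportions over resampling rounds."""

    mean_proportion: dict[str, float]
    sem_proportion: dict[str, float]
    mean_particles_per_micrograph: dict[str, float]
    n_rounds: int
    round_micrographs: list[list[str]]  # audit log of each round's draw

    def __post_init__(self) -> None:
        total = sum(self.mean_proportion.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mean proportions must sum to 1, got {total}")
        if any(v < 0 for v in self.sem_proportion.values()):
            raise ValueError("SEMs must be nonnegative")


@dataclass(frozen=True)
class MotorPairGeometry:
    """Motor-domain center pair of one 2D class, with its particle count."""

    class_id: int
    particle_count: int
    center_a_nm: tuple[float, float]
    center_b_nm: tuple[float, float]
    orientation_label: str | None = None

    def __post_init__(self) -> None:
        if self.particle_count < 0:
            raise ValueError(f"particle_count must be >= 0, got {self.particle_count}")

    @property
    def distance_nm(self) -> float:
        return math.hypot(
            self.center_b_nm[0] - self.center_a_nm[0],
            self.center_b_nm[1] - self.center_a_nm[1],
        )


def _resample_proportions(
    frame: pd.DataFrame, label_col: str, labels: tuple[str, ...], plan: ResamplingPlan
) -> ResamplingSummary:
    micrographs = sorted(frame["micrograph_id"].unique())
    if plan.required_micrographs > len(micrographs):
        raise ValueError(
            f"plan needs {plan.required_micrographs} micrographs "
            f"({plan.micrographs_per_round} x {plan.n_rounds}) but only "
            f"{len(micrographs)} are available"
        )
    rng = np.random.default_rng(plan.seed)
    order = rng.permutation(len(micrographs))
    rounds: list[list[str]] = []
    props = {lab: [] for lab in labels}
    counts_per_mg = {lab: [] for lab in labels}
    for r in range(plan.n_rounds):
        pick = [
            micrographs[i]
            for i in order[r * plan.micrographs_per_round : (r + 1) * plan.micrographs_per_round]
        ]
        rounds.append(pick)
        sub = frame[frame["micrograph_id"].isin(pick)]
        total = len(sub)
        if total == 0:
            raise ValueError(f"round {r}: selected micrographs contain no particles")
        for lab in labels:
            n = int((sub[label_col] == lab).sum())
            props[lab].append(n / total)
            counts_per_mg[lab].append(n / plan.micrographs_per_round)
    mean_p = {lab: float(np.mean(props[lab])) for lab in labels}
    # renormalize away float summation fuzz only
    s = sum(mean_p.values())
    mean_p = {lab: v / s for lab, v in mean_p.items()}
    return ResamplingSummary(
        mean_proportion=mean_p,
        sem_proportion={lab: sem(props[lab]) for lab in labels},
        mean_particles_per_micrograph={
            lab: float(np.mean(counts_per_mg[lab])) for lab in labels
        },
        n_rounds=plan.n_rounds,
        round_micrographs=rounds,
    )


def records_to_frame(records: list[ParticleRecord]) -> pd.DataFrame:
    """Tabulate particle records (one row per particle)."""
    return pd.DataFrame(
        {
            "micrograph_id": [r.micrograph_id for r in records],
            "class_label": [r.class_label for r in records],
            "orientation_label": [r.orientation_label for r in records],
        }
    )


def class_proportions_resampled(
    records: list[ParticleRecord], plan: ResamplingPlan | None = None
) -> ResamplingSummary:
    """Phi/open/ambiguous proportions via the 25-micrograph x 9-round scheme."""
    if not records:
        raise ValueError("no particle records supplied")
    plan = plan or ResamplingPlan()
    return _resample_proportions(records_to_frame(records), "class_label", CLASS_LABELS, plan)


def orientation_summary(
    records: list[ParticleRecord], plan: ResamplingPlan | None = None
) -> dict:
    """Inverted/parallel/ambiguous proportions, pooled over all particles.

    When a resampling plan is supplied, the SEM is estimated with the same
    micrograph-resampling scheme as the class proportions.
    """
    labelled = [r for r in records if r.orientation_label is not None]
    if not labelled:
        raise ValueError("no records carry orientation labels")
    n = len(labelled)
    pooled = {
        lab: sum(1 for r in labelled if r.orientation_label == lab) / n
        for lab in ORIENTATION_LABELS
    }
    out = {"pooled_proportion": pooled, "n_particles": n}
    if plan is not None:
        frame = records_to_frame(labelled)
        summary = _resample_proportions(frame, "orientation_label", ORIENTATION_LABELS, plan)
        out["resampled"] = summary
    return out


def distance_histogram(
    geometries: list[MotorPairGeometry], bin_width_nm: float = 2.5
) -> pd.DataFrame:
    """Particle-weighted histogram of inter-motor distances.

    Bins are [k*w, (k+1)*w) starting at 0 (left-closed, right-open); each 2D
    class contributes its particle count to the bin holding its distance.
    """
    if bin_width_nm <= 0:
        raise ValueError(f"bin_width_nm must be > 0, got {bin_width_nm}")
    if not geometries:
        raise ValueError("no geometries supplied")
    distances = np.array([g.distance_nm for g in geometries])
    if np.any(distances < 0):
        raise ValueError("distances must be nonnegative")
    counts = np.array([g.particle_count for g in geometries])
    idx = np.floor(distances / bin_width_nm).astype(int)
    n_bins = int(idx.max()) + 1
    binned = np.bincount(idx, weights=counts, minlength=n_bins)
    edges = np.arange(n_bins) * bin_width_nm
    return pd.DataFrame(
        {
            "bin_start_nm": edges,
            "bin_end_nm": edges + bin_width_nm,
            "particle_count": binned.astype(int),
        }
    )


def classify_pair_orientation(
    stalk_vector_a,
    stalk_vector_b,
    inter_motor_axis,
    angle_tol_deg: float = 20.0,
) -> str:
    """Orientation label from motor-domain stalk vectors.

    'inverted' when both stalks point toward the opposite motor (A along the
    inter-motor axis, B against it) within the tolerance; 'parallel' when the
    stalks' mutual angle is within the tolerance; otherwise 'ambiguous'.
    ``inter_motor_axis`` points from motor A to motor B.
    """
    a = np.asarray(stalk_vector_a, dtype=float)
    b = np.asarray(stalk_vector_b, dtype=float)
    axis = np.asarray(inter_motor_axis, dtype=float)
    for v, name in ((a, "stalk_vector_a"), (b, "stalk_vector_b"), (axis, "inter_motor_axis")):
        if np.linalg.norm(v) == 0:
            raise ValueError(f"{name} must be a nonzero vector")

    def angle_deg(u, v):
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return math.degrees(math.acos(np.clip(c, -1.0, 1.0)))

    if angle_deg(a, axis) <= angle_tol_deg and angle_deg(b, -axis) <= angle_tol_deg:
        return "inverted"
    if angle_deg(a, b) <= angle_tol_deg:
        return "parallel"
    return "ambiguous"
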