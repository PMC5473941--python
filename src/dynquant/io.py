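"""Readers and writers for the tabular and image formats the analyses use.

Events and tracks travel as headered CSV; particle class assignments as CSV
or a minimal STAR data table (a single ``data_``/``loop_`` block, the
dialect used for particle metadata in EM processing); chromatograms as
two-column CSV; image stacks as multi-page TIFF. Every writer's output is
readable by its paired reader with full fidelity of the declared fields.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams
from .empop import CLASS_LABELS, ParticleRecord
from .kinetics import BindingEvent, MicrotubuleObservation
from .motility import Track
from .sec import ChromatogramTrace

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# events and microtubules
# ---------------------------------------------------------------------------

def write_events_csv(observations: list[MicrotubuleObservation], path) -> None:
    rows = []
    for obs in observations:
        for k, ev in enumerate(obs.events):
            rows.append(
                {"mt_id": obs.mt_id, "event_id": f"{obs.mt_id}_e{k:04d}",
                 "t_start_s": ev.t_start_s, "t_end_s": ev.t_end_s,
                 "censored": int(ev.censored)}
            )
    pd.DataFrame(rows, columns=["mt_id", "event_id", "t_start_s", "t_end_s", "censored"]
                 ).to_csv(path, index=False)


def write_microtubules_csv(observations: list[MicrotubuleObservation], path) -> None:
    pd.DataFrame(
        [{"mt_id": o.mt_id, "length_um": o.length_um,
          "duration_s": o.observation_duration_s, "conc_nM": o.conc_nM}
         for o in observations]
    ).to_csv(path, index=False)


def read_observations_csv(
    events_path, microtubules_path, acquisition: AcquisitionParams | None = None
) -> list[MicrotubuleObservation]:
    """Join an event table and a microtubule table into observations.

    Event times may be given as seconds (t_start_s / t_end_s) or as frame
    indices (frame_start / frame_end, converted via the acquisition cycle).
    """
    events = pd.read_csv(events_path)
    mts = pd.read_csv(microtubules_path)
    if "mt_id" not in events.columns or "mt_id" not in mts.columns:
        raise ValueError("both tables must carry an mt_id column")
    if "t_start_s" not in events.columns:
        if "frame_start" not in events.columns:
            raise ValueError("event table needs t_start_s/t_end_s or frame_start/frame_end")
        cycle = (acquisition or AcquisitionParams()).frame_cycle_s
        events = events.assign(
            t_start_s=events["frame_start"] * cycle, t_end_s=events["frame_end"] * cycle
        )
    observations = []
    grouped = dict(tuple(events.groupby("mt_id")))
    for _, row in mts.iterrows():
        sub = grouped.get(row["mt_id"])
        evs = []
        if sub is not None:
            for _, e in sub.iterrows():
                evs.append(
                    BindingEvent(
                        mt_id=str(row["mt_id"]), t_start_s=float(e["t_start_s"]),
                        t_end_s=float(e["t_end_s"]),
                        censored=bool(e.get("censored", 0)),
                    )
                )
        observations.append(
            MicrotubuleObservation(
                mt_id=str(row["mt_id"]), length_um=float(row["length_um"]),
                observation_duration_s=float(row["duration_s"]),
                conc_nM=float(row["conc_nM"]), events=evs,
            )
        )
    return observations


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def write_tracks_csv(tracks: list[Track], path) -> None:
    rows = []
    for tr in tracks:
        for k, (t, x) in enumerate(tr.samples):
            rows.append({"track_id": tr.track_id, "mt_id": tr.mt_id,
                         "frame": k, "time_s": t, "position_um": x})
    pd.DataFrame(rows, columns=["track_id", "mt_id", "frame", "time_s", "position_um"]
                 ).to_csv(path, index=False)


def read_tracks_csv(path) -> list[Track]:
    frame = pd.read_csv(path)
    required = {"track_id", "mt_id", "time_s", "position_um"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    tracks = []
    for tid, sub in frame.groupby("track_id", sort=False):
        sub = sub.sort_values("time_s")
        tracks.append(
            Track(track_id=str(tid), mt_id=str(sub["mt_id"].iloc[0]),
                  samples=list(zip(sub["time_s"], sub["position_um"])))
        )
    return tracks


# ---------------------------------------------------------------------------
# particle tables (CSV and minimal STAR)
# ---------------------------------------------------------------------------

def _parse_star_table(path) -> pd.DataFrame:
    """Parse the first loop_ table of a STAR file into a DataFrame.

    Handles the plain dialect used for particle metadata: one ``data_``
    block, a ``loop_`` header of ``_rlnXxx`` column tags, then whitespace-
    separated rows. Comments (#) and blank lines are ignored.
    """
    columns: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("data_"):
            continue
        if line == "loop_":
            in_loop = True
            continue
        if in_loop and line.startswith("_"):
            columns.append(line.split()[0].lstrip("_"))
            continue
        if in_loop and columns:
            fields = line.split()
            if len(fields) != len(columns):
                raise ValueError(
                    f"STAR row has {len(fields)} fields, expected {len(columns)}: {line!r}"
                )
            rows.append(fields)
    if not columns:
        raise ValueError(f"no loop_ table found in {path}")
    return pd.DataFrame(rows, columns=columns)


def read_particle_table(
    path,
    micrograph_column: str | None = None,
    class_column: str | None = None,
    class_mapping: dict | None = None,
    orientation_column: str | None = None,
) -> list[ParticleRecord]:
    """Read particle class assignments from CSV or a STAR data table.

    ``class_mapping`` maps raw class ids/labels to the phi/open/ambiguous
    vocabulary; unmapped values become 'ambiguous' with a warning. Duplicate
    rows are preserved — the table counts particles, not unique molecules.
    """
    path = Path(path)
    if path.suffix.lower() == ".star":
        frame = _parse_star_table(path)
        micrograph_column = micrograph_column or "rlnMicrographName"
        class_column = class_column or "rlnClassNumber"
    else:
        frame = pd.read_csv(path)
        micrograph_column = micrograph_column or "micrograph_id"
        class_column = class_column or "class_label"
    if micrograph_column not in frame.columns:
        raise ValueError(
            f"missing micrograph column {micrograph_column!r}; "
            f"available: {list(frame.columns)}"
        )
    if class_column not in frame.columns:
        raise ValueError(f"missing class column {class_column!r}")
    records = []
    n_unmapped = 0
    for _, row in frame.iterrows():
        raw = row[class_column]
        if class_mapping is not None:
            label = class_mapping.get(raw, class_mapping.get(str(raw)))
            if label is None:
                try:
                    label = class_mapping.get(int(raw))
                except (TypeError, ValueError):
                    label = None
            if label is None:
                label = "ambiguous"
                n_unmapped += 1
        else:
            label = str(raw)
        if label not in CLASS_LABELS:
            label = "ambiguous"
            n_unmapped += 1
        orientation = None
        if orientation_column and orientation_column in frame.columns:
            val = row[orientation_column]
            orientation = str(val) if pd.notna(val) else None
        records.append(
            ParticleRecord(micrograph_id=str(row[micrograph_column]),
                           class_label=label, orientation_label=orientation)
        )
    if n_unmapped:
        logger.warning("read_particle_table: %d unmapped class values -> ambiguous",
                       n_unmapped)
    return records


def write_particle_star(records: list[ParticleRecord], path) -> None:
    """Write particle records as a minimal STAR data table."""
    lines = ["data_particles", "", "loop_",
             "_rlnMicrographName #1", "_rlnClassLabel #2"]
    for r in records:
        lines.append(f"{r.micrograph_id} {r.class_label}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_particle_csv(records: list[ParticleRecord], path) -> None:
    pd.DataFrame(
        [{"micrograph_id": r.micrograph_id, "class_label": r.class_label,
          "orientation_label": r.orientation_label or ""}
         for r in records]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# chromatograms and images
# ---------------------------------------------------------------------------

def write_chromatogram_csv(trace: ChromatogramTrace, path) -> None:
    pd.DataFrame({"volume_mL": trace.volume_mL, "a280": trace.a280}).to_csv(
        path, index=False
    )


def read_chromatogram_csv(path, label: str = "") -> ChromatogramTrace:
    frame = pd.read_csv(path)
    missing = {"volume_mL", "a280"} - set(frame.columns)
    if missing:
        raise ValueError(f"chromatogram CSV missing columns: {sorted(missing)}")
    return ChromatogramTrace(
        volume_mL=frame["volume_mL"].to_numpy(), a280=frame["a280"].to_numpy(),
        label=label or Path(path).stem,
    )


def write_tiff_stack(array: np.ndarray, path) -> None:
    """Write a (z, y, x) or (t, z, y, x) array as multi-page 16-bit TIFF."""
    import tifffile

    arr = np.asarray(array)
    tifffile.imwrite(path, np.clip(arr, 0, 65535).astype(np.uint16))


def read_tiff_stack(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
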