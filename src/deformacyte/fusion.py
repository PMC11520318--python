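"""Electro-optical correlation, coincidence statistics and the Y-gate.

Each impedance event predicts the camera frame in which its cell was
photographed (frame = floor(trigger time x frame rate)).  Frames holding two
or more cells are coincidences, quantified against the Poisson expectation;
cells imaged near the channel walls show a tear-drop artefact that inflates
the optical (but not the electrical) deformability, and are removed by a
gate on the lateral position.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simkit import AcquisitionSettings

__all__ = [
    "BlurResult",
    "GateResult",
    "MatchReport",
    "match_events_to_frames",
    "coincidence_rate",
    "coincidence_probability",
    "poisson_pmf",
    "blur_length",
    "apply_y_gate",
]

logger = logging.getLogger(__name__)

GATE_HALFWIDTH_UM = 6.3   # +/-10 px at 0.63 um per pixel


@dataclass
class MatchReport:
    n_events: int = 0
    n_frames_with_object: int = 0
    n_matched: int = 0
    n_coincident: int = 0
    unmatched_events: list = field(default_factory=list)
    unmatched_frames: list = field(default_factory=list)


@dataclass
class BlurResult:
    displacement_um: float
    pct_of_diameter: float | None = None


@dataclass
class GateResult:
    table: pd.DataFrame          # full table with gate_pass flags
    retained: pd.DataFrame       # rows passing the gate
    report: dict                 # per-group retention summary


def match_events_to_frames(events: pd.DataFrame, optics: pd.DataFrame,
                           acq: AcquisitionSettings) -> tuple[pd.DataFrame,
                                                              MatchReport]:
    """Join impedance events with per-frame optical measurements.

    Events map to ``floor(t_trigger * frame_rate)``.  Events sharing a frame
    (or whose frame shows >= 2 objects) are flagged coincident; in such
    frames only the earliest-trigger event is paired with the single
    measured (largest) object.  Row order of either input does not affect
    the pairing.
    """
    ev = events.sort_values("t_trigger_s", kind="stable").reset_index(drop=True)
    op = optics.sort_values("frame_index", kind="stable").reset_index(drop=True)
    report = MatchReport(n_events=len(ev), n_frames_with_object=len(op))
    if len(ev) == 0 or len(op) == 0:
        raise ValueError("empty event or optics table")

    fps = acq.frame_rate_hz
    ev_frame = np.floor(ev["t_trigger_s"].to_numpy() * fps).astype(int)
    op_by_frame = {int(r.frame_index): r for r in op.itertuples()}
    if not (set(ev_frame) & set(op_by_frame)):
        raise ValueError("clock ranges disjoint: no overlapping frames")

    counts = pd.Series(ev_frame).value_counts()
    rows = []
    seen_frames: set[int] = set()
    for k, row in enumerate(ev.itertuples()):
        fidx = int(ev_frame[k])
        opt = op_by_frame.get(fidx)
        multi_objects = (opt is not None
                         and getattr(opt, "n_objects_in_frame", 1) >= 2)
        coincident = counts[fidx] >= 2 or multi_objects
        matched = opt is not None and fidx not in seen_frames
        if matched:
            seen_frames.add(fidx)
        else:
            report.unmatched_events.append(int(row.event_id))
        out = {
            "event_id": int(row.event_id),
            "frame_index": fidx if matched else -1,
            "ed": getattr(row, "ed", float("nan")),
            "od": float(opt.od) if matched else float("nan"),
            "electrical_diameter_um": getattr(row, "electrical_diameter_um",
                                              float("nan")),
            "optical_diameter_um": (float(opt.optical_diameter_um)
                                    if matched else float("nan")),
            "velocity_m_s": float(row.velocity_m_s),
            "y_um": float(opt.y_um) if matched else float("nan"),
            "coincident": bool(coincident),
        }
        for extra in ("kind", "group", "truth_id"):
            if hasattr(row, extra):
                out[extra] = getattr(row, extra)
        rows.append(out)

    report.unmatched_frames = sorted(set(op_by_frame) - seen_frames)
    report.n_matched = len(seen_frames)
    report.n_coincident = int(sum(r["coincident"] for r in rows))
    if report.unmatched_events or report.unmatched_frames:
        logger.info("match: %d unmatched events, %d unmatched frames",
                    len(report.unmatched_events),
                    len(report.unmatched_frames))
    return pd.DataFrame(rows), report


def coincidence_rate(optics: pd.DataFrame | np.ndarray,
                     denominator: str = "occupied") -> float:
    """Percentage of frames holding >= 2 objects, rounded to one decimal.

    ``denominator`` is "occupied" (frames with >= 1 object, matching the
    published 53-of-2844 counting) or "all" (every frame in the table).
    """
    if isinstance(optics, pd.DataFrame):
        counts = optics["n_objects_in_frame"].to_numpy()
    else:
        counts = np.asarray(optics)
    if counts.size == 0:
        raise ValueError("zero frames")
    multi = int(np.sum(counts >= 2))
    if denominator == "occupied":
        denom = int(np.sum(counts >= 1))
    elif denominator == "all":
        denom = counts.size
    else:
        raise ValueError("denominator must be 'occupied' or 'all'")
    if denom == 0:
        raise ValueError("zero frames in denominator")
    return round(100.0 * multi / denom, 1)


def poisson_pmf(lam: float, k: int) -> float:
    """P(k) = lambda^k e^-lambda / k! for particle-count coincidences."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if k < 0 or int(k) != k:
        raise ValueError("k must be a non-negative integer")
    return float(sps.poisson.pmf(int(k), lam))


def coincidence_probability(lam: float) -> float:
    """Poisson P(>= 2 objects | >= 1 object) for frame occupancy rate lam."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam == 0:
        return 0.0
    p0 = math.exp(-lam)
    p1 = lam * p0
    return (1.0 - p0 - p1) / (1.0 - p0)


def blur_length(velocity_m_s: float, pulse_s: float,
                diameter_um: float | None = None) -> BlurResult:
    """Motion-blur displacement (um) during the LED pulse.

    Optionally also expressed as a percentage of a given cell diameter.
    """
    if velocity_m_s < 0 or pulse_s < 0:
        raise ValueError("velocity and pulse must be non-negative")
    disp = velocity_m_s * pulse_s * 1e6
    pct = None
    if diameter_um is not None:
        if diameter_um <= 0:
            raise ValueError("diameter must be positive")
        pct = 100.0 * disp / diameter_um
    return BlurResult(displacement_um=disp, pct_of_diameter=pct)


def apply_y_gate(correlated: pd.DataFrame,
                 gate_halfwidth_um: float = GATE_HALFWIDTH_UM) -> GateResult:
    """Keep events whose cell centroid is within the midline gate.

    The gate only changes membership, never the ED/OD values.  The report
    gives retained/total counts and an integer-rounded percentage per group
    (a single "all" group when no group column is present).
    """
    table = correlated.copy()
    y = table["y_um"].to_numpy(dtype=float)
    table["gate_pass"] = np.abs(y) <= gate_halfwidth_um
    table.loc[~np.isfinite(y), "gate_pass"] = False
    retained = table[table["gate_pass"]].copy()

    if "group" in table.columns:
        groups = table.groupby("group", sort=True)
    else:
        groups = [("all", table)]
    report = {}
    for name, sub in groups:
        total = len(sub)
        kept = int(sub["gate_pass"].sum())
        pct = int(round(100.0 * kept / total)) if total else 0
        report[str(name)] = {"retained": kept, "total": total,
                             "percent": pct,
                             "label": f"{kept}/{total} ({pct}%)"}
    return GateResult(table=table, retained=retained, report=report)
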