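"""Pin-array stimulus timeline and finger-pursuit kinematics.

The tactile display is an 8x8 array of laterally vibrating pins.  Apparent
motion of a single virtual ridge is produced by actuating rows in sequence:
at every refresh the ridge position advances by ``v_tact * refresh_period``
and the row currently overlapped by the ridge vibrates at 20 Hz.  The ridge
pattern repeats with a spatial period equal to the first-to-last row
distance plus one wrap gap, so exactly one ridge is felt at any time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ArrayGeometry",
    "PursuitTrace",
    "StimulusTimeline",
    "build_row_timeline",
    "ridge_spatial_period",
    "trial_kinematics",
]


@dataclass(frozen=True)
class ArrayGeometry:
    """Geometry and timing of the pin-array display.

    Defaults describe an 8-row array with 1.6 mm row pitch, a 1.6 mm wrap
    gap (spatial ridge period 12.8 mm), a 1.5 ms refresh period and 20 Hz
    pin oscillation at 0.1 mm amplitude.
    """

    n_rows: int = 8
    row_pitch: float = 1.6  # mm
    wrap_gap: float = 1.6  # mm
    refresh_period: float = 0.0015  # s
    osc_freq: float = 20.0  # Hz
    osc_amplitude: float = 0.1  # mm

    def __post_init__(self) -> None:
        if self.n_rows < 2:
            raise ValueError("n_rows must be >= 2")
        for name in ("row_pitch", "wrap_gap", "refresh_period", "osc_freq", "osc_amplitude"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class PursuitTrace:
    """Two-phase finger trajectory of one trial.

    The finger tracks the ridge at ``phase1_speed`` for the first
    ``phase1_distance`` of travel; past that point the surface velocity
    changes abruptly while the finger keeps moving (main task) or stops
    (control task), until ``total_distance`` is reached.
    ``v_prop_phase2`` is the finger velocity actually realised in phase 2
    of the main task (measured mean 10.8 mm/s for a commanded 10 mm/s).
    """

    phase1_speed: float = 10.0  # mm/s
    phase1_distance: float = 50.0  # mm
    total_distance: float = 100.0  # mm
    v_prop_phase2: float = 10.8  # mm/s

    def __post_init__(self) -> None:
        if not (self.phase1_distance > 0.0 and self.total_distance > self.phase1_distance):
            raise ValueError("need 0 < phase1_distance < total_distance")


@dataclass
class StimulusTimeline:
    """Row-actuation schedule generated by :func:`build_row_timeline`.

    ``events`` holds one record per row hand-off: the time (s) at which a
    row becomes active, the row index, and the unwrapped ridge position
    (mm) at that instant.
    """

    events: pd.DataFrame
    v_tact: float
    geometry: ArrayGeometry
    duration: float = field(default=0.0)

    def row_sequence(self) -> np.ndarray:
        return self.events["row"].to_numpy()

    def same_row_return_distances(self) -> np.ndarray:
        """Ridge travel between consecutive activations of the same row.

        Measured from the timeline itself; up to refresh-step quantisation
        this equals the spatial ridge period of the geometry.
        """
        out = []
        for _, grp in self.events.groupby("row"):
            pos = grp["ridge_position"].to_numpy()
            if len(pos) > 1:
                out.append(np.abs(np.diff(pos)))
        if not out:
            return np.empty(0)
        return np.concatenate(out)

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)


def ridge_spatial_period(geometry: ArrayGeometry) -> float:
    """Distance between successive virtual ridges (mm)."""
    return (geometry.n_rows - 1) * geometry.row_pitch + geometry.wrap_gap


def build_row_timeline(geometry: ArrayGeometry, v_tact: float, duration: float) -> StimulusTimeline:
    """Simulate the row-actuation schedule for a commanded slip velocity.

    The virtual ridge position integrates ``v_tact`` at the display refresh
    rate; the active row is the one whose 1-pitch-wide slot the ridge
    currently overlaps (the wrap gap is absorbed into the last row's slot so
    exactly one row is active at all times).  Hand-offs are immediate, with
    no cross-fading.  ``v_tact = 0`` keeps a single row active throughout.
    """
    if not duration > 0.0:
        raise ValueError(f"duration must be > 0, got {duration!r}")
    dt = geometry.refresh_period
    period = ridge_spatial_period(geometry)
    n_steps = int(np.floor(duration / dt))
    times = np.arange(n_steps + 1) * dt
    positions = v_tact * times
    wrapped = np.mod(positions, period)  # in [0, period)
    rows = np.minimum((wrapped / geometry.row_pitch).astype(int), geometry.n_rows - 1)
    change = np.empty(len(rows), dtype=bool)
    change[0] = True
    change[1:] = rows[1:] != rows[:-1]
    events = pd.DataFrame(
        {
            "time": times[change],
            "row": rows[change],
            "ridge_position": positions[change],
        }
    )
    return StimulusTimeline(events=events, v_tact=v_tact, geometry=geometry, duration=duration)


def trial_kinematics(trace: PursuitTrace, v_surf: float, condition: str) -> tuple[float, float]:
    """Phase-2 finger and slip velocities for one trial.

    Main task: the finger keeps moving, so ``v_prop = v_prop_phase2`` and
    the slip on the skin is ``v_tact = v_surf - v_prop``.  Control task: the
    finger is stationary, ``v_prop = 0`` and ``v_tact = v_surf``.
    """
    if condition == "main":
        v_prop = trace.v_prop_phase2
        return v_prop, v_surf - v_prop
    if condition == "control":
        return 0.0, v_surf
    raise ValueError(f"unknown condition {condition!r}; expected 'main' or 'control'")
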