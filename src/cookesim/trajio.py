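"""Trajectory interchange in an extended-XYZ dialect.

Frame layout::

    <n beads>
    box=<edge_nm> t=<time_ps>
    <label> <x_nm> <y_nm> <z_nm>
    ...

Labels are two letters: bead class (H/T) + molecule kind (L/P), e.g. ``TL``
for a lipid tail bead.  Coordinates are written in nm with five decimals,
so round-trips are exact to 1e-5 nm.  The box edge on the comment line is
mandatory; a frame without it is a parse error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .engine import SystemState, Trajectory
from .forcefield import CLASS_H, KIND_LIPID
from .topology import Topology
from .units import Units, DEFAULT_UNITS

__all__ = ["write_trajectory", "read_trajectory", "Frame", "bead_labels"]


@dataclass
class Frame:
    positions_nm: np.ndarray
    box_edge_nm: float
    time_ps: float
    labels: list[str]

    def to_state(self, units: Units = DEFAULT_UNITS) -> SystemState:
        pos = self.positions_nm / units.sigma_nm
        return SystemState(pos, np.zeros_like(pos),
                           self.box_edge_nm / units.sigma_nm,
                           self.time_ps / units.tau_ps)


class TrajectoryParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def bead_labels(topology: Topology) -> list[str]:
    out = []
    for b in topology.beads:
        cls = "H" if b.bead_class == CLASS_H else "T"
        kind = "L" if b.molecule_kind == KIND_LIPID else "P"
        out.append(cls + kind)
    return out


def write_trajectory(path, frames, topology: Topology | None = None,
                     labels: list[str] | None = None,
                     units: Units = DEFAULT_UNITS) -> None:
    """Write frames (SystemState list or a Trajectory) to extended XYZ."""
    if isinstance(frames, Trajectory):
        states = [frames.frame_state(i) for i in range(frames.n_frames)]
    else:
        states = list(frames)
    with open(path, "w") as fh:
        for st in states:
            n = st.positions.shape[0]
            if labels is not None:
                labs = labels
            elif topology is not None:
                labs = bead_labels(topology)
            else:
                labs = ["XX"] * n
            pos = units.sigma_to_nm(1.0) * st.wrapped().positions
            fh.write(f"{n}\n")
            fh.write(f"box={units.sigma_to_nm(st.box_edge):.5f} "
                     f"t={st.time * units.tau_ps:.5f}\n")
            for lab, (x, y, z) in zip(labs, pos):
                fh.write(f"{lab} {x:.5f} {y:.5f} {z:.5f}\n")


_COMMENT_RE = re.compile(r"box=([0-9.eE+-]+)\s+t=([0-9.eE+-]+)")


def read_trajectory(path) -> list[Frame]:
    """Read frames back; malformed input raises with the offending line."""
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError:
            raise TrajectoryParseError(
                f"expected bead count, got {lines[k]!r}", k + 1)
        if k + 1 >= len(lines):
            raise TrajectoryParseError("missing comment line", k + 2)
        m = _COMMENT_RE.search(lines[k + 1])
        if not m:
            raise TrajectoryParseError(
                "comment line must contain 'box=<nm> t=<ps>'", k + 2)
        box = float(m.group(1))
        time = float(m.group(2))
        if k + 2 + n > len(lines):
            raise TrajectoryParseError(
                f"truncated frame: expected {n} bead lines", len(lines))
        pos = np.empty((n, 3))
        labels = []
        for i in range(n):
            ln = k + 2 + i
            parts = lines[ln].split()
            if len(parts) != 4:
                raise TrajectoryParseError(
                    f"expected 'label x y z', got {lines[ln]!r}", ln + 1)
            labels.append(parts[0])
            try:
                pos[i] = [float(v) for v in parts[1:]]
            except ValueError:
                raise TrajectoryParseError(
                    f"bad coordinate in {lines[ln]!r}", ln + 1)
        frames.append(Frame(pos, box, time, labels))
        k += 2 + n
    return frames


# ----------------------------------------------------------------------
# checkpoints
# ----------------------------------------------------------------------

def save_checkpoint(path, state: SystemState,
                    rng: "np.random.Generator | None" = None) -> None:
    """Write full state (positions, velocities, box, time) plus, if given,
    the noise generator's internal state.

    A continuation from the checkpoint is exactly reproducible (same
    checkpoint, same continuation, bit for bit) and consumes the original
    run's noise stream where it left off.  It is not bit-identical to the
    unsegmented run: neighbor-list rebuild points differ across a restart
    boundary, and Langevin dynamics amplifies that rounding-level
    difference.  Equilibrium statistics are unaffected."""
    import json
    doc = {
        "positions": state.positions.tolist(),
        "velocities": state.velocities.tolist(),
        "box_edge": state.box_edge,
        "time": state.time,
    }
    if rng is not None:
        bg = rng.bit_generator.state
        doc["rng_state"] = {"bit_generator": bg["bit_generator"],
                            "state": {k: list(map(int, v)) if
                                      hasattr(v, "__len__") else int(v)
                                      for k, v in bg["state"].items()},
                            "has_uint32": int(bg.get("has_uint32", 0)),
                            "uinteger": int(bg.get("uinteger", 0))}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_checkpoint(path):
    """Read a checkpoint; returns (SystemState, rng or None)."""
    import json
    with open(path) as fh:
        doc = json.load(fh)
    state = SystemState(np.asarray(doc["positions"], dtype=float),
                        np.asarray(doc["velocities"], dtype=float),
                        float(doc["box_edge"]), float(doc["time"]))
    rng = None
    if "rng_state" in doc:
        saved = doc["rng_state"]
        bg_cls = getattr(np.random, saved["bit_generator"])
        bg = bg_cls()
        bg.state = {"bit_generator": saved["bit_generator"],
                    "state": {k: (np.array(v, dtype=np.uint64)
                                  if isinstance(v, list) else v)
                              for k, v in saved["state"].items()},
                    "has_uint32": saved["has_uint32"],
                    "uinteger": saved["uinteger"]}
        rng = np.random.Generator(bg)
    return state, rng
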