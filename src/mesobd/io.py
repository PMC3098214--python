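"""Trajectory and result sinks.

The original shell-pipe output of the ancestral C++ engine is replaced by
in-process reducers plus plain-file sinks: a frame can be written in full
(instance id, type, position, quaternion per gestalt) or reduced on the
fly (e.g. centre of mass plus end-to-end vector only) to keep output
files small.  A positions-only XYZ writer is provided for viewers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_trajectory_text", "reduce_com_ee", "write_manifest",
           "write_trajectory_text", "write_transport_csv", "write_xyz"]

TRAJ_HEADER = "# mesobd trajectory v1"


def write_trajectory_text(path, traj, system, replica: int = 0,
                          reducer: str | None = None) -> None:
    """Plain-text trajectory: per frame one ``frame t=<ps>`` line followed
    by per-gestalt records ``id template x y z qw qx qy qz``.

    ``reducer='com+ee'`` writes per frame only the centre of mass and the
    first-to-last-gestalt vector of every instance (6 numbers each)
    instead of all gestalten.
    """
    with open(path, "w") as fh:
        fh.write(TRAJ_HEADER + "\n")
        fh.write(f"# gestalten {system.n_gestalt} reducer "
                 f"{reducer or 'none'}\n")
        for f in range(traj.n_frames):
            fh.write(f"frame t={traj.times[f]:.6g}\n")
            pos = traj.pos[f, replica]
            if reducer == "com+ee":
                for inst, idx in enumerate(system.instances):
                    com = pos[idx].mean(axis=0)
                    ee = pos[idx[-1]] - pos[idx[0]]
                    fh.write(f"{inst} com+ee "
                             + " ".join(f"{v:.8g}" for v in (*com, *ee)) + "\n")
                continue
            quat = (traj.quat[f, replica] if traj.quat is not None
                    else np.tile([1.0, 0, 0, 0], (len(pos), 1)))
            active = (traj.active[f, replica] if traj.active is not None
                      else np.ones(len(pos), dtype=bool))
            for g in range(len(pos)):
                if not active[g]:
                    continue
                fh.write(f"{g} {system.g_template[g]} "
                         + " ".join(f"{v:.8g}" for v in pos[g])
                         + " " + " ".join(f"{v:.8g}" for v in quat[g]) + "\n")


def read_trajectory_text(path):
    """Read the plain-text format back: (times, frames) where each frame
    is a dict id -> (template, position, quaternion)."""
    times, frames = [], []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(TRAJ_HEADER):
            raise ValueError(f"{path} is not a mesobd trajectory")
        cur = None
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("frame"):
                times.append(float(line.split("t=")[1]))
                cur = {}
                frames.append(cur)
                continue
            parts = line.split()
            gid = int(parts[0])
            name = parts[1]
            vals = np.array([float(v) for v in parts[2:]])
            cur[gid] = (name, vals[:3], vals[3:])
    return np.asarray(times), frames


def write_xyz(path, traj, system, replica: int = 0,
              element: str = "C") -> None:
    """Positions-only XYZ for molecular viewers (one frame per block)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            pos = traj.pos[f, replica]
            fh.write(f"{len(pos)}\nt={traj.times[f]:.6g} ps\n")
            for p in pos:
                fh.write(f"{element} {p[0]:.5f} {p[1]:.5f} {p[2]:.5f}\n")


def reduce_com_ee(traj, system):
    """Post-hoc reduction equivalent to the 'com+ee' streaming reducer."""
    coms = np.stack([traj.pos[:, :, idx, :].mean(axis=2)
                     for idx in system.instances], axis=2)
    ees = np.stack([traj.pos[:, :, idx[-1], :] - traj.pos[:, :, idx[0], :]
                    for idx in system.instances], axis=2)
    return coms, ees


def write_transport_csv(path, traj) -> None:
    """CSV of (time, N_p, cumulative absorbed count per interface),
    averaged columns per replica side by side."""
    cols = {"time_ps": traj.times}
    n_p = traj.n_mobile
    for m in range(n_p.shape[1]):
        cols[f"n_p_rep{m}"] = n_p[:, m]
        if traj.n_absorbed is not None:
            for j in range(traj.n_absorbed.shape[2]):
                cols[f"n_abs_if{j}_rep{m}"] = traj.n_absorbed[:, m, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_manifest(path, cfg, seed: int, extra: dict | None = None) -> None:
    """Run manifest: schema version, seed, config hash and package
    version; reruns with an identical manifest reproduce outputs bitwise
    on the same platform."""
    from . import __version__
    from .config import SCHEMA_VERSION
    doc = {
        "schema": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": int(seed),
        "config_hash": cfg.content_hash(),
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
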