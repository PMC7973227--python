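"""Trajectory I/O: the bead extended-XYZ dialect and columnar CSV.

The native on-disk format is a human-readable extended-XYZ variant in which
each snapshot is one XYZ block and every line carries the atom id and bead
index, so ring membership is explicit::

    8
    P=4 n_atoms=2 time_index=0 timestep=2.0 length_unit=angstrom beta=1.0 hbar=1.0 box="14.926 14.926 14.926"
    O 0 0 0.1000 0.0000 0.0000
    O 0 1 ...
    ...
    H 1 3 ...

The comment line holds the configuration as key=value pairs; ``box`` is
optional.  Coordinates are written with 17 significant digits so that a
write/read round trip reproduces them to better than 1e-12.
"""

from __future__ import annotations

import shlex
from pathlib import Path

import numpy as np
import pandas as pd

from .core import RingPolymerFrame, SystemConfig, Trajectory

__all__ = ["read_trajectory", "write_trajectory"]

_REQUIRED_KEYS = ("P", "timestep", "length_unit")


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; message names the offending frame/atom."""


def _parse_header(line: str, lineno: int) -> dict:
    try:
        pairs = dict(tok.split("=", 1) for tok in shlex.split(line))
    except ValueError as exc:
        raise TrajectoryParseError(f"line {lineno}: malformed header: {line!r}") from exc
    for key in _REQUIRED_KEYS:
        if key not in pairs:
            raise TrajectoryParseError(f"line {lineno}: header missing '{key}='")
    return pairs


def _config_from_header(pairs: dict) -> SystemConfig:
    box = None
    if "box" in pairs:
        box = tuple(float(x) for x in pairs["box"].split())
    return SystemConfig(
        n_beads=int(pairs["P"]),
        timestep=float(pairs["timestep"]),
        length_unit=pairs["length_unit"],
        inverse_temperature=float(pairs.get("beta", 1.0)),
        hbar=float(pairs.get("hbar", 1.0)),
        box=box,
    )


def write_trajectory(traj: Trajectory, path: str | Path, format: str = "xyz") -> None:
    """Write a trajectory in the bead extended-XYZ dialect or as columnar CSV."""
    path = Path(path)
    if format == "csv":
        _write_csv(traj, path)
        return
    if format != "xyz":
        raise ValueError(f"unknown format {format!r}")
    cfg = traj.config
    atom_ids = traj.atom_ids
    header_tail = (
        f"timestep={cfg.timestep!r} length_unit={cfg.length_unit} "
        f"beta={cfg.inverse_temperature!r} hbar={cfg.hbar!r}"
    )
    if cfg.box is not None:
        header_tail += ' box="%r %r %r"' % cfg.box
    lines: list[str] = []
    for t in range(traj.n_snapshots):
        lines.append(str(len(atom_ids) * cfg.n_beads))
        lines.append(
            f"P={cfg.n_beads} n_atoms={len(atom_ids)} time_index={t} {header_tail}"
        )
        for a in atom_ids:
            frame = traj.frame(a, t)
            for k, (x, y, z) in enumerate(frame.beads):
                lines.append(
                    f"{frame.atom_type} {a} {k} {x:.17g} {y:.17g} {z:.17g}"
                )
    path.write_text("\n".join(lines) + "\n")


def read_trajectory(path: str | Path, format: str = "xyz") -> Trajectory:
    """Read a trajectory file; validates bead counts and time contiguity.

    Raises :class:`TrajectoryParseError` naming the frame and atom on a wrong
    bead count or non-numeric coordinate, and on a missing unit label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv(path)
    if format != "xyz":
        raise ValueError(f"unknown format {format!r}")

    raw = path.read_text().splitlines()
    config: SystemConfig | None = None
    per_atom: dict[int, list[RingPolymerFrame]] = {}
    i = 0
    while i < len(raw):
        if not raw[i].strip():
            i += 1
            continue
        try:
            n_rows = int(raw[i].strip())
        except ValueError as exc:
            raise TrajectoryParseError(
                f"line {i + 1}: expected row count, got {raw[i]!r}"
            ) from exc
        pairs = _parse_header(raw[i + 1], i + 2)
        frame_cfg = _config_from_header(pairs)
        if config is None:
            config = frame_cfg
        elif frame_cfg != config:
            raise TrajectoryParseError(f"line {i + 2}: header changes mid-file")
        t = int(pairs.get("time_index", len(next(iter(per_atom.values()), []))))
        block = raw[i + 2 : i + 2 + n_rows]
        if len(block) < n_rows:
            raise TrajectoryParseError(f"frame {t}: truncated block")
        buckets: dict[int, tuple[str, list[tuple[int, np.ndarray]]]] = {}
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) != 6:
                raise TrajectoryParseError(
                    f"frame {t}, line {i + 3 + j}: expected "
                    f"'type atom_id bead_index x y z', got {line!r}"
                )
            atype, aid_s, k_s = parts[:3]
            try:
                aid, k = int(aid_s), int(k_s)
                xyz = np.array([float(v) for v in parts[3:]])
            except ValueError as exc:
                raise TrajectoryParseError(
                    f"frame {t}, atom {aid_s}: non-numeric field in {line!r}"
                ) from exc
            buckets.setdefault(aid, (atype, []))[1].append((k, xyz))
        for aid, (atype, rows) in buckets.items():
            if len(rows) != config.n_beads:
                raise TrajectoryParseError(
                    f"frame {t}, atom {aid}: {len(rows)} beads, expected "
                    f"{config.n_beads}"
                )
            rows.sort(key=lambda r: r[0])
            if [k for k, _ in rows] != list(range(config.n_beads)):
                raise TrajectoryParseError(
                    f"frame {t}, atom {aid}: bead indices not 0..{config.n_beads - 1}"
                )
            per_atom.setdefault(aid, []).append(
                RingPolymerFrame(
                    atom_id=aid,
                    atom_type=atype,
                    time_index=t,
                    beads=np.array([xyz for _, xyz in rows]),
                )
            )
        i += 2 + n_rows
    if config is None:
        raise TrajectoryParseError(f"{path}: empty trajectory file")
    return Trajectory(config=config, frames=per_atom)


def _write_csv(traj: Trajectory, path: Path) -> None:
    cfg = traj.config
    rows = []
    for frame in traj.iter_frames():
        for k, (x, y, z) in enumerate(frame.beads):
            rows.append(
                (frame.time_index, frame.atom_id, frame.atom_type, k, x, y, z)
            )
    df = pd.DataFrame(
        rows, columns=["time_index", "atom_id", "atom_type", "bead_index", "x", "y", "z"]
    )
    header = (
        f"# P={cfg.n_beads} timestep={cfg.timestep!r} length_unit={cfg.length_unit} "
        f"beta={cfg.inverse_temperature!r} hbar={cfg.hbar!r}"
    )
    if cfg.box is not None:
        header += ' box="%r %r %r"' % cfg.box
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_csv(path: Path) -> Trajectory:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise TrajectoryParseError(f"{path}: missing '# P=... length_unit=...' header")
        pairs = _parse_header(first.lstrip("# ").strip(), 1)
        config = _config_from_header(pairs)
        df = pd.read_csv(fh)
    per_atom: dict[int, list[RingPolymerFrame]] = {}
    for (t, aid), group in df.groupby(["time_index", "atom_id"], sort=True):
        group = group.sort_values("bead_index")
        if len(group) != config.n_beads:
            raise TrajectoryParseError(
                f"frame {t}, atom {aid}: {len(group)} beads, expected {config.n_beads}"
            )
        per_atom.setdefault(int(aid), []).append(
            RingPolymerFrame(
                atom_id=int(aid),
                atom_type=str(group["atom_type"].iloc[0]),
                time_index=int(t),
                beads=group[["x", "y", "z"]].to_numpy(dtype=float),
            )
        )
    return Trajectory(config=config, frames=per_atom)
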