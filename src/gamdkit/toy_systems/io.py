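"""Multi-model PDB and XYZ trajectory I/O.

Deliberately minimal dialects: PDB v3.3 fixed columns with only
ATOM/HETATM/MODEL/ENDMDL/TER consumed (occupancy/B-factor written as
1.00/0.00), and plain XYZ with an optional ``timestep=<ps>`` token in the
comment line.  Serial numbers and residue ids are 1-based on file, 0-based
in memory.
"""

from __future__ import annotations

import os
import re

import numpy as np

from gamdkit.toy_systems.trajectory import (
    ParticleLabels,
    TrajectoryEnsemble,
    mass_for_element,
)


class TrajectoryFormatError(ValueError):
    """Raised for unparseable or internally inconsistent trajectory files."""


_TWO_LETTER_ELEMENTS = {
    "NA", "MG", "CL", "CA", "MN", "FE", "CO", "NI", "CU", "ZN", "BR", "SE",
}

_TIMESTEP_RE = re.compile(r"timestep\s*=\s*([0-9.eE+-]+)")


def infer_element(raw_name: str) -> str:
    """Element from a 4-character PDB atom-name field.

    A name beginning in column 13 (no leading blank) is elemental-symbol
    aligned, so a leading two-letter symbol like ``MG`` is honoured; names
    starting in column 14 (e.g. `` CA `` for C-alpha) are one-letter.
    """
    two_letter_aligned = len(raw_name) == 4 and raw_name[0] not in (" ", "")
    letters = "".join(c for c in raw_name if c.isalpha())
    if not letters:
        raise TrajectoryFormatError(f"cannot infer element from atom name {raw_name!r}")
    if two_letter_aligned and letters[:2].upper() in _TWO_LETTER_ELEMENTS:
        return letters[:2].upper()
    return letters[0].upper()


# ---------------------------------------------------------------------------
# PDB


def _format_pdb_name(label: ParticleLabels) -> str:
    name = label.name[:4]
    if len(name) < 4 and len(label.element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _write_pdb(traj: TrajectoryEnsemble, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("REMARK   generated by gamdkit\n")
        fh.write(f"REMARK   timestep= {traj.timestep:g} ps\n")
        for f in range(traj.n_frames):
            fh.write(f"MODEL {f + 1:>8d}\n")
            for i, label in enumerate(traj.labels):
                x, y, z = traj.coordinates[f, i]
                fh.write(
                    "ATOM  {serial:>5d} {name} {resname:>3s} {chain}{resid:>4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bfac:6.2f}          "
                    "{element:>2s}\n".format(
                        serial=i + 1,
                        name=_format_pdb_name(label),
                        resname=label.resname[:3],
                        chain="A",
                        resid=label.resid + 1,
                        x=x, y=y, z=z,
                        occ=1.00, bfac=0.00,
                        element=label.element[:2].upper(),
                    )
                )
            fh.write("TER\nENDMDL\n")
        fh.write("END\n")


def _read_pdb(path: str) -> TrajectoryEnsemble:
    frames: list[list[tuple[float, float, float]]] = []
    labels: list[ParticleLabels] = []
    current: list[tuple[float, float, float]] | None = None
    first_frame_done = False
    timestep = 1.0
    with open(path) as fh:
        for line in fh:
            record = line[:6]
            if line.startswith("REMARK"):
                m = _TIMESTEP_RE.search(line)
                if m:
                    timestep = float(m.group(1))
            elif record == "MODEL ":
                if current is not None:
                    raise TrajectoryFormatError("nested MODEL records")
                current = []
            elif record == "ENDMDL":
                if current is None:
                    raise TrajectoryFormatError("ENDMDL without MODEL")
                _close_frame(frames, current, labels, first_frame_done)
                first_frame_done = True
                current = None
            elif record in ("ATOM  ", "HETATM"):
                if current is None:  # single-model file without MODEL records
                    current = []
                name_raw = line[12:16]
                resname = line[17:20].strip()
                resid = int(line[22:26]) - 1
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                element = line[76:78].strip() if len(line) >= 78 else ""
                if not element:
                    element = infer_element(name_raw)
                if not first_frame_done:
                    labels.append(
                        ParticleLabels(
                            name=name_raw.strip(),
                            resid=resid,
                            resname=resname,
                            element=element.upper(),
                        )
                    )
                current.append((x, y, z))
            # TER / END / anything else: ignored
    if current:
        _close_frame(frames, current, labels, first_frame_done)
    if not frames:
        raise TrajectoryFormatError(f"no coordinates found in {path}")
    return _assemble(frames, labels, timestep)


def _close_frame(frames, current, labels, first_frame_done) -> None:
    if first_frame_done and len(current) != len(labels):
        raise TrajectoryFormatError(
            f"frame {len(frames) + 1} has {len(current)} atoms, "
            f"expected {len(labels)}"
        )
    frames.append(current)


def _assemble(frames, labels, timestep) -> TrajectoryEnsemble:
    coords = np.array(frames, dtype=float)
    masses = np.array([mass_for_element(lb.element) for lb in labels])
    return TrajectoryEnsemble(
        coordinates=coords, labels=labels, masses=masses, timestep=timestep
    )


# ---------------------------------------------------------------------------
# XYZ


def _write_xyz(traj: TrajectoryEnsemble, path: str) -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_particles}\n")
            fh.write(f"frame {f + 1} timestep={traj.timestep:g}\n")
            for i, label in enumerate(traj.labels):
                x, y, z = traj.coordinates[f, i]
                fh.write(f"{label.element:<2s} {x:16.6f} {y:16.6f} {z:16.6f}\n")


def _read_xyz(path: str) -> TrajectoryEnsemble:
    frames = []
    labels: list[ParticleLabels] = []
    timestep = 1.0
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        frame_no += 1
        try:
            n = int(lines[pos].split()[0])
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"frame {frame_no}: expected atom count, got {lines[pos]!r}"
            ) from exc
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        m = _TIMESTEP_RE.search(comment)
        if m and frame_no == 1:
            timestep = float(m.group(1))
        body = lines[pos + 2 : pos + 2 + n]
        if len(body) < n:
            raise TrajectoryFormatError(f"frame {frame_no}: truncated (wanted {n} atoms)")
        coords = []
        for i, row in enumerate(body):
            parts = row.split()
            if len(parts) < 4:
                raise TrajectoryFormatError(
                    f"frame {frame_no}: malformed atom line {row!r}"
                )
            el = parts[0].upper()
            coords.append(tuple(float(v) for v in parts[1:4]))
            if frame_no == 1:
                labels.append(
                    ParticleLabels(name=parts[0], resid=i, resname="XYZ", element=el)
                )
        if frame_no > 1 and n != len(labels):
            raise TrajectoryFormatError(
                f"frame {frame_no} has {n} atoms, expected {len(labels)}"
            )
        frames.append(coords)
        pos += 2 + n
    if not frames:
        raise TrajectoryFormatError(f"no frames found in {path}")
    return _assemble(frames, labels, timestep)


# ---------------------------------------------------------------------------
# public API


def _resolve_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower().replace("-", "_")
        if fmt in ("pdb", "pdb_multimodel"):
            return "pdb"
        if fmt == "xyz":
            return "xyz"
        raise ValueError(f"unknown trajectory format {fmt!r}")
    ext = os.path.splitext(path)[1].lower()
    if ext == ".pdb":
        return "pdb"
    if ext == ".xyz":
        return "xyz"
    raise ValueError(f"cannot infer format from {path!r}; pass format=")


def read_trajectory(path: str, format: str | None = None) -> TrajectoryEnsemble:
    """Read a multi-model PDB or XYZ trajectory."""
    fmt = _resolve_format(path, format)
    return _read_pdb(path) if fmt == "pdb" else _read_xyz(path)


def write_trajectory(
    traj: TrajectoryEnsemble, path: str, format: str | None = None
) -> None:
    """Write ``traj`` as multi-model PDB (1e-3 A precision) or XYZ (1e-6 A)."""
    fmt = _resolve_format(path, format)
    if fmt == "pdb":
        _write_pdb(traj, path)
    else:
        _write_xyz(traj, path)
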