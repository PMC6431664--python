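"""Reading and writing bilayer coordinate frames and topology sidecars.

Two on-disk forms are supported:

* **GRO** (GROMACS coordinate format, positions in nm), through
  MDAnalysis.  A file may contain several concatenated frame blocks;
  blocks are split on the atom-count header and each is handed to the
  MDAnalysis GRO reader.  GRO does not carry per-frame times reliably,
  so times are taken from the block title when it contains ``t= <ps>``
  and default to the block index (ps) otherwise.

* A minimal **multi-frame XYZ dialect** with explicit box, time, species
  and molecule ids per atom, paired with a JSON sidecar topology
  (:class:`~memprobe.bilayer_analysis.TopologyMap`).  One line per atom::

      <species> <mol_id> <atom_name> <x> <y> <z>

  preceded by an atom count line and a ``t=<ps> box=<Lx> <Ly> <Lz>``
  comment line, all coordinates in nm.
"""

from __future__ import annotations

import json
import re
import tempfile
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .bilayer_analysis import BilayerFrame, TopologyMap, Trajectory
from .errors import SchemaError

__all__ = [
    "read_gro",
    "write_gro",
    "read_frames_xyz",
    "write_frames_xyz",
    "read_topology_json",
    "write_topology_json",
]

_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eE]+)")
_A_PER_NM = 10.0


# ---------------------------------------------------------------------------
# GRO via MDAnalysis
# ---------------------------------------------------------------------------

def _frame_from_universe(u: mda.Universe, time_ps: float) -> BilayerFrame:
    dims = u.dimensions
    box_nm = np.asarray(dims[:3], dtype=float) / _A_PER_NM
    return BilayerFrame(
        coords=u.atoms.positions.astype(float) / _A_PER_NM,
        box=box_nm,
        atom_names=np.asarray(u.atoms.names, dtype=object),
        species=np.asarray(u.atoms.resnames, dtype=object),
        mol_ids=np.asarray(u.atoms.resids, dtype=int),
        time_ps=time_ps,
    )


def _split_gro_blocks(text: str) -> list[str]:
    lines = text.splitlines()
    blocks = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i + 1].strip())
        except (IndexError, ValueError) as exc:
            raise SchemaError(f"malformed GRO block near line {i + 1}") from exc
        end = i + 2 + n + 1  # title, count, atoms, box
        if end > len(lines):
            raise SchemaError("truncated GRO block")
        blocks.append("\n".join(lines[i:end]) + "\n")
        i = end
    if not blocks:
        raise SchemaError("no GRO frames found")
    return blocks


def read_gro(path: str | Path) -> Trajectory:
    """Read one or more concatenated GRO frame blocks into a trajectory."""
    text = Path(path).read_text()
    frames = []
    for k, block in enumerate(_split_gro_blocks(text)):
        m = _TIME_RE.search(block.splitlines()[0])
        time_ps = float(m.group(1)) if m else float(k)
        with tempfile.NamedTemporaryFile("w", suffix=".gro", delete=False) as fh:
            fh.write(block)
            tmp = fh.name
        try:
            with warnings.catch_warnings():
                # bead names are not elements; mass guessing is irrelevant here
                warnings.simplefilter("ignore")
                u = mda.Universe(tmp)
            frames.append(_frame_from_universe(u, time_ps))
        finally:
            Path(tmp).unlink(missing_ok=True)
    return Trajectory(frames=tuple(frames))


def write_gro(path: str | Path, traj: Trajectory | Iterable[BilayerFrame]) -> None:
    """Write frames as concatenated GRO blocks (positions in nm)."""
    frames = traj.frames if isinstance(traj, Trajectory) else tuple(traj)
    chunks = []
    for frame in frames:
        n = frame.n_atoms
        resids = np.asarray(frame.mol_ids, dtype=int)
        # remap molecule ids into contiguous residue indices for MDAnalysis
        _, resindex = np.unique(resids, return_inverse=True)
        n_res = int(resindex.max()) + 1
        u = mda.Universe.empty(
            n, n_residues=n_res, atom_resindex=resindex, trajectory=True
        )
        u.add_TopologyAttr("names", [str(x) for x in frame.atom_names])
        res_species = [""] * n_res
        res_ids = [0] * n_res
        for ri, sp, mid in zip(resindex, frame.species, resids):
            res_species[ri] = str(sp)
            res_ids[ri] = int(mid)
        u.add_TopologyAttr("resnames", res_species)
        u.add_TopologyAttr("resids", res_ids)
        u.atoms.positions = frame.coords * _A_PER_NM
        u.dimensions = [*(frame.box * _A_PER_NM), 90.0, 90.0, 90.0]
        with tempfile.NamedTemporaryFile("r+", suffix=".gro", delete=False) as fh:
            tmp = fh.name
        try:
            u.atoms.write(tmp)
            block = Path(tmp).read_text()
        finally:
            Path(tmp).unlink(missing_ok=True)
        lines = block.splitlines()
        lines[0] = f"memprobe frame t= {frame.time_ps:.3f} ps"
        chunks.append("\n".join(lines) + "\n")
    Path(path).write_text("".join(chunks))


# ---------------------------------------------------------------------------
# XYZ dialect
# ---------------------------------------------------------------------------

def write_frames_xyz(path: str | Path, traj: Trajectory | Iterable[BilayerFrame]) -> None:
    frames = traj.frames if isinstance(traj, Trajectory) else tuple(traj)
    out = []
    for frame in frames:
        out.append(f"{frame.n_atoms}")
        bx, by, bz = frame.box
        out.append(f"t={frame.time_ps:.6g} box={bx:.6f} {by:.6f} {bz:.6f}")
        for sp, mid, name, (x, y, z) in zip(
            frame.species, frame.mol_ids, frame.atom_names, frame.coords
        ):
            out.append(f"{sp} {mid} {name} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


def read_frames_xyz(path: str | Path) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise SchemaError(f"expected atom count at line {i + 1}") from exc
        header = lines[i + 1]
        m = _TIME_RE.search(header)
        bm = re.search(r"box\s*=\s*([-\d.eE]+)\s+([-\d.eE]+)\s+([-\d.eE]+)", header)
        if m is None or bm is None:
            raise SchemaError(f"malformed frame header at line {i + 2}")
        rows = lines[i + 2: i + 2 + n]
        if len(rows) < n:
            raise SchemaError("truncated frame")
        species, mids, names, coords = [], [], [], []
        for row in rows:
            parts = row.split()
            if len(parts) != 6:
                raise SchemaError(f"bad atom line: {row!r}")
            species.append(parts[0])
            mids.append(int(parts[1]))
            names.append(parts[2])
            coords.append([float(parts[3]), float(parts[4]), float(parts[5])])
        frames.append(BilayerFrame(
            coords=np.asarray(coords),
            box=np.asarray([float(g) for g in bm.groups()]),
            atom_names=np.asarray(names, dtype=object),
            species=np.asarray(species, dtype=object),
            mol_ids=np.asarray(mids, dtype=int),
            time_ps=float(m.group(1)),
        ))
        i += 2 + n
    if not frames:
        raise SchemaError("no frames found")
    return Trajectory(frames=tuple(frames))


# ---------------------------------------------------------------------------
# topology sidecar
# ---------------------------------------------------------------------------

def write_topology_json(path: str | Path, topo: TopologyMap) -> None:
    Path(path).write_text(json.dumps(topo.to_dict(), indent=2) + "\n")


def read_topology_json(path: str | Path) -> TopologyMap:
    return TopologyMap.from_dict(json.loads(Path(path).read_text()))
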