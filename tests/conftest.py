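"""Shared fixtures: minimal hand-built bilayer frames and topologies."""

from __future__ import annotations

import numpy as np
import pytest

from memprobe.bilayer_analysis import (
    BilayerFrame,
    SpeciesRoles,
    TopologyMap,
    Trajectory,
)


def chain_frame(chains: list[np.ndarray], box=(10.0, 10.0, 10.0),
                species: str = "LIP", prefix: str = "C",
                time_ps: float = 0.0) -> BilayerFrame:
    """Frame holding bare carbon chains, one molecule per chain."""
    names, specs, mids, coords = [], [], [], []
    for mid, chain in enumerate(chains, start=1):
        for ci, pt in enumerate(chain, start=1):
            names.append(f"{prefix}{ci}")
            specs.append(species)
            mids.append(mid)
            coords.append(pt)
    return BilayerFrame(
        coords=np.asarray(coords, dtype=float),
        box=np.asarray(box, dtype=float),
        atom_names=np.asarray(names, dtype=object),
        species=np.asarray(specs, dtype=object),
        mol_ids=np.asarray(mids, dtype=int),
        time_ps=time_ps,
    )


def chain_topology(n_carbons: int, chain_label: str = "palmitoyl") -> TopologyMap:
    return TopologyMap(species={
        "LIP": SpeciesRoles(
            role="lipid",
            chains={chain_label: tuple(f"C{i}" for i in range(1, n_carbons + 1))},
            phosphorus="P",
        )
    })


@pytest.fixture
def p_plane_frame() -> tuple[BilayerFrame, TopologyMap]:
    """Four one-atom 'lipids': P atoms at z = center +/- 1.9 nm."""
    z_mid = 5.0
    coords, names, specs, mids = [], [], [], []
    for mid, (x, dz) in enumerate(
        [(2.0, 1.9), (4.0, 1.9), (2.0, -1.9), (4.0, -1.9)], start=1
    ):
        coords.append([x, 3.0, z_mid + dz])
        names.append("P")
        specs.append("LIP")
        mids.append(mid)
    frame = BilayerFrame(
        coords=np.asarray(coords), box=np.asarray([8.0, 8.0, 10.0]),
        atom_names=np.asarray(names, dtype=object),
        species=np.asarray(specs, dtype=object),
        mol_ids=np.asarray(mids, dtype=int),
    )
    topo = TopologyMap(species={"LIP": SpeciesRoles(role="lipid", phosphorus="P")})
    return frame, topo


def single_frame_traj(frame: BilayerFrame) -> Trajectory:
    return Trajectory(frames=(frame,))
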