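"""Structural observables of planar lipid bilayers from coordinate frames.

Works on united-atom (or bead) coordinates of a membrane lying in the xy
plane with the bilayer normal along z, the standard semi-isotropic MD
setup.  Three observables are computed:

* **z-profiles** — time- and leaflet-averaged |z_group - z_bilayerCOM|
  for named atomic groups (lipid phosphorus, glycerol backbone, solute
  polar part, solute terminal methyl, ...), locating where each group
  sits across the membrane.

* **acyl-chain order parameters** — the deuterium order parameter
  S_CD(i) = <(3 cos^2 theta - 1)/2> per chain carbon, with theta the
  C-H bond angle to the bilayer normal.  Hydrogens are reconstructed
  from the carbon backbone assuming tetrahedral geometry (united-atom
  convention); the profile is reported as -S_CD, which is ~0.5 for a
  perfectly ordered all-trans chain along z and 0 for isotropic chains.

* **bilayer thickness** — twice the time-averaged distance of the
  phosphorus atoms from the bilayer center of mass (the P-P distance
  across leaflets).

Molecules are unwrapped across periodic boundaries before any center of
mass is taken, so observables are invariant under re-wrapping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .errors import CompositionError, InputValidationError, SchemaError

__all__ = [
    "SpeciesRoles",
    "TopologyMap",
    "BilayerFrame",
    "Trajectory",
    "OrderProfile",
    "ZProfile",
    "SystemComposition",
    "compose_system",
    "bilayer_center_of_mass",
    "z_profile",
    "order_parameters",
    "bilayer_thickness",
    "equilibration_split",
    "unwrap_molecules",
]

logger = logging.getLogger(__name__)

# half the tetrahedral H-C-H wedge: cos = 1/sqrt(3), sin = sqrt(2/3)
_COS_HALF_TETRA = 1.0 / math.sqrt(3.0)
_SIN_HALF_TETRA = math.sqrt(2.0 / 3.0)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesRoles:
    """Atom roles for one molecular species.

    ``chains`` maps a chain label (e.g. ``"palmitoyl"``) to carbon atom
    names ordered from the carbonyl end to the terminal methyl.  Roles
    that do not apply to a species are left empty/None.
    """

    role: str                                    # "lipid" | "herbicide" | other
    chains: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    phosphorus: str | None = None
    glycerol: tuple[str, ...] = ()
    polar: tuple[str, ...] = ()
    terminal_methyl: str | None = None
    masses: Mapping[str, float] = field(default_factory=dict)

    def mass_of(self, atom_name: str) -> float:
        return float(self.masses.get(atom_name, 1.0))


@dataclass(frozen=True)
class TopologyMap:
    """Species name -> :class:`SpeciesRoles`; resolves group selections."""

    species: Mapping[str, SpeciesRoles]

    def lipid_species(self) -> list[str]:
        return [s for s, r in self.species.items() if r.role == "lipid"]

    def herbicide_species(self) -> list[str]:
        return [s for s, r in self.species.items() if r.role == "herbicide"]

    def group_atoms(self, group: str) -> dict[str, tuple[str, ...]]:
        """Atom names per species for a named group.

        Recognized groups: ``P``, ``glycerol`` (lipid roles);
        ``polar``, ``terminal`` and ``herbicide`` (whole molecule) for
        herbicide species.
        """
        out: dict[str, tuple[str, ...]] = {}
        for sp, roles in self.species.items():
            if group == "P" and roles.phosphorus is not None:
                out[sp] = (roles.phosphorus,)
            elif group == "glycerol" and roles.glycerol:
                out[sp] = tuple(roles.glycerol)
            elif group == "polar" and roles.polar:
                out[sp] = tuple(roles.polar)
            elif group == "terminal" and roles.terminal_methyl is not None:
                out[sp] = (roles.terminal_methyl,)
            elif group == "herbicide" and roles.role == "herbicide":
                names = set(roles.polar)
                for ch in roles.chains.values():
                    names.update(ch)
                if roles.terminal_methyl:
                    names.add(roles.terminal_methyl)
                out[sp] = tuple(sorted(names))
        if not out:
            raise SchemaError(f"group {group!r} resolves to no atoms in the topology")
        return out

    def to_dict(self) -> dict:
        return {
            sp: {
                "role": r.role,
                "chains": {k: list(v) for k, v in r.chains.items()},
                "phosphorus": r.phosphorus,
                "glycerol": list(r.glycerol),
                "polar": list(r.polar),
                "terminal_methyl": r.terminal_methyl,
                "masses": dict(r.masses),
            }
            for sp, r in self.species.items()
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TopologyMap":
        species = {}
        for sp, r in d.items():
            species[sp] = SpeciesRoles(
                role=r.get("role", "lipid"),
                chains={k: tuple(v) for k, v in r.get("chains", {}).items()},
                phosphorus=r.get("phosphorus"),
                glycerol=tuple(r.get("glycerol", ())),
                polar=tuple(r.get("polar", ())),
                terminal_methyl=r.get("terminal_methyl"),
                masses=dict(r.get("masses", {})),
            )
        return cls(species=species)


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

@dataclass
class BilayerFrame:
    """One coordinate snapshot: positions in nm plus a molecule index."""

    coords: np.ndarray            # (N, 3) nm
    box: np.ndarray               # (3,) nm
    atom_names: np.ndarray        # (N,) str
    species: np.ndarray           # (N,) str
    mol_ids: np.ndarray           # (N,) int
    time_ps: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InputValidationError("coords must be (N, 3)")
        n = len(self.coords)
        for arr_name in ("atom_names", "species", "mol_ids"):
            if len(getattr(self, arr_name)) != n:
                raise InputValidationError(f"{arr_name} length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered frames plus the fraction treated as equilibration."""

    frames: tuple[BilayerFrame, ...]
    equilibration_fraction: float = 0.0

    def __post_init__(self) -> None:
        times = [f.time_ps for f in self.frames]
        if any(b < a for a, b in zip(times, times[1:])):
            raise InputValidationError("frame times must be non-decreasing")

    def production_frames(self) -> tuple[BilayerFrame, ...]:
        return equilibration_split(self, self.equilibration_fraction).frames


@dataclass(frozen=True)
class OrderProfile:
    """-S_CD (or |S_CD|) per carbon index with SE over frames."""

    carbon_indices: tuple[int, ...]   # 1-based from the carbonyl carbon
    values: tuple[float, ...]
    se: tuple[float, ...]
    chain_label: str
    convention: str = "minus"         # "minus" -> -S_CD, "abs" -> |S_CD|


@dataclass(frozen=True)
class ZProfile:
    """Mean |z - z_COM| per atomic group with SE over frames."""

    groups: tuple[str, ...]
    mean_abs_z_nm: tuple[float, ...]
    se: tuple[float, ...]


@dataclass(frozen=True)
class SystemComposition:
    n_lipids: int
    n_herbicide: int
    herbicide_species: str
    n_counterions: int
    n_waters: int = 0


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def compose_system(
    n_lipids: int,
    lipid_to_herbicide_ratio: float,
    herbicide_species: str,
    herbicide_net_charge: int,
    n_waters: int = 0,
) -> SystemComposition:
    """Molecule counts for a symmetric bilayer plus solute at a molar ratio.

    Counterions neutralize the solute charge so the net system charge is
    zero.  The lipid count must split into two equal leaflets and the
    solute count must be integral.
    """
    if n_lipids <= 0 or n_lipids % 2 != 0:
        raise CompositionError("n_lipids must be positive and even (two equal leaflets)")
    if lipid_to_herbicide_ratio <= 0:
        raise CompositionError("ratio must be > 0")
    n_herb = n_lipids / lipid_to_herbicide_ratio
    if abs(n_herb - round(n_herb)) > 1e-9:
        raise CompositionError(
            f"{n_lipids} lipids at ratio {lipid_to_herbicide_ratio} gives a "
            f"non-integral herbicide count {n_herb}"
        )
    n_herb = int(round(n_herb))
    return SystemComposition(
        n_lipids=int(n_lipids),
        n_herbicide=n_herb,
        herbicide_species=herbicide_species,
        n_counterions=abs(n_herb * int(herbicide_net_charge)),
        n_waters=int(n_waters),
    )


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def unwrap_molecules(frame: BilayerFrame) -> np.ndarray:
    """Coordinates with each molecule made contiguous across the box.

    Atoms are shifted by whole box vectors so that every atom lies within
    half a box length of its molecule's first atom (minimum-image per
    axis).  Returns a new (N, 3) array; the frame is not modified.
    """
    coords = frame.coords.copy()
    box = frame.box
    for mid in np.unique(frame.mol_ids):
        sel = frame.mol_ids == mid
        ref = coords[sel][0]
        delta = coords[sel] - ref
        coords[sel] = ref + delta - np.round(delta / box) * box
    return coords


def _atom_masses(frame: BilayerFrame, topo: TopologyMap) -> np.ndarray:
    masses = np.ones(frame.n_atoms)
    for i, (sp, name) in enumerate(zip(frame.species, frame.atom_names)):
        roles = topo.species.get(str(sp))
        if roles is not None:
            masses[i] = roles.mass_of(str(name))
    return masses


def bilayer_center_of_mass(
    frame: BilayerFrame,
    selection: np.ndarray,
    masses: np.ndarray | None = None,
    unwrapped: np.ndarray | None = None,
) -> float:
    """Mass-weighted mean z (nm) of the selected atoms, after unwrapping."""
    selection = np.asarray(selection, dtype=bool)
    if not selection.any():
        raise InputValidationError("empty selection for center of mass")
    coords = unwrap_molecules(frame) if unwrapped is None else unwrapped
    m = np.ones(selection.sum()) if masses is None else np.asarray(masses, float)[selection]
    return float(np.average(coords[selection, 2], weights=m))


def _lipid_selection(frame: BilayerFrame, topo: TopologyMap) -> np.ndarray:
    lipids = set(topo.lipid_species())
    return np.isin(frame.species, list(lipids))


def _group_selection(frame: BilayerFrame, topo: TopologyMap, group: str) -> np.ndarray:
    per_species = topo.group_atoms(group)
    sel = np.zeros(frame.n_atoms, dtype=bool)
    for sp, names in per_species.items():
        sel |= (frame.species == sp) & np.isin(frame.atom_names, list(names))
    if not sel.any():
        raise SchemaError(f"group {group!r} matches no atoms in the frame")
    return sel


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def _leaflet_group_distance(
    frame: BilayerFrame, topo: TopologyMap, group: str,
    masses: np.ndarray, unwrapped: np.ndarray, z_com: float,
) -> float:
    """Leaflet-averaged |z_groupCOM - z_com| for one frame.

    The group's atoms are split by leaflet using the z of their parent
    molecule's group COM relative to the bilayer COM; each leaflet
    contributes one mass-weighted group COM.  Molecules sitting exactly
    at the midplane are excluded from that frame (logged).
    """
    sel = _group_selection(frame, topo, group)
    z = unwrapped[:, 2]
    upper_w = lower_w = 0.0
    upper_s = lower_s = 0.0
    n_degenerate = 0
    for mid in np.unique(frame.mol_ids[sel]):
        msel = sel & (frame.mol_ids == mid)
        w = masses[msel]
        zc = float(np.average(z[msel], weights=w))
        dz = zc - z_com
        if dz > 0:
            upper_s += zc * w.sum()
            upper_w += w.sum()
        elif dz < 0:
            lower_s += zc * w.sum()
            lower_w += w.sum()
        else:
            n_degenerate += 1
    if n_degenerate:
        logger.info("excluded %d midplane-degenerate molecule(s) from group %s",
                    n_degenerate, group)
    dists = []
    if upper_w > 0:
        dists.append(abs(upper_s / upper_w - z_com))
    if lower_w > 0:
        dists.append(abs(lower_s / lower_w - z_com))
    if not dists:
        raise InputValidationError(f"group {group!r} empty after leaflet assignment")
    return float(np.mean(dists))


def z_profile(
    traj: Trajectory, topo: TopologyMap, groups: Sequence[str]
) -> ZProfile:
    """Time- and leaflet-averaged distance of each group from the bilayer COM."""
    frames = traj.production_frames()
    per_group: dict[str, list[float]] = {g: [] for g in groups}
    for frame in frames:
        unwrapped = unwrap_molecules(frame)
        masses = _atom_masses(frame, topo)
        lip = _lipid_selection(frame, topo)
        z_com = bilayer_center_of_mass(frame, lip, masses, unwrapped)
        for g in groups:
            per_group[g].append(
                _leaflet_group_distance(frame, topo, g, masses, unwrapped, z_com)
            )
    means, ses = [], []
    for g in groups:
        vals = np.asarray(per_group[g])
        means.append(float(vals.mean()))
        ses.append(float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0)
    return ZProfile(groups=tuple(groups), mean_abs_z_nm=tuple(means), se=tuple(ses))


def _reconstruct_ch_vectors(prev: np.ndarray, curr: np.ndarray, nxt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit C-H vectors of a united-atom methylene, tetrahedral construction.

    The two hydrogens of carbon ``curr`` lie in the plane bisecting the
    backbone wedge: with a = unit(prev-curr), b = unit(next-curr),
    c = -unit(a+b) and n = unit(a x b), the C-H directions are
    c*cos(half) +/- n*sin(half) with the tetrahedral half-angle
    (cos = 1/sqrt(3)).  Inputs may be (..., 3) stacks.
    """
    a = prev - curr
    b = nxt - curr
    a = a / np.linalg.norm(a, axis=-1, keepdims=True)
    b = b / np.linalg.norm(b, axis=-1, keepdims=True)
    c = -(a + b)
    c_norm = np.linalg.norm(c, axis=-1, keepdims=True)
    if np.any(c_norm < 1e-12):
        raise InputValidationError("collinear backbone triplet: C-H frame undefined")
    c = c / c_norm
    n = np.cross(a, b)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    h1 = _COS_HALF_TETRA * c + _SIN_HALF_TETRA * n
    h2 = _COS_HALF_TETRA * c - _SIN_HALF_TETRA * n
    return h1, h2


def order_parameters(
    traj: Trajectory,
    topo: TopologyMap,
    chain: str,
    species: str | None = None,
    convention: Literal["minus", "abs"] = "minus",
) -> OrderProfile:
    """Per-carbon deuterium order parameter profile of an acyl chain.

    For each internal carbon the two C-H vectors are reconstructed from
    the neighboring backbone carbons (tetrahedral united-atom
    construction) and S_CD = <(3 cos^2 theta - 1)/2> is averaged over
    hydrogens, molecules, leaflets and retained frames; the standard
    positive-for-ordered -S_CD is reported (``convention="abs"`` gives
    magnitudes).  Terminal carbons have no defined local frame and are
    omitted.  Carbon indices are 1-based from the carbonyl carbon.
    """
    candidates = [
        (sp, roles) for sp, roles in topo.species.items()
        if chain in roles.chains and (species is None or sp == species)
    ]
    if not candidates:
        raise SchemaError(f"chain {chain!r} not found in topology")
    frames = traj.production_frames()
    if not frames:
        raise InputValidationError("no frames after equilibration split")

    per_frame: list[np.ndarray] = []
    n_carbons = None
    for frame in frames:
        unwrapped = unwrap_molecules(frame)
        chain_cos2: list[np.ndarray] = []
        for sp, roles in candidates:
            names = roles.chains[chain]
            if len(names) < 3:
                raise InputValidationError(
                    f"chain {chain!r} of {sp} has {len(names)} carbons; need >= 3"
                )
            if n_carbons is None:
                n_carbons = len(names)
            sp_sel = frame.species == sp
            mids = np.unique(frame.mol_ids[sp_sel])
            # (n_mol, n_carbons, 3) coordinate stack, ordered along the chain
            stacks = []
            for mid in mids:
                msel = sp_sel & (frame.mol_ids == mid)
                name_to_idx = {
                    str(nm): i for nm, i in zip(frame.atom_names[msel], np.where(msel)[0])
                }
                try:
                    rows = [name_to_idx[nm] for nm in names]
                except KeyError as exc:
                    raise SchemaError(f"atom {exc} of chain {chain!r} missing in molecule {mid}")
                stacks.append(unwrapped[rows])
            if not stacks:
                continue
            xyz = np.stack(stacks)                        # (M, C, 3)
            h1, h2 = _reconstruct_ch_vectors(xyz[:, :-2], xyz[:, 1:-1], xyz[:, 2:])
            cos2 = np.concatenate([h1[..., 2:3] ** 2, h2[..., 2:3] ** 2], axis=-1)
            chain_cos2.append(cos2.reshape(len(xyz), -1, 2))  # (M, C-2, 2H)
        if not chain_cos2:
            raise SchemaError(f"no molecules carry chain {chain!r}")
        allc = np.concatenate(chain_cos2, axis=0)
        scd = 0.5 * (3.0 * allc - 1.0)
        per_frame.append(scd.mean(axis=(0, 2)))            # (C-2,)

    prof = np.stack(per_frame)                              # (F, C-2)
    mean_scd = prof.mean(axis=0)
    se = prof.std(axis=0, ddof=1) / math.sqrt(len(prof)) if len(prof) > 1 else np.zeros_like(mean_scd)
    vals = -mean_scd if convention == "minus" else np.abs(mean_scd)
    indices = tuple(range(2, (n_carbons or 2)))             # internal carbons, 1-based
    return OrderProfile(
        carbon_indices=indices,
        values=tuple(float(v) for v in vals),
        se=tuple(float(s) for s in se),
        chain_label=chain,
        convention=convention,
    )


def bilayer_thickness(traj: Trajectory, topo: TopologyMap) -> tuple[float, float]:
    """Phosphate-to-phosphate bilayer thickness (nm) and its SE over frames.

    Twice the time-averaged |z_P - z_COM|; every frame must have P atoms
    in both leaflets.
    """
    frames = traj.production_frames()
    vals = []
    for frame in frames:
        unwrapped = unwrap_molecules(frame)
        masses = _atom_masses(frame, topo)
        lip = _lipid_selection(frame, topo)
        z_com = bilayer_center_of_mass(frame, lip, masses, unwrapped)
        psel = _group_selection(frame, topo, "P")
        dz = unwrapped[psel, 2] - z_com
        if not ((dz > 0).any() and (dz < 0).any()):
            raise InputValidationError(
                "phosphorus atoms found in only one leaflet: not a bilayer frame"
            )
        vals.append(2.0 * float(np.abs(dz).mean()))
    arr = np.asarray(vals)
    se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return float(arr.mean()), se


def equilibration_split(traj: Trajectory, discard_fraction: float) -> Trajectory:
    """Drop the leading ``discard_fraction`` of the trajectory by time.

    Frames with time >= t_first + fraction*(t_last - t_first) are kept
    (all of them for fraction 0).  An empty result is an error.
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise InputValidationError("discard_fraction must be in [0, 1)")
    frames = traj.frames
    if not frames:
        raise InputValidationError("empty trajectory")
    if discard_fraction == 0.0:
        return Trajectory(frames=frames, equilibration_fraction=0.0)
    t0, t1 = frames[0].time_ps, frames[-1].time_ps
    cut = t0 + discard_fraction * (t1 - t0)
    kept = tuple(f for f in frames if f.time_ps > cut or math.isclose(f.time_ps, cut))
    if not kept:
        raise InputValidationError("no frames survive the equilibration split")
    return Trajectory(frames=kept, equilibration_fraction=0.0)
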