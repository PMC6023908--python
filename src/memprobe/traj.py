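"""Geometric analysis of bilayer + solute trajectories.

Observables follow the standard membrane-simulation conventions: the bilayer
normal is the z-axis, depths are |z| offsets of group centres of mass from the
bilayer centre of mass, hydrogen bonds use a donor–acceptor distance plus
hydrogen–donor–acceptor angle criterion, and solute orientation is measured as
the angle between a body-fixed vector (or aromatic-ring normal) and the
bilayer normal.  Solutes residing in opposite leaflets produce supplementary
angle populations (θ and 180° − θ); ``fold=True`` maps both onto [0, 90°].

Periodic boundaries are handled with the minimal-image convention per axis;
molecules are made whole before centre-of-mass computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .gro import Frame, read_gro

__all__ = [
    "HBondCriteria",
    "Selections",
    "TrajectorySystem",
    "AngleDistribution",
    "assign_leaflets",
    "depth_profile",
    "count_hbonds",
    "hbond_timeseries",
    "bond_vector_angles",
    "ring_normal_angles",
]

# Atomic masses (amu) keyed by the leading element letter of the atom name.
DEFAULT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06,
}


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition (MD community default: 0.35 nm / 30°)."""

    d_max: float = 0.35       # donor–acceptor distance cutoff, nm
    angle_max: float = 30.0   # hydrogen–donor–acceptor angle cutoff, degrees

    def __post_init__(self):
        if self.d_max <= 0 or self.angle_max <= 0:
            raise ValueError("hydrogen-bond criteria must be positive")


@dataclass
class Donor:
    donor: int      # heavy-atom index
    hydrogen: int   # attached hydrogen index
    side: str       # "solute" or "lipid"
    group: str | None = None  # chemical-group class for lipid donors


@dataclass
class Acceptor:
    atom: int
    side: str
    group: str | None = None  # phosphate | ester | glycerol for lipid acceptors


@dataclass
class Selections:
    """Role-tagged atom-index sets resolved against the atom table."""

    lipid: np.ndarray
    solute: np.ndarray
    phosphate: np.ndarray
    ester: np.ndarray
    glycerol: np.ndarray
    headgroup_P: np.ndarray
    donors: list[Donor]
    acceptors: list[Acceptor]
    solute_molecules: list[np.ndarray]       # atom indices per solute molecule
    lipid_molecules: list[np.ndarray]
    vector_pairs: list[tuple[int, int]]      # (from, to) per solute molecule
    ring_triplets: list[tuple[int, int, int]]
    masses: np.ndarray                        # per-atom, amu


def _molecules(atoms: pd.DataFrame, mask: np.ndarray) -> list[np.ndarray]:
    sub = atoms.loc[mask]
    return [g.index.to_numpy() for _, g in sub.groupby(["resname", "resid"], sort=True)]


def atom_masses(atoms: pd.DataFrame, overrides: dict | None = None) -> np.ndarray:
    """Per-atom masses from the leading element letter, with optional overrides
    keyed by exact atom name."""
    overrides = overrides or {}
    out = np.empty(len(atoms))
    for i, name in enumerate(atoms["name"]):
        if name in overrides:
            out[i] = overrides[name]
            continue
        lead = next((ch for ch in name if ch.isalpha()), "")
        try:
            out[i] = DEFAULT_MASSES[lead.upper()]
        except KeyError:
            raise ValueError(f"no mass for atom name {name!r}; add it to the masses map")
    return out


def resolve_selections(atoms: pd.DataFrame, config: dict) -> Selections:
    """Build index sets from a role config.

    Config layout (YAML-friendly)::

        roles:
          lipid:     {resnames: [LIP]}
          solute:    {resnames: [ALK]}
          phosphate: {atoms: [[LIP, OP1], [LIP, OP2], [LIP, P]]}
          ester:     {atoms: [[LIP, OE1], [LIP, OE2]]}
          glycerol:  {atoms: [[LIP, OG]]}
          headgroup_P: {atoms: [[LIP, P]]}
        hbond_donors:    [{residue: ALK, donor: N, hydrogen: HN}]
        hbond_acceptors: [{residue: LIP, atom: OP1, class: phosphate}, ...]
        orient_vector: {residue: ALK, from: C1, to: N}
        ring_triplet:  {residue: ALK, atoms: [C1, C2, C3]}
        masses: {MW: 18.015}          # optional per-atom-name overrides
    """
    roles = config.get("roles", {})

    def by_resnames(names):
        return atoms.index[atoms["resname"].isin(names)].to_numpy()

    def by_pairs(pairs):
        idx = []
        for resname, name in pairs:
            m = (atoms["resname"] == resname) & (atoms["name"] == name)
            idx.append(atoms.index[m].to_numpy())
        return np.sort(np.concatenate(idx)) if idx else np.array([], dtype=int)

    def role_indices(role):
        spec = roles.get(role, {})
        if "resnames" in spec:
            return by_resnames(spec["resnames"])
        if "atoms" in spec:
            return by_pairs(spec["atoms"])
        return np.array([], dtype=int)

    lipid = role_indices("lipid")
    solute = role_indices("solute")
    masses = atom_masses(atoms, config.get("masses"))

    solute_res = set(atoms.loc[solute, "resname"])
    lipid_res = set(atoms.loc[lipid, "resname"])

    donors: list[Donor] = []
    for d in config.get("hbond_donors", []):
        res, dn, hn = d["residue"], d["donor"], d["hydrogen"]
        side = "solute" if res in solute_res else "lipid"
        sub = atoms[atoms["resname"] == res]
        for _, mol in sub.groupby("resid", sort=True):
            di = mol.index[mol["name"] == dn].to_numpy()
            hi = mol.index[mol["name"] == hn].to_numpy()
            if di.size != 1 or hi.size != 1:
                raise ValueError(
                    f"donor {res}:{dn} must have exactly one attached hydrogen {hn} "
                    f"per molecule (residue {mol['resid'].iloc[0]})"
                )
            donors.append(Donor(int(di[0]), int(hi[0]), side, d.get("class")))

    acceptors: list[Acceptor] = []
    for a in config.get("hbond_acceptors", []):
        res, an = a["residue"], a["atom"]
        side = "solute" if res in solute_res else "lipid"
        m = (atoms["resname"] == res) & (atoms["name"] == an)
        for i in atoms.index[m]:
            acceptors.append(Acceptor(int(i), side, a.get("class")))

    solute_mols = _molecules(atoms, atoms.index.isin(solute))
    lipid_mols = _molecules(atoms, atoms.index.isin(lipid))

    vector_pairs = []
    ov = config.get("orient_vector")
    if ov:
        for mol in solute_mols:
            names = atoms.loc[mol, "name"]
            src = mol[names == ov["from"]]
            dst = mol[names == ov["to"]]
            if src.size == 1 and dst.size == 1:
                vector_pairs.append((int(src[0]), int(dst[0])))
            else:
                raise ValueError(f"orientation atoms {ov['from']}->{ov['to']} not unique in a solute")

    ring_triplets = []
    rt = config.get("ring_triplet")
    if rt:
        for mol in solute_mols:
            names = atoms.loc[mol, "name"]
            trip = [mol[names == nm] for nm in rt["atoms"]]
            if any(t.size != 1 for t in trip):
                raise ValueError("ring triplet atoms not unique in a solute")
            ring_triplets.append(tuple(int(t[0]) for t in trip))

    return Selections(
        lipid=lipid,
        solute=solute,
        phosphate=role_indices("phosphate"),
        ester=role_indices("ester"),
        glycerol=role_indices("glycerol"),
        headgroup_P=role_indices("headgroup_P"),
        donors=donors,
        acceptors=acceptors,
        solute_molecules=solute_mols,
        lipid_molecules=lipid_mols,
        vector_pairs=vector_pairs,
        ring_triplets=ring_triplets,
        masses=masses,
    )


@dataclass
class TrajectorySystem:
    """Frames plus role-tagged selections over a fixed atom table."""

    atoms: pd.DataFrame
    frames: list[Frame]
    selections: Selections

    def __post_init__(self):
        n = len(self.atoms)
        if not self.frames:
            raise ValueError("trajectory has no frames")
        for fr in self.frames:
            if fr.coords.shape[0] != n:
                raise ValueError("frame atom count does not match the atom table")
        sel = self.selections
        for role in ("lipid", "solute", "phosphate", "ester", "glycerol", "headgroup_P"):
            arr = getattr(sel, role)
            if arr.size and arr.max() >= n:
                raise ValueError(f"selection {role!r} indexes beyond the atom table")

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def n_solutes(self) -> int:
        return len(self.selections.solute_molecules)

    @classmethod
    def from_files(cls, traj_path, selection_path) -> "TrajectorySystem":
        atoms, frames = read_gro(traj_path)
        with open(selection_path) as fh:
            config = yaml.safe_load(fh)
        return cls(atoms, frames, resolve_selections(atoms, config))


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def _make_whole(coords: np.ndarray, box: np.ndarray, mol: np.ndarray) -> np.ndarray:
    """Shift a molecule's atoms by box vectors so it is contiguous."""
    ref = coords[mol[0]]
    return ref + _min_image(coords[mol] - ref, box)


def _com(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def _bilayer_com_z(frame: Frame, sel: Selections) -> float:
    """Mass-weighted z centre of all lipid atoms, lipids made whole along z."""
    z = frame.coords[:, 2].copy()
    for mol in sel.lipid_molecules:
        ref = z[mol[0]]
        z[mol] = ref + _min_image(z[mol] - ref, frame.box[2])
    m = sel.masses[sel.lipid]
    return float((z[sel.lipid] * m).sum() / m.sum())


def assign_leaflets(frame: Frame, sel: Selections) -> np.ndarray:
    """Label each lipid 'upper'/'lower' by the sign of its P atom's z offset
    from the bilayer centre of mass (minimal image along z)."""
    if sel.headgroup_P.size == 0:
        raise ValueError("selection role 'headgroup_P' is empty")
    com_z = _bilayer_com_z(frame, sel)
    dz = _min_image(frame.coords[sel.headgroup_P, 2] - com_z, frame.box[2])
    labels = np.where(dz >= 0, "upper", "lower")
    if np.all(dz > 0) or np.all(dz < 0):
        warnings.warn("all phosphate atoms on one side of the centre of mass: not a bilayer")
    return labels


def depth_profile(traj: TrajectorySystem) -> pd.DataFrame:
    """Per-frame |z| offsets from the bilayer centre of mass.

    Columns: time_ns, solute_z (mean over solute-molecule COMs), phosphate_z
    and glycerol_z (mean over atoms), all in nm.
    """
    sel = traj.selections
    for role in ("solute", "lipid", "headgroup_P", "glycerol"):
        if getattr(sel, role).size == 0:
            raise ValueError(f"selection role {role!r} is empty")
    rows = []
    for fr in traj.frames:
        lz = fr.box[2]
        com_z = _bilayer_com_z(fr, sel)
        sol_off = []
        for mol in sel.solute_molecules:
            whole = _make_whole(fr.coords, fr.box, mol)
            cz = _com(whole, sel.masses[mol])[2]
            sol_off.append(abs(_min_image(np.array([cz - com_z]), lz)[0]))
        p_off = np.abs(_min_image(fr.coords[sel.headgroup_P, 2] - com_z, lz))
        g_off = np.abs(_min_image(fr.coords[sel.glycerol, 2] - com_z, lz))
        rows.append((fr.time, float(np.mean(sol_off)), float(p_off.mean()), float(g_off.mean())))
    return pd.DataFrame(rows, columns=["time_ns", "solute_z", "phosphate_z", "glycerol_z"])


HBOND_CLASSES = ("phosphate", "ester", "glycerol")


def count_hbonds(
    frame: Frame, sel: Selections, criteria: HBondCriteria = HBondCriteria()
) -> dict[str, int]:
    """Count solute–lipid hydrogen bonds in one frame, keyed by lipid group.

    A bond requires donor–acceptor distance ≤ d_max and an H–D–A angle
    ≤ angle_max (minimal image).  Both directions contribute: solute donors to
    lipid acceptors (classified by the acceptor's group) and lipid donors to
    solute acceptors (classified by the lipid donor's group).
    """
    if not sel.donors or not sel.acceptors:
        raise ValueError("hydrogen-bond donors/acceptors are not configured")
    counts = {c: 0 for c in HBOND_CLASSES}
    cos_min = np.cos(np.radians(criteria.angle_max))
    xyz, box = frame.coords, frame.box
    for don in sel.donors:
        partners = [a for a in sel.acceptors if a.side != don.side]
        if not partners:
            continue
        a_idx = np.array([a.atom for a in partners])
        d_vec = _min_image(xyz[a_idx] - xyz[don.donor], box)
        dist = np.linalg.norm(d_vec, axis=1)
        h_vec = _min_image(xyz[don.hydrogen] - xyz[don.donor], box)
        h_norm = np.linalg.norm(h_vec)
        if h_norm == 0:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (d_vec @ h_vec) / (dist * h_norm)
        hit = (dist <= criteria.d_max) & (dist > 0) & (cosang >= cos_min)
        for k in np.flatnonzero(hit):
            group = partners[k].group if don.side == "solute" else don.group
            if group in counts:
                counts[group] += 1
    return counts


def hbond_timeseries(
    traj: TrajectorySystem,
    criteria: HBondCriteria = HBondCriteria(),
    window: float = 100.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-frame hydrogen-bond counts per solute, plus trailing-window means.

    ``window`` is in ns and selects frames with time ≥ t_end − window for the
    per-class means (the usual "last N ns" summary of a production run).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    times = traj.times
    if window > times[-1] - times[0] + 1e-12:
        window = times[-1] - times[0] or window
    n_sol = max(traj.n_solutes, 1)
    rows = []
    for fr in traj.frames:
        c = count_hbonds(fr, traj.selections, criteria)
        rows.append((fr.time, *(c[k] / n_sol for k in HBOND_CLASSES)))
    df = pd.DataFrame(rows, columns=["time_ns", *HBOND_CLASSES])
    df["total"] = df[list(HBOND_CLASSES)].sum(axis=1)
    tail = df["time_ns"] >= times[-1] - window
    means = {k: float(df.loc[tail, k].mean()) for k in (*HBOND_CLASSES, "total")}
    return df, means


@dataclass
class AngleDistribution:
    """Histogram of orientation angles: uniform bins on [0, 180] (or [0, 90]
    when folded), density in probability per degree."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_samples: int
    n_skipped: int = 0
    samples: np.ndarray | None = None  # raw pooled angles, for sub-bin mode refinement

    def __post_init__(self):
        w = np.diff(self.bin_edges)
        total = float((self.density * w).sum())
        if self.n_samples and abs(total - 1.0) > 1e-9:
            raise ValueError("density must integrate to 1")

    def _refine(self, coarse: float) -> float:
        # local sample mean around the winning bin beats the bin centre
        if self.samples is None:
            return coarse
        bw = float(self.bin_edges[1] - self.bin_edges[0])
        near = self.samples[np.abs(self.samples - coarse) <= bw]
        return float(near.mean()) if near.size else coarse

    @property
    def mode(self) -> float:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return self._refine(float(centers[np.argmax(self.density)]))

    def modes(self, n: int = 2, min_separation: float = 20.0) -> list[float]:
        """Up to ``n`` local maxima, highest first, at least min_separation apart."""
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        order = np.argsort(self.density)[::-1]
        picked: list[float] = []
        for i in order:
            c = float(centers[i])
            if all(abs(c - p) >= min_separation for p in picked):
                picked.append(c)
            if len(picked) == n:
                break
        return [self._refine(c) for c in picked]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_deg": self.bin_edges[:-1],
                "bin_right_deg": self.bin_edges[1:],
                "density": self.density,
            }
        )


def _histogram(samples: np.ndarray, fold: bool, bin_width: float, n_skipped: int) -> AngleDistribution:
    if fold:
        samples = np.minimum(samples, 180.0 - samples)
        top = 90.0
    else:
        top = 180.0
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    hist, _ = np.histogram(samples, bins=edges)
    n = int(hist.sum())
    density = hist / (n * bin_width) if n else hist.astype(float)
    return AngleDistribution(edges, density, n_samples=n, n_skipped=n_skipped, samples=samples)


def _angles_to_z(vectors: np.ndarray) -> tuple[np.ndarray, int]:
    norms = np.linalg.norm(vectors, axis=1)
    ok = norms > 1e-12
    cosang = np.clip(vectors[ok, 2] / norms[ok], -1.0, 1.0)
    return np.degrees(np.arccos(cosang)), int((~ok).sum())


def bond_vector_angles(
    traj: TrajectorySystem,
    fold: bool = False,
    bin_width: float = 2.0,
    skip_ns: float = 0.0,
) -> AngleDistribution:
    """Distribution of angles between a solute bond vector and the bilayer normal.

    Pools every solute in every frame (after an optional equilibration
    discard).  Unfolded distributions keep [0, 180°], so the two leaflets show
    up as supplementary-angle populations.
    """
    if not traj.selections.vector_pairs:
        raise ValueError("no orientation vector pairs configured")
    vecs = []
    for fr in traj.frames:
        if fr.time < skip_ns:
            continue
        for src, dst in traj.selections.vector_pairs:
            vecs.append(_min_image(fr.coords[dst] - fr.coords[src], fr.box))
    angles, skipped = _angles_to_z(np.asarray(vecs))
    return _histogram(angles, fold, bin_width, skipped)


def ring_normal_angles(
    traj: TrajectorySystem,
    fold: bool = False,
    bin_width: float = 2.0,
    skip_ns: float = 0.0,
) -> AngleDistribution:
    """Distribution of angles between each solute's ring-plane normal and the
    bilayer normal; the normal is the cross product of two ring edge vectors.
    Collinear (degenerate) triplets are skipped and counted."""
    if not traj.selections.ring_triplets:
        raise ValueError("no ring triplets configured")
    normals = []
    for fr in traj.frames:
        if fr.time < skip_ns:
            continue
        for a, b, c in traj.selections.ring_triplets:
            e1 = _min_image(fr.coords[b] - fr.coords[a], fr.box)
            e2 = _min_image(fr.coords[c] - fr.coords[a], fr.box)
            normals.append(np.cross(e1, e2))
    angles, skipped = _angles_to_z(np.asarray(normals))
    return _histogram(angles, fold, bin_width, skipped)
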