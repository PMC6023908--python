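"""Ground-truth-known synthetic inputs for every analysis stage.

Each generator emulates the measurement its analysis stage consumes — an ITC
thermogram for a lipid-into-alkaloid titration, replicated sνCH₂ melting
curves, a schematic bilayer + solute trajectory, and a randomized-block
root-length bioassay — and returns a machine-readable truth record alongside.
The trajectory is geometric, not physical: lipids are coarse role-tagged
scaffolds and solutes are rigid point sets, because the downstream observables
(depths, tilt angles, hydrogen-bond geometry) are purely geometric.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict

import numpy as np
import pandas as pd

from .gro import Frame
from .ftir import MeltingCurve, Spectrum, boltzmann
from .itc import (
    InjectionSchedule,
    ITCThermogram,
    concentrations_after_injections,
    eval_partition_model,
    UL_TO_L,
    UCAL_TO_CAL,
)
from .traj import TrajectorySystem, resolve_selections

__all__ = [
    "gen_itc",
    "gen_melting_curve",
    "gen_membrane_traj",
    "gen_bioassay",
    "default_selection_config",
]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------- ITC


def gen_itc(
    K: float = 800.0,
    dH: float = -4000.0,
    schedule: InjectionSchedule | None = None,
    noise_sd: float = 0.0,
    tau: float = 30.0,
    dt: float = 1.0,
    seed: int | None = 0,
) -> tuple[ITCThermogram, InjectionSchedule, dict]:
    """Render a titration thermogram for the single-partition model.

    Per-injection heats are successive differences of the cumulative-heat
    model (with overflow dilution bookkeeping); each becomes an exponential
    pulse (decay ``tau`` s) whose integrated area equals the heat, on a zero
    baseline, plus white noise of ``noise_sd`` µcal/s on the heat flow.
    K in L/mol, dH in cal/mol, noiseless when ``noise_sd`` is 0.
    """
    if K < 0:
        raise ValueError("K must be non-negative")
    schedule = schedule or InjectionSchedule.vp_itc_default()
    if tau >= schedule.spacing / 5:
        raise ValueError("pulse decay tau too long: injections would overlap")
    c_lip, c_sol = concentrations_after_injections(schedule)
    cum_cal = eval_partition_model(K, dH, schedule.cell_volume * UL_TO_L, c_sol, c_lip)
    dh_ucal = np.diff(cum_cal, prepend=0.0) / UCAL_TO_CAL

    n = schedule.n_injections
    t = np.arange(0.0, n * schedule.spacing + dt / 2, dt)
    hf = np.zeros_like(t)
    onset = 2 * dt  # keep the pulse off the shared window boundary
    for i, dh in enumerate(dh_ucal):
        t0 = i * schedule.spacing + onset
        shape = np.where(t >= t0, np.exp(-np.clip(t - t0, 0, None) / tau), 0.0)
        w = (t >= i * schedule.spacing) & (t <= (i + 1) * schedule.spacing)
        area = np.trapezoid(shape[w], t[w])
        hf += (dh / area) * shape
    if noise_sd > 0:
        hf = hf + _rng(seed).normal(0.0, noise_sd, size=hf.size)
    truth = {
        "K": K, "dH": dH, "tau_s": tau, "noise_sd_ucal_per_s": noise_sd,
        "per_injection_heat_ucal": dh_ucal.tolist(),
    }
    return ITCThermogram(t, hf), schedule, truth


# ---------------------------------------------------------------- FTIR


def default_temperature_grid(tm: float) -> np.ndarray:
    """15 temperatures with 1–3 °C steps, finest around the transition."""
    offsets = np.array([-10, -7, -5, -4, -3, -2, -1, 0, 1, 2, 3, 4, 5, 7, 10], dtype=float)
    return tm + offsets


def gen_melting_curve(
    tm: float = 23.69,
    width: float = 0.8,
    nu_gel: float = 2850.5,
    nu_fluid: float = 2853.0,
    temperatures: np.ndarray | None = None,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    spectra: bool = False,
    band_sigma: float = 4.0,
) -> tuple[MeltingCurve, dict, list[Spectrum] | None]:
    """Boltzmann melting curve with replicates and Gaussian noise.

    Defaults mimic a DMPC-like chain-melting transition.  With
    ``spectra=True`` each (temperature, replicate) also yields a Gaussian
    sνCH₂ band on a 2 cm⁻¹ grid, centred at the sigmoid value.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if nu_fluid <= nu_gel:
        raise ValueError("nu_fluid must exceed nu_gel (melting raises the wavenumber)")
    T = default_temperature_grid(tm) if temperatures is None else np.asarray(temperatures, float)
    if T.min() > tm - 3 * width or T.max() < tm + 3 * width:
        import warnings
        warnings.warn("temperature grid does not span Tm ± 3 widths; fit may be poorly anchored")
    rng = _rng(seed)
    temps, nus, reps = [], [], []
    for r in range(n_replicates):
        centre = boltzmann(T, nu_gel, nu_fluid, tm, width)
        noisy = centre + rng.normal(0.0, noise_sd, size=T.size)
        temps.append(T)
        nus.append(noisy)
        reps.append(np.full(T.size, r))
    curve = MeltingCurve(np.concatenate(temps), np.concatenate(nus), np.concatenate(reps))
    truth = {
        "Tm": tm, "width": width, "nu_gel": nu_gel, "nu_fluid": nu_fluid,
        "noise_sd": noise_sd, "n_replicates": n_replicates,
    }
    spectra_out = None
    if spectra:
        grid = np.arange(2830.0, 2880.0 + 1, 2.0)
        spectra_out = []
        for Ti, nui in zip(curve.temperature, curve.peak_wavenumber):
            absorb = np.exp(-0.5 * ((grid - nui) / band_sigma) ** 2)
            spectra_out.append(Spectrum(grid, absorb, Ti))
    return curve, truth, spectra_out


# ---------------------------------------------------------------- trajectory

# Upper-leaflet lipid template: (name, dx, dy, dz) relative to the bilayer
# midplane.  Roles: P + OP* = phosphate, OE* = ester, OG = headgroup glycerol.
_LIPID_TEMPLATE = [
    ("P", 0.00, 0.00, 2.00),
    ("OP1", 0.08, 0.00, 2.08),
    ("OP2", -0.08, 0.00, 2.08),
    ("OG", 0.00, 0.00, 1.50),
    ("OE1", 0.10, 0.00, 1.30),
    ("OE2", -0.10, 0.00, 1.30),
    ("C1", 0.00, 0.00, 0.90),
    ("C2", 0.00, 0.00, 0.50),
]

_RING_RADIUS = 0.14   # nm, aromatic-ring circumradius scale
_BOND_LEN = 0.25      # nm, ring-carbon -> amine-nitrogen vector
_NH_LEN = 0.10        # nm, N-H bond
_HB_DIST = 0.30       # nm, realized donor-acceptor distance (inside the cutoff)


def default_selection_config() -> dict:
    """Role config matching the generator's atom naming."""
    return {
        "roles": {
            "lipid": {"resnames": ["LIP"]},
            "solute": {"resnames": ["ALK"]},
            "phosphate": {"atoms": [["LIP", "P"], ["LIP", "OP1"], ["LIP", "OP2"]]},
            "ester": {"atoms": [["LIP", "OE1"], ["LIP", "OE2"]]},
            "glycerol": {"atoms": [["LIP", "OG"]]},
            "headgroup_P": {"atoms": [["LIP", "P"]]},
        },
        "hbond_donors": [{"residue": "ALK", "donor": "N", "hydrogen": "HN"}],
        "hbond_acceptors": [
            {"residue": "LIP", "atom": "OP1", "class": "phosphate"},
            {"residue": "LIP", "atom": "OP2", "class": "phosphate"},
            {"residue": "LIP", "atom": "OE1", "class": "ester"},
            {"residue": "LIP", "atom": "OE2", "class": "ester"},
            {"residue": "LIP", "atom": "OG", "class": "glycerol"},
        ],
        "orient_vector": {"residue": "ALK", "from": "C1", "to": "N"},
        "ring_triplet": {"residue": "ALK", "atoms": ["C1", "C2", "C3"]},
    }


def _solute_atoms(centre_xy, z_com, tilt_deg, ring_tilt_deg, upper: bool, masses):
    """Rigid 5-atom pseudo-solute: ring triplet C1-C3 with a plane normal at
    ``ring_tilt_deg`` from z, and a C1->N bond at ``tilt_deg`` from z (both
    mirrored for the lower leaflet).  Positioned so the COM sits at z_com."""
    a = math.radians(tilt_deg)
    b = math.radians(ring_tilt_deg)
    sz = 1.0 if upper else -1.0
    bond = np.array([math.sin(a), 0.0, sz * math.cos(a)])
    normal = np.array([math.sin(b), 0.0, sz * math.cos(b)])
    # orthonormal basis of the ring plane
    helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    pts = {}
    for k, name in enumerate(("C1", "C2", "C3")):
        ang = 2 * math.pi * k / 3
        pts[name] = _RING_RADIUS * (math.cos(ang) * u + math.sin(ang) * v)
    pts["N"] = pts["C1"] + _BOND_LEN * bond
    pts["HN"] = pts["N"] + _NH_LEN * bond
    names = ["C1", "C2", "C3", "N", "HN"]
    xyz = np.array([pts[n] for n in names])
    m = np.array([masses[n[0]] for n in names])
    com = (xyz * m[:, None]).sum(axis=0) / m.sum()
    xyz -= com
    xyz[:, 0] += centre_xy[0]
    xyz[:, 1] += centre_xy[1]
    xyz[:, 2] += z_com
    return names, xyz


def gen_membrane_traj(
    n_lipids: int = 128,
    n_solutes: int = 32,
    depth: float = 1.2,
    bond_tilt_deg: float = 35.0,
    ring_tilt_deg: float = 90.0,
    hbond_schedule: list[int] | None = None,
    n_frames: int = 5,
    frame_dt_ns: float = 10.0,
    box_z: float = 8.0,
    seed: int | None = 0,
) -> tuple[TrajectorySystem, dict, dict]:
    """Schematic bilayer + solute trajectory with prescribed observables.

    Two leaflets of role-tagged pseudo-lipids on a square lattice; rigid
    pseudo-solutes split evenly between leaflets at COM depth ``depth`` (nm,
    |z| from the bilayer COM), with the C1→N bond at ``bond_tilt_deg`` and the
    ring-plane normal at ``ring_tilt_deg`` from the bilayer normal (mirrored
    in the lower leaflet, hence supplementary unfolded angles).

    ``hbond_schedule`` prescribes per-frame hydrogen bonds per solute (0–4):
    each bond is realized by moving one partner-lipid phosphate oxygen to
    0.30 nm from the solute's N–H donor along the N→H direction; every solute
    owns four partner lipids in its own leaflet (the 4:1 lipid:solute ratio).
    Defaults follow the simulated systems the analyses are aimed at: 128
    lipids, 32 solutes, ~10 ns between analysis frames.

    Returns (system, selection_config, truth).
    """
    if n_lipids % 2 or n_solutes % 2:
        raise ValueError("n_lipids and n_solutes must be even (two leaflets)")
    if hbond_schedule is not None:
        if max(hbond_schedule) > 4:
            raise ValueError("at most 4 hydrogen bonds per solute (4 partner lipids)")
        n_frames = len(hbond_schedule)
    from .traj import DEFAULT_MASSES

    per_leaf = n_lipids // 2
    side = math.ceil(math.sqrt(per_leaf))
    spacing = 0.8
    box_xy = side * spacing
    box = np.array([box_xy, box_xy, box_z])
    z_mid = box_z / 2
    if depth + 0.5 > box_z / 2:
        raise ValueError("requested solute depth does not fit inside the box")

    names, resnames, resids, coords0 = [], [], [], []
    resid = 0
    lipid_leaflet = []
    for leaf, sign in (("upper", 1.0), ("lower", -1.0)):
        for k in range(per_leaf):
            resid += 1
            x = (k % side + 0.5) * spacing
            y = (k // side + 0.5) * spacing
            for nm, dx, dy, dz in _LIPID_TEMPLATE:
                names.append(nm)
                resnames.append("LIP")
                resids.append(resid)
                coords0.append((x + dx, y + dy, z_mid + sign * dz))
            lipid_leaflet.append(leaf)

    sol_per_leaf = n_solutes // 2
    sside = math.ceil(math.sqrt(sol_per_leaf))
    sspacing = box_xy / sside
    solute_leaflet = []
    for leaf, sign in (("upper", 1.0), ("lower", -1.0)):
        for k in range(sol_per_leaf):
            resid += 1
            cx = (k % sside + 0.5) * sspacing + 0.4 * spacing
            cy = (k // sside + 0.5) * sspacing + 0.4 * spacing
            nm_list, xyz = _solute_atoms(
                (cx % box_xy, cy % box_xy), z_mid + sign * depth,
                bond_tilt_deg, ring_tilt_deg, upper=sign > 0, masses=DEFAULT_MASSES,
            )
            for nm, p in zip(nm_list, xyz):
                names.append(nm)
                resnames.append("ALK")
                resids.append(resid)
                coords0.append(tuple(p))
            solute_leaflet.append(leaf)

    atoms = pd.DataFrame({"resid": resids, "resname": resnames, "name": names})
    coords0 = np.array(coords0)
    config = default_selection_config()
    sel = resolve_selections(atoms, config)

    # partner lipids per solute: 4 distinct lipids from the solute's leaflet
    lipid_mol_by_leaf = {"upper": [], "lower": []}
    for mol, leaf in zip(sel.lipid_molecules, lipid_leaflet):
        lipid_mol_by_leaf[leaf].append(mol)
    partners = []
    counters = {"upper": 0, "lower": 0}
    for leaf in solute_leaflet:
        pool = lipid_mol_by_leaf[leaf]
        start = counters[leaf]
        partners.append([pool[(start + j) % len(pool)] for j in range(4)])
        counters[leaf] += 4

    name_arr = atoms["name"].to_numpy()
    frames = []
    for fi in range(n_frames):
        xyz = coords0.copy()
        if hbond_schedule is not None:
            k_bonds = hbond_schedule[fi]
            for si, mol in enumerate(sel.solute_molecules):
                d_idx = mol[name_arr[mol] == "N"][0]
                h_idx = mol[name_arr[mol] == "HN"][0]
                direction = xyz[h_idx] - xyz[d_idx]
                direction /= np.linalg.norm(direction)
                for j in range(k_bonds):
                    lip = partners[si][j]
                    op1 = lip[name_arr[lip] == "OP1"][0]
                    xyz[op1] = xyz[d_idx] + _HB_DIST * direction
        if hbond_schedule is not None:
            # the schedule is a guarantee: reject geometries where a donor
            # strays within the cutoff of an acceptor it was not paired with
            acc_idx = np.array([a.atom for a in sel.acceptors])
            for mol in sel.solute_molecules:
                d_idx = mol[name_arr[mol] == "N"][0]
                d = np.linalg.norm(xyz[acc_idx] - xyz[d_idx], axis=1)
                if int(np.sum(d <= 0.35)) != hbond_schedule[fi]:
                    raise ValueError(
                        "accidental donor-acceptor contact at this depth; "
                        "choose a depth whose donors clear all lipid oxygens"
                    )
        frames.append(Frame(xyz, box.copy(), time=fi * frame_dt_ns))

    system = TrajectorySystem(atoms, frames, sel)
    truth = {
        "depth": depth,
        "bond_tilt_deg": bond_tilt_deg,
        "ring_tilt_deg": ring_tilt_deg,
        "lipid_leaflet": lipid_leaflet,
        "solute_leaflet": solute_leaflet,
        "hbond_schedule": hbond_schedule,
        "n_frames": n_frames,
    }
    return system, config, truth


# ---------------------------------------------------------------- bioassay

# Default treatment effects: fractional root-growth reduction of the kind the
# assays are designed to detect (strong for gramine, mild for hordenine).
DEFAULT_EFFECTS = {
    "Control": 0.0,
    "Hordenine 0.5 mM": 0.212,
    "Hordenine 1 mM": 0.275,
    "Gramine 0.5 mM": 0.629,
    "Gramine 1 mM": 0.726,
    "Gramine 0.5 mM + Hordenine 0.5 mM": 0.645,
}


def gen_bioassay(
    effects: dict[str, float] | None = None,
    control_mean: float = 22.6,
    control: str = "Control",
    n_blocks: int = 7,
    controls_per_block: int = 2,
    block_sd: float = 1.0,
    noise_sd: float = 1.5,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, dict]:
    """Randomized-block root-length table with known treatment effects.

    Per-dish mean root length = control_mean × (1 − effect) + block effect +
    Gaussian noise, truncated at 0 mm.  The control appears
    ``controls_per_block`` times per block (the 5 treatments + 2 controls
    layout); every other treatment once per block.
    """
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    effects = DEFAULT_EFFECTS if effects is None else effects
    if control not in effects:
        raise ValueError(f"effects must include the control label {control!r}")
    if len(effects) < 2:
        raise ValueError("need at least 2 treatments")
    rng = _rng(seed)
    block_eff = rng.normal(0.0, block_sd, size=n_blocks)
    rows = []
    dish = 0
    for b in range(n_blocks):
        for trt, eff in effects.items():
            reps = controls_per_block if trt == control else 1
            for _ in range(reps):
                dish += 1
                val = control_mean * (1.0 - eff) + block_eff[b] + rng.normal(0.0, noise_sd)
                rows.append((trt, f"B{b + 1}", dish, max(val, 0.0)))
    table = pd.DataFrame(rows, columns=["treatment", "block", "dish", "root_length_mm"])
    truth = {
        "effects": dict(effects),
        "control_mean": control_mean,
        "block_sd": block_sd,
        "noise_sd": noise_sd,
        "n_blocks": n_blocks,
    }
    return table, truth
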