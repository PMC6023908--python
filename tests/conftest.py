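import numpy as np
import pandas as pd
import pytest

from memprobe.gro import Frame
from memprobe.traj import TrajectorySystem, resolve_selections


def build_system(atom_rows, coords, box=(6.0, 6.0, 8.0), config_extra=None, times=None):
    """Assemble a TrajectorySystem from explicit atom rows and coordinates.

    ``atom_rows`` is a list of (resid, resname, name); ``coords`` one (N, 3)
    array or a list of them (one per frame).  The selection config tags LIP
    residues as lipids (P/OP* phosphate, OE* ester, OG glycerol) and ALK
    residues as solutes with an N-HN donor, like the synthetic generator.
    """
    atoms = pd.DataFrame(atom_rows, columns=["resid", "resname", "name"])
    config = {
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
    }
    if config_extra:
        config.update(config_extra)
    if isinstance(coords, np.ndarray) and coords.ndim == 2:
        coords = [coords]
    times = times or list(range(len(coords)))
    frames = [Frame(np.asarray(c, float), np.asarray(box, float), time=t)
              for c, t in zip(coords, times)]
    return TrajectorySystem(atoms, frames, resolve_selections(atoms, config))


def brute_force_hbonds(frame, sel, d_max=0.35, angle_max=30.0):
    """Independent O(N²) hydrogen-bond count, classified like count_hbonds."""
    counts = {"phosphate": 0, "ester": 0, "glycerol": 0}
    box = frame.box

    def mi(d):
        return d - box * np.round(d / box)

    for don in sel.donors:
        for acc in sel.acceptors:
            if acc.side == don.side:
                continue
            dvec = mi(frame.coords[acc.atom] - frame.coords[don.donor])
            dist = float(np.linalg.norm(dvec))
            if dist == 0 or dist > d_max:
                continue
            hvec = mi(frame.coords[don.hydrogen] - frame.coords[don.donor])
            cosang = float(dvec @ hvec / (np.linalg.norm(hvec) * dist))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
            if ang <= angle_max:
                group = acc.group if don.side == "solute" else don.group
                if group in counts:
                    counts[group] += 1
    return counts


def balanced_table(means, n_blocks=6, noise_sd=1.0, block_sd=0.5, seed=0):
    """One dish per treatment per block, Gaussian noise, additive block effects."""
    rng = np.random.default_rng(seed)
    beff = rng.normal(0, block_sd, n_blocks)
    rows = []
    dish = 0
    for b in range(n_blocks):
        for trt, mu in means.items():
            dish += 1
            rows.append((trt, f"B{b}", dish, mu + beff[b] + rng.normal(0, noise_sd)))
    return pd.DataFrame(rows, columns=["treatment", "block", "dish", "root_length_mm"])


def oracle_pairwise(table, alpha=0.05):
    """Independent block-design Tukey oracle from textbook sums of squares.

    Balanced one-dish-per-cell designs only: residual MS from
    SS_total − SS_treatment − SS_block with (a−1)(b−1) df, then pairwise
    comparisons via the studentized range.
    """
    from scipy.stats import studentized_range

    piv = table.pivot_table(index="treatment", columns="block", values="root_length_mm")
    a, b = piv.shape
    grand = piv.to_numpy().mean()
    ss_total = ((piv.to_numpy() - grand) ** 2).sum()
    ss_trt = b * ((piv.mean(axis=1) - grand) ** 2).sum()
    ss_blk = a * ((piv.mean(axis=0) - grand) ** 2).sum()
    mse = (ss_total - ss_trt - ss_blk) / ((a - 1) * (b - 1))
    df = (a - 1) * (b - 1)
    means = piv.mean(axis=1)
    sig = {}
    for i, t1 in enumerate(means.index):
        for t2 in means.index[i + 1:]:
            q = abs(means[t1] - means[t2]) / np.sqrt(mse / b)
            sig[(t1, t2)] = q > studentized_range.ppf(1 - alpha, a, df)
    return sig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
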