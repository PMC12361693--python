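"""Seeded synthetic fixtures with known ground truth.

Every generator emulates one input class of the pipeline — 7-TM sequences
with a known substitution count, ideal helical bundles, rigid-motion +
Gaussian-noise structure pairs with a known expected RMSD, harmonic
trajectories with a planted fluctuation profile, and binding-pocket scenes
with planted hydrogen bonds and waters — so each stage can be tested
against bookkeeping rather than against downloaded data.

All generators take an explicit integer seed and are byte-deterministic;
none mutates global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from Bio.Data.IUPACData import protein_letters_1to3

from .qty_code import QTY_SUBSTITUTIONS, AnnotatedSequence
from .structure import StructureModel
from .traj_analysis import Trajectory

__all__ = [
    "FixtureSpec",
    "TM_COMPOSITION",
    "LOOP_COMPOSITION",
    "make_7tm_sequence",
    "build_ideal_helix",
    "make_7tm_bundle",
    "perturb_structure",
    "make_harmonic_trajectory",
    "make_pocket_scene",
    "qty_rename",
]

_1TO3 = {k: v.upper() for k, v in protein_letters_1to3.items()}
_QTY_RENAME_3 = {"LEU": "GLN", "ILE": "THR", "VAL": "THR", "PHE": "TYR"}

# Residue composition of a hydrophobic TM helix: ~46% L/I/V/F, matching the
# TM variation band observed for real opsin redesigns.
TM_COMPOSITION = {
    "L": 0.18, "I": 0.12, "V": 0.10, "F": 0.06, "A": 0.12, "G": 0.08,
    "T": 0.06, "S": 0.06, "M": 0.04, "W": 0.03, "Y": 0.04, "C": 0.02,
    "P": 0.02, "N": 0.02, "Q": 0.02, "E": 0.01, "K": 0.01, "R": 0.01,
}

# Polar loop composition (no L/I/V/F: substitutions stay confined to TM).
LOOP_COMPOSITION = {
    "S": 0.12, "T": 0.08, "G": 0.12, "P": 0.08, "N": 0.08, "Q": 0.06,
    "E": 0.10, "K": 0.10, "R": 0.06, "D": 0.10, "A": 0.06, "H": 0.04,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study conditions.

    Defaults mirror a 7-TM opsin-like architecture: seven 23-residue
    helices with 24-residue connecting/terminal stretches (353 residues,
    ~46% TM coverage, as in a typical opsin once its soluble termini are
    counted), TM composition ~46% L/I/V/F, 0.5 Å perturbation noise and
    2000-frame harmonic trajectories.
    """

    seed: int = 0
    n_helices: int = 7
    helix_len: int = 23
    loop_len: int = 24
    tm_composition: dict[str, float] = field(
        default_factory=lambda: dict(TM_COMPOSITION))
    loop_composition: dict[str, float] = field(
        default_factory=lambda: dict(LOOP_COMPOSITION))
    noise_sigma: float = 0.5       # Å, per axis
    n_frames: int = 2000
    n_waters_inside: int = 3
    n_waters_outside: int = 5
    hbond_pairs: int = 2

    def __post_init__(self) -> None:
        if self.helix_len < 1 or self.loop_len < 1:
            raise ValueError("helix and loop lengths must be >= 1")


def _draw(rng: np.random.Generator, composition: dict[str, float],
          n: int) -> str:
    letters = sorted(composition)
    probs = np.array([composition[a] for a in letters], dtype=float)
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=n, p=probs))


def make_7tm_sequence(
    spec: FixtureSpec, seq_id: str = "synthetic_7tm"
) -> tuple[AnnotatedSequence, int]:
    """An annotated 7-TM sequence and its exact planted substitution count.

    Layout is loop–(helix–loop)×n; TM residues are drawn from the TM
    composition and the returned count is the number of L/I/V/F actually
    placed inside TM segments (the oracle for the QTY ledger).
    """
    rng = np.random.default_rng(spec.seed)
    parts = [_draw(rng, spec.loop_composition, spec.loop_len)]
    segments = []
    pos = spec.loop_len
    planted = 0
    for _ in range(spec.n_helices):
        helix = _draw(rng, spec.tm_composition, spec.helix_len)
        planted += sum(helix.count(r) for r in QTY_SUBSTITUTIONS)
        parts.append(helix)
        segments.append((pos + 1, pos + spec.helix_len))
        pos += spec.helix_len
        parts.append(_draw(rng, spec.loop_composition, spec.loop_len))
        pos += spec.loop_len
    seq = AnnotatedSequence(
        id=seq_id, residues="".join(parts),
        tm_segments=tuple(segments), provenance="user",
    )
    return seq, planted


def build_ideal_helix(
    n_residues: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
) -> np.ndarray:
    """Cα coordinates of an ideal alpha helix along +z.

    Defaults are the canonical 1.5 Å rise and 100° twist per residue on a
    2.3 Å helical radius (3.6 residues per turn, 5.4 Å pitch).
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    k = np.arange(n_residues)
    ang = np.deg2rad(twist) * k
    return np.column_stack([
        radius * np.cos(ang), radius * np.sin(ang), rise * k,
    ])


def make_7tm_bundle(
    spec: FixtureSpec, bundle_radius: float = 8.5
) -> tuple[StructureModel, AnnotatedSequence]:
    """A Cα-only seven-helix bundle carrying a synthetic 7-TM sequence.

    Helices run antiparallel (alternating up/down) on a circle of
    ``bundle_radius``; loop residues are interpolated on straight lines
    between consecutive helix termini.  Residue names follow the generated
    sequence, so QTY renaming changes surface chemistry while geometry is
    held fixed.
    """
    seq, _ = make_7tm_sequence(spec)
    n_total = len(seq)
    coords = np.zeros((n_total, 3))
    helix_xyz = []
    for h in range(spec.n_helices):
        angle = 2.0 * np.pi * h / spec.n_helices
        offset = np.array([bundle_radius * np.cos(angle),
                           bundle_radius * np.sin(angle), 0.0])
        xyz = build_ideal_helix(spec.helix_len)
        if h % 2 == 1:
            # run the helix top-to-bottom so connecting loops stay short
            xyz = xyz * np.array([1.0, -1.0, -1.0]) \
                + np.array([0.0, 0.0, xyz[-1, 2]])
        helix_xyz.append(xyz + offset)

    for h, (start, end) in enumerate(seq.tm_segments):
        coords[start - 1:end] = helix_xyz[h]

    def fill_loop(i0: int, i1: int, p_from: np.ndarray,
                  p_to: np.ndarray) -> None:
        n = i1 - i0
        for k in range(n):
            frac = (k + 1) / (n + 1)
            coords[i0 + k] = (1 - frac) * p_from + frac * p_to

    first_start = seq.tm_segments[0][0] - 1
    fill_loop(0, first_start,
              helix_xyz[0][0] + np.array([0.0, 0.0, -5.0]), helix_xyz[0][0])
    for h in range(spec.n_helices):
        end = seq.tm_segments[h][1]
        nxt = seq.tm_segments[h + 1][0] - 1 if h + 1 < spec.n_helices \
            else n_total
        p_from = helix_xyz[h][-1]
        p_to = helix_xyz[h + 1][0] if h + 1 < spec.n_helices \
            else p_from + np.array([0.0, 0.0, 5.0])
        fill_loop(end, nxt, p_from, p_to)

    model = StructureModel(
        atom_names=np.array(["CA"] * n_total),
        elements=np.array(["C"] * n_total),
        res_indices=np.arange(1, n_total + 1),
        res_names=np.array([_1TO3[r] for r in seq.residues]),
        chain_ids=np.array(["A"] * n_total),
        coords=coords,
    )
    return model, seq


def perturb_structure(
    model: StructureModel,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> StructureModel:
    """Rigid motion plus i.i.d. per-axis Gaussian noise.

    With per-axis σ the expected fitted RMSD against the original is
    σ·√3; this is the superposition module's recovery oracle.
    """
    rng = np.random.default_rng(seed)
    out = model.select(np.ones(model.n_atoms, dtype=bool))
    xyz = model.coords
    if rotation is not None:
        xyz = xyz @ np.asarray(rotation, dtype=float).T
    if translation is not None:
        xyz = xyz + np.asarray(translation, dtype=float)
    if noise_sigma > 0:
        xyz = xyz + rng.normal(0.0, noise_sigma, size=xyz.shape)
    out.coords = np.array(xyz, dtype=float)
    return out


def make_harmonic_trajectory(
    ref: StructureModel,
    per_residue_sigma: dict[int, float] | float,
    n_frames: int,
    seed: int = 0,
    frame_spacing_ps: float = 10.0,
) -> Trajectory:
    """Frames scattered around a reference with a planted fluctuation profile.

    Each atom receives i.i.d. per-axis Gaussian displacements with its
    residue's σ (Å), so the planted RMSF is σ·√3 per residue.
    ``per_residue_sigma`` maps residue index → σ, or is a single σ for all.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    if isinstance(per_residue_sigma, dict):
        sigma = np.array([per_residue_sigma.get(int(r), 0.0)
                          for r in ref.res_indices])
    else:
        sigma = np.full(ref.n_atoms, float(per_residue_sigma))
    noise = rng.normal(0.0, 1.0, size=(n_frames, ref.n_atoms, 3)) \
        * sigma[None, :, None]
    coords = ref.coords[None, :, :] + noise
    times = frame_spacing_ps * np.arange(n_frames)
    return Trajectory(topology=ref, times=times, coords=coords)


def make_pocket_scene(
    n_waters_inside: int = 3,
    n_waters_outside: int = 5,
    hbond_pairs: int = 2,
    seed: int = 0,
    pocket_cutoff: float = 5.0,
    water_cutoff: float = 3.5,
) -> tuple[StructureModel, dict]:
    """A toy ligand scene with planted pocket waters and hydrogen bonds.

    A 3-atom "RET" ligand sits at the origin ringed by four pocket
    residues at 4 Å.  ``n_waters_inside`` water oxygens are placed 3 Å
    from pocket atoms (inside the ``water_cutoff``), the outside waters
    50 Å away; donor–H···acceptor triplets satisfying the default
    criteria exactly (2.8 Å, collinear) are planted 30 Å from the pocket,
    10 Å apart, so every non-planted pair misses the criteria by a wide
    margin.  Returns the model plus a ground-truth dict with the planted
    counts and the donor/acceptor atom lists.
    """
    if min(n_waters_inside, n_waters_outside, hbond_pairs) < 0:
        raise ValueError("counts must be >= 0")
    if n_waters_inside > 16 or hbond_pairs > 50:
        raise ValueError("infeasible geometry request")
    rng = np.random.default_rng(seed)

    names, elements, ridx, rnames, chains, xyz, het = \
        [], [], [], [], [], [], []

    def add(name, element, res_index, res_name, chain, pos, hetero):
        names.append(name)
        elements.append(element)
        ridx.append(res_index)
        rnames.append(res_name)
        chains.append(chain)
        xyz.append(np.asarray(pos, dtype=float))
        het.append(hetero)

    # ligand: 3 carbons along +x
    for k in range(3):
        add(f"C{k + 1}", "C", 900, "RET", "L", (1.5 * k, 0.0, 0.0), True)

    # 4 pocket residues ringed at 4 A from the ligand's first atom
    pocket_truth = set()
    pocket_pos = []
    for k in range(4):
        ang = 2.0 * np.pi * k / 4 + 0.3
        pos = (4.0 * np.cos(ang), 4.0 * np.sin(ang), 0.0)
        add("CB", "C", k + 1, "ALA", "A", pos, False)
        pocket_truth.add(("A", k + 1))
        pocket_pos.append(np.asarray(pos))

    # inside waters: 3 A above a pocket atom (within the water cutoff)
    for k in range(n_waters_inside):
        base = pocket_pos[k % 4]
        layer = k // 4
        z = 3.0 if layer % 2 == 0 else -3.0
        off = 0.4 * (layer // 2) + 0.05 * rng.random()
        pos = (base[0] + off, base[1], z)
        add("O", "O", 100 + k, "HOH", "W", pos, True)

    # outside waters: far from everything
    for k in range(n_waters_outside):
        pos = (50.0 + 5.0 * k, 50.0, 0.0)
        add("O", "O", 300 + k, "HOH", "W", pos, True)

    # hydrogen-bond pairs, 30 A from the pocket, 10 A apart
    donors, acceptors = [], []
    for k in range(hbond_pairs):
        base = np.array([10.0 * k, 0.0, 30.0])
        u = np.array([1.0, 0.0, 0.0])
        d_pos = base
        h_pos = base + 0.96 * u
        a_pos = base + 2.8 * u
        add("OG", "O", 200 + 2 * k, "SER", "D", d_pos, False)
        d_idx = len(xyz) - 1
        add("HG", "H", 200 + 2 * k, "SER", "D", h_pos, False)
        h_idx = len(xyz) - 1
        add("OG1", "O", 201 + 2 * k, "THR", "D", a_pos, False)
        a_idx = len(xyz) - 1
        donors.append((d_idx, (h_idx,)))
        acceptors.append(a_idx)

    model = StructureModel(
        atom_names=np.array(names),
        elements=np.array(elements),
        res_indices=np.array(ridx, dtype=int),
        res_names=np.array(rnames),
        chain_ids=np.array(chains),
        coords=np.array(xyz, dtype=float),
        is_hetero=np.array(het, dtype=bool),
    )
    truth = {
        "pocket_residues": pocket_truth,
        "n_waters_inside": n_waters_inside,
        "n_waters_outside": n_waters_outside,
        "hbond_pairs": hbond_pairs,
        "donors": donors,
        "acceptors": acceptors,
        "pocket_cutoff": pocket_cutoff,
        "water_cutoff": water_cutoff,
    }
    return model, truth


def qty_rename(
    model: StructureModel, tm_segments: tuple[tuple[int, int], ...]
) -> StructureModel:
    """Rename L/I/V/F residues inside TM segments to Q/T/T/Y in place of
    geometry change.

    A controlled-test transform: side-chain identity (hence hydrophobic
    classification) changes while every coordinate stays fixed.
    """
    out = model.select(np.ones(model.n_atoms, dtype=bool))
    res_names = out.res_names.astype(object).copy()
    in_tm = np.zeros(model.n_atoms, dtype=bool)
    for start, end in tm_segments:
        in_tm |= (model.res_indices >= start) & (model.res_indices <= end)
    for i in np.flatnonzero(in_tm):
        res_names[i] = _QTY_RENAME_3.get(str(res_names[i]), res_names[i])
    out.res_names = np.array(res_names, dtype=str)
    return out
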