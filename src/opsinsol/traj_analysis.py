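"""MD trajectory post-analysis for the retinal photoisomerization study.

Operators for what one measures after simulating a retinal-bound opsin
through the 11-cis → all-trans switch: the isomerization itself (a rigid
180° rotation of the C13–C15 moiety about the C11–C12 bond), fitted RMSD
time series with running averages, per-residue RMSF, radius of gyration,
binding-pocket hydrogen-bond and water counts, and the short-range
Coulomb + Lennard-Jones interaction energy between atom groups, displayed
on a signed pseudo-logarithmic scale.

No forces are integrated here — trajectories are consumed, not produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure import StructureModel
from .superpose import kabsch_fit

__all__ = [
    "Trajectory",
    "PocketDefinition",
    "NonbondedParams",
    "HbondCriteria",
    "IsomerizationSpec",
    "COULOMB_CONSTANT",
    "WATER_RESIDUE_NAMES",
    "isomerize",
    "dihedral",
    "rmsd_series",
    "running_average",
    "rmsf",
    "radius_of_gyration",
    "define_pocket",
    "guess_donors_acceptors",
    "count_hbonds",
    "count_pocket_waters",
    "interaction_energy",
    "signed_pseudo_log",
    "trajectory_from_models",
]

#: Coulomb prefactor f = 1/(4·pi·eps0) in kJ·mol⁻¹·nm·e⁻².
COULOMB_CONSTANT = 138.935458

#: Residue names recognized as water.
WATER_RESIDUE_NAMES = frozenset({"HOH", "SOL", "WAT", "TIP3", "TIP"})


@dataclass
class Trajectory:
    """Time-ordered coordinate frames over a fixed topology.

    Times are in ps; by the study's convention the isomerization event sits
    at t = 0, with pre-event frames at negative times.
    """

    topology: StructureModel
    times: np.ndarray          # ps, shape (n_frames,), strictly increasing
    coords: np.ndarray         # Å, shape (n_frames, n_atoms, 3)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("frame atom count differs from topology")
        if len(self.times) != len(self.coords):
            raise ValueError("times and frames differ in length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    @property
    def frame_spacing(self) -> float:
        if self.n_frames < 2:
            raise ValueError("frame spacing undefined for < 2 frames")
        return float(np.median(np.diff(self.times)))

    def frame(self, i: int) -> StructureModel:
        out = self.topology.select(np.ones(self.topology.n_atoms, dtype=bool))
        out.coords = self.coords[i].copy()
        return out


@dataclass(frozen=True)
class PocketDefinition:
    """Binding-pocket membership with the provenance of its derivation."""

    residues: frozenset[tuple[str, int]]   # (chain id, residue index)
    ligand_id: str
    cutoff: float                          # Å used to derive the set
    reference_frame: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty pocket")


@dataclass(frozen=True)
class HbondCriteria:
    """Geometric hydrogen-bond criteria (donor–acceptor distance and
    H–D–A angle)."""

    max_da_distance: float = 3.5   # Å
    max_hda_angle: float = 30.0    # degrees

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("distance criterion must be positive")
        if not 0.0 < self.max_hda_angle < 180.0:
            raise ValueError("angle criterion must lie in (0,180)")


@dataclass(frozen=True)
class IsomerizationSpec:
    """Rigid bond-rotation specification.

    ``axis`` holds the indices of the two bond atoms (C11, C12 for retinal);
    ``moving`` the indices of everything distal to the bond (C13–C15 with
    their hydrogens and methyls).  The default 180° turn converts 11-cis
    retinal to all-trans.
    """

    axis: tuple[int, int]
    moving: tuple[int, ...]
    angle_deg: float = 180.0

    def __post_init__(self) -> None:
        if self.axis[0] == self.axis[1]:
            raise ValueError("axis atoms must be distinct")
        if not self.moving:
            raise ValueError("moving set is empty")
        if set(self.axis) & set(self.moving):
            raise ValueError("moving set must not contain an axis atom")


def isomerize(model: StructureModel, spec: IsomerizationSpec) -> StructureModel:
    """Rotate the moving atoms rigidly about the bond axis.

    The rotation axis runs from the first to the second axis atom and
    passes through the first; all atoms outside the moving set keep their
    coordinates bit-for-bit.
    """
    a, b = spec.axis
    origin = model.coords[a]
    axis_vec = model.coords[b] - origin
    norm = np.linalg.norm(axis_vec)
    if norm == 0:
        raise ValueError("axis atoms coincide")
    rot = Rotation.from_rotvec(np.deg2rad(spec.angle_deg) * axis_vec / norm)
    out = model.select(np.ones(model.n_atoms, dtype=bool))
    moving = np.array(spec.moving)
    out.coords[moving] = rot.apply(model.coords[moving] - origin) + origin
    return out


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle p0–p1–p2–p3 in degrees, in (−180, 180]."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def rmsd_series(
    traj: Trajectory,
    ref: StructureModel,
    fit_selection: np.ndarray | None = None,
    measure_selection: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-frame RMSD after least-squares fitting each frame to a reference.

    The rigid fit is computed on ``fit_selection`` (typically Cα atoms) and
    the RMSD measured over ``measure_selection``; both default to all
    atoms.  Returns a (time_ps, rmsd) table.
    """
    n = traj.topology.n_atoms
    if ref.n_atoms != n:
        raise ValueError("reference atom count differs from trajectory")
    fit_sel = np.ones(n, dtype=bool) if fit_selection is None \
        else np.asarray(fit_selection, dtype=bool)
    meas_sel = np.ones(n, dtype=bool) if measure_selection is None \
        else np.asarray(measure_selection, dtype=bool)
    if not fit_sel.any() or not meas_sel.any():
        raise ValueError("empty selection")
    values = np.empty(traj.n_frames)
    ref_xyz = ref.coords
    for k in range(traj.n_frames):
        frame = traj.coords[k]
        fit = kabsch_fit(frame[fit_sel], ref_xyz[fit_sel])
        moved = frame @ fit.rotation.T + fit.translation
        dev = moved[meas_sel] - ref_xyz[meas_sel]
        values[k] = np.sqrt((dev ** 2).sum(axis=1).mean())
    return pd.DataFrame({"time_ps": traj.times, "rmsd": values})


def running_average(
    series: np.ndarray | pd.Series,
    window_ps: float,
    frame_spacing_ps: float = 1.0,
) -> np.ndarray:
    """Centered moving mean with the window truncated at the series edges.

    ``window_ps`` is converted to frames through the frame spacing (the
    study uses a 1 ns window); the output has the input's length.
    """
    values = np.asarray(series, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    if window_ps < frame_spacing_ps:
        raise ValueError("window shorter than the frame spacing")
    w = max(1, int(round(window_ps / frame_spacing_ps)))
    return (
        pd.Series(values)
        .rolling(window=w, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def rmsf(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    n_fit_passes: int = 2,
    superpose: bool = True,
) -> pd.DataFrame:
    """Per-residue root-mean-square fluctuation about the mean structure.

    Frames are least-squares fitted to the running mean structure (two
    passes: first to the initial frame, then to the resulting mean), the
    per-atom fluctuation computed, and residues assigned the mean over
    their selected atoms.  ``superpose=False`` skips the fitting for
    trajectories already aligned.  Returns (chain, res_index, rmsf).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    n = traj.topology.n_atoms
    sel = np.ones(n, dtype=bool) if selection is None \
        else np.asarray(selection, dtype=bool)
    fitted = traj.coords.copy()
    ref = fitted[0]
    for _ in range(n_fit_passes if superpose else 0):
        for k in range(len(fitted)):
            fit = kabsch_fit(fitted[k][sel], ref[sel])
            fitted[k] = fitted[k] @ fit.rotation.T + fit.translation
        ref = fitted.mean(axis=0)
    if not superpose:
        ref = fitted.mean(axis=0)
    per_atom = np.sqrt(((fitted - ref) ** 2).sum(axis=2).mean(axis=0))
    df = pd.DataFrame({
        "chain": traj.topology.chain_ids[sel],
        "res_index": traj.topology.res_indices[sel],
        "rmsf": per_atom[sel],
    })
    return df.groupby(["chain", "res_index"], sort=True)["rmsf"] \
        .mean().reset_index()


def radius_of_gyration(coords: np.ndarray,
                       masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration (Å) of one coordinate frame."""
    coords = np.asarray(coords, dtype=float)
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    center = (masses[:, None] * coords).sum(axis=0) / total
    sq = ((coords - center) ** 2).sum(axis=1)
    return float(np.sqrt((masses * sq).sum() / total))


def define_pocket(
    model: StructureModel,
    ligand_id: str,
    cutoff: float = 5.0,
    reference_frame: int = 0,
) -> PocketDefinition:
    """Residues with any heavy atom within ``cutoff`` Å of the ligand.

    Waters and the ligand itself are excluded from the pocket set; an
    empty result (e.g. cutoff 0) is an error.
    """
    lig_mask = model.res_names == ligand_id
    if not lig_mask.any():
        raise ValueError(f"ligand {ligand_id!r} not found")
    heavy = model.heavy_mask()
    lig_xyz = model.coords[lig_mask & heavy]
    cand = heavy & ~lig_mask & ~np.isin(model.res_names,
                                        list(WATER_RESIDUE_NAMES))
    if cutoff > 0 and cand.any() and len(lig_xyz):
        d = cdist(model.coords[cand], lig_xyz).min(axis=1)
        close = np.flatnonzero(cand)[d <= cutoff]
    else:
        close = np.array([], dtype=int)
    residues = frozenset(
        (str(model.chain_ids[i]), int(model.res_indices[i])) for i in close
    )
    if not residues:
        raise ValueError("pocket is empty at this cutoff")
    return PocketDefinition(residues=residues, ligand_id=ligand_id,
                            cutoff=cutoff, reference_frame=reference_frame)


def guess_donors_acceptors(
    model: StructureModel, max_dh_bond: float = 1.25
) -> tuple[list[tuple[int, tuple[int, ...]]], list[int]]:
    """Heuristic polar donors/acceptors from geometry alone.

    Acceptors are all N/O heavy atoms; donors are N/O atoms with at least
    one hydrogen within ``max_dh_bond`` Å.
    """
    polar = np.isin(model.elements, ["N", "O"])
    hydrogens = np.flatnonzero(model.elements == "H")
    acceptors = [int(i) for i in np.flatnonzero(polar)]
    donors = []
    if len(hydrogens):
        h_xyz = model.coords[hydrogens]
        for i in acceptors:
            d = np.linalg.norm(h_xyz - model.coords[i], axis=1)
            attached = tuple(int(h) for h in hydrogens[d <= max_dh_bond])
            if attached:
                donors.append((i, attached))
    return donors, acceptors


def count_hbonds(
    model: StructureModel,
    donors: list[tuple[int, tuple[int, ...]]],
    acceptors: list[int],
    criteria: HbondCriteria = HbondCriteria(),
) -> int:
    """Count donor–acceptor pairs satisfying the hydrogen-bond criteria.

    A pair qualifies when the D–A distance is within the cutoff and some
    attached hydrogen makes an H–D–A angle within the angle cutoff; it is
    counted once even if several hydrogens qualify.  Donors listed without
    hydrogens are skipped with a warning.
    """
    count = 0
    for entry in donors:
        d_idx, h_indices = entry
        if not h_indices:
            warnings.warn(f"donor atom {d_idx} has no hydrogens; skipped",
                          stacklevel=2)
            continue
        d_xyz = model.coords[d_idx]
        for a_idx in acceptors:
            if a_idx == d_idx:
                continue
            a_xyz = model.coords[a_idx]
            da = a_xyz - d_xyz
            dist = np.linalg.norm(da)
            if dist > criteria.max_da_distance or dist == 0:
                continue
            for h_idx in h_indices:
                dh = model.coords[h_idx] - d_xyz
                nh = np.linalg.norm(dh)
                if nh == 0:
                    continue
                cosang = np.clip(np.dot(dh, da) / (nh * dist), -1.0, 1.0)
                if np.degrees(np.arccos(cosang)) <= criteria.max_hda_angle:
                    count += 1
                    break
    return count


def count_pocket_waters(
    model: StructureModel,
    pocket: PocketDefinition,
    water_res_names: frozenset[str] = WATER_RESIDUE_NAMES,
    cutoff: float = 3.5,
) -> int:
    """Water oxygens within ``cutoff`` Å of any pocket-residue heavy atom.

    A water sitting exactly at the cutoff is counted (<= convention).
    """
    is_water = np.isin(model.res_names, list(water_res_names))
    w_mask = is_water & (model.elements == "O")
    if not w_mask.any():
        return 0
    pocket_mask = model.heavy_mask() & ~is_water
    keys = set(pocket.residues)
    pocket_mask &= np.array([
        (str(c), int(r)) in keys
        for c, r in zip(model.chain_ids, model.res_indices)
    ])
    if not pocket_mask.any():
        return 0
    tree = cKDTree(model.coords[pocket_mask])
    d, _ = tree.query(model.coords[w_mask])
    return int((d <= cutoff).sum())


@dataclass(frozen=True)
class NonbondedParams:
    """Per-atom nonbonded parameters for short-range interaction energies.

    Charges in elementary charge units; Lennard-Jones sigma in nm and
    epsilon in kJ/mol; the cutoff (default 1.2 nm) applies to both the
    Coulomb and LJ sums.
    """

    charges: np.ndarray        # e
    sigmas: np.ndarray         # nm
    epsilons: np.ndarray       # kJ/mol
    combination_rule: str = "lorentz-berthelot"
    cutoff_nm: float = 1.2
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self) -> None:
        for name in ("charges", "sigmas", "epsilons"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if np.any(self.epsilons < 0):
            raise ValueError("epsilon must be >= 0")
        if np.any(self.sigmas <= 0):
            raise ValueError("sigma must be > 0")
        if self.cutoff_nm <= 0:
            raise ValueError("cutoff must be > 0")
        if self.combination_rule not in ("lorentz-berthelot", "geometric"):
            raise ValueError(
                f"unknown combination rule {self.combination_rule!r}"
            )


def interaction_energy(
    coords: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    params: NonbondedParams,
) -> tuple[float, float]:
    """Short-range (Coulomb, Lennard-Jones) energy between two atom groups.

    Pairwise sums over A×B pairs with r <= cutoff:
    ``f·qi·qj/r`` and ``4·eps_ij·[(sig_ij/r)^12 − (sig_ij/r)^6]``, with
    sigma/epsilon combined by the configured rule.  Coordinates are in Å
    and converted to nm internally; energies are kJ/mol.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups must be disjoint")
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    for g in (group_a, group_b):
        if g.size and (g.min() < 0 or g.max() >= len(params.charges)
                       or g.max() >= n):
            bad = int(g.max())
            raise IndexError(f"missing coordinates or parameters for atom {bad}")
    r = cdist(coords[group_a], coords[group_b]) * 0.1  # Å -> nm
    within = (r <= params.cutoff_nm) & (r > 0)
    if not within.any():
        return 0.0, 0.0
    qa = params.charges[group_a][:, None]
    qb = params.charges[group_b][None, :]
    if params.combination_rule == "lorentz-berthelot":
        sig = 0.5 * (params.sigmas[group_a][:, None]
                     + params.sigmas[group_b][None, :])
    else:
        sig = np.sqrt(params.sigmas[group_a][:, None]
                      * params.sigmas[group_b][None, :])
    eps = np.sqrt(params.epsilons[group_a][:, None]
                  * params.epsilons[group_b][None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        coulomb = np.where(within,
                           params.coulomb_constant * qa * qb / r, 0.0)
        sr6 = np.where(within, (sig / r) ** 6, 0.0)
        lj = np.where(within, 4.0 * eps * (sr6 ** 2 - sr6), 0.0)
    return float(coulomb.sum()), float(lj.sum())


def signed_pseudo_log(x, scale: float = 1.0):
    """Odd log-like rescale sign(x)·log10(1 + |x|/scale) for display of
    wide-range energies."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.log10(1.0 + np.abs(x) / scale)
    return float(out) if out.ndim == 0 else out


def trajectory_from_models(
    models: list[StructureModel],
    frame_spacing_ps: float = 1.0,
    t0_ps: float = 0.0,
) -> Trajectory:
    """Assemble a Trajectory from multi-MODEL PDB frames.

    The first model supplies the topology; times are
    ``t0 + k·frame_spacing``.
    """
    if not models:
        raise ValueError("no models")
    coords = np.stack([m.coords for m in models])
    times = t0_ps + frame_spacing_ps * np.arange(len(models))
    return Trajectory(topology=models[0], times=times, coords=coords)
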