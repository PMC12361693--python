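"""Run configuration and stage orchestration.

Three stages mirror the analysis the package exists for: sequence redesign
with characteristics (``design``), structure superposition with matrix
comparison (``structure``), and trajectory analytics (``traj``).  A
``RunConfig`` holds every stage parameter with its documented default,
round-trips through YAML losslessly, and is hashed into output provenance
headers so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as oio
from .qty_code import AnnotatedSequence, apply_qty, parse_ss3, parse_uniprot_tm
from .seq_metrics import build_report
from .structure import read_pdb
from .superpose import compare_matrices, refine_superposition, rmsd_matrix
from .traj_analysis import (
    HbondCriteria,
    count_hbonds,
    count_pocket_waters,
    define_pocket,
    guess_donors_acceptors,
    interaction_energy,
    radius_of_gyration,
    rmsd_series,
    rmsf,
    running_average,
    trajectory_from_models,
)

logger = logging.getLogger("opsinsol")

__all__ = ["RunConfig", "run_design_stage", "run_structure_stage",
           "run_traj_stage"]


@dataclass(frozen=True)
class RunConfig:
    """All stage parameters with their documented defaults."""

    # inputs
    fasta: str | None = None
    annotations: dict[str, str] = field(default_factory=dict)  # id -> file
    native_pdbs: list[str] = field(default_factory=list)
    qty_pdbs: list[str] = field(default_factory=list)
    trajectory_pdb: str | None = None
    reference_pdb: str | None = None
    params_tsv: str | None = None
    out_dir: str = "results"
    # sequence stage
    pk_set: str = "bjellqvist"
    min_helix_len: int = 5
    # superposition stage
    max_cycles: int = 5
    reject_sd: float = 2.0
    # surface stage
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    # trajectory stage
    window_ps: float = 1000.0
    frame_spacing_ps: float = 100.0
    pocket_ligand: str = "RET"
    pocket_cutoff: float = 5.0
    water_cutoff: float = 3.5
    hbond_distance: float = 3.5
    hbond_angle: float = 30.0
    nb_cutoff_nm: float = 1.2
    isomerization_time_ps: float = 0.0
    t0_ps: float = 0.0
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        # where results go and how loudly we log do not affect the analysis
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("out_dir", "log_level")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def with_overrides(self, **overrides) -> "RunConfig":
        return replace(self, **overrides)


def _load_segments(path: str, min_helix_len: int) -> list[tuple[int, int]]:
    text = Path(path).read_text()
    if "TRANSMEM" in text:
        return parse_uniprot_tm(text)
    return parse_ss3(text.strip(), min_helix_len=min_helix_len)


def run_design_stage(config: RunConfig):
    """QTY-redesign every FASTA record and tabulate its characteristics.

    Writes the variant FASTA and the characteristics table (with a min/max
    summary) under ``out_dir``.  Records without a resolvable TM
    annotation are reported and skipped; the run continues.
    """
    if config.fasta is None:
        raise ValueError("design stage needs a FASTA input")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = oio.read_fasta(config.fasta)
    reports, variants, meta, errors = [], [], {}, {}
    for rec_id, residues in records:
        ann_path = config.annotations.get(rec_id)
        if ann_path is None:
            errors[rec_id] = "no TM annotation configured"
            logger.error("design: %s: no TM annotation configured", rec_id)
            continue
        try:
            segments = _load_segments(ann_path, config.min_helix_len)
            seq = AnnotatedSequence(id=rec_id, residues=residues,
                                    tm_segments=tuple(segments))
            design = apply_qty(seq)
            reports.append(build_report(design))
            variants.append((f"{rec_id}_QTY", design.variant_residues))
            meta[f"{rec_id}_QTY"] = {
                "native": rec_id,
                "n_substitutions": str(design.n_substitutions),
                "n_tm_residues": str(design.n_tm_residues),
            }
        except (ValueError, ZeroDivisionError) as exc:
            errors[rec_id] = str(exc)
            logger.error("design: %s: %s", rec_id, exc)
    if variants:
        oio.write_fasta(variants, out_dir / "qty_variants.fasta", meta)
    table = oio.write_report_tsv(
        reports, out_dir / "design_report.tsv",
        seed=config.seed, config_hash=config.config_hash(),
    )
    return {"table": table, "reports": reports, "errors": errors}


def run_structure_stage(config: RunConfig):
    """Superpose native/QTY model pairs and compare the two RMSD matrices.

    Each native model is fitted against its paired QTY model; the two
    within-group pairwise RMSD matrices are computed and compared
    (Pearson r, mean absolute difference).  Per-pair fit provenance
    (pairs used/initial, cycles) goes to the JSON output.
    """
    if len(config.native_pdbs) != len(config.qty_pdbs):
        raise ValueError("native and QTY model lists differ in length")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    natives = [read_pdb(p)[0] for p in config.native_pdbs]
    qtys = [read_pdb(p)[0] for p in config.qty_pdbs]
    pair_results = []
    for path_n, path_q, a, b in zip(config.native_pdbs, config.qty_pdbs,
                                    natives, qtys):
        fit = refine_superposition(a, b, max_cycles=config.max_cycles,
                                   reject_sd=config.reject_sd)
        logger.info("superpose: %s vs %s rmsd=%.3f pairs=%d/%d",
                    path_n, path_q, fit.rmsd, fit.n_pairs_used,
                    fit.n_pairs_initial)
        pair_results.append({
            "native": str(path_n), "qty": str(path_q),
            "rmsd": fit.rmsd, "n_pairs_used": fit.n_pairs_used,
            "n_pairs_initial": fit.n_pairs_initial,
            "rejection_cycles": fit.rejection_cycles,
        })
    result = {"pairs": pair_results}
    if len(natives) >= 2:
        mat_n = rmsd_matrix(natives, max_cycles=config.max_cycles,
                            reject_sd=config.reject_sd)
        mat_q = rmsd_matrix(qtys, max_cycles=config.max_cycles,
                            reject_sd=config.reject_sd)
        r, mad, table = compare_matrices(mat_n, mat_q,
                                         labels=[str(p) for p in
                                                 config.native_pdbs])
        result.update({
            "native_matrix": mat_n.tolist(),
            "qty_matrix": mat_q.tolist(),
            "pearson_r": r,
            "mean_abs_diff": mad,
        })
        table.to_csv(out_dir / "matrix_comparison.tsv", sep="\t",
                     index=False)
    with open(out_dir / "superposition.json", "w") as fh:
        json.dump({"provenance": oio.provenance_header(
            config.seed, config.config_hash()), **result}, fh, indent=2)
    return result


def run_traj_stage(config: RunConfig):
    """Compute the post-isomerization analytics bundle from a trajectory.

    Per-frame RMSD (complex / protein / pocket / ligand selections) with
    running averages, per-residue RMSF, radius of gyration, pocket
    hydrogen-bond and water counts, and (when nonbonded parameters are
    provided) protein–ligand interaction energy.  One TSV per metric; the
    isomerization time convention (t = 0) is echoed as metadata.
    """
    if config.trajectory_pdb is None:
        raise ValueError("trajectory stage needs a multi-model PDB input")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    models = read_pdb(config.trajectory_pdb)
    # first-frame time relative to the t=0 isomerization convention
    traj = trajectory_from_models(
        models, frame_spacing_ps=config.frame_spacing_ps,
        t0_ps=config.t0_ps,
    )
    ref = read_pdb(config.reference_pdb)[0] if config.reference_pdb \
        else models[0]
    topo = traj.topology
    meta = {
        "isomerization_time_ps": config.isomerization_time_ps,
        "window_ps": config.window_ps,
        "note": "isomerization at t=0 by convention",
    }
    lig_mask = topo.res_names == config.pocket_ligand
    selections = {"complex": np.ones(topo.n_atoms, dtype=bool)}
    if lig_mask.any():
        selections["ligand"] = lig_mask
        selections["protein"] = ~lig_mask & ~topo.is_hetero
        pocket = define_pocket(topo, config.pocket_ligand,
                               cutoff=config.pocket_cutoff)
        keys = set(pocket.residues)
        pocket_mask = np.array([
            (str(c), int(r)) in keys
            for c, r in zip(topo.chain_ids, topo.res_indices)])
        selections["pocket"] = pocket_mask
    fit_sel = topo.ca_mask()
    if not fit_sel.any():
        fit_sel = None
    out = {"times_ps": traj.times}
    for name, sel in selections.items():
        series = rmsd_series(traj, ref, fit_selection=fit_sel,
                             measure_selection=sel)
        smooth = running_average(series["rmsd"], config.window_ps,
                                 traj.frame_spacing)
        oio.write_series_tsv(traj.times, smooth,
                             Path(config.out_dir) / f"rmsd_{name}.tsv",
                             value_name=f"rmsd_{name}_running_avg",
                             metadata=meta)
        out[f"rmsd_{name}"] = series["rmsd"].to_numpy()
        out[f"rmsd_{name}_smooth"] = smooth

    fluct = rmsf(traj)
    fluct.to_csv(out_dir / "rmsf.tsv", sep="\t", index=False)
    out["rmsf"] = fluct

    rg = np.array([radius_of_gyration(traj.coords[k][~topo.is_hetero])
                   for k in range(traj.n_frames)])
    oio.write_series_tsv(traj.times, rg, out_dir / "rg.tsv",
                         value_name="radius_of_gyration", metadata=meta)
    out["rg"] = rg

    if lig_mask.any():
        criteria = HbondCriteria(config.hbond_distance, config.hbond_angle)
        hbonds, waters = [], []
        for k in range(traj.n_frames):
            frame = traj.frame(k)
            donors, acceptors = guess_donors_acceptors(frame)
            hbonds.append(count_hbonds(frame, donors, acceptors, criteria))
            waters.append(count_pocket_waters(frame, pocket,
                                              cutoff=config.water_cutoff))
        oio.write_series_tsv(traj.times, np.array(hbonds),
                             out_dir / "pocket_hbonds.tsv",
                             value_name="n_hbonds", metadata=meta)
        oio.write_series_tsv(traj.times, np.array(waters),
                             out_dir / "pocket_waters.tsv",
                             value_name="n_waters", metadata=meta)
        out["hbonds"] = np.array(hbonds)
        out["waters"] = np.array(waters)
        if config.params_tsv:
            params = oio.read_nonbonded_tsv(config.params_tsv,
                                            cutoff_nm=config.nb_cutoff_nm)
            ie = []
            prot_idx = np.flatnonzero(selections["protein"])
            lig_idx = np.flatnonzero(lig_mask)
            for k in range(traj.n_frames):
                c, lj = interaction_energy(traj.coords[k], prot_idx,
                                           lig_idx, params)
                ie.append(c + lj)
            oio.write_series_tsv(traj.times, np.array(ie),
                                 out_dir / "interaction_energy.tsv",
                                 value_name="ie_kj_mol", metadata=meta)
            out["interaction_energy"] = np.array(ie)
    return out
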