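"""Solvent-accessible surface area and hydrophobic-surface quantification.

Water-solubilizing a membrane protein should shrink the hydrophobic belt
that the lipid bilayer normally hides.  This module measures that with a
Shrake–Rupley SASA (probe-expanded spheres sampled on a Fibonacci lattice)
and a hydrophobic surface fraction: the share of total SASA contributed by
the nonpolar residues L, I, V, F, A, M and W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

from .structure import StructureModel, three_to_one

__all__ = [
    "SasaResult",
    "DEFAULT_VDW_RADII",
    "HYDROPHOBIC_RESIDUES",
    "kyte_doolittle_set",
    "shrake_rupley_sasa",
    "hydrophobic_surface_fraction",
    "segment_surface_report",
]

#: Bondi-style van der Waals radii (Å) for heavy atoms common in proteins.
DEFAULT_VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "H": 1.20, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

#: Nonpolar residues counted as hydrophobic surface (one-letter codes).
HYDROPHOBIC_RESIDUES = frozenset("LIVFAMW")


def kyte_doolittle_set(threshold: float = 0.0) -> frozenset[str]:
    """Alternative hydrophobic set: residues with KD hydropathy > threshold."""
    return frozenset(r for r, h in _KYTE_DOOLITTLE.items() if h > threshold)


@dataclass(frozen=True)
class SasaResult:
    """Per-atom and per-residue solvent-accessible surface areas (Å²)."""

    per_atom: np.ndarray                  # Å², one entry per model atom
    per_residue: pd.DataFrame             # chain, res_index, res_name, sasa
    total: float                          # Å²
    probe_radius: float
    n_sphere_points: int


def _molecular_frame(xyz: np.ndarray) -> np.ndarray:
    """Deterministic molecule-fixed rotation from the coordinate principal
    axes, so the sample lattice co-rotates with the structure and SASA is
    exactly invariant under rigid motion (up to floating point)."""
    if len(xyz) < 3:
        return np.eye(3)
    centered = xyz - xyz.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    scale = max(w[2], 1e-12)
    if w[1] - w[0] < 1e-9 * scale or w[2] - w[1] < 1e-9 * scale:
        return np.eye(3)  # degenerate spectrum: no unique frame
    # covariant sign fix: third moment of the projections flips with the
    # axis, so the oriented frame co-rotates with the structure
    skew = (centered @ v) ** 3
    moments = skew.sum(axis=0)
    signs = np.where(moments >= 0, 1.0, -1.0)
    v = v * signs
    if np.linalg.det(v) < 0:
        k = int(np.argmin(np.abs(moments)))
        v[:, k] = -v[:, k]
    return v


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly equidistributed unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def shrake_rupley_sasa(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
    include_hydrogens: bool = False,
) -> SasaResult:
    """Shrake–Rupley SASA by sphere-point sampling.

    Each atom's sphere is expanded by the probe radius and sampled with
    ``n_points`` Fibonacci-lattice points; the accessible fraction is the
    share of points falling inside no neighboring expanded sphere.
    Hydrogens are ignored by default so predicted (heavy-atom) models and
    experimental structures are treated alike.
    """
    radii = DEFAULT_VDW_RADII if radii is None else radii
    if not include_hydrogens:
        model_eval = model.select(model.heavy_mask())
        eval_to_full = np.flatnonzero(model.heavy_mask())
    else:
        model_eval = model
        eval_to_full = np.arange(model.n_atoms)

    try:
        r_vdw = np.array([radii[str(e).upper()] for e in model_eval.elements])
    except KeyError as exc:
        raise KeyError(f"no van der Waals radius for element {exc}") from exc
    r_ext = r_vdw + probe
    xyz = model_eval.coords
    sphere = _fibonacci_sphere(n_points) @ _molecular_frame(xyz).T

    tree = cKDTree(xyz)
    max_reach = 2.0 * r_ext.max()
    per_atom_eval = np.zeros(len(xyz))
    for i in range(len(xyz)):
        pts = xyz[i] + r_ext[i] * sphere
        neighbors = [j for j in tree.query_ball_point(xyz[i], max_reach)
                     if j != i]
        if neighbors:
            nb_xyz = xyz[neighbors]
            nb_r = r_ext[np.array(neighbors)]
            d2 = ((pts[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < nb_r[None, :] ** 2).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom_eval[i] = frac * 4.0 * np.pi * r_ext[i] ** 2

    per_atom = np.zeros(model.n_atoms)
    per_atom[eval_to_full] = per_atom_eval

    df = pd.DataFrame({
        "chain": model.chain_ids,
        "res_index": model.res_indices,
        "res_name": model.res_names,
        "sasa": per_atom,
    })
    per_residue = (
        df.groupby(["chain", "res_index", "res_name"], sort=True)["sasa"]
        .sum().reset_index()
    )
    return SasaResult(
        per_atom=per_atom,
        per_residue=per_residue,
        total=float(per_atom.sum()),
        probe_radius=probe,
        n_sphere_points=n_points,
    )


def _is_hydrophobic(res_name: str, hydrophobic_set: frozenset[str]) -> bool:
    code = res_name if len(res_name) == 1 else three_to_one(res_name)
    return code in hydrophobic_set


def hydrophobic_surface_fraction(
    model: StructureModel,
    sasa: SasaResult,
    hydrophobic_set: frozenset[str] = HYDROPHOBIC_RESIDUES,
) -> float:
    """Fraction of total SASA contributed by hydrophobic residues.

    Hetero groups (ligands, waters) are excluded from both numerator and
    denominator; the denominator must be positive.
    """
    protein = ~model.is_hetero
    total = float(sasa.per_atom[protein].sum())
    if total <= 0.0:
        raise ZeroDivisionError("total SASA is zero; fraction undefined")
    hydro_mask = protein & np.array([
        _is_hydrophobic(rn, hydrophobic_set) for rn in model.res_names
    ])
    return float(sasa.per_atom[hydro_mask].sum()) / total


def segment_surface_report(
    model: StructureModel,
    sasa: SasaResult,
    segments: list[tuple[int, int]],
    hydrophobic_set: frozenset[str] = HYDROPHOBIC_RESIDUES,
    chain: str | None = None,
) -> pd.DataFrame:
    """Hydrophobic-fraction table: one row per residue segment plus the
    whole chain.

    Segments are ``(start, end)`` residue indices, 1-based inclusive, on
    one chain.
    """
    if chain is None:
        chain = model.chains()[0]
    in_chain = (model.chain_ids == chain) & ~model.is_hetero
    hydro = np.array([_is_hydrophobic(rn, hydrophobic_set)
                      for rn in model.res_names])
    rows = []

    def fraction(mask: np.ndarray) -> tuple[float, float]:
        tot = float(sasa.per_atom[mask].sum())
        hyd = float(sasa.per_atom[mask & hydro].sum())
        return tot, (hyd / tot if tot > 0 else np.nan)

    for start, end in segments:
        seg_mask = in_chain & (model.res_indices >= start) \
            & (model.res_indices <= end)
        tot, frac = fraction(seg_mask)
        rows.append({"segment": f"{start}-{end}", "sasa_total": tot,
                     "hydrophobic_fraction": frac})
    tot, frac = fraction(in_chain)
    rows.append({"segment": "chain", "sasa_total": tot,
                 "hydrophobic_fraction": frac})
    return pd.DataFrame(rows)
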