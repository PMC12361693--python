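"""Structure superposition with iterative outlier rejection.

A Kabsch least-squares fit on paired Cα atoms, wrapped in the iterative
reject-and-refit loop typical of "super"-style alignment tools: after each
fit, residue pairs deviating by more than ``reject_sd`` standard deviations
are dropped and the fit repeated, so flexible loops do not dominate the
reported RMSD.  Residue pairing is sequence-based and QTY-aware, so a
native chain aligns unambiguously onto its redesigned variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from Bio import Align
from Bio.Align import substitution_matrices

from .structure import StructureModel

__all__ = [
    "SuperpositionResult",
    "pair_residues",
    "kabsch_fit",
    "refine_superposition",
    "trim_termini",
    "rmsd_matrix",
    "compare_matrices",
    "StructureModel",
]

#: Residue pairs treated as matches when aligning native against QTY chains.
QTY_EQUIVALENT_PAIRS = {("L", "Q"), ("I", "T"), ("V", "T"), ("F", "Y")}


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform (x -> R·x + t maps the mobile onto the reference)."""

    rotation: np.ndarray     # 3x3, proper (det = +1)
    translation: np.ndarray  # 3-vector, Å
    rmsd: float              # Å, over retained pairs
    n_pairs_used: int
    n_pairs_initial: int
    rejection_cycles: int = 0


def _qty_aware_aligner() -> Align.PairwiseAligner:
    alphabet = "ACDEFGHIKLMNPQRSTVWYX"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        mat[a, a] = 1.0
    for a, b in QTY_EQUIVALENT_PAIRS:
        mat[a, b] = 1.0
        mat[b, a] = 1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def pair_residues(
    a: StructureModel, b: StructureModel,
    chain_a: str | None = None, chain_b: str | None = None,
) -> list[tuple[int, int]]:
    """Pair residues of two chains by global sequence alignment.

    Needleman–Wunsch with match +1, mismatch 0, gap −1; QTY-equivalent
    pairs (L:Q, I:T, V:T, F:Y) score as matches.  Only positions where both
    models carry a Cα atom enter the alignment, and the returned pairs hold
    the models' own residue indices.
    """
    seq_a, idx_a = a.chain_sequence(chain_a)
    seq_b, idx_b = b.chain_sequence(chain_b)
    if not seq_a or not seq_b:
        raise ValueError("cannot pair an empty chain")
    alignment = _qty_aware_aligner().align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for off in range(a1 - a0):
            pairs.append((int(idx_a[a0 + off]), int(idx_b[b0 + off])))
    return pairs


def kabsch_fit(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid fit of point set P onto Q (Kabsch, via SVD).

    Returns the proper rotation and translation minimizing the RMSD of
    ``R·P + t`` against ``Q``, with the minimized RMSD.  Requires at least
    3 non-collinear pairs.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must both be (n, 3)")
    n = len(P)
    if n < 3:
        raise ValueError(f"need >= 3 pairs, got {n}")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinear (or coincident) point sets leave the rotation undetermined
    if np.linalg.svd(Pc, compute_uv=False)[1] < 1e-8 * max(1.0, abs(Pc).max()):
        raise ValueError("degenerate (collinear) geometry")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    dev = P @ R.T + t - Q
    rmsd = float(np.sqrt((dev ** 2).sum(axis=1).mean()))
    return SuperpositionResult(
        rotation=R, translation=t, rmsd=rmsd,
        n_pairs_used=n, n_pairs_initial=n,
    )


def _paired_ca_coords(
    a: StructureModel, b: StructureModel, pairs: list[tuple[int, int]],
    chain_a: str | None, chain_b: str | None,
) -> tuple[np.ndarray, np.ndarray]:
    def ca_lookup(model: StructureModel, chain: str | None):
        mask = model.ca_mask(chain if chain is not None else model.chains()[0])
        idx = model.res_indices[mask]
        xyz = model.coords[mask]
        return {int(i): xyz[k] for k, i in enumerate(idx)}

    la, lb = ca_lookup(a, chain_a), ca_lookup(b, chain_b)
    P = np.array([la[i] for i, _ in pairs])
    Q = np.array([lb[j] for _, j in pairs])
    return P, Q


def refine_superposition(
    a: StructureModel, b: StructureModel,
    max_cycles: int = 5, reject_sd: float = 2.0,
    chain_a: str | None = None, chain_b: str | None = None,
) -> SuperpositionResult:
    """Iterative Kabsch fit of model ``a`` onto ``b`` with outlier rejection.

    After each fit, pairs whose deviation exceeds ``reject_sd`` times the
    standard deviation of all retained deviations are dropped; iteration
    stops at convergence (nothing rejected), at ``max_cycles``, or when a
    rejection would leave fewer than 3 pairs.
    """
    pairs = pair_residues(a, b, chain_a, chain_b)
    P, Q = _paired_ca_coords(a, b, pairs, chain_a, chain_b)
    n_initial = len(P)
    keep = np.ones(n_initial, dtype=bool)
    cycles = 0
    fit = kabsch_fit(P, Q)
    for _ in range(max_cycles):
        fit = kabsch_fit(P[keep], Q[keep])
        cycles += 1
        dev = np.linalg.norm(P[keep] @ fit.rotation.T + fit.translation
                             - Q[keep], axis=1)
        sd = dev.std()
        if sd <= 1e-8:  # numerically exact fit; nothing to reject
            break
        reject = dev > reject_sd * sd
        if not reject.any():
            break
        if keep.sum() - reject.sum() < 3:
            break
        keep_idx = np.flatnonzero(keep)
        keep[keep_idx[reject]] = False
    return SuperpositionResult(
        rotation=fit.rotation, translation=fit.translation, rmsd=fit.rmsd,
        n_pairs_used=int(keep.sum()), n_pairs_initial=n_initial,
        rejection_cycles=cycles,
    )


def trim_termini(
    model: StructureModel,
    keep_range: tuple[int, int] | dict[str, tuple[int, int]],
) -> StructureModel:
    """Remove atoms outside a per-chain residue range (indices preserved).

    ``keep_range`` is either one ``(start, end)`` applied to every chain or
    a chain-id → range mapping; chains absent from the mapping are kept
    whole.
    """
    if isinstance(keep_range, dict):
        ranges = keep_range
    else:
        ranges = {c: keep_range for c in model.chains()}
    for chain, (start, end) in ranges.items():
        if start > end:
            raise ValueError(f"chain {chain}: invalid range ({start},{end})")
    mask = np.ones(model.n_atoms, dtype=bool)
    for chain, (start, end) in ranges.items():
        in_chain = model.chain_ids == chain
        mask &= ~in_chain | ((model.res_indices >= start)
                             & (model.res_indices <= end))
    if not mask.any():
        raise ValueError("trim would remove every atom")
    return model.select(mask)


def rmsd_matrix(models: list[StructureModel], **kwargs) -> np.ndarray:
    """Pairwise refined-superposition RMSD matrix.

    The (i, j) and (j, i) fits can differ marginally through the rejection
    loop, so the matrix is symmetrized by averaging the two directions.
    """
    n = len(models)
    if n < 2:
        raise ValueError("need at least 2 models")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            fwd = refine_superposition(models[i], models[j], **kwargs).rmsd
            rev = refine_superposition(models[j], models[i], **kwargs).rmsd
            mat[i, j] = mat[j, i] = 0.5 * (fwd + rev)
    return mat


def compare_matrices(
    native: np.ndarray, qty: np.ndarray,
    labels: list[str] | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Compare two pairwise-RMSD matrices over their strict upper triangles.

    Returns the Pearson correlation, the mean absolute difference (Å), and
    a per-pair table sorted by decreasing |difference|.
    """
    native = np.asarray(native, dtype=float)
    qty = np.asarray(qty, dtype=float)
    if native.shape != qty.shape or native.ndim != 2:
        raise ValueError("matrices must share a square shape")
    iu = np.triu_indices(native.shape[0], k=1)
    x, y = native[iu], qty[iu]
    r = float(stats.pearsonr(x, y).statistic) if np.std(x) > 0 and np.std(y) > 0 else 1.0
    mad = float(np.abs(x - y).mean())
    if labels is None:
        labels = [str(i) for i in range(native.shape[0])]
    table = pd.DataFrame({
        "pair_a": [labels[i] for i in iu[0]],
        "pair_b": [labels[j] for j in iu[1]],
        "rmsd_native": x,
        "rmsd_qty": y,
        "difference": y - x,
    })
    table = table.reindex(
        table["difference"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
    return r, mad, table
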