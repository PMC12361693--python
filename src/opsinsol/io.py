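"""Plain-text format readers and writers: FASTA, parameter and report tables.

PDB I/O lives in :mod:`opsinsol.structure`; this module covers the
sequence and tabular side.  Output tables carry a provenance comment line
(tool version, seed, config hash) so a run can be traced.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .seq_metrics import DesignReport
from .traj_analysis import NonbondedParams

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_nonbonded_tsv",
    "write_nonbonded_tsv",
    "write_report_tsv",
    "write_series_tsv",
    "provenance_header",
]

FASTA_WRAP = 60

#: Fixed column order of the per-design characteristics table.
REPORT_COLUMNS = [
    "design_id", "variation_overall", "variation_tm",
    "mw_native", "mw_variant", "delta_mw",
    "pi_native", "pi_variant", "delta_pi",
]


def provenance_header(seed: int | None = None,
                      config_hash: str | None = None) -> str:
    from . import __version__
    parts = [f"opsinsol v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return "# " + " ".join(parts)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, residues) records.

    Sequences are uppercased (with a warning when lowercase was present);
    empty files and duplicate ids are errors.  The record id is the first
    whitespace-delimited token of the header.
    """
    records: list[tuple[str, str]] = []
    current_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal current_id, chunks
        if current_id is not None:
            records.append((current_id, "".join(chunks)))
        current_id, chunks = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if len(line) > 1 else ""
            else:
                if current_id is None:
                    raise ValueError(f"sequence data before a header in {path}")
                if line != line.upper():
                    warnings.warn("lowercase residues uppercased",
                                  stacklevel=2)
                chunks.append(line.upper())
    flush()
    if not records:
        raise ValueError(f"empty FASTA file: {path}")
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate record ids in {path}")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path,
                metadata: dict[str, dict[str, str]] | None = None) -> None:
    """Write FASTA wrapped at 60 columns.

    ``metadata`` optionally maps record id → key/value pairs appended to
    the header as ``key=value`` tokens (design provenance).
    """
    with open(path, "w") as fh:
        for rec_id, residues in records:
            header = rec_id
            if metadata and rec_id in metadata:
                header += " " + " ".join(
                    f"{k}={v}" for k, v in metadata[rec_id].items())
            fh.write(f">{header}\n")
            for i in range(0, len(residues), FASTA_WRAP):
                fh.write(residues[i:i + FASTA_WRAP] + "\n")


def read_nonbonded_tsv(path: str | Path, cutoff_nm: float = 1.2,
                       combination_rule: str = "lorentz-berthelot"
                       ) -> NonbondedParams:
    """Read a per-atom nonbonded parameter table.

    Columns: ``atom_index`` (0-based), ``charge_e``, ``sigma_nm``,
    ``epsilon_kj_mol``; rows may appear in any order but must cover
    0..n-1 without gaps.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"atom_index", "charge_e", "sigma_nm", "epsilon_kj_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parameter table missing columns {sorted(missing)}")
    df = df.sort_values("atom_index")
    if not np.array_equal(df["atom_index"].to_numpy(), np.arange(len(df))):
        raise ValueError("atom_index must cover 0..n-1 without gaps")
    return NonbondedParams(
        charges=df["charge_e"].to_numpy(),
        sigmas=df["sigma_nm"].to_numpy(),
        epsilons=df["epsilon_kj_mol"].to_numpy(),
        cutoff_nm=cutoff_nm,
        combination_rule=combination_rule,
    )


def write_nonbonded_tsv(params: NonbondedParams, path: str | Path) -> None:
    df = pd.DataFrame({
        "atom_index": np.arange(len(params.charges)),
        "charge_e": params.charges,
        "sigma_nm": params.sigmas,
        "epsilon_kj_mol": params.epsilons,
    })
    df.to_csv(path, sep="\t", index=False)


def write_report_tsv(reports: list[DesignReport], path: str | Path,
                     seed: int | None = None,
                     config_hash: str | None = None) -> pd.DataFrame:
    """Write the per-design characteristics table plus a min/max summary.

    Percentages and pI are rounded to 2 decimals, masses to 2 decimals in
    kDa; the summary rows hold the column-wise extremes over all designs.
    """
    rows = []
    for r in reports:
        rows.append({
            "design_id": r.design_id,
            "variation_overall": round(r.variation_overall, 2),
            "variation_tm": round(r.variation_tm, 2),
            "mw_native": round(r.mw_native, 2),
            "mw_variant": round(r.mw_variant, 2),
            "delta_mw": round(r.delta_mw, 2),
            "pi_native": round(r.pi_native, 2),
            "pi_variant": round(r.pi_variant, 2),
            "delta_pi": round(r.delta_pi, 2),
        })
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    numeric = df.columns.drop("design_id")
    summary = pd.DataFrame([
        {"design_id": "min", **df[numeric].min().to_dict()},
        {"design_id": "max", **df[numeric].max().to_dict()},
    ], columns=REPORT_COLUMNS)
    out = pd.concat([df, summary], ignore_index=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config_hash) + "\n")
        out.to_csv(fh, sep="\t", index=False)
    return out


def write_series_tsv(times_ps: np.ndarray, values: np.ndarray,
                     path: str | Path, value_name: str = "value",
                     metadata: dict | None = None) -> None:
    """Write a (time ps, value) series with provenance/metadata comments."""
    with open(path, "w") as fh:
        fh.write(provenance_header() + "\n")
        if metadata:
            for k, v in metadata.items():
                fh.write(f"# {k}={v}\n")
        pd.DataFrame({"time_ps": times_ps, value_name: values}) \
            .to_csv(fh, sep="\t", index=False)
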