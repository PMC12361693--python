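"""Atomic structure container and fixed-column PDB I/O.

``StructureModel`` is a flat, numpy-backed atom table: enough to superpose
models, measure surfaces and post-process trajectories, without carrying a
full topology object.  Residue numbering and chain ids are preserved as
read; multi-MODEL files become lists of models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from Bio.Data.IUPACData import protein_letters_3to1

__all__ = ["StructureModel", "read_pdb", "write_pdb", "three_to_one"]

_3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}


def three_to_one(res_name: str) -> str:
    """One-letter code for a three-letter residue name; 'X' if unknown."""
    return _3TO1.get(res_name.upper(), "X")


@dataclass
class StructureModel:
    """A set of atoms with names, residue assignment and coordinates in Å."""

    atom_names: np.ndarray      # str, shape (n,)
    elements: np.ndarray        # str, shape (n,)
    res_indices: np.ndarray     # int, 1-based, shape (n,)
    res_names: np.ndarray       # str, shape (n,)
    chain_ids: np.ndarray       # str, shape (n,)
    coords: np.ndarray          # float, shape (n, 3)
    occupancies: np.ndarray | None = None
    b_factors: np.ndarray | None = None
    is_hetero: np.ndarray | None = None
    model_id: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        n = len(self.coords)
        for name in ("atom_names", "elements", "res_indices", "res_names",
                     "chain_ids"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} atoms")
            setattr(self, name, arr)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.occupancies is None:
            self.occupancies = np.ones(n)
        if self.b_factors is None:
            self.b_factors = np.zeros(n)
        if self.is_hetero is None:
            self.is_hetero = np.zeros(n, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def select(self, mask: np.ndarray) -> "StructureModel":
        """Sub-model of the atoms where ``mask`` is true (order preserved)."""
        mask = np.asarray(mask)
        return StructureModel(
            atom_names=self.atom_names[mask],
            elements=self.elements[mask],
            res_indices=self.res_indices[mask],
            res_names=self.res_names[mask],
            chain_ids=self.chain_ids[mask],
            coords=self.coords[mask],
            occupancies=self.occupancies[mask],
            b_factors=self.b_factors[mask],
            is_hetero=self.is_hetero[mask],
            model_id=self.model_id,
        )

    def ca_mask(self, chain: str | None = None) -> np.ndarray:
        mask = (self.atom_names == "CA") & ~self.is_hetero
        if chain is not None:
            mask &= self.chain_ids == chain
        return mask

    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    def chains(self) -> list[str]:
        seen: list[str] = []
        for c in self.chain_ids:
            if c not in seen:
                seen.append(c)
        return seen

    def chain_sequence(self, chain: str | None = None) -> tuple[str, np.ndarray]:
        """One-letter sequence of a chain's Cα residues and their indices."""
        if chain is None:
            chain = self.chains()[0]
        mask = self.ca_mask(chain)
        res_idx = self.res_indices[mask]
        seq = "".join(three_to_one(rn) for rn in self.res_names[mask])
        return seq, res_idx

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "StructureModel":
        """Copy with coordinates mapped through x -> R·x + t."""
        out = self.select(np.ones(self.n_atoms, dtype=bool))
        out.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return out


def _parse_atom_line(line: str, lineno: int) -> tuple:
    try:
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip() or "A"
        res_idx = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            # fall back on the atom-name convention: first alphabetic char
            element = next((c for c in name if c.isalpha()), "C")
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed PDB record at line {lineno}: {line!r}") from exc
    return name, element.upper(), res_idx, res_name, chain, (x, y, z), occ, bfac


def read_pdb(path: str | Path) -> list[StructureModel]:
    """Read a fixed-column PDB file into one StructureModel per MODEL block.

    ATOM and HETATM records are kept (HETATM flagged); residue numbering,
    chain ids, occupancy and B-factor pass through untouched.  Files
    without MODEL records yield a single model.
    """
    models: list[StructureModel] = []
    rows: list[tuple] = []
    het: list[bool] = []
    model_id = 1

    def flush() -> None:
        nonlocal rows, het
        if rows:
            names, elements, ridx, rnames, chains, xyz, occ, bfac = zip(*rows)
            models.append(StructureModel(
                atom_names=np.array(names),
                elements=np.array(elements),
                res_indices=np.array(ridx, dtype=int),
                res_names=np.array(rnames),
                chain_ids=np.array(chains),
                coords=np.array(xyz, dtype=float),
                occupancies=np.array(occ, dtype=float),
                b_factors=np.array(bfac, dtype=float),
                is_hetero=np.array(het, dtype=bool),
                model_id=model_id,
            ))
        rows, het = [], []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                flush()
                try:
                    model_id = int(line[6:].split()[0])
                except (ValueError, IndexError):
                    model_id = len(models) + 1
            elif rec in ("ATOM  ", "HETATM"):
                rows.append(_parse_atom_line(line, lineno))
                het.append(rec == "HETATM")
            elif rec == "ENDMDL":
                flush()
                model_id = len(models) + 1
    flush()
    if not models:
        raise ValueError(f"no ATOM/HETATM records in {path}")
    return models


def write_pdb(models: StructureModel | list[StructureModel],
              path: str | Path, header: str | None = None) -> None:
    """Write one or more models in fixed-column PDB format.

    Coordinates are written to 3 decimals; multiple models are wrapped in
    MODEL/ENDMDL blocks.  ``header`` lines (if given) go out as REMARK
    records.
    """
    if isinstance(models, StructureModel):
        models = [models]
    multi = len(models) > 1
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"REMARK   1 {line}\n")
        for k, model in enumerate(models, start=1):
            if multi:
                fh.write(f"MODEL     {k:4d}\n")
            for i in range(model.n_atoms):
                rec = "HETATM" if model.is_hetero[i] else "ATOM  "
                name = str(model.atom_names[i])
                # standard PDB alignment: 1-char elements start in column 14
                padded = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = model.coords[i]
                fh.write(
                    f"{rec}{i + 1:5d} {padded:<4s} {model.res_names[i]:<3s}"
                    f" {model.chain_ids[i]:1s}{int(model.res_indices[i]):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{model.occupancies[i]:6.2f}"
                    f"{model.b_factors[i]:6.2f}          "
                    f"{str(model.elements[i]):>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
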