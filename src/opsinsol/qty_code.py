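"""QTY sequence redesign of transmembrane proteins.

The QTY code replaces the hydrophobic residues leucine, isoleucine, valine
and phenylalanine with glutamine, threonine, threonine and tyrosine
respectively — but only within annotated transmembrane (TM) alpha-helical
segments.  The substituted residues have side-chain electron densities
similar to the originals, so the redesign preserves helical geometry while
making the TM surface hydrophilic.

Coordinates for TM segments are 1-based inclusive throughout, matching the
UniProt feature convention.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "STANDARD_AA",
    "QTY_SUBSTITUTIONS",
    "AnnotatedSequence",
    "QtyDesign",
    "qty_map",
    "apply_qty",
    "parse_ss3",
    "parse_uniprot_tm",
]

#: The 20 standard amino acids (one-letter codes).
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: The QTY substitution map: hydrophobic -> hydrophilic structural analogue.
QTY_SUBSTITUTIONS = {"L": "Q", "I": "T", "V": "T", "F": "Y"}


class InvalidResidueError(ValueError):
    """A residue outside the 20 standard amino acids."""


@dataclass(frozen=True)
class AnnotatedSequence:
    """A protein sequence with transmembrane-helix annotations.

    Parameters
    ----------
    id
        Sequence identifier (e.g. a UniProt accession).
    residues
        One-letter amino-acid string over the 20 standard residues.
    tm_segments
        TM helix spans as ``(start, end)``, 1-based inclusive, sorted and
        non-overlapping.
    provenance
        Where the TM annotation came from: ``uniprot-feature``, ``ss3``
        or ``user``.
    """

    id: str
    residues: str
    tm_segments: tuple[tuple[int, int], ...] = ()
    provenance: str = "user"

    def __post_init__(self) -> None:
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise InvalidResidueError(
                f"{self.id!r}: non-standard residue(s) {sorted(bad)}"
            )
        object.__setattr__(self, "tm_segments", tuple(map(tuple, self.tm_segments)))
        n = len(self.residues)
        prev_end = 0
        for start, end in self.tm_segments:
            if not (1 <= start <= end <= n):
                raise ValueError(
                    f"{self.id!r}: segment ({start},{end}) outside 1..{n}"
                )
            if start <= prev_end:
                raise ValueError(
                    f"{self.id!r}: segments must be sorted and non-overlapping"
                )
            prev_end = end

    def __len__(self) -> int:
        return len(self.residues)

    def tm_mask(self) -> list[bool]:
        """Per-position flag (0-based list) of TM membership."""
        mask = [False] * len(self.residues)
        for start, end in self.tm_segments:
            for i in range(start - 1, end):
                mask[i] = True
        return mask

    @property
    def n_tm_residues(self) -> int:
        return sum(end - start + 1 for start, end in self.tm_segments)


@dataclass(frozen=True)
class QtyDesign:
    """A native/QTY-variant sequence pair with its substitution ledger."""

    native: AnnotatedSequence
    variant_residues: str
    substitutions: tuple[tuple[int, str, str], ...]  # (1-based pos, from, to)
    n_tm_residues: int = field(default=0)

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)

    def variant_annotated(self) -> AnnotatedSequence:
        """The variant as an AnnotatedSequence carrying the native's segments."""
        return AnnotatedSequence(
            id=f"{self.native.id}_QTY",
            residues=self.variant_residues,
            tm_segments=self.native.tm_segments,
            provenance=self.native.provenance,
        )


def qty_map(residue: str, in_tm: bool) -> str:
    """Map a single residue under the QTY code.

    Returns Q/T/T/Y for L/I/V/F when ``in_tm`` is true; otherwise returns
    the residue unchanged.  Residues outside the 20 standard amino acids
    (including B, Z, X, U, O) are rejected.
    """
    if residue not in STANDARD_AA:
        raise InvalidResidueError(f"non-standard residue {residue!r}")
    if in_tm:
        return QTY_SUBSTITUTIONS.get(residue, residue)
    return residue


def apply_qty(seq: AnnotatedSequence) -> QtyDesign:
    """Apply the QTY code to every TM segment of ``seq``.

    The variant differs from the native exactly at TM positions holding
    L, I, V or F; all other positions — including hydrophobic A/M/W inside
    TM segments — are untouched.
    """
    if len(seq.residues) == 0:
        raise ValueError("empty sequence")
    mask = seq.tm_mask()
    variant = []
    subs: list[tuple[int, str, str]] = []
    for i, res in enumerate(seq.residues):
        new = qty_map(res, mask[i])
        variant.append(new)
        if new != res:
            subs.append((i + 1, res, new))
    return QtyDesign(
        native=seq,
        variant_residues="".join(variant),
        substitutions=tuple(subs),
        n_tm_residues=seq.n_tm_residues,
    )


def parse_ss3(ss3: str, min_helix_len: int = 5) -> list[tuple[int, int]]:
    """Extract helix segments from an SS3 secondary-structure string.

    ``ss3`` is a string over {H, E, C}.  Maximal runs of 'H' of length
    >= ``min_helix_len`` are returned as 1-based inclusive ``(start, end)``
    segments.  The default minimum of 5 suppresses spurious 1–2 residue
    helix calls.
    """
    if min_helix_len < 1:
        raise ValueError("min_helix_len must be >= 1")
    bad = set(ss3) - set("HEC")
    if bad:
        raise ValueError(f"SS3 string may only contain H/E/C, got {sorted(bad)}")
    segments = []
    for m in re.finditer(r"H+", ss3):
        if m.end() - m.start() >= min_helix_len:
            segments.append((m.start() + 1, m.end()))
    return segments


_TM_RANGE = re.compile(r"TRANSMEM\s+(\S+)")


def parse_uniprot_tm(feature_table: str) -> list[tuple[int, int]]:
    """Extract TRANSMEM segments from a UniProt-style feature table.

    Accepts flat-file ``FT TRANSMEM 37..61`` lines as well as GFF-style
    lines where the type column is ``TRANSMEM`` followed by start/end
    columns.  Returns sorted 1-based inclusive segments; a table with no
    TRANSMEM features yields an empty list with a warning.
    """
    segments: list[tuple[int, int]] = []
    for line in feature_table.splitlines():
        if "TRANSMEM" not in line:
            continue
        fields = line.split()
        idx = fields.index("TRANSMEM")
        rest = fields[idx + 1 :]
        if not rest:
            raise ValueError(f"TRANSMEM feature without coordinates: {line!r}")
        if ".." in rest[0]:
            start_s, end_s = rest[0].split("..", 1)
        elif len(rest) >= 2:
            start_s, end_s = rest[0], rest[1]
        else:
            raise ValueError(f"cannot parse TRANSMEM coordinates: {line!r}")
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(
                f"malformed TRANSMEM coordinates in line: {line!r}"
            ) from exc
        if start < 1 or end < start:
            raise ValueError(f"invalid TRANSMEM range {start}..{end}")
        segments.append((start, end))
    if not segments:
        warnings.warn("no TRANSMEM features found", stacklevel=2)
    return sorted(segments)
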