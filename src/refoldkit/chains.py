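"""In-memory representation of a single protein chain.

The whole pipeline operates on one chain at a time: a one-letter sequence,
per-residue C-alpha coordinates, optionally the remaining backbone heavy
atoms (N, C, O — needed only for secondary-structure assignment) and a
per-residue confidence (pLDDT) on the 0–100 scale.  Internal indexing is
0-based and contiguous; author residue numbering from a PDB file is kept
as metadata only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: order of the extra backbone atoms stored per residue in ``backbone_coords``
BACKBONE_ATOMS = ("N", "C", "O")

#: physically plausible range for consecutive CA–CA distances (Å)
CA_CA_RANGE = (2.8, 4.2)

AA1 = "ACDEFGHIKLMNPQRSTVWY"

AA3_TO_1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
    "UNK": "X", "MSE": "M", "SEC": "U", "PYL": "O",
}
AA1_TO_3 = {v: k for k, v in reversed(AA3_TO_1.items())}


class ChainError(ValueError):
    """Raised for malformed or inconsistent chain data."""


@dataclass
class ChainStructure:
    """One protein chain: sequence, coordinates, optional confidence.

    Parameters
    ----------
    id : str
        Identifier (free text; typically filename stem plus chain id).
    sequence : str
        One-letter amino-acid sequence, length L.
    ca_coords : (L, 3) float array
        C-alpha coordinates in Å, one row per residue, in chain order.
    residue_numbers : list of str, optional
        Author residue identifiers (number + insertion code) as metadata.
    backbone_coords : (L, 3, 3) float array, optional
        N, C, O coordinates per residue (axis 1 ordered as
        :data:`BACKBONE_ATOMS`).  Required only for secondary-structure
        assignment.
    plddt : (L,) float array, optional
        Per-residue confidence on the 0–100 scale.
    """

    id: str
    sequence: str
    ca_coords: np.ndarray
    residue_numbers: list[str] | None = None
    backbone_coords: np.ndarray | None = None
    plddt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ChainError("ca_coords must have shape (L, 3)")
        L = len(self.sequence)
        if self.ca_coords.shape[0] != L:
            raise ChainError(
                f"sequence length {L} != number of CA coordinates "
                f"{self.ca_coords.shape[0]}"
            )
        if not np.all(np.isfinite(self.ca_coords)):
            raise ChainError("non-finite CA coordinates")
        if self.backbone_coords is not None:
            self.backbone_coords = np.asarray(self.backbone_coords, dtype=float)
            if self.backbone_coords.shape != (L, 3, 3):
                raise ChainError("backbone_coords must have shape (L, 3, 3)")
            if not np.all(np.isfinite(self.backbone_coords)):
                raise ChainError("non-finite backbone coordinates")
        if self.plddt is not None:
            self.plddt = np.asarray(self.plddt, dtype=float)
            if self.plddt.shape != (L,):
                raise ChainError("plddt must have one value per residue")
            if np.any(self.plddt < 0) or np.any(self.plddt > 100):
                raise ChainError("plddt values must lie in [0, 100]")
        if self.residue_numbers is not None and len(self.residue_numbers) != L:
            raise ChainError("residue_numbers length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)

    def check_geometry(self, warn: bool = True) -> bool:
        """Check consecutive CA–CA distances against :data:`CA_CA_RANGE`.

        Returns True when all consecutive distances are plausible; on
        violation either warns (default, for ingested files) or stays
        silent — callers that construct chains synthetically assert on
        the return value instead.
        """
        if len(self) < 2:
            return True
        d = np.linalg.norm(np.diff(self.ca_coords, axis=0), axis=1)
        ok = bool(np.all((d >= CA_CA_RANGE[0]) & (d <= CA_CA_RANGE[1])))
        if not ok and warn:
            bad = int(np.sum((d < CA_CA_RANGE[0]) | (d > CA_CA_RANGE[1])))
            warnings.warn(
                f"chain {self.id!r}: {bad} consecutive CA-CA distance(s) "
                f"outside {CA_CA_RANGE} Å",
                stacklevel=2,
            )
        return ok

    def slice(self, start: int, stop: int, new_id: str | None = None) -> "ChainStructure":
        """Return the contiguous residue range ``[start, stop)`` as a new chain."""
        if not (0 <= start < stop <= len(self)):
            raise ChainError(f"invalid slice [{start}, {stop}) for length {len(self)}")
        return ChainStructure(
            id=new_id if new_id is not None else self.id,
            sequence=self.sequence[start:stop],
            ca_coords=self.ca_coords[start:stop].copy(),
            residue_numbers=(
                self.residue_numbers[start:stop]
                if self.residue_numbers is not None else None
            ),
            backbone_coords=(
                self.backbone_coords[start:stop].copy()
                if self.backbone_coords is not None else None
            ),
            plddt=self.plddt[start:stop].copy() if self.plddt is not None else None,
        )
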