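"""Read and write protein chain structures (PDB) and sequences (FASTA).

PDB handling is deliberately narrow: ATOM records only, HETATM skipped,
alternate locations resolved by first occurrence, insertion codes kept in
the residue-number metadata.  Predicted-model files — the dominant input
of a refolding pipeline — have none of those complications, and real
files degrade gracefully.  Per-residue confidence (pLDDT) travels in the
B-factor column; values on the 0–1 scale (the ESMfold convention) are
auto-scaled to 0–100 (the AF2 convention) on ingest.
"""

from __future__ import annotations

import os
from pathlib import Path

import gemmi
from Bio import SeqIO

from .chains import AA1, AA1_TO_3, AA3_TO_1, ChainStructure, ChainError

__all__ = ["read_chain", "write_chain", "read_fasta", "write_fasta"]


class StructureIOError(ValueError):
    pass


def read_chain(
    path: str | os.PathLike,
    chain: str | None = None,
    plddt_from_bfactor: bool = True,
) -> ChainStructure:
    """Read one chain from a PDB file into a :class:`ChainStructure`.

    Parameters
    ----------
    path
        PDB-format file with at least one ATOM record for the chain.
    chain
        Chain identifier; ``None`` selects the first chain in the file.
    plddt_from_bfactor
        When True, the CA B-factor populates the per-residue confidence;
        if every ingested value is ≤ 1.0 the profile is multiplied by
        100 (scale auto-detection).
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    structure = gemmi.read_pdb(str(path))
    if len(structure) == 0:
        raise StructureIOError(f"{path}: no models")
    model = structure[0]
    if chain is None:
        if len(model) == 0:
            raise StructureIOError(f"{path}: no chains")
        gchain = model[0]
    else:
        gchain = model.find_chain(chain)
        if gchain is None:
            available = ", ".join(ch.name for ch in model)
            raise StructureIOError(
                f"{path}: chain {chain!r} not found (available: {available})"
            )

    sequence: list[str] = []
    resnums: list[str] = []
    cas: list[list[float]] = []
    bb: list[list[list[float]]] = []
    bfac: list[float] = []
    have_bb = True
    for res in gchain:
        if res.het_flag == "H":  # skip HETATM (waters, ligands)
            continue
        ca = res.find_atom("CA", "*")
        if ca is None:
            raise StructureIOError(
                f"{path}: residue {res.name} {res.seqid} has no CA atom"
            )
        sequence.append(AA3_TO_1.get(res.name.upper(), "X"))
        icode = res.seqid.icode.strip()
        resnums.append(f"{res.seqid.num}{icode}")
        cas.append([ca.pos.x, ca.pos.y, ca.pos.z])
        bfac.append(ca.b_iso)
        atoms = [res.find_atom(name, "*") for name in ("N", "C", "O")]
        if any(a is None for a in atoms):
            have_bb = False
        elif have_bb:
            bb.append([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
    if not sequence:
        raise StructureIOError(f"{path}: selected chain has no ATOM records")

    plddt = None
    if plddt_from_bfactor:
        plddt = bfac
        if max(bfac) <= 1.0:
            plddt = [b * 100.0 for b in bfac]
        plddt = [min(max(b, 0.0), 100.0) for b in plddt]

    out = ChainStructure(
        id=f"{path.stem}:{gchain.name}",
        sequence="".join(sequence),
        ca_coords=cas,
        residue_numbers=resnums,
        backbone_coords=bb if (have_bb and len(bb) == len(sequence)) else None,
        plddt=plddt,
    )
    out.check_geometry(warn=True)
    return out


def write_chain(s: ChainStructure, path: str | os.PathLike) -> None:
    """Write a chain as PDB ATOM records.

    CA always; N/C/O when backbone coordinates are present.  The
    confidence profile (or 0.00) goes to the B-factor column with two
    decimals; serial numbers are 1-based.
    """
    if len(s) == 0:
        raise StructureIOError("empty structure")
    path = Path(path)
    lines = []
    serial = 0
    for i, aa in enumerate(s.sequence):
        resname = AA1_TO_3.get(aa, "UNK")
        b = float(s.plddt[i]) if s.plddt is not None else 0.0
        atoms = [("CA", s.ca_coords[i], "C")]
        if s.backbone_coords is not None:
            n, c, o = s.backbone_coords[i]
            atoms = [("N", n, "N"), ("CA", s.ca_coords[i], "C"),
                     ("C", c, "C"), ("O", o, "O")]
        for name, xyz, elem in atoms:
            serial += 1
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} A{i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{b:6.2f}"
                f"          {elem:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)`` pairs in file order.

    Duplicate ids and symbols outside the 20 standard amino acids plus X
    are rejected.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    allowed = set(AA1) | {"X"}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise StructureIOError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - allowed
        if bad:
            raise StructureIOError(
                f"record {rec.id!r}: invalid symbol(s) {sorted(bad)}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | os.PathLike, width: int = 60) -> None:
    """Write ``(id, sequence)`` pairs as FASTA with fixed-width wrapping."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
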