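"""Randomized mutagenesis panels: "badly designed" sequences at controlled identity.

Starting from a parent sequence, a fixed fraction of positions is chosen
uniformly without replacement and each is substituted by one of the 19
standard amino acids other than the parent residue, so the nominal and
realized mutation loads coincide exactly.  Panels over many parents,
fractions and replicates are reproducible from a single master seed via
hash-derived per-replicate seeds.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chains import AA1
from .structure_io import write_fasta

__all__ = [
    "MutantSet",
    "mutate_sequence",
    "generate_mutant_panel",
    "sequence_identity",
    "panel_to_fasta",
    "panel_manifest",
]


@dataclass
class MutantSet:
    """All replicates of one (parent, mutation fraction) condition."""

    parent_id: str
    parent_seq: str
    fraction: float
    replicates: list[tuple[str, tuple[int, ...]]]
    seed: int


def _derive_seed(master_seed: int, parent_id: str, fraction: float, replicate: int) -> int:
    """Stable 31-bit seed from the panel coordinates (not Python's hash())."""
    key = f"{master_seed}|{parent_id}|{fraction:.10f}|{replicate}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def mutate_sequence(
    parent: str,
    fraction: float,
    rng: np.random.Generator,
) -> tuple[str, tuple[int, ...]]:
    """Substitute ``round(fraction × L)`` positions of ``parent``.

    Positions are drawn uniformly without replacement; each substitution
    is drawn uniformly from the 19 standard amino acids excluding the
    parent residue, so the realized mutation count is exact.  A positive
    fraction mutates at least one position.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    bad = set(parent) - set(AA1)
    if bad:
        raise ValueError(f"non-standard residue(s) in parent: {sorted(bad)}")
    L = len(parent)
    k = int(np.floor(fraction * L + 0.5))
    if fraction > 0 and k == 0:
        k = 1
    if k == 0:
        return parent, ()
    positions = np.sort(rng.choice(L, size=k, replace=False))
    mutant = list(parent)
    for pos in positions:
        alternatives = [aa for aa in AA1 if aa != parent[pos]]
        mutant[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(mutant), tuple(int(p) for p in positions)


def generate_mutant_panel(
    parents: list[tuple[str, str]],
    fractions: list[float],
    replicates: int,
    master_seed: int,
) -> list[MutantSet]:
    """One :class:`MutantSet` per (parent, fraction), ``replicates`` deep.

    Per-replicate RNGs are seeded from a stable hash of
    ``(master_seed, parent_id, fraction, replicate index)``, so any slice
    of the panel can be regenerated independently.  Total sequence count
    is ``len(parents) × len(fractions) × replicates``.
    """
    if not parents or not fractions:
        raise ValueError("parents and fractions must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ids = [pid for pid, _ in parents]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate parent id(s): {dupes}")
    panel = []
    for parent_id, parent_seq in parents:
        for fraction in fractions:
            reps = []
            for rep in range(replicates):
                seed = _derive_seed(master_seed, parent_id, fraction, rep)
                rng = np.random.default_rng(seed)
                reps.append(mutate_sequence(parent_seq, fraction, rng))
            panel.append(
                MutantSet(
                    parent_id=parent_id,
                    parent_seq=parent_seq,
                    fraction=fraction,
                    replicates=reps,
                    seed=master_seed,
                )
            )
    return panel


def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical residues between two equal-length sequences.

    When either sequence carries gaps the rows are treated as aligned and
    identity is computed over columns where both are non-gap; with no
    comparable columns the identity is 0.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if "-" in a or "-" in b:
        pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
        if not pairs:
            return 0.0
        return sum(x == y for x, y in pairs) / len(pairs)
    if not a:
        raise ValueError("empty sequences")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def panel_to_fasta(panel: list[MutantSet], path: str | os.PathLike) -> None:
    """Write every replicate as FASTA: ``<parent>|f<fraction>|r<replicate>``."""
    records = []
    for ms in panel:
        for rep, (seq, _) in enumerate(ms.replicates):
            records.append((f"{ms.parent_id}|f{ms.fraction:g}|r{rep}", seq))
    write_fasta(records, path)


def panel_manifest(panel: list[MutantSet]) -> pd.DataFrame:
    """Manifest table: parent, fraction, replicate, 1-based mutated positions."""
    rows = []
    for ms in panel:
        for rep, (_, positions) in enumerate(ms.replicates):
            rows.append(
                {
                    "parent_id": ms.parent_id,
                    "fraction": ms.fraction,
                    "replicate": rep,
                    "mutated_positions": ";".join(str(p + 1) for p in positions),
                }
            )
    return pd.DataFrame(rows)
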