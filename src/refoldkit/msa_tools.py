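"""MSA handling: A3M/aligned-FASTA parsing, column masking, and Neff.

An :class:`MSA` stores the ungapped query plus homolog rows mapped to
the query's column space (A3M lowercase insertions are stripped on
load).  Column masking replaces whole alignment columns with the token
X — the device used to remove native sequence context from an MSA while
keeping its depth.  The effective sequence count (Neff) is computed per
position as the sum of redundancy-corrected sequence weights over rows
with a non-gap residue at that position, summarized by the median over
positions; a sequence's weight is the reciprocal of the number of rows
(itself included) within a fractional-identity threshold of it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .chains import AA1
from .mutagenesis import sequence_identity

__all__ = ["MSA", "read_msa", "write_msa", "mask_columns", "sequence_weights", "median_neff"]

_MSA_ALPHABET = set(AA1) | {"X", "-"}


@dataclass
class MSA:
    """Query plus homolog rows, all in the query's column space."""

    query: str
    rows: list[str] = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        if not self.query:
            raise ValueError("empty query")
        L = len(self.query)
        for i, row in enumerate(self.rows):
            if len(row) != L:
                raise ValueError(
                    f"row {i} has length {len(row)}, query has {L} (ragged MSA)"
                )
            bad = set(row) - _MSA_ALPHABET
            if bad:
                raise ValueError(f"row {i}: invalid symbol(s) {sorted(bad)}")
        bad = set(self.query) - _MSA_ALPHABET
        if bad:
            raise ValueError(f"query: invalid symbol(s) {sorted(bad)}")

    @property
    def depth(self) -> int:
        """Number of sequences including the query."""
        return 1 + len(self.rows)

    def all_rows(self) -> list[str]:
        return [self.query, *self.rows]


def read_msa(path: str | os.PathLike, format: str = "a3m") -> MSA:
    """Load an alignment; the first record is the query.

    ``a3m``: lowercase characters are insertions relative to the query
    and are removed.  ``afa`` (aligned FASTA): columns where the query
    has a gap are dropped so every row lands in query coordinates.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    headers: list[str] = []
    seqs: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            headers.append(line[1:])
            seqs.append("")
        else:
            if not headers:
                raise ValueError(f"{path}: sequence data before first header")
            seqs[-1] += line
    if not seqs:
        raise ValueError(f"{path}: empty alignment")

    if format == "a3m":
        query = seqs[0].upper().replace("-", "").replace(".", "")
        rows = [
            "".join(c for c in s if not c.islower()).replace(".", "-").upper()
            for s in seqs[1:]
        ]
    elif format == "afa":
        qaln = seqs[0].upper()
        keep = [i for i, c in enumerate(qaln) if c != "-"]
        query = "".join(qaln[i] for i in keep)
        rows = ["".join(s.upper()[i] for i in keep) if len(s) == len(qaln) else s
                for s in seqs[1:]]
        for i, (r, s) in enumerate(zip(rows, seqs[1:])):
            if len(s) != len(qaln):
                raise ValueError(f"{path}: row {i + 1} is ragged")
    else:
        raise ValueError(f"unknown MSA format {format!r}")
    return MSA(query=query, rows=rows, source=str(path))


def write_msa(msa: MSA, path: str | os.PathLike, ids: list[str] | None = None) -> None:
    """Write the MSA back out in A3M form (query first, all uppercase)."""
    if ids is None:
        ids = ["query"] + [f"seq{i + 1}" for i in range(len(msa.rows))]
    if len(ids) != msa.depth:
        raise ValueError("need one id per sequence (query included)")
    with open(path, "w") as fh:
        for rid, seq in zip(ids, msa.all_rows()):
            fh.write(f">{rid}\n{seq}\n")


def mask_columns(msa: MSA, positions, mask_query: bool = False) -> MSA:
    """Replace whole alignment columns with the token X.

    Every homolog row character at the listed query positions becomes X;
    the query row is masked only when ``mask_query`` is set (keeping the
    first row equal to the exact input sequence by default, as structure
    predictors require).  The input MSA is not modified.
    """
    positions = sorted(set(int(p) for p in positions))
    L = len(msa.query)
    for p in positions:
        if not 0 <= p < L:
            raise ValueError(f"position {p} outside [0, {L})")
    pos_set = set(positions)

    def mask_row(row: str) -> str:
        return "".join("X" if i in pos_set else c for i, c in enumerate(row))

    return MSA(
        query=mask_row(msa.query) if mask_query else msa.query,
        rows=[mask_row(r) for r in msa.rows],
        source=msa.source,
    )


def sequence_weights(msa: MSA, identity_threshold: float = 0.8) -> np.ndarray:
    """Redundancy weights: 1 / (number of rows within the identity threshold).

    Identity is computed over mutually non-gap columns; the count
    includes the sequence itself, so weights lie in (0, 1].  The query is
    row 0.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must lie in (0, 1]")
    rows = msa.all_rows()
    n = len(rows)
    counts = np.ones(n, dtype=int)  # self always counts
    for i in range(n):
        for j in range(i + 1, n):
            if sequence_identity(rows[i], rows[j]) >= identity_threshold:
                counts[i] += 1
                counts[j] += 1
    return 1.0 / counts


def median_neff(msa: MSA, identity_threshold: float = 0.8) -> float:
    """Median over query positions of the per-position effective depth.

    Per position, Neff is the sum of sequence weights over rows (query
    included) carrying a non-gap residue there.
    """
    weights = sequence_weights(msa, identity_threshold)
    rows = msa.all_rows()
    L = len(msa.query)
    per_position = np.zeros(L)
    for w, row in zip(weights, rows):
        nongap = np.frombuffer(row.encode(), dtype=np.uint8) != ord("-")
        per_position += w * nongap
    return float(np.median(per_position))
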