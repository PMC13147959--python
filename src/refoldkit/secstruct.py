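"""Three-state secondary-structure assignment from backbone geometry.

A simplified dictionary-of-protein-secondary-structure assigner: amide
hydrogens are inferred from the preceding residue's C=O (placed on N,
1.01 Å, pointing away from the carbonyl oxygen), a backbone hydrogen
bond between CO(i) and NH(j) is declared when the Kabsch–Sander
electrostatic energy

    E = 0.084 · (1/d_ON + 1/d_CH − 1/d_OH − 1/d_CN) · 332  kcal/mol

falls below −0.5, two consecutive i→i+4 turns mark an α-helix (H),
parallel/antiparallel bridge patterns mark strand (E), and everything
else is coil (C).  3-10/π helices, turns and bends are collapsed into
coil; isolated β-bridges into strand.  Chains are split at CA–CA breaks
(> 4.5 Å) before assignment, and segments shorter than five residues are
coil by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chains import ChainStructure

__all__ = [
    "SecondaryStructureString",
    "assign_secondary_structure",
    "ss_composition",
    "helix_content_filter",
]

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
CHAIN_BREAK_CUTOFF = 4.5  # Å between consecutive CA atoms
_Q1Q2_F = 0.084 * 332.0


@dataclass
class SecondaryStructureString:
    """Per-residue states over {H, E, C} for one chain."""

    states: str
    source: str = ""

    def __post_init__(self):
        bad = set(self.states) - {"H", "E", "C"}
        if bad:
            raise ValueError(f"invalid state symbol(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)


def _hbond_energies(n: np.ndarray, ca: np.ndarray, c: np.ndarray, o: np.ndarray) -> np.ndarray:
    """Energy matrix E[i, j] for the CO of residue i and the NH of residue j.

    Residue 0 has no amide hydrogen (no preceding carbonyl), and pairs
    closer than two residues apart are excluded.
    """
    L = len(ca)
    # amide H on N, 1.01 Å along the direction opposite the preceding C=O
    h = np.full((L, 3), np.nan)
    co = c[:-1] - o[:-1]
    co /= np.linalg.norm(co, axis=1, keepdims=True)
    h[1:] = n[1:] + 1.01 * co

    E = np.full((L, L), np.inf)
    for j in range(1, L):
        d_on = np.linalg.norm(o - n[j], axis=1)
        d_ch = np.linalg.norm(c - h[j], axis=1)
        d_oh = np.linalg.norm(o - h[j], axis=1)
        d_cn = np.linalg.norm(c - n[j], axis=1)
        with np.errstate(divide="ignore"):
            E[:, j] = _Q1Q2_F * (1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn)
    for i in range(L):
        lo = max(0, i - 1)
        E[i, lo:i + 2] = np.inf
    return E


def _assign_segment(n, ca, c, o) -> str:
    L = len(ca)
    if L < 5:
        return "C" * L
    hbond = _hbond_energies(n, ca, c, o) < HBOND_ENERGY_CUTOFF

    states = np.full(L, "C", dtype="<U1")

    # α-helix: two consecutive i→i+4 turns cover residues i+1..i+4
    turn4 = np.zeros(L, dtype=bool)
    for i in range(L - 4):
        turn4[i] = hbond[i, i + 4]
    for i in range(L - 5):
        if turn4[i] and turn4[i + 1]:
            states[i + 1:i + 5] = "H"

    # β-bridges (parallel and antiparallel), |i − j| ≥ 3
    def hb(i, j):
        return 0 <= i < L and 0 <= j < L and hbond[i, j]

    bridge = np.zeros(L, dtype=bool)
    for i in range(L):
        for j in range(i + 3, L):
            parallel = (hb(i - 1, j) and hb(j, i + 1)) or (hb(j - 1, i) and hb(i, j + 1))
            anti = (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1))
            if parallel or anti:
                bridge[i] = bridge[j] = True
    for i in range(L):
        if bridge[i] and states[i] == "C":
            states[i] = "E"
    return "".join(states)


def assign_secondary_structure(s: ChainStructure) -> SecondaryStructureString:
    """Assign H/E/C per residue from N/CA/C/O geometry."""
    if s.backbone_coords is None:
        raise ValueError(f"chain {s.id!r} has no backbone (N/C/O) coordinates")
    ca = s.ca_coords
    n = s.backbone_coords[:, 0]
    c = s.backbone_coords[:, 1]
    o = s.backbone_coords[:, 2]

    # split at chain breaks so H-bond patterns never span a gap
    breaks = [0]
    for i in range(1, len(ca)):
        if np.linalg.norm(ca[i] - ca[i - 1]) > CHAIN_BREAK_CUTOFF:
            breaks.append(i)
    breaks.append(len(ca))

    parts = []
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        parts.append(_assign_segment(n[lo:hi], ca[lo:hi], c[lo:hi], o[lo:hi]))
    return SecondaryStructureString(states="".join(parts), source=s.id)


def ss_composition(ss: SecondaryStructureString) -> tuple[float, float, float]:
    """(helix %, strand %, coil %) over all residues; sums to 100."""
    L = len(ss)
    if L == 0:
        raise ValueError("empty secondary-structure string")
    h = 100.0 * ss.states.count("H") / L
    e = 100.0 * ss.states.count("E") / L
    return h, e, 100.0 - h - e


def helix_content_filter(
    structures: list[ChainStructure],
    lo: float = 30.0,
    hi: float = 60.0,
) -> list[ChainStructure]:
    """Keep structures whose helix percentage lies in [lo, hi] (inclusive)."""
    if lo > hi:
        raise ValueError("lo must be <= hi")
    kept = []
    for s in structures:
        h, _, _ = ss_composition(assign_secondary_structure(s))
        if lo <= h <= hi:
            kept.append(s)
    return kept
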