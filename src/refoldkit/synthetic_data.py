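"""Synthetic inputs for every pipeline stage.

Folding models are GPU tools; this module generates structurally
realistic stand-ins for everything they would produce, so the whole
evaluation pipeline is testable at desk scale:

* idealized backbones (N/CA/C/O) built from per-state dihedrals —
  α-helix (φ, ψ) = (−57°, −47°), β-strand (−119°, 113°), coil drawn from
  a broad extended/polyproline-like region — with standard bond lengths
  and angles, so consecutive CA–CA distances sit at the trans-peptide
  3.8 Å;
* "predicted model" analogs: a rigid core perturbed by small isotropic
  Gaussian noise, plus flexible terminal tails re-posed into a divergent
  conformation (rigid hinge rotation or a fresh random walk), with
  region-wise Gaussian pLDDT profiles — the geometry that makes plain
  mean scRMSD misleading and the outlier-corrected median informative;
* MSAs of controlled depth, divergence and gap rate;
* binary experimental outcomes whose log-odds are a logistic function of
  the design metrics.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chains import AA1, ChainStructure
from .designability import DesignRecord
from .msa_tools import MSA
from .oracle_eval import OutcomeTable

__all__ = [
    "SyntheticSpec",
    "OutcomeModel",
    "make_ideal_backbone",
    "simulate_prediction",
    "make_refolding_pair",
    "simulate_msa",
    "simulate_outcomes",
    "simulate_design_records",
]

# standard backbone internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0

DIHEDRALS = {"H": (-57.0, -47.0), "E": (-119.0, 113.0)}
# coil: mixture over the allowed Ramachandran basins (weight, phi range, psi range),
# giving semi-compact random-coil geometry rather than a straight rod
COIL_BASINS = (
    (0.45, (-160.0, -60.0), (90.0, 180.0)),   # extended / PP-II
    (0.40, (-100.0, -50.0), (-60.0, 0.0)),    # alpha basin
    (0.15, (40.0, 80.0), (0.0, 60.0)),        # left-handed alpha
)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic target/prediction pair.

    ``core_length`` residues form the rigid, well-predicted core;
    ``tail_lengths = (n_term, c_term)`` coil residues are appended and
    re-posed in the prediction according to ``tail_mode``.  The defaults
    emulate a full-length predicted model whose deposited counterpart
    lacks a 20-residue flexible terminus: 0.5 Å isotropic core noise, a
    90° hinged C-terminal tail, confident core (pLDDT ≈ 90) and
    low-confidence tail (≈ 60).
    """

    core_length: int = 80
    tail_lengths: tuple[int, int] = (0, 20)
    ss_layout: tuple[tuple[str, int], ...] | None = None
    core_noise_sigma: float = 0.5
    tail_mode: str = "hinge"  # none | hinge | random-walk
    hinge_angle: float = 90.0
    plddt_model: tuple[float, float, float] = (90.0, 60.0, 5.0)  # core, tail, sd
    seed: int = 0

    def __post_init__(self):
        if self.core_length < 0 or min(self.tail_lengths) < 0:
            raise ValueError("lengths must be >= 0")
        if self.core_noise_sigma < 0:
            raise ValueError("core_noise_sigma must be >= 0")
        if self.tail_mode not in ("none", "hinge", "random-walk"):
            raise ValueError(f"unknown tail_mode {self.tail_mode!r}")
        core_mean, tail_mean, _ = self.plddt_model
        if not (0 <= core_mean <= 100 and 0 <= tail_mean <= 100):
            raise ValueError("plddt means must lie in [0, 100]")

    @property
    def total_length(self) -> int:
        return self.core_length + sum(self.tail_lengths)


@dataclass
class OutcomeModel:
    """Logistic model linking design metrics to experimental success."""

    intercept: float = 0.0
    beta_plddt: float = 0.0   # per pLDDT unit
    beta_scrmsd: float = 0.0  # per Å
    seed: int = 0


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-of-reference-frame placement of the next atom."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _expand_layout(ss_layout) -> str:
    states = "".join(state * int(length) for state, length in ss_layout)
    bad = set(states) - {"H", "E", "C"}
    if bad:
        raise ValueError(f"unknown state(s) {sorted(bad)} in layout")
    return states


def make_ideal_backbone(ss_layout, seed: int = 0) -> ChainStructure:
    """Build an ideal N/CA/C/O backbone from a segment layout.

    ``ss_layout`` is a list of ``(state, length)`` with states H/E/C;
    dihedrals per state are fixed (helix, strand) or drawn from a broad
    coil distribution (seeded).  The sequence is drawn uniformly from
    the 20 standard amino acids.
    """
    states = _expand_layout(ss_layout)
    L = len(states)
    if L < 2:
        raise ValueError("layout must total at least 2 residues")
    rng = np.random.default_rng(seed)

    weights = np.array([w for w, _, _ in COIL_BASINS])

    def dihedrals_for(state: str) -> tuple[float, float]:
        if state in DIHEDRALS:
            return DIHEDRALS[state]
        _, phi_range, psi_range = COIL_BASINS[rng.choice(len(COIL_BASINS), p=weights)]
        return (rng.uniform(*phi_range), rng.uniform(*psi_range))

    phi_psi = [dihedrals_for(s) for s in states]

    n_at = np.zeros((L, 3))
    ca_at = np.zeros((L, 3))
    c_at = np.zeros((L, 3))
    a_nca = np.deg2rad(ANGLE_N_CA_C)
    n_at[0] = (0.0, 0.0, 0.0)
    ca_at[0] = (BOND_N_CA, 0.0, 0.0)
    c_at[0] = ca_at[0] + BOND_CA_C * np.array([-np.cos(a_nca), np.sin(a_nca), 0.0])
    for i in range(1, L):
        psi_prev = phi_psi[i - 1][1]
        n_at[i] = _place_atom(n_at[i - 1], ca_at[i - 1], c_at[i - 1],
                              BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_at[i] = _place_atom(ca_at[i - 1], c_at[i - 1], n_at[i],
                               BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_at[i] = _place_atom(c_at[i - 1], n_at[i], ca_at[i],
                              BOND_CA_C, ANGLE_N_CA_C, phi_psi[i][0])

    # carbonyl O in the peptide plane, bisecting CA-C-N(next)
    o_at = np.zeros((L, 3))
    for i in range(L):
        if i + 1 < L:
            n_next = n_at[i + 1]
        else:  # virtual next N from the final psi
            n_next = _place_atom(n_at[i], ca_at[i], c_at[i],
                                 BOND_C_N, ANGLE_CA_C_N, phi_psi[i][1])
        u1 = c_at[i] - ca_at[i]
        u2 = c_at[i] - n_next
        u = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
        o_at[i] = c_at[i] + BOND_C_O * u / np.linalg.norm(u)

    sequence = "".join(rng.choice(list(AA1)) for _ in range(L))
    backbone = np.stack([n_at, c_at, o_at], axis=1)
    return ChainStructure(
        id=f"synthetic-{seed}",
        sequence=sequence,
        ca_coords=ca_at,
        backbone_coords=backbone,
        plddt=None,
    )


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def simulate_prediction(target: ChainStructure, spec: SyntheticSpec) -> ChainStructure:
    """Synthetic "predicted model" of a target: noisy core, divergent tails.

    Core residues (and, under ``tail_mode='none'``, the tails too) are
    displaced by per-residue isotropic Gaussian noise of sd
    ``core_noise_sigma`` per coordinate.  Tails are re-posed: ``hinge``
    rigidly rotates each tail about its junction CA by ``hinge_angle``
    around a random axis; ``random-walk`` rebuilds tail CA positions as
    a 3.8 Å-step random walk from the junction (backbone atoms are
    dropped in this mode).  pLDDT is Normal(core mean, sd) on the core
    and Normal(tail mean, sd) on the tails, clipped to [0, 100].
    """
    L = len(target)
    if L != spec.total_length:
        raise ValueError(
            f"target length {L} != spec total {spec.total_length}"
        )
    rng = np.random.default_rng(spec.seed)
    n_t, c_t = spec.tail_lengths
    core_lo, core_hi = n_t, n_t + spec.core_length

    ca = target.ca_coords.copy()
    bb = None if target.backbone_coords is None else target.backbone_coords.copy()

    # isotropic noise, one offset per residue applied to all its atoms;
    # tails are re-posed below rather than noised, except under tail_mode
    # "none" where they behave like core
    noise = rng.normal(0.0, spec.core_noise_sigma, size=(L, 3))
    if spec.tail_mode != "none":
        noise[:core_lo] = 0.0
        noise[core_hi:] = 0.0
    ca += noise
    if bb is not None:
        bb += noise[:, None, :]

    drop_backbone = False
    if spec.tail_mode == "hinge":
        for lo, hi, pivot_idx in (
            (0, n_t, core_lo),
            (core_hi, L, core_hi - 1),
        ):
            if hi <= lo:
                continue
            pivot = ca[pivot_idx]
            R = _rotation_about_axis(rng.normal(size=3), spec.hinge_angle)
            ca[lo:hi] = (ca[lo:hi] - pivot) @ R.T + pivot
            if bb is not None:
                bb[lo:hi] = (bb[lo:hi] - pivot) @ R.T + pivot
    elif spec.tail_mode == "random-walk":
        drop_backbone = True
        for lo, hi, start_idx, reverse in (
            (0, n_t, core_lo, True),
            (core_hi, L, core_hi - 1, False),
        ):
            if hi <= lo:
                continue
            pos = ca[start_idx]
            walk = []
            for _ in range(hi - lo):
                step = rng.normal(size=3)
                pos = pos + 3.8 * step / np.linalg.norm(step)
                walk.append(pos)
            ca[lo:hi] = walk[::-1] if reverse else walk

    core_mean, tail_mean, sd = spec.plddt_model
    plddt = rng.normal(tail_mean, sd, size=L)
    plddt[core_lo:core_hi] = rng.normal(core_mean, sd, size=spec.core_length)
    plddt = np.clip(plddt, 0.0, 100.0)

    return ChainStructure(
        id=f"{target.id}|pred",
        sequence=target.sequence,
        ca_coords=ca,
        backbone_coords=None if drop_backbone else bb,
        plddt=plddt,
    )


def _default_core_layout(core_length: int) -> list[tuple[str, int]]:
    """Mixed-secondary-structure core: cycle helix/coil/strand/coil."""
    pattern = [("H", 14), ("C", 4), ("E", 8), ("C", 4)]
    layout: list[tuple[str, int]] = []
    remaining = core_length
    i = 0
    while remaining > 0:
        state, length = pattern[i % len(pattern)]
        take = min(length, remaining)
        layout.append((state, take))
        remaining -= take
        i += 1
    return layout


def make_refolding_pair(spec: SyntheticSpec) -> tuple[ChainStructure, ChainStructure]:
    """Build a (target, predicted-model) pair from a :class:`SyntheticSpec`.

    The target is an ideal backbone — mixed-secondary-structure core,
    coil tails (or the explicit ``ss_layout``); the prediction is
    :func:`simulate_prediction` applied to it.
    """
    if spec.ss_layout is not None:
        layout = list(spec.ss_layout)
    else:
        n_t, c_t = spec.tail_lengths
        layout = []
        if n_t:
            layout.append(("C", n_t))
        layout += _default_core_layout(spec.core_length)
        if c_t:
            layout.append(("C", c_t))
    target = make_ideal_backbone(layout, seed=spec.seed)
    if len(target) != spec.total_length:
        raise ValueError("ss_layout total does not match spec lengths")
    return target, simulate_prediction(target, spec)


def simulate_msa(
    query: str,
    depth: int,
    divergence: float,
    gap_rate: float = 0.0,
    seed: int = 0,
) -> MSA:
    """MSA of ``depth`` homolog rows at a controlled divergence.

    Each row is the query with Binomial(L, divergence) substitutions (to
    a different residue) and Binomial(L, gap_rate) gap positions.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not (0.0 <= divergence < 1.0 and 0.0 <= gap_rate < 1.0):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    L = len(query)
    rows = []
    for _ in range(depth):
        row = list(query)
        n_sub = rng.binomial(L, divergence)
        if n_sub:
            for pos in rng.choice(L, size=n_sub, replace=False):
                options = [aa for aa in AA1 if aa != query[pos]]
                row[pos] = options[rng.integers(len(options))]
        n_gap = rng.binomial(L, gap_rate)
        if n_gap:
            for pos in rng.choice(L, size=n_gap, replace=False):
                row[pos] = "-"
        rows.append("".join(row))
    return MSA(query=query, rows=rows, source="simulated")


def simulate_outcomes(records: list[DesignRecord], model: OutcomeModel) -> OutcomeTable:
    """Draw binary success labels from a logistic model of the metrics."""
    if not records:
        raise ValueError("empty record list")
    rng = np.random.default_rng(model.seed)
    plddt = np.array([r.plddt_mean for r in records])
    scrmsd = np.array([r.scrmsd for r in records])
    eta = model.intercept + model.beta_plddt * plddt + model.beta_scrmsd * scrmsd
    if not np.isfinite(eta).all():
        raise ValueError("non-finite linear predictor")
    prob = 1.0 / (1.0 + np.exp(-eta))
    labels = rng.random(len(records)) < prob
    return OutcomeTable(pd.DataFrame({
        "design_id": [r.design_id for r in records],
        "plddt_mean": plddt,
        "scrmsd": scrmsd,
        "outcome": labels.astype(int),
        "dataset": "simulated",
    }))


def simulate_design_records(
    n: int,
    seed: int = 0,
    plddt_loc: float = 80.0,
    plddt_scale: float = 10.0,
    scrmsd_median: float = 1.5,
    scrmsd_log_sd: float = 1.0,
    length_range: tuple[int, int] = (60, 300),
) -> list[DesignRecord]:
    """Plausible per-design metric tables for oracle benchmarks.

    pLDDT is a clipped normal; scRMSD is lognormal — design campaigns
    produce long-tailed scRMSD histograms, from sub-Å refolds to
    tens-of-Å failures.  Metrics are drawn independently; lengths are
    uniform over ``length_range``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    plddt = np.clip(rng.normal(plddt_loc, plddt_scale, n), 0.0, 100.0)
    scrmsd = rng.lognormal(np.log(scrmsd_median), scrmsd_log_sd, n)
    lengths = rng.integers(length_range[0], length_range[1], n)
    return [
        DesignRecord(
            design_id=f"sim{i:05d}",
            target_id=f"sim{i:05d}",
            plddt_mean=float(plddt[i]),
            scrmsd_naive=float(scrmsd[i]),
            length=int(lengths[i]),
        )
        for i in range(n)
    ]
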