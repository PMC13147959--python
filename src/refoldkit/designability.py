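"""Designability verdicts and dataset-level summaries.

A design is *designable* when its refolded model is confidently predicted
(mean pLDDT above a threshold, default 70) and matches the intended
target (scRMSD below a threshold, default 2.0 Å); both comparisons are
inclusive.  This module turns per-design metrics into verdicts,
aggregates them (fractions, length-binned summaries), implements
best-of-N design selection, length-uniform subsetting, and truncation of
full-length models to a deposited reference sequence.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chains import ChainStructure

__all__ = [
    "DesignRecord",
    "mean_plddt",
    "is_designable",
    "select_best_design",
    "designability_fraction",
    "length_binned_summary",
    "uniform_length_subset",
    "truncate_to_reference",
    "truncation_eligible",
    "records_to_dataframe",
    "dataframe_to_records",
    "write_records_csv",
    "read_records_csv",
]

DEFAULT_PLDDT_MIN = 70.0
DEFAULT_SCRMSD_MAX = 2.0

RECORD_COLUMNS = [
    "design_id", "target_id", "plddt_mean", "scrmsd_naive",
    "scrmsd_corrected", "length", "designable",
]


@dataclass
class DesignRecord:
    """Metrics and verdict for one design against its target."""

    design_id: str
    target_id: str
    plddt_mean: float
    scrmsd_naive: float
    length: int
    scrmsd_corrected: float | None = None
    designable: bool | None = None
    thresholds_used: tuple[float, float] = (DEFAULT_PLDDT_MIN, DEFAULT_SCRMSD_MAX)

    def __post_init__(self):
        if not 0.0 <= self.plddt_mean <= 100.0:
            raise ValueError(f"plddt_mean {self.plddt_mean} outside [0, 100]")
        if self.scrmsd_naive < 0:
            raise ValueError("scrmsd_naive must be >= 0")
        if self.scrmsd_corrected is not None and self.scrmsd_corrected < 0:
            raise ValueError("scrmsd_corrected must be >= 0")
        if self.designable is None:
            self.designable = is_designable(
                self.plddt_mean, self.scrmsd, *self.thresholds_used
            )

    @property
    def scrmsd(self) -> float:
        """The scRMSD variant the verdict is based on (corrected if present)."""
        return (
            self.scrmsd_corrected
            if self.scrmsd_corrected is not None
            else self.scrmsd_naive
        )


def mean_plddt(s: ChainStructure) -> float:
    """Arithmetic mean of the per-residue confidence over the full chain."""
    if s.plddt is None or len(s.plddt) == 0:
        raise ValueError(f"chain {s.id!r} carries no pLDDT values")
    return float(np.mean(s.plddt))


def is_designable(
    plddt_mean: float,
    scrmsd: float,
    plddt_min: float = DEFAULT_PLDDT_MIN,
    scrmsd_max: float = DEFAULT_SCRMSD_MAX,
) -> bool:
    """Designability predicate: pLDDT ≥ plddt_min and scRMSD ≤ scrmsd_max."""
    if not (np.isfinite(plddt_mean) and np.isfinite(scrmsd)):
        raise ValueError("non-finite metric")
    if scrmsd < 0:
        raise ValueError("scrmsd must be >= 0")
    return bool(plddt_mean >= plddt_min and scrmsd <= scrmsd_max)


def select_best_design(candidates: list[DesignRecord]) -> DesignRecord:
    """Best-of-N rule: the candidate with the lowest naive scRMSD.

    Ties go to the earliest list position; all candidates must target the
    same backbone.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    targets = {c.target_id for c in candidates}
    if len(targets) > 1:
        raise ValueError(f"mixed targets: {sorted(targets)}")
    best = candidates[0]
    for c in candidates[1:]:
        if c.scrmsd_naive < best.scrmsd_naive:
            best = c
    return best


def designability_fraction(
    records: list[DesignRecord],
    plddt_min: float = DEFAULT_PLDDT_MIN,
    scrmsd_max: float = DEFAULT_SCRMSD_MAX,
    use_corrected: bool = False,
) -> float:
    """Fraction of records passing the stated thresholds."""
    if not records:
        raise ValueError("empty record list")
    passing = sum(
        is_designable(
            r.plddt_mean,
            r.scrmsd_corrected if use_corrected else r.scrmsd_naive,
            plddt_min,
            scrmsd_max,
        )
        for r in records
    )
    return passing / len(records)


def length_binned_summary(
    records: list[DesignRecord],
    bin_width: int = 25,
    plddt_min: float = DEFAULT_PLDDT_MIN,
    scrmsd_max: float = DEFAULT_SCRMSD_MAX,
) -> pd.DataFrame:
    """Per-length-bin mean designability, pLDDT and scRMSD.

    Bins are half-open ``[lo, lo + bin_width)``; empty bins are omitted
    and each row carries the bin population ``n``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not records:
        raise ValueError("empty record list")
    df = records_to_dataframe(records)
    df["designable"] = [
        is_designable(r.plddt_mean, r.scrmsd_naive, plddt_min, scrmsd_max)
        for r in records
    ]
    df["bin_lo"] = (df["length"] // bin_width) * bin_width
    out = (
        df.groupby("bin_lo")
        .agg(
            designability=("designable", "mean"),
            mean_plddt=("plddt_mean", "mean"),
            mean_scrmsd=("scrmsd_naive", "mean"),
            n=("design_id", "size"),
        )
        .reset_index()
    )
    out["bin_hi"] = out["bin_lo"] + bin_width
    return out[["bin_lo", "bin_hi", "designability", "mean_plddt", "mean_scrmsd", "n"]]


def uniform_length_subset(
    records: list[DesignRecord],
    lo: int,
    hi: int,
    n_bins: int,
    rng_seed: int,
) -> list[DesignRecord]:
    """Class-balanced subset with a flat length histogram.

    Partitions ``[lo, hi)`` into ``n_bins`` equal-width bins and samples
    ``k`` records per bin without replacement, where ``k`` is the
    smallest per-bin availability — the largest count that still
    guarantees a flat distribution.  Deterministic for a given seed.
    """
    if lo >= hi:
        raise ValueError("lo must be < hi")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.linspace(lo, hi, n_bins + 1)
    bins: list[list[DesignRecord]] = [[] for _ in range(n_bins)]
    for r in records:
        if lo <= r.length < hi:
            idx = min(int((r.length - lo) / (hi - lo) * n_bins), n_bins - 1)
            bins[idx].append(r)
    for b, members in enumerate(bins):
        if not members:
            raise ValueError(
                f"empty length bin [{edges[b]:.0f}, {edges[b + 1]:.0f})"
            )
    k = min(len(members) for members in bins)
    rng = np.random.default_rng(rng_seed)
    subset: list[DesignRecord] = []
    for members in bins:
        chosen = rng.choice(len(members), size=k, replace=False)
        subset.extend(members[i] for i in sorted(chosen))
    return subset


def truncation_eligible(
    full_length: int,
    reference_length: int,
    min_extra: int = 5,
    max_extra: int = 50,
) -> bool:
    """Whether a full-length/deposited pair enters the truncation analysis.

    Eligible when the length difference d satisfies
    ``min_extra < d < max_extra`` (both strict).
    """
    d = full_length - reference_length
    return min_extra < d < max_extra


def truncate_to_reference(
    full: ChainStructure,
    reference_seq: str,
    max_mismatches: int = 0,
) -> ChainStructure:
    """Slice a full-length model down to a deposited reference sequence.

    The reference must occur exactly once as a contiguous substring of
    the full sequence (exact matching by default; ``max_mismatches``
    enables a sliding-window mode tolerating up to that many
    substitutions, still requiring a unique best window).
    """
    if len(reference_seq) > len(full):
        raise ValueError("reference longer than the full-length chain")
    if max_mismatches == 0:
        start = full.sequence.find(reference_seq)
        if start < 0:
            raise ValueError(
                f"reference not found in {full.id!r}"
            )
        if full.sequence.find(reference_seq, start + 1) >= 0:
            raise ValueError("reference matches multiple positions (ambiguous)")
    else:
        L, m = len(full), len(reference_seq)
        mismatches = [
            sum(a != b for a, b in zip(full.sequence[i:i + m], reference_seq))
            for i in range(L - m + 1)
        ]
        best = min(mismatches)
        if best > max_mismatches:
            raise ValueError("reference not found within mismatch tolerance")
        hits = [i for i, v in enumerate(mismatches) if v == best]
        if len(hits) > 1:
            raise ValueError("reference matches multiple positions (ambiguous)")
        start = hits[0]
    return full.slice(start, start + len(reference_seq), new_id=f"{full.id}|trunc")


def records_to_dataframe(records: list[DesignRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "design_id": [r.design_id for r in records],
            "target_id": [r.target_id for r in records],
            "plddt_mean": [r.plddt_mean for r in records],
            "scrmsd_naive": [r.scrmsd_naive for r in records],
            "scrmsd_corrected": [r.scrmsd_corrected for r in records],
            "length": [r.length for r in records],
            "designable": [r.designable for r in records],
        }
    )


def dataframe_to_records(df: pd.DataFrame) -> list[DesignRecord]:
    records = []
    for row in df.itertuples(index=False):
        corrected = getattr(row, "scrmsd_corrected", None)
        if corrected is not None and pd.isna(corrected):
            corrected = None
        records.append(
            DesignRecord(
                design_id=str(row.design_id),
                target_id=str(row.target_id),
                plddt_mean=float(row.plddt_mean),
                scrmsd_naive=float(row.scrmsd_naive),
                scrmsd_corrected=None if corrected is None else float(corrected),
                length=int(row.length),
            )
        )
    return records


def write_records_csv(records: list[DesignRecord], path: str | os.PathLike) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def read_records_csv(path: str | os.PathLike) -> list[DesignRecord]:
    return dataframe_to_records(pd.read_csv(path))
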