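"""End-to-end experiment orchestration.

Three reproducible experiments over synthetic or ingested data:

* ``mutagenesis`` — designability versus mutation fraction at several
  pLDDT thresholds, using a surrogate metric-degradation model in place
  of a folding oracle;
* ``correction_benchmark`` — designability of the same target/prediction
  pairs under every scRMSD variant (naive mean/median, outlier-corrected
  mean/median, iterative);
* ``oracle_benchmark`` — ROC AUCs, the threshold grid and its
  precision-/F1-optimal cells per outcome dataset.

Every run can emit a JSON manifest (config echo, library versions,
seeds, input digests) and writes machine-readable CSV only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chains import ChainStructure
from .designability import (
    DesignRecord,
    designability_fraction,
    is_designable,
    mean_plddt,
)
from .oracle_eval import (
    DEFAULT_PLDDT_AXIS,
    DEFAULT_SCRMSD_AXIS,
    OutcomeTable,
    roc_auc,
    select_optimum,
    threshold_grid_sweep,
)
from .structure_io import read_chain
from .superposition import corrected_scrmsd, iterative_outlier_superpose, scrmsd
from .synthetic_data import (
    OutcomeModel,
    SyntheticSpec,
    make_refolding_pair,
    simulate_design_records,
    simulate_outcomes,
)

logger = logging.getLogger("refoldkit")

SCRMSD_VARIANTS = (
    "naive_mean", "naive_median", "corrected_median", "corrected_mean", "iterative",
)


@dataclass
class RunConfig:
    """Configuration of one experiment run (YAML-loadable, flag-overridable)."""

    experiment: str = "correction_benchmark"
    structures_dir: str | None = None
    targets_dir: str | None = None
    metrics_csv: str | None = None
    outcomes_csv: str | None = None
    out_dir: str = "."
    plddt_min: tuple[float, ...] = (70.0,)
    scrmsd_max: float = 2.0
    plddt_axis: tuple[float, ...] = DEFAULT_PLDDT_AXIS
    scrmsd_axis: tuple[float, ...] = DEFAULT_SCRMSD_AXIS
    scrmsd_variant: str = "corrected_median"
    seed: int = 0
    # synthetic-pair settings (correction benchmark)
    n_pairs: int = 200
    core_length: int = 80
    tail_lengths: tuple[int, int] = (0, 20)
    core_noise_sigma: float = 0.5
    hinge_angle: float = 90.0
    tail_mode: str = "hinge"
    # mutagenesis settings
    n_parents: int = 50
    parent_length: int = 100
    fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    replicates: int = 64
    # oracle-benchmark simulation settings
    n_outcomes: int = 2000
    outcome_intercept: float = -13.0
    outcome_beta_plddt: float = 0.2
    outcome_beta_scrmsd: float = -1.0

    def __post_init__(self):
        if self.scrmsd_variant not in SCRMSD_VARIANTS:
            raise ValueError(
                f"scrmsd_variant must be one of {SCRMSD_VARIANTS}"
            )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("plddt_min", "plddt_axis", "scrmsd_axis", "fractions", "tail_lengths"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def compute_scrmsd_variant(prediction: ChainStructure, target: ChainStructure, variant: str) -> float:
    """One scRMSD number for a pair under the named variant."""
    mob, tar = prediction.ca_coords, target.ca_coords
    if variant == "naive_mean":
        return scrmsd(mob, tar, aggregate="mean")
    if variant == "naive_median":
        return scrmsd(mob, tar, aggregate="median")
    if variant == "corrected_median":
        return corrected_scrmsd(mob, tar, aggregate="median")[0]
    if variant == "corrected_mean":
        return corrected_scrmsd(mob, tar, aggregate="mean")[0]
    if variant == "iterative":
        return iterative_outlier_superpose(mob, tar, aggregate="median")[0]
    raise ValueError(f"unknown scRMSD variant {variant!r}")


def make_design_record(
    target: ChainStructure,
    prediction: ChainStructure,
    design_id: str,
    variant: str = "corrected_median",
    plddt_min: float = 70.0,
    scrmsd_max: float = 2.0,
) -> DesignRecord:
    """Compute the metrics of one (target, prediction) pair."""
    naive = compute_scrmsd_variant(prediction, target, "naive_mean")
    corrected = None
    if variant != "naive_mean":
        corrected = compute_scrmsd_variant(prediction, target, variant)
    return DesignRecord(
        design_id=design_id,
        target_id=target.id,
        plddt_mean=mean_plddt(prediction),
        scrmsd_naive=naive,
        scrmsd_corrected=corrected,
        length=len(prediction),
        thresholds_used=(plddt_min, scrmsd_max),
    )


def ingest_predictions(
    structures_dir: str | os.PathLike,
    targets_dir: str | os.PathLike,
    metrics_csv: str | os.PathLike | None = None,
    variant: str = "corrected_median",
    plddt_min: float = 70.0,
    scrmsd_max: float = 2.0,
) -> list[tuple[ChainStructure, ChainStructure, DesignRecord]]:
    """Adapter for real folding-model output directories.

    Prediction files follow ``<target_id>__<design_id>.pdb`` and are
    matched against ``<target_id>.pdb`` in the targets directory.
    Orphans are logged and skipped; an optional metrics CSV (columns
    ``design_id, plddt_mean``) overrides the B-factor-derived pLDDT.
    """
    structures_dir = Path(structures_dir)
    targets_dir = Path(targets_dir)
    files = sorted(structures_dir.glob("*.pdb"))
    if not files:
        raise ValueError(f"no PDB files in {structures_dir}")
    overrides: dict[str, float] = {}
    if metrics_csv is not None:
        df = pd.read_csv(metrics_csv)
        overrides = dict(zip(df["design_id"].astype(str), df["plddt_mean"].astype(float)))

    out = []
    seen_designs = set()
    for f in files:
        if "__" not in f.stem:
            raise ValueError(f"malformed pairing name (need <target>__<design>): {f.name}")
        target_id, design_id = f.stem.split("__", 1)
        seen_designs.add(design_id)
        target_path = targets_dir / f"{target_id}.pdb"
        if not target_path.is_file():
            logger.warning("orphan prediction %s: no target %s", f.name, target_path.name)
            continue
        target = read_chain(target_path)
        prediction = read_chain(f)
        record = make_design_record(
            target, prediction, design_id, variant, plddt_min, scrmsd_max
        )
        if design_id in overrides:
            record = DesignRecord(
                design_id=record.design_id,
                target_id=record.target_id,
                plddt_mean=overrides[design_id],
                scrmsd_naive=record.scrmsd_naive,
                scrmsd_corrected=record.scrmsd_corrected,
                length=record.length,
                thresholds_used=record.thresholds_used,
            )
        out.append((target, prediction, record))
    missing = sorted(set(overrides) - seen_designs)
    if missing:
        raise ValueError(f"metrics CSV lists unknown design id(s): {missing}")
    return out


def _degraded_metrics(fraction: float, rng: np.random.Generator) -> tuple[float, float]:
    """Surrogate for a folding oracle on a mutated sequence.

    Mean pLDDT decays and scRMSD grows linearly with the mutation load,
    with Gaussian scatter; at fraction 0 the parent's own refolding
    metrics (confident, sub-Å) are reproduced.
    """
    plddt = float(np.clip(rng.normal(92.0 - 55.0 * fraction, 4.0), 0.0, 100.0))
    rmsd = float(abs(rng.normal(0.55 + 4.5 * fraction, 0.4)))
    return plddt, rmsd


def run_mutagenesis_experiment(config: RunConfig) -> pd.DataFrame:
    """Designability versus mutation fraction at each pLDDT threshold.

    Parents × fractions × replicates metric draws come from the
    surrogate degradation model; returns one row per (fraction,
    plddt_min) with the designable fraction over all replicates.
    """
    rng = np.random.default_rng(config.seed)
    fractions = sorted(config.fractions)
    rows = []
    for fraction in fractions:
        metrics = [
            _degraded_metrics(fraction, rng)
            for _ in range(config.n_parents * config.replicates)
        ]
        for plddt_min in config.plddt_min:
            passing = sum(
                is_designable(p, r, plddt_min, config.scrmsd_max)
                for p, r in metrics
            )
            rows.append({
                "fraction": fraction,
                "plddt_min": plddt_min,
                "designability": passing / len(metrics),
                "n": len(metrics),
            })
    return pd.DataFrame(rows)


def synthetic_pair_set(config: RunConfig) -> list[tuple[ChainStructure, ChainStructure]]:
    """``n_pairs`` independent (target, prediction) pairs per the config."""
    pairs = []
    for i in range(config.n_pairs):
        spec = SyntheticSpec(
            core_length=config.core_length,
            tail_lengths=tuple(config.tail_lengths),
            core_noise_sigma=config.core_noise_sigma,
            tail_mode=config.tail_mode,
            hinge_angle=config.hinge_angle,
            seed=(config.seed * 100003 + i) % (2**31),
        )
        pairs.append(make_refolding_pair(spec))
    return pairs


def run_correction_benchmark(
    config: RunConfig,
    pairs: list[tuple[ChainStructure, ChainStructure]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Designability under every scRMSD variant on identical inputs.

    Returns ``(summary, per_design)``: one summary row per variant and
    the per-design values behind it.
    """
    if pairs is None:
        pairs = synthetic_pair_set(config)
    plddt_min = config.plddt_min[0]
    per_design_rows = []
    for i, (target, prediction) in enumerate(pairs):
        plddt = mean_plddt(prediction)
        row = {"design_id": f"pair{i:04d}", "plddt_mean": plddt, "length": len(prediction)}
        for variant in SCRMSD_VARIANTS:
            value = compute_scrmsd_variant(prediction, target, variant)
            row[variant] = value
            row[f"designable_{variant}"] = is_designable(
                plddt, value, plddt_min, config.scrmsd_max
            )
        per_design_rows.append(row)
    per_design = pd.DataFrame(per_design_rows)
    summary = pd.DataFrame([
        {
            "variant": variant,
            "designability": per_design[f"designable_{variant}"].mean(),
            "mean_scrmsd": per_design[variant].mean(),
            "median_scrmsd": per_design[variant].median(),
            "n": len(per_design),
        }
        for variant in SCRMSD_VARIANTS
    ])
    return summary, per_design


def run_oracle_benchmark(
    config: RunConfig,
    table: OutcomeTable | None = None,
) -> dict[str, dict]:
    """AUCs, grid optima and the F1-optimum confusion matrix per dataset."""
    if table is None:
        if config.outcomes_csv is not None:
            table = OutcomeTable.from_csv(config.outcomes_csv)
        else:
            records = simulate_design_records(config.n_outcomes, seed=config.seed)
            model = OutcomeModel(
                intercept=config.outcome_intercept,
                beta_plddt=config.outcome_beta_plddt,
                beta_scrmsd=config.outcome_beta_scrmsd,
                seed=config.seed + 1,
            )
            table = simulate_outcomes(records, model)
    results: dict[str, dict] = {}
    for name, sub in table.by_dataset().items():
        labels = sub.data["outcome"].to_numpy(int)
        entry: dict = {"n": len(sub)}
        if 0 < labels.sum() < len(labels):
            entry["auc_plddt"] = roc_auc(sub.data["plddt_mean"], labels, higher_is_better=True)
            entry["auc_scrmsd"] = roc_auc(sub.data["scrmsd"], labels, higher_is_better=False)
        else:
            logger.warning("dataset %s has a single outcome class; AUC skipped", name)
        grid = threshold_grid_sweep(sub, config.plddt_axis, config.scrmsd_axis)
        for criterion in ("precision", "f1"):
            opt = select_optimum(grid, criterion)
            entry[f"{criterion}_optimum"] = {
                "plddt_min": opt.plddt_min,
                "scrmsd_max": opt.scrmsd_max,
                "value": opt.value,
                "degenerate": opt.degenerate,
            }
        i, j = select_optimum(grid, "f1").index
        entry["confusion_at_f1_optimum"] = {
            "tp": int(grid.tp[i, j]), "fp": int(grid.fp[i, j]),
            "fn": int(grid.fn[i, j]), "tn": int(grid.tn[i, j]),
        }
        entry["grid"] = grid
        results[name] = entry
    return results


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(config: RunConfig, out_dir: str | os.PathLike) -> Path:
    """JSON manifest: config echo, library versions, input digests."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digests = {}
    for key in ("metrics_csv", "outcomes_csv"):
        value = getattr(config, key)
        if value and Path(value).is_file():
            digests[key] = _file_digest(Path(value))
    manifest = {
        "config": asdict(config),
        "versions": {
            "refoldkit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "input_digests": digests,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=list) + "\n")
    return path


def run_experiment(config: RunConfig) -> dict:
    """Dispatch on ``config.experiment``, write CSVs + manifest, return results."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_manifest(config, out_dir)
    if config.experiment == "mutagenesis":
        df = run_mutagenesis_experiment(config)
        df.to_csv(out_dir / "mutagenesis_designability.csv", index=False)
        return {"table": df}
    if config.experiment == "correction_benchmark":
        summary, per_design = run_correction_benchmark(config)
        summary.to_csv(out_dir / "correction_summary.csv", index=False)
        per_design.to_csv(out_dir / "correction_per_design.csv", index=False)
        return {"summary": summary, "per_design": per_design}
    if config.experiment == "oracle_benchmark":
        results = run_oracle_benchmark(config)
        rows = []
        for name, entry in results.items():
            entry["grid"].to_dataframe().assign(dataset=name).to_csv(
                out_dir / f"grid_{name}.csv", index=False
            )
            rows.append({
                "dataset": name,
                "n": entry["n"],
                "auc_plddt": entry.get("auc_plddt"),
                "auc_scrmsd": entry.get("auc_scrmsd"),
                "f1_opt_plddt_min": entry["f1_optimum"]["plddt_min"],
                "f1_opt_scrmsd_max": entry["f1_optimum"]["scrmsd_max"],
                "f1_opt_value": entry["f1_optimum"]["value"],
            })
        pd.DataFrame(rows).to_csv(out_dir / "oracle_summary.csv", index=False)
        return results
    raise ValueError(f"unknown experiment {config.experiment!r}")
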