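"""End-to-end orchestration: load inputs, run stages, write reports.

The pipeline chains the analysis stages over one experiment directory
(typically written by :func:`scamp.synthetic_data.generate_experiment`):
molecule expectations from the ERCC anchor, detection sensitivity with
Poisson-Binomial expectations, the logistic detection model with its
outlier catalogue, replicate precision, and accuracy against the bulk.
Stage failures are isolated and reported; dependent stages are skipped.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .reference_model import (
    BulkReference, estimate_targeted_mass, expected_molecules,
)
from . import dilution_stats, detection_model, precision_analysis, accuracy_analysis

__all__ = ["PipelineConfig", "load_inputs", "run_pipeline", "write_report"]

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Paths, stage toggles and thresholds (defaults are the benchmark's
    standard values)."""

    input_dir: str = "."
    output_dir: str = "scamp_out"
    ercc_mass_fg: float = 7.12
    trim_pct: float = 2.5
    cooks_threshold: float = 0.001
    outlier_d2_threshold: float = 4.0
    class_pct: float = 5.0
    outlier_pct: float = 1.0
    downsample_reads: int = 0  # 0 disables downsampling
    min_presence: float = 0.95
    holdout_fraction: float = 0.1
    n_boot_auc: int = 1000
    seed: int = 0
    stages: tuple = ("molecules", "sensitivity", "detection", "precision", "accuracy")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def load_inputs(config: PipelineConfig) -> dict:
    """Load and validate the experiment tables from ``input_dir``.

    Gene universes are intersected across tables; genes missing from any
    table are dropped with a logged count.
    """
    d = Path(config.input_dir)
    tables = {}
    for name, kwargs in (
        ("counts", {"index_col": 0}),
        ("metadata", {}),
        ("traits", {}),
        ("bulk", {}),
    ):
        path = d / f"{name}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"required input missing: {path}")
        tables[name] = pd.read_csv(path, sep="\t", **kwargs)
    ercc_path = d / "ercc.tsv"
    tables["ercc"] = pd.read_csv(ercc_path, sep="\t") if ercc_path.exists() else None
    counts = tables["counts"]
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene ids in counts.tsv")
    if (counts.to_numpy() < 0).any():
        bad = np.argwhere(counts.to_numpy() < 0)[0]
        raise ValueError(
            f"negative count at gene {counts.index[bad[0]]!r}, "
            f"sample {counts.columns[bad[1]]!r}"
        )
    gene_rows = counts.index[~counts.index.str.startswith("ERCC-")]
    universe = (
        set(gene_rows)
        & set(tables["traits"]["gene_id"])
        & set(tables["bulk"]["gene_id"])
    )
    dropped = len(gene_rows) - len(universe)
    if dropped:
        warnings.warn(f"{dropped} genes dropped: absent from traits or bulk")
    keep = [g for g in gene_rows if g in universe]
    tables["gene_counts"] = counts.loc[keep]
    tables["ercc_counts"] = counts.loc[counts.index.str.startswith("ERCC-")]
    tables["traits"] = tables["traits"].set_index("gene_id").loc[keep].reset_index()
    tables["bulk_ref"] = BulkReference(
        gene_id=np.array(keep),
        relative_frequency=_renormalize(tables["bulk"], keep),
        effective_length=tables["bulk"].set_index("gene_id").loc[keep, "effective_length"].to_numpy(),
    )
    return tables


def _renormalize(bulk: pd.DataFrame, keep) -> np.ndarray:
    f = bulk.set_index("gene_id").loc[keep, "relative_frequency"].to_numpy(dtype=float)
    return f / f.sum()


def _stage_molecules(tables, config):
    counts = tables["gene_counts"]
    ercc = tables["ercc_counts"]
    total_reads = counts.sum().sum() + ercc.sum().sum()
    ercc_fraction = float(ercc.sum().sum() / total_reads) if total_reads else 0.0
    if ercc_fraction > 0:
        targeted_pg = estimate_targeted_mass(config.ercc_mass_fg, ercc_fraction)
    else:
        targeted_pg = float(tables["metadata"]["input_mass_pg"].iloc[0]) * 0.024
    exp = expected_molecules(tables["bulk_ref"], targeted_pg)
    return {
        "ercc_read_fraction": ercc_fraction,
        "targeted_mass_pg": exp.targeted_mass_pg,
        "average_transcript_length_nt": exp.average_transcript_length_nt,
        "average_transcript_mass_pg": exp.average_transcript_mass_pg,
        "total_molecules": exp.total_molecules,
        "expectation": exp,
    }


def _stage_sensitivity(tables, config, molecules):
    exp = molecules["expectation"]
    p = dilution_stats.presence_probability(exp.expected_molecules)
    dist = dilution_stats.detected_gene_distribution(p)
    counts = tables["gene_counts"]
    _, detected = dilution_stats.detect(counts, tables["bulk_ref"].relative_frequency)
    ratios = {
        s: dilution_stats.byars_ratio_ci(int(detected[s]), dist.mean)
        for s in counts.columns
    }
    return {
        "expected_detected_mean": dist.mean,
        "expected_detected_ci": [int(dist.ci_low), int(dist.ci_high)],
        "detected_per_sample": detected.to_dict(),
        "obs_exp_byar_ci": {k: list(v) for k, v in ratios.items()},
        "presence_probability": pd.Series(p, index=counts.index),
    }


def _assemble_observations(tables, molecules) -> pd.DataFrame:
    counts = tables["gene_counts"]
    traits = tables["traits"].set_index("gene_id")
    meta = tables["metadata"].set_index("sample_id")
    M = pd.Series(
        molecules["expectation"].expected_molecules,
        index=molecules["expectation"].gene_id,
    )
    unamb = traits.index[traits["computationally_unambiguous"].astype(bool)]
    genes = counts.index.intersection(unamb)
    genes = genes[M.reindex(genes) > 0]
    frames = []
    for s in counts.columns:
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "sample_id": s,
                    "method": meta.loc[s, "method"],
                    "Y": (counts.loc[genes, s] >= 1).astype(int).to_numpy(),
                    "M": M.reindex(genes).to_numpy(),
                    "L": traits.loc[genes, "L"].to_numpy(),
                    "G": traits.loc[genes, "G"].to_numpy(),
                    "S": traits.loc[genes, "S"].to_numpy(),
                    "A": traits.loc[genes, "A"].to_numpy(),
                    "D": float(meta.loc[s, "depth"]) / 1e6,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _stage_detection(tables, config, molecules):
    obs = _assemble_observations(tables, molecules)
    obs, bounds = detection_model.trim_covariates(obs, config.trim_pct)
    fit = detection_model.fit_detection_glm(
        obs, split_seed=config.seed, holdout_fraction=config.holdout_fraction,
        trim_bounds=bounds,
    )
    gof = detection_model.goodness_of_fit(fit)
    auc = detection_model.auc_bootstrap(
        fit, n_boot=config.n_boot_auc, seed=config.seed
    )
    X, _ = detection_model.build_design_matrix(fit.train, fit.methods)
    p_hat = 1 / (1 + np.exp(-(X @ np.asarray(fit.result.params))))
    d2 = detection_model.squared_deviance_residuals(fit.train["Y"], p_hat)
    outliers = detection_model.classify_detection_outliers(
        fit.train, d2, config.outlier_d2_threshold
    )
    per_method = {}
    for m in fit.methods:
        per_method[m] = {
            "fifty_percent_point": detection_model.fifty_percent_point(fit, m),
            "molecular_recovery_rate": detection_model.molecular_recovery_rate(fit, m),
        }
    return {
        "fit": fit,
        "coefficients": fit.coefficients(),
        "goodness_of_fit": gof,
        "auc": auc,
        "outliers": outliers,
        "per_method": per_method,
        "n_train": len(fit.train),
        "n_holdout": len(fit.holdout),
    }


def _stage_precision(tables, config, sensitivity, detection):
    counts = tables["gene_counts"]
    sf = accuracy_analysis.size_factors(counts).factors
    pearson = precision_analysis.pairwise_correlations(counts, "pearson", sf)
    kendall = precision_analysis.pairwise_correlations(counts, "kendall", sf)
    exclude = (
        detection["outliers"]["gene_id"].unique() if detection is not None else ()
    )
    presence = sensitivity["presence_probability"] if sensitivity else None
    try:
        meansd = precision_analysis.mean_sd_regression(
            counts / sf, presence, exclude_genes=exclude,
            min_presence=config.min_presence, trim_pct=config.trim_pct,
        )
    except ValueError as exc:
        meansd = {"skipped": str(exc)}
    classes = None
    if "residuals" in meansd:
        classes = precision_analysis.classify_variability(
            meansd["residuals"], config.class_pct, config.outlier_pct
        )
    out = {
        "pearson": pearson.matrix,
        "kendall": kendall.matrix,
        "mean_sd": {k: v for k, v in meansd.items()
                    if not isinstance(v, (pd.Series, pd.DataFrame))},
        "variability_classes": classes,
    }
    if classes is not None:
        traits = tables["traits"].set_index("gene_id")
        try:
            out["variability_enrichment"] = precision_analysis.trait_enrichment(
                classes.index[classes["class"] == "high"],
                classes.index[classes["class"] == "background"],
                traits,
            )
        except ValueError as exc:
            out["variability_enrichment"] = str(exc)
    return out


def _stage_accuracy(tables, config, sensitivity, detection):
    counts = tables["gene_counts"]
    bulk = pd.Series(
        tables["bulk_ref"].relative_frequency, index=tables["bulk_ref"].gene_id
    )
    keep = counts.index
    if sensitivity is not None:
        keep = keep[sensitivity["presence_probability"].reindex(keep) > config.min_presence]
    traits = tables["traits"].set_index("gene_id")
    unamb = traits.index[traits["computationally_unambiguous"].astype(bool)]
    keep = keep.intersection(unamb)
    if detection is not None:
        keep = keep.difference(detection["outliers"]["gene_id"].unique())
    normalized, expected = accuracy_analysis.scale_reference(bulk.loc[keep], counts.loc[keep])
    fold = accuracy_analysis.fold_deviation(normalized, expected, "per_replicate")
    classes = accuracy_analysis.classify_accuracy(
        fold, config.class_pct, config.outlier_pct
    )
    enrich = accuracy_analysis.accuracy_trait_enrichment(classes, traits)
    sf = accuracy_analysis.size_factors(counts).factors
    return {
        "size_factors": sf,
        "fold_deviation_median": float(fold["fold_deviation"].median()),
        "n_genes": int(classes.shape[0]),
        "classes": classes,
        "enrichment": enrich,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; failures are isolated per stage."""
    tables = load_inputs(config)
    results: dict = {"stages": {}, "errors": {}}
    molecules = sensitivity = detection = None
    if "molecules" in config.stages:
        try:
            molecules = _stage_molecules(tables, config)
            results["stages"]["molecules"] = {
                k: v for k, v in molecules.items() if k != "expectation"
            }
        except Exception as exc:
            results["errors"]["molecules"] = str(exc)
    if "sensitivity" in config.stages and molecules is not None:
        try:
            sensitivity = _stage_sensitivity(tables, config, molecules)
            results["stages"]["sensitivity"] = {
                k: v for k, v in sensitivity.items() if k != "presence_probability"
            }
        except Exception as exc:
            results["errors"]["sensitivity"] = str(exc)
    if "detection" in config.stages and molecules is not None:
        try:
            detection = _stage_detection(tables, config, molecules)
            results["stages"]["detection"] = {
                "coefficients": detection["coefficients"].to_dict(),
                "goodness_of_fit": detection["goodness_of_fit"],
                "auc": {k: list(v) for k, v in detection["auc"].items()},
                "n_outliers": int(len(detection["outliers"])),
                "per_method": detection["per_method"],
                "n_train": detection["n_train"],
                "n_holdout": detection["n_holdout"],
            }
        except Exception as exc:
            results["errors"]["detection"] = str(exc)
    if "precision" in config.stages:
        try:
            precision = _stage_precision(tables, config, sensitivity, detection)
            results["stages"]["precision"] = {
                "pearson_mean_offdiag": _mean_offdiag(precision["pearson"]),
                "kendall_mean_offdiag": _mean_offdiag(precision["kendall"]),
                "mean_sd": precision["mean_sd"],
            }
            results["_precision_tables"] = precision
        except Exception as exc:
            results["errors"]["precision"] = str(exc)
    if "accuracy" in config.stages:
        try:
            accuracy = _stage_accuracy(tables, config, sensitivity, detection)
            results["stages"]["accuracy"] = {
                "fold_deviation_median": accuracy["fold_deviation_median"],
                "n_genes": accuracy["n_genes"],
            }
            results["_accuracy_tables"] = accuracy
        except Exception as exc:
            results["errors"]["accuracy"] = str(exc)
    results["provenance"] = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
    }
    return results


def write_report(results: dict, output_dir) -> Path:
    """Serialize the stage summaries (JSON) and tables (TSV)."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {
        "schema_version": SCHEMA_VERSION,
        "provenance": results.get("provenance", {}),
        "stages": _jsonable(results.get("stages", {})),
        "errors": results.get("errors", {}),
    }
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    for key in ("_precision_tables", "_accuracy_tables"):
        tabs = results.get(key, {})
        for name, val in tabs.items():
            if isinstance(val, pd.DataFrame):
                val.to_csv(out / f"{key.strip('_')}_{name}.tsv", sep="\t")
    return path


def _mean_offdiag(mat: pd.DataFrame) -> float:
    a = mat.to_numpy()
    iu = np.triu_indices(a.shape[0], 1)
    return float(np.nanmean(a[iu])) if iu[0].size else float("nan")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series, pd.DataFrame)):
        return _jsonable(obj.to_dict())
    return obj
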