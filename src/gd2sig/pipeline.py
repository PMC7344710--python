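"""End-to-end orchestration: load or simulate, normalize, score, evaluate.

``run_pipeline`` produces a report bundle of plain-text tables:

- ``per_sample_scores.tsv`` — log10 expression of the six panel genes plus
  the 2-gene signature score per sample,
- ``congruence.tsv`` — the 15 pair signatures with binary (and, when flow
  data supply all three phenotype levels, three-level) congruence flags,
- ``panel_evaluation.tsv`` — equal-error MCC, confusion and permutation
  p-value for each panel gene and the signature,
- ``null_mccs.txt`` / ``null_summary.json`` — the random-pair MCC null,
- ``sample_type_ranking.tsv`` — sample types ordered by descending median
  signature score,
- ``phenotypes.tsv`` — RFI phenotype calls (when flow data are given),
- ``provenance.json`` — the full configuration and library versions.

The whole bundle is a pure function of the run configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io
from .classifier_eval import EvaluationResult, evaluate_panel, random_pair_null
from .errors import DegenerateDataError, InputError
from .normalization import (
    estimate_size_factors,
    log10_transform,
    normalize_counts,
    validate_count_matrix,
)
from .phenotyping import GD2Class, classify_rfi, compute_rfi, phenotype_table
from .signature import (
    FLAGSHIP_SIGNATURE,
    GANGLIOSIDE_PANEL,
    SignatureSpec,
    check_congruence,
    check_three_level_congruence,
    enumerate_pair_signatures,
    score_signature,
)
from .synthetic_data import SimulationConfig, simulate_counts

__all__ = ["RunConfig", "run_pipeline", "rank_sample_types"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of (``counts_path`` + ``labels_path``) or ``simulation``
    must be supplied.
    """

    counts_path: str | None = None
    labels_path: str | None = None
    pool_path: str | None = None
    flow_path: str | None = None
    simulation: SimulationConfig | None = None
    pseudocount: float = 1.0
    n_perm: int = 999
    n_pairs: int = 1000
    seed: int = 0
    outdir: str = "gd2sig_report"

    def __post_init__(self) -> None:
        paths_given = self.counts_path is not None or self.labels_path is not None
        if paths_given and self.simulation is not None:
            raise InputError("supply either input paths or a simulation, not both")
        if not paths_given and self.simulation is None:
            raise InputError("supply input paths (counts + labels) or a simulation")
        if paths_given and (self.counts_path is None or self.labels_path is None):
            raise InputError("counts_path and labels_path must be given together")
        if self.pseudocount <= 0:
            raise InputError("pseudocount must be positive")
        if self.n_perm < 0 or self.n_pairs < 0:
            raise InputError("n_perm and n_pairs must be >= 0")

    @classmethod
    def from_dict(cls, payload: Mapping[str, Any]) -> "RunConfig":
        payload = dict(payload)
        sim = payload.pop("simulation", None)
        if sim is not None:
            if "background_mean_range" in sim:
                sim["background_mean_range"] = tuple(sim["background_mean_range"])
            sim = SimulationConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        return cls(simulation=sim, **payload)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(payload, Mapping):
            raise InputError(f"config {path} must be a mapping")
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        return payload


def rank_sample_types(scores: pd.Series, types: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Order sample types by descending median signature score.

    Ties in the median are broken lexicographically by type label. Returns
    a frame with columns ``sample_type, median_score, n_samples``.
    """
    if isinstance(types, pd.Series):
        types = types.to_dict()
    missing = [s for s in scores.index if s not in types]
    if missing:
        raise InputError(f"sample(s) without a type label: {missing[:5]}")
    frame = pd.DataFrame(
        {"score": scores, "sample_type": [types[s] for s in scores.index]}
    )
    agg = frame.groupby("sample_type")["score"].agg(["median", "size"])
    agg = agg.rename(columns={"median": "median_score", "size": "n_samples"})
    agg = agg.sort_values(
        by=["median_score", "sample_type"], ascending=[False, True], kind="mergesort"
    )
    return agg.reset_index()[["sample_type", "median_score", "n_samples"]]


def _load_inputs(config: RunConfig):
    """Assemble (counts, labels, types, pool, flow_records) from the config."""
    if config.simulation is not None:
        dataset = simulate_counts(config.simulation)
        labels = dataset.labels
        types = labels.map({True: "GD2_positive", False: "GD2_negative"})
        return dataset.counts, labels, types, list(dataset.pool_genes), None

    counts = io.read_count_matrix(config.counts_path)
    label_df = io.read_labels(config.labels_path)
    missing = [s for s in counts.columns if s not in label_df.index]
    if missing:
        raise InputError(f"sample(s) in counts but not in labels: {missing[:5]}")
    labels = (label_df.loc[counts.columns, "status"] == "positive").rename("status")
    if "group" in label_df.columns:
        types = label_df.loc[counts.columns, "group"]
    else:
        types = label_df.loc[counts.columns, "status"]
    pool = io.read_gene_pool(config.pool_path) if config.pool_path else []
    flow = io.read_flow_records(config.flow_path) if config.flow_path else None
    return counts, labels, types, pool, flow


def _three_level_classes(flow_records, samples) -> dict[str, GD2Class] | None:
    """Map samples to GD2 classes from flow data, if all samples are covered
    and all three classes occur; otherwise None."""
    by_line: dict[str, list] = {}
    for rec in flow_records:
        by_line.setdefault(rec.cell_line, []).append(rec)
    if not set(samples).issubset(by_line):
        return None
    classes = {
        s: classify_rfi(compute_rfi(by_line[s])) for s in samples
    }
    if {c for c in classes.values()} != set(GD2Class):
        return None
    return classes


def _panel_eval_frame(results: list[EvaluationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "predictor": r.predictor,
                "mcc": r.mcc,
                "threshold": r.threshold,
                "TP": r.confusion.tp,
                "FP": r.confusion.fp,
                "TN": r.confusion.tn,
                "FN": r.confusion.fn,
                "p_perm": r.p_perm,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write the report bundle.

    Returns the output directory. Identical configs produce byte-identical
    bundles.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts, labels, types, pool, flow = _load_inputs(config)
    validate_count_matrix(counts)

    missing = [g for g in GANGLIOSIDE_PANEL.genes if g not in counts.index]
    if missing:
        raise InputError(f"panel gene(s) missing from count matrix: {missing}")
    if labels.all() or not labels.any():
        present = "positive" if labels.all() else "negative"
        raise DegenerateDataError(
            f"labels contain a single class ({present}); both GD2 statuses "
            "are required"
        )

    if config.simulation is not None:
        io.write_count_matrix(counts, outdir / "counts.tsv")
        io.write_labels(labels, outdir / "labels.tsv", groups=types)
        io.write_gene_pool(pool, outdir / "pool.txt")

    size_factors = estimate_size_factors(counts)
    expr = normalize_counts(counts, size_factors)
    logexpr = log10_transform(expr, config.pseudocount)
    io.write_size_factors(size_factors, outdir / "size_factors.tsv")

    # (a) per-sample scores: six panel genes + the 2-gene signature
    sig_scores = score_signature(logexpr, FLAGSHIP_SIGNATURE)
    score_table = logexpr.loc[list(GANGLIOSIDE_PANEL.genes)].T.copy()
    score_table[FLAGSHIP_SIGNATURE.name] = sig_scores
    score_table["status"] = labels.map({True: "positive", False: "negative"})
    score_table.rename_axis("sample_id").to_csv(outdir / "per_sample_scores.tsv", sep="\t")

    # (b) 15-pair congruence table
    status_map = labels.to_dict()
    classes = _three_level_classes(flow, counts.columns) if flow else None
    rows = []
    for spec in enumerate_pair_signatures(GANGLIOSIDE_PANEL):
        scores = score_signature(logexpr, spec)
        row = {
            "signature": spec.name,
            "congruent_binary": check_congruence(scores, status_map),
        }
        if classes is not None:
            row["congruent_three_level"] = check_three_level_congruence(scores, classes)
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "congruence.tsv", sep="\t", index=False)

    # (c) panel evaluation (per-gene + signature MCC table)
    results = evaluate_panel(
        logexpr,
        status_map,
        GANGLIOSIDE_PANEL,
        FLAGSHIP_SIGNATURE,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    _panel_eval_frame(results).to_csv(outdir / "panel_evaluation.tsv", sep="\t", index=False)

    # (d) random-pair null
    if pool and config.n_pairs > 0:
        null = random_pair_null(
            logexpr,
            status_map,
            pool,
            n_pairs=config.n_pairs,
            seed=config.seed,
            observed=FLAGSHIP_SIGNATURE,
        )
        (outdir / "null_mccs.txt").write_text(
            "".join(f"{m!r}\n" for m in null.null_mccs)
        )
        summary = {
            "observed_signature": null.observed_name,
            "observed_mcc": null.observed_mcc,
            "p_value": null.p_value,
            "n_pairs": null.n_pairs,
            "seed": null.seed,
        }
        (outdir / "null_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )

    # (e) sample-type ranking by descending median signature score
    rank_sample_types(sig_scores, types).to_csv(
        outdir / "sample_type_ranking.tsv", sep="\t", index=False
    )

    # phenotype calls from flow data
    if flow:
        phenotype_table(flow).to_csv(outdir / "phenotypes.tsv", sep="\t")

    # (f) provenance; outdir is where the bundle lives, so recording it would
    # make otherwise-identical runs differ byte-wise
    config_record = config.to_dict()
    config_record.pop("outdir", None)
    provenance = {
        "config": config_record,
        "seed": config.seed,
        "versions": {
            "gd2sig": _package_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n"
    )
    return outdir


def _package_version() -> str:
    from . import __version__

    return __version__
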