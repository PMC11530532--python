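"""End-to-end pipeline: simulate -> score -> regress -> associate -> profile.

Every run is driven by a single :class:`RunConfig` (loadable from YAML),
all randomness flows from its one integer seed, and every artifact
directory receives a provenance record (resolved config hash, seed,
package version) so that a rerun with an identical config reproduces
identical outputs byte for byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    correlate_domains,
    export_network,
    network_to_json,
    resample_semielite_variances,
    write_graphml,
)
from .cohort import CohortConfig, default_norms, generate_cohort
from .errors import ValidationError
from .io import read_cohort, write_cohort, write_score_table
from .profiles import build_profiles, plot_profiles, summarize_profiles
from .regression import diagnose_linear, fit_all_models
from .schemes import DOMAINS, ScoringScheme, load_scheme
from .scoring import build_score_table

logger = logging.getLogger("elitesport")

STAGES = ("simulate", "score", "analyze", "variance", "profile")


@dataclass
class RunConfig:
    """Fully-resolved configuration of a pipeline run."""

    out_dir: str = "elitesport_run"
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    cohort_path: str | None = None       # read instead of simulating
    scheme_path: str | None = None       # coding-scheme overrides (YAML/JSON)
    iterations: int = 1000               # variance resampling iterations
    group_size: int = 22                 # resampled semi-elite group size
    elite_threshold: int = 13
    edge_threshold: float = 0.15
    outlier_threshold: float = 1.0
    se_policy: str = "auto"              # OLS | HC3 | HC4 | auto
    plots: bool = False

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stage(s): {sorted(unknown)}")
        if not 2 <= self.elite_threshold <= 16:
            raise ValidationError(
                f"elite_threshold must be in [2, 16], got {self.elite_threshold}"
            )
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if self.cohort_path is not None and not Path(self.cohort_path).exists():
            raise ValidationError(f"cohort_path {self.cohort_path} does not exist")
        if self.scheme_path is not None and not Path(self.scheme_path).exists():
            raise ValidationError(f"scheme_path {self.scheme_path} does not exist")
        if self.cohort_path is None and "simulate" not in self.stages \
                and self.stages:
            raise ValidationError(
                "no cohort source: provide cohort_path or enable the "
                "'simulate' stage"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        return out


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.resolved(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _write_provenance(out_dir: Path, config: RunConfig) -> None:
    record = {
        "config": config.resolved(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "package_version": __version__,
    }
    (out_dir / "provenance.json").write_text(
        json.dumps(record, indent=2, sort_keys=True)
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages; returns the in-memory artifacts."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scheme = (
        load_scheme(config.scheme_path) if config.scheme_path
        else ScoringScheme()
    )
    artifacts: dict = {}
    stages = set(config.stages)

    # --- cohort ----------------------------------------------------------
    if config.cohort_path is not None:
        cohort, report = read_cohort(config.cohort_path)
        logger.info("read cohort: %d athletes, %d row problems",
                    len(cohort), len(report))
        artifacts["row_errors"] = report
    elif "simulate" in stages:
        synthetic = generate_cohort(
            CohortConfig(seed=config.seed,
                         elite_threshold=config.elite_threshold),
            default_norms(), scheme,
        )
        cohort = synthetic.cohort
        artifacts["synthetic"] = synthetic
        write_cohort(cohort, out_dir / "cohort.csv")
        logger.info("simulated cohort: %d athletes", len(cohort))
    else:
        raise ValidationError(
            "no cohort available: provide cohort_path or enable 'simulate'"
        )
    artifacts["cohort"] = cohort

    # --- scoring ---------------------------------------------------------
    needs_scores = stages & {"score", "analyze", "variance", "profile"}
    if needs_scores:
        table = build_score_table(cohort, scheme)
        artifacts["score_table"] = table
        write_score_table(table.frame, out_dir / "scores.csv")
        (out_dir / "group_census.json").write_text(
            json.dumps(table.census, indent=2, sort_keys=True, default=str)
        )
        logger.info("scored %d athletes (%d flagged incomplete); "
                    "%d elite / %d semi-elite",
                    len(table.frame), len(table.flagged),
                    int(table.frame["elite"].sum()),
                    int((~table.frame["elite"]).sum()))

    # --- regressions -----------------------------------------------------
    if "analyze" in stages:
        models = fit_all_models(table, se_policy=config.se_policy)
        artifacts["models"] = models
        logistic_rows, linear_rows = [], []
        for key, fit in models["logistic"].items():
            block = fit.terms.copy()
            block.insert(0, "model", key)
            block["nagelkerke_r2"] = fit.nagelkerke_r2
            block["pct_correct"] = fit.pct_correct
            block["n"] = fit.n
            logistic_rows.append(block)
        for key, fit in models["linear"].items():
            block = fit.terms.copy()
            block.insert(0, "model", key)
            block["se_type"] = fit.se_type
            block["r2"] = fit.r2
            block["adj_r2"] = fit.adj_r2
            block["n"] = fit.n
            linear_rows.append(block)
        pd.concat(logistic_rows).to_csv(out_dir / "logistic_models.csv",
                                        index=False)
        pd.concat(linear_rows).to_csv(out_dir / "linear_models.csv",
                                      index=False)
        diag = diagnose_linear(models["linear"]["a"])
        artifacts["diagnostics"] = diag
        (out_dir / "linear_diagnostics.json").write_text(json.dumps({
            "durbin_watson": diag.durbin_watson,
            "dw_in_range": bool(diag.dw_in_range),
            "breusch_pagan": {"stat": diag.bp_stat, "df": diag.bp_df,
                              "p": diag.bp_p},
            "vif": {k: float(v) for k, v in diag.vif.items()},
            "vif_flagged": diag.vif_flagged,
            "n_flagged_cases": int(diag.outlier_flags.any(axis=1).sum())
            if len(diag.outlier_flags) else 0,
        }, indent=2, sort_keys=True))

    # --- associations and variance null ----------------------------------
    if "variance" in stages or "analyze" in stages:
        correlations = correlate_domains(table)
        artifacts["correlations"] = correlations
        correlations.r.to_csv(out_dir / "correlations.csv")
    if "variance" in stages:
        variance = resample_semielite_variances(
            table, group_size=config.group_size,
            iterations=config.iterations, seed=config.seed,
        )
        artifacts["variance"] = variance
        variance.frame.to_csv(out_dir / "variance_comparison.csv", index=False)
        if "analyze" in stages:
            graph = export_network(
                models["linear"]["a"], correlations, variance,
                threshold=config.edge_threshold,
            )
            artifacts["network"] = graph
            network_to_json(graph, out_dir / "network.json")
            write_graphml(graph, out_dir / "network.graphml")

    # --- individual profiles ---------------------------------------------
    if "profile" in stages:
        reports = build_profiles(table)
        summary = summarize_profiles(reports)
        artifacts["profiles"] = reports
        artifacts["profile_summary"] = summary
        summary.table.to_csv(out_dir / "profiles.csv", index=False)
        (out_dir / "profile_summary.json").write_text(json.dumps({
            "n_elite": summary.n,
            "n_with_positive_outlier": summary.n_positive_outlier,
            "n_with_negative_outlier": summary.n_negative_outlier,
            "n_positive_sum_score": summary.n_positive_sum,
            "n_ergodic_linear": summary.n_ergodic_linear,
            "n_ergodic_logistic": summary.n_ergodic_logistic,
        }, indent=2, sort_keys=True))
        if config.plots:
            plot_profiles(reports, out_dir / "profiles.png")

    _write_provenance(out_dir, config)
    return artifacts
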