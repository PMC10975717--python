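"""End-to-end pipeline: simulate or read a catalogue, impute, score,
run reformulation scenarios and reports, and write a re-runnable manifest.

All randomness flows from the single configured seed; each stage draws from
its own derived substream, so adding a stage does not perturb earlier
stages' draws.  Two runs from the same manifest produce byte-identical
outputs (the manifest records content hashes so this is checkable).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analytics import (
    class_distribution,
    compare_variants,
    fit_salt_enhancer_logistic,
    group_summaries,
    predicted_curve,
)
from .catalog import filter_complete, impute_fibre, read_products, write_products
from .market import MarketConfig, config_from_yaml, default_config, generate_market
from .reformulation import (
    STUDY_SCENARIOS,
    Scenario,
    count_class_changes,
    scenario_report,
    transition_matrix,
)
from .scoring import AlgorithmVariant, nutriscore

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "score_table"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """One reproducible pipeline run.

    Exactly one input source: a product CSV (``input_csv``) or a synthetic
    market (``market_config``, defaulting to the standard nine-group market
    when both are ``None``).
    """

    out_dir: str | Path
    input_csv: str | Path | None = None
    market_config: MarketConfig | None = None
    variants: tuple[AlgorithmVariant, ...] = (
        AlgorithmVariant.ORIGINAL,
        AlgorithmVariant.REFINED,
    )
    scenarios: tuple[Scenario, ...] = STUDY_SCENARIOS
    seed: int = 0
    curve_points: int = 50

    def __post_init__(self) -> None:
        if self.input_csv is not None and self.market_config is not None:
            raise PipelineError("configure exactly one input source, not both")


def score_table(products, variant, tables=None) -> pd.DataFrame:
    """Scored catalogue as a flat table (one row per product)."""
    rows = []
    for record in products:
        res = nutriscore(record, variant, tables)
        c = res.components
        rows.append(
            {
                "product_id": record.product_id,
                "variant": variant.value,
                "energy_pts": c.energy_pts,
                "sugars_pts": c.sugars_pts,
                "sfa_pts": c.sfa_pts,
                "sodium_pts": c.sodium_pts,
                "fvl_pts": c.fvl_pts,
                "fibre_pts": c.fibre_pts,
                "protein_pts": c.protein_pts,
                "n_total": c.n_total,
                "p_total": c.p_total,
                "total": res.total,
                "letter": res.letter,
                "protein_counted": res.protein_counted,
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run manifest.

    Stages: acquire (simulate or read) -> completeness filter -> fibre
    imputation -> scoring per variant -> scenario transitions and
    distribution report -> descriptive analytics -> logistic model.  Outputs
    are CSV/JSON files under ``out_dir``; the manifest (also written there)
    lists every file with its SHA-256 and echoes the configuration.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def emit(name: str, path: Path) -> None:
        outputs[name] = path

    # --- acquire -----------------------------------------------------------
    stage = "acquire"
    try:
        if config.input_csv is not None:
            report = read_products(config.input_csv)
            products = report.records
            if len(report.rejects):
                rejects_path = out / "rejects.csv"
                report.rejects.to_csv(rejects_path, index=False)
                emit("rejects", rejects_path)
        else:
            market = config.market_config or default_config()
            products = generate_market(market, seed=config.seed)
        stage = "filter"
        products, incomplete = filter_complete(products)
        stage = "impute"
        products = impute_fibre(products)
        catalogue_path = out / "catalogue.csv"
        write_products(products, catalogue_path)
        emit("catalogue", catalogue_path)

        # --- scoring -------------------------------------------------------
        stage = "score"
        for variant in config.variants:
            path = out / f"scores_{variant.value}.csv"
            score_table(products, variant).to_csv(path, index=False)
            emit(f"scores_{variant.value}", path)

        # --- scenarios -----------------------------------------------------
        stage = "reformulate"
        report_variant = (
            AlgorithmVariant.REFINED
            if AlgorithmVariant.REFINED in config.variants
            else config.variants[0]
        )
        change_counts = {}
        for scenario in config.scenarios:
            matrix = transition_matrix(products, report_variant, scenario)
            slug = scenario.name.replace(" ", "_").replace("%", "pct")
            path = out / f"transitions_{slug}.csv"
            matrix.to_frame().to_csv(path, index_label="baseline_class")
            emit(f"transitions_{slug}", path)
            change_counts[scenario.name] = count_class_changes(matrix)
        path = out / "scenario_distribution.csv"
        scenario_report(products, report_variant, config.scenarios).to_csv(path, index=False)
        emit("scenario_distribution", path)

        # --- analytics -----------------------------------------------------
        stage = "report"
        path = out / "class_distribution.csv"
        class_distribution(products, report_variant).to_csv(path, index=False)
        emit("class_distribution", path)
        comparison = compare_variants(products)
        path = out / "variant_moves.csv"
        comparison.moves.to_csv(path, index_label="original_class")
        emit("variant_moves", path)
        path = out / "variant_group_means.csv"
        comparison.group_means.to_csv(path, index=False)
        emit("variant_group_means", path)
        path = out / "group_summaries.csv"
        group_summaries(products, report_variant).to_csv(path, index=False)
        emit("group_summaries", path)

        stage = "logistic"
        fit = fit_salt_enhancer_logistic(products)
        fit_payload = {
            "intercept": fit.intercept,
            "slope": fit.slope,
            "se_intercept": fit.se_intercept,
            "se_slope": fit.se_slope,
            "chi2": fit.chi2,
            "df": fit.df,
            "p_value": fit.p_value,
            "pct_correct": fit.pct_correct,
            "auc": fit.auc,
            "n": fit.n,
        }
        path = out / "logistic_fit.json"
        path.write_text(json.dumps(fit_payload, indent=2, sort_keys=True) + "\n")
        emit("logistic_fit", path)
        salts = [
            r.profile.sodium_resolved_mg / 400.0
            for r in products
            if r.profile.sodium_resolved_mg is not None
        ]
        grid = np.linspace(min(salts), max(salts), config.curve_points)
        path = out / "predicted_curve.csv"
        predicted_curve(fit, grid).to_csv(path, index=False)
        emit("predicted_curve", path)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- manifest ----------------------------------------------------------
    manifest = {
        "nutriprofiler_version": __version__,
        "config": {
            "input_csv": str(config.input_csv) if config.input_csv else None,
            "market_config": (
                None
                if config.market_config is None and config.input_csv is not None
                else "default" if config.market_config is None else "custom"
            ),
            "variants": [v.value for v in config.variants],
            "scenarios": [
                {
                    "name": s.name,
                    "sodium_factor": s.sodium_factor,
                    "sfa_factor": s.sfa_factor,
                }
                for s in config.scenarios
            ],
            "seed": config.seed,
        },
        "n_products": len(products),
        "n_incomplete": len(incomplete),
        "class_changes": change_counts,
        "outputs": {
            name: {"path": str(path), "sha256": _sha256(path)}
            for name, path in sorted(outputs.items())
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
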