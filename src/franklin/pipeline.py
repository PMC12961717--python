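"""End-to-end demo pipeline: generate -> split -> train both models -> evaluate -> simulate.

``run_demo`` wires every stage together on a synthetic cohort:

1. generate a cohort with latent clinical conditions and log-normal costs;
2. split it into embeddings/training/validation/test (20/40/20/20);
3. score the HCC-style baseline with a category map covering only half of
   the latent conditions (the partial-coverage regime the baseline
   represents), normalize scores, recalibrate to the log scale, and
   decile-calibrate its dollar predictions;
4. train embeddings on the embeddings split, clusters + the boosted-tree
   model on the training split with validation early stopping, and
   decile-calibrate on the validation split;
5. evaluate both models on the test split (fit, classification, error
   frequencies, decile dispersion, dispersion decomposition, downsampled
   significance test);
6. run the favorable-selection simulation for both payment models over a
   tau grid.

All randomness derives from the config seed and the report is a plain
JSON-serializable dict, byte-identical across runs with the same config.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np

from . import claims_io, evaluation, hcc_baseline, risk_model, selection_sim
from . import embedding_clusters as ec
from .synthetic_cohort import GeneratorConfig, generate_cohort

__all__ = ["RunConfig", "run_demo"]

log = logging.getLogger("franklin")


@dataclass(frozen=True)
class RunConfig:
    """Flat, fully defaulted configuration for the demo pipeline."""

    # generator
    n_beneficiaries: int = 20_000
    n_latent_conditions: int = 10
    vocab_size: int = 300
    codes_per_condition: int = 12
    zero_dx_fraction: float = 0.05
    # split
    split_fractions: tuple[float, float, float, float] = claims_io.DEFAULT_SPLIT_FRACTIONS
    # baseline coverage: which latent conditions the category map knows about
    baseline_covered_fraction: float = 0.5
    # embeddings / clusters
    embedding_dim: int = 50
    n_clusters: int = 50
    min_count: int = 5
    # risk model
    log_offset: float = risk_model.DEFAULT_LOG_OFFSET
    n_estimators: int = 500
    max_depth: int = 6
    learning_rate: float = 0.05
    subsample: float = 0.8
    early_stopping_rounds: int = 20
    # evaluation
    tail_quantile: float = 0.20
    error_thresholds: tuple[float, float] = (20.0, 40.0)
    n_boot: int = 200
    ttest_n_samples: int = 100
    ttest_sample_size: int = 1000
    # selection simulation (plan_size must not exceed the test split)
    taus: tuple[float, ...] = (0.1, 0.3, 0.5)
    plan_size: int = 2_000
    n_samples: int = 500
    # global
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        coerced = {}
        for f in fields(cls):
            if f.name in mapping:
                v = mapping[f.name]
                coerced[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**coerced)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_mapping(tomllib.load(fh))

    def validate(self) -> None:
        self.generator_config().validate()
        if not 0 < self.baseline_covered_fraction <= 1:
            raise ValueError("baseline_covered_fraction must lie in (0, 1]")
        if not self.taus:
            raise ValueError("taus must be nonempty")
        selection_sim.SelectionConfig(
            tau=self.taus[0], plan_size=self.plan_size, n_samples=self.n_samples
        )

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(
            n_beneficiaries=self.n_beneficiaries,
            n_latent_conditions=self.n_latent_conditions,
            vocab_size=self.vocab_size,
            codes_per_condition=self.codes_per_condition,
            zero_dx_fraction=self.zero_dx_fraction,
            seed=self.seed,
        )


def _evaluate_model(
    name: str,
    predicted_cost: np.ndarray,
    predicted_log: np.ndarray,
    observed: np.ndarray,
    config: RunConfig,
    seed: int,
) -> dict:
    fit = evaluation.compute_fit_metrics(
        predicted_cost, observed, offset=config.log_offset, predicted_log=predicted_log
    )
    cls_low = evaluation.classify_extremes(predicted_cost, observed, config.tail_quantile, "low")
    cls_high = evaluation.classify_extremes(predicted_cost, observed, config.tail_quantile, "high")
    errors = evaluation.prediction_error_frequencies(
        predicted_cost, observed, config.error_thresholds
    )
    dispersion = evaluation.decile_dispersion(
        predicted_cost, observed, n_boot=config.n_boot, seed=seed
    )
    decomposition = evaluation.dispersion_decomposition(
        observed, fit.r2_log, offset=config.log_offset
    )
    return {
        "model": name,
        "fit": fit.as_dict(),
        "classification_low": cls_low.as_dict(),
        "classification_high": cls_high.as_dict(),
        "error_frequencies": errors.as_dict(),
        "decile_dispersion": dispersion.as_dict(),
        "dispersion_decomposition": decomposition.as_dict(),
    }


def run_demo(config: RunConfig, out_dir: str | Path | None = None, dry_run: bool = False) -> dict:
    """Run the full pipeline; returns (and optionally writes) the report."""
    config.validate()
    if dry_run:
        return {"config": asdict(config), "dry_run": True}

    t0 = time.perf_counter()
    seed = config.seed

    log.info("stage=generate n=%d seed=%d", config.n_beneficiaries, seed)
    cohort, truth = generate_cohort(config.generator_config())

    log.info("stage=split fractions=%s", (config.split_fractions,))
    cohort = claims_io.split_cohort(cohort, config.split_fractions, seed=seed + 1)
    emb_split = cohort.split("embeddings")
    train_split = cohort.split("training")
    val_split = cohort.split("validation")
    test_split = cohort.split("test")

    log.info("stage=baseline covered=%.0f%%", 100 * config.baseline_covered_fraction)
    n_cov = max(1, int(round(config.baseline_covered_fraction * config.n_latent_conditions)))
    cmap = hcc_baseline.category_map_from_ground_truth(truth, range(n_cov))
    base_scores_val = hcc_baseline.score_cohort(val_split, cmap)
    base_scores_test = hcc_baseline.score_cohort(test_split, cmap)
    # normalize on the validation split's mean, apply the same scale out-of-sample
    val_mean = base_scores_val.mean()
    base_cost_val = base_scores_val / val_mean * cmap.base_cost
    base_cost_test = base_scores_test / val_mean * cmap.base_cost
    obs_val = val_split.table["observed_cost"].to_numpy()
    obs_test = test_split.table["observed_cost"].to_numpy()
    base_calib = risk_model.calibrate_deciles(base_cost_val, obs_val)
    base_pay_test = base_calib.apply(base_cost_test)
    base_log_coeffs = risk_model.fit_log_recalibration(base_cost_val, obs_val, config.log_offset)
    base_log_test = risk_model.apply_log_recalibration(
        base_log_coeffs, base_cost_test, config.log_offset
    )

    log.info("stage=embeddings d=%d min_count=%d", config.embedding_dim, config.min_count)
    cooc = ec.build_cooccurrence(emb_split, min_count=config.min_count)
    emb = ec.train_embeddings(cooc, d=config.embedding_dim, seed=seed + 2)
    log.info("stage=clusters k=%d vocab=%d", config.n_clusters, len(emb.vocab))
    clusters = ec.fit_clusters(emb, k=config.n_clusters, seed=seed + 3)

    log.info("stage=train n_train=%d n_val=%d", len(train_split), len(val_split))
    bundle = risk_model.fit(
        train_split,
        val_split,
        emb,
        clusters,
        hyperparams={
            "n_estimators": config.n_estimators,
            "max_depth": config.max_depth,
            "learning_rate": config.learning_rate,
            "subsample": config.subsample,
            "early_stopping_rounds": config.early_stopping_rounds,
        },
        offset=config.log_offset,
        seed=seed + 4,
    )
    raw_val = np.maximum(
        np.exp(risk_model.predict_log_cost(bundle, val_split)) - config.log_offset,
        bundle.payment_floor,
    )
    bundle.calibration = risk_model.calibrate_deciles(raw_val, obs_val)
    franklin_pay_test = risk_model.predict_cost(bundle, test_split)
    franklin_log_test = risk_model.predict_log_cost(bundle, test_split)

    log.info("stage=evaluate n_test=%d", len(test_split))
    report_franklin = _evaluate_model(
        "franklin", franklin_pay_test, franklin_log_test, obs_test, config, seed + 5
    )
    report_baseline = _evaluate_model(
        "hcc_baseline", base_pay_test, base_log_test, obs_test, config, seed + 5
    )
    ttest = evaluation.downsampled_ttest(
        "spearman",
        franklin_pay_test,
        base_pay_test,
        obs_test,
        seed=seed + 6,
        n_samples=config.ttest_n_samples,
        sample_size=config.ttest_sample_size,
    )

    log.info("stage=simulate taus=%s plan_size=%d", list(config.taus), config.plan_size)
    # the simulator's contract: payments carry cohort-level PR = 1 on the
    # simulated population, so residual decile-calibration drift between
    # validation and test does not masquerade as selection profit
    sim_pay_f = franklin_pay_test * obs_test.mean() / franklin_pay_test.mean()
    sim_pay_h = base_pay_test * obs_test.mean() / base_pay_test.mean()
    selection = {}
    for tau in config.taus:
        cfg = selection_sim.SelectionConfig(
            tau=tau, plan_size=config.plan_size, n_samples=config.n_samples, seed=seed + 7
        )
        res_f, res_h = selection_sim.simulate_selection(obs_test, sim_pay_f, sim_pay_h, cfg)
        selection[f"tau_{tau:g}"] = {
            "franklin": res_f.as_dict(),
            "hcc_baseline": res_h.as_dict(),
        }

    report = {
        "config": asdict(config),
        "n_splits": {
            "embeddings": len(emb_split),
            "training": len(train_split),
            "validation": len(val_split),
            "test": len(test_split),
        },
        "vocabulary_size": len(emb.vocab),
        "models": {"franklin": report_franklin, "hcc_baseline": report_baseline},
        "spearman_ttest": ttest.as_dict(),
        "selection": selection,
    }
    log.info("stage=done elapsed=%.1fs", time.perf_counter() - t0)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        risk_model.save_bundle(bundle, out_dir / "model")
    return report
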