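"""Synthetic claims-like cohorts with known generative structure.

Real Medicare-scale claims are restricted data, so the rest of the package
is exercised on cohorts drawn from an explicit generative model that mimics
the statistical features the pipeline relies on:

* annual costs are log-normal: log cost = intercept + age/sex effects +
  additive effects of latent clinical conditions + N(0, sigma_eps^2);
* diagnosis codes are emitted by latent conditions, so codes belonging to
  the same condition co-occur in structured blocks (the signal the
  co-occurrence embeddings pick up);
* condition effects may be negative (cost-lowering diagnoses exist and a
  flexible risk model should exploit them);
* a stratum of beneficiaries has an empty diagnosis set, mirroring the
  large share of enrollees whose codes map to no baseline category;
* uniformly random "noise" codes dilute the block structure.

Every draw is reproducible from the config seed, and the generator returns
the ground truth (condition indicators, code->condition map, true expected
log cost) so recovery tests have an oracle.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .claims_io import Cohort

__all__ = ["GeneratorConfig", "GroundTruth", "generate_cohort", "cohort_summary", "make_code"]

#: Age bands used for summaries and demographic cells.
AGE_BANDS: tuple[tuple[int, int], ...] = ((65, 74), (75, 84), (85, 120))


def make_code(i: int) -> str:
    """Deterministic ICD-10-like synthetic code for vocabulary index ``i``.

    Letter + two digits, with a one-character subcode on every third code so
    both bare and subcoded formats flow through the validation paths.
    """
    letter = string.ascii_uppercase[(i // 100) % 26]
    body = f"{letter}{i % 100:02d}"
    if i % 3 == 0:
        return f"{body}.{string.digits[(i // 7) % 10]}"
    return body


def _default_prevalences(k: int) -> np.ndarray:
    # declining prevalence from common (~25%) to rare (~3%)
    return np.geomspace(0.25, 0.03, k)


def _default_effects(k: int) -> np.ndarray:
    # mostly cost-raising conditions, with the last fifth cost-lowering
    return np.linspace(1.2, -0.4, k)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic claims generator.

    Defaults are sized so a generated cohort has roughly Medicare-like
    demographics (mean age ~75, 56% female) and a right-skewed annual cost
    distribution with a log-scale SD near 1.2.
    """

    n_beneficiaries: int = 20_000
    n_latent_conditions: int = 10
    vocab_size: int = 300
    codes_per_condition: int = 12
    condition_prevalences: tuple[float, ...] | None = None
    condition_log_cost_effects: tuple[float, ...] | None = None
    intercept: float = 8.0  # log USD; exp(8) ~ $2981 median-ish baseline
    age_log_cost_effect: float = 0.02  # per year above 65
    female_log_cost_effect: float = -0.08
    residual_log_sd: float = 0.9
    code_emission_prob: float = 0.8
    noise_code_rate: float = 1.0
    zero_dx_fraction: float = 0.05
    zero_cost_fraction: float = 0.0
    female_fraction: float = 0.559
    seed: int = 0

    def resolved_prevalences(self) -> np.ndarray:
        if self.condition_prevalences is None:
            return _default_prevalences(self.n_latent_conditions)
        return np.asarray(self.condition_prevalences, dtype=float)

    def resolved_effects(self) -> np.ndarray:
        if self.condition_log_cost_effects is None:
            return _default_effects(self.n_latent_conditions)
        return np.asarray(self.condition_log_cost_effects, dtype=float)

    def validate(self) -> None:
        k = self.n_latent_conditions
        if self.n_beneficiaries < 1:
            raise ValueError("n_beneficiaries must be >= 1")
        if k < 2:
            raise ValueError("n_latent_conditions must be >= 2")
        if self.codes_per_condition < 1:
            raise ValueError("codes_per_condition must be >= 1")
        if self.codes_per_condition * k > self.vocab_size:
            raise ValueError(
                "vocab_size must be >= codes_per_condition * n_latent_conditions"
            )
        prev = self.resolved_prevalences()
        if len(prev) != k:
            raise ValueError("condition_prevalences length must equal n_latent_conditions")
        if np.any((prev < 0) | (prev > 1)):
            raise ValueError("condition_prevalences must lie in [0, 1]")
        if len(self.resolved_effects()) != k:
            raise ValueError("condition_log_cost_effects length must equal n_latent_conditions")
        if self.residual_log_sd < 0:
            raise ValueError("residual_log_sd must be >= 0")
        for name in ("code_emission_prob", "zero_dx_fraction", "zero_cost_fraction",
                     "female_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_code_rate < 0:
            raise ValueError("noise_code_rate must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side oracle for recovery tests.

    ``condition_indicators`` is an (n, K) boolean array; ``code_condition``
    maps every condition-emitted code to exactly one condition index (noise
    codes are absent from the map); ``expected_log_cost`` is the noiseless
    linear predictor per beneficiary.
    """

    condition_indicators: np.ndarray
    code_condition: dict[str, int]
    expected_log_cost: np.ndarray
    config: GeneratorConfig = field(repr=False, default=None)

    def condition_codes(self, c: int) -> frozenset[str]:
        return frozenset(code for code, cc in self.code_condition.items() if cc == c)


def _draw_ages(rng: np.random.Generator, n: int) -> np.ndarray:
    # gamma-shifted ages: mean ~74.9, SD ~7.2, floored at 65
    shape = (9.9 / 7.2) ** 2
    scale = 9.9 / shape
    ages = 65 + np.floor(rng.gamma(shape, scale, size=n)).astype(int)
    return np.minimum(ages, 110)


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort and its ground truth from the generative model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_beneficiaries
    k = config.n_latent_conditions
    prev = config.resolved_prevalences()
    effects = config.resolved_effects()

    ages = _draw_ages(rng, n)
    female = rng.random(n) < config.female_fraction
    sex = np.where(female, "F", "M")

    z = rng.random((n, k)) < prev[None, :]  # latent condition indicators

    mu = (
        config.intercept
        + config.age_log_cost_effect * (ages - 65)
        + config.female_log_cost_effect * female
        + z @ effects
    )
    log_cost = mu + rng.normal(0.0, config.residual_log_sd, size=n)
    cost = np.exp(log_cost)

    # optional zero-cost stratum to exercise the downstream log-offset policy
    if config.zero_cost_fraction > 0:
        cost = np.where(rng.random(n) < config.zero_cost_fraction, 0.0, cost)

    vocab = [make_code(i) for i in range(config.vocab_size)]
    code_condition = {
        vocab[c * config.codes_per_condition + j]: c
        for c in range(k)
        for j in range(config.codes_per_condition)
    }
    condition_code_idx = np.arange(k * config.codes_per_condition).reshape(
        k, config.codes_per_condition
    )

    empty_dx = rng.random(n) < config.zero_dx_fraction
    dx: list[frozenset[str]] = []
    for i in range(n):
        codes: set[str] = set()
        for c in np.flatnonzero(z[i]):
            emitted = rng.random(config.codes_per_condition) < config.code_emission_prob
            codes.update(vocab[j] for j in condition_code_idx[c][emitted])
        n_noise = rng.poisson(config.noise_code_rate)
        if n_noise:
            codes.update(vocab[j] for j in rng.integers(0, config.vocab_size, n_noise))
        dx.append(frozenset() if empty_dx[i] else frozenset(codes))

    width = len(str(n - 1))
    table = pd.DataFrame(
        {
            "id": [f"B{i:0{width}d}" for i in range(n)],
            "age": ages,
            "sex": sex,
            "observed_cost": cost,
        }
    )
    cohort = Cohort(table, dx)
    truth = GroundTruth(
        condition_indicators=z,
        code_condition=code_condition,
        expected_log_cost=mu,
        config=config,
    )
    return cohort, truth


def age_band_label(age: int) -> str:
    for lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return f"{lo}-{hi}" if hi < 120 else f"{lo}+"
    return "<65"


def cohort_summary(cohort: Cohort) -> dict:
    """Demographic and cost summary of a cohort (Table-1-style layout)."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    t = cohort.table
    n = len(t)
    bands = t["age"].map(age_band_label)
    band_counts = bands.value_counts().sort_index()
    q = t["observed_cost"].quantile([0.1, 0.25, 0.5, 0.75, 0.9])
    return {
        "n_beneficiaries": int(n),
        "sex_counts": {s: int(c) for s, c in t["sex"].value_counts().items()},
        "sex_shares": {s: float(c / n) for s, c in t["sex"].value_counts().items()},
        "age_mean": float(t["age"].mean()),
        "age_sd": float(t["age"].std(ddof=1)) if n > 1 else 0.0,
        "age_band_counts": {b: int(c) for b, c in band_counts.items()},
        "age_band_shares": {b: float(c / n) for b, c in band_counts.items()},
        "cost_mean": float(t["observed_cost"].mean()),
        "cost_quantiles": {f"p{int(p * 100)}": float(v) for p, v in q.items()},
        "empty_dx_fraction": float(np.mean([len(s) == 0 for s in cohort.dx])),
    }


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
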