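"""Accuracy, classification, error-frequency, and actuarial-dispersion metrics.

Everything a risk-adjustment comparison needs for one model on one cohort:

* fit metrics — R² of log cost, R² of cost, MAE of cost, Spearman rho, and
  the two-sample Kolmogorov–Smirnov statistic between the predicted and
  observed log-cost distributions;
* tail classification — sensitivity/specificity/precision for membership
  in the lowest or highest q-tail of the cost distribution (default 20%),
  with predicted positives taken as the same quantile of predicted cost so
  positive counts match by construction;
* substantial prediction errors — the share of beneficiaries whose
  predicted-cost percentile differs from their observed-cost percentile by
  at least a threshold (default 20 and 40 percentile points);
* within-decile dispersion — predictive ratio, IQR, and decile range
  (90th−10th percentile) of observed costs within predicted-risk deciles,
  with bootstrap CIs;
* the dispersion decomposition for log-normal costs: the predictive-ratio
  variance of a plan splits into a structural factor exp(sigma²/2) set by
  cost outliers alone and a residual factor exp((1−R²_log)·sigma²) − 1
  shrinkable by better prediction;
* a downsampled paired t-test (100 samples of 1000) so significance is not
  inflated by a huge evaluation set;
* per-subgroup fit tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FitMetrics",
    "ClassificationMetrics",
    "ErrorFrequencies",
    "DecileDispersion",
    "DispersionDecomposition",
    "DownsampledTest",
    "compute_fit_metrics",
    "classify_extremes",
    "prediction_error_frequencies",
    "decile_dispersion",
    "dispersion_decomposition",
    "residual_dispersion_factor",
    "structural_dispersion_factor",
    "simulate_plan_pr_variance",
    "downsampled_ttest",
    "subgroup_evaluate",
    "percentile_ranks",
]

DEFAULT_LOG_OFFSET = 1.0


@dataclass(frozen=True)
class FitMetrics:
    r2_log: float
    r2_cost: float
    mae_cost: float
    spearman_rho: float
    ks_log: float

    def as_dict(self) -> dict:
        return {
            "r2_log": self.r2_log,
            "r2_cost": self.r2_cost,
            "mae_cost": self.mae_cost,
            "spearman_rho": self.spearman_rho,
            "ks_log": self.ks_log,
        }


def _r2(pred: np.ndarray, obs: np.ndarray) -> float:
    sst = np.sum((obs - obs.mean()) ** 2)
    if sst == 0:
        return float("nan")
    return float(1.0 - np.sum((obs - pred) ** 2) / sst)


def compute_fit_metrics(
    predicted_cost: np.ndarray,
    observed_cost: np.ndarray,
    offset: float = DEFAULT_LOG_OFFSET,
    predicted_log: np.ndarray | None = None,
) -> FitMetrics:
    """Fit metrics between dollar-scale predictions and observations.

    ``predicted_log`` overrides the log-scale predictions used for R²_log
    and the KS statistic — pass the recalibrated log predictions for
    baselines whose native scale is dollars.
    """
    pred = np.asarray(predicted_cost, dtype=float)
    obs = np.asarray(observed_cost, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed lengths differ")
    if len(pred) < 3:
        raise ValueError("need at least 3 pairs")
    log_obs = np.log(obs + offset)
    log_pred = (
        np.asarray(predicted_log, dtype=float)
        if predicted_log is not None
        else np.log(pred + offset)
    )
    rho = stats.spearmanr(pred, obs).statistic
    ks = stats.ks_2samp(log_pred, log_obs, method="asymp").statistic
    return FitMetrics(
        r2_log=_r2(log_pred, log_obs),
        r2_cost=_r2(pred, obs),
        mae_cost=float(np.mean(np.abs(pred - obs))),
        spearman_rho=float(rho),
        ks_log=float(ks),
    )


@dataclass(frozen=True)
class ClassificationMetrics:
    tail: str  # "low" or "high"
    q: float
    cost_threshold: float
    sensitivity: float
    specificity: float
    precision: float
    tp: int
    fp: int
    fn: int
    tn: int

    def as_dict(self) -> dict:
        return {
            "tail": self.tail,
            "q": self.q,
            "cost_threshold": self.cost_threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
        }


def _tail_mask(values: np.ndarray, count: int, tail: str) -> np.ndarray:
    """Boolean mask of the ``count`` most extreme entries (stable ties)."""
    order = np.argsort(values, kind="stable")
    chosen = order[:count] if tail == "low" else order[len(values) - count :]
    mask = np.zeros(len(values), dtype=bool)
    mask[chosen] = True
    return mask


def classify_extremes(
    predicted_cost: np.ndarray,
    observed_cost: np.ndarray,
    q: float = 0.20,
    tail: str = "low",
) -> ClassificationMetrics:
    """Tail-membership classification at quantile q.

    Positives are the q-tail of observed cost; predicted positives are the
    q-tail of predicted cost, so positive and predicted-positive counts are
    equal by construction and sensitivity equals precision.
    """
    if not 0 < q < 0.5:
        raise ValueError(f"q must lie in (0, 0.5), got {q}")
    if tail not in ("low", "high"):
        raise ValueError(f"tail must be 'low' or 'high', got {tail!r}")
    pred = np.asarray(predicted_cost, dtype=float)
    obs = np.asarray(observed_cost, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed lengths differ")
    n = len(obs)
    count = int(round(q * n))
    actual_pos = _tail_mask(obs, count, tail)
    pred_pos = _tail_mask(pred, count, tail)
    tp = int(np.sum(actual_pos & pred_pos))
    fp = int(np.sum(~actual_pos & pred_pos))
    fn = int(np.sum(actual_pos & ~pred_pos))
    tn = int(np.sum(~actual_pos & ~pred_pos))
    threshold = (
        float(np.sort(obs)[count - 1]) if tail == "low" else float(np.sort(obs)[n - count])
    ) if count > 0 else float("nan")
    return ClassificationMetrics(
        tail=tail,
        q=q,
        cost_threshold=threshold,
        sensitivity=tp / max(tp + fn, 1),
        specificity=tn / max(tn + fp, 1),
        precision=tp / max(tp + fp, 1),
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )


def percentile_ranks(values: np.ndarray) -> np.ndarray:
    """Average-rank percentiles scaled to (0, 100]."""
    values = np.asarray(values, dtype=float)
    return stats.rankdata(values, method="average") * 100.0 / len(values)


@dataclass(frozen=True)
class ErrorFrequencies:
    thresholds: tuple[float, ...]
    overprediction: tuple[float, ...]
    underprediction: tuple[float, ...]
    curve: pd.DataFrame = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "thresholds": list(self.thresholds),
            "overprediction": list(self.overprediction),
            "underprediction": list(self.underprediction),
        }


def prediction_error_frequencies(
    predicted_cost: np.ndarray,
    observed_cost: np.ndarray,
    thresholds: Sequence[float] = (20.0, 40.0),
    curve_grid: Sequence[float] | None = None,
) -> ErrorFrequencies:
    """Share of beneficiaries mispredicted by >= t percentile points.

    The error is percentile_rank(predicted) − percentile_rank(observed),
    ranks computed within the evaluation cohort with average-rank ties.
    Overprediction frequency at t is the share with error >= t;
    underprediction the share with error <= −t.
    """
    pred = np.asarray(predicted_cost, dtype=float)
    obs = np.asarray(observed_cost, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed lengths differ")
    err = percentile_ranks(pred) - percentile_ranks(obs)
    over = tuple(float(np.mean(err >= t)) for t in thresholds)
    under = tuple(float(np.mean(err <= -t)) for t in thresholds)
    if curve_grid is None:
        curve_grid = np.arange(0.0, 101.0, 5.0)
    curve = pd.DataFrame(
        {
            "threshold": list(curve_grid),
            "overprediction": [float(np.mean(err >= t)) for t in curve_grid],
            "underprediction": [float(np.mean(err <= -t)) for t in curve_grid],
        }
    )
    return ErrorFrequencies(
        thresholds=tuple(float(t) for t in thresholds),
        overprediction=over,
        underprediction=under,
        curve=curve,
    )


@dataclass(frozen=True)
class DecileDispersion:
    """Per predicted-risk decile: PR, observed-cost IQR and decile range."""

    table: pd.DataFrame  # decile, pr, iqr, decile_range + CI columns

    def as_dict(self) -> dict:
        return self.table.to_dict(orient="list")


def decile_dispersion(
    predicted_cost: np.ndarray,
    observed_cost: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
) -> DecileDispersion:
    """Within-decile predictive ratios and observed-cost spread, with CIs.

    Deciles are equal-count groups ranked by predicted cost (stable ties).
    CIs are percentile bootstrap over beneficiary resampling within decile.
    """
    pred = np.asarray(predicted_cost, dtype=float)
    obs = np.asarray(observed_cost, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed lengths differ")
    order = np.argsort(pred, kind="stable")
    groups = np.array_split(order, 10)
    rng = np.random.default_rng(seed)
    rows = []
    for d, g in enumerate(groups):
        po, oo = pred[g], obs[g]
        iqr = float(np.percentile(oo, 75) - np.percentile(oo, 25))
        drange = float(np.percentile(oo, 90) - np.percentile(oo, 10))
        pr = float(po.mean() / oo.mean()) if oo.mean() > 0 else float("nan")
        boots_iqr, boots_rng, boots_pr = [], [], []
        for _ in range(n_boot):
            idx = rng.integers(0, len(g), size=len(g))
            ob = oo[idx]
            boots_iqr.append(np.percentile(ob, 75) - np.percentile(ob, 25))
            boots_rng.append(np.percentile(ob, 90) - np.percentile(ob, 10))
            boots_pr.append(po[idx].mean() / ob.mean() if ob.mean() > 0 else np.nan)
        lo, hi = (2.5, 97.5)
        rows.append(
            {
                "decile": d + 1,
                "pr": pr,
                "pr_ci_low": float(np.percentile(boots_pr, lo)),
                "pr_ci_high": float(np.percentile(boots_pr, hi)),
                "iqr": iqr,
                "iqr_ci_low": float(np.percentile(boots_iqr, lo)),
                "iqr_ci_high": float(np.percentile(boots_iqr, hi)),
                "decile_range": drange,
                "decile_range_ci_low": float(np.percentile(boots_rng, lo)),
                "decile_range_ci_high": float(np.percentile(boots_rng, hi)),
            }
        )
    return DecileDispersion(table=pd.DataFrame(rows))


def structural_dispersion_factor(sigma: float) -> float:
    """Model-independent outlier factor exp(sigma²/2) of log-normal costs."""
    return float(np.exp(sigma**2 / 2.0))


def residual_dispersion_factor(sigma: float, r2_log: float) -> float:
    """Model-controllable factor exp((1 − R²_log)·sigma²) − 1."""
    return float(np.exp((1.0 - r2_log) * sigma**2) - 1.0)


@dataclass(frozen=True)
class DispersionDecomposition:
    sigma: float
    r2_log: float
    structural_factor: float
    residual_factor: float

    def as_dict(self) -> dict:
        return {
            "sigma": self.sigma,
            "r2_log": self.r2_log,
            "structural_factor": self.structural_factor,
            "residual_factor": self.residual_factor,
        }


def dispersion_decomposition(
    observed_cost: np.ndarray, r2_log: float, offset: float = DEFAULT_LOG_OFFSET
) -> DispersionDecomposition:
    """Structural/residual split of predictive-ratio variability.

    sigma is the sample SD of log(observed + offset); for sigma = 0 the
    structural factor is 1 and the residual factor 0.
    """
    obs = np.asarray(observed_cost, dtype=float)
    if np.any(obs + offset <= 0):
        raise ValueError("observed costs must be positive after offset")
    sigma = float(np.std(np.log(obs + offset), ddof=1)) if len(obs) > 1 else 0.0
    return DispersionDecomposition(
        sigma=sigma,
        r2_log=r2_log,
        structural_factor=structural_dispersion_factor(sigma),
        residual_factor=residual_dispersion_factor(sigma, r2_log),
    )


def simulate_plan_pr_variance(
    sigma: float,
    r2_values: Sequence[float],
    plan_size: int = 1000,
    n_plans: int = 2000,
    seed: int = 0,
) -> dict:
    """Monte-Carlo check of the dispersion decomposition.

    Simulates log-normal costs (log cost L ~ N(0, sigma²)) and, for each
    requested R²_log, a Gaussian log-scale predictor P = L + eps with
    Var(eps) = (1 − R²)·sigma² — the truth-plus-noise construction, under
    which the delta-method plan-level PR variance is proportional to the
    residual dispersion factor with an R²-independent constant.  Payments
    exp(P) are scaled so the cohort-level PR is 1.  The latent costs and
    the standard-normal noise are shared across predictors (common random
    numbers), so ratios of empirical PR variances estimate ratios of
    residual factors with low Monte-Carlo error.

    Returns empirical PR variances per R², the residual factors, and the
    pairwise variance ratios alongside the predicted factor ratios.
    """
    rng = np.random.default_rng(seed)
    log_cost = rng.normal(0.0, sigma, size=(n_plans, plan_size))
    noise = rng.normal(0.0, 1.0, size=(n_plans, plan_size))
    cost = np.exp(log_cost)
    cohort_mean = cost.mean()
    pr_var: dict[float, float] = {}
    for r2 in r2_values:
        pay = np.exp(log_cost + sigma * np.sqrt(1.0 - r2) * noise)
        pay *= cohort_mean / pay.mean()
        pr = pay.mean(axis=1) / cost.mean(axis=1)
        pr_var[r2] = float(pr.var(ddof=1))
    factors = {r2: residual_dispersion_factor(sigma, r2) for r2 in r2_values}
    ratios = {}
    r2_list = list(r2_values)
    for i, a in enumerate(r2_list):
        for b in r2_list[i + 1 :]:
            ratios[(a, b)] = {
                "empirical": pr_var[a] / pr_var[b],
                "predicted": factors[a] / factors[b],
            }
    return {
        "pr_variance": pr_var,
        "residual_factors": factors,
        "ratios": ratios,
        "plan_size": plan_size,
        "n_plans": n_plans,
    }


@dataclass(frozen=True)
class DownsampledTest:
    metric: str
    n_samples: int
    sample_size: int
    differences: np.ndarray
    t_statistic: float
    p_value: float
    seed: int

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "n_samples": self.n_samples,
            "sample_size": self.sample_size,
            "mean_difference": float(np.mean(self.differences)),
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
        }


def downsampled_ttest(
    metric: Callable[[np.ndarray, np.ndarray], float] | str,
    predictions_a: np.ndarray,
    predictions_b: np.ndarray,
    observed: np.ndarray,
    seed: int = 0,
    n_samples: int = 100,
    sample_size: int = 1000,
    disjoint: bool = False,
) -> DownsampledTest:
    """Paired t-test of a metric difference over repeated subsamples.

    Each of ``n_samples`` samples of ``sample_size`` beneficiaries is
    scored under both models and the two-sided paired t-test is applied to
    the per-sample metric differences.  Sampling is with replacement by
    default (``disjoint=True`` partitions a permutation instead, requiring
    n >= n_samples*sample_size).  A metric undefined on a sample is
    redrawn once.  If every difference is zero the comparison is
    degenerate and p = 1.
    """
    named = {
        "spearman": lambda p, o: float(stats.spearmanr(p, o).statistic),
        "r2_log": lambda p, o: _r2(np.log(p + 1.0), np.log(o + 1.0)),
        "mae": lambda p, o: float(np.mean(np.abs(p - o))),
    }
    metric_name = metric if isinstance(metric, str) else getattr(metric, "__name__", "metric")
    metric_fn = named[metric] if isinstance(metric, str) else metric
    a = np.asarray(predictions_a, dtype=float)
    b = np.asarray(predictions_b, dtype=float)
    obs = np.asarray(observed, dtype=float)
    n = len(obs)
    if n < sample_size:
        raise ValueError(f"need at least {sample_size} beneficiaries, got {n}")
    rng = np.random.default_rng(seed)
    if disjoint:
        if n < n_samples * sample_size:
            raise ValueError("cohort too small for disjoint samples")
        perm = rng.permutation(n)
        index_sets = [
            perm[i * sample_size : (i + 1) * sample_size] for i in range(n_samples)
        ]
    else:
        index_sets = [rng.choice(n, size=sample_size, replace=True) for _ in range(n_samples)]
    diffs = []
    for idx in index_sets:
        for attempt in range(2):
            ma = metric_fn(a[idx], obs[idx])
            mb = metric_fn(b[idx], obs[idx])
            if np.isfinite(ma) and np.isfinite(mb):
                break
            if attempt == 0:
                idx = rng.choice(n, size=sample_size, replace=True)
            else:
                raise ValueError("metric undefined on a redrawn sample")
        diffs.append(ma - mb)
    diffs = np.asarray(diffs)
    if np.allclose(diffs, 0.0):
        t_stat, p = 0.0, 1.0
    else:
        res = stats.ttest_1samp(diffs, 0.0)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return DownsampledTest(
        metric=metric_name,
        n_samples=n_samples,
        sample_size=sample_size,
        differences=diffs,
        t_statistic=t_stat,
        p_value=p,
        seed=seed,
    )


def subgroup_evaluate(
    predicted_cost: np.ndarray,
    observed_cost: np.ndarray,
    subgroup: Sequence,
    offset: float = DEFAULT_LOG_OFFSET,
    predicted_log: np.ndarray | None = None,
    min_size: int = 30,
) -> pd.DataFrame:
    """Fit metrics per subgroup level, with shares and small-level flags."""
    pred = np.asarray(predicted_cost, dtype=float)
    obs = np.asarray(observed_cost, dtype=float)
    labels = pd.Series(list(subgroup))
    if len(labels) != len(pred):
        raise ValueError("subgroup length must match predictions")
    rows = []
    for level, idx in labels.groupby(labels).groups.items():
        sel = np.asarray(idx, dtype=int)
        plog = predicted_log[sel] if predicted_log is not None else None
        if len(sel) >= 3:
            m = compute_fit_metrics(pred[sel], obs[sel], offset=offset, predicted_log=plog)
        else:  # too small for correlation-based metrics; flagged below
            m = FitMetrics(*(float("nan"),) * 5)
        rows.append(
            {
                "level": level,
                "n": len(sel),
                "share": len(sel) / len(pred),
                "below_min_size": len(sel) < min_size,
                **m.as_dict(),
            }
        )
    return pd.DataFrame(rows)
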