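"""Brute-force reference implementations used to cross-check the package.

Everything here is written for clarity at tiny input sizes (exhaustive
counting, O(n^2) loops, explicit transitive closure) and stays independent
of the code paths it validates.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence


def average_ranks(values: Sequence[float]) -> list[float]:
    """Rank with average tie handling by explicit counting."""
    n = len(values)
    ranks = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(less + (equal + 1) / 2)
    return ranks


def spearman_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation of average ranks."""
    rx, ry = average_ranks(x), average_ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    if vx == 0 or vy == 0:
        return math.nan
    return cov / math.sqrt(vx * vy)


def ks_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sample sup-distance between empirical CDFs at all sample points."""
    points = sorted(set(x) | set(y))
    best = 0.0
    for p in points:
        fx = sum(1 for v in x if v <= p) / len(x)
        fy = sum(1 for v in y if v <= p) / len(y)
        best = max(best, abs(fx - fy))
    return best


def quantile_oracle(values: Sequence[float], q: float) -> float:
    """Linear-interpolation quantile on the sorted sample."""
    s = sorted(values)
    pos = (len(s) - 1) * q
    lo = math.floor(pos)
    hi = math.ceil(pos)
    if lo == hi:
        return float(s[lo])
    return s[lo] + (pos - lo) * (s[hi] - s[lo])


def tail_indices_oracle(values: Sequence[float], count: int, tail: str) -> set[int]:
    """Indices of the ``count`` most extreme values; ties broken by position."""
    order = sorted(range(len(values)), key=lambda i: values[i])  # stable
    chosen = order[:count] if tail == "low" else order[len(values) - count :]
    return set(chosen)


def confusion_oracle(
    pred: Sequence[float], obs: Sequence[float], q: float, tail: str
) -> dict:
    n = len(obs)
    count = int(round(q * n))
    actual = tail_indices_oracle(obs, count, tail)
    predicted = tail_indices_oracle(pred, count, tail)
    tp = len(actual & predicted)
    fp = len(predicted - actual)
    fn = len(actual - predicted)
    tn = n - tp - fp - fn
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def percentile_error_oracle(
    pred: Sequence[float], obs: Sequence[float], threshold: float
) -> tuple[float, float]:
    """(overprediction, underprediction) frequencies at one threshold."""
    n = len(obs)
    pr = [r * 100 / n for r in average_ranks(pred)]
    po = [r * 100 / n for r in average_ranks(obs)]
    errs = [a - b for a, b in zip(pr, po)]
    over = sum(1 for e in errs if e >= threshold) / n
    under = sum(1 for e in errs if e <= -threshold) / n
    return over, under


def suppression_oracle(
    codes: Iterable[str],
    icd_to_category: Mapping[str, str],
    edges: Sequence[tuple[str, str]],
    categories: Iterable[str],
) -> set[str]:
    """Category assignment with transitive suppression via explicit closure."""
    cats = sorted(set(categories))
    reach = {(a, b) for a, b in edges}
    # transitive closure by repeated relaxation
    changed = True
    while changed:
        changed = False
        for a in cats:
            for b in cats:
                if (a, b) in reach:
                    continue
                if any((a, m) in reach and (m, b) in reach for m in cats):
                    reach.add((a, b))
                    changed = True
    present = {icd_to_category[c] for c in codes if c in icd_to_category}
    return {
        c for c in present if not any(d != c and (d, c) in reach for d in present)
    }
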