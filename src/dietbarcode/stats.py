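"""Exact and Monte-Carlo tests for category-count comparisons.

Used to compare ingested-biomass proportions with assigned-read proportions
across the three food categories, and detection counts between sequencing
platforms.  The two-sided 2x2 test follows the probability-mass convention
(sum the probabilities of all tables, under fixed margins, that are at most
as probable as the observed one); r x c tables use a margin-preserving
Monte-Carlo permutation estimate of the same rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import hypergeom

_TIE_RTOL = 1e-7


@dataclass
class MonteCarloP:
    p_value: float
    std_error: float
    n_permutations: int


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Enumerates the full hypergeometric distribution over tables with the
    observed margins and sums the probabilities <= that of the observed table
    (within relative tolerance 1e-7 for ties).  A zero margin makes the table
    degenerate: p = 1 by convention, with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    a, b = t[0]
    c, d = t[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0 or n == 0:
        warnings.warn("degenerate margin in 2x2 table; p = 1 by convention", stacklevel=2)
        return 1.0
    p_obs = hypergeom.pmf(a, n, r1, c1)
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    probs = hypergeom.pmf(k, n, r1, c1)
    p = probs[probs <= p_obs * (1 + _TIE_RTOL)].sum()
    return float(min(p, 1.0))


def _log_table_prob(t: np.ndarray) -> float:
    """Log conditional probability of an r x c table given its margins."""
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()
    return float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
        - gammaln(t + 1).sum()
    )


def fisher_exact_rxc(table, n_permutations: int = 10_000, seed: int = 0) -> MonteCarloP:
    """Monte-Carlo Fisher exact test for an r x c table.

    Samples margin-preserving tables by permuting one categorical label
    vector against the other and counts tables at most as probable as the
    observed one; reported with the plus-one correction (b + 1) / (n + 1)
    and a binomial standard error.  Deterministic under a fixed seed.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2 or (t < 0).any():
        raise ValueError("need an r x c (r, c >= 2) table of non-negative integers")
    if n_permutations < 1000:
        raise ValueError("n_permutations must be >= 1000")
    rng = np.random.default_rng(seed)
    r, c = t.shape
    row_labels = np.repeat(np.arange(r), t.sum(axis=1))
    col_labels = np.repeat(np.arange(c), t.sum(axis=0))
    log_obs = _log_table_prob(t)
    tol = abs(log_obs) * _TIE_RTOL + 1e-12
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(col_labels)
        sampled = np.zeros((r, c), dtype=int)
        np.add.at(sampled, (row_labels, perm), 1)
        if _log_table_prob(sampled) <= log_obs + tol:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    se = float(np.sqrt(p * (1 - p) / n_permutations))
    return MonteCarloP(p_value=float(p), std_error=se, n_permutations=n_permutations)


def compare_detection_counts(summary_a, summary_b) -> dict[str, dict]:
    """Per-category detected/missed 2x2 tables between two platforms.

    Inputs are mappings category -> DetectionSummary (or any object with
    ``expected`` and ``observed_total``).  Detected counts are capped at the
    expected denominator so that "missed" stays non-negative when carry-over
    detections overshoot.  Categories with no expected occurrences are
    skipped with a note.
    """
    if set(summary_a) != set(summary_b):
        raise ValueError("summaries do not share categories")
    out: dict[str, dict] = {}
    for cat in summary_a:
        sa, sb = summary_a[cat], summary_b[cat]
        if sa.expected == 0 or sb.expected == 0:
            out[cat] = {"table": None, "p_value": None, "note": "no expected occurrences"}
            continue
        det_a = min(sa.observed_total, sa.expected)
        det_b = min(sb.observed_total, sb.expected)
        table = [[det_a, sa.expected - det_a], [det_b, sb.expected - det_b]]
        out[cat] = {"table": table, "p_value": fisher_exact_2x2(table), "note": ""}
    return out


def detection_long_table(summaries: dict[str, dict]) -> "pd.DataFrame":
    """Model-ready long-format detection table (platform, category, detected).

    One row per expected occurrence with a 0/1 outcome — the input a binomial
    GLM of detectability would consume; the model fit itself is out of scope
    here.
    """
    import pandas as pd

    rows = []
    for platform, cats in summaries.items():
        for cat, s in cats.items():
            det = min(s.observed_total, s.expected)
            rows += [
                {"platform": platform, "category": cat, "detected": 1}
            ] * det
            rows += [
                {"platform": platform, "category": cat, "detected": 0}
            ] * (s.expected - det)
    return pd.DataFrame(rows, columns=["platform", "category", "detected"])
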