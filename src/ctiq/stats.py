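"""Reconstruction-comparison statistics.

* one-way repeated-measures ANOVA with Bonferroni-corrected pairwise
  comparisons against a baseline reconstruction (quantitative metrics),
* Wilcoxon signed-rank for paired ordinal reader scores,
* Cohen's kappa with agreement-band labels for two-reader agreement,
* percent-change summaries.

Conventions: the Bonferroni family is the three comparisons against the
baseline (multiplier 3, configurable via ``n_comparisons``); Wilcoxon drops
zero differences and mid-ranks ties, using exact sign-assignment
enumeration for <= 12 non-zero pairs and a normal approximation with
continuity and tie correction above; kappa is unweighted, and when both
raters are constant (expected agreement 1) it is defined as 0 with a
degenerate flag.  p < 0.05 is flagged significant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
KAPPA_BANDS = ((0.20, "poor"), (0.40, "fair"), (0.60, "moderate"), (0.80, "good"))


@dataclass
class StatResult:
    test: str
    comparison: str
    statistic: float
    df: tuple | None
    p_raw: float
    p_adjusted: float
    adjust_method: str
    significant: bool
    degenerate: bool = False
    direction: str = ""


@dataclass
class KappaResult:
    kappa: float
    band: str
    degenerate: bool
    n: int
    observed_agreement: float
    expected_agreement: float


def bonferroni(p_raw: float, n_comparisons: int) -> float:
    """p_adjusted = min(1, n*p)."""
    return min(1.0, n_comparisons * p_raw)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def rm_anova_bonferroni(metrics: pd.DataFrame | np.ndarray,
                        baseline: str | int = 0,
                        condition_names: Sequence[str] | None = None,
                        n_comparisons: int | None = None) -> list[StatResult]:
    """Within-subject ANOVA plus Bonferroni-adjusted paired comparisons.

    ``metrics`` is subjects x conditions (wide); rows with any missing cell
    are dropped listwise.  The omnibus F is the one-way within-subject
    ANOVA (no sphericity correction — available upstream via pingouin's
    correction flag if wanted); each non-baseline condition is compared to
    ``baseline`` with a paired t-test, Bonferroni-multiplied by the family
    size (default: number of non-baseline conditions).
    """
    if isinstance(metrics, pd.DataFrame):
        wide = metrics.copy()
    else:
        arr = np.asarray(metrics, dtype=float)
        names = list(condition_names) if condition_names is not None else [f"C{i}" for i in range(arr.shape[1])]
        wide = pd.DataFrame(arr, columns=names)
    wide = wide.dropna(axis=0)
    n_subj, n_cond = wide.shape
    if n_subj < 3:
        raise ValueError(f"repeated-measures ANOVA needs >= 3 complete subjects, got {n_subj}")
    if n_cond < 2:
        raise ValueError("need >= 2 conditions")
    base = wide.columns[baseline] if isinstance(baseline, int) else baseline
    if base not in wide.columns:
        raise ValueError(f"baseline {base!r} not among conditions {list(wide.columns)}")
    others = [c for c in wide.columns if c != base]
    fam = n_comparisons if n_comparisons is not None else len(others)

    results: list[StatResult] = []
    col_const = [np.allclose(wide[c], wide[c].iloc[0]) for c in wide.columns]
    if np.allclose(wide.to_numpy(), wide.to_numpy()[:, [0]]):
        # all conditions identical: no condition effect at all
        results.append(StatResult("rm_anova", "omnibus", 0.0,
                                  (n_cond - 1, (n_cond - 1) * (n_subj - 1)),
                                  1.0, 1.0, "none", False, degenerate=True))
    else:
        import pingouin as pg

        long = wide.reset_index(names="subject").melt(
            id_vars="subject", var_name="condition", value_name="value")
        aov = pg.rm_anova(data=long, dv="value", within="condition", subject="subject",
                          correction=False, detailed=True)
        f = float(aov.loc[0, "F"])
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        p = float(aov.loc[0, p_col])
        df1, df2 = int(aov.loc[0, "DF"]), int(aov.loc[1, "DF"])
        results.append(StatResult("rm_anova", "omnibus", f, (df1, df2), p, p, "none",
                                  p < ALPHA, degenerate=any(col_const)))

    for c in others:
        diff = wide[c] - wide[base]
        if np.allclose(diff, 0):
            results.append(StatResult("paired_t", f"{c} vs {base}", 0.0, (n_subj - 1,),
                                      1.0, 1.0, "bonferroni", False, degenerate=True))
            continue
        t = sps.ttest_rel(wide[c], wide[base])
        p_adj = bonferroni(float(t.pvalue), fam)
        direction = "increase" if diff.mean() > 0 else "decrease"
        results.append(StatResult("paired_t", f"{c} vs {base}", float(t.statistic),
                                  (n_subj - 1,), float(t.pvalue), p_adj, "bonferroni",
                                  p_adj < ALPHA, direction=direction))
    return results


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float],
                         exact_limit: int = 12) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zero differences are dropped (Wilcoxon's original treatment — relevant
    here because reader-score comparisons contain many ties); ties among
    |differences| get mid-ranks.  For <= ``exact_limit`` non-zero pairs the
    p-value is the exact tail probability over all 2^n sign assignments of
    the mid-ranks; above that, a normal approximation with continuity
    correction and tie-corrected variance Var(W+) = sum(r_i^2)/4 is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired vectors differ in length: {a.shape} vs {b.shape}")
    d = b - a
    d = d[d != 0]
    n = d.size
    if n == 0:
        return StatResult("wilcoxon", "paired", float("nan"), None, 1.0, 1.0,
                          "none", False, degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0

    if n <= exact_limit:
        # exact null: every sign assignment of the mid-ranks equally likely
        dev = abs(w_plus - mu)
        count = 0
        for signs in itertools.product((0.0, 1.0), repeat=n):
            w = float(np.dot(signs, ranks))
            if abs(w - mu) >= dev - 1e-12:
                count += 1
        p = count / 2.0**n
        method = "exact"
    else:
        sigma = np.sqrt((ranks**2).sum() / 4.0)
        z = (abs(w_plus - mu) - 0.5) / sigma
        p = min(1.0, 2.0 * sps.norm.sf(z))
        method = "normal_cc"
    return StatResult(f"wilcoxon_{method}", "paired", w_plus, (n,), p, p, "none",
                      p < ALPHA,
                      direction="increase" if w_plus > mu else ("decrease" if w_plus < mu else ""))


# ---------------------------------------------------------------------------
# Cohen's kappa


def kappa_band(kappa: float) -> str:
    """Agreement band: <=0.20 poor, <=0.40 fair, <=0.60 moderate, <=0.80 good, else excellent."""
    for cut, name in KAPPA_BANDS:
        if kappa <= cut:
            return name
    return "excellent"


def cohen_kappa(scores_1: Sequence[int], scores_2: Sequence[int],
                categories: Sequence[int] = (1, 2, 3, 4)) -> KappaResult:
    """Unweighted Cohen's kappa on the cross-table over ``categories``.

    kappa = (p_o - p_e) / (1 - p_e).  When both raters are constant the
    expected agreement is 1 and the ratio is undefined; by convention the
    result is kappa = 0 with the degenerate flag set.
    """
    s1 = np.asarray(scores_1)
    s2 = np.asarray(scores_2)
    if s1.shape != s2.shape:
        raise ValueError(f"score vectors differ in length: {s1.shape} vs {s2.shape}")
    if s1.size == 0:
        raise ValueError("empty score vectors")
    cats = list(categories)
    for v in np.concatenate([s1, s2]):
        if v not in cats:
            raise ValueError(f"score {v} outside categories {cats}")
    k = len(cats)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((k, k))
    for x, y in zip(s1, s2):
        table[idx[x], idx[y]] += 1
    n = table.sum()
    p_o = float(np.trace(table) / n)
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    p_e = float((row * col).sum())
    if np.isclose(p_e, 1.0):
        return KappaResult(0.0, kappa_band(0.0), True, int(n), p_o, p_e)
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(float(kappa), kappa_band(kappa), False, int(n), p_o, p_e)


# ---------------------------------------------------------------------------
# percent change


def percent_change(baseline: float, new: float, direction: str = "reduction") -> float:
    """Percent change relative to baseline.

    reduction = 100*(baseline - new)/baseline; increase = 100*(new -
    baseline)/baseline.  Rounded only at display.
    """
    if baseline == 0:
        raise ValueError("percent change undefined for baseline 0")
    if direction == "reduction":
        return 100.0 * (baseline - new) / baseline
    if direction == "increase":
        return 100.0 * (new - baseline) / baseline
    raise ValueError(f"direction must be 'reduction' or 'increase', got {direction!r}")
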