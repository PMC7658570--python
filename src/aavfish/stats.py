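"""Downstream statistics for per-cell genome counts.

Limiting-dilution regression with a linear-vs-power model contrast,
per-cell count distributions, expression-versus-count trends, and
pairwise group comparisons by pooled two-sample t tests with Bonferroni
correction.

The limiting-dilution logic: if one genome suffices to produce one
punctum, an x-fold drop in vector titer produces an x-fold drop in the
mean puncta count per cell (linear in titer); if y genomes in close
proximity were required per punctum, the same dilution produces an
x^y-fold drop. The package fits ordinary least squares of group mean
count on titer, reports R^2 with a 95% confidence band, and overlays
the count ~ titer^y prediction anchored at the highest-titer group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm


@dataclass
class DilutionFit:
    """Limiting-dilution regression output."""

    titers: list[float]
    group_means: list[float]
    group_sems: list[float]
    slope: float
    intercept: float
    r_squared: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    power_exponent: float
    power_predictions: list[float]
    power_r_squared_loglog: float | None = None
    n_cells: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def mean_ci_band(self, titers, alpha: float = 0.05) -> np.ndarray:
        """95% CI half-width of the fitted mean response at ``titers``."""
        x = np.asarray(self.titers, dtype=float)
        xq = np.asarray(titers, dtype=float)
        n = len(x)
        resid = np.asarray(self.group_means) - (self.intercept + self.slope * x)
        s2 = float(resid @ resid) / (n - 2)
        sxx = float(((x - x.mean()) ** 2).sum())
        se = np.sqrt(s2 * (1.0 / n + (xq - x.mean()) ** 2 / sxx))
        return sps.t.ppf(1 - alpha / 2, n - 2) * se


def dilution_fit(
    titers,
    counts_per_group,
    power_exponent: float = 2.0,
) -> DilutionFit:
    """OLS of group mean puncta count on titer, plus power-model overlay.

    ``counts_per_group`` is one array of per-cell counts per titer
    group. R^2 is computed over the group means (the titer series'
    presentation unit); per-group SEMs are carried for display. The
    alternative count ~ titer^y prediction is anchored at the
    highest-titer group's observed mean, and its goodness of fit is
    reported in log-log space over groups with nonzero means.
    """
    titers = np.asarray(titers, dtype=float)
    if len(titers) < 3:
        raise ValueError("need at least 3 titer groups for a dilution fit")
    if len(counts_per_group) != len(titers):
        raise ValueError("one count array required per titer group")
    if np.ptp(titers) == 0:
        raise ValueError("all titers equal: no dilution series to regress on")
    groups = [np.asarray(c, dtype=float) for c in counts_per_group]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every titer group needs at least one cell")
    means = np.array([g.mean() for g in groups])
    sems = np.array([
        g.std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else 0.0 for g in groups
    ])

    X = sm.add_constant(titers)
    fit = sm.OLS(means, X).fit()
    intercept, slope = fit.params
    ci = fit.conf_int(alpha=0.05)
    # guard the degenerate flat series (zero total sum of squares)
    ss_tot = float(((means - means.mean()) ** 2).sum())
    if ss_tot > 0:
        r_squared = float(fit.rsquared)
    else:
        r_squared = 1.0 if float(fit.ssr) < 1e-300 else 0.0

    top = int(np.argmax(titers))
    power_pred = means[top] * (titers / titers[top]) ** power_exponent
    pos = means > 0
    if pos.sum() >= 2 and np.ptp(np.log(titers[pos])) > 0:
        ly = np.log(means[pos])
        lp = np.log(power_pred[pos])
        ss_res = float(((ly - lp) ** 2).sum())
        ss_tot = float(((ly - ly.mean()) ** 2).sum())
        power_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else None
    else:
        power_r2 = None

    return DilutionFit(
        titers=titers.tolist(),
        group_means=means.tolist(),
        group_sems=sems.tolist(),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r_squared,
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        power_exponent=float(power_exponent),
        power_predictions=power_pred.tolist(),
        power_r_squared_loglog=power_r2,
        n_cells=[int(len(g)) for g in groups],
    )


def count_distribution(
    counts, bins: tuple[int, ...] = (0, 1, 2, 3, 4), group: str | None = None
) -> dict:
    """Histogram of per-cell genome counts with a terminal overflow bin.

    ``bins`` lists the exact counts reported individually; everything
    above the last one lands in a ``>last`` bin. Also reports the
    fractions of cells with zero and with at least one genome, and the
    mean count.
    """
    counts = np.asarray(counts)
    if counts.size and (np.any(counts < 0) or np.any(counts != np.floor(counts))):
        raise ValueError("counts must be non-negative integers")
    counts = counts.astype(int)
    n = len(counts)
    hist = {str(b): int((counts == b).sum()) for b in bins}
    hist[f">{bins[-1]}"] = int((counts > bins[-1]).sum())
    frac = {k: (v / n if n else 0.0) for k, v in hist.items()}
    return {
        "group": group,
        "n_cells": n,
        "histogram": hist,
        "fractions": frac,
        "fraction_zero": float((counts == 0).mean()) if n else None,
        "fraction_positive": float((counts >= 1).mean()) if n else None,
        "mean_count": float(counts.mean()) if n else None,
    }


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    return float(rx @ ry / denom) if denom > 0 else 0.0


def expression_by_count(
    counts,
    intensities,
    bins: tuple[int, ...] = (0, 1, 2, 3, 4),
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Expression intensity binned by genome count, with a trend test.

    Reports mean and SEM of intensity per count bin and the Spearman
    rank correlation between count and intensity with a two-sided
    permutation p-value (intensities permuted against counts,
    ``n_permutations`` draws, seeded). With fewer than two distinct
    counts the trend is undefined and reported as None.
    """
    counts = np.asarray(counts, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if counts.shape != intensities.shape:
        raise ValueError("counts and intensities must align")
    edges = list(bins)
    labels = [str(b) for b in edges] + [f">{edges[-1]}"]
    which = np.digitize(counts, edges + [np.inf], right=True)
    per_bin = []
    for i, lab in enumerate(labels):
        vals = intensities[which == i]
        per_bin.append({
            "bin": lab,
            "n": int(len(vals)),
            "mean": float(vals.mean()) if len(vals) else None,
            "sem": float(vals.std(ddof=1) / np.sqrt(len(vals)))
            if len(vals) > 1 else None,
        })
    if len(np.unique(counts)) < 2:
        return {"bins": per_bin, "rho": None, "p_value": None}
    rho = _spearman(counts, intensities)
    rng = np.random.default_rng(seed)
    rx = sps.rankdata(counts)
    ry = sps.rankdata(intensities)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:  # one variable constant: no orderable trend
        return {"bins": per_bin, "rho": 0.0, "p_value": 1.0}
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = rx @ rng.permutation(ry) / denom
    p = (1 + np.sum(np.abs(null) >= abs(rho) - 1e-12)) / (n_permutations + 1)
    return {"bins": per_bin, "rho": float(rho), "p_value": float(p)}


def student_t_pooled(a, b) -> tuple[float, float]:
    """Two-tailed two-sample Student's t test with pooled variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    sa2, sb2 = a.var(ddof=1), b.var(ddof=1)
    if sa2 == 0 and sb2 == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0  # identical constants: no evidence either way
        return float("inf"), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def compare_groups(samples: dict, correction: str = "bonferroni") -> pd.DataFrame:
    """All pairwise pooled t tests between named groups.

    Adjusted p = min(1, m * p) with m the number of comparisons made
    (Bonferroni). Returns one row per unordered pair.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    names = list(samples)
    pairs = [(names[i], names[j]) for i in range(len(names))
             for j in range(i + 1, len(names))]
    m = len(pairs)
    rows = []
    for ga, gb in pairs:
        t, p = student_t_pooled(samples[ga], samples[gb])
        p_adj = min(1.0, m * p) if correction == "bonferroni" else p
        rows.append({
            "group_a": ga, "group_b": gb, "t": t, "p": p, "p_adjusted": p_adj,
            "n_comparisons": m,
        })
    return pd.DataFrame(rows)
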