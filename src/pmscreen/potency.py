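"""Particle potency estimation and ranking from dose-response fold-changes.

The dose-effect model is ``fold_change = (dose + 1) ** beta``: beta is the
rate of change of log fold-effect with log(dose + 1), so the model passes
through fold-change 1 at dose 0 by construction.  Taking logs gives the
no-intercept regression y = beta * x with x = ln(dose + 1), y = ln(fc),
whose exact least-squares solution is beta = sum(x*y) / sum(x*x); dose-0
points carry x = 0 and cannot move the estimate.

Per-endpoint betas keep their sign (resazurin betas are negative); magnitudes
are taken only at averaging time.  The magnitude-average over the two
cytotoxicity assays and over the statistically significant peptides give the
cytotoxicity- and proteomics-based potency estimates used to rank particles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InputError


@dataclass
class PotencyEstimate:
    """Fitted potency exponent for one endpoint of one particle."""

    endpoint: str
    particle: str
    beta: float
    rss: float
    n_points: int


def fit_beta(
    doses,
    fold_changes,
    endpoint: str = "",
    particle: str = "",
) -> PotencyEstimate:
    """No-intercept log-log least squares for ``fold_change = (dose+1)**beta``.

    ``doses`` and ``fold_changes`` are flat arrays over all replicate points.
    Requires positive fold-changes (the log is undefined otherwise) and at
    least two points at two distinct nonzero doses.
    """
    d = np.asarray(doses, dtype=float)
    fc = np.asarray(fold_changes, dtype=float)
    if d.shape != fc.shape:
        raise InputError("doses and fold_changes must have equal length")
    if np.any(fc <= 0) or np.any(~np.isfinite(fc)):
        raise InputError("fold-changes must be positive and finite (log undefined)")
    if np.any(d < 0):
        raise InputError("doses must be nonnegative")
    nonzero = d > 0
    if np.unique(d[nonzero]).size < 2 or nonzero.sum() < 2:
        raise DegenerateInputError(
            "fit_beta requires >= 2 points at >= 2 distinct nonzero doses"
        )
    x = np.log1p(d)
    y = np.log(fc)
    beta = float(np.dot(x, y) / np.dot(x, x))
    rss = float(np.sum((y - beta * x) ** 2))
    return PotencyEstimate(endpoint, particle, beta, rss, int(d.size))


def fit_beta_matrix(fold_changes: pd.DataFrame) -> pd.Series:
    """Per-feature beta for a features x (dose, replicate) fold-change block.

    Vectorized, NaN-aware variant of :func:`fit_beta` used over peptide
    matrices; nonpositive fold-changes are masked out per feature.  Features
    without >= 2 points at >= 2 distinct nonzero doses fit to NaN.
    """
    doses = fold_changes.columns.get_level_values("dose").to_numpy(dtype=float)
    x = np.log1p(doses)
    values = fold_changes.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(values > 0, np.log(values), np.nan)
    mask = np.isfinite(y) & (x[None, :] > 0)
    sxx = np.where(mask, x[None, :] ** 2, 0.0).sum(axis=1)
    sxy = np.nansum(np.where(mask, x[None, :] * y, 0.0), axis=1)
    n_doses = np.array(
        [np.unique(doses[m & (doses > 0)]).size for m in np.isfinite(y)]
    )
    n_points = mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = sxy / sxx
    beta[(n_doses < 2) | (n_points < 2)] = np.nan
    return pd.Series(beta, index=fold_changes.index, name="beta")


def average_cytotox_beta(
    ldh: PotencyEstimate | float, resazurin: PotencyEstimate | float
) -> float:
    """Magnitude-average the two cytotoxicity endpoint betas: (|b_LDH|+|b_Rz|)/2."""
    values = []
    for name, est in (("ldh", ldh), ("resazurin", resazurin)):
        beta = est.beta if isinstance(est, PotencyEstimate) else est
        if beta is None or not math.isfinite(beta):
            raise InputError(f"missing or non-finite {name} potency estimate")
        values.append(abs(beta))
    return 0.5 * (values[0] + values[1])


def average_proteomic_beta(betas) -> float | None:
    """Mean |beta| over the significant peptides; ``None`` when the set is empty."""
    arr = np.asarray(
        [b.beta if isinstance(b, PotencyEstimate) else b for b in betas], dtype=float
    )
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return None
    return float(np.mean(np.abs(arr)))


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention for potency tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def rank_particles(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Rank particles by magnitude-averaged potency in both arms.

    ``table`` is indexed by particle with columns ``beta_ave_cytotox`` and
    ``beta_ave_proteomic``.  Rank 1 is the largest average; ties share the
    smaller rank.  Concordance between the two rank vectors is reported as an
    exact-match flag plus Kendall's tau (undefined, i.e. NaN, when either
    vector is constant).
    """
    if len(table) < 2:
        raise InputError("rank_particles requires >= 2 particles")
    out = table.copy()
    for col in ("beta_ave_cytotox", "beta_ave_proteomic"):
        if col not in out.columns:
            raise InputError(f"rank_particles: missing column {col}")
        # particles without an average (no-potency sentinel) stay unranked
        out[col.replace("beta_ave", "rank")] = (
            out[col].rank(ascending=False, method="min").astype("Int64")
        )
    both = out[["rank_cytotox", "rank_proteomic"]].dropna()
    cy = both["rank_cytotox"].to_numpy(dtype=float)
    pr = both["rank_proteomic"].to_numpy(dtype=float)
    if cy.size < 2 or np.ptp(cy) == 0 or np.ptp(pr) == 0:
        tau = float("nan")
    else:
        tau = float(stats.kendalltau(cy, pr).statistic)
    concordance = {
        "exact_match": bool(cy.size == len(out) and np.array_equal(cy, pr)),
        "kendall_tau": tau,
    }
    return out, concordance


def build_potency_table(
    cytotox_estimates: pd.DataFrame,
    proteomic_averages: pd.Series,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the per-particle potency table for one cell line and rank it.

    ``cytotox_estimates`` is indexed by particle with columns ``beta_ldh``
    and ``beta_resazurin``; ``proteomic_averages`` maps particle to its mean
    |beta| over significant peptides (NaN for the no-potency sentinel).
    """
    table = cytotox_estimates.copy()
    table["beta_ave_cytotox"] = [
        average_cytotox_beta(row.beta_ldh, row.beta_resazurin)
        for row in table.itertuples()
    ]
    table["beta_ave_proteomic"] = proteomic_averages.reindex(table.index)
    return rank_particles(table)
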