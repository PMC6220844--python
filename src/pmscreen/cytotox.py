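"""Classical cytotoxicity arm: control normalization and dose-wise significance.

Two endpoints per well: the resazurin-reduction signal (metabolic viability,
decreases with dose) and the LDH release ratio (supernatant over total
activity, membrane damage, increases with dose).  Each well is normalized to
the mean of the matching no-treatment controls, giving per-replicate
fold-changes; doses are then compared to control by one-way ANOVA with a
rank-transform fallback when normality or variance homogeneity fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, InputError

ENDPOINTS = ("resazurin", "ldh")

FOLD_CHANGE_COLUMNS = [
    "cell_line",
    "particle",
    "dose",
    "replicate",
    "endpoint",
    "fold_change",
]


def normalize_to_control(plate: pd.DataFrame) -> pd.DataFrame:
    """Convert a cytotoxicity plate into tidy per-well fold-changes.

    The endpoint value of each well (resazurin signal; LDH ratio =
    release/total) is divided by the mean endpoint value of the dose-0 wells
    of the same (cell line, particle), yielding two dose-response series per
    particle.  Control fold-changes average to 1 by construction.
    """
    required = {"cell_line", "particle", "dose", "replicate", "resazurin",
                "ldh_release", "ldh_total"}
    missing_cols = required - set(plate.columns)
    if missing_cols:
        raise InputError(f"cytotoxicity plate lacks columns {sorted(missing_cols)}")
    if (plate["ldh_total"] <= 0).any():
        raise InputError("ldh_total must be positive in every well")

    values = plate.assign(
        resazurin=plate["resazurin"].astype(float),
        ldh=plate["ldh_release"] / plate["ldh_total"],
    )

    rows = []
    for (cell, particle), grp in values.groupby(["cell_line", "particle"], sort=True):
        controls = grp[grp["dose"] == 0]
        if controls.empty:
            raise InputError(f"no dose-0 controls for ({cell}, {particle})")
        for endpoint in ENDPOINTS:
            ctrl_mean = controls[endpoint].mean()
            if ctrl_mean == 0:
                raise DegenerateInputError(
                    f"zero control mean for {endpoint} in ({cell}, {particle})"
                )
            for row in grp.itertuples():
                rows.append(
                    (
                        cell,
                        particle,
                        float(row.dose),
                        int(row.replicate),
                        endpoint,
                        getattr(row, endpoint) / ctrl_mean,
                    )
                )
    return pd.DataFrame(rows, columns=FOLD_CHANGE_COLUMNS)


@dataclass
class DoseAnovaResult:
    """Outcome of the dose-wise significance assessment for one series."""

    anova_p: float
    rank_transformed: bool
    per_dose: pd.DataFrame  # columns: dose, p_raw, p_adj, significant
    method: str

    def flagged_doses(self) -> list[float]:
        return self.per_dose.loc[self.per_dose["significant"], "dose"].tolist()


def _assumptions_hold(groups: list[np.ndarray], gate_alpha: float) -> bool:
    """Shapiro-Wilk per group and Levene across groups, both at ``gate_alpha``.

    Groups too small for Shapiro (n < 3) or with zero variance leave the
    normality gate undecided and are treated as passing; Levene still guards
    the variance assumption.
    """
    for g in groups:
        if g.size >= 3 and np.ptp(g) > 0:
            if stats.shapiro(g).pvalue < gate_alpha:
                return False
    if all(np.ptp(g) == 0 for g in groups):
        return True
    return stats.levene(*groups).pvalue >= gate_alpha


def dose_anova(
    series: pd.DataFrame,
    alpha: float = 0.05,
    gate_alpha: float = 0.05,
    method: str = "holm",
) -> DoseAnovaResult:
    """One-way ANOVA of fold-changes vs the 0-dose control, per dose flags.

    ``series`` needs columns ``dose`` and ``fold_change`` with >= 2
    replicates per dose.  When normality (Shapiro-Wilk) or variance
    homogeneity (Levene) fails at ``gate_alpha``, all values are
    rank-transformed first.  Dose-vs-control comparisons use pairwise t tests
    with Holm adjustment (``method="holm"``) or Dunnett's test
    (``method="dunnett"``); flags are at ``alpha``.
    """
    if method not in ("holm", "dunnett"):
        raise ValueError(f"unknown comparison method: {method}")
    doses = np.sort(series["dose"].unique())
    if doses.size < 2 or doses[0] != 0:
        raise InputError("dose_anova requires a 0-dose control and >= 2 doses")
    groups = [
        series.loc[series["dose"] == d, "fold_change"].to_numpy(dtype=float)
        for d in doses
    ]
    if any(g.size < 2 for g in groups):
        raise InputError("dose_anova requires >= 2 replicates per dose")

    values = np.concatenate(groups)
    if np.ptp(values) == 0:  # all wells identical: nothing to test
        per_dose = pd.DataFrame(
            {
                "dose": doses[1:],
                "p_raw": 1.0,
                "p_adj": 1.0,
                "significant": False,
            }
        )
        return DoseAnovaResult(1.0, False, per_dose, method)

    ranked = not _assumptions_hold(groups, gate_alpha)
    if ranked:
        flat = stats.rankdata(values)
        splits = np.cumsum([g.size for g in groups])[:-1]
        groups = np.split(flat, splits)

    anova_p = float(stats.f_oneway(*groups).pvalue)
    control = groups[0]
    if method == "dunnett":
        res = stats.dunnett(*groups[1:], control=control)
        p_raw = np.asarray(res.pvalue, dtype=float)
        p_adj = p_raw  # Dunnett p-values are already familywise
    else:
        p_raw = np.array(
            [stats.ttest_ind(g, control).pvalue for g in groups[1:]], dtype=float
        )
        p_adj = multipletests(p_raw, method="holm")[1]

    per_dose = pd.DataFrame(
        {
            "dose": doses[1:],
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        }
    )
    return DoseAnovaResult(anova_p, ranked, per_dose, method)


def analyze_plate(
    plate: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "holm",
) -> tuple[pd.DataFrame, dict]:
    """Normalize a plate and run the dose assessment on every series.

    Returns the tidy fold-change table and a JSON-ready significance report
    keyed ``cell_line/particle/endpoint``.
    """
    fold = normalize_to_control(plate)
    report: dict = {}
    for (cell, particle, endpoint), grp in fold.groupby(
        ["cell_line", "particle", "endpoint"], sort=True
    ):
        res = dose_anova(grp, alpha=alpha, method=method)
        report[f"{cell}/{particle}/{endpoint}"] = {
            "anova_p": res.anova_p,
            "rank_transformed": res.rank_transformed,
            "method": res.method,
            "doses": res.per_dose["dose"].tolist(),
            "p_adj": res.per_dose["p_adj"].tolist(),
            "significant": res.per_dose["significant"].tolist(),
        }
    return fold, report
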