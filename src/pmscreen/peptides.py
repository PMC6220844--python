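"""Proteomic statistics arm: normalization, paired dose-pair tests, clustering.

Peptide intensities are normalized within each biological replicate to the
same replicate's no-treatment control, then every unordered dose pair is
compared per peptide with one-sided paired t-tests in both directions.  A
peptide is called significant when the smaller of the two one-sided p-values
beats alpha in any dose pair (optionally Benjamini-Hochberg corrected across
peptides).  Significant fold-change profiles are clustered by average linkage
on correlation distance of log2 fold-changes for the heatmap.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .spectra import FeatureMatrix

TEST_COLUMNS = [
    "cell_line",
    "particle",
    "feature_mz",
    "dose_low",
    "dose_high",
    "n_pairs",
    "t",
    "p_increase",
    "p_decrease",
    "direction",
    "significant",
    "untestable",
]


def normalize_peptides(matrix: FeatureMatrix, design: pd.DataFrame) -> pd.DataFrame:
    """Fold-changes of each feature against its own replicate's dose-0 sample.

    Returns a DataFrame indexed by feature m/z with MultiIndex columns
    (cell_line, particle, dose, replicate).  Features missing (or nonpositive)
    in a replicate's control are NaN for that replicate; dose-0 columns are
    exactly 1 where defined.
    """
    samples = design.drop_duplicates("sample_id").set_index("sample_id")
    unknown = [s for s in matrix.sample_ids if s not in samples.index]
    if unknown:
        raise InputError(f"design table lacks samples {unknown}")

    columns: dict[tuple, pd.Series] = {}
    groups = samples.loc[matrix.sample_ids].groupby(
        ["cell_line", "particle", "replicate"], sort=True
    )
    for (cell, particle, rep), grp in groups:
        ctrl = grp.index[grp["dose"] == 0]
        if len(ctrl) == 0:
            raise InputError(
                f"replicate {rep} of ({cell}, {particle}) has no dose-0 control"
            )
        ctrl_int = matrix.intensities[ctrl[0]]
        denom = ctrl_int.where(ctrl_int > 0)
        for sid in grp.index:
            dose = float(samples.at[sid, "dose"])
            columns[(cell, particle, dose, int(rep))] = (
                matrix.intensities[sid] / denom
            )
    out = pd.DataFrame(columns)
    out.columns = pd.MultiIndex.from_tuples(
        out.columns, names=["cell_line", "particle", "dose", "replicate"]
    )
    return out.sort_index(axis=1)


def _one_sided_paired(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized paired t over rows: returns (n, t, p_increase, p_decrease).

    ``a``/``b`` are features x replicates; NaN pairs are ignored per feature.
    Zero-variance differences give t = 0 (p = 0.5 both ways) when the mean
    difference is zero, otherwise an infinite t.
    """
    diff = b - a
    valid = ~np.isnan(diff)
    n = valid.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(valid, diff, np.nan), axis=1)
        sd = np.nanstd(np.where(valid, diff, np.nan), axis=1, ddof=1)
    t = np.full(mean.shape, np.nan)
    testable = n >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t[testable] = mean[testable] / (sd[testable] / np.sqrt(n[testable]))
    t[testable & (sd == 0) & (mean == 0)] = 0.0
    t[testable & (sd == 0) & (mean > 0)] = np.inf
    t[testable & (sd == 0) & (mean < 0)] = -np.inf
    df = np.maximum(n - 1, 1)
    p_inc = stats.t.sf(t, df)
    p_dec = stats.t.cdf(t, df)
    # one-sided p-values live in (0, 1]: clip the point masses at 0
    tiny = np.finfo(float).tiny
    return n, t, np.clip(p_inc, tiny, 1.0), np.clip(p_dec, tiny, 1.0)


def paired_dose_tests(
    fold_changes: pd.DataFrame,
    alpha: float = 0.05,
    log_scale: bool = False,
) -> pd.DataFrame:
    """One-sided paired t-tests in both directions over all dose pairs.

    For every feature, (cell line, particle) block and unordered dose pair
    d1 < d2, the per-replicate fold-changes at d1 and d2 are paired by
    biological replicate.  ``p_increase`` tests fc(d2) > fc(d1),
    ``p_decrease`` the reverse; the feature-pair is flagged significant when
    the smaller one-sided p-value is below ``alpha`` (no correction for the
    two directions, mirroring the screening protocol; see
    :func:`select_significant` for the optional BH step).  Pairs with fewer
    than 2 complete replicates are marked untestable rather than raising.
    With ``log_scale`` the test runs on log fold-changes.
    """
    values = fold_changes
    if log_scale:
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.log(fold_changes.where(fold_changes > 0))
    rows = []
    blocks = sorted(
        set(
            zip(
                values.columns.get_level_values("cell_line"),
                values.columns.get_level_values("particle"),
            )
        )
    )
    for cell, particle in blocks:
        block = values.xs((cell, particle), axis=1, level=["cell_line", "particle"])
        doses = sorted(block.columns.get_level_values("dose").unique())
        for d1, d2 in itertools.combinations(doses, 2):
            a_df = block.xs(d1, axis=1, level="dose")
            b_df = block.xs(d2, axis=1, level="dose")
            a_df, b_df = a_df.align(b_df, join="outer", axis=1)
            n, t, p_inc, p_dec = _one_sided_paired(
                a_df.to_numpy(dtype=float), b_df.to_numpy(dtype=float)
            )
            untestable = n < 2
            min_p = np.minimum(p_inc, p_dec)
            direction = np.where(p_inc <= p_dec, "increase", "decrease")
            sig = (min_p < alpha) & ~untestable
            for i, mz in enumerate(values.index):
                rows.append(
                    (
                        cell,
                        particle,
                        float(mz),
                        float(d1),
                        float(d2),
                        int(n[i]),
                        float(t[i]),
                        float(p_inc[i]),
                        float(p_dec[i]),
                        direction[i] if not untestable[i] else "",
                        bool(sig[i]),
                        bool(untestable[i]),
                    )
                )
    return pd.DataFrame(rows, columns=TEST_COLUMNS)


def select_significant(
    results: pd.DataFrame,
    alpha: float = 0.05,
    correction: str | None = None,
) -> dict[tuple[str, str], list[float]]:
    """Features with any dose-pair minimum p below alpha, per (cell, particle).

    With ``correction="bh"`` the per-feature minimum p-values within each
    (cell line, particle) block are Benjamini-Hochberg adjusted across
    features before thresholding; the default applies no multiplicity
    correction.
    """
    if results.empty:
        raise InputError("select_significant requires a nonempty result table")
    if correction not in (None, "bh"):
        raise ValueError(f"unknown correction: {correction}")
    testable = results[~results["untestable"]].copy()
    testable["min_p"] = testable[["p_increase", "p_decrease"]].min(axis=1)
    out: dict[tuple[str, str], list[float]] = {}
    for (cell, particle), grp in testable.groupby(["cell_line", "particle"], sort=True):
        per_feature = grp.groupby("feature_mz")["min_p"].min()
        if correction == "bh":
            rejected = multipletests(per_feature.to_numpy(), alpha=alpha, method="fdr_bh")[0]
            selected = per_feature.index[rejected]
        else:
            selected = per_feature.index[per_feature < alpha]
        out[(cell, particle)] = sorted(float(m) for m in selected)
    return out


@dataclass
class ClusterResult:
    """Hierarchical clustering of a fold-change block."""

    ordered: pd.DataFrame  # rows and columns in dendrogram leaf order
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    degenerate: bool = False


def _linkage_order(data: np.ndarray) -> tuple[np.ndarray | None, np.ndarray]:
    """Average linkage on correlation distance; leaf order, input-index tie-break."""
    if data.shape[0] < 2:
        return None, np.arange(data.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = pdist(data, metric="correlation")
    if not np.all(np.isfinite(dist)):
        return None, np.arange(data.shape[0])
    linkage = average(dist)
    return linkage, leaves_list(linkage)


def cluster_heatmap(
    fold_changes: pd.DataFrame,
    image_path=None,
    csv_path=None,
) -> ClusterResult:
    """Cluster features and conditions of a (significant) fold-change block.

    Rows (features) and columns (conditions) are clustered by average linkage
    on correlation distance of log2 fold-changes.  SciPy's linkage on the
    ordered condensed distances gives a deterministic leaf order; exact ties
    resolve by input index.  A constant matrix has no defined correlation
    distance: the input order is kept and a warning issued.  When paths are
    given, a green(down)/red(up) heatmap image and the leaf-ordered matrix
    CSV are written.
    """
    if fold_changes.shape[0] < 2 or fold_changes.shape[1] < 2:
        raise InputError("cluster_heatmap requires >= 2 features and >= 2 conditions")
    log2 = np.log2(fold_changes.to_numpy(dtype=float))
    log2 = np.nan_to_num(log2, nan=0.0, posinf=0.0, neginf=0.0)

    row_linkage, row_order = _linkage_order(log2)
    col_linkage, col_order = _linkage_order(log2.T)
    degenerate = row_linkage is None or col_linkage is None
    if degenerate:
        warnings.warn(
            "degenerate (constant) matrix: keeping input order", stacklevel=2
        )
    ordered = fold_changes.iloc[row_order, col_order]

    if csv_path is not None:
        ordered.to_csv(csv_path)
    if image_path is not None:
        _write_heatmap(np.log2(np.asarray(ordered, dtype=float)), ordered, image_path)
    return ClusterResult(ordered, row_linkage, col_linkage, degenerate)


def _write_heatmap(log2_values: np.ndarray, ordered: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap, TwoSlopeNorm

    cmap = LinearSegmentedColormap.from_list(
        "green_black_red", ["#00a000", "#000000", "#d00000"]
    )
    span = float(np.nanmax(np.abs(log2_values), initial=0.0)) or 1.0
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.25 * ordered.shape[1] + 2), max(3.0, 0.02 * ordered.shape[0] + 2))
    )
    im = ax.imshow(
        np.nan_to_num(log2_values),
        aspect="auto",
        cmap=cmap,
        norm=TwoSlopeNorm(vcenter=0.0, vmin=-span, vmax=span),
        interpolation="nearest",
    )
    ax.set_xticks(range(ordered.shape[1]))
    ax.set_xticklabels(["/".join(str(v) for v in c) if isinstance(c, tuple) else str(c)
                        for c in ordered.columns], rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{ordered.shape[0]} peptides")
    fig.colorbar(im, ax=ax, label="log2 fold-change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
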