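"""End-to-end orchestration: simulate -> spectra -> statistics -> potency table.

Each stage reads its inputs from, and writes its outputs to, the run's output
directory, so any stage can be re-run from persisted intermediates with an
identical final result.  :func:`analyze_experiment` is the in-memory core
used both by :func:`run_pipeline` and by simulation studies that loop over
many seeds without touching the disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cytotox as cytotox_mod
from . import peptides as peptides_mod
from . import potency as potency_mod
from . import spectra as spectra_mod
from .config import PipelineConfig, ProcessingParams
from .errors import PmScreenError
from .simulate import (
    SimulatedExperiment,
    read_fixture,
    simulate_experiment,
    write_fixture,
)
from .spectra import FeatureMatrix, RawSpectrum

log = logging.getLogger("pmscreen")

REPORT_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# in-memory core
# ---------------------------------------------------------------------------


def process_spectra(
    spectra: list[RawSpectrum],
    design: pd.DataFrame,
    params: ProcessingParams,
) -> tuple[dict[str, FeatureMatrix], pd.DataFrame]:
    """Spectra -> per-cell-line feature matrices (and the spot-RSD table).

    Per sample: optional Savitzky-Golay smoothing, peak detection at the S/N
    threshold, spot merging.  Per cell line: cross-sample alignment, then the
    top-N filter on the ensemble S/N (mean over the samples where a feature
    was detected) at the S/N floor.
    """
    by_sample: dict[str, list[pd.DataFrame]] = {}
    for spec in spectra:
        s = spectra_mod.smooth(spec, params.smooth_window) if params.smooth_window else spec
        peaks = spectra_mod.detect_peaks(
            s,
            snr_threshold=params.snr_detect,
            baseline_window=params.baseline_window,
            noise_window=params.noise_window,
        )
        by_sample.setdefault(spec.sample_id, []).append(peaks)

    samples = design.drop_duplicates("sample_id").set_index("sample_id")
    merged: dict[str, pd.DataFrame] = {}
    rsd_rows = []
    for sid, peaklists in by_sample.items():
        m = spectra_mod.merge_spots(
            peaklists,
            tolerance_ppm=params.tolerance_ppm,
            min_spot_fraction=params.min_spot_fraction,
        )
        merged[sid] = m
        for row in m.itertuples():
            rsd_rows.append((sid, row.mz, row.rsd, row.n_spots))
    rsd_table = pd.DataFrame(rsd_rows, columns=["sample_id", "mz", "rsd", "n_spots"])

    matrices: dict[str, FeatureMatrix] = {}
    for cell in sorted(samples["cell_line"].unique()):
        cell_samples = [s for s in merged if samples.at[s, "cell_line"] == cell]
        fm = spectra_mod.align_features(
            {s: merged[s] for s in cell_samples}, tolerance_ppm=params.tolerance_ppm
        )
        matrices[cell] = _top_features(fm, params)
        log.info(
            "cell line %s: %d aligned features, %d retained after top-%d S/N filter",
            cell, len(fm.mz), len(matrices[cell].mz), params.top_n,
        )
    return matrices, rsd_table


def _top_features(fm: FeatureMatrix, params: ProcessingParams) -> FeatureMatrix:
    """Keep the top-N features by ensemble S/N (floor applied), m/z tie-break."""
    if fm.intensities.empty:
        return fm
    ensemble = pd.DataFrame(
        {
            "mz": fm.mz,
            "height": fm.intensities.mean(axis=1).to_numpy(),
            "snr": fm.snr.mean(axis=1).to_numpy(),
        }
    )
    kept = spectra_mod.select_top_features(ensemble, n=params.top_n, snr_floor=params.snr_floor)
    keep_mz = np.sort(kept["mz"].to_numpy())
    mask = np.isin(fm.mz, keep_mz)
    return FeatureMatrix(
        intensities=fm.intensities.loc[mask], snr=fm.snr.loc[mask]
    )


@dataclass
class PipelineResult:
    """Everything the end-to-end analysis produced, per cell line."""

    fold_changes_cytotox: pd.DataFrame
    anova_report: dict
    feature_matrices: dict[str, FeatureMatrix]
    rsd_table: pd.DataFrame
    fold_changes_peptides: pd.DataFrame
    dose_pair_tests: pd.DataFrame
    significant: dict[tuple[str, str], list[float]]
    peptide_betas: dict[tuple[str, str], pd.Series]
    potency_tables: dict[str, pd.DataFrame]
    concordance: dict[str, dict]
    clusters: dict[str, peptides_mod.ClusterResult] = field(default_factory=dict)

    def report(self, seed: int, alpha: float) -> dict:
        """Versioned JSON-ready report (no timestamps: byte-stable per seed)."""
        cells = {}
        for cell, table in self.potency_tables.items():
            cells[cell] = {
                "potency_table": json.loads(table.to_json(orient="index")),
                "concordance": self.concordance[cell],
                "n_significant": {
                    particle: len(feats)
                    for (c, particle), feats in self.significant.items()
                    if c == cell
                },
            }
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "seed": seed,
            "alpha": alpha,
            "cytotox_anova": self.anova_report,
            "cell_lines": cells,
        }


def analyze_experiment(
    spectra: list[RawSpectrum],
    design: pd.DataFrame,
    plate: pd.DataFrame,
    config: PipelineConfig,
) -> PipelineResult:
    """Run both analysis arms and assemble the ranked potency tables."""
    params = config.processing

    # cytotoxicity arm
    fold_cyto, anova_report = cytotox_mod.analyze_plate(
        plate, alpha=config.alpha, method=config.anova_method
    )
    cyto_estimates: dict[str, pd.DataFrame] = {}
    for cell, cell_fold in fold_cyto.groupby("cell_line", sort=True):
        rows = {}
        for particle, grp in cell_fold.groupby("particle", sort=True):
            betas = {}
            for endpoint, series in grp.groupby("endpoint", sort=True):
                est = potency_mod.fit_beta(
                    series["dose"], series["fold_change"],
                    endpoint=endpoint, particle=particle,
                )
                betas[f"beta_{endpoint}"] = est.beta
            rows[particle] = betas
        cyto_estimates[cell] = pd.DataFrame.from_dict(rows, orient="index")

    # proteomic arm
    matrices, rsd_table = process_spectra(spectra, design, params)
    fold_pept = peptides_mod.normalize_peptides(_stack_matrices(matrices), design)
    tests = peptides_mod.paired_dose_tests(
        fold_pept, alpha=config.alpha, log_scale=config.log_scale_tests
    )
    significant = peptides_mod.select_significant(
        tests, alpha=config.alpha, correction="bh" if config.bh_correction else None
    )

    peptide_betas: dict[tuple[str, str], pd.Series] = {}
    prot_averages: dict[str, dict[str, float]] = {}
    for (cell, particle), feats in significant.items():
        block = fold_pept.xs((cell, particle), axis=1, level=["cell_line", "particle"])
        betas = potency_mod.fit_beta_matrix(block)
        peptide_betas[(cell, particle)] = betas
        ave = potency_mod.average_proteomic_beta(betas.loc[feats]) if feats else None
        prot_averages.setdefault(cell, {})[particle] = (
            np.nan if ave is None else ave
        )

    potency_tables: dict[str, pd.DataFrame] = {}
    concordance: dict[str, dict] = {}
    for cell, estimates in cyto_estimates.items():
        averages = pd.Series(prot_averages.get(cell, {}), dtype=float)
        table, conc = potency_mod.build_potency_table(estimates, averages)
        potency_tables[cell] = table
        concordance[cell] = conc

    return PipelineResult(
        fold_changes_cytotox=fold_cyto,
        anova_report=anova_report,
        feature_matrices=matrices,
        rsd_table=rsd_table,
        fold_changes_peptides=fold_pept,
        dose_pair_tests=tests,
        significant=significant,
        peptide_betas=peptide_betas,
        potency_tables=potency_tables,
        concordance=concordance,
    )


def _stack_matrices(matrices: dict[str, FeatureMatrix]) -> FeatureMatrix:
    """Concatenate per-cell-line matrices into one (features never shared)."""
    if len(matrices) == 1:
        return next(iter(matrices.values()))
    intens, snrs = [], []
    for cell in sorted(matrices):
        fm = matrices[cell]
        intens.append(fm.intensities)
        snrs.append(fm.snr)
    merged_i = pd.concat(intens, axis=0).groupby(level=0).first().sort_index()
    merged_s = pd.concat(snrs, axis=0).groupby(level=0).first().sort_index()
    return FeatureMatrix(intensities=merged_i, snr=merged_s)


# ---------------------------------------------------------------------------
# persisted stages
# ---------------------------------------------------------------------------


def _fixture_dir(config: PipelineConfig) -> Path:
    return config.input_dir if config.input_dir is not None else config.outdir / "fixture"


def stage_simulate(config: PipelineConfig) -> SimulatedExperiment:
    """Generate the synthetic experiment and persist it as a fixture."""
    sim_config = config.sim.to_simulation_config(seed=config.seed)
    experiment = simulate_experiment(sim_config)
    manifest = write_fixture(config.outdir / "fixture", experiment)
    log.info("simulated %d spectra into %s", manifest["n_spectra"], config.outdir)
    return experiment


def stage_peaks(config: PipelineConfig) -> dict[str, FeatureMatrix]:
    """Spectra from the fixture/input directory -> feature matrix CSVs."""
    spectra, design, _, _ = read_fixture(_fixture_dir(config))
    matrices, rsd_table = process_spectra(spectra, design, config.processing)
    config.outdir.mkdir(parents=True, exist_ok=True)
    for cell, fm in matrices.items():
        fm.to_csv(config.outdir / f"feature_matrix_{cell}.csv")
    rsd_table.to_csv(config.outdir / "spot_rsd.csv", index=False)
    return matrices


def stage_cytotox(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Cytotoxicity plate CSV -> tidy fold-changes + significance report."""
    plate = pd.read_csv(_fixture_dir(config) / "cytotox.csv")
    fold, report = cytotox_mod.analyze_plate(
        plate, alpha=config.alpha, method=config.anova_method
    )
    config.outdir.mkdir(parents=True, exist_ok=True)
    fold.to_csv(config.outdir / "cytotox_foldchange.csv", index=False)
    (config.outdir / "cytotox_anova.json").write_text(
        json.dumps(report, indent=1, sort_keys=True)
    )
    return fold, report


def stage_peptides(config: PipelineConfig) -> pd.DataFrame:
    """Feature matrices -> fold-changes, dose-pair tests, significant sets, heatmaps."""
    design = pd.read_csv(_fixture_dir(config) / "design.csv")
    matrices = {}
    for path in sorted(config.outdir.glob("feature_matrix_*.csv")):
        cell = path.stem.removeprefix("feature_matrix_")
        matrices[cell] = FeatureMatrix.from_csv(path)
    if not matrices:
        raise PmScreenError("stage peptides: no feature_matrix_*.csv found (run peaks first)")
    fold = peptides_mod.normalize_peptides(_stack_matrices(matrices), design)
    tests = peptides_mod.paired_dose_tests(
        fold, alpha=config.alpha, log_scale=config.log_scale_tests
    )
    significant = peptides_mod.select_significant(
        tests, alpha=config.alpha, correction="bh" if config.bh_correction else None
    )
    fold.to_csv(config.outdir / "peptide_foldchange.csv")
    tests.to_csv(config.outdir / "dose_pair_tests.csv", index=False)
    (config.outdir / "significant_features.json").write_text(
        json.dumps(
            {f"{c}/{p}": feats for (c, p), feats in significant.items()},
            indent=1,
            sort_keys=True,
        )
    )
    if config.heatmap:
        for cell in matrices:
            _write_cell_heatmap(fold, significant, cell, config)
    return tests


def _write_cell_heatmap(fold, significant, cell, config) -> None:
    feats = sorted({mz for (c, _), f in significant.items() if c == cell for mz in f})
    block = fold.xs(cell, axis=1, level="cell_line").loc[
        [mz for mz in fold.index if mz in set(feats)]
    ]
    block = block.drop(columns=[0.0], level="dose", errors="ignore").dropna(how="any")
    if block.shape[0] < 2 or block.shape[1] < 2:
        log.info("cell line %s: too few significant features for a heatmap", cell)
        return
    peptides_mod.cluster_heatmap(
        block,
        image_path=config.outdir / f"heatmap_{cell}.png",
        csv_path=config.outdir / f"heatmap_{cell}.csv",
    )


def stage_potency(config: PipelineConfig) -> tuple[dict[str, pd.DataFrame], dict]:
    """Persisted fold-changes -> ranked potency tables + concordance report."""
    fold_cyto = pd.read_csv(config.outdir / "cytotox_foldchange.csv")
    fold_pept = _read_fold_changes(config.outdir / "peptide_foldchange.csv")
    significant_raw = json.loads(
        (config.outdir / "significant_features.json").read_text()
    )
    significant = {
        tuple(key.split("/", 1)): feats for key, feats in significant_raw.items()
    }

    tables: dict[str, pd.DataFrame] = {}
    concordance: dict[str, dict] = {}
    for cell, cell_fold in fold_cyto.groupby("cell_line", sort=True):
        rows = {}
        for particle, grp in cell_fold.groupby("particle", sort=True):
            rows[particle] = {
                f"beta_{endpoint}": potency_mod.fit_beta(
                    series["dose"], series["fold_change"],
                    endpoint=endpoint, particle=particle,
                ).beta
                for endpoint, series in grp.groupby("endpoint", sort=True)
            }
        estimates = pd.DataFrame.from_dict(rows, orient="index")
        averages = {}
        for particle in estimates.index:
            feats = significant.get((cell, particle), [])
            block = fold_pept.xs(
                (cell, particle), axis=1, level=["cell_line", "particle"]
            )
            betas = potency_mod.fit_beta_matrix(block)
            ave = potency_mod.average_proteomic_beta(betas.loc[feats]) if feats else None
            averages[particle] = np.nan if ave is None else ave
        table, conc = potency_mod.build_potency_table(
            estimates, pd.Series(averages, dtype=float)
        )
        tables[cell] = table
        concordance[cell] = conc
        table.to_csv(config.outdir / f"potency_table_{cell}.csv")
    (config.outdir / "concordance.json").write_text(
        json.dumps(concordance, indent=1, sort_keys=True)
    )
    return tables, concordance


def _read_fold_changes(path: Path) -> pd.DataFrame:
    fold = pd.read_csv(path, header=[0, 1, 2, 3], index_col=0)
    fold.columns = pd.MultiIndex.from_tuples(
        [(c, p, float(d), int(r)) for c, p, d, r in fold.columns],
        names=["cell_line", "particle", "dose", "replicate"],
    )
    fold.index = fold.index.astype(float)
    return fold


STAGES = ("simulate", "peaks", "cytotox", "peptides", "potency")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the versioned JSON report.

    Stage failures propagate with the stage name prepended; partial outputs
    stay on disk next to a ``FAILED`` marker naming the stage.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    (config.outdir / "run_log.json").write_text(
        json.dumps(
            json.loads(config.model_dump_json()), indent=1, sort_keys=True
        )
    )
    failed_marker = config.outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    current = "simulate"
    try:
        if config.input_dir is None:
            stage_simulate(config)
        spectra, design, plate, _ = read_fixture(_fixture_dir(config))
        current = "analysis"
        result = analyze_experiment(spectra, design, plate, config)
        current = "persist"
        _persist_result(result, config)
    except Exception as exc:
        failed_marker.write_text(f"stage {current}: {exc}\n")
        raise PmScreenError(f"stage {current} failed: {exc}") from exc
    return result


def _persist_result(result: PipelineResult, config: PipelineConfig) -> None:
    out = config.outdir
    result.fold_changes_cytotox.to_csv(out / "cytotox_foldchange.csv", index=False)
    (out / "cytotox_anova.json").write_text(
        json.dumps(result.anova_report, indent=1, sort_keys=True)
    )
    for cell, fm in result.feature_matrices.items():
        fm.to_csv(out / f"feature_matrix_{cell}.csv")
    result.rsd_table.to_csv(out / "spot_rsd.csv", index=False)
    result.fold_changes_peptides.to_csv(out / "peptide_foldchange.csv")
    result.dose_pair_tests.to_csv(out / "dose_pair_tests.csv", index=False)
    (out / "significant_features.json").write_text(
        json.dumps(
            {f"{c}/{p}": feats for (c, p), feats in result.significant.items()},
            indent=1,
            sort_keys=True,
        )
    )
    for cell, table in result.potency_tables.items():
        table.to_csv(out / f"potency_table_{cell}.csv")
    if config.heatmap:
        for cell in result.feature_matrices:
            _write_cell_heatmap(
                result.fold_changes_peptides, result.significant, cell, config
            )
    (out / "report.json").write_text(
        json.dumps(result.report(config.seed, config.alpha), indent=1, sort_keys=True)
    )
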