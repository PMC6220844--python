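"""Seeded synthetic particle-exposure experiments (spectra + cytotoxicity plates).

The generator emulates the statistical structure of an in vitro screening
study: two cell lines exposed to three particles at doses 0/30/100 ug cm^-2
(plus 300 for cytotoxicity), five technical MALDI spots per sample, ~700
tryptic-peptide peaks per fingerprint, and a responsive peptide subset whose
heights follow the dose-effect model ``fold_change = (dose + 1) ** beta``.

Noise model: multiplicative lognormal on peak heights (median 1, so the
log-log potency fit is unbiased), an exponentially decaying baseline and
additive Gaussian detector noise.  Fixing the seed fixes every emitted byte.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .reference import REFERENCE_POTENCIES, ParticleBetas
from .spectra import RawSpectrum

DESIGN_COLUMNS = [
    "sample_id",
    "cell_line",
    "particle",
    "dose",
    "replicate",
    "spot",
    "spectrum_path",
]
CYTOTOX_COLUMNS = [
    "cell_line",
    "particle",
    "dose",
    "replicate",
    "resazurin",
    "ldh_release",
    "ldh_total",
]


def _default_betas() -> dict[str, ParticleBetas]:
    return dict(REFERENCE_POTENCIES["J774"])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic screening experiment.

    Doses are in ug cm^-2, m/z values in Th, intensities in arbitrary units.
    ``beta_true`` maps each particle to its (LDH, resazurin, mean proteomic
    |beta|) exponents; defaults are the published macrophage potencies.
    """

    seed: int = 0
    cell_lines: tuple[str, ...] = ("J774", "A549")
    particles: tuple[str, ...] = ("SiO2", "EHC6802", "TiO2")
    doses_proteomic: tuple[float, ...] = (0.0, 30.0, 100.0)
    doses_cytotox: tuple[float, ...] = (0.0, 30.0, 100.0, 300.0)
    n_bio_replicates: int = 3
    n_spots: int = 5
    n_peptides_total: int = 700
    n_responsive: int = 200
    beta_true: Mapping[str, ParticleBetas] = field(default_factory=_default_betas)
    mz_range: tuple[float, float] = (700.0, 3100.0)
    mz_step: float = 0.1
    intensity_cv: float = 0.15
    baseline_amplitude: float = 50.0
    detector_noise_sd: float = 1.0
    peak_width_sigma: float = 0.8
    basal_height_range: tuple[float, float] = (2.5, 250.0)

    def validate(self) -> None:
        for name in ("doses_proteomic", "doses_cytotox"):
            doses = getattr(self, name)
            if len(doses) < 2 or doses[0] != 0.0:
                raise ConfigurationError(f"{name}: must start with dose 0")
            if any(d < 0 for d in doses) or any(np.diff(doses) <= 0):
                raise ConfigurationError(
                    f"{name}: doses must be nonnegative and strictly increasing"
                )
        if self.n_bio_replicates < 2:
            raise ConfigurationError("n_bio_replicates: must be >= 2")
        if self.n_spots < 1:
            raise ConfigurationError("n_spots: must be >= 1")
        if not 0 < self.n_responsive <= self.n_peptides_total:
            raise ConfigurationError(
                "n_responsive: must satisfy 0 < n_responsive <= n_peptides_total"
            )
        if not self.mz_range[0] < self.mz_range[1]:
            raise ConfigurationError("mz_range: low bound must be below high bound")
        if self.mz_step <= 0:
            raise ConfigurationError("mz_step: must be > 0")
        for name in ("intensity_cv", "baseline_amplitude", "detector_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: must be >= 0")
        if self.peak_width_sigma <= 0:
            raise ConfigurationError("peak_width_sigma: must be > 0")
        if not 0 < self.basal_height_range[0] < self.basal_height_range[1]:
            raise ConfigurationError("basal_height_range: need 0 < low < high")
        missing = [p for p in self.particles if p not in self.beta_true]
        if missing:
            raise ConfigurationError(f"beta_true: missing particles {missing}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """What the generator actually put into the data.

    ``peptide_beta`` holds the signed proteomic exponent per (peptide,
    particle); non-responsive peptides have beta exactly 0.  ``cytotox_beta``
    holds the per-endpoint exponents.  True fold-change at dose 0 is exactly
    1 everywhere.
    """

    peptide_mz: np.ndarray
    responsive: np.ndarray  # indices into peptide_mz
    peptide_beta: pd.DataFrame  # peptides x particles, signed
    basal_height: np.ndarray
    cytotox_beta: dict[str, dict[str, float]]  # particle -> endpoint -> beta
    sample_fold_change: pd.DataFrame  # peptides x (particle, dose)

    def true_fold_change(self, particle: str, dose: float) -> np.ndarray:
        return (dose + 1.0) ** self.peptide_beta[particle].to_numpy()

    def to_json(self) -> str:
        payload = {
            "peptide_mz": self.peptide_mz.tolist(),
            "responsive": self.responsive.tolist(),
            "peptide_beta": {
                p: self.peptide_beta[p].tolist() for p in self.peptide_beta.columns
            },
            "basal_height": self.basal_height.tolist(),
            "cytotox_beta": self.cytotox_beta,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        beta = pd.DataFrame(raw["peptide_beta"])
        # per-sample fold-changes are derivable from beta; persist only dose 0
        fc = pd.DataFrame({(p, 0.0): np.ones(len(beta)) for p in beta.columns})
        fc.columns = pd.MultiIndex.from_tuples(fc.columns, names=["particle", "dose"])
        return cls(
            peptide_mz=np.asarray(raw["peptide_mz"], dtype=float),
            responsive=np.asarray(raw["responsive"], dtype=int),
            peptide_beta=beta,
            basal_height=np.asarray(raw["basal_height"], dtype=float),
            cytotox_beta=raw["cytotox_beta"],
            sample_fold_change=fc,
        )


@dataclass
class SimulatedExperiment:
    spectra: list[RawSpectrum]
    design: pd.DataFrame
    cytotox: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _draw_truth(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    lo, hi = config.mz_range
    n = config.n_peptides_total
    spacing = (hi - lo) / (n + 1)
    centres = lo + spacing * np.arange(1, n + 1)
    centres = centres + rng.uniform(-0.2, 0.2, size=n) * spacing

    log_lo, log_hi = np.log(config.basal_height_range)
    basal = np.exp(rng.uniform(log_lo, log_hi, size=n))

    responsive = np.sort(rng.choice(n, size=config.n_responsive, replace=False))
    half = config.n_responsive // 2
    base_signs = np.ones(config.n_responsive)
    base_signs[:half] = -1.0  # half down-, half up-regulated

    # each particle perturbs the responsive set with its own signature
    # (independent signs and relative sensitivities), mirroring the
    # particle-distinct expression profiles seen in real exposures
    beta = pd.DataFrame(
        0.0, index=np.arange(n), columns=list(config.particles), dtype=float
    )
    for particle in config.particles:
        signs = rng.permutation(base_signs)
        rel = rng.uniform(0.5, 1.5, size=config.n_responsive)
        rel /= rel.mean()  # per-particle mean |beta| hits its target exactly
        target = config.beta_true[particle].proteomic_mean_abs
        beta.loc[responsive, particle] = signs * rel * target

    fc = {}
    for particle in config.particles:
        for dose in config.doses_proteomic:
            fc[(particle, float(dose))] = (dose + 1.0) ** beta[particle].to_numpy()
    fc_df = pd.DataFrame(fc)
    fc_df.columns = pd.MultiIndex.from_tuples(fc_df.columns, names=["particle", "dose"])

    cyto = {
        p: {
            "ldh": float(config.beta_true[p].ldh),
            "resazurin": float(config.beta_true[p].resazurin),
        }
        for p in config.particles
    }
    return GroundTruth(
        peptide_mz=centres,
        responsive=responsive,
        peptide_beta=beta,
        basal_height=basal,
        cytotox_beta=cyto,
        sample_fold_change=fc_df,
    )


def _render_spectrum(
    grid: np.ndarray,
    centres: np.ndarray,
    heights: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    intensity = np.zeros_like(grid)
    sigma = config.peak_width_sigma
    reach = 6.0 * sigma
    for c, h in zip(centres, heights):
        i0 = int(np.searchsorted(grid, c - reach))
        i1 = int(np.searchsorted(grid, c + reach))
        window = grid[i0:i1]
        intensity[i0:i1] += h * np.exp(-0.5 * ((window - c) / sigma) ** 2)
    lo, hi = config.mz_range
    decay = (hi - lo) / 3.0
    intensity += config.baseline_amplitude * np.exp(-(grid - lo) / decay)
    if config.detector_noise_sd > 0:
        intensity += rng.normal(0.0, config.detector_noise_sd, size=grid.size)
    return np.clip(intensity, 0.0, None)


def sample_id(cell_line: str, particle: str, dose: float, replicate: int) -> str:
    return f"{cell_line}_{particle}_d{dose:g}_r{replicate}"


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate spectra, a cytotoxicity plate, a design table and the ground truth.

    One :class:`RawSpectrum` per (cell line, particle, dose, replicate, spot);
    responsive peptide heights scale as ``basal * (dose + 1) ** beta`` with
    multiplicative lognormal spot noise.  The cytotoxicity plate carries
    resazurin signals (decreasing with dose) and LDH release/total pairs
    (release ratio increasing with dose) per replicate well of the cytotox
    dose grid.  Identical seeds give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    sigma_ln = _lognormal_sigma(config.intensity_cv)

    # -- cytotoxicity plate (drawn before the spectra, fixed order) --------
    cyto_rows = []
    resaz_base, ldh_total, ldh_ratio_base = 1000.0, 2.0, 0.10
    for cell in config.cell_lines:
        for particle in config.particles:
            b = truth.cytotox_beta[particle]
            for dose in config.doses_cytotox:
                for rep in range(1, config.n_bio_replicates + 1):
                    noise = np.exp(rng.normal(0.0, sigma_ln, size=2))
                    resaz = resaz_base * (dose + 1.0) ** b["resazurin"] * noise[0]
                    release = (
                        ldh_total
                        * ldh_ratio_base
                        * (dose + 1.0) ** b["ldh"]
                        * noise[1]
                    )
                    cyto_rows.append(
                        (cell, particle, float(dose), rep, resaz, release, ldh_total)
                    )
    cytotox = pd.DataFrame(cyto_rows, columns=CYTOTOX_COLUMNS)

    # -- spectra -----------------------------------------------------------
    lo, hi = config.mz_range
    grid = np.arange(lo, hi + config.mz_step / 2, config.mz_step)
    spectra: list[RawSpectrum] = []
    design_rows = []
    for cell in config.cell_lines:
        for particle in config.particles:
            fold = truth.sample_fold_change[particle]
            for dose in config.doses_proteomic:
                dose_fc = fold[float(dose)].to_numpy()
                for rep in range(1, config.n_bio_replicates + 1):
                    sid = sample_id(cell, particle, dose, rep)
                    for spot in range(1, config.n_spots + 1):
                        mult = np.exp(
                            rng.normal(0.0, sigma_ln, size=config.n_peptides_total)
                        )
                        heights = truth.basal_height * dose_fc * mult
                        intensity = _render_spectrum(
                            grid, truth.peptide_mz, heights, config, rng
                        )
                        spectra.append(
                            RawSpectrum(grid, intensity, sample_id=sid, spot_index=spot)
                        )
                        design_rows.append(
                            (sid, cell, particle, float(dose), rep, spot, "")
                        )
    design = pd.DataFrame(design_rows, columns=DESIGN_COLUMNS)
    return SimulatedExperiment(
        spectra=spectra, design=design, cytotox=cytotox, truth=truth, config=config
    )


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture(dirpath: str | os.PathLike, experiment: SimulatedExperiment) -> dict:
    """Write a simulated experiment to disk and return a checksum manifest.

    Layout: ``spectra/<sample>_s<spot>.txt`` (two-column text), ``design.csv``,
    ``cytotox.csv``, ``ground_truth.json`` and ``manifest.json``.
    """
    root = Path(dirpath)
    try:
        (root / "spectra").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {root}: {exc}") from exc

    design = experiment.design.copy()
    paths = []
    for i, spec in enumerate(experiment.spectra):
        rel = f"spectra/{spec.sample_id}_s{spec.spot_index}.txt"
        spec.to_text(root / rel)
        paths.append(rel)
    design["spectrum_path"] = paths
    design.to_csv(root / "design.csv", index=False)
    experiment.cytotox.to_csv(root / "cytotox.csv", index=False)
    (root / "ground_truth.json").write_text(experiment.truth.to_json())

    files = paths + ["design.csv", "cytotox.csv", "ground_truth.json"]
    manifest = {
        "n_spectra": len(experiment.spectra),
        "seed": experiment.config.seed,
        "files": {rel: _sha256(root / rel) for rel in sorted(files)},
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_fixture(
    dirpath: str | os.PathLike,
) -> tuple[list[RawSpectrum], pd.DataFrame, pd.DataFrame, GroundTruth | None]:
    """Read a fixture directory back: (spectra, design, cytotox plate, truth).

    Works for real-data directories as well: only ``design.csv`` is required,
    ``cytotox.csv`` and ``ground_truth.json`` are optional.
    """
    root = Path(dirpath)
    design = pd.read_csv(root / "design.csv")
    spectra = [
        RawSpectrum.from_text(
            root / row.spectrum_path, sample_id=row.sample_id, spot_index=int(row.spot)
        )
        for row in design.itertuples()
    ]
    cytotox_path = root / "cytotox.csv"
    cytotox = pd.read_csv(cytotox_path) if cytotox_path.exists() else pd.DataFrame()
    truth_path = root / "ground_truth.json"
    truth = GroundTruth.from_json(truth_path.read_text()) if truth_path.exists() else None
    return spectra, design, cytotox, truth
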