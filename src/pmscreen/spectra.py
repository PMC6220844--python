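"""Raw MALDI-TOF spectrum processing: baseline, noise, peaks, spot merging, alignment.

The chain turns continuous peptide-mass-fingerprint traces into an aligned
peptides x samples feature matrix:

``RawSpectrum -> detect_peaks (per spot) -> merge_spots (per sample)
-> align_features (across samples) -> FeatureMatrix``

Peak picking is deliberately simple and auditable: a rolling-minimum baseline
recentred on the local residual median, a sliding-window MAD noise estimate,
and local-maximum centroiding with an S/N threshold.  Peak lists are plain
:class:`pandas.DataFrame` objects with columns ``mz``, ``height``, ``snr``
(plus ``rsd`` and ``n_spots`` after spot merging).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .errors import FormatError, InputError

PEAK_COLUMNS = ["mz", "height", "snr"]
MERGED_COLUMNS = ["mz", "height", "snr", "rsd", "n_spots"]


@dataclass
class RawSpectrum:
    """One continuous (m/z, intensity) trace for a single spot of a sample.

    ``mz`` must be strictly increasing and ``intensity`` nonnegative, both of
    equal length >= 2.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    spot_index: int = 0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise FormatError("spectrum arrays must be one-dimensional")
        if self.mz.size != self.intensity.size:
            raise FormatError("mz and intensity arrays differ in length")
        if self.mz.size < 2:
            raise FormatError("spectrum must contain at least 2 points")
        if not np.all(np.diff(self.mz) > 0):
            raise FormatError("mz values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise FormatError("intensity values must be nonnegative")

    def __len__(self) -> int:
        return int(self.mz.size)

    # -- text I/O ----------------------------------------------------------

    def to_text(self, path: str | os.PathLike) -> None:
        """Write as two whitespace-delimited columns (m/z, intensity)."""
        np.savetxt(path, np.column_stack([self.mz, self.intensity]), fmt="%.17g")

    @classmethod
    def from_text(
        cls, path: str | os.PathLike, sample_id: str = "", spot_index: int = 0
    ) -> "RawSpectrum":
        data = np.loadtxt(path, ndmin=2)
        if data.shape[1] != 2:
            raise FormatError(f"{path}: expected two columns (m/z, intensity)")
        return cls(data[:, 0], data[:, 1], sample_id=sample_id, spot_index=spot_index)


def read_mzml(path: str | os.PathLike, sample_id: str = "") -> list[RawSpectrum]:
    """Read MS1 profile arrays from an mzML file, one :class:`RawSpectrum` per scan."""
    from pyteomics import mzml  # local import: optional entry point

    spectra: list[RawSpectrum] = []
    with mzml.read(str(path)) as reader:
        for i, scan in enumerate(reader):
            if int(scan.get("ms level", 1)) != 1:
                continue
            spectra.append(
                RawSpectrum(
                    scan["m/z array"],
                    np.clip(scan["intensity array"], 0.0, None),
                    sample_id=sample_id,
                    spot_index=i,
                )
            )
    return spectra


# ---------------------------------------------------------------------------
# baseline / noise / smoothing
# ---------------------------------------------------------------------------


def _window_points(spectrum: RawSpectrum, window: float) -> int:
    """Convert a window in Th to an odd number of grid points (>= 3)."""
    if window <= 0:
        raise ValueError("window must be > 0 Th")
    step = float(np.median(np.diff(spectrum.mz)))
    w = max(3, int(round(window / step)))
    return w + 1 if w % 2 == 0 else w


def estimate_baseline(spectrum: RawSpectrum, window: float = 30.0) -> np.ndarray:
    """Estimate the slowly varying baseline under the peaks.

    A rolling minimum (width ``window`` Th) is smoothed by a rolling mean of
    the same width and then recentred by the running median of the residual,
    so that the result tracks the centre of the noise floor instead of its
    lower tail.  The recentring is what keeps S/N ratios on a meaningful
    scale: the raw min-mean envelope sits ~3 noise SDs below the floor.
    """
    w = _window_points(spectrum, window)
    envelope = ndimage.minimum_filter1d(spectrum.intensity, size=w, mode="nearest")
    envelope = ndimage.uniform_filter1d(envelope, size=w, mode="nearest")
    resid = spectrum.intensity - envelope
    recentre = ndimage.median_filter(resid, size=w, mode="nearest")
    return envelope + recentre


def estimate_noise(
    spectrum: RawSpectrum, baseline: np.ndarray, window: float = 15.0
) -> np.ndarray:
    """Per-point noise: 1.4826 x sliding-window MAD of the residual.

    The MAD is taken about the running median of the residual so that peaks
    and residual baseline curvature do not inflate the estimate.  The result
    is floored at a machine-scale epsilon and therefore strictly positive.
    """
    w = _window_points(spectrum, window)
    resid = spectrum.intensity - np.asarray(baseline, dtype=float)
    centre = ndimage.median_filter(resid, size=w, mode="nearest")
    mad = ndimage.median_filter(np.abs(resid - centre), size=w, mode="nearest")
    noise = 1.4826 * mad
    scale = max(float(np.max(np.abs(resid), initial=0.0)), 1.0)
    return np.maximum(noise, np.finfo(float).eps * scale)


def smooth(spectrum: RawSpectrum, window: float = 1.5, polyorder: int = 2) -> RawSpectrum:
    """Savitzky-Golay smoothing, returned as a new spectrum (clipped at 0).

    Applied before peak detection to suppress single-point detector noise;
    a quadratic over ~2x the peak sigma leaves Gaussian peak tops nearly
    untouched.  ``window`` is in Th.
    """
    w = _window_points(spectrum, window)
    if w <= polyorder:
        w = polyorder + 1 + (polyorder % 2)
    smoothed = signal.savgol_filter(spectrum.intensity, w, polyorder, mode="nearest")
    return RawSpectrum(
        spectrum.mz,
        np.clip(smoothed, 0.0, None),
        sample_id=spectrum.sample_id,
        spot_index=spectrum.spot_index,
    )


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------


def detect_peaks(
    spectrum: RawSpectrum,
    snr_threshold: float = 2.0,
    baseline_window: float = 30.0,
    noise_window: float = 15.0,
    baseline: np.ndarray | None = None,
    noise: np.ndarray | None = None,
) -> pd.DataFrame:
    """Detect peaks as above-threshold local maxima of the residual.

    A point is a peak apex when the baseline-subtracted intensity is strictly
    greater than both neighbours, positive, and its S/N (height over the
    local noise estimate) reaches ``snr_threshold``.  The centroid is the
    intensity-weighted mean m/z over the contiguous region above half the
    apex height.  Returns a peak list sorted by m/z.
    """
    if snr_threshold <= 0:
        raise ValueError("snr_threshold must be > 0")
    if baseline is None:
        baseline = estimate_baseline(spectrum, baseline_window)
    if noise is None:
        noise = estimate_noise(spectrum, baseline, noise_window)
    resid = spectrum.intensity - np.asarray(baseline, dtype=float)

    inner = resid[1:-1]
    is_apex = (inner > resid[:-2]) & (inner > resid[2:]) & (inner > 0)
    apexes = np.flatnonzero(is_apex) + 1
    snr = resid[apexes] / noise[apexes]
    apexes = apexes[snr >= snr_threshold]

    rows = []
    for apex in apexes:
        height = resid[apex]
        half = 0.5 * height
        lo = apex
        while lo > 0 and resid[lo - 1] >= half and resid[lo - 1] <= resid[lo]:
            lo -= 1
        hi = apex
        n = resid.size
        while hi < n - 1 and resid[hi + 1] >= half and resid[hi + 1] <= resid[hi]:
            hi += 1
        region = slice(lo, hi + 1)
        weights = resid[region]
        centroid = float(np.average(spectrum.mz[region], weights=weights))
        rows.append((centroid, float(height), float(height / noise[apex])))

    peaks = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    return peaks.sort_values("mz", kind="stable", ignore_index=True)


def select_top_features(
    peaks: pd.DataFrame, n: int = 200, snr_floor: float = 3.0
) -> pd.DataFrame:
    """Keep the ``n`` highest-S/N peaks at or above ``snr_floor``.

    Ties in S/N break by ascending m/z, so the selection is deterministic.
    Fewer than ``n`` peaks may be returned.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    kept = peaks[peaks["snr"] >= snr_floor]
    kept = kept.sort_values(["snr", "mz"], ascending=[False, True], kind="stable")
    return kept.head(n).reset_index(drop=True)


# ---------------------------------------------------------------------------
# clustering of centroids (shared by spot merging and cross-sample alignment)
# ---------------------------------------------------------------------------


def _cluster_centroids(mz: np.ndarray, tolerance_ppm: float) -> np.ndarray:
    """Greedy single-linkage clustering of sorted centroids.

    Consecutive centroids are chained into one cluster while the gap stays
    within ``tolerance_ppm`` of the local m/z.  Returns cluster labels for
    the (sorted) input.
    """
    labels = np.zeros(mz.size, dtype=int)
    if mz.size == 0:
        return labels
    gaps = np.diff(mz)
    breaks = gaps > tolerance_ppm * 1e-6 * mz[:-1]
    labels[1:] = np.cumsum(breaks)
    return labels


def _resolve_clusters(
    mz: np.ndarray, source: np.ndarray, tolerance_ppm: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Cluster sorted centroids and keep one member per (cluster, source).

    Within each cluster a source (spot or sample) contributes only its peak
    nearest the cluster mean.  Returns (kept row indices, cluster label per
    kept row, number of clusters).
    """
    labels = _cluster_centroids(mz, tolerance_ppm)
    n_clusters = int(labels[-1]) + 1 if labels.size else 0
    counts = np.bincount(labels, minlength=n_clusters)
    means = np.bincount(labels, weights=mz, minlength=n_clusters) / counts
    dist = np.abs(mz - means[labels])
    order = np.lexsort((dist, source, labels))
    lab_o, src_o = labels[order], source[order]
    first = np.ones(order.size, dtype=bool)
    first[1:] = (lab_o[1:] != lab_o[:-1]) | (src_o[1:] != src_o[:-1])
    kept = order[first]
    kept.sort()
    return kept, labels[kept], n_clusters


def merge_spots(
    peaklists: list[pd.DataFrame],
    tolerance_ppm: float = 250.0,
    min_spot_fraction: float = 0.6,
) -> pd.DataFrame:
    """Merge the technical-spot peak lists of one sample into a consensus list.

    Peaks are matched across spots within ``tolerance_ppm``; the merged height
    is the mean over the spots where the feature was detected and the
    per-feature RSD (sd/mean, ddof=1) quantifies spot repeatability.  Features
    detected in fewer than ``min_spot_fraction`` of the spots are dropped.
    """
    if len(peaklists) == 0:
        raise InputError("merge_spots requires at least one spot peak list")
    n_spots = len(peaklists)
    pooled = pd.concat(
        [pl.assign(_spot=i) for i, pl in enumerate(peaklists)], ignore_index=True
    )
    if pooled.empty:
        return pd.DataFrame(columns=MERGED_COLUMNS)
    pooled = pooled.sort_values("mz", kind="stable", ignore_index=True)

    mz = pooled["mz"].to_numpy(dtype=float)
    height = pooled["height"].to_numpy(dtype=float)
    snr = pooled["snr"].to_numpy(dtype=float)
    spot = pooled["_spot"].to_numpy()
    kept, kl, n_clusters = _resolve_clusters(mz, spot, tolerance_ppm)

    n_det = np.bincount(kl, minlength=n_clusters)
    mean_mz = np.bincount(kl, weights=mz[kept], minlength=n_clusters) / n_det
    mean_h = np.bincount(kl, weights=height[kept], minlength=n_clusters) / n_det
    mean_snr = np.bincount(kl, weights=snr[kept], minlength=n_clusters) / n_det
    dev = height[kept] - mean_h[kl]
    ssq = np.bincount(kl, weights=dev * dev, minlength=n_clusters)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(ssq / np.maximum(n_det - 1, 1))
        rsd = np.where(n_det > 1, sd / mean_h, 0.0)

    keep = n_det / n_spots >= min_spot_fraction
    merged = pd.DataFrame(
        {
            "mz": mean_mz[keep],
            "height": mean_h[keep],
            "snr": mean_snr[keep],
            "rsd": rsd[keep],
            "n_spots": n_det[keep],
        }
    )
    return merged.sort_values("mz", kind="stable", ignore_index=True)


# ---------------------------------------------------------------------------
# cross-sample alignment
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Aligned peptide features x samples intensities (missing values allowed).

    ``intensities`` and ``snr`` are DataFrames indexed by the strictly
    increasing consensus m/z, with one column per sample (sorted by id).
    """

    intensities: pd.DataFrame
    snr: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.snr is None:
            self.snr = self.intensities * np.nan
        mz = self.intensities.index.to_numpy(dtype=float)
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise FormatError("feature m/z index must be strictly increasing")

    @property
    def mz(self) -> np.ndarray:
        return self.intensities.index.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def to_csv(self, path: str | os.PathLike) -> None:
        out = self.intensities.copy()
        out.insert(0, "mz", self.intensities.index.to_numpy(dtype=float))
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike | io.TextIOBase) -> "FeatureMatrix":
        df = pd.read_csv(path)
        df = df.set_index("mz")
        df.index = df.index.astype(float)
        return cls(intensities=df)


def align_features(
    merged: dict[str, pd.DataFrame], tolerance_ppm: float = 250.0
) -> FeatureMatrix:
    """Align per-sample consensus peak lists into a feature matrix.

    Greedy single-linkage matching of centroids within ``tolerance_ppm``
    (default 250 ppm, reflecting external-calibration mass accuracy).  Each
    sample contributes at most one peak per feature (the one nearest the
    cluster mean); the consensus m/z is the mean of the member centroids.
    Missing values stay explicit as NaN.  The result is invariant to the
    order in which samples are supplied.
    """
    if len(merged) < 2:
        raise InputError("align_features requires at least 2 samples")
    sample_ids = sorted(merged)
    pooled = pd.concat(
        [merged[s].assign(_sample=i) for i, s in enumerate(sample_ids)],
        ignore_index=True,
    )
    if pooled.empty:
        empty = pd.DataFrame(columns=sample_ids, index=pd.Index([], name="mz"))
        return FeatureMatrix(intensities=empty, snr=empty.copy())
    pooled = pooled.sort_values("mz", kind="stable", ignore_index=True)

    mz = pooled["mz"].to_numpy(dtype=float)
    height = pooled["height"].to_numpy(dtype=float)
    snr = pooled["snr"].to_numpy(dtype=float)
    sample = pooled["_sample"].to_numpy()
    kept, kl, n_clusters = _resolve_clusters(mz, sample, tolerance_ppm)

    n_members = np.bincount(kl, minlength=n_clusters)
    consensus = np.bincount(kl, weights=mz[kept], minlength=n_clusters) / n_members
    heights = np.full((n_clusters, len(sample_ids)), np.nan)
    snrs = np.full((n_clusters, len(sample_ids)), np.nan)
    heights[kl, sample[kept]] = height[kept]
    snrs[kl, sample[kept]] = snr[kept]

    order = np.argsort(consensus, kind="stable")
    index = pd.Index(consensus[order], name="mz")
    return FeatureMatrix(
        intensities=pd.DataFrame(heights[order], index=index, columns=sample_ids),
        snr=pd.DataFrame(snrs[order], index=index, columns=sample_ids),
    )
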