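"""Spectral preprocessing: reference normalization, binning, Pareto scaling.

The pipeline mirrors standard urinary NMR chemometrics practice: each
spectrum is normalized to the integral of the TSP reference singlet at
0.00 ppm (removing urinary dilution), bucketed into fixed 0.0092-ppm bins
with the residual-water region 4.6-5.2 ppm excluded, then mean-centered
and Pareto-scaled (divide by the square root of the column standard
deviation) before multivariate modeling.

Binning convention: bins are half-open [left, right) intervals laid down
from the high-ppm end of the axis toward the low end; the single point at
exactly ppm_max is assigned to the first (topmost) bin; a trailing partial
bin at ppm_min is kept. A bin's value is the SUM of point intensities
falling in it. Any bin overlapping the exclusion window is dropped
entirely. Columns are ordered by descending bin-center ppm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Spectrum, SpectrumSet

__all__ = [
    "BinnedMatrix",
    "ScalingParams",
    "normalize_to_reference",
    "bin_spectrum",
    "build_matrix",
    "pareto_scale",
    "apply_scaling",
]

DEFAULT_BIN_WIDTH = 0.0092
WATER_WINDOW = (4.6, 5.2)
DEFAULT_REF_WINDOW = (-0.05, 0.05)


@dataclass
class BinnedMatrix:
    """Samples x bins feature table with its bin-edge bookkeeping."""

    values: np.ndarray  # (n_samples, n_bins)
    bin_edges: list[tuple[float, float]]  # (left_ppm, right_ppm), descending centers
    excluded_region: tuple[float, float] | None
    sample_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.bin_edges):
            raise ValueError("bin_edges length must match column count")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length must match row count")

    @property
    def bin_centers(self) -> np.ndarray:
        return np.array([(l + r) / 2 for l, r in self.bin_edges])

    def to_csv(self, values_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        cols = [f"{c:.4f}" for c in self.bin_centers]
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=cols)
        df.index.name = "sample_id"
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        df.to_csv(values_path)
        if sidecar_path is not None:
            meta = {
                "bin_edges": [list(e) for e in self.bin_edges],
                "excluded_region": list(self.excluded_region) if self.excluded_region else None,
                "sample_ids": self.sample_ids,
            }
            Path(sidecar_path).write_text(json.dumps(meta))


@dataclass
class ScalingParams:
    """Column means/SDs estimated on training data; reused on new samples."""

    col_means: np.ndarray
    col_sds: np.ndarray  # sample SD, denominator n-1
    scale_kind: str = "pareto"

    def __post_init__(self) -> None:
        self.col_means = np.asarray(self.col_means, dtype=float)
        self.col_sds = np.asarray(self.col_sds, dtype=float)
        if self.col_means.shape != self.col_sds.shape:
            raise ValueError("means/sds length mismatch")
        if np.any(self.col_sds < 0):
            raise ValueError("sds must be >= 0")
        if self.scale_kind not in ("pareto", "center_only"):
            raise ValueError("scale_kind must be 'pareto' or 'center_only'")


def normalize_to_reference(
    spectrum: Spectrum,
    ref_window: tuple[float, float] = DEFAULT_REF_WINDOW,
    sample_id: str = "<sample>",
) -> Spectrum:
    """Divide intensities by the trapezoidal integral over the reference window.

    The window is intersected with the spectral axis (the default TSP
    window straddles 0 ppm while axes often start at 0). After the call
    the reference integral equals 1.
    """
    ppm = spectrum.ppm
    lo, hi = min(ref_window), max(ref_window)
    lo = max(lo, ppm.min())
    hi = min(hi, ppm.max())
    if not lo < hi:
        raise ValueError(f"reference window {ref_window} does not overlap the axis")
    order = np.argsort(ppm)
    p, y = ppm[order], spectrum.intensity[order]
    mask = (p >= lo) & (p <= hi)
    if mask.sum() < 2:
        raise ValueError("reference window contains fewer than 2 axis points")
    integral = float(np.trapezoid(y[mask], p[mask]))
    if integral <= 0:
        raise ValueError(f"non-positive reference integral in sample {sample_id}")
    return Spectrum(spectrum.ppm, spectrum.intensity / integral, spectrum.label)


def _bin_edges_for_axis(
    ppm_min: float, ppm_max: float, width: float
) -> list[tuple[float, float]]:
    """All bin edges from ppm_max downward, trailing partial bin kept."""
    n_bins = int(np.ceil((ppm_max - ppm_min) / width - 1e-12))
    edges = []
    for k in range(n_bins):
        right = ppm_max - k * width
        left = max(ppm_min, ppm_max - (k + 1) * width)
        edges.append((left, right))
    return edges


def _overlaps(edge: tuple[float, float], window: tuple[float, float]) -> bool:
    left, right = edge
    lo, hi = window
    return left < hi and right > lo


def bin_spectrum(
    spectrum: Spectrum,
    width: float = DEFAULT_BIN_WIDTH,
    exclude: tuple[float, float] | None = WATER_WINDOW,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Bucket one spectrum into fixed-width bins, dropping water-region bins.

    Returns (bin_values, bin_edges) ordered by descending ppm. Bin values
    are sums of point intensities in [left, right); the point at exactly
    ppm_max goes to the first bin; bins overlapping `exclude` are dropped.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    ppm = spectrum.ppm
    ppm_min, ppm_max = float(ppm.min()), float(ppm.max())
    if width > ppm_max - ppm_min:
        raise ValueError("bin width exceeds axis span")
    edges = _bin_edges_for_axis(ppm_min, ppm_max, width)
    idx = np.floor((ppm_max - ppm) / width).astype(int)
    idx = np.clip(idx, 0, len(edges) - 1)  # ppm_max point into bin 0
    values = np.bincount(idx, weights=spectrum.intensity, minlength=len(edges))
    if exclude is not None:
        keep = [i for i, e in enumerate(edges) if not _overlaps(e, exclude)]
        values = values[keep]
        edges = [edges[i] for i in keep]
    return values, edges


def build_matrix(
    spectrum_set: SpectrumSet,
    width: float = DEFAULT_BIN_WIDTH,
    exclude: tuple[float, float] | None = WATER_WINDOW,
) -> BinnedMatrix:
    """Bin every spectrum of a set sharing one axis into one feature matrix."""
    rows = []
    edges_ref: list[tuple[float, float]] | None = None
    for i in range(len(spectrum_set)):
        values, edges = bin_spectrum(spectrum_set.spectrum(i), width, exclude)
        if edges_ref is None:
            edges_ref = edges
        rows.append(values)
    assert edges_ref is not None
    return BinnedMatrix(
        values=np.vstack(rows),
        bin_edges=edges_ref,
        excluded_region=exclude,
        sample_ids=list(spectrum_set.sample_ids),
        labels=None if spectrum_set.labels is None else spectrum_set.labels.copy(),
    )


def pareto_scale(matrix: BinnedMatrix | np.ndarray) -> tuple[np.ndarray, ScalingParams]:
    """Mean-center and Pareto-scale: x -> (x - mean) / sqrt(sd), sd with n-1.

    Zero-variance columns become all zeros and are kept (not dropped) so
    bin bookkeeping stays aligned. Requires at least two samples.
    """
    X = matrix.values if isinstance(matrix, BinnedMatrix) else np.asarray(matrix, float)
    if X.shape[0] < 2:
        raise ValueError("Pareto scaling needs at least 2 samples")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    params = ScalingParams(means, sds, "pareto")
    return apply_scaling(X, params), params


def apply_scaling(
    matrix: BinnedMatrix | np.ndarray, params: ScalingParams
) -> np.ndarray:
    """Scale new data with stored training means/SDs (never re-estimated)."""
    X = matrix.values if isinstance(matrix, BinnedMatrix) else np.asarray(matrix, float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != params.col_means.size:
        raise ValueError(
            f"column count {X.shape[1]} does not match scaling params "
            f"({params.col_means.size})"
        )
    centered = X - params.col_means
    if params.scale_kind == "center_only":
        return centered
    denom = np.sqrt(params.col_sds)
    out = np.zeros_like(centered)
    nz = denom > 0
    out[:, nz] = centered[:, nz] / denom[nz]
    return out
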