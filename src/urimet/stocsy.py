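"""Statistical total correlation spectroscopy (STOCSY) marker identification.

Correlates a driver variable — by default the OPLS predictive score — with
every spectral bin. The exported profile is the per-bin covariance with
the driver, colored by the Pearson correlation; bins whose |r| clears a
threshold are matched to library signatures by chemical shift to annotate
the metabolites responsible for class separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import BinnedMatrix
from .signatures import MetaboliteSignature

__all__ = ["StocsyResult", "run_stocsy", "annotate_peaks", "group_difference_test"]


@dataclass
class StocsyResult:
    """Per-bin correlation/covariance with the driver plus annotations."""

    corr: np.ndarray
    cov: np.ndarray
    bin_centers: np.ndarray
    constant_bins: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    annotations: list[tuple[str, list[int]]] = field(default_factory=list)
    unassigned: list[int] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"bin_center": self.bin_centers, "cov": self.cov, "corr": self.corr}
        ).to_csv(path, index=False)

    def annotations_to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "annotations": [
                        {"metabolite": m, "bins": b} for m, b in self.annotations
                    ],
                    "unassigned_bins": self.unassigned,
                }
            )
        )


def run_stocsy(matrix: BinnedMatrix | np.ndarray, driver: np.ndarray,
               bin_centers: np.ndarray | None = None) -> StocsyResult:
    """Correlate the driver with every bin.

    corr_j is the Pearson correlation of the driver with column j; cov_j
    the sample covariance (denominator n-1). Constant columns get corr 0
    by convention and are flagged in ``constant_bins``.
    """
    if isinstance(matrix, BinnedMatrix):
        X = matrix.values
        centers = matrix.bin_centers
    else:
        X = np.asarray(matrix, dtype=float)
        centers = np.asarray(bin_centers, float) if bin_centers is not None \
            else np.arange(X.shape[1], dtype=float)
    d = np.asarray(driver, dtype=float).ravel()
    if d.size != X.shape[0]:
        raise ValueError("driver length must equal sample count")
    if np.ptp(d) == 0:
        raise ValueError("driver is constant")
    n = d.size
    dc = d - d.mean()
    Xc = X - X.mean(axis=0)
    cov = dc @ Xc / (n - 1)
    sd_d = dc.std(ddof=1)
    sd_x = Xc.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd_x == 0)
    denom = sd_d * np.where(sd_x == 0, 1.0, sd_x)
    corr = cov / denom
    corr[constant] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    return StocsyResult(corr=corr, cov=cov, bin_centers=centers, constant_bins=constant)


def annotate_peaks(
    result: StocsyResult,
    signature_library: list[MetaboliteSignature],
    r_threshold: float = 0.6,
    ppm_tol: float = 0.02,
) -> list[tuple[str, list[int]]]:
    """Match high-|correlation| bins to library signatures by chemical shift.

    A bin qualifies when |corr| >= r_threshold; it is assigned to every
    signature with a peak center within ppm_tol of the bin center.
    Qualifying bins matching no signature are listed as unassigned.
    Updates and returns result.annotations.
    """
    if not signature_library:
        raise ValueError("empty signature library")
    hot = np.flatnonzero(np.abs(result.corr) >= r_threshold)
    matched: dict[str, list[int]] = {}
    assigned = set()
    for sig in signature_library:
        bins = [
            int(b)
            for b in hot
            if any(abs(result.bin_centers[b] - pk.center_ppm) <= ppm_tol for pk in sig.peaks)
        ]
        if bins:
            matched[sig.name] = bins
            assigned.update(bins)
    result.annotations = sorted(matched.items())
    result.unassigned = [int(b) for b in hot if b not in assigned]
    return result.annotations


def group_difference_test(
    metabolite_levels: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Two-sided rank-sum (Mann-Whitney) test per metabolite.

    Returns a table with p-value and direction ("increased"/"decreased"/
    "unchanged" in cases, from group medians). The exact null distribution
    is used when sample sizes permit and there are no ties (scipy's
    default policy).
    """
    if isinstance(metabolite_levels, pd.DataFrame):
        names = list(metabolite_levels.columns)
        X = metabolite_levels.to_numpy(float)
    else:
        X = np.asarray(metabolite_levels, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"m{j}" for j in range(X.shape[1])]
    labels = np.asarray(labels).ravel()
    g0, g1 = X[labels == 0], X[labels == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each group needs at least 2 samples")
    rows = []
    for j, name in enumerate(names):
        res = stats.mannwhitneyu(g1[:, j], g0[:, j], alternative="two-sided")
        med1, med0 = float(np.median(g1[:, j])), float(np.median(g0[:, j]))
        if med1 > med0:
            direction = "increased"
        elif med1 < med0:
            direction = "decreased"
        else:
            direction = "unchanged"
        rows.append({"metabolite": name, "p_value": float(res.pvalue), "direction": direction})
    return pd.DataFrame(rows)
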