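"""Diagnostic-accuracy panel and ROC biomarker ranking.

Implements the standard screening-test arithmetic:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    PPV  = sens*prev / [sens*prev + (1 - spec)(1 - prev)]
    NPV  = spec*(1 - prev) / [(1 - sens)*prev + spec*(1 - prev)]
    +LR  = sens / (1 - spec)        (reported "N/A" when spec = 1)
    -LR  = (1 - sens) / spec        (undefined when spec = 0)

plus ROC curves whose trapezoidal AUC equals the Mann-Whitney pair-count
probability (ties counted one half), per-metabolite level estimation by
window integration over signature lines, and oriented multi-marker AUC
ranking.

Formatting conventions: the diagnostic panel reports percentages rounded
half-up to one decimal; the serum-marker panel truncates to one decimal
(its conservative historical convention); both are explicit, documented
choices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .preprocess import normalize_to_reference, DEFAULT_REF_WINDOW
from .signatures import MetaboliteSignature
from .simulate import Spectrum, SpectrumSet

__all__ = [
    "ConfusionCounts",
    "DiagnosticReport",
    "RocCurve",
    "confusion",
    "accuracy_panel",
    "accuracy_panel_from_rates",
    "marker_panel_from_counts",
    "roc_auc",
    "multi_roc_ranking",
    "metabolite_levels",
    "pct_half_up",
    "pct_truncated",
]

PLR_NA = "N/A"


def pct_half_up(x: float, decimals: int = 1) -> str:
    """Percentage string, rounded half-up (0.36585 -> '36.6%')."""
    q = Decimal(1).scaleb(-decimals)
    return f"{Decimal(repr(100 * x)).quantize(q, rounding=ROUND_HALF_UP)}%"


def pct_truncated(x: float, decimals: int = 1) -> str:
    """Percentage string, truncated toward zero (0.0625 -> '6.2%')."""
    factor = 10**decimals
    return f"{math.floor(100 * x * factor + 1e-9) / factor:.{decimals}f}%"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.positives + self.negatives

    def per_class_strings(self) -> tuple[str, str]:
        """('correct/total' controls, 'correct/total' cases)."""
        return f"{self.tn}/{self.negatives}", f"{self.tp}/{self.positives}"


@dataclass(frozen=True)
class DiagnosticReport:
    """The full accuracy panel. plr is None when specificity = 1 (reported
    as the 'N/A' sentinel); nlr is None when specificity = 0."""

    sensitivity: float
    specificity: float
    prevalence: float
    ppv: float
    npv: float
    plr: float | None
    nlr: float | None

    def formatted(self) -> dict[str, str]:
        """One-decimal percent strings (half-up) and 1-2 decimal ratios."""
        return {
            "prevalence": pct_half_up(self.prevalence),
            "sensitivity": pct_half_up(self.sensitivity),
            "specificity": pct_half_up(self.specificity),
            "ppv": pct_half_up(self.ppv),
            "npv": pct_half_up(self.npv),
            "plr": PLR_NA if self.plr is None else f"{self.plr:.1f}",
            "nlr": PLR_NA if self.nlr is None else f"{self.nlr:.2f}",
        }


def confusion(labels_true: np.ndarray, labels_pred: np.ndarray) -> ConfusionCounts:
    """Confusion counts for binary labels (1 = case/positive)."""
    t = np.asarray(labels_true).ravel()
    p = np.asarray(labels_pred).ravel()
    if t.size != p.size:
        raise ValueError("label vectors must have equal length")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
    )


def accuracy_panel_from_rates(
    sensitivity: float, specificity: float, prevalence: float
) -> DiagnosticReport:
    """Accuracy panel from sensitivity, specificity and prevalence."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1) for PPV/NPV")
    se, sp, pr = sensitivity, specificity, prevalence
    ppv_den = se * pr + (1 - sp) * (1 - pr)
    npv_den = (1 - se) * pr + sp * (1 - pr)
    ppv = se * pr / ppv_den if ppv_den > 0 else float("nan")
    npv = sp * (1 - pr) / npv_den if npv_den > 0 else float("nan")
    plr = None if sp == 1 else se / (1 - sp)
    nlr = None if sp == 0 else (1 - se) / sp
    return DiagnosticReport(se, sp, pr, ppv, npv, plr, nlr)


def accuracy_panel(
    counts: ConfusionCounts, prevalence: float | None = None
) -> DiagnosticReport:
    """Accuracy panel from confusion counts.

    Prevalence defaults to the evaluated set's composition; pass an
    external population prevalence to project predictive values elsewhere.
    """
    if counts.positives == 0 or counts.negatives == 0:
        raise ValueError("both classes must be present")
    se = counts.tp / counts.positives
    sp = counts.tn / counts.negatives
    pr = counts.positives / counts.total if prevalence is None else prevalence
    return accuracy_panel_from_rates(se, sp, pr)


def marker_panel_from_counts(
    pos_above_cutoff: int, pos_total: int, neg_above_cutoff: int, neg_total: int
) -> dict:
    """Sensitivity/specificity of a threshold marker from raw counts.

    Positives above the cut-off are detections; negatives above it are
    false positives. Reported percent strings are truncated to one
    decimal.
    """
    if pos_total <= 0 or neg_total <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= pos_above_cutoff <= pos_total and 0 <= neg_above_cutoff <= neg_total):
        raise ValueError("counts out of range")
    sens = pos_above_cutoff / pos_total
    spec = 1 - neg_above_cutoff / neg_total
    return {
        "sensitivity": sens,
        "specificity": spec,
        "sensitivity_pct": pct_truncated(sens),
        "specificity_pct": pct_truncated(spec),
    }


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve over all distinct score thresholds, trapezoidal AUC.

    A sample is called positive when its score >= threshold. The AUC
    equals the Mann-Whitney probability that a random case outscores a
    random control, with ties counted one half.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if s.size != y.size:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.unique(s)[::-1]
    tpr = np.empty(thresholds.size + 2)
    fpr = np.empty(thresholds.size + 2)
    tpr[0] = fpr[0] = 0.0
    for i, thr in enumerate(thresholds, start=1):
        called = s >= thr
        tpr[i] = (called & (y == 1)).sum() / n_pos
        fpr[i] = (called & (y == 0)).sum() / n_neg
    tpr[-1] = fpr[-1] = 1.0
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def multi_roc_ranking(
    metabolite_levels_matrix: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Oriented per-metabolite AUC ranking.

    Each metabolite's AUC is computed on its raw level; when the raw AUC
    is below 0.5 the orientation is flipped (the marker is *decreased* in
    cases) so the reported AUC is always >= 0.5, with the direction
    recorded. Rows are sorted by descending oriented AUC.
    """
    if isinstance(metabolite_levels_matrix, pd.DataFrame):
        names = list(metabolite_levels_matrix.columns)
        X = metabolite_levels_matrix.to_numpy(float)
    else:
        X = np.asarray(metabolite_levels_matrix, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"m{j}" for j in range(X.shape[1])]
    if X.shape[1] < 1:
        raise ValueError("need at least one metabolite column")
    rows = []
    for j, name in enumerate(names):
        raw = roc_auc(X[:, j], labels).auc
        if raw >= 0.5:
            rows.append({"metabolite": name, "auc": raw, "direction": "increased"})
        else:
            rows.append({"metabolite": name, "auc": 1 - raw, "direction": "decreased"})
    return (
        pd.DataFrame(rows)
        .sort_values("auc", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )


def metabolite_levels(
    spectrum_set: SpectrumSet,
    signature_library: list[MetaboliteSignature],
    window_ppm: float = 0.02,
    ref_window: tuple[float, float] = DEFAULT_REF_WINDOW,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-sample metabolite levels by window integration.

    After reference normalization, each metabolite's level is the summed
    intensity over +/- window_ppm windows around every one of its
    signature line centers. A transparent stand-in for database-fitted
    quantification; levels are proportional to concentration for
    isolated, noiseless peaks.
    """
    ppm = spectrum_set.ppm
    for sig in signature_library:
        for pk in sig.peaks:
            if not (ppm.min() <= pk.center_ppm <= ppm.max()):
                raise ValueError(
                    f"{sig.name} peak at {pk.center_ppm} ppm is outside the axis"
                )
    masks = {
        sig.name: np.any(
            [np.abs(ppm - pk.center_ppm) <= window_ppm for pk in sig.peaks], axis=0
        )
        for sig in signature_library
    }
    rows = []
    for i in range(len(spectrum_set)):
        spec = spectrum_set.spectrum(i)
        if normalize:
            spec = normalize_to_reference(spec, ref_window, spectrum_set.sample_ids[i])
        rows.append({name: float(spec.intensity[m].sum()) for name, m in masks.items()})
    return pd.DataFrame(rows, index=spectrum_set.sample_ids)
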