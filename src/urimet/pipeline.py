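"""End-to-end study replica and published-table verification.

``run_study_replica`` sequences the whole analysis — simulate (or load) a
cohort, TSP-normalize, bin with water exclusion, Pareto-scale, fit and
blinded-holdout-validate the OPLS-DA model, run STOCSY marker
identification, rank metabolites by ROC, and emit a diagnostic-accuracy
report — into one seeded, reproducible run directory.

``verify_reference_tables`` recomputes, from the published validation
counts shipped below as a plain fixture, every cell of the published
diagnostic-accuracy table and the serum-marker rates, and reports
computed vs published. Two published percentage cells (stage-0 PPV and
advanced-adenoma NPV) differ by one unit in the last printed digit from
what the published formulas give on the published counts (exactly 7/8 and
52/55); the verification reports them honestly as mismatches.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .signatures import build_signature_library
from .simulate import (
    SimConfig,
    CohortDesign,
    SpectrumSet,
    simulate_cohort,
    write_spectrum_set,
    read_spectrum_set,
)
from .preprocess import (
    normalize_to_reference,
    build_matrix,
    pareto_scale,
    DEFAULT_BIN_WIDTH,
    WATER_WINDOW,
    DEFAULT_REF_WINDOW,
)
from .opls import fit_opls, cross_validate_q2, holdout_validate, CUTOFF
from .stocsy import run_stocsy, annotate_peaks, group_difference_test
from .diagnostics import (
    ConfusionCounts,
    accuracy_panel,
    accuracy_panel_from_rates,
    marker_panel_from_counts,
    metabolite_levels,
    multi_roc_ranking,
    pct_half_up,
)

__all__ = [
    "RunConfig",
    "run_study_replica",
    "verify_reference_tables",
    "REFERENCE_VALIDATION_COUNTS",
    "REFERENCE_ACCURACY_TABLE",
    "REFERENCE_SERUM_MARKER",
]

log = logging.getLogger("urimet")

# ---------------------------------------------------------------------------
# Published reference fixture: blinded-validation counts per diagnostic model
# (controls correct/total, cases correct/total) and the published accuracy
# panel derived from them, plus the serum tumor-marker counts.
# ---------------------------------------------------------------------------

REFERENCE_VALIDATION_COUNTS: dict[str, dict[str, int]] = {
    "All CRN": {"ctrl_correct": 50, "ctrl_total": 52, "case_correct": 30, "case_total": 30},
    "Pre-invasive CRN": {"ctrl_correct": 50, "ctrl_total": 52, "case_correct": 19, "case_total": 20},
    "Stage 0 CRC": {"ctrl_correct": 51, "ctrl_total": 52, "case_correct": 7, "case_total": 7},
    "Advanced adenoma": {"ctrl_correct": 52, "ctrl_total": 52, "case_correct": 9, "case_total": 12},
}

#: Published panel values (percent / ratio) as printed in the source table.
REFERENCE_ACCURACY_TABLE: dict[str, dict[str, float | str]] = {
    "All CRN": {"prevalence": 36.6, "sensitivity": 100.0, "specificity": 96.2,
                "ppv": 93.8, "npv": 100.0, "plr": 26.0, "nlr": 0.00},
    "Pre-invasive CRN": {"prevalence": 27.8, "sensitivity": 95.0, "specificity": 96.2,
                         "ppv": 90.5, "npv": 98.0, "plr": 24.7, "nlr": 0.05},
    "Stage 0 CRC": {"prevalence": 11.9, "sensitivity": 100.0, "specificity": 98.1,
                    "ppv": 87.6, "npv": 100.0, "plr": 52.0, "nlr": 0.00},
    "Advanced adenoma": {"prevalence": 18.8, "sensitivity": 75.0, "specificity": 100.0,
                         "ppv": 100.0, "npv": 94.6, "plr": "N/A", "nlr": 0.25},
}

#: Serum tumor-marker counts (patients/controls above cut-off) and the
#: published sensitivity/specificity percentages.
REFERENCE_SERUM_MARKER = {
    "pos_above": 2, "pos_total": 32, "neg_above": 1, "neg_total": 156,
    "published_sensitivity": 6.2, "published_specificity": 99.3,
}


@dataclass
class RunConfig:
    """Resolved configuration for one study-replica run.

    Defaults are the analysis constants of the replicated protocol:
    0.0092-ppm bins, 4.6-5.2 ppm water exclusion, one predictive plus
    three orthogonal components, 7-fold internal cross-validation, a
    one-third blinded holdout and a 0.5 class cut-off.
    """

    spectra_csv: str | None = None      # load this wide CSV instead of simulating
    labels_csv: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    design: CohortDesign = field(default_factory=CohortDesign)
    bin_width: float = DEFAULT_BIN_WIDTH
    exclude: tuple[float, float] = WATER_WINDOW
    ref_window: tuple[float, float] = DEFAULT_REF_WINDOW
    n_orth: int = 3
    cv_folds: int = 7
    holdout_fraction: float = 1 / 3
    cutoff: float = CUTOFF
    r_threshold: float = 0.6
    seed: int = 0
    write_spectra: bool = False

    def resolved(self) -> dict:
        d = asdict(self)
        d["exclude"] = list(self.exclude)
        d["ref_window"] = list(self.ref_window)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    d = asdict(cfg)
    d["seed"] = seed
    return SimConfig(**d)


def run_study_replica(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full pipeline and write all stage outputs under out_dir.

    Outputs: labels.csv (and spectra.csv when requested), binned_matrix.csv
    + binned_matrix.meta.json, model.json, scores.csv, report.json +
    report.txt, stocsy.csv + stocsy_annotations.json, roc_ranking.csv,
    markers.csv, config_resolved.yaml. Deterministic per seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        library = build_signature_library()

        stage = "cohort"
        if config.spectra_csv is not None:
            sset = read_spectrum_set(config.spectra_csv, config.labels_csv)
            if sset.labels is None:
                raise ValueError("class labels are required for model fitting")
        else:
            sset, _ = simulate_cohort(config.design, _with_seed(config.sim, config.seed))
        labels = sset.labels
        log.info("cohort: %d controls, %d cases", (labels == 0).sum(), (labels == 1).sum())
        pd.DataFrame({"sample_id": sset.sample_ids, "label": labels}).to_csv(
            out / "labels.csv", index=False
        )
        if config.write_spectra:
            write_spectrum_set(sset, out / "spectra.csv")

        stage = "normalization"
        norm = np.vstack(
            [
                normalize_to_reference(
                    sset.spectrum(i), config.ref_window, sset.sample_ids[i]
                ).intensity
                for i in range(len(sset))
            ]
        )
        nset = SpectrumSet(sset.ppm, norm, sset.sample_ids, labels)

        stage = "binning"
        matrix = build_matrix(nset, config.bin_width, config.exclude)
        matrix.to_csv(out / "binned_matrix.csv", out / "binned_matrix.meta.json")
        log.info("binning: %d samples x %d retained bins", *matrix.values.shape)

        stage = "model fit"
        X_scaled, params = pareto_scale(matrix)
        model = fit_opls(X_scaled, labels, n_orth=config.n_orth, scaling=params)
        model.q2 = cross_validate_q2(
            X_scaled, labels, config.n_orth, config.cv_folds, config.seed
        )
        log.info("fit: R2Y=%.3f Q2=%.3f", model.r2y, model.q2)
        model.to_json(
            out / "model.json",
            seed=config.seed, n_orth=config.n_orth, cv_folds=config.cv_folds,
            config_hash=config.config_hash(), urimet_version=__version__,
        )
        pd.DataFrame(
            {
                "sample_id": matrix.sample_ids,
                "label": labels,
                "t_p": model.t_p,
                "t_o1": model.T_o[:, 0] if config.n_orth else np.zeros_like(model.t_p),
            }
        ).to_csv(out / "scores.csv", index=False)

        stage = "holdout validation"
        hmodel, counts = holdout_validate(
            matrix.values, labels, config.holdout_fraction, config.n_orth,
            config.seed, config.cutoff, config.cv_folds,
        )
        cc = ConfusionCounts(
            tp=counts["case_correct"],
            fn=counts["case_total"] - counts["case_correct"],
            tn=counts["control_correct"],
            fp=counts["control_total"] - counts["control_correct"],
        )
        panel = accuracy_panel(cc)
        log.info(
            "holdout: controls %d/%d, cases %d/%d",
            counts["control_correct"], counts["control_total"],
            counts["case_correct"], counts["case_total"],
        )

        stage = "stocsy"
        stoc = run_stocsy(X_scaled, model.t_p, matrix.bin_centers)
        annotate_peaks(stoc, library, config.r_threshold)
        stoc.to_csv(out / "stocsy.csv")
        stoc.annotations_to_json(out / "stocsy_annotations.json")

        stage = "roc"
        levels = metabolite_levels(sset, library, ref_window=config.ref_window)
        ranking = multi_roc_ranking(levels, labels)
        ranking.to_csv(out / "roc_ranking.csv", index=False)
        markers = group_difference_test(levels, labels)
        markers.to_csv(out / "markers.csv", index=False)

        stage = "report"
        ctrl_str, case_str = cc.per_class_strings()
        report = {
            "r2y": round(model.r2y, 6),
            "q2": round(model.q2, 6),
            "holdout_q2": round(hmodel.q2, 6),
            "prediction": {"controls": ctrl_str, "cases": case_str},
            "panel": panel.formatted(),
            "provenance": {
                "seed": config.seed,
                "config_hash": config.config_hash(),
                "urimet_version": __version__,
            },
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))
        (out / "report.txt").write_text(_format_report_text(report))
        with open(out / "config_resolved.yaml", "w") as fh:
            yaml.safe_dump(config.resolved(), fh, sort_keys=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return out


def _format_report_text(report: dict) -> str:
    p = report["panel"]
    lines = [
        "Model fit          R2Y = {r2y:.3f}   Q2 = {q2:.3f}".format(**report),
        "Holdout prediction controls {controls}   cases {cases}".format(
            **report["prediction"]
        ),
        "Prevalence   Sens    Spec    PPV     NPV     (+)LR  (-)LR",
        f"{p['prevalence']:>10}  {p['sensitivity']:>6}  {p['specificity']:>6}  "
        f"{p['ppv']:>6}  {p['npv']:>6}  {p['plr']:>5}  {p['nlr']:>5}",
        f"seed={report['provenance']['seed']} config={report['provenance']['config_hash']}",
    ]
    return "\n".join(lines) + "\n"


def _panel_from_counts(c: dict[str, int]):
    se = Fraction(c["case_correct"], c["case_total"])
    sp = Fraction(c["ctrl_correct"], c["ctrl_total"])
    pr = Fraction(c["case_total"], c["case_total"] + c["ctrl_total"])
    return accuracy_panel_from_rates(float(se), float(sp), float(pr))


def verify_reference_tables() -> pd.DataFrame:
    """Recompute every published accuracy cell from the published counts.

    Returns a tidy table (model, quantity, computed, published, match);
    match compares at the published precision (half a unit in the last
    printed digit). Also includes the serum-marker sensitivity/specificity
    rates.
    """
    rows = []
    ratio_decimals = {"plr": 1, "nlr": 2}
    for name, c in REFERENCE_VALIDATION_COUNTS.items():
        panel = _panel_from_counts(c)
        published = REFERENCE_ACCURACY_TABLE[name]
        computed = {
            "prevalence": 100 * panel.prevalence,
            "sensitivity": 100 * panel.sensitivity,
            "specificity": 100 * panel.specificity,
            "ppv": 100 * panel.ppv,
            "npv": 100 * panel.npv,
            "plr": "N/A" if panel.plr is None else panel.plr,
            "nlr": panel.nlr,
        }
        for qty, pub in published.items():
            comp = computed[qty]
            if isinstance(pub, str) or isinstance(comp, str):
                match = pub == comp
            else:
                decimals = ratio_decimals.get(qty, 1)
                match = abs(round(comp, decimals) - pub) <= 0.5 * 10**-decimals + 1e-12
            rows.append(
                {
                    "model": name, "quantity": qty,
                    "computed": comp if isinstance(comp, str) else round(comp, 3),
                    "published": pub, "match": bool(match),
                }
            )
    m = REFERENCE_SERUM_MARKER
    panel = marker_panel_from_counts(
        m["pos_above"], m["pos_total"], m["neg_above"], m["neg_total"]
    )
    for qty, key in (("sensitivity", "sensitivity_pct"), ("specificity", "specificity_pct")):
        comp = float(panel[key].rstrip("%"))
        pub = m[f"published_{qty}"]
        rows.append(
            {
                "model": "Serum marker", "quantity": qty,
                "computed": comp, "published": pub,
                "match": bool(abs(comp - pub) <= 0.05 + 1e-12),
            }
        )
    return pd.DataFrame(rows)
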