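"""Synthetic urine 1H-NMR cohort simulation.

Generates seeded, fully reproducible 500 MHz one-dimensional proton
spectra with the statistical structure the downstream analysis assumes:

* each metabolite contributes first-order multiplets (Lorentzian lines)
  at its library chemical shifts;
* a TSP reference singlet sits at 0.00 ppm at a fixed concentration that
  is *not* subject to the per-subject dilution factor, so reference
  normalization is genuinely exercised;
* a broad Gaussian residual-water hump is centered at 4.9 ppm inside the
  4.6-5.2 ppm region that preprocessing excludes;
* per-subject urinary dilution is a single multiplicative log-normal
  factor applied to all metabolite signals;
* case spectra shift each marker's mean concentration by the configured
  fold change in the direction of its signature (up = multiplied,
  down = divided).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .signatures import MetaboliteSignature, build_signature_library

__all__ = [
    "SimConfig",
    "CohortDesign",
    "Spectrum",
    "SpectrumSet",
    "render_multiplet",
    "simulate_spectrum",
    "simulate_cohort",
    "write_spectrum_set",
    "read_spectrum_set",
]

#: TSP reference concentration (arbitrary units); fixed for every subject.
TSP_CONCENTRATION = 1.0
#: Center and width (ppm) of the residual-water hump.
WATER_CENTER_PPM = 4.9
WATER_SIGMA_PPM = 0.12


@dataclass(frozen=True)
class SimConfig:
    """Acquisition/simulation parameters for one synthetic spectrum set.

    linewidth_hz is the Lorentzian half-width at half-maximum; on a
    ``field_MHz`` spectrometer it corresponds to linewidth_hz/field_MHz
    ppm. j_hz is the scalar coupling used for all multiplet splittings.
    """

    ppm_min: float = 0.0
    ppm_max: float = 9.5
    n_points: int = 16384
    field_MHz: float = 500.0
    linewidth_hz: float = 1.0
    j_hz: float = 7.0
    noise_sd: float = 0.005
    dilution_log_sd: float = 0.3
    water_amplitude: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ppm_min < self.ppm_max:
            raise ValueError("ppm_min must be < ppm_max")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        for name in ("field_MHz", "linewidth_hz", "j_hz", "noise_sd",
                     "dilution_log_sd", "water_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.field_MHz == 0:
            raise ValueError("field_MHz must be positive")

    def axis(self) -> np.ndarray:
        """The ppm axis, ascending, n_points long."""
        return np.linspace(self.ppm_min, self.ppm_max, self.n_points)


@dataclass(frozen=True)
class CohortDesign:
    """Case/control cohort layout and effect structure.

    fold_change multiplies (direction=up) or divides (direction=down) each
    marker's mean concentration in cases. within_group_cv is the
    per-subject biological coefficient of variation applied log-normally
    to every metabolite independently.
    """

    n_control: int = 156
    n_case: int = 92
    fold_change: float = 2.0
    within_group_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_case < 0 or self.n_control + self.n_case < 1:
            raise ValueError("need n_control >= 0, n_case >= 0, total >= 1")
        if not self.fold_change > 0:
            raise ValueError("fold_change must be > 0")
        if self.within_group_cv < 0:
            raise ValueError("within_group_cv must be >= 0")


@dataclass
class Spectrum:
    """One real-valued processed spectrum: ppm axis plus intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D vectors of equal length")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")


@dataclass
class SpectrumSet:
    """A stack of spectra sharing one ppm axis.

    intensities is (n_samples, n_points); labels is 0=control / 1=case
    (or None when unlabeled)."""

    ppm: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.shape[1] != self.ppm.size:
            raise ValueError("intensities must be (n_samples, n_points)")
        if len(self.sample_ids) != self.intensities.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.size != self.intensities.shape[0]:
                raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return self.intensities.shape[0]

    def spectrum(self, i: int) -> Spectrum:
        lab = None if self.labels is None else int(self.labels[i])
        return Spectrum(self.ppm, self.intensities[i], lab)


def render_multiplet(
    center_ppm: float,
    multiplicity: str,
    rel_intensity: float,
    config: SimConfig,
) -> list[tuple[float, float]]:
    """First-order multiplet line positions and weights.

    s: one line at the center. d: two lines at center +/- J/(2*field) ppm.
    t: three lines spaced J/field ppm with 1:2:1 weights. m: a binomial
    quintet (1:4:6:4:1)/16 spaced J/field ppm, a simple symmetric stand-in
    for higher-order patterns. Weights sum to 1 before scaling by
    rel_intensity.
    """
    j_ppm = config.j_hz / config.field_MHz
    if multiplicity == "s":
        lines = [(center_ppm, 1.0)]
    elif multiplicity == "d":
        lines = [(center_ppm - j_ppm / 2, 0.5), (center_ppm + j_ppm / 2, 0.5)]
    elif multiplicity == "t":
        lines = [
            (center_ppm - j_ppm, 0.25),
            (center_ppm, 0.5),
            (center_ppm + j_ppm, 0.25),
        ]
    elif multiplicity == "m":
        weights = (1 / 16, 4 / 16, 6 / 16, 4 / 16, 1 / 16)
        lines = [(center_ppm + (k - 2) * j_ppm, w) for k, w in enumerate(weights)]
    else:
        raise ValueError(f"unknown multiplicity code {multiplicity!r}")
    return [(pos, w * rel_intensity) for pos, w in lines]


def _lorentzian(ppm: np.ndarray, center: float, hwhm_ppm: float) -> np.ndarray:
    """Unit-area Lorentzian line."""
    return (hwhm_ppm / np.pi) / ((ppm - center) ** 2 + hwhm_ppm**2)


def _render_signal(
    ppm: np.ndarray,
    signatures: list[MetaboliteSignature],
    concentrations: dict[str, float],
    config: SimConfig,
) -> np.ndarray:
    hwhm = config.linewidth_hz / config.field_MHz
    signal = np.zeros_like(ppm)
    by_name = {s.name: s for s in signatures}
    for name, conc in concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}")
        if conc == 0:
            continue
        sig = by_name.get(name)
        if sig is None:
            raise KeyError(f"no signature named {name!r}")
        for peak in sig.peaks:
            for pos, w in render_multiplet(
                peak.center_ppm, peak.multiplicity, peak.rel_intensity, config
            ):
                signal += conc * w * _lorentzian(ppm, pos, hwhm)
    return signal


def simulate_spectrum(
    concentrations: dict[str, float],
    config: SimConfig,
    signatures: list[MetaboliteSignature] | None = None,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Render one spectrum from metabolite concentrations.

    intensity = sum over lines of concentration x weight x Lorentzian,
    plus the fixed TSP singlet at 0.00 ppm, a broad Gaussian water hump at
    4.9 ppm scaled by config.water_amplitude, and white Gaussian noise of
    standard deviation config.noise_sd. Deterministic for a given seed.
    """
    if signatures is None:
        signatures = build_signature_library()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ppm = config.axis()
    hwhm = config.linewidth_hz / config.field_MHz
    intensity = _render_signal(ppm, signatures, concentrations, config)
    intensity += TSP_CONCENTRATION * _lorentzian(ppm, 0.0, hwhm)
    if config.water_amplitude > 0:
        intensity += config.water_amplitude * np.exp(
            -0.5 * ((ppm - WATER_CENTER_PPM) / WATER_SIGMA_PPM) ** 2
        )
    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd, size=ppm.size)
    return Spectrum(ppm, intensity)


def _case_mean(sig: MetaboliteSignature, fold_change: float) -> float:
    if sig.direction == "up":
        return sig.base_conc * fold_change
    if sig.direction == "down":
        return sig.base_conc / fold_change
    return sig.base_conc


def simulate_cohort(
    design: CohortDesign,
    config: SimConfig,
    signatures: list[MetaboliteSignature] | None = None,
) -> tuple[SpectrumSet, np.ndarray]:
    """Simulate a labeled case/control cohort.

    Controls draw each metabolite concentration around its signature's
    base level; cases around base x fold_change (direction up) or
    base / fold_change (direction down). A per-subject log-normal dilution
    factor multiplies all metabolite signals but not the TSP reference or
    the water hump. Labels: 0 = control, 1 = case (controls first).
    """
    if signatures is None:
        signatures = build_signature_library()
    rng = np.random.default_rng(config.seed)
    ppm = config.axis()
    # log-normal biological spread with the requested CV
    sigma_bio = float(np.sqrt(np.log1p(design.within_group_cv**2)))
    n_total = design.n_control + design.n_case
    labels = np.concatenate(
        [np.zeros(design.n_control, dtype=int), np.ones(design.n_case, dtype=int)]
    )
    intensities = np.empty((n_total, ppm.size))
    hwhm = config.linewidth_hz / config.field_MHz
    tsp = TSP_CONCENTRATION * _lorentzian(ppm, 0.0, hwhm)
    water = (
        config.water_amplitude
        * np.exp(-0.5 * ((ppm - WATER_CENTER_PPM) / WATER_SIGMA_PPM) ** 2)
        if config.water_amplitude > 0
        else 0.0
    )
    for i, lab in enumerate(labels):
        dilution = float(np.exp(rng.normal(0.0, config.dilution_log_sd)))
        conc = {}
        for sig in signatures:
            mean = _case_mean(sig, design.fold_change) if lab == 1 else sig.base_conc
            # mean-preserving log-normal subject effect
            conc[sig.name] = mean * float(
                np.exp(rng.normal(-0.5 * sigma_bio**2, sigma_bio))
            )
        signal = _render_signal(ppm, signatures, conc, config)
        intensity = dilution * signal + tsp + water
        if config.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, config.noise_sd, size=ppm.size)
        intensities[i] = intensity
    ids = [f"ctrl_{i:03d}" for i in range(design.n_control)] + [
        f"case_{i:03d}" for i in range(design.n_case)
    ]
    return SpectrumSet(ppm, intensities, ids, labels), labels


def write_spectrum_set(
    sset: SpectrumSet,
    spectra_path: str | Path,
    labels_path: str | Path | None = None,
    config: SimConfig | None = None,
    config_path: str | Path | None = None,
) -> None:
    """Write wide CSV (ppm + one column per sample), labels CSV, config YAML."""
    df = pd.DataFrame({"ppm": sset.ppm})
    for i, sid in enumerate(sset.sample_ids):
        df[sid] = sset.intensities[i]
    df.to_csv(spectra_path, index=False)
    if labels_path is not None and sset.labels is not None:
        pd.DataFrame({"sample_id": sset.sample_ids, "label": sset.labels}).to_csv(
            labels_path, index=False
        )
    if config is not None and config_path is not None:
        with open(config_path, "w") as fh:
            yaml.safe_dump(asdict(config), fh, sort_keys=False)


def read_spectrum_set(
    spectra_path: str | Path, labels_path: str | Path | None = None
) -> SpectrumSet:
    """Read the wide-CSV spectra format (first column ppm)."""
    df = pd.read_csv(spectra_path)
    ppm = df.iloc[:, 0].to_numpy(float)
    sample_ids = list(df.columns[1:])
    intensities = df.iloc[:, 1:].to_numpy(float).T
    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path).set_index("sample_id")["label"]
        labels = lab.loc[sample_ids].to_numpy(int)
    return SpectrumSet(ppm, intensities, sample_ids, labels)
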