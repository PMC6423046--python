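"""Urinary metabolite signature library.

Each signature records the 1H chemical shifts, first-order multiplicities
and relative intensities of a metabolite's resonances, together with the
direction of its concentration change in colorectal-neoplasia (CRN) urine
relative to healthy controls. The built-in library covers the eleven
discriminating urinary markers: five increased in CRN (3-aminoisobutyrate,
alanine, taurine, urea, valine) and six decreased (ascorbate, citrate,
creatinine, glycerol, hippurate, threonine).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Peak", "MetaboliteSignature", "build_signature_library"]

MULTIPLICITIES = ("s", "d", "t", "m")


@dataclass(frozen=True)
class Peak:
    """A single multiplet: chemical-shift center (ppm), multiplicity code
    (s/d/t/m) and relative intensity (> 0, arbitrary units)."""

    center_ppm: float
    multiplicity: str
    rel_intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.multiplicity not in MULTIPLICITIES:
            raise ValueError(
                f"unknown multiplicity {self.multiplicity!r}; expected one of {MULTIPLICITIES}"
            )
        if not self.rel_intensity > 0:
            raise ValueError("rel_intensity must be strictly positive")


@dataclass(frozen=True)
class MetaboliteSignature:
    """A named metabolite with its peak list and case-vs-control direction.

    direction: "up" (increased in cases), "down" (decreased in cases) or
    "flat" (no class effect). base_conc is the mean control-level
    concentration in arbitrary units.
    """

    name: str
    peaks: tuple[Peak, ...]
    direction: str = "flat"
    base_conc: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "flat"):
            raise ValueError(f"direction must be up/down/flat, got {self.direction!r}")
        if not self.peaks:
            raise ValueError("signature needs at least one peak")
        if not self.base_conc >= 0:
            raise ValueError("base_conc must be non-negative")


def _sig(name: str, direction: str, base_conc: float, *peaks: tuple) -> MetaboliteSignature:
    return MetaboliteSignature(
        name=name,
        peaks=tuple(Peak(c, m, i) for c, m, i in peaks),
        direction=direction,
        base_conc=base_conc,
    )


def build_signature_library() -> list[MetaboliteSignature]:
    """Return the 11 urinary CRN marker signatures.

    Chemical shifts and multiplicities are the published assignments for
    each marker; directions are relative to healthy controls (up =
    elevated in neoplasia). Relative intensities within a metabolite are
    uniform (1.0) — window integration downstream sums over all of a
    signature's lines, so only the total matters for level estimation.
    Base concentrations are rough urinary orders of magnitude in arbitrary
    units (creatinine and citrate dominate real urine spectra).
    """
    return [
        _sig("3-aminoisobutyrate", "up", 1.0, (1.18, "d", 1.0)),
        _sig("alanine", "up", 1.0, (1.48, "d", 1.0)),
        _sig("ascorbate", "down", 1.0, (3.75, "m", 1.0), (4.53, "m", 1.0)),
        _sig("citrate", "down", 3.0, (2.54, "d", 1.0), (2.71, "d", 1.0)),
        _sig("creatinine", "down", 5.0, (3.05, "s", 1.0), (4.07, "s", 1.0)),
        _sig("glycerol", "down", 1.5, (3.58, "m", 1.0), (3.66, "m", 1.0), (3.78, "m", 1.0)),
        _sig(
            "hippurate", "down", 2.0,
            (3.98, "d", 1.0), (7.56, "t", 1.0), (7.64, "t", 1.0), (7.83, "m", 1.0),
        ),
        _sig("taurine", "up", 1.5, (3.27, "t", 1.0), (3.45, "t", 1.0)),
        _sig("threonine", "down", 1.0, (1.31, "d", 1.0), (3.58, "d", 1.0)),
        _sig("urea", "up", 4.0, (5.80, "s", 1.0)),
        _sig("valine", "up", 1.0, (0.99, "d", 1.0)),
    ]
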