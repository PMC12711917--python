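"""Circular-dichroism processing for calmodulin secondary structure.

Calmodulin is predominantly alpha-helical in both its apo and calcium-bound
states, so structural perturbations by missense variants are read out from
two descriptors of the far-UV CD spectrum rather than a full deconvolution:

* ``theta_222/208`` — ratio of mean residue ellipticity at 222 and 208 nm,
  sensitive to helix packing and environment;
* ``delta_222/222`` — relative change in the 222 nm signal on calcium
  binding, (theta_apo - theta_Ca) / theta_apo.

Both descriptors are invariant to uniform scaling of the spectra, so the
choice of mean-residue normalization convention (number of peptide bonds,
148, vs residues, 149) does not affect them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import stats as clstats

__all__ = [
    "CDSpectrum",
    "SpectralDescriptors",
    "to_mre",
    "descriptor_ratio",
    "descriptor_delta",
    "compare_descriptors",
    "average_spectra",
    "subtract_blank",
]

N_RESIDUES = 149


@dataclass(frozen=True)
class CDSpectrum:
    wavelengths: np.ndarray   # nm, must cover 208 and 222
    theta: np.ndarray         # ellipticity (mdeg raw, or MRE after to_mre)
    condition: str = "apo"    # "apo" (EDTA) or "calcium"
    concentration: float = 20e-6   # molar
    path_cm: float = 0.1
    n_residues: int = N_RESIDUES
    units: str = "mdeg"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        th = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "theta", th)
        if wl.shape != th.shape:
            raise ValueError("wavelength and theta shapes differ")
        if not (wl.min() <= 208.0 and wl.max() >= 222.0):
            raise ValueError("spectrum must cover 208 and 222 nm")
        if self.concentration <= 0 or self.path_cm <= 0:
            raise ValueError("concentration and path length must be positive")

    def at(self, wavelength: float) -> float:
        """Ellipticity at a wavelength, linearly interpolated if needed."""
        order = np.argsort(self.wavelengths)
        return float(
            np.interp(wavelength, self.wavelengths[order], self.theta[order])
        )


@dataclass(frozen=True)
class SpectralDescriptors:
    theta_222: float
    theta_208: float
    ratio_222_208: float       # NaN when theta_208 ~ 0 (flagged undefined)
    delta222_over_222: float = math.nan


def to_mre(s: CDSpectrum, per_peptide_bond: bool = True) -> CDSpectrum:
    """Convert raw (buffer-subtracted) mdeg to mean residue ellipticity.

    theta_MRE = theta_mdeg / (10 * path_cm * conc_M * n_units), with
    n_units = n_residues - 1 peptide bonds by default (the mature protein
    lacks Met1; the alternative whole-residue convention only rescales).
    """
    if s.units == "mre":
        return s
    n_units = s.n_residues - 1 if per_peptide_bond else s.n_residues
    factor = 10.0 * s.path_cm * s.concentration * n_units
    return CDSpectrum(
        wavelengths=s.wavelengths,
        theta=s.theta / factor,
        condition=s.condition,
        concentration=s.concentration,
        path_cm=s.path_cm,
        n_residues=s.n_residues,
        units="mre",
    )


def descriptor_ratio(s: CDSpectrum, atol: float = 1e-12) -> float:
    """theta(222)/theta(208); NaN (undefined) for a near-zero denominator."""
    t222, t208 = s.at(222.0), s.at(208.0)
    scale = max(abs(s.theta).max(), 1.0)
    if abs(t208) <= atol * scale:
        return math.nan
    return t222 / t208


def descriptor_delta(apo: CDSpectrum, calcium: CDSpectrum) -> float:
    """(theta_apo(222) - theta_Ca(222)) / theta_apo(222) on matched grids."""
    if apo.wavelengths.shape != calcium.wavelengths.shape or not np.allclose(
        apo.wavelengths, calcium.wavelengths
    ):
        raise ValueError("wavelength grids differ between conditions")
    t_apo = apo.at(222.0)
    if t_apo == 0:
        raise ZeroDivisionError("apo spectrum is zero at 222 nm")
    return (t_apo - calcium.at(222.0)) / t_apo


def descriptors(apo: CDSpectrum, calcium: CDSpectrum | None = None) -> SpectralDescriptors:
    return SpectralDescriptors(
        theta_222=apo.at(222.0),
        theta_208=apo.at(208.0),
        ratio_222_208=descriptor_ratio(apo),
        delta222_over_222=(
            descriptor_delta(apo, calcium) if calcium is not None else math.nan
        ),
    )


def average_spectra(spectra: list[CDSpectrum]) -> CDSpectrum:
    """Average technical recordings (performed before buffer subtraction)."""
    first = spectra[0]
    for s in spectra[1:]:
        if not np.allclose(s.wavelengths, first.wavelengths):
            raise ValueError("technical recordings on different grids")
    theta = np.mean([s.theta for s in spectra], axis=0)
    return CDSpectrum(
        wavelengths=first.wavelengths, theta=theta, condition=first.condition,
        concentration=first.concentration, path_cm=first.path_cm,
        n_residues=first.n_residues, units=first.units,
    )


def subtract_blank(s: CDSpectrum, blank: CDSpectrum) -> CDSpectrum:
    if not np.allclose(s.wavelengths, blank.wavelengths):
        raise ValueError("blank recorded on a different grid")
    return CDSpectrum(
        wavelengths=s.wavelengths, theta=s.theta - blank.theta,
        condition=s.condition, concentration=s.concentration,
        path_cm=s.path_cm, n_residues=s.n_residues, units=s.units,
    )


def compare_descriptors(
    groups: dict[str, list[float]], wt_label: str = "WT", alpha: float = 0.05
) -> clstats.DunnettResult:
    """Dunnett many-to-one comparison of a descriptor across variants."""
    if wt_label not in groups:
        raise ValueError(f"missing WT group {wt_label!r}")
    return clstats.anova_dunnett(
        [(label, vals) for label, vals in groups.items()],
        reference=wt_label,
        alpha=alpha,
    )
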