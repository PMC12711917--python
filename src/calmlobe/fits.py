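"""Equilibrium binding-model fits for the calmodulin functional assays.

Three models are fitted:

* **Hill titration** — intrinsic phenylalanine (N-lobe) or tyrosine
  (C-lobe) fluorescence vs free Ca2+:
  ``FI = FI_span * [Ca]^h / ([Ca]^h + K_D,app^h) + FI_initial``.
* **Stoichiometric (ligand-depletion) isotherm** — anisotropy of a labeled
  Ca_V1.2 IQ-domain peptide (~20 nM) titrated with calmodulin.  Because the
  probe and K_D are comparable, the exact quadratic solution for the bound
  fraction is used rather than the hyperbolic approximation; the smaller
  quadratic root is the physical branch and keeps the bound fraction in
  [0, 1].
* **Calcium sensitivity (EC50)** — a variable-slope logistic of log10 K_D
  against log10 free Ca2+ across the eight-calcium-level affinity profile:
  ``logK_D(x) = logK_D_initial + logK_D_span / (1 + 10^((log10 EC50 - x) * slope))``.
  (The EC50 enters on the log-calcium axis; span is negative for the
  physiological affinity-increasing transition.)

All fits are bounded least squares (lmfit) with deterministic self-starts
derived from the data, and report per-parameter uncertainties plus an
explicit convergence/plausibility flag — a questionable fit is never
returned silently as a good one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np

from . import stats as clstats

__all__ = [
    "TitrationCurve",
    "HillFit",
    "IsothermSeries",
    "StoichFit",
    "AffinityProfile",
    "EC50Fit",
    "hill_model",
    "stoichiometric_bound_fraction",
    "ec50_model",
    "fit_hill",
    "fit_stoichiometric",
    "build_affinity_profile",
    "fit_ec50",
    "anisotropy_from_intensities",
    "compare_to_wt",
]

DILUTION_FACTOR = 38.0 / 68.0  # serial transfer 38 ul into 30 ul


@dataclass(frozen=True)
class TitrationCurve:
    free_ca: np.ndarray        # molar, > 0
    intensity: np.ndarray      # arbitrary units
    channel: str = "tyrosine"  # tyrosine = C-lobe, phenylalanine = N-lobe
    replicate: str = "r1"

    def __post_init__(self) -> None:
        ca = np.asarray(self.free_ca, dtype=float)
        fi = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "free_ca", ca)
        object.__setattr__(self, "intensity", fi)
        if ca.shape != fi.shape:
            raise ValueError("free_ca and intensity shapes differ")
        if np.any(ca <= 0):
            raise ValueError("free calcium must be positive")

    def valid_for_fitting(self) -> bool:
        decades = math.log10(self.free_ca.max() / self.free_ca.min())
        return self.free_ca.size >= 6 and decades >= 2.0


@dataclass(frozen=True)
class HillFit:
    kd_app: float
    h: float
    fi_span: float
    fi_initial: float
    stderr: dict = field(default_factory=dict)
    converged: bool = True
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class IsothermSeries:
    cam_total: np.ndarray   # molar titrant series
    anisotropy: np.ndarray
    iq_total: float         # molar, known probe concentration (~20 nM)
    free_ca: float          # molar, the row's clamped calcium
    replicate: str = "r1"

    def __post_init__(self) -> None:
        cam = np.asarray(self.cam_total, dtype=float)
        fa = np.asarray(self.anisotropy, dtype=float)
        object.__setattr__(self, "cam_total", cam)
        object.__setattr__(self, "anisotropy", fa)
        if cam.shape != fa.shape:
            raise ValueError("cam_total and anisotropy shapes differ")
        if np.any(cam < 0):
            raise ValueError("total calmodulin must be nonnegative")
        if self.iq_total <= 0:
            raise ValueError("iq_total must be positive")


@dataclass(frozen=True)
class StoichFit:
    kd: float
    fa_span: float
    fa_initial: float
    free_ca: float
    stderr: dict = field(default_factory=dict)
    converged: bool = True
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class AffinityProfile:
    log_free_ca: np.ndarray
    log_kd: np.ndarray
    log_kd_err: np.ndarray
    variant: str = ""
    excluded: tuple[str, ...] = ()


@dataclass(frozen=True)
class EC50Fit:
    ec50: float              # molar midpoint on the calcium axis
    slope: float
    log_kd_span: float
    log_kd_initial: float
    stderr: dict = field(default_factory=dict)
    converged: bool = True
    flags: tuple[str, ...] = ()

    @property
    def pca50(self) -> float:
        return -math.log10(self.ec50)


# ---------------------------------------------------------------------------
# model functions


def hill_model(ca, kd_app, h, fi_span, fi_initial):
    ca = np.asarray(ca, dtype=float)
    num = ca ** h
    return fi_span * num / (num + kd_app ** h) + fi_initial


def stoichiometric_bound_fraction(cam_total, kd, iq_total):
    """Exact ligand-depletion bound fraction of the IQ probe.

    Smaller root of the binding quadratic; lies in [0, min(cam, iq)/iq]
    for all nonnegative inputs.
    """
    cam = np.asarray(cam_total, dtype=float)
    q = (kd + iq_total + cam) / (2.0 * iq_total)
    disc = np.maximum(q * q - cam / iq_total, 0.0)
    return q - np.sqrt(disc)


def stoich_model(cam_total, kd, fa_span, fa_initial, iq_total):
    return fa_span * stoichiometric_bound_fraction(cam_total, kd, iq_total) + fa_initial


def ec50_model(log_ca, log10_ec50, slope, log_kd_span, log_kd_initial):
    x = np.asarray(log_ca, dtype=float)
    return log_kd_initial + log_kd_span / (1.0 + 10.0 ** ((log10_ec50 - x) * slope))


def anisotropy_from_intensities(i_par, i_perp, g: float = 0.99):
    """FA = (I_par - G*I_perp) / (I_par + 2*G*I_perp)."""
    i_par = np.asarray(i_par, dtype=float)
    i_perp = np.asarray(i_perp, dtype=float)
    denom = i_par + 2.0 * g * i_perp
    if np.any(denom <= 0):
        raise ValueError("nonpositive total intensity")
    return (i_par - g * i_perp) / denom


# ---------------------------------------------------------------------------
# fitting


def _half_signal_abscissa(x: np.ndarray, y: np.ndarray) -> float:
    """Abscissa where the signal crosses halfway between its extremes."""
    order = np.argsort(x)
    x, y = x[order], y[order]
    half = (y[0] + y[-1]) / 2.0
    sign = np.sign(y - half)
    idx = np.nonzero(np.diff(sign))[0]
    if idx.size == 0:
        return float(np.sqrt(x[0] * x[-1]))
    i = idx[0]
    # linear interpolation in log-x
    f = (half - y[i]) / (y[i + 1] - y[i]) if y[i + 1] != y[i] else 0.5
    return float(10 ** (np.log10(x[i]) + f * (np.log10(x[i + 1]) - np.log10(x[i]))))


def fit_hill(curve: TitrationCurve, start: dict | None = None) -> HillFit:
    """Least-squares Hill fit with quartile-based self-start."""
    if not curve.valid_for_fitting():
        raise ValueError("need >= 6 points spanning >= 2 decades of calcium")
    ca, fi = curve.free_ca, curve.intensity
    p = lmfit.Parameters()
    kd0 = (start or {}).get("kd_app", _half_signal_abscissa(ca, fi))
    p.add("log10_kd", value=math.log10(kd0), min=-12.0, max=0.0)
    p.add("h", value=(start or {}).get("h", 1.0), min=0.3, max=6.0)
    p.add("fi_span", value=(start or {}).get("fi_span", fi.max() - fi.min()))
    p.add("fi_initial", value=(start or {}).get("fi_initial", fi.min()))

    def resid(pars):
        return hill_model(
            ca, 10.0 ** pars["log10_kd"], pars["h"], pars["fi_span"], pars["fi_initial"]
        ) - fi

    res = lmfit.minimize(resid, p, method="leastsq")
    kd = 10.0 ** res.params["log10_kd"].value
    flags = []
    if not res.success:
        flags.append("no-convergence")
    if kd > 10.0 * ca.max() or kd < ca.min() / 10.0:
        flags.append("kd-outside-data-range")
    err = {}
    if res.params["log10_kd"].stderr is not None:
        err["kd_app"] = kd * math.log(10) * res.params["log10_kd"].stderr
        for name in ("h", "fi_span", "fi_initial"):
            err[name] = res.params[name].stderr
    return HillFit(
        kd_app=kd,
        h=res.params["h"].value,
        fi_span=res.params["fi_span"].value,
        fi_initial=res.params["fi_initial"].value,
        stderr=err,
        converged=res.success and not flags,
        flags=tuple(flags),
    )


def fit_stoichiometric(
    iso: IsothermSeries, start: dict | None = None, fit_iq: bool = False
) -> StoichFit:
    """Fit the exact quadratic isotherm; IQ_total fixed unless ``fit_iq``."""
    cam, fa = iso.cam_total, iso.anisotropy
    p = lmfit.Parameters()
    kd0 = (start or {}).get("kd", _half_signal_abscissa(cam[cam > 0], fa[cam > 0]))
    p.add("log10_kd", value=math.log10(max(kd0, 1e-13)), min=-13.0, max=-2.0)
    p.add("fa_span", value=(start or {}).get("fa_span", fa.max() - fa.min()))
    p.add("fa_initial", value=(start or {}).get("fa_initial", fa.min()))
    if fit_iq:
        p.add("iq_total", value=iso.iq_total, min=iso.iq_total / 10, max=iso.iq_total * 10)

    def resid(pars):
        iq = pars["iq_total"].value if fit_iq else iso.iq_total
        return stoich_model(
            cam, 10.0 ** pars["log10_kd"], pars["fa_span"], pars["fa_initial"], iq
        ) - fa

    res = lmfit.minimize(resid, p, method="leastsq")
    kd = 10.0 ** res.params["log10_kd"].value
    flags = []
    if not res.success:
        flags.append("no-convergence")
    if res.params["log10_kd"].value <= p["log10_kd"].min + 1e-6:
        flags.append("tighter-than-resolvable-at-this-iq")
    err = {}
    if res.params["log10_kd"].stderr is not None:
        err["kd"] = kd * math.log(10) * res.params["log10_kd"].stderr
        err["log10_kd"] = res.params["log10_kd"].stderr
        for name in ("fa_span", "fa_initial"):
            err[name] = res.params[name].stderr
    return StoichFit(
        kd=kd,
        fa_span=res.params["fa_span"].value,
        fa_initial=res.params["fa_initial"].value,
        free_ca=iso.free_ca,
        stderr=err,
        converged=res.success and not flags,
        flags=tuple(flags),
    )


def build_affinity_profile(
    fits: Sequence[StoichFit], variant: str = ""
) -> AffinityProfile:
    """log10-transform per-calcium K_D fits into a calcium-affinity profile.

    Flagged (non-converged or resolution-limited) fits are excluded and
    recorded; at least four usable points are required for EC50 fitting.
    """
    usable = [f for f in fits if f.converged]
    excluded = tuple(
        f"pCa{-math.log10(f.free_ca):.2f}:{'/'.join(f.flags) or 'not-converged'}"
        for f in fits
        if not f.converged
    )
    if len(usable) < 4:
        raise ValueError(
            f"only {len(usable)} usable fits (need >= 4); excluded: {excluded}"
        )
    log_ca = np.array([math.log10(f.free_ca) for f in usable])
    log_kd = np.array([math.log10(f.kd) for f in usable])
    err = np.array([f.stderr.get("log10_kd") or np.nan for f in usable])
    order = np.argsort(log_ca)
    return AffinityProfile(
        log_free_ca=log_ca[order],
        log_kd=log_kd[order],
        log_kd_err=err[order],
        variant=variant,
        excluded=excluded,
    )


def fit_ec50(profile: AffinityProfile, start: dict | None = None) -> EC50Fit:
    """Variable-slope logistic fit of the calcium-affinity profile."""
    x, y = profile.log_free_ca, profile.log_kd
    if x.size < 4:
        raise ValueError("need >= 4 profile points")
    p = lmfit.Parameters()
    p.add(
        "log10_ec50",
        value=(start or {}).get("log10_ec50", _logistic_mid_start(x, y)),
        min=x.min() - 3.0,
        max=x.max() + 3.0,
    )
    p.add("slope", value=(start or {}).get("slope", 1.0), min=0.2, max=10.0)
    p.add("log_kd_span", value=(start or {}).get("log_kd_span", y[-1] - y[0]))
    p.add("log_kd_initial", value=(start or {}).get("log_kd_initial", y[0]))

    def resid(pars):
        return ec50_model(
            x, pars["log10_ec50"], pars["slope"], pars["log_kd_span"], pars["log_kd_initial"]
        ) - y

    res = lmfit.minimize(resid, p, method="leastsq")
    mid = res.params["log10_ec50"].value
    flags = []
    if not res.success:
        flags.append("no-convergence")
    if not x.min() <= mid <= x.max():
        flags.append("midpoint-extrapolated")
    err = {
        name: res.params[name].stderr
        for name in ("log10_ec50", "slope", "log_kd_span", "log_kd_initial")
        if res.params[name].stderr is not None
    }
    return EC50Fit(
        ec50=10.0 ** mid,
        slope=res.params["slope"].value,
        log_kd_span=res.params["log_kd_span"].value,
        log_kd_initial=res.params["log_kd_initial"].value,
        stderr=err,
        converged=res.success and "no-convergence" not in flags,
        flags=tuple(flags),
    )


def _logistic_mid_start(x: np.ndarray, y: np.ndarray) -> float:
    half = (y[0] + y[-1]) / 2.0
    return float(np.interp(half, y[np.argsort(y)], x[np.argsort(y)]))


def compare_to_wt(
    fits_per_group: dict[str, Sequence[float]],
    wt_label: str = "WT",
    log_transform: bool = True,
    alpha: float = 0.05,
) -> clstats.DunnettResult:
    """Dunnett comparison of per-replicate fitted constants against WT.

    Dissociation constants / EC50 values are log10-transformed before
    testing (variance stabilization on the multiplicative scale), matching
    how the assay replicates are analyzed.  One family per calcium level:
    run this once per level.
    """
    if wt_label not in fits_per_group:
        raise ValueError(f"missing WT group {wt_label!r}")
    groups = []
    for label, values in fits_per_group.items():
        vals = np.asarray(values, dtype=float)
        if log_transform:
            if np.any(vals <= 0):
                raise ValueError(f"group {label!r} has nonpositive values")
            vals = np.log10(vals)
        groups.append((label, vals))
    return clstats.anova_dunnett(groups, reference=wt_label, alpha=alpha)
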