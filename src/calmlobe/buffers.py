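"""Dual-chelator free-calcium buffer speciation and recipe design.

Free Ca2+ in the titration assays is clamped with a dual-chelator system
(EGTA buffers the nanomolar range, NTA the micromolar-millimolar range) at
fixed free Mg2+.  With pH-apparent association constants K' the coupled
mass balances are

    Ca_tot = Ca_f * (1 + K'_CaEGTA * EGTA_f + K'_CaNTA * NTA_f)
    Mg_tot = Mg_f * (1 + K'_MgEGTA * EGTA_f + K'_MgNTA * NTA_f)
    EGTA_tot = EGTA_f * (1 + K'_CaEGTA * Ca_f + K'_MgEGTA * Mg_f)
    NTA_tot  = NTA_f  * (1 + K'_CaNTA * Ca_f + K'_MgNTA * Mg_f)

Given free metal concentrations the free chelator concentrations are
explicit, so the solver is a damped Newton iteration on the two log free
metal concentrations (positivity by construction) with residual-checked
convergence.  Recipe design inverts the speciation: it solves for the
total Ca/Mg that hit the target free concentrations, then converts totals
into volume fractions of the three stock buffers.

The apparent constants are configuration data, not physics hard-coded in
the solver: the defaults are plausible pH 7.2 values and every guarantee
made here (mass conservation, forward-inverse roundtrip) holds for any
positive constant set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BufferSystem",
    "StockSet",
    "Recipe",
    "SpeciationError",
    "InfeasibleTargetError",
    "solve_free_ions",
    "design_recipe",
]


class SpeciationError(RuntimeError):
    """Speciation solve failed to converge (diagnostics in message)."""


class InfeasibleTargetError(ValueError):
    """Requested free-ion targets lie outside the stock-mixing envelope."""


@dataclass(frozen=True)
class BufferSystem:
    """Chelator totals and pH-apparent association constants (M^-1).

    Defaults follow the assay buffer: 50 mM HEPES, 100 mM KCl, 2 mM NTA,
    0.5 mM EGTA, pH 7.2.  HEPES/KCl are inert here.
    """

    total_egta: float = 0.5e-3
    total_nta: float = 2.0e-3
    ph: float = 7.2
    k_ca_egta: float = 3.0e6
    k_mg_egta: float = 40.0
    k_ca_nta: float = 6.0e3
    k_mg_nta: float = 7.0e2
    hepes: float = 50e-3
    kcl: float = 100e-3

    def __post_init__(self) -> None:
        if min(self.k_ca_egta, self.k_mg_egta, self.k_ca_nta, self.k_mg_nta) <= 0:
            raise ValueError("association constants must be positive")
        if self.total_egta < 0 or self.total_nta < 0:
            raise ValueError("chelator totals must be nonnegative")


@dataclass(frozen=True)
class StockSet:
    """The three mixing stocks (totals at the final 1x concentration scale).

    All stocks share the chelator background, so the mixed chelator totals
    are independent of the mixing ratio; only total Ca and Mg vary.  The
    optional spiked calcium stock extends the envelope to millimolar free
    calcium.
    """

    ca_stock_total_ca: float = 3.0e-3
    mg_stock_total_mg: float = 30.0e-3
    spiked_ca_stock_total_ca: float | None = 12.5e-3

    def __post_init__(self) -> None:
        if self.ca_stock_total_ca <= 0 or self.mg_stock_total_mg <= 0:
            raise ValueError("stock concentrations must be positive")


@dataclass(frozen=True)
class Recipe:
    """Volume fractions (no-Ca, Ca, Mg stocks) and predicted speciation."""

    fraction_zero: float
    fraction_ca: float
    fraction_mg: float
    total_ca: float
    total_mg: float
    free_ca: float
    free_mg: float
    spiked: bool = False

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.fraction_zero, self.fraction_ca, self.fraction_mg)


def _free_chelators(ca_f, mg_f, sys: BufferSystem):
    egta_f = sys.total_egta / (1.0 + sys.k_ca_egta * ca_f + sys.k_mg_egta * mg_f)
    nta_f = sys.total_nta / (1.0 + sys.k_ca_nta * ca_f + sys.k_mg_nta * mg_f)
    return egta_f, nta_f


def _totals_from_free(ca_f, mg_f, sys: BufferSystem):
    egta_f, nta_f = _free_chelators(ca_f, mg_f, sys)
    ca_tot = ca_f * (1.0 + sys.k_ca_egta * egta_f + sys.k_ca_nta * nta_f)
    mg_tot = mg_f * (1.0 + sys.k_mg_egta * egta_f + sys.k_mg_nta * nta_f)
    return ca_tot, mg_tot


def solve_free_ions(
    total_ca: float,
    total_mg: float,
    system: BufferSystem,
    rtol: float = 1e-12,
    max_iter: int = 200,
) -> dict[str, float]:
    """Solve the coupled mass balances for free ion and species concentrations.

    Returns a dict with free_ca, free_mg, free_egta, free_nta and the four
    complex concentrations.  Residuals of all four mass balances are
    verified below 1e-9 relative; non-convergence raises SpeciationError.
    """
    if total_ca < 0 or total_mg < 0:
        raise ValueError("totals must be nonnegative")
    sys_ = system

    # Zero totals short-circuit the corresponding dimension.
    active = [total_ca > 0, total_mg > 0]
    x = np.log(np.array([max(total_ca, 1e-30), max(total_mg, 1e-30)]))
    targets = np.array([total_ca, total_mg])

    def residual(logx):
        ca_f, mg_f = np.exp(logx)
        if not active[0]:
            ca_f = 0.0
        if not active[1]:
            mg_f = 0.0
        ca_tot, mg_tot = _totals_from_free(ca_f, mg_f, sys_)
        return np.array([ca_tot - targets[0], mg_tot - targets[1]])

    scale = np.where(targets > 0, targets, 1.0)
    converged = False
    for _ in range(max_iter):
        r = residual(x)
        if np.all(np.abs(r) <= rtol * scale):
            converged = True
            break
        # numerical Jacobian wrt log free concentrations
        J = np.zeros((2, 2))
        h = 1e-7
        for j in range(2):
            if not active[j]:
                J[j, j] = 1.0
                continue
            xp = x.copy()
            xp[j] += h
            J[:, j] = (residual(xp) - r) / h
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError as exc:
            raise SpeciationError(f"singular Jacobian at x={x}") from exc
        step = np.clip(step, -2.0, 2.0)  # damping in log space
        # backtracking line search on the residual norm
        lam, r0 = 1.0, np.linalg.norm(r / scale)
        for _ in range(40):
            xn = x + lam * step
            if np.linalg.norm(residual(xn) / scale) < r0:
                break
            lam *= 0.5
        x = x + lam * step

    ca_f, mg_f = np.exp(x)
    if not active[0]:
        ca_f = 0.0
    if not active[1]:
        mg_f = 0.0
    if not converged:
        r = residual(x)
        if not np.all(np.abs(r) <= 1e-9 * scale):
            raise SpeciationError(
                f"no convergence: totals=({total_ca:g},{total_mg:g}), "
                f"residuals={r}, free=({ca_f:g},{mg_f:g})"
            )
    egta_f, nta_f = _free_chelators(ca_f, mg_f, sys_)
    return {
        "free_ca": float(ca_f),
        "free_mg": float(mg_f),
        "free_egta": float(egta_f),
        "free_nta": float(nta_f),
        "ca_egta": float(sys_.k_ca_egta * ca_f * egta_f),
        "mg_egta": float(sys_.k_mg_egta * mg_f * egta_f),
        "ca_nta": float(sys_.k_ca_nta * ca_f * nta_f),
        "mg_nta": float(sys_.k_mg_nta * mg_f * nta_f),
    }


def design_recipe(
    target_free_ca: float,
    target_free_mg: float,
    stocks: StockSet = StockSet(),
    system: BufferSystem = BufferSystem(),
) -> Recipe:
    """Find stock volume fractions producing the target free Ca2+ and Mg2+.

    Because the chelator background is identical in every stock, the mixed
    totals are linear in the fractions; the design therefore inverts the
    speciation analytically for the required totals and maps them onto
    fractions, preferring the plain calcium stock and falling back to the
    spiked stock when the target exceeds its envelope.
    """
    if target_free_ca < 0 or target_free_mg < 0:
        raise ValueError("targets must be nonnegative")
    total_ca, total_mg = _totals_from_free(target_free_ca, target_free_mg, system)

    spiked = False
    ca_stock = stocks.ca_stock_total_ca
    f_ca = total_ca / ca_stock if total_ca > 0 else 0.0
    f_mg = total_mg / stocks.mg_stock_total_mg if total_mg > 0 else 0.0
    if f_ca + f_mg > 1.0 and stocks.spiked_ca_stock_total_ca:
        ca_stock = stocks.spiked_ca_stock_total_ca
        f_ca = total_ca / ca_stock
        spiked = True
    if f_ca + f_mg > 1.0 or f_ca > 1.0 or f_mg > 1.0:
        env_ca = solve_free_ions(
            (1.0 - f_mg) * ca_stock if f_mg < 1 else 0.0, total_mg, system
        )["free_ca"] if f_mg < 1 else 0.0
        raise InfeasibleTargetError(
            f"free Ca {target_free_ca:g} M at free Mg {target_free_mg:g} M "
            f"needs totals Ca={total_ca:g}, Mg={total_mg:g} M exceeding the "
            f"stock envelope (max achievable free Ca ~{env_ca:g} M)"
        )

    # forward verification of the designed mixture
    sol = solve_free_ions(total_ca, total_mg, system)
    for got, want in ((sol["free_ca"], target_free_ca), (sol["free_mg"], target_free_mg)):
        if want > 0 and abs(got - want) > 1e-3 * want:
            raise SpeciationError(
                f"roundtrip mismatch: designed {want:g}, speciation gives {got:g}"
            )
    return Recipe(
        fraction_zero=1.0 - f_ca - f_mg,
        fraction_ca=f_ca,
        fraction_mg=f_mg,
        total_ca=total_ca,
        total_mg=total_mg,
        free_ca=sol["free_ca"],
        free_mg=sol["free_mg"],
        spiked=spiked,
    )


def pca(free_ca: float) -> float:
    """pCa = -log10 of free calcium (molar)."""
    if free_ca <= 0:
        raise ValueError("free calcium must be positive")
    return -math.log10(free_ca)
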