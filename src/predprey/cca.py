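"""Joint tiger-leopard analysis: multiplicative split, canonical correlation,
Wilks' test, margins and the competition gap.

Total predator biomass is split multiplicatively into a tiger effect and the
relative increase contributed by leopards,

    log(T + L) = log T + log((T + L) / T),

so the second term is the leopard component after accounting for tiger
predation (zero when there are no leopards, log 2 when the two biomasses are
equal). Canonical correlation analysis then finds the linear combination
``alpha1 * logT + alpha2 * logRatio`` maximally correlated with log prey
biomass; with a single prey variable the canonical correlation rho equals the
multiple correlation of the regression of log x on the two predator
components.

Scaling convention: the prey-side variate is taken as ``k * log x`` with
``k`` the exponent of the total-predator power law, and the predator-side
coefficients are scaled so both canonical variates have equal sample standard
deviation (sd = |k| * sd(log x), divisor n - 1). Under that matched-sd
convention the fitted relation reads

    alpha1 * logT + alpha2 * logRatio = rho * k * log x + const,

from which the margins follow: holding leopards at zero gives the tiger
margin slope ``rho * k / alpha1``; holding tigers at a reference biomass
(default 1 kg/km^2, below the smallest observed tiger biomass) gives the
leopard margin slope ``rho * k / alpha2``. The gap between a species' margin
(competitor absent) and its single-species regression (competitor present)
is read as the biomass cost of intraguild competition.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ParkYearBiomass
from .power_law import PowerLawFit, _logfn

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredatorDecomposition:
    """Per-observation multiplicative decomposition of predator biomass.

    ``log_tiger + log_ratio == log(T + L)`` holds exactly for every record,
    and ``log_ratio >= 0`` since leopard biomass is non-negative.
    """

    log_tiger: np.ndarray
    log_ratio: np.ndarray
    log_prey: np.ndarray
    parks: tuple[str, ...]
    years: tuple[int, ...]
    log_base: object = 10

    @property
    def n(self) -> int:
        return self.log_tiger.size

    @property
    def log_total(self) -> np.ndarray:
        return self.log_tiger + self.log_ratio


def decompose_predators(
    records: Sequence[ParkYearBiomass], *, log_base=10
) -> PredatorDecomposition:
    """Build the (logT, log((T+L)/T), logx) decomposition.

    Records with ``T = 0`` or ``x <= 0`` are rejected (their log is
    undefined); leopard-missing records are excluded with a warning.
    """
    logf = _logfn(log_base)
    usable = []
    for r in records:
        if r.leopard_missing:
            warnings.warn(f"record ({r.park}, {r.year}) lacks leopard biomass; "
                          "excluded from the joint analysis", stacklevel=2)
            continue
        if r.T <= 0:
            raise ValueError(
                f"record ({r.park}, {r.year}): tiger biomass is {r.T}; "
                "log T is undefined so the record cannot enter the decomposition"
            )
        if r.x <= 0:
            raise ValueError(f"record ({r.park}, {r.year}): prey biomass must be positive")
        if r.L < 0:
            raise ValueError(f"record ({r.park}, {r.year}): negative leopard biomass")
        usable.append(r)
    if not usable:
        raise ValueError("no records with both predators available")
    lt = np.array([logf(r.T) for r in usable])
    # computed as log(T+L) - log(T) so the identity holds at machine precision
    lr = np.array([logf(r.predator_total) for r in usable]) - lt
    lx = np.array([logf(r.x) for r in usable])
    return PredatorDecomposition(
        log_tiger=lt, log_ratio=lr, log_prey=lx,
        parks=tuple(r.park for r in usable), years=tuple(r.year for r in usable),
        log_base=log_base,
    )


@dataclass(frozen=True)
class CCAFit:
    """Predator-side canonical coefficients and correlation.

    ``alpha1``/``alpha2`` multiply logT and logRatio; ``rho`` is the
    canonical correlation; ``k`` the prey-side power-law exponent used for
    the matched-sd scaling. Means and the observed log-prey range are kept so
    margin lines can be anchored and extrapolation flagged.
    """

    alpha1: float
    alpha2: float
    rho: float
    k: float
    n: int
    mean_log_tiger: float
    mean_log_ratio: float
    mean_log_prey: float
    sd_log_prey: float
    log_prey_range: tuple[float, float]
    log_base: object = 10
    p: int = 2
    q: int = 1
    normalization: str = "matched-sd (predator variate sd = |k| * sd(log x))"

    @property
    def predator_variate_mean(self) -> float:
        return self.alpha1 * self.mean_log_tiger + self.alpha2 * self.mean_log_ratio

    def summary_dict(self) -> dict:
        return {
            "kind": "cca_fit",
            "alpha1": self.alpha1, "alpha2": self.alpha2, "rho": self.rho,
            "k": self.k, "n": self.n, "p": self.p, "q": self.q,
            "normalization": self.normalization, "log_base": str(self.log_base),
        }


def fit_cca(decomp: PredatorDecomposition, k: float | None = None) -> CCAFit:
    """Canonical correlation of (logT, logRatio) with log prey biomass.

    ``k`` is the total-predator power-law exponent used to scale the prey
    variate; when ``None`` it is the OLS slope of log(T+L) on log x computed
    from the decomposition itself (numerically what a vague-prior Bayesian
    fit converges to). Signs are fixed so rho >= 0 and the predator variate
    correlates positively with log prey biomass.
    """
    if decomp.n <= 3:
        raise ValueError(f"need more than 3 joint observations, got {decomp.n}")
    Z = np.column_stack([decomp.log_tiger, decomp.log_ratio])
    x = decomp.log_prey
    if np.ptp(x) == 0:
        raise ValueError("log prey biomass has zero variance")
    for j, name in enumerate(("log tiger biomass", "log predator ratio")):
        if np.ptp(Z[:, j]) == 0:
            raise ValueError(f"{name} has zero variance; the joint fit is degenerate")
    Zc = Z - Z.mean(axis=0)
    xc = x - x.mean()
    Szz = Zc.T @ Zc / (decomp.n - 1)
    szx = Zc.T @ xc / (decomp.n - 1)
    sxx = float(xc @ xc) / (decomp.n - 1)
    cond = np.linalg.cond(Szz)
    if cond > 1e10:
        raise np.linalg.LinAlgError(
            "log tiger biomass and the leopard ratio are (near-)collinear "
            f"(condition number {cond:.2e}); canonical weights are not identifiable"
        )
    w = np.linalg.solve(Szz, szx)
    r2 = float(szx @ w) / sxx
    rho = math.sqrt(min(max(r2, 0.0), 1.0))
    if k is None:
        k = float((Zc.sum(axis=1) @ xc) / (xc @ xc))  # OLS slope of log(T+L) on log x
    var_w = float(w @ Szz @ w)
    if var_w <= 0:
        raise np.linalg.LinAlgError("degenerate predator variate (zero variance)")
    alpha = w * (abs(k) * math.sqrt(sxx) / math.sqrt(var_w))
    # sign convention: predator variate positively correlated with log prey
    if float(alpha @ szx) < 0:
        alpha = -alpha
    return CCAFit(
        alpha1=float(alpha[0]), alpha2=float(alpha[1]), rho=rho, k=float(k),
        n=decomp.n,
        mean_log_tiger=float(decomp.log_tiger.mean()),
        mean_log_ratio=float(decomp.log_ratio.mean()),
        mean_log_prey=float(x.mean()),
        sd_log_prey=float(np.std(x, ddof=1)),
        log_prey_range=(float(x.min()), float(x.max())),
        log_base=decomp.log_base,
    )


@dataclass(frozen=True)
class ScaledRelationship:
    """The fitted relation alpha1*logT + alpha2*logRatio = slope*logx + intercept,
    with slope = rho * k under the matched-sd convention."""

    slope: float
    intercept: float
    cca: CCAFit

    def predict_predator_variate(self, log_prey: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(log_prey, dtype=float) + self.intercept

    def summary_dict(self) -> dict:
        return {"kind": "scaled_relationship", "slope": self.slope,
                "intercept": self.intercept, "rho": self.cca.rho, "k": self.cca.k}


def scaled_relationship(cca: CCAFit, powerfit: PowerLawFit | None = None) -> ScaledRelationship:
    """Combine the CCA with the total-predator power-law fit into the
    rho-scaled linear relation. When ``powerfit`` is given it must describe
    the same observations (same n and prey mean) and its posterior-mean ``k``
    must match the one stored in the CCA fit."""
    if powerfit is not None:
        if powerfit.n != cca.n or abs(powerfit.mean_logx - cca.mean_log_prey) > 1e-8:
            raise ValueError(
                "CCA and power-law fits describe different observation sets "
                f"(n {cca.n} vs {powerfit.n}, mean log prey "
                f"{cca.mean_log_prey:.6f} vs {powerfit.mean_logx:.6f})"
            )
    slope = cca.rho * cca.k
    intercept = cca.predator_variate_mean - slope * cca.mean_log_prey
    return ScaledRelationship(slope=slope, intercept=intercept, cca=cca)


@dataclass(frozen=True)
class WilksResult:
    """Wilks' Lambda significance test of the canonical correlation via
    Bartlett's chi-square approximation."""

    lambda_: float
    chisq: float
    df: int
    pvalue: float
    n: int
    rho: float

    def summary_dict(self) -> dict:
        return {"kind": "wilks_test", "lambda": self.lambda_, "chisq": self.chisq,
                "df": self.df, "pvalue": self.pvalue, "n": self.n, "rho": self.rho}


def wilks_test(rho: float, n: int, p: int = 2, q: int = 1) -> WilksResult:
    """Test rho = 0 with Wilks' Lambda = 1 - rho^2 (single canonical pair) and
    Bartlett's statistic chi2 = -(n - 1 - (p + q + 1)/2) * ln(Lambda) on
    p*q degrees of freedom."""
    if not (0.0 <= rho <= 1.0):
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    if n <= p + q + 1:
        raise ValueError(f"n = {n} too small for the Bartlett approximation "
                         f"(need n > p + q + 1 = {p + q + 1})")
    lam = 1.0 - rho * rho
    mult = n - 1 - (p + q + 1) / 2.0
    df = p * q
    if lam == 0.0:
        return WilksResult(0.0, math.inf, df, 0.0, n, rho)
    chisq = -mult * math.log(lam)
    return WilksResult(lam, chisq, df, float(stats.chi2.sf(chisq, df)), n, rho)


@dataclass(frozen=True)
class Margins:
    """Marginal prey-scaling slopes when one competitor is held at its minimum.

    Tiger margin: leopards absent (L = 0, logRatio = 0) — slope rho*k/alpha1.
    Leopard margin: tigers held at ``tiger_reference`` kg/km^2 — slope
    rho*k/alpha2 for log(T + L). Lines are anchored at the sample means via
    the scaled relationship's centering constant.
    """

    tiger_slope: float
    tiger_intercept: float
    leopard_slope: float
    leopard_intercept: float
    tiger_reference: float
    cca: CCAFit
    notes: tuple[str, ...] = field(default=())

    def predict_log_tiger(self, log_prey: np.ndarray) -> np.ndarray:
        """Margin line for log tiger biomass (no leopards)."""
        return self.tiger_intercept + self.tiger_slope * np.asarray(log_prey, dtype=float)

    def predict_log_total_at_reference(self, log_prey: np.ndarray) -> np.ndarray:
        """Margin line for log total biomass with T held at the reference."""
        return self.leopard_intercept + self.leopard_slope * np.asarray(log_prey, dtype=float)

    def predict_leopard_biomass(self, prey_biomass: np.ndarray) -> np.ndarray:
        """Leopard biomass (kg/km^2) along its margin: total minus the tiger
        reference, floored at zero."""
        logf = _logfn(self.cca.log_base)
        base = 10.0 if self.cca.log_base in (10, "10") else math.e
        total = base ** self.predict_log_total_at_reference(logf(np.asarray(prey_biomass, float)))
        return np.maximum(total - self.tiger_reference, 0.0)

    def predict_tiger_biomass(self, prey_biomass: np.ndarray) -> np.ndarray:
        logf = _logfn(self.cca.log_base)
        base = 10.0 if self.cca.log_base in (10, "10") else math.e
        return base ** self.predict_log_tiger(logf(np.asarray(prey_biomass, float)))

    def summary_dict(self) -> dict:
        return {
            "kind": "margins",
            "tiger_margin_slope": self.tiger_slope,
            "tiger_margin_intercept": self.tiger_intercept,
            "leopard_margin_slope": self.leopard_slope,
            "leopard_margin_intercept": self.leopard_intercept,
            "tiger_reference_kg_km2": self.tiger_reference,
            "notes": list(self.notes),
        }


def margins(
    cca: CCAFit,
    powerfit: PowerLawFit | None = None,
    tiger_reference: float = 1.0,
) -> Margins:
    """Derive the marginal slopes and anchored margin lines.

    Setting logRatio = 0 in ``alpha1 logT + alpha2 logRatio = rho k logx + c``
    gives the tiger margin ``logT = (rho k / alpha1) logx + c / alpha1``;
    setting T to the reference (so logT = log(ref)) gives the leopard margin
    for log(T + L). A zero alpha leaves the corresponding margin undefined
    (NaN, with a note) rather than raising.
    """
    if tiger_reference <= 0:
        raise ValueError("tiger_reference must be positive (kg/km^2)")
    rel = scaled_relationship(cca, powerfit)
    logf = _logfn(cca.log_base)
    log_ref = float(logf(tiger_reference))
    notes: list[str] = []
    if cca.alpha1 == 0.0:
        tiger_slope = tiger_int = math.nan
        notes.append("alpha1 = 0: tiger margin undefined")
    else:
        tiger_slope = rel.slope / cca.alpha1
        tiger_int = rel.intercept / cca.alpha1
    if cca.alpha2 == 0.0:
        leopard_slope = leopard_int = math.nan
        notes.append("alpha2 = 0: leopard margin undefined")
    else:
        leopard_slope = rel.slope / cca.alpha2
        leopard_int = (rel.intercept - cca.alpha1 * log_ref) / cca.alpha2 + log_ref
    return Margins(
        tiger_slope=float(tiger_slope), tiger_intercept=float(tiger_int),
        leopard_slope=float(leopard_slope), leopard_intercept=float(leopard_int),
        tiger_reference=tiger_reference, cca=cca, notes=tuple(notes),
    )


@dataclass(frozen=True)
class CompetitionEstimate:
    """Margin-vs-regression predictions over a prey-biomass grid.

    ``gap = margin_prediction - regression_prediction`` in kg/km^2: the
    biomass a species is predicted to forgo to its competitor at each prey
    level (the shaded region of the joint-analysis figure).
    """

    species: str
    grid: pd.DataFrame  # columns: prey_biomass, margin_pred, regression_pred, gap, extrapolated

    def summary_dict(self) -> dict:
        return {
            "kind": "competition_estimate",
            "species": self.species,
            "mean_gap_kg_km2": float(self.grid["gap"].mean()),
            "max_gap_kg_km2": float(self.grid["gap"].max()),
            "n_grid": int(len(self.grid)),
        }


def competition_gap(
    margin: Margins,
    single_fit: PowerLawFit,
    x_grid: Sequence[float],
    *,
    species: str | None = None,
) -> CompetitionEstimate:
    """Gap between a species' margin (competitor absent) and its
    single-species regression (competitor present) on the kg/km^2 scale.

    ``species`` defaults to the single fit's label ("tiger" or "leopard").
    Grid points outside the observed prey-biomass range are flagged
    ``extrapolated`` rather than dropped.
    """
    x = np.asarray(list(x_grid), dtype=float)
    if x.size == 0:
        raise ValueError("x_grid is empty")
    if np.any(x <= 0):
        raise ValueError("prey biomass grid must be strictly positive")
    species = species or single_fit.label
    if species not in ("tiger", "leopard"):
        raise ValueError(f"species must be 'tiger' or 'leopard', got {species!r}")
    logf = _logfn(margin.cca.log_base)
    base = 10.0 if margin.cca.log_base in (10, "10") else math.e
    lx = logf(x)
    if species == "tiger":
        margin_pred = margin.predict_tiger_biomass(x)
    else:
        margin_pred = margin.predict_leopard_biomass(x)
    regression_pred = base ** single_fit.predict_log(lx)
    lo, hi = margin.cca.log_prey_range
    grid = pd.DataFrame({
        "prey_biomass": x,
        "margin_pred": margin_pred,
        "regression_pred": regression_pred,
        "gap": margin_pred - regression_pred,
        "extrapolated": (lx < lo) | (lx > hi),
    })
    if grid["extrapolated"].any():
        logger.info("%d of %d grid points lie outside the observed prey range",
                    int(grid["extrapolated"].sum()), len(grid))
    return CompetitionEstimate(species=species, grid=grid)


def leopard_margin_sensitivity(
    cca: CCAFit,
    references: Sequence[float],
    prey_biomass: float,
) -> pd.DataFrame:
    """Sensitivity of the leopard margin to the tiger reference biomass.

    For each reference value, reports the margin intercept and the predicted
    leopard biomass at ``prey_biomass`` (kg/km^2). The slope rho*k/alpha2 is
    reference-independent; only the anchoring moves.
    """
    rows = []
    for ref in references:
        m = margins(cca, tiger_reference=float(ref))
        rows.append({
            "tiger_reference": float(ref),
            "leopard_margin_slope": m.leopard_slope,
            "leopard_margin_intercept": m.leopard_intercept,
            "leopard_biomass_at_x": float(m.predict_leopard_biomass(np.array([prey_biomass]))[0]),
        })
    return pd.DataFrame(rows)
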