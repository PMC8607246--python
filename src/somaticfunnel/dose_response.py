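"""DMSO normalization and four-parameter-logistic (4PL) IC50 fitting for
kinase-inhibitor viability screens.

Model, on x = log10(concentration):

    y(x) = bottom + (top - bottom) / (1 + 10^((log_ic50 - x) * hill))

so that hill < 0 gives the descending curve of an inhibitor (y ~ top at low
dose, ~ bottom at saturation) and y(log_ic50) = (top + bottom) / 2 always.
Responses are percentages of the averaged DMSO (vehicle) control.
Concentrations are treated as micromolar throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize

from .errors import SomaticFunnelError

log = logging.getLogger(__name__)


@dataclass
class DoseResponseData:
    compound: str
    concentrations: np.ndarray  # micromolar, > 0, one per well
    responses: np.ndarray       # % of DMSO control, one per well

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise SomaticFunnelError("concentrations and responses differ in length")
        if np.any(self.concentrations <= 0):
            raise SomaticFunnelError("concentrations must be strictly positive")


@dataclass
class FourPLFit:
    compound: str
    top: float
    bottom: float
    hill: float
    log_ic50: float  # log10 micromolar
    rss: float
    converged: bool

    @property
    def ic50(self) -> float:
        return float(10.0 ** self.log_ic50)

    def predict(self, concentrations) -> np.ndarray:
        x = np.log10(np.asarray(concentrations, dtype=float))
        return _four_pl(x, self.top, self.bottom, self.hill, self.log_ic50)


def _four_pl(x, top, bottom, hill, log_ic50):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - x) * hill))


def normalize_to_control(
    compound: str,
    concentrations: Sequence[float],
    raw_luminescence: Sequence[float],
    dmso_luminescence: Sequence[float],
) -> DoseResponseData:
    """Express raw luminescence as a percentage of the mean DMSO control."""
    dmso = np.asarray(dmso_luminescence, dtype=float)
    if dmso.size == 0:
        raise SomaticFunnelError("at least one DMSO control well is required")
    mean_dmso = float(dmso.mean())
    if mean_dmso <= 0:
        raise SomaticFunnelError(f"mean DMSO luminescence must be positive, got {mean_dmso}")
    responses = 100.0 * np.asarray(raw_luminescence, dtype=float) / mean_dmso
    return DoseResponseData(compound, np.asarray(concentrations, float), responses)


def normalize_plate(plate: pd.DataFrame, dmso_label: str = "DMSO") -> Tuple[DoseResponseData, ...]:
    """Normalize a long-format plate table (compound, concentration_um,
    replicate, luminescence); DMSO rows are the vehicle control."""
    dmso = plate.loc[plate["compound"] == dmso_label, "luminescence"]
    out = []
    for compound, grp in plate[plate["compound"] != dmso_label].groupby("compound", sort=True):
        out.append(
            normalize_to_control(
                str(compound),
                grp["concentration_um"].to_numpy(),
                grp["luminescence"].to_numpy(),
                dmso.to_numpy(),
            )
        )
    return tuple(out)


def fit_4pl(
    data: DoseResponseData,
    max_restarts: int = 3,
    seed: int = 0,
    weighting: str = "relative",
) -> FourPLFit:
    """Least-squares 4PL fit.

    Initialization: top = max response, bottom = min response, log_ic50 =
    median log-dose, hill = -1.  With ``weighting="relative"`` (default)
    the fit is iteratively reweighted with sigma proportional to the model
    value — the efficient estimator when well noise is multiplicative, as
    in luminescence viability readouts; ``weighting="none"`` gives ordinary
    least squares.  On failure the fit restarts from jittered initials;
    after all restarts fail the best-effort parameters are returned with
    ``converged=False``.  Dose-independent (flat) data are rejected.
    """
    if weighting not in ("relative", "none"):
        raise SomaticFunnelError(f"unknown weighting {weighting!r}")
    x = np.log10(data.concentrations)
    y = data.responses
    if np.unique(data.concentrations).size < 4:
        raise SomaticFunnelError("4PL fit needs at least 4 distinct concentrations")
    if float(np.ptp(y)) < 1e-9:
        raise SomaticFunnelError(f"{data.compound}: no dose dependence in responses")
    p0 = np.array([float(y.max()), float(y.min()), -1.0, float(np.median(x))])
    rng = np.random.default_rng(seed)
    best: Optional[Tuple[np.ndarray, float]] = None
    converged = False
    for attempt in range(1 + max_restarts):
        init = p0 if attempt == 0 else p0 * rng.normal(1.0, 0.2, size=4)
        try:
            popt, _ = curve_fit(_four_pl, x, y, p0=init, maxfev=20000)
            if weighting == "relative":
                for _ in range(3):
                    sigma = np.clip(np.abs(_four_pl(x, *popt)), 1e-3, None)
                    popt, _ = curve_fit(_four_pl, x, y, p0=popt, sigma=sigma,
                                        maxfev=20000)
                popt = _mle_polish(x, y, popt)
        except RuntimeError:
            continue
        rss = float(np.sum((y - _four_pl(x, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
        converged = True
        if attempt == 0:
            break
    if best is None:
        log.warning("%s: 4PL fit did not converge; returning initial guess", data.compound)
        rss = float(np.sum((y - _four_pl(x, *p0)) ** 2))
        best = (p0, rss)
    popt, rss = best
    top, bottom, hill, log_ic50 = (float(v) for v in popt)
    return FourPLFit(
        compound=data.compound, top=top, bottom=bottom, hill=hill,
        log_ic50=log_ic50, rss=rss, converged=converged,
    )


def _mle_polish(x: np.ndarray, y: np.ndarray, p0: np.ndarray) -> np.ndarray:
    """Refine a weighted fit with the exact profile likelihood for
    multiplicative Gaussian noise, y_i ~ N(f_i, (cv * f_i)^2), whose extra
    sum-log-f term iterative reweighting omits.  Skipped when residuals are
    (numerically) zero, where that likelihood degenerates."""
    f0 = _four_pl(x, *p0)
    if np.any(f0 <= 0):
        return p0
    rel = y / f0 - 1.0
    if float(np.mean(rel * rel)) < 1e-12:
        return p0

    def nll(p):
        f = _four_pl(x, *p)
        if np.any(f <= 0):
            return 1e12
        r = y / f - 1.0
        return 0.5 * len(y) * np.log(np.mean(r * r)) + float(np.sum(np.log(f)))

    res = minimize(nll, p0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12,
                            "maxiter": 20000, "maxfev": 20000})
    return res.x if res.fun <= nll(p0) else p0


def fit_plate(plate: pd.DataFrame, dmso_label: str = "DMSO") -> pd.DataFrame:
    """Fit every compound on a long-format plate; one row per compound."""
    rows = []
    for data in normalize_plate(plate, dmso_label):
        fit = fit_4pl(data)
        rows.append({
            "compound": fit.compound, "ic50_um": fit.ic50,
            "top": fit.top, "bottom": fit.bottom, "hill": fit.hill,
            "rss": fit.rss, "converged": fit.converged,
        })
    return pd.DataFrame(rows)
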