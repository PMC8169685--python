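"""GloSensor cAMP dose-response analysis.

Luminescence readings from reporter-transfected cells are normalized per
experiment to the maximum per-dose mean, then fitted with a logistic
concentration-response model on log10 molar dose:

    agonist:    y = bottom + (top - bottom) / (1 + 10**(-(pXC50 + log10 d) * h))
    antagonist: y = bottom + (top - bottom) / (1 + 10**(+(pXC50 + log10 d) * h))

where ``pXC50 = -log10`` of the half-maximal concentration (pEC50 for an
agonist, pIC50 for an antagonist) and ``h`` is the hill slope.  The default
fit is the three-parameter model (bottom, top, pXC50) with the hill slope
fixed at 1; a variable-slope four-parameter mode is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DomainError, FitError, InsufficientSampleError

__all__ = [
    "DoseResponseCurve",
    "DoseResponseFit",
    "logistic_response",
    "normalize_luminescence",
    "fit_logistic",
    "fit_experiments",
    "summarize_pxc50",
]

_ORIENTATIONS = ("agonist", "antagonist")


@dataclass(frozen=True)
class DoseResponseCurve:
    """Generating parameters of a logistic dose-response curve."""

    bottom: float
    top: float
    pxc50: float
    hill: float = 1.0
    orientation: str = "agonist"

    def __post_init__(self) -> None:
        if self.orientation not in _ORIENTATIONS:
            raise DomainError(f"orientation must be one of {_ORIENTATIONS}")
        if self.top < self.bottom:
            raise DomainError("top must be >= bottom")
        if not np.isfinite(self.pxc50):
            raise DomainError("pXC50 must be finite")
        if self.hill <= 0:
            raise DomainError("hill slope must be > 0")


def logistic_response(
    dose_m: np.ndarray | float,
    bottom: float,
    top: float,
    pxc50: float,
    hill: float = 1.0,
    orientation: str = "agonist",
) -> np.ndarray:
    """Evaluate the logistic model at molar doses (> 0).

    At ``dose = 10**-pXC50`` the response is the midpoint ``(top+bottom)/2``;
    an agonist curve rises to ``top`` with dose, an antagonist curve falls
    to ``bottom``.
    """
    dose = np.asarray(dose_m, float)
    if np.any(dose <= 0):
        raise DomainError("doses must be positive molar concentrations")
    if orientation not in _ORIENTATIONS:
        raise DomainError(f"orientation must be one of {_ORIENTATIONS}")
    sign = -1.0 if orientation == "agonist" else 1.0
    x = sign * (pxc50 + np.log10(dose)) * hill
    return bottom + (top - bottom) / (1.0 + np.power(10.0, x))


def normalize_luminescence(
    readings: pd.DataFrame,
    *,
    value_col: str = "luminescence",
    dose_col: str = "dose_M",
    experiment_col: str = "experiment",
) -> pd.DataFrame:
    """Normalize raw luminescence to the maximum per-dose mean per experiment.

    Within each experiment the per-dose means are computed and every reading
    is divided by the largest of them, so the strongest dose level has mean
    exactly 1.  The operation is idempotent.
    """
    for col in (value_col, dose_col, experiment_col):
        if col not in readings.columns:
            raise DomainError(f"missing column {col!r}")
    if not len(readings):
        raise InsufficientSampleError("no readings to normalize")
    out = readings.copy()
    dose_means = out.groupby([experiment_col, dose_col], observed=True)[value_col].transform("mean")
    max_mean = (
        out.assign(_m=dose_means)
        .groupby(experiment_col, observed=True)["_m"]
        .transform("max")
    )
    if (max_mean <= 0).any():
        bad = out.loc[max_mean <= 0, experiment_col].iloc[0]
        raise DomainError(
            f"experiment {bad!r} has non-positive maximum per-dose mean"
        )
    out["normalized"] = out[value_col] / max_mean
    return out


@dataclass
class DoseResponseFit:
    """Fitted logistic parameters with asymptotic standard errors."""

    orientation: str
    bottom: float
    top: float
    pxc50: float
    hill: float
    se: dict[str, float]
    rss: float
    n: int
    hill_mode: str
    converged: bool = True
    info: dict = field(default_factory=dict)

    def predict(self, dose_m) -> np.ndarray:
        return logistic_response(
            dose_m, self.bottom, self.top, self.pxc50, self.hill, self.orientation
        )

    def to_dict(self) -> dict:
        d = {
            "orientation": self.orientation,
            "bottom": self.bottom,
            "top": self.top,
            "pxc50": self.pxc50,
            "hill": self.hill,
            "rss": self.rss,
            "n": self.n,
            "hill_mode": self.hill_mode,
            "converged": self.converged,
        }
        d.update({f"se_{k}": v for k, v in self.se.items()})
        return d


def _initial_guess(log_dose: np.ndarray, resp: np.ndarray, orientation: str):
    """Fixed starting heuristics: asymptotes from the extreme per-dose means,
    pXC50 from the dose nearest half-maximum."""
    means = pd.Series(resp).groupby(pd.Series(log_dose)).mean()
    bottom0, top0 = float(means.min()), float(means.max())
    half = 0.5 * (bottom0 + top0)
    nearest = (means - half).abs().idxmin()
    return bottom0, top0, float(-nearest)


def fit_logistic(
    doses_m: np.ndarray,
    responses: np.ndarray,
    orientation: str = "agonist",
    hill_mode: str = "fixed",
) -> DoseResponseFit:
    """Least-squares logistic fit on log10 dose.

    ``hill_mode="fixed"`` fits the three-parameter model (bottom, top,
    pXC50) with hill slope 1; ``hill_mode="fitted"`` adds a variable slope.
    Doses are molar and must include at least four distinct levels.
    """
    if orientation not in _ORIENTATIONS:
        raise DomainError(f"orientation must be one of {_ORIENTATIONS}")
    if hill_mode not in ("fixed", "fitted"):
        raise DomainError("hill_mode must be 'fixed' or 'fitted'")
    doses = np.asarray(doses_m, float)
    resp = np.asarray(responses, float)
    if doses.shape != resp.shape:
        raise DomainError("doses and responses must have the same shape")
    if np.any(doses <= 0):
        raise DomainError("doses must be positive molar concentrations")
    n_distinct = np.unique(doses).size
    if n_distinct < 4:
        raise InsufficientSampleError(
            f"need >= 4 distinct doses for the 3-parameter fit, got {n_distinct}"
        )
    log_dose = np.log10(doses)
    means = pd.Series(resp).groupby(pd.Series(log_dose)).mean()
    if np.ptp(means.to_numpy()) < 1e-12:
        raise FitError(
            "responses are constant across doses: top == bottom, pXC50 undefined"
        )
    # warn when the dose-mean trend contradicts the declared orientation
    rho = stats.spearmanr(means.index.to_numpy(), means.to_numpy()).statistic
    expected = 1.0 if orientation == "agonist" else -1.0
    if np.isfinite(rho) and rho * expected < -0.5:
        warnings.warn(
            f"per-dose means trend against the declared {orientation} orientation",
            stacklevel=2,
        )

    bottom0, top0, pxc500 = _initial_guess(log_dose, resp, orientation)

    if hill_mode == "fixed":
        names = ("bottom", "top", "pxc50")

        def model(x, bottom, top, pxc50):
            return logistic_response(10.0**x, bottom, top, pxc50, 1.0, orientation)

        p0 = (bottom0, top0, pxc500)
    else:
        names = ("bottom", "top", "pxc50", "hill")

        def model(x, bottom, top, pxc50, hill):
            return logistic_response(10.0**x, bottom, top, pxc50, hill, orientation)

        p0 = (bottom0, top0, pxc500, 1.0)

    rss0 = float(np.sum((model(log_dose, *p0) - resp) ** 2))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                model, log_dose, resp, p0=p0, maxfev=20000
            )
    except RuntimeError as exc:
        raise FitError(f"logistic fit did not converge: {exc}") from exc
    rss = float(np.sum((model(log_dose, *popt) - resp) ** 2))
    if rss > rss0 + 1e-9:
        raise FitError("optimizer returned a worse fit than the starting point")
    with np.errstate(invalid="ignore"):
        se_vals = np.sqrt(np.diag(pcov))
    params = dict(zip(names, (float(v) for v in popt)))
    se = dict(zip(names, (float(v) for v in se_vals)))
    if params["top"] < params["bottom"]:
        # canonicalize so the invariant top >= bottom holds
        params["bottom"], params["top"] = params["top"], params["bottom"]
        se["bottom"], se["top"] = se["top"], se["bottom"]
    return DoseResponseFit(
        orientation=orientation,
        bottom=params["bottom"],
        top=params["top"],
        pxc50=params["pxc50"],
        hill=params.get("hill", 1.0),
        se=se,
        rss=rss,
        n=int(resp.size),
        hill_mode=hill_mode,
        info={"rss_init": rss0, "p0": tuple(float(v) for v in p0)},
    )


def fit_experiments(
    readings: pd.DataFrame,
    orientation: str = "agonist",
    hill_mode: str = "fixed",
    *,
    dose_col: str = "dose_M",
    experiment_col: str = "experiment",
) -> dict[str, DoseResponseFit]:
    """Normalize and fit each experiment separately.

    Vehicle rows (dose 0) contribute only to normalization context and are
    excluded from the fit.
    """
    norm = normalize_luminescence(
        readings, dose_col=dose_col, experiment_col=experiment_col
    )
    fits: dict[str, DoseResponseFit] = {}
    for exp, grp in norm.groupby(experiment_col, observed=True):
        grp = grp[grp[dose_col] > 0]
        fits[str(exp)] = fit_logistic(
            grp[dose_col].to_numpy(),
            grp["normalized"].to_numpy(),
            orientation=orientation,
            hill_mode=hill_mode,
        )
    return fits


def summarize_pxc50(fits) -> dict[str, float]:
    """Mean, SD and s.e.m. of pXC50 across replicate experiment fits.

    The per-fit asymptotic standard errors describe within-experiment
    uncertainty; this summary describes between-experiment spread.  Both are
    reported because they answer different questions.
    """
    if isinstance(fits, dict):
        fits = list(fits.values())
    vals = np.array([f.pxc50 for f in fits], float)
    if vals.size == 0:
        raise InsufficientSampleError("no fits to summarize")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    return {
        "mean": float(vals.mean()),
        "sd": sd,
        "sem": sd / np.sqrt(vals.size) if vals.size > 1 else float("nan"),
        "n": int(vals.size),
    }
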