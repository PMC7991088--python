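"""Ratiometric titration analysis: %FRET, Boltzmann dose-response fits, selectivity.

A ratiometric CFP/YFP sensor titrated with a cyclic nucleotide is read out as
fluorescence intensities at 485 nm (CFP) and 527 nm (YFP). The response at
ligand concentration Cx relative to the zero-ligand baseline C0 is

    %FRET = [ (FI_527(Cx) / FI_485(Cx)) - (FI_527(C0) / FI_485(C0)) ] * 100

so the baseline point maps to 0 by construction. Plotted against
log10-concentration, %FRET follows the Boltzmann sigmoid

    y = bottom + (top - bottom) / (1 + exp((logEC50 - x) / slope_factor))

which is algebraically identical to the four-parameter Hill (log-logistic)
equation with Hill slope n_H = 1 / (slope_factor * ln 10). Both the Boltzmann
slope factor and the derived Hill slope are reported. The EC50 ratio of an
off-target to the target nucleotide quantifies selectivity (fold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TitrationPoint",
    "DoseResponseFit",
    "FitError",
    "percent_fret",
    "boltzmann",
    "fit_boltzmann",
    "fit_replicates",
    "selectivity",
    "simulate_titration",
]

LN10 = math.log(10.0)

REQUIRED_COLUMNS = ("concentration", "fi_485", "fi_527", "replicate", "nucleotide")


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or the data are degenerate."""


@dataclass(frozen=True)
class TitrationPoint:
    """One intensity reading: concentration (mol/L; 0 denotes the C0 baseline)."""

    concentration: float
    fi_485: float
    fi_527: float
    replicate_id: str = "r1"
    nucleotide: str = "cGMP"

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.fi_485 <= 0:
            raise ValueError("fi_485 must be positive (it is a denominator)")


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted Boltzmann parameters with derived quantities and standard errors.

    ``span = top - bottom`` is the maximal FRET change; ``hill_slope`` is the
    Hill coefficient implied by the slope factor.
    """

    bottom: float
    top: float
    log_ec50: float
    slope_factor: float
    r_squared: float
    standard_errors: dict
    n_points: int

    @property
    def ec50(self) -> float:
        return 10.0**self.log_ec50

    @property
    def hill_slope(self) -> float:
        return 1.0 / (self.slope_factor * LN10)

    @property
    def span(self) -> float:
        return self.top - self.bottom

    @property
    def ec50_se(self) -> float:
        """Standard error of EC50 by the delta method from se(log_ec50)."""
        return self.ec50 * LN10 * self.standard_errors["log_ec50"]

    @property
    def hill_slope_se(self) -> float:
        """Standard error of the Hill slope by the delta method from se(slope_factor)."""
        return self.standard_errors["slope_factor"] / (self.slope_factor**2 * LN10)

    def to_dict(self) -> dict:
        return {
            "bottom": self.bottom,
            "top": self.top,
            "span": self.span,
            "log_ec50": self.log_ec50,
            "ec50": self.ec50,
            "ec50_se": self.ec50_se,
            "slope_factor": self.slope_factor,
            "hill_slope": self.hill_slope,
            "hill_slope_se": self.hill_slope_se,
            "r_squared": self.r_squared,
            "standard_errors": self.standard_errors,
            "n_points": self.n_points,
        }


def percent_fret(points: pd.DataFrame | Sequence[TitrationPoint]) -> pd.DataFrame:
    """%FRET per concentration for one replicate, relative to its C0 baseline.

    Requires exactly one zero-concentration (C0) row; that row maps to
    exactly 0. Negative values are allowed (a ratio drop below baseline).

    Returns a DataFrame with ``concentration`` and ``percent_fret`` columns,
    C0 row included.
    """
    if not isinstance(points, pd.DataFrame):
        df = pd.DataFrame(
            {
                "concentration": [p.concentration for p in points],
                "fi_485": [p.fi_485 for p in points],
                "fi_527": [p.fi_527 for p in points],
            }
        )
    else:
        df = points
    for col in ("concentration", "fi_485", "fi_527"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    if (df["fi_485"] <= 0).any():
        raise ValueError("fi_485 must be positive for all points (ratio denominator)")
    c0 = df[df["concentration"] == 0]
    if len(c0) != 1:
        raise ValueError(
            f"exactly one C0 (zero-concentration) point required, found {len(c0)}"
        )
    r0 = float(c0["fi_527"].iloc[0] / c0["fi_485"].iloc[0])
    ratio = df["fi_527"] / df["fi_485"]
    return pd.DataFrame(
        {
            "concentration": df["concentration"].to_numpy(dtype=float),
            "percent_fret": (ratio - r0).to_numpy(dtype=float) * 100.0,
        }
    )


def boltzmann(x, bottom, top, log_ec50, slope_factor):
    """Boltzmann sigmoid on a log10-concentration axis."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + np.exp((log_ec50 - x) / slope_factor))


def fit_boltzmann(
    x: np.ndarray,
    y: np.ndarray,
    weights: Optional[np.ndarray] = None,
    fix_bottom: Optional[float] = None,
    max_restarts: int = 10,
    restart_seed: int = 0,
) -> DoseResponseFit:
    """Least-squares Boltzmann fit of %FRET vs. log10 concentration.

    Initialization: bottom/top from the y extrema, logEC50 from linear
    interpolation of the mid-response crossing, slope factor 0.5. On
    non-convergence the start is jittered up to ``max_restarts`` times before
    a :class:`FitError` is raised. ``fix_bottom`` constrains the lower
    asymptote (e.g. 0 for a baseline-anchored fit). Unweighted by default.

    C0 (zero concentration) has no log coordinate and must be excluded by the
    caller before fitting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(np.unique(x)) < (4 if fix_bottom is None else 3) + 1:
        raise FitError("need at least one more distinct concentration than parameters")
    if np.ptp(y) == 0 or np.var(y) == 0:
        raise FitError("degenerate response: y has zero variance")

    y_lo, y_hi = float(y.min()), float(y.max())
    mid = 0.5 * (y_lo + y_hi)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    # first crossing of the mid-response, linearly interpolated
    log_ec50_0 = float(np.interp(mid, ys, xs)) if np.all(np.diff(ys) >= 0) else float(
        xs[np.argmin(np.abs(ys - mid))]
    )
    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        sigma = 1.0 / np.sqrt(w)

    if fix_bottom is None:
        p0 = np.array([y_lo, y_hi, log_ec50_0, 0.5])

        def model(xv, b, t, l50, sf):
            return boltzmann(xv, b, t, l50, sf)

        names = ["bottom", "top", "log_ec50", "slope_factor"]
    else:
        p0 = np.array([y_hi, log_ec50_0, 0.5])

        def model(xv, t, l50, sf):
            return boltzmann(xv, fix_bottom, t, l50, sf)

        names = ["top", "log_ec50", "slope_factor"]

    rng = np.random.default_rng(restart_seed)
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        start = p0 if attempt == 0 else p0 * (1 + 0.2 * rng.standard_normal(len(p0))) + 0.1 * rng.standard_normal(len(p0))
        try:
            popt, pcov = curve_fit(
                model, x, y, p0=start, sigma=sigma, maxfev=20000, absolute_sigma=False
            )
            if not np.all(np.isfinite(popt)):
                raise RuntimeError("non-finite parameter estimate")
            break
        except Exception as err:  # noqa: BLE001 - restart on any fit failure
            last_err = err
    else:
        raise FitError(
            f"Boltzmann fit failed after {max_restarts} restarts: {last_err}"
        )

    resid = y - model(x, *popt)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    perr = np.sqrt(np.diag(pcov))
    se = dict(zip(names, (float(v) for v in perr)))
    if fix_bottom is None:
        bottom, top, log_ec50, sf = (float(v) for v in popt)
    else:
        bottom = float(fix_bottom)
        top, log_ec50, sf = (float(v) for v in popt)
        se = {"bottom": 0.0, **se}
    if sf <= 0:
        # a negative slope factor means the sigmoid was fit upside down;
        # flip to the equivalent increasing parameterization
        bottom, top, sf = top, bottom, -sf
        se["bottom"], se["top"] = se.get("top", 0.0), se.get("bottom", 0.0)
    return DoseResponseFit(
        bottom=bottom,
        top=top,
        log_ec50=log_ec50,
        slope_factor=sf,
        r_squared=r2,
        standard_errors=se,
        n_points=len(x),
    )


def fit_replicates(
    table: pd.DataFrame,
    nucleotide: Optional[str] = None,
    fix_bottom: Optional[float] = None,
) -> tuple[list[DoseResponseFit], dict]:
    """Fit each replicate of a titration table independently and aggregate.

    The table uses the raw-intensity schema (``concentration``, ``fi_485``,
    ``fi_527``, ``replicate``, ``nucleotide``). Each replicate is converted to
    %FRET against its own C0 baseline and fitted separately; the aggregate
    reports mean and s.d. of EC50, Hill slope and span across replicates,
    mirroring the convention of independent titration experiments.
    """
    df = table
    for col in REQUIRED_COLUMNS[:4]:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    if nucleotide is not None:
        if "nucleotide" not in df.columns:
            raise ValueError("missing column 'nucleotide'")
        df = df[df["nucleotide"] == nucleotide]
        if df.empty:
            raise ValueError(f"no rows for nucleotide {nucleotide!r}")
    fits = []
    for _, sub in df.groupby("replicate", sort=True):
        pf = percent_fret(sub)
        mask = pf["concentration"] > 0
        x = np.log10(pf.loc[mask, "concentration"].to_numpy())
        y = pf.loc[mask, "percent_fret"].to_numpy()
        fits.append(fit_boltzmann(x, y, fix_bottom=fix_bottom))
    ec50s = np.array([f.ec50 for f in fits])
    hills = np.array([f.hill_slope for f in fits])
    spans = np.array([f.span for f in fits])
    r2s = np.array([f.r_squared for f in fits])
    agg = {
        "n_replicates": len(fits),
        "ec50_mean": float(ec50s.mean()),
        "ec50_sd": float(ec50s.std(ddof=1)) if len(fits) > 1 else 0.0,
        "hill_slope_mean": float(hills.mean()),
        "hill_slope_sd": float(hills.std(ddof=1)) if len(fits) > 1 else 0.0,
        "span_mean": float(spans.mean()),
        "span_sd": float(spans.std(ddof=1)) if len(fits) > 1 else 0.0,
        "r_squared_min": float(r2s.min()),
    }
    return fits, agg


def selectivity(fit_target: DoseResponseFit, fit_offtarget: DoseResponseFit) -> float:
    """Fold selectivity: EC50(off-target) / EC50(target). >1 favours the target."""
    if fit_target.ec50 <= 0 or fit_offtarget.ec50 <= 0:
        raise ValueError("EC50 values must be positive")
    return fit_offtarget.ec50 / fit_target.ec50


def simulate_titration(
    bottom: float = 0.0,
    top: float = 26.0,
    ec50_m: float = 277e-9,
    hill_slope: float = 1.5,
    concentrations_m: Optional[np.ndarray] = None,
    noise_sd: float = 1.0,
    n_replicates: int = 3,
    seed: int = 0,
    nucleotide: str = "cGMP",
    fi_485: float = 100.0,
    baseline_ratio: float = 1.0,
) -> pd.DataFrame:
    """Synthetic ratiometric titration table with a known dose-response truth.

    Defaults emulate a high-affinity cGMP response: 26 %FRET span, EC50
    277 nM, Hill slope 1.5, and Gaussian noise of 1 %FRET on each reading.
    Intensities are emitted so that :func:`percent_fret` inverts them exactly
    in the noiseless case: the 485 nm channel is held at a fixed reference
    value and the 527 nm channel is solved from the target %FRET. Each
    replicate includes one exact C0 (zero-concentration) baseline row.

    Concentrations default to half-log spacing over 1e-10..1e-2 M.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if concentrations_m is None:
        concentrations_m = 10.0 ** np.arange(-10.0, -1.9, 0.5)
    conc = np.asarray(concentrations_m, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive (C0 is added automatically)")
    slope_factor = 1.0 / (hill_slope * LN10)
    x = np.log10(conc)
    y_true = boltzmann(x, bottom, top, math.log10(ec50_m), slope_factor)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        rid = f"r{rep}"
        rows.append(
            {
                "concentration": 0.0,
                "fi_485": fi_485,
                "fi_527": baseline_ratio * fi_485,
                "replicate": rid,
                "nucleotide": nucleotide,
            }
        )
        y = y_true + (rng.standard_normal(len(conc)) * noise_sd if noise_sd > 0 else 0.0)
        fi_527 = (y / 100.0 + baseline_ratio) * fi_485
        for c, f527 in zip(conc, fi_527):
            rows.append(
                {
                    "concentration": float(c),
                    "fi_485": fi_485,
                    "fi_527": float(f527),
                    "replicate": rid,
                    "nucleotide": nucleotide,
                }
            )
    return pd.DataFrame(rows)
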