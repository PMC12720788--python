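"""One-exponential uptake-curve fitting and EX2 interpretation.

Peptide-level deuterium uptake under EX2 exchange with a dominant rate is
well described by D(t) = A (1 - exp(-k t)) with plateau A and observed
rate k_HDX.  Fits are bounded nonlinear least squares on the individual
replicate points; the fitted rate is reported in s^-1 and min^-1 and can
be inverted to an opening equilibrium constant K_op = k_HDX / k_int when
EX2 holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd

from .io import Peptide, ProteinState

__all__ = [
    "ExpFit",
    "Kop",
    "fit_one_exponential",
    "fit_uptake_curves",
    "kop_from_ex2",
    "rate_class",
    "compare_fits",
    "RATE_CLASS_THRESHOLDS",
]

K_BOUNDS = (1e-6, 10.0)  # s^-1 search window for the observed rate

#: Rate-regime boundaries in min^-1: fast >= 10, slow < 0.05,
#: intermediate in between.  A reporting convention, configurable per call.
RATE_CLASS_THRESHOLDS = {"fast": 10.0, "slow": 0.05}


@dataclass(frozen=True)
class ExpFit:
    """Fitted one-exponential uptake parameters.

    ``amplitude`` is the plateau (same units as the fitted uptake,
    typically relative %); ``k_hdx`` the observed exchange rate in s^-1
    (``k_hdx_per_min`` = 60 x ``k_hdx``); ``se_k`` its approximate
    standard error; ``sse`` the residual sum of squares.
    """

    amplitude: float
    k_hdx: float
    sse: float
    se_k: float
    converged: bool
    n_points: int

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.k_hdx < 0:
            raise ValueError("amplitude and k_hdx must be >= 0")

    @property
    def k_hdx_per_min(self) -> float:
        return 60.0 * self.k_hdx


@dataclass(frozen=True)
class Kop:
    """Opening equilibrium constant K_op = k_open / k_close (dimensionless);
    the protection factor is its reciprocal."""

    value: float

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("K_op must be positive")

    @property
    def protection_factor(self) -> float:
        return 1.0 / self.value


def _model(t, amplitude, rate):
    return amplitude * -np.expm1(-rate * t)


def fit_one_exponential(times, uptake) -> ExpFit:
    """Bounded least-squares fit of D(t) = A (1 - exp(-k t)).

    ``times``/``uptake`` are paired arrays; replicates enter as individual
    points with uniform weights, and t = 0 points act as exact anchors
    (the model passes through zero by construction).  Requires at least 3
    distinct non-zero timepoints and a non-zero signal.  Initialisation:
    A0 = max observed uptake, k0 = ln 2 / (earliest time reaching A0 / 2,
    else the median non-zero time); k is constrained to
    [1e-6, 10] s^-1 and A to (0, 1.2 x max uptake].
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(uptake, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and uptake must have matching shapes")
    if not (np.isfinite(t).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in the uptake curve")
    nonzero = np.unique(t[t > 0])
    if nonzero.size < 3:
        raise ValueError(
            f"need >= 3 distinct non-zero timepoints, got {nonzero.size}"
        )
    ymax = float(y.max())
    if ymax <= 0:
        raise ValueError("all-zero uptake curve: no exchange signal to fit")

    half_times = np.sort(t[(t > 0) & (y >= 0.5 * ymax)])
    t_half = float(half_times[0]) if half_times.size else float(np.median(nonzero))
    k0 = float(np.clip(np.log(2.0) / t_half, *K_BOUNDS))

    model = lmfit.Model(_model)
    params = model.make_params(
        amplitude={"value": ymax, "min": 1e-12, "max": 1.2 * ymax},
        rate={"value": k0, "min": K_BOUNDS[0], "max": K_BOUNDS[1]},
    )
    result = model.fit(y, params, t=t)
    k_hat = float(result.params["rate"].value)
    a_hat = float(result.params["amplitude"].value)
    se = result.params["rate"].stderr
    at_bounds = (
        k_hat <= K_BOUNDS[0] * (1 + 1e-6)
        or k_hat >= K_BOUNDS[1] * (1 - 1e-6)
        or a_hat >= 1.2 * ymax * (1 - 1e-9)
    )
    return ExpFit(
        amplitude=a_hat,
        k_hdx=k_hat,
        sse=float(np.sum(result.residual**2)),
        se_k=float(se) if se is not None else float("nan"),
        converged=bool(result.success) and not at_bounds,
        n_points=int(t.size),
    )


def fit_uptake_curves(
    records: pd.DataFrame,
    state: ProteinState | None = None,
    peptide: Peptide | tuple[int, int] | None = None,
    column: str = "relative_uptake_pct",
) -> pd.DataFrame:
    """Fit every (peptide, state) uptake curve in a canonical table.

    Returns one row per curve with the fitted plateau, rate in both s^-1
    and min^-1, standard error, SSE, convergence flag and rate class.
    """
    df = records
    if state is not None:
        ligand = state.ligand if state.ligand else "apo"
        df = df[(df["variant"] == state.variant) & (df["ligand"] == ligand)]
    if peptide is not None:
        start, end = (
            (peptide.start, peptide.end)
            if isinstance(peptide, Peptide)
            else peptide
        )
        df = df[(df["start"] == start) & (df["end"] == end)]
    if df.empty:
        raise ValueError("no records match the requested peptide/state")
    rows = []
    for (start, end, variant, ligand), grp in df.groupby(
        ["start", "end", "variant", "ligand"], sort=True
    ):
        fit = fit_one_exponential(grp["exposure_s"], grp[column])
        rows.append(
            {
                "start": start,
                "end": end,
                "variant": variant,
                "ligand": ligand,
                "amplitude": fit.amplitude,
                "k_hdx_s": fit.k_hdx,
                "k_hdx_min": fit.k_hdx_per_min,
                "se_k": fit.se_k,
                "sse": fit.sse,
                "converged": fit.converged,
                "rate_class": rate_class(fit.k_hdx_per_min),
            }
        )
    return pd.DataFrame(rows)


def kop_from_ex2(k_hdx: float, k_int: float) -> Kop:
    """Opening equilibrium constant from an observed EX2 rate:
    K_op = k_HDX / k_int.

    Valid only in the EX2 regime (asserted by the caller); an observed
    rate above the intrinsic rate is impossible for a protected amide and
    is rejected as a regime violation.
    """
    if k_int <= 0:
        raise ValueError("k_int must be positive")
    if k_hdx > k_int:
        raise ValueError(
            f"k_hdx {k_hdx:g} exceeds k_int {k_int:g}: K_op would exceed 1, "
            "inconsistent with EX2 on a protected amide"
        )
    if k_hdx <= 0:
        raise ValueError("k_hdx must be positive")
    return Kop(value=k_hdx / k_int)


def rate_class(
    k_hdx_per_min: float, thresholds: dict[str, float] | None = None
) -> str:
    """Classify an observed rate (min^-1) as fast / intermediate / slow."""
    if k_hdx_per_min < 0:
        raise ValueError("rate must be >= 0")
    th = RATE_CLASS_THRESHOLDS if thresholds is None else thresholds
    if k_hdx_per_min >= th["fast"]:
        return "fast"
    if k_hdx_per_min < th["slow"]:
        return "slow"
    return "intermediate"


def compare_fits(fit_a: ExpFit, fit_b: ExpFit) -> dict:
    """Rate ratio k_B / k_A with propagated standard error and a
    qualitative verdict.

    The relative errors add in quadrature; the verdict is ``distinct``
    when the +/- 2 SE interval around the ratio excludes 1.
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("compare_fits requires two converged fits")
    ratio = fit_b.k_hdx / fit_a.k_hdx
    rel_a = fit_a.se_k / fit_a.k_hdx if np.isfinite(fit_a.se_k) else np.nan
    rel_b = fit_b.se_k / fit_b.k_hdx if np.isfinite(fit_b.se_k) else np.nan
    se_ratio = ratio * float(np.hypot(rel_a, rel_b))
    distinct = bool(
        np.isfinite(se_ratio)
        and (ratio - 2.0 * se_ratio > 1.0 or ratio + 2.0 * se_ratio < 1.0)
    )
    return {"ratio": ratio, "se_ratio": se_ratio, "distinct": distinct}
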