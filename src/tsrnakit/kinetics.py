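"""Helicase unwinding and binding kinetics.

Single-turnover duplex-separation time courses follow the integrated rate
law of a homogeneous first-order reaction,

    Frac_ss(t) = A * (1 - exp(-k * t)),

where ``k`` (min^-1) is the observed unwinding rate constant and ``A`` the
plateau fraction of duplexes separated.  Equilibrium binding (EMSA fraction
shifted vs protein concentration) follows the one-site specific binding
isotherm,

    B([P]) = Bmax * [P] / (Kd + [P]).

Both are fitted by nonlinear least squares (scipy's trust-region reflective
under parameter bounds) with asymptotic standard errors from the covariance
of the fit.  Initialisation: A0 = max observed fraction; k0 from log-linear
regression of -ln(1 - Frac/A0) on t over the early points.  Technical
duplicates are averaged before fitting; biological replicates are pooled
(per-replicate fitting available via ``fit_unwinding`` on subsets).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class FitError(RuntimeError):
    pass


@dataclass
class UnwindingDataset:
    timepoints: np.ndarray  # minutes, strictly increasing
    frac_ss: np.ndarray  # shape (n_replicates, n_timepoints), in [0, 1]
    baseline_subtracted: bool = False

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.frac_ss = np.atleast_2d(np.asarray(self.frac_ss, dtype=float))
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.frac_ss.shape[1] != self.timepoints.size:
            raise ValueError("frac_ss columns must match timepoints")


@dataclass
class UnwindingFit:
    k_unw: float  # per minute
    amplitude: float  # plateau fraction in [0, 1]
    se_k: float
    se_amplitude: float
    rss: float
    converged: bool


@dataclass
class BindingFit:
    kd: float  # nM
    bmax: float  # fraction
    se_kd: float
    se_bmax: float
    rss: float
    converged: bool


def fraction_ss(intensity_ss: float, intensity_ds: float) -> float:
    """Fraction single-stranded from band intensities:
    I_ss / (I_ds + I_ss)."""
    if intensity_ss < 0 or intensity_ds < 0:
        raise ValueError("band intensities must be >= 0")
    total = intensity_ss + intensity_ds
    if total == 0:
        raise ValueError("both band intensities are zero")
    return intensity_ss / total


def subtract_time_zero(dataset: UnwindingDataset) -> UnwindingDataset:
    """Remove the signal already separated at t = 0 (spontaneous displacement
    baseline): frac(t) <- max(0, frac(t) - frac(0)) per replicate."""
    if dataset.timepoints[0] != 0:
        raise ValueError("baseline subtraction requires a t=0 point")
    baseline = dataset.frac_ss[:, [0]]
    adjusted = np.clip(dataset.frac_ss - baseline, 0.0, None)
    return replace(dataset, frac_ss=adjusted, baseline_subtracted=True)


def first_order_association(t: np.ndarray, amplitude: float, k: float) -> np.ndarray:
    return amplitude * (1.0 - np.exp(-k * t))


def one_site_binding(conc: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    return bmax * conc / (kd + conc)


def _initial_unwinding_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    a0 = float(np.max(y))
    a0 = min(max(a0, 1e-3), 1.5)
    # log-linearise over points well below the plateau
    with np.errstate(divide="ignore", invalid="ignore"):
        z = 1.0 - y / (a0 * 1.05)
        mask = (z > 1e-6) & (t > 0)
        if mask.sum() >= 2:
            slope = np.polyfit(t[mask], -np.log(z[mask]), 1)[0]
            k0 = float(slope) if slope > 0 else 0.1
        else:
            k0 = 0.1
    return a0, k0


def fit_unwinding(dataset: UnwindingDataset) -> UnwindingFit:
    """Pooled nonlinear least-squares fit of Frac = A(1 - e^{-kt}).

    Requires >= 3 distinct timepoints.  Non-convergence is flagged on the
    result, never silently replaced.
    """
    t = dataset.timepoints
    if t.size < 3:
        raise ValueError("need at least 3 distinct timepoints")
    t_all = np.tile(t, dataset.frac_ss.shape[0])
    y_all = dataset.frac_ss.ravel()
    a0, k0 = _initial_unwinding_guess(t, dataset.frac_ss.mean(axis=0))
    try:
        popt, pcov = curve_fit(
            first_order_association,
            t_all,
            y_all,
            p0=[a0, max(k0, 1e-3)],
            bounds=([0.0, 1e-9], [1.5, np.inf]),
            maxfev=10000,
        )
        perr = np.sqrt(np.diag(pcov))
        resid = y_all - first_order_association(t_all, *popt)
        return UnwindingFit(
            k_unw=float(popt[1]),
            amplitude=float(popt[0]),
            se_k=float(perr[1]),
            se_amplitude=float(perr[0]),
            rss=float(resid @ resid),
            converged=bool(np.all(np.isfinite(perr))),
        )
    except RuntimeError:
        return UnwindingFit(np.nan, np.nan, np.nan, np.nan, np.nan, converged=False)


def fit_binding(
    protein_conc: Sequence[float],
    fraction_bound: Sequence[float] | np.ndarray,
) -> BindingFit:
    """One-site specific binding fit, B = Bmax [P] / (Kd + [P]).

    ``fraction_bound`` may be 1-D (one curve) or (n_replicates, n_conc);
    replicates are pooled.  Bmax is softly bounded (warned above 1 via the
    flag on the dataclass consumer side, hard cap 1.5)."""
    conc = np.asarray(protein_conc, dtype=float)
    y = np.atleast_2d(np.asarray(fraction_bound, dtype=float))
    if y.shape[1] != conc.size:
        raise ValueError("fraction_bound columns must match protein_conc")
    c_all = np.tile(conc, y.shape[0])
    y_all = y.ravel()
    b0 = min(max(float(np.max(y_all)), 1e-3), 1.5)
    half = b0 / 2
    above = conc[np.mean(y, axis=0) >= half]
    kd0 = float(above[0]) if above.size else float(np.median(conc[conc > 0]))
    try:
        popt, pcov = curve_fit(
            one_site_binding,
            c_all,
            y_all,
            p0=[b0, max(kd0, 1e-6)],
            bounds=([0.0, 1e-12], [1.5, np.inf]),
            maxfev=10000,
        )
        perr = np.sqrt(np.diag(pcov))
        resid = y_all - one_site_binding(c_all, *popt)
        return BindingFit(
            kd=float(popt[1]),
            bmax=float(popt[0]),
            se_kd=float(perr[1]),
            se_bmax=float(perr[0]),
            rss=float(resid @ resid),
            converged=bool(np.all(np.isfinite(perr))),
        )
    except RuntimeError:
        return BindingFit(np.nan, np.nan, np.nan, np.nan, np.nan, converged=False)


def average_technical_duplicates(df: pd.DataFrame, value: str = "frac_ss") -> pd.DataFrame:
    """Mean over technical duplicates per (replicate, timepoint/conc) before
    fitting, matching the assay's averaging convention."""
    keys = [c for c in ("replicate", "time_min", "conc_nM") if c in df.columns]
    return df.groupby(keys, as_index=False)[value].mean()


def unwinding_dataset_from_table(df: pd.DataFrame) -> UnwindingDataset:
    """Long-format kinetic table (time_min, replicate, frac_ss) to a dataset;
    technical duplicate rows are averaged first."""
    df = average_technical_duplicates(df)
    wide = df.pivot(index="replicate", columns="time_min", values="frac_ss").sort_index(axis=1)
    return UnwindingDataset(wide.columns.to_numpy(dtype=float), wide.to_numpy())
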