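"""Isothermal titration calorimetry: thermogram integration and lipid-partition fitting.

A titration injects small aliquots of a concentrated vesicle suspension into a
dilute solute (here an alkaloid) held in the calorimeter cell.  Each injection
produces a heat pulse; the cumulative heat after *i* injections follows a
single-partition-equilibrium model,

    sum_k dh_k = dH * V_cell * C_A0 * K*C_L0 / (1 + K*C_L0)

with K the mole-fraction partition constant (L/mol), dH the molar transfer
enthalpy of the solute from water to the bilayer (cal/mol), and C_A0 / C_L0 the
total solute and lipid concentrations in the cell after the i-th injection.

Internal units: calories, mol/L, litres.  File I/O uses µcal and µL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "InjectionSchedule",
    "ITCThermogram",
    "InjectionHeats",
    "PartitionFit",
    "PartitionFitter",
    "integrate_thermogram",
    "concentrations_after_injections",
    "eval_partition_model",
    "fit_partition",
]

UL_TO_L = 1e-6
UCAL_TO_CAL = 1e-6


@dataclass(frozen=True)
class InjectionSchedule:
    """Injection programme of a titration.

    Parameters mirror the instrument method: per-injection volumes (µL),
    spacing between injections (s), cell volume (µL), syringe lipid
    concentration (mol/L) and initial cell solute concentration (mol/L).
    ``exclude_first`` drops the small priming injection from the fitted
    series while keeping it in the dilution bookkeeping.
    """

    injection_volumes: tuple[float, ...]
    spacing: float = 600.0
    cell_volume: float = 1456.5
    syringe_lipid_conc: float = 0.01
    initial_cell_solute_conc: float = 1e-5
    exclude_first: bool = True

    def __post_init__(self) -> None:
        vols = tuple(float(v) for v in self.injection_volumes)
        object.__setattr__(self, "injection_volumes", vols)
        if len(vols) < 1:
            raise ValueError("schedule needs at least one injection")
        if any(v <= 0 for v in vols):
            raise ValueError("injection volumes must be positive")
        if self.cell_volume <= max(vols):
            raise ValueError("cell volume must exceed every injection volume")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.syringe_lipid_conc <= 0 or self.initial_cell_solute_conc <= 0:
            raise ValueError("concentrations must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    @classmethod
    def vp_itc_default(cls, **kw) -> "InjectionSchedule":
        """2 µL priming injection followed by 28 × 10 µL, 600 s apart."""
        return cls(injection_volumes=(2.0,) + (10.0,) * 28, **kw)


@dataclass(frozen=True)
class ITCThermogram:
    """Raw heat-flow record: time (s), heat flow (µcal/s), cell temperature (°C)."""

    time: np.ndarray
    heat_flow: np.ndarray
    temperature: float = 26.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        hf = np.asarray(self.heat_flow, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "heat_flow", hf)
        if t.size == 0 or hf.size != t.size:
            raise ValueError("time and heat_flow must be non-empty and equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(hf))):
            raise ValueError("thermogram contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "heat_flow_ucal_per_s": self.heat_flow})

    @classmethod
    def from_csv(cls, path, temperature: float = 26.0) -> "ITCThermogram":
        df = pd.read_csv(path)
        missing = {"time_s", "heat_flow_ucal_per_s"} - set(df.columns)
        if missing:
            raise ValueError(f"thermogram CSV missing columns: {sorted(missing)}")
        return cls(df["time_s"].to_numpy(), df["heat_flow_ucal_per_s"].to_numpy(), temperature)


@dataclass
class InjectionHeats:
    """Per-injection integrated heats (µcal) with the matching concentration ladder.

    ``used`` marks injections entering the fit (the priming injection is
    excluded when the schedule says so, but still dilutes the cell).
    """

    per_injection_heat: np.ndarray
    lipid_conc_after: np.ndarray
    solute_conc_after: np.ndarray
    used: np.ndarray

    @property
    def cumulative_heat(self) -> np.ndarray:
        return np.cumsum(self.per_injection_heat)

    def fitted_series(self):
        """Fitting view of the heats: (C_L, C_A, cumulative µcal, reference).

        The cumulative sum restarts after any excluded leading injection, so
        the fitted series is the heat evolved by the analysed injections only;
        ``reference`` is the (C_A, C_L) state after the last excluded
        injection (None when nothing is excluded), at which the model must be
        re-zeroed to stay consistent with the restarted sum.
        """
        dh = np.where(self.used, self.per_injection_heat, 0.0)
        cum = np.cumsum(dh)
        m = self.used
        ref = None
        excluded = np.flatnonzero(~m)
        leading = excluded[excluded < np.argmax(m)] if m.any() else excluded
        if leading.size:
            j = leading[-1]
            ref = (self.solute_conc_after[j], self.lipid_conc_after[j])
        return self.lipid_conc_after[m], self.solute_conc_after[m], cum[m], ref

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "injection": np.arange(1, self.per_injection_heat.size + 1),
                "heat_ucal": self.per_injection_heat,
                "cumulative_ucal": self.cumulative_heat,
                "lipid_conc_M": self.lipid_conc_after,
                "solute_conc_M": self.solute_conc_after,
                "used": self.used,
            }
        )


@dataclass
class PartitionFit:
    """Result of the partition-model fit (K in L/mol, dH in cal/mol)."""

    K: float
    dH: float
    K_uncertainty: float
    dH_uncertainty: float
    residual_sum_squares: float  # µcal², on the fitted series
    converged: bool
    message: str = ""
    n_points: int = 0

    def as_dict(self) -> dict:
        return {
            "K_L_per_mol": self.K,
            "dH_cal_per_mol": self.dH,
            "K_se": self.K_uncertainty,
            "dH_se": self.dH_uncertainty,
            "rss_ucal2": self.residual_sum_squares,
            "converged": self.converged,
            "n_points": self.n_points,
            "message": self.message,
        }


def concentrations_after_injections(
    schedule: InjectionSchedule, dilution: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Total lipid and solute concentration in the cell after each injection.

    Overflow-cell model: the cell volume is fixed, each injection of volume
    v displaces a perfectly mixed aliquot, so after injection i the fraction
    of original cell content retained is f_i = prod_j (1 - v_j/V).  The lipid
    delivered from the syringe accumulates to C_L = C_syr * (1 - f_i); the
    solute is diluted to C_A = C_A(0) * f_i.  With ``dilution=False`` the
    solute concentration is held constant (no-displacement variant).
    """
    v = np.asarray(schedule.injection_volumes, dtype=float)
    V = schedule.cell_volume
    if np.any(v >= V):
        raise ValueError("injection volume must be smaller than the cell volume")
    f = np.cumprod(1.0 - v / V)
    c_lipid = schedule.syringe_lipid_conc * (1.0 - f)
    if dilution:
        c_solute = schedule.initial_cell_solute_conc * f
    else:
        c_solute = np.full_like(f, schedule.initial_cell_solute_conc)
    return c_lipid, c_solute


def _baseline(time: np.ndarray, heat_flow: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Linear baseline anchored at inter-injection plateau medians.

    For each injection window the median of the last 10 % of the window is
    taken as the plateau value (the signal has relaxed back to baseline by
    then); anchors sit at window ends and the baseline is interpolated
    linearly between them, extended flat before the first anchor.
    """
    anchors_t, anchors_v = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        tail_lo = hi - 0.10 * (hi - lo)
        m = (time >= tail_lo) & (time <= hi)
        if not np.any(m):  # very sparse sampling: fall back to the whole window
            m = (time >= lo) & (time <= hi)
        anchors_t.append(hi)
        anchors_v.append(np.median(heat_flow[m]))
    return np.interp(time, anchors_t, anchors_v)


def integrate_thermogram(
    thermogram: ITCThermogram, schedule: InjectionSchedule, dilution: bool = True
) -> InjectionHeats:
    """Integrate a raw thermogram into per-injection heats (µcal).

    Injection *i* starts at t = i * spacing and ends at the next injection;
    the heat is the trapezoidal integral of (heat flow − baseline) over the
    window.  The first injection is dropped from the fitted series when the
    schedule's ``exclude_first`` is set, but its volume still dilutes the cell.
    """
    n = schedule.n_injections
    edges = schedule.spacing * np.arange(n + 1)
    t, hf = thermogram.time, thermogram.heat_flow
    if t[0] > edges[0] or t[-1] < edges[-1] - 1e-9:
        for i in range(n):
            if t[-1] < edges[i + 1] - 1e-9:
                raise ValueError(
                    f"thermogram ends at {t[-1]:.1f} s, before the window of "
                    f"injection {i + 1} ([{edges[i]:.0f}, {edges[i + 1]:.0f}] s)"
                )
        raise ValueError("thermogram does not start at the first injection")

    corrected = hf - _baseline(t, hf, edges)
    heats = np.empty(n)
    for i in range(n):
        m = (t >= edges[i]) & (t <= edges[i + 1])
        heats[i] = np.trapezoid(corrected[m], t[m])

    c_lipid, c_solute = concentrations_after_injections(schedule, dilution=dilution)
    used = np.ones(n, dtype=bool)
    if schedule.exclude_first:
        used[0] = False
    return InjectionHeats(heats, c_lipid, c_solute, used)


def eval_partition_model(
    K: float, dH: float, cell_volume: float, C_A: np.ndarray, C_L: np.ndarray
) -> np.ndarray:
    """Predicted cumulative heat (cal): dH * V_cell * C_A * K*C_L / (1 + K*C_L).

    ``cell_volume`` in litres, concentrations in mol/L, dH in cal/mol.
    """
    if K < 0:
        raise ValueError("partition constant K must be non-negative")
    C_A = np.asarray(C_A, dtype=float)
    C_L = np.asarray(C_L, dtype=float)
    if np.any(C_A < 0) or np.any(C_L < 0):
        raise ValueError("concentrations must be non-negative")
    x = K * C_L
    return dH * cell_volume * C_A * x / (1.0 + x)


class PartitionFitter(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares estimator for the single-partition ITC model.

    fit(X, y) takes X with columns (C_A, C_L) in mol/L and y the cumulative
    heat in calories; free parameters are K (L/mol, bounded below by 0) and
    dH (cal/mol).  Asymptotic standard errors come from the Jacobian at the
    optimum.

    When the titration's first (priming) injection is excluded from the data,
    the measured cumulative series starts from zero *after* that injection;
    pass its concentration state as ``X_ref`` to fit and the model predicts
    F(i) − F(ref) instead of F(i).

    Parameters
    ----------
    cell_volume_l : cell volume in litres.
    """

    def __init__(self, cell_volume_l: float = 1.4565e-3):
        self.cell_volume_l = cell_volume_l

    def fit(self, X, y, X_ref=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X_ref is not None:
            X_ref = np.asarray(X_ref, dtype=float).reshape(2)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: (C_A, C_L)")
        if X.shape[0] != y.size:
            raise ValueError("X and y length mismatch")
        if not np.all(np.isfinite(y)):
            raise ValueError("cumulative heats must be finite")
        if y.size < 5:
            raise ValueError("need at least 5 usable injections to fit")
        C_A, C_L = X[:, 0], X[:, 1]

        self.n_points_ = int(y.size)
        scale = np.max(np.abs(y))
        if scale == 0:
            # All-zero heats: K is unidentifiable, flag instead of raising.
            self.K_, self.dH_ = np.nan, np.nan
            self.K_se_, self.dH_se_ = np.nan, np.nan
            self.rss_ = 0.0
            self.converged_ = False
            self.message_ = "non-identifiable: all cumulative heats are zero"
            return self

        def shape(K):
            # model divided by dH: the saturation profile at this K
            g = self.cell_volume_l * C_A * K * C_L / (1.0 + K * C_L)
            if X_ref is not None:
                g = g - self.cell_volume_l * X_ref[0] * K * X_ref[1] / (1.0 + K * X_ref[1])
            return g

        def profiled(logk):
            # dH enters linearly: project it out and return (RSS, dH) at this K
            g = shape(10.0**logk)
            gg = float(g @ g)
            if gg == 0:
                return float(y @ y), 0.0
            dh = float(g @ y) / gg
            r = dh * g - y
            return float(r @ r), dh

        # coarse log-K scan brackets the global minimum of the profiled RSS,
        # then Brent refines it; this sidesteps the long K*dH-degenerate
        # valley that defeats a joint 2-parameter descent at extreme K
        grid = np.linspace(-3.0, 10.0, 261)
        rss_grid = np.array([profiled(lk)[0] for lk in grid])
        i = int(np.argmin(rss_grid))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
        from scipy.optimize import minimize_scalar

        best = minimize_scalar(
            lambda lk: profiled(lk)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        k_opt = float(10.0 ** best.x)
        dh_opt = profiled(best.x)[1]

        def resid(p):
            out = eval_partition_model(p[0], p[1], self.cell_volume_l, C_A, C_L)
            if X_ref is not None:
                out = out - eval_partition_model(
                    p[0], p[1], self.cell_volume_l, X_ref[:1], X_ref[1:]
                )
            return out - y

        # polish from the projected optimum and collect the Jacobian for SEs
        sol = least_squares(
            resid,
            x0=[k_opt, dh_opt],
            bounds=([0.0, -np.inf], [np.inf, np.inf]),
            x_scale=[max(k_opt, 1e-6), max(abs(dh_opt), 1.0)],
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        self.K_, self.dH_ = float(sol.x[0]), float(sol.x[1])
        self.rss_ = float(np.sum(sol.fun**2))
        self.converged_ = bool(sol.success) and np.all(np.isfinite(sol.x))
        self.message_ = sol.message

        dof = max(y.size - 2, 1)
        s2 = self.rss_ / dof
        JTJ = sol.jac.T @ sol.jac
        try:
            cov = s2 * np.linalg.inv(JTJ)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            self.K_se_, self.dH_se_ = float(se[0]), float(se[1])
        except np.linalg.LinAlgError:
            self.K_se_ = self.dH_se_ = np.nan
            self.converged_ = False
            self.message_ = "singular Jacobian (parameters not identifiable)"
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return eval_partition_model(self.K_, self.dH_, self.cell_volume_l, X[:, 0], X[:, 1])


def fit_partition(heats: InjectionHeats, schedule: InjectionSchedule) -> PartitionFit:
    """Fit the partition model to integrated injection heats.

    Heats arrive in µcal and are converted to calories for the fit; the
    reported residual sum of squares is back in µcal².
    """
    c_lipid, c_solute, cum_ucal, ref = heats.fitted_series()
    y_cal = cum_ucal * UCAL_TO_CAL
    est = PartitionFitter(cell_volume_l=schedule.cell_volume * UL_TO_L)
    X = np.column_stack([c_solute, c_lipid])
    est.fit(X, y_cal, X_ref=ref)
    rss_ucal2 = est.rss_ / UCAL_TO_CAL**2 if np.isfinite(est.rss_) else np.nan
    return PartitionFit(
        K=est.K_,
        dH=est.dH_,
        K_uncertainty=est.K_se_,
        dH_uncertainty=est.dH_se_,
        residual_sum_squares=rss_ucal2,
        converged=est.converged_,
        message=est.message_,
        n_points=est.n_points_,
    )
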