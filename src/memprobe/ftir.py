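"""FTIR lipid thermotropics: sνCH₂ band picking and melting-temperature fits.

The symmetric methylene stretching band near 2850 cm⁻¹ shifts to higher
wavenumber as lipid acyl chains melt from the gel to the liquid-crystalline
phase.  Plotting the band maximum against temperature gives a sigmoid whose
inflection is the phase-transition temperature Tm; the shift ΔTm induced by an
additive quantifies membrane perturbation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "Spectrum",
    "MeltingCurve",
    "MeltingFit",
    "BoltzmannMelt",
    "pick_symmetric_ch2_peak",
    "melting_curve_from_spectra",
    "build_melting_curve",
    "fit_boltzmann",
    "delta_tm",
]

SYM_CH2_WINDOW = (2840.0, 2865.0)


@dataclass(frozen=True)
class Spectrum:
    """A single IR spectrum at one temperature (wavenumber in cm⁻¹)."""

    wavenumber: np.ndarray
    absorbance: np.ndarray
    temperature: float

    def __post_init__(self):
        w = np.asarray(self.wavenumber, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavenumber", w)
        object.__setattr__(self, "absorbance", a)
        if w.size < 3 or w.size != a.size:
            raise ValueError("spectrum needs >= 3 points on equal-length grids")
        d = np.diff(w)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotone")


@dataclass
class PeakPick:
    position: float  # cm⁻¹
    at_edge: bool    # maximum sits on the window edge: band may lie outside


@dataclass
class MeltingCurve:
    """(temperature, sνCH₂ peak position) points, possibly replicated."""

    temperature: np.ndarray
    peak_wavenumber: np.ndarray
    replicate_id: np.ndarray | None = None
    n_replicates: np.ndarray | None = None  # set by build_melting_curve

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.peak_wavenumber = np.asarray(self.peak_wavenumber, dtype=float)
        if self.temperature.size == 0 or self.temperature.size != self.peak_wavenumber.size:
            raise ValueError("temperature and peak_wavenumber must be equal-length, non-empty")
        if self.replicate_id is not None:
            self.replicate_id = np.asarray(self.replicate_id)

    def sorted(self) -> "MeltingCurve":
        order = np.argsort(self.temperature, kind="stable")
        return MeltingCurve(
            self.temperature[order],
            self.peak_wavenumber[order],
            None if self.replicate_id is None else self.replicate_id[order],
            None if self.n_replicates is None else self.n_replicates[order],
        )

    def to_frame(self) -> pd.DataFrame:
        d = {"temperature_C": self.temperature, "wavenumber_cm1": self.peak_wavenumber}
        if self.replicate_id is not None:
            d["replicate"] = self.replicate_id
        if self.n_replicates is not None:
            d["n_replicates"] = self.n_replicates
        return pd.DataFrame(d)

    @classmethod
    def from_csv(cls, path) -> "MeltingCurve":
        df = pd.read_csv(path)
        missing = {"temperature_C", "wavenumber_cm1"} - set(df.columns)
        if missing:
            raise ValueError(f"melting-curve CSV missing columns: {sorted(missing)}")
        rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
        return cls(df["temperature_C"].to_numpy(), df["wavenumber_cm1"].to_numpy(), rep)


@dataclass
class MeltingFit:
    """Boltzmann sigmoid parameters; Tm (°C) is the inflection point."""

    Tm: float
    width: float
    nu_gel: float
    nu_fluid: float
    Tm_uncertainty: float
    converged: bool
    message: str = ""

    def as_dict(self) -> dict:
        return {
            "Tm_C": self.Tm,
            "width_C": self.width,
            "nu_gel_cm1": self.nu_gel,
            "nu_fluid_cm1": self.nu_fluid,
            "Tm_se_C": self.Tm_uncertainty,
            "converged": self.converged,
            "message": self.message,
        }


def pick_symmetric_ch2_peak(
    spectrum: Spectrum, window: tuple[float, float] = SYM_CH2_WINDOW
) -> PeakPick:
    """Locate the sνCH₂ band maximum inside a wavenumber window.

    The discrete maximum is refined by a three-point parabola through the
    neighbouring grid points, giving sub-grid precision on the standard
    2 cm⁻¹ instrument grid.  A maximum on the window edge is flagged: the
    band may lie outside the window (or the spectrum is featureless).
    """
    lo, hi = min(window), max(window)
    if lo >= hi:
        raise ValueError("empty peak-search window")
    w, a = spectrum.wavenumber, spectrum.absorbance
    m = (w >= lo) & (w <= hi)
    if not np.any(m):
        raise ValueError(f"window [{lo}, {hi}] cm⁻¹ contains no spectral points")
    idx = np.flatnonzero(m)
    j = idx[np.argmax(a[idx])]
    at_edge = j == idx[0] or j == idx[-1]
    if at_edge:
        return PeakPick(position=float(w[j]), at_edge=True)
    # parabolic vertex through (w[j-1..j+1], a[j-1..j+1]); grid may be non-uniform
    x0, x1, x2 = w[j - 1], w[j], w[j + 1]
    y0, y1, y2 = a[j - 1], a[j], a[j + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    A = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    B = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if A == 0:  # flat triple: keep the discrete maximum
        return PeakPick(position=float(x1), at_edge=False)
    vertex = -B / (2 * A)
    # never trust a refinement that leaves the bracketing interval
    vertex = float(np.clip(vertex, min(x0, x2), max(x0, x2)))
    return PeakPick(position=vertex, at_edge=False)


def linear_baseline(spectrum: Spectrum, anchors: tuple[float, float]) -> Spectrum:
    """Subtract a two-point linear baseline through the absorbance at two anchors."""
    w, a = spectrum.wavenumber, spectrum.absorbance
    x0, x1 = anchors
    if x1 == x0:
        raise ValueError("baseline anchors must differ")
    order = np.argsort(w)
    y0 = np.interp(x0, w[order], a[order])
    y1 = np.interp(x1, w[order], a[order])
    base = y0 + (w - x0) * (y1 - y0) / (x1 - x0)
    return Spectrum(w, a - base, spectrum.temperature)


def build_melting_curve(points: MeltingCurve) -> MeltingCurve:
    """Average replicate peak positions at each temperature.

    Temperatures with fewer replicates than others are averaged over what is
    available; the per-temperature replicate count is kept alongside.
    """
    df = points.to_frame()
    g = df.groupby("temperature_C")["wavenumber_cm1"].agg(["mean", "count"]).reset_index()
    return MeltingCurve(
        g["temperature_C"].to_numpy(),
        g["mean"].to_numpy(),
        replicate_id=None,
        n_replicates=g["count"].to_numpy(),
    )


def melting_curve_from_spectra(
    manifest_path, window: tuple[float, float] = SYM_CH2_WINDOW
) -> MeltingCurve:
    """Assemble a melting curve by peak-picking one spectrum per row of a manifest.

    The manifest CSV has columns ``file`` (spectrum CSV with ``wavenumber_cm1``
    and ``absorbance``, resolved relative to the manifest), ``temperature_C``
    and ``replicate``.
    """
    import os

    manifest = pd.read_csv(manifest_path)
    missing = {"file", "temperature_C", "replicate"} - set(manifest.columns)
    if missing:
        raise ValueError(f"spectra manifest missing columns: {sorted(missing)}")
    base = os.path.dirname(os.fspath(manifest_path))
    temps, nus, reps = [], [], []
    for row in manifest.itertuples(index=False):
        df = pd.read_csv(os.path.join(base, row.file))
        spec = Spectrum(df["wavenumber_cm1"].to_numpy(), df["absorbance"].to_numpy(),
                        float(row.temperature_C))
        pick = pick_symmetric_ch2_peak(spec, window)
        if pick.at_edge:
            warnings.warn(f"{row.file}: band maximum on the window edge")
        temps.append(spec.temperature)
        nus.append(pick.position)
        reps.append(row.replicate)
    return MeltingCurve(np.array(temps), np.array(nus), np.array(reps))


def boltzmann(T, nu_gel, nu_fluid, Tm, width):
    """ν(T) = nu_fluid + (nu_gel − nu_fluid) / (1 + exp((T − Tm)/width))."""
    return nu_fluid + (nu_gel - nu_fluid) / (1.0 + np.exp((T - Tm) / width))


class BoltzmannMelt(BaseEstimator, RegressorMixin):
    """Four-parameter Boltzmann sigmoid estimator for lipid chain melting.

    fit(T, nu) estimates (nu_gel, nu_fluid, Tm, width); ``tm_`` is the
    inflection point, reported with its asymptotic standard error ``tm_se_``.
    A fitted width below ``min_width`` (°C) marks the transition as
    step-like relative to the temperature sampling.
    """

    def __init__(self, min_width: float = 1e-3):
        self.min_width = min_width

    def fit(self, T, nu):
        T = np.asarray(T, dtype=float).ravel()
        nu = np.asarray(nu, dtype=float).ravel()
        if T.size != nu.size:
            raise ValueError("temperature and wavenumber arrays differ in length")
        if np.unique(T).size < 5:
            raise ValueError("need at least 5 distinct temperatures spanning the transition")
        order = np.argsort(T)
        T, nu = T[order], nu[order]

        lo, hi = float(np.min(nu)), float(np.max(nu))
        span = hi - lo
        if span == 0:
            self._flag_failure(T, nu, "flat curve: no transition present")
            return self
        # Tm0 at half height, width0 = 1 °C
        half = lo + 0.5 * span
        tm0 = float(T[np.argmin(np.abs(nu - half))])
        p0 = [lo, hi, tm0, 1.0]

        def resid(p):
            return boltzmann(T, *p) - nu

        sol = least_squares(
            resid, p0,
            bounds=([-np.inf, -np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf, np.inf]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        nu_gel, nu_fluid, tm, width = (float(v) for v in sol.x)
        self.nu_gel_, self.nu_fluid_, self.tm_, self.width_ = nu_gel, nu_fluid, tm, width
        self.rss_ = float(np.sum(sol.fun**2))
        ok = bool(sol.success) and nu_fluid > nu_gel and width >= self.min_width
        # reject fits whose inflection was extrapolated outside the data
        if not (T[0] <= tm <= T[-1]):
            ok = False
        self.converged_ = ok
        self.message_ = sol.message if ok else (
            "step-like transition (width -> 0)" if width < self.min_width else
            "fit did not identify a sigmoidal transition"
        )
        dof = max(T.size - 4, 1)
        s2 = self.rss_ / dof
        try:
            cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
            self.tm_se_ = float(math.sqrt(max(cov[2, 2], 0.0)))
        except np.linalg.LinAlgError:
            self.tm_se_ = np.nan
            self.converged_ = False
        return self

    def _flag_failure(self, T, nu, msg):
        self.nu_gel_ = self.nu_fluid_ = float(np.mean(nu))
        self.tm_ = np.nan
        self.width_ = np.nan
        self.tm_se_ = np.nan
        self.rss_ = float(np.sum((nu - np.mean(nu)) ** 2))
        self.converged_ = False
        self.message_ = msg

    def predict(self, T):
        return boltzmann(np.asarray(T, dtype=float), self.nu_gel_, self.nu_fluid_, self.tm_, self.width_)


def fit_boltzmann(curve: MeltingCurve) -> MeltingFit:
    """Fit the Boltzmann sigmoid to a (possibly replicated) melting curve."""
    est = BoltzmannMelt().fit(curve.temperature, curve.peak_wavenumber)
    return MeltingFit(
        Tm=est.tm_,
        width=est.width_,
        nu_gel=est.nu_gel_,
        nu_fluid=est.nu_fluid_,
        Tm_uncertainty=est.tm_se_,
        converged=est.converged_,
        message=est.message_,
    )


def delta_tm(fit_with: MeltingFit, fit_without: MeltingFit) -> tuple[float, float]:
    """ΔTm = Tm(with additive) − Tm(without), with root-sum-square uncertainty."""
    if not (fit_with.converged and fit_without.converged):
        raise ValueError("delta_tm requires two converged melting fits")
    d = fit_with.Tm - fit_without.Tm
    se = math.hypot(fit_with.Tm_uncertainty, fit_without.Tm_uncertainty)
    return d, se
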