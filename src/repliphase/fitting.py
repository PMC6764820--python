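"""Binding and quantitation curve fits.

Hill fits of titrations (A(c) = A0 + (Amax−A0)·cⁿ/(Kdⁿ + cⁿ)),
four-parameter-logistic competition curves yielding an apparent
inhibition constant, and linear standard curves with inverse prediction
of sample concentration. Nonlinear fits use least squares with
multi-start initialization (log-spaced Kd/IC50 seeds across the
concentration range) to avoid local minima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model


def hill_model(c, a0, amax, kd, n):
    """A(c) = A0 + (Amax − A0) · cⁿ / (Kdⁿ + cⁿ)."""
    c = np.asarray(c, dtype=np.float64)
    cn = np.power(c, n, where=c > 0, out=np.zeros_like(c))
    return a0 + (amax - a0) * cn / (kd ** n + cn)


def logistic4_model(c, bottom, top, ic50, slope):
    """Descending 4PL: bottom + (top − bottom) / (1 + (c/IC50)^slope)."""
    c = np.asarray(c, dtype=np.float64)
    ratio = np.power(c / ic50, slope, where=c > 0, out=np.zeros_like(c))
    return bottom + (top - bottom) / (1.0 + ratio)


@dataclass
class TitrationCurve:
    """Concentration–signal data (concentrations in M)."""

    concentrations: np.ndarray
    signal: np.ndarray
    signal_sd: np.ndarray | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=np.float64)
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.concentrations.shape != self.signal.shape:
            raise ValueError("concentrations and signal must have equal length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")

    @classmethod
    def from_csv(cls, path) -> "TitrationCurve":
        df = pd.read_csv(path)
        sd = df["signal_sd"].to_numpy() if "signal_sd" in df.columns else None
        return cls(df["concentration"].to_numpy(), df["signal"].to_numpy(), sd)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"concentration": self.concentrations, "signal": self.signal})
        if self.signal_sd is not None:
            df["signal_sd"] = self.signal_sd
        df.to_csv(path, index=False)


@dataclass
class HillFit:
    kd: float
    n: float
    a0: float
    amax: float
    stderr: dict[str, float | None] = field(default_factory=dict)
    residual_norm: float = 0.0
    success: bool = True


def _kd_seeds(conc: np.ndarray, n_seeds: int = 7) -> np.ndarray:
    pos = conc[conc > 0]
    if pos.size == 0:
        return np.array([1.0])
    return np.geomspace(pos.min(), pos.max(), n_seeds)


def fit_hill(curve: TitrationCurve, fix_n: float | None = None) -> HillFit:
    """Least-squares Hill fit with multi-start Kd initialization.

    ``fix_n`` pins the Hill coefficient (e.g. 1.0); otherwise n floats.
    Constant signal is a degenerate input and raises.
    """
    conc, sig = curve.concentrations, curve.signal
    if conc.size < 4:
        raise ValueError("need at least 4 titration points")
    if np.ptp(sig) == 0:
        raise ValueError("degenerate titration: signal is constant, "
                         "no transition to fit")
    model = Model(hill_model)
    best = None
    for kd0 in _kd_seeds(conc):
        params = model.make_params(a0=sig[np.argmin(conc)],
                                   amax=sig[np.argmax(conc)], kd=kd0, n=1.0)
        params["kd"].set(min=1e-15)
        params["n"].set(min=1e-3, max=10.0)
        if fix_n is not None:
            params["n"].set(value=fix_n, vary=False)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(sig, params, c=conc)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("Hill fit failed to converge from any start")
    p = best.params
    return HillFit(kd=p["kd"].value, n=p["n"].value, a0=p["a0"].value,
                   amax=p["amax"].value,
                   stderr={k: p[k].stderr for k in ("kd", "n", "a0", "amax")},
                   residual_norm=float(np.sqrt(best.chisqr)),
                   success=bool(best.success))


@dataclass
class CompetitionFit:
    ic50: float
    kc: float                      # apparent inhibition constant
    slope: float
    top: float
    bottom: float
    residual_norm: float = 0.0
    corrected: bool = False


def fit_competition(curve: TitrationCurve,
                    probe_kd: float | None = None,
                    probe_concentration: float | None = None,
                    cheng_prusoff: bool = False) -> CompetitionFit:
    """Four-parameter-logistic fit of a competition titration.

    By default the apparent inhibition constant is reported as the fitted
    IC50 directly. With ``cheng_prusoff=True`` (requires the probe's Kd
    and concentration), Kc = IC50 / (1 + [probe]/Kd).
    """
    conc, sig = curve.concentrations, curve.signal
    if conc.size < 4:
        raise ValueError("need at least 4 points")
    order = np.argsort(conc)
    if sig[order][0] < sig[order][-1]:
        warnings.warn("competition signal is not descending; check plateaus")
    model = Model(logistic4_model)
    best = None
    for ic0 in _kd_seeds(conc):
        params = model.make_params(bottom=sig.min(), top=sig.max(),
                                   ic50=ic0, slope=1.0)
        params["ic50"].set(min=1e-15)
        params["slope"].set(min=1e-3, max=10.0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(sig, params, c=conc)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("competition fit failed to converge")
    p = best.params
    ic50 = p["ic50"].value
    kc = ic50
    corrected = False
    if cheng_prusoff:
        if probe_kd is None or probe_concentration is None:
            raise ValueError("Cheng–Prusoff correction needs probe_kd and "
                             "probe_concentration")
        kc = ic50 / (1.0 + probe_concentration / probe_kd)
        corrected = True
    return CompetitionFit(ic50=ic50, kc=kc, slope=p["slope"].value,
                          top=p["top"].value, bottom=p["bottom"].value,
                          residual_norm=float(np.sqrt(best.chisqr)),
                          corrected=corrected)


@dataclass
class StandardCurve:
    """OLS line of intensity vs amount with inverse prediction."""

    slope: float
    intercept: float
    r_squared: float
    amount_range: tuple[float, float]

    def invert(self, intensity: float) -> tuple[float, bool]:
        """Predicted amount and an extrapolation flag."""
        if self.slope == 0:
            raise ValueError("slope is zero; curve cannot be inverted")
        amount = (intensity - self.intercept) / self.slope
        lo, hi = self.amount_range
        return amount, not (lo <= amount <= hi)


def fit_standard_curve(amounts, intensities) -> StandardCurve:
    amounts = np.asarray(amounts, dtype=np.float64)
    intensities = np.asarray(intensities, dtype=np.float64)
    if amounts.size < 3:
        raise ValueError("need at least 3 standards")
    slope, intercept = np.polyfit(amounts, intensities, 1)
    pred = slope * amounts + intercept
    ss_res = float(np.sum((intensities - pred) ** 2))
    ss_tot = float(np.sum((intensities - intensities.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(slope=float(slope), intercept=float(intercept),
                         r_squared=r2,
                         amount_range=(float(amounts.min()), float(amounts.max())))


def standard_curve_concentration(standards, sample_intensity: float,
                                 volume_liters: float,
                                 amount_to_moles: float = 1.0) -> tuple[float, bool]:
    """Concentration (M) of a sample from a standard dilution series.

    ``standards`` is an iterable of (amount, intensity) pairs; the sample
    amount is obtained by inverse prediction and converted with
    ``amount_to_moles`` (moles per amount unit) and the compartment
    volume. Returns (concentration, extrapolated_flag).
    """
    if volume_liters <= 0:
        raise ValueError("volume must be > 0")
    pairs = np.asarray(list(standards), dtype=np.float64)
    curve = fit_standard_curve(pairs[:, 0], pairs[:, 1])
    amount, extrapolated = curve.invert(sample_intensity)
    if extrapolated:
        warnings.warn("sample intensity falls outside the standard range")
    return amount * amount_to_moles / volume_liters, extrapolated
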