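"""Titration analysis: detection limits and working dilutions.

Serial dilutions of an immunogen produce saturating calibration curves;
the limit of detection (LOD) is the lowest tested concentration whose
cognate-spot signal passes the positivity rule, reported as a strict
decade bound ("<10^k") in the style of panel summary tables. Response
curves are fitted with a Langmuir binding isotherm, the same form the
synthetic generator uses, so fit and simulation stay consistent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .quantify import DEFAULT_MULTIPLIER, positivity_call

__all__ = [
    "DilutionSeries",
    "LODEstimate",
    "estimate_lod",
    "fit_response_curve",
    "ResponseCurveModel",
    "ResponseCurveResults",
    "select_working_dilution",
    "lod_table",
]

TRACER_MODES = ("single", "top_prb_mix")


@dataclass(frozen=True)
class DilutionSeries:
    """One antibody's serial-dilution assay.

    ``concentrations`` (cells/mL for lysates, ug/mL for proteins/EPS)
    must be strictly increasing with at least 3 points; ``signals`` are
    the cognate-spot summarised fluorescences and ``backgrounds`` the
    per-point background estimates. ``tracer_mode`` distinguishes the
    single fluorescent tracer from the pooled tracer mix.
    """

    antibody_code: str
    concentrations: np.ndarray
    signals: np.ndarray
    backgrounds: np.ndarray
    tracer_mode: str = "single"

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        f = np.asarray(self.signals, dtype=float)
        b = np.broadcast_to(
            np.asarray(self.backgrounds, dtype=float), c.shape
        ).copy()
        if len(c) < 3:
            raise ValueError("dilution series needs at least 3 points")
        if not (np.diff(c) > 0).all():
            raise ValueError("concentrations must be strictly increasing")
        if c.shape != f.shape:
            raise ValueError("signals and concentrations differ in length")
        if self.tracer_mode not in TRACER_MODES:
            raise ValueError(f"tracer_mode must be one of {TRACER_MODES}")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "signals", f)
        object.__setattr__(self, "backgrounds", b)

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class LODEstimate:
    """Decade-bound detection limit for one antibody/tracer combination."""

    antibody_code: str
    lod_concentration: float | None  # lowest passing tested concentration
    tracer_mode: str = "single"

    @property
    def detected(self) -> bool:
        return self.lod_concentration is not None

    @property
    def lod_bound(self) -> str:
        """Table-style bound: ``"<10^k"`` or ``"-"`` when never detected."""
        if self.lod_concentration is None:
            return "-"
        k = math.log10(self.lod_concentration)
        if abs(k - round(k)) < 1e-9:
            return f"<10^{round(k)}"
        return f"<{self.lod_concentration:g}"

    @property
    def decade(self) -> float | None:
        if self.lod_concentration is None:
            return None
        return math.log10(self.lod_concentration)


def estimate_lod(
    series: DilutionSeries, multiplier: float = DEFAULT_MULTIPLIER
) -> LODEstimate:
    """Scan the series upward for the first positivity-passing point.

    The LOD is the lowest tested concentration whose signal strictly
    exceeds ``multiplier`` times that point's background; no
    interpolation between tested decades is attempted.
    """
    for c, f, b in zip(series.concentrations, series.signals, series.backgrounds):
        if positivity_call(f, b, multiplier):
            return LODEstimate(series.antibody_code, float(c), series.tracer_mode)
    return LODEstimate(series.antibody_code, None, series.tracer_mode)


def _langmuir(c, baseline, fmax, k):
    return baseline + fmax * c / (c + k)


class ResponseCurveModel:
    """Langmuir concentration-response model for a dilution series.

    F(c) = baseline + Fmax * c / (c + K); two binding parameters plus a
    baseline. Fitted by non-linear least squares.
    """

    def __init__(self, series: DilutionSeries):
        if len(series) < 4:
            raise ValueError("response-curve fit needs at least 4 points")
        self.series = series

    def fit(self) -> "ResponseCurveResults":
        c = self.series.concentrations
        f = self.series.signals
        span = float(f.max() - f.min())
        p0 = [float(f.min()), max(span, 1e-6), float(np.median(c))]
        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    _langmuir,
                    c,
                    f,
                    p0=p0,
                    bounds=([0.0, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
                    maxfev=20000,
                )
        except RuntimeError:
            popt, pcov = np.array(p0), np.full((3, 3), np.nan)
            converged = False
        resid = f - _langmuir(c, *popt)
        return ResponseCurveResults(self, popt, pcov, resid, converged)


class ResponseCurveResults:
    """Fitted Langmuir curve: parameters, uncertainties, diagnostics."""

    def __init__(self, model, popt, pcov, resid, converged):
        self.model = model
        self.baseline, self.fmax, self.k = (float(v) for v in popt)
        self.params = {"baseline": self.baseline, "Fmax": self.fmax, "K": self.k}
        with np.errstate(invalid="ignore"):
            self.bse = {
                name: float(np.sqrt(pcov[i, i]))
                for i, name in enumerate(("baseline", "Fmax", "K"))
            }
        self.residuals = resid
        self.rss = float(np.sum(resid**2))
        self.converged = converged
        # A flat series fits with Fmax ~ 0: no usable response.
        span = float(model.series.signals.max() - model.series.signals.min())
        self.flat = self.fmax < max(0.05 * max(span, 1.0), 1e-6)
        self.flagged = (not converged) or self.flat

    def predict(self, c) -> np.ndarray:
        return _langmuir(np.asarray(c, dtype=float), self.baseline, self.fmax, self.k)

    def summary(self) -> str:
        s = self.model.series
        lines = [
            f"Langmuir response curve: {s.antibody_code} ({s.tracer_mode} tracer)",
            "-" * 56,
            f"{'parameter':<10}{'estimate':>14}{'std err':>14}",
        ]
        for name in ("baseline", "Fmax", "K"):
            lines.append(f"{name:<10}{self.params[name]:>14.4g}{self.bse[name]:>14.4g}")
        lines.append(f"RSS = {self.rss:.4g}   n = {len(s)}")
        if not self.converged:
            lines.append("WARNING: fit did not converge (flagged)")
        if self.flat:
            lines.append("WARNING: flat series, Fmax ~ 0 (flagged)")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.series
        ax.semilogx(s.concentrations, s.signals, "ko", label="observed")
        grid = np.geomspace(s.concentrations[0], s.concentrations[-1], 200)
        ax.semilogx(grid, self.predict(grid), "r-", label="Langmuir fit")
        ax.set_xlabel("concentration")
        ax.set_ylabel("fluorescence (a.u.)")
        ax.set_title(s.antibody_code)
        ax.legend()
        return ax


def fit_response_curve(series: DilutionSeries) -> ResponseCurveResults:
    """Functional wrapper: fit the Langmuir curve to one series."""
    return ResponseCurveModel(series).fit()


def select_working_dilution(
    concentrations,
    signals,
    plateau_fraction: float = 0.9,
) -> tuple[float | None, bool]:
    """Smallest tracer concentration reaching the signal plateau.

    Returns ``(concentration, plateau_found)``. The plateau level is the
    fitted Langmuir asymptote (baseline + Fmax); the working concentration
    is the smallest tested point at or above ``plateau_fraction`` of it.
    A series still rising at its top point (top signal below the plateau
    fraction of the asymptote) is flagged with ``plateau_found=False``.
    """
    c = np.asarray(concentrations, dtype=float)
    f = np.asarray(signals, dtype=float)
    series = DilutionSeries("tracer", c, f, np.zeros_like(c))
    res = ResponseCurveModel(series).fit()
    plateau = res.baseline + res.fmax
    if res.flagged or plateau <= 0:
        return None, False
    level = plateau_fraction * plateau
    if f[-1] < level:
        return None, False  # still rising: no plateau within tested range
    idx = int(np.argmax(f >= level))
    return float(c[idx]), True


def lod_table(estimates: list[LODEstimate]):
    """Panel-style LOD table: antibody, LOD, LOD with pooled tracer mix."""
    import pandas as pd

    by_ab: dict[str, dict] = {}
    for e in estimates:
        row = by_ab.setdefault(e.antibody_code, {"LOD": "-", "LOD_TOP-PRB": "-"})
        key = "LOD" if e.tracer_mode == "single" else "LOD_TOP-PRB"
        row[key] = e.lod_bound
    return pd.DataFrame.from_dict(by_ab, orient="index").rename_axis("antibody")
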