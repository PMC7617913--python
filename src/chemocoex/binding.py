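"""Steady-state chemokine:GAG affinity estimation and binding normalisations.

Equilibrium bio-layer interferometry (BLI) reports, per analyte
concentration C, the plateau signal of chemokine binding to an immobilised
glycosaminoglycan (GAG). Under the one-site Langmuir steady-state model the
expected equilibrium response is

    Req(C) = Rmax * C / (KD + C)

with KD the dissociation constant (nM; the concentration at half-maximal
binding) and Rmax the maximal response (instrument units, e.g. nm shift).
``fit_kd`` estimates (KD, Rmax) by unweighted nonlinear least squares on
blank-subtracted equilibrium signals; replicate curves are fitted jointly
(stacked), not averaged. A fit is flagged when the highest concentration
reaches less than half-saturation, where KD is poorly constrained.

Also here: the flow-cytometry normalisation of binding MFI to wild-type
cells and the percent-of-control inhibition readout used for endothelial
chemokine presentation assays.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from chemocoex._util import substream

logger = logging.getLogger(__name__)


class BindingError(ValueError):
    pass


class FitError(RuntimeError):
    """Raised when the least-squares fit fails to converge."""


@dataclass(frozen=True)
class BindingCurve:
    """Concentration series with equilibrium signals, sorted by concentration.

    ``replicate`` optionally groups points into replicate curves; ``blank``
    optionally carries reference-sensor signals for subtraction.
    """

    concentrations: np.ndarray  # nM, strictly positive
    signals: np.ndarray
    replicate: np.ndarray | None = None
    blank: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if c.shape != s.shape or c.ndim != 1:
            raise BindingError("concentrations and signals must be equal-length 1-d arrays")
        if (c <= 0).any():
            raise BindingError("concentrations must be strictly positive (nM)")
        for name in ("replicate", "blank"):
            arr = getattr(self, name)
            if arr is not None and len(np.asarray(arr)) != len(c):
                raise BindingError(f"{name} length mismatch")
        order = np.argsort(c, kind="stable")
        object.__setattr__(self, "concentrations", c[order])
        object.__setattr__(self, "signals", s[order])
        if self.replicate is not None:
            object.__setattr__(self, "replicate", np.asarray(self.replicate)[order])
        if self.blank is not None:
            object.__setattr__(self, "blank", np.asarray(self.blank, dtype=float)[order])

    def __len__(self) -> int:
        return len(self.concentrations)

    def blank_subtracted(self) -> "BindingCurve":
        if self.blank is None:
            return self
        return BindingCurve(
            concentrations=self.concentrations,
            signals=subtract_reference(self.signals, self.blank),
            replicate=self.replicate,
        )


@dataclass(frozen=True)
class AffinityFit:
    """Fitted steady-state affinity: KD (nM), Rmax (signal units), diagnostics."""

    kd: float
    rmax: float
    rss: float
    converged: bool
    kd_se: float
    rmax_se: float
    saturation_fraction: float  # max(C)/(max(C)+KD)
    low_saturation: bool
    n_points: int


def steady_state_signal(
    c: float | np.ndarray, kd: float, rmax: float
) -> float | np.ndarray:
    """One-site Langmuir isotherm: Req = Rmax * C / (KD + C)."""
    if kd <= 0 or rmax <= 0:
        raise BindingError(f"KD and Rmax must be positive, got KD={kd}, Rmax={rmax}")
    c_arr = np.asarray(c, dtype=float)
    if (c_arr < 0).any():
        raise BindingError("concentration must be non-negative")
    out = rmax * c_arr / (kd + c_arr)
    return float(out) if np.isscalar(c) else out


def subtract_reference(signals, blank_signals) -> np.ndarray:
    """Elementwise blank-sensor subtraction; negative results are allowed (logged)."""
    s = np.asarray(signals, dtype=float)
    b = np.asarray(blank_signals, dtype=float)
    if s.shape != b.shape:
        raise BindingError(f"signal/blank length mismatch: {s.shape} vs {b.shape}")
    out = s - b
    neg = int((out < 0).sum())
    if neg:
        logger.info("blank subtraction produced %d negative corrected signals", neg)
    return out


def fit_kd(curve: BindingCurve) -> AffinityFit:
    """Fit (KD, Rmax) to an equilibrium curve by nonlinear least squares.

    Initialisation: KD0 = the concentration whose signal is nearest half of
    the maximum, Rmax0 = 1.1 * max signal. Positivity is enforced by bounds;
    convergence tolerance 1e-10 on relative parameter change, at most 500
    iterations. Blank signals, when attached, are subtracted first.
    Standard errors come from the Gauss-Newton covariance at the optimum.
    """
    curve = curve.blank_subtracted()
    c = curve.concentrations
    s = curve.signals
    if len(np.unique(c)) < 4:
        raise BindingError(f"need >=4 distinct concentrations, have {len(np.unique(c))}")
    if not np.isfinite(s).all():
        raise BindingError("signals contain non-finite values")
    # means per concentration, for the shape sanity check only (fit uses all points)
    uniq = np.unique(c)
    mean_per_c = np.array([s[c == u].mean() for u in uniq])
    if np.all(np.diff(mean_per_c) < 0):
        raise BindingError(
            "signals decrease monotonically with concentration; not a saturation curve"
        )
    smax = float(s.max())
    if smax <= 0:
        raise BindingError("all signals non-positive; nothing to fit")
    kd0 = float(c[np.argmin(np.abs(s - smax / 2.0))])
    rmax0 = 1.1 * smax

    def residuals(theta: np.ndarray) -> np.ndarray:
        kd, rmax = theta
        return rmax * c / (kd + c) - s

    res = least_squares(
        residuals,
        x0=[kd0, rmax0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        xtol=1e-10,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=500,
    )
    if not res.success:
        raise FitError(f"KD fit did not converge: {res.message} (status {res.status})")
    kd, rmax = map(float, res.x)
    rss = float(res.fun @ res.fun)
    dof = max(len(c) - 2, 1)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * rss / dof
        kd_se, rmax_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        kd_se = rmax_se = float("inf")
    sat = float(c.max() / (c.max() + kd))
    low_sat = sat < 0.5
    if low_sat:
        warnings.warn(
            f"highest concentration reaches only {100 * sat:.1f}% saturation; "
            "KD is poorly constrained",
            stacklevel=2,
        )
    return AffinityFit(
        kd=kd,
        rmax=rmax,
        rss=rss,
        converged=True,
        kd_se=kd_se,
        rmax_se=rmax_se,
        saturation_fraction=sat,
        low_saturation=low_sat,
        n_points=len(c),
    )


def simulate_binding_curve(
    kd: float,
    rmax: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> BindingCurve:
    """Model-generated equilibrium curve with additive Gaussian noise (seeded)."""
    if noise_sd < 0:
        raise BindingError("noise_sd must be non-negative")
    c = np.asarray(concentrations, dtype=float)
    clean = steady_state_signal(c, kd, rmax)
    rng = substream(seed, "fits")
    signals = clean + rng.normal(0.0, noise_sd, size=c.shape) if noise_sd > 0 else clean
    return BindingCurve(concentrations=c, signals=np.asarray(signals, dtype=float))


def twofold_dilutions(top_nM: float = 2000.0, n: int = 8) -> np.ndarray:
    """Standard BLI concentration series: n two-fold dilutions from the top (nM)."""
    return top_nM / (2.0 ** np.arange(n))[::-1]


@dataclass(frozen=True)
class InhibitionResult:
    """Percent inhibition relative to a chemokine-alone control."""

    raw: float  # 100*(1 - with/control); may fall outside [0, 100]
    clipped: float  # convenience value clipped to [0, 100]


def percent_inhibition(signal_with_competitor: float, signal_control: float) -> InhibitionResult:
    """Percent-of-control inhibition: 100 * (1 - with/control)."""
    if signal_control <= 0:
        raise BindingError(f"control signal must be positive, got {signal_control}")
    raw = 100.0 * (1.0 - signal_with_competitor / signal_control)
    return InhibitionResult(raw=raw, clipped=float(np.clip(raw, 0.0, 100.0)))


def normalize_to_reference(mfi_values, reference_mfi: float) -> np.ndarray:
    """Binding MFI relative to the wild-type (reference) MFI."""
    if reference_mfi <= 0:
        raise BindingError(f"reference MFI must be positive, got {reference_mfi}")
    return np.asarray(mfi_values, dtype=float) / float(reference_mfi)
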