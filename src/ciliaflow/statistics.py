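"""Order parameters, correlation lengths and flow-regime classification.

Three emergent regimes are distinguished from two scalars of the steady flow:

* polarization ``P = |mean(U/|U|)|``, the orientational order of the flow;
* integral length ``Lambda``, the normalized integral of the directional
  vorticity autocorrelations, measuring the flow-structure size in units of
  the dimensional screening length ``sqrt(mu_m/kappa) = lambda*D``.

Classification: ``P >= 0.9`` is fully aligned; otherwise ``Lambda >= 1.5``
is swirly and ``Lambda < 1.5`` poorly aligned.

The swirl size ``Lambda'`` is the first zero crossing of the ensemble-mean
vorticity autocorrelation, in units of the element side D — the emergent
vortex scale.  Signed (not absolute) vorticity is used in the correlations:
the autocorrelation of an unsigned field could never cross zero, while the
swirl-size definition requires a zero crossing.  The spatial mean of the curl
vanishes identically on a periodic domain, so no mean subtraction is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CorrelationProfile",
    "RegimeRecord",
    "SwirlSize",
    "polarization",
    "vorticity_field",
    "autocorrelation",
    "integral_length",
    "classify_regime",
    "swirl_size",
    "REGIMES",
]

REGIMES = ("poorly_aligned", "swirly", "fully_aligned")


def polarization(ux: np.ndarray, uy: np.ndarray, eps_speed: float = 0.0) -> float:
    """Magnitude of the spatial mean of unit velocity vectors, in [0, 1].

    Numerically stagnant nodes (speed below ``eps_speed``) are excluded; if
    every node is stagnant the polarization is undefined and 0 is returned.
    """
    speed = np.hypot(ux, uy)
    mask = speed > max(eps_speed, 0.0)
    if not mask.any():
        import warnings

        warnings.warn("all nodes below eps_speed; polarization undefined, returning 0")
        return 0.0
    mx = (ux[mask] / speed[mask]).mean()
    my = (uy[mask] / speed[mask]).mean()
    return float(np.hypot(mx, my))


def vorticity_field(
    ux: np.ndarray, uy: np.ndarray, D: float, U0: float, dn: float = 1.0
) -> np.ndarray:
    """Signed non-dimensional curl (D/U0) * (dUy/dx - dUx/dy), periodic wrap.

    Central differences on the periodic grid; arrays are indexed [ix, iy].
    The field's magnitude is the non-dimensional vorticity used for display.
    """
    duy_dx = (np.roll(uy, -1, axis=0) - np.roll(uy, 1, axis=0)) / (2.0 * dn)
    dux_dy = (np.roll(ux, -1, axis=1) - np.roll(ux, 1, axis=1)) / (2.0 * dn)
    return (D / U0) * (duy_dx - dux_dy)


@dataclass(frozen=True)
class CorrelationProfile:
    """Directional vorticity autocorrelations R_x, R_y on lags 0..L/2.

    Lags are in grid spacings; ``R_mean = (R_x + R_y)/2``.
    """

    lags: np.ndarray
    Rx: np.ndarray
    Ry: np.ndarray

    @property
    def R_mean(self) -> np.ndarray:
        return 0.5 * (self.Rx + self.Ry)

    @property
    def first_zero(self) -> float | None:
        """Smallest lag where R_mean crosses zero (linear interpolation)."""
        return _first_zero(self.lags, self.R_mean)


def _first_zero(lags: np.ndarray, r: np.ndarray) -> float | None:
    neg = np.flatnonzero(r <= 0.0)
    if neg.size == 0:
        return None
    j = int(neg[0])
    if j == 0:
        return float(lags[0])
    if r[j] == 0.0:
        return float(lags[j])
    t = r[j - 1] / (r[j - 1] - r[j])
    return float(lags[j - 1] + t * (lags[j] - lags[j - 1]))


def _axis_autocorr(omega: np.ndarray, axis: int) -> np.ndarray:
    """Circular autocorrelation along ``axis``, averaged over the other axis."""
    n = omega.shape[axis]
    spec = np.fft.rfft(omega, axis=axis)
    power = (spec * spec.conj()).real
    corr = np.fft.irfft(power, n=n, axis=axis)
    corr = corr.mean(axis=1 - axis)
    return corr[: n // 2 + 1] / corr[0]


def autocorrelation(omega: np.ndarray) -> CorrelationProfile:
    """FFT-based periodic autocorrelation of the signed vorticity field.

    ``R_x`` correlates along x (axis 0) and averages over y; ``R_y`` the
    converse.  Lags run from 0 to half the (shorter) domain extent.
    """
    if float(np.mean(omega**2)) <= 0.0:
        raise ValueError("uniform flow has no correlation structure (zero vorticity variance)")
    rx = _axis_autocorr(omega, axis=0)
    ry = _axis_autocorr(omega, axis=1)
    m = min(rx.size, ry.size)
    lags = np.arange(m, dtype=float)
    return CorrelationProfile(lags=lags, Rx=rx[:m], Ry=ry[:m])


def integral_length(
    profile: CorrelationProfile, lambda_: float, D: float
) -> tuple[float, str]:
    """Integral length Lambda = sqrt(kappa/mu_m) * int_0^T R_mean dtau.

    ``sqrt(kappa/mu_m) = 1/(lambda*D)`` in lattice units.  The integral is
    truncated at the first zero crossing of ``R_mean`` (beyond it, periodic
    image anticorrelations contaminate the tail), falling back to the maximum
    available lag L/2 when no crossing exists.  Returns (Lambda, truncation
    mode), the mode being ``"first_zero"`` or ``"half_domain"``.
    """
    r = profile.R_mean
    lags = profile.lags
    z = _first_zero(lags, r)
    if z is None:
        integral = float(np.trapezoid(r, lags))
        mode = "half_domain"
    else:
        inside = lags < z
        xs = np.append(lags[inside], z)
        ys = np.append(r[inside], 0.0)
        integral = float(np.trapezoid(ys, xs))
        mode = "first_zero"
    return integral / (lambda_ * D), mode


def classify_regime(P: float, Lambda: float) -> str:
    """Deterministic three-way regime label from (P, Lambda)."""
    if not 0.0 <= P <= 1.0 + 1e-9:
        raise ValueError("polarization must lie in [0, 1]")
    if Lambda < 0:
        raise ValueError("integral length must be non-negative")
    if P >= 0.9:
        return "fully_aligned"
    if Lambda >= 1.5:
        return "swirly"
    return "poorly_aligned"


@dataclass(frozen=True)
class SwirlSize:
    """Ensemble swirl size: first zero of <R> in units of D.

    ``confined`` flags profiles whose mean correlation never crosses zero
    within half the domain — the structure is limited by the box, and the
    value (set to the maximum lag) must not enter scaling fits.
    """

    value: float
    confined: bool
    n_profiles: int


def swirl_size(profiles: list[CorrelationProfile], D: float) -> SwirlSize:
    """First zero crossing of the run-averaged R_mean, normalized by D."""
    if not profiles:
        raise ValueError("need at least one correlation profile")
    m = min(p.lags.size for p in profiles)
    lags = profiles[0].lags[:m]
    mean_r = np.mean([p.R_mean[:m] for p in profiles], axis=0)
    z = _first_zero(lags, mean_r)
    if z is None:
        return SwirlSize(value=float(lags[-1]) / D, confined=True, n_profiles=len(profiles))
    return SwirlSize(value=z / D, confined=False, n_profiles=len(profiles))


@dataclass(frozen=True)
class RegimeRecord:
    """Classification record of one converged run."""

    phi: float
    lambda_: float
    polarization: float
    integral_length: float
    label: str
    converged: bool
    n_updates: int
    seed_geometry: int
    seed_orientation: int
    seed_noise: int
    truncation: str = "first_zero"
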