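"""Parametric excess-hazard model: a gamma-density wave plus a triangle wave.

The excess hazard of death attributable to the cancer, as a function of time
``t`` (years) since diagnosis, is modelled as

    h(t) = A * f_gamma(t; k, theta) + H * max(0, 1 - |t - p_c| / w)

where ``f_gamma`` is the gamma probability density with shape ``k`` and scale
``theta``.  Because the gamma density integrates to one, ``A`` is the expected
number of lifetime excess deaths per person contributed by the smooth wave;
the triangle contributes its area ``H * w`` (reduced when the peak sits closer
than ``w`` to diagnosis, since negative times are excluded).  The total area
under the excess hazard (AUC) is the expected number of lifetime excess deaths
per person, and the implied lifetime probability of death from the cancer is
``1 - exp(-AUC)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special


@dataclass(frozen=True)
class TrigamParams:
    """Parameters of the gamma-wave + triangle-wave excess hazard.

    Parameters
    ----------
    A : float
        Gamma-wave amplitude: expected lifetime excess deaths per person
        contributed by the smooth wave (>= 0).
    k : float
        Gamma shape (> 0).
    theta : float
        Gamma scale in years (> 0).
    H : float
        Triangle peak height, per person-year (>= 0).
    p_c : float
        Triangle peak location, years since diagnosis (>= 0).
    w : float
        Triangle half-width, years (> 0).
    """

    A: float = 0.0
    k: float = 2.0
    theta: float = 3.0
    H: float = 0.0
    p_c: float = 3.0
    w: float = 2.0

    def __post_init__(self) -> None:
        if self.A < 0 or self.H < 0:
            raise ValueError("amplitudes A and H must be nonnegative")
        if self.k <= 0 or self.theta <= 0 or self.w <= 0:
            raise ValueError("k, theta and w must be positive")
        if self.p_c < 0:
            raise ValueError("triangle peak p_c must be nonnegative")

    # -- hazard ---------------------------------------------------------

    def hazard(self, t):
        """Excess hazard h(t) per person-year; t in years since diagnosis."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time since diagnosis must be nonnegative")
        out = np.zeros_like(t)
        if self.A > 0:
            # gamma pdf written via gammaln for stability at large k
            with np.errstate(divide="ignore", invalid="ignore"):
                logpdf = (
                    (self.k - 1.0) * np.log(t)
                    - t / self.theta
                    - special.gammaln(self.k)
                    - self.k * np.log(self.theta)
                )
            pdf = np.where(t > 0, np.exp(logpdf), 1.0 / self.theta if self.k == 1.0 else 0.0)
            out = out + self.A * pdf
        if self.H > 0:
            out = out + self.H * np.maximum(0.0, 1.0 - np.abs(t - self.p_c) / self.w)
        return out if out.shape else float(out)

    # -- integrals ------------------------------------------------------

    def _tri_primitive(self, x):
        """Integral of the (untruncated) triangle from its left foot to x."""
        x = np.asarray(x, dtype=float)
        left = self.p_c - self.w
        u = np.clip(x - left, 0.0, self.w)          # rising limb
        v = np.clip(x - self.p_c, 0.0, self.w)      # falling limb
        rising = self.H * u * u / (2.0 * self.w)
        falling = self.H * (v - v * v / (2.0 * self.w))
        return rising + falling

    def cum_hazard(self, t):
        """Cumulative excess hazard: integral of h over [0, t]."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time since diagnosis must be nonnegative")
        if self.A > 0:
            gamma_part = self.A * special.gammainc(self.k, t / self.theta)
        else:
            gamma_part = np.zeros_like(t)
        tri_part = self._tri_primitive(t) - self._tri_primitive(0.0)
        out = gamma_part + tri_part
        return out if out.shape else float(out)

    @property
    def auc(self) -> float:
        """Area under the excess hazard over t >= 0 (lifetime excess deaths)."""
        full_triangle = self.H * self.w
        truncated = self._tri_primitive(0.0)  # mass on t < 0, excluded
        return float(self.A + full_triangle - truncated)

    def breakpoints(self) -> np.ndarray:
        """Non-smooth points of h on t >= 0 (triangle feet and peak)."""
        pts = np.array([self.p_c - self.w, self.p_c, self.p_c + self.w])
        return np.unique(pts[pts > 0])


def h_trigam(t, p: TrigamParams):
    """Evaluate the trigam excess hazard at times ``t`` (years)."""
    return p.hazard(t)


def trigam_auc(p: TrigamParams) -> float:
    """Area under the trigam excess hazard over t >= 0."""
    return p.auc
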