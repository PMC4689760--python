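"""Dunnett many-to-one multiple comparisons.

Adjusted p-values and simultaneous critical values come from the joint
distribution of the k treatment-vs-control t statistics, which share the
control mean and the pooled variance estimate (correlation 1/2 at equal
group sizes). The max-|t| tail probability is computed by numerical
integration: conditioning on the control-mean deviate and the pooled-SD
scale factor makes the k statistics independent, so

    P(max |T_i| <= c) = E_{Z0, W}[ prod_i Phi-interval_i(Z0, c W) ]

with Z0 ~ N(0,1) handled by Gauss-Hermite quadrature and W = s/sigma
(nu W^2 ~ chi^2_nu) by Gauss-Legendre quadrature over its effective support.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.optimize import brentq
from scipy.special import gammaln

__all__ = ["prob_max_abs_t", "dunnett_pvalues", "dunnett_critical_value"]

_N_HERMITE = 96
_N_LEGENDRE = 128


def _quadrature(nu: int):
    """Quadrature nodes/weights for (Z0, W). Cached per pooled df."""
    x, wx = np.polynomial.hermite.hermgauss(_N_HERMITE)
    z_nodes = np.sqrt(2.0) * x
    z_weights = wx / np.sqrt(np.pi)

    w_lo = np.sqrt(stats.chi2.ppf(1e-12, nu) / nu)
    w_hi = np.sqrt(stats.chi2.ppf(1 - 1e-12, nu) / nu)
    y, wy = np.polynomial.legendre.leggauss(_N_LEGENDRE)
    w_nodes = 0.5 * (w_hi - w_lo) * y + 0.5 * (w_hi + w_lo)
    scale = 0.5 * (w_hi - w_lo)
    # chi-scale density f_W(w) = 2 (nu/2)^{nu/2} / Gamma(nu/2) w^{nu-1} exp(-nu w^2 / 2)
    log_f = (
        np.log(2.0)
        + 0.5 * nu * np.log(0.5 * nu)
        - gammaln(0.5 * nu)
        + (nu - 1) * np.log(w_nodes)
        - 0.5 * nu * w_nodes**2
    )
    w_weights = scale * wy * np.exp(log_f)
    return z_nodes, z_weights, w_nodes, w_weights


def prob_max_abs_t(c, nu: int, ns, n_control: int):
    """P(max_i |T_i| <= c) for Dunnett's statistics.

    Parameters
    ----------
    c
        Scalar or array of thresholds (>= 0).
    nu
        Pooled-variance degrees of freedom.
    ns
        Treatment group sizes (length k).
    n_control
        Control group size.
    """
    c = np.atleast_1d(np.asarray(c, dtype=float))
    ns = np.asarray(ns, dtype=float)
    z_nodes, z_weights, w_nodes, w_weights = _quadrature(int(nu))
    s_i = np.sqrt(1.0 / ns + 1.0 / n_control)  # (k,)

    # shapes: c (nc,1,1,1), w (nw,1,1), z (nz,1), groups (k,)
    cw = c[:, None, None, None] * w_nodes[None, :, None, None] * s_i  # (nc, nw, 1, k)
    shift = z_nodes[None, None, :, None] / np.sqrt(n_control)  # (1,1,nz,1)
    root_n = np.sqrt(ns)
    upper = stats.norm.cdf(root_n * (shift + cw))
    lower = stats.norm.cdf(root_n * (shift - cw))
    inner = np.prod(upper - lower, axis=-1)  # (nc, nw, nz)
    over_z = inner @ z_weights  # (nc, nw)
    prob = over_z @ w_weights  # (nc,)
    prob = np.clip(prob, 0.0, 1.0)
    return prob if prob.size > 1 else float(prob[0])


def dunnett_pvalues(t_obs, nu: int, ns, n_control: int) -> np.ndarray:
    """Two-sided Dunnett-adjusted p-values for observed t statistics."""
    t_obs = np.atleast_1d(np.abs(np.asarray(t_obs, dtype=float)))
    return 1.0 - np.atleast_1d(prob_max_abs_t(t_obs, nu, ns, n_control))


def dunnett_critical_value(alpha: float, nu: int, ns, n_control: int) -> float:
    """Two-sided simultaneous critical value at family-wise level alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return brentq(
        lambda c: prob_max_abs_t(c, nu, ns, n_control) - (1.0 - alpha), 1e-6, 50.0,
        xtol=1e-10,
    )
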