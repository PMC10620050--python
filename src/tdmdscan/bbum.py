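"""Bi-beta-uniform mixture (BBUM) modelling of two-sided p-values.

For unidirectional discovery the two-sided p-values are split by the sign of
the fold-change.  Both branches share a uniform null of weight ``lambda`` and
a secondary Beta(a, 1) component capturing spurious, direction-symmetric
signal; the expected (up) direction additionally carries a primary
Beta(r*a, 1) component of fraction ``theta`` within the non-uniform mass:

    background:  f(p) = lam + (1-lam) * a * p**(a-1)
    signal:      f(p) = lam + (1-lam) * [theta * r*a * p**(r*a-1)
                                         + (1-theta) * a * p**(a-1)]

with 0 < r < 1, so the primary component is more concentrated near zero than
the secondary.  Parameters are fitted by joint maximum likelihood over both
branches; FDR-adjusted values for the signal branch are posterior
null-or-secondary fractions, monotonized in the q-value style.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

P_CLIP_LO = 1e-12
#: starting grid for the quasi-Newton fits (8 points)
START_GRID = [
    (lam, a, theta, r)
    for lam in (0.3, 0.9)
    for a in (0.3, 0.7)
    for theta, r in ((0.05, 0.1), (0.2, 0.5))
]
#: r above this (or theta below the corresponding floor) flags the boundary
#: where the primary beta degenerates into the secondary and theta is
#: unidentifiable.
R_BOUNDARY = 0.98
THETA_BOUNDARY = 1e-4


class BbumError(ValueError):
    pass


@dataclass(frozen=True)
class BbumParams:
    """Fitted BBUM parameters.

    lam: uniform/null weight; a: secondary beta shape in (0, 1]; theta:
    primary fraction of the non-uniform mass in the signal branch; r: primary
    shape multiplier (primary shape = r * a).  ``boundary`` is set when the
    fit lands where theta is unidentifiable (r -> 1 or theta -> 0).
    """

    lam: float
    a: float
    theta: float
    r: float
    loglik: float
    n_signal: int = 0
    n_background: int = 0
    boundary: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise BbumError("lambda must be in [0, 1]")
        if not (0.0 < self.a <= 1.0):
            raise BbumError("a must be in (0, 1]")
        if not (0.0 <= self.theta <= 1.0):
            raise BbumError("theta must be in [0, 1]")
        if not (0.0 < self.r < 1.0):
            raise BbumError("r must be in (0, 1)")


def bbum_density(p, params: BbumParams, branch: str) -> np.ndarray:
    """Mixture density at p (vectorised) for the given branch."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise BbumError("p must lie in (0, 1]")
    lam, a, theta, r = params.lam, params.a, params.theta, params.r
    beta_sec = a * p ** (a - 1.0)
    if branch == "background":
        return lam + (1.0 - lam) * beta_sec
    if branch == "signal":
        beta_pri = (r * a) * p ** (r * a - 1.0)
        return lam + (1.0 - lam) * (theta * beta_pri + (1.0 - theta) * beta_sec)
    raise BbumError(f"unknown branch {branch!r}")


def _negloglik(x, logp_sig, logp_bg, n_cens_sig=0, n_cens_bg=0, log_clip=np.log(P_CLIP_LO)):
    """Negative log-likelihood in logit coordinates.

    Values at the lower clip are treated as left-censored (log-CDF
    contribution): an extreme p-value carries the information "at most the
    clip", not a density spike at the clip boundary.
    """
    lam = float(np.clip(expit(x[0]), 0.0, 1.0))
    a = float(np.clip(expit(x[1]), 1e-9, 1.0))
    theta = float(np.clip(expit(x[2]), 0.0, 1.0))
    r = float(np.clip(expit(x[3]), 1e-9, 1.0 - 1e-12))
    ra = r * a
    # log densities without exponentiating p**(a-1) for stability
    sec_sig = np.log(a) + (a - 1.0) * logp_sig
    pri_sig = np.log(ra) + (ra - 1.0) * logp_sig
    mix_sig = np.logaddexp(
        np.log(theta + 1e-300) + pri_sig, np.log(1.0 - theta + 1e-300) + sec_sig
    )
    f_sig = np.logaddexp(np.log(lam + 1e-300), np.log(1.0 - lam + 1e-300) + mix_sig)
    sec_bg = np.log(a) + (a - 1.0) * logp_bg
    f_bg = np.logaddexp(np.log(lam + 1e-300), np.log(1.0 - lam + 1e-300) + sec_bg)
    nll = -(f_sig.sum() + f_bg.sum())
    if n_cens_sig:
        c = np.exp(log_clip)
        cdf_sig = lam * c + (1.0 - lam) * (
            theta * c**ra + (1.0 - theta) * c**a
        )
        nll -= n_cens_sig * np.log(cdf_sig + 1e-300)
    if n_cens_bg:
        c = np.exp(log_clip)
        cdf_bg = lam * c + (1.0 - lam) * c**a
        nll -= n_cens_bg * np.log(cdf_bg + 1e-300)
    return nll


def fit_bbum(p_signal, p_background) -> BbumParams:
    """Joint MLE of the BBUM parameters over both fold-change directions.

    lambda and a are shared between branches; theta and r act on the signal
    branch only.  Optimisation is quasi-Newton (BFGS) in logit-transformed
    coordinates from an 8-point start grid; the best log-likelihood wins.
    Deterministic given the inputs (order- and duplication-invariant up to
    floating-point addition order).
    """
    p_signal = np.asarray(p_signal, dtype=float)
    p_background = np.asarray(p_background, dtype=float)
    if p_signal.size == 0 or p_background.size == 0:
        raise BbumError("both p-value sets must be non-empty")
    n_cens_sig = int((p_signal <= P_CLIP_LO).sum())
    n_cens_bg = int((p_background <= P_CLIP_LO).sum())
    logp_sig = np.log(np.sort(np.minimum(p_signal[p_signal > P_CLIP_LO], 1.0)))
    logp_bg = np.log(np.sort(np.minimum(p_background[p_background > P_CLIP_LO], 1.0)))

    results = []
    for lam0, a0, theta0, r0 in START_GRID:
        x0 = np.array([logit(lam0), logit(a0), logit(theta0), logit(r0)])
        res = minimize(
            _negloglik,
            x0,
            args=(logp_sig, logp_bg, n_cens_sig, n_cens_bg),
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-8, "gtol": 1e-8},
        )
        if np.isfinite(res.fun):
            results.append(res)
    if not results:
        raise BbumError("BBUM fit failed to converge from every start")
    # near-ties (flat likelihood ridges, e.g. uniform data) break toward the
    # interpretable solution: more uniform weight, less primary mass
    f_best = min(res.fun for res in results)
    tol = 1e-6 * max(1.0, abs(f_best))
    best = min(
        (res for res in results if res.fun <= f_best + tol),
        key=lambda res: (-expit(res.x[0]), expit(res.x[2])),
    )
    lam, a, theta, r = expit(best.x)
    a = min(float(a), 1.0)
    r = float(np.clip(r, 1e-9, 1.0 - 1e-9))
    boundary = bool((r > R_BOUNDARY) or (theta < THETA_BOUNDARY))
    return BbumParams(
        lam=float(lam),
        a=float(a),
        theta=float(theta),
        r=r,
        loglik=-float(best.fun),
        n_signal=int(p_signal.size),
        n_background=int(p_background.size),
        boundary=boundary,
    )


def bbum_fdr(p_signal, params: BbumParams) -> np.ndarray:
    """FDR-adjusted values for signal-direction p-values.

    The raw estimate q(p) is the null-plus-secondary fraction of the fitted
    signal-branch CDF at p:

        q(p) = [lam*p + (1-lam)(1-theta)*p**a]
               / [lam*p + (1-lam)(1-theta)*p**a + (1-lam)*theta*p**(r*a)]

    monotonized so padj(p_i) = min over p_j >= p_i of q(p_j).  With theta = 0
    there is no primary component and every padj is 1.
    """
    p = np.clip(np.asarray(p_signal, dtype=float), P_CLIP_LO, 1.0)
    lam, a, theta, r = params.lam, params.a, params.theta, params.r
    if theta <= 0.0 or params.boundary:
        # no primary component, or a degenerate fit (r -> 1) in which the
        # primary cannot be separated from the secondary: no discoveries
        return np.ones_like(p)
    null_mass = lam * p + (1.0 - lam) * (1.0 - theta) * p**a
    sig_mass = (1.0 - lam) * theta * p ** (r * a)
    q = null_mass / (null_mass + sig_mass)
    order = np.argsort(p)[::-1]  # largest p first
    q_sorted = q[order]
    running = np.minimum.accumulate(q_sorted)
    padj = np.empty_like(q)
    padj[order] = running
    return np.clip(padj, 0.0, 1.0)
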