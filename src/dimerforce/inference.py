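"""Lifetime, Bell-model, rupture-force and re-dimerization fits.

The statistical layer of the pipeline:

* censored-exponential lifetime estimates at one force (the MLE
  ``tau = total observed time / number of ruptures`` handles right-censored
  dwells coherently), or a least-squares fit of the empirical rupture
  probability ``P(t) = 1 - exp(-k t)``;
* bootstrap resampling (default M = 20 size-N resamples with replacement)
  yielding mean / sd / se of both the rate ``k`` and the lifetime
  ``tau = 1/k``;
* a weighted log-linear Bell fit ``ln k(f) = ln k0 + delta * f / kBT``;
* Gaussian (mixture) fits of rupture-force histograms;
* the re-dimerization probability curve
  ``P(F) = 1 / (exp((F - Fc) dx / kBT) + 1)`` and its complement, the
  rupture probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import norm

from .kinetics import BellParams
from .polymer import DEFAULT_ENV, PolymerEnvironment
from .traces import DwellRecord

__all__ = [
    "LifetimeEstimate",
    "BootstrapConfig",
    "BellFit",
    "GaussianPeak",
    "RedimerCurve",
    "fit_lifetime",
    "bootstrap_rates",
    "fit_bell",
    "fit_force_histogram",
    "fit_redimerization",
    "fit_exponential_mixture",
]

logger = logging.getLogger(__name__)


@dataclass
class LifetimeEstimate:
    """Characteristic lifetime / rupture rate at one force.

    ``tau * k = 1`` by construction; sd/se fields are populated by the
    bootstrap. ``unbounded`` flags an all-censored sample where tau has no
    finite MLE.
    """

    force: float
    tau: float
    k_rupture: float
    n_obs: int
    n_censored: int
    tau_sd: float | None = None
    tau_se: float | None = None
    k_sd: float | None = None
    k_se: float | None = None
    unbounded: bool = False
    bootstrap_k: np.ndarray | None = None


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling settings: M size-N resamples drawn with replacement."""

    n_resamples: int = 20
    rng_seed: int = 0
    estimator: str = "mle"  # "mle" (censored MLE) or "curve" (P(t) fit)

    def __post_init__(self) -> None:
        if self.n_resamples < 2:
            raise ValueError("n_resamples must be >= 2")
        if self.estimator not in ("mle", "curve"):
            raise ValueError("estimator must be 'mle' or 'curve'")


@dataclass
class BellFit:
    """Fitted Bell parameters with uncertainties (k0 in 1/s, delta in nm)."""

    params: BellParams
    k0_se: float
    delta_se: float
    covariance: np.ndarray
    n_points: int


@dataclass(frozen=True)
class GaussianPeak:
    mean: float
    sd: float
    weight: float


@dataclass(frozen=True)
class RedimerCurve:
    """Half-transition force Fc (pN) and width parameter dx (nm)."""

    Fc: float
    delta_x: float
    kBT: float = DEFAULT_ENV.kBT

    def __post_init__(self) -> None:
        if self.delta_x <= 0:
            raise ValueError("delta_x must be > 0")

    def redimerization_probability(self, force):
        force = np.asarray(force, dtype=float)
        return 1.0 / (np.exp((force - self.Fc) * self.delta_x / self.kBT) + 1.0)

    def rupture_probability(self, force):
        return 1.0 - self.redimerization_probability(force)


def _split_dwells(dwells: Sequence[DwellRecord]):
    t = np.array([d.dwell for d in dwells], dtype=float)
    c = np.array([d.censored for d in dwells], dtype=bool)
    forces = np.array([d.force for d in dwells], dtype=float)
    return t, c, forces


def _tau_mle(t: np.ndarray, c: np.ndarray) -> float:
    n_unc = int((~c).sum())
    if n_unc == 0:
        return np.inf
    return float(t.sum() / n_unc)


def _tau_curve(t: np.ndarray, c: np.ndarray) -> float:
    """Least-squares fit of P(t) = 1 - exp(-k t) to the empirical curve.

    Without censoring the empirical rupture probability is the ECDF of the
    dwell times; with censoring it is one minus the Kaplan-Meier survival
    estimate.
    """
    if (~c).sum() == 0:
        return np.inf
    if c.any():
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter()
        km.fit(t, event_observed=~c)
        grid = np.sort(t[~c])
        p = 1.0 - km.survival_function_at_times(grid).to_numpy()
    else:
        grid = np.sort(t)
        p = np.arange(1, len(grid) + 1) / len(grid)
    k0 = 1.0 / max(grid.mean(), 1e-12)
    popt, _ = curve_fit(
        lambda tt, k: 1.0 - np.exp(-k * tt), grid, p, p0=[k0], maxfev=10000
    )
    k = float(popt[0])
    if k <= 0:
        raise RuntimeError("rupture-probability fit returned a non-positive rate")
    return 1.0 / k


def fit_lifetime(dwells: Sequence[DwellRecord], estimator: str = "mle") -> LifetimeEstimate:
    """Point estimate of the characteristic lifetime at one force.

    The default censored-exponential MLE is
    ``tau = (sum of all dwells, censored included) / (number of ruptures)``.
    An all-censored sample yields ``tau = inf`` with the ``unbounded`` flag
    set rather than an error.
    """
    dwells = list(dwells)
    if not dwells:
        raise ValueError("need at least one dwell record")
    t, c, forces = _split_dwells(dwells)
    tau = _tau_mle(t, c) if estimator == "mle" else _tau_curve(t, c)
    unbounded = not np.isfinite(tau)
    return LifetimeEstimate(
        force=float(np.median(forces)),
        tau=tau,
        k_rupture=0.0 if unbounded else 1.0 / tau,
        n_obs=len(dwells),
        n_censored=int(c.sum()),
        unbounded=unbounded,
    )


def bootstrap_rates(
    dwells: Sequence[DwellRecord], cfg: BootstrapConfig = BootstrapConfig()
) -> LifetimeEstimate:
    """Bootstrap mean / sd / se of the rupture rate and lifetime.

    Draws ``M = cfg.n_resamples`` resamples of size N with replacement from
    the N observed dwells, re-fits each, and summarizes the pools of ``k``
    and ``tau = 1/k`` values separately. Resamples that cannot be fitted
    (all records censored) are redrawn and counted in the log.
    """
    dwells = list(dwells)
    if len(dwells) < 2:
        raise ValueError("bootstrap needs at least 2 dwell records")
    t, c, forces = _split_dwells(dwells)
    if (~c).sum() == 0:
        raise ValueError("cannot bootstrap an all-censored sample")
    n = len(dwells)
    rng = np.random.default_rng(cfg.rng_seed)
    estimator = _tau_mle if cfg.estimator == "mle" else _tau_curve
    taus = np.empty(cfg.n_resamples)
    redrawn = 0
    for m in range(cfg.n_resamples):
        while True:
            idx = rng.integers(0, n, size=n)
            tau = estimator(t[idx], c[idx])
            if np.isfinite(tau):
                break
            redrawn += 1
        taus[m] = tau
    if redrawn:
        logger.info("bootstrap: redrew %d degenerate (all-censored) resamples", redrawn)
    ks = 1.0 / taus
    M = cfg.n_resamples
    est = LifetimeEstimate(
        force=float(np.median(forces)),
        tau=float(taus.mean()),
        k_rupture=float(ks.mean()),
        n_obs=n,
        n_censored=int(c.sum()),
        tau_sd=float(taus.std(ddof=1)),
        tau_se=float(taus.std(ddof=1) / np.sqrt(M)),
        k_sd=float(ks.std(ddof=1)),
        k_se=float(ks.std(ddof=1) / np.sqrt(M)),
        bootstrap_k=ks,
    )
    return est


def fit_bell(
    points: Iterable[tuple[float, float, float | None]] | pd.DataFrame,
    env: PolymerEnvironment = DEFAULT_ENV,
) -> BellFit:
    """Weighted least-squares Bell fit of force-dependent rupture rates.

    ``points`` are (force, k_rupture, se_k) triples (se may be None) or a
    DataFrame with columns ``force_pN``, ``k_per_s`` and optionally
    ``k_se``. The fit is linear in log space:
    ``ln k = ln k0 + (delta / kBT) f``, weighted by the propagated
    ``se(ln k) = se_k / k`` when uncertainties are available.
    """
    if isinstance(points, pd.DataFrame):
        rows = [
            (r.force_pN, r.k_per_s, getattr(r, "k_se", None))
            for r in points.itertuples()
        ]
    else:
        rows = [(p[0], p[1], p[2] if len(p) > 2 else None) for p in points]
    if len(rows) < 2:
        raise ValueError("Bell fit needs rates at >= 2 forces")
    f = np.array([r[0] for r in rows], dtype=float)
    k = np.array([r[1] for r in rows], dtype=float)
    if np.any(k <= 0):
        raise ValueError("all rupture rates must be positive")
    ses = [r[2] for r in rows]
    have_se = all(s is not None and s > 0 for s in ses)
    y = np.log(k)
    X = np.column_stack([np.ones_like(f), f])
    import statsmodels.api as sm

    with np.errstate(divide="ignore", invalid="ignore"):
        if have_se:
            w = 1.0 / (np.array(ses, dtype=float) / k) ** 2
            res = sm.WLS(y, X, weights=w).fit()
            intercept, slope = res.params
            # The per-point variances are known (bootstrap-propagated), so
            # the parameter covariance is the unscaled (X' W X)^-1 rather
            # than the residual-rescaled estimate.
            cov = np.linalg.inv(X.T @ (w[:, None] * X))
        else:
            res = sm.OLS(y, X).fit()
            intercept, slope = res.params
            cov = np.asarray(res.cov_params())
    if len(rows) == 2:
        # Two points determine the line exactly; no residual dof.
        cov = np.zeros((2, 2))
    k0 = float(np.exp(intercept))
    delta = float(slope * env.kBT)
    k0_se = k0 * float(np.sqrt(max(cov[0, 0], 0.0)))
    delta_se = env.kBT * float(np.sqrt(max(cov[1, 1], 0.0)))
    return BellFit(
        params=BellParams(k0=k0, delta=delta),
        k0_se=k0_se,
        delta_se=delta_se,
        covariance=cov,
        n_points=len(rows),
    )


def fit_force_histogram(
    forces: Sequence[float], n_components: int = 1, rng_seed: int = 0
) -> list[GaussianPeak]:
    """Gaussian (mixture) fit of a rupture/refolding force distribution.

    Returns peaks sorted by ascending mean. One component uses the exact
    normal MLE; two components use an EM Gaussian mixture initialized from
    a sorted-sample split with a fixed seed.
    """
    forces = np.asarray(list(forces), dtype=float)
    if forces.size < 10:
        raise ValueError("need at least 10 forces for a histogram fit")
    if np.ptp(forces) == 0:
        raise ValueError("degenerate sample: all forces identical (sd = 0)")
    if n_components == 1:
        mu, sd = norm.fit(forces)
        return [GaussianPeak(mean=float(mu), sd=float(sd), weight=1.0)]
    if n_components == 2:
        from sklearn.mixture import GaussianMixture

        if np.unique(forces).size < 2:
            raise ValueError("fewer distinct forces than mixture components")
        gm = GaussianMixture(
            n_components=2, n_init=5, random_state=rng_seed, covariance_type="full"
        )
        gm.fit(forces.reshape(-1, 1))
        peaks = [
            GaussianPeak(
                mean=float(gm.means_[i, 0]),
                sd=float(np.sqrt(gm.covariances_[i, 0, 0])),
                weight=float(gm.weights_[i]),
            )
            for i in range(2)
        ]
        return sorted(peaks, key=lambda p: p.mean)
    raise ValueError("n_components must be 1 or 2")


def fit_redimerization(
    points: Iterable[tuple[float, float]],
    env: PolymerEnvironment = DEFAULT_ENV,
) -> RedimerCurve:
    """Fit the re-dimerization probability curve to (force, probability) data.

    ``P(F) = 1 / (exp((F - Fc) dx / kBT) + 1)``: a two-state Boltzmann
    sigmoid with half-transition force Fc and width set by dx. The fitted
    curve satisfies ``P(Fc) = 0.5`` exactly, and the rupture probability is
    its complement.
    """
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("re-dimerization fit needs >= 3 points")
    F = np.array([p[0] for p in pts], dtype=float)
    P = np.array([p[1] for p in pts], dtype=float)
    if np.any((P < 0) | (P > 1)):
        raise ValueError("probabilities must lie in [0, 1]")

    def curve(f, Fc, dx):
        return 1.0 / (np.exp((f - Fc) * dx / env.kBT) + 1.0)

    Fc0 = float(F[np.argmin(np.abs(P - 0.5))])
    popt, _ = curve_fit(curve, F, P, p0=[Fc0, 2.0], maxfev=20000)
    Fc, dx = float(popt[0]), float(abs(popt[1]))
    return RedimerCurve(Fc=Fc, delta_x=dx, kBT=env.kBT)


def fit_exponential_mixture(
    dwells: Sequence[float],
    n_components: int = 2,
    n_iter: int = 500,
    tol: float = 1e-10,
    rng_seed: int = 0,
) -> list[tuple[float, float]]:
    """EM fit of a mixture of exponentials to uncensored dwell times.

    Returns (rate, weight) pairs sorted by ascending rate. This automatic
    clustering of dwell sub-populations is a convenience beyond the manual
    per-cluster assignment used for the clustered-lifetime analyses.
    """
    t = np.asarray(list(dwells), dtype=float)
    if t.size < 2 * n_components:
        raise ValueError("too few dwells for the requested mixture")
    rng = np.random.default_rng(rng_seed)
    q = np.quantile(t, np.linspace(0.15, 0.85, n_components))
    rates = 1.0 / np.maximum(q, 1e-12) * rng.uniform(0.9, 1.1, n_components)
    weights = np.full(n_components, 1.0 / n_components)
    ll_old = -np.inf
    for _ in range(n_iter):
        dens = weights[:, None] * rates[:, None] * np.exp(-np.outer(rates, t))
        tot = dens.sum(axis=0)
        ll = float(np.log(tot).sum())
        resp = dens / tot
        weights = resp.mean(axis=1)
        rates = resp.sum(axis=1) / (resp * t).sum(axis=1)
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    order = np.argsort(rates)
    return [(float(rates[i]), float(weights[i])) for i in order]
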