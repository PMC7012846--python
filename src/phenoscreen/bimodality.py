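"""Bimodality screen: one von Mises mode or two?

A recurring failure mode in long-running phenological archives is that
one event name covers two distinct seasonal events — the classic case is
a bird's "first arrival" recorded both for spring and autumn migration.
Such series look bimodal on the annual circle.

The screen fits (i) a single von Mises distribution and (ii) a
two-component von Mises mixture by EM, compares them with BIC, and flags
a series as suspicious when the mixture wins by at least ``bic_threshold``
(default 5) AND the circular distance between the two fitted component
means exceeds ``sep_threshold_days`` (default 30 days).  Both gates must
hold: strong BIC support for two modes 20 days apart is treated as
seasonal spread, not mislabelling.

The same rule is applied at two levels: per (site, name, event type)
triplet, and per (name, event type) pair pooled over sites — the latter
catches names used for a spring event at some sites and an autumn event
at others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import i0e

from .circular import (
    KAPPA_MAX,
    CircularSample,
    angle_to_day,
    circ_dist_days,
    inv_bessel_ratio,
    vm_fit,
    vm_logpdf,
)
from .io import Database

__all__ = [
    "DEFAULT_BIC_THRESHOLD",
    "DEFAULT_SEP_DAYS",
    "DEFAULT_MIN_N_MIXTURE",
    "MixtureFit",
    "BimodalityReport",
    "bic",
    "fit_vm_mixture",
    "screen_bimodality",
    "screen_triplets",
    "screen_pairs",
    "bimodality_report_frame",
]

DEFAULT_BIC_THRESHOLD = 5.0
DEFAULT_SEP_DAYS = 30.0
DEFAULT_MIN_N_MIXTURE = 20
WEIGHT_FLOOR = 0.01
EM_TOL = 1e-8
EM_MAX_ITER = 500
DEFAULT_RESTARTS = 10

# parameter counts for BIC: single VM has (mu, kappa); the mixture adds
# a second component and a weight
K_SINGLE = 2
K_MIXTURE = 5


def bic(loglik: float, k_params: int, n: int) -> float:
    """Bayesian Information Criterion, k*ln(n) - 2*loglik (lower is better)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return k_params * np.log(n) - 2.0 * loglik


@dataclass(frozen=True)
class MixtureFit:
    """EM fit of a two-component von Mises mixture.

    ``w`` is the weight of component 1; components are exchangeable
    (label swap leaves the log-likelihood unchanged).
    """

    w: float
    mu1: float
    kappa1: float
    mu2: float
    kappa2: float
    loglik: float
    n_iter: int
    converged: bool
    best_of_restarts: int

    def mean_days(self, period: float = 365.25) -> tuple[float, float]:
        return (float(angle_to_day(self.mu1, period)),
                float(angle_to_day(self.mu2, period)))

    def separation_days(self, period: float = 365.25) -> float:
        d1, d2 = self.mean_days(period)
        return float(circ_dist_days(d1, d2, period))


@dataclass(frozen=True)
class BimodalityReport:
    """Single-vs-mixture comparison for one series or pooled pair.

    ``delta_bic = bic_single - bic_mixture`` (positive favours the
    mixture); ``flagged`` iff delta_bic >= bic_threshold and the
    component mean separation exceeds the day threshold.
    """

    key: tuple
    n: int
    bic_single: float | None
    bic_mixture: float | None
    delta_bic: float | None
    mean1_day: float | None
    mean2_day: float | None
    mean_separation_days: float | None
    flagged: bool
    skipped: bool = False
    mixture: MixtureFit | None = None


def _mixture_loglik(theta: np.ndarray, w, mu1, k1, mu2, k2) -> tuple[float, np.ndarray]:
    la = np.log(w) + vm_logpdf(theta, mu1, k1)
    lb = np.log1p(-w) + vm_logpdf(theta, mu2, k2)
    tot = np.logaddexp(la, lb)
    return float(tot.sum()), np.exp(np.vstack([la, lb]) - tot)


def _em_run(theta: np.ndarray, w, mu1, k1, mu2, k2,
            tol: float, max_iter: int, trace: list | None = None):
    """One EM run from a given start; returns params, loglik, iters, converged."""
    n = theta.size
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    log2pi = np.log(2.0 * np.pi)

    def comp_logpdf(mu, kappa):
        # kappa*(cos(theta - mu) - 1) - log(2*pi*i0e(kappa)), expanded so the
        # trig of theta is computed once per run
        return (kappa * (cos_t * np.cos(mu) + sin_t * np.sin(mu) - 1.0)
                - log2pi - np.log(i0e(kappa)))

    def eval_ll(w, mu1, k1, mu2, k2):
        la = np.log(w) + comp_logpdf(mu1, k1)
        lb = np.log1p(-w) + comp_logpdf(mu2, k2)
        tot = np.logaddexp(la, lb)
        return float(tot.sum()), np.exp(la - tot)

    ll, g1 = eval_ll(w, mu1, k1, mu2, k2)
    if trace is not None:
        trace.append(ll)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M-step: weighted circular MLE per component, weight update
        w = min(max(g1.sum() / n, WEIGHT_FLOOR), 1.0 - WEIGHT_FLOOR)
        params = []
        for g in (g1, 1.0 - g1):
            gs = g.sum()
            if gs <= 0:
                params.append(None)
                continue
            c = np.dot(g, cos_t) / gs
            s = np.dot(g, sin_t) / gs
            rbar = min(float(np.hypot(c, s)), 1.0)
            params.append((float(np.arctan2(s, c) % (2 * np.pi)),
                           inv_bessel_ratio(rbar, kappa_max=KAPPA_MAX)))
        if params[0] is not None:
            mu1, k1 = params[0]
        if params[1] is not None:
            mu2, k2 = params[1]
        new_ll, g1 = eval_ll(w, mu1, k1, mu2, k2)
        if trace is not None:
            trace.append(new_ll)
        if abs(new_ll - ll) <= tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    return (w, mu1, k1, mu2, k2), ll, it, converged


def _kde_peak_start(theta: np.ndarray, kernel_kappa: float = 20.0):
    """Deterministic start: the two strongest antipodal-ish peaks of a
    circular (von Mises kernel) density estimate on a fixed grid."""
    grid = np.linspace(0.0, 2 * np.pi, 256, endpoint=False)
    dens = np.exp(kernel_kappa * np.cos(grid[:, None] - theta[None, :])).sum(axis=1)
    i1 = int(np.argmax(dens))
    # second peak: best grid point at least a quarter circle from the first
    d = np.minimum(np.abs(grid - grid[i1]), 2 * np.pi - np.abs(grid - grid[i1]))
    far = d >= np.pi / 2
    i2 = int(np.argmax(np.where(far, dens, -np.inf))) if far.any() else (i1 + 128) % 256
    return 0.5, float(grid[i1]), 5.0, float(grid[i2]), 5.0


def fit_vm_mixture(sample: CircularSample, restarts: int = DEFAULT_RESTARTS,
                   tol: float = EM_TOL, max_iter: int = EM_MAX_ITER,
                   seed: int | None = 0,
                   min_n: int = DEFAULT_MIN_N_MIXTURE) -> MixtureFit | None:
    """Fit a two-component von Mises mixture by EM, best of several starts.

    Each random restart splits the sample by a random diameter through
    the circle's centre and fits one component per arc; one additional
    deterministic start is taken from the two strongest well-separated
    peaks of a circular kernel density estimate.  The accepted iteration
    sequence is monotone in log-likelihood up to the convergence
    tolerance; weights are floored at 0.01 and kappa capped at 500 to
    rule out degenerate one-point spikes.

    Returns ``None`` for samples smaller than ``min_n`` (too few points
    for five parameters).
    """
    theta = sample.angles
    n = theta.size
    if n < min_n:
        return None
    rng = np.random.default_rng(seed)
    starts = [_kde_peak_start(theta)]
    for _ in range(restarts):
        phi = rng.uniform(0.0, 2 * np.pi)
        side = np.sin(theta - phi) >= 0.0
        if side.all() or (~side).all():
            # diameter missed the data spread; push one point across
            side = side.copy()
            i_flip = rng.integers(n)
            side[i_flip] = ~side[i_flip]
        f1 = vm_fit(CircularSample(sample.days[side], sample.period))
        f2 = vm_fit(CircularSample(sample.days[~side], sample.period))
        w0 = min(max(side.mean(), WEIGHT_FLOOR), 1 - WEIGHT_FLOOR)
        starts.append((w0, f1.mu, min(f1.kappa, KAPPA_MAX),
                       f2.mu, min(f2.kappa, KAPPA_MAX)))

    best = None
    for s_idx, start in enumerate(starts):
        params, ll, it, conv = _em_run(theta, *start, tol=tol, max_iter=max_iter)
        if best is None or ll > best[1]:
            best = (params, ll, it, conv, s_idx)
    (w, mu1, k1, mu2, k2), ll, it, conv, s_idx = best
    return MixtureFit(w=w, mu1=mu1, kappa1=k1, mu2=mu2, kappa2=k2,
                      loglik=ll, n_iter=it, converged=conv,
                      best_of_restarts=s_idx)


def screen_bimodality(sample: CircularSample,
                      bic_threshold: float = DEFAULT_BIC_THRESHOLD,
                      sep_threshold_days: float = DEFAULT_SEP_DAYS,
                      min_n: int = DEFAULT_MIN_N_MIXTURE,
                      restarts: int = DEFAULT_RESTARTS,
                      seed: int | None = 0,
                      key: tuple = ()) -> BimodalityReport:
    """Apply the two-gate bimodality rule to one date series."""
    n = len(sample)
    if n < min_n:
        return BimodalityReport(key=key, n=n, bic_single=None,
                                bic_mixture=None, delta_bic=None,
                                mean1_day=None, mean2_day=None,
                                mean_separation_days=None,
                                flagged=False, skipped=True)
    single = vm_fit(sample)
    mix = fit_vm_mixture(sample, restarts=restarts, seed=seed, min_n=min_n)
    bic_s = bic(single.loglik, K_SINGLE, n)
    bic_m = bic(mix.loglik, K_MIXTURE, n)
    delta = bic_s - bic_m
    d1, d2 = mix.mean_days(sample.period)
    sep = mix.separation_days(sample.period)
    flagged = (delta >= bic_threshold) and (sep > sep_threshold_days)
    return BimodalityReport(key=key, n=n, bic_single=float(bic_s),
                            bic_mixture=float(bic_m), delta_bic=float(delta),
                            mean1_day=d1, mean2_day=d2,
                            mean_separation_days=sep, flagged=flagged,
                            mixture=mix)


def _grouped_clean(db: Database, by: list[str]):
    rec = db.records
    usable = (rec["quality"].fillna("") == "") & rec["dayofyear"].notna()
    sub = rec.loc[usable]
    pos = pd.Series(np.flatnonzero(usable.to_numpy()), index=sub.index)
    for key, grp in sub.groupby(by, sort=True):
        key = (key,) if isinstance(key, str) else tuple(key)
        yield key, pos.loc[grp.index].to_numpy()


def _screen_grouped(db: Database, by: list[str], period: float,
                    seed: int | None, **kwargs) -> list[BimodalityReport]:
    days_all = db.records["dayofyear"].to_numpy(dtype=float, na_value=np.nan)
    reports = []
    for i, (key, rows) in enumerate(_grouped_clean(db, by)):
        subseed = None if seed is None else seed + i
        sample = CircularSample(days_all[rows], period=period)
        reports.append(screen_bimodality(sample, seed=subseed, key=key, **kwargs))
    return reports


def screen_triplets(db: Database, period: float = 365.25,
                    seed: int | None = 0, **kwargs) -> list[BimodalityReport]:
    """Bimodality screen per (study site, name, event type) triplet."""
    return _screen_grouped(db, ["studysite", "taxon", "eventtype"],
                           period, seed, **kwargs)


def screen_pairs(db: Database, period: float = 365.25,
                 seed: int | None = 0, **kwargs) -> list[BimodalityReport]:
    """Bimodality screen per (name, event type) pair, pooled over sites.

    Catches event names whose meaning differs across sites (e.g. spring
    at some sites, autumn at others), which triplet-level screening
    cannot see.
    """
    return _screen_grouped(db, ["taxon", "eventtype"], period, seed, **kwargs)


def bimodality_report_frame(reports: list[BimodalityReport]) -> pd.DataFrame:
    """One row per screened series/pair with the quantities behind the call."""
    rows = []
    for r in reports:
        rows.append({
            **{f"key_{i}": k for i, k in enumerate(r.key)},
            "n": r.n,
            "bic_single": r.bic_single,
            "bic_mixture": r.bic_mixture,
            "delta_bic": r.delta_bic,
            "mean1_day": r.mean1_day,
            "mean2_day": r.mean2_day,
            "separation_days": r.mean_separation_days,
            "flagged": r.flagged,
            "skipped": r.skipped,
        })
    return pd.DataFrame(rows)
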