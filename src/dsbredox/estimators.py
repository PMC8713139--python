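"""Free-energy estimators for paired forward/backward work distributions.

Two estimators of the free-energy difference between the alchemical end
states are provided, both rooted in the Crooks fluctuation theorem
P_F(W) / P_B(-W) = exp(beta (W - dG)):

* **CGI** (Crooks Gaussian Intersection): fit Gaussians to the forward
  works and to the negated backward works; dG is the abscissa where the two
  fitted densities intersect.  For equal variances this reduces to the
  midpoint of the two means.
* **BAR** (Bennett acceptance ratio): the maximum-likelihood estimate, the
  unique root of a self-consistent equation in the Fermi function
  f(t) = 1 / (1 + e^t).

Uncertainties come from a paired bootstrap (each direction resampled
independently, with replacement).  Overlap and normality diagnostics screen
for the failure mode both estimators share: forward and reverse work
distributions that barely overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .constants import beta as beta_of_T
from .work_io import WorkSet

EstimatorName = Literal["cgi", "bar"]


class EstimationError(RuntimeError):
    """Raised when an estimator cannot produce a defined answer."""


@dataclass(frozen=True)
class GaussianFit:
    """Sample mean / unbiased sd of one work distribution (kJ/mol)."""

    mean: float
    sd: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class OverlapReport:
    """Diagnostics for a forward/backward work-distribution pair.

    bhattacharyya: overlap coefficient of the two fitted Gaussians in [0, 1]
    (1 = identical).  ks_p_*: one-sample Kolmogorov-Smirnov p-value of each
    direction's works against its own fitted Gaussian — an approximate
    normality screen, since the null uses fitted parameters.  mean_gap:
    forward mean minus negated-backward mean, i.e. the total dissipated work
    across both switching directions.
    """

    bhattacharyya: float
    ks_p_forward: float
    ks_p_backward: float
    mean_gap: float
    warning: str | None = None


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A dG estimate (kJ/mol) with provenance and diagnostics."""

    dG: float
    method: str
    n_forward: int
    n_backward: int
    beta: float
    se: float | None = None
    diagnostics: OverlapReport | None = None

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.se is not None and self.se < 0:
            raise ValueError("se must be non-negative")


def fit_gaussian(ws: WorkSet) -> GaussianFit:
    """Sample mean and unbiased (n-1) standard deviation of a work set."""
    if ws.n < 2:
        raise EstimationError(f"need >=2 samples to fit, got {ws.n}")
    mean = float(np.mean(ws.works))
    sd = float(np.std(ws.works, ddof=1))
    return GaussianFit(mean=mean, sd=sd, n=ws.n, degenerate=(sd == 0.0))


def _check_pair(forward: WorkSet, backward: WorkSet) -> float:
    if forward.direction != "forward" or backward.direction != "backward":
        raise EstimationError("expected a (forward, backward) work-set pair")
    if forward.n < 2 or backward.n < 2:
        raise EstimationError("need >=2 samples in each direction")
    if forward.temperature != backward.temperature:
        raise EstimationError(
            "forward/backward temperatures differ: "
            f"{forward.temperature} vs {backward.temperature}"
        )
    return beta_of_T(forward.temperature)


def _gaussian_intersection(
    mu_f: float, sd_f: float, mu_r: float, sd_r: float
) -> tuple[float, str | None]:
    """Intersection abscissa of two normal densities, with root policy.

    Equal variances give the exact midpoint.  Otherwise the quadratic
    (1/sd_f^2 - 1/sd_r^2) x^2 - 2 (mu_f/sd_f^2 - mu_r/sd_r^2) x
      + (mu_f^2/sd_f^2 - mu_r^2/sd_r^2) - 2 ln(sd_r/sd_f) = 0
    is solved; the root inside [min(mu), max(mu)] is preferred, and when
    zero or two roots fall inside, the one nearest the midpoint is taken and
    a warning is set.  Complex roots fall back to the midpoint.
    """
    midpoint = 0.5 * (mu_f + mu_r)
    if sd_f == sd_r:
        return midpoint, None
    a = 1.0 / sd_f**2 - 1.0 / sd_r**2
    b = -2.0 * (mu_f / sd_f**2 - mu_r / sd_r**2)
    c = mu_f**2 / sd_f**2 - mu_r**2 / sd_r**2 - 2.0 * np.log(sd_r / sd_f)
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return midpoint, "complex intersection roots; fell back to midpoint"
    sq = np.sqrt(disc)
    roots = np.array([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    lo, hi = min(mu_f, mu_r), max(mu_f, mu_r)
    inside = roots[(roots >= lo) & (roots <= hi)]
    if inside.size == 1:
        return float(inside[0]), None
    pool = inside if inside.size else roots
    pick = float(pool[np.argmin(np.abs(pool - midpoint))])
    which = "both" if inside.size == 2 else "no"
    return pick, f"{which} intersection roots inside [mu_r, mu_f]; took nearest midpoint"


def cgi_estimate(forward: WorkSet, backward: WorkSet) -> FreeEnergyEstimate:
    """Crooks Gaussian Intersection estimate of dG.

    Backward works are negated into the forward frame before fitting.
    Raises :class:`EstimationError` if either fitted sd is degenerate.
    """
    beta = _check_pair(forward, backward)
    fit_f = fit_gaussian(forward)
    fit_r = fit_gaussian(
        WorkSet(backward.label, "forward", -backward.works, backward.temperature)
    )
    if fit_f.degenerate or fit_r.degenerate:
        raise EstimationError("degenerate (zero-sd) work distribution; CGI undefined")
    dg, warning = _gaussian_intersection(fit_f.mean, fit_f.sd, fit_r.mean, fit_r.sd)
    diag = overlap_diagnostics(forward, backward)
    if warning is not None:
        diag = OverlapReport(
            diag.bhattacharyya, diag.ks_p_forward, diag.ks_p_backward,
            diag.mean_gap, warning,
        )
    return FreeEnergyEstimate(
        dG=dg, method="CGI", n_forward=forward.n, n_backward=backward.n,
        beta=beta, diagnostics=diag,
    )


def bar_objective(
    dg: float | np.ndarray, w_f: np.ndarray, w_rtilde: np.ndarray, beta: float
) -> float | np.ndarray:
    """Self-consistency function whose unique root is the BAR estimate.

    With f(t) = 1/(1+e^t), M = ln(n_F/n_B) and W~ the negated backward
    works: g(dG) = sum_i f(M + beta (W_F,i - dG)) - sum_j f(-M + beta (dG - W~_j)).
    g is strictly monotone in dG (from -n_B to +n_F), so the root is unique
    whenever the two work distributions overlap at all.
    """
    m = np.log(w_f.size / w_rtilde.size)
    scalar = np.isscalar(dg) or np.ndim(dg) == 0
    dg_arr = np.atleast_1d(np.asarray(dg, dtype=float))
    fwd = expit(-(m + beta * (w_f[:, None] - dg_arr[None, :]))).sum(axis=0)
    rev = expit(-(-m + beta * (dg_arr[None, :] - w_rtilde[:, None]))).sum(axis=0)
    out = fwd - rev
    return float(out[0]) if scalar else out


def bar_estimate(
    forward: WorkSet, backward: WorkSet, tol: float = 1e-8
) -> FreeEnergyEstimate:
    """Bennett acceptance ratio estimate of dG, by bracketed root finding.

    The initial bracket is [min - 50, max + 50] kJ/mol over all works in the
    forward frame.  Non-overlapping work distributions are reported as an
    :class:`EstimationError`: either the bracket shows no sign change, or
    the objective underflows to a flat zero plateau around the root (both
    Fermi sums vanish between the two clusters), leaving dG undetermined.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    beta = _check_pair(forward, backward)
    w_f = forward.works
    w_rt = -backward.works
    allw = np.concatenate([w_f, w_rt])
    lo, hi = float(allw.min() - 50.0), float(allw.max() + 50.0)
    g_lo = bar_objective(lo, w_f, w_rt, beta)
    g_hi = bar_objective(hi, w_f, w_rt, beta)
    if np.sign(g_lo) == np.sign(g_hi):
        raise EstimationError(
            "BAR objective has no sign change on the bracket; forward and "
            "backward work distributions do not overlap"
        )
    root = optimize.brentq(
        lambda x: bar_objective(x, w_f, w_rt, beta), lo, hi, xtol=tol
    )
    delta = 0.5
    if max(
        abs(bar_objective(root - delta, w_f, w_rt, beta)),
        abs(bar_objective(root + delta, w_f, w_rt, beta)),
    ) < 1e-10:
        raise EstimationError(
            "BAR objective is numerically flat around the root; forward and "
            "backward work distributions do not overlap"
        )
    try:
        diag: OverlapReport | None = overlap_diagnostics(forward, backward)
    except EstimationError:
        diag = None  # degenerate sd: BAR itself is still well defined
    return FreeEnergyEstimate(
        dG=float(root), method="BAR", n_forward=forward.n, n_backward=backward.n,
        beta=beta, diagnostics=diag,
    )


_ESTIMATORS: dict[str, Callable[[WorkSet, WorkSet], FreeEnergyEstimate]] = {
    "cgi": cgi_estimate,
    "bar": bar_estimate,
}


def get_estimator(name: EstimatorName) -> Callable[[WorkSet, WorkSet], FreeEnergyEstimate]:
    try:
        return _ESTIMATORS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown estimator {name!r}; choose from {sorted(_ESTIMATORS)}")


def _cgi_batch(f_mat: np.ndarray, rt_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise CGI over resample matrices; returns (estimates, failed mask).

    Implements the same intersection-and-root-selection policy as
    :func:`cgi_estimate`, vectorized.  Degenerate (zero-sd) rows are failures.
    """
    mu_f, sd_f = f_mat.mean(axis=1), f_mat.std(axis=1, ddof=1)
    mu_r, sd_r = rt_mat.mean(axis=1), rt_mat.std(axis=1, ddof=1)
    failed = (sd_f == 0.0) | (sd_r == 0.0)
    sd_f, sd_r = np.where(failed, 1.0, sd_f), np.where(failed, 1.0, sd_r)
    mid = 0.5 * (mu_f + mu_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = 1.0 / sd_f**2 - 1.0 / sd_r**2
        b = -2.0 * (mu_f / sd_f**2 - mu_r / sd_r**2)
        c = mu_f**2 / sd_f**2 - mu_r**2 / sd_r**2 - 2.0 * np.log(sd_r / sd_f)
        disc = b * b - 4.0 * a * c
        equal_var = a == 0.0
        safe_a = np.where(equal_var, 1.0, a)
        sq = np.sqrt(np.maximum(disc, 0.0))
        roots = np.stack([(-b - sq) / (2 * safe_a), (-b + sq) / (2 * safe_a)])
        lo, hi = np.minimum(mu_f, mu_r), np.maximum(mu_f, mu_r)
        inside = (roots >= lo) & (roots <= hi)
        dist = np.abs(roots - mid)
        masked = np.where(inside, dist, np.inf)
        use_masked = inside.any(axis=0)
        pick = np.where(use_masked, np.argmin(masked, axis=0), np.argmin(dist, axis=0))
        chosen = roots[pick, np.arange(roots.shape[1])]
    out = np.where(equal_var | (disc < 0.0), mid, chosen)
    return out, failed


def _bar_batch(
    f_mat: np.ndarray, rt_mat: np.ndarray, beta: float, n_iter: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise BAR over resample matrices by vectorized bisection.

    Rows whose objective shows no sign change on the +-50 kJ/mol bracket
    (non-overlapping resample) are failures.
    """
    m = np.log(f_mat.shape[1] / rt_mat.shape[1])

    def g(x: np.ndarray) -> np.ndarray:
        fwd = expit(-(m + beta * (f_mat - x[:, None]))).sum(axis=1)
        rev = expit(-(-m + beta * (x[:, None] - rt_mat))).sum(axis=1)
        return fwd - rev

    lo = np.minimum(f_mat.min(axis=1), rt_mat.min(axis=1)) - 50.0
    hi = np.maximum(f_mat.max(axis=1), rt_mat.max(axis=1)) + 50.0
    failed = np.sign(g(lo)) == np.sign(g(hi))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        below = g(mid) < 0.0
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi), failed


def bootstrap_se(
    forward: WorkSet,
    backward: WorkSet,
    estimator: EstimatorName = "bar",
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Bootstrap standard error of a dG estimator (kJ/mol).

    Each direction is resampled independently with replacement; the SE is
    the ddof-1 standard deviation of the estimator over ``n_boot`` paired
    resamples (vectorized over resamples).  Deterministic given ``seed``.
    If the estimator fails on more than 10 % of resamples an
    :class:`EstimationError` carries the failure count; occasional failures
    are dropped from the SE.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    beta = _check_pair(forward, backward)
    rng = np.random.default_rng(seed)
    f_mat = forward.works[rng.integers(0, forward.n, size=(n_boot, forward.n))]
    rt_mat = -backward.works[rng.integers(0, backward.n, size=(n_boot, backward.n))]
    name = estimator.lower()
    if name == "cgi":
        values, failed = _cgi_batch(f_mat, rt_mat)
    elif name == "bar":
        values, failed = _bar_batch(f_mat, rt_mat, beta)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    n_failed = int(failed.sum())
    if n_failed > 0.1 * n_boot:
        raise EstimationError(
            f"estimator failed on {n_failed}/{n_boot} bootstrap resamples"
        )
    return float(np.std(values[~failed], ddof=1))


def overlap_diagnostics(forward: WorkSet, backward: WorkSet) -> OverlapReport:
    """Overlap and approximate-normality screens for a work-set pair.

    The Bhattacharyya coefficient of two normals N(m1, s1^2), N(m2, s2^2)
    has the closed form sqrt(2 s1 s2 / (s1^2 + s2^2)) *
    exp(-(m1 - m2)^2 / (4 (s1^2 + s2^2))).
    """
    _check_pair(forward, backward)
    fit_f = fit_gaussian(forward)
    neg = WorkSet(backward.label, "forward", -backward.works, backward.temperature)
    fit_r = fit_gaussian(neg)
    if fit_f.degenerate or fit_r.degenerate:
        raise EstimationError("degenerate work distribution; overlap undefined")
    s2 = fit_f.sd**2 + fit_r.sd**2
    bc = float(
        np.sqrt(2.0 * fit_f.sd * fit_r.sd / s2)
        * np.exp(-((fit_f.mean - fit_r.mean) ** 2) / (4.0 * s2))
    )
    ks_f = stats.kstest(forward.works, "norm", args=(fit_f.mean, fit_f.sd)).pvalue
    ks_b = stats.kstest(neg.works, "norm", args=(fit_r.mean, fit_r.sd)).pvalue
    return OverlapReport(
        bhattacharyya=bc,
        ks_p_forward=float(ks_f),
        ks_p_backward=float(ks_b),
        mean_gap=fit_f.mean - fit_r.mean,
    )
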