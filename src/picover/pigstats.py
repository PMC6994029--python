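"""Chromatophore-index statistics and the PiC ~ CI beta-regression model.

The traditional Chromatophore Index (CI, also Melanophore Index for melanin)
scores each chromatophore/chromatosome on the 5-class Hogben–Slome ordinal
scale (1 = fully punctate, 5 = fully dispersed) and averages the classes over
a region.  Pigment cover (PiC) is a fraction in (0, 1), so the two methods
are compared with a beta regression: PiC ~ Beta(μφ, (1−μ)φ) with
g(μ) = β0 + β1·CI for a link g ∈ {logit, log, log–log}, selected by AIC.

On brown-shrimp (*Crangon crangon*) exopod images the fitted log-link model
is ln(PiC) = −3.362 + 0.659·CI, valid for 1 ≤ CI ≤ 5; that calibration is
exposed by :func:`predict_pic_from_ci` and reused as ground truth by the
simulation-based recovery checks.

Supporting comparison statistics: Friedman's test for inter-observer
variation (repeated measures, ordinal/proportion data), the Wilcoxon
signed-rank test for paired background comparisons, and ordinary
least-squares concordance between sRGB and linearized measurements.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

# Reference calibration fitted on 50 brown-shrimp exopod images
# (log link): ln(predicted PiC) = intercept + slope * CI.
DARK_PIC_INTERCEPT = -3.362
DARK_PIC_SLOPE = 0.659
CI_MIN, CI_MAX = 1.0, 5.0


@dataclass(frozen=True)
class CIRecord:
    """A region's chromatophore index: mean Hogben–Slome class, or 5 when
    overlap makes individual chromatosomes uncountable."""

    classifications: tuple[int, ...]
    overlap_flag: bool
    ci: float

    def __post_init__(self) -> None:
        if not CI_MIN <= self.ci <= CI_MAX:
            raise ValueError("ci must lie in [1, 5]")


def compute_ci(
    classifications: Sequence[int] | None, overlap_flag: bool = False
) -> CIRecord:
    """Average the per-chromatosome classes; heavily overlapping regions where
    chromatosomes cannot be told apart take the maximum index 5."""
    cls = tuple(classifications) if classifications else ()
    if overlap_flag:
        return CIRecord(cls, True, CI_MAX)
    if not cls:
        raise ValueError("no classifications given and overlap_flag not set")
    if any(c not in (1, 2, 3, 4, 5) for c in cls):
        raise ValueError("classes must be integers in 1..5")
    return CIRecord(cls, False, float(np.mean(cls)))


def predict_pic_from_ci(ci: float) -> float:
    """Predicted dark-pigment cover fraction for a chromatophore index.

    Evaluates ``exp(−3.362 + 0.659·ci)``, the log-link calibration above,
    clamped to [0, 1] (clamping is logged if it fires).  Valid only for
    1 ≤ ci ≤ 5.
    """
    if not CI_MIN <= ci <= CI_MAX:
        raise ValueError(
            f"ci={ci} outside the calibrated domain [1, 5]; the model is "
            "only valid for 1 <= CI <= 5"
        )
    raw = math.exp(DARK_PIC_INTERCEPT + DARK_PIC_SLOPE * ci)
    if raw > 1.0:
        logger.warning("predicted PiC %.4f clamped to 1.0 at ci=%.3f", raw, ci)
        return 1.0
    return raw


# ---------------------------------------------------------------------------
# Beta regression with link selection.

class Link(Enum):
    """Mean link functions; enum order is the AIC tie-break order."""

    LOGIT = "logit"
    LOG = "log"
    LOGLOG = "loglog"


def _link_fn(link: Link):
    if link is Link.LOGIT:
        return special.logit, special.expit
    if link is Link.LOG:
        return np.log, np.exp
    # log–log: g(mu) = −ln(−ln mu), the convention of the betareg-style links
    return (
        lambda mu: -np.log(-np.log(mu)),
        lambda eta: np.exp(-np.exp(-eta)),
    )


@dataclass(frozen=True)
class BetaRegFit:
    link: Link
    beta: tuple[float, float]  # (intercept, slope) on the link scale
    phi: float
    loglik: float
    aic: float
    pseudo_r2: float
    n_obs: int
    converged: bool

    @property
    def intercept(self) -> float:
        return self.beta[0]

    @property
    def slope(self) -> float:
        return self.beta[1]


def _adjust_boundaries(y: np.ndarray) -> np.ndarray:
    """Shrink {0,1} responses off the boundary: y* = (y(n−1)+0.5)/n.

    The beta likelihood is undefined at exactly 0 or 1; this is the usual
    compression applied to every observation when any boundary value occurs.
    """
    n = y.size
    logger.info("boundary PiC values present; compressed with y*=(y(n-1)+0.5)/n")
    return (y * (n - 1) + 0.5) / n


def _beta_nll(params: np.ndarray, X: np.ndarray, y: np.ndarray, ginv) -> float:
    beta, tau = params[:2], params[2]
    if abs(tau) > 25:  # phi overflow guard
        return 1e10
    eta = X @ beta
    mu = ginv(eta)
    if not np.all((mu > 1e-12) & (mu < 1 - 1e-12)):
        return 1e10
    phi = math.exp(tau)
    a, b = mu * phi, (1.0 - mu) * phi
    ll = np.sum(
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )
    return -ll if np.isfinite(ll) else 1e10


def fit_beta_regression(
    pic: Sequence[float], ci: Sequence[float], link: Link = Link.LOG
) -> BetaRegFit:
    """Maximum-likelihood beta regression of cover fractions on a predictor.

    The beta density is parameterized by mean μ and precision φ with
    g(μ) = β0 + β1·ci.  Returns coefficients, φ, log-likelihood,
    AIC = −2·loglik + 2·3, and pseudo-R² (squared Pearson correlation between
    the link-transformed, boundary-adjusted response and the linear
    predictor).

    Starting values: OLS of g(y) on the predictor for β and a
    method-of-moments estimate for φ; optimization is a deterministic
    Nelder–Mead descent from that start, so refits on identical data are
    bit-identical.
    """
    y = np.asarray(pic, dtype=np.float64)
    x = np.asarray(ci, dtype=np.float64)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("pic and ci must be 1-D sequences of equal length")
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 observations to fit 3 parameters")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope is unidentifiable")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("pic values must lie in [0, 1]")
    if np.any((y == 0) | (y == 1)):
        y = _adjust_boundaries(y)

    g, ginv = _link_fn(link)
    X = np.column_stack([np.ones(n), x])
    # start: link-scale OLS for beta, moments for phi
    gy = g(y)
    beta0, *_ = np.linalg.lstsq(X, gy, rcond=None)
    mu0 = np.clip(ginv(X @ beta0), 1e-6, 1 - 1e-6)
    resid_var = max(np.var(y - mu0, ddof=2), 1e-8)
    phi0 = max(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0, 1.0)
    start = np.array([beta0[0], beta0[1], math.log(phi0)])

    res = optimize.minimize(
        _beta_nll,
        start,
        args=(X, y, ginv),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 20000, "maxfev": 20000},
    )
    if not res.success or res.fun >= 1e9:
        raise RuntimeError(
            f"beta regression did not converge (link={link.value}): {res.message}"
        )
    beta = (float(res.x[0]), float(res.x[1]))
    phi = math.exp(res.x[2])
    loglik = -float(res.fun)
    aic = -2.0 * loglik + 2.0 * 3
    eta_hat = X @ res.x[:2]
    r = np.corrcoef(g(y), eta_hat)[0, 1]
    return BetaRegFit(link, beta, phi, loglik, aic, float(r**2), n, True)


def compare_links_aic(
    pic: Sequence[float], ci: Sequence[float]
) -> list[tuple[BetaRegFit, float]]:
    """Fit all three links and rank ascending by AIC.

    Returns ``(fit, delta_aic)`` pairs, ``delta_aic`` relative to the best
    link.  Exact AIC ties fall back to the fixed enum order
    (logit, log, log–log).
    """
    order = {lk: i for i, lk in enumerate(Link)}
    fits = [fit_beta_regression(pic, ci, lk) for lk in Link]
    fits.sort(key=lambda f: (f.aic, order[f.link]))
    best = fits[0].aic
    return [(f, f.aic - best) for f in fits]


# ---------------------------------------------------------------------------
# Nonparametric comparison statistics.

def friedman_test(table: np.ndarray) -> tuple[float, int, float]:
    """Friedman's rank test for a blocks × treatments table.

    Within-block mid-ranks with the standard tie correction:
    ``χ² = (k−1)·Σ_j (R_j − n(k+1)/2)² / (A − C)`` where A = Σ r_ij² and
    C = n·k·(k+1)²/4; df = k−1; p from the χ² distribution.  Unlike the
    common k ≥ 3 implementations this form also handles k = 2 treatments.
    """
    tbl = np.asarray(table, dtype=np.float64)
    if tbl.ndim != 2:
        raise ValueError("need a 2-D blocks × treatments table")
    n, k = tbl.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 treatments and 2 blocks")
    if np.unique(tbl).size < 2:
        raise ValueError("table is constant: no ranking information")
    ranks = np.apply_along_axis(stats.rankdata, 1, tbl)
    rj = ranks.sum(axis=0)
    a = float((ranks**2).sum())
    c = n * k * (k + 1) ** 2 / 4.0
    df = k - 1
    if a == c:  # every block fully tied; no evidence of treatment differences
        return 0.0, df, 1.0
    chi2 = (k - 1) * float(((rj - n * (k + 1) / 2.0) ** 2).sum()) / (a - c)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def wilcoxon_signed_rank(
    paired_a: Sequence[float],
    paired_b: Sequence[float],
    method: str = "approx",
) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples, reported as (Z, p).

    Zero differences are dropped; |differences| are mid-ranked.  Z uses the
    normal approximation with tie-corrected variance and *no* continuity
    correction; positive Z means ``paired_a`` tends to exceed ``paired_b``.
    ``method="exact"`` replaces the p-value with the exact signed-rank
    distribution (no ties across |d| assumed by that variant).
    """
    a = np.asarray(paired_a, dtype=np.float64)
    b = np.asarray(paired_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 non-zero differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, t_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float((t_counts**3 - t_counts).sum()) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        raise ValueError("degenerate variance: all |differences| tied to zero")
    z = (w_plus - mu) / math.sqrt(sigma2)
    if method == "approx":
        p = 2.0 * stats.norm.sf(abs(z))
    elif method == "exact":
        p = _wilcoxon_exact_p(ranks, w_plus)
    else:
        raise ValueError("method must be 'approx' or 'exact'")
    return z, float(min(p, 1.0))


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    n = ranks.size
    if n > 20:
        raise ValueError("exact method limited to 20 non-zero differences")
    total = ranks.sum()
    ge = sum(
        1
        for signs in itertools.product((0.0, 1.0), repeat=n)
        for w in (float(np.dot(signs, ranks)),)
        if min(w, total - w) <= min(w_plus, total - w_plus)
    )
    return ge / 2.0**n  # two-sided: mass of both tails at least as extreme


def linear_concordance(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """OLS of y on x, returned as (slope, intercept, r²).

    Used to compare PiC measured on sRGB images against linearized/normalized
    images: a slope near 1 with high r² indicates the two pipelines agree.
    """
    xv = np.asarray(x, dtype=np.float64)
    yv = np.asarray(y, dtype=np.float64)
    if xv.shape != yv.shape or xv.ndim != 1 or xv.size < 3:
        raise ValueError("need at least 3 (x, y) pairs")
    if np.ptp(xv) == 0:
        raise ValueError("constant x: slope undefined")
    fit = stats.linregress(xv, yv)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
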