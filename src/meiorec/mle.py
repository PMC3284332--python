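"""Joint likelihood for the conversion DSB rate and geometric tract length.

Model
-----
Noncrossover conversion DSBs fall on a chromatid as a Poisson process with
rate ``lambda`` per bp per transmitted chromatid.  From a DSB the conversion
tract extends independently leftward and rightward; each one-sided extension
L is geometric with cessation probability ``p``::

    P(L = l) = (1 - p)^l p,        mean (1 - p) / p

Data are of two kinds.  (1) Spans: gaps of length ``a`` between adjacent
genotyped markers showing no conversion.  Truncating at one DSB per span
(the zero- and one-DSB Poisson terms only), the span probability is

    P_noGC(a) = e^{-a lam} + a lam e^{-a lam} * (1/a) *
                sum_{k=1..a} P_k(left tract misses distal flank)
                           * P_k(right tract misses proximal flank)

where the DSB ordinate k is at distance k from the distal flanking marker
and a - k + 1 from the proximal one, and a tract reaches a marker when its
extension is at least that distance (the DSB site itself counts as
converted).  (2) Observed conversions: within the span ``i`` between the
outer nonconverted markers, a single DSB at ordinate k must extend far
enough to cover every converted marker on each side without reaching the
flanking nonconverted marker.

The inner sums have closed geometric forms, so a full likelihood over a
span histogram with b = 10,000 costs O(b) per parameter pair.

The joint MLE is found by a log-spaced grid search refined with
Nelder-Mead; interval estimates are the parameter values at which the
ln-likelihood falls two units below the maximum with the other parameter
held at its MLE, and nested hypotheses about the genome-wide number of
recombination events are compared with a chi-square likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .detect import ConversionEvent, SpanHistogram

__all__ = [
    "GCModelParams",
    "GCConformation",
    "LikelihoodFit",
    "DerivedRates",
    "tract_pmf",
    "tract_cdf",
    "p_no_gc_span",
    "p_gc_conformation",
    "log_likelihood",
    "fit",
    "profile_ci",
    "likelihood_ratio_test",
    "derived_rates",
    "conformations_from_events",
]

X_ARM_LENGTH = 22_400_000
GENOME_EUCHROMATIC_LENGTH = 119_000_000
CO_PER_MEIOSIS = 5.0


@dataclass(frozen=True)
class GCModelParams:
    """lambda: DSB rate per nucleotide per transmitted chromatid; p: per-step
    cessation probability of the geometric tract extension."""

    dsb_rate: float
    tract_p: float

    def __post_init__(self) -> None:
        if self.dsb_rate < 0:
            raise ValueError("dsb_rate must be >= 0")
        if not (0.0 < self.tract_p <= 1.0):
            raise ValueError("tract_p must be in (0, 1]")

    @property
    def one_sided_mean_tract(self) -> float:
        return (1.0 - self.tract_p) / self.tract_p


@dataclass(frozen=True)
class GCConformation:
    """Observed conversion geometry: span ``i`` between the outer
    nonconverted markers, with the first/last converted markers at
    ``left_offset`` / ``i - right_offset``."""

    i: int
    left_offset: int
    right_offset: int

    def __post_init__(self) -> None:
        if self.left_offset < 1 or self.right_offset < 1:
            raise ValueError("offsets must be >= 1")
        if self.left_offset + self.right_offset > self.i:
            raise ValueError("offsets exceed span: no converted site inside")

    @property
    def min_tract(self) -> int:
        return self.i - self.left_offset - self.right_offset


def conformations_from_events(events: list[ConversionEvent]) -> list[GCConformation]:
    return [GCConformation(ev.max_tract, ev.left_offset, ev.right_offset)
            for ev in events]


@dataclass
class LikelihoodFit:
    dsb_rate: float
    tract_p: float
    max_lnl: float
    converged: bool
    at_boundary: bool
    grid_shape: tuple
    dsb_rate_ci: tuple | None = None
    one_sided_tract_ci: tuple | None = None

    @property
    def params(self) -> GCModelParams:
        return GCModelParams(self.dsb_rate, self.tract_p)


@dataclass(frozen=True)
class DerivedRates:
    one_sided_mean_tract: float
    total_mean_tract: float
    per_bp_conversion_rate: float
    per_arm_rate: float
    genome_haploid_rate: float
    per_meiosis_rate: float
    gc_co_ratio: float | None


def tract_pmf(L, p):
    """P(one-sided extension = L) = (1-p)^L p."""
    L = np.asarray(L)
    if np.any(L < 0):
        raise ValueError("tract length must be >= 0")
    _check_p(p)
    return (1.0 - p) ** L * p


def tract_cdf(L, p):
    """P(one-sided extension <= L) = 1 - (1-p)^(L+1); cdf(-1) = 0."""
    L = np.asarray(L)
    _check_p(p)
    return np.where(L < 0, 0.0, 1.0 - (1.0 - p) ** (np.maximum(L, -1) + 1.0))


def _check_p(p) -> None:
    if not (0.0 < p <= 1.0):
        raise ValueError("p must be in (0, 1]")


def _avoidance_sum(i, p):
    """S(i) = sum_{k=1..i} (1 - q^k)(1 - q^{i-k+1}), q = 1 - p, closed form.

    This is the average flank-avoidance factor times i: expanding the
    product and summing the two geometric series gives
    S(i) = i - 2 q (1 - q^i) / p + i q^{i+1}.
    """
    i = np.asarray(i, dtype=float)
    q = 1.0 - p
    if q == 0.0:
        return i.copy()
    qi = np.exp(i * np.log(q))
    return i - 2.0 * q * (1.0 - qi) / p + i * qi * q


def p_no_gc_span(i, params: GCModelParams):
    """Probability that a span of length ``i`` shows no converted flanking
    markers, truncated at one DSB (zero- plus one-DSB Poisson terms)."""
    i_arr = np.asarray(i, dtype=float)
    if np.any(i_arr < 1):
        raise ValueError("span length must be >= 1")
    lam, p = params.dsb_rate, params.tract_p
    s = _avoidance_sum(i_arr, p)
    out = np.exp(-i_arr * lam) * (1.0 + lam * s)
    return out if np.ndim(i) else float(out)


def p_gc_conformation(conf: GCConformation, params: GCModelParams) -> float:
    """Probability of an observed conversion conformation (single DSB).

    For a DSB at ordinate k the leftward extension must cover the farthest
    converted marker left of k (distance k - d_f, or nothing if d_f >= k)
    and stay short of the distal flank (distance k); symmetrically on the
    right with the last converted marker at d_l = i - right_offset and the
    proximal flank at distance i - k + 1.
    """
    lam, p = params.dsb_rate, params.tract_p
    if lam == 0.0:
        return 0.0
    i, d_f = conf.i, conf.left_offset
    d_l = conf.i - conf.right_offset
    q = 1.0 - p
    k = np.arange(1, i + 1, dtype=float)
    with np.errstate(divide="ignore"):
        logq = np.log(q) if q > 0.0 else -np.inf

    def qpow(e):
        e = np.asarray(e, dtype=float)
        if q == 0.0:
            return np.where(e == 0.0, 1.0, 0.0)
        return np.exp(e * logq)

    left = qpow(np.maximum(0.0, k - d_f)) - qpow(k)
    right = qpow(np.maximum(0.0, d_l - k)) - qpow(i - k + 1.0)
    return float(lam * np.exp(-i * lam) * np.sum(left * right))


def log_likelihood(
    hist: SpanHistogram,
    confs: list[GCConformation],
    params: GCModelParams,
) -> float:
    """Eq-style joint ln-likelihood: sum_a N_a ln P_noGC(a) + sum_c ln P_GC(c)."""
    a, n_a = hist.nonzero()
    lnl = 0.0
    if a.size:
        pa = p_no_gc_span(a, params)
        if np.any(pa <= 0.0):
            return float("-inf")
        lnl += float(np.dot(n_a, np.log(pa)))
    for conf in confs:
        pc = p_gc_conformation(conf, params)
        if pc <= 0.0:
            return float("-inf")
        lnl += float(np.log(pc))
    return lnl


class _LnLEvaluator:
    """Caches the span statistics so repeated (lambda, p) evaluations are
    O(#distinct span lengths)."""

    def __init__(self, hist: SpanHistogram, confs: list[GCConformation]):
        self.a, self.n_a = hist.nonzero()
        self.a = self.a.astype(float)
        self.w_total = float(np.dot(self.n_a, self.a))
        self.confs = list(confs)
        self.conf_i = np.array([c.i for c in self.confs], dtype=float)
        self._kernel_cache: dict[float, np.ndarray] = {}

    def _kernels(self, p: float) -> np.ndarray:
        got = self._kernel_cache.get(p)
        if got is None:
            got = np.array([
                _conf_sum(c, p) for c in self.confs
            ])
            self._kernel_cache[p] = got
        return got

    def lnl(self, lam: float, p: float) -> float:
        if lam < 0 or not (0.0 < p <= 1.0):
            return float("-inf")
        s = _avoidance_sum(self.a, p)
        span_term = -lam * self.w_total + float(
            np.dot(self.n_a, np.log1p(lam * s)))
        if not self.confs:
            return span_term
        if lam == 0.0:
            return float("-inf")
        kern = self._kernels(p)
        if np.any(kern <= 0.0):
            return float("-inf")
        gc_term = float(np.sum(np.log(lam) - self.conf_i * lam + np.log(kern)))
        return span_term + gc_term

    def lnl_lambda_grid(self, lams: np.ndarray, p: float) -> np.ndarray:
        """Vectorized over a lambda grid at fixed p."""
        s = _avoidance_sum(self.a, p)
        span = -lams * self.w_total + np.log1p(np.outer(lams, s)) @ self.n_a
        if not self.confs:
            return span
        kern = self._kernels(p)
        if np.any(kern <= 0.0):
            return np.full(lams.shape, -np.inf)
        with np.errstate(divide="ignore"):
            gc = (len(self.confs) * np.log(lams)
                  - lams * self.conf_i.sum() + np.log(kern).sum())
        return span + gc


def _conf_sum(conf: GCConformation, p: float) -> float:
    """sum_k P_k(GCLeft) P_k(GCRight) for one conformation."""
    i, d_f = conf.i, conf.left_offset
    d_l = conf.i - conf.right_offset
    q = 1.0 - p
    k = np.arange(1, i + 1, dtype=float)
    if q == 0.0:
        left = np.where(np.maximum(0.0, k - d_f) == 0.0, 1.0, 0.0) - \
            np.where(k == 0.0, 1.0, 0.0)
        right = np.where(np.maximum(0.0, d_l - k) == 0.0, 1.0, 0.0) - \
            np.where(i - k + 1.0 == 0.0, 1.0, 0.0)
        return float(np.sum(left * right))
    logq = np.log(q)
    left = np.exp(np.maximum(0.0, k - d_f) * logq) - np.exp(k * logq)
    right = np.exp(np.maximum(0.0, d_l - k) * logq) - np.exp((i - k + 1.0) * logq)
    return float(np.sum(left * right))


def fit(
    hist: SpanHistogram,
    confs: list[GCConformation],
    lam_bounds: tuple = (1e-10, 1e-6),
    p_bounds: tuple = (1e-4, 1.0),
    grid_shape: tuple = (60, 60),
    refine: bool = True,
) -> LikelihoodFit:
    """Joint MLE of (lambda, p) by log-spaced grid search plus Nelder-Mead
    refinement; ties broken toward smaller lambda."""
    ev = _LnLEvaluator(hist, confs)
    if ev.a.size == 0 and not confs:
        raise ValueError("no spans and no conversions: nothing to fit")
    lams = np.geomspace(lam_bounds[0], lam_bounds[1], grid_shape[0])
    ps = np.geomspace(p_bounds[0], p_bounds[1], grid_shape[1])
    best = (-np.inf, lams[0], ps[0])
    for p in ps:
        vals = ev.lnl_lambda_grid(lams, p)
        j = int(np.argmax(vals))  # first occurrence -> smaller lambda
        if vals[j] > best[0]:
            best = (float(vals[j]), float(lams[j]), float(p))
    max_lnl, lam_hat, p_hat = best
    converged = True
    # without conversions the likelihood is monotone in lambda: the grid
    # already sits at the boundary and refinement has nothing to do
    if refine and confs:
        def neg(x):
            lam = np.exp(x[0])
            p = np.exp(x[1])
            if p > 1.0 or not (lam_bounds[0] <= lam <= lam_bounds[1]):
                return np.inf
            return -ev.lnl(lam, p)

        res = optimize.minimize(
            neg, [np.log(lam_hat), np.log(p_hat)], method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        if -res.fun >= max_lnl:
            lam_hat, p_hat = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
            max_lnl = float(-res.fun)
        converged = bool(res.success or -res.fun >= best[0])
    at_boundary = bool(
        lam_hat <= lam_bounds[0] * (1 + 1e-6) or not confs)
    return LikelihoodFit(
        dsb_rate=lam_hat, tract_p=min(p_hat, 1.0), max_lnl=max_lnl,
        converged=converged, at_boundary=at_boundary, grid_shape=grid_shape)


def _scan_bound(f, x_hat: float, target: float, direction: int,
                bound: float, tol: float = 1e-4) -> tuple[float, bool]:
    """Geometric bracketing + bisection (in log space) for f(x) = target."""
    x = x_hat
    factor = 2.0 if direction > 0 else 0.5
    prev = x
    for _ in range(200):
        nxt = x * factor
        if (direction > 0 and nxt >= bound) or (direction < 0 and nxt <= bound):
            nxt = bound
        if f(nxt) < target:
            lo, hi = (x, nxt) if direction > 0 else (nxt, x)
            for _ in range(200):
                mid = np.sqrt(lo * hi)
                if f(mid) >= target:
                    if direction > 0:
                        lo = mid
                    else:
                        hi = mid
                else:
                    if direction > 0:
                        hi = mid
                    else:
                        lo = mid
                if hi / lo < 1.0 + tol:
                    break
            return (lo if direction > 0 else hi), False
        prev, x = x, nxt
        if x == bound:
            return bound, True  # open-ended: target not crossed inside range
    return x, True


def profile_ci(
    fit_result: LikelihoodFit,
    hist: SpanHistogram,
    confs: list[GCConformation],
    delta_lnl: float = 2.0,
    lam_bounds: tuple = (1e-12, 1e-4),
    p_bounds: tuple = (1e-6, 1.0),
) -> LikelihoodFit:
    """Interval estimates at ``max_lnl - delta_lnl`` holding the other
    parameter at its MLE.  Returns the fit with CI fields populated; the
    tract CI is reported on the one-sided mean scale (1 - p)/p."""
    ev = _LnLEvaluator(hist, confs)
    lam_hat, p_hat = fit_result.dsb_rate, fit_result.tract_p
    target = fit_result.max_lnl - delta_lnl

    lam_lo, open_lo = _scan_bound(lambda x: ev.lnl(x, p_hat), lam_hat, target,
                                  -1, lam_bounds[0])
    lam_hi, open_hi = _scan_bound(lambda x: ev.lnl(x, p_hat), lam_hat, target,
                                  +1, lam_bounds[1])
    p_lo, p_open_lo = _scan_bound(lambda x: ev.lnl(lam_hat, x), p_hat, target,
                                  -1, p_bounds[0])
    p_hi, p_open_hi = _scan_bound(lambda x: ev.lnl(lam_hat, min(x, 1.0)),
                                  p_hat, target, +1, p_bounds[1])
    mean = lambda p: (1.0 - p) / p  # noqa: E731  decreasing in p
    fit_result.dsb_rate_ci = (lam_lo, lam_hi, open_lo or open_hi)
    fit_result.one_sided_tract_ci = (mean(min(p_hi, 1.0)), mean(p_lo),
                                     p_open_lo or p_open_hi)
    return fit_result


def likelihood_ratio_test(
    hist: SpanHistogram,
    confs: list[GCConformation],
    constrained_total_events: float,
    observed_co_per_meiosis: float = CO_PER_MEIOSIS,
    genome_length: float = GENOME_EUCHROMATIC_LENGTH,
    free_fit: LikelihoodFit | None = None,
) -> dict:
    """Test a fixed genome-wide number of recombination events per meiosis.

    The constrained model pins lambda so that conversion events per meiosis
    (4 haploid products x lambda x genome length) equal
    ``constrained_total_events - observed_co_per_meiosis``; p stays free.
    The statistic 2(lnL_free - lnL_constrained) is referred to chi-square
    with 1 degree of freedom.
    """
    if constrained_total_events < observed_co_per_meiosis:
        raise ValueError("constrained total below the observed CO count")
    lam_c = (constrained_total_events - observed_co_per_meiosis) / (
        4.0 * genome_length)
    if free_fit is None:
        free_fit = fit(hist, confs)
    ev = _LnLEvaluator(hist, confs)

    res = optimize.minimize_scalar(
        lambda x: -ev.lnl(lam_c, float(np.exp(x))),
        bounds=(np.log(1e-6), 0.0), method="bounded",
        options={"xatol": 1e-10})
    lnl_c = -float(res.fun)
    stat = 2.0 * (free_fit.max_lnl - lnl_c)
    if stat < -1e-6:
        raise RuntimeError("constrained ln-likelihood exceeds free maximum")
    stat = max(stat, 0.0)
    return {
        "statistic": stat,
        "df": 1,
        "p_value": float(stats.chi2.sf(stat, 1)),
        "lambda_constrained": lam_c,
        "tract_p_constrained": float(np.exp(res.x)),
        "lnl_constrained": lnl_c,
        "lnl_free": free_fit.max_lnl,
    }


def derived_rates(
    params: GCModelParams,
    arm_length: float = X_ARM_LENGTH,
    genome_length: float = GENOME_EUCHROMATIC_LENGTH,
    co_per_meiosis: float = CO_PER_MEIOSIS,
) -> DerivedRates:
    """Rates implied by (lambda, p): mean tract lengths, per-bp conversion
    rate, per-arm and genome-wide event rates and the GC:CO ratio."""
    one_sided = params.one_sided_mean_tract
    total = 2.0 * one_sided
    lam = params.dsb_rate
    haploid = lam * genome_length
    per_meiosis = 4.0 * haploid
    ratio = per_meiosis / co_per_meiosis if co_per_meiosis > 0 else None
    return DerivedRates(
        one_sided_mean_tract=one_sided,
        total_mean_tract=total,
        per_bp_conversion_rate=lam * total,
        per_arm_rate=lam * arm_length,
        genome_haploid_rate=haploid,
        per_meiosis_rate=per_meiosis,
        gc_co_ratio=ratio,
    )
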