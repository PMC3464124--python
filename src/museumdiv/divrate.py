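"""Diversification-rate tests on branching times of a dated phylogeny.

The battery discriminates "museum" (steady accumulation, constant rates)
from "cradle" (recent rapid accumulation) diversification:

* the gamma statistic and its Monte Carlo constant-rates (MCCR) correction
  for incomplete taxon sampling;
* rate-constant (pure birth, birth-death) versus rate-variable (density
  dependent, multi-rate Yule) model fits compared by AIC (dAIC_RC);
* fixed-time rate-shift tests at user-specified geological events;
* the relative cladogenesis test with Bonferroni correction;
* whole-clade net-diversification estimators under assumed relative
  extinction fractions.

Likelihood convention: all Yule-family likelihoods condition on the crown
event, count n-2 branching events, and use the total exposure
``sum_{k=2..n} k * g_k`` (g_k = time with exactly k lineages, including
the final interval to the present).  Under this convention the pure-birth
MLE is ``(n-2) / sum k g_k``.  Combinatorial constants common to all
models are dropped consistently, so AIC differences are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import minimize_scalar, minimize
from scipy.special import gammaln
from scipy.stats import chi2, norm

from .phylo import BranchingTimes, TreeError, branching_times, node_ages

__all__ = [
    "GammaResult",
    "MccrResult",
    "ModelFit",
    "ShiftTestResult",
    "RelCladResult",
    "NetDivRate",
    "gamma_stat",
    "mccr_test",
    "fit_rate_constant",
    "fit_rate_variable",
    "fit_all_models",
    "delta_aic_rc",
    "shift_at_time_test",
    "rel_cladogenesis_test",
    "rc_tail_probability",
    "ms_netdiv",
    "EVENT_TIMES_MA",
]

#: Default ages (Ma) for the named geological/climatic events at which
#: fixed-time rate shifts are tested: end-Eocene greenhouse maximum,
#: late-Oligocene warming event, mid-Miocene climatic optimum,
#: Plio-Pleistocene glaciations.  Editable via configuration.
EVENT_TIMES_MA = {"EOGM": 34.0, "LOWE": 25.0, "MMCO": 15.0, "PPG": 2.6}


# ---------------------------------------------------------------------------
# gamma statistic


@dataclass(frozen=True)
class GammaResult:
    gamma: float
    p_one_tailed: float  # Phi(gamma): small when branching is early-heavy


def _as_bt(bt) -> BranchingTimes:
    if isinstance(bt, BranchingTimes):
        return bt
    return branching_times(bt)


def gamma_stat(bt) -> GammaResult:
    """Constant-rates gamma statistic of Pybus & Harvey.

    With internode intervals g_k (time with exactly k lineages) and
    cumulative weights T_i = sum_{k=2..i} k g_k:

        gamma = [ mean(T_2..T_{n-1}) - T_n / 2 ] / [ T_n sqrt(1/(12(n-2))) ]

    Under a completely sampled pure-birth process gamma ~ N(0, 1); the
    one-tailed p-value Phi(gamma) is small when branching concentrates
    early (diversification slow-down).
    """
    bt = _as_bt(bt)
    n = bt.n_tips
    if n < 3:
        raise TreeError("gamma needs at least 3 tips")
    g = bt.internode_intervals()           # g_2 .. g_n
    k = np.arange(2, n + 1)
    cum = np.cumsum(k * g)                 # T_2 .. T_n
    total = cum[-1]
    if total <= 0:
        raise TreeError("total weighted tree length is zero")
    interior_mean = float(np.mean(cum[:-1]))
    gamma = (interior_mean - total / 2.0) / (total * math.sqrt(1.0 / (12.0 * (n - 2))))
    return GammaResult(gamma=float(gamma), p_one_tailed=float(norm.cdf(gamma)))


# ---------------------------------------------------------------------------
# fast pure-birth simulation + uniform pruning (null for the MCCR test)


def yule_branching_times(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Branching-time ages of a complete pure-birth tree with n tips.

    The present is placed at the moment the (n+1)-th lineage would arise,
    so every internode interval g_k ~ Exp(k * rate), the convention under
    which gamma is exactly standard normal in distribution.
    """
    k = np.arange(2, n + 1)
    g = rng.exponential(1.0 / (k * rate))
    times = np.cumsum(g[::-1])[::-1]       # age of event starting interval k
    return times


def _yule_pruned_bt(n_total: int, n_sampled: int, rng: np.random.Generator) -> np.ndarray:
    """Branching times of a pure-birth tree pruned to a uniform tip subset.

    Simulates topology and times jointly with flat arrays (no tree objects)
    and returns the ages of the sampled tips' pairwise MRCAs, descending.
    """
    # forward simulation: nodes 0..2n-2; root = 0
    n_nodes = 2 * n_total - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    event_time = np.zeros(n_nodes)         # split time, measured from crown

    active = [1, 2]
    parent[1] = parent[2] = 0
    left[0], right[0] = 1, 2
    next_id = 3
    t = 0.0
    for k in range(2, n_total + 1):
        t += rng.exponential(1.0 / k)
        if k == n_total:
            break
        i = active.pop(int(rng.integers(len(active))))
        event_time[i] = t
        left[i], right[i] = next_id, next_id + 1
        parent[next_id] = parent[next_id + 1] = i
        active.extend((next_id, next_id + 1))
        next_id += 2
    present = t
    tips = np.array(active)

    sampled = rng.choice(tips, size=n_sampled, replace=False)
    # count sampled tips below each node, bottom-up (children have larger ids)
    below = np.zeros(n_nodes, dtype=np.int64)
    below[sampled] = 1
    for i in range(n_nodes - 1, 0, -1):
        below[parent[i]] += below[i]
    internal = left >= 0
    keep = internal & (below[left.clip(0)] > 0) & (below[right.clip(0)] > 0)
    ages = present - event_time[keep]
    ages.sort()
    return ages[::-1]


@dataclass(frozen=True)
class MccrResult:
    n_total: int
    n_sampled: int
    replicates: int
    seed: int
    observed_gamma: float | None
    critical_value: float              # 5th percentile of the null
    p_value: float | None              # fraction of null <= observed
    null_gammas: np.ndarray = field(repr=False, default=None)


def mccr_test(
    observed_gamma: float | None,
    n_total: int,
    n_sampled: int,
    replicates: int = 10000,
    seed: int = 0,
) -> MccrResult:
    """Monte Carlo constant-rates test under incomplete taxon sampling.

    Simulates complete pure-birth trees with ``n_total`` tips, prunes each
    uniformly at random to ``n_sampled`` tips, and builds the null gamma
    distribution.  The speciation rate is immaterial (gamma is invariant
    to time rescaling) and fixed at 1.
    """
    if n_sampled < 3:
        raise TreeError("need at least 3 sampled tips")
    if n_sampled > n_total:
        raise TreeError("n_sampled cannot exceed n_total")
    rng = np.random.default_rng(seed)
    nulls = np.empty(replicates)
    if n_sampled == n_total:
        for r in range(replicates):
            ages = yule_branching_times(n_total, 1.0, rng)
            bt = BranchingTimes(n_tips=n_total, ages=ages)
            nulls[r] = gamma_stat(bt).gamma
    else:
        for r in range(replicates):
            ages = _yule_pruned_bt(n_total, n_sampled, rng)
            bt = BranchingTimes(n_tips=n_sampled, ages=ages)
            nulls[r] = gamma_stat(bt).gamma
    crit = float(np.percentile(nulls, 5.0))
    p = None if observed_gamma is None else float(np.mean(nulls <= observed_gamma))
    return MccrResult(
        n_total=n_total,
        n_sampled=n_sampled,
        replicates=replicates,
        seed=seed,
        observed_gamma=observed_gamma,
        critical_value=crit,
        p_value=p,
        null_gammas=nulls,
    )


# ---------------------------------------------------------------------------
# rate-constant / rate-variable model battery


@dataclass(frozen=True)
class ModelFit:
    model: str
    k: int
    lnl: float
    params: dict

    @property
    def aic(self) -> float:
        return -2.0 * self.lnl + 2.0 * self.k

    @property
    def rate_variable(self) -> bool:
        return self.model in ("DDL", "DDX", "yule2rate", "yule3rate")


def _exposure_terms(bt: BranchingTimes):
    """(event ages, per-interval lineage counts k=2..n, intervals g_k)."""
    g = bt.internode_intervals()
    k = np.arange(2, bt.n_tips + 1)
    return k, g


def _yule_lnl_of_rates(rates: np.ndarray, k: np.ndarray, g: np.ndarray) -> float:
    """Piecewise/lineage-dependent Yule log-likelihood.

    ``rates[i]`` is the per-lineage speciation rate during the interval
    with ``k[i]`` lineages; the event terminating each interval except the
    last contributes log(rate), all intervals contribute -k*rate*g.
    """
    if np.any(rates <= 0):
        return -np.inf
    lnl = float(np.sum(np.log(rates[:-1]))) - float(np.dot(k * rates, g))
    return lnl


def fit_pure_birth(bt) -> ModelFit:
    """Closed-form Yule fit: lambda_hat = (n-2) / sum k g_k."""
    bt = _as_bt(bt)
    k, g = _exposure_terms(bt)
    exposure = float(np.dot(k, g))
    lam = (bt.n_tips - 2) / exposure
    lnl = (bt.n_tips - 2) * math.log(lam) - lam * exposure
    return ModelFit("pureBirth", k=1, lnl=lnl, params={"lambda": lam})


def fit_bd(bt) -> ModelFit:
    """Birth-death fit (net rate r, relative extinction a = mu/lambda).

    Nee-style likelihood conditioned on the crown event; reduces exactly
    to the pure-birth likelihood at a = 0.
    """
    bt = _as_bt(bt)
    n = bt.n_tips
    ages = bt.ages  # descending, crown first

    def lnl(r, a):
        if r <= 0 or not (0 <= a < 1):
            return -np.inf
        val = (n - 2) * math.log(r) + r * float(np.sum(ages[1:]))
        val += n * math.log(1 - a)
        z = np.exp(r * ages) - a
        if np.any(z <= 0):
            return -np.inf
        val -= 2.0 * float(np.sum(np.log(z)))
        return val

    pb = fit_pure_birth(bt)
    r0 = pb.params["lambda"]
    best = (lnl(r0, 0.0), r0, 0.0)
    for a0 in (0.0, 0.5, 0.9):
        res = minimize(
            lambda v: -lnl(v[0], v[1]),
            x0=[r0, a0],
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000},
        )
        if -res.fun > best[0]:
            best = (-res.fun, float(res.x[0]), float(res.x[1]))
    lnl_best, r, a = best
    lam = r / (1 - a)
    return ModelFit("bd", k=2, lnl=lnl_best,
                    params={"r": r, "a": a, "lambda": lam, "mu": lam * a})


def fit_ddl(bt) -> ModelFit:
    """Density-dependent (linear): lambda(N) = lambda0 * (1 - N/K)."""
    bt = _as_bt(bt)
    k, g = _exposure_terms(bt)
    n = bt.n_tips

    def prof_lnl(K):
        rates_shape = 1.0 - k / K
        if np.any(rates_shape <= 0):
            return -np.inf, 0.0
        # profile lambda0 in closed form: events/(weighted exposure) is not
        # exact here because log terms carry the shape; optimize numerically
        def neg(l0):
            return -_yule_lnl_of_rates(l0 * rates_shape, k, g)
        res = minimize_scalar(neg, bounds=(1e-10, 1e6), method="bounded",
                              options={"xatol": 1e-12})
        return -res.fun, float(res.x)

    best = (-np.inf, None, None)
    for K in np.concatenate([np.linspace(n + 1e-6, 5 * n, 60), [10.0 * n, 100.0 * n]]):
        f, l0 = prof_lnl(K)
        if f > best[0]:
            best = (f, l0, float(K))
    res = minimize_scalar(lambda K: -prof_lnl(K)[0],
                          bounds=(n + 1e-9, 1000.0 * n), method="bounded",
                          options={"xatol": 1e-9})
    f, l0 = prof_lnl(float(res.x))
    if f > best[0]:
        best = (f, l0, float(res.x))
    lnl, l0, K = best
    # K -> infinity is the constant-rate boundary of the family; take it
    # when the finite-K profile never improves on it
    pb = fit_pure_birth(bt)
    if pb.lnl >= lnl:
        lnl, l0, K = pb.lnl, pb.params["lambda"], math.inf
    return ModelFit("DDL", k=2, lnl=lnl, params={"lambda0": l0, "K": K})


def fit_ddx(bt) -> ModelFit:
    """Density-dependent (exponential): lambda(N) = lambda0 * N**(-x)."""
    bt = _as_bt(bt)
    k, g = _exposure_terms(bt)

    def obj(v):
        l0, x = v
        if l0 <= 0:
            return np.inf
        return -_yule_lnl_of_rates(l0 * np.power(k, -x), k, g)

    pb = fit_pure_birth(bt)
    best = (pb.lnl, pb.params["lambda"], 0.0)
    for x0 in (-0.5, 0.0, 0.5):
        res = minimize(obj, x0=[pb.params["lambda"], x0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000})
        if -res.fun > best[0]:
            best = (-res.fun, float(res.x[0]), float(res.x[1]))
    lnl, l0, x = best
    return ModelFit("DDX", k=2, lnl=lnl, params={"lambda0": l0, "x": x})


def _segment_lnl(k: np.ndarray, g: np.ndarray, events: np.ndarray) -> tuple[float, float]:
    """Closed-form Yule MLE on a segment: (lnl contribution, lambda_hat).

    ``events`` marks intervals terminated by an event inside the segment;
    exposure is sum k g over the segment's intervals.
    """
    exposure = float(np.dot(k, g))
    m = int(np.sum(events))
    if exposure <= 0:
        return (0.0, 0.0) if m == 0 else (-np.inf, np.inf)
    if m == 0:
        return 0.0, 0.0  # rate unidentifiable; supremum as lambda -> 0
    lam = m / exposure
    return m * math.log(lam) - m, lam


def _split_segments(bt: BranchingTimes, shifts: list[float]):
    """Split interval/exposure arrays at the shift ages (descending).

    Returns per-segment (k, g, event-mask) triples; an event at exactly a
    shift age belongs to the older segment.
    """
    k, g = _exposure_terms(bt)
    ages = bt.ages
    bounds_hi = ages                                     # interval upper edges
    bounds_lo = np.concatenate([ages[1:], [0.0]])        # interval lower edges
    # interval i spans (bounds_lo[i], bounds_hi[i]) with k[i] lineages and is
    # terminated by the event at bounds_lo[i] (except the last, censored at 0)
    cuts = [np.inf] + sorted(shifts, reverse=True) + [0.0]
    segments = []
    for hi, lo in zip(cuts[:-1], cuts[1:]):
        seg_k, seg_g, seg_e = [], [], []
        for i in range(len(g)):
            overlap = min(bounds_hi[i], hi) - max(bounds_lo[i], lo)
            if overlap < 0:  # zero-length intervals stay: ties carry events
                continue
            seg_k.append(k[i])
            seg_g.append(overlap)
            has_event = (i < len(g) - 1) and (lo <= bounds_lo[i] < hi)
            seg_e.append(has_event)
        segments.append((np.array(seg_k), np.array(seg_g),
                         np.array(seg_e, dtype=bool)))
    return segments


def _multi_rate_yule(bt: BranchingTimes, shifts: list[float]):
    """lnL and per-segment rates of a piecewise-constant Yule model."""
    total = 0.0
    lams = []
    for seg_k, seg_g, seg_e in _split_segments(bt, shifts):
        lnl, lam = _segment_lnl(seg_k, seg_g, seg_e)
        total += lnl
        lams.append(lam)
    return total, lams


def fit_yule2rate(bt) -> ModelFit:
    """Two-rate Yule; the shift time is profiled over observed branching times."""
    bt = _as_bt(bt)
    candidates = bt.ages[1:-1] if len(bt.ages) > 2 else bt.ages[1:]
    best = (-np.inf, None, None)
    for st in candidates:
        lnl, lams = _multi_rate_yule(bt, [float(st)])
        if lnl > best[0]:
            best = (lnl, float(st), lams)
    lnl, st, lams = best
    return ModelFit("yule2rate", k=3, lnl=lnl,
                    params={"lambda1": lams[0], "lambda2": lams[1], "shift": st})


def fit_yule3rate(bt) -> ModelFit:
    """Three-rate Yule; both shift times profiled over branching times."""
    bt = _as_bt(bt)
    if bt.n_tips < 6:
        raise TreeError("yule3rate needs at least 6 tips")
    candidates = [float(a) for a in bt.ages[1:-1]]
    best = (-np.inf, None, None)
    for st1, st2 in combinations(candidates, 2):
        hi, lo = max(st1, st2), min(st1, st2)
        lnl, lams = _multi_rate_yule(bt, [hi, lo])
        if lnl > best[0]:
            best = (lnl, (hi, lo), lams)
    lnl, (st1, st2), lams = best
    return ModelFit("yule3rate", k=5, lnl=lnl,
                    params={"lambda1": lams[0], "lambda2": lams[1],
                            "lambda3": lams[2], "shift1": st1, "shift2": st2})


def fit_rate_constant(bt) -> list[ModelFit]:
    bt = _as_bt(bt)
    return [fit_pure_birth(bt), fit_bd(bt)]


def fit_rate_variable(bt) -> list[ModelFit]:
    bt = _as_bt(bt)
    fits = [fit_ddl(bt), fit_ddx(bt), fit_yule2rate(bt)]
    if bt.n_tips >= 6:
        fits.append(fit_yule3rate(bt))
    return fits


def fit_all_models(bt) -> list[ModelFit]:
    bt = _as_bt(bt)
    return fit_rate_constant(bt) + fit_rate_variable(bt)


def delta_aic_rc(fits: list[ModelFit]) -> dict:
    """dAIC_RC = best (min) RC-model AIC minus best RV-model AIC.

    Negative values favour the rate-constant model.  Guide thresholds
    (4.0 for ~30 tips, 5.5 for ~100) are reported alongside; the LR and
    its chi-square (d.f. = 1) p-value compare the two selected models.
    """
    rc = [f for f in fits if not f.rate_variable]
    rv = [f for f in fits if f.rate_variable]
    if not rc or not rv:
        raise ValueError("need at least one rate-constant and one rate-variable fit")
    best_rc = min(rc, key=lambda f: f.aic)
    best_rv = min(rv, key=lambda f: f.aic)
    lr = 2.0 * (best_rv.lnl - best_rc.lnl)
    return {
        "best_rc": best_rc,
        "best_rv": best_rv,
        "delta_aic_rc": best_rc.aic - best_rv.aic,
        "lr": lr,
        "lr_p": float(chi2.sf(max(lr, 0.0), df=1)),
        "thresholds": {"n30": 4.0, "n100": 5.5},
    }


# ---------------------------------------------------------------------------
# fixed-time shift test


@dataclass(frozen=True)
class ShiftTestResult:
    shift_age: float
    lam_before: float
    lam_after: float
    lnl_shift: float
    lnl_constant: float
    lr: float
    p_value: float


def shift_at_time_test(bt, shift_age: float) -> ShiftTestResult:
    """Yule rate-shift test at a fixed age (chi-square, d.f. = 1).

    Fits one rate older than ``shift_age`` and one younger (the straddling
    interval is split at the shift) against the constant-rate Yule fit.
    """
    bt = _as_bt(bt)
    if not (0.0 < shift_age < bt.crown_age):
        raise TreeError("shift age must lie strictly inside (0, crown age)")
    n_before = int(np.sum(bt.ages[1:] > shift_age))  # crown event excluded
    n_after = len(bt.ages[1:]) - n_before
    if n_before == 0 or n_after == 0:
        raise TreeError("no branching events on one side of the shift age")
    lnl_shift, lams = _multi_rate_yule(bt, [shift_age])
    const = fit_pure_birth(bt)
    lr = 2.0 * (lnl_shift - const.lnl)
    return ShiftTestResult(
        shift_age=shift_age,
        lam_before=lams[0],
        lam_after=lams[1],
        lnl_shift=lnl_shift,
        lnl_constant=const.lnl,
        lr=lr,
        p_value=float(chi2.sf(max(lr, 0.0), df=1)),
    )


# ---------------------------------------------------------------------------
# relative cladogenesis test


def rc_tail_probability(r: int, n_total: int, k: int) -> float:
    """P(a given one of k contemporaneous lineages leaves >= r of N tips).

    Under the equal-rates Markov null the descendant partition is uniform
    over compositions of N into k positive parts:
    P(>= r) = sum_{m=r..N-k+1} C(N-m-1, k-2) / C(N-1, k-1).
    """
    if k < 2:
        return 1.0
    if r <= 1:
        return 1.0
    if r > n_total - k + 1:
        return 0.0

    def logc(a, b):
        if b < 0 or b > a:
            return -np.inf
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    denom = logc(n_total - 1, k - 1)
    total = 0.0
    for m in range(r, n_total - k + 2):
        total += math.exp(logc(n_total - m - 1, k - 2) - denom)
    return min(total, 1.0)


@dataclass(frozen=True)
class RelCladResult:
    labels: list              # per tested node: representative tip labels
    n_descendants: np.ndarray
    k_lineages: np.ndarray
    p_values: np.ndarray
    p_bonferroni: np.ndarray
    alpha: float
    significant: np.ndarray   # boolean, after Bonferroni

    @property
    def any_significant(self) -> bool:
        return bool(np.any(self.significant))


def rel_cladogenesis_test(tree, alpha: float = 0.05) -> RelCladResult:
    """Relative cladogenesis test over all slices through a chronogram.

    Each internal non-root node is tested at the slice just after its
    parent's split: with k lineages alive there and N total tips, the
    node's descendant count is referred to the uniform-composition null.
    The Bonferroni correction multiplies by the number of tested nodes.
    """
    ages = node_ages(tree)
    internal = sorted(
        (a for nd, a in ages.items() if not nd.is_leaf()), reverse=True
    )
    n_total = sum(1 for nd in ages if nd.is_leaf())
    rank = {}
    for i, a in enumerate(internal):
        rank.setdefault(a, i + 1)  # lineages after the i-th oldest split = i+1

    labels, descendants, ks, pvals = [], [], [], []
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        k = rank[ages[node.parent_node]] + 1
        r = sum(1 for _ in node.leaf_iter())
        p = rc_tail_probability(r, n_total, k)
        first_tip = next(node.leaf_iter()).taxon.label
        labels.append(first_tip)
        descendants.append(r)
        ks.append(k)
        pvals.append(p)
    p_arr = np.array(pvals)
    m = len(p_arr)
    p_bonf = np.minimum(p_arr * m, 1.0)
    return RelCladResult(
        labels=labels,
        n_descendants=np.array(descendants),
        k_lineages=np.array(ks),
        p_values=p_arr,
        p_bonferroni=p_bonf,
        alpha=alpha,
        significant=p_bonf < alpha,
    )


# ---------------------------------------------------------------------------
# whole-clade net diversification


@dataclass(frozen=True)
class NetDivRate:
    epsilon: float
    r_crown: float | None
    r_stem: float | None


def ms_netdiv(n: int, t: float, epsilon: float, mode: str = "both") -> NetDivRate:
    """Whole-clade net diversification rate under relative extinction eps.

    Survival-conditioned moment estimators:
    stem  r = ln(n (1-eps) + eps) / t
    crown r = ln(n (1-eps) / 2 + eps) / t
    which reduce exactly to ln(n)/t and ln(n/2)/t at eps = 0.
    """
    if n < 2:
        raise ValueError("need n >= 2 extant species")
    if t <= 0:
        raise ValueError("age must be positive")
    if not (0.0 <= epsilon < 1.0):
        raise ValueError("epsilon must lie in [0, 1)")
    r_stem = math.log(n * (1 - epsilon) + epsilon) / t
    r_crown = math.log(n * (1 - epsilon) / 2.0 + epsilon) / t
    if mode == "stem":
        return NetDivRate(epsilon, None, r_stem)
    if mode == "crown":
        return NetDivRate(epsilon, r_crown, None)
    return NetDivRate(epsilon, r_crown, r_stem)
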