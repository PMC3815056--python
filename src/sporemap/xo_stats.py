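"""Statistical procedures for crossover maps and tetrad viability.

Contingency testing: Fisher exact (2x2 by probability ordering, larger
tables by exact enumeration when feasible), Pearson chi-square, and a
Monte-Carlo chi-square that samples tables with fixed margins from the
conditional null (Patefield sampling), with the add-one p estimator
p = (1 + #{X2_sim >= X2_obs}) / (B + 1).

Tetrad viability: the observed numbers of tetrads with 4..0 viable spores
are modelled by a three-parameter multinomial — per-meiosis MI
nondisjunction d (all four spores aneuploid), per-division MII
nondisjunction m (that daughter's two spores aneuploid), and independent
background death v of euploid spores — fitted by maximum likelihood with
bootstrap confidence intervals.  The MI-vs-double-MII attribution ratio for
the zero-viable class is d / ((1-d) m^2): a single MI failure versus two
independent rare MII failures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

__all__ = [
    "ContingencyError",
    "TetradCounts",
    "NDModelParams",
    "fisher_exact",
    "exact_rxc",
    "chisq",
    "chisq_mc",
    "compare_maps",
    "total_viability",
    "tetrad_distribution_test",
    "nd_model_probs",
    "nd_fit",
    "NDFitResult",
    "nd_zero_attribution",
    "spore_viability",
]


class ContingencyError(ValueError):
    pass


def _as_table(t) -> np.ndarray:
    arr = np.asarray(t)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ContingencyError(f"need an r x c table with r,c >= 2, "
                               f"got shape {arr.shape}")
    if np.any(arr < 0):
        raise ContingencyError("counts must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ContingencyError("counts must be integers")
    return np.round(arr).astype(np.int64)


# -- exact tests ---------------------------------------------------------

def fisher_exact(t) -> float:
    """Two-sided Fisher exact p-value.

    2x2 tables use the probability-ordering convention (sum of
    hypergeometric probabilities of tables at most as probable as the
    observed one); larger tables are routed to :func:`exact_rxc`.
    """
    arr = _as_table(t)
    if arr.shape == (2, 2):
        return float(stats.fisher_exact(arr, alternative="two-sided")[1])
    return exact_rxc(arr)


def _log_table_prob(first_row: np.ndarray, col_sums: np.ndarray,
                    log_denom: float) -> float:
    # P(table | margins) = prod_j C(n_j, a_j) / C(N, r1)
    a = first_row
    n = col_sums
    return float(np.sum(gammaln(n + 1) - gammaln(a + 1) - gammaln(n - a + 1))
                 - log_denom)


def exact_rxc(t, max_tables: int = 5_000_000) -> float:
    """Exact probability-ordering test for a 2 x c table by full
    enumeration of tables with the observed margins.

    Raises :class:`ContingencyError` when the table has more than two rows
    or the enumeration would exceed ``max_tables`` (callers should fall
    back to :func:`chisq_mc`).
    """
    arr = _as_table(t)
    if arr.shape[0] != 2:
        raise ContingencyError(
            "exact enumeration implemented for 2 x c tables only")
    col_sums = arr.sum(axis=0)
    r1 = int(arr.sum(axis=1)[0])
    N = int(arr.sum())
    c = arr.shape[1]

    # feasibility estimate: product of per-column ranges
    est = 1
    for n_j in col_sums[:-1]:
        est *= (min(int(n_j), r1) + 1)
        if est > max_tables:
            raise ContingencyError(
                f"enumeration over ~{est}+ tables exceeds cap {max_tables}")

    log_denom = gammaln(N + 1) - gammaln(r1 + 1) - gammaln(N - r1 + 1)
    log_p_obs = _log_table_prob(arr[0], col_sums, log_denom)

    total = 0.0
    stack = [(0, r1, 0.0)]
    # iterative DFS over first-row entries a_0 .. a_{c-2}; last is forced
    while stack:
        j, remaining, log_acc = stack.pop()
        if j == c - 1:
            if remaining <= col_sums[j]:
                lp = (log_acc + gammaln(col_sums[j] + 1)
                      - gammaln(remaining + 1)
                      - gammaln(col_sums[j] - remaining + 1) - log_denom)
                if lp <= log_p_obs + 1e-10:
                    total += np.exp(lp)
            continue
        hi = min(int(col_sums[j]), remaining)
        # cannot leave more than the capacity of the remaining columns
        cap_rest = int(col_sums[j + 1:].sum())
        lo = max(0, remaining - cap_rest)
        for a in range(lo, hi + 1):
            la = (gammaln(col_sums[j] + 1) - gammaln(a + 1)
                  - gammaln(col_sums[j] - a + 1))
            stack.append((j + 1, remaining - a, log_acc + la))
    return float(min(total, 1.0))


# -- chi-square ----------------------------------------------------------

def _pearson_x2(arr: np.ndarray) -> tuple[float, np.ndarray]:
    row = arr.sum(axis=1, keepdims=True)
    col = arr.sum(axis=0, keepdims=True)
    n = arr.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ContingencyError("zero margin: chi-square undefined")
    expected = row * col / n
    x2 = float(((arr - expected) ** 2 / expected).sum())
    return x2, expected


def chisq(t) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (X2, df, asymptotic p).
    """
    arr = _as_table(t)
    x2, _ = _pearson_x2(arr)
    df = (arr.shape[0] - 1) * (arr.shape[1] - 1)
    p = float(stats.chi2.sf(x2, df))
    return x2, df, p


def chisq_mc(t, B: int = 2000, seed=None) -> tuple[float, float]:
    """Monte-Carlo chi-square over tables with the observed fixed margins.

    Tables are drawn from the conditional distribution under independence
    (Patefield sampling); p = (1 + #{X2_sim >= X2_obs}) / (B + 1), which
    never returns an exact zero.
    """
    if B < 1:
        raise ContingencyError("B must be >= 1")
    arr = _as_table(t)
    x2_obs, expected = _pearson_x2(arr)
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(arr.sum(axis=1), arr.sum(axis=0), seed=rng)
    sims = sampler.rvs(B, method="patefield")
    x2_sim = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
    exceed = int((x2_sim >= x2_obs - 1e-9).sum())
    return x2_obs, (1 + exceed) / (B + 1)


# -- map comparison ------------------------------------------------------

@dataclass(frozen=True)
class MapComparison:
    per_interval_p: dict
    total_cM_a: float
    total_cM_b: float
    whole_chromosome_x2: float
    whole_chromosome_p: float
    distribution_x2: float
    distribution_p: float
    notes: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, v) for k, v in self.per_interval_p.items()],
            columns=["interval", "fisher_p"])


def compare_maps(im_a, im_b, B: int = 2000, seed=None) -> MapComparison:
    """Compare two interval maps over the same intervals.

    Per interval: Fisher exact on (recombinant, parental) x strain.  Whole
    chromosome: the chromosome treated as one interval — a chi-square on the
    2x2 of (total events, informative complement) per strain; this
    construction is a reconstruction, flagged in the notes.  Distribution:
    Monte-Carlo chi-square on the strains x intervals recombinant-count
    table.
    """
    from . import xo_map

    names_a = [iv.name for iv in im_a.intervals]
    names_b = [iv.name for iv in im_b.intervals]
    if names_a != names_b:
        raise ContingencyError("interval maps cover different intervals")

    per_interval = {}
    rec_a, rec_b = [], []
    for iv_a, iv_b in zip(im_a.intervals, im_b.intervals):
        tab = np.array([
            [iv_a.n_recombinant, iv_a.n_informative - iv_a.n_recombinant],
            [iv_b.n_recombinant, iv_b.n_informative - iv_b.n_recombinant],
        ])
        per_interval[iv_a.name] = (
            1.0 if tab.sum() == 0 else fisher_exact(tab))
        rec_a.append(iv_a.n_recombinant)
        rec_b.append(iv_b.n_recombinant)

    tot_rec_a = sum(rec_a)
    tot_inf_a = sum(iv.n_informative for iv in im_a.intervals)
    tot_rec_b = sum(rec_b)
    tot_inf_b = sum(iv.n_informative for iv in im_b.intervals)
    whole = np.array([[tot_rec_a, tot_inf_a - tot_rec_a],
                      [tot_rec_b, tot_inf_b - tot_rec_b]])
    x2_whole, _, p_whole = chisq(whole)

    dist = np.array([rec_a, rec_b])
    keep = dist.sum(axis=0) > 0
    if keep.sum() >= 2:
        x2_dist, p_dist = chisq_mc(dist[:, keep], B=B, seed=seed)
    else:
        x2_dist, p_dist = 0.0, 1.0

    return MapComparison(
        per_interval_p=per_interval,
        total_cM_a=xo_map.map_length(im_a),
        total_cM_b=xo_map.map_length(im_b),
        whole_chromosome_x2=x2_whole,
        whole_chromosome_p=p_whole,
        distribution_x2=x2_dist,
        distribution_p=p_dist,
        notes=(
            "whole-chromosome test: 2x2 of (crossover events, informative "
            "complement) per strain — a reconstruction of the "
            "chromosome-as-one-interval chi-square",
        ),
    )


# -- tetrad viability ----------------------------------------------------

@dataclass(frozen=True)
class TetradCounts:
    """Counts of tetrads with 4, 3, 2, 1, 0 viable spores, in that order."""

    counts: tuple[int, int, int, int, int]

    def __post_init__(self):
        counts = tuple(int(c) for c in self.counts)
        if len(counts) != 5 or any(c < 0 for c in counts):
            raise ContingencyError("need five non-negative class counts")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_dict(cls, d: dict) -> "TetradCounts":
        return cls(tuple(int(d.get(k, 0)) for k in (4, 3, 2, 1, 0)))

    @classmethod
    def from_tetrads(cls, tetrads) -> "TetradCounts":
        tally = {k: 0 for k in (4, 3, 2, 1, 0)}
        for t in tetrads:
            tally[t.n_viable] += 1
        return cls.from_dict(tally)

    @property
    def total(self) -> int:
        return sum(self.counts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class NDModelParams:
    v: float  # background spore death
    d: float  # MI nondisjunction per meiosis
    m: float  # MII nondisjunction per division

    def __post_init__(self):
        for name in ("v", "d", "m"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ContingencyError(f"{name} must lie in [0,1], got {val}")


def total_viability(tc: TetradCounts) -> float:
    """Overall spore viability percentage: 100 x sum(k n_k) / (4 sum n_k)."""
    if tc.total == 0:
        raise ContingencyError("no tetrads")
    weighted = sum(k * n for k, n in zip((4, 3, 2, 1, 0), tc.counts))
    return 100.0 * weighted / (4 * tc.total)


def tetrad_distribution_test(a: TetradCounts, b: TetradCounts,
                             B: int = 10_000, seed=None) -> float:
    """Exact test on the 2x5 table of viability-class counts; falls back to
    the Monte-Carlo chi-square (flagged by a warning) when enumeration is
    infeasible."""
    if a.total == 0 or b.total == 0:
        raise ContingencyError("both strains need tetrads")
    table = np.array([a.counts, b.counts])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        return 1.0
    try:
        return exact_rxc(table)
    except ContingencyError:
        warnings.warn("2x5 enumeration infeasible; using Monte-Carlo "
                      "chi-square approximation", stacklevel=2)
        _, p = chisq_mc(table, B=max(B, 10_000), seed=seed)
        return p


def nd_model_probs(params: NDModelParams) -> np.ndarray:
    """Closed-form class probabilities for (4, 3, 2, 1, 0) viable spores.

    With probability d the meiosis suffers MI nondisjunction (0 euploid
    spores); otherwise each MII division independently fails with
    probability m, costing that daughter's two spores; surviving euploid
    spores then die independently with probability v.
    """
    v, d, m = params.v, params.d, params.m
    p_euploid = {
        4: (1 - d) * (1 - m) ** 2,
        2: (1 - d) * 2 * m * (1 - m),
        0: d + (1 - d) * m ** 2,
    }
    probs = np.zeros(5)
    for e, pe in p_euploid.items():
        if pe == 0:
            continue
        for k in range(e + 1):
            probs[4 - k] += pe * stats.binom.pmf(k, e, 1 - v)
    return probs


@dataclass(frozen=True)
class NDFitResult:
    params: NDModelParams
    loglik: float
    ci: dict = field(default_factory=dict)  # name -> (lo, hi)
    flat_likelihood: bool = False

    @property
    def v(self):
        return self.params.v

    @property
    def d(self):
        return self.params.d

    @property
    def m(self):
        return self.params.m


def _nd_nll(theta: np.ndarray, counts: np.ndarray) -> float:
    params = NDModelParams(*np.clip(theta, 0.0, 1.0))
    probs = np.clip(nd_model_probs(params), 1e-300, 1.0)
    return float(-(counts * np.log(probs)).sum())


def _nd_mle(counts: np.ndarray, starts) -> tuple[np.ndarray, float]:
    best_x, best_f = None, np.inf
    for x0 in starts:
        res = optimize.minimize(
            _nd_nll, x0, args=(counts,), method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * 3)
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    return np.clip(best_x, 0.0, 1.0), -best_f


def nd_fit(tc: TetradCounts, n_boot: int = 1000, seed=None,
           min_tetrads: int = 20) -> NDFitResult:
    """Maximum-likelihood fit of (v, d, m) to tetrad viability-class counts,
    with percentile bootstrap confidence intervals."""
    if tc.total < min_tetrads:
        raise ContingencyError(
            f"need at least {min_tetrads} tetrads, got {tc.total}")
    counts = tc.as_array()
    rng = np.random.default_rng(seed)
    starts = [np.array([0.05, 0.05, 0.05]), np.array([0.02, 0.2, 0.05]),
              np.array([0.2, 0.02, 0.2]), np.array([0.01, 0.01, 0.01])]
    mle, loglik = _nd_mle(counts, starts)

    # flat-likelihood screen: random perturbations should lose likelihood
    flat = False
    for _ in range(8):
        probe = np.clip(mle + rng.normal(scale=0.05, size=3), 0, 1)
        if np.max(np.abs(probe - mle)) > 0.02 and \
                -_nd_nll(probe, counts) >= loglik - 1e-6:
            flat = True
            break
    if flat:
        warnings.warn("nondisjunction model likelihood is flat near the "
                      "optimum; the fit may be non-identifiable",
                      stacklevel=2)

    ci = {}
    if n_boot > 0:
        p_hat = counts / counts.sum()
        draws = rng.multinomial(tc.total, p_hat, size=n_boot).astype(float)
        boots = np.empty((n_boot, 3))
        for i, sample in enumerate(draws):
            boots[i], _ = _nd_mle(sample, [mle])
        lo = np.percentile(boots, 2.5, axis=0)
        hi = np.percentile(boots, 97.5, axis=0)
        ci = {name: (float(l), float(h))
              for name, l, h in zip(("v", "d", "m"), lo, hi)}

    return NDFitResult(params=NDModelParams(*mle), loglik=loglik, ci=ci,
                       flat_likelihood=flat)


def nd_zero_attribution(params: NDModelParams) -> float:
    """P(zero-viable via a single MI failure) / P(zero-viable via double
    MII failure): d / ((1-d) m^2).  Infinite when d > 0 and m = 0."""
    numerator = params.d
    denominator = (1 - params.d) * params.m ** 2
    if denominator == 0:
        return 0.0 if numerator == 0 else float("inf")
    return numerator / denominator


def spore_viability(spot_counts: Sequence[tuple[int, int]]) -> float:
    """Unweighted mean of per-spot germination percentages."""
    if not spot_counts:
        raise ContingencyError("no spots counted")
    pcts = []
    for germinated, total in spot_counts:
        if total <= 0:
            raise ContingencyError("spot with zero spores")
        pcts.append(100.0 * germinated / total)
    return float(np.mean(pcts))
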