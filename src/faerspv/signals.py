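"""Disproportionality signal detection on drug-event 2x2 tables.

For a target adverse event and each drug of interest, spontaneous-report
databases are summarized by the 2x2 table

    a = reports with the drug (primary suspect) and the event
    b = reports with the drug, other events
    c = reports with other drugs and the event
    d = reports with other drugs, other events

Four classical measures of disproportionate reporting are implemented:

* ROR  = ad/bc with a Wald 95% CI on the log scale;
* PRR  = [a/(a+b)] / [c/(c+d)] with the Pearson chi-square statistic;
* BCPNN information component IC = log2(a/E) with E = (a+b)(a+c)/N, and a
  lower credibility bound (Noren's closed-form approximation by default,
  the Bate-1998 Bayesian estimator as an alternative mode);
* MGPS empirical-Bayes geometric mean (EBGM) under a two-component gamma
  mixture prior fitted to the whole database by marginal maximum
  likelihood, with EBGM05 the 5th posterior percentile.

A drug-event pair is a *consensus signal* when it passes all four methods'
conventional thresholds.  The module also provides the algebraic inverse
``reconstruct_table`` which recovers the full 2x2 table from a published
(a, event total, ROR, PRR) quadruple, letting every derived column of a
published signal table be checked for self-consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug-event table; cells may be real-valued (reconstruction)."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        # float cells avoid int64 overflow in N*(ad-bc)^2 and allow
        # real-valued reconstructed tables
        for name in ("a", "b", "c", "d"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")
        if self.n <= 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def drug_margin(self) -> float:
        return self.a + self.b

    @property
    def event_margin(self) -> float:
        return self.a + self.c

    def corrected(self, add: float = 0.5) -> "ContingencyTable":
        """Haldane-Anscombe correction: add to every cell."""
        return ContingencyTable(self.a + add, self.b + add, self.c + add, self.d + add)

    def rounded(self) -> "ContingencyTable":
        return ContingencyTable(*(float(round(x)) for x in (self.a, self.b, self.c, self.d)))


@dataclass
class GammaMixturePrior:
    """DuMouchel two-component gamma prior on the relative reporting rate.

    The rate lambda of a pair's observed count a ~ Poisson(lambda*E) is
    drawn from w*Gamma(alpha1, beta1) + (1-w)*Gamma(alpha2, beta2)
    (shape/rate parameterization).
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    loglik: float = float("nan")
    converged: bool = True

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0.0 < self.w < 1.0:
            raise ValueError("mixture weight must lie in (0,1)")

    @property
    def mean(self) -> float:
        return self.w * self.alpha1 / self.beta1 + (1 - self.w) * self.alpha2 / self.beta2

    def as_dict(self) -> dict:
        return asdict(self)


#: DuMouchel's classic starting values (alpha1, beta1, alpha2, beta2, w).
DUMOUCHEL_INIT = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass
class SignalCriteria:
    """Per-method signal thresholds (classical literature values)."""

    ror_min_a: int = 3
    ror_ci_lower: float = 1.0
    prr_min: float = 2.0
    prr_chi2_min: float = 4.0
    prr_min_a: int = 3
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0


@dataclass
class SignalStats:
    """All four methods' statistics for one drug-event pair."""

    drug: str
    table: ContingencyTable
    ror: float = np.nan
    ror_lo: float = np.nan
    ror_hi: float = np.nan
    prr: float = np.nan
    chi2: float = np.nan
    expected: float = np.nan
    rr: float = np.nan
    ic: float = np.nan
    ic025: float = np.nan
    ebgm: float = np.nan
    ebgm05: float = np.nan
    flags: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# table construction

def build_contingency(store, drug: str, target_pts: Iterable[str]) -> ContingencyTable:
    """Count the 2x2 table for one drug from a deduplicated case store.

    ``a`` counts cases where the drug is a primary suspect and any target
    preferred term is present.  Cases with several PS drugs contribute to
    each drug's table; cases with no PS drug sit in the c/d margin.
    """
    ps = store.ps_drugs()
    drug_pids = set(ps.loc[ps["generic_name"] == drug, "primaryid"])
    event_pids = set(store.event_primaryids(target_pts))
    n = store.n_cases
    a = len(drug_pids & event_pids)
    b = len(drug_pids) - a
    c = len(event_pids) - a
    d = n - a - b - c
    return ContingencyTable(a, b, c, d)


def contingency_all(store, target_pts: Iterable[str],
                    drugs: Sequence[str] | None = None) -> pd.DataFrame:
    """Vectorized 2x2 tables for many drugs at once.

    Returns a frame indexed by drug with columns a, b, c, d.  ``drugs``
    defaults to every primary-suspect generic name in the store.
    """
    ps = store.ps_drugs().drop_duplicates(["primaryid", "generic_name"])
    event_pids = pd.Index(store.event_primaryids(target_pts))
    n = store.n_cases
    n_event = len(event_pids)
    ps = ps.assign(event=ps["primaryid"].isin(event_pids))
    grouped = ps.groupby("generic_name")["event"].agg(["size", "sum"])
    if drugs is not None:
        grouped = grouped.reindex(list(drugs), fill_value=0)
    out = pd.DataFrame(index=grouped.index)
    out["a"] = grouped["sum"].astype(int)
    out["b"] = (grouped["size"] - grouped["sum"]).astype(int)
    out["c"] = n_event - out["a"]
    out["d"] = n - n_event - out["b"]
    out.index.name = "drug"
    return out


# ---------------------------------------------------------------------------
# frequentist measures

def ror_with_ci(table: ContingencyTable, zero_correction: bool = False
                ) -> tuple[float, float, float]:
    """Reporting odds ratio with Wald 95% CI.

    Any zero cell makes the estimate undefined; with
    ``zero_correction=True`` the Haldane-Anscombe +0.5 is applied to all
    cells instead.  Undefined values are returned as NaN.
    """
    t = table
    if zero_correction and min(t.a, t.b, t.c, t.d) == 0:
        t = t.corrected()
    if min(t.a, t.b, t.c, t.d) <= 0:
        return (np.nan, np.nan, np.nan)
    ror = (t.a * t.d) / (t.b * t.c)
    se = np.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (ror, ror * np.exp(-Z_95 * se), ror * np.exp(Z_95 * se))


def prr_chi2(table: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Proportional reporting ratio and Pearson chi-square.

    The chi-square is the plain Pearson statistic
    N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)); Yates' continuity correction is
    available as an option but off by default.
    """
    t = table
    if t.drug_margin == 0 or (t.c + t.d) == 0 or t.c == 0:
        return (np.nan, np.nan)
    prr = (t.a / t.drug_margin) / (t.c / (t.c + t.d))
    denom = t.drug_margin * (t.c + t.d) * t.event_margin * (t.b + t.d)
    if denom == 0:
        return (prr, np.nan)
    dev = abs(t.a * t.d - t.b * t.c)
    if yates:
        dev = max(dev - t.n / 2.0, 0.0)
    chi2 = t.n * dev ** 2 / denom
    return (prr, chi2)


def expected_count(table: ContingencyTable) -> tuple[float, float]:
    """Independence-expected count E=(a+b)(a+c)/N and relative rate a/E."""
    t = table
    e = t.drug_margin * t.event_margin / t.n
    rr = t.a / e if e > 0 else np.nan
    return (e, rr)


# ---------------------------------------------------------------------------
# BCPNN

def bcpnn_ic(table: ContingencyTable, mode: str = "mle") -> tuple[float, float]:
    """Information component and its lower 2.5% bound.

    ``mode="mle"``: IC = log2(a/E), IC025 by Noren's closed form
    IC - 3.3*a^(-1/2) - 2*a^(-3/2).  ``mode="bate"``: the Bate-1998
    Bayesian posterior expectation and a normal-approximation bound from
    the posterior variance.  a = 0 is undefined in mle mode (NaN).
    """
    t = table
    if mode == "mle":
        e, rr = expected_count(t)
        if t.a <= 0 or e <= 0:
            return (np.nan, np.nan)
        ic = np.log2(rr)
        ic025 = ic - 3.3 * t.a ** -0.5 - 2.0 * t.a ** -1.5
        return (ic, ic025)
    if mode == "bate":
        return _bate_ic(t)
    raise ValueError(f"unknown BCPNN mode {mode!r}")


def _bate_ic(t: ContingencyTable) -> tuple[float, float]:
    """Bate et al. (1998) BCPNN estimator with Beta(1,1) margins."""
    n = t.n
    a1 = b1 = 1.0  # prior on P(drug), P(event)
    al = be = 2.0
    g11 = 1.0
    nx = t.drug_margin
    ny = t.event_margin
    gamma = g11 * (n + al) * (n + be) / ((nx + a1) * (ny + b1))
    e_ic = np.log2(
        (t.a + g11) * (n + al) * (n + be)
        / ((n + gamma) * (nx + a1) * (ny + b1))
    )
    var = (1 / np.log(2) ** 2) * (
        (n - t.a + gamma - g11) / ((t.a + g11) * (1 + n + gamma))
        + (n - nx + al - a1) / ((nx + a1) * (1 + n + al))
        + (n - ny + be - b1) / ((ny + b1) * (1 + n + be))
    )
    return (e_ic, e_ic - 1.96 * np.sqrt(var))


# ---------------------------------------------------------------------------
# MGPS

def _mixture_loglik(params: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    """Marginal log-likelihood of counts under the gamma-mixture prior.

    Marginally a ~ w*NB(alpha1, beta1/(beta1+E)) + (1-w)*NB(alpha2,
    beta2/(beta2+E)); params are log-transformed (logit for w).
    """
    la1, lb1, la2, lb2, zw = params
    al1, be1, al2, be2 = np.exp([la1, lb1, la2, lb2])
    w = special.expit(zw)
    with np.errstate(all="ignore"):
        l1 = _nb_logpmf(a, al1, be1 / (be1 + e))
        l2 = _nb_logpmf(a, al2, be2 / (be2 + e))
        m = np.maximum(l1, l2)
        mix = m + np.log(w * np.exp(l1 - m) + (1 - w) * np.exp(l2 - m))
    total = np.sum(mix)
    return float(total) if np.isfinite(total) else -1e300


def _nb_logpmf(k: np.ndarray, r: float, p) -> np.ndarray:
    return (special.gammaln(k + r) - special.gammaln(r) - special.gammaln(k + 1)
            + r * np.log(p) + k * np.log1p(-p))


def fit_mgps_hyperprior(
    a: Sequence[float],
    e: Sequence[float],
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
) -> GammaMixturePrior:
    """Fit the five MGPS hyperparameters by marginal maximum likelihood.

    Optimizes in log-parameterization (logit for the weight) with
    L-BFGS-B from multiple starts: DuMouchel's classic init plus seeded
    perturbations.  Deterministic for fixed inputs and seed.  Raises
    ``RuntimeError`` carrying the best-so-far prior if no start converges.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(e <= 0):
        raise ValueError("all expected counts must be positive")
    rng = np.random.default_rng(seed)
    base = np.array([np.log(DUMOUCHEL_INIT[0]), np.log(DUMOUCHEL_INIT[1]),
                     np.log(DUMOUCHEL_INIT[2]), np.log(DUMOUCHEL_INIT[3]),
                     special.logit(DUMOUCHEL_INIT[4])])
    starts = [base]
    for _ in range(n_starts - 1):
        starts.append(base + rng.normal(0, 1.0, size=5))

    best = None
    any_ok = False
    for x0 in starts:
        res = optimize.minimize(
            lambda p: -_mixture_loglik(p, a, e), x0, method="L-BFGS-B",
            bounds=[(-12.0, 12.0)] * 5,
            options={"ftol": tol, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
        any_ok = any_ok or res.success
    la1, lb1, la2, lb2, zw = best.x
    prior = GammaMixturePrior(
        alpha1=float(np.exp(la1)), beta1=float(np.exp(lb1)),
        alpha2=float(np.exp(la2)), beta2=float(np.exp(lb2)),
        w=float(special.expit(zw)), loglik=-float(best.fun), converged=any_ok,
    )
    if not any_ok:
        raise RuntimeError(
            f"MGPS hyperprior fit did not converge from any start; "
            f"best log-likelihood {prior.loglik:.3f}, prior {prior.as_dict()}")
    return prior


def posterior_mixture(a: float, e: float, prior: GammaMixturePrior
                      ) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Posterior of lambda given a: mixture weight and two gamma components.

    Returns ``(q, (shape1, rate1), (shape2, rate2))`` where q is the
    posterior probability of the first component.
    """
    l1 = _nb_logpmf(np.array([a]), prior.alpha1, prior.beta1 / (prior.beta1 + e))[0]
    l2 = _nb_logpmf(np.array([a]), prior.alpha2, prior.beta2 / (prior.beta2 + e))[0]
    m = max(l1, l2)
    w1 = prior.w * np.exp(l1 - m)
    w2 = (1 - prior.w) * np.exp(l2 - m)
    q = w1 / (w1 + w2)
    return (q, (prior.alpha1 + a, prior.beta1 + e), (prior.alpha2 + a, prior.beta2 + e))


def ebgm_scores(a: float, e: float, prior: GammaMixturePrior) -> tuple[float, float]:
    """EBGM and EBGM05 for one pair under a fitted prior.

    EBGM = exp(E[ln lambda | a]) using E[ln Gamma(shape, rate)] =
    psi(shape) - ln(rate); EBGM05 is the 5th percentile of the posterior
    gamma mixture, found by root-finding on its CDF.
    """
    q, (s1, r1), (s2, r2) = posterior_mixture(a, e, prior)
    e_ln = q * (special.digamma(s1) - np.log(r1)) + (1 - q) * (special.digamma(s2) - np.log(r2))
    ebgm = float(np.exp(e_ln))

    def cdf(x):
        return (q * special.gammainc(s1, r1 * x)
                + (1 - q) * special.gammainc(s2, r2 * x))

    lo, hi = 1e-12, 1.0
    while cdf(hi) < 0.05:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - pathological prior
            return (ebgm, np.nan)
    ebgm05 = float(optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-12))
    return (ebgm, ebgm05)


# ---------------------------------------------------------------------------
# flags and assembly

def evaluate_signal(s: SignalStats, criteria: SignalCriteria | None = None) -> dict:
    """Per-method signal booleans plus their conjunction.

    A method whose statistic is missing yields False and is listed under
    ``not_evaluable``.
    """
    c = criteria or SignalCriteria()
    a = s.table.a
    not_evaluable = []
    def ok(value):  # noqa: E306 - tiny local guard
        return value is not None and np.isfinite(value)

    if ok(s.ror_lo):
        f_ror = a >= c.ror_min_a and s.ror_lo > c.ror_ci_lower
    else:
        f_ror = False
        not_evaluable.append("ror")
    if ok(s.prr) and ok(s.chi2):
        f_prr = s.prr >= c.prr_min and s.chi2 >= c.prr_chi2_min and a >= c.prr_min_a
    else:
        f_prr = False
        not_evaluable.append("prr")
    if ok(s.ic025):
        f_ic = s.ic025 > c.ic025_min
    else:
        f_ic = False
        not_evaluable.append("bcpnn")
    if ok(s.ebgm05):
        f_mgps = s.ebgm05 > c.ebgm05_min
    else:
        f_mgps = False
        not_evaluable.append("mgps")
    return {
        "ror": bool(f_ror), "prr": bool(f_prr), "bcpnn": bool(f_ic),
        "mgps": bool(f_mgps),
        "consensus": bool(f_ror and f_prr and f_ic and f_mgps),
        "not_evaluable": not_evaluable,
    }


def compute_signal_stats(
    drug: str,
    table: ContingencyTable,
    prior: GammaMixturePrior | None = None,
    criteria: SignalCriteria | None = None,
    ic_mode: str = "mle",
    zero_correction: bool = False,
) -> SignalStats:
    """All four methods' statistics and flags for one drug-event pair."""
    s = SignalStats(drug=drug, table=table)
    s.ror, s.ror_lo, s.ror_hi = ror_with_ci(table, zero_correction=zero_correction)
    s.prr, s.chi2 = prr_chi2(table)
    s.expected, s.rr = expected_count(table)
    s.ic, s.ic025 = bcpnn_ic(table, mode=ic_mode)
    if prior is not None and s.expected > 0:
        s.ebgm, s.ebgm05 = ebgm_scores(table.a, s.expected, prior)
    s.flags = evaluate_signal(s, criteria)
    return s


def signal_table(
    tables: pd.DataFrame,
    prior: GammaMixturePrior | None = None,
    criteria: SignalCriteria | None = None,
    ic_mode: str = "mle",
) -> pd.DataFrame:
    """Per-drug signal summary frame from a ``contingency_all`` result.

    Columns mirror a published signal table: N (=a), ROR with CI, PRR with
    chi-square, EBGM with EBGM05, IC with IC025, per-method flags, and
    the consensus flag.
    """
    rows = []
    for drug, row in tables.iterrows():
        t = ContingencyTable(row["a"], row["b"], row["c"], row["d"])
        s = compute_signal_stats(str(drug), t, prior=prior, criteria=criteria,
                                 ic_mode=ic_mode)
        rows.append({
            "drug": drug, "a": int(t.a), "b": int(t.b), "c": int(t.c), "d": int(t.d),
            "ror": s.ror, "ror_lo": s.ror_lo, "ror_hi": s.ror_hi,
            "prr": s.prr, "chi2": s.chi2, "expected": s.expected, "rr": s.rr,
            "ic": s.ic, "ic025": s.ic025, "ebgm": s.ebgm, "ebgm05": s.ebgm05,
            "flag_ror": s.flags["ror"], "flag_prr": s.flags["prr"],
            "flag_bcpnn": s.flags["bcpnn"], "flag_mgps": s.flags["mgps"],
            "consensus": s.flags["consensus"],
        })
    return pd.DataFrame(rows).set_index("drug")


# ---------------------------------------------------------------------------
# algebraic reconstruction

def reconstruct_table(a: float, event_total: float, ror: float, prr: float
                      ) -> ContingencyTable:
    """Recover the full 2x2 table from (a, event margin, ROR, PRR).

    With c = event_total - a fixed, the ROR and PRR identities are linear
    in b and d:  b = a(PRR-1)/(ROR-PRR),  d = ROR*b*c/a.  Raises
    ``ValueError`` for non-reconstructible inputs (ROR = PRR, or a
    negative solution).  Cells are returned unrounded; use ``.rounded()``
    for integer counts.
    """
    if not 0 < a < event_total:
        raise ValueError("a must lie strictly between 0 and event_total")
    if ror == prr:
        raise ValueError("non-reconstructible inputs: ror equals prr")
    c = event_total - a
    b = a * (prr - 1.0) / (ror - prr)
    if b <= 0:
        raise ValueError("non-reconstructible inputs: negative drug margin")
    d = ror * b * c / a
    if d <= 0:
        raise ValueError("non-reconstructible inputs: negative d cell")
    table = ContingencyTable(a, b, c, d)
    # self-check: both identities must hold to near machine precision
    ror_back = (table.a * table.d) / (table.b * table.c)
    prr_back = (table.a / table.drug_margin) / (table.c / (table.c + table.d))
    if abs(ror_back - ror) > 1e-9 * ror or abs(prr_back - prr) > 1e-9 * prr:
        raise ValueError("reconstruction failed self-check")  # pragma: no cover
    return table
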