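"""Disproportionality statistics over report–event contingency tables.

For every event term (MedDRA PT, or SOC) with at least one target-drug
report, a four-compartment table is built over unique (report, term) pairs:

    a  target drug & target event      b  target drug & other events
    c  other drugs & target event      d  other drugs & other events

Four signal statistics are computed per table:

* ROR  — reporting odds ratio ad/bc, Woolf log-normal 95% CI.
* PRR  — proportional reporting ratio [a/(a+b)]/[c/(c+d)] with Pearson χ²
  on the 2×2 (no continuity correction by default; Yates switchable).
* BCPNN IC — Bayesian information component log2 P(drug,event)/P(drug)P(event)
  in the closed posterior form of Bate et al. (1998) with the standard
  weakly-informative priors; IC025 = E(IC) − 2√V(IC).
* MGPS EBGM — DuMouchel's (1999) empirical-Bayes geometric mean of the
  posterior relative reporting rate λ under a two-component gamma mixture
  prior fitted by maximum marginal likelihood across all tables; EB05 is
  the 5th posterior percentile.

A term is *retained* when it passes all four standard criteria
(a≥3 & ROR lower CI>1; a≥3 & PRR≥2 & χ²≥4; IC025>0; EB05>2); an
"any k of 4" rule is available as a configuration switch.  Tables with a
zero cell make ROR/PRR non-evaluable (flag false) — no Haldane correction
is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import digamma, gammainc, gammaln

__all__ = [
    "ContingencyTable",
    "RorResult",
    "PrrResult",
    "IcResult",
    "EbgmResult",
    "MgpsPrior",
    "ScreenConfig",
    "SignalResult",
    "DUMOUCHEL_START",
    "build_tables",
    "ror_stat",
    "prr_stat",
    "bcpnn_ic",
    "fit_mgps_prior",
    "ebgm_stat",
    "evaluate_criteria",
    "screen",
    "results_frame",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Four-compartment counts for one (drug, event) pair.

    Counting unit is the unique (report, term) pair: one report can
    contribute several terms, each term once.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.N <= 0:
            raise ValueError("contingency table must have N > 0")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count under independence, E = (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.N


class RorResult(NamedTuple):
    ror: float
    ci_low: float
    ci_high: float


class PrrResult(NamedTuple):
    prr: float
    chi2: float


class IcResult(NamedTuple):
    ic: float
    ic025: float


class EbgmResult(NamedTuple):
    ebgm: float
    eb05: float


def build_tables(
    event_rows: pd.DataFrame,
    cohort_ids: Iterable[str],
    level: str = "PT",
) -> dict[str, ContingencyTable]:
    """Contingency tables for every term with a ≥ 1.

    ``event_rows`` is the coded event table over the FULL deduplicated
    database (cohort + background).  At SOC level a report counts once per
    organ class regardless of how many of its PTs fall in it.  N and the
    cohort pair total a+b are identical across all terms at a given level.
    """
    if level not in ("PT", "SOC"):
        raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")
    col = "pt" if level == "PT" else "soc"
    if event_rows.empty:
        return {}
    pairs = event_rows.loc[:, ["primaryid", col]].drop_duplicates()
    N = len(pairs)
    in_cohort = pairs["primaryid"].isin(set(cohort_ids)).to_numpy()
    cohort_total = int(in_cohort.sum())
    a_counts = pairs.loc[in_cohort, col].value_counts()
    term_totals = pairs[col].value_counts()
    tables: dict[str, ContingencyTable] = {}
    for term, a in a_counts.items():
        a = int(a)
        tt = int(term_totals[term])
        tables[str(term)] = ContingencyTable(
            a=a, b=cohort_total - a, c=tt - a, d=N - cohort_total - tt + a
        )
    return tables


def ror_stat(t: ContingencyTable) -> RorResult | None:
    """Reporting odds ratio with Woolf 95% CI; None (non-evaluable) when
    any cell is zero."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return None
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return RorResult(ror, ror * math.exp(-1.96 * se), ror * math.exp(1.96 * se))


def prr_stat(t: ContingencyTable, *, yates: bool = False) -> PrrResult | None:
    """Proportional reporting ratio and Pearson χ² (continuity correction
    optional); None when a margin is zero."""
    ab, cd, ac, bd = t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d
    if min(ab, cd, ac, bd) == 0 or t.c == 0:
        return None
    prr = (t.a / ab) / (t.c / cd)
    diff = abs(t.a * t.d - t.b * t.c)
    if yates:
        diff = max(diff - t.N / 2, 0.0)
    chi2 = t.N * diff * diff / (ab * cd * ac * bd)
    return PrrResult(prr, chi2)


# BCPNN hyperparameters of Bate et al. (1998): uniform Beta(1,1) margins
# and a joint prior calibrated so E[p11] = E[p1]E[p2] a priori.
_A1 = _B1 = 1.0
_AL = _BE = 2.0
_G11 = 1.0


def bcpnn_ic(t: ContingencyTable) -> IcResult:
    """Closed-form posterior expectation and lower 95% bound of the
    information component; IC025 = E(IC) − 2√V(IC)."""
    a, N = t.a, t.N
    ab, ac = t.a + t.b, t.a + t.c
    g = _G11 * (N + _AL) * (N + _BE) / ((ab + _A1) * (ac + _B1))
    eic = math.log2(
        (a + _G11) * (N + _AL) * (N + _BE) / ((N + g) * (ab + _A1) * (ac + _B1))
    )
    vic = (
        (N - a + g - _G11) / ((a + _G11) * (1 + N + g))
        + (N - ab + _AL - _A1) / ((ab + _A1) * (1 + N + _AL))
        + (N - ac + _BE - _B1) / ((ac + _B1) * (1 + N + _BE))
    ) / math.log(2) ** 2
    return IcResult(eic, eic - 2 * math.sqrt(vic))


@dataclass(frozen=True)
class MgpsPrior:
    """Two-component gamma mixture prior for the relative reporting rate λ,
    parameterized by shapes α, rates β and mixture weight w."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    loglik: float = float("nan")
    converged: bool = True
    n_cells: int = 0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma mixture shapes/rates must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")


#: DuMouchel's published starting point (α1, β1, α2, β2, w).
DUMOUCHEL_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _nb_logpmf(a: np.ndarray, alpha: float, beta: float, E: np.ndarray) -> np.ndarray:
    """Negative-binomial marginal of a Poisson(λE) count with λ ~
    Gamma(shape α, rate β): size α, success prob β/(β+E)."""
    p = beta / (beta + E)
    return (
        gammaln(alpha + a)
        - gammaln(alpha)
        - gammaln(a + 1.0)
        + alpha * np.log(p)
        + a * np.log1p(-p)
    )


def _log_w(theta4: float) -> tuple[float, float]:
    # stable log(sigmoid) and log(1 - sigmoid)
    return -np.logaddexp(0.0, -theta4), -np.logaddexp(0.0, theta4)


def fit_mgps_prior(
    tables: Iterable[ContingencyTable],
    *,
    seed: int = 0,
    tol: float = 1e-8,
    n_jitter: int = 4,
    max_iter: int = 4000,
) -> MgpsPrior:
    """Empirical-Bayes fit of the gamma-mixture hyperparameters.

    Maximizes the summed log negative-binomial mixture marginal of the
    observed counts a_i given expectations E_i over (α1, β1, α2, β2, w).
    Multi-start quasi-Newton (L-BFGS-B) on a log/logit transform so
    positivity and the [0,1] weight box hold by construction: DuMouchel's
    published start plus ``n_jitter`` jittered starts (fixed seed), best
    final value wins; deterministic given the seed.
    """
    tabs = list(tables)
    a = np.array([t.a for t in tabs], dtype=float)
    E = np.array([t.expected for t in tabs], dtype=float)
    keep = E > 0
    a, E = a[keep], E[keep]
    if a.size == 0 or np.all(a == 0):
        raise ValueError("degenerate data for MGPS fit: no cells with a positive count")

    def nll(theta: np.ndarray) -> float:
        with np.errstate(over="ignore"):
            a1, b1, a2, b2 = np.exp(np.clip(theta[:4], -30, 30))
        lw1, lw2 = _log_w(float(theta[4]))
        l1 = _nb_logpmf(a, a1, b1, E)
        l2 = _nb_logpmf(a, a2, b2, E)
        val = -float(np.logaddexp(lw1 + l1, lw2 + l2).sum())
        return val if np.isfinite(val) else 1e300

    rng = np.random.default_rng(seed)
    starts = [DUMOUCHEL_START]
    for _ in range(n_jitter):
        jitter = np.exp(rng.normal(0.0, 0.5, size=4)) * np.array(DUMOUCHEL_START[:4])
        w_j = 1.0 / (1.0 + math.exp(-(math.log(0.5) + rng.normal(0.0, 1.0))))
        starts.append((*jitter, w_j))

    best = None
    traces = []
    for s in starts:
        theta0 = np.array([math.log(v) for v in s[:4]] + [math.log(s[4] / (1 - s[4]))])
        res = minimize(
            nll,
            theta0,
            method="L-BFGS-B",
            bounds=[(-14.0, 14.0)] * 5,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
        )
        traces.append((s, float(res.fun), bool(res.success)))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"MGPS hyperparameter fit failed from every start: {traces}")
    a1, b1, a2, b2 = np.exp(best.x[:4])
    w = 1.0 / (1.0 + math.exp(-float(best.x[4])))
    return MgpsPrior(
        float(a1), float(b1), float(a2), float(b2), float(w),
        loglik=-float(best.fun),
        converged=bool(best.success),
        n_cells=int(a.size),
    )


def ebgm_stat(t: ContingencyTable, prior: MgpsPrior) -> EbgmResult | None:
    """Posterior EBGM = 2^{E[log2 λ | a]} and EB05 (5th percentile).

    The posterior over λ is again a two-gamma mixture with components
    Gamma(αj + a, βj + E) and weight proportional to the prior weight times
    the negative-binomial marginal likelihood of a.  E[ln λ] uses the
    digamma function; EB05 is found by root-finding on the mixture CDF.
    """
    E = t.expected
    if E <= 0:
        return None
    a = float(t.a)
    aE = np.array([E])
    l1 = float(_nb_logpmf(np.array([a]), prior.alpha1, prior.beta1, aE)[0])
    l2 = float(_nb_logpmf(np.array([a]), prior.alpha2, prior.beta2, aE)[0])
    if prior.w <= 0.0:
        q1 = 0.0
    elif prior.w >= 1.0:
        q1 = 1.0
    else:
        lw1 = math.log(prior.w) + l1
        lw2 = math.log1p(-prior.w) + l2
        m = np.logaddexp(lw1, lw2)
        q1 = float(np.exp(lw1 - m))
    q2 = 1.0 - q1
    s1, r1 = prior.alpha1 + a, prior.beta1 + E
    s2, r2 = prior.alpha2 + a, prior.beta2 + E
    elog = q1 * (digamma(s1) - math.log(r1)) + q2 * (digamma(s2) - math.log(r2))
    ebgm = math.exp(elog)

    def cdf(x: float) -> float:
        return q1 * gammainc(s1, r1 * x) + q2 * gammainc(s2, r2 * x)

    hi = max(10.0 * ebgm, 10.0)
    while cdf(hi) < 0.05:
        hi *= 10.0
    eb05 = brentq(lambda x: cdf(x) - 0.05, 1e-12, hi, xtol=1e-8)
    return EbgmResult(ebgm, float(eb05))


@dataclass(frozen=True)
class ScreenConfig:
    """Signal criteria thresholds and screening options.

    Defaults are the four standard published criteria; ``retention`` is
    "all" (conjunction) or an integer k for "significant in ≥ k of 4".
    """

    min_cases: int = 3
    ror_ci_low: float = 1.0
    prr_threshold: float = 2.0
    chi2_threshold: float = 4.0
    ic025_threshold: float = 0.0
    eb05_threshold: float = 2.0
    yates: bool = False
    retention: str | int = "all"
    mgps_seed: int = 0
    mgps_tol: float = 1e-8
    mgps_n_jitter: int = 4

    def __post_init__(self) -> None:
        if isinstance(self.retention, int) and not 1 <= self.retention <= 4:
            raise ValueError("integer retention rule must be between 1 and 4")
        if self.retention not in ("all",) and not isinstance(self.retention, int):
            raise ValueError(f"unknown retention rule {self.retention!r}")


@dataclass
class SignalResult:
    """All statistics, per-algorithm flags and the retention verdict for
    one term at one level."""

    level: str
    term: str
    soc: str
    table: ContingencyTable
    ror: RorResult | None = None
    prr: PrrResult | None = None
    ic: IcResult | None = None
    ebgm: EbgmResult | None = None
    flags: dict[str, bool] = field(default_factory=dict)
    retained: bool = False


def evaluate_criteria(res: SignalResult, config: ScreenConfig = ScreenConfig()) -> SignalResult:
    """Set the per-algorithm flags and the retention verdict in place.

    A non-evaluable statistic (None) always yields a false flag.
    """
    a = res.table.a
    flags = {
        "ROR": res.ror is not None and a >= config.min_cases and res.ror.ci_low > config.ror_ci_low,
        "PRR": (
            res.prr is not None
            and a >= config.min_cases
            and res.prr.prr >= config.prr_threshold
            and res.prr.chi2 >= config.chi2_threshold
        ),
        "BCPNN": res.ic is not None and res.ic.ic025 > config.ic025_threshold,
        "MGPS": res.ebgm is not None and res.ebgm.eb05 > config.eb05_threshold,
    }
    res.flags = flags
    n_true = sum(flags.values())
    res.retained = n_true == 4 if config.retention == "all" else n_true >= int(config.retention)
    return res


def screen(
    event_rows: pd.DataFrame,
    cohort_ids: Iterable[str],
    level: str = "PT",
    *,
    config: ScreenConfig | None = None,
    prior: MgpsPrior | None = None,
) -> list[SignalResult]:
    """Full disproportionality screen at one level.

    Computes all four statistics for every term with a ≥ 1, fitting the
    MGPS prior across all tables at this level unless one is supplied.
    Output is sorted by SOC, then descending a, then term, and includes
    retained and non-retained terms with their flags.
    """
    config = config or ScreenConfig()
    tables = build_tables(event_rows, cohort_ids, level)
    if not tables:
        return []
    if prior is None:
        prior = fit_mgps_prior(
            tables.values(),
            seed=config.mgps_seed,
            tol=config.mgps_tol,
            n_jitter=config.mgps_n_jitter,
        )
    if level == "PT":
        soc_of = dict(
            event_rows.drop_duplicates("pt")[["pt", "soc"]].itertuples(index=False, name=None)
        )
    results = []
    for term, t in tables.items():
        res = SignalResult(
            level=level,
            term=term,
            soc=term if level == "SOC" else soc_of.get(term, "UNMAPPED"),
            table=t,
            ror=ror_stat(t),
            prr=prr_stat(t, yates=config.yates),
            ic=bcpnn_ic(t),
            ebgm=ebgm_stat(t, prior),
        )
        results.append(evaluate_criteria(res, config))
    results.sort(key=lambda r: (r.soc, -r.table.a, r.term))
    return results


def results_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Flatten screen output to the standard signal-table layout:
    term, SOC, case count, ROR (CI), PRR (χ²), EBGM (EB05), IC (IC025),
    per-algorithm flags and the retention verdict."""
    columns = [
        "level", "soc", "term", "a", "b", "c", "d",
        "ror", "ror_ci_low", "ror_ci_high", "prr", "chi2",
        "ebgm", "eb05", "ic", "ic025",
        "flag_ror", "flag_prr", "flag_bcpnn", "flag_mgps", "retained",
    ]
    if not results:
        return pd.DataFrame(columns=columns)
    rows = []
    for r in results:
        rows.append(
            {
                "level": r.level,
                "soc": r.soc,
                "term": r.term,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "ror": r.ror.ror if r.ror else float("nan"),
                "ror_ci_low": r.ror.ci_low if r.ror else float("nan"),
                "ror_ci_high": r.ror.ci_high if r.ror else float("nan"),
                "prr": r.prr.prr if r.prr else float("nan"),
                "chi2": r.prr.chi2 if r.prr else float("nan"),
                "ebgm": r.ebgm.ebgm if r.ebgm else float("nan"),
                "eb05": r.ebgm.eb05 if r.ebgm else float("nan"),
                "ic": r.ic.ic if r.ic else float("nan"),
                "ic025": r.ic.ic025 if r.ic else float("nan"),
                "flag_ror": r.flags.get("ROR", False),
                "flag_prr": r.flags.get("PRR", False),
                "flag_bcpnn": r.flags.get("BCPNN", False),
                "flag_mgps": r.flags.get("MGPS", False),
                "retained": r.retained,
            }
        )
    return pd.DataFrame(rows)
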