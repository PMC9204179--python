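"""Empirical-Bayes gamma-Poisson shrinkage for spontaneous-report tables.

Model
-----
For a drug x event contingency table with cell counts N_ij, the baseline
expected count under independence of the margins is

    E_ij = N_i. * N_.j / N_..

Each cell's relative reporting rate lambda has a two-component gamma mixture
prior (shape/rate parameterization throughout),

    lambda ~ pi * Gamma(alpha1, beta1) + (1 - pi) * Gamma(alpha2, beta2),
    N | lambda ~ Poisson(lambda * E),

so the marginal of N is a mixture of two negative binomials with success
probability beta/(beta + E).  Hyperparameters theta = (alpha1, beta1,
alpha2, beta2, pi) are estimated by maximizing the marginal likelihood over
all cells; the posterior for a cell is the conjugate gamma mixture with
component weight Q_n, and the empirical Bayes geometric mean is

    EBGM = 2 ** E[log2 lambda | N],
    E[log2 lambda | N] = [Q_n (psi(a1+N) - ln(b1+E))
                          + (1-Q_n)(psi(a2+N) - ln(b2+E))] / ln 2,

with EB05/EB95 the posterior 5th/95th percentiles of lambda.  No
stratification is applied when computing E (a documented extension point).

The model is exposed statsmodels-style: :class:`GammaPoissonShrinker` is
built from a report table and ``fit()`` returns :class:`GPSResults` carrying
the fitted prior, its log-likelihood, per-cell posterior summaries, and a
``summary()`` table.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from ._text import quarter_key

__all__ = [
    "MixturePrior",
    "ReportTable",
    "GammaPoissonShrinker",
    "GPSResults",
    "PosteriorSummary",
    "expected_counts",
    "marginal_loglik",
    "fit_prior",
    "posterior_summary",
    "cumulative_quarterly_ebgm",
    "CANONICAL_START",
]

_LOG2 = np.log(2.0)
PARAM_BOUNDS = (1e-4, 1e4)       # box bounds on shapes and rates
_LOGIT_BOUND = 15.0              # keeps pi in (~3e-7, 1 - 3e-7)


class FitError(RuntimeError):
    """Hyperparameter optimization failed on every restart."""


@dataclass(frozen=True)
class MixturePrior:
    """Two-gamma mixture prior on the relative reporting rate lambda."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    pi: float

    def validate(self) -> "MixturePrior":
        for name in ("alpha1", "beta1", "alpha2", "beta2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi must be in [0,1], got {self.pi}")
        return self

    @property
    def mean(self) -> float:
        """Prior mean of lambda."""
        return self.pi * self.alpha1 / self.beta1 + (1 - self.pi) * self.alpha2 / self.beta2

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.beta1, self.alpha2, self.beta2, self.pi])


#: canonical optimizer start (the traditional gamma-Poisson shrinker default)
CANONICAL_START = MixturePrior(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


# ---------------------------------------------------------------------------
# Report table
# ---------------------------------------------------------------------------

class ReportTable:
    """Drug x event count table with margins and independence-model E.

    Rows or columns whose margin is zero carry no information and are
    dropped at construction so that E > 0 for every retained cell.
    """

    def __init__(self, counts: pd.DataFrame):
        counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("report counts must be non-negative integers")
        counts = counts.loc[counts.sum(axis=1) > 0, counts.sum(axis=0) > 0]
        if counts.size == 0:
            raise ValueError("empty report table")
        self.counts = counts

    @classmethod
    def from_reports(
        cls,
        reports: pd.DataFrame,
        through_quarter: str | None = None,
    ) -> "ReportTable":
        """Aggregate tidy rows (drug, event_pt[, quarter], count) into a table.

        ``through_quarter`` keeps only rows with quarter <= the given label
        (cumulative slicing).
        """
        df = reports.copy()
        if through_quarter is not None:
            if "quarter" not in df.columns:
                raise ValueError("cumulative slicing requires a 'quarter' column")
            cutoff = quarter_key(through_quarter)
            df = df[df["quarter"].map(quarter_key) <= cutoff]
        if df.empty:
            raise ValueError("no reports in the requested window")
        pivot = df.pivot_table(
            index="drug", columns="event_pt", values="count", aggfunc="sum", fill_value=0
        )
        return cls(pivot)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def expected(self) -> pd.DataFrame:
        """E_ij = N_i. * N_.j / N_.. — sums to the grand total."""
        n = self.counts.to_numpy(dtype=float)
        row = n.sum(axis=1, keepdims=True)
        col = n.sum(axis=0, keepdims=True)
        return pd.DataFrame(row * col / n.sum(), index=self.counts.index,
                            columns=self.counts.columns)

    def flat(self) -> pd.DataFrame:
        """Tidy cells: drug, event_pt, N, E."""
        e = self.expected()
        out = self.counts.stack().rename("N").reset_index()
        out.columns = ["drug", "event_pt", "N"]
        out["E"] = e.stack().to_numpy()
        return out


def expected_counts(table: ReportTable) -> pd.DataFrame:
    """Independence-model expected counts for every cell of the table."""
    return table.expected()


# ---------------------------------------------------------------------------
# Marginal likelihood
# ---------------------------------------------------------------------------

def _marginal_logpmf_components(
    n: np.ndarray, e: np.ndarray, prior: MixturePrior
) -> tuple[np.ndarray, np.ndarray]:
    lp1 = stats.nbinom.logpmf(n, prior.alpha1, prior.beta1 / (prior.beta1 + e))
    lp2 = stats.nbinom.logpmf(n, prior.alpha2, prior.beta2 / (prior.beta2 + e))
    with np.errstate(divide="ignore"):
        lw1 = np.log(prior.pi) if prior.pi > 0 else -np.inf
        lw2 = np.log1p(-prior.pi) if prior.pi < 1 else -np.inf
    return lw1 + lp1, lw2 + lp2


def marginal_logpmf(n, e, prior: MixturePrior) -> np.ndarray:
    """Per-cell log marginal P(N | E, theta): mixture of negative binomials."""
    prior.validate()
    n = np.atleast_1d(np.asarray(n))
    e = np.atleast_1d(np.asarray(e, dtype=float))
    if np.any(e <= 0):
        raise ValueError("all expected counts must be > 0")
    t1, t2 = _marginal_logpmf_components(n, e, prior)
    return np.logaddexp(t1, t2)


def marginal_loglik(n, e, prior: MixturePrior) -> float:
    """Summed log marginal likelihood over cells (computed in log space)."""
    per_cell = marginal_logpmf(n, e, prior)
    bad = np.flatnonzero(~np.isfinite(per_cell))
    if bad.size:
        i = int(bad[0])
        raise FloatingPointError(
            f"non-finite marginal log-likelihood at cell {i} "
            f"(N={np.atleast_1d(n)[i]}, E={np.atleast_1d(e)[i]})"
        )
    return float(per_cell.sum())


# ---------------------------------------------------------------------------
# Hyperparameter fitting
# ---------------------------------------------------------------------------

def _to_unconstrained(prior: MixturePrior) -> np.ndarray:
    a = prior.as_array()
    return np.concatenate([np.log(a[:4]), [special.logit(a[4])]])


def _from_unconstrained(x: np.ndarray) -> MixturePrior:
    a = np.exp(x[:4])
    return MixturePrior(a[0], a[1], a[2], a[3], float(special.expit(x[4])))


@dataclass(frozen=True)
class PriorFit:
    prior: MixturePrior
    llf: float
    converged: bool
    n_restarts: int
    start: MixturePrior


def fit_prior(
    n,
    e,
    start: MixturePrior = CANONICAL_START,
    n_restarts: int = 4,
    seed: int = 0,
) -> PriorFit:
    """Maximize the marginal likelihood by bounded quasi-Newton (L-BFGS-B).

    Optimization runs in log/logit-transformed space with box bounds
    [1e-4, 1e4] on shapes/rates.  The canonical start is tried first, then
    ``n_restarts`` jittered restarts drawn from a fixed-seed stream; the best
    restart is returned.  Deterministic for fixed seed.
    """
    n = np.asarray(n).ravel()
    e = np.asarray(e, dtype=float).ravel()
    if n.size < 5:
        raise ValueError(f"need >=5 cells to fit the prior, got {n.size}")
    if np.any(e <= 0):
        raise ValueError("all expected counts must be > 0")

    lo, hi = np.log(PARAM_BOUNDS[0]), np.log(PARAM_BOUNDS[1])
    bounds = [(lo, hi)] * 4 + [(-_LOGIT_BOUND, _LOGIT_BOUND)]

    def neg_ll(x: np.ndarray) -> float:
        prior = _from_unconstrained(x)
        t1, t2 = _marginal_logpmf_components(n, e, prior)
        per_cell = np.logaddexp(t1, t2)
        if not np.all(np.isfinite(per_cell)):
            return 1e300
        return -float(per_cell.sum())

    rng = np.random.default_rng(seed)
    x0 = np.clip(_to_unconstrained(start), [b[0] for b in bounds], [b[1] for b in bounds])
    starts = [x0]
    for _ in range(n_restarts):
        starts.append(
            np.clip(x0 + rng.normal(0.0, 0.5, size=5),
                    [b[0] for b in bounds], [b[1] for b in bounds])
        )

    best: optimize.OptimizeResult | None = None
    any_converged = False
    for x_init in starts:
        res = optimize.minimize(neg_ll, x_init, method="L-BFGS-B", bounds=bounds)
        if np.isfinite(res.fun):
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
    if best is None or not any_converged:
        raise FitError(
            "prior optimization failed to converge on all restarts; "
            f"last trace: {best.message if best is not None else 'no finite objective'}"
        )
    return PriorFit(
        prior=_from_unconstrained(best.x).validate(),
        llf=-float(best.fun),
        converged=True,
        n_restarts=n_restarts,
        start=start,
    )


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Per-cell posterior quantities (arrays aligned with the input cells)."""

    N: np.ndarray
    E: np.ndarray
    Q1: np.ndarray        # posterior weight of component 1
    eblog2: np.ndarray    # posterior mean of log2 lambda
    ebgm: np.ndarray      # 2 ** eblog2
    eb05: np.ndarray | None = None
    eb95: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"N": self.N, "E": self.E, "Q1": self.Q1, "EBGM": self.ebgm}
        if self.eb05 is not None:
            data["EB05"] = self.eb05
            data["EB95"] = self.eb95
        return pd.DataFrame(data)


def _mixture_quantile(
    p: float, q1: float, a1: float, b1: float, a2: float, b2: float
) -> float:
    """Quantile of q1*Gamma(a1,b1) + (1-q1)*Gamma(a2,b2) by bracketed root-finding.

    The mixture quantile lies between the component quantiles, which supplies
    the bracket; the root of CDF(x) - p is located to high precision so the
    CDF at the returned point is within 1e-6 of p.
    """
    if q1 >= 1.0 - 1e-12:
        return float(stats.gamma.ppf(p, a1, scale=1.0 / b1))
    if q1 <= 1e-12:
        return float(stats.gamma.ppf(p, a2, scale=1.0 / b2))
    x1 = stats.gamma.ppf(p, a1, scale=1.0 / b1)
    x2 = stats.gamma.ppf(p, a2, scale=1.0 / b2)
    lo, hi = min(x1, x2), max(x1, x2)

    def cdf_diff(x: float) -> float:
        return (
            q1 * special.gammainc(a1, b1 * x)
            + (1.0 - q1) * special.gammainc(a2, b2 * x)
            - p
        )

    if hi - lo < 1e-14:
        return float(lo)
    return float(optimize.brentq(cdf_diff, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200))


def posterior_summary(
    n, e, prior: MixturePrior, quantiles: bool = True
) -> PosteriorSummary:
    """Conjugate posterior summaries for cells (N, E) under a mixture prior.

    Posterior: Q_n * Gamma(a1+N, b1+E) + (1-Q_n) * Gamma(a2+N, b2+E), with
    Q_n proportional to pi * NB1(N).  EBGM is the posterior geometric mean of
    lambda on the base-2 log scale; EB05/EB95 are posterior percentiles of
    lambda found by bracketed root-finding on the mixture CDF.
    """
    prior.validate()
    n = np.atleast_1d(np.asarray(n, dtype=float))
    e = np.atleast_1d(np.asarray(e, dtype=float))
    if np.any(e <= 0):
        raise ValueError("expected count E must be > 0")

    t1, t2 = _marginal_logpmf_components(n, e, prior)
    denom = np.logaddexp(t1, t2)
    with np.errstate(invalid="ignore"):
        q1 = np.exp(t1 - denom)
    q1 = np.clip(np.nan_to_num(q1, nan=0.0), 0.0, 1.0)

    a1p, b1p = prior.alpha1 + n, prior.beta1 + e
    a2p, b2p = prior.alpha2 + n, prior.beta2 + e
    eblog2 = (
        q1 * (special.digamma(a1p) - np.log(b1p))
        + (1.0 - q1) * (special.digamma(a2p) - np.log(b2p))
    ) / _LOG2
    ebgm = np.exp2(eblog2)

    eb05 = eb95 = None
    if quantiles:
        eb05 = np.array([
            _mixture_quantile(0.05, q1[i], a1p[i], b1p[i], a2p[i], b2p[i])
            for i in range(n.size)
        ])
        eb95 = np.array([
            _mixture_quantile(0.95, q1[i], a1p[i], b1p[i], a2p[i], b2p[i])
            for i in range(n.size)
        ])
    return PosteriorSummary(n.astype(int), e, q1, eblog2, ebgm, eb05, eb95)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class GammaPoissonShrinker:
    """Empirical-Bayes gamma-Poisson shrinkage model for a report table.

    Parameters
    ----------
    table : ReportTable or tidy DataFrame with columns drug, event_pt, count
        The drug x event contingency data.
    """

    def __init__(self, table: ReportTable | pd.DataFrame):
        if isinstance(table, pd.DataFrame):
            table = ReportTable.from_reports(table)
        self.table = table
        cells = table.flat()
        self.cells = cells
        self.endog = cells["N"].to_numpy()
        self.expected = cells["E"].to_numpy(dtype=float)

    @property
    def nobs(self) -> int:
        return len(self.cells)

    def loglike(self, prior: MixturePrior) -> float:
        return marginal_loglik(self.endog, self.expected, prior)

    def fit(
        self,
        start: MixturePrior = CANONICAL_START,
        n_restarts: int = 4,
        seed: int = 0,
    ) -> "GPSResults":
        fit = fit_prior(self.endog, self.expected, start=start,
                        n_restarts=n_restarts, seed=seed)
        return GPSResults(self, fit)


class GPSResults:
    """Fitted gamma-Poisson shrinker: prior estimates and posterior scores."""

    def __init__(self, model: GammaPoissonShrinker, fit: PriorFit):
        self.model = model
        self.prior = fit.prior
        self.llf = fit.llf
        self.fit_info = fit

    def posterior(self, quantiles: bool = True) -> pd.DataFrame:
        """Per-cell posterior table: drug, event_pt, N, E, Q1, EBGM[, EB05, EB95]."""
        summ = posterior_summary(
            self.model.endog, self.model.expected, self.prior, quantiles=quantiles
        )
        out = self.model.cells[["drug", "event_pt"]].copy()
        return pd.concat([out.reset_index(drop=True), summ.to_frame()], axis=1)

    def ebgm(self, drug: str, event_pt: str, quantiles: bool = False):
        """EBGM (optionally with EB05/EB95) for one drug-event cell."""
        cells = self.model.cells
        mask = (cells["drug"] == drug) & (cells["event_pt"] == event_pt)
        if not mask.any():
            raise KeyError(f"cell ({drug!r}, {event_pt!r}) not in table")
        i = int(np.flatnonzero(mask.to_numpy())[0])
        summ = posterior_summary(
            self.model.endog[i], self.model.expected[i], self.prior, quantiles=quantiles
        )
        if quantiles:
            return float(summ.ebgm[0]), float(summ.eb05[0]), float(summ.eb95[0])
        return float(summ.ebgm[0])

    def summary(self, top: int = 10) -> str:
        p = self.prior
        post = self.posterior(quantiles=False).sort_values("EBGM", ascending=False)
        lines = [
            "Gamma-Poisson Shrinker Results",
            "=" * 64,
            f"cells: {self.model.nobs}    grand total: {self.model.table.grand_total}",
            f"log marginal likelihood: {self.llf:.4f}",
            (
                f"prior: pi={p.pi:.4f}  "
                f"G1(shape={p.alpha1:.4f}, rate={p.beta1:.4f})  "
                f"G2(shape={p.alpha2:.4f}, rate={p.beta2:.4f})"
            ),
            f"prior mean lambda: {p.mean:.4f}",
            "-" * 64,
            f"top {min(top, len(post))} cells by EBGM:",
            post.head(top).to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)

    def plot_signals(self, ax=None, top: int = 20):
        """Bar plot of the top EBGM cells (requires matplotlib)."""
        import matplotlib.pyplot as plt

        post = self.posterior(quantiles=False).sort_values("EBGM", ascending=False).head(top)
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.3 * len(post) + 1))
        labels = post["drug"] + " / " + post["event_pt"]
        ax.barh(labels[::-1], post["EBGM"][::-1])
        ax.axvline(1.0, color="k", lw=0.8)
        ax.set_xlabel("EBGM")
        return ax


# ---------------------------------------------------------------------------
# Cumulative-by-quarter series
# ---------------------------------------------------------------------------

def cumulative_quarterly_ebgm(
    reports: pd.DataFrame,
    drug: str,
    event_pt: str,
    fit_kwargs: Mapping | None = None,
    quarters: Iterable[str] | None = None,
) -> pd.Series:
    """EBGM of one cell over cumulative quarterly slices of dated reports.

    For each quarter q the table is rebuilt from all reports with quarter
    <= q and the prior refit from scratch (no warm start), so any single
    point of the series is reproducible in isolation.  Quarters where the
    cell has no reports yet are missing (NaN).
    """
    fit_kwargs = dict(fit_kwargs or {})
    if quarters is None:
        quarters = sorted(reports["quarter"].unique(), key=quarter_key)
    values: dict[str, float] = {}
    for q in quarters:
        table = ReportTable.from_reports(reports, through_quarter=q)
        counts = table.counts
        if drug not in counts.index or event_pt not in counts.columns or \
                counts.loc[drug, event_pt] == 0:
            values[q] = np.nan
            continue
        res = GammaPoissonShrinker(table).fit(**fit_kwargs)
        values[q] = res.ebgm(drug, event_pt)
    return pd.Series(values, name="EBGM")
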