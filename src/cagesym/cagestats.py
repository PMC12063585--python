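"""Cage-level acquisition, development, mortality, and climate statistics.

Implements the analysis path for the cage experiment: the over-full-cage
exclusion filter, early/late stage coding, per-cage summaries, a
quasibinomial (dispersion-adjusted) logistic regression of cage
proportions with an F test for the treatment term, a Poisson model of
per-cage deaths assessed by likelihood ratio, Holm-adjusted pairwise Wald
contrasts with a compact letter display, and a tie-corrected Mann-Whitney
U test for comparing daily climate maxima between years.

The GLMs are fitted by iteratively reweighted least squares with the
treatment factor in cell-means coding, so coefficients are per-treatment
group means on the link scale.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

__all__ = [
    "exclude_overfull_cages",
    "stage_class",
    "summarize_cages",
    "GLMFit",
    "fit_binomial_props",
    "fit_poisson_counts",
    "pairwise_contrasts",
    "holm_adjust",
    "compact_letters",
    "daily_maxima",
    "mann_whitney_u",
    "MannWhitneyResult",
    "compare_climate_years",
]


# ---------------------------------------------------------------------------
# filters and summaries

def exclude_overfull_cages(
    cages: pd.DataFrame, bugs: pd.DataFrame, max_bugs: int = 12
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop cages from which more than ``max_bugs`` bugs were recovered.

    More recovered bugs than were released indicates wild bugs entered the
    cage, so the whole cage is excluded.  Recovered bugs are all bug rows
    for the cage, alive or dead.  Returns filtered (cages, bugs).
    """
    recovered = bugs[bugs["cage_id"].notna()].groupby("cage_id").size()
    overfull = set(recovered.index[recovered > max_bugs])
    if overfull:
        logger.info(
            "excluding %d cage(s) with > %d recovered bugs: %s",
            len(overfull), max_bugs, sorted(overfull),
        )
    keep_cages = cages[~cages["cage_id"].isin(overfull)]
    keep_bugs = bugs[~bugs["cage_id"].isin(overfull)]
    return keep_cages, keep_bugs


_STAGE_CLASS = {
    "instar3": "early",
    "instar4": "early",
    "instar5": "late",
    "adult": "late",
}


def stage_class(stage: str) -> str:
    """Code an endpoint stage as ``early`` (instar 3-4) or ``late`` (instar 5 / adult).

    Second instars are the stage released into cages, not an endpoint, and
    raise a ValueError.
    """
    try:
        return _STAGE_CLASS[stage]
    except KeyError:
        raise ValueError(
            f"stage {stage!r} has no early/late class (endpoint stages are "
            f"{sorted(_STAGE_CLASS)})"
        ) from None


def summarize_cages(bugs: pd.DataFrame) -> pd.DataFrame:
    """One summary row per cage: tested, positive, late, dead, recovered counts.

    ``n_late`` is counted over surviving bugs only (life stages were
    recorded for survivors); ``n_alive = n_recovered - n_dead`` is the
    denominator for late-stage proportions.
    """
    rows = []
    caged = bugs[bugs["cage_id"].notna()]
    for cage_id, grp in caged.groupby("cage_id", sort=True):
        alive = grp[grp["alive"]]
        late = sum(
            stage_class(s) == "late" for s in alive["stage"] if s in _STAGE_CLASS
        )
        rows.append(
            {
                "cage_id": cage_id,
                "treatment": grp["treatment"].iloc[0],
                "year": grp["year"].iloc[0],
                "n_tested": len(grp),
                "n_positive": int(grp["symbiont_positive"].sum()),
                "n_late": int(late),
                "n_dead": int((~grp["alive"]).sum()),
                "n_recovered": len(grp),
                "n_alive": len(alive),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GLMs by IRLS

@dataclass
class GLMFit:
    """A fitted one-factor GLM in cell-means coding.

    ``coefficients`` are per-treatment group estimates on the link scale
    (logit for the binomial families, log for Poisson); ``fitted`` are the
    corresponding group probabilities or rates.  ``statistic`` is the
    treatment-term test: an F statistic on scaled deviance for the
    quasibinomial fit, the likelihood-ratio chi-square for Poisson.
    """

    family: str
    levels: list[str]
    coefficients: pd.Series
    cov: pd.DataFrame = field(repr=False)
    dispersion: float = 1.0
    deviance: float = 0.0
    null_deviance: float = 0.0
    fitted: pd.Series = None
    statistic_name: str = ""
    statistic: float = float("nan")
    df: tuple = ()
    p_value: float = float("nan")
    boundary_levels: set = field(default_factory=set)
    warnings: list = field(default_factory=list)
    n_obs: int = 0


_ETA_CAP = 30.0  # logit/log scale cap flagging boundary (separated) estimates


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    trials: np.ndarray | None,
    family: str,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit a binomial (with trials) or Poisson GLM by IRLS.

    Returns (beta, unscaled covariance, converged).
    """
    n_obs, p = X.shape
    if family == "binomial":
        eta = logit((y + 0.5) / (trials + 1.0))
    else:
        eta = np.log(y + 0.5)
    beta = np.linalg.lstsq(X, eta, rcond=None)[0]
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_CAP, _ETA_CAP)
        if family == "binomial":
            mu_p = expit(eta)
            mu = trials * mu_p
            w = np.maximum(trials * mu_p * (1 - mu_p), 1e-12)
            z = eta + (y - mu) / w
        else:
            mu = np.exp(eta)
            w = np.maximum(mu, 1e-12)
            z = eta + (y - mu) / w
        xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ xw, xw.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = np.clip(X @ beta, -_ETA_CAP, _ETA_CAP)
    if family == "binomial":
        mu_p = expit(eta)
        w = np.maximum(trials * mu_p * (1 - mu_p), 1e-12)
    else:
        w = np.maximum(np.exp(eta), 1e-12)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]))
    return beta, cov, converged


def _binomial_deviance(y: np.ndarray, trials: np.ndarray, mu_p: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / (trials * mu_p)), 0.0)
        r = trials - y
        t2 = np.where(r > 0, r * np.log(r / (trials * (1 - mu_p))), 0.0)
    return float(2.0 * np.sum(t1 + t2))


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(t - (y - mu)))


def _one_factor_design(treatments: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    levels = sorted(set(treatments))
    X = np.zeros((len(treatments), len(levels)))
    for i, t in enumerate(treatments):
        X[i, levels.index(t)] = 1.0
    return X, levels


def fit_binomial_props(
    summaries: pd.DataFrame, response: str = "positive"
) -> GLMFit:
    """Quasibinomial logistic regression of cage proportions on treatment.

    ``response='positive'`` models symbiont-positive out of tested bugs per
    cage; ``'late'`` models late-stage out of surviving bugs.  The
    dispersion is estimated as Pearson chi-square over residual degrees of
    freedom, and the treatment term is assessed by the drop-one F test on
    the dispersion-scaled deviance change, as is standard for
    quasi-likelihood fits.  Completely separated levels (all successes or
    all failures) are flagged as boundary estimates.
    """
    if response == "positive":
        y = summaries["n_positive"].to_numpy(dtype=float)
        trials = summaries["n_tested"].to_numpy(dtype=float)
    elif response == "late":
        y = summaries["n_late"].to_numpy(dtype=float)
        if "n_alive" in summaries:
            trials = summaries["n_alive"].to_numpy(dtype=float)
        else:
            trials = (summaries["n_recovered"] - summaries["n_dead"]).to_numpy(dtype=float)
    else:
        raise ValueError("response must be 'positive' or 'late'")
    ok = trials > 0
    if not ok.all():
        logger.info("dropping %d cage(s) with zero trials", int((~ok).sum()))
    y, trials = y[ok], trials[ok]
    treatments = summaries.loc[ok, "treatment"].tolist()
    X, levels = _one_factor_design(treatments)
    n_obs, k = X.shape
    warnings_: list[str] = []

    beta, cov_u, converged = _irls(X, y, trials, "binomial")
    if not converged:
        warnings_.append("IRLS did not converge within 100 iterations")
    eta = np.clip(X @ beta, -_ETA_CAP, _ETA_CAP)
    mu_p = expit(eta)
    deviance = _binomial_deviance(y, trials, mu_p)
    pearson = float(np.sum((y - trials * mu_p) ** 2 / np.maximum(trials * mu_p * (1 - mu_p), 1e-12)))
    df_resid = n_obs - k
    dispersion = pearson / df_resid if df_resid > 0 else float("nan")

    boundary = set()
    for j, lvl in enumerate(levels):
        in_lvl = X[:, j] == 1.0
        if y[in_lvl].sum() == 0 or y[in_lvl].sum() == trials[in_lvl].sum():
            boundary.add(lvl)
    if boundary:
        warnings_.append(
            f"complete separation: boundary estimate(s) for level(s) {sorted(boundary)}"
        )

    # intercept-only null fit for the treatment-term test
    statistic = p_value = float("nan")
    df_t: tuple = ()
    null_dev = deviance
    X0 = np.ones((n_obs, 1))
    beta0, _, _ = _irls(X0, y, trials, "binomial")
    null_dev = _binomial_deviance(y, trials, expit(np.clip(X0 @ beta0, -_ETA_CAP, _ETA_CAP)))
    if k > 1 and df_resid > 0 and dispersion > 0:
        statistic = ((null_dev - deviance) / (k - 1)) / dispersion
        df_t = (k - 1, df_resid)
        p_value = float(stats.f.sf(statistic, k - 1, df_resid))

    coef = pd.Series(beta, index=levels, name="logit")
    return GLMFit(
        family="quasibinomial",
        levels=levels,
        coefficients=coef,
        cov=pd.DataFrame(cov_u * (dispersion if dispersion == dispersion else 1.0),
                         index=levels, columns=levels),
        dispersion=dispersion,
        deviance=deviance,
        null_deviance=null_dev,
        fitted=pd.Series(expit(beta), index=levels, name="probability"),
        statistic_name="F",
        statistic=float(statistic),
        df=df_t,
        p_value=p_value,
        boundary_levels=boundary,
        warnings=warnings_,
        n_obs=n_obs,
    )


def fit_poisson_counts(summaries: pd.DataFrame) -> GLMFit:
    """Poisson regression of per-cage death counts on treatment.

    Log-link fit in cell-means coding; the treatment term is assessed by
    the likelihood-ratio test (deviance drop against the intercept-only
    model, chi-square with k-1 df).  Levels with all-zero counts are
    boundary estimates and flagged.
    """
    y = summaries["n_dead"].to_numpy(dtype=float)
    treatments = summaries["treatment"].tolist()
    X, levels = _one_factor_design(treatments)
    n_obs, k = X.shape
    warnings_: list[str] = []

    beta, cov_u, converged = _irls(X, y, None, "poisson")
    if not converged:
        warnings_.append("IRLS did not converge within 100 iterations")
    mu = np.exp(np.clip(X @ beta, -_ETA_CAP, _ETA_CAP))
    deviance = _poisson_deviance(y, mu)
    pearson = float(np.sum((y - mu) ** 2 / np.maximum(mu, 1e-12)))
    df_resid = n_obs - k
    dispersion = pearson / df_resid if df_resid > 0 else float("nan")

    boundary = {
        lvl for j, lvl in enumerate(levels) if y[X[:, j] == 1.0].sum() == 0
    }
    if boundary:
        warnings_.append(f"all-zero counts in level(s) {sorted(boundary)}")

    X0 = np.ones((n_obs, 1))
    beta0, _, _ = _irls(X0, y, None, "poisson")
    null_dev = _poisson_deviance(y, np.exp(np.clip(X0 @ beta0, -_ETA_CAP, _ETA_CAP)))
    statistic = p_value = float("nan")
    df_t: tuple = ()
    if k > 1:
        statistic = null_dev - deviance  # = 2 (loglik_full - loglik_null)
        df_t = (k - 1,)
        p_value = float(stats.chi2.sf(statistic, k - 1))

    return GLMFit(
        family="poisson",
        levels=levels,
        coefficients=pd.Series(beta, index=levels, name="log_rate"),
        cov=pd.DataFrame(cov_u, index=levels, columns=levels),
        dispersion=dispersion,
        deviance=deviance,
        null_deviance=null_dev,
        fitted=pd.Series(np.exp(beta), index=levels, name="rate"),
        statistic_name="LRT",
        statistic=float(statistic),
        df=df_t,
        p_value=p_value,
        boundary_levels=boundary,
        warnings=warnings_,
        n_obs=n_obs,
    )


# ---------------------------------------------------------------------------
# pairwise contrasts

def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment of a vector of p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def compact_letters(
    levels: Sequence[str], sig_pairs: Sequence[tuple[str, str]]
) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Levels sharing a letter are not significantly different; each
    significant pair is separated into distinct letter groups.
    """
    levels = list(levels)
    groups: list[set[str]] = [set(levels)]
    for a, b in sig_pairs:
        new_groups: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                new_groups.extend([g - {a}, g - {b}])
            else:
                new_groups.append(g)
        # absorb subsets
        groups = []
        for g in sorted(new_groups, key=len, reverse=True):
            if g and not any(g <= other for other in groups):
                groups.append(g)
    groups.sort(key=lambda g: tuple(levels.index(x) for x in sorted(g, key=levels.index)))
    letters = {lvl: "" for lvl in levels}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for lvl in g:
            letters[lvl] += letter
    return {lvl: "".join(sorted(s)) for lvl, s in letters.items()}


def pairwise_contrasts(fit: GLMFit, alpha: float = 0.05) -> tuple[pd.DataFrame, dict[str, str]]:
    """All-pairs Wald contrasts on the link scale with Holm adjustment.

    Standard errors come from the fit's (dispersion-scaled, for
    quasibinomial) covariance.  Pairs involving a boundary (separated)
    level are marked indeterminate and treated as non-significant in the
    letter display.  Returns (contrast table, compact letters at ``alpha``).
    """
    levels = fit.levels
    rows = []
    for a, b in itertools.combinations(levels, 2):
        est = fit.coefficients[a] - fit.coefficients[b]
        var = fit.cov.loc[a, a] + fit.cov.loc[b, b] - 2 * fit.cov.loc[a, b]
        indet = a in fit.boundary_levels or b in fit.boundary_levels
        if indet or var <= 0:
            rows.append({"level_a": a, "level_b": b, "estimate": est, "se": math.sqrt(max(var, 0)),
                         "z": float("nan"), "p_raw": float("nan"), "indeterminate": True})
            continue
        se = math.sqrt(var)
        z = est / se
        rows.append({"level_a": a, "level_b": b, "estimate": est, "se": se,
                     "z": z, "p_raw": float(2 * stats.norm.sf(abs(z))),
                     "indeterminate": False})
    table = pd.DataFrame(rows)
    determinate = ~table["indeterminate"]
    adj = np.full(len(table), np.nan)
    if determinate.any():
        adj[determinate.to_numpy()] = holm_adjust(table.loc[determinate, "p_raw"].tolist())
    table["p_holm"] = adj
    table["significant"] = (table["p_holm"] <= alpha).fillna(False)
    sig_pairs = [
        (r["level_a"], r["level_b"]) for _, r in table.iterrows() if r["significant"]
    ]
    letters = compact_letters(levels, sig_pairs)
    return table, letters


# ---------------------------------------------------------------------------
# climate comparison

def daily_maxima(series: pd.DataFrame) -> pd.DataFrame:
    """Per-calendar-day maxima of temperature and humidity.

    Days are the local calendar date of each timestamp; days with no
    readings are simply absent.
    """
    if len(series) == 0:
        raise ValueError("climate series is empty")
    s = series.copy()
    s["date"] = pd.to_datetime(s["timestamp"]).dt.date
    out = s.groupby("date")[["temperature", "humidity"]].max()
    out.columns = ["temperature_max", "humidity_max"]
    return out.reset_index()


@dataclass
class MannWhitneyResult:
    """Mann-Whitney U result.

    ``u`` counts pairs (x_i, y_j) with x_i > y_j plus half the ties.
    ``w`` is the rank-sum of the first sample, i.e. ``u + n_x (n_x + 1)/2``
    (conventions differ between software ecosystems; both are reported).
    ``p`` is two-sided, exact by enumeration for small samples, otherwise
    by normal approximation with tie-corrected variance and continuity
    correction.
    """

    u: float
    w: float
    p: float
    method: str
    n_x: int
    n_y: int


_EXACT_MIN_N = 8
_EXACT_MAX_COMBS = 500_000


def _exact_u_pvalue(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    pooled = np.concatenate([x, y])
    n, total = len(x), len(pooled)
    m = (pooled[:, None] > pooled[None, :]).astype(float)
    m += 0.5 * (pooled[:, None] == pooled[None, :])
    np.fill_diagonal(m, 0.0)
    combos = np.array(list(itertools.combinations(range(total), n)), dtype=np.intp)
    onehot = np.zeros((len(combos), total))
    np.put_along_axis(onehot, combos, 1.0, axis=1)
    u_all = onehot @ m.sum(axis=1) - ((onehot @ m) * onehot).sum(axis=1)
    p_le = float(np.mean(u_all <= u_obs + 1e-9))
    p_ge = float(np.mean(u_all >= u_obs - 1e-9))
    return min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``method`` is ``'auto'`` (exact enumeration when min(n, m) <= 8 and the
    number of label assignments is tractable, normal approximation
    otherwise), ``'exact'``, or ``'normal'``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n, m_ = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[:n].sum())
    u = r1 - n * (n + 1) / 2.0
    w = r1

    if method == "auto":
        feasible = min(n, m_) <= _EXACT_MIN_N and math.comb(n + m_, min(n, m_)) <= _EXACT_MAX_COMBS
        method = "exact" if feasible else "normal"
    if method == "exact":
        if math.comb(n + m_, min(n, m_)) > _EXACT_MAX_COMBS:
            raise ValueError("exact enumeration infeasible for these sample sizes")
        p = _exact_u_pvalue(x, y, u)
    elif method == "normal":
        big_n = n + m_
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n * m_ / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u - n * m_ / 2.0) - 0.5) / math.sqrt(var)
            p = min(1.0, float(2 * stats.norm.sf(max(z, 0.0))))
    else:
        raise ValueError("method must be 'auto', 'exact', or 'normal'")
    return MannWhitneyResult(u=u, w=w, p=p, method=method, n_x=n, n_y=m_)


def compare_climate_years(
    series_a: pd.DataFrame, series_b: pd.DataFrame
) -> dict[str, dict]:
    """Compare daily maxima of two climate series (e.g. two years).

    For temperature and humidity separately, reports the Mann-Whitney test
    on the per-day maxima plus both the mean and the median daily maximum
    of each series.
    """
    max_a = daily_maxima(series_a)
    max_b = daily_maxima(series_b)
    out = {}
    for var in ("temperature_max", "humidity_max"):
        res = mann_whitney_u(max_a[var], max_b[var])
        out[var] = {
            "u": res.u,
            "w": res.w,
            "p": res.p,
            "method": res.method,
            "mean_a": float(max_a[var].mean()),
            "mean_b": float(max_b[var].mean()),
            "median_a": float(max_a[var].median()),
            "median_b": float(max_b[var].median()),
            "n_days_a": len(max_a),
            "n_days_b": len(max_b),
        }
    return out
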