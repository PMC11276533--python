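"""Descriptive statistics and self-report/ancestry association analyses.

Covers the survey-style reporting layer: recoding of write-in skin color
terms into census categories, contingency-table tests (chi-square, exact
Fisher for sparse tables), Kruskal-Wallis comparisons of ancestry across
categories, quartile cross-tabulations, and age-adjusted quantile regression
of ancestry proportion on self-reported category (reference level Black)
with the Koenker-Machado pseudo-R-squared.
"""

from __future__ import annotations

import unicodedata
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .genio import CENSUS_CATEGORIES, NOT_ANSWERED, PT_CENSUS

#: Write-in terms for tanned/light-dark skin color collapsed into Mixed
#: (matched case- and diacritic-insensitively, with or without the
#: "claro/a" qualifier).
MIXED_WRITE_INS = {
    "moreno", "morena", "moreninho", "moreninha",
    "moreno claro", "morena clara", "moreno escuro", "morena escura",
}

ANALYSIS_CATEGORIES = ("Black", "Mixed", "White")


def _fold(s: str) -> str:
    s = unicodedata.normalize("NFKD", s.strip().lower())
    return "".join(ch for ch in s if not unicodedata.combining(ch))


def recode_category(raw_label: str | None) -> str:
    """Map a raw self-report to a census category.

    Census labels (English or Portuguese) pass through; the write-in lexicon
    of "moreno/a (claro/a)" terms collapses into Mixed; unknown write-ins
    become "Other" with a warning; empty input is NotAnswered.
    """
    if raw_label is None or (isinstance(raw_label, float) and np.isnan(raw_label)):
        return NOT_ANSWERED
    s = str(raw_label).strip()
    if s == "":
        return NOT_ANSWERED
    if s in CENSUS_CATEGORIES or s == NOT_ANSWERED:
        return s
    folded = _fold(s)
    for cat in CENSUS_CATEGORIES + (NOT_ANSWERED,):
        if folded == cat.lower():
            return cat
    if folded in PT_CENSUS:
        return PT_CENSUS[folded]
    if folded in MIXED_WRITE_INS:
        return "Mixed"
    warnings.warn(f"unrecognized write-in category {raw_label!r} -> Other")
    return "Other"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Published-style rounding: half away from zero, fixed decimals."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Exact Fisher test for small RxC tables


def _table_logprob(t: np.ndarray, logfact_margins: float) -> float:
    return logfact_margins - gammaln(t + 1).sum()


def fisher_exact_rxc(table: np.ndarray, max_tables: int = 2_000_000) -> float:
    """Exact Fisher p for an RxC table by enumeration over fixed margins.

    p is the total probability of all tables (under the multivariate
    hypergeometric null) whose probability does not exceed the observed
    table's.  Intended for sparse tables; raises if the enumeration would
    exceed ``max_tables``.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a non-negative 2-D array")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()
    logfact_margins = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    p_obs = _table_logprob(t, logfact_margins)
    total = 0.0
    count = 0

    r, c = t.shape

    def recurse(i: int, remaining_cols: np.ndarray, acc: np.ndarray):
        nonlocal total, count
        if i == r - 1:
            last = remaining_cols
            if (last < 0).any():
                return
            cand = np.vstack([acc, last]) if len(acc) else last[None, :]
            lp = _table_logprob(cand, logfact_margins)
            count += 1
            if count > max_tables:
                raise RuntimeError("fisher_exact_rxc: enumeration exceeds max_tables")
            if lp <= p_obs + 1e-9:
                total += np.exp(lp)
            return
        for comp in _compositions(rows[i], remaining_cols):
            recurse(i + 1, remaining_cols - comp, np.vstack([acc, comp]) if len(acc) else comp[None, :])

    recurse(0, cols.copy(), np.empty((0, c), dtype=int))
    return float(min(1.0, total))


def _compositions(total: int, caps: np.ndarray):
    """All ways to split `total` into len(caps) parts with part_j <= caps[j]."""
    c = len(caps)
    if c == 1:
        if 0 <= total <= caps[0]:
            yield np.array([total])
        return
    for first in range(max(0, total - caps[1:].sum()), min(total, caps[0]) + 1):
        for rest in _compositions(total - first, caps[1:]):
            yield np.concatenate(([first], rest))


# ---------------------------------------------------------------------------
# Descriptive tests


def descriptive_tests(samples, proportions, categories: tuple[str, ...] = ANALYSIS_CATEGORIES) -> pd.DataFrame:
    """Category-by-covariate and ancestry-by-category tests (Black/Mixed/White).

    Chi-square for category x sex and category x age-group, switching to the
    exact Fisher test when any expected cell is below 5; Kruskal-Wallis for
    each ancestry proportion across the three categories.
    """
    meta = samples.frame
    sub = meta[meta["category"].isin(categories)]
    results = []
    for covar in ("sex", "age_group"):
        ct = pd.crosstab(sub["category"], sub[covar])
        obs = ct.to_numpy()
        expected = stats.contingency.expected_freq(obs)
        if (expected < 5).any():
            try:
                p = fisher_exact_rxc(obs)
                results.append({"test": f"category_x_{covar}", "method": "fisher_exact", "statistic": np.nan, "p": p})
                continue
            except RuntimeError:
                warnings.warn(f"category_x_{covar}: Fisher enumeration too large, using chi-square")
        chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
        results.append({"test": f"category_x_{covar}", "method": "chi_square", "statistic": chi2, "p": p})
    q = proportions.q if hasattr(proportions, "q") else proportions
    q = q.reindex(sub["sample_id"]).dropna()
    cat = sub.set_index("sample_id").loc[q.index, "category"]
    for anc in q.columns:
        groups = [q.loc[cat == c, anc].to_numpy() for c in categories if (cat == c).sum() > 0]
        if len(groups) < 2:
            continue
        h, p = stats.kruskal(*groups)
        results.append({"test": f"{anc}_by_category", "method": "kruskal_wallis", "statistic": h, "p": p})
    return pd.DataFrame(results)


# ---------------------------------------------------------------------------
# Quartile tables


@dataclass
class QuartileTable:
    counts: pd.DataFrame  # categories x quartiles
    percentages: pd.DataFrame  # row percentages, half-up to 1 dp
    cutpoints: np.ndarray


def quartile_table(
    q_values: pd.Series, categories: pd.Series, analysis_categories: tuple[str, ...] = ANALYSIS_CATEGORIES
) -> QuartileTable:
    """Cross-tabulate self-report against quartiles of one ancestry.

    Quartile cut points are the empirical quartiles of the analyzed sample.
    Bins are half-open with ties at a cut point assigned to the lower bin.
    Percentages are row percentages (count / category total).
    """
    cat = categories.reindex(q_values.index)
    mask = cat.isin(analysis_categories)
    vals = q_values[mask]
    cat = cat[mask]
    cuts = np.quantile(vals.to_numpy(float), [0.25, 0.5, 0.75])
    idx = np.searchsorted(cuts, vals.to_numpy(float), side="left")  # ties -> lower bin
    quart = pd.Series(idx + 1, index=vals.index)
    counts = pd.crosstab(cat, quart).reindex(
        index=list(analysis_categories), columns=[1, 2, 3, 4], fill_value=0
    )
    counts.columns = [f"Q{j}" for j in counts.columns]
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct = pct.map(lambda x: round_half_up(x, 1))
    return QuartileTable(counts=counts, percentages=pct, cutpoints=cuts)


# ---------------------------------------------------------------------------
# Quantile regression


@dataclass
class QuantRegFit:
    tau: float
    coefficients: pd.DataFrame  # term, beta, ci_low, ci_high, p
    pseudo_r2: float
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.pseudo_r2 <= 1 + 1e-9:
            raise ValueError("pseudo_r2 must lie in [0, 1]")


def quantile_regression(
    y: pd.Series,
    category: pd.Series,
    age: pd.Series | None = None,
    tau: float = 0.5,
    reference: str = "Black",
    ci_method: str = "bootstrap",
    n_boot: int = 1000,
    seed: int = 0,
    analysis_categories: tuple[str, ...] = ANALYSIS_CATEGORIES,
) -> QuantRegFit:
    """Quantile regression of an ancestry proportion on category (+ age).

    Minimizes the check loss sum rho_tau(y - X beta); the pseudo-R-squared is
    the Koenker-Machado 1 - V(fitted)/V(tau-quantile intercept only).  CIs are
    seeded xy-pair bootstrap percentiles by default ("asymptotic" uses the
    kernel-based standard errors instead).  p-values are asymptotic.
    """
    import statsmodels.api as sm

    cat = category.reindex(y.index)
    mask = cat.isin(analysis_categories) & y.notna()
    if age is not None:
        age = age.reindex(y.index)
        mask &= age.notna()
    yv = y[mask].astype(float)
    cat = pd.Categorical(cat[mask], categories=[reference] + [c for c in analysis_categories if c != reference])
    dummies = pd.get_dummies(cat, drop_first=True, dtype=float)
    x = pd.DataFrame({"intercept": np.ones(len(yv))}, index=yv.index)
    for col in dummies.columns:
        x[str(col)] = dummies[col].to_numpy()
    if age is not None:
        x["age"] = age[mask].astype(float).to_numpy()
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # name the offending column for the error
        for col in x.columns:
            others = x.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(x.to_numpy()):
                raise ValueError(f"degenerate design: column {col!r} is collinear")
        raise ValueError("degenerate design matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.QuantReg(yv.to_numpy(), x.to_numpy()).fit(q=tau)
    beta = res.params
    pvals = res.pvalues
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, len(beta)))
        xa = x.to_numpy()
        ya = yv.to_numpy()
        n = len(ya)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for b in range(n_boot):
                take = rng.integers(0, n, size=n)
                try:
                    boots[b] = sm.QuantReg(ya[take], xa[take]).fit(q=tau).params
                except Exception:
                    boots[b] = np.nan
        lo = np.nanpercentile(boots, 2.5, axis=0)
        hi = np.nanpercentile(boots, 97.5, axis=0)
    elif ci_method == "asymptotic":
        ci = res.conf_int()
        lo, hi = ci[:, 0], ci[:, 1]
    else:
        raise ValueError("ci_method must be 'bootstrap' or 'asymptotic'")
    coef = pd.DataFrame(
        {"term": list(x.columns), "beta": beta, "ci_low": lo, "ci_high": hi, "p": pvals}
    )
    return QuantRegFit(tau=tau, coefficients=coef, pseudo_r2=float(max(0.0, res.prsquared)), n=len(yv))
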