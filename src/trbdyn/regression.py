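"""Cross-sectional modelling of diversity against age and sex.

Evenness is regressed on age with weighted least squares, the weight of a
sample being its total curated copy count, so deeply sequenced repertoires
(whose evenness estimates are the most precise) count more:

    J_i = β0 + β1·AGE_i (+ β2·SEX_i + β3·AGE_i·SEX_i) + ε_i,  ε_i ~ N(0, σ²/w_i)

with men as the reference sex.  Model search is backward elimination on the
Bayesian Information Criterion, respecting marginality (the interaction is
removed before its main effects).  The piecewise analysis brute-forces
every age split (younger group = ages ≤ split) with at least ``min_group``
donors on each side, runs the BIC selection within each side, and keeps the
split minimizing the sum of the two BICs.

The WLS solution, standard errors, overall F test and Gaussian
log-likelihood are computed in closed form here; the breakpoint search
refits thousands of small models, and the closed form keeps that cheap.
The log-likelihood convention matches a weighted Gaussian linear model
(weights enter as inverse relative variances), and the BIC counts the
residual variance as an estimated parameter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TERM_AGE = "AGE"
TERM_SEX = "SEX"
TERM_AGE_SEX = "AGE:SEX"

#: fixed ordering used for design matrices and deterministic tie-breaks
ALL_TERMS = (TERM_AGE, TERM_SEX, TERM_AGE_SEX)

_HIERARCHY = {TERM_AGE_SEX: (TERM_AGE, TERM_SEX)}


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of a cross-sectional model.

    The intercept is always present.  ``terms`` is a subset of
    ``{AGE, SEX, AGE:SEX}`` respecting marginality.  ``weight_col`` names
    the per-sample weight column (total copy counts by default).
    """

    response: str = "status_J"
    terms: tuple[str, ...] = (TERM_AGE, TERM_SEX, TERM_AGE_SEX)
    weight_col: str = "N"

    def __post_init__(self) -> None:
        terms = tuple(t for t in ALL_TERMS if t in self.terms)
        if len(terms) != len(self.terms):
            unknown = set(self.terms) - set(ALL_TERMS)
            if unknown:
                raise ValueError(f"unknown terms {sorted(unknown)}")
        object.__setattr__(self, "terms", terms)
        for term, parents in _HIERARCHY.items():
            if term in self.terms and not all(p in self.terms for p in parents):
                raise ValueError(f"{term} requires {parents} (marginality)")

    def without(self, term: str) -> "ModelSpec":
        return ModelSpec(
            response=self.response,
            terms=tuple(t for t in self.terms if t != term),
            weight_col=self.weight_col,
        )

    def removable_terms(self) -> list[str]:
        """Terms whose removal keeps the model hierarchical."""
        out = []
        for term in self.terms:
            needed_by = [t for t, ps in _HIERARCHY.items() if term in ps and t in self.terms]
            if not needed_by:
                out.append(term)
        return out


@dataclass
class RegressionFit:
    """A fitted weighted linear model."""

    spec: ModelSpec
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    n: int
    df_resid: int
    rss_w: float  # weighted residual sum of squares (weights mean-normalized)
    llf: float
    bic: float
    fvalue: float
    f_pvalue: float  # overall F test, full model vs intercept-only
    r: float  # unweighted correlation between AGE and the response

    @property
    def slope(self) -> float:
        return self.params.get(TERM_AGE, 0.0)

    @property
    def slope_se(self) -> float:
        return self.bse.get(TERM_AGE, np.nan)

    def summary_row(self) -> dict:
        return {
            "N": self.n,
            "b_0": round(self.params["Intercept"], 4),
            "b_1": round(self.params.get(TERM_AGE, 0.0), 4),
            "b_2": round(self.params.get(TERM_SEX, 0.0), 4),
            "model_p": self.f_pvalue,
            "r": round(self.r, 3),
        }


def _female_indicator(sex: pd.Series) -> np.ndarray:
    vals = sex.astype(str).str.lower()
    return (vals.isin(["female", "f", "woman", "1", "true", "sex.female"])).to_numpy(float)


def design_matrix(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    n = len(data)
    cols = [np.ones(n)]
    names = ["Intercept"]
    age = data["age"].to_numpy(float)
    female = _female_indicator(data["sex"]) if "sex" in data.columns else np.zeros(n)
    for term in spec.terms:
        if term == TERM_AGE:
            cols.append(age)
        elif term == TERM_SEX:
            cols.append(female)
        elif term == TERM_AGE_SEX:
            cols.append(age * female)
        names.append(term)
    return np.column_stack(cols), names


def weighted_fit(data: pd.DataFrame, spec: ModelSpec) -> RegressionFit:
    """Closed-form weighted least squares with F test and BIC.

    Weights are normalized to mean one before fitting (the likelihood is
    invariant to their scale; normalization keeps reported variances on the
    response scale).  Raises on singular designs, naming the collinear
    term — e.g. a SEX term fitted to a single-sex subset.
    """
    X, names = design_matrix(data, spec)
    y = data[spec.response].to_numpy(float)
    w = data[spec.weight_col].to_numpy(float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n={n} too small for {k} coefficients")
    w = w / w.mean()

    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    rank = np.linalg.matrix_rank(Xw)
    if rank < k:
        for drop in range(k - 1, 0, -1):
            reduced = np.delete(Xw, drop, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(
                    f"singular design: term {names[drop]!r} is collinear "
                    "(e.g. a sex term on a single-sex subset)"
                )
        raise ValueError("singular design")

    beta, *_ = np.linalg.lstsq(Xw, y * sw, rcond=None)
    resid = y - X @ beta
    rss = float(np.sum(w * resid**2))
    df_resid = n - k
    s2 = rss / df_resid
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    bse = np.sqrt(np.maximum(s2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(bse > 0, beta / bse, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)

    # overall F: full model against the weighted-mean-only model
    ybar_w = float(np.sum(w * y) / np.sum(w))
    rss0 = float(np.sum(w * (y - ybar_w) ** 2))
    if k > 1 and rss > 0:
        fvalue = ((rss0 - rss) / (k - 1)) / (rss / df_resid)
        f_pvalue = float(stats.f.sf(fvalue, k - 1, df_resid))
    elif k > 1:
        fvalue, f_pvalue = np.inf, 0.0
    else:
        fvalue, f_pvalue = np.nan, np.nan

    sigma2_ml = rss / n
    if sigma2_ml > 0:
        llf = 0.5 * float(np.sum(np.log(w))) - 0.5 * n * (
            np.log(2.0 * np.pi) + 1.0 + np.log(sigma2_ml)
        )
    else:
        llf = np.inf
    bic = -2.0 * llf + np.log(n) * (k + 1)

    age = data["age"].to_numpy(float)
    y_sd = y.std()
    r = float(np.corrcoef(age, y)[0, 1]) if y_sd > 0 and age.std() > 0 else 0.0

    return RegressionFit(
        spec=spec,
        params=dict(zip(names, beta)),
        bse=dict(zip(names, bse)),
        pvalues=dict(zip(names, pvals)),
        n=n,
        df_resid=df_resid,
        rss_w=rss,
        llf=float(llf),
        bic=float(bic),
        fvalue=float(fvalue),
        f_pvalue=float(f_pvalue),
        r=r,
    )


_LOG2PI = np.log(2.0 * np.pi)


def _wls_bic(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> Optional[float]:
    """BIC of a weighted LS fit (weights already mean-normalized).

    Returns None on a rank-deficient design.  Must stay numerically
    identical to the BIC reported by :func:`weighted_fit`.
    """
    n, k = X.shape
    if n <= k:
        return None
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    beta, _, rank, _ = np.linalg.lstsq(Xw, y * sw, rcond=None)
    if rank < k:
        return None
    resid = y * sw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    if sigma2 <= 0:
        return -np.inf
    llf = 0.5 * float(np.sum(np.log(w))) - 0.5 * n * (_LOG2PI + 1.0 + np.log(sigma2))
    return -2.0 * llf + np.log(n) * (k + 1)


def _drop_collinear(terms: list[str], cols: dict[str, np.ndarray], sw: np.ndarray) -> list[str]:
    """Remove the last collinear term (and its dependents), mirroring the
    singular-design handling of :func:`weighted_fit`/:func:`estimable_spec`."""
    X = np.column_stack([np.ones(sw.size)] + [cols[t] for t in terms]) * sw[:, None]
    rank = np.linalg.matrix_rank(X)
    for drop in range(len(terms), 0, -1):
        if np.linalg.matrix_rank(np.delete(X, drop, axis=1)) == rank:
            victim = terms[drop - 1]
            out = [t for t in terms if t != victim]
            for dependent, parents in _HIERARCHY.items():
                if victim in parents and dependent in out:
                    out.remove(dependent)
            return out
    return terms[:-1]


def _greedy_terms(
    cols: dict[str, np.ndarray], y: np.ndarray, w: np.ndarray, terms: tuple[str, ...]
) -> tuple[tuple[str, ...], float]:
    """Numpy-only estimability demotion + greedy BIC elimination.

    Shares its selection semantics with :func:`bic_backward_select`; the
    piecewise scan calls this thousands of times, so it avoids DataFrame
    and distribution-function overhead entirely.
    """
    w = w / w.mean()
    sw = np.sqrt(w)
    current = list(terms)

    def build(ts: list[str]) -> np.ndarray:
        return np.column_stack([np.ones(y.size)] + [cols[t] for t in ts])

    while True:
        bic = _wls_bic(build(current), y, w)
        if bic is not None:
            break
        current = _drop_collinear(current, cols, sw)

    while True:
        best = None
        for term in current:
            if any(term in ps and t in current for t, ps in _HIERARCHY.items()):
                continue
            reduced = [t for t in current if t != term]
            b = _wls_bic(build(reduced), y, w)
            if b is not None and (best is None or b < best[0]):
                best = (b, reduced)
        if best is not None and best[0] < bic:
            bic, current = best[0], best[1]
        else:
            return tuple(current), bic


def estimable_spec(data: pd.DataFrame, full: ModelSpec) -> ModelSpec:
    """Largest hierarchical submodel of ``full`` estimable on ``data``.

    Subgroups produced by the piecewise split can make terms collinear
    (a single-sex or single-age stratum); such terms are dropped, dependents
    first, before model selection starts.
    """
    spec = full
    while True:
        try:
            weighted_fit(data, spec)
            return spec
        except ValueError as err:
            msg = str(err)
            dropped = False
            for term in reversed(spec.terms):
                if f"{term!r}" in msg:
                    for dependent, parents in _HIERARCHY.items():
                        if term in parents and dependent in spec.terms:
                            spec = spec.without(dependent)
                    spec = spec.without(term)
                    dropped = True
                    break
            if not dropped:
                raise


def bic_backward_select(
    data: pd.DataFrame, full: ModelSpec
) -> tuple[ModelSpec, RegressionFit]:
    """Greedy backward elimination on BIC.

    At each step the removable term whose removal lowers the BIC the most
    is dropped; the search stops when no removal lowers it.  Deterministic:
    ties are broken by the fixed term ordering.
    """
    spec = estimable_spec(data, full)
    fit = weighted_fit(data, spec)
    while True:
        candidates = []
        for term in spec.removable_terms():
            reduced = spec.without(term)
            candidates.append((weighted_fit(data, reduced).bic, term, reduced))
        if not candidates:
            return spec, fit
        best_bic, _, best_spec = min(candidates, key=lambda c: c[0])
        if best_bic < fit.bic:
            spec = best_spec
            fit = weighted_fit(data, spec)
        else:
            return spec, fit


def enumerate_submodels(full: ModelSpec):
    """All hierarchical submodels of ``full`` (exhaustive oracle helper)."""
    specs = []
    for size in range(len(full.terms) + 1):
        for combo in itertools.combinations(full.terms, size):
            try:
                specs.append(
                    ModelSpec(response=full.response, terms=combo, weight_col=full.weight_col)
                )
            except ValueError:
                continue
    return specs


@dataclass
class PiecewiseFit:
    """Best age split and the selected models on each side."""

    split_age: int  # last age included in the younger group
    younger: RegressionFit
    older: RegressionFit
    bic_sum: float
    trace: pd.DataFrame = field(repr=False, default=None)  # split_age, bic_sum per candidate

    @property
    def n_younger(self) -> int:
        return self.younger.n

    @property
    def n_older(self) -> int:
        return self.older.n


def piecewise_search(
    data: pd.DataFrame,
    full: ModelSpec,
    min_group: int = 5,
    age_col: str = "age",
) -> PiecewiseFit:
    """Brute-force breakpoint search over all feasible age splits.

    For every distinct age a, the younger group is {age ≤ a} and the older
    group the rest; splits leaving fewer than ``min_group`` samples on
    either side are infeasible.  Within each side the model is chosen by
    :func:`bic_backward_select` and the split minimizing the BIC sum wins;
    ties go to the youngest split age.
    """
    ages = data[age_col].to_numpy()
    distinct = np.unique(ages)
    candidates = [
        int(a)
        for a in distinct[:-1]
        if (ages <= a).sum() >= min_group and (ages > a).sum() >= min_group
    ]
    if not candidates:
        raise ValueError(
            f"no feasible split: no age leaves >= {min_group} samples on both sides"
        )

    order = np.argsort(ages, kind="stable")
    age_s = ages[order].astype(float)
    y = data[full.response].to_numpy(float)[order]
    w = data[full.weight_col].to_numpy(float)[order]
    female = (
        _female_indicator(data["sex"])[order]
        if "sex" in data.columns
        else np.zeros(age_s.size)
    )
    cols = {TERM_AGE: age_s, TERM_SEX: female, TERM_AGE_SEX: age_s * female}

    rows = []
    best = None
    for a in candidates:
        cut = int(np.searchsorted(age_s, a, side="right"))
        total = 0.0
        for sl in (slice(None, cut), slice(cut, None)):
            sub_cols = {t: cols[t][sl] for t in full.terms}
            _, bic = _greedy_terms(sub_cols, y[sl], w[sl], full.terms)
            total += bic
        rows.append({"split_age": a, "bic_sum": total})
        if best is None or total < best[0]:
            best = (total, a)
    total, a = best
    _, fit_young = bic_backward_select(data[data[age_col] <= a], full)
    _, fit_old = bic_backward_select(data[data[age_col] > a], full)
    return PiecewiseFit(
        split_age=a,
        younger=fit_young,
        older=fit_old,
        bic_sum=total,
        trace=pd.DataFrame(rows),
    )


def compare_slopes(a: RegressionFit, b: RegressionFit) -> tuple[float, float]:
    """T test for equality of the two fits' age slopes.

    Welch construction: t = (β1a − β1b)/√(SE_a² + SE_b²) with
    Satterthwaite degrees of freedom from the two residual dfs; two-sided p.
    """
    for fit in (a, b):
        if TERM_AGE not in fit.params:
            raise ValueError("both fits must contain the AGE term")
    se_a, se_b = a.slope_se, b.slope_se
    denom = np.hypot(se_a, se_b)
    if denom == 0:
        return 0.0, 1.0
    t = (a.slope - b.slope) / denom
    df = (se_a**2 + se_b**2) ** 2 / (
        se_a**4 / a.df_resid + se_b**4 / b.df_resid
    )
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), p


def cross_sectional_table(
    data: pd.DataFrame,
    response: str,
    min_group: int = 5,
    subsets: Sequence[str] = ("all", "men", "women"),
) -> pd.DataFrame:
    """General + piecewise fits for all donors and per sex, as a tidy table."""
    rows = []
    for subset in subsets:
        if subset == "all":
            sub = data
            full = ModelSpec(response=response)
        else:
            sexval = "male" if subset == "men" else "female"
            sub = data[data["sex"].astype(str).str.lower() == sexval]
            full = ModelSpec(response=response, terms=(TERM_AGE,))
        if len(sub) < min_group:
            continue
        _, general = bic_backward_select(sub, full)
        # the general row reports the AGE model even if BIC dropped AGE
        if TERM_AGE not in general.params:
            general = weighted_fit(
                sub, ModelSpec(response=response, terms=(TERM_AGE,))
            )
        rows.append({"subset": subset, "segment": "general", **general.summary_row()})
        try:
            pw = piecewise_search(sub, full, min_group=min_group)
        except ValueError:
            continue
        rows.append(
            {
                "subset": subset,
                "segment": f"young<= {pw.split_age}",
                **pw.younger.summary_row(),
            }
        )
        rows.append(
            {
                "subset": subset,
                "segment": f"old> {pw.split_age}",
                **pw.older.summary_row(),
            }
        )
    return pd.DataFrame(rows)
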