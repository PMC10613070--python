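"""Longitudinal mixed-effects modelling of repertoire evenness.

Repeated measures from the same donors (three samplings roughly a decade
apart) are modelled with linear mixed-effects models.  Fixed effects may
include age, sex (men = reference), cell type (CD4 = reference) and the
age×sex and age×cell-type interactions; random variation enters as a
per-donor intercept and, for the sorted-compartment analysis, an
additional per-donor cell-type intercept:

    J_it = β0 + β1·AGE + β2·SEX + β3·AGE·SEX
             (+ β4·AGE·CELLTYPE) + u_i (+ v_i·CELLTYPE) + ε_it

Estimation is by maximum likelihood (not REML) so that likelihood-ratio
tests between nested fixed-effect structures are valid; backward selection
removes, one at a time, the least significant removable fixed term whose
LRT p-value exceeds ``alpha``.  The intraclass correlation of a random
grouping is its variance share of the total (all components + residual).

Two derived summaries reproduce the printed presentation of such models:
the *initial diversity* of a donor is their model intercept at age zero
(fixed intercept + sex offset + predicted donor/cell-type offsets), and
the per-year *group slope* is β1 + β3·[female] + β4·[CD8].  Both are pure
arithmetic on a coefficient table, so they work identically on a fresh fit
and on a published table of coefficients; a bundled reference table for a
six-donor design is provided for worked examples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

TERM_AGE = "AGE"
TERM_SEX = "SEX"
TERM_AGE_SEX = "AGE:SEX"
TERM_CELLTYPE = "CELLTYPE"
TERM_AGE_CELLTYPE = "AGE:CELLTYPE"

ALL_FIXED_TERMS = (TERM_AGE, TERM_SEX, TERM_AGE_SEX, TERM_CELLTYPE, TERM_AGE_CELLTYPE)

_HIERARCHY = {
    TERM_AGE_SEX: (TERM_AGE, TERM_SEX),
    TERM_AGE_CELLTYPE: (TERM_AGE, TERM_CELLTYPE),
}

GROUP_DONOR = "DONOR"
GROUP_DONOR_CELLTYPE = "DONOR:CELLTYPE"


@dataclass(frozen=True)
class MixedSpec:
    """Fixed terms and random-intercept groupings of a longitudinal model."""

    response: str = "status_J"
    fixed: tuple[str, ...] = (TERM_AGE, TERM_SEX, TERM_AGE_SEX)
    random: tuple[str, ...] = (GROUP_DONOR,)

    def __post_init__(self) -> None:
        fixed = tuple(t for t in ALL_FIXED_TERMS if t in self.fixed)
        unknown = set(self.fixed) - set(ALL_FIXED_TERMS)
        if unknown:
            raise ValueError(f"unknown fixed terms {sorted(unknown)}")
        object.__setattr__(self, "fixed", fixed)
        for term, parents in _HIERARCHY.items():
            if term in self.fixed and not all(p in self.fixed for p in parents):
                raise ValueError(f"{term} requires {parents} (marginality)")
        if GROUP_DONOR not in self.random:
            raise ValueError("at least the DONOR random intercept is required")

    def without(self, term: str) -> "MixedSpec":
        return MixedSpec(
            response=self.response,
            fixed=tuple(t for t in self.fixed if t != term),
            random=self.random,
        )

    def removable_terms(self) -> list[str]:
        out = []
        for term in self.fixed:
            needed = [t for t, ps in _HIERARCHY.items() if term in ps and t in self.fixed]
            if not needed:
                out.append(term)
        return out


@dataclass
class MixedFit:
    """A fitted linear mixed-effects model (ML)."""

    spec: MixedSpec
    params: dict[str, float]  # fixed effects, keys Intercept/AGE/SEX/...
    bse: dict[str, float]
    donor_intercepts: dict[str, float]  # predicted random intercepts (BLUPs)
    donor_celltype_offsets: dict[str, float]  # predicted CD8 offsets, if modelled
    donor_sex: dict[str, str]
    var_components: dict[str, float]  # per random grouping
    resid_var: float
    llf: float
    n: int
    converged: bool

    @property
    def total_variance(self) -> float:
        return sum(self.var_components.values()) + self.resid_var

    @property
    def n_donors(self) -> int:
        return len(self.donor_intercepts)

    def term_df(self, term: str) -> int:
        """Containment degrees of freedom for a fixed term's t interval.

        Terms constant within a donor (intercept, sex) are tested against
        the between-donor stratum; terms varying within a donor (anything
        involving age or cell type) against the within-donor stratum.  This
        is the standard small-sample choice for nested designs; the normal
        reference is noticeably anti-conservative at 18 observations.
        """
        between = {"Intercept", TERM_SEX}
        if term in between:
            return max(self.n_donors - 2, 1)
        return max(self.n - self.n_donors - 2, 1)

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        """t interval for one fixed effect with containment df."""
        crit = stats.t.ppf(0.5 + level / 2.0, self.term_df(term))
        est, se = self.params[term], self.bse[term]
        return est - crit * se, est + crit * se


def _prepare(data: pd.DataFrame, spec: MixedSpec) -> pd.DataFrame:
    df = data.copy()
    df["_female"] = (
        df["sex"].astype(str).str.lower().isin(["female", "f", "woman", "1"])
    ).astype(float)
    if "celltype" in df.columns:
        df["_cd8"] = (
            df["celltype"].astype(str).str.upper().isin(["CD8", "1"])
        ).astype(float)
    elif TERM_CELLTYPE in spec.fixed or GROUP_DONOR_CELLTYPE in spec.random:
        raise ValueError("cell-type terms requested but no 'celltype' column present")
    df["_donor"] = df["donor"].astype(str)
    return df


def _design(df: pd.DataFrame, spec: MixedSpec) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    age = df["age"].to_numpy(float)
    female = df["_female"].to_numpy(float)
    cd8 = df["_cd8"].to_numpy(float) if "_cd8" in df.columns else None
    mapping = {
        TERM_AGE: lambda: age,
        TERM_SEX: lambda: female,
        TERM_AGE_SEX: lambda: age * female,
        TERM_CELLTYPE: lambda: cd8,
        TERM_AGE_CELLTYPE: lambda: age * cd8,
    }
    for term in spec.fixed:
        cols.append(mapping[term]())
        names.append(term)
    return np.column_stack(cols), names


def fit_lmm(data: pd.DataFrame, spec: MixedSpec, maxiter: int = 500) -> MixedFit:
    """Fit the mixed model by maximum likelihood via statsmodels MixedLM.

    Expects columns: the response, ``age``, ``sex``, ``donor`` and (for
    cell-type models) ``celltype``.  Raises on non-convergence; a random
    variance estimated on the zero boundary produces a warning and a
    pinned-at-zero component, not an error.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    df = _prepare(data, spec)
    if df["_donor"].nunique() < 2:
        raise ValueError("need at least 2 donors")
    exog, names = _design(df, spec)
    endog = df[spec.response].to_numpy(float)

    vc_formula = None
    use_vc = GROUP_DONOR_CELLTYPE in spec.random
    if use_vc:
        vc_formula = {"celltype": "0 + _cd8"}
    model = MixedLM(
        endog,
        exog,
        groups=df["_donor"].to_numpy(),
        exog_re=np.ones((len(df), 1)),
        exog_vc=None,
    )
    if use_vc:
        # variance-component construction needs the formula interface
        fixed_rhs = " + ".join(
            {
                TERM_AGE: "age",
                TERM_SEX: "_female",
                TERM_AGE_SEX: "age:_female",
                TERM_CELLTYPE: "_cd8",
                TERM_AGE_CELLTYPE: "age:_cd8",
            }[t]
            for t in spec.fixed
        ) or "1"
        model = MixedLM.from_formula(
            f"{spec.response} ~ {fixed_rhs}",
            groups="_donor",
            re_formula="1",
            vc_formula=vc_formula,
            data=df,
        )

    # boundary variance estimates can make the Hessian singular or stall an
    # optimizer; cascade through optimizers before giving up
    result = None
    last_err: Optional[Exception] = None
    for methods in (["lbfgs", "cg"], ["powell"], ["nm"]):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                candidate = model.fit(reml=False, maxiter=maxiter, method=methods)
        except (np.linalg.LinAlgError, ValueError) as err:
            last_err = err
            continue
        if result is None or (candidate.converged and not result.converged):
            result = candidate
        if candidate.converged:
            break
    if result is None:
        raise RuntimeError(
            f"mixed model failed to fit for response {spec.response!r}: {last_err}"
        )
    if not result.converged:
        raise RuntimeError(
            f"mixed model did not converge for response {spec.response!r}; "
            f"estimates at stop: {np.asarray(result.params).round(6).tolist()}"
        )

    # map statsmodels parameter names back to term names
    if use_vc:
        sm_names = list(result.model.exog_names)
        rename = {
            "Intercept": "Intercept",
            "age": TERM_AGE,
            "_female": TERM_SEX,
            "age:_female": TERM_AGE_SEX,
            "_cd8": TERM_CELLTYPE,
            "age:_cd8": TERM_AGE_CELLTYPE,
        }
        fe = np.asarray(result.fe_params, dtype=float)
        fe_se = np.asarray(result.bse_fe, dtype=float)
        params = {rename[nm]: fe[i] for i, nm in enumerate(sm_names)}
        bse = {rename[nm]: fe_se[i] for i, nm in enumerate(sm_names)}
    else:
        params = {nm: float(v) for nm, v in zip(names, result.fe_params)}
        bse = {nm: float(v) for nm, v in zip(names, result.bse_fe)}

    donor_var = float(np.asarray(result.cov_re)[0, 0])
    var_components = {GROUP_DONOR: donor_var}
    if use_vc:
        var_components[GROUP_DONOR_CELLTYPE] = float(result.vcomp[0])
    resid_var = float(result.scale)
    if donor_var <= 1e-12:
        warnings.warn(
            "donor random-intercept variance estimated at the zero boundary",
            stacklevel=2,
        )

    donor_intercepts: dict[str, float] = {}
    donor_ct: dict[str, float] = {}
    for donor, re_vals in result.random_effects.items():
        vals = np.asarray(re_vals, dtype=float)
        donor_intercepts[str(donor)] = float(vals[0])
        if use_vc and vals.size > 1:
            donor_ct[str(donor)] = float(vals[1:].sum())
    donor_sex = {
        str(d): ("female" if f > 0.5 else "male")
        for d, f in df.groupby("_donor")["_female"].first().items()
    }

    return MixedFit(
        spec=spec,
        params=params,
        bse=bse,
        donor_intercepts=donor_intercepts,
        donor_celltype_offsets=donor_ct,
        donor_sex=donor_sex,
        var_components=var_components,
        resid_var=resid_var,
        llf=float(result.llf),
        n=len(df),
        converged=bool(result.converged),
    )


def lrt_backward_select(
    data: pd.DataFrame, full: MixedSpec, alpha: float = 0.05
) -> tuple[MixedSpec, MixedFit]:
    """Backward elimination of fixed effects by likelihood-ratio tests.

    Each step refits by ML without one removable term; the term with the
    largest LRT p-value above ``alpha`` is dropped.  The random structure
    is never altered.

    The LR statistic is referred to an F distribution through the exact
    Gaussian identity LR = n·ln(1 + F/df2) rather than to χ²(1): at the
    longitudinal design sizes this pipeline targets (tens of observations)
    the χ² reference is markedly anti-conservative, while the F form is
    exact in the fixed-effects-only limit and close to nominal with random
    intercepts.
    """
    spec = full
    fit = fit_lmm(data, spec)
    n_random = len(spec.random)
    while True:
        worst: Optional[tuple[float, str, MixedFit]] = None
        for term in spec.removable_terms():
            reduced_fit = fit_lmm(data, spec.without(term))
            lr = max(2.0 * (fit.llf - reduced_fit.llf), 0.0)
            df2 = max(fit.n - (len(spec.fixed) + 1) - n_random, 1)
            fstat = np.expm1(lr / fit.n) * df2
            p = float(stats.f.sf(fstat, 1, df2))
            if worst is None or p > worst[0]:
                worst = (p, term, reduced_fit)
        if worst is None or worst[0] <= alpha:
            return spec, fit
        spec = spec.without(worst[1])
        fit = worst[2]


def icc(fit: MixedFit, grouping: str = GROUP_DONOR) -> float:
    """Share of total variance attributable to one random grouping."""
    if grouping not in fit.var_components:
        raise ValueError(
            f"unknown grouping {grouping!r}; available: {sorted(fit.var_components)}"
        )
    return fit.var_components[grouping] / fit.total_variance


# ---------------------------------------------------------------------------
# coefficient-table arithmetic


@dataclass
class CoefficientTable:
    """Coefficients of a final longitudinal model, fit- or literature-sourced.

    ``b4`` is the age×cell-type slope (0 when the model has none);
    ``celltype_offsets`` are the per-donor CD8 intercept offsets (empty for
    whole-blood models).
    """

    response: str
    b0: float
    b1: float
    b2: float
    b3: float = 0.0
    b4: float = 0.0
    donor_offsets: dict[str, float] = field(default_factory=dict)
    celltype_offsets: dict[str, float] = field(default_factory=dict)
    donor_sex: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_fit(cls, fit: MixedFit) -> "CoefficientTable":
        return cls(
            response=fit.spec.response,
            b0=fit.params.get("Intercept", 0.0),
            b1=fit.params.get(TERM_AGE, 0.0),
            b2=fit.params.get(TERM_SEX, 0.0),
            b3=fit.params.get(TERM_AGE_SEX, 0.0),
            b4=fit.params.get(TERM_AGE_CELLTYPE, 0.0),
            donor_offsets=dict(fit.donor_intercepts),
            celltype_offsets=dict(fit.donor_celltype_offsets),
            donor_sex=dict(fit.donor_sex),
        )

    def donors_of(self, sex: str) -> list[str]:
        donors = [d for d, s in self.donor_sex.items() if s == sex]
        if not donors:
            raise ValueError(f"no donors of sex {sex!r}")
        return sorted(donors)


@dataclass(frozen=True)
class GroupSummary:
    """Initial (age-zero) diversity of one sex (and cell-type) group."""

    sex: str
    cell_type: Optional[str]
    mean_initial: float
    sd_initial: float
    n_donors: int


def summarize_initial_diversity(
    coefs: CoefficientTable | MixedFit,
    sex: str,
    cell_type: Optional[str] = None,
    ndigits: int = 4,
) -> GroupSummary:
    """Mean ± SD (n−1) of the per-donor model intercepts for one group.

    A donor's initial diversity is β0 + β2·[female] + their predicted
    intercept offset, plus their cell-type offset when summarizing CD8.
    Values are rounded to ``ndigits`` decimals for reporting.
    """
    if isinstance(coefs, MixedFit):
        coefs = CoefficientTable.from_fit(coefs)
    donors = coefs.donors_of(sex)
    if len(donors) < 2:
        raise ValueError(f"SD undefined: fewer than 2 donors of sex {sex!r}")
    base = coefs.b0 + (coefs.b2 if sex == "female" else 0.0)
    values = []
    for d in donors:
        v = base + coefs.donor_offsets.get(d, 0.0)
        if cell_type is not None and cell_type.upper() == "CD8":
            v += coefs.celltype_offsets.get(d, 0.0)
        values.append(v)
    arr = np.asarray(values)
    return GroupSummary(
        sex=sex,
        cell_type=cell_type,
        mean_initial=round(float(arr.mean()), ndigits),
        sd_initial=round(float(arr.std(ddof=1)), ndigits),
        n_donors=len(donors),
    )


def slope_for_group(
    coefs: CoefficientTable | MixedFit,
    sex: str,
    cell_type: Optional[str] = None,
    ndigits: int = 4,
) -> float:
    """Per-year diversity slope for one group: β1 + β3·[female] + β4·[CD8]."""
    if isinstance(coefs, MixedFit):
        coefs = CoefficientTable.from_fit(coefs)
    slope = coefs.b1
    if sex == "female":
        slope += coefs.b3
    if cell_type is not None and cell_type.upper() == "CD8":
        slope += coefs.b4
    return round(float(slope), ndigits)


# ---------------------------------------------------------------------------
# reference coefficient tables (bundled worked example)

_REFERENCE_FILE = "longitudinal_reference_coefficients.tsv"


def load_reference_coefficients(
    response: str, model: str = "whole_blood", path: Optional[Path | str] = None
) -> CoefficientTable:
    """Load a bundled (or user) coefficient table.

    ``response`` is ``"status"`` or ``"sequence"``; ``model`` is
    ``"whole_blood"`` (donor random intercepts only) or ``"celltype"``
    (additional per-donor CD8 offsets).  The bundled table describes a
    six-donor design: donors 1–3 are men, donors 4–6 women.
    """
    if path is None:
        text = resources.files("trbdyn.data").joinpath(_REFERENCE_FILE).read_text()
        from io import StringIO

        table = pd.read_csv(StringIO(text), sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    sel = table[(table["model"] == model) & (table["response"] == response)]
    if sel.empty:
        raise ValueError(f"no coefficients for model={model!r} response={response!r}")
    values = dict(zip(sel["term"], sel["value"].astype(float)))
    donors = [str(i) for i in range(1, 7)]
    return CoefficientTable(
        response=response,
        b0=values["b0"],
        b1=values["b1"],
        b2=values["b2"],
        b3=values.get("b3", 0.0),
        b4=values.get("b4", 0.0),
        donor_offsets={d: values[f"d{d}"] for d in donors if f"d{d}" in values},
        celltype_offsets={d: values[f"c{d}"] for d in donors if f"c{d}" in values},
        donor_sex={d: ("male" if int(d) <= 3 else "female") for d in donors},
    )
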