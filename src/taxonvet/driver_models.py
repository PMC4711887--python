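"""Logistic models for the drivers of taxon-name issues.

The response is a binary issue indicator per occurrence record (``hasIssue``
or one of the four single-issue flags); the candidate predictors are the five
standardized covariates: ``basisOfRecord`` (PreservedSpecimen vs
FossilSpecimen), geographic region, clade, year of collection, and the
institution's digitally accessible record count.  Year enters centered and
scaled; the institutional record count enters log-transformed, centered and
scaled (record volumes span orders of magnitude).  Reference levels are
PreservedSpecimen, North America and Aves, all configurable.

Model search considers every subset of the 10 unordered two-way interactions
between the five covariates (1,024 candidate models for the full set),
ranking the fits by AIC.  Fit quality is reported as McFadden's and
Nagelkerke's pseudo-R², both computed from the fitted and null
log-likelihoods.  Records whose response is indeterminate (names that could
not be judged for synonymy) are dropped before fitting.

The API follows the Model/Results convention: build an
:class:`IssueDriverModel` from a data frame, call :meth:`~IssueDriverModel.fit`,
and read estimates, AIC, pseudo-R² and effect profiles off the returned
:class:`IssueDriverResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import chain, combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "DEFAULT_COVARIATES",
    "DEFAULT_REFERENCE_LEVELS",
    "ModelSpec",
    "ModelFitError",
    "IssueDriverModel",
    "IssueDriverResults",
    "fit_issue_model",
    "enumerate_interaction_sets",
    "select_model_aic",
    "pseudo_r2",
    "effect_profile",
]

DEFAULT_COVARIATES: tuple[str, ...] = (
    "basisOfRecord",
    "region",
    "clade",
    "year",
    "institutionRecords",
)

CATEGORICAL_COVARIATES = ("basisOfRecord", "region", "clade")

DEFAULT_REFERENCE_LEVELS: dict[str, str] = {
    "basisOfRecord": "PreservedSpecimen",
    "region": "North America",
    "clade": "Aves",
}


class ModelFitError(RuntimeError):
    """A model failed to converge or showed separation; names the terms."""


@dataclass(frozen=True)
class ModelSpec:
    """Response, main effects, and the included two-way interaction pairs."""

    response: str
    main_effects: tuple[str, ...] = DEFAULT_COVARIATES
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        mains = set(self.main_effects)
        for a, b in self.interactions:
            if a not in mains or b not in mains:
                raise ValueError(
                    f"interaction ({a}, {b}) lacks a matching main effect"
                )

    @property
    def n_interactions(self) -> int:
        return len(self.interactions)


def _term_for(covariate: str) -> str:
    if covariate == "year":
        return "standardize(year)"
    if covariate == "institutionRecords":
        return "standardize(np.log(institutionRecords))"
    return covariate


def build_formula(spec: ModelSpec) -> str:
    """Patsy formula for a model spec (continuous terms scaled in-formula)."""
    terms = [_term_for(c) for c in spec.main_effects]
    terms += [f"{_term_for(a)}:{_term_for(b)}" for a, b in spec.interactions]
    rhs = " + ".join(terms) if terms else "1"
    return f"{spec.response} ~ {rhs}"


def _prepare_frame(
    data: pd.DataFrame,
    spec: ModelSpec,
    reference_levels: Mapping[str, str],
) -> pd.DataFrame:
    df = data.copy()
    # drop indeterminate responses (e.g. synonymy that could not be judged)
    resp = df[spec.response]
    if resp.dtype == object:
        keep = resp.isin(["yes", "no", True, False, 0, 1])
        df = df.loc[keep].copy()
        df[spec.response] = (
            df[spec.response].map({"yes": 1, "no": 0, True: 1, False: 0, 1: 1, 0: 0})
        )
    df[spec.response] = df[spec.response].astype(int)
    for cov in spec.main_effects:
        if cov in CATEGORICAL_COVARIATES:
            levels = list(pd.unique(df[cov].astype(str)))
            ref = reference_levels.get(cov)
            if ref in levels:
                levels = [ref] + sorted(l for l in levels if l != ref)
            else:
                levels = sorted(levels)
            df[cov] = pd.Categorical(df[cov].astype(str), categories=levels)
    return df


class IssueDriverModel:
    """Logistic (binomial GLM, logit link) model of issue probability.

    Parameters
    ----------
    data : DataFrame with the response column and the covariate columns.
    spec : the response/main-effect/interaction specification.
    reference_levels : reference category per categorical covariate.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        spec: ModelSpec,
        reference_levels: Mapping[str, str] | None = None,
    ):
        self.spec = spec
        self.reference_levels = dict(DEFAULT_REFERENCE_LEVELS)
        if reference_levels:
            self.reference_levels.update(reference_levels)
        missing = [c for c in (spec.response, *spec.main_effects) if c not in data]
        if missing:
            raise ValueError(f"data lacks required columns: {missing}")
        self.frame = _prepare_frame(data, spec, self.reference_levels)
        resp = self.frame[spec.response]
        if len(self.frame) == 0:
            raise ValueError("no usable observations after dropping indeterminate")
        if resp.nunique() < 2:
            raise ValueError(
                f"response {spec.response!r} is constant; cannot fit a logit model"
            )
        for cov in spec.main_effects:
            if cov in CATEGORICAL_COVARIATES:
                counts = self.frame[cov].value_counts()
                empty = [str(l) for l in counts.index[counts == 0]]
                if empty:
                    raise ValueError(f"{cov}: empty factor levels {empty}")
        self.formula = build_formula(spec)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        interactions: Sequence[tuple[str, str]] = (),
        reference_levels: Mapping[str, str] | None = None,
    ) -> "IssueDriverModel":
        spec = ModelSpec(
            response=response,
            main_effects=tuple(covariates),
            interactions=tuple(tuple(p) for p in interactions),
        )
        return cls(data, spec, reference_levels)

    def fit(self) -> "IssueDriverResults":
        """Maximum-likelihood fit; raises :class:`ModelFitError` on
        non-convergence or separation, naming the offending terms."""
        try:
            res = smf.glm(
                self.formula, data=self.frame, family=sm.families.Binomial()
            ).fit(maxiter=200)
        except Exception as exc:  # separation can surface as LinAlgError etc.
            raise ModelFitError(
                f"fit failed for {self.formula!r}: {exc}"
            ) from exc
        if not getattr(res, "converged", True):
            raise ModelFitError(f"IRLS did not converge for {self.formula!r}")
        runaway = [name for name, se in res.bse.items() if not np.isfinite(se) or se > 1e3]
        if runaway:
            raise ModelFitError(
                f"separation suspected: unstable standard errors for terms {runaway}"
            )
        null_res = smf.glm(
            f"{self.spec.response} ~ 1", data=self.frame,
            family=sm.families.Binomial(),
        ).fit()
        return IssueDriverResults(model=self, _res=res, _null=null_res)


@dataclass
class IssueDriverResults:
    """Estimates and diagnostics of a fitted issue-driver model."""

    model: IssueDriverModel
    _res: object
    _null: object

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def pvalues(self) -> pd.Series:
        return self._res.pvalues

    @property
    def llf(self) -> float:
        return float(self._res.llf)

    @property
    def llnull(self) -> float:
        return float(self._null.llf)

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    @property
    def n_params(self) -> int:
        return int(self._res.df_model) + 1

    @property
    def aic(self) -> float:
        # AIC identity: -2 logLik + 2 (number of estimated parameters)
        return -2.0 * self.llf + 2.0 * self.n_params

    @property
    def mcfadden_r2(self) -> float:
        return pseudo_r2(self.llf, self.llnull, self.nobs)[0]

    @property
    def nagelkerke_r2(self) -> float:
        return pseudo_r2(self.llf, self.llnull, self.nobs)[1]

    def predict(self, new_data: pd.DataFrame | None = None) -> pd.Series:
        return self._res.predict(new_data)

    def summary(self):
        """statsmodels summary table of the underlying GLM fit."""
        return self._res.summary()

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "std_err": self.bse,
                "p_value": self.pvalues,
            }
        )

    def effect_profile(
        self,
        focal: str,
        grid: Sequence | None = None,
        alpha: float = 0.05,
    ) -> pd.DataFrame:
        """Predicted issue probability over a grid of the focal predictor.

        Non-focal covariates are held at their reference level (categorical)
        or mean (continuous).  Confidence bands are delta-method intervals
        from the GLM prediction machinery.  Grid values outside the observed
        range are annotated, not rejected.
        """
        return effect_profile(self, focal, grid, alpha)


def pseudo_r2(llf: float, llnull: float, nobs: int) -> tuple[float, float]:
    """(McFadden, Nagelkerke) pseudo-R² from model and null log-likelihoods.

    McFadden: ``1 - llf/llnull``.  Nagelkerke: the Cox–Snell ratio
    ``1 - exp((2/n)(llnull - llf))`` rescaled by its maximum
    ``1 - exp((2/n) llnull)``.
    """
    if nobs <= 0:
        raise ValueError("nobs must be positive")
    if llnull == 0.0:
        raise ValueError("null log-likelihood of zero is degenerate")
    mcfadden = 1.0 - llf / llnull
    cox_snell = 1.0 - math.exp((2.0 / nobs) * (llnull - llf))
    max_cs = 1.0 - math.exp((2.0 / nobs) * llnull)
    nagelkerke = cox_snell / max_cs
    return mcfadden, nagelkerke


def pseudo_r2_from_results(
    results: IssueDriverResults, null_results
) -> tuple[float, float]:
    """Pseudo-R² from two fitted results; errors on mismatched observations."""
    n_null = int(getattr(null_results, "nobs", 0))
    if n_null != results.nobs:
        raise ValueError(
            f"model fitted on {results.nobs} observations but null on {n_null}"
        )
    return pseudo_r2(results.llf, float(null_results.llf), results.nobs)


def fit_issue_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    reference_levels: Mapping[str, str] | None = None,
) -> IssueDriverResults:
    """Fit one logistic issue model (functional wrapper over the Model class)."""
    return IssueDriverModel(data, spec, reference_levels).fit()


def enumerate_interaction_sets(
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> list[tuple[tuple[str, str], ...]]:
    """All subsets of the unordered covariate pairs: 2^C(k,2) sets."""
    pairs = list(combinations(covariates, 2))
    return [
        tuple(subset)
        for subset in chain.from_iterable(
            combinations(pairs, r) for r in range(len(pairs) + 1)
        )
    ]


@dataclass
class RankedModel:
    """One member of the AIC-ranked enumeration."""

    spec: ModelSpec
    results: IssueDriverResults | None
    aic: float
    delta_aic: float = float("nan")
    error: str = ""


def select_model_aic(
    data: pd.DataFrame,
    response: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    reference_levels: Mapping[str, str] | None = None,
    max_models: int | None = None,
) -> list[RankedModel]:
    """Exhaustive AIC ranking over all two-way-interaction subsets.

    Fits one model per subset of the C(k,2) covariate pairs (2^10 = 1,024
    for the full five-covariate set) and returns them AIC-ascending with
    ΔAIC relative to the best.  A member whose fit fails is flagged with the
    error and ranked last; the enumeration continues.  ``max_models`` caps
    the enumeration for exploratory runs (a greedy fallback for larger
    covariate sets than five is deliberately out of scope).
    """
    sets = enumerate_interaction_sets(covariates)
    if max_models is not None:
        sets = sets[:max_models]
    ranked: list[RankedModel] = []
    for interactions in sets:
        spec = ModelSpec(
            response=response,
            main_effects=tuple(covariates),
            interactions=interactions,
        )
        try:
            res = fit_issue_model(data, spec, reference_levels)
            ranked.append(RankedModel(spec=spec, results=res, aic=res.aic))
        except (ModelFitError, ValueError) as exc:
            ranked.append(
                RankedModel(spec=spec, results=None, aic=float("inf"), error=str(exc))
            )
    ranked.sort(key=lambda m: m.aic)
    best = ranked[0].aic
    for m in ranked:
        m.delta_aic = m.aic - best
    return ranked


def effect_profile(
    results: IssueDriverResults,
    focal: str,
    grid: Sequence | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Predicted probabilities with delta-method confidence bands.

    Returns a frame with columns ``{focal}``, ``probability``, ``ci_low``,
    ``ci_high`` and ``outside_observed_range``.
    """
    frame = results.model.frame
    spec = results.spec
    if focal not in spec.main_effects:
        raise ValueError(f"{focal!r} is not a covariate of this model")

    if grid is None:
        if focal in CATEGORICAL_COVARIATES:
            grid = list(frame[focal].cat.categories)
        else:
            lo, hi = frame[focal].min(), frame[focal].max()
            grid = list(np.linspace(lo, hi, 25))

    new = {}
    for cov in spec.main_effects:
        if cov == focal:
            continue
        if cov in CATEGORICAL_COVARIATES:
            ref = results.model.reference_levels.get(cov)
            cats = list(frame[cov].cat.categories)
            new[cov] = ref if ref in cats else cats[0]
        else:
            new[cov] = float(frame[cov].mean())
    profile = pd.DataFrame({focal: list(grid)})
    for cov, val in new.items():
        profile[cov] = val
    for cov in CATEGORICAL_COVARIATES:
        if cov in profile:
            profile[cov] = pd.Categorical(
                profile[cov].astype(str), categories=list(frame[cov].cat.categories)
            )

    pred = results._res.get_prediction(profile)
    sf = pred.summary_frame(alpha=alpha)
    out = pd.DataFrame(
        {
            focal: list(grid),
            "probability": sf["mean"].to_numpy(),
            "ci_low": sf["mean_ci_lower"].to_numpy(),
            "ci_high": sf["mean_ci_upper"].to_numpy(),
        }
    )
    if focal in CATEGORICAL_COVARIATES:
        out["outside_observed_range"] = [
            g not in set(frame[focal].cat.categories) for g in grid
        ]
    else:
        lo, hi = frame[focal].min(), frame[focal].max()
        out["outside_observed_range"] = [(g < lo) or (g > hi) for g in grid]
    return out


def build_design(
    data: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    interactions: Sequence[tuple[str, str]] = (),
    reference_levels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Design matrix (with intercept) for a covariate frame.

    Shares the term construction of the fitting path so simulated outcomes
    and fitted models agree on column meaning.
    """
    from patsy import dmatrix

    refs = dict(DEFAULT_REFERENCE_LEVELS)
    if reference_levels:
        refs.update(reference_levels)
    spec = ModelSpec(
        response="__dummy__",
        main_effects=tuple(covariates),
        interactions=tuple(tuple(p) for p in interactions),
    )
    df = data.copy()
    df["__dummy__"] = 0
    df = _prepare_frame(df, spec, refs)
    rhs = build_formula(spec).split("~", 1)[1]
    mat = dmatrix(rhs, df, return_type="dataframe")
    return mat
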