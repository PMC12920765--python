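"""Endpoint contrast: internal concentration at day 0 versus day 42.

Ordinary least squares of concentration on time point, habitat and their
interaction, with each term tested by comparing the model including it
against the model excluding it (extra-sum-of-squares F). The interaction
is tested against the full model; main effects are tested between the
additive model and the additive model without that term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "TERMS",
    "TermTest",
    "EndpointFit",
    "endpoint_subset",
    "fit_endpoint_model",
    "test_term",
    "test_all_terms",
    "group_means",
    "residual_diagnostics",
]

TERMS = ("time_point", "habitat", "interaction")

_FULL = "concentration ~ C(time_point) + C(habitat) + C(time_point):C(habitat)"
_ADDITIVE = "concentration ~ C(time_point) + C(habitat)"
_REDUCED = {
    "interaction": (_ADDITIVE, _FULL),
    "time_point": ("concentration ~ C(habitat)", _ADDITIVE),
    "habitat": ("concentration ~ C(time_point)", _ADDITIVE),
}


@dataclass(frozen=True)
class TermTest:
    term: str
    f_stat: float
    df_num: int
    df_den: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "f_stat": self.f_stat,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p_value": self.p_value,
        }


@dataclass
class EndpointFit:
    """Fitted endpoint linear model plus the design frame it used."""

    model: object  # statsmodels RegressionResults
    frame: pd.DataFrame
    reference_levels: dict[str, str]

    @property
    def coefficients(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.model.params.items()}


def endpoint_subset(
    data: pd.DataFrame, t0: float = 0.0, t1: float = 42.0
) -> pd.DataFrame:
    """Rows at the two endpoint days, with a categorical time_point label."""
    sub = data.loc[data["time_days"].isin([t0, t1])].copy()
    sub["time_point"] = np.where(sub["time_days"] == t0, "t0", "t42")
    return sub


def _check_cells(sub: pd.DataFrame) -> None:
    counts = sub.groupby(["time_point", "habitat"], observed=True).size()
    for tp in sorted(sub["time_point"].unique()):
        for hab in sorted(sub["habitat"].unique()):
            if (tp, hab) not in counts.index:
                raise ValueError(f"empty design cell: time_point={tp}, habitat={hab}")


def fit_endpoint_model(data: pd.DataFrame) -> EndpointFit:
    """OLS of concentration on time point, habitat, and their interaction.

    Treatment coding with alphabetically-first reference levels (recorded
    in the returned record).
    """
    sub = endpoint_subset(data)
    if sub["time_point"].nunique() < 2 or sub["habitat"].nunique() < 2:
        raise ValueError("need both time points and both habitats present")
    _check_cells(sub)
    model = smf.ols(_FULL, data=sub).fit()
    refs = {
        "time_point": sorted(sub["time_point"].unique())[0],
        "habitat": sorted(sub["habitat"].unique())[0],
    }
    return EndpointFit(model=model, frame=sub, reference_levels=refs)


def test_term(data: pd.DataFrame, term: str) -> TermTest:
    """Extra-sum-of-squares F-test for one model term."""
    if term not in TERMS:
        raise ValueError(f"unknown term {term!r}; expected one of {TERMS}")
    sub = endpoint_subset(data)
    _check_cells(sub)
    reduced_f, full_f = _REDUCED[term]
    reduced = smf.ols(reduced_f, data=sub).fit()
    full = smf.ols(full_f, data=sub).fit()
    df_num = int(reduced.df_resid - full.df_resid)
    df_den = int(full.df_resid)
    f_stat = ((reduced.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    f_stat = max(0.0, float(f_stat))
    p_value = float(stats.f.sf(f_stat, df_num, df_den))
    return TermTest(term=term, f_stat=f_stat, df_num=df_num, df_den=df_den, p_value=p_value)


def test_all_terms(data: pd.DataFrame) -> list[TermTest]:
    return [test_term(data, term) for term in TERMS]


def group_means(data: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and n of concentration per time_point x habitat cell."""
    sub = endpoint_subset(data)
    out = (
        sub.groupby(["time_point", "habitat"], observed=True)["concentration"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
    )
    return out


def residual_diagnostics(fit: EndpointFit) -> dict:
    """Quantitative stand-ins for the visual residual checks.

    Returns the Shapiro-Wilk test on residuals, the ratio of the largest
    to the smallest group residual variance, and a residual-vs-fitted
    table suitable for plotting.
    """
    resid = np.asarray(fit.model.resid)
    if len(resid) < 4:
        raise ValueError("need at least 4 observations for diagnostics")
    sw_stat, sw_p = stats.shapiro(resid)
    frame = fit.frame.assign(resid=resid, fitted=np.asarray(fit.model.fittedvalues))
    group_var = frame.groupby(["time_point", "habitat"], observed=True)["resid"].var(ddof=1)
    group_var = group_var.dropna()
    ratio = float(group_var.max() / group_var.min()) if group_var.min() > 0 else np.inf
    table = frame[["colony_id", "time_point", "habitat", "fitted", "resid"]].copy()
    return {
        "shapiro_stat": float(sw_stat),
        "shapiro_p": float(sw_p),
        "variance_ratio": ratio,
        "residual_table": table,
    }
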