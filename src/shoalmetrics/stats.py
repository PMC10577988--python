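"""Group-comparison statistics in the reporting style of the assay suite.

Behavioral metrics are compared across populations / diets / weeks with
the model family matched to the response type: Gaussian linear models for
continuous scores, Poisson GLMs for counts (discrete responses on a 0.1
grid, such as meter ketone readings, are first multiplied by 10 so the
Poisson family applies), Gamma GLMs for positive ratio-type indices, and
random-intercept mixed models for repeated weekly recordings of the same
groups. Model fitting is delegated to statsmodels; the bespoke parts are
the cell-contrast construction and the native Holm step-down correction.
Significance stars follow the usual 0.05 / 0.01 / 0.001 thresholds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ComparisonSpec", "ContrastTable", "holm_adjust", "compare_groups"]

_FAMILIES = {"gaussian", "poisson", "gamma", "mixed"}


@dataclass(frozen=True)
class ComparisonSpec:
    """What to compare and under which model family.

    ``factors`` are categorical design columns (e.g. population, diet,
    week); ``group_col`` identifies the repeated-measures unit for the
    mixed family; ``scale_hack`` multiplies the response before Poisson
    fitting (the x10 trick for 0.1-step meter readings).
    """

    response: str
    family: str = "gaussian"
    factors: tuple[str, ...] = ("population",)
    group_col: str | None = None
    scale_hack: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {sorted(_FAMILIES)}")
        if self.scale_hack is not None and not self.scale_hack > 0:
            raise ValueError("scale_hack must be positive")
        if self.family == "mixed" and self.group_col is None:
            raise ValueError("mixed family needs group_col")


@dataclass(frozen=True)
class ContrastTable:
    """Pairwise cell contrasts with raw and Holm-adjusted p-values."""

    table: pd.DataFrame
    family: str
    response: str

    def __post_init__(self) -> None:
        t = self.table
        if ((t["p_adjusted"] + 1e-12) < t["p_raw"]).any():
            raise AssertionError("adjusted p below raw p")


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order.

    Sort ascending; the i-th smallest is multiplied by (m - i), running
    maxima enforce monotonicity and values cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, p[order] * (m - np.arange(m)))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(metrics: pd.DataFrame, spec: ComparisonSpec) -> ContrastTable:
    """Fit the family model and test all pairwise cell contrasts.

    The factor columns are crossed into a single *cell* label (one cell
    per factor-level combination); the model fits one mean per cell, and
    every cell pair is tested with a Wald contrast, Holm-corrected.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = metrics.copy()
    for c in (spec.response, *spec.factors):
        if c not in df.columns:
            raise ValueError(f"column {c!r} missing from metrics table")
    df["_cell"] = (
        df[list(spec.factors)].astype(str).agg(":".join, axis=1)
    )
    cells = sorted(df["_cell"].unique())
    if len(cells) < 2:
        raise ValueError("need at least two factor-level cells to compare")

    y = df[spec.response].astype(float)
    if spec.family == "poisson":
        if spec.scale_hack is not None:
            y = y * spec.scale_hack
        y = np.round(y)
    df["_y"] = y

    formula = "_y ~ C(_cell)"
    if spec.family == "gaussian":
        fit = smf.ols(formula, data=df).fit()
    elif spec.family == "poisson":
        fit = smf.glm(formula, data=df, family=sm.families.Poisson()).fit()
    elif spec.family == "gamma":
        if (df["_y"] <= 0).any():
            raise ValueError("gamma family needs a strictly positive response")
        fit = smf.glm(
            formula, data=df, family=sm.families.Gamma(sm.families.links.Log())
        ).fit()
    else:  # mixed: random intercept per repeated-measures unit
        fit = smf.mixedlm(formula, data=df, groups=df[spec.group_col]).fit(reml=True)

    if spec.family == "mixed":
        names = list(fit.fe_params.index)  # contrasts act on fixed effects
    else:
        names = list(fit.params.index)
    k = len(names)

    def cell_vector(cell: str) -> np.ndarray:
        v = np.zeros(k)
        for i, nm in enumerate(names):
            if nm == "Intercept":
                v[i] = 1.0
            elif nm == f"C(_cell)[T.{cell}]":
                v[i] = 1.0
        return v

    rows = []
    for a, b in itertools.combinations(cells, 2):
        contrast = np.atleast_2d(cell_vector(b) - cell_vector(a))
        res = fit.t_test(contrast)
        rows.append(
            {
                "contrast": f"{b} - {a}",
                "estimate": float(np.atleast_1d(res.effect)[0]),
                "p_raw": float(np.atleast_1d(res.pvalue).ravel()[0]),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = holm_adjust(table["p_raw"].to_numpy())
    table["stars"] = [_stars(p) for p in table["p_adjusted"]]
    return ContrastTable(table=table, family=spec.family, response=spec.response)
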