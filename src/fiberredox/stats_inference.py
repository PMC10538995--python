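"""Mixed-effects inference over fiber types and timepoints.

The modelling surface mirrors statsmodels: :class:`RedoxMixedModel` is built
from a long per-subject, per-timepoint, per-fiber-type table and ``fit()``
returns a :class:`RedoxMixedResults` carrying the REML estimates, estimated
marginal means, Tukey-adjusted pairwise contrasts with percent-difference
effect sizes, and a ``summary()`` table. The model is a linear mixed model
with fixed effects for time and fiber type (optionally their interaction
and/or sex) and a random intercept per participant, which tolerates cells
missing at random without dropping whole subjects.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ContrastResult",
    "RedoxMixedModel",
    "RedoxMixedResults",
    "fit_mixed_model",
    "pairwise_contrasts",
    "exercise_delta",
    "spearman_correlation",
    "percent_difference",
]


@dataclass
class ContrastResult:
    """One pairwise comparison of estimated marginal means.

    ``estimate`` is level_a minus level_b on the outcome scale;
    ``percent_difference`` expresses it relative to level_b (the reference),
    with the 95% CI transformed onto the same percent scale; ``p_adjusted``
    is Tukey-adjusted over the factor's pairs.
    """

    level_a: str
    level_b: str
    estimate: float
    se: float
    df: float
    percent_difference: float
    ci_low: float
    ci_high: float
    p_unadjusted: float
    p_adjusted: float

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_adjusted) or 0.0 <= self.p_adjusted <= 1.0):
            raise ValueError("adjusted p must lie in [0, 1]")


def percent_difference(a: float, b: float) -> float:
    """Percent difference of ``a`` relative to reference ``b``: 100 (a-b)/b.

    Note pd(a, b) != -pd(b, a) in general; always state the reference.
    """
    if b <= 0:
        raise ValueError("reference mean must be > 0 for a percent difference")
    return 100.0 * (a - b) / b


class RedoxMixedModel:
    """Linear mixed model for per-subject, per-cell outcomes.

    Parameters
    ----------
    data : DataFrame
        Long table with one row per (subject, timepoint, fiber_type); must
        contain ``outcome_col`` and the columns named by the fixed factors and
        ``groups``.
    fixed : sequence of str
        Fixed-effect factor columns (categorical), e.g. ("timepoint",
        "fiber_type") or ("sex", "fiber_type").
    interaction : bool
        Include the two-way interaction of the fixed factors.
    groups : str
        Column of the random-intercept grouping factor (participants).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome_col: str = "value",
        fixed: Sequence[str] = ("timepoint", "fiber_type"),
        interaction: bool = False,
        groups: str = "subject_id",
    ) -> None:
        data = data.dropna(subset=[outcome_col]).copy()
        if data[groups].nunique() < 2:
            raise ValueError("need >= 2 subjects")
        for f in fixed:
            n_levels = data[f].nunique()
            if n_levels < 2:
                raise ValueError(
                    f"fixed factor {f!r} has {n_levels} level(s); the design is "
                    "singular — drop the factor or supply more levels"
                )
        self.data = data
        self.outcome_col = outcome_col
        self.fixed = tuple(fixed)
        self.interaction = interaction
        self.groups = groups
        op = "*" if interaction else "+"
        self.formula = f"{outcome_col} ~ " + f" {op} ".join(
            f"C({f})" for f in fixed
        )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "RedoxMixedModel":
        return cls(data, **kwargs)

    def fit(self, reml: bool = True) -> "RedoxMixedResults":
        model = sm.MixedLM.from_formula(
            self.formula, data=self.data, groups=self.data[self.groups]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            try:
                result = model.fit(reml=reml, method="lbfgs")
            except np.linalg.LinAlgError:
                # gradient-based REML can hit a singular information matrix
                # when the random-intercept variance collapses to 0; the
                # derivative-free profile search is robust there
                result = model.fit(reml=reml, method="powell")
        if not result.converged:
            raise RuntimeError(
                "mixed model did not converge; "
                f"gradient norm at stop: {np.linalg.norm(result.params):.3g}, "
                f"n_obs={len(self.data)}, groups={self.data[self.groups].nunique()}"
            )
        return RedoxMixedResults(self, result)


class RedoxMixedResults:
    """Fitted mixed model: marginal means, contrasts, variance components."""

    def __init__(self, model: RedoxMixedModel, result) -> None:
        self.model = model
        self.result = result
        self.fe_params = result.fe_params
        self.cov_fe = self._model_based_cov_fe()
        self.design_info = result.model.data.design_info
        n_obs = len(model.data)
        rank = np.linalg.matrix_rank(result.model.exog)
        n_groups = model.data[model.groups].nunique()
        #: containment-style denominator df for within-subject contrasts
        self.df_resid = float(max(n_obs - rank - (n_groups - 1), 1))

    def _model_based_cov_fe(self) -> np.ndarray:
        """GLS covariance of the fixed effects, (X' V^-1 X)^-1, conditional on
        the estimated variance components.

        Computed directly (per group, V_g = scale*I + Z G Z') rather than from
        the REML Hessian, which is singular whenever a variance component sits
        on the boundary (e.g. the noiseless limit); pseudo-inverses keep the
        degenerate limits well defined, with SEs going to 0 as noise does.
        """
        model = self.result.model
        X = np.asarray(model.exog)
        G = np.atleast_2d(np.asarray(self.result.cov_re))
        scale = float(self.result.scale)
        k = X.shape[1]
        info = np.zeros((k, k))
        for g in model.group_labels:
            idx = np.flatnonzero(np.asarray(model.groups) == g)
            Xg = X[idx]
            Zg = np.ones((len(idx), 1))
            Vg = scale * np.eye(len(idx)) + Zg @ G @ Zg.T
            info += Xg.T @ np.linalg.pinv(Vg) @ Xg
        return np.linalg.pinv(info)

    # -- variance components ------------------------------------------------
    @property
    def subject_var(self) -> float:
        return float(np.asarray(self.result.cov_re).ravel()[0])

    @property
    def residual_var(self) -> float:
        return float(self.result.scale)

    # -- estimated marginal means ------------------------------------------
    def _emm_design(self, factor: str, level: str) -> np.ndarray:
        """Mean fixed-effect design row for one level of ``factor``, averaged
        over an equally weighted grid of the other factors' levels."""
        from patsy import build_design_matrices

        others = [f for f in self.model.fixed if f != factor]
        grids = [sorted(self.model.data[f].unique()) for f in others]
        rows = []
        for combo in itertools.product(*grids) if grids else [()]:
            rec = {factor: level}
            rec.update(dict(zip(others, combo)))
            rows.append(rec)
        grid_df = pd.DataFrame(rows)
        (X,) = build_design_matrices([self.design_info], grid_df)
        return np.asarray(X).mean(axis=0)

    def emm(self, factor: str) -> pd.Series:
        """Estimated marginal means of every level of ``factor``."""
        self._check_factor(factor)
        levels = sorted(self.model.data[factor].unique())
        beta = np.asarray(self.fe_params)
        return pd.Series(
            {lv: float(self._emm_design(factor, lv) @ beta) for lv in levels},
            name=f"emm[{factor}]",
        )

    def _check_factor(self, factor: str) -> None:
        if factor not in self.model.fixed:
            raise ValueError(f"factor {factor!r} is not in the model")

    # -- pairwise Tukey contrasts ------------------------------------------
    def contrasts(
        self, factor: str, levels: Sequence[str] | None = None
    ) -> list[ContrastResult]:
        """All pairwise contrasts of ``factor``'s marginal means.

        p-values use the studentized-range (Tukey) family over the factor's
        pairs; the percent difference takes the second (later-listed) level of
        each pair as reference, and the percent-scale CI is the contrast's
        95% t-interval divided by the reference mean.
        """
        self._check_factor(factor)
        if levels is None:
            levels = sorted(self.model.data[factor].unique())
        beta = np.asarray(self.fe_params)
        k = len(levels)
        rows_by_level = {lv: self._emm_design(factor, lv) for lv in levels}
        results = []
        for a, b in itertools.combinations(levels, 2):
            c = rows_by_level[a] - rows_by_level[b]
            est = float(c @ beta)
            se = float(np.sqrt(c @ self.cov_fe @ c))
            ref = float(rows_by_level[b] @ beta)
            if se > 0:
                t = est / se
                p_un = 2.0 * stats.t.sf(abs(t), self.df_resid)
                p_adj = float(
                    stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, self.df_resid)
                )
                p_adj = min(max(p_adj, p_un), 1.0)
                tcrit = stats.t.ppf(0.975, self.df_resid)
                lo, hi = est - tcrit * se, est + tcrit * se
            else:
                p_un = p_adj = 1.0 if abs(est) < 1e-10 else 0.0
                lo = hi = est
            results.append(
                ContrastResult(
                    level_a=a,
                    level_b=b,
                    estimate=est,
                    se=se,
                    df=self.df_resid,
                    percent_difference=percent_difference(ref + est, ref)
                    if ref > 0
                    else float("nan"),
                    ci_low=100.0 * lo / ref if ref > 0 else float("nan"),
                    ci_high=100.0 * hi / ref if ref > 0 else float("nan"),
                    p_unadjusted=float(p_un),
                    p_adjusted=float(p_adj),
                )
            )
        return results

    def omnibus(self, factor: str) -> tuple[float, float]:
        """Wald F-test of the factor's coefficients: returns (F, p)."""
        self._check_factor(factor)
        names = list(self.fe_params.index)
        idx = [i for i, nm in enumerate(names) if f"C({factor})" in nm]
        if not idx:
            raise ValueError(f"no coefficients found for factor {factor!r}")
        L = np.zeros((len(idx), len(names)))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
        beta = np.asarray(self.fe_params)
        mid = L @ self.cov_fe @ L.T
        stat = float(beta @ L.T @ np.linalg.solve(mid, L @ beta)) / len(idx)
        p = float(stats.f.sf(stat, len(idx), self.df_resid))
        return stat, p

    def summary(self) -> str:
        """Readable summary: fixed effects, variance components, contrasts."""
        lines = [
            "Linear mixed model (REML), random intercept per "
            f"{self.model.groups}",
            f"formula: {self.model.formula}",
            f"n_obs={len(self.model.data)}, "
            f"groups={self.model.data[self.model.groups].nunique()}, "
            f"df_resid~{self.df_resid:.0f}",
            "",
            "Fixed effects:",
        ]
        bse = np.sqrt(np.diag(self.cov_fe))
        for i, (nm, b) in enumerate(self.fe_params.items()):
            lines.append(f"  {nm:<40s} {b:>10.4f}  (SE {bse[i]:.4f})")
        lines += [
            "",
            f"Variance components: subject {self.subject_var:.5g}, "
            f"residual {self.residual_var:.5g}",
        ]
        for factor in self.model.fixed:
            fstat, p = self.omnibus(factor)
            lines.append(f"Omnibus {factor}: F={fstat:.3f}, p={p:.4f}")
            lines.append(f"Tukey pairwise contrasts [{factor}]:")
            for c in self.contrasts(factor):
                lines.append(
                    f"  {c.level_a} vs {c.level_b}: {c.percent_difference:+.1f}% "
                    f"(95% CI {c.ci_low:.1f}, {c.ci_high:.1f}), "
                    f"p_adj={c.p_adjusted:.4f}"
                )
        return "\n".join(lines)


def fit_mixed_model(
    data: pd.DataFrame,
    outcome_col: str = "value",
    fixed: Sequence[str] = ("timepoint", "fiber_type"),
    interaction: bool = False,
    groups: str = "subject_id",
    reml: bool = True,
) -> RedoxMixedResults:
    """Fit the mixed model (functional front-end to :class:`RedoxMixedModel`)."""
    return RedoxMixedModel(
        data, outcome_col=outcome_col, fixed=fixed, interaction=interaction,
        groups=groups
    ).fit(reml=reml)


def pairwise_contrasts(
    results: RedoxMixedResults, factor: str
) -> list[ContrastResult]:
    """Tukey-adjusted pairwise contrasts of ``factor`` from a fitted model."""
    return results.contrasts(factor)


def exercise_delta(
    data: pd.DataFrame,
    from_tp: str,
    to_tp: str,
    outcome_col: str = "value",
) -> pd.DataFrame:
    """Per-subject, per-fiber-type change: value(to) - value(from).

    Subjects missing either timepoint get a missing delta, never zero.
    """
    if from_tp == to_tp:
        raise ValueError("from and to timepoints must differ")
    sub = data[data.timepoint.isin([from_tp, to_tp])]
    wide = sub.pivot_table(
        index=["subject_id", "fiber_type"],
        columns="timepoint",
        values=outcome_col,
        aggfunc="mean",
        dropna=False,
    )
    for tp in (from_tp, to_tp):
        if tp not in wide.columns:
            wide[tp] = np.nan
    out = wide.reset_index()
    out["delta"] = out[to_tp] - out[from_tp]
    return out[["subject_id", "fiber_type", "delta"]]


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-sided p.

    Pairs with any missing value are dropped; needs >= 3 complete pairs. A
    constant vector leaves the rank correlation undefined: (NaN, NaN) is
    returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: Spearman rho undefined, reported missing")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
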