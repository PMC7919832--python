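"""Context modelling of click density: design construction, collinearity
screening, GLMM fitting helpers, Wald tests, Holm-adjusted pairwise
contrasts, and percent-change effect reporting.

The response is the per-minute click count; ``log(n_individuals)`` enters
as an exposure offset, the number of individuals also enters as a numeric
fixed effect (so its coefficient measures deviation from proportionality),
and date, observation session, and observation (minute) are crossed random
intercepts.  Enrichment is coded as four 0/1 indicators (toys, humans,
humans-and-toys, new object); live-fish minutes are excluded from fitting
because of their small sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import GlmmFit, fit_poisson_glmm

__all__ = [
    "FACTOR_LEVELS",
    "ENRICHMENT_INDICATORS",
    "EffectTest",
    "build_design",
    "vif",
    "overdispersion_ratio",
    "aic_select",
    "wald_test",
    "default_predictor_groups",
    "pairwise_contrasts",
    "holm_adjust",
    "percent_change",
    "fit_context_model",
]

#: Factor vocabularies; the first level of each factor is the reference.
FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "season": ("spring", "summer", "fall", "winter"),
    "time_of_day": ("morning", "noon", "afternoon"),
    "training": ("outside", "during"),
    "grouping": ("together", "separated"),
    "unusual_event": ("none", "pool_cleaning", "noise", "social_event",
                      "other"),
    "visitors": ("none", "few", "many"),
}

ENRICHMENT_INDICATORS = ("toys", "humans", "humans_and_toys", "new_object")


@dataclass
class EffectTest:
    """A Wald chi-squared test of one predictor (group of coefficients)."""

    predictor: str
    chi2: float
    df: int
    p: float
    p_adjusted: float | None = None
    percent_change: float | None = None

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValueError("chi2 must be non-negative")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def build_design(
    counts: pd.DataFrame,
    annotations: pd.DataFrame,
    drop_live_fish: bool = True,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, dict[str, np.ndarray]]:
    """Assemble response, offset, fixed-effect design and grouping factors.

    Factors are reference-level dummy coded (references: spring, morning,
    outside training, together, no event, no visitors); enrichment enters
    through its four indicator columns.  Rows with ``live_fish == 1`` are
    excluded.  Unknown factor levels raise with the offending row's
    ``minute_index``.

    Returns ``(y, offset, X, groups)`` with ``offset = log(n_individuals)``
    and ``groups`` holding date/session/observation label vectors.
    """
    df = annotations.merge(counts, on="minute_index", how="inner")
    if df.isna().any().any():
        raise ValueError("missing values in counts/annotations")
    for factor, levels in FACTOR_LEVELS.items():
        bad = ~df[factor].isin(levels)
        if bad.any():
            row = df.loc[bad, "minute_index"].iloc[0]
            val = df.loc[bad, factor].iloc[0]
            raise ValueError(
                f"unknown level {val!r} for factor {factor!r} at "
                f"minute_index {row}"
            )
    if (df["n_individuals"] < 1).any():
        raise ValueError("n_individuals must be >= 1")
    if drop_live_fish and "live_fish" in df.columns:
        df = df.loc[df["live_fish"] != 1]
    df = df.reset_index(drop=True)

    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    X["n_individuals"] = df["n_individuals"].astype(float)
    for factor, levels in FACTOR_LEVELS.items():
        for level in levels[1:]:
            X[f"{factor}[{level}]"] = (df[factor] == level).astype(float)
    for ind in ENRICHMENT_INDICATORS:
        X[f"enrichment[{ind}]"] = df[ind].astype(float)
    # levels unobserved in this dataset would give identically-zero columns
    empty = [c for c in X.columns
             if c != "intercept" and X[c].abs().sum() == 0]
    X = X.drop(columns=empty)

    y = df["click_count"].to_numpy()
    offset = np.log(df["n_individuals"].to_numpy(dtype=float))
    groups = {
        "date": df["date_id"].to_numpy(),
        "session": df["session_id"].to_numpy(),
        "observation": df["minute_index"].to_numpy(),
    }
    return y, offset, X, groups


def vif(design: pd.DataFrame, threshold: float = 3.0) -> pd.DataFrame:
    """Variance inflation factors, ``VIF_j = 1 / (1 - R^2_j)``.

    Each non-intercept column is regressed (with intercept) on the other
    non-intercept columns.  Exactly collinear columns report ``inf``.
    Returns a table with columns ``column, vif, flagged``.
    """
    cols = [c for c in design.columns if c != "intercept"]
    if len(cols) < 2:
        raise ValueError("need at least two non-intercept columns")
    M = design[cols].to_numpy(dtype=float)
    n = M.shape[0]
    if n <= len(cols):
        raise ValueError("need more rows than columns")
    out = []
    for j, name in enumerate(cols):
        target = M[:, j]
        others = np.column_stack(
            [np.ones(n)] + [M[:, k] for k in range(len(cols)) if k != j])
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        ss_tot = float(np.sum((target - target.mean()) ** 2))
        if ss_tot == 0:
            r2 = 1.0
        else:
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        v = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        out.append({"column": name, "vif": v, "flagged": v > threshold})
    return pd.DataFrame(out)


def overdispersion_ratio(
    response: np.ndarray,
    fitted: np.ndarray,
    n_params: int,
) -> tuple[float, float]:
    """Pearson overdispersion ratio and its chi-squared p-value.

    ``ratio = sum((y - mu)^2 / mu) / (n - n_params)``; under a
    well-specified Poisson model the numerator is ~chi2 with ``n - k``
    degrees of freedom, so ratios near 1 are expected.
    """
    y = np.asarray(response, dtype=float)
    mu = np.asarray(fitted, dtype=float)
    dof = len(y) - n_params
    if dof <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    pearson = float(np.sum((y - mu) ** 2 / mu))
    ratio = pearson / dof
    p = float(stats.chi2.sf(pearson, dof))
    return ratio, p


def aic_select(fits: list[GlmmFit]) -> GlmmFit:
    """The converged fit with the lowest AIC; ties go to fewer parameters."""
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fit to select from")
    return min(converged, key=lambda f: (f.aic, f.n_params))


def default_predictor_groups(X: pd.DataFrame) -> dict[str, list[str]]:
    """Group design columns by predictor for Wald testing."""
    groups: dict[str, list[str]] = {}
    for col in X.columns:
        if col == "intercept":
            continue
        if col == "n_individuals":
            groups.setdefault("n_individuals", []).append(col)
        elif col.startswith("enrichment["):
            groups.setdefault(col[len("enrichment["):-1], []).append(col)
        else:
            factor = col.split("[")[0]
            groups.setdefault(factor, []).append(col)
    return groups


def wald_test(
    fit: GlmmFit,
    predictor_groups: dict[str, list[str]] | None = None,
) -> list[EffectTest]:
    """Wald chi-squared test per predictor group.

    For a group g of coefficients, ``chi2 = beta_g' V_g^{-1} beta_g`` with
    ``df = |g|``.  Single-coefficient groups also report the percent change
    ``100 * (exp(beta) - 1)``.
    """
    if predictor_groups is None:
        X = pd.DataFrame(columns=fit.coef.index)
        predictor_groups = default_predictor_groups(X)
    tests = []
    for name, cols in predictor_groups.items():
        beta = fit.coef[cols].to_numpy()
        V = fit.cov.loc[cols, cols].to_numpy()
        try:
            chi2 = float(beta @ np.linalg.solve(V, beta))
        except np.linalg.LinAlgError:
            raise ValueError(f"singular covariance for predictor group {name!r}")
        df = len(cols)
        p = float(stats.chi2.sf(chi2, df))
        pc = percent_change(float(beta[0])) if df == 1 else None
        tests.append(EffectTest(predictor=name, chi2=chi2, df=df, p=p,
                                percent_change=pc))
    return tests


def holm_adjust(pvalues: list[float]) -> list[float]:
    """Holm (sequential Bonferroni) step-down adjustment.

    The i-th smallest p-value is multiplied by (m - i + 1); running maxima
    enforce monotonicity and results are capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min((m - rank) * p[idx], 1.0)
        running = max(running, val)
        adj[idx] = running
    return adj.tolist()


def percent_change(beta: float) -> float:
    """Percent change in click density per unit of a log-link coefficient."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return 100.0 * float(np.expm1(beta))


def fit_context_model(
    counts: pd.DataFrame,
    annotations: pd.DataFrame,
    random_effects: tuple[str, ...] = ("date", "session", "observation"),
    fix_sd: dict[str, float] | None = None,
    **fit_kwargs,
) -> GlmmFit:
    """Build the design and fit the Poisson GLMM with the given random effects."""
    y, offset, X, groups = build_design(counts, annotations)
    groups = {k: v for k, v in groups.items() if k in random_effects}
    return fit_poisson_glmm(y, X, offset=offset, groups=groups,
                            fix_sd=fix_sd, **fit_kwargs)


def pairwise_contrasts(
    counts: pd.DataFrame,
    annotations: pd.DataFrame,
    factor: str,
    random_effects: tuple[str, ...] = ("date", "session", "observation"),
    reference_fit: GlmmFit | None = None,
    reoptimize: bool = False,
    **fit_kwargs,
) -> tuple[list[EffectTest], list[str]]:
    """Holm-adjusted pairwise level contrasts for a multi-level factor.

    Each level pair is tested by refitting the same model on the subset of
    minutes at one of the two levels, so the pair's dummy coefficient is the
    contrast of interest.  By default the variance components are held at
    the reference fit's estimates during the refits (set ``reoptimize`` to
    re-estimate them per pair).  Pairs whose subset drops a level of any
    other factor are skipped with a warning record.

    Returns ``(tests, warnings)`` with ``p_adjusted`` filled by Holm.
    """
    levels = FACTOR_LEVELS.get(factor)
    if levels is None:
        raise ValueError(f"unknown factor {factor!r}")
    present = [lv for lv in levels
               if (annotations[factor] == lv).any()]
    if len(present) < 3:
        raise ValueError("pairwise contrasts need a factor with >= 3 levels")
    fix = dict(fit_kwargs.pop("fix_sd", None) or {})
    if reference_fit is not None and not reoptimize:
        fix = {name: sd for name, sd in reference_fit.re_sd.items()
               if name in random_effects}
    tests: list[EffectTest] = []
    warn_records: list[str] = []
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            a, b = present[i], present[j]
            mask = annotations[factor].isin([a, b])
            sub_annot = annotations.loc[mask].copy()
            # recode so `a` is the pair's reference level
            order = [lv for lv in FACTOR_LEVELS[factor] if lv in (a, b)]
            if order[0] != a:
                a, b = b, a
            sub_counts = counts[counts["minute_index"].isin(
                sub_annot["minute_index"])]
            try:
                y, offset, X, groups = build_design(sub_counts, sub_annot)
            except ValueError as err:
                warn_records.append(f"{a} vs {b}: {err}")
                continue
            # make `a` the pair's reference: drop its dummy (if it has one)
            # and any column emptied by the subsetting
            keep = [c for c in X.columns
                    if c != f"{factor}[{a}]"
                    and (c == "intercept" or X[c].abs().sum() > 0)]
            dropped_needed = f"{factor}[{b}]" not in keep
            if dropped_needed:
                warn_records.append(
                    f"{a} vs {b}: subset leaves no rows at level {b}")
                continue
            X = X[keep]
            groups = {k: v for k, v in groups.items() if k in random_effects}
            fit = fit_poisson_glmm(y, X, offset=offset, groups=groups,
                                   fix_sd=fix or None, **fit_kwargs)
            col = f"{factor}[{b}]"
            beta = float(fit.coef[col])
            se = float(fit.se[col])
            chi2 = (beta / se) ** 2 if se > 0 else np.inf
            p = float(stats.chi2.sf(chi2, 1))
            tests.append(EffectTest(predictor=f"{factor}: {b} vs {a}",
                                    chi2=float(chi2), df=1, p=p,
                                    percent_change=percent_change(beta)))
    adj = holm_adjust([t.p for t in tests])
    for t, pa in zip(tests, adj):
        t.p_adjusted = pa
    for w in warn_records:
        warnings.warn(w, stacklevel=2)
    return tests, warn_records
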