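"""Peptide-level significance tests for differential HDX-MS.

Two selectable models:

* **linear model** — per common peptide, replicate-level uptake is fit to
  ``D = b0 + b_s*state + b_t*time + b_st*state:time + eps`` with state and
  time as categorical factors; each term is tested with an
  extra-sum-of-squares F test and p-values are adjusted across peptides by
  the Benjamini-Hochberg procedure (step-up ``p* = p * m / i`` with the
  cumulative-minimum monotonicity pass).
* **hybrid test** — a two-pronged rule per peptide-exposure cell: the
  absolute uptake difference must exceed a global threshold derived from
  the pooled per-state variances at a chosen significance level, and a
  Welch's t-test must confirm the difference.

Exposure-0 rows never enter either test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hdxdiff.cluster_io import PEPTIDE_KEY
from hdxdiff.differential import summed_difference

log = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# multiple testing


def benjamini_hochberg(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, in the input order.

    Each raw p at ascending rank ``i`` is scaled to ``p * m / i``; the
    step-up pass (cumulative minimum from the largest rank down) restores
    monotonicity and values are clipped at 1.  ``m`` defaults to the number
    of hypotheses in the list but may be larger.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise StatsError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise StatsError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise StatsError("m must be >= the number of p-values")
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, len(p) + 1)
    scaled = p[order] * m / ranks
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.clip(adjusted, 0.0, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# linear (ANOVA-style) model


@dataclass
class LinearModelFit:
    """Per-peptide fit diagnostics exposed for audit."""
    p_state: float
    p_time: float
    p_interaction: float
    sse_full: float
    df_resid: int
    beta_state: float       # uptake offset of state B vs A (additive fit)
    interaction_dropped: bool


def _dummies(labels: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    levels = np.unique(labels)
    return np.column_stack([(labels == lv).astype(float)
                            for lv in levels[1:]]) if len(levels) > 1 \
        else np.empty((len(labels), 0))


def _sse(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of the design."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def fit_peptide_model(reps: pd.DataFrame) -> LinearModelFit:
    """Fit the categorical state x time model to one peptide's replicate
    uptakes and test each term.

    ``reps`` needs columns ``state``, ``exposure`` and ``uptake`` covering
    two states and >= 2 non-zero exposures (exposure-0 rows are dropped
    here).  Main effects are tested by the extra sum of squares of removing
    the term from the additive model, and the interaction by comparing the
    full against the additive model, all against the full model's residual
    mean square — the classical two-way ANOVA partition on balanced
    designs.

    When the design is saturated (one replicate per cell) the interaction
    is dropped, its p-value reported as NaN, and main effects are tested
    against the additive model's residual.
    """
    d = reps[reps["exposure"] > 0]
    states = np.unique(d["state"])
    times = np.unique(d["exposure"])
    if len(states) < 2:
        raise StatsError("need two states to fit the peptide model")
    if len(times) < 2:
        raise StatsError("insufficient timepoints (need >= 2 non-zero exposures)")

    y = d["uptake"].to_numpy(dtype=float)
    n = len(y)
    S = _dummies(d["state"].to_numpy())
    T = _dummies(d["exposure"].to_numpy())
    ST = np.column_stack([S[:, i] * T[:, j]
                          for i in range(S.shape[1])
                          for j in range(T.shape[1])]) if S.size and T.size \
        else np.empty((n, 0))
    one = np.ones((n, 1))

    X_full = np.hstack([one, S, T, ST])
    X_add = np.hstack([one, S, T])
    X_time = np.hstack([one, T])
    X_state = np.hstack([one, S])

    sse_full, rank_full = _sse(X_full, y)
    sse_add, rank_add = _sse(X_add, y)
    sse_time, rank_time = _sse(X_time, y)
    sse_state, rank_state = _sse(X_state, y)

    df_full = n - rank_full
    interaction_dropped = df_full <= 0
    if interaction_dropped:
        log.warning("saturated interaction design (one replicate per cell); "
                    "falling back to the additive model")
        mse, df_err = sse_add / (n - rank_add), n - rank_add
        p_interaction = np.nan
    else:
        mse, df_err = sse_full / df_full, df_full
        df_int = rank_full - rank_add
        f_int = (sse_add - sse_full) / df_int / mse
        p_interaction = float(stats.f.sf(f_int, df_int, df_err))

    df_s = rank_add - rank_time
    df_t = rank_add - rank_state
    f_state = (sse_time - sse_add) / df_s / mse
    f_time = (sse_state - sse_add) / df_t / mse
    p_state = float(stats.f.sf(f_state, df_s, df_err))
    p_time = float(stats.f.sf(f_time, df_t, df_err))

    beta_add, *_ = np.linalg.lstsq(X_add, y, rcond=None)
    beta_state = float(beta_add[1]) if S.shape[1] else 0.0

    return LinearModelFit(p_state=p_state, p_time=p_time,
                          p_interaction=p_interaction,
                          sse_full=sse_full if not interaction_dropped else sse_add,
                          df_resid=df_err, beta_state=beta_state,
                          interaction_dropped=interaction_dropped)


def linear_model_test(rep_uptake: pd.DataFrame, state_a: str, state_b: str,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Run the linear-model test for every common peptide.

    ``rep_uptake`` is the replicate-level uptake table (post charge-state
    filtering) holding both states.  Raw per-term p-values are adjusted by
    Benjamini-Hochberg separately for the state family and the interaction
    family (m = number of peptides tested); a peptide is significant when
    either adjusted p falls below ``alpha``, with direction taken from the
    sign of its summed uptake difference.
    """
    d = rep_uptake[rep_uptake["state"].isin([state_a, state_b])]
    rows = []
    for key, grp in d.groupby(PEPTIDE_KEY, sort=True):
        if grp[grp["exposure"] > 0]["state"].nunique() < 2:
            continue
        if grp[grp["exposure"] > 0]["exposure"].nunique() < 2:
            continue
        fit = fit_peptide_model(grp)
        sub = grp[grp["exposure"] > 0]
        mean_by_state = sub.groupby("state")["uptake"].mean()
        rows.append(dict(zip(PEPTIDE_KEY, key),
                         p_state=fit.p_state, p_time=fit.p_time,
                         p_interaction=fit.p_interaction,
                         beta_state=fit.beta_state,
                         df_resid=fit.df_resid,
                         sum_delta=float(
                             sub[sub["state"] == state_b].groupby("exposure")["uptake"].mean().sum()
                             - sub[sub["state"] == state_a].groupby("exposure")["uptake"].mean().sum()),
                         mean_delta=float(mean_by_state.get(state_b, np.nan)
                                          - mean_by_state.get(state_a, np.nan))))
    if not rows:
        raise StatsError("no peptide had both states and >= 2 timepoints")
    res = pd.DataFrame(rows)
    res["q_state"] = benjamini_hochberg(res["p_state"].to_numpy())
    has_int = res["p_interaction"].notna()
    q_int = np.full(len(res), np.nan)
    if has_int.any():
        q_int[has_int.to_numpy()] = benjamini_hochberg(
            res.loc[has_int, "p_interaction"].to_numpy())
    res["q_interaction"] = q_int
    return classify_linear(res, alpha)


def classify_linear(results: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Apply the significance rule and direction call to fitted peptides.

    significant <=> ``q_state < alpha`` or ``q_interaction < alpha``;
    direction is deprotected for a positive summed uptake difference,
    protected for a negative one, none when not significant.
    """
    res = results.copy()
    q_int = res["q_interaction"].fillna(np.inf)
    res["significant"] = (res["q_state"] < alpha) | (q_int < alpha)
    res["direction"] = np.where(
        ~res["significant"], "none",
        np.where(res["sum_delta"] > 0, "deprotected", "protected"))
    res.attrs["alpha"] = alpha
    return res


# ---------------------------------------------------------------------------
# hybrid test: global threshold + Welch


def global_threshold(differentials: pd.DataFrame, alpha: float = 0.05) -> float:
    """Global |delta_d| critical value from pooled per-state variances.

    Pooled variance per state is the mean of the per-cell variances
    (``sd^2``) across all peptide-exposure cells; with modal replicate
    counts ``n_a``, ``n_b`` the threshold is
    ``t_{1-alpha/2, n_a+n_b-2} * sqrt(pooled_a/n_a + pooled_b/n_b)``.
    """
    d = differentials[~differentials["exposure_zero"]]
    d = d[(d["n_a"] >= 2) & (d["n_b"] >= 2)]
    if len(d) < 2:
        raise StatsError("need >= 2 peptide-exposure cells with n >= 2 "
                         "replicates in both states")
    pooled_a = float((d["sd_a"] ** 2).mean())
    pooled_b = float((d["sd_b"] ** 2).mean())
    if pooled_a <= 0 or pooled_b <= 0:
        log.warning("a state has all-zero variance; threshold degenerates to 0")
        return 0.0
    n_a = int(d["n_a"].mode().iloc[0])
    n_b = int(d["n_b"].mode().iloc[0])
    df = n_a + n_b - 2
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    return float(t_crit * np.sqrt(pooled_a / n_a + pooled_b / n_b))


def welch_t_test(d_a: float, sd_a: float, n_a: int,
                 d_b: float, sd_b: float, n_b: int
                 ) -> tuple[float, float, float]:
    """Welch's two-sample t-test from summary statistics.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom and
    a two-sided p-value.  Both SDs zero is degenerate: p is 0 if the means
    differ, else 1.
    """
    if n_a < 2 or n_b < 2:
        raise StatsError("welch_t_test needs n >= 2 in both states")
    if sd_a < 0 or sd_b < 0:
        raise StatsError("standard deviations must be non-negative")
    va, vb = sd_a ** 2 / n_a, sd_b ** 2 / n_b
    if va + vb == 0:
        log.warning("degenerate Welch test: both variances zero")
        if d_a == d_b:
            return 0.0, float(n_a + n_b - 2), 1.0
        return np.inf if d_b > d_a else -np.inf, float(n_a + n_b - 2), 0.0
    t = (d_b - d_a) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (n_a - 1) + vb ** 2 / (n_b - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def hybrid_classify(differentials: pd.DataFrame, alpha: float = 0.05,
                    per_exposure_threshold: bool = False) -> pd.DataFrame:
    """Two-pronged hybrid significance test per peptide-exposure cell.

    A cell is significant when ``|delta_d|`` exceeds the global threshold
    AND the Welch p-value is below ``alpha``; a peptide is rolled up as
    significant when any of its exposures passes.  The threshold is global
    across exposures by default; ``per_exposure_threshold`` computes one
    per timepoint instead.
    """
    d = differentials[~differentials["exposure_zero"]].copy()
    if per_exposure_threshold:
        thr = {e: global_threshold(differentials[differentials["exposure"] == e]
                                   .assign(exposure_zero=False), alpha)
               for e in d["exposure"].unique()}
        d["threshold"] = d["exposure"].map(thr)
    else:
        d["threshold"] = global_threshold(differentials, alpha)

    welch = [welch_t_test(r.d_a, r.sd_a, int(r.n_a), r.d_b, r.sd_b, int(r.n_b))
             if r.n_a >= 2 and r.n_b >= 2 else (np.nan, np.nan, np.nan)
             for r in d.itertuples()]
    d[["t_stat", "df", "p_value"]] = pd.DataFrame(welch, index=d.index)
    untestable = d["p_value"].isna()
    if untestable.any():
        log.warning("%d peptide-exposure cells have < 2 replicates in a "
                    "state and cannot be Welch-tested", int(untestable.sum()))
    d["significant"] = (d["delta_d"].abs() > d["threshold"]) \
        & (d["p_value"] < alpha)
    d["direction"] = np.where(~d["significant"], "none",
                              np.where(d["delta_d"] > 0, "deprotected",
                                       "protected"))
    d.attrs["alpha"] = alpha
    return d.reset_index(drop=True)


def hybrid_peptide_rollup(hybrid_results: pd.DataFrame) -> pd.DataFrame:
    """Peptide-level summary of hybrid cells: significant if any exposure
    passed; direction is the consensus of significant cells (mixed when
    both signs occur)."""
    rows = []
    for key, grp in hybrid_results.groupby(PEPTIDE_KEY, sort=True):
        sig = grp[grp["significant"]]
        if sig.empty:
            direction = "none"
        else:
            dirs = set(sig["direction"])
            direction = dirs.pop() if len(dirs) == 1 else "mixed"
        rows.append(dict(zip(PEPTIDE_KEY, key),
                         significant=not direction == "none",
                         direction=direction,
                         min_p=float(grp["p_value"].min()),
                         max_abs_delta=float(grp["delta_d"].abs().max()),
                         sum_delta=float(grp["delta_d"].sum())))
    return pd.DataFrame(rows)


def attach_summed_deltas(results: pd.DataFrame,
                         differentials: pd.DataFrame) -> pd.DataFrame:
    """Replace model-internal summed deltas with the differential module's
    summed_difference values (aggregated uptake scale)."""
    sums = summed_difference(differentials)[PEPTIDE_KEY + ["sum_delta", "se_sum"]]
    out = results.drop(columns=[c for c in ("sum_delta", "se_sum")
                                if c in results], errors="ignore")
    return out.merge(sums, on=PEPTIDE_KEY, how="left")
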