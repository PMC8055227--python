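"""Cross-state uptake differences for peptides common to two states.

Sign convention: ``delta_d = d_B - d_A`` where A is the user-designated
reference state, so a positive difference means more uptake in state B
(deprotection upon the A -> B change).  Peptide identity is
(start, end, sequence, modification) — charge-agnostic, matching the
aggregation upstream.  Exposures are matched exactly after rounding to six
decimals; exposure-0 rows are carried through flagged but are excluded
from downstream statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from hdxdiff.cluster_io import PEPTIDE_KEY

log = logging.getLogger(__name__)


class DifferentialError(ValueError):
    pass


def _canonical_exposure(e: pd.Series) -> pd.Series:
    return e.round(6)


def match_common_peptides(state_a: pd.DataFrame, state_b: pd.DataFrame
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Peptide keys present in both states with >= 1 shared non-zero exposure.

    Parameters are PeptideUptake tables (one state each).  Returns
    ``(common, only_a, only_b)`` as DataFrames of unique peptide keys.
    Raises if the intersection is empty.
    """
    def keys_with_exposures(df):
        d = df[df["exposure"] > 0].copy()
        d["exposure"] = _canonical_exposure(d["exposure"])
        return d.groupby(PEPTIDE_KEY)["exposure"].agg(set)

    ex_a = keys_with_exposures(state_a)
    ex_b = keys_with_exposures(state_b)
    shared = [k for k in ex_a.index.intersection(ex_b.index)
              if ex_a[k] & ex_b[k]]
    all_a = state_a[PEPTIDE_KEY].drop_duplicates()
    all_b = state_b[PEPTIDE_KEY].drop_duplicates()
    common = pd.DataFrame(shared, columns=PEPTIDE_KEY).sort_values(
        PEPTIDE_KEY).reset_index(drop=True)
    if common.empty:
        raise DifferentialError(
            f"no common peptides: state A has {len(all_a)}, "
            f"state B has {len(all_b)}, shared with a common non-zero "
            "exposure: 0")
    merged_a = all_a.merge(common, how="left", indicator=True)
    only_a = merged_a[merged_a["_merge"] == "left_only"][PEPTIDE_KEY]
    merged_b = all_b.merge(common, how="left", indicator=True)
    only_b = merged_b[merged_b["_merge"] == "left_only"][PEPTIDE_KEY]
    return common, only_a.reset_index(drop=True), only_b.reset_index(drop=True)


def uptake_difference(state_a: pd.DataFrame, state_b: pd.DataFrame,
                      keys: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-peptide, per-exposure uptake differences with propagated SE.

    ``delta_d = d_b - d_a`` and ``se_delta = sqrt(sd_a^2/n_a + sd_b^2/n_b)``.
    Exposures present in only one state are skipped and logged.  The
    returned table has one row per (peptide key, shared exposure) with
    columns ``d_a, d_b, delta_d, se_delta, sd_a, sd_b, n_a, n_b`` and an
    ``exposure_zero`` flag.
    """
    if keys is None:
        keys, _, _ = match_common_peptides(state_a, state_b)

    def prep(df, suffix):
        d = df.copy()
        d["exposure"] = _canonical_exposure(d["exposure"])
        d = d.merge(keys, on=PEPTIDE_KEY)
        cols = {"d_mean": f"d_{suffix}", "d_sd": f"sd_{suffix}",
                "n_rep": f"n_{suffix}"}
        return d[PEPTIDE_KEY + ["exposure"] + list(cols)].rename(columns=cols)

    a = prep(state_a, "a")
    b = prep(state_b, "b")
    merged = a.merge(b, on=PEPTIDE_KEY + ["exposure"], how="outer",
                     indicator=True)
    unmatched = merged["_merge"] != "both"
    if unmatched.any():
        log.info("skipped %d peptide-exposure cells present in only one state",
                 int(unmatched.sum()))
    out = merged[~unmatched].drop(columns="_merge").copy()
    out["delta_d"] = out["d_b"] - out["d_a"]
    out["se_delta"] = np.sqrt(out["sd_a"] ** 2 / out["n_a"]
                              + out["sd_b"] ** 2 / out["n_b"])
    out["exposure_zero"] = out["exposure"] == 0
    return out.sort_values(PEPTIDE_KEY + ["exposure"]).reset_index(drop=True)


def summed_difference(records: pd.DataFrame) -> pd.DataFrame:
    """Per-peptide sum of delta_d over non-zero exposures.

    ``se_sum = sqrt(sum se_delta^2)`` (independent-timepoint quadrature).
    Returns one row per peptide key with ``sum_delta`` and ``se_sum``.
    """
    d = records[~records["exposure_zero"]]
    if d.empty:
        raise DifferentialError("no non-zero-exposure differential records")
    grouped = d.groupby(PEPTIDE_KEY, sort=True)
    out = grouped.agg(sum_delta=("delta_d", "sum"),
                      n_exposures=("exposure", "nunique"))
    out["se_sum"] = grouped["se_delta"].apply(
        lambda s: float(np.sqrt((s ** 2).sum())))
    return out.reset_index()
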