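"""From centroid m/z to per-peptide deuterium uptake.

The chain is: deconvolute each centroid to a neutral mass, subtract the
intensity-weighted exposure-0 reference mass of the peptide/state group to
get per-replicate uptake, drop redundant or poor-quality charge states,
aggregate replicate rows to an intensity-weighted mean and standard
deviation per (peptide, state, exposure), and optionally rescale with a
back-exchange correction factor derived from a maximally-labelled control
state.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from hdxdiff.cluster_io import Dataset, PEPTIDE_KEY

log = logging.getLogger(__name__)

PROTON_MASS = 1.00727646688  # Da

GROUP_KEY = ["protein", "state"] + PEPTIDE_KEY        # one peptide in one state
CELL_KEY = GROUP_KEY + ["exposure"]                   # ... at one timepoint


class UptakeError(ValueError):
    """Raised when uptake cannot be computed (e.g. no exposure-0 reference)."""


def neutral_mass(center, charge):
    """Neutral (uncharged) mass in Da from a centroid m/z and charge.

    ``M = (m/z - m_proton) * z`` with ``m_proton = 1.00727646688`` Da.
    Accepts scalars or arrays.
    """
    center = np.asarray(center, dtype=float)
    charge = np.asarray(charge, dtype=float)
    if np.any(center <= 0) or np.any(charge < 1):
        raise UptakeError("center must be > 0 and charge >= 1")
    result = (center - PROTON_MASS) * charge
    return float(result) if result.ndim == 0 else result


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    total = weights.sum()
    if total <= 0:
        return float(np.mean(values))
    return float((values * weights).sum() / total)


def replicate_uptake(records: pd.DataFrame,
                     reference_mass: float | None = None) -> pd.DataFrame:
    """Per-row deuterium uptake for one (protein, state, peptide) group.

    The reference mass is the intensity-weighted mean neutral mass over all
    exposure-0 rows of the group (so exposure-0 uptakes are centred on 0);
    each row's uptake is its neutral mass minus the reference.

    Parameters
    ----------
    records : DataFrame
        Cluster records of a single peptide in a single state.
    reference_mass : float, optional
        Externally supplied reference (e.g. a cross-state pooled reference)
        used when the group itself has no exposure-0 rows.

    Returns
    -------
    DataFrame with added ``neutral_mass`` and ``uptake`` columns.
    """
    out = records.copy()
    out["neutral_mass"] = neutral_mass(out["center"].to_numpy(),
                                       out["charge"].to_numpy())
    zero = out["exposure"] == 0
    if zero.any():
        ref = _weighted_mean(out.loc[zero, "neutral_mass"].to_numpy(),
                             out.loc[zero, "intensity"].to_numpy(dtype=float))
    elif reference_mass is not None:
        ref = float(reference_mass)
    else:
        key = out.iloc[0]
        raise UptakeError(
            "no exposure-0 reference for "
            f"{key['protein']}/{key['state']}/{key['sequence']} and no "
            "fallback reference supplied")
    out["uptake"] = out["neutral_mass"] - ref
    return out


def compute_replicate_uptake(dataset: Dataset,
                             cross_state_reference: bool = False,
                             on_missing_reference: str = "error") -> pd.DataFrame:
    """Replicate-level uptake for every (protein, state, peptide) group.

    Parameters
    ----------
    dataset : Dataset
        Parsed cluster records.
    cross_state_reference : bool
        When a group has no exposure-0 rows, fall back to the pooled
        exposure-0 reference of the same peptide across all states of the
        protein (off by default: references are within-state, matching the
        DynamX grouping).
    on_missing_reference : {"error", "skip"}
        What to do when no reference exists at all.
    """
    df = dataset.records
    pooled_ref: dict[tuple, float] = {}
    if cross_state_reference:
        zero = df[df["exposure"] == 0]
        for key, grp in zero.groupby(["protein"] + PEPTIDE_KEY, sort=False):
            nm = neutral_mass(grp["center"].to_numpy(), grp["charge"].to_numpy())
            pooled_ref[key] = _weighted_mean(
                np.atleast_1d(nm), grp["intensity"].to_numpy(dtype=float))

    pieces = []
    for key, grp in df.groupby(GROUP_KEY, sort=False):
        ref = pooled_ref.get((key[0],) + tuple(key[2:]))
        try:
            pieces.append(replicate_uptake(grp, reference_mass=ref))
        except UptakeError:
            if on_missing_reference == "skip":
                log.warning("skipping group without reference: %s", key)
                continue
            raise
    if not pieces:
        raise UptakeError("no peptide group had a usable exposure-0 reference")
    return pd.concat(pieces, ignore_index=True)


def filter_charge_states(reps: pd.DataFrame,
                         k_sigma: float = 3.0,
                         min_intensity_frac: float = 0.01
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop redundant / poor-quality charge-state rows.

    Within each (peptide, state, exposure) cell two rules apply, iterated
    to a fixed point so the filter is idempotent:

    * intensity floor — rows carrying less than ``min_intensity_frac`` of
      the cell's summed intensity;
    * robust outlier — rows whose uptake deviates from the cell's
      intensity-weighted median by more than ``k_sigma`` times the robust
      SD (1.4826 x median absolute deviation).

    The last remaining row of a cell is never dropped.

    Returns
    -------
    (kept, dropped) : two DataFrames; `dropped` has a ``drop_reason`` column.
    """
    kept_parts, dropped_parts = [], []
    for _, cell in reps.groupby(CELL_KEY, sort=False):
        cur = cell
        reasons = {}
        while len(cur) > 1:
            inten = cur["intensity"].to_numpy(dtype=float)
            uptake = cur["uptake"].to_numpy(dtype=float)
            low = inten < min_intensity_frac * inten.sum()
            med = _weighted_median(uptake, inten)
            mad = np.median(np.abs(uptake - med))
            robust_sd = 1.4826 * mad
            out = (np.abs(uptake - med) > k_sigma * robust_sd) if robust_sd > 0 \
                else np.zeros(len(cur), dtype=bool)
            drop = low | out
            if not drop.any():
                break
            if drop.all():  # never empty a cell: keep the strongest row
                keep_idx = int(np.argmax(inten))
                drop[keep_idx] = False
                if not drop.any():
                    break
            for idx, is_low, is_out in zip(cur.index, low, out):
                if is_low and idx not in reasons:
                    reasons[idx] = "low_intensity"
                elif is_out and idx not in reasons:
                    reasons[idx] = "outlier"
            cur = cur.loc[~drop]
        kept_parts.append(cur)
        dropped = cell.loc[[i for i in cell.index if i not in cur.index]].copy()
        if len(dropped):
            dropped["drop_reason"] = [reasons.get(i, "outlier") for i in dropped.index]
            dropped_parts.append(dropped)
    kept = pd.concat(kept_parts) if kept_parts else reps.iloc[0:0]
    dropped = (pd.concat(dropped_parts) if dropped_parts
               else reps.iloc[0:0].assign(drop_reason=pd.Series(dtype=str)))
    return kept.reset_index(drop=True), dropped.reset_index(drop=True)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    if w.sum() <= 0:
        return float(np.median(values))
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * w.sum())])


def weighted_aggregate(reps: pd.DataFrame) -> dict:
    """Intensity-weighted mean uptake and SD for one (peptide, state,
    exposure) cell of replicate rows.

    ``d_mean = sum(I_i D_i) / sum(I_i)``;
    ``d_sd = sqrt( sum I_i (D_i - d_mean)^2 / sum I_i * n/(n-1) )`` with the
    small-sample factor applied when the cell holds ``n >= 2`` distinct raw
    files (charge states of one injection are not independent replicates);
    a single-replicate cell gets ``d_sd = 0`` and is flagged.

    All-zero intensities fall back to unweighted statistics with a warning.
    """
    uptake = reps["uptake"].to_numpy(dtype=float)
    inten = reps["intensity"].to_numpy(dtype=float)
    n_rep = int(reps["raw_file"].nunique())
    if inten.sum() <= 0:
        log.warning("all intensities zero; falling back to unweighted mean/SD")
        inten = np.ones_like(inten)
    d_mean = _weighted_mean(uptake, inten)
    if n_rep >= 2:
        var = ((inten * (uptake - d_mean) ** 2).sum() / inten.sum()
               * n_rep / (n_rep - 1))
        d_sd = float(np.sqrt(var))
        single = False
    else:
        d_sd = 0.0
        single = True
    return {"d_mean": d_mean, "d_sd": d_sd, "n_rep": n_rep,
            "single_replicate": single}


def aggregate_uptake(rep_uptake: pd.DataFrame) -> pd.DataFrame:
    """Aggregate replicate-level uptake to one row per (protein, peptide,
    state, exposure): the PeptideUptake table.

    Columns: the peptide key, ``max_uptake``, ``state``, ``exposure``,
    ``d_mean``, ``d_sd``, ``n_rep``, ``single_replicate``, plus
    ``corrected`` / ``correction_factor`` placeholders filled by
    :func:`back_exchange_correct`.
    """
    rows = []
    for key, cell in rep_uptake.groupby(CELL_KEY, sort=True):
        agg = weighted_aggregate(cell)
        rows.append(dict(zip(CELL_KEY, key),
                         max_uptake=float(cell["max_uptake"].iloc[0]),
                         **agg))
    out = pd.DataFrame(rows)
    out["corrected"] = False
    out["correction_factor"] = np.nan
    return out


def back_exchange_correct(uptakes: pd.DataFrame,
                          control_state: str,
                          deuterium_fraction: float = 0.9
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rescale uptake using a maximally-labelled control state.

    For each peptide the control's mean uptake at its largest exposure,
    ``d_max_obs``, estimates the recoverable label; the scalar correction
    factor is ``max_uptake * deuterium_fraction / d_max_obs`` and both
    ``d_mean`` and ``d_sd`` of every analysis state are multiplied by it.
    The per-peptide back-exchange percentage
    ``100 * (1 - d_max_obs / (max_uptake * deuterium_fraction))`` is
    returned for the data-quality summary.

    Peptides missing from the control, or with ``d_max_obs <= 0``
    (uncorrectable), pass through unchanged and flagged.

    Returns
    -------
    (corrected, backexchange) : the corrected PeptideUptake table with the
    control state removed, and a per-peptide back-exchange table.
    """
    if not 0 < deuterium_fraction <= 1:
        raise UptakeError("deuterium_fraction must be in (0, 1]")
    if control_state not in set(uptakes["state"]):
        raise UptakeError(f"control state {control_state!r} not in data; "
                          f"states: {sorted(set(uptakes['state']))}")

    control = uptakes[(uptakes["state"] == control_state)
                      & (uptakes["exposure"] > 0)]
    factors = {}
    bx_rows = []
    pep_key = ["protein"] + PEPTIDE_KEY
    for key, grp in control.groupby(pep_key, sort=True):
        top = grp.loc[grp["exposure"].idxmax()]
        d_max_obs = float(top["d_mean"])
        d_theo = float(top["max_uptake"]) * deuterium_fraction
        row = dict(zip(pep_key, key), d_max_obs=d_max_obs,
                   max_theoretical=d_theo)
        if d_max_obs <= 0 or d_theo <= 0:
            row.update(correction_factor=np.nan, back_exchange_pct=np.nan,
                       status="uncorrectable")
        else:
            factor = d_theo / d_max_obs
            if factor > 5 or factor < 1:
                log.warning("correction factor %.3g for %s outside [1, 5]",
                            factor, key)
            row.update(correction_factor=factor,
                       back_exchange_pct=100.0 * (1.0 - d_max_obs / d_theo),
                       status="ok")
        bx_rows.append(row)
        factors[key] = row["correction_factor"]

    out = uptakes[uptakes["state"] != control_state].copy()
    cf = np.full(len(out), np.nan)
    corrected = np.zeros(len(out), dtype=bool)
    for i, (_, row) in enumerate(out.iterrows()):
        key = tuple(row[c] for c in pep_key)
        f = factors.get(key, np.nan)
        if np.isfinite(f):
            cf[i] = f
            corrected[i] = True
    out.loc[corrected, "d_mean"] *= cf[corrected]
    out.loc[corrected, "d_sd"] *= cf[corrected]
    out["corrected"] = corrected
    out["correction_factor"] = cf
    n_missing = int((~corrected).sum())
    if n_missing:
        log.warning("%d uptake rows passed through uncorrected "
                    "(peptide missing from control or uncorrectable)", n_missing)
    return out.reset_index(drop=True), pd.DataFrame(bx_rows)
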