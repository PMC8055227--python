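"""Data-quality summaries, per-residue tracks and plot tables.

All numerical content lives in plain DataFrames ("plot tables") that are
pure functions of their inputs and export to CSV with fixed float
formatting, so repeated runs are byte-identical; the matplotlib renderings
are thin views over those tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hdxdiff.cluster_io import Dataset, PEPTIDE_KEY

CLASS_COLORS = {"deprotected": "#d7191c",   # red
                "protected": "#2c7bb6",     # blue
                "non-significant": "#9a9a9a",
                "mixed": "#7b3294",
                "none": "#e0e0e0"}

FLOAT_FMT = "%.6f"


class SummaryError(ValueError):
    pass


@dataclass
class ResidueTrack:
    """Per-residue coverage/redundancy vectors over a protein sequence."""
    protein_length: int
    coverage: np.ndarray      # 0/1 per residue (1-based residue r -> index r-1)
    redundancy: np.ndarray    # peptide count per residue

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": np.arange(1, self.protein_length + 1),
                             "coverage": self.coverage,
                             "redundancy": self.redundancy})


def residue_tracks(peptides: pd.DataFrame, protein_length: int) -> ResidueTrack:
    """Coverage and redundancy tracks from peptide spans (1-based inclusive).

    Duplicate peptide keys are counted once.  Spans outside
    ``[1, protein_length]`` are fatal.
    """
    redundancy = np.zeros(protein_length, dtype=int)
    if len(peptides) == 0:
        return ResidueTrack(protein_length, redundancy.copy(), redundancy)
    keys = peptides[PEPTIDE_KEY].drop_duplicates()
    for row in keys.itertuples(index=False):
        if row.start < 1 or row.end > protein_length:
            raise SummaryError(
                f"peptide {row.start}-{row.end} ({row.sequence}) outside "
                f"protein 1-{protein_length}")
        redundancy[row.start - 1:row.end] += 1
    return ResidueTrack(protein_length=protein_length,
                        coverage=(redundancy > 0).astype(int),
                        redundancy=redundancy)


def compare_tracks(track_a: ResidueTrack, track_b: ResidueTrack) -> pd.DataFrame:
    """Per-residue deltas (b - a) of coverage and redundancy."""
    if track_a.protein_length != track_b.protein_length:
        raise SummaryError("protein lengths differ between tracks")
    return pd.DataFrame({
        "residue": np.arange(1, track_a.protein_length + 1),
        "coverage_delta": track_b.coverage - track_a.coverage,
        "redundancy_delta": track_b.redundancy - track_a.redundancy,
    })


@dataclass
class SummaryReport:
    """Data-quality summary in the spirit of community HDX-MS reporting
    guidelines."""
    n_peptides: int
    protein_length: int
    coverage_percent: float
    mean_peptide_length: float
    mean_redundancy: float
    replicates_per_state: dict = field(default_factory=dict)
    exposures: list = field(default_factory=list)
    back_exchange_mean: float | None = None
    back_exchange_min: float | None = None
    back_exchange_max: float | None = None
    test_model: str | None = None
    alpha: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [("peptides", self.n_peptides),
                ("protein length (residues)", self.protein_length),
                ("sequence coverage (%)", round(self.coverage_percent, 2)),
                ("mean peptide length", round(self.mean_peptide_length, 2)),
                ("mean redundancy", round(self.mean_redundancy, 2)),
                ("exposures (min)", ", ".join(f"{e:g}" for e in self.exposures))]
        for state, n in sorted(self.replicates_per_state.items()):
            rows.append((f"replicates [{state}]", n))
        if self.back_exchange_mean is not None:
            rows.append(("back exchange mean (%)", round(self.back_exchange_mean, 1)))
            rows.append(("back exchange min (%)", round(self.back_exchange_min, 1)))
            rows.append(("back exchange max (%)", round(self.back_exchange_max, 1)))
        if self.test_model is not None:
            rows.append(("statistical model", self.test_model))
            rows.append(("significance level", self.alpha))
        return pd.DataFrame(rows, columns=["quantity", "value"])

    def to_markdown(self) -> str:
        df = self.to_frame()
        width = max(len(str(q)) for q in df["quantity"])
        lines = [f"| {'quantity'.ljust(width)} | value |",
                 f"|{'-' * (width + 2)}|-------|"]
        lines += [f"| {str(q).ljust(width)} | {v} |"
                  for q, v in df.itertuples(index=False)]
        return "\n".join(lines)


def summarize(dataset: Dataset, uptakes: pd.DataFrame,
              protein_length: int | None = None,
              back_exchange: pd.DataFrame | None = None,
              test_model: str | None = None,
              alpha: float | None = None) -> SummaryReport:
    """Assemble the data-quality report for one protein's dataset.

    ``protein_length`` defaults to the maximum peptide end observed (real
    constructs may have uncovered termini — override when known).
    """
    recs = dataset.records
    peptides = recs[PEPTIDE_KEY].drop_duplicates()
    if protein_length is None:
        protein_length = int(recs["end"].max())
    track = residue_tracks(peptides, protein_length)
    lengths = peptides["end"] - peptides["start"] + 1
    covered = track.coverage.sum()
    reps = {state: int(grp["raw_file"].nunique())
            for state, grp in recs.groupby("state")}
    report = SummaryReport(
        n_peptides=len(peptides),
        protein_length=protein_length,
        coverage_percent=100.0 * covered / protein_length,
        mean_peptide_length=float(lengths.mean()),
        mean_redundancy=float(track.redundancy[track.coverage > 0].mean())
        if covered else 0.0,
        replicates_per_state=reps,
        exposures=sorted(recs["exposure"].unique()),
        test_model=test_model, alpha=alpha)
    if back_exchange is not None and "back_exchange_pct" in back_exchange:
        bx = back_exchange["back_exchange_pct"].dropna()
        if len(bx):
            report.back_exchange_mean = float(bx.mean())
            report.back_exchange_min = float(bx.min())
            report.back_exchange_max = float(bx.max())
    return report


# ---------------------------------------------------------------------------
# plot tables


def _classify_rows(df: pd.DataFrame) -> pd.Series:
    cls = np.where(~df["significant"], "non-significant",
                   np.where(df["delta_d" if "delta_d" in df else "sum_delta"] > 0,
                            "deprotected", "protected"))
    return pd.Series(cls, index=df.index)


def woods_data(differentials: pd.DataFrame, test_results: pd.DataFrame,
               exposure: float | str) -> pd.DataFrame:
    """Table behind a Woods plot: one horizontal bar per peptide.

    ``exposure`` is a timepoint in minutes or ``"sum"`` for the summed
    view.  Columns: x0 (start), x1 (end), y (delta_d), class, color.
    """
    from hdxdiff.differential import summed_difference

    if exposure == "sum":
        data = summed_difference(differentials).rename(
            columns={"sum_delta": "delta_d"})
    else:
        avail = sorted(differentials.loc[~differentials["exposure_zero"],
                                         "exposure"].unique())
        if exposure not in avail:
            raise SummaryError(
                f"exposure {exposure} not present; available: {avail}")
        data = differentials[differentials["exposure"] == exposure]
    sig = test_results[PEPTIDE_KEY + ["significant"]].drop_duplicates(PEPTIDE_KEY)
    merged = data.merge(sig, on=PEPTIDE_KEY, how="left")
    merged["significant"] = merged["significant"].fillna(False).astype(bool)
    merged["class"] = _classify_rows(merged)
    merged["color"] = merged["class"].map(CLASS_COLORS)
    out = merged.rename(columns={"start": "x0", "end": "x1",
                                 "delta_d": "y"})
    cols = ["x0", "x1", "sequence", "modification", "y", "class", "color"]
    return out[cols].sort_values(["x0", "x1", "sequence"]).reset_index(drop=True)


def volcano_data(differentials: pd.DataFrame, test_results: pd.DataFrame,
                 model: str = "linear", alpha: float = 0.05,
                 y_cap: float = 16.0) -> pd.DataFrame:
    """Table behind a volcano plot: uptake difference vs -log10 p.

    For the linear model, x is the per-peptide summed delta and y is
    ``-log10`` of the smaller adjusted p-value (state or interaction
    family); for the hybrid model one point per peptide-exposure cell with
    the Welch p-value.  Zero p-values are capped at ``y_cap`` and flagged.
    Guide-line values (alpha line and, for hybrid, the +/- threshold) are
    stored in ``.attrs["guides"]``.
    """
    if model == "linear":
        res = test_results.copy()
        q = np.fmin(res["q_state"],
                    res["q_interaction"].fillna(np.inf)).astype(float)
        out = res[PEPTIDE_KEY].copy()
        out["delta_d"] = res["sum_delta"].to_numpy()
        out["p_plot"] = q
        out["significant"] = res["significant"].to_numpy()
        guides = {"alpha": alpha}
    elif model == "hybrid":
        res = test_results.copy()
        out = res[PEPTIDE_KEY + ["exposure"]].copy()
        out["delta_d"] = res["delta_d"].to_numpy()
        out["p_plot"] = res["p_value"].to_numpy()
        out["significant"] = res["significant"].to_numpy()
        guides = {"alpha": alpha,
                  "threshold": float(res["threshold"].iloc[0])
                  if len(res) else np.nan}
    else:
        raise SummaryError(f"unknown model {model!r}")
    with np.errstate(divide="ignore"):
        y = -np.log10(out["p_plot"].to_numpy(dtype=float))
    out["capped"] = ~np.isfinite(y) | (y > y_cap)
    out["neg_log10_p"] = np.where(out["capped"], y_cap, y)
    out["class"] = _classify_rows(out)
    out["color"] = out["class"].map(CLASS_COLORS)
    out = out.sort_values(list(out.columns[:4])).reset_index(drop=True)
    out.attrs["guides"] = guides
    return out


def barcode_data(test_results: pd.DataFrame, protein_length: int,
                 exposures: list[float] | None = None) -> pd.DataFrame:
    """Residue x exposure significance-consensus matrix.

    Per residue and exposure: ``deprotected`` when every significant
    covering peptide has a positive uptake difference, ``protected`` when
    all are negative, ``mixed`` otherwise, ``none`` when no significant
    peptide covers the residue.  ``test_results`` is a hybrid per-cell
    table; a linear-model table (no exposure column) yields a single
    "sum" column.
    """
    res = test_results.copy()
    if "exposure" not in res.columns:
        res["exposure"] = "sum"
        delta_col = "sum_delta"
    else:
        delta_col = "delta_d"
    if exposures is None:
        exposures = sorted(res["exposure"].unique(), key=str)
    mat = pd.DataFrame("none", index=np.arange(1, protein_length + 1),
                       columns=exposures)
    mat.index.name = "residue"
    for exp in exposures:
        sub = res[(res["exposure"] == exp) & res["significant"]]
        pos = np.zeros(protein_length, dtype=int)
        neg = np.zeros(protein_length, dtype=int)
        for row in sub.itertuples(index=False):
            lo, hi = int(row.start) - 1, int(row.end)
            if getattr(row, delta_col) > 0:
                pos[lo:hi] += 1
            else:
                neg[lo:hi] += 1
        col = np.where((pos > 0) & (neg == 0), "deprotected",
                       np.where((neg > 0) & (pos == 0), "protected",
                                np.where((pos > 0) & (neg > 0), "mixed",
                                         "none")))
        mat[exp] = col
    return mat


def write_table(df: pd.DataFrame, path) -> None:
    """CSV export with fixed float formatting (byte-stable across runs)."""
    df.to_csv(path, index=isinstance(df.index, pd.Index)
              and df.index.name is not None,
              float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# static renderings (smoke-testable; numbers live in the tables above)


def plot_woods(table: pd.DataFrame, path, title: str = "Woods plot") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for row in table.itertuples(index=False):
        ax.hlines(row.y, row.x0, row.x1, colors=row.color, linewidth=2.5)
    ax.axhline(0, color="black", linewidth=0.6)
    ax.set_xlabel("residue")
    ax.set_ylabel(r"$\Delta D$ (Da)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_volcano(table: pd.DataFrame, path, title: str = "Volcano plot") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.5))
    ax.scatter(table["delta_d"], table["neg_log10_p"],
               c=table["color"], s=14, edgecolors="none")
    guides = table.attrs.get("guides", {})
    if "alpha" in guides:
        ax.axhline(-np.log10(guides["alpha"]), color="black",
                   linestyle=":", linewidth=0.8)
    if "threshold" in guides and np.isfinite(guides.get("threshold", np.nan)):
        ax.axvline(guides["threshold"], color="black", linestyle=":",
                   linewidth=0.8)
        ax.axvline(-guides["threshold"], color="black", linestyle=":",
                   linewidth=0.8)
    ax.set_xlabel(r"$\Delta D$ (Da)")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_barcode(matrix: pd.DataFrame, path, title: str = "Barcode plot") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    classes = ["none", "protected", "mixed", "deprotected"]
    cmap = ListedColormap([CLASS_COLORS[c] for c in classes])
    coded = matrix.apply(lambda col: col.map({c: i for i, c in
                                              enumerate(classes)})).T
    fig, ax = plt.subplots(figsize=(8, 0.6 + 0.4 * len(coded)))
    ax.imshow(coded.to_numpy(dtype=float), aspect="auto", cmap=cmap,
              vmin=0, vmax=len(classes) - 1, interpolation="nearest")
    ax.set_yticks(range(len(coded)), [str(e) for e in coded.index])
    ax.set_xlabel("residue")
    ax.set_ylabel("exposure (min)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_coverage(track: ResidueTrack, path,
                  title: str = "Coverage and redundancy") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    residues = np.arange(1, track.protein_length + 1)
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.fill_between(residues, track.redundancy, step="mid",
                    color="#2c7bb6", alpha=0.7)
    ax.set_xlabel("residue")
    ax.set_ylabel("redundancy (peptides)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
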