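"""Microarray processing: spatial correction, quantile normalization,
feature summarization, differential-expression testing and DE calling.

The processing order follows standard two-color-free NimbleGen-style
pipelines: correct each hybridization for smooth spatial bias, force all
samples onto a common intensity distribution by quantile normalization,
summarize probes to features on the log2 scale, test each feature with a
two-group one-way ANOVA F-test, adjust p-values by Benjamini-Hochberg, and
call a feature up-regulated when log2FC >= 1 with adjusted p <= 0.05 (down
when log2FC <= -1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from ferrex.stats import bh_adjust, two_group_f_matrix

log = logging.getLogger(__name__)

META_COLS = ["probe", "x", "y", "feature"]

FC_CUTOFF = 1.0
ALPHA = 0.05


class IntensityMatrix:
    """Probe x sample fluorescence with grid coordinates.

    ``frame`` holds the metadata columns ``probe, x, y, feature`` plus one
    positive-valued column per sample; ``conditions`` maps each sample
    column to ``"control"`` or ``"iron"``.
    """

    def __init__(self, frame: pd.DataFrame, conditions: dict[str, str]):
        missing = [c for c in META_COLS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        self.frame = frame.reset_index(drop=True)
        self.conditions = dict(conditions)
        samples = self.sample_columns
        if not samples:
            raise ValueError("no sample columns")
        values = self.frame[samples].to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("missing intensity values")
        if (values <= 0).any():
            raise ValueError("fluorescence values must be > 0")
        counts = pd.Series(list(self.conditions.values())).value_counts()
        if (counts < 2).any() or len(counts) < 2:
            raise ValueError("need >= 2 samples in each of two conditions")

    @property
    def sample_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c in self.conditions]

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.sample_columns if self.conditions[s] == condition]

    def values(self) -> np.ndarray:
        return self.frame[self.sample_columns].to_numpy(dtype=float)

    def replace_values(self, values: np.ndarray) -> "IntensityMatrix":
        frame = self.frame.copy()
        frame[self.sample_columns] = values
        return IntensityMatrix(frame, self.conditions)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, conditions: dict[str, str] | None = None) -> "IntensityMatrix":
        frame = pd.read_csv(path, sep="\t")
        if conditions is None:
            conditions = {
                c: ("iron" if c.startswith("iron") else "control")
                for c in frame.columns
                if c not in META_COLS
            }
        return cls(frame, conditions)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    cutoff = 0.5 * w.sum()
    return float(v[np.searchsorted(cum, cutoff)])


def default_bandwidth(matrix: IntensityMatrix) -> float:
    """10% of the grid diagonal."""
    x = matrix.frame["x"].to_numpy(dtype=float)
    y = matrix.frame["y"].to_numpy(dtype=float)
    diag = float(np.hypot(x.max() - x.min(), y.max() - y.min()))
    return max(0.1 * diag, 1.0)


def spatial_smooth(matrix: IntensityMatrix, bandwidth: float | None = None) -> IntensityMatrix:
    """Global distance-weighted spatial correction.

    Per sample, the local background at each probe is the Gaussian-distance
    weighted median of log2 intensities within 3 bandwidths; the deviation
    of the local background from the array-wide median is subtracted from
    each probe's log2 value, and the result returned on the linear scale.
    """
    if bandwidth is None:
        bandwidth = default_bandwidth(matrix)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    xy = matrix.frame[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    neighbors = tree.query_ball_point(xy, r=3.0 * bandwidth)
    log2v = np.log2(matrix.values())
    corrected = np.empty_like(log2v)
    for j in range(log2v.shape[1]):
        col = log2v[:, j]
        global_med = np.median(col)
        local = np.empty(len(col))
        for i, idx in enumerate(neighbors):
            idx = np.asarray(idx)
            d2 = ((xy[idx] - xy[i]) ** 2).sum(axis=1)
            w = np.exp(-d2 / (2.0 * bandwidth**2))
            local[i] = _weighted_median(col[idx], w)
        corrected[:, j] = col - (local - global_med)
    return matrix.replace_values(np.exp2(corrected))


def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Force every sample column onto the mean-of-sorted-columns distribution.

    Ties within a column receive the mean of the reference values their
    ranks span, so the transform is invariant to row order.
    """
    values = matrix.values()
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return matrix.replace_values(out)


def summarize_features(
    matrix: IntensityMatrix,
    locus_specific: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Per-feature per-sample mean of log2 probe intensities.

    If ``locus_specific`` is given (probe id -> flag), non-specific probes
    are dropped first; features left with zero probes are excluded and
    logged.  Returns a feature x sample DataFrame of log2 values.
    """
    frame = matrix.frame
    if locus_specific is not None:
        keep = frame["probe"].map(locus_specific).fillna(False).astype(bool)
        dropped_features = set(frame.loc[~keep, "feature"]) - set(frame.loc[keep, "feature"])
        if dropped_features:
            log.warning(
                "%d feature(s) excluded: no locus-specific probes (%s...)",
                len(dropped_features), sorted(dropped_features)[:3],
            )
        frame = frame.loc[keep]
    samples = matrix.sample_columns
    log2frame = frame[["feature"]].assign(**{s: np.log2(frame[s]) for s in samples})
    return log2frame.groupby("feature", sort=True)[samples].mean()


def summarize_families(feature_values: pd.DataFrame, family_of: dict[str, str]) -> pd.DataFrame:
    """Roll locus-level log2 values up to TE families (mean over member loci)."""
    members = feature_values.loc[feature_values.index.isin(family_of)]
    fams = members.index.map(family_of)
    return members.groupby(fams).mean()


def de_test(control, iron) -> tuple[float, float, float]:
    """Two-group differential-expression test on log2 replicate values.

    Returns ``(log2fc, F, p)`` where log2FC = mean(iron) - mean(control) on
    the log2 scale and the F-test is the one-way two-group ANOVA (equivalent
    to a two-sided equal-variance t-test).
    """
    control = np.asarray(control, dtype=float)
    iron = np.asarray(iron, dtype=float)
    f, p = two_group_f_matrix(control[None, :], iron[None, :])
    return float(iron.mean() - control.mean()), float(f[0]), float(p[0])


def de_table(feature_values: pd.DataFrame, conditions: dict[str, str], kind: str = "gene") -> pd.DataFrame:
    """DE statistics for every row of a feature x sample log2 matrix.

    Output columns: feature, kind, log2FC, p_raw, p_adj, status.
    """
    control_cols = [s for s in feature_values.columns if conditions[s] == "control"]
    iron_cols = [s for s in feature_values.columns if conditions[s] == "iron"]
    a = feature_values[control_cols].to_numpy(dtype=float)
    b = feature_values[iron_cols].to_numpy(dtype=float)
    f, p = two_group_f_matrix(a, b)
    records = pd.DataFrame(
        {
            "feature": feature_values.index,
            "kind": kind,
            "log2FC": b.mean(axis=1) - a.mean(axis=1),
            "p_raw": p,
        }
    )
    records["p_adj"] = bh_adjust(records["p_raw"].to_numpy())
    return call_de(records)


def call_de(records: pd.DataFrame, fc_cutoff: float = FC_CUTOFF, alpha: float = ALPHA) -> pd.DataFrame:
    """Apply the DE thresholds with boundary inclusion: up iff log2FC >=
    fc_cutoff and p_adj <= alpha; down iff log2FC <= -fc_cutoff and
    p_adj <= alpha; otherwise ns."""
    records = records.copy()
    sig = records["p_adj"] <= alpha
    records["status"] = "ns"
    records.loc[sig & (records["log2FC"] >= fc_cutoff), "status"] = "up"
    records.loc[sig & (records["log2FC"] <= -fc_cutoff), "status"] = "down"
    return records


@dataclass
class DeSummary:
    """Dataset-level DE counts and the percentages derived from them."""

    n_up: int
    n_down: int
    pct_up: float | None  # % of DE features that are up, 1 decimal
    n_de_loci: int | None = None
    n_total_loci: int | None = None
    pct_de_loci: int | None = None  # % of all loci DE, nearest integer
    n_families_de: int | None = None

    def as_dict(self) -> dict:
        return {
            "n_up": self.n_up,
            "n_down": self.n_down,
            "pct_up": self.pct_up,
            "n_de_loci": self.n_de_loci,
            "n_total_loci": self.n_total_loci,
            "pct_de_loci": self.pct_de_loci,
            "n_families_de": self.n_families_de,
        }


def pct_up(n_up: int, n_down: int) -> float | None:
    """Percentage of DE features that are up-regulated, one decimal place."""
    if n_up + n_down == 0:
        return None
    return round(100.0 * n_up / (n_up + n_down), 1)


def pct_of_total(n_de: int, n_total: int) -> int | None:
    """Percentage of all loci that are DE, rounded to the nearest integer."""
    if n_total == 0:
        return None
    return int(round(100.0 * n_de / n_total))


def de_summary(
    gene_records: pd.DataFrame,
    te_records: pd.DataFrame | None = None,
    family_records: pd.DataFrame | None = None,
) -> DeSummary:
    n_up = int((gene_records["status"] == "up").sum())
    n_down = int((gene_records["status"] == "down").sum())
    summary = DeSummary(n_up=n_up, n_down=n_down, pct_up=pct_up(n_up, n_down))
    if te_records is not None:
        de = te_records["status"] != "ns"
        summary.n_de_loci = int(de.sum())
        summary.n_total_loci = int(len(te_records))
        summary.pct_de_loci = pct_of_total(summary.n_de_loci, summary.n_total_loci)
    if family_records is not None:
        summary.n_families_de = int((family_records["status"] != "ns").sum())
    return summary


def family_rollup(te_records: pd.DataFrame, family_of: dict[str, str]) -> pd.DataFrame:
    """Roll locus-level DE calls up to families: a family is DE when at
    least one member locus is DE (up wins over down when both occur)."""
    recs = te_records.assign(family=te_records["feature"].map(family_of))
    rows = []
    for family, grp in recs.groupby("family", sort=True):
        if (grp["status"] == "up").any():
            status = "up"
        elif (grp["status"] == "down").any():
            status = "down"
        else:
            status = "ns"
        rows.append({"feature": family, "kind": "te_family", "status": status,
                     "n_loci": len(grp), "n_loci_de": int((grp["status"] != "ns").sum())})
    return pd.DataFrame(rows)


def normalize(matrix: IntensityMatrix, bandwidth: float | None = None) -> IntensityMatrix:
    """Spatial correction followed by quantile normalization."""
    return quantile_normalize(spatial_smooth(matrix, bandwidth=bandwidth))
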