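"""Half-dataset quality statistics and per-frame triage.

Data quality in serial crystallography is judged on random half
datasets: frames are split uniformly into two halves, each half is
merged independently, and the halves are compared per resolution shell
through

* CC1/2 — Pearson correlation of merged intensities (Friedel mates
  averaged together),
* CCano — Pearson correlation of the anomalous differences
  ΔI = I(+) − I(−) (Friedel mates kept separate),
* Rsplit — (1/√2)·Σ|I_A − I_B| / (Σ(I_A + I_B)/2).

Frame triage: the hit rule (≥ 3 spots at resolution lower than 5 Å),
per-frame ⟨I/σ⟩, descending-⟨I/σ⟩ sorting, rejection-threshold scans and
cumulative-image curves.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .crystal import PointGroup, UnitCell, assign_shells_d, d_spacing, shell_edges, unique_reflections

__all__ = [
    "hit_find",
    "frame_i_over_sigma",
    "frame_table",
    "sort_frames",
    "split_halves",
    "cc_half",
    "cc_ano",
    "r_split",
    "shell_table",
    "resolution_cutoff",
    "cumulative_curve",
    "rejection_scan",
    "ScanResult",
    "MIN_COMMON",
]

#: Correlations over fewer than this many common reflections are
#: reported as missing (NaN), not zero.
MIN_COMMON = 3

HIT_RESOLUTION = 5.0  # Å; spots at lower resolution (larger d) count
HIT_MIN_SPOTS = 3


def hit_find(d_spacings, min_spots: int = HIT_MIN_SPOTS, d_threshold: float = HIT_RESOLUTION) -> bool:
    """Hit rule: at least ``min_spots`` spots at resolution lower than 5 Å.

    "Lower resolution" means larger d-spacing; a frame full of
    high-resolution spots with nothing below 5 Å is not a hit.
    """
    d = np.asarray(d_spacings, dtype=float)
    return int(np.sum(d > d_threshold)) >= min_spots


def frame_i_over_sigma(obs: pd.DataFrame) -> float:
    """Arithmetic mean of I/σ over one frame's observations."""
    if len(obs) == 0:
        raise ValueError("frame has no observations")
    return float(np.mean(obs["intensity"].to_numpy() / obs["sigma"].to_numpy()))


def frame_table(obs: pd.DataFrame) -> pd.DataFrame:
    """Per-frame summary: n_obs and ⟨I/σ⟩, indexed by frame_id."""
    ios = obs["intensity"].to_numpy() / obs["sigma"].to_numpy()
    g = pd.DataFrame({"frame_id": obs["frame_id"].to_numpy(), "ios": ios}).groupby("frame_id")
    out = g.agg(n_obs=("ios", "size"), mean_i_over_sigma=("ios", "mean"))
    return out


def sort_frames(frame_stats: pd.DataFrame) -> np.ndarray:
    """Frame ids ordered by descending ⟨I/σ⟩; ties broken by frame_id."""
    df = frame_stats.reset_index()
    df = df.sort_values(["mean_i_over_sigma", "frame_id"], ascending=[False, True])
    return df["frame_id"].to_numpy()


def split_halves(frame_ids: Sequence, seed: int = 0):
    """Uniformly random split of frames into two near-equal halves."""
    ids = np.asarray(frame_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    half = (len(ids) + 1) // 2
    return ids[perm[:half]], ids[perm[half:]]


def _friedel_mean(merged: pd.DataFrame) -> pd.Series:
    """Average Friedel mates: one intensity per ASU triple."""
    return merged.groupby(["h", "k", "l"])["i_merged"].mean()


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < MIN_COMMON:
        return float("nan")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(sp_stats.pearsonr(a, b)[0])


def cc_half(merged_a: pd.DataFrame, merged_b: pd.DataFrame) -> float:
    """CC1/2: Pearson correlation of Friedel-averaged merged intensities.

    Duplicated noiseless halves give exactly 1.0; fewer than three common
    reflections give NaN.
    """
    a = _friedel_mean(merged_a)
    b = _friedel_mean(merged_b)
    j = pd.concat([a.rename("a"), b.rename("b")], axis=1, join="inner")
    if len(j) >= MIN_COMMON and j["a"].equals(j["b"]):
        return 1.0  # exact identity short-circuits float rounding
    return _pearson(j["a"].to_numpy(), j["b"].to_numpy())


def _anom_diff(merged: pd.DataFrame) -> pd.Series:
    """ΔI = I(+) − I(−) per ASU triple where both mates are present."""
    p = merged.set_index(["h", "k", "l"])
    plus = p[p["friedel"] > 0]["i_merged"]
    minus = p[p["friedel"] < 0]["i_merged"]
    j = pd.concat([plus.rename("p"), minus.rename("m")], axis=1, join="inner")
    return j["p"] - j["m"]


def cc_ano(merged_a: pd.DataFrame, merged_b: pd.DataFrame) -> float:
    """CCano: Pearson correlation of half-set anomalous differences."""
    da = _anom_diff(merged_a)
    db = _anom_diff(merged_b)
    j = pd.concat([da.rename("a"), db.rename("b")], axis=1, join="inner")
    return _pearson(j["a"].to_numpy(), j["b"].to_numpy())


def r_split(merged_a: pd.DataFrame, merged_b: pd.DataFrame) -> float:
    """Rsplit = (1/√2)·Σ|I_A−I_B| / (Σ(I_A+I_B)/2) over common reflections."""
    ka = merged_a.set_index(["h", "k", "l", "friedel"])["i_merged"]
    kb = merged_b.set_index(["h", "k", "l", "friedel"])["i_merged"]
    j = pd.concat([ka.rename("a"), kb.rename("b")], axis=1, join="inner")
    if len(j) == 0:
        return float("nan")
    a, b = j["a"].to_numpy(), j["b"].to_numpy()
    denom = np.sum(a + b) / 2.0
    if denom == 0:
        return float("nan")
    return float(np.sum(np.abs(a - b)) / (np.sqrt(2.0) * denom))


def shell_table(
    merged_a: pd.DataFrame,
    merged_b: pd.DataFrame,
    cell: UnitCell,
    pg: PointGroup,
    n_shells: int = 10,
    d_min: Optional[float] = None,
    d_max: Optional[float] = None,
    merged_all: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-shell half-dataset statistics.

    Shells are equal reciprocal volume between ``d_max`` and ``d_min``
    (defaults: data range).  Multiplicity, ⟨I/σ⟩ and completeness come
    from ``merged_all`` when given (otherwise the union of the halves is
    approximated by half A).  Completeness counts Friedel-collapsed
    unique reflections against the full enumeration for the cell.
    """
    full = merged_all if merged_all is not None else merged_a
    d_full = d_spacing(full[["h", "k", "l"]].to_numpy(), cell)
    if d_min is None:
        d_min = float(d_full.min())
    if d_max is None:
        d_max = float(d_full.max())
    edges = shell_edges(n_shells, d_min, d_max)
    H_ref, _ = unique_reflections(cell, pg, d_min, d_max)
    ref_shell = assign_shells_d(d_spacing(H_ref, cell), n_shells, d_min, d_max)
    n_possible = np.array([(ref_shell == i).sum() for i in range(n_shells)])

    def per_shell(df):
        d = d_spacing(df[["h", "k", "l"]].to_numpy(), cell)
        return assign_shells_d(d, n_shells, d_min, d_max)

    sa = per_shell(merged_a)
    sb = per_shell(merged_b)
    sf = per_shell(full)
    rows = []
    for i in range(n_shells):
        ma, mb = merged_a[sa == i], merged_b[sb == i]
        mf = full[sf == i]
        uniq = mf.groupby(["h", "k", "l"]).size()
        rows.append(
            {
                "shell": i,
                "d_low": edges[i],
                "d_high": edges[i + 1],
                "n_unique": len(uniq),
                "completeness": len(uniq) / n_possible[i] if n_possible[i] else np.nan,
                "multiplicity": float(mf["multiplicity"].mean()) if len(mf) else np.nan,
                "mean_i_over_sigma": float(
                    (mf["i_merged"] / mf["sigma_merged"]).mean()
                ) if len(mf) else np.nan,
                "cc_half": cc_half(ma, mb),
                "cc_ano": cc_ano(ma, mb),
                "r_split": r_split(ma, mb),
            }
        )
    return pd.DataFrame(rows)


def resolution_cutoff(shell_stats: pd.DataFrame, metric: str = "cc_half", threshold: float = 0.5):
    """Resolution limit: d_high of the last shell passing the threshold.

    Walks from low to high resolution and stops at the first shell whose
    metric falls below ``threshold`` (no interpolation).  Returns None
    when the very first shell already fails.
    """
    df = shell_stats.sort_values("d_low", ascending=False)
    limit = None
    for _, row in df.iterrows():
        if np.isnan(row[metric]) or row[metric] < threshold:
            break
        limit = float(row["d_high"])
    return limit


@dataclasses.dataclass
class ScanResult:
    """A 1-D scan of a quality metric against a control axis."""

    axis: np.ndarray
    metric: np.ndarray
    argmax: float

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.axis) != len(self.metric):
            raise ValueError("axis and metric must have equal length")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis must be strictly increasing")


def _finite_argmax(axis: np.ndarray, metric: np.ndarray) -> float:
    m = np.where(np.isfinite(metric), metric, -np.inf)
    if not np.any(np.isfinite(metric)):
        return float("nan")
    return float(axis[int(np.argmax(m))])


def cumulative_curve(
    obs: pd.DataFrame,
    frame_order: Sequence,
    step: int,
    metric_fn: Callable[[pd.DataFrame], float],
) -> ScanResult:
    """Evaluate a metric on the first n frames for n = step, 2·step, …

    ``frame_order`` fixes the accumulation order (e.g. collection order
    or descending ⟨I/σ⟩); the final point always covers all frames.
    """
    order = np.asarray(frame_order)
    counts = list(range(step, len(order), step)) + [len(order)]
    metric = []
    for n in counts:
        sel = obs[obs["frame_id"].isin(order[:n])]
        metric.append(metric_fn(sel))
    metric = np.asarray(metric, dtype=float)
    axis = np.asarray(counts, dtype=float)
    return ScanResult(axis=axis, metric=metric, argmax=_finite_argmax(axis, metric))


def rejection_scan(
    obs: pd.DataFrame,
    frame_stats: pd.DataFrame,
    thresholds: Sequence[float],
    metric_fn: Callable[[pd.DataFrame], float],
) -> ScanResult:
    """Scan the per-frame ⟨I/σ⟩ rejection threshold.

    For each threshold, frames with ⟨I/σ⟩ ≥ threshold are kept, merged by
    ``metric_fn`` and scored; NaN marks thresholds that reject every
    frame.  ``argmax`` is the threshold with the best metric.
    """
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    ios = frame_stats["mean_i_over_sigma"]
    metric = []
    for t in thresholds:
        keep = ios.index[ios.to_numpy() >= t]
        sel = obs[obs["frame_id"].isin(keep)]
        metric.append(metric_fn(sel) if len(sel) else float("nan"))
    metric = np.asarray(metric, dtype=float)
    return ScanResult(axis=thresholds, metric=metric,
                      argmax=_finite_argmax(thresholds, metric))
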