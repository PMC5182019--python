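"""Per-frame linear scaling and Monte-Carlo merging.

Snapshot observations of the same unique reflection are averaged in a
Monte-Carlo manner: random orientations and partialities average out
over many frames.  Each frame first receives a linear scale factor s_i
minimising the squared residual between its observations and a merged
reference, Σ (I_obs − s_i·I_ref)², whose closed form is
s_i = Σ I_obs·I_ref / Σ I_ref².  Scaling and merging alternate until the
scales converge; the overall scale is unobservable, so scales are
normalised to geometric mean 1.

Merged sigma follows the Monte-Carlo (process_hkl) convention: the
standard error of the mean of the scaled observations for multiplicity
≥ 2, and the propagated single-observation sigma otherwise.  Friedel
mates are kept separate throughout so anomalous differences survive
merging.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .crystal import PointGroup, asu_map

__all__ = [
    "UnscalableFrameError",
    "frame_scale",
    "monte_carlo_merge",
    "iterative_scale_merge",
    "MERGED_COLUMNS",
]

log = logging.getLogger(__name__)

#: Columns of a merged dataset: ASU Miller triple, Friedel sign (±1),
#: merged intensity, merged sigma, multiplicity.
MERGED_COLUMNS = ["h", "k", "l", "friedel", "i_merged", "sigma_merged", "multiplicity"]


class UnscalableFrameError(ValueError):
    """Raised when a frame shares no usable reflections with the reference."""


def frame_scale(i_obs, i_ref) -> float:
    """Least-squares linear scale s minimising Σ(I_obs − s·I_ref)².

    Closed form s = Σ I_obs·I_ref / Σ I_ref² over the shared reflections.
    Raises :class:`UnscalableFrameError` when no overlap exists, the
    reference has zero power, or the solution is non-positive.
    """
    i_obs = np.asarray(i_obs, dtype=float)
    i_ref = np.asarray(i_ref, dtype=float)
    if i_obs.size == 0:
        raise UnscalableFrameError("no shared reflections")
    denom = float(i_ref @ i_ref)
    if denom == 0.0:
        raise UnscalableFrameError("reference intensities are all zero")
    s = float(i_obs @ i_ref) / denom
    if s <= 0.0:
        raise UnscalableFrameError(f"non-positive scale {s:.3g}")
    return s


def _with_asu(obs: pd.DataFrame, pg: PointGroup) -> pd.DataFrame:
    if {"asu_h", "asu_k", "asu_l", "friedel"} <= set(obs.columns):
        return obs
    out = obs.copy()
    H = out[["h", "k", "l"]].to_numpy(dtype=np.int64)
    H_asu, sign = asu_map(H, pg)
    out["asu_h"], out["asu_k"], out["asu_l"] = H_asu[:, 0], H_asu[:, 1], H_asu[:, 2]
    out["friedel"] = sign
    return out


def monte_carlo_merge(
    obs: pd.DataFrame,
    pg: PointGroup,
    scales=None,
) -> pd.DataFrame:
    """Monte-Carlo merge observations into a unique reflection list.

    Parameters
    ----------
    obs : observation table with columns h, k, l, intensity, sigma,
        frame_id (ASU columns are computed if absent).
    pg : point group used for ASU mapping (Friedel mates kept separate).
    scales : optional mapping/Series frame_id → s_i; missing ⇒ all 1.

    Returns
    -------
    DataFrame with :data:`MERGED_COLUMNS`, sorted by (h, k, l, friedel).
    """
    if len(obs) == 0:
        return pd.DataFrame(columns=MERGED_COLUMNS)
    work = _with_asu(obs, pg)
    if scales is None:
        s = np.ones(len(work))
    else:
        s = pd.Series(scales).reindex(work["frame_id"]).to_numpy(dtype=float)
        if np.any(~np.isfinite(s)) or np.any(s <= 0):
            raise ValueError("every observation's frame needs a positive scale")
    scaled = work["intensity"].to_numpy() / s
    scaled_sigma = work["sigma"].to_numpy() / s
    df = pd.DataFrame(
        {
            "h": work["asu_h"].to_numpy(),
            "k": work["asu_k"].to_numpy(),
            "l": work["asu_l"].to_numpy(),
            "friedel": work["friedel"].to_numpy(),
            "i_scaled": scaled,
            "sig_scaled": scaled_sigma,
        }
    )
    g = df.groupby(["h", "k", "l", "friedel"], sort=True)
    agg = g.agg(
        i_merged=("i_scaled", "mean"),
        sd=("i_scaled", "std"),  # ddof=1, NaN for N=1
        multiplicity=("i_scaled", "size"),
        sig_single=("sig_scaled", "first"),
    ).reset_index()
    n = agg["multiplicity"].to_numpy()
    sem = agg["sd"].to_numpy() / np.sqrt(n)
    agg["sigma_merged"] = np.where(n >= 2, sem, agg["sig_single"].to_numpy())
    return agg[MERGED_COLUMNS]


def _frame_scales_against(
    work: pd.DataFrame, merged: pd.DataFrame
) -> pd.Series:
    """Closed-form per-frame scales against a merged reference."""
    ref = merged.set_index(["h", "k", "l", "friedel"])["i_merged"]
    key = pd.MultiIndex.from_arrays(
        [work["asu_h"], work["asu_k"], work["asu_l"], work["friedel"]]
    )
    i_ref = ref.reindex(key).to_numpy()
    i_obs = work["intensity"].to_numpy()
    frame = work["frame_id"].to_numpy()
    ok = np.isfinite(i_ref)
    num = pd.Series(i_obs[ok] * i_ref[ok]).groupby(frame[ok]).sum()
    den = pd.Series(i_ref[ok] * i_ref[ok]).groupby(frame[ok]).sum()
    return num / den


def iterative_scale_merge(
    obs: pd.DataFrame,
    pg: PointGroup,
    n_iter: int = 5,
    tol: float = 1e-4,
):
    """Alternate Monte-Carlo merging and per-frame scaling.

    Starts with all scales 1, scales each frame against the current
    merged set, and iterates until the largest relative scale change
    drops below ``tol`` or ``n_iter`` rounds elapse.  Afterwards the
    scales are normalised to geometric mean 1 (the global scale is a
    gauge freedom) and the data are merged one final time.

    Frames that cannot be scaled (no overlap with the reference, zero
    reference power, or a non-positive solution) are excluded and
    logged; if every frame is unscalable a hard error is raised.

    Returns ``(scales, merged, info)`` where ``scales`` is a Series
    indexed by frame_id, ``merged`` a merged DataFrame and ``info`` a
    dict with convergence diagnostics.
    """
    if n_iter < 1:
        raise ValueError("need at least one iteration")
    if len(obs) == 0:
        raise UnscalableFrameError("no observations to merge")
    work = _with_asu(obs, pg)
    frame_ids = pd.Index(np.unique(work["frame_id"].to_numpy()))
    scales = pd.Series(1.0, index=frame_ids)
    converged = False
    iterations = 0
    for iterations in range(1, n_iter + 1):
        merged = monte_carlo_merge(work, pg, scales=scales)
        new = _frame_scales_against(work, merged)
        bad = new.index[~np.isfinite(new) | (new <= 0)]
        new = new.drop(bad)
        dropped = frame_ids.difference(new.index)
        if len(dropped) == len(frame_ids):
            raise UnscalableFrameError("all frames unscalable")
        if len(dropped):
            log.warning("excluding %d unscalable frame(s)", len(dropped))
            work = work[~work["frame_id"].isin(dropped)]
            frame_ids = pd.Index(new.index)
            scales = scales.reindex(frame_ids)
        change = float(np.max(np.abs(new / scales.reindex(new.index) - 1.0)))
        scales = new
        if change < tol:
            converged = True
            break
    scales = scales / np.exp(np.log(scales).mean())  # geometric-mean gauge
    merged = monte_carlo_merge(work, pg, scales=scales)
    info = {"converged": converged, "iterations": iterations,
            "n_frames": len(frame_ids)}
    return scales, merged, info
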