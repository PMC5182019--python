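"""Canonical processing pipelines built from the library blocks.

The default route mirrors the full-intensity strategy that works best
for rotational snapshots: inverse-Lorentz correction, single-frame
full-intensity estimation (divide by PEAK), a rotation-step-dependent
minimum-PEAK cutoff, then per-frame scaling and Monte-Carlo merging.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import corrections, merging, stats
from .anomalous import anomalous_fourier_map, bijvoet_differences, peak_height_at
from .crystal import PointGroup, UnitCell
from .simulate import GroundTruth

__all__ = [
    "standard_correction",
    "truth_phase_series",
    "make_peak_height_metric",
    "make_ccano_metric",
]


def standard_correction(
    obs: pd.DataFrame,
    min_peak: Optional[float] = None,
    lorentz: bool = True,
    fulls: bool = True,
) -> pd.DataFrame:
    """Lorentz correction + full-intensity estimation + PEAK cutoff.

    ``min_peak=None`` resolves the cutoff from the rotation step via the
    default table.
    """
    out = obs
    if lorentz:
        out, _ = corrections.apply_lorentz_correction(out)
    if fulls:
        out = corrections.full_from_partial(out)
    if min_peak is None:
        step = float(out["delta_phi"].max()) if len(out) else 0.0
        min_peak = corrections.default_peak_cutoff(step) if step > 0 else 0.0
    out, _ = corrections.filter_partiality(out, min_peak)
    return out


def truth_phase_series(truth: GroundTruth) -> pd.Series:
    """Model phases indexed by the ASU Miller triple."""
    return pd.Series(truth.phases, index=pd.MultiIndex.from_arrays(truth.hkl.T))


def make_peak_height_metric(
    truth: GroundTruth,
    site,
    d_min: Optional[float] = None,
    scale: bool = False,
) -> Callable[[pd.DataFrame], float]:
    """Metric: anomalous-map height (rms units) at a site, from raw obs.

    The returned callable merges the observations it is given, extracts
    Bijvoet differences, runs the difference synthesis with the
    ground-truth model phases and reports the interpolated height.
    """
    phases = truth_phase_series(truth)
    d_min = d_min or truth.d_min

    def metric(obs: pd.DataFrame) -> float:
        if len(obs) == 0:
            return float("nan")
        if scale:
            _, merged, _ = merging.iterative_scale_merge(obs, truth.pg)
        else:
            merged = merging.monte_carlo_merge(obs, truth.pg)
        diffs = bijvoet_differences(merged, truth.pg)
        if len(diffs) < 10:
            return float("nan")
        phi = phases.reindex(
            pd.MultiIndex.from_arrays([diffs["h"], diffs["k"], diffs["l"]])
        ).to_numpy()
        map_ = anomalous_fourier_map(diffs, phi, truth.cell, truth.pg, d_min=d_min)
        return peak_height_at(map_, site).height

    return metric


def make_ccano_metric(pg: PointGroup, half_seed: int = 0) -> Callable[[pd.DataFrame], float]:
    """Metric: CCano between random half datasets of the given frames."""

    def metric(obs: pd.DataFrame) -> float:
        ids = np.unique(obs["frame_id"].to_numpy())
        if len(ids) < 2:
            return float("nan")
        a, b = stats.split_halves(ids, seed=half_seed)
        return stats.cc_ano(
            merging.monte_carlo_merge(obs[obs["frame_id"].isin(a)], pg),
            merging.monte_carlo_merge(obs[obs["frame_id"].isin(b)], pg),
        )

    return metric
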