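"""Per-observation corrections applied before merging.

Rotational snapshots need an inverse-Lorentz correction with respect to
the spindle axis: a reciprocal-lattice node sweeping slowly through the
Ewald sphere accumulates more intensity than a fast one, by the Lorentz
factor 1/|ẑ·(ŝ′×ŝ₀)| where ẑ is the spindle axis and ŝ′, ŝ₀ the unit
diffracted/incident beam directions.  Stills are left untouched.

Partial intensities can be converted to/from full-intensity estimates by
the recorded partiality (PEAK fraction), filtered by a minimum-PEAK
cutoff (with rotation-step-dependent defaults), and their counting-
statistics sigmas inflated by the standard two-parameter error model
σ′² = a·(σ² + b·I²).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "lorentz_inverse",
    "apply_lorentz_correction",
    "filter_partiality",
    "partial_from_full",
    "full_from_partial",
    "inflate_sigma",
    "default_peak_cutoff",
    "PEAK_CUTOFF_TABLE",
    "LORENTZ_FLOOR",
]

#: Default minimum-partiality cutoffs per rotation step (degrees).  Steps
#: of 1.0° and larger use the last entry.
PEAK_CUTOFF_TABLE = {0.1: 0.30, 0.25: 0.50, 0.5: 0.70, 1.0: 0.80}

#: Observations with inverse Lorentz factor below this are discarded
#: rather than corrected: near-spindle nodes have unbounded correction
#: variance.
LORENTZ_FLOOR = 0.01


def default_peak_cutoff(delta_phi: float) -> float:
    """Optimal minimum-PEAK cutoff for a given rotation step (degrees).

    Piecewise-constant table: 30% at 0.1°, 50% at 0.25°, 70% at 0.5° and
    80% at 1.0° or larger; steps between table points use the nearest
    smaller entry, steps below 0.1° use 30%.
    """
    if delta_phi >= 1.0:
        return PEAK_CUTOFF_TABLE[1.0]
    best = 0.30
    for step, cut in sorted(PEAK_CUTOFF_TABLE.items()):
        if delta_phi >= step:
            best = cut
    return best


def _unit_check(*vecs) -> None:
    for v in vecs:
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValueError("lorentz_inverse requires unit-length vectors")


def lorentz_inverse(s0, s1, spindle) -> float:
    """Inverse Lorentz factor |ẑ·(ŝ₁×ŝ₀)| for unit vectors; lies in [0,1]."""
    s0 = np.asarray(s0, dtype=float)
    s1 = np.asarray(s1, dtype=float)
    spindle = np.asarray(spindle, dtype=float)
    _unit_check(s0, s1, spindle)
    return float(abs(spindle @ np.cross(s1, s0)))


def lorentz_inverse_array(s1: np.ndarray, s0, spindle) -> np.ndarray:
    """Vectorised inverse Lorentz factor for an (N, 3) array of ŝ₁."""
    s0 = np.asarray(s0, dtype=float)
    spindle = np.asarray(spindle, dtype=float)
    cross = np.cross(s1, s0[None, :])
    return np.abs(cross @ spindle)


@dataclasses.dataclass
class CorrectionReport:
    """Bookkeeping for a correction pass."""

    n_in: int
    n_kept: int
    n_dropped: int


def apply_lorentz_correction(
    obs: pd.DataFrame,
    s0=(0.0, 1.0, 0.0),
    spindle=(0.0, 0.0, 1.0),
    floor: float = LORENTZ_FLOOR,
):
    """Multiply intensity and sigma by the inverse Lorentz factor.

    Applies only to rotational snapshots (``delta_phi > 0``); still
    frames pass through unchanged.  Observations with factor below
    ``floor`` are dropped.  Returns ``(corrected, CorrectionReport)``.
    """
    required = {"s1x", "s1y", "s1z", "delta_phi"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"observations lack geometry columns: {sorted(missing)}")
    out = obs.copy()
    rot = out["delta_phi"].to_numpy() > 0
    s1 = out.loc[rot, ["s1x", "s1y", "s1z"]].to_numpy()
    linv = lorentz_inverse_array(s1, s0, spindle)
    factor = np.ones(len(out))
    factor[rot] = linv
    keep = factor >= np.where(rot, floor, 0.0)
    out["intensity"] = out["intensity"].to_numpy() * factor
    out["sigma"] = out["sigma"].to_numpy() * factor
    kept = out[keep].reset_index(drop=True)
    report = CorrectionReport(n_in=len(obs), n_kept=len(kept), n_dropped=int((~keep).sum()))
    return kept, report


def filter_partiality(obs: pd.DataFrame, min_peak: float):
    """Keep observations with partiality ≥ min_peak, preserving order.

    Returns ``(kept, CorrectionReport)``.
    """
    if not 0.0 <= min_peak <= 1.0:
        raise ValueError("min_peak must lie in [0, 1]")
    keep = obs["peak_fraction"].to_numpy() >= min_peak
    kept = obs[keep].reset_index(drop=True)
    return kept, CorrectionReport(n_in=len(obs), n_kept=len(kept), n_dropped=int((~keep).sum()))


def partial_from_full(obs: pd.DataFrame) -> pd.DataFrame:
    """Convert full-intensity estimates to partials: I,σ ×= PEAK."""
    out = obs.copy()
    p = out["peak_fraction"].to_numpy()
    out["intensity"] = out["intensity"].to_numpy() * p
    out["sigma"] = out["sigma"].to_numpy() * p
    out["kind"] = "partial"
    return out


def full_from_partial(obs: pd.DataFrame) -> pd.DataFrame:
    """Estimate full intensities from partials: I,σ /= PEAK.

    This is the single-frame full-intensity estimate: dividing a partial
    observation (and its error) by the recorded rocking-curve fraction.
    Low-partiality observations get large error bars, which is why a
    minimum-PEAK cutoff helps downstream.
    """
    out = obs.copy()
    p = out["peak_fraction"].to_numpy()
    if np.any(p <= 0):
        raise ValueError("partiality must be positive to estimate full intensities")
    out["intensity"] = out["intensity"].to_numpy() / p
    out["sigma"] = out["sigma"].to_numpy() / p
    out["kind"] = "full"
    return out


def inflate_sigma(obs: pd.DataFrame, a: float = 4.0, b: float = 1e-4) -> pd.DataFrame:
    """Apply the two-parameter error model σ′ = sqrt(a·(σ² + b·I²)).

    Defaults a = 4, b = 10⁻⁴ (the XDS CORRECT default error model).
    """
    if a <= 0 or b < 0:
        raise ValueError("need a > 0 and b >= 0")
    out = obs.copy()
    i = out["intensity"].to_numpy()
    s = out["sigma"].to_numpy()
    out["sigma"] = np.sqrt(a * (s * s + b * i * i))
    return out
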