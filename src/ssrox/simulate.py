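"""Synthetic serial rotation-crystallography experiment generator.

Emulates single-frame integrated observations from a raster-plus-rotation
(serial synchrotron) experiment on an orthorhombic protein microcrystal
slurry with mercury anomalous scatterers:

* ground-truth structure factors built by direct summation over randomly
  placed dummy atoms (so centric phase restrictions, Friedel relations
  and point-group symmetry all emerge from the physics rather than being
  imposed),
* a Gaussian rocking curve (truncated at ±3σ) that turns the mosaic
  spread and the wedge width into a closed-form partiality,
* the rotation-method Lorentz effect on recorded intensities,
* per-crystal log-normal scale variation and a configurable hit rate,
* dose-dependent damage: global Wilson-B-like intensity decay plus
  exponential heavy-atom occupancy loss with a characteristic
  "half dose" (occupancy falls to 1/e).

Every stochastic choice flows from a single integer seed; identical
configurations produce identical datasets.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.stats import norm

from .crystal import PointGroup, UnitCell, asu_map, centric_flags, d_spacing

__all__ = [
    "HeavyAtomSite",
    "DamageModel",
    "FrameGeometry",
    "SimConfig",
    "GroundTruth",
    "FrameRecord",
    "generate_ground_truth",
    "reflections_in_wedge",
    "simulate_frame",
    "simulate_experiment",
    "OBS_COLUMNS",
]

#: Columns of the observation table emitted by the simulator (one row per
#: integrated spot on one frame).
OBS_COLUMNS = [
    "frame_id",
    "crystal_id",
    "h",
    "k",
    "l",
    "intensity",
    "sigma",
    "peak_fraction",
    "kind",
    "s1x",
    "s1y",
    "s1z",
    "phi_start",
    "delta_phi",
]

#: Observations whose inverse Lorentz factor falls below this are dropped
#: by the simulator (the node is nearly parallel to the spindle and the
#: recorded intensity would be unboundedly amplified).
LORENTZ_SIM_FLOOR = 1e-3

_TRUNC = 3.0  # rocking curve truncated at ±3σ
_TRUNC_MASS = norm.cdf(_TRUNC) - norm.cdf(-_TRUNC)


@dataclasses.dataclass(frozen=True)
class HeavyAtomSite:
    """An anomalous scatterer in the asymmetric unit.

    ``f0`` is the normal scattering factor (electrons, taken resolution
    independent at the low resolutions that carry the anomalous signal),
    ``f_prime``/``f_double_prime`` the dispersive and absorptive
    corrections at the working wavelength.  Defaults approximate Hg at
    0.98 Å.
    """

    frac_xyz: tuple
    occupancy: float = 1.0
    b_iso: float = 20.0
    f0: float = 80.0
    f_prime: float = -5.0
    f_double_prime: float = 7.7

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if self.b_iso < 0 or self.f_double_prime < 0:
            raise ValueError("b_iso and f'' must be non-negative")


@dataclasses.dataclass(frozen=True)
class DamageModel:
    """Dose-dependent radiation damage.

    half_dose_site : MGy at which heavy-atom occupancy falls to 1/e
        (site-specific damage); ``inf`` disables it.
    b_per_dose : Å²/MGy global B-factor inflation; intensities decay as
        exp(−b_per_dose · D · s²/2) with s = 1/d.
    scale_decay : optional resolution-independent decay rate per MGy.
    """

    half_dose_site: float = math.inf
    b_per_dose: float = 0.0
    scale_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.half_dose_site <= 0 or self.b_per_dose < 0 or self.scale_decay < 0:
            raise ValueError("damage rates must be non-negative (half dose positive)")


@dataclasses.dataclass(frozen=True)
class FrameGeometry:
    """Diffraction geometry of one frame.

    The spindle axis and incident beam are fixed in the laboratory frame;
    ``orientation`` is the rotation applied to the crystal's reciprocal
    basis at φ = 0.  ``delta_phi = 0`` encodes a still.
    """

    orientation: np.ndarray
    phi_start: float = 0.0
    delta_phi: float = 0.5
    spindle_axis: tuple = (0.0, 0.0, 1.0)
    s0: tuple = (0.0, 1.0, 0.0)
    wavelength: float = 0.9839

    def __post_init__(self) -> None:
        U = np.asarray(self.orientation, dtype=float)
        if U.shape != (3, 3) or abs(np.linalg.det(U)) < 1e-9:
            raise ValueError("orientation must be a non-singular 3x3 matrix")
        for v in (self.spindle_axis, self.s0):
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError("spindle_axis and s0 must be unit vectors")
        if self.delta_phi < 0:
            raise ValueError("delta_phi must be non-negative")
        object.__setattr__(self, "orientation", U)


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Experiment-level simulation parameters.

    Defaults mirror the study conditions: 0.03° mosaic rocking width,
    0.5° wedges, 1.2 MGy per frame, and a ~40% hit rate.
    """

    n_frames: int = 1000
    delta_phi_deg: float = 0.5
    mosaicity_deg: float = 0.03
    crystal_scale_sigma: float = 0.3
    dose_per_frame: float = 1.2
    noise_b0: float = 25.0
    poisson_gain: float = 1.0
    hit_fraction: float = 0.4
    weak_frame_fraction: float = 0.0
    weak_frame_factor: float = 0.1
    wavelength: float = 0.9839
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if not 0.0 <= self.hit_fraction <= 1.0:
            raise ValueError("hit_fraction must lie in [0, 1]")
        if self.mosaicity_deg <= 0:
            raise ValueError("mosaicity must be positive")
        if not 0.0 <= self.weak_frame_fraction <= 1.0:
            raise ValueError("weak_frame_fraction must lie in [0, 1]")

    @property
    def noise_enabled(self) -> bool:
        return self.noise_b0 > 0 or self.poisson_gain > 0


@dataclasses.dataclass
class FrameRecord:
    """Per-image bookkeeping carried alongside the observations."""

    frame_id: int
    crystal_id: int
    n_obs: int = 0
    scale: float = 1.0  # merging-side scale factor s_i (filled by scaling)
    true_scale: float = 1.0  # simulator ground truth
    mean_i_over_sigma: float = float("nan")
    accumulated_dose: float = 0.0
    delta_phi: float = 0.0
    phi_start: float = 0.0
    n_dropped_lorentz: int = 0


@dataclasses.dataclass
class GroundTruth:
    """Simulator-side truth: structure factors, sites, phases, damage hooks.

    ``hkl`` lists the canonical ASU representatives; ``i_plus``/``i_minus``
    are the Bijvoet intensities of +h/−h on an arbitrary common scale at
    zero dose.  ``phases`` are the protein-only (heavy-atom-free) model
    phases in radians used for the anomalous difference synthesis.
    """

    cell: UnitCell
    pg: PointGroup
    d_min: float
    hkl: np.ndarray  # (n, 3) ASU representatives
    centric: np.ndarray  # (n,) bool
    f_protein: np.ndarray  # (n,) complex, F_P(+h)
    site_geometry: np.ndarray  # (n, n_sites) complex, Σ_sym exp(2πi h·x)·exp(−B s²/4)
    sites: tuple
    damage: DamageModel = dataclasses.field(default_factory=DamageModel)
    seed: int = 0

    def __post_init__(self) -> None:
        self._dose_cache: dict = {}
        self._expanded: Optional[tuple] = None

    # -- structure-factor algebra -------------------------------------

    @property
    def phases(self) -> np.ndarray:
        """Protein-only model phases (radians) for the +h representatives."""
        return np.angle(self.f_protein)

    @property
    def inv_d(self) -> np.ndarray:
        return 1.0 / d_spacing(self.hkl, self.cell)

    def site_occupancies(self, dose: float) -> np.ndarray:
        occ0 = np.array([s.occupancy for s in self.sites])
        if not self.sites:
            return occ0
        return occ0 * np.exp(-dose / self.damage.half_dose_site)

    def intensities(self, dose: float = 0.0):
        """Bijvoet-pair true intensities (i_plus, i_minus) at a dose.

        Site occupancies decay with the site half dose; the whole pattern
        additionally decays with the global B inflation and optional
        resolution-independent factor.  Centric reflections are forced to
        exact Bijvoet equality (they are mathematically equal; forcing
        removes last-ulp noise).
        """
        key = round(float(dose), 9)
        if key in self._dose_cache:
            return self._dose_cache[key]
        if self.sites:
            occ = self.site_occupancies(dose)
            fc = np.array(
                [s.f0 + s.f_prime + 1j * s.f_double_prime for s in self.sites]
            )
            heavy = self.site_geometry @ (occ * fc)
            heavy_minus = np.conj(self.site_geometry) @ (occ * fc)
        else:
            heavy = heavy_minus = 0.0
        f_plus = self.f_protein + heavy
        f_minus = np.conj(self.f_protein) + heavy_minus
        i_plus = np.abs(f_plus) ** 2
        i_minus = np.abs(f_minus) ** 2
        i_minus[self.centric] = i_plus[self.centric]
        s2 = self.inv_d**2
        decay = np.exp(-self.damage.b_per_dose * dose * s2 / 2.0)
        decay *= math.exp(-self.damage.scale_decay * dose)
        out = (i_plus * decay, i_minus * decay)
        self._dose_cache[key] = out
        return out

    def bijvoet_true(self, dose: float = 0.0) -> np.ndarray:
        """Ground-truth anomalous differences ΔI = I(+) − I(−)."""
        ip, im = self.intensities(dose)
        return ip - im

    # -- observable-reflection bookkeeping ----------------------------

    def expanded(self):
        """All observable reflections in the full sphere to d_min.

        Returns (H_all, asu_index, friedel) where each row of ``H_all``
        is an as-indexed Miller triple, ``asu_index`` points into
        :attr:`hkl` and ``friedel`` is ±1.
        """
        if self._expanded is None:
            cell, pg = self.cell, self.pg
            hmax = int(cell.a / self.d_min) + 1
            kmax = int(cell.b / self.d_min) + 1
            lmax = int(cell.c / self.d_min) + 1
            h, k, l = np.meshgrid(
                np.arange(-hmax, hmax + 1),
                np.arange(-kmax, kmax + 1),
                np.arange(-lmax, lmax + 1),
                indexing="ij",
            )
            H = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
            H = H[np.any(H != 0, axis=1)]
            d = d_spacing(H, cell)
            H = H[d >= self.d_min]
            H_asu, sign = asu_map(H, pg)
            idx = _index_rows(H_asu, self.hkl)
            keep = idx >= 0
            self._expanded = (H[keep], idx[keep], sign[keep])
        return self._expanded


def _index_rows(rows: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Locate each row of ``rows`` in ``table`` (−1 where absent)."""
    scale = 2 * int(max(np.abs(rows).max(), np.abs(table).max())) + 3
    key = lambda H: (H[:, 0] * scale + H[:, 1]) * scale + H[:, 2]
    tk = key(table)
    order = np.argsort(tk)
    pos = np.searchsorted(tk[order], key(rows))
    pos = np.clip(pos, 0, len(tk) - 1)
    found = tk[order][pos] == key(rows)
    out = np.where(found, order[pos], -1)
    return out


def generate_ground_truth(
    cell: UnitCell,
    pg: PointGroup,
    d_min: float,
    sites: Sequence[HeavyAtomSite] = (),
    seed: int = 0,
    n_dummy_atoms: int = 300,
    dummy_f: float = 6.0,
    dummy_b: float = 20.0,
    damage: DamageModel = DamageModel(),
) -> GroundTruth:
    """Build ground-truth structure factors by dummy-atom direct summation.

    The protein component is the coherent sum over ``n_dummy_atoms``
    randomly placed point scatterers, expanded over the point-group
    symmetry (treated as a symmorphic rotation group at the origin), so
    Friedel relations and centric phase restrictions hold exactly.
    Heavy-atom sites contribute through per-site geometric factors so
    occupancies can be re-weighted later (radiation damage).
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    if d_min < 0.5:
        raise ValueError("d_min below 0.5 Å rejected (grid blow-up guard)")
    from .crystal import unique_reflections

    H, cen = unique_reflections(cell, pg, d_min)
    rng = np.random.default_rng(seed)
    xyz = rng.random((n_dummy_atoms, 3))
    R = pg.op_array  # real-space rotations of the symmorphic group
    # symmetry-expand atom positions: x' = R x (rotation part only)
    xyz_all = np.einsum("mij,nj->mni", R, xyz).reshape(-1, 3)
    s2 = (1.0 / d_spacing(H, cell)) ** 2  # (n,)
    debye = np.exp(-dummy_b * s2 / 4.0)
    phase = np.exp(2j * np.pi * (H @ xyz_all.T))  # (n, atoms)
    f_protein = dummy_f * debye * phase.sum(axis=1)
    geom = np.zeros((len(H), len(sites)), dtype=complex)
    for j, site in enumerate(sites):
        x_all = np.einsum("mij,j->mi", R, np.asarray(site.frac_xyz, dtype=float))
        ph = np.exp(2j * np.pi * (H @ x_all.T)).sum(axis=1)
        geom[:, j] = ph * np.exp(-site.b_iso * s2 / 4.0)
    return GroundTruth(
        cell=cell,
        pg=pg,
        d_min=d_min,
        hkl=H,
        centric=cen,
        f_protein=f_protein,
        site_geometry=geom,
        sites=tuple(sites),
        damage=damage,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# frame geometry: which reflections diffract within a wedge, and how much


def _wedge_solutions(truth: GroundTruth, geom: FrameGeometry, mosaicity_deg: float):
    """Reflecting-condition solve for every observable reflection.

    Returns arrays (obs_index, partiality, s1_unit, lorentz_inv) for the
    reflections whose rocking interval overlaps the wedge.
    """
    H_all, asu_idx, sign = truth.expanded()
    B = truth.cell.b_matrix
    lam = geom.wavelength
    # lab frame with e3 = spindle axis
    ez = np.asarray(geom.spindle_axis, dtype=float)
    s0 = np.asarray(geom.s0, dtype=float)
    e1 = s0 - ez * (s0 @ ez)
    n1 = np.linalg.norm(e1)
    if n1 < 1e-9:  # beam parallel to spindle: degenerate geometry
        raise ValueError("incident beam must not be parallel to the spindle axis")
    e1 /= n1
    e2 = np.cross(ez, e1)
    basis = np.vstack([e1, e2, ez])  # rows: spindle frame

    r0 = (basis @ geom.orientation @ B @ H_all.T).T  # (N, 3) in spindle frame
    k0 = basis @ (s0 / lam)
    x, y, z = r0[:, 0], r0[:, 1], r0[:, 2]
    P = x * k0[0] + y * k0[1]
    Q = x * k0[1] - y * k0[0]
    C = -0.5 * np.einsum("ni,ni->n", r0, r0) - z * k0[2]
    Rho = np.hypot(P, Q)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosarg = C / Rho
    reachable = (Rho > 0) & (np.abs(cosarg) <= 1.0)
    delta = np.arctan2(Q, P)
    alpha = np.arccos(np.clip(cosarg, -1.0, 1.0))
    phi_s = math.radians(geom.phi_start)
    phi_e = phi_s + math.radians(geom.delta_phi)
    sigma = math.radians(mosaicity_deg)

    idx_list, part_list, s1_list, linv_list = [], [], [], []
    for phi_c in (delta + alpha, delta - alpha):
        # wrap each crossing angle to within π of the wedge centre
        mid = 0.5 * (phi_s + phi_e)
        phi_c = mid + np.mod(phi_c - mid + np.pi, 2 * np.pi) - np.pi
        if geom.delta_phi > 0:
            a = (phi_s - phi_c) / sigma
            b = (phi_e - phi_c) / sigma
            lo = np.clip(a, -_TRUNC, _TRUNC)
            hi = np.clip(b, -_TRUNC, _TRUNC)
            part = (norm.cdf(hi) - norm.cdf(lo)) / _TRUNC_MASS
        else:
            off = (phi_c - phi_s) / sigma
            part = np.where(np.abs(off) < _TRUNC, np.exp(-0.5 * off**2), 0.0)
        sel = reachable & (part > 1e-9)
        if not np.any(sel):
            continue
        phi_c = phi_c[sel]
        c, s = np.cos(phi_c), np.sin(phi_c)
        xs, ys, zs = x[sel], y[sel], z[sel]
        r = np.column_stack([xs * c - ys * s, xs * s + ys * c, zs])
        s1 = (k0 + r) * lam  # unit diffracted-beam direction
        s1 /= np.linalg.norm(s1, axis=1, keepdims=True)
        s0u = k0 * lam
        linv = np.abs(s1[:, 0] * s0u[1] - s1[:, 1] * s0u[0])  # |ez·(s1×s0)| in spindle frame
        idx_list.append(np.nonzero(sel)[0])
        part_list.append(part[sel])
        s1_list.append(basis.T @ s1.T)  # back to lab frame, (3, k)
        linv_list.append(linv)
    if not idx_list:
        empty = np.empty(0)
        return np.empty(0, dtype=int), empty, np.empty((0, 3)), empty
    obs_index = np.concatenate(idx_list)
    part = np.concatenate(part_list)
    s1 = np.concatenate([m.T for m in s1_list], axis=0)
    linv = np.concatenate(linv_list)
    return obs_index, part, s1, linv


def reflections_in_wedge(
    truth: GroundTruth, geom: FrameGeometry, mosaicity_deg: float
) -> pd.DataFrame:
    """Reflections whose rocking curve overlaps the frame's wedge.

    Returns a DataFrame with as-indexed Miller indices, the ASU
    representative, the Friedel sign and the partiality (fraction of the
    truncated-Gaussian rocking curve swept by the wedge; for a still,
    the rocking-profile ordinate at the static position).
    """
    H_all, asu_idx, sign = truth.expanded()
    obs_index, part, s1, linv = _wedge_solutions(truth, geom, mosaicity_deg)
    H = H_all[obs_index]
    return pd.DataFrame(
        {
            "h": H[:, 0],
            "k": H[:, 1],
            "l": H[:, 2],
            "asu_index": asu_idx[obs_index],
            "friedel": sign[obs_index],
            "partiality": part,
            "s1x": s1[:, 0],
            "s1y": s1[:, 1],
            "s1z": s1[:, 2],
            "lorentz_inv": linv,
        }
    )


def simulate_frame(
    truth: GroundTruth,
    geom: FrameGeometry,
    config: SimConfig,
    crystal_scale: float = 1.0,
    accumulated_dose: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    frame_id: int = 0,
    crystal_id: int = 0,
):
    """Simulate the integrated observations of one frame.

    Recorded intensity = scale × partiality × L × I_true(dose) + noise,
    with L the Lorentz factor (reciprocal of the inverse factor used in
    the correction step).  Near-spindle reflections with inverse factor
    below :data:`LORENTZ_SIM_FLOOR` are dropped and counted on the frame
    record.  Returns ``(FrameRecord, DataFrame)``.
    """
    if accumulated_dose < 0:
        raise ValueError("accumulated dose must be non-negative")
    rng = rng or np.random.default_rng(config.seed)
    H_all, asu_idx, sign = truth.expanded()
    obs_index, part, s1, linv = _wedge_solutions(truth, geom, config.mosaicity_deg)
    n_dropped = int(np.sum(linv < LORENTZ_SIM_FLOOR)) if geom.delta_phi > 0 else 0
    if geom.delta_phi > 0:
        keep = linv >= LORENTZ_SIM_FLOOR
        obs_index, part, s1, linv = obs_index[keep], part[keep], s1[keep], linv[keep]
        lorentz = 1.0 / linv
    else:
        lorentz = np.ones_like(part)
    ip, im = truth.intensities(accumulated_dose)
    idx = asu_idx[obs_index]
    i_true = np.where(sign[obs_index] > 0, ip[idx], im[idx])
    signal = crystal_scale * part * lorentz * i_true
    if config.noise_enabled:
        sigma = np.sqrt(config.poisson_gain * np.clip(signal, 0, None) + config.noise_b0**2)
        intensity = signal + rng.normal(0.0, 1.0, size=signal.shape) * sigma
    else:
        sigma = np.ones_like(signal)
        intensity = signal
    H = H_all[obs_index]
    n = len(H)
    frame = FrameRecord(
        frame_id=frame_id,
        crystal_id=crystal_id,
        n_obs=n,
        true_scale=crystal_scale,
        accumulated_dose=accumulated_dose,
        delta_phi=geom.delta_phi,
        phi_start=geom.phi_start,
        n_dropped_lorentz=n_dropped,
        mean_i_over_sigma=float(np.mean(intensity / sigma)) if n else float("nan"),
    )
    obs = pd.DataFrame(
        {
            "frame_id": np.full(n, frame_id),
            "crystal_id": np.full(n, crystal_id),
            "h": H[:, 0],
            "k": H[:, 1],
            "l": H[:, 2],
            "intensity": intensity,
            "sigma": sigma,
            "peak_fraction": part,
            "kind": np.full(n, "partial", dtype=object),
            "s1x": s1[:, 0],
            "s1y": s1[:, 1],
            "s1z": s1[:, 2],
            "phi_start": np.full(n, geom.phi_start),
            "delta_phi": np.full(n, geom.delta_phi),
        }
    )
    return frame, obs


def simulate_experiment(
    truth: GroundTruth,
    config: SimConfig,
    base_dose: float = 0.0,
):
    """Simulate a full serial run of ``config.n_frames`` frames.

    Each hit frame gets an independent uniformly random orientation and a
    log-normal crystal scale; a configurable fraction of frames is made
    tenfold weaker to emulate poorly diffracting crystals.  Every frame
    absorbs ``dose_per_frame`` on top of ``base_dose`` (repeated scans of
    the same sample are modelled by raising ``base_dose`` scan by scan).

    Returns ``(frames, observations)``: a list of :class:`FrameRecord`
    and one concatenated observation DataFrame.
    """
    rng = np.random.default_rng(config.seed)
    frames: list[FrameRecord] = []
    chunks: list[pd.DataFrame] = []
    crystal_id = 0
    for frame_id in range(config.n_frames):
        if rng.random() >= config.hit_fraction:
            frames.append(
                FrameRecord(frame_id=frame_id, crystal_id=-1, n_obs=0,
                            accumulated_dose=base_dose, delta_phi=config.delta_phi_deg)
            )
            # keep the stream position independent of hit/miss pattern length
            continue
        U = Rotation.random(random_state=rng).as_matrix()
        scale = float(np.exp(rng.normal(0.0, config.crystal_scale_sigma)))
        if config.weak_frame_fraction > 0 and rng.random() < config.weak_frame_fraction:
            scale *= config.weak_frame_factor
        geom = FrameGeometry(
            orientation=U,
            phi_start=0.0,
            delta_phi=config.delta_phi_deg,
            wavelength=config.wavelength,
        )
        frame, obs = simulate_frame(
            truth,
            geom,
            config,
            crystal_scale=scale,
            accumulated_dose=base_dose + config.dose_per_frame,
            rng=rng,
            frame_id=frame_id,
            crystal_id=crystal_id,
        )
        crystal_id += 1
        frames.append(frame)
        if len(obs):
            chunks.append(obs)
    observations = (
        pd.concat(chunks, ignore_index=True)
        if chunks
        else pd.DataFrame(columns=OBS_COLUMNS)
    )
    return frames, observations
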