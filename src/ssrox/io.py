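"""File formats: observation tables, XDS_ASCII-style readers, SHELX export.

The interchange format is a plain TSV observation table, one integrated
spot per row, preceded by ``#``-prefixed metadata lines of the form
``# key = <json value>``.  Metadata must appear before the header row
and carries the cell, point group, diffraction geometry and simulation
provenance.  Round trips (write → read) are lossless to full double
precision.

A declaration-driven reader for XDS_ASCII-style reflection files
(``!ITEM_H=1`` etc.) is provided for interoperability, plus a SHELX
HKLF4 fixed-format writer (3I4, 2F8.2) for downstream substructure
programs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .crystal import PointGroup, UnitCell
from .simulate import OBS_COLUMNS, DamageModel, GroundTruth, HeavyAtomSite, SimConfig

__all__ = [
    "write_observations",
    "read_observations",
    "read_xds_ascii",
    "write_shelx_hklf4",
    "write_merged",
    "read_merged",
    "write_ground_truth",
    "read_ground_truth_tables",
    "read_sites",
    "read_phases",
    "load_config",
    "FormatError",
]

#: Metadata keys every observation table must carry.
REQUIRED_METADATA = ["cell", "point_group", "spindle", "s0", "wavelength"]


class FormatError(ValueError):
    """A file does not conform to the expected format."""


# ---------------------------------------------------------------------------
# internal observation table


def metadata_from_sim(cell: UnitCell, pg: PointGroup, config: SimConfig) -> dict:
    return {
        "cell": [cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma],
        "point_group": pg.name,
        "spindle": [0.0, 0.0, 1.0],
        "s0": [0.0, 1.0, 0.0],
        "wavelength": config.wavelength,
        "dose_per_frame": config.dose_per_frame,
        "seed": config.seed,
    }


def write_observations(path, obs: pd.DataFrame, metadata: dict) -> None:
    """Write an observation table with '#'-metadata header lines."""
    missing = [k for k in REQUIRED_METADATA if k not in metadata]
    if missing:
        raise FormatError(f"metadata missing required key(s): {missing}")
    path = Path(path)
    with path.open("w") as fh:
        for key, value in metadata.items():
            fh.write(f"# {key} = {json.dumps(value)}\n")
        obs.to_csv(fh, sep="\t", index=False, columns=OBS_COLUMNS, float_format="%.17g")


def read_observations(path):
    """Read an observation table; returns ``(metadata, DataFrame)``.

    Parse failures name the offending line; missing metadata names the
    key.
    """
    path = Path(path)
    metadata = {}
    lines = path.read_text().splitlines()
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                raise FormatError(f"{path}:{i + 1}: malformed metadata line")
            key, _, value = body.partition("=")
            try:
                metadata[key.strip()] = json.loads(value.strip())
            except json.JSONDecodeError:
                raise FormatError(f"{path}:{i + 1}: metadata value is not valid JSON") from None
        else:
            data_start = i
            break
    else:
        raise FormatError(f"{path}: missing header")
    for key in REQUIRED_METADATA:
        if key not in metadata:
            raise FormatError(f"{path}: missing metadata key {key!r}")
    header = lines[data_start].split("\t")
    if header[:3] != ["frame_id", "crystal_id", "h"]:
        raise FormatError(f"{path}:{data_start + 1}: missing header")
    body = "\n".join(lines[data_start:])
    numeric = {c: float for c in OBS_COLUMNS if c not in ("kind",)}
    for c in ("frame_id", "crystal_id", "h", "k", "l"):
        numeric[c] = "int64"
    try:
        obs = pd.read_csv(pd.io.common.StringIO(body), sep="\t", dtype=numeric)
    except (ValueError, TypeError):
        # locate the offending line for the error message
        for j, line in enumerate(lines[data_start + 1 :], start=data_start + 2):
            fields = line.split("\t")
            for col, val in zip(header, fields):
                if col == "kind":
                    continue
                try:
                    float(val)
                except ValueError:
                    raise FormatError(
                        f"{path}:{j}: non-numeric value {val!r} in column {col!r}"
                    ) from None
        raise FormatError(f"{path}: malformed observation table") from None
    return metadata, obs


# ---------------------------------------------------------------------------
# XDS_ASCII-style reflection files


def read_xds_ascii(path):
    """Read an XDS_ASCII-style reflection file.

    Columns are mapped by the ``!ITEM_<NAME>=<index>`` declarations, not
    by position.  H, K, L, IOBS and SIGMA(IOBS) are mandatory; a missing
    PEAK column sets every partiality to 1 with a warning.  PEAK values
    follow the XDS convention of percentages and are divided by 100.
    Geometry columns are not part of this dialect, so tables read this
    way carry ``delta_phi = 0`` and skip the Lorentz correction.
    """
    path = Path(path)
    items = {}
    metadata = {}
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("!"):
                body = line[1:].strip()
                if body.startswith("ITEM_") and "=" in body:
                    name, _, idx = body.partition("=")
                    items[name[5:].strip()] = int(idx) - 1
                elif "=" in body and not body.startswith("END_OF"):
                    key, _, value = body.partition("=")
                    metadata[key.strip()] = value.strip()
                if body.startswith("END_OF_DATA"):
                    break
                continue
            if not line.strip():
                continue
            fields = line.split()
            try:
                rows.append([float(x) for x in fields])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric reflection record") from None
    for req in ("H", "K", "L", "IOBS", "SIGMA(IOBS)"):
        if req not in items:
            raise FormatError(f"{path}: missing mandatory !ITEM_{req} declaration")
    arr = np.asarray(rows, dtype=float)
    if arr.size == 0:
        raise FormatError(f"{path}: no reflection records")
    get = lambda name: arr[:, items[name]]
    if "PEAK" in items:
        peak = get("PEAK") / 100.0
    else:
        warnings.warn(f"{path}: no PEAK column; partialities set to 1")
        peak = np.ones(len(arr))
    n = len(arr)
    obs = pd.DataFrame(
        {
            "frame_id": np.zeros(n, dtype=np.int64),
            "crystal_id": np.zeros(n, dtype=np.int64),
            "h": get("H").astype(np.int64),
            "k": get("K").astype(np.int64),
            "l": get("L").astype(np.int64),
            "intensity": get("IOBS"),
            "sigma": get("SIGMA(IOBS)"),
            "peak_fraction": peak,
            "kind": np.full(n, "full", dtype=object),
            "s1x": np.zeros(n),
            "s1y": np.zeros(n),
            "s1z": np.zeros(n),
            "phi_start": np.zeros(n),
            "delta_phi": np.zeros(n),
        }
    )
    return metadata, obs


# ---------------------------------------------------------------------------
# merged datasets


def write_merged(path, merged: pd.DataFrame, metadata: Optional[dict] = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key} = {json.dumps(value)}\n")
        merged.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_merged(path):
    path = Path(path)
    metadata = {}
    lines = path.read_text().splitlines()
    start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            start = i
            break
        key, _, value = line[1:].strip().partition("=")
        metadata[key.strip()] = json.loads(value.strip())
    df = pd.read_csv(pd.io.common.StringIO("\n".join(lines[start:])), sep="\t")
    return metadata, df


def write_shelx_hklf4(merged: pd.DataFrame, path, scale_policy: str = "auto") -> float:
    """Write merged intensities in SHELX HKLF4 fixed format (3I4, 2F8.2).

    Friedel mates are written as ±hkl rows.  A global scale keeps the
    largest |I| inside the 8-character field (``scale_policy="auto"``;
    ``"none"`` fails instead of scaling).  Returns the applied scale.
    Index magnitudes above 999 and empty datasets are errors.
    """
    if len(merged) == 0:
        raise FormatError("cannot write an empty dataset")
    H = merged[["h", "k", "l"]].to_numpy(dtype=np.int64) * merged["friedel"].to_numpy()[:, None]
    if np.abs(H).max() > 999:
        raise FormatError("Miller index magnitude exceeds the I4 field")
    i = merged["i_merged"].to_numpy(dtype=float)
    s = merged["sigma_merged"].to_numpy(dtype=float)
    limit = 9999.99
    biggest = max(np.abs(i).max(), np.abs(s).max())
    scale = 1.0
    if biggest > limit:
        if scale_policy != "auto":
            raise FormatError("intensities overflow the F8.2 field (use scale_policy='auto')")
        scale = limit / biggest
    with Path(path).open("w") as fh:
        for (hh, kk, ll), ii, ss in zip(H, i * scale, s * scale):
            fh.write(f"{hh:4d}{kk:4d}{ll:4d}{ii:8.2f}{ss:8.2f}\n")
        fh.write(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")
    return scale


# ---------------------------------------------------------------------------
# ground truth sidecar, sites, phases


def write_ground_truth(path, truth: GroundTruth) -> None:
    """JSON sidecar with true intensities, phases and sites for validation."""
    ip, im = truth.intensities(0.0)
    payload = {
        "cell": [truth.cell.a, truth.cell.b, truth.cell.c,
                 truth.cell.alpha, truth.cell.beta, truth.cell.gamma],
        "point_group": truth.pg.name,
        "d_min": truth.d_min,
        "seed": truth.seed,
        "sites": [
            {
                "frac_xyz": list(s.frac_xyz),
                "occupancy": s.occupancy,
                "b_iso": s.b_iso,
                "f0": s.f0,
                "f_prime": s.f_prime,
                "f_double_prime": s.f_double_prime,
            }
            for s in truth.sites
        ],
        "damage": dataclasses.asdict(truth.damage),
        "hkl": truth.hkl.tolist(),
        "centric": truth.centric.astype(int).tolist(),
        "i_true_plus": ip.tolist(),
        "i_true_minus": im.tolist(),
        "phases": truth.phases.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth_tables(path):
    """Read the sidecar back as (metadata, DataFrame of per-reflection truth)."""
    payload = json.loads(Path(path).read_text())
    H = np.asarray(payload["hkl"], dtype=np.int64)
    df = pd.DataFrame(
        {
            "h": H[:, 0],
            "k": H[:, 1],
            "l": H[:, 2],
            "centric": np.asarray(payload["centric"], dtype=bool),
            "i_true_plus": payload["i_true_plus"],
            "i_true_minus": payload["i_true_minus"],
            "phase": payload["phases"],
        }
    )
    meta = {k: payload[k] for k in ("cell", "point_group", "d_min", "seed", "sites", "damage")}
    return meta, df


def read_sites(path):
    """Read heavy-atom sites: whitespace-separated ``x y z [label]`` lines."""
    sites = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: need at least x y z")
        try:
            xyz = tuple(float(x) for x in fields[:3])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from None
        label = fields[3] if len(fields) > 3 else f"site{len(sites) + 1}"
        sites.append((label, xyz))
    return sites


def read_phases(path):
    """Read a phase table ``h k l phase_deg`` into a (h,k,l) → radians dict."""
    table = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise FormatError(f"{path}:{lineno}: expected 'h k l phase(deg)'")
        try:
            h, k, l = (int(x) for x in fields[:3])
            table[(h, k, l)] = np.radians(float(fields[3]))
        except ValueError:
            raise FormatError(f"{path}:{lineno}: malformed phase record") from None
    return table


# ---------------------------------------------------------------------------
# run configuration


_CONFIG_SECTIONS = {"cell", "point_group", "d_min", "sites", "simulation", "damage",
                    "n_dummy_atoms", "dummy_f", "dummy_b"}


def load_config(path):
    """Load and validate a simulation config (YAML or JSON).

    Returns a dict with keys cell (:class:`UnitCell`), pg
    (:class:`PointGroup`), d_min, sites, config (:class:`SimConfig`),
    damage (:class:`DamageModel`) and ground-truth generator options.
    Unknown keys anywhere are rejected with a message naming them.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_SECTIONS
    if unknown:
        raise FormatError(f"{path}: unknown config key(s): {sorted(unknown)}")

    def build(cls, section, name):
        section = section or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        bad = set(section) - fields
        if bad:
            raise FormatError(f"{path}: unknown {name} key(s): {sorted(bad)}")
        return cls(**section)

    cell = UnitCell(*raw.get("cell", [47.3, 76.7, 84.0, 90.0, 90.0, 90.0]))
    pg = PointGroup(name=str(raw.get("point_group", "222")))
    sites = [build(HeavyAtomSite, s, "site") for s in raw.get("sites", [])]
    for s in raw.get("sites", []):
        if "frac_xyz" not in s:
            raise FormatError(f"{path}: each site needs frac_xyz")
    return {
        "cell": cell,
        "pg": pg,
        "d_min": float(raw.get("d_min", 3.0)),
        "sites": [dataclasses.replace(s, frac_xyz=tuple(s.frac_xyz)) for s in sites],
        "config": build(SimConfig, raw.get("simulation"), "simulation"),
        "damage": build(DamageModel, raw.get("damage"), "damage"),
        "n_dummy_atoms": int(raw.get("n_dummy_atoms", 300)),
        "dummy_f": float(raw.get("dummy_f", 6.0)),
        "dummy_b": float(raw.get("dummy_b", 20.0)),
    }
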