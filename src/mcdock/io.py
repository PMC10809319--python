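"""Readers and writers for the package's artifact formats.

* PDB subset — fixed-width ATOM/HETATM (plus MODEL/ENDMDL) records only,
  1-based residue numbering, coordinates to 3 decimals (format-limited);
  unknown record types are skipped and logged.
* Ensemble container — HDF5: ``/frames`` holds full-precision coordinates,
  energies, trajectory ids and step indices; ``/weights`` optionally holds
  canonical weights with their temperature; the root attributes carry the
  system id, units and the hash of the configuration that produced it.
* Bias function — two-column text (energy knot, bias value) with a header
  naming T_low/T_high/T_ref and the interpolation rule.
* Weights — two-column text (snapshot index, weight) with the temperature
  and a normalization checksum in the header.
* Reports — CSV with a leading ``# config_hash=…`` comment line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from .engine import BiasFunction, SamplingSchedule, Snapshot
from .errors import InputError, ParseError
from .systems import (
    ToySystem,
    make_double_well,
    make_gated_pocket,
    make_harmonic,
    make_mueller,
)

logger = logging.getLogger(__name__)

UNITS = {"length": "angstrom", "energy": "kcal/mol", "temperature": "K"}


# ---------------------------------------------------------------------------
# PDB subset
# ---------------------------------------------------------------------------


@dataclass
class Structure:
    """Minimal structure record for the PDB-subset format."""

    names: list
    residue_names: list
    residue_ids: list  # 1-based, preserved verbatim
    chain_ids: list
    coords: np.ndarray
    elements: list
    hetatm: list = field(default_factory=list)

    def __len__(self):
        return len(self.names)


def _parse_atom_line(line: str, lineno: int):
    if len(line.rstrip("\n")) < 54:
        raise ParseError(f"line {lineno}: truncated ATOM/HETATM record")
    try:
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip() or "A"
        res_id = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed ATOM/HETATM record ({exc})")
    if not element:
        element = (name[:1] or "C").upper()
    return name, res_name, chain, res_id, (x, y, z), element


def read_pdb_models(path) -> list:
    """All MODEL blocks of a PDB-subset file (one Structure each)."""
    models = []
    current = None
    ignored = set()

    def fresh():
        return Structure([], [], [], [], np.zeros((0, 3)), [], [])

    coords_buf = []
    current = fresh()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                name, res_name, chain, res_id, xyz, el = _parse_atom_line(line, lineno)
                current.names.append(name)
                current.residue_names.append(res_name)
                current.residue_ids.append(res_id)
                current.chain_ids.append(chain)
                current.elements.append(el)
                current.hetatm.append(rec == "HETATM")
                coords_buf.append(xyz)
            elif rec == "MODEL":
                if coords_buf:
                    current.coords = np.array(coords_buf)
                    models.append(current)
                current = fresh()
                coords_buf = []
            elif rec in ("ENDMDL", "END", "TER", ""):
                if rec == "ENDMDL" and coords_buf:
                    current.coords = np.array(coords_buf)
                    models.append(current)
                    current = fresh()
                    coords_buf = []
            else:
                ignored.add(rec)
    if coords_buf:
        current.coords = np.array(coords_buf)
        models.append(current)
    if ignored:
        logger.info("ignored PDB record types: %s", sorted(ignored))
    if not models:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return models


def read_pdb_subset(path) -> Structure:
    """First model of a PDB-subset file."""
    return read_pdb_models(path)[0]


def write_pdb_subset(structure: Structure, path, model_structures=None):
    """Write one structure (or a list of models) in the PDB subset."""
    models = model_structures if model_structures is not None else [structure]
    multi = len(models) > 1
    with open(path, "w") as fh:
        for m_idx, s in enumerate(models, start=1):
            if multi:
                fh.write(f"MODEL {m_idx:8d}\n")
            for i in range(len(s)):
                rec = "HETATM" if (s.hetatm and s.hetatm[i]) else "ATOM  "
                x, y, z = s.coords[i]
                fh.write(
                    f"{rec}{i + 1:5d} {s.names[i]:<4.4s}"
                    f"{s.residue_names[i]:>4.3s} {s.chain_ids[i]:1.1s}"
                    f"{s.residue_ids[i]:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {s.elements[i]:>2.2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def structure_from_snapshot(snapshot: Snapshot, roles=None) -> Structure:
    """Map a toy-system snapshot to a bead Structure (one residue per bead).

    Beads named by role: ligand beads become HETATM ``LIG`` entries.
    """
    coords = snapshot.coords
    if coords.shape[1] != 3:
        pad = np.zeros((coords.shape[0], 3))
        pad[:, : coords.shape[1]] = coords
        coords = pad
    n = coords.shape[0]
    role_of = {}
    for role, idx in (roles or {}).items():
        if role in ("ligand", "gate"):
            for i in np.asarray(idx):
                role_of[int(i)] = role
    names, res_names, het = [], [], []
    for i in range(n):
        role = role_of.get(i, "receptor")
        if role == "ligand":
            names.append("L")
            res_names.append("LIG")
            het.append(True)
        elif role == "gate":
            names.append("G")
            res_names.append("GAT")
            het.append(False)
        else:
            names.append("R")
            res_names.append("REC")
            het.append(False)
    return Structure(
        names=names,
        residue_names=res_names,
        residue_ids=list(range(1, n + 1)),
        chain_ids=["A"] * n,
        coords=coords.copy(),
        elements=["C"] * n,
        hetatm=het,
    )


# ---------------------------------------------------------------------------
# Ensemble container (HDF5)
# ---------------------------------------------------------------------------


def write_ensemble(
    path, snapshots, system_id="toy", config_hash="", weights=None, T=None
):
    coords = np.stack([s.coords for s in snapshots])
    with h5py.File(path, "w") as h5:
        h5.attrs["system_id"] = system_id
        h5.attrs["config_hash"] = config_hash
        for key, v in UNITS.items():
            h5.attrs[f"unit_{key}"] = v
        g = h5.create_group("frames")
        g.create_dataset("coords", data=coords)
        g.create_dataset("energy", data=np.array([s.energy for s in snapshots]))
        g.create_dataset("traj_id", data=np.array([s.traj_id for s in snapshots]))
        g.create_dataset("step", data=np.array([s.step for s in snapshots]))
        if weights is not None:
            w = h5.create_group("weights")
            w.create_dataset("weights", data=np.asarray(weights, dtype=float))
            w.attrs["T"] = float(T if T is not None else 0.0)


def read_ensemble(path):
    """Returns (snapshots, meta dict, weights-or-None, T-or-None)."""
    with h5py.File(path, "r") as h5:
        coords = h5["frames/coords"][...]
        energy = h5["frames/energy"][...]
        traj_id = h5["frames/traj_id"][...]
        step = h5["frames/step"][...]
        meta = dict(h5.attrs)
        weights = None
        T = None
        if "weights" in h5:
            weights = h5["weights/weights"][...]
            T = float(h5["weights"].attrs["T"])
    n_frames = {coords.shape[0], energy.size, traj_id.size, step.size}
    if len(n_frames) != 1:
        raise ParseError(f"{path}: inconsistent frame counts across blocks")
    snaps = [
        Snapshot(coords[i], float(energy[i]), int(traj_id[i]), int(step[i]))
        for i in range(coords.shape[0])
    ]
    return snaps, meta, weights, T


# ---------------------------------------------------------------------------
# Bias and weight tables (text)
# ---------------------------------------------------------------------------


def write_bias(bias: BiasFunction, path, config_hash=""):
    with open(path, "w") as fh:
        fh.write(f"# T_low={bias.T_low} T_high={bias.T_high} T_ref={bias.T_ref} "
                 f"interpolation={bias.interpolation}\n")
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        fh.write("# energy_knot_kcal_mol bias_kcal_mol\n")
        for e, b in zip(bias.energy_knots, bias.bias_values):
            fh.write(f"{float(e)!r} {float(b)!r}\n")


def read_bias(path) -> BiasFunction:
    header = {}
    knots, vals = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        header[k] = v
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"line {lineno}: expected two columns")
            try:
                knots.append(float(parts[0]))
                vals.append(float(parts[1]))
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric bias entry")
    return BiasFunction(
        np.array(knots),
        np.array(vals),
        T_low=float(header.get("T_low", 300.0)),
        T_high=float(header.get("T_high", 700.0)),
        T_ref=float(header.get("T_ref", 300.0)),
        interpolation=header.get("interpolation", "linear"),
    )


def write_weights(weights, T, path, config_hash=""):
    weights = np.asarray(weights, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"# T={float(T)!r} checksum={float(weights.sum())!r}\n")
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        for i, w in enumerate(weights):
            fh.write(f"{i} {float(w)!r}\n")


def read_weights(path):
    """Returns (weights, T); verifies the normalization checksum."""
    T = None
    checksum = None
    idx, vals = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("T="):
                        T = float(tok[2:])
                    elif tok.startswith("checksum="):
                        checksum = float(tok[9:])
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"line {lineno}: expected two columns")
            idx.append(int(parts[0]))
            vals.append(float(parts[1]))
    w = np.array(vals)[np.argsort(idx)]
    if checksum is not None and abs(w.sum() - checksum) > 1e-12:
        raise ParseError(f"{path}: weight checksum mismatch")
    return w, T


# ---------------------------------------------------------------------------
# CSV reports
# ---------------------------------------------------------------------------


def write_report_csv(df: pd.DataFrame, path, config_hash=""):
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_report_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def cluster_table(clusters, projection, extra: dict | None = None) -> pd.DataFrame:
    """Cluster summary: CFE, population and PC coordinates of representatives.

    ``extra`` maps column name → per-cluster values (e.g. RASA, R(exp),
    RMSD against a supplied reference).
    """
    rows = []
    for k, c in enumerate(clusters, start=1):
        pc = projection.pc_coords[c.representative_index]
        rows.append(
            {
                "cluster": f"r{k}",
                "CFE_kcal_mol": c.cfe,
                "population": c.population,
                "PC1": pc[0],
                "PC2": pc[1],
                "n_members": c.member_indices.size,
                "representative_index": c.representative_index,
            }
        )
    df = pd.DataFrame(rows)
    for name, values in (extra or {}).items():
        df[name] = values
    return df


def validation_table(report) -> pd.DataFrame:
    return pd.DataFrame(report.to_records())


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


_BUILDERS = {
    "harmonic": make_harmonic,
    "double_well": make_double_well,
    "mueller_like_2d": make_mueller,
    "gated_pocket": make_gated_pocket,
}


def build_system(cfg: dict) -> ToySystem:
    """Build a ToySystem from the ``system`` section of a config."""
    sc = dict(cfg.get("system", cfg))
    pot = sc.pop("potential_id", None)
    if pot not in _BUILDERS:
        raise InputError(f"unknown potential_id {pot!r}")
    if pot == "mueller_like_2d":
        return make_mueller(**sc)
    return _BUILDERS[pot](**sc)


def build_schedule(cfg: dict, seed=None) -> SamplingSchedule:
    sc = dict(cfg.get("schedule", {}))
    if seed is not None:
        sc["seed"] = int(seed)
    return SamplingSchedule(**sc)
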