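"""Readers/writers for on-disk artifacts and run configuration.

Table formats are UTF-8 TSV with a single header line ('.' decimal
separator).  Coordinates are right-handed Cartesian in nm.  Chain indices
are 1-based; linker *i* connects nucleosomes *i* and *i + 1* of the same
array.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("nucleofold")

UNIT_NORM_TOL = 1e-6

POSE_COLUMNS = [
    "sample_id",
    "tomogram_id",
    "array_id",
    "nuc_index",
    "x_nm",
    "y_nm",
    "z_nm",
    "nx",
    "ny",
    "nz",
    "near_boundary",
    "linker_to_next_resolved",
]

PATH_COLUMNS = ["array_id", "linker_index", "S_bp", "E_bp", "resolved", "points"]


class FormatError(ValueError):
    """Raised when an input file does not match the documented layout."""


class ValidationError(ValueError):
    """Raised when file contents violate a table invariant."""


# ---------------------------------------------------------------------------
# pose tables


@dataclass
class PoseTable:
    """One record per fitted nucleosome (centroid + fitted-plane normal)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        validate_pose_frame(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def centroids(self) -> np.ndarray:
        return self.df[["x_nm", "y_nm", "z_nm"]].to_numpy(float)

    def normals(self) -> np.ndarray:
        return self.df[["nx", "ny", "nz"]].to_numpy(float)

    def array_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["array_id"]))


@dataclass
class PathTable:
    """One record per traced open-DNA stretch (polyline + peel annotations)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        validate_path_frame(self.df)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class Scene:
    """A collection of nucleosome arrays from one sample/condition."""

    poses: PoseTable
    paths: PathTable | None = None
    name: str = "scene"

    def __len__(self) -> int:
        return len(self.poses)


def validate_pose_frame(df: pd.DataFrame) -> None:
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pose table is missing column(s): {missing}")
    xyz = df[["x_nm", "y_nm", "z_nm"]].to_numpy(float)
    if not np.isfinite(xyz).all():
        rows = np.where(~np.isfinite(xyz).all(axis=1))[0]
        raise ValidationError(f"non-finite centroid at row(s) {rows.tolist()}")
    nrm = np.linalg.norm(df[["nx", "ny", "nz"]].to_numpy(float), axis=1)
    bad = np.where(np.abs(nrm - 1.0) > max(UNIT_NORM_TOL, 1e-6) * 10)[0]
    # tolerance is relaxed one order for text round-trips; exact-unit vectors
    # written at full precision always pass
    if bad.size:
        raise ValidationError(
            f"plane_normal is not unit length at row(s) {bad.tolist()} "
            f"(norms {nrm[bad][:5].tolist()})"
        )
    for array_id, sub in df.groupby("array_id", sort=False):
        idx = np.sort(sub["nuc_index"].to_numpy(int))
        if len(np.unique(idx)) != len(idx):
            raise ValidationError(f"duplicate nuc_index in array {array_id!r}")
        if not np.array_equal(idx, np.arange(idx[0], idx[0] + len(idx))) or idx[0] != 1:
            raise ValidationError(
                f"nuc_index not contiguous from 1 in array {array_id!r}: {idx.tolist()}"
            )


def validate_path_frame(df: pd.DataFrame) -> None:
    missing = [c for c in PATH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"path table is missing column(s): {missing}")
    if (df["S_bp"].to_numpy(float) < 0).any() or (df["E_bp"].to_numpy(float) < 0).any():
        raise ValidationError("S_bp and E_bp must be >= 0")
    for i, rec in df.iterrows():
        if rec["resolved"] and len(parse_points(rec["points"])) < 2:
            raise ValidationError(f"resolved linker with <2 polyline points at row {i}")


def parse_points(text: str) -> np.ndarray:
    """Parse the ';'-separated 'x,y,z' polyline serialization."""
    if not isinstance(text, str) or not text.strip():
        return np.zeros((0, 3))
    pts = [tuple(float(v) for v in chunk.split(",")) for chunk in text.split(";")]
    return np.asarray(pts, dtype=float)


def format_points(points: np.ndarray) -> str:
    return ";".join(",".join(repr(float(v)) for v in p) for p in np.asarray(points))


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tomogram_id": str, "array_id": str})
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; expected {list(columns)}")
    for col in df.columns:
        if df[col].dtype == object and set(df[col].dropna().unique()) <= {"True", "False"}:
            df[col] = df[col] == "True"
    return df


def read_pose_table(path: str | Path) -> PoseTable:
    """Read and validate a nucleosome pose TSV."""
    return PoseTable(_read_tsv(path, POSE_COLUMNS))


def write_pose_table(table: PoseTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_path_table(path: str | Path) -> PathTable:
    """Read and validate a traced open-DNA path TSV."""
    return PathTable(_read_tsv(path, PATH_COLUMNS))


def write_path_table(table: PathTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# multi-model PDB ensembles

_KIND_TO_ATOM = {
    "core": ("C", "CA"),
    "linker": ("P", "P"),
    "tail": ("N", "NT"),
    "lh": ("O", "OL"),
}
_ATOM_TO_KIND = {v[1]: k for k, v in _KIND_TO_ATOM.items()}


def write_ensemble_pdb(ensemble, path: str | Path) -> None:
    """Write sampled configurations as a multi-model pseudo-atom PDB.

    One MODEL per configuration (always, also for a single frame);
    coordinates in Angstrom (nm x 10); pseudo-atoms typed by bead kind
    (core, linker, tail, lh).
    """
    frames = np.asarray(ensemble.frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("ensemble must contain at least one configuration")
    kinds = list(ensemble.bead_kinds)
    n_atoms = frames.shape[1]
    if len(kinds) != n_atoms:
        raise ValueError("bead_kinds length does not match frame width")
    with open(path, "w") as fh:
        for m, frame in enumerate(frames, start=1):
            fh.write(f"MODEL {m:>8d}\n")
            for i, (kind, xyz) in enumerate(zip(kinds, frame), start=1):
                element, name = _KIND_TO_ATOM[kind]
                x, y, z = (float(v) * 10.0 for v in xyz)
                fh.write(
                    f"HETATM{i % 100000:>5d} {name:<4s}{kind[:3].upper():>4s}"
                    f" A{i % 10000:>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_ensemble_pdb(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read back a multi-model bead PDB; returns (frames in nm, bead kinds)."""
    frames: list[list[list[float]]] = []
    kinds: list[str] = []
    current: list[list[float]] | None = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("MODEL"):
            current = []
        elif line.startswith("ENDMDL"):
            frames.append(current)
            current = None
        elif line.startswith(("ATOM", "HETATM")) and current is not None:
            current.append(
                [
                    float(line[30:38]) / 10.0,
                    float(line[38:46]) / 10.0,
                    float(line[46:54]) / 10.0,
                ]
            )
            if len(frames) == 0:
                kinds.append(_ATOM_TO_KIND.get(line[12:16].strip(), "core"))
    if not frames:
        raise FormatError(f"{path}: no MODEL blocks found")
    return np.asarray(frames, dtype=float), kinds


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Effective run configuration with defaults for every knob."""

    seed: int = 0
    samples: tuple[str, ...] = ("PN1", "PN56")
    # analysis thresholds (nm / deg)
    contact_nm: float = 11.0
    trans_nm: float = 28.0
    boundary_nm: float = 5.0
    stack_para_deg: float = 25.0
    stack_n_nm: float = 8.0
    stem_nm: float = 2.5
    # simulator parameters
    nacl_mm: float = 150.0
    mg: bool = False
    lh_per_nucleosome: float = 1.0
    replicates: int = 20
    ensemble_size: int = 2000
    burn_in_sweeps: int = 2000
    sweeps_per_frame: int = 10
    bead_move_nm: float = 0.6
    core_move_nm: float = 1.0
    core_rot_deg: float = 20.0
    pivot_fraction: float = 0.02
    literal_kappa: bool = False

    def __post_init__(self) -> None:
        for name in ("contact_nm", "trans_nm", "boundary_nm", "stack_para_deg",
                     "stack_n_nm", "stem_nm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be > 0")
        if self.ensemble_size < 1:
            raise ValidationError("ensemble_size must be >= 1")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_CONFIG_SECTIONS = ("analysis", "simulator")


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; unknown keys are rejected with the valid key list.

    An empty/missing file yields the all-defaults config.  A missing seed
    falls back to the default seed with a logged warning.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise FormatError("config file must contain a YAML mapping")
            raw = dict(loaded)
    flat: dict = {}
    for section in _CONFIG_SECTIONS:
        sub = raw.pop(section, None)
        if sub:
            if not isinstance(sub, dict):
                raise FormatError(f"config section {section!r} must be a mapping")
            flat.update(sub)
    flat.update(raw)
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(flat) - valid)
    if unknown:
        raise FormatError(
            f"unknown config key(s) {unknown}; valid keys: {sorted(valid)}"
        )
    if "samples" in flat:
        flat["samples"] = tuple(flat["samples"])
    if "seed" not in flat:
        logger.warning("no seed in config; using default seed %d", RunConfig.seed)
    cfg = RunConfig(**flat)
    logger.info("effective config hash=%s seed=%d", cfg.hash(), cfg.seed)
    return cfg
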