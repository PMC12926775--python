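"""Domain types, file readers/writers, configuration, and logging.

The canonical interchange format is a long ("tidy") scan table with one row
per scan × unit, where a unit is either a named ROI (``core``/``control``)
or a vertex index on a common surface mesh.  Columns::

    participant,timepoint,day,session,scan,unit_type,unit,thickness_mm,rmspm

ROI masks travel as FreeSurfer label-format text files (0-based vertex
indices).  Configuration is YAML or JSON with a fixed key set.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("clusterscan")

SCAN_TABLE_COLUMNS = [
    "participant",
    "timepoint",
    "day",
    "session",
    "scan",
    "unit_type",
    "unit",
    "thickness_mm",
    "rmspm",
]

#: key columns whose combination must be unique per row
_KEY_COLUMNS = ["participant", "timepoint", "day", "session", "scan", "unit_type", "unit"]


def setup_logging(level: str = "INFO") -> None:
    """Configure package logging to stderr at the given level."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


class ValidationError(ValueError):
    """An input violates a documented invariant; the message names the offender."""


@dataclass(frozen=True)
class MeshGraph:
    """Undirected surface mesh: vertex count, edges, and a parcel lookup.

    Supports connected-component cluster extraction and parcel-based ROI
    construction; geometry (coordinates, areas) is deliberately absent.
    """

    n_vertices: int
    edges: np.ndarray  # (m, 2) int array, undirected
    parcel_of: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        object.__setattr__(self, "edges", edges)
        if edges.size and (edges.min() < 0 or edges.max() >= self.n_vertices):
            raise ValidationError("mesh edge endpoint out of range")
        if edges.size and (edges[:, 0] == edges[:, 1]).any():
            raise ValidationError("mesh contains a self-loop")

    def parcel_vertices(self, parcel: str) -> np.ndarray:
        return np.array(sorted(v for v, p in self.parcel_of.items() if p == parcel), dtype=int)

    @classmethod
    def from_tsv(cls, edges_path: str | Path, parcels_path: str | Path | None = None,
                 n_vertices: int | None = None) -> "MeshGraph":
        """Read edges from a two-column TSV and (optionally) a vertex→parcel TSV."""
        edges = pd.read_csv(edges_path, sep="\t", header=None).to_numpy(dtype=int)
        parcel_of: dict[int, str] = {}
        if parcels_path is not None:
            pt = pd.read_csv(parcels_path, sep="\t", header=None, names=["vertex", "parcel"])
            parcel_of = dict(zip(pt["vertex"].astype(int), pt["parcel"].astype(str)))
        if n_vertices is None:
            candidates = [edges.max() + 1 if edges.size else 0]
            if parcel_of:
                candidates.append(max(parcel_of) + 1)
            n_vertices = max(candidates)
        return cls(n_vertices=n_vertices, edges=edges, parcel_of=parcel_of)

    def to_tsv(self, edges_path: str | Path, parcels_path: str | Path | None = None) -> None:
        pd.DataFrame(self.edges).to_csv(edges_path, sep="\t", header=False, index=False)
        if parcels_path is not None:
            pd.DataFrame(sorted(self.parcel_of.items())).to_csv(
                parcels_path, sep="\t", header=False, index=False)


@dataclass
class ClusterScanDataset:
    """Long-format repeated thickness measurements with the nested design.

    Each row is one scan × unit observation.  The nesting is
    timepoint → day → session → scan; ROI-unit rows of the same scan share
    that scan's acquisition (and hence its motion score and any scan-level
    random effect).
    """

    table: pd.DataFrame
    timepoint_order: tuple[str, ...] = ()

    def __post_init__(self):
        df = self.table
        missing = [c for c in SCAN_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"scan table missing column(s): {missing}")
        bad = df.index[~(pd.to_numeric(df["thickness_mm"], errors="coerce") > 0)]
        if len(bad):
            raise ValidationError(f"non-positive or unparseable thickness at row {bad[0]}")
        badm = df.index[pd.to_numeric(df["rmspm"], errors="coerce") < 0]
        if len(badm):
            raise ValidationError(f"negative motion score at row {badm[0]}")
        dup = df.duplicated(subset=_KEY_COLUMNS)
        if dup.any():
            raise ValidationError(
                f"duplicate (participant,timepoint,day,session,scan,unit) key at row "
                f"{df.index[dup][0]}")
        if not self.timepoint_order:
            # order of first appearance defines the strict timepoint order
            self.timepoint_order = tuple(pd.unique(df["timepoint"]))
        df["timepoint"] = pd.Categorical(df["timepoint"], categories=self.timepoint_order,
                                         ordered=True)
        df["thickness_mm"] = df["thickness_mm"].astype(float)
        df["rmspm"] = df["rmspm"].astype(float)

    @property
    def design(self) -> tuple[int, int, int, int]:
        """(n_timepoints, max days/timepoint, max sessions/day, max scans/session)."""
        df = self.table
        n_tp = df["timepoint"].nunique()
        n_day = df.groupby("timepoint", observed=True)["day"].nunique().max()
        n_sess = df.groupby(["timepoint", "day"], observed=True)["session"].nunique().max()
        n_scan = (df.groupby(["timepoint", "day", "session"], observed=True)["scan"]
                  .nunique().max())
        return int(n_tp), int(n_day), int(n_sess), int(n_scan)

    @property
    def n_scans(self) -> int:
        return self.table.groupby(
            ["participant", "timepoint", "day", "session", "scan"], observed=True).ngroups

    def scans_per_timepoint(self) -> pd.Series:
        return (self.table.drop_duplicates(["participant", "timepoint", "day", "session", "scan"])
                .groupby("timepoint", observed=True).size())

    def roi_subset(self, roi: str) -> pd.DataFrame:
        df = self.table
        return df[(df["unit_type"] == "roi") & (df["unit"] == roi)].copy()


def read_scan_table(path: str | Path) -> ClusterScanDataset:
    """Read and validate the canonical long-format scan table (CSV or TSV)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"participant": str, "timepoint": str,
                                           "scan": str, "unit_type": str, "unit": str})
    return ClusterScanDataset(df)


def write_scan_table(dataset: ClusterScanDataset, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    out = dataset.table.copy()
    out["timepoint"] = out["timepoint"].astype(str)
    out[SCAN_TABLE_COLUMNS].to_csv(path, sep=sep, index=False)


def read_wide_vertex_table(path: str | Path) -> ClusterScanDataset:
    """Alternate reader: wide per-vertex matrix → the same internal dataset.

    Expected TSV layout: columns ``participant,timepoint,day,session,scan,rmspm``
    followed by one ``v<k>`` column per vertex.
    """
    df = pd.read_csv(path, sep="\t", dtype={"participant": str, "timepoint": str, "scan": str})
    meta = ["participant", "timepoint", "day", "session", "scan", "rmspm"]
    vcols = [c for c in df.columns if c not in meta]
    long = df.melt(id_vars=meta, value_vars=vcols, var_name="unit",
                   value_name="thickness_mm")
    long["unit"] = long["unit"].str.lstrip("v")
    long["unit_type"] = "vertex"
    return ClusterScanDataset(long[SCAN_TABLE_COLUMNS].copy())


# ---------------------------------------------------------------------------
# FreeSurfer label format (text): comment line, count line, then
# "<vertex> <x> <y> <z> <value>" rows.  Vertex indices are 0-based.

def read_label_mask(path: str | Path):
    """Read a FreeSurfer label-format text file into an :class:`ROIMask`."""
    from clusterscan.roi import ROIMask

    lines = Path(path).read_text().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 2 or not lines[0].startswith("#"):
        raise ValidationError(f"{path}: not a label file (missing comment header)")
    count = int(lines[1].split()[0])
    rows = lines[2:]
    if len(rows) != count:
        raise ValidationError(
            f"{path}: declared {count} vertices but found {len(rows)} rows")
    vertices = frozenset(int(r.split()[0]) for r in rows)
    if len(vertices) != count:
        raise ValidationError(f"{path}: duplicate vertex rows")
    name = Path(path).stem.replace(".label", "")
    return ROIMask(name=name, vertices=vertices, source={"path": str(path)})


def write_label_mask(mask, path: str | Path) -> None:
    """Write an ROI mask as a FreeSurfer label file (coordinates zero-filled)."""
    verts = sorted(mask.vertices)
    lines = [f"#!ascii label, clusterscan mask '{mask.name}'", f"{len(verts)}"]
    lines += [f"{v}  0.000  0.000  0.000 0.0000000000" for v in verts]
    Path(path).write_text("\n".join(lines) + "\n")
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps({"name": mask.name, "n_vertices": len(verts),
                                   "source": mask.source}, indent=2,
                                  default=str))


# ---------------------------------------------------------------------------
# Normative cohort table

@dataclass
class NormativeCohortTable:
    """Control-cohort thickness with age (years) and sex (0=female, 1=male).

    ``thickness`` is (n_subjects, n_units); units are ROI names or vertex
    indices, carried in ``unit_names``.
    """

    age: np.ndarray
    sex: np.ndarray
    thickness: np.ndarray
    unit_names: tuple = ()

    def __post_init__(self):
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=int)
        self.thickness = np.atleast_2d(np.asarray(self.thickness, dtype=float))
        n = len(self.age)
        if self.thickness.shape[0] != n or len(self.sex) != n:
            raise ValidationError("cohort arrays have inconsistent subject counts")
        if n < 4:
            raise ValidationError("normative regression needs >= 4 subjects (3 parameters)")
        if not set(np.unique(self.sex)) <= {0, 1}:
            raise ValidationError("sex must be coded 0 (female) / 1 (male)")
        if len(set(self.sex)) == 1 and len(set(self.age)) == 1:
            raise ValidationError("degenerate cohort: single age and single sex")
        if not self.unit_names:
            self.unit_names = tuple(range(self.thickness.shape[1]))

    @property
    def n_subjects(self) -> int:
        return len(self.age)

    @classmethod
    def from_csv(cls, path: str | Path) -> "NormativeCohortTable":
        """Columns: subject, age, sex, then one thickness column per unit."""
        df = pd.read_csv(path)
        ucols = [c for c in df.columns if c not in ("subject", "age", "sex")]
        return cls(age=df["age"].to_numpy(), sex=df["sex"].to_numpy(),
                   thickness=df[ucols].to_numpy(), unit_names=tuple(ucols))

    def to_csv(self, path: str | Path) -> None:
        meta = pd.DataFrame({"subject": [f"C{i:03d}" for i in range(self.n_subjects)],
                             "age": self.age, "sex": self.sex})
        units = pd.DataFrame(self.thickness, columns=[str(u) for u in self.unit_names])
        pd.concat([meta, units], axis=1).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Analysis configuration

@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable thresholds of the pipeline with their field defaults.

    Defaults encode the analysis constants: core-ROI W threshold −2,
    control-ROI exclusion W < −0.25, motion exclusion RMSpm > 10 mm/min,
    64-mm sphere radius for the displacement metric, 10,000 bootstrap
    replicates, and the <5%-for-2-consecutive-steps plateau rule.
    """

    w_core_threshold: float = -2.0
    w_control_exclusion: float = -0.25
    motion_threshold: float = 10.0  # mm/min
    sphere_radius: float = 64.0  # mm
    bootstrap_reps: int = 10_000
    max_scans: int = 32
    plateau_rel_tol: float = 0.05
    plateau_consecutive: int = 2
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not np.isfinite(v):
                raise ValidationError(f"config field {f.name} must be finite")
        if self.bootstrap_reps < 1:
            raise ValidationError("bootstrap_reps must be >= 1")
        if not 0 < self.plateau_rel_tol < 1:
            raise ValidationError("plateau_rel_tol must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML/JSON; unknown keys are errors."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)  # YAML is a superset of JSON
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValidationError(f"{path}: config must be a mapping")
            data.update(loaded)
    if overrides:
        data.update(overrides)
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    return AnalysisConfig(**data)
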