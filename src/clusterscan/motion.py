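"""Rigid-motion quality control: sphere-RMS displacement and scan exclusion.

During each TR a volumetric navigator estimates the head's rigid transform
relative to the first TR.  A transform (R, t) is summarized as the RMS of
the point displacement it induces over a solid sphere of radius r centered
at c — for p uniform in the sphere, displacement (R - I) p + t has mean
squared norm

    (r^2 / 5) * trace(A^T A) + || A c + t ||^2 ,  A = R - I,

because E[q] = 0 and E[q q^T] = (r^2/5) I for q = p - c.  Per-TR values are
reduced to one score per scan, RMS displacement per minute (RMSpm), and
scans with RMSpm strictly above 10 mm/min are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from clusterscan.io import ClusterScanDataset, ValidationError

DEFAULT_SPHERE_RADIUS = 64.0  # mm
DEFAULT_MOTION_THRESHOLD = 10.0  # mm/min


@dataclass
class MotionTrace:
    """Per-TR rigid transforms relative to the first TR of the scan."""

    rotations: np.ndarray  # (n_tr, 3, 3)
    translations: np.ndarray  # (n_tr, 3) mm
    tr_duration: float  # seconds

    def __post_init__(self):
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        if self.rotations.ndim != 3 or self.rotations.shape[1:] != (3, 3):
            raise ValidationError("rotations must be (n_tr, 3, 3)")
        if self.translations.shape != (self.rotations.shape[0], 3):
            raise ValidationError("translations must be (n_tr, 3)")
        if self.n_tr < 2:
            raise ValidationError("a motion trace needs >= 2 TRs")
        if self.tr_duration <= 0:
            raise ValidationError("non-positive TR duration")
        for k, R in enumerate(self.rotations):
            _check_rotation(R, f"TR {k}")

    @property
    def n_tr(self) -> int:
        return self.rotations.shape[0]

    @property
    def duration_minutes(self) -> float:
        return self.n_tr * self.tr_duration / 60.0

    @classmethod
    def from_tsv(cls, path, tr_duration: float) -> "MotionTrace":
        """Read 12 row-major transform entries per TR (3x3 rotation + translation)."""
        arr = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
        if arr.shape[1] != 12:
            raise ValidationError(f"expected 12 columns per TR, got {arr.shape[1]}")
        rot = arr[:, :9].reshape(-1, 3, 3)
        return cls(rotations=rot, translations=arr[:, 9:12], tr_duration=tr_duration)

    def to_tsv(self, path) -> None:
        flat = np.hstack([self.rotations.reshape(self.n_tr, 9), self.translations])
        pd.DataFrame(flat).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class MotionSummary:
    scan_id: str
    rmspm: float  # mm/min
    displacements: np.ndarray  # per-TR step (or to-first) displacement, mm
    excluded: bool = False
    mode: str = "framewise"

    def __post_init__(self):
        if self.rmspm < 0:
            raise ValidationError("rmspm must be >= 0")


def _check_rotation(R: np.ndarray, label: str = "") -> None:
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
        raise ValidationError(f"non-orthonormal rotation matrix {label}".strip())


def rms_displacement(rotation: np.ndarray, translation: np.ndarray,
                     radius: float = DEFAULT_SPHERE_RADIUS,
                     center: np.ndarray | None = None) -> float:
    """Closed-form RMS point displacement of a rigid transform over a solid sphere."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    _check_rotation(R)
    A = R - np.eye(3)
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    msq = (radius ** 2 / 5.0) * np.trace(A.T @ A) + np.sum((A @ c + t) ** 2)
    return float(np.sqrt(msq))


def compute_rmspm(trace: MotionTrace, radius: float = DEFAULT_SPHERE_RADIUS,
                  mode: str = "framewise", scan_id: str = "") -> MotionSummary:
    """Reduce a motion trace to one RMS-displacement-per-minute score.

    ``framewise`` (default): per-TR step k is the sphere-RMS displacement of
    the relative transform from TR k-1 to TR k; RMSpm is the summed path
    length divided by the scan duration in minutes.  ``mean-to-first``: the
    mean of per-TR displacements relative to TR 1 divided by the duration.
    The two readings of "displacement ... averaged over the duration" are
    both provided because the original metric is not fully specified; the
    mode used is recorded on the summary.
    """
    minutes = trace.duration_minutes
    if minutes <= 0:
        raise ValidationError("non-positive scan duration")
    if mode == "framewise":
        steps = np.empty(trace.n_tr - 1)
        for k in range(1, trace.n_tr):
            # relative transform TR k-1 -> k: p |-> R_k R_{k-1}^T (p - t_{k-1}) ... for
            # transforms given relative to TR 1: x_k = R_k p + t_k, so
            # x_k = R_rel x_{k-1} + t_rel with R_rel = R_k R_{k-1}^-1,
            # t_rel = t_k - R_rel t_{k-1}
            R_rel = trace.rotations[k] @ trace.rotations[k - 1].T
            t_rel = trace.translations[k] - R_rel @ trace.translations[k - 1]
            steps[k - 1] = rms_displacement(R_rel, t_rel, radius=radius)
        rmspm = steps.sum() / minutes
        disp = steps
    elif mode == "mean-to-first":
        disp = np.array([rms_displacement(trace.rotations[k], trace.translations[k],
                                          radius=radius)
                         for k in range(trace.n_tr)])
        rmspm = disp.mean() / minutes
    else:
        raise ValidationError(f"unknown RMSpm mode {mode!r}")
    return MotionSummary(scan_id=scan_id, rmspm=float(rmspm), displacements=disp,
                         mode=mode)


def filter_scans(dataset: ClusterScanDataset,
                 threshold: float = DEFAULT_MOTION_THRESHOLD
                 ) -> tuple[ClusterScanDataset, pd.DataFrame]:
    """Discard scans with RMSpm strictly greater than ``threshold``.

    Returns the filtered dataset and a QC report with per
    participant × timepoint counts, discards, and percentages.
    """
    df = dataset.table
    if df["rmspm"].isna().any():
        raise ValidationError("every scan needs a motion score before QC filtering")
    keep = df["rmspm"] <= threshold  # strict > excludes; == threshold is kept
    scan_keys = ["participant", "timepoint", "day", "session", "scan"]
    scans = df.drop_duplicates(scan_keys)[scan_keys + ["rmspm"]]
    scans = scans.assign(excluded=scans["rmspm"] > threshold)
    report = (scans.groupby(["participant", "timepoint"], observed=True)
              .agg(n_scans=("excluded", "size"), n_excluded=("excluded", "sum"))
              .reset_index())
    report["pct_excluded"] = 100.0 * report["n_excluded"] / report["n_scans"]
    report["threshold"] = threshold
    filtered = ClusterScanDataset(df[keep].reset_index(drop=True),
                                  timepoint_order=dataset.timepoint_order)
    return filtered, report
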