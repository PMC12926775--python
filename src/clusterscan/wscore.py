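"""Normative age/sex regression and W-score computation.

For every surface unit (vertex or ROI) a multiple linear regression

    T = beta0 + beta1 * age + beta2 * sex + eps

is fit by ordinary least squares on a control cohort.  A patient's observed
thickness is then standardized against the cohort's prediction:

    W = (observed - predicted) / SD

where SD is the residual standard deviation of that unit's regression.
W behaves like a covariate-adjusted z-score; more negative values mean the
cortex is thinner than expected for the participant's age and sex.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from clusterscan.io import NormativeCohortTable, ValidationError

#: residual SDs below this are treated as degenerate (exact interpolation)
DEGENERATE_SD_TOL = 1e-10


@dataclass
class NormativeModel:
    """Per-unit coefficients (beta0, beta1 age slope, beta2 sex contrast) and residual SD."""

    beta: np.ndarray  # (n_units, 3)
    resid_sd: np.ndarray  # (n_units,)
    n_subjects: int
    unit_names: tuple = ()
    sd_denominator: str = "n-p"  # or "n-1"
    degenerate: np.ndarray = field(default=None)  # bool per unit

    def __post_init__(self):
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.resid_sd = np.atleast_1d(np.asarray(self.resid_sd, dtype=float))
        if not np.all(np.isfinite(self.beta)):
            raise ValidationError("non-finite normative coefficients")
        if np.any(self.resid_sd < 0):
            raise ValidationError("negative residual SD")
        if self.degenerate is None:
            self.degenerate = self.resid_sd <= DEGENERATE_SD_TOL

    @property
    def n_units(self) -> int:
        return self.beta.shape[0]

    def predict(self, age: float, sex: int) -> np.ndarray:
        x = np.array([1.0, float(age), float(sex)])
        return self.beta @ x

    def to_json(self, path: str | Path) -> None:
        obj = {
            "beta": self.beta.tolist(),
            "resid_sd": self.resid_sd.tolist(),
            "n_subjects": self.n_subjects,
            "unit_names": [str(u) for u in self.unit_names],
            "sd_denominator": self.sd_denominator,
        }
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeModel":
        obj = json.loads(Path(path).read_text())
        return cls(beta=np.array(obj["beta"]), resid_sd=np.array(obj["resid_sd"]),
                   n_subjects=obj["n_subjects"], unit_names=tuple(obj["unit_names"]),
                   sd_denominator=obj.get("sd_denominator", "n-p"))


@dataclass
class WScoreMap:
    """Per-unit W-scores and the model-predicted thickness they derive from."""

    w: np.ndarray
    predicted: np.ndarray
    unit_names: tuple = ()

    def __post_init__(self):
        self.w = np.atleast_1d(np.asarray(self.w, dtype=float))
        self.predicted = np.atleast_1d(np.asarray(self.predicted, dtype=float))


def fit_normative(cohort: NormativeCohortTable, sd_denominator: str = "n-p") -> NormativeModel:
    """Fit the per-unit OLS normative regression on a control cohort.

    Parameters
    ----------
    cohort
        Control subjects with age, sex, and thickness per unit.
    sd_denominator
        ``"n-p"`` (default) divides the residual sum of squares by the
        residual degrees of freedom ``n - 3``; ``"n-1"`` uses the sample-SD
        convention.

    Raises
    ------
    ValidationError
        If the (1, age, sex) design matrix is rank deficient; the message
        names the collinear column.
    """
    n = cohort.n_subjects
    X = np.column_stack([np.ones(n), cohort.age, cohort.sex.astype(float)])
    rank = np.linalg.matrix_rank(X)
    if rank < 3:
        culprit = "sex" if len(set(cohort.sex)) == 1 else "age"
        raise ValidationError(
            f"normative design matrix rank deficient (rank {rank} < 3): "
            f"column '{culprit}' is collinear with the intercept")
    Y = cohort.thickness  # (n, u)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = (resid ** 2).sum(axis=0)
    if sd_denominator == "n-p":
        dof = n - 3
    elif sd_denominator == "n-1":
        dof = n - 1
    else:
        raise ValidationError(f"unknown sd_denominator {sd_denominator!r}")
    resid_sd = np.sqrt(rss / dof)
    model = NormativeModel(beta=beta.T, resid_sd=resid_sd, n_subjects=n,
                           unit_names=cohort.unit_names, sd_denominator=sd_denominator)
    if model.degenerate.any():
        warnings.warn(f"{int(model.degenerate.sum())} unit(s) have ~zero residual SD "
                      "(exact interpolation); flagged degenerate", stacklevel=2)
    return model


def compute_wscores(model: NormativeModel, age: float, sex: int,
                    thickness: np.ndarray, on_degenerate: str = "raise") -> WScoreMap:
    """Convert observed thickness to W-scores under a fitted normative model.

    ``on_degenerate`` controls units whose residual SD is ~0: ``"raise"``
    (default) or ``"nan"`` (emit NaN with a warning).
    """
    thickness = np.atleast_1d(np.asarray(thickness, dtype=float))
    if thickness.shape[0] != model.n_units:
        raise ValidationError(
            f"thickness has {thickness.shape[0]} units, model has {model.n_units}")
    predicted = model.predict(age, sex)
    deg = model.degenerate
    if deg.any():
        if on_degenerate == "raise":
            raise ValidationError(
                f"{int(deg.sum())} degenerate unit(s) (residual SD ~ 0); "
                "pass on_degenerate='nan' to emit NaN instead")
        warnings.warn(f"{int(deg.sum())} degenerate unit(s) set to NaN", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (thickness - predicted) / model.resid_sd
    w = np.where(deg, np.nan, w)
    return WScoreMap(w=w, predicted=predicted, unit_names=model.unit_names)
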