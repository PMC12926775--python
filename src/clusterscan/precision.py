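"""Bootstrap precision of atrophy estimates versus scans per timepoint.

How many fast scans per visit are enough?  For a pair of timepoints the
*reference atrophy rate* is the average of B bootstrap estimates of the
thickness difference, each obtained by resampling 32 scans with replacement
per timepoint.  Precision at k scans is then quantified by the mean percent
deviation of k-scan bootstrap estimates from that reference:

    deviation_b = 100 * | estimate_b - reference | / reference .

The deviation curve over k = 1..32 falls with diminishing returns; the
recommended scan count is the first k where the reduction in deviation is
below 5% of the immediately preceding value for two consecutive steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from clusterscan.io import ValidationError

DEFAULT_B = 10_000
DEFAULT_N_REFERENCE = 32  # scans resampled per timepoint for the reference rate
REFERENCE_TOL = 1e-8


@dataclass
class PrecisionCurve:
    """Mean percent deviation (with IQR) per scan count, plus the plateau."""

    interval: str
    reference_rate: float  # mm; positive = thinning
    k_values: np.ndarray
    mean_deviation: np.ndarray  # percent
    q1: np.ndarray
    q3: np.ndarray
    B: int = DEFAULT_B
    seed: int | None = None
    plateau_k: int | None = None
    plateau_deviation: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.mean_deviation = np.asarray(self.mean_deviation, dtype=float)
        if np.any(self.mean_deviation < 0):
            raise ValidationError("percent deviations must be >= 0")
        if len(self.k_values) != len(self.mean_deviation):
            raise ValidationError("curve arrays must align")


def reference_rate(reference_values: np.ndarray, followup_values: np.ndarray,
                   B: int = DEFAULT_B, n_resample: int = DEFAULT_N_REFERENCE,
                   rng: np.random.Generator | None = None,
                   seed: int | None = None) -> float:
    """Bootstrap reference atrophy rate between two timepoints.

    Each of the B estimates is mean(resampled reference) − mean(resampled
    follow-up) with ``n_resample`` (default 32) scans drawn with replacement
    per timepoint — even when fewer scans survived QC, resampling draws from
    what exists.  Positive values mean thinning.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    ref = np.asarray(reference_values, dtype=float)
    fol = np.asarray(followup_values, dtype=float)
    if len(ref) < 1 or len(fol) < 1:
        raise ValidationError("need >= 1 scan per timepoint")
    if rng is None:
        rng = np.random.default_rng(seed)
    i_ref = rng.integers(0, len(ref), size=(B, n_resample))
    i_fol = rng.integers(0, len(fol), size=(B, n_resample))
    estimates = ref[i_ref].mean(axis=1) - fol[i_fol].mean(axis=1)
    return float(estimates.mean())


def deviation_curve(reference_values: np.ndarray, followup_values: np.ndarray,
                    k_range=range(1, 33), B: int = DEFAULT_B,
                    seed: int | None = None, interval: str = "",
                    n_reference: int = DEFAULT_N_REFERENCE,
                    rel_tol: float = 0.05, consecutive: int = 2
                    ) -> PrecisionCurve:
    """Bootstrap percent-deviation curve over scans per timepoint.

    Fresh bootstrap draws are taken for every k (recorded in ``meta``).
    Fails when the reference rate is ~0 (percent deviation undefined —
    typically a control ROI with no decline; use the core ROI).
    """
    rng = np.random.default_rng(seed)
    ref_rate = reference_rate(reference_values, followup_values, B=B,
                              n_resample=n_reference, rng=rng)
    if abs(ref_rate) < REFERENCE_TOL:
        raise ValidationError(
            "reference atrophy rate is ~0; percent deviation is undefined "
            "(this usually means a no-decline ROI — use the core ROI)")
    ref = np.asarray(reference_values, dtype=float)
    fol = np.asarray(followup_values, dtype=float)
    k_values = list(k_range)
    mean_dev, q1s, q3s = [], [], []
    for k in k_values:
        i_ref = rng.integers(0, len(ref), size=(B, k))
        i_fol = rng.integers(0, len(fol), size=(B, k))
        est = ref[i_ref].mean(axis=1) - fol[i_fol].mean(axis=1)
        dev = 100.0 * np.abs(est - ref_rate) / abs(ref_rate)
        mean_dev.append(dev.mean())
        q1s.append(np.percentile(dev, 25))
        q3s.append(np.percentile(dev, 75))
    curve = PrecisionCurve(interval=interval, reference_rate=ref_rate,
                           k_values=np.array(k_values),
                           mean_deviation=np.array(mean_dev),
                           q1=np.array(q1s), q3=np.array(q3s), B=B, seed=seed,
                           meta={"fresh_draws_per_k": True,
                                 "n_reference": n_reference})
    if len(k_values) >= consecutive + 1:
        k_p, dev_p = detect_plateau(curve, rel_tol=rel_tol,
                                    consecutive=consecutive)
    else:  # too few scan counts to ever see sustained diminishing returns
        k_p, dev_p = None, None
    curve.plateau_k, curve.plateau_deviation = k_p, dev_p
    return curve


def detect_plateau(curve: PrecisionCurve | np.ndarray, rel_tol: float = 0.05,
                   consecutive: int = 2) -> tuple[int | None, float | None]:
    """First scan count with sustained diminishing returns.

    Returns the smallest K whose last ``consecutive`` steps each reduced the
    deviation by less than ``rel_tol`` of the immediately preceding value
    (an *increase* in deviation also qualifies), together with the deviation
    at K; ``(None, None)`` when the curve never plateaus.
    """
    if isinstance(curve, PrecisionCurve):
        dev = curve.mean_deviation
        ks = curve.k_values
    else:
        dev = np.asarray(curve, dtype=float)
        ks = np.arange(1, len(dev) + 1)
    if len(dev) < consecutive + 1:
        raise ValidationError(f"curve needs >= {consecutive + 1} points")
    qualifies = (dev[:-1] - dev[1:]) < rel_tol * dev[:-1]
    run = 0
    for i, ok in enumerate(qualifies):
        run = run + 1 if ok else 0
        if run >= consecutive:
            return int(ks[i + 1]), float(dev[i + 1])
    return None, None


def plot_curve(curve: PrecisionCurve, path) -> None:
    """IQR-banded percent-deviation plot (one panel per interval)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.k_values, curve.mean_deviation, color="C0", lw=1.5)
    ax.fill_between(curve.k_values, curve.q1, curve.q3, color="C0", alpha=0.25)
    if curve.plateau_k is not None:
        ax.axvline(curve.plateau_k, color="C3", ls="--", lw=1)
    ax.set_xlabel("scans per timepoint")
    ax.set_ylabel("percent deviation")
    ax.set_title(curve.interval or "precision curve")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
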