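"""Per-vertex mixed models inside the core mask with a singular-fit cascade.

Each vertex inside the core ROI gets its own longitudinal model (Timepoint
+ motion; no ROI factor, since the analysis runs within a single mask).
Estimation starts from the full nested random-intercept structure; on a
singular fit the model is refit with scan-only intercepts, and if that is
singular too, with fixed effects only:

    model_code 2 = nested day/session/scan, 1 = scan-only, 0 = fixed-only.

From each vertex's estimated marginal means, percent-change maps are built
for the three timepoint pairs.  A vertex's change for a pair is flagged
significant when the Timepoint main effect has p < .05 AND the pairwise
contrast has p < .05/3 (Bonferroni over the three pairs); no further
adjustment over vertices is applied.  Vertices where no model converges are
reported as explicit gaps, never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from clusterscan.io import ValidationError
from clusterscan.lme import (ConvergenceError, LMEFit, LMEModelSpec,
                             anova_fixed_effects, estimated_marginal_means,
                             fit_lme, pairwise_contrasts, percent_change,
                             timepoint_pairs)
from clusterscan.roi import ROIMask

#: vertex-model cascade, most to least complex
_CASCADE = (
    (2, LMEModelSpec(include_roi=False, random="nested", strata=())),
    (1, LMEModelSpec(include_roi=False, random="scan", strata=())),
    (0, LMEModelSpec(include_roi=False, random="none", strata=())),
)


@dataclass
class VertexChangeMap:
    """Per-vertex percent change, p-values, significance flags, model codes."""

    table: pd.DataFrame  # vertex, pair, pct_change, p_main, p_pair, significant, model_code
    alpha_main: float = 0.05
    alpha_pair: float = 0.05 / 3

    def for_pair(self, pair_label: str) -> pd.DataFrame:
        return self.table[self.table["pair"] == pair_label]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def fit_vertex_cascade(vertex_df: pd.DataFrame, seed: int = 0
                       ) -> tuple[LMEFit | None, int]:
    """Fit one vertex's data, falling back on singular fits.

    ``vertex_df`` holds one row per scan: timepoint, day, session, scan,
    rmspm, thickness.  Returns ``(fit, model_code)``; ``(None, -1)`` when
    all three models fail to converge (the vertex becomes a gap).
    """
    for code, spec in _CASCADE:
        try:
            fit = fit_lme(vertex_df, spec, seed=seed)
        except (ConvergenceError, ValidationError):
            continue
        if code == 0 or not fit.singular:
            return fit, code
    return None, -1


def vertex_change_maps(vertex_fits: dict[int, tuple[LMEFit | None, int]],
                       alpha_main: float = 0.05,
                       alpha_pair: float = 0.05 / 3) -> VertexChangeMap:
    """Percent-change and significance maps from per-vertex fits.

    Significance per (vertex, pair): Timepoint main-effect p < ``alpha_main``
    and the pair's contrast p < ``alpha_pair``.  Percent change is relative
    to the pair's earlier (reference) timepoint, so thinning is negative.
    """
    if not any(f is not None for f, _ in vertex_fits.values()):
        raise ValidationError("no vertex produced a usable fit")
    rows = []
    for vertex, (fit, code) in sorted(vertex_fits.items()):
        if fit is None:
            continue  # explicit gap: vertex absent from the table
        emms = estimated_marginal_means(fit)
        ftab = anova_fixed_effects(fit)
        p_main = float(ftab.loc[ftab["term"] == "timepoint", "p"].iloc[0])
        pairs = timepoint_pairs(fit.tp_levels)
        contrasts = pairwise_contrasts(fit, family_size=len(pairs))
        for (earlier, later), con in zip(pairs, contrasts):
            pct = percent_change(emms, (earlier, later), None, ndigits=None)
            sig = bool(p_main < alpha_main and con.p_raw < alpha_pair)
            rows.append({"vertex": vertex, "pair": f"{earlier}-{later}",
                         "pct_change": pct, "p_main": p_main,
                         "p_pair": con.p_raw, "significant": sig,
                         "model_code": code})
    return VertexChangeMap(pd.DataFrame(rows), alpha_main=alpha_main,
                           alpha_pair=alpha_pair)


def run_vertexwise(meta: pd.DataFrame, maps: np.ndarray, mask: ROIMask,
                   seed: int = 0) -> VertexChangeMap:
    """Cascade-fit every vertex in ``mask`` from per-scan vertex maps.

    ``meta`` has one row per scan (timepoint/day/session/scan/rmspm) aligned
    with the rows of ``maps`` (n_scans, n_vertices).
    """
    if maps.shape[0] != len(meta):
        raise ValidationError("meta rows and map rows differ")
    fits: dict[int, tuple[LMEFit | None, int]] = {}
    for v in mask.index_array():
        df = meta.copy()
        df["thickness"] = maps[:, v]
        fits[int(v)] = fit_vertex_cascade(df, seed=seed)
    return vertex_change_maps(fits)
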