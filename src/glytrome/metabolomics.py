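"""Amino-acid metabolite quantification with heavy-standard calibration.

Stable-isotope-labelled ("heavy") amino-acid standards spiked before
extraction serve two purposes: a per-sample normalization factor (heavy
recovery against a pooled reference) and a concentration calibration
curve y = alpha + beta*x fitted on the best-R-squared contiguous subset
of a dilution ladder (at least five points).  Genotype contrasts use
per-amino-acid Welch t-tests with the two-stage BKY step-up at q = 1%,
and a Grubbs outlier test (alpha = 0.001) on the fold-change vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bky_adjust, grubbs_test

__all__ = [
    "CalibrationFit", "fit_calibration", "quantify_normalize",
    "amino_acid_tests",
]


@dataclass
class CalibrationFit:
    amino_acid: str
    alpha: float          # intercept (MS1 area units)
    beta: float           # slope (area per pmol)
    r_squared: float
    points_used: int
    start_index: int      # first ladder point of the accepted subset

    def concentration(self, area) -> np.ndarray:
        """Solve y = alpha + beta*x for x."""
        return (np.asarray(area, dtype=float) - self.alpha) / self.beta


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    beta, alpha = np.polyfit(x, y, 1)
    resid = y - (alpha + beta * x)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
    return alpha, beta, r2


def fit_calibration(concentrations, areas, amino_acid: str = "",
                    min_points: int = 5) -> CalibrationFit:
    """Best-R-squared linear calibration over contiguous ladder subsets.

    Ladder points are sorted by concentration; every contiguous subset of
    at least ``min_points`` is fitted by OLS and the subset with maximal
    R-squared (positive slope) is kept, which drops saturated or
    below-range ladder ends.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x.size < min_points:
        raise ValueError(f"calibration needs >= {min_points} points")
    order = np.argsort(x)
    x, y = x[order], y[order]
    best: CalibrationFit | None = None
    for i in range(0, x.size - min_points + 1):
        for j in range(i + min_points, x.size + 1):
            alpha, beta, r2 = _ols(x[i:j], y[i:j])
            if beta <= 0:
                continue
            # prefer strictly better fits; on (numerical) ties keep the
            # subset using more of the ladder
            if (best is None or r2 > best.r_squared + 1e-9
                    or (abs(r2 - best.r_squared) <= 1e-9
                        and j - i > best.points_used)):
                best = CalibrationFit(amino_acid, float(alpha), float(beta),
                                      float(r2), j - i, i)
    if best is None:
        raise ValueError("no contiguous subset with positive slope")
    return best


def quantify_normalize(areas: pd.DataFrame, pooled_heavy: pd.Series,
                       tissue_weights: pd.Series) -> pd.DataFrame:
    """Heavy-standard and tissue-weight normalization of endogenous areas.

    ``areas`` is long-form (amino_acid, sample, channel in {endogenous,
    heavy}, area).  Per sample, the normalization factor is the mean over
    amino acids of heavy area / pooled heavy area; endogenous areas are
    divided by that factor and then by tissue weight relative to the
    first sample.  Samples missing the heavy channel are excluded (count
    in ``attrs['n_excluded_samples']``).  Returns amino_acid x sample
    normalized levels.
    """
    endo = areas[areas["channel"] == "endogenous"].pivot(
        index="amino_acid", columns="sample", values="area")
    heavy = areas[areas["channel"] == "heavy"].pivot(
        index="amino_acid", columns="sample", values="area")
    excluded = [s for s in endo.columns
                if s not in heavy.columns or heavy[s].isna().any()]
    samples = [s for s in endo.columns if s not in excluded]
    ref_weight = tissue_weights.loc[samples].iloc[0]
    out = {}
    for s in samples:
        factor = (heavy[s] / pooled_heavy.reindex(heavy.index)).mean()
        out[s] = endo[s] / factor / (tissue_weights[s] / ref_weight)
    levels = pd.DataFrame(out)
    levels.attrs["n_excluded_samples"] = len(excluded)
    return levels


def amino_acid_tests(levels: pd.DataFrame,
                     groups: tuple[str, str] = ("WT", "KO"),
                     q_stage: float = 0.01, grubbs_alpha: float = 0.001,
                     ) -> pd.DataFrame:
    """Per-amino-acid genotype t-tests, BKY FDR, and fold-change outlier.

    Fold change = mean(KO)/mean(WT) of normalized levels.  q-values use
    the two-stage BKY step-up with stage parameter ``q_stage``; the
    fold-change vector across amino acids is screened with a Grubbs test
    at ``grubbs_alpha`` (skipped below 3 amino acids).
    """
    cols_a = [c for c in levels.columns if c.startswith(groups[0] + "_")]
    cols_b = [c for c in levels.columns if c.startswith(groups[1] + "_")]
    if len(cols_a) < 3 or len(cols_b) < 3:
        raise ValueError("each group needs >= 3 samples")
    a = levels[cols_a].to_numpy(dtype=float)
    b = levels[cols_b].to_numpy(dtype=float)
    t, p = sps.ttest_ind(b, a, axis=1, equal_var=False)
    fc = b.mean(axis=1) / a.mean(axis=1)
    out = pd.DataFrame({
        f"mean_{groups[0].lower()}": a.mean(axis=1),
        f"mean_{groups[1].lower()}": b.mean(axis=1),
        "fold_change": fc, "t": t, "p": p,
        "q": bky_adjust(p, q=q_stage),
    }, index=levels.index)
    out["grubbs_outlier"] = False
    if len(out) >= 3:
        res = grubbs_test(fc, alpha=grubbs_alpha)
        out.attrs["grubbs_statistic"] = res.statistic
        if res.outlier_index is not None:
            out.iloc[res.outlier_index,
                     out.columns.get_loc("grubbs_outlier")] = True
    return out
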