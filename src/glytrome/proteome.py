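"""Direction-stratified proteome analysis and amino-acid-content
comparisons.

Works from a protein x sample table of log2 intensities.  Per protein,
the t-test difference is mean(KO) - mean(WT) in log2 space; proteins are
stratified into decreased / increased / ns by BKY FDR and sign, and the
amino-acid content of each stratum is compared with two-sided
Mann-Whitney tests (decreased vs ns and increased vs ns).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bky_adjust, mann_whitney_exact

__all__ = ["protein_differential", "stratify_and_compare"]


def protein_differential(table: pd.DataFrame,
                         groups: tuple[str, str] = ("WT", "KO"),
                         q_threshold: float = 0.05) -> pd.DataFrame:
    """Per-protein Welch t-test on log2 intensities with BKY FDR strata.

    Proteins missing every value in one group are reported as ``ns`` with
    ``incomplete=True``.  Stratum: decreased/increased iff q < threshold,
    by the sign of difference = mean(alt) - mean(ref).
    """
    cols_a = [c for c in table.columns if c.startswith(groups[0] + "_")]
    cols_b = [c for c in table.columns if c.startswith(groups[1] + "_")]
    if len(cols_a) < 3 or len(cols_b) < 3:
        raise ValueError("each group needs >= 3 replicates")
    a = table[cols_a].to_numpy(dtype=float)
    b = table[cols_b].to_numpy(dtype=float)
    complete = ~(np.isnan(a).all(axis=1) | np.isnan(b).all(axis=1))
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")   # empty-group slices become NaN
        t, p = sps.ttest_ind(b, a, axis=1, equal_var=False,
                             nan_policy="omit")
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
    out = pd.DataFrame({
        f"mean_{groups[0].lower()}": mean_a,
        f"mean_{groups[1].lower()}": mean_b,
        "difference": mean_b - mean_a,
        "t": t, "p": p,
        "incomplete": ~complete,
    }, index=table.index)
    q = np.full(len(out), np.nan)
    ok = complete & np.isfinite(out["p"].to_numpy(dtype=float))
    q[ok] = bky_adjust(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    stratum = np.where(ok & (q < q_threshold) & (out["difference"] < 0),
                       "decreased",
                       np.where(ok & (q < q_threshold) & (out["difference"] > 0),
                                "increased", "ns"))
    out["stratum"] = stratum
    return out


def stratify_and_compare(differentials: pd.DataFrame,
                         content: pd.Series, amino_acid: str = "Gly",
                         subset: list[str] | None = None) -> dict:
    """Per-stratum content distributions and pairwise Mann-Whitney tests.

    ``content`` holds per-protein composition (percent) for the amino
    acid of interest.  Returns per-stratum summary (n, mean, median, IQR,
    min, max), decreased-vs-ns and increased-vs-ns two-sided p-values,
    and -- when ``subset`` is given -- the same comparison of the subset
    against the whole cohort.
    """
    shared = differentials.index.intersection(content.index)
    if len(shared) < 0.9 * len(differentials):
        raise ValueError("composition available for < 90% of proteins")
    strata = differentials.loc[shared, "stratum"]
    vals = content.loc[shared].astype(float)

    summaries = {}
    vectors = {}
    for s in ("decreased", "increased", "ns"):
        v = vals[strata == s]
        if v.empty:
            raise ValueError(f"empty stratum: {s}")
        vectors[s] = v.to_numpy()
        summaries[s] = {
            "n": int(v.size), "mean": float(v.mean()),
            "median": float(v.median()),
            "iqr": float(v.quantile(0.75) - v.quantile(0.25)),
            "min": float(v.min()), "max": float(v.max()),
        }
    out = {
        "amino_acid": amino_acid,
        "strata": summaries,
        "p_decreased_vs_ns": mann_whitney_exact(
            vectors["decreased"], vectors["ns"]).p_two_sided,
        "p_increased_vs_ns": mann_whitney_exact(
            vectors["increased"], vectors["ns"]).p_two_sided,
    }
    if subset is not None:
        sub = vals[vals.index.isin(subset)]
        if sub.empty:
            raise ValueError("empty subset")
        out["subset"] = {
            "n": int(sub.size), "median": float(sub.median()),
            "iqr": float(sub.quantile(0.75) - sub.quantile(0.25)),
            "p_vs_all": mann_whitney_exact(sub.to_numpy(),
                                           vals.to_numpy()).p_two_sided,
        }
    return out
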