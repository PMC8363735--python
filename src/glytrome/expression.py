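"""Isodecoder expression: UMI handling, CPM filters, NB exact-test
differential expression, and tRNA-fragment classification.

The differential-expression path mirrors the count-based small-RNA
convention: counts-per-million normalization, a mean-CPM >= 20 retention
filter, a conditional negative-binomial exact test with a common
method-of-moments dispersion, two-stage BKY FDR, and a |fold change| >=
1.5 call threshold on pseudo-counted CPM means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bky_adjust, estimate_dispersion_mom, nb_exact_test

__all__ = [
    "CountMatrix", "umi_extract_dedup", "cpm_and_filter", "isodecoder_de",
    "family_rollup", "fragment_class", "classify_fragments",
    "fragment_family_tests",
]


class CountMatrix:
    """Feature x sample nonnegative integer counts with a lazy CPM view.

    Sample group is the column-name prefix before '_' (e.g. WT_rep1).
    """

    def __init__(self, counts: pd.DataFrame):
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.counts = counts
        self.library_sizes = counts.sum(axis=0)
        if (self.library_sizes == 0).any():
            bad = list(self.library_sizes[self.library_sizes == 0].index)
            raise ValueError(f"zero library size in samples: {bad}")
        self._cpm: pd.DataFrame | None = None

    @property
    def cpm(self) -> pd.DataFrame:
        if self._cpm is None:
            self._cpm = self.counts / self.library_sizes * 1e6
        return self._cpm

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for col in self.counts.columns:
            out.setdefault(col.split("_")[0], []).append(col)
        return out

    def group_columns(self, group: str) -> list[str]:
        return self.groups[group]


# ------------------------------------------------------------------- UMI

from .simulate import Y3_PREFIX, Y3_SUFFIX, Y5_PREFIX, Y5_SUFFIX


def umi_extract_dedup(reads: list[tuple[str, str]],
                      ) -> tuple[pd.Series, dict]:
    """Extract both 4-nt UMIs, collapse PCR duplicates, count molecules.

    Read layout follows the forked-linker design: the 5' linker ends in
    GATC immediately followed by 4 UMI bases and a fixed spacer; the 3'
    linker starts with GTATCCAGT immediately followed by 4 UMI bases.
    Reads in which either linker pattern is missing are dropped and
    counted.  The molecule count per insert is the number of distinct
    8-nt concatenated UMI tags observed for it.
    """
    tags: dict[str, set[str]] = {}
    dropped = 0
    for _, seq in reads:
        i5 = seq.find(Y5_PREFIX)
        if i5 < 0:
            dropped += 1
            continue
        umi1_start = i5 + len(Y5_PREFIX)
        umi1 = seq[umi1_start: umi1_start + 4]
        spacer_start = umi1_start + 4
        if not seq.startswith(Y5_SUFFIX, spacer_start):
            dropped += 1
            continue
        insert_start = spacer_start + len(Y5_SUFFIX)
        i3 = seq.rfind(Y3_PREFIX)
        if i3 < insert_start:
            dropped += 1
            continue
        umi2 = seq[i3 + len(Y3_PREFIX): i3 + len(Y3_PREFIX) + 4]
        if len(umi1) < 4 or len(umi2) < 4:
            dropped += 1
            continue
        insert = seq[insert_start:i3]
        tags.setdefault(insert, set()).add(umi1 + umi2)
    counts = pd.Series({ins: len(t) for ins, t in sorted(tags.items())},
                       dtype=int, name="molecules")
    return counts, {"dropped": dropped, "parsed": len(reads) - dropped}


# --------------------------------------------------------- DE and filtering

def cpm_and_filter(matrix: CountMatrix, min_cpm: float = 20.0) -> pd.Series:
    """Retain features whose mean CPM is >= min_cpm in at least one group."""
    groups = matrix.groups
    if any(len(cols) < 2 for cols in groups.values()):
        raise ValueError("each group needs >= 2 samples")
    keep = pd.Series(False, index=matrix.counts.index)
    for cols in groups.values():
        keep |= matrix.cpm[cols].mean(axis=1) >= min_cpm
    return keep


def isodecoder_de(matrix: CountMatrix, groups: tuple[str, str] = ("WT", "KO"),
                  dispersion: float | None = None, fc_threshold: float = 1.5,
                  q_threshold: float = 0.05, min_cpm: float = 20.0,
                  ) -> pd.DataFrame:
    """Per-feature NB exact-test differential expression.

    Counts are scaled to a common library size (geometric mean); the
    common dispersion defaults to a method-of-moments estimate over the
    retained features.  logFC is sign(KO - WT) on CPM + 0.5 pseudo-counted
    group means; a feature is called significant iff BKY q < q_threshold
    and |fold change| >= fc_threshold.
    """
    ref_group, alt_group = groups
    cols_a = matrix.group_columns(ref_group)
    cols_b = matrix.group_columns(alt_group)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    keep = cpm_and_filter(matrix, min_cpm=min_cpm)
    counts = matrix.counts.loc[keep, cols_a + cols_b]
    libs = matrix.library_sizes[cols_a + cols_b]
    common = float(np.exp(np.log(libs.to_numpy()).mean()))
    scaled = np.rint(counts.to_numpy() * (common / libs.to_numpy())).astype(int)
    if dispersion is None:
        dispersion = estimate_dispersion_mom(scaled,
                                             (len(cols_a), len(cols_b)))
    n_a = len(cols_a)
    pvals = np.empty(scaled.shape[0])
    for i in range(scaled.shape[0]):
        pvals[i] = nb_exact_test(scaled[i, :n_a], scaled[i, n_a:],
                                 dispersion).p_two_sided
    cpm = matrix.cpm
    mean_a = cpm.loc[keep, cols_a].mean(axis=1)
    mean_b = cpm.loc[keep, cols_b].mean(axis=1)
    logfc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    out = pd.DataFrame({
        f"mean_cpm_{ref_group.lower()}": mean_a,
        f"mean_cpm_{alt_group.lower()}": mean_b,
        "logfc": logfc,
        "p": pvals,
    }, index=counts.index)
    out["q"] = bky_adjust(out["p"].to_numpy())
    out["significant"] = ((out["q"] < q_threshold)
                          & (np.abs(out["logfc"]) >= np.log2(fc_threshold)))
    out["direction"] = np.where(out["logfc"] < 0, "down", "up")
    out.attrs["dispersion"] = dispersion
    out.attrs["n_filtered_out"] = int((~keep).sum())
    return out


def family_rollup(de: pd.DataFrame, families: pd.Series) -> pd.DataFrame:
    """Per isoacceptor family: significant up/down counts and totals."""
    df = de.copy()
    df["family"] = families.reindex(de.index)
    rows = []
    for fam, sub in df.groupby("family"):
        sig = sub["significant"]
        rows.append((fam, len(sub), int(sig.sum()),
                     int((sig & (sub["direction"] == "down")).sum()),
                     int((sig & (sub["direction"] == "up")).sum())))
    return pd.DataFrame(rows, columns=["family", "n_isodecoders",
                                       "n_significant", "n_sig_down",
                                       "n_sig_up"]).set_index("family")


# ------------------------------------------------------------- tRF classes

def fragment_class(end: str, length: int) -> str:
    """Length-window class of a tRNA-derived fragment.

    3' 17-22 nt -> tRF-3; 5' 33-35 nt -> tiRNA; 5' 28-32 nt -> tRF-5c
    (a subclass of tRF-5); 5' 14-32 nt -> tRF-5; anything else is
    unclassified.
    """
    if end not in ("5'", "3'"):
        raise ValueError(f"unknown end label: {end!r}")
    if end == "3'":
        return "tRF-3" if 17 <= length <= 22 else "unclassified"
    if 33 <= length <= 35:
        return "tiRNA"
    if 28 <= length <= 32:
        return "tRF-5c"
    if 14 <= length <= 32:
        return "tRF-5"
    return "unclassified"


def classify_fragments(records: pd.DataFrame) -> pd.DataFrame:
    """Add the length-window class column to a fragment record frame."""
    out = records.copy()
    out["class"] = [fragment_class(e, l)
                    for e, l in zip(out["end"], out["length"])]
    return out


def fragment_family_tests(records: pd.DataFrame,
                          groups: tuple[str, str] = ("WT", "KO"),
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(family, class) CPM sums and per-isoacceptor t-tests.

    CPM is computed over all fragment counts per sample; fragments with
    CPM 0 in any sample are excluded.  tRF-5c rows also contribute to the
    tRF-5 tally (overlapping windows).  Returns (per-class sums, per-family
    test table).
    """
    records = classify_fragments(records)
    sample_cols = [c for c in records.columns
                   if c.startswith(tuple(g + "_" for g in groups))]
    cpm = records[sample_cols] / records[sample_cols].sum(axis=0) * 1e6
    keep = (cpm > 0).all(axis=1)
    records, cpm = records[keep], cpm[keep]

    tallies = []
    for cls in ("tRF-3", "tRF-5", "tRF-5c", "tiRNA"):
        sel = records["class"] == cls
        if cls == "tRF-5":
            sel |= records["class"] == "tRF-5c"
        grouped = cpm[sel].groupby(records.loc[sel, "family"]).sum()
        grouped.insert(0, "class", cls)
        tallies.append(grouped.reset_index())
    sums = pd.concat(tallies, ignore_index=True)

    a_cols = [c for c in sample_cols if c.startswith(groups[0] + "_")]
    b_cols = [c for c in sample_cols if c.startswith(groups[1] + "_")]
    rows = []
    for (fam, cls), sub in sums.groupby(["family", "class"]):
        a = sub[a_cols].to_numpy().ravel()
        b = sub[b_cols].to_numpy().ravel()
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append((fam, cls, a.mean(), b.mean(), float(t), float(p)))
    tests = pd.DataFrame(rows, columns=["family", "class",
                                        f"mean_cpm_{groups[0].lower()}",
                                        f"mean_cpm_{groups[1].lower()}",
                                        "t", "p"])
    return sums, tests
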