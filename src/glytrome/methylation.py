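"""Per-cytosine m5C quantification from bisulfite amplicon reads.

Bisulfite chemistry converts unmethylated C to U (read as T) while
methylated C is protected, so the per-site C fraction over aligned reads
estimates methylation.  Alignment is done in three-letter space (C and T
collapsed) so conversion status cannot bias placement; methylation is
then tallied from the original read bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats as sps

from .stats import bky_adjust
from .simulate import TRNAReferenceSet

__all__ = [
    "Alignment", "convert_and_align", "call_site_methylation",
    "methylation_matrix", "differential_methylation", "modification_index",
]

MIN_READ_LENGTH = 40


@dataclass
class Alignment:
    read_id: str
    isodecoder_id: str
    offset: int          # 0-based offset of the read on the reference
    mismatches: int
    read_seq: str


def _encode(seq: str, collapse_ct: bool) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    if collapse_ct:
        arr[arr == ord("C")] = ord("T")
    return arr


def convert_and_align(reads: list[tuple[str, str]], ref: TRNAReferenceSet,
                      max_mismatches: int = 2, margin: int = 2,
                      bisulfite: bool = True,
                      ) -> tuple[list[Alignment], dict]:
    """Ungapped best-hit alignment of reads against every reference.

    In bisulfite mode both read and reference are collapsed to three-letter
    space (C -> T).  Every offset of every reference is scanned; the best
    hit is kept if its mismatch count is <= ``max_mismatches`` and it beats
    the second-best candidate by at least ``margin`` mismatches, otherwise
    the read is discarded as ambiguous.  Reads shorter than 40 nt or longer
    than every reference are dropped.
    """
    if len(ref) == 0:
        raise ValueError("empty reference set")
    # windows per (reference, read length), built lazily
    enc_refs = {r.isodecoder_id: _encode(r.sequence, bisulfite) for r in ref}
    window_cache: dict[tuple[str, int], np.ndarray] = {}
    stats = {"aligned": 0, "ambiguous": 0, "unaligned": 0, "too_short": 0}

    by_len: dict[int, list[tuple[str, str]]] = {}
    for rid, seq in reads:
        if len(seq) < MIN_READ_LENGTH:
            stats["too_short"] += 1
            continue
        by_len.setdefault(len(seq), []).append((rid, seq))

    alignments: list[Alignment] = []
    for L, group in by_len.items():
        enc_reads = np.stack([_encode(s, bisulfite) for _, s in group])
        # candidate mismatch counts per read across all (ref, offset)
        cand_mm = []
        cand_key = []
        for iso, enc in enc_refs.items():
            if enc.size < L:
                continue
            key = (iso, L)
            if key not in window_cache:
                window_cache[key] = sliding_window_view(enc, L)
            windows = window_cache[key]
            mm = (enc_reads[:, None, :] != windows[None, :, :]).sum(axis=2)
            cand_mm.append(mm)
            cand_key.extend((iso, off) for off in range(windows.shape[0]))
        if not cand_mm:
            stats["unaligned"] += len(group)
            continue
        allmm = np.concatenate(cand_mm, axis=1)   # reads x candidates
        best_idx = allmm.argmin(axis=1)
        best = allmm[np.arange(len(group)), best_idx]
        tmp = allmm.copy()
        tmp[np.arange(len(group)), best_idx] = np.iinfo(np.int64).max
        second = tmp.min(axis=1) if allmm.shape[1] > 1 else np.full(
            len(group), np.iinfo(np.int64).max)
        for i, (rid, seq) in enumerate(group):
            if best[i] > max_mismatches:
                stats["unaligned"] += 1
            elif second[i] - best[i] < margin:
                stats["ambiguous"] += 1
            else:
                iso, off = cand_key[best_idx[i]]
                alignments.append(Alignment(rid, iso, off, int(best[i]), seq))
                stats["aligned"] += 1
    return alignments, stats


def call_site_methylation(alignments: list[Alignment], ref: TRNAReferenceSet,
                          coverage_threshold: int = 100) -> pd.DataFrame:
    """Tally original-space C/T at every annotated cytosine (one replicate).

    Returns one row per annotated site with c_count, t_count, coverage,
    fraction = C/(C+T) and a ``masked`` flag for coverage below the
    threshold.  Bases other than C/T at the site are ignored.
    """
    by_iso: dict[str, list[Alignment]] = {}
    for a in alignments:
        by_iso.setdefault(a.isodecoder_id, []).append(a)
    rows = []
    for rec in ref:
        alns = by_iso.get(rec.isodecoder_id, [])
        for site in rec.sites:
            p0 = site.position - 1
            c = t = 0
            for a in alns:
                j = p0 - a.offset
                if 0 <= j < len(a.read_seq):
                    base = a.read_seq[j]
                    if base == "C":
                        c += 1
                    elif base == "T":
                        t += 1
            cov = c + t
            frac = c / cov if cov else np.nan
            rows.append((rec.isodecoder_id, site.position, site.label,
                         site.enzyme, c, t, cov, frac,
                         cov < coverage_threshold))
    return pd.DataFrame(rows, columns=[
        "isodecoder_id", "pos", "label", "enzyme", "c_count", "t_count",
        "coverage", "fraction", "masked"])


def methylation_matrix(reads_by_replicate: dict[str, list[tuple[str, str]]],
                       ref: TRNAReferenceSet, coverage_threshold: int = 100,
                       max_mismatches: int = 2, margin: int = 2,
                       ) -> pd.DataFrame:
    """Align and call every replicate; long frame with a replicate column."""
    frames = []
    for rep, reads in reads_by_replicate.items():
        alns, _ = convert_and_align(reads, ref, max_mismatches, margin)
        df = call_site_methylation(alns, ref, coverage_threshold)
        df.insert(0, "replicate", rep)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def differential_methylation(matrix_wt: pd.DataFrame, matrix_ko: pd.DataFrame,
                             ) -> pd.DataFrame:
    """Per-site two-sample t-test of replicate methylation fractions.

    delta is reported in percentage points as 100*(mean_wt - mean_ko), so
    positive delta means a methylation deficit in KO.  q-values come from
    the two-stage BKY step-up across all sites of the run.  Sites masked or
    with fewer than two replicates in either group are excluded.
    """
    key = ["isodecoder_id", "pos", "label", "enzyme"]
    rows = []
    wt_groups = matrix_wt[~matrix_wt["masked"]].groupby(key)
    ko_groups = matrix_ko[~matrix_ko["masked"]].groupby(key).groups
    for site, wt_df in wt_groups:
        if site not in ko_groups:
            continue
        ko_df = matrix_ko.loc[ko_groups[site]]
        wt = wt_df["fraction"].dropna().to_numpy()
        ko = ko_df["fraction"].dropna().to_numpy()
        if wt.size < 2 or ko.size < 2:
            continue
        t, p = _ttest(wt, ko)
        rows.append((*site, wt.mean(), ko.mean(),
                     100.0 * (wt.mean() - ko.mean()), t, p))
    out = pd.DataFrame(rows, columns=key + ["mean_wt", "mean_ko", "delta",
                                            "t", "p"])
    if len(out):
        out["q"] = bky_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    return out


def modification_index(alignments: list[Alignment], ref: TRNAReferenceSet,
                       positions: dict[str, list[int]] | None = None,
                       ) -> pd.DataFrame:
    """Per-position mismatch fraction from standard (non-bisulfite) alignments.

    A misincorporation-fraction proxy for reverse-transcription-blocking
    modifications (m1A, m3C, m1G).  ``positions`` maps isodecoder id to
    1-based positions to query; by default every position is queried.
    Zero-coverage positions are masked (NaN).
    """
    by_iso: dict[str, list[Alignment]] = {}
    for a in alignments:
        by_iso.setdefault(a.isodecoder_id, []).append(a)
    rows = []
    for rec in ref:
        alns = by_iso.get(rec.isodecoder_id, [])
        qpos = (positions.get(rec.isodecoder_id, [])
                if positions is not None
                else range(1, len(rec.sequence) + 1))
        for pos in qpos:
            p0 = pos - 1
            cov = mm = 0
            for a in alns:
                j = p0 - a.offset
                if 0 <= j < len(a.read_seq):
                    cov += 1
                    if a.read_seq[j] != rec.sequence[p0]:
                        mm += 1
            rows.append((rec.isodecoder_id, pos, cov,
                         mm / cov if cov else np.nan))
    return pd.DataFrame(rows, columns=["isodecoder_id", "pos", "coverage",
                                       "mismatch_fraction"])
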