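"""Codon-resolved ribosome occupancy from footprint records.

Pipeline: infer per-read-length P-site offsets from the metagene 5'-end
histogram around the start codon, assign each footprint's A-site
(P-site + 3 nt) to a codon, cap stall-driven excess with a
loess-prediction correction, and contrast per-codon dwell time (DT) and
A-site occupancy between genotypes.  Coordinates are 0-based half-open
on the transcript; codon index = floor(nt offset within CDS / 3).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bky_adjust, loess_fit, mann_whitney_exact

__all__ = [
    "infer_psite_offsets", "codonize_footprints", "celp_normalize",
    "dwell_and_asite", "OFFSET_WINDOW", "DEFAULT_OFFSET",
]

OFFSET_WINDOW = (10, 15)      # plausible P-site offsets, inclusive
DEFAULT_OFFSET = 12
SENSE_CODONS = sorted(
    c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in ("TAA", "TAG", "TGA"))
EDGE_EXCLUDE = 5              # codons trimmed at both CDS ends for DT


def infer_psite_offsets(footprints: pd.DataFrame,
                        cds_annotations: dict[str, tuple[int, int]],
                        min_per_length: int = 500,
                        ) -> tuple[dict[int, int], dict[int, bool]]:
    """Per read length, P-site offset from the start-codon metagene peak.

    For each footprint the candidate offset is cds_start - 5' position
    (the distance that would put its P-site on the start codon); the
    offset is the argmax of that histogram within ``OFFSET_WINDOW``.
    Length classes with fewer than ``min_per_length`` footprints, or with
    no clear peak, fall back to ``DEFAULT_OFFSET`` with a low-confidence
    flag.  Returns (length -> offset, length -> confident).
    """
    offsets: dict[int, int] = {}
    confident: dict[int, bool] = {}
    starts = footprints["transcript"].map(
        {t: se[0] for t, se in cds_annotations.items()})
    d = starts - footprints["pos"]
    lo, hi = OFFSET_WINDOW
    for length, sub in d.groupby(footprints["length"]):
        length = int(length)
        in_win = sub[(sub >= lo) & (sub <= hi)]
        if len(sub) < min_per_length or in_win.empty:
            offsets[length] = DEFAULT_OFFSET
            confident[length] = False
            continue
        hist = in_win.value_counts()
        peak = hist.max()
        second = hist.iloc[1] if len(hist) > 1 else 0
        # a real initiation peak clearly beats the next-best window slot;
        # flat (uniform) metagenes fall back to the global default
        if peak < 2.0 * max(second, 1):
            offsets[length] = DEFAULT_OFFSET
            confident[length] = False
        else:
            offsets[length] = int(hist.idxmax())
            confident[length] = True
    return offsets, confident


def codonize_footprints(footprints: pd.DataFrame,
                        cds_annotations: dict[str, tuple[int, int]],
                        offsets: dict[int, int],
                        ) -> tuple[dict[str, dict[str, np.ndarray]], dict]:
    """Assign each footprint's A-site nucleotide to a CDS codon.

    A-site nt = 5' position + offset(length) + 3.  Footprints whose
    A-site falls outside the CDS, or on an unknown transcript, are
    dropped and counted.  Returns ({sample: {transcript: codon count
    vector}}, stats).
    """
    stats = {"assigned": 0, "dropped_outside_cds": 0,
             "dropped_unknown_transcript": 0}
    vectors: dict[str, dict[str, np.ndarray]] = {}
    samples = (footprints["sample"].unique()
               if "sample" in footprints.columns else ["all"])
    for sample in samples:
        sub = (footprints[footprints["sample"] == sample]
               if "sample" in footprints.columns else footprints)
        per_tx: dict[str, np.ndarray] = {
            t: np.zeros((se[1] - se[0]) // 3, dtype=float)
            for t, se in cds_annotations.items()}
        for t, pos, length in zip(sub["transcript"], sub["pos"],
                                  sub["length"]):
            if t not in cds_annotations:
                stats["dropped_unknown_transcript"] += 1
                continue
            start, end = cds_annotations[t]
            a_nt = pos + offsets.get(int(length), DEFAULT_OFFSET) + 3
            if start <= a_nt < end:
                per_tx[t][(a_nt - start) // 3] += 1
                stats["assigned"] += 1
            else:
                stats["dropped_outside_cds"] += 1
        vectors[sample] = per_tx
    return vectors, stats


def celp_normalize(codon_vectors: dict[str, np.ndarray], span: float = 0.3,
                   excess_threshold: float = 5.0, min_codons: int = 50,
                   min_counts: int = 100,
                   ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Cap consistent excess over a loess prediction of the codon profile.

    Per transcript, the profile is loess-smoothed over codon positions;
    positions with observed/fitted above ``excess_threshold`` are capped
    at fitted * threshold.  Transcripts below the size/count minimums are
    passed through uncorrected and flagged with an all-False mask.
    Returns (corrected vectors, per-position excess flags).
    """
    corrected: dict[str, np.ndarray] = {}
    flags: dict[str, np.ndarray] = {}
    for t, vec in codon_vectors.items():
        vec = np.asarray(vec, dtype=float)
        if vec.size < min_codons or vec.sum() < min_counts:
            corrected[t] = vec.copy()
            flags[t] = np.zeros(vec.size, dtype=bool)
            continue
        fitted = loess_fit(np.arange(vec.size, dtype=float), vec, span=span)
        excess = vec / np.maximum(fitted, 1e-12)
        flag = excess > excess_threshold
        out = vec.copy()
        out[flag] = fitted[flag] * excess_threshold
        corrected[t] = out
        flags[t] = flag
    return corrected, flags


def _group_vectors(vectors: dict[str, dict[str, np.ndarray]],
                   samples: list[str]) -> dict[str, np.ndarray]:
    """Sum per-transcript codon vectors across a group's samples."""
    out: dict[str, np.ndarray] = {}
    for s in samples:
        for t, v in vectors[s].items():
            out[t] = out.get(t, 0) + np.asarray(v, dtype=float)
    return out


def dwell_and_asite(corrected_wt: dict[str, np.ndarray],
                    corrected_ko: dict[str, np.ndarray],
                    cds_set: dict[str, str], min_instances: int = 20,
                    ) -> pd.DataFrame:
    """Per-codon dwell time and A-site occupancy contrast (KO vs WT).

    Per transcript, densities are normalized to the interior mean (first
    and last ``EDGE_EXCLUDE`` codons excluded); DT per group is the 5%
    trimmed mean of normalized density over every interior instance of
    the codon, relative DT = DT_KO/DT_WT.  A-site occupancy contrast is
    the log2 ratio of library-normalized summed counts.  Significance:
    Mann-Whitney across per-transcript mean normalized densities, BKY
    FDR over the testable sense codons; codons with fewer instances than
    ``min_instances`` are masked (NaN).
    """
    transcripts = sorted(set(corrected_wt) & set(corrected_ko) & set(cds_set))
    inst_values: dict[str, dict[str, list[np.ndarray]]] = {
        "WT": {c: [] for c in SENSE_CODONS},
        "KO": {c: [] for c in SENSE_CODONS}}
    per_tx_mean: dict[str, dict[str, list[float]]] = {
        "WT": {c: [] for c in SENSE_CODONS},
        "KO": {c: [] for c in SENSE_CODONS}}
    raw_sum = {"WT": dict.fromkeys(SENSE_CODONS, 0.0),
               "KO": dict.fromkeys(SENSE_CODONS, 0.0)}
    lib = {"WT": 0.0, "KO": 0.0}

    for t in transcripts:
        cds = cds_set[t]
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        n = len(codons)
        if n <= 2 * EDGE_EXCLUDE + 1:
            continue
        interior = slice(EDGE_EXCLUDE, n - EDGE_EXCLUDE)
        for group, vecs in (("WT", corrected_wt), ("KO", corrected_ko)):
            vec = np.asarray(vecs[t], dtype=float)
            lib[group] += vec.sum()
            mean = vec[interior].mean()
            if mean <= 0:
                continue
            dens = vec / mean
            by_codon: dict[str, list[float]] = {}
            for ci in range(EDGE_EXCLUDE, n - EDGE_EXCLUDE):
                c = codons[ci]
                if c in raw_sum[group]:
                    raw_sum[group][c] += vec[ci]
                    by_codon.setdefault(c, []).append(dens[ci])
            for c, vals in by_codon.items():
                inst_values[group][c].append(np.asarray(vals))
                per_tx_mean[group][c].append(float(np.mean(vals)))

    rows = []
    for c in SENSE_CODONS:
        wt_inst = (np.concatenate(inst_values["WT"][c])
                   if inst_values["WT"][c] else np.array([]))
        ko_inst = (np.concatenate(inst_values["KO"][c])
                   if inst_values["KO"][c] else np.array([]))
        n_inst = min(wt_inst.size, ko_inst.size)
        if n_inst < min_instances:
            rows.append((c, n_inst, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        dt_wt = sps.trim_mean(wt_inst, 0.05)
        dt_ko = sps.trim_mean(ko_inst, 0.05)
        rel = dt_ko / dt_wt if dt_wt > 0 else np.nan
        occ_wt = raw_sum["WT"][c] / lib["WT"] if lib["WT"] else np.nan
        occ_ko = raw_sum["KO"][c] / lib["KO"] if lib["KO"] else np.nan
        occ_lr = (np.log2(occ_ko / occ_wt)
                  if occ_wt and occ_ko else np.nan)
        res = mann_whitney_exact(per_tx_mean["WT"][c], per_tx_mean["KO"][c])
        rows.append((c, n_inst, dt_wt, dt_ko, rel, occ_lr, res.p_two_sided))
    out = pd.DataFrame(rows, columns=["codon", "n_instances", "dt_wt",
                                      "dt_ko", "relative_dt",
                                      "asite_log2_ratio", "p"]
                       ).set_index("codon")
    testable = out["p"].notna()
    q = pd.Series(np.nan, index=out.index)
    if testable.any():
        q[testable] = bky_adjust(out.loc[testable, "p"].to_numpy())
    out["q"] = q
    return out


def group_and_correct(vectors: dict[str, dict[str, np.ndarray]],
                      groups: tuple[str, str] = ("WT", "KO"),
                      span: float = 0.3, excess_threshold: float = 5.0,
                      ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Convenience: pool replicate codon vectors per group and CELP-correct."""
    pooled = {}
    for g in groups:
        samples = [s for s in vectors if s.startswith(g + "_") or s == g]
        pooled[g] = _group_vectors(vectors, samples)
    wt, _ = celp_normalize(pooled[groups[0]], span=span,
                           excess_threshold=excess_threshold)
    ko, _ = celp_normalize(pooled[groups[1]], span=span,
                           excess_threshold=excess_threshold)
    return wt, ko
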