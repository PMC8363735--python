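"""Codon and amino-acid composition, per-gene logTER, and
content-translation association testing.

logTER (log translation efficiency ratio) normalizes the change in
protein expression by the change in RNA level for every gene:
logTER = log2(protein KO/WT) - log2(RNA KO/WT).  Association between a
codon (or amino-acid) content vector and logTER is assessed two ways:
a Pearson correlation, and mutual-information gene-set enrichment with a
permutation null over high-content gene sets.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats as sps

from .stats import EnrichmentResult, mutual_information_perm

__all__ = [
    "GLYCINE_CODONS", "ALL_CODONS", "codon_counts",
    "glycine_codon_fraction", "composition_tables", "compute_logter",
    "content_association",
]

GLYCINE_CODONS = ("GGA", "GGC", "GGG", "GGT")
ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
_STOP_CODONS = {"TAA", "TAG", "TGA"}
_AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


class CompositionError(ValueError):
    """CDS cannot be decomposed (internal stop or ambiguous base)."""


def codon_counts(cds: str) -> dict[str, int]:
    """Exact codon counts of a CDS; the terminal stop codon is excluded.

    Raises :class:`CompositionError` on internal stops or ambiguous bases.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise CompositionError("CDS length not divisible by 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in _STOP_CODONS:
        codons = codons[:-1]
    counts: dict[str, int] = {}
    for i, c in enumerate(codons):
        if any(b not in "ACGT" for b in c):
            raise CompositionError(f"ambiguous base in codon {i}: {c}")
        if c in _STOP_CODONS:
            raise CompositionError(f"internal stop codon at position {i}")
        counts[c] = counts.get(c, 0) + 1
    return counts


def glycine_codon_fraction(cds: str) -> float:
    counts = codon_counts(cds)
    total = sum(counts.values())
    return sum(counts.get(c, 0) for c in GLYCINE_CODONS) / total if total else 0.0


def composition_tables(cds_set: dict[str, str],
                       ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-gene codon fractions and per-protein amino-acid percentages.

    The protein composition is computed from the CDS translation (stop
    excluded).  Genes with internal stops or ambiguous bases are flagged
    and excluded.  Returns (codon fractions summing to 1 per gene,
    amino-acid percentages summing to 100 per protein, flagged genes).
    """
    codon_rows, aa_rows, flagged, index = [], [], [], []
    for gene, cds in cds_set.items():
        try:
            counts = codon_counts(cds)
        except CompositionError:
            flagged.append(gene)
            continue
        total = sum(counts.values())
        codon_rows.append([counts.get(c, 0) / total for c in ALL_CODONS])
        protein = str(Seq(cds).translate()).rstrip("*")
        aa_rows.append([100.0 * protein.count(a) / len(protein)
                        for a in _AA_LETTERS])
        index.append(gene)
    codon_df = pd.DataFrame(codon_rows, index=index, columns=ALL_CODONS)
    aa_df = pd.DataFrame(aa_rows, index=index, columns=list(_AA_LETTERS))
    return codon_df, aa_df, flagged


def compute_logter(protein_table: pd.DataFrame, rna_table: pd.DataFrame,
                   groups: tuple[str, str] = ("WT", "KO")) -> pd.DataFrame:
    """Per-gene log2 differentials and logTER from linear abundance tables.

    Each modality's log2FC is the difference of group-mean log2
    abundances; logTER = protein log2FC - RNA log2FC.  Genes missing from
    either table are excluded (count in ``attrs['n_excluded']``).
    """
    shared = protein_table.index.intersection(rna_table.index)
    if shared.empty:
        raise ValueError("no shared gene ids between protein and RNA tables")

    def lfc(table: pd.DataFrame) -> pd.Series:
        cols_a = [c for c in table.columns if c.startswith(groups[0] + "_")]
        cols_b = [c for c in table.columns if c.startswith(groups[1] + "_")]
        if len(cols_a) < 2 or len(cols_b) < 2:
            raise ValueError("each group needs >= 2 replicates")
        log2 = np.log2(table.loc[shared])
        return log2[cols_b].mean(axis=1) - log2[cols_a].mean(axis=1)

    out = pd.DataFrame({"protein_log2fc": lfc(protein_table),
                        "rna_log2fc": lfc(rna_table)})
    out["logter"] = out["protein_log2fc"] - out["rna_log2fc"]
    out = out.dropna()
    out.attrs["n_excluded"] = (len(protein_table.index.union(rna_table.index))
                               - len(out))
    return out


def content_association(logter: pd.Series | pd.DataFrame,
                        content: pd.Series, mode: str = "quartile",
                        n_clusters: int = 10, n_bins: int = 5,
                        n_perm: int = 10_000, rng_seed: int = 0) -> dict:
    """Association between a content vector and logTER.

    Pearson r with p, plus MI gene-set enrichment of either the top
    content quartile (``mode='quartile'``) or contiguous content-ranked
    clusters within the top 50% (``mode='clusters'``), each with per-bin
    hypergeometric enrichment, Bonferroni-adjusted.
    """
    if isinstance(logter, pd.DataFrame):
        logter = logter["logter"]
    shared = logter.index.intersection(content.index)
    if len(shared) < 50:
        raise ValueError("need >= 50 genes with both logTER and content")
    y = logter.loc[shared].to_numpy(dtype=float)
    x = content.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant content vector")
    r, p = sps.pearsonr(x, y)
    out: dict = {"r": float(r), "p": float(p), "n": len(shared)}

    order = np.argsort(-x, kind="mergesort")     # descending content
    if mode == "quartile":
        member = np.zeros(len(shared), dtype=int)
        member[order[: max(2, len(shared) // 4)]] = 1
        out["enrichment"] = mutual_information_perm(
            y, member, n_bins=n_bins, n_perm=n_perm, rng_seed=rng_seed)
    elif mode == "clusters":
        top = order[: len(shared) // 2]
        chunks = np.array_split(top, n_clusters)
        results: list[EnrichmentResult] = []
        for ci, chunk in enumerate(chunks):
            member = np.zeros(len(shared), dtype=int)
            member[chunk] = 1
            results.append(mutual_information_perm(
                y, member, n_bins=n_bins, n_perm=n_perm,
                rng_seed=rng_seed + ci))
        out["clusters"] = results
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return out
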