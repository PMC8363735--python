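"""Synthetic-data generators for every input the pipeline consumes.

Each generator is a pure function of a :class:`~glytrome.config.ScenarioConfig`
(and an assay-specific derived seed), so a scenario seed fully determines
every file the pipeline sees.  The default configuration encodes the
knockout effect structure the toolkit targets: glycine-family isodecoder
depletion, Nsun2-site methylation collapse with Dnmt2 sites untouched,
GGA-specific ribosome stalling, glycine-codon-dependent translational
deficit, and a 2.46-fold glycine increase in the metabolome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError, ScenarioConfig, derive_seed

__all__ = [
    "SiteAnnotation", "TRNARecord", "TRNAReferenceSet",
    "generate_reference", "effect_map", "generate_bisulfite_reads",
    "generate_count_tables", "generate_fragment_records",
    "generate_cds", "generate_ribo_profiles", "generate_omics_tables",
    "generate_proteome_table", "generate_umi_reads",
    "AMINO_ACIDS_MEASURED", "BISULFITE_PANEL_FAMILIES",
]

_BASES = np.array(list("ACGT"))

# codon -> amino acid (3-letter families handled by one-letter code)
from Bio.Data.CodonTable import unambiguous_dna_by_id as _tables
_CODON_TABLE = _tables[1]
_STOPS = set(_CODON_TABLE.stop_codons)

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}

# the 19 canonical amino acids measurable by the MS assay (cysteine is too
# reactive to quantify)
AMINO_ACIDS_MEASURED = sorted(set(_AA3.values()) - {"Cys"})

# amplicon panel mirroring the six highly expressed tRNAs assayed by
# targeted bisulfite sequencing
BISULFITE_PANEL_FAMILIES = [
    ("Gly", "GCC"), ("Glu", "TTC"), ("Glu", "CTC"),
    ("Asp", "GTC"), ("Val", "AAC"), ("Pro", "TGG"),
]

GLYCINE_CODONS = ("GGA", "GGC", "GGG", "GGT")


def _revcomp(s: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(s))


# ---------------------------------------------------------------- reference

@dataclass
class SiteAnnotation:
    position: int          # 1-based on the isodecoder sequence
    label: str             # canonical label, e.g. "C39"
    enzyme: str            # "Nsun2", "Dnmt2" or "none"


@dataclass
class TRNARecord:
    isodecoder_id: str
    family: str            # isoacceptor family (amino acid, 3-letter)
    anticodon: str
    sequence: str
    sites: list[SiteAnnotation] = field(default_factory=list)


@dataclass
class TRNAReferenceSet:
    records: list[TRNARecord]

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def get(self, isodecoder_id: str) -> TRNARecord:
        for r in self.records:
            if r.isodecoder_id == isodecoder_id:
                return r
        raise KeyError(isodecoder_id)

    def subset(self, ids) -> "TRNAReferenceSet":
        ids = set(ids)
        return TRNAReferenceSet([r for r in self.records
                                 if r.isodecoder_id in ids])

    def bisulfite_panel(self) -> "TRNAReferenceSet":
        """First isodecoder of each panel (family, anticodon) pair."""
        chosen = []
        for fam, ac in BISULFITE_PANEL_FAMILIES:
            for r in self.records:
                if r.family == fam and r.anticodon == ac:
                    chosen.append(r)
                    break
        return TRNAReferenceSet(chosen)

    # ------------------------------------------------------------------ I/O
    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.isodecoder_id} {r.family}-{r.anticodon}\n")
                fh.write(r.sequence + "\n")

    def sites_frame(self) -> pd.DataFrame:
        rows = [(r.isodecoder_id, s.position, s.label, s.enzyme)
                for r in self.records for s in r.sites]
        return pd.DataFrame(rows, columns=["isodecoder_id", "pos", "label",
                                           "enzyme"])

    def to_sites_tsv(self, path) -> None:
        self.sites_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_files(cls, fasta_path, sites_path) -> "TRNAReferenceSet":
        from Bio import SeqIO
        sites = pd.read_csv(sites_path, sep="\t")
        by_id: dict[str, list[SiteAnnotation]] = {}
        for _, row in sites.iterrows():
            by_id.setdefault(row["isodecoder_id"], []).append(
                SiteAnnotation(int(row["pos"]), row["label"], row["enzyme"]))
        records = []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            fam, _, ac = rec.description.split()[-1].partition("-")
            records.append(TRNARecord(rec.id, fam, ac, str(rec.seq),
                                      by_id.get(rec.id, [])))
        return cls(records)


def _nongly_anticodons() -> list[tuple[str, str]]:
    """(family, anticodon) pairs for all non-Gly sense codons.

    Panel families come first so every panel member always exists.
    """
    pairs = []
    seen = set()
    for fam, ac in BISULFITE_PANEL_FAMILIES:
        if fam == "Gly":
            continue
        pairs.append((fam, ac))
        seen.add((fam, ac))
    for codon, aa in sorted(_CODON_TABLE.forward_table.items()):
        fam = _AA3[aa]
        if fam == "Gly":
            continue
        ac = _revcomp(codon)
        if (fam, ac) not in seen:
            pairs.append((fam, ac))
            seen.add((fam, ac))
    return pairs


def generate_reference(config: ScenarioConfig) -> TRNAReferenceSet:
    """Generate the isodecoder reference set with annotated cytosines.

    Sequences are random on a 76-nt cloverleaf-length scaffold with the
    anticodon at positions 34-36; longer isodecoders pad the variable
    loop (after position 48) so annotated coordinates stay canonical.
    Gly isodecoders carry four Nsun2-regulated cytosines (C39, C46-C48)
    plus the Dnmt2 site C37; non-Gly families carry at most three Nsun2
    sites, and Asp-GTC additionally carries the Dnmt2 site C38.
    """
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed, "reference"))

    # anticodon assignment: Gly split across GCC/CCC/TCC, the rest cycle
    # through every non-Gly anticodon
    n_gly = config.gly_isodecoder_count
    gly_acs = [["GCC", "CCC", "TCC"][i % 3] for i in range(n_gly)]
    gly_acs.sort(key=["GCC", "CCC", "TCC"].index)
    nongly = _nongly_anticodons()
    records = []
    counters: dict[tuple[str, str], int] = {}

    def make_record(fam: str, ac: str) -> TRNARecord:
        counters[(fam, ac)] = counters.get((fam, ac), 0) + 1
        iso_id = f"tRNA-{fam}-{ac}-{counters[(fam, ac)]}"
        length = int(rng.choice([76, 76, 76, 82, 88]))
        seq = rng.choice(_BASES, size=length)
        pad = length - 76
        # anticodon at 34-36 (1-based)
        seq[33:36] = list(ac)
        if fam == "Gly":
            site_defs = [(37, "C37", "Dnmt2"), (39, "C39", "Nsun2"),
                         (46, "C46", "Nsun2"), (47, "C47", "Nsun2"),
                         (48, "C48", "Nsun2")]
        elif fam == "Asp" and ac == "GTC":
            site_defs = [(38, "C38", "Dnmt2"), (46, "C46", "Nsun2"),
                         (47, "C47", "Nsun2"), (48, "C48", "Nsun2")]
        else:
            site_defs = [(46, "C46", "Nsun2"), (47, "C47", "Nsun2"),
                         (48, "C48", "Nsun2")]
        sites = []
        for pos, label, enzyme in site_defs:
            seq[pos - 1] = "C"
            sites.append(SiteAnnotation(pos, label, enzyme))
        if pad:
            # variable-loop padding inserted after position 60 keeps every
            # annotated coordinate canonical
            seq = np.concatenate([seq[:60], rng.choice(_BASES, size=pad),
                                  seq[60:76]])
        return TRNARecord(iso_id, fam, ac, "".join(seq), sites)

    for ac in gly_acs:
        records.append(make_record("Gly", ac))
    for i in range(config.n_isodecoders - n_gly):
        fam, ac = nongly[i % len(nongly)]
        records.append(make_record(fam, ac))
    return TRNAReferenceSet(records)


def effect_map(ref: TRNAReferenceSet, config: ScenarioConfig) -> dict[str, float]:
    """KO/WT expression fold change per isodecoder.

    Seven Gly isodecoders get the strong depletion, the remaining three the
    weak one (mirroring 4 GCC + 2 CCC + 1 TCC significant deficits); two
    non-Gly isodecoders go down and two (Asn-GTT, Met-CAT when present) up.
    """
    fc: dict[str, float] = {}
    gly = [r for r in ref if r.family == "Gly"]
    strong = ([r for r in gly if r.anticodon == "GCC"]
              + [r for r in gly if r.anticodon == "CCC"][:2]
              + [r for r in gly if r.anticodon == "TCC"][:1])
    strong_ids = {r.isodecoder_id for r in strong[:7]}
    for r in gly:
        fc[r.isodecoder_id] = (config.gly_depletion_strong
                               if r.isodecoder_id in strong_ids
                               else config.gly_depletion_weak)
    nongly = [r for r in ref if r.family != "Gly"]
    up = [r for r in nongly if (r.family, r.anticodon) in
          (("Asn", "GTT"), ("Met", "CAT"))][:config.nongly_up_count]
    up_ids = {r.isodecoder_id for r in up}
    down_pool = [r for r in nongly if r.isodecoder_id not in up_ids]
    down_ids = {r.isodecoder_id for r in down_pool[:config.nongly_down_count]}
    for r in nongly:
        if r.isodecoder_id in up_ids:
            fc[r.isodecoder_id] = config.nongly_up_fc
        elif r.isodecoder_id in down_ids:
            fc[r.isodecoder_id] = config.nongly_down_fc
        else:
            fc[r.isodecoder_id] = 1.0
    return fc


# ----------------------------------------------------------- bisulfite reads

def generate_bisulfite_reads(ref: TRNAReferenceSet, config: ScenarioConfig,
                             group: str) -> dict[str, list[tuple[str, str]]]:
    """Simulate bisulfite-converted amplicon reads for one genotype group.

    Each read is a full-length copy of its reference in which every
    annotated cytosine retains C with its site's methylation probability
    and every unannotated cytosine converts to T with the configured
    conversion efficiency.  Returns {replicate label: [(read id, seq)]}.
    """
    if group not in ("WT", "KO"):
        raise ValueError(f"unknown group label: {group!r}")
    profile = config.methylation_wt if group == "WT" else config.methylation_ko
    out: dict[str, list[tuple[str, str]]] = {}
    for rep in range(1, config.n_replicates_bisulfite + 1):
        rep_label = f"{group}_rep{rep}"
        rng = np.random.default_rng(
            derive_seed(config.seed, f"bisulfite:{rep_label}"))
        reads: list[tuple[str, str]] = []
        for rec in ref:
            seq = np.array(list(rec.sequence))
            c_pos = np.flatnonzero(seq == "C")          # 0-based
            site_by_pos = {s.position - 1: s for s in rec.sites}
            p_keep = np.full(c_pos.size, 1.0 - config.conversion_efficiency)
            for j, pos in enumerate(c_pos):
                if pos in site_by_pos:
                    p_keep[j] = profile.get(site_by_pos[pos].label, 0.0)
            n = config.reads_per_amplicon
            keep = rng.random((n, c_pos.size)) < p_keep
            for i in range(n):
                read = seq.copy()
                read[c_pos[~keep[i]]] = "T"
                reads.append((f"{rec.isodecoder_id}|{rep_label}|{i}",
                              "".join(read)))
        out[rep_label] = reads
    return out


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    """Write (id, seq) pairs as Phred-33 FASTQ with constant quality 'I'."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    from Bio import SeqIO
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


# ------------------------------------------------------------- count tables

def _nb_draw(rng, mean, dispersion):
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_count_tables(ref: TRNAReferenceSet, config: ScenarioConfig,
                          ) -> pd.DataFrame:
    """Negative-binomial isodecoder counts (features x samples).

    Per-isodecoder baseline means are log-normal; KO means are scaled by
    the configured fold changes.  Columns are WT_rep#/KO_rep#.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "counts"))
    fc = effect_map(ref, config)
    ids = [r.isodecoder_id for r in ref]
    base = rng.lognormal(mean=np.log(300.0), sigma=1.0, size=len(ids))
    cols = {}
    for rep in range(1, config.n_replicates_counts + 1):
        cols[f"WT_rep{rep}"] = _nb_draw(rng, base, config.nb_dispersion)
    ko_mean = base * np.array([fc[i] for i in ids])
    for rep in range(1, config.n_replicates_counts + 1):
        cols[f"KO_rep{rep}"] = _nb_draw(rng, ko_mean, config.nb_dispersion)
    return pd.DataFrame(cols, index=pd.Index(ids, name="isodecoder_id"))


def generate_fragment_records(ref: TRNAReferenceSet, config: ScenarioConfig,
                              n_species_per_isodecoder: int = 3,
                              ) -> pd.DataFrame:
    """tRNA-derived fragment species with per-sample NB counts.

    Each isodecoder emits a few fragment species (end, length) with
    lengths uniform in the class windows; Gly 5' fragments are depleted
    in KO with the strong fold change.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "fragments"))
    rows = []
    for rec in ref:
        for k in range(n_species_per_isodecoder):
            if rng.random() < 0.6:
                end, length = "5'", int(rng.integers(14, 36))
            else:
                end, length = "3'", int(rng.integers(17, 23))
            base = rng.lognormal(np.log(150.0), 0.8)
            fc = (config.gly_depletion_strong
                  if rec.family == "Gly" and end == "5'" else 1.0)
            row = {"fragment_id": f"{rec.isodecoder_id}|{end}|{length}|{k}",
                   "isodecoder_id": rec.isodecoder_id, "family": rec.family,
                   "anticodon": rec.anticodon, "end": end, "length": length}
            for rep in range(1, config.n_replicates_counts + 1):
                row[f"WT_rep{rep}"] = int(_nb_draw(rng, base,
                                                   config.nb_dispersion))
            for rep in range(1, config.n_replicates_counts + 1):
                row[f"KO_rep{rep}"] = int(_nb_draw(rng, base * fc,
                                                   config.nb_dispersion))
            rows.append(row)
    return pd.DataFrame(rows).set_index("fragment_id")


# ----------------------------------------------------------------- CDS set

_SENSE_NON_GLY = sorted(c for c in _CODON_TABLE.forward_table
                        if c not in GLYCINE_CODONS)
_GLY_WEIGHTS = np.array([0.4, 0.3, 0.15, 0.15])  # GGA-biased usage


def generate_cds(config: ScenarioConfig) -> tuple[dict[str, str], pd.Series]:
    """Random CDS set with gene-specific glycine codon content.

    Returns (gene -> CDS sequence, per-gene glycine codon fraction truth).
    Each CDS starts with ATG, ends with TAA and contains no internal stop.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "cds"))
    genes: dict[str, str] = {}
    gly_frac = {}
    for g in range(config.n_genes):
        gene = f"gene{g:04d}"
        n_codons = int(rng.integers(100, 301))      # sense codons incl. ATG
        f = float(np.clip(rng.normal(0.065, 0.03), 0.005, 0.20))
        is_gly = rng.random(n_codons - 1) < f
        body = np.where(
            is_gly,
            rng.choice(GLYCINE_CODONS, size=n_codons - 1, p=_GLY_WEIGHTS),
            rng.choice(_SENSE_NON_GLY, size=n_codons - 1))
        genes[gene] = "ATG" + "".join(body) + "TAA"
        gly_frac[gene] = is_gly.mean() * (n_codons - 1) / n_codons
    return genes, pd.Series(gly_frac, name="gly_codon_fraction")


# --------------------------------------------------------- ribosome profiles

UTR5_LEN = 30
UTR3_LEN = 30
LENGTH_PROBS = {27: 0.10, 28: 0.20, 29: 0.35, 30: 0.25, 31: 0.10}
TRUE_OFFSETS = {27: 11, 28: 12, 29: 12, 30: 13, 31: 13}


def transcript_annotations(cds_set: dict[str, str]) -> dict[str, tuple[int, int]]:
    """Transcript -> (cds_start, cds_end), 0-based half-open, with fixed UTRs."""
    return {g: (UTR5_LEN, UTR5_LEN + len(s)) for g, s in cds_set.items()}


def generate_ribo_profiles(cds_set: dict[str, str], config: ScenarioConfig,
                           ) -> tuple[pd.DataFrame, dict[str, tuple[int, int]],
                                      dict[int, int], pd.DataFrame]:
    """Footprints with codon-specific stall structure.

    Footprint rate per codon is proportional to transcript abundance times
    the A-site codon's stall multiplier (GGA multiplier applies in KO
    only); the first coding A-site carries an initiation enrichment.  Read
    lengths come from 27-31 nt with the fixed length->offset map
    ``TRUE_OFFSETS`` recorded as ground truth.  Returns (footprints,
    transcript annotations, true offsets, RNA counts).
    """
    for g, s in cds_set.items():
        if len(s) % 3 != 0:
            raise ValueError(f"CDS length of {g} not divisible by 3")
    rng = np.random.default_rng(derive_seed(config.seed, "ribo"))
    transcripts = sorted(cds_set)[: config.n_ribo_transcripts]
    ann = transcript_annotations({g: cds_set[g] for g in transcripts})
    lengths = np.array(sorted(LENGTH_PROBS))
    probs = np.array([LENGTH_PROBS[l] for l in lengths])

    abundance = pd.Series(rng.lognormal(0.0, 0.5, size=len(transcripts)),
                          index=transcripts)
    rows = []
    rna_rows = {}
    for group in ("WT", "KO"):
        for rep in range(1, config.n_replicates_ribo + 1):
            sample = f"{group}_rep{rep}"
            rna_rows[sample] = {}
            for g in transcripts:
                cds = cds_set[g]
                n_codons = len(cds) // 3
                codons = [cds[3 * i: 3 * i + 3] for i in range(n_codons)]
                # A-site can sit on codons 1 .. n_codons-2 (stop excluded)
                w = np.ones(n_codons - 2)
                for ci in range(1, n_codons - 1):
                    mult = 1.0
                    if group == "KO" and codons[ci] == "GGA":
                        mult = config.ribo_stall_gga_ko
                    w[ci - 1] = mult
                w[0] *= config.init_peak
                w = w / w.sum()
                n_fp = rng.poisson(config.footprints_per_transcript
                                   * abundance[g] / abundance.mean())
                a_codons = rng.choice(np.arange(1, n_codons - 1), size=n_fp,
                                      p=w)
                ls = rng.choice(lengths, size=n_fp, p=probs)
                offs = np.array([TRUE_OFFSETS[l] for l in ls])
                pos5 = ann[g][0] + 3 * a_codons - 3 - offs
                for p, l in zip(pos5, ls):
                    rows.append((g, int(p), int(l), sample))
                rna_rows[sample][g] = rng.poisson(
                    1000.0 * abundance[g] / abundance.mean())
    fp = pd.DataFrame(rows, columns=["transcript", "pos", "length", "sample"])
    rna = pd.DataFrame(rna_rows)
    rna.index.name = "transcript"
    return fp, ann, dict(TRUE_OFFSETS), rna


# ----------------------------------------------------- omics + metabolomics

def generate_omics_tables(cds_set: dict[str, str], config: ScenarioConfig,
                          ) -> dict:
    """Protein table, RNA table and metabolite area bundle.

    Per-gene RNA log2FC ~ N(0, rna_lfc_sd); protein log2FC adds the
    glycine-content translational-efficiency term ter_gly_slope * (gly
    codon fraction - cohort mean) plus N(0, protein_lfc_sd).  The
    metabolite table covers the 19 measurable amino acids with a log-normal
    area model (CV metab_cv), the configured glycine KO/WT fold change, and
    near-constant heavy-standard areas (CV heavy_cv).
    """
    rng = np.random.default_rng(derive_seed(config.seed, "omics"))
    from .codon import glycine_codon_fraction
    genes = sorted(cds_set)
    gly = np.array([glycine_codon_fraction(cds_set[g]) for g in genes])
    rna_lfc = rng.normal(0.0, config.rna_lfc_sd, size=len(genes))
    prot_lfc = (rna_lfc
                + config.ter_gly_slope * (gly - gly.mean())
                + rng.normal(0.0, config.protein_lfc_sd, size=len(genes)))

    def table(lfc: np.ndarray, base_log2: np.ndarray, noise_sd: float,
              ) -> pd.DataFrame:
        cols = {}
        for rep in range(1, config.n_replicates_counts + 1):
            cols[f"WT_rep{rep}"] = 2.0 ** (
                base_log2 + rng.normal(0, noise_sd, size=len(genes)))
        for rep in range(1, config.n_replicates_counts + 1):
            cols[f"KO_rep{rep}"] = 2.0 ** (
                base_log2 + lfc + rng.normal(0, noise_sd, size=len(genes)))
        return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))

    base = rng.normal(10.0, 1.5, size=len(genes))
    rna_table = table(rna_lfc, base, 0.10)
    protein_table = table(prot_lfc, base, 0.10)

    metab = _generate_metabolites(config, rng)
    return {"protein": protein_table, "rna": rna_table,
            "rna_lfc": pd.Series(rna_lfc, index=genes),
            "protein_lfc": pd.Series(prot_lfc, index=genes),
            **metab}


def _generate_metabolites(config: ScenarioConfig, rng) -> dict:
    aas = AMINO_ACIDS_MEASURED
    wt_mean = pd.Series(rng.lognormal(np.log(1e6), 0.5, size=len(aas)),
                        index=aas)
    heavy_nominal = pd.Series(rng.lognormal(np.log(5e5), 0.3, size=len(aas)),
                              index=aas)
    sigma = np.sqrt(np.log1p(config.metab_cv**2))
    samples = ([f"WT_rep{i}" for i in range(1, config.n_replicates_metabolites + 1)]
               + [f"KO_rep{i}" for i in range(1, config.n_replicates_metabolites + 1)])
    weights = pd.Series(rng.uniform(10.0, 20.0, size=len(samples)),
                        index=samples, name="tissue_weight_mg")
    ref_w = weights.iloc[0]
    rows = []
    for s in samples:
        group_fc = {aa: 1.0 for aa in aas}
        if s.startswith("KO"):
            group_fc["Gly"] = config.glycine_metab_fc
        # the per-sample tissue weight scales everything extracted from it
        wfac = weights[s] / ref_w
        for aa in aas:
            endo = (wt_mean[aa] * group_fc[aa]
                    * np.exp(rng.normal(-sigma**2 / 2, sigma)) * wfac)
            heavy = heavy_nominal[aa] * np.exp(
                rng.normal(0, config.heavy_cv))
            rows.append((aa, s, "endogenous", endo))
            rows.append((aa, s, "heavy", heavy))
    areas = pd.DataFrame(rows, columns=["amino_acid", "sample", "channel",
                                        "area"])
    return {"metabolite_areas": areas, "pooled_heavy": heavy_nominal,
            "tissue_weights": weights}


def generate_proteome_table(config: ScenarioConfig, n_proteins: int = 5820,
                            n_decreased: int = 635, n_increased: int = 853,
                            lfc: float = 0.8, noise_sd: float = 0.25,
                            n_per_group: int = 5) -> dict:
    """Protein log2-intensity table with a discrete injected stratum truth.

    Decreased/increased proteins get -lfc/+lfc in KO; glycine content is
    drawn around 6.6% with the decreased stratum shifted up (+0.53 pp) and
    the increased stratum shifted down (-0.2 pp), mirroring the observed
    glycine enrichment of down-regulated proteins.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "proteome"))
    ids = [f"prot{i:04d}" for i in range(n_proteins)]
    truth = np.array(["ns"] * n_proteins, dtype=object)
    truth[:n_decreased] = "decreased"
    truth[n_decreased:n_decreased + n_increased] = "increased"
    rng.shuffle(truth)
    delta = np.where(truth == "decreased", -lfc,
                     np.where(truth == "increased", lfc, 0.0))
    base = rng.normal(20.0, 2.0, size=n_proteins)
    cols = {}
    for rep in range(1, n_per_group + 1):
        cols[f"WT_rep{rep}"] = base + rng.normal(0, noise_sd, n_proteins)
    for rep in range(1, n_per_group + 1):
        cols[f"KO_rep{rep}"] = base + delta + rng.normal(0, noise_sd,
                                                         n_proteins)
    table = pd.DataFrame(cols, index=pd.Index(ids, name="protein_id"))
    gly = rng.normal(6.63, 2.2, size=n_proteins)
    gly += np.where(truth == "decreased", 0.53,
                    np.where(truth == "increased", -0.2, 0.0))
    gly = np.clip(gly, 0.0, None)
    return {"table": table,
            "truth": pd.Series(truth, index=ids, name="stratum"),
            "gly_content": pd.Series(gly, index=ids, name="gly_percent")}


# ------------------------------------------------------------------ UMI seq

Y5_PREFIX = "GTTCAGAGTTCTACAGTCCGACGATC"   # ends in GATC; UMI follows
Y5_SUFFIX = "ACTGGATAC"
Y3_PREFIX = "GTATCCAGT"                    # UMI follows
Y3_SUFFIX = "TGGAATTCTCGGGTGCCAAGG"


def generate_umi_reads(inserts: dict[str, int], seed: int = 0,
                       duplication: float = 2.0) -> list[tuple[str, str]]:
    """Linker-ligated reads with 4-nt UMIs at both ends.

    ``inserts`` maps insert sequence -> number of distinct molecules; each
    molecule gets a unique UMI pair and a Poisson(duplication - 1) + 1
    number of PCR copies.
    """
    rng = np.random.default_rng(seed)
    reads = []
    i = 0
    for insert, n_mol in inserts.items():
        for _ in range(n_mol):
            umi1 = "".join(rng.choice(_BASES, size=4))
            umi2 = "".join(rng.choice(_BASES, size=4))
            seq = (Y5_PREFIX + umi1 + Y5_SUFFIX + insert
                   + Y3_PREFIX + umi2 + Y3_SUFFIX)
            for _ in range(1 + rng.poisson(max(duplication - 1.0, 0.0))):
                reads.append((f"read{i}", seq))
                i += 1
    rng.shuffle(reads)
    return reads
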