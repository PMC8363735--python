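"""End-to-end orchestration of the synthetic-scenario pipeline.

Stages communicate exclusively through files in per-stage write-once
directories, so a run is reproducible from its YAML config alone; the
manifest records a digest of every output.  All randomness flows from
the scenario seed via per-stage derived seeds (stage-name hashing), so
stage order never changes results.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import codon, expression, metabolomics, methylation, proteome, ribo
from .config import ScenarioConfig
from . import simulate as sim

__all__ = ["STAGES", "run_pipeline", "PipelineError"]

STAGES = ["simulate", "methylation", "expression", "fragments", "logter",
          "ribo", "proteome", "metabolome", "report"]

_DEPS = {
    "simulate": [],
    "methylation": ["simulate"],
    "expression": ["simulate"],
    "fragments": ["simulate"],
    "logter": ["simulate"],
    "ribo": ["simulate"],
    "proteome": ["simulate"],
    "metabolome": ["simulate"],
    "report": ["methylation", "expression", "logter", "ribo", "proteome",
               "metabolome"],
}


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ------------------------------------------------------------------ stages

def _stage_simulate(config: ScenarioConfig, outdir: Path) -> None:
    d = outdir / "simulate"
    d.mkdir(parents=True)
    ref = sim.generate_reference(config)
    ref.to_fasta(d / "reference.fa")
    ref.to_sites_tsv(d / "sites.tsv")
    panel = ref.bisulfite_panel()
    panel.to_fasta(d / "panel.fa")
    panel.to_sites_tsv(d / "panel_sites.tsv")
    for group in ("WT", "KO"):
        for rep, reads in sim.generate_bisulfite_reads(panel, config,
                                                       group).items():
            sim.write_fastq(reads, d / f"bisulfite_{rep}.fastq")
    sim.generate_count_tables(ref, config).to_csv(d / "counts.tsv", sep="\t")
    sim.generate_fragment_records(ref, config).to_csv(d / "fragments.tsv",
                                                      sep="\t")
    cds_set, gly_truth = sim.generate_cds(config)
    with open(d / "cds.fa", "w") as fh:
        for g, s in sorted(cds_set.items()):
            fh.write(f">{g}\n{s}\n")
    gly_truth.to_csv(d / "gly_codon_fraction.tsv", sep="\t")
    fp, ann, offsets, rna_ribo = sim.generate_ribo_profiles(cds_set, config)
    fp.to_csv(d / "footprints.tsv", sep="\t", index=False)
    pd.DataFrame([(t, s, e) for t, (s, e) in sorted(ann.items())],
                 columns=["transcript", "cds_start", "cds_end"]
                 ).to_csv(d / "cds_annotations.tsv", sep="\t", index=False)
    with open(d / "true_offsets.json", "w") as fh:
        json.dump(offsets, fh)
    rna_ribo.to_csv(d / "ribo_rna_counts.tsv", sep="\t")
    omics = sim.generate_omics_tables(cds_set, config)
    omics["protein"].to_csv(d / "protein_abundance.tsv", sep="\t")
    omics["rna"].to_csv(d / "rna_abundance.tsv", sep="\t")
    omics["metabolite_areas"].to_csv(d / "metabolite_areas.tsv", sep="\t",
                                     index=False)
    omics["pooled_heavy"].rename("area").to_csv(d / "pooled_heavy.tsv",
                                                sep="\t")
    omics["tissue_weights"].to_csv(d / "tissue_weights.tsv", sep="\t")
    prot = sim.generate_proteome_table(config)
    prot["table"].to_csv(d / "proteome_log2.tsv", sep="\t")
    prot["gly_content"].to_csv(d / "proteome_gly_content.tsv", sep="\t")
    prot["truth"].to_csv(d / "proteome_truth.tsv", sep="\t")


def _stage_methylation(config: ScenarioConfig, outdir: Path) -> None:
    d = outdir / "methylation"
    d.mkdir(parents=True)
    src = outdir / "simulate"
    panel = sim.TRNAReferenceSet.from_files(src / "panel.fa",
                                            src / "panel_sites.tsv")
    matrices = {}
    for group in ("WT", "KO"):
        reads_by_rep = {}
        for rep in range(1, config.n_replicates_bisulfite + 1):
            label = f"{group}_rep{rep}"
            reads_by_rep[label] = sim.read_fastq(
                src / f"bisulfite_{label}.fastq")
        matrices[group] = methylation.methylation_matrix(reads_by_rep, panel)
        matrices[group].to_csv(d / f"site_methylation_{group}.tsv", sep="\t",
                               index=False)
    diff = methylation.differential_methylation(matrices["WT"],
                                                matrices["KO"])
    diff.to_csv(d / "differential_methylation.tsv", sep="\t", index=False)


def _stage_expression(config: ScenarioConfig, outdir: Path) -> None:
    d = outdir / "expression"
    d.mkdir(parents=True)
    counts = pd.read_csv(outdir / "simulate" / "counts.tsv", sep="\t",
                         index_col=0)
    de = expression.isodecoder_de(expression.CountMatrix(counts))
    de.to_csv(d / "isodecoder_de.tsv", sep="\t")
    families = pd.Series({i: i.split("-")[1] for i in counts.index})
    expression.family_rollup(de, families).to_csv(d / "family_rollup.tsv",
                                                  sep="\t")


def _stage_fragments(config: ScenarioConfig, outdir: Path) -> None:
    d = outdir / "fragments"
    d.mkdir(parents=True)
    records = pd.read_csv(outdir / "simulate" / "fragments.tsv", sep="\t",
                          index_col=0)
    sums, tests = expression.fragment_family_tests(records)
    sums.to_csv(d / "fragment_class_cpm.tsv", sep="\t", index=False)
    tests.to_csv(d / "fragment_family_tests.tsv", sep="\t", index=False)


def _stage_logter(config: ScenarioConfig, outdir: Path) -> None:
    d = outdir / "logter"
    d.mkdir(parents=True)
    src = outdir / "simulate"
    protein = pd.read_csv(src / "protein_abundance.tsv", sep="\t",
                          index_col=0)
    rna = pd.read_csv(src / "rna_abundance.tsv", sep="\t", index_col=0)
    cds_set = _read_fasta(src / "cds.fa")
    logter = codon.compute_logter(protein, rna)
    codon_df, _, _ = codon.composition_tables(cds_set)
    gly_content = codon_df[list(codon.GLYCINE_CODONS)].sum(axis=1)
    logter["gly_codon_fraction"] = gly_content.reindex(logter.index)
    logter.to_csv(d / "logter.tsv", sep="\t")
    assoc = codon.content_association(
        logter, gly_content, rng_seed=config.stage_seed("logter"))
    enr = assoc.pop("enrichment")
    assoc.update({"mi": enr.mi, "z": enr.z, "p_perm": enr.p_perm})
    with open(d / "gly_association.json", "w") as fh:
        json.dump(assoc, fh, indent=2)


def _stage_ribo(config: ScenarioConfig, outdir: Path) -> None:
    d = outdir / "ribo"
    d.mkdir(parents=True)
    src = outdir / "simulate"
    fp = pd.read_csv(src / "footprints.tsv", sep="\t")
    ann_df = pd.read_csv(src / "cds_annotations.tsv", sep="\t")
    ann = {r.transcript: (int(r.cds_start), int(r.cds_end))
           for r in ann_df.itertuples()}
    cds_set = _read_fasta(src / "cds.fa")
    offsets, confident = ribo.infer_psite_offsets(fp, ann)
    pd.DataFrame({"length": list(offsets), "offset": list(offsets.values()),
                  "confident": [confident[l] for l in offsets]}
                 ).to_csv(d / "psite_offsets.tsv", sep="\t", index=False)
    vectors, stats = ribo.codonize_footprints(fp, ann, offsets)
    wt, ko = ribo.group_and_correct(vectors)
    table = ribo.dwell_and_asite(wt, ko, cds_set)
    table.to_csv(d / "dwell_time.tsv", sep="\t")
    with open(d / "codonize_stats.json", "w") as fh:
        json.dump(stats, fh)


def _stage_proteome(config: ScenarioConfig, outdir: Path) -> None:
    d = outdir / "proteome"
    d.mkdir(parents=True)
    src = outdir / "simulate"
    table = pd.read_csv(src / "proteome_log2.tsv", sep="\t", index_col=0)
    gly = pd.read_csv(src / "proteome_gly_content.tsv", sep="\t",
                      index_col=0).iloc[:, 0]
    diff = proteome.protein_differential(table)
    diff.to_csv(d / "protein_differential.tsv", sep="\t")
    comp = proteome.stratify_and_compare(diff, gly)
    with open(d / "glycine_strata.json", "w") as fh:
        json.dump(comp, fh, indent=2)


def _stage_metabolome(config: ScenarioConfig, outdir: Path) -> None:
    d = outdir / "metabolome"
    d.mkdir(parents=True)
    src = outdir / "simulate"
    areas = pd.read_csv(src / "metabolite_areas.tsv", sep="\t")
    pooled = pd.read_csv(src / "pooled_heavy.tsv", sep="\t",
                         index_col=0).iloc[:, 0]
    weights = pd.read_csv(src / "tissue_weights.tsv", sep="\t",
                          index_col=0).iloc[:, 0]
    levels = metabolomics.quantify_normalize(areas, pooled, weights)
    levels.to_csv(d / "normalized_levels.tsv", sep="\t")
    tests = metabolomics.amino_acid_tests(levels)
    tests.to_csv(d / "amino_acid_tests.tsv", sep="\t")


def _stage_report(config: ScenarioConfig, outdir: Path) -> None:
    d = outdir / "report"
    d.mkdir(parents=True)
    meth = pd.read_csv(outdir / "methylation" / "differential_methylation.tsv",
                       sep="\t")
    de = pd.read_csv(outdir / "expression" / "isodecoder_de.tsv", sep="\t",
                     index_col=0)
    rollup = pd.read_csv(outdir / "expression" / "family_rollup.tsv",
                         sep="\t", index_col=0)
    with open(outdir / "logter" / "gly_association.json") as fh:
        assoc = json.load(fh)
    dwell = pd.read_csv(outdir / "ribo" / "dwell_time.tsv", sep="\t",
                        index_col=0)
    with open(outdir / "proteome" / "glycine_strata.json") as fh:
        strata = json.load(fh)
    metab = pd.read_csv(outdir / "metabolome" / "amino_acid_tests.tsv",
                        sep="\t", index_col=0)
    nsun2 = meth[meth["enzyme"] == "Nsun2"]
    dnmt2 = meth[meth["enzyme"] == "Dnmt2"]
    gly_de = de[de.index.str.contains("-Gly-")]
    rel = dwell["relative_dt"].dropna()
    summary = {
        "methylation": {
            "min_nsun2_delta_points": float(nsun2["delta"].min()),
            "min_nsun2_relative_deficit_pct": float(
                (100.0 * (nsun2["mean_wt"] - nsun2["mean_ko"])
                 / nsun2["mean_wt"]).min()),
            "max_abs_dnmt2_delta_points": float(dnmt2["delta"].abs().max()),
        },
        "expression": {
            "n_gly_isodecoders": int(len(gly_de)),
            "n_gly_negative_logfc": int((gly_de["logfc"] < 0).sum()),
            "n_gly_significant_down": int(
                (gly_de["significant"] & (gly_de["logfc"] < 0)).sum()),
            "n_significant_total": int(de["significant"].sum()),
            "family_rollup": rollup.to_dict(orient="index"),
        },
        "logter": {"pearson_r": assoc["r"], "pearson_p": assoc["p"],
                   "mi_z": assoc["z"], "mi_p_perm": assoc["p_perm"]},
        "ribo": {
            "gga_relative_dt": float(dwell.loc["GGA", "relative_dt"]),
            "gga_is_max_relative_dt": bool(
                rel.idxmax() == "GGA") if len(rel) else False,
        },
        "proteome": strata,
        "metabolome": {
            "glycine_fold_change": float(metab.loc["Gly", "fold_change"]),
            "glycine_is_grubbs_outlier": bool(
                metab.loc["Gly", "grubbs_outlier"]),
            "n_grubbs_outliers": int(metab["grubbs_outlier"].sum()),
        },
    }
    with open(d / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


_RUNNERS = {
    "simulate": _stage_simulate, "methylation": _stage_methylation,
    "expression": _stage_expression, "fragments": _stage_fragments,
    "logter": _stage_logter, "ribo": _stage_ribo,
    "proteome": _stage_proteome, "metabolome": _stage_metabolome,
    "report": _stage_report,
}


def run_pipeline(config: ScenarioConfig, outdir, stages=None) -> dict:
    """Run the requested stages in dependency order; return the manifest.

    Each stage writes once into its own subdirectory of ``outdir``; a
    stage whose upstream outputs are missing raises a
    :class:`PipelineError` naming the stage to run first.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    requested = list(STAGES) if stages is None else [s for s in STAGES
                                                     if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    config.to_yaml(outdir / "config.yaml")
    for stage in requested:
        for dep in _DEPS[stage]:
            if not (outdir / dep).is_dir():
                raise PipelineError(
                    f"stage '{stage}' needs outputs of '{dep}'; run "
                    f"'{dep}' first")
        if (outdir / stage).exists():
            raise PipelineError(
                f"output directory for stage '{stage}' already exists "
                f"(stages are write-once)")
        _RUNNERS[stage](config, outdir)
    manifest = {
        "seed": config.seed,
        "version": __import__("glytrome").__version__,
        "config_sha256": _sha256(outdir / "config.yaml"),
        "stages": requested,
        "files": {
            str(p.relative_to(outdir)): _sha256(p)
            for stage in requested
            for p in sorted((outdir / stage).rglob("*")) if p.is_file()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
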