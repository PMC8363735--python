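"""Synthetic-scenario generator: structure, forced cases, recovery."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from glytrome import ScenarioConfig
from glytrome import simulate as sim
from glytrome.config import ConfigurationError


# ---------------------------------------------------------------- reference

def test_reference_counts_and_gly_structure(reference, default_config):
    assert len(reference) == default_config.n_isodecoders == 162
    gly = [r for r in reference if r.family == "Gly"]
    assert len(gly) == 10
    assert set(r.anticodon for r in gly) == {"GCC", "CCC", "TCC"}
    for r in gly:
        nsun2 = [s.label for s in r.sites if s.enzyme == "Nsun2"]
        assert sorted(nsun2) == ["C39", "C46", "C47", "C48"]
        assert [s.label for s in r.sites if s.enzyme == "Dnmt2"] == ["C37"]


def test_reference_nongly_sites_and_invariants(reference):
    ids = [r.isodecoder_id for r in reference]
    assert len(set(ids)) == len(ids)
    for r in reference:
        if r.family != "Gly":
            assert sum(s.enzyme == "Nsun2" for s in r.sites) <= 3
        # anticodon at canonical positions 34-36 (1-based)
        assert r.sequence[33:36] == r.anticodon
        assert 60 <= len(r.sequence) <= 100
        for s in r.sites:
            assert r.sequence[s.position - 1] == "C"


def test_reference_single_gly_record():
    cfg = ScenarioConfig(seed=1, n_isodecoders=1, gly_isodecoder_count=1)
    ref = sim.generate_reference(cfg)
    assert len(ref) == 1
    rec = ref.records[0]
    assert rec.family == "Gly"
    assert sum(s.enzyme == "Nsun2" for s in rec.sites) == 4


def test_reference_config_error():
    with pytest.raises(ConfigurationError):
        ScenarioConfig(seed=1, n_isodecoders=5, gly_isodecoder_count=10)


def test_reference_seed_determinism(tmp_path, default_config):
    digests = []
    for d in ("a", "b"):
        ref = sim.generate_reference(ScenarioConfig(seed=42))
        fa, tsv = tmp_path / f"{d}.fa", tmp_path / f"{d}.tsv"
        ref.to_fasta(fa)
        ref.to_sites_tsv(tsv)
        digests.append((hashlib.sha256(fa.read_bytes()).hexdigest(),
                        hashlib.sha256(tsv.read_bytes()).hexdigest()))
    assert digests[0] == digests[1]


def test_reference_fasta_tsv_roundtrip(tmp_path, panel):
    panel.to_fasta(tmp_path / "p.fa")
    panel.to_sites_tsv(tmp_path / "p.tsv")
    back = sim.TRNAReferenceSet.from_files(tmp_path / "p.fa",
                                           tmp_path / "p.tsv")
    assert [r.isodecoder_id for r in back] == [r.isodecoder_id for r in panel]
    assert back.records[0].sequence == panel.records[0].sequence
    assert ([ (s.position, s.label, s.enzyme) for s in back.records[0].sites]
            == [(s.position, s.label, s.enzyme)
                for s in panel.records[0].sites])


# ----------------------------------------------------------- bisulfite reads

def _one_amplicon_config(**meth):
    wt = {"C46": 0.9, "C47": 0.9, "C48": 0.9, "C39": 0.15, "C37": 0.9,
          "C38": 0.9}
    wt.update(meth)
    return ScenarioConfig(seed=3, n_isodecoders=1, gly_isodecoder_count=1,
                          methylation_wt=wt, n_replicates_bisulfite=1,
                          reads_per_amplicon=500)


def test_bisulfite_forced_probabilities():
    cfg = _one_amplicon_config(C46=1.0, C47=0.0)
    cfg = ScenarioConfig(**{**cfg.to_dict(), "conversion_efficiency": 1.0})
    ref = sim.generate_reference(cfg)
    rec = ref.records[0]
    p46 = next(s.position for s in rec.sites if s.label == "C46") - 1
    p47 = next(s.position for s in rec.sites if s.label == "C47") - 1
    reads = sim.generate_bisulfite_reads(ref, cfg, "WT")["WT_rep1"]
    assert all(seq[p46] == "C" for _, seq in reads)   # probability 1 -> kept
    assert all(seq[p47] == "T" for _, seq in reads)   # probability 0 -> converted


def test_bisulfite_half_methylated_binomial_interval():
    cfg = _one_amplicon_config(C46=0.5)
    cfg = ScenarioConfig(**{**cfg.to_dict(), "reads_per_amplicon": 10_000})
    ref = sim.generate_reference(cfg)
    rec = ref.records[0]
    p46 = next(s.position for s in rec.sites if s.label == "C46") - 1
    reads = sim.generate_bisulfite_reads(ref, cfg, "WT")["WT_rep1"]
    frac = np.mean([seq[p46] == "C" for _, seq in reads])
    assert abs(frac - 0.5) < 0.02     # binomial 99% interval at n=10,000


def test_bisulfite_non_c_positions_conserved():
    cfg = _one_amplicon_config()
    ref = sim.generate_reference(cfg)
    rec = ref.records[0]
    reads = sim.generate_bisulfite_reads(ref, cfg, "WT")["WT_rep1"]
    non_c = [i for i, b in enumerate(rec.sequence) if b != "C"]
    for _, seq in reads[:100]:
        assert all(seq[i] == rec.sequence[i] for i in non_c)


def test_bisulfite_unknown_group_raises(panel, default_config):
    with pytest.raises(ValueError):
        sim.generate_bisulfite_reads(panel, default_config, "HET")


# ------------------------------------------------------------- count tables

def test_counts_null_scenario_equal_group_means(reference):
    cfg = ScenarioConfig(seed=5, gly_depletion_strong=1.0,
                         gly_depletion_weak=1.0, nongly_down_fc=1.0,
                         nongly_up_fc=1.0, n_replicates_counts=30)
    counts = sim.generate_count_tables(reference, cfg)
    wt = counts[[c for c in counts if c.startswith("WT")]].mean(axis=1)
    ko = counts[[c for c in counts if c.startswith("KO")]].mean(axis=1)
    ratio = (ko.sum()) / (wt.sum())
    assert ratio == pytest.approx(1.0, abs=0.05)


def test_counts_poisson_limit_variance():
    cfg = ScenarioConfig(seed=6, nb_dispersion=0.0, n_replicates_counts=200)
    ref = sim.generate_reference(ScenarioConfig(seed=6, n_isodecoders=20,
                                                gly_isodecoder_count=2))
    counts = sim.generate_count_tables(ref, cfg)
    wt = counts[[c for c in counts if c.startswith("WT")]]
    ratios = wt.var(axis=1) / wt.mean(axis=1)
    # variance/mean -> 1 in the Poisson limit
    assert np.median(ratios) == pytest.approx(1.0, abs=0.25)


def test_counts_default_fold_changes_recovered(reference):
    cfg = ScenarioConfig(seed=7, n_replicates_counts=250)
    counts = sim.generate_count_tables(reference, cfg)
    fc = sim.effect_map(reference, cfg)
    wt = counts[[c for c in counts if c.startswith("WT")]].mean(axis=1)
    ko = counts[[c for c in counts if c.startswith("KO")]].mean(axis=1)
    gly_ids = [r.isodecoder_id for r in reference if r.family == "Gly"]
    est = (ko / wt).loc[gly_ids]
    for iso in gly_ids:
        assert est[iso] == pytest.approx(fc[iso], rel=0.15)
    assert sorted(set(round(fc[i], 2) for i in gly_ids)) == [0.4, 0.85]
    assert sum(fc[i] == 0.4 for i in gly_ids) == 7


# ----------------------------------------------------------------- ribosome

def test_ribo_rejects_bad_cds(small_ribo_config):
    with pytest.raises(ValueError):
        sim.generate_ribo_profiles({"g": "ATGGG"}, small_ribo_config)


def test_ribo_uniform_when_no_stall(cds_small):
    cds_set, _ = cds_small
    cfg = ScenarioConfig(seed=12, ribo_stall_gga_ko=1.0, init_peak=1.0,
                         n_ribo_transcripts=5,
                         footprints_per_transcript=20_000)
    fp, ann, offsets, _ = sim.generate_ribo_profiles(cds_set, cfg)
    from glytrome import ribo
    vec, _ = ribo.codonize_footprints(fp, ann, offsets)
    t = sorted(ann)[0]
    v = vec["KO_rep1"][t]
    interior = v[5:-5]
    # expected occupancy uniform along the interior
    assert interior.std() / interior.mean() < 0.5
    assert interior.mean() > 0


def test_ribo_gga_density_elevated(cds_small):
    cds_set, _ = cds_small
    cfg = ScenarioConfig(seed=13, n_ribo_transcripts=20,
                         footprints_per_transcript=3000)
    fp, ann, offsets, _ = sim.generate_ribo_profiles(cds_set, cfg)
    from glytrome import ribo
    vec, _ = ribo.codonize_footprints(fp, ann, offsets)
    ko = {}
    for t, v in vec["KO_rep1"].items():
        ko[t] = np.asarray(v, float)
    dens = []
    for t, v in ko.items():
        cds = cds_set[t]
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        interior = v[5:-5]
        m = interior.mean()
        if m == 0:
            continue
        for ci in range(5, len(codons) - 5):
            if codons[ci] == "GGA":
                dens.append(v[ci] / m)
    assert np.mean(dens) == pytest.approx(3.0, rel=0.2)


def test_ribo_true_offsets_in_window():
    assert all(10 <= o <= 15 for o in sim.TRUE_OFFSETS.values())


# ----------------------------------------------------- omics + metabolomics

def test_omics_zero_slope_zero_logter(cds_small):
    cds_set, _ = cds_small
    cfg = ScenarioConfig(seed=14, ter_gly_slope=0.0, n_genes=40)
    om = sim.generate_omics_tables(cds_set, cfg)
    from glytrome import codon
    lt = codon.compute_logter(om["protein"], om["rna"])
    assert abs(lt["logter"].mean()) < 0.1


def test_metabolite_table_has_19_amino_acids(cds_small, default_config):
    cds_set, _ = cds_small
    om = sim.generate_omics_tables(cds_set, default_config)
    areas = om["metabolite_areas"]
    assert areas["amino_acid"].nunique() == 19
    assert "Cys" not in set(areas["amino_acid"])


def test_metabolite_glycine_ratio_at_large_n(cds_small):
    cds_set, _ = cds_small
    cfg = ScenarioConfig(seed=15, n_replicates_metabolites=200)
    om = sim.generate_omics_tables(cds_set, cfg)
    areas = om["metabolite_areas"]
    endo = areas[areas["channel"] == "endogenous"]
    gly = endo[endo["amino_acid"] == "Gly"].set_index("sample")["area"]
    w = om["tissue_weights"]
    adj = gly / (w / w.iloc[0])       # remove the tissue-weight scaling
    wt = adj[[s for s in adj.index if s.startswith("WT")]].mean()
    ko = adj[[s for s in adj.index if s.startswith("KO")]].mean()
    assert ko / wt == pytest.approx(2.46, rel=0.05)


def test_proteome_generator_strata_sizes(default_config):
    out = sim.generate_proteome_table(default_config, n_proteins=500,
                                      n_decreased=60, n_increased=80)
    truth = out["truth"]
    assert (truth == "decreased").sum() == 60
    assert (truth == "increased").sum() == 80
    assert out["table"].shape == (500, 10)
    assert (out["gly_content"] >= 0).all()


# ------------------------------------------------------------------ UMI seq

def test_umi_reads_layout():
    reads = sim.generate_umi_reads({"ACGTACGTACGTACGTACGT": 1}, seed=0,
                                   duplication=1.0)
    _, seq = reads[0]
    assert seq.startswith(sim.Y5_PREFIX)
    i = len(sim.Y5_PREFIX)
    assert seq[i + 4: i + 4 + len(sim.Y5_SUFFIX)] == sim.Y5_SUFFIX
    assert seq.endswith(sim.Y3_SUFFIX)
    assert sim.Y3_PREFIX in seq
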