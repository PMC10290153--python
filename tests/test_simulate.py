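"""Generator contracts: coordinates, determinism, mixture structure, truth."""

import math

import numpy as np
import pytest

from trfscan import simulate
from trfscan.config import SimConfig
from trfscan.errors import ConfigError, DataError
from trfscan.pipeline import guard_not_truth
from trfscan.sequtils import revcomp
from trfscan.seqio import write_fasta


def test_locus_intervals_are_one_based_closed(toy, sim_config):
    _, loci = toy
    assert len(loci) == sim_config.trna_copies == 15
    for loc in loci:
        assert loc.end - loc.start + 1 == sim_config.trna_gene_length == 71
        assert loc.gene_name.startswith("TRNAG-")


def test_single_copy_interval_arithmetic():
    cfg = SimConfig(seed=5, trna_copies=1, n_chromosomes=1)
    _, loci = simulate.generate_toy_genome(cfg)
    (loc,) = loci
    assert loc.end == loc.start + 70


def test_minus_strand_loci_carry_reverse_complement(toy):
    genome, loci = toy
    plus = [l for l in loci if l.strand == "+"]
    minus = [l for l in loci if l.strand == "-"]
    assert plus and minus, "both strands should be represented at 15 copies"
    gene_fwd = genome[plus[0].chrom][plus[0].start - 1: plus[0].end]
    for loc in minus:
        assert genome[loc.chrom][loc.start - 1: loc.end] == revcomp(gene_fwd)


def test_fragment_longer_than_gene_rejected():
    with pytest.raises(ConfigError):
        SimConfig(fragment_length=80, trna_gene_length=71).validate()


def test_same_seed_identical_fasta_bytes(tmp_path, sim_config):
    paths = []
    for name in ("a.fasta", "b.fasta"):
        genome, _ = simulate.generate_toy_genome(sim_config)
        p = tmp_path / name
        write_fasta(genome, p)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_generators_deterministic(sim_config, toy):
    genome, loci = toy
    r1 = simulate.simulate_small_rna_reads(genome, loci, sim_config)
    r2 = simulate.simulate_small_rna_reads(genome, loci, sim_config)
    assert [rs.reads for rs in r1] == [rs.reads for rs in r2]
    p1, _, _ = simulate.simulate_proteome(sim_config)
    p2, _, _ = simulate.simulate_proteome(sim_config)
    assert p1.equals(p2)
    m1, _, _ = simulate.simulate_metabolome(sim_config)
    m2, _, _ = simulate.simulate_metabolome(sim_config)
    assert m1.equals(m2)


def test_expected_group_ratio_is_configured_fold():
    cfg = SimConfig()
    bg_c, mir_c, trf_c = simulate._group_weights(cfg, "coarse")
    bg_f, mir_f, trf_f = simulate._group_weights(cfg, "fine")
    assert trf_c / trf_f == pytest.approx(cfg.trf_fold)
    assert mir_c == mir_f
    assert bg_c + mir_c + trf_c == pytest.approx(1.0)
    assert bg_f + mir_f + trf_f == pytest.approx(1.0)


def test_empty_locus_list_with_fragment_component_rejected(sim_config):
    with pytest.raises(ConfigError):
        simulate.simulate_small_rna_reads({}, [], sim_config)


def test_dominant_fraction_matches_binomial_oracle(toy):
    """Within the 32nt component, the dominant sequence frequency should sit
    within 3 binomial standard errors of the configured fraction."""
    cfg = SimConfig(seed=7, read_depth=100_000, n_per_group=2)
    genome, loci = toy
    readsets = simulate.simulate_small_rna_reads(genome, loci, cfg)
    frag = simulate.fragment_sequence(genome, loci, cfg.fragment_length)
    decoys = set(simulate.decoy_sequences(genome, loci, cfg))
    coarse = [rs for rs in readsets if rs.group == "coarse"][0]
    n_dom = sum(r == frag for r in coarse.reads)
    n_decoy = sum(r in decoys for r in coarse.reads)
    n = n_dom + n_decoy
    p_hat = n_dom / n
    se = math.sqrt(0.9 * 0.1 / n)
    assert abs(p_hat - cfg.dominant_fraction_coarse) < 3 * se


def test_no_fragment_component_gives_flat_32(toy):
    """With the 32nt weight at zero the spectrum has no systematic excess at 32."""
    cfg = SimConfig(seed=11, trf_weight_coarse=0.0, read_depth=100_000)
    spectra = simulate.simulate_length_counts(cfg)
    for s in spectra:
        background = [s.normalized[L] for L in s.normalized
                      if L not in (22, 32)]
        mu, sd = np.mean(background), np.std(background)
        assert abs(s.normalized[32] - mu) < 5 * sd + 5.0


def test_proteome_null_pvalues_calibrated():
    """Zero planted effects: the downstream test rejects at its nominal rate."""
    from trfscan.integration import call_deps
    cfg = SimConfig(seed=3, protein_count=2000, n_up_proteins=0,
                    n_down_proteins=0, n_per_group=10, n_extra_targets=0)
    table, groups, _ = simulate.simulate_proteome(cfg)
    _, _, stats = call_deps(table, groups)
    rate = (stats["p_value"] < 0.05).mean()
    assert 0.03 < rate < 0.07


def test_planted_half_fold_passes_down_cutoff():
    cfg = SimConfig(seed=4, protein_noise_sd=0.05, n_per_group=5)
    table, groups, truth = simulate.simulate_proteome(cfg)
    from trfscan.integration import call_deps
    _, down, stats = call_deps(table, groups)
    planted = truth["down"]
    assert set(planted) <= down
    assert (stats.loc[planted, "fold"] < 0.83).all()


def test_qc_zero_noise_identical_profiles():
    cfg = SimConfig(seed=9, qc_noise_sd=0.0)
    table, roles, _ = simulate.simulate_metabolome(cfg)
    qc_cols = [c for c, r in roles.items() if r == "QC"]
    assert len(qc_cols) == cfg.n_qc
    for c in qc_cols[1:]:
        assert np.allclose(table[qc_cols[0]], table[c])


def test_qpcr_zero_noise_identities():
    cfg = SimConfig(seed=2, qpcr_noise_sd=0.0)
    q1 = simulate.simulate_qpcr(cfg, fold_coarse_over_fine=1.0)
    dct = q1["ct_target"] - q1["ct_reference"]
    assert np.allclose(dct, dct.iloc[0])
    from trfscan.differential import ddct
    q2 = simulate.simulate_qpcr(cfg, fold_coarse_over_fine=2.0)
    out = ddct(q2, control_group="fine")
    assert out["ddct"] == pytest.approx(-1.0)
    assert out["coarse"] == pytest.approx(2.0)


def test_truth_files_refused_as_pipeline_input(tmp_path):
    p = tmp_path / ("sim" + simulate.TRUTH_SUFFIX)
    p.write_text("{}")
    with pytest.raises(DataError):
        guard_not_truth(p)


def test_decoys_avoid_loci_and_fragment(toy, sim_config):
    genome, loci = toy
    frag = simulate.fragment_sequence(genome, loci, sim_config.fragment_length)
    decoys = simulate.decoy_sequences(genome, loci, sim_config)
    assert len(decoys) == sim_config.n_decoys == len(set(decoys))
    assert frag not in decoys
    gene_seqs = {genome[l.chrom][l.start - 1: l.end] for l in loci}
    for d in decoys:
        assert all(d not in g for g in gene_seqs)
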