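"""Generator invariants: determinism, composition, planted truth."""

import numpy as np
import pandas as pd
import pytest

from methylscape.annotation import read_gff3, write_gff3
from methylscape.simulate import (
    CONTROL_LABEL,
    SimulationConfig,
    TruthTable,
    simulate_annotation,
    simulate_bisulfite_counts,
    simulate_expression,
    simulate_genome,
)


def test_same_seed_identical_outputs(sim_config, study):
    genome2 = simulate_genome(sim_config)
    assert genome2 == study["genome"]
    tables2, truth2 = simulate_bisulfite_counts(
        sim_config, genome2, study["annotation"], CONTROL_LABEL
    )
    for t1, t2 in zip(study["control_tables"], tables2):
        pd.testing.assert_frame_equal(t1, t2)
    assert truth2 == study["truth"]


def test_gc_fraction_extremes_and_sampling_bound():
    only_gc = simulate_genome(SimulationConfig(seed=2, gc_fraction=1.0, chrom_length=2000,
                                               spike_in_length=500, n_chromosomes=1))
    assert set(only_gc["chr1"]) <= {"G", "C"}
    half = simulate_genome(SimulationConfig(seed=3, gc_fraction=0.5, chrom_length=100_000,
                                            spike_in_length=500, n_chromosomes=1))
    seq = half["chr1"]
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    se = np.sqrt(0.25 / len(seq))
    assert abs(gc - 0.5) < 3 * se


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(chrom_length=-5)
    with pytest.raises(ValueError):
        SimulationConfig(dmr_effect=0.5)
    with pytest.raises(ValueError):
        SimulationConfig(frac_degs_with_dmr=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(nonconversion_rate=1.2)


def test_annotation_structure(study):
    ann = study["annotation"]
    assert len(ann.genes) == study["config"].n_genes
    assert len(ann.tes) == study["config"].n_tes
    gene_ivs = {g.chrom: [] for g in ann.genes}
    for g in ann.genes:
        assert len(g.exons) >= 1
        # exons disjoint, ordered, inside the gene span
        for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
            assert e1 <= s2
        assert g.exons[0][0] == g.start and g.exons[-1][1] == g.end
        assert 0 <= g.start < g.end <= ann.chrom_lengths[g.chrom]
        gene_ivs[g.chrom].append((g.start, g.end))
    # TEs intergenic: no overlap with any gene
    for t in ann.tes:
        assert 0 <= t.start < t.end <= ann.chrom_lengths[t.chrom]
        for gs, ge in gene_ivs.get(t.chrom, []):
            assert t.end <= gs or t.start >= ge


def test_annotation_without_genes_is_tes_only():
    cfg = SimulationConfig(seed=4, n_genes=0, n_tes=5)
    genome = simulate_genome(cfg)
    ann = simulate_annotation(cfg, genome)
    assert ann.genes == [] and len(ann.tes) == 5


def test_gff3_round_trip(tmp_path, study):
    path = tmp_path / "ann.gff3"
    write_gff3(study["annotation"], path)
    back = read_gff3(path)
    assert back.chrom_lengths == study["annotation"].chrom_lengths
    orig = {g.gene_id: (g.chrom, g.start, g.end, g.strand, tuple(g.exons))
            for g in study["annotation"].genes}
    rt = {g.gene_id: (g.chrom, g.start, g.end, g.strand, tuple(g.exons))
          for g in back.genes}
    assert rt == orig
    assert {(t.te_id, t.start, t.end) for t in back.tes} == \
        {(t.te_id, t.start, t.end) for t in study["annotation"].tes}


def test_spike_in_is_unmethylated_up_to_error_rate(study):
    cfg = study["config"]
    spike = pd.concat(
        [t[t["chrom"] == cfg.spike_in_name] for t in study["control_tables"]]
    )
    total = spike["total_reads"].sum()
    assert total > 1e5
    frac = spike["meth_reads"].sum() / total
    e = cfg.nonconversion_rate
    se = np.sqrt(e * (1 - e) / total)
    assert abs(frac - e) < 3 * se


def test_zero_error_rate_means_zero_spike_in_meth():
    cfg = SimulationConfig(seed=5, nonconversion_rate=0.0, chrom_length=20_000,
                           n_genes=4, n_tes=2, n_planted_dmrs=0, spike_in_length=5000)
    genome = simulate_genome(cfg)
    ann = simulate_annotation(cfg, genome)
    tables, _ = simulate_bisulfite_counts(cfg, genome, ann, CONTROL_LABEL)
    for t in tables:
        spike = t[t["chrom"] == cfg.spike_in_name]
        assert (spike["meth_reads"] == 0).all()


def test_planted_window_levels_shift_by_effect():
    """A 4-fold hyper window on a 0.2 CG background reaches ~0.8 in treatment."""
    cfg = SimulationConfig(
        seed=6, context_level_means={"CG": 0.2, "CHG": 0.15, "CHH": 0.05},
        dmr_effect=4.0, n_planted_dmrs=8,
    )
    genome = simulate_genome(cfg)
    ann = simulate_annotation(cfg, genome)
    ctrl, truth = simulate_bisulfite_counts(cfg, genome, ann, CONTROL_LABEL)
    trt, _ = simulate_bisulfite_counts(cfg, genome, ann, "treatment")

    def window_level(tables, chrom, start, end):
        sub = pd.concat(tables)
        sub = sub[(sub["chrom"] == chrom) & (sub["context"] == "CG")
                  & (sub["pos"] - 1 >= start) & (sub["pos"] - 1 < end)]
        return sub["meth_reads"].sum() / sub["total_reads"].sum()

    hypers = [d for d in truth.planted_dmrs if d[4] == "hyper"]
    assert hypers, "seeded truth should contain hyper windows"
    ctrl_levels, trt_levels = [], []
    for chrom, start, end, _ctx, _dir in hypers:
        c = window_level(ctrl, chrom, start, end)
        t = window_level(trt, chrom, start, end)
        # per-window: sampling noise of ~10 beta-drawn sites
        assert c == pytest.approx(0.2, abs=0.1)
        assert t == pytest.approx(0.8, abs=0.2)
        ctrl_levels.append(c)
        trt_levels.append(t)
    assert np.mean(ctrl_levels) == pytest.approx(0.2, abs=0.05)
    assert np.mean(trt_levels) == pytest.approx(0.8, abs=0.08)


def test_level_means_recovered_per_context(study):
    """Observed pooled methylated fraction tracks m + (1-m)e per context."""
    cfg = study["config"]
    t = study["control_tables"][0]
    genomic = t[t["chrom"] != cfg.spike_in_name]
    e = cfg.nonconversion_rate
    for ctx, mu in cfg.context_level_means.items():
        sub = genomic[genomic["context"] == ctx]
        frac = sub["meth_reads"].sum() / sub["total_reads"].sum()
        expected = mu + (1 - mu) * e
        # beta-distributed levels: allow a generous band around the mean
        assert frac == pytest.approx(expected, abs=0.03)


def test_truth_round_trip(tmp_path, study, sim_config):
    truth = study["truth"]
    expr = simulate_expression(sim_config, study["annotation"], truth, "t4h")
    assert len(expr) == sim_config.n_genes
    truth.write(tmp_path / "truth")
    back = TruthTable.read(tmp_path / "truth")
    assert back == truth


def test_truth_intervals_within_bounds_and_links_exist(study):
    ann = study["annotation"]
    gene_ids = {g.gene_id for g in ann.genes}
    for chrom, start, end, ctx, direction in study["truth"].planted_dmrs:
        assert 0 <= start < end <= ann.chrom_lengths[chrom]
        assert direction in ("hyper", "hypo")
    for *_, gid, region in study["truth"].dmr_to_gene_links:
        assert gid in gene_ids and region in ("upstream", "body")


def test_expression_planted_degs_pass_filter_and_links(study, sim_config):
    from methylscape.expression import filter_degs

    truth = study["truth"]
    expr = simulate_expression(sim_config, study["annotation"], truth, "t4h")
    degs = filter_degs(expr)
    planted = truth.deg_ids("t4h")
    assert planted <= set(degs["gene_id"])          # all planted recovered
    assert set(degs["gene_id"]) == planted          # and nothing else passes
    n_linked = round(sim_config.frac_degs_with_dmr * sim_config.n_planted_degs)
    linked_genes = {g for *_, g, _r in truth.dmr_to_gene_links}
    assert len(planted & linked_genes) >= n_linked


def test_no_planted_degs_means_no_degs(study):
    from methylscape.expression import filter_degs

    cfg = SimulationConfig(seed=7, n_planted_degs=0)
    expr = simulate_expression(cfg, study["annotation"], TruthTable(), "t4h")
    assert len(filter_degs(expr)) == 0
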