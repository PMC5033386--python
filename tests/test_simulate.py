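"""Synthetic-data generator: genealogy, evolution, conversion, reads."""

import numpy as np
import pytest
from scipy import stats as sps

from transpoly.distances import distance_matrix
from transpoly.simulate import (
    GeneNode,
    SimConfig,
    apply_gene_conversion,
    evolve_alignment,
    generate_amplicon_reads,
    realized_dnds,
    simulate_dataset,
    simulate_gene_genealogy,
    species_tree_root_age,
)


def test_config_validation():
    with pytest.raises(ValueError, match="unrealizable"):
        SimConfig(duplication_times=(10.0,)).validate()  # younger than root (20 My)
    with pytest.raises(ValueError):
        SimConfig(chimera_fraction=1.0).validate()
    with pytest.raises(ValueError):
        SimConfig(error_rate=-0.1).validate()
    SimConfig().validate()


def test_single_lineage_single_allele_matches_species_tree():
    cfg = SimConfig(seed=1, duplication_times=(40.0,), n_alleles_per_species_per_lineage=1)
    g, truth = simulate_gene_genealogy(cfg)

    def topo(node):
        if node.is_leaf:
            return node.label.split("_")[0]
        return frozenset(topo(c) for c in node.children)

    expected = frozenset(
        {
            "Cycy",
            frozenset(
                {
                    "Gagl",
                    frozenset(
                        {
                            "Pipi",
                            frozenset(
                                {"Cofr", frozenset({"Coma", frozenset({"Cobr", "Coco"})})}
                            ),
                        }
                    ),
                }
            ),
        }
    )
    assert topo(g) == expected


def test_default_scenario_four_disjoint_all_species_lineages():
    cfg = SimConfig(seed=4)
    g, truth = simulate_gene_genealogy(cfg)
    members = {}
    for a, l in truth.lineage_membership.items():
        members.setdefault(l, set()).add(a)
    assert len(members) == 4
    species = {m.split("_")[0] for m in next(iter(members.values()))}
    for mem in members.values():
        assert {m.split("_")[0] for m in mem} == species
        assert len(species) == 7


@pytest.mark.parametrize("seed", range(5))
def test_lineage_tmrca_below_founding_time(seed):
    cfg = SimConfig(seed=seed)
    g, truth = simulate_gene_genealogy(cfg)
    tmrcas = truth.lineage_tmrcas()
    for lid, t in tmrcas.items():
        assert t <= truth.lineage_founding[lid]


def test_genealogy_deterministic_under_seed():
    a, _ = simulate_gene_genealogy(SimConfig(seed=5))
    b, _ = simulate_gene_genealogy(SimConfig(seed=5))
    assert a.newick() == b.newick()
    c, _ = simulate_gene_genealogy(SimConfig(seed=6))
    assert c.newick() != a.newick()


def test_zero_branch_lengths_give_identical_sequences():
    g = GeneNode(None, 0.0, [GeneNode("s_L1_1", 0.0), GeneNode("s_L1_2", 0.0)])
    aln, _ = evolve_alignment(g, SimConfig(seed=1))
    assert aln.seqs[0] == aln.seqs[1]


def test_realized_dnds_neutral_control_near_one():
    cfg = SimConfig(seed=2, pbr_omega=1.0, fragment_length=60000, pbr_codons=frozenset())
    g = GeneNode(None, 10.0, [GeneNode("s_L1_1", 0.0), GeneNode("s_L1_2", 0.0)])
    _, tr = evolve_alignment(g, cfg)
    assert realized_dnds(tr, cfg) == pytest.approx(1.0, abs=0.15)


def test_pbr_acceleration_partition_contrast():
    cfg = SimConfig(seed=3, pbr_omega=5.0)
    g, tr = simulate_gene_genealogy(cfg)
    _, tr = evolve_alignment(g, cfg, tr)
    assert realized_dnds(tr, cfg, "pbr") > realized_dnds(tr, cfg, "non_pbr")


def test_conversion_rate_zero_leaves_alignment_unchanged():
    cfg = SimConfig(seed=1, conversion_rate=0.0)
    g, tr = simulate_gene_genealogy(cfg)
    aln, tr = evolve_alignment(g, cfg, tr)
    aln2, tr2 = apply_gene_conversion(aln, g, cfg, tr)
    assert aln2.seqs == aln.seqs
    assert tr2.conversion_events == []


def test_conversion_copy_semantics():
    cfg = SimConfig(seed=8, conversion_rate=0.5, conversion_tract=40)
    g, tr = simulate_gene_genealogy(cfg)
    aln, tr = evolve_alignment(g, cfg, tr)
    before = dict(zip(aln.labels, aln.seqs))
    aln2, tr2 = apply_gene_conversion(aln, g, cfg, tr)
    after = dict(zip(aln2.labels, aln2.seqs))
    assert tr2.conversion_events
    # replaying the logged events on the input alignment reproduces the output
    replay = dict(before)
    for ev in tr2.conversion_events:
        s, e = ev["start"], ev["end"]
        assert e - s == cfg.conversion_tract
        replay[ev["acceptor"]] = (
            replay[ev["acceptor"]][:s] + replay[ev["donor"]][s:e] + replay[ev["acceptor"]][e:]
        )
    assert replay == after


def test_conversion_tract_longer_than_fragment_errors():
    cfg = SimConfig(seed=1, conversion_rate=0.1, conversion_tract=500)
    g, tr = simulate_gene_genealogy(cfg)
    aln, tr = evolve_alignment(g, cfg, tr)
    with pytest.raises(ValueError, match="tract"):
        apply_gene_conversion(aln, g, cfg, tr)


def test_conversion_reduces_within_species_distance():
    deltas = []
    for seed in range(6):
        base = dict(seed=seed, conversion_tract=60)
        cfg0 = SimConfig(**base, conversion_rate=0.0)
        cfg1 = SimConfig(**base, conversion_rate=1.0)
        g, tr = simulate_gene_genealogy(cfg0)
        aln, tr = evolve_alignment(g, cfg0, tr)
        aln1, _ = apply_gene_conversion(aln, g, cfg1, tr)

        def within_species(a):
            tot, n = 0.0, 0
            for sp in set(a.species):
                idx = [i for i, s in enumerate(a.species) if s == sp]
                D = distance_matrix([a.seqs[i] for i in idx], model="p")
                iu = np.triu_indices(len(idx), k=1)
                tot += D[iu].sum()
                n += iu[0].size
            return tot / n

        deltas.append(within_species(aln) - within_species(aln1))
    assert np.mean(deltas) > 0


def test_reads_exact_when_noise_free():
    cfg = SimConfig(seed=2, error_rate=0.0, chimera_fraction=0.0)
    aln, reads, truth = simulate_dataset(cfg)
    true_seqs = set(aln.seqs)
    for b in reads.batches:
        for r in b.reads:
            assert r.seq in true_seqs
    assert truth.chimera_reads == []


def test_chimera_count_within_binomial_bounds():
    cfg = SimConfig(
        seed=5,
        chimera_fraction=0.1,
        error_rate=0.0,
        read_depth_mean=40.0,
    )
    aln, reads, truth = simulate_dataset(cfg)
    n = len(reads.raw_reads)
    k = len(truth.chimera_reads)
    lo, hi = sps.binom.interval(0.999, n, 0.1)
    assert lo <= k <= hi


def test_reads_byte_identical_under_seed(tmp_path):
    cfg = SimConfig(seed=9)
    _, reads1, _ = simulate_dataset(cfg)
    _, reads2, _ = simulate_dataset(SimConfig(seed=9))
    f1, f2 = tmp_path / "r1.fa", tmp_path / "r2.fa"
    reads1.to_fasta(f1)
    reads2.to_fasta(f2)
    assert f1.read_bytes() == f2.read_bytes()


def test_depth_mean_below_one_errors():
    cfg = SimConfig(seed=1, read_depth_mean=0.5)
    g, tr = simulate_gene_genealogy(cfg)
    aln, tr = evolve_alignment(g, cfg, tr)
    with pytest.raises(ValueError, match="depth"):
        generate_amplicon_reads(aln, cfg, tr)


def test_truth_json_roundtrip(tmp_path, default_sim):
    import json

    _, _, _, truth = default_sim
    p = tmp_path / "truth.json"
    truth.to_json(p)
    obj = json.loads(p.read_text())
    assert set(obj["lineage_membership"].values()) == {"L1", "L2", "L3", "L4"}
    assert obj["true_alleles"]


def test_species_tree_root_age():
    assert species_tree_root_age(SimConfig().species_tree) == pytest.approx(20.0)
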