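import numpy as np
import pytest

from _oracles import brute_force_ssms
from conftest import random_gene

from ssmotif import (
    AtomicMotif,
    GeneMotifSet,
    MotifDatabase,
    SSMEngine,
    SSMType,
    complement,
    enumerate_ssms,
    extract_nodes,
    potential_ssm_count,
    reverse,
    reverse_complement,
    ssm_count_result,
    ssm_type_grid,
    window_count,
)


def gene(gid, *seqs):
    return GeneMotifSet(gid, tuple(AtomicMotif(f"m{i}", s) for i, s in enumerate(seqs)))


@pytest.mark.parametrize("length,l,expected", [(9, 8, 2), (10, 8, 3), (5, 8, 0), (8, 8, 1)])
def test_window_count(length, l, expected):
    assert window_count(length, l) == expected


def test_potential_counts_worked_example(worked_genes):
    g1, g2, g3 = worked_genes
    assert potential_ssm_count(g1, g2, l=8) == 15  # (2 + 3) x 3
    assert potential_ssm_count(g2, g3, l=8) == 9  # 3 x (1 + 2)


def test_potential_count_zero_when_one_side_has_no_windows(worked_genes):
    g1 = gene("a", "ACGTA")  # length 5 < 8
    assert potential_ssm_count(g1, worked_genes[1], l=8) == 0


def test_potential_count_is_bilinear():
    rng = np.random.default_rng(1)
    g1 = random_gene(rng, "a", [9, 12, 10])
    g2 = random_gene(rng, "b", [11, 8])
    doubled = GeneMotifSet(
        "a2",
        g1.motifs + tuple(AtomicMotif(f"d{m.motif_id}", m.sequence) for m in g1.motifs),
    )
    for l in (6, 8, 10):
        assert potential_ssm_count(doubled, g2, l) == 2 * potential_ssm_count(g1, g2, l)


def test_extract_nodes_merges_complementary_windows():
    nodes = extract_nodes(gene("g1", "AAAAAAAA"), gene("g2", "TTTTTTTT"), l=8)
    assert len(nodes) == 1
    assert nodes[0].gene_ids == frozenset({"g1", "g2"})
    assert nodes[0].occurrence_count == 2


def test_extract_nodes_single_gene_windows():
    nodes = extract_nodes(gene("g1", "ACGTACGTA"), GeneMotifSet("g2"), l=8)
    assert len(nodes) == 2
    assert all(n.gene_ids == frozenset({"g1"}) for n in nodes)
    assert [n.canonical for n in nodes] == sorted(n.canonical for n in nodes)


def test_extract_nodes_empty():
    assert extract_nodes(GeneMotifSet("g1"), GeneMotifSet("g2"), l=8) == ()


def test_enumerate_ssms_shared_node_is_singleton_clique():
    ssms = enumerate_ssms(gene("g1", "AAAAAAAA"), gene("g2", "AAAAAAAA"), SSMType(8, 0))
    assert len(ssms) == 1
    (ssm,) = ssms
    assert ssm.canonical_keys == ("AAAAAAAA",)


def test_enumerate_ssms_no_match():
    assert enumerate_ssms(gene("g1", "AAAAAAAA"), gene("g2", "CCCCCCCC"), SSMType(8, 0)) == ()


def test_enumerate_ssms_discards_single_gene_cliques():
    """{A8, A7C} spans both genes; the clique {A7C, A6C2} is gene-2 only."""
    g1 = gene("g1", "AAAAAAAA")
    g2 = gene("g2", "AAAAAAAC", "AAAAAACC")
    ssms = enumerate_ssms(g1, g2, SSMType(8, 1))
    assert len(ssms) == 1
    assert ssms[0].canonical_keys == ("AAAAAAAA", "AAAAAAAC")


def test_ssm_count_result_examples():
    g1 = gene("g1", "AAAAAAAA")
    g2 = gene("g2", "AAAAAAAC", "AAAAAACC")
    r = ssm_count_result(g1, g2, SSMType(8, 1))
    assert (r.ssm_count, r.potential_count, r.ssmc) == (1, 2, 0.5)

    degenerate = ssm_count_result(gene("g1", "ACGTA"), g2, SSMType(8, 1))
    assert degenerate.potential_count == 0 and degenerate.ssmc is None

    self_pair = ssm_count_result(gene("g1", "AAAAAAAA"), gene("g1", "AAAAAAAA"), SSMType(8, 0))
    assert self_pair.ssmc == 1.0


def test_type_grid_matches_direct_enumeration():
    expected = [
        (l, d) for l in range(6, 15) for d in range(0, min(5, l // 3) + 1)
    ]
    grid = ssm_type_grid()
    assert [(t.l, t.d) for t in grid] == expected
    assert len(grid) == 36


@pytest.mark.parametrize("l,d", [(5, 0), (15, 0), (6, 3), (14, 5), (8, -1)])
def test_invalid_types_rejected(l, d):
    with pytest.raises(ValueError):
        SSMType(l, d)


def test_pair_swap_symmetry():
    rng = np.random.default_rng(7)
    for _ in range(20):
        g1 = random_gene(rng, "a", list(rng.integers(6, 14, size=rng.integers(1, 4))))
        g2 = random_gene(rng, "b", list(rng.integers(6, 14, size=rng.integers(1, 4))))
        for t in (SSMType(6, 1), SSMType(8, 2), SSMType(10, 2)):
            r12 = ssm_count_result(g1, g2, t)
            r21 = ssm_count_result(g2, g1, t)
            assert (r12.ssm_count, r12.potential_count) == (r21.ssm_count, r21.potential_count)


def test_strand_and_orientation_symmetry_small():
    rng = np.random.default_rng(11)
    transforms = [lambda s: s, complement, reverse, reverse_complement]
    for _ in range(15):
        g1 = random_gene(rng, "a", list(rng.integers(7, 13, size=2)))
        g2 = random_gene(rng, "b", list(rng.integers(7, 13, size=2)))
        g2t = GeneMotifSet(
            "b",
            tuple(
                AtomicMotif(m.motif_id, transforms[rng.integers(0, 4)](m.sequence))
                for m in g2.motifs
            ),
        )
        for t in (SSMType(6, 1), SSMType(7, 2)):
            assert ssm_count_result(g1, g2, t).ssm_count == ssm_count_result(g1, g2t, t).ssm_count


def test_existence_monotone_in_d():
    """If a pair has an SSM at distance d it has one at d+1 (edges only grow).

    The count itself is not monotone and is deliberately not asserted."""
    rng = np.random.default_rng(13)
    for _ in range(25):
        g1 = random_gene(rng, "a", [int(rng.integers(8, 12))], alphabet="ACG")
        g2 = random_gene(rng, "b", [int(rng.integers(8, 12))], alphabet="ACG")
        for l, dmax in ((6, 2), (9, 3)):
            present = [
                len(enumerate_ssms(g1, g2, SSMType(l, d))) > 0 for d in range(dmax + 1)
            ]
            for lower, higher in zip(present, present[1:]):
                assert not (lower and not higher)


def test_engine_agrees_with_reference_path():
    rng = np.random.default_rng(3)
    grid = ssm_type_grid()
    for _ in range(8):
        g1 = random_gene(rng, "a", list(rng.integers(6, 16, size=rng.integers(1, 4))))
        g2 = random_gene(rng, "b", list(rng.integers(6, 16, size=rng.integers(1, 4))))
        engine = SSMEngine(MotifDatabase([g1, g2]), grid)
        results = engine.pair_results("a", "b")
        for t in grid:
            ref = ssm_count_result(g1, g2, t)
            assert results[t].ssm_count == ref.ssm_count
            assert results[t].potential_count == ref.potential_count


def test_enumerate_matches_brute_force_oracle_small():
    rng = np.random.default_rng(5)
    checked = 0
    while checked < 20:
        g1 = random_gene(rng, "a", [int(rng.integers(6, 9))], alphabet="AC")
        g2 = random_gene(rng, "b", [int(rng.integers(6, 9))], alphabet="AC")
        t = SSMType(6, int(rng.integers(0, 3)))
        if len(extract_nodes(g1, g2, t.l)) > 12:
            continue
        got = {s.canonical_keys for s in enumerate_ssms(g1, g2, t)}
        assert got == brute_force_ssms(g1, g2, t)
        checked += 1


def test_pair_results_tsv_export(tmp_path, worked_genes):
    from ssmotif.core import write_pair_results_tsv

    g1, g2, _ = worked_genes
    engine = SSMEngine(MotifDatabase([g1, g2]))
    path = tmp_path / "pair.tsv"
    write_pair_results_tsv(engine.pair_results("g1", "g2"), path)
    lines = path.read_text().splitlines()
    assert lines[0] == "gene1\tgene2\tl\td\tssm_count\tpotential_count\tssmc"
    row_l8 = [ln for ln in lines[1:] if ln.split("\t")[2] == "8"][0]
    assert row_l8.split("\t")[5] == "15"
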