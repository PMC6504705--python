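"""Fisher/BH machinery, GO and k-mer enrichment, motif matching, DE overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from evopattern import enrichment as en
from evopattern.enrichment import ContingencyTable, MotifEntry
from evopattern.synthetic_data import (SimulationConfig, simulate_genome,
                                       simulate_series_variants)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def test_fisher_two_sided_small_table():
    """(2,0;0,2): hypergeometric outcomes have masses 1/6, 4/6, 1/6; the
    two extremes sum to 1/3."""
    assert en.fisher_exact(ContingencyTable(2, 0, 0, 2)) == pytest.approx(1 / 3)


def test_fisher_one_sided_greater():
    """(3,1;1,3) greater: (C(4,3)C(4,1)+C(4,4)C(4,0))/C(8,4) = 17/70."""
    p = en.fisher_exact(ContingencyTable(3, 1, 1, 3), "greater")
    assert p == pytest.approx(17 / 70)


@pytest.mark.parametrize("table", [(0, 5, 0, 7), (3, 0, 4, 0), (0, 0, 3, 4)])
def test_fisher_zero_margin_gives_one(table):
    assert en.fisher_exact(ContingencyTable(*table)) == pytest.approx(1.0)


def test_fisher_negative_cell_rejected():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 2, 3, 4)


def test_fisher_agrees_with_scipy_small_tables():
    """Library cross-check on every table with total <= 14, all alternatives."""
    for tot in range(1, 15):
        for a in range(tot + 1):
            for b in range(tot - a + 1):
                for c in range(tot - a - b + 1):
                    d = tot - a - b - c
                    for alt in ("two-sided", "greater", "less"):
                        ours = en.fisher_exact(ContingencyTable(a, b, c, d), alt)
                        ref = stats.fisher_exact([[a, b], [c, d]],
                                                 alternative=alt)[1]
                        assert ours == pytest.approx(ref, abs=1e-12)


def test_fisher_agrees_with_scipy_large_margins():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a = int(rng.integers(0, 50))
        b = int(rng.integers(0, 100_000))
        c = int(rng.integers(0, 500))
        d = int(rng.integers(1, 500_000))
        ours = en.fisher_exact(ContingencyTable(a, b, c, d))
        ref = stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def bh_reference(pvalues):
    """Independent step-up implementation: q_(i) = min_{j>=i}(p_(j) m / j)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


def test_bh_worked_example():
    np.testing.assert_allclose(en.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])


def test_bh_single_p_is_identity():
    assert en.bh_adjust([0.37])[0] == pytest.approx(0.37)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        en.bh_adjust([0.5, 1.5])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_bh_matches_reference_and_is_permutation_invariant(pvals):
    q = en.bh_adjust(pvals)
    np.testing.assert_allclose(q, bh_reference(pvals), atol=1e-12)
    assert np.all(q <= 1.0 + 1e-12)
    rng = np.random.default_rng(1)
    perm = rng.permutation(len(pvals))
    q_perm = en.bh_adjust(list(np.asarray(pvals)[perm]))
    np.testing.assert_allclose(np.asarray(q)[perm], q_perm, atol=1e-12)


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

def _uniform_go_universe(n=100, per_gene=("GO:A", "GO:B")):
    return {f"g{i}": set(per_gene) for i in range(n)}


def test_go_concentrated_term_is_significant():
    gene_go = {f"g{i}": {"GO:COMMON"} for i in range(100)}
    for i in range(3):
        gene_go[f"g{i}"] = {"GO:COMMON", "GO:FOCAL"}
    res = en.go_enrichment(gene_go, variant_genes=[f"g{i}" for i in range(3)])
    row = res[res.unit_id == "GO:FOCAL"].iloc[0]
    assert row.a == 3 and row.b == 0
    assert row.p_raw < 0.01 and bool(row.significant)


def test_go_min_count_excludes_singletons():
    gene_go = _uniform_go_universe(20)
    gene_go["g0"] = {"GO:A", "GO:B", "GO:RARE"}
    res = en.go_enrichment(gene_go, variant_genes=["g0", "g1"], min_count=2)
    assert "GO:RARE" not in set(res.unit_id)       # seen once among variant genes
    assert {"GO:A", "GO:B"} <= set(res.unit_id)    # seen twice


def test_go_no_variant_genes_gives_empty_result():
    res = en.go_enrichment(_uniform_go_universe(), variant_genes=[])
    assert res.empty


def test_go_empty_mapping_errors():
    with pytest.raises(ValueError):
        en.go_enrichment({}, variant_genes=["g1"])


def test_go_contingency_cells_count_genes_and_associations():
    gene_go = {"g1": {"X", "Y"}, "g2": {"X"}, "g3": {"Y"}, "g4": {"Y"}}
    res = en.go_enrichment(gene_go, variant_genes=["g1", "g2"], min_count=2)
    row = res[res.unit_id == "X"].iloc[0]
    # a: variant genes with X; b: other genes with X; c/d: remaining associations
    assert (row.a, row.b, row.c, row.d) == (2, 0, 1, 2)


# ---------------------------------------------------------------------------
# k-mer scan
# ---------------------------------------------------------------------------

def test_kmer_scan_manual_window_enumeration():
    """'ACGCG' with a variant at offset 2, k=2: windows AC,CG,GC,CG; the two
    windows covering offset 2 (CG at 1-2, GC at 2-3) are variant."""
    df = en.kmer_scan(["ACGCG"], [[2]], k_min=2, k_max=2)
    counts = {r.kmer: (r.variant, r.nonvariant) for r in df.itertuples()}
    assert counts == {"AC": (0, 1), "CG": (1, 1), "GC": (1, 0)}


def test_kmer_scan_no_variants_all_nonvariant():
    df = en.kmer_scan(["ACGTACGT"], [[]], k_min=1, k_max=3)
    assert (df.variant == 0).all()


def test_kmer_scan_k1_counts_sum_to_sequence_length():
    seqs = ["ACGTAC", "GGTT"]
    df = en.kmer_scan(seqs, [[0], []], k_min=1, k_max=1)
    assert (df.variant + df.nonvariant).sum() == sum(map(len, seqs))


def test_kmer_scan_window_conservation_all_k():
    rng = np.random.default_rng(3)
    seqs = ["".join(rng.choice(list("ACGT"), size=n)) for n in (50, 7, 3)]
    positions = [[5, 20], [0], []]
    df = en.kmer_scan(seqs, positions, k_min=1, k_max=5)
    for k, group in df.groupby("k"):
        expected = sum(max(0, len(s) - k + 1) for s in seqs)
        assert (group.variant + group.nonvariant).sum() == expected


def test_kmer_scan_skips_non_acgt_windows():
    df = en.kmer_scan(["ACNGT"], [[]], k_min=2, k_max=2)
    assert set(df.kmer) == {"AC", "GT"}


def test_kmer_scan_position_out_of_bounds_errors():
    with pytest.raises(ValueError):
        en.kmer_scan(["ACGT"], [[7]], 1, 1)


def test_kmer_scan_short_sequence_contributes_nothing_at_large_k():
    df = en.kmer_scan(["ACG"], [[]], k_min=4, k_max=4)
    assert df.empty


# ---------------------------------------------------------------------------
# k-mer enrichment
# ---------------------------------------------------------------------------

def _cg_biased_dataset(seed=3, n_random=300):
    cfg = SimulationConfig(seed=seed, n_background=0, n_cold_fixed=0,
                           n_hot_fixed=0, n_random=n_random,
                           variant_region="intergenic", cg_variant_weight=10.0)
    genome, genes, _, _ = simulate_genome(cfg)
    records, _ = simulate_series_variants(cfg, genome, genes)
    return en.collect_intergenic_inputs(genome, genes, records)


def test_cg_targeted_bias_detected_at_k2():
    """Variants placed on intergenic CG dinucleotides at 10x weight make
    'CG' significantly enriched in the k=2 family."""
    seqs, positions = _cg_biased_dataset()
    counts = en.kmer_scan(seqs, positions, k_min=2, k_max=2)
    res = en.kmer_enrichment(counts)
    row = res[res.unit_id == "CG"].iloc[0]
    assert bool(row.significant) and row.q_bh <= 0.05
    # enrichment direction: CG's variant share exceeds the family's
    assert row.a / (row.a + row.b) > row.c / (row.c + row.d)


def test_kmer_palindrome_strand_invariance():
    """For the palindromic CG the scan is invariant under reverse
    complementing every input sequence."""
    seqs, positions = _cg_biased_dataset()
    comp = str.maketrans("ACGT", "TGCA")
    rc_seqs = [s.translate(comp)[::-1] for s in seqs]
    rc_pos = [[len(s) - 1 - p for p in pos] for s, pos in zip(seqs, positions)]
    fwd = en.kmer_scan(seqs, positions, 2, 2).set_index("kmer")
    rev = en.kmer_scan(rc_seqs, rc_pos, 2, 2).set_index("kmer")
    assert fwd.loc["CG", "variant"] == rev.loc["CG", "variant"]
    assert fwd.loc["CG", "nonvariant"] == rev.loc["CG", "nonvariant"]


def test_kmer_single_kmer_group_skipped():
    counts = pd.DataFrame({"k": [5], "kmer": ["AAAAA"], "variant": [2],
                           "nonvariant": [10]})
    res = en.kmer_enrichment(counts)
    assert res.empty


def test_kmer_zero_occurrence_rows_excluded():
    counts = pd.DataFrame({"k": [1, 1, 1], "kmer": ["A", "C", "G"],
                           "variant": [1, 0, 2], "nonvariant": [9, 0, 8]})
    res = en.kmer_enrichment(counts)
    assert set(res.unit_id) == {"A", "G"}


# ---------------------------------------------------------------------------
# Motif annotation
# ---------------------------------------------------------------------------

RE1 = MotifEntry("RE1", ("GGGCGCGGAACAAGG",), "repressor element")
OCT = MotifEntry("OCT", ("CGCGGATC",), "octamer-binding motif")
AMBIG = MotifEntry("AMBIG", ("ARYGT",), "with IUPAC codes")


def _enriched(kmers):
    return pd.DataFrame({"unit_id": kmers, "significant": True})


def test_kmer_substring_hits_motif():
    res = en.annotate_motifs(_enriched(["CGCGG"]), [RE1, OCT])
    assert set(res.motif) == {"RE1", "OCT"}
    assert not res.confident.any()        # length 5 < 6


def test_kmer_length_six_hit_is_confident():
    res = en.annotate_motifs(_enriched(["CGCGGA"]), [OCT])
    assert len(res) == 1 and bool(res.iloc[0].confident)


def test_kmer_without_motif_hit_gives_empty_annotation():
    assert en.annotate_motifs(_enriched(["TTTTT"]), [RE1, OCT]).empty


@pytest.mark.parametrize("kmer,hits", [
    ("AACGT", True),    # R matches A, Y matches C
    ("AGTGT", True),    # R matches G, Y matches T
    ("ATCGT", False),   # T does not match R
])
def test_iupac_codes_match_their_nucleotide_sets(kmer, hits):
    assert en.iupac_contains(AMBIG.sequences[0], kmer) is hits


# ---------------------------------------------------------------------------
# DE overlap
# ---------------------------------------------------------------------------

def test_de_overlap_null_simulation_rarely_significant():
    """Independent 10% DE rates in variant and non-variant genes should not
    produce a small p-value."""
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(1000)]
    flags = {g: bool(rng.random() < 0.10) for g in genes}
    variant_genes = list(rng.choice(genes, size=100, replace=False))
    _, p = en.de_overlap_test(variant_genes, flags)
    assert p > 0.05


def test_de_overlap_perfect_association_small_p():
    flags = {f"v{i}": True for i in range(15)}
    flags.update({f"o{i}": False for i in range(85)})
    table, p = en.de_overlap_test([f"v{i}" for i in range(15)], flags)
    assert (table.a, table.b, table.c, table.d) == (15, 0, 0, 85)
    assert p == pytest.approx(en.fisher_exact(table))
    assert p < 1e-10


def test_de_overlap_empty_variant_set_errors():
    with pytest.raises(ValueError):
        en.de_overlap_test([], {"g1": True})


def test_de_overlap_unknown_genes_dropped(caplog):
    flags = {"g1": True, "g2": False, "g3": False}
    table, _ = en.de_overlap_test(["g1", "gX"], flags)
    assert table.a + table.b == 1
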