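"""Gene-order extraction, block finding against an exhaustive oracle, census."""
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastevo.blocks import (GeneOrder, block_census, extract_gene_order, find_blocks,
                             filter_reduced)
from plastevo.simulate import SimulationConfig, simulate_plastome
from plastevo.structure import detect_inverted_repeat


def order(taxon, genes, signs=None):
    return GeneOrder(taxon=taxon, genes=list(genes),
                     signs=list(signs) if signs else [1] * len(genes))


# ---------------------------------------------------------------------------------
# independent oracle: token-string containment on doubled circular orders
# ---------------------------------------------------------------------------------

def oracle_run_valid(ref, other, i, j):
    """Interval [i, j) of the reference order valid in ``other``?

    Validity by token-substring search on the doubled circular order (independent of
    the index arithmetic in the implementation): the run, with signs relative to the
    reference, must occur forward, or reversed with flipped signs.
    """
    run = [(g, s) for g, s in zip(ref.genes[i:j], ref.signs[i:j])]
    if any(g not in other.genes for g, _ in run):
        return "not_applicable"
    doubled = list(zip(other.genes, other.signs)) * 2
    m = len(other.genes)
    fwd = any(doubled[k:k + len(run)] == run for k in range(m))
    rev_run = [(g, -s) for g, s in reversed(run)]
    rev = any(doubled[k:k + len(run)] == rev_run for k in range(m))
    if fwd:
        return "forward"
    if rev:
        return "reverse"
    return "broken"


def oracle_blocks(orders, ref_taxon):
    """Greedy maximal runs using only the oracle validity test."""
    ref = next(o for o in orders if o.taxon == ref_taxon)
    others = [o for o in orders if o.taxon != ref_taxon]
    out, i = [], 0
    while i < len(ref.genes):
        j = i + 1
        while j < len(ref.genes) and all(
                oracle_run_valid(ref, o, i, j + 1) != "broken" for o in others):
            j += 1
        out.append(ref.genes[i:j])
        i = j
    return out


class TestExtractGeneOrder:
    def test_full_genome_order(self, full_sim, reference):
        rec, _ = full_sim
        structure = detect_inverted_repeat(rec)
        o = extract_gene_order(rec, structure, reference=reference)
        assert len(o) == 113                    # IR duplicates appear once
        assert o.genes[0] == "trnH-GUG"         # order starts at JLA
        assert len(set(o.genes)) == 113

    def test_inverted_segment_flips_signs(self, reference):
        rec, _ = simulate_plastome(SimulationConfig(seed=3))
        st0 = detect_inverted_repeat(rec)
        base = extract_gene_order(rec, st0, reference=reference)
        rec2, _ = simulate_plastome(SimulationConfig(
            seed=3, inversions=(("psbD", "psaA"),), taxon="Inv sp."))
        o2 = extract_gene_order(rec2, detect_inverted_repeat(rec2), reference=reference)
        i0, i1 = base.genes.index("psbD"), base.genes.index("psaA")
        seg = base.genes[i0:i1 + 1]
        assert o2.genes[i0:i1 + 1] == seg[::-1]
        for g in seg:
            assert o2.signs[o2.genes.index(g)] == -base.signs[base.genes.index(g)]

    def test_repeated_symbols_rejected(self):
        with pytest.raises(ValueError, match="repeated"):
            order("T", ["a", "b", "a"])


class TestFindBlocks:
    def test_two_identical_orders_one_constant_block(self):
        a = order("A", "abcdefgh")
        b = order("B", "abcdefgh")
        blocks = find_blocks([a, b], "A")
        assert len(blocks) == 1
        assert blocks[0].constant
        assert blocks[0].genes == list("abcdefgh")

    def test_internal_inversion_gives_three_blocks(self):
        a = order("A", "abcdefgh")
        # b carries c..g reversed and negated
        b = order("B", ["a", "b", "g", "f", "e", "d", "c", "h"],
                  signs=[1, 1, -1, -1, -1, -1, -1, 1])
        blocks = find_blocks([a, b], "A")
        assert [blk.genes for blk in blocks] == [["a", "b"], ["c", "d", "e", "f", "g"], ["h"]]
        assert [blk.constant for blk in blocks] == [True, False, True]
        assert blocks[1].orientations["B"] == "reverse"
        assert [blk.genes for blk in blocks] == oracle_blocks([a, b], "A")

    def test_translocated_gene_forms_own_block(self):
        a = order("A", "abcde")
        b = order("B", "acdeb")     # b translocated
        blocks = find_blocks([a, b], "A")
        assert [blk.genes for blk in blocks] == oracle_blocks([a, b], "A")
        assert ["b"] in [blk.genes for blk in blocks]

    def test_missing_genes_are_not_applicable(self):
        a = order("A", "abcdef")
        b = order("B", "abef")      # c, d missing
        blocks = find_blocks([a, b], "A")
        for blk in blocks:
            if "c" in blk.genes or "d" in blk.genes:
                assert blk.orientations["B"] == "not_applicable" or \
                    all(g in b.genes for g in blk.genes)
        assert [blk.genes for blk in blocks] == oracle_blocks([a, b], "A")

    def test_rotation_of_circular_orders_is_irrelevant(self):
        a = order("A", "abcdefgh")
        b = order("B", ["a", "b", "g", "f", "e", "d", "c", "h"],
                  signs=[1, 1, -1, -1, -1, -1, -1, 1])
        base = [blk.genes for blk in find_blocks([a, b], "A")]
        for k in range(1, 8):
            rot = order("B", b.genes[k:] + b.genes[:k], b.signs[k:] + b.signs[:k])
            assert [blk.genes for blk in find_blocks([a, rot], "A")] == base

    def test_global_reversal_flips_orientations_consistently(self):
        a = order("A", "abcdefgh")
        b = order("B", ["a", "b", "g", "f", "e", "d", "c", "h"],
                  signs=[1, 1, -1, -1, -1, -1, -1, 1])
        rev = order("B", [g for g in reversed(b.genes)], [-s for s in reversed(b.signs)])
        base = find_blocks([a, b], "A")
        flipped = find_blocks([a, rev], "A")
        assert [blk.genes for blk in base] == [blk.genes for blk in flipped]
        for x, y in zip(base, flipped):
            if x.orientations["B"] == "forward":
                assert y.orientations["B"] == "reverse"
            elif x.orientations["B"] == "reverse":
                assert y.orientations["B"] == "forward"

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_exhaustive_oracle_on_small_orders(self, data):
        """Block boundaries equal the interval-enumeration oracle on <=8-gene toys."""
        n = data.draw(st.integers(3, 8), label="n_genes")
        genes = [chr(ord("a") + k) for k in range(n)]
        ref = order("REF", genes, data.draw(
            st.lists(st.sampled_from([1, -1]), min_size=n, max_size=n), label="ref_signs"))
        others = []
        for t in range(data.draw(st.integers(1, 3), label="n_other")):
            perm = data.draw(st.permutations(genes), label=f"perm{t}")
            keep = data.draw(st.integers(max(2, n - 3), n), label=f"keep{t}")
            perm = list(perm)[:keep]
            signs = data.draw(st.lists(st.sampled_from([1, -1]), min_size=len(perm),
                                       max_size=len(perm)), label=f"signs{t}")
            others.append(order(f"T{t}", perm, signs))
        blocks = find_blocks([ref] + others, "REF")
        assert [blk.genes for blk in blocks] == oracle_blocks([ref] + others, "REF")
        # blocks partition the reference order
        assert [g for blk in blocks for g in blk.genes] == genes
        # orientation agreement with the oracle validity test
        for blk in blocks:
            i = genes.index(blk.genes[0])
            j = i + len(blk.genes)
            for o in others:
                assert blk.orientations[o.taxon] == oracle_run_valid(ref, o, i, j)


class TestCensusAndFiltering:
    def test_all_constant_toy_set(self):
        blocks = find_blocks([order("A", "abcd"), order("B", "abcd")], "A")
        census = block_census(blocks)
        assert census["rearranged"] == 0 and census["constant"] == 1

    def test_one_inversion_census(self):
        a = order("A", "abcdefgh")
        b = order("B", ["a", "b", "g", "f", "e", "d", "c", "h"],
                  signs=[1, 1, -1, -1, -1, -1, -1, 1])
        census = block_census(find_blocks([a, b], "A"))
        assert census["rearranged"] == 1 and census["constant"] == 2

    def test_empty_block_list(self):
        census = block_census([])
        assert census["n_blocks"] == 0
        assert census["constant"] == census["rearranged"] == 0

    def test_severely_reduced_genomes_excluded(self, reference, full_sim, stage_sims):
        rec_full, _ = full_sim
        rec3, _ = stage_sims["stage3_housekeeping"]
        o_full = extract_gene_order(rec_full, reference=reference)
        o3 = extract_gene_order(rec3, reference=reference)
        kept = filter_reduced([o_full, o3], reference)
        assert [o.taxon for o in kept] == [rec_full.taxon]

    def test_length_bins(self, full_sim, reference):
        rec, _ = full_sim
        o = extract_gene_order(rec, detect_inverted_repeat(rec), reference=reference)
        blocks = find_blocks([o, GeneOrder(taxon="B", genes=list(o.genes),
                                           signs=list(o.signs))], o.taxon)
        census = block_census(blocks)
        assert census["by_length_bin"][">10kb"] == 1    # one whole-genome block
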