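"""IR detection, quadripartite partition, junctions, GC and structure tables."""
import random

import pytest

from conftest import toy_record
from plastevo import tables
from plastevo.io import PlastomeRecord, revcomp
from plastevo.structure import (add_length_summary, detect_inverted_repeat, gc_content,
                                junction_genes, length_summary, structure_table)
from plastevo.simulate import SimulationConfig, simulate_plastome


def planted_ir_record(n=150_000, ir=25_000, ssc=18_000, seed=0, mismatches=0):
    """Bare sequence with an exact planted IR (no annotation)."""
    rng = random.Random(seed)
    lsc = n - ssc - 2 * ir
    lsc_seq = "".join(rng.choices("ACGT", k=lsc))
    ir_seq = "".join(rng.choices("ACGT", k=ir))
    ssc_seq = "".join(rng.choices("ACGT", k=ssc))
    ira = revcomp(ir_seq)
    if mismatches:
        s = list(ira)
        for pos in rng.sample(range(10, ir - 10), mismatches):
            s[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[pos]]
        ira = "".join(s)
    # guard bases so the planted repeat cannot extend by chance at any boundary
    lsc_seq = "A" + lsc_seq[1:-1] + "A"
    ssc_seq = "C" + ssc_seq[1:-1] + "C"
    seq = lsc_seq + ir_seq + ssc_seq + ira
    return PlastomeRecord(accession="PLANT", taxon="Planted sp.", sequence=seq)


class TestDetectInvertedRepeat:
    def test_planted_25kb_ir_recovered_exactly(self):
        rec = planted_ir_record()
        st = detect_inverted_repeat(rec)
        assert st.structure_class == "quadripartite"
        assert st.ir_length == 25_000
        assert st.lsc_length + st.ssc_length + 2 * st.ir_length == 150_000
        assert st.lsc_length >= st.ssc_length

    @pytest.mark.parametrize("ir_len", [261, 10_000, 27_000])
    def test_planted_ir_lengths_exact(self, ir_len):
        cfg = SimulationConfig(seed=31, ir_length=ir_len)
        rec, truth = simulate_plastome(cfg)
        st = detect_inverted_repeat(rec)
        assert st.ir_length == ir_len == truth.ir_length
        assert st.structure_class == "quadripartite"

    def test_no_repeat_is_single_copy_only(self):
        # a Gastrodia-like IR-less genome
        rng = random.Random(3)
        rec = PlastomeRecord(accession="G", taxon="Gastrodia-like",
                             sequence="".join(rng.choices("ACGT", k=35_000)))
        st = detect_inverted_repeat(rec)
        assert st.structure_class == "single_copy_only"
        assert st.ir_length == 0
        assert st.lsc_length == 35_000

    def test_ssc_contracted_genome(self):
        # Hetaeria-like geometry: IR 31,960 bp, SSC 2,320 bp
        rec, _ = simulate_plastome(SimulationConfig(
            seed=7, genome_length_target=130_934, ir_length=31_960, ssc_length=2_320,
            deletions=tuple(f"ndh{x}" for x in "ABCDEFGHIJK")))
        st = detect_inverted_repeat(rec)
        assert st.ir_length == 31_960
        assert st.ssc_length == 2_320

    def test_epipogium_roseum_like_tiny_ir(self):
        # IR shrunk to 261 bp (too small for the rrn block); min_len 100 must admit it
        rec, _ = simulate_plastome(SimulationConfig(
            seed=8, genome_length_target=150_000, ir_length=261, ssc_length=9_000))
        st = detect_inverted_repeat(rec, min_len=100)
        assert st.ir_length == 261
        assert st.structure_class == "quadripartite"

    def test_head_to_head_irs_no_ssc(self, reference):
        ssc_genes = tuple(reference.region_genes("SSC"))
        rec, truth = simulate_plastome(SimulationConfig(
            seed=9, ssc_length=0, deletions=ssc_genes,
            genome_length_target=110_000, ir_length=18_000))
        st = detect_inverted_repeat(rec)
        assert st.structure_class == "no_SSC_tripartite" == truth.structure_class
        assert st.ir_length == 18_000
        assert st.ssc_length == 0

    def test_rotation_and_revcomp_invariance(self):
        base = planted_ir_record(n=60_000, ir=9_000, ssc=6_000, seed=5)
        st0 = detect_inverted_repeat(base)
        geometry = (st0.ir_length, st0.lsc_length, st0.ssc_length, st0.structure_class)
        rng = random.Random(11)
        for _ in range(4):
            k = rng.randrange(60_000)
            rot = PlastomeRecord(accession="R", taxon="R",
                                 sequence=base.sequence[k:] + base.sequence[:k])
            st = detect_inverted_repeat(rot)
            assert (st.ir_length, st.lsc_length, st.ssc_length, st.structure_class) == geometry
        rc = PlastomeRecord(accession="C", taxon="C", sequence=revcomp(base.sequence))
        st = detect_inverted_repeat(rc)
        assert (st.ir_length, st.lsc_length, st.ssc_length, st.structure_class) == geometry

    def test_mismatch_tolerant_extension(self):
        rec = planted_ir_record(n=80_000, ir=12_000, ssc=8_000, seed=6, mismatches=20)
        exact = detect_inverted_repeat(rec, max_mismatch_rate=0.0)
        tol = detect_inverted_repeat(rec, max_mismatch_rate=0.01)
        assert exact.ir_length < 12_000         # mismatches break the exact match
        assert tol.ir_length > exact.ir_length  # tolerant extension recovers more
        assert tol.ir_length >= 0.95 * 12_000

    def test_linear_record_errors(self):
        rec = PlastomeRecord(accession="L", taxon="L", sequence="ACGT" * 100,
                             topology="linear")
        with pytest.raises(ValueError, match="linear"):
            detect_inverted_repeat(rec)

    def test_region_lengths_always_sum(self):
        for seed in range(3):
            rec, _ = simulate_plastome(SimulationConfig(seed=seed))
            st = detect_inverted_repeat(rec)
            assert st.lsc_length + st.ssc_length + 2 * st.ir_length == len(rec.sequence)


class TestJunctionGenes:
    def test_typical_photosynthetic_layout(self, full_sim):
        rec, _ = full_sim
        st = detect_inverted_repeat(rec)
        j = dict((name, (gene, off)) for name, gene, off in junction_genes(rec, st))
        assert j["JSB"] == ("ndhF", 0)      # ndhF sits on the IRb/SSC boundary
        assert j["JSA"] == ("ycf1", 0)      # ycf1 sits on the SSC/IRa boundary
        assert j["JLB"][0] in ("rps19", "rpl22")
        assert j["JLB"][1] <= 0             # on the single-copy side

    def test_gene_spanning_junction_scores_zero(self, full_sim):
        rec, _ = full_sim
        st = detect_inverted_repeat(rec)
        # plant a feature straddling JSA explicitly
        jsa = st.junctions["JSA"]
        rec2 = toy_record([("ycf1", "other", "CDS", [(jsa - 50, jsa + 49, 1)], False)],
                          length=len(rec.sequence))
        rec2 = PlastomeRecord(accession="X", taxon="X", sequence=rec.sequence,
                              features=rec2.features)
        j = dict((n, (g, o)) for n, g, o in junction_genes(rec2, st))
        assert j["JSA"] == ("ycf1", 0)

    def test_offset_sign_toward_ir(self, full_sim):
        rec, _ = full_sim
        st = detect_inverted_repeat(rec)
        jlb = st.junctions["JLB"]
        # rpl22 ending 40 bp short of JLB (single-copy side) -> offset -40
        rec2 = PlastomeRecord(accession="X", taxon="X", sequence=rec.sequence,
                              features=toy_record(
                                  [("rpl22", "rpl", "CDS", [(jlb - 439, jlb - 40, 1)], False)],
                                  length=len(rec.sequence)).features)
        j = dict((n, (g, o)) for n, g, o in junction_genes(rec2, st))
        assert j["JLB"] == ("rpl22", -40)

    def test_no_features_errors(self, full_sim):
        rec, _ = full_sim
        st = detect_inverted_repeat(rec)
        bare = PlastomeRecord(accession="B", taxon="B", sequence=rec.sequence)
        with pytest.raises(ValueError, match="features"):
            junction_genes(bare, st)


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [("GCGC", 100.0), ("ATAT", 0.0),
                                              ("ACGT", 50.0), ("ACGTN", 50.0)])
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_against_position_counting_oracle(self):
        rng = random.Random(17)
        seq = "".join(rng.choices("ACGTN", weights=[30, 18, 19, 30, 3], k=10_000))
        gc = at = 0
        for ch in seq:              # brute-force position-by-position count
            if ch in "GC":
                gc += 1
            elif ch in "AT":
                at += 1
        assert gc_content(seq) == pytest.approx(100.0 * gc / (gc + at))

    def test_all_n_errors(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")


class TestStructureTable:
    def test_published_length_summaries(self):
        t1 = tables.load_table1()
        s1 = length_summary(add_length_summary(t1))
        assert s1["min"] == 35_056 and s1["max"] == 159_341
        t2 = tables.load_table2(orchids_only=True)
        s2 = length_summary(add_length_summary(t2))
        assert s2["min"] == 19_047 and s2["max"] == 178_131

    def test_single_record_min_equals_max(self, full_sim):
        rec, _ = full_sim
        df = structure_table([rec])
        s = length_summary(df)
        assert s["min"] == s["max"] == len(rec.sequence)
        assert set(df.columns) >= {"taxon", "length_bp", "lsc_bp", "ssc_bp", "ir_bp",
                                   "gc_percent"}

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            structure_table([])
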