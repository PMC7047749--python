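"""Synthetic annotated plastomes with known ground truth.

The generator lays the 113-gene reference complement out in a canonical
photosynthetic-orchid order (psbA just after JLA, ndhF at JSB, ycf1 at JSA), plants an
exact inverted repeat around the rrn block, and applies requested deletions,
pseudogenizations (premature stops / 1-bp frameshift / large in-frame deletion),
segment inversions and AT-shifted composition.  Gene sequences are synthetic ORFs
(random sense codons, valid start, terminal stop) — status calling depends only on
frame properties, so sequence realism is unnecessary.  Every record comes with a
ground-truth sidecar; the same seed reproduces the same bytes.

Defaults state a typical photosynthetic orchid plastome: 150 kb genome, 26.5 kb IR,
18 kb SSC, 37% GC.  Stage presets state the published degradation patterns (ndh class
first, photosynthesis/rpo second, housekeeping erosion last, down to a ~30-gene
Gastrodia-like genome that has also lost its IR).
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import dendropy

from plastevo.dollo import LossEvent, LossEventSet
from plastevo.io import GeneFeature, PlastomeRecord, revcomp
from plastevo.reference import ReferenceGene, ReferenceGeneSet

SENSE_CODONS = sorted({a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"}
                      - {"TAA", "TAG", "TGA"})

#: default stated world (typical photosynthetic orchid, Table-2-like values)
GENOME_LENGTH = 150_000
IR_LENGTH = 26_500
SSC_LENGTH = 18_000
GC_TARGET = 37.0

NDH_GENES = ("ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF", "ndhG", "ndhH",
             "ndhI", "ndhJ", "ndhK")

#: the Gastrodia-like stage-3 survivor set: 23 intact genes plus a handful of tRNAs
STAGE3_KEEP = ("accD", "clpP", "matK", "rpl2", "rpl14", "rpl16", "rpl20", "rpl36",
               "rps2", "rps3", "rps4", "rps7", "rps8", "rps11", "rps12", "rps14",
               "rps18", "rps19", "rrn5", "rrn16", "rrn23", "ycf1", "ycf2",
               "trnC-GCA", "trnfM-CAU", "trnE-UUC", "trnQ-UUG", "trnM-CAU")


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length_target: int = GENOME_LENGTH
    ir_length: int = IR_LENGTH          # 0 = no IR (single-copy genome)
    ssc_length: int = SSC_LENGTH
    gc_target: float = GC_TARGET
    stage: str = "full"                 # label recorded in the ground truth
    deletions: tuple[str, ...] = ()
    #: gene -> (mode, parameter); modes: stops_k (k premature stops), frameshift,
    #: large_indel (in-frame deletion of `param` bp)
    pseudogenizations: dict[str, tuple[str, int]] = field(default_factory=dict)
    #: segments to invert, as (first_gene, last_gene) ranges in canonical order
    inversions: tuple[tuple[str, str], ...] = ()
    taxon: str = "Synthetica plastomica"
    accession: str = "SYN000001"

    def __post_init__(self):
        overlap = set(self.deletions) & set(self.pseudogenizations)
        if overlap:
            raise ValueError(f"genes both deleted and pseudogenized: {sorted(overlap)}")
        if self.ir_length < 0:
            raise ValueError("ir_length must be >= 0")


@dataclass
class GroundTruth:
    statuses: dict[str, str]            # gene -> present | pseudogene | absent
    structure_class: str
    ir_length: int
    lsc_length: int
    ssc_length: int
    stage: str
    inversions: tuple[tuple[str, str], ...]

    def n_functional(self) -> int:
        return sum(1 for v in self.statuses.values() if v == "present")


# -- stage presets ------------------------------------------------------------------

def stage_preset(stage: str, seed: int = 0, **overrides) -> SimulationConfig:
    """A config stating one of the published degradation stages."""
    ref = ReferenceGeneSet.default()
    base = dict(seed=seed, stage=stage)
    if stage == "full":
        pass
    elif stage == "near_full":
        base["deletions"] = ("ndhF", "ndhK")
    elif stage == "stage1_ndh":
        base["deletions"] = NDH_GENES[:8]
        base["pseudogenizations"] = {g: ("stops_k", 8) for g in NDH_GENES[8:]}
    elif stage == "stage2_photo":
        photo = tuple(g.name for g in ref.genes
                      if g.gene_class in ("pet", "psa", "psb", "rpo"))
        base["deletions"] = NDH_GENES + photo[::2]
        base["pseudogenizations"] = {g: ("stops_k", 8) for g in photo[1::2]}
        base["genome_length_target"] = 120_000
        base["ssc_length"] = 10_000
        base["ir_length"] = 22_000
        base["gc_target"] = 36.0
    elif stage == "intermediate":
        photo = tuple(g.name for g in ref.genes
                      if g.gene_class in ("pet", "psa", "psb", "rpo"))
        house = ("trnG-UCC", "trnS-GCU", "trnT-GGU", "rpl22", "rpl32", "rps15", "rps16")
        base["deletions"] = NDH_GENES + photo + house
        base["genome_length_target"] = 95_000
        base["ssc_length"] = 9_000
        base["ir_length"] = 17_000
        base["gc_target"] = 35.0
    elif stage == "stage3_housekeeping":
        lost = tuple(g.name for g in ref.genes if g.name not in STAGE3_KEEP)
        base["deletions"] = lost[:-2] if len(lost) > 2 else lost
        base["pseudogenizations"] = {g: ("stops_k", 8) for g in lost[-2:]}
        base["genome_length_target"] = 36_000
        base["ir_length"] = 0
        base["ssc_length"] = 0
        base["gc_target"] = 30.0
    else:
        raise ValueError(f"unknown stage preset {stage!r}")
    base.update(overrides)
    return SimulationConfig(**base)


# -- sequence helpers ---------------------------------------------------------------

def _bases(rng: random.Random, n: int, gc: float) -> str:
    g = gc / 200.0      # per-base probability of G and of C
    a = (100.0 - gc) / 200.0
    return "".join(rng.choices("ACGT", weights=[a, g, g, a], k=n))


def _orf(rng: random.Random, length: int, gc: float) -> str:
    """Synthetic CDS: ATG + sense codons + TAA, biased toward the GC target."""
    assert length % 3 == 0 and length >= 9
    ncod = length // 3 - 2
    g, a = gc / 200.0, (100.0 - gc) / 200.0
    weights = [g ** sum(1 for ch in c if ch in "GC") *
               a ** sum(1 for ch in c if ch in "AT")
               for c in SENSE_CODONS]
    body = "".join(rng.choices(SENSE_CODONS, weights=weights, k=ncod))
    return "ATG" + body + "TAA"


def _gene_sequence(rng: random.Random, gene: ReferenceGene, gc: float) -> list[str]:
    """Exon sequences (reading order) for one gene."""
    if gene.kind == "CDS":
        total = gene.ref_length
        seq = _orf(rng, total, gc)
    else:
        seq = _bases(rng, gene.ref_length, gc)
    if gene.n_exons == 1:
        return [seq]
    # split into n_exons pieces at codon-agnostic points (splicing restores the frame)
    cuts = sorted(rng.sample(range(10, len(seq) - 10), gene.n_exons - 1))
    pieces, prev = [], 0
    for c in cuts:
        pieces.append(seq[prev:c])
        prev = c
    pieces.append(seq[prev:])
    return pieces


def _apply_pseudogenization(rng: random.Random, exons: list[str], kind: str, mode: str,
                            param: int) -> list[str]:
    if kind != "CDS":
        # non-coding genes are "pseudogenized" by truncation beyond the length tolerance
        joined = "".join(exons)
        keep = max(4, int(len(joined) * 0.5))
        return [joined[:keep]]
    joined = "".join(exons)
    if mode == "stops_k":
        k = max(1, param)
        ncod = len(joined) // 3
        sites = rng.sample(range(2, ncod - 2), min(k, max(1, ncod - 4)))
        s = list(joined)
        for c in sites:
            s[3 * c:3 * c + 3] = "TAA"      # non-editable internal stop
        joined = "".join(s)
    elif mode == "frameshift":
        pos = len(joined) // 2
        joined = joined[:pos] + joined[pos + 1:]
    elif mode == "large_indel":
        drop = max(33, param - param % 3)   # in-frame deletion beyond the threshold
        pos = 3 * ((len(joined) // 2) // 3)
        joined = joined[:pos] + joined[pos + drop:]
    else:
        raise ValueError(f"unknown pseudogenization mode {mode!r}")
    if len(exons) == 1:
        return [joined]
    # preserve the exon count by re-cutting proportionally
    cuts = sorted(rng.sample(range(5, len(joined) - 5), len(exons) - 1))
    pieces, prev = [], 0
    for c in cuts:
        pieces.append(joined[prev:c])
        prev = c
    pieces.append(joined[prev:])
    return pieces


# -- genome assembly ----------------------------------------------------------------

class _SegmentBuilder:
    """Accumulates sequence and plus-strand-relative features for one region."""

    def __init__(self, rng: random.Random, gc: float):
        self.rng = rng
        self.gc = gc
        self.parts: list[str] = []
        self.length = 0
        self.features: list[GeneFeature] = []

    def spacer(self, n: int):
        if n > 0:
            self.parts.append(_bases(self.rng, n, self.gc))
            self.length += n

    def gene(self, gene: ReferenceGene, exon_seqs: list[str], pseudo: bool,
             intron_len: int = 120):
        strand = gene.strand
        # exon_seqs are in reading order; on the minus strand they are laid down
        # reverse-complemented and in reversed genomic order
        genomic = exon_seqs if strand == 1 else [revcomp(e) for e in reversed(exon_seqs)]
        exons = []
        for i, es in enumerate(genomic):
            if i > 0:
                self.spacer(intron_len)
            s = self.length + 1
            self.parts.append(es)
            self.length += len(es)
            exons.append((s, self.length, strand))
        self.features.append(GeneFeature(
            name=gene.name, gene_class=gene.gene_class, kind=gene.kind,
            exons=exons, annotated_pseudo=pseudo))

    def sequence(self) -> str:
        return "".join(self.parts)


def simulate_plastome(config: SimulationConfig,
                      reference: ReferenceGeneSet | None = None
                      ) -> tuple[PlastomeRecord, GroundTruth]:
    """Build one annotated synthetic plastome plus its ground-truth sidecar."""
    ref = reference or ReferenceGeneSet.default()
    rng = random.Random(config.seed)
    deleted = set(config.deletions)
    pseudo = dict(config.pseudogenizations)
    unknown = (deleted | set(pseudo)) - set(ref.names)
    if unknown:
        raise ValueError(f"unknown genes in config: {sorted(unknown)}")

    statuses: dict[str, str] = {}
    exon_store: dict[str, list[str]] = {}
    for g in ref.genes:
        if g.name in deleted:
            statuses[g.name] = "absent"
            continue
        exons = _gene_sequence(rng, g, config.gc_target)
        if g.name in pseudo:
            mode, param = pseudo[g.name]
            exons = _apply_pseudogenization(rng, exons, g.kind, mode, param)
            statuses[g.name] = "pseudogene"
        else:
            statuses[g.name] = "present"
        exon_store[g.name] = exons

    # region rosters after deletions; a too-small IR pushes its genes into the LSC
    lsc_genes = [g for g in ref.genes if g.region == "LSC" and g.name in exon_store]
    ir_genes = [g for g in ref.genes if g.region == "IR" and g.name in exon_store]
    ssc_genes = [g for g in ref.genes if g.region == "SSC" and g.name in exon_store]
    single_copy = config.ir_length == 0

    def content_length(genes: list[ReferenceGene]) -> int:
        tot = 0
        for g in genes:
            tot += sum(len(e) for e in exon_store[g.name])
            tot += 120 * (len(exon_store[g.name]) - 1)
        return tot

    min_gap = 40

    def fits(genes: list[ReferenceGene], target: int) -> bool:
        return target >= content_length(genes) + min_gap * (len(genes) + 1) + 500

    if not single_copy and config.ssc_length > 0 and not fits(ssc_genes, config.ssc_length):
        # SSC contraction by IR expansion: the IR engulfs the SSC-resident genes
        ir_genes = ir_genes + ssc_genes
        ssc_genes = []
    if not single_copy and not fits(ir_genes, config.ir_length):
        lsc_genes = lsc_genes + ir_genes        # IR too contracted to hold its genes
        ir_genes = []
    if single_copy:
        lsc_genes = lsc_genes + ir_genes + ssc_genes
        ir_genes, ssc_genes = [], []

    def build_segment(genes: list[ReferenceGene], target: int, label: str,
                      first_gap: int | None = None,
                      last_gap: int | None = None) -> _SegmentBuilder:
        """Lay genes with spacers to hit ``target`` exactly.

        ``first_gap``/``last_gap`` pin the segment-edge spacers (junction geometry);
        unpinned gaps are at least ``min_gap`` and share the slack.
        """
        b = _SegmentBuilder(rng, config.gc_target)
        k = len(genes)
        fixed = [first_gap, last_gap]
        if k == 0:
            fixed = [None, None]        # a gene-free segment is one big spacer
        n_flex = (k + 1) - sum(1 for f in fixed if f is not None)
        if n_flex == 0:
            fixed[1] = None             # keep one flexible gap to absorb slack
            n_flex = 1
        fixed_total = sum(f for f in fixed if f is not None)
        slack = target - content_length(genes) - fixed_total
        if slack < n_flex * min_gap:
            need = content_length(genes) + fixed_total + n_flex * min_gap
            raise ValueError(f"{label} target {target} bp cannot hold its {k} genes "
                             f"({need} bp needed)")
        flex = _split_gap(rng, slack, n_flex, min_gap)
        gaps = []
        fi = 0
        for pos in range(k + 1):
            if pos == 0 and fixed[0] is not None:
                gaps.append(fixed[0])
            elif pos == k and fixed[1] is not None:
                gaps.append(fixed[1])
            else:
                gaps.append(flex[fi])
                fi += 1
        for g, gap in zip(genes, gaps[:-1]):
            b.spacer(gap)
            b.gene(g, exon_store[g.name], statuses[g.name] == "pseudogene")
        b.spacer(gaps[-1])
        assert b.length == target, (b.length, target)
        return b

    n_target = config.genome_length_target
    if single_copy:
        lsc_target = n_target
        ssc_target = ir_target = 0
    else:
        ir_target = config.ir_length
        ssc_target = config.ssc_length
        lsc_target = n_target - ssc_target - 2 * ir_target
        if lsc_target <= ssc_target:
            raise ValueError("genome_length_target leaves LSC shorter than SSC")

    # LSC edge gaps pinned so the JLB/JLA-nearest genes are deterministic
    lsc = build_segment(lsc_genes, lsc_target, "LSC",
                        first_gap=min_gap if lsc_genes else None,
                        last_gap=min_gap if lsc_genes else None)
    seq_parts = [lsc.sequence()]
    features = list(lsc.features)
    offset = lsc.length

    truth_class = "single_copy_only"
    if not single_copy:
        # IR genes sit well back from the IR ends so junction genes are the flanking
        # single-copy ones (mirroring ndhF at JSB / ycf1 at JSA in real plastomes)
        ir_edge = 250 if ir_genes else None
        irb = build_segment(ir_genes, ir_target, "IR", first_gap=ir_edge, last_gap=ir_edge)
        irb_seq = irb.sequence()
        seq_parts.append(irb_seq)
        for f in irb.features:
            features.append(_shift(f, offset))
        offset += irb.length

        if ssc_target > 0:
            # ndhF opens the SSC flush at JSB and ycf1 closes it flush at JSA
            ssc_first = 0 if (ssc_genes and ssc_genes[0].name == "ndhF") else None
            ssc_last = 0 if (ssc_genes and ssc_genes[-1].name == "ycf1") else None
            ssc = build_segment(ssc_genes, ssc_target, "SSC",
                                first_gap=ssc_first, last_gap=ssc_last)
            seq_parts.append(ssc.sequence())
            for f in ssc.features:
                features.append(_shift(f, offset))
            offset += ssc.length
            truth_class = "quadripartite"
        elif ssc_genes:
            raise ValueError("ssc_length 0 but SSC genes remain; delete them or move them")
        else:
            truth_class = "no_SSC_tripartite"

        # IRa: exact reverse complement of IRb, features mirrored
        ira_seq = revcomp(irb_seq)
        seq_parts.append(ira_seq)
        for f in irb.features:
            features.append(_mirror(f, irb.length, offset))
        offset += len(ira_seq)

    seq = "".join(seq_parts)
    assert len(seq) == n_target, (len(seq), n_target)

    if not single_copy:
        seq = _guard_ir_boundaries(seq, lsc.length, ir_target, ssc_target)

    record = PlastomeRecord(
        accession=config.accession, taxon=config.taxon, sequence=seq,
        features=sorted(features, key=lambda f: (f.start, f.name)),
        topology="circular",
        metadata={"life_form": "terrestrial",
                  "trophic_mode": ("photosynthetic" if config.stage in ("full", "near_full",
                                                                        "stage1_ndh")
                                   else "mycoheterotrophic")})

    for first, last in config.inversions:
        record = invert_segment(record, first, last)
    record.validate()

    truth = GroundTruth(
        statuses=statuses, structure_class=truth_class,
        ir_length=0 if single_copy else ir_target,
        lsc_length=lsc_target if not single_copy else len(seq),
        ssc_length=ssc_target, stage=config.stage, inversions=config.inversions)
    return record, truth


def _split_gap(rng: random.Random, total: int, k: int, min_gap: int) -> list[int]:
    """Split ``total`` into k gaps of at least ``min_gap`` (deterministic given rng)."""
    assert total >= k * min_gap
    extra = total - k * min_gap
    cuts = sorted(rng.choices(range(extra + 1), k=k - 1)) if k > 1 else []
    gaps, prev = [], 0
    for c in cuts:
        gaps.append(min_gap + c - prev)
        prev = c
    gaps.append(min_gap + extra - prev)
    return gaps


def _shift(f: GeneFeature, offset: int) -> GeneFeature:
    return GeneFeature(name=f.name, gene_class=f.gene_class, kind=f.kind,
                       exons=[(s + offset, e + offset, st) for s, e, st in f.exons],
                       annotated_pseudo=f.annotated_pseudo)


def _mirror(f: GeneFeature, seg_len: int, offset: int) -> GeneFeature:
    """IRa copy of an IRb feature: coordinates mirrored, strand flipped."""
    exons = [(offset + seg_len - e + 1, offset + seg_len - s + 1, -st)
             for s, e, st in f.exons]
    exons.sort(key=lambda x: x[0])
    return GeneFeature(name=f.name, gene_class=f.gene_class, kind=f.kind,
                       exons=exons, annotated_pseudo=f.annotated_pseudo)


def _guard_ir_boundaries(seq: str, lsc_len: int, ir_len: int, ssc_len: int) -> str:
    """Pin the four bases flanking the IR copies so the repeat cannot extend by chance.

    Extension pairs the base left of IRb with the base right of IRa (and right of IRb
    with left of IRa); fixing each pair to identical non-complementary bases stops it.
    """
    n = len(seq)
    s = list(seq)
    jlb = lsc_len                   # 0-based first base of IRb
    jsb = lsc_len + ir_len          # first base of SSC (or of IRa when no SSC)
    jsa = jsb + ssc_len             # first base of IRa
    s[jlb - 1] = "A"                # last LSC base
    s[(jsa + ir_len) % n] = "A"     # first base after IRa (wraps to LSC start)
    if ssc_len > 0:
        # with no SSC the copies abut head-to-head and cannot extend inward anyway
        s[jsb % n] = "C"            # first SSC base (ndhF's stop-codon end: harmless)
        s[jsa - 1] = "C"            # last SSC base (ycf1's stop-codon end: harmless)
    return "".join(s)


# -- inversions ---------------------------------------------------------------------

def invert_segment(record: PlastomeRecord, first_gene: str, last_gene: str) -> PlastomeRecord:
    """Reverse-complement the span from ``first_gene`` start to ``last_gene`` end.

    Features wholly inside the span get mirrored coordinates and flipped strands;
    features straddling the span boundary are not supported (config error).
    """
    fa = record.feature_by_name(first_gene)
    fb = record.feature_by_name(last_gene)
    if fa is None or fb is None:
        raise ValueError(f"inversion endpoints not found: {first_gene}, {last_gene}")
    a, b = fa.start, fb.end
    if b <= a:
        raise ValueError("inversion span must run forward without wrapping the origin")
    seq = record.sequence
    inv = seq[:a - 1] + revcomp(seq[a - 1:b]) + seq[b:]
    feats = []
    for f in record.features:
        if f.start >= a and f.end <= b:
            exons = [(a + b - e, a + b - s, -st) for s, e, st in f.exons]
            exons.sort(key=lambda x: x[0])
            feats.append(GeneFeature(name=f.name, gene_class=f.gene_class, kind=f.kind,
                                     exons=exons, annotated_pseudo=f.annotated_pseudo))
        elif f.end < a or f.start > b:
            feats.append(f)
        else:
            raise ValueError(f"feature {f.name} straddles the inversion span")
    return PlastomeRecord(accession=record.accession, taxon=record.taxon, sequence=inv,
                          features=sorted(feats, key=lambda f: (f.start, f.name)),
                          topology=record.topology, metadata=dict(record.metadata))


# -- clade simulation ---------------------------------------------------------------

def simulate_clade(tree: dendropy.Tree,
                   loss_plan: dict[str | tuple[str, ...], tuple[str, ...]],
                   base_config: SimulationConfig | None = None
                   ) -> tuple[dict[str, PlastomeRecord], LossEventSet]:
    """Simulate one genome per tip under an edge-wise gene-loss plan.

    A ``loss_plan`` key names the child clade of an edge — either a single tip label
    (terminal edge) or a tuple of tip labels (internal edge); the value lists the genes
    lost on that edge.  Each tip's complement is the reference minus everything lost on
    its root-to-tip path; losing a gene twice on one path is an error.  Returns the
    records keyed by tip label and the true loss-event set (edge ids as in
    :func:`plastevo.dollo.dollo_map`: smallest tip label of the child clade).
    """
    base = base_config or SimulationConfig()
    clades = {frozenset(leaf.taxon.label for leaf in node.leaf_iter())
              for node in tree.preorder_node_iter()}
    losses_per_tip: dict[str, set[str]] = {leaf.taxon.label: set()
                                           for leaf in tree.leaf_node_iter()}
    events: list[LossEvent] = []
    for key, genes in loss_plan.items():
        clade = frozenset([key]) if isinstance(key, str) else frozenset(key)
        if clade not in clades:
            raise KeyError(f"no tree edge whose child clade is {sorted(clade)}")
        for gene in genes:
            for tip in clade:
                if gene in losses_per_tip[tip]:
                    raise ValueError(f"gene {gene} lost twice on the path to {tip}")
                losses_per_tip[tip].add(gene)
            events.append(LossEvent(gene=gene, edge_id=min(clade), tips=clade))
    records: dict[str, PlastomeRecord] = {}
    for i, (tip, lost) in enumerate(sorted(losses_per_tip.items())):
        cfg = replace(base, taxon=tip, accession=f"SYN{i + 1:06d}",
                      seed=(base.seed * 10_007 + i) % (2 ** 31),
                      deletions=tuple(sorted(lost)), pseudogenizations={})
        rec, _ = simulate_plastome(cfg)
        records[tip] = rec
    return records, LossEventSet(events=events)
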