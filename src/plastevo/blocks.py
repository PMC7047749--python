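"""Shared gene-order blocks and the constant-vs-rearranged block census.

Rearrangements are assessed at gene granularity: each genome is reduced to a circular
signed gene order (sign = strand, IR duplicates collapsed to the IRb copy), and a block
is a maximal run of reference genes that is contiguous and consistently oriented in
every taxon where all of its genes occur.  Taxa missing any member gene are
not-applicable for that block; a block is constant when every applicable taxon carries
it in the same orientation.  Severely reduced genomes (more than a configurable fraction
of reference genes missing) are excluded from the census, mirroring how heavily degraded
mycoheterotrophs are left out of whole-genome alignment studies.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from plastevo.io import PlastomeRecord
from plastevo.reference import ReferenceGeneSet
from plastevo.structure import QuadripartiteStructure

#: exclude a genome from block finding when this fraction of reference genes is missing
MAX_MISSING_FRACTION = 0.60

LENGTH_BINS = ((0, 1_000, "<1kb"), (1_000, 5_000, "1-5kb"),
               (5_000, 10_000, "5-10kb"), (10_000, float("inf"), ">10kb"))


@dataclass
class GeneOrder:
    """Circular signed gene order of one genome (IR duplicates collapsed)."""

    taxon: str
    genes: list[str]
    signs: list[int]
    pseudo: set[str] = field(default_factory=set)
    lengths: dict[str, int] = field(default_factory=dict)   # gene -> bp on this genome
    regions: dict[str, str] = field(default_factory=dict)   # gene -> LSC | IR | SSC

    def __post_init__(self):
        if len(self.genes) != len(set(self.genes)):
            dupes = {g for g in self.genes if self.genes.count(g) > 1}
            raise ValueError(f"{self.taxon}: repeated symbols after IR collapse: {sorted(dupes)}")
        if len(self.signs) != len(self.genes):
            raise ValueError("signs and genes length mismatch")

    def index(self) -> dict[str, tuple[int, int]]:
        return {g: (i, s) for i, (g, s) in enumerate(zip(self.genes, self.signs))}

    def __len__(self):
        return len(self.genes)


def extract_gene_order(record: PlastomeRecord,
                       structure: QuadripartiteStructure | None = None,
                       include_pseudo: bool = True,
                       reference: ReferenceGeneSet | None = None) -> GeneOrder:
    """Signed circular gene order starting at the JLA junction (or position 1).

    IR-resident genes annotated twice keep only the copy starting inside IRb (or, with
    no structure call, the first copy encountered).  Pseudogenes are kept and flagged;
    absent genes are simply not present.
    """
    ref = reference or ReferenceGeneSet.default()
    n = len(record.sequence)
    start = 1
    irb = None
    if structure is not None and structure.structure_class == "quadripartite":
        start = structure.junctions["JLA"]
        irb = structure.regions["IRb"]

    feats = [f for f in record.features if f.name in ref]
    if not include_pseudo:
        feats = [f for f in feats if not f.annotated_pseudo]

    def rot(pos: int) -> int:
        return (pos - start) % n

    # collapse duplicates: prefer the copy inside IRb, else the first after rotation
    chosen: dict[str, object] = {}
    for f in sorted(feats, key=lambda f: rot(f.start)):
        if f.name not in chosen:
            chosen[f.name] = f
        elif irb is not None and _inside(f.start, irb, n) and not _inside(chosen[f.name].start, irb, n):
            chosen[f.name] = f
    ordered = sorted(chosen.values(), key=lambda f: rot(f.start))

    regions = {}
    if structure is not None:
        for f in ordered:
            regions[f.name] = _region_of(f.start, structure, n)
    return GeneOrder(
        taxon=record.taxon,
        genes=[f.name for f in ordered],
        signs=[f.strand for f in ordered],
        pseudo={f.name for f in ordered if f.annotated_pseudo},
        lengths={f.name: f.exon_length for f in ordered},
        regions=regions)


def _inside(pos: int, interval: tuple[int, int], n: int) -> bool:
    s, e = interval
    for p in (pos, pos + n):
        if s <= p <= e:
            return True
    return False


def _region_of(pos: int, structure: QuadripartiteStructure, n: int) -> str:
    for name in ("LSC", "IRb", "SSC", "IRa"):
        if name in structure.regions and _inside(pos, structure.regions[name], n):
            return "IR" if name in ("IRb", "IRa") else name
    return "LSC"


# ---------------------------------------------------------------------------------
# block finding
# ---------------------------------------------------------------------------------

@dataclass
class SyntenyBlock:
    id: int
    genes: list[str]                        # ordered along the reference
    orientations: dict[str, str]            # taxon -> forward | reverse | not_applicable
    length_bp: int                          # on the reference taxon
    region: str                             # LSC | IR | SSC
    constant: bool


def find_blocks(orders: list[GeneOrder], reference_taxon: str) -> list[SyntenyBlock]:
    """Greedy maximal common runs along the reference gene order.

    Built left to right along the reference: a run extends while it stays contiguous
    and co-oriented in every taxon that carries all of its genes.  The reference order
    anchors the segmentation (it starts at JLA), so blocks are reported in reference
    coordinates; the *other* orders are treated as fully circular, making the result
    invariant to their rotation.  Deterministic.
    """
    if len(orders) < 2:
        raise ValueError("need at least two gene orders")
    by_taxon = {o.taxon: o for o in orders}
    if reference_taxon not in by_taxon:
        raise KeyError(f"reference taxon {reference_taxon!r} not among orders")
    ref = by_taxon[reference_taxon]
    others = [o for o in orders if o.taxon != reference_taxon]

    blocks: list[SyntenyBlock] = []
    i = 0
    while i < len(ref.genes):
        j = i + 1
        while j < len(ref.genes) and _run_ok(ref, others, i, j + 1):
            j += 1
        run = list(range(i, j))
        genes = [ref.genes[p] for p in run]
        orientations = {reference_taxon: "forward"}
        for o in others:
            orientations[o.taxon] = _run_orientation(ref, o, i, j)
        blocks.append(_make_block(len(blocks) + 1, ref, genes, orientations))
        i = j
    return blocks


def _make_block(bid: int, ref: GeneOrder, genes: list[str],
                orientations: dict[str, str]) -> SyntenyBlock:
    applicable = [v for v in orientations.values() if v != "not_applicable"]
    return SyntenyBlock(
        id=bid, genes=genes, orientations=orientations,
        length_bp=sum(ref.lengths.get(g, 0) for g in genes),
        region=_block_region(ref, genes),
        constant=len(set(applicable)) == 1)


def _run_ok(ref: GeneOrder, others: list[GeneOrder], i: int, j: int) -> bool:
    return all(_run_orientation(ref, o, i, j) != "broken" for o in others)


def _run_orientation(ref: GeneOrder, other: GeneOrder, i: int, j: int) -> str:
    """Orientation of reference run [i, j) within ``other``.

    Returns forward/reverse when the run appears contiguously (circularly) with a
    consistent joint orientation, ``not_applicable`` when any member gene is missing,
    and ``broken`` when all genes occur but not as a co-oriented contiguous run.
    """
    idx = other.index()
    genes = ref.genes[i:j]
    if any(g not in idx for g in genes):
        return "not_applicable"
    if len(genes) == 1:
        g = genes[0]
        rel = idx[g][1] * ref.signs[i]
        return "forward" if rel == 1 else "reverse"
    m = len(other.genes)
    positions = [idx[g][0] for g in genes]
    rel_signs = [idx[g][1] * ref.signs[i + k] for k, g in enumerate(genes)]
    fwd = all((positions[k + 1] - positions[k]) % m == 1 for k in range(len(genes) - 1)) \
        and all(s == 1 for s in rel_signs)
    rev = all((positions[k] - positions[k + 1]) % m == 1 for k in range(len(genes) - 1)) \
        and all(s == -1 for s in rel_signs)
    if fwd:
        return "forward"
    if rev:
        return "reverse"
    return "broken"


def _block_region(ref: GeneOrder, genes: list[str]) -> str:
    regions = [ref.regions.get(g, "LSC") for g in genes]
    return max(set(regions), key=regions.count)


def filter_reduced(orders: list[GeneOrder], reference: ReferenceGeneSet | None = None,
                   max_missing_fraction: float = MAX_MISSING_FRACTION) -> list[GeneOrder]:
    """Drop severely reduced genomes before block analysis."""
    ref = reference or ReferenceGeneSet.default()
    keep = []
    for o in orders:
        missing = 1.0 - len(set(o.genes) & set(ref.names)) / len(ref)
        if missing <= max_missing_fraction:
            keep.append(o)
    return keep


# ---------------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------------

def block_census(blocks: list[SyntenyBlock]) -> dict:
    """Counts of constant vs rearranged blocks, by region and by length bin."""
    census = {
        "n_blocks": len(blocks),
        "constant": sum(1 for b in blocks if b.constant),
        "rearranged": sum(1 for b in blocks if not b.constant),
        "by_region": {r: 0 for r in ("LSC", "IR", "SSC")},
        "by_length_bin": {label: 0 for _, _, label in LENGTH_BINS},
    }
    for b in blocks:
        census["by_region"][b.region] = census["by_region"].get(b.region, 0) + 1
        for lo, hi, label in LENGTH_BINS:
            if lo <= b.length_bp < hi:
                census["by_length_bin"][label] += 1
                break
    return census


def blocks_table(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    """Block table with per-taxon orientation columns (F/R/NA)."""
    code = {"forward": "F", "reverse": "R", "not_applicable": "NA"}
    taxa = sorted({t for b in blocks for t in b.orientations})
    rows = []
    for b in blocks:
        row = {"block_id": b.id, "genes": ",".join(b.genes), "length_bp": b.length_bp,
               "region": b.region, "constant": b.constant}
        for t in taxa:
            row[t] = code[b.orientations[t]]
        rows.append(row)
    return pd.DataFrame(rows)
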