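"""Gene/pseudogene status calling and the gene- and intron-content matrices.

A protein-coding gene is called *present* when its spliced frame is intact: a valid
start (ATG, or the ACG/TTG alternative starts known from plastid transcript editing),
length divisible by three, and no internal stop codons — or at most five internal stops
when every one of them is an RNA-editing-tolerable UGA (a genomic TGA can correspond to
an edited arginine CGA codon; TAA/TAG internal stops have no such single C-to-U origin
and are treated as real).  A gene is a *pseudogene* on more than five internal stops, a
broken frame (uncompensated frameshift), or a large indel relative to the reference
length.  tRNA/rRNA genes are length-checked against the catalogue (within 20%).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from plastevo.io import GeneFeature, PlastomeRecord
from plastevo.reference import ReferenceGeneSet

STOP_CODONS = {"TAA", "TAG", "TGA"}
#: internal stops rescuable under the C->U editing reading (see module docstring)
EDITABLE_STOPS = {"TGA"}
START_CODONS = {"ATG"}
ALT_START_CODONS = {"ACG", "TTG"}

#: default threshold for a "large abnormal indel", bp
LARGE_INDEL_BP = 30
#: maximum internal stops still compatible with an edited, functional transcript
MAX_EDITABLE_STOPS = 5
#: tRNA/rRNA length tolerance relative to the reference, fraction
RNA_LENGTH_TOL = 0.20


@dataclass
class GeneStatus:
    value: str                              # present | pseudogene | absent
    evidence: list[str] = field(default_factory=list)

    def __eq__(self, other):
        if isinstance(other, str):
            return self.value == other
        return isinstance(other, GeneStatus) and self.value == other.value

    @property
    def functional(self) -> bool:
        return self.value == "present"


def call_gene_status(feature: GeneFeature | None, cds_sequence: str | None = None,
                     ref_length: int | None = None,
                     large_indel_bp: int = LARGE_INDEL_BP) -> GeneStatus:
    """Status of one gene from its feature and spliced sequence.

    ``cds_sequence`` must be the spliced sequence in reading orientation for CDS
    features; for tRNA/rRNA only the length is used.  ``ref_length`` enables the
    large-indel check (and is required for tRNA/rRNA calls).
    """
    if feature is None:
        return GeneStatus("absent", ["missing"])
    if feature.kind in ("tRNA", "rRNA"):
        if feature.annotated_pseudo:
            return GeneStatus("pseudogene", ["annotated_pseudo"])
        length = feature.exon_length
        if ref_length is not None and abs(length - ref_length) > RNA_LENGTH_TOL * ref_length:
            return GeneStatus("pseudogene", [f"length_deviation={length - ref_length:+d}"])
        return GeneStatus("present", [])

    if not cds_sequence:
        raise ValueError(f"{feature.name}: CDS feature without a sequence")
    seq = cds_sequence.upper()
    evidence: list[str] = []
    if feature.annotated_pseudo:
        return GeneStatus("pseudogene", ["annotated_pseudo"])

    if len(seq) % 3 != 0:
        # a compensating indel pair within 10 codons would restore frame length;
        # frame length itself is the observable here, so a broken length is a frameshift
        return GeneStatus("pseudogene", ["frameshift"])
    if ref_length is not None and abs(len(seq) - ref_length) > large_indel_bp:
        return GeneStatus("pseudogene", [f"large_indel={len(seq) - ref_length:+d}"])

    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    start = codons[0]
    internal = codons[1:-1]     # the terminal codon is never counted as internal
    stops = [c for c in internal if c in STOP_CODONS]

    if start not in START_CODONS | ALT_START_CODONS:
        return GeneStatus("pseudogene", ["no_start"])
    if start in ALT_START_CODONS:
        evidence.append("alt_start")

    if not stops:
        return GeneStatus("present", evidence)
    if len(stops) <= MAX_EDITABLE_STOPS and all(c in EDITABLE_STOPS for c in stops):
        evidence.append(f"internal_stops={len(stops)}")
        return GeneStatus("present", evidence)
    evidence.append(f"internal_stops={len(stops)}")
    return GeneStatus("pseudogene", evidence)


# ---------------------------------------------------------------------------------
# gene-status matrix (taxa x reference genes)
# ---------------------------------------------------------------------------------

@dataclass
class GeneStatusMatrix:
    taxa: list[str]
    genes: list[str]
    cells: dict[tuple[str, str], GeneStatus]

    def status(self, taxon: str, gene: str) -> GeneStatus:
        return self.cells[(taxon, gene)]

    def row(self, taxon: str) -> dict[str, GeneStatus]:
        return {g: self.cells[(taxon, g)] for g in self.genes}

    def tallies(self, taxon: str) -> dict[str, int]:
        counts = {"n_present": 0, "n_pseudo": 0, "n_absent": 0}
        for g in self.genes:
            v = self.cells[(taxon, g)].value
            counts["n_present" if v == "present" else
                   "n_pseudo" if v == "pseudogene" else "n_absent"] += 1
        return counts

    def n_functional(self, taxon: str) -> int:
        return self.tallies(taxon)["n_present"]

    def as_dataframe(self) -> pd.DataFrame:
        code = {"present": "P", "pseudogene": "PSEUDO", "absent": "A"}
        data = {g: [code[self.cells[(t, g)].value] for t in self.taxa] for g in self.genes}
        return pd.DataFrame(data, index=self.taxa)

    def to_long(self) -> pd.DataFrame:
        """Heatmap-ready long format: taxon, gene, status."""
        rows = [(t, g, self.cells[(t, g)].value) for t in self.taxa for g in self.genes]
        return pd.DataFrame(rows, columns=["taxon", "gene", "status"])

    def subset(self, taxa: list[str]) -> "GeneStatusMatrix":
        missing = [t for t in taxa if t not in self.taxa]
        if missing:
            raise KeyError(f"taxa not in matrix: {missing}")
        cells = {(t, g): self.cells[(t, g)] for t in taxa for g in self.genes}
        return GeneStatusMatrix(taxa=list(taxa), genes=list(self.genes), cells=cells)


_STATUS_RANK = {"present": 2, "pseudogene": 1, "absent": 0}


def build_status_matrix(records: list[PlastomeRecord],
                        reference: ReferenceGeneSet | None = None) -> GeneStatusMatrix:
    """One row per taxon over the 113 reference genes.

    IR-resident genes annotated twice are counted once (the best-supported copy wins:
    present > pseudogene).  Non-reference symbols are ignored with a warning.
    """
    ref = reference or ReferenceGeneSet.default()
    taxa, cells = [], {}
    for rec in records:
        taxon = rec.taxon
        if taxon in taxa:       # disambiguate repeated organism names by accession
            taxon = f"{rec.taxon} ({rec.accession})"
            suffix = 2
            while taxon in taxa:
                taxon = f"{rec.taxon} ({rec.accession}.{suffix})"
                suffix += 1
            warnings.warn(f"duplicate taxon {rec.taxon!r}; row renamed to {taxon!r}")
        taxa.append(taxon)
        best: dict[str, GeneStatus] = {}
        unknown = []
        for f in rec.features:
            if f.name not in ref:
                unknown.append(f.name)
                continue
            g = ref[f.name]
            seq = rec.spliced(f) if g.kind == "CDS" else None
            st = call_gene_status(f, seq, ref_length=g.ref_length)
            if f.name not in best or _STATUS_RANK[st.value] > _STATUS_RANK[best[f.name].value]:
                best[f.name] = st
        if unknown:
            warnings.warn(f"{taxon}: non-reference gene symbols ignored: {sorted(set(unknown))}")
        for gname in ref.names:
            cells[(taxon, gname)] = best.get(gname, GeneStatus("absent", ["missing"]))
    return GeneStatusMatrix(taxa=taxa, genes=list(ref.names), cells=cells)


# ---------------------------------------------------------------------------------
# intron matrix (taxa x 20 catalogued introns)
# ---------------------------------------------------------------------------------

@dataclass
class IntronMatrix:
    taxa: list[str]
    introns: list[tuple[str, int]]          # (gene, intron number from the 5' end)
    cells: dict[tuple[str, str, int], str]  # -> intron_present | intron_lost_gene_retained | lost_with_gene

    def as_dataframe(self) -> pd.DataFrame:
        cols = [f"{g}({i})" for g, i in self.introns]
        data = {f"{g}({i})": [self.cells[(t, g, i)] for t in self.taxa]
                for g, i in self.introns}
        return pd.DataFrame(data, index=self.taxa, columns=cols)


def build_intron_matrix(records: list[PlastomeRecord],
                        reference: ReferenceGeneSet | None = None,
                        status_matrix: GeneStatusMatrix | None = None) -> IntronMatrix:
    """Intron presence over the 20-intron catalogue.

    Intron *i* of a gene is present when the annotated exon count exceeds *i*; a
    present gene with fewer exons has lost the intron without losing the gene; a
    pseudogenized or absent gene scores ``lost_with_gene`` for all its introns.
    """
    ref = reference or ReferenceGeneSet.default()
    status = status_matrix or build_status_matrix(records, ref)
    catalogue = ref.intron_catalogue
    cells = {}
    for rec in records:
        taxon = rec.taxon
        # the copy with the most exons represents an IR-duplicated gene
        exon_counts: dict[str, int] = {}
        for f in rec.features:
            if f.name in ref:
                exon_counts[f.name] = max(exon_counts.get(f.name, 0), len(f.exons))
        for gene, i in catalogue:
            if status.status(taxon, gene).value != "present":
                cells[(taxon, gene, i)] = "lost_with_gene"
            elif exon_counts.get(gene, 1) > i:
                cells[(taxon, gene, i)] = "intron_present"
            else:
                cells[(taxon, gene, i)] = "intron_lost_gene_retained"
    return IntronMatrix(taxa=[r.taxon for r in records], introns=catalogue, cells=cells)
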