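"""The fixed 113-gene plastid reference catalogue and its intron catalogue.

A canonical angiosperm plastome carries 113 distinct genes: 6 *atp*, 11 *ndh*, 6 *pet*,
9 *rpl*, 4 *rpo*, 12 *rps*, 4 *rrn*, 5 *psa*, 15 *psb*, 30 *trn* and 11 ungrouped genes.
Sixteen of them carry one intron and two (*clpP*, *ycf3*) carry two, for 20 catalogued
introns in total.  The roster ships as a packaged data file and can be overridden with a
user table of the same layout.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

GENE_CLASSES = ("atp", "ndh", "pet", "rpl", "rpo", "rps", "rrn", "psa", "psb", "trn", "other")

#: gene classes making up the photosynthetic light-reaction machinery plus the
#: plastid-encoded polymerase; their loss marks the second degradation stage
PHOTOSYNTHESIS_CLASSES = frozenset({"pet", "psa", "psb", "rpo"})
#: translation/transcription housekeeping classes whose erosion marks the third stage
HOUSEKEEPING_CLASSES = frozenset({"rpl", "rps", "rrn", "trn"})


@dataclass(frozen=True)
class ReferenceGene:
    name: str
    gene_class: str
    kind: str            # CDS | tRNA | rRNA
    ref_length: int      # summed exon length, nt
    n_exons: int
    region: str          # LSC | IR | SSC in the canonical layout
    strand: int          # +1 / -1 in the canonical layout


class ReferenceGeneSet:
    """The ordered reference gene catalogue (canonical circular order)."""

    def __init__(self, genes: list[ReferenceGene]):
        self.genes = list(genes)
        self._by_name = {g.name: g for g in self.genes}
        if len(self._by_name) != len(self.genes):
            raise ValueError("duplicate gene names in reference catalogue")

    @classmethod
    def default(cls) -> "ReferenceGeneSet":
        with resources.files("plastevo.data").joinpath("reference_genes.tsv").open() as fh:
            return cls._parse(fh)

    @classmethod
    def from_table(cls, path: str | Path) -> "ReferenceGeneSet":
        with open(path) as fh:
            return cls._parse(fh)

    @classmethod
    def _parse(cls, fh) -> "ReferenceGeneSet":
        genes = []
        for row in csv.DictReader(fh, delimiter="\t"):
            genes.append(ReferenceGene(
                name=row["name"], gene_class=row["gene_class"], kind=row["kind"],
                ref_length=int(row["ref_length"]), n_exons=int(row["n_exons"]),
                region=row["region"], strand=int(row["strand"])))
        return cls(genes)

    # -- catalogue views ------------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [g.name for g in self.genes]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> ReferenceGene:
        return self._by_name[name]

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def class_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {c: 0 for c in GENE_CLASSES}
        for g in self.genes:
            sizes[g.gene_class] += 1
        return sizes

    def class_of(self, name: str) -> str:
        if name in self._by_name:
            return self._by_name[name].gene_class
        return infer_gene_class(name)

    @property
    def intron_catalogue(self) -> list[tuple[str, int]]:
        """(gene, intron number) pairs, introns numbered 1.. from the 5' end."""
        out = []
        for g in self.genes:
            for i in range(1, g.n_exons):
                out.append((g.name, i))
        return out

    def region_genes(self, region: str) -> list[str]:
        return [g.name for g in self.genes if g.region == region]


def infer_gene_class(name: str) -> str:
    """Class of a (possibly non-reference) symbol from its stem."""
    low = name.lower()
    for pref in ("atp", "ndh", "pet", "rpl", "rpo", "rps", "rrn", "psa", "psb", "trn"):
        if low.startswith(pref):
            return pref
    return "other"
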