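"""Readers and writers for GenBank, FASTA, status-matrix TSV and newick inputs.

Coordinates are 1-based inclusive (GenBank convention) on a circular molecule whose
origin is position 1.  A feature spanning the origin is stored as a single feature
whose wrap exon keeps its GenBank start and carries an end beyond the sequence length
(interpreted modulo the genome length), so exon lengths stay additive.
"""
from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from plastevo.reference import ReferenceGeneSet

LIFE_FORMS = {"terrestrial", "epiphyte", "unknown"}
TROPHIC_MODES = {"photosynthetic", "mixotrophic", "mycoheterotrophic", "unknown"}

# Annotation dialects seen across re-annotated public records.  Keys are already
# case-normalized stems; the trnC anticodon variant is a known in-print inconsistency
# (the catalogue anticodon is GCA).
SYNONYMS = {
    "trnC-GGA": "trnC-GCA",
    "rrn16S": "rrn16", "rrn23S": "rrn23", "rrn4.5S": "rrn4.5", "rrn5S": "rrn5",
    "16S": "rrn16", "23S": "rrn23", "4.5S": "rrn4.5", "5S": "rrn5",
    "psbA1": "psbA",
    "ycf15": "ycf15",  # non-reference, passes through
}

_TRNA_RE = re.compile(r"^trn(f?)([A-Za-z])[-_ ]?\(?([ACGTUacgtu]{3})?\)?$")


@dataclass
class GeneFeature:
    """One annotated gene with its exon structure.

    ``exons`` is an ordered list of (start, end, strand) with 1-based inclusive
    coordinates and strand +1/-1.  Intron count is ``len(exons) - 1`` (the
    trans-spliced rps12 is exempt from exon contiguity, not from this count).
    """

    name: str
    gene_class: str
    kind: str                      # CDS | tRNA | rRNA
    exons: list[tuple[int, int, int]]
    annotated_pseudo: bool = False
    raw_name: str | None = None

    @property
    def start(self) -> int:
        return min(e[0] for e in self.exons)

    @property
    def end(self) -> int:
        return max(e[1] for e in self.exons)

    @property
    def strand(self) -> int:
        return self.exons[0][2]

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def exon_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.exons)


@dataclass
class PlastomeRecord:
    """One annotated circular plastid genome."""

    accession: str
    taxon: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    topology: str = "circular"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        self.metadata.setdefault("life_form", "unknown")
        self.metadata.setdefault("trophic_mode", "unknown")

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"{self.accession}: non-ACGTN characters in sequence")
        n = len(self.sequence)
        for f in self.features:
            for s, e, strand in f.exons:
                if not (1 <= s <= n) or not (1 <= e <= 2 * n) or strand not in (1, -1):
                    raise ValueError(f"{self.accession}:{f.name}: exon ({s},{e}) outside [1,{n}]")

    def feature_by_name(self, name: str) -> GeneFeature | None:
        for f in self.features:
            if f.name == name:
                return f
        return None

    def extract(self, start: int, end: int, strand: int = 1) -> str:
        """Wrap-aware 1-based inclusive slice, reverse-complemented for strand -1."""
        n = len(self.sequence)
        if end <= n:
            seg = self.sequence[start - 1:end]
        else:  # wraps the origin
            seg = self.sequence[start - 1:] + self.sequence[:end - n]
        return revcomp(seg) if strand == -1 else seg

    def spliced(self, feature: GeneFeature) -> str:
        """Spliced gene sequence in reading orientation."""
        exons = sorted(feature.exons, key=lambda e: e[0])
        parts = [self.extract(s, e, 1) for s, e, _ in exons]
        seq = "".join(parts)
        return revcomp(seq) if feature.strand == -1 else seq


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------------
# gene-name normalization
# ---------------------------------------------------------------------------------

def normalize_gene_name(raw: str, reference: ReferenceGeneSet | None = None) -> str:
    """Map an annotation dialect to the catalogue symbol.

    Case-folds the stem, canonicalizes tRNA anticodon suffixes (DNA -> RNA alphabet,
    upper case) and applies the synonym table.  Unknown names pass through cleaned but
    unchanged; use ``reference.__contains__`` to flag them as non-reference.
    """
    if not raw or not raw.strip():
        raise ValueError("empty gene name")
    name = raw.strip().replace(" ", "")
    if name in SYNONYMS:
        name = SYNONYMS[name]
    m = _TRNA_RE.match(name) or _TRNA_RE.match(name[0].lower() + name[1:])
    if name.lower().startswith("trn") and m:
        fmet, aa, anticodon = m.groups()
        aa = aa.upper() if not fmet else aa
        sym = f"trn{'f' if fmet else ''}{aa if not fmet else 'M'}"
        if anticodon:
            sym += "-" + anticodon.upper().replace("T", "U")
        name = SYNONYMS.get(sym, sym)
        return name
    # case-insensitive match against the catalogue roster
    ref = reference or _default_reference()
    low = name.lower()
    for g in ref.names:
        if g.lower() == low:
            return g
    # common stylings: leading capital (NdhF), internal casing noise
    return name[0].lower() + name[1:] if name[0].isupper() else name


_REF_CACHE: ReferenceGeneSet | None = None


def _default_reference() -> ReferenceGeneSet:
    global _REF_CACHE
    if _REF_CACHE is None:
        _REF_CACHE = ReferenceGeneSet.default()
    return _REF_CACHE


# ---------------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------------

def read_genbank(path: str | Path, reference: ReferenceGeneSet | None = None) -> PlastomeRecord:
    """Parse a GenBank flat file into a :class:`PlastomeRecord`.

    gene/CDS/tRNA/rRNA features are collected; joined locations become multi-exon
    features; ``/pseudo`` qualifiers set ``annotated_pseudo``.  When a locus has both a
    ``gene`` feature and a typed feature (CDS/tRNA/rRNA) the typed one wins.
    """
    try:
        rec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on malformed input
        raise ValueError(f"{path}: not a readable GenBank flat file: {exc}") from exc
    if len(rec.seq) == 0:
        raise ValueError(f"{path}: record has no ORIGIN sequence")
    ref = reference or _default_reference()
    n = len(rec.seq)

    typed: dict[tuple, GeneFeature] = {}
    gene_only: dict[tuple, GeneFeature] = {}
    for feat in rec.features:
        if feat.type not in ("gene", "CDS", "tRNA", "rRNA"):
            continue
        raw = (feat.qualifiers.get("gene") or feat.qualifiers.get("locus_tag") or [None])[0]
        if raw is None:
            continue
        name = normalize_gene_name(raw, ref)
        exons = _exons_from_location(feat.location, n)
        pseudo = "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers
        kind = feat.type if feat.type != "gene" else (ref[name].kind if name in ref else "CDS")
        gf = GeneFeature(name=name, gene_class=ref.class_of(name), kind=kind,
                         exons=exons, annotated_pseudo=pseudo, raw_name=raw)
        key = (name, gf.start)
        if feat.type == "gene":
            gene_only.setdefault(key, gf)
        else:
            typed[key] = gf

    feats = dict(gene_only)
    # a typed feature supersedes the gene feature for the same symbol; the gene
    # feature's /pseudo flag is kept if only it carries one
    typed_names: dict[str, list[tuple]] = {}
    for key, gf in typed.items():
        typed_names.setdefault(gf.name, []).append(key)
    for key in list(feats):
        name = feats[key].name
        if name in typed_names:
            if feats[key].annotated_pseudo:
                for tkey in typed_names[name]:
                    typed[tkey].annotated_pseudo = True
            del feats[key]
    feats.update(typed)
    features = sorted(feats.values(), key=lambda f: (f.start, f.name))

    meta = {"life_form": "unknown", "trophic_mode": "unknown"}
    for feat in rec.features:
        if feat.type == "source":
            for k in ("life_form", "trophic_mode"):
                if k in feat.qualifiers:
                    meta[k] = feat.qualifiers[k][0]
    topology = rec.annotations.get("topology", "circular")
    taxon = rec.annotations.get("organism") or rec.description or rec.id
    return PlastomeRecord(accession=rec.id, taxon=taxon, sequence=str(rec.seq),
                          features=features, topology=topology, metadata=meta)


def _exons_from_location(loc, n: int) -> list[tuple[int, int, int]]:
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    exons = [(int(p.start) + 1, int(p.end), int(p.strand or 1)) for p in parts]
    exons.sort(key=lambda e: e[0])
    # merge a split that is really one exon wrapping the origin
    if len(exons) >= 2 and exons[0][0] == 1 and exons[-1][1] == n \
            and exons[0][2] == exons[-1][2]:
        first, last = exons[0], exons[-1]
        merged = (last[0], n + first[1], last[2])
        exons = [merged] + exons[1:-1]
        exons.sort(key=lambda e: e[0])
    return exons


def write_genbank(record: PlastomeRecord, path: str | Path) -> None:
    """Serialize a record back to a GenBank flat file (lossless for our fields)."""
    rec = SeqRecord(Seq(record.sequence), id=record.accession, name=record.accession[:16],
                    description=record.taxon)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = record.topology
    rec.annotations["organism"] = record.taxon
    n = len(record.sequence)
    src = SeqFeature(SimpleLocation(0, n, strand=1), type="source")
    src.qualifiers["organism"] = [record.taxon]
    for k in ("life_form", "trophic_mode"):
        if record.metadata.get(k, "unknown") != "unknown":
            src.qualifiers[k] = [record.metadata[k]]
    rec.features.append(src)
    for f in record.features:
        locs = []
        for s, e, strand in f.exons:
            if e <= n:
                locs.append(SimpleLocation(s - 1, e, strand=strand))
            else:  # wrap exon: split for serialization; re-merged on read
                locs.append(SimpleLocation(s - 1, n, strand=strand))
                locs.append(SimpleLocation(0, e - n, strand=strand))
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        feat = SeqFeature(loc, type=f.kind)
        feat.qualifiers["gene"] = [f.name]
        if f.annotated_pseudo:
            feat.qualifiers["pseudo"] = [""]
        rec.features.append(feat)
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------------
# status-matrix TSV  (cells P / PSEUDO / A; the Greek Ψ is accepted on input)
# ---------------------------------------------------------------------------------

_CELL_CODES = {"P": "present", "PSEUDO": "pseudogene", "Ψ": "pseudogene", "A": "absent"}
_CODE_OF = {"present": "P", "pseudogene": "PSEUDO", "absent": "A"}


def read_status_table(path: str | Path):
    """Read a taxa x genes status TSV into a :class:`~plastevo.genecontent.GeneStatusMatrix`."""
    from plastevo.genecontent import GeneStatus, GeneStatusMatrix
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        genes = header[1:]
        taxa, cells = [], {}
        for row in reader:
            if not row:
                continue
            taxon = row[0]
            taxa.append(taxon)
            for gene, cell in zip(genes, row[1:]):
                if cell not in _CELL_CODES:
                    raise ValueError(
                        f"{path}: unknown status code {cell!r} at row {taxon!r}, column {gene!r}")
                cells[(taxon, gene)] = GeneStatus(_CELL_CODES[cell])
    return GeneStatusMatrix(taxa=taxa, genes=genes, cells=cells)


def write_status_table(matrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(matrix.genes) + "\n")
        for taxon in matrix.taxa:
            codes = [_CODE_OF[matrix.cells[(taxon, g)].value] for g in matrix.genes]
            fh.write(taxon + "\t" + "\t".join(codes) + "\n")


# ---------------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted newick tree; duplicate tip labels are an error."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True, rooting="force-rooted")
    except Exception as exc:
        raise ValueError(f"{path}: unreadable newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate tip labels: {sorted(dupes)}")
    return tree
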