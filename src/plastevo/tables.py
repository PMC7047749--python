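"""Loaders for the packaged published summary tables used as desk-scale fixtures.

Three tables ship with the package: per-accession general features of 129 plastomes
(124 orchids + 5 outgroups: lengths, LSC/SSC/IR, GC, gene counts), the lengths of the
24 newly sequenced plastomes, and the minimal-gene table for the seven extremely
degraded plastomes together with each gene's presence count over the other 117
orchids.  A printed gene inventory of the reduced *Gastrodia elata* plastome is also
packaged.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from plastevo.genecontent import GeneStatus, GeneStatusMatrix

#: placeholder taxon standing for the orchids that carry every Table-3 gene
OTHER_ORCHIDS_REPRESENTATIVE = "Other Orchidaceae (representative)"


def _data(name: str):
    return resources.files("plastevo.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """Lengths of the 24 newly sequenced plastomes."""
    with _data("table1_new_plastomes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_table2(orchids_only: bool = False) -> pd.DataFrame:
    """General features of the 129 study accessions (124 orchids + 5 outgroups)."""
    with _data("table2_accessions.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df[df["group"] == "orchid"].reset_index(drop=True) if orchids_only else df


def load_table3_status() -> GeneStatusMatrix:
    """The seven extremely degraded plastomes x the 20 shared genes (all present)."""
    from plastevo.io import read_status_table
    with resources.as_file(_data("table3_minimal_genes.tsv")) as path:
        return read_status_table(path)


def load_table3_exceptions() -> pd.DataFrame:
    """Per-gene presence counts over the other 117 orchids, with named exceptions."""
    with _data("table3_other_orchids.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def load_table3_full_matrix() -> GeneStatusMatrix:
    """Status matrix over all 124 orchids restricted to the 20 Table-3 genes.

    The seven degraded plastomes appear by name; the other 117 are represented by the
    taxa the table names as exceptions (absent or pseudogenized for specific genes)
    plus one representative row carrying every gene.  Gene-wise intersections over this
    matrix equal intersections over the full 124-taxon set, because a Table-3 gene is
    missing from the 117 only in the named exception taxa.
    """
    seven = load_table3_status()
    exc = load_table3_exceptions()
    genes = list(seven.genes)

    exception_status: dict[tuple[str, str], str] = {}
    for _, row in exc.iterrows():
        note = row["exceptions"]
        if not note:
            continue
        for part in str(note).split(","):
            part = part.strip()
            if not part:
                continue
            taxon = part.split("(")[0].strip()
            status = "pseudogene" if "Pseudogene" in part else "absent"
            exception_status[(taxon, row["gene"])] = status

    extra_taxa = sorted({t for t, _ in exception_status}) + [OTHER_ORCHIDS_REPRESENTATIVE]
    taxa = list(seven.taxa) + extra_taxa
    cells = dict(seven.cells)
    for t in extra_taxa:
        for g in genes:
            cells[(t, g)] = GeneStatus(exception_status.get((t, g), "present"))
    return GeneStatusMatrix(taxa=taxa, genes=genes, cells=cells)


def load_gastrodia_genes() -> pd.DataFrame:
    """The printed gene inventory of the reduced Gastrodia elata plastome."""
    with _data("gastrodia_elata_genes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def gastrodia_status_matrix(trnas: tuple[str, ...] = ("trnC-GCA", "trnE-UUC", "trnfM-CAU",
                                                      "trnM-CAU", "trnQ-UUG")) -> GeneStatusMatrix:
    """A full 113-gene status row for Gastrodia elata from the printed inventory.

    The printed list names 23 intact genes and two pseudogenes; its five tRNAs are not
    itemized in print, so a plausible five (including the two named in the minimal-gene
    table) stand in — the row's pseudogene tally and stage call do not depend on which.
    """
    from plastevo.reference import ReferenceGeneSet
    ref = ReferenceGeneSet.default()
    inv = load_gastrodia_genes()
    status = {row["gene"]: ("present" if row["status"] == "P" else "pseudogene")
              for _, row in inv.iterrows()}
    for t in trnas:
        status[t] = "present"
    taxon = "Gastrodia elata"
    cells = {(taxon, g): GeneStatus(status.get(g, "absent")) for g in ref.names}
    return GeneStatusMatrix(taxa=[taxon], genes=list(ref.names), cells=cells)
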