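import pytest

from plastevo.io import GeneFeature, PlastomeRecord
from plastevo.reference import ReferenceGeneSet
from plastevo.simulate import SimulationConfig, simulate_plastome, stage_preset


@pytest.fixture(scope="session")
def reference():
    return ReferenceGeneSet.default()


@pytest.fixture(scope="session")
def full_sim():
    """One default (full, photosynthetic) simulated plastome + ground truth."""
    return simulate_plastome(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def stage_sims():
    """One simulated plastome per degradation stage preset, keyed by stage."""
    out = {}
    for stage in ("full", "near_full", "stage1_ndh", "stage2_photo",
                  "intermediate", "stage3_housekeeping"):
        out[stage] = simulate_plastome(stage_preset(stage, seed=202))
    return out


def toy_record(genes, length=10_000, taxon="Toy sp.", accession="TOY1"):
    """Record with hand-placed features over a poly-A backbone.

    ``genes`` is a list of (name, gene_class, kind, exons, pseudo, sequence) where
    ``sequence`` (optional) is written at the exon coordinates.
    """
    seq = list("A" * length)
    feats = []
    for spec in genes:
        name, gene_class, kind, exons, pseudo = spec[:5]
        if len(spec) == 6 and spec[5]:
            written = spec[5]
            pos = 0
            for s, e, strand in exons:
                n = e - s + 1
                seq[s - 1:e] = written[pos:pos + n]
                pos += n
        feats.append(GeneFeature(name=name, gene_class=gene_class, kind=kind,
                                 exons=list(exons), annotated_pseudo=pseudo))
    return PlastomeRecord(accession=accession, taxon=taxon, sequence="".join(seq),
                          features=feats)
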