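"""Degradation-stage classification, minimal common gene sets and correlations.

Mycoheterotrophic plastomes lose genes in three stages rather than on a continuum:
first the 11-gene *ndh* class, then the photosynthesis light-reaction machinery
(*pet*/*psa*/*psb*) together with the plastid-encoded polymerase (*rpo*), and finally
the translation/transcription housekeeping apparatus (*rpl*/*rps*/*trn* and friends),
leaving 27–33 functional genes.  The empirical count clusters — at least 55 functional
genes in stage 2, at most 33 in stage 3 — set the default thresholds; genomes with
clear housekeeping erosion on top of a stage-2 loss pattern sit in an intermediate
class even when their raw count is still stage-2-like.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from plastevo.genecontent import GeneStatusMatrix
from plastevo.reference import (HOUSEKEEPING_CLASSES, PHOTOSYNTHESIS_CLASSES,
                                ReferenceGeneSet)


@dataclass
class StageThresholds:
    """Stage boundaries from the published count clusters; all config-exposed."""

    stage3_max: int = 33        # stage 3: at most this many functional genes
    stage2_min: int = 55        # stage 2: at least this many functional genes
    ndh_min: int = 4            # stage 1: at least this many ndh genes nonfunctional
    other_max: int = 3          # stage 1: at most this many non-ndh genes nonfunctional
    near_full_max: int = 3      # near-full: 1..this many genes nonfunctional
    housekeeping_min: int = 3   # intermediate: housekeeping losses beyond a stage-2 pattern


@dataclass
class DegradationCall:
    taxon: str
    n_functional: int
    stage: str      # full | near_full | stage1_ndh | stage2_photo | intermediate | stage3_housekeeping
    trigger: str


def classify_stage(matrix: GeneStatusMatrix, taxon: str,
                   reference: ReferenceGeneSet | None = None,
                   thresholds: StageThresholds | None = None) -> DegradationCall:
    """Classify one genome row into a loss stage (pseudogenes count as nonfunctional).

    Rules are applied in order so every possible row resolves: stage 3 on the count
    cluster alone; intermediate when housekeeping erosion accompanies photosynthesis
    losses above the stage-3 count; stage 2 on photosynthesis/rpo losses at a high
    count; stage 1 on an ndh-dominated pattern; near-full for 1–3 losses; full
    otherwise.
    """
    ref = reference or ReferenceGeneSet.default()
    if list(matrix.genes) != list(ref.names):
        raise ValueError("matrix is not over the reference gene catalogue")
    th = thresholds or StageThresholds()

    nonfunc = [g for g in matrix.genes if not matrix.status(taxon, g).functional]
    nf = len(matrix.genes) - len(nonfunc)
    by_class: dict[str, int] = {}
    for g in nonfunc:
        by_class[ref.class_of(g)] = by_class.get(ref.class_of(g), 0) + 1
    n_ndh = by_class.get("ndh", 0)
    n_photo = sum(by_class.get(c, 0) for c in PHOTOSYNTHESIS_CLASSES)
    n_house = sum(by_class.get(c, 0) for c in HOUSEKEEPING_CLASSES)
    n_other = len(nonfunc) - n_ndh

    if nf <= th.stage3_max:
        stage, why = "stage3_housekeeping", f"{nf} functional genes <= {th.stage3_max}"
    elif n_ndh >= th.ndh_min and n_other <= th.other_max:
        # an ndh-dominated pattern (up to a few incidental losses) stays stage 1 even
        # when one of the incidental losses is a photosynthesis gene
        stage, why = "stage1_ndh", f"{n_ndh}/11 ndh nonfunctional, {n_other} others"
    elif n_house >= th.housekeeping_min and n_photo >= 1:
        stage = "intermediate"
        why = (f"{n_house} housekeeping losses beyond a stage-2 pattern "
               f"with {nf} functional genes")
    elif n_photo >= 1 and nf >= th.stage2_min:
        stage, why = "stage2_photo", f"photosynthesis/rpo losses with {nf} functional genes"
    elif n_photo >= 1 and nf > th.stage3_max:
        # between the stage-2 and stage-3 count clusters without housekeeping erosion
        stage, why = "intermediate", f"photosynthesis losses at {nf} functional genes"
    elif 1 <= len(nonfunc) <= th.near_full_max:
        stage, why = "near_full", f"{len(nonfunc)} genes nonfunctional"
    else:
        stage, why = "full", "no qualifying loss pattern"
    return DegradationCall(taxon=taxon, n_functional=nf, stage=stage, trigger=why)


def classify_all(matrix: GeneStatusMatrix, reference: ReferenceGeneSet | None = None,
                 thresholds: StageThresholds | None = None) -> list[DegradationCall]:
    return [classify_stage(matrix, t, reference, thresholds) for t in matrix.taxa]


# ---------------------------------------------------------------------------------
# minimal common gene sets
# ---------------------------------------------------------------------------------

def minimal_common_genes(matrix: GeneStatusMatrix,
                         taxa_subset: list[str] | None = None) -> set[str]:
    """Genes with *present* status in every taxon of the subset (pseudogene != present)."""
    taxa = list(taxa_subset) if taxa_subset is not None else list(matrix.taxa)
    if not taxa:
        raise ValueError("empty taxon subset")
    missing = [t for t in taxa if t not in matrix.taxa]
    if missing:
        raise KeyError(f"taxa not in matrix: {missing}")
    return {g for g in matrix.genes
            if all(matrix.status(t, g).value == "present" for t in taxa)}


# ---------------------------------------------------------------------------------
# correlation summaries
# ---------------------------------------------------------------------------------

@dataclass
class CorrelationSummary:
    label: str                              # subset label, e.g. "mycoheterotrophic"
    pair: tuple[str, str]                   # variable pair
    r_squared: float | None                 # None when undefined (zero variance)
    n: int


DEFAULT_PAIRS = (("length_bp", "lsc_bp"), ("length_bp", "ir_bp"),
                 ("length_bp", "n_functional"))


def correlation_summary(df: pd.DataFrame, grouping: str | None = None,
                        pairs: tuple = DEFAULT_PAIRS) -> list[CorrelationSummary]:
    """Squared Pearson correlations per group per variable pair.

    ``df`` holds one row per genome with the variables as columns; ``grouping`` names a
    column defining subsets (None = one group over everything).  Groups with fewer than
    three members are skipped with a warning; zero-variance variables yield an
    undefined (None) r-squared.
    """
    groups = [("all", df)] if grouping is None else list(df.groupby(grouping))
    out = []
    for label, sub in groups:
        if len(sub) < 3:
            warnings.warn(f"group {label!r} has {len(sub)} members (<3); skipped")
            continue
        for x, y in pairs:
            if x not in sub.columns or y not in sub.columns:
                continue
            xy = sub[[x, y]].dropna()
            if len(xy) < 3 or xy[x].nunique() == 1 or xy[y].nunique() == 1:
                out.append(CorrelationSummary(str(label), (x, y), None, len(xy)))
                continue
            r, _ = stats.pearsonr(xy[x], xy[y])
            out.append(CorrelationSummary(str(label), (x, y), float(r * r), len(xy)))
    return out
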