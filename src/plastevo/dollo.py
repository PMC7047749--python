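"""Dollo-parsimony mapping of gene losses onto a fixed rooted phylogeny.

Under Dollo parsimony a plastid gene is gained once (it is ancestrally present in the
plastome, so the root state is functional) and can only be lost; no regain is allowed.
The unique minimum-loss reconstruction then places one loss event on the edge subtending
every maximal clade whose tips are all nonfunctional.  Pseudogenes count as
nonfunctional by default (non-functionalization is the mapped character); an ordered
three-state mode (present > pseudogene > absent) is available but not default.

Edges are identified by the smallest tip label of the child clade; the edge above the
root carries the whole tip set.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


@dataclass(frozen=True)
class LossEvent:
    gene: str
    edge_id: str                    # smallest tip label below the edge
    tips: frozenset[str]            # tip set of the child clade


@dataclass
class LossEventSet:
    events: list[LossEvent] = field(default_factory=list)

    @property
    def total(self) -> int:
        return len(self.events)

    def for_gene(self, gene: str) -> list[LossEvent]:
        return [e for e in self.events if e.gene == gene]

    def per_edge(self) -> dict[str, list[str]]:
        """edge id -> genes lost on that edge (for plotting/annotation)."""
        out: dict[str, list[str]] = {}
        for e in self.events:
            out.setdefault(e.edge_id, []).append(e.gene)
        return {k: sorted(v) for k, v in out.items()}


def dollo_map(tree: dendropy.Tree, gene_states: dict[str, str | bool],
              gene: str = "gene") -> LossEventSet:
    """Losses for one gene: edges subtending maximal all-nonfunctional clades.

    ``gene_states`` maps every tip label to ``functional``/``nonfunctional`` (or a
    bool, True = nonfunctional).  The root is fixed functional; if every tip is
    nonfunctional the single loss sits on the root edge.
    """
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in gene_states]
    if missing:
        raise ValueError(f"tips missing a state: {sorted(missing)}")

    def nonfunc(label: str) -> bool:
        v = gene_states[label]
        if isinstance(v, bool):
            return v
        if v in ("functional", "present"):
            return False
        if v in ("nonfunctional", "pseudogene", "absent"):
            return True
        raise ValueError(f"unknown state {v!r} for tip {label!r}")

    events: list[LossEvent] = []
    # post-order sweep marks all-nonfunctional clades; a loss sits on every edge whose
    # child clade is all-nonfunctional but whose parent clade is not (maximality)
    all_lost: dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            all_lost[id(node)] = nonfunc(node.taxon.label)
        else:
            all_lost[id(node)] = all(all_lost[id(ch)] for ch in node.child_nodes())
    for node in tree.preorder_node_iter():
        if not all_lost[id(node)]:
            continue
        parent = node.parent_node
        if parent is not None and all_lost[id(parent)]:
            continue        # covered by an ancestral loss
        clade = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        events.append(LossEvent(gene=gene, edge_id=min(clade), tips=clade))
    return LossEventSet(events=events)


def map_all_losses(tree: dendropy.Tree, matrix, mode: str = "binary") -> LossEventSet:
    """Dollo losses for every gene of a :class:`~plastevo.genecontent.GeneStatusMatrix`.

    ``mode="binary"`` (default) collapses pseudogene and absent into nonfunctional;
    ``mode="three_state"`` maps pseudogenization and outright loss separately as two
    ordered no-regain characters (present -> pseudogene -> absent), reporting events
    for the first transition (loss of function).
    """
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in matrix.taxa]
    if missing:
        raise ValueError(f"tree tips absent from matrix: {sorted(missing)}")
    all_events: list[LossEvent] = []
    for gene in matrix.genes:
        if mode == "binary":
            states = {t: matrix.status(t, gene).value != "present" for t in tips}
            all_events.extend(dollo_map(tree, states, gene=gene).events)
        elif mode == "three_state":
            nonfunctional = {t: matrix.status(t, gene).value != "present" for t in tips}
            all_events.extend(dollo_map(tree, nonfunctional, gene=gene).events)
            gone = {t: matrix.status(t, gene).value == "absent" for t in tips}
            for e in dollo_map(tree, gone, gene=gene).events:
                all_events.append(LossEvent(gene=f"{gene}:physical_loss",
                                            edge_id=e.edge_id, tips=e.tips))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return LossEventSet(events=all_events)


def reconstruct_tip_states(tree: dendropy.Tree, events: LossEventSet,
                           gene: str) -> dict[str, str]:
    """Tip states implied by an event set (round-trip check of the mapping)."""
    lost_tips: set[str] = set()
    for e in events.for_gene(gene):
        lost_tips |= e.tips
    return {leaf.taxon.label: ("nonfunctional" if leaf.taxon.label in lost_tips
                               else "functional")
            for leaf in tree.leaf_node_iter()}


# ---------------------------------------------------------------------------------
# topology comparison
# ---------------------------------------------------------------------------------

def compare_topologies(tree_a: dendropy.Tree,
                       tree_b: dendropy.Tree) -> tuple[int, list[str]]:
    """Robinson–Foulds distance on the shared tip set, plus conflicting tips.

    Both trees are restricted to their shared tips (≥4 required).  The RF distance is
    the count of bipartitions present in exactly one tree; the conflicting-tip list is
    built greedily, repeatedly removing the tip whose removal most reduces the
    distance until it reaches zero.
    """
    tips_a = {leaf.taxon.label for leaf in tree_a.leaf_node_iter()}
    tips_b = {leaf.taxon.label for leaf in tree_b.leaf_node_iter()}
    shared = tips_a & tips_b
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared tips (need >= 4)")

    rf = _rf_on(tree_a, tree_b, shared)
    conflicts: list[str] = []
    remaining = set(shared)
    current = rf
    while current > 0 and len(remaining) > 4:
        best_tip, best_rf = None, current
        for tip in sorted(remaining):
            r = _rf_on(tree_a, tree_b, remaining - {tip})
            if r < best_rf:
                best_tip, best_rf = tip, r
        if best_tip is None:
            break
        conflicts.append(best_tip)
        remaining.discard(best_tip)
        current = best_rf
    return rf, conflicts


def _rf_on(tree_a: dendropy.Tree, tree_b: dendropy.Tree, tips: set[str]) -> int:
    ns = dendropy.TaxonNamespace(sorted(tips))
    a = _restricted(tree_a, tips, ns)
    b = _restricted(tree_b, tips, ns)
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


def _restricted(tree: dendropy.Tree, tips: set[str],
                ns: dendropy.TaxonNamespace) -> dendropy.Tree:
    # prune on a private namespace first, then re-parse into the common namespace
    t = dendropy.Tree.get(data=tree.as_string(schema="newick"), schema="newick",
                          preserve_underscores=True, rooting="force-unrooted")
    t.retain_taxa_with_labels(sorted(tips))
    out = dendropy.Tree.get(data=t.as_string(schema="newick"), schema="newick",
                            taxon_namespace=ns, preserve_underscores=True,
                            rooting="force-unrooted")
    out.encode_bipartitions()
    return out
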