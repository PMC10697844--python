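"""Duplication-timing classification of gene trees against a species tree.

A node of a rooted gene tree is called a duplication node when the species
sets of (at least) two of its children intersect — the species-overlap
rule, the minimal topology-only criterion (no branch lengths, no
reconciliation costs).  Each duplication is then assigned to the smallest
named ancestral clade (configured on the species tree and ordered by
nesting, e.g. focal species < spiders < spiders+scorpions < arachnids <
spiders+insects) that contains the union of species below the node.
Finally, focal-species paralog pairs are read off each duplication node as
all cross-child gene pairs, so every pair is emitted exactly once, at its
gene-tree MRCA.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

logger = logging.getLogger("scevolink")

UNASSIGNED = "unassigned"


class CladeConfigError(ValueError):
    """Named-clade configuration is inconsistent with the species tree."""


def _read_tree(source, schema: str = "newick") -> dendropy.Tree:
    if isinstance(source, dendropy.Tree):
        return source
    text = str(source)
    if "(" in text:  # newick string
        return dendropy.Tree.get(data=text, schema=schema, preserve_underscores=True)
    return dendropy.Tree.get(path=text, schema=schema, preserve_underscores=True)


@dataclass
class SpeciesTree:
    """Rooted species tree plus an ordered, nested map of named clades."""

    tree: dendropy.Tree
    named_clades: dict  # clade name -> frozenset of species, in nesting order

    def __post_init__(self) -> None:
        self.tree = _read_tree(self.tree)
        clades = {k: frozenset(v) for k, v in self.named_clades.items()}
        names = list(clades)
        for a, b in zip(names, names[1:]):
            if not clades[a] < clades[b]:
                raise CladeConfigError(
                    f"named clades must be strictly nested in order: {a} is not a "
                    f"proper subset of {b}"
                )
        leaves = self.species()
        for name, members in clades.items():
            extra = members - leaves
            if extra:
                logger.warning(
                    "clade %s names species absent from the species tree: %s",
                    name, sorted(extra),
                )
        self.named_clades = clades

    def species(self) -> frozenset:
        return frozenset(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def clade_node(self, name: str):
        """The species-tree node whose leaf set equals the named clade, if any."""
        members = self.named_clades[name] & self.species()
        if not members:
            raise CladeConfigError(f"clade {name} has no species in the tree")
        if len(members) == 1:
            (only,) = members
            for lf in self.tree.leaf_node_iter():
                if lf.taxon.label == only:
                    return lf
            raise CladeConfigError(f"species {only} not found")
        node = self.tree.mrca(taxon_labels=sorted(members))
        return node

    @classmethod
    def from_files(cls, newick_path, clades_path) -> "SpeciesTree":
        return cls(_read_tree(newick_path), read_clade_config(clades_path))


def read_clade_config(path) -> dict:
    """Parse an ordered 'name: sp1,sp2,...' clade config file."""
    clades: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, members = line.partition(":")
        clades[name.strip()] = frozenset(s.strip() for s in members.split(",") if s.strip())
    if not clades:
        raise CladeConfigError(f"no clades found in {path}")
    return clades


@dataclass
class GeneTree:
    """Rooted gene tree with leaf labels '<SPECIES><delimiter><gene_id>'."""

    tree: dendropy.Tree
    delimiter: str = "|"

    def __post_init__(self) -> None:
        self.tree = _read_tree(self.tree)
        if sum(1 for _ in self.tree.leaf_node_iter()) < 2:
            raise ValueError("gene tree needs >= 2 leaves")

    def leaf_species(self, leaf) -> str:
        return leaf.taxon.label.split(self.delimiter, 1)[0]

    def leaf_gene(self, leaf) -> str:
        label = leaf.taxon.label
        if self.delimiter not in label:
            raise ValueError(f"leaf label {label!r} lacks delimiter {self.delimiter!r}")
        return label.split(self.delimiter, 1)[1]

    def species(self) -> frozenset:
        return frozenset(self.leaf_species(lf) for lf in self.tree.leaf_node_iter())

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, text: str, delimiter: str = "|") -> "GeneTree":
        return cls(_read_tree(text), delimiter)


def read_gene_trees(path, delimiter: str = "|") -> list:
    """Read one-or-more newick gene trees (one per line or a tree list)."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick", preserve_underscores=True)
    return [GeneTree(t, delimiter) for t in trees]


@dataclass
class DupEvent:
    """A classified duplication node with its focal-species paralog pairs."""

    node: object
    species_union: frozenset
    scenario: str
    paralog_pairs: list = field(default_factory=list)


def _species_sets(gt: GeneTree) -> dict:
    """Postorder species set per node."""
    out: dict = {}
    for node in gt.tree.postorder_node_iter():
        if node.is_leaf():
            out[node] = frozenset({gt.leaf_species(node)})
        else:
            s = frozenset()
            for ch in node.child_nodes():
                s |= out[ch]
            out[node] = s
    return out


def detect_duplication_nodes(gt: GeneTree) -> list:
    """Internal nodes whose children's species sets overlap (species-overlap rule).

    Multifurcating nodes are flagged if any pair of children shares a
    species; the pairs involved are handled during pair extraction rather
    than by arbitrary binarization.
    """
    sets = _species_sets(gt)
    dups = []
    for node in gt.tree.preorder_internal_node_iter():
        children = node.child_nodes()
        if len(children) > 2:
            logger.warning("non-binary node with %d children; treating child pairs "
                           "sharing species as one event", len(children))
        for a, b in itertools.combinations(children, 2):
            if sets[a] & sets[b]:
                dups.append(node)
                break
    return dups


def assign_scenario(species_union, named_clades: dict) -> str:
    """Smallest configured clade (in nesting order) containing the union."""
    for name, members in named_clades.items():
        if species_union <= members:
            return name
    return UNASSIGNED


def classify_duplications(
    gt: GeneTree, st: SpeciesTree, focal: str, require_focal: bool = True,
) -> list:
    """Classify every duplication node of ``gt`` into a named ancestral scenario.

    For each duplication node, ``species_union`` is the set of species below
    it and the scenario is the smallest named clade containing that union
    (``unassigned`` when none does — e.g. a species missing from every
    configured clade, reported with a warning).  By default only events
    whose descendants include the focal species are returned.
    """
    sets = _species_sets(gt)
    unknown = gt.species() - frozenset().union(*st.named_clades.values())
    if unknown:
        logger.warning("gene-tree species absent from every named clade: %s", sorted(unknown))
    events = []
    for node in detect_duplication_nodes(gt):
        union = sets[node]
        if require_focal and focal not in union:
            continue
        events.append(DupEvent(node, union, assign_scenario(union, st.named_clades)))
    return events


def extract_paralog_pairs(events, gt: GeneTree, focal: str) -> list:
    """Focal-species paralog pairs per duplication event.

    At each duplication node, every pair of children whose species sets
    intersect contributes the cross product of the focal-species genes in
    the two children.  A pair's gene-tree MRCA is exactly the node it is
    emitted at, so no pair is reported twice across nested duplications.
    Returns a list of (gene_a, gene_b, scenario) with gene_a < gene_b, and
    also fills each event's ``paralog_pairs``.
    """
    sets = _species_sets(gt)
    focal_below: dict = {}
    for node in gt.tree.postorder_node_iter():
        if node.is_leaf():
            focal_below[node] = (
                [gt.leaf_gene(node)] if gt.leaf_species(node) == focal else []
            )
        else:
            genes: list = []
            for ch in node.child_nodes():
                genes.extend(focal_below[ch])
            focal_below[node] = genes

    out = []
    for ev in events:
        ev.paralog_pairs = []
        children = ev.node.child_nodes()
        for a, b in itertools.combinations(children, 2):
            if not (sets[a] & sets[b]):
                continue
            for ga in focal_below[a]:
                for gb in focal_below[b]:
                    pair = tuple(sorted((ga, gb)))
                    ev.paralog_pairs.append(pair)
                    out.append((pair[0], pair[1], ev.scenario))
    return out


# Default desk-scale taxon set: focal sheet-web spider, a burrowing spider,
# a scorpion, a mite, and two insects.  H3 keeps its spider+scorpion meaning
# through the configurable clade list.
DEFAULT_SPECIES_NEWICK = "((((Hgra,Aka),Cscu),Ture),(Dmel,Amel));"
DEFAULT_CLADES = {
    "H1": frozenset({"Hgra"}),
    "H2": frozenset({"Hgra", "Aka"}),
    "H3": frozenset({"Hgra", "Aka", "Cscu"}),
    "H4": frozenset({"Hgra", "Aka", "Cscu", "Ture"}),
    "H5": frozenset({"Hgra", "Aka", "Cscu", "Ture", "Dmel", "Amel"}),
}
DEFAULT_FOCAL = "Hgra"


def default_species_tree() -> SpeciesTree:
    return SpeciesTree(DEFAULT_SPECIES_NEWICK, dict(DEFAULT_CLADES))
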