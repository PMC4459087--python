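"""Chronograms: time-calibrated trees, and the packaged aquatic-bird fixture.

A :class:`Chronogram` wraps a rooted dendropy tree whose edge lengths are in
millions of years (MY).  It is ultrametric in time: every tip sits at age 0
and each internal node's age is its time distance to any descendant tip.

The reference fixture is a 17-taxon aquatic-bird chronogram: six flamingos
(two genera of three species), two grebes, and nine outgroup waterbirds
(penguin, tubenose, tropicbird, frigatebird, gannet, cormorant, anhinga,
pelican, hamerkop).  Anchored node ages: the youngest split
(Phoenicoparrus jamesi-P. andinus) at 0.5 MY, crown flamingos at 4.4 MY,
the seven fossil-calibrated splits at their calibration minima (with the
penguin-tubenose divergence at 62 MY, just above its 60.5 MY minimum), and
the remaining uncalibrated nodes interpolated between those anchors.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import dendropy

__all__ = [
    "Chronogram",
    "make_reference_chronogram",
    "FLAMINGOS",
    "GREBES",
    "OUTGROUP_PRIORITY",
    "ALL_TAXA",
    "NODE_CLADES",
    "YOUNG_NODE",
    "OLD_NODE",
    "REFERENCE_NEWICK",
]

FLAMINGOS = (
    "Phoenicopterus_ruber",
    "Phoenicopterus_roseus",
    "Phoenicopterus_chilensis",
    "Phoenicoparrus_minor",
    "Phoenicoparrus_jamesi",
    "Phoenicoparrus_andinus",
)
GREBES = ("Podiceps_cristatus", "Tachybaptus_ruficollis")

# Non-flamingo taxa in the order they are retained when a run keeps only the
# first k "outgroups" (grebes first: they carry the two youngest calibrations).
OUTGROUP_PRIORITY = GREBES + (
    "Spheniscus_humboldti",
    "Procellaria_aequinoctialis",
    "Fregata_minor",
    "Sula_leucogaster",
    "Pelecanus_occidentalis",
    "Scopus_umbretta",
    "Anhinga_melanogaster",
    "Phalacrocorax_auritus",
    "Phaethon_lepturus",
)
ALL_TAXA = FLAMINGOS + OUTGROUP_PRIORITY

# Branch lengths encode the anchored ages listed in the module docstring.
REFERENCE_NEWICK = (
    "((Phaethon_lepturus:40.0,"
    "(((Phoenicopterus_ruber:2.5,(Phoenicopterus_roseus:1.5,Phoenicopterus_chilensis:1.5):1.0):1.9,"
    "(Phoenicoparrus_minor:3.0,(Phoenicoparrus_jamesi:0.5,Phoenicoparrus_andinus:0.5):2.5):1.4):28.2,"
    "(Podiceps_cristatus:8.7,Tachybaptus_ruficollis:8.7):23.9):7.4):24.0,"
    "((Spheniscus_humboldti:62.0,Procellaria_aequinoctialis:62.0):1.0,"
    "((Pelecanus_occidentalis:28.3,Scopus_umbretta:28.3):24.7,"
    "(Fregata_minor:51.8,(Sula_leucogaster:33.0,"
    "(Phalacrocorax_auritus:23.0,Anhinga_melanogaster:23.0):10.0):18.8):1.2):10.0):1.0);"
)


def _c(*taxa: str) -> frozenset:
    return frozenset(taxa)


#: Named internal nodes of the reference fixture, keyed by their taxon clade.
NODE_CLADES: dict[str, frozenset] = {
    "jamesi_andinus": _c("Phoenicoparrus_jamesi", "Phoenicoparrus_andinus"),
    "roseus_chilensis": _c("Phoenicopterus_roseus", "Phoenicopterus_chilensis"),
    "crown_Phoenicopterus": _c(*FLAMINGOS[:3]),
    "crown_Phoenicoparrus": _c(*FLAMINGOS[3:]),
    "crown_Phoenicopteridae": _c(*FLAMINGOS),
    "crown_Podicipedidae": _c(*GREBES),
    "crown_Mirandornithes": _c(*FLAMINGOS, *GREBES),
    "Phaethontidae_Mirandornithes": _c(*FLAMINGOS, *GREBES, "Phaethon_lepturus"),
    "divergence_Sphenisciformes_Procellariiformes": _c(
        "Spheniscus_humboldti", "Procellaria_aequinoctialis"
    ),
    "stem_Anhingidae": _c("Anhinga_melanogaster", "Phalacrocorax_auritus"),
    "stem_Sulidae": _c("Sula_leucogaster", "Anhinga_melanogaster", "Phalacrocorax_auritus"),
    "stem_Fregatidae": _c(
        "Fregata_minor", "Sula_leucogaster", "Anhinga_melanogaster", "Phalacrocorax_auritus"
    ),
    "stem_Pelecanidae": _c("Pelecanus_occidentalis", "Scopus_umbretta"),
    "core_waterbirds": _c(
        "Pelecanus_occidentalis",
        "Scopus_umbretta",
        "Fregata_minor",
        "Sula_leucogaster",
        "Anhinga_melanogaster",
        "Phalacrocorax_auritus",
    ),
    "crown_Aequornithes": _c(
        "Spheniscus_humboldti",
        "Procellaria_aequinoctialis",
        "Pelecanus_occidentalis",
        "Scopus_umbretta",
        "Fregata_minor",
        "Sula_leucogaster",
        "Anhinga_melanogaster",
        "Phalacrocorax_auritus",
    ),
    "root": _c(*ALL_TAXA),
}

#: Representative young and old nodes used in the sensitivity summaries.
YOUNG_NODE = "crown_Phoenicopteridae"
OLD_NODE = "divergence_Sphenisciformes_Procellariiformes"

_AGE_TOL = 1e-6


class Chronogram:
    """A rooted tree with taxon labels and (optionally) node ages in MY.

    Wraps a :class:`dendropy.Tree`.  If every edge has a length, node ages
    are computed from tip depths and the tree must be ultrametric to within
    1e-6 MY; a bare topology (no lengths) is also accepted, with ages left
    undefined -- the dating engine only needs the topology.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.tree.is_rooted = True
        self._index_clades()
        self._compute_ages()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Chronogram":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises schema-specific errors
            raise ValueError(f"malformed newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_newick_path(cls, path) -> "Chronogram":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- internals --------------------------------------------------------

    def _index_clades(self) -> None:
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node.clade = frozenset({node.taxon.label})
            else:
                node.clade = frozenset().union(*(c.clade for c in node.child_nodes()))

    def _compute_ages(self) -> None:
        lengths = [e.length for e in self.tree.preorder_edge_iter() if e.head_node.parent_node]
        self.has_ages = all(l is not None for l in lengths) and len(lengths) > 0
        if not self.has_ages:
            for node in self.tree:
                node.age = None
            return
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node.age = 0.0
                continue
            ages = [c.age + c.edge.length for c in node.child_nodes()]
            if max(ages) - min(ages) > _AGE_TOL:
                raise ValueError(
                    f"tree is not ultrametric at clade {sorted(node.clade)[:3]}...: "
                    f"child depths {ages}"
                )
            node.age = float(ages[0])

    # -- queries ----------------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def root(self):
        return self.tree.seed_node

    @property
    def root_age(self) -> Optional[float]:
        return self.root.age

    def mrca(self, labels: Iterable[str]):
        labels = list(labels)
        missing = set(labels) - set(self.taxa)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        node = self.tree.mrca(taxon_labels=labels)
        if node is None:
            raise ValueError(f"no MRCA found for {labels}")
        return node

    def age_of(self, labels: Iterable[str]) -> float:
        return self.mrca(labels).age

    def internal_nodes(self):
        """(clade, age, node) triples for internal nodes, postorder."""
        return [
            (n.clade, n.age, n)
            for n in self.tree.postorder_internal_node_iter()
        ]

    def is_monophyletic(self, labels: Iterable[str]) -> bool:
        labels = frozenset(labels)
        return self.mrca(labels).clade == labels

    # -- manipulation -----------------------------------------------------

    def prune_to(self, keep: Sequence[str]) -> "Chronogram":
        keep = list(keep)
        missing = set(keep) - set(self.taxa)
        if missing:
            raise KeyError(f"cannot keep unknown taxa: {sorted(missing)}")
        sub = self.tree.extract_tree_with_taxa_labels(labels=keep)
        return Chronogram(sub)

    def scaled(self, factor: float) -> "Chronogram":
        """A copy with every branch length (hence every age) multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        clone = self.tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return Chronogram(clone)

    # -- output -----------------------------------------------------------

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        ).strip()


def make_reference_chronogram(seed: int = 0) -> Chronogram:
    """The packaged 17-taxon aquatic-bird fixture.

    The fixture is fully deterministic; ``seed`` is accepted for interface
    uniformity with the other generators and does not alter the anchored
    ages (the truth the rest of the pipeline is judged against).
    """
    return Chronogram.from_newick(REFERENCE_NEWICK)


def node_label_for(clade: frozenset) -> Optional[str]:
    """Name of a reference node whose full clade is ``clade``, if any."""
    for label, full in NODE_CLADES.items():
        if full == clade:
            return label
    return None
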