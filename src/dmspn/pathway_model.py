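"""Metabolic pathway definitions and their conversion to enzyme graphs.

A metabolic pathway is modelled as a list of reactions, each carrying
substrate and product compound identifiers and the EC numbers of the
enzymes that catalyse it.  For network analysis every pathway is reduced
to an undirected graph whose nodes are enzymes (EC numbers): two enzymes
are adjacent when they act on the same reaction, or when a compound
produced by one is consumed by the other.  Ubiquitous "currency"
compounds (ATP, H2O, ...) can optionally be blacklisted so that they do
not create edges.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping
from xml.etree import ElementTree

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Reaction:
    """One reaction: substrates -> products, catalysed by `enzymes`."""

    reaction_id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    enzymes: tuple[str, ...]
    reversible: bool = False


@dataclass
class PathwayDefinition:
    """A pathway: its reactions, the enzymes they reference, and a class label.

    `class_label` is the pathway's metabolism category (e.g. "lipid
    metabolism"); subpathways mined from this pathway inherit it.
    """

    pathway_id: str
    name: str = ""
    reactions: list[Reaction] = field(default_factory=list)
    class_label: str = ""

    @property
    def enzymes(self) -> frozenset[str]:
        return frozenset(ec for r in self.reactions for ec in r.enzymes)


@dataclass(frozen=True)
class EnzymeGraph:
    """Undirected enzyme graph of one pathway; edges stored as sorted pairs."""

    pathway_id: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u > v:
                raise ValueError(f"edge ({u!r}, {v!r}) not canonically ordered")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge endpoint outside node set: ({u!r}, {v!r})")


class GeneAnnotationMap:
    """Bidirectional mapping between gene IDs and the EC numbers they encode."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()) -> None:
        self._gene_to_ecs: dict[str, set[str]] = {}
        self._ec_to_genes: dict[str, set[str]] = {}
        for gene, ec in pairs:
            self.add(gene, ec)

    def add(self, gene: str, ec: str) -> None:
        if not gene or not ec:
            raise ValueError("gene and EC must be nonempty")
        self._gene_to_ecs.setdefault(gene, set()).add(ec)
        self._ec_to_genes.setdefault(ec, set()).add(gene)

    def ecs_of(self, gene: str) -> frozenset[str]:
        return frozenset(self._gene_to_ecs.get(gene, ()))

    def genes_of(self, ec: str) -> frozenset[str]:
        return frozenset(self._ec_to_genes.get(ec, ()))

    def genes_of_enzymes(self, ecs: Iterable[str]) -> frozenset[str]:
        out: set[str] = set()
        for ec in ecs:
            out |= self._ec_to_genes.get(ec, set())
        return frozenset(out)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._gene_to_ecs)

    @property
    def enzymes(self) -> frozenset[str]:
        return frozenset(self._ec_to_genes)

    def n_pairs(self) -> int:
        return sum(len(v) for v in self._gene_to_ecs.values())

    def items(self) -> Iterable[tuple[str, str]]:
        for gene in sorted(self._gene_to_ecs):
            for ec in sorted(self._gene_to_ecs[gene]):
                yield gene, ec

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneAnnotationMap):
            return NotImplemented
        return self._gene_to_ecs == other._gene_to_ecs


def parse_kgml(file_path: str | Path, class_label: str = "") -> PathwayDefinition:
    """Parse a KGML pathway file into a :class:`PathwayDefinition`.

    Enzymes of a reaction are resolved through ``entry`` elements of type
    ``enzyme`` whose ``reaction`` attribute names the reaction; EC numbers
    are read from the entry ``name`` (an ``ec:`` prefix is stripped).
    Reversibility comes from the reaction ``type`` attribute.  A file
    without enzyme entries yields an empty definition with a warning.
    """
    file_path = Path(file_path)
    try:
        tree = ElementTree.parse(file_path)
    except ElementTree.ParseError as exc:
        raise ValueError(f"malformed KGML in {file_path}: {exc}") from exc
    root = tree.getroot()
    pathway_id = root.get("name", root.get("number", file_path.stem))
    name = root.get("title", "")

    # reaction name -> ECs, via enzyme entries
    rxn_enzymes: dict[str, set[str]] = {}
    n_enzyme_entries = 0
    for entry in root.iter("entry"):
        if entry.get("type") != "enzyme":
            continue
        n_enzyme_entries += 1
        ecs = {tok.removeprefix("ec:") for tok in entry.get("name", "").split() if tok}
        for rxn in entry.get("reaction", "").split():
            rxn_enzymes.setdefault(rxn, set()).update(ecs)
    if n_enzyme_entries == 0:
        log.warning("%s: no enzyme entries; pathway will be empty", file_path)

    reactions: list[Reaction] = []
    for rxn in root.iter("reaction"):
        rid = rxn.get("name", "")
        ecs = rxn_enzymes.get(rid, set())
        if not ecs:
            continue
        subs = tuple(s.get("name", "") for s in rxn.findall("substrate"))
        prods = tuple(p.get("name", "") for p in rxn.findall("product"))
        reactions.append(
            Reaction(
                reaction_id=rid,
                substrates=subs,
                products=prods,
                enzymes=tuple(sorted(ecs)),
                reversible=rxn.get("type", "irreversible") == "reversible",
            )
        )
    return PathwayDefinition(
        pathway_id=pathway_id, name=name, reactions=reactions, class_label=class_label
    )


def build_enzyme_graph(
    pw: PathwayDefinition, currency_blacklist: Iterable[str] = ()
) -> EnzymeGraph:
    """Convert a pathway to its undirected enzyme graph.

    Two enzymes A != B are adjacent iff they appear on the same reaction,
    or some non-blacklisted compound is produced by a reaction of A and
    consumed by a reaction of B (either direction; reversible reactions
    contribute both orientations).
    """
    blacklist = set(currency_blacklist)
    edges: set[tuple[str, str]] = set()

    def _add(a: str, b: str) -> None:
        if a != b:
            edges.add((a, b) if a < b else (b, a))

    # rule (i): co-catalysis of one reaction
    for r in pw.reactions:
        for a, b in itertools.combinations(r.enzymes, 2):
            _add(a, b)

    # rule (ii): compound handoff, product of one reaction = substrate of another
    produces: dict[str, set[str]] = {}  # compound -> enzymes producing it
    consumes: dict[str, set[str]] = {}  # compound -> enzymes consuming it
    for r in pw.reactions:
        subs, prods = set(r.substrates), set(r.products)
        if r.reversible:
            subs, prods = subs | prods, subs | prods
        for c in prods - blacklist:
            produces.setdefault(c, set()).update(r.enzymes)
        for c in subs - blacklist:
            consumes.setdefault(c, set()).update(r.enzymes)
    for c, producers in produces.items():
        for a in producers:
            for b in consumes.get(c, ()):
                _add(a, b)

    return EnzymeGraph(
        pathway_id=pw.pathway_id, nodes=frozenset(pw.enzymes), edges=frozenset(edges)
    )


def load_gene_annotations(file_path: str | Path) -> GeneAnnotationMap:
    """Read a two-column TSV (gene ID, EC number) into a GeneAnnotationMap.

    Lines starting with '#' are comments; rows with a missing field are
    rejected and counted in the log; duplicate rows collapse.
    """
    ann = GeneAnnotationMap()
    n_rejected = 0
    with open(file_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                n_rejected += 1
                continue
            ann.add(parts[0], parts[1])
    if n_rejected:
        log.warning("%s: rejected %d malformed rows", file_path, n_rejected)
    return ann


def load_compound_blacklist(file_path: str | Path) -> frozenset[str]:
    """Read a one-column list of currency compound IDs.

    Full-line and trailing '#' comments are allowed; only the first
    whitespace-separated token of each line is kept.
    """
    out: set[str] = set()
    with open(file_path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line.split()[0])
    return frozenset(out)


def default_currency_blacklist() -> frozenset[str]:
    """The shipped starter list of ATP/NAD(P)H/H2O-class compound IDs."""
    from importlib import resources

    ref = resources.files("dmspn").joinpath("data/currency_metabolites.txt")
    with resources.as_file(ref) as path:
        return load_compound_blacklist(path)


def annotation_from_mapping(gene_to_ecs: Mapping[str, Iterable[str]]) -> GeneAnnotationMap:
    """Build a GeneAnnotationMap from a gene -> ECs mapping."""
    return GeneAnnotationMap(
        (g, ec) for g, ecs in gene_to_ecs.items() for ec in ecs
    )
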