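"""Foreground branch/clade labeling.

Users define the lineages of interest as named species sets in a TSV file
(name, token, comma-separated species).  The token follows CodeML's tree
dialect: ``#k`` marks the stem branch of the set's MRCA, ``$k`` marks the
whole clade (every branch of the MRCA subtree, stem included) as one rate
class.  Because node identity is given by species content, the same scheme
annotates every per-gene tree automatically — including pruned trees of
nonubiquitous genes, where the label is re-derived from the surviving
species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .trees import Node, Phylogeny, _LABEL_RE


class LabelingError(ValueError):
    pass


@dataclass(frozen=True)
class CladeDefinition:
    name: str
    token: str  # "#k" (branch) or "$k" (clade)
    species: frozenset[str]

    def __post_init__(self) -> None:
        if not _LABEL_RE.match(self.token):
            raise LabelingError(f"{self.name}: malformed label token {self.token!r}")
        if not self.species:
            raise LabelingError(f"{self.name}: empty species set")

    @property
    def is_clade_token(self) -> bool:
        return self.token.startswith("$")


@dataclass
class LabelScheme:
    definitions: list[CladeDefinition]

    def __post_init__(self) -> None:
        names = [d.name for d in self.definitions]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise LabelingError(f"duplicate definition names: {dup}")

    def __iter__(self):
        return iter(self.definitions)

    def __len__(self) -> int:
        return len(self.definitions)


@dataclass
class MonophylyReport:
    """Definitions whose present species are not monophyletic in a given
    tree (labeled at the MRCA anyway, but loudly flagged), and definitions
    skipped because none of their species survive in the tree."""

    non_monophyletic: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)


def parse_label_scheme(text: str, tree_taxa: frozenset[str] | None = None) -> LabelScheme:
    """Parse the three-column TSV (name, token, comma-separated species).

    Unknown species (vs the species tree) and malformed tokens are fatal,
    reported with the line number.  Tokens may repeat across definitions:
    several clades can share one rate class.
    """
    definitions: list[CladeDefinition] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#!") or line.startswith("//"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) != 3:
            raise LabelingError(f"line {lineno}: expected 3 tab-separated columns, got {len(parts)}")
        name, token, species_csv = parts
        if not _LABEL_RE.match(token):
            raise LabelingError(f"line {lineno}: malformed label token {token!r}")
        species = frozenset(s.strip() for s in species_csv.split(",") if s.strip())
        if not species:
            raise LabelingError(f"line {lineno}: no species listed")
        if tree_taxa is not None:
            unknown = species - tree_taxa
            if unknown:
                raise LabelingError(
                    f"line {lineno}: species not in the species tree: {sorted(unknown)}"
                )
        definitions.append(CladeDefinition(name=name, token=token, species=species))
    if not definitions:
        raise LabelingError("label scheme contains no definitions")
    return LabelScheme(definitions)


def mrca_edge(tree: Phylogeny, species: frozenset[str] | set[str]) -> Node:
    """Node whose descendant leaf set is the minimal superset of ``species``.

    A singleton set resolves to the leaf itself (its terminal branch).
    """
    species = frozenset(species)
    missing = species - tree.leaf_names
    if missing:
        raise LabelingError(f"species not in tree: {sorted(missing)}")
    sets = tree.descendant_leaf_sets()
    best: Node | None = None
    best_size = None
    for node in tree.postorder():
        leafset = sets[id(node)]
        if species <= leafset and (best_size is None or len(leafset) < best_size):
            best, best_size = node, len(leafset)
    assert best is not None  # the root always contains the set
    return best


def annotate(tree: Phylogeny, scheme: LabelScheme) -> tuple[Phylogeny, MonophylyReport]:
    """Place each definition's token on the MRCA of its species present in
    this tree.  Returns a labeled copy plus a monophyly report."""
    labeled = tree.copy()
    report = MonophylyReport()
    sets = labeled.descendant_leaf_sets()
    for defn in scheme:
        present = defn.species & labeled.leaf_names
        if not present:
            report.skipped.append(defn.name)
            continue
        node = mrca_edge(labeled, present)
        if sets[id(node)] != present:
            report.non_monophyletic.append(defn.name)
        node.label = defn.token
    return labeled, report
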