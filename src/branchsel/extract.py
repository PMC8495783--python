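"""The extract stage: match branches/clades across taxon-incomplete gene
trees and assemble per-clade dN/dS, dN, dS tables.

A branch or clade of interest is defined by its species set.  In a gene
missing some taxa the "same" branch can still exist; two inclusion
policies are offered:

* **Mode A** — every species of the definition must be present in the
  gene, and they must form exactly one branch of the gene tree (genes may
  lack species *external* to the clade only).
* **Mode B** — species *inside* the clade may also be missing, subject to
  a threshold: a proportion (< 1, e.g. 0.8 ⇒ at least 80% of the clade's
  species present, rounded up) or an absolute minimum count (≥ 1).

In both modes the present species must be the exact leaf set of some edge
of the gene tree (monophyly in that gene); otherwise the gene is reported
unmatched with its reason rather than silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .codeml_io import BranchMetrics, ModelFit
from .labeling import CladeDefinition
from .trees import Phylogeny


class ExtractError(ValueError):
    pass


@dataclass(frozen=True)
class ExtractConfig:
    mode: str = "A"  # "A" | "B"
    threshold: float = 1.0  # <1: proportion of clade species; >=1: absolute count
    require_monophyly: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("A", "B"):
            raise ExtractError(f"mode must be 'A' or 'B', got {self.mode!r}")
        if self.mode == "B":
            if self.threshold <= 0:
                raise ExtractError("threshold must be positive")
            if self.threshold >= 1 and self.threshold != int(self.threshold):
                raise ExtractError("absolute-count threshold must be an integer")

    def min_present(self, clade_size: int) -> int:
        if self.mode == "A":
            return clade_size
        if self.threshold < 1:
            return math.ceil(self.threshold * clade_size)
        return int(self.threshold)


# reasons for an unmatched gene
BELOW_THRESHOLD = "below-threshold"
NOT_MONOPHYLETIC = "not-monophyletic"
SINGLE_SPECIES_CLADE = "clade-reduced-to-single-species-with-clade-token"
METRICS_MISSING = "metrics-missing"


@dataclass
class MatchResult:
    gene_id: str
    definition: str
    matched: bool
    present_species: frozenset[str]
    matched_leaf_set: frozenset[str] | None = None
    reason: str | None = None


def enumerate_branch_species(tree: Phylogeny) -> dict[frozenset[str], object]:
    """Descendant species set of every edge (leaf edges → singletons)."""
    sets = tree.descendant_leaf_sets()
    return {sets[id(n)]: n for n in tree.preorder() if n.parent is not None}


def match_definition(
    defn: CladeDefinition,
    gene_taxa: frozenset[str],
    gene_tree: Phylogeny,
    cfg: ExtractConfig,
) -> MatchResult:
    """Decide whether a definition's branch/clade exists in one gene."""
    if gene_tree.leaf_names != gene_taxa:
        raise ExtractError(
            f"{defn.name}: gene tree leaves do not equal the gene taxon set"
        )
    present = defn.species & gene_taxa
    base = dict(gene_id="", definition=defn.name, present_species=present)
    if len(present) < cfg.min_present(len(defn.species)):
        return MatchResult(matched=False, reason=BELOW_THRESHOLD, **base)
    if len(present) == 1 and defn.is_clade_token and len(defn.species) > 1:
        # a clade reduced to one surviving species is no clade at all;
        # a '#' branch definition still matches the terminal branch
        return MatchResult(matched=False, reason=SINGLE_SPECIES_CLADE, **base)
    edge_sets = {s for s in enumerate_branch_species(gene_tree)}
    if present not in edge_sets:
        return MatchResult(matched=False, reason=NOT_MONOPHYLETIC, **base)
    return MatchResult(matched=True, matched_leaf_set=present, **base)


AGGREGATE_KEY = "clade-mean"


@dataclass
class MetricRow:
    gene_id: str
    branch: str  # comma-joined leaf set, or the derived aggregate marker
    dnds: float
    dn: float
    ds: float
    derived: bool = False


def _branch_name(leaf_set: frozenset[str]) -> str:
    return ",".join(sorted(leaf_set))


def retrieve_metrics(
    match: MatchResult, defn: CladeDefinition, fit: ModelFit
) -> tuple[list[MetricRow], str | None]:
    """Rows of (dN/dS, dN, dS) for one matched gene.

    '#' definitions yield the single stem-branch row.  '$' definitions
    yield every branch inside the clade plus the stem, plus an unweighted
    mean row explicitly marked as derived.  A fit without the stem row
    (e.g. a site-model output with no branch table) is reported as
    metrics-missing.
    """
    if not match.matched or match.matched_leaf_set is None:
        raise ExtractError(f"{defn.name}/{match.gene_id}: cannot retrieve metrics for an unmatched gene")
    by_key = fit.metrics_by_key()
    target = match.matched_leaf_set
    if target not in by_key:
        return [], METRICS_MISSING

    def row(bm: BranchMetrics) -> MetricRow:
        return MetricRow(
            gene_id=match.gene_id, branch=_branch_name(bm.leaf_set), dnds=bm.dnds, dn=bm.dn, ds=bm.ds
        )

    if not defn.is_clade_token:
        return [row(by_key[target])], None

    clade_rows = [row(bm) for key, bm in sorted(by_key.items(), key=lambda kv: _branch_name(kv[0]))
                  if key <= target]
    mean = MetricRow(
        gene_id=match.gene_id,
        branch=AGGREGATE_KEY,
        dnds=sum(r.dnds for r in clade_rows) / len(clade_rows),
        dn=sum(r.dn for r in clade_rows) / len(clade_rows),
        ds=sum(r.ds for r in clade_rows) / len(clade_rows),
        derived=True,
    )
    return clade_rows + [mean], None


@dataclass
class ExtractTable:
    definition: str
    rows: list[MetricRow] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "branch": r.branch,
                    "dnds": r.dnds,
                    "dn": r.dn,
                    "ds": r.ds,
                    "derived": r.derived,
                }
                for r in self.rows
            ],
            columns=["gene_id", "branch", "dnds", "dn", "ds", "derived"],
        )


def build_tables(
    genes: dict[str, tuple[Phylogeny, ModelFit]],
    definitions: list[CladeDefinition],
    cfg: ExtractConfig,
) -> tuple[dict[str, ExtractTable], pd.DataFrame]:
    """One metric table per definition plus a coverage report.

    ``genes`` maps gene_id → (gene tree, best-fit ModelFit).  Genes that do
    not meet the matching criteria for a definition appear in the coverage
    report with their reason — never silently omitted.
    """
    if not definitions:
        raise ExtractError("no branch/clade definitions supplied")
    if not genes:
        raise ExtractError("no genes to extract from")
    tables = {d.name: ExtractTable(definition=d.name) for d in definitions}
    coverage_rows = []
    for gene_id in sorted(genes):
        tree, fit = genes[gene_id]
        for defn in definitions:
            match = match_definition(defn, tree.leaf_names, tree, cfg)
            match.gene_id = gene_id
            reason = match.reason
            if match.matched:
                rows, reason = retrieve_metrics(match, defn, fit)
                tables[defn.name].rows.extend(rows)
            coverage_rows.append(
                {
                    "gene_id": gene_id,
                    "definition": defn.name,
                    "matched": match.matched and reason is None,
                    "n_present": len(match.present_species),
                    "n_defined": len(defn.species),
                    "reason": reason or "",
                }
            )
    coverage = pd.DataFrame(
        coverage_rows,
        columns=["gene_id", "definition", "matched", "n_present", "n_defined", "reason"],
    )
    return tables, coverage
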