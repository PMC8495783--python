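"""CodeML interoperability: control files, replicate starts, mlc parsing.

Two nested models (the "general" and the "alternative", where the
alternative is the restricted one) are each described by a CodeML control
template.  Per gene and per replicate, the template is rendered with the
gene's paths and a random ω starting value, the model is fitted — by the
external ``codeml`` binary when available, or by the built-in engine — and
the replicate with the best likelihood is kept.

Branch identity in parsed output is keyed by descendant leaf sets, never
by CodeML's volatile node numbers: node numbering differs between pruned
trees, and leaf-set keys are what makes cross-gene matching of branches
possible for nonubiquitous genes.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import engine
from .alignments import CodonAlignment, write_gene_alignment
from .trees import Phylogeny, parse_newick, write_newick

GENERAL = "general"
ALTERNATIVE = "alternative"

OMEGA_START_RANGE = (0.05, 2.0)


class CodemlError(RuntimeError):
    pass


class MlcParseError(CodemlError):
    pass


@dataclass
class ControlTemplate:
    """Key→value CodeML options; seqfile/treefile/outfile (and omega) are
    placeholders filled at render time; everything else passes through."""

    options: dict[str, str]

    REQUIRED = ("seqfile", "treefile", "outfile")

    @classmethod
    def from_text(cls, text: str) -> "ControlTemplate":
        options: dict[str, str] = {}
        for raw in text.splitlines():
            line = raw.split("*", 1)[0].strip()  # '*' starts a CodeML comment
            if not line:
                continue
            if "=" not in line:
                raise CodemlError(f"malformed control line (no '='): {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            options[key] = value
        missing = [k for k in cls.REQUIRED if k not in options]
        if missing:
            raise CodemlError(f"control template lacks required placeholders: {missing}")
        return cls(options=options)

    @property
    def model_code(self) -> str | None:
        return self.options.get("model")

    def engine_model(self) -> str:
        """Map the CodeML 'model' option onto the built-in engine.

        model = 0 → M0 (one ω); model = 2 → branch model (ω per label
        class).  Anything else is pass-through for the external binary only.
        """
        code = (self.model_code or "0").strip()
        if code == "0":
            return "M0"
        if code == "2":
            return "branch"
        raise CodemlError(
            f"built-in engine supports model = 0 (M0) or 2 (branch); got model = {code}"
        )


def render_control(
    template: ControlTemplate,
    seqfile: str | Path,
    treefile: str | Path,
    outfile: str | Path,
    start_omega: float,
) -> str:
    """Render a concrete control file with paths and the replicate's ω start."""
    options = dict(template.options)
    options["seqfile"] = str(seqfile)
    options["treefile"] = str(treefile)
    options["outfile"] = str(outfile)
    options["omega"] = f"{start_omega:g}"
    return "".join(f"{key} = {value}\n" for key, value in options.items())


def draw_start_omegas(n: int, rng: np.random.Generator | int) -> list[float]:
    """n replicate ω starting values, uniform on [0.05, 2.0]."""
    if n < 1:
        raise CodemlError("need at least one replicate")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    lo, hi = OMEGA_START_RANGE
    return [float(x) for x in rng.uniform(lo, hi, size=n)]


@dataclass(frozen=True)
class BranchMetrics:
    """Per-branch estimates keyed by the branch's descendant leaf set."""

    leaf_set: frozenset[str]
    t: float
    dnds: float
    dn: float
    ds: float


@dataclass
class ModelFit:
    gene_id: str
    model_tag: str  # "general" | "alternative"
    lnl: float
    np: int
    branch_metrics: list[BranchMetrics] = field(default_factory=list)
    replicate_index: int = 1
    start_omega: float = float("nan")

    def metrics_by_key(self) -> dict[frozenset[str], BranchMetrics]:
        return {bm.leaf_set: bm for bm in self.branch_metrics}


_LNL_RE = re.compile(r"lnL\(ntime:\s*\d+\s+np:\s*(\d+)\):\s*(-?\d+\.?\d*)")
_BRANCH_ROW_RE = re.compile(r"^\s*(\d+)\.\.(\d+)\s")


def _find_tree_line(text: str, expected_taxa: frozenset[str]) -> Phylogeny | None:
    """A newick line echoed inside the mlc fixes the leaf numbering order;
    node numbering across CodeML versions is otherwise a convention."""
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("(") and line.endswith(";"):
            try:
                tree = parse_newick(line)
            except Exception:
                continue
            if tree.leaf_names == expected_taxa:
                return tree
    return None


def _header_columns(line: str) -> list[str]:
    return line.split()


def parse_mlc(text: str, tree: Phylogeny) -> ModelFit:
    """Parse CodeML main output into a ModelFit.

    Requires the ``lnL(ntime: .. np: ..): value`` line; the per-branch
    table (columns branch, t, dN/dS or w, dN, dS) is optional — site-model
    outputs yield an empty branch_metrics list.  Branch rows ``a..b`` are
    resolved through CodeML node numbering (leaves 1..N in appearance
    order, internals N+1.. preorder) to the descendant leaf set of node b.
    """
    m = _LNL_RE.search(text)
    if not m:
        raise MlcParseError("no lnL line found in CodeML output")
    np_count = int(m.group(1))
    lnl = float(m.group(2))

    numbering_tree = _find_tree_line(text, tree.leaf_names) or tree
    numbering = engine.codeml_numbering(numbering_tree)
    sets = numbering_tree.descendant_leaf_sets()
    number_to_leafset = {numbering[id(n)]: sets[id(n)] for n in numbering_tree.preorder()}

    metrics: list[BranchMetrics] = []
    lines = text.splitlines()
    header_cols: list[str] | None = None
    for line in lines:
        if header_cols is None:
            cols = _header_columns(line)
            if cols and cols[0] == "branch" and "t" in cols and ("dN/dS" in cols or "w" in cols):
                header_cols = cols
            continue
        if not _BRANCH_ROW_RE.match(line):
            if line.strip() and not line.strip()[0].isdigit():
                header_cols = None  # table ended
            continue
        fields = line.split()
        row = dict(zip(header_cols, fields))
        child = int(row["branch"].split("..")[1])
        if child not in number_to_leafset:
            raise MlcParseError(f"branch row references unknown node {child}")
        dnds_col = "dN/dS" if "dN/dS" in row else "w"
        try:
            metrics.append(
                BranchMetrics(
                    leaf_set=number_to_leafset[child],
                    t=float(row["t"]),
                    dnds=float(row[dnds_col]),
                    dn=float(row["dN"]),
                    ds=float(row["dS"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise MlcParseError(f"malformed branch row {line!r}: {exc}") from exc

    gene_id = ""
    return ModelFit(gene_id=gene_id, model_tag="", lnl=lnl, np=np_count, branch_metrics=metrics)


# --- running one gene ----------------------------------------------------


@dataclass
class ReplicateRecord:
    gene_id: str
    model_tag: str
    replicate_index: int
    start_omega: float
    lnl: float | None  # None = replicate failed
    mlc_text: str | None = None


def _run_engine_replicate(
    aln: CodonAlignment,
    tree: Phylogeny,
    template: ControlTemplate,
    start_omega: float,
) -> tuple[engine.EngineFit, str]:
    model = template.engine_model()
    fit = engine.fit(aln, tree, model=model, start_omega=start_omega)
    mlc_tree = tree if model == "branch" else _strip_labels(tree)
    mlc = engine.emulate_codeml_output(fit, mlc_tree, aln.gene_id)
    return fit, mlc


def _strip_labels(tree: Phylogeny) -> Phylogeny:
    bare = tree.copy()
    for node in bare.preorder():
        node.label = None
    return bare


def _run_codeml_replicate(
    aln: CodonAlignment,
    tree: Phylogeny,
    template: ControlTemplate,
    start_omega: float,
    codeml_path: str,
) -> str:
    """Run the external binary in an isolated scratch directory (CodeML
    writes fixed-name files) and return the mlc text."""
    with tempfile.TemporaryDirectory(prefix="codeml_") as tmp:
        tmpdir = Path(tmp)
        seqfile = tmpdir / "gene.fas"
        treefile = tmpdir / "gene.nwk"
        outfile = tmpdir / "gene.mlc"
        write_gene_alignment(aln, seqfile)
        treefile.write_text(write_newick(tree) + "\n")
        ctl = render_control(template, seqfile, treefile, outfile, start_omega)
        (tmpdir / "codeml.ctl").write_text(ctl)
        proc = subprocess.run(
            [codeml_path, "codeml.ctl"],
            cwd=tmpdir,
            capture_output=True,
            text=True,
            timeout=3600,
        )
        if proc.returncode != 0 or not outfile.exists():
            raise CodemlError(
                f"codeml failed for {aln.gene_id} (exit {proc.returncode}): {proc.stderr[-500:]}"
            )
        return outfile.read_text()


def run_gene(
    aln: CodonAlignment,
    tree: Phylogeny,
    templates: dict[str, ControlTemplate],
    n_replicates: int,
    rng: np.random.Generator | int,
    backend: str = "engine",
) -> tuple[ModelFit, ModelFit, list[ReplicateRecord]]:
    """Fit the general and the alternative model with replicate ω starts.

    Returns, per model, the replicate with the maximum log-likelihood
    (ties broken by lowest replicate index) plus the full replicate log.
    All replicates failing for a model is an error; the caller marks the
    gene failed and continues the batch.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if set(templates) != {GENERAL, ALTERNATIVE}:
        raise CodemlError(f"templates must be keyed by {{'general', 'alternative'}}, got {set(templates)}")
    if backend not in ("engine", "codeml"):
        raise CodemlError(f"unknown backend {backend!r}")
    codeml_path = None
    if backend == "codeml":
        codeml_path = shutil.which("codeml")
        if codeml_path is None:
            raise CodemlError("codeml binary not found on PATH (use backend='engine')")

    starts = draw_start_omegas(n_replicates, rng)
    records: list[ReplicateRecord] = []
    best: dict[str, ModelFit] = {}

    for model_tag in (GENERAL, ALTERNATIVE):
        template = templates[model_tag]
        for idx, w0 in enumerate(starts, start=1):
            try:
                if backend == "engine":
                    _, mlc = _run_engine_replicate(aln, tree, template, w0)
                else:
                    mlc = _run_codeml_replicate(aln, tree, template, w0, codeml_path)
                fit = parse_mlc(mlc, tree)
                fit.gene_id = aln.gene_id
                fit.model_tag = model_tag
                fit.replicate_index = idx
                fit.start_omega = w0
            except (CodemlError, engine.EngineError):
                records.append(ReplicateRecord(aln.gene_id, model_tag, idx, w0, None, None))
                continue
            records.append(ReplicateRecord(aln.gene_id, model_tag, idx, w0, fit.lnl, mlc))
            if model_tag not in best or fit.lnl > best[model_tag].lnl:
                best[model_tag] = fit
        if model_tag not in best:
            raise CodemlError(f"all {n_replicates} replicates failed for {aln.gene_id} ({model_tag})")

    return best[GENERAL], best[ALTERNATIVE], records
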