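"""Built-in Goldman–Yang codon-model backend.

Implements the M0 (single-ω) and branch (per-label ω class) codon models
on a fixed tree: rate-matrix construction, pruning-algorithm likelihood,
bounded maximum-likelihood fitting, alignment simulation, and an emulator
that writes CodeML-style main output ("mlc") text.  The backend makes the
whole pipeline runnable and testable without an external CodeML binary and
powers the parameter-recovery and LRT-calibration checks.

Model: 61 sense codons of the standard genetic code; instantaneous rate
between codons i≠j is 0 if they differ at more than one position, else

    q_ij = π_j · κ^[transition] · ω^[nonsynonymous]

with the matrix scaled so the expected substitution rate per unit branch
length is one.  Codon frequencies default to equal (1/61); frequency
estimation (e.g. F3x4) is deliberately out of scope — this is a compact,
well-tested likelihood engine, not a CodeML replacement.  Branch lengths
are taken from the input tree and never re-optimized, so the free
parameters are κ plus one ω per rate class (np = 1 + #classes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .alignments import CodonAlignment, STANDARD_CODE
from .trees import Phylogeny

BACKGROUND = "background"

# --- static codon machinery (standard code, 61 sense codons) -------------

_NUC = "TCAG"
CODONS: list[str] = [
    a + b + c
    for a in _NUC
    for b in _NUC
    for c in _NUC
    if (a + b + c) not in STANDARD_CODE.stop_codons
]
N_STATES = len(CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def _is_transition(x: str, y: str) -> bool:
    return (x in _PURINES and y in _PURINES) or (x in _PYRIMIDINES and y in _PYRIMIDINES)


def _neighbor_arrays() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    ii, jj, ts, ns = [], [], [], []
    aa = STANDARD_CODE.codon_table
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            ii.append(i)
            jj.append(j)
            ts.append(_is_transition(ci[k], cj[k]))
            ns.append(aa[ci] != aa[cj])
    return (
        np.array(ii, dtype=np.intp),
        np.array(jj, dtype=np.intp),
        np.array(ts, dtype=bool),
        np.array(ns, dtype=bool),
    )


_I, _J, _TS, _NS = _neighbor_arrays()

EQUAL_FREQS = np.full(N_STATES, 1.0 / N_STATES)


class EngineError(RuntimeError):
    pass


@dataclass
class CodonModelParams:
    """κ, per-class ω, and equilibrium codon frequencies."""

    kappa: float
    omega_by_class: dict[str, float]
    codon_freqs: np.ndarray = field(default_factory=lambda: EQUAL_FREQS.copy())

    def __post_init__(self) -> None:
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.codon_freqs.shape != (N_STATES,):
            raise EngineError(f"codon_freqs must have length {N_STATES}")
        if np.any(self.codon_freqs < 0) or abs(self.codon_freqs.sum() - 1.0) > 1e-12:
            raise EngineError("codon frequencies must be nonnegative and sum to 1")
        if self.kappa <= 0:
            raise EngineError("kappa must be positive")
        for token, w in self.omega_by_class.items():
            if w < 0:
                raise EngineError(f"omega for class {token!r} must be >= 0")

    def omega_for(self, token: str) -> float:
        if token in self.omega_by_class:
            return self.omega_by_class[token]
        return self.omega_by_class[BACKGROUND]


@dataclass
class EngineFit:
    params: CodonModelParams
    lnl: float
    np: int  # free parameters actually optimized: kappa + one omega per class
    converged: bool


def build_rate_matrix(params: CodonModelParams, class_token: str = BACKGROUND) -> np.ndarray:
    """Scaled GY94 generator for one ω class.

    Entries between codons differing at >1 position are zero; diagonal is
    minus the row sum; the matrix is scaled to an expected rate of one
    substitution per codon per unit branch length.
    """
    omega = params.omega_for(class_token)
    pi = params.codon_freqs
    rates = pi[_J] * np.where(_TS, params.kappa, 1.0) * np.where(_NS, omega, 1.0)
    Q = np.zeros((N_STATES, N_STATES))
    Q[_I, _J] = rates
    Q[np.diag_indices_from(Q)] = -Q.sum(axis=1)
    mu = -float(pi @ np.diag(Q))
    if mu <= 0:
        raise EngineError("degenerate rate matrix (zero expected rate)")
    return Q / mu


def _syn_nonsyn_flux(params: CodonModelParams) -> tuple[float, float]:
    """Unnormalized nonsynonymous (at ω=1) and synonymous flux, (A, B)."""
    pi = params.codon_freqs
    w = pi[_I] * pi[_J] * np.where(_TS, params.kappa, 1.0)
    return float(w[_NS].sum()), float(w[~_NS].sum())


class _ClassMatrices:
    """Eigendecomposition of one class's generator in the π-symmetrized
    basis; transition matrices come from exp of the eigenvalues."""

    def __init__(self, Q: np.ndarray, freqs: np.ndarray):
        d = np.sqrt(freqs)
        S = Q * (d[:, None] / d[None, :])
        S = (S + S.T) / 2.0  # enforce exact symmetry
        self.w, self.U = np.linalg.eigh(S)
        self.d = d

    def pmatrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise EngineError(f"negative branch length {t}")
        E = (self.U * np.exp(self.w * t)) @ self.U.T
        P = E * (self.d[None, :] / self.d[:, None])
        np.clip(P, 0.0, None, out=P)
        return P


def branch_classes(tree: Phylogeny) -> dict[int, str]:
    """Effective ω-class token per branch (keyed by id(child node)).

    A ``#`` token applies only to the stem branch of the node carrying it;
    a ``$`` token applies to every branch of the subtree, stem included,
    unless overridden deeper down (CodeML clade-label semantics).
    Unlabeled branches belong to the background class.
    """
    classes: dict[int, str] = {}

    def walk(node, inherited: str) -> None:
        for child in node.children:
            if child.label is not None:
                token = child.label
            else:
                token = inherited
            classes[id(child)] = token
            # only clade tokens propagate downward
            next_inherited = child.label if (child.label or "").startswith("$") else inherited
            walk(child, next_inherited)

    walk(tree.root, BACKGROUND)
    return classes


def _encode_alignment(aln: CodonAlignment, leaf_order: list[str]) -> np.ndarray:
    """(ntaxa, ncodons) int matrix of codon states; -1 = missing (gap/N)."""
    codes = np.empty((len(leaf_order), aln.n_codons), dtype=np.int64)
    for r, name in enumerate(leaf_order):
        for c, codon in enumerate(aln.codons(name)):
            codes[r, c] = CODON_INDEX.get(codon, -1)
    return codes


def log_likelihood(aln: CodonAlignment, tree: Phylogeny, params: CodonModelParams) -> float:
    """Felsenstein pruning over unique site patterns.

    Gap- or N-containing codons contribute an all-ones conditional vector
    (missing data).  Per-node rescaling guards against underflow.
    """
    leaves = tree.leaves()
    leaf_order = [lf.name for lf in leaves]
    missing = set(leaf_order) - set(aln.sequences)
    if missing:
        raise EngineError(f"alignment lacks sequences for tree taxa: {sorted(missing)}")
    if aln.n_codons == 0:
        return 0.0

    codes = _encode_alignment(aln, leaf_order)
    patterns, counts = np.unique(codes, axis=1, return_counts=True)
    npat = patterns.shape[1]

    classes = branch_classes(tree)
    eig = {
        token: _ClassMatrices(build_rate_matrix(params, token), params.codon_freqs)
        for token in set(classes.values())
    }

    leaf_row = {name: r for r, name in enumerate(leaf_order)}
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros(npat)

    for node in tree.postorder():
        if node.is_leaf:
            L = np.zeros((N_STATES, npat))
            states = patterns[leaf_row[node.name]]
            obs = states >= 0
            L[states[obs], np.nonzero(obs)[0]] = 1.0
            L[:, ~obs] = 1.0
            partial[id(node)] = L
        else:
            L = np.ones((N_STATES, npat))
            for child in node.children:
                t = child.length
                if t is None:
                    raise EngineError("tree lacks branch lengths (required by the engine)")
                P = eig[classes[id(child)]].pmatrix(t)
                L *= P @ partial.pop(id(child))
            scale = L.max(axis=0)
            if np.any(scale <= 0):
                return -math.inf
            L /= scale
            logscale += np.log(scale)
            partial[id(node)] = L

    site_l = params.codon_freqs @ partial[id(tree.root)]
    if np.any(site_l <= 0):
        return -math.inf
    return float(counts @ (np.log(site_l) + logscale))


_KAPPA_BOUNDS = (0.01, 50.0)
_OMEGA_BOUNDS = (1e-4, 20.0)


def fit(
    aln: CodonAlignment,
    tree: Phylogeny,
    model: str = "M0",
    start_omega: float = 0.5,
    start_kappa: float = 2.0,
    codon_freqs: np.ndarray | None = None,
) -> EngineFit:
    """Maximize the log-likelihood over κ and the per-class ω values.

    model="M0": a single ω for all branches (labels ignored).
    model="branch": one ω per distinct label class on the tree (background
    plus each token present); M0 is the special case with no labels.
    """
    freqs = EQUAL_FREQS.copy() if codon_freqs is None else np.asarray(codon_freqs, float)
    if model == "M0":
        work_tree = tree.copy()
        for node in work_tree.preorder():
            node.label = None
        class_tokens = [BACKGROUND]
    elif model == "branch":
        work_tree = tree
        class_tokens = sorted(set(branch_classes(tree).values()), key=lambda t: (t != BACKGROUND, t))
    else:
        raise EngineError(f"unknown model {model!r} (engine supports 'M0' and 'branch')")

    n_classes = len(class_tokens)

    def unpack(x: np.ndarray) -> CodonModelParams:
        vals = np.exp(x)
        omegas = dict(zip(class_tokens, vals[1:]))
        omegas.setdefault(BACKGROUND, vals[1])
        return CodonModelParams(kappa=float(vals[0]), omega_by_class=omegas, codon_freqs=freqs)

    def objective(x: np.ndarray) -> float:
        return -log_likelihood(aln, work_tree, unpack(x))

    def solve(k0: float, w0: float):
        x0 = np.log(np.concatenate([[k0], np.full(n_classes, w0)]))
        lb = [math.log(_KAPPA_BOUNDS[0])] + [math.log(_OMEGA_BOUNDS[0])] * n_classes
        ub = [math.log(_KAPPA_BOUNDS[1])] + [math.log(_OMEGA_BOUNDS[1])] * n_classes
        return minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=list(zip(lb, ub)),
            options={"ftol": 1e-10, "maxiter": 500},
        )

    k0 = min(max(start_kappa, _KAPPA_BOUNDS[0]), _KAPPA_BOUNDS[1])
    w0 = min(max(start_omega, _OMEGA_BOUNDS[0]), _OMEGA_BOUNDS[1])
    if not np.isfinite(objective(np.log(np.concatenate([[k0], np.full(n_classes, w0)])))):
        k0, w0 = 2.0, 0.5  # fallback start
    res = solve(k0, w0)
    if not np.isfinite(res.fun):
        raise EngineError("likelihood non-finite at optimum")
    return EngineFit(
        params=unpack(res.x), lnl=-float(res.fun), np=1 + n_classes, converged=bool(res.success)
    )


def simulate_codon_alignment(
    tree: Phylogeny,
    params: CodonModelParams,
    n_codons: int,
    rng: np.random.Generator | int,
    gene_id: str = "sim",
) -> CodonAlignment:
    """Simulate codon evolution down the tree.

    The root state is drawn from the equilibrium frequencies and each child
    state from the transition-matrix row of its parent's state, branch by
    branch; labeled branches evolve under their class ω.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    sequences: dict[str, str] = {}
    if n_codons == 0:
        return CodonAlignment(gene_id=gene_id, sequences={lf.name: "" for lf in tree.leaves()})

    classes = branch_classes(tree)
    eig = {
        token: _ClassMatrices(build_rate_matrix(params, token), params.codon_freqs)
        for token in set(classes.values())
    }
    states: dict[int, np.ndarray] = {
        id(tree.root): rng.choice(N_STATES, size=n_codons, p=params.codon_freqs)
    }
    for node in tree.preorder():
        if node.parent is None:
            continue
        t = node.length
        if t is None:
            raise EngineError("tree lacks branch lengths (required by the simulator)")
        P = eig[classes[id(node)]].pmatrix(t)
        P /= P.sum(axis=1, keepdims=True)
        cum = np.cumsum(P, axis=1)
        parent_states = states[id(node.parent)]
        u = rng.random(n_codons)
        child = np.empty(n_codons, dtype=np.int64)
        for s in np.unique(parent_states):
            mask = parent_states == s
            child[mask] = np.searchsorted(cum[s], u[mask])
        np.clip(child, 0, N_STATES - 1, out=child)
        states[id(node)] = child
        if node.is_leaf:
            sequences[node.name] = "".join(CODONS[s] for s in child)
    return CodonAlignment(gene_id=gene_id, sequences=sequences)


# --- CodeML main-output emulation ----------------------------------------


def codeml_numbering(tree: Phylogeny) -> dict[int, int]:
    """CodeML-style node numbers: leaves 1..N in newick appearance order,
    internal nodes N+1.. in preorder (root first)."""
    numbering: dict[int, int] = {}
    n_leaves = len(tree.leaves())
    next_leaf, next_internal = 1, n_leaves + 1
    for node in tree.preorder():
        if node.is_leaf:
            numbering[id(node)] = next_leaf
            next_leaf += 1
        else:
            numbering[id(node)] = next_internal
            next_internal += 1
    return numbering


def emulate_codeml_output(fit_result: EngineFit, tree: Phylogeny, gene_id: str) -> str:
    """Write CodeML-style main output text for a fitted model.

    Contains the lnL/np line, the tree echoed as newick, and a per-branch
    table with t, dN/dS, dN and dS.  dN and dS are derived from the branch
    length, the class ω, κ and the model's synonymous/nonsynonymous site
    proportions, so dN/dS always equals the class ω exactly.
    """
    from .trees import write_newick  # local import to avoid cycle at module load

    params = fit_result.params
    classes = branch_classes(tree)
    numbering = codeml_numbering(tree)
    A, B = _syn_nonsyn_flux(params)

    n_branches = tree.n_edges()
    lines = [
        f"CODONML (emulated engine output)  {gene_id}",
        "",
        f"lnL(ntime: {n_branches:2d}  np: {fit_result.np:2d}):  {fit_result.lnl:.6f}      +0.000000",
        "",
        write_newick(tree, include_labels=True, include_lengths=True),
        "",
        f"kappa (ts/tv) = {params.kappa:.5f}",
        "",
        " branch           t  dN/dS        dN        dS",
    ]
    for node in tree.preorder():
        if node.parent is None:
            continue
        t = node.length or 0.0
        omega = params.omega_for(classes[id(node)])
        denom = B + omega * A
        pn, ps = A / (A + B), B / (A + B)
        dn = t * (omega * A / denom) / pn if denom > 0 else 0.0
        ds = t * (B / denom) / ps if denom > 0 else 0.0
        a, b = numbering[id(node.parent)], numbering[id(node)]
        lines.append(f"  {a:2d}..{b:<3d} {t:10.6f} {omega:7.6f} {dn:9.6f} {ds:9.6f}")
    lines.append("")
    return "\n".join(lines)
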