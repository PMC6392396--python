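"""Phylogenetic pipeline for the interspecific models.

The bee models can constrain the species-level random effect by a
phylogeny.  Because a fully resolved species-level tree is rarely
available, the pipeline mirrors common practice with genus backbones:

1. prune a genus backbone to the genera present in the data;
2. graft each genus's species onto its tip as an equal-branch-length
   polytomy (so phylogenetic structure is asserted at and above the
   genus level only);
3. date the tree with penalized likelihood (correlated-rates model) to
   obtain an ultrametric chronogram;
4. quantify phylogenetic signal in a species-level trait with Pagel's
   lambda, and expose the shared-path-length covariance matrix the
   phylogenetic GLMM uses.

Trees are handled through dendropy; this module owns the algorithmic
steps (grafting geometry, the penalized-likelihood objective, the lambda
profile likelihood), not the Newick grammar.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Phylogeny",
    "LambdaResult",
    "read_newick",
    "write_newick",
    "prune_to_genera",
    "graft_species_polytomies",
    "chronogram_pl",
    "pagels_lambda",
    "phylo_covariance",
]


class Phylogeny:
    """A rooted tree with nonnegative branch lengths and unique tip labels.

    Thin wrapper over a :class:`dendropy.Tree` that enforces this
    package's invariants at construction and exposes the few geometric
    queries the pipeline needs (depths, ultrametricity, covariance).
    """

    def __init__(self, tree: dendropy.Tree):
        if tree.seed_node is None:
            raise ValueError("empty tree")
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if any(lab is None for lab in labels):
            raise ValueError("every tip must be labelled")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise ValueError(f"duplicate tip label(s): {sorted(dupes)}")
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            if node.edge.length is None:
                raise ValueError(f"missing branch length above {node_label(node)!r}")
            if node.edge.length < 0:
                raise ValueError(f"negative branch length above {node_label(node)!r}")
        self.tree = tree

    # -- basic queries ----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def node_depths(self) -> dict[dendropy.Node, float]:
        """Root-to-node path length for every node (root depth 0)."""
        depths: dict[dendropy.Node, float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    def tip_depths(self) -> dict[str, float]:
        depths = self.node_depths()
        return {leaf.taxon.label: depths[leaf] for leaf in self.tree.leaf_node_iter()}

    @property
    def is_ultrametric(self) -> bool:
        """True iff all root-to-tip depths agree within 1e-6 x depth."""
        d = list(self.tip_depths().values())
        dmax = max(d)
        if dmax == 0:
            return True
        return (dmax - min(d)) <= 1e-6 * dmax

    def clone(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        u = "ultrametric" if self.is_ultrametric else "non-ultrametric"
        return f"<Phylogeny: {self.n_tips} tips, {u}>"


def node_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon else "<internal>"


# ---------------------------------------------------------------------------
# Newick I/O


def _tree_from_string(text: str) -> dendropy.Tree:
    # field convention: unquoted underscores in Newick stand for spaces in
    # taxon labels (species binomials), quoted labels are taken literally
    return dendropy.Tree.get(
        data=text,
        schema="newick",
        preserve_underscores=False,
        suppress_internal_node_taxa=True,
        rooting="force-rooted",
    )


def read_newick(path: str | Path) -> Phylogeny:
    """Read a Newick tree; duplicate tips or malformed input raise."""
    text = Path(path).read_text(encoding="utf-8")
    return parse_newick(text)


def parse_newick(text: str) -> Phylogeny:
    try:
        tree = _tree_from_string(text)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


def write_newick(phylogeny: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(to_newick(phylogeny), encoding="utf-8")


def to_newick(phylogeny: Phylogeny) -> str:
    out = io.StringIO()
    phylogeny.tree.write(
        file=out,
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    )
    return out.getvalue()


# ---------------------------------------------------------------------------
# backbone surgery


def prune_to_genera(backbone: Phylogeny, genera: set[str] | Sequence[str]) -> Phylogeny:
    """Induced subtree on the kept genus tips.

    Degree-2 internal nodes left by the pruning are collapsed with their
    branch lengths summed, so patristic distances among kept tips are
    preserved exactly.
    """
    genera = set(genera)
    present = set(backbone.tip_labels)
    unknown = genera - present
    if unknown:
        raise ValueError(f"genera not in backbone: {sorted(unknown)}")
    if not genera:
        raise ValueError("no genera to keep")
    tree = backbone.tree.clone(depth=1)
    tree.retain_taxa_with_labels(sorted(genera))
    # retain_taxa suppresses unifurcations, summing edge lengths; the root
    # may still carry a single child chain -- collapse it as well.
    while tree.seed_node.num_child_nodes() == 1:
        child = tree.seed_node.child_nodes()[0]
        tree.seed_node = child
        child.parent_node = None
        child.edge.length = None if child.is_internal() else child.edge.length
    tree.seed_node.edge.length = None
    return Phylogeny(tree)


def graft_species_polytomies(
    backbone: Phylogeny,
    species_to_genus: Mapping[str, str],
    fraction: float = 0.5,
) -> tuple[Phylogeny, list[str]]:
    """Expand genus tips into equal-branch-length species polytomies.

    Each genus tip with S >= 2 assigned species becomes an internal node
    whose S species tips all hang at ``fraction`` x (that genus's
    terminal edge length); the genus stem is shortened by the same
    amount, so every root-to-tip depth is preserved.  A genus with one
    species is simply relabelled.  Species whose genus is not a backbone
    tip are returned in the excluded list, not raised.

    Congeneric species end up equidistant from each other and share the
    full genus-stem history -- phylogenetic structure below the genus
    level is deliberately flat.
    """
    if not species_to_genus:
        raise ValueError("empty species-to-genus mapping")
    if not (0 < fraction < 1):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")

    by_genus: dict[str, list[str]] = {}
    for species, genus in species_to_genus.items():
        by_genus.setdefault(genus, []).append(species)

    phylo = backbone.clone()
    tree = phylo.tree
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    excluded = sorted(
        sp for sp, gen in species_to_genus.items() if gen not in tips
    )

    for genus, species_list in sorted(by_genus.items()):
        if genus not in tips:
            continue
        node = tips[genus]
        species_list = sorted(species_list)
        if len(species_list) == 1:
            node.taxon.label = species_list[0]
            continue
        stem = node.edge.length
        tip_len = fraction * stem
        node.edge.length = stem - tip_len
        node.taxon = None
        for species in species_list:
            taxon = tree.taxon_namespace.require_taxon(label=species)
            child = node.new_child(taxon=taxon, edge_length=tip_len)
            assert child.edge.length == tip_len
    return Phylogeny(tree), excluded


# ---------------------------------------------------------------------------
# penalized-likelihood chronogram (correlated-rates model)


@dataclass
class _PLState:
    """Index arrays describing the tree for the vectorized objective."""

    parent: np.ndarray        # parent node index per edge
    child: np.ndarray         # child node index per edge
    x: np.ndarray             # observed branch lengths per edge
    edge_parent_edge: np.ndarray  # index of the parent's edge, -1 at root children
    root_child_edges: np.ndarray
    n_internal: int           # internal non-root nodes (free ages)
    node_order: list          # preorder nodes
    age_param_index: np.ndarray  # per node: index into s-params or -1


def chronogram_pl(
    tree: Phylogeny,
    smoothing: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> Phylogeny:
    """Date a tree by penalized likelihood with correlated rates.

    Each edge j has an unknown rate r_j and duration t_j (difference of
    the adjacent node ages); the observed branch length x_j is scored by
    a Poisson-type log-likelihood x_j*ln(r_j t_j) - r_j t_j, and rate
    variation is penalized by ``smoothing`` times the sum of squared
    rate differences between adjacent edges (plus the variance of the
    rates of the root's child edges).  Node ages are free up to the
    arbitrary overall time scale; the root age is fixed at 1, so output
    branch lengths are in relative time and the chronogram is exactly
    ultrametric by construction.

    Raises RuntimeError with the objective trace if the optimizer fails.
    """
    if smoothing <= 0:
        raise ValueError("smoothing must be positive")
    phylo = tree.clone()
    t = phylo.tree
    nodes = list(t.preorder_node_iter())
    index = {node: i for i, node in enumerate(nodes)}
    n_nodes = len(nodes)

    edges = [node for node in nodes if node.parent_node is not None]
    parent_idx = np.array([index[e.parent_node] for e in edges])
    child_idx = np.array([index[e] for e in edges])
    x = np.array([e.edge.length for e in edges], dtype=float)

    edge_index_of_child = {index[e]: j for j, e in enumerate(edges)}
    edge_parent_edge = np.array(
        [edge_index_of_child.get(index[e.parent_node], -1) for e in edges]
    )
    root_children = np.array([j for j, e in enumerate(edges)
                              if e.parent_node is t.seed_node])

    internal = [node for node in nodes
                if node.parent_node is not None and not node.is_leaf()]
    age_param = np.full(n_nodes, -1)
    for k, node in enumerate(internal):
        age_param[index[node]] = k
    n_free = len(internal)
    is_leaf = np.array([node.is_leaf() for node in nodes])

    # initial ages: proportional to the maximum path length below each node
    height = np.zeros(n_nodes)
    for node in reversed(nodes):
        i = index[node]
        if node.is_leaf():
            height[i] = 0.0
        else:
            height[i] = max(
                height[index[c]] + max(c.edge.length, 1e-8)
                for c in node.child_nodes()
            )
    root_h = height[index[t.seed_node]]

    def ages_from_params(s_logit: np.ndarray) -> np.ndarray:
        s = 1.0 / (1.0 + np.exp(-s_logit))
        ages = np.zeros(n_nodes)
        for node in nodes:  # preorder: parent before child
            i = index[node]
            if node.parent_node is None:
                ages[i] = 1.0
            elif is_leaf[i]:
                ages[i] = 0.0
            else:
                ages[i] = ages[index[node.parent_node]] * s[age_param[i]]
        return ages

    def objective(theta: np.ndarray) -> float:
        s_logit = theta[:n_free]
        log_r = theta[n_free:]
        r = np.exp(np.clip(log_r, -30, 30))
        ages = ages_from_params(s_logit)
        dur = np.maximum(ages[parent_idx] - ages[child_idx], 1e-12)
        mu = r * dur
        ll = np.sum(np.where(x > 0, x * np.log(mu), 0.0) - mu)
        has_parent = edge_parent_edge >= 0
        pen = np.sum((r[has_parent] - r[edge_parent_edge[has_parent]]) ** 2)
        if root_children.size > 1:
            pen += np.var(r[root_children])
        return -(ll - smoothing * pen)

    # initialization: clock-like ages, one global rate
    s0 = []
    for node in internal:
        i = index[node]
        pa = height[index[node.parent_node]] if node.parent_node.parent_node is not None else root_h
        ratio = np.clip(height[i] / max(pa, 1e-9), 1e-3, 1 - 1e-3)
        s0.append(math.log(ratio / (1 - ratio)))
    ages0 = ages_from_params(np.array(s0)) if n_free else np.zeros(n_nodes)
    dur0 = np.maximum(ages0[parent_idx] - ages0[child_idx], 1e-9)
    rate0 = max(x.sum() / dur0.sum(), 1e-9)
    theta0 = np.concatenate([np.array(s0), np.full(len(edges), math.log(rate0))])

    trace: list[float] = []

    def cb(theta_k):
        trace.append(-objective(theta_k))

    res = optimize.minimize(
        objective, theta0, method="L-BFGS-B", callback=cb,
        options={"maxiter": max_iter, "ftol": tol},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter, still usable trace
        raise RuntimeError(
            f"penalized-likelihood optimizer failed: {res.message}; "
            f"objective trace: {[round(v, 4) for v in trace]}"
        )

    ages = ages_from_params(res.x[:n_free])
    for node in nodes:
        if node.parent_node is not None:
            node.edge.length = float(
                ages[index[node.parent_node]] - ages[index[node]]
            )
    out = Phylogeny(t)
    out.pl_objective_trace = trace  # type: ignore[attr-defined]
    out.pl_rates = np.exp(res.x[n_free:])  # type: ignore[attr-defined]
    if not out.is_ultrametric:  # pragma: no cover - construction guarantees it
        raise RuntimeError("chronogram is not ultrametric")
    return out


# ---------------------------------------------------------------------------
# phylogenetic covariance and Pagel's lambda


def phylo_covariance(tree: Phylogeny) -> pd.DataFrame:
    """Shared-path-length matrix: entry (i, j) = root-to-MRCA distance.

    The diagonal holds tip depths.  Under Brownian trait evolution this
    is the trait covariance up to a rate constant, and it is what the
    phylogenetic GLMM uses for its species random effect.
    """
    labels = tree.tip_labels
    pos = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    cov = np.zeros((n, n))
    depths = tree.node_depths()

    tips_below: dict[dendropy.Node, list[int]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            k = pos[node.taxon.label]
            tips_below[node] = [k]
            cov[k, k] = depths[node]
        else:
            groups = [tips_below[c] for c in node.child_nodes()]
            d = depths[node]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            cov[i, j] = cov[j, i] = d
            tips_below[node] = [i for g in groups for i in g]
    return pd.DataFrame(cov, index=labels, columns=labels)


@dataclass(frozen=True)
class LambdaResult:
    """Maximum-likelihood Pagel's lambda with its likelihood-ratio test."""

    lambda_hat: float
    loglik_at_hat: float
    loglik_at_zero: float
    lr_pvalue: float
    mu_hat: float
    sigma2_hat: float


def _lambda_profile_loglik(lam: float, C: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Profile log-likelihood at lambda, with profiled mean and rate."""
    n = len(y)
    V = lam * C + (1.0 - lam) * np.diag(np.diag(C))
    # tiny ridge: near-zero branch lengths make tips numerically identical
    V = V + (1e-9 * np.mean(np.diag(C))) * np.eye(n)
    L = np.linalg.cholesky(V)
    one = np.ones(n)
    Li_y = np.linalg.solve(L, y)
    Li_1 = np.linalg.solve(L, one)
    mu = (Li_1 @ Li_y) / (Li_1 @ Li_1)
    resid = Li_y - mu * Li_1
    sigma2 = float(resid @ resid) / n
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdetV + n)
    return ll, float(mu), sigma2


def pagels_lambda(
    tree: Phylogeny,
    trait: Mapping[str, float],
    boundary_mixture: bool = False,
) -> LambdaResult:
    """ML estimate of Pagel's lambda for a species-level trait.

    lambda scales the off-diagonal phylogenetic covariance (diagonal
    preserved): 0 = star-like independence, 1 = Brownian motion on the
    tree.  The ancestral mean and the Brownian rate are profiled
    analytically; lambda is maximized on [0, 1] by bounded Brent search.
    The likelihood-ratio test compares the optimum against lambda = 0
    on a chi-square(1) scale (or a 50:50 boundary mixture when
    ``boundary_mixture`` is set, since lambda = 0 sits on the parameter
    boundary).

    Requires an ultrametric tree -- on a non-ultrametric tree the
    diagonal-preserving rescaling conflates depth variation with signal.
    """
    if len(trait) < 4:
        raise ValueError(f"need >= 4 species with trait values, got {len(trait)}")
    if not tree.is_ultrametric:
        raise ValueError("pagels_lambda requires an ultrametric tree (chronogram)")
    tips = set(tree.tip_labels)
    missing = sorted(set(trait) - tips)
    if missing:
        raise ValueError(f"trait species not in tree: {missing}")

    species = sorted(trait)
    C = phylo_covariance(tree).loc[species, species].to_numpy()
    y = np.array([float(trait[s]) for s in species])

    def neg(lam: float) -> float:
        return -_lambda_profile_loglik(lam, C, y)[0]

    res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    candidates = [float(res.x), 0.0, 1.0]
    lam_hat = min(candidates, key=neg)
    ll_hat, mu_hat, s2_hat = _lambda_profile_loglik(lam_hat, C, y)
    ll_zero = _lambda_profile_loglik(0.0, C, y)[0]
    lr = max(2.0 * (ll_hat - ll_zero), 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    if boundary_mixture:
        p = 1.0 if lr == 0 else 0.5 * p
    return LambdaResult(
        lambda_hat=float(lam_hat),
        loglik_at_hat=float(ll_hat),
        loglik_at_zero=float(ll_zero),
        lr_pvalue=min(p, 1.0),
        mu_hat=mu_hat,
        sigma2_hat=s2_hat,
    )
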