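"""Log-space pruning over a tree and the reverse pass for gradients.

The forward pass is Felsenstein's post-order dynamic program: each node
carries, per alignment column, the log partial likelihood vector of the
data below it conditional on the node's state.  Leaf vectors are logs of
residue profiles (one-hot for observed residues, indicator profiles for
ambiguity codes and gaps); an internal node sums, over its children, the
log of the child's message ``P(t_child) . exp(logpartial_child)``, every
reduction done with logsumexp.  The column log likelihood marginalizes the
root under the equilibrium distribution of the column's model.

The reverse pass sweeps the tree once in pre-order and backpropagates
through the same logsumexp recursions, yielding ``dL/dP(t_e)`` for every
edge in time linear in the node count.  Those per-edge gradients are
pulled back to ``dL/dQ`` per model through the spectral adjoint — the
branch-local inner terms are summed over all edges sharing a model, and
the two outer matrix multiplications are applied once per model.  Branch
length gradients come almost for free: ``dL/dt_e = <dL/dP(t_e), Q P(t_e)>``
under the trace inner product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import matexp_grad
from .reversible_model import SpectralForm, backprop_params


class TreeError(ValueError):
    """Malformed tree or tree/alignment mismatch."""


class PhyloTree:
    """Rooted tree with branch lengths, stored as parent-pointer arrays.

    ``parent[i]`` is the parent index of node ``i`` (-1 for the root) and
    ``lengths[i]`` the length of the edge above node ``i`` (0 at the root).
    ``names[i]`` labels leaves; internal labels are optional.
    Multifurcations are allowed.
    """

    def __init__(self, parent: np.ndarray, lengths: np.ndarray, names: list[str | None]):
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.names = list(names)
        n = len(self.parent)
        if not (len(self.lengths) == len(self.names) == n):
            raise TreeError("parent, lengths and names must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        if not np.all(np.isfinite(self.lengths)) or np.any(self.lengths < 0):
            raise TreeError("branch lengths must be finite and >= 0")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.postorder = self._postorder()
        self.leaves = [i for i in range(n) if not self.children[i]]
        leaf_names = [self.names[i] for i in self.leaves]
        if any(nm is None for nm in leaf_names):
            raise TreeError("every leaf must be named")
        if len(set(leaf_names)) != len(leaf_names):
            raise TreeError("duplicate leaf names")

    def _postorder(self) -> list[int]:
        order: list[int] = []
        stack = [(self.root, False)]
        seen = 0
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            seen += 1
            if seen > len(self.parent):
                raise TreeError("cycle detected in parent pointers")
            stack.append((node, True))
            for c in self.children[node]:
                stack.append((c, False))
        if len(order) != len(self.parent):
            raise TreeError("tree is not connected")
        return order

    @property
    def num_nodes(self) -> int:
        return len(self.parent)

    @property
    def num_leaves(self) -> int:
        return len(self.leaves)

    def leaf_index(self) -> dict[str, int]:
        return {self.names[i]: i for i in self.leaves}


class LeafProfiles:
    """Per-(leaf, column) residue profiles with optional column weights.

    ``profiles[k, c]`` is the n-vector for taxon ``taxa[k]`` at column
    ``c``: one-hot for an observed residue, an indicator over compatible
    states for ambiguity codes, all-ones for gaps/unknowns.  ``weights``
    multiply each column's log likelihood (pattern compression); default 1.
    """

    def __init__(
        self,
        taxa: list[str],
        profiles: np.ndarray,
        weights: np.ndarray | None = None,
    ):
        self.taxa = list(taxa)
        self.profiles = np.asarray(profiles, dtype=float)
        if self.profiles.ndim != 3 or self.profiles.shape[0] != len(self.taxa):
            raise ValueError(
                "profiles must have shape (num_taxa, num_columns, num_states)"
            )
        if np.any(self.profiles < 0) or not np.all(np.isfinite(self.profiles)):
            raise ValueError("profiles must be finite and non-negative")
        if np.any(self.profiles.max(axis=2) <= 0):
            raise ValueError("every profile needs at least one positive entry")
        if weights is None:
            weights = np.ones(self.profiles.shape[1])
        self.weights = np.asarray(weights, dtype=float)
        if self.weights.shape != (self.profiles.shape[1],):
            raise ValueError("weights must have one entry per column")

    @property
    def num_columns(self) -> int:
        return self.profiles.shape[1]

    @property
    def num_states(self) -> int:
        return self.profiles.shape[2]

    def subset_columns(self, cols: np.ndarray) -> "LeafProfiles":
        return LeafProfiles(self.taxa, self.profiles[:, cols], self.weights[cols])


class ColumnModelMap:
    """Assignment of alignment columns to substitution models.

    ``specs`` is the model table (spectral forms); ``assignment[c]`` the
    model index of column ``c``.  ``assignment=None`` means a single global
    model for all columns (the fast path: per-edge transition matrices are
    computed once, not per column).
    """

    def __init__(self, specs: list[SpectralForm], assignment: np.ndarray | None = None):
        if not specs:
            raise ValueError("need at least one model")
        self.specs = list(specs)
        n = specs[0].n
        if any(s.n != n for s in specs):
            raise ValueError("all models must share one state count")
        self.n = n
        self.assignment = None if assignment is None else np.asarray(assignment, dtype=int)
        if self.assignment is not None:
            if np.any(self.assignment < 0) or np.any(self.assignment >= len(specs)):
                raise ValueError("column assigned to a model index out of range")

    @classmethod
    def global_model(cls, spec: SpectralForm) -> "ColumnModelMap":
        return cls([spec], None)

    @classmethod
    def per_column(cls, specs: list[SpectralForm]) -> "ColumnModelMap":
        return cls(specs, np.arange(len(specs)))

    @property
    def num_models(self) -> int:
        return len(self.specs)

    def resolve(self, num_columns: int) -> np.ndarray:
        """Per-column model indices, materialized."""
        if self.assignment is None:
            return np.zeros(num_columns, dtype=int)
        if len(self.assignment) != num_columns:
            raise ValueError(
                f"model map covers {len(self.assignment)} columns, data has {num_columns}"
            )
        return self.assignment

    def subset_columns(self, cols: np.ndarray) -> "ColumnModelMap":
        if self.assignment is None:
            return self
        return ColumnModelMap(self.specs, self.assignment[cols])


@dataclass
class GradientBundle:
    """Log likelihood plus every gradient the reverse pass produces.

    ``g_q[m]`` is ``dL/dQ`` for model ``m`` (zero if no column uses it),
    ``g_exch[m]`` / ``g_sqrt_pi[m]`` the parameter gradients, and ``g_t[i]``
    the derivative w.r.t. the length of the edge above node ``i`` (0 at the
    root, which has no edge).
    """

    loglik: float
    col_logliks: np.ndarray
    g_q: list[np.ndarray]
    g_exch: list[np.ndarray]
    g_sqrt_pi: list[np.ndarray]
    g_t: np.ndarray


@dataclass
class PruningCache:
    """Forward-pass state reused by the reverse pass."""

    tree: PhyloTree
    profiles: LeafProfiles
    models: ColumnModelMap
    assignment: np.ndarray
    p_edge: dict[int, np.ndarray]  # node -> (num_models, n, n), edge above node
    log_partials: np.ndarray  # (num_nodes, C, n)
    messages: dict[int, np.ndarray]  # node -> (C, n) log message to its parent
    col_logliks: np.ndarray  # (C,) unweighted


def _logsumexp(x: np.ndarray, axis: int) -> np.ndarray:
    """logsumexp that maps all -inf slices to -inf instead of nan."""
    m = np.max(x, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        out = np.log(np.sum(np.exp(x - m), axis=axis))
    return out + np.squeeze(m, axis=axis)


def _check_inputs(
    tree: PhyloTree, profiles: LeafProfiles, models: ColumnModelMap
) -> np.ndarray:
    if profiles.num_states != models.n:
        raise ValueError(
            f"profiles have {profiles.num_states} states, models have {models.n}"
        )
    leaf_by_name = tree.leaf_index()
    if set(profiles.taxa) != set(leaf_by_name):
        missing = set(leaf_by_name) - set(profiles.taxa)
        extra = set(profiles.taxa) - set(leaf_by_name)
        raise TreeError(
            f"taxon mismatch between tree and profiles (missing={sorted(missing)}, "
            f"unmatched={sorted(extra)})"
        )
    return models.resolve(profiles.num_columns)


def pruning_forward(
    tree: PhyloTree, profiles: LeafProfiles, models: ColumnModelMap
) -> tuple[np.ndarray, PruningCache]:
    """Post-order log-space pruning.

    Returns the per-column (unweighted) log likelihoods and a cache of
    partials, messages and per-edge transition matrices for the reverse
    pass.  The total weighted log likelihood is
    ``profiles.weights @ col_logliks``.
    """
    assignment = _check_inputs(tree, profiles, models)
    n = models.n
    num_cols = profiles.num_columns
    leaf_by_name = tree.leaf_index()
    taxon_row = {name: k for k, name in enumerate(profiles.taxa)}

    multi = models.num_models > 1
    p_edge: dict[int, np.ndarray] = {}
    log_partials = np.zeros((tree.num_nodes, num_cols, n))
    messages: dict[int, np.ndarray] = {}

    with np.errstate(divide="ignore"):
        for name, node in leaf_by_name.items():
            log_partials[node] = np.log(profiles.profiles[taxon_row[name]])

    for node in tree.postorder:
        if tree.children[node]:
            log_partials[node] = 0.0
            for child in tree.children[node]:
                log_partials[node] += messages[child]
        if node == tree.root:
            continue
        t = tree.lengths[node]
        p = np.stack([matexp_grad.expm_spectral(s, t) for s in models.specs])
        p_edge[node] = p
        with np.errstate(divide="ignore"):
            logp = np.log(p)
        ell = log_partials[node]
        if multi:
            msg = _logsumexp(logp[assignment] + ell[:, None, :], axis=2)
        else:
            msg = _logsumexp(logp[0][None, :, :] + ell[:, None, :], axis=2)
        messages[node] = msg

    log_pi = np.log(np.stack([s.pi for s in models.specs]))
    root_prior = log_pi[assignment] if multi else log_pi[0][None, :]
    col_logliks = _logsumexp(root_prior + log_partials[tree.root], axis=1)
    if not np.all(np.isfinite(col_logliks)):
        bad = int(np.flatnonzero(~np.isfinite(col_logliks))[0])
        raise ValueError(f"non-finite log likelihood at column {bad}")
    cache = PruningCache(
        tree=tree,
        profiles=profiles,
        models=models,
        assignment=assignment,
        p_edge=p_edge,
        log_partials=log_partials,
        messages=messages,
        col_logliks=col_logliks,
    )
    return col_logliks, cache


def reverse_pass(cache: PruningCache) -> GradientBundle:
    """Pre-order backpropagation through the pruning recursions.

    One sweep produces ``dL/dP`` per edge; per model, the spectral
    adjoint's inner terms are accumulated over its edges and the outer
    transform applied once, giving ``dL/dQ``; parameter gradients follow by
    the chain rule through the (S, sqrt-pi) build, with the root prior's
    ``dL/dpi`` folded in.  ``dL/dt_e = <dL/dP, Q P>``.
    """
    tree, models = cache.tree, cache.models
    num_models = models.num_models
    multi = num_models > 1
    n = models.n
    w = cache.profiles.weights
    assignment = cache.assignment

    ell_root = cache.log_partials[tree.root]
    log_pi = np.log(np.stack([s.pi for s in models.specs]))
    root_prior = log_pi[assignment] if multi else log_pi[0][None, :]
    # dL/d logpartial_root, weighted per column
    g_node = {
        tree.root: w[:, None]
        * np.exp(root_prior + ell_root - cache.col_logliks[:, None])
    }

    # root-prior contribution to dL/dpi per model
    e_root = w[:, None] * np.exp(ell_root - cache.col_logliks[:, None])
    if multi:
        g_pi = [e_root[assignment == m].sum(axis=0) for m in range(num_models)]
    else:
        g_pi = [e_root.sum(axis=0)]

    inner_sum = [np.zeros((n, n)) for _ in range(num_models)]
    g_t = np.zeros(tree.num_nodes)

    for node in reversed(tree.postorder):
        if node == tree.root:
            continue
        parent = tree.parent[node]
        g_parent = g_node[parent]
        ell = cache.log_partials[node]
        msg = cache.messages[node]
        p = cache.p_edge[node]
        with np.errstate(invalid="ignore", over="ignore"):
            expo = ell[:, None, :] - msg[:, :, None]
            expo = np.where(np.isnan(expo), -np.inf, expo)
            g_p_cols = g_parent[:, :, None] * np.exp(expo)
        g_p_cols = np.where(g_parent[:, :, None] == 0.0, 0.0, g_p_cols)

        if multi:
            p_cols = p[assignment]
            g_node[node] = np.einsum("cab,cab->cb", g_p_cols, p_cols)
            g_p_models = np.zeros((num_models, n, n))
            np.add.at(g_p_models, assignment, g_p_cols)
        else:
            g_node[node] = np.einsum("cab,ab->cb", g_p_cols, p[0])
            g_p_models = g_p_cols.sum(axis=0)[None, :, :]

        t = tree.lengths[node]
        for m, spec in enumerate(models.specs):
            g_p_m = g_p_models[m]
            if multi and not np.any(g_p_m):
                continue
            g_t[node] += float(np.sum(g_p_m * (spec.q @ p[m])))
            inner_sum[m] += matexp_grad.expm_adjoint_inner(spec, g_p_m, t)

    g_q = [
        matexp_grad.adjoint_outer(spec, inner_sum[m])
        for m, spec in enumerate(models.specs)
    ]
    g_exch, g_sqrt_pi = [], []
    for m, spec in enumerate(models.specs):
        ge, gr = backprop_params(
            g_q[m], spec.params, g_pi=g_pi[m], normalize=spec.normalized
        )
        g_exch.append(ge)
        g_sqrt_pi.append(gr)

    loglik = float(np.dot(w, cache.col_logliks))
    return GradientBundle(
        loglik=loglik,
        col_logliks=cache.col_logliks,
        g_q=g_q,
        g_exch=g_exch,
        g_sqrt_pi=g_sqrt_pi,
        g_t=g_t,
    )


def loglik_and_grad(
    tree: PhyloTree, profiles: LeafProfiles, models: ColumnModelMap
) -> GradientBundle:
    """Forward and reverse pass in one call."""
    _, cache = pruning_forward(tree, profiles, models)
    return reverse_pass(cache)


def brute_force_likelihood(
    tree: PhyloTree, profiles: LeafProfiles, models: ColumnModelMap
) -> np.ndarray:
    """Per-column log likelihood by exhaustive ancestral-state enumeration.

    Exponential in the number of internal nodes; refuses trees with more
    than 7 leaves.  Test oracle, not a user-facing code path.
    """
    if tree.num_leaves > 7:
        raise TreeError("brute force enumeration limited to <= 7 leaves")
    assignment = _check_inputs(tree, profiles, models)
    n = models.n
    internal = [i for i in tree.postorder if tree.children[i]]
    leaf_by_name = tree.leaf_index()
    taxon_row = {name: k for k, name in enumerate(profiles.taxa)}
    num_cols = profiles.num_columns

    out = np.empty(num_cols)
    for c in range(num_cols):
        spec = models.specs[assignment[c]]
        p = {
            node: matexp_grad.expm_spectral(spec, tree.lengths[node])
            for node in range(tree.num_nodes)
            if node != tree.root
        }
        total = 0.0
        for states in np.ndindex(*([n] * len(internal))):
            state_of = dict(zip(internal, states))
            term = spec.pi[state_of[tree.root]]
            for node in internal:
                a = state_of[node]
                for child in tree.children[node]:
                    row = p[child][a]
                    if tree.children[child]:
                        term *= row[state_of[child]]
                    else:
                        prof = profiles.profiles[taxon_row[tree.names[child]], c]
                        term *= float(row @ prof)
            total += term
        out[c] = np.log(total)
    return out
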