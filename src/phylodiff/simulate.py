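"""Random trees and CTMC-evolved alignments for testing and benchmarks.

Topologies are generated by sequential random coalescence: starting from
the requested number of lineages, pairs are merged uniformly at random
until one root remains, and every edge gets an independent Exp(mean)
branch length.  Columns evolve down the tree under their assigned
reversible model: the root state is drawn from the model's equilibrium
distribution and each child state from the parent's row of ``P(t_edge)``.
Everything is deterministic given the seed.

The 20-state test model returned by :func:`example_aa_params` is a fixed,
seeded random reversible parameter set — a synthetic stand-in with the
shape of an empirical amino-acid matrix, not estimates from data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import matexp_grad
from .felsenstein import ColumnModelMap, LeafProfiles, PhyloTree
from .reversible_model import ReversibleParams, spectral_decompose

DNA_ALPHABET = "ACGT"
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


def alphabet_for(n: int) -> str:
    if n == 4:
        return DNA_ALPHABET
    if n == 20:
        return AA_ALPHABET
    raise ValueError(f"no residue alphabet for n={n} states")


@dataclass(frozen=True)
class SimSpec:
    """Conditions of one simulation run (seed mandatory)."""

    num_taxa: int
    num_columns: int
    branch_length_mean: float
    seed: int
    models: ColumnModelMap | None = None

    def __post_init__(self) -> None:
        if self.num_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if self.num_columns < 1:
            raise ValueError("need at least 1 column")
        if not self.branch_length_mean > 0:
            raise ValueError("branch_length_mean must be positive")


def random_tree(spec: SimSpec) -> PhyloTree:
    """Random bifurcating topology by sequential coalescence of lineages.

    Leaves are named ``t0001 ...``; all 2*num_taxa - 1 nodes carry an
    Exp(branch_length_mean) edge length except the root.
    """
    rng = np.random.default_rng(spec.seed)
    total = 2 * spec.num_taxa - 1
    parent = np.full(total, -1, dtype=int)
    lengths = np.zeros(total)
    names: list[str | None] = [f"t{i + 1:04d}" for i in range(spec.num_taxa)] + [
        None
    ] * (spec.num_taxa - 1)
    active = list(range(spec.num_taxa))
    next_id = spec.num_taxa
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        parent[a] = next_id
        parent[b] = next_id
        lengths[a] = rng.exponential(spec.branch_length_mean)
        lengths[b] = rng.exponential(spec.branch_length_mean)
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return PhyloTree(parent, lengths, names)


def simulate_alignment(
    tree: PhyloTree, models: ColumnModelMap, seed: int
) -> tuple[LeafProfiles, dict[str, str]]:
    """Evolve one-hot columns down the tree.

    Returns the leaf profiles and the same data as FASTA-writable residue
    strings (taxon -> sequence), using the standard nucleotide or
    amino-acid alphabet for the model's state count.
    """
    rng = np.random.default_rng(seed)
    n = models.n
    # number of columns comes from the model map; a global map needs num_columns
    if models.assignment is None:
        raise ValueError(
            "simulate_alignment needs a per-column assignment; use "
            "ColumnModelMap(specs, np.zeros(C, dtype=int)) for a global model"
        )
    assignment = models.assignment
    num_cols = len(assignment)
    multi = models.num_models > 1

    pi_table = np.stack([s.pi for s in models.specs])
    pi_cols = pi_table[assignment]
    states = np.empty((tree.num_nodes, num_cols), dtype=int)
    u = rng.random(num_cols)
    states[tree.root] = (u[:, None] > np.cumsum(pi_cols, axis=1)).sum(axis=1)

    for node in reversed(tree.postorder):
        if node == tree.root:
            continue
        t = tree.lengths[node]
        p = np.stack([matexp_grad.expm_spectral(s, t) for s in models.specs])
        rows = (
            p[assignment, states[tree.parent[node]], :]
            if multi
            else p[0][states[tree.parent[node]], :]
        )
        u = rng.random(num_cols)
        states[node] = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)

    alphabet = alphabet_for(n)
    taxa = [tree.names[i] for i in tree.leaves]
    profiles = np.zeros((len(taxa), num_cols, n))
    sequences: dict[str, str] = {}
    for k, leaf in enumerate(tree.leaves):
        s = states[leaf]
        profiles[k, np.arange(num_cols), s] = 1.0
        sequences[tree.names[leaf]] = "".join(alphabet[x] for x in s)
    return LeafProfiles(taxa, profiles), sequences


def random_reversible_params(
    n: int, rng: np.random.Generator, exch_scale: float = 1.0
) -> ReversibleParams:
    """Random positive exchangeabilities (log-normal) and sqrt_pi (Dirichlet pi)."""
    k = n * (n - 1) // 2
    exch = exch_scale * rng.lognormal(mean=0.0, sigma=0.5, size=k)
    pi = rng.dirichlet(np.full(n, 5.0))
    return ReversibleParams(n, exch, np.sqrt(pi))


def example_aa_params(seed: int = 20250101) -> ReversibleParams:
    """The bundled 20-state test model (synthetic; fixed seed)."""
    return random_reversible_params(20, np.random.default_rng(seed))


def simulate_global(
    num_taxa: int,
    num_columns: int,
    params: ReversibleParams,
    seed: int,
    branch_length_mean: float = 0.1,
    normalize_rate: bool = True,
) -> tuple[PhyloTree, LeafProfiles, ColumnModelMap]:
    """Convenience: random tree + alignment under one global model.

    The returned ``ColumnModelMap`` is the global (fast-path) map of the
    generating model.
    """
    spec = SimSpec(num_taxa, num_columns, branch_length_mean, seed)
    tree = random_tree(spec)
    sf = spectral_decompose(params, normalize=normalize_rate)
    sim_map = ColumnModelMap([sf], np.zeros(num_columns, dtype=int))
    profiles, _ = simulate_alignment(tree, sim_map, seed + 1)
    return tree, profiles, ColumnModelMap.global_model(sf)
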