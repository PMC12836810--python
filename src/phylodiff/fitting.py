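"""Gradient-based maximum-likelihood fitting of reversible models.

Three model kinds are supported: one GTR matrix shared by every column
(``global_gtr``), shared exchangeabilities with an independent equilibrium
distribution per column (``shared_S_column_pi``), and a fully independent
GTR per column (``per_column_gtr``).  All positive parameters are
optimized in log space, so the problem is unconstrained and the analytic
gradients from the reverse pass transfer with a single chain-rule factor.
The driver is L-BFGS (memory 10, Wolfe line search via SciPy's L-BFGS-B
with no bounds); optimization stops when an iteration improves the log
likelihood by less than ``rel_improve_tol`` relative (default 1e-6, i.e.
0.0001%) or at ``max_iters``.

Every model's generator is rate-normalized by default (one expected
substitution per unit branch length at equilibrium).  Normalization makes
the objective invariant to the overall scale of the exchangeabilities and
— always — to the scale of sqrt_pi, which is exactly the counting behind
``count_free_parameters`` (e.g. 190 - 1 + 19 = 208 for a global
amino-acid GTR).  The flat directions are harmless to L-BFGS; the count
reports identifiable degrees of freedom, not the raw vector length.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .felsenstein import ColumnModelMap, LeafProfiles, PhyloTree, loglik_and_grad
from .reversible_model import (
    ReversibleParams,
    params_to_text,
    spectral_decompose,
)

MODEL_KINDS = ("global_gtr", "shared_S_column_pi", "per_column_gtr")


@dataclass
class FitConfig:
    """Settings for :func:`fit`."""

    model_kind: str = "global_gtr"
    max_iters: int = 1000
    rel_improve_tol: float = 1e-6
    l2_penalty: float = 0.0
    seed: int | None = None
    init_jitter: float = 0.0
    normalize_rate: bool = True

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.rel_improve_tol <= 0:
            raise ValueError("rel_improve_tol must be positive")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be >= 0")


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    params: list[ReversibleParams]
    loglik: float
    initial_loglik: float
    trace: list[float]
    termination: str
    n_iterations: int
    n_free_parameters: int
    config: FitConfig = field(repr=False)

    def report(self) -> str:
        lines = [
            f"model_kind: {self.config.model_kind}",
            f"free_parameters: {self.n_free_parameters}",
            f"initial_loglik: {self.initial_loglik:.10g}",
            f"final_loglik: {self.loglik:.10g}",
            f"iterations: {self.n_iterations}",
            f"termination: {self.termination}",
        ]
        return "\n".join(lines) + "\n"

    def write_trace_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "loglik"])
            for i, value in enumerate(self.trace):
                writer.writerow([i, f"{value:.12g}"])

    def params_text(self) -> str:
        return "".join(params_to_text(p) for p in self.params)


def count_free_parameters(
    n: int, model_kind: str, num_columns: int = 1
) -> int:
    """Identifiable parameter count of a rate-normalized model.

    Per GTR matrix: ``n(n-1)/2`` exchangeabilities minus one overall scale
    (absorbed by rate normalization) plus ``n - 1`` free equilibrium
    frequencies.  A shared-S model keeps one exchangeability block but one
    frequency block per column.
    """
    if n < 2:
        raise ValueError("need at least 2 states")
    k = n * (n - 1) // 2
    if model_kind == "global_gtr":
        return k - 1 + (n - 1)
    if model_kind == "shared_S_column_pi":
        return k - 1 + num_columns * (n - 1)
    if model_kind == "per_column_gtr":
        return num_columns * (k - 1 + (n - 1))
    raise ValueError(f"unknown model kind {model_kind!r}")


def _pack(params_list: list[ReversibleParams], kind: str) -> np.ndarray:
    if kind == "global_gtr":
        p = params_list[0]
        return np.concatenate([np.log(p.exch), np.log(p.sqrt_pi)])
    if kind == "shared_S_column_pi":
        s = np.log(params_list[0].exch)
        rs = [np.log(p.sqrt_pi) for p in params_list]
        return np.concatenate([s, *rs])
    return np.concatenate(
        [np.concatenate([np.log(p.exch), np.log(p.sqrt_pi)]) for p in params_list]
    )


def _unpack(x: np.ndarray, n: int, kind: str, num_models: int) -> list[ReversibleParams]:
    k = n * (n - 1) // 2
    if kind == "global_gtr":
        return [ReversibleParams(n, np.exp(x[:k]), np.exp(x[k : k + n]))]
    if kind == "shared_S_column_pi":
        exch = np.exp(x[:k])
        out = []
        for m in range(num_models):
            r = np.exp(x[k + m * n : k + (m + 1) * n])
            out.append(ReversibleParams(n, exch, r))
        return out
    out = []
    stride = k + n
    for m in range(num_models):
        block = x[m * stride : (m + 1) * stride]
        out.append(ReversibleParams(n, np.exp(block[:k]), np.exp(block[k:])))
    return out


def _default_init(n: int, kind: str, num_models: int, config: FitConfig) -> list[ReversibleParams]:
    base = [
        ReversibleParams(n, np.ones(n * (n - 1) // 2), np.ones(n))
        for _ in range(num_models)
    ]
    if config.init_jitter > 0.0:
        rng = np.random.default_rng(config.seed)
        jittered = []
        for p in base:
            e = p.exch * np.exp(config.init_jitter * rng.standard_normal(p.exch.shape))
            r = p.sqrt_pi * np.exp(config.init_jitter * rng.standard_normal(n))
            jittered.append(ReversibleParams(n, e, r))
        base = jittered
    if kind == "shared_S_column_pi":
        shared = base[0].exch
        base = [ReversibleParams(n, shared, p.sqrt_pi) for p in base]
    return base


def fit(
    tree: PhyloTree,
    profiles: LeafProfiles,
    config: FitConfig,
    init: list[ReversibleParams] | ReversibleParams | None = None,
) -> FitResult:
    """Maximize the tree log likelihood over the chosen model kind.

    ``init`` may be a single parameter set (broadcast to every model) or a
    list with one entry per model; the default is equal exchangeabilities
    and a uniform equilibrium, optionally jittered.
    """
    n = profiles.num_states
    num_cols = profiles.num_columns
    kind = config.model_kind
    num_models = 1 if kind == "global_gtr" else num_cols
    k = n * (n - 1) // 2

    if init is None:
        init_list = _default_init(n, kind, num_models, config)
    elif isinstance(init, ReversibleParams):
        init_list = [init] * num_models
    else:
        init_list = list(init)
        if len(init_list) != num_models:
            raise ValueError(f"init must supply {num_models} parameter sets")

    assignment = None if kind == "global_gtr" else np.arange(num_cols)

    def build_models(params_list: list[ReversibleParams]) -> ColumnModelMap:
        specs = [
            spectral_decompose(p, normalize=config.normalize_rate) for p in params_list
        ]
        return ColumnModelMap(specs, assignment)

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        params_list = _unpack(x, n, kind, num_models)
        bundle = loglik_and_grad(tree, profiles, build_models(params_list))
        grad_blocks = []
        if kind == "global_gtr":
            p = params_list[0]
            grad_blocks.append(bundle.g_exch[0] * p.exch)
            grad_blocks.append(bundle.g_sqrt_pi[0] * p.sqrt_pi)
        elif kind == "shared_S_column_pi":
            exch = params_list[0].exch
            g_s = sum(bundle.g_exch) * exch
            grad_blocks.append(g_s)
            for m, p in enumerate(params_list):
                grad_blocks.append(bundle.g_sqrt_pi[m] * p.sqrt_pi)
        else:
            for m, p in enumerate(params_list):
                grad_blocks.append(bundle.g_exch[m] * p.exch)
                grad_blocks.append(bundle.g_sqrt_pi[m] * p.sqrt_pi)
        grad = np.concatenate(grad_blocks)
        f = -bundle.loglik
        g = -grad
        if config.l2_penalty > 0.0:
            f += config.l2_penalty * float(np.dot(x, x))
            g = g + 2.0 * config.l2_penalty * x
        return f, g

    x0 = _pack(init_list, kind)
    f0, _ = objective(x0)
    trace = [-f0]

    last_f = [f0]

    def wrapped(x: np.ndarray) -> tuple[float, np.ndarray]:
        f, g = objective(x)
        last_f[0] = f
        return f, g

    def callback(_xk: np.ndarray) -> None:
        trace.append(-last_f[0])

    res = minimize(
        wrapped,
        x0,
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={
            "maxiter": config.max_iters,
            "maxcor": 10,
            "ftol": config.rel_improve_tol,
            "gtol": 1e-12,
        },
    )
    params_list = _unpack(res.x, n, kind, num_models)
    final_bundle = loglik_and_grad(tree, profiles, build_models(params_list))
    return FitResult(
        params=params_list,
        loglik=final_bundle.loglik,
        initial_loglik=-f0,
        trace=trace,
        termination=str(res.message),
        n_iterations=int(res.nit),
        n_free_parameters=count_free_parameters(n, kind, num_cols),
        config=config,
    )
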