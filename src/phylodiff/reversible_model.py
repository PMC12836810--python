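"""Time-reversible rate matrices in the (S, sqrt-pi) parametrization.

A reversible continuous-time Markov chain on ``n`` residues is parametrized
by the strictly-upper-triangular exchangeabilities ``s_ij >= 0`` of a
symmetric matrix ``S`` and a positive vector ``sqrt_pi`` whose normalized
squares give the equilibrium distribution ``pi``.  The generator is

    Q = diag(sqrt_pi)^-1 . S . diag(sqrt_pi)

with the diagonal of ``S`` chosen so that every row of ``Q`` sums to zero.
Because ``S`` (with that diagonal) is symmetric it has an orthogonal
eigendecomposition ``S = B Lam B^T``, which yields a real, numerically
stable diagonalization ``Q = A Lam A^-1`` with ``A = diag(sqrt_pi)^-1 B``
and ``A^-1 = B^T diag(sqrt_pi)``.  Everything downstream (transition
matrices, their directional derivatives and adjoints) works on this
spectral form.

The scale of ``sqrt_pi`` is immaterial: ``Q`` and ``pi`` only depend on the
normalized squares.  Entries of ``sqrt_pi`` below 1e-10 are clamped to
1e-10 on entry to keep the conjugation well conditioned; gradients at
clamped coordinates are set to zero (a subgradient choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: entries of sqrt_pi below this are replaced by it
SQRT_PI_CLAMP = 1e-10


class InvalidParameterError(ValueError):
    """Raised for non-finite, negative, or mis-shaped model parameters."""


class NumericalError(RuntimeError):
    """Raised when a numerical kernel produces an unusable result."""


def clamp_sqrt_pi(raw: np.ndarray) -> np.ndarray:
    """Clamp entries of a raw sqrt-pi vector below 1e-10 up to 1e-10.

    Parameters must be finite and non-negative; anything else is a user
    error, not a value to be silently repaired.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise InvalidParameterError("sqrt_pi must be a 1-D vector")
    if not np.all(np.isfinite(raw)):
        raise InvalidParameterError("sqrt_pi entries must be finite")
    if np.any(raw < 0):
        raise InvalidParameterError("sqrt_pi entries must be non-negative")
    return np.maximum(raw, SQRT_PI_CLAMP)


def _triu_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


@dataclass(frozen=True)
class ReversibleParams:
    """Free parameters of a reversible substitution model.

    Attributes
    ----------
    n
        Number of states (4 for nucleotides, 20 for amino acids; any
        ``n >= 2`` is accepted).
    exch
        The ``n(n-1)/2`` exchangeabilities ``s_ij`` (``i < j``) in row-major
        upper-triangular order.  Non-negative.
    sqrt_pi
        Positive vector of length ``n``; clamped at 1e-10 on construction.
        Its scale is arbitrary.
    """

    n: int
    exch: np.ndarray
    sqrt_pi: np.ndarray
    clamp_mask: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        exch = np.asarray(self.exch, dtype=float)
        m = self.n * (self.n - 1) // 2
        if exch.shape != (m,):
            raise InvalidParameterError(
                f"expected {m} exchangeabilities for n={self.n}, got shape {exch.shape}"
            )
        if not np.all(np.isfinite(exch)) or np.any(exch < 0):
            raise InvalidParameterError("exchangeabilities must be finite and >= 0")
        raw = np.asarray(self.sqrt_pi, dtype=float)
        if raw.shape != (self.n,):
            raise InvalidParameterError(
                f"expected sqrt_pi of length {self.n}, got shape {raw.shape}"
            )
        clamped = clamp_sqrt_pi(raw)
        object.__setattr__(self, "exch", exch)
        object.__setattr__(self, "sqrt_pi", clamped)
        object.__setattr__(self, "clamp_mask", raw < SQRT_PI_CLAMP)

    @property
    def pi(self) -> np.ndarray:
        """Equilibrium distribution: normalized squares of sqrt_pi."""
        sq = self.sqrt_pi**2
        return sq / sq.sum()

    def exch_matrix(self) -> np.ndarray:
        """Symmetric matrix with the exchangeabilities off-diagonal, zero diagonal."""
        s = np.zeros((self.n, self.n))
        iu, ju = _triu_indices(self.n)
        s[iu, ju] = self.exch
        s[ju, iu] = self.exch
        return s


@dataclass(frozen=True)
class SpectralForm:
    """Eigendecomposition ``Q = A Lam A^-1`` of a reversible generator.

    ``q`` is the generator that the decomposition reconstructs.  If
    ``normalized`` the generator has been divided by its mean rate
    ``mu = -sum_i pi_i q_ii`` (one expected substitution per unit branch
    length); ``mu`` records the divisor (1.0 otherwise).
    """

    eigvals: np.ndarray
    a: np.ndarray
    a_inv: np.ndarray
    sqrt_pi: np.ndarray
    pi: np.ndarray
    q: np.ndarray
    params: ReversibleParams
    normalized: bool
    mu: float

    @property
    def n(self) -> int:
        return self.a.shape[0]


def stationary_distribution(params: ReversibleParams) -> np.ndarray:
    """Equilibrium distribution pi implied by the sqrt-pi parameters."""
    return params.pi


def build_rate_matrix(params: ReversibleParams, normalize: bool = False) -> np.ndarray:
    """Construct the generator ``Q`` from the parameters.

    Off-diagonal entries are ``q_ij = s_ij * sqrt_pi_j / sqrt_pi_i``; the
    diagonal makes every row sum to zero, which also guarantees detailed
    balance ``pi_i q_ij = pi_j q_ji``.  With ``normalize`` the matrix is
    rescaled to one expected substitution per unit time at equilibrium.
    """
    q = _raw_rate_matrix(params)
    if normalize:
        mu = _mean_rate(params, q)
        q = q / mu
    return q


def _raw_rate_matrix(params: ReversibleParams) -> np.ndarray:
    r = params.sqrt_pi
    q = params.exch_matrix() * (r[None, :] / r[:, None])
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _mean_rate(params: ReversibleParams, q_raw: np.ndarray) -> float:
    mu = -float(np.dot(params.pi, np.diag(q_raw)))
    if mu <= 0.0:
        raise InvalidParameterError(
            "cannot rate-normalize a zero generator (all exchangeabilities are 0)"
        )
    return mu


def spectral_decompose(params: ReversibleParams, normalize: bool = False) -> SpectralForm:
    """Symmetric eigendecomposition of the generator.

    Diagonalizes ``S_full = diag(sqrt_pi) Q diag(sqrt_pi)^-1`` (symmetric:
    exchangeabilities off-diagonal, Q's diagonal on the diagonal) with
    ``numpy.linalg.eigh`` and conjugates the orthogonal eigenvectors back.
    """
    r = params.sqrt_pi
    q_raw = _raw_rate_matrix(params)
    s_full = params.exch_matrix()
    np.fill_diagonal(s_full, np.diag(q_raw))
    mu = 1.0
    if normalize:
        mu = _mean_rate(params, q_raw)
        s_full = s_full / mu
    try:
        eigvals, b = np.linalg.eigh(s_full)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - eigh on symmetric input
        raise NumericalError(
            f"eigendecomposition failed for parameters exch={params.exch!r} "
            f"sqrt_pi={params.sqrt_pi!r}"
        ) from exc
    a = b / r[:, None]
    a_inv = b.T * r[None, :]
    return SpectralForm(
        eigvals=eigvals,
        a=a,
        a_inv=a_inv,
        sqrt_pi=r,
        pi=params.pi,
        q=q_raw / mu,
        params=params,
        normalized=normalize,
        mu=mu,
    )


def backprop_params(
    g_q: np.ndarray,
    params: ReversibleParams,
    g_pi: np.ndarray | None = None,
    normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Pull a gradient w.r.t. the generator back to the free parameters.

    Parameters
    ----------
    g_q
        ``dL/dQ`` where ``Q`` is the generator produced by
        :func:`build_rate_matrix` with the same ``normalize`` flag.
    g_pi
        Optional additional ``dL/dpi`` term (e.g. from a root prior that
        uses the equilibrium distribution directly).
    normalize
        Must match the flag used in the forward build; the chain rule then
        also passes through the mean-rate rescaling.

    Returns
    -------
    (g_exch, g_sqrt_pi)
        Gradients in the natural (unlogged) parameter space.  Coordinates
        of ``sqrt_pi`` that were clamped on entry get zero gradient.
    """
    n = params.n
    g_q = np.asarray(g_q, dtype=float)
    if g_q.shape != (n, n):
        raise InvalidParameterError(f"g_q must be {n}x{n}, got {g_q.shape}")
    if not np.all(np.isfinite(g_q)):
        raise InvalidParameterError("g_q must be finite")
    r = params.sqrt_pi
    pi = params.pi
    q_raw = _raw_rate_matrix(params)

    g_pi_eff = np.zeros(n) if g_pi is None else np.asarray(g_pi, dtype=float).copy()
    if normalize:
        mu = _mean_rate(params, q_raw)
        c = float(np.sum(g_q * q_raw)) / mu**2
        g_eff = g_q / mu + c * np.diag(pi)
        g_pi_eff += c * np.diag(q_raw)
    else:
        g_eff = g_q

    # fold the row-sum constraint: q_ii = -sum_{j != i} q_ij
    h = g_eff - np.diag(g_eff)[:, None]
    np.fill_diagonal(h, 0.0)

    ratio = r[None, :] / r[:, None]
    m = h * ratio
    iu, ju = _triu_indices(n)
    g_exch = m[iu, ju] + m.T[iu, ju]

    hq = h * q_raw  # diagonal of h is zero, so only off-diagonal terms enter
    g_r = (hq.sum(axis=0) - hq.sum(axis=1)) / r

    # pi = r^2 / sum(r^2)
    sq_sum = float(np.sum(r**2))
    g_r += (2.0 * r / sq_sum) * (g_pi_eff - float(np.dot(g_pi_eff, pi)))

    g_r = np.where(params.clamp_mask, 0.0, g_r)
    return g_exch, g_r


# ---------------------------------------------------------------------------
# plain-text serialization


def params_to_text(params: ReversibleParams) -> str:
    """Serialize to the package's whitespace parameter dialect.

    Line 1: ``n``; line 2: the n(n-1)/2 exchangeabilities (row-major upper
    triangle); line 3: the n sqrt_pi values.  Close in spirit to the
    PAML/IQ-TREE rate-matrix layout but carrying sqrt_pi, not pi.
    """
    exch = " ".join(repr(float(v)) for v in params.exch)
    spi = " ".join(repr(float(v)) for v in params.sqrt_pi)
    return f"{params.n}\n{exch}\n{spi}\n"


def params_from_text(text: str) -> ReversibleParams:
    """Inverse of :func:`params_to_text` (any whitespace layout accepted)."""
    tokens = text.split()
    if not tokens:
        raise InvalidParameterError("empty parameter file")
    try:
        n = int(tokens[0])
    except ValueError as exc:
        raise InvalidParameterError(f"bad state count {tokens[0]!r}") from exc
    m = n * (n - 1) // 2
    values = tokens[1:]
    if len(values) != m + n:
        raise InvalidParameterError(
            f"expected {m} exchangeabilities + {n} sqrt_pi values, got {len(values)} numbers"
        )
    arr = np.array([float(v) for v in values])
    return ReversibleParams(n=n, exch=arr[:m], sqrt_pi=arr[m:])
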