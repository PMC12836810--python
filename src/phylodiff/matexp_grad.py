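"""Transition matrices and their derivatives through the spectral form.

Given a diagonalization ``Q = A Lam A^-1`` the transition matrix over a
branch of length ``t`` is ``P(t) = A exp(Lam t) A^-1`` — two matrix
multiplications instead of a full matrix exponential.  The directional
(Fréchet) derivative of ``Q -> e^{Qt}`` along ``E`` is

    D(E) = A (A^-1 E A  (.)  X(Lam, t)) A^-1

where ``(.)`` is the Hadamard product and ``X`` is the divided-difference
matrix

    X_ii = t e^{t lam_i},      X_ij = (e^{t lam_i} - e^{t lam_j}) / (lam_i - lam_j).

The adjoint (transposed Jacobian), which carries a downstream gradient
``G = dL/dP(t)`` back to ``dL/dQ`` in reverse-mode differentiation, is

    D*(G) = A^-T (A^T G A^-T  (.)  X(Lam, t)) A^T,

again four matrix multiplications.  When many branches share one ``Q`` the
two outer multiplications can be factored out of the per-branch sum, which
is what :func:`expm_adjoint_inner` exposes.

The naive divided-difference quotient cancels catastrophically as
``lam_i -> lam_j``.  We evaluate it in the equivalent symmetric form

    X_ij = t * exp(t (lam_i + lam_j) / 2) * sinch(t (lam_i - lam_j) / 2),

``sinch(z) = sinh(z)/z`` (``sinch(0) = 1``), which is branch-free,
continuous in the eigenvalue gap, and accurate down to coincident
eigenvalues.  For very large gaps (|z| beyond the sinh overflow range,
which well-scaled generators never reach) the plain quotient — harmless
there — is used instead.
"""

from __future__ import annotations

import numpy as np

from .reversible_model import NumericalError, SpectralForm

#: above this |t*gap/2| the sinch product risks overflow; quotient takes over
_SINCH_OVERFLOW = 350.0

#: transition-matrix entries below this are a decomposition failure
_NEGATIVE_ENTRY_LIMIT = -1e-8


def phi_matrix(eigvals: np.ndarray, t: float) -> np.ndarray:
    """Divided-difference matrix ``X(Lam, t)`` of the spectral Fréchet formula.

    Symmetric, with ``X_ii = t exp(t lam_i)`` and off-diagonal entries the
    divided differences of ``exp(t .)``; finite and continuous for any real
    eigenvalues and ``t >= 0``, including repeated eigenvalues.
    """
    lam = np.asarray(eigvals, dtype=float)
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    mean = 0.5 * t * (lam[:, None] + lam[None, :])
    half_gap = 0.5 * t * (lam[:, None] - lam[None, :])
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        sinch = np.where(half_gap == 0.0, 1.0, np.sinh(half_gap) / half_gap)
        x = t * np.exp(mean) * sinch
        big = np.abs(half_gap) > _SINCH_OVERFLOW
        if np.any(big):
            diff = np.exp(t * lam[:, None]) - np.exp(t * lam[None, :])
            gap = lam[:, None] - lam[None, :]
            x = np.where(big, diff / gap, x)
    return x


def expm_spectral(spec: SpectralForm, t: float) -> np.ndarray:
    """Transition matrix ``P(t) = A exp(Lam t) A^-1``.

    Round-off can leave entries marginally outside [0, 1]; overshoots
    smaller than 1e-8 are clipped without renormalizing rows (row sums stay
    exact to first order), larger ones indicate a broken decomposition and
    raise :class:`NumericalError`.
    """
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    p = (spec.a * np.exp(spec.eigvals * t)) @ spec.a_inv
    low = p.min()
    if low < _NEGATIVE_ENTRY_LIMIT:
        raise NumericalError(
            f"transition matrix entry {low:g} at t={t}: spectral decomposition unusable"
        )
    if low < 0.0 or p.max() > 1.0:
        p = np.clip(p, 0.0, 1.0)
    return p


def frechet_forward(spec: SpectralForm, d_q: np.ndarray, t: float) -> np.ndarray:
    """Directional derivative of ``Q -> e^{Qt}`` along ``d_q`` (forward mode)."""
    d_q = np.asarray(d_q, dtype=float)
    n = spec.n
    if d_q.shape != (n, n):
        raise ValueError(f"d_q must be {n}x{n}, got {d_q.shape}")
    x = phi_matrix(spec.eigvals, t)
    return spec.a @ ((spec.a_inv @ d_q @ spec.a) * x) @ spec.a_inv


def expm_adjoint(spec: SpectralForm, g_p: np.ndarray, t: float) -> np.ndarray:
    """Adjoint of the Fréchet derivative: maps ``dL/dP(t)`` to ``dL/dQ``.

    Satisfies ``<frechet_forward(M), N> = <M, expm_adjoint(N)>`` under the
    trace inner product for all matrices M, N.
    """
    inner = expm_adjoint_inner(spec, g_p, t)
    return spec.a_inv.T @ inner @ spec.a.T


def expm_adjoint_inner(spec: SpectralForm, g_p: np.ndarray, t: float) -> np.ndarray:
    """Branch-local part ``A^T g_p A^-T (.) X(Lam, t)`` of the adjoint.

    Callers accumulating gradients over many branches that share one
    generator sum these inner terms and apply the two outer multiplications
    ``A^-T (sum) A^T`` once.
    """
    g_p = np.asarray(g_p, dtype=float)
    n = spec.n
    if g_p.shape != (n, n):
        raise ValueError(f"g_p must be {n}x{n}, got {g_p.shape}")
    x = phi_matrix(spec.eigvals, t)
    return (spec.a.T @ g_p @ spec.a_inv.T) * x


def adjoint_outer(spec: SpectralForm, inner_sum: np.ndarray) -> np.ndarray:
    """Apply the factored-out outer transform to a summed inner term."""
    return spec.a_inv.T @ inner_sum @ spec.a.T
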