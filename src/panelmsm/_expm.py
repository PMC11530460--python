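"""Batched matrix exponentials and their adjoints for small dense matrices.

The likelihood evaluates thousands of 4x4 matrix exponentials per call;
``expm_batch`` vectorises scaling-and-squaring with a truncated Taylor
series over a leading batch axis, and ``expm_vjp`` provides the exact
reverse-mode adjoint via the block-triangular Frechet identity

    expm([[A, E], [0, A]]) = [[expm(A), L(A, E)], [0, expm(A)]].

Both are dtype-generic (complex-step safe).
"""

from __future__ import annotations

import numpy as np

_TAYLOR_TERMS = 16  # ||B|| <= 0.5 => truncation error < 0.5^16/16! ~ 7e-19


def expm_batch(A: np.ndarray) -> np.ndarray:
    """exp(A[i]) for a stack of square matrices A with shape (..., n, n).

    Scaling-and-squaring with per-matrix scaling chosen from the infinity
    norm, followed by a fixed-order Taylor series on the scaled matrices.
    """
    A = np.asarray(A)
    n = A.shape[-1]
    norm = np.abs(A).sum(axis=-1).max(axis=-1)  # infinity norm per matrix
    with np.errstate(divide="ignore"):
        s = np.ceil(np.log2(np.maximum(norm, 1e-300))).astype(int) + 1
    s = np.maximum(s, 0)
    scale = (2.0 ** s)[..., None, None]
    B = A / scale
    eye = np.broadcast_to(np.eye(n, dtype=A.dtype), A.shape).copy()
    term = eye.copy()
    S = eye.copy()
    for k in range(1, _TAYLOR_TERMS + 1):
        term = np.matmul(term, B) / k
        S = S + term
    smax = int(s.max()) if s.size else 0
    for i in range(smax):
        mask = s > i
        S[mask] = np.matmul(S[mask], S[mask])
    return S


def expm_batch_cached(A: np.ndarray):
    """Like :func:`expm_batch` but also returns a cache of intermediates
    for :func:`expm_batch_vjp` (reverse-mode differentiation)."""
    A = np.asarray(A)
    n = A.shape[-1]
    norm = np.abs(A).sum(axis=-1).max(axis=-1)
    with np.errstate(divide="ignore"):
        s = np.ceil(np.log2(np.maximum(norm, 1e-300))).astype(int) + 1
    s = np.maximum(s, 0)
    scale = (2.0 ** s)[..., None, None]
    B = A / scale
    eye = np.broadcast_to(np.eye(n, dtype=A.dtype), A.shape).copy()
    terms = [eye]
    S = eye.copy()
    for k in range(1, _TAYLOR_TERMS + 1):
        terms.append(np.matmul(terms[-1], B) / k)
        S = S + terms[-1]
    smax = int(s.max()) if s.size else 0
    squarings = []
    for i in range(smax):
        mask = s > i
        pre = S[mask].copy()
        squarings.append((mask, pre))
        S[mask] = np.matmul(pre, pre)
    cache = (B, scale, terms, squarings)
    return S, cache


def expm_batch_vjp(cache, grad_out: np.ndarray) -> np.ndarray:
    """Reverse-mode adjoint of :func:`expm_batch_cached`: maps the
    cotangent of exp(A) back to the cotangent of A."""
    B, scale, terms, squarings = cache
    bar = np.array(grad_out, copy=True)
    for mask, pre in reversed(squarings):
        preT = np.swapaxes(pre, -1, -2)
        bar[mask] = np.matmul(preT, bar[mask]) + np.matmul(bar[mask], preT)
    # Taylor chain: t_k = t_{k-1} @ B / k, S = sum_k t_k
    Bt = np.swapaxes(B, -1, -2)
    bar_B = np.zeros_like(B)
    u = bar.copy()  # cotangent of t_K
    for k in range(_TAYLOR_TERMS - 1, -1, -1):
        bar_B += np.matmul(np.swapaxes(terms[k], -1, -2), u) / (k + 1)
        u = bar + np.matmul(u, Bt) / (k + 1)
    return bar_B / scale


def expm_vjp(A: np.ndarray, grad_out: np.ndarray) -> np.ndarray:
    """Adjoint of ``expm``: given ``Wbar = d(loss)/d(expm(A))`` return
    ``d(loss)/dA = L(A^T, Wbar)`` for a batch of matrices.

    Each pair is embedded in a 2n x 2n block-triangular matrix whose
    exponential's upper-right block is the Frechet derivative. ``Wbar`` is
    normalised per matrix before the embedding (the map is linear in
    ``Wbar``) so badly scaled cotangents do not degrade accuracy.
    """
    A = np.asarray(A)
    W = np.asarray(grad_out)
    n = A.shape[-1]
    wnorm = np.abs(W).sum(axis=-1).max(axis=-1)
    wnorm = np.maximum(wnorm, 1e-300)
    Wn = W / wnorm[..., None, None]
    At = np.swapaxes(A, -1, -2)
    block = np.zeros(A.shape[:-2] + (2 * n, 2 * n), dtype=np.result_type(A, W))
    block[..., :n, :n] = At
    block[..., n:, n:] = At
    block[..., :n, n:] = Wn
    full = expm_batch(block)
    return full[..., :n, n:] * wnorm[..., None, None]
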