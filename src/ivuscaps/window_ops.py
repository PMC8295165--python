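"""Fused windowed-routing contractions.

The locally constrained routing loop needs three contractions between the
per-position transformed children ``F[H, W, T, J, D]`` (padded; T child
types, J parent types, D flattened capsule entries), the per-window
coefficients ``C[Ho, Wo, k, k, T, J]`` and the parents ``Y[Ho, Wo, J, D]``:

* weighted sum       ``S[h,w,j,:]  = sum_{a,b,t} C[h,w,a,b,t,j] * F[h*s+a, w*s+b, t, j, :]``
* agreement          ``A[h,w,a,b,t,j] = <F[h*s+a, w*s+b, t, j, :], Y[h,w,j,:]>``
* scatter (backward) ``G[p,q,t,j,:] += sum C[h,w,a,b,t,j] * Y[h,w,j,:]`` over windows hitting (p, q)

Materializing the windowed child tensor (k^2 times the compact one) for
these would dominate runtime and memory; the numba kernels below walk the
compact tensor in place instead.  The three kernels are mutually each
other's adjoints, so both differentiable ops are built from the same
trio:

* ``window_weighted_sum``: forward = sum kernel; gradients = agreement
  kernel (for the coefficients) and scatter kernel (for the children).
* ``window_agreement``: forward = agreement kernel; gradients = scatter
  kernel (children) and sum kernel (parents).

All kernels are exact (plain multiply-accumulate loops, no fastmath), so
they agree with the explicit-loop oracles to float roundoff.
"""

from __future__ import annotations

import numba
import numpy as np

from .autodiff import Tensor, _make

__all__ = ["window_weighted_sum", "window_agreement", "capsule_transform"]


@numba.njit(cache=True)
def _t_fwd(X, W):  # [H,W,T,a,b] x [T,J,b,c] -> [H,W,T,J,a,c]
    h_n, w_n, t_n, a_n, b_n = X.shape
    j_n, c_n = W.shape[1], W.shape[3]
    out = np.zeros((h_n, w_n, t_n, j_n, a_n, c_n), dtype=X.dtype)
    for h in range(h_n):
        for w in range(w_n):
            for t in range(t_n):
                for j in range(j_n):
                    for a in range(a_n):
                        for b in range(b_n):
                            x = X[h, w, t, a, b]
                            for c in range(c_n):
                                out[h, w, t, j, a, c] += x * W[t, j, b, c]
    return out


@numba.njit(cache=True)
def _t_bwd_x(G, W):  # -> [H,W,T,a,b]
    h_n, w_n, t_n, j_n, a_n, c_n = G.shape
    b_n = W.shape[2]
    out = np.zeros((h_n, w_n, t_n, a_n, b_n), dtype=G.dtype)
    for h in range(h_n):
        for w in range(w_n):
            for t in range(t_n):
                for j in range(j_n):
                    for a in range(a_n):
                        for b in range(b_n):
                            acc = 0.0
                            for c in range(c_n):
                                acc += G[h, w, t, j, a, c] * W[t, j, b, c]
                            out[h, w, t, a, b] += acc
    return out


@numba.njit(cache=True)
def _t_bwd_w(X, G):  # -> [T,J,b,c]
    h_n, w_n, t_n, a_n, b_n = X.shape
    j_n, c_n = G.shape[3], G.shape[5]
    out = np.zeros((t_n, j_n, b_n, c_n), dtype=X.dtype)
    for h in range(h_n):
        for w in range(w_n):
            for t in range(t_n):
                for j in range(j_n):
                    for a in range(a_n):
                        for b in range(b_n):
                            x = X[h, w, t, a, b]
                            for c in range(c_n):
                                out[t, j, b, c] += x * G[h, w, t, j, a, c]
    return out


def capsule_transform(x: Tensor, w: Tensor) -> Tensor:
    """Right-multiply every grid capsule by its per-(child, parent) matrix:
    ``out[h,w,t,j] = X[h,w,t] @ W[t,j]`` for ``X [H,W,T,s,s]`` and a bank
    ``W [T,J,s,s]``, giving ``[H,W,T,J,s,s]``."""
    X = np.ascontiguousarray(x.data)
    W = np.ascontiguousarray(w.data)

    def backward(g):
        g = np.ascontiguousarray(g)
        return (_t_bwd_x(g, W), _t_bwd_w(X, g))

    return _make(_t_fwd(X, W), (x, w), backward)


@numba.njit(cache=True)
def _k_sum(C, F, stride):  # -> [Ho, Wo, J, D]
    ho, wo, k, _, t_types, j_types = C.shape
    d = F.shape[-1]
    out = np.zeros((ho, wo, j_types, d), dtype=F.dtype)
    for h in range(ho):
        for w in range(wo):
            for a in range(k):
                for b in range(k):
                    for t in range(t_types):
                        for j in range(j_types):
                            c = C[h, w, a, b, t, j]
                            if c != 0.0:
                                for e in range(d):
                                    out[h, w, j, e] += \
                                        c * F[h * stride + a, w * stride + b,
                                              t, j, e]
    return out


@numba.njit(cache=True)
def _k_agree(F, Y, k, stride):  # -> [Ho, Wo, k, k, T, J]
    ho, wo, j_types, d = Y.shape
    t_types = F.shape[2]
    out = np.zeros((ho, wo, k, k, t_types, j_types), dtype=F.dtype)
    for h in range(ho):
        for w in range(wo):
            for a in range(k):
                for b in range(k):
                    for t in range(t_types):
                        for j in range(j_types):
                            acc = 0.0
                            for e in range(d):
                                acc += F[h * stride + a, w * stride + b,
                                         t, j, e] * Y[h, w, j, e]
                            out[h, w, a, b, t, j] = acc
    return out


@numba.njit(cache=True)
def _k_scatter(C, Y, hp, wp, stride):  # -> [Hp, Wp, T, J, D]
    ho, wo, k, _, t_types, j_types = C.shape
    d = Y.shape[-1]
    out = np.zeros((hp, wp, t_types, j_types, d), dtype=Y.dtype)
    for h in range(ho):
        for w in range(wo):
            for a in range(k):
                for b in range(k):
                    for t in range(t_types):
                        for j in range(j_types):
                            c = C[h, w, a, b, t, j]
                            if c != 0.0:
                                for e in range(d):
                                    out[h * stride + a, w * stride + b,
                                        t, j, e] += c * Y[h, w, j, e]
    return out


def _contiguous(t: Tensor) -> np.ndarray:
    return np.ascontiguousarray(t.data)


def window_weighted_sum(flat: Tensor, coeffs: Tensor, stride: int = 1) -> Tensor:
    """Coefficient-weighted sum of windowed children.

    ``flat``: padded children ``[Hp, Wp, T, J, D]``; ``coeffs``:
    ``[Ho, Wo, k, k, T, J]``.  Returns ``[Ho, Wo, J, D]``.
    """
    F = _contiguous(flat)
    C = _contiguous(coeffs)
    hp, wp = F.shape[:2]
    k = C.shape[2]

    def backward(g):
        g = np.ascontiguousarray(g)
        return (_k_scatter(C, g, hp, wp, stride), _k_agree(F, g, k, stride))

    return _make(_k_sum(C, F, stride), (flat, coeffs), backward)


def window_agreement(flat: Tensor, parents: Tensor, window: int,
                     stride: int = 1) -> Tensor:
    """Inner products between every windowed child and its parent.

    ``flat``: padded children ``[Hp, Wp, T, J, D]``; ``parents``:
    ``[Ho, Wo, J, D]``.  Returns ``[Ho, Wo, k, k, T, J]``.
    """
    F = _contiguous(flat)
    Y = _contiguous(parents)
    hp, wp = F.shape[:2]

    def backward(g):
        g = np.ascontiguousarray(g)
        return (_k_scatter(g, Y, hp, wp, stride), _k_sum(g, F, stride))

    return _make(_k_agree(F, Y, window, stride), (flat, parents), backward)
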