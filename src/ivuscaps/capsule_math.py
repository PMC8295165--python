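"""Closed-form capsule primitives and iterative routing.

A *capsule* is a small tensor (a vector, or a pose/appearance matrix pair)
whose magnitude signals the presence of an entity and whose entries encode
its properties.  Child capsules in one layer are coupled to parent capsules
in the next by an iterative routing procedure that assigns each child a
probability distribution over parents.

Two routing algorithms are provided:

* **dynamic routing** for vector capsules — agreement is the dot product
  between a transformed child and the squashed parent;
* **dual routing** for matrix capsules carrying a pose matrix (geometry)
  and an appearance matrix (texture) — one shared coefficient set couples
  both streams, and the agreement is the sum of the two Frobenius inner
  products.

All functions accept plain numpy arrays or autodiff tensors and return the
same kind; inside a network they run on tensors so that every routing
iteration stays in the differentiated graph.

Shape conventions: routing operates on the last axes
``[..., n_children, n_parents, capsule_dims...]``; arbitrary leading axes
(e.g. a spatial grid) are broadcast over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, astensor

__all__ = [
    "RoutingSpec", "PoseTreatment", "TransformParams",
    "squash", "psquash", "transform_pose", "transform_appearance",
    "normalize_pose", "add_coordinates", "route_dynamic", "route_dual",
]

_PSQUASH_FLOOR = 1e-12
_SQUASH_EPS = 1e-16

POSE_TREATMENT_MODES = (
    "normalize_transform_with_coords",
    "normalize_pose_with_coords",
    "normalize_pose_no_coords",
    "none",
)


@dataclass(frozen=True)
class RoutingSpec:
    """Configuration of the child-to-parent routing procedure."""

    algorithm: str = "dual"          # {"dynamic", "dual"}
    iterations: int = 3
    window: int = 5                  # spatial window of locally constrained routing
    stride: int = 1

    def __post_init__(self):
        if self.algorithm not in ("dynamic", "dual"):
            raise ValueError(f"unknown routing algorithm {self.algorithm!r}")
        if self.iterations < 1:
            raise ValueError("routing iterations must be >= 1")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("routing window must be a positive odd integer")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass(frozen=True)
class PoseTreatment:
    """How pose information is conditioned before routing.

    ``normalize_pose_with_coords`` (normalize the pose matrix columns, then
    add scaled receptive-field coordinates) is the variant that performs
    best on vessel-wall segmentation; ``normalize_transform_with_coords``
    normalizes the transformation matrix instead, and ``none`` leaves poses
    untouched.
    """

    mode: str = "normalize_pose_with_coords"
    coord_scale: float = 1.0

    def __post_init__(self):
        if self.mode not in POSE_TREATMENT_MODES:
            raise ValueError(f"unknown pose treatment mode {self.mode!r}")
        if self.coord_scale < 0:
            raise ValueError("coord_scale must be >= 0")

    @property
    def normalizes_transform(self) -> bool:
        return self.mode == "normalize_transform_with_coords"

    @property
    def normalizes_pose(self) -> bool:
        return self.mode in ("normalize_pose_with_coords", "normalize_pose_no_coords")

    @property
    def adds_coordinates(self) -> bool:
        return self.mode in ("normalize_transform_with_coords",
                             "normalize_pose_with_coords")


@dataclass
class TransformParams:
    """Learnable transform of one (child type, parent type) pair.

    One instance per pair, shared across all spatial positions and window
    offsets.  ``appearance_bias`` is a scalar added entrywise before the
    appearance transform; a full-matrix bias is available via
    ``matrix_bias=True`` at layer level.
    """

    pose_transform: np.ndarray
    appearance_transform: np.ndarray
    appearance_bias: float = 0.0

    def __post_init__(self):
        self.pose_transform = np.asarray(self.pose_transform, dtype=float)
        self.appearance_transform = np.asarray(self.appearance_transform, dtype=float)
        for name in ("pose_transform", "appearance_transform"):
            m = getattr(self, name)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"{name} must be a square matrix")


def _prepare(x, check: bool = True):
    """Return (tensor, was_array).  Finiteness is only checked on arrays."""
    if isinstance(x, Tensor):
        return x, False
    arr = np.asarray(x, dtype=float)
    if check and not np.all(np.isfinite(arr)):
        raise ValueError("input contains non-finite entries")
    return Tensor(arr), True


def _result(t: Tensor, was_array: bool):
    return t.data if was_array else t


def _capsule_axes(x: Tensor, axis):
    if axis is None:
        return tuple(range(x.ndim))
    if isinstance(axis, int):
        return (axis,)
    return tuple(axis)


def squash(x, axis=None):
    """Norm-bounding nonlinearity ``v = (n² / (1 + n²)) · x / n``, ``n = ‖x‖``.

    The Euclidean (vector) or Frobenius (matrix) norm of the output is
    ``n² / (1 + n²) < 1``; the direction of ``x`` is preserved and the zero
    input maps to zero.  ``axis`` selects the axes that make up a single
    capsule (default: the whole tensor); reduction is over those axes with
    broadcasting over the rest.
    """
    t, was_array = _prepare(x)
    axes = _capsule_axes(t, axis)
    s = ad.tsum(ad.square(t), axis=axes, keepdims=True)
    factor = ad.sqrt(s + _SQUASH_EPS) / (1.0 + s)
    return _result(t * factor, was_array)


def psquash(m, axis=(-2, -1)):
    """Pose nonlinearity: divide by the maximum absolute entry.

    For nonzero input the output's largest absolute entry is exactly 1; the
    all-zero matrix is mapped to itself (the denominator is floored at a
    small positive value instead of dividing by zero).
    """
    t, was_array = _prepare(m)
    axes = _capsule_axes(t, axis)
    denom = ad.maximum(ad.amax(ad.absolute(t), axis=axes, keepdims=True),
                       _PSQUASH_FLOOR)
    return _result(t / denom, was_array)


def transform_pose(pose, params):
    """Map a child pose into a parent frame: ``P̂ = P · Wᴾ``."""
    w = params.pose_transform if isinstance(params, TransformParams) else params
    t, was_array = _prepare(pose)
    wt, w_arr = _prepare(w)
    if t.shape[-1] != wt.shape[-2]:
        raise ValueError(
            f"pose side {t.shape[-1]} does not match transform side {wt.shape[-2]}")
    return _result(ad.matmul(t, wt), was_array and w_arr)


def transform_appearance(appearance, params, bias=None):
    """Map a child appearance into a parent frame: ``Â = (A + b) · Wᴬ``.

    ``b`` is a learnable scalar added entrywise (broadcast matrix biases are
    accepted too).
    """
    if isinstance(params, TransformParams):
        w, b = params.appearance_transform, params.appearance_bias
    else:
        w, b = params, (0.0 if bias is None else bias)
    t, was_array = _prepare(appearance)
    wt, w_arr = _prepare(w)
    if t.shape[-1] != wt.shape[-2]:
        raise ValueError(
            f"appearance side {t.shape[-1]} does not match transform side {wt.shape[-2]}")
    b = b if isinstance(b, Tensor) else float(b) if np.isscalar(b) else astensor(b)
    return _result(ad.matmul(t + b, wt), was_array and w_arr)


def normalize_pose(matrix, treatment: PoseTreatment | None = None):
    """Scale every column of a pose (or pose-transform) matrix to unit length.

    Zero columns are left at zero; with ``treatment.mode == "none"`` the
    input is returned unchanged.  Columns live on the second-to-last axis's
    complement, i.e. the norm is taken down each column (over rows).
    """
    if treatment is not None and treatment.mode == "none":
        return matrix
    t, was_array = _prepare(matrix)
    norms = ad.sqrt(ad.tsum(ad.square(t), axis=-2, keepdims=True))
    return _result(t / ad.maximum(norms, _PSQUASH_FLOOR), was_array)


def add_coordinates(pose, position, scale: float = 1.0):
    """Add scaled receptive-field-center coordinates to the last pose column.

    ``position`` is the (row, col) center of the capsule's receptive field,
    normalized to [0, 1] over the feature grid; ``scale * row`` and
    ``scale * col`` are added to the first two entries of the last column.
    """
    row, col = float(position[0]), float(position[1])
    if not (0.0 <= row <= 1.0 and 0.0 <= col <= 1.0):
        raise ValueError("position must be normalized to [0, 1]")
    t, was_array = _prepare(pose)
    offset = np.zeros(t.shape[-2:], dtype=t.dtype)
    offset[0, -1] = scale * row
    offset[1, -1] = scale * col
    return _result(t + offset, was_array)


def _check_children(shape, cap_ndim: int):
    if len(shape) < cap_ndim + 2:
        raise ValueError("routing input needs [..., children, parents, capsule] axes")
    ni, nj = shape[-cap_ndim - 2], shape[-cap_ndim - 1]
    if ni < 1:
        raise ValueError("routing requires at least one child capsule")
    if nj < 1:
        raise ValueError("routing requires at least one parent capsule")
    return ni, nj


def _flat_activate(s: Tensor, pose_entries: int | None) -> Tensor:
    """Apply the nonlinearity on flattened parent capsules ``[Z, Nj, D]``.

    Dual mode (``pose_entries`` set): Psquash on the leading pose block,
    squash on the appearance block.  Dynamic mode: squash on the whole
    vector.  Both norms are invariant to the flattening.
    """
    if pose_entries is None:
        return squash(s, axis=-1)
    pose_flat = psquash(ad.narrow(s, 0, pose_entries), axis=-1)
    app_flat = squash(ad.narrow(s, pose_entries, s.shape[-1]), axis=-1)
    return ad.concatenate([pose_flat, app_flat], axis=-1)


def _route_flat(x: Tensor, spec: RoutingSpec, pose_entries: int | None):
    """Shared routing loop on flattened children ``[Z, Ni, Nj, D]``.

    Coupling logits start at zero, so the first iteration's coefficients
    are exactly uniform (softmax of zeros) and are treated as a constant.
    The logit update after the final iteration is skipped: it could no
    longer influence the returned parents or coefficients.
    """
    z, ni, nj, d = x.shape
    logits = None
    coeffs = None
    parents = None
    for it in range(spec.iterations):
        if logits is None:
            s = ad.tsum(x, axis=1) * (1.0 / nj)          # uniform coefficients
        else:
            coeffs = ad.softmax(logits, axis=-1)         # [Z, Ni, Nj]
            s = ad.einsum("zij,zijd->zjd", coeffs, x)
        parents = _flat_activate(s, pose_entries)
        if it < spec.iterations - 1:
            agree = ad.einsum("zijd,zjd->zij", x, parents)
            logits = agree if logits is None else logits + agree
    if coeffs is None:
        coeffs = Tensor(np.full((z, ni, nj), 1.0 / nj, dtype=x.dtype))
    return parents, coeffs


def route_dynamic(children, spec: RoutingSpec):
    """Dynamic routing-by-agreement for vector capsules.

    ``children`` holds the transformed child vectors ``û_{j|i}`` with shape
    ``[..., n_children, n_parents, d]``.  Coupling logits start at zero each
    forward pass; per iteration the coefficients are the softmax of the
    logits over parents, parents are the squashed coefficient-weighted sums,
    and the logits grow by the child-parent dot-product agreement.

    Returns ``(parents, coefficients)`` with shapes
    ``[..., n_parents, d]`` and ``[..., n_children, n_parents]``; for every
    child the coefficients are nonnegative and sum to 1 over parents.
    """
    if spec.algorithm != "dynamic":
        raise ValueError("route_dynamic requires spec.algorithm == 'dynamic'")
    t, was_array = _prepare(children)
    ni, nj = _check_children(t.shape, 1)
    lead = t.shape[:-3]
    d = t.shape[-1]
    x = ad.reshape(t, (-1, ni, nj, d))
    parents, coeffs = _route_flat(x, spec, pose_entries=None)
    parents = ad.reshape(parents, lead + (nj, d))
    coeffs = ad.reshape(coeffs, lead + (ni, nj))
    return (_result(parents, was_array), _result(coeffs, was_array))


def route_dual(children_pose, children_appearance, spec: RoutingSpec):
    """Dual routing for matrix capsules.

    ``children_pose`` (``[..., i, j, pP, pP]``) and ``children_appearance``
    (``[..., i, j, pA, pA]``) are the transformed child matrices ``P̂_{j|i}``
    and ``Â_{j|i}``; they must be index-aligned.  A single coefficient set
    couples both streams.  Per iteration::

        c    = softmax(logits) over parents
        P̃_j  = Σ_i c_ij P̂_{j|i}          Ã_j = Σ_i c_ij Â_{j|i}
        P_j  = Psquash(P̃_j)              A_j = squash(Ã_j)
        logits += ⟨P̂_{j|i}, P_j⟩_F + ⟨Â_{j|i}, A_j⟩_F

    Returns ``(parent_pose, parent_appearance, coefficients)``.
    """
    if spec.algorithm != "dual":
        raise ValueError("route_dual requires spec.algorithm == 'dual'")
    tp, p_arr = _prepare(children_pose)
    ta, a_arr = _prepare(children_appearance)
    was_array = p_arr and a_arr
    _check_children(tp.shape, 2)
    _check_children(ta.shape, 2)
    if tp.shape[:-2] != ta.shape[:-2]:
        raise ValueError(
            f"pose children {tp.shape[:-2]} and appearance children {ta.shape[:-2]} "
            "are not index-aligned")
    lead = tp.shape[:-4]
    ni, nj = tp.shape[-4], tp.shape[-3]
    p, q = tp.shape[-1], ta.shape[-1]
    x = ad.concatenate([ad.reshape(tp, (-1, ni, nj, p * p)),
                        ad.reshape(ta, (-1, ni, nj, q * q))], axis=-1)
    parents, coeffs = _route_flat(x, spec, pose_entries=p * p)
    pose_out = ad.reshape(ad.narrow(parents, 0, p * p), lead + (nj, p, p))
    app_out = ad.reshape(ad.narrow(parents, p * p, p * p + q * q),
                         lead + (nj, q, q))
    coeffs = ad.reshape(coeffs, lead + (ni, nj))
    return (_result(pose_out, p_arr), _result(app_out, a_arr),
            _result(coeffs, was_array))
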