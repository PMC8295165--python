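"""Shared fixtures and independent reference implementations.

The reference (oracle) functions below use explicit python loops and no
code from the package's routing/layer implementations; tests compare the
vectorized implementation against them on small random instances.
"""

from __future__ import annotations

import numpy as np
import pytest

from ivuscaps.capsule_math import RoutingSpec
from ivuscaps.capsule_network import ArchitectureConfig


# --------------------------------------------------------------------------
# reference implementations
# --------------------------------------------------------------------------

def ref_squash(x):
    n = np.linalg.norm(x)
    if n == 0:
        return np.zeros_like(x)
    return x * n / (1.0 + n * n)


def ref_psquash(m):
    d = np.abs(m).max()
    return m / d if d > 1e-12 else m


def ref_route_dynamic(u_hat, iterations):
    """Step-by-step dynamic routing: u_hat [Ni, Nj, d]."""
    ni, nj, _ = u_hat.shape
    logits = np.zeros((ni, nj))
    for it in range(iterations):
        coeffs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        parents = np.zeros((nj, u_hat.shape[2]))
        for j in range(nj):
            s = sum(coeffs[i, j] * u_hat[i, j] for i in range(ni))
            parents[j] = ref_squash(s)
        if it < iterations - 1:
            for i in range(ni):
                for j in range(nj):
                    logits[i, j] += u_hat[i, j] @ parents[j]
    return parents, coeffs


def ref_route_dual(p_hat, a_hat, iterations):
    """Step-by-step dual routing: p_hat [Ni, Nj, pP, pP], a_hat [Ni, Nj, pA, pA]."""
    ni, nj = p_hat.shape[:2]
    logits = np.zeros((ni, nj))
    for it in range(iterations):
        coeffs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        pose = np.zeros((nj,) + p_hat.shape[2:])
        app = np.zeros((nj,) + a_hat.shape[2:])
        for j in range(nj):
            pt = sum(coeffs[i, j] * p_hat[i, j] for i in range(ni))
            at = sum(coeffs[i, j] * a_hat[i, j] for i in range(ni))
            pose[j] = ref_psquash(pt)
            app[j] = ref_squash(at)
        if it < iterations - 1:
            for i in range(ni):
                for j in range(nj):
                    logits[i, j] += ((p_hat[i, j] * pose[j]).sum()
                                     + (a_hat[i, j] * app[j]).sum())
    return pose, app, coeffs


def ref_conv_capsule_layer(pose, app, wp, wa, bias, window, iterations,
                           stride=1, algorithm="dual",
                           treatment="normalize_pose_with_coords",
                           coord_scale=1.0):
    """Quadruple-loop reference of the locally constrained routing layer.

    Children are all capsules of all types in the window around each output
    position (zero capsules outside the grid); transforms are shared across
    positions and offsets; pose treatment and coordinate addition follow
    the layer contract (normalization of the transformed pose, coordinates
    of the child's own position).
    """
    h, w, ti = pose.shape[:3]
    to = wp.shape[1]
    p, q = pose.shape[-1], app.shape[-1]
    half = (window - 1) // 2
    wp_used = wp.copy()
    if treatment == "normalize_transform_with_coords":
        for i in range(ti):
            for j in range(to):
                for col in range(p):
                    n = np.linalg.norm(wp_used[i, j][:, col])
                    if n > 1e-12:
                        wp_used[i, j][:, col] /= n
    p_hat = np.zeros((h, w, ti, to, p, p))
    a_hat = np.zeros((h, w, ti, to, q, q))
    for r in range(h):
        for c in range(w):
            for i in range(ti):
                for j in range(to):
                    pm = pose[r, c, i] @ wp_used[i, j]
                    if treatment in ("normalize_pose_with_coords",
                                     "normalize_pose_no_coords"):
                        for col in range(p):
                            n = np.linalg.norm(pm[:, col])
                            if n > 1e-12:
                                pm[:, col] = pm[:, col] / n
                    if treatment in ("normalize_pose_with_coords",
                                     "normalize_transform_with_coords"):
                        pm = pm.copy()
                        pm[0, -1] += coord_scale * r / max(h - 1, 1)
                        pm[1, -1] += coord_scale * c / max(w - 1, 1)
                    p_hat[r, c, i, j] = pm
                    a_hat[r, c, i, j] = (app[r, c, i] + bias[i, j]) @ wa[i, j]
    ho = -(-h // stride)
    wo = -(-w // stride)
    pose_out = np.zeros((ho, wo, to, p, p))
    app_out = np.zeros((ho, wo, to, q, q))
    for ro in range(ho):
        for co in range(wo):
            r0, c0 = ro * stride, co * stride
            ch_p, ch_a = [], []
            for dr in range(-half, half + 1):
                for dc in range(-half, half + 1):
                    rr, cc = r0 + dr, c0 + dc
                    for i in range(ti):
                        if 0 <= rr < h and 0 <= cc < w:
                            ch_p.append(p_hat[rr, cc, i])
                            ch_a.append(a_hat[rr, cc, i])
                        else:
                            ch_p.append(np.zeros((to, p, p)))
                            ch_a.append(np.zeros((to, q, q)))
            ch_p, ch_a = np.array(ch_p), np.array(ch_a)
            if algorithm == "dual":
                po, ao, _ = ref_route_dual(ch_p, ch_a, iterations)
            else:
                flat = np.concatenate(
                    [ch_p.reshape(len(ch_p), to, p * p),
                     ch_a.reshape(len(ch_a), to, q * q)], axis=-1)
                vec, _ = ref_route_dynamic(flat, iterations)
                po = vec[:, :p * p].reshape(to, p, p)
                ao = vec[:, p * p:].reshape(to, q, q)
            pose_out[ro, co] = po
            app_out[ro, co] = ao
    return pose_out, app_out


def ref_average_hausdorff(a, b):
    """Brute-force all-pairs average Hausdorff distance."""
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).mean(), d.min(axis=0).mean())


def ref_hausdorff(a, b):
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_config():
    """Small two-level capsule architecture used throughout the tests."""
    return ArchitectureConfig(
        shape=(2, 4), layers_per_level=1, window=3,
        pose_size=2, appearance_size=3,
        routing=RoutingSpec(algorithm="dual", iterations=2, window=3))


@pytest.fixture(scope="session")
def phantom_batch():
    from ivuscaps.phantom_data import generate_arrays
    return generate_arrays(3, 2, 64, seed=11)
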