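"""Numba kernels for the Debye sum.

Two evaluation strategies:

* ``debye_exact`` — O(N^2 * nQ) double loop with per-Q effective scattering
  lengths, so per-bead Gaussian form factors are exact.  Used for models up
  to a few thousand beads (the screening hot path).
* ``pair_histogram`` — O(N^2) weighted pair-distance histogram with
  first-moment bin centers; I(Q) then costs O(n_bins * nQ).  Used for very
  large point-bead models (e.g. dense sphere fills), where the exact double
  loop would be wasteful.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def debye_exact_q(xyz, q, bq):
    """Debye sum with per-Q effective scattering lengths.

    xyz : (N, 3) positions, q : (nQ,), bq : (nQ, N) effective b of each bead
    at each Q.  Returns I : (nQ,) with the i = j term included as b_i^2.
    """
    n = xyz.shape[0]
    nq = q.shape[0]
    out = np.zeros(nq)
    for k in range(nq):
        s = 0.0
        for i in range(n):
            s += bq[k, i] * bq[k, i]
        out[k] = s
    for i in range(n):
        xi, yi, zi = xyz[i, 0], xyz[i, 1], xyz[i, 2]
        for j in range(i + 1, n):
            dx = xi - xyz[j, 0]
            dy = yi - xyz[j, 1]
            dz = zi - xyz[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            for k in range(nq):
                qd = q[k] * d
                if qd < 1e-9:
                    sinc = 1.0
                else:
                    sinc = np.sin(qd) / qd
                out[k] += 2.0 * bq[k, i] * bq[k, j] * sinc
    return out


@njit(cache=True)
def cross_term_q(xyz_a, xyz_b, q, bq_a, bq_b):
    """Cross pair sum P(A,B) = sum_i sum_j b_i b_j sinc(Q d_ij), i in A, j in B."""
    na = xyz_a.shape[0]
    nb = xyz_b.shape[0]
    nq = q.shape[0]
    out = np.zeros(nq)
    for i in range(na):
        xi, yi, zi = xyz_a[i, 0], xyz_a[i, 1], xyz_a[i, 2]
        for j in range(nb):
            dx = xi - xyz_b[j, 0]
            dy = yi - xyz_b[j, 1]
            dz = zi - xyz_b[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            for k in range(nq):
                qd = q[k] * d
                if qd < 1e-9:
                    sinc = 1.0
                else:
                    sinc = np.sin(qd) / qd
                out[k] += bq_a[k, i] * bq_b[k, j] * sinc
    return out


@njit(cache=True)
def pair_histogram(xyz, b, bin_width, n_bins):
    """Weighted pair-distance histogram.

    Returns (w, wd): per-bin sums of b_i*b_j and b_i*b_j*d_ij over i < j.
    """
    n = xyz.shape[0]
    w = np.zeros(n_bins)
    wd = np.zeros(n_bins)
    for i in range(n):
        xi, yi, zi = xyz[i, 0], xyz[i, 1], xyz[i, 2]
        bi = b[i]
        for j in range(i + 1, n):
            dx = xi - xyz[j, 0]
            dy = yi - xyz[j, 1]
            dz = zi - xyz[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            k = int(d / bin_width)
            if k >= n_bins:
                k = n_bins - 1
            ww = bi * b[j]
            w[k] += ww
            wd[k] += ww * d
    return w, wd


def histogram_intensity(q, w, wd, self_term):
    """I(Q) from a weighted pair histogram (first-moment bin distances)."""
    occupied = w != 0.0
    dbar = wd[occupied] / w[occupied]
    wocc = w[occupied]
    qd = np.outer(q, dbar)
    sinc = np.sinc(qd / np.pi)  # np.sinc(x) = sin(pi x)/(pi x)
    return self_term + 2.0 * sinc @ wocc
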