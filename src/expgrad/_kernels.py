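"""Numba-compiled 2x2 max-pooling kernels.

The convolutions use BLAS shift-matmuls (see ``nnlayers.Conv2D``), which
beat fused loops on wide-SIMD CPUs; pooling, however, is index bookkeeping
that BLAS cannot express, and the compiled loop is ~10x faster than the
reshape/argmax formulation at full image size.  Deterministic: ties route
to the first maximum.  Falls back to pure NumPy when numba is missing.
"""

from __future__ import annotations

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(f):
            return f
        return wrap


@njit(cache=True)
def maxpool2_fwd(x, out, idx):
    """2x2 stride-2 max; idx records the flat in-window argmax (first max)."""
    n_im, h2, w2, c_n = out.shape
    for n in range(n_im):
        for i in range(h2):
            for j in range(w2):
                for c in range(c_n):
                    best = x[n, 2 * i, 2 * j, c]
                    bk = 0
                    v = x[n, 2 * i, 2 * j + 1, c]
                    if v > best:
                        best = v
                        bk = 1
                    v = x[n, 2 * i + 1, 2 * j, c]
                    if v > best:
                        best = v
                        bk = 2
                    v = x[n, 2 * i + 1, 2 * j + 1, c]
                    if v > best:
                        best = v
                        bk = 3
                    out[n, i, j, c] = best
                    idx[n, i, j, c] = bk


@njit(cache=True)
def maxpool2_bwd(dy, idx, dx):
    n_im, h2, w2, c_n = dy.shape
    for n in range(n_im):
        for i in range(h2):
            for j in range(w2):
                for c in range(c_n):
                    k = idx[n, i, j, c]
                    dx[n, 2 * i + k // 2, 2 * j + k % 2, c] += dy[n, i, j, c]
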