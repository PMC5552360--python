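"""Hot-loop Euler-Maruyama propagation kernels.

The public model API (``drift``, ``em_step``, ``simulate`` ...) lives in
:mod:`repmc.model`.  This module holds the inner loops that advance a block
of ``(P, 14)`` states, with one parameter row ``(Q, m, alpha, beta_a)`` per
state row, over many integration steps.  They are compiled with numba when
it is available and fall back to vectorised numpy otherwise; the two paths
are required (and tested) to agree.

Conventions shared by every kernel here:

* state layout per cell is ``[a, b, c, A, B, C, S]``, cells stacked, so a
  state row has 14 components;
* ``fv`` is the fixed-parameter vector ``(beta_b, beta_c, eta, kappa,
  k_s0, k_s1)``;
* ``amp`` is the per-component multiplicative noise amplitude: the update is
  ``x + h*drift + amp*x*z`` with ``z`` a standard normal draw, followed by
  clamping at zero (concentrations cannot be negative);
* noise arrays ``z`` have shape ``(n_steps, P, 14)`` and are generated by
  the caller from a numpy ``Generator`` so that reproducibility is owned by
  a single RNG stream.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every test run
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


def drift_vec(x: np.ndarray, Q, m, al, ba, fv: np.ndarray) -> np.ndarray:
    """Deterministic drift of the coupled repressilator, vectorised.

    ``x`` has shape ``(..., 14)``; ``Q, m, al, ba`` broadcast against
    ``x[..., 0]``.  Returns an array of the same shape as ``x``.
    """
    bb, bc, eta, kap, ks0, ks1 = fv
    out = np.empty_like(x)
    s_e = 0.5 * Q * (x[..., 6] + x[..., 13])
    for off in (0, 7):
        a = x[..., off]
        b = x[..., off + 1]
        c = x[..., off + 2]
        A = x[..., off + 3]
        B = x[..., off + 4]
        C = x[..., off + 5]
        S = x[..., off + 6]
        out[..., off] = -(a - al / (1.0 + C**m))
        out[..., off + 1] = -(b - al / (1.0 + A**m))
        out[..., off + 2] = -(c - al / (1.0 + B**m) - kap * S / (1.0 + S))
        out[..., off + 3] = ba * (a - A)
        out[..., off + 4] = bb * (b - B)
        out[..., off + 5] = bc * (c - C)
        out[..., off + 6] = -(ks0 * S - ks1 * B + eta * (S - s_e))
    return out


@njit(cache=True, fastmath=True)
def _em_chunk_numba(x, th, fv, amp, h, z):  # pragma: no cover - compiled
    n_steps = z.shape[0]
    n_p = x.shape[0]
    bb = fv[0]
    bc = fv[1]
    eta = fv[2]
    kap = fv[3]
    ks0 = fv[4]
    ks1 = fv[5]
    for s in range(n_steps):
        for p in range(n_p):
            Q = th[p, 0]
            m = th[p, 1]
            al = th[p, 2]
            ba = th[p, 3]
            s_e = 0.5 * Q * (x[p, 6] + x[p, 13])
            for off in range(0, 14, 7):
                a = x[p, off]
                b = x[p, off + 1]
                c = x[p, off + 2]
                A = x[p, off + 3]
                B = x[p, off + 4]
                C = x[p, off + 5]
                S = x[p, off + 6]
                na = a + h * (-(a - al / (1.0 + C**m))) + amp[off] * a * z[s, p, off]
                nb = (
                    b
                    + h * (-(b - al / (1.0 + A**m)))
                    + amp[off + 1] * b * z[s, p, off + 1]
                )
                nc = (
                    c
                    + h * (-(c - al / (1.0 + B**m) - kap * S / (1.0 + S)))
                    + amp[off + 2] * c * z[s, p, off + 2]
                )
                nA = A + h * (ba * (a - A)) + amp[off + 3] * A * z[s, p, off + 3]
                nB = B + h * (bb * (b - B)) + amp[off + 4] * B * z[s, p, off + 4]
                nC = C + h * (bc * (c - C)) + amp[off + 5] * C * z[s, p, off + 5]
                nS = (
                    S
                    + h * (-(ks0 * S - ks1 * B + eta * (S - s_e)))
                    + amp[off + 6] * S * z[s, p, off + 6]
                )
                x[p, off] = na if na > 0.0 else 0.0
                x[p, off + 1] = nb if nb > 0.0 else 0.0
                x[p, off + 2] = nc if nc > 0.0 else 0.0
                x[p, off + 3] = nA if nA > 0.0 else 0.0
                x[p, off + 4] = nB if nB > 0.0 else 0.0
                x[p, off + 5] = nC if nC > 0.0 else 0.0
                x[p, off + 6] = nS if nS > 0.0 else 0.0


@njit(cache=True, fastmath=True)
def _em_chunk_det_numba(x, th, fv, h, n_steps):  # pragma: no cover - compiled
    n_p = x.shape[0]
    bb = fv[0]
    bc = fv[1]
    eta = fv[2]
    kap = fv[3]
    ks0 = fv[4]
    ks1 = fv[5]
    for _s in range(n_steps):
        for p in range(n_p):
            Q = th[p, 0]
            m = th[p, 1]
            al = th[p, 2]
            ba = th[p, 3]
            s_e = 0.5 * Q * (x[p, 6] + x[p, 13])
            for off in range(0, 14, 7):
                a = x[p, off]
                b = x[p, off + 1]
                c = x[p, off + 2]
                A = x[p, off + 3]
                B = x[p, off + 4]
                C = x[p, off + 5]
                S = x[p, off + 6]
                na = a + h * (-(a - al / (1.0 + C**m)))
                nb = b + h * (-(b - al / (1.0 + A**m)))
                nc = c + h * (-(c - al / (1.0 + B**m) - kap * S / (1.0 + S)))
                nA = A + h * (ba * (a - A))
                nB = B + h * (bb * (b - B))
                nC = C + h * (bc * (c - C))
                nS = S + h * (-(ks0 * S - ks1 * B + eta * (S - s_e)))
                x[p, off] = na if na > 0.0 else 0.0
                x[p, off + 1] = nb if nb > 0.0 else 0.0
                x[p, off + 2] = nc if nc > 0.0 else 0.0
                x[p, off + 3] = nA if nA > 0.0 else 0.0
                x[p, off + 4] = nB if nB > 0.0 else 0.0
                x[p, off + 5] = nC if nC > 0.0 else 0.0
                x[p, off + 6] = nS if nS > 0.0 else 0.0


def _em_chunk_numpy(x, th, fv, amp, h, z):
    Q = th[:, 0]
    m = th[:, 1]
    al = th[:, 2]
    ba = th[:, 3]
    for s in range(z.shape[0]):
        d = drift_vec(x, Q, m, al, ba, fv)
        x[:] = x + h * d + amp * x * z[s]
        np.maximum(x, 0.0, out=x)


def _em_chunk_det_numpy(x, th, fv, h, n_steps):
    Q = th[:, 0]
    m = th[:, 1]
    al = th[:, 2]
    ba = th[:, 3]
    for _s in range(n_steps):
        d = drift_vec(x, Q, m, al, ba, fv)
        x[:] = x + h * d
        np.maximum(x, 0.0, out=x)


def em_chunk(x, th, fv, amp, h, z, *, use_numba: bool | None = None) -> None:
    """Advance states ``x`` (in place) by ``z.shape[0]`` noisy EM steps."""
    if use_numba is None:
        use_numba = HAVE_NUMBA
    if use_numba:
        _em_chunk_numba(x, th, fv, amp, h, z)
    else:
        _em_chunk_numpy(x, th, fv, amp, h, z)


def em_chunk_det(x, th, fv, h, n_steps, *, use_numba: bool | None = None) -> None:
    """Advance states ``x`` (in place) by ``n_steps`` deterministic EM steps."""
    if use_numba is None:
        use_numba = HAVE_NUMBA
    if use_numba:
        _em_chunk_det_numba(x, th, fv, h, n_steps)
    else:
        _em_chunk_det_numpy(x, th, fv, h, n_steps)
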