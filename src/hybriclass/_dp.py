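"""Dynamic-programming kernels for minimum duplex free energy.

The model: two strands are aligned antiparallel at every ungapped offset.
At a given offset a position is *pairable* when the two opposing bases are
Watson-Crick complements.  A duplex conformation chooses a subset of the
pairable positions to actually pair; adjacent paired positions form a
nearest-neighbor stack contributing its tabulated free energy, and the
stretch between two non-adjacent paired positions costs the cheaper of a
per-position mismatch penalty or an affine interior-loop penalty.  One
initiation term is charged per duplex.  The kernel returns the minimum
free energy over all offsets and conformations; +inf means no pairable
position exists anywhere (no binding).

Sequences enter as uint8 codes A=0, T=1, C=2, G=3 (so the complement of
code ``x`` is ``x ^ 1``).  Kernels are JIT-compiled with numba when it is
importable; a pure-Python fallback with identical semantics is kept for
environments without it.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit, prange

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

    prange = range

INF = np.inf


@njit(cache=True)
def _duplex_dg_codes(a, b_rc, stack_dg, init_dg, mm_dg, loop_open_dg, loop_ext_dg):
    """Minimum duplex free energy of strand ``a`` against the strand whose
    reverse complement codes are ``b_rc``; +inf when no base can pair."""
    la = a.shape[0]
    lb = b_rc.shape[0]
    if la < 2 or lb < 2:
        return INF
    best_total = INF
    f = np.empty(min(la, lb), dtype=np.float64)
    for shift in range(-(la - 1), lb):
        i0 = -shift if shift < 0 else 0
        i1 = min(la, lb - shift)
        n = i1 - i0
        if n < 1:
            continue
        # f[k]: best energy of a conformation whose last paired position is
        # overlap index k (only defined where the bases are complementary).
        best_here = INF
        m_mm = INF  # min over closed positions k' of f[k'] - mm_dg*k'
        m_loop = INF  # min over closed positions k' of f[k'] - loop_ext_dg*k'
        prev_matched = False
        for k in range(n):
            i = i0 + k
            j = i + shift
            if k >= 2 and f[k - 2] < INF:
                v = f[k - 2]
                if v - mm_dg * (k - 2) < m_mm:
                    m_mm = v - mm_dg * (k - 2)
                if v - loop_ext_dg * (k - 2) < m_loop:
                    m_loop = v - loop_ext_dg * (k - 2)
            if a[i] == b_rc[j]:
                e = 0.0  # start a fresh duplex at this pair
                if prev_matched and f[k - 1] < INF:
                    cand = f[k - 1] + stack_dg[a[i - 1], a[i]]
                    if cand < e:
                        e = cand
                if m_mm < INF:
                    cand = m_mm + mm_dg * (k - 1)
                    if cand < e:
                        e = cand
                if m_loop < INF:
                    cand = m_loop + loop_open_dg + loop_ext_dg * (k - 2)
                    if cand < e:
                        e = cand
                f[k] = e
                if e < best_here:
                    best_here = e
                prev_matched = True
            else:
                f[k] = INF
                prev_matched = False
        if best_here < INF:
            total = init_dg + best_here
            if total < best_total:
                best_total = total
    return best_total


@njit(cache=True)
def _dg_pairs_codes(A, B_rc, stack_dg, init_dg, mm_dg, loop_open_dg, loop_ext_dg):
    """Elementwise duplex free energies of aligned pair lists (row i of A
    against row i of B_rc)."""
    n = A.shape[0]
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        out[i] = _duplex_dg_codes(
            A[i], B_rc[i], stack_dg, init_dg, mm_dg, loop_open_dg, loop_ext_dg
        )
    return out


@njit(cache=True)
def _dg_matrix_codes(A, B_rc, stack_dg, init_dg, mm_dg, loop_open_dg, loop_ext_dg):
    """Pairwise duplex free energies: rows index A, columns index B_rc."""
    n = A.shape[0]
    m = B_rc.shape[0]
    out = np.empty((n, m), dtype=np.float64)
    for i in range(n):
        for j in range(m):
            out[i, j] = _duplex_dg_codes(
                A[i], B_rc[j], stack_dg, init_dg, mm_dg, loop_open_dg, loop_ext_dg
            )
    return out
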