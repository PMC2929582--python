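"""Numba-compiled minimum-free-energy folding recursions (Zuker-style).

Matrices:
  V[i,j]  — minimum energy of the segment i..j given that (i,j) is paired.
  WM[i,j] — minimum energy of i..j as multiloop content with >=1 branch
            (each branch charged the per-branch term, unpaired bases the
            per-nucleotide term).
  W[j]    — minimum energy of the exterior prefix 0..j.

Internal/bulge loops are capped at ``max_internal`` total unpaired
nucleotides, the usual search restriction for this family of algorithms.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e9


@njit(cache=False)
def fold_matrices(seq, pair_type, stack, hairpin, bulge, internal,
                  ml_a, ml_b, ml_c, min_hp, max_int):
    n = seq.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)

    for span in range(min_hp + 1, n):
        for i in range(0, n - span):
            j = i + span
            pt = pair_type[seq[i], seq[j]]
            if pt >= 0:
                best = hairpin[j - i - 1]
                # interior: inner pair (k,l), u5+u3 unpaired, capped
                for u5 in range(0, max_int + 1):
                    k = i + 1 + u5
                    if k + min_hp + 1 >= j:
                        break
                    for u3 in range(0, max_int - u5 + 1):
                        l = j - 1 - u3
                        if l <= k + min_hp:
                            break
                        if V[k, l] >= INF:
                            continue
                        if u5 == 0 and u3 == 0:
                            pt_in = pair_type[seq[k], seq[l]]
                            e = stack[pt, pt_in] + V[k, l]
                        elif u5 == 0 or u3 == 0:
                            e = bulge[u5 + u3] + V[k, l]
                        else:
                            e = internal[u5 + u3] + V[k, l]
                        if e < best:
                            best = e
                # multiloop: split interior i+1..j-1 into two WM parts
                for k in range(i + 2, j):
                    if WM[i + 1, k - 1] < INF and WM[k, j - 1] < INF:
                        e = ml_a + ml_b + WM[i + 1, k - 1] + WM[k, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best

            # WM over the same (i, j)
            best_wm = INF
            if V[i, j] < INF:
                best_wm = V[i, j] + ml_b
            if WM[i + 1, j] + ml_c < best_wm:
                best_wm = WM[i + 1, j] + ml_c
            if WM[i, j - 1] + ml_c < best_wm:
                best_wm = WM[i, j - 1] + ml_c
            for k in range(i + 1, j + 1):
                if WM[i, k - 1] < INF and WM[k, j] < INF:
                    e = WM[i, k - 1] + WM[k, j]
                    if e < best_wm:
                        best_wm = e
            WM[i, j] = best_wm

    W = np.zeros(n)
    for j in range(n):
        best = W[j - 1] if j > 0 else 0.0
        for i in range(0, j):
            left = W[i - 1] if i > 0 else 0.0
            if V[i, j] < INF and left + V[i, j] < best:
                best = left + V[i, j]
        W[j] = best
    return V, WM, W
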