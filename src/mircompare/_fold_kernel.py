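"""Numba-compiled dynamic-programming core for hairpin MFE folding.

Fills the V (energy of the best structure closed by pair i,j) and M
(best multiloop-segment energy with >=1 branch) tables under the
nearest-neighbor model passed in as flat arrays.  Traceback is done in
Python (see :mod:`mircompare.folding`); the tables alone carry enough
information to reconstruct an optimal structure deterministically.
"""

import numpy as np
from numba import njit

INF = 1e30


@njit(cache=True)
def fill_tables(codes, pt, stack, hp, bu, il, ml_a, ml_b, min_loop, max_interior):
    n = codes.shape[0]
    V = np.full((n, n), INF)
    M = np.full((n, n), INF)
    for d in range(min_loop + 1, n):
        for i in range(n - d):
            j = i + d
            p_ij = pt[codes[i], codes[j]]
            if p_ij >= 0:
                best = hp[j - i - 1]
                # interior loops / bulges / stacks, total unpaired <= max_interior
                kmax = min(i + max_interior + 1, j - min_loop - 1)
                for k in range(i + 1, kmax + 1):
                    l1 = k - i - 1
                    lmin = k + min_loop + 1
                    lo = j - 1 - (max_interior - l1)
                    if lo > lmin:
                        lmin = lo
                    for l in range(lmin, j):
                        if V[k, l] >= INF:
                            continue
                        l2 = j - l - 1
                        if l1 == 0 and l2 == 0:
                            e = stack[p_ij, pt[codes[k], codes[l]]]
                        elif l1 == 0 or l2 == 0:
                            e = bu[l1 + l2]
                        else:
                            e = il[l1 + l2]
                        tot = V[k, l] + e
                        if tot < best:
                            best = tot
                # multiloop closure: >=2 branches inside
                for k in range(i + 2, j - 1):
                    if M[i + 1, k] < INF and M[k + 1, j - 1] < INF:
                        tot = ml_a + ml_b + M[i + 1, k] + M[k + 1, j - 1]
                        if tot < best:
                            best = tot
                V[i, j] = best
            # M: segment holding at least one branch
            best_m = INF
            if V[i, j] < INF:
                best_m = V[i, j] + ml_b
            if M[i + 1, j] < best_m:
                best_m = M[i + 1, j]
            if M[i, j - 1] < best_m:
                best_m = M[i, j - 1]
            for k in range(i + 1, j):
                if M[i, k] < INF and M[k + 1, j] < INF:
                    tot = M[i, k] + M[k + 1, j]
                    if tot < best_m:
                        best_m = tot
            M[i, j] = best_m
    return V, M
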