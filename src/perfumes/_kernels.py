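"""Numba kernels for the internal secondary-structure engine.

The energy model is deliberately minimal so that every quantity computed
here can be cross-checked by exhaustive enumeration on short sequences:
a structure is a non-crossing set of allowed pairs, its energy is
``n_pairs * e_pair + n_stacks * e_stack`` where a stack is a nested
adjacent pair ((i, j), (i+1, j-1)).

All tables are triangular float64 matrices indexed [i, j] with i <= j.
Three tables are maintained per quantity:

* ``T``   — all admissible structures on [i, j]
* ``Tb``  — structures on [i, j] in which (i, j) itself is paired
* ``Tnp`` — structures on [i, j] in which i is *not* paired to j

Constraints enter through ``allowed`` (pair (i, j) may form) and
``can_unpair`` (position may stay single).  Positions belonging to a
forced pair have ``can_unpair`` False and ``allowed`` True only for the
designated partner, which makes every admissible structure contain every
forced pair.
"""

import numpy as np
from numba import njit

INF = 1e30


@njit(cache=True)
def _e_get(E, i, j):
    if j < i:
        return 0.0
    return E[i, j]


@njit(cache=True)
def mfe_tables(n, allowed, can_unpair, e_pair, e_stack):
    E = np.zeros((n, n))
    Eb = np.full((n, n), INF)
    Enp = np.zeros((n, n))
    for i in range(n):
        v = 0.0 if can_unpair[i] else INF
        E[i, i] = v
        Enp[i, i] = v
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            # Eb: (i, j) paired
            if allowed[i, j]:
                if j - 1 >= i + 1:
                    v1 = Enp[i + 1, j - 1]
                    v2 = Eb[i + 1, j - 1]
                    inner = v1 if v1 < e_stack + v2 else e_stack + v2
                else:
                    inner = 0.0
                if inner < INF / 2:
                    Eb[i, j] = e_pair + inner
            # E / Enp: right decomposition on j
            best = INF
            bestnp = INF
            if can_unpair[j]:
                v = _e_get(E, i, j - 1)
                if v < best:
                    best = v
                if v < bestnp:
                    bestnp = v
            for k in range(i, j):
                if allowed[k, j] and Eb[k, j] < INF / 2:
                    v = _e_get(E, i, k - 1) + Eb[k, j]
                    if v < best:
                        best = v
                    if k != i and v < bestnp:
                        bestnp = v
            E[i, j] = best
            Enp[i, j] = bestnp
    return E, Eb, Enp


@njit(cache=True)
def mfe_traceback(n, E, Eb, Enp, allowed, can_unpair, e_pair, e_stack):
    """Deterministic traceback: at the 5'-most undecided position prefer
    opening a pair over leaving it unpaired, then the smallest partner;
    inside a pair prefer the stacked continuation on ties."""
    tol = 1e-9
    partner = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return partner
    # stack entries: (i, j, mode) mode 0=E, 1=Eb, 2=Enp
    stack = np.empty((3 * n + 3, 3), dtype=np.int64)
    top = 0
    stack[top, 0] = 0
    stack[top, 1] = n - 1
    stack[top, 2] = 0
    top += 1
    while top > 0:
        top -= 1
        i = stack[top, 0]
        j = stack[top, 1]
        mode = stack[top, 2]
        if j < i:
            continue
        if mode == 1:
            partner[i] = j
            partner[j] = i
            if j - 1 >= i + 1:
                target = Eb[i, j] - e_pair
                if Eb[i + 1, j - 1] < INF / 2 and abs(e_stack + Eb[i + 1, j - 1] - target) < tol:
                    stack[top, 0] = i + 1
                    stack[top, 1] = j - 1
                    stack[top, 2] = 1
                    top += 1
                else:
                    stack[top, 0] = i + 1
                    stack[top, 1] = j - 1
                    stack[top, 2] = 2
                    top += 1
            continue
        target = E[i, j] if mode == 0 else Enp[i, j]
        if i == j:
            continue
        # left decomposition: try pairing i first (smallest partner)
        found = False
        kmax = j if mode == 0 else j - 1
        for k in range(i + 1, kmax + 1):
            if allowed[i, k] and Eb[i, k] < INF / 2:
                v = Eb[i, k] + _e_get(E, k + 1, j)
                if abs(v - target) < tol:
                    stack[top, 0] = i
                    stack[top, 1] = k
                    stack[top, 2] = 1
                    top += 1
                    stack[top, 0] = k + 1
                    stack[top, 1] = j
                    stack[top, 2] = 0
                    top += 1
                    found = True
                    break
        if not found:
            # i unpaired
            stack[top, 0] = i + 1
            stack[top, 1] = j
            stack[top, 2] = 0
            top += 1
    return partner


@njit(cache=True)
def pf_tables(n, allowed, can_unpair, qpair, qstack):
    Z = np.zeros((n, n))
    Zb = np.zeros((n, n))
    Znp = np.zeros((n, n))
    for i in range(n):
        v = 1.0 if can_unpair[i] else 0.0
        Z[i, i] = v
        Znp[i, i] = v
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            if allowed[i, j]:
                if j - 1 >= i + 1:
                    inner = Znp[i + 1, j - 1] + qstack * Zb[i + 1, j - 1]
                else:
                    inner = 1.0
                Zb[i, j] = qpair * inner
            tot = 0.0
            totnp = 0.0
            if can_unpair[j]:
                v = Z[i, j - 1] if j - 1 >= i else 1.0
                tot += v
                totnp += v
            for k in range(i, j):
                if allowed[k, j] and Zb[k, j] > 0.0:
                    v = (Z[i, k - 1] if k - 1 >= i else 1.0) * Zb[k, j]
                    tot += v
                    if k != i:
                        totnp += v
            Z[i, j] = tot
            Znp[i, j] = totnp
    return Z, Zb, Znp


@njit(cache=True)
def sample_structures(n, Z, Zb, Znp, allowed, can_unpair, qpair, qstack,
                      n_samples, seed):
    np.random.seed(seed)
    out = np.full((n_samples, n), -1, dtype=np.int64)
    stack = np.empty((3 * n + 3, 3), dtype=np.int64)
    for s in range(n_samples):
        top = 0
        stack[top, 0] = 0
        stack[top, 1] = n - 1
        stack[top, 2] = 0
        top += 1
        while top > 0:
            top -= 1
            i = stack[top, 0]
            j = stack[top, 1]
            mode = stack[top, 2]
            if j < i:
                continue
            if mode == 1:
                out[s, i] = j
                out[s, j] = i
                if j - 1 >= i + 1:
                    wns = Znp[i + 1, j - 1]
                    wst = qstack * Zb[i + 1, j - 1]
                    r = np.random.random() * (wns + wst)
                    if r < wst:
                        stack[top, 0] = i + 1
                        stack[top, 1] = j - 1
                        stack[top, 2] = 1
                        top += 1
                    else:
                        stack[top, 0] = i + 1
                        stack[top, 1] = j - 1
                        stack[top, 2] = 2
                        top += 1
                continue
            if i == j:
                continue
            total = Z[i, j] if mode == 0 else Znp[i, j]
            r = np.random.random() * total
            acc = 0.0
            if can_unpair[j]:
                acc += Z[i, j - 1] if j - 1 >= i else 1.0
            if r < acc:
                stack[top, 0] = i
                stack[top, 1] = j - 1
                stack[top, 2] = 0
                top += 1
                continue
            done = False
            klo = i if mode == 0 else i + 1
            lastk = -1
            for k in range(klo, j):
                if allowed[k, j] and Zb[k, j] > 0.0:
                    lastk = k
                    w = (Z[i, k - 1] if k - 1 >= i else 1.0) * Zb[k, j]
                    acc += w
                    if r < acc:
                        stack[top, 0] = i
                        stack[top, 1] = k - 1
                        stack[top, 2] = 0
                        top += 1
                        stack[top, 0] = k
                        stack[top, 1] = j
                        stack[top, 2] = 1
                        top += 1
                        done = True
                        break
            if not done:
                # numerical slack: fall back to the last admissible option
                if lastk >= 0:
                    stack[top, 0] = i
                    stack[top, 1] = lastk - 1
                    stack[top, 2] = 0
                    top += 1
                    stack[top, 0] = lastk
                    stack[top, 1] = j
                    stack[top, 2] = 1
                    top += 1
                elif can_unpair[j]:
                    stack[top, 0] = i
                    stack[top, 1] = j - 1
                    stack[top, 2] = 0
                    top += 1
    return out
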