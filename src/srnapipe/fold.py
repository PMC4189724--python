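"""Deterministic nearest-neighbor RNA secondary-structure prediction.

The built-in model minimises a free energy composed of

* stacking energies for adjacent canonical pairs (Watson-Crick and G:U),
* hairpin-loop penalties linear in loop size,
* internal-loop/bulge penalties linear in the number of unpaired bases, and
* affine multiloop penalties (closing + per-branch + per-unpaired terms),

over all pseudoknot-free structures with hairpin loops of at least
``MIN_HAIRPIN_LOOP`` bases.  Energies are handled internally in hundredths of
kcal/mol so the dynamic program is exact integer arithmetic; the public API
reports kcal/mol.

Two independent routes compute the same quantity:

- :func:`fold` — Zuker-style dynamic programming (optionally numba-jitted),
- :func:`exhaustive_mfe` — brute-force enumeration of every structure,
  feasible for sequences up to ~22 nt and used as a correctness oracle.

An external folding backend (e.g. a ViennaRNA wrapper) may be plugged in via
the ``backend`` argument of :func:`fold_hairpin`; the built-in model is the
default and has no third-party dependencies.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from srnapipe.seqs import to_rna

# Base encoding used throughout this module.
_ENC = {"A": 0, "C": 1, "G": 2, "U": 3}

# Pair indices in order AU, CG, GC, UA, GU, UG; -1 = not pairable.
PAIR_INDEX = np.full((4, 4), -1, dtype=np.int64)
for _i, (_a, _b) in enumerate([(0, 3), (1, 2), (2, 1), (3, 0), (2, 3), (3, 2)]):
    PAIR_INDEX[_a, _b] = _i

# Stacking energies, hundredths of kcal/mol.  Row: closing pair (i,j);
# column: inner pair (i+1,j-1).  Values follow the Turner-style nearest-
# neighbor tables for Watson-Crick and G:U stacks.
STACK100 = np.array(
    [
        #  AU    CG    GC    UA    GU    UG
        [-93, -224, -208, -110, -55, -136],  # AU
        [-211, -326, -236, -208, -141, -211],  # CG
        [-235, -342, -326, -224, -153, -251],  # GC
        [-133, -235, -211, -93, -127, -100],  # UA
        [-136, -251, -211, -100, -50, 129],  # GU
        [-110, -141, -127, -55, 30, -50],  # UG
    ],
    dtype=np.int64,
)

MIN_HAIRPIN_LOOP = 3
MAX_INTERNAL_LOOP = 30  # cap on unpaired bases in an internal loop / bulge
HAIRPIN_BASE100 = 410
HAIRPIN_PER_NT100 = 30
INTERNAL_BASE100 = 200
INTERNAL_PER_NT100 = 40
MULTI_CLOSE100 = 340
MULTI_BRANCH100 = 40
MULTI_UNPAIRED100 = 10

_INF = 1 << 40

MAX_FOLD_LENGTH = 400


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as an int array, raising on foreign characters."""
    rna = to_rna(seq)
    try:
        return np.array([_ENC[b] for b in rna], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGUT character in sequence: {exc.args[0]!r}") from None


def _fold_tables(enc, pair_index, stack, params):
    """Fill the V/WM/WM2/W tables of the minimisation.  numba-jittable."""
    (
        min_hp,
        max_int,
        hp_a,
        hp_b,
        in_a,
        in_b,
        mu_a,
        mu_b,
        mu_c,
        inf,
    ) = params
    n = enc.shape[0]
    V = np.full((n, n), inf, dtype=np.int64)
    WM = np.full((n, n), inf, dtype=np.int64)
    WM2 = np.full((n, n), inf, dtype=np.int64)
    W = np.zeros(n, dtype=np.int64)
    for length in range(2, n + 1):
        for i in range(0, n - length + 1):
            j = i + length - 1
            pi_ij = pair_index[enc[i], enc[j]]
            if pi_ij >= 0 and j - i - 1 >= min_hp:
                best = hp_a + hp_b * (j - i - 1)
                for k in range(i + 1, j):
                    left = k - i - 1
                    if left > max_int:
                        break
                    for l in range(j - 1, k, -1):
                        unpaired = left + (j - 1 - l)
                        if unpaired > max_int:
                            break
                        if V[k, l] >= inf:
                            continue
                        if unpaired == 0:
                            e = stack[pi_ij, pair_index[enc[k], enc[l]]] + V[k, l]
                        else:
                            e = in_a + in_b * unpaired + V[k, l]
                        if e < best:
                            best = e
                if j - i - 1 >= 2 and WM2[i + 1, j - 1] < inf:
                    e = mu_a + WM2[i + 1, j - 1]
                    if e < best:
                        best = e
                V[i, j] = best
            # segment energies inside a multiloop
            wm = inf
            if WM[i + 1, j] < inf:
                wm = WM[i + 1, j] + mu_c
            if WM[i, j - 1] < inf and WM[i, j - 1] + mu_c < wm:
                wm = WM[i, j - 1] + mu_c
            if V[i, j] < inf and V[i, j] + mu_b < wm:
                wm = V[i, j] + mu_b
            wm2 = inf
            for k in range(i + 1, j):
                if WM[i, k] < inf and WM[k + 1, j] < inf:
                    cand = WM[i, k] + WM[k + 1, j]
                    if cand < wm2:
                        wm2 = cand
                    if cand < wm:
                        wm = cand
            WM[i, j] = wm
            WM2[i, j] = wm2
    for j in range(n):
        best = 0 if j == 0 else W[j - 1]
        for i in range(0, j):
            if V[i, j] < inf:
                left = 0 if i == 0 else W[i - 1]
                if left + V[i, j] < best:
                    best = left + V[i, j]
        W[j] = best
    return V, WM, WM2, W


try:  # optional acceleration; the pure-Python path is identical
    from numba import njit as _njit

    _fold_tables_fast = _njit(cache=True)(_fold_tables)
except ImportError:  # pragma: no cover
    _fold_tables_fast = _fold_tables


def _params() -> tuple:
    return (
        MIN_HAIRPIN_LOOP,
        MAX_INTERNAL_LOOP,
        HAIRPIN_BASE100,
        HAIRPIN_PER_NT100,
        INTERNAL_BASE100,
        INTERNAL_PER_NT100,
        MULTI_CLOSE100,
        MULTI_BRANCH100,
        MULTI_UNPAIRED100,
        _INF,
    )


def structure_energy100(enc: np.ndarray, partner: np.ndarray) -> int:
    """Energy (hundredths kcal/mol) of a given structure by loop decomposition.

    ``partner[i]`` is the paired position of ``i`` or -1.  Independent of the
    dynamic program; used both by the enumeration oracle and by duplex
    diagnostics.
    """
    n = len(enc)
    total = 0
    for i in range(n):
        j = partner[i]
        if j <= i:
            continue
        if PAIR_INDEX[enc[i], enc[j]] < 0:
            raise ValueError(f"positions {i},{j} cannot pair")
        # collect directly enclosed pairs
        children = []
        k = i + 1
        while k < j:
            if partner[k] != -1:
                l = partner[k]
                if l < k or l > j:
                    raise ValueError("crossing pairs (pseudoknot) in structure")
                children.append((k, l))
                k = l + 1
            else:
                k += 1
        if not children:
            size = j - i - 1
            if size < MIN_HAIRPIN_LOOP:
                raise ValueError(f"hairpin loop of size {size} below minimum")
            total += HAIRPIN_BASE100 + HAIRPIN_PER_NT100 * size
        elif len(children) == 1:
            k, l = children[0]
            unpaired = (k - i - 1) + (j - l - 1)
            if unpaired == 0:
                total += STACK100[
                    PAIR_INDEX[enc[i], enc[j]], PAIR_INDEX[enc[k], enc[l]]
                ]
            else:
                total += INTERNAL_BASE100 + INTERNAL_PER_NT100 * unpaired
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            total += (
                MULTI_CLOSE100
                + MULTI_BRANCH100 * len(children)
                + MULTI_UNPAIRED100 * unpaired
            )
    return total


def structure_energy(seq: str, pairs) -> float:
    """Energy in kcal/mol of an explicit structure (iterable of (i, j) pairs)."""
    enc = encode(seq)
    partner = pairs_to_partner(len(enc), pairs)
    return structure_energy100(enc, partner) / 100.0


def pairs_to_partner(n: int, pairs) -> np.ndarray:
    partner = np.full(n, -1, dtype=np.int64)
    for i, j in pairs:
        if not (0 <= i < j < n):
            raise ValueError(f"pair ({i},{j}) out of range")
        if partner[i] != -1 or partner[j] != -1:
            raise ValueError("position paired twice")
        partner[i], partner[j] = j, i
    return partner


def partner_to_dotbracket(partner: np.ndarray) -> str:
    out = []
    for i, j in enumerate(partner):
        out.append("." if j == -1 else ("(" if j > i else ")"))
    return "".join(out)


def dotbracket_to_pairs(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"bad structure character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pairs


def _traceback(enc, V, WM, WM2, W, params) -> np.ndarray:
    (min_hp, max_int, hp_a, hp_b, in_a, in_b, mu_a, mu_b, mu_c, inf) = params
    n = len(enc)
    partner = np.full(n, -1, dtype=np.int64)
    stack: list[tuple[str, int, int]] = []
    # exterior loop
    j = n - 1
    while j >= 0:
        if j > 0 and W[j] == W[j - 1]:
            j -= 1
            continue
        if W[j] == 0:
            break
        found = False
        for i in range(0, j + 1):
            left = 0 if i == 0 else W[i - 1]
            if V[i, j] < inf and left + V[i, j] == W[j]:
                stack.append(("V", i, j))
                j = i - 1
                found = True
                break
        if not found:  # pragma: no cover - W is built from these cases
            raise AssertionError("exterior traceback failed")
    while stack:
        kind, i, j = stack.pop()
        if kind == "V":
            partner[i], partner[j] = j, i
            if V[i, j] == hp_a + hp_b * (j - i - 1):
                continue
            pi_ij = PAIR_INDEX[enc[i], enc[j]]
            found = False
            for k in range(i + 1, j):
                left = k - i - 1
                if left > max_int or found:
                    break
                for l in range(j - 1, k, -1):
                    unpaired = left + (j - 1 - l)
                    if unpaired > max_int:
                        break
                    if V[k, l] >= inf:
                        continue
                    if unpaired == 0:
                        e = STACK100[pi_ij, PAIR_INDEX[enc[k], enc[l]]] + V[k, l]
                    else:
                        e = in_a + in_b * unpaired + V[k, l]
                    if e == V[i, j]:
                        stack.append(("V", k, l))
                        found = True
                        break
            if found:
                continue
            if j - i - 1 >= 2 and V[i, j] == mu_a + WM2[i + 1, j - 1]:
                stack.append(("WM2", i + 1, j - 1))
                continue
            raise AssertionError("V traceback failed")  # pragma: no cover
        if kind == "WM2":
            for k in range(i + 1, j):
                if WM[i, k] < inf and WM[k + 1, j] < inf:
                    if WM[i, k] + WM[k + 1, j] == WM2[i, j]:
                        stack.append(("WM", i, k))
                        stack.append(("WM", k + 1, j))
                        break
            else:  # pragma: no cover
                raise AssertionError("WM2 traceback failed")
            continue
        # kind == "WM"
        if V[i, j] < inf and WM[i, j] == V[i, j] + mu_b:
            stack.append(("V", i, j))
        elif WM[i + 1, j] < inf and WM[i, j] == WM[i + 1, j] + mu_c:
            stack.append(("WM", i + 1, j))
        elif WM[i, j - 1] < inf and WM[i, j] == WM[i, j - 1] + mu_c:
            stack.append(("WM", i, j - 1))
        else:
            for k in range(i + 1, j):
                if WM[i, k] < inf and WM[k + 1, j] < inf:
                    if WM[i, k] + WM[k + 1, j] == WM[i, j]:
                        stack.append(("WM", i, k))
                        stack.append(("WM", k + 1, j))
                        break
            else:  # pragma: no cover
                raise AssertionError("WM traceback failed")
    return partner


def fold(seq: str) -> tuple[str, float]:
    """Minimum-free-energy structure of ``seq`` under the built-in model.

    Returns ``(dot_bracket, mfe_kcal_per_mol)``.  The open structure has
    energy zero, so the reported MFE is always <= 0.
    """
    enc = encode(seq)
    n = len(enc)
    if n == 0:
        raise ValueError("empty sequence")
    if n < MIN_HAIRPIN_LOOP + 2:
        return "." * n, 0.0
    params = _params()
    V, WM, WM2, W = _fold_tables_fast(enc, PAIR_INDEX, STACK100, params)
    mfe100 = int(W[n - 1])
    if mfe100 >= 0:
        return "." * n, 0.0
    partner = _traceback(enc, V, WM, WM2, W, params)
    return partner_to_dotbracket(partner), mfe100 / 100.0


def fold_hairpin(
    seq: str, backend: Callable[[str], tuple[str, float]] | None = None
) -> tuple[str, float]:
    """Fold a putative precursor sequence.

    ``backend`` may supply an alternative folding engine with the same
    ``seq -> (structure, mfe)`` contract (for example a ViennaRNA wrapper);
    by default the deterministic built-in model is used.
    """
    if len(seq) > MAX_FOLD_LENGTH:
        raise ValueError(
            f"sequence of {len(seq)} nt exceeds folding limit {MAX_FOLD_LENGTH}"
        )
    if backend is not None:
        structure, mfe = backend(to_rna(seq))
        if len(structure) != len(seq):
            raise ValueError("backend returned a structure of mismatched length")
        return structure, float(mfe)
    return fold(seq)


def enumerate_structures(seq: str):
    """Yield every pseudoknot-free structure of ``seq`` as a list of pairs.

    Purely recursive enumeration; exponential, intended for sequences up to
    ~22 nt where it serves as the independent oracle for :func:`fold`.
    """
    enc = encode(seq)
    n = len(enc)
    if n > 24:
        raise ValueError("enumeration is only feasible for sequences <= 24 nt")

    def gen(i: int, j: int):
        if i >= j:
            yield []
            return
        yield from gen(i + 1, j)
        for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            if PAIR_INDEX[enc[i], enc[k]] >= 0:
                for inner in gen(i + 1, k - 1):
                    for outer in gen(k + 1, j):
                        yield [(i, k)] + inner + outer

    yield from gen(0, n - 1)


def exhaustive_mfe(seq: str) -> tuple[list[tuple[int, int]], float]:
    """Brute-force MFE over all structures; oracle counterpart of :func:`fold`."""
    enc = encode(seq)
    best_pairs: list[tuple[int, int]] = []
    best = 0
    for pairs in enumerate_structures(seq):
        partner = pairs_to_partner(len(enc), pairs)
        e = structure_energy100(enc, partner)
        if e < best:
            best, best_pairs = e, pairs
    return best_pairs, best / 100.0
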