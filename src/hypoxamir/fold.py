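"""Deterministic RNA secondary-structure prediction.

The built-in folder is a maximum base-pairing dynamic program (Nussinov-type,
minimum hairpin loop of 3, G:U allowed) with two pragmatic refinements that
make its structures usable for hairpin screening:

* lonely pairs (helices of length 1) are removed after traceback, and
* the reported energy is a stacking sum over the remaining helices, using a
  per-pair strength (GC 3.3, AU 2.1, GU 1.4 kcal/mol) averaged across each
  stacked pair of pairs — a crude but monotone stand-in for a nearest-
  neighbor model, in kcal/mol so that thermodynamic folders can be swapped
  in behind the same contract.

A folder is any callable ``seq -> (dot_bracket, energy)``.  ViennaRNA's RNA
bindings, when importable, are exposed as the ``"vienna"`` backend.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

Folder = Callable[[str], tuple[str, float]]

MIN_HAIRPIN_LOOP = 3

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_PAIR_STRENGTH = {
    ("G", "C"): 3.3,
    ("C", "G"): 3.3,
    ("A", "U"): 2.1,
    ("U", "A"): 2.1,
    ("G", "U"): 1.4,
    ("U", "G"): 1.4,
}


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 if unpaired); raises on unbalanced input."""
    stack: list[int] = []
    table = [-1] * len(structure)
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced structure at position {i}")
            j = stack.pop()
            table[j] = i
            table[i] = j
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if stack:
        raise ValueError("unbalanced structure: unclosed '('")
    return table


def _helices(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group a nested pair list into maximal stacked runs."""
    pairs = sorted(pairs)
    byi = dict(pairs)
    helices: list[list[tuple[int, int]]] = []
    seen: set[tuple[int, int]] = set()
    for i, j in pairs:
        if (i, j) in seen:
            continue
        helix = [(i, j)]
        seen.add((i, j))
        while byi.get(helix[-1][0] + 1) == helix[-1][1] - 1:
            nxt = (helix[-1][0] + 1, helix[-1][1] - 1)
            helix.append(nxt)
            seen.add(nxt)
        helices.append(helix)
    return helices


def stacking_energy(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Stacking-sum energy (kcal/mol, <= 0) of a nested pair set."""
    rna = _rna(seq)
    energy = 0.0
    for helix in _helices(pairs):
        for (i1, j1), (i2, j2) in zip(helix, helix[1:]):
            s1 = _PAIR_STRENGTH.get((rna[i1], rna[j1]), 0.0)
            s2 = _PAIR_STRENGTH.get((rna[i2], rna[j2]), 0.0)
            energy -= (s1 + s2) / 2.0
    return energy


def nussinov_fold(seq: str) -> tuple[str, float]:
    """Fold by maximum pairing; returns (dot-bracket, stacking energy)."""
    rna = _rna(seq)
    n = len(rna)
    if n <= MIN_HAIRPIN_LOOP + 1:
        return "." * n, 0.0
    enc = np.frombuffer(rna.encode(), dtype=np.uint8)
    code = np.zeros(n, dtype=np.int8)  # A=0 C=1 G=2 U=3, other=-1
    for k, b in enumerate(b"ACGU"):
        code[enc == b] = k
    code[~np.isin(enc, np.frombuffer(b"ACGU", dtype=np.uint8))] = -1
    pairable = np.zeros((n, n), dtype=bool)
    ok = {(0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)}
    for a, b in ok:
        pairable |= (code[:, None] == a) & (code[None, :] == b)
    pairable[code == -1, :] = False
    pairable[:, code == -1] = False

    M = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        i = np.arange(0, n - span)
        j = i + span
        best = np.where(pairable[i, j], M[i + 1, j - 1] + 1, 0)
        for d in range(0, span):
            np.maximum(best, M[i, i + d] + M[np.minimum(i + d + 1, j), j], out=best)
        M[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_HAIRPIN_LOOP or M[i, j] == 0:
            continue
        m = M[i, j]
        if pairable[i, j] and m == M[i + 1, j - 1] + 1:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        if m == M[i + 1, j]:
            stack.append((i + 1, j))
            continue
        if m == M[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i + 1, j - 1):
            if M[i, k] + M[k + 1, j] == m:
                stack.append((i, k))
                stack.append((k + 1, j))
                break

    pairs = [p for helix in _helices(pairs) if len(helix) >= 2 for p in helix]
    structure = ["."] * n
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    return "".join(structure), stacking_energy(rna, pairs)


def vienna_fold(seq: str) -> tuple[str, float]:
    """Thermodynamic folding through ViennaRNA's Python bindings."""
    import RNA  # deferred: optional backend

    structure, mfe = RNA.fold(_rna(seq))
    return structure, float(mfe)


def get_folder(name: str = "builtin") -> Folder:
    if name == "builtin":
        return nussinov_fold
    if name == "vienna":
        return vienna_fold
    raise ValueError(f"unknown folding backend {name!r}")
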