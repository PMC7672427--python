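"""Nearest-neighbor free-energy model for RNA stem-loops.

The model is intentionally small: Watson-Crick and GU wobble stacking
doublets, hairpin-loop initiation by loop size, and a per-terminal
AU/GU helix-end penalty, all at 37 degC.  It approximates the published
nearest-neighbor parameter sets closely enough to rank and design
hairpins, but it is self-contained so that every energy it reports can
be reproduced by hand summation over the tables below.

Two evaluation routes are provided and kept deliberately independent:

* :func:`hairpin_energy` scores a *given* single stem-loop fold.
* :func:`enumerate_mfe` searches *all* nested secondary structures of a
  short sequence for the global minimum under the same tables.

The second route is the verification oracle for the first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

__all__ = [
    "EnergyModel",
    "VALID_PAIRS",
    "hairpin_energy",
    "structure_energy",
    "enumerate_mfe",
    "sequence_mfe",
    "parse_dot_bracket",
]

#: Gas constant times 310.15 K, kcal/mol.
RT37 = 0.0019872 * 310.15

#: Base pairs the model can close.
VALID_PAIRS = frozenset({"AU", "UA", "CG", "GC", "GU", "UG"})

#: Pairs that attract the helix-end penalty when they terminate a helix.
_WEAK_ENDS = frozenset({"AU", "UA", "GU", "UG"})

# Stacking free energies, kcal/mol at 37 degC.  Key is (pair1, pair2)
# for the doublet 5'-X1 X2-3' / 3'-Y1 Y2-5' with pair1 = X1.Y1 and
# pair2 = X2.Y2.  Only one member of each symmetry-related pair of
# doublets is listed; _complete_stacks() fills in the mirror images via
# dG(p1, p2) == dG(rev(p2), rev(p1)).
_STACK_SEED = {
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CG", "UA"): -2.08,
    ("CG", "AU"): -2.11,
    ("GC", "UA"): -2.24,
    ("GC", "AU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GC", "GC"): -3.26,
    ("GC", "CG"): -3.42,
    # wobble-containing doublets
    ("AU", "GU"): -0.55,
    ("AU", "UG"): -1.36,
    ("UA", "GU"): -1.00,
    ("UA", "UG"): -1.27,
    ("CG", "GU"): -1.41,
    ("CG", "UG"): -2.11,
    ("GC", "GU"): -1.53,
    ("GC", "UG"): -2.51,
    ("GU", "GU"): 0.47,
    ("GU", "UG"): 1.29,
    ("UG", "GU"): -0.30,
}


def _rev(pair: str) -> str:
    return pair[::-1]


def _complete_stacks(seed: dict) -> dict:
    table = dict(seed)
    for (p1, p2), dg in seed.items():
        mirror = (_rev(p2), _rev(p1))
        if mirror in table and abs(table[mirror] - dg) > 1e-9:
            raise ValueError(f"inconsistent stack symmetry for {mirror}")
        table[mirror] = dg
    return table


_STACKS = _complete_stacks(_STACK_SEED)

# Hairpin-loop initiation, kcal/mol, loop sizes 3..9 tabulated; 10..30
# extended with the Jacobson-Stockmayer 1.75*RT*ln(n/9) term at build
# time so the table itself covers 3..30.
_LOOP_SEED = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}


def _build_loop_table() -> dict:
    table = dict(_LOOP_SEED)
    for n in range(10, 31):
        table[n] = round(_LOOP_SEED[9] + 1.75 * RT37 * math.log(n / 9.0), 2)
    return table


@dataclass(frozen=True)
class EnergyModel:
    """Parameter container for the stem-loop free-energy model."""

    stack_dg: dict = field(default_factory=lambda: dict(_STACKS))
    hairpin_loop_init: dict = field(default_factory=_build_loop_table)
    au_end_penalty: float = 0.45
    temperature: float = 37.0

    def stack(self, pair1: str, pair2: str) -> float:
        """dG of stacking ``pair2`` directly inside ``pair1``."""
        try:
            return self.stack_dg[(pair1, pair2)]
        except KeyError:
            raise ValueError(f"no stacking entry for doublet {pair1}/{pair2}")

    def loop_init(self, size: int) -> float:
        """Hairpin-loop initiation dG for ``size`` unpaired nucleotides."""
        if size < 3:
            raise ValueError("hairpin loop must contain at least 3 nt")
        if size in self.hairpin_loop_init:
            return self.hairpin_loop_init[size]
        top = max(self.hairpin_loop_init)
        return self.hairpin_loop_init[top] + 1.75 * RT37 * math.log(size / top)

    def end_penalty(self, pair: str) -> float:
        return self.au_end_penalty if pair in _WEAK_ENDS else 0.0


DEFAULT_MODEL = EnergyModel()


def hairpin_energy(stem5: str, loop: str, stem3: str,
                   model: EnergyModel = DEFAULT_MODEL) -> float:
    """Free energy of a fully paired stem-loop fold, kcal/mol.

    The fold is the canonical one: ``stem5[i]`` pairs ``stem3[-1 - i]``
    and the loop is entirely unpaired.  Returns ``min(dG, 0.0)`` — a
    fold less stable than the open chain is reported as 0 (unfolded
    reference state).
    """
    n = len(stem5)
    if n == 0:
        raise ValueError("no stem")
    if len(stem3) != n:
        raise ValueError("not a closed stem: arm lengths differ")
    pairs = []
    for i in range(n):
        p = stem5[i] + stem3[n - 1 - i]
        if p not in VALID_PAIRS:
            raise ValueError(f"not a closed stem: {p} at stem index {i}")
        pairs.append(p)
    dg = model.loop_init(len(loop))
    for i in range(n - 1):
        dg += model.stack(pairs[i], pairs[i + 1])
    dg += model.end_penalty(pairs[0])      # outer helix terminus
    dg += model.end_penalty(pairs[-1])     # loop-closing terminus
    return min(dg, 0.0)


# ---------------------------------------------------------------------------
# structure scoring and exhaustive MFE search
# ---------------------------------------------------------------------------

def parse_dot_bracket(db: str) -> list:
    """Return the list of (i, j) pairs encoded by a dot-bracket string."""
    stack, pairs = [], []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"bad dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return sorted(pairs)


def structure_energy(seq: str, db: str, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Score an arbitrary nested structure under the model.

    Adjacent pairs stack; each helix pays the end penalty once per open
    terminus; a pair enclosing only unpaired bases pays hairpin-loop
    initiation.  Bulge/internal/multibranch loops carry no penalty in
    this reduced model (they simply interrupt stacking).
    """
    if len(seq) != len(db):
        raise ValueError("sequence/structure length mismatch")
    pairs = parse_dot_bracket(db)
    pairset = set(pairs)
    paired = [False] * len(seq)
    for i, j in pairs:
        paired[i] = paired[j] = True
    dg = 0.0
    for i, j in pairs:
        p = seq[i] + seq[j]
        if p not in VALID_PAIRS:
            raise ValueError(f"invalid pair {p} at ({i},{j})")
        inner = (i + 1, j - 1) in pairset
        outer = (i - 1, j + 1) in pairset
        if inner:
            dg += model.stack(p, seq[i + 1] + seq[j - 1])
        else:
            dg += model.end_penalty(p)
        if not outer:
            dg += model.end_penalty(p)
        if not any(paired[k] for k in range(i + 1, j)):
            dg += model.loop_init(j - i - 1)
    return dg


_MAX_ENUM_LEN = 25
_MIN_LOOP = 3


def enumerate_mfe(seq: str, model: EnergyModel = DEFAULT_MODEL):
    """Global MFE over all nested structures of a short sequence.

    Exhaustive interval search under the same tables as
    :func:`hairpin_energy` / :func:`structure_energy`; the open chain
    (energy 0) is always a candidate so the returned dG is <= 0.  Ties
    are broken toward fewer pairs, then the lexicographically smallest
    dot-bracket among the optimal decompositions.

    Returns ``(dot_bracket, dG)``.
    """
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    if n > _MAX_ENUM_LEN:
        raise ValueError(f"sequence longer than enumeration cap of {_MAX_ENUM_LEN} nt")
    if any(c not in "ACGU" for c in seq):
        raise ValueError("sequence must be RNA (ACGU)")

    def can_pair(i: int, j: int) -> bool:
        return seq[i] + seq[j] in VALID_PAIRS and j - i - 1 >= _MIN_LOOP

    @lru_cache(maxsize=None)
    def closed(i: int, j: int):
        """Best (dG, npairs, db) for [i, j] given that (i, j) pairs.

        The helix-end penalty for the *outer* side of (i, j) is not
        included here; callers add it when the outer side is open.
        """
        p = seq[i] + seq[j]
        best = None
        # hairpin closure: everything inside unpaired
        cand = (model.loop_init(j - i - 1) + model.end_penalty(p),
                1, "(" + "." * (j - i - 1) + ")")
        best = cand
        # stacked continuation
        if i + 1 < j - 1 and can_pair(i + 1, j - 1):
            e, k, db = closed(i + 1, j - 1)
            cand = (e + model.stack(p, seq[i + 1] + seq[j - 1]), k + 1, "(" + db + ")")
            if _better(cand, best):
                best = cand
        # interrupted interior (bulge/internal/multibranch): at least one
        # pair inside, but (i+1, j-1) not paired to each other
        interior = open_nonempty(i + 1, j - 1, forbid_span=True)
        if interior is not None:
            e, k, db = interior
            cand = (e + model.end_penalty(p), k + 1, "(" + db + ")")
            if _better(cand, best):
                best = cand
        return best

    @lru_cache(maxsize=None)
    def free(i: int, j: int):
        """Best (dG, npairs, db) for [i, j] with no constraint."""
        if i > j:
            return (0.0, 0, "")
        best = None
        e, k, db = free(i + 1, j)
        best = (e, k, "." + db)
        for m in range(i + _MIN_LOOP + 1, j + 1):
            if not can_pair(i, m):
                continue
            e1, k1, db1 = closed(i, m)
            e1 += model.end_penalty(seq[i] + seq[m])  # outer side open
            e2, k2, db2 = free(m + 1, j)
            cand = (e1 + e2, k1 + k2, db1 + db2)
            if _better(cand, best):
                best = cand
        return best

    def open_nonempty(i: int, j: int, forbid_span: bool = False):
        """Best structure of [i, j] containing >= 1 pair; optionally
        excluding the one where i pairs j."""
        if i > j:
            return None
        best = None
        sub = open_nonempty(i + 1, j)
        if sub is not None:
            e, k, db = sub
            cand = (e, k, "." + db)
            best = cand
        for m in range(i + _MIN_LOOP + 1, j + 1):
            if forbid_span and m == j:
                continue
            if not can_pair(i, m):
                continue
            e1, k1, db1 = closed(i, m)
            e1 += model.end_penalty(seq[i] + seq[m])
            e2, k2, db2 = free(m + 1, j)
            cand = (e1 + e2, k1 + k2, db1 + db2)
            if best is None or _better(cand, best):
                best = cand
        return best

    e, k, db = free(0, n - 1)
    if e >= -1e-12:
        return "." * n, 0.0
    return db, e


def _better(a, b) -> bool:
    """Tie-break ordering: lower dG, then fewer pairs, then lexicographic."""
    if a[0] < b[0] - 1e-9:
        return True
    if a[0] > b[0] + 1e-9:
        return False
    return (a[1], a[2]) < (b[1], b[2])


def sequence_mfe(seq: str, model: EnergyModel = DEFAULT_MODEL) -> float:
    """MFE of a free short sequence (0.0 if nothing can fold)."""
    return enumerate_mfe(seq, model)[1]
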