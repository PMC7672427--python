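"""Stem-loop regulation elements for 5'-UTRs.

A regulation element ("RgE") is a designed RNA hairpin placed in the
5'-UTR of an mRNA to attenuate translation initiation.  Its efficacy is
governed by three properties: the fold free energy (dG), the
GC-content of the stem, and the position of its first nucleotide
relative to the 5'-cap (cap nucleotide = +1).
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass

import numpy as np

from .energy import DEFAULT_MODEL, VALID_PAIRS, EnergyModel, hairpin_energy

__all__ = [
    "Hairpin",
    "PlacedElement",
    "GC_LOW_THRESHOLD",
    "GC_HIGH_THRESHOLD",
    "stem_gc_content",
    "classify_gc",
    "hairpin_mfe",
    "place_element",
    "parse_placed",
    "design_stem",
    "strip_overhangs",
    "hairpins_to_fasta",
    "hairpins_from_fasta",
    "property_table",
]

#: Stem GC fraction below which an element is classed "low".
GC_LOW_THRESHOLD = 0.40
#: Stem GC fraction above which an element is classed "high".
GC_HIGH_THRESHOLD = 0.75

#: Default transcript insertion point: the cloning site cleaves at +15
#: relative to the transcription start, so an element with no spacer and
#: the full leader starts at position 15.
DEFAULT_INSERTION_POINT = 15

#: Unstructured leader used upstream of placed elements (CAA repeats do
#: not base-pair); long enough for the default insertion point.
DEFAULT_LEADER = "ACAACAACAACAAC"


def _normalize_rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    if any(c not in "ACGU" for c in s):
        raise ValueError(f"not an RNA/DNA sequence: {seq!r}")
    return s


@dataclass(frozen=True)
class Hairpin:
    """A single stem-loop element.

    ``stem5`` and ``stem3`` are both given 5'->3'; ``stem5[i]`` pairs
    with ``stem3[len-1-i]``.  ``position`` is the transcript coordinate
    of ``stem5[0]`` with the cap nucleotide at +1.
    """

    name: str
    stem5: str
    loop: str
    stem3: str
    position: int = DEFAULT_INSERTION_POINT

    def __post_init__(self):
        for attr in ("stem5", "loop", "stem3"):
            object.__setattr__(self, attr, _normalize_rna(getattr(self, attr)))
        if len(self.stem5) == 0:
            raise ValueError("no stem")
        if len(self.stem5) != len(self.stem3):
            raise ValueError("not a closed stem: arm lengths differ")
        n = len(self.stem5)
        for i in range(n):
            p = self.stem5[i] + self.stem3[n - 1 - i]
            if p not in VALID_PAIRS:
                raise ValueError(f"not a closed stem: {p} at stem index {i}")
        if len(self.loop) < 3:
            raise ValueError("loop must be at least 3 nt")
        if self.position < 1:
            raise ValueError("position must be >= 1 (cap = +1)")

    @property
    def sequence(self) -> str:
        """Full element sequence, 5'->3' (stem5 + loop + stem3)."""
        return self.stem5 + self.loop + self.stem3

    @property
    def dot_bracket(self) -> str:
        n = len(self.stem5)
        return "(" * n + "." * len(self.loop) + ")" * n

    @classmethod
    def from_sequence(cls, name: str, seq: str, stem_len: int,
                      position: int = DEFAULT_INSERTION_POINT) -> "Hairpin":
        """Split a contiguous element sequence into stem5/loop/stem3."""
        seq = _normalize_rna(seq)
        if len(seq) < 2 * stem_len + 3:
            raise ValueError("sequence too short for the stated stem length")
        return cls(name, seq[:stem_len], seq[stem_len:len(seq) - stem_len],
                   seq[len(seq) - stem_len:], position)


def stem_gc_content(h: Hairpin) -> float:
    """GC fraction over both stem arms; the loop is excluded."""
    stem = h.stem5 + h.stem3
    if not stem:
        raise ValueError("no stem")
    return (stem.count("G") + stem.count("C")) / len(stem)


def classify_gc(frac: float) -> str:
    """Class label {'low','medium','high'} for a stem GC fraction."""
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"GC fraction out of [0, 1]: {frac}")
    if frac < GC_LOW_THRESHOLD:
        return "low"
    if frac > GC_HIGH_THRESHOLD:
        return "high"
    return "medium"


def hairpin_mfe(h: Hairpin, model: EnergyModel = DEFAULT_MODEL) -> float:
    """dG (kcal/mol, 37 degC) of the element's designed fold.

    Cloning overhangs must already be stripped (see
    :func:`strip_overhangs`); only stem and loop enter the calculation.
    Returns ``min(dG, 0.0)``, the open chain being the 0 reference.
    """
    return hairpin_energy(h.stem5, h.loop, h.stem3, model)


def strip_overhangs(seq: str, left: int, right: int) -> str:
    """Remove cloning-overhang nucleotides before any energy calculation."""
    if left < 0 or right < 0:
        raise ValueError("overhang lengths must be >= 0")
    return seq[left:len(seq) - right if right else len(seq)]


@dataclass(frozen=True)
class PlacedElement:
    """A hairpin embedded in a full 5'-UTR."""

    hairpin: Hairpin
    leader: str
    spacer: str
    downstream: str = ""

    @property
    def full_utr(self) -> str:
        return self.leader + self.spacer + self.hairpin.sequence + self.downstream

    @property
    def position(self) -> int:
        """Transcript coordinate of the first stem nucleotide (cap = +1)."""
        return len(self.leader) + len(self.spacer) + 1


def place_element(h: Hairpin, insertion_point: int = DEFAULT_INSERTION_POINT,
                  leader: str = DEFAULT_LEADER, downstream: str = "") -> PlacedElement:
    """Embed a hairpin in a 5'-UTR at its annotated position.

    Elements downstream of the insertion point are pushed there with CAA
    spacer repeats; elements upstream of it keep only a truncated
    leader.  The spacer gap must therefore be a multiple of 3.
    """
    leader = _normalize_rna(leader) if leader else ""
    pos = h.position
    if pos < 3:
        raise ValueError("position must be >= 3")
    if pos > insertion_point:
        gap = pos - insertion_point
        if gap % 3 != 0:
            raise ValueError(
                f"spacer of {gap} nt is not a whole number of CAA repeats")
        spacer = "CAA" * (gap // 3)
        lead = leader[:insertion_point - 1]
    else:
        spacer = ""
        lead = leader[:pos - 1]
    if len(lead) != min(pos, insertion_point) - 1:
        raise ValueError("leader too short for the requested insertion point")
    return PlacedElement(h, lead, spacer, downstream)


def parse_placed(full_utr: str, name: str, stem_len: int, loop_len: int,
                 element_start: int) -> PlacedElement:
    """Re-parse a full UTR back into a placed element.

    ``element_start`` is the 1-based transcript coordinate of the first
    stem nucleotide; round-trips :func:`place_element` output.
    """
    utr = _normalize_rna(full_utr)
    i = element_start - 1
    elem = utr[i:i + 2 * stem_len + loop_len]
    upstream = utr[:i]
    n_caa = 0
    while upstream.endswith("CAA") and n_caa < len(upstream) // 3:
        upstream = upstream[:-3]
        n_caa += 1
    h = Hairpin.from_sequence(name, elem, stem_len, position=element_start)
    return PlacedElement(h, upstream, "CAA" * n_caa,
                         utr[i + 2 * stem_len + loop_len:])


# ---------------------------------------------------------------------------
# target-driven stem design
# ---------------------------------------------------------------------------

_GC_PAIRS = ("GC", "CG")
_AU_PAIRS = ("AU", "UA")


def design_stem(target_dg: float, gc_class: str, loop: str = "GAAA",
                model: EnergyModel = DEFAULT_MODEL, tol: float = 1.0,
                position: int = DEFAULT_INSERTION_POINT, seed: int = 0,
                max_stem: int = 18, n_candidates: int = 400) -> Hairpin:
    """Search for a hairpin whose fold dG hits ``target_dg`` +- ``tol``.

    Stems are searched length-ascending; at each length, pair
    compositions compatible with the requested GC class are sampled with
    a seeded generator and the first feasible candidate wins, so results
    are deterministic for a given seed.
    """
    if target_dg > 0:
        raise ValueError("target dG must be <= 0")
    if gc_class not in ("low", "medium", "high"):
        raise ValueError(f"unknown GC class {gc_class!r}")
    loop = _normalize_rna(loop)
    if len(loop) < 3:
        raise ValueError("loop must be at least 3 nt")
    rng = np.random.default_rng(seed)
    for n in range(2, max_stem + 1):
        for _ in range(n_candidates):
            pairs = _sample_pairs(rng, n, gc_class)
            if pairs is None:
                break
            stem5 = "".join(p[0] for p in pairs)
            stem3 = "".join(p[1] for p in reversed(pairs))
            h = Hairpin(f"designed_{gc_class}_{n}bp", stem5, loop, stem3,
                        position=position)
            if classify_gc(stem_gc_content(h)) != gc_class:
                continue
            if abs(hairpin_mfe(h, model) - target_dg) <= tol:
                return h
    raise ValueError(
        f"unreachable target: no {gc_class}-GC stem of <= {max_stem} bp "
        f"reaches {target_dg} +- {tol} kcal/mol")


def _sample_pairs(rng, n: int, gc_class: str):
    """Draw an ordered list of n base pairs honouring the GC class."""
    if gc_class == "high":
        lo = int(math.ceil(GC_HIGH_THRESHOLD * n + 1e-9))
        if lo * 1.0 / n <= GC_HIGH_THRESHOLD:
            lo += 1
        hi = n
    elif gc_class == "low":
        lo = 0
        hi = int(math.floor(GC_LOW_THRESHOLD * n - 1e-9))
        if hi < 0:
            return None
    else:
        lo = int(math.ceil(GC_LOW_THRESHOLD * n))
        hi = int(math.floor(GC_HIGH_THRESHOLD * n))
    if lo > hi:
        return None
    k = int(rng.integers(lo, hi + 1))
    kinds = ["gc"] * k + ["au"] * (n - k)
    rng.shuffle(kinds)
    return [str(rng.choice(_GC_PAIRS if kd == "gc" else _AU_PAIRS))
            for kd in kinds]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def hairpins_to_fasta(hairpins, path=None) -> str:
    """Write elements as FASTA; the description carries position and dG."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for h in hairpins:
        dg = hairpin_mfe(h)
        records.append(SeqRecord(Seq(h.sequence), id=h.name,
                                 description=f"position={h.position} dg={dg:.2f}"))
    buf = _io.StringIO()
    seqio_write(records, buf, "fasta")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def hairpins_from_fasta(path, stem_lens) -> list:
    """Read elements from FASTA; ``stem_lens`` maps record id -> stem length."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(path, "fasta"):
        pos = DEFAULT_INSERTION_POINT
        for tok in rec.description.split():
            if tok.startswith("position="):
                pos = int(tok.split("=", 1)[1])
        out.append(Hairpin.from_sequence(rec.id, str(rec.seq),
                                         stem_lens[rec.id], position=pos))
    return out


def property_table(hairpins, model: EnergyModel = DEFAULT_MODEL):
    """Per-element property table (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for h in hairpins:
        gc = stem_gc_content(h)
        rows.append({"name": h.name, "dg_kcal_mol": hairpin_mfe(h, model),
                     "gc_fraction": gc, "gc_class": classify_gc(gc),
                     "position": h.position})
    return pd.DataFrame(rows)
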