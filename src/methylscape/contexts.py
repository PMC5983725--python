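"""Cytosine sequence-context classification.

A cytosine's context is read from the two bases immediately 3' of it on its
own strand: CG if the next base is G, CHG if the next base is H (A, C or T)
and the one after is G, CHH if both are H.  Minus-strand cytosines appear as
G on the reference (plus) strand and their context is read leftwards in
complement space.  Cytosines closer than 2 bp to the 3' end of their strand,
or followed by an ambiguous base, carry the :data:`UNDEFINED` sentinel and
are excluded from methylation calling.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

#: Sentinel for positions whose context cannot be determined.
UNDEFINED = "NA"

CONTEXTS = ("CG", "CHG", "CHH")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte codes used by the vectorised scanner
_A, _C, _G, _T = (ord(b) for b in "ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def classify_context(genome: Mapping[str, str], chrom: str, pos: int, strand: str) -> str:
    """Classify the context of one cytosine.

    Parameters
    ----------
    genome
        Mapping of chromosome name to plus-strand sequence.
    chrom, pos, strand
        1-based position and strand of the cytosine.  On the minus strand the
        reference base at ``pos`` is G (a cytosine when read 5'->3' on the
        minus strand).

    Returns
    -------
    str
        ``"CG"``, ``"CHG"``, ``"CHH"`` or :data:`UNDEFINED`.

    Raises
    ------
    ValueError
        If the base at the given position/strand is not a cytosine.
    """
    seq = genome[chrom]
    i = pos - 1
    if i < 0 or i >= len(seq):
        raise ValueError(f"position {pos} outside {chrom} (length {len(seq)})")
    base = seq[i].upper()
    if strand == "+":
        if base != "C":
            raise ValueError(f"{chrom}:{pos}:+ is {base!r}, not a cytosine")
        if i + 2 >= len(seq):
            return UNDEFINED
        nxt = seq[i + 1].upper()
        nn = seq[i + 2].upper()
    elif strand == "-":
        if base != "G":
            raise ValueError(f"{chrom}:{pos}:- is {base!r}, not a cytosine")
        if i - 2 < 0:
            return UNDEFINED
        nxt = seq[i - 1].upper().translate(_COMP)
        nn = seq[i - 2].upper().translate(_COMP)
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if nxt == "G":
        return "CG"
    if nxt in "ACT":
        if nn == "G":
            return "CHG"
        if nn in "ACT":
            return "CHH"
    return UNDEFINED


def find_cytosines(seq: str) -> pd.DataFrame:
    """Locate every context-defined cytosine on both strands of a sequence.

    Returns a DataFrame with columns ``pos`` (1-based), ``strand`` and
    ``context``, sorted by position then strand.  Positions within 2 bp of a
    strand's 3' end and contexts involving ambiguous bases are omitted.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    n = arr.size

    frames = []

    # plus strand: C at i, next bases at i+1, i+2
    idx = np.flatnonzero(arr == _C)
    idx = idx[idx + 2 < n]
    if idx.size:
        n1 = arr[idx + 1]
        n2 = arr[idx + 2]
        frames.append(_context_frame(idx, "+", n1 == _G, _is_h(n1), n2 == _G, _is_h(n2)))

    # minus strand: G at i; next base 3' on minus strand is complement of i-1
    idx = np.flatnonzero(arr == _G)
    idx = idx[idx - 2 >= 0]
    if idx.size:
        p1 = arr[idx - 1]
        p2 = arr[idx - 2]
        # complement(p) == G  <=>  p == C ; complement(p) is H <=> p in {A,G,T}
        frames.append(
            _context_frame(idx, "-", p1 == _C, _is_comp_h(p1), p2 == _C, _is_comp_h(p2))
        )

    if not frames:
        return pd.DataFrame({"pos": pd.Series(dtype=int),
                             "strand": pd.Series(dtype=str),
                             "context": pd.Series(dtype=str)})
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="mergesort", ignore_index=True)


def _is_h(b: np.ndarray) -> np.ndarray:
    return (b == _A) | (b == _C) | (b == _T)


def _is_comp_h(b: np.ndarray) -> np.ndarray:
    # complement is in {A,C,T}  <=>  base is in {T,G,A}
    return (b == _T) | (b == _G) | (b == _A)


def _context_frame(idx, strand, n1_is_g, n1_is_h, n2_is_g, n2_is_h) -> pd.DataFrame:
    context = np.full(idx.size, UNDEFINED, dtype=object)
    context[n1_is_g] = "CG"
    context[n1_is_h & n2_is_g] = "CHG"
    context[n1_is_h & n2_is_h] = "CHH"
    keep = context != UNDEFINED
    return pd.DataFrame(
        {"pos": idx[keep] + 1, "strand": strand, "context": context[keep]}
    )
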