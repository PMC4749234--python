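"""Secondary-structure thermodynamics for design-scale oligonucleotides.

Replaces a full thermodynamic-alignment program with two primitives that
cover what probe/primer screening needs:

* :func:`hairpin_best` — the most stable contiguous stem-loop (stem >= 2 bp,
  loop >= 3 nt) found by exhaustive enumeration, scored by nearest-neighbor
  stacks plus a tabulated entropic loop penalty;
* :func:`dimer_best` — the most stable ungapped complementary register
  between two oligos (self- or cross-dimer), scored as a bimolecular duplex
  over the paired core.

A labelled nucleotide (Z) inside a stem or paired core contributes its
full-match context increments; outside it contributes nothing (the
conservative neutral choice), and a label within 2 nt of a predicted stem
end is flagged with a warning on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .oligo import Oligo, clean_seq, complement, as_dna, revcomp
from .params import NNParamTable
from .thermo import tm_unimolecular, tm_bimolecular, duplex_thermo

MIN_STEM = 2
MIN_LOOP = 3


@dataclass(frozen=True)
class FoldResult:
    """A predicted secondary structure and its thermodynamics."""

    kind: str  # hairpin | homodimer | heterodimer
    dH: float
    dS: float
    tm: float
    structure: tuple[tuple[int, int], ...]  # paired positions (i, j), 0-based
    loop_len: int | None = None  # hairpin only
    warnings: tuple[str, ...] = field(default=())

    def dot_bracket(self, length_a: int, length_b: int | None = None) -> str:
        """Render as dot-bracket; for dimers the two strands are joined by
        ``&`` and the second strand's coordinates follow the first."""
        if length_b is None:
            chars = ["."] * length_a
            for i, j in self.structure:
                chars[i] = "("
                chars[j] = ")"
            return "".join(chars)
        a = ["."] * length_a
        b = ["."] * length_b
        for i, j in self.structure:
            a[i] = "("
            b[j] = ")"
        return "".join(a) + "&" + "".join(b)


def _pairs(a: str, b: str) -> bool:
    """True if bases a (top) and b (bottom) form a Watson-Crick pair;
    Z pairs as T."""
    return complement(as_dna(a)) == as_dna(b)


def _stem_thermo(seq: str, i: int, j: int, s: int, table: NNParamTable) -> tuple[float, float]:
    """Stack sums for a stem pairing (i+k, j-k), k = 0..s-1."""
    dH = 0.0
    dS = 0.0
    for k in range(s - 1):
        top = as_dna(seq[i + k: i + k + 2])
        bottom = as_dna(seq[j - k]) + as_dna(seq[j - k - 1])
        h, sv = table.stack(top, bottom)
        dH += h
        dS += sv
    # label increments inside the stem (flanking pair must also be in the stem)
    for k in range(s):
        for pos, other in ((i + k, j - k), (j - k, i + k)):
            if seq[pos] != "Z":
                continue
            for nb, ctx in ((pos - 1, seq[pos - 1] + "Z" if pos > 0 else None),
                            (pos + 1, "Z" + seq[pos + 1] if pos < len(seq) - 1 else None)):
                if ctx is None:
                    continue
                in_stem = (i <= nb <= i + s - 1) or (j - s + 1 <= nb <= j)
                if in_stem:
                    h, sv = table.z_match_increments[ctx]
                    dH += h
                    dS += sv
    return dH, dS


def hairpin_best(oligo: Oligo | str, table: NNParamTable) -> FoldResult | None:
    """Maximum-Tm stem-loop structure, or ``None`` if no stem can form.

    Enumerates every contiguous stem (length >= 2 bp) enclosing a loop of
    >= 3 nt; scores it as the sum of stem stacks plus the entropic loop
    penalty; the hairpin Tm uses the concentration-free unimolecular form
    Tm = dH/dS - 273.15. Ties resolve to the first structure in (i, j, stem)
    order, making results deterministic.
    """
    seq = oligo.seq if isinstance(oligo, Oligo) else clean_seq(oligo)
    n = len(seq)
    if n > 60:
        raise ValueError("hairpin prediction is limited to oligos <= 60 nt")
    best: FoldResult | None = None
    for i in range(n):
        for j in range(i + 2 * MIN_STEM + MIN_LOOP - 1, n):
            # grow the stem inwards from outermost pair (i, j)
            if not _pairs(seq[i], seq[j]):
                continue
            max_s = 0
            s = 0
            while (i + s < j - s and _pairs(seq[i + s], seq[j - s])
                   and (j - s) - (i + s) - 1 >= MIN_LOOP):
                s += 1
            max_s = s
            for s in range(MIN_STEM, max_s + 1):
                loop_len = (j - s + 1) - (i + s - 1) - 1
                dH, dS = _stem_thermo(seq, i, j, s, table)
                dS_total = dS + table.loop_penalty_ds(loop_len)
                if dH >= 0 or dS_total >= 0:
                    continue  # no melting transition
                tm = tm_unimolecular(dH, dS_total, include_ct=False)
                if best is None or tm > best.tm + 1e-12:
                    pairs = tuple((i + k, j - k) for k in range(s))
                    warns = _label_edge_warnings(seq, i, j, s)
                    best = FoldResult(
                        kind="hairpin", dH=dH, dS=dS_total, tm=tm,
                        structure=pairs, loop_len=loop_len, warnings=warns,
                    )
    return best


def _label_edge_warnings(seq: str, i: int, j: int, s: int) -> tuple[str, ...]:
    """Warn when a label lies outside the stem but within 2 nt of a stem end:
    dye behaviour there is poorly characterised and scored as neutral."""
    stem = set(range(i, i + s)) | set(range(j - s + 1, j + 1))
    edges = (i, i + s - 1, j - s + 1, j)
    warns = []
    for pos, b in enumerate(seq):
        if b == "Z" and pos not in stem and any(abs(pos - e) <= 2 for e in edges):
            warns.append(f"label at position {pos} is within 2 nt of a stem end; "
                         "its effect is not modelled")
    return tuple(warns)


def _core_thermo(core_a: str, core_rb: str, table: NNParamTable, ct: float):
    """Bimolecular thermodynamics of a fully complementary paired core;
    ``core_rb`` is the partner written 3'->5' and may carry labels too."""
    dt = duplex_thermo(core_a, as_dna(core_rb), table, ct=ct)
    dH, dS = dt.dH, dt.dS
    # label increments on the partner strand (its own 5'->3' order is the
    # reverse of core_rb)
    L = len(core_rb)
    for i, ch in enumerate(core_rb):
        if ch != "Z":
            continue
        if i + 1 < L:
            h, s = table.z_match_increments[as_dna(core_rb[i + 1]) + "Z"]
            dH += h
            dS += s
        if i - 1 >= 0:
            h, s = table.z_match_increments["Z" + as_dna(core_rb[i - 1])]
            dH += h
            dS += s
    return dH, dS, tm_bimolecular(dH, dS, ct)


def dimer_best(a: Oligo | str, b: Oligo | str, table: NNParamTable,
               ct: float = 2e-6) -> FoldResult | None:
    """Most stable ungapped complementary register between two oligos.

    Slides ``a`` (5'->3') against ``b`` (antiparallel, 3'->5') through every
    register; within each register every maximal complementary run of >= 3
    bases (>= 2 stacks) is scored as a bimolecular duplex over the paired
    core. Returns the run with the highest Tm, or ``None`` when no such run
    exists.
    """
    import numpy as np

    sa = a.seq if isinstance(a, Oligo) else clean_seq(a)
    sb = b.seq if isinstance(b, Oligo) else clean_seq(b)
    if len(sa) > 60 or len(sb) > 60:
        raise ValueError("dimer scan is limited to oligos <= 60 nt")
    rb = sb[::-1]  # b written 3'->5'
    na, nb = len(sa), len(rb)
    kind = "homodimer" if sa == sb else "heterodimer"
    # a[i] pairs rb[j] at register off = i - j  <=>  as_dna(a)[i] == revcomp(b)[j]
    A = np.frombuffer(as_dna(sa).encode("ascii"), dtype=np.uint8)
    C = np.frombuffer(revcomp(sb).encode("ascii"), dtype=np.uint8)
    M = A[:, None] == C[None, :]
    best: FoldResult | None = None
    for k in range(-(na - 1), nb):
        diag = np.diagonal(M, offset=k)
        if int(diag.sum()) < 3:
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(
            ([0], diag.astype(np.int8), [0]))))
        ia0, jb0 = max(0, -k), max(0, k)
        for r0, r1 in zip(edges[::2], edges[1::2]):
            if r1 - r0 < 3:
                continue
            core_a = sa[ia0 + r0:ia0 + r1]
            core_rb = rb[jb0 + r0:jb0 + r1]
            dH, dS, tm = _core_thermo(core_a, core_rb, table, ct)
            if best is None or tm > best.tm + 1e-12:
                pairs = tuple((ia0 + t, nb - 1 - (jb0 + t))
                              for t in range(r0, r1))
                best = FoldResult(kind=kind, dH=dH, dS=dS, tm=tm,
                                  structure=pairs)
    return best
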