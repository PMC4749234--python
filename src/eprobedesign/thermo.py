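"""Nearest-neighbor duplex thermodynamics with labelled-nucleotide increments.

The engine sums published dinucleotide stack enthalpies/entropies (Watson-
Crick, single internal mismatches, terminal mismatches) plus initiation
terms, applies an entropy-based salt correction, and — for every labelled
thymidine ``Z`` in the probe — adds the incremental (ddH, ddS) terms keyed by
the flanking dinucleotide context:

* both neighbors matched: the full-match context increments (``z_match``),
* a single-base mismatch immediately 5' or 3' of the label: the pooled
  mismatch-side increments (``z_mismatch``).

Units: dH kcal/mol, dS cal/mol/K, temperatures degC at the API surface,
Kelvin internally; R = 1.9872 cal/mol/K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .oligo import Oligo, clean_seq, complement, as_dna
from .params import NNParamTable, R_CAL

T0_K = 273.15
T37_K = 310.15


class ThermoError(ValueError):
    pass


class UnparameterizedDuplexError(ThermoError):
    """Duplex configuration with no nearest-neighbor parameters."""


def gibbs_at(dH: float, dS: float, T: float) -> float:
    """Gibbs free energy dG(T) = dH - (T + 273.15) dS / 1000 (kcal/mol).

    ``T`` is in degC; dH in kcal/mol, dS in cal/mol/K.
    """
    return dH - (T + T0_K) * dS / 1000.0


def tm_bimolecular(dH: float, dS: float, ct: float) -> float:
    """Duplex melting temperature (degC) for two complementary strands,

    Tm = dH / (dS + R ln(C_T / 4)) - 273.15,

    with ``ct`` the total single-strand concentration (mol/L).
    """
    if ct <= 0:
        raise ThermoError(f"total strand concentration must be positive, got {ct}")
    denom = dS + R_CAL * math.log(ct / 4.0)
    if denom == 0:
        raise ThermoError("zero denominator in Tm expression")
    return 1000.0 * dH / denom - T0_K


def tm_unimolecular(dH: float, dS: float, ct: float = 1.0, include_ct: bool = True) -> float:
    """Self-folding melting temperature (degC).

    By default evaluates Tm = dH / (dS + R ln C_T) - 273.15. With
    ``include_ct=False`` the concentration term is dropped (the conventional
    unimolecular form Tm = dH / dS - 273.15); the two coincide at C_T = 1.
    """
    if ct <= 0:
        raise ThermoError(f"concentration must be positive, got {ct}")
    denom = dS + (R_CAL * math.log(ct) if include_ct else 0.0)
    if denom == 0:
        raise ThermoError("zero denominator in Tm expression")
    return 1000.0 * dH / denom - T0_K


@dataclass(frozen=True)
class DuplexThermo:
    """Summed thermodynamics of one duplex or self-fold.

    dG(T) and Tm are pure functions of the fields; the Tm formula is chosen
    by ``molecularity``.
    """

    dH: float
    dS: float
    molecularity: str = "bimolecular"  # or "unimolecular"
    ct: float = 2e-6

    def __post_init__(self) -> None:
        if self.molecularity not in ("bimolecular", "unimolecular"):
            raise ValueError(f"bad molecularity {self.molecularity!r}")

    def gibbs(self, T: float) -> float:
        return gibbs_at(self.dH, self.dS, T)

    @property
    def tm(self) -> float:
        if self.molecularity == "bimolecular":
            return tm_bimolecular(self.dH, self.dS, self.ct)
        return tm_unimolecular(self.dH, self.dS, self.ct)


def duplex_thermo(
    probe: Oligo | str,
    target: str,
    table: NNParamTable,
    ct: float = 2e-6,
    salt_correct: bool = True,
) -> DuplexThermo:
    """Thermodynamics of an end-to-end (gap-free) probe/target hybrid.

    Parameters
    ----------
    probe : Oligo or str
        The (possibly labelled) strand, 5'->3'.
    target : str
        The opposing strand written 3'->5' so that ``target[i]`` faces
        ``probe[i]`` (use :func:`eprobedesign.oligo.pairing_strand` for the
        perfect complement). Must be plain DNA and the same length as the
        probe.
    table : NNParamTable
    ct : float
        Total single-strand concentration (mol/L) used for the derived Tm.
    salt_correct : bool
        Apply the table's entropy-based salt correction.

    Notes
    -----
    ``Z`` pairs as T for all stack lookups; each label then contributes its
    flanking-context increments. A label with single-base mismatches on
    *both* flanks has no published parameters and raises
    :class:`UnparameterizedDuplexError` (run a calibration to add them), as
    do two adjacent labels. A mismatch at the labelled position itself is
    scored by the mismatch stacks with no label increment.
    """
    seq = probe.seq if isinstance(probe, Oligo) else clean_seq(probe)
    cseq = clean_seq(target, allow_z=False)
    if len(seq) != len(cseq):
        raise ThermoError(
            f"probe ({len(seq)} nt) and target ({len(cseq)} nt) must align end-to-end"
        )
    if len(seq) < 2:
        raise ThermoError("duplex must be at least 2 bp")
    if "ZZ" in seq:
        raise UnparameterizedDuplexError("two adjacent labelled nucleotides are unsupported")

    n = len(seq)
    dna = as_dna(seq)
    mismatch = [complement(dna[i]) != cseq[i] for i in range(n)]
    for i in range(n - 1):
        if mismatch[i] and mismatch[i + 1]:
            raise UnparameterizedDuplexError(
                "adjacent mismatches at positions "
                f"{i},{i + 1} have no nearest-neighbor parameters"
            )

    dH = 0.0
    dS = 0.0
    lo, hi = 0, n  # stack window after terminal-mismatch trimming

    # terminal mismatches replace the outermost stack where tabulated
    left_key = cseq[1::-1] + "/" + dna[1::-1]
    tv = table.terminal_stack(left_key) if mismatch[0] else None
    if tv is not None:
        dH += tv[0]
        dS += tv[1]
        lo = 1
    right_key = dna[-2:] + "/" + cseq[-2:]
    tv = table.terminal_stack(right_key) if mismatch[-1] else None
    if tv is not None:
        dH += tv[0]
        dS += tv[1]
        hi = n - 1

    for i in range(lo, hi - 1):
        try:
            h, s = table.stack(dna[i:i + 2], cseq[i:i + 2])
        except KeyError as exc:
            raise UnparameterizedDuplexError(str(exc)) from None
        dH += h
        dS += s

    # initiation terms (terminal pair identity taken from the full sequence)
    for key in ("init", "init_allA/T" if set(dna) <= {"A", "T"} else "init_oneG/C"):
        h, s = table.initiation.get(key, (0.0, 0.0))
        dH += h
        dS += s
    if dna.startswith("T"):
        h, s = table.initiation.get("init_5T/A", (0.0, 0.0))
        dH += h
        dS += s
    if dna.endswith("A"):
        h, s = table.initiation.get("init_5T/A", (0.0, 0.0))
        dH += h
        dS += s
    for end in (dna[0], dna[-1]):
        key = "init_A/T" if end in "AT" else "init_G/C"
        h, s = table.initiation.get(key, (0.0, 0.0))
        dH += h
        dS += s

    # label increments keyed by flanking context
    for i, b in enumerate(seq):
        if b != "Z":
            continue
        mm5 = i > 0 and mismatch[i - 1]
        mm3 = i < n - 1 and mismatch[i + 1]
        if mm5 and mm3:
            raise UnparameterizedDuplexError(
                f"label at position {i} flanked by mismatches on both sides: "
                "no parameters available; run a calibration to derive them"
            )
        if mismatch[i]:
            # mismatch at the labelled base itself: stacks already scored it
            # (Z as T); no published label increment applies.
            continue
        if mm5:
            h, s = table.z_mismatch_increments["NZ/AN"]
            dH += h
            dS += s
        elif i > 0:
            h, s = table.z_match_increments[seq[i - 1] + "Z"]
            dH += h
            dS += s
        if mm3:
            h, s = table.z_mismatch_increments["ZN/NA"]
            dH += h
            dS += s
        elif i < n - 1:
            h, s = table.z_match_increments["Z" + seq[i + 1]]
            dH += h
            dS += s

    if salt_correct:
        dS += table.salt.entropy_correction(n)

    return DuplexThermo(dH=dH, dS=dS, molecularity="bimolecular", ct=ct)


def probe_tm(probe: Oligo | str, table: NNParamTable, ct: float = 2e-6) -> float:
    """Tm of a probe against its perfect complement."""
    from .oligo import pairing_strand

    seq = probe.seq if isinstance(probe, Oligo) else clean_seq(probe)
    return duplex_thermo(seq, pairing_strand(as_dna(seq)), table, ct=ct).tm
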