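"""Synthetic data generators: melting curves, calibration sets, templates.

Everything is deterministic under an explicit seed, and the melting-curve
generator is the exact inverse of the two-state signal model fitted by
:mod:`eprobedesign.meltcurve`, so parameter-recovery tests are
self-consistent. Defaults emulate the calibration experiments the engine's
parameters come from: a 4-95 degC scan, Gaussian noise on the
log-fluorescence, three replicates per duplex, total strand concentration
2 uM.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .oligo import pairing_strand, complement
from .params import NNParamTable, Z_MISMATCH_KEYS
from .thermo import duplex_thermo
from .meltcurve import MeltCurve, model_curve
from .design.task import VariantSpec

# reference oligos used across the structure/designer test experiments: a
# 20-mer with a thymidine at every second position (for positional label
# scans), 15/25-mer variants with T runs at both ends, and two stem-loop
# formers with thymidines in the overhang, stem and loop.
REF_20MER = "TGTGTATCTTTCTCTTTCTC"
REF_15MER = "TTTATCGTTCGCTTT"
REF_25MER = "TTTCCTACCCACTTTTCTCCCATTT"
SELF_A = "ACTTTTTTGCATTAGCAAAT"
SELF_B = "ACTTTCGTTTTTTTAAACGT"


@dataclass(frozen=True)
class SynthSpec:
    """Ground truth for one synthetic melting experiment."""

    dH: float = -70.0
    dS: float = -190.0
    ct: float = 2e-6
    molecularity: str = "bimolecular"
    baseline_unbound: tuple[float, float] = (0.8, -0.002)
    baseline_bound: tuple[float, float] = (2.0, -0.005)
    noise_sigma: float = 0.01
    n_replicates: int = 3
    temp_start: float = 4.0
    temp_stop: float = 95.0
    temp_step: float = 0.5
    seed: int = 0

    def grid(self) -> np.ndarray:
        g = np.arange(self.temp_start, self.temp_stop + 1e-9, self.temp_step)
        if g.size < 2 or np.any(np.diff(g) <= 0):
            raise ValueError("temperature grid must be ascending")
        return g


def gen_melt_curve(spec: SynthSpec) -> list[MeltCurve]:
    """Replicate melting curves from the exact two-state signal model plus
    i.i.d. Gaussian noise in logF; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    t = spec.grid()
    clean = model_curve(t, spec.dH, spec.dS, spec.baseline_unbound,
                        spec.baseline_bound, spec.ct, spec.molecularity)
    out = []
    for r in range(spec.n_replicates):
        noise = rng.normal(0.0, spec.noise_sigma, t.size) if spec.noise_sigma > 0 else 0.0
        out.append(MeltCurve(t.copy(), clean + noise, ct=spec.ct,
                             meta={"replicate": r}))
    return out


def _mismatch_bases(base: str) -> list[str]:
    """Target bases that mispair with ``base`` (anything but its complement)."""
    return [b for b in "ACGT" if b != complement(base)]


def gen_calibration_set(
    table: NNParamTable,
    true_increments: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    noise_sigma: float = 0.01,
    n_replicates: int = 3,
    probe: str = REF_20MER,
    ct: float = 2e-6,
    n_pairs: int = 24,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, tuple[float, float]]]:
    """Synthetic calibration experiment with known ground truth.

    Builds up to ``n_pairs`` labelled-probe/target duplexes covering
    single-base mismatches immediately 5' and 3' of the label (plus one
    far-label control per distinct target for the baseline adjustment),
    simulates their melting curves from a parameter table whose pooled
    mismatch-side increments are replaced by ``true_increments``, and
    returns ``(curves, manifest, truth)`` in the pipeline's file schema.
    """
    if true_increments is None:
        true_increments = dict(table.z_mismatch_increments)
    truth_table = replace_increments(table, true_increments)

    L = len(probe)
    t_positions = [i for i in range(2, L - 2) if probe[i] == "T"]
    pairs = []  # (probe_with_z, target, dist_label_mismatch)
    for zpos in t_positions:
        for side in (-1, +1):
            n_idx = zpos + side
            if not 0 <= n_idx < L:
                continue
            for mbase in _mismatch_bases(probe[n_idx]):
                labelled = probe[:zpos] + "Z" + probe[zpos + 1:]
                target = list(pairing_strand(probe))
                target[n_idx] = mbase
                pairs.append((labelled, "".join(target)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order[:n_pairs]]

    # one far-label (d > 3) control per distinct target
    controls = []
    for target in {t: None for _, t in pairs}:
        mm = [i for i in range(L) if complement(probe[i]) != target[i]]
        far = [i for i in t_positions if all(abs(i - m) > 3 for m in mm)]
        if far:
            zc = far[len(far) // 2]
            controls.append((probe[:zc] + "Z" + probe[zc + 1:], target))
    duplexes = pairs + controls

    curve_rows = []
    manifest_rows = []
    for k, (pseq, target) in enumerate(duplexes):
        thermo = duplex_thermo(pseq, target, truth_table, ct=ct)
        spec = SynthSpec(dH=thermo.dH, dS=thermo.dS, ct=ct,
                         noise_sigma=noise_sigma, n_replicates=n_replicates,
                         seed=int(rng.integers(0, 2**31 - 1)))
        cid = f"pair{k:03d}"
        for r, mc in enumerate(gen_melt_curve(spec)):
            curve_rows.append(pd.DataFrame({
                "curve_id": cid, "replicate": r,
                "temp_C": mc.temps, "logF": mc.logF}))
        zpos = pseq.index("Z")
        manifest_rows.append({
            "curve_id": cid, "probe_seq": pseq,
            "label_pos_from_3p": L - zpos,  # 1-based, counted from the 3' end
            "target_seq": target, "ct_molar": ct})
    curves = pd.concat(curve_rows, ignore_index=True)
    manifest = pd.DataFrame(manifest_rows)
    return curves, manifest, dict(true_increments)


def replace_increments(table: NNParamTable,
                       z_mismatch: dict[str, tuple[float, float]]) -> NNParamTable:
    """Copy of ``table`` with the pooled mismatch-side increments replaced."""
    if set(z_mismatch) != set(Z_MISMATCH_KEYS):
        raise ValueError(f"need exactly keys {Z_MISMATCH_KEYS}")
    return dc_replace(table, z_mismatch_increments=dict(z_mismatch),
                      provenance=dict(table.provenance))


def gen_design_target(length: int, gc: float = 0.5, variant: bool = False,
                      seed: int = 0) -> tuple[str, VariantSpec | None]:
    """Random design template with an optional planted SNP.

    ``gc`` is the per-base G+C probability; the SNP, when requested, is
    planted in the central third of the template (away from the edges where
    no probe could cover it).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])
    template = "".join(np.array(list("ATGC"))[rng.choice(4, size=length, p=p / p.sum())])
    v = None
    if variant:
        pos = int(rng.integers(length // 3, max(2 * length // 3, length // 3 + 1)))
        ref = template[pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        v = VariantSpec(start=pos, ref=ref, alt=alt)
    return template, v
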