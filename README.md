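# eprobedesign

Primer and internal-probe design for qPCR and melting-curve genotyping,
with full thermodynamic support for **Eprobes** — hybridization probes that
carry a single thymidine double-labelled with thiazole orange (sequence
code `Z`). An Eprobe fluoresces only when hybridized, and the intercalating
dye moieties measurably *stabilise* the duplex, so standard DNA
nearest-neighbor parameters mispredict its melting temperature. This
package is for assay developers who need primer/probe sets whose predicted
wild-type and variant melting temperatures are reliable enough to genotype
by melting-curve analysis.

## What it computes

**Thermodynamic engine.** Duplex enthalpy and entropy are summed over
nearest-neighbor dinucleotide stacks (unified Watson–Crick parameters,
published single-mismatch and terminal-mismatch tables, entropy-based salt
correction), and melting temperatures follow

    Tm = ΔH° / (ΔS° + R ln(C_T / 4)) − 273.15        (duplex)
    Tm = ΔH° / (ΔS° + R ln C_T) − 273.15             (self-fold, as printed;
                                                      a switch drops the ln C_T term)

with R = 1.9872 cal mol⁻¹ K⁻¹ and C_T the total single-strand
concentration. Each labelled thymidine adds incremental terms
(ΔΔH°, ΔΔS°) keyed by its flanking dinucleotide context; a single-base
mismatch immediately 5′ or 3′ of the label uses the pooled parameters

| context | ΔΔH° (kcal/mol) | ΔΔS° (cal/mol/K) | ΔΔG°₃₇ (kcal/mol) |
|---------|-----------------|------------------|--------------------|
| mismatch 5′ of label (NTᴱ/AN) | −3.6 | −4.4 | −2.2 |
| mismatch 3′ of label (TᴱN/NA) | −2.9 | −3.2 | −1.9 |

**Designer.** An exhaustive Primer3-style search over every admissible
(left primer, right primer, internal probe) triple — probes on both
strands, every admissible dye-labelling position — minimising a weighted
penalty that covers Tm/length deviations, primer–probe
cross-complementarity, within-template mis-hybridization, probe
self-folding (hairpin Tm ceiling, default 24 °C), and in genotyping mode a
reward for a large allele Tm gap ΔTm = Tm(wild-type) − Tm(variant) under
floors on both Tm values. Label placement obeys the positional rules:
at least 3 positions from either probe end, and either ≥ 3 nt from the
variant (*far* mode, strong signal for both alleles) or within 1 nt
(*near* mode, signal-suppression assays).

**Calibration.** The incremental parameters themselves are derived from
fluorescence melting curves: two-state van't Hoff fits of log-fluorescence
curves (linear bound/unbound baselines), replicate averaging, a
mean-offset baseline adjustment using far-label (d > 3) duplexes, and an
SVD least-squares decomposition into the pooled nearest-neighbor classes.
`eprobedesign calibrate` regenerates the parameter files from a curve file
and manifest.

## Worked example

```python
import eprobedesign as ep

table = ep.default_table()
template, variant = ep.synth.gen_design_target(90, gc=0.45, variant=True, seed=3)

settings = ep.DesignSettings(
    primer_len=(16, 17), primer_len_opt=16,
    primer_tm=(48, 56), primer_tm_opt=52, primer_gc=(0, 100),
    probe_len=(14, 16), probe_len_opt=15,
    probe_tm=(35, 65), probe_tm_opt=50,
    probe_tm_min_wt=30, probe_tm_min_variant=20,
    product_size=(50, 90))
task = ep.DesignTask(template=template, mode="genotyping",
                     variant=variant, settings=settings)
best = ep.choose_primer_probe_sets(task, table)[0]
print(best.left.oligo.seq, best.right.oligo.seq, best.probe.oligo.seq)
print(f"dTm = {best.delta_tm:.2f}")
```

prints

```
GATTTGGCTGGTACTTCGT GGAATGTTTATGGGCCGT GTCCACTGCZACTC
dTm = 13.72
```

i.e. the top-ranked set amplifies a 77-bp product and places a minus-strand
Eprobe (label `Z` at position 10) over the G→T variant; the probe melts
13.7 °C lower on the variant allele than on the wild type — an easily
resolved gap in a melting-curve readout. The same task runs from the shell
via `eprobedesign design task.txt` with Boulder-IO-style `KEY=VALUE`
records, and `eprobedesign melt / fold / calibrate / synth` expose the
engine, the hairpin finder, the calibration pipeline and the synthetic-data
generators individually.

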