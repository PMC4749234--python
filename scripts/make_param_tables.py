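"""Regenerate the shipped default parameter directory.

Materialises the published unified Watson-Crick, internal-mismatch and
terminal-mismatch nearest-neighbor tables from Bio.SeqUtils.MeltingTemp
(DNA_NN3 / DNA_IMM1 / DNA_TMM1), together with the pooled mismatch-adjacent
label increments, placeholder full-match label increments, hairpin-loop
entropic penalties and default salt conditions, into
``src/eprobedesign/data/params``.

Run from the repository root::

    python scripts/make_param_tables.py
"""

from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from Bio.SeqUtils import MeltingTemp as mt

from eprobedesign.params import (
    NNParamTable,
    SaltConditions,
    write_param_files,
    Z_MATCH_KEYS,
    Z_MISMATCH_KEYS,
    PLACEHOLDER_Z_MATCH,
)

OUT = Path(__file__).resolve().parents[1] / "src" / "eprobedesign" / "data" / "params"

# pooled incremental parameters for a single-base mismatch immediately 5'
# (NZ/AN) or 3' (ZN/NA) of the labelled thymidine: (ddH kcal/mol, ddS cal/mol/K)
Z_MISMATCH = {
    "NZ/AN": (-3.6, -4.4),
    "ZN/NA": (-2.9, -3.2),
}

# hairpin-loop free-energy initiation at 37C (kcal/mol) by loop length,
# converted to a purely entropic penalty dS = -1000 * dG37 / 310.15
LOOP_DG37 = {
    3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.1, 8: 4.1, 9: 4.2, 10: 4.3,
    12: 4.5, 14: 4.6, 16: 4.7, 18: 4.8, 20: 4.9, 25: 5.2, 30: 5.4,
}


def main() -> None:
    wc = {k: tuple(v) for k, v in mt.DNA_NN3.items() if "/" in k and not k.startswith("init")}
    init = {k: tuple(v) for k, v in mt.DNA_NN3.items() if k.startswith("init") or k == "sym"}
    imm = {k: tuple(v) for k, v in mt.DNA_IMM1.items() if "I" not in k}
    tmm = {k: tuple(v) for k, v in mt.DNA_TMM1.items()}

    prov = {}
    for k in wc or init:
        prov[k] = "unified98"
    prov.update({k: "unified98" for k in init})
    prov.update({k: "mismatch-lit" for k in imm})
    prov.update({k: "terminal-mm-lit" for k in tmm})
    prov.update({k: "placeholder" for k in Z_MATCH_KEYS})
    prov.update({k: "this-calibration" for k in Z_MISMATCH_KEYS})

    table = NNParamTable(
        wc_stacks=wc,
        mm_stacks=imm,
        terminal_mm=tmm,
        initiation=init,
        z_match_increments={k: PLACEHOLDER_Z_MATCH for k in Z_MATCH_KEYS},
        z_mismatch_increments=dict(Z_MISMATCH),
        loop_ds={n: -1000.0 * g / 310.15 for n, g in LOOP_DG37.items()},
        salt=SaltConditions(),
        provenance=prov,
    )
    table.validate()
    write_param_files(table, OUT)
    print(f"wrote parameter files to {OUT}")


if __name__ == "__main__":
    main()
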