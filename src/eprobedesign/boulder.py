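"""Boulder-IO-style task files, FASTA ingest and report rendering.

Task files are line-oriented ``KEY=VALUE`` records terminated by a line
containing a single ``=``. A leading record without a ``SEQUENCE_TEMPLATE``
provides global settings defaults for the records that follow. Unknown keys
are warned about, never fatal. Reports are byte-stable: sorted keys, fixed
numeric formats (Tm two decimals, penalties four), ``\\n`` newlines, C
locale.
"""

from __future__ import annotations

import warnings
from pathlib import Path

from Bio import SeqIO

from .design.task import DesignTask, DesignSettings, VariantSpec, DesignError
from .design.engine import PrimerProbeSet
from .oligo import clean_seq


class TaskFileError(ValueError):
    pass


_SETTING_KEYS = {
    "PRIMER_MIN_SIZE", "PRIMER_OPT_SIZE", "PRIMER_MAX_SIZE",
    "PRIMER_MIN_TM", "PRIMER_OPT_TM", "PRIMER_MAX_TM",
    "PRIMER_MIN_GC", "PRIMER_OPT_GC_PERCENT", "PRIMER_MAX_GC",
    "PRIMER_PRODUCT_SIZE_RANGE", "PRIMER_PRODUCT_OPT_SIZE",
    "PRIMER_INTERNAL_MIN_SIZE", "PRIMER_INTERNAL_OPT_SIZE", "PRIMER_INTERNAL_MAX_SIZE",
    "PRIMER_INTERNAL_MIN_TM", "PRIMER_INTERNAL_OPT_TM", "PRIMER_INTERNAL_MAX_TM",
    "PRIMER_NUM_RETURN",
    "EPD_HAIRPIN_TM_MAX", "EPD_LABEL_END_MIN_DISTANCE",
    "EPD_PROBE_TM_MIN_WT", "EPD_PROBE_TM_MIN_VARIANT",
    "EPD_PROBE_TERMINAL_CLEAR", "EPD_CT_MOLAR",
    "EPD_FIX_LEFT_END3", "EPD_FIX_RIGHT_END3",
}
_RECORD_KEYS = {
    "SEQUENCE_ID", "SEQUENCE_TEMPLATE", "SEQUENCE_INCLUDED_REGION",
    "SEQUENCE_EXCLUDED_REGION", "EPD_TASK", "EPD_VARIANT",
    "EPD_PROBE_CHEMISTRY", "EPD_LABEL_MODE",
}


def _parse_records(path: Path) -> list[dict[str, str]]:
    records: list[dict[str, str]] = []
    current: dict[str, str] = {}
    with open(path, encoding="ascii") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.strip() == "=":
                if current:
                    records.append(current)
                    current = {}
                continue
            if "=" not in line:
                raise TaskFileError(f"{path}:{ln}: expected KEY=VALUE, got {line!r}")
            key, _, value = line.partition("=")
            current[key.strip()] = value.strip()
    if current:
        records.append(current)
    return records


def parse_variant(text: str) -> VariantSpec:
    """Parse ``start:ref>alt`` (0-based start; empty ref = insertion,
    empty alt = deletion), e.g. ``10:C>T``, ``10:>ACG``, ``10:ACG>``."""
    try:
        pos_part, _, allele_part = text.partition(":")
        ref, sep, alt = allele_part.partition(">")
        if not sep:
            raise ValueError("missing '>'")
        return VariantSpec(start=int(pos_part), ref=ref, alt=alt)
    except (ValueError, DesignError) as exc:
        raise TaskFileError(f"malformed EPD_VARIANT value {text!r}: {exc}") from None


def _region(text: str) -> tuple[int, int]:
    start, _, length = text.replace(",", " ").partition(" ")
    return (int(start), int(start) + int(length))


def _settings_from_record(rec: dict[str, str], base: DesignSettings) -> DesignSettings:
    kw = {}
    g = rec.get
    if "PRIMER_MIN_SIZE" in rec or "PRIMER_MAX_SIZE" in rec:
        kw["primer_len"] = (int(g("PRIMER_MIN_SIZE", base.primer_len[0])),
                            int(g("PRIMER_MAX_SIZE", base.primer_len[1])))
    if "PRIMER_OPT_SIZE" in rec:
        kw["primer_len_opt"] = int(rec["PRIMER_OPT_SIZE"])
    if "PRIMER_MIN_TM" in rec or "PRIMER_MAX_TM" in rec:
        kw["primer_tm"] = (float(g("PRIMER_MIN_TM", base.primer_tm[0])),
                           float(g("PRIMER_MAX_TM", base.primer_tm[1])))
    if "PRIMER_OPT_TM" in rec:
        kw["primer_tm_opt"] = float(rec["PRIMER_OPT_TM"])
    if "PRIMER_MIN_GC" in rec or "PRIMER_MAX_GC" in rec:
        kw["primer_gc"] = (float(g("PRIMER_MIN_GC", base.primer_gc[0])),
                           float(g("PRIMER_MAX_GC", base.primer_gc[1])))
    if "PRIMER_OPT_GC_PERCENT" in rec:
        kw["primer_gc_opt"] = float(rec["PRIMER_OPT_GC_PERCENT"])
    if "PRIMER_PRODUCT_SIZE_RANGE" in rec:
        lo, _, hi = rec["PRIMER_PRODUCT_SIZE_RANGE"].partition("-")
        kw["product_size"] = (int(lo), int(hi))
    if "PRIMER_PRODUCT_OPT_SIZE" in rec:
        kw["product_size_opt"] = int(rec["PRIMER_PRODUCT_OPT_SIZE"])
    if "PRIMER_INTERNAL_MIN_SIZE" in rec or "PRIMER_INTERNAL_MAX_SIZE" in rec:
        kw["probe_len"] = (int(g("PRIMER_INTERNAL_MIN_SIZE", base.probe_len[0])),
                           int(g("PRIMER_INTERNAL_MAX_SIZE", base.probe_len[1])))
    if "PRIMER_INTERNAL_OPT_SIZE" in rec:
        kw["probe_len_opt"] = int(rec["PRIMER_INTERNAL_OPT_SIZE"])
    if "PRIMER_INTERNAL_MIN_TM" in rec or "PRIMER_INTERNAL_MAX_TM" in rec:
        kw["probe_tm"] = (float(g("PRIMER_INTERNAL_MIN_TM", base.probe_tm[0])),
                          float(g("PRIMER_INTERNAL_MAX_TM", base.probe_tm[1])))
    if "PRIMER_INTERNAL_OPT_TM" in rec:
        kw["probe_tm_opt"] = float(rec["PRIMER_INTERNAL_OPT_TM"])
    if "PRIMER_NUM_RETURN" in rec:
        kw["top_n"] = int(rec["PRIMER_NUM_RETURN"])
    if "EPD_HAIRPIN_TM_MAX" in rec:
        kw["hairpin_tm_max"] = float(rec["EPD_HAIRPIN_TM_MAX"])
    if "EPD_LABEL_END_MIN_DISTANCE" in rec:
        kw["label_end_min_distance"] = int(rec["EPD_LABEL_END_MIN_DISTANCE"])
    if "EPD_PROBE_TM_MIN_WT" in rec:
        kw["probe_tm_min_wt"] = float(rec["EPD_PROBE_TM_MIN_WT"])
    if "EPD_PROBE_TM_MIN_VARIANT" in rec:
        kw["probe_tm_min_variant"] = float(rec["EPD_PROBE_TM_MIN_VARIANT"])
    if "EPD_PROBE_TERMINAL_CLEAR" in rec:
        kw["probe_terminal_clear"] = int(rec["EPD_PROBE_TERMINAL_CLEAR"])
    if "EPD_CT_MOLAR" in rec:
        kw["ct"] = float(rec["EPD_CT_MOLAR"])
    if "EPD_FIX_LEFT_END3" in rec:
        kw["fix_left_end3"] = int(rec["EPD_FIX_LEFT_END3"])
    if "EPD_FIX_RIGHT_END3" in rec:
        kw["fix_right_end3"] = int(rec["EPD_FIX_RIGHT_END3"])
    if "EPD_LABEL_MODE" in rec:
        kw["label_variant_mode"] = rec["EPD_LABEL_MODE"].lower()
    try:
        return base.with_(**kw) if kw else base
    except (ValueError, DesignError) as exc:
        raise TaskFileError(f"bad setting value: {exc}") from None


def read_task(path: str | Path, defaults: DesignSettings | None = None) -> list[DesignTask]:
    """Parse a task file into :class:`DesignTask` objects.

    A record lacking ``SEQUENCE_TEMPLATE`` but containing only settings keys
    updates the defaults for subsequent records; any other record without a
    template is an error naming the record index.
    """
    path = Path(path)
    records = _parse_records(path)
    settings = defaults or DesignSettings()
    tasks: list[DesignTask] = []
    for idx, rec in enumerate(records):
        unknown = set(rec) - _SETTING_KEYS - _RECORD_KEYS
        if unknown:
            warnings.warn(f"record {idx}: ignoring unknown keys {sorted(unknown)}",
                          stacklevel=2)
        if "SEQUENCE_TEMPLATE" not in rec:
            if set(rec) - _SETTING_KEYS - {"SEQUENCE_ID"} - unknown:
                raise TaskFileError(f"record {idx}: missing SEQUENCE_TEMPLATE")
            settings = _settings_from_record(rec, settings)
            continue
        rec_settings = _settings_from_record(rec, settings)
        variant = parse_variant(rec["EPD_VARIANT"]) if "EPD_VARIANT" in rec else None
        mode = rec.get("EPD_TASK", "pcr").lower()
        mode = {"pcr": "qpcr", "qpcr": "qpcr", "genotyping": "genotyping"}.get(mode)
        if mode is None:
            raise TaskFileError(f"record {idx}: EPD_TASK must be pcr|genotyping")
        excluded = []
        if "SEQUENCE_EXCLUDED_REGION" in rec:
            for chunk in rec["SEQUENCE_EXCLUDED_REGION"].split():
                excluded.append(_region(chunk))
        try:
            tasks.append(DesignTask(
                template=rec["SEQUENCE_TEMPLATE"],
                mode=mode,
                variant=variant,
                included_region=(_region(rec["SEQUENCE_INCLUDED_REGION"])
                                 if "SEQUENCE_INCLUDED_REGION" in rec else None),
                excluded_regions=tuple(excluded),
                probe_chemistry=rec.get("EPD_PROBE_CHEMISTRY", "eprobe").lower(),
                settings=rec_settings,
                seq_id=rec.get("SEQUENCE_ID", f"task{idx}"),
            ))
        except DesignError as exc:
            raise TaskFileError(f"record {idx}: {exc}") from None
    return tasks


def read_fasta(path: str | Path) -> dict[str, str]:
    """Named sequences from a FASTA file (whitespace stripped, upper-cased)."""
    path = Path(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = clean_seq(str(rec.seq).replace(" ", ""), allow_z=False)
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


# ---------------------------------------------------------------------------
# report rendering


def _tm(x: float | None) -> str:
    return "NA" if x is None else f"{x:.2f}"


def _pen(x: float) -> str:
    return f"{x:.4f}"


def write_report(sets: list[PrimerProbeSet], task: DesignTask,
                 fmt: str = "boulder") -> str:
    """Render ranked sets; ``boulder`` output mirrors the input key style
    and is byte-stable; ``human`` output prints 1-based inclusive
    coordinates (stated in its header)."""
    if fmt == "boulder":
        return _boulder_report(sets, task)
    if fmt == "human":
        return _human_report(sets, task)
    raise ValueError(f"unknown report format {fmt!r}")


def _boulder_report(sets: list[PrimerProbeSet], task: DesignTask) -> str:
    kv: dict[str, str] = {
        "SEQUENCE_ID": task.seq_id,
        "EPD_TASK": task.mode,
        "EPD_PROBE_CHEMISTRY": task.probe_chemistry,
        "EPD_NUM_RETURNED": str(len(sets)),
    }
    if not sets:
        kv["EPD_DIAGNOSIS"] = "no primer-probe set satisfied the constraints"
    for i, s in enumerate(sets):
        kv[f"PRIMER_LEFT_{i}_SEQUENCE"] = s.left.oligo.seq
        kv[f"PRIMER_LEFT_{i}"] = f"{s.left.oligo.start},{len(s.left.oligo)}"
        kv[f"PRIMER_LEFT_{i}_TM"] = _tm(s.left.tm)
        kv[f"PRIMER_LEFT_{i}_PENALTY"] = _pen(s.left.penalty)
        kv[f"PRIMER_RIGHT_{i}_SEQUENCE"] = s.right.oligo.seq
        kv[f"PRIMER_RIGHT_{i}"] = f"{s.right.oligo.start},{len(s.right.oligo)}"
        kv[f"PRIMER_RIGHT_{i}_TM"] = _tm(s.right.tm)
        kv[f"PRIMER_RIGHT_{i}_PENALTY"] = _pen(s.right.penalty)
        kv[f"PROBE_{i}_SEQUENCE"] = s.probe.oligo.seq
        kv[f"PROBE_{i}"] = f"{s.probe.oligo.start},{len(s.probe.oligo)}"
        kv[f"PROBE_{i}_STRAND"] = s.probe.oligo.strand
        kv[f"PROBE_{i}_TM"] = _tm(s.probe.tm)
        kv[f"PROBE_{i}_PENALTY"] = _pen(s.probe.penalty)
        if s.probe.label_pos is not None:
            kv[f"PROBE_{i}_LABEL_POSITION"] = str(s.probe.label_pos)
        if task.mode == "genotyping":
            kv[f"PROBE_{i}_TM_WT"] = _tm(s.tm_wt)
            kv[f"PROBE_{i}_TM_VARIANT"] = _tm(s.tm_variant)
            kv[f"PROBE_{i}_DELTA_TM"] = _tm(s.delta_tm)
        kv[f"PAIR_{i}_PRODUCT_SIZE"] = str(s.product_size)
        kv[f"PAIR_{i}_PENALTY"] = _pen(s.total_penalty)
    lines = [f"{k}={kv[k]}" for k in sorted(kv)]
    lines.append("=")
    return "\n".join(lines) + "\n"


def _human_report(sets: list[PrimerProbeSet], task: DesignTask) -> str:
    out = [f"# design report for {task.seq_id} ({task.mode} mode; "
           "coordinates 1-based inclusive)"]
    if not sets:
        out.append("no primer-probe set satisfied the constraints")
        return "\n".join(out) + "\n"
    for i, s in enumerate(sets):
        out.append(f"set {i}  total_penalty={_pen(s.total_penalty)}  "
                   f"product={s.product_size} bp")
        for name, c in (("left ", s.left), ("right", s.right), ("probe", s.probe)):
            o = c.oligo
            out.append(f"  {name}  {o.seq:<30} {o.start + 1}-{o.end} ({o.strand})  "
                       f"Tm={_tm(c.tm)}")
        if task.mode == "genotyping":
            out.append(f"  probe Tm wild-type={_tm(s.tm_wt)}  "
                       f"variant={_tm(s.tm_variant)}  delta={_tm(s.delta_tm)}")
    return "\n".join(out) + "\n"


def parse_boulder_report(text: str) -> dict[str, str]:
    """Parse a boulder report back into a key->value map (round-trip aid)."""
    out = {}
    for line in text.splitlines():
        if line.strip() == "=" or not line.strip():
            continue
        k, _, v = line.partition("=")
        out[k] = v
    return out
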