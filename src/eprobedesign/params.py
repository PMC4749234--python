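"""Nearest-neighbor parameter tables and their on-disk format.

A parameter directory holds plain tab-separated files::

    stack_wc.tsv     Watson-Crick dinucleotide stacks
    stack_mm.tsv     single internal-mismatch stacks
    terminal_mm.tsv  terminal-mismatch stacks
    init.tsv         duplex initiation / terminal-pair / symmetry terms
    z_match.tsv      incremental terms for Z flanked by matched pairs
    z_mismatch.tsv   pooled incremental terms for a mismatch next to Z
    loops.tsv        hairpin-loop entropic penalties by loop length
    salt.tsv         cation concentrations and correction scheme

Stack keys follow the ``TOP/BOTTOM`` convention with the top strand written
5'->3' and the bottom strand 3'->5'; reverse-complement-equivalent stacks are
stored once and looked up via the reversed key (``key[::-1]``).

Energetic columns are ``dH_kcal`` (kcal/mol) and ``dS_cal`` (cal/mol/K); a
``provenance`` column records where each entry came from (e.g. ``unified98``,
``mismatch-lit``, ``placeholder``, ``calibrated``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

# gas constant, cal / (mol K)
R_CAL = 1.9872

#: the two pooled mismatch-adjacent label contexts: a single-base mismatch
#: immediately 5' of the labelled thymidine (NZ/AN) or immediately 3' of it
#: (ZN/NA).
Z_MISMATCH_KEYS = ("NZ/AN", "ZN/NA")

#: full-match label contexts keyed by the flanking dinucleotide on the
#: labelled strand (5'->3'); e.g. "AZ" = label with an A 5'-neighbor.
Z_MATCH_KEYS = ("AZ", "CZ", "GZ", "TZ", "ZA", "ZC", "ZG", "ZT")

_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}

STACK_FILES = {
    "wc_stacks": "stack_wc.tsv",
    "mm_stacks": "stack_mm.tsv",
    "terminal_mm": "terminal_mm.tsv",
    "initiation": "init.tsv",
    "z_match_increments": "z_match.tsv",
    "z_mismatch_increments": "z_mismatch.tsv",
}

#: placeholder full-match label increments, shipped only until a calibration
#: run regenerates real values (provenance=placeholder). Stabilising, with
#: dG37 close to the mismatch-adjacent increments.
PLACEHOLDER_Z_MATCH = (-4.0, -6.5)


class ParamFileError(ValueError):
    """Malformed or missing parameter file."""


@dataclass
class SaltConditions:
    """Cation concentrations (mol/L) and the applied correction scheme.

    The default scheme is the entropy-based monovalent correction
    ``dS' = dS + 0.368 (N-1) ln[Na+]`` with divalent cations folded in via
    the equivalent-monovalent conversion ``[Na+]eq = [mon] +
    120 sqrt([Mg2+] - [dNTP]) (mM)``.
    """

    monovalent: float = 0.05
    divalent: float = 0.0
    dntp: float = 0.0
    scheme: str = "santalucia1998-entropy"

    def effective_monovalent(self) -> float:
        """Equivalent monovalent concentration in mol/L."""
        mon_mM = self.monovalent * 1e3
        mg_mM = max(self.divalent - self.dntp, 0.0) * 1e3
        if mg_mM > 0:
            mon_mM += 120.0 * math.sqrt(mg_mM)
        return mon_mM / 1e3

    def entropy_correction(self, n_bases: int) -> float:
        """Additive dS correction (cal/mol/K) for an ``n_bases``-long duplex."""
        na = self.effective_monovalent()
        if na <= 0:
            raise ValueError("non-positive effective monovalent concentration")
        return 0.368 * (n_bases - 1) * math.log(na)


@dataclass
class NNParamTable:
    """Complete nearest-neighbor parameter set for the duplex engine.

    All per-key values are ``(dH_kcal, dS_cal)`` tuples.
    """

    wc_stacks: dict[str, tuple[float, float]]
    mm_stacks: dict[str, tuple[float, float]]
    terminal_mm: dict[str, tuple[float, float]]
    initiation: dict[str, tuple[float, float]]
    z_match_increments: dict[str, tuple[float, float]]
    z_mismatch_increments: dict[str, tuple[float, float]]
    loop_ds: dict[int, float] = field(default_factory=dict)
    salt: SaltConditions = field(default_factory=SaltConditions)
    provenance: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        missing = [k for k in _wc_canonical_keys() if not self._has(self.wc_stacks, k)]
        if missing:
            raise ParamFileError(f"missing Watson-Crick stacks: {missing}")
        for name in ("wc_stacks", "mm_stacks", "terminal_mm", "initiation",
                     "z_match_increments", "z_mismatch_increments"):
            for key, (dh, ds) in getattr(self, name).items():
                g37 = dh - 310.15 * ds / 1000.0
                if not math.isfinite(g37):
                    raise ParamFileError(f"non-finite entry {name}[{key!r}]")
        got = tuple(sorted(self.z_mismatch_increments))
        if got != tuple(sorted(Z_MISMATCH_KEYS)):
            raise ParamFileError(
                f"z_mismatch_increments must have exactly keys {Z_MISMATCH_KEYS}, got {got}"
            )

    @staticmethod
    def _has(d: dict, key: str) -> bool:
        return key in d or key[::-1] in d

    # -- lookups ------------------------------------------------------------

    def stack(self, top: str, bottom: str) -> tuple[float, float]:
        """Look up a dinucleotide stack: ``top`` 5'->3' vs ``bottom`` 3'->5'.

        Watson-Crick stacks are tried first, then the single-mismatch table.
        """
        key = top + "/" + bottom
        for table in (self.wc_stacks, self.mm_stacks):
            if key in table:
                return table[key]
            if key[::-1] in table:
                return table[key[::-1]]
        raise KeyError(f"no stack parameters for {key} "
                       "(more than one mismatch per dinucleotide?)")

    def terminal_stack(self, key: str) -> tuple[float, float] | None:
        if key in self.terminal_mm:
            return self.terminal_mm[key]
        if key[::-1] in self.terminal_mm:
            return self.terminal_mm[key[::-1]]
        return None

    def loop_penalty_ds(self, loop_len: int) -> float:
        """Entropic hairpin-loop penalty (cal/mol/K), linearly interpolated
        between tabulated loop lengths and linearly extrapolated beyond."""
        if not self.loop_ds:
            raise ParamFileError("no loop penalty table loaded")
        pts = sorted(self.loop_ds.items())
        if loop_len <= pts[0][0]:
            return pts[0][1]
        for (l0, s0), (l1, s1) in zip(pts, pts[1:]):
            if l0 <= loop_len <= l1:
                w = (loop_len - l0) / (l1 - l0)
                return s0 + w * (s1 - s0)
        (l0, s0), (l1, s1) = pts[-2], pts[-1]
        slope = (s1 - s0) / (l1 - l0)
        return s1 + slope * (loop_len - l1)


def _wc_canonical_keys() -> list[str]:
    """The 10 unique Watson-Crick stack keys under reverse-complement
    symmetry (canonical form: lexicographically smaller of key / key[::-1])."""
    from .oligo import complement

    seen = set()
    for a in "ACGT":
        for b in "ACGT":
            key = a + b + "/" + complement(a) + complement(b)
            canon = min(key, key[::-1])
            seen.add(canon)
    return sorted(seen)


# ---------------------------------------------------------------------------
# file I/O


def _read_tsv(path: Path) -> list[list[str]]:
    rows = []
    with open(path, encoding="ascii") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append((ln, line.split("\t")))
    return rows


def _read_energy_file(path: Path) -> tuple[dict[str, tuple[float, float]], dict[str, str]]:
    values: dict[str, tuple[float, float]] = {}
    prov: dict[str, str] = {}
    for ln, cells in _read_tsv(path):
        if cells[0] == "key":  # header
            continue
        if len(cells) < 3:
            raise ParamFileError(f"{path.name}:{ln}: expected >=3 columns")
        key = cells[0]
        try:
            dh, ds = float(cells[1]), float(cells[2])
        except ValueError as exc:
            raise ParamFileError(f"{path.name}:{ln}: malformed numeric: {exc}") from None
        values[key] = (dh, ds)
        prov[key] = cells[3] if len(cells) > 3 else ""
    return values, prov


def load_param_tables(path: str | Path) -> NNParamTable:
    """Load a parameter directory into a validated :class:`NNParamTable`.

    A missing ``z_match.tsv`` / ``z_mismatch.tsv`` degrades gracefully to
    clearly flagged placeholder increments (a warning is recorded on the
    table and emitted); a missing Watson-Crick stack file is a hard error.
    """
    path = Path(path)
    if not (path / STACK_FILES["wc_stacks"]).exists():
        raise ParamFileError(f"missing required file {STACK_FILES['wc_stacks']} in {path}")

    tables: dict[str, dict[str, tuple[float, float]]] = {}
    provenance: dict[str, str] = {}
    warn_list: list[str] = []
    for attr, fname in STACK_FILES.items():
        fpath = path / fname
        if not fpath.exists():
            if attr == "z_match_increments":
                tables[attr] = {k: PLACEHOLDER_Z_MATCH for k in Z_MATCH_KEYS}
                for k in Z_MATCH_KEYS:
                    provenance[k] = "placeholder"
                msg = f"{fname} not found; using flagged placeholder label increments"
                warn_list.append(msg)
                warnings.warn(msg, stacklevel=2)
                continue
            if attr == "z_mismatch_increments":
                tables[attr] = {k: PLACEHOLDER_Z_MATCH for k in Z_MISMATCH_KEYS}
                for k in Z_MISMATCH_KEYS:
                    provenance[k] = "placeholder"
                msg = f"{fname} not found; using flagged placeholder mismatch-side increments"
                warn_list.append(msg)
                warnings.warn(msg, stacklevel=2)
                continue
            raise ParamFileError(f"missing required file {fname} in {path}")
        values, prov = _read_energy_file(fpath)
        tables[attr] = values
        provenance.update(prov)

    loop_ds: dict[int, float] = {}
    loops_path = path / "loops.tsv"
    if loops_path.exists():
        for ln, cells in _read_tsv(loops_path):
            if cells[0] == "loop_len":
                continue
            try:
                loop_ds[int(cells[0])] = float(cells[1])
            except ValueError as exc:
                raise ParamFileError(f"loops.tsv:{ln}: malformed numeric: {exc}") from None

    salt = SaltConditions()
    salt_path = path / "salt.tsv"
    if salt_path.exists():
        kv = {}
        for ln, cells in _read_tsv(salt_path):
            if cells[0] == "key":
                continue
            kv[cells[0]] = cells[1]
        try:
            salt = SaltConditions(
                monovalent=float(kv.get("monovalent_M", salt.monovalent)),
                divalent=float(kv.get("divalent_M", salt.divalent)),
                dntp=float(kv.get("dntp_M", salt.dntp)),
                scheme=kv.get("scheme", salt.scheme),
            )
        except ValueError as exc:
            raise ParamFileError(f"salt.tsv: malformed numeric: {exc}") from None

    table = NNParamTable(
        wc_stacks=tables["wc_stacks"],
        mm_stacks=tables["mm_stacks"],
        terminal_mm=tables["terminal_mm"],
        initiation=tables["initiation"],
        z_match_increments=tables["z_match_increments"],
        z_mismatch_increments=tables["z_mismatch_increments"],
        loop_ds=loop_ds,
        salt=salt,
        provenance=provenance,
        warnings=warn_list,
    )
    table.validate()
    return table


def _fmt(x: float) -> str:
    # repr round-trips floats exactly, giving bit-exact write->read identity
    return repr(float(x))


def write_param_files(table: NNParamTable, path: str | Path) -> None:
    """Write a parameter directory; inverse of :func:`load_param_tables`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for attr, fname in STACK_FILES.items():
        values = getattr(table, attr)
        with open(path / fname, "w", encoding="ascii", newline="\n") as fh:
            fh.write("key\tdH_kcal\tdS_cal\tprovenance\n")
            for key in sorted(values):
                dh, ds = values[key]
                prov = table.provenance.get(key, "")
                fh.write(f"{key}\t{_fmt(dh)}\t{_fmt(ds)}\t{prov}\n")
    with open(path / "loops.tsv", "w", encoding="ascii", newline="\n") as fh:
        fh.write("loop_len\tdS_penalty\n")
        for llen in sorted(table.loop_ds):
            fh.write(f"{llen}\t{_fmt(table.loop_ds[llen])}\n")
    with open(path / "salt.tsv", "w", encoding="ascii", newline="\n") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"monovalent_M\t{_fmt(table.salt.monovalent)}\n")
        fh.write(f"divalent_M\t{_fmt(table.salt.divalent)}\n")
        fh.write(f"dntp_M\t{_fmt(table.salt.dntp)}\n")
        fh.write(f"scheme\t{table.salt.scheme}\n")


def default_param_dir() -> Path:
    """Directory of the parameter files shipped with the package."""
    return Path(__file__).parent / "data" / "params"


def default_table() -> NNParamTable:
    """Load the shipped default parameter set."""
    return load_param_tables(default_param_dir())
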