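"""Design-task description: template, regions, variant, settings."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from ..oligo import clean_seq


class DesignError(ValueError):
    pass


class NoCandidatesError(DesignError):
    """Raised when a candidate pool is empty; carries a per-constraint
    rejection census naming the binding constraint."""

    def __init__(self, what: str, census: dict[str, int]):
        self.what = what
        self.census = dict(census)
        worst = max(census, key=census.get) if census else "no admissible window"
        super().__init__(
            f"no {what} candidates; most restrictive constraint: {worst} "
            f"(rejections: {census})"
        )


@dataclass(frozen=True)
class VariantSpec:
    """A genetic variant: replace ``ref`` by ``alt`` at 0-based ``start``.

    Empty ``ref`` is an insertion; empty ``alt`` a deletion.
    """

    start: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", clean_seq(self.ref, allow_z=False) if self.ref else "")
        object.__setattr__(self, "alt", clean_seq(self.alt, allow_z=False) if self.alt else "")
        if self.start < 0:
            raise DesignError("variant start must be >= 0")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


def apply_variant(template: str, v: VariantSpec) -> str:
    """Return the template with the variant applied.

    The template must carry ``ref`` at ``v.start``; the result's length
    changes by ``len(alt) - len(ref)``.
    """
    template = clean_seq(template, allow_z=False)
    if template[v.start:v.start + len(v.ref)] != v.ref:
        raise DesignError(
            f"template does not carry ref allele {v.ref!r} at {v.start} "
            f"(found {template[v.start:v.start + len(v.ref)]!r})"
        )
    return template[:v.start] + v.alt + template[v.start + len(v.ref):]


@dataclass(frozen=True)
class DesignSettings:
    """All tunable design constraints, optima and penalty weights.

    Lengths are nt, temperatures degC, concentrations mol/L. The defaults
    target short qPCR amplicons with a labelled (Eprobe) internal probe:

    * ``hairpin_tm_max`` — probes whose predicted self-folding Tm exceeds
      this ceiling (default 24) are rejected to limit background signal;
    * ``label_end_min_distance`` — the labelled nucleotide must sit at least
      this many positions (1-based, default 3) from either probe end;
    * ``label_variant_mode`` — "far" keeps the label >= 3 nt from the
      variant (strong signal for both alleles), "near" within 1 nt
      (signal-suppression assays);
    * ``probe_terminal_clear`` — number of terminal probe positions in which
      the variant must not fall, pushing the discriminating mismatch toward
      the probe centre;
    * ``probe_tm_min_wt`` / ``probe_tm_min_variant`` — floors keeping both
      allele Tm values above the instrument's detection temperature.
    """

    # primers
    primer_len: tuple[int, int] = (18, 25)
    primer_len_opt: int = 20
    primer_tm: tuple[float, float] = (57.0, 63.0)
    primer_tm_opt: float = 60.0
    primer_gc: tuple[float, float] = (20.0, 80.0)
    primer_gc_opt: float = 50.0
    primer_hairpin_tm_max: float = 47.0
    # probe
    probe_len: tuple[int, int] = (14, 26)
    probe_len_opt: int = 18
    probe_tm: tuple[float, float] = (45.0, 68.0)
    probe_tm_opt: float = 55.0
    probe_tm_min_wt: float = 45.0
    probe_tm_min_variant: float = 35.0
    hairpin_tm_max: float = 24.0
    label_end_min_distance: int = 3
    label_variant_mode: str = "far"  # far | near
    probe_terminal_clear: int = 2
    # product
    product_size: tuple[int, int] = (60, 200)
    product_size_opt: int | None = None
    # fixed 3' ends (template coordinates) for allele-specific primers
    fix_left_end3: int | None = None
    fix_right_end3: int | None = None
    # penalty weights
    wt_primer_tm: float = 1.0
    wt_primer_len: float = 1.0
    wt_primer_gc: float = 0.0
    wt_probe_tm: float = 1.0
    wt_probe_len: float = 0.25
    wt_pair_tm_diff: float = 0.5
    wt_product_size: float = 0.05
    wt_cross_dimer: float = 0.1
    wt_specificity: float = 0.5
    wt_delta_tm: float = -1.0  # reward: larger allele Tm gap lowers the score
    wt_label_rank: float = 0.01
    specificity_min_margin: float = 10.0
    cross_dimer_tm_tol: float = 0.0
    # conditions
    ct: float = 2e-6
    top_n: int = 5

    def __post_init__(self) -> None:
        for name in ("primer_len", "primer_tm", "primer_gc", "probe_len",
                     "probe_tm", "product_size"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise DesignError(f"empty range for {name}: ({lo}, {hi})")
        if self.label_variant_mode not in ("far", "near"):
            raise DesignError(f"label_variant_mode must be far|near, got "
                              f"{self.label_variant_mode!r}")

    def with_(self, **kw) -> "DesignSettings":
        return replace(self, **kw)


@dataclass(frozen=True)
class DesignTask:
    """One design request over a template sequence."""

    template: str
    mode: str = "qpcr"  # qpcr | genotyping
    variant: VariantSpec | None = None
    included_region: tuple[int, int] | None = None  # 0-based half-open
    excluded_regions: tuple[tuple[int, int], ...] = ()
    probe_chemistry: str = "eprobe"  # dna | eprobe
    settings: DesignSettings = field(default_factory=DesignSettings)
    seq_id: str = "task"

    def __post_init__(self) -> None:
        object.__setattr__(self, "template", clean_seq(self.template, allow_z=False))
        n = len(self.template)
        if self.mode not in ("qpcr", "genotyping"):
            raise DesignError(f"mode must be qpcr|genotyping, got {self.mode!r}")
        if self.probe_chemistry not in ("dna", "eprobe"):
            raise DesignError(f"probe_chemistry must be dna|eprobe, got "
                              f"{self.probe_chemistry!r}")
        if self.mode == "genotyping" and self.variant is None:
            raise DesignError("genotyping mode requires a variant")
        regions = list(self.excluded_regions)
        if self.included_region is not None:
            regions.append(self.included_region)
        for lo, hi in regions:
            if not (0 <= lo <= hi <= n):
                raise DesignError(f"region ({lo}, {hi}) outside template of length {n}")
        if self.variant is not None:
            # validates ref allele placement
            apply_variant(self.template, self.variant)

    @property
    def variant_template(self) -> str | None:
        if self.variant is None:
            return None
        return apply_variant(self.template, self.variant)
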