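"""Designer: variant editing, enumeration, label placement, genotyping,
specificity and the combination search against an exhaustive oracle."""

import math

import pytest

from eprobedesign.design import (
    DesignSettings,
    DesignTask,
    NoCandidatesError,
    VariantSpec,
    apply_variant,
    choose_primer_probe_sets,
    enumerate_primers,
    enumerate_probes,
    genotype_tms,
    place_label,
    specificity_check,
)
from eprobedesign.design.engine import _ThermoCache
from eprobedesign.design.task import DesignError
from eprobedesign.oligo import Oligo, pairing_strand, revcomp
from eprobedesign.synth import gen_design_target

from conftest import random_dna

TOY_SETTINGS = DesignSettings(
    primer_len=(16, 17), primer_len_opt=16,
    primer_tm=(48.0, 56.0), primer_tm_opt=52.0,
    primer_gc=(0.0, 100.0),
    probe_len=(14, 16), probe_len_opt=15,
    probe_tm=(35.0, 65.0), probe_tm_opt=50.0,
    probe_tm_min_wt=30.0, probe_tm_min_variant=20.0,
    product_size=(50, 90),
)


class TestApplyVariant:
    def test_empty_edit_is_identity(self):
        tpl = "ACGTACGTACGTACGTACGT"
        assert apply_variant(tpl, VariantSpec(5, "", "")) == tpl

    def test_snp(self):
        tpl = "AAAAACAAAAAAAAAAAAAA"
        out = apply_variant(tpl, VariantSpec(5, "C", "T"))
        assert out[5] == "T" and out[:5] == tpl[:5] and out[6:] == tpl[6:]

    def test_deletion_matches_string_edit_oracle(self):
        tpl = "ACGTACGTACGTACGTACGT"
        v = VariantSpec(7, tpl[7:10], "")
        out = apply_variant(tpl, v)
        assert out == tpl[:7] + tpl[10:]
        assert len(out) == len(tpl) - 3

    def test_insertion(self):
        tpl = "ACGTACGT"
        assert apply_variant(tpl, VariantSpec(4, "", "GGG")) == "ACGTGGGACGT"

    def test_ref_mismatch_rejected(self):
        with pytest.raises(DesignError, match="ref allele"):
            apply_variant("ACGT", VariantSpec(1, "A", "T"))


class TestPlaceLabel:
    def test_no_thymidine(self):
        assert place_label("AAAAAAAAAA", DesignSettings()) == []

    def test_forced_single_position(self):
        # 5-mer of T: end distance 3 leaves only the centre
        assert place_label("TTTTT", DesignSettings()) == [3]

    def test_far_mode_matches_enumeration_oracle(self):
        seq = "".join("T" if (i + 1) % 2 == 0 else "A" for i in range(20))
        st = DesignSettings(label_variant_mode="far")
        got = place_label(seq, st, variant_offset_in_probe=10)
        centre = 10.5
        want = [p for p in range(1, 21)
                if seq[p - 1] == "T" and 3 <= p <= 18 and abs(p - 10) >= 3]
        want.sort(key=lambda p: (-abs(p - 10), abs(p - centre), p))
        assert got == want

    def test_near_mode_keeps_only_adjacent(self):
        seq = "".join("T" if (i + 1) % 2 == 0 else "A" for i in range(20))
        st = DesignSettings(label_variant_mode="near")
        got = place_label(seq, st, variant_offset_in_probe=10)
        assert got and all(abs(p - 10) <= 1 for p in got)


class TestEnumeratePrimers:
    def test_template_too_short_diagnoses(self, table):
        task = DesignTask(template="ACGTACGT", settings=TOY_SETTINGS)
        with pytest.raises(NoCandidatesError):
            enumerate_primers(task, table)

    def test_matches_substring_filter_oracle(self, table):
        tpl, _ = gen_design_target(80, 0.5, seed=7)
        task = DesignTask(template=tpl, settings=TOY_SETTINGS)
        left, right = enumerate_primers(task, table)
        cache = _ThermoCache(table, TOY_SETTINGS.ct)
        st = TOY_SETTINGS
        expect_left = set()
        for s in range(len(tpl)):
            for L in range(st.primer_len[0], st.primer_len[1] + 1):
                if s + L > len(tpl):
                    continue
                seq = tpl[s:s + L]
                tm = cache.tm(seq)
                gc = 100.0 * sum(c in "GC" for c in seq) / L
                if (st.primer_tm[0] <= tm <= st.primer_tm[1]
                        and st.primer_gc[0] <= gc <= st.primer_gc[1]
                        and cache.hairpin_tm(seq) <= st.primer_hairpin_tm_max):
                    expect_left.add((s, L))
        assert {(c.oligo.start, len(c.oligo)) for c in left} == expect_left

    def test_fixed_three_prime_end_restricts_pool(self, table):
        tpl, _ = gen_design_target(80, 0.5, seed=7)
        free_left, _ = enumerate_primers(DesignTask(template=tpl,
                                                    settings=TOY_SETTINGS), table)
        end3 = free_left[0].oligo.end - 1  # a 3' end known to be admissible
        st = TOY_SETTINGS.with_(fix_left_end3=end3)
        left, _right = enumerate_primers(DesignTask(template=tpl, settings=st), table)
        assert left and all(c.oligo.end - 1 == end3 for c in left)
        assert len(left) <= sum(1 for c in free_left if c.oligo.end - 1 == end3)

    def test_primers_avoid_variant_in_genotyping(self, table):
        tpl, v = gen_design_target(90, 0.5, variant=True, seed=12)
        task = DesignTask(template=tpl, mode="genotyping", variant=v,
                          settings=TOY_SETTINGS)
        left, right = enumerate_primers(task, table)
        for c in left + right:
            assert not (c.oligo.start <= v.start < c.oligo.end)


class TestEnumerateProbes:
    def test_strand_counts_equal_for_plain_dna(self, table):
        tpl, _ = gen_design_target(70, 0.5, seed=3)
        task = DesignTask(template=tpl, probe_chemistry="dna",
                          settings=TOY_SETTINGS)
        pool = enumerate_probes(task, table)
        plus = sum(1 for c in pool if c.oligo.strand == "+")
        minus = sum(1 for c in pool if c.oligo.strand == "-")
        assert plus == minus > 0

    def test_genotyping_probes_cover_variant_with_clearance(self, table):
        tpl, v = gen_design_target(90, 0.5, variant=True, seed=12)
        st = TOY_SETTINGS.with_(probe_terminal_clear=3)
        task = DesignTask(template=tpl, mode="genotyping", variant=v,
                          settings=st, probe_chemistry="dna")
        pool = enumerate_probes(task, table)
        for c in pool:
            assert c.oligo.start + 3 <= v.start <= c.oligo.end - 1 - 3

    def test_variant_at_edge_empties_pool(self, table):
        tpl = random_dna_fixed()
        v = VariantSpec(0, tpl[0], "G" if tpl[0] != "G" else "A")
        task = DesignTask(template=tpl, mode="genotyping", variant=v,
                          settings=TOY_SETTINGS, probe_chemistry="dna")
        with pytest.raises(NoCandidatesError, match="probe"):
            enumerate_probes(task, table)

    def test_eprobe_probes_respect_label_rules(self, table):
        tpl, v = gen_design_target(90, 0.5, variant=True, seed=12)
        task = DesignTask(template=tpl, mode="genotyping", variant=v,
                          settings=TOY_SETTINGS)
        pool = enumerate_probes(task, table)
        for c in pool:
            p = c.label_pos
            L = len(c.oligo)
            assert c.oligo.seq[p - 1] == "Z"
            assert p >= 3 and L - p + 1 >= 3
            if c.oligo.strand == "+":
                voff = v.start - c.oligo.start + 1
            else:
                voff = c.oligo.end - v.start
            assert abs(p - voff) >= 3  # far mode default


def random_dna_fixed() -> str:
    import numpy as np

    return random_dna(np.random.default_rng(99), 80)


class TestSpecificity:
    def test_unique_site_returns_none(self, table, rng):
        tpl = random_dna(rng, 80)
        probe = Oligo(tpl[30:45], strand="+", start=30)
        # random 80-mers essentially never carry a second near-match site
        off = specificity_check(probe, tpl, ("+", 30), table)
        assert off is None or off < probe_tm_of(probe, table) - 20

    def test_exact_duplicate_site_matches_intended_tm(self, table, rng):
        core = random_dna(rng, 15)
        tpl = random_dna(rng, 20) + core + random_dna(rng, 10) + core + random_dna(rng, 20)
        probe = Oligo(core, strand="+", start=20)
        off = specificity_check(probe, tpl, ("+", 20), table)
        assert off == pytest.approx(probe_tm_of(probe, table), abs=1e-9)

    def test_near_duplicate_matches_register_oracle(self, table, rng):
        core = random_dna(rng, 15)
        variant = core[:7] + ("A" if core[7] != "A" else "G") + core[8:]
        tpl = random_dna(rng, 18) + core + random_dna(rng, 8) + variant + random_dna(rng, 18)
        probe = Oligo(core, strand="+", start=18)
        got = specificity_check(probe, tpl, ("+", 18), table)
        # oracle: scan both strands naively
        from eprobedesign.design.engine import _probe_target_on
        from eprobedesign.thermo import duplex_thermo, ThermoError, UnparameterizedDuplexError
        best = None
        for strand in ("+", "-"):
            text = core if strand == "+" else revcomp(core)
            for s in range(len(tpl) - 15 + 1):
                if (strand, s) == ("+", 18):
                    continue
                if sum(a != b for a, b in zip(text, tpl[s:s + 15])) > 3:
                    continue
                shadow = Oligo(core, strand=strand, start=s)
                try:
                    t = duplex_thermo(core, _probe_target_on(tpl, shadow, s), table).tm
                except (UnparameterizedDuplexError, ThermoError):
                    continue
                best = t if best is None else max(best, t)
        assert (got is None) == (best is None)
        if best is not None:
            assert got == pytest.approx(best, abs=1e-9)


def probe_tm_of(probe: Oligo, table) -> float:
    from eprobedesign.thermo import duplex_thermo

    return duplex_thermo(probe.seq, pairing_strand(probe.dna_seq), table).tm


class TestGenotypeTms:
    def test_identical_templates_give_zero_delta(self, table, rng):
        tpl = random_dna(rng, 60)
        probe = Oligo(tpl[20:36], strand="+", start=20)
        gt = genotype_tms(probe, tpl, tpl, table)
        assert gt.delta_tm == pytest.approx(0.0, abs=1e-12)

    def test_central_mismatch_destabilises(self, table, rng):
        tpl = random_dna(rng, 60)
        var = tpl[:28] + ("T" if tpl[28] == "G" else "G") + tpl[29:]
        probe = Oligo(tpl[20:36], strand="+", start=20)
        gt = genotype_tms(probe, tpl, var, table)
        assert gt.delta_tm > 0

    def test_cytosine_probe_discriminates_better_than_guanine(self, table):
        # same site and flanks; probe base C yields a C.T mismatch on the
        # variant, probe base G a G.T mismatch: C mismatches are the weakest,
        # G the strongest, so the C probe shows the larger Tm drop
        flank5, flank3 = "ACGTAGCA", "TCAGGCAT"
        wt_c = flank5 + "G" + flank3   # probe base C pairs G
        wt_g = flank5 + "C" + flank3   # probe base G pairs C
        var_c = flank5 + "A" + flank3  # probe C vs A -> C.T pairing partner
        var_g = flank5 + "A" + flank3  # probe G vs A -> G.T
        probe_c = Oligo(pairing_strand(wt_c)[::-1], strand="-", start=0)
        probe_g = Oligo(pairing_strand(wt_g)[::-1], strand="-", start=0)
        d_c = genotype_tms(probe_c, wt_c, var_c, table).delta_tm
        d_g = genotype_tms(probe_g, wt_g, var_g, table).delta_tm
        assert d_c > d_g

    def test_indel_under_probe_is_flagged(self, table, rng):
        tpl = random_dna(rng, 60)
        var = tpl[:28] + tpl[31:]  # 3-nt deletion under the probe
        probe = Oligo(tpl[20:36], strand="+", start=20)
        gt = genotype_tms(probe, tpl, var, table)
        assert gt.indel_mode


def oracle_choose(task, table):
    """Independent exhaustive triple enumeration with its own combination
    logic (shared thermodynamic primitives, separate search/scoring code)."""
    from eprobedesign.design.engine import _ThermoCache

    st = task.settings
    cache = _ThermoCache(table, st.ct)
    left, right = enumerate_primers(task, table, cache)
    probes = enumerate_probes(task, table, cache)
    size_opt = (st.product_size_opt if st.product_size_opt is not None
                else sum(st.product_size) / 2.0)
    rows = []
    for pc in probes:
        off = specificity_check(pc.oligo, task.template,
                                (pc.oligo.strand, pc.oligo.start), table, ct=st.ct)
        margin = math.inf if off is None else pc.tm - off
        if margin < st.specificity_min_margin:
            continue
        spen = (0.0 if math.isinf(margin) else
                st.wt_specificity * max(0.0, st.specificity_min_margin - margin))
        for lc in left:
            if pc.oligo.start < lc.oligo.end:
                continue
            for rc in right:
                if rc.oligo.start < lc.oligo.end or pc.oligo.end > rc.oligo.start:
                    continue
                product = rc.oligo.end - lc.oligo.start
                if not st.product_size[0] <= product <= st.product_size[1]:
                    continue
                worst = max(cache.dimer_tm(lc.oligo.seq, rc.oligo.seq),
                            cache.dimer_tm(lc.oligo.seq, pc.oligo.seq),
                            cache.dimer_tm(rc.oligo.seq, pc.oligo.seq))
                total = (lc.penalty + rc.penalty
                         + st.wt_pair_tm_diff * abs(lc.tm - rc.tm)
                         + st.wt_product_size * abs(product - size_opt)
                         + pc.penalty + spen
                         + st.wt_cross_dimer * max(0.0, worst - st.cross_dimer_tm_tol))
                rows.append(((round(total, 9), abs(product - size_opt),
                              lc.oligo.start, 0 if pc.oligo.strand == "+" else 1,
                              rc.oligo.start, pc.oligo.start, pc.label_pos or 0),
                             lc, rc, pc, total))
    rows.sort(key=lambda r: r[0])
    return rows[:st.top_n]


class TestChoosePrimerProbeSets:
    def test_matches_exhaustive_oracle(self, table):
        for seed, mode in [(3, "genotyping"), (7, "qpcr"), (21, "genotyping")]:
            tpl, v = gen_design_target(90, 0.45, variant=(mode == "genotyping"),
                                       seed=seed)
            task = DesignTask(template=tpl, mode=mode, variant=v,
                              settings=TOY_SETTINGS)
            got = choose_primer_probe_sets(task, table)
            want = oracle_choose(task, table)
            assert len(got) == len(want)
            for g, (tie, lc, rc, pc, total) in zip(got, want):
                assert g.total_penalty == pytest.approx(total, abs=1e-9)
                assert (g.left.oligo, g.right.oligo, g.probe.oligo) == (
                    lc.oligo, rc.oligo, pc.oligo)

    def test_deterministic_reports(self, table):
        from eprobedesign.boulder import write_report

        tpl, v = gen_design_target(90, 0.45, variant=True, seed=3)
        task = DesignTask(template=tpl, mode="genotyping", variant=v,
                          settings=TOY_SETTINGS)
        r1 = write_report(choose_primer_probe_sets(task, table), task)
        r2 = write_report(choose_primer_probe_sets(task, table), task)
        assert r1 == r2

    def test_reverse_complement_template_mirrors_penalties(self, table):
        tpl, _ = gen_design_target(90, 0.45, seed=7)
        t1 = DesignTask(template=tpl, settings=TOY_SETTINGS)
        t2 = DesignTask(template=revcomp(tpl), settings=TOY_SETTINGS)
        s1 = choose_primer_probe_sets(t1, table)
        s2 = choose_primer_probe_sets(t2, table)
        assert [round(s.total_penalty, 9) for s in s1] == [
            round(s.total_penalty, 9) for s in s2]
        n = len(tpl)
        # the top set maps to mirrored coordinates
        a, b = s1[0], s2[0]
        assert b.left.oligo.start == n - a.right.oligo.end
        assert b.right.oligo.end == n - a.left.oligo.start

    def test_shorter_probe_with_larger_delta_ranks_first(self, table):
        # two admissible probe lengths; the shorter one sees the mismatch in
        # a shorter duplex, gets the larger allele Tm gap, and wins even
        # though the length optimum favors the longer probe
        tpl, v = gen_design_target(90, 0.45, variant=True, seed=3)
        st = TOY_SETTINGS.with_(probe_len=(14, 16), probe_len_opt=16,
                                wt_probe_tm=0.0)
        task = DesignTask(template=tpl, mode="genotyping", variant=v,
                          settings=st, probe_chemistry="dna")
        pool = enumerate_probes(task, table)
        by_key = {}
        for c in pool:
            by_key.setdefault((c.oligo.strand, c.oligo.start), {})[len(c.oligo)] = c
        compared = 0
        for variants in by_key.values():
            if 14 in variants and 16 in variants:
                short, long_ = variants[14], variants[16]
                if short.delta_tm > long_.delta_tm + 0.5:
                    compared += 1
                    assert short.penalty < long_.penalty
        assert compared > 0

    def test_genotyping_report_lists_both_allele_tms(self, table):
        from eprobedesign.boulder import write_report

        tpl, v = gen_design_target(90, 0.45, variant=True, seed=3)
        task = DesignTask(template=tpl, mode="genotyping", variant=v,
                          settings=TOY_SETTINGS)
        sets = choose_primer_probe_sets(task, table)
        report = write_report(sets, task)
        assert "PROBE_0_TM_WT" in report
        assert "PROBE_0_TM_VARIANT" in report
        assert "PROBE_0_DELTA_TM" in report
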