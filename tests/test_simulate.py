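"""Generator: reference construction, protection masks, chemistry, salt wash."""

import re

import numpy as np
import pytest

from nomefoot import (ArchitectureConfig, FootprintSpec, NucleosomeSpec,
                      apply_chemistry, classify_contexts, make_reference,
                      simulate_molecules, simulate_salt_condition)


def _noise_free(nucleosomes=(), footprints=(), **kw):
    kw.setdefault("enzyme_efficiency", 1.0)
    kw.setdefault("inconversion_rate", 0.0)
    return ArchitectureConfig(nucleosomes=list(nucleosomes),
                              footprints=list(footprints), **kw)


class TestMakeReference:
    @pytest.mark.parametrize("seed", [1, 7, 31])
    def test_site_counts_near_requested_density(self, seed):
        ref = make_reference(600, gpc_spacing=10, cpg_spacing=25, seed=seed)
        ctx = classify_contexts(ref, strands="+")
        n_gch = sum(c.context == "GCH" for c in ctx)
        n_hcg = sum(c.context == "HCG" for c in ctx)
        assert abs(n_gch - 60) <= 6    # +-10% of length / gpc_spacing
        assert abs(n_hcg - 24) <= 2.4  # +-10% of length / cpg_spacing

    def test_deterministic_for_fixed_seed(self):
        a = make_reference(600, 10, 25, seed=5)
        b = make_reference(600, 10, 25, seed=5)
        c = make_reference(600, 10, 25, seed=6)
        assert a.sequence == b.sequence
        assert a.sequence != c.sequence

    def test_no_ambiguous_gcg_context_on_either_strand(self):
        ref = make_reference(800, 8, 20, seed=3)
        assert "GCG" not in ref.sequence
        assert "CGC" not in ref.sequence  # a GCG on the minus strand

    def test_primer_regions_carry_no_informative_sites(self):
        ref = make_reference(600, 10, 25, seed=2)
        positions = {c.position for c in classify_contexts(ref, strands="both")}
        for a, b in ref.primer_masks:
            assert not positions & set(range(a, b))
            assert "GC" not in ref.sequence[a:b]
            assert "CG" not in ref.sequence[a:b]

    def test_impossible_spacing_raises(self):
        with pytest.raises(ValueError):
            make_reference(200, gpc_spacing=300, seed=1)
        with pytest.raises(ValueError):
            make_reference(100, gpc_spacing=10, seed=1)

    def test_dense_request_rounds_up_to_gcg_free_layout(self):
        # 1 bp GpC spacing cannot exist without creating GCG; the generator
        # falls back to the densest valid layout
        ref = make_reference(1000, gpc_spacing=1, seed=1)
        ctx = [c for c in classify_contexts(ref, strands="both")
               if c.channel != "excluded"]
        assert "GCG" not in ref.sequence
        assert len(ctx) > 400  # roughly two informative sites per 3 bp


class TestSimulateMolecules:
    def test_mask_geometry_without_jitter(self):
        ref = make_reference(1000, 20, 0, seed=1, tss_offset=450,
                             tts_offset=550)
        cfg = _noise_free([NucleosomeSpec(220, 0.0, 1.0)], n_molecules=4,
                          seed=9)
        masks, _ = simulate_molecules(ref, cfg)
        expect = np.zeros(1000, dtype=np.uint8)
        expect[450 + 220 - 73: 450 + 220 + 73] = 1  # dyad +-73 bp = 146 bp
        assert (masks == expect).all()

    def test_occupancy_frequency_binomial(self):
        ref = make_reference(600, 20, 0, seed=1)
        cfg = _noise_free([NucleosomeSpec(0, 0.0, 0.5)], n_molecules=10000,
                          seed=11)
        _, truth = simulate_molecules(ref, cfg)
        frac = truth.occupied[:, 0].mean()
        se = np.sqrt(0.25 / 10000)
        assert abs(frac - 0.5) <= 3 * se

    def test_independent_dyads_joint_frequency(self):
        ref = make_reference(1000, 20, 0, seed=1, tss_offset=500,
                             tts_offset=600)
        cfg = _noise_free(
            [NucleosomeSpec(-200, 0.0, 0.6), NucleosomeSpec(200, 0.0, 0.3)],
            n_molecules=20000, seed=13)
        _, truth = simulate_molecules(ref, cfg)
        p_joint = (truth.occupied[:, 0] & truth.occupied[:, 1]).mean()
        p_prod = truth.occupied[:, 0].mean() * truth.occupied[:, 1].mean()
        assert abs(p_joint - p_prod) < 0.02

    def test_truth_mask_is_union_of_particles(self):
        ref = make_reference(1000, 20, 0, seed=4, tss_offset=450,
                             tts_offset=550)
        cfg = _noise_free([NucleosomeSpec(-150, 30.0, 0.7)],
                          [FootprintSpec(35, 50, 0.5)], ndr=(-100, 200),
                          n_molecules=300, seed=21)
        masks, truth = simulate_molecules(ref, cfg)
        half = cfg.nucleosome_len // 2
        for i in range(0, 300, 37):
            expect = np.zeros(1000, dtype=np.uint8)
            if truth.occupied[i, 0]:
                d = int(truth.dyads[i, 0])
                expect[d - half: d - half + cfg.nucleosome_len] = 1
            expect[350:650] = 0  # NDR carve-out applies to nucleosomes only
            if truth.footprint_present[i, 0]:
                lo, hi = truth.footprint_intervals[0]
                expect[lo:hi] = 1
            assert (masks[i] == expect).all()

    def test_nothing_to_simulate_raises(self):
        ref = make_reference(600, 20, 0, seed=1)
        with pytest.raises(ValueError):
            simulate_molecules(ref, ArchitectureConfig(n_molecules=5))

    def test_dyad_outside_reference_raises(self):
        ref = make_reference(600, 20, 0, seed=1)
        cfg = _noise_free([NucleosomeSpec(5000, 0.0, 1.0)], n_molecules=5)
        with pytest.raises(ValueError):
            simulate_molecules(ref, cfg)

    def test_reproducible_for_fixed_seed(self):
        ref = make_reference(600, 20, 0, seed=1)
        cfg = _noise_free([NucleosomeSpec(-100, 25.0, 0.5)], n_molecules=50,
                          seed=3)
        m1, _ = simulate_molecules(ref, cfg)
        m2, _ = simulate_molecules(ref, cfg)
        assert (m1 == m2).all()


class TestChemistry:
    def test_unprotected_limit_retains_every_informative_cytosine(self):
        ref = make_reference(600, 10, 25, seed=2)
        for mode in ("single", "dual"):
            cfg = _noise_free([NucleosomeSpec(0, 0.0, 0.0)], n_molecules=2,
                              seed=1)
            masks, _ = simulate_molecules(ref, cfg)
            assert not masks.any()
            chem = apply_chemistry(ref, masks, cfg, mode=mode)
            read = chem.reads[0]
            informative = {c.position for c in classify_contexts(ref, mode)
                           if c.channel == "accessibility"}
            for i, base in enumerate(ref.sequence):
                if base != "C":
                    assert read[i] == base
                elif i in informative:
                    assert read[i] == "C"
                elif mode == "single" and read[i] == "C":
                    # endogenous/ambiguous CpG channel may stay methylated
                    # only via M.CviPI on GCG; plain Cs must convert
                    ctx = {c.position: c.context
                           for c in classify_contexts(ref, mode)}
                    assert ctx.get(i) == "GCG"

    def test_fully_protected_limit_converts_every_cytosine(self):
        ref = make_reference(600, 10, 25, seed=2)
        cfg = _noise_free(footprints=[FootprintSpec(0, 600, 1.0)],
                          n_molecules=2, seed=1)
        masks, _ = simulate_molecules(ref, cfg)
        assert masks.all()
        chem = apply_chemistry(ref, masks, cfg, mode="dual")
        assert "C" not in chem.reads[0]
        assert chem.reads[0] == ref.sequence.replace("C", "T")

    def test_inconversion_rate_recovered_on_protected_molecules(self):
        ref = make_reference(1500, 20, 0, seed=6)
        cfg = ArchitectureConfig(
            footprints=[FootprintSpec(0, 1500, 1.0)], n_molecules=300,
            inconversion_rate=0.009, seed=8)
        masks, _ = simulate_molecules(ref, cfg)
        chem = apply_chemistry(ref, masks, cfg)
        sites = [c.position for c in classify_contexts(ref)
                 if c.channel == "accessibility"]
        retained = total = 0
        for read in chem.reads:
            for p in sites:
                retained += read[p] == "C"
                total += 1
        assert total >= 2e4
        se = np.sqrt(0.009 * 0.991 / total)
        assert abs(retained / total - 0.009) <= 3 * se

    def test_dual_mode_on_methylated_locus_warns(self):
        ref = make_reference(600, 10, 25, seed=2)
        cfg = _noise_free([NucleosomeSpec(0, 0.0, 0.0)], n_molecules=2,
                          endogenous_cpg_meth=0.9, seed=1)
        masks, _ = simulate_molecules(ref, cfg)
        chem = apply_chemistry(ref, masks, cfg, mode="dual")
        assert chem.warnings

    def test_deterministic_reads_for_fixed_seed(self):
        ref = make_reference(600, 10, 25, seed=2)
        cfg = ArchitectureConfig(nucleosomes=[NucleosomeSpec(-100, 20.0, 0.6)],
                                 n_molecules=20, seed=17)
        masks, _ = simulate_molecules(ref, cfg)
        r1 = apply_chemistry(ref, masks, cfg).reads
        r2 = apply_chemistry(ref, masks, cfg).reads
        assert r1 == r2


class TestSaltCondition:
    def _setup(self, footprints):
        ref = make_reference(1000, 20, 0, seed=3, tss_offset=450,
                             tts_offset=550)
        cfg = _noise_free([NucleosomeSpec(-200, 0.0, 1.0)], footprints,
                          n_molecules=10, seed=5)
        masks, truth = simulate_molecules(ref, cfg)
        return ref, masks, truth

    def test_labile_footprint_removed_nucleosome_kept(self):
        ref, masks, truth = self._setup([FootprintSpec(35, 50, 1.0, True)])
        salt = simulate_salt_condition(truth)
        assert (salt == truth.nucleosome_mask).all()

    def test_no_footprints_identity(self):
        ref, masks, truth = self._setup([])
        assert (simulate_salt_condition(truth) == masks).all()

    def test_accessibility_gained_only_at_labile_interval(self):
        ref, masks, truth = self._setup([
            FootprintSpec(-50, 40, 1.0, salt_labile=False),
            FootprintSpec(35, 50, 1.0, salt_labile=True)])
        salt = simulate_salt_condition(truth)
        diff = (masks.astype(int) - salt.astype(int))
        changed = np.flatnonzero(diff.any(axis=0))
        lo, hi = truth.footprint_intervals[1]
        assert changed.size > 0
        assert set(changed) <= set(range(lo, hi))
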