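"""Context classification and state calling."""

import re

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nomefoot import (ArchitectureConfig, FootprintSpec, MoleculeStates,
                      NucleosomeSpec, ReferenceLocus, apply_chemistry,
                      call_states, call_states_batch, check_dual_eligibility,
                      classify_contexts, filter_molecules, make_reference,
                      simulate_molecules)


def _ref(seq, tss=None, tts=None):
    n = len(seq)
    return ReferenceLocus("x", seq, tss if tss is not None else 0,
                          tts if tts is not None else n - 1)


class TestClassifyContexts:
    def test_single_gch_site(self):
        ctx = classify_contexts(_ref("AGCAA"))
        assert len(ctx) == 1
        c = ctx[0]
        assert (c.position, c.context, c.strand, c.channel) == \
            (2, "GCH", "+", "accessibility")

    def test_gcg_yields_no_usable_site(self):
        ctx = classify_contexts(_ref("AGCGA"))
        usable = [c for c in ctx if c.channel != "excluded"]
        assert usable == []
        assert any(c.context == "GCG" for c in ctx)

    def test_hcg_channel_depends_on_mode(self):
        ref = _ref("AACGA")
        single = classify_contexts(ref, mode="single")
        dual = classify_contexts(ref, mode="dual")
        assert [c.channel for c in single if c.context == "HCG"] == ["endogenous"]
        assert [c.channel for c in dual if c.context == "HCG"] == ["accessibility"]

    def test_counts_match_regex_oracle_both_strands(self):
        ref = make_reference(600, 10, 25, seed=7)
        s = ref.sequence
        in_primer = set()
        for a, b in ref.primer_masks:
            in_primer |= set(range(a, b))

        def scan(pattern, shift):
            return {m.start() + shift for m in re.finditer(pattern, s)} - in_primer

        oracle = {
            ("GCH", "+"): scan(r"(?=GC[ACT])", 1),
            ("HCG", "+"): scan(r"(?=[ACT]CG)", 1),
            ("GCG", "+"): scan(r"(?=GCG)", 1),
            ("GCH", "-"): scan(r"(?=[ATG]GC)", 1) | scan(r"(?=^GC)", 0),
            ("HCG", "-"): scan(r"(?=CG[ATG])", 1),
            ("GCG", "-"): scan(r"(?=CGC)", 1),
        }
        got: dict[tuple, set] = {}
        for c in classify_contexts(ref, strands="both"):
            got.setdefault((c.context, c.strand), set()).add(c.position)
        for key, positions in oracle.items():
            assert got.get(key, set()) == positions, key

    @given(st.text(alphabet="ACGT", min_size=3, max_size=80))
    def test_channel_partition_covers_every_cytosine(self, seq):
        ref = ReferenceLocus("h", seq, 0, len(seq) - 1) \
            if len(seq) >= 2 else None
        if ref is None:
            return
        from nomefoot.states import CODE_OTHER_C, context_code_arrays
        cp, cm = context_code_arrays(seq)
        n_c_both = seq.count("C") + seq.count("G")
        assert (cp > 0).sum() + (cm > 0).sum() == n_c_both
        ctx = classify_contexts(ref, strands="both")
        n_other = (cp == CODE_OTHER_C).sum() + (cm == CODE_OTHER_C).sum()
        assert len(ctx) + n_other == n_c_both

    def test_dual_mode_never_reduces_accessibility_sites(self):
        for seed in (1, 2, 3):
            ref = make_reference(600, 10, 25, seed=seed)
            n_single = sum(c.channel == "accessibility"
                           for c in classify_contexts(ref, "single"))
            n_dual = sum(c.channel == "accessibility"
                         for c in classify_contexts(ref, "dual"))
            assert n_dual >= n_single


class TestCallStates:
    def test_noise_free_round_trip_recovers_protection_mask(self):
        ref = make_reference(600, 10, 25, seed=2)
        cfg = ArchitectureConfig(
            nucleosomes=[NucleosomeSpec(-100, 0.0, 1.0)],
            enzyme_efficiency=1.0, inconversion_rate=0.0, n_molecules=3,
            seed=4)
        masks, _ = simulate_molecules(ref, cfg)
        for mode in ("single", "dual"):
            chem = apply_chemistry(ref, masks, cfg, mode=mode,
                                   both_strands=True)
            mols = call_states_batch(chem.reads, ref, mode=mode,
                                     read_strands=chem.read_strands,
                                     molecule_ids=chem.molecule_ids)
            for m, strand in zip(mols, chem.read_strands):
                idx = int(m.molecule_id[-5:])
                for p, s in zip(m.acc_positions, m.acc_states):
                    assert s in (0, 1)
                    assert (masks[idx][p] == 1) == (s == 0)

    def test_all_converted_read_is_all_protected(self):
        ref = make_reference(600, 10, 0, seed=2)
        read = ref.sequence.replace("C", "T")
        m = call_states(read, ref)
        assert (m.acc_states == 0).all()
        assert m.conversion_qc == 1.0

    def test_enzyme_efficiency_recovered_at_open_sites(self):
        ref = make_reference(600, 10, 0, seed=2)
        cfg = ArchitectureConfig(
            nucleosomes=[NucleosomeSpec(0, 0.0, 0.0)],
            enzyme_efficiency=0.95, inconversion_rate=0.0, n_molecules=1000,
            seed=6)
        masks, _ = simulate_molecules(ref, cfg)
        chem = apply_chemistry(ref, masks, cfg)
        mols = call_states_batch(chem.reads, ref,
                                 read_strands=chem.read_strands,
                                 molecule_ids=chem.molecule_ids)
        states = np.concatenate([m.acc_states for m in mols])
        frac = np.mean(states == 1)
        se = np.sqrt(0.95 * 0.05 / states.size)
        assert abs(frac - 0.95) <= 3 * se

    def test_length_mismatch_raises(self):
        ref = make_reference(600, 10, 0, seed=2)
        with pytest.raises(ValueError):
            call_states("ACGT", ref)

    def test_zero_informative_sites_warns_and_returns_missing(self, caplog):
        ref = ReferenceLocus("empty", "A" * 300, 100, 200)
        with caplog.at_level("WARNING"):
            m = call_states("A" * 300, ref)
        assert m.n_informative == 0
        assert "zero informative" in caplog.text

    def test_non_ct_bases_are_missing_not_protected(self):
        ref = _ref("AAGCAAA")
        read = "AAGNAAA"  # N at the site position
        m = call_states(read, ref)
        assert m.acc_states.tolist() == [-1]


class TestFilterMolecules:
    def test_threshold_recount(self):
        rng = np.random.default_rng(0)
        mols = []
        for i in range(100):
            qc = rng.uniform(0.8, 1.0)
            n_sites = rng.integers(0, 12)
            states = np.ones(int(n_sites), dtype=np.int8)
            mols.append(MoleculeStates(f"m{i}", "x", np.arange(n_sites),
                                       states, conversion_qc=float(qc)))
        kept = filter_molecules(mols, min_conversion=0.95, min_informative=5)
        expect = [m for m in mols
                  if m.conversion_qc >= 0.95 and m.n_informative >= 5]
        assert [m.molecule_id for m in kept] == [m.molecule_id for m in expect]

    def test_boundary_cases(self):
        good = MoleculeStates("a", "x", np.arange(6), np.ones(6, np.int8),
                              conversion_qc=0.99)
        bad = MoleculeStates("b", "x", np.arange(6), np.ones(6, np.int8),
                             conversion_qc=0.50)
        assert [m.molecule_id for m in filter_molecules([good, bad])] == ["a"]


class TestDualEligibility:
    def _mol(self, endo_states, mid="m0"):
        arr = np.asarray(endo_states, dtype=np.int8)
        return MoleculeStates(mid, "x", np.arange(1), np.ones(1, np.int8),
                              endo_positions=np.arange(arr.size),
                              endo_states=arr)

    def test_unmethylated_locus_is_eligible(self):
        res = check_dual_eligibility([self._mol([0, 0, 0, 0])])
        assert res.eligible and res.mean_endogenous_methylation == 0.0

    def test_fully_methylated_locus_is_ineligible(self):
        res = check_dual_eligibility([self._mol([1, 1, 1, 1])])
        assert not res.eligible

    def test_monoallelic_50_50_pattern_is_ineligible(self):
        # nc886-like: half the molecules fully methylated, half unmethylated
        ref = make_reference(600, 10, 25, seed=9)
        cfg = ArchitectureConfig(
            nucleosomes=[NucleosomeSpec(0, 0.0, 0.0)],
            endogenous_cpg_meth=[(0.5, 1.0), (0.5, 0.0)],
            enzyme_efficiency=1.0, inconversion_rate=0.0, n_molecules=400,
            seed=10)
        masks, _ = simulate_molecules(ref, cfg)
        chem = apply_chemistry(ref, masks, cfg, mode="single")
        mols = call_states_batch(chem.reads, ref,
                                 read_strands=chem.read_strands,
                                 molecule_ids=chem.molecule_ids)
        res = check_dual_eligibility(mols)
        assert not res.eligible
        assert abs(res.mean_endogenous_methylation - 0.5) < 0.05

    def test_zero_hcg_sites_raises(self):
        m = MoleculeStates("m0", "x", np.arange(3), np.ones(3, np.int8))
        with pytest.raises(ValueError):
            check_dual_eligibility([m])
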