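"""Distinguish protein footprints from nucleosomes with a salt-wash
comparison.

A 400 mM NaCl wash strips chromatin-associated proteins but not histones.
Here the simulated architecture carries a salt-labile footprint just
downstream of the TSS (pol III-like) and a salt-resistant footprint just
upstream (TFIIIB-like).  Only the labile footprint should gain
accessibility after the wash.
"""

import numpy as np

from nomefoot import (ArchitectureConfig, FootprintSpec, NucleosomeSpec,
                      apply_chemistry, build_metaplot, call_states_batch,
                      compare_conditions, make_reference, simulate_molecules,
                      simulate_salt_condition)

loci, native, salt = {}, {}, {}
for li in range(8):
    ref = make_reference(1000, gpc_spacing=20, seed=40 + li, tss_offset=450,
                         tts_offset=550, locus_id=f"L{li}")
    cfg = ArchitectureConfig(
        nucleosomes=[NucleosomeSpec(-150, 20.0, 0.8),
                     NucleosomeSpec(220, 20.0, 0.8)],
        footprints=[FootprintSpec(-50, 40, 0.8, salt_labile=False),
                    FootprintSpec(35, 50, 0.8, salt_labile=True)],
        ndr=(-100, 200),
        n_molecules=100,
        seed=500 + li,
    )
    masks, truth = simulate_molecules(ref, cfg)
    chem_n = apply_chemistry(ref, masks, cfg)
    chem_s = apply_chemistry(
        ref, simulate_salt_condition(truth), cfg,
        rng=np.random.default_rng([500 + li, 13]))
    native[ref.locus_id] = call_states_batch(
        chem_n.reads, ref, read_strands=chem_n.read_strands,
        molecule_ids=chem_n.molecule_ids)
    salt[ref.locus_id] = call_states_batch(
        chem_s.reads, ref, read_strands=chem_s.read_strands,
        molecule_ids=chem_s.molecule_ids)
    loci[ref.locus_id] = ref

mp_native = build_metaplot(native, loci, "TSS", flank=400)
mp_salt = build_metaplot(salt, loci, "TSS", flank=400)
flags = compare_conditions(mp_native, mp_salt, min_delta=10.0)

print("simulated footprints: salt-resistant [-70,-30), salt-labile [+10,+60)")
for f in flags:
    print(f"flagged interval [{f.start:+d}, {f.end:+d}) bp: "
          f"+{f.mean_delta:.0f} accessibility points after NaCl")
print("-> only the salt-labile TSS footprint changes; the upstream "
      "(TFIIIB-like) footprint and both nucleosomes are untouched")
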