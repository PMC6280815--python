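"""Alpha diversity, rarefaction, core / rare-biosphere flags, Welch tests.

Computes per-sample diversity descriptors of a synthetic community, flags
the permanent rare taxa, and tests genus proportions between dry and wet
conditions with the two-sided Welch t-test (p < 0.005 flag).
"""

import warnings

import tsen

warnings.simplefilter("ignore")

study = tsen.generate_study(
    tsen.StudyDesign(seed=1), n_genera=150, rb_target=0.9,
    core_fraction=0.3, noise_sd=0.1, seed=1,
)
table = study.genus_table

rep = tsen.alpha_diversity(table.data["A1"])
print(f"sample A1: S_obs={rep.s_obs}  H={rep.shannon:.3f} nats  "
      f"J={rep.pielou:.3f}  Chao1={rep.chao1:.1f}")

depths = [10, 100, 1000, int(table.data['A1'].sum())]
curve = tsen.rarefaction_curve(table.data["A1"], depths)
print("rarefaction:", ", ".join(f"E[S|{d}]={s:.1f}" for d, s in curve))

flags = tsen.core_and_rare(table, rb_threshold=0.01)
both = [t for t in flags.core_taxa if t in set(flags.rare_taxa)]
print(f"core {len(flags.core_taxa)}, rare {len(flags.rare_taxa)}, "
      f"permanently rare core members: {len(both)}")

part = tsen.condition_partition(table)
print(f"shared dry/wet: {len(part['shared'])}, "
      f"unique dry: {len(part['unique']['dry'])}, "
      f"unique wet: {len(part['unique']['wet'])}")

rel = tsen.relative_abundance(table).data
meta = study.design.metadata()
dry = [s for s in table.samples if meta.loc[s, "condition"] == "dry"]
wet = [s for s in table.samples if meta.loc[s, "condition"] == "wet"]
res = tsen.welch_differential(rel[dry], rel[wet], p_cut=0.005)
hits = [r for r in res if r.significant]
print(f"Welch p<0.005 genera: {len(hits)}")
# Chao1 >= S_obs always; a taxon can be both core (present everywhere) and
# rare (below 1% everywhere) -- the permanent rare taxa.
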