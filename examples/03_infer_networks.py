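"""Infer interaction networks from time series and validate against truth.

Fits an ensemble of candidate gLV models to noise-free replicate series,
ranks them by Bray-Curtis regeneration score, builds the consensus network,
splits it by interaction sign, pools sites into a global network, and
checks sign recovery against the known generating model.
"""

import warnings

import numpy as np

import tsen

warnings.simplefilter("ignore")

design = tsen.StudyDesign(n_sites=3, n_timepoints=24, seed=8)
study = tsen.generate_study(
    design, n_genera=6, rb_target=0.0, core_fraction=1.0,
    noise_sd=0.0, seed=8, x0_jitter=1.0, n_internal_steps=48,
)
series = [study.observed_series[s] for s in design.site_labels]

candidates = tsen.infer_candidates(series, n_candidates=100, seed=8)
scores = sorted(c.bcd_score for c in candidates)
print(f"candidate BCD scores: best={scores[0]:.4f} worst={scores[-1]:.4f}")

consensus = tsen.consensus_network(candidates, top_k=20, agreement=0.5)
pos, neg = tsen.split_by_sign(consensus)
fp, fn = tsen.interaction_fractions(consensus)
print(f"consensus: {consensus.n_edges} edges "
      f"({pos.n_edges} positive, {neg.n_edges} negative; "
      f"fractions {fp:.3f}/{fn:.3f})")

best = min(candidates, key=lambda c: c.bcd_score)
A_true = study.truth_model.A
off = ~np.eye(6, dtype=bool)
mags = np.abs(A_true[off])
cut = np.quantile(mags[mags > 0], 1 / 3)
strong = (np.abs(A_true) >= cut) & off & (A_true != 0)
acc = np.mean(np.sign(best.A[strong]) == np.sign(A_true[strong]))
print(f"sign recovery on strong planted edges: {acc:.2f}")
# A BCD near zero means the candidate regenerates the observed profiles
# almost exactly; sign recovery of 1.0 means every strong planted
# interaction was inferred with the correct sign.
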