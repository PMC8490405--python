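"""Score all single mutations of a reference sequence and probe epistasis.

The mutational-effect score is the statistical-energy change dE of the
substitution in the fixed reference background: negative = predicted
beneficial (more family-like), positive = deleterious.
"""

import numpy as np

import ardca
from ardca import fixtures as fx

spec = fx.FixtureSpec(L=8, q=4, M=10_000, seed=5, coupling_scale=0.5)
truth = fx.random_armodel(spec)
alignment = truth.sample(10_000, seed=6)
model, _ = ardca.fit(alignment, ardca.TrainingConfig.preset(
    "effects_contacts", order="entropic", theta=None))

reference = alignment.codes[0]
scan = ardca.dms_scan(model, reference)
print(f"reference: {model.alphabet.decode(reference)}")
best = np.unravel_index(np.argmin(scan.delta_E), scan.delta_E.shape)
worst = np.unravel_index(np.argmax(scan.delta_E), scan.delta_E.shape)
sym = model.alphabet.symbols
print(f"most beneficial substitution: site {best[0] + 1} "
      f"{sym[reference[best[0]]]}->{sym[best[1]]}  "
      f"dE = {scan.delta_E[best]:.3f}")
print(f"most deleterious substitution: site {worst[0] + 1} "
      f"{sym[reference[worst[0]]]}->{sym[worst[1]]}  "
      f"dE = {scan.delta_E[worst]:.3f}")

# epistasis: deviation of a double mutant from additivity of its singles
i, j = 0, 5
bi = int((reference[i] + 1) % model.q)
bj = int((reference[j] + 1) % model.q)
dd = ardca.epistasis(model, reference, (i, bi), (j, bj))
print(f"epistasis ddE of ({i + 1}:{sym[bi]}, {j + 1}:{sym[bj]}) = {dd:.4f}")
print("ddE = 0 would mean the two mutations act independently; its "
      "magnitude measures the effective coupling between the two sites")
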