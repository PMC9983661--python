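"""Entropy estimator bias under multinomial read sampling.

The plug-in entropy of observed proportions underestimates the true
profile entropy at finite library size; the Miller-Madow correction
(m - 1) / (2 N ln 2) removes most of that bias. Shown here on a small
Zipf profile where the effect is visible.
"""

import numpy as np

from liberality import base_profile_zipf, miller_madow_correct, shannon_entropy

rng = np.random.default_rng(0)
G, N, reps = 50, 500, 2000

profile = base_profile_zipf(G, 1.0)
H_true = shannon_entropy(profile)

plugin, corrected = [], []
for counts in rng.multinomial(N, profile.p, size=reps):
    H = shannon_entropy(counts / N)
    plugin.append(H)
    corrected.append(miller_madow_correct(H, int((counts > 0).sum()), N))

print(f"true entropy           : {H_true:.4f} bits")
print(f"plug-in mean           : {np.mean(plugin):.4f} bits "
      f"(bias {np.mean(plugin) - H_true:+.4f})")
print(f"Miller-Madow mean      : {np.mean(corrected):.4f} bits "
      f"(bias {np.mean(corrected) - H_true:+.4f})")
print()
print("The plug-in mean sits below the truth; the corrected mean is closer.")
print("At RNA-seq library sizes (millions of reads) the bias is tiny, which")
print("is why the plug-in estimator is the default.")
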