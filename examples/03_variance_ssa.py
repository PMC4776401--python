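"""Estimate per-channel measurement variance with rank-1 SSA.

Generates a noisy synthetic subject, smooths each channel with the
rank-1 singular-spectrum trend, and compares the recovered standard
deviation with the true injected noise level.
"""

import numpy as np

from glufa import estimate_variance, synth_subject

subject = synth_subject("AA-C3", noise_cv=0.05, seed=42)

print("channel              true sd   SSA sd    (5% multiplicative noise)")
for (proto, chan), true_var in sorted(subject.sigma2.items()):
    series = subject.get(proto, chan)
    est = estimate_variance(series)
    print(
        f"{proto:6s} {chan:10s}   {np.sqrt(true_var):7.3f}   "
        f"{np.sqrt(est.sigma2):7.3f}"
    )

print(
    "\nThe SSA estimate is computed from the raw series alone (no model), "
    "so it can weight the\nfitting objective without being co-estimated "
    "with the kinetic parameters.  A single\nsingular triple tracks the "
    "gently varying meal-test channels well but cannot follow the\nsharp "
    "IV-test excursions, so those sigma estimates also absorb unmodeled "
    "trend -- one\nreason the weights are kept per protocol and channel."
)
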