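"""Vet candidate FRET traces and compute corrected FRET efficiency.

Simulated intensity traces: genuine single dimers (one-step acceptor loss,
anti-correlated donor), two-dimer puncta (multi-step), and flat donor-only
traces.  The vetting stage must keep the first class and name a reason for
rejecting the others; accepted traces then get corrected efficiencies.
"""

import numpy as np
from collections import Counter

from fretspt import CorrectionFactors, compute_fret_efficiency, vet_fret_trace
from fretspt.fretscore import FretTrace
from fretspt.simulate import simulate_trace_set


def as_trace(df):
    return FretTrace(0, 1, df.frame.to_numpy(), df.I_DD.to_numpy(),
                     df.I_AD.to_numpy(), df[["x_um", "y_um"]].to_numpy(),
                     df[["xa_um", "ya_um"]].to_numpy())


singles = [vet_fret_trace(as_trace(df))
           for df, _ in simulate_trace_set(100, seed=11, snr=8.0,
                                           p_internalize=0.3)]
puncta = [vet_fret_trace(as_trace(df))
          for df, _ in simulate_trace_set(100, seed=12, snr=8.0,
                                          multi_step=True)]

print(f"single dimers accepted: {np.mean([t.accepted for t in singles]):.2f}")
print(f"two-dimer puncta rejected: "
      f"{np.mean([not t.accepted for t in puncta]):.2f}")
print("punctum rejection reasons:",
      dict(Counter(t.reason for t in puncta if not t.accepted)))

factors = CorrectionFactors(alpha=0.05, delta=0.02, gamma=1.1)
means = []
for t in singles:
    if t.accepted:
        e = compute_fret_efficiency(t, factors)
        e = e[np.isfinite(e)]
        if len(e):
            means.append(e.mean())
print(f"mean corrected E over {len(means)} accepted traces: "
      f"{np.mean(means):.3f} (generator value 0.90)")
# Multi-step puncta are endocytic-vesicle-like objects carrying several
# dyes; excluding them keeps the lifetime and mobility statistics
# single-complex.
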