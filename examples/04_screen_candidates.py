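"""Screen scored regions for reference-locus-like PTE candidates.

Three criteria, all relative to a known strong tethering element: strong
MEL18 signal, MEL18/SUZ12 ratio above the reference ratio, and strong
MEL18+SUZ12 binding in a second cell line.
"""

import numpy as np
import pandas as pd

from ptetools.screen import ScreenParams, ccnd2_like_screen, high_confidence_ptes

rng = np.random.default_rng(0)
cohort = pd.DataFrame(
    {
        "mel18": rng.uniform(0, 6_000, 12),
        "suz12": rng.uniform(100, 3_000, 12),
        "mel18_second": rng.uniform(0, 6_000, 12),
        "suz12_second": rng.uniform(0, 6_000, 12),
    }
)
# thresholds derived from the scores at a named reference locus
params = ScreenParams.from_reference(
    ref_mel18=6_000, ref_suz12=2_000, ref_mel18_second=5_000, ref_suz12_second=4_000
)
out = ccnd2_like_screen(cohort, params)
cols = ["mel18", "suz12", "mel18_suz12_ratio", "pass_signal", "pass_ratio",
        "pass_second_line", "pass_screen"]
print(out[cols].round(1).to_string(index=False))
print(f"\n{int(out.pass_screen.sum())} of {len(out)} regions pass all three criteria")

# The high-confidence rule applies to refined consensus peaks instead:
peaks = pd.DataFrame(
    {"quartile": ["Q4", "Q4", "Q3", "Q2"], "accuracy": [35.0, 400.0, 120.0, 10.0]}
)
hc = high_confidence_ptes(peaks)
print("\nHigh-confidence PTEs (Q4/Q3 and accuracy better than +-301 bp):")
print(hc.to_string(index=False))
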