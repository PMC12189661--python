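"""Build the summed/averaged PETH and the BE/TT/PE window-rate triple.

A single-type TP-PTP cohort shows the expected signature: elevated rate in
the 1 s tetanization window, partially elevated post-event rate, and a
difference curve near zero before the stimulus.
"""

import numpy as np

from peristim import build_peth, generate_cohort, pooled_window_rates, single_type_spec

spec = single_type_spec("control-SNc", "TP-PTP", n_neurons=100, seed=20250528)
trains, _, _ = generate_cohort(spec)

pooled = pooled_window_rates(trains, spec.windows)
print(f"pooled rates: M_BE={pooled.m_be:.2f}  M_TT={pooled.m_tt:.2f}  M_PE={pooled.m_pe:.2f} spikes/s")

res = build_peth(trains, bin_width=1.0, span=spec.windows)
mid = np.searchsorted(res.bin_edges, 0.0)
for k in range(mid - 2, mid + 3):
    print(
        f"bin [{res.bin_edges[k]:+5.1f},{res.bin_edges[k+1]:+5.1f}) s: "
        f"summed={res.summed_counts[k]:5d}  avg={res.averaged_rate[k]:6.2f} Hz  "
        f"diff={res.difference_curve[k]:+6.2f} Hz"
    )
# The tetanization bin [0, 1) jumps by roughly the configured 3.21-fold;
# baseline bins hover near zero difference from the pooled BE rate.
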