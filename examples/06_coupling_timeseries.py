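"""Temporal structure of a coupling: windowed nMI, CCF and dwell times.

Follows one planted fragment pair along a long synthetic trajectory: the
sliding-window nMI series shows the coupling is stationary, the
cross-correlation of the two letter series (as 0/1 signals) peaks at lag 0,
and the dwell-time statistics recover the geometric dwell lengths implied by
the switch rate.
"""

import numpy as np

from fragnet import cross_correlation, dwell_times, markov_letters, windowed_nmi

m = markov_letters(n_fragments=4, n_frames=4000, planted_pairs=((0, 1),),
                   coupling_strength=0.9, switch_rate=0.1, seed=12,
                   frame_interval=0.1)  # 0.1 ns per frame

series = windowed_nmi(m, (0, 1), window=100, stride=50)
print(f"windowed nMI of the coupled pair: mean {series.values.mean():.2f} "
      f"over {series.values.size} windows "
      f"({series.window_length} frames each)")

null = windowed_nmi(m, (2, 3), window=100, stride=50)
print(f"windowed nMI of an independent pair: mean {null.values.mean():.3f} "
      "(bias correction keeps the null near zero)")

x = (m.codes[:, 0] == m.codes[0, 0]).astype(float)
y = (m.codes[:, 1] == m.codes[0, 0]).astype(float)
ccf = cross_correlation(x, y, max_lag=50, dt=0.1)
print(f"CCF of the two state signals: amplitude {ccf.peak_amplitude:.2f} "
      f"at lag {ccf.peak_lag:.1f} ns, correlation time tau = "
      f"{ccf.correlation_time:.1f} ns")

rep = dwell_times(m, 0)
print(f"dwell times of fragment 0: mean {rep.mean_dwell:.1f} frames "
      f"(expected 1/switch_rate = 10), median {rep.quantiles['50']:.0f}")
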