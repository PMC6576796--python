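"""Temporal structure of fragment couplings.

Windowed nMI series resolve when a coupling is active along a trajectory;
cross-correlation functions between two such series (or between any two
numeric observables, e.g. end-to-end distances of two segments) report the
coupling amplitude and lag; dwell-time statistics of the letter series
characterise how long local states persist between transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import FragmentStateMatrix
from .info import normalized_mi

__all__ = [
    "CCFResult",
    "CouplingSeries",
    "DwellReport",
    "cross_correlation",
    "dwell_times",
    "windowed_nmi",
]


@dataclass
class CouplingSeries:
    times: np.ndarray      # window centres, ns (frame units if no interval)
    values: np.ndarray     # nMI per window, in [0, 1]
    window_length: int     # frames
    stride: int            # frames
    pair: tuple[int, int]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "nmi": self.values})


def windowed_nmi(m: FragmentStateMatrix, pair: tuple[int, int],
                 window: int = 50, stride: int = 10) -> CouplingSeries:
    """nMI of a fragment pair in sliding windows along the trajectory."""
    i, j = pair
    F = m.n_frames
    if window > F:
        raise ValueError(f"window {window} exceeds {F} frames")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    dt = m.frame_interval if m.frame_interval else 1.0
    starts = range(0, F - window + 1, stride)
    times, values = [], []
    for s in starts:
        x = m.codes[s:s + window, i]
        y = m.codes[s:s + window, j]
        values.append(normalized_mi(x, y))
        times.append((s + (window - 1) / 2.0) * dt)
    return CouplingSeries(times=np.asarray(times), values=np.asarray(values),
                          window_length=window, stride=stride, pair=(i, j))


@dataclass
class CCFResult:
    lags: np.ndarray            # ns (or frames), negative to positive
    correlation: np.ndarray     # Pearson r per lag, in [-1, 1]
    peak_amplitude: float
    peak_lag: float
    correlation_time: float     # lag where |CCF| decays to peak/e


def cross_correlation(x: np.ndarray, y: np.ndarray, max_lag: int,
                      dt: float = 1.0) -> CCFResult:
    """Cross-correlation function of two series.

    At each integer lag L the Pearson correlation of the overlapping
    mean-centred segments x[t], y[t+L] is computed (no FFT wrap-around, so
    shrinking overlap at large lags introduces no bias).  Positive peak lag
    means y trails x.  The correlation time tau is the smallest |lag| >=
    |peak lag| where |CCF| falls to peak/e, linearly interpolated.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be equal-length 1-D")
    n = x.size
    if n < 2 * max_lag + 2:
        raise ValueError(f"need >= {2 * max_lag + 2} samples for max_lag={max_lag}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant series: correlation undefined")
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.empty(lags.size)
    for k, L in enumerate(lags):
        if L >= 0:
            xs, ys = x[: n - L], y[L:]
        else:
            xs, ys = x[-L:], y[: n + L]
        xs = xs - xs.mean()
        ys = ys - ys.mean()
        denom = np.sqrt((xs ** 2).sum() * (ys ** 2).sum())
        r[k] = (xs * ys).sum() / denom if denom > 0 else 0.0
    peak_idx = int(np.argmax(np.abs(r)))
    peak = float(r[peak_idx])
    peak_lag = float(lags[peak_idx]) * dt
    target = abs(peak) / np.e
    tau = float(max_lag) * dt  # fallback: no decay within range
    absr = np.abs(r)
    for k in range(peak_idx, lags.size - 1):
        if absr[k + 1] <= target:
            frac = (absr[k] - target) / max(absr[k] - absr[k + 1], 1e-30)
            tau = abs((lags[k] + frac) * dt - peak_lag)
            break
    return CCFResult(lags=lags * dt, correlation=r, peak_amplitude=peak,
                     peak_lag=peak_lag, correlation_time=tau)


@dataclass
class DwellReport:
    dwells: list[tuple[str, int]]   # (letter, length in frames), in order
    dwell_ns: np.ndarray | None     # lengths in ns when frame_interval known
    quantiles: dict[str, float]     # 25/50/75% of dwell length (frames)

    @property
    def mean_dwell(self) -> float:
        return float(np.mean([d for _, d in self.dwells]))


def dwell_times(m: FragmentStateMatrix, fragment: int) -> DwellReport:
    """Run-length encoding of one fragment's letter series."""
    col = m.codes[:, fragment]
    letters = m.alphabet.letters
    dwells: list[tuple[str, int]] = []
    start = 0
    for t in range(1, col.size + 1):
        if t == col.size or col[t] != col[start]:
            dwells.append((letters[col[start]], t - start))
            start = t
    lengths = np.array([d for _, d in dwells], float)
    q = {p: float(np.percentile(lengths, int(p))) for p in ("25", "50", "75")}
    dwell_ns = lengths * m.frame_interval if m.frame_interval else None
    return DwellReport(dwells=dwells, dwell_ns=dwell_ns, quantiles=q)
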