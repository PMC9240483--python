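"""Sliding-window fitting of per-site statistics and significance thresholds.

Per-site statistics are noisy (a handful of reads per site); the genome scan
therefore averages them in overlapping windows (default 1 Mb, advanced in
10 kb steps) before thresholding.

Three threshold constructions are provided:

* ``null_envelope_delta`` — Monte-Carlo quantiles of |dSNPindex| under the
  no-QTL null: each bulk's allele frequency is the mean of 2*bulk_size fair
  Bernoulli draws (F2 segregation among the bulked individuals), and reads
  are binomial at the sequencing depth. This is the standard QTL-seq-style
  simulated confidence envelope.
* ``ed_threshold_median_sd`` — median of the fitted values plus n standard
  deviations (default 3), the genome-wide ED threshold construction.
* ``ed_threshold_quantile`` — empirical quantile (default 0.99, linear
  interpolation) of the fitted values, used to refine broad ED regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ScanTrack", "ThresholdSet", "make_windows", "fit_track",
    "null_envelope_delta", "ed_threshold_median_sd", "ed_threshold_quantile",
]

FitMethod = Literal["mean", "distance_weighted"]


@dataclass(frozen=True)
class ThresholdSet:
    """Thresholds from one construction method.

    ``values`` maps level -> threshold for envelope methods; scalar methods
    use the single key ``None``.
    """

    method: Literal["null_envelope", "median_plus_3sd", "quantile_99"]
    values: dict

    @property
    def scalar(self) -> float:
        if len(self.values) == 1:
            return next(iter(self.values.values()))
        raise ValueError(f"{self.method} has multiple levels: {sorted(self.values)}")

    def at(self, level: float) -> float:
        return self.values[level]


@dataclass
class ScanTrack:
    """Fitted window values for one statistic along one chromosome.

    ``fitted`` is NaN for windows containing no sites; such windows are
    excluded from thresholding and can never seed a region.
    """

    chrom: str
    window_size_bp: int
    step_bp: int
    window_starts: np.ndarray  # 1-based
    window_ends: np.ndarray    # 1-based inclusive, truncated at chrom end
    fitted: np.ndarray
    n_sites: np.ndarray
    statistic: Literal["delta_snp_index", "ed_powered"]

    def __post_init__(self) -> None:
        if not (len(self.window_starts) == len(self.window_ends)
                == len(self.fitted) == len(self.n_sites)):
            raise ValueError("track arrays must have equal length")
        steps = np.diff(self.window_starts)
        if steps.size and not np.all(steps == self.step_bp):
            raise ValueError("windows must be equally stepped")
        if np.any(np.isnan(self.fitted) != (self.n_sites == 0)):
            raise ValueError("fitted must be NaN exactly on empty windows")


def make_windows(chrom_length: int, window_size: int, step: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """1-based sliding windows: starts 1, 1+step, ... while start <= length.

    Trailing windows are truncated at the chromosome end.
    """
    if window_size <= 0 or step <= 0:
        raise ValueError("window_size and step must be positive")
    if window_size < step:
        raise ValueError("window_size must be >= step")
    if chrom_length < 1:
        raise ValueError("chrom_length must be >= 1")
    starts = np.arange(1, chrom_length + 1, step, dtype=np.int64)
    ends = np.minimum(starts + window_size - 1, chrom_length)
    return starts, ends


def fit_track(positions: Sequence[int], values: Sequence[float], chrom: str,
              windows: tuple[np.ndarray, np.ndarray],
              statistic: Literal["delta_snp_index", "ed_powered"],
              fit_method: FitMethod = "mean",
              window_size: int | None = None, step: int | None = None,
              ) -> ScanTrack:
    """Fit one statistic in sliding windows.

    ``mean`` averages the statistic over sites in the window. The
    ``distance_weighted`` fit uses tricube kernel weights
    ``(1 - (d/h)^3)^3`` with ``d`` the site's distance from the window
    centre and ``h`` half the nominal window size, so sites near the centre
    dominate; if every in-window site sits exactly on the window edge
    (all weights zero) the fit falls back to the unweighted mean.
    """
    pos = np.asarray(positions, dtype=np.int64)
    val = np.asarray(values, dtype=float)
    if pos.size != val.size:
        raise ValueError("positions and values must align")
    if np.any(np.diff(pos) < 0):
        raise ValueError("sites must be sorted by position")
    starts, ends = windows
    if window_size is None:
        window_size = int(ends[0] - starts[0] + 1)
    if step is None:
        step = int(starts[1] - starts[0]) if starts.size > 1 else window_size

    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="right")
    fitted = np.full(starts.size, np.nan)
    n_sites = (hi - lo).astype(np.int64)
    h = window_size / 2.0
    for w in range(starts.size):
        if n_sites[w] == 0:
            continue
        v = val[lo[w]:hi[w]]
        if fit_method == "mean":
            fitted[w] = v.mean()
        elif fit_method == "distance_weighted":
            centre = (starts[w] + ends[w]) / 2.0
            d = np.abs(pos[lo[w]:hi[w]] - centre)
            wt = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
            tot = wt.sum()
            fitted[w] = (v * wt).sum() / tot if tot > 0 else v.mean()
        else:
            raise ValueError(f"unknown fit_method {fit_method!r}")
    return ScanTrack(chrom=chrom, window_size_bp=int(window_size),
                     step_bp=int(step), window_starts=starts, window_ends=ends,
                     fitted=fitted, n_sites=n_sites, statistic=statistic)


def null_envelope_delta(depth_aa: int, depth_ab: int, bulk_size: int,
                        levels: Sequence[float] = (0.90, 0.95, 0.99),
                        reps: int = 100_000,
                        rng: np.random.Generator | None = None) -> ThresholdSet:
    """Monte-Carlo |dSNPindex| envelope under the no-QTL null.

    Per replicate: each bulk's pooled L-allele frequency is
    Binomial(2*bulk_size, 1/2) / (2*bulk_size) — free F2 segregation among
    the bulked individuals — and its observed SNP-index comes from binomial
    read sampling at the given depth. Thresholds are the |delta| quantiles
    at each requested level.
    """
    if depth_aa < 1 or depth_ab < 1 or bulk_size < 1:
        raise ValueError("depths and bulk_size must be >= 1")
    if reps < 1_000:
        raise ValueError(f"reps must be >= 1000 for stable quantiles, got {reps}")
    levels = tuple(levels)
    if any(not 0 < q < 1 for q in levels):
        raise ValueError("levels must lie in (0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    two_n = 2 * bulk_size
    freq_aa = rng.binomial(two_n, 0.5, size=reps) / two_n
    freq_ab = rng.binomial(two_n, 0.5, size=reps) / two_n
    idx_aa = rng.binomial(depth_aa, freq_aa) / depth_aa
    idx_ab = rng.binomial(depth_ab, freq_ab) / depth_ab
    abs_delta = np.abs(idx_aa - idx_ab)
    qs = np.quantile(abs_delta, levels)
    return ThresholdSet(method="null_envelope",
                        values={lvl: float(q) for lvl, q in zip(levels, qs)})


def _finite(fitted: Sequence[float]) -> np.ndarray:
    x = np.asarray(fitted, dtype=float)
    return x[np.isfinite(x)]


def ed_threshold_median_sd(fitted_values: Sequence[float], n_sd: float = 3.0
                           ) -> ThresholdSet:
    """Genome-wide threshold: median + n_sd * sample SD of fitted values."""
    x = _finite(fitted_values)
    if x.size < 2:
        raise ValueError("need >= 2 non-missing fitted values")
    value = float(np.median(x) + n_sd * np.std(x, ddof=1))
    return ThresholdSet(method="median_plus_3sd", values={None: value})


def ed_threshold_quantile(fitted_values: Sequence[float], q: float = 0.99
                          ) -> ThresholdSet:
    """Empirical q-quantile of fitted values (linear interpolation)."""
    if not 0 < q < 1:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    x = _finite(fitted_values)
    if x.size == 0:
        raise ValueError("no non-missing fitted values")
    return ThresholdSet(method="quantile_99",
                        values={None: float(np.quantile(x, q))})
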