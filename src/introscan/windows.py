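"""Windowed population-genetic statistics: pi, d_XY, F_ST, Tajima's D.

All statistics consume :class:`~introscan.haplotypes.SiteAlleleCounts`
(per-site, per-population counts of called A/C/G/T alleles), so simulated
haploid data and VCF-derived diploid data share one code path.  Windows are
0-based half-open internally and reported 1-based inclusive.

Missing-data policy: a window's value is NA unless more than
``min_callable_fraction`` (default 20%) of its base pairs have callable
data for the statistic, mirroring the genotyped-site rule used for the
tree windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .haplotypes import SiteAlleleCounts

__all__ = [
    "GenomicWindow",
    "WindowStatRecord",
    "make_windows",
    "pi_window",
    "dxy_window",
    "fst_wc_window",
    "tajimas_d_window",
    "pi_windows",
    "dxy_windows",
    "fst_wc_windows",
    "tajimas_d_windows",
    "sliding_dxy",
    "rescale_density",
    "records_to_frame",
]

DEFAULT_WINDOW_SIZE = 50_000
DEFAULT_MIN_CALLABLE_FRACTION = 0.2


@dataclass(frozen=True)
class GenomicWindow:
    """Half-open window [start, end) on a scaffold (0-based internally)."""

    scaffold: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty window {self.start}..{self.end}")

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end

    def label(self) -> str:
        return f"{self.scaffold}:{self.start_1based}..{self.end_1based}"


@dataclass(frozen=True)
class WindowStatRecord:
    window: GenomicWindow
    statistic: str
    value: float  # NaN when below the callable-sites minimum
    n_sites_used: int
    n_sites_possible: int

    @property
    def is_na(self) -> bool:
        return not np.isfinite(self.value)


def make_windows(
    scaffold_lengths: Mapping[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> list[GenomicWindow]:
    """Non-overlapping tiling windows; terminal partial windows retained."""
    out: list[GenomicWindow] = []
    for scaffold, length in scaffold_lengths.items():
        if length < 1:
            raise ValueError(f"scaffold {scaffold} has length {length}")
        for start in range(0, length, window_size):
            out.append(GenomicWindow(scaffold, start, min(start + window_size, length)))
    return out


# ---------------------------------------------------------------------------
# per-site building blocks
# ---------------------------------------------------------------------------


def _pi_sites(counts: SiteAlleleCounts, pop: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-site unbiased heterozygosity; NaN where < 2 called alleles."""
    c = counts.counts[pop].astype(np.float64)
    n = c.sum(axis=1)
    ok = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = (n**2 - (c**2).sum(axis=1)) / (n * (n - 1.0))
    pi[~ok] = np.nan
    return pi, ok


def _dxy_sites(counts: SiteAlleleCounts, pop_a: str, pop_b: str):
    ca = counts.counts[pop_a].astype(np.float64)
    cb = counts.counts[pop_b].astype(np.float64)
    na = ca.sum(axis=1)
    nb = cb.sum(axis=1)
    ok = (na >= 1) & (nb >= 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - (ca / na[:, None] * cb / nb[:, None]).sum(axis=1)
    d[~ok] = np.nan
    return d, ok


def _biallelic_freqs(counts: SiteAlleleCounts, pops: Sequence[str]):
    """Sites biallelic in the pooled populations; returns per-pop (n, p) for
    the first observed allele plus the site mask."""
    pooled = counts.pool(pops)
    n_alleles = (pooled > 0).sum(axis=1)
    biallelic = n_alleles == 2
    # index of the first (reference-like) allele at each site
    first = np.argmax(pooled > 0, axis=1)
    idx = np.arange(counts.n_sites)
    out = {}
    for p in pops:
        c = counts.counts[p].astype(np.float64)
        n = c.sum(axis=1)
        x = c[idx, first]
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = x / n
        out[p] = (n, x, freq)
    return biallelic, out


def _wc_components(n1, p1, n2, p2):
    """Weir & Cockerham (1984) variance components for one biallelic site,
    two populations, alleles treated as the sampling unit (no
    within-individual component)."""
    nbar = (n1 + n2) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 / 2.0)
    return a, b


_TAJIMA_CACHE: dict[int, tuple[float, ...]] = {}


def tajima_constants(n: int) -> tuple[float, ...]:
    """a1, a2, b1, b2, c1, c2, e1, e2 for sample size ``n`` (Tajima 1989)."""
    if n in _TAJIMA_CACHE:
        return _TAJIMA_CACHE[n]
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    _TAJIMA_CACHE[n] = (a1, a2, b1, b2, c1, c2, e1, e2)
    return _TAJIMA_CACHE[n]


# ---------------------------------------------------------------------------
# windowed statistics
# ---------------------------------------------------------------------------


def _window_cols(counts: SiteAlleleCounts, window: GenomicWindow) -> slice:
    lo = int(np.searchsorted(counts.positions, window.start + 1))
    hi = int(np.searchsorted(counts.positions, window.end, side="right"))
    return slice(lo, hi)


def _mean_record(
    window: GenomicWindow,
    statistic: str,
    values: np.ndarray,
    min_callable_fraction: float,
) -> WindowStatRecord:
    used = int(np.isfinite(values).sum())
    possible = window.span
    if used == 0 or used / possible <= min_callable_fraction:
        value = float("nan")
    else:
        value = float(np.nanmean(values))
    return WindowStatRecord(window, statistic, value, used, possible)


def pi_window(
    counts: SiteAlleleCounts,
    window: GenomicWindow,
    population: str,
    min_callable_fraction: float = DEFAULT_MIN_CALLABLE_FRACTION,
) -> WindowStatRecord:
    """Nei's intrapopulation nucleotide diversity, mean over callable sites."""
    cols = _window_cols(counts, window)
    pi, _ = _pi_sites(counts, population)
    return _mean_record(window, f"pi[{population}]", pi[cols], min_callable_fraction)


def dxy_window(
    counts: SiteAlleleCounts,
    window: GenomicWindow,
    pop_a: str,
    pop_b: str,
    min_callable_fraction: float = DEFAULT_MIN_CALLABLE_FRACTION,
    denominator: str = "callable",
) -> WindowStatRecord:
    """Nei's absolute divergence d_XY.

    ``denominator="callable"`` (default) averages over sites callable in
    both populations; ``"span"`` divides the summed per-site divergence by
    the window's full base-pair span instead, for comparison with tools
    that treat uncallable sites as invariant.
    """
    return dxy_windows(
        counts, [window], pop_a, pop_b, min_callable_fraction, denominator
    )[0]


def fst_wc_window(
    counts: SiteAlleleCounts,
    window: GenomicWindow,
    pop_a: str,
    pop_b: str,
    min_callable_fraction: float = DEFAULT_MIN_CALLABLE_FRACTION,
) -> WindowStatRecord:
    """Weir-Cockerham weighted F_ST over polymorphic biallelic sites."""
    recs = fst_wc_windows(counts, [window], pop_a, pop_b, min_callable_fraction)
    return recs[0]


def tajimas_d_window(
    counts: SiteAlleleCounts,
    window: GenomicWindow,
    population: str,
    min_callable_fraction: float = DEFAULT_MIN_CALLABLE_FRACTION,
) -> WindowStatRecord:
    recs = tajimas_d_windows(counts, [window], population, min_callable_fraction)
    return recs[0]


def pi_windows(
    counts: SiteAlleleCounts,
    windows: Sequence[GenomicWindow],
    population: str,
    min_callable_fraction: float = DEFAULT_MIN_CALLABLE_FRACTION,
) -> list[WindowStatRecord]:
    pi, _ = _pi_sites(counts, population)
    return [
        _mean_record(
            w, f"pi[{population}]", pi[_window_cols(counts, w)], min_callable_fraction
        )
        for w in windows
    ]


def dxy_windows(
    counts: SiteAlleleCounts,
    windows: Sequence[GenomicWindow],
    pop_a: str,
    pop_b: str,
    min_callable_fraction: float = DEFAULT_MIN_CALLABLE_FRACTION,
    denominator: str = "callable",
) -> list[WindowStatRecord]:
    if denominator not in ("callable", "span"):
        raise ValueError(f"unknown d_XY denominator mode {denominator!r}")
    d, _ = _dxy_sites(counts, pop_a, pop_b)
    name = f"dxy[{pop_a},{pop_b}]"
    out = []
    for w in windows:
        vals = d[_window_cols(counts, w)]
        if denominator == "callable":
            out.append(_mean_record(w, name, vals, min_callable_fraction))
            continue
        used = int(np.isfinite(vals).sum())
        if used == 0 or used / w.span <= min_callable_fraction:
            value = float("nan")
        else:
            value = float(np.nansum(vals)) / w.span
        out.append(WindowStatRecord(w, name, value, used, w.span))
    return out


def fst_wc_windows(
    counts: SiteAlleleCounts,
    windows: Sequence[GenomicWindow],
    pop_a: str,
    pop_b: str,
    min_callable_fraction: float = DEFAULT_MIN_CALLABLE_FRACTION,
) -> list[WindowStatRecord]:
    """Windowed W&C F_ST: sum(a) / sum(a + b) over usable polymorphic sites.

    The weighted ("ratio of sums") estimator matches the windowed output of
    standard VCF tooling.  Sites with more than two alleles are excluded.
    """
    biallelic, freqs = _biallelic_freqs(counts, [pop_a, pop_b])
    n1, _, p1 = freqs[pop_a]
    n2, _, p2 = freqs[pop_b]
    callable_ = (n1 >= 2) & (n2 >= 2)
    usable = biallelic & callable_
    poly = usable & np.isfinite(p1) & np.isfinite(p2)
    # polymorphic within the pooled pair: 0 < pooled frequency < 1
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_p = (n1 * p1 + n2 * p2) / (n1 + n2)
    poly &= (pooled_p > 0) & (pooled_p < 1)
    a, b = _wc_components(n1, p1, n2, p2)
    name = f"fst_wc[{pop_a},{pop_b}]"
    out = []
    for w in windows:
        cols = _window_cols(counts, w)
        m = poly[cols]
        used = int(m.sum())
        # callable accounting follows the d_XY convention: sites with data in
        # both populations, whether or not they are polymorphic
        callable_sites = int(callable_[cols].sum())
        if used == 0 or callable_sites / w.span <= min_callable_fraction:
            value = float("nan")
        else:
            asum = float(a[cols][m].sum())
            absum = float((a[cols][m] + b[cols][m]).sum())
            value = asum / absum if absum != 0 else float("nan")
        out.append(WindowStatRecord(w, name, value, used, w.span))
    return out


def tajimas_d_windows(
    counts: SiteAlleleCounts,
    windows: Sequence[GenomicWindow],
    population: str,
    min_callable_fraction: float = DEFAULT_MIN_CALLABLE_FRACTION,
) -> list[WindowStatRecord]:
    """Tajima's D per window.

    The normalising constants assume a constant number of sequences; with
    ragged missingness they are computed from the modal per-site called
    allele count within the window (an approximation, documented as such).
    Sites with more than two alleles are excluded.  Windows without
    segregating sites are NA.
    """
    c = counts.counts[population].astype(np.float64)
    n = c.sum(axis=1)
    n_alleles = (c > 0).sum(axis=1)
    pi, _ = _pi_sites(counts, population)
    seg = (n_alleles == 2) & (n >= 2)
    usable = (n >= 2) & (n_alleles <= 2)
    name = f"tajimas_d[{population}]"
    out = []
    for w in windows:
        cols = _window_cols(counts, w)
        nw = n[cols]
        use = usable[cols]
        callable_sites = int(use.sum())
        s = int(seg[cols].sum())
        if (
            callable_sites == 0
            or callable_sites / w.span <= min_callable_fraction
            or s == 0
        ):
            out.append(WindowStatRecord(w, name, float("nan"), s, w.span))
            continue
        counts_of_n = np.bincount(nw[use].astype(np.int64))
        modal_n = int(np.argmax(counts_of_n))
        if modal_n < 3:
            out.append(WindowStatRecord(w, name, float("nan"), s, w.span))
            continue
        a1, a2, b1, b2, c1, c2, e1, e2 = tajima_constants(modal_n)
        pi_sum = float(np.nansum(np.where(use, pi[cols], 0.0)))
        var = e1 * s + e2 * s * (s - 1.0)
        d = (pi_sum - s / a1) / np.sqrt(var)
        out.append(WindowStatRecord(w, name, float(d), s, w.span))
    return out


def sliding_dxy(
    counts: SiteAlleleCounts,
    scaffold_length: int,
    window_size: int,
    step: int,
    pop_a: str,
    pop_b: str,
    min_callable_fraction: float = DEFAULT_MIN_CALLABLE_FRACTION,
) -> list[WindowStatRecord]:
    """d_XY in overlapping windows of ``window_size`` sliding by ``step``."""
    if not window_size >= step >= 1:
        raise ValueError("need window_size >= step >= 1")
    scaffold = counts.scaffold
    if scaffold_length < window_size:
        windows = [GenomicWindow(scaffold, 0, scaffold_length)]
    else:
        n_win = (scaffold_length - window_size) // step + 1
        windows = [
            GenomicWindow(scaffold, k * step, k * step + window_size)
            for k in range(n_win)
        ]
    return dxy_windows(counts, windows, pop_a, pop_b, min_callable_fraction)


def rescale_density(
    values: Iterable[float],
    bins: int | np.ndarray = 50,
    range_: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram rescaled so the maximum bin height is exactly 1.

    Returns ``(bin_edges, heights)``.  This is the normalisation used for
    the d_XY and proportion distribution summaries.
    """
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        raise ValueError("rescale_density requires at least one finite value")
    hist, edges = np.histogram(vals, bins=bins, range=range_)
    return edges, hist / hist.max()


def records_to_frame(records: Sequence[WindowStatRecord]) -> pd.DataFrame:
    """Tab-separated-friendly table: scaffold, 1-based coords, value, sites."""
    return pd.DataFrame(
        {
            "scaffold": [r.window.scaffold for r in records],
            "start": [r.window.start_1based for r in records],
            "end": [r.window.end_1based for r in records],
            "statistic": [r.statistic for r in records],
            "value": [r.value for r in records],
            "n_sites_used": [r.n_sites_used for r in records],
            "n_sites_possible": [r.n_sites_possible for r in records],
        }
    )
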