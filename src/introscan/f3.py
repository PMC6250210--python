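"""Three-population f3 test with block-jackknife standard errors.

f3(C; A, B) = E[(c - a)(c - b)] over allele frequencies, with the unbiased
finite-sample correction h_C / n_C subtracted at every site, where
h_C = c(1-c) n_C / (n_C - 1) is the unbiased target heterozygosity.
Significantly negative values indicate that the target C is admixed between
populations related to the two sources.  The statistic is reported
unnormalised (no heterozygosity denominator); a normalised mode divides by
the mean h_C.

Standard errors come from a weighted delete-one block jackknife over
contiguous genomic blocks (Busing et al. 1999), robust to linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .haplotypes import SiteAlleleCounts

__all__ = ["F3Result", "f3_site", "f3_genome", "f3_all_orderings"]

DEFAULT_BLOCK_SIZE = 500_000


@dataclass(frozen=True)
class F3Result:
    """One tip ordering's f3 estimate: f3(target; source_a, source_b)."""

    target: str
    source_a: str
    source_b: str
    f3_estimate: float
    jackknife_se: float
    z_score: float
    n_blocks: int
    n_sites: int
    reliable: bool = True

    def label(self) -> str:
        return f"f3({self.source_a},{self.source_b};{self.target})"


def f3_site(
    x_a: float, n_a: float, x_b: float, n_b: float, x_c: float, n_c: float
) -> float:
    """Unbiased per-site f3 from allele counts (x of n) in A, B and target C.

    Returns NaN when the target has fewer than 2 called alleles (the
    heterozygosity correction is undefined there).
    """
    if n_c < 2 or n_a < 1 or n_b < 1:
        return float("nan")
    a = x_a / n_a
    b = x_b / n_b
    c = x_c / n_c
    h_c = c * (1.0 - c) * n_c / (n_c - 1.0)
    return (c - a) * (c - b) - h_c / n_c


def _site_values(
    counts: SiteAlleleCounts, target: str, source_a: str, source_b: str
):
    """Vectorised per-site f3 values and the used-site mask."""
    pops = [source_a, source_b, target]
    pooled = counts.pool(pops)
    n_alleles = (pooled > 0).sum(axis=1)
    first = np.argmax(pooled > 0, axis=1)
    idx = np.arange(counts.n_sites)
    freqs = {}
    totals = {}
    for p in pops:
        cnt = counts.counts[p].astype(np.float64)
        n = cnt.sum(axis=1)
        x = cnt[idx, first]
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[p] = x / n
        totals[p] = n
    n_c = totals[target]
    used = (
        (n_alleles == 2)
        & (n_c >= 2)
        & (totals[source_a] >= 1)
        & (totals[source_b] >= 1)
    )
    a = freqs[source_a]
    b = freqs[source_b]
    c = freqs[target]
    with np.errstate(invalid="ignore", divide="ignore"):
        h_c = c * (1.0 - c) * n_c / (n_c - 1.0)
        vals = (c - a) * (c - b) - h_c / n_c
        het = h_c
    return vals, het, used


def _busing_jackknife(theta_hat: float, theta_j: np.ndarray, m_j: np.ndarray):
    """Weighted delete-one jackknife variance for unequal block sizes."""
    n = m_j.sum()
    g = len(m_j)
    h = n / m_j
    theta_dot = g * theta_hat - float(((1.0 - m_j / n) * theta_j).sum())
    pseudo = h * theta_hat - (h - 1.0) * theta_j
    var = float((((pseudo - theta_dot) ** 2) / (h - 1.0)).sum() / g)
    return np.sqrt(var)


def f3_genome(
    counts: SiteAlleleCounts,
    target: str,
    source_a: str,
    source_b: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
    normalized: bool = False,
) -> F3Result:
    """Genome-wide f3 with block-jackknife SE and Z-score.

    Sites used: biallelic in the union of the three populations,
    polymorphic in that union, with >= 2 target alleles and >= 1 allele in
    each source.  Blocks are contiguous ``block_size``-bp spans, weighted
    by their site counts in the jackknife.
    """
    vals, het, used = _site_values(counts, target, source_a, source_b)
    n_sites = int(used.sum())
    if n_sites == 0:
        raise ValueError("no usable biallelic polymorphic sites for f3")
    v = vals[used]
    h = het[used]
    block_ids = counts.positions[used] // block_size
    uniq, inv = np.unique(block_ids, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise ValueError(f"need >= 2 jackknife blocks with data, got {g}")
    m_j = np.bincount(inv).astype(np.float64)
    sums = np.bincount(inv, weights=v)
    hsums = np.bincount(inv, weights=h)
    tot = float(v.sum())
    htot = float(h.sum())
    n = float(n_sites)
    if normalized:
        theta_hat = tot / htot
        theta_j = (tot - sums) / (htot - hsums)
    else:
        theta_hat = tot / n
        theta_j = (tot - sums) / (n - m_j)
    se = _busing_jackknife(theta_hat, theta_j, m_j)
    reliable = se > 0
    z = theta_hat / se if se > 0 else float("inf") * np.sign(theta_hat)
    return F3Result(
        target=target,
        source_a=source_a,
        source_b=source_b,
        f3_estimate=float(theta_hat),
        jackknife_se=float(se),
        z_score=float(z),
        n_blocks=g,
        n_sites=n_sites,
        reliable=bool(reliable),
    )


def f3_all_orderings(
    counts: SiteAlleleCounts,
    pop_i1: str,
    pop_i2: str,
    pop_o: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> dict[str, F3Result]:
    """f3 with each population as target, keyed by target label.

    The three orderings are f3(I1, I2; O), f3(I1, O; I2) and f3(I2, O; I1).
    """
    return {
        pop_o: f3_genome(counts, pop_o, pop_i1, pop_i2, block_size),
        pop_i2: f3_genome(counts, pop_i2, pop_i1, pop_o, block_size),
        pop_i1: f3_genome(counts, pop_i1, pop_i2, pop_o, block_size),
    }
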