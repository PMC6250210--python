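"""Quartet trees and tree-tip distance proportions.

For every 50-kb window and every (I2, O) sample pair — together with two
fixed I1 anchor samples — a four-tip tree is built from Jukes-Cantor
distances by least-squares fitting on the four-point-condition topology.
The statistic is

    Proportion_ab = d_a / (d_a + d_b)

with d_a the patristic distance between the I2 and O tips and d_b the mean
patristic distance of the two I1 tips to O.  Under the species tree
((I1, I2), O) the proportion is ~0.5; values well below 0.5 mark candidate
introgressed windows where the outgroup is closer to the sympatric ingroup.

The distance/least-squares tree replaces per-window maximum-likelihood
trees: for four taxa the proportion depends only on patristic distances,
and the distance tree is deterministic and fast.  Externally computed
Newick trees can be supplied per window instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeMatrix, PopulationMap, expected_mismatch_table
from .windows import GenomicWindow

__all__ = [
    "QuartetResult",
    "QuartetTree",
    "TailReport",
    "pairwise_distance",
    "quartet_tree",
    "quartet_tree_from_newick",
    "proportion_ab",
    "enumerate_quartets",
    "window_proportion_scan",
    "tail_analysis",
]

DEFAULT_MAX_DISTANCE = 5.0
DEFAULT_MIN_CALLABLE = 0.2
TAIL_OFFSETS = (0.05, 0.10, 0.15)

_MISMATCH = expected_mismatch_table()


def pairwise_distance(
    seq1: np.ndarray,
    seq2: np.ndarray,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> tuple[float, int]:
    """Jukes-Cantor corrected distance between two masked call vectors.

    Ambiguity codes contribute their mean mismatch over compatible base
    resolutions (a heterozygote against a matching homozygote counts 0.5).
    Saturated comparisons (mismatch fraction >= 0.75) are capped at
    ``max_distance``.  Returns ``(distance, n_jointly_callable_sites)``;
    the distance is NaN when no site is callable in both.
    """
    mis = _MISMATCH[seq1, seq2]
    ok = np.isfinite(mis)
    n = int(ok.sum())
    if n == 0:
        return float("nan"), 0
    p = float(mis[ok].mean())
    if p >= 0.75:
        return max_distance, n
    d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    return min(d, max_distance), n


@dataclass(frozen=True)
class QuartetTree:
    """Unrooted 4-tip tree as tip labels plus a patristic distance matrix."""

    tips: tuple[str, str, str, str]
    patristic_matrix: np.ndarray

    def patristic(self, a: str, b: str) -> float:
        i, j = self.tips.index(a), self.tips.index(b)
        return float(self.patristic_matrix[i, j])


_PAIRINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


def quartet_tree(dist: np.ndarray, tips: Sequence[str]) -> QuartetTree:
    """Least-squares unrooted tree for four taxa.

    The topology is the split minimising the four-point-condition residual
    (equivalently, the pairing with the smallest sum of within-cherry
    distances); the five branch lengths are the least-squares fit to the
    six pairwise distances, clamped at zero.  On an additive (tree-metric)
    matrix the patristic distances reproduce the input exactly.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (4, 4) or not np.isfinite(dist).all():
        raise ValueError("quartet_tree needs a complete finite 4x4 matrix")
    sums = [dist[a, b] + dist[c, d] for (a, b), (c, d) in _PAIRINGS]
    (a, b), (c, d) = _PAIRINGS[int(np.argmin(sums))]
    # order: e_a, e_b, e_c, e_d (tip branches), m (internal)
    pairs = list(combinations(range(4), 2))
    design = np.zeros((6, 5))
    y = np.zeros(6)
    cherry = {a: 0, b: 0, c: 1, d: 1}
    col = {a: 0, b: 1, c: 2, d: 3}
    for r, (i, j) in enumerate(pairs):
        design[r, col[i]] = 1.0
        design[r, col[j]] = 1.0
        if cherry[i] != cherry[j]:
            design[r, 4] = 1.0
        y[r] = dist[i, j]
    lengths, *_ = np.linalg.lstsq(design, y, rcond=None)
    lengths = np.maximum(lengths, 0.0)
    pat = np.zeros((4, 4))
    for i, j in pairs:
        p = lengths[col[i]] + lengths[col[j]]
        if cherry[i] != cherry[j]:
            p += lengths[4]
        pat[i, j] = pat[j, i] = p
    return QuartetTree(tuple(tips), pat)


def quartet_tree_from_newick(newick: str, tips: Sequence[str]) -> QuartetTree:
    """Adopt an externally computed tree (e.g. per-window ML) via its
    patristic distances."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [t for t in tips if t not in taxa]
    if missing:
        raise ValueError(f"tips absent from newick tree: {missing}")
    pat = np.zeros((4, 4))
    for i, j in combinations(range(4), 2):
        d = pdm.patristic_distance(taxa[tips[i]], taxa[tips[j]])
        pat[i, j] = pat[j, i] = d
    return QuartetTree(tuple(tips), pat)


@dataclass(frozen=True)
class QuartetResult:
    """Proportion_ab for one window and one (I2, O) sample combination."""

    window: GenomicWindow
    i2_sample: str
    o_sample: str
    d_a: float
    d_b: float
    proportion: float  # NaN when d_a + d_b == 0
    n_sites_used: int

    @property
    def combination(self) -> str:
        return f"{self.i2_sample}|{self.o_sample}"


def proportion_ab(
    tree: QuartetTree, roles: Mapping[str, str]
) -> tuple[float, float, float]:
    """d_a, d_b and Proportion_ab from a role-labelled quartet tree.

    ``roles`` maps tip name -> role; exactly one I2 tip, one O tip and two
    I1 tips are required.  d_b is the mean of the two I1-to-O patristic
    distances, so swapping the I1 tips leaves the proportion unchanged.
    """
    by_role: dict[str, list[str]] = {}
    for tip, role in roles.items():
        by_role.setdefault(role, []).append(tip)
    if sorted(by_role) != ["I1", "I2", "O"] or (
        len(by_role["I1"]) != 2 or len(by_role["I2"]) != 1 or len(by_role["O"]) != 1
    ):
        raise ValueError(f"roles must be exactly {{I2, O, I1, I1}}, got {roles}")
    o = by_role["O"][0]
    d_a = tree.patristic(by_role["I2"][0], o)
    d_b = 0.5 * (
        tree.patristic(by_role["I1"][0], o) + tree.patristic(by_role["I1"][1], o)
    )
    total = d_a + d_b
    prop = d_a / total if total > 0 else float("nan")
    return d_a, d_b, prop


def enumerate_quartets(
    popmap: PopulationMap, mode: str = "simulated"
) -> list[tuple[str, str]]:
    """All (I2, O) sample combinations to cross with the fixed I1 pair.

    ``simulated``: every I2 sample against every O sample (8 x 8 = 64 with
    the default model).  ``empirical``: within each sympatric population,
    every I2-role sample against every O-role sample from the same
    population (the three-population field design gives 8 + 8 + 16 = 32).
    """
    fixed = popmap.fixed_i1_samples()
    if len(fixed) != 2:
        raise ValueError(f"exactly 2 fixed I1 samples required, got {len(fixed)}")
    if mode == "simulated":
        i2 = popmap.role_samples("I2")
        o = popmap.role_samples("O")
        if not i2 or not o:
            raise ValueError("missing I2 or O role samples")
        return [(s2, so) for s2 in i2 for so in o]
    if mode == "empirical":
        out = []
        for pop in popmap.populations():
            members = popmap.population_samples(pop)
            i2 = [s for s in members if popmap.info[s].role == "I2"]
            o = [s for s in members if popmap.info[s].role == "O"]
            out.extend((s2, so) for s2 in i2 for so in o)
        if not out:
            raise ValueError("no sympatric I2/O pairs found")
        return out
    raise ValueError(f"unknown mode {mode!r}")


def window_proportion_scan(
    matrix: HaplotypeMatrix,
    windows: Sequence[GenomicWindow],
    combinations_: Sequence[tuple[str, str]],
    popmap: PopulationMap,
    min_callable: float = DEFAULT_MIN_CALLABLE,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> list[QuartetResult]:
    """Proportion_ab for every window x combination passing the callable rule.

    A window/combination is analysed only when all four sequences have more
    than ``min_callable`` of the window's sites genotyped; pairwise
    distances are cached per window across combinations.
    """
    fixed = popmap.fixed_i1_samples()
    if len(fixed) != 2:
        raise ValueError("exactly 2 fixed I1 samples required")
    i1a, i1b = fixed
    idx = {s: matrix.sample_index(s) for s in matrix.samples}
    results: list[QuartetResult] = []
    for w in windows:
        cols = matrix.site_slice(w.start, w.end)
        frac = matrix.callable_fraction(w.start, w.end)
        cache: dict[tuple[str, str], tuple[float, int]] = {}

        def dist(s1: str, s2: str) -> tuple[float, int]:
            key = (s1, s2) if s1 <= s2 else (s2, s1)
            if key not in cache:
                cache[key] = pairwise_distance(
                    matrix.calls[idx[key[0]], cols],
                    matrix.calls[idx[key[1]], cols],
                    max_distance,
                )
            return cache[key]

        for s_i2, s_o in combinations_:
            tips = (s_i2, s_o, i1a, i1b)
            if any(frac[idx[t]] <= min_callable for t in tips):
                continue
            dmat = np.zeros((4, 4))
            n_min = w.span
            bad = False
            for i, j in combinations(range(4), 2):
                d, nij = dist(tips[i], tips[j])
                if not np.isfinite(d):
                    bad = True
                    break
                dmat[i, j] = dmat[j, i] = d
                n_min = min(n_min, nij)
            if bad:
                continue
            tree = quartet_tree(dmat, tips)
            roles = {s_i2: "I2", s_o: "O", i1a: "I1", i1b: "I1"}
            d_a, d_b, prop = proportion_ab(tree, roles)
            results.append(
                QuartetResult(w, s_i2, s_o, d_a, d_b, prop, n_min)
            )
    return results


@dataclass(frozen=True)
class TailReport:
    """Symmetry of the proportion distribution tails, per combination."""

    means: dict[str, float]
    counts: pd.DataFrame  # combination, offset, n_above, n_below
    flagged: pd.DataFrame  # combination, scaffold, start, end, proportion
    scaffold_hits: pd.DataFrame  # scaffold, n_combinations_flagging


def tail_analysis(
    results: Sequence[QuartetResult],
    offsets: Sequence[float] = TAIL_OFFSETS,
    min_results: int = 30,
) -> TailReport:
    """Count windows above/below each combination's mean at fixed offsets.

    Windows below mean - max(offset) are flagged as candidate introgressed
    regions; scaffolds are aggregated across combinations with the number
    of combinations flagging each.
    """
    by_combo: dict[str, list[QuartetResult]] = {}
    for r in results:
        if np.isfinite(r.proportion):
            by_combo.setdefault(r.combination, []).append(r)
    if not by_combo:
        raise ValueError("no finite proportion results")
    means: dict[str, float] = {}
    count_rows = []
    flag_rows = []
    flag_offset = max(offsets)
    for combo, rs in by_combo.items():
        if len(rs) < min_results:
            raise ValueError(
                f"combination {combo} has {len(rs)} results; >= {min_results} required"
            )
        props = np.array([r.proportion for r in rs])
        mu = float(props.mean())
        means[combo] = mu
        for off in offsets:
            count_rows.append(
                {
                    "combination": combo,
                    "offset": off,
                    "n_above": int((props > mu + off).sum()),
                    "n_below": int((props < mu - off).sum()),
                }
            )
        for r in rs:
            if r.proportion < mu - flag_offset:
                flag_rows.append(
                    {
                        "combination": combo,
                        "scaffold": r.window.scaffold,
                        "start": r.window.start_1based,
                        "end": r.window.end_1based,
                        "proportion": r.proportion,
                    }
                )
    counts = pd.DataFrame(count_rows)
    flagged = pd.DataFrame(
        flag_rows, columns=["combination", "scaffold", "start", "end", "proportion"]
    )
    if len(flagged):
        hits = (
            flagged.groupby("scaffold")["combination"]
            .nunique()
            .rename("n_combinations_flagging")
            .reset_index()
        )
    else:
        hits = pd.DataFrame(columns=["scaffold", "n_combinations_flagging"])
    return TailReport(means, counts, flagged, hits)
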