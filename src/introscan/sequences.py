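"""Sequence evolution along local genealogies under HKY85.

Each genealogy interval is evolved site-by-site: the root state is drawn
from the stationary base frequencies and every branch applies the HKY
transition matrix for ``branch_length * branch_scale`` expected
substitutions per site.  For uniform base frequencies the per-branch
sampling uses an exact shortcut: the number of sites whose state differs
across the branch is Binomial(sites, 1 - P_ii(d)), and each changed site
picks a transition or transversion target with the matching conditional
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coalescent import LocalGenealogy, sample_genealogies
from .haplotypes import HaplotypeMatrix
from .hky import hky_transition_matrix
from .model import DemographicModel

__all__ = ["SimulatedHaplotypes", "evolve_sequences", "simulate"]

# internal state coding 0=A,1=C,2=G,3=T; transition partner is state ^ 2
_CODE_TO_MASK = np.array([1, 2, 4, 8], dtype=np.uint8)


@dataclass
class SimulatedHaplotypes:
    """Simulated calls plus the generating model and true genealogies."""

    haplotypes: HaplotypeMatrix
    model: DemographicModel
    genealogies: list[LocalGenealogy]


def _distinct_sites(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k distinct site indices in [0, n); rejection sampling when k << n."""
    if k >= n:
        return np.arange(n)
    if k > n // 16:
        return rng.choice(n, size=k, replace=False)
    pos = np.unique(rng.integers(0, n, size=k))
    while len(pos) < k:
        extra = rng.integers(0, n, size=k - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return pos


def _evolve_tree_uniform(
    tree,
    length: int,
    rng: np.random.Generator,
    e2: np.ndarray,
    e3: np.ndarray,
    p_diff: np.ndarray,
    n_changed: np.ndarray,
) -> list[np.ndarray]:
    """Per-node site states for one interval, uniform base frequencies.

    ``e2``/``e3``/``p_diff``/``n_changed`` are per-branch arrays computed by
    the caller (batched across intervals for speed).
    """
    n_nodes = tree.n_nodes
    states: list[np.ndarray | None] = [None] * n_nodes
    states[tree.root] = rng.integers(0, 4, size=length, dtype=np.uint8)
    parent = tree.parent
    for node in range(n_nodes - 2, -1, -1):
        k = int(n_changed[node])
        if k == 0:
            states[node] = states[parent[node]]
            continue
        st = states[parent[node]].copy()
        # conditional on a change: transition vs either transversion
        pr_ts = (0.25 + 0.25 * e2[node] - 0.5 * e3[node]) / p_diff[node]
        if k == 1:
            pos = int(rng.integers(0, length))
            if rng.random() < pr_ts:
                st[pos] ^= 2
            else:
                st[pos] ^= 1 + 2 * int(rng.integers(0, 2))
        else:
            pos = _distinct_sites(rng, length, k)
            ts = rng.random(k) < pr_ts
            xor = np.where(ts, 2, 1 + 2 * rng.integers(0, 2, size=k)).astype(np.uint8)
            st[pos] = st[pos] ^ xor
        states[node] = st
    return states  # type: ignore[return-value]


def _evolve_tree_general(
    tree, length: int, scale: float, kappa: float, freqs, rng: np.random.Generator
) -> list[np.ndarray]:
    """General-frequency path: per-branch categorical sampling."""
    n_nodes = tree.n_nodes
    states: list[np.ndarray | None] = [None] * n_nodes
    states[tree.root] = rng.choice(4, size=length, p=freqs).astype(np.uint8)
    parent = tree.parent
    time = tree.time
    for node in range(n_nodes - 2, -1, -1):
        d = (time[parent[node]] - time[node]) * scale
        p = hky_transition_matrix(d, kappa, freqs)
        cum = np.cumsum(p, axis=1)
        par_states = states[parent[node]]
        st = np.empty(length, dtype=np.uint8)
        u = rng.random(length)
        for s in range(4):
            mask = par_states == s
            if mask.any():
                st[mask] = np.searchsorted(cum[s], u[mask]).astype(np.uint8)
        states[node] = np.minimum(st, 3)
        del u
    return states  # type: ignore[return-value]


def evolve_sequences(
    genealogies: list[LocalGenealogy],
    model: DemographicModel,
    rng: np.random.Generator | None = None,
) -> SimulatedHaplotypes:
    """Evolve sequences for every genealogy interval; returns full haplotypes."""
    if not genealogies:
        raise ValueError("no genealogies supplied")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    freqs = np.asarray(model.base_frequencies, dtype=float)
    uniform = bool(np.allclose(freqs, 0.25, atol=1e-12))
    n = model.n_samples
    total = genealogies[-1].end
    out = np.empty((n, total), dtype=np.uint8)
    if uniform:
        # batch the per-branch change counts across all intervals
        n_branch = 2 * n - 2
        kappa = model.hky_kappa
        beta = 4.0 / (kappa + 2.0)
        d_all = np.concatenate(
            [g.tree.branch_lengths() for g in genealogies]
        ) * model.branch_scale
        e2_all = np.exp(-beta * d_all)
        e3_all = np.exp(-beta * d_all * (kappa + 1.0) * 0.5)
        p_diff_all = 0.75 - 0.25 * e2_all - 0.5 * e3_all
        np.clip(p_diff_all, 0.0, 1.0, out=p_diff_all)
        spans = np.repeat(np.array([g.span for g in genealogies]), n_branch)
        n_changed_all = rng.binomial(spans, p_diff_all)
        for i, gen in enumerate(genealogies):
            sl = slice(i * n_branch, (i + 1) * n_branch)
            states = _evolve_tree_uniform(
                gen.tree,
                gen.span,
                rng,
                e2_all[sl],
                e3_all[sl],
                p_diff_all[sl],
                n_changed_all[sl],
            )
            for tip in range(n):
                out[tip, gen.start : gen.end] = states[tip]
    else:
        for gen in genealogies:
            states = _evolve_tree_general(
                gen.tree, gen.span, model.branch_scale, model.hky_kappa, freqs, rng
            )
            for tip in range(n):
                out[tip, gen.start : gen.end] = states[tip]
    matrix = HaplotypeMatrix(
        scaffold="sim1",
        positions=np.arange(1, total + 1),
        samples=model.sample_names(),
        calls=_CODE_TO_MASK[out],
        provenance="simulated",
    )
    return SimulatedHaplotypes(matrix, model, genealogies)


def simulate(
    model: DemographicModel, mode: str = "smc", block_bp: int = 1000
) -> SimulatedHaplotypes:
    """Full simulation: genealogies plus sequences, deterministically seeded.

    Genealogy sampling and mutation sampling use independent random streams
    derived from ``model.seed``.
    """
    ss = np.random.SeedSequence(model.seed)
    g_seed, m_seed = ss.spawn(2)
    genealogies = sample_genealogies(
        model, np.random.default_rng(g_seed), mode=mode, block_bp=block_bp
    )
    return evolve_sequences(genealogies, model, np.random.default_rng(m_seed))
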