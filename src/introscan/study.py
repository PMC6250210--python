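"""Orchestration: the simulation-calibration study and the divergence scan.

The study sweeps admixture direction x total frequency x pulse schedule,
and for every cell runs the three detectors on freshly simulated data:
f3 in all tip orderings, windowed d_XY for the three population pairs, and
the quartet proportion distribution with its tail symmetry counts.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .f3 import F3Result, f3_all_orderings, f3_genome
from .haplotypes import PopulationMap, allele_counts
from .model import DemographicModel, make_pulse_schedule
from .sequences import simulate
from .treeprop import TailReport, enumerate_quartets, tail_analysis, window_proportion_scan
from .windows import (
    GenomicWindow,
    WindowStatRecord,
    dxy_windows,
    make_windows,
    records_to_frame,
)

logger = logging.getLogger(__name__)

__all__ = ["StudyCell", "DivergenceScanResult", "run_simulation_study", "divergence_scan", "report"]

FRACTION_GRID = (0.0, 0.05, 0.1, 0.2, 0.3)
DIRECTIONS = ("O->I2", "I2->O")


@dataclass
class StudyCell:
    """All detector outputs for one grid cell."""

    direction: str
    total_fraction: float
    schedule_mode: str
    seed: int
    f3: dict[str, F3Result]
    dxy_means: dict[str, float]
    dxy_records: dict[str, list[WindowStatRecord]]
    proportion_mean: float
    n_proportions: int
    tails: TailReport | None


def _parse_direction(direction: str, model: DemographicModel) -> tuple[str, str]:
    roles = {"I1": model.ingroup1, "I2": model.ingroup2, "O": model.outgroup}
    try:
        src, dst = direction.split("->")
        return roles[src.strip()], roles[dst.strip()]
    except (ValueError, KeyError) as err:
        raise ValueError(f"bad direction {direction!r}; use e.g. 'O->I2'") from err


def run_simulation_study(
    base_model: DemographicModel,
    directions: tuple[str, ...] = DIRECTIONS,
    fractions: tuple[float, ...] = FRACTION_GRID,
    schedule_modes: tuple[str, ...] = ("single",),
    window_size: int = 50_000,
    recombination_mode: str = "smc",
    max_combinations: int | None = None,
    run_tails: bool = True,
) -> tuple[pd.DataFrame, list[StudyCell]]:
    """Run the full calibration grid; returns a summary table and cells.

    Every cell is independently seeded from ``base_model.seed``.  At
    ``total_fraction == 0`` the direction is irrelevant and the cell is run
    once, labelled ``"none"``.
    """
    cells: list[StudyCell] = []
    rows = []
    length = base_model.chromosome_length
    block_size = min(500_000, max(length // 10, 1))
    cell_index = 0
    seen_zero = False
    for mode in schedule_modes:
        for direction in directions:
            for frac in fractions:
                if frac == 0.0:
                    if seen_zero:
                        continue
                    seen_zero = True
                    label = "none"
                else:
                    label = direction
                cell_index += 1
                seed = (base_model.seed * 7919 + cell_index * 104729) % (2**31)
                try:
                    cell = _run_cell(
                        base_model, direction, frac, mode, label, seed,
                        window_size, block_size, recombination_mode,
                        max_combinations, run_tails,
                    )
                except Exception as err:
                    raise RuntimeError(
                        f"study cell failed: direction={label} f={frac} "
                        f"schedule={mode}: {err}"
                    ) from err
                cells.append(cell)
                row = {
                    "direction": label,
                    "total_fraction": frac,
                    "schedule": mode,
                    "seed": seed,
                    "proportion_mean": cell.proportion_mean,
                    "n_proportions": cell.n_proportions,
                }
                for tgt, res in cell.f3.items():
                    row[f"f3_target_{tgt}"] = res.f3_estimate
                    row[f"f3_target_{tgt}_z"] = res.z_score
                for pair, mean in cell.dxy_means.items():
                    row[f"dxy_{pair}"] = mean
                rows.append(row)
                logger.info("study cell done: %s f=%s %s", label, frac, mode)
    return pd.DataFrame(rows), cells


def _run_cell(
    base_model, direction, frac, mode, label, seed,
    window_size, block_size, recombination_mode, max_combinations, run_tails,
) -> StudyCell:
    src, dst = _parse_direction(direction if label != "none" else "O->I2", base_model)
    pulses = make_pulse_schedule(frac, mode, source=src, dest=dst)
    model = base_model.with_pulses(pulses).with_seed(seed)
    sim = simulate(model, mode=recombination_mode)
    matrix = sim.haplotypes
    popmap = PopulationMap.for_simulation(model)
    groups = {p: popmap.population_samples(p) for p in model.population_labels}
    counts = allele_counts(matrix, groups, ploidy=1)
    f3 = f3_all_orderings(
        counts, model.ingroup1, model.ingroup2, model.outgroup, block_size
    )
    windows = make_windows({matrix.scaffold: model.chromosome_length}, window_size)
    pairs = [
        (model.ingroup1, model.ingroup2),
        (model.ingroup1, model.outgroup),
        (model.ingroup2, model.outgroup),
    ]
    dxy_records = {}
    dxy_means = {}
    for a, b in pairs:
        recs = dxy_windows(counts, windows, a, b)
        key = f"{a},{b}"
        dxy_records[key] = recs
        vals = [r.value for r in recs if not r.is_na]
        dxy_means[key] = float(np.mean(vals)) if vals else float("nan")
    combos = enumerate_quartets(popmap, mode="simulated")
    if max_combinations is not None:
        combos = combos[:max_combinations]
    props = window_proportion_scan(matrix, windows, combos, popmap)
    finite = [r.proportion for r in props if np.isfinite(r.proportion)]
    prop_mean = float(np.mean(finite)) if finite else float("nan")
    tails = None
    if run_tails and finite:
        try:
            tails = tail_analysis(props)
        except ValueError:
            tails = None  # too few windows per combination at small scale
    return StudyCell(
        label, frac, mode, seed, f3, dxy_means, dxy_records,
        prop_mean, len(finite), tails,
    )


def _cell_seed(base_seed: int, *parts: int) -> int:
    ss = np.random.SeedSequence([int(base_seed) % (2**31), *[int(p) for p in parts]])
    return int(ss.generate_state(1)[0] % (2**31))


def f3_calibration(
    base_model: DemographicModel,
    directions: tuple[str, ...] = DIRECTIONS,
    fractions: tuple[float, ...] = FRACTION_GRID,
    n_replicates: int = 5,
    schedule_mode: str = "single",
    recombination_mode: str = "smc",
) -> pd.DataFrame:
    """Replicated f3(I1, O; I2) point estimates over the admixture grid.

    The f=0 cell is direction-free: it is simulated once per replicate and
    its estimate is shared by every direction.  Each (direction, fraction,
    replicate) cell is independently seeded from ``base_model.seed``.
    """
    rows = []
    for rep in range(n_replicates):
        zero_cache: dict[int, F3Result] | None = None
        for d_idx, direction in enumerate(directions):
            src, dst = _parse_direction(direction, base_model)
            for frac in fractions:
                if frac == 0.0 and zero_cache is not None:
                    res = zero_cache[rep]
                else:
                    seed = _cell_seed(
                        base_model.seed,
                        rep,
                        0 if frac == 0.0 else d_idx + 1,
                        round(frac * 1000),
                    )
                    pulses = make_pulse_schedule(
                        frac, schedule_mode, source=src, dest=dst
                    )
                    model = base_model.with_pulses(pulses).with_seed(seed)
                    sim = simulate(model, mode=recombination_mode)
                    popmap = PopulationMap.for_simulation(model)
                    groups = {
                        p: popmap.population_samples(p)
                        for p in model.population_labels
                    }
                    counts = allele_counts(sim.haplotypes, groups, ploidy=1)
                    block = min(500_000, max(model.chromosome_length // 10, 1))
                    res = f3_genome(
                        counts, model.ingroup2, model.ingroup1, model.outgroup, block
                    )
                    if frac == 0.0:
                        zero_cache = {rep: res}
                rows.append(
                    {
                        "direction": direction,
                        "total_fraction": frac,
                        "replicate": rep,
                        "f3": res.f3_estimate,
                        "se": res.jackknife_se,
                        "z": res.z_score,
                    }
                )
                logger.info(
                    "f3 calibration %s f=%.2f rep=%d: %.4f",
                    direction, frac, rep, res.f3_estimate,
                )
    return pd.DataFrame(rows)


def detection_threshold(calibration: pd.DataFrame, direction: str) -> float | None:
    """Smallest admixture fraction whose f3(I1, O; I2) point estimate is
    negative in the majority of replicates; None if no fraction qualifies."""
    sub = calibration[calibration.direction == direction]
    for frac in sorted(sub.total_fraction.unique()):
        reps = sub[sub.total_fraction == frac].f3
        if (reps < 0).sum() > len(reps) / 2:
            return float(frac)
    return None


@dataclass
class DivergenceScanResult:
    """Top-1% most divergent windows under d_XY and F_ST and their overlap."""

    ranked_dxy: pd.DataFrame
    ranked_fst: pd.DataFrame
    top_dxy: list[GenomicWindow]
    top_fst: list[GenomicWindow]
    intersection: list[GenomicWindow]
    n_analyzed: int
    top_fraction: float = 0.01


def divergence_scan(
    dxy_records: list[WindowStatRecord],
    fst_records: list[WindowStatRecord],
    top_fraction: float = 0.01,
) -> DivergenceScanResult:
    """Rank windows by each statistic and intersect the top-1% sets.

    Windows NA under either statistic are excluded.  Each ranked table also
    reports the window's percentile under the other statistic.
    """
    key = lambda r: (r.window.scaffold, r.window.start)
    fst_by = {key(r): r for r in fst_records}
    pairs = [
        (r, fst_by[key(r)])
        for r in dxy_records
        if key(r) in fst_by and not r.is_na and not fst_by[key(r)].is_na
    ]
    n = len(pairs)
    if n == 0:
        raise ValueError("no windows analysed under both statistics")
    if n < 100:
        logger.warning("divergence_scan: only %d windows; top 1%% is 1 window", n)
    k = math.ceil(top_fraction * n)
    dxy_vals = np.array([p[0].value for p in pairs])
    fst_vals = np.array([p[1].value for p in pairs])

    def pct(vals):
        order = vals.argsort().argsort()
        return 100.0 * (order + 1) / len(vals)

    dxy_pct, fst_pct = pct(dxy_vals), pct(fst_vals)
    frame = pd.DataFrame(
        {
            "scaffold": [p[0].window.scaffold for p in pairs],
            "start": [p[0].window.start_1based for p in pairs],
            "end": [p[0].window.end_1based for p in pairs],
            "dxy": dxy_vals,
            "fst": fst_vals,
            "dxy_percentile": dxy_pct,
            "fst_percentile": fst_pct,
        }
    )
    ranked_dxy = frame.sort_values("dxy", ascending=False).reset_index(drop=True)
    ranked_fst = frame.sort_values("fst", ascending=False).reset_index(drop=True)
    top_dxy = [p[0].window for p in (pairs[i] for i in np.argsort(-dxy_vals)[:k])]
    top_fst = [p[1].window for p in (pairs[i] for i in np.argsort(-fst_vals)[:k])]
    set_fst = {(w.scaffold, w.start) for w in top_fst}
    inter = [w for w in top_dxy if (w.scaffold, w.start) in set_fst]
    return DivergenceScanResult(ranked_dxy, ranked_fst, top_dxy, top_fst, inter, n)


def report(
    out_dir: str | Path,
    study: tuple[pd.DataFrame, list[StudyCell]] | None = None,
    f3_results: dict[str, F3Result] | None = None,
    window_tables: dict[str, list[WindowStatRecord]] | None = None,
    tails: TailReport | None = None,
    scan: DivergenceScanResult | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Collate stage outputs into tables plus a human-readable summary.

    Absent stages are marked "not run".  A JSON manifest records the
    configuration, seed and package version for reproducibility.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["introscan run summary", "====================", ""]
    if study is not None:
        df, _ = study
        df.to_csv(out_dir / "study_summary.tsv", sep="\t", index=False)
        lines.append(f"simulation study: {len(df)} grid cells (study_summary.tsv)")
        for _, r in df.iterrows():
            lines.append(
                f"  {r['direction']:>6} f={r['total_fraction']:<4} "
                f"{r['schedule']}: proportion_mean={r['proportion_mean']:.4f}"
            )
    else:
        lines.append("simulation study: not run")
    if f3_results is not None:
        rows = []
        for res in f3_results.values():
            rows.append(
                {
                    "ordering": res.label(),
                    "f3": res.f3_estimate,
                    "se": res.jackknife_se,
                    "z": res.z_score,
                    "n_blocks": res.n_blocks,
                    "n_sites": res.n_sites,
                }
            )
        pd.DataFrame(rows).to_csv(out_dir / "f3.tsv", sep="\t", index=False)
        lines.append(f"f3: {len(rows)} orderings (f3.tsv)")
    else:
        lines.append("f3: not run")
    if window_tables:
        for name, recs in window_tables.items():
            records_to_frame(recs).to_csv(
                out_dir / f"windows_{name}.tsv", sep="\t", index=False
            )
        lines.append(f"window statistics: {', '.join(window_tables)} written")
    else:
        lines.append("window statistics: not run")
    if tails is not None:
        tails.counts.to_csv(out_dir / "tail_counts.tsv", sep="\t", index=False)
        tails.flagged.to_csv(out_dir / "tail_flagged.tsv", sep="\t", index=False)
        tails.scaffold_hits.to_csv(
            out_dir / "tail_scaffold_hits.tsv", sep="\t", index=False
        )
        lines.append(
            f"tail analysis: {len(tails.means)} combinations, "
            f"{len(tails.flagged)} flagged windows"
        )
    else:
        lines.append("tail analysis: not run")
    if scan is not None:
        scan.ranked_dxy.to_csv(out_dir / "scan_ranked_dxy.tsv", sep="\t", index=False)
        scan.ranked_fst.to_csv(out_dir / "scan_ranked_fst.tsv", sep="\t", index=False)
        lines.append(
            f"divergence scan: {scan.n_analyzed} windows, "
            f"top sets of {len(scan.top_dxy)}, intersection {len(scan.intersection)}"
        )
    else:
        lines.append("divergence scan: not run")
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config or {},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out_dir / "summary.txt"
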