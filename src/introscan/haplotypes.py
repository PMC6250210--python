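"""Shared in-memory currency: haplotype matrices, population maps, allele counts.

Calls are stored as IUPAC bitmasks in a ``uint8`` matrix (A=1, C=2, G=4,
T=8; heterozygous diploid genotypes are the OR of their two bases; 0 means
missing/uncallable).  The same container carries simulated haploid data and
VCF-derived empirical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "BASES",
    "BASE_TO_MASK",
    "MASK_TO_CHAR",
    "CHAR_TO_MASK",
    "expected_mismatch_table",
    "HaplotypeMatrix",
    "SampleInfo",
    "PopulationMap",
    "SiteAlleleCounts",
    "allele_counts",
]

BASES = "ACGT"
BASE_TO_MASK = {"A": 1, "C": 2, "G": 4, "T": 8}
_IUPAC = {
    1: "A", 2: "C", 4: "G", 8: "T",
    3: "M", 5: "R", 9: "W", 6: "S", 10: "Y", 12: "K",
    7: "V", 11: "H", 13: "D", 14: "B", 15: "N", 0: "N",
}
MASK_TO_CHAR = np.array([_IUPAC[m] for m in range(16)], dtype="U1")

CHAR_TO_MASK = {c: m for m, c in _IUPAC.items() if m != 0}
CHAR_TO_MASK.update({"N": 0, "-": 0, "?": 0, ".": 0})

_POPCOUNT = np.array([bin(m).count("1") for m in range(16)])


def expected_mismatch_table() -> np.ndarray:
    """16x16 expected mismatch between IUPAC masks.

    Entry ``[a, b]`` is the mean mismatch over all compatible base
    resolutions of the two calls: ``1 - |a & b| / (|a| * |b|)``.  A
    heterozygote against a matching homozygote scores 0.5.  Entries
    involving a missing call (mask 0) are NaN.
    """
    tab = np.full((16, 16), np.nan)
    for a in range(1, 16):
        for b in range(1, 16):
            tab[a, b] = 1.0 - _POPCOUNT[a & b] / (_POPCOUNT[a] * _POPCOUNT[b])
    return tab


@dataclass
class HaplotypeMatrix:
    """Samples x sites call matrix for one scaffold.

    ``positions`` are 1-based base-pair coordinates, strictly increasing;
    ``calls[i, j]`` is the IUPAC mask of sample ``i`` at site ``j``.
    """

    scaffold: str
    positions: np.ndarray
    samples: list[str]
    calls: np.ndarray
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.uint8)
        if self.calls.shape != (len(self.samples), len(self.positions)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.positions)} sites"
            )
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)

    def site_slice(self, start: int, end: int) -> slice:
        """Column slice of sites with 0-based half-open bp span [start, end)."""
        lo = int(np.searchsorted(self.positions, start + 1))
        hi = int(np.searchsorted(self.positions, end, side="right"))
        return slice(lo, hi)

    def callable_fraction(self, start: int, end: int) -> np.ndarray:
        """Per-sample fraction of bp in [start, end) with a non-missing call."""
        cols = self.site_slice(start, end)
        span = max(end - start, 1)
        return (self.calls[:, cols] != 0).sum(axis=1) / span

    def sequence_string(self, sample: str, cols: slice | None = None) -> str:
        row = self.calls[self.sample_index(sample)]
        if cols is not None:
            row = row[cols]
        return "".join(MASK_TO_CHAR[row])

    @classmethod
    def from_strings(
        cls,
        sequences: Mapping[str, str],
        scaffold: str = "scaf1",
        positions: Iterable[int] | None = None,
        provenance: str = "simulated",
    ) -> "HaplotypeMatrix":
        samples = list(sequences)
        rows = []
        for s in samples:
            rows.append([CHAR_TO_MASK[c.upper()] for c in sequences[s]])
        calls = np.array(rows, dtype=np.uint8)
        if positions is None:
            positions = np.arange(1, calls.shape[1] + 1)
        return cls(scaffold, np.asarray(list(positions)), samples, calls, provenance)


@dataclass(frozen=True)
class SampleInfo:
    population: str
    species: str
    role: str  # one of I1, I2, O
    fixed_i1: bool = False


@dataclass
class PopulationMap:
    """Sample-to-population/species/role assignments."""

    info: dict[str, SampleInfo]

    def samples(self) -> list[str]:
        return list(self.info)

    def role_samples(self, role: str) -> list[str]:
        return [s for s, i in self.info.items() if i.role == role]

    def population_samples(self, population: str) -> list[str]:
        return [s for s, i in self.info.items() if i.population == population]

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for i in self.info.values():
            seen.setdefault(i.population, None)
        return list(seen)

    def fixed_i1_samples(self) -> list[str]:
        return [s for s, i in self.info.items() if i.fixed_i1]

    def role_groups(self) -> dict[str, list[str]]:
        return {r: self.role_samples(r) for r in ("I1", "I2", "O")}

    @classmethod
    def for_simulation(cls, model) -> "PopulationMap":
        """Roles follow the simulated populations; the first two I1 samples
        are the fixed quartet anchors."""
        info: dict[str, SampleInfo] = {}
        roles = {model.ingroup1: "I1", model.ingroup2: "I2", model.outgroup: "O"}
        n_fixed = 0
        for name, pop in zip(model.sample_names(), model.sample_populations()):
            role = roles[pop]
            fixed = role == "I1" and n_fixed < 2
            if fixed:
                n_fixed += 1
            info[name] = SampleInfo(pop, pop, role, fixed)
        return cls(info)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationMap":
        """Read a tab-separated map: sample, population, species, role[, fixed_i1]."""
        info: dict[str, SampleInfo] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"population map line needs >=4 columns: {line!r}")
            fixed = len(parts) > 4 and parts[4].strip().lower() in {"1", "true", "yes"}
            info[parts[0]] = SampleInfo(parts[1], parts[2], parts[3], fixed)
        return cls(info)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["#sample\tpopulation\tspecies\trole\tfixed_i1"]
        for s, i in self.info.items():
            lines.append(
                f"{s}\t{i.population}\t{i.species}\t{i.role}\t{int(i.fixed_i1)}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class SiteAlleleCounts:
    """Per-site, per-population counts of called alleles (A, C, G, T columns)."""

    scaffold: str
    positions: np.ndarray
    counts: dict[str, np.ndarray]
    ploidy: int = 1

    def totals(self, pop: str) -> np.ndarray:
        return self.counts[pop].sum(axis=1)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def pool(self, pops: Iterable[str]) -> np.ndarray:
        out = None
        for p in pops:
            out = self.counts[p].copy() if out is None else out + self.counts[p]
        return out


def allele_counts(
    matrix: HaplotypeMatrix,
    groups: Mapping[str, list[str]],
    ploidy: int = 1,
) -> SiteAlleleCounts:
    """Count called alleles per population at every site.

    With ``ploidy=1`` only unambiguous single-base calls contribute (one
    allele each).  With ``ploidy=2`` each call contributes two alleles: a
    homozygote adds two of its base, a two-base IUPAC heterozygote one of
    each.
    """
    counts: dict[str, np.ndarray] = {}
    for pop, names in groups.items():
        idx = [matrix.sample_index(s) for s in names]
        sub = matrix.calls[idx]
        out = np.zeros((matrix.n_sites, 4), dtype=np.int32)
        for col, bit in enumerate((1, 2, 4, 8)):
            if ploidy == 1:
                out[:, col] = (sub == bit).sum(axis=0)
            else:
                has = ((sub & bit) > 0) & (_POPCOUNT[sub] <= 2)
                out[:, col] = has.sum(axis=0) + ((sub == bit) & has).sum(axis=0)
        counts[pop] = out
    return SiteAlleleCounts(matrix.scaffold, matrix.positions, counts, ploidy)
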