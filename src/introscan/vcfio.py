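"""File formats: VCF (read/write), per-window FASTA, Newick sidecars, BED, config.

Reading applies the depth and missingness filters used throughout the
pipeline: genotypes with per-sample depth below the threshold are set
missing, and sites where more than the allowed fraction of samples is
missing are dropped.  Variant and invariant SNP sites are both retained;
indel/symbolic records are excluded.  Diploid genotypes are collapsed to
one IUPAC-coded call per sample (heterozygotes become two-base ambiguity
codes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .coalescent import LocalGenealogy
from .haplotypes import BASE_TO_MASK, MASK_TO_CHAR, HaplotypeMatrix
from .windows import GenomicWindow, WindowStatRecord

logger = logging.getLogger(__name__)

__all__ = [
    "VcfData",
    "read_vcf",
    "write_vcf",
    "write_window_fastas",
    "write_genealogies",
    "read_genealogy_table",
    "write_bed",
    "read_bed",
    "read_config",
]

DEFAULT_MIN_DEPTH = 5
DEFAULT_MAX_MISSING = 0.40


@dataclass
class VcfData:
    """Per-scaffold haplotype matrices plus filter accounting."""

    matrices: dict[str, HaplotypeMatrix]
    ploidy: int
    sites_read: int
    sites_kept: int
    sites_dropped_missing: int
    sites_dropped_nonsnp: int


def read_vcf(
    path: str | Path,
    min_genotype_depth: int = DEFAULT_MIN_DEPTH,
    max_missing_fraction: float = DEFAULT_MAX_MISSING,
    require_depth: bool = True,
) -> VcfData:
    """Read a multi-sample VCF (variant plus invariant sites) with filters.

    Genotypes with FORMAT/DP below ``min_genotype_depth`` are set missing;
    sites with more than ``max_missing_fraction`` of samples missing after
    depth masking are dropped.  ``require_depth=False`` permits VCFs
    without a DP field (e.g. simulator round-trips), in which case no depth
    mask is applied.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    per_scaffold: dict[str, tuple[list[int], list[np.ndarray]]] = {}
    sites_read = kept = dropped_missing = dropped_nonsnp = 0
    ploidy = 0
    last_pos: dict[str, int] = {}
    for v in vcf:
        sites_read += 1
        alleles = [v.REF] + [a for a in v.ALT]
        if any(len(a) != 1 or a.upper() not in BASE_TO_MASK for a in alleles if a):
            dropped_nonsnp += 1
            continue
        chrom = v.CHROM
        if chrom in last_pos and v.POS <= last_pos[chrom]:
            raise ValueError(
                f"VCF not sorted: {chrom}:{v.POS} after {chrom}:{last_pos[chrom]}"
            )
        last_pos[chrom] = v.POS
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is None and require_depth and min_genotype_depth > 0:
            raise ValueError(
                "VCF has no per-genotype FORMAT/DP field, required for the "
                f"minimum depth filter (min_genotype_depth={min_genotype_depth})"
            )
        allele_masks = np.array(
            [BASE_TO_MASK[a.upper()] for a in alleles], dtype=np.uint8
        )
        gts = v.genotypes  # [[a0, a1, phased], ...] or [[a0, phased], ...]
        row = np.zeros(n, dtype=np.uint8)
        for i, g in enumerate(gts):
            calls = g[:-1]
            if ploidy == 0:
                ploidy = len(calls)
            if any(a < 0 for a in calls):
                continue
            if dp is not None and dp[i][0] < min_genotype_depth:
                continue
            mask = 0
            for a in calls:
                mask |= int(allele_masks[a])
            row[i] = mask
        if (row == 0).sum() / n > max_missing_fraction:
            dropped_missing += 1
            continue
        kept += 1
        pos_list, rows = per_scaffold.setdefault(chrom, ([], []))
        pos_list.append(v.POS)
        rows.append(row)
    matrices = {}
    for chrom, (pos_list, rows) in per_scaffold.items():
        matrices[chrom] = HaplotypeMatrix(
            scaffold=chrom,
            positions=np.array(pos_list, dtype=np.int64),
            samples=samples,
            calls=np.array(rows, dtype=np.uint8).T,
            provenance="vcf",
        )
        logger.info(
            "read_vcf %s: %d sites kept", chrom, len(pos_list)
        )
    logger.info(
        "read_vcf: %d read, %d kept, %d dropped (missingness), %d dropped (non-SNP)",
        sites_read, kept, dropped_missing, dropped_nonsnp,
    )
    return VcfData(
        matrices, max(ploidy, 1), sites_read, kept, dropped_missing, dropped_nonsnp
    )


def write_vcf(
    matrix: HaplotypeMatrix,
    path: str | Path,
    contig_length: int | None = None,
    depth: int | None = None,
) -> None:
    """Write a minimal haploid multi-sample VCF (variant + invariant sites).

    The first base observed at a site is the REF allele; additional bases
    become ALTs.  ``depth`` adds a constant FORMAT/DP value so the output
    round-trips through the depth filter.
    """
    if contig_length is None:
        contig_length = int(matrix.positions[-1]) if matrix.n_sites else 0
    bit_to_char = {1: "A", 2: "C", 4: "G", 8: "T"}
    fmt = "GT:DP" if depth is not None else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={matrix.scaffold},length={contig_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        calls = matrix.calls
        for j in range(matrix.n_sites):
            col = calls[:, j]
            alleles: list[int] = []
            for c in col:
                if c != 0 and c in bit_to_char and c not in alleles:
                    alleles.append(int(c))
            if not alleles:
                continue
            ref = bit_to_char[alleles[0]]
            alt = ",".join(bit_to_char[a] for a in alleles[1:]) or "."
            index = {a: k for k, a in enumerate(alleles)}
            gts = []
            for c in col:
                g = "." if c == 0 or c not in index else str(index[int(c)])
                gts.append(f"{g}:{depth}" if depth is not None else g)
            fh.write(
                f"{matrix.scaffold}\t{matrix.positions[j]}\t.\t{ref}\t{alt}"
                f"\t.\t.\t.\t{fmt}\t" + "\t".join(gts) + "\n"
            )


def write_window_fastas(
    matrix: HaplotypeMatrix,
    windows: list[GenomicWindow],
    out_dir: str | Path,
) -> list[Path]:
    """One FASTA alignment per window, tip names as in the matrix."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for w in windows:
        cols = matrix.site_slice(w.start, w.end)
        records = [
            SeqRecord(
                Seq("".join(MASK_TO_CHAR[matrix.calls[i, cols]])),
                id=name,
                description="",
            )
            for i, name in enumerate(matrix.samples)
        ]
        p = out_dir / f"{w.scaffold}_{w.start_1based}_{w.end_1based}.fasta"
        SeqIO.write(records, p, "fasta")
        paths.append(p)
    return paths


def write_genealogies(
    genealogies: list[LocalGenealogy],
    path: str | Path,
    labels: list[str] | None = None,
) -> None:
    """Tab-separated sidecar: start, end (0-based half-open) and Newick."""
    with open(path, "w") as fh:
        fh.write("#start\tend\tnewick\n")
        for g in genealogies:
            fh.write(f"{g.start}\t{g.end}\t{g.tree.newick(labels)}\n")


def read_genealogy_table(path: str | Path) -> list[tuple[int, int, str]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        s, e, nwk = line.split("\t")
        out.append((int(s), int(e), nwk))
    return out


def write_bed(
    records: list[WindowStatRecord] | list[GenomicWindow], path: str | Path
) -> None:
    """BED export (0-based half-open); window records include value column."""
    with open(path, "w") as fh:
        for r in records:
            w = r.window if isinstance(r, WindowStatRecord) else r
            if isinstance(r, WindowStatRecord):
                fh.write(f"{w.scaffold}\t{w.start}\t{w.end}\t{r.statistic}\t{r.value:.8g}\n")
            else:
                fh.write(f"{w.scaffold}\t{w.start}\t{w.end}\n")


def read_bed(path: str | Path) -> list[GenomicWindow]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        out.append(GenomicWindow(parts[0], int(parts[1]), int(parts[2])))
    return out


def read_config(path: str | Path) -> dict[str, str]:
    """Key-value config file: one ``key = value`` per line, '#' comments."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {line!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out
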