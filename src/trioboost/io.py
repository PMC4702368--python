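"""Readers and writers: VCF genotypes, PED-like pedigrees, CSV reports.

Simulated datasets are emitted as phased VCF 4.2 (GT only) plus a
whitespace-delimited pedigree file (``FID IID SIRE DAM SEX``); user data
enters through the same pair of files.  Coordinates: internal locus indices
are 0-based, VCF positions are 1-based with 1 Morgan mapped to 1e8 bp
(the map is genetic-only, but VCF requires integer positions).  The major
allele is written as REF, the minor as ALT; unknown entries become ``./.``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pysam

from .simulate import GeneticMap, PanelMask, TrioDataset

__all__ = [
    "PedigreeRecord",
    "write_vcf",
    "read_vcf",
    "write_pedigree",
    "read_pedigree",
    "write_report",
    "PedigreeError",
]

log = logging.getLogger(__name__)

MORGAN_BP = 100_000_000  # 1 Morgan -> 1e8 bp for VCF emission
REF_BASE, ALT_BASE = "A", "C"


class PedigreeError(ValueError):
    """Malformed pedigree file or pedigree/VCF inconsistency."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One PED-like line; sire/dam '0' flags a founder."""

    family: str
    individual: str
    sire: str
    dam: str
    sex: int  # 1 = male, 2 = female, 0 = unknown


def _vcf_positions(gmap: GeneticMap) -> List[Tuple[str, int]]:
    """(contig, 1-based position) per locus; collisions nudged upward."""
    out = []
    for c, (name, _len) in enumerate(gmap.chromosomes):
        prev = 0
        for p in gmap.positions[c]:
            pos = int(round(p * MORGAN_BP)) + 1
            if pos <= prev:
                pos = prev + 1
            out.append((name, pos))
            prev = pos
    return out


def write_vcf(dataset: TrioDataset, path) -> None:
    """Write a dataset as phased VCF 4.2 (one record per locus, GT only)."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for name, length in dataset.gmap.chromosomes:
        header.contigs.add(name, length=int(round(length * MORGAN_BP)) + 10)
    for sample in dataset.ids:
        header.add_sample(sample)
    positions = _vcf_positions(dataset.gmap)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, (contig, pos) in enumerate(positions):
            rec = vcf.new_record(
                contig=contig, start=pos - 1, alleles=(REF_BASE, ALT_BASE)
            )
            rec.id = f"snp{j + 1}"
            for i, sample in enumerate(dataset.ids):
                a0, a1 = dataset.haplos[i, 0, j], dataset.haplos[i, 1, j]
                if np.isnan(a0) or np.isnan(a1):
                    rec.samples[sample]["GT"] = (None, None)
                else:
                    rec.samples[sample]["GT"] = (int(a0), int(a1))
                    rec.samples[sample].phased = True
            vcf.write(rec)


def read_vcf(path, pedigree_path, require_phased: bool = True) -> TrioDataset:
    """Read a VCF plus trio pedigree back into a :class:`TrioDataset`.

    Only biallelic records are used; multi-allelic ones are skipped with a
    logged count.  Unknown genotypes become NaN; the offspring mask is
    reconstructed from them (mode ``shared_panel`` if identical across
    offspring, else ``per_offspring_random``).  With ``require_phased``,
    unphased non-missing genotypes raise (allele-level work needs phase).
    """
    pedigree = read_pedigree(pedigree_path)
    trios = [
        (r.sire, r.dam, r.individual)
        for r in pedigree
        if r.sire != "0" and r.dam != "0"
    ]
    if not trios:
        raise PedigreeError("pedigree contains no complete trios")
    sires = [t[0] for t in trios]
    dams = [t[1] for t in trios]
    offspring = [t[2] for t in trios]
    ordered = sires + dams + offspring

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        missing = [s for s in ordered if s not in samples]
        if missing:
            raise PedigreeError(
                f"pedigree individuals absent from VCF: {', '.join(missing)}"
            )
        chrom_order: List[str] = []
        positions: dict = {}
        calls: List[np.ndarray] = []
        n_skipped = 0
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_skipped += 1
                continue
            col = np.empty((len(ordered), 2), dtype=np.float32)
            for i, s in enumerate(ordered):
                call = rec.samples[s]
                gt = call["GT"]
                if gt is None or any(a is None for a in gt):
                    col[i] = np.nan
                else:
                    if require_phased and not call.phased:
                        raise PedigreeError(
                            f"unphased genotype for {s} at {rec.chrom}:{rec.pos}; "
                            "allele-level mode requires phased input"
                        )
                    col[i] = gt
            if rec.chrom not in positions:
                chrom_order.append(rec.chrom)
                positions[rec.chrom] = []
            positions[rec.chrom].append((rec.pos - 1) / MORGAN_BP)
            calls.append(col)
        if n_skipped:
            log.warning("skipped %d non-biallelic VCF records", n_skipped)

    haplos = np.stack(calls, axis=2) if calls else np.empty((len(ordered), 2, 0), np.float32)
    gmap = GeneticMap(
        [(c, max(positions[c]) if positions[c] else 1.0) for c in chrom_order],
        [np.asarray(positions[c]) for c in chrom_order],
    )
    n_trios = len(trios)
    truth = np.nan_to_num(haplos, nan=0.0).astype(np.uint8)
    off = haplos[2 * n_trios :]
    masked = np.isnan(off).any(axis=1)
    mode = (
        "shared_panel"
        if masked.size and np.all(masked == masked[:1])
        else "per_offspring_random"
    )
    mask = PanelMask(mode, float(masked.mean()) if masked.size else 0.0, masked)
    ds = TrioDataset(
        ids=ordered,
        trios=trios,
        haplos=haplos,
        truth=truth,
        gmap=gmap,
        mask=mask,
    )
    ds.n_skipped_records = n_skipped
    return ds


def write_pedigree(trios: Sequence[Tuple[str, str, str]], path) -> None:
    """PED-like trio pedigree: parents as founders, offspring linked to both."""
    lines = []
    for k, (sire, dam, child) in enumerate(trios):
        fid = f"F{k + 1}"
        lines.append(f"{fid} {sire} 0 0 1")
        lines.append(f"{fid} {dam} 0 0 2")
        lines.append(f"{fid} {child} {sire} {dam} 0")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pedigree(path) -> List[PedigreeRecord]:
    """Parse a PED-like pedigree; malformed lines raise with their number."""
    records = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 5:
            raise PedigreeError(
                f"{path}: line {ln}: expected 5 fields (FID IID SIRE DAM SEX), "
                f"got {len(fields)}"
            )
        fid, iid, sire, dam, sex = fields
        try:
            sex_i = int(sex)
        except ValueError:
            raise PedigreeError(f"{path}: line {ln}: sex must be an integer") from None
        records.append(PedigreeRecord(fid, iid, sire, dam, sex_i))
    ids = {r.individual for r in records}
    for r in records:
        for parent in (r.sire, r.dam):
            if parent != "0" and parent not in ids:
                raise PedigreeError(
                    f"{path}: parent {parent} of {r.individual} not in file"
                )
    return records


def write_report(report, path) -> None:
    """Write the long accuracy table and its aggregated means as CSV.

    The long rows go to ``path``; the version-level and dataset-level means
    go to sibling files suffixed ``_means`` and ``_dataset_means``.  The
    informational runtime column is excluded so identical seeds give
    byte-identical files.
    """
    path = Path(path)
    long = report.long.drop(columns=["runtime_s"], errors="ignore")
    long.to_csv(path, index=False)
    report.version_means().to_csv(
        path.with_name(path.stem + "_means" + path.suffix), index=False
    )
    report.dataset_means().to_csv(
        path.with_name(path.stem + "_dataset_means" + path.suffix), index=False
    )
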