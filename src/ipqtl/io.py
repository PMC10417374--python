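"""Readers and writers for the plain-text formats used across the package.

Cross file dialect (CSV): row 1 = marker names, row 2 = chromosome labels,
row 3 = cM positions; each subsequent row is one individual, first field the
individual id, then one genotype letter per marker: A (recurrent
homozygote), H (heterozygote), - (missing). Round-trips bit-exactly.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genetics_core import MISSING, BackcrossGenotypes, GeneticMap

__all__ = [
    "read_cross_csv",
    "write_cross_csv",
    "read_vcf_dosages",
    "scan_to_csv",
    "peaks_to_csv",
]

_CODE_TO_LETTER = {0: "A", 1: "H", MISSING: "-"}
_LETTER_TO_CODE = {v: k for k, v in _CODE_TO_LETTER.items()}


def write_cross_csv(path, geno: BackcrossGenotypes) -> None:
    gmap = geno.map
    names = gmap.all_marker_names()
    chroms: list[str] = []
    pos: list[str] = []
    for c in gmap.chromosomes:
        chroms.extend([c] * len(gmap.marker_names[c]))
        pos.extend(repr(float(p)) for p in gmap.positions[c])  # shortest exact decimal
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id"] + names)
        w.writerow([""] + chroms)
        w.writerow([""] + pos)
        for i, ind in enumerate(geno.individual_ids):
            w.writerow([ind] + [_CODE_TO_LETTER[int(g)] for g in geno.matrix[i]])


def read_cross_csv(path) -> BackcrossGenotypes:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise ValueError("cross file needs 3 header rows and >= 1 individual")
    names = rows[0][1:]
    chrom_row = rows[1][1:]
    pos_row = [float(p) for p in rows[2][1:]]

    chromosomes: list[str] = []
    marker_names: dict[str, list[str]] = {}
    positions: dict[str, list[float]] = {}
    for name, c, p in zip(names, chrom_row, pos_row):
        if c not in marker_names:
            chromosomes.append(c)
            marker_names[c] = []
            positions[c] = []
        marker_names[c].append(name)
        positions[c].append(p)
    gmap = GeneticMap(
        chromosomes=chromosomes,
        marker_names=marker_names,
        positions={c: np.asarray(p) for c, p in positions.items()},
    )

    ids = []
    mat = []
    for row in rows[3:]:
        if not row:
            continue
        ids.append(row[0])
        try:
            mat.append([_LETTER_TO_CODE[g] for g in row[1:]])
        except KeyError as exc:
            raise ValueError(f"unknown genotype letter {exc} for individual {row[0]!r}") from exc
    return BackcrossGenotypes(map=gmap, matrix=np.asarray(mat, dtype=np.int8), individual_ids=ids)


def read_vcf_dosages(path, r2_field: str = "R2") -> tuple[pd.DataFrame, pd.Series]:
    """SNV dosage matrix (0/1/2 alt-allele counts) and per-SNV R^2 from a VCF.

    Multi-allelic sites are skipped with a warning. The R^2 INFO field is
    read when present (NaN otherwise). Requires cyvcf2.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    r2: dict[str, float] = {}
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping multi-allelic site {var.CHROM}:{var.POS}")
            continue
        vid = var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}"
        gt = var.gt_types.astype(float)  # 0=hom-ref 1=het 2=unknown 3=hom-alt
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        cols[vid] = dos
        val = var.INFO.get(r2_field)
        r2[vid] = float(val) if val is not None else np.nan
    dosages = pd.DataFrame(cols, index=samples)
    return dosages, pd.Series(r2)


def scan_to_csv(scans, path) -> None:
    """Write one or more ScanResults as tidy CSV."""
    if not isinstance(scans, (list, tuple)):
        scans = [scans]
    pd.concat([s.to_frame() for s in scans], ignore_index=True).to_csv(path, index=False)


def peaks_to_csv(peaks, path) -> None:
    from .qtl_mapping import peaks_to_frame

    peaks_to_frame(peaks).to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
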