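"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions are fixed package-wide: every in-memory position is
1-based inclusive (VCF/GFF3 convention).  BED is 0-based half-open on disk
and converted at the boundary.  Readers are gzip-transparent.

Only biallelic SNPs enter the pipeline; multiallelic and indel VCF records
are skipped with a counter so callers can log the loss.
"""
from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

# genotype codes used in every GenotypeMatrix
NO_CALL = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2


def xopen(path: str | Path, mode: str = "rt") -> IO:
    """Open a file, transparently decompressing ``.gz`` paths."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Joint genotypes of all sequenced lines at biallelic SNP sites.

    Attributes
    ----------
    samples
        Sample (line) names, one per row of ``gt``.
    chrom, positions, ref, alt
        Per-site arrays; positions are 1-based.
    gt
        ``(n_samples, n_sites)`` int8 array of genotype codes
        (``NO_CALL``/``HOM_REF``/``HET``/``HOM_ALT``).
    ad
        Optional ``(n_samples, n_sites, 2)`` ref/alt allele depths.
    dp
        Optional ``(n_samples, n_sites)`` total depths.
    n_skipped
        Number of multiallelic/indel records dropped when reading.
    """

    samples: list[str]
    chrom: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    ad: np.ndarray | None = None
    dp: np.ndarray | None = None
    n_skipped: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, names: Iterable[str]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.samples)}
        return np.array([idx[n] for n in names], dtype=np.intp)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Multiallelic and indel records are skipped and tallied in
    ``n_skipped``.  Raises :class:`FormatError` on a missing file, a
    malformed header, or zero samples.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"VCF not found: {path}")
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:  # pragma: no cover - pysam message
        raise FormatError(f"malformed VCF header in {path}: {exc}") from exc
    samples = list(vf.header.samples)
    if not samples:
        raise FormatError(f"VCF has zero samples: {path}")

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    gts: list[list[int]] = []
    ads: list[list[tuple[int, int]]] = []
    dps: list[list[int]] = []
    skipped = 0
    has_ad = True
    has_dp = True
    for rec in vf:
        rec_alts = rec.alts or ()
        if (
            len(rec_alts) != 1
            or len(rec.ref) != 1
            or len(rec_alts[0]) != 1
            or rec.ref not in "ACGT"
            or rec_alts[0] not in "ACGT"
        ):
            skipped += 1
            continue
        row_gt, row_ad, row_dp = [], [], []
        for name in samples:
            smp = rec.samples[name]
            alleles = smp.get("GT")
            if alleles is None or any(a is None for a in alleles):
                row_gt.append(NO_CALL)
            else:
                n_alt = sum(alleles)
                row_gt.append((HOM_REF, HET, HOM_ALT)[n_alt])
            ad = smp.get("AD")
            if ad is None or any(a is None for a in ad):
                has_ad = False
                row_ad.append((0, 0))
            else:
                row_ad.append((int(ad[0]), int(ad[1])))
            dp = smp.get("DP")
            if dp is None:
                has_dp = False
                row_dp.append(0)
            else:
                row_dp.append(int(dp))
        chroms.append(rec.chrom)
        positions.append(rec.pos)
        refs.append(rec.ref)
        alts.append(rec_alts[0])
        gts.append(row_gt)
        ads.append(row_ad)
        dps.append(row_dp)
    vf.close()

    n_sites = len(positions)
    gt = np.array(gts, dtype=np.int8).T if n_sites else np.empty((len(samples), 0), np.int8)
    ad_arr = np.array(ads, dtype=np.int32).transpose(1, 0, 2) if (n_sites and has_ad) else None
    dp_arr = np.array(dps, dtype=np.int32).T if (n_sites and has_dp) else None
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype="U1"),
        alt=np.array(alts, dtype="U1"),
        gt=gt,
        ad=ad_arr,
        dp=dp_arr,
        n_skipped=skipped,
    )


_GT_STRING = {NO_CALL: "./.", HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1"}

_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        fmt = "GT:AD:DP" if matrix.ad is not None else "GT"
        for j in range(matrix.n_sites):
            cols = [
                str(matrix.chrom[j]),
                str(int(matrix.positions[j])),
                ".",
                str(matrix.ref[j]),
                str(matrix.alt[j]),
                ".",
                ".",
                ".",
                fmt,
            ]
            for i in range(matrix.n_samples):
                cell = _GT_STRING[int(matrix.gt[i, j])]
                if matrix.ad is not None:
                    r, a = matrix.ad[i, j]
                    dp = matrix.dp[i, j] if matrix.dp is not None else r + a
                    cell += f":{int(r)},{int(a)}:{int(dp)}"
                cols.append(cell)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# callable masks (BED)
# ---------------------------------------------------------------------------

@dataclass
class CallableMask:
    """Non-overlapping, sorted genomic intervals; 1-based inclusive in memory."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_callable(self) -> int:
        return int(
            sum((iv[:, 1] - iv[:, 0] + 1).sum() for iv in self.intervals.values())
        )

    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean membership for 1-based ``positions`` on ``chrom``."""
        positions = np.asarray(positions)
        iv = self.intervals.get(chrom)
        if iv is None or not len(iv):
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(iv[:, 0], positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(positions.shape, dtype=bool)
        out[ok] = positions[ok] <= iv[idx[ok], 1]
        return out

    def to_boolean(self, chrom: str, length: int) -> np.ndarray:
        """Dense boolean array of length ``length`` (index i = position i+1)."""
        mask = np.zeros(length, dtype=bool)
        for start, end in self.intervals.get(chrom, np.empty((0, 2), np.int64)):
            mask[start - 1 : end] = True
        return mask

    @classmethod
    def from_boolean(cls, mask: np.ndarray, chrom: str = "chr1") -> "CallableMask":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return cls({chrom: np.empty((0, 2), dtype=np.int64)})
        padded = np.concatenate([[False], mask, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1) + 1  # to 1-based
        ends = np.flatnonzero(diff == -1)  # inclusive 1-based
        return cls({chrom: np.column_stack([starts, ends]).astype(np.int64)})


def _merge_intervals(iv: np.ndarray) -> tuple[np.ndarray, bool]:
    """Sort and merge overlapping/touching 1-based inclusive intervals."""
    order = np.lexsort((iv[:, 1], iv[:, 0]))
    iv = iv[order]
    merged = [iv[0].tolist()]
    did_merge = not np.array_equal(order, np.arange(len(iv)))
    for start, end in iv[1:]:
        if start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], int(end))
            did_merge = True
        else:
            merged.append([int(start), int(end)])
    return np.array(merged, dtype=np.int64), did_merge


def read_bed(path: str | Path) -> CallableMask:
    """Read a BED file (0-based half-open) into a :class:`CallableMask`.

    Unsorted or overlapping intervals are merged with a warning.
    """
    raw: dict[str, list[list[int]]] = {}
    with xopen(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"bad BED line: {line!r}")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise FormatError(f"empty/inverted BED interval: {line!r}")
            raw.setdefault(chrom, []).append([start + 1, end])  # to 1-based incl.
    intervals = {}
    warned = False
    for chrom, ivs in raw.items():
        merged, did_merge = _merge_intervals(np.array(ivs, dtype=np.int64))
        intervals[chrom] = merged
        warned = warned or did_merge
    if warned:
        warnings.warn("BED intervals were unsorted or overlapping; merged", stacklevel=2)
    return CallableMask(intervals)


def write_bed(mask: CallableMask, path: str | Path) -> None:
    """Write a :class:`CallableMask` as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in mask.intervals:
            for start, end in mask.intervals[chrom]:
                fh.write(f"{chrom}\t{start - 1}\t{end}\n")


# ---------------------------------------------------------------------------
# FASTA / TSV
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    with xopen(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
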