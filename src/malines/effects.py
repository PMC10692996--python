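"""Minimal variant-effect prediction over a toy gene annotation.

One consequence per variant (the most severe), drawn from the eight terms
the downstream tables use, with a fixed consequence -> impact mapping:

    HIGH      stop_gained, splice_donor_variant
    MODERATE  missense_variant
    LOW       synonymous_variant
    MODIFIER  upstream_gene_variant, downstream_gene_variant,
              intron_variant, intergenic_variant

Severity precedence when regions overlap:
splice_donor > stop_gained > missense > synonymous > intron > upstream >
downstream > intergenic.  Splice donors are the first two intronic bases
after an exon in transcription direction.  Coding changes are evaluated by
translating the affected codon with the standard genetic code.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import spectrum
from .errors import FormatError

#: severity order, most severe first
CONSEQUENCES = (
    "splice_donor_variant",
    "stop_gained",
    "missense_variant",
    "synonymous_variant",
    "intron_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
)

IMPACT_OF = {
    "splice_donor_variant": "HIGH",
    "stop_gained": "HIGH",
    "missense_variant": "MODERATE",
    "synonymous_variant": "LOW",
    "upstream_gene_variant": "MODIFIER",
    "downstream_gene_variant": "MODIFIER",
    "intron_variant": "MODIFIER",
    "intergenic_variant": "MODIFIER",
}

IMPACTS = ("HIGH", "LOW", "MODERATE", "MODIFIER")

_SEVERITY = {c: i for i, c in enumerate(CONSEQUENCES)}


def impact_of(consequence: str) -> str:
    """Impact class for a consequence term; raises ``ValueError`` if unknown."""
    try:
        return IMPACT_OF[consequence]
    except KeyError:
        raise ValueError(f"unknown consequence term: {consequence!r}") from None


@dataclass
class Transcript:
    """A transcript with exons and CDS segments (1-based inclusive)."""

    transcript_id: str
    gene_id: str
    seqid: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise FormatError(
                    f"exon [{s},{e}] outside transcript {self.transcript_id}"
                )
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise FormatError(f"overlapping exons in {self.transcript_id}")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 - e1 > 1
        ]

    def splice_donor_positions(self) -> set[int]:
        """First two intronic bases after each exon, in transcription direction."""
        sites: set[int] = set()
        for istart, iend in self.introns:
            if self.strand == "+":
                sites.update(p for p in (istart, istart + 1) if p <= iend)
            else:
                sites.update(p for p in (iend, iend - 1) if p >= istart)
        return sites

    def cds_positions(self) -> np.ndarray:
        """Genomic positions of the spliced CDS in translation order."""
        segs = [np.arange(s, e + 1) for s, e in self.cds]
        joined = np.concatenate(segs) if segs else np.empty(0, np.int64)
        return joined[::-1] if self.strand == "-" else joined


@dataclass
class Annotation:
    """A set of transcripts plus the up/downstream window length W (bp)."""

    transcripts: list[Transcript]
    window: int = 500

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise FormatError("window must be > 0")

    @classmethod
    def from_gff3(cls, path: str | Path, window: int = 500) -> "Annotation":
        """Load transcripts from a GFF3 file (gene -> mRNA -> exon/CDS)."""
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        transcripts = []
        for t in db.features_of_type("mRNA"):
            exons = [(f.start, f.end) for f in db.children(t, featuretype="exon")]
            cds = [(f.start, f.end) for f in db.children(t, featuretype="CDS")]
            parents = list(db.parents(t, featuretype="gene"))
            gene_id = parents[0].id if parents else t.id
            transcripts.append(
                Transcript(
                    transcript_id=t.id,
                    gene_id=gene_id,
                    seqid=t.seqid,
                    strand=t.strand,
                    start=t.start,
                    end=t.end,
                    exons=exons,
                    cds=cds,
                )
            )
        if not transcripts:
            raise FormatError(f"no mRNA features in {path}")
        return cls(transcripts=transcripts, window=window)

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for t in self.transcripts:
                fh.write(
                    f"{t.seqid}\ttoy\tgene\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t"
                    f"ID={t.gene_id}\n"
                )
                fh.write(
                    f"{t.seqid}\ttoy\tmRNA\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={t.gene_id}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{t.seqid}\ttoy\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )
                phase = 0
                cds = t.cds if t.strand == "+" else t.cds[::-1]
                for s, e in cds:
                    fh.write(
                        f"{t.seqid}\ttoy\tCDS\t{s}\t{e}\t.\t{t.strand}\t{phase}\t"
                        f"Parent={t.transcript_id}\n"
                    )
                    phase = (3 - ((e - s + 1 - phase) % 3)) % 3


def _coding_consequence(
    transcript: Transcript, pos: int, ref: str, alt: str, reference: str
) -> str:
    """Classify a SNP inside the CDS by translating the affected codon."""
    cds_pos = transcript.cds_positions()
    idx = int(np.flatnonzero(cds_pos == pos)[0])
    codon_start = (idx // 3) * 3
    codon_positions = cds_pos[codon_start : codon_start + 3]
    if len(codon_positions) < 3:  # trailing partial codon in a malformed CDS
        return "synonymous_variant"
    bases = [reference[p - 1] for p in codon_positions]
    offset = idx - codon_start
    ref_codon = bases.copy()
    alt_codon = bases.copy()
    if transcript.strand == "-":
        from .seqcodes import COMPLEMENT

        ref_codon = [COMPLEMENT[b] for b in ref_codon]
        alt_codon = [COMPLEMENT[b] for b in alt_codon]
        ref_codon[offset] = COMPLEMENT[ref]
        alt_codon[offset] = COMPLEMENT[alt]
    else:
        ref_codon[offset] = ref
        alt_codon[offset] = alt
    aa_ref = str(Seq("".join(ref_codon)).translate())
    aa_alt = str(Seq("".join(alt_codon)).translate())
    if aa_ref == aa_alt:
        return "synonymous_variant"
    if aa_alt == "*":
        return "stop_gained"
    # stop_lost / start_lost fold into the nearest of the eight terms
    return "missense_variant"


def predict_effect(
    position: int,
    ref: str,
    alt: str,
    annotation: Annotation,
    reference: str,
    seqid: str = "chr1",
) -> str:
    """Most severe consequence of a biallelic SNP under the toy annotation.

    ``reference`` is the full chromosome sequence (used for codon context).
    Raises ``ValueError`` when the position falls outside the sequence.
    """
    if not (1 <= position <= len(reference)):
        raise ValueError(f"position {position} outside sequence of length {len(reference)}")
    candidates: list[str] = []
    W = annotation.window
    for t in annotation.transcripts:
        if t.seqid != seqid:
            continue
        if t.start <= position <= t.end:
            in_exon = any(s <= position <= e for s, e in t.exons)
            in_cds = any(s <= position <= e for s, e in t.cds)
            if in_cds:
                candidates.append(_coding_consequence(t, position, ref, alt, reference))
            elif in_exon:
                candidates.append("intron_variant")  # non-coding exon folds to MODIFIER
            elif position in t.splice_donor_positions():
                candidates.append("splice_donor_variant")
            else:
                candidates.append("intron_variant")
        else:
            before = t.start - W <= position < t.start
            after = t.end < position <= t.end + W
            if t.strand == "+":
                if before:
                    candidates.append("upstream_gene_variant")
                elif after:
                    candidates.append("downstream_gene_variant")
            else:
                if before:
                    candidates.append("downstream_gene_variant")
                elif after:
                    candidates.append("upstream_gene_variant")
    if not candidates:
        return "intergenic_variant"
    return min(candidates, key=_SEVERITY.__getitem__)


def effect_table(
    effects_by_regime: Mapping[str, Iterable[str]],
    regimes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-regime consequence counts with the derived impact rows appended.

    Rows are indexed by consequence term then impact class; columns are
    regimes.  Impact rows are deterministic sums of the consequence rows.
    """
    if regimes is None:
        regimes = list(effects_by_regime)
    table = pd.DataFrame(
        0, index=list(CONSEQUENCES), columns=list(regimes), dtype=np.int64
    )
    for regime, terms in effects_by_regime.items():
        for term in terms:
            if term not in _SEVERITY:
                raise ValueError(f"unknown consequence term: {term!r}")
            table.loc[term, regime] += 1
    return pd.concat([table, impacts_from_consequences(table)])


def impacts_from_consequences(consequence_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a consequence x regime table into impact x regime rows."""
    impact = pd.DataFrame(
        0, index=list(IMPACTS), columns=consequence_table.columns, dtype=np.int64
    )
    for term in consequence_table.index:
        impact.loc[impact_of(term)] += consequence_table.loc[term].astype(np.int64)
    return impact


def compare_effect_counts(
    counts: Sequence[int], B: int = 10_000, seed: int = 0
) -> spectrum.ChisqResult:
    """Equal-proportions goodness of fit across regimes for one category."""
    if sum(counts) < 1:
        raise ValueError("category total must be >= 1")
    return spectrum.chisq_gof(counts, None, B=B, seed=seed)
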