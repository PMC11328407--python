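"""Functional annotation of editing sites from transcript models.

Assigns each site a functional category (CDS-derived missense/synonymous/
stop-related, 5'UTR, 3'UTR, intronic, lincRNA, intergenic) and, for coding
sites, computes the coding consequence in HGVS c./p. notation (e.g.
``c.1099A>G`` / ``p.S367G``): the genomic position is mapped to a 1-based
CDS coordinate in transcript orientation, the affected codon is substituted
A->G at the right offset, and both codons are translated with the standard
genetic code.

Ambiguity policy: one canonical transcript per gene (longest CDS, then
longest exonic span); sites overlapped by genes on both strands are
strand-ambiguous and reported without a category; category precedence
across genes is CDS > UTR > intron > lincRNA > intergenic.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

CATEGORIES = (
    "missense",
    "synonymous",
    "stop_related",
    "5UTR",
    "3UTR",
    "intronic",
    "lincRNA",
    "intergenic",
)

# precedence among overlapping genes (lower = wins); CDS categories resolved
# after recoding all rank equally at the CDS level
_PRECEDENCE = {
    "CDS": 0,
    "5UTR": 1,
    "3UTR": 1,
    "intronic": 2,
    "lincRNA": 3,
    "intergenic": 4,
}


class CoordinateError(ValueError):
    pass


class RecodingError(ValueError):
    pass


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: sorted 1-based inclusive exon and CDS intervals."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        for name, ivals in (("exons", self.exons), ("cds", self.cds)):
            prev_end = 0
            for s, e in ivals:
                if s > e:
                    raise ValueError(f"{name}: interval ({s},{e}) reversed")
                if s <= prev_end:
                    raise ValueError(f"{name}: intervals overlap or are unsorted")
                prev_end = e
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError("CDS interval not contained in an exon")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def cds_partial(self) -> bool:
        """True when the CDS length is not a whole number of codons."""
        return bool(self.cds) and self.cds_length % 3 != 0

    # ---- coordinate maps (all 1-based) ------------------------------------

    def _oriented(self, ivals: tuple[tuple[int, int], ...]):
        return ivals if self.strand == "+" else tuple(reversed(ivals))

    def genomic_to_cds(self, pos: int) -> int:
        """1-based coding coordinate of a genomic position inside the CDS."""
        acc = 0
        for s, e in self._oriented(self.cds):
            if s <= pos <= e:
                offset = (pos - s) if self.strand == "+" else (e - pos)
                return acc + offset + 1
            acc += e - s + 1
        raise CoordinateError(
            f"{self.transcript_id}: genomic position {pos} is outside the CDS; "
            "categorize the site first"
        )

    def cds_to_genomic(self, cds_pos: int) -> int:
        if cds_pos < 1 or cds_pos > self.cds_length:
            raise CoordinateError(f"cds position {cds_pos} out of range")
        rem = cds_pos - 1
        for s, e in self._oriented(self.cds):
            length = e - s + 1
            if rem < length:
                return s + rem if self.strand == "+" else e - rem
            rem -= length
        raise AssertionError("unreachable")

    def genomic_to_transcript(self, pos: int) -> int:
        acc = 0
        for s, e in self._oriented(self.exons):
            if s <= pos <= e:
                offset = (pos - s) if self.strand == "+" else (e - pos)
                return acc + offset + 1
            acc += e - s + 1
        raise CoordinateError(f"position {pos} not exonic in {self.transcript_id}")

    def transcript_to_genomic(self, tpos: int) -> int:
        if tpos < 1 or tpos > self.exonic_length:
            raise CoordinateError(f"transcript position {tpos} out of range")
        rem = tpos - 1
        for s, e in self._oriented(self.exons):
            length = e - s + 1
            if rem < length:
                return s + rem if self.strand == "+" else e - rem
            rem -= length
        raise AssertionError("unreachable")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def is_exonic(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def is_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)

    def region_of(self, pos: int) -> str:
        """Raw region label for a genomic position within the gene span."""
        if not self.contains(pos):
            return "intergenic"
        if self.biotype == "lincRNA":
            return "lincRNA" if self.is_exonic(pos) else "intronic"
        if self.is_cds(pos):
            return "CDS"
        if self.is_exonic(pos):
            if not self.cds:  # non-coding exon of any biotype
                return "lincRNA"
            tpos = self.genomic_to_transcript(pos)
            cds_start_t = self.genomic_to_transcript(self.cds_to_genomic(1))
            return "5UTR" if tpos < cds_start_t else "3UTR"
        return "intronic"


@dataclass(frozen=True)
class RecodingResult:
    category: str
    cds_pos: int
    codon_index: int  # 1-based residue number
    codon_offset: int  # 1..3 within the codon
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    hgvs_c: str
    hgvs_p: str


def recode(cds_pos: int, cds_sequence: str) -> RecodingResult:
    """Consequence of an A>G edit at a 1-based CDS coordinate.

    ``cds_sequence`` is the transcript-oriented coding sequence; the base at
    ``cds_pos`` must be A (inosine is read as G, so editing is always A>G in
    transcript orientation).
    """
    seq = cds_sequence.upper()
    if cds_pos < 1 or cds_pos > len(seq):
        raise CoordinateError(f"cds position {cds_pos} outside sequence of length {len(seq)}")
    if seq[cds_pos - 1] != "A":
        raise RecodingError(
            f"transcript base at c.{cds_pos} is {seq[cds_pos - 1]}, expected A "
            "(model/sequence mismatch)"
        )
    codon_index = (cds_pos + 2) // 3
    codon_offset = (cds_pos - 1) % 3 + 1
    start = (codon_index - 1) * 3
    ref_codon = seq[start : start + 3]
    if len(ref_codon) < 3:
        raise RecodingError(f"partial terminal codon at residue {codon_index}")
    alt_codon = ref_codon[: codon_offset - 1] + "G" + ref_codon[codon_offset:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == "*" or alt_aa == "*":
        category = "stop_related"
    elif ref_aa == alt_aa:
        category = "synonymous"
    else:
        category = "missense"
    return RecodingResult(
        category=category,
        cds_pos=cds_pos,
        codon_index=codon_index,
        codon_offset=codon_offset,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        hgvs_c=f"c.{cds_pos}A>G",
        hgvs_p=f"p.{ref_aa}{codon_index}{alt_aa}",
    )


class TranscriptIndex:
    """Canonical-transcript index with interval lookup per chromosome.

    Keeps one transcript per gene (longest CDS, then longest exonic span,
    then transcript_id for determinism).
    """

    def __init__(self, models: Iterable[TranscriptModel]):
        canonical: dict[str, TranscriptModel] = {}
        for m in models:
            cur = canonical.get(m.gene_id)
            key = (m.cds_length, m.exonic_length, m.transcript_id)
            if cur is None or key > (cur.cds_length, cur.exonic_length, cur.transcript_id):
                canonical[m.gene_id] = m
        self.models = sorted(canonical.values(), key=lambda m: (m.chrom, m.start, m.gene_id))
        self._by_chrom: dict[str, tuple[list[int], list[TranscriptModel]]] = {}
        for m in self.models:
            starts, ms = self._by_chrom.setdefault(m.chrom, ([], []))
            starts.append(m.start)
            ms.append(m)

    def overlapping(self, chrom: str, pos: int) -> list[TranscriptModel]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ms = entry
        hi = bisect.bisect_right(starts, pos)
        # genes here are short relative to spacing; linear scan back is fine
        return [m for m in ms[:hi] if m.end >= pos]

    def strand_at(self, chrom: str, pos: int) -> Optional[str]:
        """'+', '-', 'ambiguous' (both strands overlap) or None."""
        strands = {m.strand for m in self.overlapping(chrom, pos)}
        if not strands:
            return None
        if len(strands) > 1:
            return "ambiguous"
        return strands.pop()


@dataclass(frozen=True)
class SiteAnnotation:
    chrom: str
    pos: int
    strand: Optional[str]
    category: Optional[str]  # None when strand-ambiguous
    gene_id: Optional[str]
    transcript_id: Optional[str]
    recoding: Optional[RecodingResult] = None


def categorize(
    chrom: str,
    pos: int,
    index: TranscriptIndex,
    cds_sequences: Optional[dict[str, str]] = None,
) -> SiteAnnotation:
    """Categorize a site; recode it when it lands in a CDS.

    Sites overlapped by genes on opposite strands get no category (they are
    withheld from A-to-I typing and reported separately).
    """
    overlapping = index.overlapping(chrom, pos)
    if not overlapping:
        return SiteAnnotation(chrom, pos, None, "intergenic", None, None)
    strands = {m.strand for m in overlapping}
    if len(strands) > 1:
        return SiteAnnotation(chrom, pos, None, None, None, None)
    strand = strands.pop()
    best: Optional[tuple[int, str, TranscriptModel]] = None
    for m in overlapping:
        region = m.region_of(pos)
        rank = _PRECEDENCE[region]
        if best is None or (rank, m.gene_id) < (best[0], best[2].gene_id):
            best = (rank, region, m)
    assert best is not None
    _, region, model = best
    recoding = None
    category = region
    if region == "CDS":
        if cds_sequences is not None and model.transcript_id in cds_sequences:
            cds_pos = model.genomic_to_cds(pos)
            recoding = recode(cds_pos, cds_sequences[model.transcript_id])
            category = recoding.category
        else:
            category = "missense"  # CDS hit without a sequence: level unknown
    return SiteAnnotation(
        chrom, pos, strand, category, model.gene_id, model.transcript_id, recoding
    )


def annotate_events(
    events: pd.DataFrame,
    index: TranscriptIndex,
    cds_sequences: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Add category/gene/HGVS columns to an events table (chrom, pos keys)."""
    cats, genes, hgvs_c, hgvs_p = [], [], [], []
    for r in events.itertuples():
        ann = categorize(str(r.chrom), int(r.pos), index, cds_sequences)
        cats.append(ann.category if ann.category is not None else "strand_ambiguous")
        genes.append(ann.gene_id)
        hgvs_c.append(ann.recoding.hgvs_c if ann.recoding else None)
        hgvs_p.append(ann.recoding.hgvs_p if ann.recoding else None)
    out = events.copy()
    out["category"] = cats
    out["gene_id"] = genes
    out["hgvs_c"] = hgvs_c
    out["hgvs_p"] = hgvs_p
    return out


# ---- readers / writers ----------------------------------------------------

_TABLE_COLUMNS = [
    "gene_id", "transcript_id", "chrom", "strand", "biotype",
    "exon_starts", "exon_ends", "cds_starts", "cds_ends",
]


def _join(ivals, which):
    return ",".join(str(iv[which]) for iv in ivals) if ivals else "."


def write_transcript_table(models: Iterable[TranscriptModel], path) -> None:
    rows = [
        {
            "gene_id": m.gene_id,
            "transcript_id": m.transcript_id,
            "chrom": m.chrom,
            "strand": m.strand,
            "biotype": m.biotype,
            "exon_starts": _join(m.exons, 0),
            "exon_ends": _join(m.exons, 1),
            "cds_starts": _join(m.cds, 0),
            "cds_ends": _join(m.cds, 1),
        }
        for m in models
    ]
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def _parse_intervals(starts: str, ends: str) -> tuple[tuple[int, int], ...]:
    if starts in (".", "") or (isinstance(starts, float) and np.isnan(starts)):
        return ()
    ss = [int(x) for x in str(starts).split(",")]
    es = [int(x) for x in str(ends).split(",")]
    return tuple(zip(ss, es))


def read_transcript_table(path) -> list[TranscriptModel]:
    """Read the simplified tab-separated transcript-model table."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"transcript table missing columns: {sorted(missing)}")
    return [
        TranscriptModel(
            gene_id=r.gene_id,
            transcript_id=r.transcript_id,
            chrom=r.chrom,
            strand=r.strand,
            exons=_parse_intervals(r.exon_starts, r.exon_ends),
            cds=_parse_intervals(r.cds_starts, r.cds_ends),
            biotype=r.biotype,
        )
        for r in frame.itertuples()
    ]


def read_gtf(path) -> list[TranscriptModel]:
    """Read exon/CDS features from a GTF into transcript models."""
    import pyranges as pr

    df = pr.read_gtf(path, as_df=True)
    models = []
    for (tid,), sub in df[df.Feature.isin(["exon", "CDS"])].groupby(["transcript_id"]):
        exons = sub[sub.Feature == "exon"]
        cds = sub[sub.Feature == "CDS"]
        biotype = "protein_coding"
        for col in ("gene_biotype", "gene_type", "transcript_biotype"):
            if col in sub.columns and sub[col].notna().any():
                biotype = str(sub[col].dropna().iloc[0])
                break
        if biotype in ("lincRNA", "lncRNA"):
            biotype = "lincRNA"
        # GTF is 1-based inclusive in text; pyranges converts Start to 0-based
        def ivals(part):
            pairs = sorted((int(s) + 1, int(e)) for s, e in zip(part.Start, part.End))
            return tuple(pairs)

        models.append(
            TranscriptModel(
                gene_id=str(exons.gene_id.iloc[0]),
                transcript_id=str(tid),
                chrom=str(exons.Chromosome.iloc[0]),
                strand=str(exons.Strand.iloc[0]),
                exons=ivals(exons),
                cds=ivals(cds) if len(cds) else (),
                biotype=biotype,
            )
        )
    return models


def read_cds_fasta(path) -> dict[str, str]:
    """CDS sequences keyed by transcript_id (transcript orientation)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_cds_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for tid in sequences:
            fh.write(f">{tid}\n")
            seq = sequences[tid]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
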