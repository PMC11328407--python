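"""Per-site, per-sample variant screening from pileup-style input.

A-to-I editing shows up in RNA-seq as A>G mismatches on the transcribed
strand (T>C when the gene is on the minus strand). This module counts
quality-filtered alleles from samtools-mpileup text or pre-counted allele
tables, applies the screening thresholds (base quality, depth, alternative
allele depth, mismatch frequency), resolves A-to-I identity from the gene
strand and computes per-sample editing levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, TextIO

import pandas as pd

_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class PileupParseError(ValueError):
    """Malformed mpileup line (reported with its 1-based line number)."""


@dataclass(frozen=True)
class CallingThresholds:
    """Screening thresholds for candidate editing sites.

    Defaults are the standard RNA-editing screen: base quality >= 25,
    sequencing depth >= 10, alternative allele depth >= 2 and mismatch
    frequency >= 1%.
    """

    min_base_quality: int = 25
    min_depth: int = 10
    min_alt_depth: int = 2
    min_frequency: float = 0.01

    def __post_init__(self) -> None:
        if self.min_base_quality < 0 or self.min_depth < 0 or self.min_alt_depth < 0:
            raise ValueError("thresholds must be non-negative")
        if not (0 < self.min_frequency <= 1):
            raise ValueError("min_frequency must be in (0, 1]")


@dataclass(frozen=True)
class AlleleCountRecord:
    """Quality-filtered allele counts for one site in one sample.

    ``ref_count``/``alt_count`` count only bases passing the quality
    threshold; ``other_count`` collects passing bases that are neither the
    reference nor the majority alternative (including deletion placeholders
    and reference skips). ``below_quality`` tracks bases dropped by the
    quality screen so that the pileup depth column is fully conserved.
    """

    chrom: str
    pos: int  # 1-based
    ref_base: str
    alt_base: Optional[str]  # None when no non-reference base was observed
    sample_id: str
    ref_count: int
    alt_count: int
    other_count: int = 0
    below_quality: int = 0

    def __post_init__(self) -> None:
        if self.ref_base not in _BASES:
            raise ValueError(f"invalid ref base {self.ref_base!r}")
        if self.alt_base is not None and self.alt_base not in _BASES:
            raise ValueError(f"invalid alt base {self.alt_base!r}")
        if self.alt_base == self.ref_base:
            raise ValueError("alt base equals ref base")
        if min(self.ref_count, self.alt_count, self.other_count) < 0:
            raise ValueError("negative counts")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count + self.other_count

    @property
    def frequency(self) -> float:
        denom = self.ref_count + self.alt_count
        return self.alt_count / denom if denom else 0.0


@dataclass(frozen=True)
class VariantCall:
    record: AlleleCountRecord
    passes: bool
    is_a_to_i: Optional[bool] = None  # None until a strand is resolved
    strand: Optional[str] = None

    @property
    def frequency(self) -> float:
        return self.record.frequency


def parse_pileup(
    stream: TextIO | Iterable[str],
    sample_id: str,
    thresholds: CallingThresholds | None = None,
) -> list[AlleleCountRecord]:
    """Parse 6-column samtools-mpileup text into allele-count records.

    Columns: chrom, pos, ref, depth, base string, quality string. The base
    string dialect handled: ``.``/``,`` reference matches, ``ACGTacgt``
    substitutions, ``^`` + mapping quality (read start), ``$`` (read end),
    ``+n``/``-n`` indel runs (consumed, no counts), ``*`` deletion
    placeholders and ``<``/``>`` reference skips (counted as "other").
    Only bases with Phred quality >= ``min_base_quality`` contribute to
    ref/alt/other counts. The most frequent non-reference base becomes the
    alternative allele; ties break in base order A < C < G < T.
    """
    thresholds = thresholds or CallingThresholds()
    records: list[AlleleCountRecord] = []
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise PileupParseError(f"line {line_no}: expected 6 columns, got {len(fields)}")
        chrom, pos_s, ref, depth_s, bases, quals = fields[:6]
        ref = ref.upper()
        if ref not in _BASES:
            raise PileupParseError(f"line {line_no}: invalid reference base {ref!r}")
        try:
            pos, depth_col = int(pos_s), int(depth_s)
        except ValueError as exc:
            raise PileupParseError(f"line {line_no}: non-integer pos/depth") from exc

        counts = dict.fromkeys(_BASES, 0)
        ref_count = other = below_q = 0
        i = qi = 0
        while i < len(bases):
            c = bases[i]
            if c == "^":
                i += 2  # caret is followed by a mapping-quality char
                continue
            if c == "$":
                i += 1
                continue
            if c in "+-":
                j = i + 1
                while j < len(bases) and bases[j].isdigit():
                    j += 1
                if j == i + 1:
                    raise PileupParseError(f"line {line_no}: bare '{c}' without indel length")
                i = j + int(bases[i + 1 : j])
                continue
            # every remaining symbol consumes one quality character
            if qi >= len(quals):
                raise PileupParseError(
                    f"line {line_no}: base string longer than quality string"
                )
            q = ord(quals[qi]) - 33
            qi += 1
            if q < thresholds.min_base_quality:
                below_q += 1
            elif c in ".,":
                ref_count += 1
            elif c.upper() in counts:
                if c.upper() == ref:
                    ref_count += 1
                else:
                    counts[c.upper()] += 1
            else:  # '*', '<', '>', 'N'
                other += 1
            i += 1
        if qi != len(quals):
            raise PileupParseError(
                f"line {line_no}: quality string longer than base string "
                f"({len(quals) - qi} unused)"
            )
        if ref_count + sum(counts.values()) + other + below_q != depth_col:
            raise PileupParseError(
                f"line {line_no}: parsed bases do not sum to depth column {depth_col}"
            )
        alt_base = None
        best = 0
        for b in _BASES:  # base order breaks ties deterministically
            if b != ref and counts[b] > best:
                alt_base, best = b, counts[b]
        other += sum(n for b, n in counts.items() if b != ref and b != alt_base)
        records.append(
            AlleleCountRecord(
                chrom=chrom,
                pos=pos,
                ref_base=ref,
                alt_base=alt_base,
                sample_id=sample_id,
                ref_count=ref_count,
                alt_count=best,
                other_count=other,
                below_quality=below_q,
            )
        )
    return records


def call_variant(
    record: AlleleCountRecord, thresholds: CallingThresholds | None = None
) -> Optional[VariantCall]:
    """Screen one record; returns a passing call or ``None``.

    Passing requires depth >= min_depth AND alt depth >= min_alt_depth AND
    alt/(ref+alt) frequency >= min_frequency.
    """
    thresholds = thresholds or CallingThresholds()
    if record.alt_base is None:
        return None
    passes = (
        record.depth >= thresholds.min_depth
        and record.alt_count >= thresholds.min_alt_depth
        and record.frequency >= thresholds.min_frequency
    )
    return VariantCall(record=record, passes=True) if passes else None


def screen_records(
    records: Iterable[AlleleCountRecord], thresholds: CallingThresholds | None = None
) -> list[VariantCall]:
    """Screen records keeping non-passing ones (with ``passes=False``).

    Downstream retention and per-sample editing-level summaries need the
    covered-but-non-passing samples too; `call_variant` is the strict
    pass-only view of the same screen.
    """
    thresholds = thresholds or CallingThresholds()
    out = []
    for r in records:
        out.append(VariantCall(record=r, passes=call_variant(r, thresholds) is not None))
    return out


def resolve_editing_type(
    ref_base: str, alt_base: str, gene_strand: Optional[str], strand_agnostic: bool = False
) -> bool:
    """True iff the mismatch is A-to-I given the gene strand.

    A>G on '+' or T>C on '-' (the reverse complement). With
    ``strand_agnostic=True`` an unknown strand accepts either orientation;
    callers should then flag the site as strand-unresolved.
    """
    if ref_base not in _BASES or alt_base not in _BASES:
        raise ValueError("invalid base")
    if gene_strand == "+":
        return ref_base == "A" and alt_base == "G"
    if gene_strand == "-":
        return ref_base == "T" and alt_base == "C"
    if strand_agnostic:
        return (ref_base, alt_base) in (("A", "G"), ("T", "C"))
    raise ValueError(f"unknown strand {gene_strand!r} (enable strand_agnostic to allow)")


def editing_level(ref_count: int, alt_count: int) -> float:
    """Editing level alt/(ref+alt); NaN when no informative reads."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("negative counts")
    denom = ref_count + alt_count
    return alt_count / denom if denom else math.nan


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def records_from_table(table: pd.DataFrame) -> list[AlleleCountRecord]:
    """Build records from a pre-counted allele TSV.

    Required columns: chrom, pos, ref, alt, sample_id, ref_count,
    alt_count; other_count is optional.
    """
    required = {"chrom", "pos", "ref", "alt", "sample_id", "ref_count", "alt_count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"allele table missing columns: {sorted(missing)}")
    has_other = "other_count" in table.columns
    return [
        AlleleCountRecord(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref_base=str(r.ref),
            alt_base=None if pd.isna(r.alt) else str(r.alt),
            sample_id=str(r.sample_id),
            ref_count=int(r.ref_count),
            alt_count=int(r.alt_count),
            other_count=int(r.other_count) if has_other else 0,
        )
        for r in table.itertuples()
    ]


def calls_to_frame(calls: Iterable[VariantCall]) -> pd.DataFrame:
    """Long-format call table (one row per passing site x sample)."""
    rows = []
    for c in calls:
        r = c.record
        rows.append(
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref_base,
                "alt": r.alt_base,
                "strand": c.strand if c.strand is not None else ".",
                "sample_id": r.sample_id,
                "ref_count": r.ref_count,
                "alt_count": r.alt_count,
                "other_count": r.other_count,
                "level": editing_level(r.ref_count, r.alt_count),
                "is_a_to_i": c.is_a_to_i,
                "passes": c.passes,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "strand", "sample_id",
            "ref_count", "alt_count", "other_count", "level", "is_a_to_i", "passes",
        ],
    )


def type_calls(
    calls: Iterable[VariantCall],
    strand_lookup,
) -> list[VariantCall]:
    """Resolve A-to-I identity for calls using a strand lookup.

    ``strand_lookup(chrom, pos)`` returns '+', '-', None (no overlapping
    gene) or 'ambiguous' (genes on both strands). Sites without a resolved
    strand are kept with ``is_a_to_i=None`` so they can be reported
    separately, per the strand-ambiguity policy.
    """
    typed = []
    for c in calls:
        r = c.record
        strand = strand_lookup(r.chrom, r.pos)
        if strand in ("+", "-") and r.alt_base is not None:
            flag = resolve_editing_type(r.ref_base, r.alt_base, strand)
        else:
            flag = None
        typed.append(replace(c, is_a_to_i=flag, strand=strand if strand in ("+", "-") else None))
    return typed
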