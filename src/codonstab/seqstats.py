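"""Coding-sequence composition statistics.

Reads and validates ORF FASTA files and computes the per-transcript summaries
the downstream stability statistics consume: length-normalized codon
frequencies in any of the three reading frames, translations, amino-acid
frequencies, GC/GC3 content, and homopolymeric amino-acid repeats.

Conventions
-----------
* Codonization is non-overlapping (width 3, step 3) and drops any trailing
  partial codon. Frames ``+1``/``+2`` skip one/two leading nucleotides first.
* Stop codons and codons containing N are excluded from codon-frequency
  numerators *and* denominators, so every profile lives on the same 61-codon
  simplex.
* Translation keeps internal stops as ``*`` and maps any N-containing codon
  to ``X``; amino-acid frequencies are taken over canonical residues plus the
  ``X`` fraction, excluding ``*``.
* Repeat coordinates are 1-based inclusive residue positions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import UndefinedProfileError, ValidationError
from .genetic_code import (
    AMINO_ACIDS,
    SENSE_CODONS,
    STOP_CODONS,
    is_gc3,
    translate_codon,
)

logger = logging.getLogger(__name__)

_VALID_NT = frozenset("ACGTN")

Frame = int  # one of 0, 1, 2


@dataclass(frozen=True)
class CodingSequence:
    """A validated ATG-initiated open reading frame.

    ``seq`` is an uppercase nucleotide string over {A,C,G,T,N}, at least one
    codon long. Construction does not require the ATG start (use
    :func:`read_cds_fasta` with ``require_atg=True`` for the filtered
    universe) so frameshifted and reporter sequences remain representable.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        if len(seq) < 3:
            raise ValidationError(f"{self.id}: sequence shorter than one codon")
        bad = set(seq) - _VALID_NT
        if bad:
            raise ValidationError(f"{self.id}: invalid nucleotides {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def codons(self, frame: Frame = 0) -> list[str]:
        """Non-overlapping triplets in the given frame; trailing partial dropped."""
        if frame not in (0, 1, 2):
            raise ValidationError(f"frame must be 0, 1 or 2, got {frame!r}")
        s = self.seq[frame:]
        return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]

    @property
    def starts_with_atg(self) -> bool:
        return self.seq.startswith("ATG")


@dataclass(frozen=True)
class CodonUsageProfile:
    """61 sense-codon frequencies of one transcript in one reading frame."""

    transcript_id: str
    frame: Frame
    freq: dict[str, float]

    def as_series(self) -> pd.Series:
        """Dense length-61 Series over :data:`SENSE_CODONS` (absent -> 0)."""
        return pd.Series(self.freq, index=list(SENSE_CODONS), dtype=float).fillna(0.0)


@dataclass(frozen=True)
class AminoAcidProfile:
    """Frequencies of the 20 canonical residues plus the unknown-X fraction."""

    transcript_id: str
    freq: dict[str, float]
    x_fraction: float = 0.0

    def as_series(self) -> pd.Series:
        return pd.Series(self.freq, index=list(AMINO_ACIDS), dtype=float).fillna(0.0)


@dataclass(frozen=True)
class RepeatRecord:
    """A maximal homopolymeric amino-acid run (1-based, inclusive start)."""

    gene_id: str
    amino_acid: str
    length: int
    start: int


@dataclass
class FastaReadReport:
    """Attrition bookkeeping for :func:`read_cds_fasta`."""

    n_input: int = 0
    n_retained: int = 0
    n_dropped_non_atg: int = 0
    n_collapsed_duplicates: int = 0


def read_cds_fasta(
    path: str | Path,
    require_atg: bool = True,
    longest_per_id: bool = True,
) -> tuple[list[CodingSequence], FastaReadReport]:
    """Load coding sequences from a (multi-)FASTA file.

    When ``longest_per_id`` is set, identifiers seen more than once keep only
    their longest sequence (ties broken by the lexicographically smallest
    sequence). When ``require_atg`` is set, records not starting with ATG are
    dropped and counted in the report. Input order of retained identifiers is
    preserved.
    """
    path = Path(path)
    report = FastaReadReport()
    by_id: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        report.n_input += 1
        seq = str(rec.seq).upper()
        if rec.id in by_id:
            report.n_collapsed_duplicates += 1
            old = by_id[rec.id]
            if (len(seq), seq) != (len(old), old):
                # longest wins; equal length -> lexicographically smallest
                if len(seq) > len(old) or (len(seq) == len(old) and seq < old):
                    by_id[rec.id] = seq
        else:
            by_id[rec.id] = seq
        if not longest_per_id and report.n_collapsed_duplicates:
            raise ValidationError(
                f"duplicate identifier {rec.id!r} with longest_per_id disabled"
            )

    records: list[CodingSequence] = []
    for tid, seq in by_id.items():
        if require_atg and not seq.startswith("ATG"):
            report.n_dropped_non_atg += 1
            continue
        records.append(CodingSequence(tid, seq))
    report.n_retained = len(records)
    if report.n_input and not records:
        warnings.warn(
            f"{path.name}: all {report.n_input} records removed by filtering",
            stacklevel=2,
        )
    logger.info(
        "%s: %d records read, %d retained (%d non-ATG dropped, %d duplicates collapsed)",
        path.name, report.n_input, report.n_retained,
        report.n_dropped_non_atg, report.n_collapsed_duplicates,
    )
    return records, report


def codon_frequencies(cds: CodingSequence, frame: Frame = 0) -> CodonUsageProfile:
    """Length-normalized sense-codon frequencies of one transcript.

    Stop codons and triplets containing N are left out of both numerator and
    denominator; frequencies over the counted codons sum to 1.
    """
    counts: dict[str, int] = {}
    total = 0
    for codon in cds.codons(frame):
        if codon in STOP_CODONS or "N" in codon:
            continue
        counts[codon] = counts.get(codon, 0) + 1
        total += 1
    if total == 0:
        raise UndefinedProfileError(
            f"{cds.id}: no countable sense codons in frame +{frame}"
        )
    return CodonUsageProfile(
        cds.id, frame, {c: n / total for c, n in sorted(counts.items())}
    )


def translate_cds(cds: CodingSequence, frame: Frame = 0) -> str:
    """Frame-0 (by default) translation with ``*`` for stops and ``X`` for
    N-containing codons; internal stops do not abort translation."""
    return "".join(translate_codon(c) for c in cds.codons(frame))


def aa_frequencies(protein: str, transcript_id: str = "") -> AminoAcidProfile:
    """Amino-acid frequencies of a translation.

    ``*`` is excluded from numerator and denominator; ``X`` counts toward the
    denominator and is reported separately, so the 20 canonical frequencies
    plus ``x_fraction`` sum to 1.
    """
    if not protein:
        raise UndefinedProfileError("empty protein string")
    counts: dict[str, int] = {}
    n_x = 0
    for aa in protein:
        if aa == "*":
            continue
        if aa == "X":
            n_x += 1
        elif aa in AMINO_ACIDS:
            counts[aa] = counts.get(aa, 0) + 1
        else:
            raise ValidationError(f"unexpected residue {aa!r}")
    total = sum(counts.values()) + n_x
    if sum(counts.values()) == 0:
        raise UndefinedProfileError(
            f"{transcript_id or protein[:10]}: no canonical residues to profile"
        )
    return AminoAcidProfile(
        transcript_id,
        {aa: n / total for aa, n in sorted(counts.items())},
        x_fraction=n_x / total,
    )


def composition_stats(cds: CodingSequence) -> tuple[float, float]:
    """Return ``(gc_content, gc3_frequency)`` of an ORF.

    GC content is (G+C)/(A+C+G+T) over the whole sequence (N ignored);
    GC3 is the fraction of frame-0 sense codons whose third base is G or C,
    with stop and N-containing codons excluded.
    """
    acgt = sum(cds.seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise UndefinedProfileError(f"{cds.id}: all-N sequence")
    gc = (cds.seq.count("G") + cds.seq.count("C")) / acgt
    sense = [c for c in cds.codons(0) if c not in STOP_CODONS and "N" not in c]
    if not sense:
        raise UndefinedProfileError(f"{cds.id}: no sense codons for GC3")
    gc3 = sum(is_gc3(c) for c in sense) / len(sense)
    return gc, gc3


def find_homopolymer_repeats(
    protein: str, gene_id: str = "", min_length: int = 5
) -> list[RepeatRecord]:
    """All maximal runs of >= ``min_length`` identical canonical residues.

    Runs are maximal in both directions; ``*``/``X`` break runs and never form
    them. Positions are 1-based residue coordinates.
    """
    if not protein:
        raise ValidationError("empty protein string")
    out: list[RepeatRecord] = []
    i = 0
    n = len(protein)
    while i < n:
        j = i
        while j < n and protein[j] == protein[i]:
            j += 1
        if protein[i] in AMINO_ACIDS and j - i >= min_length:
            out.append(RepeatRecord(gene_id, protein[i], j - i, i + 1))
        i = j
    return out


def longest_repeat_per_gene(records: Iterable[RepeatRecord]) -> list[RepeatRecord]:
    """Per (gene, amino acid), keep only the longest run; ties keep the first
    (smallest start) occurrence."""
    best: dict[tuple[str, str], RepeatRecord] = {}
    for rec in records:
        key = (rec.gene_id, rec.amino_acid)
        cur = best.get(key)
        if cur is None or rec.length > cur.length or (
            rec.length == cur.length and rec.start < cur.start
        ):
            best[key] = rec
    return sorted(best.values(), key=lambda r: (r.gene_id, r.amino_acid))


def profiles_frame(profiles: Iterable[CodonUsageProfile]) -> pd.DataFrame:
    """Stack codon profiles into a transcripts x 61 DataFrame (absent -> 0)."""
    rows = {p.transcript_id: p.as_series() for p in profiles}
    return pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=list(SENSE_CODONS), fill_value=0.0
    )


def aa_profiles_frame(profiles: Iterable[AminoAcidProfile]) -> pd.DataFrame:
    """Stack amino-acid profiles into a transcripts x 20 DataFrame."""
    rows = {p.transcript_id: p.as_series() for p in profiles}
    return pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=list(AMINO_ACIDS), fill_value=0.0
    )


def profile_transcriptome(
    records: Sequence[CodingSequence], frame: Frame = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Codon- and amino-acid-frequency matrices for a set of ORFs.

    Amino-acid profiles always come from the frame-0 translation regardless of
    the codon frame, matching how frameshifted codon statistics are compared
    against in-frame protein composition.
    """
    codon_rows = []
    aa_rows = []
    for cds in records:
        codon_rows.append(codon_frequencies(cds, frame))
        aa_rows.append(aa_frequencies(translate_cds(cds), cds.id))
    return profiles_frame(codon_rows), aa_profiles_frame(aa_rows)
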