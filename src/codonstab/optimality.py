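"""Codon optimality from tRNA-seq: tAI computation and reporter design.

The tRNA adaptation index (tAI) of a codon summarizes the availability of the
tRNAs able to decode it. Per-anticodon read abundances (reads per million,
aggregated over isodecoder genes) are combined over the decoding anticodons
with wobble-pairing penalties::

    W(codon) = sum over decoding anticodons a of (1 - s[pair]) * RPM(a)
    tAI(codon) = W(codon) / max W

Codons with tAI strictly greater than the median of the 61 sense-codon values
are classified *optimal*; all others (including a codon exactly at the
median) are *non-optimal*.

The default wobble penalties are the classical selective-constraint values
(G:U 0.41, I:C 0.28, I:A 0.9999, U:G 0.68); ATG and TGG are decoded only by
their Watson-Crick anticodons since no other elongator tRNA reads them.
Selenocysteine and initiator-methionine tRNA genes must be excluded from the
counts and are recognized by substring match on the gene identifier.

The reporter designer re-encodes an ORF to a requested percent-optimal by
randomly flipping synonymous codons across the optimality boundary, leaving
every non-flipped codon untouched — maximizing sequence similarity between
variants of the same protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, UnreachableTargetError, ValidationError
from .genetic_code import (
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    SYNONYMOUS_CODONS,
    reverse_complement,
)
from .seqstats import CodingSequence

#: Wobble penalty s for each codon:anticodon third-position pairing class.
#: Keys name the codon base then the (unmodified) anticodon wobble base;
#: A34 anticodons are assumed inosine-modified (I:U treated as cognate).
DEFAULT_WOBBLE_PENALTIES: dict[str, float] = {
    "T:G": 0.41,    # G:U wobble
    "C:A": 0.28,    # I:C
    "A:A": 0.9999,  # I:A
    "G:T": 0.68,    # U:G
}

#: Codons read only by their Watson-Crick anticodon (no elongator wobble).
_WC_ONLY = frozenset({"ATG", "TGG"})

_EXCLUDED_GENE_PATTERNS = ("sec", "imet", "selcys")


def decoding_anticodons(
    codon: str, penalties: Mapping[str, float] | None = None
) -> list[tuple[str, float]]:
    """(anticodon, 1 - s) pairs able to read ``codon`` under the wobble model."""
    penalties = DEFAULT_WOBBLE_PENALTIES if penalties is None else penalties
    wc = reverse_complement(codon)
    pairs = [(wc, 1.0)]
    if codon not in _WC_ONLY:
        for key, s in penalties.items():
            codon_base, anticodon_base = key.split(":")
            if codon[2] == codon_base:
                wobble = anticodon_base + wc[1:]
                if wobble != wc and reverse_complement(wobble) not in STOP_CODONS:
                    pairs.append((wobble, 1.0 - s))
    return pairs


@dataclass(frozen=True)
class TAITable:
    """Per-codon tAI values with the median-rule optimality calls."""

    tai: pd.Series          # index: 61 sense codons, max value 1.0
    median: float
    optimal: pd.Series      # boolean, tai > median

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tai": self.tai, "optimal": self.optimal})

    @classmethod
    def from_values(cls, tai: Mapping[str, float] | pd.Series) -> "TAITable":
        """Build a table from externally supplied tAI values (e.g. published
        vectors), applying the same scale normalization and median rule."""
        s = pd.Series(tai, dtype=float).reindex(list(SENSE_CODONS))
        if s.isna().any():
            missing = list(s.index[s.isna()])
            raise ValidationError(f"tAI vector missing codons: {missing[:5]}...")
        if s.max() <= 0:
            raise DegenerateInputError("tAI vector has no positive entries")
        s = s / s.max()
        med = float(s.median())
        return cls(tai=s, median=med, optimal=s > med)


def read_trna_counts(path) -> pd.DataFrame:
    """Read a TSV of per-gene tRNA-seq counts (gene, anticodon, count)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "anticodon": str})
    return validate_trna_counts(df)


def validate_trna_counts(counts: pd.DataFrame) -> pd.DataFrame:
    required = {"gene", "anticodon", "count"}
    missing = required - set(counts.columns)
    if missing:
        raise ValidationError(f"tRNA count table missing columns {sorted(missing)}")
    bad = ~counts["anticodon"].str.fullmatch("[ACGT]{3}")
    if bad.any():
        raise ValidationError(
            f"invalid anticodons: {sorted(counts.loc[bad, 'anticodon'].unique())}"
        )
    if (counts["count"] < 0).any():
        raise ValidationError("negative read counts")
    return counts


def tai_from_counts(
    counts: pd.DataFrame,
    wobble_penalties: Mapping[str, float] | None = None,
    exclude_gene_patterns: Iterable[str] = _EXCLUDED_GENE_PATTERNS,
) -> TAITable:
    """Compute the per-codon tAI table from per-gene tRNA-seq read counts.

    Genes whose identifier contains any of ``exclude_gene_patterns``
    (case-insensitive; default Sec/iMet) are removed, counts are aggregated by
    anticodon and converted to reads per million, and codon weights are summed
    over decoding anticodons with wobble penalties. Scale-invariant in the
    total depth.
    """
    counts = validate_trna_counts(counts)
    patterns = tuple(p.lower() for p in exclude_gene_patterns)
    keep = ~counts["gene"].str.lower().str.contains("|".join(patterns), regex=True)
    counts = counts[keep]
    total = counts["count"].sum()
    if total <= 0:
        raise DegenerateInputError("all tRNA read counts are zero after exclusions")
    rpm = counts.groupby("anticodon")["count"].sum() * 1e6 / total

    w = pd.Series(0.0, index=list(SENSE_CODONS))
    for codon in SENSE_CODONS:
        w[codon] = sum(
            weight * rpm.get(anticodon, 0.0)
            for anticodon, weight in decoding_anticodons(codon, wobble_penalties)
        )
    if w.max() <= 0:
        raise DegenerateInputError("no codon is decoded by any observed anticodon")
    tai = w / w.max()
    med = float(tai.median())
    return TAITable(tai=tai, median=med, optimal=tai > med)


def classify_optimal(tai: TAITable) -> dict[str, str]:
    """Map each of the 61 sense codons to ``"optimal"``/``"non-optimal"``.

    Strictly-greater-than-median is optimal; a codon exactly at the median is
    non-optimal.
    """
    return {
        codon: ("optimal" if bool(tai.optimal[codon]) else "non-optimal")
        for codon in SENSE_CODONS
    }


def percent_optimal(cds: CodingSequence, tai: TAITable) -> float:
    """Percent of frame-0 sense codons classified optimal (0-100 scale)."""
    sense = [c for c in cds.codons(0) if c not in STOP_CODONS and "N" not in c]
    if not sense:
        raise ValidationError(f"{cds.id}: no sense codons")
    n_opt = sum(bool(tai.optimal[c]) for c in sense)
    return 100.0 * n_opt / len(sense)


def _flippable_split(tai: TAITable) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Per amino acid, the optimal and non-optimal synonym lists."""
    opt: dict[str, list[str]] = {}
    non: dict[str, list[str]] = {}
    for aa, codons in SYNONYMOUS_CODONS.items():
        opt[aa] = [c for c in codons if bool(tai.optimal[c])]
        non[aa] = [c for c in codons if not bool(tai.optimal[c])]
    return opt, non


def optimality_bounds(cds: CodingSequence, tai: TAITable) -> tuple[float, float]:
    """Theoretical (min, max) percent-optimal for the protein encoded by
    ``cds``: amino acids with single-sided synonym sets pin the bounds."""
    opt, non = _flippable_split(tai)
    sense = [c for c in cds.codons(0) if c not in STOP_CODONS and "N" not in c]
    if not sense:
        raise ValidationError(f"{cds.id}: no sense codons")
    n = len(sense)
    n_max = sum(1 for c in sense if opt[CODON_TO_AA[c]])
    n_min = sum(1 for c in sense if not non[CODON_TO_AA[c]])
    return 100.0 * n_min / n, 100.0 * n_max / n


def flip_to_target_optimality(
    cds: CodingSequence, tai: TAITable, target: float, seed: int
) -> CodingSequence:
    """Design a synonymous variant of ``cds`` with ~``target`` percent-optimal.

    Candidate positions (codons whose amino acid has synonyms on the needed
    side of the median) are shuffled once with the seeded generator and
    consumed until the realized percent crosses the target; the walk stops on
    whichever side of the target is nearer, so the result is within half a
    flip (one codon) of the request. Each flipped codon's replacement is drawn
    uniformly among the synonyms on the desired side; all other codons are
    untouched, so the translation is preserved exactly.
    """
    lo, hi = optimality_bounds(cds, tai)
    if not (lo - 1e-9 <= target <= hi + 1e-9):
        raise UnreachableTargetError(target, lo, hi)

    codons = cds.codons(0)
    sense_idx = [
        i for i, c in enumerate(codons) if c not in STOP_CODONS and "N" not in c
    ]
    n = len(sense_idx)
    opt_syn, non_syn = _flippable_split(tai)
    is_opt = {i: bool(tai.optimal[codons[i]]) for i in sense_idx}
    current = 100.0 * sum(is_opt.values()) / n

    rng = np.random.default_rng(seed)
    if current < target:
        direction, syn_pool = +1, opt_syn
        candidates = [i for i in sense_idx if not is_opt[i] and opt_syn[CODON_TO_AA[codons[i]]]]
    else:
        direction, syn_pool = -1, non_syn
        candidates = [i for i in sense_idx if is_opt[i] and non_syn[CODON_TO_AA[codons[i]]]]
    rng.shuffle(candidates)

    step = 100.0 / n
    for i in candidates:
        if abs(current - target) <= step / 2:
            break
        nxt = current + direction * step
        # stop on whichever side of the target is nearer
        if abs(nxt - target) > abs(current - target):
            break
        pool = syn_pool[CODON_TO_AA[codons[i]]]
        codons[i] = pool[int(rng.integers(len(pool)))]
        current = nxt

    return CodingSequence(cds.id, "".join(codons))
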