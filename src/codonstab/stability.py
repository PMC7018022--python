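"""Codon and amino-acid stabilization coefficients (CSC / AASC).

A CSC is the Pearson correlation, across transcripts, between a codon's
length-normalized frequency and mRNA half-life; the AASC is the analogous
correlation for amino-acid frequency. Coefficients are reported with two-sided
p-values, Fisher-z 95% confidence intervals, a significance tier (stabilizing
/ destabilizing at p below a configurable threshold) and a genome-wide flag
(p < 5e-8). A codon whose frequency has zero variance across the joined
transcripts yields an NA coefficient, never a silent zero.

Transcript-level scores are frequency-weighted sums of the per-codon (per
amino acid) coefficients over a transcript's ORF; NA coefficients are dropped
with the remaining weights renormalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UndefinedProfileError, ValidationError
from .genetic_code import AMINO_ACIDS, CODON_TO_AA, SENSE_CODONS, SYNONYMOUS_CODONS
from .seqstats import AminoAcidProfile, CodonUsageProfile

logger = logging.getLogger(__name__)

GENOME_WIDE_ALPHA = 5e-8


def read_halflife_table(path) -> pd.DataFrame:
    """Read a TSV half-life table (transcript_id, half_life in hours)."""
    df = pd.read_csv(path, sep="\t")
    return validate_halflife_table(df)


def validate_halflife_table(halflives: pd.DataFrame) -> pd.DataFrame:
    required = {"transcript_id", "half_life"}
    missing = required - set(halflives.columns)
    if missing:
        raise ValidationError(f"half-life table missing columns {sorted(missing)}")
    if (halflives["half_life"] <= 0).any():
        raise ValidationError("half-lives must be positive")
    return halflives


def _pearson_with_ci(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Pearson r, two-sided p, and Fisher-z 95% CI; NaNs when x is constant."""
    n = len(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    if n > 3 and abs(r) < 1:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    else:
        lo = hi = np.nan
    return r, p, lo, hi


def _correlation_table(
    freq: pd.DataFrame,
    halflives: pd.DataFrame,
    columns: list[str],
    coef_name: str,
    alpha: float,
) -> pd.DataFrame:
    hl = validate_halflife_table(halflives).set_index("transcript_id")["half_life"]
    common = freq.index.intersection(hl.index)
    n_dropped = (len(freq) - len(common)) + (len(hl) - len(common))
    if n_dropped:
        logger.info(
            "%s: %d transcripts dropped by inner join (%d retained)",
            coef_name, n_dropped, len(common),
        )
    if len(common) < 3:
        raise InsufficientDataError(
            f"only {len(common)} transcripts shared between profiles and half-lives"
        )
    y = hl.loc[common].to_numpy(dtype=float)
    x_mat = freq.loc[common, columns].to_numpy(dtype=float)

    rows = []
    for j, col in enumerate(columns):
        r, p, lo, hi = _pearson_with_ci(x_mat[:, j], y)
        if np.isnan(r):
            tier = "na"
        elif p < alpha:
            tier = "stabilizing" if r > 0 else "destabilizing"
        else:
            tier = "ns"
        rows.append(
            {
                coef_name: r,
                "p_value": p,
                "ci_low": lo,
                "ci_high": hi,
                "tier": tier,
                "genome_wide": bool(p < GENOME_WIDE_ALPHA) if not np.isnan(r) else False,
            }
        )
    out = pd.DataFrame(rows, index=pd.Index(columns))
    out.attrs["n_transcripts"] = len(common)
    return out


def compute_csc(
    profiles: "list[CodonUsageProfile] | pd.DataFrame",
    halflives: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Codon stability coefficients for all 61 non-stop codons.

    ``profiles`` is either a list of :class:`CodonUsageProfile` or an already
    stacked transcripts x 61 frequency DataFrame. Returns a 61-row DataFrame
    indexed by codon with columns ``csc, p_value, ci_low, ci_high, tier,
    genome_wide``; the joined transcript count is in ``.attrs["n_transcripts"]``.
    """
    from .seqstats import profiles_frame

    freq = profiles if isinstance(profiles, pd.DataFrame) else profiles_frame(profiles)
    return _correlation_table(freq, halflives, list(SENSE_CODONS), "csc", alpha)


def compute_aasc(
    profiles: "list[AminoAcidProfile] | pd.DataFrame",
    halflives: pd.DataFrame,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Amino-acid stabilization coefficients (20 rows, same columns as CSC).

    The default significance threshold is 0.001 (the amino-acid analyses use a
    stricter tier than the 0.01 used for codons); pass ``alpha`` to override.
    """
    from .seqstats import aa_profiles_frame

    freq = profiles if isinstance(profiles, pd.DataFrame) else aa_profiles_frame(profiles)
    return _correlation_table(freq, halflives, list(AMINO_ACIDS), "aasc", alpha)


@dataclass(frozen=True)
class TranscriptScore:
    """Frequency-weighted average CSC and AASC of one transcript."""

    transcript_id: str
    avg_csc: float
    avg_aasc: float
    gc3_frequency: float | None = None
    gc_content: float | None = None
    n_excluded_codon_terms: int = 0
    n_excluded_aa_terms: int = 0


def _weighted_average(freq: pd.Series, coef: pd.Series) -> tuple[float, int]:
    """Sum(freq * coef) with NA coefficients excluded and weights renormalized."""
    valid = coef.notna()
    n_excluded = int((~valid & (freq > 0)).sum())
    w = freq[valid]
    total = w.sum()
    if total <= 0:
        raise UndefinedProfileError("all applicable coefficients are NA")
    return float((w * coef[valid]).sum() / total), n_excluded


def transcript_average_score(
    profile: CodonUsageProfile,
    aa_profile: AminoAcidProfile,
    csc: pd.DataFrame,
    aasc: pd.DataFrame,
    gc3_frequency: float | None = None,
    gc_content: float | None = None,
) -> TranscriptScore:
    """Transcript-level average CSC and AASC.

    avg_csc = sum over the 61 codons of freq * CSC, and analogously for the 20
    amino acids. NA coefficients are excluded with the remaining weights
    renormalized; the number of excluded nonzero-frequency terms is reported.
    Frame-0 profiles are expected.
    """
    if profile.frame != 0:
        raise ValidationError("transcript scores are defined on frame-0 profiles")
    avg_csc, nc = _weighted_average(profile.as_series(), csc["csc"])
    aa_freq = aa_profile.as_series()
    avg_aasc, na = _weighted_average(aa_freq, aasc["aasc"])
    return TranscriptScore(
        profile.transcript_id, avg_csc, avg_aasc,
        gc3_frequency, gc_content, nc, na,
    )


def transcript_scores_table(
    records,
    csc: pd.DataFrame,
    aasc: pd.DataFrame,
) -> pd.DataFrame:
    """Per-transcript score table (avg_csc, avg_aasc, gc3_frequency,
    gc_content) for a collection of coding sequences."""
    from .seqstats import aa_frequencies, codon_frequencies, composition_stats, translate_cds

    rows = []
    for cds in records:
        gc, gc3 = composition_stats(cds)
        score = transcript_average_score(
            codon_frequencies(cds, 0),
            aa_frequencies(translate_cds(cds), cds.id),
            csc, aasc, gc3_frequency=gc3, gc_content=gc,
        )
        rows.append(
            {
                "transcript_id": score.transcript_id,
                "avg_csc": score.avg_csc,
                "avg_aasc": score.avg_aasc,
                "gc3_frequency": gc3,
                "gc_content": gc,
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")


@dataclass(frozen=True)
class EffectPartition:
    """Amino acids (and their codons) split by effect size on stability."""

    extreme_aas: frozenset[str]
    moderate_aas: frozenset[str]
    extreme_codons: tuple[str, ...]
    moderate_codons: tuple[str, ...]


def amino_acid_effect_partition(
    aasc: pd.DataFrame,
    effect_threshold: float = 0.10,
    p_threshold: float = 1e-30,
) -> EffectPartition:
    """Split amino acids into *extreme* (|AASC| > 0.10 and p < 1e-30) and
    *moderate* (everything else); codons inherit their amino acid's class."""
    extreme = frozenset(
        aa
        for aa in AMINO_ACIDS
        if pd.notna(aasc.loc[aa, "aasc"])
        and abs(aasc.loc[aa, "aasc"]) > effect_threshold
        and aasc.loc[aa, "p_value"] < p_threshold
    )
    moderate = frozenset(AMINO_ACIDS) - extreme
    return EffectPartition(
        extreme_aas=extreme,
        moderate_aas=moderate,
        extreme_codons=tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] in extreme),
        moderate_codons=tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] in moderate),
    )


def count_exclusive_amino_acids(csc: pd.DataFrame) -> int:
    """Number of multi-codon amino acids whose synonymous CSCs all share a
    strict sign (all > 0 or all < 0); NA or exactly-zero CSCs disqualify."""
    count = 0
    for aa, codons in SYNONYMOUS_CODONS.items():
        if len(codons) < 2:
            continue
        values = csc.loc[list(codons), "csc"]
        if values.isna().any() or (values == 0).any():
            continue
        if (values > 0).all() or (values < 0).all():
            count += 1
    return count
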