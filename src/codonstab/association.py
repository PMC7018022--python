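"""Downstream association statistics.

Covers the statistical readouts layered on top of the stability
coefficients: the GC3-versus-optimality Fisher exact test, the reciprocal
transform and the linear model of transformed half-lives on transcript
scores, codon-level models of CSC against tRNA availability and free
amino-acid concentration, covariate-binned half-life stratification
(Kruskal-Wallis), and two-group rank-sum comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    InsufficientDataError,
    RankDeficiencyError,
    ValidationError,
)
from .genetic_code import CODON_TO_AA, SENSE_CODONS, is_gc3
from .optimality import TAITable
from .stability import EffectPartition, validate_halflife_table

#: Amino acids excluded from free-concentration models (NA or outlier assay
#: values in the lysate measurements): cysteine and glutamate.
DEFAULT_FREE_AA_EXCLUSIONS = frozenset({"C", "E"})


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_value: float
    table: pd.DataFrame  # 2x2 counts: rows GC3/AT3, columns optimal/non-optimal


def fisher_gc3_vs_optimality(tai: TAITable) -> FisherResult:
    """Two-sided Fisher exact test of GC3 identity against optimality calls.

    Builds the 2x2 contingency of the 61 sense codons (GC3/AT3 x optimal/
    non-optimal) and tests association by conditional hypergeometric
    enumeration.
    """
    rows = {"GC3": [0, 0], "AT3": [0, 0]}
    for codon in SENSE_CODONS:
        key = "GC3" if is_gc3(codon) else "AT3"
        rows[key][0 if bool(tai.optimal[codon]) else 1] += 1
    table = pd.DataFrame(rows, index=["optimal", "non-optimal"]).T
    odds, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
    return FisherResult(float(odds), float(p), table)


def reciprocal_transform(halflives: "pd.DataFrame | pd.Series | np.ndarray"):
    """Map half-lives to -1/x (monotone increasing, all-negative), the
    transform that symmetrizes a right-skewed half-life distribution for
    linear modeling."""
    if isinstance(halflives, pd.DataFrame):
        values = validate_halflife_table(halflives)["half_life"]
        return -1.0 / values
    arr = halflives if isinstance(halflives, pd.Series) else np.asarray(halflives, float)
    if (np.asarray(arr) <= 0).any():
        raise ValidationError("half-lives must be positive for -1/x transform")
    return -1.0 / arr


@dataclass(frozen=True)
class ModelFit:
    """OLS summary in the layout of the printed model tables."""

    params: pd.DataFrame  # index: term; columns: beta, ci_low, ci_high, p_value
    adj_r_squared: float
    overall_p: float
    n: int

    def __repr__(self) -> str:  # compact, table-like
        lines = [f"ModelFit(n={self.n}, adj_R2={self.adj_r_squared:.4f}, "
                 f"overall_p={self.overall_p:.3g})"]
        lines.append(self.params.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def _ols(y: pd.Series, X: pd.DataFrame) -> ModelFit:
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise RankDeficiencyError(f"regressor {col!r} is constant")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.to_numpy(), 0.0)
        worst = corr.stack().idxmax()
        raise RankDeficiencyError(f"collinear regressors, e.g. {worst}")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)
    params = pd.DataFrame(
        {
            "beta": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p_value": fit.pvalues,
        }
    ).rename(index={"const": "(Intercept)"})
    return ModelFit(params, float(fit.rsquared_adj), float(fit.f_pvalue), int(fit.nobs))


def fit_halflife_model(
    scores: pd.DataFrame, halflives: pd.DataFrame
) -> ModelFit:
    """OLS of -1/half-life on transcript average CSC and GC3 frequency.

    ``scores`` is the per-transcript table from
    :func:`codonstab.stability.transcript_scores_table` (columns ``avg_csc``
    and ``gc3_frequency``); the response is the reciprocal-transformed
    half-life after an inner join on transcript id.
    """
    hl = validate_halflife_table(halflives).set_index("transcript_id")["half_life"]
    common = scores.index.intersection(hl.index)
    if len(common) < 10:
        raise InsufficientDataError(f"only {len(common)} transcripts after join")
    y = reciprocal_transform(hl.loc[common])
    X = scores.loc[common, ["avg_csc", "gc3_frequency"]].rename(
        columns={"avg_csc": "Transcript Average CSC",
                 "gc3_frequency": "GC3 Codon Frequency"}
    )
    return _ols(y, X)


def validate_free_aa_table(free_aa: pd.DataFrame) -> pd.DataFrame:
    required = {"amino_acid", "concentration"}
    missing = required - set(free_aa.columns)
    if missing:
        raise ValidationError(f"free amino-acid table missing columns {sorted(missing)}")
    if (free_aa["concentration"] <= 0).any():
        raise ValidationError("free amino-acid concentrations must be positive")
    return free_aa


def fit_csc_model(
    csc: pd.DataFrame,
    tai: TAITable,
    free_aa: pd.DataFrame,
    codon_subset: str = "all",
    partition: EffectPartition | None = None,
    exclusions: frozenset[str] = DEFAULT_FREE_AA_EXCLUSIONS,
) -> ModelFit:
    """Codon-level OLS of CSC on tAI and free amino-acid concentration.

    ``codon_subset`` selects ``"all"``, ``"moderate"`` or ``"extreme"`` codons
    (the latter two need ``partition`` from
    :func:`codonstab.stability.amino_acid_effect_partition`). Codons encoding
    the excluded amino acids (default Cys/Glu) are removed first, so with a
    HeLa-like six-amino-acid extreme set the three subsets have 57, 38 and 19
    rows. ``free_aa`` has columns ``amino_acid`` and ``concentration``
    (relative to glycine); each codon carries its amino acid's concentration.
    """
    free = validate_free_aa_table(free_aa).set_index("amino_acid")["concentration"]
    if codon_subset == "all":
        codons = [c for c in SENSE_CODONS]
    elif codon_subset in ("moderate", "extreme"):
        if partition is None:
            raise ValidationError("codon_subset requires an EffectPartition")
        codons = list(
            partition.moderate_codons if codon_subset == "moderate"
            else partition.extreme_codons
        )
    else:
        raise ValidationError(f"unknown codon_subset {codon_subset!r}")
    codons = [c for c in codons if CODON_TO_AA[c] not in exclusions]
    missing_aa = {CODON_TO_AA[c] for c in codons} - set(free.index)
    if missing_aa:
        raise ValidationError(f"free amino-acid table lacks {sorted(missing_aa)}")
    if len(codons) < 3:
        raise InsufficientDataError(f"{len(codons)} codons in subset {codon_subset!r}")

    frame = pd.DataFrame(
        {
            "csc": csc.loc[codons, "csc"],
            "tAI": tai.tai[codons],
            "[Free amino acid]": [free[CODON_TO_AA[c]] for c in codons],
        },
        index=codons,
    ).dropna()
    if len(frame) < 3:
        raise InsufficientDataError("fewer than 3 codons with defined CSC")
    return _ols(frame["csc"], frame[["tAI", "[Free amino acid]"]])


@dataclass(frozen=True)
class StratificationResult:
    bins: pd.DataFrame         # per bin: n, median, q1, q3, lo_edge, hi_edge
    statistic: float           # Kruskal-Wallis H
    p_value: float


def stratify_halflives(
    halflives: pd.DataFrame,
    covariate: pd.Series,
    bin_edges: Sequence[float] | None = None,
    n_bins: int = 5,
) -> StratificationResult:
    """Bin half-lives by a per-transcript covariate and test for an overall
    difference with the Kruskal-Wallis rank test.

    Default bins are ``n_bins`` fixed-width intervals over the covariate's
    observed range; explicit ``bin_edges`` override. Empty bins are dropped;
    at least two nonempty bins are required.
    """
    hl = validate_halflife_table(halflives).set_index("transcript_id")["half_life"]
    common = hl.index.intersection(covariate.index)
    hl, cov = hl.loc[common], covariate.loc[common]
    if bin_edges is None:
        bin_edges = np.linspace(cov.min(), cov.max(), n_bins + 1)
    if len(np.unique(bin_edges)) < 3:
        raise InsufficientDataError("stratification needs >= 2 nonempty bins")
    labels = pd.cut(cov, bins=np.unique(bin_edges), include_lowest=True)
    groups = [hl[labels == interval] for interval in labels.cat.categories]
    rows = [
        {
            "bin": str(interval),
            "lo_edge": interval.left,
            "hi_edge": interval.right,
            "n": len(g),
            "median": g.median(),
            "q1": g.quantile(0.25),
            "q3": g.quantile(0.75),
        }
        for interval, g in zip(labels.cat.categories, groups)
        if len(g) > 0
    ]
    nonempty = [g for g in groups if len(g) > 0]
    if len(nonempty) < 2:
        raise InsufficientDataError("stratification needs >= 2 nonempty bins")
    h, p = stats.kruskal(*nonempty)
    return StratificationResult(pd.DataFrame(rows), float(h), float(p))


@dataclass(frozen=True)
class GroupComparison:
    median_a: float
    median_b: float
    median_difference: float  # A - B
    n_a: int
    n_b: int
    p_value: float


def compare_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_max_n: int = 20,
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two samples.

    Uses exact enumeration when both groups are small (n <= ``exact_max_n``)
    and tie-free, otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be nonempty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= exact_max_n and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        float(np.median(a)), float(np.median(b)),
        float(np.median(a) - np.median(b)), len(a), len(b), float(res.pvalue),
    )


def impute_max_halflife(
    halflives: pd.DataFrame,
    transcript_ids: Iterable[str],
    value: float = 24.0,
) -> pd.DataFrame:
    """Append transcripts that passed depth filters but failed model fitting
    due to high stability, at an assigned ceiling half-life (default 24 h).

    An explicit, logged imputation used before gene-group comparisons so that
    very stable transcripts (e.g. cytoplasmic ribosomal proteins) are not
    silently missing from the stable tail. Ids already present are left
    unchanged.
    """
    hl = validate_halflife_table(halflives)
    present = set(hl["transcript_id"])
    new = [tid for tid in transcript_ids if tid not in present]
    if not new:
        return hl.copy()
    extra = pd.DataFrame({"transcript_id": new, "half_life": value})
    return pd.concat([hl, extra], ignore_index=True)
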