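"""Synthetic data with known truth for every pipeline stage.

Generates a miniature transcriptome and the measurements the analysis
consumes — half-lives with planted composition effects, spike-in-distorted
decay timecourses, and tRNA-seq counts consistent with a known tAI vector —
together with a truth manifest, so parameter recovery can be asserted without
any external download.

Generative model
----------------
* **Transcriptome**: each ORF starts with ATG and continues with codons drawn
  i.i.d. from a per-transcript composition sampled from a Dirichlet over the
  61 sense codons; only sense codons are drawn, so frame-0 has no internal
  stops and length is divisible by 3. Lengths (in codons) are lognormal.
* **Half-lives**: log half-life is linear in the transcript's observed codon
  and amino-acid frequencies plus Gaussian noise, then scaled to a target
  median — guaranteeing positivity and the right skew seen in real half-life
  distributions. With planted per-codon effects this makes CSC sign recovery
  a well-defined ground truth.
* **Timecourse**: true abundance decays exponentially at the clearance rate
  plus the growth-dilution rate ln2/doubling_time; per-timepoint spike-in
  distortion is applied inversely so spike-in normalization can undo it;
  multiplicative lognormal noise comes last.
* **tRNA counts**: nonnegative anticodon abundances reproducing the requested
  tAI vector under the wobble model are found by nonnegative least squares,
  then read counts are drawn multinomially at the requested depth and split
  across two isodecoder genes per anticodon (plus Sec/iMet decoy genes that
  the tAI computation must ignore).

All randomness derives from ``config.seed``; every generator uses its own
fixed stream (NumPy PCG64 via ``default_rng([seed, stream])``) so outputs are
reproducible individually and jointly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import FeasibilityError, ValidationError
from .genetic_code import SENSE_CODONS
from .optimality import DEFAULT_WOBBLE_PENALTIES, decoding_anticodons
from .seqstats import (
    CodingSequence,
    aa_frequencies,
    aa_profiles_frame,
    codon_frequencies,
    profiles_frame,
    translate_cds,
)

LN2 = math.log(2.0)

_STREAM_TRANSCRIPTOME = 1
_STREAM_HALFLIFE = 2
_STREAM_TIMECOURSE = 3
_STREAM_TRNA = 4
_STREAM_TAI = 5


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the assumed conditions.

    ``beta_codon``/``beta_aa`` plant log-linear composition effects on
    half-life (units: change in log half-life per unit frequency);
    ``codon_alpha`` is the symmetric Dirichlet concentration controlling
    between-transcript codon-usage variability (smaller = more variable);
    timecourse settings follow a 10-timepoint, 12-hour chase in cells
    doubling every 15 h.
    """

    n_transcripts: int = 200
    seed: int = 0
    # sequence composition
    length_log_mean: float = math.log(350.0)   # codons
    length_log_sigma: float = 0.45
    min_length_codons: int = 30
    codon_alpha: float = 2.0
    # half-life model
    beta_codon: dict[str, float] = field(default_factory=dict)
    beta_aa: dict[str, float] = field(default_factory=dict)
    halflife_sigma: float = 0.3
    median_halflife: float = 4.0               # hours
    # timecourse
    timepoints: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0)
    doubling_time: float = 15.0                # hours
    spike_log_sigma: float = 0.2
    noise_sigma: float = 0.1
    t0_fpkm_log_mean: float = math.log(30.0)
    t0_fpkm_log_sigma: float = 1.0
    total_reads: float = 2e7
    spike_fraction: float = 0.01
    # tRNA-seq
    trna_depth: int = 1_000_000
    trna_decoy_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.n_transcripts < 3:
            raise ValidationError("n_transcripts must be >= 3")
        for name in ("halflife_sigma", "spike_log_sigma", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        unknown = set(self.beta_codon) - set(SENSE_CODONS)
        if unknown:
            raise ValidationError(f"beta_codon for non-sense codons: {sorted(unknown)}")


@dataclass
class TruthManifest:
    """Ground truth recorded alongside the generated artifacts."""

    config: SimulationConfig
    codon_freq: pd.DataFrame | None = None     # observed frame-0 frequencies
    aa_freq: pd.DataFrame | None = None
    eta: pd.Series | None = None               # linear predictor of log half-life
    half_life: pd.Series | None = None         # hours
    decay_rate: pd.Series | None = None        # ln2 / half_life
    spike_factors: pd.Series | None = None     # relative to t0
    t0_fpkm: pd.Series | None = None
    true_tai: pd.Series | None = None
    anticodon_abundance: pd.Series | None = None


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_transcriptome(
    config: SimulationConfig,
) -> tuple[list[CodingSequence], TruthManifest]:
    """Draw ATG-initiated stop-free ORFs with Dirichlet-multinomial codon usage."""
    rng = _rng(config, _STREAM_TRANSCRIPTOME)
    codon_arr = np.array(SENSE_CODONS)
    records: list[CodingSequence] = []
    for i in range(config.n_transcripts):
        n_codons = max(
            config.min_length_codons,
            int(round(rng.lognormal(config.length_log_mean, config.length_log_sigma))),
        )
        p = rng.dirichlet(np.full(len(SENSE_CODONS), config.codon_alpha))
        body = rng.choice(codon_arr, size=n_codons - 1, p=p)
        records.append(CodingSequence(f"synth{i:05d}", "ATG" + "".join(body)))

    manifest = TruthManifest(config=config)
    manifest.codon_freq = profiles_frame(codon_frequencies(r, 0) for r in records)
    manifest.aa_freq = aa_profiles_frame(
        aa_frequencies(translate_cds(r), r.id) for r in records
    )
    return records, manifest


def generate_halflives(manifest: TruthManifest, config: SimulationConfig) -> pd.DataFrame:
    """Half-life table with log-linear planted composition effects."""
    if manifest.codon_freq is None:
        raise ValidationError("manifest lacks codon frequencies; run generate_transcriptome")
    rng = _rng(config, _STREAM_HALFLIFE)
    eta = pd.Series(0.0, index=manifest.codon_freq.index)
    for codon, beta in config.beta_codon.items():
        eta += beta * manifest.codon_freq[codon]
    for aa, beta in config.beta_aa.items():
        eta += beta * manifest.aa_freq[aa]
    eta += rng.normal(0.0, config.halflife_sigma, size=len(eta))
    half_life = np.exp(eta)
    half_life *= config.median_halflife / np.median(half_life)

    manifest.eta = eta
    manifest.half_life = pd.Series(half_life, index=eta.index)
    manifest.decay_rate = LN2 / manifest.half_life
    return pd.DataFrame(
        {"transcript_id": eta.index, "half_life": half_life}
    ).reset_index(drop=True)


def generate_timecourse(
    halflives: pd.DataFrame,
    config: SimulationConfig,
    manifest: TruthManifest | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Raw FPKM matrix plus spike-in/total read counts for a chase timecourse.

    Returns ``(raw_fpkm, spike_reads, total_reads)`` shaped for
    :func:`codonstab.halflife.spike_in_normalize`. The recorded truth allows
    exact round-trip checks at zero noise.
    """
    rng = _rng(config, _STREAM_TIMECOURSE)
    t = np.asarray(config.timepoints)
    ids = list(halflives["transcript_id"])
    hl = halflives["half_life"].to_numpy(dtype=float)
    growth = LN2 / config.doubling_time if not math.isinf(config.doubling_time) else 0.0

    t0 = rng.lognormal(config.t0_fpkm_log_mean, config.t0_fpkm_log_sigma, size=len(ids))
    signal = t0[:, None] * np.exp(-(LN2 / hl[:, None] + growth) * t[None, :])

    rel_spike = np.concatenate(
        [[1.0], rng.lognormal(0.0, config.spike_log_sigma, size=len(t) - 1)]
    )
    raw = signal * rel_spike[None, :]
    if config.noise_sigma > 0:
        raw = raw * rng.lognormal(0.0, config.noise_sigma, size=raw.shape)

    columns = [float(x) for x in t]
    raw_fpkm = pd.DataFrame(raw, index=ids, columns=columns)
    spike_counts = config.spike_fraction * rel_spike * config.total_reads
    spike_reads = pd.DataFrame(
        [spike_counts, spike_counts], index=["Luc", "LYSa"], columns=columns
    )
    total_reads = pd.Series(config.total_reads, index=columns)

    if manifest is not None:
        manifest.spike_factors = pd.Series(rel_spike, index=columns)
        manifest.t0_fpkm = pd.Series(t0, index=ids)
    return raw_fpkm, spike_reads, total_reads


def random_feasible_tai(
    config: SimulationConfig, penalties=None
) -> tuple[pd.Series, pd.Series]:
    """A tAI vector realizable under the wobble model, built forward from
    random anticodon abundances. Returns (tai, anticodon_abundance)."""
    rng = _rng(config, _STREAM_TAI)
    anticodons = sorted(
        {a for codon in SENSE_CODONS for a, _ in decoding_anticodons(codon, penalties)}
    )
    abundance = pd.Series(rng.lognormal(0.0, 1.0, size=len(anticodons)), index=anticodons)
    w = pd.Series(
        {
            codon: sum(wgt * abundance[a] for a, wgt in decoding_anticodons(codon, penalties))
            for codon in SENSE_CODONS
        }
    )
    return w / w.max(), abundance


def generate_trna_counts(
    true_tai: pd.Series,
    config: SimulationConfig,
    penalties=None,
    manifest: TruthManifest | None = None,
) -> pd.DataFrame:
    """tRNA-seq count table whose tAI reproduces ``true_tai`` at high depth.

    Solves for nonnegative anticodon abundances under the wobble model by
    NNLS (raising :class:`FeasibilityError` when no exact solution exists),
    then draws multinomial read counts at ``config.trna_depth`` and splits
    each anticodon across two isodecoder genes. Decoy Sec/iMet genes carry
    ``config.trna_decoy_fraction`` of the depth each.
    """
    penalties = DEFAULT_WOBBLE_PENALTIES if penalties is None else penalties
    tai = pd.Series(true_tai, dtype=float).reindex(list(SENSE_CODONS))
    if tai.isna().any() or (tai < 0).any() or tai.max() <= 0:
        raise ValidationError("true_tai must be a nonnegative vector over the 61 codons")
    anticodons = sorted(
        {a for codon in SENSE_CODONS for a, _ in decoding_anticodons(codon, penalties)}
    )
    m = np.zeros((len(SENSE_CODONS), len(anticodons)))
    col = {a: j for j, a in enumerate(anticodons)}
    for i, codon in enumerate(SENSE_CODONS):
        for a, wgt in decoding_anticodons(codon, penalties):
            m[i, col[a]] = wgt
    target = (tai / tai.max()).to_numpy()
    abundance, residual = nnls(m, target)
    if residual > 1e-6 * np.linalg.norm(target):
        raise FeasibilityError(
            f"tAI vector not realizable under the wobble model (residual {residual:.3g})"
        )

    rng = _rng(config, _STREAM_TRNA)
    p = abundance / abundance.sum()
    counts = rng.multinomial(config.trna_depth, p)
    rows = []
    for a, c in zip(anticodons, counts):
        first = int(c) // 2
        rows.append({"gene": f"tRNA-{a}-1", "anticodon": a, "count": first})
        rows.append({"gene": f"tRNA-{a}-2", "anticodon": a, "count": int(c) - first})
    decoy = int(config.trna_decoy_fraction * config.trna_depth)
    rows.append({"gene": "tRNA-iMet-CAT-1", "anticodon": "CAT", "count": decoy})
    rows.append({"gene": "tRNA-SeC-TCA-1", "anticodon": "TCA", "count": decoy})

    if manifest is not None:
        manifest.true_tai = tai / tai.max()
        manifest.anticodon_abundance = pd.Series(abundance, index=anticodons)
    return pd.DataFrame(rows)


def write_fixture_set(outdir, config: SimulationConfig) -> TruthManifest:
    """Generate and write the full fixture set (FASTA, half-life TSV,
    timecourse TSVs, tRNA count TSV) plus a JSON truth summary."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, manifest = generate_transcriptome(config)
    with open(outdir / "transcriptome.fasta", "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")
    halflives = generate_halflives(manifest, config)
    halflives.to_csv(outdir / "halflives.tsv", sep="\t", index=False)
    raw, spikes, totals = generate_timecourse(halflives, config, manifest)
    raw.to_csv(outdir / "timecourse_fpkm.tsv", sep="\t")
    spikes.to_csv(outdir / "spike_reads.tsv", sep="\t")
    totals.rename("total_reads").to_csv(outdir / "total_reads.tsv", sep="\t")
    tai, _ = random_feasible_tai(config)
    counts = generate_trna_counts(tai, config, manifest=manifest)
    counts.to_csv(outdir / "trna_counts.tsv", sep="\t", index=False)
    truth = {
        "seed": config.seed,
        "n_transcripts": config.n_transcripts,
        "beta_codon": config.beta_codon,
        "beta_aa": config.beta_aa,
        "median_halflife": config.median_halflife,
        "half_life": manifest.half_life.round(6).to_dict(),
        "true_tai": manifest.true_tai.round(6).to_dict(),
        "spike_factors": {str(k): round(v, 6) for k, v in manifest.spike_factors.items()},
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return manifest
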