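"""CSC/AASC correlation statistics, transcript scores, effect partitions."""

import numpy as np
import pandas as pd
import pytest

import codonstab as cs
from codonstab.errors import InsufficientDataError, ValidationError
from codonstab.genetic_code import AMINO_ACIDS, SENSE_CODONS, SYNONYMOUS_CODONS
from conftest import make_aasc_table, make_csc_table


def pearson_oracle(x, y):
    """Textbook covariance / sigma formula, independent of scipy."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def hl_table(ids, values):
    return pd.DataFrame({"transcript_id": ids, "half_life": values})


def profile_matrix(freqs: dict[str, list[float]], n: int) -> pd.DataFrame:
    ids = [f"t{i}" for i in range(n)]
    mat = pd.DataFrame(0.0, index=ids, columns=list(SENSE_CODONS))
    for codon, values in freqs.items():
        mat[codon] = values
    return mat


class TestComputeCsc:
    def test_perfect_correlation_and_antisymmetry(self):
        mat = profile_matrix({"GTG": [0.1, 0.2, 0.3, 0.4]}, 4)
        up = cs.compute_csc(mat, hl_table(mat.index, [1, 2, 3, 4]))
        down = cs.compute_csc(mat, hl_table(mat.index, [4, 3, 2, 1]))
        assert up.loc["GTG", "csc"] == pytest.approx(1.0)
        assert down.loc["GTG", "csc"] == pytest.approx(-1.0)

    def test_zero_variance_codon_is_na(self):
        mat = profile_matrix({"GTG": [0.25] * 4, "AAA": [0.1, 0.2, 0.3, 0.4]}, 4)
        table = cs.compute_csc(mat, hl_table(mat.index, [1, 2, 3, 4]))
        assert np.isnan(table.loc["GTG", "csc"])
        assert table.loc["GTG", "tier"] == "na"
        assert not table.loc["GTG", "genome_wide"]

    def test_matches_pearson_oracle(self, small_transcriptome, small_config):
        records, manifest = small_transcriptome
        halflives = cs.generate_halflives(manifest, small_config)
        table = cs.compute_csc(manifest.codon_freq, halflives)
        assert len(table) == 61
        y = halflives.set_index("transcript_id")["half_life"]
        y = y.loc[manifest.codon_freq.index]
        for codon in ["GTG", "AGT", "TTT", "GCC", "ATG"]:
            x = manifest.codon_freq[codon]
            if np.ptp(x.to_numpy()) == 0:
                continue
            assert table.loc[codon, "csc"] == pytest.approx(
                pearson_oracle(x, y), abs=1e-9
            )

    def test_ci_brackets_estimate_and_tiers(self, small_transcriptome, small_config):
        records, manifest = small_transcriptome
        halflives = cs.generate_halflives(manifest, small_config)
        table = cs.compute_csc(manifest.codon_freq, halflives)
        defined = table.dropna(subset=["csc"])
        assert ((defined["ci_low"] <= defined["csc"]) & (defined["csc"] <= defined["ci_high"])).all()
        sig = defined[defined["p_value"] < 0.01]
        assert (sig["tier"] == np.where(sig["csc"] > 0, "stabilizing", "destabilizing")).all()
        assert (defined.loc[defined["p_value"] >= 0.01, "tier"] == "ns").all()

    def test_inner_join_and_minimum_n(self):
        mat = profile_matrix({"GTG": [0.1, 0.2, 0.3, 0.4]}, 4)
        # extra half-life ids are dropped; too few shared -> error
        table = cs.compute_csc(mat, hl_table(list(mat.index) + ["zz"], [1, 2, 3, 4, 9]))
        assert table.attrs["n_transcripts"] == 4
        with pytest.raises(InsufficientDataError):
            cs.compute_csc(mat.iloc[:2], hl_table(mat.index[:2], [1, 2]))

    def test_permutation_null_shrinks_csc(self, small_config):
        """Shuffling half-lives against profiles destroys planted structure."""
        cfg = cs.SimulationConfig(
            n_transcripts=300, seed=21, beta_codon={"GTG": 8.0, "AGT": -8.0},
            halflife_sigma=0.2,
        )
        _, manifest = cs.generate_transcriptome(cfg)
        halflives = cs.generate_halflives(manifest, cfg)
        structured = cs.compute_csc(manifest.codon_freq, halflives)["csc"].abs().mean()
        rng = np.random.default_rng(0)
        perm_means = []
        for _ in range(20):
            shuffled = halflives.copy()
            shuffled["half_life"] = rng.permutation(shuffled["half_life"].to_numpy())
            perm_means.append(
                cs.compute_csc(manifest.codon_freq, shuffled)["csc"].abs().mean()
            )
        assert np.mean(perm_means) < structured

    def test_planted_sign_recovery(self):
        cfg = cs.SimulationConfig(
            n_transcripts=2000, seed=5,
            beta_codon={"GTG": 8.0, "GCC": 6.0, "AGT": -8.0, "CAT": -6.0},
        )
        _, manifest = cs.generate_transcriptome(cfg)
        halflives = cs.generate_halflives(manifest, cfg)
        table = cs.compute_csc(manifest.codon_freq, halflives)
        for codon, beta in cfg.beta_codon.items():
            assert np.sign(table.loc[codon, "csc"]) == np.sign(beta)
            assert table.loc[codon, "p_value"] < 0.01

    def test_frameshifted_profiles_decorrelate_csc(self):
        """Frame-0-planted effects weaken when CSC uses F+1 profiles."""
        cfg = cs.SimulationConfig(
            n_transcripts=400, seed=8, beta_codon={"GTG": 8.0, "AGT": -8.0},
        )
        records, manifest = cs.generate_transcriptome(cfg)
        halflives = cs.generate_halflives(manifest, cfg)
        f0 = cs.compute_csc(manifest.codon_freq, halflives)["csc"]
        shifted = cs.seqstats.profiles_frame(
            cs.codon_frequencies(r, 1) for r in records
        )
        f1 = cs.compute_csc(shifted, halflives)["csc"]
        both = pd.concat([f0, f1], axis=1, keys=["f0", "f1"]).dropna()
        rank_corr = both.corr(method="spearman").iloc[0, 1]
        assert rank_corr < 1.0 - 1e-6


class TestComputeAasc:
    def test_proportional_and_constant(self):
        ids = [f"t{i}" for i in range(5)]
        mat = pd.DataFrame(0.0, index=ids, columns=list(AMINO_ACIDS))
        mat["V"] = [0.1, 0.15, 0.2, 0.25, 0.3]
        mat["S"] = 0.2
        table = cs.compute_aasc(mat, hl_table(ids, [1, 1.5, 2, 2.5, 3]))
        assert len(table) == 20
        assert table.loc["V", "aasc"] == pytest.approx(1.0)
        assert np.isnan(table.loc["S", "aasc"])

    def test_matches_pearson_oracle(self, small_transcriptome, small_config):
        _, manifest = small_transcriptome
        halflives = cs.generate_halflives(manifest, small_config)
        table = cs.compute_aasc(manifest.aa_freq, halflives)
        y = halflives.set_index("transcript_id")["half_life"].loc[manifest.aa_freq.index]
        for aa in ["V", "S", "L"]:
            assert table.loc[aa, "aasc"] == pytest.approx(
                pearson_oracle(manifest.aa_freq[aa], y), abs=1e-9
            )


class TestTranscriptScores:
    def test_degenerate_weighting(self):
        csc = make_csc_table({c: 0.0 for c in SENSE_CODONS} | {"GTG": 0.31})
        aasc = make_aasc_table({aa: 0.0 for aa in AMINO_ACIDS} | {"V": 0.12})
        prof = cs.codon_frequencies(cs.CodingSequence("t", "GTGGTG"), 0)
        aa_prof = cs.aa_frequencies("VV", "t")
        score = cs.transcript_average_score(prof, aa_prof, csc, aasc)
        assert score.avg_csc == pytest.approx(0.31)
        assert score.avg_aasc == pytest.approx(0.12)

    def test_symmetric_cancellation(self):
        csc = make_csc_table({c: 0.0 for c in SENSE_CODONS} | {"GTG": 0.2, "GTT": -0.2})
        aasc = make_aasc_table({aa: 0.0 for aa in AMINO_ACIDS})
        prof = cs.codon_frequencies(cs.CodingSequence("t", "GTGGTT"), 0)
        score = cs.transcript_average_score(prof, cs.aa_frequencies("VV", "t"), csc, aasc)
        assert score.avg_csc == pytest.approx(0.0)

    def test_na_renormalization(self):
        values = {c: 0.1 for c in SENSE_CODONS}
        values["GTT"] = np.nan
        csc = make_csc_table(values)
        csc.loc["GTT", "csc"] = np.nan
        aasc = make_aasc_table({aa: 0.0 for aa in AMINO_ACIDS})
        prof = cs.codon_frequencies(cs.CodingSequence("t", "GTGGTT"), 0)
        score = cs.transcript_average_score(prof, cs.aa_frequencies("VV", "t"), csc, aasc)
        # GTT excluded, weights renormalized over GTG alone
        assert score.avg_csc == pytest.approx(0.1)
        assert score.n_excluded_codon_terms == 1

    def test_matches_dot_product_oracle(self, small_transcriptome, small_config):
        records, manifest = small_transcriptome
        halflives = cs.generate_halflives(manifest, small_config)
        csc = cs.compute_csc(manifest.codon_freq, halflives)
        aasc = cs.compute_aasc(manifest.aa_freq, halflives)
        scores = cs.transcript_scores_table(records[:10], csc, aasc)
        for cds in records[:10]:
            f = manifest.codon_freq.loc[cds.id]
            valid = csc["csc"].notna()
            expected = (f[valid] * csc.loc[valid, "csc"]).sum() / f[valid].sum()
            assert scores.loc[cds.id, "avg_csc"] == pytest.approx(expected, abs=1e-12)

    def test_frame_zero_required(self):
        csc = make_csc_table({c: 0.1 for c in SENSE_CODONS})
        aasc = make_aasc_table({aa: 0.0 for aa in AMINO_ACIDS})
        prof = cs.codon_frequencies(cs.CodingSequence("t", "AGTGGTT"), 1)
        with pytest.raises(ValidationError):
            cs.transcript_average_score(prof, cs.aa_frequencies("VV", "t"), csc, aasc)


class TestEffectPartition:
    def test_rule_application(self):
        aasc = make_aasc_table(
            {aa: 0.0 for aa in AMINO_ACIDS} | {"V": 0.12, "A": 0.12},
            p_values={"V": 1e-40, "A": 1e-10},
        )
        part = cs.amino_acid_effect_partition(aasc)
        assert "V" in part.extreme_aas
        assert "A" in part.moderate_aas  # effect size passes, p fails

    def test_hela_like_partition_sizes(self):
        """Three stabilizing + three destabilizing extreme amino acids split
        the 61 codons 19 / 42."""
        extremes = {"V": 0.15, "I": 0.14, "Y": 0.12, "S": -0.16, "H": -0.13, "Q": -0.11}
        aasc = make_aasc_table(
            {aa: extremes.get(aa, 0.02) for aa in AMINO_ACIDS},
            p_values={aa: (1e-45 if aa in extremes else 1e-5) for aa in AMINO_ACIDS},
        )
        part = cs.amino_acid_effect_partition(aasc)
        assert part.extreme_aas == frozenset(extremes)
        assert len(part.extreme_codons) == 19
        assert len(part.moderate_codons) == 42


class TestExclusiveAminoAcids:
    def test_extremes(self):
        assert cs.count_exclusive_amino_acids(
            make_csc_table({c: 0.1 for c in SENSE_CODONS})
        ) == 18
        alternating = {
            c: (0.1 if i % 2 == 0 else -0.1)
            for aa, codons in SYNONYMOUS_CODONS.items()
            for i, c in enumerate(codons)
        }
        assert cs.count_exclusive_amino_acids(make_csc_table(alternating)) == 0

    def test_na_and_zero_disqualify(self):
        values = {c: 0.1 for c in SENSE_CODONS}
        values["GTT"] = np.nan   # V loses exclusivity
        values["GCT"] = 0.0      # A loses exclusivity
        assert cs.count_exclusive_amino_acids(make_csc_table(values)) == 16

    def test_planted_count(self):
        """A table with exactly 11 sign-consistent multi-codon families."""
        exclusive = ["V", "I", "Y", "A", "G", "S", "H", "Q", "P", "T", "R"]
        values = {}
        for aa, codons in SYNONYMOUS_CODONS.items():
            if len(codons) < 2:
                values.update({c: 0.05 for c in codons})
            elif aa in exclusive:
                sign = 1 if aa in "VIYAG" else -1
                values.update({c: sign * (0.05 + 0.01 * i) for i, c in enumerate(codons)})
            else:
                values.update(
                    {c: (0.05 if i == 0 else -0.05) for i, c in enumerate(codons)}
                )
        assert cs.count_exclusive_amino_acids(make_csc_table(values)) == 11
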