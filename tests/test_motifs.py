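import itertools

import numpy as np
import pytest

from vdrmeta import (
    DR3_CONSENSUS,
    Genome,
    GenomicInterval,
    PeakCall,
    dr3_threshold_sweep,
    fe_window_curve,
    log_odds_score,
    motif_density_profile,
    motif_snp_distance,
    pwm_from_iupac,
    read_jaspar,
    scan_summit_region,
)
from vdrmeta.motifs import IUPAC, PWM, MotifHit, revcomp

L = len(DR3_CONSENSUS)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def plant(seq, motif, center):
    """Place a motif centered at ``center`` (start = center - len//2)."""
    start = center - len(motif) // 2
    return seq[:start] + motif + seq[start + len(motif):]


def peak_at(summit, chrom="chr1", fe=1.0):
    return PeakCall(GenomicInterval(chrom, summit - 150, summit + 150), summit, fe, 5.0)


def scan_oracle(pwm, window, flank, threshold):
    """Exhaustive offset x strand enumeration with the stated tie-breaks."""
    best = None
    for start in range(len(window) - pwm.length + 1):
        for strand in "+-":
            score = log_odds_score(pwm, window[start : start + pwm.length], strand)
            if score > threshold and (best is None or score > best.score):
                best = MotifHit(offset=start - flank, strand=strand, score=score)
    return best


class TestPwmConstruction:
    def test_n_column_is_uniform(self):
        assert np.allclose(pwm_from_iupac("N").probs[:, 0], 0.25)

    def test_unambiguous_column_hits_probability_floor(self):
        col = pwm_from_iupac("A", 0.997).probs[:, 0]
        assert np.allclose(col, [0.997, 0.001, 0.001, 0.001])

    def test_twofold_degenerate_column_splits_match_probability(self):
        col = pwm_from_iupac("R", 0.994).probs[:, 0]
        assert np.allclose(col, [0.497, 0.003, 0.497, 0.003])

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError):
            pwm_from_iupac("RGGTCAX")

    def test_columns_sum_to_one(self, pwm):
        assert np.allclose(pwm.probs.sum(axis=0), 1.0)

    def test_jaspar_round_trip(self, tmp_path, pwm):
        f = tmp_path / "motif.jaspar"
        counts = np.round(pwm.probs * 1000).astype(int)
        lines = [">MA0000.1 DR3"]
        for i, base in enumerate("ACGT"):
            lines.append(f"{base} [ " + " ".join(map(str, counts[i])) + " ]")
        f.write_text("\n".join(lines) + "\n")
        loaded = read_jaspar(f)
        assert loaded.length == pwm.length
        assert np.allclose(loaded.probs, pwm.probs, atol=5e-3)


class TestLogOddsScore:
    def test_uniform_pwm_scores_zero(self):
        uniform = PWM("U", np.full((4, 6), 0.25), np.full(4, 0.25))
        assert log_odds_score(uniform, "ACGTAC") == 0.0

    def test_single_column_log_ratio(self):
        p = pwm_from_iupac("A", 0.997)
        assert log_odds_score(p, "A") == pytest.approx(np.log(0.997 / 0.25))
        assert log_odds_score(p, "C") == pytest.approx(np.log(0.001 / 0.25))

    def test_minus_strand_equals_reverse_complement(self, pwm):
        rng = np.random.default_rng(41)
        for _ in range(100):
            seq = random_seq(rng, L)
            assert log_odds_score(pwm, seq, "-") == pytest.approx(
                log_odds_score(pwm, revcomp(seq), "+")
            )

    def test_length_mismatch_rejected(self, pwm):
        with pytest.raises(ValueError):
            log_odds_score(pwm, "ACGT")

    def test_maximum_attained_exactly_by_consensus_expansions(self, pwm):
        # every expansion of the degenerate consensus scores the maximum;
        # flipping any informative (non-N) base scores strictly less
        max_score = pwm.max_score()
        expansions = [
            "".join(choice)
            for choice in itertools.product(*(IUPAC[c] for c in DR3_CONSENSUS))
        ]
        for seq in expansions[:: max(1, len(expansions) // 64)]:
            assert log_odds_score(pwm, seq) == pytest.approx(max_score)
        seq = expansions[0]
        for i, letter in enumerate(DR3_CONSENSUS):
            if letter == "N":
                continue
            for b in set("ACGT") - set(IUPAC[letter]):
                mutant = seq[:i] + b + seq[i + 1:]
                assert log_odds_score(pwm, mutant) < max_score - 1.0


class TestScanSummitRegion:
    def test_planted_consensus_found_at_summit(self, pwm):
        rng = np.random.default_rng(43)
        seq = plant(random_seq(rng, 600), "AGGTCAATGGGTTCA", 300)
        g = Genome.from_dict({"chr1": seq})
        hit = scan_summit_region(pwm, g, "chr1", 300, 100)
        assert hit is not None
        assert hit.offset == -(L // 2)  # motif covers the summit
        assert hit.strand == "+"
        assert hit.score == pytest.approx(pwm.max_score())

    def test_all_n_window_has_no_hit(self, pwm):
        g = Genome.from_dict({"chr1": "N" * 400})
        assert scan_summit_region(pwm, g, "chr1", 200, 100, threshold=0.0) is None

    def test_strand_symmetric_detection(self, pwm):
        rng = np.random.default_rng(47)
        motif = "GGGTCAGAGAGTTCA"
        base = random_seq(rng, 600)
        fwd = Genome.from_dict({"chr1": plant(base, motif, 290)})
        rev = Genome.from_dict({"chr1": plant(base, revcomp(motif), 290)})
        h_fwd = scan_summit_region(pwm, fwd, "chr1", 300, 100)
        h_rev = scan_summit_region(pwm, rev, "chr1", 300, 100)
        assert h_fwd.strand == "+" and h_rev.strand == "-"
        assert h_fwd.score == pytest.approx(h_rev.score)
        assert h_fwd.offset == h_rev.offset

    def test_agrees_with_exhaustive_oracle_on_random_windows(self, pwm):
        rng = np.random.default_rng(53)
        for i in range(40):
            seq = random_seq(rng, 400)
            if i % 2:  # half the windows get a degraded planted motif
                motif = list("AGGTCAATGGGTTCA")
                for j in rng.choice(L, size=rng.integers(0, 3), replace=False):
                    motif[j] = "ACGT"[rng.integers(4)]
                seq = plant(seq, "".join(motif), int(rng.integers(150, 250)))
            g = Genome.from_dict({"chr1": seq})
            threshold = float(rng.choice([0.0, 4.0, 9.184643]))
            got = scan_summit_region(pwm, g, "chr1", 200, 100, threshold)
            window = g.fetch("chr1", 100, 300)
            expect = scan_oracle(pwm, window, 100, threshold)
            if expect is None:
                assert got is None
            else:
                assert got.offset == expect.offset and got.strand == expect.strand
                assert got.score == pytest.approx(expect.score)

    def test_flank_shorter_than_motif_rejected(self, pwm):
        g = Genome.from_dict({"chr1": "ACGT" * 100})
        with pytest.raises(ValueError):
            scan_summit_region(pwm, g, "chr1", 200, 10)


class TestThresholdSweep:
    def test_perfect_motifs_score_everywhere_below_max(self, pwm):
        rng = np.random.default_rng(59)
        seqs = []
        for i in range(20):
            seqs.append(plant(random_seq(rng, 400), "AGGTCAATGAGTTCA", 200))
        g = Genome.from_dict({f"chr{i}": s for i, s in enumerate(seqs)})
        peaks = [peak_at(200, chrom=f"chr{i}") for i in range(20)]
        table = dr3_threshold_sweep(peaks, g, pwm, [4.0, 9.184643, 16.0])
        assert (table["pct_with_hit"] == 100.0).all()

    def test_monotone_non_increasing_in_threshold(self, pwm, motif_peak_set):
        genome, peaks, _ = motif_peak_set
        table = dr3_threshold_sweep(peaks[:400], genome, pwm, [4.0, 6.0, 9.184643, 12.0])
        pct = table["pct_with_hit"].to_numpy()
        assert (np.diff(pct) <= 0).all()

    def test_unsorted_thresholds_rejected(self, pwm):
        with pytest.raises(ValueError):
            dr3_threshold_sweep([], None, pwm, [9.0, 4.0])


class TestDensityProfile:
    def test_summit_planted_motifs_concentrate_centrally(self, pwm):
        rng = np.random.default_rng(61)
        seq = random_seq(rng, 40_000)
        peaks = []
        for i in range(20):
            c = 1000 + i * 1900
            seq = plant(seq, "AGGTCAATGGGTTCA", c)
            peaks.append(peak_at(c))
        g = Genome.from_dict({"chr1": seq})
        prof = motif_density_profile(peaks, g, pwm, 9.184643, 500, 25)
        hot = prof.loc[prof["hits_per_peak_per_bp"].idxmax(), "offset"]
        assert hot == 0  # central bin [0, 25) holds the centered hits
        assert prof[prof["offset"].abs() > 100]["hits_per_peak_per_bp"].sum() == 0

    def test_uniformly_planted_motifs_give_flat_profile(self, pwm):
        rng = np.random.default_rng(67)
        peaks, chroms = [], {}
        n_planted = 2000
        per_peak = 4
        for i in range(n_planted // per_peak):
            seq = random_seq(rng, 2200)
            for _ in range(per_peak):
                c = int(rng.integers(600, 1600))  # uniform in +/-500 of summit
                seq = plant(seq, "AGGTCAATGGGTTCA", c)
            chroms[f"chr{i}"] = seq
            peaks.append(peak_at(1100, chrom=f"chr{i}"))
        g = Genome.from_dict(chroms)
        prof = motif_density_profile(peaks, g, pwm, 9.184643, 500, 100)
        dens = prof["hits_per_peak_per_bp"].to_numpy()
        assert dens.max() / dens.min() < 2.0

    def test_empty_peak_list_gives_zero_profile(self, pwm):
        prof = motif_density_profile([], Genome.from_dict({}), pwm, 9.0, 500, 25)
        assert (prof["hits_per_peak_per_bp"] == 0).all()


class TestFeWindowCurve:
    def test_all_peaks_with_motif_saturate(self, pwm):
        rng = np.random.default_rng(71)
        chroms, peaks = {}, []
        for i in range(100):
            chroms[f"chr{i}"] = plant(random_seq(rng, 500), "AGGTCAATGGGTTCA", 250)
            peaks.append(peak_at(250, chrom=f"chr{i}", fe=float(rng.uniform(1, 30))))
        table = fe_window_curve(peaks, Genome.from_dict(chroms), pwm, rank_window=50)
        assert (table["dr3_pct"] == 100.0).all()

    def test_motif_only_in_top_ranked_window(self, pwm):
        rng = np.random.default_rng(73)
        chroms, peaks = {}, []
        for i in range(300):
            fe = 300.0 - i  # rank == index
            seq = random_seq(rng, 500)
            if i < 100:
                seq = plant(seq, "AGGTCAATGGGTTCA", 250)
            chroms[f"chr{i}"] = seq
            peaks.append(peak_at(250, chrom=f"chr{i}", fe=fe))
        table = fe_window_curve(peaks, Genome.from_dict(chroms), pwm)
        assert table["dr3_pct"].tolist() == [100.0, 0.0, 0.0]

    def test_too_few_peaks_rejected(self, pwm):
        with pytest.raises(ValueError):
            fe_window_curve([peak_at(200)], None, pwm)

    def test_false_positive_rate_on_motif_free_sequence(self, pwm, motif_peak_set):
        genome, peaks, truth = motif_peak_set
        free = [p for p, planted in zip(peaks, truth["planted"]) if not planted]
        table = fe_window_curve(free[:1000], genome, pwm)
        assert (table["dr3_pct"] < 5.0).all()


class TestSnpDistance:
    def test_snp_at_central_nucleotide(self):
        assert motif_snp_distance([("chr1", 100)], {"chr1": np.array([100])}) == [0.0]

    def test_upstream_snp_is_negative(self):
        assert motif_snp_distance([("chr1", 100)], {"chr1": np.array([95])}) == [-5.0]

    def test_chromosome_without_snps_is_missing(self):
        (d,) = motif_snp_distance([("chr2", 100)], {"chr1": np.array([95])})
        assert np.isnan(d)

    def test_random_configurations_match_linear_scan_oracle(self):
        rng = np.random.default_rng(79)
        for _ in range(100):
            snps = np.unique(rng.integers(0, 2000, size=rng.integers(1, 20)))
            center = int(rng.integers(0, 2000))
            (got,) = motif_snp_distance([("chr1", center)], {"chr1": snps})
            dists = [int(s) - center for s in snps]
            best = min(dists, key=lambda d: (abs(d), d))
            assert got == best
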