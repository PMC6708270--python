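import io
import math

import numpy as np
import pytest
import yaml

from carrierdetect.carrier_filter import build_carrier_index, classify_read, reverse_complement
from carrierdetect.quantitation import ddpcr_copies
from carrierdetect.read_qc import mean_qscore
from carrierdetect.sequence_io import parse_read_id, write_fastq
from carrierdetect.synthetic_data import (
    ErrorModel,
    FragmentModel,
    QualityModel,
    RunConfig,
    _apply_errors,
    _quality_string,
    generate_genome,
    load_config,
    simulate_bad_pore_read,
    simulate_ddpcr,
    simulate_read,
    simulate_run,
)


class TestGenerateGenome:
    def test_deterministic_per_seed(self):
        assert generate_genome(1_000, 0.5, 3).bases == generate_genome(1_000, 0.5, 3).bases
        assert generate_genome(1_000, 0.5, 3).bases != generate_genome(1_000, 0.5, 4).bases

    def test_gc_extremes(self):
        assert set(generate_genome(500, 1.0, 0).bases) <= {"G", "C"}
        assert set(generate_genome(500, 0.0, 0).bases) <= {"A", "T"}

    def test_gc_fraction_within_binomial_noise(self):
        genome = generate_genome(100_000, 0.5, 12)
        gc = sum(genome.bases.count(b) for b in "GC") / len(genome)
        sigma = math.sqrt(0.25 / 100_000)
        assert abs(gc - 0.5) < 3 * sigma

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            generate_genome(0, 0.5, 0)


class TestErrorProcess:
    def test_substitution_rate_matches_binomial(self):
        rng = np.random.default_rng(8)
        n = 50_000
        frag = rng.integers(0, 4, size=n).astype(np.uint8)
        out = _apply_errors(frag, ErrorModel(0.06, 0.0, 0.0), rng)
        mismatches = int((out != frag).sum())
        sigma = math.sqrt(n * 0.06 * 0.94)
        assert abs(mismatches - 0.06 * n) < 3 * sigma

    def test_indel_rates_shift_length(self):
        rng = np.random.default_rng(9)
        n = 50_000
        frag = rng.integers(0, 4, size=n).astype(np.uint8)
        deleted = _apply_errors(frag, ErrorModel(0.0, 0.0, 0.04), rng)
        inserted = _apply_errors(frag, ErrorModel(0.0, 0.03, 0.0), rng)
        assert abs(deleted.size - n * 0.96) < 3 * math.sqrt(n * 0.04 * 0.96)
        assert abs(inserted.size - n * 1.03) < 3 * math.sqrt(n * 0.03 * 0.97)


class TestSimulateRead:
    def test_zero_errors_give_exact_fragment(self):
        genome = generate_genome(5_000, 0.5, 1)
        noerr = ErrorModel(0.0, 0.0, 0.0)
        read, label = simulate_read(genome, 800, channel=9, seed=4, errors=noerr)
        assert read.bases in genome.bases or reverse_complement(read.bases) in genome.bases
        assert label.origin == "carrier" and len(read) == 800

    def test_read_id_round_trips_through_parser(self):
        genome = generate_genome(2_000, 0.5, 2)
        read, _ = simulate_read(genome, 300, channel=117, seed=5)
        assert parse_read_id(read.read_id) == (117, read.uuid)
        assert read.channel == 117

    def test_fragment_longer_than_genome_is_error(self):
        genome = generate_genome(400, 0.5, 3)
        with pytest.raises(ValueError):
            simulate_read(genome, 500, channel=1, seed=0)

    def test_quality_string_calibrated_to_drawn_mean(self):
        rng = np.random.default_rng(6)
        for target in (7.0, 9.0, 10.5, 13.0):
            q = _quality_string(2_000, target, 1.5, rng)
            assert mean_qscore(q) == pytest.approx(target, abs=0.25)


class TestBadPoreReads:
    def test_band_quality_and_carrier_dissimilarity(self):
        carrier = generate_genome(48_502, 0.5, 7, "carrier")
        index = build_carrier_index(carrier, 17)
        for seed in range(10):
            read, label = simulate_bad_pore_read(101, seed)
            assert label.origin == "bad_pore"
            assert 267 <= len(read) <= 865
            assert mean_qscore(read.quality) >= 9.0
            assert classify_read(read, index).shared_fraction < 0.01


class TestSimulateRun:
    def test_read_count_conservation(self):
        config = RunConfig(seed=0, n_carrier_reads=50, n_target_reads=5, n_contam_reads=3,
                           bad_pore_channels=(7, 99), bad_pore_reads_per_channel=10)
        run = simulate_run(config)
        assert len(run.reads) == config.total_reads == 78
        assert len(run.truth) == 78

    def test_truth_table_aligned_row_for_row(self):
        run = simulate_run(RunConfig(seed=1, n_carrier_reads=30))
        for read, label in zip(run.reads, run.truth):
            assert read.read_id == label.read_id
            assert label.origin in {"carrier", "target", "contaminant", "bad_pore"}

    def test_genuine_reads_avoid_bad_pore_channels(self):
        run = simulate_run(RunConfig(seed=2, n_carrier_reads=60, bad_pore_channels=(3,),
                                     bad_pore_reads_per_channel=5))
        for read, label in zip(run.reads, run.truth):
            if label.origin == "bad_pore":
                assert read.channel == 3
            else:
                assert read.channel != 3

    def test_same_seed_is_byte_identical(self):
        config = RunConfig(seed=11, n_carrier_reads=40)
        buffers = []
        for _ in range(2):
            run = simulate_run(config)
            buf = io.StringIO()
            for r in run.reads:
                buf.write(f"@{r.read_id}\n{r.bases}\n+\n{r.quality}\n")
            buffers.append(buf.getvalue())
        assert buffers[0] == buffers[1]


class TestSimulateDdpcr:
    def test_zero_copies_zero_positives(self):
        assert simulate_ddpcr(0, 20_000, 0) == (0, 20_000)

    def test_unit_occupancy_positive_fraction(self):
        n_positive, n = simulate_ddpcr(20_000, 20_000, 13)
        p = 1 - math.exp(-1)
        assert abs(n_positive / n - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_seed_reproducibility(self):
        assert simulate_ddpcr(500, 20_000, 7) == simulate_ddpcr(500, 20_000, 7)

    def test_round_trip_with_estimator(self):
        n_positive, n = simulate_ddpcr(2_000, 20_000, 21)
        result = ddpcr_copies(n_positive, n)
        assert result.copies == pytest.approx(2_000, rel=0.1)


class TestConfigFile:
    def test_yaml_round_trip(self, tmp_path):
        payload = {
            "seed": 5,
            "n_carrier_reads": 123,
            "bad_pore_channels": [4, 8],
            "errors": {"substitution": 0.05, "insertion": 0.02, "deletion": 0.03},
            "carrier_fragment": {"median_bp": 5000, "sigma": 0.9},
        }
        path = tmp_path / "run.yaml"
        path.write_text(yaml.safe_dump(payload))
        config = load_config(path)
        assert config.seed == 5 and config.n_carrier_reads == 123
        assert config.bad_pore_channels == (4, 8)
        assert config.errors == ErrorModel(0.05, 0.02, 0.03)
        assert config.carrier_fragment == FragmentModel(5000, 0.9)
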