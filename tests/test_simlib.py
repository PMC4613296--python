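"""Synthetic library generator: determinism, ground truth, noise models."""

import numpy as np
import pytest

from axomir import simlib
from axomir.knownmatch import family_key
from axomir.simlib import (
    PlantedFamily,
    SimulationConfig,
    generate_libraries,
    generate_reference,
    mutate_sequence,
)

from test_novelfam import reference_dp


class TestMutateSequence:
    def test_zero_substitutions_identity(self):
        seq = "ACGTACGTACGTACGTACGT"
        assert mutate_sequence(seq, 0, np.random.default_rng(0)) == seq

    def test_exact_hamming_distance(self):
        rng = np.random.default_rng(1)
        seq = "A" * 20
        for n in (1, 2, 5, 20):
            out = mutate_sequence(seq, n, rng)
            assert len(out) == 20
            assert sum(a != b for a, b in zip(seq, out)) == n

    def test_over_length_rejected(self):
        with pytest.raises(ValueError):
            mutate_sequence("ACGT", 5, np.random.default_rng(0))


class TestGenerateReference:
    def test_deterministic_fasta(self, tmp_path):
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        generate_reference(10, 5, 42, p1)
        generate_reference(10, 5, 42, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_pairwise_distance_above_six(self):
        entries = generate_reference(10, 5, 42)
        for i, a in enumerate(entries):
            for b in entries[i + 1 :]:
                assert reference_dp(a.sequence, b.sequence) > 6

    def test_lengths_and_names(self):
        entries = generate_reference(12, 4, 7)
        assert len({e.name for e in entries}) == 12
        for e in entries:
            assert 20 <= len(e.sequence) <= 24
            assert e.name.startswith("syn-mir-")
            assert e.family_key == family_key(e.name)

    def test_more_families_than_mirnas_rejected(self):
        with pytest.raises(ValueError):
            generate_reference(3, 5, 1)


class TestGenerateLibraries:
    def test_depths_exact_and_deterministic(self, tmp_path):
        config = simlib.make_scenario(9, n_reads_control=1500, n_reads_blastema=1200)
        c1, b1, t1 = generate_libraries(config)
        c2, b2, t2 = generate_libraries(config)
        assert len(c1) == 1500 and len(b1) == 1200
        p1, p2 = tmp_path / "c1.fastq", tmp_path / "c2.fastq"
        simlib.write_fastq(c1, p1)
        simlib.write_fastq(c2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert t1.reads.equals(t2.reads)

    def test_noise_free_reads_copy_their_mirna(self):
        config = simlib.make_scenario(
            9,
            n_reads_control=1000,
            n_reads_blastema=1000,
            substitution_rate=0.0,
            noise_fraction=0.0,
            adapter_readthrough_fraction=0.0,
            n_planted=0,
        )
        control, _, truth = generate_libraries(config)
        mature = {e.name: e.sequence for e in config.reference_mirnas}
        truth_c = truth.reads.set_index("read_id")
        for read in control:
            label = truth_c.loc[read.read_id, "label"]
            assert read.sequence == mature[label]

    def test_planted_counts_pass_through(self):
        import dataclasses

        config = simlib.make_scenario(3, n_reads_control=2000, n_reads_blastema=2000)
        fam = dataclasses.replace(config.planted_novel_families[0], count_control=0)
        config.planted_novel_families = [fam] + list(config.planted_novel_families[1:])
        control, blastema, truth = generate_libraries(config)
        assert truth.family_counts("control").get(fam.family_id, 0) == 0
        assert truth.family_counts("blastema")[fam.family_id] == fam.count_blastema

    def test_label_totals_sum_to_depth(self):
        config = simlib.make_scenario(
            5,
            n_reads_control=3000,
            n_reads_blastema=2500,
            noise_fraction=0.05,
            adapter_artifact_fraction=0.01,
        )
        _, _, truth = generate_libraries(config)
        assert sum(truth.label_counts("control").values()) == 3000
        assert sum(truth.label_counts("blastema").values()) == 2500
        assert simlib.ADAPTER_LABEL in truth.label_counts("control")

    def test_substituted_reads_at_recorded_distance(self):
        config = simlib.make_scenario(
            5, n_reads_control=2000, n_reads_blastema=2000,
            substitution_rate=0.02, adapter_readthrough_fraction=0.0, n_planted=0,
        )
        control, _, truth = generate_libraries(config)
        mature = {e.name: e.sequence for e in config.reference_mirnas}
        truth_c = truth.reads.set_index("read_id")
        known = truth_c[~truth_c["label"].isin([simlib.NOISE_LABEL, simlib.ADAPTER_LABEL])]
        for read in control:
            if read.read_id not in known.index:
                continue
            row = known.loc[read.read_id]
            hamming = sum(a != b for a, b in zip(read.sequence, mature[row["label"]]))
            assert hamming == row["n_substitutions"]

    def test_expression_weights_recovered_at_depth(self):
        """Empirical per-miRNA read fractions match the normalized abundance
        weights within 3 standard errors at depth 50,000."""
        config = simlib.make_scenario(
            13,
            n_reads_control=50_000,
            n_reads_blastema=100,
            noise_fraction=0.0,
            n_planted=0,
        )
        _, _, truth = generate_libraries(config)
        counts = truth.label_counts("control")
        weights = {n: w[0] for n, w in config.expression_profile.items()}
        total_w = sum(weights.values())
        n = 50_000
        for name, w in weights.items():
            p = w / total_w
            se = (p * (1 - p) / n) ** 0.5
            assert abs(counts.get(name, 0) / n - p) <= 3 * se + 1 / n

    def test_empty_profile_and_no_planted_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                seed=1,
                n_reads_control=10,
                n_reads_blastema=10,
                reference_mirnas=[],
                expression_profile={},
            ).validate()

    def test_close_planted_seeds_rejected(self):
        seed_seq = "ACGTACGTACGTACGTACGT"
        fams = [
            PlantedFamily("p1", seed_seq, 0, 0, 10, 10),
            PlantedFamily("p2", seed_seq[:-1] + "T", 0, 0, 10, 10),
        ]
        config = SimulationConfig(
            seed=1,
            n_reads_control=100,
            n_reads_blastema=100,
            reference_mirnas=[],
            expression_profile={},
            planted_novel_families=fams,
            noise_fraction=0.8,
        )
        with pytest.raises(ValueError, match="ambiguous"):
            config.validate()

    def test_fraction_out_of_range_rejected(self):
        config = simlib.make_scenario(1, n_reads_control=100, n_reads_blastema=100)
        config.noise_fraction = 1.5
        with pytest.raises(ValueError, match="noise_fraction"):
            config.validate()
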