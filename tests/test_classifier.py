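"""Instance-based classifier: yield-sum scoring, tie handling,
permutation invariance, evaluation arithmetic and persistence."""

import numpy as np
import pytest

from hybriclass import classifier, nucleic, thermo
from hybriclass.classifier import TubeLibrary, classify_sequence


@pytest.fixture(scope="module")
def conditions():
    return thermo.HybridizationConditions()


def random_library(rng, n_classes=3, per_class=5, length=59) -> TubeLibrary:
    return TubeLibrary(
        tubes={
            c: [nucleic.random_sequence(length, rng=rng) for _ in range(per_class)]
            for c in range(n_classes)
        }
    )


class TestClassifySequence:
    def test_planted_complement_tube_wins(self, conditions):
        rng = np.random.default_rng(0)
        query = nucleic.random_sequence(59, rng=rng)
        probe_mates = [query] * 10  # instances identical to the query sequence
        library = TubeLibrary(
            tubes={
                0: [nucleic.random_sequence(59, rng=rng) for _ in range(10)],
                1: probe_mates,
                2: [nucleic.random_sequence(59, rng=rng) for _ in range(10)],
            }
        )
        res = classify_sequence(query, library, conditions)
        assert res.predicted_label == 1
        assert res.per_class_yield_sum[1] == pytest.approx(10.0, abs=0.1)
        assert res.per_class_yield_sum[0] < 1.0

    def test_identical_tubes_tie_to_smallest_label(self, conditions, caplog):
        rng = np.random.default_rng(1)
        seqs = [nucleic.random_sequence(59, rng=rng) for _ in range(4)]
        library = TubeLibrary(tubes={2: list(seqs), 5: list(seqs), 7: list(seqs)})
        with caplog.at_level("WARNING"):
            res = classify_sequence(nucleic.random_sequence(59, rng=rng), library, conditions)
        assert res.predicted_label == 2
        assert any("tie" in r.message for r in caplog.records)

    def test_single_class_library(self, conditions):
        rng = np.random.default_rng(2)
        library = TubeLibrary(tubes={4: [nucleic.random_sequence(59, rng=rng)]})
        res = classify_sequence(nucleic.random_sequence(59, rng=rng), library, conditions)
        assert res.predicted_label == 4

    def test_empty_library_rejected(self, conditions):
        with pytest.raises(ValueError):
            classify_sequence("A" * 59, TubeLibrary(), conditions)

    def test_length_mismatch_rejected(self, conditions):
        rng = np.random.default_rng(3)
        library = random_library(rng, length=40)
        with pytest.raises(ValueError, match="length"):
            classify_sequence(nucleic.random_sequence(59, rng=rng), library, conditions)

    def test_invariant_under_within_tube_permutation(self, conditions):
        rng = np.random.default_rng(4)
        library = random_library(rng)
        query = nucleic.random_sequence(59, rng=rng)
        res = classify_sequence(query, library, conditions)
        shuffled = TubeLibrary(
            tubes={c: list(reversed(s)) for c, s in library.tubes.items()}
        )
        res2 = classify_sequence(query, shuffled, conditions)
        assert res.predicted_label == res2.predicted_label
        for c in library.tubes:
            assert res.per_class_yield_sum[c] == pytest.approx(
                res2.per_class_yield_sum[c], abs=1e-12
            )

    def test_adding_instance_never_decreases_sum(self, conditions):
        rng = np.random.default_rng(5)
        library = random_library(rng)
        query = nucleic.random_sequence(59, rng=rng)
        base = classify_sequence(query, library, conditions).per_class_yield_sum[0]
        library.tubes[0].append(nucleic.random_sequence(59, rng=rng))
        grown = classify_sequence(query, library, conditions).per_class_yield_sum[0]
        assert grown >= base


class TestTubeLibrary:
    def test_fasta_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        library = random_library(rng)
        path = tmp_path / "library.fasta"
        library.to_fasta(path)
        assert TubeLibrary.from_fasta(path).tubes == library.tubes

    def test_duplicates_retained(self):
        library = TubeLibrary(tubes={0: ["A" * 59] * 3})
        assert len(library.tubes[0]) == 3

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            TubeLibrary(tubes={0: ["ACGT"], 1: ["ACGTA"]})


class TestEvaluateAndNeighbors:
    def test_library_shape(self, full_run):
        library = full_run["library"]
        assert sorted(library.tubes) == list(range(10))
        assert all(len(v) == 200 for v in library.tubes.values())

    def test_accuracy_equals_weighted_per_class_mean(self, full_run):
        ev = full_run["evaluation"]
        counts = ev.confusion_matrix.sum(axis=1)
        weighted = sum(
            ev.per_class_accuracy[c] * counts[c] for c in ev.per_class_accuracy
        ) / counts.sum()
        assert ev.overall_accuracy == pytest.approx(weighted, abs=1e-12)

    def test_confusion_matrix_totals(self, full_run):
        ev = full_run["evaluation"]
        assert ev.confusion_matrix.to_numpy().sum() == 100
        assert np.trace(ev.confusion_matrix.to_numpy()) == round(
            100 * ev.overall_accuracy
        )

    def test_misclassified_listing_consistent(self, full_run):
        ev = full_run["evaluation"]
        assert len(ev.misclassified) == round(100 * (1 - ev.overall_accuracy))

    def test_evaluate_length_mismatch(self, full_run):
        with pytest.raises(ValueError):
            classifier.evaluate(
                full_run["corpus"]["test_x"][:5],
                full_run["corpus"]["test_y"][:4],
                full_run["library"],
                full_run["feature_model"],
                full_run["encoder_model"],
            )

    def test_top_k_neighbors_contract(self, full_run, conditions):
        table, composition = classifier.top_k_neighbors(
            full_run["corpus"]["test_x"][0],
            full_run["library"],
            50,
            full_run["feature_model"],
            full_run["encoder_model"],
            conditions,
        )
        assert len(table) == 50
        ys = table["yield"].to_numpy()
        assert np.all(np.diff(ys) <= 1e-12)  # sorted descending
        assert sum(composition.values()) == pytest.approx(1.0)

    def test_top_k_exceeding_library_warns(self, full_run, conditions):
        small = TubeLibrary(tubes={0: full_run["library"].tubes[0][:3]})
        with pytest.warns(UserWarning, match="exceeds"):
            table, _ = classifier.top_k_neighbors(
                full_run["corpus"]["test_x"][0],
                small,
                10,
                full_run["feature_model"],
                full_run["encoder_model"],
                conditions,
            )
        assert len(table) == 3
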