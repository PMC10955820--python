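"""DNA sequence primitives: validation, reverse complement, homopolymer
checks, one-hot tensor conversion and FASTA I/O.

Sequences are plain Python strings over the uppercase alphabet ``ACGT``;
every public function validates its input so that downstream numerical code
can assume canonical form.  Base matrices use the fixed row order
A, T, C, G (index 0..3) throughout the package — note this is *not*
alphabetical order.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Fixed row order of base matrices.
BASE_ORDER = "ATCG"
BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_COMP_TABLE = str.maketrans("ATCG", "TAGC")

#: Row permutation implementing the base-wise complement on a 4xL matrix
#: (A<->T is rows 0<->1, C<->G is rows 2<->3 under BASE_ORDER).
COMPLEMENT_ROWS = np.array([1, 0, 3, 2])


class SequenceError(ValueError):
    """Raised for sequences containing characters outside {A,T,C,G}."""


def validate_sequence(seq: str) -> str:
    """Validate ``seq`` and return it unchanged.

    Lowercase letters are rejected rather than silently upcased so that
    data errors surface early.
    """
    if not isinstance(seq, str):
        raise SequenceError(f"expected str, got {type(seq).__name__}")
    if len(seq) == 0:
        raise SequenceError("empty sequence")
    for pos, ch in enumerate(seq):
        if ch not in BASE_INDEX:
            raise SequenceError(
                f"invalid character {ch!r} at position {pos}; "
                "sequences must be uppercase over A, T, C, G"
            )
    return seq


def reverse_complement(seq: str) -> str:
    """Return the reverse complement (A<->T, C<->G, read 3'->5')."""
    validate_sequence(seq)
    return seq.translate(_COMP_TABLE)[::-1]


def has_homopolymer(seq: str, min_run: int = 3) -> bool:
    """True iff some base repeats at least ``min_run`` times consecutively.

    Runs of three or more identical bases (AAA, TTTT, ...) are excluded
    from synthetic training corpora for synthesis realism.
    """
    validate_sequence(seq)
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        if run >= min_run:
            return True
    return False


def one_hot(seq: str) -> np.ndarray:
    """Encode a sequence as a hard 4xL base matrix (rows A, T, C, G)."""
    validate_sequence(seq)
    idx = np.fromiter((BASE_INDEX[b] for b in seq), dtype=np.intp, count=len(seq))
    m = np.zeros((4, len(seq)), dtype=np.float64)
    m[idx, np.arange(len(seq))] = 1.0
    return m


def decode_base_matrix(m: np.ndarray) -> str:
    """Decode a 4xL base matrix to a sequence by per-column argmax.

    Ties are broken by row order A < T < C < G (the first maximal row),
    which makes decoding deterministic for uniform columns.
    """
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
        raise ValueError(f"expected a 4xL matrix with L >= 1, got shape {m.shape}")
    # np.argmax returns the first maximum, which is exactly the A<T<C<G rule.
    return "".join(BASE_ORDER[i] for i in np.argmax(m, axis=0))


def soft_reverse_complement(m: np.ndarray) -> np.ndarray:
    """Continuous extension of reverse complement to soft base matrices.

    Reverses column order and swaps the A/T and C/G rows; coincides with
    ``one_hot(reverse_complement(s))`` on hard matrices and is linear, so
    gradients pass through it unchanged (up to the same permutation).
    """
    m = np.asarray(m)
    if m.shape[-2] != 4:
        raise ValueError(f"expected (...,4,L), got shape {m.shape}")
    return m[..., COMPLEMENT_ROWS, ::-1]


def random_sequence(
    length: int,
    forbid_homopolymer: bool = False,
    rng: np.random.Generator | int | None = None,
) -> str:
    """Draw a uniform random sequence of the given length.

    With ``forbid_homopolymer`` the draw is constructive: each base is
    uniform over the bases that do not complete a run of three, which keeps
    the sampler rejection-free and uniform over admissible sequences at
    each step.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(rng)
    if not forbid_homopolymer:
        return "".join(BASE_ORDER[i] for i in rng.integers(0, 4, size=length))
    out: list[str] = []
    run = 0
    for _ in range(length):
        if run >= 2:
            choices = [b for b in BASE_ORDER if b != out[-1]]
            base = choices[rng.integers(0, 3)]
        else:
            base = BASE_ORDER[rng.integers(0, 4)]
        run = run + 1 if out and base == out[-1] else 1
        out.append(base)
    return "".join(out)


# ---------------------------------------------------------------------------
# FASTA I/O
#
# Headers written by this package follow the dialect "classLabel|instanceIndex"
# so that a classifier tube library can be reconstructed from a file.

def format_record_id(class_label: int, instance_index: int) -> str:
    return f"{class_label}|{instance_index:04d}"


def parse_record_id(record_id: str) -> tuple[int, int]:
    """Parse a ``classLabel|instanceIndex`` header; raises on other dialects."""
    try:
        label_s, idx_s = record_id.split("|")
        return int(label_s), int(idx_s)
    except Exception as exc:
        raise ValueError(f"cannot parse record id {record_id!r} as 'class|index'") from exc


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` tuples, validating bases."""
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        try:
            validate_sequence(seq)
        except SequenceError as exc:
            raise SequenceError(f"record {rec.id!r}: {exc}") from exc
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write ``(id, sequence)`` records as FASTA, 80-column wrapped, 5'->3'."""
    seq_records = []
    for rid, seq in records:
        validate_sequence(seq)
        seq_records.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(seq_records)


def sequences_to_onehot_batch(seqs: Sequence[str]) -> np.ndarray:
    """Stack equal-length sequences into an (N, 4, L) hard tensor."""
    if not seqs:
        raise ValueError("empty sequence list")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must have equal length")
    return np.stack([one_hot(s) for s in seqs])


def encode_batch(seqs: Sequence[str]) -> np.ndarray:
    """Integer-encode sequences (A=0,T=1,C=2,G=3) into an (N, L) uint8 array."""
    if not seqs:
        raise ValueError("empty sequence list")
    length = len(seqs[0])
    arr = np.empty((len(seqs), length), dtype=np.uint8)
    for i, s in enumerate(seqs):
        validate_sequence(s)
        if len(s) != length:
            raise ValueError("sequences must have equal length")
        arr[i] = [BASE_INDEX[b] for b in s]
    return arr
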