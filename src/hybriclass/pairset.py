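"""Generation, deduplication and yield-balancing of the sequence-pair
corpus used to train the yield predictor.

Pairs are 59-nt by default, homopolymer-free (no run of 3+ identical
bases), and labeled with the equilibrium yield from the thermodynamic
backend.  Two independent random strands almost always have a yield near
zero, so a corpus of purely independent pairs cannot be balanced across
the yield range; the generator therefore draws a mixture of

* independent random pairs (low-yield mass),
* a random strand paired with a k-point-mutated copy of its reverse
  complement, k uniform on 0..length (mass at both extremes), and
* the same construction with k confined to the duplex melting transition,
  which supplies the otherwise-rare intermediate yields.

Balancing then samples evenly from equal-width yield bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .nucleic import random_sequence, reverse_complement, validate_sequence
from .thermo import HybridizationConditions, pair_yields

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MixtureWeights:
    """Component probabilities of the pair generator.

    ``independent``: two unrelated random strands (yield mass near 0).
    ``mutated_uniform``: a strand vs a k-point-mutated copy of its reverse
    complement, k uniform on 0..length (mass near 0 and 1).
    ``mutated_transition``: the same construction with k confined to the
    duplex melting transition (roughly a third to a bit over half of the
    positions mutated), which is where intermediate yields live.
    """

    independent: float = 0.25
    mutated_uniform: float = 0.25
    mutated_transition: float = 0.5

    def __post_init__(self) -> None:
        total = self.independent + self.mutated_uniform + self.mutated_transition
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


#: Melting-transition window as fractions of sequence length (for 59-nt:
#: 19..33 mutations).  Outside it, two-state yields are pinned near 0 or 1.
TRANSITION_K_FRACTION = (0.32, 0.56)


@dataclass(frozen=True)
class YieldLabeledPair:
    first: str
    second: str
    yield_label: float

    def __post_init__(self) -> None:
        validate_sequence(self.first)
        validate_sequence(self.second)
        if not 0.0 <= self.yield_label <= 1.0:
            raise ValueError(f"yield {self.yield_label} outside [0, 1]")

    @property
    def key(self) -> frozenset:
        """Unordered identity: (a, b) and (b, a) are the same pair."""
        return frozenset((self.first, self.second))


def _creates_run(chars: list[str], pos: int, base: str) -> bool:
    """Would substituting ``base`` at ``pos`` create a run of 3 through it?"""
    n = len(chars)
    left = 0
    i = pos - 1
    while i >= 0 and chars[i] == base:
        left += 1
        i -= 1
    right = 0
    i = pos + 1
    while i < n and chars[i] == base:
        right += 1
        i += 1
    return left + right + 1 >= 3


def _mutate(seq: str, k: int, rng: np.random.Generator) -> str:
    """Apply k point substitutions at distinct positions, constructively
    keeping the sequence homopolymer-free at every step (a substitution
    only ever picks among the alternative bases that do not complete a
    run of three through the mutated position)."""
    bases = "ATCG"
    for _ in range(50):
        chars = list(seq)
        order = rng.permutation(len(seq))
        mutated = 0
        for pos in order:
            if mutated == k:
                break
            options = [
                b for b in bases if b != chars[pos] and not _creates_run(chars, pos, b)
            ]
            if not options:
                continue
            chars[pos] = options[rng.integers(0, len(options))]
            mutated += 1
        if mutated == k:
            return "".join(chars)
    raise RuntimeError("could not produce a homopolymer-free mutant")


def _draw_pair(length: int, rng: np.random.Generator, mixture: MixtureWeights) -> tuple[str, str]:
    a = random_sequence(length, forbid_homopolymer=True, rng=rng)
    u = rng.random()
    if u < mixture.independent:
        b = random_sequence(length, forbid_homopolymer=True, rng=rng)
    else:
        if u < mixture.independent + mixture.mutated_uniform:
            k = int(rng.integers(0, length + 1))
        else:
            k_lo = int(round(TRANSITION_K_FRACTION[0] * length))
            k_hi = int(round(TRANSITION_K_FRACTION[1] * length))
            k = int(rng.integers(k_lo, k_hi + 1))
        # reverse complement preserves homopolymer-freeness; mutation
        # redraws until the mutant is admissible too
        b = _mutate(reverse_complement(a), k, rng) if k > 0 else reverse_complement(a)
    return a, b


def generate_pairs(
    n: int,
    length: int = 59,
    conditions: HybridizationConditions | None = None,
    seed: int | np.random.Generator = 0,
    mixture: MixtureWeights | None = None,
) -> list[YieldLabeledPair]:
    """Generate ``n`` homopolymer-free pairs labeled by the yield backend."""
    if n < 1:
        raise ValueError("n must be >= 1")
    conditions = conditions or HybridizationConditions()
    mixture = mixture or MixtureWeights()
    rng = np.random.default_rng(seed)
    drawn = [_draw_pair(length, rng, mixture) for _ in range(n)]
    firsts = [a for a, _ in drawn]
    seconds = [b for _, b in drawn]
    ys = pair_yields(firsts, seconds, conditions)
    return [YieldLabeledPair(a, b, float(y)) for a, b, y in zip(firsts, seconds, ys)]


def generate_balanced_pairs(
    per_bin: int,
    n_bins: int = 10,
    length: int = 59,
    conditions: HybridizationConditions | None = None,
    seed: int | np.random.Generator = 0,
    max_factor: float = 10.0,
) -> list[YieldLabeledPair]:
    """Draw pairs adaptively until every yield bin holds ``per_bin`` of them.

    Batches are generated, labeled, deduplicated against everything seen,
    and routed to equal-width yield bins; once the extreme bins are full,
    drawing shifts to the transition component that feeds the middle bins.
    Gives up (with a warning) after ``max_factor * n_bins * per_bin`` draws,
    returning whatever was collected — middle bins are the scarce ones.
    """
    conditions = conditions or HybridizationConditions()
    rng = np.random.default_rng(seed)
    buckets: list[list[YieldLabeledPair]] = [[] for _ in range(n_bins)]
    seen: set = set()
    max_draws = int(max_factor * n_bins * per_bin)
    drawn_total = 0
    batch_size = 4096
    while drawn_total < max_draws and any(len(b) < per_bin for b in buckets):
        extremes_unfilled = len(buckets[0]) < per_bin or len(buckets[-1]) < per_bin
        mixture = (
            MixtureWeights(0.25, 0.25, 0.5)
            if extremes_unfilled
            else MixtureWeights(0.02, 0.03, 0.95)
        )
        n_batch = min(batch_size, max_draws - drawn_total)
        drawn = [_draw_pair(length, rng, mixture) for _ in range(n_batch)]
        drawn_total += n_batch
        ys = pair_yields([a for a, _ in drawn], [b for _, b in drawn], conditions)
        for (a, b), y in zip(drawn, ys):
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            idx = min(int(y * n_bins), n_bins - 1)
            if len(buckets[idx]) < per_bin:
                buckets[idx].append(YieldLabeledPair(a, b, float(y)))
    for i, bucket in enumerate(buckets):
        if len(bucket) < per_bin:
            logger.warning(
                "yield bin %d/%d filled to %d of %d after %d draws",
                i, n_bins, len(bucket), per_bin, drawn_total,
            )
    return [p for bucket in buckets for p in bucket]


def dedupe(pairs: Sequence[YieldLabeledPair]) -> list[YieldLabeledPair]:
    """Drop exact duplicates, treating (a, b) and (b, a) as the same pair;
    keeps the first occurrence, preserving order."""
    seen: set = set()
    out: list[YieldLabeledPair] = []
    for p in pairs:
        k = p.key
        if k not in seen:
            seen.add(k)
            out.append(p)
    return out


def balance_by_yield(
    pairs: Sequence[YieldLabeledPair],
    n_bins: int = 10,
    per_bin: int = 100,
    seed: int | np.random.Generator = 0,
) -> list[YieldLabeledPair]:
    """Sample up to ``per_bin`` pairs from each of ``n_bins`` equal-width
    yield bins (last bin right-closed, so a label of exactly 1.0 lands in
    the top bin).  Bins with insufficient supply contribute what they have,
    with a warning."""
    if per_bin < 1:
        raise ValueError("per_bin must be >= 1")
    if not pairs:
        logger.warning("balance_by_yield called with no pairs")
        return []
    rng = np.random.default_rng(seed)
    labels = np.array([p.yield_label for p in pairs])
    bin_idx = np.minimum((labels * n_bins).astype(int), n_bins - 1)
    out: list[YieldLabeledPair] = []
    for b in range(n_bins):
        members = np.flatnonzero(bin_idx == b)
        if len(members) < per_bin:
            logger.warning(
                "yield bin %d/%d has only %d pairs (wanted %d)",
                b, n_bins, len(members), per_bin,
            )
            chosen = members
        else:
            chosen = rng.choice(members, size=per_bin, replace=False)
        out.extend(pairs[i] for i in sorted(chosen))
    return out


def write_pairs_tsv(pairs: Sequence[YieldLabeledPair], path) -> None:
    df = pd.DataFrame(
        {
            "first_seq": [p.first for p in pairs],
            "second_seq": [p.second for p in pairs],
            "yield": [f"{p.yield_label:.6f}" for p in pairs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> list[YieldLabeledPair]:
    df = pd.read_csv(path, sep="\t", dtype={"first_seq": str, "second_seq": str})
    expected = ["first_seq", "second_seq", "yield"]
    if list(df.columns) != expected:
        raise ValueError(f"expected columns {expected}, got {list(df.columns)}")
    out: list[YieldLabeledPair] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(YieldLabeledPair(row.first_seq, row.second_seq, float(row[2])))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {row_number}: {exc}") from exc
    return out
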