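"""Duplex hybridization thermodynamics and equilibrium yield.

This is the default yield oracle of the package.  It combines

* a nearest-neighbor duplex free-energy model: the minimum free energy over
  all antiparallel ungapped registrations of the two strands, with
  contiguous Watson-Crick stacks contributing tabulated dH - T*dS terms,
  fixed penalties for internal mismatches, an affine penalty for interior
  loops, and one initiation term per duplex (see :mod:`hybriclass._dp`), and
* a two-state mass-action equilibrium A + B <=> AB at equal initial strand
  concentrations, giving the closed-form duplex fraction ("yield").

The model deliberately ignores intramolecular secondary structure,
complexes larger than two strands, salt corrections and dangling ends; it
is a transparent, fully testable approximation of a partition-function
calculation.  A different oracle (e.g. a NUPACK installation) can be used
by registering an adapter callable and selecting the ``external_adapter``
backend in :class:`HybridizationConditions`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _dp
from .nucleic import encode_batch, reverse_complement, validate_sequence

#: Gas constant in kcal/(mol*K).
R_KCAL = 1.98720425864083e-3

#: Sentinel free energy meaning "no binding possible".
NO_BINDING = np.inf

_WC_STACKS = ("AA", "AT", "TA", "CA", "GT", "CT", "GA", "CG", "GC", "GG")
_RC = {"A": "T", "T": "A", "C": "G", "G": "C"}
_CODE = {"A": 0, "T": 1, "C": 2, "G": 3}


class BackendError(RuntimeError):
    """Raised when the external adapter backend is selected but absent."""


@dataclass(frozen=True)
class NNParameterTable:
    """Nearest-neighbor duplex parameters.

    ``stack_dH``/``stack_dS`` map the 10 unique Watson-Crick dinucleotide
    stacks (top strand 5'->3') to enthalpy (kcal/mol) and entropy
    (cal/(mol*K)); the remaining 6 dinucleotides follow by
    reverse-complement symmetry.  ``init_dH``/``init_dS`` are charged once
    per duplex.  The imperfect-duplex penalties are temperature-independent
    free energies in kcal/mol.
    """

    stack_dH: dict[str, float]
    stack_dS: dict[str, float]
    init_dH: float
    init_dS: float
    mismatch_penalty_dG: float
    loop_open_dG: float
    loop_extend_dG: float

    def stack_dg(self, dinucleotide: str, temperature_celsius: float) -> float:
        """Free energy of one stack at the given temperature."""
        key = dinucleotide if dinucleotide in self.stack_dH else _revcomp2(dinucleotide)
        t_kelvin = temperature_celsius + 273.15
        return self.stack_dH[key] - t_kelvin * self.stack_dS[key] / 1000.0

    def init_dg(self, temperature_celsius: float) -> float:
        t_kelvin = temperature_celsius + 273.15
        return self.init_dH - t_kelvin * self.init_dS / 1000.0

    def stack_dg_table(self, temperature_celsius: float) -> np.ndarray:
        """4x4 array of stack free energies indexed by top-strand codes."""
        table = np.empty((4, 4), dtype=np.float64)
        for x in "ATCG":
            for y in "ATCG":
                table[_CODE[x], _CODE[y]] = self.stack_dg(x + y, temperature_celsius)
        return table


def _revcomp2(d: str) -> str:
    return _RC[d[1]] + _RC[d[0]]


def load_parameters() -> NNParameterTable:
    """Load the bundled, versioned nearest-neighbor parameter file."""
    text = (
        importlib.resources.files("hybriclass.data")
        .joinpath("nn_params.txt")
        .read_text()
    )
    values: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, val = line.split()
        values[key] = float(val)
    stack_dH = {s: values[f"stack_{s}_dH"] for s in _WC_STACKS}
    stack_dS = {s: values[f"stack_{s}_dS"] for s in _WC_STACKS}
    return NNParameterTable(
        stack_dH=stack_dH,
        stack_dS=stack_dS,
        init_dH=values["init_dH"],
        init_dS=values["init_dS"],
        mismatch_penalty_dG=values["mismatch_penalty_dG"],
        loop_open_dG=values["loop_open_dG"],
        loop_extend_dG=values["loop_extend_dG"],
    )


_DEFAULT_PARAMS: NNParameterTable | None = None


def default_parameters() -> NNParameterTable:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = load_parameters()
    return _DEFAULT_PARAMS


@dataclass
class HybridizationConditions:
    """Reaction conditions governing every yield computation.

    Defaults follow the protocol used throughout the package: 25 degrees C,
    both strands at 1 nM, and complexes of at most two strands.
    """

    temperature_celsius: float = 25.0
    initial_concentration_molar: float = 1e-9
    max_complex_size: int = 2
    backend: str = "builtin_two_state"
    params: NNParameterTable = field(default_factory=default_parameters)

    def __post_init__(self) -> None:
        if not 0.0 <= self.temperature_celsius <= 100.0:
            raise ValueError("temperature must be within [0, 100] degrees C")
        if self.initial_concentration_molar <= 0:
            raise ValueError("concentration must be positive")
        if self.max_complex_size != 2:
            raise ValueError("only complexes of size 2 are supported")
        if self.backend not in ("builtin_two_state", "external_adapter"):
            raise ValueError(f"unknown backend {self.backend!r}")


#: Adapter registry for the external backend.  An adapter is a callable
#: (seq_a, seq_b, conditions) -> yield in [0, 1].
_ADAPTER: Callable[[str, str, HybridizationConditions], float] | None = None


def register_adapter(fn: Callable[[str, str, HybridizationConditions], float] | None) -> None:
    """Register (or clear, with ``None``) the external yield adapter."""
    global _ADAPTER
    _ADAPTER = fn


def duplex_free_energy(
    a: str,
    b: str,
    params: NNParameterTable | None = None,
    temperature_celsius: float = 25.0,
) -> float:
    """Minimum duplex free energy of strands ``a`` and ``b`` in kcal/mol.

    Returns :data:`NO_BINDING` (+inf) when no Watson-Crick pair can form at
    any registration, or when either strand is shorter than two bases.
    """
    validate_sequence(a)
    validate_sequence(b)
    params = params or default_parameters()
    a_codes = encode_batch([a])[0]
    b_rc_codes = encode_batch([reverse_complement(b)])[0]
    return float(
        _dp._duplex_dg_codes(
            a_codes,
            b_rc_codes,
            params.stack_dg_table(temperature_celsius),
            params.init_dg(temperature_celsius),
            params.mismatch_penalty_dG,
            params.loop_open_dG,
            params.loop_extend_dG,
        )
    )


def equilibrium_yield(delta_g: float, conditions: HybridizationConditions) -> float:
    """Two-state equilibrium duplex fraction for a given duplex dG.

    Solves ``K*c0*(1-y)**2 = y`` with ``K = exp(-dG/RT)`` (reference state
    1 M) and both strands initially at ``c0``.  The numerically stable root
    of the quadratic is ``y = 2x / (2x + 1 + sqrt(4x + 1))`` with
    ``x = K*c0``, which is exact for x -> 0 and x -> inf alike.
    """
    if np.isinf(delta_g) and delta_g > 0:
        return 0.0
    t_kelvin = conditions.temperature_celsius + 273.15
    log_x = -delta_g / (R_KCAL * t_kelvin) + np.log(conditions.initial_concentration_molar)
    if log_x > 700.0:  # K*c0 overflows; yield is 1 to machine precision
        return 1.0
    x = np.exp(log_x)
    return float(2.0 * x / (2.0 * x + 1.0 + np.sqrt(4.0 * x + 1.0)))


def predict_yield(a: str, b: str, conditions: HybridizationConditions | None = None) -> float:
    """Equilibrium hybridization yield of the two physical strands as given.

    The builtin backend composes :func:`duplex_free_energy` with
    :func:`equilibrium_yield`; callers pass the actual strands (the
    classifier passes the query's reverse complement explicitly as the
    probe).  Symmetric in its two arguments.
    """
    conditions = conditions or HybridizationConditions()
    if conditions.backend == "external_adapter":
        if _ADAPTER is None:
            raise BackendError(
                "backend 'external_adapter' selected but no adapter registered; "
                "call thermo.register_adapter(fn) first"
            )
        return float(_ADAPTER(a, b, conditions))
    dg = duplex_free_energy(
        a, b, conditions.params, conditions.temperature_celsius
    )
    return equilibrium_yield(dg, conditions)


def yield_matrix(
    queries: Sequence[str],
    targets: Sequence[str],
    conditions: HybridizationConditions | None = None,
    chunk_size: int = 256,
) -> np.ndarray:
    """Pairwise yields: element (i, j) is ``predict_yield(queries[i], targets[j])``.

    The builtin backend evaluates the free-energy DP in compiled chunks;
    results are identical to calling :func:`predict_yield` elementwise.
    """
    if len(queries) == 0 or len(targets) == 0:
        raise ValueError("queries and targets must be non-empty")
    conditions = conditions or HybridizationConditions()
    if conditions.backend == "external_adapter":
        out = np.empty((len(queries), len(targets)))
        for i, q in enumerate(queries):
            for j, t in enumerate(targets):
                out[i, j] = predict_yield(q, t, conditions)
        return out
    params = conditions.params
    stack = params.stack_dg_table(conditions.temperature_celsius)
    init = params.init_dg(conditions.temperature_celsius)
    A = encode_batch(list(queries))
    B_rc = encode_batch([reverse_complement(t) for t in targets])
    out = np.empty((len(queries), len(targets)))
    for start in range(0, len(queries), chunk_size):
        stop = min(start + chunk_size, len(queries))
        dg = _dp._dg_matrix_codes(
            A[start:stop],
            B_rc,
            stack,
            init,
            params.mismatch_penalty_dG,
            params.loop_open_dG,
            params.loop_extend_dG,
        )
        out[start:stop] = _equilibrium_yield_array(dg, conditions)
    return out


def pair_yields(
    firsts: Sequence[str],
    seconds: Sequence[str],
    conditions: HybridizationConditions | None = None,
) -> np.ndarray:
    """Elementwise yields of aligned pair lists: ``predict_yield(firsts[i],
    seconds[i])`` for every i, evaluated in one compiled pass."""
    if len(firsts) != len(seconds) or len(firsts) == 0:
        raise ValueError("firsts and seconds must be equal-length, non-empty lists")
    conditions = conditions or HybridizationConditions()
    if conditions.backend == "external_adapter":
        return np.array([predict_yield(a, b, conditions) for a, b in zip(firsts, seconds)])
    params = conditions.params
    dg = _dp._dg_pairs_codes(
        encode_batch(list(firsts)),
        encode_batch([reverse_complement(b) for b in seconds]),
        params.stack_dg_table(conditions.temperature_celsius),
        params.init_dg(conditions.temperature_celsius),
        params.mismatch_penalty_dG,
        params.loop_open_dG,
        params.loop_extend_dG,
    )
    return _equilibrium_yield_array(dg, conditions)


def _equilibrium_yield_array(dg: np.ndarray, conditions: HybridizationConditions) -> np.ndarray:
    t_kelvin = conditions.temperature_celsius + 273.15
    log_x = np.where(
        np.isposinf(dg),
        -np.inf,
        -dg / (R_KCAL * t_kelvin) + np.log(conditions.initial_concentration_molar),
    )
    y = np.empty_like(log_x)
    hi = log_x > 700.0
    y[hi] = 1.0
    x = np.exp(log_x[~hi])
    y[~hi] = 2.0 * x / (2.0 * x + 1.0 + np.sqrt(4.0 * x + 1.0))
    return y
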