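"""Boltzmann-ensemble computations over nested RNA secondary structures.

The default ("simple") energy model assigns one stacking-free energy per
base pair (GC -3.0, AU -2.0, GU -1.0 kcal/mol), no loop terms, and a
minimum hairpin loop of 3 nt.  Under it the partition function

    Z = sum over all nested structures S of exp(-E(S) / (R*T)),
    E(S) = sum of pair energies, open chain included with E = 0,

is computed by a McCaskill-style O(n^3) dynamic program in log space.
Hard constraints (a set of required pairs) restrict the sum to structures
containing all of them; the probability that a given stem-loop forms in
sequence context is the ratio of the constrained to the total partition
function.  An exhaustive enumeration of the ensemble is provided as an
independent reference for short sequences.

An optional "turner" backend delegates the same two-partition-function
ratio to ViennaRNA's full nearest-neighbour model for work that needs
quantitative fidelity rather than provable correctness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .seqio import RNA_ALPHABET, ValidationError

GAS_CONSTANT_R = 1.9872e-3  # kcal / (mol * K)
MIN_HAIRPIN = 3  # unpaired nt strictly between a pair
NEG_INF = float("-inf")

__all__ = [
    "GAS_CONSTANT_R",
    "EnergyModel",
    "FoldResult",
    "partition_function",
    "log_partition_function",
    "constrained_probability",
    "probability_vs_temperature",
    "pair_probability_matrix",
    "enumerate_structures",
    "enumeration_partition",
    "celsius_to_kelvin",
]


def celsius_to_kelvin(t_c: float) -> float:
    if t_c <= -273.15:
        raise ValidationError(f"temperature {t_c} degC is at or below absolute zero")
    return t_c + 273.15


@dataclass(frozen=True)
class EnergyModel:
    """Backend selection plus simple-backend pair energies (kcal/mol)."""

    backend: str = "simple"
    pair_energies: dict = field(
        default_factory=lambda: {"GC": -3.0, "AU": -2.0, "GU": -1.0}
    )
    temperature: float = 310.15  # kelvin
    allow_GU: bool = True

    def __post_init__(self) -> None:
        if self.backend not in ("simple", "turner"):
            raise ValidationError(f"unknown backend {self.backend!r}")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive kelvin")

    def with_temperature_celsius(self, t_c: float) -> "EnergyModel":
        return replace(self, temperature=celsius_to_kelvin(t_c))

    @property
    def beta(self) -> float:
        return 1.0 / (GAS_CONSTANT_R * self.temperature)

    def pair_energy(self, a: str, b: str) -> float | None:
        """Energy of pair (a, b), or None if not pairable."""
        key = "".join(sorted((a, b)))
        # sorted keys: CG, AU, GU
        if key == "CG":
            return self.pair_energies["GC"]
        if key == "AU":
            return self.pair_energies["AU"]
        if key == "GU" and self.allow_GU:
            return self.pair_energies["GU"]
        return None


@dataclass(frozen=True)
class FoldResult:
    """Partition-function outputs at one temperature."""

    log_z_total: float
    log_z_constrained: float
    temperature: float  # kelvin

    @property
    def z_total(self) -> float:
        return math.exp(self.log_z_total)

    @property
    def z_constrained(self) -> float:
        return math.exp(self.log_z_constrained)

    @property
    def p_substructure(self) -> float:
        if self.log_z_constrained == NEG_INF:
            return 0.0
        return min(1.0, math.exp(self.log_z_constrained - self.log_z_total))


def _check_sequence(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = sorted(set(seq) - RNA_ALPHABET)
    if not seq:
        raise ValidationError("empty sequence")
    if bad:
        raise ValidationError(f"invalid characters in sequence: {bad}")
    return seq


def _pair_log_weights(seq: str, model: EnergyModel) -> np.ndarray:
    """lw[i, j] = log Boltzmann weight of pair (i, j), -inf if impossible."""
    n = len(seq)
    lw = np.full((n, n), NEG_INF)
    beta = model.beta
    for i in range(n):
        for j in range(i + MIN_HAIRPIN + 1, n):
            e = model.pair_energy(seq[i], seq[j])
            if e is not None:
                lw[i, j] = -beta * e
    return lw


def _validate_constraints(seq: str, required_pairs, model: EnergyModel) -> dict:
    """Return a position->partner map, or raise for impossible constraints."""
    req: dict[int, int] = {}
    pairs = sorted(tuple(p) for p in required_pairs)
    n = len(seq)
    for i, j in pairs:
        if not (0 <= i < j < n):
            raise ValidationError(f"required pair ({i},{j}) out of bounds")
        if j - i - 1 < MIN_HAIRPIN:
            raise ValidationError(
                f"required pair ({i},{j}) violates the {MIN_HAIRPIN}-nt "
                "minimum hairpin loop"
            )
        if model.pair_energy(seq[i], seq[j]) is None:
            raise ValidationError(
                f"required pair ({i},{j}) is not complementary "
                f"({seq[i]}-{seq[j]})"
            )
        if i in req or j in req:
            raise ValidationError(f"position reused in required pairs at ({i},{j})")
        req[i] = j
        req[j] = i
    # nestedness: no i < k < j < l among required pairs
    open_pairs = [(i, j) for i, j in pairs]
    for a, (i, j) in enumerate(open_pairs):
        for k, l in open_pairs[a + 1:]:
            if i < k < j < l:
                raise ValidationError(
                    f"required pairs ({i},{j}) and ({k},{l}) cross"
                )
    return req


def _log_dp(seq: str, lw: np.ndarray, req: dict[int, int] | None) -> np.ndarray:
    """LZ[i][j] = log partition function of the half-open span seq[i:j].

    With constraints, spans that cannot realize all required pairs whose
    5' partner lies inside them get weight 0 (-inf), which propagates the
    hard constraint exactly.
    """
    n = len(seq)
    LZ = np.full((n + 1, n + 1), NEG_INF)
    for i in range(n + 1):
        LZ[i, i] = 0.0
    req = req or {}
    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            terms = []
            partner = req.get(i)
            if partner is None or partner < i:
                # i unpaired is allowed only when i carries no constraint
                # (a partner < i can never occur: spans never split pairs
                #  that the recursion itself placed)
                if i not in req:
                    terms.append(LZ[i + 1, j])
            ks = (
                range(i + MIN_HAIRPIN + 1, j)
                if partner is None
                else ([partner] if i + MIN_HAIRPIN + 1 <= partner < j else [])
            )
            for k in ks:
                if lw[i, k] == NEG_INF:
                    continue
                if k in req and req[k] != i:
                    continue
                inner = LZ[i + 1, k]
                outer = LZ[k + 1, j]
                if inner == NEG_INF or outer == NEG_INF:
                    continue
                terms.append(lw[i, k] + inner + outer)
            terms = [t for t in terms if t > NEG_INF]
            if terms:
                arr = np.array(terms)
                m = arr.max()
                LZ[i, j] = m + math.log(np.exp(arr - m).sum())
    return LZ


def log_partition_function(seq: str, model: EnergyModel, required_pairs=None) -> float:
    """Log partition function, optionally with required-pair hard constraints."""
    seq = _check_sequence(seq)
    if model.backend != "simple":
        raise ValidationError("log partition values are exposed for the simple backend")
    req = _validate_constraints(seq, required_pairs, model) if required_pairs else None
    lw = _pair_log_weights(seq, model)
    return float(_log_dp(seq, lw, req)[0, len(seq)])


def partition_function(seq: str, model: EnergyModel) -> float:
    """Total ensemble weight Z (>= 1: the open chain contributes 1)."""
    return math.exp(log_partition_function(seq, model))


def _turner_constrained_probability(seq, required_pairs, temperature_k) -> FoldResult:
    import RNA  # ViennaRNA bindings; optional backend

    t_c = temperature_k - 273.15
    md = RNA.md()
    md.temperature = t_c
    seq_dna = seq
    fc = RNA.fold_compound(seq_dna, md)
    _, f_total = fc.pf()
    fc_c = RNA.fold_compound(seq_dna, md)
    for i, j in sorted(required_pairs):
        fc_c.hc_add_bp(
            i + 1, j + 1, RNA.CONSTRAINT_CONTEXT_ALL_LOOPS | RNA.CONSTRAINT_CONTEXT_ENFORCE
        )
    _, f_constrained = fc_c.pf()
    rt = GAS_CONSTANT_R * temperature_k
    return FoldResult(
        log_z_total=-f_total / rt,
        log_z_constrained=-f_constrained / rt,
        temperature=temperature_k,
    )


def constrained_probability(seq: str, required_pairs, model: EnergyModel) -> FoldResult:
    """Probability that all ``required_pairs`` form, in full-sequence context.

    An empty constraint set yields p = 1 exactly.  A required pair that is
    non-complementary, crossing, or sterically impossible raises
    :class:`ValidationError` — distinct from p = 0 for a legal but
    thermodynamically unfavourable constraint.
    """
    seq = _check_sequence(seq)
    required_pairs = sorted(tuple(p) for p in (required_pairs or []))
    _validate_constraints(seq, required_pairs, model)
    if model.backend == "turner":
        return _turner_constrained_probability(seq, required_pairs, model.temperature)
    lw = _pair_log_weights(seq, model)
    lz_total = float(_log_dp(seq, lw, None)[0, len(seq)])
    if not required_pairs:
        lz_con = lz_total
    else:
        req = _validate_constraints(seq, required_pairs, model)
        lz_con = float(_log_dp(seq, lw, req)[0, len(seq)])
    return FoldResult(
        log_z_total=lz_total, log_z_constrained=lz_con, temperature=model.temperature
    )


def probability_vs_temperature(
    seq: str, required_pairs, model: EnergyModel, t_grid_celsius
) -> list[tuple[float, FoldResult]]:
    """FoldResult at each temperature of a Celsius grid (e.g. 25-28 degC)."""
    t_grid = list(t_grid_celsius)
    if not t_grid:
        raise ValidationError("empty temperature grid")
    out = []
    for t_c in t_grid:
        m = model.with_temperature_celsius(t_c)
        out.append((t_c, constrained_probability(seq, required_pairs, m)))
    return out


def pair_probability_matrix(seq: str, model: EnergyModel) -> np.ndarray:
    """P[i, j] = probability that pair (i, j) forms (simple backend).

    Inside-outside recursion over the unambiguous decomposition used by
    the partition function; O(n^4) with vectorized inner sums, adequate
    for the alignment-row lengths the conservation analysis uses.
    """
    seq = _check_sequence(seq)
    if model.backend != "simple":
        raise ValidationError("pair_probability_matrix implements the simple backend")
    n = len(seq)
    lw = _pair_log_weights(seq, model)
    LZ = _log_dp(seq, lw, None)
    lz_total = LZ[0, n]
    pairable = [(i, j) for i in range(n) for j in range(n) if lw[i, j] > NEG_INF]
    # outside weights, computed in decreasing span order
    LO = np.full((n, n), NEG_INF)
    for i, j in sorted(pairable, key=lambda p: p[0] - p[1]):
        terms = [LZ[0, i] + LZ[j + 1, n]]
        if i > 0 and j < n - 1:
            # enclosing pairs (k, l), k < i, l > j, with (k, l) the direct
            # (innermost) enclosing pair: gaps fill independently
            block = LO[:i, j + 1:] + lw[:i, j + 1:]
            if np.any(block > NEG_INF):
                left = LZ[1:i + 1, i]        # LZ[k+1, i] for k in 0..i-1
                right = LZ[j + 1, j + 1:n]   # LZ[j+1, l] for l in j+1..n-1
                full = block + left[:, None] + right[None, :]
                m = full.max()
                if m > NEG_INF:
                    terms.append(m + math.log(np.exp(full - m).sum()))
        arr = np.array(terms)
        m = arr.max()
        LO[i, j] = m + math.log(np.exp(arr - m).sum())
    P = np.zeros((n, n))
    for i, j in pairable:
        lzb = lw[i, j] + LZ[i + 1, j]
        val = lzb + LO[i, j] - lz_total
        P[i, j] = math.exp(val) if val < 0 else min(1.0, math.exp(val))
    return P


# ---------------------------------------------------------------------------
# Exhaustive enumeration: the independent reference for short sequences.
# ---------------------------------------------------------------------------

def enumerate_structures(seq: str, model: EnergyModel) -> Iterator[frozenset]:
    """Yield every valid nested structure (as a frozenset of pairs).

    Exponential; intended for sequences short enough that the ensemble is
    explicitly countable.  Kept free of the dynamic program so it can act
    as an independent reference.
    """
    seq = _check_sequence(seq)
    n = len(seq)
    pairable = {}
    for i in range(n):
        pairable[i] = [
            j
            for j in range(i + MIN_HAIRPIN + 1, n)
            if model.pair_energy(seq[i], seq[j]) is not None
        ]

    def rec(i: int, j: int) -> list[frozenset]:
        # structures of the half-open span [i, j)
        if j - i <= 0:
            return [frozenset()]
        out = []
        for s in rec(i + 1, j):  # i unpaired
            out.append(s)
        for k in pairable[i]:
            if k >= j:
                break
            for inner in rec(i + 1, k):
                for outer in rec(k + 1, j):
                    out.append(inner | outer | {(i, k)})
        return out

    yield from rec(0, n)


def enumeration_partition(
    seq: str, model: EnergyModel, required_pairs=None
) -> tuple[float, float]:
    """(Z_total, Z_constrained) by brute-force enumeration."""
    seq = _check_sequence(seq)
    required = {tuple(p) for p in (required_pairs or [])}
    beta = model.beta
    z_total = 0.0
    z_con = 0.0
    for s in enumerate_structures(seq, model):
        e = sum(model.pair_energy(seq[i], seq[j]) for i, j in s)
        w = math.exp(-beta * e)
        z_total += w
        if required <= s:
            z_con += w
    return z_total, z_con
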