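"""Shared fixtures: fixture sequence sets and independent oracles."""

from __future__ import annotations

import random

import pytest

from dlekit.rna_thermo import EnergyModel


@pytest.fixture(scope="session")
def simple_model() -> EnergyModel:
    return EnergyModel()


@pytest.fixture(scope="session")
def short_fixture_sequences() -> list[str]:
    """Deterministic set of sequences <= 14 nt for enumeration checks."""
    rng = random.Random(1)
    seqs = ["AAAA", "GAAAC", "GGGAAAACCC", "GCACUUGGGAAAAACCC"[:14], "ACGUACGUACGUAC"]
    for _ in range(30):
        n = rng.randint(4, 14)
        seqs.append("".join(rng.choice("ACGU") for _ in range(n)))
    return seqs


def brute_force_scan(seq: str, d, region=None):
    """Exhaustive-decomposition oracle for the DLE grammar.

    Tests every (anchor, spacer, stem, loop) decomposition independently
    of the scanner's search strategy; returns tuples
    (anchor_start, spacer_len, stem_bp, loop_len).
    """
    from dlekit.dle_scan import can_pair

    n = len(seq)
    lo, hi = (0, n) if region is None else region
    out = []
    for a in range(lo, hi - len(d.anchor) + 1):
        if seq[a:a + len(d.anchor)] != d.anchor:
            continue
        if d.require_preceding_A and (a == 0 or seq[a - 1] != "A"):
            continue
        ae = a + len(d.anchor)
        for s in range(d.spacer_min, d.spacer_max + 1):
            spacer = seq[ae:ae + s]
            if len(spacer) < s:
                continue
            if d.spacer_alphabet == "pyrimidine" and set(spacer) - set("UC"):
                continue
            for k in range(d.stem_min_bp, d.stem_max_bp + 1):
                for l in range(d.loop_min, d.loop_max + 1):
                    end = ae + s + k + l + k
                    if end > hi:
                        continue
                    stem5 = ae + s
                    ok = all(
                        can_pair(seq[stem5 + m], seq[end - 1 - m], d.allow_GU)
                        for m in range(k)
                    )
                    if ok:
                        out.append((a, s, k, l))
    return out
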