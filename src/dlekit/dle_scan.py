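"""Composite DLE motif grammar matching.

The dorsal localization element (DLE) is a bipartite 3'UTR element: a short
GCAC-anchored sequence motif followed, after a short spacer, by a hairpin
(stem-loop).  Two presets mirror the two descriptor variants used in
practice:

* ``relaxed`` — anchor GCAC, spacer of 2-5 nucleotides of any identity,
  a stem of at least 3 bp, and a variable loop (3-30 nt by default).
* ``strict``  — anchor GCAC, spacer of 2-3 pyrimidines (U/C), stem of
  3-20 bp, loop of 5-12 nt.  Used for cross-species screens where false
  positives are costlier.

A match is a full decomposition anchor|spacer|stem5|loop|stem3 with every
stem position base-paired (Watson-Crick, plus G.U wobble unless disabled).
Overlapping decompositions at one anchor are collapsed to the
maximal-stem representative per (anchor, loop-start); full enumeration is
available via ``enumerate_all=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .seqio import Interval, Transcript, ValidationError

PYRIMIDINES = frozenset("UC")

WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
GU_PAIRS = frozenset({("G", "U"), ("U", "G")})

__all__ = [
    "DleDescriptor",
    "DleMatch",
    "RELAXED",
    "STRICT",
    "PRESETS",
    "can_pair",
    "match_dle",
    "apply_mutant",
    "MUTANT_KINDS",
]


def can_pair(a: str, b: str, allow_gu: bool = True) -> bool:
    """Whether bases a, b can form a pair under the descriptor's rule."""
    return (a, b) in WC_PAIRS or (allow_gu and (a, b) in GU_PAIRS)


@dataclass(frozen=True)
class DleDescriptor:
    """Parameterized composite motif grammar."""

    name: str = "custom"
    anchor: str = "GCAC"
    require_preceding_A: bool = False
    spacer_min: int = 2
    spacer_max: int = 5
    spacer_alphabet: str = "any"  # "any" or "pyrimidine"
    stem_min_bp: int = 3
    stem_max_bp: int = 20
    loop_min: int = 3
    loop_max: int = 30
    allow_GU: bool = True

    def __post_init__(self) -> None:
        if not self.anchor or set(self.anchor) - set("ACGU"):
            raise ValidationError(f"bad anchor {self.anchor!r}")
        if not (0 <= self.spacer_min <= self.spacer_max):
            raise ValidationError("need 0 <= spacer_min <= spacer_max")
        if not (1 <= self.stem_min_bp <= self.stem_max_bp):
            raise ValidationError("need 1 <= stem_min_bp <= stem_max_bp")
        if not (3 <= self.loop_min <= self.loop_max):
            # hairpin loops shorter than 3 nt are sterically disallowed
            raise ValidationError("need 3 <= loop_min <= loop_max")
        if self.spacer_alphabet not in ("any", "pyrimidine"):
            raise ValidationError(f"bad spacer_alphabet {self.spacer_alphabet!r}")

    def spacer_ok(self, s: str) -> bool:
        if self.spacer_alphabet == "pyrimidine":
            return all(c in PYRIMIDINES for c in s)
        return True


RELAXED = DleDescriptor(
    name="relaxed",
    spacer_min=2,
    spacer_max=5,
    spacer_alphabet="any",
    stem_min_bp=3,
    stem_max_bp=20,
    loop_min=3,
    loop_max=30,
)

STRICT = DleDescriptor(
    name="strict",
    spacer_min=2,
    spacer_max=3,
    spacer_alphabet="pyrimidine",
    stem_min_bp=3,
    stem_max_bp=20,
    loop_min=5,
    loop_max=12,
)

PRESETS = {"relaxed": RELAXED, "strict": STRICT}


@dataclass(frozen=True)
class DleMatch:
    """One grammar hit: adjacent anchor|spacer|stem5|loop|stem3 intervals.

    ``pairs`` lists (i, j) stem base pairs with the 5' index first,
    outermost pair first.
    """

    transcript_id: str
    anchor: Interval
    spacer: Interval
    stem5: Interval
    loop: Interval
    stem3: Interval
    pairs: tuple[tuple[int, int], ...]
    descriptor_name: str = ""

    @property
    def span(self) -> Interval:
        """Anchor through stem3, the whole element."""
        return Interval(self.anchor.start, self.stem3.end)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def element_seq(self, t: Transcript) -> str:
        return t.subseq(self.span)


def _find_anchors(seq: str, d: DleDescriptor, region: Interval) -> list[int]:
    anchors = []
    start = region.start
    while True:
        pos = seq.find(d.anchor, start, region.end)
        if pos == -1:
            break
        if not d.require_preceding_A or (pos > 0 and seq[pos - 1] == "A"):
            anchors.append(pos)
        start = pos + 1
    return anchors


def match_dle(
    t: Transcript,
    d: DleDescriptor,
    region: Interval | None = None,
    enumerate_all: bool = False,
) -> list[DleMatch]:
    """Match the composite grammar; see module docstring for collapsing.

    ``region`` defaults to the whole 3'UTR; the entire element
    (anchor through stem3) must fit inside it.  Matches are reported in
    left-to-right anchor order, then loop-start order (deterministic).
    """
    seq = t.seq
    if region is None:
        region = Interval(t.utr_start, len(seq))
    if region.end > len(seq):
        raise ValidationError(
            f"region [{region.start},{region.end}) outside transcript "
            f"{t.id!r} of length {len(seq)}"
        )
    hits: list[DleMatch] = []
    for a in _find_anchors(seq, d, region):
        ae = a + len(d.anchor)
        # best decomposition per loop-start: (n_pairs, -loop_len) maximal
        per_loopstart: dict[int, DleMatch] = {}
        enumerated: list[DleMatch] = []
        for s_len in range(d.spacer_min, d.spacer_max + 1):
            spacer = seq[ae:ae + s_len]
            if len(spacer) < s_len or not d.spacer_ok(spacer):
                continue
            stem5_start = ae + s_len
            for k in range(d.stem_min_bp, d.stem_max_bp + 1):
                loop_start = stem5_start + k
                for l_len in range(d.loop_min, d.loop_max + 1):
                    stem3_start = loop_start + l_len
                    stem3_end = stem3_start + k
                    if stem3_end > region.end:
                        break
                    ok = all(
                        can_pair(seq[stem5_start + m], seq[stem3_end - 1 - m], d.allow_GU)
                        for m in range(k)
                    )
                    if not ok:
                        continue
                    pairs = tuple(
                        (stem5_start + m, stem3_end - 1 - m) for m in range(k)
                    )
                    match = DleMatch(
                        transcript_id=t.id,
                        anchor=Interval(a, ae),
                        spacer=Interval(ae, stem5_start),
                        stem5=Interval(stem5_start, loop_start),
                        loop=Interval(loop_start, stem3_start),
                        stem3=Interval(stem3_start, stem3_end),
                        pairs=pairs,
                        descriptor_name=d.name,
                    )
                    if enumerate_all:
                        enumerated.append(match)
                    else:
                        prev = per_loopstart.get(loop_start)
                        if prev is None or (k, -len(match.loop)) > (
                            prev.n_pairs,
                            -len(prev.loop),
                        ):
                            per_loopstart[loop_start] = match
        if enumerate_all:
            enumerated.sort(key=lambda m: (m.loop.start, -m.n_pairs, len(m.loop)))
            hits.extend(enumerated)
        else:
            hits.extend(per_loopstart[ls] for ls in sorted(per_loopstart))
    return hits


MUTANT_KINDS = ("dG", "dSL", "dGSL", "SM", "SR", "LM")

_UNICODE_ALIASES = {"ΔG": "dG", "ΔSL": "dSL", "ΔGSL": "dGSL"}

# substitution that cannot pair (even as wobble) with the given partner base
_PAIR_BREAKER = {"A": "C", "C": "A", "G": "A", "U": "C"}


def _delete(seq: str, iv: Interval) -> str:
    return seq[: iv.start] + seq[iv.end:]


def apply_mutant(t: Transcript, match: DleMatch, kind: str) -> Transcript:
    """Apply one of the classic DLE mutants, defined against a located match.

    dG   delete the anchor sequence motif
    dSL  delete the stem-loop (stem5+loop+stem3)
    dGSL delete both the anchor and the stem-loop
    SM   substitute the 5' stem arm to abolish complementarity (stem mutant)
    SR   swap the two stem arms (stem restore: pairing preserved)
    LM   substitute the loop sequence (alternating UC), structure untouched
    """
    kind = _UNICODE_ALIASES.get(kind, kind)
    if kind not in MUTANT_KINDS:
        raise ValidationError(f"unknown mutant kind {kind!r}; use one of {MUTANT_KINDS}")
    if match.stem3.end > len(t.seq):
        raise ValidationError("match coordinates outside transcript")
    seq = t.seq
    if kind == "dG":
        new = _delete(seq, match.anchor)
    elif kind == "dSL":
        new = _delete(seq, Interval(match.stem5.start, match.stem3.end))
    elif kind == "dGSL":
        new = _delete(seq, Interval(match.stem5.start, match.stem3.end))
        new = _delete(new, match.anchor)
    elif kind == "SM":
        stem3 = seq[match.stem3.start:match.stem3.end]
        k = len(stem3)
        # stem5[m] pairs stem3[k-1-m]; break each pair
        new5 = "".join(_PAIR_BREAKER[stem3[k - 1 - m]] for m in range(k))
        new = seq[: match.stem5.start] + new5 + seq[match.stem5.end:]
    elif kind == "SR":
        arm5 = seq[match.stem5.start:match.stem5.end]
        arm3 = seq[match.stem3.start:match.stem3.end]
        new = (
            seq[: match.stem5.start]
            + arm3
            + seq[match.stem5.end:match.stem3.start]
            + arm5
            + seq[match.stem3.end:]
        )
    else:  # LM
        loop_len = len(match.loop)
        new_loop = ("UC" * loop_len)[:loop_len]
        new = seq[: match.loop.start] + new_loop + seq[match.loop.end:]
    deleted_before_utr = 0
    if kind in ("dG", "dSL", "dGSL"):
        removed = [match.anchor] if kind == "dG" else []
        if kind in ("dSL", "dGSL"):
            removed.append(Interval(match.stem5.start, match.stem3.end))
        if kind == "dGSL":
            removed.append(match.anchor)
        for iv in removed:
            deleted_before_utr += max(0, min(iv.end, t.utr_start) - iv.start)
    return replace(
        t, seq=new, utr_start=t.utr_start - deleted_before_utr, id=f"{t.id}_{kind}"
    )
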