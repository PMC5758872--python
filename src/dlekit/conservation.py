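"""Cross-species DLE conservation: orthologue scan, alignment, consensus.

The orthologue analysis runs the strict descriptor over each species'
longest 3'UTR (plus up to 100 nt of trailing CDS context), aligns the
matched element regions, and scores a consensus structure by averaging
each sequence's base-pair probabilities (from the thermodynamic model)
through the alignment columns.  A column pair's averaged probability is
its *pair reliability*; the consensus dot-bracket is a greedy
maximum-reliability nested matching over column pairs above threshold.

This is a deliberately transparent surrogate for tree-weighted consensus
structure predictors: it uses evolutionary information only through the
averaging, not through a phylogeny, and is documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dle_scan import DleDescriptor, DleMatch, STRICT, match_dle
from .rna_thermo import EnergyModel, pair_probability_matrix
from .seqio import AlignmentSet, Interval, Transcript, ValidationError

__all__ = [
    "ConsensusStructure",
    "scan_orthologues",
    "motif_region",
    "align_motif_regions",
    "consensus_structure",
    "progressive_align",
]

GAP = "-"

# Needleman-Wunsch scores for the motif-region aligner
MATCH = 2.0
MISMATCH = -1.0
GAP_OPEN = -4.0
GAP_EXTEND = -1.0


def scan_orthologues(
    transcripts: list[Transcript],
    descriptor: DleDescriptor = STRICT,
    cds_context: int = 100,
) -> list[DleMatch]:
    """Strict-preset matches per species, scanning UTR + trailing CDS context.

    Each transcript contributes the matches found in the window starting
    ``cds_context`` nucleotides before its 3'UTR (or at the start of the
    available CDS context when shorter).  Species with no match are simply
    absent from the output.
    """
    out = []
    for t in transcripts:
        start = max(0, t.utr_start - cds_context)
        region = Interval(start, len(t.seq))
        out.extend(match_dle(t, descriptor, region=region))
    return out


def motif_region(match: DleMatch, t: Transcript, flanks: int = 10) -> tuple[str, Interval]:
    """The element +- flanks, clamped to the transcript."""
    iv = Interval(
        max(0, match.anchor.start - flanks), min(len(t.seq), match.stem3.end + flanks)
    )
    return t.subseq(iv), iv


def _score(col_counts: dict[str, int], n_rows: int, base: str) -> float:
    s = 0.0
    for b, c in col_counts.items():
        s += c * (MATCH if b == base else MISMATCH)
    return s / n_rows


def _align_seq_to_profile(
    profile: list[dict[str, int]], n_rows: int, seq: str
) -> tuple[list[int | None], list[int | None]]:
    """Affine-gap NW of a sequence against a column profile.

    Returns (profile_path, seq_path): aligned column index lists where
    ``None`` marks a gap in that component.  Deterministic tie-break:
    match/mismatch > gap-in-seq > gap-in-profile.
    """
    m, n = len(profile), len(seq)
    neg = float("-inf")
    M = np.full((m + 1, n + 1), neg)   # ends in aligned pair
    X = np.full((m + 1, n + 1), neg)   # ends with gap in seq (profile col vs -)
    Y = np.full((m + 1, n + 1), neg)   # ends with gap in profile (- vs seq char)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for j in range(1, n + 1):
        Y[0, j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = _score(profile[i - 1], n_rows, seq[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND)
            Y[i, j] = max(M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXTEND)
    # traceback
    i, j = m, n
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    prof_path: list[int | None] = []
    seq_path: list[int | None] = []
    while i > 0 or j > 0:
        if state == 0:
            prof_path.append(i - 1)
            seq_path.append(j - 1)
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev)) if (i, j) != (0, 0) else 0
        elif state == 1:
            prof_path.append(i - 1)
            seq_path.append(None)
            opened = M[i - 1, j] + GAP_OPEN
            state = 0 if opened >= X[i - 1, j] + GAP_EXTEND else 1
            i -= 1
        else:
            prof_path.append(None)
            seq_path.append(j - 1)
            opened = M[i, j - 1] + GAP_OPEN
            state = 0 if opened >= Y[i, j - 1] + GAP_EXTEND else 2
            j -= 1
    prof_path.reverse()
    seq_path.reverse()
    return prof_path, seq_path


def progressive_align(named_seqs: list[tuple[str, str]]) -> AlignmentSet:
    """Progressive profile Needleman-Wunsch in input order.

    Scores: match +2, mismatch -1, gap open -4, gap extend -1.  Guide
    order is the input order, so the result is deterministic.
    """
    if not named_seqs:
        raise ValidationError("no sequences to align")
    ids = [name for name, _ in named_seqs]
    rows = [named_seqs[0][1]]
    for _, seq in named_seqs[1:]:
        n_rows = len(rows)
        profile = []
        for col in range(len(rows[0])):
            counts: dict[str, int] = {}
            for r in rows:
                c = r[col]
                if c != GAP:
                    counts[c] = counts.get(c, 0) + 1
            profile.append(counts)
        prof_path, seq_path = _align_seq_to_profile(profile, n_rows, seq)
        new_rows = []
        for r in rows:
            new_rows.append(
                "".join(GAP if p is None else r[p] for p in prof_path)
            )
        new_rows.append(
            "".join(GAP if s is None else seq[s] for s in seq_path)
        )
        rows = new_rows
    return AlignmentSet(rows=list(zip(ids, rows)))


def align_motif_regions(
    matches: list[DleMatch],
    transcripts: list[Transcript],
    flanks: int = 10,
) -> AlignmentSet:
    """Multiple alignment of matched element regions +- flanks.

    A single match is returned as its own trivial alignment.
    """
    if not matches:
        raise ValidationError("no matches to align")
    by_id = {t.id: t for t in transcripts}
    named = []
    for m in matches:
        t = by_id.get(m.transcript_id)
        if t is None:
            raise ValidationError(f"no transcript for match on {m.transcript_id!r}")
        seq, _ = motif_region(m, t, flanks)
        named.append((m.transcript_id, seq))
    return progressive_align(named)


@dataclass
class ConsensusStructure:
    """Alignment-level pair reliabilities and the consensus dot-bracket."""

    columns: int
    pair_reliability: np.ndarray      # (columns, columns), upper triangle used
    single_reliability: np.ndarray    # per column
    conservation: np.ndarray          # per column identity fraction
    dot_bracket: str

    def consensus_pairs(self) -> list[tuple[int, int]]:
        stack: list[int] = []
        pairs = []
        for idx, c in enumerate(self.dot_bracket):
            if c == "(":
                stack.append(idx)
            elif c == ")":
                pairs.append((stack.pop(), idx))
        return sorted(pairs)

    def format_block(self, aln: AlignmentSet) -> str:
        """Aligned rows plus conservation / paired-reliability tracks."""
        width = max(len(rid) for rid, _ in aln.rows) if aln.rows else 10
        width = max(width, len("reliab_paired"))
        lines = [f"{rid:<{width}}  {row}" for rid, row in aln.rows]
        paired_rel = np.zeros(self.columns)
        for i, j in self.consensus_pairs():
            paired_rel[i] = paired_rel[j] = self.pair_reliability[i, j]

        def track(values: np.ndarray) -> str:
            return "".join(str(min(9, int(v * 10))) for v in values)

        lines.append(f"{'structure':<{width}}  {self.dot_bracket}")
        lines.append(f"{'conservation':<{width}}  {track(self.conservation)}")
        lines.append(f"{'reliab_paired':<{width}}  {track(paired_rel)}")
        return "\n".join(lines)


def consensus_structure(
    aln: AlignmentSet,
    model: EnergyModel | None = None,
    pair_threshold: float = 0.5,
) -> ConsensusStructure:
    """Average per-row pair probabilities through alignment columns.

    For each row, base-pair probabilities of its ungapped sequence are
    computed under the thermodynamic model and mapped to column pairs;
    a row contributes 0 to any column pair in which it has a gap.  The
    consensus dot-bracket is the greedy maximum-reliability nested,
    conflict-free matching over column pairs with averaged reliability
    >= ``pair_threshold``.
    """
    if not aln.rows:
        raise ValidationError("empty alignment")
    model = model or EnergyModel()
    ncol = aln.column_count
    nrow = len(aln.rows)
    rel = np.zeros((ncol, ncol))
    single = np.zeros(ncol)
    for _, row in aln.rows:
        cols = [c for c, ch in enumerate(row) if ch != GAP]
        seq = "".join(row[c] for c in cols)
        if not seq:
            continue
        P = pair_probability_matrix(seq, model)
        unpaired = 1.0 - P.sum(axis=0) - P.sum(axis=1)
        for a, col_a in enumerate(cols):
            single[col_a] += max(0.0, unpaired[a])
            for b in range(a + 1, len(cols)):
                if P[a, b] > 0:
                    rel[col_a, cols[b]] += P[a, b]
    rel /= nrow
    single /= nrow
    # column-wise identity fraction (gaps never count toward the majority)
    conservation = np.zeros(ncol)
    for c in range(ncol):
        counts: dict[str, int] = {}
        for _, row in aln.rows:
            ch = row[c]
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        conservation[c] = max(counts.values()) / nrow if counts else 0.0
    # greedy nested matching by descending reliability
    candidates = [
        (rel[i, j], i, j)
        for i in range(ncol)
        for j in range(i + 1, ncol)
        if rel[i, j] >= pair_threshold
    ]
    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))
    chosen: list[tuple[int, int]] = []
    used: set[int] = set()
    for _, i, j in candidates:
        if i in used or j in used:
            continue
        if any(a < i < b < j or i < a < j < b for a, b in chosen):
            continue
        chosen.append((i, j))
        used.update((i, j))
    db = ["."] * ncol
    for i, j in chosen:
        db[i], db[j] = "(", ")"
    return ConsensusStructure(
        columns=ncol,
        pair_reliability=rel,
        single_reliability=single,
        conservation=conservation,
        dot_bracket="".join(db),
    )
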