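"""Sequence-context analysis of DLE hairpin formation.

A simple tandem repeat near a DLE can base-pair against the element's stem
arm and thereby sequester it into alternative structures: the repeat
"masks" the hairpin.  This module finds maximal dinucleotide (by default
CA) repeat runs, performs in-silico deletions, and quantifies how a
deletion changes the probability that the DLE stem forms, per temperature
— reported as the per-temperature fold change p_after / p_before.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .dle_scan import DleDescriptor, DleMatch, match_dle
from .rna_thermo import EnergyModel, probability_vs_temperature
from .seqio import Interval, Transcript, ValidationError

__all__ = [
    "RepeatRun",
    "MaskingReport",
    "find_repeats",
    "delete_interval",
    "masking_analysis",
]

DEFAULT_T_GRID = (25.0, 26.0, 27.0, 28.0)  # degC; common rearing range


@dataclass(frozen=True)
class RepeatRun:
    """A maximal tandem run of ``unit``, e.g. (CA)x8."""

    transcript_id: str
    interval: Interval
    unit: str
    n_units: int


def find_repeats(
    t: Transcript, unit: str = "CA", min_units: int = 4
) -> list[RepeatRun]:
    """All maximal, non-overlapping runs of ``unit`` with >= min_units copies."""
    if not unit or set(unit) - set("ACGU"):
        raise ValidationError(f"invalid repeat unit {unit!r}")
    if min_units < 2:
        raise ValidationError("min_units must be >= 2")
    seq = t.seq
    u = len(unit)
    runs = []
    i = 0
    while i + u <= len(seq):
        if seq[i:i + u] != unit:
            i += 1
            continue
        # maximal: not preceded by another full copy of the unit
        if i >= u and seq[i - u:i] == unit:
            i += 1
            continue
        count = 1
        while seq[i + count * u:i + (count + 1) * u] == unit:
            count += 1
        if count >= min_units:
            runs.append(
                RepeatRun(
                    transcript_id=t.id,
                    interval=Interval(i, i + count * u),
                    unit=unit,
                    n_units=count,
                )
            )
            i += count * u
        else:
            i += 1
    return runs


def delete_interval(t: Transcript, iv: Interval) -> Transcript:
    """Excise [iv.start, iv.end) from the transcript (in-silico deletion)."""
    if iv.end > len(t.seq):
        raise ValidationError(
            f"deletion [{iv.start},{iv.end}) outside transcript of length {len(t.seq)}"
        )
    removed_before_utr = max(0, min(iv.end, t.utr_start) - iv.start)
    return replace(
        t,
        seq=t.seq[: iv.start] + t.seq[iv.end:],
        utr_start=t.utr_start - removed_before_utr,
    )


@dataclass
class MaskingReport:
    """Per-temperature stem-formation probabilities before/after a deletion."""

    transcript_id: str
    dle: DleMatch
    deleted: Interval
    t_grid: tuple[float, ...]
    p_before: tuple[float, ...]
    p_after: tuple[float, ...]

    @property
    def fold_change(self) -> tuple[float, ...]:
        return tuple(
            a / b if b > 0 else float("inf") if a > 0 else float("nan")
            for a, b in zip(self.p_after, self.p_before)
        )

    @property
    def fold_change_range(self) -> tuple[float, float]:
        fc = self.fold_change
        return (min(fc), max(fc))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": self.transcript_id,
                "temperature_C": self.t_grid,
                "p_before": self.p_before,
                "p_after": self.p_after,
                "fold_change": self.fold_change,
            }
        )


def _relocate_by_shift(dle: DleMatch, deletion: Interval) -> DleMatch:
    shift = -len(deletion) if deletion.end <= dle.anchor.start else 0
    if shift == 0:
        return dle
    return DleMatch(
        transcript_id=dle.transcript_id,
        anchor=dle.anchor.shift(shift),
        spacer=dle.spacer.shift(shift),
        stem5=dle.stem5.shift(shift),
        loop=dle.loop.shift(shift),
        stem3=dle.stem3.shift(shift),
        pairs=tuple((i + shift, j + shift) for i, j in dle.pairs),
        descriptor_name=dle.descriptor_name,
    )


def _relocate_by_rescan(
    after: Transcript, dle: DleMatch, before: Transcript, descriptor: DleDescriptor
) -> DleMatch:
    target = dle.element_seq(before)
    region = Interval(0, len(after.seq))
    for cand in match_dle(after, descriptor, region=region, enumerate_all=True):
        if cand.element_seq(after) == target and len(cand.loop) == len(dle.loop) \
                and cand.n_pairs == dle.n_pairs:
            return cand
    raise ValidationError(
        "could not re-locate the DLE after deletion; the deletion may have "
        "disrupted the element"
    )


def masking_analysis(
    t: Transcript,
    dle: DleMatch,
    deletion: Interval,
    model: EnergyModel,
    t_grid_celsius=DEFAULT_T_GRID,
    descriptor: DleDescriptor | None = None,
) -> MaskingReport:
    """Quantify how deleting ``deletion`` changes DLE stem formation.

    The deletion must not overlap the element (anchor through stem3): the
    analysis asks how *context* affects an intact motif.  After deletion
    the element is re-located — by re-scanning with ``descriptor`` when
    given, else by coordinate shift — and verified to carry the same
    local sequence.
    """
    if deletion.overlaps(dle.span):
        raise ValidationError(
            "deletion overlaps the DLE element; context analysis requires "
            "the motif intact"
        )
    if deletion.end > len(t.seq):
        raise ValidationError("deletion outside transcript bounds")
    t_after = delete_interval(t, deletion)
    if descriptor is not None:
        dle_after = _relocate_by_rescan(t_after, dle, t, descriptor)
    else:
        dle_after = _relocate_by_shift(dle, deletion)
    if dle_after.element_seq(t_after) != dle.element_seq(t):
        raise ValidationError("re-located DLE sequence differs after deletion")
    before = probability_vs_temperature(t.seq, dle.pairs, model, t_grid_celsius)
    after = probability_vs_temperature(
        t_after.seq, dle_after.pairs, model, t_grid_celsius
    )
    return MaskingReport(
        transcript_id=t.id,
        dle=dle,
        deleted=deletion,
        t_grid=tuple(t_grid_celsius),
        p_before=tuple(r.p_substructure for _, r in before),
        p_after=tuple(r.p_substructure for _, r in after),
    )
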