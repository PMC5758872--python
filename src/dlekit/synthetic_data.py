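"""Synthetic inputs with known ground truth for every pipeline stage.

Generators:

* planted-DLE UTR cohorts (rejection-screened so that the planted strict
  element is the *only* strict match, making recall/precision exact),
* masked-DLE constructs: a planted element with an adjacent (CA)k repeat
  whose bases can pair against the stem arm, plus the repeat-deleted
  counterpart (the in-silico analogue of the cyc / cycDCA comparison),
* orthologue families diverged from a planted-DLE ancestor, optionally
  with compensatory (pairing-preserving) stem substitutions,
* two-channel embryo-like image cohorts with a bright blastoderm disc of
  known GFP/RFP ratio, and measurement-level cohorts for ANOVA studies.

Everything is deterministic under (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dle_scan import DleDescriptor, DleMatch, STRICT, match_dle
from .reporter_quant import EmbryoMeasurement, EmbryoStack
from .seqio import Interval, Transcript, ValidationError

__all__ = [
    "SimConfig",
    "ImageConfig",
    "MaskedConstruct",
    "FamilyTruth",
    "gen_planted_utrs",
    "plant_masked_dle",
    "plant_inert_deletion",
    "gen_orthologue_family",
    "gen_embryo_cohort",
    "write_cohort",
    "gen_measurement_cohort",
]

BASES = np.array(list("ACGU"))
WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
WC_PAIR_CHOICES = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")]


@dataclass
class ImageConfig:
    shape: tuple[int, int] = (64, 64)
    n_slices: int = 15
    focus_window: int = 4
    disc_radius: int = 12
    rfp_amplitude: float = 3000.0
    background_level: float = 100.0
    noise_cv: float = 0.2
    out_of_focus_scale: float = 0.15
    ratio_per_group: dict = field(default_factory=lambda: {"control": 0.5, "Mybx1": 0.75})
    stages: tuple[str, ...] = ("1K", "sphere", "30pc-epiboly")
    n_per_cell: int = 34
    n_controls: int = 3


@dataclass
class SimConfig:
    seed: int = 0
    n_sequences: int = 200
    utr_length: int = 200
    gc_content: float = 0.4
    descriptor: DleDescriptor = STRICT
    plant_positions: list[int] | None = None
    ca_units: int = 8
    family_size: int = 7
    per_site_divergence: float = 0.2
    compensatory: bool = True
    image: ImageConfig = field(default_factory=ImageConfig)

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.utr_length < 30 or self.family_size < 2:
            raise ValidationError("counts too small")
        if not (0 <= self.gc_content <= 1 and 0 <= self.per_site_divergence <= 1):
            raise ValidationError("probabilities must lie in [0, 1]")
        if self.ca_units < 2:
            raise ValidationError("ca_units must be >= 2")


def _random_background(rng: np.random.Generator, length: int, gc: float) -> list[str]:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G U
    return list(rng.choice(BASES, size=length, p=probs))


def _sample_element(rng: np.random.Generator, d: DleDescriptor) -> tuple[str, dict]:
    """A random sequence satisfying the descriptor, with its decomposition."""
    spacer_len = int(rng.integers(d.spacer_min, d.spacer_max + 1))
    alphabet = "UC" if d.spacer_alphabet == "pyrimidine" else "ACGU"
    spacer = "".join(rng.choice(list(alphabet), size=spacer_len))
    stem_len = int(rng.integers(d.stem_min_bp, min(d.stem_max_bp, 5) + 1))
    pairs = [WC_PAIR_CHOICES[i] for i in rng.integers(0, 4, size=stem_len)]
    stem5 = "".join(p[0] for p in pairs)
    stem3 = "".join(p[1] for p in reversed(pairs))
    loop_len = int(rng.integers(max(d.loop_min, 3), min(d.loop_max, 8) + 1))
    loop = "".join(rng.choice(list("ACGU"), size=loop_len))
    element = d.anchor + spacer + stem5 + loop + stem3
    layout = {
        "anchor_len": len(d.anchor),
        "spacer_len": spacer_len,
        "stem_len": stem_len,
        "loop_len": loop_len,
    }
    return element, layout


def _planted_match(t_id: str, start: int, layout: dict, d: DleDescriptor) -> DleMatch:
    a = start
    ae = a + layout["anchor_len"]
    s5 = ae + layout["spacer_len"]
    lo = s5 + layout["stem_len"]
    s3 = lo + layout["loop_len"]
    s3e = s3 + layout["stem_len"]
    return DleMatch(
        transcript_id=t_id,
        anchor=Interval(a, ae),
        spacer=Interval(ae, s5),
        stem5=Interval(s5, lo),
        loop=Interval(lo, s3),
        stem3=Interval(s3, s3e),
        pairs=tuple((s5 + m, s3e - 1 - m) for m in range(layout["stem_len"])),
        descriptor_name=d.name,
    )


def _sample_family_element(rng: np.random.Generator, d: DleDescriptor) -> tuple[str, dict]:
    """Element variant for family simulations: a 6-bp G/C stem, A-only loop.

    A planted 'conserved structure' must be thermodynamically real in
    every family member: under the stacking-free pair-energy model a weak
    stem in a pairing-rich context has a diffuse ensemble and would not
    constitute ground truth.  G/C-only arms (with runs capped at 2 so no
    shifted helix register is fully complementary) over an adenosine loop
    give a hairpin that dominates its local ensemble.
    """
    # the anchor's G always has legal spacer partners (they sit beyond the
    # minimum hairpin distance), so a tri-C spacer is used to split that
    # probability three ways; its terminal C also blocks outward-shifted
    # helix registers against the G-opening arm
    spacer_len = 3
    spacer = "CCC"
    stem_len = 6

    def has_shift_register(arm: list[str]) -> bool:
        # a shift-d self-match of >= 3 consecutive positions means the two
        # arms also pair in a register offset by d, splitting the ensemble
        for d in range(1, stem_len - 2):
            run = 0
            for m in range(stem_len - d):
                run = run + 1 if arm[m] == arm[m + d] else 0
                if run >= 3:
                    return True
        return False

    while True:
        arm = ["G", "C"] + [
            "G" if rng.random() < 0.5 else "C" for _ in range(stem_len - 2)
        ]
        if not has_shift_register(arm):
            break
    stem5 = "".join(arm)
    stem3 = "".join(WC_COMPLEMENT[c] for c in reversed(arm))
    loop_len = int(rng.integers(5, 8))
    loop = "A" * loop_len
    element = d.anchor + spacer + stem5 + loop + stem3
    layout = {
        "anchor_len": len(d.anchor),
        "spacer_len": spacer_len,
        "stem_len": stem_len,
        "loop_len": loop_len,
    }
    return element, layout


def gen_planted_utrs(
    cfg: SimConfig,
    max_tries: int = 200,
    element_sampler=None,
    background_alphabet: str | None = None,
) -> tuple[list[Transcript], pd.DataFrame]:
    """UTR-like sequences, each with exactly one planted strict DLE.

    Backgrounds are rejection-screened: a candidate is kept only if the
    scanner reports exactly one match whose anchor sits at the planted
    position, so planted-motif recall and precision are well defined.
    """
    rng = np.random.default_rng(cfg.seed)
    d = cfg.descriptor
    sampler = element_sampler or _sample_element
    transcripts = []
    rows = []
    for idx in range(cfg.n_sequences):
        placed = None
        for _ in range(max_tries):
            element, layout = sampler(rng, d)
            if len(element) >= cfg.utr_length:
                continue
            if cfg.plant_positions is not None:
                pos = cfg.plant_positions[idx % len(cfg.plant_positions)]
            else:
                pos = int(rng.integers(0, cfg.utr_length - len(element) + 1))
            if background_alphabet is not None:
                bg = list(rng.choice(list(background_alphabet), size=cfg.utr_length))
            else:
                bg = _random_background(rng, cfg.utr_length, cfg.gc_content)
            bg[pos:pos + len(element)] = list(element)
            seq = "".join(bg)
            t = Transcript(id=f"synth_utr_{idx:04d}", seq=seq, utr_start=0)
            hits = match_dle(t, d)
            # accept only if every reported hit is the planted element
            # (alternative decompositions at the planted anchor are fine)
            if hits and {h.anchor.start for h in hits} == {pos}:
                placed = (t, pos, layout)
                break
        if placed is None:
            raise ValidationError(
                "rejection sampling failed: descriptor too permissive for "
                "this length/composition; shorten the UTR or tighten the descriptor"
            )
        t, pos, layout = placed
        m = _planted_match(t.id, pos, layout, d)
        transcripts.append(t)
        rows.append(
            {
                "id": t.id,
                "anchor_start": m.anchor.start,
                "element_start": m.span.start,
                "element_end": m.span.end,
                "stem_bp": m.n_pairs,
                "loop_len": len(m.loop),
            }
        )
    return transcripts, pd.DataFrame(rows)


@dataclass
class MaskedConstruct:
    """Paired masked/unmasked constructs with the planted element."""

    masked: Transcript
    unmasked: Transcript
    deletion: Interval
    match: DleMatch
    descriptor: DleDescriptor


def plant_masked_dle(cfg: SimConfig) -> MaskedConstruct:
    """A planted strict DLE with an adjacent (CA)k repeat that can pair
    against the (UG-containing) 5' stem arm, total length <= 40 for
    enumeration tractability; plus the repeat-deleted counterpart.

    The construct is deterministic given ``ca_units``; the seed matters
    only through the config contract (same config, same bytes).
    """
    if cfg.ca_units < 4:
        raise ValidationError("ca_units must be >= 4 for a masked construct")
    # AA GCAC UU UGU AAAAA ACA G (CA)k AA
    head = "AA" + "GCAC" + "UU" + "UGU" + "AAAAA" + "ACA" + "G"
    repeat = "CA" * cfg.ca_units
    seq = head + repeat + "AA"
    if len(seq) > 40:
        raise ValidationError(
            f"construct length {len(seq)} exceeds the 40-nt enumeration budget; "
            "reduce ca_units"
        )
    layout = {"anchor_len": 4, "spacer_len": 2, "stem_len": 3, "loop_len": 5}
    t_masked = Transcript(id="masked_dle", seq=seq, utr_start=0)
    match = _planted_match(t_masked.id, 2, layout, STRICT)
    deletion = Interval(len(head), len(head) + len(repeat))
    from .context import delete_interval

    t_unmasked = Transcript(
        id="unmasked_dle",
        seq=delete_interval(t_masked, deletion).seq,
        utr_start=0,
    )
    return MaskedConstruct(
        masked=t_masked,
        unmasked=t_unmasked,
        deletion=deletion,
        match=match,
        descriptor=STRICT,
    )


def plant_inert_deletion(poly_a_len: int = 10) -> MaskedConstruct:
    """A control construct whose deletable run cannot pair with anything.

    The construct contains no U, so the poly-A run has zero pairing
    potential; deleting it must leave the stem-formation probability
    unchanged.  Named fields mirror :func:`plant_masked_dle`.
    """
    # CC GCAC CC GGG AACAA CCC A^k CC  (no U anywhere)
    head = "CC" + "GCAC" + "CC" + "GGG" + "AACAA" + "CCC"
    run = "A" * poly_a_len
    seq = head + run + "CC"
    layout = {"anchor_len": 4, "spacer_len": 2, "stem_len": 3, "loop_len": 5}
    t_masked = Transcript(id="inert_ctx", seq=seq, utr_start=0)
    match = _planted_match(t_masked.id, 2, layout, STRICT)
    deletion = Interval(len(head), len(head) + len(run))
    from .context import delete_interval

    t_unmasked = Transcript(
        id="inert_ctx_del",
        seq=delete_interval(t_masked, deletion).seq,
        utr_start=0,
    )
    return MaskedConstruct(
        masked=t_masked,
        unmasked=t_unmasked,
        deletion=deletion,
        match=match,
        descriptor=STRICT,
    )


@dataclass
class FamilyTruth:
    """Ground truth for a simulated orthologue family."""

    ancestor: Transcript
    anchor_start: int
    element: Interval
    stem_pairs: tuple[tuple[int, int], ...]
    loop: Interval


def gen_orthologue_family(cfg: SimConfig) -> tuple[list[Transcript], FamilyTruth]:
    """Star-phylogeny family from a planted-DLE ancestor (no indels).

    With ``compensatory`` on, the anchor is frozen, spacer sites mutate
    only within pyrimidines, and stem pairs mutate only as
    pairing-preserving double substitutions — the purifying-selection
    signature of a conserved sequence/structure element.  With it off,
    every site mutates independently.
    """
    rng = np.random.default_rng(cfg.seed)
    # adenosine background: pairing-inert against the G/C element arms, the
    # standard planted-benchmark trick of embedding signal in inert context
    anc_cfg = SimConfig(
        seed=int(rng.integers(0, 2**31 - 1)),
        n_sequences=1,
        utr_length=max(40, min(cfg.utr_length, 80)),
        gc_content=0.0,
        descriptor=cfg.descriptor,
        family_size=cfg.family_size,
    )
    [ancestor], truth_df = gen_planted_utrs(
        anc_cfg,
        element_sampler=_sample_family_element,
        background_alphabet="A",
    )
    row = truth_df.iloc[0]
    stem_len = int(row["stem_bp"])
    element = Interval(int(row["element_start"]), int(row["element_end"]))
    anchor_start = int(row["anchor_start"])
    d = cfg.descriptor
    anchor_iv = Interval(anchor_start, anchor_start + len(d.anchor))
    spacer_iv = Interval(anchor_iv.end, element.end - 2 * stem_len - int(row["loop_len"]))
    stem5_start = spacer_iv.end
    loop_iv = Interval(stem5_start + stem_len, stem5_start + stem_len + int(row["loop_len"]))
    stem_pairs = tuple(
        (stem5_start + m, element.end - 1 - m) for m in range(stem_len)
    )
    p = cfg.per_site_divergence
    family = [Transcript(id="sp0", seq=ancestor.seq, utr_start=0, gene="sp0")]
    for k in range(1, cfg.family_size):
        seq = list(ancestor.seq)
        if cfg.compensatory:
            protected = set(range(anchor_iv.start, anchor_iv.end))
            stem_positions = {i for pr in stem_pairs for i in pr}
            clamp = {stem_pairs[0], stem_pairs[-1]}
            for i, j in stem_pairs:
                if rng.random() < p:
                    # helix-end pairs stay G/C clamped (an A-U boundary
                    # pair would leak into the adenosine background);
                    # interior pairs swap over the full Watson-Crick set
                    choices = WC_PAIR_CHOICES[:2] if (i, j) in clamp else WC_PAIR_CHOICES
                    a, b = choices[int(rng.integers(0, len(choices)))]
                    seq[i], seq[j] = a, b
            for pos in range(len(seq)):
                if pos in protected or pos in stem_positions:
                    continue
                if rng.random() < p:
                    if spacer_iv.start <= pos < spacer_iv.end:
                        seq[pos] = "C" if seq[pos] == "U" else "U"
                    else:
                        choices = [b for b in "ACGU" if b != seq[pos]]
                        seq[pos] = choices[int(rng.integers(0, 3))]
        else:
            for pos in range(len(seq)):
                if rng.random() < p:
                    choices = [b for b in "ACGU" if b != seq[pos]]
                    seq[pos] = choices[int(rng.integers(0, 3))]
        family.append(
            Transcript(id=f"sp{k}", seq="".join(seq), utr_start=0, gene=f"sp{k}")
        )
    truth = FamilyTruth(
        ancestor=ancestor,
        anchor_start=anchor_start,
        element=element,
        stem_pairs=stem_pairs,
        loop=loop_iv,
    )
    return family, truth


def truth_alignment(
    family: list[Transcript], truth: FamilyTruth, flanks: int = 10
) -> tuple["AlignmentSet", int]:
    """The generator's ground-truth alignment of the element region.

    Families are simulated without indels, so homologous positions share
    coordinates and the true alignment of element +- flanks is simply the
    raw rows — the synthetic analogue of a curated alignment.  Returns
    (alignment, region_start) so transcript coordinates map to columns by
    subtracting ``region_start``.
    """
    from .seqio import AlignmentSet

    start = max(0, truth.element.start - flanks)
    end = min(min(len(t.seq) for t in family), truth.element.end + flanks)
    rows = [(t.id, t.seq[start:end]) for t in family]
    return AlignmentSet(rows=rows), start


def select_homologous_matches(
    family: list[Transcript], truth: FamilyTruth, descriptor: DleDescriptor = STRICT
) -> list[DleMatch]:
    """Per species, the grammar decomposition homologous to the planted one.

    Uses full enumeration so the selection is by ground-truth coordinates
    (anchor, stem arms, loop), not by the scanner's collapsing rule.
    Species in which the planted decomposition no longer matches are
    omitted.
    """
    out = []
    for t in family:
        region = Interval(0, len(t.seq))
        for m in match_dle(t, descriptor, region=region, enumerate_all=True):
            if (
                m.anchor.start == truth.anchor_start
                and m.stem5.start == truth.stem_pairs[0][0]
                and m.n_pairs == len(truth.stem_pairs)
                and m.loop == truth.loop
            ):
                out.append(m)
                break
    return out


def _disc_mask(shape: tuple[int, int], center: tuple[int, int], radius: int) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def gen_embryo_cohort(
    cfg: SimConfig,
) -> tuple[list[EmbryoStack], pd.DataFrame]:
    """Two-channel embryo-like stacks with a bright blastoderm disc.

    The disc appears at full amplitude only in the planted focus block;
    other slices carry a strongly attenuated copy.  RFP amplitude is
    fixed; GFP = group ratio x RFP signal, both over a common background
    level, with multiplicative Gaussian noise at ``noise_cv``.
    """
    ic = cfg.image
    rng = np.random.default_rng(cfg.seed)
    stacks = []
    rows = []

    def noisy(x: np.ndarray) -> np.ndarray:
        if ic.noise_cv == 0:
            return x
        return np.clip(x * (1 + ic.noise_cv * rng.standard_normal(x.shape)), 0, None)

    def build(embryo_id, group, stage, ratio, is_control):
        h, w = ic.shape
        margin = ic.disc_radius + 2
        center = (
            int(rng.integers(margin, h - margin)),
            int(rng.integers(margin, w - margin)),
        )
        focus_start = int(rng.integers(0, ic.n_slices - ic.focus_window + 1))
        disc = _disc_mask(ic.shape, center, ic.disc_radius)
        gfp = np.zeros((ic.n_slices, h, w))
        rfp = np.zeros((ic.n_slices, h, w))
        for z in range(ic.n_slices):
            scale = (
                1.0
                if focus_start <= z < focus_start + ic.focus_window
                else ic.out_of_focus_scale
            )
            r_plane = np.full((h, w), ic.background_level)
            g_plane = np.full((h, w), ic.background_level)
            if not is_control:
                r_plane = r_plane + scale * ic.rfp_amplitude * disc
                g_plane = g_plane + scale * ratio * ic.rfp_amplitude * disc
            rfp[z] = noisy(r_plane)
            gfp[z] = noisy(g_plane)
        stacks.append(
            EmbryoStack(
                embryo_id=embryo_id,
                group=group,
                stage=stage,
                gfp=gfp,
                rfp=rfp,
                is_control=is_control,
            )
        )
        rows.append(
            {
                "embryo_id": embryo_id,
                "group": group,
                "stage": stage,
                "is_control": is_control,
                "true_ratio": ratio if not is_control else float("nan"),
                "roi_area": int(disc.sum()) if not is_control else 0,
                "focus_start": focus_start,
                "focus_end": focus_start + ic.focus_window,
            }
        )

    for i in range(ic.n_controls):
        build(f"ctrl_{i:03d}", "uninjected", "na", 0.0, True)
    idx = 0
    for group, ratio in ic.ratio_per_group.items():
        for stage in ic.stages:
            for _ in range(ic.n_per_cell):
                build(f"emb_{idx:04d}", group, stage, ratio, False)
                idx += 1
    return stacks, pd.DataFrame(rows)


def write_cohort(stacks: list[EmbryoStack], truth: pd.DataFrame, outdir) -> None:
    """Write 16-bit multi-page TIFFs, the TSV sample sheet, and the truth TSV."""
    import pathlib

    import tifffile

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sheet = []
    for s in stacks:
        gpath = out / f"{s.embryo_id}_gfp.tif"
        rpath = out / f"{s.embryo_id}_rfp.tif"
        tifffile.imwrite(gpath, np.clip(s.gfp, 0, 65535).astype(np.uint16))
        tifffile.imwrite(rpath, np.clip(s.rfp, 0, 65535).astype(np.uint16))
        sheet.append(
            {
                "embryo_id": s.embryo_id,
                "group": s.group,
                "stage": s.stage,
                "gfp_path": gpath.name,
                "rfp_path": rpath.name,
                "is_control": int(s.is_control),
            }
        )
    pd.DataFrame(sheet).to_csv(out / "samples.tsv", sep="\t", index=False)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def gen_measurement_cohort(
    seed: int,
    group_means: dict[str, float],
    stage_scales: dict[str, float] | None = None,
    n_per_cell: int = 34,
    cv: float = 0.2,
) -> list[EmbryoMeasurement]:
    """Measurement-level cohort for ANOVA simulation studies.

    Per-embryo ratios are Gaussian with mean group_mean x stage_scale and
    standard deviation cv x mean.  Used to study type-I error and power of
    the group comparison without the imaging stage.
    """
    rng = np.random.default_rng(seed)
    stage_scales = stage_scales or {"1K": 1.0, "sphere": 1.25, "30pc-epiboly": 1.5}
    out = []
    idx = 0
    for group, gmean in group_means.items():
        for stage, scale in stage_scales.items():
            mean = gmean * scale
            for _ in range(n_per_cell):
                ratio = rng.normal(mean, cv * mean)
                # unit RFP denominator and zero backgrounds make the
                # recorded ratio equal the sampled value exactly
                m = EmbryoMeasurement(
                    embryo_id=f"sim_{idx:05d}",
                    group=group,
                    stage=stage,
                    roi_area=1,
                    mean_gfp=float(ratio),
                    mean_rfp=1.0,
                    bg_gfp=0.0,
                    bg_rfp=0.0,
                )
                out.append(m)
                idx += 1
    return out


def simulate_anova_rejections(
    base_seed: int,
    group_means: dict[str, float],
    n_cohorts: int = 100,
    n_per_cell: int = 34,
    cv: float = 0.2,
    alpha: float = 0.05,
) -> int:
    """Number of cohorts (out of ``n_cohorts``) whose two-way ANOVA group
    effect is significant at ``alpha``.

    With equal group means this estimates the test's type-I error; with a
    planted difference it estimates power.  Cohort c uses seed
    ``base_seed + c``.
    """
    from .reporter_quant import compare_groups

    rejections = 0
    for c in range(n_cohorts):
        ms = gen_measurement_cohort(
            seed=base_seed + c,
            group_means=group_means,
            n_per_cell=n_per_cell,
            cv=cv,
        )
        out = compare_groups(ms)
        if out["anova"].loc["group", "PR(>F)"] < alpha:
            rejections += 1
    return rejections
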