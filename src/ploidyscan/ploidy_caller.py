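"""Embryo-level verdicts from per-gene percent depths.

Dosage banding uses midpoint cuts between the nominal anchors
0 / 50 / 100 / 150 (% of mean genome depth), half-open on the right:
ABSENT [0, 25), HEMIZYGOUS [25, 75), DISOMIC [75, 125),
AMPLIFIED [125, inf).

Because percent depth is self-normalized, a clean maternal-only
haploid reads 100% everywhere it retains material — indistinguishable
from a diploid by dosage alone. Haploidy is therefore called from
declared paternal-only markers (by default the transgene and the Y
arm) being absent, which is exactly why those markers exist in the
assay design.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .depth_quant import (
    DepthProfile,
    GeneDepthSummary,
    compute_gene_summaries,
    mean_genome_depth,
    mito_normalized_depth,
)

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import GeneInterval, GenomeLayout


class DosageState(enum.Enum):
    ABSENT = "ABSENT"  # nominal 0%
    HEMIZYGOUS = "HEMIZYGOUS"  # nominal 50%
    DISOMIC = "DISOMIC"  # nominal 100%
    AMPLIFIED = "AMPLIFIED"  # nominal >= 150%


@dataclass(frozen=True)
class CallerThresholds:
    """Band edges and marker thresholds; all config-exposed."""

    absent_max: float = 25.0
    hemizygous_max: float = 75.0
    disomic_max: float = 125.0
    transgene_min_percent: float = 25.0
    transgene_evenness_min: float = 0.9
    transgene_bins: int = 10
    min_concordant: int = 3  # "multiple genes" = strict majority of 5

    def __post_init__(self) -> None:
        if not 0 < self.absent_max < self.hemizygous_max < self.disomic_max:
            raise ValueError("band edges must be increasing and positive")
        if not 1 <= self.min_concordant <= 5:
            raise ValueError("min_concordant must be in 1..5")
        if self.transgene_bins < 2:
            raise ValueError("transgene_bins must be >= 2")


DEFAULT_THRESHOLDS = CallerThresholds()
DEFAULT_PATERNAL_MARKERS = ("egfp", "Y")


@dataclass(frozen=True)
class ArmCall:
    """Majority-vote dosage state over one arm's marker genes.

    ``state`` is None when no state reaches the concordance threshold
    (an ambiguous arm).
    """

    arm: str
    state: DosageState | None
    per_gene: tuple[DosageState, ...]
    concordance: float

    @property
    def ambiguous(self) -> bool:
        return self.state is None


@dataclass(frozen=True)
class TransgeneCall:
    present: bool
    evenness: float
    percent: float


@dataclass(frozen=True)
class PloidyCall:
    embryo_id: str
    transgene_present: bool
    transgene_evenness: float
    transgene_percent: float
    sex: str  # male | female | undetermined
    ploidy: str  # haploid | diploid | segmental_aneuploid | ambiguous
    arm_calls: tuple[ArmCall, ...]

    def to_dict(self) -> dict:
        return {
            "embryo_id": self.embryo_id,
            "transgene_present": self.transgene_present,
            "transgene_evenness": self.transgene_evenness,
            "transgene_percent": self.transgene_percent,
            "sex": self.sex,
            "ploidy": self.ploidy,
            "arm_calls": [
                {
                    "arm": a.arm,
                    "state": a.state.value if a.state else "ambiguous",
                    "per_gene": [s.value for s in a.per_gene],
                    "concordance": a.concordance,
                }
                for a in self.arm_calls
            ],
        }


def classify_gene_dosage(
    percent_depth: float, thresholds: CallerThresholds = DEFAULT_THRESHOLDS
) -> DosageState:
    """Map a percent depth onto its dosage band (a partition of [0, inf))."""
    if percent_depth < 0:
        raise ValueError(f"negative percent depth {percent_depth}")
    if percent_depth < thresholds.absent_max:
        return DosageState.ABSENT
    if percent_depth < thresholds.hemizygous_max:
        return DosageState.HEMIZYGOUS
    if percent_depth < thresholds.disomic_max:
        return DosageState.DISOMIC
    return DosageState.AMPLIFIED


def call_arm_dosage(
    arm: str,
    gene_states: Sequence[DosageState],
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
) -> ArmCall:
    """Majority vote over exactly five per-gene states."""
    if len(gene_states) != 5:
        raise ValueError(f"arm {arm!r}: expected 5 gene states, got {len(gene_states)}")
    counts = Counter(gene_states)
    majority_state, majority_n = counts.most_common(1)[0]
    concordance = majority_n / len(gene_states)
    state = majority_state if majority_n >= thresholds.min_concordant else None
    return ArmCall(
        arm=arm, state=state, per_gene=tuple(gene_states), concordance=concordance
    )


def call_transgene_presence(
    profile: DepthProfile,
    transgene: "GeneInterval",
    genome_mean: float,
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
) -> TransgeneCall:
    """Present iff the transgene's percent depth is meaningful AND its
    reads are spread across (nearly) the whole element.

    The evenness gate rejects spurious pile-ups: depth concentrated in
    a couple of bins can clear the percent cut without representing a
    real transgene copy.
    """
    if genome_mean <= 0:
        raise ValueError("undefined normalization: mean genome depth <= 0")
    arr = profile.track(transgene.sequence_name)[transgene.start : transgene.end]
    if arr.size < thresholds.transgene_bins:
        raise ValueError(
            f"transgene shorter than {thresholds.transgene_bins} bp"
        )
    bins = np.array_split(arr, thresholds.transgene_bins)
    evenness = float(np.mean([b.mean() > 0 for b in bins]))
    percent = 100.0 * float(arr.mean()) / genome_mean
    present = (
        percent >= thresholds.transgene_min_percent
        and evenness >= thresholds.transgene_evenness_min
    )
    return TransgeneCall(present=present, evenness=evenness, percent=percent)


def infer_sex(y_arm: ArmCall, x_arm: ArmCall) -> str:
    """Male: Y material present with a hemizygous X. Female: no Y with
    a disomic-band X (true in both diploid XX and self-normalized
    haploid X embryos). Anything else is undetermined."""
    if y_arm.ambiguous or x_arm.ambiguous:
        return "undetermined"
    if y_arm.state in (DosageState.HEMIZYGOUS, DosageState.DISOMIC) and (
        x_arm.state is DosageState.HEMIZYGOUS
    ):
        return "male"
    if y_arm.state is DosageState.ABSENT and x_arm.state is DosageState.DISOMIC:
        return "female"
    return "undetermined"


def call_ploidy(
    embryo_id: str,
    arm_calls: Sequence[ArmCall],
    transgene: TransgeneCall,
    paternal_markers: Iterable[str] = DEFAULT_PATERNAL_MARKERS,
    sex_arms: Sequence[str] = ("X", "Y"),
    required_arms: Sequence[str] | None = None,
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
) -> PloidyCall:
    """Combine arm dosage states and paternal markers into a verdict.

    diploid: transgene present and every non-sex arm DISOMIC.
    haploid: every paternal marker absent and every non-sex arm DISOMIC
    (dosage self-normalizes to 100% in a clean haploid).
    segmental_aneuploid: some non-sex arm lost (HEMIZYGOUS or ABSENT)
    while paternal material is still present.
    ambiguous: anything else.
    """
    by_arm = {a.arm: a for a in arm_calls}
    if required_arms is not None:
        missing = [a for a in required_arms if a not in by_arm]
        if missing:
            raise ValueError(f"missing arm calls: {missing}")
    marker_names = list(paternal_markers)

    def marker_present(name: str) -> bool:
        if name in by_arm:
            call = by_arm[name]
            return call.state is not DosageState.ABSENT  # ambiguous counts present
        return transgene.present

    def marker_absent(name: str) -> bool:
        if name in by_arm:
            return by_arm[name].state is DosageState.ABSENT
        return (not transgene.present) and transgene.percent < thresholds.absent_max

    autosome_calls = [a for a in arm_calls if a.arm not in sex_arms]
    all_disomic = all(a.state is DosageState.DISOMIC for a in autosome_calls)
    any_lost = any(
        a.state in (DosageState.HEMIZYGOUS, DosageState.ABSENT)
        for a in autosome_calls
    )
    any_marker_present = any(marker_present(m) for m in marker_names)
    all_markers_absent = all(marker_absent(m) for m in marker_names)

    if transgene.present and all_disomic:
        ploidy = "diploid"
    elif all_markers_absent and all_disomic:
        ploidy = "haploid"
    elif any_lost and any_marker_present:
        ploidy = "segmental_aneuploid"
    else:
        ploidy = "ambiguous"

    x_call = by_arm.get("X")
    y_call = by_arm.get("Y")
    sex = infer_sex(y_call, x_call) if x_call and y_call else "undetermined"

    return PloidyCall(
        embryo_id=embryo_id,
        transgene_present=transgene.present,
        transgene_evenness=transgene.evenness,
        transgene_percent=transgene.percent,
        sex=sex,
        ploidy=ploidy,
        arm_calls=tuple(arm_calls),
    )


@dataclass(frozen=True)
class EmbryoReport:
    """Full per-embryo output: verdict plus the numbers behind it."""

    call: PloidyCall
    summaries: tuple[GeneDepthSummary, ...]
    genome_mean: float
    mito_ratio: float | None


def call_embryo(
    profile: DepthProfile,
    layout: "GenomeLayout",
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
    paternal_markers: Iterable[str] = DEFAULT_PATERNAL_MARKERS,
) -> EmbryoReport:
    """End-to-end call for one embryo from a dense depth profile."""
    genome_mean = mean_genome_depth(profile, layout)
    summaries = compute_gene_summaries(profile, layout.genes, genome_mean)
    percent_by_gene = {s.gene: s.percent_depth for s in summaries}
    arm_calls = []
    for arm in layout.nuclear_arms:
        states = [
            classify_gene_dosage(percent_by_gene[g.name], thresholds)
            for g in layout.genes_on(arm)
        ]
        arm_calls.append(call_arm_dosage(arm, states, thresholds))
    transgene = call_transgene_presence(
        profile, layout.transgene_interval, genome_mean, thresholds
    )
    call = call_ploidy(
        profile.embryo_id,
        arm_calls,
        transgene,
        paternal_markers=paternal_markers,
        sex_arms=layout.sex_arms,
        required_arms=layout.nuclear_arms,
        thresholds=thresholds,
    )
    try:
        mito_ratio = mito_normalized_depth(profile, layout)
    except ValueError:
        mito_ratio = None
    return EmbryoReport(
        call=call,
        summaries=tuple(summaries),
        genome_mean=genome_mean,
        mito_ratio=mito_ratio,
    )
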