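"""Synthetic genomes, depth profiles and embryo-fate cohorts.

Everything downstream of read alignment consumes only per-position
depth, so a miniature multi-sequence reference is enough to exercise
the whole pipeline: seven nuclear arms with five marker genes each, a
mitochondrion, an ``egfp`` transgene and a randomized negative-control
sequence. Depth is simulated per karyotype (copy number per sequence)
with optional Poisson counting noise, and embryo fates are simulated
per cross under a three-way first-division outcome model.

All randomness flows from explicit integer seeds through
``numpy.random.SeedSequence`` sub-streams, so per-embryo draws do not
depend on cohort size or ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .depth_quant import DepthProfile

NUCLEAR_ARMS = ("Y", "X", "2L", "2R", "3L", "3R", "4")
SEX_ARMS = ("Y", "X")
AUTOSOME_ARMS = ("2L", "2R", "3L", "3R", "4")
GENES_PER_ARM = 5

MITO_NAME = "mito"
TRANSGENE_NAME = "egfp"
NEG_CONTROL_NAME = "neg_control"

MITO_LENGTH = 19_500
TRANSGENE_LENGTH = 720
NEG_CONTROL_LENGTH = 714  # fixed-size randomized decoy sequence

ROLES = ("nuclear_arm", "mitochondrion", "transgene", "negative_control")

FIRST_DIVISION_OUTCOMES = ("normal", "complete_paternal_loss", "partial_paternal_loss")
PLOIDY_CLASSES = ("diploid", "haploid", "aneuploid_arrested")

COHORT_COLUMNS = [
    "cross",
    "first_division",
    "reached_blastula",
    "ploidy",
    "hatched",
    "adult",
    "fallout_count",
    "divisions_scored",
    "divisions_errored",
]


def _entropy(seed: int, *tail: int) -> np.random.SeedSequence:
    # SeedSequence wants non-negative entropy words
    return np.random.SeedSequence([seed & 0xFFFFFFFFFFFFFFFF, *tail])


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceInfo:
    name: str
    length: int
    role: str

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"sequence {self.name!r}: non-positive length")
        if self.role not in ROLES:
            raise ValueError(f"sequence {self.name!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class GeneInterval:
    name: str
    sequence_name: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.name!r}: bad interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeLayout:
    """Miniature reference: sequences with roles plus marker-gene intervals."""

    sequences: tuple[SequenceInfo, ...]
    genes: tuple[GeneInterval, ...]
    baseline_copy: Mapping[str, int]
    seed: int = 0
    sex_arms: tuple[str, ...] = SEX_ARMS

    def __post_init__(self) -> None:
        lengths = {}
        for s in self.sequences:
            if s.name in lengths:
                raise ValueError(f"duplicate sequence name {s.name!r}")
            lengths[s.name] = s.length
        by_seq: dict[str, list[GeneInterval]] = {}
        names = set()
        for g in self.genes:
            if g.name in names:
                raise ValueError(f"duplicate gene name {g.name!r}")
            names.add(g.name)
            if g.sequence_name not in lengths:
                raise ValueError(
                    f"gene {g.name!r} on unknown sequence {g.sequence_name!r}"
                )
            if g.end > lengths[g.sequence_name]:
                raise ValueError(f"gene {g.name!r} extends past its sequence")
            by_seq.setdefault(g.sequence_name, []).append(g)
        for seq, gs in by_seq.items():
            gs = sorted(gs, key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping genes {a.name!r} and {b.name!r} on {seq!r}"
                    )

    def sequence_lengths(self) -> dict[str, int]:
        return {s.name: s.length for s in self.sequences}

    def roles(self) -> dict[str, str]:
        return {s.name: s.role for s in self.sequences}

    @property
    def nuclear_arms(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sequences if s.role == "nuclear_arm")

    def genes_on(self, sequence_name: str) -> tuple[GeneInterval, ...]:
        return tuple(g for g in self.genes if g.sequence_name == sequence_name)

    def gene(self, name: str) -> GeneInterval:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(f"no gene named {name!r}")

    @property
    def transgene_interval(self) -> GeneInterval:
        for s in self.sequences:
            if s.role == "transgene":
                return GeneInterval(
                    name=s.name, sequence_name=s.name, start=0, end=s.length
                )
        raise ValueError("layout has no transgene")


def build_layout(
    arm_length_bp: int = 100_000,
    gene_length_bp: int = 1_000,
    seed: int = 0,
    *,
    mito_length_bp: int = MITO_LENGTH,
    transgene_length_bp: int = TRANSGENE_LENGTH,
) -> GenomeLayout:
    """Construct the default miniature layout.

    Seven nuclear arms of ``arm_length_bp`` each carry five evenly
    spaced, non-overlapping genes of ``gene_length_bp``; auxiliary
    sequences are one mitochondrion, one transgene and one 714-bp
    negative control. Deterministic given ``seed`` (the seed only
    affects FASTA base content, not coordinates).
    """
    if arm_length_bp <= 0 or gene_length_bp <= 0:
        raise ValueError("lengths must be positive")
    if mito_length_bp <= 0 or transgene_length_bp <= 0:
        raise ValueError("lengths must be positive")
    slack = arm_length_bp - GENES_PER_ARM * gene_length_bp
    if slack < 0:
        raise ValueError(
            f"{GENES_PER_ARM} genes of {gene_length_bp} bp cannot fit in a "
            f"{arm_length_bp} bp arm"
        )
    sequences = [
        SequenceInfo(name=a, length=arm_length_bp, role="nuclear_arm")
        for a in NUCLEAR_ARMS
    ]
    sequences.append(SequenceInfo(MITO_NAME, mito_length_bp, "mitochondrion"))
    sequences.append(SequenceInfo(TRANSGENE_NAME, transgene_length_bp, "transgene"))
    sequences.append(SequenceInfo(NEG_CONTROL_NAME, NEG_CONTROL_LENGTH, "negative_control"))

    genes = []
    for arm in NUCLEAR_ARMS:
        for i in range(GENES_PER_ARM):
            # even spacing: slack split into six gaps around five genes
            start = round((i + 1) * slack / (GENES_PER_ARM + 1)) + i * gene_length_bp
            genes.append(
                GeneInterval(
                    name=f"{arm}g{i + 1}",
                    sequence_name=arm,
                    start=start,
                    end=start + gene_length_bp,
                )
            )

    baseline = {a: 2 for a in NUCLEAR_ARMS}
    baseline["Y"] = 0  # diploid female reference state
    baseline[MITO_NAME] = 1
    baseline[TRANSGENE_NAME] = 0
    baseline[NEG_CONTROL_NAME] = 0
    return GenomeLayout(
        sequences=tuple(sequences),
        genes=tuple(genes),
        baseline_copy=baseline,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# karyotypes and depth simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Karyotype:
    """Copy number per sequence, plus a mitochondrial depth multiplier.

    ``mito_scale`` is the mitochondrion's depth relative to one nuclear
    copy; mitochondria are far more abundant than any nuclear sequence
    so the default is deliberately large.
    """

    copies: Mapping[str, int]
    mito_scale: float = 100.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.mito_scale <= 0:
            raise ValueError("mito_scale must be positive")
        for name, c in self.copies.items():
            if int(c) != c or c < 0:
                raise ValueError(f"copy number for {name!r} must be a non-negative integer")

    def validate_against(self, layout: GenomeLayout) -> None:
        roles = layout.roles()
        for s in layout.sequences:
            if s.role in ("mitochondrion", "negative_control"):
                continue
            if s.name not in self.copies:
                raise ValueError(f"karyotype missing copy number for {s.name!r}")
        for name, c in self.copies.items():
            role = roles.get(name)
            if role is None:
                raise ValueError(f"karyotype names unknown sequence {name!r}")
            if role == "nuclear_arm" and not 0 <= c <= 3:
                raise ValueError(f"nuclear arm {name!r}: copies must be in 0..3")
            if role == "negative_control" and c != 0:
                raise ValueError("negative-control copies must be 0")


def _arm_copies(x: int, y: int, autosomes: int, transgene: int) -> dict[str, int]:
    copies = {a: autosomes for a in AUTOSOME_ARMS}
    copies["X"] = x
    copies["Y"] = y
    copies[TRANSGENE_NAME] = transgene
    return copies


KARYOTYPE_PRESETS = {
    "diploid_XY": _arm_copies(x=1, y=1, autosomes=2, transgene=1),
    "diploid_XX": _arm_copies(x=2, y=0, autosomes=2, transgene=1),
    "haploid_maternal": _arm_copies(x=1, y=0, autosomes=1, transgene=0),
    "aneuploid_2L_loss": {**_arm_copies(x=2, y=0, autosomes=2, transgene=1), "2L": 1},
}


def preset_karyotype(label: str, mito_scale: float = 100.0) -> Karyotype:
    try:
        copies = KARYOTYPE_PRESETS[label]
    except KeyError:
        raise KeyError(
            f"unknown karyotype {label!r}; known: {sorted(KARYOTYPE_PRESETS)}"
        ) from None
    return Karyotype(copies=dict(copies), mito_scale=mito_scale, label=label)


def simulate_depth(
    layout: GenomeLayout,
    karyotype: Karyotype,
    target_coverage: float,
    noise: str = "poisson",
    seed: int = 0,
    embryo_id: str | None = None,
) -> DepthProfile:
    """Simulate per-position depth for one embryo.

    The expected depth of sequence ``s`` is
    ``target_coverage * copies(s) / 2`` (so a disomic sequence sits at
    the target coverage); the mitochondrion uses ``mito_scale`` in
    place of a copy number and the negative control is always 0. With
    ``noise="poisson"`` each position is an independent Poisson draw
    around that mean.
    """
    if target_coverage <= 0:
        raise ValueError("target_coverage must be positive")
    if noise not in ("none", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")
    karyotype.validate_against(layout)
    rng = np.random.default_rng(_entropy(seed))
    tracks: dict[str, np.ndarray] = {}
    for s in layout.sequences:
        if s.role == "mitochondrion":
            mean = target_coverage * karyotype.mito_scale / 2.0
        elif s.role == "negative_control":
            mean = 0.0
        else:
            mean = target_coverage * karyotype.copies[s.name] / 2.0
        if noise == "none" or mean == 0.0:
            tracks[s.name] = np.full(s.length, mean, dtype=float)
        else:
            tracks[s.name] = rng.poisson(mean, s.length).astype(float)
    label = embryo_id or (karyotype.label or "embryo")
    return DepthProfile(embryo_id=label, tracks=tracks)


# ---------------------------------------------------------------------------
# embryo-fate model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossFateParams:
    """Fate probabilities and defect-count distributions for one cross.

    The first division has three outcomes: ``normal`` (the embryo
    develops as a diploid), ``complete_paternal_loss`` (a maternal-only
    haploid that blastulates but never hatches) and
    ``partial_paternal_loss`` (aneuploid arrest before blastulation).
    """

    p_partial_loss: float
    p_complete_loss: float
    p_normal: float
    p_blastula_given_haploid: float = 1.0
    p_blastula_given_diploid: float = 1.0
    p_hatch_given_diploid: float = 1.0
    p_hatch_given_haploid: float = 0.0
    p_adult_given_hatched: float = 1.0
    fallout_mean: float = 0.0
    fallout_sd: float = 0.0
    division_error_rate_mean: float = 0.01
    division_error_rate_concentration: float = 20.0
    divisions_scored: int = 20

    def __post_init__(self) -> None:
        triple = (self.p_partial_loss, self.p_complete_loss, self.p_normal)
        for p in triple + (
            self.p_blastula_given_haploid,
            self.p_blastula_given_diploid,
            self.p_hatch_given_diploid,
            self.p_hatch_given_haploid,
            self.p_adult_given_hatched,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(triple) - 1.0) > 1e-9:
            raise ValueError(
                f"first-division probabilities sum to {sum(triple)}, not 1"
            )
        if self.fallout_mean < 0 or self.fallout_sd < 0:
            raise ValueError("fallout moments must be non-negative")
        if not 0.0 < self.division_error_rate_mean < 1.0:
            raise ValueError("division_error_rate_mean must be in (0, 1)")
        if self.division_error_rate_concentration <= 0:
            raise ValueError("division_error_rate_concentration must be positive")
        if self.divisions_scored <= 0:
            raise ValueError("divisions_scored must be positive")


@dataclass(frozen=True)
class FateParams:
    """Per-cross fate parameters for a four-cross experiment."""

    crosses: Mapping[str, CrossFateParams]

    def __post_init__(self) -> None:
        if not self.crosses:
            raise ValueError("at least one cross required")

    @classmethod
    def default(cls) -> "FateParams":
        # CI split: ~70% first-division arrest; of the ~30% reaching
        # the blastoderm, 42% diploid / 58% haploid. Hatch-given-diploid
        # 0.7 is a fitted slack for late diploid lethality, not a
        # measured value. Adult-given-hatched: 94/137, 520/548, 511/588.
        return cls(
            crosses={
                "wild_type": CrossFateParams(
                    p_partial_loss=0.05,
                    p_complete_loss=0.03,
                    p_normal=0.92,
                    p_hatch_given_diploid=1.0,
                    p_adult_given_hatched=0.95,
                    fallout_mean=0.3,
                    fallout_sd=0.6,
                    division_error_rate_mean=0.02,
                    division_error_rate_concentration=20.0,
                ),
                "CI": CrossFateParams(
                    p_partial_loss=0.70,
                    p_complete_loss=0.174,
                    p_normal=0.126,
                    p_hatch_given_diploid=0.7,
                    p_adult_given_hatched=0.69,
                    fallout_mean=8.0,
                    fallout_sd=5.0,
                    division_error_rate_mean=0.15,
                    division_error_rate_concentration=8.0,
                ),
                "rescue": CrossFateParams(
                    p_partial_loss=0.06,
                    p_complete_loss=0.06,
                    p_normal=0.88,
                    p_hatch_given_diploid=1.0,
                    p_adult_given_hatched=0.87,
                    fallout_mean=0.8,
                    fallout_sd=1.0,
                    division_error_rate_mean=0.05,
                    division_error_rate_concentration=15.0,
                ),
                "reciprocal": CrossFateParams(
                    p_partial_loss=0.05,
                    p_complete_loss=0.04,
                    p_normal=0.91,
                    p_hatch_given_diploid=1.0,
                    p_adult_given_hatched=0.95,
                    fallout_mean=0.3,
                    fallout_sd=0.6,
                    division_error_rate_mean=0.02,
                    division_error_rate_concentration=20.0,
                ),
            }
        )

    @classmethod
    def from_config(cls, path) -> "FateParams":
        """Load overrides from a ``cross.field = value`` key/value file,
        starting from the defaults."""
        base = {name: cp for name, cp in cls.default().crosses.items()}
        overrides: dict[str, dict[str, float]] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'cross.field = value'")
                key, value = (part.strip() for part in line.split("=", 1))
                if "." not in key:
                    raise ValueError(f"{path}:{lineno}: key must be 'cross.field'")
                cross, fieldname = key.split(".", 1)
                overrides.setdefault(cross, {})[fieldname] = (
                    int(value) if fieldname == "divisions_scored" else float(value)
                )
        crosses = dict(base)
        for cross, kv in overrides.items():
            if cross in crosses:
                crosses[cross] = replace(crosses[cross], **kv)
            else:
                crosses[cross] = CrossFateParams(**kv)
        return cls(crosses=crosses)


class CohortTable:
    """Per-embryo fate records (one row per embryo) with invariants."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        self.df = df.reset_index(drop=True)
        self.validate()

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        df = self.df
        if (df["divisions_errored"] > df["divisions_scored"]).any():
            raise ValueError("divisions_errored exceeds divisions_scored")
        if (df["fallout_count"] < 0).any():
            raise ValueError("negative fallout_count")
        bad = ~df["ploidy"].isin(PLOIDY_CLASSES)
        if bad.any():
            raise ValueError(f"unknown ploidy class: {df.loc[bad, 'ploidy'].unique()}")
        if (df["hatched"] & ~df["reached_blastula"]).any():
            raise ValueError("hatched embryo that never blastulated")
        if (df["adult"] & ~df["hatched"]).any():
            raise ValueError("adult that never hatched")
        if ((df["ploidy"] == "haploid") & df["hatched"]).any():
            raise ValueError("hatched haploid")
        if (
            (df["first_division"] == "partial_paternal_loss") & df["reached_blastula"]
        ).any():
            raise ValueError("arrested embryo that blastulated")

    def counts(self, cross: str) -> dict[str, tuple[int, int]]:
        sub = self.df[self.df["cross"] == cross]
        if sub.empty:
            raise KeyError(f"no embryos for cross {cross!r}")
        n = len(sub)
        return {
            "blastula": (int(sub["reached_blastula"].sum()), n),
            "hatch": (int(sub["hatched"].sum()), n),
            "adult_given_hatched": (int(sub["adult"].sum()), int(sub["hatched"].sum())),
        }

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CohortTable":
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={
                "cross": str,
                "first_division": str,
                "ploidy": str,
                "fallout_count": int,
                "divisions_scored": int,
                "divisions_errored": int,
            },
        )
        for col in ("reached_blastula", "hatched", "adult"):
            if df[col].dtype != bool:
                df[col] = df[col].astype(str).str.lower().map({"true": True, "false": False})
        return cls(df)


def _draw_fallout(rng: np.random.Generator, mean: float, sd: float) -> int:
    if mean == 0:
        return 0
    var = sd * sd
    if var <= mean:
        return int(rng.poisson(mean))
    # negative binomial by moment matching: p = mean/var, r = mean^2/(var-mean)
    p = mean / var
    r = mean * mean / (var - mean)
    return int(rng.negative_binomial(r, p))


def _simulate_embryo(
    rng: np.random.Generator, cp: CrossFateParams, cross: str
) -> dict:
    u = rng.random()
    if u < cp.p_partial_loss:
        first_division = "partial_paternal_loss"
        ploidy = "aneuploid_arrested"
        reached = False
        hatched = False
    elif u < cp.p_partial_loss + cp.p_complete_loss:
        first_division = "complete_paternal_loss"
        ploidy = "haploid"
        reached = rng.random() < cp.p_blastula_given_haploid
        hatched = False  # haploids never hatch in this model
    else:
        first_division = "normal"
        ploidy = "diploid"
        reached = rng.random() < cp.p_blastula_given_diploid
        hatched = reached and rng.random() < cp.p_hatch_given_diploid
    adult = hatched and rng.random() < cp.p_adult_given_hatched
    fallout = _draw_fallout(rng, cp.fallout_mean, cp.fallout_sd)
    m, k = cp.division_error_rate_mean, cp.division_error_rate_concentration
    err_rate = rng.beta(m * k, (1.0 - m) * k)
    errored = int(rng.binomial(cp.divisions_scored, err_rate))
    return {
        "cross": cross,
        "first_division": first_division,
        "reached_blastula": reached,
        "ploidy": ploidy,
        "hatched": hatched,
        "adult": adult,
        "fallout_count": fallout,
        "divisions_scored": cp.divisions_scored,
        "divisions_errored": errored,
    }


def simulate_cohort(
    params: FateParams, n_embryos_per_cross: int, seed: int = 0
) -> CohortTable:
    """Simulate one fate record per embryo per cross.

    Each embryo gets its own seeded sub-stream keyed by (cross index,
    embryo index), so embryo *i* of a cross is identical no matter how
    many embryos are simulated.
    """
    if n_embryos_per_cross <= 0:
        raise ValueError("n_embryos_per_cross must be positive")
    rows = []
    for ci, (cross, cp) in enumerate(params.crosses.items()):
        for i in range(n_embryos_per_cross):
            rng = np.random.default_rng(_entropy(seed, ci, i))
            rows.append(_simulate_embryo(rng, cp, cross))
    return CohortTable(pd.DataFrame(rows, columns=COHORT_COLUMNS))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def write_fasta(layout: GenomeLayout, path, line_width: int = 70) -> None:
    """Random uppercase sequences per layout entry, seeded from the layout."""
    with open(path, "w") as fh:
        for idx, s in enumerate(layout.sequences):
            rng = np.random.default_rng(_entropy(layout.seed, idx))
            seq = rng.choice(_BASES, size=s.length)
            text = seq.tobytes().decode("ascii")
            fh.write(f">{s.name}\n")
            for i in range(0, len(text), line_width):
                fh.write(text[i : i + line_width] + "\n")


def write_genes_bed(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for g in layout.genes:
            fh.write(f"{g.sequence_name}\t{g.start}\t{g.end}\t{g.name}\t0\t+\n")


def write_manifest_tsv(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tlength\trole\n")
        for s in layout.sequences:
            fh.write(f"{s.name}\t{s.length}\t{s.role}\n")


def read_manifest_tsv(path, genes: Iterable[GeneInterval] = (), seed: int = 0) -> GenomeLayout:
    """Rebuild a layout from a sequence manifest plus (optionally) genes."""
    sequences = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["name", "length", "role"]:
            raise ValueError(f"{path}: unexpected manifest header {header}")
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            name, length, role = line.split("\t")
            sequences.append(SequenceInfo(name=name, length=int(length), role=role))
    baseline = {}
    for s in sequences:
        if s.role == "nuclear_arm":
            baseline[s.name] = 0 if s.name == "Y" else 2
        elif s.role == "mitochondrion":
            baseline[s.name] = 1
        else:
            baseline[s.name] = 0
    return GenomeLayout(
        sequences=tuple(sequences),
        genes=tuple(genes),
        baseline_copy=baseline,
        seed=seed,
    )


def expected_percent_depth(
    layout: GenomeLayout, karyotype: Karyotype, sequence_name: str
) -> float:
    """Closed-form noise-free percent depth of any position on
    ``sequence_name``: 100 * copies / length-weighted mean copies of
    the denominator arms."""
    from .depth_quant import denominator_sequences

    denom = denominator_sequences(layout)
    lengths = layout.sequence_lengths()
    wsum = sum(lengths[a] * karyotype.copies[a] for a in denom)
    total = sum(lengths[a] for a in denom)
    mean_copies = wsum / total
    if mean_copies == 0:
        raise ValueError("denominator arms all at zero copies")
    return 100.0 * karyotype.copies[sequence_name] / mean_copies
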