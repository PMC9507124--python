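"""Per-position depth ingestion and normalized depth statistics.

The central statistic is *percent depth*: the mean depth across a gene
divided by the mean depth across the embryo's genome, times 100. Because
every embryo is normalized to itself, percent depth is invariant to
library size and sequencing effort, and a gene's expected value reduces
to ``100 * copies(gene) / copy-weighted genome mean``.

Coordinates are 0-based, half-open everywhere; bedGraph gaps densify to
depth 0 (a real zero, not missing data).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import GeneInterval, GenomeLayout


class BedgraphError(ValueError):
    """Malformed or inconsistent bedGraph input."""


@dataclass
class DepthProfile:
    """Dense per-position depth for one embryo, one array per sequence."""

    embryo_id: str
    tracks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, arr in self.tracks.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"track {name!r} must be one-dimensional")
            if np.any(arr < 0):
                raise ValueError(f"track {name!r} contains negative depth")
            self.tracks[name] = arr

    def track(self, name: str) -> np.ndarray:
        try:
            return self.tracks[name]
        except KeyError:
            raise KeyError(f"no depth track for sequence {name!r}") from None


@dataclass(frozen=True)
class GeneDepthSummary:
    """Mean depth over a gene and its percent of mean genome depth."""

    gene: str
    mean_depth: float
    percent_depth: float


def denominator_sequences(layout: "GenomeLayout") -> list[str]:
    """Sequences entering the mean-genome-depth denominator.

    Autosomal nuclear arms only. The mitochondrion, transgene and
    negative control are queries or independent normalizers, and the
    sex arms are excluded because their copy number varies with sex:
    in a real, autosome-dominated genome that variation barely moves
    the genome mean, but the miniature equal-length layout would let
    it swamp the denominator and shift every nominal dosage anchor.
    """
    return [
        s.name
        for s in layout.sequences
        if s.role == "nuclear_arm" and s.name not in layout.sex_arms
    ]


def read_depth_bedgraph(path, layout: "GenomeLayout") -> DepthProfile:
    """Parse a 4-column bedGraph into a dense :class:`DepthProfile`.

    Positions not covered by any interval get depth 0. Intervals may
    arrive unsorted but must not overlap.
    """
    lengths = layout.sequence_lengths()
    tracks = {name: np.zeros(n, dtype=float) for name, n in lengths.items()}
    seen: dict[str, list[tuple[int, int, int]]] = {name: [] for name in lengths}
    embryo_id = _stem(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise BedgraphError(
                    f"{path}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            chrom, start_s, end_s, depth_s = fields
            if chrom not in lengths:
                raise BedgraphError(
                    f"{path}:{lineno}: unknown sequence {chrom!r}"
                )
            try:
                start, end = int(start_s), int(end_s)
                depth = float(depth_s)
            except ValueError as exc:
                raise BedgraphError(f"{path}:{lineno}: {exc}") from None
            if start < 0 or end <= start:
                raise BedgraphError(
                    f"{path}:{lineno}: bad interval [{start}, {end})"
                )
            if end > lengths[chrom]:
                raise BedgraphError(
                    f"{path}:{lineno}: interval end {end} beyond "
                    f"{chrom!r} length {lengths[chrom]}"
                )
            if depth < 0:
                raise BedgraphError(f"{path}:{lineno}: negative depth {depth}")
            seen[chrom].append((start, end, lineno))
            tracks[chrom][start:end] = depth
    for chrom, ivals in seen.items():
        ivals.sort()
        for (s1, e1, l1), (s2, e2, l2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise BedgraphError(
                    f"{path}: overlapping intervals on {chrom!r}: "
                    f"[{s1}, {e1}) at line {l1} and [{s2}, {e2}) at line {l2}"
                )
    return DepthProfile(embryo_id=embryo_id, tracks=tracks)


def write_depth_bedgraph(profile: DepthProfile, path) -> None:
    """Write a profile as 4-column bedGraph, run-length encoded.

    Zero-depth runs are omitted; the reader densifies them back, so a
    write/read round trip is value-identical.
    """
    with open(path, "w") as fh:
        for name in profile.tracks:
            arr = profile.tracks[name]
            if arr.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                vs = str(int(v)) if float(v).is_integer() else repr(float(v))
                fh.write(f"{name}\t{s}\t{e}\t{vs}\n")


def read_annotation_bed(path, layout: "GenomeLayout") -> list["GeneInterval"]:
    """Read gene intervals from a BED file (>= 4 columns) and validate
    them against the layout. Strand (column 6) is accepted and ignored."""
    from .synthetic_data import GeneInterval

    lengths = layout.sequence_lengths()
    genes: list[GeneInterval] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns")
            chrom, start_s, end_s, name = fields[:4]
            if chrom not in lengths:
                raise ValueError(f"{path}:{lineno}: unknown sequence {chrom!r}")
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            if start < 0 or end > lengths[chrom]:
                raise ValueError(
                    f"{path}:{lineno}: interval outside {chrom!r} bounds"
                )
            if name in names:
                raise ValueError(f"{path}:{lineno}: duplicate gene {name!r}")
            names.add(name)
            genes.append(
                GeneInterval(name=name, sequence_name=chrom, start=start, end=end)
            )
    return genes


def mean_genome_depth(
    profile: DepthProfile,
    layout: "GenomeLayout",
    sequences: Sequence[str] | None = None,
) -> float:
    """Length-weighted mean depth over the denominator sequences.

    ``sequences`` overrides the default autosomal-arm denominator
    (see :func:`denominator_sequences`).
    """
    if sequences is None:
        sequences = denominator_sequences(layout)
    total_len = 0
    total_depth = 0.0
    for name in sequences:
        arr = profile.track(name)
        total_len += arr.size
        total_depth += float(arr.sum())
    if total_len == 0:
        raise ValueError("denominator has zero total length")
    return total_depth / total_len


def compute_gene_summaries(
    profile: DepthProfile,
    genes: Iterable["GeneInterval"],
    genome_mean: float,
) -> list[GeneDepthSummary]:
    """Percent depth per gene: 100 * mean(gene depth) / genome mean."""
    if genome_mean <= 0:
        raise ValueError("undefined normalization: mean genome depth <= 0")
    out = []
    for g in genes:
        arr = profile.track(g.sequence_name)[g.start : g.end]
        mean_depth = float(arr.mean()) if arr.size else 0.0
        out.append(
            GeneDepthSummary(
                gene=g.name,
                mean_depth=mean_depth,
                percent_depth=100.0 * mean_depth / genome_mean,
            )
        )
    return out


def mito_normalized_depth(profile: DepthProfile, layout: "GenomeLayout") -> float:
    """Mean genome depth divided by mean mitochondrial depth.

    A within-embryo control: the ratio is invariant to overall library
    scale, so a depressed value flags genome-wide (nuclear) depth loss
    relative to the mitochondrial baseline.
    """
    mito = [s.name for s in layout.sequences if s.role == "mitochondrion"]
    if not mito:
        raise ValueError("layout has no mitochondrion")
    mito_mean = float(np.mean(np.concatenate([profile.track(m) for m in mito])))
    if mito_mean <= 0:
        raise ValueError("mitochondrial mean depth is zero")
    return mean_genome_depth(profile, layout) / mito_mean


def _stem(path) -> str:
    import os

    base = os.path.basename(os.fspath(path))
    for suffix in (".bedgraph", ".bedGraph", ".bg", ".txt"):
        if base.endswith(suffix):
            return base[: -len(suffix)]
    return os.path.splitext(base)[0]
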