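"""Published per-group counts used as worked examples and fixtures.

Where only a percentage and an N were published, the count is
reconstructed as round-half-up(percent/100 * N); those entries are
flagged ``reconstructed`` below. Counts published directly (k/N) are
used verbatim.
"""

from __future__ import annotations

import importlib.resources

# Pooled blastulation vs hatch, per cross: {"blastula": (k, n), "hatch": (k, n)}.
# CI blastula 28% of 159 -> 45; CI hatch 2% of 2397 -> 48 (reconstructed);
# others reconstructed the same way.
LETHAL_PHASE_POOLED = {
    "wild_type": {"blastula": (113, 117), "hatch": (1111, 1208)},
    "CI": {"blastula": (45, 159), "hatch": (48, 2397)},
    "rescue": {"blastula": (57, 66), "hatch": (1127, 1281)},
    "reciprocal": {"blastula": (47, 47), "hatch": (1182, 1299)},
}

# Live-staging replicate of the same comparison (reconstructed:
# 38% of 147 -> 56; 16% of 110 -> 18; 91% of 40 -> 36; 92% of 58 -> 53).
LETHAL_PHASE_LIVE = {
    "wild_type": {"blastula": (36, 40), "hatch": (53, 58)},
    "CI": {"blastula": (56, 147), "hatch": (18, 110)},
}

# Abnormal embryos / embryos scored, by cross and nuclear-cycle window.
# All published directly as k/N.
ABNORMALITY_COUNTS = {
    "wt_cycles_2_9": (0, 64),
    "wt_cycles_10_11": (0, 13),
    "wt_cycles_12_14": (1, 58),
    "ci_cycles_2_9": (2, 63),
    "ci_cycles_10_11": (26, 108),
    "ci_cycles_12_14": (72, 190),
    "rescue_cycles_12_14": (7, 128),
}

# The three CI stage groups compared by the exact test (2x3 table).
CI_STAGE_GROUPS = ("ci_cycles_2_9", "ci_cycles_10_11", "ci_cycles_12_14")

# Late-window comparison across crosses (2x3 table).
LATE_STAGE_GROUPS = ("wt_cycles_12_14", "ci_cycles_12_14", "rescue_cycles_12_14")

# Hatched-egg-to-adult survival, published directly as k/N.
EGG_TO_ADULT = {
    "wild_type": (520, 548),
    "CI": (94, 137),
    "rescue": (511, 588),
}


def all_tables() -> dict[str, tuple[int, int]]:
    """Flat name -> (affected, total) view of every printed table."""
    out: dict[str, tuple[int, int]] = {}
    for cross, kv in LETHAL_PHASE_POOLED.items():
        out[f"pooled_{cross}_blastula"] = kv["blastula"]
        out[f"pooled_{cross}_hatch"] = kv["hatch"]
    for cross, kv in LETHAL_PHASE_LIVE.items():
        out[f"live_{cross}_blastula"] = kv["blastula"]
        out[f"live_{cross}_hatch"] = kv["hatch"]
    out.update(ABNORMALITY_COUNTS)
    for cross, kt in EGG_TO_ADULT.items():
        out[f"egg_to_adult_{cross}"] = kt
    return out


def counts_config_path():
    """Path to the shipped plain-text counts fixture."""
    return importlib.resources.files("ploidyscan").joinpath("data/printed_counts.txt")


def parse_counts_config(path) -> dict[str, tuple[int, int]]:
    """Parse a plain-text counts file: ``name<TAB>affected<TAB>total``
    per line, ``#`` comments allowed."""
    tables: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'name affected total'")
            name, k, t = fields
            if name in tables:
                raise ValueError(f"{path}:{lineno}: duplicate table {name!r}")
            tables[name] = (int(k), int(t))
    return tables
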