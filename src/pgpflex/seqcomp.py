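"""Glycine/proline content statistics over TMD regions of aligned
ABC-exporter sequences.

Glycine and proline are helix breakers; their abundance in the
transmembrane helices of an exporter family is a sequence-level proxy
for helical flexibility.  This module counts G/P per sequence over an
annotated alignment-column span and compares groups of sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .ensemble_io import AlignmentBlock

GAP = "-"
AMINO = set("ACDEFGHIKLMNPQRSTVWY") | {"B", "Z", "X", "U", "O"}  # incl. ambiguity codes


@dataclass(frozen=True)
class GlyProCount:
    """Per-sequence G and P counts over one region; n_residues counts
    the non-gap characters."""

    seq_id: str
    region: str
    n_gly: int
    n_pro: int
    n_residues: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_gly + self.n_pro <= self.n_residues):
            raise ValueError("G+P counts exceed residue count")


@dataclass
class CompositionSummary:
    """All per-sequence counts for a region plus a joint (n_gly, n_pro)
    histogram and marginal statistics."""

    region: str
    counts: List[GlyProCount]
    joint: pd.DataFrame  # index n_gly, columns n_pro, values counts
    mean_gly: float
    mean_pro: float
    quantiles_gly: Dict[float, float]
    quantiles_pro: Dict[float, float]

    @property
    def n_sequences(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.seq_id, c.region, c.n_gly, c.n_pro, c.n_residues) for c in self.counts],
            columns=["seq_id", "region", "n_gly", "n_pro", "n_residues"],
        )


def count_glypro(row: str, span: Tuple[int, int], seq_id: str = "",
                 region: str = "") -> GlyProCount:
    """Count G and P among the non-gap characters of ``row`` within the
    half-open column interval ``span``.  Case-insensitive; characters
    outside the amino-acid alphabet (plus gap) are an error.
    """
    lo, hi = span
    if not (0 <= lo <= hi <= len(row)):
        raise ValueError(f"span ({lo}, {hi}) outside alignment width {len(row)}")
    segment = row[lo:hi].upper()
    n_gly = n_pro = n_res = 0
    for ch in segment:
        if ch == GAP:
            continue
        if ch not in AMINO:
            raise ValueError(f"invalid character {ch!r} in sequence {seq_id!r}")
        n_res += 1
        if ch == "G":
            n_gly += 1
        elif ch == "P":
            n_pro += 1
    return GlyProCount(seq_id=seq_id, region=region, n_gly=n_gly,
                       n_pro=n_pro, n_residues=n_res)


def summarize_composition(block: AlignmentBlock, region: str) -> CompositionSummary:
    """Per-sequence G/P counts over a named region of the alignment,
    with a joint histogram and marginal means/quantiles.

    Output ordering is deterministic (sorted by seq_id)."""
    if region not in block.region_spans:
        raise ValueError(f"unknown region {region!r}; have {sorted(block.region_spans)}")
    span = block.region_spans[region]
    counts = [
        count_glypro(row, span, seq_id=sid, region=region)
        for sid, row in sorted(zip(block.ids, block.rows), key=lambda x: x[0])
    ]
    gly = np.array([c.n_gly for c in counts])
    pro = np.array([c.n_pro for c in counts])
    joint = pd.crosstab(pd.Series(gly, name="n_gly"), pd.Series(pro, name="n_pro"))
    qs = (0.05, 0.25, 0.5, 0.75, 0.95)
    return CompositionSummary(
        region=region,
        counts=counts,
        joint=joint,
        mean_gly=float(gly.mean()),
        mean_pro=float(pro.mean()),
        quantiles_gly={q: float(np.quantile(gly, q)) for q in qs},
        quantiles_pro={q: float(np.quantile(pro, q)) for q in qs},
    )


@dataclass
class GroupComparison:
    """Difference of mean counts (a − b) with percentile bootstrap CIs."""

    diff_gly: float
    diff_pro: float
    ci_gly: Tuple[float, float]
    ci_pro: Tuple[float, float]
    n_resamples: int
    seed: int

    def significant_gly(self) -> bool:
        return not (self.ci_gly[0] <= 0.0 <= self.ci_gly[1])

    def significant_pro(self) -> bool:
        return not (self.ci_pro[0] <= 0.0 <= self.ci_pro[1])


def compare_groups(summary_a: CompositionSummary, summary_b: CompositionSummary,
                   n_resamples: int = 10_000, seed: int = 0,
                   ci_level: float = 0.95) -> GroupComparison:
    """Seeded percentile-bootstrap comparison of mean G and P counts
    between two sequence groups."""
    ga = np.array([c.n_gly for c in summary_a.counts], dtype=float)
    gb = np.array([c.n_gly for c in summary_b.counts], dtype=float)
    pa = np.array([c.n_pro for c in summary_a.counts], dtype=float)
    pb = np.array([c.n_pro for c in summary_b.counts], dtype=float)
    if ga.size == 0 or gb.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, ga.size, size=(n_resamples, ga.size))
    ib = rng.integers(0, gb.size, size=(n_resamples, gb.size))
    boot_g = ga[ia].mean(axis=1) - gb[ib].mean(axis=1)
    boot_p = pa[ia].mean(axis=1) - pb[ib].mean(axis=1)
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    return GroupComparison(
        diff_gly=float(ga.mean() - gb.mean()),
        diff_pro=float(pa.mean() - pb.mean()),
        ci_gly=(float(np.quantile(boot_g, lo_q)), float(np.quantile(boot_g, hi_q))),
        ci_pro=(float(np.quantile(boot_p, lo_q)), float(np.quantile(boot_p, hi_q))),
        n_resamples=n_resamples,
        seed=seed,
    )
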