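"""Crosslink restraint validation of predicted complex models.

Crosslinked residue pairs are mapped onto model Cα coordinates and classified
as satisfied (Cα-Cα distance within the crosslinker-compatible maximum, 30 Å
for DSSO by default, inclusive) or violated.  Violation percentages are
tallied per PPI — heteromeric and self links separately — and summarised
against model confidence (ipTM) in bins, reproducing the standard
violation-vs-confidence boxplot construction: per-PPI percentages first, then
median and quartiles per ipTM bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from xlscreen.model_io import StructureModel
from xlscreen.xlnet import CrosslinkRecord

__all__ = [
    "RestraintResult",
    "ViolationSummary",
    "DEFAULT_THRESHOLD",
    "DEFAULT_IPTM_EDGES",
    "map_restraints",
    "violation_summary",
    "violation_by_iptm",
]

DEFAULT_THRESHOLD = 30.0  # Å, Cα-Cα, DSSO-compatible
# confidence ranges used to stratify violation: random-like, gray zone split
# at 0.75, and high confidence
DEFAULT_IPTM_EDGES = (0.0, 0.55, 0.75, 0.85, 1.0)


@dataclass
class RestraintResult:
    """One crosslink record mapped (or not) onto one model."""

    record: CrosslinkRecord
    mapped: bool
    distance: float = float("nan")  # Å, defined when mapped
    heteromeric: bool = False
    chain_assignment: tuple[tuple[str, int], tuple[str, int]] | None = None

    def satisfied(self, threshold: float = DEFAULT_THRESHOLD) -> bool:
        if not self.mapped:
            raise ValueError("satisfaction undefined for unmapped restraints")
        return self.distance <= threshold


@dataclass
class ViolationSummary:
    """Per-PPI violation tallies at a fixed distance threshold."""

    ppi: tuple[str, ...]
    iptm: float
    n_hetero_mapped: int = 0
    n_hetero_violated: int = 0
    n_self_mapped: int = 0
    n_self_violated: int = 0
    n_unmapped: int = 0
    threshold: float = DEFAULT_THRESHOLD

    @property
    def pct_hetero_violated(self) -> float:
        """100 * violated / mapped over heteromeric links; NaN when none mapped."""
        if self.n_hetero_mapped == 0:
            return float("nan")
        return 100.0 * self.n_hetero_violated / self.n_hetero_mapped


def map_restraints(
    model: StructureModel,
    records: Iterable[CrosslinkRecord],
) -> list[RestraintResult]:
    """Assign each crosslink end to a model chain and measure the distance.

    Each end maps to a chain carrying its accession; when an accession occurs
    on several chains (homo-oligomers, and both orders of a self link), the
    assignment minimising the Cα-Cα distance is chosen — the standard
    convention for ambiguous crosslinks.  Records whose accession is absent
    or whose residue is unresolved are returned as mapped=False.
    """
    results = []
    for rec in records:
        ends_a = [
            (c, rec.res_a) for c in model.chains_for(rec.protein_a)
            if c.ca(rec.res_a) is not None
        ]
        ends_b = [
            (c, rec.res_b) for c in model.chains_for(rec.protein_b)
            if c.ca(rec.res_b) is not None
        ]
        best = None
        for ca, ra in ends_a:
            for cb, rb in ends_b:
                if ca is cb and ra == rb:
                    continue  # an end cannot link to itself on the same chain
                d = float(np.linalg.norm(ca.ca(ra) - cb.ca(rb)))
                if best is None or d < best[0]:
                    best = (d, ((ca.chain_id, ra), (cb.chain_id, rb)))
        if best is None:
            results.append(RestraintResult(record=rec, mapped=False,
                                           heteromeric=not rec.is_self))
        else:
            results.append(
                RestraintResult(
                    record=rec,
                    mapped=True,
                    distance=best[0],
                    heteromeric=not rec.is_self,
                    chain_assignment=best[1],
                )
            )
    return results


def violation_summary(
    results: Sequence[RestraintResult],
    threshold: float = DEFAULT_THRESHOLD,
    ppi: tuple[str, ...] = (),
    iptm: float = float("nan"),
) -> ViolationSummary:
    """Tally satisfied/violated restraints from one model.

    A restraint is satisfied iff its distance <= ``threshold`` (inclusive).
    Heteromeric and self links are tallied separately; unmapped records are
    counted but excluded from all denominators.
    """
    s = ViolationSummary(ppi=tuple(ppi), iptm=iptm, threshold=threshold)
    for res in results:
        if not res.mapped:
            s.n_unmapped += 1
            continue
        violated = res.distance > threshold
        if res.heteromeric:
            s.n_hetero_mapped += 1
            s.n_hetero_violated += int(violated)
        else:
            s.n_self_mapped += 1
            s.n_self_violated += int(violated)
    return s


def violation_by_iptm(
    summaries: Iterable[ViolationSummary],
    bin_edges: Sequence[float] = DEFAULT_IPTM_EDGES,
) -> list[dict]:
    """Median and quartiles of heteromeric violation % per ipTM bin.

    Bins are half-open (low, high] except the first, which includes its lower
    edge.  Summaries with no mapped heteromeric links (undefined percentage)
    are excluded from the bins and reported in the per-bin ``n_undefined``
    side count.  Empty bins are flagged.
    """
    edges = list(bin_edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise ValueError("bin edges must be strictly increasing")
    bins = [
        {"range": (lo, hi), "n": 0, "n_undefined": 0, "median": float("nan"),
         "q25": float("nan"), "q75": float("nan"), "empty": True, "values": []}
        for lo, hi in zip(edges[:-1], edges[1:])
    ]

    def _bin_for(x: float):
        for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            if (lo < x <= hi) or (i == 0 and x == lo):
                return bins[i]
        return None

    for s in summaries:
        b = _bin_for(s.iptm)
        if b is None:
            continue
        pct = s.pct_hetero_violated
        if np.isnan(pct):
            b["n_undefined"] += 1
        else:
            b["values"].append(pct)
    for b in bins:
        vals = b.pop("values")
        b["n"] = len(vals)
        if vals:
            b["empty"] = False
            b["median"] = float(np.median(vals))
            b["q25"], b["q75"] = (float(q) for q in np.percentile(vals, [25, 75]))
    return bins
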