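"""Confidence calibration of predicted complex models.

Predicted protein pairs are tiered by their best ipTM: below the low cut the
prediction is indistinguishable from random pairing, above the high cut it is
high confidence, and in between lies a gray zone where external evidence
(e.g. crosslinks) must arbitrate.  The cuts themselves are justified by a
target-decoy noise model: the ipTM histogram of real candidate pairs
(bimodal) is compared with decoys built from shuffled partners (one-tailed),
with target uncertainty estimated over repeated subsamples.  Homology
filtering (BLAST tabular hits against the PDB) and database/STRING annotation
round out the candidate bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from xlscreen.model_io import ScoreRecord
from xlscreen.xlnet import canonical_pair

__all__ = [
    "NoiseModelResult",
    "HomologyHit",
    "LOW_CUT",
    "HIGH_CUT",
    "tier_models",
    "decoy_noise",
    "parse_blast_tab",
    "homology_filter",
    "annotate_pairs",
    "read_score_table",
    "write_score_table",
]

LOW_CUT = 0.55   # below: random-like prediction
HIGH_CUT = 0.85  # above: high-confidence model


@dataclass
class NoiseModelResult:
    """Target-vs-decoy ipTM histogram comparison."""

    bin_edges: np.ndarray
    target_median_freq: np.ndarray
    target_sd: np.ndarray
    decoy_freq: np.ndarray
    n_subsample: int
    n_reps: int
    decoys_above_high_cut: int


@dataclass(frozen=True)
class HomologyHit:
    """One BLAST hit of a query protein (or pair key) against a PDB chain."""

    query: str
    subject: str  # PDB chain id, e.g. "1ABC_A"
    identity: float  # percent
    evalue: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity must be in [0, 100], got {self.identity}")
        if self.evalue <= 0:
            raise ValueError(f"evalue must be > 0, got {self.evalue}")

    @property
    def pdb_entry(self) -> str:
        return self.subject.split("_")[0]


def tier_models(
    records: Iterable[ScoreRecord],
    low: float = LOW_CUT,
    high: float = HIGH_CUT,
) -> dict[str, list[ScoreRecord]]:
    """Partition records into high_confidence / gray_zone / random_like.

    High confidence is strict (best ipTM > ``high``); the gray zone is
    ``low < best <= high``; everything else is random-like.  The three tiers
    always partition the input.
    """
    tiers: dict[str, list[ScoreRecord]] = {
        "high_confidence": [], "gray_zone": [], "random_like": []
    }
    for rec in records:
        score = rec.best_iptm
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"ipTM outside [0, 1]: {score} for {rec.members}")
        if score > high:
            tiers["high_confidence"].append(rec)
        elif score > low:
            tiers["gray_zone"].append(rec)
        else:
            tiers["random_like"].append(rec)
    return tiers


def decoy_noise(
    target: Sequence[ScoreRecord],
    decoy: Sequence[ScoreRecord],
    n_subsample: int = 300,
    n_reps: int = 10,
    bin_width: float = 0.1,
    seed: int = 0,
    high_cut: float = HIGH_CUT,
) -> NoiseModelResult:
    """Target-decoy ipTM noise model.

    ``n_reps`` subsamples of ``n_subsample`` target records (without
    replacement) are histogrammed on 0.1-wide bins; the per-bin median and
    standard deviation of the subsample frequencies summarise the target
    distribution, against the full decoy set's frequencies.  The count of
    decoys above the high-confidence cut is the empirical false-positive
    check (zero in the study this emulates).
    """
    if len(target) < n_subsample:
        raise ValueError(
            f"need >= {n_subsample} target records (got {len(target)}); "
            "reduce n_subsample"
        )
    rng = np.random.default_rng(seed)
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)

    target_scores = np.array(sorted(r.best_iptm for r in target))
    decoy_scores = np.array([r.best_iptm for r in decoy])

    freqs = np.empty((n_reps, n_bins))
    for rep in range(n_reps):
        sub = rng.choice(target_scores, size=n_subsample, replace=False)
        counts, _ = np.histogram(sub, bins=edges)
        freqs[rep] = counts / n_subsample
    decoy_counts, _ = np.histogram(decoy_scores, bins=edges)
    decoy_freq = (decoy_counts / len(decoy_scores)
                  if len(decoy_scores) else np.zeros(n_bins))
    return NoiseModelResult(
        bin_edges=edges,
        target_median_freq=np.median(freqs, axis=0),
        target_sd=freqs.std(axis=0, ddof=0),
        decoy_freq=decoy_freq,
        n_subsample=n_subsample,
        n_reps=n_reps,
        decoys_above_high_cut=int(np.sum(decoy_scores > high_cut)),
    )


def parse_blast_tab(path: str | Path) -> list[HomologyHit]:
    """Parse standard 12-column tabular alignment output (BLAST outfmt 6)."""
    hits = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ValueError(f"row {i}: expected 12 tab-separated columns, "
                             f"got {len(fields)}")
        try:
            hits.append(HomologyHit(
                query=fields[0],
                subject=fields[1],
                identity=float(fields[2]),
                evalue=max(float(fields[10]), 1e-200),  # 0.0 floored
            ))
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return hits


def homology_filter(
    hits: Iterable[HomologyHit],
    pairs: Sequence[tuple[str, str]],
    min_identity: float = 30.0,
    max_evalue: float = 1e-3,
) -> dict[tuple[str, str], bool]:
    """Flag pairs whose structure is already represented in the PDB.

    A hit passes iff identity >= ``min_identity`` AND evalue < ``max_evalue``.
    A pair is flagged when a passing hit is keyed by the pair itself
    ("ACC1--ACC2"), or when both members have passing hits to chains of the
    same PDB entry (a homologous complex).  Paralogs hitting the same PDB
    chain remain distinct queries and are judged independently.
    """
    passing_by_query: dict[str, set[str]] = {}
    for hit in hits:
        if hit.identity >= min_identity and hit.evalue < max_evalue:
            passing_by_query.setdefault(hit.query, set()).add(hit.pdb_entry)
    flags = {}
    for raw in pairs:
        pair = canonical_pair(*raw)
        key = f"{pair[0]}--{pair[1]}"
        if key in passing_by_query:
            flags[pair] = True
            continue
        entries_a = passing_by_query.get(pair[0], set())
        entries_b = passing_by_query.get(pair[1], set())
        flags[pair] = bool(entries_a & entries_b)
    return flags


def annotate_pairs(
    pairs: Sequence[tuple[str, str]],
    string_scores: Mapping[tuple[str, str], float] = {},
    db_pairs: Iterable[tuple[str, str]] = (),
    pdb_homolog: Mapping[tuple[str, str], bool] = {},
    string_cutoff: float = 0.4,
) -> dict[tuple[str, str], set[str]]:
    """Annotate candidate pairs against prior knowledge.

    ``string_annotated``: combined association score > ``string_cutoff``;
    ``novel_interaction``: absent from both the curated database and STRING;
    ``novel_interface``: no homologous structure in the PDB.
    """
    strings = {canonical_pair(*p): s for p, s in string_scores.items()}
    db = {canonical_pair(*p) for p in db_pairs}
    homologs = {canonical_pair(*p): f for p, f in pdb_homolog.items()}
    out = {}
    for raw in pairs:
        pair = canonical_pair(*raw)
        ann: set[str] = set()
        in_string = strings.get(pair, 0.0) > string_cutoff
        if in_string:
            ann.add("string_annotated")
        if homologs.get(pair, False):
            ann.add("pdb_homolog")
        else:
            ann.add("novel_interface")
        if pair not in db and not in_string:
            ann.add("novel_interaction")
        out[pair] = ann
    return out


def read_score_table(path: str | Path) -> list[ScoreRecord]:
    """Read a score TSV: protein_a, protein_b, model_idx, iptm, ptm[, origin]."""
    df = pd.read_csv(path, sep="\t")
    grouped: dict[tuple[str, str], ScoreRecord] = {}
    for row in df.sort_values("model_idx").itertuples(index=False):
        pair = canonical_pair(str(row.protein_a), str(row.protein_b))
        rec = grouped.get(pair)
        if rec is None:
            origin = set(str(getattr(row, "origin", "")).split(";")) - {"", "nan"}
            rec = grouped[pair] = ScoreRecord(members=pair, origin=origin)
        rec.model_scores.append((float(row.iptm), float(row.ptm)))
    return sorted(grouped.values(), key=lambda r: r.members)


def write_score_table(records: Sequence[ScoreRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        a, b = rec.members[0], rec.members[-1]
        for idx, (iptm, ptm) in enumerate(rec.model_scores):
            rows.append((a, b, idx, iptm, ptm, ";".join(sorted(rec.origin))))
    pd.DataFrame(
        rows, columns=["protein_a", "protein_b", "model_idx", "iptm", "ptm", "origin"]
    ).to_csv(path, sep="\t", index=False)
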