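"""Crosslink tables -> canonical residue pairs -> PPI network -> filters.

An FDR-filtered crosslinking-MS table (xiFDR-style residue-pair export) is
parsed into canonical :class:`CrosslinkRecord` objects, aggregated into
protein-protein interaction (PPI) evidence, and filtered the way whole-cell
crosslinking networks usually are: interactions touching a handful of highly
abundant, promiscuously crosslinking hub proteins and interactions internal to
the ribosome are removed.  A final candidate list for structure prediction is
assembled by merging crosslinking, co-fractionation and curated-database pair
lists with provenance-aware exclusion rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CrosslinkRecord",
    "PPIEvidence",
    "SchemaError",
    "DEFAULT_HUBS",
    "DEFAULT_COLUMNS",
    "canonical_pair",
    "parse_crosslinks",
    "write_crosslinks",
    "aggregate_ppis",
    "filter_network",
    "merge_candidates",
]

# Abundant, highly crosslinked proteins removed from the network by default:
# ribosomal L7/L12, L1 and S3, elongation factors EF-Tu and EF-G, and the cold
# shock RNA chaperones CspC and CspB.
DEFAULT_HUBS = frozenset({"RplL", "RplA", "RpsC", "TufA", "FusA", "CspC", "CspB"})

DEFAULT_COLUMNS: Mapping[str, str] = {
    "protein_a": "Protein1",
    "res_a": "LinkPos1",
    "protein_b": "Protein2",
    "res_b": "LinkPos2",
}


class SchemaError(ValueError):
    """Raised when a table lacks a required column."""


@dataclass(frozen=True, order=True)
class CrosslinkRecord:
    """One crosslinked residue pair (a Cα-Cα distance restraint).

    Residue positions are 1-based over the full protein sequence.  Records are
    canonical: ``protein_a <= protein_b`` lexicographically, and for self links
    ``res_a <= res_b``; :meth:`canonical` enforces this.  ``true_distance`` and
    ``planted`` carry generator ground truth on synthetic records and are
    ignored by identity/ordering.
    """

    protein_a: str
    res_a: int
    protein_b: str
    res_b: int
    dataset_tag: str = "synthetic"
    true_distance: float | None = field(default=None, compare=False)
    planted: bool | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.res_a < 1 or self.res_b < 1:
            raise ValueError(
                f"residue positions must be >= 1, got {self.res_a}, {self.res_b}"
            )

    @property
    def is_self(self) -> bool:
        return self.protein_a == self.protein_b

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)

    @property
    def key(self) -> tuple[str, int, str, int]:
        return (self.protein_a, self.res_a, self.protein_b, self.res_b)

    def canonical(self) -> "CrosslinkRecord":
        a = (self.protein_a, self.res_a)
        b = (self.protein_b, self.res_b)
        if a <= b:
            return self
        return replace(self, protein_a=b[0], res_a=b[1], protein_b=a[0], res_b=a[1])


@dataclass
class PPIEvidence:
    """Evidence for one heteromeric protein pair."""

    pair: tuple[str, str]  # canonical (sorted) accessions
    n_unique_residue_pairs: int = 0
    sources: set[str] = field(default_factory=lambda: {"XLMS"})
    dataset_tags: set[str] = field(default_factory=set)
    intra_ribosome: bool = False
    involves_hub: bool = False
    novel: bool = False


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def parse_crosslinks(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    dataset_tag: str | None = None,
) -> list[CrosslinkRecord]:
    """Parse a crosslink residue-pair table (CSV or TSV).

    ``columns`` maps the four logical fields (protein_a, res_a, protein_b,
    res_b) to table column names; defaults match an xiFDR residue-pair export.
    An optional ``Dataset`` column (or the ``dataset_tag`` argument) tags each
    record's source dataset.  Records are canonicalized and deduplicated at
    the (protein_a, res_a, protein_b, res_b) level.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    for logical, name in colmap.items():
        if name not in df.columns:
            raise SchemaError(f"missing required column {name!r} (for {logical})")

    records: list[CrosslinkRecord] = []
    for idx, row in df.iterrows():
        ra, rb = int(row[colmap["res_a"]]), int(row[colmap["res_b"]])
        if ra < 1 or rb < 1:
            raise ValueError(f"row {idx}: residue position must be >= 1, got {ra}, {rb}")
        tag = dataset_tag or str(row.get("Dataset", "synthetic"))
        rec = CrosslinkRecord(
            protein_a=str(row[colmap["protein_a"]]),
            res_a=ra,
            protein_b=str(row[colmap["protein_b"]]),
            res_b=rb,
            dataset_tag=tag,
        ).canonical()
        records.append(rec)
    return dedupe(records)


def dedupe(records: Iterable[CrosslinkRecord]) -> list[CrosslinkRecord]:
    """Collapse duplicate residue pairs; multi-dataset provenance keeps the
    lexicographically first tag (tags are also recoverable from the raw rows)."""
    seen: dict[tuple, CrosslinkRecord] = {}
    for rec in records:
        rec = rec.canonical()
        prev = seen.get(rec.key)
        if prev is None or rec.dataset_tag < prev.dataset_tag:
            seen[rec.key] = rec
    return sorted(seen.values())


def write_crosslinks(records: Sequence[CrosslinkRecord], path: str | Path) -> None:
    """Write records as CSV with the default column names (round-trips)."""
    df = pd.DataFrame(
        {
            "Protein1": [r.protein_a for r in records],
            "LinkPos1": [r.res_a for r in records],
            "Protein2": [r.protein_b for r in records],
            "LinkPos2": [r.res_b for r in records],
            "Dataset": [r.dataset_tag for r in records],
        }
    )
    df.to_csv(path, index=False)


def aggregate_ppis(
    records: Iterable[CrosslinkRecord],
) -> tuple[list[PPIEvidence], dict[str, int]]:
    """Aggregate canonical records into per-pair evidence.

    Returns (heteromeric PPI evidence list, self-link-only protein counts).
    The second element maps proteins seen *only* in self links to their number
    of unique self residue pairs.
    """
    unique = dedupe(records)
    by_pair: dict[tuple[str, str], PPIEvidence] = {}
    self_counts: dict[str, int] = {}
    for rec in unique:
        if rec.is_self:
            self_counts[rec.protein_a] = self_counts.get(rec.protein_a, 0) + 1
            continue
        ev = by_pair.get(rec.pair)
        if ev is None:
            ev = by_pair[rec.pair] = PPIEvidence(pair=rec.pair, n_unique_residue_pairs=0)
        ev.n_unique_residue_pairs += 1
        ev.dataset_tags.add(rec.dataset_tag)
    hetero_proteins = {p for pair in by_pair for p in pair}
    self_only = {p: n for p, n in self_counts.items() if p not in hetero_proteins}
    return sorted(by_pair.values(), key=lambda e: e.pair), self_only


def network_stats(ppis: Sequence[PPIEvidence]) -> dict[str, int]:
    """Summary counts: heteromeric PPIs, unique residue pairs, unique proteins."""
    return {
        "n_ppis": len(ppis),
        "n_residue_pairs": sum(e.n_unique_residue_pairs for e in ppis),
        "n_proteins": len({p for e in ppis for p in e.pair}),
    }


def filter_network(
    ppis: Sequence[PPIEvidence],
    hub_accessions: Iterable[str] = DEFAULT_HUBS,
    ribosome_accessions: Iterable[str] = (),
    known_pairs: Iterable[tuple[str, str]] = (),
) -> tuple[list[PPIEvidence], list[PPIEvidence]]:
    """Remove hub-touching PPIs and intra-ribosome PPIs.

    Returns (kept, removed).  ``known_pairs`` (a curated-database snapshot)
    marks survivors absent from it as novel.  Filter accessions that never
    occur in the network trigger a warning, not an error, because accession
    mappings drift between proteome releases.
    """
    hubs = set(hub_accessions)
    ribo = set(ribosome_accessions)
    known = {canonical_pair(*p) for p in known_pairs}
    in_network = {p for e in ppis for p in e.pair}
    stray = (hubs | ribo) - in_network
    if stray and in_network:
        warnings.warn(f"filter accessions not present in network: {sorted(stray)}",
                      stacklevel=2)
    kept, removed = [], []
    for ev in ppis:
        a, b = ev.pair
        ev.involves_hub = a in hubs or b in hubs
        ev.intra_ribosome = a in ribo and b in ribo
        ev.novel = ev.pair not in known
        (removed if ev.involves_hub or ev.intra_ribosome else kept).append(ev)
    return kept, removed


def merge_candidates(
    xl: Iterable[tuple[str, str]],
    cofrac: Iterable[tuple[str, str]],
    db: Iterable[tuple[str, str]],
    ribosome_accessions: Iterable[str] = (),
    pdb_homolog_pairs: Iterable[tuple[str, str]] = (),
) -> dict[tuple[str, str], set[str]]:
    """Assemble the combined candidate list for structure prediction.

    Union of the three sources with provenance retained, minus:

    - intra-ribosome pairs (all sources);
    - homodimers from the database source (experimental homodimer evidence
      is kept — it may reflect a cross-chain link in a homo-oligomer);
    - database pairs with a homologous structure already in the PDB
      (experimentally derived pairs with PDB homologs are retained).

    Returns a mapping from canonical pair to its source set.
    """
    ribo = set(ribosome_accessions)
    homologs = {canonical_pair(*p) for p in pdb_homolog_pairs}
    candidates: dict[tuple[str, str], set[str]] = {}
    for source, pairs in (("XLMS", xl), ("CoFrac", cofrac), ("database", db)):
        for raw in pairs:
            pair = canonical_pair(*raw)
            if pair[0] in ribo and pair[1] in ribo:
                continue
            if source == "database" and (pair[0] == pair[1] or pair in homologs):
                continue
            candidates.setdefault(pair, set()).add(source)
    return candidates
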