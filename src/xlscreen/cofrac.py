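"""Co-fractionation MS (SEC) analysis: from elution profiles to PPI candidates.

Implements the candidate-generation chain applied to crosslinked vs untreated
*B. subtilis* SEC runs: abundance filtering (>= 3 peptides and >= 9.5e6 iBAQ
in all three replicates of at least one condition, ribosomal proteins
removed), max-normalized and smoothed profiles, a documented co-elution score
stand-in (clamped Pearson correlation of smoothed normalized profiles — the
original study used PCprophet's pre-GO co-elution score, which can be replayed
from a score table), the complex-level filter chain (<= 10 members, peak
elution before 19.5 ml, score >= 0.8 in >= 2 replicates of either condition,
all-against-all pairwise expansion), condition comparison, and ROC curves
against known vs random pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import pearsonr

from xlscreen.xlnet import canonical_pair

__all__ = [
    "CONDITIONS",
    "ElutionMatrix",
    "CoelutionRecord",
    "filter_abundance",
    "normalize_profiles",
    "coelution_score",
    "score_complexes",
    "expand_complex",
    "candidate_pairs",
    "compare_conditions",
    "roc_curve",
]

CONDITIONS = ("crosslinked", "untreated")

# default SEC geometry: fraction i collected at 10.5 + (i - 0.5) * 0.2 ml
_ML_OFFSET = 10.5
_ML_STEP = 0.2


@dataclass
class ElutionMatrix:
    """Protein intensity profiles over SEC fractions, replicates, conditions.

    ``intensities`` has shape (proteins, fractions, replicates, 2) with the
    condition axis ordered as :data:`CONDITIONS`.  ``peptide_counts`` and
    ``ibaq`` have shape (proteins, replicates, 2).
    """

    proteins: list[str]
    intensities: np.ndarray
    peptide_counts: np.ndarray | None = None
    ibaq: np.ndarray | None = None
    ml_offset: float = _ML_OFFSET
    ml_step: float = _ML_STEP
    ground_truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 4 or self.intensities.shape[3] != 2:
            raise ValueError("intensities must have shape (P, F, R, 2)")
        if self.intensities.shape[0] != len(self.proteins):
            raise ValueError("protein axis does not match protein list")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.ml_step <= 0:
            raise ValueError("fraction-to-ml map must be strictly increasing")
        self._index = {p: i for i, p in enumerate(self.proteins)}

    @property
    def n_fractions(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.intensities.shape[2]

    def fraction_to_ml(self, fraction: float) -> float:
        """Elution volume (ml) at the midpoint of a 1-based fraction."""
        return self.ml_offset + (fraction - 0.5) * self.ml_step

    def profiles(self, protein: str, condition: str) -> np.ndarray:
        """(replicates, fractions) intensity array for one protein."""
        ci = CONDITIONS.index(condition)
        return self.intensities[self._index[protein], :, :, ci].T

    def to_csv(self, path: str | Path) -> None:
        """Long-format CSV: protein, fraction, replicate, condition, intensity."""
        P, F, R, _ = self.intensities.shape
        rows = []
        for pi, prot in enumerate(self.proteins):
            for ci, cond in enumerate(CONDITIONS):
                for r in range(R):
                    for f in range(F):
                        rows.append((prot, f + 1, r + 1, cond,
                                     self.intensities[pi, f, r, ci]))
        pd.DataFrame(rows, columns=["protein", "fraction", "replicate",
                                    "condition", "intensity"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ElutionMatrix":
        df = pd.read_csv(path)
        proteins = sorted(df["protein"].astype(str).unique())
        F = int(df["fraction"].max())
        R = int(df["replicate"].max())
        arr = np.zeros((len(proteins), F, R, 2))
        pidx = {p: i for i, p in enumerate(proteins)}
        cidx = {c: i for i, c in enumerate(CONDITIONS)}
        for row in df.itertuples(index=False):
            arr[pidx[str(row.protein)], int(row.fraction) - 1,
                int(row.replicate) - 1, cidx[row.condition]] = row.intensity
        return cls(proteins=proteins, intensities=arr)


@dataclass
class CoelutionRecord:
    """Co-elution evidence for one pair within one complex and condition."""

    pair: tuple[str, str]
    condition: str
    replicate_scores: np.ndarray  # in [0, 1], one per replicate
    complex_id: str = ""
    complex_size: int = 2
    peak_elution_ml: float = 0.0

    def __post_init__(self) -> None:
        self.pair = canonical_pair(*self.pair)
        self.replicate_scores = np.asarray(self.replicate_scores, dtype=float)
        if np.any((self.replicate_scores < 0) | (self.replicate_scores > 1)):
            raise ValueError("replicate scores must lie in [0, 1]")


def filter_abundance(
    m: ElutionMatrix,
    min_peptides: int = 3,
    min_ibaq: float = 9.5e6,
    ribosome_accessions: Iterable[str] = (),
) -> list[str]:
    """Proteins quantified reliably enough for co-elution analysis.

    A protein is retained iff it has >= ``min_peptides`` identified peptides
    AND >= ``min_ibaq`` iBAQ in *all* replicates of at least one condition.
    Ribosomal proteins are removed when a ribosome set is supplied.
    """
    if m.peptide_counts is None or m.ibaq is None:
        raise ValueError("abundance filtering needs peptide_counts and ibaq")
    ribo = set(ribosome_accessions)
    ok = (m.peptide_counts >= min_peptides) & (m.ibaq >= min_ibaq)  # (P, R, 2)
    per_condition = ok.all(axis=1)  # (P, 2)
    keep = per_condition.any(axis=1)
    return [p for p, k in zip(m.proteins, keep) if k and p not in ribo]


def _normalize(profile: np.ndarray) -> np.ndarray | None:
    peak = profile.max()
    if peak <= 0:
        return None
    return profile / peak


def normalize_profiles(
    m: ElutionMatrix,
    group: Sequence[str],
    condition: str,
    smooth_sigma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Group elution profile: max-normalized, averaged, optionally smoothed.

    Each protein/replicate profile is scaled to maximum 1, then averaged over
    replicates and group members; the deviation is one standard deviation per
    fraction over the contributing profiles.  Smoothing (Gaussian, sigma in
    fractions) is applied to the mean.  All-zero profiles are excluded with a
    warning.
    """
    if not group:
        raise ValueError("group must be non-empty")
    normalized = []
    for prot in group:
        for rep_profile in m.profiles(prot, condition):
            norm = _normalize(rep_profile)
            if norm is None:
                warnings.warn(f"all-zero profile excluded: {prot}", stacklevel=2)
                continue
            normalized.append(norm)
    if not normalized:
        raise ValueError("no non-zero profiles in group")
    stack = np.vstack(normalized)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=0)
    if smooth_sigma > 0:
        mean = gaussian_filter1d(mean, smooth_sigma)
    return mean, sd


def coelution_score(
    a_profiles: np.ndarray,
    b_profiles: np.ndarray,
    smooth_sigma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate co-elution score: clamped Pearson on smoothed profiles.

    Stand-in for an external complex-centric co-elution score: each replicate
    profile is max-normalized and Gaussian-smoothed, then scored as
    ``max(0, pearson_r)``.  Returns (scores, zero_variance_flags); a profile
    with zero variance scores 0 and is flagged.
    """
    a = np.atleast_2d(np.asarray(a_profiles, dtype=float))
    b = np.atleast_2d(np.asarray(b_profiles, dtype=float))
    if a.shape != b.shape:
        raise ValueError("profile sets must share the fraction grid and replicates")
    scores = np.zeros(a.shape[0])
    flags = np.zeros(a.shape[0], dtype=bool)
    for r in range(a.shape[0]):
        pa, pb = _normalize(a[r]), _normalize(b[r])
        if pa is None or pb is None:
            flags[r] = True
            continue
        if smooth_sigma > 0:
            pa = gaussian_filter1d(pa, smooth_sigma)
            pb = gaussian_filter1d(pb, smooth_sigma)
        if np.ptp(pa) == 0 or np.ptp(pb) == 0:
            flags[r] = True
            continue
        scores[r] = max(0.0, pearsonr(pa, pb).statistic)
    return scores, flags


def expand_complex(members: Sequence[str]) -> list[tuple[str, str]]:
    """All-against-all binary expansion of a co-eluting group."""
    uniq = sorted(set(members))
    return [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1:]]


def score_complexes(
    m: ElutionMatrix,
    complexes: Mapping[str, Sequence[str]],
    smooth_sigma: float = 1.0,
) -> list[CoelutionRecord]:
    """Score every within-complex pair in both conditions.

    The peak elution of a complex is the fraction of maximum of the
    group-averaged normalized profile, mapped to ml.  Pairs are expanded
    all-against-all within each complex.
    """
    records: list[CoelutionRecord] = []
    for cid, members in complexes.items():
        members = sorted(set(members))
        for cond in CONDITIONS:
            try:
                mean, _ = normalize_profiles(m, members, cond, smooth_sigma)
            except ValueError:
                continue
            peak_ml = m.fraction_to_ml(float(np.argmax(mean) + 1))
            for a, b in expand_complex(members):
                scores, _ = coelution_score(
                    m.profiles(a, cond), m.profiles(b, cond), smooth_sigma
                )
                records.append(
                    CoelutionRecord(
                        pair=(a, b),
                        condition=cond,
                        replicate_scores=scores,
                        complex_id=cid,
                        complex_size=len(members),
                        peak_elution_ml=peak_ml,
                    )
                )
    return records


def candidate_pairs(
    records: Iterable[CoelutionRecord],
    score_cutoff: float = 0.8,
    min_replicates: int = 2,
    max_members: int = 10,
    max_elution_ml: float = 19.5,
) -> dict[str, set[tuple[str, str]]]:
    """The candidate filter chain, per condition and as a union.

    A record survives if its complex has <= ``max_members`` members and peaks
    before ``max_elution_ml``; a pair becomes a candidate in a condition if
    some surviving record there reaches ``score_cutoff`` in at least
    ``min_replicates`` replicates.  The union collects pairs passing in
    either condition.
    """
    out: dict[str, set[tuple[str, str]]] = {c: set() for c in CONDITIONS}
    for rec in records:
        if rec.complex_size > max_members or rec.peak_elution_ml >= max_elution_ml:
            continue
        if int(np.sum(rec.replicate_scores >= score_cutoff)) >= min_replicates:
            out[rec.condition].add(rec.pair)
    out["union"] = out[CONDITIONS[0]] | out[CONDITIONS[1]]
    return out


def compare_conditions(
    records: Iterable[CoelutionRecord],
    band: float = 0.1,
) -> dict[tuple[str, str], str]:
    """Classify each pair's co-elution change between conditions.

    The per-condition summary score is the median over replicates (max over
    records if a pair occurs in several complexes).  ``|Δ| <= band`` is
    ``similar``; otherwise the sign of (crosslinked - untreated) decides;
    pairs observed in only one condition are ``missing``.
    """
    summary: dict[tuple[str, str], dict[str, float]] = {}
    for rec in records:
        med = float(np.median(rec.replicate_scores))
        entry = summary.setdefault(rec.pair, {})
        entry[rec.condition] = max(entry.get(rec.condition, 0.0), med)
    result = {}
    for pair, scores in summary.items():
        if len(scores) < 2:
            result[pair] = "missing"
            continue
        delta = scores["crosslinked"] - scores["untreated"]
        if abs(delta) <= band:
            result[pair] = "similar"
        else:
            result[pair] = "higher_crosslinked" if delta > 0 else "higher_untreated"
    return result


def roc_curve(
    known_pairs: Sequence[tuple[str, str]],
    decoy_pairs: Sequence[tuple[str, str]],
    records: Iterable[CoelutionRecord],
) -> list[tuple[float, float, float]]:
    """ROC over co-elution score cutoffs 0.0..1.0 in 0.1 steps.

    TPR at a cutoff is the fraction of known pairs whose score (max over
    conditions of the median replicate score; 0 when absent from the records)
    reaches the cutoff; FPR likewise on the decoy pairs.
    """
    if not known_pairs:
        raise ValueError("known pair set must be non-empty")
    best: dict[tuple[str, str], float] = {}
    for rec in records:
        med = float(np.median(rec.replicate_scores))
        key = rec.pair
        best[key] = max(best.get(key, 0.0), med)

    def _score(pair) -> float:
        return best.get(canonical_pair(*pair), 0.0)

    known_scores = np.array([_score(p) for p in known_pairs])
    decoy_scores = np.array([_score(p) for p in decoy_pairs])
    curve = []
    for cutoff in np.linspace(0.0, 1.0, 11):
        tpr = float(np.mean(known_scores >= cutoff))
        fpr = float(np.mean(decoy_scores >= cutoff)) if len(decoy_pairs) else 0.0
        curve.append((float(cutoff), tpr, fpr))
    return curve
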