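"""Synthetic data with ground truth for every downstream stage.

Generates:

- Cα-only toy chains and multi-chain complexes (jittered ideal helices on a
  self-avoiding path), written as plain PDB;
- crosslinked residue pairs sampled within / beyond a distance bound, each
  carrying its true Cα-Cα distance so violation calls can be scored exactly;
- target and decoy confidence-score tables (bimodal targets, one-tailed
  decoys, emulating how real complex predictions separate from shuffled-pair
  decoys);
- SEC elution matrices (proteins x fractions x replicates x two conditions)
  with Gaussian co-elution peaks, multiplicative log-normal replicate noise
  and a crosslinking-dependent stabilization effect for labile complex
  members.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from xlscreen.cofrac import CONDITIONS, ElutionMatrix
from xlscreen.model_io import Chain, ScoreRecord, StructureModel
from xlscreen.xlnet import CrosslinkRecord

__all__ = [
    "SimConfig",
    "gen_toy_structure",
    "gen_toy_complex",
    "gen_crosslinks",
    "gen_score_table",
    "gen_elution_dataset",
]

# Ideal polyalanine helix parameters: ~3.8 Å Cα-Cα rise along the path,
# nearest non-adjacent approach (i, i+3) ~5 Å, so the 3.5 Å self-avoidance
# bound holds by construction.
_HELIX_RADIUS = 2.3
_HELIX_TWIST = np.deg2rad(100.0)
_HELIX_RISE = 1.5


@dataclass
class SimConfig:
    """Study conditions for the synthetic screen.

    Defaults mirror the experimental design the package targets: 50 SEC
    fractions, 3 replicates per condition, crosslinks satisfiable within
    28 Å Cα-Cα (scored against a 30 Å threshold downstream), bimodal target
    vs one-tailed decoy confidence scores with no decoy mass above 0.85.
    """

    seed: int = 0
    n_proteins: int = 30
    residues_min: int = 40
    residues_max: int = 80
    complex_spec: list[tuple[str, ...]] = field(default_factory=list)
    xl_within_max: float = 28.0
    xl_decoy_frac: float = 0.0
    n_fractions: int = 50
    n_replicates: int = 3
    stabilization_gain: float = 1.0
    labile_frac: float = 0.5
    noise_sigma: float = 0.25  # log-normal sigma on elution intensities
    abundance_fail_frac: float = 0.2
    peak_sigma: float = 1.5  # elution peak width in fractions
    # target mixture: (weight, mean, sd) per truncated-normal component
    target_score_mixture: tuple[tuple[float, float, float], ...] = (
        (0.45, 0.30, 0.12),
        (0.55, 0.90, 0.04),
    )
    # decoy: Beta(a, b) scaled to [0, truncation]; truncation 0.85 puts zero
    # decoy mass above the high-confidence cut
    decoy_score_mixture: tuple[float, float, float] = (1.2, 5.0, 0.85)

    def __post_init__(self) -> None:
        if self.n_fractions < 2:
            raise ValueError("n_fractions must be >= 2")
        for p in (self.xl_decoy_frac, self.labile_frac, self.abundance_fail_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.stabilization_gain < 0:
            raise ValueError("stabilization_gain must be non-negative")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _helix(n_res: int) -> np.ndarray:
    t = np.arange(n_res)
    return np.column_stack(
        [
            _HELIX_RADIUS * np.cos(t * _HELIX_TWIST),
            _HELIX_RADIUS * np.sin(t * _HELIX_TWIST),
            _HELIX_RISE * t,
        ]
    )


def _valid_chain(coords: np.ndarray) -> bool:
    steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    if np.any(np.abs(steps - 3.8) > 0.1):
        return False
    if len(coords) > 2:
        d = cdist(coords, coords)
        mask = np.abs(np.subtract.outer(np.arange(len(coords)),
                                        np.arange(len(coords)))) >= 2
        if d[mask].min() < 3.5:
            return False
    return True


def gen_toy_structure(n_res: int, seed: int) -> np.ndarray:
    """Self-avoiding helical Cα trace: consecutive spacing 3.8 ± 0.1 Å,
    non-adjacent residues never closer than 3.5 Å."""
    if n_res < 2:
        raise ValueError(f"n_res must be >= 2, got {n_res}")
    rng = np.random.default_rng(seed)
    base = _helix(n_res) @ _random_rotation(rng).T
    for _ in range(50):
        coords = base + rng.normal(0.0, 0.02, size=base.shape)
        if _valid_chain(coords):
            return coords
    return base  # the unjittered helix always satisfies both constraints


def gen_toy_complex(
    members: Sequence[tuple[str, int]],
    seed: int,
    interface_distance: float = 8.0,
    model_id: str = "toy",
    iptm: float = 0.9,
    ptm: float = 0.8,
) -> StructureModel:
    """Multi-chain toy complex.

    ``members`` lists (accession, n_res) per chain; repeated accessions give
    homo-oligomers.  Each chain after the first is translated so its middle
    residue sits ``interface_distance`` Å from the middle residue of the
    previous chain — guaranteeing satisfiable inter-chain crosslinks — while
    keeping all other inter-chain contacts above 3.5 Å.
    """
    if not members:
        raise ValueError("complex needs at least one member")
    rng = np.random.default_rng(seed)
    chain_ids = [chr(ord("A") + i) for i in range(len(members))]
    chains: list[Chain] = []
    placed: list[np.ndarray] = []
    for i, (acc, n_res) in enumerate(members):
        coords = gen_toy_structure(n_res, int(rng.integers(2**31)))
        if placed:
            ref = placed[-1]
            anchor = ref[len(ref) // 2]
            mid = len(coords) // 2
            for _ in range(2000):
                # fresh orientation and approach direction each attempt
                spun = (coords - coords[mid]) @ _random_rotation(rng).T
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cand = spun + anchor + interface_distance * u
                dmin = min(cdist(cand, prev).min() for prev in placed)
                # designated pair sits at interface_distance; nothing clashes
                if dmin >= 3.5:
                    coords = cand
                    break
            else:
                raise RuntimeError("could not place chain without clashes")
        placed.append(coords)
        chains.append(
            Chain(
                chain_id=chain_ids[i],
                accession=acc,
                coords=coords,
                residue_numbers=np.arange(1, n_res + 1),
                plddt=np.full(n_res, 90.0),
            )
        )
    return StructureModel(model_id=model_id, chains=chains, iptm=iptm, ptm=ptm)


def _all_residue_pairs(model: StructureModel):
    """Flat (chain_idx, row) list and full distance matrix over resolved Cα."""
    index = [
        (ci, ri)
        for ci, chain in enumerate(model.chains)
        for ri in range(chain.n_resolved)
    ]
    coords = np.vstack([c.coords for c in model.chains])
    return index, coords, cdist(coords, coords)


def gen_crosslinks(
    model: StructureModel,
    n_true: int,
    n_random: int,
    seed: int,
    max_dist: float = 28.0,
    dataset_tag: str = "synthetic",
) -> list[CrosslinkRecord]:
    """Sample crosslink records on a model with ground-truth distances.

    ``n_true`` records come only from residue pairs with Cα-Cα <= ``max_dist``
    (the crosslinker-compatible set); ``n_random`` are uniform over all
    residue pairs regardless of distance.  Each record carries the true
    distance and a planted flag.
    """
    if len(model.chains) < 2:
        raise ValueError("model must have at least 2 chains")
    index, _, dmat = _all_residue_pairs(model)
    n = len(index)
    iu = np.triu_indices(n, k=1)
    dists = dmat[iu]
    rng = np.random.default_rng(seed)

    records: list[CrosslinkRecord] = []

    def _make(flat_idx: int, planted: bool) -> CrosslinkRecord:
        i, j = iu[0][flat_idx], iu[1][flat_idx]
        (ci, ri), (cj, rj) = index[i], index[j]
        ca, cb = model.chains[ci], model.chains[cj]
        return CrosslinkRecord(
            protein_a=ca.accession,
            res_a=int(ca.residue_numbers[ri]),
            protein_b=cb.accession,
            res_b=int(cb.residue_numbers[rj]),
            dataset_tag=dataset_tag,
            true_distance=float(dmat[i, j]),
            planted=planted,
        ).canonical()

    if n_true > 0:
        ok = np.flatnonzero(dists <= max_dist)
        if ok.size == 0:
            raise ValueError(
                f"no satisfiable pairs: no residue pair within {max_dist} Å"
            )
        picks = rng.choice(ok, size=n_true, replace=n_true > ok.size)
        records.extend(_make(int(k), True) for k in picks)
    if n_random > 0:
        picks = rng.choice(len(dists), size=n_random, replace=n_random > len(dists))
        records.extend(_make(int(k), False) for k in picks)
    return records


def _sample_target(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    weights = np.array([c[0] for c in cfg.target_score_mixture], dtype=float)
    weights /= weights.sum()
    comps = rng.choice(len(weights), size=n, p=weights)
    out = np.empty(n)
    for k, (_, mu, sd) in enumerate(cfg.target_score_mixture):
        mask = comps == k
        out[mask] = rng.normal(mu, sd, size=mask.sum())
    return np.clip(out, 0.0, 1.0)


def _sample_decoy(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    a, b, trunc = cfg.decoy_score_mixture
    return trunc * rng.beta(a, b, size=n)


def gen_score_table(
    n_target: int,
    n_decoy: int,
    cfg: SimConfig,
    seed: int,
    n_models: int = 5,
) -> tuple[list[ScoreRecord], list[ScoreRecord]]:
    """Target and decoy confidence-score tables.

    Targets draw their best ipTM from the bimodal mixture (a confident mode
    above the high cut and a diffuse low mode); decoys from a one-tailed
    distribution whose default truncation places zero mass above 0.85.  The
    remaining model slots score at or below the best.
    """
    if n_target < 0 or n_decoy < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)

    def _records(best: np.ndarray, prefix: str, origin: str) -> list[ScoreRecord]:
        out = []
        for i, b in enumerate(best):
            others = b * rng.uniform(0.5, 1.0, size=n_models - 1)
            iptms = np.concatenate([[b], others])
            ptms = np.clip(0.4 + 0.5 * iptms + rng.normal(0, 0.03, n_models), 0, 1)
            out.append(
                ScoreRecord(
                    members=(f"{prefix}{i:04d}a", f"{prefix}{i:04d}b"),
                    model_scores=[(float(x), float(p)) for x, p in zip(iptms, ptms)],
                    origin={origin},
                )
            )
        return out

    targets = _records(_sample_target(rng, n_target, cfg), "T", "XLMS")
    decoys = _records(_sample_decoy(rng, n_decoy, cfg), "D", "decoy")
    return targets, decoys


def _gauss(frac: np.ndarray, peak: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((frac - peak) / sigma) ** 2)


def gen_elution_dataset(cfg: SimConfig, seed: int) -> ElutionMatrix:
    """SEC elution matrix with planted complexes and a stabilization effect.

    Complex members share a Gaussian peak at an early ('large assembly')
    fraction in the crosslinked condition.  Labile members revert to their
    monomer fraction (>= 5 fractions later) when untreated; with
    ``stabilization_gain`` 0 the crosslinked condition reverts identically,
    so both conditions are drawn from the same distribution.  Replicate noise
    is multiplicative log-normal.  Ground truth (complex membership, labile
    flags, peak fractions, abundance pass/fail) is attached as
    ``ElutionMatrix.ground_truth``.
    """
    if not cfg.complex_spec:
        raise ValueError("complex_spec must be non-empty")
    rng = np.random.default_rng(seed)

    proteins: list[str] = []
    for comp in cfg.complex_spec:
        for acc in comp:
            if acc not in proteins:
                proteins.append(acc)
    n_extra = max(0, cfg.n_proteins - len(proteins))
    proteins += [f"MONO{i:03d}" for i in range(n_extra)]

    P, F, R = len(proteins), cfg.n_fractions, cfg.n_replicates
    fracs = np.arange(1, F + 1, dtype=float)

    # complexes elute early, monomers late; >= 5 fraction separation planted
    lo_complex, hi_complex = 5.0, max(6.0, 0.35 * F)
    lo_mono = hi_complex + 5.0
    hi_mono = max(lo_mono + 1.0, 0.9 * F)

    complex_peaks = rng.uniform(lo_complex, hi_complex, size=len(cfg.complex_spec))
    monomer_peak = {p: float(rng.uniform(lo_mono, hi_mono)) for p in proteins}
    amplitude = {p: float(rng.lognormal(mean=np.log(1e8), sigma=0.8)) for p in proteins}

    membership: dict[str, tuple[int, float]] = {}
    labile: dict[str, bool] = {}
    for ci, comp in enumerate(cfg.complex_spec):
        for acc in comp:
            membership[acc] = (ci, float(complex_peaks[ci]))
            labile[acc] = bool(rng.random() < cfg.labile_frac)

    w = min(1.0, cfg.stabilization_gain)
    intensities = np.zeros((P, F, R, 2))
    for pi, prot in enumerate(proteins):
        if prot in membership:
            _, cpeak = membership[prot]
            mpeak = monomer_peak[prot]
            if labile[prot]:
                untreated = _gauss(fracs, mpeak, cfg.peak_sigma)
                crosslinked = (1 - w) * untreated + w * _gauss(fracs, cpeak, cfg.peak_sigma)
            else:
                untreated = crosslinked = _gauss(fracs, cpeak, cfg.peak_sigma)
        else:
            untreated = crosslinked = _gauss(fracs, monomer_peak[prot], cfg.peak_sigma)
        for cond_idx, shape in enumerate((crosslinked, untreated)):
            for r in range(R):
                noise = rng.lognormal(mean=0.0, sigma=cfg.noise_sigma, size=F)
                intensities[pi, :, r, cond_idx] = amplitude[prot] * shape * noise

    # planted abundance-filter ledger
    fails = rng.random(P) < cfg.abundance_fail_frac
    peptide_counts = np.where(fails[:, None, None], 2, 3 + rng.integers(0, 20, (P, R, 2)))
    ibaq = np.where(fails[:, None, None], 1e6, 1e7 * rng.lognormal(1.0, 0.5, (P, R, 2)))

    ground_truth = {
        "complexes": [tuple(c) for c in cfg.complex_spec],
        "complex_peaks": complex_peaks.tolist(),
        "monomer_peak": monomer_peak,
        "labile": labile,
        "abundance_pass": [p for p, f in zip(proteins, fails) if not f],
    }
    return ElutionMatrix(
        proteins=proteins,
        intensities=intensities,
        peptide_counts=peptide_counts.astype(int),
        ibaq=ibaq,
        ground_truth=ground_truth,
    )
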