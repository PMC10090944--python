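"""Reading and writing predicted multi-chain models (coordinates + confidence).

Models are consumed as Cα-only coordinate sets.  Coordinates come from PDB or
mmCIF files (via :mod:`gemmi`); confidence scores (ipTM, pTM, per-residue
pLDDT, optional PAE matrix) come from a sidecar JSON record, keeping the
package independent of any particular prediction engine's internal format.

The sidecar schema requires the keys ``model_id``, ``chains`` (a list of
``{"chain_id": ..., "accession": ...}`` mappings in chain order), ``iptm`` and
``ptm``; ``pae_path`` (a JSON file holding a square nested list) is optional.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

__all__ = [
    "Chain",
    "StructureModel",
    "ScoreRecord",
    "MappingError",
    "read_model",
    "write_model",
    "best_model",
]


class MappingError(KeyError):
    """Raised when a chain-to-accession mapping is missing or inconsistent."""


@dataclass
class Chain:
    """One chain of a model: Cα coordinates for the resolved residues.

    ``residue_numbers`` is the index map from coordinate rows to 1-based
    positions in the full protein sequence; residues lacking a Cα atom are
    simply absent from it.  ``length`` is the full sequence length (highest
    residue number seen if not stated explicitly).
    """

    chain_id: str
    accession: str
    coords: np.ndarray  # (n_resolved, 3) in Å
    residue_numbers: np.ndarray  # (n_resolved,), 1-based, strictly increasing
    length: int = 0
    plddt: np.ndarray | None = None  # (n_resolved,) in [0, 100]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        if self.coords.shape[0] != self.residue_numbers.shape[0]:
            raise ValueError("coords and residue_numbers length mismatch")
        if self.length == 0:
            self.length = int(self.residue_numbers.max(initial=0))

    @property
    def n_resolved(self) -> int:
        return int(self.coords.shape[0])

    def ca(self, residue_number: int) -> np.ndarray | None:
        """Cα position of a 1-based residue number, or None if unresolved."""
        idx = np.searchsorted(self.residue_numbers, residue_number)
        if idx < len(self.residue_numbers) and self.residue_numbers[idx] == residue_number:
            return self.coords[idx]
        return None

    def unresolved(self) -> list[int]:
        """Residue numbers in 1..length without a Cα coordinate."""
        present = set(self.residue_numbers.tolist())
        return [i for i in range(1, self.length + 1) if i not in present]


@dataclass
class StructureModel:
    """Multi-chain predicted model with confidence scores."""

    model_id: str
    chains: list[Chain]
    iptm: float = float("nan")
    ptm: float = float("nan")
    pae: np.ndarray | None = None  # (N, N) expected position errors in Å

    def __post_init__(self) -> None:
        for score, name in ((self.iptm, "iptm"), (self.ptm, "ptm")):
            if not np.isnan(score) and not 0.0 <= score <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {score}")
        if self.pae is not None:
            self.pae = np.asarray(self.pae, dtype=float)
            n = sum(c.length for c in self.chains)
            if self.pae.shape != (n, n):
                raise ValueError(
                    f"PAE matrix shape {self.pae.shape} does not match total "
                    f"residue count {n}"
                )

    @property
    def accessions(self) -> set[str]:
        return {c.accession for c in self.chains}

    def chains_for(self, accession: str) -> list[Chain]:
        return [c for c in self.chains if c.accession == accession]


@dataclass
class ScoreRecord:
    """Per-PPI prediction confidence: one (ipTM, pTM) per predicted model."""

    members: tuple[str, ...]  # accession pair or triple, canonical order
    model_scores: list[tuple[float, float]] = field(default_factory=list)
    origin: set[str] = field(default_factory=set)  # subset of {XLMS, CoFrac, database}
    annotation: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.members = tuple(self.members)

    @property
    def best_iptm(self) -> float:
        if not self.model_scores:
            raise ValueError("score record has no model scores")
        return max(s[0] for s in self.model_scores)

    @property
    def pair_key(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


def best_model(record: ScoreRecord) -> int:
    """Index of the top-ranking model by ipTM; ties break to the lower index."""
    if not record.model_scores:
        raise ValueError("score record has no model scores")
    return int(max(range(len(record.model_scores)),
                   key=lambda i: (record.model_scores[i][0], -i)))


def _chain_map(sidecar: dict) -> dict[str, str]:
    try:
        return {c["chain_id"]: c["accession"] for c in sidecar["chains"]}
    except KeyError as exc:
        raise MappingError(f"sidecar chain record missing key: {exc}") from exc


def read_model(coords_path: str | Path, scores_path: str | Path) -> StructureModel:
    """Read a model from PDB/mmCIF coordinates and a sidecar score record.

    Only Cα atoms are extracted.  Residues lacking a Cα are excluded from the
    coordinate arrays; the per-chain ``residue_numbers`` map records the gap.
    pLDDT is taken from the B-factor column when present (the convention of
    deposited predicted models).
    """
    coords_path = Path(coords_path)
    sidecar = json.loads(Path(scores_path).read_text())
    chain_map = _chain_map(sidecar)

    try:
        st = gemmi.read_structure(str(coords_path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse coordinates from {coords_path}: {exc}") from exc
    st.setup_entities()
    model = st[0]

    chains: list[Chain] = []
    for ch in model:
        if ch.name not in chain_map:
            raise MappingError(
                f"chain {ch.name!r} in {coords_path.name} has no accession in the sidecar"
            )
        xyz, nums, plddt = [], [], []
        for res in ch:
            ca = res.find_atom("CA", "*")
            if ca is None:
                continue
            xyz.append([ca.pos.x, ca.pos.y, ca.pos.z])
            nums.append(res.seqid.num)
            plddt.append(ca.b_iso)
        chains.append(
            Chain(
                chain_id=ch.name,
                accession=chain_map[ch.name],
                coords=np.array(xyz, dtype=float).reshape(-1, 3),
                residue_numbers=np.array(nums, dtype=int),
                plddt=np.array(plddt, dtype=float) if plddt else None,
            )
        )

    pae = None
    if sidecar.get("pae_path"):
        pae_file = Path(sidecar["pae_path"])
        if not pae_file.is_absolute():
            pae_file = Path(scores_path).parent / pae_file
        pae = np.asarray(json.loads(pae_file.read_text()), dtype=float)

    def _score(key: str) -> float:
        val = sidecar.get(key)
        return float("nan") if val is None else float(val)

    return StructureModel(
        model_id=str(sidecar["model_id"]),
        chains=chains,
        iptm=_score("iptm"),
        ptm=_score("ptm"),
        pae=pae,
    )


def write_model(model: StructureModel, coords_path: str | Path,
                scores_path: str | Path | None = None,
                remarks: Sequence[str] = ()) -> None:
    """Write a Cα-only model as PDB (plus optional sidecar score JSON)."""
    st = gemmi.Structure()
    st.name = model.model_id
    md = gemmi.Model("1")
    for chain in model.chains:
        ch = gemmi.Chain(chain.chain_id)
        for row, resnum in enumerate(chain.residue_numbers):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(resnum), " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            x, y, z = chain.coords[row]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            if chain.plddt is not None:
                atom.b_iso = float(chain.plddt[row])
            res.add_atom(atom)
            ch.add_residue(res)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    doc_lines = [f"REMARK 300 {r}" for r in remarks]
    pdb_text = st.make_pdb_string()
    Path(coords_path).write_text("\n".join(doc_lines) + ("\n" if doc_lines else "") + pdb_text)

    if scores_path is not None:
        sidecar = {
            "model_id": model.model_id,
            "chains": [{"chain_id": c.chain_id, "accession": c.accession}
                       for c in model.chains],
            "iptm": None if np.isnan(model.iptm) else float(model.iptm),
            "ptm": None if np.isnan(model.ptm) else float(model.ptm),
        }
        Path(scores_path).write_text(json.dumps(sidecar, indent=1))
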