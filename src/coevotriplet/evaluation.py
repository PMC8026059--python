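"""CASP-style contact evaluation: separation ranges and top-L/k precision.

A predicted contact map is scored against the native one by ranking
unordered residue pairs (i < j) within a sequence-separation range —
medium range is 12 <= |i-j| <= 23, long range is |i-j| >= 24 — by
descending predicted probability and measuring the fraction of native
contacts among the top L/k pairs, for k in {10, 5, 2, 1}. Native contacts
are pairs whose C-beta atoms (C-alpha for glycine) lie strictly below
8.0 A; residues without resolved coordinates are excluded from both
numerator and denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RANGES",
    "EvalReport",
    "rank_contacts",
    "precision_at",
    "evaluate_target",
    "read_structure_cb",
]

#: sequence-separation ranges: name -> (min |i-j|, max |i-j| inclusive)
RANGES: dict[str, tuple[int, int]] = {
    "medium": (12, 23),
    "long": (24, 10 ** 9),
}

DEPTHS = (10, 5, 2, 1)


@dataclass
class EvalReport:
    """Precision grid over {medium, long} x {L/10, L/5, L/2, L}."""

    target: str
    length: int
    precision: dict[tuple[str, int], float] = field(default_factory=dict)
    evaluated: dict[tuple[str, int], int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "target": self.target,
            "L": self.length,
            "precision": {f"{rng}/top-L/{k}": v for (rng, k), v in self.precision.items()},
            "evaluated": {f"{rng}/top-L/{k}": v for (rng, k), v in self.evaluated.items()},
        }

    def to_tsv(self) -> str:
        lines = ["range\tdepth\tprecision\tevaluated"]
        for (rng, k), v in sorted(self.precision.items()):
            lines.append(f"{rng}\tL/{k}\t{v:.4f}\t{self.evaluated[(rng, k)]}")
        return "\n".join(lines) + "\n"


def _eligible_pairs(ell: int, range_name: str) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = RANGES[range_name]
    iu, ju = np.triu_indices(ell, k=lo)
    sep = ju - iu
    keep = sep <= hi
    return iu[keep], ju[keep]


def rank_contacts(p: np.ndarray, range_name: str, depth: int) -> list[tuple[int, int]]:
    """Top-``depth`` unordered pairs in a separation range.

    Pairs are sorted by descending probability with ties broken by
    ascending (i, j); each unordered pair is counted once. A non-symmetric
    input is symmetrized by averaging, so P and P^T rank identically.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if range_name not in RANGES:
        raise ValueError(f"unknown range {range_name!r}")
    p = 0.5 * (p + p.T)
    ell = p.shape[0]
    iu, ju = _eligible_pairs(ell, range_name)
    vals = p[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    return [(int(iu[o]), int(ju[o])) for o in order[:depth]]


def precision_at(p: np.ndarray, native: np.ndarray, range_name: str,
                 k_denominator: int) -> float:
    """Top-L/k precision of predicted contacts in a separation range.

    Depth is floor(L / k) with a minimum of 1; when fewer eligible pairs
    exist, the denominator is the number actually evaluated.
    """
    if p.shape != native.shape:
        raise ValueError("prediction and native maps must have the same shape")
    ell = p.shape[0]
    depth = max(1, ell // k_denominator)
    pairs = rank_contacts(p, range_name, depth)
    if not pairs:
        return 0.0
    hits = sum(bool(native[i, j]) for i, j in pairs)
    return hits / len(pairs)


def evaluate_target(pred, native_labels, target: str = "target") -> EvalReport:
    """Full medium/long x four-depth precision grid.

    ``pred`` may be a :class:`~coevotriplet.network.DistogramPrediction`
    or a bare (L, L) contact-probability matrix; ``native_labels`` a
    :class:`~coevotriplet.network.LabelMap` or a boolean contact map.
    """
    from coevotriplet.network import DistogramPrediction, contact_probability

    if isinstance(pred, DistogramPrediction):
        p = contact_probability(pred)
    else:
        p = np.asarray(pred, dtype=np.float64)
    native = getattr(native_labels, "contacts", native_labels)
    native = np.asarray(native, dtype=bool)
    if not native.any():
        if hasattr(native_labels, "mask") and not native_labels.mask.any():
            raise ValueError("empty native mask")
    report = EvalReport(target=target, length=p.shape[0])
    for range_name in RANGES:
        for k in DEPTHS:
            ell = p.shape[0]
            depth = max(1, ell // k)
            pairs = rank_contacts(p, range_name, depth)
            hits = sum(bool(native[i, j]) for i, j in pairs)
            report.precision[(range_name, k)] = hits / len(pairs) if pairs else 0.0
            report.evaluated[(range_name, k)] = len(pairs)
    return report


def read_structure_cb(path: str | Path):
    """Per-residue interaction-site coordinates from a PDB-format file.

    Returns ``(coords, residue_names)`` with one row per standard residue
    of the first chain of the first model: the C-beta position, or C-alpha
    for glycine (no warning), or C-alpha as a flagged fallback when a
    non-glycine residue lacks a C-beta. Residues with neither atom get NaN
    coordinates (masked downstream). Alternate locations resolve to the
    first listed.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import is_aa

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    chain = next(model.get_chains())
    coords: list[np.ndarray] = []
    names: list[str] = []
    for residue in chain.get_residues():
        if not is_aa(residue, standard=False) and residue.id[0] != " ":
            continue
        resname = residue.get_resname()
        atom = None
        if resname == "GLY":
            if "CA" in residue:
                atom = residue["CA"]
        elif "CB" in residue:
            atom = residue["CB"]
        elif "CA" in residue:
            atom = residue["CA"]
            warnings.warn(f"residue {resname} {residue.id[1]}: C-beta missing, "
                          "using C-alpha", RuntimeWarning)
        if atom is None:
            coords.append(np.full(3, np.nan))
        else:
            coords.append(np.asarray(atom.get_coord(), dtype=np.float64))
        names.append(resname)
    if not any(np.all(np.isfinite(c)) for c in coords):
        raise ValueError(f"no parsable residues with coordinates in {path}")
    return np.stack(coords), names
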