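"""Serialization: feature containers, checkpoints, RR contact lists, PDB/TSV.

Feature tensors and model checkpoints go into HDF5 containers with shape
and configuration metadata embedded, so a file is self-describing. Contact
predictions are written in the CASP RR text convention
(``i j 0 8 probability``, 1-based residue numbers, best first).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from coevotriplet.network import NetConfig, TripletDistogramNet

__all__ = [
    "save_features",
    "load_features",
    "save_checkpoint",
    "load_checkpoint",
    "write_rr",
    "read_rr",
    "write_distance_tsv",
    "read_distance_tsv",
    "write_toy_pdb",
]


def save_features(path: str | Path, tensors: dict[str, np.ndarray],
                  meta: dict | None = None) -> None:
    """Store named (L, L, C) feature tensors in one HDF5 file."""
    with h5py.File(path, "w") as fh:
        for name, arr in tensors.items():
            ds = fh.create_dataset(name, data=np.asarray(arr, dtype=np.float32),
                                   compression="gzip", compression_opts=4)
            ds.attrs["shape"] = arr.shape
        fh.attrs["meta"] = json.dumps(meta or {})


def load_features(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    with h5py.File(path, "r") as fh:
        tensors = {name: fh[name][...] for name in fh.keys()}
        meta = json.loads(fh.attrs.get("meta", "{}"))
    return tensors, meta


def save_checkpoint(path: str | Path, model: TripletDistogramNet) -> None:
    """Model weights plus the embedded NetConfig."""
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("params")
        for name, arr in model.state_arrays().items():
            grp.create_dataset(name, data=arr)
        fh.attrs["config"] = json.dumps(dataclasses.asdict(model.cfg))


def load_checkpoint(path: str | Path) -> TripletDistogramNet:
    with h5py.File(path, "r") as fh:
        cfg_dict = json.loads(fh.attrs["config"])
        cfg_dict["features"] = tuple(cfg_dict["features"])
        cfg = NetConfig(**cfg_dict)
        model = TripletDistogramNet(cfg)
        arrays = {name: fh["params"][name][...] for name in fh["params"].keys()}
    model.load_state_arrays(arrays)
    return model


def write_rr(path: str | Path, contact_probs: np.ndarray, min_separation: int = 1,
             max_pairs: int | None = None, sequence: str | None = None) -> None:
    """CASP RR contact list: ``i j 0 8 prob`` (1-based, descending)."""
    ell = contact_probs.shape[0]
    iu, ju = np.triu_indices(ell, k=max(1, min_separation))
    vals = contact_probs[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    if max_pairs is not None:
        order = order[:max_pairs]
    with open(path, "w") as fh:
        if sequence:
            fh.write(sequence + "\n")
        for o in order:
            fh.write(f"{iu[o] + 1} {ju[o] + 1} 0 8 {vals[o]:.6f}\n")


def read_rr(path: str | Path, length: int) -> np.ndarray:
    """Read an RR file back into a symmetric (L, L) probability matrix."""
    p = np.zeros((length, length))
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 5:
                continue  # sequence or header line
            try:
                i, j = int(parts[0]) - 1, int(parts[1]) - 1
            except ValueError:
                continue
            prob = float(parts[4])
            p[i, j] = p[j, i] = prob
    return p


def write_distance_tsv(path: str | Path, d: np.ndarray) -> None:
    np.savetxt(path, d, delimiter="\t", fmt="%.4f")


def read_distance_tsv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")


def write_toy_pdb(path: str | Path, coords: np.ndarray, atom_name: str = "CB",
                  res_name: str = "ALA") -> None:
    """Write toy-chain sites as single-chain PDB ATOM records."""
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(np.asarray(coords, dtype=float), start=1):
            fh.write(
                f"ATOM  {i:5d}  {atom_name:<3s}{res_name:>4s} A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           "
                f"{atom_name[0]}\n")
        fh.write("END\n")
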