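"""Synthetic data: toy 3D chains, planted Potts models, Gibbs-sampled MSAs.

The generator provides ground truth the real pipeline never has: a known
structure, a known contact map, and a known coupling topology. A toy chain
(one interaction site per residue, consecutive sites 3.8 units apart,
excluded volume, radial confinement) yields a contact map at the 8-unit
cutoff; a Potts model is planted on those contacts (each contacting pair
gets a favored-state coupling block, everything else zero); sequences are
then drawn by single-site Gibbs sampling from exactly the conditional
distribution that pseudolikelihood maximization later fits. Every stage of
feature extraction, network training and evaluation can therefore be scored
against the planted truth.

All randomness flows from per-call integer seeds, so any artifact is
reproducible from its seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from coevotriplet.alphabet import GAP_CODE, N_STATES
from coevotriplet.coevolution import PottsModel
from coevotriplet.msa import Alignment

__all__ = [
    "ToyStructure",
    "SimConfig",
    "generate_structure",
    "plant_potts",
    "gibbs_sample_msa",
    "make_training_example",
    "contact_map_from_coords",
]

#: distance cutoff (in chain units, read as Angstroms) defining a contact
CONTACT_CUTOFF: float = 8.0


@dataclass
class ToyStructure:
    """A self-avoiding 3D chain standing in for a native backbone."""

    coords: np.ndarray          # (L, 3)
    chain_step: float = 3.8
    seed: int = 0

    @property
    def length(self) -> int:
        return self.coords.shape[0]

    def distance_matrix(self) -> np.ndarray:
        return squareform(pdist(self.coords))

    def contact_map(self, cutoff: float = CONTACT_CUTOFF) -> np.ndarray:
        """Boolean contact map at ``cutoff`` (strictly below), False diagonal."""
        d = self.distance_matrix()
        contacts = d < cutoff
        np.fill_diagonal(contacts, False)
        return contacts


@dataclass
class SimConfig:
    """Study conditions for one simulated protein family.

    Defaults are the desk-scale reference conditions used throughout the
    tests: a 30-residue chain, 2000 sequences, planted coupling strength
    1.5, weak random fields, and 200 Gibbs sweeps of burn-in per chain.
    """

    L: int = 30
    N: int = 2000
    coupling_strength: float = 1.5
    field_scale: float = 0.3
    gibbs_sweeps: int = 200
    burn_in: int = 200
    thinning: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 2 or self.N < 1:
            raise ValueError("need L >= 2 and N >= 1")
        if self.gibbs_sweeps < self.burn_in:
            raise ValueError("gibbs_sweeps must be >= burn_in")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


def generate_structure(L: int, seed: int = 0, compactness: float = 0.3,
                       chain_step: float = 3.8, min_distance: float = 3.6,
                       persistence: float = 1.5, max_retries: int = 300) -> ToyStructure:
    """Grow a self-avoiding chain with radial confinement.

    Each step moves ``chain_step`` in a random direction with persistence
    toward the previous step direction (chain stiffness) and a bias toward
    the origin with strength ``compactness``, which together control the
    density of the 8-unit contact map (calibrated so an L = 50 chain has a
    contacting-pair fraction of roughly 0.1, within the (0.02, 0.25)
    band typical of globular backbones). Chains violating excluded volume
    are regrown; for L >= 30 the chain is additionally required to form at
    least one long-range contact (|i-j| >= 24 below 8 units), so every
    generated structure exercises the evaluation ranges.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    rng = np.random.default_rng(seed)
    r0 = chain_step * max(1.5, L ** (1.0 / 3.0))
    for _attempt in range(max_retries):
        coords = np.zeros((L, 3))
        ok = True
        prev_dir = None
        for i in range(1, L):
            placed = False
            for _trial in range(80):
                pos = coords[i - 1]
                d = rng.standard_normal(3) - compactness * pos / r0
                if prev_dir is not None:
                    d = d + persistence * prev_dir
                norm = np.linalg.norm(d)
                if norm < 1e-12:
                    continue
                step_dir = d / norm
                cand = pos + chain_step * step_dir
                if i >= 2:
                    dists = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                    if dists.min() < min_distance:
                        continue
                coords[i] = cand
                prev_dir = step_dir
                placed = True
                break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        structure = ToyStructure(coords=coords, chain_step=chain_step, seed=seed)
        if L >= 30:
            contacts = structure.contact_map()
            i, j = np.nonzero(np.triu(contacts, k=24))
            if i.size == 0:
                continue
        return structure
    raise RuntimeError(f"structure generation exhausted {max_retries} retries (seed={seed})")


def contact_map_from_coords(coords: np.ndarray, cutoff: float = CONTACT_CUTOFF) -> np.ndarray:
    d = squareform(pdist(coords))
    contacts = d < cutoff
    np.fill_diagonal(contacts, False)
    return contacts


def plant_potts(structure: ToyStructure, cfg: SimConfig) -> PottsModel:
    """Plant a Potts model on the structure's contact map.

    Every contacting pair (i, j) receives a coupling block that rewards a
    random one-to-one pairing of states: B[a, pi(a)] = coupling_strength
    for a seeded permutation pi, so ||J_ij||_F = coupling_strength * sqrt(21)
    for every planted pair. Non-contact blocks are exactly zero. Fields are
    i.i.d. Gaussian scaled by field_scale, with the gap state disfavored by
    a constant offset so simulated alignments stay mostly gap-free.
    """
    rng = np.random.default_rng(cfg.seed)
    ell = structure.length
    if ell != cfg.L:
        raise ValueError("structure length does not match cfg.L")
    h = cfg.field_scale * rng.standard_normal((ell, N_STATES))
    h[:, GAP_CODE] -= 1.0
    j = np.zeros((ell, ell, N_STATES, N_STATES))
    contacts = structure.contact_map()
    for i, k in zip(*np.nonzero(np.triu(contacts, k=1))):
        perm = rng.permutation(N_STATES)
        block = np.zeros((N_STATES, N_STATES))
        block[np.arange(N_STATES), perm] = cfg.coupling_strength
        j[i, k] = block
        j[k, i] = block.T
    return PottsModel(h=h, J=j)


def _partner_lists(model: PottsModel) -> list[np.ndarray]:
    """Sites coupled to each site (nonzero blocks) — sparse Gibbs updates."""
    norms = np.sqrt(np.sum(model.J ** 2, axis=(2, 3)))
    return [np.nonzero(norms[l] > 0)[0] for l in range(model.length)]


def gibbs_sample_msa(model: PottsModel, cfg: SimConfig,
                     single_chain: bool = False) -> Alignment:
    """Draw an alignment from the Potts model by single-site Gibbs sampling.

    The update kernel is exactly the model's conditional
    P(sigma_l = a | rest) ∝ exp(h_l(a) + sum_{k != l} J_lk(a, sigma_k)).
    By default N independent chains (one per sequence) are initialized from
    the fields-only distribution and swept ``gibbs_sweeps`` times; the
    ``single_chain`` flag instead records a thinned trajectory of one chain
    after burn-in.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    ell = model.length
    if ell != cfg.L:
        raise ValueError("model length does not match cfg.L")
    model = model.symmetrized()
    partners = _partner_lists(model)

    def init_states(n: int) -> np.ndarray:
        logits = model.h[None].repeat(n, axis=0)
        g = rng.gumbel(size=logits.shape)
        return np.argmax(logits + g, axis=2).astype(np.int64)

    def sweep(states: np.ndarray) -> None:
        n = states.shape[0]
        for l in range(ell):
            logits = np.broadcast_to(model.h[l], (n, N_STATES)).copy()
            for k in partners[l]:
                logits += model.J[l, k][:, states[:, k]].T
            g = rng.gumbel(size=(n, N_STATES))
            states[:, l] = np.argmax(logits + g, axis=1)

    if single_chain:
        states = init_states(1)
        samples = np.empty((cfg.N, ell), dtype=np.int64)
        for _ in range(cfg.burn_in):
            sweep(states)
        for m in range(cfg.N):
            for _ in range(cfg.thinning):
                sweep(states)
            samples[m] = states[0]
    else:
        samples = init_states(cfg.N)
        for _ in range(cfg.gibbs_sweeps):
            sweep(samples)
    ids = [f"sim{m}" for m in range(cfg.N)]
    return Alignment(samples.astype(np.int8), ids=ids, query_index=0)


def make_training_example(structure: ToyStructure, aln: Alignment,
                          plm_maxiter: int = 60, shrinkage: float = 0.1):
    """Features + labels for one simulated protein.

    Returns ``(features, labels)`` where ``features`` maps
    {"cov", "pre", "plm"} to (L, L, 441) float32 tensors and ``labels`` is
    the 12-bin :class:`~coevotriplet.network.LabelMap` derived from the
    structure's distance matrix.
    """
    from coevotriplet.coevolution import (assemble_feature_tensor, compute_cov,
                                          compute_plm, compute_pre)
    from coevotriplet.msa import compute_frequencies, compute_weights_and_neff
    from coevotriplet.network import labels_from_structure

    if structure.length != aln.length:
        raise ValueError("structure and alignment lengths differ")
    ws = compute_weights_and_neff(aln)
    stats = compute_frequencies(aln, weights=ws.weights)
    cov = compute_cov(stats)
    pre = compute_pre(cov, shrinkage=shrinkage)
    plm = compute_plm(aln, weights=ws.weights, maxiter=plm_maxiter)
    features = {
        "cov": assemble_feature_tensor(cov),
        "pre": assemble_feature_tensor(pre),
        "plm": assemble_feature_tensor(plm),
    }
    labels = labels_from_structure(structure.coords)
    return features, labels
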