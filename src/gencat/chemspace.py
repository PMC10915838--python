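"""Reaction featurization, 2D chemical-space maps and diverse subset selection.

Reactions are represented as concatenated Morgan (circular) fingerprints of
their components — catalyst, co-catalyst, SubA, SubB and solvent — each in a
fixed 1024-bit block; an absent component contributes an all-zero block.
Maps are built by exact PCA to 100 dimensions followed by a t-SNE embedding
(perplexity 30), and diverse substrate panels are chosen on the 2D map with
a deterministic farthest point sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .reactions import ReactionRecord, SubstratePanel

#: Common solvent names -> representative SMILES for fingerprinting.
SOLVENT_SMILES = {
    "toluene": "Cc1ccccc1",
    "benzene": "c1ccccc1",
    "xylene": "Cc1ccccc1C",
    "dcm": "ClCCl",
    "dichloromethane": "ClCCl",
    "chloroform": "ClC(Cl)Cl",
    "dce": "ClCCCl",
    "thf": "C1CCOC1",
    "dioxane": "C1COCCO1",
    "et2o": "CCOCC",
    "diethyl ether": "CCOCC",
    "mtbe": "CC(C)(C)OC",
    "acetonitrile": "CC#N",
    "mecn": "CC#N",
    "methanol": "CO",
    "ethanol": "CCO",
    "water": "O",
    "dmso": "CS(C)=O",
    "dmf": "CN(C)C=O",
    "ethyl acetate": "CCOC(C)=O",
    "hexane": "CCCCCC",
    "cyclohexane": "C1CCCCC1",
}

DEFAULT_COMPONENTS = ("catalyst", "cocatalyst", "sub_a", "sub_b", "solvent")


class FeaturizationError(ValueError):
    pass


@dataclass(frozen=True)
class FingerprintConfig:
    """Concatenated-Morgan-fingerprint reaction representation.

    ``n_bits`` is the per-component block size and ``component_order`` is
    fixed for the lifetime of any model trained on these features.
    """

    n_bits: int = 1024
    radius: int = 2
    component_order: tuple[str, ...] = DEFAULT_COMPONENTS

    def __post_init__(self) -> None:
        if self.n_bits <= 0:
            raise ValueError("n_bits must be positive")

    @property
    def n_features(self) -> int:
        return self.n_bits * len(self.component_order)


_GENERATORS: dict[tuple[int, int], object] = {}


def _morgan(smiles: str, radius: int, n_bits: int, component: str) -> np.ndarray:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(
            f"component {component!r}: unparseable SMILES {smiles!r}"
        )
    key = (radius, n_bits)
    gen = _GENERATORS.get(key)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
        _GENERATORS[key] = gen
    return np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)


def solvent_to_smiles(solvent: str) -> str | None:
    """Map a solvent name to a representative SMILES.

    Unknown names are tried as SMILES themselves; if that fails the solvent
    block is zeroed (returns None).
    """
    if not solvent:
        return None
    smi = SOLVENT_SMILES.get(solvent.strip().lower())
    if smi is not None:
        return smi
    return solvent if Chem.MolFromSmiles(solvent) is not None else None


def featurize_reaction(
    record: ReactionRecord, config: FingerprintConfig = FingerprintConfig()
) -> np.ndarray:
    """Concatenated per-component fingerprint blocks (uint8, 0/1)."""
    blocks = []
    for component in config.component_order:
        if component == "solvent":
            smi = solvent_to_smiles(record.solvent)
        else:
            smi = getattr(record, component)
        if not smi:
            blocks.append(np.zeros(config.n_bits, dtype=np.uint8))
        else:
            blocks.append(_morgan(smi, config.radius, config.n_bits, component))
    return np.concatenate(blocks)


def featurize_many(records, config: FingerprintConfig = FingerprintConfig()) -> np.ndarray:
    return np.stack([featurize_reaction(r, config) for r in records])


@dataclass
class EmbeddingMap:
    """2D map coordinates of a reaction set with its embedding settings."""

    coords: np.ndarray
    pca_dims: int
    perplexity: float
    seed: int
    pca_coords: np.ndarray = field(repr=False, default=None)


def reduce_pca(vectors: np.ndarray, pca_dims: int = 100) -> np.ndarray:
    """Exact (deterministic, full-SVD) PCA stage of the map pipeline."""
    X = np.asarray(vectors, dtype=float)
    n_comp = min(pca_dims, X.shape[0], X.shape[1])
    return PCA(n_components=n_comp, svd_solver="full").fit_transform(X)


def embed_map(
    vectors: np.ndarray,
    pca_dims: int = 100,
    perplexity: float = 30.0,
    seed: int = 0,
) -> EmbeddingMap:
    """PCA to ``pca_dims`` then t-SNE to 2D; deterministic for a fixed seed.

    Perplexity is clamped below the sample count as t-SNE requires.
    """
    X = np.asarray(vectors, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to embed")
    Z = reduce_pca(X, pca_dims)
    eff_perplexity = min(perplexity, (X.shape[0] - 1) / 3.0)
    tsne = TSNE(
        n_components=2,
        perplexity=eff_perplexity,
        init="pca",
        random_state=seed,
    )
    coords = np.asarray(tsne.fit_transform(Z), dtype=float)
    return EmbeddingMap(coords, pca_dims, eff_perplexity, seed, pca_coords=Z)


def farthest_point_sample(coords: np.ndarray, k: int, seed: int | None = None) -> list[int]:
    """Greedy maximin subset of ``k`` point indices.

    The first point is the one farthest from the centroid; each subsequent
    point maximizes its minimum Euclidean distance to the selected set.
    Ties break to the lowest index, so the result is deterministic and the
    ``seed`` argument is accepted only for interface symmetry.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k = {k} outside [1, {n}]")
    centroid = X.mean(axis=0)
    d = np.linalg.norm(X - centroid, axis=1)
    first = int(np.argmax(d))  # np.argmax returns the lowest tying index
    selected = [first]
    min_dist = np.linalg.norm(X - X[first], axis=1)
    for _ in range(k - 1):
        min_dist[selected] = -np.inf
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, np.linalg.norm(X - X[nxt], axis=1))
    return selected


def select_panel(
    records,
    k: int = 50,
    config: FingerprintConfig | None = None,
    pca_dims: int = 100,
    perplexity: float = 30.0,
    seed: int = 0,
    name: str = "GPS",
) -> tuple[SubstratePanel, EmbeddingMap, list[int]]:
    """Pick a diversity-maximizing substrate panel from a reaction set.

    Builds the 2D map from SubA+SubB fingerprint blocks only, then runs
    farthest point sampling.  Returns (panel, map, selected indices).
    """
    if config is None:
        config = FingerprintConfig(component_order=("sub_a", "sub_b"))
    vectors = featurize_many(records, config)
    emb = embed_map(vectors, pca_dims=pca_dims, perplexity=perplexity, seed=seed)
    idx = farthest_point_sample(emb.coords, k)
    pairs = []
    for i in idx:
        pair = (records[i].sub_a, records[i].sub_b)
        if pair not in pairs:
            pairs.append(pair)
    panel = SubstratePanel(tuple(pairs), name=name, provenance=f"fps(k={k}, seed={seed})")
    return panel, emb, idx
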