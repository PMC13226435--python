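"""Era-sliced 2D chemical-space maps of generic frameworks.

Frameworks are encoded as circular (Morgan/ECFP4-style) fingerprints,
compressed by PCA, and projected to two dimensions with t-SNE. Nodes are
deduplicated frameworks weighted by their molecule frequency, so one point
per distinct shape with size proportional to how often that shape occurs.
Era slicing re-embeds the frameworks known up to each snapshot year,
visualizing how occupied chemical space spreads over time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit.Chem import rdFingerprintGenerator
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from . import chem


@dataclass
class FingerprintMatrix:
    keys: list[str]
    bits: np.ndarray  # (n_keys, n_bits) uint8
    n_bits: int
    radius: int


@dataclass
class EmbeddingResult:
    keys: list[str]
    coords: np.ndarray  # (n_keys, 2)
    weights: np.ndarray  # (n_keys,) molecule frequency per framework
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "framework": self.keys,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "weight": self.weights.astype(int),
            }
        )


def circular_fingerprint(mol: chem.Mol, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """Morgan circular fingerprint (radius 2 = diameter-4 neighbourhoods).

    Deterministic and invariant to input atom ordering, since hashing works
    on the molecular graph, not the SMILES spelling.
    """
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError("cannot fingerprint an empty molecule")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def fingerprint_matrix(keys: list[str], radius: int = 2, n_bits: int = 2048) -> FingerprintMatrix:
    """Fingerprints for a list of (framework) SMILES keys, order-preserving."""
    rows = []
    for key in keys:
        mol = chem.parse_smiles(key)
        if mol is None:
            raise ValueError(f"unparseable framework SMILES: {key!r}")
        rows.append(circular_fingerprint(mol, radius=radius, n_bits=n_bits))
    return FingerprintMatrix(list(keys), np.asarray(rows, dtype=np.uint8), n_bits, radius)


def reduce_dimensions(matrix: FingerprintMatrix | np.ndarray, n_components: int = 50) -> np.ndarray:
    """Mean-centred PCA projection of the fingerprint matrix."""
    X = matrix.bits if isinstance(matrix, FingerprintMatrix) else np.asarray(matrix)
    X = X.astype(float)
    if X.shape[0] < 2:
        raise ValueError("need at least two fingerprint vectors to reduce")
    limit = min(X.shape[0], X.shape[1])
    if n_components > limit:
        warnings.warn(
            f"n_components reduced from {n_components} to {limit} "
            "(fewer vectors than requested components)",
            stacklevel=2,
        )
        n_components = limit
    pca = PCA(n_components=n_components, svd_solver="full")
    return pca.fit_transform(X)


def embed_2d(coords: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """t-SNE projection to 2D; bit-reproducible for a fixed seed."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least three points for a 2D embedding")
    if perplexity >= n:
        raise ValueError(
            f"perplexity {perplexity} must be smaller than the number of points {n}; "
            "lower --perplexity or embed more frameworks"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
        max_iter=1000,
    )
    return tsne.fit_transform(coords)


def snapshot_series(
    data: pd.DataFrame,
    eras: list[int],
    seed: int = 0,
    cumulative: bool = True,
    radius: int = 2,
    n_bits: int = 2048,
    n_components: int = 50,
    perplexity: float = 30.0,
) -> dict[int, EmbeddingResult]:
    """Embed the framework population at each era cut-off year.

    ``data`` needs columns ``framework`` (generic framework SMILES, empty
    for acyclic molecules) and ``year``. Cumulative mode (default) takes
    all molecules dated up to each era's end; windowed mode takes only
    molecules between consecutive cut-offs. Frameworks are deduplicated
    and weighted by molecule frequency; eras with fewer than three
    distinct frameworks are skipped with a warning. The perplexity is
    clamped below the point count so small eras remain embeddable.
    """
    eras = sorted(eras)
    years = pd.to_numeric(data["year"], errors="coerce")
    results: dict[int, EmbeddingResult] = {}
    prev_cut = -np.inf
    for cut in eras:
        if cumulative:
            mask = years <= cut
        else:
            mask = (years > prev_cut) & (years <= cut)
        prev_cut = cut
        frames = data.loc[mask, "framework"]
        frames = frames[frames.astype(bool)]
        counts = frames.value_counts().sort_index()
        keys = list(counts.index)
        if len(keys) < 3:
            warnings.warn(f"era {cut}: fewer than 3 distinct frameworks, skipped", stacklevel=2)
            continue
        fpm = fingerprint_matrix(keys, radius=radius, n_bits=n_bits)
        reduced = reduce_dimensions(fpm, n_components=n_components)
        eff_perp = min(perplexity, max(2.0, (len(keys) - 1) / 3.0))
        coords = embed_2d(reduced, perplexity=eff_perp, seed=seed)
        results[cut] = EmbeddingResult(
            keys=keys,
            coords=coords,
            weights=counts.to_numpy(),
            params={
                "radius": radius,
                "n_bits": n_bits,
                "n_components": n_components,
                "perplexity": eff_perp,
                "seed": seed,
                "cumulative": cumulative,
            },
        )
    return results


def plot_snapshot(result: EmbeddingResult, path: str, title: str = "") -> None:
    """Static scatter of one era: node size and colour follow frequency."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    w = result.weights.astype(float)
    size = 10 + 90 * (w - w.min()) / max(float(np.ptp(w)), 1.0)
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(result.coords[:, 0], result.coords[:, 1], s=size, c=w,
                    cmap="viridis", alpha=0.8, edgecolors="none")
    fig.colorbar(sc, ax=ax, label="framework frequency")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
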