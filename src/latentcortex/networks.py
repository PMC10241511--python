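"""Functional-network mapping through the latent space.

Latent timecourses from all subjects of a group are concatenated and
decomposed with temporal ICA (extended Infomax after PCA reduction, 30
components by default), yielding temporally independent "latent bases".
Each basis is visualized on the cortex by a Monte-Carlo linearization of the
decoder: scale the basis by n random factors, decode each scaled vector, and
take the covariance between the scaling factor and the decoded activity at
every vertex.  The sign of each map is fixed so its strongest location is an
activation, and maps are thresholded at a fraction of their maximum absolute
value for display.

Because ICA components are defined only up to permutation and sign,
comparisons across groups one-to-one pair bases by absolute Pearson
correlation (greedily, strongest pair first).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import GridMapping, GridSequence, from_grid
from .vae import LatentTimeseries, VAEModel, decode

__all__ = [
    "NetworkBasis",
    "CorticalMap",
    "concat_latents",
    "temporal_ica",
    "basis_to_cortex",
    "fix_sign",
    "threshold_map",
    "match_bases",
    "reproducibility_curve",
]


@dataclass
class NetworkBasis:
    """Temporal-ICA decomposition of concatenated latent timecourses.

    ``unmixing`` (n_components, k) maps latent series to component series;
    ``mixing`` (k, n_components) holds the latent bases as columns, ordered
    by explained variance in latent space.  ``W @ M`` is the identity on the
    retained PCA subspace.
    """

    unmixing: np.ndarray
    mixing: np.ndarray
    sources: np.ndarray  # (n_components, sum T), unit variance
    boundaries: np.ndarray  # subject start/end indices into sources
    mean: np.ndarray  # (k,) latent mean removed before ICA
    seed: int
    group_tag: str = "group"

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]


@dataclass
class CorticalMap:
    """Per-vertex map of one latent basis."""

    values: np.ndarray
    sign_fixed: bool = False
    threshold_fraction: float | None = None


def concat_latents(latents) -> tuple:
    """Column-wise concatenation of latent timecourses across subjects.

    Returns ``(Zcat, boundaries)`` with ``boundaries[i]:boundaries[i+1]``
    delimiting subject i's frames.
    """
    mats = []
    for lt in latents:
        mats.append(lt.mu if isinstance(lt, LatentTimeseries) else
                    np.asarray(lt, dtype=np.float64))
    if not mats:
        raise ValueError("empty latent list")
    dim = mats[0].shape[0]
    if any(m.shape[0] != dim for m in mats):
        raise ValueError("latent dimensions differ across subjects")
    boundaries = np.cumsum([0] + [m.shape[1] for m in mats])
    return np.concatenate(mats, axis=1), boundaries


def temporal_ica(Zcat: np.ndarray, n_components: int = 30, seed: int = 0,
                 group_tag: str = "group") -> NetworkBasis:
    """Temporal ICA of latent timecourses: PCA to ``n_components`` followed
    by extended Infomax on the reduced series.

    Components are unit-variance in time, ordered by the latent-space
    variance they explain; output is defined up to permutation and sign but
    deterministic for a fixed seed.
    """
    from mne.preprocessing import infomax

    Zcat = np.asarray(Zcat, dtype=np.float64)
    k, T = Zcat.shape
    if T <= n_components:
        raise ValueError(f"need more than {n_components} frames, got {T}")
    mean = Zcat.mean(axis=1)
    Zc = Zcat - mean[:, None]
    # PCA over latent dimensions (samples = time points)
    U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    if (s[:n_components] <= 1e-12 * s[0]).any():
        raise ValueError(f"latent data rank below n_components={n_components}")
    comp = U[:, :n_components]  # (k, n_components)
    sv = s[:n_components]
    # whitened PCA scores, (T, n_components), unit variance
    scores = Vt[:n_components].T * np.sqrt(T - 1)
    wht = comp / sv * np.sqrt(T - 1)  # Zc -> scores:  scores = Zc.T @ wht

    unmix_ica = infomax(scores, extended=True,
                        rng=np.random.default_rng(seed), verbose="error")
    W = unmix_ica @ wht.T  # (n_components, k): latent series -> sources
    sources = W @ Zc  # (n_components, T), approx unit variance

    # rescale sources to exactly unit variance, fold scale into the mixing
    sd = sources.std(axis=1, ddof=1)
    W = W / sd[:, None]
    sources = sources / sd[:, None]
    M = np.linalg.pinv(W)  # (k, n_components): latent bases

    # order by explained variance in latent space (basis norm, since the
    # sources are unit-variance)
    order = np.argsort(-np.linalg.norm(M, axis=0))
    W, M, sources = W[order], M[:, order], sources[order]

    return NetworkBasis(unmixing=W, mixing=M, sources=sources,
                        boundaries=np.array([0, T]), mean=mean, seed=seed,
                        group_tag=group_tag)


def _decode_to_vertices(decoder, Z: np.ndarray, mapping: GridMapping | None):
    """Run latent column vectors through a decoder, returning (V, n) values.

    ``decoder`` is a trained VAE model (decoded grids are inverted through
    ``mapping``) or any callable taking a (k, n) latent matrix and returning
    either (n, H, W, 2) grid frames or a (V, n) vertex matrix directly.
    """
    if isinstance(decoder, VAEModel):
        out = decode(decoder, Z)
    else:
        out = np.asarray(decoder(Z), dtype=np.float64)
        if out.ndim == 2:
            return out
    if mapping is None:
        raise ValueError("grid-valued decoder output requires a GridMapping")
    seq = GridSequence(frames=out, validity=mapping.validity,
                       mapping_id=mapping.mesh_id)
    return from_grid(seq, mapping).values


def basis_to_cortex(basis_vector: np.ndarray, decoder,
                    mapping: GridMapping | None = None,
                    n_scales: int = 1000, seed: int = 0) -> CorticalMap:
    """Cortical map of a latent basis via random-scaling covariance.

    Draws ``n_scales`` standard-normal factors s, decodes s * basis for each,
    and assigns every vertex the sample covariance between s and the decoded
    activity there.  For a linear decoder D this is Var(s) * D @ basis; for
    the trained nonlinear decoder it is the local linearization of the
    basis direction.  Deterministic given ``seed``.

    Factors are drawn antithetically (each draw paired with its negation):
    this halves the Monte-Carlo variance from even decoder components and
    makes the map of ``-b`` exactly the negation of the map of ``b``.
    """
    b = np.asarray(basis_vector, dtype=np.float64).ravel()
    rng = np.random.default_rng(seed)
    half = rng.standard_normal((n_scales + 1) // 2)
    s = np.concatenate([half, -half])[:n_scales]
    Z = np.outer(b, s)  # (k, n_scales)
    verts = _decode_to_vertices(decoder, Z, mapping)  # (V, n_scales)
    sc = s - s.mean()
    values = (verts - verts.mean(axis=1, keepdims=True)) @ sc / (n_scales - 1)
    return CorticalMap(values=values)


def fix_sign(cmap: CorticalMap) -> CorticalMap:
    """Negate the whole map iff its strongest-|value| vertex is negative.

    Ties on |value| resolve to the lowest vertex index (np.argmax
    convention).  An all-zero map is returned unchanged with a warning.
    """
    v = cmap.values
    if v.size == 0:
        raise ValueError("empty map")
    if not np.any(v):
        warnings.warn("all-zero map: sign left unchanged")
        return CorticalMap(values=v.copy(), sign_fixed=True,
                           threshold_fraction=cmap.threshold_fraction)
    peak = np.argmax(np.abs(v))
    out = -v if v[peak] < 0 else v.copy()
    return CorticalMap(values=out, sign_fixed=True,
                       threshold_fraction=cmap.threshold_fraction)


def threshold_map(cmap: CorticalMap, fraction: float = 0.15) -> CorticalMap:
    """Zero all values with |v| < fraction * max|v| (display thresholding)."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    v = cmap.values.copy()
    if fraction > 0 and v.size:
        cut = fraction * np.abs(v).max()
        v[np.abs(v) < cut] = 0.0
    return CorticalMap(values=v, sign_fixed=cmap.sign_fixed,
                       threshold_fraction=fraction)


def _abs_corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    Ac /= np.linalg.norm(Ac, axis=0)
    Bc /= np.linalg.norm(Bc, axis=0)
    return np.abs(Ac.T @ Bc)


def match_bases(basesA: np.ndarray, basesB: np.ndarray, method: str = "greedy"):
    """One-to-one pairing of basis columns by absolute Pearson correlation.

    Greedy by default (strongest remaining pair first), mirroring how the
    reproducibility analysis pairs components; ``method='optimal'`` solves
    the assignment problem exactly (used as an oracle for small k).

    Returns ``(pairs, rs)``: ``pairs[i] = (a, b)`` sorted by descending |r|.
    """
    A = np.asarray(basesA, dtype=np.float64)
    B = np.asarray(basesB, dtype=np.float64)
    if A.shape != B.shape:
        raise ValueError(f"basis shapes differ: {A.shape} vs {B.shape}")
    C = _abs_corr_matrix(A, B)
    k = C.shape[0]
    if method == "optimal":
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(-C)
        rs = C[rows, cols]
        order = np.argsort(-rs)
        return [(int(rows[i]), int(cols[i])) for i in order], rs[order]
    pairs, rs = [], []
    Cw = C.copy()
    for _ in range(k):
        a, b = np.unravel_index(np.argmax(Cw), Cw.shape)
        pairs.append((int(a), int(b)))
        rs.append(float(Cw[a, b]))
        Cw[a, :] = -1.0
        Cw[:, b] = -1.0
    return pairs, np.array(rs)


def reproducibility_curve(group_latents: dict, n_components: int = 30,
                          n_seeds: int = 100, top_k=(1, 3, 5, 10, 15),
                          seed: int = 0):
    """Similarity of latent bases between groups as a function of top-k.

    For each ICA initialization seed, runs temporal ICA per group, pairs
    bases across each group pair, and averages the top-k matched |r| values.
    Returns ``{(groupA, groupB): {"k": ks, "mean": ..., "sd": ...}}``.
    """
    if len(group_latents) < 2:
        raise ValueError("need at least 2 groups")
    names = list(group_latents)
    zcats = {name: concat_latents(group_latents[name])[0] for name in names}
    top_k = list(top_k)
    sims = {pair: [] for pair in
            [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]}
    rng = np.random.default_rng(seed)
    for _ in range(n_seeds):
        ica_seed = int(rng.integers(0, 2**31 - 1))
        bases = {name: temporal_ica(zcats[name], n_components, seed=ica_seed)
                 for name in names}
        for a, b in sims:
            _, rs = match_bases(bases[a].mixing, bases[b].mixing)
            sims[(a, b)].append([rs[:kk].mean() for kk in top_k])
    return {
        pair: {
            "k": np.array(top_k),
            "mean": np.mean(vals, axis=0),
            "sd": np.std(vals, axis=0, ddof=1) if len(vals) > 1
            else np.full(len(top_k), np.nan),
        }
        for pair, vals in sims.items()
    }
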