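"""Matrix factorisations and multi-block analysis.

PCA (mean-centred SVD), non-negative matrix factorisation with a
multi-restart best-explained-variance policy, JADE independent component
analysis (joint approximate diagonalisation of fourth-order cumulant
matrices), and ComDim/CCSWA common components with per-block saliences.
Oblique (scalene) score coordinates and spider-diagram loading signatures
support the interpretation of non-orthogonal factorisations.

Conventions making every output deterministic and comparable across runs:
components are ordered by decreasing eigenvalue / energy / |kurtosis|,
each loading's largest-magnitude element is made positive, and all stochastic
operations take explicit seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.decomposition import NMF as _SkNMF

from .preprocess import DataBlock, PeakWindow

__all__ = [
    "Decomposition",
    "ComDimResult",
    "ScreeResult",
    "BSSModel",
    "ObliqueAxes",
    "pca",
    "scree_select",
    "nmf",
    "explained_variance",
    "jade_ica",
    "comdim",
    "inter_axis_angle",
    "oblique_scores",
    "loading_signature",
]


@dataclass
class Decomposition:
    """Scores/loadings factorisation of one data block.

    ``scores`` is samples x p, ``loadings`` p x features, so the (centred or
    raw) data are approximated by ``scores @ loadings``.  ``explained`` holds
    per-component explained-variance fractions, ``total_ev`` their sum for
    PCA / the reconstruction EV for NMF and ICA.
    """

    kind: str
    scores: np.ndarray
    loadings: np.ndarray
    explained: np.ndarray
    total_ev: float
    p: int
    eigenvalues: np.ndarray | None = None
    seed: int | None = None
    n_restarts: int | None = None
    feature_axis: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class ComDimResult:
    """Common components Q (orthonormal, samples x p), per-block saliences
    (blocks x p, >= 0), residual blocks and per-block explained variance."""

    Q: np.ndarray
    saliences: np.ndarray
    residuals: list[np.ndarray]
    block_ev: np.ndarray
    block_names: list[str]
    inner_method: str
    p: int
    row_ids: list[str] = field(default_factory=list)


@dataclass
class ScreeResult:
    p: int
    table: pd.DataFrame
    flat: bool = False


@dataclass
class BSSModel:
    """Blind-source-separation model x = A s: N_c observed mixtures of N_s
    unknown sources through the mixing matrix A."""

    mixing: np.ndarray  # N_c x N_s
    sources: np.ndarray  # N_s x T
    observations: np.ndarray  # N_c x T

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.sources = np.asarray(self.sources, dtype=float)
        self.observations = np.asarray(self.observations, dtype=float)
        if self.mixing.shape != (self.n_sensors, self.n_sources):
            raise ValueError("mixing matrix shape must be (N_c, N_s)")

    @property
    def n_sources(self) -> int:
        return self.sources.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.observations.shape[0]

    @property
    def residual(self) -> float:
        """Relative Frobenius misfit of x = A s."""
        return float(
            np.linalg.norm(self.observations - self.mixing @ self.sources)
            / max(np.linalg.norm(self.observations), 1e-300)
        )


@dataclass
class ObliqueAxes:
    """Two latent vectors and their inter-axis angle for scalene score
    plots; ``alpha`` is kept consistent with cos(alpha) = <u,v>/(|u||v|)."""

    u: np.ndarray
    v: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not 0.0 < self.alpha < 180.0:
            raise ValueError("alpha must lie strictly between 0 and 180")
        expected = inter_axis_angle(self.u, self.v)
        if abs(np.cos(np.radians(self.alpha)) -
               np.cos(np.radians(expected))) > 1e-9:
            raise ValueError("alpha inconsistent with the vectors' angle")

    @classmethod
    def from_vectors(cls, u, v) -> "ObliqueAxes":
        return cls(u=np.asarray(u, float), v=np.asarray(v, float),
                   alpha=inter_axis_angle(u, v))


def _block_matrix(block) -> np.ndarray:
    if isinstance(block, DataBlock):
        return block.matrix
    return np.asarray(block, dtype=float)


def _feature_axis(block) -> pd.DataFrame | None:
    return block.feature_axis if isinstance(block, DataBlock) else None


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """In place: make each loading's largest-magnitude element positive."""
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0


def pca(block, p: int) -> Decomposition:
    """Principal component analysis by mean-centred singular value
    decomposition; per-component explained variance is lambda_i over the total
    variance, and full-rank reconstruction is exact."""
    X = _block_matrix(block)
    n, f = X.shape
    if not 1 <= p <= min(n - 1, f):
        raise ValueError(f"p must be in [1, {min(n - 1, f)}] for a {n}x{f} matrix")
    Xc = X - X.mean(axis=0)
    total = np.linalg.norm(Xc) ** 2
    if total == 0:
        raise ValueError("constant matrix has zero variance")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    scores = U[:, :p] * s[:p]
    loadings = Vt[:p].copy()
    _fix_signs(loadings, scores)
    explained = eig[:p] / eig.sum()
    return Decomposition(
        kind="pca",
        scores=scores,
        loadings=loadings,
        explained=explained,
        total_ev=float(explained.sum()),
        p=p,
        eigenvalues=eig,
        feature_axis=_feature_axis(block),
        meta={"centered": True},
    )


def scree_select(eigenvalues) -> ScreeResult:
    """Suggest the component count from the scree of sorted eigenvalues.

    Returns the index (1-based) before the largest relative drop among the
    first min(10, n-1) eigenvalues, plus the full scree table for manual
    override; a flat scree (all drops ~0) yields p=1 with a warning flag.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size < 3:
        return ScreeResult(p=eig.size, table=pd.DataFrame({"eigenvalue": eig}))
    if np.any(np.diff(eig) > 1e-12 * max(eig.max(), 1.0)):
        raise ValueError("eigenvalues must be sorted in descending order")
    m = min(10, eig.size - 1)
    head = eig[: m + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        drops = np.where(head[:-1] > 0, (head[:-1] - head[1:]) / head[:-1], 0.0)
    table = pd.DataFrame(
        {
            "component": np.arange(1, eig.size + 1),
            "eigenvalue": eig,
            "relative_drop": np.concatenate(
                [drops, np.full(eig.size - m, np.nan)]
            ),
        }
    )
    flat = bool(np.all(drops <= 1e-12))
    if flat:
        warnings.warn("flat scree: no dominant eigenvalue drop", stacklevel=2)
        return ScreeResult(p=1, table=table, flat=True)
    return ScreeResult(p=int(np.argmax(drops)) + 1, table=table)


def explained_variance(block, reconstruction, convention: str = "raw") -> float:
    """1 - ||X - Xhat||_F^2 / ||Xref||_F^2, with Xref the column-centred matrix
    under the "centered" convention (PCA) and the raw matrix under "raw"
    (NMF)."""
    X = _block_matrix(block)
    Xhat = np.asarray(reconstruction, dtype=float)
    if X.shape != Xhat.shape:
        raise ValueError("shape mismatch between data and reconstruction")
    ref = X - X.mean(axis=0) if convention == "centered" else X
    denom = np.linalg.norm(ref) ** 2
    if denom == 0:
        raise ValueError("zero-norm reference matrix")
    return 1.0 - np.linalg.norm(X - Xhat) ** 2 / denom


def nmf(
    block,
    p: int,
    n_restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> Decomposition:
    """Non-negative matrix factorisation X ~ W H, best of ``n_restarts``
    random initialisations by explained variance 1 - ||X - WH||_F^2/||X||_F^2.

    Components are ordered by energy and scaled so each loading row has unit
    L2 norm; W, H >= 0 elementwise.  NMF is non-unique (rotational
    ambiguity), hence the multi-restart max-EV selection policy.
    """
    X = _block_matrix(block)
    if p < 1:
        raise ValueError("p must be >= 1")
    if p > min(X.shape):
        raise ValueError("p must not exceed min(n_samples, n_features)")
    if np.any(X < 0):
        raise ValueError(
            "NMF requires a non-negative matrix; clip or shift negative entries first"
        )
    norm2 = np.linalg.norm(X) ** 2
    if norm2 == 0:
        raise ValueError("zero matrix")
    restart_seeds = [
        int(child.generate_state(1, np.uint32)[0] >> 1)
        for child in np.random.SeedSequence(seed).spawn(max(n_restarts, 1))
    ]
    best = None
    for rs in restart_seeds:
        model = _SkNMF(
            n_components=p,
            init="random",
            solver="cd",
            tol=tol,
            max_iter=max_iter,
            random_state=rs,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # max_iter convergence chatter
            W = model.fit_transform(X)
        H = model.components_
        ev = 1.0 - np.linalg.norm(X - W @ H) ** 2 / norm2
        if best is None or ev > best[0]:
            best = (ev, W, H)
    ev, W, H = best
    # unit-norm loading rows, energy-ordered
    norms = np.linalg.norm(H, axis=1)
    norms[norms == 0] = 1.0
    H = H / norms[:, None]
    W = W * norms[None, :]
    energy = np.linalg.norm(W, axis=0)
    order = np.argsort(-energy)
    W, H, energy = W[:, order], H[order], energy[order]
    comp_frac = energy**2 / max((energy**2).sum(), 1e-300)
    return Decomposition(
        kind="nmf",
        scores=W,
        loadings=H,
        explained=comp_frac * ev,
        total_ev=float(ev),
        p=p,
        seed=seed,
        n_restarts=n_restarts,
        feature_axis=_feature_axis(block),
        meta={"tol": tol, "max_iter": max_iter, "convention": "raw"},
    )


# ---------------------------------------------------------------------------
# JADE independent component analysis
# ---------------------------------------------------------------------------

def _jade_cumulant_matrices(Z: np.ndarray) -> list[np.ndarray]:
    """Parallel set of fourth-order cumulant matrices of whitened data Z
    (n observations x m variables, identity covariance)."""
    n, m = Z.shape
    eye = np.eye(m)
    mats = []
    for i in range(m):
        for j in range(i + 1):
            w = Z[:, i] * Z[:, j]
            Q = (Z * w[:, None]).T @ Z / n
            if i == j:
                Q -= eye + 2.0 * np.outer(eye[i], eye[i])
            else:
                Q -= np.outer(eye[i], eye[j]) + np.outer(eye[j], eye[i])
                Q *= np.sqrt(2.0)  # weight for off-diagonal pair
            mats.append(Q)
    return mats


def _joint_diagonalize(mats: list[np.ndarray], tol: float = 1e-9,
                       max_sweeps: int = 100) -> np.ndarray:
    """Joint approximate diagonalisation by Jacobi rotations; returns the
    orthogonal matrix V maximising the sum of squared diagonals of V^T C V."""
    m = mats[0].shape[0]
    V = np.eye(m)
    C = [M.copy() for M in mats]
    for _ in range(max_sweeps):
        rotated = False
        for p in range(m - 1):
            for q in range(p + 1, m):
                g1 = np.array([M[p, p] - M[q, q] for M in C])
                g2 = np.array([M[p, q] + M[q, p] for M in C])
                ton = g1 @ g1 - g2 @ g2
                toff = 2.0 * (g1 @ g2)
                theta = 0.5 * np.arctan2(toff, ton + np.hypot(ton, toff))
                if abs(np.sin(theta)) > tol:
                    rotated = True
                    c, s = np.cos(theta), np.sin(theta)
                    G = np.array([[c, -s], [s, c]])
                    idx = [p, q]
                    for M in C:
                        M[:, idx] = M[:, idx] @ G
                        M[idx, :] = G.T @ M[idx, :]
                    V[:, idx] = V[:, idx] @ G
        if not rotated:
            break
    return V


def jade_ica(block, p: int) -> Decomposition:
    """JADE independent component analysis.

    The data are whitened by PCA to ``p`` dimensions; fourth-order cumulant
    matrices of the whitened scores are then jointly diagonalised by Jacobi
    rotations.  Under the blind-source-separation model x = A s with
    statistically independent, non-Gaussian sources, the rotated whitened
    scores recover the sources up to sign and permutation.  Components are
    ordered by descending |excess kurtosis| and sign-fixed as in PCA; a
    warning flag is set when all components look Gaussian (the model is then
    unidentifiable).
    """
    X = _block_matrix(block)
    n, f = X.shape
    if not 1 <= p <= min(n - 1, f):
        raise ValueError(f"p must be in [1, {min(n - 1, f)}]")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > max(n, f) * np.finfo(float).eps * s[0]))
    if p > rank:
        raise ValueError(f"p={p} exceeds the numerical rank {rank}")
    Z = np.sqrt(n) * U[:, :p]  # whitened: Z.T Z / n = I
    V = _joint_diagonalize(_jade_cumulant_matrices(Z)) if p > 1 else np.eye(1)
    Y = Z @ V
    kurt = np.mean(Y**4, axis=0) - 3.0  # unit variance by construction
    order = np.argsort(-np.abs(kurt))
    Y, V, kurt = Y[:, order], V[:, order], kurt[order]
    # X_c (rank-p part) = Y @ loadings
    loadings = V.T @ np.diag(s[:p]) @ Vt[:p] / np.sqrt(n)
    _fix_signs(loadings, Y)
    recon_ev = float((s[:p] ** 2).sum() / max((s**2).sum(), 1e-300))
    gaussian_warning = bool(np.all(np.abs(kurt) < 0.1))
    if gaussian_warning:
        warnings.warn(
            "all components near-Gaussian: ICA is unidentifiable", stacklevel=2
        )
    return Decomposition(
        kind="ica",
        scores=Y,
        loadings=loadings,
        explained=(s[:p] ** 2) / max((s**2).sum(), 1e-300),
        total_ev=recon_ev,
        p=p,
        feature_axis=_feature_axis(block),
        meta={"kurtosis": kurt, "gaussian_warning": gaussian_warning,
              "mixing": V},
    )


# ---------------------------------------------------------------------------
# ComDim / CCSWA
# ---------------------------------------------------------------------------

def comdim(
    blocks: list,
    p: int,
    inner_method: str = "pca",
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ComDimResult:
    """Common components and specific weights analysis of multi-block data.

    Each block (samples x features) is scaled to unit Frobenius norm and
    represented by its cross-product matrix W_k = X_k X_k^T, modelled as
    W_k = Q Lambda^(k) Q^T + E_k with one orthonormal set of common
    components Q shared by all blocks and a non-negative diagonal salience
    matrix Lambda^(k) per block.  Components are extracted one by one: with
    ``inner_method="pca"`` the common component q is the dominant eigenvector
    of the salience-weighted sum of the (deflated) W_k, iterated with
    lambda_k = q^T W_k q to convergence; with ``inner_method="ica"`` q is the
    leading JADE component of the salience-weighted concatenated blocks.
    After each dimension every block is deflated by X_k <- (I - q q^T) X_k.

    The sum of block k's saliences over all dimensions measures how much that
    block contributes to the common space; exhaustive deflation conserves
    trace(W_k).
    """
    if inner_method not in ("pca", "ica"):
        raise ValueError("inner_method must be 'pca' or 'ica'")
    mats = [_block_matrix(b) for b in blocks]
    if not mats:
        raise ValueError("no blocks")
    N = mats[0].shape[0]
    row_ids = blocks[0].row_ids if isinstance(blocks[0], DataBlock) else []
    names = [
        b.block_name if isinstance(b, DataBlock) else f"block{k}"
        for k, b in enumerate(blocks)
    ]
    for b in blocks[1:]:
        bm = _block_matrix(b)
        if bm.shape[0] != N:
            raise ValueError("blocks must share samples (rows)")
        if isinstance(b, DataBlock) and row_ids and b.row_ids != row_ids:
            raise ValueError("blocks must share row_ids")
    if not 1 <= p <= N - 1:
        raise ValueError(f"p must be in [1, N-1] = [1, {N - 1}]")

    Xs = []
    for M in mats:
        norm = np.linalg.norm(M)
        if norm == 0:
            raise ValueError("zero-norm block")
        Xs.append(M / norm)
    K = len(Xs)
    traces = np.array([np.linalg.norm(X) ** 2 for X in Xs])  # trace of W_k

    Q = np.zeros((N, p))
    saliences = np.zeros((K, p))
    for d in range(p):
        Ws = [X @ X.T for X in Xs]
        lam = np.ones(K)
        q = None
        for _ in range(max_iter):
            M = sum(l * W for l, W in zip(lam, Ws))
            if inner_method == "pca":
                evals, evecs = linalg.eigh(M, subset_by_index=(N - 1, N - 1))
                q_new = evecs[:, 0]
            else:
                q_new = _leading_ica_direction(Xs, lam, M)
            j = int(np.argmax(np.abs(q_new)))
            if q_new[j] < 0:
                q_new = -q_new
            lam = np.array([q_new @ W @ q_new for W in Ws])
            if q is not None and np.linalg.norm(q_new - q) < tol:
                q = q_new
                break
            q = q_new
        # numerical safety: re-orthogonalise against previous components
        if d > 0:
            q = q - Q[:, :d] @ (Q[:, :d].T @ q)
            q /= np.linalg.norm(q)
            lam = np.array([q @ W @ q for W in Ws])
        Q[:, d] = q
        saliences[:, d] = lam
        Xs = [X - np.outer(q, q @ X) for X in Xs]

    residuals = Xs
    block_ev = saliences.sum(axis=1) / traces
    return ComDimResult(
        Q=Q,
        saliences=saliences,
        residuals=residuals,
        block_ev=block_ev,
        block_names=names,
        inner_method=inner_method,
        p=p,
        row_ids=list(row_ids),
    )


def _leading_ica_direction(Xs, lam, M) -> np.ndarray:
    """Leading JADE component (in sample space) of the salience-weighted
    concatenated blocks; falls back to the dominant eigenvector of the
    weighted cross-product sum when the deflated data are rank-deficient."""
    G = np.hstack([np.sqrt(max(l, 0.0)) * X for l, X in zip(lam, Xs)])
    n = G.shape[0]
    Gc = G  # rows are already comparable; no centring, as W_k uses raw X_k
    U, s, _ = np.linalg.svd(Gc, full_matrices=False)
    rank = int(np.sum(s > max(Gc.shape) * np.finfo(float).eps * max(s[0], 1e-300)))
    m = min(3, rank)
    if m < 2:
        evals, evecs = linalg.eigh(M, subset_by_index=(n - 1, n - 1))
        return evecs[:, 0]
    Z = np.sqrt(n) * U[:, :m]
    V = _joint_diagonalize(_jade_cumulant_matrices(Z))
    Y = Z @ V
    kurt = np.abs(np.mean(Y**4, axis=0) - 3.0)
    y = Y[:, int(np.argmax(kurt))]
    return y / np.linalg.norm(y)


# ---------------------------------------------------------------------------
# Oblique score coordinates and loading signatures
# ---------------------------------------------------------------------------

def inter_axis_angle(u, v) -> float:
    """Angle between two latent vectors in degrees:
    cos(alpha) = <u, v> / (||u|| ||v||)."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("inter-axis angle undefined for a zero vector")
    cos = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def oblique_scores(scores: np.ndarray, alpha: float) -> np.ndarray:
    """Map two score columns into scalene plotting coordinates with
    inter-axis angle ``alpha`` (degrees): (s1, s2) -> (s1 + s2 cos a, s2 sin a).

    Euclidean distances in the plot then equal distances in the oblique
    metric induced by the two (non-orthogonal) latent vectors.
    """
    if not 0.0 < alpha < 180.0:
        raise ValueError("alpha must be strictly between 0 and 180 degrees")
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[1] != 2:
        raise ValueError("scores must have exactly two columns")
    a = np.radians(alpha)
    return np.column_stack([S[:, 0] + S[:, 1] * np.cos(a), S[:, 1] * np.sin(a)])


def loading_signature(
    decomposition: Decomposition, windows: list[PeakWindow]
) -> pd.DataFrame:
    """Spider-diagram table of net loading integrals per component and window.

    Each window (optionally per colour sub-spectrum when colour metadata is
    present) gets the net baseline-subtracted integral of every component's
    loading; each window column is then normalised by its greatest absolute
    magnitude over all components, so values lie in [-1, 1] with at least one
    +-1 per (reachable) window.
    """
    if not windows:
        raise ValueError("no windows given")
    fa = decomposition.feature_axis
    if fa is None:
        raise ValueError("decomposition carries no feature_axis metadata")
    positions = fa["position"].to_numpy()
    modalities = fa["modality"].to_numpy() if "modality" in fa else None
    colours = fa["colour"].to_numpy() if "colour" in fa else None
    groups = sorted(set(colours)) if colours is not None else [None]

    cols = {}
    for window in windows:
        for colour in groups:
            sel = (positions >= window.center - window.half_width) & (
                positions <= window.center + window.half_width
            )
            if window.modality is not None and modalities is not None:
                sel &= modalities == window.modality
            if colour is not None:
                sel &= colours == colour
            key = (window.label, colour) if colour is not None else window.label
            if sel.sum() < 2:
                cols[key] = np.zeros(decomposition.p)
                continue
            x = positions[sel]
            vals = np.zeros(decomposition.p)
            for c in range(decomposition.p):
                y = decomposition.loadings[c, sel]
                baseline = y[0] + (y[-1] - y[0]) * (x - x[0]) / max(x[-1] - x[0], 1e-300)
                vals[c] = np.trapezoid(y - baseline, x)
            peak = np.max(np.abs(vals))
            cols[key] = vals / peak if peak > 0 else vals
    table = pd.DataFrame(cols, index=pd.RangeIndex(1, decomposition.p + 1,
                                                   name="component"))
    return table
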