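"""Trilinear PARAFAC decomposition of sample x excitation x emission tensors.

Alternating least squares with non-negativity in all three modes, missing
cells (scatter excision, ragged scan ranges) excluded from the least
squares via row-wise weighted updates, multi-start initialization,
split-half validation with Tucker congruence matching, and projection of
fixed spectral loadings onto non-normalized EEMs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .eem import EEM

__all__ = [
    "EEMTensor",
    "ParafacModel",
    "SplitHalfReport",
    "normalize_for_fit",
    "fit_parafac",
    "split_half_validate",
    "project_scores",
    "normalize_scores",
    "tucker_congruence",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)

CONGRUENCE_THRESHOLD = 0.95


@dataclass(frozen=True)
class EEMTensor:
    """Stack of EEMs sharing grids: values is (sample, excitation, emission)."""

    sample_ids: list
    excitation: np.ndarray
    emission: np.ndarray
    values: np.ndarray
    mask: np.ndarray  # True = missing

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "excitation", np.asarray(self.excitation, dtype=float))
        object.__setattr__(self, "emission", np.asarray(self.emission, dtype=float))
        if v.shape != m.shape or v.ndim != 3:
            raise ValueError("values and mask must be 3-way arrays of equal shape")
        if v.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        frac = m.reshape(v.shape[0], -1).mean(axis=1)
        if np.any(frac >= 0.95):
            raise ValueError("a sample has (nearly) all cells missing")

    @classmethod
    def from_eems(cls, sample_ids: list, eems: list[EEM], trim: bool = True,
                  em_range: tuple | None = None,
                  ex_range: tuple | None = None) -> "EEMTensor":
        """Stack EEMs with identical grids.

        em_range/ex_range restrict the fitted grids to a validated spectral
        window (ragged scan ranges leave sparsely observed emission
        wavelengths whose loadings would be noise-pinned); trim additionally
        drops grid lines with zero observed coverage.
        """
        ref = eems[0]
        for e in eems[1:]:
            if not (np.array_equal(e.excitation, ref.excitation)
                    and np.array_equal(e.emission, ref.emission)):
                raise ValueError("all EEMs must share excitation/emission grids")
        values = np.stack([e.intensity for e in eems])
        mask = np.stack([e.mask for e in eems])
        ex, em = ref.excitation, ref.emission
        if em_range is not None:
            sel = (em >= em_range[0]) & (em <= em_range[1])
            values, mask, em = values[:, :, sel], mask[:, :, sel], em[sel]
        if ex_range is not None:
            sel = (ex >= ex_range[0]) & (ex <= ex_range[1])
            values, mask, ex = values[:, sel], mask[:, sel], ex[sel]
        if trim:
            obs = ~mask
            keep_ex = obs.any(axis=(0, 2))
            keep_em = obs.any(axis=(0, 1))
            values = values[:, keep_ex][:, :, keep_em]
            mask = mask[:, keep_ex][:, :, keep_em]
            ex, em = ex[keep_ex], em[keep_em]
        values = np.where(mask, 0.0, values)
        return cls(list(sample_ids), ex, em, values, mask)


@dataclass(frozen=True)
class ParafacModel:
    """Fitted trilinear model. Spectral loadings are scaled to unit maximum
    per component; all scale sits in the per-sample scores."""

    n_components: int
    excitation: np.ndarray
    emission: np.ndarray
    ex_loadings: np.ndarray   # (n_excitation, k), >= 0, unit max
    em_loadings: np.ndarray   # (n_emission, k), >= 0, unit max
    scores: np.ndarray        # (n_samples, k), >= 0
    sample_ids: list
    explained_variance: float
    iterations: int
    converged: bool
    seed: int
    sse: float
    core_consistency: float


@dataclass(frozen=True)
class SplitHalfReport:
    """Per-component min(ex, em) Tucker congruence between half-models."""

    congruence_ex: np.ndarray
    congruence_em: np.ndarray
    pass_threshold: float
    passed: bool

    @property
    def min_congruence(self) -> np.ndarray:
        return np.minimum(self.congruence_ex, self.congruence_em)


def normalize_for_fit(t: EEMTensor) -> tuple[EEMTensor, np.ndarray]:
    """Divide each sample slab by its own maximum observed intensity.

    Returns the normalized tensor and the per-sample scale factors; samples
    with non-positive maxima are excluded (logged).
    """
    obs = np.where(t.mask, -np.inf, t.values)
    maxima = obs.reshape(t.values.shape[0], -1).max(axis=1)
    keep = maxima > 0
    if not np.all(keep):
        dropped = [sid for sid, k in zip(t.sample_ids, keep) if not k]
        log.warning("normalize_for_fit excluded samples with non-positive max: %s", dropped)
    factors = maxima[keep]
    values = t.values[keep] / factors[:, None, None]
    return (
        EEMTensor([s for s, k in zip(t.sample_ids, keep) if k],
                  t.excitation, t.emission, values, t.mask[keep]),
        factors,
    )


def tucker_congruence(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity between two loading vectors."""
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return 0.0
    return float(np.dot(x, y) / (nx * ny))


def _nnls_cd(G: np.ndarray, C: np.ndarray, X: np.ndarray,
             n_sweeps: int = 6, tol: float = 1e-10) -> np.ndarray:
    """Row-wise non-negative least squares from normal equations.

    Solves min_{A>=0} sum_rows ||x_row - Z a_row||^2 where G = Z'Z (k x k,
    shared or batched per row) and C = X Z (rows x k), by cyclic coordinate
    descent, which decreases the objective at every coordinate update.
    X is the current iterate (warm start), modified in place.
    """
    k = C.shape[-1]
    batched = G.ndim == 3
    if batched:
        diag = np.stack([G[:, j, j] for j in range(k)], axis=1)  # (rows, k)
    else:
        diag = np.diag(G)
    safe = np.where(diag > 0, diag, 1.0)
    for _ in range(n_sweeps):
        delta = 0.0
        for j in range(k):
            if batched:
                s = (X * G[:, :, j]).sum(axis=1)
                num = C[:, j] - s + X[:, j] * diag[:, j]
                new = np.where(diag[:, j] > 0,
                               np.maximum(num / safe[:, j], 0.0), 0.0)
            else:
                num = C[:, j] - X @ G[:, j] + X[:, j] * diag[j]
                new = (np.maximum(num / safe[j], 0.0) if diag[j] > 0
                       else np.zeros(X.shape[0]))
            d = np.abs(new - X[:, j])
            if d.size:
                delta = max(delta, float(d.max()))
            X[:, j] = new
        if delta < tol:
            break
    return X


def _khatri_rao(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Columnwise Kronecker product: (I*J, k) from (I, k) and (J, k)."""
    i, k = U.shape
    j = V.shape[0]
    return (U[:, None, :] * V[None, :, :]).reshape(i * j, k)


def _model_tensor(A: np.ndarray, B: np.ndarray, C: np.ndarray) -> np.ndarray:
    s = A.shape[0]
    return (A @ _khatri_rao(B, C).T).reshape(s, B.shape[0], C.shape[0])


def _pair_products(M: np.ndarray) -> np.ndarray:
    """All columnwise pair products: (rows, k*k) from (rows, k)."""
    r, k = M.shape
    return (M[:, :, None] * M[:, None, :]).reshape(r, k * k)


def _fit_single(values: np.ndarray, mask: np.ndarray, k: int, rng: np.random.Generator,
                tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    """One ALS run with missing cells excluded from the least squares.

    Each mode update solves row-wise weighted non-negative least squares
    using only observed cells, so unobserved regions never pin factor
    values; a fast path exploits a mask shared across samples (the usual
    case: scan windows and scatter excision do not depend on the sample).
    """
    n_s, n_ex, n_em = values.shape
    obs = ~mask
    w = obs.astype(float)
    V = np.where(mask, 0.0, values)
    V0 = V.reshape(n_s, n_ex * n_em)
    V1 = np.ascontiguousarray(V.transpose(1, 0, 2)).reshape(n_ex, n_s * n_em)
    V2 = np.ascontiguousarray(V.transpose(2, 0, 1)).reshape(n_em, n_s * n_ex)
    shared = bool(np.all(mask == mask[0]))
    w2d = w[0] if shared else None                       # (n_ex, n_em)
    sse_prev = np.inf
    # initialize spectral modes only; scores follow from the first update,
    # making the run equivariant to sample ordering
    B = rng.uniform(0.1, 1.0, size=(n_ex, k))
    C = rng.uniform(0.1, 1.0, size=(n_em, k))
    A = np.zeros((n_s, k))
    converged = False
    reseeds = 0
    it = 0
    for it in range(1, max_iter + 1):
        if shared:
            BB = _pair_products(B)                       # (n_ex, k^2)
            CC = _pair_products(C)                       # (n_em, k^2)
            wCC = w2d @ CC                               # (n_ex, k^2)
            wBB = w2d.T @ BB                             # (n_em, k^2)
            # mode A: identical normal matrix for every sample
            G = (BB * wCC).sum(axis=0).reshape(k, k)
            A = _nnls_cd(G, V0 @ _khatri_rao(B, C), A)
            AA = A.T @ A
            # mode B: per-excitation-row normal matrices
            GB = AA[None, :, :] * wCC.reshape(n_ex, k, k)
            B = _nnls_cd(GB, V1 @ _khatri_rao(A, C), B)
            BB = _pair_products(B)
            wBB = w2d.T @ BB
            # mode C: per-emission-row normal matrices
            GC = AA[None, :, :] * wBB.reshape(n_em, k, k)
            C = _nnls_cd(GC, V2 @ _khatri_rao(A, B), C)
        else:
            GA = np.einsum("ijl,jr,jq,lr,lq->irq", w, B, B, C, C, optimize=True)
            A = _nnls_cd(GA, V0 @ _khatri_rao(B, C), A)
            GB = np.einsum("ijl,ir,iq,lr,lq->jrq", w, A, A, C, C, optimize=True)
            B = _nnls_cd(GB, V1 @ _khatri_rao(A, C), B)
            GC = np.einsum("ijl,ir,iq,jr,jq->lrq", w, A, A, B, B, optimize=True)
            C = _nnls_cd(GC, V2 @ _khatri_rao(A, B), C)
        # a component whose column hit exactly zero in any mode can never
        # recover under non-negative updates; reseed it (counts as a fresh
        # perturbation, so the monotonicity ledger restarts)
        dead = ((A.sum(axis=0) == 0) | (B.sum(axis=0) == 0)
                | (C.sum(axis=0) == 0))
        if dead.any() and reseeds < 5 and it < max_iter:
            reseeds += 1
            B[:, dead] = rng.uniform(0.1, 1.0, size=(n_ex, int(dead.sum())))
            C[:, dead] = rng.uniform(0.1, 1.0, size=(n_em, int(dead.sum())))
            A[:, dead] = 0.0
            sse_prev = np.inf
            continue
        est = _model_tensor(A, B, C)
        sse = float(np.sum((V - est * w) ** 2))
        if sse > sse_prev * (1 + 1e-9) + 1e-12:
            raise AssertionError(
                f"ALS residual SSE increased at iteration {it}: {sse_prev} -> {sse}"
            )
        if sse_prev < np.inf and abs(sse_prev - sse) <= tol * max(sse_prev, 1e-300):
            sse_prev = sse
            converged = True
            break
        sse_prev = sse
    return A, B, C, sse_prev, it, converged


def _apply_scale_convention(A, B, C):
    """Unit-max spectral loadings; scale absorbed into scores; components
    ordered by decreasing total score."""
    bmax = B.max(axis=0)
    cmax = C.max(axis=0)
    bmax = np.where(bmax > 0, bmax, 1.0)
    cmax = np.where(cmax > 0, cmax, 1.0)
    B = B / bmax
    C = C / cmax
    A = A * bmax * cmax
    order = np.argsort(-A.sum(axis=0))
    return A[:, order], B[:, order], C[:, order]


def _core_consistency(values, mask, A, B, C) -> float:
    """Core-consistency diagnostic (percent): 100 * (1 - ||G - T||^2 / ||T||^2)
    where G is the least-squares Tucker3 core for the fixed PARAFAC factors
    and T the superdiagonal target."""
    k = A.shape[1]
    Xc = np.where(mask, _model_tensor(A, B, C), values)
    try:
        Ap, Bp, Cp = (np.linalg.pinv(M) for M in (A, B, C))
    except np.linalg.LinAlgError:
        return float("nan")
    G = np.einsum("ri,ijl,sj,tl->rst", Ap, Xc, Bp, Cp, optimize=True)
    T = np.zeros((k, k, k))
    for r in range(k):
        T[r, r, r] = 1.0
    denom = float(np.sum(T ** 2))
    return 100.0 * (1.0 - float(np.sum((G - T) ** 2)) / denom)


def fit_parafac(t: EEMTensor, k: int, tol: float = 1e-8, max_iter: int = 2500,
                n_starts: int = 10, seed: int = 0) -> ParafacModel:
    """Fit a k-component non-negative PARAFAC model by multi-start ALS.

    The best of n_starts random initializations (by observed-cell residual
    SSE) is kept. Components are ordered by decreasing total score, with
    spectral loadings scaled to unit maximum.
    """
    if k < 1:
        raise ValueError(f"n_components must be >= 1, got {k}")
    if k > min(t.values.shape):
        raise ValueError(f"k={k} exceeds smallest tensor mode {min(t.values.shape)}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        A, B, C, sse, its, conv = _fit_single(t.values, t.mask, k, rng, tol, max_iter)
        if best is None or sse < best[3]:
            best = (A, B, C, sse, its, conv)
    A, B, C, sse, its, conv = best
    if not conv:
        log.warning("no ALS start converged within max_iter=%d", max_iter)
    A, B, C = _apply_scale_convention(A, B, C)
    obs = ~t.mask
    sst = float(np.sum(t.values[obs] ** 2))
    ev = 1.0 - sse / sst if sst > 0 else float("nan")
    return ParafacModel(
        n_components=k, excitation=t.excitation, emission=t.emission,
        ex_loadings=B, em_loadings=C, scores=A, sample_ids=list(t.sample_ids),
        explained_variance=float(np.clip(ev, 0.0, 1.0)), iterations=its,
        converged=conv, seed=seed, sse=sse,
        core_consistency=_core_consistency(t.values, t.mask, A, B, C),
    )


def match_components(ex_a, em_a, ex_b, em_b) -> list[tuple[int, int, float, float]]:
    """Greedy matching of components between two models by spectral
    congruence; returns (idx_a, idx_b, ex_congruence, em_congruence)."""
    k = ex_a.shape[1]
    cong_ex = np.array([[tucker_congruence(ex_a[:, i], ex_b[:, j]) for j in range(k)]
                        for i in range(k)])
    cong_em = np.array([[tucker_congruence(em_a[:, i], em_b[:, j]) for j in range(k)]
                        for i in range(k)])
    combined = np.minimum(cong_ex, cong_em)
    pairs = []
    free_a, free_b = set(range(k)), set(range(k))
    for _ in range(k):
        best = max(((i, j) for i in free_a for j in free_b), key=lambda ij: combined[ij])
        i, j = best
        pairs.append((i, j, float(cong_ex[i, j]), float(cong_em[i, j])))
        free_a.discard(i)
        free_b.discard(j)
    return sorted(pairs)


def split_half_validate(t: EEMTensor, k: int, seed: int = 0, tol: float = 1e-8,
                        max_iter: int = 2500, n_starts: int = 10,
                        threshold: float = CONGRUENCE_THRESHOLD) -> SplitHalfReport:
    """Split-half validation: independent fits on two random sample halves,
    greedy spectral matching, pass iff every matched component has both ex
    and em Tucker congruence >= threshold."""
    n = t.values.shape[0]
    if n < 8:
        raise ValueError(f"split-half validation needs >= 8 samples, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    halves = perm[: n // 2], perm[n // 2:]
    models = []
    for idx_half, half in enumerate(halves):
        sub = EEMTensor([t.sample_ids[i] for i in half], t.excitation, t.emission,
                        t.values[half], t.mask[half])
        models.append(fit_parafac(sub, k, tol=tol, max_iter=max_iter,
                                  n_starts=n_starts, seed=seed + 1 + idx_half))
    pairs = match_components(models[0].ex_loadings, models[0].em_loadings,
                             models[1].ex_loadings, models[1].em_loadings)
    cong_ex = np.array([p[2] for p in pairs])
    cong_em = np.array([p[3] for p in pairs])
    passed = bool(np.all(np.minimum(cong_ex, cong_em) >= threshold))
    return SplitHalfReport(cong_ex, cong_em, threshold, passed)


def project_scores(model: ParafacModel, original: EEMTensor) -> np.ndarray:
    """Score each sample of `original` with the model's fixed spectral
    loadings by masked non-negative least squares (per-sample)."""
    if not (np.array_equal(model.excitation, original.excitation)
            and np.array_equal(model.emission, original.emission)):
        raise ValueError("tensor grids do not match model loadings")
    B, C = model.ex_loadings, model.em_loadings
    w = (~original.mask).astype(float)
    # per-sample normal equations with the sample's own observation mask
    G = np.einsum("sjl,jr,jq,lr,lq->srq", w, B, B, C, C, optimize=True)
    rhs = np.einsum("sjl,jr,lr->sr", w * original.values, B, C, optimize=True)
    k = model.n_components
    scores = np.zeros((original.values.shape[0], k))
    scores = _nnls_cd(G, rhs, scores, n_sweeps=500, tol=1e-14)
    return scores


def normalize_scores(scores: np.ndarray) -> np.ndarray:
    """Per-sample component fractions (rows sum to 1); all-zero rows -> NaN."""
    scores = np.asarray(scores, dtype=float)
    totals = scores.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(totals > 0, scores / totals, np.nan)
    return frac


def save_model(model: ParafacModel, outdir) -> None:
    """Plain-text bundle: one CSV per mode plus JSON metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = ",".join(f"C{i+1}" for i in range(model.n_components))
    np.savetxt(outdir / "ex_loadings.csv",
               np.column_stack([model.excitation, model.ex_loadings]),
               delimiter=",", header="excitation_nm," + header, comments="")
    np.savetxt(outdir / "em_loadings.csv",
               np.column_stack([model.emission, model.em_loadings]),
               delimiter=",", header="emission_nm," + header, comments="")
    with open(outdir / "scores.csv", "w") as fh:
        fh.write("sample_id," + header + "\n")
        for sid, row in zip(model.sample_ids, model.scores):
            fh.write(sid + "," + ",".join(repr(float(v)) for v in row) + "\n")
    meta = {
        "n_components": model.n_components,
        "explained_variance": model.explained_variance,
        "iterations": model.iterations,
        "converged": model.converged,
        "seed": model.seed,
        "sse": model.sse,
        "core_consistency": model.core_consistency,
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_model(outdir) -> ParafacModel:
    outdir = Path(outdir)
    ex = np.loadtxt(outdir / "ex_loadings.csv", delimiter=",", skiprows=1)
    em = np.loadtxt(outdir / "em_loadings.csv", delimiter=",", skiprows=1)
    sample_ids, rows = [], []
    with open(outdir / "scores.csv") as fh:
        next(fh)
        for line in fh:
            parts = line.strip().split(",")
            sample_ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    meta = json.loads((outdir / "metadata.json").read_text())
    return ParafacModel(
        n_components=meta["n_components"], excitation=ex[:, 0], emission=em[:, 0],
        ex_loadings=ex[:, 1:], em_loadings=em[:, 1:], scores=np.array(rows),
        sample_ids=sample_ids, explained_variance=meta["explained_variance"],
        iterations=meta["iterations"], converged=meta["converged"],
        seed=meta["seed"], sse=meta["sse"], core_consistency=meta["core_consistency"],
    )
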