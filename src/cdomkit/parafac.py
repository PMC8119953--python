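"""Non-negative trilinear PARAFAC for EEM datasets.

The model is ``X[i,j,k] = sum_f A[i,f] B[j,f] C[k,f]`` with sample scores
``A``, emission loadings ``B`` and excitation loadings ``C``, all
constrained nonnegative.  Fitting is alternating least squares with the
per-row subproblems solved exactly by NNLS on the (F x F) normal
equations; missing cells (the scatter mask) are handled by
expectation-maximization imputation, so the minimized residual sum of
squares runs over observed cells only.

Scale and permutation indeterminacy are absorbed by convention: spectral
loadings are unit Euclidean norm (all magnitude lives in the scores) and
components are ordered by descending emission-peak wavelength, ties broken
by descending excitation peak.

Validation follows standard EEM practice: split-half refits on the three
half-pairs built from four interleaved quarters, with components matched
across halves by Tucker congruence; core consistency is available as an
auxiliary diagnostic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import linear_sum_assignment, nnls

from .preprocess import EEMDataset
from .synthetic import ComponentSpectrum


class FitError(RuntimeError):
    """PARAFAC fitting failed in every start."""


def tucker_congruence(u: np.ndarray, v: np.ndarray) -> float:
    """Tucker congruence coefficient: sum(uv)/sqrt(sum(u^2) sum(v^2))."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("congruence undefined for a zero vector")
    return float(u @ v / (nu * nv))


@dataclass
class ParafacModel:
    """A fitted nonnegative trilinear model."""

    n_components: int
    scores: np.ndarray          # n_samples x F, carries all magnitude (R.U.)
    em_loadings: np.ndarray     # n_em x F, unit norm
    ex_loadings: np.ndarray     # n_ex x F, unit norm
    em_grid: np.ndarray
    ex_grid: np.ndarray
    explained_variance: float   # % of observed-cell sum of squares
    rss: float
    n_iterations: int
    converged: bool
    start_seed: int
    sample_ids: list[str] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        return np.einsum("if,jf,kf->ijk", self.scores,
                         self.em_loadings, self.ex_loadings)

    @property
    def em_peaks(self) -> np.ndarray:
        return self.em_grid[np.argmax(self.em_loadings, axis=0)]

    @property
    def ex_peaks(self) -> np.ndarray:
        return self.ex_grid[np.argmax(self.ex_loadings, axis=0)]


@dataclass
class ValidationReport:
    scheme: str
    threshold: float
    per_pair: list[dict]            # pair label -> per-component congruences
    min_congruence: float
    validated: bool


@dataclass
class OutlierReport:
    leverages: np.ndarray
    flagged: list[str]
    criterion: str
    refit_recommended: bool


# ---------------------------------------------------------------------------
# NNLS machinery
# ---------------------------------------------------------------------------

def _nnls_rows(G: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Solve min ||Z x - y||, x >= 0 for every row of H = Y Z, given
    G = Z'Z.  Uses the Cholesky trick: the problem equals
    min ||L' x - L^-1 h|| with G = L L'."""
    F = G.shape[0]
    ridge = 1e-12 * max(float(np.trace(G)) / F, 1.0)
    L = np.linalg.cholesky(G + ridge * np.eye(F))
    B = solve_triangular(L, H.T, lower=True)        # F x n_rows
    out = np.empty_like(H)
    LT = L.T.copy()
    for i in range(H.shape[0]):
        out[i], _ = nnls(LT, B[:, i])
    return out


def _ls_rows(G: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Unconstrained counterpart of :func:`_nnls_rows` (normal equations)."""
    F = G.shape[0]
    ridge = 1e-12 * max(float(np.trace(G)) / F, 1.0)
    c = cho_factor(G + ridge * np.eye(F))
    return cho_solve(c, H.T).T


def _als(
    X: np.ndarray,
    M: np.ndarray,
    F: int,
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    tol: float,
    max_iter: int,
    nonneg: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    """EM-imputed ALS.  ``M`` is the (em x ex) observation mask; masked
    cells of ``X`` are ignored (they are re-imputed from the running model
    every sweep)."""
    solve_rows = _nnls_rows if nonneg else _ls_rows
    M3 = np.broadcast_to(M[None, :, :], X.shape)
    Xobs = np.where(M3, X, 0.0)
    tss = float(np.sum(Xobs[M3] ** 2))
    Xc = Xobs.copy()
    rss_prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        G = (B.T @ B) * (C.T @ C)
        H = np.einsum("ijk,jf,kf->if", Xc, B, C, optimize=True)
        A = solve_rows(G, H)
        G = (A.T @ A) * (C.T @ C)
        H = np.einsum("ijk,if,kf->jf", Xc, A, C, optimize=True)
        B = solve_rows(G, H)
        G = (A.T @ A) * (B.T @ B)
        H = np.einsum("ijk,if,jf->kf", Xc, A, B, optimize=True)
        C = solve_rows(G, H)
        model = np.einsum("if,jf,kf->ijk", A, B, C, optimize=True)
        rss = float(np.sum((Xobs[M3] - model[M3]) ** 2))
        Xc = np.where(M3, Xobs, model)
        if rss <= 1e-15 * tss:
            converged = True
            break
        if rss_prev < np.inf and abs(rss_prev - rss) <= tol * rss_prev:
            converged = True
            break
        rss_prev = rss
    return A, B, C, rss, it, converged


def _svd_start(X: np.ndarray, M: np.ndarray, F: int) -> tuple[np.ndarray, ...]:
    """Nonnegative start from the leading singular vectors of each
    zero-filled unfolding."""
    Xz = np.where(np.broadcast_to(M[None, :, :], X.shape), X, 0.0)
    n, j, k = Xz.shape
    mats = (Xz.reshape(n, j * k),
            np.moveaxis(Xz, 1, 0).reshape(j, n * k),
            np.moveaxis(Xz, 2, 0).reshape(k, n * j))
    out = []
    for dim, mat in zip((n, j, k), mats):
        u, _, _ = np.linalg.svd(mat, full_matrices=False)
        m = min(F, u.shape[1])
        start = np.abs(u[:, :m])
        if m < F:
            start = np.hstack([start, np.full((dim, F - m), 1e-3)])
        out.append(start + 1e-6)
    return tuple(out)


def _normalize_and_order(
    A: np.ndarray, B: np.ndarray, C: np.ndarray,
    em_grid: np.ndarray, ex_grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Push all magnitude into the scores; order components by descending
    emission peak, ties by descending excitation peak."""
    A, B, C = A.copy(), B.copy(), C.copy()
    for f in range(A.shape[1]):
        nb = np.linalg.norm(B[:, f])
        nc = np.linalg.norm(C[:, f])
        if nb > 0:
            B[:, f] /= nb
        if nc > 0:
            C[:, f] /= nc
        A[:, f] *= nb * nc
    em_pk = em_grid[np.argmax(B, axis=0)]
    ex_pk = ex_grid[np.argmax(C, axis=0)]
    order = np.lexsort((-ex_pk, -em_pk))
    return A[:, order], B[:, order], C[:, order]


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

def fit_parafac(
    ds: EEMDataset,
    F: int,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 2500,
    seed: int = 0,
    nonneg: bool = True,
    coarse_iter: int = 400,
) -> ParafacModel:
    """Best-of-``n_starts`` masked (non-negative) ALS fit.

    ``n_starts`` random nonnegative starts plus one SVD-based start are run
    with the full tolerance but a capped sweep budget (``coarse_iter``);
    the best final RSS is then refined to ``max_iter``.  Deterministic
    given ``seed``.
    """
    if F < 1:
        raise ValueError("F must be >= 1")
    n, j, k = ds.tensor.shape
    if F > min(n, j, k):
        raise ValueError(f"F={F} exceeds a tensor dimension {(n, j, k)}")
    if n < 2 * F:
        raise ValueError(f"need at least 2F={2*F} samples to fit F={F}")
    X = np.asarray(ds.tensor, dtype=float)
    M = np.asarray(ds.mask, dtype=bool).copy()
    # the mask is authoritative; any non-finite cell is also unobserved
    finite = np.all(np.isfinite(np.where(np.broadcast_to(M, X.shape), X, 0.0)), axis=0)
    M &= finite
    M3 = np.broadcast_to(M[None, :, :], X.shape)
    tss = float(np.sum(np.where(M3, X, 0.0) ** 2))
    if tss == 0:
        raise ValueError("dataset has zero total sum of squares")

    rng = np.random.default_rng(seed)
    start_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_starts)]
    scale = np.sqrt(np.mean(np.where(M3, X, 0.0) ** 2)) + 1e-12

    candidates: list[tuple[float, tuple, int]] = []
    try:
        A0, B0, C0 = _svd_start(X, M, F)
        res = _als(X, M, F, A0, B0, C0, tol, coarse_iter, nonneg)
        candidates.append((res[3], res[:3], -1))
    except np.linalg.LinAlgError:
        pass
    for s in start_seeds:
        r = np.random.default_rng(s)
        A0 = r.uniform(0.1, 1.0, size=(n, F)) * scale
        B0 = r.uniform(0.1, 1.0, size=(j, F))
        C0 = r.uniform(0.1, 1.0, size=(k, F))
        res = _als(X, M, F, A0, B0, C0, tol, coarse_iter, nonneg)
        candidates.append((res[3], res[:3], s))
    if not candidates:
        raise FitError("all PARAFAC starts failed")
    candidates.sort(key=lambda c: c[0])
    best_rss, (A, B, C), best_seed = candidates[0]
    A, B, C, rss, extra_it, converged = _als(
        X, M, F, A, B, C, tol, max_iter, nonneg)
    A, B, C = _normalize_and_order(A, B, C, ds.em, ds.ex)
    ev = 100.0 * (1.0 - rss / tss)
    return ParafacModel(
        n_components=F, scores=A, em_loadings=B, ex_loadings=C,
        em_grid=ds.em.copy(), ex_grid=ds.ex.copy(),
        explained_variance=ev, rss=rss,
        n_iterations=extra_it, converged=converged, start_seed=best_seed,
        sample_ids=ds.sample_ids,
    )


def explained_variance(model: ParafacModel, ds: EEMDataset) -> float:
    """100 * (1 - RSS/TSS) over observed (unmasked, finite) cells."""
    M = np.asarray(ds.mask, dtype=bool)
    M3 = np.broadcast_to(M[None, :, :], ds.tensor.shape)
    finite = np.isfinite(ds.tensor)
    use = M3 & finite
    X = ds.tensor
    recon = model.reconstruct()
    tss = float(np.sum(X[use] ** 2))
    if tss == 0:
        raise ValueError("TSS is zero")
    rss = float(np.sum((X[use] - recon[use]) ** 2))
    return 100.0 * (1.0 - rss / tss)


# ---------------------------------------------------------------------------
# validation and diagnostics
# ---------------------------------------------------------------------------

def _match_loadings(
    b1: np.ndarray, c1: np.ndarray, b2: np.ndarray, c2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal one-to-one component matching between two fits by combined
    (em x ex) congruence; returns (assignment, em_congruences, ex_congruences)."""
    F = b1.shape[1]
    cem = np.zeros((F, F))
    cex = np.zeros((F, F))
    for p in range(F):
        for q in range(F):
            try:
                cem[p, q] = tucker_congruence(b1[:, p], b2[:, q])
                cex[p, q] = tucker_congruence(c1[:, p], c2[:, q])
            except ValueError:
                cem[p, q] = cex[p, q] = 0.0
    row, col = linear_sum_assignment(-(cem * cex))
    return col, cem[row, col], cex[row, col]


def split_half_validate(
    ds: EEMDataset,
    F: int,
    scheme: str = "S4C6T3",
    threshold: float = 0.95,
    n_starts: int = 3,
    tol: float = 1e-7,
    max_iter: int = 1500,
    seed: int = 0,
) -> ValidationReport:
    """Split-half validation on the three half-pairs of four interleaved
    quarters (robust to ordered manifests).

    Each half is refit independently; components are matched across the
    halves by congruence and the model validates when every pair's minimum
    per-component congruence (both spectral modes) reaches ``threshold``.
    """
    n = ds.n_samples
    if n < 4 * F:
        raise ValueError(f"need at least 4F={4*F} samples for split-half at F={F}")
    quarters = [np.arange(n)[np.arange(n) % 4 == q] for q in range(4)]
    pairs = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
    per_pair = []
    overall_min = 1.0
    for pi, (ha, hb) in enumerate(pairs):
        ia = np.concatenate([quarters[q] for q in ha])
        ib = np.concatenate([quarters[q] for q in hb])
        ma = fit_parafac(ds.subset(ia), F, n_starts=n_starts, tol=tol,
                         max_iter=max_iter, seed=seed + 101 * pi + 1)
        mb = fit_parafac(ds.subset(ib), F, n_starts=n_starts, tol=tol,
                         max_iter=max_iter, seed=seed + 101 * pi + 2)
        _, cem, cex = _match_loadings(ma.em_loadings, ma.ex_loadings,
                                      mb.em_loadings, mb.ex_loadings)
        pair_min = float(min(cem.min(), cex.min()))
        overall_min = min(overall_min, pair_min)
        per_pair.append({
            "pair": f"Q{ha[0]+1}{ha[1]+1} vs Q{hb[0]+1}{hb[1]+1}",
            "em_congruence": cem.tolist(),
            "ex_congruence": cex.tolist(),
            "min_congruence": pair_min,
            "passed": pair_min >= threshold,
        })
    return ValidationReport(
        scheme=scheme, threshold=threshold, per_pair=per_pair,
        min_congruence=overall_min,
        validated=bool(all(p["passed"] for p in per_pair)),
    )


def detect_outliers(
    ds: EEMDataset, model: ParafacModel, leverage_cut: float = 0.2,
) -> OutlierReport:
    """Sample-mode leverages from the score matrix hat diagonal."""
    A = model.scores
    h = np.einsum("if,fg,ig->i", A, np.linalg.pinv(A.T @ A), A)
    h = np.clip(h, 0.0, 1.0)
    ids = ds.sample_ids
    flagged = [ids[i] for i in np.where(h > leverage_cut)[0]]
    return OutlierReport(
        leverages=h, flagged=flagged,
        criterion=f"score-mode leverage > {leverage_cut}",
        refit_recommended=bool(flagged),
    )


def match_components(
    model: ParafacModel,
    library: list[ComponentSpectrum],
    library_em_grid: np.ndarray,
    library_ex_grid: np.ndarray,
    threshold: float = 0.95,
) -> pd.DataFrame:
    """Match fitted components against a spectral library (OpenFluor-style).

    Library loadings are interpolated onto the model grids; an entry
    matches when min(em congruence, ex congruence) >= ``threshold``.
    Returns a tidy table sorted by descending match score within component.
    """
    if not library:
        raise ValueError("empty component library")
    rows = []
    for f in range(model.n_components):
        for comp in library:
            bem = np.interp(model.em_grid, library_em_grid, comp.emission_loading)
            bex = np.interp(model.ex_grid, library_ex_grid, comp.excitation_loading)
            if np.linalg.norm(bem) == 0 or np.linalg.norm(bex) == 0:
                continue
            cem = tucker_congruence(model.em_loadings[:, f], bem)
            cex = tucker_congruence(model.ex_loadings[:, f], bex)
            score = min(cem, cex)
            if score >= threshold:
                rows.append({
                    "model_component": f, "library_component": comp.name,
                    "em_congruence": cem, "ex_congruence": cex,
                    "match_score": score,
                })
    df = pd.DataFrame(rows, columns=["model_component", "library_component",
                                     "em_congruence", "ex_congruence",
                                     "match_score"])
    if len(df):
        df = df.sort_values(["model_component", "match_score"],
                            ascending=[True, False]).reset_index(drop=True)
    return df


def core_consistency(model: ParafacModel, ds: EEMDataset) -> float:
    """Core-consistency diagnostic (percent; 100 for a perfect trilinear
    structure).  Auxiliary only — split-half is the validation gate."""
    A, B, C = model.scores, model.em_loadings, model.ex_loadings
    M = np.asarray(ds.mask, dtype=bool)
    M3 = np.broadcast_to(M[None, :, :], ds.tensor.shape)
    recon = model.reconstruct()
    X = np.where(M3 & np.isfinite(ds.tensor), ds.tensor, recon)
    n, j, k = X.shape
    F = model.n_components
    X1 = X.reshape(n, j * k)
    # W[(j,k),(p,q)] = B[j,p]*C[k,q], raveled consistently with X1
    W = np.einsum("jp,kq->jkpq", B, C).reshape(j * k, F * F)
    G = (np.linalg.pinv(A) @ X1 @ np.linalg.pinv(W).T).reshape(F, F, F)
    T = np.zeros((F, F, F))
    for f in range(F):
        T[f, f, f] = 1.0
    denom = float(np.sum(T ** 2))
    return 100.0 * (1.0 - float(np.sum((G - T) ** 2)) / denom)


def select_n_components(
    ds: EEMDataset,
    candidates: list[int],
    n_starts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 2500,
    split_threshold: float = 0.95,
    split_starts: int = 3,
    seed: int = 0,
) -> tuple[int | None, pd.DataFrame]:
    """Fit every candidate F, validate each by split-half, and return the
    largest validated F with the full diagnostic table.

    Returns ``(None, diagnostics)`` when no candidate validates.
    """
    if not candidates:
        raise ValueError("candidate list must not be empty")
    rows = []
    models: dict[int, ParafacModel] = {}
    for F in sorted(candidates):
        try:
            model = fit_parafac(ds, F, n_starts=n_starts, tol=tol,
                                max_iter=max_iter, seed=seed + F)
            report = split_half_validate(ds, F, threshold=split_threshold,
                                         n_starts=split_starts, seed=seed + F)
            cc = core_consistency(model, ds)
            models[F] = model
            rows.append({
                "F": F, "explained_variance": model.explained_variance,
                "core_consistency": cc,
                "split_half_min_congruence": report.min_congruence,
                "validated": report.validated,
                "error": "",
            })
        except (ValueError, FitError) as exc:
            rows.append({"F": F, "explained_variance": np.nan,
                         "core_consistency": np.nan,
                         "split_half_min_congruence": np.nan,
                         "validated": False, "error": str(exc)})
    diag = pd.DataFrame(rows)
    validated = diag.loc[diag["validated"], "F"]
    selected = int(validated.max()) if len(validated) else None
    return selected, diag
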