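"""Signature extraction and exposure refitting.

A catalogue matrix V (classes x samples) is factorised as V ~ S.E with S a
column-stochastic signature matrix and E the per-sample exposures, using
non-negative matrix factorisation with multiplicative (Frobenius) updates
and multiple random restarts.  Extracted signatures are matched to a
reference set by cosine similarity.  Per-sample exposures are estimated by
quadratic programming on the probability simplex, then signatures
contributing less than a threshold proportion (default 10%) are dropped and
the remaining signatures refit, iterated to a fixed point.

The same machinery serves 96-class substitution catalogues and 32-class
rearrangement catalogues: nothing here assumes a particular alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.decomposition import NMF

logger = logging.getLogger(__name__)


@dataclass
class SignatureModel:
    """Column-stochastic signatures plus count-scale exposures.

    ``signatures`` is m x k with each column summing to 1; ``exposures`` is
    k x n with column j summing to the total classified events of sample j.
    """

    class_labels: Sequence[str]
    signatures: np.ndarray
    exposures: np.ndarray
    reconstruction_error: float
    sample_ids: Sequence[str] = field(default_factory=list)
    signature_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.signature_ids:
            self.signature_ids = [f"S{i + 1}" for i in range(self.signatures.shape[1])]

    @property
    def k(self) -> int:
        return self.signatures.shape[1]

    def signatures_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.signatures, index=list(self.class_labels), columns=list(self.signature_ids)
        )

    def exposures_frame(self) -> pd.DataFrame:
        cols = list(self.sample_ids) if len(self.sample_ids) else None
        return pd.DataFrame(self.exposures, index=list(self.signature_ids), columns=cols)


@dataclass(frozen=True)
class SignatureMatch:
    """Best reference match for one extracted signature."""

    extracted_id: str
    reference_id: str
    cosine: float


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two non-negative vectors, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def extract_signatures(
    catalogues: np.ndarray | pd.DataFrame,
    k: int,
    n_restarts: int = 200,
    seed: int = 0,
    max_iter: int = 10_000,
    tol: float = 1e-6,
    class_labels: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> SignatureModel:
    """De-novo NMF signature extraction with random restarts.

    Runs ``n_restarts`` multiplicative-update factorisations from seeded
    random initialisations and keeps the one with the lowest Frobenius
    reconstruction error.  Signature columns are normalised to sum to 1 with
    the scale absorbed into exposures; exposures are then refit per sample
    by :func:`fit_exposures` so per-sample totals are conserved exactly.
    Deterministic for a fixed ``seed``.
    """
    if isinstance(catalogues, pd.DataFrame):
        class_labels = class_labels or list(catalogues.index)
        sample_ids = sample_ids or list(catalogues.columns)
        V = catalogues.to_numpy(dtype=float)
    else:
        V = np.asarray(catalogues, dtype=float)
    m, n = V.shape
    if k < 1 or k > min(m, n):
        raise ValueError(f"rank k={k} outside [1, min(m, n)={min(m, n)}]")
    if (V < 0).any():
        raise ValueError("catalogue counts must be non-negative")
    if not (V.sum(axis=0) > 0).any():
        raise ValueError("all-zero catalogue matrix")

    rng = np.random.default_rng(seed)
    best_err = np.inf
    best_W = best_H = None
    for _ in range(n_restarts):
        rs = int(rng.integers(0, 2**31 - 1))
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=max_iter,
            tol=tol,
            random_state=rs,
        )
        W = model.fit_transform(V)
        H = model.components_
        err = float(np.linalg.norm(V - W @ H))
        if err < best_err:
            best_err, best_W, best_H = err, W, H

    colsums = best_W.sum(axis=0)
    colsums[colsums == 0] = 1.0
    S = best_W / colsums
    # QP refit conserves per-sample totals exactly (raw NMF H does not)
    E = np.column_stack([fit_exposures(V[:, j], S) for j in range(n)])
    return SignatureModel(
        class_labels=list(class_labels) if class_labels else [f"c{i}" for i in range(m)],
        signatures=S,
        exposures=E,
        reconstruction_error=best_err,
        sample_ids=list(sample_ids) if sample_ids else [f"sample{j}" for j in range(n)],
    )


def rank_survey(
    catalogues: np.ndarray | pd.DataFrame,
    k_range: Sequence[int],
    n_restarts: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Reconstruction error and restart stability over a range of ranks.

    Stability is the mean silhouette (cosine distance) of restart signatures
    clustered into k groups — high when restarts keep finding the same
    signatures.  The rank choice is left to the user.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    V = catalogues.to_numpy(dtype=float) if isinstance(catalogues, pd.DataFrame) else np.asarray(catalogues, dtype=float)
    rows = []
    rng = np.random.default_rng(seed)
    for k in k_range:
        sigs = []
        errs = []
        for _ in range(n_restarts):
            rs = int(rng.integers(0, 2**31 - 1))
            model = NMF(n_components=k, init="random", solver="mu", beta_loss="frobenius",
                        max_iter=2000, tol=1e-5, random_state=rs)
            W = model.fit_transform(V)
            errs.append(float(np.linalg.norm(V - W @ model.components_)))
            W = W / np.maximum(W.sum(axis=0), 1e-12)
            sigs.append(W.T)
        X = np.vstack(sigs)
        X = X / np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-12)
        if k == 1:
            sil = 1.0
        else:
            labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
            sil = float(silhouette_score(X, labels, metric="cosine"))
        rows.append({"k": k, "best_error": min(errs), "mean_error": float(np.mean(errs)),
                     "silhouette": sil})
    return pd.DataFrame(rows)


def match_to_reference(
    model: SignatureModel,
    reference: np.ndarray | pd.DataFrame,
    reference_ids: Sequence[str] | None = None,
) -> list[SignatureMatch]:
    """Best cosine-similarity reference match per extracted signature.

    Ties break to the lowest reference index (logged).  Reference columns
    must share the model's class alphabet and ordering.
    """
    if isinstance(reference, pd.DataFrame):
        if list(reference.index) != list(model.class_labels):
            raise ValueError("reference class alphabet/order does not match the model")
        reference_ids = reference_ids or list(reference.columns)
        R = reference.to_numpy(dtype=float)
    else:
        R = np.asarray(reference, dtype=float)
        if R.shape[0] != len(model.class_labels):
            raise ValueError("reference class alphabet length does not match the model")
    if reference_ids is None:
        reference_ids = [f"R{i + 1}" for i in range(R.shape[1])]
    matches = []
    for i, sid in enumerate(model.signature_ids):
        cosines = np.array([cosine_similarity(model.signatures[:, i], R[:, r]) for r in range(R.shape[1])])
        best = int(np.argmax(cosines))  # argmax takes the first (lowest index) on ties
        if (cosines == cosines[best]).sum() > 1:
            logger.info("cosine tie for %s; keeping lowest reference index %s", sid, reference_ids[best])
        matches.append(SignatureMatch(extracted_id=sid, reference_id=reference_ids[best],
                                      cosine=float(cosines[best])))
    return matches


def fit_exposures(catalogue_column: np.ndarray, signatures: np.ndarray) -> np.ndarray:
    """Quadratic-programming exposure refit for one sample.

    Solves min ||v/T - S.w||^2 subject to w >= 0, sum(w) = 1 (T the sample
    total) and returns w*T, i.e. mutation counts attributed per signature.
    """
    v = np.asarray(catalogue_column, dtype=float)
    S = np.asarray(signatures, dtype=float)
    if S.ndim != 2 or S.shape[1] == 0:
        raise ValueError("empty signature set")
    if S.shape[0] != v.shape[0]:
        raise ValueError("catalogue and signature alphabets differ in length")
    k = S.shape[1]
    T = v.sum()
    if T == 0:
        return np.zeros(k)
    b = v / T
    StS = S.T @ S
    Stb = S.T @ b

    def objective(w):
        r = S @ w - b
        return float(r @ r)

    def grad(w):
        return 2.0 * (StS @ w - Stb)

    w0 = np.full(k, 1.0 / k)
    res = optimize.minimize(
        objective,
        w0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones_like(w)}],
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    s = w.sum()
    if s == 0:
        raise ValueError("degenerate QP solution (all-zero weights)")
    w /= s
    return w * T


def prune_and_reassign(
    exposures: np.ndarray,
    catalogue_column: np.ndarray,
    signatures: np.ndarray,
    threshold: float = 0.10,
) -> np.ndarray:
    """Drop signatures below ``threshold`` of the sample total and refit.

    Iterates drop-and-refit until every surviving signature carries at
    least ``threshold`` of the total or a single signature remains; dropped
    signatures get exposure 0 and the sample total is preserved.
    """
    w = np.asarray(exposures, dtype=float).copy()
    v = np.asarray(catalogue_column, dtype=float)
    S = np.asarray(signatures, dtype=float)
    T = v.sum()
    if T == 0:
        return np.zeros_like(w)
    active = np.arange(S.shape[1])
    for _pass in range(S.shape[1]):
        props = w[active] / T
        below = props < threshold
        if not below.any() or len(active) == 1:
            break
        keep = active[~below]
        if len(keep) == 0:  # keep the single largest contributor
            keep = active[[int(np.argmax(w[active]))]]
        logger.info("prune pass %d: dropping %d signature(s)", _pass + 1, len(active) - len(keep))
        active = keep
        w = np.zeros_like(w)
        w[active] = fit_exposures(v, S[:, active])
    return w


def refit_cohort(
    catalogues: np.ndarray | pd.DataFrame,
    signatures: np.ndarray | pd.DataFrame,
    prune_threshold: float | None = 0.10,
) -> np.ndarray:
    """QP-refit (and optionally prune) exposures for every sample column."""
    V = catalogues.to_numpy(dtype=float) if isinstance(catalogues, pd.DataFrame) else np.asarray(catalogues, dtype=float)
    S = signatures.to_numpy(dtype=float) if isinstance(signatures, pd.DataFrame) else np.asarray(signatures, dtype=float)
    cols = []
    for j in range(V.shape[1]):
        w = fit_exposures(V[:, j], S)
        if prune_threshold is not None:
            w = prune_and_reassign(w, V[:, j], S, threshold=prune_threshold)
        cols.append(w)
    return np.column_stack(cols)
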