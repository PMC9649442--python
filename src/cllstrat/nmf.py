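"""Genomic-subgroup discovery by offset non-negative matrix factorization.

The binary feature matrix of each IGHV stratum (the genomic alterations plus
binarized percent germline identity, age and sex) is factorized as
V ~ W H + b 1^T, where the nonnegative offset b absorbs features shared by
every patient so the basis columns W (the genomic signatures, GS) capture
subgroup-specific structure. Fitting minimizes the generalized
Kullback–Leibler divergence with multiplicative updates, which never
increase the objective.

The number of subgroups is chosen by consensus clustering: many random
restarts per candidate rank, a patient co-assignment consensus matrix, and
its cophenetic correlation coefficient; the same statistic on randomized
data guards against overfitting. Signatures are the max-normalized basis
columns, with defining features at normalized weight >= 0.5. Patients are
assigned by deconvolution — forward selection of the signature combination
that best reconstructs the patient's feature vector — and the resulting
signature proportions can be refined with a Gaussian-mixture clustering
selected by BIC at maximal parsimony.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.optimize import linear_sum_assignment, nnls
from scipy.spatial.distance import squareform
from sklearn.mixture import GaussianMixture

_EPS = np.finfo(float).tiny


@dataclass
class NMFModel:
    W: np.ndarray            # features x k
    H: np.ndarray            # k x patients
    offset: np.ndarray       # per-feature
    k: int
    final_objective: float
    objective_trace: list[float]
    seed: int
    feature_ids: list[str]
    patient_ids: list[str]

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H + self.offset[:, None]


def _kl_divergence(V: np.ndarray, Lam: np.ndarray) -> float:
    Lam = np.maximum(Lam, _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(V > 0, V * np.log(V / Lam), 0.0)
    return float(np.sum(term - V + Lam))


def fit_nmf_offset(
    V: np.ndarray | pd.DataFrame,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    feature_ids: Optional[Sequence[str]] = None,
    patient_ids: Optional[Sequence[str]] = None,
) -> NMFModel:
    """Fit V ~ W H + offset·1^T (features x patients) under KL divergence.

    Multiplicative updates for W, H and the offset; iteration stops when the
    relative objective change drops below ``tol`` or at ``max_iter``.
    All-zero feature rows are dropped with a warning (their updates are
    degenerate) and reported with zero weight and offset.
    """
    if isinstance(V, pd.DataFrame):
        feature_ids = list(V.index)
        patient_ids = list(V.columns)
        V = V.to_numpy(dtype=float)
    else:
        V = np.asarray(V, dtype=float)
        feature_ids = list(feature_ids) if feature_ids else [f"f{i}" for i in range(V.shape[0])]
        patient_ids = list(patient_ids) if patient_ids else [f"p{j}" for j in range(V.shape[1])]
    if np.any(V < 0):
        raise ValueError("V must be nonnegative")
    if not 1 <= k < min(V.shape):
        raise ValueError("rank k must satisfy 1 <= k < min(V.shape)")

    zero_rows = np.where(V.sum(axis=1) == 0)[0]
    if zero_rows.size:
        warnings.warn(f"{zero_rows.size} all-zero feature rows dropped from the fit",
                      stacklevel=2)
    active = np.setdiff1d(np.arange(V.shape[0]), zero_rows)
    Va = V[active]
    F, N = Va.shape

    rng = np.random.default_rng(seed)
    W = rng.uniform(0.1, 1.0, size=(F, k))
    H = rng.uniform(0.1, 1.0, size=(k, N))
    b = rng.uniform(0.01, 0.1, size=F)

    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        Lam = np.maximum(W @ H + b[:, None], _EPS)
        R = Va / Lam
        W *= (R @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        Lam = np.maximum(W @ H + b[:, None], _EPS)
        R = Va / Lam
        H *= (W.T @ R) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        Lam = np.maximum(W @ H + b[:, None], _EPS)
        R = Va / Lam
        b *= R.sum(axis=1) / N
        obj = _kl_divergence(Va, np.maximum(W @ H + b[:, None], _EPS))
        trace.append(obj)
        if prev - obj < tol * max(abs(prev), 1.0) and len(trace) > 1:
            break
        prev = obj

    W_full = np.zeros((V.shape[0], k))
    b_full = np.zeros(V.shape[0])
    W_full[active] = W
    b_full[active] = b
    return NMFModel(
        W=W_full, H=H, offset=b_full, k=k,
        final_objective=trace[-1], objective_trace=trace,
        seed=seed, feature_ids=feature_ids, patient_ids=patient_ids,
    )


@dataclass
class RankEstimate:
    k_grid: list[int]
    cophenetic: dict[int, float]
    cophenetic_randomized: dict[int, float]
    consensus_matrices: dict[int, np.ndarray]


def _consensus_cophenetic(labels_per_run: list[np.ndarray]) -> tuple[float, np.ndarray]:
    n = labels_per_run[0].size
    consensus = np.zeros((n, n))
    for labels in labels_per_run:
        consensus += (labels[:, None] == labels[None, :]).astype(float)
    consensus /= len(labels_per_run)
    np.fill_diagonal(consensus, 1.0)
    dist = 1.0 - consensus
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0] if condensed.size else 0.0):
        return float("nan"), consensus  # zero-variance distances: undefined
    link = average(condensed)
    coph, _ = cophenet(link, condensed)
    return float(coph), consensus


def _run_labels(V: np.ndarray, k: int, seed: int) -> np.ndarray:
    model = fit_nmf_offset(V, k, seed=seed)
    # ties broken toward the lowest signature index by argmax
    return np.argmax(model.H, axis=0)


def estimate_rank(
    V: np.ndarray | pd.DataFrame,
    k_min: int = 2,
    k_max: int = 6,
    n_runs: int = 30,
    seed: int = 0,
    randomized: bool = True,
) -> RankEstimate:
    """Consensus-clustering rank estimation.

    Per candidate rank: ``n_runs`` random restarts; patients co-assigned by
    the argmax of H; consensus matrix averaged over runs; cophenetic
    correlation between consensus distances and their average-linkage
    hierarchical representation. The same statistic is computed on data with
    each feature's values permuted across patients (randomized control).
    k = 1 yields an all-ones consensus and is reported as NaN.
    """
    if isinstance(V, pd.DataFrame):
        V = V.to_numpy(dtype=float)
    V = np.asarray(V, dtype=float)
    if n_runs < 10:
        raise ValueError("need at least 10 restarts per rank")
    if k_max >= V.shape[1]:
        raise ValueError("k_max must be below the number of patients")
    rng = np.random.default_rng(seed)
    V_rand = np.array([rng.permutation(row) for row in V]) if randomized else None

    k_grid = list(range(k_min, k_max + 1))
    coph: dict[int, float] = {}
    coph_rand: dict[int, float] = {}
    consensus: dict[int, np.ndarray] = {}
    seeds = rng.integers(0, 2**31 - 1, size=(len(k_grid), n_runs, 2))
    for i, k in enumerate(k_grid):
        if k == 1:
            coph[k] = float("nan")
            consensus[k] = np.ones((V.shape[1], V.shape[1]))
            continue
        labels = [_run_labels(V, k, int(seeds[i, r, 0])) for r in range(n_runs)]
        coph[k], consensus[k] = _consensus_cophenetic(labels)
        if randomized:
            labels_r = [_run_labels(V_rand, k, int(seeds[i, r, 1])) for r in range(n_runs)]
            coph_rand[k], _ = _consensus_cophenetic(labels_r)
    return RankEstimate(k_grid, coph, coph_rand, consensus)


def select_rank(estimate: RankEstimate) -> int:
    """Rank with the highest cophenetic coefficient; ties to the smallest k."""
    valid = {k: v for k, v in estimate.cophenetic.items() if np.isfinite(v)}
    if not valid:
        raise ValueError("no rank with a defined cophenetic coefficient")
    best = max(valid.values())
    return min(k for k, v in valid.items() if v >= best - 1e-12)


@dataclass
class GenomicSignature:
    label: str
    feature_weights: pd.Series          # max-normalized, in [0, 1]
    defining_features: list[str]
    empty: bool = False


def extract_signatures(
    model: NMFModel, cutoff: float = 0.5, stratum: str = "u"
) -> list[GenomicSignature]:
    """Max-normalize basis columns and threshold defining features.

    Signatures are labelled ``{stratum}-GS{i}`` in order of decreasing total
    patient load (row sums of H). An empty defining set is retained and
    flagged.
    """
    load_order = np.argsort(-model.H.sum(axis=1), kind="stable")
    sigs: list[GenomicSignature] = []
    for rank_i, col in enumerate(load_order, start=1):
        w = model.W[:, col].astype(float)
        peak = w.max()
        norm = w / peak if peak > 0 else w
        weights = pd.Series(norm, index=model.feature_ids)
        defining = [f for f, v in weights.items() if v >= cutoff]
        sigs.append(
            GenomicSignature(
                label=f"{stratum}-GS{rank_i}",
                feature_weights=weights,
                defining_features=defining,
                empty=not defining,
            )
        )
    return sigs


@dataclass
class SubgroupAssignment:
    patient: str
    proportions: pd.Series  # per-signature, sums to 1
    label: str
    flagged: bool = False
    cluster: Optional[int] = None


def deconvolve_sample(
    x: np.ndarray | pd.Series,
    signatures: Sequence[GenomicSignature],
    patient: str = "",
    improvement_tol: float = 1e-3,
    min_weight: float = 0.06,
) -> SubgroupAssignment:
    """Assign a patient by forward-selection reconstruction.

    Signature profiles and the patient vector are normalized to unit sum;
    signatures are added greedily, refitting nonnegative least squares over
    the selected set, while the sum-of-squares reconstruction error improves
    by more than ``improvement_tol``. Signatures contributing less than
    ``min_weight`` of the total are discarded and the weights renormalized
    to proportions. An all-zero patient vector yields uniform proportions,
    flagged.
    """
    if not signatures:
        raise ValueError("no signatures supplied")
    S = np.column_stack([s.feature_weights.to_numpy(dtype=float) for s in signatures])
    S = S / np.maximum(S.sum(axis=0), _EPS)
    labels = [s.label for s in signatures]
    x = np.asarray(x, dtype=float)
    if x.shape[0] != S.shape[0]:
        raise ValueError("patient vector not aligned to signature feature space")
    total = x.sum()
    if total == 0:
        props = pd.Series(np.full(len(labels), 1.0 / len(labels)), index=labels)
        return SubgroupAssignment(patient, props, labels[0], flagged=True)
    xn = x / total

    chosen: list[int] = []
    err = float(np.sum(xn**2))
    weights = np.zeros(len(labels))
    while len(chosen) < len(labels):
        best_err, best_j, best_w = err, None, None
        for j in range(len(labels)):
            if j in chosen:
                continue
            cols = chosen + [j]
            w, residual = nnls(S[:, cols], xn)
            sse = residual**2
            if sse < best_err - improvement_tol:
                best_err, best_j, best_w = sse, j, w
        if best_j is None:
            break
        chosen.append(best_j)
        err = best_err
        weights = np.zeros(len(labels))
        weights[chosen] = best_w

    if weights.sum() == 0:
        props = pd.Series(np.full(len(labels), 1.0 / len(labels)), index=labels)
        return SubgroupAssignment(patient, props, labels[0], flagged=True)
    frac = weights / weights.sum()
    frac[frac < min_weight] = 0.0
    if frac.sum() == 0:
        frac = weights / weights.sum()
    frac = frac / frac.sum()
    props = pd.Series(frac, index=labels)
    return SubgroupAssignment(patient, props, str(props.idxmax()))


def assign_cohort(
    V: pd.DataFrame, signatures: Sequence[GenomicSignature]
) -> list[SubgroupAssignment]:
    """Deconvolve every patient column of a features x patients matrix."""
    return [
        deconvolve_sample(V[p].to_numpy(dtype=float), signatures, patient=str(p))
        for p in V.columns
    ]


def cluster_assignments(
    proportions: pd.DataFrame,
    max_components: int = 8,
    seed: int = 0,
    bic_tolerance: float = 2.0,
) -> pd.Series:
    """Gaussian-mixture clustering of signature proportions.

    Component counts 1..``max_components`` are fitted; the selected model is
    the most parsimonious (fewest components) within ``bic_tolerance`` BIC
    units of the optimum. Singular covariances are handled by sklearn's
    covariance regularization. Degenerate inputs (fewer distinct rows than
    components) fall back to one cluster with a warning.
    """
    if len(proportions) < 2:
        raise ValueError("need at least two patients to cluster")
    X = proportions.to_numpy(dtype=float)
    n_unique = np.unique(X, axis=0).shape[0]
    upper = min(max_components, n_unique, len(X) - 1)
    if upper < 1:
        warnings.warn("degenerate proportion matrix; single cluster returned", stacklevel=2)
        return pd.Series(np.zeros(len(X), dtype=int), index=proportions.index)
    bics: dict[int, float] = {}
    models: dict[int, GaussianMixture] = {}
    for n in range(1, upper + 1):
        gm = GaussianMixture(
            n_components=n, covariance_type="full", reg_covar=1e-6,
            random_state=seed, n_init=3,
        ).fit(X)
        bics[n] = gm.bic(X)
        models[n] = gm
    best = min(bics.values())
    n_sel = min(n for n, b in bics.items() if b <= best + bic_tolerance)
    return pd.Series(models[n_sel].predict(X), index=proportions.index, name="cluster")


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(a @ b / (na * nb))


def match_signatures(
    sigs_a: Sequence[GenomicSignature], sigs_b: Sequence[GenomicSignature]
) -> tuple[dict[str, str], float]:
    """Optimal (Hungarian) matching of two signature sets by cosine
    similarity; returns the label mapping a -> b and the mean matched
    similarity."""
    A = np.column_stack([s.feature_weights.to_numpy() for s in sigs_a])
    B = np.column_stack([s.feature_weights.to_numpy() for s in sigs_b])
    sim = np.zeros((A.shape[1], B.shape[1]))
    for i in range(A.shape[1]):
        for j in range(B.shape[1]):
            sim[i, j] = cosine_similarity(A[:, i], B[:, j])
    rows, cols = linear_sum_assignment(-sim)
    mapping = {sigs_a[i].label: sigs_b[j].label for i, j in zip(rows, cols)}
    return mapping, float(sim[rows, cols].mean())


@dataclass
class ValidationResult:
    confusion: pd.DataFrame   # full-data label x predicted label, test samples
    agreement: int
    n_test: int
    signature_similarity: float
    test_patients: list[str] = field(default_factory=list)


def split_validate(
    V: pd.DataFrame,
    k: int,
    seed: int = 0,
    train_frac: float = 0.8,
    n_test: Optional[int] = None,
    stratum: str = "u",
    n_restarts: int = 5,
) -> ValidationResult:
    """Hold-out agreement between training-based and full-data assignment.

    ``V`` is features x patients. A random hold-out set (size
    ``n_test`` if given, else the 1 - ``train_frac`` fraction) is removed;
    offset NMF at rank ``k`` is fitted on the remaining patients (best of
    ``n_restarts`` restarts by final objective) and, separately, on the full
    matrix; training signatures are matched to the full-data signatures by
    Hungarian cosine matching; every patient is assigned under both models
    by deconvolution, and the confusion matrix of the held-out patients'
    labels is returned along with the agreement count.
    """
    patients = list(V.columns)
    if n_test is None:
        n_test = int(round(len(patients) * (1.0 - train_frac)))
    if len(patients) - n_test < 5:
        raise ValueError("training stratum too small after hold-out")
    rng = np.random.default_rng(seed)
    test_idx = rng.choice(len(patients), size=n_test, replace=False)
    test = [patients[i] for i in sorted(test_idx)]
    train = [p for p in patients if p not in set(test)]

    def _best_fit(M: pd.DataFrame, base_seed: int) -> NMFModel:
        fits = [
            fit_nmf_offset(M, k, seed=base_seed + r) for r in range(n_restarts)
        ]
        return min(fits, key=lambda m: m.final_objective)

    full_model = _best_fit(V, int(rng.integers(0, 2**30)))
    train_model = _best_fit(V[train], int(rng.integers(0, 2**30)))
    full_sigs = extract_signatures(full_model, stratum=stratum)
    train_sigs = extract_signatures(train_model, stratum=stratum)
    mapping, sim = match_signatures(train_sigs, full_sigs)

    full_labels = {a.patient: a.label for a in assign_cohort(V, full_sigs)}
    pred_labels = {
        a.patient: mapping[a.label] for a in assign_cohort(V, train_sigs)
    }
    labels = sorted({s.label for s in full_sigs})
    confusion = pd.DataFrame(0, index=labels, columns=labels)
    agreement = 0
    for p in test:
        confusion.loc[full_labels[p], pred_labels[p]] += 1
        agreement += int(full_labels[p] == pred_labels[p])
    return ValidationResult(confusion, agreement, n_test, sim, test)
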