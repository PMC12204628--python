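"""Individual cluster-membership (Q) matrices and K selection.

Three producers and one consumer:

* :func:`em_admixture` — maximum-likelihood admixture clustering by EM on
  the standard admixture likelihood (each allele copy of an individual is
  drawn from a cluster chosen by the individual's membership vector, with
  cluster-specific allele frequencies).  A fast, deterministic
  point-estimate counterpart of MCMC admixture samplers.
* :func:`dapc_cluster` — a discriminant-analysis-of-principal-components
  style clusterer: one-hot allele dosages, centred PCA, k-means over a K
  range scored by BIC, then a linear discriminant step that converts the
  k-means partition into per-individual posterior memberships.
* :func:`hierarchical_cluster` — recursive clustering with the stopping
  rules used for nested population structure: stop when all samples share
  one sampling location, when the mean best-cluster assignment of a run
  drops below 80%, or when fewer than ten individuals remain.
* :func:`read_q_matrix` — ingestion of externally produced Q-matrices
  (plain TSV, CLUMPP-style rows, or a STRUCTURE output file's inferred-
  ancestry block), so genuine MCMC runs can feed the connectivity stage.

:func:`select_k_evanno` implements the second-order rate of change of the
log-likelihood (delta-K) over replicate runs; :func:`amu_prevalence`
averages memberships per management unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from amupopgen.io import GenotypeTable

logger = logging.getLogger(__name__)

MEMBERSHIP_SUM_TOL = (0.99, 1.01)


@dataclass
class QMatrix:
    """Per-individual cluster membership proportions from one method."""

    individual_ids: list[str]
    memberships: np.ndarray  # (n, K)
    method: str
    loglik: float | None = None
    run_seed: int | None = None
    cluster_freqs: list[np.ndarray] | None = None  # per locus (K, n_alleles)

    def __post_init__(self) -> None:
        self.memberships = np.asarray(self.memberships, dtype=float)
        if self.memberships.ndim != 2 or self.memberships.shape[0] != len(self.individual_ids):
            raise ValueError("memberships must be (n_individuals, K)")
        sums = self.memberships.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("membership rows must sum to 1 within 1e-6")

    @property
    def K(self) -> int:
        return self.memberships.shape[1]

    def modal_cluster(self) -> np.ndarray:
        """Hard assignment to the highest-membership cluster (ties -> lowest index)."""
        return self.memberships.argmax(axis=1)

    def mean_assignment(self) -> float:
        """Mean over individuals of the maximum membership."""
        return float(self.memberships.max(axis=1).mean())


@dataclass
class KSelectionReport:
    """Replicate log-likelihoods (or BIC) per K and the chosen K."""

    table: pd.DataFrame  # columns K, mean, sd, delta_k (or K, bic)
    chosen_k: int | None
    criterion: str  # "evanno" or "bic"
    no_structure_signal: bool = False


# ---------------------------------------------------------------------------
# EM admixture
# ---------------------------------------------------------------------------

def _encode_alleles(table: GenotypeTable) -> tuple[list[np.ndarray], list[int]]:
    """Per locus: (n, 2) allele-index array with -1 for missing, and allele counts."""
    encoded = []
    n_alleles = []
    for j in range(table.n_loci):
        col = table.calls[:, j, :]
        typed = (col > 0).all(axis=1)
        alleles = np.unique(col[typed].ravel())
        lut = {a: i for i, a in enumerate(alleles.tolist())}
        idx = np.full(col.shape, -1, dtype=np.int64)
        for a, i in lut.items():
            idx[col == a] = i
        idx[~typed] = -1
        encoded.append(idx)
        n_alleles.append(len(alleles))
    return encoded, n_alleles


def em_admixture(
    table: GenotypeTable,
    K: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> QMatrix:
    """EM point estimate of the admixture model with independent frequencies.

    The log-likelihood is non-decreasing across iterations; convergence is
    declared when its gain drops below ``tol``.  ``seed`` controls the
    random initialisation, so replicate runs with different seeds probe
    different local optima.
    """
    n = table.n_individuals
    if K < 1:
        raise ValueError("K must be at least 1")
    distinct = len({tuple(row.ravel()) for row in table.calls})
    if K > distinct:
        raise ValueError(
            f"K={K} exceeds the {distinct} distinct multilocus genotypes (degenerate)"
        )
    encoded, n_alleles = _encode_alleles(table)
    if K == 1:
        q = np.ones((n, 1))
        loglik = 0.0
        for j in range(table.n_loci):
            idx = encoded[j]
            typed = idx >= 0
            if not typed.any():
                continue
            counts = np.bincount(idx[typed], minlength=n_alleles[j]).astype(float)
            p = counts / counts.sum()
            loglik += float(np.sum(np.log(p[idx[typed]])))
        return QMatrix(list(table.individual_ids), q, "em_admixture", loglik, seed)

    rng = np.random.default_rng(seed)
    q = rng.dirichlet(np.ones(K), size=n)
    freqs = [rng.dirichlet(np.ones(max(a, 1)), size=K) for a in n_alleles]

    prev_ll = -np.inf
    loglik = prev_ll
    for _ in range(max_iter):
        q_num = np.zeros((n, K))
        copies = np.zeros(n)
        new_freqs = [np.full((K, a), 1e-9) for a in n_alleles]
        loglik = 0.0
        for j in range(table.n_loci):
            idx = encoded[j]  # (n, 2)
            for copy in range(2):
                a_idx = idx[:, copy]
                typed = a_idx >= 0
                if not typed.any():
                    continue
                fk = freqs[j][:, a_idx[typed]].T  # (n_typed, K)
                w = q[typed] * fk
                tot = w.sum(axis=1, keepdims=True)
                tot[tot <= 0] = 1e-300
                loglik += float(np.sum(np.log(tot)))
                resp = w / tot
                q_num[typed] += resp
                copies[typed] += 1
                np.add.at(new_freqs[j].T, a_idx[typed], resp)
        copies[copies == 0] = 1
        q = q_num / copies[:, None]
        q = q / q.sum(axis=1, keepdims=True)
        for j in range(table.n_loci):
            new_freqs[j] /= new_freqs[j].sum(axis=1, keepdims=True)
        freqs = new_freqs
        if loglik - prev_ll < tol and np.isfinite(prev_ll):
            prev_ll = loglik
            break
        prev_ll = loglik
    return QMatrix(
        list(table.individual_ids), q, "em_admixture", prev_ll, seed, cluster_freqs=freqs
    )


def admixture_loglik(table: GenotypeTable, q: QMatrix) -> float:
    """Observed-data log-likelihood of a fitted admixture model.

    Invariant under any common permutation of the cluster indices of the
    membership matrix and the cluster allele frequencies.
    """
    if q.cluster_freqs is None:
        raise ValueError("QMatrix carries no cluster allele frequencies")
    encoded, _ = _encode_alleles(table)
    ll = 0.0
    for j in range(table.n_loci):
        idx = encoded[j]
        for copy in range(2):
            a_idx = idx[:, copy]
            typed = a_idx >= 0
            if not typed.any():
                continue
            fk = q.cluster_freqs[j][:, a_idx[typed]].T
            tot = (q.memberships[typed] * fk).sum(axis=1)
            ll += float(np.sum(np.log(np.maximum(tot, 1e-300))))
    return ll


def em_admixture_replicates(
    table: GenotypeTable,
    k_values: Sequence[int],
    n_replicates: int = 3,
    seed: int = 0,
    **kwargs,
) -> list[tuple[int, float, QMatrix]]:
    """Run ``n_replicates`` EM fits per K with distinct derived seeds."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=len(k_values) * n_replicates)
    out = []
    i = 0
    for k in k_values:
        for _ in range(n_replicates):
            q = em_admixture(table, k, seed=int(seeds[i]), **kwargs)
            out.append((k, q.loglik, q))
            i += 1
    return out


def select_k_evanno(runs: Sequence[tuple[int, float]]) -> KSelectionReport:
    """Delta-K selection over replicate log-likelihoods.

    ``runs`` is a flat list of (K, loglik) with at least 3 replicates per K
    over a contiguous K range.  Delta-K at interior K is
    ``|mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K))``; the chosen K
    maximises delta-K.  When every second difference is (numerically) zero
    — a featureless likelihood curve — no structure signal is reported.
    """
    df = pd.DataFrame(runs, columns=["K", "loglik"]) if not isinstance(runs, pd.DataFrame) else runs
    grouped = df.groupby("K")["loglik"]
    counts = grouped.count()
    if (counts < 3).any():
        bad = counts[counts < 3].index.tolist()
        raise ValueError(f"need >=3 replicates per K; too few at K={bad}")
    ks = sorted(counts.index)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K range must be contiguous")
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    rows = []
    scale = max(1.0, float(np.abs(mean).max()))
    second_diffs = []
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1]:
            d2 = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
            second_diffs.append(d2)
            if sd[k] > 0:
                dk = d2 / sd[k]
            else:
                logger.warning("Evanno: sd=0 at K=%d, delta-K undefined there", k)
        rows.append({"K": k, "mean": mean[k], "sd": sd[k], "delta_k": dk})
    table = pd.DataFrame(rows)
    no_signal = bool(second_diffs) and max(second_diffs) < 1e-9 * scale
    chosen = None
    if not no_signal and table["delta_k"].notna().any():
        chosen = int(table.loc[table["delta_k"].idxmax(), "K"])
    return KSelectionReport(table, chosen, "evanno", no_structure_signal=no_signal)


# ---------------------------------------------------------------------------
# DAPC-style clustering
# ---------------------------------------------------------------------------

def _dosage_matrix(table: GenotypeTable) -> np.ndarray:
    """One-hot allele dosage (0/1/2 copies per allele column); missing -> column mean."""
    blocks = []
    for j in range(table.n_loci):
        col = table.calls[:, j, :]
        typed = (col > 0).all(axis=1)
        alleles = np.unique(col[typed].ravel())
        if alleles.size == 0:
            continue
        block = np.zeros((table.n_individuals, alleles.size))
        for k, a in enumerate(alleles):
            block[:, k] = (col == a).sum(axis=1)
        if (~typed).any():
            means = block[typed].mean(axis=0)
            block[~typed] = means
        blocks.append(block)
    return np.concatenate(blocks, axis=1)


def dapc_cluster(
    table: GenotypeTable,
    k_range: Sequence[int] = range(1, 11),
    n_pcs: int | str = "auto",
    seed: int = 0,
) -> tuple[QMatrix, KSelectionReport]:
    """PCA + k-means with BIC K selection, then a discriminant step.

    The k-means partitioning and its BIC(K) = n ln(WSS/n) + K ln(n) are
    computed on the full principal-component space (retaining all PCs for
    the partitioning step is standard practice); the chosen K minimises
    BIC.  The discriminant step then works on the reduced space:
    ``n_pcs='auto'`` keeps the components explaining 90% of variance.  The
    linear-discriminant posterior over the k-means labels is the returned
    Q-matrix.
    """
    k_range = list(k_range)
    n = table.n_individuals
    if n < max(k_range):
        raise ValueError("more clusters requested than individuals")
    X = _dosage_matrix(table)
    X = X - X.mean(axis=0)
    rank = int(np.linalg.matrix_rank(X))
    pca = PCA(n_components=min(n - 1, X.shape[1]), random_state=seed)
    scores = pca.fit_transform(X)
    if n_pcs == "auto":
        cum = np.cumsum(pca.explained_variance_ratio_)
        keep = int(np.searchsorted(cum, 0.9) + 1)
    else:
        keep = int(n_pcs)
        if keep > rank:
            logger.warning("n_pcs=%d exceeds rank %d; reduced", keep, rank)
            keep = rank
    keep = max(1, min(keep, scores.shape[1]))

    rows = []
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        if k == 1:
            wss = float(np.sum(scores**2))
            labels_by_k[k] = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed)
            labels_by_k[k] = km.fit_predict(scores)
            wss = float(km.inertia_)
        wss = max(wss, 1e-12)
        rows.append({"K": k, "bic": n * np.log(wss / n) + k * np.log(n)})
    report_table = pd.DataFrame(rows)
    chosen = int(report_table.loc[report_table["bic"].idxmin(), "K"])
    report = KSelectionReport(report_table, chosen, "bic")

    labels = labels_by_k[chosen]
    if chosen == 1 or np.unique(labels).size == 1:
        q = np.ones((n, 1))
        return QMatrix(list(table.individual_ids), q, "dapc", run_seed=seed), report
    Z = scores[:, :keep]
    lda = LinearDiscriminantAnalysis()
    lda.fit(Z, labels)
    post = lda.predict_proba(Z)
    post = post / post.sum(axis=1, keepdims=True)
    return QMatrix(list(table.individual_ids), post, "dapc", run_seed=seed), report


# ---------------------------------------------------------------------------
# Hierarchical procedure
# ---------------------------------------------------------------------------

@dataclass
class ClusterNode:
    """One node of the hierarchical clustering tree."""

    individual_ids: list[str]
    qmatrix: QMatrix | None = None
    children: list["ClusterNode"] | None = None
    stop_reason: str | None = None

    def leaves(self) -> list["ClusterNode"]:
        if not self.children:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


def hierarchical_cluster(
    table: GenotypeTable,
    grouping: pd.DataFrame,
    clusterer: Callable[[GenotypeTable, int], QMatrix] | None = None,
    min_cluster_size: int = 10,
    min_mean_assignment: float = 0.8,
    seed: int = 0,
) -> ClusterNode:
    """Recursively cluster individuals with the three stopping rules.

    Recursion into a set of individuals stops when (1) all of them come
    from the same sampling location, (2) the clustering run on them assigns
    individuals to their best cluster with mean membership below
    ``min_mean_assignment`` (the low-confidence split is then discarded),
    or (3) fewer than ``min_cluster_size`` individuals remain.  Every
    individual ends up in exactly one leaf.

    The default clusterer is a two-cluster EM admixture fit.
    """
    if clusterer is None:
        def clusterer(sub: GenotypeTable, s: int) -> QMatrix:
            return em_admixture(sub, K=2, seed=s)

    amu_of = dict(zip(grouping["individual_id"], grouping["amu_code"]))
    rng = np.random.default_rng(seed)

    def recurse(ids: list[str]) -> ClusterNode:
        locations = {amu_of[i] for i in ids}
        if len(locations) <= 1:
            return ClusterNode(ids, stop_reason="single_location")
        if len(ids) < min_cluster_size:
            return ClusterNode(ids, stop_reason="too_small")
        sub = table.subset(ids)
        try:
            q = clusterer(sub, int(rng.integers(2**31)))
        except ValueError as exc:
            return ClusterNode(ids, stop_reason=f"clusterer_failed: {exc}")
        if q.mean_assignment() < min_mean_assignment:
            return ClusterNode(ids, qmatrix=q, stop_reason="low_assignment")
        hard = q.modal_cluster()
        children_ids = [
            [iid for iid, h in zip(ids, hard) if h == k] for k in range(q.K)
        ]
        children_ids = [c for c in children_ids if c]
        if len(children_ids) <= 1:
            return ClusterNode(ids, qmatrix=q, stop_reason="no_split")
        return ClusterNode(ids, qmatrix=q, children=[recurse(c) for c in children_ids])

    return recurse(list(table.individual_ids))


# ---------------------------------------------------------------------------
# External Q-matrices
# ---------------------------------------------------------------------------

def _normalise_rows(ids: list[str], rows: list[list[float]], method: str) -> QMatrix:
    arr = np.asarray(rows, dtype=float)
    sums = arr.sum(axis=1)
    bad = (sums < MEMBERSHIP_SUM_TOL[0]) | (sums > MEMBERSHIP_SUM_TOL[1])
    if bad.any():
        culprits = [ids[i] for i in np.flatnonzero(bad)]
        raise ValueError(
            f"membership rows sum outside {MEMBERSHIP_SUM_TOL}: {culprits}"
        )
    arr = arr / sums[:, None]
    return QMatrix(ids, arr, method)


def read_q_matrix(
    path: str | Path,
    dialect: str = "tsv",
    known_ids: Sequence[str] | None = None,
) -> QMatrix:
    """Read an externally produced Q-matrix.

    Dialects: ``tsv`` (header ``individual_id`` + K columns), ``clumpp``
    (rows ``id ... : q1 q2 ...``), ``structure_f`` (a STRUCTURE results
    file; the fixed-width "Inferred ancestry of individuals" block is
    located and parsed, label taken from the second column).
    Rows summing within [0.99, 1.01] are renormalised; anything further off
    is an error, as are ids absent from ``known_ids`` when given.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    ids: list[str] = []
    rows: list[list[float]] = []
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        ids = df.iloc[:, 0].astype(str).tolist()
        rows = df.iloc[:, 1:].to_numpy(dtype=float).tolist()
    elif dialect == "clumpp":
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if ":" in line:
                head, tail = line.split(":", 1)
                ids.append(head.split()[0])
                rows.append([float(v) for v in tail.split()])
            else:
                toks = line.split()
                ids.append(toks[0])
                rows.append([float(v) for v in toks[1:]])
    elif dialect == "structure_f":
        in_block = False
        for line in text.splitlines():
            if "Inferred ancestry of individuals" in line:
                in_block = True
                continue
            if in_block:
                stripped = line.strip()
                if not stripped:
                    if ids:
                        break
                    continue
                if stripped.lower().startswith("label"):
                    continue
                if ":" not in stripped:
                    break
                head, tail = stripped.split(":", 1)
                toks = head.split()
                if len(toks) < 2:
                    continue
                ids.append(toks[1])
                rows.append([float(v) for v in tail.split()])
        if not ids:
            raise ValueError(f"{path}: no 'Inferred ancestry' block found")
    else:
        raise ValueError(f"unknown Q-matrix dialect {dialect!r}")
    if known_ids is not None:
        unknown = [i for i in ids if i not in set(known_ids)]
        if unknown:
            raise ValueError(f"Q-matrix contains unknown individual ids: {unknown}")
    return _normalise_rows(ids, rows, f"external:{dialect}")


def write_q_matrix(q: QMatrix, path: str | Path) -> Path:
    """Write a Q-matrix as TSV (individual_id + K membership columns)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(q.memberships, columns=[f"q{k + 1}" for k in range(q.K)])
    df.insert(0, "individual_id", q.individual_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def amu_prevalence(q: QMatrix, grouping: pd.DataFrame) -> pd.DataFrame:
    """Mean membership vector (soft counts) per management unit.

    Rows index AMU codes, columns the K clusters; every row sums to 1.
    """
    amu_of = dict(zip(grouping["individual_id"], grouping["amu_code"]))
    missing = [i for i in q.individual_ids if i not in amu_of]
    if missing:
        raise ValueError(f"individuals without an AMU: {missing}")
    codes = [amu_of[i] for i in q.individual_ids]
    df = pd.DataFrame(q.memberships, columns=[f"q{k + 1}" for k in range(q.K)])
    df["amu_code"] = codes
    prev = df.groupby("amu_code", sort=False).mean()
    return prev
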