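"""Patient stratification by EM mixture modelling of cognitive profiles.

Patients with similar 11-dimensional impairment profiles are grouped with a
Gaussian mixture fitted by expectation-maximization, so that the scoring
criteria can look at what worked for *similar* patients.  The mixture uses
diagonal covariances with a quantization-aware variance floor (profiles are
stored as integers but treated as real-valued; see ``VARIANCE_FLOOR``),
k-means initialization from an explicit seed,
and soft assignment: each patient gets a posterior probability of belonging
to each cluster.

When the number of components is not given it is selected by 10-fold
cross-validated held-out log-likelihood, adding components while the mean
held-out log-likelihood keeps improving.  Every time a new patient enters
treatment the mixture is refitted on the full cohort including them.

The module follows the model/results idiom: ``ProfileMixture`` holds the
data and fit settings, ``ProfileMixture.fit()`` returns a
``ProfileMixtureResults`` carrying the estimates, the log-likelihood trace
and diagnostics, with ``assign`` and ``summary`` hanging off the results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .profile import CognitiveProfile
from .taxonomy import ABI_TAXONOMY, Taxonomy

#: Profiles are quantized to integer impairment levels, so per-dimension
#: component SDs below half a level carry no clinical meaning; they only let
#: EM place near-spike components on lattice values, which inflates
#: cross-validated likelihood and multiplies spurious clusters.  The floor is
#: therefore the squared quantization half-width, (1/2)^2.
VARIANCE_FLOOR = 0.25


@dataclass(frozen=True)
class ClusterAssignment:
    """Soft cluster membership of one patient."""

    patient_id: str
    cluster_index: int
    posterior: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.posterior) - 1.0) > 1e-9:
            raise ValueError("posterior responsibilities must sum to 1")
        if self.cluster_index != int(np.argmax(self.posterior)):
            raise ValueError("cluster_index must be the argmax of the posterior")


def _log_density(X: np.ndarray, weights, means, variances) -> np.ndarray:
    """Per-sample, per-component log of (weight x diagonal-Gaussian density)."""
    n, d = X.shape
    out = np.empty((n, len(weights)))
    for k in range(len(weights)):
        diff = X - means[k]
        out[:, k] = (
            np.log(weights[k])
            - 0.5 * (d * np.log(2 * np.pi) + np.log(variances[k]).sum())
            - 0.5 * (diff**2 / variances[k]).sum(axis=1)
        )
    return out


def _em(
    X: np.ndarray,
    k: int,
    seed: int,
    tol: float,
    max_iter: int,
    variance_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    """Run EM to convergence; returns (weights, means, variances, ll_trace, converged)."""
    n, d = X.shape
    if n < k:
        raise ValueError(f"cannot fit {k} components to {n} profiles")
    if k == 1:
        labels = np.zeros(n, dtype=int)
        centers = X.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k, n_init=3, random_state=seed).fit(X)
        labels, centers = km.labels_, km.cluster_centers_
    weights = np.bincount(labels, minlength=k).astype(float)
    weights = np.maximum(weights, 1e-3)
    weights /= weights.sum()
    means = centers.copy()
    variances = np.empty((k, d))
    for j in range(k):
        members = X[labels == j]
        variances[j] = members.var(axis=0) if len(members) else X.var(axis=0)
    variances = np.maximum(variances, variance_floor)

    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        log_joint = _log_density(X, weights, means, variances)
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(log_norm.sum())
        resp = np.exp(log_joint - log_norm[:, None])

        if trace and abs(ll - trace[-1]) <= tol * max(1.0, abs(trace[-1])):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)

        nk = resp.sum(axis=0) + 1e-12
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        variances = (resp.T @ X**2) / nk[:, None] - means**2
        variances = np.maximum(variances, variance_floor)
    return weights, means, variances, trace, converged


class ProfileMixture:
    """Gaussian mixture model over a cohort of cognitive profiles.

    Parameters
    ----------
    data : array-like of shape (n_patients, n_subfunctions)
        Impairment vectors in taxonomy order, treated as real-valued.
    patient_ids : sequence of str, optional
    taxonomy : Taxonomy
    variance_floor : float
        Lower bound applied to every per-dimension variance; keeps the
        11-dimensional fit stable on small, integer-valued cohorts.
    """

    def __init__(
        self,
        data,
        patient_ids: Sequence[str] | None = None,
        taxonomy: Taxonomy = ABI_TAXONOMY,
        variance_floor: float = VARIANCE_FLOOR,
    ) -> None:
        self.data = np.asarray(data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != taxonomy.n_subfunctions:
            raise ValueError(
                f"data must be (n, {taxonomy.n_subfunctions}), got {self.data.shape}"
            )
        if len(self.data) < 2:
            raise ValueError("need at least 2 profiles to fit a mixture")
        self.patient_ids = (
            list(patient_ids)
            if patient_ids is not None
            else [f"p{i}" for i in range(len(self.data))]
        )
        if len(self.patient_ids) != len(self.data):
            raise ValueError("patient_ids length does not match data")
        self.taxonomy = taxonomy
        self.variance_floor = variance_floor

    @classmethod
    def from_profiles(
        cls,
        profiles: Sequence[CognitiveProfile],
        patient_ids: Sequence[str] | None = None,
        **kwargs,
    ) -> "ProfileMixture":
        taxonomy = profiles[0].taxonomy
        X = np.vstack([p.as_vector() for p in profiles])
        return cls(X, patient_ids, taxonomy=taxonomy, **kwargs)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        taxonomy: Taxonomy = ABI_TAXONOMY,
        id_column: str = "patient_id",
        **kwargs,
    ) -> "ProfileMixture":
        """Build from a cohort table with one column per subfunction."""
        ids = df[id_column].astype(str).tolist() if id_column in df.columns else None
        X = df[list(taxonomy.subfunction_names)].to_numpy(dtype=float)
        return cls(X, ids, taxonomy=taxonomy, **kwargs)

    # -- model selection ----------------------------------------------------

    def cv_loglik(self, k: int, seed: int, n_folds: int = 10, tol: float = 1e-6,
                  max_iter: int = 200) -> float:
        """Mean held-out per-sample log-likelihood of a k-component fit."""
        n = len(self.data)
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        folds = np.array_split(order, min(n_folds, n))
        scores = []
        for i, fold in enumerate(folds):
            train = np.setdiff1d(order, fold)
            if len(train) < k:
                return -np.inf
            w, m, v, _, _ = _em(
                self.data[train], k, seed + 7919 * i + k, tol, max_iter, self.variance_floor
            )
            held = logsumexp(_log_density(self.data[fold], w, m, v), axis=1)
            scores.append(held.mean())
        return float(np.mean(scores))

    def select_k(self, seed: int = 0, k_max: int = 10, tol: float = 1e-6,
                 max_iter: int = 200) -> int:
        """Pick K by 10-fold CV: grow K while held-out log-likelihood improves."""
        best_k, best_score = 1, self.cv_loglik(1, seed, tol=tol, max_iter=max_iter)
        for k in range(2, min(k_max, len(self.data)) + 1):
            score = self.cv_loglik(k, seed, tol=tol, max_iter=max_iter)
            if score <= best_score + 1e-7:
                break
            best_k, best_score = k, score
        return best_k

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        k: int | None = None,
        seed: int = 0,
        tol: float = 1e-6,
        max_iter: int = 200,
    ) -> "ProfileMixtureResults":
        """Fit the mixture; ``k=None`` selects K by cross-validation."""
        if k is None:
            k = self.select_k(seed=seed, tol=tol, max_iter=max_iter)
        elif k < 1:
            raise ValueError("k must be >= 1")
        weights, means, variances, trace, converged = _em(
            self.data, k, seed, tol, max_iter, self.variance_floor
        )
        return ProfileMixtureResults(
            model=self,
            k=k,
            weights=weights,
            means=means,
            variances=variances,
            log_likelihood=trace[-1],
            ll_trace=tuple(trace),
            converged=converged,
            seed=seed,
        )


@dataclass
class ProfileMixtureResults:
    """Fitted mixture: estimates, log-likelihood trace and diagnostics."""

    model: ProfileMixture
    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    ll_trace: tuple[float, ...]
    converged: bool
    seed: int

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if (self.variances < self.model.variance_floor - 1e-12).any():
            raise ValueError("variances below the variance floor")

    # -- inference ----------------------------------------------------------

    def responsibilities(self, X) -> np.ndarray:
        """Posterior cluster probabilities for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        log_joint = _log_density(X, self.weights, self.means, self.variances)
        return np.exp(log_joint - logsumexp(log_joint, axis=1)[:, None])

    def predict(self, X) -> np.ndarray:
        return self.responsibilities(X).argmax(axis=1)

    def assign(
        self, profile: CognitiveProfile | np.ndarray, patient_id: str = "?"
    ) -> ClusterAssignment:
        """Assign one patient to a cluster with full posterior."""
        vec = profile.as_vector() if isinstance(profile, CognitiveProfile) else np.asarray(profile, float)
        if vec.shape != (self.means.shape[1],):
            raise ValueError(
                f"profile has dimension {vec.shape}, expected ({self.means.shape[1]},)"
            )
        post = self.responsibilities(vec)[0]
        return ClusterAssignment(patient_id, int(post.argmax()), tuple(float(p) for p in post))

    def assignments(self) -> list[ClusterAssignment]:
        """Cluster assignment for every patient in the training cohort."""
        post = self.responsibilities(self.model.data)
        return [
            ClusterAssignment(pid, int(row.argmax()), tuple(float(p) for p in row))
            for pid, row in zip(self.model.patient_ids, post)
        ]

    # -- reporting / persistence --------------------------------------------

    def summary(self) -> str:
        lines = [
            "Cognitive-profile mixture model",
            "=" * 64,
            f"components: {self.k}    patients: {len(self.model.data)}",
            f"log-likelihood: {self.log_likelihood:.3f}    "
            f"iterations: {len(self.ll_trace)}    converged: {self.converged}",
            "",
            f"{'cluster':>7} {'weight':>8}  mean impairment profile",
        ]
        names = self.model.taxonomy.subfunction_names
        lines.append(f"{'':>7} {'':>8}  " + " ".join(f"{n[:4]:>4}" for n in names))
        for j in range(self.k):
            vals = " ".join(f"{m:4.1f}" for m in self.means[j])
            lines.append(f"{j:>7} {self.weights[j]:>8.3f}  {vals}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "weights": self.weights.tolist(),
                "means": self.means.tolist(),
                "variances": self.variances.tolist(),
                "log_likelihood": self.log_likelihood,
                "converged": self.converged,
                "seed": self.seed,
            },
            indent=2,
        )

    @classmethod
    def from_json(
        cls, text: str, model: ProfileMixture | None = None
    ) -> "ProfileMixtureResults":
        d = json.loads(text)
        if model is None:
            # A 2-row placeholder satisfies the constructor; inference only
            # needs the parameter arrays.
            model = ProfileMixture(np.zeros((2, len(d["means"][0]))))
        return cls(
            model=model,
            k=d["k"],
            weights=np.asarray(d["weights"]),
            means=np.asarray(d["means"]),
            variances=np.asarray(d["variances"]),
            log_likelihood=d["log_likelihood"],
            ll_trace=(d["log_likelihood"],),
            converged=d["converged"],
            seed=d["seed"],
        )


def refit_with_patient(
    profiles: Sequence[CognitiveProfile],
    new_profile: CognitiveProfile,
    seed: int = 0,
    k: int | None = None,
    patient_ids: Sequence[str] | None = None,
    new_patient_id: str = "new",
) -> tuple[ProfileMixtureResults, ClusterAssignment]:
    """Refit the mixture on the cohort plus a newly arriving patient.

    Mirrors the running system's behaviour: clusters are recomputed every
    time a new patient starts treatment, then the new patient is assigned.
    """
    ids = list(patient_ids) if patient_ids is not None else [f"p{i}" for i in range(len(profiles))]
    all_profiles = list(profiles) + [new_profile]
    mixture = ProfileMixture.from_profiles(all_profiles, ids + [new_patient_id])
    results = mixture.fit(k=k, seed=seed)
    return results, results.assign(new_profile, new_patient_id)
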