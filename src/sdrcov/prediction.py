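"""Predicting the binding profile of a new domain from aligned neighbours.

Given a query sequence aligned to the training MSA, the baseline predictor
averages the training PWMs weighted by whole-sequence identity to the
query. The covariation-weighted predictor refines this per target peptide
site k: instead of counting every MSA column equally, columns are weighted
by their uncertainty coefficient with site k, so a domain that matches the
query exactly at the residues that covary with site k dominates the
average there even if it is globally dissimilar.

Both predictors are evaluated with a repeated left-out protocol: a random
fraction of domains is held out, covariation maps and similarities are
recomputed from the training rows only, and each held-out domain's
predicted profile is compared to its measured one by a per-site
root-mean-square error. Near-duplicate rows (>= 90% identity by default)
should be collapsed with :func:`remove_redundant` before splitting so the
same domain cannot sit in both sets.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import N_RESIDUES
from .covariation import CovariationMap, covariation_map
from .errors import InsufficientDataError, ParameterError, SdrcovError
from .io import DomainAlignment, ProfileSet
from .weighting import SequenceWeights, uniform_weights

logger = logging.getLogger(__name__)

METHODS = ("uniform_similarity", "covariation_weighted", "regression_tree")

#: largest possible per-site RMSE: two delta profiles on different residues
MAX_PROFILE_ERROR = float(np.sqrt(2.0 / N_RESIDUES))


@dataclasses.dataclass
class PredictedProfile:
    """A predicted binding profile for one query domain."""

    matrix: np.ndarray  # (w, 20)
    method: str
    per_site_error: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise SdrcovError("predicted profile site does not sum to 1")


@dataclasses.dataclass
class ValidationSummary:
    """Aggregate of a repeated left-out validation run."""

    repeats: int
    leftout_fraction: float
    seed: int
    method_mean: dict[str, float]
    method_std: dict[str, float]
    per_repeat: pd.DataFrame  # columns: repeat, method, mean_error, n_test


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of columns where both rows carry the same non-gap residue,
    over the full alignment length."""
    if len(seq_a) != len(seq_b):
        raise SdrcovError(
            f"aligned rows differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    matches = sum(1 for a, b in zip(seq_a, seq_b) if a == b and a != "-")
    return matches / len(seq_a)


def _encode_query(query: str, m: int) -> np.ndarray:
    from .io import DomainAlignment as _DA

    probe = _DA(ids=["query"], rows=[query])
    if probe.m != m:
        raise SdrcovError(
            f"query length {probe.m} does not match alignment width {m}"
        )
    return probe.codes()[0]


def predict_pwm_uniform(
    alignment: DomainAlignment, profiles: ProfileSet, query: str
) -> PredictedProfile:
    """Identity-weighted average of the training PWMs.

    If the query shares no residue with any training row, the average falls
    back to uniform weights 1/n.
    """
    if alignment.n < 1:
        raise InsufficientDataError("no training rows")
    sims = np.array([sequence_identity(query, row) for row in alignment.rows])
    if sims.sum() <= 0:
        sims = np.full(alignment.n, 1.0)
    sims = sims / sims.sum()
    matrix = np.einsum("i,ikr->kr", sims, profiles.matrices)
    matrix /= matrix.sum(axis=1, keepdims=True)
    return PredictedProfile(matrix=matrix, method="uniform_similarity")


def predict_pwm_covariation(
    alignment: DomainAlignment,
    profiles: ProfileSet,
    query: str,
    cov_map: CovariationMap,
) -> PredictedProfile:
    """Covariation-weighted profile prediction.

    For target site k the similarity between the query q and training row i
    is s_k(q, i) = sum_j UC(A_j, W_k) [q_j = A_ij] / sum_j UC(A_j, W_k),
    with filtered MSA sites contributing UC = 0. If every UC weight for
    some k is zero, that site falls back to the uniform-similarity
    predictor (logged).
    """
    q = _encode_query(query, alignment.m)
    codes = alignment.codes()
    uniform = None
    out = np.empty((profiles.w, N_RESIDUES))
    match = (codes == q) & (q >= 0)  # (n, m) residue agreement with query
    for k in range(1, profiles.w + 1):
        uc = cov_map.uc_site_weights(k, alignment.m)
        total = uc.sum()
        if total <= 0:
            if uniform is None:
                logger.info(
                    "all covariation weights zero for PWM site %d; "
                    "falling back to uniform similarity", k,
                )
                uniform = predict_pwm_uniform(alignment, profiles, query)
            out[k - 1] = uniform.matrix[k - 1]
            continue
        sims = match @ (uc / total)  # s_k(q, i) per training row
        if sims.sum() <= 0:
            sims = np.full(alignment.n, 1.0)
        sims = sims / sims.sum()
        col = sims @ profiles.matrices[:, k - 1, :]
        out[k - 1] = col / col.sum()
    return PredictedProfile(matrix=out, method="covariation_weighted")


def predict_pwm_regression_tree(*args, **kwargs):
    """Hook for a per-probability regression-tree predictor.

    Deliberately unimplemented: tree models were consistently outperformed
    by the weighted-average predictors on this task and are out of scope.
    """
    raise NotImplementedError(
        "the regression-tree predictor is a documented hook and is not "
        "implemented; use 'uniform_similarity' or 'covariation_weighted'"
    )


def prediction_error(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Per-site root-mean-square difference between two (w, 20) profiles:
    sqrt(mean over all w*20 entries of the squared difference)."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise SdrcovError(
            f"profile shapes differ: {predicted.shape} vs {actual.shape}"
        )
    return float(np.sqrt(np.mean((predicted - actual) ** 2)))


def remove_redundant(
    alignment: DomainAlignment,
    profiles: ProfileSet,
    threshold: float = 0.9,
) -> tuple[DomainAlignment, ProfileSet]:
    """Greedy near-duplicate removal in input order: a row is dropped when
    its identity to any already-kept row reaches ``threshold``; the paired
    PWM rows are dropped in tandem."""
    if not 0 < threshold <= 1:
        raise ParameterError("identity threshold must be in (0, 1]")
    kept: list[int] = []
    for i, row in enumerate(alignment.rows):
        if all(
            sequence_identity(row, alignment.rows[p]) < threshold for p in kept
        ):
            kept.append(i)
    return alignment.subset(kept), profiles.subset(kept)


def leave_out_validation(
    alignment: DomainAlignment,
    profiles: ProfileSet,
    leftout_fraction: float = 0.2,
    repeats: int = 100,
    methods: Sequence[str] = ("uniform_similarity", "covariation_weighted"),
    seed: int = 0,
    base: float = 20.0,
    uc_variant: str = "symmetric",
    weights: SequenceWeights | None = None,
) -> ValidationSummary:
    """Repeated random left-out validation.

    Each repeat holds out ``round(leftout_fraction * n)`` rows (at least 1);
    covariation maps and similarities are computed from the training rows
    only, every held-out row is predicted by each method, and the repeat's
    mean profile error per method is recorded. The summary reports the mean
    and standard deviation of these per-repeat means. Splits derive from
    per-repeat substreams of ``seed``, so repeats are independent and the
    whole run is reproducible.
    """
    if not 0 < leftout_fraction < 1:
        raise ParameterError("leftout_fraction must be in (0, 1)")
    if repeats < 1:
        raise ParameterError("repeats must be >= 1")
    for method in methods:
        if method not in METHODS:
            raise ParameterError(f"unknown prediction method {method!r}")
        if method == "regression_tree":
            predict_pwm_regression_tree()
    n = alignment.n
    if n < 3:
        raise InsufficientDataError(
            "left-out validation needs at least 3 rows after redundancy removal"
        )
    n_test = max(1, round(leftout_fraction * n))
    if n - n_test < 2:
        raise InsufficientDataError(
            f"leaving out {n_test} of {n} rows leaves fewer than 2 for training"
        )

    streams = np.random.SeedSequence(seed).spawn(repeats)
    records = []
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        test_idx = np.sort(rng.choice(n, size=n_test, replace=False))
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        train_aln = alignment.subset(train_idx)
        train_prof = profiles.subset(train_idx)
        train_w = (
            weights.subset(train_idx) if weights is not None
            else uniform_weights(train_idx.size)
        )
        cmap = None
        if "covariation_weighted" in methods:
            cmap = covariation_map(
                train_aln, train_prof, train_w, base=base, uc_variant=uc_variant
            )
        errors: dict[str, list[float]] = {m: [] for m in methods}
        for t in test_idx:
            query = alignment.rows[t]
            actual = profiles.matrices[t]
            for method in methods:
                if method == "uniform_similarity":
                    pred = predict_pwm_uniform(train_aln, train_prof, query)
                else:
                    pred = predict_pwm_covariation(train_aln, train_prof, query, cmap)
                errors[method].append(prediction_error(pred.matrix, actual))
        for method in methods:
            records.append(
                {
                    "repeat": rep,
                    "method": method,
                    "mean_error": float(np.mean(errors[method])),
                    "n_test": n_test,
                }
            )
    per_repeat = pd.DataFrame(records)
    grouped = per_repeat.groupby("method")["mean_error"]
    return ValidationSummary(
        repeats=repeats,
        leftout_fraction=leftout_fraction,
        seed=seed,
        method_mean={m: float(v) for m, v in grouped.mean().items()},
        method_std={m: float(v) for m, v in grouped.std(ddof=0).items()},
        per_repeat=per_repeat,
    )
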