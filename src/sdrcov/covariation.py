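"""Weighted entropies, mutual information and the uncertainty coefficient
between MSA sites and PWM sites — the package's core statistic.

The setting generalizes classical two-MSA covariation analysis: on one side
an alignment column ``A_j`` gives a sample distribution over residues, on
the other side each domain contributes not a residue but a probability
column ``W_ik`` of its binding profile. With normalized sequence weights
``a_i`` the three distributions are

    p_j(x)     = sum_i a_i [A_ij = x]
    p_k(y)     = sum_i a_i W_ik(y)
    p_jk(x, y) = sum_i a_i [A_ij = x] W_ik(y)

whose entropies combine into MI(j, k) = H(A_j) + H(W_k) - H(A_j, W_k).
Because raw MI is inflated at individually diverse sites, the default
ranking score is the uncertainty coefficient, a normalized MI; the
symmetric form 2 MI / (H(A_j) + H(W_k)) is the default and both asymmetric
variants MI / H(A_j) and MI / H(W_k) are selectable.

Two significance measures are available per pair: a chi-square
approximation (for base-2 MI, 2 n ln(2) MI is asymptotically chi-square
with (|R_j| - 1)(|R_k| - 1) degrees of freedom, with cardinalities taken as
the number of residues with nonzero marginal probability) and a permutation
test that shuffles the alignment column across rows while keeping weights
attached to rows and profiles fixed.

Sites are pre-filtered: only gap-free columns whose most frequent residue
holds at most half of the total sequence weight enter the map, the rest
carry too little covariation information or would need gap handling the
model does not define.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2

from .alphabet import N_RESIDUES
from .errors import (
    AlignmentError,
    GapError,
    ParameterError,
    SdrcovError,
)
from .io import DomainAlignment, ProfileSet
from .weighting import SequenceWeights

UC_VARIANTS = ("symmetric", "msa", "pwm")

#: negative MI beyond this magnitude signals an internal inconsistency
_MI_CLAMP = 1e-9


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SiteDistribution:
    """A residue distribution at one site, tagged with its origin."""

    probs: np.ndarray
    source: str  # 'msa_site' | 'pwm_site'

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_RESIDUES,):
            raise SdrcovError(f"site distribution must have {N_RESIDUES} entries")
        if np.any(self.probs < -1e-12) or abs(self.probs.sum() - 1.0) > 1e-9:
            raise SdrcovError("site distribution is not a probability vector")


@dataclasses.dataclass
class JointDistribution:
    """Joint residue distribution of MSA site ``msa_site`` and PWM site
    ``pwm_site``; marginals reproduce the two site distributions by
    construction."""

    probs: np.ndarray  # (20, 20); rows = MSA residue, columns = PWM residue
    msa_site: int
    pwm_site: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_RESIDUES, N_RESIDUES):
            raise SdrcovError("joint distribution must be 20x20")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise SdrcovError("joint distribution does not sum to 1")

    def msa_marginal(self) -> np.ndarray:
        return self.probs.sum(axis=1)

    def pwm_marginal(self) -> np.ndarray:
        return self.probs.sum(axis=0)


def _column_codes(alignment: DomainAlignment, j: int) -> np.ndarray:
    codes = alignment.codes()
    if not 1 <= j <= alignment.m:
        raise AlignmentError(f"MSA site {j} outside [1, {alignment.m}]")
    col = codes[:, j - 1]
    if np.any(col < 0):
        raise GapError(
            f"MSA site {j} contains gaps; apply filter_sites before scoring"
        )
    return col


def msa_site_distribution(
    alignment: DomainAlignment, weights: SequenceWeights, j: int
) -> SiteDistribution:
    """Weighted residue frequencies of alignment column ``j`` (1-based)."""
    col = _column_codes(alignment, j)
    probs = np.bincount(col, weights=weights.values, minlength=N_RESIDUES)
    return SiteDistribution(probs=probs / probs.sum(), source="msa_site")


def pwm_site_distribution(
    profiles: ProfileSet, weights: SequenceWeights, k: int
) -> SiteDistribution:
    """Weighted average of the domains' profile columns at peptide site ``k``."""
    if not 1 <= k <= profiles.w:
        raise SdrcovError(f"PWM site {k} outside [1, {profiles.w}]")
    probs = weights.values @ profiles.matrices[:, k - 1, :]
    return SiteDistribution(probs=probs / probs.sum(), source="pwm_site")


def joint_distribution(
    alignment: DomainAlignment,
    profiles: ProfileSet,
    weights: SequenceWeights,
    j: int,
    k: int,
) -> JointDistribution:
    """Joint distribution of (residue at MSA site j, residue at PWM site k)."""
    col = _column_codes(alignment, j)
    probs = np.zeros((N_RESIDUES, N_RESIDUES))
    contrib = weights.values[:, None] * profiles.matrices[:, k - 1, :]
    np.add.at(probs, col, contrib)
    probs /= probs.sum()
    return JointDistribution(probs=probs, msa_site=j, pwm_site=k)


# ---------------------------------------------------------------------------
# information measures
# ---------------------------------------------------------------------------


def entropy(dist: SiteDistribution | JointDistribution | np.ndarray, base: float = 20.0) -> float:
    """Shannon entropy -sum p log_base p with the 0 log 0 = 0 convention.

    With base 20 a residue distribution scores in [0, 1]: a fully conserved
    site has entropy 0, a uniform site entropy 1.
    """
    if base <= 1:
        raise ParameterError(f"log base must exceed 1, got {base}")
    p = dist.probs if hasattr(dist, "probs") else np.asarray(dist, dtype=float)
    p = p[p > 0]
    return float(-(p * (np.log(p) / math.log(base))).sum())


def mutual_information(h_msa: float, h_pwm: float, h_joint: float) -> float:
    """MI = H(A_j) + H(W_k) - H(A_j, W_k), clamped at 0 for tiny negative
    floating-point cancellation; a genuinely negative value raises."""
    mi = h_msa + h_pwm - h_joint
    if mi < 0:
        if mi < -_MI_CLAMP:
            raise SdrcovError(
                f"mutual information {mi} below the floating-point clamp; "
                "inputs are inconsistent"
            )
        mi = 0.0
    return mi


def uncertainty_coefficient(
    mi: float, h_msa: float, h_pwm: float, variant: str = "symmetric"
) -> float:
    """Normalized MI penalizing diverse-site inflation.

    ``symmetric``: 2 MI / (H_msa + H_pwm); ``msa``: MI / H_msa;
    ``pwm``: MI / H_pwm. A zero denominator yields 0 — such a pair carries
    no information and must not rank.
    """
    if variant not in UC_VARIANTS:
        raise ParameterError(f"unknown UC variant {variant!r}; use one of {UC_VARIANTS}")
    if mi < 0:
        raise ParameterError("mutual information must be non-negative")
    if variant == "symmetric":
        denom = h_msa + h_pwm
        num = 2.0 * mi
    elif variant == "msa":
        denom, num = h_msa, mi
    else:
        denom, num = h_pwm, mi
    if denom <= 0:
        return 0.0
    return num / denom


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------


def chi2_pvalue(mi_bits: float, n: int, card_msa: int, card_pwm: int) -> float:
    """Chi-square upper-tail p-value for an observed base-2 MI.

    For independent sites, 2 n ln(2) MI is asymptotically chi-square with
    (card_msa - 1)(card_pwm - 1) degrees of freedom, where the cardinalities
    count residues with nonzero marginal probability.
    """
    if n < 2:
        raise ParameterError("chi-square approximation needs n >= 2 sequences")
    if card_msa < 2 or card_pwm < 2:
        raise ParameterError(
            "chi-square test undefined for a site with a single residue"
        )
    stat = 2.0 * math.log(2.0) * n * max(mi_bits, 0.0)
    dof = (card_msa - 1) * (card_pwm - 1)
    return float(_chi2.sf(stat, dof))


def _mi_for_column(
    col: np.ndarray,
    pwm_cols: np.ndarray,
    weights: np.ndarray,
    base: float,
) -> float:
    """Base-``base`` MI of an encoded gap-free column against profile columns."""
    p_msa = np.bincount(col, weights=weights, minlength=N_RESIDUES)
    p_msa /= p_msa.sum()
    p_pwm = weights @ pwm_cols
    p_pwm /= p_pwm.sum()
    joint = np.zeros((N_RESIDUES, N_RESIDUES))
    np.add.at(joint, col, weights[:, None] * pwm_cols)
    joint /= joint.sum()
    return mutual_information(
        entropy(p_msa, base), entropy(p_pwm, base), entropy(joint.ravel(), base)
    )


def permutation_pvalue(
    alignment: DomainAlignment,
    profiles: ProfileSet,
    weights: SequenceWeights,
    j: int,
    k: int,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    base: float = 20.0,
) -> float:
    """Permutation p-value for MI(j, k).

    Each permutation shuffles the residues of MSA column ``j`` across rows —
    weights stay attached to rows and the profile set is untouched — which
    breaks the pairing while preserving both marginal compositions. The
    estimate is (1 + #{MI* >= MI_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    col = _column_codes(alignment, j)
    pwm_cols = profiles.matrices[:, k - 1, :]
    mi_obs = _mi_for_column(col, pwm_cols, weights.values, base)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(col.size)
        mi_star = _mi_for_column(col[perm], pwm_cols, weights.values, base)
        if mi_star >= mi_obs - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# site filtering
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SiteVerdict:
    site: int
    kept: bool
    reasons: frozenset[str]
    majority_fraction: float


@dataclasses.dataclass
class FilterReport:
    """Per-site keep/drop verdicts for the MSA."""

    verdicts: list[SiteVerdict]

    def kept_sites(self) -> list[int]:
        return [v.site for v in self.verdicts if v.kept]

    def verdict(self, j: int) -> SiteVerdict:
        return self.verdicts[j - 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "j": [v.site for v in self.verdicts],
                "kept": [v.kept for v in self.verdicts],
                "reasons": [",".join(sorted(v.reasons)) for v in self.verdicts],
                "majority_fraction": [v.majority_fraction for v in self.verdicts],
            }
        )


def filter_sites(
    alignment: DomainAlignment, weights: SequenceWeights
) -> FilterReport:
    """Keep only gap-free sites whose most frequent residue occupies no more
    than half of the total sequence weight (the boundary is inclusive: a
    fraction of exactly 0.5 is kept)."""
    codes = alignment.codes()
    verdicts = []
    for j in range(1, alignment.m + 1):
        col = codes[:, j - 1]
        reasons = set()
        has_gap = bool(np.any(col < 0))
        if has_gap:
            reasons.add("has_gap")
            counts = np.bincount(
                col[col >= 0],
                weights=weights.values[col >= 0],
                minlength=N_RESIDUES,
            )
        else:
            counts = np.bincount(col, weights=weights.values, minlength=N_RESIDUES)
        majority = float(counts.max()) if counts.size else 0.0
        # weights are normalized, so the total sequence weight is 1
        if majority > 0.5 + 1e-12:
            reasons.add("too_conserved")
        verdicts.append(
            SiteVerdict(
                site=j,
                kept=not reasons,
                reasons=frozenset(reasons),
                majority_fraction=majority,
            )
        )
    return FilterReport(verdicts=verdicts)


# ---------------------------------------------------------------------------
# the covariation map
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PairScore:
    j: int
    k: int
    h_msa: float
    h_pwm: float
    h_joint: float
    mi: float
    uc: float
    card_msa: int
    card_pwm: int
    p_chi2: float | None = None
    p_perm: float | None = None


@dataclasses.dataclass
class CovariationMap:
    """Scores for every (kept MSA site, PWM site) pair.

    ``pairs`` maps (j, k) to a :class:`PairScore`; filtered MSA sites are
    absent and documented in ``filter_report``.
    """

    pairs: dict[tuple[int, int], PairScore]
    filter_report: FilterReport
    base: float
    uc_variant: str
    score: str = "uc"  # default ranking score
    pwm_labels: list[str] | None = None

    def score_of(self, j: int, k: int) -> float:
        pair = self.pairs[(j, k)]
        return pair.uc if self.score == "uc" else pair.mi

    def uc_site_weights(self, k: int, m: int) -> np.ndarray:
        """Length-m vector of UC(A_j, W_k) with 0 at filtered sites; used as
        site weights by covariation-weighted profile prediction."""
        out = np.zeros(m)
        for (j, kk), pair in self.pairs.items():
            if kk == k:
                out[j - 1] = pair.uc
        return out

    def to_frame(self) -> pd.DataFrame:
        labels = self.pwm_labels
        rows = []
        for (j, k) in sorted(self.pairs):
            p = self.pairs[(j, k)]
            rows.append(
                {
                    "j": j,
                    "k": k,
                    "pwm_label": labels[k - 1] if labels else str(k),
                    "H_msa": p.h_msa,
                    "H_pwm": p.h_pwm,
                    "H_joint": p.h_joint,
                    "MI": p.mi,
                    "UC": p.uc,
                    "card_msa": p.card_msa,
                    "card_pwm": p.card_pwm,
                    "p_chi2": p.p_chi2 if p.p_chi2 is not None else np.nan,
                    "p_perm": p.p_perm if p.p_perm is not None else np.nan,
                }
            )
        return pd.DataFrame(rows)


def covariation_map(
    alignment: DomainAlignment,
    profiles: ProfileSet,
    weights: SequenceWeights | None = None,
    base: float = 20.0,
    score: str = "uc",
    uc_variant: str = "symmetric",
    tests: Iterable[str] = (),
    n_perm: int = 999,
    seed: int = 0,
) -> CovariationMap:
    """Score every kept MSA site against every PWM site.

    ``tests`` may contain ``"chi2"`` and/or ``"perm"``; permutation seeds are
    derived per pair from ``seed`` so the map is deterministic and
    independent of evaluation order. Chi-square p-values are reported as NaN
    for pairs whose effective contingency table is degenerate (a single
    residue on either side).
    """
    if alignment.ids != profiles.ids:
        raise AlignmentError(
            "alignment and profile ids do not match (order matters)"
        )
    if score not in ("uc", "mi"):
        raise ParameterError(f"score must be 'uc' or 'mi', got {score!r}")
    tests = set(tests)
    unknown = tests - {"chi2", "perm"}
    if unknown:
        raise ParameterError(f"unknown tests: {sorted(unknown)}")
    if weights is None:
        weights = SequenceWeights(np.full(alignment.n, 1.0 / alignment.n))

    report = filter_sites(alignment, weights)
    codes = alignment.codes()
    pairs: dict[tuple[int, int], PairScore] = {}
    ln2 = math.log(2.0)
    for j in report.kept_sites():
        col = codes[:, j - 1]
        p_msa = np.bincount(col, weights=weights.values, minlength=N_RESIDUES)
        p_msa /= p_msa.sum()
        h_msa = entropy(p_msa, base)
        card_msa = int(np.count_nonzero(p_msa > 0))
        for k in range(1, profiles.w + 1):
            pwm_cols = profiles.matrices[:, k - 1, :]
            p_pwm = weights.values @ pwm_cols
            p_pwm /= p_pwm.sum()
            h_pwm = entropy(p_pwm, base)
            joint = np.zeros((N_RESIDUES, N_RESIDUES))
            np.add.at(joint, col, weights.values[:, None] * pwm_cols)
            joint /= joint.sum()
            h_joint = entropy(joint.ravel(), base)
            mi = mutual_information(h_msa, h_pwm, h_joint)
            uc = uncertainty_coefficient(mi, h_msa, h_pwm, uc_variant)
            card_pwm = int(np.count_nonzero(p_pwm > 0))
            pair = PairScore(
                j=j,
                k=k,
                h_msa=h_msa,
                h_pwm=h_pwm,
                h_joint=h_joint,
                mi=mi,
                uc=uc,
                card_msa=card_msa,
                card_pwm=card_pwm,
            )
            if "chi2" in tests:
                mi_bits = mi * math.log(base) / ln2
                if card_msa >= 2 and card_pwm >= 2:
                    pair.p_chi2 = chi2_pvalue(mi_bits, alignment.n, card_msa, card_pwm)
                else:
                    pair.p_chi2 = float("nan")
            if "perm" in tests:
                rng = np.random.default_rng([seed, j, k])
                pair.p_perm = permutation_pvalue(
                    alignment, profiles, weights, j, k,
                    n_perm=n_perm, seed=rng, base=base,
                )
            pairs[(j, k)] = pair
    return CovariationMap(
        pairs=pairs,
        filter_report=report,
        base=base,
        uc_variant=uc_variant,
        score=score,
        pwm_labels=profiles.labels(),
    )


def rank_pairs(
    cmap: CovariationMap, per_msa_site_best: bool = False
) -> list[tuple[int, int, float]]:
    """Pairs sorted by the map's ranking score, descending.

    With ``per_msa_site_best`` only the highest-scoring PWM site per MSA
    site is retained before sorting — low-scoring pairs are noisier, so
    ranking focuses on each domain site's best peptide partner. Ties break
    by (j, k) ascending.
    """
    items = [(j, k, cmap.score_of(j, k)) for (j, k) in cmap.pairs]
    if per_msa_site_best:
        best: dict[int, tuple[int, int, float]] = {}
        for j, k, s in sorted(items, key=lambda t: (t[0], t[1])):
            if j not in best or s > best[j][2] + 1e-15:
                best[j] = (j, k, s)
        items = list(best.values())
    return sorted(items, key=lambda t: (-t[2], t[0], t[1]))
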