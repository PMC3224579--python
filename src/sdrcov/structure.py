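"""Structure-based evaluation of covariation scores.

Covarying (domain site, peptide site) pairs are expected to sit close in a
co-crystal structure of the bound complex, so a negative correlation
between covariation score and physical distance is a quick, unbiased check
of the score. Three residue-pair distance metrics are supported:

* ``residue_center`` — Euclidean distance between heavy-atom centroids,
* ``alpha_carbon`` — CA–CA distance (missing CA yields a missing entry),
* ``closest_atom_vdw`` — minimum over heavy-atom pairs of the interatomic
  distance minus both van der Waals radii (Bondi set); may be negative.

Significance of the Pearson correlation uses the Fisher transformation:
z = atanh(r) with standard error 1/sqrt(n - 3), two-sided.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.stats import norm

from .covariation import CovariationMap, rank_pairs
from .errors import InsufficientDataError, ParameterError
from .io import Residue, SiteMap

METRICS = ("residue_center", "alpha_carbon", "closest_atom_vdw")
MODES = ("all_pairs", "best_per_msa_site")

#: Bondi van der Waals radii (Å) for elements common in protein structures
BONDI_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "H": 1.20,
}

#: fallback radius for elements outside the table
DEFAULT_RADIUS = 1.70


def vdw_radius(element: str) -> float:
    return BONDI_RADII.get(element.upper(), DEFAULT_RADIUS)


@dataclasses.dataclass
class CorrelationResult:
    """Pearson correlation between covariation score and distance."""

    r: float
    n_pairs: int
    p_value: float
    mode: str
    n_dropped: int = 0


def residue_distance(res_a: Residue, res_b: Residue, metric: str) -> float:
    """Distance between two residues under a named metric; NaN marks a pair
    that cannot be evaluated (missing CA under ``alpha_carbon``)."""
    if metric not in METRICS:
        raise ParameterError(f"unknown metric {metric!r}; use one of {METRICS}")
    if res_a.coords.size == 0 or res_b.coords.size == 0:
        raise ParameterError("residue without heavy atoms")
    if metric == "residue_center":
        return float(
            np.linalg.norm(res_a.coords.mean(axis=0) - res_b.coords.mean(axis=0))
        )
    if metric == "alpha_carbon":
        try:
            ca_a = res_a.coords[res_a.atom_names.index("CA")]
            ca_b = res_b.coords[res_b.atom_names.index("CA")]
        except ValueError:
            return float("nan")
        return float(np.linalg.norm(ca_a - ca_b))
    # closest_atom_vdw
    diff = res_a.coords[:, None, :] - res_b.coords[None, :, :]
    dists = np.linalg.norm(diff, axis=2)
    ra = np.array([vdw_radius(e) for e in res_a.elements])
    rb = np.array([vdw_radius(e) for e in res_b.elements])
    return float((dists - ra[:, None] - rb[None, :]).min())


def distance_table(
    structure: dict[tuple[str, int], Residue],
    site_map: SiteMap,
    metric: str,
) -> pd.DataFrame:
    """One distance per mapped (domain site j, peptide site k) pair.

    Columns: j, k, domain_residue, peptide_residue, distance. Pairs that
    cannot be evaluated under the metric carry NaN.
    """
    rows = []
    for j, dom_key in sorted(site_map.domain_map.items()):
        for k, pep_key in sorted(site_map.peptide_map.items()):
            d = residue_distance(structure[dom_key], structure[pep_key], metric)
            rows.append(
                {
                    "j": j,
                    "k": k,
                    "domain_residue": f"{dom_key[0]}:{dom_key[1]}",
                    "peptide_residue": f"{pep_key[0]}:{pep_key[1]}",
                    "distance": d,
                }
            )
    return pd.DataFrame(rows)


def fisher_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson r via the Fisher z-transformation."""
    if n < 4:
        raise InsufficientDataError("Fisher-transform p-value needs n >= 4")
    r = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    z = math.atanh(r) * math.sqrt(n - 3)
    return float(2.0 * norm.sf(abs(z)))


def score_distance_correlation(
    cmap: CovariationMap,
    table: pd.DataFrame,
    mode: str = "all_pairs",
) -> CorrelationResult:
    """Pearson correlation of covariation score against physical distance.

    ``best_per_msa_site`` first reduces the map to each MSA site's
    top-scoring PWM site (ties to the smaller k) before joining with the
    distance table; low-scoring pairs are noisier, so this is the headline
    mode. Missing distances are dropped and counted.
    """
    if mode not in MODES:
        raise ParameterError(f"unknown mode {mode!r}; use one of {MODES}")
    pairs = rank_pairs(cmap, per_msa_site_best=(mode == "best_per_msa_site"))
    by_pair = {(j, k): s for j, k, s in pairs}

    scores, dists = [], []
    n_dropped = 0
    for _, row in table.iterrows():
        key = (int(row["j"]), int(row["k"]))
        if key not in by_pair:
            continue
        if not np.isfinite(row["distance"]):
            n_dropped += 1
            continue
        scores.append(by_pair[key])
        dists.append(float(row["distance"]))
    n = len(scores)
    if n < 4:
        raise InsufficientDataError(
            f"only {n} overlapping (score, distance) pairs; need >= 4"
        )
    r = float(np.corrcoef(scores, dists)[0, 1])
    return CorrelationResult(
        r=r,
        n_pairs=n,
        p_value=fisher_pvalue(r, n),
        mode=mode,
        n_dropped=n_dropped,
    )
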