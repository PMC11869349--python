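"""Synthetic cohort generator for proximal-humerus morphometry studies.

Generates per-subject tables (sex, age, height, weight, BMI, ethnicity, side,
and the five morphometric parameters) whose statistical structure matches the
published summary statistics of a 70-subject single-center cohort: per-sex
means and SDs for each parameter, the pairwise correlations among head height
(HHH), articular surface diameter (ASD) and head diameter (HHD), and the
height-parameter correlations.  Ethnicity is assigned independently of all
parameters (a null effect), so ethnicity comparisons on generated cohorts
are exact type-I-error experiments.

Within each sex, (height, HHH, ASD, HHD) are drawn from a multivariate normal
assembled from the configured means/SDs and correlation matrix; correlations
not supplied are filled by the product heuristic ``corr(a,b) ~
corr(a,c) * corr(c,b)`` through a shared variable and the matrix is projected
to the nearest positive semidefinite matrix by eigenvalue clipping.  The
neck-shaft angle and medial offset are drawn independently per sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortParams",
    "generate_cohort",
    "generate_trivariate",
    "nearest_psd_correlation",
    "build_correlation_matrix",
    "PARAMETER_COLUMNS",
    "SEX_SUMMARIES",
    "RESULTS_CORRELATIONS",
    "HEIGHT_CORRELATIONS",
    "ETHNICITY_PROPORTIONS",
]

PARAMETER_COLUMNS = (
    "neck_shaft_angle_deg",
    "hhh_mm",
    "asd_mm",
    "hhd_mm",
    "medial_offset_mm",
)

# Published per-sex summaries (mean, sd, n): 24 male / 46 female.
SEX_SUMMARIES: dict[str, dict[str, tuple[float, float, int]]] = {
    "neck_shaft_angle_deg": {"male": (132.63, 6.67, 24), "female": (131.13, 4.82, 46)},
    "hhh_mm":               {"male": (15.30, 1.37, 24),  "female": (13.80, 1.61, 46)},
    "asd_mm":               {"male": (43.83, 2.26, 24),  "female": (38.16, 2.70, 46)},
    "hhd_mm":               {"male": (49.08, 3.12, 24),  "female": (42.21, 3.70, 46)},
    "medial_offset_mm":     {"male": (6.27, 2.28, 24),   "female": (6.24, 1.75, 46)},
}

# Pairwise correlations among the three size parameters (study-wide).
RESULTS_CORRELATIONS = {
    ("hhd_mm", "hhh_mm"): 0.528,
    ("hhd_mm", "asd_mm"): 0.916,
    ("asd_mm", "hhh_mm"): 0.679,
}

# Height-parameter correlations (height column of the body-profile table).
HEIGHT_CORRELATIONS = {
    "neck_shaft_angle_deg": 0.13,
    "hhh_mm": 0.30,
    "asd_mm": 0.64,
    "hhd_mm": 0.62,
    "medial_offset_mm": 0.07,
}

HEIGHT_CM = (157.35, 12.98)
AGE_YEARS = (51.11, 12.98)
WEIGHT_KG = (52.44, 9.83)

ETHNICITY_PROPORTIONS = {
    "Pangkal Pinang": 0.0285,
    "North Sumatera": 0.0428,
    "Riau": 0.0142,
    "West Sumatera": 0.0285,
    "South Sumatera": 0.0142,
    "West Java": 0.2714,
    "Jakarta": 0.4142,
    "Central Java": 0.1142,
    "East Java": 0.0285,
    "South Sulawesi": 0.0142,
    "Papua": 0.0285,
}

_POSITIVE_FLOOR = 1e-6  # parameters are clipped here to stay positive


@dataclass(frozen=True)
class CohortParams:
    """Configuration of one synthetic cohort draw."""

    n_male: int = 24
    n_female: int = 46
    sex_summaries: dict = field(default_factory=lambda: dict(SEX_SUMMARIES))
    size_correlations: dict = field(default_factory=lambda: dict(RESULTS_CORRELATIONS))
    height_correlations: dict = field(default_factory=lambda: dict(HEIGHT_CORRELATIONS))
    height_cm: tuple[float, float] = HEIGHT_CM
    age_years: tuple[float, float] = AGE_YEARS
    weight_kg: tuple[float, float] = WEIGHT_KG
    ethnicity_proportions: dict = field(
        default_factory=lambda: dict(ETHNICITY_PROPORTIONS))
    seed: int = 0

    def __post_init__(self):
        if self.n_male < 0 or self.n_female < 0 or self.n_male + self.n_female == 0:
            raise ValueError("group sizes must be non-negative and not both zero")
        for r in list(self.size_correlations.values()) + list(
                self.height_correlations.values()):
            if r is not None and not -1.0 <= r <= 1.0:
                raise ValueError(f"correlation {r} outside [-1, 1] is not repairable")


def nearest_psd_correlation(corr: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalues are clipped at ``floor``, the matrix reassembled, and the
    diagonal renormalised to one.
    """
    corr = np.asarray(corr, dtype=float)
    sym = 0.5 * (corr + corr.T)
    w, v = np.linalg.eigh(sym)
    if w.min() >= 0:
        return sym
    w = np.clip(w, floor, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def build_correlation_matrix(variables: list[str], known: dict) -> np.ndarray:
    """Assemble a correlation matrix from known pairs, filling gaps.

    ``known`` maps unordered pairs to r (``None`` counts as unknown).  A
    missing pair (a, b) is filled by the product heuristic r(a,c)*r(c,b)
    through the first variable c for which both legs are known (0 if none),
    then the matrix is projected to the nearest PSD correlation matrix.
    """
    k = len(variables)

    def lookup(a, b):
        return known.get((a, b), known.get((b, a)))

    corr = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r = lookup(variables[i], variables[j])
            if r is None:
                r = 0.0
                for m in range(k):
                    if m in (i, j):
                        continue
                    leg1 = lookup(variables[i], variables[m])
                    leg2 = lookup(variables[m], variables[j])
                    if leg1 is not None and leg2 is not None:
                        r = leg1 * leg2
                        break
            corr[i, j] = corr[j, i] = r
    return nearest_psd_correlation(corr)


def _draw_mvn(rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray,
              corr: np.ndarray, n: int) -> np.ndarray:
    cov = corr * np.outer(sd, sd)
    # Tiny jitter keeps the Cholesky factor defined after PSD repair.
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(mean)))
    z = rng.standard_normal((n, len(mean)))
    return mean + z @ chol.T

def generate_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Draw one synthetic cohort table; deterministic given the seed."""
    p = params or CohortParams()
    rng = np.random.default_rng(p.seed)

    size_vars = ["height_cm", "hhh_mm", "asd_mm", "hhd_mm"]
    known = dict(p.size_correlations)
    for param, r in p.height_correlations.items():
        if param in size_vars:
            known[("height_cm", param)] = r
    corr = build_correlation_matrix(size_vars, known)

    frames = []
    for sex, n in (("male", p.n_male), ("female", p.n_female)):
        if n == 0:
            continue
        mean = np.array([p.height_cm[0]] + [p.sex_summaries[v][sex][0]
                                            for v in size_vars[1:]])
        sd = np.array([p.height_cm[1]] + [p.sex_summaries[v][sex][1]
                                          for v in size_vars[1:]])
        draw = _draw_mvn(rng, mean, sd, corr, n)
        angle = rng.normal(p.sex_summaries["neck_shaft_angle_deg"][sex][0],
                           p.sex_summaries["neck_shaft_angle_deg"][sex][1], n)
        offset = rng.normal(p.sex_summaries["medial_offset_mm"][sex][0],
                            p.sex_summaries["medial_offset_mm"][sex][1], n)
        frames.append(pd.DataFrame({
            "sex": sex,
            "height_cm": draw[:, 0],
            "hhh_mm": draw[:, 1],
            "asd_mm": draw[:, 2],
            "hhd_mm": draw[:, 3],
            "neck_shaft_angle_deg": angle,
            "medial_offset_mm": offset,
        }))
    table = pd.concat(frames, ignore_index=True)
    n_total = len(table)

    table["age_years"] = rng.normal(*p.age_years, n_total)
    table["weight_kg"] = np.clip(rng.normal(*p.weight_kg, n_total), 1.0, None)
    table["height_cm"] = np.clip(table["height_cm"], 50.0, None)
    table["bmi"] = table["weight_kg"] / (table["height_cm"] / 100.0) ** 2

    labels = list(p.ethnicity_proportions)
    probs = np.array([p.ethnicity_proportions[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    table["ethnicity"] = rng.choice(labels, size=n_total, p=probs)
    table["side"] = rng.choice(["left", "right"], size=n_total)

    for col in PARAMETER_COLUMNS:
        table[col] = np.clip(table[col], _POSITIVE_FLOOR, None)
    table.insert(0, "subject", [f"S{i + 1:04d}" for i in range(n_total)])

    column_order = ["subject", "sex", "age_years", "height_cm", "weight_kg",
                    "bmi", "ethnicity", "side", *PARAMETER_COLUMNS]
    return table[column_order]


def generate_trivariate(n: int, r_hhd_hhh: float = 0.528,
                        r_hhd_asd: float = 0.916, r_asd_hhh: float = 0.679,
                        seed: int = 0) -> pd.DataFrame:
    """Standardised trivariate normal sample of (hhh, asd, hhd).

    Used for correlation-recovery experiments: the sample Pearson
    correlations converge to the configured values at rate ~(1-r^2)/sqrt(n).
    Raises if the implied correlation matrix is not positive definite.
    """
    if n < 3:
        raise ValueError("generate_trivariate: need n >= 3")
    for r in (r_hhd_hhh, r_hhd_asd, r_asd_hhh):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    corr = np.array([
        [1.0, r_asd_hhh, r_hhd_hhh],
        [r_asd_hhh, 1.0, r_hhd_asd],
        [r_hhd_hhh, r_hhd_asd, 1.0],
    ])
    if np.linalg.eigvalsh(corr).min() <= 0:
        raise ValueError("correlation matrix is not positive definite")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 3))
    sample = z @ np.linalg.cholesky(corr).T
    return pd.DataFrame(sample, columns=["hhh_mm", "asd_mm", "hhd_mm"])
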