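"""Synthetic two-group resting-state cohorts with known connectivity effects.

The real study cohort (27 healthy controls, 24 chronic low back pain
patients; 360 cortical parcels; six 5-minute runs at TR 0.8 s, ~2,250
samples) is not publicly deposited, so this module generates cohorts with
the statistical structure the downstream analysis assumes: each group's
parcel time series are zero-mean correlated Gaussian draws from a modular
(community-structured) covariance, and the patient group's covariance is
perturbed at a known set of "affected" parcels. Because the effect is
injected at the covariance level, group differences in graph metrics arise
mechanistically through thresholded connectivity, as they would in real
functional MRI — not by writing differences into the metrics directly.

The "affected nodes" ground truth is a construct of this generator (the
study reports no such truth); it exists so that recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .connectivity import FCMatrix

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "SyntheticCohort",
    "generate_cohort",
    "generate_disability_scores",
]

GROUP_HC = "HC"
GROUP_LBP = "LBP"

#: Oswestry Disability Index moments per group (mean, sd), 0-100 scale
ODI_DEFAULTS = {GROUP_HC: (5.63, 5.60), GROUP_LBP: (33.3, 15.3)}

#: smallest eigenvalue admitted after positive-definiteness repair
_PD_FLOOR = 1e-4


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    Attributes
    ----------
    n_hc, n_lbp : int
        Group sizes; defaults follow the study cohort (27 controls, 24
        patients).
    n_nodes : int
        Parcel count; 360 matches the multi-modal cortical parcellation.
    n_timepoints : int
        Samples per series; 2,250 approximates six 5-min runs at TR 0.8 s.
    n_affected : int
        Number of parcels whose connectivity differs in the patient group.
    effect_size : float
        Multiplicative perturbation strength: off-diagonal covariance on
        affected rows/columns is scaled by (1 + effect_size). 0 gives a
        null cohort with identical group covariances.
    noise_sd : float
        SD of independent observation noise added to each sample; attenuates
        all correlations uniformly (default 0.5 keeps attenuation mild).
    seed : int
        Master RNG seed; generation is bit-reproducible for a fixed
        parameter set.
    """

    n_hc: int = 27
    n_lbp: int = 24
    n_nodes: int = 360
    n_timepoints: int = 2250
    n_affected: int = 0
    effect_size: float = 0.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_lbp, self.n_nodes, self.n_timepoints) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.n_affected <= self.n_nodes:
            raise ValueError("n_affected must lie in [0, n_nodes]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SubjectRecord:
    """One subject: identity, group label, optional score, data payload."""

    subject_id: str
    group: str
    odi: float | None = None
    series: np.ndarray | None = None
    fc: FCMatrix | None = None


@dataclass
class SyntheticCohort:
    subjects: list[SubjectRecord]
    affected_nodes: np.ndarray
    group_covariances: dict[str, np.ndarray]
    spec: CohortSpec = field(default_factory=CohortSpec)

    def labels(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])


def _nearest_pd(cov: np.ndarray, floor: float = _PD_FLOOR) -> np.ndarray:
    """Eigenvalue clipping: replace eigenvalues below ``floor`` by it."""
    cov = (cov + cov.T) / 2.0
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() >= floor:
        return cov
    vals = np.maximum(vals, floor)
    repaired = vecs @ np.diag(vals) @ vecs.T
    return (repaired + repaired.T) / 2.0


def _base_covariance(n_nodes: int, rng: np.random.Generator) -> np.ndarray:
    """Modular correlation structure: strong within randomly assigned
    communities, weak between, plus a small symmetric jitter so edge
    weights are generically distinct."""
    n_comm = max(2, n_nodes // 12)
    comm = rng.integers(0, n_comm, size=n_nodes)
    same = comm[:, None] == comm[None, :]
    cov = np.where(same, 0.35, 0.03)
    jitter = rng.uniform(-0.02, 0.02, size=(n_nodes, n_nodes))
    cov = cov + (jitter + jitter.T) / 2.0
    np.fill_diagonal(cov, 1.0)
    return _nearest_pd(cov)


def _perturb_covariance(
    cov: np.ndarray, affected: np.ndarray, effect_size: float
) -> np.ndarray:
    """Scale off-diagonal covariance on affected rows/columns by
    (1 + effect_size); each entry receives the factor once even when both
    endpoints are affected. Entries are clipped to +/-0.98 and the result
    repaired to positive definite."""
    if effect_size == 0 or affected.size == 0:
        return cov.copy()
    n = cov.shape[0]
    mask = np.zeros(n, dtype=bool)
    mask[affected] = True
    touched = mask[:, None] | mask[None, :]
    np.fill_diagonal(touched, False)
    out = cov.copy()
    out[touched] = np.clip(cov[touched] * (1.0 + effect_size), -0.98, 0.98)
    out = _nearest_pd(out)
    if np.linalg.eigvalsh(out).min() <= 0:
        raise ValueError(
            "perturbed covariance could not be repaired to positive definite"
        )
    return out


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full two-group cohort of parcel time series.

    Each subject's series is ``L @ white`` noise (L the Cholesky factor of
    the group covariance) plus independent N(0, noise_sd^2) observation
    noise; series are Gaussian without temporal autocorrelation, which is
    sufficient because Pearson correlation is the only downstream consumer.
    """
    master = np.random.SeedSequence(spec.seed)
    ss_struct, ss_subjects = master.spawn(2)
    rng = np.random.default_rng(ss_struct)

    cov_hc = _base_covariance(spec.n_nodes, rng)
    affected = np.sort(
        rng.choice(spec.n_nodes, size=spec.n_affected, replace=False)
    ).astype(int)
    cov_lbp = _perturb_covariance(cov_hc, affected, spec.effect_size)

    chol = {GROUP_HC: np.linalg.cholesky(cov_hc), GROUP_LBP: np.linalg.cholesky(cov_lbp)}
    groups = [GROUP_HC] * spec.n_hc + [GROUP_LBP] * spec.n_lbp
    subjects = []
    child_seeds = ss_subjects.spawn(len(groups))
    for idx, (group, child) in enumerate(zip(groups, child_seeds)):
        sub_rng = np.random.default_rng(child)
        white = sub_rng.standard_normal((spec.n_nodes, spec.n_timepoints))
        series = chol[group] @ white
        if spec.noise_sd > 0:
            series = series + spec.noise_sd * sub_rng.standard_normal(series.shape)
        subjects.append(
            SubjectRecord(subject_id=f"sub-{idx:03d}", group=group, series=series)
        )
    return SyntheticCohort(
        subjects=subjects,
        affected_nodes=affected,
        group_covariances={GROUP_HC: cov_hc, GROUP_LBP: cov_lbp},
        spec=spec,
    )


def generate_disability_scores(
    cohort: SyntheticCohort,
    hc_mean: float = ODI_DEFAULTS[GROUP_HC][0],
    hc_sd: float = ODI_DEFAULTS[GROUP_HC][1],
    lbp_mean: float = ODI_DEFAULTS[GROUP_LBP][0],
    lbp_sd: float = ODI_DEFAULTS[GROUP_LBP][1],
    seed: int = 0,
) -> SyntheticCohort:
    """Attach truncated-normal disability (ODI-like) scores in [0, 100].

    Defaults reproduce the study groups' reported score moments (patients
    33.3 +/- 15.3, controls 5.63 +/- 5.60). The score is bounded on
    [0, 100] by construction, hence the truncated normal. Returns the same
    cohort with ``odi`` filled in on every subject.
    """
    for name, mean in (("hc_mean", hc_mean), ("lbp_mean", lbp_mean)):
        if not 0 <= mean <= 100:
            raise ValueError(f"{name} must lie in [0, 100]")
    for name, sd in (("hc_sd", hc_sd), ("lbp_sd", lbp_sd)):
        if sd < 0:
            raise ValueError(f"{name} must be >= 0")
    params = {GROUP_HC: (hc_mean, hc_sd), GROUP_LBP: (lbp_mean, lbp_sd)}
    rng = np.random.default_rng(seed)
    for sub in cohort.subjects:
        mean, sd = params[sub.group]
        if sd == 0:
            sub.odi = float(mean)
            continue
        a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
        sub.odi = float(
            stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
        )
    return cohort


def null_spec(spec: CohortSpec) -> CohortSpec:
    """The same cohort specification with the group effect switched off."""
    return replace(spec, n_affected=0, effect_size=0.0)
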