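"""Synthetic cohorts with the statistical structure the pipeline assumes.

Every stage of the analysis can be exercised without any imaging download:

* a toy contiguous-block parcellation stands in for the AAL atlas;
* each voxel's BOLD-like series is a standardized AR(1) process whose
  lag-one coefficient phi is the single irregularity knob — higher phi
  means a smoother, more predictable series and therefore *lower* sample
  entropy (phi = 0 is white noise);
* group/age/region structure enters through trajectory templates: the
  control template lowers phi steadily with age (entropy rises through
  development), while the case template adds an age-dependent offset that
  raises phi in childhood and adulthood and lowers it around mid-adolescence
  (entropy deficit outside adolescence, excess near the adolescent peak).
  Two region templates — a flatter "subcortical-like" one and a steeper
  "cortical-like" one — plant a two-cluster structure in the differential
  curves;
* behavioral scores are drawn from a known linear model on regional
  entropy, age, and sex, so regression recovery is checkable against
  ground truth.

All generation is a pure function of the root seed: subject volumes use
``default_rng([seed, subject_index])`` substreams, so any subject can be
regenerated independently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .entropy import EntropyParams, profiles_to_frame, regional_profile
from .errors import ParameterError
from .io import Parcellation, BoldVolume, SubjectRecord, load_aal90_table
from .trajectories import build_age_windows

logger = logging.getLogger(__name__)

#: Region ids given the flatter "subcortical-like" template when n_regions = 90:
#: cingulate, hippocampal, parietal, paracentral and basal-ganglia/thalamus ids.
SUBCORTICAL_LIKE_IDS = frozenset(
    [33, 34, 37, 38, 39, 40] + list(range(59, 71)) + list(range(71, 79)))


@dataclass
class TrajectoryTemplate:
    """Maps (group, age) to the AR(1) coefficient for one region family.

    ``phi_young``/``phi_old`` anchor the control trajectory (phi falls
    linearly with age, so control entropy rises monotonically). The case
    offset is ``amplitude * (offset_frac - exp(-(age - peak_age)^2 / (2 w^2)))``:
    positive (lower entropy) far from ``peak_age``, negative (higher
    entropy) near it.
    """

    amplitude: float = 0.04
    peak_age: float = 14.0
    peak_width: float = 3.0
    offset_frac: float = 0.4
    phi_young: float = 0.45
    phi_old: float = 0.25
    age_range: tuple[float, float] = (6.0, 30.0)

    def control_phi(self, age: float):
        a0, a1 = self.age_range
        frac = (np.asarray(age, dtype=float) - a0) / (a1 - a0)
        return np.clip(self.phi_young + (self.phi_old - self.phi_young) * frac, 0.0, 0.95)

    def case_offset(self, age: float):
        age = np.asarray(age, dtype=float)
        bump = np.exp(-((age - self.peak_age) ** 2) / (2.0 * self.peak_width ** 2))
        return self.amplitude * (self.offset_frac - bump)

    def phi(self, group: str, age: float):
        base = self.control_phi(age)
        if group == "control":
            return base
        return np.clip(base + self.case_offset(age), 0.0, 0.95)


@dataclass
class SyntheticCohortSpec:
    """Study conditions for one synthetic cohort; pure function of ``seed``."""

    n_per_group: int = 20
    age_range: tuple[float, float] = (6.0, 30.0)
    grid_shape: tuple[int, int, int] = (9, 9, 10)
    n_regions: int = 90
    series_length: int = 120
    male_frac: float = 0.85
    noise_sd: float = 1.0
    true_betas: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    # template amplitudes: case/control entropy gap on the order of 0.01 nats
    subcortical_amplitude: float = 0.02
    cortical_amplitude: float = 0.05

    def __post_init__(self) -> None:
        if self.series_length < 77:
            raise ParameterError(
                f"series_length must be >= 77 (shortest admissible epoch), got {self.series_length}")
        if self.n_per_group < 1:
            raise ParameterError("n_per_group must be >= 1")

    def templates(self) -> dict[str, TrajectoryTemplate]:
        return {
            "subcortical": TrajectoryTemplate(amplitude=self.subcortical_amplitude),
            "cortical": TrajectoryTemplate(amplitude=self.cortical_amplitude),
        }

    def region_family(self, region_id: int) -> str:
        if self.n_regions == 90:
            return "subcortical" if region_id in SUBCORTICAL_LIKE_IDS else "cortical"
        return "subcortical" if region_id <= self.n_regions // 3 else "cortical"


def make_toy_parcellation(grid_shape: tuple[int, int, int], n_regions: int) -> Parcellation:
    """Contiguous flat-order blocks labeled 1..n_regions covering the grid."""
    n_vox = int(np.prod(grid_shape))
    if n_vox < n_regions:
        raise ParameterError(f"grid of {n_vox} voxels cannot hold {n_regions} regions")
    bounds = np.linspace(0, n_vox, n_regions + 1).astype(int)
    flat = np.zeros(n_vox, dtype=np.int64)
    for rid in range(1, n_regions + 1):
        flat[bounds[rid - 1]:bounds[rid]] = rid
    labels = flat.reshape(grid_shape)
    if n_regions == 90:
        table = load_aal90_table()
    else:
        table = pd.DataFrame({
            "region_id": np.arange(1, n_regions + 1),
            "name": [f"Toy region {i}" for i in range(1, n_regions + 1)],
            "hemisphere": ["L" if i % 2 else "R" for i in range(1, n_regions + 1)],
        })
    return Parcellation(labels=labels, region_table=table)


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(subject_index)])


def simulate_subject_bold(record: SubjectRecord, spec: SyntheticCohortSpec,
                          parc: Parcellation, subject_index: int,
                          burn_in: int = 50) -> BoldVolume:
    """AR(1) voxel series, x_t = phi x_{t-1} + eps_t, standardized to unit variance.

    phi is set per voxel by the subject's group and age through the region
    family's template; generation is deterministic in (spec.seed,
    subject_index).
    """
    rng = _subject_rng(spec.seed, subject_index)
    shape = parc.labels.shape
    n_vox = int(np.prod(shape))
    t = spec.series_length
    templates = spec.templates()
    phi_by_region = {rid: float(templates[spec.region_family(rid)].phi(record.group, record.age))
                     for rid in parc.region_ids}
    flat_labels = parc.labels.ravel()
    eps = rng.standard_normal((n_vox, t + burn_in))
    data = np.zeros((n_vox, t))
    for phi in set(phi_by_region.values()):
        rows = np.isin(flat_labels, [rid for rid, p in phi_by_region.items() if p == phi])
        if not rows.any():
            continue
        sig = lfilter([1.0], [1.0, -phi], eps[rows], axis=1)[:, burn_in:]
        data[rows] = sig
    # background voxels (label 0) stay zero and fall outside the default mask
    sd = data.std(axis=1, keepdims=True, ddof=1)
    nonzero = sd[:, 0] > 0
    data[nonzero] = (data[nonzero] - data[nonzero].mean(axis=1, keepdims=True)) / sd[nonzero]
    vol = data.reshape(*shape, t)
    mask = parc.labels > 0
    return BoldVolume(data=vol, voxel_mask=mask, subject_id=record.subject_id)


def simulate_cohort(spec: SyntheticCohortSpec) -> list[SubjectRecord]:
    """Balanced two-group cohort with uniform ages; deterministic in the seed.

    Volumes are not materialized here (memory); regenerate any subject's
    volume with :func:`simulate_subject_bold` via its cohort index.
    """
    rng = np.random.default_rng([int(spec.seed), 10_000_019])
    n = 2 * spec.n_per_group
    ages = rng.uniform(*spec.age_range, size=n)
    sexes = np.where(rng.random(n) < spec.male_frac, "male", "female")
    records = []
    for i in range(n):
        group = "case" if i < spec.n_per_group else "control"
        records.append(SubjectRecord(
            subject_id=f"S{i:04d}", group=group, age=float(ages[i]),
            sex=str(sexes[i]), fiq=float(rng.normal(105, 15))))
    return records


def cohort_profiles(spec: SyntheticCohortSpec, records: list[SubjectRecord],
                    parc: Parcellation, params: EntropyParams | None = None,
                    progress: bool = False) -> pd.DataFrame:
    """Simulate each subject's volume, compute its regional profile, discard the volume."""
    profiles = []
    for i, rec in enumerate(records):
        vol = simulate_subject_bold(rec, spec, parc, subject_index=i)
        profiles.append(regional_profile(vol, parc, params))
        if progress and (i + 1) % 25 == 0:
            logger.info("cohort_profiles: %d/%d subjects", i + 1, len(records))
    return profiles_to_frame(profiles)


def simulate_behavior(profiles: pd.DataFrame, records: list[SubjectRecord],
                      true_betas: dict[str, float], noise_sd: float, seed: int,
                      response: str = "SCORE") -> list[SubjectRecord]:
    """Write a linear-model behavioral score into each record (in place).

    ``true_betas`` maps predictor names — ``R<id>`` for regional entropies,
    ``age``, ``sex``, ``intercept`` — to coefficients. Subjects with any
    missing required entropy get a missing score.
    """
    rng = np.random.default_rng([int(seed), 77_003])
    from .association import SEX_CODE

    region_terms = {k: v for k, v in true_betas.items() if k.startswith("R")}
    for rec in records:
        if rec.subject_id not in profiles.index:
            rec.behavioral_scores[response] = None
            continue
        row = profiles.loc[rec.subject_id]
        score = true_betas.get("intercept", 0.0)
        ok = True
        for term, beta in region_terms.items():
            v = row.get(term, np.nan)
            if not np.isfinite(v):
                ok = False
                break
            score += beta * float(v)
        if not ok:
            rec.behavioral_scores[response] = None
            continue
        score += true_betas.get("age", 0.0) * rec.age
        score += true_betas.get("sex", 0.0) * SEX_CODE[rec.sex]
        rec.behavioral_scores[response] = float(score + rng.normal(0.0, noise_sd))
    return records


def planted_cluster_labels(spec: SyntheticCohortSpec) -> dict[int, int]:
    """Ground-truth region cluster ids (1 = subcortical-like, 2 = cortical-like)."""
    parc_ids = range(1, spec.n_regions + 1)
    return {rid: (1 if spec.region_family(rid) == "subcortical" else 2) for rid in parc_ids}


def default_windows():
    return build_age_windows(6, 26, 5, 1)
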