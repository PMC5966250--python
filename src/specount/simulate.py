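"""Synthetic spectral-count matrices and patient cohorts with known truth.

The raw mass-spectrometry and patient-level data behind the PT/LT
(primary pancreatic tumor vs paired liver metastasis) comparison are not
public, so this module generates inputs with the statistical structure the
analysis assumes, together with ground-truth labels for recovery testing.

Count model
-----------
Per protein *i*, a latent expected count ``lam_i`` is drawn from a
log-normal law (the heavy tail of spectral-count data); per sample the
observed count is Poisson around ``lam_i`` times the sample's depth factor,
thinned by a Bernoulli dropout whose probability decreases with the
expected count (``p_drop = p0 * exp(-lam / tau)``) — this mechanically
reproduces one-group-only identifications.  Differential proteins are
planted by multiplying one group's expected count by ``de_fold``;
non-planted proteins have identical expected counts in both groups.
Protein lengths are drawn independently of abundance by default (a
length-proportional option exists) so the NSAF length correction is
exercised both ways.

Cohort model
------------
Each patient is synchronous (liver metastasis at diagnosis) with a fixed
probability and is then excluded from recurrence-time simulation.  For the
remaining at-risk patients, time to liver recurrence follows a proportional
hazards model with an exponential (or Weibull) baseline and planted log
hazard ratios for marker positivity and for tumor size above a cutoff;
administrative censoring times are uniform.  The metastasis group is
derived from the outcome: metachronous if the recurrence is observed,
none otherwise.  All times are in months.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import CohortTable, ProteinAnnotationTable, SpectralCountMatrix

# ---------------------------------------------------------------------------
# configurations


@dataclass
class DropoutRule:
    """Per-sample Bernoulli dropout, probability decreasing in expected count.

    ``p_drop(lam) = p0 * exp(-lam / tau)``; ``kind="none"`` disables dropout.
    """

    kind: str = "exponential"
    p0: float = 0.9
    tau: float = 3.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "exponential"):
            raise ConfigError(f"unknown dropout kind {self.kind!r}")
        if not (0.0 <= self.p0 <= 1.0):
            raise ConfigError(f"dropout p0 must be in [0,1], got {self.p0}")
        if self.tau <= 0:
            raise ConfigError(f"dropout tau must be > 0, got {self.tau}")

    def dropout_prob(self, lam: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return np.zeros_like(lam)
        return self.p0 * np.exp(-lam / self.tau)


@dataclass
class CountSimConfig:
    """Configuration of the spectral-count generator.

    ``abundance_median``/``abundance_sigma`` parameterize the log-normal law
    of expected counts per protein per sample (median on the count scale,
    sigma on the log scale).  ``lt_depth_factor`` multiplies every LT
    sample's expected counts, emulating the deeper identification typically
    seen in one tissue; it is 1 by default and cancels out of the pooled
    ratio statistics.  ``sample_depth_sigma`` adds log-normal per-sample
    depth variability (0 by default: the pooled comparison assumes stable
    per-sample depth; turn it on to stress that assumption).
    """

    n_proteins: int = 4000
    n_cases: int = 7
    abundance_median: float = 2.0
    abundance_sigma: float = 1.2
    de_fraction: float = 0.0
    de_fold: float = 4.0
    dropout: DropoutRule = field(default_factory=DropoutRule)
    length_median: float = 400.0
    length_sigma: float = 0.45
    length_proportional: bool = False
    lt_depth_factor: float = 1.0
    sample_depth_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.dropout, dict):
            self.dropout = DropoutRule(**self.dropout)
        if self.n_proteins <= 0 or self.n_cases <= 0:
            raise ConfigError("n_proteins and n_cases must be positive")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ConfigError(f"de_fraction must be in [0,1], got {self.de_fraction}")
        if self.de_fraction > 0 and self.de_fold <= 1:
            raise ConfigError(f"de_fold must be > 1, got {self.de_fold}")
        if self.abundance_median <= 0 or self.abundance_sigma < 0:
            raise ConfigError("invalid abundance law")
        if self.length_median < 50:
            raise ConfigError("length_median must be >= 50 amino acids")
        if self.lt_depth_factor <= 0 or self.sample_depth_sigma < 0:
            raise ConfigError("invalid depth parameters")


@dataclass
class CohortSimConfig:
    """Configuration of the patient-cohort generator.

    ``marker_positive_rate_by_group`` needs keys ``"synchronous"`` (patients
    with liver metastasis at diagnosis) and ``"at_risk"`` (everyone else;
    enrichment of positivity among metachronous patients then emerges from
    the planted hazard, as in the real cohort).  ``baseline_hazard`` is
    ``("exponential", rate_per_month)`` or ``("weibull", scale_rate, shape)``;
    ``censoring_law`` is ``("uniform", lo, hi)`` or ``("fixed", t)`` months.
    """

    n_patients: int = 70
    sync_probability: float = 8.0 / 70.0
    marker_name: str = "CNPY2"
    marker_positive_rate_by_group: dict = field(
        default_factory=lambda: {"synchronous": 0.875, "at_risk": 0.45}
    )
    baseline_hazard: tuple = ("exponential", 0.0005)
    marker_log_hr: float = float(np.log(6.19))
    size_log_hr: float = float(np.log(4.63))
    size_cutoff_mm: float = 42.0
    censoring_law: tuple = ("uniform", 6.0, 240.0)
    ki67_median: float = 3.0
    ki67_sigma: float = 1.1
    size_median_mm: float = 22.0
    size_sigma: float = 0.7
    sync_covariate_shift: float = 1.8
    invasion_rates: dict = field(
        default_factory=lambda: {
            "lymph_node_metastasis": 0.17,
            "vascular_invasion": 0.45,
            "lymphatic_invasion": 0.30,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.sync_probability, *self.marker_positive_rate_by_group.values()]
        probs += list(self.invasion_rates.values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("probabilities must lie in [0,1]")
        kind = self.baseline_hazard[0]
        if kind not in ("exponential", "weibull"):
            raise ConfigError(f"unknown baseline hazard {kind!r}")
        if any(v <= 0 for v in self.baseline_hazard[1:]):
            raise ConfigError("hazard parameters must be positive")
        ckind = self.censoring_law[0]
        if ckind not in ("uniform", "fixed"):
            raise ConfigError(f"unknown censoring law {ckind!r}")
        if any(v <= 0 for v in self.censoring_law[1:]):
            raise ConfigError("censoring times must be positive")
        for key in ("synchronous", "at_risk"):
            if key not in self.marker_positive_rate_by_group:
                raise ConfigError(f"marker_positive_rate_by_group needs key {key!r}")


@dataclass
class SimulationTruth:
    """Ground truth of a simulation run, for recovery testing.

    ``de_proteins`` maps planted accessions to ``(direction, fold)`` with
    direction "LT" (LT-up) or "PT" (PT-up); ``planted_hrs`` maps covariate
    names to the true hazard ratios.
    """

    de_proteins: dict[str, tuple[str, float]] = field(default_factory=dict)
    planted_hrs: dict[str, float] = field(default_factory=dict)

    @property
    def de_accessions(self) -> set[str]:
        return set(self.de_proteins)


# ---------------------------------------------------------------------------
# count simulation


def simulate_counts(
    config: CountSimConfig,
) -> tuple[SpectralCountMatrix, ProteinAnnotationTable, SimulationTruth]:
    """Draw a paired PT/LT spectral-count matrix with planted differentials."""
    rng = np.random.default_rng(config.seed)
    n, k = config.n_proteins, config.n_cases
    accessions = np.array([f"SIM{i:05d}" for i in range(n)])

    lengths = np.maximum(
        50,
        np.round(
            rng.lognormal(np.log(config.length_median), config.length_sigma, n)
        ).astype(int),
    )
    lam = rng.lognormal(np.log(config.abundance_median), config.abundance_sigma, n)
    if config.length_proportional:
        lam = lam * lengths / config.length_median

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    de_dir = rng.choice(np.array(["PT", "LT"]), size=n_de)

    lam_pt = lam.copy()
    lam_lt = lam.copy() * config.lt_depth_factor
    for idx, d in zip(de_idx, de_dir):
        if d == "LT":
            lam_lt[idx] *= config.de_fold
        else:
            lam_pt[idx] *= config.de_fold

    sample_ids, groups, cases, columns = [], [], [], []
    for group, lam_g in (("PT", lam_pt), ("LT", lam_lt)):
        for c in range(k):
            depth = (
                rng.lognormal(0.0, config.sample_depth_sigma)
                if config.sample_depth_sigma > 0
                else 1.0
            )
            lam_s = lam_g * depth
            detected = rng.random(n) >= config.dropout.dropout_prob(lam_s)
            counts = np.where(detected, rng.poisson(lam_s), 0)
            sample_ids.append(f"{group}_{c + 1:02d}")
            groups.append(group)
            cases.append(f"case_{c + 1:02d}")
            columns.append(counts)

    counts_df = pd.DataFrame(
        np.column_stack(columns), index=pd.Index(accessions, name="accession"),
        columns=sample_ids, dtype=np.int64,
    )
    matrix = SpectralCountMatrix(
        counts_df,
        pd.Series(groups, index=sample_ids, name="group"),
        pd.Series(cases, index=sample_ids, name="case"),
    )
    ann = ProteinAnnotationTable(
        pd.DataFrame(
            {"length": lengths, "symbol": accessions, "description": ""},
            index=pd.Index(accessions, name="accession"),
        )
    )
    truth = SimulationTruth(
        de_proteins={
            accessions[idx]: (d, config.de_fold) for idx, d in zip(de_idx, de_dir)
        }
    )
    return matrix, ann, truth


def venn_calibrated_config(
    n_proteins: int = 6000, n_cases: int = 7, seed: int = 0, **overrides
) -> CountSimConfig:
    """Generator configuration calibrated so the PT-only / LT-only / shared
    identification partition matches the observed discovery-set structure
    (roughly 20% / 30% / 50% of the union, with LT the deeper group).

    The calibrated parameters are a packaged fixture
    (``fixtures/venn_calibration.json``).
    """
    ref = resources.files("specount") / "fixtures" / "venn_calibration.json"
    params = json.loads(ref.read_text())
    params.pop("target_fractions", None)
    params.update(overrides)
    return CountSimConfig(n_proteins=n_proteins, n_cases=n_cases, seed=seed, **params)


# ---------------------------------------------------------------------------
# cohort simulation


def _draw_event_times(rng, hazard: tuple, lp: np.ndarray) -> np.ndarray:
    u = rng.random(lp.size)
    if hazard[0] == "exponential":
        rate = hazard[1] * np.exp(lp)
        return -np.log(u) / rate
    scale, shape = hazard[1], hazard[2]  # h(t) = scale*shape*t^(shape-1)*exp(lp)
    return (-np.log(u) / (scale * np.exp(lp))) ** (1.0 / shape)


def _draw_censoring(rng, law: tuple, size: int) -> np.ndarray:
    if law[0] == "fixed":
        return np.full(size, float(law[1]))
    return rng.uniform(law[1], law[2], size)


def simulate_cohort(config: CohortSimConfig) -> tuple[CohortTable, SimulationTruth]:
    """Draw a patient cohort under the planted proportional-hazards model."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    sync = rng.random(n) < config.sync_probability

    shift = np.where(sync, config.sync_covariate_shift, 1.0)
    ki67 = np.clip(
        rng.lognormal(np.log(config.ki67_median), config.ki67_sigma, n) * shift,
        0.1, 95.0,
    )
    size = np.round(
        np.clip(
            rng.lognormal(np.log(config.size_median_mm), config.size_sigma, n) * shift,
            5.0, 160.0,
        )
    )  # whole millimetres, as recorded clinically; the hazard uses the same value
    rates = config.marker_positive_rate_by_group
    marker = np.where(
        sync,
        rng.random(n) < rates["synchronous"],
        rng.random(n) < rates["at_risk"],
    ).astype(int)
    invasion = {
        col: (rng.random(n) < rate).astype(int)
        for col, rate in config.invasion_rates.items()
    }

    size_high = (size >= config.size_cutoff_mm).astype(int)
    lp = config.marker_log_hr * marker + config.size_log_hr * size_high
    event_time = _draw_event_times(rng, config.baseline_hazard, lp)
    censor_time = _draw_censoring(rng, config.censoring_law, n)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    group = np.where(sync, "synchronous", np.where(event == 1, "metachronous", "none"))
    # month-resolution follow-up, floored at 0.1 so times stay positive
    rfs = np.where(sync, np.nan, np.maximum(np.round(observed, 1), 0.1))
    recurrence = np.where(sync, np.nan, event)

    # overall survival: recurrence shortens life; otherwise administrative
    post = rng.exponential(36.0, n)
    os_months = np.maximum(
        np.round(np.where(sync, censor_time * 0.6,
                          np.where(event == 1, observed + post, observed)), 1),
        0.1,
    )
    death = ((sync | (event == 1)) & (rng.random(n) < 0.5)).astype(int)

    grade = np.select(
        [ki67 < 3.0, ki67 < 20.0], ["G1", "G2"], default="G3"
    )
    stage = np.select(
        [sync, size >= 40, size >= 20], ["IV", "III", "II"], default="I"
    )
    mitoses = rng.poisson(np.clip(ki67 / 4.0, 0.2, 10.0))

    table = pd.DataFrame(
        {
            "patient_id": [f"PX{i + 1:04d}" for i in range(n)],
            "group": group,
            "gender": rng.choice(np.array(["male", "female"]), n),
            "age": rng.integers(25, 85, n),
            "function_type": rng.choice(
                np.array(["NF", "insulinoma", "gastrinoma"]), n, p=[0.7, 0.2, 0.1]
            ),
            "who_grade": grade,
            "ki67": np.round(ki67, 1),
            "mitotic_count": mitoses,
            "tumor_size_mm": size,
            "lymph_node_metastasis": invasion["lymph_node_metastasis"],
            "vascular_invasion": invasion["vascular_invasion"],
            "lymphatic_invasion": invasion["lymphatic_invasion"],
            "enets_stage": stage,
            f"marker_{config.marker_name}": marker,
            "liver_rfs_months": rfs,
            "liver_recurrence": recurrence,
            "os_months": os_months,
            "death": death,
        }
    )
    truth = SimulationTruth(
        planted_hrs={
            f"marker_{config.marker_name}": float(np.exp(config.marker_log_hr)),
            "size_high": float(np.exp(config.size_log_hr)),
        }
    )
    return CohortTable(table), truth


def write_config(config, path: str | Path) -> None:
    """Echo a simulation config (including seed) as JSON next to its output."""
    with open(path, "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=str)
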