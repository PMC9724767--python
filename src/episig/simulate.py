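"""Synthetic methylation cohorts with planted episignatures.

Emulates the data layout of an EPIC-style case/control study: a small case
group carrying a planted differentially-methylated probe set, a large
healthy-control pool, and a background cohort of samples with unrelated
rare disorders, plus age, sex and batch nuisance structure.  Probe counts
are scaled down from array scale (~850k) to desk scale (10k-50k) — the
statistical geometry (tiny case group, strong per-probe effects, bimodal
baseline betas, logit-scale noise) is what downstream stages consume.

Generation model, per probe ``p`` and sample ``i`` on the log2-logit scale::

    M_pi = mu_p + plant_pi + age/sex/batch terms + Normal(0, noise_sd)
    beta_pi = 2**M_pi / (1 + 2**M_pi)

Baseline means ``mu_p`` come from a three-component mixture of mostly
unmethylated (~0.1), intermediate (~0.5) and mostly methylated (~0.9)
probes.  The planted case effect is expressed as a target mean difference
``delta_beta`` on the beta scale and solved on the logit scale per probe;
the shift direction is flipped per probe when the shifted mean would leave
the representable beta range, so planted probes are a mix of hyper- and
hypomethylated, as in real episignatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .preprocess import logit_clip, inverse_logit

# beta range representable by the generator before logit conversion
_CLIP_LO = 0.03
_CLIP_HI = 0.97
_CLIP_TOLERANCE = 0.02

_MIXTURE_CENTERS = (0.1, 0.5, 0.9)
_MIXTURE_WEIGHTS = (0.35, 0.30, 0.35)
_MIXTURE_JITTER_SD = 0.04


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic cohort.

    Defaults encode the study geometry the pipeline targets: 8 cases, a
    200-sample healthy control pool for matching, a 270-sample background
    of unaffected controls and other-disorder samples, 20k probes with a
    175-probe planted signature at a 0.2 beta effect, and logit-scale
    noise of 0.4 log2 units.
    """

    n_probes: int = 20_000
    n_signature_probes: int = 175
    delta_beta: float = 0.2
    n_cases: int = 8
    n_controls: int = 200
    n_reference: int = 270
    #: optional second case group carrying a DISJOINT planted signature,
    #: for experiments contrasting two episignatures
    n_cases_alt: int = 0
    age_range: tuple[float, float] = (10.0, 80.0)
    sex_ratio: float = 0.5
    noise_sd: float = 0.4
    n_age_probes: int = 1000
    age_slope: float = 0.02
    n_sex_probes: int = 500
    sex_shift: float = 2.0
    n_batch_probes: int = 500
    batch_shift: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signature_probes > self.n_probes:
            raise ValueError("n_signature_probes must be <= n_probes")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not -1.0 <= self.delta_beta <= 1.0:
            raise ValueError("delta_beta must be in [-1, 1]")
        for name in ("n_probes", "n_cases", "n_controls", "n_reference",
                     "n_cases_alt", "n_age_probes", "n_sex_probes",
                     "n_batch_probes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class PlantedTruth:
    """Ground truth of a simulated cohort: which probes carry which effect.

    Probe sets may overlap (a signature probe can also drift with age);
    overlaps are recorded, not forbidden.
    """

    signature_probe_ids: list[str]
    alt_signature_probe_ids: list[str] = field(default_factory=list)
    age_probe_ids: list[str] = field(default_factory=list)
    sex_probe_ids: list[str] = field(default_factory=list)
    batch_probe_ids: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _planted_target(baseline: np.ndarray, delta: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Shifted case means on the beta scale, flipping direction to stay in range.

    Returns (targets, clipped_flag) where clipped_flag marks probes whose
    achievable shift falls short of |delta| by more than the clip tolerance.
    """
    sign = np.where(rng.random(baseline.shape) < 0.5, 1.0, -1.0) * np.sign(delta or 1.0)
    up = baseline + sign * abs(delta)
    flip = (up < _CLIP_LO) | (up > _CLIP_HI)
    sign[flip] *= -1.0
    target = np.clip(baseline + sign * abs(delta), _CLIP_LO, _CLIP_HI)
    clipped = np.abs(target - baseline) < abs(delta) - _CLIP_TOLERANCE
    return target, clipped


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Generate (beta matrix, sample sheet, planted truth) for one cohort.

    Fully determined by ``config.seed``: child random streams are spawned
    in a fixed order, so repeated calls are bit-identical.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_probes, rng_samples, rng_plant, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    probe_ids = np.array([f"cg{i:08d}" for i in range(config.n_probes)])

    # baseline probe means: three-component mixture with jitter
    component = rng_probes.choice(3, size=config.n_probes, p=_MIXTURE_WEIGHTS)
    centers = np.asarray(_MIXTURE_CENTERS)[component]
    baseline = np.clip(
        centers + rng_probes.normal(0.0, _MIXTURE_JITTER_SD, config.n_probes),
        _CLIP_LO, _CLIP_HI,
    )

    # nuisance and signature probe assignments (disjoint signatures;
    # nuisance sets drawn independently and may overlap anything)
    n_sig_total = config.n_signature_probes * (2 if config.n_cases_alt else 1)
    sig_all = rng_probes.choice(config.n_probes, size=n_sig_total, replace=False)
    sig_idx = sig_all[: config.n_signature_probes]
    alt_idx = sig_all[config.n_signature_probes:]
    # nuisance counts cap at the probe count so scaled-down cohorts work
    age_idx = rng_probes.choice(
        config.n_probes, size=min(config.n_age_probes, config.n_probes),
        replace=False)
    sex_idx = rng_probes.choice(
        config.n_probes, size=min(config.n_sex_probes, config.n_probes),
        replace=False)
    batch_idx = rng_probes.choice(
        config.n_probes, size=min(config.n_batch_probes, config.n_probes),
        replace=False)

    # sample sheet
    groups = (
        ["case"] * config.n_cases
        + ["case_alt"] * config.n_cases_alt
        + ["control"] * config.n_controls
        + ["reference_disorder"] * config.n_reference
    )
    n_samples = len(groups)
    sample_ids = (
        [f"case_{i + 1:03d}" for i in range(config.n_cases)]
        + [f"alt_{i + 1:03d}" for i in range(config.n_cases_alt)]
        + [f"ctrl_{i + 1:03d}" for i in range(config.n_controls)]
        + [f"ref_{i + 1:03d}" for i in range(config.n_reference)]
    )
    lo, hi = config.age_range
    ages = rng_samples.uniform(lo, hi, n_samples)
    sexes = np.where(rng_samples.random(n_samples) < config.sex_ratio, "F", "M")
    batches = np.where(rng_samples.random(n_samples) < 0.5, "B1", "B2")
    sheet = pd.DataFrame(
        {"sample_id": sample_ids, "group": groups, "age": np.round(ages, 1),
         "sex": sexes, "batch": batches}
    )

    # latent means on log2-logit scale: probes x samples
    latent = np.tile(logit_clip(baseline, _CLIP_LO)[:, None], (1, n_samples))

    warnings: list[str] = []
    is_case = np.asarray([g == "case" for g in groups])
    is_alt = np.asarray([g == "case_alt" for g in groups])
    for idx, mask, label in ((sig_idx, is_case, "signature"),
                             (alt_idx, is_alt, "alt signature")):
        if len(idx) == 0 or not mask.any() or config.delta_beta == 0:
            continue
        target, clipped = _planted_target(baseline[idx], config.delta_beta, rng_plant)
        latent[np.ix_(idx, np.flatnonzero(mask))] = logit_clip(target, _CLIP_LO)[:, None]
        if clipped.any():
            warnings.append(
                f"{int(clipped.sum())} {label} probes clipped beyond tolerance; "
                f"achievable |delta_beta| reduced"
            )

    # nuisance terms affect ALL samples on their designated probes
    age_centered = ages - (lo + hi) / 2.0
    latent[np.ix_(age_idx, np.arange(n_samples))] += (
        config.age_slope * age_centered[None, :]
    )
    is_f = sexes == "F"
    latent[np.ix_(sex_idx, np.flatnonzero(is_f))] += config.sex_shift
    if config.batch_shift != 0:
        in_b2 = batches == "B2"
        latent[np.ix_(batch_idx, np.flatnonzero(in_b2))] += config.batch_shift

    noise = rng_noise.normal(0.0, config.noise_sd, latent.shape)
    beta_values = inverse_logit(latent + noise)

    beta = pd.DataFrame(beta_values, index=pd.Index(probe_ids, name="probe_id"),
                        columns=sample_ids)
    truth = PlantedTruth(
        signature_probe_ids=list(probe_ids[sig_idx]),
        alt_signature_probe_ids=list(probe_ids[alt_idx]),
        age_probe_ids=list(probe_ids[age_idx]),
        sex_probe_ids=list(probe_ids[sex_idx]),
        batch_probe_ids=list(probe_ids[batch_idx]),
        warnings=warnings,
    )
    return beta, sheet, truth
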