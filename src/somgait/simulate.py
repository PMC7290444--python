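"""Synthetic gait-cohort generator.

Emulates a pediatric movement-analysis dataset: typically developing (TD)
limbs are smooth, periodic joint-angle templates plus small inter-limb
noise; pathological limbs add archetype-specific one-sided deviations on
top of the same template.  The five archetypes mirror clinically described
cerebral-palsy gait patterns:

* ``mild``          - near-TD gait with extra swing-phase knee flexion,
                      pelvic obliquity and mildly reduced plantarflexion;
* ``external_foot`` - strongly out-toeing gait with pelvic retraction;
* ``crouch``        - persistent hip/knee flexion with excess dorsiflexion
                      and anterior pelvic tilt;
* ``rotational``    - marked hip rotation and ab/adduction asymmetry;
* ``jump``          - equinus (plantarflexed ankle), reduced swing knee
                      flexion, anterior tilt and in-toeing.

Per-limb noise has two components: a constant per-variable offset between
limbs (marker-placement-like) and a smooth low-order random waveform within
the curve, with a combined per-variable RMS of about 2 degrees at the
defaults.  Deviation amplitudes default to 1.5-2x that noise SD (3 degrees
for secondary features, 4 for pattern-defining ones) so the archetypes are
recoverable by clustering without being trivially separated.
Paired orthosis trials are produced by shrinking a limb's whole deviation
(archetype + noise) multiplicatively, with the per-limb shrink factor
chosen so the expected gait-profile-score change matches the archetype's
configured orthosis effect; negative effects (worsening) are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GaitCycle, ReferenceProfile, KINEMATIC_VARIABLES, N_SAMPLES, GRID_PERCENT
from .scores import compute_gvs, compute_gps

#: Upper bound on |second difference| of any template curve (deg/sample^2).
TEMPLATE_MAX_CURVATURE = 1.0

_THETA = 2.0 * np.pi * GRID_PERCENT / 100.0

#: Low-order Fourier coefficients of the TD template, per variable:
#: (offset, [(harmonic, cos_amp, sin_amp), ...]) in degrees.  Magnitudes are
#: physiologic for a self-selected-speed pediatric gait cycle; integer
#: harmonics keep every curve exactly periodic (value at 0% == 100%).
_TD_FOURIER: dict[str, tuple[float, list[tuple[int, float, float]]]] = {
    "pelvic_tilt": (12.0, [(2, 1.2, 0.8)]),
    "pelvic_obliquity": (0.0, [(1, 1.0, 3.0)]),
    "pelvic_rotation": (0.0, [(1, 2.0, 4.0)]),
    "hip_flexion": (12.0, [(1, 23.0, 6.0), (2, 0.0, 3.0)]),
    "hip_abdadd": (1.0, [(1, 3.0, 2.0)]),
    "hip_rotation": (2.0, [(1, 1.5, 2.5)]),
    "knee_flexion": (26.0, [(1, -18.0, 6.0), (2, -8.0, 4.0)]),
    "ankle_dorsiflexion": (1.0, [(1, 0.0, 6.0), (2, -5.0, 0.0)]),
    "foot_progression": (-8.0, [(1, 1.0, 1.5)]),
}

#: Smooth unit deviation shapes over the cycle, bounded in [-1, 1].
_SHAPES: dict[str, np.ndarray] = {
    "constant": np.ones(N_SAMPLES),
    "early_stance": np.exp(-((GRID_PERCENT - 15.0) ** 2) / (2.0 * 8.0**2)),
    "swing": np.exp(-((GRID_PERCENT - 75.0) ** 2) / (2.0 * 10.0**2)),
    "ramp": GRID_PERCENT / 100.0,
}


@dataclass
class ArchetypeSpec:
    """One pathological gait pattern as planted curve deviations.

    ``deviations`` maps a kinematic variable to (amplitude_deg, shape_name,
    sign); sign +1 plants deviation toward flexion / dorsiflexion / inward
    progression, -1 toward the opposite side.  Deviations are one-sided per
    variable so the directional-score ground truth is unambiguous: the shape
    is rescaled to unit RMS over the cycle, so at zero noise the planted
    one-sided score equals the amplitude exactly (peaked shapes such as the
    swing bump therefore exceed the amplitude at their peak).
    """

    name: str
    deviations: dict[str, tuple[float, str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var, (amp, shape, sign) in self.deviations.items():
            if var not in KINEMATIC_VARIABLES:
                raise ValueError(f"{self.name}: unknown variable {var}")
            if amp < 0:
                raise ValueError(f"{self.name}/{var}: amplitude must be >= 0")
            if shape not in _SHAPES:
                raise ValueError(f"{self.name}/{var}: unknown shape {shape}")
            if sign not in (-1, 1):
                raise ValueError(f"{self.name}/{var}: sign must be +/-1")

    def deviation_curves(self, scale: float = 1.0) -> dict[str, np.ndarray]:
        out = {v: np.zeros(N_SAMPLES) for v in KINEMATIC_VARIABLES}
        for var, (amp, shape, sign) in self.deviations.items():
            unit = _SHAPES[shape]
            unit = unit / np.sqrt(np.mean(unit**2))  # unit-RMS waveform
            out[var] = out[var] + scale * amp * sign * unit
        return out


#: Default archetype battery: amplitudes are 3 deg (secondary features,
#: 1.5x the default total noise SD of ~2 deg) or 4 deg (defining features, 2x).
ARCHETYPES: dict[str, ArchetypeSpec] = {
    # near-TD gait: extra swing knee flexion, pelvic obliquity, and mildly
    # reduced push-off plantarflexion (planted as early-stance dorsiflexion)
    "mild": ArchetypeSpec(
        "mild",
        {
            "knee_flexion": (3.0, "swing", 1),
            "pelvic_obliquity": (3.0, "constant", 1),
            "ankle_dorsiflexion": (3.0, "early_stance", 1),
        },
    ),
    # strongly out-toeing gait with pelvic retraction
    "external_foot": ArchetypeSpec(
        "external_foot",
        {
            "foot_progression": (4.0, "constant", -1),
            "pelvic_rotation": (3.0, "constant", 1),
        },
    ),
    # crouch: persistent hip and knee flexion with excess dorsiflexion and
    # anterior pelvic tilt
    "crouch": ArchetypeSpec(
        "crouch",
        {
            "hip_flexion": (4.0, "constant", 1),
            "knee_flexion": (4.0, "constant", 1),
            "ankle_dorsiflexion": (3.0, "constant", 1),
            "pelvic_tilt": (3.0, "constant", 1),
        },
    ),
    # asymmetric rotational pattern: dominant hip rotation and ab/adduction
    "rotational": ArchetypeSpec(
        "rotational",
        {
            "hip_rotation": (4.0, "constant", 1),
            "hip_abdadd": (4.0, "constant", 1),
        },
    ),
    # jump/equinus: plantarflexed ankle, reduced swing knee flexion,
    # anterior tilt and in-toeing
    "jump": ArchetypeSpec(
        "jump",
        {
            "ankle_dorsiflexion": (4.0, "constant", -1),
            "knee_flexion": (3.0, "swing", -1),
            "pelvic_tilt": (3.0, "constant", 1),
            "foot_progression": (4.0, "constant", 1),
        },
    ),
}

#: The TD archetype: no planted deviation.
TD_ARCHETYPE = ArchetypeSpec("TD", {})

#: Orthosis designs sampled for prescribed CP limbs, with probabilities
#: mirroring a typical clinical prescription mix (posterior leaf springs
#: dominate).
_ORTHOSIS_TYPES = ("GRAFO", "PLS", "solid", "hinged", "other")
_ORTHOSIS_PROBS = (0.065, 0.698, 0.151, 0.050, 0.036)


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults emulate the modeled clinical cohort scale: 25 TD children
    contributing both limbs plus 40 limbs per pathological archetype, each
    limb treated as an independent observation.
    """

    n_td_children: int = 25
    n_limbs_per_archetype: int = 40
    inter_limb_noise_sd: float = 1.0  # deg; constant per-variable offset per limb
    smooth_noise_scale: float = 1.7  # deg; RMS of smooth within-curve noise
    orthosis_fraction: float = 0.7  # share of CP limbs with a prescribed orthosis
    # mean GPS change per archetype, chosen so that with the default spread
    # roughly 30-55% of prescribed limbs improve (orthoses help only part of
    # a clinical caseload) and improved limbs gain ~1 GPS point on average
    orthosis_effect: dict[str, float] = field(
        default_factory=lambda: {
            "mild": -0.8,
            "external_foot": 0.15,
            "crouch": -0.45,
            "rotational": -0.45,
            "jump": 0.0,
        }
    )
    orthosis_effect_sd: float = 1.5  # deg; per-limb spread of the GPS change
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_td_children < 0 or self.n_limbs_per_archetype < 0:
            raise ValueError("cohort counts must be non-negative")
        if self.inter_limb_noise_sd < 0 or self.smooth_noise_scale < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.orthosis_fraction <= 1.0:
            raise ValueError("orthosis_fraction must lie in [0, 1]")


def make_td_template() -> dict[str, np.ndarray]:
    """The noiseless TD gait cycle: 9 smooth periodic curves in degrees."""
    out = {}
    for var, (offset, harmonics) in _TD_FOURIER.items():
        curve = np.full(N_SAMPLES, offset)
        for h, ca, sa in harmonics:
            curve = curve + ca * np.cos(h * _THETA) + sa * np.sin(h * _THETA)
        out[var] = curve
    return out


def template_reference() -> ReferenceProfile:
    """The TD template wrapped as a (zero-SD) reference profile."""
    tmpl = make_td_template()
    return ReferenceProfile(
        mean_curves=dict(tmpl),
        sd_curves={v: np.zeros(N_SAMPLES) for v in KINEMATIC_VARIABLES},
        n_limbs=1,
    )


def _smooth_noise(rng: np.random.Generator, scale: float) -> np.ndarray:
    """Random low-order Fourier series with RMS approximately ``scale`` deg."""
    if scale == 0.0:
        return np.zeros(N_SAMPLES)
    # offset + 3 harmonics; coefficient SD scale/2 gives E[RMS^2] ~= scale^2
    c = rng.normal(0.0, scale / 2.0, size=7)
    curve = np.full(N_SAMPLES, c[0])
    for h in (1, 2, 3):
        curve = curve + c[2 * h - 1] * np.cos(h * _THETA) + c[2 * h] * np.sin(h * _THETA)
    return curve


def _limb_noise(config: CohortConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    noise = {}
    for v in KINEMATIC_VARIABLES:
        offset = rng.normal(0.0, config.inter_limb_noise_sd)
        noise[v] = offset + _smooth_noise(rng, config.smooth_noise_scale)
    return noise


def sample_limb(
    archetype: ArchetypeSpec,
    config: CohortConfig,
    rng: np.random.Generator,
    *,
    limb_id: str,
    subject_id: str,
    side: str,
    cohort: str,
) -> tuple[GaitCycle, dict[str, np.ndarray]]:
    """Draw one barefoot limb: template + archetype deviation + noise.

    Returns the cycle and its total deviation from the template (the
    generator's ground truth, reused to build the paired orthosis trial).
    """
    tmpl = make_td_template()
    planted = archetype.deviation_curves()
    noise = _limb_noise(config, rng)
    deviation = {v: planted[v] + noise[v] for v in KINEMATIC_VARIABLES}
    curves = {v: tmpl[v] + deviation[v] for v in KINEMATIC_VARIABLES}
    cycle = GaitCycle(
        limb_id=limb_id,
        subject_id=subject_id,
        side=side,
        cohort=cohort,
        condition="barefoot",
        orthosis_type="none",
        curves=curves,
    )
    return cycle, deviation


def _orthosis_pair(
    barefoot: GaitCycle,
    deviation: dict[str, np.ndarray],
    orthosis_type: str,
    target_delta: float,
) -> GaitCycle:
    """Paired orthosis trial: deviations shrunk to hit the target GPS change.

    The limb's GPS against the noiseless template scales linearly with the
    deviation scale s, so s = 1 - delta/GPS_barefoot yields an expected
    GPS change of ``target_delta`` (clamped at s = 0, full correction).
    """
    ref = template_reference()
    gps_bare = compute_gps(compute_gvs(barefoot, ref)).gps
    s = 1.0 if gps_bare <= 0 else max(0.0, 1.0 - target_delta / gps_bare)
    tmpl = make_td_template()
    curves = {v: tmpl[v] + s * deviation[v] for v in KINEMATIC_VARIABLES}
    return GaitCycle(
        limb_id=barefoot.limb_id,
        subject_id=barefoot.subject_id,
        side=barefoot.side,
        cohort=barefoot.cohort,
        condition="orthosis",
        orthosis_type=orthosis_type,
        curves=curves,
    )


def generate_cohort(config: CohortConfig | None = None) -> tuple[list[GaitCycle], pd.DataFrame]:
    """Full labeled cohort: TD limbs, five archetypes, paired orthosis trials.

    Returns the cycles (barefoot for all limbs; an additional orthosis
    condition for prescribed CP limbs) and a truth table with one row per
    limb: limb_id, archetype, orthosis_type, target_delta_gps.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    cycles: list[GaitCycle] = []
    truth_rows = []

    for child in range(config.n_td_children):
        for side in ("left", "right"):
            limb_id = f"TD{child:03d}_{side[0].upper()}"
            cycle, _ = sample_limb(
                TD_ARCHETYPE,
                config,
                rng,
                limb_id=limb_id,
                subject_id=f"TD{child:03d}",
                side=side,
                cohort="TD",
            )
            cycles.append(cycle)
            truth_rows.append(
                {"limb_id": limb_id, "archetype": "TD", "orthosis_type": "none",
                 "target_delta_gps": np.nan}
            )

    for name, spec in ARCHETYPES.items():
        effect_mean = config.orthosis_effect.get(name, 0.0)
        for i in range(config.n_limbs_per_archetype):
            side = "left" if i % 2 == 0 else "right"
            subject = f"CP_{name}_{i // 2:03d}"
            limb_id = f"{subject}_{side[0].upper()}"
            cycle, deviation = sample_limb(
                spec, config, rng,
                limb_id=limb_id, subject_id=subject, side=side, cohort="CP",
            )
            prescribed = rng.random() < config.orthosis_fraction
            otype = "none"
            target = np.nan
            if prescribed:
                otype = _ORTHOSIS_TYPES[
                    rng.choice(len(_ORTHOSIS_TYPES), p=np.asarray(_ORTHOSIS_PROBS) /
                               np.sum(_ORTHOSIS_PROBS))
                ]
                target = rng.normal(effect_mean, config.orthosis_effect_sd)
                cycle = GaitCycle(
                    limb_id=cycle.limb_id,
                    subject_id=cycle.subject_id,
                    side=cycle.side,
                    cohort=cycle.cohort,
                    condition="barefoot",
                    orthosis_type=otype,  # prescription recorded on barefoot row too
                    curves=cycle.curves,
                )
                cycles.append(cycle)
                cycles.append(_orthosis_pair(cycle, deviation, otype, target))
            else:
                cycles.append(cycle)
            truth_rows.append(
                {"limb_id": limb_id, "archetype": name, "orthosis_type": otype,
                 "target_delta_gps": target}
            )

    truth = pd.DataFrame(truth_rows, columns=["limb_id", "archetype", "orthosis_type",
                                              "target_delta_gps"])
    return cycles, truth
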