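"""Synthetic paired pre/post serum NMR cohorts.

The generator emulates the statistical structure the downstream analysis
assumes, not the physics of acquisition.  Each virtual patient contributes
one pre-treatment and one post-treatment serum sample, each rendered on two
channels: a CPMG-like spectrum (all metabolites, sharp lines) and a
diffusion-edited-like spectrum (broad lipid signals only).  Signals are
Lorentzian mixtures on a descending ppm axis with a smooth Gaussian-hump
baseline and white noise; the alanine methyl signal is a 7 Hz doublet
(0.0175 ppm at 400 MHz), all other multiplets are collapsed to singlets.

Planted treatment structure
---------------------------
* Induction chemotherapy multiplies each metabolite's concentration by a
  fixed effect: lipids up (0.9/1.3/5.3 ppm), alanine, glucose and NAG down.
* Males carry elevated *pre-treatment* glucose and alanine; post levels
  converge across sexes, so the glucose/alanine decrease is male-driven.
* Three response subgroups: ``full`` responders carry the full effect;
  ``weak_A`` ("Red"-like) carry a strongly attenuated effect; ``weak_B``
  ("Green"-like) are equally attenuated but additionally *start* with a
  largely post-like metabolic profile (most visibly elevated lipids and
  lowered alanine) and a lower initial nodal stage.
* Tumour volumes are planted so that the radiological regression percentage
  correlates with the per-patient lipid (1.3 ppm) change in males only.

All randomness flows from one master seed; per-patient substreams are
spawned with fixed offsets so cohorts are reproducible under subsetting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import DEFAULT_PANEL, REGION_METABOLITE, PanelRegion
from .spectra import (CHANNEL_CPMG, CHANNEL_DIFF, TIMEPOINT_POST,
                      TIMEPOINT_PRE, Spectrum)

SUBGROUPS = ("full", "weak_A", "weak_B")

#: 7 Hz scalar coupling expressed in ppm at 400 MHz.
J_DOUBLET_PPM = 7.0 / 400.0


@dataclass(frozen=True)
class SignalSite:
    """One resonance of a metabolite: position, weight and line shape."""

    center_ppm: float
    weight: float  # fraction of the metabolite's intensity at this site
    multiplicity: int = 1
    lorentz_hw: float = 0.005  # Lorentzian half-width at half-maximum, ppm
    channels: tuple[str, ...] = (CHANNEL_CPMG,)


#: Spectral model: metabolite (concentration key) -> resonance sites.
#: Lipid lines appear on both channels (broader on the diffusion-edited one,
#: handled by a channel-dependent width factor below); small metabolites are
#: CPMG-only.  A few non-panel background metabolites make the spectra
#: realistic without carrying any treatment effect.
SIGNAL_MODEL: dict[str, tuple[SignalSite, ...]] = {
    "lipid_09": (SignalSite(0.90, 1.0, 1, 0.020, (CHANNEL_CPMG, CHANNEL_DIFF)),),
    "lipid_13": (SignalSite(1.30, 1.0, 1, 0.020, (CHANNEL_CPMG, CHANNEL_DIFF)),),
    "lipid_53": (SignalSite(5.30, 1.0, 1, 0.020, (CHANNEL_CPMG, CHANNEL_DIFF)),),
    "alanine": (SignalSite(1.48, 1.0, 2, 0.0035),),
    "nag": (SignalSite(2.07, 1.0, 1, 0.008),),
    "glucose": tuple(
        SignalSite(ppm, w, 1, 0.004)
        for ppm, w in zip(
            (3.24, 3.42, 3.44, 3.51, 3.56, 3.72, 3.76, 3.83, 3.90, 5.20),
            (0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10),
        )
    ),
    # background metabolites, no treatment effect
    "lactate": (SignalSite(1.33, 0.75, 2, 0.0035), SignalSite(4.11, 0.25, 1, 0.0035)),
    "creatinine": (SignalSite(3.04, 1.0, 1, 0.0035),),
    "citrate": (SignalSite(2.54, 0.5, 1, 0.005), SignalSite(2.66, 0.5, 1, 0.005)),
    "formate": (SignalSite(8.46, 1.0, 1, 0.0035),),
    "histidine": (SignalSite(7.05, 0.5, 1, 0.004), SignalSite(7.75, 0.5, 1, 0.004)),
}

#: Baseline concentrations, arbitrary units.
BASE_CONCENTRATIONS: dict[str, float] = {
    "lipid_09": 150.0,
    "lipid_13": 250.0,
    "lipid_53": 60.0,
    "alanine": 25.0,
    "nag": 40.0,
    "glucose": 120.0,
    "lactate": 60.0,
    "creatinine": 20.0,
    "citrate": 15.0,
    "formate": 2.0,
    "histidine": 5.0,
}

#: Post/pre effect multipliers implied by the observed between-class median
#: ratios (increase: 1/(1 - mr/100); decrease: 1 - mr/100).  Glucose and
#: alanine carry only a small common decrease here; the bulk of their drop
#: is male-specific and enters through the pre-treatment sex elevation.
DEFAULT_EFFECTS: dict[str, float] = {
    "lipid_09": 1.0281,
    "lipid_13": 1.0939,
    "lipid_53": 1.0797,
    "alanine": 0.96,
    "nag": 0.9097,
    "glucose": 0.97,
}

#: Male pre-treatment elevation of glucose and alanine (multiplicative).
DEFAULT_SEX_PRE_MULTIPLIERS: dict[str, float] = {"glucose": 1.10, "alanine": 1.15}


@dataclass
class EffectProfile:
    """Planted treatment-effect structure of a synthetic cohort.

    Attributes
    ----------
    effects
        Post/pre multiplicative change per metabolite key; metabolites not
        listed are unchanged.  The default profile has lipid changes > 1
        and alanine/glucose/NAG changes < 1.
    attenuation
        Response attenuation per weak subgroup, in [0, 1]; 1 = full effect,
        0 = no response.  Applied on the log scale (effect ** attenuation).
    weak_b_baseline_shift
        Fraction (in [0, 1]) of the full effect profile already present at
        baseline in the ``weak_B`` subgroup (1 = baseline at the
        full-response post level): elevated lipids, lowered alanine,
        glucose and NAG before treatment.
    sex_pre_multipliers
        Male pre-treatment elevation factors (metabolite key -> factor).
    biological_sd
        Between-patient log-SD of baseline concentrations.
    response_sd
        Per-patient, per-metabolite log-SD of the realised response.
    noise_sd
        Additive white noise SD per spectral point (intensity units).
    baseline_amplitude
        Amplitude of the smooth broad baseline hump.
    shift_sd
        SD of the random per-sample ppm calibration offset (corrected later
        by alanine referencing).
    """

    effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    attenuation: dict[str, float] = field(
        default_factory=lambda: {"weak_A": 0.15, "weak_B": 0.15})
    weak_b_baseline_shift: float = 0.8
    sex_pre_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEX_PRE_MULTIPLIERS))
    biological_sd: float = 0.04
    response_sd: float = 0.03
    noise_sd: float = 1.0
    baseline_amplitude: float = 5.0
    shift_sd: float = 0.002

    def __post_init__(self) -> None:
        for key, value in self.effects.items():
            if value <= 0:
                raise ValueError(f"effect for {key} must be positive")
        for grp, a in self.attenuation.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"attenuation for {grp} must be in [0, 1]")
        if not 0.0 <= self.weak_b_baseline_shift <= 1.0:
            raise ValueError("weak_b_baseline_shift must be in [0, 1]")


@dataclass
class CohortSpec:
    """Size and composition of a synthetic cohort.

    Defaults mirror the study cohort scale: 53 patients, 66% male, roughly
    64/19/17% full/weak_A/weak_B responders.
    """

    n_patients: int = 53
    male_fraction: float = 0.66
    proportions: tuple[float, float, float] = (34 / 53, 10 / 53, 9 / 53)
    n_points: int = 16384
    ppm_max: float = 9.3
    ppm_min: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not math.isclose(sum(self.proportions), 1.0, abs_tol=1e-9):
            raise ValueError("subgroup proportions must sum to 1")
        if any(p < 0 for p in self.proportions):
            raise ValueError("subgroup proportions must be nonnegative")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        # a 0.002 ppm grid over 9.0-0.5 ppm implies 4250 buckets; require at
        # least two raw points per bucket
        n_buckets = int((9.0 - 0.5) / 0.002 + 1e-9)
        if self.n_points < 2 * n_buckets:
            raise ValueError(
                f"n_points must be >= {2 * n_buckets} (2 points per 0.002 ppm bucket)")


def planted_effect_windows(tail_half_widths: float = 8.0
                           ) -> list[tuple[float, float]]:
    """ppm windows carrying planted treatment-effect signal.

    A Lorentzian line correlates with its metabolite's concentration far
    into its tails (correlation is amplitude-blind), so the support of a
    planted effect extends several line widths beyond the quantification
    region.  Each panel region's window is its integration region widened
    by ``tail_half_widths`` times the synthesis line width of the
    underlying resonance.
    """
    windows = []
    for region in DEFAULT_PANEL:
        met = REGION_METABOLITE[region.name]
        site = min(SIGNAL_MODEL[met],
                   key=lambda s: abs(s.center_ppm - region.center_ppm))
        pad = region.half_width + tail_half_widths * site.lorentz_hw
        windows.append((region.center_ppm - pad, region.center_ppm + pad))
    return windows


def _lorentz(x: np.ndarray, center: float, hw: float) -> np.ndarray:
    """Unit-area Lorentzian in ppm units (hw = half width at half maximum)."""
    return (hw / math.pi) / ((x - center) ** 2 + hw ** 2)


def _axis(n_points: int, ppm_max: float, ppm_min: float) -> np.ndarray:
    return np.linspace(ppm_max, ppm_min, n_points)


def generate_spectrum(
    concentrations: Mapping[str, float],
    panel: Sequence[PanelRegion] | None = None,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator | None = None,
    *,
    channel: str = CHANNEL_CPMG,
    baseline_amplitude: float = 5.0,
    shift: float = 0.0,
    n_points: int = 16384,
    ppm_max: float = 9.3,
    ppm_min: float = 0.2,
    signal_model: Mapping[str, tuple[SignalSite, ...]] | None = None,
    **ids,
) -> Spectrum:
    """Render one synthetic 1D spectrum from metabolite concentrations.

    Intensities are a sum of unit-area Lorentzian lines (one per resonance
    site and multiplet line), scaled by concentration, plus a smooth broad
    baseline and additive Gaussian noise.  Deterministic for a fixed seed.

    Parameters
    ----------
    concentrations
        Metabolite key -> nonnegative concentration (arbitrary units).
    panel
        Accepted for interface compatibility; resonance positions and line
        shapes come from ``signal_model`` (which covers the default panel).
    noise_sd, seed
        White-noise SD per point and RNG seed (int or Generator).
    channel
        ``"cpmg"`` renders all metabolites; ``"diff"`` renders only signals
        declaring the diffusion-edited channel, with 2x broader lines.
    shift
        Constant ppm mis-calibration added to the axis (referencing target).
    """
    del panel  # geometry comes from the signal model
    model = dict(signal_model) if signal_model is not None else SIGNAL_MODEL
    for key, conc in concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {key}")
    if ppm_max <= ppm_min:
        raise ValueError("ppm_max must exceed ppm_min (strictly monotone axis)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ppm = _axis(n_points, ppm_max, ppm_min)
    intensity = np.zeros(n_points)
    width_factor = 2.0 if channel == CHANNEL_DIFF else 1.0
    for key, conc in concentrations.items():
        if conc == 0 or key not in model:
            continue
        for site in model[key]:
            if channel not in site.channels and channel == CHANNEL_DIFF:
                continue
            hw = site.lorentz_hw * width_factor
            m = site.multiplicity
            if m == 1:
                centers = (site.center_ppm,)
            else:  # symmetric multiplet around the site center, 7 Hz spacing
                span = (m - 1) * J_DOUBLET_PPM
                centers = tuple(site.center_ppm - span / 2 + k * J_DOUBLET_PPM
                                for k in range(m))
            amp = conc * site.weight / m
            for c in centers:
                intensity += amp * _lorentz(ppm, c, hw)
    if baseline_amplitude:
        intensity += baseline_amplitude * np.exp(-0.5 * ((ppm - 4.7) / 1.8) ** 2)
    if noise_sd:
        intensity += rng.normal(0.0, noise_sd, n_points)
    return Spectrum(ppm + shift, intensity, channel=channel, **ids)


# ---------------------------------------------------------------------------
# cohort generation

_SITES = ("Oropharynx", "Nasopharynx", "Hypopharynx", "Larynx", "Other")
_SITE_P = (20 / 53, 12 / 53, 10 / 53, 9 / 53, 2 / 53)
_CT_STAGES = ("0", "1", "2", "3", "4")
_CT_P = (3 / 53, 5 / 53, 11 / 53, 23 / 53, 11 / 53)
_CN_STAGES = ("0", "1", "2", "2a", "2b", "2c", "3")
_CN_P = (5 / 53, 5 / 53, 11 / 53, 2 / 53, 9 / 53, 10 / 53, 11 / 53)
_CN_STAGES_LOWN = ("0", "1", "2a")
_CN_P_LOWN = (0.45, 0.40, 0.15)
_REGIMENS = ("TPF", "PF", "PC")
_REGIMEN_P = (23 / 53, 28 / 53, 2 / 53)
_CYCLES = (1, 2, 3, 4)
_CYCLES_P = (9 / 53, 6 / 53, 36 / 53, 2 / 53)
_AE_NAMES = ("anemia", "leukopenia", "neutropenia", "thrombocytopenia")


def _patient_rng(master_seed: int, index: int, stream: int) -> np.random.Generator:
    # fixed offsets: patient substreams independent of cohort size/order
    return np.random.default_rng(np.random.SeedSequence([master_seed, index, stream]))


def _sample_concentrations(profile: EffectProfile, rng: np.random.Generator,
                           male: bool, subgroup: str
                           ) -> tuple[dict[str, float], dict[str, float]]:
    """Return planted (pre, post) concentration dicts for one patient."""
    keys = list(BASE_CONCENTRATIONS)
    bio = {k: math.exp(rng.normal(0.0, profile.biological_sd)) for k in keys}
    pre = {k: BASE_CONCENTRATIONS[k] * bio[k] for k in keys}
    if male:
        for k, mult in profile.sex_pre_multipliers.items():
            pre[k] *= mult
    # full-response post level: common effect, sex elevation not re-applied
    post_full = {k: BASE_CONCENTRATIONS[k] * bio[k] * profile.effects.get(k, 1.0)
                 for k in keys}
    if subgroup == "weak_B":
        # post-like baseline: the whole effect profile (most visibly the
        # elevated lipids and lowered alanine) already partly in place
        s = profile.weak_b_baseline_shift
        for k in keys:
            if post_full[k] != pre[k]:
                pre[k] = pre[k] * (post_full[k] / pre[k]) ** s
    att = 1.0 if subgroup == "full" else profile.attenuation.get(subgroup, 1.0)
    post = {}
    for k in keys:
        ratio = post_full[k] / pre[k]
        noise = math.exp(rng.normal(0.0, profile.response_sd)) \
            if profile.response_sd else 1.0
        post[k] = pre[k] * ratio ** att * noise
    return pre, post


def _stage_num(stage: str) -> int:
    return int(stage[0])


def _tnm_group(ct: str, cn: str) -> str:
    """Coarse TNM v7 grouping for HNSCC from T and N (M0 assumed)."""
    t, n = _stage_num(ct), _stage_num(cn)
    if n == 3 or t == 4 and n >= 2:
        return "IVb"
    if t == 4 or n == 2:
        return "IVa"
    return "III"


def generate_cohort(
    spec: CohortSpec,
    profile: EffectProfile | None = None,
    *,
    render_spectra: bool = True,
) -> tuple[list[Spectrum], pd.DataFrame, pd.DataFrame]:
    """Generate a paired pre/post cohort.

    Returns
    -------
    spectra
        Four spectra per patient (pre/post x cpmg/diff), empty list when
        ``render_spectra`` is False.
    clinical
        One row per patient: sex, age, cT/cN/cM/yT/yN, tumour volumes,
        regimen, cycles, CTCAE grades.
    truth
        Planted ground truth: subgroup label, planted concentrations and
        per-metabolite log post/pre changes.
    """
    profile = profile if profile is not None else EffectProfile()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    n = spec.n_patients

    sexes = np.where(rng.random(n) < spec.male_fraction, "M", "F")
    subgroups = rng.choice(SUBGROUPS, size=n, p=spec.proportions)
    ages = np.clip(np.round(rng.normal(55, 12, n)), 22, 80).astype(int)

    spectra: list[Spectrum] = []
    clin_rows, truth_rows = [], []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        male = sexes[i] == "M"
        subgroup = str(subgroups[i])
        prng = _patient_rng(spec.seed, i, 1)
        pre, post = _sample_concentrations(profile, prng, male, subgroup)
        log_delta = {k: math.log(post[k] / pre[k]) for k in BASE_CONCENTRATIONS}

        if render_spectra:
            srng = _patient_rng(spec.seed, i, 2)
            for timepoint, conc in ((TIMEPOINT_PRE, pre), (TIMEPOINT_POST, post)):
                shift = srng.normal(0.0, profile.shift_sd) if profile.shift_sd else 0.0
                for channel in (CHANNEL_CPMG, CHANNEL_DIFF):
                    spectra.append(generate_spectrum(
                        conc,
                        noise_sd=profile.noise_sd,
                        seed=srng,
                        channel=channel,
                        baseline_amplitude=profile.baseline_amplitude,
                        shift=shift,
                        n_points=spec.n_points,
                        ppm_max=spec.ppm_max,
                        ppm_min=spec.ppm_min,
                        sample_id=f"{pid}_{timepoint}",
                        patient_id=pid,
                        timepoint=timepoint,
                    ))

        crng = _patient_rng(spec.seed, i, 3)
        # regression % coupled to the planted lipid 1.3 ppm change in males
        if male:
            reg = 55.0 + 380.0 * log_delta["lipid_13"] + crng.normal(0.0, 8.0)
        else:
            reg = 78.0 + crng.normal(0.0, 13.0)
        reg = float(np.clip(reg, -15.0, 100.0))
        pre_vol = float(np.exp(crng.normal(math.log(30.0), 0.5)))
        post_vol = max(pre_vol * (1.0 - reg / 100.0), 0.0)

        site = str(crng.choice(_SITES, p=_SITE_P))
        ct = str(crng.choice(_CT_STAGES, p=_CT_P))
        if subgroup == "weak_B":  # planted lower initial nodal stage
            cn = str(crng.choice(_CN_STAGES_LOWN, p=_CN_P_LOWN))
        else:
            cn = str(crng.choice(_CN_STAGES, p=_CN_P))
        downstage = 3 if reg >= 85 else 2 if reg >= 55 else 1 if reg >= 25 else 0
        yt = str(max(_stage_num(ct) - downstage, 0))
        n_down = max(downstage - int(crng.integers(0, 2)), 0)
        yn = str(max(_stage_num(cn) - n_down, 0))
        grades = {f"ctcae_{ae}": int(g) for ae, g in zip(
            _AE_NAMES, crng.choice([0, 1, 2, 3], size=4, p=[0.35, 0.35, 0.2, 0.1]))}

        clin_rows.append({
            "patient_id": pid, "sex": sexes[i], "age": int(ages[i]),
            "site": site, "cT": ct, "cN": cn, "cM": "0", "yT": yt, "yN": yn,
            "tnm_group": _tnm_group(ct, cn),
            "pre_volume_cm3": round(pre_vol, 3),
            "post_volume_cm3": round(post_vol, 3),
            "regimen": str(crng.choice(_REGIMENS, p=_REGIMEN_P)),
            "cycles": int(crng.choice(_CYCLES, p=_CYCLES_P)),
            **grades,
        })
        truth_rows.append({
            "patient_id": pid, "subgroup": subgroup, "sex": sexes[i],
            **{f"pre_{k}": v for k, v in pre.items()},
            **{f"post_{k}": v for k, v in post.items()},
            **{f"log_delta_{k}": v for k, v in log_delta.items()},
        })

    clinical = pd.DataFrame(clin_rows).set_index("patient_id")
    truth = pd.DataFrame(truth_rows).set_index("patient_id")
    return spectra, clinical, truth
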