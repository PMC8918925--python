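"""Synthetic 24-h AF RR-interval cohort generator.

Emulates two-class Holter cohorts (AF-induced heart failure vs AF
controls) at the beat-to-beat statistical level: a patient's RR stream
is a log-normally modulated AR(1) process around a circadian heart-rate
profile, with occasional artifact gaps.  Class effects live in the 24-h
mean heart rate, the RR coefficient of variation, the lag-1
autocorrelation of log-RR (which controls spectral complexity: higher
autocorrelation concentrates spectral power at low frequencies and
lowers spectral entropy), and the circadian modulation depth (blunted
in heart failure).

The generator makes no claim about ECG morphology or AV-node
physiology; it produces streams whose segment-level feature statistics
carry a tunable class signal, so the full analysis pipeline can be
exercised and calibrated without patient data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .rr_core import RRSeries, DAY_START_S, LABEL_POSITIVE, LABEL_NEGATIVE

#: 24-h mean heart rates (bpm) of the two classes, AF-HF first
DEFAULT_MEAN_HR = (91.6, 78.7)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Per-class pairs are ordered (AF-HF, control).

    n_per_class : patients per class (cohort of 2n).
    duration_h : recording length in hours, starting 08:00.
    mean_hr : per-class 24-h mean heart rate, bpm.
    hr_sd_bpm : between-patient SD of the mean heart rate, bpm.
    cv_rr : per-class coefficient of variation of RR (AF beat-to-beat
        irregularity; heart-failure patients run slightly lower).
    cv_sd : between-patient SD of the RR coefficient of variation.
    ar_rho : per-class lag-1 autocorrelation of log-RR; higher values
        lower the spectral entropy of the tachogram.
    rho_sd : between-patient SD of the log-RR autocorrelation.
    circadian_amp : per-class fractional day/night HR modulation
        (sinusoid peaking at 15:00); blunted in heart failure.
    night_attenuation : fraction by which the between-class gaps in
        mean HR, cv_rr and ar_rho shrink during the night window
        (22:00-08:00), emulating the compression of autonomic
        class differences during sleep.  The daytime HR gap is widened
        so that each class's 24-h mean heart rate stays exactly on its
        target; cv/rho gaps are simply attenuated at night.
    artifact_rate : expected artifact gaps per hour; a gap deletes the
        beats it covers and is represented as one long RR interval so
        beat timing stays exact.
    seed : master seed; fixed seed gives byte-identical cohorts.
    """

    n_per_class: int = 26
    duration_h: float = 24.0
    mean_hr: tuple[float, float] = DEFAULT_MEAN_HR
    hr_sd_bpm: float = 4.0
    cv_rr: tuple[float, float] = (0.15, 0.21)
    cv_sd: float = 0.035
    ar_rho: tuple[float, float] = (0.5, 0.0)
    rho_sd: float = 0.15
    circadian_amp: tuple[float, float] = (0.04, 0.10)
    night_attenuation: float = 0.6
    artifact_rate: float = 0.2
    gap_range_s: tuple[float, float] = (30.0, 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for hr in self.mean_hr:
            if not 30.0 < hr < 220.0:
                raise ValueError(f"mean_hr {hr} outside (30, 220) bpm")
        for cv in self.cv_rr:
            if cv <= 0:
                raise ValueError("cv_rr must be > 0")
        for rho in self.ar_rho:
            if not abs(rho) < 1:
                raise ValueError("|ar_rho| must be < 1")
        if self.n_per_class < 1 or self.duration_h <= 0:
            raise ValueError("n_per_class and duration_h must be positive")
        if not 0.0 <= self.night_attenuation <= 1.0:
            raise ValueError("night_attenuation must be in [0, 1]")

    def class_params(self, label: str) -> dict[str, float]:
        i = 0 if label == LABEL_POSITIVE else 1
        return {
            "mean_hr": self.mean_hr[i],
            "cv_rr": self.cv_rr[i],
            "ar_rho": self.ar_rho[i],
            "circadian_amp": self.circadian_amp[i],
        }

    def phase_params(self, label: str, is_day: bool) -> dict[str, float]:
        """Class parameters effective during the day or night window.

        Night pulls each class parameter toward the two-class midpoint
        by ``night_attenuation``; the day HR gap is widened so the
        14 h/10 h weighted mean of the two phases reproduces the class
        24-h target exactly.
        """
        p = self.class_params(label)
        att = self.night_attenuation
        mid = {
            "mean_hr": 0.5 * (self.mean_hr[0] + self.mean_hr[1]),
            "cv_rr": 0.5 * (self.cv_rr[0] + self.cv_rr[1]),
            "ar_rho": 0.5 * (self.ar_rho[0] + self.ar_rho[1]),
        }
        out = dict(p)
        hr_gap = p["mean_hr"] - mid["mean_hr"]
        if is_day:
            # (14*day_gap + 10*night_gap)/24 == gap, night_gap = (1-att)*gap
            out["mean_hr"] = mid["mean_hr"] + hr_gap * (24.0 - 10.0 * (1 - att)) / 14.0
        else:
            out["mean_hr"] = mid["mean_hr"] + hr_gap * (1 - att)
            out["cv_rr"] = mid["cv_rr"] + (p["cv_rr"] - mid["cv_rr"]) * (1 - att)
            out["ar_rho"] = mid["ar_rho"] + (p["ar_rho"] - mid["ar_rho"]) * (1 - att)
        return out


#: circadian acrophase (peak HR), seconds since midnight
ACROPHASE_S = 15 * 3600


def simulate_patient(
    config: CohortConfig,
    class_label: str,
    patient_seed: int,
    base_hr: float | None = None,
) -> RRSeries:
    """One patient's RR stream under the class's generative parameters.

    RR_n = (60000 / HR(t_n)) * exp(eps_n), where eps is a stationary
    AR(1) process in log space with unit multiplicative mean, and HR(t)
    carries the patient's base rate times a sinusoidal circadian term.
    Beats are generated until the recording duration is covered; gaps
    are injected as Poisson events.  ``base_hr`` overrides the
    patient's drawn base heart rate (the cohort wrapper uses this to
    pin the class mean exactly).
    """
    from scipy.signal import lfilter

    from .rr_core import circadian_tag_for

    p = config.class_params(class_label)
    rng = np.random.default_rng(patient_seed)
    drawn = p["mean_hr"] + config.hr_sd_bpm * rng.standard_normal()
    if base_hr is None:
        base_hr = drawn
    base_hr = float(np.clip(base_hr, 35.0, 215.0))
    hr_offset = base_hr - p["mean_hr"]  # patient-level deviation
    cv_offset = config.cv_sd * rng.standard_normal()
    rho_offset = config.rho_sd * rng.standard_normal()
    amp = p["circadian_amp"]
    duration_s = config.duration_h * 3600.0

    n_guess = int(duration_s * base_hr / 60.0 * 1.3) + 16
    z = rng.standard_normal(n_guess)

    # phase-aware generation: parameters are held fixed within short
    # beat chunks (~3 min, far below the circadian and day/night time
    # scales), which vectorises the otherwise sequential time update;
    # the AR(1) state in log space carries across chunk boundaries
    chunk = 256
    rr = np.empty(n_guess)
    t = 0.0
    n = 0
    eps_prev = None
    while n < n_guess and t < duration_s:
        hi = min(n + chunk, n_guess)
        clock = DAY_START_S + t
        phase = config.phase_params(class_label, circadian_tag_for(clock) == "day")
        rho = float(np.clip(phase["ar_rho"] + rho_offset, -0.9, 0.95))
        cv = max(phase["cv_rr"] + cv_offset, 1e-4)
        sigma = np.sqrt(np.log1p(cv**2))
        innov = sigma * np.sqrt(1.0 - rho**2) * z[n:hi]
        if eps_prev is None:
            innov = innov.copy()
            innov[0] = sigma * z[n]  # stationary start
            eps, zf = lfilter([1.0], [1.0, -rho], innov, zi=[0.0])
        else:
            eps, zf = lfilter([1.0], [1.0, -rho], innov, zi=[rho * eps_prev])
        eps_prev = float(eps[-1])
        noise = np.exp(eps - sigma**2 / 2.0)
        hr = (phase["mean_hr"] + hr_offset) * (
            1.0 + amp * np.cos(2.0 * np.pi * (clock - ACROPHASE_S) / 86_400.0)
        )
        vals = 60_000.0 / hr * noise
        rr[n:hi] = vals
        t += float(vals.sum()) / 1000.0
        n = hi
    # trim beats past the requested duration
    onsets = np.concatenate(([0.0], np.cumsum(rr[1 : n]) / 1000.0))
    n = int(np.searchsorted(onsets, duration_s, side="left"))
    n = max(n, 2)
    rr = rr[:n]

    # artifact gaps: delete covered beats; the interval after a gap
    # absorbs the deleted beats' total duration so cumulative beat
    # timing stays exact
    n_gaps = rng.poisson(config.artifact_rate * config.duration_h)
    if n_gaps > 0:
        starts = np.sort(rng.uniform(0.0, duration_s, size=n_gaps))
        lengths = rng.uniform(*config.gap_range_s, size=n_gaps)
        onsets = np.concatenate(([0.0], np.cumsum(rr[1:]) / 1000.0))
        keep = np.ones(n, dtype=bool)
        for s0, glen in zip(starts, lengths):
            covered = (onsets > s0) & (onsets <= s0 + glen) & keep
            covered[0] = False
            idx = np.nonzero(covered)[0]
            if idx.size == 0 or idx[-1] + 1 >= n:
                continue
            keep[idx] = False
            rr[idx[-1] + 1] += float(rr[idx].sum())
        rr = rr[keep]

    return RRSeries(
        patient_id=f"p{patient_seed}",
        label=class_label,
        rr=rr,
        start_clock=float(DAY_START_S),
    )


def simulate_cohort(config: CohortConfig) -> tuple[list[RRSeries], dict]:
    """Balanced two-class cohort plus a manifest of every parameter.

    Per-patient seeds are spawned deterministically from the master
    seed, so the same config reproduces byte-identical streams.
    """
    master = np.random.default_rng(config.seed)
    patient_seeds = master.integers(0, 2**31 - 1, size=2 * config.n_per_class)
    series: list[RRSeries] = []
    manifest: dict = {"config": _config_dict(config), "patients": []}
    k = 0
    for label, prefix in ((LABEL_POSITIVE, "HF"), (LABEL_NEGATIVE, "CTR")):
        # centred between-patient heterogeneity: the class sample mean
        # of base heart rates equals the class target exactly
        z = master.standard_normal(config.n_per_class)
        if config.n_per_class > 1:
            z = z - z.mean()
        base_hrs = config.class_params(label)["mean_hr"] + config.hr_sd_bpm * z
        for i in range(config.n_per_class):
            seed_i = int(patient_seeds[k])
            s = simulate_patient(config, label, seed_i, base_hr=float(base_hrs[i]))
            s = RRSeries(
                patient_id=f"{prefix}{i + 1:02d}",
                label=label,
                rr=s.rr,
                start_clock=s.start_clock,
            )
            series.append(s)
            manifest["patients"].append(
                {"patient_id": s.patient_id, "label": label, "seed": seed_i,
                 "n_beats": len(s)}
            )
            k += 1
    return series, manifest


def _config_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    return d


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def synthetic_feature_table(
    n_patients: int = 52,
    segments_per_patient: int = 20,
    n_features: int = 14,
    informative: Sequence[int] = (0,),
    effect_size: float = 2.0,
    duplicate_of: int | None = None,
    duplicate_noise: float = 0.02,
    seed: int = 0,
):
    """Direct feature-matrix cohort for selection experiments.

    Produces a lineage DataFrame (patient_id, label, f00..fNN) where the
    ``informative`` columns carry a patient-level standardized class
    effect of ``effect_size`` and all other columns are pure noise.
    Optionally appends a near-copy of feature ``duplicate_of`` to probe
    correlation gating.  Segment noise within a patient is iid N(0, 1);
    patient-level random intercepts (SD 0.5) make grouped splitting
    matter.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    half = n_patients // 2
    labels = [LABEL_POSITIVE] * half + [LABEL_NEGATIVE] * (n_patients - half)
    rows = []
    names = [f"f{j:02d}" for j in range(n_features)]
    for pidx, lab in enumerate(labels):
        shift = effect_size if lab == LABEL_POSITIVE else 0.0
        intercepts = 0.5 * rng.standard_normal(n_features)
        x = rng.standard_normal((segments_per_patient, n_features)) + intercepts
        for j in range(n_features):
            if j in informative:
                x[:, j] += shift
        df = pd.DataFrame(x, columns=names)
        df.insert(0, "patient_id", f"s{pidx:03d}")
        df.insert(1, "label", lab)
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    if duplicate_of is not None:
        dup_name = f"f{duplicate_of:02d}_dup"
        out[dup_name] = out[f"f{duplicate_of:02d}"] + duplicate_noise * rng.standard_normal(
            len(out)
        )
    return out
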