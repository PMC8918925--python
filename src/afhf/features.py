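"""Beat-to-beat features of a 5-min RR segment.

Fourteen features are computed per segment: mean, SD and RMSSD of the RR
and relative-RR (relRR) series; phase-rectified signal averaging (PRSA)
deceleration capacity (DC) and deceleration reserve (DR) of the RR
series; and Shannon, sample, and spectral entropy of both series.
Acceleration capacity (AC) is computed as an auxiliary quantity needed
by DR.

A feature that cannot be computed on a given segment (e.g. PRSA with no
valid anchors, sample entropy with no template matches) is returned as
NaN; downstream model code drops such segments with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .rr_core import Segment, to_relative

logger = logging.getLogger(__name__)

#: the 14 model features, in canonical order
FEATURE_NAMES: tuple[str, ...] = (
    "mean_rr",
    "mean_relrr",
    "sd_rr",
    "sd_relrr",
    "rmssd_rr",
    "rmssd_relrr",
    "dc",
    "dr",
    "shanen_rr",
    "shanen_relrr",
    "sampen_rr",
    "sampen_relrr",
    "specen_rr",
    "specen_relrr",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable parameters of the feature extractors.

    shannon_bins : equal-width histogram bins over the segment's own
        min-max range (scale-free).
    sampen_m, sampen_r_factor : sample-entropy template length and
        tolerance as a fraction of the segment SD (Chebyshev distance).
    prsa_half_width : beats averaged on each side of a PRSA anchor; 2 is
        the minimum that forms the DC quadruple.
    prsa_anchor_limit : anchors with a beat-to-beat change larger than
        this fraction are excluded as artifacts.
    specen_method : 'periodogram' (raw, beat-indexed) or 'welch'.
    relrr_mode : 'ratio' (100*RR_n/RR_{n-1}) or 'symmetric'.
    """

    shannon_bins: int = 16
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    prsa_half_width: int = 2
    prsa_anchor_limit: float = 0.20
    specen_method: str = "periodogram"
    relrr_mode: str = "ratio"
    dr_strategy: str = "sum"  # DR = DC + AC


@dataclass(frozen=True)
class FeatureVector:
    mean_rr: float
    mean_relrr: float
    sd_rr: float
    sd_relrr: float
    rmssd_rr: float
    rmssd_relrr: float
    dc: float
    dr: float
    shanen_rr: float
    shanen_relrr: float
    sampen_rr: float
    sampen_relrr: float
    specen_rr: float
    specen_relrr: float
    ac: float  # auxiliary, not one of the 14

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def time_domain(x: Sequence[float]) -> tuple[float, float, float]:
    """Mean, sample SD (ddof=1) and RMSSD of a numeric sequence."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return np.nan, np.nan, np.nan
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    d = np.diff(x)
    rmssd = float(np.sqrt(np.mean(d * d)))
    return mean, sd, rmssd


def prsa_capacity(
    rr: Sequence[float],
    direction: str = "decel",
    half_width: int = 2,
    anchor_limit: float = 0.20,
) -> float:
    """PRSA deceleration/acceleration capacity of an RR series (ms).

    Anchors are beats longer (decel) or shorter (accel) than their
    predecessor, excluding changes beyond ``anchor_limit`` (artifact
    guard) and anchors without ``half_width`` beats on either side.  The
    anchor-aligned average X(k) yields

        capacity = (X(0) + X(1) - X(-1) - X(-2)) / 4

    Returns NaN when no valid anchors exist.
    """
    rr = np.asarray(rr, dtype=float)
    L = int(half_width)
    if rr.size < 2 * L + 2:
        return np.nan
    ratio = rr[1:] / rr[:-1]
    if direction == "decel":
        is_anchor = ratio > 1.0
    elif direction == "accel":
        is_anchor = ratio < 1.0
    else:
        raise ValueError(f"unknown PRSA direction {direction!r}")
    is_anchor &= np.abs(ratio - 1.0) <= anchor_limit
    idx = np.nonzero(is_anchor)[0] + 1  # anchor index into rr
    idx = idx[(idx >= L) & (idx <= rr.size - 1 - L)]
    if idx.size == 0:
        return np.nan
    # X(k) for k = -2..1 is all DC needs; average the anchor-aligned rows
    x0 = rr[idx].mean()
    x1 = rr[idx + 1].mean()
    xm1 = rr[idx - 1].mean()
    xm2 = rr[idx - 2].mean()
    return float((x0 + x1 - xm1 - xm2) / 4.0)


def deceleration_reserve(
    rr: Sequence[float],
    half_width: int = 2,
    anchor_limit: float = 0.20,
) -> tuple[float, float, float]:
    """(DC, AC, DR) of an RR series.

    DR = DC + AC quantifies the asymmetry between decelerating and
    accelerating heart-rate excursions (AC is negative by construction,
    so a balanced series gives DR near 0).  Any undefined component
    makes DR NaN.
    """
    dc = prsa_capacity(rr, "decel", half_width, anchor_limit)
    ac = prsa_capacity(rr, "accel", half_width, anchor_limit)
    dr = dc + ac if np.isfinite(dc) and np.isfinite(ac) else np.nan
    return dc, ac, dr


def shannon_entropy(x: Sequence[float], n_bins: int = 16) -> float:
    """Shannon entropy (bits) of the equal-width histogram of ``x``.

    Bins span the sequence's own min-max range, making the value
    invariant to scaling.  A constant sequence has entropy 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return np.nan
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def sample_entropy(x: Sequence[float], m: int = 2, r_factor: float = 0.2) -> float:
    """Sample entropy (nats) with template length ``m`` and tolerance
    ``r = r_factor * sd(x)`` under the Chebyshev distance.

    Self-matches are excluded.  Returns NaN when no template pairs match
    at either length, or the series is too short.  A constant series is
    given entropy 0 (all templates match under any positive tolerance).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        return np.nan
    sd = np.std(x, ddof=1)
    if sd == 0:
        return 0.0
    r = r_factor * sd

    def _count(mm: int) -> int:
        n_t = n - mm + 1
        # running Chebyshev distance between all template pairs
        d = np.abs(x[:n_t, None] - x[None, :n_t])
        for k in range(1, mm):
            np.maximum(d, np.abs(x[k : k + n_t, None] - x[None, k : k + n_t]), out=d)
        within = d <= r
        return int(within.sum()) - n_t  # drop self-matches

    # match counts use templates of a common index range so that the
    # conditional probability is well defined
    n_t = n - m  # templates of length m that extend to length m+1
    d = np.abs(x[:n_t, None] - x[None, :n_t])
    for k in range(1, m):
        np.maximum(d, np.abs(x[k : k + n_t, None] - x[None, k : k + n_t]), out=d)
    b = int((d <= r).sum()) - n_t
    np.maximum(d, np.abs(x[m : m + n_t, None] - x[None, m : m + n_t]), out=d)
    a = int((d <= r).sum()) - n_t
    if a <= 0 or b <= 0:
        return np.nan
    return float(-np.log(a / b))


def spectral_entropy(x: Sequence[float], method: str = "periodogram") -> float:
    """Normalised spectral entropy of a beat-indexed series, in [0, 1].

    The mean-subtracted tachogram is treated as unit-spaced; the
    periodogram over positive-frequency bins is normalised to a
    probability vector p and the entropy -sum p log2 p is divided by
    log2 K, so 0 means a single spectral line and 1 a flat spectrum.
    Returns NaN for a constant series (zero power).
    """
    from scipy.signal import periodogram, welch

    x = np.asarray(x, dtype=float)
    if x.size < 8:
        return np.nan
    x = x - np.mean(x)
    if method == "periodogram":
        _, pxx = periodogram(x, detrend=False)
    elif method == "welch":
        _, pxx = welch(x, nperseg=min(128, x.size), detrend=False)
    else:
        raise ValueError(f"unknown spectral method {method!r}")
    pxx = pxx[1:]  # drop the DC bin; mean already removed
    total = pxx.sum()
    if total <= 0:
        return np.nan
    p = pxx / total
    p = p[p > 0]
    k = pxx.size
    return float(-np.sum(p * np.log2(p)) / np.log2(k))


def extract_features(
    rr: Sequence[float], config: FeatureConfig = FeatureConfig()
) -> FeatureVector:
    """All 14 features (plus auxiliary AC) of one RR segment."""
    rr = np.asarray(rr, dtype=float)
    rel = to_relative(rr, mode=config.relrr_mode).values
    mean_rr, sd_rr, rmssd_rr = time_domain(rr)
    mean_rel, sd_rel, rmssd_rel = time_domain(rel)
    dc, ac, dr = deceleration_reserve(
        rr, config.prsa_half_width, config.prsa_anchor_limit
    )
    return FeatureVector(
        mean_rr=mean_rr,
        mean_relrr=mean_rel,
        sd_rr=sd_rr,
        sd_relrr=sd_rel,
        rmssd_rr=rmssd_rr,
        rmssd_relrr=rmssd_rel,
        dc=dc,
        dr=dr,
        shanen_rr=shannon_entropy(rr, config.shannon_bins),
        shanen_relrr=shannon_entropy(rel, config.shannon_bins),
        sampen_rr=sample_entropy(rr, config.sampen_m, config.sampen_r_factor),
        sampen_relrr=sample_entropy(rel, config.sampen_m, config.sampen_r_factor),
        specen_rr=spectral_entropy(rr, config.specen_method),
        specen_relrr=spectral_entropy(rel, config.specen_method),
        ac=ac,
    )


def feature_table(
    segments: Iterable[Segment], config: FeatureConfig = FeatureConfig()
) -> pd.DataFrame:
    """Feature matrix with lineage: one row per segment.

    Columns: patient_id, segment_idx, circadian_tag, start_clock, label,
    the 14 features, and auxiliary ``ac``.
    """
    rows = []
    for seg in segments:
        fv = extract_features(seg.rr, config)
        row = {
            "patient_id": seg.patient_id,
            "segment_idx": seg.segment_idx,
            "circadian_tag": seg.circadian_tag,
            "start_clock": seg.start_clock,
            "label": seg.label,
        }
        row.update(fv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
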