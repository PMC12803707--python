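"""Synthetic parcellated BOLD data with planted, recoverable effects.

Real story-listening fMRI data cannot be shared, so the pipeline is
exercised end-to-end on simulated data in which every effect the analyses
look for is planted with a known magnitude:

* **Temporal synchrony** — subject *i*'s region time course is the mixture
  ``lam_c(t) * s_r(t) + sqrt(1 - lam_c(t)^2) * eps_ir(t)`` of a unit-variance
  shared story signal ``s_r`` and unit-variance subject-specific AR(1) noise
  ``eps``; the per-condition mixing weight ``lam`` directly controls
  leave-one-out temporal ISC via the closed form
  ``lam^2 / sqrt(lam^2 + (1 - lam^2)/(n-1))``.
* **Spatial synchrony** — each region's voxels carry a condition-specific
  spatial pattern mixed from a shared profile and a subject profile by
  ``spatial_lambda``, so spatial ISC is controlled the same way.
* **Envelope coupling** — the HRF-convolved speech envelope is added with
  opposite signs in "auditory" and "cingulo-opercular" region sets.
* **Clarity activation** — an HRF-convolved regressor of condition codes
  (-2..+2) is added with a per-region-set slope.
* **Event boundaries** — unit impulses at boundary onsets, convolved with
  the canonical HRF and scaled per network, give boundary-locked transients
  that should peak ~5 s after the boundary.

Everything is deterministic given ``SynthParams.seed``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .design import (
    CONDITION_CODES,
    CONDITIONS,
    EventSet,
    Parcellation,
    Schedule,
    default_parcellation,
)
from .errors import InvalidParameterError
from .glm import canonical_hrf, convolve_regressor, envelope_1s

#: Region sets that planted couplings refer to, mapped to the networks whose
#: regions they contain.  In the seven-network grouping, auditory cortex
#: falls inside the somatomotor network and the cingulo-opercular system
#: corresponds to the ventral-attention network.
REGION_SETS: dict[str, str] = {
    "auditory": "somatomotor",
    "cingulo_opercular": "ventral_attention",
}


def _default_lambda() -> dict[str, float]:
    # Shared-signal synchrony falls off as masking increases.
    return {"clear": 0.6, "+14 dB": 0.5, "+9 dB": 0.4, "+4 dB": 0.3, "-1 dB": 0.2}


def _default_spatial_lambda() -> dict[str, float]:
    return {"clear": 0.6, "+14 dB": 0.5, "+9 dB": 0.4, "+4 dB": 0.3, "-1 dB": 0.2}


def _default_envelope_beta() -> dict[str, float]:
    # BOLD tracks the envelope positively in auditory regions and with
    # opposite sign in the cingulo-opercular set.
    return {"auditory": 0.5, "cingulo_opercular": -0.25}


def _default_condition_slope() -> dict[str, float]:
    # Auditory activity declines with masking; cingulo-opercular (listening
    # effort) activity rises with masking.
    return {"auditory": -0.2, "cingulo_opercular": 0.2}


def _default_boundary_amp() -> dict[str, float]:
    # The HRF kernel peaks at ~0.175, so an impulse of 3 gives a transient
    # of ~0.52 noise-sd units: SNR ~ 0.5 against unit noise.
    return {"frontoparietal": 3.0, "ventral_attention": 3.0}


@dataclass
class SynthParams:
    """Parameters of the synthetic study.

    Defaults are a desk-scale stand-in for the real study (40 subjects x
    1,000 regions x 3 stories): 20 subjects, 50 regions, 10 voxels per
    region, 2 stories of 4 segments per condition.  ``version`` selects one
    of the three speech-clarity randomizations; one simulated dataset is one
    randomization subgroup (simulate several versions with disjoint
    ``subject_id_offset`` ranges and pool the ISC tables for a full-cohort
    analysis).

    ``sync_region_set`` optionally restricts the per-condition synchrony
    profile ``lambda_by_condition`` to one region set; all other regions
    then get a flat lambda equal to the profile's mean, so they are
    synchronized but carry no condition trend.
    """

    n_subjects: int = 20
    n_regions: int = 50
    voxels_per_region: int = 10
    n_stories: int = 2
    segments_per_condition: int = 4
    segment_length_s: float = 30.0
    tr_s: float = 1.0
    lambda_by_condition: dict = field(default_factory=_default_lambda)
    spatial_lambda_by_condition: dict = field(default_factory=_default_spatial_lambda)
    envelope_beta: dict = field(default_factory=_default_envelope_beta)
    condition_slope: dict = field(default_factory=_default_condition_slope)
    boundary_amp: dict = field(default_factory=_default_boundary_amp)
    n_boundaries_per_story: int = 12
    boundary_min_gap_s: float = 20.0
    boundary_pre_dip: float = 0.0  # optional negative dip 3 s before boundary
    ar1_phi: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0
    version: int = 1
    subject_id_offset: int = 0
    sync_region_set: str | None = None

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_regions, self.voxels_per_region,
               self.n_stories, self.segments_per_condition) < 1:
            raise InvalidParameterError("counts must be >= 1")
        if not 30.0 <= self.segment_length_s <= 33.0:
            raise InvalidParameterError(
                f"segment_length_s must be in [30, 33], got {self.segment_length_s}"
            )
        if self.version not in (1, 2, 3):
            raise InvalidParameterError(f"version must be 1..3, got {self.version}")
        for name in ("lambda_by_condition", "spatial_lambda_by_condition"):
            lam = getattr(self, name)
            if set(lam) != set(CONDITIONS):
                raise InvalidParameterError(f"{name} must map all five conditions")
            if any(not 0.0 <= v <= 1.0 for v in lam.values()):
                raise InvalidParameterError(f"{name} weights must be in [0, 1]")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise InvalidParameterError("ar1_phi must be in [0, 1)")
        if self.noise_sd <= 0:
            raise InvalidParameterError("noise_sd must be positive")
        if self.sync_region_set is not None and self.sync_region_set not in REGION_SETS:
            raise InvalidParameterError(
                f"unknown region set {self.sync_region_set!r}; "
                f"choose from {sorted(REGION_SETS)}"
            )

    @property
    def story_duration_s(self) -> float:
        return self.segment_length_s * len(CONDITIONS) * self.segments_per_condition

    @property
    def subjects(self) -> list[int]:
        return list(range(self.subject_id_offset,
                          self.subject_id_offset + self.n_subjects))


@dataclass
class GroundTruth:
    """Planted effect sizes, keyed the way the analyses estimate them."""

    envelope_beta: dict  # region -> beta
    condition_slope: dict  # region -> slope per code step
    lambda_by_condition: dict  # condition -> lam (sync_region_set regions)
    lambda_flat: float  # lam in regions outside sync_region_set
    sync_regions: list  # regions following lambda_by_condition
    spatial_lambda_by_condition: dict
    boundary_amp: dict  # region -> transient impulse amplitude
    boundary_times: dict  # story -> onset seconds


@dataclass
class SyntheticDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    params: SynthParams
    schedule: Schedule  # story-relative segments for every story
    events: EventSet
    parcellation: Parcellation
    parcel: dict  # subject -> {story -> DataFrame (volumes x regions)}
    voxels: dict | None  # subject -> {story -> {region -> ndarray (V x T)}}
    envelopes: dict  # story -> 1 s envelope array
    truth: GroundTruth

    @property
    def subjects(self) -> list[int]:
        return list(self.parcel)

    @property
    def stories(self) -> list[int]:
        return self.schedule.stories


# ---------------------------------------------------------------------------
# schedules, envelopes, event times


def make_schedule(
    n_segments_per_condition: int,
    segment_length_s: float = 30.0,
    version: int = 1,
    seed: int = 0,
    story=0,
) -> Schedule:
    """Pseudorandom balanced condition order with no immediate repeats.

    Produces ``5 * n_segments_per_condition`` contiguous segments of equal
    length for one story; each condition appears exactly
    ``n_segments_per_condition`` times and no condition follows itself.
    ``(seed, version, story)`` fully determine the order, and different
    versions give different orders for the same seed.
    """
    if n_segments_per_condition < 1:
        raise InvalidParameterError("n_segments_per_condition must be >= 1")
    if version not in (1, 2, 3):
        raise InvalidParameterError(f"version must be 1..3, got {version}")
    story_key = zlib.crc32(str(story).encode())
    rng = np.random.default_rng([abs(int(seed)), 11, int(version), story_key])
    order = _no_repeat_order(n_segments_per_condition, rng)
    rows = []
    for i, cond in enumerate(order):
        rows.append(
            (
                i * segment_length_s,
                (i + 1) * segment_length_s,
                cond,
                CONDITION_CODES[cond],
                story,
                version,
            )
        )
    return Schedule(
        pd.DataFrame(
            rows,
            columns=["onset_s", "offset_s", "condition", "code", "story", "version"],
        )
    )


def _no_repeat_order(n_per_condition: int, rng: np.random.Generator) -> list[str]:
    """Greedy sampler (restart on dead end) for a balanced no-repeat order."""
    for _ in range(10_000):
        counts = {c: n_per_condition for c in CONDITIONS}
        order: list[str] = []
        prev = None
        while any(counts.values()):
            avail = [c for c in CONDITIONS if counts[c] > 0 and c != prev]
            if not avail:
                break  # dead end; restart
            w = np.array([counts[c] for c in avail], dtype=float)
            cond = avail[rng.choice(len(avail), p=w / w.sum())]
            order.append(cond)
            counts[cond] -= 1
            prev = cond
        if len(order) == n_per_condition * len(CONDITIONS):
            return order
    raise InvalidParameterError("could not build a no-repeat condition order")


def make_envelope(
    duration_s: float, sample_rate: float = 100.0, seed: int = 0
) -> np.ndarray:
    """Zero-mean band-limited noise standing in for a story waveform.

    White Gaussian noise low-pass filtered at 8 Hz (the scale of syllabic
    envelope fluctuations), demeaned, unit-variance.  Deterministic per seed.
    """
    if duration_s <= 0:
        raise InvalidParameterError(f"duration_s must be positive, got {duration_s}")
    n = int(round(duration_s * sample_rate))
    rng = np.random.default_rng([abs(int(seed)), 12])
    w = rng.standard_normal(n)
    b, a = spsig.butter(4, min(8.0 / (sample_rate / 2), 0.99))
    x = spsig.filtfilt(b, a, w)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def make_event_times(
    duration_s: float, n_boundaries: int, min_gap_s: float, seed: int = 0
) -> np.ndarray:
    """Sorted boundary onsets with pairwise gaps >= ``min_gap_s``.

    All times lie in ``[min_gap_s, duration_s - min_gap_s]``.  Raises if the
    boundaries cannot be packed (needs ``(n+1) * min_gap <= duration``).
    """
    if n_boundaries < 1:
        raise InvalidParameterError("n_boundaries must be >= 1")
    slack = duration_s - (n_boundaries + 1) * min_gap_s
    if slack < 0:
        raise InvalidParameterError(
            f"cannot place {n_boundaries} boundaries with {min_gap_s} s gaps "
            f"in {duration_s} s"
        )
    rng = np.random.default_rng([abs(int(seed)), 13])
    u = np.sort(rng.uniform(0.0, slack, size=n_boundaries))
    return u + min_gap_s * (1 + np.arange(n_boundaries))


# ---------------------------------------------------------------------------
# signal components


def _ar1(rng: np.random.Generator, shape: tuple, phi: float) -> np.ndarray:
    """Unit-marginal-variance AR(1) noise along the last axis."""
    warm = 100
    n = shape[-1]
    w = rng.standard_normal(shape[:-1] + (n + warm,))
    if phi == 0.0:
        return w[..., warm:]
    x = spsig.lfilter([np.sqrt(1 - phi**2)], [1.0, -phi], w, axis=-1)
    return x[..., warm:]


def _lambda_series(schedule: Schedule, story, n_vol: int, tr_s: float,
                   lam: dict) -> np.ndarray:
    """Per-volume mixing weight from the segment containing each volume."""
    out = np.zeros(n_vol)
    t = np.arange(n_vol) * tr_s
    for _, row in schedule.for_story(story).iterrows():
        out[(row["onset_s"] <= t) & (t < row["offset_s"])] = lam[row["condition"]]
    return out


def _planted_terms(
    params: SynthParams,
    schedule: Schedule,
    story,
    env_1s: np.ndarray,
    boundaries: np.ndarray,
    region_sets: dict,
    boundary_amp_per_region: np.ndarray,
) -> np.ndarray:
    """Deterministic (subject-independent) signal, one row per region."""
    n_vol = int(round(params.story_duration_s / params.tr_s))
    hrf = canonical_hrf(params.tr_s)
    n_regions = params.n_regions

    env = env_1s[:n_vol]
    env_reg = convolve_regressor(env, hrf)
    env_reg = (env_reg - env_reg.mean()) / env_reg.std()

    t = np.arange(n_vol) * params.tr_s
    code_series = np.zeros(n_vol)
    for _, row in schedule.for_story(story).iterrows():
        code_series[(row["onset_s"] <= t) & (t < row["offset_s"])] = row["code"]
    code_reg = convolve_regressor(code_series, hrf)

    impulses = np.zeros(n_vol)
    vols = np.round(boundaries / params.tr_s).astype(int)
    np.add.at(impulses, vols[(vols >= 0) & (vols < n_vol)], 1.0)
    if params.boundary_pre_dip:
        pre = vols - int(round(3.0 / params.tr_s))
        dip = np.zeros(n_vol)
        np.add.at(dip, pre[(pre >= 0) & (pre < n_vol)], -params.boundary_pre_dip)
        impulses = impulses + dip
    bound_reg = convolve_regressor(impulses, hrf)

    planted = np.zeros((n_regions, n_vol))
    for set_name, beta in params.envelope_beta.items():
        planted[region_sets[set_name]] += beta * env_reg
    for set_name, slope in params.condition_slope.items():
        planted[region_sets[set_name]] += slope * code_reg
    planted += boundary_amp_per_region[:, None] * bound_reg
    return planted


def simulate_dataset(
    params: SynthParams, include_voxels: bool = True
) -> SyntheticDataset:
    """Simulate one randomization subgroup's parcellated BOLD data.

    Region series are ``noise_sd * (lam_c(t) s_r(t) + sqrt(1-lam^2) eps)``
    plus the planted envelope, clarity, and boundary terms; voxel blocks add
    a condition-specific spatial pattern and voxel noise, both mean-centered
    across voxels so the region series equals the voxel mean exactly.

    Set ``include_voxels=False`` to skip voxel blocks (much cheaper) when
    only region-level analyses are needed.
    """
    p = params
    seed = abs(int(p.seed))
    n_vol = int(round(p.story_duration_s / p.tr_s))
    parcellation = default_parcellation(p.n_regions, p.voxels_per_region)

    region_sets = {
        name: np.array([r for r in parcellation.region_ids
                        if parcellation.network_of(r) == net], dtype=int)
        for name, net in REGION_SETS.items()
    }
    networks = np.array([parcellation.network_of(r) for r in parcellation.region_ids])
    boundary_amp_per_region = np.array(
        [p.boundary_amp.get(n, 0.0) for n in networks]
    )

    lam_flat = float(np.mean(list(p.lambda_by_condition.values())))
    if p.sync_region_set is None:
        sync_mask = np.ones(p.n_regions, dtype=bool)
    else:
        sync_mask = np.zeros(p.n_regions, dtype=bool)
        sync_mask[region_sets[p.sync_region_set]] = True

    seg_frames = []
    events: dict = {}
    envelopes: dict = {}
    for story in range(p.n_stories):
        sched = make_schedule(
            p.segments_per_condition, p.segment_length_s, p.version, seed, story=story
        )
        seg_frames.append(sched.segments)
        events[story] = make_event_times(
            p.story_duration_s,
            p.n_boundaries_per_story,
            p.boundary_min_gap_s,
            seed=seed * 1000 + 17 * (story + 1),
        )
        wav = make_envelope(
            p.story_duration_s, 100.0, seed=seed * 1000 + 23 * (story + 1)
        )
        envelopes[story] = envelope_1s(wav, 100.0)
    schedule = Schedule(pd.concat(seg_frames, ignore_index=True))
    event_set = EventSet(events)

    parcel: dict = {s: {} for s in p.subjects}
    voxels: dict | None = {s: {} for s in p.subjects} if include_voxels else None

    for story in range(p.n_stories):
        lam_t = _lambda_series(
            schedule, story, n_vol, p.tr_s, p.lambda_by_condition
        )
        lam_rt = np.where(sync_mask[:, None], lam_t[None, :], lam_flat)
        planted = _planted_terms(
            p, schedule, story, envelopes[story], events[story],
            region_sets, boundary_amp_per_region,
        )
        shared_rng = np.random.default_rng([seed, 21, p.version, story])
        s_shared = shared_rng.standard_normal((p.n_regions, n_vol))
        # shared spatial profile per region, centered across voxels
        p_shared = shared_rng.standard_normal(
            (p.n_regions, len(CONDITIONS), p.voxels_per_region)
        )
        p_shared -= p_shared.mean(axis=-1, keepdims=True)

        slam = np.array([p.spatial_lambda_by_condition[c] for c in CONDITIONS])
        cond_idx_t = np.full(n_vol, -1)
        t = np.arange(n_vol) * p.tr_s
        cond_pos = {c: i for i, c in enumerate(CONDITIONS)}
        for _, row in schedule.for_story(story).iterrows():
            cond_idx_t[(row["onset_s"] <= t) & (t < row["offset_s"])] = cond_pos[
                row["condition"]
            ]

        for subject in p.subjects:
            sub_rng = np.random.default_rng([seed, 22, p.version, story, subject])
            eps = _ar1(sub_rng, (p.n_regions, n_vol), p.ar1_phi)
            series = p.noise_sd * (
                lam_rt * s_shared + np.sqrt(1.0 - lam_rt**2) * eps
            ) + planted
            parcel[subject][story] = pd.DataFrame(
                series.T, columns=parcellation.region_ids
            )
            if include_voxels:
                q = sub_rng.standard_normal(
                    (p.n_regions, len(CONDITIONS), p.voxels_per_region)
                )
                q -= q.mean(axis=-1, keepdims=True)
                # pattern[r, c, v] = slam_c p_shared + sqrt(1-slam^2) q
                pattern = (
                    slam[None, :, None] * p_shared
                    + np.sqrt(1.0 - slam[None, :, None] ** 2) * q
                ) * p.noise_sd
                vox_noise = 0.5 * p.noise_sd * sub_rng.standard_normal(
                    (p.n_regions, p.voxels_per_region, n_vol)
                )
                vox_noise -= vox_noise.mean(axis=1, keepdims=True)
                blocks = {}
                for ri, region in enumerate(parcellation.region_ids):
                    pat_t = np.where(
                        cond_idx_t[None, :] >= 0,
                        pattern[ri, np.clip(cond_idx_t, 0, None), :].T,
                        0.0,
                    )
                    blocks[region] = (
                        series[ri][None, :] + pat_t + vox_noise[ri]
                    )
                voxels[subject][story] = blocks

    truth = GroundTruth(
        envelope_beta={
            r: sum(
                beta
                for name, beta in p.envelope_beta.items()
                if r in region_sets[name]
            )
            for r in parcellation.region_ids
        },
        condition_slope={
            r: sum(
                sl
                for name, sl in p.condition_slope.items()
                if r in region_sets[name]
            )
            for r in parcellation.region_ids
        },
        lambda_by_condition=dict(p.lambda_by_condition),
        lambda_flat=lam_flat,
        sync_regions=[r for r, m in zip(parcellation.region_ids, sync_mask) if m],
        spatial_lambda_by_condition=dict(p.spatial_lambda_by_condition),
        boundary_amp=dict(zip(parcellation.region_ids, boundary_amp_per_region)),
        boundary_times={s: events[s].copy() for s in events},
    )
    return SyntheticDataset(
        params=p,
        schedule=schedule,
        events=event_set,
        parcellation=parcellation,
        parcel=parcel,
        voxels=voxels,
        envelopes=envelopes,
        truth=truth,
    )


def null_params(**overrides) -> SynthParams:
    """Parameters with every planted effect removed (flat lambda, no
    couplings, no boundary transients) — the null configuration used for
    calibration checks."""
    base = dict(
        lambda_by_condition={c: 0.4 for c in CONDITIONS},
        spatial_lambda_by_condition={c: 0.4 for c in CONDITIONS},
        envelope_beta={},
        condition_slope={},
        boundary_amp={},
    )
    base.update(overrides)
    return SynthParams(**base)
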