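"""Envelope and condition GLMs on region-averaged BOLD time courses.

The regressor-construction chain is: extract the speech amplitude envelope
(mean |waveform| in 1 s bins, matching the 1 s TR), convolve with the
canonical double-gamma hemodynamic response function, assemble a design
matrix (per-story envelope or per-story-by-condition regressors plus one
intercept per story), fit ordinary least squares per region, and reduce the
coefficients with a contrast vector.

Two standard contrasts are provided: the *envelope* contrast (story envelope
regressors weighted 1, everything else 0 — positive means BOLD tracks the
speech envelope) and the *clarity* contrast (condition regressors weighted
by the codes −2..+2 — positive means BOLD grows with speech masking, i.e.,
with listening effort).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import CONDITIONS, Schedule, condition_boxcars
from .errors import DegenerateDesignError, InvalidInputError, InvalidParameterError

HRF_DURATION_S = 32.0
HRF_RESPONSE_SHAPE = 6.0
HRF_UNDERSHOOT_SHAPE = 16.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0


@dataclass(frozen=True)
class Hrf:
    """Canonical double-gamma HRF sampled at ``tr_s`` over [0, 32] s.

    kernel[0] = 0 and the kernel has a single positive peak (at 5 s for the
    default gamma shapes) followed by a single negative undershoot.
    """

    kernel: np.ndarray
    tr_s: float


def canonical_hrf(tr_s: float = 1.0) -> Hrf:
    """Canonical HRF: gamma(shape 6, scale 1) minus gamma(shape 16)/6.

    The positive lobe is a gamma density with shape 6 and scale 1, whose
    mode — and hence the kernel peak — sits at (6−1)·1 = 5 s, matching the
    standard hemodynamic delay.  The undershoot is a gamma density with
    shape 16, scaled by 1/6.  Sampled at ``tr_s`` spacing over [0, 32] s
    (inclusive), giving ``32/tr_s + 1`` samples at integer-divisor TRs.
    """
    if not 0 < tr_s <= 4:
        raise InvalidParameterError(f"tr_s must be in (0, 4], got {tr_s}")
    t = np.arange(0.0, HRF_DURATION_S + tr_s / 2, tr_s)
    kernel = sps.gamma.pdf(t, HRF_RESPONSE_SHAPE) - HRF_UNDERSHOOT_RATIO * sps.gamma.pdf(
        t, HRF_UNDERSHOOT_SHAPE
    )
    return Hrf(kernel=kernel, tr_s=tr_s)


def envelope_1s(waveform, sample_rate: float) -> np.ndarray:
    """Amplitude envelope: mean of |waveform| within 1 s bins.

    A trailing partial second is averaged over the samples it has.
    """
    w = np.asarray(waveform, dtype=float).ravel()
    if w.size == 0:
        raise InvalidInputError("empty waveform")
    if sample_rate < 1:
        raise InvalidInputError(f"sample_rate must be >= 1 Hz, got {sample_rate}")
    sr = int(round(sample_rate))
    a = np.abs(w)
    n_full = a.size // sr
    out = []
    if n_full:
        out.append(a[: n_full * sr].reshape(n_full, sr).mean(axis=1))
    if a.size > n_full * sr:
        out.append([a[n_full * sr:].mean()])
    return np.concatenate(out)


def convolve_regressor(series, hrf: Hrf) -> np.ndarray:
    """Causal linear convolution with the HRF, truncated to the input length."""
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 1:
        raise InvalidInputError("empty regressor series")
    return np.convolve(x, hrf.kernel)[: x.size]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def build_envelope_design(
    envelopes: dict, n_volumes: dict, tr_s: float = 1.0
) -> pd.DataFrame:
    """Design matrix for the envelope GLM: per-story envelope + intercepts.

    ``envelopes`` maps story -> 1 s envelope values; ``n_volumes`` maps
    story -> run length in volumes.  Each story's envelope is convolved with
    the canonical HRF *within* the story (no cross-story bleed), z-scored,
    and placed in its own column; one disjoint intercept column per story.
    Rows are the stories concatenated in ``envelopes`` order.
    """
    hrf = canonical_hrf(tr_s)
    stories = list(envelopes)
    blocks = []
    total = sum(n_volumes[s] for s in stories)
    columns = [f"envelope[{s}]" for s in stories] + [f"intercept[{s}]" for s in stories]
    design = np.zeros((total, len(columns)))
    row = 0
    for i, story in enumerate(stories):
        nv = n_volumes[story]
        env = np.asarray(envelopes[story], dtype=float)
        if env.size < nv:
            env = np.pad(env, (0, nv - env.size))
        reg = _zscore(convolve_regressor(env[:nv], hrf))
        design[row : row + nv, i] = reg
        design[row : row + nv, len(stories) + i] = 1.0
        row += nv
        blocks.append((story, nv))
    return pd.DataFrame(design, columns=columns)


def build_condition_design(
    schedule: Schedule, n_volumes: dict, tr_s: float = 1.0
) -> pd.DataFrame:
    """Design matrix for the clarity GLM.

    One HRF-convolved boxcar regressor per (story, condition) — 5 per story
    — plus one intercept per story (18 regressors for a three-story run).
    Convolution is done per story before row-wise concatenation.
    """
    hrf = canonical_hrf(tr_s)
    stories = schedule.stories
    cond_cols = [f"{c}[{s}]" for s in stories for c in CONDITIONS]
    int_cols = [f"intercept[{s}]" for s in stories]
    total = sum(n_volumes[s] for s in stories)
    design = np.zeros((total, len(cond_cols) + len(int_cols)))
    columns = cond_cols + int_cols
    row = 0
    for si, story in enumerate(stories):
        nv = n_volumes[story]
        box = condition_boxcars(schedule, nv, tr_s, story=story)
        for ci, cond in enumerate(CONDITIONS):
            reg = convolve_regressor(box[cond].to_numpy(), hrf)
            design[row : row + nv, si * len(CONDITIONS) + ci] = reg
        design[row : row + nv, len(cond_cols) + si] = 1.0
        row += nv
    return pd.DataFrame(design, columns=columns)


def clarity_contrast_vector(design: pd.DataFrame) -> np.ndarray:
    """Contrast weights: code −2..+2 on each condition regressor, 0 elsewhere."""
    from .design import CONDITION_CODES

    w = np.zeros(design.shape[1])
    for i, col in enumerate(design.columns):
        name = col.split("[")[0]
        if name in CONDITION_CODES:
            w[i] = CONDITION_CODES[name]
    return w


def envelope_contrast_vector(design: pd.DataFrame) -> np.ndarray:
    """Contrast weights: 1 on each story envelope regressor, 0 elsewhere."""
    w = np.zeros(design.shape[1])
    for i, col in enumerate(design.columns):
        if col.startswith("envelope["):
            w[i] = 1.0
    return w


def fit_glm(series, design: pd.DataFrame) -> np.ndarray:
    """Ordinary least-squares coefficients of ``series`` on ``design``.

    Raises
    ------
    DegenerateDesignError
        If the design is rank deficient; the message names columns involved
        in the collinearity.
    """
    y = np.asarray(series, dtype=float).ravel()
    X = design.to_numpy(dtype=float)
    if y.size != X.shape[0]:
        raise InvalidInputError(
            f"series has {y.size} volumes but design has {X.shape[0]} rows"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(design.columns[j])
        raise DegenerateDesignError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def contrast(coefficients, weights) -> float:
    """Dot product of coefficients with a contrast vector."""
    b = np.asarray(coefficients, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if b.size != w.size:
        raise InvalidInputError(
            f"contrast length {w.size} != number of coefficients {b.size}"
        )
    return float(b @ w)


def nuisance_regress(series, motion) -> np.ndarray:
    """Residualize a time course against the six motion parameters.

    Fits OLS of ``series`` on the motion columns plus an intercept and
    returns the residual, which is orthogonal to every motion column (and
    has zero mean).
    """
    y = np.asarray(series, dtype=float).ravel()
    M = np.asarray(motion, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if M.shape[0] != y.size:
        raise InvalidInputError(
            f"motion has {M.shape[0]} rows but series has {y.size} volumes"
        )
    X = np.column_stack([np.ones(y.size), M])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def fit_contrast_table(
    data: dict, design: pd.DataFrame, weights, contrast_name: str
) -> pd.DataFrame:
    """Fit the GLM per subject and region and tabulate contrast values.

    ``data`` maps subject -> DataFrame (volumes x regions) whose rows match
    the design.  Returns a tidy frame (subject, region, contrast_name,
    value).
    """
    rows = []
    for subject, series in data.items():
        X = design.to_numpy(dtype=float)
        pinv = np.linalg.pinv(X)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            fit_glm(series.iloc[:, 0], design)  # raises with column names
        betas = pinv @ series.to_numpy(dtype=float)
        w = np.asarray(weights, dtype=float)
        vals = w @ betas
        for region, v in zip(series.columns, vals):
            rows.append((subject, region, contrast_name, float(v)))
    return pd.DataFrame(rows, columns=["subject", "region", "contrast_name", "value"])
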