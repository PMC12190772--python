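"""Ground-truth-known synthetic resting EEG.

The generative model mirrors what the analysis pipeline assumes it is
measuring, so every downstream estimate can be checked against a known
truth:

* a small set of fixed, zero-mean, unit-norm scalp topographies
  ("microstate templates");
* a discrete-time semi-Markov process switching between them — at each
  change point the next state is drawn from a row-stochastic transition
  matrix with zero diagonal, and the dwell in a state is geometric with a
  per-state mean (memoryless, so a first-order Markov transition-probability
  estimator is unbiased);
* an oscillatory carrier at the subject's alpha center frequency whose
  rectified envelope produces global-field-power peaks at twice the alpha
  rate, as in the resting-EEG microstate literature;
* spatially mixed 1/f^chi background noise plus a small white sensor-noise
  floor, scaled to a requested signal-to-noise variance ratio;
* per-subject clinical scores generated as linear functions of ground-truth
  microstate parameters plus Gaussian noise, clipped to the instruments'
  ranges (ABC 0-158, SRS 0-195).

Everything is deterministic given its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EEGRecording
from .spectral import PSD

__all__ = [
    "GroundTruth",
    "CohortSpec",
    "Cohort",
    "make_templates",
    "simulate_label_sequence",
    "simulate_eeg",
    "simulate_psd",
    "simulate_cohort",
    "stationary_occupancy",
    "ground_truth_params",
]

#: Clinical instrument score ranges used for clipping simulated scores.
ABC_RANGE = (0.0, 158.0)
SRS_RANGE = (0.0, 195.0)

ABC_SUBSCALES = ["sensory", "relating", "body_movement", "language", "social_self_help"]
SRS_SUBSCALES = [
    "social_awareness",
    "social_cognition",
    "communication",
    "social_motivation",
    "restrictive_repetitive",
]


@dataclass
class GroundTruth:
    """Generative parameters for one subject.

    ``templates``: k x n_channels zero-mean unit-norm maps.
    ``tp_matrix``: k x k row-stochastic change-point transition probabilities
    (zero diagonal). ``mean_durations``: per-state expected dwell in ms.
    ``alpha_peak_power`` is in log10 power units above the aperiodic curve;
    ``aperiodic_offset`` is log10(µV²/Hz).
    """

    templates: np.ndarray
    tp_matrix: np.ndarray
    mean_durations: np.ndarray
    alpha_cf: float
    alpha_peak_power: float
    aperiodic_offset: float
    aperiodic_exponent: float
    seed: int
    label_sequence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        self.tp_matrix = np.asarray(self.tp_matrix, dtype=float)
        self.mean_durations = np.asarray(self.mean_durations, dtype=float)
        _validate_tp(self.tp_matrix)
        if np.any(self.mean_durations <= 0):
            raise ValueError("mean_durations must be positive (ms)")
        k = self.tp_matrix.shape[0]
        if self.templates.shape[0] != k or self.mean_durations.shape[0] != k:
            raise ValueError("templates / durations / tp_matrix disagree on k")
        norms = np.linalg.norm(self.templates, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("templates must have unit norm")
        if not np.allclose(self.templates.mean(axis=1), 0.0, atol=1e-8):
            raise ValueError("templates must have zero channel mean")

    @property
    def k(self) -> int:
        return self.tp_matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.templates.shape[1]

    def occupancy(self) -> np.ndarray:
        """Analytic stationary fraction of time in each state."""
        return stationary_occupancy(self.tp_matrix, self.mean_durations)


def _validate_tp(tp: np.ndarray) -> None:
    tp = np.asarray(tp, dtype=float)
    if tp.ndim != 2 or tp.shape[0] != tp.shape[1]:
        raise ValueError("tp_matrix must be square")
    if tp.shape[0] < 2:
        raise ValueError("need at least 2 states for off-diagonal transitions")
    if np.any(np.abs(np.diag(tp)) > 1e-12):
        raise ValueError("tp_matrix diagonal must be zero")
    if np.any(tp < -1e-12):
        raise ValueError("tp_matrix entries must be non-negative")
    rows = tp.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-8):
        raise ValueError(f"tp_matrix rows must sum to 1, got {rows}")


def make_templates(k: int, n_channels: int, seed: int) -> np.ndarray:
    """Draw ``k`` zero-mean, unit-norm topographies with pairwise correlation 0.

    The zero-mean subspace of an ``n_channels``-dimensional sensor space has
    dimension ``n_channels - 1``, so at most that many mutually uncorrelated
    maps exist; we require ``k <= n_channels - 1``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_channels - 1:
        raise ValueError(
            f"cannot place {k} uncorrelated zero-mean maps in {n_channels} channels"
        )
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_channels, k))
    g -= g.mean(axis=0, keepdims=True)
    # orthonormal basis of the span; columns stay zero-mean
    q, r = np.linalg.qr(g)
    q *= np.sign(np.diag(r))  # deterministic sign
    templates = q.T
    # fix sign so the largest-|value| channel is positive (polarity is
    # arbitrary downstream, this just makes output reproducible to the eye)
    for t in templates:
        if t[np.argmax(np.abs(t))] < 0:
            t *= -1.0
    return templates


def stationary_occupancy(tp_matrix: np.ndarray, mean_durations: np.ndarray) -> np.ndarray:
    """Fraction of time in each state of the semi-Markov process.

    pi is the stationary distribution of the embedded (change-point) chain;
    occupancy_i = pi_i * d_i / sum_j pi_j d_j.
    """
    tp = np.asarray(tp_matrix, dtype=float)
    _validate_tp(tp)
    d = np.asarray(mean_durations, dtype=float)
    w, v = np.linalg.eig(tp.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi) / np.abs(pi).sum()
    occ = pi * d
    return occ / occ.sum()


def _embedded_chain(tp: np.ndarray, start: int, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate the change-point (embedded) Markov chain."""
    cum = np.cumsum(tp, axis=1)
    u = rng.random(n_steps)
    states = np.empty(n_steps + 1, dtype=np.int64)
    states[0] = start
    s = start
    for i in range(n_steps):
        s = int(np.searchsorted(cum[s], u[i], side="right"))
        s = min(s, tp.shape[0] - 1)
        states[i + 1] = s
    return states


def simulate_label_sequence(
    tp_matrix: np.ndarray,
    mean_durations: np.ndarray,
    n_samples: int,
    fs: float,
    seed: int,
) -> np.ndarray:
    """Semi-Markov per-sample state sequence covering ``n_samples``.

    Dwell times are geometric (support >= 1 sample) with per-state mean
    ``mean_durations`` (ms) converted to samples at ``fs``; successor states
    are drawn from ``tp_matrix`` at each change point.
    """
    tp = np.asarray(tp_matrix, dtype=float)
    _validate_tp(tp)
    d_ms = np.asarray(mean_durations, dtype=float)
    if np.any(d_ms <= 0):
        raise ValueError("mean_durations must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    d_samp = np.maximum(d_ms * fs / 1000.0, 1.0)
    p_geo = 1.0 / d_samp

    occ = stationary_occupancy(tp, d_ms)
    start = int(rng.choice(tp.shape[0], p=occ))

    # generate dwells in blocks until the horizon is covered
    labels: list[np.ndarray] = []
    covered = 0
    s = start
    while covered < n_samples:
        n_blk = max(16, int(1.4 * (n_samples - covered) / d_samp.mean()))
        states = _embedded_chain(tp, s, n_blk, rng)
        dwells = rng.geometric(p_geo[states])
        labels.append(np.repeat(states, dwells))
        covered += int(dwells.sum())
        s = int(states[-1])
        # re-enter loop from a fresh transition out of the last state
        if covered < n_samples:
            states_next = _embedded_chain(tp, s, 1, rng)
            s = int(states_next[-1])
    return np.concatenate(labels)[:n_samples]


def _pink_noise(
    n_samples: int, n_channels: int, fs: float, exponent: float, rng: np.random.Generator,
    f_lo: float = 1.0,
) -> np.ndarray:
    """Gaussian noise with power spectral density ∝ 1/f^exponent above f_lo.

    Components below ``f_lo`` (and DC) are zeroed so the variance budget lives
    in the analysis band rather than in slow drift.
    """
    white = rng.standard_normal((n_samples, n_channels))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    band = freqs >= f_lo
    gain[band] = freqs[band] ** (-exponent / 2.0)
    out = np.fft.irfft(spec * gain[:, None], n=n_samples, axis=0)
    return out


def simulate_eeg(
    ground_truth: GroundTruth,
    fs: float,
    duration_s: float,
    snr: float,
    seed: int,
    amplitude_uv: float = 250.0,
    sensor_noise_ratio: float = 0.001,
) -> EEGRecording:
    """Synthesize one subject's resting EEG from their ground truth.

    Each sample is the active template scaled by ``amplitude_uv`` times a
    sinusoidal envelope at ``alpha_cf`` (random phase per dwell), plus
    spatially mixed 1/f^exponent noise and a white sensor-noise floor; the
    noise is scaled so that var(signal)/var(noise) = ``snr``. The channel
    mean is removed per sample.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    n = int(round(duration_s * fs))
    min_dwell = float(np.min(ground_truth.mean_durations)) * fs / 1000.0
    if n < max(1.0, min_dwell):
        raise ValueError("duration too short for a single dwell")
    rng = np.random.default_rng(seed)

    gt = ground_truth
    labels = gt.label_sequence
    label_seed = int(rng.integers(2**31))  # drawn unconditionally: keeps the
    if labels is None or len(labels) != n:  # stream identical either way
        labels = simulate_label_sequence(
            gt.tp_matrix, gt.mean_durations, n, fs, label_seed
        )
        gt.label_sequence = labels  # record the realized sequence as truth
    t = np.arange(n) / fs
    # random carrier phase per dwell
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    phases = rng.uniform(0, 2 * np.pi, size=len(starts))
    phase = np.repeat(phases, np.diff(np.concatenate([starts, [n]])))
    envelope = np.sin(2 * np.pi * gt.alpha_cf * t + phase)
    signal = amplitude_uv * envelope[:, None] * gt.templates[labels]

    pink = _pink_noise(n, gt.n_channels, fs, gt.aperiodic_exponent, rng)
    mix, _ = np.linalg.qr(rng.standard_normal((gt.n_channels, gt.n_channels)))
    noise = pink @ mix.T
    noise += np.sqrt(sensor_noise_ratio) * noise.std() * rng.standard_normal(noise.shape)
    sig_std = signal.std()
    if sig_std == 0:  # template-free: pure background at a plausible scale
        data = noise * (30.0 / noise.std())
    else:
        data = signal + noise * sig_std / (np.sqrt(snr) * noise.std())
    data -= data.mean(axis=1, keepdims=True)
    return EEGRecording(data=data, fs=fs)


def simulate_psd(
    offset: float,
    exponent: float,
    peaks: list[tuple[float, float, float]],
    freqs: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PSD:
    """Power spectrum from the aperiodic + Gaussian-peak model.

    log10 power = offset - exponent*log10(f)
                  + sum of Gaussians(center, height, bandwidth=2*sd)
                  + N(0, noise_sd)
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be positive and strictly increasing")
    log_power = offset - exponent * np.log10(freqs)
    for cf, height, bw in peaks:
        sd = bw / 2.0
        log_power = log_power + height * np.exp(-((freqs - cf) ** 2) / (2 * sd**2))
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        log_power = log_power + rng.normal(0.0, noise_sd, size=freqs.shape)
    return PSD(freqs=freqs, power=10.0**log_power)


# ---------------------------------------------------------------------------
# cohort generation


def _default_clinical_model() -> list[tuple[str, float, dict[str, float], float]]:
    """(score, intercept, {ground-truth param: coefficient}, noise sd).

    Couplings target zero-order correlations around |r| ~ 0.4 between the
    named microstate parameter and the subscale, on the scale of the
    instruments (ABC total anchored near 51 +/- 16, SRS near 101 +/- 22).
    """
    return [
        ("abc_sensory", 25.0, {"occurrence_D": -6.5}, 4.5),
        ("abc_relating", 11.0, {}, 5.0),
        ("abc_body_movement", 10.0, {}, 4.5),
        ("abc_language", 10.0, {}, 4.5),
        ("abc_social_self_help", 10.0, {}, 4.5),
        ("srs_social_awareness", 20.0, {}, 6.0),
        ("srs_social_cognition", 20.0, {}, 6.0),
        ("srs_communication", 1.0, {"duration_C": 0.22}, 5.5),
        ("srs_social_motivation", -4.0, {"coverage_A": 105.0}, 5.5),
        ("srs_restrictive_repetitive", 41.0, {"coverage_E": -105.0}, 5.5),
    ]


@dataclass
class CohortSpec:
    """Study-design parameters for a two-group synthetic cohort.

    Defaults emulate the target study design: 59 subjects per group
    (47 male / 12 female), 62-channel EEG at 1000 Hz, ~80 s of clean signal,
    five microstates with ~90 ms mean dwell, and an ASD group with reduced
    coverage of state C, slightly raised coverage of state A, and lower
    alpha center frequency.
    """

    n_per_group: int = 59
    n_channels: int = 62
    fs: float = 1000.0
    duration_s: float = 80.0
    k: int = 5
    male_fraction: float = 47.0 / 59.0
    mean_duration_ms: float = 90.0
    duration_jitter_sd: float = 0.10  # lognormal sd of per-subject dwell scale
    coverage_jitter_sd: float = 0.02  # per-state occupancy jitter (absolute)
    tp_concentration: float = 120.0  # Dirichlet concentration for TP rows
    alpha_cf_mean: float = 9.0
    alpha_cf_sd: float = 0.5
    alpha_power_mean: float = 0.6
    alpha_power_sd: float = 0.15
    aperiodic_offset_mean: float = 1.5
    aperiodic_offset_sd: float = 0.2
    aperiodic_exponent_mean: float = 1.4
    aperiodic_exponent_sd: float = 0.15
    snr: float = 4.0
    group_effects: dict = field(
        default_factory=lambda: {
            "coverage": {2: -0.05, 0: +0.03},  # ASD: less C, more A
            "alpha_cf": -0.4,
            "alpha_power": -0.05,
        }
    )
    clinical_model: list = field(default_factory=_default_clinical_model)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.fs <= 2 * 45.0:
            raise ValueError("fs must exceed twice the 45 Hz analysis band edge")
        noise_sds = [m[3] for m in self.clinical_model]
        if any(sd < 0 for sd in noise_sds):
            raise ValueError("clinical noise SDs must be >= 0")


@dataclass
class Cohort:
    """A simulated two-group study: per-subject truth, scores, recordings."""

    subjects: pd.DataFrame  # id, group, gender, age
    clinical: pd.DataFrame  # id + ABC/SRS subscales and totals (ASD rows)
    ground_truth: dict[str, GroundTruth]
    recordings: dict[str, EEGRecording]


def _subject_truth(
    spec: CohortSpec,
    templates: np.ndarray,
    group: str,
    rng: np.random.Generator,
    seed: int,
    with_labels: bool,
) -> GroundTruth:
    k = spec.k
    # target occupancy: uniform + jitter + group shift, renormalized
    occ = np.full(k, 1.0 / k) + rng.normal(0.0, spec.coverage_jitter_sd, size=k)
    if group == "ASD":
        for state, delta in spec.group_effects.get("coverage", {}).items():
            occ[int(state)] += delta
    occ = np.clip(occ, 0.02, None)
    occ /= occ.sum()

    # transition matrix: near-uniform off-diagonal rows with Dirichlet jitter
    tp = np.zeros((k, k))
    for i in range(k):
        row = rng.dirichlet(np.full(k - 1, spec.tp_concentration / (k - 1)))
        tp[i, np.arange(k) != i] = row

    # dwell means chosen so the analytic occupancy equals the target exactly
    w, v = np.linalg.eig(tp.T)
    pi = np.real(v[:, int(np.argmin(np.abs(w - 1.0)))])
    pi = np.abs(pi) / np.abs(pi).sum()
    d = occ / pi
    d *= spec.mean_duration_ms / (pi @ d)  # mean dwell over visits = target
    d *= float(np.exp(rng.normal(0.0, spec.duration_jitter_sd)))

    cf = rng.normal(spec.alpha_cf_mean, spec.alpha_cf_sd)
    power = rng.normal(spec.alpha_power_mean, spec.alpha_power_sd)
    if group == "ASD":
        cf += spec.group_effects.get("alpha_cf", 0.0)
        power += spec.group_effects.get("alpha_power", 0.0)
    gt = GroundTruth(
        templates=templates,
        tp_matrix=tp,
        mean_durations=d,
        alpha_cf=float(np.clip(cf, 6.5, 13.0)),
        alpha_peak_power=float(np.clip(power, 0.05, None)),
        aperiodic_offset=float(rng.normal(spec.aperiodic_offset_mean, spec.aperiodic_offset_sd)),
        aperiodic_exponent=float(
            np.clip(rng.normal(spec.aperiodic_exponent_mean, spec.aperiodic_exponent_sd), 0.5, None)
        ),
        seed=seed,
    )
    if with_labels:
        n = int(round(spec.duration_s * spec.fs))
        gt.label_sequence = simulate_label_sequence(
            gt.tp_matrix, gt.mean_durations, n, spec.fs, seed
        )
    return gt


def ground_truth_params(gt: GroundTruth, state_names: list[str] | None = None) -> dict[str, float]:
    """Flatten a subject's generative truth into named analysis-scale parameters.

    coverage_X: stationary occupancy; duration_X: mean dwell (ms);
    occurrence_X: expected visits per second = coverage * 1000 / duration.
    """
    names = state_names or [chr(ord("A") + i) for i in range(gt.k)]
    occ = gt.occupancy()
    out: dict[str, float] = {}
    for i, name in enumerate(names):
        out[f"coverage_{name}"] = float(occ[i])
        out[f"duration_{name}"] = float(gt.mean_durations[i])
        out[f"occurrence_{name}"] = float(occ[i] * 1000.0 / gt.mean_durations[i])
    out["alpha_cf"] = gt.alpha_cf
    out["alpha_power"] = gt.alpha_peak_power
    out["aperiodic_offset"] = gt.aperiodic_offset
    out["aperiodic_exponent"] = gt.aperiodic_exponent
    return out


def simulate_cohort(
    spec: CohortSpec,
    with_labels: bool = True,
    with_eeg: bool = False,
) -> Cohort:
    """Generate a two-group cohort with known per-subject ground truth.

    ``with_eeg=False`` skips voltage synthesis (label sequences and scores
    only), which is what the statistical-calibration studies need; pipelines
    exercising the signal path pass ``with_eeg=True``.
    """
    rng = np.random.default_rng(spec.seed)
    templates = make_templates(spec.k, spec.n_channels, int(rng.integers(2**31)))

    rows = []
    clin_rows = []
    registry: dict[str, GroundTruth] = {}
    recordings: dict[str, EEGRecording] = {}
    clipped = 0
    for group in ("TD", "ASD"):
        n_male = int(round(spec.male_fraction * spec.n_per_group))
        for j in range(spec.n_per_group):
            sid = f"{group.lower()}{j:03d}"
            subj_seed = int(rng.integers(2**31))
            gt = _subject_truth(spec, templates, group, rng, subj_seed, with_labels)
            registry[sid] = gt
            rows.append(
                {
                    "id": sid,
                    "group": group,
                    "gender": "M" if j < n_male else "F",
                    "age": float(np.clip(rng.normal(4.6, 1.0), 3.0, 6.0)),
                }
            )
            if with_eeg:
                recordings[sid] = simulate_eeg(
                    gt, spec.fs, spec.duration_s, spec.snr, seed=subj_seed + 1
                )
            if group == "ASD":
                params = ground_truth_params(gt)
                scores: dict[str, float] = {"id": sid}
                for score, intercept, coefs, noise_sd in spec.clinical_model:
                    dropped = [p for p in coefs if p not in params]
                    if dropped:  # couplings to states this cohort lacks
                        warnings.warn(
                            f"clinical model terms {dropped} refer to absent "
                            "ground-truth parameters; skipped"
                        )
                    val = intercept + sum(
                        c * params[p] for p, c in coefs.items() if p in params
                    ) + rng.normal(0.0, noise_sd)
                    lo, hi = ABC_RANGE if score.startswith("abc") else SRS_RANGE
                    clipped_val = float(np.clip(val, lo, hi))
                    if clipped_val != val:
                        clipped += 1
                    scores[score] = clipped_val
                scores["abc_total"] = sum(scores[f"abc_{s}"] for s in ABC_SUBSCALES)
                scores["srs_total"] = sum(scores[f"srs_{s}"] for s in SRS_SUBSCALES)
                clin_rows.append(scores)
    if clipped:
        warnings.warn(f"{clipped} simulated clinical scores clipped to instrument range")
    return Cohort(
        subjects=pd.DataFrame(rows),
        clinical=pd.DataFrame(clin_rows),
        ground_truth=registry,
        recordings=recordings,
    )
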