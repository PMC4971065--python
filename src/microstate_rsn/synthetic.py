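"""Two-group synthetic EEG with known microstate ground truth.

The generator emulates the study conditions end to end: 64-channel
10-20 EEG at 125 Hz, ~10 min per subject, 16 subjects per group, with a
semi-Markov microstate sequence whose per-state mean dwell times default
to the group-level values reported for adolescent narcolepsy patients
and matched controls, and 15 RSN time courses at TR = 2.2 s coupled to
the microstate sequence through a known slope matrix.

The EEG model for sample t with active state s(t):

    x(t) = A * sin(2*pi*f*t + phi(t)) * T_{s(t)} + noise,

a 10 Hz alpha carrier with slow phase drift modulating the state's
unit-norm template, plus spatially white Gaussian noise scaled to the
configured signal-to-noise ratio.  GFP maxima fall at the alpha
half-cycle extrema; the field polarity flips every half-cycle, which is
exactly why microstate maps are treated as polarity-invariant.  The
signed carrier keeps its spectrum inside the 1-40 Hz analysis band, so
the pipeline's own band-pass leaves the state structure intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .backfit import Segmentation
from .clustering import TemplateSet, canonical_reference_maps, default_labels
from .io_formats import EEGRecording, Montage, SubjectTable, builtin_montage
from .rsn_sorting import RSNTimecourseSet, build_regressors

#: group-level mean dwell times (ms) per state A-D used as generator defaults
TABLE_DURATIONS_MS = {
    "patient": (87.58, 90.47, 75.92, 61.14),
    "control": (101.44, 80.02, 72.92, 61.54),
}


def default_coupling(K: int = 4, n_components: int = 15) -> np.ndarray:
    """Ground-truth microstate -> component slope matrix.

    State A drives two components (2 and 10), the remaining states one
    component each; all other couplings are zero.
    """
    c = np.zeros((K, n_components))
    c[0, 2] = 1.0
    c[0, 10] = 1.0
    if K > 1:
        c[1, 5] = 1.0
    if K > 2:
        c[2, 0] = 0.8
    if K > 3:
        c[3, 7] = 0.8
    return c


@dataclass
class SimConfig:
    n_channels: int = 64
    fs: float = 125.0
    duration_s: float = 600.0
    K_true: int = 4
    mean_duration_ms: dict = field(
        default_factory=lambda: {g: tuple(v) for g, v in TABLE_DURATIONS_MS.items()}
    )
    duration_shape: float = 2.0          # gamma shape of dwell times
    carrier_freq_hz: float = 10.0
    amplitude_uv: float = 40.0
    phase_drift_sd: float = 0.05         # rad per sample, random-walk drift
    snr: float = 3.0                     # state-signal RMS / noise RMS
    n_subjects_per_group: int = 16
    n_components: int = 15
    tr_s: float = 2.2
    n_volumes: int = 270
    coupling: np.ndarray | None = None
    ar1_noise_coef: float = 0.3
    rsn_noise_sd: float = 0.5            # marginal SD of the AR(1) noise
    transition_matrix: np.ndarray | None = None  # next-state kernel (rows sum 1)
    seed: int = 0

    def __post_init__(self):
        if self.K_true < 2:
            raise ValueError("K_true must be >= 2")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        for g, durs in self.mean_duration_ms.items():
            if len(durs) != self.K_true:
                raise ValueError(f"group {g!r}: need {self.K_true} mean durations")
            if any(d <= 0 for d in durs):
                raise ValueError("mean durations must be positive")
        if self.coupling is None:
            self.coupling = default_coupling(self.K_true, self.n_components)
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.shape != (self.K_true, self.n_components):
            raise ValueError("coupling must be K_true x n_components")
        if not np.all(np.isfinite(self.coupling)):
            raise ValueError("coupling must be finite")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class GroundTruth:
    """Everything the generator knows: templates, labels, coupling, subjects."""

    templates: TemplateSet
    label_sequences: dict  # subject_id -> per-sample state labels
    coupling: np.ndarray
    subjects: SubjectTable


def _smooth_random_map(pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Spatially smooth random topography: a few signed Gaussian bumps."""
    n_bumps = rng.integers(2, 4)
    v = np.zeros(pos.shape[0])
    for _ in range(n_bumps):
        center = rng.uniform(-0.8, 0.8, size=2)
        width = rng.uniform(0.35, 0.7)
        sign = rng.choice([-1.0, 1.0])
        v += sign * np.exp(-np.sum((pos - center) ** 2, axis=1) / (2 * width**2))
    v = v - v.mean()
    norm = np.linalg.norm(v)
    return v / norm if norm > 1e-9 else v


def make_templates(
    montage: Montage, K: int = 4, seed: int | np.random.Generator = 0,
    max_abs_corr: float = 0.7, perturb: float = 0.15,
) -> TemplateSet:
    """K smooth, average-referenced, unit-norm ground-truth topographies.

    The first four mimic the canonical A-D patterns (oblique
    posterior-anterior gradients, occipital-frontal gradient,
    fronto-central focus) with a small seeded smooth perturbation;
    further maps are random smooth bump patterns.  Maps are re-drawn
    until every pair satisfies |spatial correlation| <= ``max_abs_corr``.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if K >= montage.n_channels:
        raise ValueError("K must be smaller than the channel count")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    pos = montage.positions
    pos = (pos - pos.mean(axis=0)) / np.abs(pos - pos.mean(axis=0)).max()
    base = canonical_reference_maps(montage).templates

    maps = np.empty((K, montage.n_channels))
    for k in range(K):
        for attempt in range(200):
            # escalate the perturbation if the canonical-style base map
            # cannot satisfy the separation constraint on this montage
            if k < base.shape[0] and attempt < 50:
                m = base[k] + perturb * (1 + attempt) * _smooth_random_map(pos, rng)
            else:
                m = _smooth_random_map(pos, rng)
            m = m - m.mean()
            norm = np.linalg.norm(m)
            if norm < 1e-9:
                continue
            m /= norm
            if k == 0 or np.max(np.abs(maps[:k] @ m)) <= max_abs_corr:
                maps[k] = m
                break
        else:
            raise RuntimeError("could not draw templates satisfying the "
                               "pairwise correlation constraint")
    return TemplateSet(maps, default_labels(K))


def simulate_labels(
    cfg: SimConfig,
    group: str,
    seed: int | np.random.Generator = 0,
    n_samples: int | None = None,
) -> np.ndarray:
    """Semi-Markov microstate label sequence for one subject.

    Run lengths are gamma-distributed (shape ``cfg.duration_shape``)
    with the configured per-state mean, rounded to at least one sample;
    the next state is drawn uniformly among the other K-1 states unless
    ``cfg.transition_matrix`` provides a kernel.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    durs = np.asarray(cfg.mean_duration_ms[group], dtype=float)
    sample_ms = 1000.0 / cfg.fs
    if np.any(durs < sample_ms):
        raise ValueError("mean duration below one sample period")
    n = n_samples if n_samples is not None else cfg.n_samples
    K = cfg.K_true
    P = cfg.transition_matrix
    if P is not None:
        P = np.asarray(P, dtype=float)
        if P.shape != (K, K) or not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("transition_matrix must be K x K row-stochastic")

    labels = np.empty(n, dtype=int)
    state = int(rng.integers(K))
    pos = 0
    shape = cfg.duration_shape
    while pos < n:
        dur_ms = rng.gamma(shape, durs[state] / shape)
        length = max(1, int(round(dur_ms / sample_ms)))
        labels[pos : pos + length] = state
        pos += length
        if P is None:
            step = int(rng.integers(K - 1))
            state = step if step < state else step + 1
        else:
            state = int(rng.choice(K, p=P[state]))
    return labels


def simulate_eeg(
    cfg: SimConfig,
    truth: GroundTruth,
    subject_id: str,
    seed: int | np.random.Generator = 0,
) -> EEGRecording:
    """Alpha-carrier EEG for one subject of the cohort."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    labels = truth.label_sequences[subject_id]
    n = labels.size
    t = np.arange(n) / cfg.fs
    drift = np.cumsum(rng.normal(0.0, cfg.phase_drift_sd, size=n))
    carrier = np.sin(2 * np.pi * cfg.carrier_freq_hz * t + drift)
    signal = cfg.amplitude_uv * carrier * truth.templates.templates[labels].T
    signal_rms = np.sqrt(np.mean(signal**2))
    if np.isfinite(cfg.snr):
        noise_sd = signal_rms / cfg.snr
        data = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    else:
        data = signal
    data = data - data.mean(axis=0, keepdims=True)
    row = truth.subjects.table.set_index("subject_id").loc[subject_id]
    return EEGRecording(data, cfg.fs, montage_for(cfg, truth), subject_id,
                        str(row["group"]))


def montage_for(cfg: SimConfig, truth: GroundTruth) -> Montage:
    """Montage consistent with the ground-truth templates."""
    if truth.templates.n_channels == 64:
        return builtin_montage("standard-10-20-64")
    # generic circular layout for non-standard channel counts (tests)
    C = truth.templates.n_channels
    ang = np.linspace(0, 2 * np.pi, C, endpoint=False)
    pos = np.column_stack([np.cos(ang), np.sin(ang)])
    return Montage(tuple(f"ch{i:02d}" for i in range(C)), pos)


def _ar1(n: int, coef: float, marginal_sd: float,
         rng: np.random.Generator, size: int) -> np.ndarray:
    eps = rng.normal(0.0, 1.0, size=(size, n))
    x = sps.lfilter([1.0], [1.0, -coef], eps, axis=1)
    return x * (marginal_sd * np.sqrt(1.0 - coef**2))


def simulate_rsn_timecourses(
    cfg: SimConfig,
    truth: GroundTruth,
    subject_id: str,
    seed: int | np.random.Generator = 0,
) -> RSNTimecourseSet:
    """Component time courses coupled to the subject's microstate sequence.

    Each component is the coupling-weighted sum of the HRF-convolved,
    TR-sampled state boxcars plus AR(1) Gaussian noise.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    labels = truth.label_sequences[subject_id]
    scan_samples = int(np.ceil(cfg.n_volumes * cfg.tr_s * cfg.fs))
    if labels.size < scan_samples:
        raise ValueError("label sequence shorter than the fMRI scan")
    row = truth.subjects.table.set_index("subject_id").loc[subject_id]
    seg = Segmentation(labels=labels, corr=np.ones(labels.size), fs=cfg.fs,
                       subject_id=subject_id, group=str(row["group"]))
    regs = build_regressors(seg, cfg.tr_s, cfg.n_volumes, n_states=cfg.K_true)
    clean = truth.coupling.T @ regs  # (n_components, n_volumes)
    noise = _ar1(cfg.n_volumes, cfg.ar1_noise_coef, cfg.rsn_noise_sd,
                 rng, cfg.n_components)
    return RSNTimecourseSet(clean + noise, tr_s=cfg.tr_s,
                            subject_id=subject_id, group=str(row["group"]))


def sim_config_from_yaml(path, **overrides) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML file plus keyword overrides."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update(overrides)
    if "coupling" in raw and raw["coupling"] is not None:
        raw["coupling"] = np.asarray(raw["coupling"], dtype=float)
    if "mean_duration_ms" in raw:
        raw["mean_duration_ms"] = {
            g: tuple(v) for g, v in raw["mean_duration_ms"].items()
        }
    return SimConfig(**raw)


def make_subject_table(cfg: SimConfig, seed: int | np.random.Generator = 0) -> SubjectTable:
    """Subject metadata: two groups, ages 13-20, mixed gender."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rows = []
    for group, prefix in (("patient", "p"), ("control", "c")):
        for i in range(cfg.n_subjects_per_group):
            rows.append({
                "subject_id": f"{prefix}{i:02d}",
                "group": group,
                "age": float(np.round(rng.uniform(13.0, 20.0), 1)),
                "gender": str(rng.choice(["F", "M"])),
            })
    return SubjectTable(pd.DataFrame(rows))


def simulate_cohort_truth(
    cfg: SimConfig,
    montage: Montage | None = None,
    seed: int | None = None,
) -> GroundTruth:
    """Templates, per-subject label sequences and metadata for a cohort."""
    root = np.random.default_rng(cfg.seed if seed is None else seed)
    if montage is None:
        montage = builtin_montage("standard-10-20-64")
    templates = make_templates(montage, cfg.K_true, root)
    subjects = make_subject_table(cfg, root)
    label_sequences = {}
    for _, row in subjects.table.iterrows():
        label_sequences[row["subject_id"]] = simulate_labels(
            cfg, row["group"], root
        )
    return GroundTruth(
        templates=templates,
        label_sequences=label_sequences,
        coupling=cfg.coupling.copy(),
        subjects=subjects,
    )
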