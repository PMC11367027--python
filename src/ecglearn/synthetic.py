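"""Seeded generator of PTB-XL-like multi-label 12-lead ECG records.

The waveform model is a sum of Gaussian bumps (synthetic P, Q, R, S, T plus
an ST-segment plateau) repeated at a per-record heart rate with per-beat
timing jitter, scaled by a fixed per-lead gain vector, with sinusoidal
baseline wander and additive Gaussian noise.  Diagnostic superclasses modify
the template additively:

* ``MI``   – deepened Q wave and a positive ST-segment offset;
* ``STTC`` – reduced/inverted T wave and a negative ST offset;
* ``CD``   – widened QRS bumps (conduction delay);
* ``HYP``  – scaled-up QRS amplitudes (increased voltage);
* ``NORM`` – the unmodified template.

Multi-label records receive the union (sequential composition) of effects.
This is a parametric stand-in for real ECG physiology, built so that class
membership is recoverable from simple morphological features and every
downstream stage is testable without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks, peak_widths, welch

from .dataio import DEFAULT_VOCABULARY, Dataset, ECGRecord

#: Fixed per-lead gain vector (conventional order I..V6); aVR is inverted.
LEAD_GAINS = np.array(
    [0.6, 1.0, 0.5, -0.8, 0.4, 0.7, 0.45, 0.9, 1.1, 1.2, 1.0, 0.8]
)

DEFAULT_PREVALENCES = {
    "NORM": 0.45, "MI": 0.15, "STTC": 0.15, "CD": 0.15, "HYP": 0.10,
}

# Base beat morphology: (centre offset from R [s], width sigma [s], amplitude [mV])
_BASE_WAVES = {
    "P": (-0.20, 0.040, 0.15),
    "Q": (-0.04, 0.012, -0.15),
    "R": (0.00, 0.020, 1.00),
    "S": (0.04, 0.015, -0.25),
    "ST": (0.12, 0.060, 0.00),
    "T": (0.30, 0.070, 0.30),
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic ECG generator.

    Defaults emulate the 100 Hz / 10 s / 12-lead PTB-XL subset used for
    desk-scale experiments: 3000 records of which 35 carry null labels.
    """

    n_records: int = 3000
    class_prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    multi_label_rate: float = 0.25
    n_null_labels: int = 35
    sampling_rate: int = 100
    duration_s: float = 10.0
    n_leads: int = 12
    noise_sd: float = 0.05
    baseline_wander_amplitude: float = 0.10
    heart_rate_range: tuple[float, float] = (60.0, 100.0)
    seed: int = 0

    def validate(self) -> None:
        p = np.array([self.class_prevalences[c] for c in DEFAULT_VOCABULARY])
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_prevalences must be nonnegative and sum to 1")
        if not (0 <= self.n_null_labels <= self.n_records):
            raise ValueError("n_null_labels must be between 0 and n_records")
        if not (0.0 <= self.multi_label_rate <= 1.0):
            raise ValueError("multi_label_rate must be a probability")


PRESETS = {
    "ptbxl_like": GeneratorConfig(),
    "tiny": GeneratorConfig(n_records=60, n_null_labels=3, duration_s=4.0,
                            multi_label_rate=0.2),
}


def preset_config(name: str, seed: int | None = None) -> GeneratorConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = replace(PRESETS[name])
    if seed is not None:
        cfg.seed = seed
    return cfg


def _class_waves(labels: frozenset[str] | None) -> dict:
    """Beat-wave parameters after applying the union of class effects."""
    waves = {k: list(v) for k, v in _BASE_WAVES.items()}
    if not labels:
        return waves
    if "MI" in labels:
        waves["Q"][2] *= 3.0           # deepened Q
        waves["ST"][2] += 0.15         # ST elevation
    if "STTC" in labels:
        waves["T"][2] -= 0.45          # flattened / inverted T
        waves["ST"][2] -= 0.10
    if "CD" in labels:
        for w in ("Q", "R", "S"):
            waves[w][1] *= 1.8         # widened QRS
    if "HYP" in labels:
        for w in ("Q", "R", "S"):
            waves[w][2] *= 1.6         # increased QRS voltage
    return waves


def render_beat_train(t: np.ndarray, beat_times: np.ndarray, waves: dict) -> np.ndarray:
    """Deterministic lead-independent waveform: Gaussian bumps at each beat."""
    base = np.zeros_like(t)
    for centre, width, amp in waves.values():
        if amp == 0.0:
            continue
        for bt in beat_times:
            base += amp * np.exp(-0.5 * ((t - bt - centre) / width) ** 2)
    return base


def _synthesize_record(rng: np.random.Generator, cfg: GeneratorConfig,
                       labels: frozenset[str] | None) -> np.ndarray:
    n = int(round(cfg.sampling_rate * cfg.duration_s))
    t = np.arange(n) / cfg.sampling_rate
    hr = rng.uniform(*cfg.heart_rate_range)
    period = 60.0 / hr
    n_beats = int(np.ceil(cfg.duration_s / period)) + 2
    onsets = 0.3 + period * np.arange(n_beats)
    onsets = onsets + rng.normal(0.0, 0.02 * period, size=n_beats)
    base = render_beat_train(t, onsets, _class_waves(labels))
    gains = LEAD_GAINS[: cfg.n_leads]
    phase = rng.uniform(0, 2 * np.pi)
    wander = cfg.baseline_wander_amplitude * np.sin(2 * np.pi * 0.33 * t + phase)
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_leads, n)) if cfg.noise_sd > 0 \
        else np.zeros((cfg.n_leads, n))
    return (gains[:, None] * base[None, :] + wander[None, :] + noise).astype(np.float32)


def _draw_labels(rng: np.random.Generator, cfg: GeneratorConfig) -> frozenset[str]:
    classes = list(DEFAULT_VOCABULARY)
    p = np.array([cfg.class_prevalences[c] for c in classes])
    primary = rng.choice(len(classes), p=p)
    labels = {classes[primary]}
    if rng.random() < cfg.multi_label_rate:
        q = p.copy()
        q[primary] = 0.0
        if q.sum() > 0:
            labels.add(classes[rng.choice(len(classes), p=q / q.sum())])
    return frozenset(labels)


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Generate a seeded multi-label 12-lead dataset.

    A pure function of the config (including its seed): identical inputs give
    bit-identical archives.  Exactly ``n_null_labels`` records, chosen
    uniformly at random, carry null labels; their signals are NORM-like.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    null_idx = set(rng.choice(config.n_records, size=config.n_null_labels,
                              replace=False).tolist())
    width = len(str(max(config.n_records - 1, 1)))
    records = []
    for i in range(config.n_records):
        labels = None if i in null_idx else _draw_labels(rng, config)
        signal = _synthesize_record(rng, config, labels)
        records.append(ECGRecord(record_id=f"syn{i:0{width}d}", signal=signal,
                                 sampling_rate=config.sampling_rate, labels=labels))
    return Dataset(records=records, vocabulary=DEFAULT_VOCABULARY,
                   provenance={"generator": "ecglearn.synthetic",
                               "seed": int(config.seed),
                               "n_records": int(config.n_records)})


def split_dataset(dataset: Dataset, train_fraction: float, seed: int) -> tuple[Dataset, Dataset]:
    """Stratified (by primary label) disjoint train/test split of a dataset."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(dataset.records):
        key = min(rec.labels) if rec.has_labels() else "__null__"
        groups.setdefault(key, []).append(i)
    n_train_total = int(round(train_fraction * len(dataset)))
    train_idx: list[int] = []
    for key in sorted(groups):
        idx = np.array(groups[key])
        rng.shuffle(idx)
        k = int(round(train_fraction * len(idx)))
        train_idx.extend(idx[:k].tolist())
    # adjust to the exact requested count by moving boundary items
    rest_arr = np.array(sorted(set(range(len(dataset))) - set(train_idx)), dtype=int)
    rng.shuffle(rest_arr)
    rest = rest_arr.tolist()
    while len(train_idx) < n_train_total and rest:
        train_idx.append(rest.pop())
    while len(train_idx) > n_train_total:
        rest.append(train_idx.pop())
    train_set = set(train_idx)
    tr = [r for i, r in enumerate(dataset.records) if i in train_set]
    te = [r for i, r in enumerate(dataset.records) if i not in train_set]
    prov = dict(dataset.provenance)
    return (Dataset(tr, dataset.vocabulary, {**prov, "split": "train"}),
            Dataset(te, dataset.vocabulary, {**prov, "split": "test"}))


def generate_split(config: GeneratorConfig, train_fraction: float,
                   seed: int) -> tuple[Dataset, Dataset]:
    """Generate a dataset and split it into disjoint train/test parts.

    The parts cover all records and, for n_records >= 500, preserve each
    class's prevalence to within a few percentage points (stratified split).
    """
    return split_dataset(generate_dataset(config), train_fraction, seed)


# ---------------------------------------------------------------------------
# Simple morphological features (used for separability checks and sanity)
# ---------------------------------------------------------------------------

def morphology_features(record: ECGRecord) -> np.ndarray:
    """Per-lead summary features: QRS bandpower, mean offset, max, min.

    Flat vector of length 4 * n_leads.  Deliberately simple: enough for a
    linear one-vs-rest probe of class separability, no beat segmentation.
    """
    sig = np.asarray(record.signal, dtype=np.float64)
    fs = record.sampling_rate
    feats = []
    for lead in sig:
        f, pxx = welch(lead, fs=fs, nperseg=min(256, lead.size))
        band = (f >= 5.0) & (f <= 40.0)
        feats.extend([
            float(np.trapezoid(pxx[band], f[band])),
            float(lead.mean()),
            float(lead.max()),
            float(lead.min()),
        ])
    return np.array(feats)


def mean_qrs_width(record: ECGRecord, lead: int = 1) -> float:
    """Mean R-peak width at half prominence, in seconds (crude, threshold based)."""
    x = np.asarray(record.signal[lead], dtype=np.float64)
    x = x - np.median(x)
    height = 0.5 * float(x.max())
    peaks, _ = find_peaks(x, height=height, distance=int(0.3 * record.sampling_rate))
    if peaks.size == 0:
        return float("nan")
    widths = peak_widths(x, peaks, rel_height=0.5)[0]
    return float(widths.mean() / record.sampling_rate)
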