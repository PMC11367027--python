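"""Record/label containers, native archive I/O, and preprocessing filters.

An :class:`ECGRecord` is one multi-lead ECG signal (lead x sample matrix, mV)
with a sampling rate and a possibly-null set of diagnostic superclass labels.
A :class:`Dataset` is an ordered collection of records sharing a label
vocabulary.  The preprocessing operations mirror the standard PTB-XL-style
workflow: drop unannotated records, then fix a single sampling rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: PTB-XL diagnostic superclasses, in canonical order.
DEFAULT_VOCABULARY: tuple[str, ...] = ("NORM", "MI", "STTC", "CD", "HYP")

#: Conventional 12-lead order used by the synthetic generator.
LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)


@dataclass(frozen=True)
class ECGRecord:
    """One multi-lead ECG signal with annotations.

    Parameters
    ----------
    record_id : str
        Unique identifier within a dataset.
    signal : ndarray, shape (n_leads, n_samples)
        Amplitudes in mV; must be finite.
    sampling_rate : int
        Samples per second per lead (Hz), positive.
    labels : frozenset of str or None
        Diagnostic classes.  ``None`` marks an unannotated (null-labeled)
        record; an empty set is distinct but equally dropped by
        :func:`filter_null_labels`.
    """

    record_id: str
    signal: np.ndarray
    sampling_rate: int
    labels: frozenset[str] | None

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal)
        if sig.ndim != 2:
            raise ValueError(f"record {self.record_id!r}: signal must be 2-D (lead x sample)")
        if not np.all(np.isfinite(sig)):
            raise ValueError(f"record {self.record_id!r}: signal contains non-finite entries")
        if int(self.sampling_rate) <= 0:
            raise ValueError(f"record {self.record_id!r}: sampling_rate must be positive")
        object.__setattr__(self, "signal", sig)
        if self.labels is not None:
            object.__setattr__(self, "labels", frozenset(self.labels))

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def has_labels(self) -> bool:
        return self.labels is not None and len(self.labels) > 0


@dataclass
class Dataset:
    """Ordered list of :class:`ECGRecord` with a shared class vocabulary."""

    records: list[ECGRecord]
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record_ids in dataset")
        self.vocabulary = tuple(self.vocabulary)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> ECGRecord:
        return self.records[i]


def filter_null_labels(dataset: Dataset) -> Dataset:
    """Drop records whose label set is null or empty.

    Order is preserved and the input is not modified.  Idempotent.
    """
    kept = [r for r in dataset.records if r.has_labels()]
    return Dataset(records=kept, vocabulary=dataset.vocabulary,
                   provenance=dict(dataset.provenance))


def select_sampling_rate(dataset: Dataset, rate: int) -> Dataset:
    """Bring every record to ``rate`` Hz by integer-stride decimation.

    Records already at ``rate`` pass through unchanged.  A record at ``k*rate``
    Hz keeps every k-th sample (plain decimation, no anti-alias filter).  A
    source rate that is not an integer multiple of the target is an error.
    """
    rate = int(rate)
    if rate <= 0:
        raise ValueError("target rate must be positive")
    out: list[ECGRecord] = []
    for rec in dataset.records:
        if rec.sampling_rate == rate:
            out.append(rec)
            continue
        if rec.sampling_rate % rate != 0:
            raise ValueError(
                f"record {rec.record_id!r}: source rate {rec.sampling_rate} Hz "
                f"is not an integer multiple of {rate} Hz"
            )
        k = rec.sampling_rate // rate
        out.append(replace(rec, signal=rec.signal[:, ::k], sampling_rate=rate))
    return Dataset(records=out, vocabulary=dataset.vocabulary,
                   provenance=dict(dataset.provenance))


def encode_labels(dataset: Dataset) -> np.ndarray:
    """Multi-label indicator matrix, shape (n_records, n_classes).

    Entry (i, c) is 1 iff class ``vocabulary[c]`` is in record i's labels.
    Null-labeled records must have been filtered out first; a label outside
    the vocabulary is an error.
    """
    vocab = dataset.vocabulary
    index = {c: j for j, c in enumerate(vocab)}
    Y = np.zeros((len(dataset), len(vocab)), dtype=np.int64)
    for i, rec in enumerate(dataset.records):
        if rec.labels is None:
            raise ValueError(f"record {rec.record_id!r} has null labels; filter first")
        for lab in rec.labels:
            if lab not in index:
                raise ValueError(f"record {rec.record_id!r}: label {lab!r} not in vocabulary")
            Y[i, index[lab]] = 1
    return Y


# ---------------------------------------------------------------------------
# Native archive format: <dir>/signals.npz + <dir>/meta.json
# ---------------------------------------------------------------------------

def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as a signals archive plus a JSON sidecar.

    The directory holds one ``signals.npz`` (one array per record, keyed by
    record id) and a diff-able ``meta.json`` with ids, rates, labels,
    vocabulary, and provenance.  Round-trips bit-exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {r.record_id: r.signal for r in dataset.records}
    np.savez_compressed(path / "signals.npz", **arrays)
    meta = {
        "format": "ecglearn-native-v1",
        "vocabulary": list(dataset.vocabulary),
        "provenance": dataset.provenance,
        "records": [
            {
                "record_id": r.record_id,
                "sampling_rate": int(r.sampling_rate),
                "labels": (None if r.labels is None else sorted(r.labels)),
            }
            for r in dataset.records
        ],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def _read_native(path: Path) -> Dataset:
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no meta.json under {path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("format") != "ecglearn-native-v1":
        raise ValueError(f"{meta_path}: unrecognised archive format tag {meta.get('format')!r}")
    with np.load(path / "signals.npz") as npz:
        records = []
        for entry in meta["records"]:
            rid = entry["record_id"]
            if rid not in npz:
                raise ValueError(f"malformed archive: record {rid!r} listed in meta.json "
                                 f"but missing from signals.npz")
            labels = entry["labels"]
            records.append(ECGRecord(
                record_id=rid,
                signal=npz[rid],
                sampling_rate=int(entry["sampling_rate"]),
                labels=None if labels is None else frozenset(labels),
            ))
    return Dataset(records=records, vocabulary=tuple(meta["vocabulary"]),
                   provenance=meta.get("provenance", {}))


def read_dataset(path: str | Path, format: str = "native") -> Dataset:
    """Read a dataset from disk.

    ``format`` is one of ``native`` (the archive written by
    :func:`write_dataset`) or ``wfdb`` (a directory of PhysioNet ``.hea`` /
    ``.dat`` pairs, read-only).
    """
    path = Path(path)
    if format == "native":
        return _read_native(path)
    if format == "wfdb":
        return read_wfdb_dir(path)
    raise ValueError(f"unknown dataset format {format!r}")


def export_labels_csv(dataset: Dataset, path: str | Path) -> None:
    """Write labels/metadata (not signals) as CSV: one row per record."""
    import pandas as pd

    rows = [
        {
            "record_id": r.record_id,
            "sampling_rate": r.sampling_rate,
            "n_leads": r.n_leads,
            "n_samples": r.n_samples,
            "labels": "" if r.labels is None else "|".join(sorted(r.labels)),
            "null": r.labels is None,
        }
        for r in dataset.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Minimal WFDB reader (header + format-16 signal files), read-only
# ---------------------------------------------------------------------------

def read_wfdb_dir(path: str | Path, vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY) -> Dataset:
    """Read a directory of WFDB ``.hea``/``.dat`` pairs.

    Supports the common single-segment, format-16 (16-bit little-endian,
    interleaved) layout.  Amplitudes are converted to physical units via the
    per-signal gain and baseline from the header.  Records carry null labels
    (WFDB headers hold no class annotations).
    """
    path = Path(path)
    records: list[ECGRecord] = []
    for hea in sorted(path.glob("*.hea")):
        name, n_sig, fs, n_samp, sig_specs = _parse_wfdb_header(hea)
        dat_files = {spec["file"] for spec in sig_specs}
        if len(dat_files) != 1:
            raise ValueError(f"{hea}: multi-file records not supported")
        dat = path / dat_files.pop()
        raw = np.fromfile(dat, dtype="<i2")
        if raw.size != n_sig * n_samp:
            raise ValueError(f"{dat}: expected {n_sig * n_samp} samples, found {raw.size}")
        raw = raw.reshape(n_samp, n_sig).T.astype(np.float64)
        sig = np.empty_like(raw)
        for i, spec in enumerate(sig_specs):
            sig[i] = (raw[i] - spec["baseline"]) / spec["gain"]
        records.append(ECGRecord(record_id=name, signal=sig,
                                 sampling_rate=fs, labels=None))
    return Dataset(records=records, vocabulary=vocabulary,
                   provenance={"source": str(path), "format": "wfdb"})


def _parse_wfdb_header(hea: Path):
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    name, n_sig = head[0], int(head[1])
    fs = int(float(head[2])) if len(head) > 2 else 250
    n_samp = int(head[3]) if len(head) > 3 else 0
    specs = []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        fmt = tok[1]
        if fmt.split("x")[0] != "16":
            raise ValueError(f"{hea}: unsupported WFDB signal format {fmt!r} (only 16)")
        gain, baseline = 200.0, 0
        if len(tok) > 2:
            g = tok[2]
            if "/" in g:
                g = g.split("/")[0]
            if "(" in g:
                g, base = g.split("(")
                baseline = int(base.rstrip(")"))
            gain = float(g) if float(g) != 0 else 200.0
        specs.append({"file": tok[0], "gain": gain, "baseline": baseline})
    return name, n_sig, fs, n_samp, specs


def write_wfdb_dir(dataset: Dataset, path: str | Path, gain: float = 200.0) -> None:
    """Write records as WFDB format-16 pairs (testing/interchange helper)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for rec in dataset.records:
        dat_name = f"{rec.record_id}.dat"
        lines = [f"{rec.record_id} {rec.n_leads} {rec.sampling_rate} {rec.n_samples}"]
        for i in range(rec.n_leads):
            lead = LEAD_NAMES[i] if i < len(LEAD_NAMES) else f"ch{i}"
            lines.append(f"{dat_name} 16 {gain:g}(0)/mV 16 0 0 0 0 {lead}")
        (path / f"{rec.record_id}.hea").write_text("\n".join(lines) + "\n")
        digital = np.rint(rec.signal * gain).astype("<i2")
        digital.T.tofile(path / dat_name)
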