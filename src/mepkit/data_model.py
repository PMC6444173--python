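"""Session/record/master data model, annotation, validation and serialization.

A *session* is one recruitment-curve recording: a stack of sweeps (one per
stimulation trial) spanning a range of ascending stimulation intensities
under a single experimental condition.  A *record* groups the sessions of one
subject, with the first session always taken as the baseline condition.  A
*master* groups records across subjects that share the same condition
sequence.

Sweeps are stored in canonical ``[samples x channels x sweeps]`` order; all
readers normalize to it.  Trials per intensity may be ragged; the sweep axis
stays flat and per-intensity blocks are addressed by cumulative-sum offsets.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import scipy.io

__all__ = [
    "ValidationError",
    "DataFormatError",
    "SessionData",
    "RecordFile",
    "MasterFile",
    "SessionResult",
    "AnalysisResult",
    "ResultsBundle",
    "load_session",
    "save_session",
    "annotate_session",
    "reorder_by_intensity",
    "remove_trials",
    "build_record",
    "build_master",
    "save_record",
    "load_record",
    "save_master",
    "load_master",
    "export_results",
    "load_results",
]

AXES = ("samples", "channels", "sweeps")


class ValidationError(ValueError):
    """Annotation or structural rule violated (exit code 2 at the CLI)."""


class DataFormatError(IOError):
    """Input container unreadable or malformed (exit code 3 at the CLI)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SessionData:
    """One recruitment-curve session.

    Parameters
    ----------
    sweeps
        ``[samples x channels x sweeps]`` signal array (e.g. mV).
    sampling_rate_hz
        Acquisition rate; 0 until annotated.
    stim_intensities
        Strictly ascending stimulation intensities (device units, e.g. mA).
    trials_per_stim
        Number of trials recorded at each intensity; ``sum == n_sweeps``.
    """

    sweeps: np.ndarray
    sampling_rate_hz: float = 0.0
    stim_intensities: np.ndarray = field(default_factory=lambda: np.empty(0))
    trials_per_stim: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int))
    channel_labels: list[str] = field(default_factory=list)
    session_id: int = 0

    def __post_init__(self) -> None:
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        if self.sweeps.ndim != 3:
            raise ValidationError(
                f"sweeps must be 3-axis [samples x channels x sweeps], "
                f"got {self.sweeps.ndim} axes")
        self.stim_intensities = np.asarray(self.stim_intensities, dtype=float)
        self.trials_per_stim = np.asarray(self.trials_per_stim, dtype=int)
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        # full validation requires the sampling rate; partially annotated
        # sessions (e.g. reordered before annotation) defer to annotate_session
        if self.annotated and self.sampling_rate_hz > 0:
            self.validate()

    # -- shape accessors ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.sweeps.shape[1]

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[2]

    @property
    def annotated(self) -> bool:
        return self.stim_intensities.size > 0

    @property
    def sweep_duration_ms(self) -> float:
        return self.n_samples / self.sampling_rate_hz * 1000.0

    def trial_offsets(self) -> np.ndarray:
        """Start index of each intensity block along the flat sweep axis."""
        return np.concatenate([[0], np.cumsum(self.trials_per_stim)])

    def sweep_index(self, intensity_idx: int, trial_idx: int) -> int:
        """Flat sweep index of trial ``trial_idx`` at intensity ``intensity_idx``."""
        n_int = len(self.trials_per_stim)
        if not 0 <= intensity_idx < n_int:
            raise ValidationError(f"intensity index {intensity_idx} out of range")
        if not 0 <= trial_idx < self.trials_per_stim[intensity_idx]:
            raise ValidationError(
                f"trial index {trial_idx} out of range at intensity "
                f"{intensity_idx}")
        return int(self.trial_offsets()[intensity_idx]) + trial_idx

    def validate(self) -> None:
        if int(self.trials_per_stim.sum()) != self.n_sweeps:
            raise ValidationError(
                f"annotation/sweep mismatch: trials sum to "
                f"{int(self.trials_per_stim.sum())} but session has "
                f"{self.n_sweeps} sweeps")
        if len(self.stim_intensities) != len(self.trials_per_stim):
            raise ValidationError(
                "stim_intensities and trials_per_stim length mismatch")
        if np.any(np.diff(self.stim_intensities) <= 0):
            raise ValidationError("stim_intensities must be strictly ascending")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if np.any(self.trials_per_stim < 1):
            raise ValidationError("every intensity needs at least one trial")


@dataclass
class RecordFile:
    """All sessions of one subject; element 0 is the baseline condition."""

    subject_id: str
    sessions: list[tuple[int, "SessionData | str", str]]  # (id, data|path, label)
    baseline_index: int = 0

    def __post_init__(self) -> None:
        if not self.sessions:
            raise ValidationError("record needs at least one session")
        ids = [s[0] for s in self.sessions]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate session ids within record")
        self.baseline_index = 0

    @property
    def condition_labels(self) -> list[str]:
        return [s[2] for s in self.sessions]


@dataclass
class MasterFile:
    """Records of several subjects sharing one condition sequence."""

    records: list[RecordFile]
    condition_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("master needs at least one record")
        counts = {len(r.sessions) for r in self.records}
        if len(counts) != 1:
            raise ValidationError(
                f"all records must have the same number of sessions, "
                f"got counts {sorted(counts)}")
        if not self.condition_labels:
            self.condition_labels = self.records[0].condition_labels


@dataclass
class SessionResult:
    """Everything computed for one session, mirroring the saved-data layout."""

    session_id: int
    start_ms: float
    stop_ms: float
    channel_index: int
    filtered: bool
    sampling_rate_hz: float
    stim_intensities: np.ndarray
    trials_per_stim: np.ndarray
    epochs: np.ndarray                  # [epoch_samples x sweeps], unfiltered
    metric_name: str
    per_trial: list[np.ndarray]         # ragged: one vector per intensity
    per_intensity_mean: np.ndarray
    fit_params: dict | None = None      # P, M, L, K, Q
    fit_error: float | None = None
    tolerance_used: float | None = None
    r_squared: float | None = None
    saturated: bool | None = None
    iterations: int | None = None
    rec_curve_x: np.ndarray | None = None
    rec_curve_y: np.ndarray | None = None

    def validate(self) -> None:
        if len(self.per_intensity_mean) != len(self.stim_intensities):
            raise ValidationError(
                "per-intensity mean vector length must equal the number of "
                "stimulation intensities")
        if self.per_intensity_mean.size == 0:
            raise ValidationError("bundle incomplete: per-intensity means missing")
        if self.rec_curve_x is not None and len(self.rec_curve_x):
            lo, hi = self.stim_intensities[0], self.stim_intensities[-1]
            if not (np.isclose(self.rec_curve_x[0], lo)
                    and np.isclose(self.rec_curve_x[-1], hi)):
                raise ValidationError(
                    "curve-fit dense x must span the stimulation range")


@dataclass
class AnalysisResult:
    """One curve-comparison analysis: bar data across conditions."""

    metric_type: str                    # MEP | STIM | SLOPE | DIRECT
    cutoff_pct: float | None
    condition_labels: list[str]
    group_means: np.ndarray
    group_sems: np.ndarray


@dataclass
class ResultsBundle:
    sessions: list[SessionResult]
    analyses: list[AnalysisResult] = field(default_factory=list)

    def validate(self) -> None:
        if not self.sessions:
            raise ValidationError("bundle must contain at least one session")
        for s in self.sessions:
            s.validate()


# ---------------------------------------------------------------------------
# Session I/O
# ---------------------------------------------------------------------------

def _canonicalize(arr: np.ndarray, layout: tuple[str, ...] | None) -> np.ndarray:
    """Move a stored 2- or 3-axis array into [samples x channels x sweeps]."""
    if arr.ndim not in (2, 3):
        raise DataFormatError(
            f"session array must have 2 or 3 axes, got {arr.ndim}")
    if layout is None:
        layout = AXES[:arr.ndim] if arr.ndim == 3 else ("samples", "sweeps")
    layout = tuple(layout)
    if len(layout) != arr.ndim or len(set(layout)) != len(layout) \
            or not set(layout) <= set(AXES):
        raise ValidationError(
            f"layout {layout!r} must be a permutation of {AXES} "
            f"matching the stored array's {arr.ndim} axes")
    if arr.ndim == 2:
        if "channels" in layout:
            raise ValidationError(
                "2-axis input is single-channel; layout cannot name 'channels'")
        arr = arr[:, None, :] if layout == ("samples", "sweeps") else arr.T[:, None, :]
        return arr
    return np.transpose(arr, [layout.index(a) for a in AXES])


def load_session(path: str | os.PathLike, dataset_key: str | None = None,
                 layout: tuple[str, ...] | None = None) -> SessionData:
    """Read a session container (MAT-file v5 or HDF5) into canonical order.

    ``dataset_key`` names the MAT variable or HDF5 dataset holding the sweep
    array; if omitted, the single data variable / the ``/sweeps`` dataset is
    used.  ``layout`` describes the stored axis order as a permutation of
    ``("samples", "channels", "sweeps")`` (2-axis input drops ``"channels"``
    and is treated as single-channel).  Annotation stored in an HDF5
    container's ``/annotation`` group is attached automatically.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise DataFormatError(f"no such file: {path}")
    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as f:
            key = dataset_key or "sweeps"
            if key not in f:
                raise DataFormatError(f"dataset {key!r} not found in {path}")
            arr = np.asarray(f[key])
            sess = SessionData(_canonicalize(arr, layout))
            if "annotation" in f:
                ann = f["annotation"]
                sess = annotate_session(
                    sess,
                    np.asarray(ann["stim_intensities"]),
                    np.asarray(ann["trials_per_stim"], dtype=int),
                    float(ann["sampling_rate_hz"][()]))
                if "channel_labels" in ann:
                    sess.channel_labels = [
                        s.decode() if isinstance(s, bytes) else str(s)
                        for s in ann["channel_labels"][()]]
                if "session_id" in ann:
                    sess.session_id = int(ann["session_id"][()])
            return sess
    try:
        mat = scipy.io.loadmat(path)
    except Exception as exc:
        raise DataFormatError(f"unreadable container {path}: {exc}") from exc
    keys = [k for k in mat if not k.startswith("__")]
    if dataset_key is not None:
        if dataset_key not in mat:
            raise DataFormatError(f"variable {dataset_key!r} not in {path}")
        arr = mat[dataset_key]
    elif len(keys) == 1:
        arr = mat[keys[0]]
    else:
        raise DataFormatError(
            f"MAT-file holds several variables {keys}; pass dataset_key")
    arr = np.asarray(arr)
    if not np.issubdtype(arr.dtype, np.number):
        raise DataFormatError("session payload is not numeric")
    return SessionData(_canonicalize(arr.astype(float), layout))


def save_session(session: SessionData, path: str | os.PathLike) -> None:
    """Write a session to the documented HDF5 layout (/sweeps, /annotation)."""
    with h5py.File(os.fspath(path), "w") as f:
        f.create_dataset("sweeps", data=session.sweeps)
        if session.annotated:
            ann = f.create_group("annotation")
            ann.create_dataset("stim_intensities", data=session.stim_intensities)
            ann.create_dataset("trials_per_stim", data=session.trials_per_stim)
            ann.create_dataset("sampling_rate_hz", data=session.sampling_rate_hz)
            ann.create_dataset(
                "channel_labels",
                data=np.array(session.channel_labels, dtype="S"))
            ann.create_dataset("session_id", data=session.session_id)


# ---------------------------------------------------------------------------
# Annotation and sweep bookkeeping
# ---------------------------------------------------------------------------

def annotate_session(data: SessionData, intensities, trials,
                     fs: float) -> SessionData:
    """Attach stimulation-intensity annotation to a loaded session.

    Validates every structural invariant: trials must sum to the sweep count,
    intensities must ascend strictly, the sampling rate must be positive.
    """
    intensities = np.asarray(intensities, dtype=float)
    trials = np.asarray(trials, dtype=int)
    if len(intensities) != len(trials):
        raise ValidationError("intensities and trials must have equal length")
    out = replace(data, stim_intensities=intensities, trials_per_stim=trials,
                  sampling_rate_hz=float(fs))
    out.validate()
    return out


def reorder_by_intensity(data: SessionData,
                         per_sweep_labels) -> SessionData:
    """Stably sort sweeps by their per-sweep intensity labels.

    Annotation (intensities and trial counts) is rebuilt from the label
    multiplicities; ties keep acquisition order.  Applying the operation to an
    already-ordered session is the identity, so it is idempotent.
    """
    labels = np.asarray(per_sweep_labels, dtype=float)
    if len(labels) != data.n_sweeps:
        raise ValidationError(
            f"{len(labels)} labels for {data.n_sweeps} sweeps")
    order = np.argsort(labels, kind="stable")
    intensities, counts = np.unique(labels, return_counts=True)
    out = replace(data, sweeps=data.sweeps[:, :, order],
                  stim_intensities=intensities,
                  trials_per_stim=counts.astype(int))
    if out.sampling_rate_hz > 0:
        out.validate()
    return out


def remove_trials(data: SessionData,
                  flagged: list[tuple[int, int]]) -> SessionData:
    """Drop flagged sweeps (whole sweeps, all channels).

    ``flagged`` holds (intensity index, trial index) pairs.  Trial counts are
    decremented; removing every trial of an intensity is refused because the
    per-intensity mean would become undefined.
    """
    if not flagged:
        return data
    flat = {data.sweep_index(i, j) for i, j in set(flagged)}
    new_trials = data.trials_per_stim.copy()
    for i, _ in set(flagged):
        new_trials[i] -= 1
    if np.any(new_trials < 1):
        empty = int(np.argmin(new_trials))
        raise ValidationError(
            f"intensity index {empty} left empty by trial removal")
    keep = [k for k in range(data.n_sweeps) if k not in flat]
    out = replace(data, sweeps=data.sweeps[:, :, keep],
                  trials_per_stim=new_trials)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Record / master construction and manifests
# ---------------------------------------------------------------------------

def build_record(subject: str, sessions) -> RecordFile:
    """Group a subject's sessions; the first entry becomes the baseline."""
    norm = []
    for k, entry in enumerate(sessions):
        if isinstance(entry, SessionData):
            norm.append((entry.session_id or k, entry, f"cond{k}"))
        else:
            norm.append(tuple(entry))
    return RecordFile(subject_id=subject, sessions=norm)


def build_master(records: list[RecordFile]) -> MasterFile:
    """Group records across subjects; session counts must match."""
    return MasterFile(records=list(records))


def save_record(record: RecordFile, path: str | os.PathLike) -> None:
    """Write a record as a JSON manifest referencing session files by path."""
    entries = []
    for sid, ref, label in record.sessions:
        if isinstance(ref, SessionData):
            raise ValidationError(
                "record manifest needs session file paths; save sessions "
                "first (save_session) and reference them by path")
        entries.append({"session_id": sid, "path": ref, "condition": label})
    doc = {"format": "mepkit-record", "version": 1,
           "subject_id": record.subject_id, "sessions": entries}
    with open(os.fspath(path), "w") as f:
        json.dump(doc, f, indent=1, sort_keys=True)
        f.write("\n")


def load_record(path: str | os.PathLike) -> RecordFile:
    path = os.fspath(path)
    try:
        with open(path) as f:
            doc = json.load(f)
    except (OSError, json.JSONDecodeError) as exc:
        raise DataFormatError(f"unreadable record manifest {path}: {exc}") from exc
    if doc.get("format") != "mepkit-record":
        raise DataFormatError(f"{path} is not a record manifest")
    base = os.path.dirname(path)
    sessions = [(e["session_id"], os.path.join(base, e["path"]),
                 e["condition"]) for e in doc["sessions"]]
    return RecordFile(subject_id=doc["subject_id"], sessions=sessions)


def save_master(master: MasterFile, path: str | os.PathLike,
                record_paths: list[str]) -> None:
    doc = {"format": "mepkit-master", "version": 1,
           "condition_labels": master.condition_labels,
           "records": list(record_paths)}
    with open(os.fspath(path), "w") as f:
        json.dump(doc, f, indent=1, sort_keys=True)
        f.write("\n")


def load_master(path: str | os.PathLike) -> MasterFile:
    path = os.fspath(path)
    try:
        with open(path) as f:
            doc = json.load(f)
    except (OSError, json.JSONDecodeError) as exc:
        raise DataFormatError(f"unreadable master manifest {path}: {exc}") from exc
    if doc.get("format") != "mepkit-master":
        raise DataFormatError(f"{path} is not a master manifest")
    base = os.path.dirname(path)
    records = [load_record(os.path.join(base, p)) for p in doc["records"]]
    master = MasterFile(records=records)
    if doc.get("condition_labels"):
        master.condition_labels = doc["condition_labels"]
    return master


# ---------------------------------------------------------------------------
# Results export
# ---------------------------------------------------------------------------

_FIT_SCALARS = ("fit_error", "tolerance_used", "r_squared", "iterations")


def export_results(bundle: ResultsBundle, path: str | os.PathLike,
                   format: str = "hdf5") -> list[str]:
    """Write a results bundle to disk.

    ``format="hdf5"`` produces a single container whose numeric content
    round-trips bit-identically through :func:`load_results`.
    ``format="csv"`` produces a JSON manifest plus CSV tables (per-trial
    values, per-intensity means, fitted-curve samples, analysis bars).
    Returns the list of files written.
    """
    bundle.validate()
    path = os.fspath(path)
    if format.lower() in ("hdf5", "h5"):
        _export_hdf5(bundle, path)
        return [path]
    if format.lower() in ("csv", "json+csv"):
        return _export_csv(bundle, path)
    raise ValidationError(f"unknown results format {format!r}")


def _export_hdf5(bundle: ResultsBundle, path: str) -> None:
    with h5py.File(path, "w") as f:
        for i, s in enumerate(bundle.sessions):
            g = f.create_group(f"sessions/{i}")
            g.attrs.update({
                "session_id": s.session_id,
                "start_ms": s.start_ms, "stop_ms": s.stop_ms,
                "channel_index": s.channel_index, "filtered": s.filtered,
                "sampling_rate_hz": s.sampling_rate_hz,
                "metric_name": s.metric_name,
            })
            g.create_dataset("stim_intensities", data=s.stim_intensities)
            g.create_dataset("trials_per_stim", data=s.trials_per_stim)
            g.create_dataset("epochs", data=s.epochs)
            g.create_dataset("per_trial", data=np.concatenate(s.per_trial))
            g.create_dataset("per_intensity_mean", data=s.per_intensity_mean)
            if s.fit_params is not None:
                fit = g.create_group("fit")
                for k, v in s.fit_params.items():
                    fit.attrs[k] = v
                for name in _FIT_SCALARS:
                    fit.attrs[name] = getattr(s, name)
                fit.attrs["saturated"] = bool(s.saturated)
                fit.create_dataset("rec_curve_x", data=s.rec_curve_x)
                fit.create_dataset("rec_curve_y", data=s.rec_curve_y)
        for i, a in enumerate(bundle.analyses):
            g = f.create_group(f"analyses/{i}")
            g.attrs["metric_type"] = a.metric_type
            g.attrs["cutoff_pct"] = -1.0 if a.cutoff_pct is None else a.cutoff_pct
            g.create_dataset("condition_labels",
                             data=np.array(a.condition_labels, dtype="S"))
            g.create_dataset("bar_data", data=a.group_means)
            g.create_dataset("bar_error", data=a.group_sems)


def load_results(path: str | os.PathLike) -> ResultsBundle:
    """Read back an HDF5 results bundle written by :func:`export_results`."""
    sessions, analyses = [], []
    with h5py.File(os.fspath(path), "r") as f:
        for idx in sorted(f["sessions"], key=int):
            g = f[f"sessions/{idx}"]
            trials = np.asarray(g["trials_per_stim"], dtype=int)
            flat = np.asarray(g["per_trial"])
            offs = np.concatenate([[0], np.cumsum(trials)])
            per_trial = [flat[offs[i]:offs[i + 1]] for i in range(len(trials))]
            kw = dict(
                session_id=int(g.attrs["session_id"]),
                start_ms=float(g.attrs["start_ms"]),
                stop_ms=float(g.attrs["stop_ms"]),
                channel_index=int(g.attrs["channel_index"]),
                filtered=bool(g.attrs["filtered"]),
                sampling_rate_hz=float(g.attrs["sampling_rate_hz"]),
                stim_intensities=np.asarray(g["stim_intensities"]),
                trials_per_stim=trials,
                epochs=np.asarray(g["epochs"]),
                metric_name=str(g.attrs["metric_name"]),
                per_trial=per_trial,
                per_intensity_mean=np.asarray(g["per_intensity_mean"]),
            )
            if "fit" in g:
                fit = g["fit"]
                kw.update(
                    fit_params={k: float(fit.attrs[k]) for k in "PMLKQ"},
                    fit_error=float(fit.attrs["fit_error"]),
                    tolerance_used=float(fit.attrs["tolerance_used"]),
                    r_squared=float(fit.attrs["r_squared"]),
                    saturated=bool(fit.attrs["saturated"]),
                    iterations=int(fit.attrs["iterations"]),
                    rec_curve_x=np.asarray(fit["rec_curve_x"]),
                    rec_curve_y=np.asarray(fit["rec_curve_y"]),
                )
            sessions.append(SessionResult(**kw))
        if "analyses" in f:
            for i in sorted(f["analyses"], key=int):
                g = f[f"analyses/{i}"]
                cutoff = float(g.attrs["cutoff_pct"])
                analyses.append(AnalysisResult(
                    metric_type=str(g.attrs["metric_type"]),
                    cutoff_pct=None if cutoff < 0 else cutoff,
                    condition_labels=[s.decode() for s in g["condition_labels"]],
                    group_means=np.asarray(g["bar_data"]),
                    group_sems=np.asarray(g["bar_error"]),
                ))
    return ResultsBundle(sessions=sessions, analyses=analyses)


def _export_csv(bundle: ResultsBundle, outdir: str) -> list[str]:
    os.makedirs(outdir, exist_ok=True)
    written = []

    def _write(name, header, rows):
        p = os.path.join(outdir, name)
        with open(p, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(header)
            w.writerows(rows)
        written.append(p)

    trial_rows, mean_rows, curve_rows = [], [], []
    manifest: dict = {"format": "mepkit-results", "version": 1, "sessions": []}
    for s in bundle.sessions:
        manifest["sessions"].append({
            "session_id": s.session_id, "metric": s.metric_name,
            "start_ms": s.start_ms, "stop_ms": s.stop_ms,
            "channel_index": s.channel_index, "filtered": s.filtered,
            "sampling_rate_hz": s.sampling_rate_hz,
            "tolerance": s.tolerance_used,
            "fit": s.fit_params,
            "fit_error": s.fit_error, "r_squared": s.r_squared,
            "saturated": s.saturated, "iterations": s.iterations,
        })
        for i, (x, vals) in enumerate(zip(s.stim_intensities, s.per_trial)):
            for j, v in enumerate(vals):
                trial_rows.append([s.session_id, repr(float(x)), i, j,
                                   repr(float(v))])
            mean_rows.append([s.session_id, repr(float(x)),
                              repr(float(s.per_intensity_mean[i]))])
        if s.rec_curve_x is not None:
            for x, y in zip(s.rec_curve_x, s.rec_curve_y):
                curve_rows.append([s.session_id, repr(float(x)), repr(float(y))])

    _write("per_trial.csv",
           ["session_id", "intensity", "intensity_idx", "trial_idx", "value"],
           trial_rows)
    _write("per_intensity_mean.csv", ["session_id", "intensity", "mean"],
           mean_rows)
    if curve_rows:
        _write("rec_curve.csv", ["session_id", "x", "y"], curve_rows)
    bar_rows = []
    for a in bundle.analyses:
        for label, m, se in zip(a.condition_labels, a.group_means, a.group_sems):
            bar_rows.append([a.metric_type,
                             "" if a.cutoff_pct is None else a.cutoff_pct,
                             label, repr(float(m)), repr(float(se))])
    if bar_rows:
        _write("bar_data.csv",
               ["metric_type", "cutoff_pct", "condition", "mean", "sem"],
               bar_rows)
    mpath = os.path.join(outdir, "manifest.json")
    with open(mpath, "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
        f.write("\n")
    written.append(mpath)
    return written
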