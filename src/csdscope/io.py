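"""Recording I/O: delimited text, HDF5 container, and EDF interchange.

Three on-disk representations are supported:

* **delimited** — one header row of channel labels, one column per channel,
  with sampling rate / time origin / subject metadata in a YAML sidecar
  (``<stem>.meta.yaml``).  Human-readable, lossless at float precision.
* **container** — a single HDF5 file holding the data matrix and all
  metadata as attributes; the lossless native format.
* **EDF** — European Data Format for interchange with other ECoG/EEG
  software.  16-bit quantized; reading goes through MNE, writing uses a
  minimal EDF+ compatible writer (per-channel physical scaling, 1-second
  data records).
"""

from __future__ import annotations

import datetime
import pathlib

import numpy as np
import yaml

from .exceptions import FormatError, RoleMappingError
from .recording import Recording, SubjectMeta, resolve_role

_DELIM_EXT = {".csv", ".tsv", ".txt"}
_CONTAINER_EXT = {".h5", ".hdf5"}


def _sidecar_path(path: pathlib.Path) -> pathlib.Path:
    return path.with_name(path.stem + ".meta.yaml")


def infer_format(path) -> str:
    ext = pathlib.Path(path).suffix.lower()
    if ext in _DELIM_EXT:
        return "delimited"
    if ext in _CONTAINER_EXT:
        return "container"
    if ext == ".edf":
        return "edf"
    raise FormatError(f"cannot infer recording format from extension {ext!r}")


def load_recording(path, format: str | None = None) -> Recording:
    """Load a recording, resolving channel labels to electrode roles."""
    path = pathlib.Path(path)
    fmt = format or infer_format(path)
    if fmt == "delimited":
        return _load_delimited(path)
    if fmt == "container":
        return _load_container(path)
    if fmt == "edf":
        return _load_edf(path)
    raise FormatError(f"unknown format {fmt!r}")


def save_recording(rec: Recording, path, format: str | None = None) -> pathlib.Path:
    """Write a recording in the requested format; returns the path written."""
    path = pathlib.Path(path)
    fmt = format or infer_format(path)
    if fmt == "delimited":
        _save_delimited(rec, path)
    elif fmt == "container":
        _save_container(rec, path)
    elif fmt == "edf":
        _save_edf(rec, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    return path


# ---------------------------------------------------------------- delimited

def _save_delimited(rec: Recording, path: pathlib.Path) -> None:
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    header = sep.join(rec.channels)
    np.savetxt(path, rec.data.T, delimiter=sep, header=header, comments="",
               fmt="%.9g")
    meta = {"fs": float(rec.fs), "t0": float(rec.t0),
            "channels": {lab: lab for lab in rec.channels}}
    if rec.subject is not None:
        meta["subject"] = rec.subject.to_dict()
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def _load_delimited(path: pathlib.Path) -> Recording:
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    with open(path) as fh:
        labels = [s.strip() for s in fh.readline().rstrip("\n").split(sep)]
    data = np.loadtxt(path, delimiter=sep, skiprows=1, ndmin=2)
    if data.shape[1] != len(labels):
        raise FormatError(f"{path}: {len(labels)} header labels but "
                          f"{data.shape[1]} data columns")
    if not np.isfinite(data).all():
        raise FormatError(f"{path}: non-finite or missing samples "
                          "(mismatched channel lengths?)")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata file {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    role_map = meta.get("channels", {})
    roles = tuple(resolve_role(role_map.get(lab, lab)) for lab in labels)
    subject = SubjectMeta.from_dict(meta["subject"]) if "subject" in meta else None
    return Recording(data=data.T, fs=float(meta["fs"]),
                     channels=roles, t0=float(meta.get("t0", 0.0)),
                     subject=subject)


# ---------------------------------------------------------------- container

def _save_container(rec: Recording, path: pathlib.Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=rec.data)
        d.attrs["units"] = "mV"
        f.attrs["fs"] = float(rec.fs)
        f.attrs["t0"] = float(rec.t0)
        f.attrs["channels"] = list(rec.channels)
        if rec.subject is not None:
            for k, v in rec.subject.to_dict().items():
                f.attrs[f"subject_{k}"] = v


def _load_container(path: pathlib.Path) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["fs"])
        t0 = float(f.attrs.get("t0", 0.0))
        channels = tuple(resolve_role(str(c)) for c in f.attrs["channels"])
        subject = None
        if "subject_subject_id" in f.attrs:
            subject = SubjectMeta(
                subject_id=str(f.attrs["subject_subject_id"]),
                genotype=str(f.attrs["subject_genotype"]),
                group=str(f.attrs["subject_group"]))
    return Recording(data=data, fs=fs, channels=channels, t0=t0, subject=subject)


# ---------------------------------------------------------------------- EDF

def _pad(s: str, width: int) -> bytes:
    b = s.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def _save_edf(rec: Recording, path: pathlib.Path) -> None:
    """Minimal EDF writer: 1-s data records, per-channel physical scaling.

    The sampling rate must be a whole number of samples per second; a
    trailing partial second is dropped (EDF stores whole records only).
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF export requires an integer sampling rate")
    spr = int(round(fs))
    n_rec = rec.n_samples // spr
    if n_rec < 1:
        raise FormatError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, :n_rec * spr]
    ns = data.shape[0]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    # avoid zero span on flat channels
    flat = phys_max - phys_min < 1e-9
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    gain = (dig_max - dig_min) / (phys_max - phys_min)

    subj = rec.subject
    patient = (f"{subj.subject_id} X X X genotype_{subj.genotype} group_{subj.group}"
               if subj else "X X X X")
    now = datetime.datetime(2000, 1, 1)
    header = b"".join([
        _pad("0", 8),
        _pad(patient, 80),
        _pad("Startdate 01-JAN-2000 X X csdscope", 80),
        _pad(now.strftime("%d.%m.%y"), 8),
        _pad(now.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (ns + 1)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    fields = []
    fields.append(b"".join(_pad(lab, 16) for lab in rec.channels))
    fields.append(b"".join(_pad("AgCl cup electrode", 80) for _ in range(ns)))
    fields.append(b"".join(_pad("mV", 8) for _ in range(ns)))
    fields.append(b"".join(_pad(f"{v:.6g}", 8) for v in phys_min))
    fields.append(b"".join(_pad(f"{v:.6g}", 8) for v in phys_max))
    fields.append(b"".join(_pad(str(dig_min), 8) for _ in range(ns)))
    fields.append(b"".join(_pad(str(dig_max), 8) for _ in range(ns)))
    fields.append(b"".join(_pad("HP:0.001Hz LP:1000Hz", 80) for _ in range(ns)))
    fields.append(b"".join(_pad(str(spr), 8) for _ in range(ns)))
    fields.append(b"".join(_pad("", 32) for _ in range(ns)))

    dig = np.round((data - phys_min[:, None]) * gain[:, None] + dig_min)
    dig = np.clip(dig, dig_min, dig_max).astype("<i2")
    # records: for each second, all channels back to back
    blocks = dig.reshape(ns, n_rec, spr).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(fields))
        fh.write(blocks.tobytes())


def _load_edf(path: pathlib.Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()  # MNE converts to SI volts
    data_mv = data * 1e3
    try:
        roles = tuple(resolve_role(name) for name in raw.ch_names)
    except RoleMappingError:
        raise RoleMappingError(
            f"{path}: EDF channel labels {raw.ch_names} do not map to "
            "electrode roles")
    # subject metadata was encoded into the EDF patient-id field
    with open(path, "rb") as fh:
        fh.seek(8)
        patient = fh.read(80).decode("ascii", "replace").split()
    subject = None
    geno = next((p[len("genotype_"):] for p in patient
                 if p.startswith("genotype_")), None)
    group = next((p[len("group_"):] for p in patient
                  if p.startswith("group_")), None)
    if geno and group and patient:
        subject = SubjectMeta(subject_id=patient[0], genotype=geno, group=group)
    return Recording(data=data_mv, fs=float(raw.info["sfreq"]),
                     channels=roles, subject=subject)
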