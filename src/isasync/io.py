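"""File formats: EDF/BDF recordings, plain-text montages, HDF5 phase tensors.

Writing uses a minimal European Data Format implementation (EDF: 16-bit,
BDF/BioSemi: 24-bit, one-second data records); reading goes through MNE,
which also serves as an independent check on the writer.  Montages are
plain-text tables (name x y z per line); phase tensors round-trip through
HDF5 with band-edge metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .preprocess import PhaseTensor
from .synth import Participant, Recording

__all__ = [
    "write_montage",
    "read_montage",
    "write_recording_edf",
    "read_recording",
    "save_phase_tensor",
    "load_phase_tensor",
]

_EDF_DIG = (-32768, 32767)
_BDF_DIG = (-8388608, 8388607)


def write_montage(path, ch_names, positions) -> None:
    positions = np.asarray(positions, dtype=float)
    with open(path, "w") as fh:
        fh.write("# name x y z\n")
        for name, (x, y, z) in zip(ch_names, positions):
            fh.write(f"{name} {x:.10f} {y:.10f} {z:.10f}\n")


def read_montage(path) -> tuple:
    names, pos = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"malformed montage line: {line!r}")
            names.append(parts[0])
            pos.append([float(v) for v in parts[1:]])
    return names, np.asarray(pos)


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        b = b[:width]
    return b.ljust(width)


def _num(value, width: int) -> bytes:
    s = f"{value:.10g}"[:width]
    return _pad(s, width)


def write_recording_edf(rec: Recording, path, truth=None, bdf: bool = False) -> None:
    """Serialize one session to EDF (16-bit) or BDF (24-bit).

    EEG channels are written in microvolts and the GSR channel (labelled
    ``GSR1``) in arbitrary conductance units, with per-channel physical
    ranges taken from the data.  A JSON sidecar (<file>.json) records the
    participant metadata, exact sample count and, optionally, the synthetic
    ground truth.
    """
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))  # one-second data records
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    signals = [rec.eeg[c] for c in range(rec.eeg.shape[0])] + [rec.gsr]
    labels = list(rec.ch_names) + ["GSR1"]
    units = ["uV"] * rec.eeg.shape[0] + ["uS"]
    ns = len(signals)
    n_samples = rec.eeg.shape[1]
    n_records = int(np.ceil(n_samples / spr))

    dig_min, dig_max = _BDF_DIG if bdf else _EDF_DIG
    phys = []
    for x in signals:
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            hi = lo + 1.0
        margin = 0.001 * (hi - lo)
        phys.append((lo - margin, hi + margin))

    with open(path, "wb") as fh:
        if bdf:
            fh.write(b"\xffBIOSEMI")
        else:
            fh.write(_pad("0", 8))
        fh.write(_pad(f"X X X {rec.participant.id}", 80))
        fh.write(_pad(f"Startdate X X X X session {rec.session_index}", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_num(256 + 256 * ns, 8))
        fh.write(_pad("24BIT" if bdf else "", 44))
        fh.write(_num(n_records, 8))
        fh.write(_num(1, 8))
        fh.write(_num(ns, 4))
        for lab in labels:
            fh.write(_pad(lab, 16))
        for _ in labels:
            fh.write(_pad("synthetic", 80))
        for unit in units:
            fh.write(_pad(unit, 8))
        for lo, hi in phys:
            fh.write(_num(lo, 8))
        for lo, hi in phys:
            fh.write(_num(hi, 8))
        for _ in labels:
            fh.write(_num(dig_min, 8))
        for _ in labels:
            fh.write(_num(dig_max, 8))
        for _ in labels:
            fh.write(_pad("", 80))
        for _ in labels:
            fh.write(_num(spr, 8))
        for _ in labels:
            fh.write(_pad("", 32))

        # re-read the rounded physical bounds so scaling matches the header
        hdr_phys = [
            (float(_num(lo, 8).decode()), float(_num(hi, 8).decode()))
            for lo, hi in phys
        ]
        digital = []
        for x, (lo, hi) in zip(signals, hdr_phys):
            gain = (hi - lo) / (dig_max - dig_min)
            d = np.round((x - lo) / gain).astype(np.int64) + dig_min
            digital.append(np.clip(d, dig_min, dig_max))
        for r in range(n_records):
            sl = slice(r * spr, (r + 1) * spr)
            for d in digital:
                chunk = d[sl]
                if chunk.size < spr:  # pad the final partial record
                    chunk = np.concatenate(
                        [chunk, np.full(spr - chunk.size, chunk[-1] if chunk.size else 0)]
                    )
                if bdf:
                    as32 = chunk.astype("<i4").view(np.uint8).reshape(-1, 4)
                    fh.write(as32[:, :3].tobytes())
                else:
                    fh.write(chunk.astype("<i2").tobytes())

    sidecar = {
        "participant": {
            "id": rec.participant.id,
            "group": rec.participant.group,
            "sex": rec.participant.sex,
            "age": rec.participant.age,
        },
        "session_index": rec.session_index,
        "n_samples": int(n_samples),
        "fs": fs,
        "eeg_channels": list(rec.ch_names),
    }
    if truth is not None:
        sidecar["ground_truth"] = {
            "lag": np.asarray(truth.lag).tolist(),
            "kappa": np.asarray(truth.kappa).tolist(),
            "expected_psi": np.asarray(truth.expected_psi).tolist(),
        }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def _find_gsr(ch_names) -> int:
    hits = [
        i
        for i, name in enumerate(ch_names)
        if "GSR" in name.upper() or "EDA" in name.upper()
    ]
    if len(hits) != 1:
        raise ValueError(
            f"expected exactly one GSR/EDA channel, found {len(hits)} in {ch_names}"
        )
    return hits[0]


def read_recording(path, montage_path) -> Recording:
    """Read an EDF/BDF recording plus a montage table into a Recording.

    The GSR channel is identified by name (GSR/EDA); EEG channels are
    matched to montage entries by name.  EEG data are returned in
    microvolts regardless of MNE's internal SI scaling; a JSON sidecar, if
    present, supplies participant metadata and trims record padding.
    """
    import mne

    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    ch_names = list(raw.ch_names)
    gsr_idx = _find_gsr(ch_names)

    data = raw.get_data()
    orig_units = getattr(raw, "_orig_units", {}) or {}
    # MNE converts channels with recognized physical dimensions to SI units
    # and leaves unrecognized ones at their header's physical values; undo
    # the conversion to recover the header values.
    undo = {"uV": 1e6, "µV": 1e6, "mV": 1e3}
    scaled = np.empty_like(data)
    for i, name in enumerate(ch_names):
        scaled[i] = data[i] * undo.get(orig_units.get(name, ""), 1.0)

    eeg_names = [n for i, n in enumerate(ch_names) if i != gsr_idx]
    eeg = scaled[[i for i in range(len(ch_names)) if i != gsr_idx]]
    gsr = scaled[gsr_idx]

    mont_names, mont_pos = read_montage(montage_path)
    lookup = {n: p for n, p in zip(mont_names, mont_pos)}
    missing = [n for n in eeg_names if n not in lookup]
    if missing:
        raise ValueError(f"montage lacks positions for channels: {missing}")
    montage = np.array([lookup[n] for n in eeg_names])

    participant = Participant(id="unknown", group="Novice", sex="M", age=1.0)
    session = 0
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        p = meta.get("participant", {})
        participant = Participant(
            id=p.get("id", "unknown"),
            group=p.get("group", "Novice"),
            sex=p.get("sex", "M"),
            age=p.get("age", 1.0),
        )
        session = meta.get("session_index", 0)
        n_samples = meta.get("n_samples")
        if n_samples is not None:
            eeg = eeg[:, :n_samples]
            gsr = gsr[:n_samples]

    return Recording(
        eeg=eeg,
        gsr=gsr,
        fs=float(raw.info["sfreq"]),
        montage=montage,
        ch_names=eeg_names,
        participant=participant,
        session_index=session,
    )


def save_phase_tensor(path, pt: PhaseTensor) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("phases", data=pt.phases, compression="gzip")
        fh.create_dataset("valid_mask", data=pt.valid_mask)
        if pt.bandpassed is not None:
            fh.create_dataset("bandpassed", data=pt.bandpassed, compression="gzip")
        fh.attrs["fs"] = pt.fs
        fh.attrs["band_edges"] = np.asarray(pt.band_edges, dtype=float)


def load_phase_tensor(path) -> PhaseTensor:
    with h5py.File(path, "r") as fh:
        edges = [tuple(e) for e in np.atleast_2d(fh.attrs["band_edges"])]
        return PhaseTensor(
            phases=fh["phases"][()],
            fs=float(fh.attrs["fs"]),
            band_edges=edges,
            valid_mask=fh["valid_mask"][()].astype(bool),
            bandpassed=fh["bandpassed"][()] if "bandpassed" in fh else None,
        )
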