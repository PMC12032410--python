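"""File formats: WFDB-compatible records, marker/fiducial tables, manifests.

Signals are stored in the classic WFDB layout — a text header (``.hea``) plus
a binary format-16 signal file (``.dat``, interleaved little-endian int16) —
using a gain of 1 ADC unit per microvolt by default.  Only the subset of the
header needed here is understood: one signal file per record, format 16,
``gain(baseline)/units`` with units V, mV or uV.  Values are converted to
microvolts on read regardless of stored units.

Everything else is delimited text (CSV) or JSON keyed by zero-padded record
ids.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .leads import MultiLeadSignal
from .synth import FIDUCIAL_NAMES, GroundTruthFiducials, SyntheticRecord

_UNIT_TO_UV = {"uV": 1.0, "mV": 1000.0, "V": 1_000_000.0}


class FormatError(RuntimeError):
    pass


def write_wfdb(signal: MultiLeadSignal, directory, record_name: str,
               gain: float = 1.0, units: str = "uV"):
    """Write header + format-16 signal files; values quantized to int16.

    ``gain`` is in ADC units per ``units``; the default (1 adu/uV) stores
    whole microvolts, ample for physiologic ECG amplitudes.
    """
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    adc = np.round(signal.samples * gain / _UNIT_TO_UV[units] * _UNIT_TO_UV["uV"])
    if np.abs(adc).max() > 32767:
        warnings.warn(f"{record_name}: samples clipped to int16 range")
        adc = np.clip(adc, -32768, 32767)
    adc = adc.astype("<i2")
    lines = [f"{record_name} {signal.n_leads} {signal.sampling_rate:g} {signal.n_samples}"]
    for name in signal.lead_names:
        lines.append(f"{record_name}.dat 16 {gain:g}(0)/{units} 16 0 0 0 0 {name}")
    (d / f"{record_name}.hea").write_text("\n".join(lines) + "\n")
    adc.T.tofile(d / f"{record_name}.dat")


def read_wfdb(directory, record_name: str) -> MultiLeadSignal:
    """Read one record; returns amplitudes in microvolts."""
    d = pathlib.Path(directory)
    header = d / f"{record_name}.hea"
    if not header.exists():
        raise FormatError(f"header {header} not found")
    lines = [l for l in header.read_text().splitlines()
             if l.strip() and not l.startswith("#")]
    first = lines[0].split()
    n_sig, fs, n_samp = int(first[1]), float(first[2]), int(first[3])
    names, gains, units = [], [], []
    dat_file = None
    for line in lines[1:1 + n_sig]:
        parts = line.split()
        dat_file = parts[0]
        fmt = parts[1]
        if fmt != "16":
            raise FormatError(f"unsupported signal format {fmt!r} (only 16)")
        gain_spec = parts[2]
        unit = "mV"
        if "/" in gain_spec:
            gain_spec, unit = gain_spec.split("/")
        gain = float(gain_spec.split("(")[0]) if gain_spec else 200.0
        if unit not in _UNIT_TO_UV:
            raise FormatError(f"unsupported units {unit!r}")
        names.append(parts[-1])
        gains.append(gain if gain != 0 else 200.0)
        units.append(unit)
    raw = np.fromfile(d / dat_file, dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise FormatError(
            f"{dat_file}: expected {n_sig * n_samp} samples, found {raw.size}")
    adc = raw.reshape(n_samp, n_sig).T.astype(float)
    phys_uv = adc / np.asarray(gains)[:, None] * np.array(
        [_UNIT_TO_UV[u] for u in units])[:, None]
    return MultiLeadSignal(phys_uv, fs, tuple(names))


def read_wfdb_cohort(path, metadata_filter: Optional[dict] = None,
                     require_leads: int = 12,
                     require_fs: Optional[float] = 500.0) -> list:
    """Read all records under ``path``, optionally filtered by manifest labels.

    Returns ``[(record_id, MultiLeadSignal), ...]`` in id order.  Records
    failing the lead-count or sampling-rate checks are skipped with a warning.
    ``metadata_filter`` matches column values in ``manifest.csv`` (e.g.
    ``{"label": "normal"}``).
    """
    d = pathlib.Path(path)
    ids = sorted(h.stem for h in d.glob("*.hea"))
    manifest = None
    if (d / "manifest.csv").exists():
        manifest = pd.read_csv(d / "manifest.csv", dtype={"record_id": str})
        manifest = manifest.set_index("record_id")
    if metadata_filter:
        if manifest is None:
            raise FormatError("metadata filter given but no manifest.csv found")
        keep = manifest
        for col, val in metadata_filter.items():
            keep = keep[keep[col] == val]
        ids = [i for i in ids if i in keep.index]
    out = []
    for rid in ids:
        try:
            sig = read_wfdb(d, rid)
        except FormatError as exc:
            warnings.warn(f"{rid}: skipped ({exc})")
            continue
        if sig.n_leads != require_leads:
            warnings.warn(f"{rid}: skipped ({sig.n_leads} leads, need {require_leads})")
            continue
        if require_fs and sig.sampling_rate != require_fs:
            warnings.warn(f"{rid}: skipped (fs {sig.sampling_rate}, need {require_fs})")
            continue
        out.append((rid, sig))
    if not out:
        warnings.warn(f"no matching records under {path}")
    return out


def fiducials_frame(records: Sequence[SyntheticRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for b in range(rec.fiducials.n_beats):
            row = {"record_id": rec.record_id, "beat": b}
            row.update(dict(zip(FIDUCIAL_NAMES, rec.fiducials.beats[b])))
            rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(records: Sequence[SyntheticRecord], directory,
                 extra_manifest: Optional[dict] = None):
    """Write WFDB records + fiducials.csv + manifest.csv + manifest.json."""
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    digest = hashlib.sha256()
    for rec in records:
        write_wfdb(rec.signal, d, rec.record_id)
        digest.update(np.round(rec.signal.samples).astype("<i2").tobytes())
        rows.append({"record_id": rec.record_id, "label": "normal",
                     "heart_rate": rec.params.heart_rate,
                     "global_scale": rec.params.global_scale,
                     "n_beats": rec.fiducials.n_beats})
    pd.DataFrame(rows).to_csv(d / "manifest.csv", index=False)
    fiducials_frame(records).to_csv(d / "fiducials.csv", index=False)
    meta = {"n_records": len(records), "cohort_sha256": digest.hexdigest()}
    meta.update(extra_manifest or {})
    write_manifest(d / "manifest.json", meta)


def read_fiducials(path) -> dict:
    """fiducials.csv -> {record_id: GroundTruthFiducials} (bounds unknown -> large)."""
    frame = pd.read_csv(path, dtype={"record_id": str})
    out = {}
    for rid, grp in frame.groupby("record_id"):
        beats = grp.sort_values("beat")[list(FIDUCIAL_NAMES)].to_numpy(int)
        out[rid] = GroundTruthFiducials(beats, int(beats.max()) + 1)
    return out


def write_manifest(path, payload: dict):
    """JSON manifest; every run artifact records its config and seed."""
    from . import __version__
    body = {"software": "leadrecon", "version": __version__}
    body.update(payload)
    pathlib.Path(path).write_text(json.dumps(body, indent=2, default=str) + "\n")


def read_manifest(path) -> dict:
    return json.loads(pathlib.Path(path).read_text())


# -- model checkpoints -------------------------------------------------------

def save_generator(generator, path, extra: Optional[dict] = None):
    """Checkpoint with the structural config embedded."""
    from dataclasses import asdict
    meta = {"config": asdict(generator.config)}
    meta.update(extra or {})
    arrays = {f"p{i}": p.value for i, p in enumerate(generator.params)}
    np.savez(path, meta=json.dumps(meta, default=str), **arrays)


def load_generator(path):
    from .models import Generator, GeneratorConfig
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        cfg = dict(meta["config"])
        for key in ("down_channels", "up_channels", "dropout_layers"):
            cfg[key] = tuple(cfg[key])
        gen = Generator(GeneratorConfig(**cfg))
        state = [np.asarray(data[f"p{i}"]) for i in range(len(gen.params))]
    gen.load_state(state)
    return gen
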