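"""Device CSV dialect and cohort manifest I/O.

Each recording is one CSV file with header ``time_s,phase,<sensors>`` where the
sensor columns follow the canonical array order (TGS2600 ... Alkane).  Baseline
rows come first (phase = ``baseline``), then response rows (phase =
``response``); within each phase, time stamps are t_k = (k + 1) / sampling_rate
seconds after phase start.  Labels and origins live in a separate manifest CSV
(``sample_id,path,label,origin``), never in the recording file.

Reads are strict by default (exact expected point counts); lenient mode accepts
whatever point counts the file carries, since real devices jitter around the
nominal sampling rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (
    CANONICAL_SENSORS,
    LABEL_CANCER,
    LABEL_HEALTHY,
    ORIGIN_REAL,
    ORIGIN_SYNTHETIC,
    BreathSample,
)

PHASE_BASELINE = "baseline"
PHASE_RESPONSE = "response"


class DeviceFormatError(ValueError):
    """A device CSV or manifest violates the documented dialect."""


@dataclass
class CohortManifest:
    """Ordered mapping of sample files to labels and origins."""

    entries: list[tuple[str, str, str, str]]  # (sample_id, path, label, origin)

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DeviceFormatError(f"duplicate sample_id(s): {dupes}")
        for sid, _, label, origin in self.entries:
            if label not in (LABEL_HEALTHY, LABEL_CANCER):
                raise DeviceFormatError(f"{sid}: unknown label {label!r}")
            if origin not in (ORIGIN_REAL, ORIGIN_SYNTHETIC):
                raise DeviceFormatError(f"{sid}: unknown origin {origin!r}")


def write_sample_csv(sample: BreathSample, destination: str | Path) -> Path:
    """Write one recording in the device dialect; returns the path written."""
    destination = Path(destination)
    n_base = sample.baseline.shape[1]
    rate = 1.0 / float(np.diff(sample.time_grid)[0]) if sample.time_grid.size > 1 else 0.97
    t_base = (np.arange(n_base) + 1.0) / rate
    rows = {
        "time_s": np.concatenate([t_base, sample.time_grid]),
        "phase": [PHASE_BASELINE] * n_base + [PHASE_RESPONSE] * sample.time_grid.size,
    }
    for i, name in enumerate(sample.sensor_names):
        rows[name] = np.concatenate([sample.baseline[i], sample.response[i]])
    pd.DataFrame(rows).to_csv(destination, index=False)
    return destination


def read_sample_csv(
    source: str | Path,
    sample_id: str | None = None,
    label: str = LABEL_HEALTHY,
    origin: str = ORIGIN_REAL,
    strict: bool = True,
    expected_points: tuple[int, int] = (29, 29),
) -> BreathSample:
    """Read a device CSV back into a :class:`BreathSample`.

    The label and origin are caller-supplied (normally from the manifest); the
    file itself carries only signals.  Shuffled sensor columns are reordered
    into canonical order.  In strict mode the baseline/response row counts must
    equal ``expected_points``.
    """
    source = Path(source)
    df = pd.read_csv(source, float_precision="round_trip")
    for col in ("time_s", "phase"):
        if col not in df.columns:
            raise DeviceFormatError(f"{source}: missing column {col!r}")
    sensor_cols = [c for c in df.columns if c not in ("time_s", "phase")]
    if set(sensor_cols) != set(CANONICAL_SENSORS):
        missing = sorted(set(CANONICAL_SENSORS) - set(sensor_cols))
        extra = sorted(set(sensor_cols) - set(CANONICAL_SENSORS))
        raise DeviceFormatError(
            f"{source}: wrong sensor set (missing {missing}, unexpected {extra})"
        )
    parts = {}
    for phase in (PHASE_BASELINE, PHASE_RESPONSE):
        block = df[df["phase"] == phase]
        if block.empty:
            raise DeviceFormatError(f"{source}: no {phase!r} rows")
        t = block["time_s"].to_numpy(dtype=float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise DeviceFormatError(f"{source}: non-monotone time_s in {phase} phase")
        parts[phase] = block
    n_base, n_resp = len(parts[PHASE_BASELINE]), len(parts[PHASE_RESPONSE])
    if strict and (n_base, n_resp) != expected_points:
        raise DeviceFormatError(
            f"{source}: expected {expected_points[0]} baseline and "
            f"{expected_points[1]} response rows, found {n_base} and {n_resp}"
        )
    if not strict and (n_base, n_resp) != expected_points:
        warnings.warn(
            f"{source}: lenient read accepted {n_base} baseline / {n_resp} response rows",
            stacklevel=2,
        )
    baseline = parts[PHASE_BASELINE][list(CANONICAL_SENSORS)].to_numpy(dtype=float).T
    response = parts[PHASE_RESPONSE][list(CANONICAL_SENSORS)].to_numpy(dtype=float).T
    return BreathSample(
        sample_id=sample_id or source.stem,
        label=label,
        origin=origin,
        sensor_names=CANONICAL_SENSORS,
        baseline=baseline,
        response=response,
        time_grid=parts[PHASE_RESPONSE]["time_s"].to_numpy(dtype=float),
    )


def write_manifest(
    samples: list[BreathSample], directory: str | Path, manifest_name: str = "manifest.csv"
) -> Path:
    """Write each sample's CSV plus a manifest into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for sample in samples:
        fname = f"{sample.sample_id}.csv"
        write_sample_csv(sample, directory / fname)
        entries.append((sample.sample_id, fname, sample.label, sample.origin))
    CohortManifest(entries)  # validate before writing
    manifest_path = directory / manifest_name
    pd.DataFrame(entries, columns=["sample_id", "path", "label", "origin"]).to_csv(
        manifest_path, index=False
    )
    return manifest_path


def read_manifest(
    source: str | Path, strict: bool = True, expected_points: tuple[int, int] = (29, 29)
) -> tuple[CohortManifest, list[BreathSample]]:
    """Read a manifest and all recordings it references, in manifest order.

    Paths are resolved relative to the manifest's directory.  An empty manifest
    yields an empty cohort.
    """
    source = Path(source)
    if not source.exists():
        raise DeviceFormatError(f"manifest not found: {source}")
    df = pd.read_csv(source)
    for col in ("sample_id", "path", "label", "origin"):
        if col not in df.columns:
            raise DeviceFormatError(f"{source}: manifest missing column {col!r}")
    manifest = CohortManifest(
        [tuple(str(v) for v in row) for row in df[["sample_id", "path", "label", "origin"]].itertuples(index=False)]
    )
    samples = []
    for sid, rel, label, origin in manifest.entries:
        path = source.parent / rel
        if not path.exists():
            raise DeviceFormatError(f"manifest references missing file: {path}")
        samples.append(
            read_sample_csv(
                path, sample_id=sid, label=label, origin=origin,
                strict=strict, expected_points=expected_points,
            )
        )
    return manifest, samples
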