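"""Readers/writers, run configuration, and the end-to-end pipeline.

Recordings travel as SNIRF-layout HDF5 (written with h5py: data1 with a
measurementList, probe, stim, and metaDataTags carrying the headband
channel roles); item responses and laterality values as CSV; config
snapshots, summaries, and run manifests as JSON. All writes are atomic
(temp file + rename).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .laterality import epoch, laterality_table, m1_lat, slope_matrix
from .montage import build_montage
from .preprocess import DEFAULT_BANDS, BandDefinition, RawRecording, run_pipeline
from .sem import FitConfig, ModelData, diagnose, fit, summarize
from .simulate import ItemResponses, SimConfig, generate_cohort

log = logging.getLogger("fnirslat")

__all__ = [
    "read_snirf",
    "write_snirf",
    "read_items",
    "write_items",
    "RunConfig",
    "RunManifest",
    "run_all",
]


# ---------------------------------------------------------------------------
# atomic write helpers


def _atomic_write_bytes(path: Path, payload: bytes) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path, text: str) -> None:
    _atomic_write_bytes(Path(path), text.encode())


def write_json(path, obj) -> None:
    atomic_write_text(path, json.dumps(obj, indent=1, sort_keys=True) + "\n")


def write_csv(path, frame: pd.DataFrame) -> None:
    atomic_write_text(path, frame.to_csv(index=False, lineterminator="\n"))


def _hash_file(path) -> str:
    """Content hash: logical for HDF5 (header timestamps vary), bytes otherwise."""
    path = Path(path)
    h = hashlib.sha256()
    if path.suffix in (".h5", ".snirf", ".hdf5"):
        with h5py.File(path, "r") as f:
            names: list[str] = []
            f.visit(names.append)
            for name in sorted(names):
                node = f[name]
                h.update(name.encode())
                if isinstance(node, h5py.Dataset):
                    h.update(np.asarray(node[()]).tobytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# SNIRF


def write_snirf(rec: RawRecording, path) -> None:
    """Write a recording as SNIRF-layout HDF5 (intensities, stim, montage)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as f:
            f.create_dataset("formatVersion", data="1.0")
            nirs = f.create_group("nirs")
            data = nirs.create_group("data1")
            wavelengths = sorted(
                {w for c in rec.montage.channels for w in c.wavelengths}
            )
            n = rec.n_samples
            cols = []
            k = 0
            sources = rec.montage.long_sources + rec.montage.short_sources
            detectors = rec.montage.detectors
            for ci, cid in enumerate(rec.channel_ids):
                ch = rec.montage.channel(cid)
                for wi, w in enumerate(ch.wavelengths):
                    k += 1
                    ml = data.create_group(f"measurementList{k}")
                    ml.create_dataset("sourceIndex", data=sources.index(ch.source) + 1)
                    ml.create_dataset(
                        "detectorIndex", data=detectors.index(ch.detector) + 1
                    )
                    ml.create_dataset(
                        "wavelengthIndex", data=wavelengths.index(w) + 1
                    )
                    ml.create_dataset("dataType", data=1)  # CW amplitude
                    ml.create_dataset("dataTypeIndex", data=1)
                    cols.append(rec.intensity[ci, wi])
            data.create_dataset(
                "dataTimeSeries", data=np.column_stack(cols), dtype="f8"
            )
            data.create_dataset("time", data=np.arange(n) / rec.fs, dtype="f8")
            probe = nirs.create_group("probe")
            probe.create_dataset("wavelengths", data=np.asarray(wavelengths, float))
            probe.create_dataset("sourceLabels", data=np.array(sources, dtype="S"))
            probe.create_dataset("detectorLabels", data=np.array(detectors, dtype="S"))
            stim = nirs.create_group("stim1")
            stim.create_dataset("name", data="task")
            stim.create_dataset(
                "data",
                data=np.column_stack(
                    [rec.events, np.full_like(rec.events, rec.task_s),
                     np.ones_like(rec.events)]
                ),
            )
            meta = nirs.create_group("metaDataTags")
            meta.create_dataset("SubjectID", data=rec.participant_id)
            meta.create_dataset("MeasurementDate", data="unknown")
            meta.create_dataset("MeasurementTime", data="unknown")
            meta.create_dataset("LengthUnit", data="cm")
            meta.create_dataset("TimeUnit", data="s")
            meta.create_dataset("FrequencyUnit", data="Hz")
            meta.create_dataset("LesionSide", data=rec.lesion_side)
            meta.create_dataset("TaskDuration", data=float(rec.task_s))
            meta.create_dataset("SampleRate", data=float(rec.fs))
            meta.create_dataset(
                "ChannelIDs", data=np.array(rec.channel_ids, dtype="S")
            )
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _read_str(ds) -> str:
    val = ds[()]
    return val.decode() if isinstance(val, bytes) else str(val)


def read_snirf(path) -> RawRecording:
    """Read a recording written by :func:`write_snirf`.

    The montage is rebuilt from the headband definition and checked
    against the stored channel list; missing stimulus information or
    non-positive intensities raise.
    """
    mont = build_montage()
    try:
        handle = h5py.File(path, "r")
    except OSError as err:
        raise ValueError(f"unreadable SNIRF file {path}: {err}") from err
    with handle as f:
        try:
            nirs = f["nirs"]
            data = nirs["data1"]
            series = np.asarray(data["dataTimeSeries"])
            time = np.asarray(data["time"])
            meta = nirs["metaDataTags"]
            channel_ids = [s.decode() for s in meta["ChannelIDs"][()]]
        except KeyError as err:
            raise ValueError(f"not a recognizable SNIRF recording: {err}") from err
        if "stim1" not in nirs:
            raise ValueError("SNIRF file has no stimulus block")
        stim = np.asarray(nirs["stim1"]["data"])
        if time.size != series.shape[0]:
            raise ValueError("time vector does not match data series")
        fs = float(meta["SampleRate"][()]) if "SampleRate" in meta else float(
            1.0 / np.median(np.diff(time))
        )
        known = {c.id for c in mont.channels}
        if set(channel_ids) != known:
            raise ValueError("stored channels do not match the headband montage")
        n = series.shape[0]
        intensity = np.empty((len(channel_ids), 2, n))
        k = 0
        for ci in range(len(channel_ids)):
            for wi in range(2):
                intensity[ci, wi] = series[:, k]
                k += 1
        return RawRecording(
            montage=mont,
            channel_ids=channel_ids,
            intensity=intensity,
            fs=fs,
            events=stim[:, 0],
            task_s=float(meta["TaskDuration"][()]),
            participant_id=_read_str(meta["SubjectID"]),
            lesion_side=_read_str(meta["LesionSide"]),
        )


# ---------------------------------------------------------------------------
# item tables


def write_items(items: ItemResponses, path) -> None:
    write_csv(path, items.table)


def read_items(path) -> ItemResponses:
    table = pd.read_csv(path)
    return ItemResponses(table)


# ---------------------------------------------------------------------------
# run configuration / orchestration


@dataclass
class RunConfig:
    out_dir: str = "fnirslat_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    bands: dict = field(
        default_factory=lambda: {
            name: [b.low, b.high] for name, b in DEFAULT_BANDS.items()
        }
    )
    dpf: tuple = (6.0, 6.0)
    filter_order: int = 4
    shift_targets: bool = False
    mcmc: FitConfig = field(default_factory=FitConfig)
    ess_floor: float = 100.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            if "pair_loadings" in self.sim:
                self.sim["pair_loadings"] = tuple(self.sim["pair_loadings"])
            self.sim = SimConfig(**self.sim)
        if isinstance(self.mcmc, dict):
            self.mcmc = FitConfig(**self.mcmc)
        # one seed drives everything unless sub-seeds were set explicitly
        self.sim = dataclasses.replace(self.sim, seed=self.sim.seed or self.seed)
        self.mcmc = dataclasses.replace(
            self.mcmc, seed=self.mcmc.seed or self.seed + 1
        )

    def band_definitions(self) -> dict[str, BandDefinition]:
        return {
            name: BandDefinition(name, lo, hi)
            for name, (lo, hi) in self.bands.items()
        }

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        payload = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        return cls(**payload)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dpf"] = [float(x) for x in self.dpf]
        d["sim"]["pair_loadings"] = [float(x) for x in self.sim.pair_loadings]
        return d


@dataclass
class RunManifest:
    stages: list[str]
    hashes: dict[str, str]
    started: str
    finished: str
    version: str
    diagnostics_passed: bool

    def to_dict(self) -> dict:
        return asdict(self)


def run_all(config: RunConfig) -> RunManifest:
    """simulate -> preprocess -> laterality -> fit -> summarize, with
    outputs, a config snapshot, and a manifest written to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    stages: list[str] = []
    outputs: list[Path] = []

    def stage(name: str):
        log.info("stage %s", name)
        stages.append(name)

    try:
        stage("simulate")
        recordings, items, truth = generate_cohort(config.sim)
        for rec in recordings:
            p = out / f"{rec.participant_id}.snirf"
            write_snirf(rec, p)
            outputs.append(p)
        write_items(items, out / "items.csv")
        truth.to_json(out / "truth.json")
        outputs += [out / "items.csv", out / "truth.json"]

        stage("preprocess")
        bands = config.band_definitions()
        cleans = [
            run_pipeline(
                rec,
                bands=bands,
                dpf=tuple(config.dpf),
                filter_order=config.filter_order,
                shift_targets=config.shift_targets,
            )
            for rec in recordings
        ]

        stage("laterality")
        records = []
        for clean in cleans:
            slopes = slope_matrix(epoch(clean))
            records.append(
                m1_lat(
                    slopes,
                    clean.channel_ids,
                    clean.montage,
                    clean.lesion_side,
                    clean.participant_id,
                )
            )
        lat = laterality_table(records)
        write_csv(out / "m1lat.csv", lat)
        meta = pd.DataFrame(
            {
                "participant_id": truth.participant_ids,
                "lesion_side": truth.lesion_sides,
            }
        )
        write_csv(out / "meta.csv", meta)
        outputs += [out / "m1lat.csv", out / "meta.csv"]

        stage("fit")
        data = ModelData.from_tables(items, lat)
        posterior = fit(data, config.mcmc)
        write_csv(out / "posterior.csv", posterior.to_dataframe())
        outputs.append(out / "posterior.csv")

        stage("summarize")
        report = diagnose(posterior, ess_floor=config.ess_floor)
        summary = summarize(posterior)
        summary["diagnostics"] = report.to_dict()
        summary["usable"] = bool(report.passed)
        write_json(out / "summary.json", summary)
        outputs.append(out / "summary.json")
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed during stage '{stages[-1] if stages else '?'}': {err}"
        ) from err

    # the snapshot carries run-local metadata (paths), so it is written
    # beside the outputs but not hashed into the manifest
    write_json(out / "config_snapshot.json", config.to_dict())
    manifest = RunManifest(
        stages=stages,
        hashes={p.name: _hash_file(p) for p in outputs},
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
        version=__version__,
        diagnostics_passed=bool(report.passed),
    )
    write_json(out / "manifest.json", manifest.to_dict())
    return manifest
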