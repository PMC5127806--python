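"""Dataset and model persistence.

Two on-disk dataset layouts are supported:

* **HDF5** — one file with groups ``stimulus`` and ``response`` holding a
  dataset per trial (``trial000``, ``trial001``, ...) and the sampling
  rate as a root attribute.  Written with ``track_times=False`` so the
  same data always produce byte-identical files.
* **Delimited** — a directory of per-trial TSV matrices (time in rows,
  variables in columns) plus a ``dataset.json`` sidecar carrying the
  sampling rate and trial order.

Fitted models round-trip through a small HDF5 container holding weights,
bias, the ridge parameter, lag window, direction and package version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from . import __version__
from .exceptions import InvalidArgumentError, TRFError
from .lagmat import LagSpec
from .regress import TRFModel

__all__ = [
    "DatasetBundle",
    "save_dataset",
    "load_dataset",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

_SIDECAR = "dataset.json"


@dataclass
class DatasetBundle:
    """Aligned multi-trial stimulus and response time series."""

    stimuli: list[np.ndarray]
    responses: list[np.ndarray]
    fs: float
    trial_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.stimuli) != len(self.responses):
            raise InvalidArgumentError(
                f"{len(self.stimuli)} stimuli but {len(self.responses)} responses"
            )
        if len(self.stimuli) == 0:
            raise InvalidArgumentError("empty dataset: no trials")
        if self.fs <= 0:
            raise InvalidArgumentError(f"fs must be positive, got {self.fs}")
        if not self.trial_ids:
            self.trial_ids = [f"trial{i:03d}" for i in range(len(self.stimuli))]
        if len(self.trial_ids) != len(self.stimuli):
            raise InvalidArgumentError("trial_ids length does not match trial count")
        self.stimuli = [np.atleast_2d(np.asarray(s, dtype=float).T).T if np.asarray(s).ndim == 1
                        else np.asarray(s, dtype=float) for s in self.stimuli]
        self.responses = [np.atleast_2d(np.asarray(r, dtype=float).T).T if np.asarray(r).ndim == 1
                          else np.asarray(r, dtype=float) for r in self.responses]
        bad = [tid for tid, s, r in zip(self.trial_ids, self.stimuli, self.responses)
               if s.shape[0] != r.shape[0]]
        if bad:
            raise InvalidArgumentError(
                "stimulus/response length mismatch in trial(s): " + ", ".join(bad)
            )

    @property
    def n_trials(self) -> int:
        return len(self.stimuli)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("hdf5", "delimited"):
            raise InvalidArgumentError(f"unknown format: {fmt!r}")
        return fmt
    if path.is_dir() or path.suffix == "":
        return "delimited"
    return "hdf5"


def save_dataset(bundle: DatasetBundle, path: str | Path, fmt: str | None = None,
                 kernel: np.ndarray | None = None) -> None:
    """Write a dataset; optionally store a ground-truth kernel alongside
    (HDF5 only)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "hdf5":
        with h5py.File(path, "w", track_order=True) as f:
            f.attrs["fs"] = bundle.fs
            f.attrs["trial_ids"] = [tid.encode() for tid in bundle.trial_ids]
            gs = f.create_group("stimulus", track_order=True)
            gr = f.create_group("response", track_order=True)
            for tid, s, r in zip(bundle.trial_ids, bundle.stimuli, bundle.responses):
                gs.create_dataset(tid, data=s, track_times=False)
                gr.create_dataset(tid, data=r, track_times=False)
            if kernel is not None:
                f.create_dataset("kernel", data=np.asarray(kernel, dtype=float),
                                 track_times=False)
        return
    path.mkdir(parents=True, exist_ok=True)
    for tid, s, r in zip(bundle.trial_ids, bundle.stimuli, bundle.responses):
        np.savetxt(path / f"{tid}_stimulus.tsv", s, delimiter="\t", fmt="%.17g")
        np.savetxt(path / f"{tid}_response.tsv", r, delimiter="\t", fmt="%.17g")
    (path / _SIDECAR).write_text(json.dumps(
        {"fs": bundle.fs, "trial_ids": bundle.trial_ids}, indent=2) + "\n")


def load_dataset(path: str | Path, fmt: str | None = None) -> DatasetBundle:
    """Read a dataset written by :func:`save_dataset`.

    Raises a validation error naming the offending trials on length
    mismatch, and a config-required error if the sampling rate is absent.
    """
    path = Path(path)
    if not path.exists():
        raise TRFError(f"no such dataset: {path}")
    fmt = _infer_format(path, fmt)
    if fmt == "hdf5":
        try:
            h = h5py.File(path, "r")
        except OSError as exc:
            raise TRFError(f"{path}: cannot read dataset container ({exc})") from exc
        with h as f:
            if "fs" not in f.attrs:
                raise TRFError(f"{path}: missing required 'fs' attribute")
            fs = float(f.attrs["fs"])
            if "stimulus" not in f or "response" not in f:
                raise TRFError(f"{path}: empty dataset (no stimulus/response groups)")
            ids = [t.decode() if isinstance(t, bytes) else str(t)
                   for t in f.attrs.get("trial_ids", list(f["stimulus"].keys()))]
            stimuli = [f["stimulus"][t][()] for t in ids]
            responses = [f["response"][t][()] for t in ids]
        return DatasetBundle(stimuli=stimuli, responses=responses, fs=fs, trial_ids=ids)
    sidecar = path / _SIDECAR
    if not sidecar.exists():
        raise TRFError(
            f"{path}: missing {_SIDECAR} sidecar (the sampling rate is required)"
        )
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise TRFError(f"{sidecar}: missing required 'fs' entry")
    ids = meta.get("trial_ids")
    if not ids:
        raise TRFError(f"{path}: empty dataset (no trials listed)")
    stimuli = [np.atleast_2d(np.loadtxt(path / f"{tid}_stimulus.tsv", ndmin=2))
               for tid in ids]
    responses = [np.atleast_2d(np.loadtxt(path / f"{tid}_response.tsv", ndmin=2))
                 for tid in ids]
    return DatasetBundle(stimuli=stimuli, responses=responses, fs=float(meta["fs"]),
                         trial_ids=list(ids))


def save_model(model: TRFModel, path: str | Path) -> None:
    """Persist a fitted model to an HDF5 container."""
    with h5py.File(Path(path), "w", track_order=True) as f:
        f.attrs["format"] = "trflab-model"
        f.attrs["version"] = __version__
        f.attrs["direction"] = model.direction
        f.attrs["lambda"] = model.lam
        f.attrs["tmin_ms"] = model.lagspec.tmin_ms
        f.attrs["tmax_ms"] = model.lagspec.tmax_ms
        f.attrs["fs"] = model.lagspec.fs
        f.create_dataset("weights", data=model.weights, track_times=False)
        f.create_dataset("bias", data=model.bias, track_times=False)


def load_model(path: str | Path) -> TRFModel:
    """Load a model saved by :func:`save_model`; warns on version skew."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "trflab-model":
                raise TRFError(f"{path}: not a trflab model container")
            if f.attrs.get("version") != __version__:
                logger.warning("%s: saved by trflab %s, loading with %s",
                               path, f.attrs.get("version"), __version__)
            spec = LagSpec(float(f.attrs["tmin_ms"]), float(f.attrs["tmax_ms"]),
                           float(f.attrs["fs"]))
            return TRFModel(direction=str(f.attrs["direction"]),
                            weights=f["weights"][()], bias=f["bias"][()],
                            lam=float(f.attrs["lambda"]), lagspec=spec)
    except OSError as exc:
        raise TRFError(f"{path}: cannot read model container ({exc})") from exc
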