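"""Epoch containers, run configuration and the experiment driver.

The on-disk epoch container is a small HDF5 layout (schema ``bsblsel-epochs``
v1) holding the feature matrix, labels, block structure, channel names and,
when present, the speller metadata.  Reading and writing round-trip
bit-exactly.  :func:`run_experiment` executes the full simulate/load ->
select -> train -> evaluate chain described by a :class:`RunConfig` and
writes a machine-readable summary stamped with the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .blocks import BlockStructure, EpochDataset
from .blda import BLDA
from .bsbl import FitConfig, RegionalBSBL
from .pipeline import SpellerLayout, accuracy, decode_session
from .regions import (RegionMap, builtin_region_map, load_montage,
                      load_region_map, standard_montage)
from .simulate import P300SimSpec, gen_p300_session

logger = logging.getLogger(__name__)

SCHEMA = "bsblsel-epochs"
SCHEMA_VERSION = 1

__all__ = ["write_epochs", "read_epochs", "RunConfig", "run_experiment"]


def write_epochs(path, dataset: EpochDataset) -> None:
    """Write an :class:`EpochDataset` (plus speller metadata) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA
        f.attrs["schema_version"] = SCHEMA_VERSION
        if dataset.sampling_rate is not None:
            f.attrs["sampling_rate"] = float(dataset.sampling_rate)
        f.create_dataset("features", data=dataset.features)
        f.create_dataset("labels", data=dataset.labels)
        f.create_dataset("block_sizes",
                         data=np.asarray(dataset.structure.block_sizes))
        f.create_dataset("channel_names",
                         data=np.array(dataset.channel_names, dtype="S"))
        for name in ("codes", "trial", "epoch"):
            arr = getattr(dataset, name)
            if arr is not None:
                f.create_dataset(name, data=arr)
        if dataset.true_chars is not None:
            f.create_dataset("true_chars",
                             data=np.array(dataset.true_chars, dtype="S"))


def read_epochs(path) -> EpochDataset:
    """Read an epoch container; validates schema and invariants."""
    with h5py.File(path, "r") as f:
        schema = f.attrs.get("schema")
        version = int(f.attrs.get("schema_version", -1))
        if schema != SCHEMA or version != SCHEMA_VERSION:
            raise ValueError(
                f"unrecognised container schema {schema!r} v{version} "
                f"(expected {SCHEMA!r} v{SCHEMA_VERSION})")
        labels = f["labels"][:]
        if set(np.unique(labels)) <= {0.0, 1.0}:
            logger.info("coercing {1,0} labels to {+1,-1}")
        kw = {}
        for name in ("codes", "trial", "epoch"):
            if name in f:
                kw[name] = f[name][:]
        if "true_chars" in f:
            kw["true_chars"] = [s.decode() for s in f["true_chars"][:]]
        return EpochDataset(
            features=f["features"][:], labels=labels,
            structure=BlockStructure(tuple(int(s) for s in f["block_sizes"][:])),
            channel_names=[s.decode() for s in f["channel_names"][:]],
            sampling_rate=(float(f.attrs["sampling_rate"])
                           if "sampling_rate" in f.attrs else None), **kw)


@dataclass
class RunConfig:
    """Declarative description of one channel-selection experiment.

    Either ``data`` points at an epoch container, or ``simulate`` holds
    keyword arguments for :class:`~bsblsel.simulate.P300SimSpec`.  ``fit``
    mirrors :class:`~bsblsel.bsbl.FitConfig` field names.  ``mode`` is
    ``auto`` (tau-thresholded selection) or ``fixed_m`` (top-M with
    backfill, M from ``m``).
    """

    output_dir: str = "results"
    data: str | None = None
    simulate: dict = field(default_factory=dict)
    montage: str | None = None           # path, or None for the built-in
    region_map: str | None = None        # path, or None for the built-in
    fit: dict = field(default_factory=dict)
    mode: str = "auto"
    m: int | None = None
    n_epochs_used: int | None = None
    train_characters: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "fixed_m"):
            raise ValueError("mode must be 'auto' or 'fixed_m'")
        if self.mode == "fixed_m" and not self.m:
            raise ValueError("mode='fixed_m' requires m")
        FitConfig(**self.fit)  # validate early

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = cls(**(yaml.safe_load(Path(path).read_text()) or {}))
        for key in ("data", "montage", "region_map"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config field {key!r}: {p} not found")
        return cfg

    def digest(self) -> str:
        """Hash of the result-determining fields (output_dir excluded)."""
        d = asdict(self)
        d.pop("output_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _resolve_inputs(config: RunConfig):
    if config.data:
        dataset = read_epochs(config.data)
        if config.montage:
            montage = load_montage(config.montage)
        else:
            montage = standard_montage(dataset.n_channels)
    else:
        sim_kw = dict(config.simulate)
        sim_kw.setdefault("seed", config.seed)
        spec = P300SimSpec(**sim_kw)
        dataset, _ = gen_p300_session(spec)
        montage = spec.montage or standard_montage(spec.n_channels)
    if config.region_map:
        regions = load_region_map(config.region_map, montage)
    else:
        regions = builtin_region_map(montage)
    return dataset, montage, regions


def run_experiment(config: RunConfig) -> dict:
    """Execute simulate/load -> select -> train -> evaluate; write outputs.

    The dataset's trials are split by character: the first
    ``train_characters`` fraction trains selection and the classifier, the
    rest is decoded and scored.  Outputs (selection table, EM trace,
    summary.json) land in ``output_dir``; the summary carries the config
    hash and seed so identical configs reproduce identical files.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        dataset, montage, regions = _resolve_inputs(config)
    except Exception as err:
        raise RuntimeError(f"[stage: inputs] {err}") from err

    if dataset.trial is None or dataset.true_chars is None:
        raise RuntimeError("[stage: split] dataset lacks trial metadata; "
                           "run_experiment needs a speller session")
    trials = sorted(set(dataset.trial.tolist()))
    n_train = max(1, int(round(config.train_characters * len(trials))))
    if n_train >= len(trials):
        raise RuntimeError("[stage: split] no test characters left")
    train_mask = np.isin(dataset.trial, trials[:n_train])
    X, y = dataset.features, dataset.labels

    try:
        fit_kw = dict(config.fit)
        fit_kw.setdefault("seed", config.seed)
        cfgf = FitConfig(**fit_kw)
        sel = RegionalBSBL(
            n_times=dataset.n_times, regions=regions, tau=cfgf.tau,
            b_mode=cfgf.b_mode, max_iter=cfgf.max_iter, tol=cfgf.tol,
            max_prune_per_iter=cfgf.max_prune_per_iter,
            ar_clamp=cfgf.ar_clamp, sigma2_floor=cfgf.sigma2_floor,
            n_select=config.m if config.mode == "fixed_m" else None,
            seed=cfgf.seed)
        sel.fit(X[train_mask], y[train_mask],
                channel_names=dataset.channel_names)
    except Exception as err:
        raise RuntimeError(f"[stage: selection] {err}") from err

    try:
        clf = BLDA().fit(sel.transform(X[train_mask]), y[train_mask])
    except Exception as err:
        raise RuntimeError(f"[stage: classifier] {err}") from err

    try:
        test_mask = ~train_mask
        test_ds = EpochDataset(
            features=X[test_mask], labels=y[test_mask],
            structure=dataset.structure, channel_names=dataset.channel_names,
            sampling_rate=dataset.sampling_rate,
            codes=dataset.codes[test_mask], trial=dataset.trial[test_mask],
            epoch=dataset.epoch[test_mask])
        scores = clf.decision_function(sel.transform(X[test_mask]))
        predicted = decode_session(scores, test_ds,
                                   n_epochs_used=config.n_epochs_used)
        true = [dataset.true_chars[t] for t in trials[n_train:]]
        acc = accuracy(predicted, true)
    except Exception as err:
        raise RuntimeError(f"[stage: evaluation] {err}") from err

    sel.selection_.table().to_csv(out / "selection.csv", index=False)
    sel.result_.trace_table().to_csv(out / "trace.csv", index=False)
    summary = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "mode": config.mode,
        "accuracy_percent": acc,
        "n_selected": int(len(sel.selected_channels_)),
        "selected_channels": [dataset.channel_names[c]
                              for c in sel.selected_channels_],
        "n_iterations": int(sel.n_iter_),
        "sigma2": float(sel.sigma2_),
        "status": sel.result_.status,
        "predicted": predicted,
        "true": true,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True) + "\n")
    return summary
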